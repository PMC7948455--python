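"""Umbrella screening workflow: simulate (or load) -> fit -> FRET ->
interference -> hit calling -> counter-screen triage -> summaries.

:func:`run_screen_workflow` executes the full decision flow of a
lifetime-FRET screen on one plate trio (primary FRET plate, donor-only
interference plate, free-acceptor counter plate) and writes every stage
output plus a reconciled JSON run report into the output directory. The
same configuration and seed reproduce identical stage outputs.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .config import ScreenConfig, SimConfig
from .decay import InstrumentResponse, fit_plate
from .fret import donor_reference, fret_table
from .io import (
    read_plate_map,
    read_spectra,
    read_waveforms,
    write_fits,
    write_plate_map,
    write_spectra,
    write_waveforms,
)
from .layout import PlateLayout, make_lopac_layout, make_uniform_layout
from .screen import call_hits, flag_interference, triage_with_counter
from .simulate import CompoundEffect, simulate_plate

logger = logging.getLogger("fltscreen")


class PlantedEffects(BaseModel):
    """How many of each non-inert effect class the simulator plants.

    Planted compounds are spread evenly over the compound list; all other
    compounds are inert. Magnitudes are chosen to be unambiguous at the
    default photon budget: modulators remove all specific FRET at the
    screening concentration, interferers shift the donor lifetime by
    ``interferer_shift_ns`` and contaminate the spectrum, cytotoxic
    compounds lose ``viability_loss`` of both FRET components.
    """

    n_modulators: int = Field(default=8, ge=0)
    n_interferers: int = Field(default=2, ge=0)
    n_cytotoxic: int = Field(default=2, ge=0)
    modulator_ec50_uM: float = 0.1
    interferer_shift_ns: float = 0.15
    interferer_contaminant: float = 0.3
    viability_loss: float = 0.9
    effect_time_constant_min: float = 30.0


class RunConfig(BaseModel):
    """Configuration of one end-to-end screening run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    plate_format: int = 1536
    timepoint_min: float = 120.0
    sim: SimConfig = SimConfig()
    screen: ScreenConfig = ScreenConfig()
    planted: PlantedEffects = PlantedEffects()
    # used when simulate is False
    layout_path: Optional[str] = None
    primary_waveforms: Optional[str] = None
    donor_waveforms: Optional[str] = None
    counter_waveforms: Optional[str] = None
    donor_spectra: Optional[str] = None
    log_level: str = "INFO"


class RunReport(BaseModel):
    """Reconciled record of an executed run."""

    version: str
    config: Dict
    started: str
    finished: str
    wells_per_plate: int
    fits_converged: Dict[str, int]
    fits_failed: Dict[str, int]
    compounds_total: int
    compounds_flagged: int
    n_hits: int
    hit_rate_pct: float
    n_candidates: int
    n_undesired: int
    n_unclassified: int

    def reconcile(self) -> None:
        """Raise if stage counts are mutually inconsistent."""
        for plate, conv in self.fits_converged.items():
            if conv + self.fits_failed[plate] != self.wells_per_plate:
                raise ValueError(f"plate {plate}: fits do not sum to well count")
        if self.n_hits > self.compounds_total - self.compounds_flagged:
            raise ValueError("more hits than unflagged compounds")
        if self.n_candidates + self.n_undesired + self.n_unclassified != self.n_hits:
            raise ValueError("triage classes do not sum to hit count")


def _planted_effects(layout: PlateLayout, planted: PlantedEffects) -> Dict[str, CompoundEffect]:
    ids = layout.compound_ids()
    effects: Dict[str, CompoundEffect] = {cid: CompoundEffect() for cid in ids}
    wanted = [
        (
            "modulator",
            planted.n_modulators,
            dict(
                max_fret_change=1.0,
                ec50=planted.modulator_ec50_uM,
                effect_time_constant=planted.effect_time_constant_min,
            ),
        ),
        (
            "interferer",
            planted.n_interferers,
            dict(
                donor_lifetime_shift=planted.interferer_shift_ns,
                spectral_contaminant_fraction=planted.interferer_contaminant,
            ),
        ),
        (
            "cytotoxic",
            planted.n_cytotoxic,
            dict(
                viability_loss=planted.viability_loss,
                effect_time_constant=planted.effect_time_constant_min,
            ),
        ),
    ]
    n_special = sum(n for _, n, _ in wanted)
    if n_special > len(ids):
        raise ValueError("more planted effects than compound wells")
    step = max(len(ids) // max(n_special, 1), 1)
    pos = 0
    for klass, n, kwargs in wanted:
        for _ in range(n):
            effects[ids[pos % len(ids)]] = CompoundEffect(effect_class=klass, **kwargs)
            pos += step
    return effects


def run_screen_workflow(config: RunConfig) -> RunReport:
    """Run the full screen flow; writes all stage outputs under ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    irf = InstrumentResponse.gaussian(config.sim.irf_center, config.sim.irf_width_sigma)

    truth_hits: set = set()
    if config.simulate:
        if config.plate_format == 1536:
            layout = make_lopac_layout()
        else:
            layout = make_uniform_layout(
                config.plate_format, dmso_columns=(1, 2, 23, 24)
            )
        effects = _planted_effects(layout, config.planted)
        plates = {}
        for i, assay in enumerate(("primary", "donor_only", "counter")):
            sim = simulate_plate(
                layout,
                effects,
                config.sim,
                timepoint_min=config.timepoint_min,
                assay=assay,
                seed=config.seed + i,
            )
            plates[assay] = sim
            write_waveforms(sim.waveforms, out / f"{assay}_waveforms.tsv")
            sim.truth.to_csv(out / f"{assay}_truth.csv", index=False)
        write_plate_map(layout, out / "plate_map.csv")
        write_spectra(plates["donor_only"].spectra, out / "donor_spectra.csv")
        waveforms = {k: p.waveforms for k, p in plates.items()}
        donor_spectra = plates["donor_only"].spectra
        truth_hits = set(
            plates["primary"]
            .truth.query("effect_class == 'modulator' and role == 'compound'")["compound_id"]
        )
    else:
        needed = {
            "layout_path": config.layout_path,
            "primary_waveforms": config.primary_waveforms,
            "donor_waveforms": config.donor_waveforms,
        }
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValueError(
                f"simulate is disabled but required inputs are missing: {missing}"
            )
        layout = read_plate_map(config.layout_path)
        waveforms = {
            "primary": read_waveforms(config.primary_waveforms),
            "donor_only": read_waveforms(config.donor_waveforms),
        }
        if config.counter_waveforms:
            waveforms["counter"] = read_waveforms(config.counter_waveforms)
        donor_spectra = read_spectra(config.donor_spectra) if config.donor_spectra else None

    # stage: lifetime fits
    fits: Dict[str, pd.DataFrame] = {}
    fits_converged: Dict[str, int] = {}
    fits_failed: Dict[str, int] = {}
    for assay, plate in waveforms.items():
        df = fit_plate(plate, irf)
        fits[assay] = df
        fits_converged[assay] = int(df["converged"].sum())
        fits_failed[assay] = int((~df["converged"]).sum())
        write_fits(df, out / f"{assay}_fits.csv")
        logger.info("fitted %s plate: %d/%d converged", assay, fits_converged[assay], len(df))

    # stage: FRET efficiencies against the donor-only reference
    tau_d_ref = donor_reference(fits["donor_only"], layout)
    fret = fret_table(fits["primary"], tau_d_ref)
    fret.to_csv(out / "primary_fret.csv", index=False)

    # stage: interference screen (mandatory before hit calls)
    flags = flag_interference(fits["donor_only"], donor_spectra, layout, config.screen)
    flags.to_csv(out / "interference_flags.csv", index=False)
    for cid in flags.loc[flags["flagged"], "compound_id"]:
        logger.warning("compound %s excluded: interference", cid)

    # stage: hit calling and triage
    primary = call_hits(fits["primary"], layout, flags, config.screen)
    primary.compounds.to_csv(out / "screen_results.csv", index=False)
    if "counter" in fits:
        counter = call_hits(fits["counter"], layout, flags, config.screen)
        triage = triage_with_counter(primary, counter)
    else:
        triage = pd.DataFrame(
            {
                "compound_id": sorted(primary.hit_ids),
                "primary_delta_sd": pd.NA,
                "counter_delta_sd": pd.NA,
                "classification": "unclassified",
                "reason": "no counter screen",
            }
        )
    triage.to_csv(out / "triage.csv", index=False)

    summary = pd.DataFrame(
        [
            {
                "timepoint_min": config.timepoint_min,
                "n_compounds": primary.n_compound_wells,
                "n_flagged": primary.n_flagged,
                "n_hits": primary.n_hits,
                "hit_rate_pct": primary.hit_rate_pct,
                "mu_dmso_ns": primary.mu_dmso,
                "sd_dmso_ns": primary.sd_dmso,
            }
        ]
    )
    summary.to_csv(out / "summary.csv", index=False)
    if truth_hits:
        recovered = truth_hits & primary.hit_ids
        logger.info(
            "planted modulators recovered as hits: %d/%d", len(recovered), len(truth_hits)
        )

    cls_counts = triage["classification"].value_counts().to_dict() if len(triage) else {}
    report = RunReport(
        version=__version__,
        config=config.model_dump(),
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        wells_per_plate=len(layout),
        fits_converged=fits_converged,
        fits_failed=fits_failed,
        compounds_total=primary.n_compound_wells,
        compounds_flagged=primary.n_flagged,
        n_hits=primary.n_hits,
        hit_rate_pct=primary.hit_rate_pct,
        n_candidates=int(cls_counts.get("candidate", 0)),
        n_undesired=int(cls_counts.get("undesired", 0)),
        n_unclassified=int(cls_counts.get("unclassified", 0)),
    )
    report.reconcile()
    (out / "run_report.json").write_text(json.dumps(report.model_dump(), indent=2))
    return report
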