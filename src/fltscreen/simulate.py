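"""Synthetic fluorescence-lifetime FRET plates with known ground truth.

Emulates the statistical structure of a lifetime-based FRET screen in
1536-well (or reduced 384-well) plates: per-well photon-count decay
waveforms with Poisson counting noise, two-band emission spectra, and
compound effect classes —

* ``inert``        — no effect (the null the SD thresholds are calibrated on);
* ``modulator``    — removes a dose- and time-dependent fraction of the
  *specific* (actin-tethered) FRET, the effect class a true binding
  disrupter such as an actin-severing tool compound produces;
* ``interferer``   — intrinsically fluorescent compound: shifts the apparent
  donor-only lifetime and contaminates the emission spectrum without touching
  the interaction;
* ``cytotoxic``    — scales specific *and* nonspecific FRET toward zero
  (cell lysis abolishes both);
* ``aggregator``   — modelled identically to ``cytotoxic`` on the optical
  readout; distinguished in secondary sedimentation assays, not here.

Every generator takes an explicit seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .decay import DecayWaveform, InstrumentResponse, PlateWaveforms
from .layout import PlateLayout

__all__ = [
    "CompoundEffect",
    "TitrationModel",
    "SimulatedPlate",
    "simulate_decay",
    "simulate_plate",
    "simulate_titration",
    "simulate_dose_series",
    "simulate_fitted_tau_plate",
    "hill_fraction",
    "time_ramp",
    "SPECTRAL_BANDS",
]

EFFECT_CLASSES = ("inert", "modulator", "interferer", "cytotoxic", "aggregator")

#: emission bands carried per well: donor (~510 nm), acceptor (~600 nm) and an
#: intermediate band where compound autofluorescence shows up (~560 nm).
SPECTRAL_BANDS = ("donor_510", "contaminant_560", "acceptor_600")

# relative band intensities of a clean donor-only well
_BASE_SPECTRUM = np.array([1.0, 0.05, 0.08])
# band profile of a fluorescent contaminant
_CONTAMINANT_SPECTRUM = np.array([0.3, 0.5, 0.2])


@dataclass(frozen=True)
class CompoundEffect:
    """Ground-truth effect of one compound on the assay.

    ``max_fret_change`` is the fraction of the specific FRET removed at
    saturating concentration (modulators); ``viability_loss`` scales both
    FRET components toward zero (cytotoxic/aggregator); interferers shift
    the donor lifetime by ``donor_lifetime_shift`` ns and mix a
    ``spectral_contaminant_fraction`` of a foreign band profile into the
    emission spectrum. ``effect_time_constant`` (minutes) controls the
    saturating-exponential onset of the modulator/viability effects.
    """

    effect_class: str = "inert"
    max_fret_change: float = 0.0
    ec50: float = 1.0
    hill_slope: float = 1.0
    donor_lifetime_shift: float = 0.0
    spectral_contaminant_fraction: float = 0.0
    viability_loss: float = 0.0
    effect_time_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown effect class {self.effect_class!r}; expected one of {EFFECT_CLASSES}"
            )
        for name in ("max_fret_change", "spectral_contaminant_fraction", "viability_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.effect_class == "inert":
            if (
                self.max_fret_change != 0
                or self.donor_lifetime_shift != 0
                or self.spectral_contaminant_fraction != 0
                or self.viability_loss != 0
            ):
                raise ValueError("inert compounds must have all effect magnitudes zero")


def hill_fraction(concentration: float, ec50: float, hill_slope: float) -> float:
    """Fractional occupancy c^n / (c^n + ec50^n); 0 at c=0, 1/2 at c=ec50."""
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if concentration == 0:
        return 0.0
    # log-space ratio avoids overflow at extreme concentration/ec50 ratios
    r = hill_slope * (np.log(ec50) - np.log(concentration))
    return float(1.0 / (1.0 + np.exp(r)))


def time_ramp(timepoint_min: float, time_constant_min: float) -> float:
    """Saturating-exponential effect onset: 1 - exp(-t/tc); 1 for tc = 0."""
    if time_constant_min <= 0:
        return 1.0
    return float(1.0 - np.exp(-timepoint_min / time_constant_min))


def effective_fret(
    effect: CompoundEffect,
    concentration: float,
    timepoint_min: float,
    e_specific: float,
    e_nonspecific: float,
) -> Tuple[float, float]:
    """Apply a compound's effect to the (specific, nonspecific) FRET pair."""
    ramp = time_ramp(timepoint_min, effect.effect_time_constant)
    e_s, e_n = e_specific, e_nonspecific
    if effect.effect_class == "modulator":
        occ = hill_fraction(concentration, effect.ec50, effect.hill_slope)
        e_s = e_s * (1.0 - effect.max_fret_change * occ * ramp)
    elif effect.effect_class in ("cytotoxic", "aggregator"):
        loss = effect.viability_loss * ramp
        e_s = e_s * (1.0 - loss)
        e_n = e_n * (1.0 - loss)
    return e_s, e_n


def simulate_decay(
    lifetime: float,
    counts: float,
    config: SimConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    noiseless: bool = False,
) -> DecayWaveform:
    """Simulate one well's photon-count decay histogram.

    The expected histogram is the IRF-convolved exponential normalized so the
    window's expected total equals ``counts``; each bin is then an
    independent Poisson draw (or the expectation itself when ``noiseless``).
    """
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    if counts <= 0:
        raise ValueError("counts must be positive")
    t = config.time_grid()
    irf = InstrumentResponse.gaussian(config.irf_center, config.irf_width_sigma)
    shape = irf.decay_shape(t, lifetime)
    lam = counts * shape / shape.sum()
    if noiseless:
        return DecayWaveform(t, lam)
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    return DecayWaveform(t, rng.poisson(lam).astype(float))


@dataclass
class SimulatedPlate:
    """Simulated waveforms, spectra and the generating ground truth."""

    waveforms: PlateWaveforms
    spectra: pd.DataFrame  # tidy: well, band, intensity
    truth: pd.DataFrame  # per well: role, compound_id, conc, tau, E components
    assay: str
    timepoint_min: float


def _simulate_spectrum(
    rng: np.random.Generator, contaminant_fraction: float, noise_cv: float
) -> np.ndarray:
    base = (1.0 - contaminant_fraction) * _BASE_SPECTRUM + contaminant_fraction * (
        _CONTAMINANT_SPECTRUM * _BASE_SPECTRUM.sum()
    )
    noisy = base * (1.0 + noise_cv * rng.standard_normal(base.size))
    return np.maximum(noisy, 0.0)


def simulate_plate(
    layout: PlateLayout,
    effects: Mapping[str, CompoundEffect],
    config: SimConfig,
    timepoint_min: float = 120.0,
    assay: str = "primary",
    seed: Optional[int] = None,
) -> SimulatedPlate:
    """Simulate every well of a plate at one read timepoint.

    Parameters
    ----------
    layout : PlateLayout
        Well roles and compound placement; every compound well's id must
        appear in ``effects``.
    effects : mapping compound_id -> CompoundEffect
        Ground-truth effect per compound. The ``tool`` role always uses the
        built-in saturating modulator (full specific-FRET removal).
    assay : {"primary", "counter", "donor_only"}
        ``primary`` wells carry specific + nonspecific FRET (donor +
        Lifeact-acceptor), ``counter`` wells nonspecific FRET only (donor +
        free acceptor), ``donor_only`` wells no FRET — the interference
        reference plate.
    """
    if assay not in ("primary", "counter", "donor_only"):
        raise ValueError(f"unknown assay kind {assay!r}")
    missing = sorted(
        {
            w.compound_id
            for w in layout.compound_wells
            if w.compound_id is not None and w.compound_id not in effects
        }
    )
    if missing:
        raise ValueError(f"no effect entry for compound ids: {', '.join(missing[:10])}")

    if assay == "primary":
        base_s, base_n = config.specific_fret, config.baseline_nonspecific_fret
    elif assay == "counter":
        base_s, base_n = 0.0, config.baseline_nonspecific_fret
    else:
        base_s, base_n = 0.0, 0.0

    tool_effect = CompoundEffect(
        effect_class="modulator", max_fret_change=1.0, ec50=1e-6, hill_slope=1.0
    )

    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = config.time_grid()
    irf = InstrumentResponse.gaussian(config.irf_center, config.irf_width_sigma)

    n_wells = len(layout.wells)
    counts = np.empty((n_wells, t.size))
    labels: List[str] = []
    spec_records = []
    truth_records = []
    for i, w in enumerate(layout.wells):
        label = w.label
        labels.append(label)
        effect = CompoundEffect()
        conc = 0.0
        if w.role == "compound":
            effect = effects[w.compound_id]
            conc = w.conc_uM or 0.0
        elif w.role == "tool":
            effect = tool_effect
            conc = w.conc_uM or 1.0
        e_s, e_n = effective_fret(effect, conc, timepoint_min, base_s, base_n)
        e_total = min(e_s + e_n, 0.999)
        tau_d = config.donor_lifetime + effect.donor_lifetime_shift
        tau = tau_d * (1.0 - e_total)
        shape = irf.decay_shape(t, tau)
        lam = config.counts_per_well * shape / shape.sum()
        counts[i] = rng.poisson(lam)

        band_values = _simulate_spectrum(
            rng, effect.spectral_contaminant_fraction, config.spectral_noise_cv
        )
        for band, inten in zip(SPECTRAL_BANDS, band_values):
            spec_records.append({"well": label, "band": band, "intensity": float(inten)})
        truth_records.append(
            {
                "well": label,
                "role": w.role,
                "compound_id": w.compound_id,
                "conc_uM": conc,
                "effect_class": effect.effect_class,
                "tau_true_ns": tau,
                "tau_donor_ns": tau_d,
                "E_total": e_total,
                "E_specific": e_s,
                "E_nonspecific": e_n,
            }
        )

    return SimulatedPlate(
        waveforms=PlateWaveforms(times=t, counts=counts, wells=labels),
        spectra=pd.DataFrame.from_records(spec_records),
        truth=pd.DataFrame.from_records(truth_records),
        assay=assay,
        timepoint_min=timepoint_min,
    )


@dataclass(frozen=True)
class TitrationModel:
    """Acceptor-expression titration of the FRET readout.

    The specific (actin-tethered) component saturates exponentially with
    acceptor expression level to ``e_max``; the nonspecific (collisional /
    overexpression) component grows linearly through the origin.
    """

    e_max: float = 0.12
    rate: float = 1.0
    nonspecific_slope: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.e_max < 1.0:
            raise ValueError("e_max must lie in (0, 1)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.nonspecific_slope < 0:
            raise ValueError("nonspecific_slope must be nonnegative")


def simulate_titration(
    acceptor_levels: Sequence[float], model: TitrationModel
) -> pd.DataFrame:
    """Total and nonspecific FRET versus acceptor expression level.

    Returns a table (level, specific_fret, nonspecific_fret, total_fret);
    the total is capped just below 1.
    """
    levels = np.asarray(acceptor_levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("acceptor levels must be nonnegative")
    specific = model.e_max * (1.0 - np.exp(-model.rate * levels))
    nonspecific = model.nonspecific_slope * levels
    total = np.minimum(specific + nonspecific, 0.999)
    return pd.DataFrame(
        {
            "level": levels,
            "specific_fret": specific,
            "nonspecific_fret": nonspecific,
            "total_fret": total,
        }
    )


def half_log_concentrations(
    c_min: float = 0.01, c_max: float = 30.0, n_points: int = 12
) -> np.ndarray:
    """Log-spaced concentration grid for dose-response plates.

    The default twelve points span 0.01-30 uM at a ~0.3-dex step, the
    roughly half-log grid conventional for concentration-response screens.
    """
    if c_min <= 0 or c_max <= c_min:
        raise ValueError("need 0 < c_min < c_max")
    return np.logspace(np.log10(c_min), np.log10(c_max), n_points)


def simulate_dose_series(
    effect: CompoundEffect,
    concentrations: Sequence[float],
    replicates: int,
    config: SimConfig,
    seed: Optional[int] = None,
    timepoint_min: float = 120.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Tidy concentration-response table of total-FRET readouts.

    FRET at each concentration follows the Hill-scaled modulator model
    applied to the configured baselines, plus Gaussian well-to-well noise of
    SD ``noise_sd`` (on the FRET scale).
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 4:
        raise ValueError("at least 4 concentrations are required for a fittable series")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for c in conc:
        e_s, e_n = effective_fret(
            effect, c, timepoint_min, config.specific_fret, config.baseline_nonspecific_fret
        )
        e_total = e_s + e_n
        for rep in range(replicates):
            noise = noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0
            rows.append(
                {"concentration_uM": float(c), "replicate": rep + 1, "fret": e_total + noise}
            )
    return pd.DataFrame.from_records(rows)


def simulate_fitted_tau_plate(
    n_compound: int,
    n_dmso: int,
    tau_mean: float,
    tau_sd: float,
    seed: int,
    compound_shifts: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Draw a fitted-lifetime table directly from the well-noise model.

    The per-well fitted lifetime of a high-count Poisson decay is, to good
    approximation, Gaussian around the true lifetime; this generator draws
    that Gaussian directly, bypassing waveform synthesis and refitting, so
    that null-calibration studies can reach millions of wells. ``tau_sd``
    should come from a Monte-Carlo calibration of the full simulate-and-fit
    path at the photon budget of interest. ``compound_shifts`` plants true
    lifetime shifts (ns) on selected compound indices.

    Returns a table (well, role, compound_id, tau_ns, converged) compatible
    with the hit-calling layer.
    """
    if tau_sd <= 0:
        raise ValueError("tau_sd must be positive")
    rng = np.random.default_rng(seed)
    tau_c = tau_mean + tau_sd * rng.standard_normal(n_compound)
    if compound_shifts:
        for idx, shift in compound_shifts.items():
            tau_c[idx] += shift
    tau_d = tau_mean + tau_sd * rng.standard_normal(n_dmso)
    return pd.DataFrame(
        {
            "well": [f"X{i:07d}" for i in range(n_compound + n_dmso)],
            "role": ["compound"] * n_compound + ["dmso"] * n_dmso,
            "compound_id": [f"C{i:07d}" for i in range(n_compound)] + [None] * n_dmso,
            "tau_ns": np.concatenate([tau_c, tau_d]),
            "converged": True,
        }
    )
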