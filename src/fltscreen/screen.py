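"""Screening decision layer: interference flags, SD-threshold hit calling,
reproducibility statistics, Z'-factor quality control and counter-screen
triage.

The hit statistic is the donor+acceptor lifetime tau_DA expressed in units
of the same plate's DMSO-control SD: a compound is a hit when
|tau_DA - mu_DMSO| > k sigma_DMSO (k = 4 by default). Compounds first pass
an interference screen on a paired donor-only plate: a compound whose
donor-only lifetime deviates by more than 3 SD, or whose emission-band
spectrum deviates from the DMSO mean spectrum by more than 3 SD of the DMSO
spectral-deviation scores, is excluded from hit calling — its FRET readout
is untrustworthy regardless of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .layout import PlateLayout

__all__ = [
    "flag_interference",
    "call_hits",
    "call_hits_from_table",
    "ScreenResult",
    "hit_reproducibility",
    "ReproducibilityResult",
    "mean_sem",
    "z_prime",
    "ZPrimeResult",
    "screen_timecourse",
    "TimecourseResult",
    "triage_with_counter",
]


def _dmso_stats(values: np.ndarray) -> Tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def spectral_deviation_scores(spectra: pd.DataFrame, dmso_wells: Set[str]) -> pd.Series:
    """Log-scaled cosine dissimilarity of each well's spectrum from the DMSO mean.

    ``spectra`` is tidy (well, band, intensity). The raw dissimilarity
    1 - cos(v_well, v_dmso_mean) is zero for a well whose band *shape*
    matches the controls and is insensitive to overall brightness, but its
    null distribution is chi-square-like (right-skewed), so a mean + 3 SD
    cut on the raw score over-flags clean wells. The returned score is
    log10(1 - cos), whose null is near-symmetric; genuine contamination
    moves it by orders of magnitude.
    """
    mat = spectra.pivot(index="well", columns="band", values="intensity")
    if mat.isna().any().any():
        raise ValueError("spectra table is ragged: every well needs every band")
    dmso_rows = mat.loc[mat.index.isin(dmso_wells)]
    if dmso_rows.empty:
        raise ValueError("no DMSO wells found in spectra table")
    ref = dmso_rows.mean(axis=0).to_numpy()
    v = mat.to_numpy()
    denom = np.linalg.norm(v, axis=1) * np.linalg.norm(ref)
    cos = (v @ ref) / np.where(denom > 0, denom, np.inf)
    dissim = np.maximum(1.0 - cos, 1e-15)
    return pd.Series(np.log10(dissim), index=mat.index, name="spectral_score")


def flag_interference(
    donor_fits: pd.DataFrame,
    donor_spectra: Optional[pd.DataFrame],
    layout: PlateLayout,
    config: Optional[ScreenConfig] = None,
) -> pd.DataFrame:
    """Flag fluorescent interfering compounds from a donor-only plate.

    A compound is lifetime-flagged when its donor-only lifetime deviates
    from the DMSO mean by more than ``interference_threshold_sd`` DMSO SDs
    (two-sided), and spectrum-flagged when its spectral-deviation score
    exceeds the DMSO score mean by the same number of DMSO-score SDs
    (one-sided: the score is a nonnegative dissimilarity). Either flag
    excludes the compound from hit calling.

    Parameters
    ----------
    donor_fits : DataFrame
        Per-well fits of the donor-only plate (well, tau_ns, converged).
    donor_spectra : DataFrame or None
        Tidy per-well band intensities of the donor-only plate; None skips
        the spectral test.
    layout : PlateLayout
        Shared compound layout of the donor-only and FRET plates.

    Returns
    -------
    DataFrame with one row per compound: tau shift in DMSO-SD units,
    spectral score in DMSO-SD units, and the two flags plus their union.
    """
    if donor_fits is None or len(donor_fits) == 0:
        raise ValueError(
            "donor-only fits are required: the interference screen is mandatory "
            "before hit calling"
        )
    config = config or ScreenConfig()
    k = config.interference_threshold_sd

    fits = donor_fits.set_index("well")
    dmso_labels = [w.label for w in layout.dmso_wells]
    dmso_tau = fits.loc[
        fits.index.isin(dmso_labels) & fits["converged"], "tau_ns"
    ].to_numpy()
    if dmso_tau.size < 2:
        raise ValueError("need >= 2 converged DMSO wells on the donor-only plate")
    mu, sd = _dmso_stats(dmso_tau)

    scores: Optional[pd.Series] = None
    s_mu = s_sd = float("nan")
    if donor_spectra is not None:
        scores = spectral_deviation_scores(donor_spectra, set(dmso_labels))
        dmso_scores = scores.loc[scores.index.isin(dmso_labels)].to_numpy()
        s_mu, s_sd = _dmso_stats(dmso_scores)

    records = []
    for w in layout.compound_wells:
        if w.compound_id is None:
            continue
        row: Dict[str, object] = {"compound_id": w.compound_id, "well": w.label}
        if w.label in fits.index and bool(fits.at[w.label, "converged"]):
            z = (float(fits.at[w.label, "tau_ns"]) - mu) / sd if sd > 0 else np.inf
        else:
            z = np.nan  # unfittable donor-only well: treat as interference
        row["tau_shift_sd"] = z
        row["lifetime_flag"] = bool(np.isnan(z) or abs(z) > k)
        if scores is not None and w.label in scores.index:
            if s_sd > 0:
                sz = (float(scores.at[w.label]) - s_mu) / s_sd
            else:
                sz = np.inf if float(scores.at[w.label]) > s_mu else 0.0
            row["spectral_score_sd"] = sz
            row["spectral_flag"] = bool(sz > k)
        else:
            row["spectral_score_sd"] = np.nan
            row["spectral_flag"] = False
        row["flagged"] = bool(row["lifetime_flag"] or row["spectral_flag"])
        records.append(row)
    return pd.DataFrame.from_records(records)


@dataclass
class ScreenResult:
    """Hit calls and plate-level summary for one plate at one timepoint.

    ``compounds`` has one row per compound well: signed lifetime shift in
    DMSO-SD units (``delta_sd``), the tau_DA shift direction, interference
    status and the hit call. Hit rate uses all compound wells as the
    denominator.
    """

    compounds: pd.DataFrame
    mu_dmso: float
    sd_dmso: float
    n_dmso: int
    hit_threshold_sd: float
    n_compound_wells: int
    n_flagged: int
    n_hits: int

    @property
    def hit_rate_pct(self) -> float:
        return 100.0 * self.n_hits / self.n_compound_wells if self.n_compound_wells else 0.0

    @property
    def hit_ids(self) -> Set[str]:
        df = self.compounds
        return set(df.loc[df["is_hit"], "compound_id"])

    def summary(self) -> str:
        lines = [
            "Screen result",
            "-" * 34,
            f"DMSO tau_DA       {self.mu_dmso:.4f} +/- {self.sd_dmso:.4f} ns (n={self.n_dmso})",
            f"hit threshold     {self.hit_threshold_sd:g} SD",
            f"compound wells    {self.n_compound_wells}",
            f"interference      {self.n_flagged} excluded",
            f"hits              {self.n_hits} ({self.hit_rate_pct:.1f}%)",
        ]
        return "\n".join(lines)


def call_hits_from_table(
    table: pd.DataFrame,
    flags: Optional[pd.DataFrame] = None,
    config: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Call hits on a role-tagged fitted-lifetime table (vectorized core).

    ``table`` needs columns well, role, compound_id, tau_ns, converged.
    mu and sigma come from the table's converged DMSO rows; a compound is a
    hit when |tau_DA - mu| > k sigma (two-sided by default; one-sided
    calling keeps only tau_DA increases, i.e. FRET decreases). Compounds
    flagged by the interference screen are excluded before hit statistics.
    """
    config = config or ScreenConfig()
    conv = table["converged"].to_numpy(dtype=bool)
    role = table["role"].to_numpy()
    tau = table["tau_ns"].to_numpy(dtype=float)

    dmso_tau = tau[(role == "dmso") & conv]
    if dmso_tau.size < config.min_dmso_wells:
        raise ValueError(
            f"need >= {config.min_dmso_wells} converged DMSO wells per plate, "
            f"found {dmso_tau.size}"
        )
    mu, sd = _dmso_stats(dmso_tau)
    if sd == 0:
        sd = np.finfo(float).tiny  # all-identical controls: any shift is infinite SDs

    flagged_ids: Set[str] = set()
    if flags is not None and len(flags):
        flagged_ids = set(flags.loc[flags["flagged"], "compound_id"])

    k = config.hit_threshold_sd
    is_cpd = role == "compound"
    cpd = table.loc[is_cpd, ["compound_id", "well", "tau_ns"]].copy()
    c_conv = conv[is_cpd]
    c_tau = tau[is_cpd]
    delta = np.where(c_conv, (c_tau - mu) / sd, np.nan)
    cpd["tau_ns"] = np.where(c_conv, c_tau, np.nan)
    cpd["delta_sd"] = delta
    cpd["direction"] = np.select(
        [~c_conv, delta > 0], ["none", "increase"], default="decrease"
    )
    cpd["interference_flagged"] = (
        cpd["compound_id"].isin(flagged_ids) if flagged_ids else False
    )
    exceeds = (np.abs(delta) > k) if config.two_sided else (delta > k)  # NaN -> False
    cpd["is_hit"] = c_conv & exceeds & ~cpd["interference_flagged"].to_numpy()
    compounds = cpd.reset_index(drop=True)[
        ["compound_id", "well", "tau_ns", "delta_sd", "direction", "interference_flagged", "is_hit"]
    ]
    return ScreenResult(
        compounds=compounds,
        mu_dmso=mu,
        sd_dmso=float(sd),
        n_dmso=int(dmso_tau.size),
        hit_threshold_sd=k,
        n_compound_wells=len(compounds),
        n_flagged=int(compounds["interference_flagged"].sum()),
        n_hits=int(compounds["is_hit"].sum()),
    )


def call_hits(
    fret_fits: pd.DataFrame,
    layout: PlateLayout,
    flags: Optional[pd.DataFrame] = None,
    config: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Call hits on a FRET plate's fitted tau_DA values.

    Joins the plate layout's roles onto the per-well fit table and delegates
    to :func:`call_hits_from_table`.
    """
    roles = layout.to_frame()[["well", "role", "compound_id"]]
    table = roles.merge(
        fret_fits[["well", "tau_ns", "converged"]], on="well", how="left"
    )
    table["converged"] = table["converged"].fillna(False).astype(bool)
    return call_hits_from_table(table, flags, config)


def mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and standard error of the mean (SD/sqrt(n), ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values for a SEM")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass
class ReproducibilityResult:
    """Cross-plate hit-reproducibility percentages.

    ``per_plate`` holds, for each plate and level k, the percentage of that
    plate's hits that recur as hits on at least k plates (the plate itself
    included); ``aggregate`` holds mean +/- SEM over plates per level.
    Plates with zero hits have undefined percentages (NaN) and drop out of
    the aggregate.
    """

    per_plate: pd.DataFrame
    aggregate: pd.DataFrame


def hit_reproducibility(
    hit_sets: Sequence[Iterable[str]], levels: Sequence[int] = (2, 3, 4)
) -> ReproducibilityResult:
    """Repeated-hit percentages across replicate screens of one compound set.

    For plate p and level k: 100 * |{hits of p found on >= k plates}| /
    |hits of p|, with the plate itself counted among the k.
    """
    sets = [set(s) for s in hit_sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 replicate plates")
    counts: Dict[str, int] = {}
    for s in sets:
        for c in s:
            counts[c] = counts.get(c, 0) + 1
    rows = []
    for p, s in enumerate(sets, start=1):
        for k in levels:
            if k > len(sets):
                continue
            if not s:
                pct = np.nan
            else:
                pct = 100.0 * sum(1 for c in s if counts[c] >= k) / len(s)
            rows.append({"plate": p, "level": k, "pct_repeated": pct})
    per_plate = pd.DataFrame.from_records(rows)
    agg_rows = []
    for k, grp in per_plate.groupby("level"):
        vals = grp["pct_repeated"].dropna().to_numpy()
        if vals.size >= 2:
            m, sem = mean_sem(vals)
        elif vals.size == 1:
            m, sem = float(vals[0]), np.nan
        else:
            m, sem = np.nan, np.nan
        agg_rows.append({"level": k, "mean_pct": m, "sem_pct": sem, "n_plates": vals.size})
    return ReproducibilityResult(per_plate=per_plate, aggregate=pd.DataFrame(agg_rows))


@dataclass
class ZPrimeResult:
    """Z'-factor of a half-DMSO / half-tool assay plate.

    Z' = 1 - 3 (sigma_DMSO + sigma_Tool) / |mu_DMSO - mu_Tool|, computed on
    tau_DA with sample SDs. Z' >= 0.5 is the customary HTS-ready threshold.
    """

    z_prime: float
    mu_dmso: float
    sigma_dmso: float
    mu_tool: float
    sigma_tool: float
    n_dmso: int
    n_tool: int

    def summary(self) -> str:
        return (
            f"Z' = {self.z_prime:.3f}\n"
            f"DMSO  tau_DA: {self.mu_dmso:.4f} +/- {self.sigma_dmso:.4f} ns "
            f"(n={self.n_dmso})\n"
            f"tool  tau_DA: {self.mu_tool:.4f} +/- {self.sigma_tool:.4f} ns "
            f"(n={self.n_tool})"
        )


def z_prime(dmso_values: Sequence[float], tool_values: Sequence[float]) -> ZPrimeResult:
    """Z'-factor from DMSO-control and tool-compound lifetime groups."""
    d = np.asarray(dmso_values, dtype=float)
    t = np.asarray(tool_values, dtype=float)
    if d.size < 2 or t.size < 2:
        raise ValueError("need >= 2 values in each group")
    mu_d, sd_d = _dmso_stats(d)
    mu_t, sd_t = _dmso_stats(t)
    window = abs(mu_d - mu_t)
    if window == 0:
        raise ValueError(
            "Z' undefined: DMSO and tool means are equal (no assay window)"
        )
    z = 1.0 - 3.0 * (sd_d + sd_t) / window
    return ZPrimeResult(
        z_prime=float(z),
        mu_dmso=mu_d,
        sigma_dmso=sd_d,
        mu_tool=mu_t,
        sigma_tool=sd_t,
        n_dmso=int(d.size),
        n_tool=int(t.size),
    )


@dataclass
class TimecourseResult:
    """Hit calls per read timepoint plus the timepoint with most hits."""

    results: Dict[float, ScreenResult]
    summary: pd.DataFrame
    best_timepoint: float


def screen_timecourse(
    fits_by_timepoint: Mapping[float, pd.DataFrame],
    layout: PlateLayout,
    flags: Optional[pd.DataFrame] = None,
    config: Optional[ScreenConfig] = None,
) -> TimecourseResult:
    """Call hits at each read timepoint of one plate (same layout throughout)."""
    if not fits_by_timepoint:
        raise ValueError("no timepoints supplied")
    n_wells = {tp: len(df) for tp, df in fits_by_timepoint.items()}
    if len(set(n_wells.values())) != 1:
        raise ValueError(f"timepoints have mismatched well counts: {n_wells}")
    results = {
        tp: call_hits(df, layout, flags, config)
        for tp, df in sorted(fits_by_timepoint.items())
    }
    summary = pd.DataFrame(
        [
            {
                "timepoint_min": tp,
                "n_hits": r.n_hits,
                "hit_rate_pct": r.hit_rate_pct,
                "mu_dmso": r.mu_dmso,
                "sd_dmso": r.sd_dmso,
            }
            for tp, r in results.items()
        ]
    )
    best = float(summary.loc[summary["n_hits"].idxmax(), "timepoint_min"])
    return TimecourseResult(results=results, summary=summary, best_timepoint=best)


def triage_with_counter(
    primary: ScreenResult,
    counter: ScreenResult,
    counter_threshold_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Classify primary-screen hits against the free-acceptor counter screen.

    A primary hit whose counter-screen |delta_sd| stays below the counter
    threshold is a ``candidate`` (its FRET loss needs the actin tether); one
    that also moves the counter readout is ``undesired`` (cytotoxicity,
    aggregation or optical artifact). Hits absent from the counter screen
    are ``unclassified``.
    """
    if counter_threshold_sd is None:
        counter_threshold_sd = counter.hit_threshold_sd
    counter_by_id = counter.compounds.set_index("compound_id")
    rows = []
    for rec in primary.compounds.itertuples():
        if not rec.is_hit:
            continue
        row = {
            "compound_id": rec.compound_id,
            "primary_delta_sd": rec.delta_sd,
            "counter_delta_sd": np.nan,
        }
        if rec.compound_id not in counter_by_id.index:
            row["classification"] = "unclassified"
            row["reason"] = "absent from counter screen"
        else:
            cd = float(counter_by_id.at[rec.compound_id, "delta_sd"])
            row["counter_delta_sd"] = cd
            if np.isnan(cd):
                row["classification"] = "unclassified"
                row["reason"] = "counter-screen well not fitted"
            elif abs(cd) > counter_threshold_sd:
                row["classification"] = "undesired"
                row["reason"] = "counter-active"
            else:
                row["classification"] = "candidate"
                row["reason"] = "counter-inactive"
        rows.append(row)
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "compound_id",
            "primary_delta_sd",
            "counter_delta_sd",
            "classification",
            "reason",
        ],
    )
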