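"""Secondary-assay arithmetic: cosedimentation bound fractions, aggregation
flags and relative cell viability.

These are the orthogonal, lower-throughput assays used to assign a mode of
action to screen hits: ultracentrifugation cosedimentation of the acceptor
peptide (Lifeact) or the actin-binding domain (ABD) with F-actin, pelleting
of the ABD without actin (aggregation), and trypan-blue viable-cell counts.
Group comparisons against the DMSO control use an unpaired two-sample
t-test at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "lifeact_bound_fraction",
    "lifeact_bound_table",
    "abd_bound_summary",
    "aggregation_flag",
    "relative_viability",
]

ArrayLike = Union[float, np.ndarray]
P_THRESHOLD = 0.05


def lifeact_bound_fraction(supernatant_signal: ArrayLike, no_actin_signal: float) -> ArrayLike:
    """Fraction of acceptor peptide bound to F-actin from supernatant signal.

    bound = 1 - F_sample / F_no_actin, where F_sample is the supernatant
    fluorescence of a compound or DMSO reaction and F_no_actin that of the
    actin-free control (everything unbound). Values outside [0, 1] are
    retained — noise can push a sample slightly past either end — and are
    the caller's cue to inspect the run.
    """
    if no_actin_signal <= 0:
        raise ValueError("no-actin reference signal must be positive")
    s = np.asarray(supernatant_signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("supernatant signals must be nonnegative")
    out = 1.0 - s / no_actin_signal
    return float(out) if out.ndim == 0 else out


def _ttest_vs_dmso(values: np.ndarray, dmso: np.ndarray, alternative: str = "two-sided"):
    """Unpaired t-test; returns (p, significant, available)."""
    if values.size < 2 or dmso.size < 2:
        return float("nan"), False, False
    res = stats.ttest_ind(values, dmso, alternative=alternative)
    p = float(res.pvalue)
    return p, bool(p < P_THRESHOLD), True


def lifeact_bound_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition bound fractions from a tidy supernatant-fluorescence table.

    ``table`` columns: sample_id (or condition), condition in
    {compound-name, 'dmso', 'no_actin'}, replicate, signal. The no-actin
    mean is the 100%-unbound reference; each other condition gets its mean
    bound fraction, the value relative to the DMSO mean, and a two-sample
    significance flag against the DMSO replicates.
    """
    cond = table["condition"].str.lower()
    ref_rows = table.loc[cond == "no_actin", "signal"].to_numpy(dtype=float)
    if ref_rows.size == 0:
        raise ValueError("exactly one no_actin reference condition is required; none found")
    ref = float(ref_rows.mean())
    bound = lifeact_bound_fraction(table["signal"].to_numpy(dtype=float), ref)
    work = table.assign(bound_fraction=bound, _cond=cond)
    dmso_bound = work.loc[work["_cond"] == "dmso", "bound_fraction"].to_numpy()
    if dmso_bound.size == 0:
        raise ValueError("DMSO control rows are required")
    dmso_mean = float(dmso_bound.mean())
    rows = []
    for name, grp in work[~work["_cond"].isin(["no_actin"])].groupby("condition"):
        vals = grp["bound_fraction"].to_numpy()
        p, sig, avail = _ttest_vs_dmso(vals, dmso_bound)
        rows.append(
            {
                "condition": name,
                "n": vals.size,
                "bound_fraction": float(vals.mean()),
                "relative_to_dmso": float(vals.mean() / dmso_mean) if dmso_mean != 0 else np.nan,
                "out_of_range": bool(np.any((vals < 0) | (vals > 1))),
                "p_value": p,
                "significant": sig,
                "significance_available": avail,
            }
        )
    return pd.DataFrame.from_records(rows)


def abd_bound_summary(
    table: pd.DataFrame,
    total_signal: Optional[float] = None,
    dmso_bound_fraction: float = 0.9,
) -> pd.DataFrame:
    """Relative ABD-actin binding from unbound-supernatant densitometry.

    ``table`` columns: condition, replicate, unbound_signal (supernatant
    densitometry after SDS-PAGE). Bound protein is total - unbound. The
    total lane signal comes either from an explicit no-spin reference
    (``total_signal``) or is calibrated from the DMSO lanes assuming
    ``dmso_bound_fraction`` of the ABD cosediments under control conditions
    (the assay is designed to run near-saturated, ~0.9). Each compound's
    mean bound signal is reported relative to the DMSO mean, with an
    unpaired two-sample comparison at p < 0.05; significance is reported as
    unavailable for single replicates.
    """
    cond = table["condition"].str.lower()
    dmso_unbound = table.loc[cond == "dmso", "unbound_signal"].to_numpy(dtype=float)
    if dmso_unbound.size == 0:
        raise ValueError("DMSO reference rows are required")
    if total_signal is None:
        if not 0 < dmso_bound_fraction < 1:
            raise ValueError("dmso_bound_fraction must lie in (0, 1)")
        total_signal = float(dmso_unbound.mean() / (1.0 - dmso_bound_fraction))
    if total_signal <= 0:
        raise ValueError("total signal must be positive")
    work = table.assign(bound=total_signal - table["unbound_signal"], _cond=cond)
    dmso_bound = work.loc[work["_cond"] == "dmso", "bound"].to_numpy(dtype=float)
    dmso_mean = float(dmso_bound.mean())
    rows = []
    for name, grp in work[work["_cond"] != "dmso"].groupby("condition"):
        vals = grp["bound"].to_numpy(dtype=float)
        p, sig, avail = _ttest_vs_dmso(vals, dmso_bound)
        rows.append(
            {
                "condition": name,
                "n": vals.size,
                "relative_binding": float(vals.mean() / dmso_mean) if dmso_mean != 0 else np.nan,
                "p_value": p,
                "significant": sig,
                "significance_available": avail,
            }
        )
    return pd.DataFrame.from_records(rows)


def aggregation_flag(table: pd.DataFrame) -> pd.DataFrame:
    """Flag compounds that promote ABD pelleting without actin (aggregation).

    ``table`` columns: condition, replicate, pellet_fraction — the fraction
    of ABD found in the pellet of a no-actin spin. A compound is flagged
    aggregator when its pellet fraction significantly exceeds the DMSO
    control (one-sided unpaired comparison, p < 0.05).
    """
    cond = table["condition"].str.lower()
    dmso = table.loc[cond == "dmso", "pellet_fraction"].to_numpy(dtype=float)
    if dmso.size == 0:
        raise ValueError("DMSO reference rows are required")
    rows = []
    for name, grp in table[cond != "dmso"].groupby("condition"):
        vals = grp["pellet_fraction"].to_numpy(dtype=float)
        p, sig, avail = _ttest_vs_dmso(vals, dmso, alternative="greater")
        rows.append(
            {
                "condition": name,
                "n": vals.size,
                "pellet_fraction": float(vals.mean()),
                "relative_to_dmso": float(vals.mean() / dmso.mean()) if dmso.mean() else np.nan,
                "p_value": p,
                "aggregator": sig,
                "significance_available": avail,
            }
        )
    return pd.DataFrame.from_records(rows)


@dataclass
class ViabilityResult:
    """Treated-versus-DMSO viable-cell ratio."""

    ratio: float

    @property
    def percent_decrease(self) -> float:
        return (1.0 - self.ratio) * 100.0


def relative_viability(treated_count: float, dmso_count: float) -> ViabilityResult:
    """Relative viability from trypan-blue viable-cell counts.

    ratio = treated/DMSO; percent decrease = (1 - ratio) * 100.
    """
    if dmso_count <= 0:
        raise ValueError("DMSO viable count must be positive")
    if treated_count < 0:
        raise ValueError("treated viable count must be nonnegative")
    return ViabilityResult(ratio=float(treated_count) / float(dmso_count))
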