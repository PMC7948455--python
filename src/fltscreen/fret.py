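"""FRET efficiencies from lifetimes, Förster-distance predictions, and
DMSO-control normalization.

FRET efficiency is the fractional shortening of the donor lifetime by the
acceptor, E = 1 - tau_DA/tau_D. The geometric prediction for a dipole pair
at separation r with Förster distance R0 is E = 1/(1 + (r/R0)^6). Screen
readouts are reported relative to the mean of the same plate's DMSO control
wells. Slightly negative noise-driven efficiencies are preserved, not
clipped, so SD-based hit statistics stay Gaussian-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .layout import PlateLayout

__all__ = [
    "fret_efficiency",
    "forster_efficiency",
    "ForsterPair",
    "relative_to_dmso",
    "NormalizedResult",
]

ArrayLike = Union[float, np.ndarray]


def fret_efficiency(tau_DA: ArrayLike, tau_D: ArrayLike) -> ArrayLike:
    """FRET efficiency E = 1 - tau_DA/tau_D from donor lifetimes in ns.

    ``tau_DA`` is the donor lifetime in the presence of acceptor, ``tau_D``
    the unquenched donor reference. Accepts scalars or arrays.
    """
    tau_DA = np.asarray(tau_DA, dtype=float)
    tau_D = np.asarray(tau_D, dtype=float)
    if np.any(tau_DA <= 0) or np.any(tau_D <= 0):
        raise ValueError("lifetimes must be positive")
    out = 1.0 - tau_DA / tau_D
    return float(out) if out.ndim == 0 else out


def forster_efficiency(r: ArrayLike, r0: float) -> ArrayLike:
    """Predicted FRET efficiency for separation ``r`` and Förster distance ``r0``.

    E = 1/(1 + (r/r0)^6), both distances in the same units (Å by convention).
    """
    if r0 <= 0:
        raise ValueError("Förster distance r0 must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be nonnegative")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ForsterPair:
    """A donor-acceptor pair at separation ``r`` Å with Förster distance ``r0`` Å."""

    r: float
    r0: float

    @property
    def E_predicted(self) -> float:
        return forster_efficiency(self.r, self.r0)


@dataclass
class NormalizedResult:
    """Per-well values divided by the plate's DMSO-control mean."""

    values: pd.Series  # relative values, indexed by well
    dmso_mean: float
    dmso_sd: float
    n_dmso: int


def relative_to_dmso(values: pd.Series, layout: PlateLayout) -> NormalizedResult:
    """Normalize per-well values to the mean over the plate's DMSO wells.

    ``values`` is indexed by well label. The DMSO mean and SD (ddof=1) are
    reported alongside; at least two DMSO wells with values are required.
    """
    dmso_labels = [w.label for w in layout.dmso_wells]
    dmso_vals = values.reindex(dmso_labels).dropna()
    if len(dmso_vals) < 2:
        raise ValueError(
            f"need >= 2 DMSO wells with values to normalize; found {len(dmso_vals)}"
        )
    mu = float(dmso_vals.mean())
    if mu == 0:
        raise ValueError("DMSO mean is zero; cannot normalize")
    sd = float(dmso_vals.std(ddof=1))
    return NormalizedResult(values=values / mu, dmso_mean=mu, dmso_sd=sd, n_dmso=len(dmso_vals))


def fret_table(fits: pd.DataFrame, tau_d_ref: float) -> pd.DataFrame:
    """Attach FRET efficiencies to a per-well lifetime-fit table.

    ``tau_d_ref`` is the donor-only reference lifetime (typically the mean of
    a paired donor-only plate's converged DMSO fits). Non-converged wells get
    NaN efficiencies.
    """
    if tau_d_ref <= 0:
        raise ValueError("donor reference lifetime must be positive")
    out = fits.copy()
    ok = out["converged"] & (out["tau_ns"] > 0)
    out["E"] = np.where(ok, 1.0 - out["tau_ns"] / tau_d_ref, np.nan)
    out["tau_D_ref_ns"] = tau_d_ref
    return out


def donor_reference(donor_fits: pd.DataFrame, layout: PlateLayout) -> float:
    """Donor-only reference lifetime: mean over converged DMSO wells."""
    dmso_labels = {w.label for w in layout.dmso_wells}
    sel = donor_fits["converged"] & donor_fits["well"].isin(dmso_labels)
    vals = donor_fits.loc[sel, "tau_ns"]
    if len(vals) < 2:
        raise ValueError("need >= 2 converged donor-only DMSO wells for a tau_D reference")
    return float(vals.mean())
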