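"""Hill-equation concentration-response fitting and EC50 reporting.

The four-parameter logistic (Hill) model, in the plate-reader convention:

    response(c) = bottom + (top - bottom) / (1 + (ec50 / c)^slope)

``top`` and ``bottom`` are the two plateaus; a negative ``slope`` describes
a response that falls with concentration (the usual shape for a FRET-loss
modulator), so ``bottom <= top`` always holds and the curve passes through
(top + bottom)/2 at c = EC50 regardless of direction. Optimization runs in
log10(EC50) space for numerical stability, with deterministic
data-driven initialization (no random restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["HillModel", "DoseResponseFit", "fit_hill", "summarize_replicates", "ReplicateSummary"]


def hill_curve(c: np.ndarray, ec50: float, slope: float, top: float, bottom: float) -> np.ndarray:
    """Evaluate the four-parameter Hill curve at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    # log-space ratio keeps extreme c/ec50 ratios finite
    z = slope * (np.log(ec50) - np.log(c))
    return bottom + (top - bottom) / (1.0 + np.exp(np.clip(z, -700, 700)))


@dataclass
class DoseResponseFit:
    """Fitted Hill parameters with approximate standard errors.

    ``ec50`` is in the units of the input concentrations (uM by convention);
    ``hill_slope`` is signed (negative = response falls with concentration).
    ``stderr`` holds linearized standard errors keyed by parameter name;
    ``converged`` is False for flat or otherwise unfittable data.
    """

    ec50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_points: int
    stderr: Dict[str, float] = field(default_factory=dict)
    message: str = ""

    def predict(self, concentrations: Sequence[float]) -> np.ndarray:
        return hill_curve(np.asarray(concentrations, float), self.ec50, self.hill_slope, self.top, self.bottom)

    @property
    def midpoint_response(self) -> float:
        return 0.5 * (self.top + self.bottom)

    def summary(self) -> str:
        def fmt(name: str, value: float) -> str:
            se = self.stderr.get(name)
            return f"{value:.4g} +/- {se:.2g}" if se is not None and np.isfinite(se) else f"{value:.4g}"

        rows = [
            ("EC50 (uM)", fmt("ec50", self.ec50)),
            ("Hill slope", fmt("hill_slope", self.hill_slope)),
            ("top", fmt("top", self.top)),
            ("bottom", fmt("bottom", self.bottom)),
            ("RSS", f"{self.rss:.4g}"),
            ("points", f"{self.n_points}"),
            ("converged", str(self.converged)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Hill dose-response fit", "-" * 30]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


class HillModel:
    """Hill concentration-response model for one compound's dose series.

    Parameters
    ----------
    concentrations : sequence of float
        Strictly positive concentrations; >= 4 distinct values spanning at
        least 1.5 log10 units are required.
    responses : sequence of float
        Responses (e.g. DMSO-relative FRET), same length.
    fix_top, fix_bottom : float, optional
        Pin a plateau (e.g. ``fix_top=1`` for DMSO-relative data).
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        responses: Sequence[float],
        fix_top: Optional[float] = None,
        fix_bottom: Optional[float] = None,
    ):
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(responses, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        distinct = np.unique(c)
        if distinct.size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        span = np.log10(distinct.max() / distinct.min())
        if span < 1.5:
            raise ValueError(
                f"concentration range spans only {span:.2f} log10 units; need >= 1.5"
            )
        self.c = c
        self.y = y
        self.fix_top = fix_top
        self.fix_bottom = fix_bottom

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        concentration_col: str = "concentration_uM",
        response_col: str = "response",
        **kwargs,
    ) -> "HillModel":
        return cls(df[concentration_col].to_numpy(), df[response_col].to_numpy(), **kwargs)

    # deterministic initialization: plateaus from the extreme-concentration
    # means, slope sign from the data trend, ec50 from midpoint interpolation
    def _initial_guess(self):
        order = np.argsort(self.c)
        c_s, y_s = self.c[order], self.y[order]
        means = pd.Series(y_s).groupby(c_s).mean()
        lo_mean = float(means.iloc[0])
        hi_mean = float(means.iloc[-1])
        descending = hi_mean < lo_mean
        top0 = self.fix_top if self.fix_top is not None else max(lo_mean, hi_mean)
        bottom0 = self.fix_bottom if self.fix_bottom is not None else min(lo_mean, hi_mean)
        slope0 = -1.0 if descending else 1.0
        mid = 0.5 * (lo_mean + hi_mean)
        cg = means.index.to_numpy(dtype=float)
        yg = means.to_numpy()
        # first grid crossing of the midpoint
        ec50_0 = float(np.sqrt(cg[0] * cg[-1]))
        for i in range(len(yg) - 1):
            y1, y2 = yg[i], yg[i + 1]
            if (y1 - mid) * (y2 - mid) <= 0 and y1 != y2:
                f = (mid - y1) / (y2 - y1)
                ec50_0 = float(
                    10 ** (np.log10(cg[i]) + f * (np.log10(cg[i + 1]) - np.log10(cg[i])))
                )
                break
        return ec50_0, slope0, float(top0), float(bottom0)

    def fit(self) -> DoseResponseFit:
        y_range = float(self.y.max() - self.y.min())
        ec50_0, slope0, top0, bottom0 = self._initial_guess()
        if y_range == 0:
            return DoseResponseFit(
                ec50=float("nan"),
                hill_slope=float("nan"),
                top=top0,
                bottom=bottom0,
                rss=0.0,
                converged=False,
                n_points=self.c.size,
                message="flat response: EC50 undefined",
            )

        free = ["log_ec50", "slope"]
        x0 = [np.log10(ec50_0), slope0]
        lo = [np.log10(self.c.min()) - 3.0, -10.0]
        hi = [np.log10(self.c.max()) + 3.0, 10.0]
        if self.fix_top is None:
            free.append("top")
            x0.append(top0)
            lo.append(-np.inf)
            hi.append(np.inf)
        if self.fix_bottom is None:
            free.append("bottom")
            x0.append(bottom0)
            lo.append(-np.inf)
            hi.append(np.inf)

        def unpack(x):
            params = dict(zip(free, x))
            top = self.fix_top if self.fix_top is not None else params["top"]
            bottom = self.fix_bottom if self.fix_bottom is not None else params["bottom"]
            return 10 ** params["log_ec50"], params["slope"], top, bottom

        def residuals(x):
            ec50, slope, top, bottom = unpack(x)
            return hill_curve(self.c, ec50, slope, top, bottom) - self.y

        sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        ec50, slope, top, bottom = unpack(sol.x)
        rss = float(2.0 * sol.cost)
        dof = max(self.c.size - len(free), 1)

        stderr: Dict[str, float] = {}
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
            se = np.sqrt(np.diag(cov))
            for name, s in zip(free, se):
                if name == "log_ec50":
                    stderr["ec50"] = float(ec50 * np.log(10) * s)  # delta method
                elif name == "slope":
                    stderr["hill_slope"] = float(s)
                else:
                    stderr[name] = float(s)
        except np.linalg.LinAlgError:
            pass

        at_edge = (
            np.isclose(np.log10(ec50), lo[0], atol=1e-6)
            or np.isclose(np.log10(ec50), hi[0], atol=1e-6)
        )
        converged = bool(sol.success) and not at_edge
        msg = "" if converged else ("EC50 at search bound" if at_edge else sol.message)
        if top < bottom:  # normalize plateau naming: top is the upper plateau
            top, bottom, slope = bottom, top, -slope
        return DoseResponseFit(
            ec50=float(ec50),
            hill_slope=float(slope),
            top=float(top),
            bottom=float(bottom),
            rss=rss,
            converged=converged,
            n_points=int(self.c.size),
            stderr=stderr,
            message=msg,
        )


def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
    fix_top: Optional[float] = None,
    fix_bottom: Optional[float] = None,
) -> DoseResponseFit:
    """Fit a four-parameter Hill curve; see :class:`HillModel`."""
    return HillModel(concentrations, responses, fix_top=fix_top, fix_bottom=fix_bottom).fit()


@dataclass
class ReplicateSummary:
    """EC50 agreement across replicate plates."""

    mean_ec50: float
    sd_ec50: float
    ec50s: np.ndarray
    outlier_plates: np.ndarray  # indices into ec50s deviating > 3 pooled SD

    def summary(self) -> str:
        lines = [
            f"mean EC50: {self.mean_ec50:.4g} (SD {self.sd_ec50:.2g}, n={self.ec50s.size})",
            "per-plate: " + ", ".join(f"{v:.4g}" for v in self.ec50s),
        ]
        if self.outlier_plates.size:
            lines.append(f"outlier plates (index): {list(self.outlier_plates)}")
        return "\n".join(lines)


def summarize_replicates(fits: Sequence[DoseResponseFit]) -> ReplicateSummary:
    """Mean and dispersion of EC50 over replicate-plate fits.

    Non-converged fits are dropped; >= 2 converged fits are required. Plates
    whose EC50 deviates from the mean by more than 3x the pooled SD are
    flagged as outliers (the pooled SD excludes the plate under test, so a
    single wild plate cannot mask itself).
    """
    ec50s = np.array([f.ec50 for f in fits if f.converged], dtype=float)
    if ec50s.size < 2:
        raise ValueError("need >= 2 converged fits to summarize replicates")
    mean = float(ec50s.mean())
    sd = float(ec50s.std(ddof=1))
    outliers = []
    for i in range(ec50s.size):
        rest = np.delete(ec50s, i)
        rest_sd = float(rest.std(ddof=1)) if rest.size > 1 else 0.0
        if rest_sd > 0 and abs(ec50s[i] - rest.mean()) > 3.0 * rest_sd:
            outliers.append(i)
        elif rest_sd == 0 and ec50s[i] != rest.mean():
            outliers.append(i)
    return ReplicateSummary(
        mean_ec50=mean, sd_ec50=sd, ec50s=ec50s, outlier_plates=np.array(outliers, dtype=int)
    )
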