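"""Per-well fluorescence-lifetime recovery from photon-count decay waveforms.

The measurement model is a single-exponential donor decay convolved with the
instrument response function (IRF), plus a constant background:

    m(t) = A * (h_irf * exp(-t/tau))(t) + b

For a Gaussian IRF the convolution has the closed exponentially-modified-
Gaussian form, evaluated here in a numerically stable split (scaled
complementary error function near the rising edge, plain exponential deep in
the tail). Fits minimize Poisson-weighted squared residuals with
``scipy.optimize.least_squares``; weighting uses 1/max(count, 1) variances,
the correct heteroscedasticity for photon counting.

Usage follows the Model/Results convention::

    model = ExponentialDecayModel(waveform, irf=InstrumentResponse.gaussian(2.0, 0.15))
    res = model.fit()
    res.tau, res.tau_stderr, res.reduced_chi2
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "DecayWaveform",
    "PlateWaveforms",
    "InstrumentResponse",
    "ExponentialDecayModel",
    "DecayFitResult",
    "fit_single_exponential",
    "fit_plate",
    "goodness_of_fit",
]

TAU_BOUNDS = (0.1, 10.0)  # ns; out-of-bound convergence is flagged, not clamped
MIN_NONZERO_BINS = 20


@dataclass
class DecayWaveform:
    """Binned photon counts versus arrival time for one well."""

    times: np.ndarray  # bin midpoints, ns
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have identical shape")
        if self.times.ndim != 1:
            raise ValueError("waveform arrays must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("bin times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not a valid photon histogram")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class PlateWaveforms:
    """All wells of a plate on one shared time grid."""

    times: np.ndarray
    counts: np.ndarray  # (n_wells, n_bins)
    wells: List[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.wells), self.times.size):
            raise ValueError("counts must be (n_wells, n_bins) matching wells and times")

    def __len__(self) -> int:
        return len(self.wells)

    def waveform(self, well: str) -> DecayWaveform:
        i = self.wells.index(well)
        return DecayWaveform(self.times, self.counts[i])

    def __iter__(self):
        for i, w in enumerate(self.wells):
            yield w, DecayWaveform(self.times, self.counts[i])


@dataclass(frozen=True)
class InstrumentResponse:
    """Instrument response function: Gaussian parameters or a tabulated shape.

    The tabulated form is stored nonnegative and normalized to unit area on
    its grid.
    """

    kind: str
    center: Optional[float] = None
    sigma: Optional[float] = None
    table_times: Optional[np.ndarray] = None
    table_values: Optional[np.ndarray] = None

    @classmethod
    def gaussian(cls, center: float, sigma: float) -> "InstrumentResponse":
        if sigma <= 0:
            raise ValueError("IRF sigma must be positive")
        return cls(kind="gaussian", center=float(center), sigma=float(sigma))

    @classmethod
    def tabulated(cls, times: np.ndarray, values: np.ndarray) -> "InstrumentResponse":
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise ValueError("tabulated IRF must be nonnegative")
        area = np.trapezoid(values, times)
        if area <= 0:
            raise ValueError("tabulated IRF must have positive area")
        return cls(kind="tabulated", table_times=times, table_values=values / area)

    def decay_shape(self, times: np.ndarray, tau: float) -> np.ndarray:
        """Unit-amplitude single-exponential decay convolved with this IRF."""
        if self.kind == "gaussian":
            return exp_conv_gauss(times, tau, self.center, self.sigma)
        # discrete convolution on the waveform grid, assuming a shared grid origin
        dt = float(np.median(np.diff(times)))
        irf = np.interp(times, self.table_times, self.table_values, left=0.0, right=0.0)
        decay = np.exp(-(times - times[0]) / tau)
        full = np.convolve(irf, decay)[: times.size] * dt
        return full

    @classmethod
    def parse(cls, text: str) -> "InstrumentResponse":
        """Parse a CLI-style spec such as ``gaussian:2.0,0.15``."""
        kind, _, params = text.partition(":")
        if kind.strip().lower() != "gaussian":
            raise ValueError(f"unsupported IRF spec {text!r}; expected 'gaussian:center,sigma'")
        try:
            center_s, sigma_s = params.split(",")
            return cls.gaussian(float(center_s), float(sigma_s))
        except ValueError as exc:
            raise ValueError(f"malformed IRF spec {text!r}") from exc


def exp_conv_gauss(t: np.ndarray, tau: float, center: float, sigma: float) -> np.ndarray:
    """Single-exponential decay convolved with a normalized Gaussian.

    Closed form (exponentially modified Gaussian):

        f(t) = 1/2 * exp(sigma^2/(2 tau^2) - (t-center)/tau)
                   * erfc((sigma/tau - (t-center)/sigma)/sqrt(2))

    Evaluated via ``erfcx`` where the erfc argument is positive (rising edge)
    and via the plain exponential form in the tail, so neither branch
    overflows for small tau or long windows.
    """
    t = np.asarray(t, dtype=float)
    dt = (t - center) / sigma
    u = sigma / tau - dt  # erfc argument * sqrt(2)
    out = np.empty_like(t)
    pos = u >= 0
    # rising edge: 1/2 exp(-dt^2/2) erfcx(u/sqrt 2)
    out[pos] = 0.5 * np.exp(-0.5 * dt[pos] ** 2) * special.erfcx(u[pos] / math.sqrt(2))
    # tail: direct form, exponent is safely negative there
    ex = 0.5 * sigma**2 / tau**2 - (t[~pos] - center) / tau
    out[~pos] = 0.5 * np.exp(ex) * special.erfc(u[~pos] / math.sqrt(2))
    return out


@dataclass
class DecayFitResult:
    """Result of a single-well lifetime fit.

    ``tau`` is the fluorescence lifetime in ns; ``converged`` is False when
    the optimizer failed, the waveform was unusable, or the solution sits at
    the lifetime bounds.
    """

    tau: float
    amplitude: float
    baseline: float
    tau_stderr: float
    reduced_chi2: float
    converged: bool
    n_bins_used: int
    mode: str
    message: str = ""
    well: Optional[str] = None

    def summary(self) -> str:
        rows = [
            ("lifetime tau (ns)", f"{self.tau:.4f} +/- {self.tau_stderr:.4f}"),
            ("amplitude (counts)", f"{self.amplitude:.1f}"),
            ("baseline (counts/bin)", f"{self.baseline:.3f}"),
            ("reduced chi^2", f"{self.reduced_chi2:.3f}"),
            ("bins used", f"{self.n_bins_used}"),
            ("mode", self.mode),
            ("converged", str(self.converged)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Single-exponential decay fit", "-" * 34]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


class ExponentialDecayModel:
    """One-exponential decay model for a single well's waveform.

    Parameters
    ----------
    waveform : DecayWaveform
        Binned photon counts on a strictly increasing time grid.
    irf : InstrumentResponse
        Instrument response; shared across a plate in :func:`fit_plate`.
    mode : {"reconvolution", "tail"}
        ``reconvolution`` fits the IRF-convolved model over the full window;
        ``tail`` fits a bare exponential to bins well past the IRF peak.
    """

    def __init__(
        self,
        waveform: DecayWaveform,
        irf: InstrumentResponse,
        mode: str = "reconvolution",
    ):
        if mode not in ("reconvolution", "tail"):
            raise ValueError(f"unknown fit mode {mode!r}")
        if waveform.counts.sum() <= 0:
            raise ValueError("cannot fit an all-zero waveform")
        if int(np.count_nonzero(waveform.counts)) < MIN_NONZERO_BINS:
            raise ValueError(
                f"waveform has fewer than {MIN_NONZERO_BINS} nonzero bins; not fittable"
            )
        self.waveform = waveform
        self.irf = irf
        self.mode = mode

    # -- internal pieces -------------------------------------------------
    def _tail_selection(self) -> np.ndarray:
        c = self.waveform.counts
        t = self.waveform.times
        peak = int(np.argmax(c))
        if self.irf.kind == "gaussian":
            start_time = t[peak] + 3.0 * self.irf.sigma
        else:
            start_time = t[peak] + 0.5
        return t >= start_time

    def _initial_guess(self) -> Tuple[float, float, float]:
        """tau0 from log-linear regression on the decay tail; deterministic."""
        t = self.waveform.times
        c = self.waveform.counts
        n_base = max(5, int(0.02 * c.size))
        b0 = max(float(np.mean(c[-n_base:])), 0.0)
        peak = int(np.argmax(c))
        sel = np.zeros(c.size, dtype=bool)
        sel[peak:] = True
        sel &= c > max(5.0, 0.05 * c.max())
        net = c[sel] - b0
        good = net > 0
        if good.sum() >= 3:
            slope, _ = np.polyfit(t[sel][good], np.log(net[good]), 1)
            tau0 = -1.0 / slope if slope < 0 else 2.0
        else:
            tau0 = 2.0
        tau0 = float(np.clip(tau0, TAU_BOUNDS[0] * 1.5, TAU_BOUNDS[1] / 1.5))
        a0 = max(float(c.max() - b0), 1.0)
        if self.mode == "reconvolution":
            shape_peak = float(np.max(self.irf.decay_shape(t, tau0)))
            a0 = a0 / max(shape_peak, 1e-12)
        return tau0, a0, b0

    def _model(self, t: np.ndarray, tau: float, amplitude: float, baseline: float) -> np.ndarray:
        if self.mode == "reconvolution":
            return amplitude * self.irf.decay_shape(t, tau) + baseline
        return amplitude * np.exp(-(t - t[0]) / tau) + baseline

    # -- public API ------------------------------------------------------
    def fit(self) -> DecayFitResult:
        if self.mode == "tail":
            sel = self._tail_selection()
        else:
            sel = np.ones(self.waveform.counts.size, dtype=bool)
        t = self.waveform.times[sel]
        c = self.waveform.counts[sel]
        if t.size < 4:
            raise ValueError("fewer than 4 bins available for fitting")
        w = 1.0 / np.sqrt(np.maximum(c, 1.0))

        tau0, a0, b0 = self._initial_guess()
        x0 = np.array([tau0, a0, b0])
        lo = np.array([TAU_BOUNDS[0], 0.0, 0.0])
        hi = np.array([TAU_BOUNDS[1], np.inf, np.inf])

        # Poisson weights: start from observed counts, then reweight from the
        # fitted model. Pure observed-count weighting over-weights downward
        # fluctuations and biases tau low by ~1% at 1e5 counts; two model
        # reweighting passes remove that bias while staying a weighted
        # least-squares minimization throughout.
        sol = None
        for _ in range(3):
            weights = w

            def residuals(x: np.ndarray, weights=weights) -> np.ndarray:
                return (self._model(t, *x) - c) * weights

            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            x0 = sol.x
            w = 1.0 / np.sqrt(np.maximum(self._model(t, *sol.x), 1.0))
        tau, amplitude, baseline = (float(v) for v in sol.x)
        dof = max(t.size - 3, 1)
        red_chi2 = float(2.0 * sol.cost / dof)

        at_bound = math.isclose(tau, TAU_BOUNDS[0]) or math.isclose(tau, TAU_BOUNDS[1])
        converged = bool(sol.success) and not at_bound
        message = "" if converged else (sol.message if not sol.success else "tau at fit bound")

        tau_stderr = float("nan")
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * max(red_chi2, 1e-12)
            tau_stderr = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass

        return DecayFitResult(
            tau=tau,
            amplitude=amplitude,
            baseline=baseline,
            tau_stderr=tau_stderr,
            reduced_chi2=red_chi2,
            converged=converged,
            n_bins_used=int(t.size),
            mode=self.mode,
            message=message,
        )


def fit_single_exponential(
    waveform: DecayWaveform, irf: InstrumentResponse, mode: str = "reconvolution"
) -> DecayFitResult:
    """Fit one well; see :class:`ExponentialDecayModel`."""
    return ExponentialDecayModel(waveform, irf, mode).fit()


def fit_plate(
    plate: PlateWaveforms, irf: InstrumentResponse, mode: str = "reconvolution"
) -> pd.DataFrame:
    """Fit every well of a plate with a shared IRF and shared bounds.

    Wells that cannot be fitted (all-zero or degenerate waveforms) are
    flagged ``converged = False`` with NaN parameters; the rest of the plate
    is unaffected. Returns a tidy table with one row per well.
    """
    records = []
    for well, wf in plate:
        try:
            res = fit_single_exponential(wf, irf, mode)
            records.append(
                {
                    "well": well,
                    "tau_ns": res.tau,
                    "tau_stderr": res.tau_stderr,
                    "amplitude": res.amplitude,
                    "baseline": res.baseline,
                    "chi2": res.reduced_chi2,
                    "converged": res.converged,
                    "n_bins_used": res.n_bins_used,
                }
            )
        except ValueError:
            records.append(
                {
                    "well": well,
                    "tau_ns": float("nan"),
                    "tau_stderr": float("nan"),
                    "amplitude": float("nan"),
                    "baseline": float("nan"),
                    "chi2": float("nan"),
                    "converged": False,
                    "n_bins_used": 0,
                }
            )
    return pd.DataFrame.from_records(records)


def goodness_of_fit(
    fit: DecayFitResult, waveform: DecayWaveform, irf: InstrumentResponse
) -> Tuple[float, np.ndarray]:
    """Reduced chi-square and the Poisson-weighted residual trace of a fit.

    Residuals are (model - data)/sqrt(max(data, 1)) on the bins the fit used,
    suitable for QC plots; reduced chi^2 divides by (n_bins - 3).
    """
    model = ExponentialDecayModel(waveform, irf, fit.mode)
    sel = model._tail_selection() if fit.mode == "tail" else np.ones(waveform.counts.size, bool)
    t, c = waveform.times[sel], waveform.counts[sel]
    m = model._model(t, fit.tau, fit.amplitude, fit.baseline)
    resid = (m - c) / np.sqrt(np.maximum(c, 1.0))
    red_chi2 = float(np.sum(resid**2) / max(t.size - 3, 1))
    return red_chi2, resid
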