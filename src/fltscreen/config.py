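"""Run-level configuration objects.

Two validated configuration models are shared across the package:
:class:`SimConfig` parameterizes the synthetic plate generator (time grid,
donor lifetime, instrument response, photon budget) and :class:`ScreenConfig`
parameterizes the screening decision layer (SD thresholds, timepoints).
"""

from __future__ import annotations

from typing import Tuple

from pydantic import BaseModel, Field, model_validator


class SimConfig(BaseModel):
    """Parameters of the synthetic fluorescence-lifetime plate generator.

    Parameters
    ----------
    donor_lifetime : float
        Unquenched donor (GFP) lifetime tau_D in ns.
    time_window : tuple of float
        (start, stop) of the photon arrival-time window in ns.
    bin_width : float
        Histogram bin width in ns.
    counts_per_well : float
        Expected total photon count collected per well.
    irf_center : float
        Center of the Gaussian instrument response, ns after the window start.
    irf_width_sigma : float
        Gaussian instrument-response width (sigma) in ns.
    seed : int
        Base seed; identical configuration and seed give byte-identical plates.
    timepoints : list of float
        Post-compound-load read times in minutes.
    baseline_total_fret : float
        FRET efficiency of untreated donor+acceptor (Lifeact-mCherry) wells:
        specific plus nonspecific transfer.
    baseline_nonspecific_fret : float
        FRET efficiency of the free-acceptor (mCherry) counter-screen wells.
    spectral_noise_cv : float
        Coefficient of variation of the simulated emission-band intensities.
    """

    donor_lifetime: float = Field(default=2.60, gt=0)
    time_window: Tuple[float, float] = (0.0, 25.0)
    bin_width: float = Field(default=0.05, gt=0)
    counts_per_well: float = Field(default=1e5, gt=0)
    irf_center: float = Field(default=2.0, ge=0)
    irf_width_sigma: float = Field(default=0.15, gt=0)
    seed: int = 0
    timepoints: Tuple[float, ...] = (20.0, 120.0, 180.0)
    baseline_total_fret: float = Field(default=0.123, ge=0, lt=1)
    baseline_nonspecific_fret: float = Field(default=0.059, ge=0, lt=1)
    spectral_noise_cv: float = Field(default=0.02, ge=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_window(self) -> "SimConfig":
        t0, t1 = self.time_window
        if t1 <= t0:
            raise ValueError("time_window stop must exceed start")
        if (t1 - t0) < 5.0 * self.donor_lifetime:
            raise ValueError(
                "time_window must span at least 5 donor lifetimes "
                f"({5.0 * self.donor_lifetime:.2f} ns); got {t1 - t0:.2f} ns"
            )
        if self.baseline_nonspecific_fret > self.baseline_total_fret:
            raise ValueError(
                "nonspecific FRET baseline cannot exceed the total FRET baseline"
            )
        return self

    @property
    def specific_fret(self) -> float:
        """Specific (actin-tethered) FRET component of the total baseline."""
        return self.baseline_total_fret - self.baseline_nonspecific_fret

    @property
    def n_bins(self) -> int:
        import math

        t0, t1 = self.time_window
        return int(math.floor((t1 - t0) / self.bin_width + 1e-9))

    def time_grid(self):
        """Bin-midpoint times in ns."""
        import numpy as np

        t0, _ = self.time_window
        return t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


class ScreenConfig(BaseModel):
    """Decision thresholds of the screening layer.

    ``hit_threshold_sd`` is k of the ``|tau_DA - mu_DMSO| > k sigma_DMSO``
    hit rule (default 4; 3 and 5 are the standard alternatives);
    ``interference_threshold_sd`` is the 3-SD donor-only lifetime / spectral
    interference rule. Hits are two-sided by default: both FRET increases
    and decreases are kept, with the direction recorded.
    """

    hit_threshold_sd: float = Field(default=4.0, gt=0)
    interference_threshold_sd: float = Field(default=3.0, gt=0)
    timepoints: Tuple[float, ...] = (20.0, 120.0, 180.0)
    two_sided: bool = True
    min_dmso_wells: int = Field(default=16, ge=2)

    model_config = {"frozen": True}
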