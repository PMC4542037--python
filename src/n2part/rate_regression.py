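"""Excess-isotopologue time series and production-rate regression.

Raw observations are vial incubations killed at fixed times (default grid
0, 3, 6, 12, 24 h, three replicate vials per kill time).  The production
rate of each labeled isotopologue is the ordinary least-squares slope of
excess amount versus time, pooling all replicate points; significance of
accumulation is a one-sided t-test of slope > 0 (production cannot be
negative at the pathway level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .isotope_core import InvalidInputError

__all__ = [
    "TREATMENTS",
    "ZONES",
    "FERTILIZATIONS",
    "InsufficientDataError",
    "VialSeries",
    "SlopeFit",
    "compute_excess",
    "fit_production_rate",
    "detect_accumulation",
]

logger = logging.getLogger("n2part")

TREATMENTS = ("amm15", "amm15_nit14", "nit15")
ZONES = ("rhizosphere", "non_rhizosphere")
FERTILIZATIONS = ("control", "N")


class InsufficientDataError(InvalidInputError):
    """Raised when a series has too few points for the requested fit."""


@dataclass
class VialSeries:
    """Time series of excess isotopologue amounts for one sample x treatment.

    Amounts are nmol N2 per g dry soil, excess over the time-zero /
    natural-abundance baseline; times are hours after tracer injection.
    Arrays are parallel over observations (replicate vials x kill times).
    """

    sample_id: str
    zone: str
    fertilization: str
    treatment: str
    time_h: np.ndarray
    replicate: np.ndarray
    excess29: np.ndarray
    excess30: np.ndarray
    dry_mass_g: Optional[np.ndarray] = None
    f_no3: Optional[float] = None
    f_nh4: Optional[float] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise InvalidInputError(
                f"unknown zone {self.zone!r}; allowed: {ZONES}"
            )
        if self.fertilization not in FERTILIZATIONS:
            raise InvalidInputError(
                f"unknown fertilization {self.fertilization!r}; "
                f"allowed: {FERTILIZATIONS}"
            )
        if self.treatment not in TREATMENTS:
            raise InvalidInputError(
                f"unknown treatment {self.treatment!r}; allowed: {TREATMENTS}"
            )
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.excess29 = np.asarray(self.excess29, dtype=float)
        self.excess30 = np.asarray(self.excess30, dtype=float)
        n = self.time_h.size
        for name in ("replicate", "excess29", "excess30"):
            if getattr(self, name).size != n:
                raise InvalidInputError(
                    f"{name} length {getattr(self, name).size} != time_h length {n}"
                )
        if n and np.nanmin(self.time_h) < 0:
            raise InvalidInputError("time_h must be >= 0")
        if self.dry_mass_g is not None:
            self.dry_mass_g = np.asarray(self.dry_mass_g, dtype=float)
            if np.any(self.dry_mass_g <= 0):
                raise InvalidInputError("dry_mass_g must be > 0")

    def __len__(self) -> int:
        return int(self.time_h.size)

    @property
    def n_replicates(self) -> int:
        return int(np.unique(self.replicate).size)

    def select_replicate(self, rep: int) -> "VialSeries":
        mask = self.replicate == rep
        return replace(
            self,
            time_h=self.time_h[mask],
            replicate=self.replicate[mask],
            excess29=self.excess29[mask],
            excess30=self.excess30[mask],
            dry_mass_g=None if self.dry_mass_g is None else self.dry_mass_g[mask],
        )


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of excess amount vs time for one isotopologue.

    ``p_value`` is one-sided for slope > 0 (t with n-2 df);
    ``p_two_sided`` is the usual two-sided p.
    """

    slope: float
    intercept: float
    se_slope: float
    r2: float
    p_value: float
    p_two_sided: float
    n_points: int


def compute_excess(
    series: VialSeries, baseline_policy: str = "t0_mean"
) -> VialSeries:
    """Convert raw isotopologue amounts to excess over baseline.

    ``t0_mean`` (default) subtracts the mean of the time-zero observations
    from each channel, so the t=0 mean excess is 0 by construction.
    ``natural_abundance`` assumes amounts are already expressed relative to
    the natural-abundance expectation and subtracts nothing.
    """
    if baseline_policy == "natural_abundance":
        return replace(series)
    if baseline_policy != "t0_mean":
        raise InvalidInputError(
            f"unknown baseline_policy {baseline_policy!r}; "
            "allowed: 't0_mean', 'natural_abundance'"
        )
    at_t0 = series.time_h == 0
    if not np.any(at_t0):
        raise InsufficientDataError(
            "baseline_policy 't0_mean' needs at least one time-zero "
            "observation; supply a baseline or use 'natural_abundance'"
        )
    b29 = float(np.nanmean(series.excess29[at_t0]))
    b30 = float(np.nanmean(series.excess30[at_t0]))
    return replace(
        series, excess29=series.excess29 - b29, excess30=series.excess30 - b30
    )


def fit_production_rate(
    series: VialSeries,
    isotopologue: int = 29,
    time_window: Optional[Tuple[float, float]] = None,
) -> SlopeFit:
    """OLS production-rate fit for one isotopologue, pooling replicates.

    Parameters
    ----------
    series
        Excess time series (all replicate points enter one regression).
    isotopologue
        29 or 30.
    time_window
        Optional (t_min, t_max) in hours restricting the fitted points,
        e.g. an initial linear window; default uses all points.
    """
    if isotopologue == 29:
        y = series.excess29
    elif isotopologue == 30:
        y = series.excess30
    else:
        raise InvalidInputError(f"isotopologue must be 29 or 30, got {isotopologue}")
    t = series.time_h
    if time_window is not None:
        lo, hi = time_window
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    ok = np.isfinite(t) & np.isfinite(y)
    n_dropped = t.size - int(ok.sum())
    if n_dropped:
        logger.warning(
            "%s/%s %dN2: dropped %d non-finite observation(s)",
            series.sample_id, series.treatment, isotopologue, n_dropped,
        )
        t, y = t[ok], y[ok]
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct time points, got {np.unique(t).size}"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError("zero time variance; cannot fit a slope")

    res = stats.linregress(t, y)
    n = t.size
    if res.stderr > 0:
        tstat = res.slope / res.stderr
        p_one = float(stats.t.sf(tstat, df=n - 2))
    else:
        # perfect fit: significance degenerates to the sign of the slope
        p_one = 0.0 if res.slope > 0 else 1.0
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        r2=float(res.rvalue**2) if math.isfinite(res.rvalue) else 0.0,
        p_value=p_one,
        p_two_sided=float(res.pvalue),
        n_points=n,
    )


def detect_accumulation(fit: SlopeFit, alpha: float = 0.05) -> bool:
    """True iff the isotopologue accumulates: slope > 0 at one-sided alpha."""
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    return fit.slope > 0 and fit.p_value < alpha
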