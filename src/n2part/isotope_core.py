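"""Isotope-pairing model for partitioning N2 production.

Forward model: each N2 molecule is formed by pairing two N atoms.
Denitrification draws both atoms from the nitrate/nitrite pool (15N mole
fraction ``f_no3``); anammox draws one atom from the ammonium pool
(``f_nh4``) and one from the nitrate/nitrite pool.  Random, independent
pairing within each pathway makes the isotopologue fluxes binomial in the
label fractions:

    denitrification:  p30 = D f_n^2            anammox:  p30 = A f_a f_n
                      p29 = 2 D f_n (1 - f_n)            p29 = A [f_a (1-f_n) + f_n (1-f_a)]
                      p28 = D (1 - f_n)^2                p28 = A (1-f_a)(1-f_n)

with f_n = f_no3 and f_a = f_nh4.  The backward direction (the isotope
pairing technique, IPT) inverts the 15NO3- treatment, where f_a ~ 0:

    D = p30 / f_n^2
    A = f_n^-1 [ p29 + 2 (1 - f_n^-1) p30 ]

which is the exact algebraic inverse of the forward model at f_a = 0.

All rates are in nmol N2 g^-1 dry soil h^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "NATURAL_ABUNDANCE_15N",
    "F_NO3_STOCK",
    "F_NH4_STOCK",
    "InvalidInputError",
    "UndefinedContributionError",
    "LabelFractions",
    "ProductionRates",
    "ProcessRates",
    "IsotopologueFlux",
    "pairing_forward",
    "ipt_invert",
    "contribution",
    "display_percent",
    "spike_concentration",
]

#: Natural abundance of 15N (mole fraction), the default for unlabeled pools.
NATURAL_ABUNDANCE_15N = 0.00366

#: 15N enrichment of the nitrate tracer stock (15N-KNO3).
F_NO3_STOCK = 0.9815

#: 15N enrichment of the ammonium tracer stock (15N-(NH4)2SO4).
F_NH4_STOCK = 0.9914


class InvalidInputError(ValueError):
    """Raised when inputs violate a model precondition."""


class UndefinedContributionError(ValueError):
    """Raised when the anammox contribution is undefined (A + D = 0)."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LabelFractions:
    """15N mole fractions of the substrate pools.

    Parameters
    ----------
    f_no3
        15N mole fraction of the nitrate/nitrite pool, in [0, 1].
    f_nh4
        15N mole fraction of the ammonium pool, in [0, 1].
    """

    f_no3: float
    f_nh4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_no3", "f_nh4"):
            v = _require_finite(name, getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
            object.__setattr__(self, name, v)


@dataclass
class ProductionRates:
    """Fitted excess production rates of the labeled isotopologues.

    ``p29``/``p30`` are slopes of excess 29N2 / 30N2 versus time, in
    nmol N2 g^-1 dry soil h^-1; ``se29``/``se30`` their standard errors.
    The significance flags record whether each slope tested > 0.
    """

    p29: float
    p30: float
    se29: float = 0.0
    se30: float = 0.0
    p29_signif: Optional[bool] = None
    p30_signif: Optional[bool] = None

    def __post_init__(self) -> None:
        self.p29 = _require_finite("p29", self.p29)
        self.p30 = _require_finite("p30", self.p30)
        for name in ("se29", "se30"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v}")
            setattr(self, name, v)


@dataclass
class ProcessRates:
    """Pathway rates and the anammox share of total N2 production.

    ``ra`` is 100 * A / (A + D) in percent; NaN when A + D = 0.
    ``clamped`` records that a negative raw solution was truncated to 0.
    Confidence intervals are filled by the pipeline's bootstrap.
    """

    anammox: float
    denitrification: float
    ra: float
    clamped: bool = False
    ci_anammox: Optional[Tuple[float, float]] = None
    ci_denit: Optional[Tuple[float, float]] = None
    ci_ra: Optional[Tuple[float, float]] = None
    raw_anammox: float = field(default=math.nan, repr=False)
    raw_denitrification: float = field(default=math.nan, repr=False)


@dataclass(frozen=True)
class IsotopologueFlux:
    """Per-pathway isotopologue production rates and their totals."""

    anammox_p28: float
    anammox_p29: float
    anammox_p30: float
    denit_p28: float
    denit_p29: float
    denit_p30: float

    @property
    def p28(self) -> float:
        return self.anammox_p28 + self.denit_p28

    @property
    def p29(self) -> float:
        return self.anammox_p29 + self.denit_p29

    @property
    def p30(self) -> float:
        return self.anammox_p30 + self.denit_p30

    @property
    def anammox_total(self) -> float:
        return self.anammox_p28 + self.anammox_p29 + self.anammox_p30

    @property
    def denit_total(self) -> float:
        return self.denit_p28 + self.denit_p29 + self.denit_p30

    @property
    def total(self) -> float:
        return self.anammox_total + self.denit_total


def pairing_forward(
    anammox_rate: float, denit_rate: float, labels: LabelFractions
) -> IsotopologueFlux:
    """Predict isotopologue production rates from pathway rates and labels.

    Parameters
    ----------
    anammox_rate, denit_rate
        Pathway rates A and D, nmol N2 g^-1 h^-1, both >= 0.
    labels
        15N mole fractions of the two substrate pools.

    Returns
    -------
    IsotopologueFlux
        Mass-28/29/30 production rates per pathway.  Per pathway the three
        components sum to that pathway's rate (atom-pair bookkeeping is
        conservative).
    """
    a = _require_finite("anammox_rate", anammox_rate)
    d = _require_finite("denit_rate", denit_rate)
    if a < 0 or d < 0:
        raise InvalidInputError(f"rates must be >= 0, got A={a}, D={d}")
    fn, fa = labels.f_no3, labels.f_nh4
    return IsotopologueFlux(
        anammox_p28=a * (1.0 - fa) * (1.0 - fn),
        anammox_p29=a * (fa * (1.0 - fn) + fn * (1.0 - fa)),
        anammox_p30=a * fa * fn,
        denit_p28=d * (1.0 - fn) ** 2,
        denit_p29=2.0 * d * fn * (1.0 - fn),
        denit_p30=d * fn * fn,
    )


def ipt_invert(
    prod: ProductionRates, labels: LabelFractions, clamp: bool = True
) -> ProcessRates:
    """Invert 29/30N2 production rates to anammox and denitrification rates.

    Implements the 15NO3- treatment inversion (assumes the ammonium pool is
    effectively unlabeled, ``f_nh4`` ~ 0):

        D = p30 / f_no3^2
        A = f_no3^-1 [ p29 + 2 (1 - f_no3^-1) p30 ]

    Negative solutions (possible from measurement noise) are clamped to 0
    and flagged when ``clamp`` is true; the anammox share ``ra`` is computed
    from the clamped values.
    """
    fn = labels.f_no3
    if fn == 0.0:
        raise InvalidInputError("ipt_invert requires f_no3 > 0")
    p29 = _require_finite("p29", prod.p29)
    p30 = _require_finite("p30", prod.p30)

    d_raw = p30 / (fn * fn)
    a_raw = (p29 + 2.0 * (1.0 - 1.0 / fn) * p30) / fn

    a, d = a_raw, d_raw
    clamped = False
    if clamp:
        if a < 0.0:
            a, clamped = 0.0, True
        if d < 0.0:
            d, clamped = 0.0, True
    ra = contribution(a, d) if (a + d) > 0 else math.nan
    return ProcessRates(
        anammox=a,
        denitrification=d,
        ra=ra,
        clamped=clamped,
        raw_anammox=a_raw,
        raw_denitrification=d_raw,
    )


def contribution(anammox_rate: float, denit_rate: float) -> float:
    """Percent of total N2 production attributable to anammox.

    ra = 100 * A / (A + D), in [0, 100].  Undefined (error) when both
    rates are zero; report such samples as not-applicable, never as 0%.
    """
    a = _require_finite("anammox_rate", anammox_rate)
    d = _require_finite("denit_rate", denit_rate)
    if a < 0 or d < 0:
        raise InvalidInputError(f"rates must be >= 0, got A={a}, D={d}")
    if a + d == 0:
        raise UndefinedContributionError(
            "contribution undefined: both rates are zero"
        )
    return 100.0 * a / (a + d)


def display_percent(ra: float) -> int:
    """Round a percentage for display: nearest integer, halves away from zero."""
    ra = _require_finite("ra", ra)
    return int(math.floor(abs(ra) + 0.5)) * (1 if ra >= 0 else -1)


def spike_concentration(
    stock_mM: float, injected_ul: float, vial_ml: float
) -> float:
    """Added-N concentration (uM) from injecting tracer stock into a vial.

    100 ul of a 12 mM N stock into a 12.0 ml vial gives 100 uM added N.
    """
    stock_mM = _require_finite("stock_mM", stock_mM)
    injected_ul = _require_finite("injected_ul", injected_ul)
    vial_ml = _require_finite("vial_ml", vial_ml)
    if stock_mM <= 0 or vial_ml <= 0 or injected_ul < 0:
        raise InvalidInputError(
            "stock_mM and vial_ml must be > 0 and injected_ul >= 0"
        )
    return stock_mM * injected_ul / vial_ml
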