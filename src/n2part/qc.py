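"""Treatment-based quality control for the isotope-pairing incubations.

Two control treatments license the 15NO3- rate calculation:

* 15NH4+ only — no labeled N2 should accumulate.  Accumulation means
  residual 14NOx- survived the preincubation (or label reached the NOx
  pool), invalidating the assumption that the post-spike nitrate pool is
  essentially all tracer.
* 15NH4+ + 14NO3- — 29N2 should accumulate but 30N2 should not: the
  qualitative anammox signature (one ammonium-derived 15N atom paired with
  one unlabeled nitrate-derived atom), while denitrification of unlabeled
  nitrate stays at mass 28.

Both verdicts are deterministic given the data and alpha.  A QC failure
annotates downstream rates as unvalidated; it never aborts the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from .isotope_core import InvalidInputError
from .rate_regression import (
    SlopeFit,
    VialSeries,
    detect_accumulation,
    fit_production_rate,
)

__all__ = ["QCResult", "check_preincubation", "check_anammox_signature"]


@dataclass
class QCResult:
    """Verdict of one QC check, with the slope-fit evidence retained."""

    check_name: str
    passed: bool
    detail: str
    fits: Dict[int, SlopeFit]


def _require_treatment(series: VialSeries, expected: str, check: str) -> None:
    if series.treatment != expected:
        raise InvalidInputError(
            f"{check} requires the {expected!r} treatment, "
            f"got {series.treatment!r}"
        )
    if len(series) == 0:
        raise InvalidInputError(f"{check}: empty series")


def check_preincubation(
    amm15_series: VialSeries, alpha: float = 0.05
) -> QCResult:
    """Pass iff neither 29N2 nor 30N2 accumulates in the 15NH4+-only vials.

    Accumulation of either labeled isotopologue indicates residual NOx-
    (ambient 14NOx- not consumed during preincubation, or nitrification of
    the tracer), so the nitrate-pool label fraction is not controlled.
    """
    _require_treatment(amm15_series, "amm15", "check_preincubation")
    fits = {
        m: fit_production_rate(amm15_series, isotopologue=m) for m in (29, 30)
    }
    acc = {m: detect_accumulation(fits[m], alpha) for m in (29, 30)}
    passed = not acc[29] and not acc[30]
    if passed:
        detail = (
            "no significant 29N2 or 30N2 accumulation: residual NOx- "
            "removed by preincubation"
        )
    else:
        which = " and ".join(f"{m}N2" for m in (29, 30) if acc[m])
        detail = (
            f"significant {which} accumulation in the 15NH4+-only "
            "treatment: residual NOx- pool suspected"
        )
    return QCResult("preincubation", passed, detail, fits)


def check_anammox_signature(
    amm15_nit14_series: VialSeries, alpha: float = 0.05
) -> QCResult:
    """Pass iff 29N2 accumulates but 30N2 does not (15NH4+ + 14NO3-).

    Anammox pairing one labeled ammonium atom with one unlabeled
    nitrate-derived atom produces 29N2 almost exclusively; 30N2 would
    require two labeled atoms, which neither pathway can supply here.
    """
    _require_treatment(
        amm15_nit14_series, "amm15_nit14", "check_anammox_signature"
    )
    fits = {
        m: fit_production_rate(amm15_nit14_series, isotopologue=m)
        for m in (29, 30)
    }
    acc29 = detect_accumulation(fits[29], alpha)
    acc30 = detect_accumulation(fits[30], alpha)
    passed = acc29 and not acc30
    if passed:
        detail = "29N2 accumulated but not 30N2: anammox signature confirmed"
    elif not acc29:
        detail = "no significant 29N2 accumulation: anammox not detected"
    else:
        detail = (
            "30N2 accumulated alongside 29N2: signal not attributable to "
            "anammox alone"
        )
    return QCResult("anammox_signature", passed, detail, fits)
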