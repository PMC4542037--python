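"""End-to-end orchestration: table I/O -> QC -> rate regression -> IPT
inversion -> group statistics -> versioned report.

Input is a delimited text table (comma or tab) with one row per vial
observation.  Mandatory columns: sample_id, zone, fertilization,
treatment, time_h, replicate, and either excess29/excess30 (amounts
already expressed as excess over baseline) or raw29/raw30 (converted with
the configured baseline policy) — never both.  Optional columns:
dry_mass_g, f_no3, f_nh4; unknown columns are carried as metadata.

The report is deterministic: the same inputs, configuration and seed give
a byte-identical JSON document.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._version import __version__
from .isotope_core import (
    F_NO3_STOCK,
    InvalidInputError,
    LabelFractions,
    ProcessRates,
    ProductionRates,
    contribution,
    display_percent,
    ipt_invert,
)
from .qc import QCResult, check_anammox_signature, check_preincubation
from .rate_regression import (
    FERTILIZATIONS,
    InsufficientDataError,
    TREATMENTS,
    VialSeries,
    ZONES,
    compute_excess,
    detect_accumulation,
    fit_production_rate,
)
from .group_stats import duncan_mrt, summarize, ttest_two

__all__ = [
    "SchemaError",
    "ExperimentConfig",
    "ExperimentReport",
    "read_timeseries_table",
    "run_experiment",
    "write_report",
]

logger = logging.getLogger("n2part")

REPORT_SCHEMA_VERSION = 1

_MANDATORY = ("sample_id", "zone", "fertilization", "treatment", "time_h", "replicate")
_NUMERIC = ("time_h", "replicate", "excess29", "excess30", "raw29", "raw30",
            "dry_mass_g", "f_no3", "f_nh4")
_KNOWN = set(_MANDATORY) | set(_NUMERIC)


class SchemaError(InvalidInputError):
    """Raised when an input table violates the expected schema."""


@dataclass
class ExperimentConfig:
    """Tunable constants of one pipeline run.

    ``f_no3_default`` defaults to the nitrate tracer stock enrichment
    (0.9815): after preincubation removes ambient NOx-, the post-spike
    nitrate pool is essentially all tracer.  Per-sample measured label
    fractions in the input table override it.
    """

    alpha: float = 0.05
    f_no3_default: float = F_NO3_STOCK
    f_nh4_default: float = 0.0
    baseline_policy: str = "t0_mean"
    bootstrap_iterations: int = 1000
    seed: int = 0
    rate_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.bootstrap_iterations < 0:
            raise InvalidInputError("bootstrap_iterations must be >= 0")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExperimentConfig":
        """Load from a flat key = value text file (# starts a comment)."""
        kwargs: Dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"config line {lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in ("alpha", "f_no3_default", "f_nh4_default"):
                kwargs[key] = float(value)
            elif key in ("bootstrap_iterations", "seed"):
                kwargs[key] = int(value)
            elif key == "baseline_policy":
                kwargs[key] = value
            elif key == "rate_window":
                if value.lower() in ("", "none"):
                    kwargs[key] = None
                else:
                    lo, hi = (float(v) for v in value.split(","))
                    kwargs[key] = (lo, hi)
            else:
                raise SchemaError(f"config line {lineno}: unknown key {key!r}")
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_dict(self) -> Dict:
        d = asdict(self)
        if self.rate_window is not None:
            d["rate_window"] = list(self.rate_window)
        return d


# ---------------------------------------------------------------------------
# input

def read_timeseries_table(
    path: Union[str, Path], dialect: Optional[str] = None
) -> List[VialSeries]:
    """Read and validate a vial time-series table into VialSeries records.

    ``dialect`` may be 'csv', 'tsv' or an explicit delimiter; by default
    the separator is sniffed.  Raises :class:`SchemaError` with column
    names / line numbers on malformed input.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", None: None}.get(dialect, dialect)
    import csv as _csv

    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header found") from None
    except _csv.Error:
        # the sniffer cannot find a delimiter in an empty/headerless file
        raise SchemaError(
            f"{path}: empty or malformed file, no delimited header found"
        ) from None
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    has_excess = "excess29" in df.columns or "excess30" in df.columns
    has_raw = "raw29" in df.columns or "raw30" in df.columns
    if has_excess and has_raw:
        raise SchemaError(
            f"{path}: give either excess29/excess30 or raw29/raw30, not both"
        )
    if not has_excess and not has_raw:
        raise SchemaError(
            f"{path}: missing amount columns (excess29/excess30 or raw29/raw30)"
        )
    pair = ("excess29", "excess30") if has_excess else ("raw29", "raw30")
    for col in pair:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column(s): {col}")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & coerced.isna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(
                f"{path}: column {col!r} has unparsable numeric value(s) "
                f"at line(s) {lines}"
            )
        df[col] = coerced

    bad_trt = sorted(set(df["treatment"].astype(str)) - set(TREATMENTS))
    if bad_trt:
        raise SchemaError(
            f"{path}: unknown treatment code(s) {bad_trt}; "
            f"allowed: {list(TREATMENTS)}"
        )

    extra_cols = [c for c in df.columns if c not in _KNOWN]
    if extra_cols:
        logger.info("%s: carrying extra column(s) as metadata: %s",
                    path, ", ".join(extra_cols))

    e29, e30 = pair
    out: List[VialSeries] = []
    for (sample_id, treatment), sub in df.groupby(
        ["sample_id", "treatment"], sort=True
    ):
        for col in ("zone", "fertilization"):
            if sub[col].nunique() > 1:
                raise SchemaError(
                    f"{path}: sample {sample_id!r} treatment {treatment!r} "
                    f"has inconsistent {col} values"
                )
        meta: Dict = {
            "source": str(path),
            "source_rows": [int(i) + 2 for i in sub.index],
            "is_raw": has_raw,
        }
        for c in extra_cols:
            meta[c] = sub[c].tolist()

        def _opt_scalar(col: str) -> Optional[float]:
            if col not in sub.columns:
                return None
            vals = sub[col].dropna()
            return float(vals.iloc[0]) if len(vals) else None

        out.append(
            VialSeries(
                sample_id=str(sample_id),
                zone=str(sub["zone"].iloc[0]),
                fertilization=str(sub["fertilization"].iloc[0]),
                treatment=str(treatment),
                time_h=sub["time_h"].to_numpy(),
                replicate=sub["replicate"].to_numpy(),
                excess29=sub[e29].to_numpy(),
                excess30=sub[e30].to_numpy(),
                dry_mass_g=(
                    sub["dry_mass_g"].to_numpy()
                    if "dry_mass_g" in sub.columns
                    else None
                ),
                f_no3=_opt_scalar("f_no3"),
                f_nh4=_opt_scalar("f_nh4"),
                metadata=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# computation

def _fast_slope(t: np.ndarray, y: np.ndarray) -> float:
    tm = t.mean()
    return float(np.dot(t - tm, y - y.mean()) / np.dot(t - tm, t - tm))


def _bootstrap_rates(
    series: VialSeries,
    labels: LabelFractions,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> Optional[Dict[str, Optional[List[float]]]]:
    """Percentile CIs from resampling replicate vials within each kill time."""
    b = config.bootstrap_iterations
    if b == 0:
        return None
    t = series.time_h
    if config.rate_window is not None:
        lo, hi = config.rate_window
        keep = (t >= lo) & (t <= hi)
    else:
        keep = np.ones(t.size, dtype=bool)
    keep &= (
        np.isfinite(t) & np.isfinite(series.excess29) & np.isfinite(series.excess30)
    )
    t = t[keep]
    y29 = series.excess29[keep]
    y30 = series.excess30[keep]
    groups = [np.flatnonzero(t == u) for u in np.unique(t)]

    a_bs = np.empty(b)
    d_bs = np.empty(b)
    ra_bs = np.full(b, np.nan)
    fn = labels.f_no3
    for i in range(b):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        p29 = _fast_slope(t[idx], y29[idx])
        p30 = _fast_slope(t[idx], y30[idx])
        d = max(p30 / (fn * fn), 0.0)
        a = max((p29 + 2.0 * (1.0 - 1.0 / fn) * p30) / fn, 0.0)
        a_bs[i], d_bs[i] = a, d
        if a + d > 0:
            ra_bs[i] = 100.0 * a / (a + d)

    def ci(x: np.ndarray) -> Optional[List[float]]:
        x = x[np.isfinite(x)]
        if x.size == 0:
            return None
        lo, hi = np.percentile(x, [2.5, 97.5])
        return [float(lo), float(hi)]

    return {"anammox": ci(a_bs), "denitrification": ci(d_bs), "ra": ci(ra_bs)}


def _qc_to_dict(qc: QCResult) -> Dict:
    return {
        "check_name": qc.check_name,
        "passed": bool(qc.passed),
        "detail": qc.detail,
        "fits": {
            str(m): {
                "slope": f.slope,
                "se_slope": f.se_slope,
                "p_value": f.p_value,
                "n_points": f.n_points,
            }
            for m, f in qc.fits.items()
        },
    }


def _per_replicate_rates(
    series: VialSeries, labels: LabelFractions, config: ExperimentConfig
) -> Dict[str, List[float]]:
    out: Dict[str, List[float]] = {"anammox": [], "denitrification": [], "ra": []}
    for rep in sorted(np.unique(series.replicate)):
        sub = series.select_replicate(int(rep))
        try:
            f29 = fit_production_rate(sub, 29, time_window=config.rate_window)
            f30 = fit_production_rate(sub, 30, time_window=config.rate_window)
        except InsufficientDataError:
            logger.warning(
                "%s replicate %d: too few points for a per-replicate fit",
                series.sample_id, rep,
            )
            continue
        proc = ipt_invert(ProductionRates(f29.slope, f30.slope), labels)
        out["anammox"].append(proc.anammox)
        out["denitrification"].append(proc.denitrification)
        if math.isfinite(proc.ra):
            out["ra"].append(proc.ra)
    return out


def _data_checksum(data: Sequence[VialSeries]) -> str:
    h = hashlib.sha256()
    for s in sorted(data, key=lambda s: (s.sample_id, s.treatment)):
        h.update(f"{s.sample_id}|{s.zone}|{s.fertilization}|{s.treatment}".encode())
        for arr in (s.time_h, s.replicate, s.excess29, s.excess30):
            h.update(np.asarray(arr, dtype=float).tobytes())
    return h.hexdigest()


@dataclass
class ExperimentReport:
    """Pipeline output: per-sample rates, QC verdicts, group statistics."""

    samples: Dict[str, Dict]
    group_stats: Dict
    skipped: List[Dict]
    provenance: Dict
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> Dict:
        return {
            "schema_version": self.schema_version,
            "samples": self.samples,
            "group_stats": self.group_stats,
            "skipped": self.skipped,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=True) + "\n"

    def text_table(self) -> str:
        """Plain-text summary: one row per sample group."""
        header = (
            f"{'sample':<10}{'zone':<16}{'fert':<9}"
            f"{'anammox':>10}{'denitrif':>10}{'ra_%':>7}{'ra':>5}"
            f"  {'A':<4}{'D':<4}{'ra':<4}{'QC':<6}"
        )
        lines = [header, "-" * len(header)]
        letters = self.group_stats.get("duncan_letters", {})
        for sid in sorted(self.samples):
            rec = self.samples[sid]
            la = letters.get("anammox", {}).get(sid, "-")
            ld = letters.get("denitrification", {}).get(sid, "-")
            lr = letters.get("ra", {}).get(sid, "-")
            qc = rec.get("validated")
            qc_s = "ok" if qc else ("FAIL" if qc is False else "n/a")
            ra = rec["rates"]["ra"]
            ra_s = f"{ra:7.2f}" if ra is not None else "    n/a"
            ra_d = rec["rates"]["ra_display"]
            ra_d_s = f"{ra_d:>4d}%" if ra_d is not None else "  n/a"
            lines.append(
                f"{sid:<10}{rec['zone']:<16}{rec['fertilization']:<9}"
                f"{rec['rates']['anammox']:>10.3f}"
                f"{rec['rates']['denitrification']:>10.3f}"
                f"{ra_s}{ra_d_s}"
                f"  {la:<4}{ld:<4}{lr:<4}{qc_s:<6}"
            )
        lines.append("")
        lines.append(
            "rates in nmol N2 g-1 dry soil h-1; groups sharing a letter do "
            "not differ (Duncan, alpha={:g})".format(
                self.provenance["config"]["alpha"]
            )
        )
        return "\n".join(lines) + "\n"


def run_experiment(
    data: Sequence[VialSeries], config: Optional[ExperimentConfig] = None
) -> ExperimentReport:
    """Run the full analysis over a collection of vial series.

    For each sample the 15NO3- treatment series is required (samples
    without one are skipped and logged); the 15NH4+ and 15NH4+ + 14NO3-
    series feed the QC checks when present.  Rates come from pooled-
    replicate OLS slopes inverted through the pairing model; uncertainty
    from a seeded bootstrap over replicate vials; group letters from
    Duncan's test on per-replicate rates; zone contrasts from pooled
    t-tests within each fertilization level.
    """
    if config is None:
        config = ExperimentConfig()

    by_sample: Dict[str, Dict[str, VialSeries]] = {}
    for s in data:
        slot = by_sample.setdefault(s.sample_id, {})
        if s.treatment in slot:
            raise InvalidInputError(
                f"duplicate series for sample {s.sample_id!r} "
                f"treatment {s.treatment!r}"
            )
        slot[s.treatment] = s

    samples: Dict[str, Dict] = {}
    skipped: List[Dict] = []
    per_rep_by_sample: Dict[str, Dict[str, List[float]]] = {}

    for idx, sample_id in enumerate(sorted(by_sample)):
        trt = by_sample[sample_id]
        if "nit15" not in trt:
            msg = "no nit15 series: rates cannot be computed"
            logger.error("sample %s skipped: %s", sample_id, msg)
            skipped.append({"sample_id": sample_id, "reason": msg})
            continue

        def _prepared(series: VialSeries) -> VialSeries:
            if series.metadata.get("is_raw"):
                return compute_excess(series, config.baseline_policy)
            return series

        qc: Dict[str, Dict] = {}
        if "amm15" in trt:
            qc["preincubation"] = _qc_to_dict(
                check_preincubation(_prepared(trt["amm15"]), config.alpha)
            )
        else:
            logger.warning("sample %s: no amm15 series, preincubation QC skipped",
                           sample_id)
        if "amm15_nit14" in trt:
            qc["anammox_signature"] = _qc_to_dict(
                check_anammox_signature(_prepared(trt["amm15_nit14"]), config.alpha)
            )
        else:
            logger.warning(
                "sample %s: no amm15_nit14 series, anammox-signature QC skipped",
                sample_id,
            )
        validated = all(v["passed"] for v in qc.values()) if qc else None

        nit = _prepared(trt["nit15"])
        fit29 = fit_production_rate(nit, 29, time_window=config.rate_window)
        fit30 = fit_production_rate(nit, 30, time_window=config.rate_window)
        labels = LabelFractions(
            f_no3=nit.f_no3 if nit.f_no3 is not None else config.f_no3_default,
            f_nh4=config.f_nh4_default,
        )
        prod = ProductionRates(
            p29=fit29.slope,
            p30=fit30.slope,
            se29=fit29.se_slope,
            se30=fit30.se_slope,
            p29_signif=detect_accumulation(fit29, config.alpha),
            p30_signif=detect_accumulation(fit30, config.alpha),
        )
        proc = ipt_invert(prod, labels)
        if proc.clamped:
            logger.warning(
                "sample %s: negative raw rate clamped to 0 "
                "(raw A=%.4g, raw D=%.4g)",
                sample_id, proc.raw_anammox, proc.raw_denitrification,
            )

        rng = np.random.default_rng([config.seed, idx])
        cis = _bootstrap_rates(nit, labels, config, rng)

        per_rep = _per_replicate_rates(nit, labels, config)
        per_rep_by_sample[sample_id] = per_rep
        ra_ok = math.isfinite(proc.ra)

        samples[sample_id] = {
            "zone": nit.zone,
            "fertilization": nit.fertilization,
            "labels": {"f_no3": labels.f_no3, "f_nh4": labels.f_nh4},
            "production": {
                "p29": prod.p29, "p30": prod.p30,
                "se29": prod.se29, "se30": prod.se30,
                "p29_significant": prod.p29_signif,
                "p30_significant": prod.p30_signif,
                "r2_29": fit29.r2, "r2_30": fit30.r2,
                "n_points": fit29.n_points,
            },
            "rates": {
                "anammox": proc.anammox,
                "denitrification": proc.denitrification,
                "ra": proc.ra if ra_ok else None,
                "ra_display": display_percent(proc.ra) if ra_ok else None,
                "clamped": proc.clamped,
                "ci_anammox": None if cis is None else cis["anammox"],
                "ci_denitrification": None if cis is None else cis["denitrification"],
                "ci_ra": None if cis is None else cis["ra"],
            },
            "per_replicate": {
                **per_rep,
                "ra_mean": (
                    float(np.mean(per_rep["ra"])) if per_rep["ra"] else None
                ),
            },
            "qc": qc,
            "validated": validated,
        }

    if not samples:
        raise InvalidInputError("all samples skipped: nothing to analyze")

    group_stats = _group_statistics(samples, per_rep_by_sample, config)

    provenance = {
        "software": {"name": "n2part", "version": __version__},
        "config": config.to_dict(),
        "seed": config.seed,
        "input_sha256": _data_checksum(data),
        "n_series": len(data),
    }
    return ExperimentReport(
        samples=samples,
        group_stats=group_stats,
        skipped=skipped,
        provenance=provenance,
    )


def _group_statistics(
    samples: Dict[str, Dict],
    per_rep: Dict[str, Dict[str, List[float]]],
    config: ExperimentConfig,
) -> Dict:
    metrics = ("anammox", "denitrification", "ra")
    stats_out: Dict = {"duncan_letters": {}, "summaries": {}, "t_tests": {}}

    usable = {
        sid: pr for sid, pr in per_rep.items()
        if all(len(pr[m]) >= 2 for m in metrics)
    }
    for metric in metrics:
        ids = sorted(usable)
        groups = [usable[sid][metric] for sid in ids]
        stats_out["summaries"][metric] = [
            {"group_id": s.group_id, "n": s.n, "mean": s.mean, "se": s.se}
            for s in summarize(groups, ids)
        ] if ids else []
        if len(ids) >= 2:
            try:
                res = duncan_mrt(groups, alpha=config.alpha, group_ids=ids)
                stats_out["duncan_letters"][metric] = dict(
                    zip(res.group_ids, res.letters)
                )
            except InvalidInputError as exc:
                logger.warning("Duncan test skipped for %s: %s", metric, exc)

    # rhizosphere vs non-rhizosphere within each fertilization level
    for fert in FERTILIZATIONS:
        zone_ids = {
            z: [sid for sid in usable
                if samples[sid]["fertilization"] == fert
                and samples[sid]["zone"] == z]
            for z in ZONES
        }
        if not all(zone_ids[z] for z in ZONES):
            continue
        entry = {}
        for metric in metrics:
            a = [v for sid in zone_ids["rhizosphere"] for v in usable[sid][metric]]
            b = [v for sid in zone_ids["non_rhizosphere"] for v in usable[sid][metric]]
            try:
                t, p = ttest_two(a, b)
                entry[metric] = {"t": t, "p": p,
                                 "significant": bool(p < config.alpha)}
            except InvalidInputError as exc:
                logger.warning("t-test skipped (%s, %s): %s", fert, metric, exc)
        if entry:
            stats_out["t_tests"][fert] = entry
    return stats_out


def write_report(
    report: ExperimentReport,
    path: Union[str, Path],
    format: str = "json",
) -> Path:
    """Serialize a report; verifies internal consistency before writing.

    Every reported anammox share must be recomputable from the reported
    rates (guards against report-assembly bugs).
    """
    for sid, rec in report.samples.items():
        a = rec["rates"]["anammox"]
        d = rec["rates"]["denitrification"]
        ra = rec["rates"]["ra"]
        if a + d > 0:
            expect = contribution(a, d)
            if ra is None or abs(ra - expect) > 1e-9:
                raise InvalidInputError(
                    f"report inconsistency for sample {sid!r}: "
                    f"ra={ra} but contribution(A, D)={expect}"
                )
        elif ra is not None:
            raise InvalidInputError(
                f"report inconsistency for sample {sid!r}: ra reported "
                "although A + D = 0"
            )

    path = Path(path)
    if format == "json":
        path.write_text(report.to_json())
    elif format == "text_table":
        path.write_text(report.text_table())
    else:
        raise InvalidInputError(
            f"unknown report format {format!r}; allowed: json, text_table"
        )
    return path
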