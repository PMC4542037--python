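"""Group comparison layer: means +/- s.e., one-way ANOVA, Duncan's multiple
range test with compact letter display, and two-group Student's t-tests.

Duncan's test compares ordered group means against least significant
ranges.  For a span of r ordered means the critical range is

    R_r = q(p_r, r, df) * sqrt(MSE / n_h),      p_r = (1 - alpha)^(r - 1)

where q is the studentized-range quantile at cumulative probability p_r
(protection level), MSE and df come from the one-way ANOVA, and n_h is the
harmonic mean of group sizes (the standard extension to unbalanced
designs).  Two means differ iff their gap exceeds the range for their span
and they are not both inside a span already declared homogeneous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .isotope_core import InvalidInputError

__all__ = [
    "GroupSummary",
    "DuncanResult",
    "anova_oneway",
    "duncan_mrt",
    "ttest_two",
    "summarize",
]

logger = logging.getLogger("n2part")


@dataclass
class GroupSummary:
    group_id: str
    n: int
    mean: float
    se: float
    letter: str = ""


@dataclass
class DuncanResult:
    """Duncan multiple-range verdicts, one letter string per input group.

    Groups sharing any letter are not significantly different at alpha.
    """

    group_ids: List[str]
    letters: List[str]
    means: List[float]
    mse: float
    df_error: int
    critical_ranges: dict  # span r -> least significant range

    def letter_of(self, group_id: str) -> str:
        return self.letters[self.group_ids.index(group_id)]


def _as_groups(groups: Sequence[Sequence[float]], min_n: int) -> List[np.ndarray]:
    out = []
    for i, g in enumerate(groups):
        arr = np.asarray(g, dtype=float)
        if arr.ndim != 1 or arr.size < min_n:
            raise InvalidInputError(
                f"group {i} needs n >= {min_n}, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"group {i} contains non-finite values")
        out.append(arr)
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns the F statistic and p-value.  Requires >= 2 groups with n >= 2
    each and nonzero total variance.
    """
    if len(groups) < 2:
        raise InvalidInputError("anova_oneway needs >= 2 groups")
    gs = _as_groups(groups, min_n=2)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        raise InvalidInputError("zero total variance: F is undefined")
    f, p = stats.f_oneway(*gs)
    return float(f), float(p)


def ttest_two(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided pooled-variance Student's t-test."""
    ga, gb = _as_groups([a, b], min_n=2)
    if np.ptp(ga) == 0 and np.ptp(gb) == 0 and ga[0] == gb[0]:
        raise InvalidInputError(
            "degenerate t-test: both groups constant and equal"
        )
    t, p = stats.ttest_ind(ga, gb, equal_var=True)
    return float(t), float(p)


def summarize(
    groups: Sequence[Sequence[float]],
    group_ids: Optional[Sequence[str]] = None,
) -> List[GroupSummary]:
    """Mean and standard error (sd/sqrt(n)) per group."""
    if group_ids is None:
        group_ids = [f"group{i+1}" for i in range(len(groups))]
    if len(group_ids) != len(groups):
        raise InvalidInputError("group_ids length must match groups")
    out = []
    for gid, g in zip(group_ids, groups):
        arr = np.asarray(g, dtype=float)
        if arr.size == 0:
            raise InvalidInputError(f"group {gid!r} is empty")
        mean = float(np.mean(arr))
        if arr.size == 1:
            logger.warning("group %r has n=1: s.e. undefined, reported as 0", gid)
            se = 0.0
        else:
            se = float(np.std(arr, ddof=1) / math.sqrt(arr.size))
            if se == 0.0:
                logger.warning("group %r has zero variance: s.e. = 0", gid)
        out.append(GroupSummary(group_id=str(gid), n=int(arr.size), mean=mean, se=se))
    return out


@lru_cache(maxsize=512)
def _duncan_quantile(alpha: float, r: int, df: int) -> float:
    # protection level (1-alpha)^(r-1): Duncan's per-span significance level
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (r - 1), r, df))


def duncan_mrt(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    group_ids: Optional[Sequence[str]] = None,
) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Implements the classical step-down procedure on the sorted means: the
    widest span is tested first; a span whose extreme means differ by less
    than its least significant range is declared homogeneous as a whole
    (no pair inside it is tested further).  Homogeneous spans become the
    letters of the compact letter display; the display is invariant to the
    input order of the groups.
    """
    if len(groups) < 2:
        raise InvalidInputError("duncan_mrt needs >= 2 groups")
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    gs = _as_groups(groups, min_n=2)
    if group_ids is None:
        group_ids = [f"group{i+1}" for i in range(len(gs))]
    k = len(gs)
    sizes = np.array([g.size for g in gs], dtype=float)
    means = np.array([g.mean() for g in gs])
    df_error = int(sizes.sum()) - k
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    mse = sse / df_error
    n_h = k / float(np.sum(1.0 / sizes))
    sem = math.sqrt(mse / n_h)

    ranges = {
        r: _duncan_quantile(alpha, r, df_error) * sem for r in range(2, k + 1)
    }

    # order by mean ascending; ties keep input order (gap 0, so the tie
    # cannot create a significant pair either way)
    order = np.argsort(means, kind="stable")
    sm = means[order]

    homogeneous: set = set()

    def scan(i: int, j: int) -> None:
        # the same sub-span can be reached through both recursion branches
        if i >= j or (i, j) in homogeneous:
            return
        if sm[j] - sm[i] <= ranges[j - i + 1]:
            homogeneous.add((i, j))
        else:
            scan(i, j - 1)
            scan(i + 1, j)

    scan(0, k - 1)

    # keep maximal homogeneous spans; uncovered singletons get their own letter
    spans = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in homogeneous)
    ]
    for pos in range(k):
        if not any(a <= pos <= b for a, b in spans):
            spans.append((pos, pos))
    spans.sort()

    letters_sorted = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(spans):
        letter = _letter(idx)
        for pos in range(a, b + 1):
            letters_sorted[pos] += letter

    letters = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        letters[int(orig)] = letters_sorted[pos]
    return DuncanResult(
        group_ids=[str(g) for g in group_ids],
        letters=letters,
        means=[float(m) for m in means],
        mse=mse,
        df_error=df_error,
        critical_ranges=ranges,
    )


def _letter(idx: int) -> str:
    # a..z, then aa, ab, ... for pathological numbers of groups
    out = ""
    idx += 1
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
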