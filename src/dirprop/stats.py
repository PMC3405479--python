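"""Study statistics: one-way ANOVA, expert-score summaries, and
point-biserial correlation of agreement metrics against dichotomized
expert scores (scores 1-2 pooled vs. score 3)."""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy import stats as sps

__all__ = [
    "ExpertScore",
    "ScoreSummary",
    "one_way_anova",
    "point_biserial",
    "score_summary",
    "dichotomize_scores",
]

VALID_SCORES = (1, 2, 3)


@dataclass
class ExpertScore:
    """Clinical-utility rating of one propagated ROI.

    1 = no edits required; 2 = minor edits, useful; 3 = major edits, not
    useful.
    """

    roi_label: str
    algorithm: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in VALID_SCORES:
            raise ValueError(f"score must be one of {VALID_SCORES}, got {self.value}")


@dataclass
class ScoreSummary:
    counts: dict  # score -> count
    n_total: int
    proportion_useful: float  # fraction scored 1 or 2
    proportion_major: float  # fraction scored 3

    @property
    def percent_useful(self) -> int:
        """proportion_useful as a percentage rounded to the nearest integer."""
        return int(round(100.0 * self.proportion_useful))

    @property
    def percent_major(self) -> int:
        return int(round(100.0 * self.proportion_major))


def score_summary(scores) -> ScoreSummary:
    """Tally scores and compute the useful (1-2) and major-edit (3) rates."""
    values = [s.value if isinstance(s, ExpertScore) else int(s) for s in scores]
    if not values:
        raise ValueError("score_summary requires at least one score")
    bad = [v for v in values if v not in VALID_SCORES]
    if bad:
        raise ValueError(f"invalid score values: {sorted(set(bad))}")
    counts = Counter(values)
    n = len(values)
    useful = (counts.get(1, 0) + counts.get(2, 0)) / n
    major = counts.get(3, 0) / n
    return ScoreSummary({k: counts.get(k, 0) for k in VALID_SCORES}, n, useful, major)


def dichotomize_scores(values) -> np.ndarray:
    """0 for scores 1-2 (useful), 1 for score 3 (major edits)."""
    arr = np.asarray([v.value if isinstance(v, ExpertScore) else int(v) for v in values])
    if not np.isin(arr, VALID_SCORES).all():
        raise ValueError("scores must be 1, 2 or 3")
    return (arr == 3).astype(int)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA between/within decomposition.

    Returns (F, p) with p from the F distribution on (k-1, N-k) degrees of
    freedom.  Zero between-group variance gives F = 0, p = 1; zero
    within-group variance with unequal means gives F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("one_way_anova needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = k - 1
    df_w = n_total - k
    if ssb <= 1e-300:
        return 0.0, 1.0
    if ssw <= 1e-300:
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def point_biserial(binary_group, values) -> tuple[float, float]:
    """Point-biserial correlation: Pearson r of a 0/1 coding with values.

    Returns (r_pb, two-sided p) with p from the t transform on n-2 degrees
    of freedom.
    """
    g = np.asarray(binary_group, dtype=np.float64)
    x = np.asarray(values, dtype=np.float64)
    if g.shape != x.shape or g.ndim != 1:
        raise ValueError("binary_group and values must be equal-length 1D")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("binary_group must contain only 0 and 1")
    if len(np.unique(g)) < 2:
        raise ValueError("both binary levels must be present")
    if np.ptp(x) == 0:
        raise ValueError("values are constant; correlation undefined")
    gc = g - g.mean()
    xc = x - x.mean()
    r = float((gc * xc).sum() / np.sqrt((gc * gc).sum() * (xc * xc).sum()))
    n = len(x)
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip * r_clip))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p
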