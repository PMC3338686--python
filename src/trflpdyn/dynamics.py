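"""Moving-window change-rate statistic for community time series.

Pairwise similarity between fingerprints is the Pearson product-moment
correlation of their relative-abundance vectors, expressed as a percentage
(r x 100).  The change value between two consecutive sampling dates is
100 - similarity; plotting change against the later date of each pair is the
moving-window analysis, and the mean +/- sample standard deviation of the
change values is the headline rate-of-change statistic Delta_t for the
sampling interval (Delta_t(15 days) for a 15-day campaign).

A negative correlation makes the change value exceed 100%; values are not
clamped (the subtraction formula is applied literally) but a warning is
issued, since the change-percentage framing presumes r >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import CommunityProfile, ProfileSeries


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of Pearson similarity percentages (r x 100)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        self.values = v


@dataclass
class ChangeSeries:
    """Consecutive-pair change percentages and their Delta_t summary."""

    pair_end_days: np.ndarray  # later day of each consecutive pair
    gap_days: np.ndarray  # actual spacing of the pair (may differ from nominal)
    changes: np.ndarray  # 100 - similarity, percent
    delta_t_mean: float
    delta_t_sd: float  # sample (n-1) sd; NaN when < 2 retained pairs
    n_pairs_used: int
    excluded_before_day: float | None = None
    pair_labels: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "pair_end_day": self.pair_end_days,
                "gap_days": self.gap_days,
                "change_percent": self.changes,
            }
        ).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "delta_t_mean": self.delta_t_mean,
            "delta_t_sd": self.delta_t_sd,
            "n_pairs": self.n_pairs_used,
            "excluded_before_day": self.excluded_before_day,
        }


def _aligned_vectors(
    a: CommunityProfile, b: CommunityProfile
) -> tuple[np.ndarray, np.ndarray]:
    bins = sorted(set(a.abundances) | set(b.abundances))
    return a.as_vector(bins), b.as_vector(bins)


def pearson_similarity(a: CommunityProfile, b: CommunityProfile) -> float:
    """Pearson correlation of two profiles over the union of their bins, x 100."""
    x, y = _aligned_vectors(a, b)
    if len(x) < 2:
        raise ValueError(
            f"samples {a.sample_id!r}/{b.sample_id!r}: need >= 2 bins for correlation"
        )
    for v, p in ((x, a), (y, b)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"sample {p.sample_id!r}: constant abundance vector (zero variance)"
            )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return 100.0 * r


def similarity_matrix(series: ProfileSeries) -> SimilarityMatrix:
    """All pairwise Pearson similarities; symmetric with a diagonal of 100."""
    n = len(series)
    if n < 2:
        raise ValueError("need >= 2 samples")
    m = np.full((n, n), 100.0)
    profs = list(series)
    for i in range(n):
        for j in range(i + 1, n):
            s = pearson_similarity(profs[i], profs[j])
            m[i, j] = m[j, i] = s
    return SimilarityMatrix(series.sample_ids, m)


def moving_window(
    series: ProfileSeries, exclude_before_day: float | None = None
) -> ChangeSeries:
    """Change values between consecutive sampling dates, summarized as Delta_t.

    Consecutive means adjacent in the time-sorted series even if the gap
    differs from the nominal interval; the actual gap is recorded per pair.
    Delta_t statistics cover only pairs whose later day is strictly greater
    than ``exclude_before_day`` (all pairs when None) — used to drop an
    initial non-stationary start-up phase from the summary.
    """
    profs = list(series)
    if len(profs) < 2:
        raise ValueError("need >= 2 samples")
    end_days, gaps, changes, labels = [], [], [], []
    negative = []
    for prev, cur in zip(profs, profs[1:]):
        sim = pearson_similarity(prev, cur)
        if sim < 0:
            negative.append((prev.sample_id, cur.sample_id))
        end_days.append(cur.time_days)
        gaps.append(cur.time_days - prev.time_days)
        changes.append(100.0 - sim)
        labels.append((prev.sample_id, cur.sample_id))
    if negative:
        warnings.warn(
            f"negative Pearson correlation for pair(s) {negative}: change value "
            "exceeds 100%",
            stacklevel=2,
        )
    end_days_arr = np.array(end_days)
    changes_arr = np.array(changes)
    if exclude_before_day is None:
        used = np.ones(len(changes_arr), dtype=bool)
    else:
        used = end_days_arr > exclude_before_day
    n_used = int(used.sum())
    if n_used == 0:
        mean = float("nan")
        sd = float("nan")
    else:
        mean = float(changes_arr[used].mean())
        sd = float(changes_arr[used].std(ddof=1)) if n_used >= 2 else float("nan")
    return ChangeSeries(
        pair_end_days=end_days_arr,
        gap_days=np.array(gaps),
        changes=changes_arr,
        delta_t_mean=mean,
        delta_t_sd=sd,
        n_pairs_used=n_used,
        excluded_before_day=exclude_before_day,
        pair_labels=labels,
    )
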