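"""Mantel tests between community and environmental distance matrices.

The Mantel statistic r_M is the Pearson correlation between the corresponding
off-diagonal (upper-triangle) entries of two distance matrices; its null
distribution is built by jointly permuting the rows and columns of one matrix.
The sampled-mode P-value uses the (1 + b)/(1 + n_perm) estimator; for n <= 7
samples an exhaustive mode enumerates all n! relabelings and reports the exact
proportion (the identity relabeling is included, so P > 0).

Distance matrices travel as :class:`skbio.DistanceMatrix`.  The community
matrix defaults to Bray-Curtis dissimilarity on relative abundances (the
ecological convention); ``one-minus-pearson`` is offered for consistency with
the moving-window similarity.  Environmental matrices are absolute differences
of a single (optionally z-scored) variable, with missing values handled
complete-case.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .profiles import ProfileSeries

logger = logging.getLogger(__name__)

COMMUNITY_METRICS = ("bray-curtis", "one-minus-pearson")
_EXHAUSTIVE_MAX_N = 7


@dataclass
class MantelResult:
    r_m: float
    p_value: float
    n_samples: int
    n_permutations: int | None  # None in exhaustive mode
    exhaustive: bool
    tail: str

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r_m <= 1.0 + 1e-12):
            raise ValueError(f"r_M out of range: {self.r_m}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"P out of range: {self.p_value}")


def community_distance(
    series: ProfileSeries, metric: str = "bray-curtis"
) -> DistanceMatrix:
    """Pairwise community distances on the relative-abundance matrix."""
    if metric not in COMMUNITY_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; options: {', '.join(COMMUNITY_METRICS)}"
        )
    if len(series) < 3:
        raise ValueError("need >= 3 samples")
    M = series.matrix().to_numpy()
    if metric == "bray-curtis":
        d = squareform(pdist(M, metric="braycurtis"))
    else:
        r = np.corrcoef(M)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=series.sample_ids)


def variable_distance(
    env: pd.DataFrame, variable: str, standardize: bool = True
) -> DistanceMatrix:
    """|z_i - z_j| distances on one covariate, complete-case over samples."""
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in env table")
    x = pd.to_numeric(env[variable], errors="coerce")
    ids = env["sample_id"].astype(str)
    keep = x.notna()
    dropped = list(ids[~keep])
    if dropped:
        logger.info("variable %r: dropping samples with missing values: %s",
                    variable, dropped)
    x = x[keep].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"variable {variable!r}: fewer than 3 non-missing values")
    if standardize:
        sd = x.std(ddof=1)
        if sd > 0:
            x = (x - x.mean()) / sd
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(d, ids=list(ids[keep]))


def _triangle(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_test(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    mode: str = "sampled",
) -> MantelResult:
    """Mantel correlation between two distance matrices with permutation P.

    ``dy`` is aligned to ``dx``'s labels, then its rows/columns are jointly
    permuted to build the null.  ``tail='greater'`` tests for positive
    association (the usual ecological question); ``'two-sided'`` compares
    absolute values.  ``mode='exhaustive'`` enumerates all n! relabelings
    (n <= 7 only).
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if mode not in ("sampled", "exhaustive"):
        raise ValueError("mode must be 'sampled' or 'exhaustive'")
    sx, sy = set(dx.ids), set(dy.ids)
    if sx != sy:
        raise ValueError(
            f"label mismatch: only in first = {sorted(sx - sy)}, "
            f"only in second = {sorted(sy - sx)}"
        )
    n = dx.shape[0]
    if n < 4:
        raise ValueError("need >= 4 samples for a Mantel test")
    dy = dy.filter(dx.ids)  # align order
    X = dx.data
    Y = dy.data
    tx = _triangle(X)
    if tx.std() == 0 or _triangle(Y).std() == 0:
        raise ValueError("zero variance in distance triangle")
    txc = tx - tx.mean()
    tx_norm = math.sqrt(float(txc @ txc))

    def corr_with(yperm: np.ndarray) -> float:
        ty = _triangle(yperm)
        tyc = ty - ty.mean()
        return float(txc @ tyc) / (tx_norm * math.sqrt(float(tyc @ tyc)))

    r_obs = corr_with(Y)

    def extreme(r_null: float) -> bool:
        if tail == "greater":
            return r_null >= r_obs - 1e-12
        return abs(r_null) >= abs(r_obs) - 1e-12

    if mode == "exhaustive":
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive mode limited to n <= {_EXHAUSTIVE_MAX_N} (n = {n})"
            )
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            if extreme(corr_with(Y[np.ix_(p, p)])):
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, n, None, True, tail)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if extreme(corr_with(Y[np.ix_(p, p)])):
            b += 1
    return MantelResult(r_obs, (1 + b) / (1 + n_perm), n, n_perm, False, tail)


def mantel_table(
    series: ProfileSeries,
    env: pd.DataFrame,
    variables: list[str] | None = None,
    *,
    metric: str = "bray-curtis",
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    standardize: bool = True,
) -> pd.DataFrame:
    """One Mantel test per environmental variable against the community matrix.

    Reproduces the classic per-variable association table: one row per
    covariate with r_M and P.  Samples missing a variable are dropped from
    both matrices for that variable only (complete-case per variable).
    """
    if variables is None:
        variables = [
            c for c in env.columns
            if c not in ("sample_id", "time_days")
            and pd.api.types.is_numeric_dtype(env[c])
        ]
    dcom_full = community_distance(series, metric)
    rows = []
    rng = np.random.default_rng(seed)
    for v in variables:
        dv = variable_distance(env, v, standardize=standardize)
        dcom = dcom_full.filter(dv.ids) if set(dv.ids) != set(dcom_full.ids) else dcom_full
        res = mantel_test(
            dcom, dv, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), tail=tail,
        )
        rows.append(
            dict(variable=v, r_M=res.r_m, P=res.p_value, n=res.n_samples)
        )
    return pd.DataFrame(rows)
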