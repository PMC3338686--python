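"""Canonical correspondence analysis (CCA) with Monte-Carlo permutation inference.

CCA is the constrained form of correspondence analysis (CA): the chi-square
standardized abundance matrix is projected onto the span of the (row-weighted)
environmental covariates before the eigen-decomposition, so the canonical axes
are the directions of community variation that are linear combinations of the
measured variables.  Variance is measured as chi-square inertia; constrained
plus residual inertia equals the total inertia of the unconstrained CA.

With P = Y / grand total, row sums r and column sums c, the standardized
matrix is

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j),        total inertia = sum Q^2.

Constraints X are weighted-standardized (weights r), the fitted matrix
Q_hat = H_X Q is obtained by weighted least squares, and its singular values
squared are the canonical eigenvalues.  Significance of the constraints is
assessed by unrestricted Monte-Carlo permutation of the rows of X (the "full
model" scheme); forward selection of variables conditions on the already
included set by permuting the candidate's residuals.

Everything here is implemented from first principles on top of numpy
linear algebra; no ordination library is called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EIG_TOL = 1e-12
_VIF_THRESHOLD = 20.0


@dataclass
class CCAResult:
    """Eigenstructure and scores of a fitted canonical correspondence analysis."""

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    site_scores: pd.DataFrame  # linear-combination (constrained) site scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # per-variable arrow coordinates
    scaling: str
    dropped_variables: list[str] = field(default_factory=list)
    p_first_axis: float | None = None
    p_all_axes: float | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def species_variance_explained_pct(self) -> float:
        """Share of species (community) variance captured by the constraints, %."""
        return 100.0 * self.constrained_inertia / self.total_inertia

    def species_env_explained_pct(self, n_display_axes: int = 2) -> float:
        """Share of the species-environment relation shown by the first axes, %."""
        k = min(n_display_axes, self.n_axes)
        if self.constrained_inertia == 0:
            return 0.0
        return 100.0 * float(self.eigenvalues[:k].sum()) / self.constrained_inertia

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "residual_inertia": self.residual_inertia,
            "species_variance_explained_pct": self.species_variance_explained_pct,
            "species_env_explained_pct_2axes": self.species_env_explained_pct(2),
            "scaling": self.scaling,
            "dropped_variables": self.dropped_variables,
            "p_first_axis": self.p_first_axis,
            "p_all_axes": self.p_all_axes,
        }


@dataclass
class ForwardSelectionTrace:
    """Per-round record of greedy covariate selection with permutation tests."""

    rows: pd.DataFrame  # variable, added_inertia, pseudo_F, p_value, included
    included: list[str]
    alpha: float
    n_perm: int
    seed: int | None


def _as_matrix(Y) -> tuple[np.ndarray, list, list]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), list(Y.index), list(Y.columns)
    a = np.asarray(Y, dtype=float)
    return a, list(range(a.shape[0])), list(range(a.shape[1]))


def chi_square_standardize(Y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square standardized matrix Q plus row and column weights.

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j) with P = Y / grand total; the
    total CA inertia is the squared Frobenius norm of Q.
    """
    A, rows, cols = _as_matrix(Y)
    if (A < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    total = A.sum()
    if total <= 0:
        raise ValueError("abundance matrix has zero grand total")
    P = A / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    zr = np.nonzero(r == 0)[0]
    if len(zr):
        raise ValueError(f"zero row sum(s) at: {[rows[i] for i in zr]}")
    zc = np.nonzero(c == 0)[0]
    if len(zc):
        raise ValueError(f"zero column sum(s) at: {[cols[i] for i in zc]}")
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


def _screen_constraints(
    X: np.ndarray,
    names: list[str],
    r: np.ndarray,
    vif_threshold: float | None = _VIF_THRESHOLD,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Weighted-standardize X, dropping constant, collinear and high-VIF columns."""
    dropped: list[str] = []
    keep = []
    cols = []
    for j, name in enumerate(names):
        x = X[:, j]
        mu = float(r @ x)
        sd = float(np.sqrt(r @ (x - mu) ** 2))
        if sd < 1e-12:
            dropped.append(name)
            continue
        keep.append(name)
        cols.append((x - mu) / sd)
    if dropped:
        warnings.warn(f"dropping constant constraint column(s): {dropped}", stacklevel=3)
    if not cols:
        return np.empty((len(r), 0)), [], dropped
    Xs = np.column_stack(cols)
    # exact collinearity: rank-revealing QR on the weighted matrix
    Xw = np.sqrt(r)[:, None] * Xs
    qr_r = np.linalg.qr(Xw, mode="r")
    diag = np.abs(np.diag(qr_r))
    while Xs.shape[1] > 1:
        Xw = np.sqrt(r)[:, None] * Xs
        qr_r = np.linalg.qr(Xw, mode="r")
        diag = np.abs(np.diag(qr_r))
        tol = max(Xw.shape) * np.finfo(float).eps * diag.max()
        if (diag > tol).all():
            break
        j = int(np.argmin(diag))
        dropped.append(keep[j])
        warnings.warn(
            f"dropping collinear constraint column {keep[j]!r}", stacklevel=3
        )
        keep = keep[:j] + keep[j + 1 :]
        Xs = np.delete(Xs, j, axis=1)
    # variance-inflation screening on the weighted correlation matrix
    while vif_threshold is not None and Xs.shape[1] > 1:
        Xw = np.sqrt(r)[:, None] * Xs
        corr = Xw.T @ Xw
        try:
            vif = np.diag(np.linalg.inv(corr))
        except np.linalg.LinAlgError:
            vif = np.full(Xs.shape[1], np.inf)
        if np.nanmax(vif) <= vif_threshold:
            break
        j = int(np.argmax(vif))
        dropped.append(keep[j])
        warnings.warn(
            f"dropping constraint column {keep[j]!r} (VIF {vif[j]:.1f} > "
            f"{vif_threshold:g})",
            stacklevel=3,
        )
        keep = keep[:j] + keep[j + 1 :]
        Xs = np.delete(Xs, j, axis=1)
    return Xs, keep, dropped


def _orthonormal_basis(Xw: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-truncated QR)."""
    if Xw.shape[1] == 0:
        return Xw
    q, rr = np.linalg.qr(Xw)
    diag = np.abs(np.diag(rr))
    tol = max(Xw.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    return q[:, diag > tol]


def fit_cca(
    Y,
    X,
    scaling: str = "species",
    n_perm: int | None = None,
    seed: int | None = None,
    vif_threshold: float | None = _VIF_THRESHOLD,
) -> CCAResult:
    """Fit CCA of abundance matrix Y constrained by covariates X.

    ``scaling`` selects the biplot focus: ``"species"`` (inter-species
    distances: species in principal coordinates, sites in standard
    coordinates) or ``"site"`` (the converse).  When ``n_perm`` is given the
    global Monte-Carlo permutation P-values for the first axis and for all
    canonical axes are attached to the result.
    """
    if scaling not in ("species", "site"):
        raise ValueError("scaling must be 'species' or 'site'")
    A, site_ids, species_ids = _as_matrix(Y)
    Xv, _, xnames = _as_matrix(X)
    xnames = [str(v) for v in xnames]
    if Xv.shape[0] != A.shape[0]:
        raise ValueError("Y and X must have the same number of samples")
    Q, r, c = chi_square_standardize(A)
    total_inertia = float((Q**2).sum())
    sqrt_r = np.sqrt(r)

    Xs, kept, dropped = _screen_constraints(Xv, xnames, r, vif_threshold)
    n, m = Q.shape
    if Xs.shape[1] == 0:
        empty = pd.DataFrame(index=site_ids)
        return CCAResult(
            eigenvalues=np.empty(0),
            total_inertia=total_inertia,
            constrained_inertia=0.0,
            residual_inertia=total_inertia,
            site_scores=empty,
            species_scores=pd.DataFrame(index=species_ids),
            biplot_scores=pd.DataFrame(index=kept),
            scaling=scaling,
            dropped_variables=dropped,
        )

    B = _orthonormal_basis(sqrt_r[:, None] * Xs)
    Q_hat = B @ (B.T @ Q)
    U, s, Vt = np.linalg.svd(Q_hat, full_matrices=False)
    k_max = min(B.shape[1], m - 1, n - 1)
    eig = s**2
    k = int(min(k_max, (eig > _EIG_TOL).sum()))
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    eigenvalues = s**2
    constrained = float((Q_hat**2).sum())
    residual = total_inertia - constrained

    # sign convention: largest-magnitude species score positive on each axis
    raw_species = V / np.sqrt(c)[:, None]
    for a in range(k):
        col = raw_species[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, a] *= -1.0
            V[:, a] *= -1.0
            raw_species[:, a] *= -1.0

    axes = [f"CCA{i + 1}" for i in range(k)]
    if scaling == "species":
        species = raw_species * s  # principal coordinates
        sites = U / sqrt_r[:, None]  # standard coordinates
    else:
        species = raw_species
        sites = (U * s) / sqrt_r[:, None]

    # biplot arrows: weighted correlation of each kept covariate with the
    # (weighted) constrained site axes
    arrows = np.zeros((len(kept), k))
    lc_w = U  # weighted LC scores are exactly the left singular vectors
    for j in range(len(kept)):
        xw = sqrt_r * Xs[:, j]
        arrows[j] = xw @ lc_w
    if scaling == "species":
        arrows = arrows * s / np.sqrt(eigenvalues.max()) if k else arrows

    result = CCAResult(
        eigenvalues=eigenvalues,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        residual_inertia=residual,
        site_scores=pd.DataFrame(sites, index=site_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=species_ids, columns=axes),
        biplot_scores=pd.DataFrame(arrows, index=kept, columns=axes),
        scaling=scaling,
        dropped_variables=dropped,
    )
    if n_perm is not None:
        result.p_first_axis = permutation_test(
            A, Xv if not isinstance(X, pd.DataFrame) else X,
            statistic="first", n_perm=n_perm, seed=seed,
            vif_threshold=vif_threshold,
        )
        result.p_all_axes = permutation_test(
            A, Xv if not isinstance(X, pd.DataFrame) else X,
            statistic="trace", n_perm=n_perm, seed=seed,
            vif_threshold=vif_threshold,
        )
    return result


def _permuted_stats(
    Q: np.ndarray,
    sqrt_r: np.ndarray,
    r: np.ndarray,
    Xs: np.ndarray,
    perm_idx: np.ndarray,
    statistic: str,
) -> np.ndarray:
    """Constrained-inertia statistics for a stack of row permutations of Xs."""
    P = Xs[perm_idx]  # (n_perm, n, p)
    means = np.einsum("i,kip->kp", r, P)
    Pc = P - means[:, None, :]
    Pw = sqrt_r[None, :, None] * Pc
    Bk, _ = np.linalg.qr(Pw)
    T = np.einsum("kiq,im->kqm", Bk, Q)
    if statistic == "trace":
        return (T**2).sum(axis=(1, 2))
    sv = np.linalg.svd(T, compute_uv=False)
    return sv[:, 0] ** 2


def permutation_test(
    Y,
    X,
    statistic: str = "trace",
    n_perm: int = 499,
    seed: int | None = None,
    vif_threshold: float | None = _VIF_THRESHOLD,
) -> float:
    """Global Monte-Carlo permutation test of the CCA constraints.

    The rows of X are permuted as whole cases ("under the full model");
    ``statistic`` is either the sum of all canonical eigenvalues (``trace``)
    or the first canonical eigenvalue (``first``).  The P-value uses the
    (1 + b) / (1 + n_perm) estimator, so it can never be exactly zero; its
    minimum attainable value with 499 permutations is 1/500 = 0.002.
    """
    if statistic not in ("trace", "first"):
        raise ValueError("statistic must be 'trace' or 'first'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A, _, _ = _as_matrix(Y)
    Xv, _, xnames = _as_matrix(X)
    Q, r, c = chi_square_standardize(A)
    sqrt_r = np.sqrt(r)
    Xs, kept, _ = _screen_constraints(Xv, [str(v) for v in xnames], r, vif_threshold)
    if Xs.shape[1] == 0:
        return 1.0
    B = _orthonormal_basis(sqrt_r[:, None] * Xs)
    T = B.T @ Q
    if statistic == "trace":
        observed = float((T**2).sum())
    else:
        observed = float(np.linalg.svd(T, compute_uv=False)[0] ** 2)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    perm_idx = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    # permute the raw (unstandardized) columns as cases; re-standardization
    # happens inside the batched statistic because the row weights stay put
    Xraw = Xs  # already standardized wrt original weights; columns re-centered per perm
    stats = _permuted_stats(Q, sqrt_r, r, Xraw, perm_idx, statistic)
    b = int((stats >= observed - 1e-12).sum())
    return (1 + b) / (1 + n_perm)


def forward_select(
    Y,
    X,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int | None = None,
    statistic: str = "pseudo_f",
    vif_threshold: float | None = _VIF_THRESHOLD,
) -> ForwardSelectionTrace:
    """Greedy forward selection of constraints with Monte-Carlo testing.

    Each round evaluates every excluded variable's additional constrained
    inertia given the included set, permutation-tests the best candidate
    (permuting its residuals with respect to the included variables), and
    includes it when P < alpha.  ``statistic`` is the pseudo-F ratio
    (default) or the raw added inertia; the two rank candidates identically.
    """
    if statistic not in ("pseudo_f", "inertia"):
        raise ValueError("statistic must be 'pseudo_f' or 'inertia'")
    A, _, _ = _as_matrix(Y)
    Xv, _, xnames = _as_matrix(X)
    xnames = [str(v) for v in xnames]
    Q, r, c = chi_square_standardize(A)
    sqrt_r = np.sqrt(r)
    n = A.shape[0]
    rng = np.random.default_rng(seed)

    Xs, kept, _ = _screen_constraints(Xv, xnames, r, vif_threshold)
    candidates = dict(zip(kept, Xs.T))
    included: list[str] = []
    Zo = _orthonormal_basis(sqrt_r[:, None])  # intercept direction
    Q_r = Q - Zo @ (Zo.T @ Q)
    R0 = float((Q_r**2).sum())
    rows: list[dict] = []

    while candidates:
        deltas = {}
        units = {}
        for name, x in candidates.items():
            e = sqrt_r * x
            g = e - Zo @ (Zo.T @ e)
            ng2 = float(g @ g)
            if ng2 < 1e-20:
                deltas[name] = 0.0
                units[name] = None
                continue
            u = g / np.sqrt(ng2)
            deltas[name] = float(((u @ Q_r) ** 2).sum())
            units[name] = g
        best = max(deltas, key=lambda nm: deltas[nm])
        d_best = deltas[best]
        df_res = n - len(included) - 2
        if d_best < 1e-12 or df_res <= 0 or units[best] is None:
            for name in candidates:
                rows.append(
                    dict(variable=name, added_inertia=deltas[name],
                         pseudo_F=np.nan, p_value=np.nan, included=False)
                )
            break
        f_best = d_best / ((R0 - d_best) / df_res)

        # conditional permutation: shuffle the candidate's residuals w.r.t.
        # the included set, re-orthogonalize, and recompute the statistic
        g = units[best]
        w = g / sqrt_r  # raw residual values
        perm_idx = np.vstack([rng.permutation(n) for _ in range(n_perm)])
        E = w[perm_idx] * sqrt_r[None, :]
        G = E - (E @ Zo) @ Zo.T
        N2 = (G**2).sum(axis=1)
        ok = N2 > 1e-20
        D = np.zeros(n_perm)
        D[ok] = ((G[ok] @ Q_r) ** 2).sum(axis=1) / N2[ok]
        if statistic == "pseudo_f":
            stat_perm = D / ((R0 - D) / df_res)
            stat_obs = f_best
        else:
            stat_perm = D
            stat_obs = d_best
        b = int((stat_perm >= stat_obs - 1e-12).sum())
        p = (1 + b) / (1 + n_perm)
        take = p < alpha
        rows.append(
            dict(variable=best, added_inertia=d_best, pseudo_F=f_best,
                 p_value=p, included=bool(take))
        )
        if not take:
            for name in candidates:
                if name != best:
                    rows.append(
                        dict(variable=name, added_inertia=deltas[name],
                             pseudo_F=np.nan, p_value=np.nan, included=False)
                    )
            break
        included.append(best)
        u = units[best] / np.linalg.norm(units[best])
        Zo = np.column_stack([Zo, u])
        Q_r = Q_r - np.outer(u, u @ Q_r)
        R0 = float((Q_r**2).sum())
        del candidates[best]

    trace = pd.DataFrame(
        rows, columns=["variable", "added_inertia", "pseudo_F", "p_value", "included"]
    )
    return ForwardSelectionTrace(
        rows=trace, included=included, alpha=alpha, n_perm=n_perm, seed=seed
    )
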