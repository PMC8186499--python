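"""Ordination and correlation support analyses.

Correspondence analysis (CA) visualises unconstrained beta diversity of
the community table via the chi-square residual decomposition; redundancy
analysis (RDA) with a single enzyme-activity constraint quantifies the
fraction of community variance explained by the activity, with
significance from a permutation test on the constraint. Pearson helpers
serve the operational-parameter correlations (e.g. methane production
rate vs hydrolase activity over day windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

_EIG_TOL = 1e-12


class OrdinationError(ValueError):
    pass


@dataclass
class OrdinationResult:
    """Scores and inertia of a CA or RDA fit.

    For RDA, ``eigenvalues`` holds the constrained axis only (a single
    constraint yields one canonical axis); residual unconstrained axes
    are reported separately. ``constrained_fraction`` is constrained
    inertia / total inertia (the R² the permutation test assesses).
    """

    method: str
    sample_scores: pd.DataFrame
    feature_scores: pd.DataFrame
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_fraction: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    residual_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def _canonicalize_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip axis signs so each axis' first non-zero feature loading is > 0."""
    for k in range(v.shape[1]):
        col = v[:, k]
        nz = np.flatnonzero(np.abs(col) > _EIG_TOL)
        if len(nz) and col[nz[0]] < 0:
            v[:, k] = -col
            u[:, k] = -u[:, k]
    return u, v


def correspondence_analysis(abundance) -> OrdinationResult:
    """CA of a non-negative abundance table (samples × features).

    Decomposes the standardised chi-square residuals
    (p_ij − r_i c_j) / √(r_i c_j) by SVD; the eigenvalues (squared
    singular values) sum to the table's total inertia χ²/N. Rows and
    columns must each have a positive total. Rank-deficient tables yield
    fewer axes, not an error.
    """
    X = pd.DataFrame(abundance)
    M = X.to_numpy(dtype=float)
    if (M < 0).any():
        raise OrdinationError("abundance: negative entries")
    if (M.sum(axis=1) == 0).any() or (M.sum(axis=0) == 0).any():
        raise OrdinationError("abundance: all-zero rows/columns must be removed")
    N = M.sum()
    P = M / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = linalg.svd(S, full_matrices=False)
    keep = s**2 > _EIG_TOL
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    # principal coordinates
    row_scores = (U * s) / np.sqrt(r)[:, None]
    col_scores = (V * s) / np.sqrt(c)[:, None]
    row_scores, col_scores = _canonicalize_signs(row_scores, col_scores)
    axes = [f"CA{k + 1}" for k in range(len(s))]
    return OrdinationResult(
        method="CA",
        sample_scores=pd.DataFrame(row_scores, index=X.index, columns=axes),
        feature_scores=pd.DataFrame(col_scores, index=X.columns, columns=axes),
        eigenvalues=s**2,
        total_inertia=float(np.sum(s**2)),
    )


def hellinger(abundance: np.ndarray) -> np.ndarray:
    """Hellinger transform: square root of row-relative abundances."""
    M = np.asarray(abundance, dtype=float)
    totals = M.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise OrdinationError("abundance: zero-total rows")
    return np.sqrt(M / totals)


def rda(
    abundance,
    constraint,
    n_permutations: int = 999,
    transform: str = "hellinger",
    seed: int | None = 0,
) -> OrdinationResult:
    """RDA of a community table constrained by one explanatory variable.

    Species responses are (optionally Hellinger-) transformed and
    centred; fitted values come from the per-species least-squares
    regression on the centred constraint. The constrained fraction
    R² = SS(fitted)/SS(total); significance is a permutation test on the
    constraint values with p = (1 + #{permuted R² ≥ observed}) /
    (1 + n_permutations).
    """
    X = pd.DataFrame(abundance)
    x = np.asarray(constraint, dtype=float)
    if len(x) != X.shape[0]:
        raise OrdinationError("constraint: one value per sample required")
    if X.shape[0] < 3:
        raise OrdinationError("abundance: need >= 3 samples")
    if np.ptp(x) == 0:
        raise OrdinationError("constraint: constant (no variance to constrain on)")
    if transform not in ("hellinger", "none"):
        raise OrdinationError(f"transform: unknown {transform!r}")

    Y = X.to_numpy(dtype=float)
    if transform == "hellinger":
        Y = hellinger(Y)
    Y = Y - Y.mean(axis=0)
    xc = x - x.mean()
    ss_x = xc @ xc

    beta = (xc @ Y) / ss_x  # per-species slope
    fitted = np.outer(xc, beta)
    ss_total = float(np.sum(Y**2))
    if ss_total == 0:
        raise OrdinationError("abundance: no variance after centring")
    r2 = float(np.sum(fitted**2)) / ss_total

    perm_p = None
    if n_permutations:
        if seed is None:
            raise OrdinationError("seed: required when permutations are requested")
        rng = np.random.default_rng(seed)
        n = len(xc)
        perms = np.empty((n_permutations, n))
        for i in range(n_permutations):
            perms[i] = xc[rng.permutation(n)]
        # per-permutation R² = Σ_j (x'ᵀ Y_j)² / ss_x / ss_total
        num = np.sum((perms @ Y) ** 2, axis=1) / ss_x
        perm_r2 = num / ss_total
        perm_p = float((1 + np.sum(perm_r2 >= r2 - _EIG_TOL)) / (1 + n_permutations))

    # canonical axis from the rank-1 fitted matrix; residual PCA axes
    U, s, Vt = linalg.svd(fitted, full_matrices=False)
    keep = s**2 > _EIG_TOL
    U1, s1, V1 = U[:, keep], s[keep], Vt[keep].T
    resid = Y - fitted
    Ur, sr, Vrt = linalg.svd(resid, full_matrices=False)
    keep_r = sr**2 > _EIG_TOL
    Ur, sr, Vr = Ur[:, keep_r][:, :2], sr[keep_r][:2], Vrt[keep_r].T[:, :2]

    n_samp = Y.shape[0]
    samp = np.hstack([U1 * s1, Ur * sr])
    feat = np.hstack([V1, Vr])
    samp, feat = _canonicalize_signs(samp, feat)
    axes = [f"RDA{k + 1}" for k in range(U1.shape[1])] + [
        f"PC{k + 1}" for k in range(Ur.shape[1])
    ]
    return OrdinationResult(
        method="RDA",
        sample_scores=pd.DataFrame(samp, index=X.index, columns=axes),
        feature_scores=pd.DataFrame(feat, index=X.columns, columns=axes),
        eigenvalues=s1**2 / (n_samp - 1),
        total_inertia=ss_total / (n_samp - 1),
        constrained_fraction=r2,
        permutation_p=perm_p,
        n_permutations=n_permutations or None,
        seed=seed,
        residual_eigenvalues=sr**2 / (n_samp - 1),
    )


def pearson(x, y) -> float:
    """Product-moment correlation of two paired series (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise OrdinationError("pearson: need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise OrdinationError("pearson: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_window(
    days, x, y, day_min: float = -np.inf, day_max: float = np.inf
) -> float:
    """Pearson correlation restricted to days in [day_min, day_max]."""
    days = np.asarray(days, dtype=float)
    m = (days >= day_min) & (days <= day_max)
    return pearson(np.asarray(x, dtype=float)[m], np.asarray(y, dtype=float)[m])


def ordination_summary(result: OrdinationResult) -> pd.DataFrame:
    """One-row summary TSV payload (method, R², p, permutations, seed)."""
    def _num(v):
        return np.nan if v is None else v

    return pd.DataFrame(
        [
            {
                "method": result.method,
                "n_axes": len(result.eigenvalues),
                "total_inertia": result.total_inertia,
                "r_squared": _num(result.constrained_fraction),
                "permutation_p": _num(result.permutation_p),
                "n_permutations": _num(result.n_permutations),
                "seed": _num(result.seed),
            }
        ]
    )
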