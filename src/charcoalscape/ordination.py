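"""Redundancy analysis (RDA) with Monte Carlo permutation testing.

RDA is the constrained extension of PCA: the response matrix Y is regressed
on the predictor matrix X, and the fitted values are eigen-decomposed.  Axis
importance is reported as a percentage of the *total* variance of (centred,
optionally standardised) Y, and significance is assessed by permuting the
rows of Y and recomputing the sum of constrained eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["OrdinationResult", "rda", "permutation_test"]


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray           # constrained, non-increasing
    explained_pct: np.ndarray         # % of total variance of Y per axis
    site_scores: np.ndarray           # n x k
    response_scores: np.ndarray       # q x k (loadings of the response variables)
    biplot_scores: pd.DataFrame       # p x k correlations of predictors with axes
    total_variance: float
    p_value: float | None = None
    n_permutations: int | None = None

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size

    def scores_frames(self, response_names=None) -> dict[str, pd.DataFrame]:
        axes = [f"RDA{i+1}" for i in range(self.n_axes)]
        out = {
            "sites": pd.DataFrame(self.site_scores, columns=axes),
            "responses": pd.DataFrame(
                self.response_scores, columns=axes, index=response_names
            ),
            "biplot": self.biplot_scores.copy(),
        }
        return out


def _prepare(M, standardise: bool, what: str):
    if isinstance(M, pd.DataFrame):
        names = list(M.columns)
        A = M.to_numpy(dtype=float)
    else:
        A = np.asarray(M, dtype=float)
        names = [f"{what}{j+1}" for j in range(A.shape[1])]
    if np.isnan(A).any():
        raise ValueError(f"{what} matrix contains missing values")
    A = A - A.mean(axis=0)
    if standardise:
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [names[j] for j in np.nonzero(sd == 0)[0]]
            raise ValueError(f"zero-variance columns in {what}: {bad}")
        A = A / sd
    return A, names


def _check_rank(Xc, names, tol=1e-10):
    q, r, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        raise ValueError("predictor matrix has no variance")
    rank = int(np.sum(diag > tol * diag[0]))
    if rank < Xc.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"collinear predictor columns: {bad}")


def rda(
    Y,
    X,
    standardise_y: bool = True,
    standardise_x: bool = True,
    n_permutations: int | None = None,
    seed: int = 0,
) -> OrdinationResult:
    """Redundancy analysis of responses Y (n x q) on predictors X (n x p).

    After centring (and by default unit-variance scaling, since the response
    variables mix counts, areas, percentages and an index), the fitted
    values ``Yhat = X (X'X)^-1 X' Y`` are decomposed by SVD.  Constrained
    eigenvalues are the squared singular values / (n - 1); each axis is
    reported as a percentage of the total variance of Y.  Site scores are
    the projections of the fitted values, response scores the corresponding
    loadings, and biplot scores the correlations of each predictor with the
    site scores.
    """
    Yc, y_names = _prepare(Y, standardise_y, "Y")
    Xc, x_names = _prepare(X, standardise_x, "X")
    n, q_resp = Yc.shape
    p = Xc.shape[1]
    if Xc.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    if n <= p + 1:
        raise ValueError("need more observations than predictors (n > p + 1)")
    _check_rank(Xc, x_names)

    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig[0], 1e-300) * 1e-12 if eig.size else np.array([], bool)
    k = int(np.sum(keep))
    k = min(k, p, q_resp)
    U, s, Vt, eig = U[:, :k], s[:k], Vt[:k], eig[:k]

    total_var = float(np.sum(Yc.var(axis=0, ddof=1)))
    explained = 100.0 * eig / total_var
    site = U * s  # projections of fitted values on the constrained axes
    resp = Vt.T
    biplot = np.zeros((p, k))
    for j in range(p):
        xj = Xc[:, j]
        for a in range(k):
            sa = site[:, a]
            denom = np.std(xj) * np.std(sa)
            biplot[j, a] = np.corrcoef(xj, sa)[0, 1] if denom > 0 else 0.0
    result = OrdinationResult(
        eigenvalues=eig,
        explained_pct=explained,
        site_scores=site,
        response_scores=resp,
        biplot_scores=pd.DataFrame(
            biplot, index=x_names, columns=[f"RDA{i+1}" for i in range(k)]
        ),
        total_variance=total_var,
    )
    if n_permutations is not None:
        result.p_value = permutation_test(
            Y, X, n_perm=n_permutations, seed=seed,
            standardise_y=standardise_y, standardise_x=standardise_x,
        )
        result.n_permutations = n_permutations
    return result


def permutation_test(
    Y,
    X,
    n_perm: int = 10000,
    seed: int = 0,
    standardise_y: bool = True,
    standardise_x: bool = True,
) -> float:
    """Monte Carlo significance of the constrained variance.

    The statistic is the sum of constrained eigenvalues (equivalent to the
    constrained pseudo-F at fixed X); rows of Y are permuted and
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``, so p is never 0.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    Yc, _ = _prepare(Y, standardise_y, "Y")
    Xc, _ = _prepare(X, standardise_x, "X")
    n = Yc.shape[0]
    Q, _ = np.linalg.qr(Xc)
    observed = float(np.sum((Q.T @ Yc) ** 2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = float(np.sum((Q.T @ Yc[perm]) ** 2))
        if stat >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
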