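"""Randomized dependence coefficient (RDC).

The RDC measures nonlinear dependence between two scalar time series in
three steps: (i) an empirical-copula transform maps each series to (0,1),
removing marginal distributions; (ii) k random sinusoidal features
``sin(u W + b)`` with ``W ~ N(0, s^2)`` and ``b ~ U(0, 2*pi)`` lift the
copula samples into a feature space; (iii) regularized canonical
correlation analysis (RCCA) returns the largest correlation achievable
between linear combinations of the two feature sets.  The score lies in
[0, 1], is invariant to strictly monotone marginal transformations, and
captures dependencies Pearson correlation misses.

The estimator is randomized, so the final score is the median over a few
independent feature draws, all derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import rankdata


@dataclass
class RDCParams:
    """Tunables of the RDC estimator.

    ``k`` random projections at scale ``s`` (standard deviation of the
    normal projection weights); ridge regularization stabilizes the CCA
    eigenproblem; the score is the median over ``n_repeats`` feature draws.
    """

    k: int = 20
    s: float = 1.0 / 6.0
    n_repeats: int = 5
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def copula_transform(x: np.ndarray) -> np.ndarray:
    """Empirical-copula (rank) transform onto the open interval (0, 1).

    ``out[m] = #{j : x[j] <= x[m]} / (n + 1)``; ties share the count of
    values less than or equal to them, and the n+1 denominator keeps the
    output strictly below 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("input must be 1-D with at least 2 samples")
    return rankdata(x, method="max") / (x.shape[0] + 1)


def random_features(
    u: np.ndarray,
    k: int = 20,
    s: float = 1.0 / 6.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random sinusoidal feature map ``sin(u W + b)`` of a copula series.

    ``W`` is 1 x k with entries N(0, s^2); ``b`` is k-dimensional uniform on
    [0, 2*pi).  Entries are bounded by 1 in magnitude.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = np.asarray(u, dtype=np.float64).reshape(-1, 1)
    W = rng.normal(0.0, s, size=(1, k))
    b = rng.uniform(0.0, 2 * np.pi, size=k)
    return np.sin(u @ W + b)


def rcca_max_correlation(
    phiX: np.ndarray, phiY: np.ndarray, ridge: float = 1e-3
) -> float:
    """Largest canonical correlation between two feature matrices.

    Solves ``max_{a,b} corr(phiX a, phiY b)`` with ridge-regularized
    covariance blocks, via Cholesky whitening and an SVD.  The ridge is
    dimensionless: each block receives ``ridge * mean(diag(block))`` on its
    diagonal, so regularization strength is independent of feature scale
    (the sinusoidal features at the default projection scale have variance
    far below 1).  The result is clipped to [0, 1] (floating point can push
    it marginally above 1).
    """
    phiX = np.asarray(phiX, dtype=np.float64)
    phiY = np.asarray(phiY, dtype=np.float64)
    if phiX.shape[0] != phiY.shape[0]:
        raise ValueError("feature matrices must have the same number of rows")
    n = phiX.shape[0]
    Xc = phiX - phiX.mean(axis=0)
    Yc = phiY - phiY.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxx += ridge * np.mean(np.diag(Cxx)) * np.eye(Cxx.shape[0])
    Cyy += ridge * np.mean(np.diag(Cyy)) * np.eye(Cyy.shape[0])
    Cxy = Xc.T @ Yc / (n - 1)
    try:
        Lx = linalg.cholesky(Cxx, lower=True)
        Ly = linalg.cholesky(Cyy, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance block; use ridge > 0 to regularize"
        ) from err
    K = linalg.solve_triangular(Lx, Cxy, lower=True)
    K = linalg.solve_triangular(Ly, K.T, lower=True).T
    smax = linalg.svdvals(K)[0]
    return float(np.clip(smax, 0.0, 1.0))


def rdc_against_references(
    sources: np.ndarray,
    references: list[np.ndarray] | tuple,
    params: RDCParams | None = None,
) -> np.ndarray:
    """RDC of every source row against every reference series.

    Computes the same estimator as :func:`rdc` but shares the copula
    transform and random-feature maps of the references (and of each
    source) across all pairings, which is substantially faster when many
    components are scored against a fixed pair of reference sensors.
    Each (repeat, series) random draw comes from its own seed-sequence
    child, so the result is deterministic for fixed params.

    Returns an array of shape ``(n_sources, n_references)``.
    """
    params = params or RDCParams()
    sources = np.atleast_2d(np.asarray(sources, dtype=np.float64))
    n = sources.shape[1]
    for ref in references:
        if len(ref) != n:
            raise ValueError("references must have the same length as the sources")
    u_refs = [copula_transform(np.asarray(r, dtype=np.float64)) for r in references]
    u_srcs = [copula_transform(s) for s in sources]
    n_src, n_ref, k = len(u_srcs), len(u_refs), params.k
    vals = np.empty((params.n_repeats, n_src, n_ref))
    eye = np.eye(k)
    for r in range(params.n_repeats):
        rng_r = np.random.default_rng(np.random.SeedSequence([params.seed, r]))
        W_r = rng_r.normal(0.0, params.s, size=(1, k))
        b_r = rng_r.uniform(0.0, 2 * np.pi, size=k)
        # every series shares the repeat's (W, b) draw — see rdc() — and the
        # source maps are stacked for blocked GEMMs; float32 is ample for a
        # correlation quoted to ~2 decimal places
        S = np.stack(u_srcs, axis=1)[:, :, None] * W_r[0]
        S += b_r
        S = np.sin(S, out=S).astype(np.float32)  # (n, n_src, k)
        S -= S.mean(axis=0, dtype=np.float64).astype(np.float32)
        St = np.ascontiguousarray(S.transpose(1, 2, 0))
        Cxx = (St @ St.transpose(0, 2, 1)).astype(np.float64) / (n - 1)
        diag_means = np.einsum("ikk->i", Cxx) / k
        Lx = np.linalg.cholesky(Cxx + params.ridge * diag_means[:, None, None] * eye)
        Sflat = S.reshape(n, n_src * k)
        for j, u_ref in enumerate(u_refs):
            phi_ref = np.sin(u_ref[:, None] * W_r[0] + b_r)
            Yc = (phi_ref - phi_ref.mean(axis=0)).astype(np.float32)
            Cyy = (Yc.T @ Yc).astype(np.float64) / (n - 1)
            Cyy += params.ridge * np.mean(np.diag(Cyy)) * eye
            Ly = linalg.cholesky(Cyy, lower=True)
            cross = (Sflat.T @ Yc).astype(np.float64).reshape(n_src, k, k) / (n - 1)
            for i in range(n_src):
                K = linalg.solve_triangular(Lx[i], cross[i], lower=True)
                K = linalg.solve_triangular(Ly, K.T, lower=True).T
                vals[r, i, j] = np.clip(linalg.svdvals(K)[0], 0.0, 1.0)
    return np.median(vals, axis=0)


def rdc(x: np.ndarray, y: np.ndarray, params: RDCParams | None = None) -> float:
    """Randomized dependence coefficient between two equal-length series.

    Median over ``params.n_repeats`` random-feature draws of the RCCA
    canonical correlation between the feature maps of the two
    copula-transformed inputs.  Within a repeat both inputs share the same
    projection draw (each feature map still has the prescribed
    ``sin(u W + b)`` law); this coupling makes the estimator exactly
    symmetric in its arguments and deterministic for fixed params.
    """
    params = params or RDCParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    u = copula_transform(x)
    v = copula_transform(y)
    values = []
    for r in range(params.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, r]))
        W = rng.normal(0.0, params.s, size=(1, params.k))
        b = rng.uniform(0.0, 2 * np.pi, size=params.k)
        phiX = np.sin(u[:, None] * W[0] + b)
        phiY = np.sin(v[:, None] * W[0] + b)
        values.append(rcca_max_correlation(phiX, phiY, params.ridge))
    return float(np.median(values))
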