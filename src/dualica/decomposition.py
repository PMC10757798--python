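"""Dual ICA decomposition and component-number selection.

The matrix M (genes x conditions) is decomposed twice with FastICA:

* ``M = G A`` — the "condition ICs": columns of the signal matrix G live in
  gene space, and gene clusters are later trimmed out of their tails.
* ``M^T = C B`` — the "gene ICs": columns of C live in condition space and
  yield condition clusters.

The number of components on each side is chosen from a scree of aggregate
non-Gaussianity: for each candidate r, the D'Agostino omnibus K^2 statistic
(Z_skew^2 + Z_kurt^2, chi-squared with 2 df under normality) is computed per
component and summed. The curve rises steeply while real non-Gaussian
signals are still being split out and flattens once only noise components
are added; the knee of that curve (kneedle algorithm) is the chosen r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .data import LFCMatrix
from .exceptions import (
    DegenerateSampleError,
    SampleTooSmallError,
    TooFewPointsError,
)

__all__ = [
    "ICADecomposition",
    "ComponentScree",
    "run_ica",
    "dagostino_k2",
    "k2_scree",
    "kneedle",
    "choose_components",
    "dual_decompose",
    "default_scree_grid",
]

#: offset separating the gene-side seed stream from the condition side
_GENE_SEED_OFFSET = 10007

MIN_K2_SAMPLE = 8


@dataclass
class ICADecomposition:
    """One FastICA run: ``X - mean ~= signal @ mixing``.

    ``signal`` has one zero-mean, unit-variance column per component;
    ``mixing`` holds the weights recombining components into the original
    columns. ``row_ids``/``col_ids`` carry the labels of the decomposed
    matrix when known.
    """

    signal: np.ndarray  # (n_rows, r)
    mixing: np.ndarray  # (r, n_cols)
    mean: np.ndarray  # (n_cols,)
    n_components: int
    seed: int
    converged: bool
    n_iter: int = 0
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None

    def reconstruct(self) -> np.ndarray:
        return self.signal @ self.mixing + self.mean


@dataclass
class ComponentScree:
    """Aggregate K^2 non-Gaussianity versus number of components.

    ``metric`` is the raw sum of per-component K^2. ``null_metric``, when
    present, is the same quantity computed on a matched pure-Gaussian
    matrix (parallel analysis): ICA overfits non-Gaussian-looking
    projections out of noise, especially at few samples, and this baseline
    measures exactly that inflation. ``excess_metric`` (raw minus null) is
    what actually rises while real signals are being split out and
    flattens afterwards.
    """

    r_grid: list[int]
    metric: np.ndarray  # sum of per-component K^2, one value per r
    per_component_k2: list[np.ndarray]
    seed: int
    null_metric: np.ndarray | None = None

    @property
    def excess_metric(self) -> np.ndarray:
        if self.null_metric is None:
            return self.metric
        return self.metric - self.null_metric

    def to_frame(self, chosen: int | None = None):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "r": self.r_grid,
                "metric": self.metric,
                "chosen": [r == chosen for r in self.r_grid],
            }
        )
        if self.null_metric is not None:
            frame["null_metric"] = self.null_metric
            frame["excess_metric"] = self.excess_metric
        return frame


def _skew_contrast(x):
    # G(u) = u^3/3: the third-cumulant contrast, sensitive to asymmetric
    # (one-tailed) sources that even contrasts like logcosh cannot see
    return x**2, (2 * x).mean(axis=-1)


def _cumulant_score(S: np.ndarray) -> float:
    """Sum of squared skewness + squared excess kurtosis per component.

    Raw-moment analogue of the D'Agostino K^2 idea (skew AND kurtosis),
    used to pick between candidate unmixings; unlike the K^2 Z-statistics
    it does not saturate, so a clean separation of skewed sources outscores
    a symmetric mixture of them.
    """
    sk = scipy.stats.skew(S, axis=0)
    ku = scipy.stats.kurtosis(S, axis=0)
    return float((sk**2 + ku**2).sum())


def run_ica(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    contrast: str = "auto",
) -> ICADecomposition:
    """Run FastICA (whitened, unit-variance components).

    ``contrast="auto"`` (default) estimates the unmixing twice — once with
    the logcosh contrast (robust for symmetric heavy-tailed sources) and
    once with the third-cumulant (skewness) contrast (required for
    one-tailed sources, which are invisible to even contrast functions) —
    and keeps the solution with the larger summed squared-skewness +
    squared-excess-kurtosis of its components. ``"logcosh"`` or ``"skew"``
    force a single contrast.

    Deterministic for a fixed seed. Non-convergence at ``max_iter`` is
    recorded in ``converged`` rather than raised: iteration caps on large
    matrices rarely harm component quality.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite (no NaN/Inf)")
    if not 1 <= n_components <= min(X.shape):
        raise ValueError(
            f"n_components={n_components} must be in [1, {min(X.shape)}]"
        )
    if contrast == "auto":
        funs = ["logcosh", _skew_contrast]
    elif contrast == "logcosh":
        funs = ["logcosh"]
    elif contrast == "skew":
        funs = [_skew_contrast]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    best = None
    best_score = -np.inf
    for fun in funs:
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            fun=fun,
            max_iter=max_iter,
            tol=tol,
            random_state=int(seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            S = ica.fit_transform(X)
        score = _cumulant_score(S) if len(funs) > 1 else 0.0
        if score > best_score:
            best_score = score
            best = (S, ica)
    S, ica = best
    n_iter = int(ica.n_iter_)
    return ICADecomposition(
        signal=S,
        mixing=ica.mixing_.T,
        mean=ica.mean_,
        n_components=int(n_components),
        seed=int(seed),
        converged=n_iter < max_iter,
        n_iter=n_iter,
    )


def dagostino_k2(sample: np.ndarray) -> tuple[float, float]:
    """D'Agostino omnibus normality test.

    Returns ``(K2, p)`` where ``K2 = Z_skew^2 + Z_kurt^2`` and ``p`` comes
    from the chi-squared distribution with 2 degrees of freedom. Large K^2
    means non-Gaussian.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < MIN_K2_SAMPLE:
        raise SampleTooSmallError(
            f"D'Agostino K^2 needs >= {MIN_K2_SAMPLE} observations, "
            f"got {sample.size}"
        )
    if np.ptp(sample) == 0:
        raise DegenerateSampleError("sample has zero variance")
    with warnings.catch_warnings():
        # scipy warns about kurtosistest validity for n < 20; the caller
        # decides what sample sizes to trust.
        warnings.simplefilter("ignore")
        k2, p = scipy.stats.normaltest(sample)
    return float(k2), float(p)


#: seed offset for the parallel-analysis (null baseline) scree
_NULL_SEED_OFFSET = 777013


def _k2_sums(X, r_grid, seed, max_iter):
    metric = np.empty(len(r_grid))
    per_component = []
    for idx, r in enumerate(r_grid):
        decomp = run_ica(X, r, seed=seed + r, max_iter=max_iter)
        k2s = np.array(
            [dagostino_k2(decomp.signal[:, j])[0] for j in range(r)]
        )
        per_component.append(k2s)
        metric[idx] = k2s.sum()
    return metric, per_component


def k2_scree(
    X: np.ndarray,
    r_grid,
    seed: int = 0,
    max_iter: int = 500,
    null_correction: bool = True,
) -> ComponentScree:
    """Sum of per-component K^2 for each candidate component count.

    One ICA run per grid point, at the derived seed ``seed + r`` so the
    whole scree is reproducible from the single top-level seed. With
    ``null_correction`` (default) the identical protocol is also run on a
    same-shaped standard-normal matrix and stored as ``null_metric``: at
    small sample sizes ICA extracts non-Gaussian-looking projections out
    of pure noise, so the raw sum keeps growing with r; the excess over
    the null baseline is what flattens past the true signal count.
    """
    r_grid = [int(r) for r in r_grid]
    if any(b <= a for a, b in zip(r_grid, r_grid[1:])):
        raise ValueError("r_grid must be strictly ascending")
    X = np.asarray(X, dtype=float)
    if r_grid and r_grid[-1] > min(X.shape):
        raise ValueError(
            f"max(r_grid)={r_grid[-1]} exceeds min matrix dimension "
            f"{min(X.shape)}"
        )
    metric, per_component = _k2_sums(X, r_grid, seed, max_iter)
    null_metric = None
    if null_correction:
        rng = np.random.default_rng(seed + _NULL_SEED_OFFSET)
        X_null = rng.standard_normal(X.shape)
        null_metric, _ = _k2_sums(X_null, r_grid, seed, max_iter)
    return ComponentScree(
        r_grid=r_grid,
        metric=metric,
        per_component_k2=per_component,
        seed=seed,
        null_metric=null_metric,
    )


def kneedle(x, y, sensitivity: float = 1.0) -> float | None:
    """Knee of a concave-increasing curve (kneedle algorithm).

    Both axes are min-max normalized, the difference curve
    ``d = y_norm - x_norm`` is formed, and the knee is the first local
    maximum of ``d`` after which ``d`` drops below
    ``d_max - sensitivity * mean(diff(x_norm))`` before the next local
    maximum. Returns the x value of the knee, or None when the curve has
    no knee (e.g. a straight line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise TooFewPointsError("knee detection needs at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly ascending")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    if np.ptp(y) == 0:
        return None
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / np.ptp(y)
    d = yn - xn

    # interior local maxima of the difference curve
    lmx = [
        i
        for i in range(1, d.size - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if not lmx:
        return None
    step = float(np.mean(np.diff(xn)))
    for pos, i in enumerate(lmx):
        threshold = d[i] - sensitivity * step
        stop = lmx[pos + 1] if pos + 1 < len(lmx) else d.size
        for j in range(i + 1, stop):
            if d[j] < threshold:
                return float(x[i])
    return None


def choose_components(
    scree: ComponentScree, sensitivity: float = 1.0
) -> tuple[int, bool]:
    """Pick the component count at the knee of the K^2 scree.

    Uses the null-corrected (excess) metric when the scree carries one.
    Returns ``(r, used_fallback)``. When kneedle finds no knee (flat or
    linear scree), falls back to the grid point with the largest drop in
    incremental metric gain, with a warning.
    """
    if len(scree.r_grid) < 3:
        raise TooFewPointsError(
            f"scree has {len(scree.r_grid)} points; need >= 3"
        )
    knee = kneedle(scree.r_grid, scree.excess_metric, sensitivity=sensitivity)
    if knee is not None:
        return int(knee), False
    gains = np.diff(scree.excess_metric)
    drops = gains[:-1] - gains[1:]
    i = int(np.argmax(drops)) + 1  # grid index whose gain drops most after
    warnings.warn(
        "no knee found in K^2 scree; falling back to the grid point with "
        f"the largest drop in incremental gain (r={scree.r_grid[i]})",
        stacklevel=2,
    )
    return scree.r_grid[i], True


def default_scree_grid(n: int, m: int, step: int = 2, cap: int = 100) -> list[int]:
    """Even grid 2, 4, ... up to min(n, m, cap)."""
    top = min(n, m, cap)
    return list(range(2, top + 1, step))


def dual_decompose(
    M: LFCMatrix,
    k: int,
    l: int,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[ICADecomposition, ICADecomposition]:
    """Run ICA on M (k condition ICs) and on M^T (l gene ICs).

    Returns ``(condition_decomp, gene_decomp)``: the condition
    decomposition has signal G (n_genes x k) and mixing A (k x m); the
    gene decomposition has signal C (m x l) and mixing B (l x n_genes).
    """
    if not M.preprocessed:
        raise ValueError(
            "dual_decompose expects a preprocessed LFCMatrix; call "
            "preprocess() first (or construct with preprocessed=True if "
            "the matrix is already standardized)"
        )
    condition_decomp = run_ica(M.values, k, seed=seed, max_iter=max_iter)
    condition_decomp.row_ids = list(M.gene_ids)
    condition_decomp.col_ids = list(M.condition_ids)
    gene_decomp = run_ica(
        M.values.T, l, seed=seed + _GENE_SEED_OFFSET, max_iter=max_iter
    )
    gene_decomp.row_ids = list(M.condition_ids)
    gene_decomp.col_ids = list(M.gene_ids)
    return condition_decomp, gene_decomp
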