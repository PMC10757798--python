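"""Scikit-learn style estimators for the Dual ICA pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import data as _data
from .association import regression_association, significant_pairs
from .data import LFCMatrix
from .decomposition import (
    choose_components,
    default_scree_grid,
    dual_decompose,
    k2_scree,
)
from .extraction import (
    MIN_REMAINING,
    assign_orphan_conditions,
    extract_all,
)
from .modules import build_modules

__all__ = ["LFCPreprocessor", "DualICA"]

#: seed offset separating the gene-axis scree stream from the condition axis
_SCREE_GENE_OFFSET = 31013


def _as_lfc_matrix(X, preprocessed: bool = False) -> LFCMatrix:
    if isinstance(X, LFCMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return LFCMatrix.from_frame(X, preprocessed=preprocessed)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D genes x conditions matrix")
    n, m = X.shape
    return LFCMatrix(
        values=X,
        gene_ids=[f"g{i}" for i in range(n)],
        condition_ids=[f"c{j}" for j in range(m)],
        preprocessed=preprocessed,
    )


class LFCPreprocessor(TransformerMixin, BaseEstimator):
    """Column standardization followed by symmetric clipping.

    A stateless transformer (each matrix is normalized against its own
    column statistics, like :class:`sklearn.preprocessing.Normalizer`), so
    ``fit`` only validates parameters.

    Parameters
    ----------
    clip_bound : float, default 6.0
        Symmetric clipping bound applied after standardization.
    clip_first : bool, default False
        Clip the raw LFCs before standardizing instead of after.
    """

    def __init__(self, clip_bound: float = 6.0, clip_first: bool = False):
        self.clip_bound = clip_bound
        self.clip_first = clip_first

    def fit(self, X, y=None):
        if self.clip_bound <= 0:
            raise ValueError(
                f"clip_bound must be positive, got {self.clip_bound}"
            )
        self.n_features_in_ = _as_lfc_matrix(X).n_conditions
        return self

    def transform(self, X):
        M = _as_lfc_matrix(X)
        out = _data.preprocess(M, bound=self.clip_bound, clip_first=self.clip_first)
        if isinstance(X, pd.DataFrame):
            return out.to_frame()
        if isinstance(X, LFCMatrix):
            return out
        return out.values


class DualICA(BaseEstimator):
    """Dual ICA biclustering of a genes x conditions LFC matrix.

    Runs the whole pipeline on ``fit``: preprocessing, a K^2 scree with
    knee-based component selection on both the matrix and its transpose,
    the two ICA decompositions, D'Agostino tail extraction of signed gene
    and condition clusters, the orphan-condition rule, the melted OLS
    association with Wald/BH/Z significance calls, and module assembly.

    Parameters
    ----------
    n_condition_ics, n_gene_ics : int or "auto"
        Component counts k and l; "auto" selects each from the knee of its
        K^2 scree.
    scree_grid : sequence of int or None
        Candidate component counts for the scree; None means an even grid
        2, 4, ... up to min(n, m, 100).
    clip_bound : float
        Symmetric clipping bound applied during preprocessing.
    preprocess : bool
        Standardize + clip before decomposing. Set False only if X is
        already standardized.
    alpha_extract : float
        D'Agostino p-value threshold ending tail extraction.
    alpha_assoc : float
        BH-adjusted q-value threshold for significant IC pairs.
    z_min : float
        Minimum |Z| of a coefficient (against the empirical coefficient
        distribution) for significance.
    sensitivity : float
        kneedle sensitivity for the scree knee.
    tie_components : bool
        When both component counts are "auto", use the same value
        k = l = min(condition-side knee, gene-side knee). The planted
        block model implies one shared signal rank, and the transpose-side
        scree overestimates it when conditions are few (ICA overfits
        non-Gaussian projections at small sample sizes), so the smaller
        knee is the conservative shared estimate. Set False to select each
        side independently from its own scree.
    min_remaining : int
        Extraction floor: stop trimming an IC below this many remaining
        coefficients.
    max_iter : int
        FastICA iteration cap.
    random_state : int
        Top-level seed; every internal run derives its seed from it.

    Attributes
    ----------
    preprocessed_ : LFCMatrix
        The standardized, clipped matrix that was decomposed.
    scree_condition_, scree_gene_ : ComponentScree or None
        Screes used for automatic selection (None when k/l were fixed).
    n_condition_ics_, n_gene_ics_ : int
        The component counts used.
    condition_decomposition_, gene_decomposition_ : ICADecomposition
        G/A from ICA(M) and C/B from ICA(M^T).
    gene_clusters_, condition_clusters_ : list of SignedCluster
    association_ : AssociationResult
    significant_pairs_ : list of (condition_ic, gene_ic)
    modules_ : list of InteractingModule

    Examples
    --------
    >>> from dualica import DualICA, synthetic
    >>> M, truth = synthetic.generate(
    ...     300, 30, [synthetic.ModuleSpec(30, 8, 4.0)], seed=0)
    >>> est = DualICA(scree_grid=range(2, 13, 2), random_state=0).fit(M)
    >>> len(est.modules_) >= 1
    True
    """

    def __init__(
        self,
        n_condition_ics="auto",
        n_gene_ics="auto",
        scree_grid=None,
        clip_bound: float = 6.0,
        preprocess: bool = True,
        clip_first: bool = False,
        alpha_extract: float = 0.05,
        alpha_assoc: float = 0.05,
        z_min: float = 2.0,
        sensitivity: float = 1.0,
        tie_components: bool = True,
        min_remaining: int = MIN_REMAINING,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.n_condition_ics = n_condition_ics
        self.n_gene_ics = n_gene_ics
        self.scree_grid = scree_grid
        self.clip_bound = clip_bound
        self.preprocess = preprocess
        self.clip_first = clip_first
        self.alpha_extract = alpha_extract
        self.alpha_assoc = alpha_assoc
        self.z_min = z_min
        self.sensitivity = sensitivity
        self.tie_components = tie_components
        self.min_remaining = min_remaining
        self.max_iter = max_iter
        self.random_state = random_state

    def _validate(self) -> None:
        for name in ("alpha_extract", "alpha_assoc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.z_min < 0:
            raise ValueError(f"z_min must be >= 0, got {self.z_min}")
        if self.clip_bound <= 0:
            raise ValueError(
                f"clip_bound must be positive, got {self.clip_bound}"
            )
        if self.sensitivity <= 0:
            raise ValueError(
                f"sensitivity must be positive, got {self.sensitivity}"
            )

    def fit(self, X, y=None):
        """Run the full pipeline on a genes x conditions LFC matrix.

        ``X`` may be an :class:`LFCMatrix`, a labeled DataFrame, or a bare
        array (labels are then generated).
        """
        self._validate()
        seed = int(self.random_state)
        raw = _as_lfc_matrix(X)
        self.raw_ = raw
        if self.preprocess and not raw.preprocessed:
            M = _data.preprocess(
                raw, bound=self.clip_bound, clip_first=self.clip_first
            )
        elif raw.preprocessed:
            M = raw
        else:
            M = LFCMatrix(
                values=raw.values,
                gene_ids=raw.gene_ids,
                condition_ids=raw.condition_ids,
                preprocessed=True,
            )
        self.preprocessed_ = M
        n, m = M.shape

        grid = (
            list(self.scree_grid)
            if self.scree_grid is not None
            else default_scree_grid(n, m)
        )
        self.scree_condition_ = None
        self.scree_gene_ = None
        k = self.n_condition_ics
        l = self.n_gene_ics
        if k == "auto":
            self.scree_condition_ = k2_scree(
                M.values, grid, seed=seed, max_iter=self.max_iter
            )
            k, self.scree_condition_fallback_ = choose_components(
                self.scree_condition_, sensitivity=self.sensitivity
            )
        if l == "auto":
            self.scree_gene_ = k2_scree(
                M.values.T,
                grid,
                seed=seed + _SCREE_GENE_OFFSET,
                max_iter=self.max_iter,
            )
            l, self.scree_gene_fallback_ = choose_components(
                self.scree_gene_, sensitivity=self.sensitivity
            )
        if (
            self.tie_components
            and self.n_condition_ics == "auto"
            and self.n_gene_ics == "auto"
        ):
            k = l = min(int(k), int(l))
        self.n_condition_ics_ = int(k)
        self.n_gene_ics_ = int(l)

        cond_decomp, gene_decomp = dual_decompose(
            M, self.n_condition_ics_, self.n_gene_ics_,
            seed=seed, max_iter=self.max_iter,
        )
        self.condition_decomposition_ = cond_decomp
        self.gene_decomposition_ = gene_decomp

        self.gene_clusters_ = extract_all(
            cond_decomp, "gene",
            alpha=self.alpha_extract, min_remaining=self.min_remaining,
        )
        clusters = extract_all(
            gene_decomp, "condition",
            alpha=self.alpha_extract, min_remaining=self.min_remaining,
        )
        self.condition_clusters_ = assign_orphan_conditions(
            gene_decomp, clusters
        )

        self.association_ = regression_association(
            cond_decomp.signal, gene_decomp.signal, M,
            alpha=self.alpha_assoc, z_min=self.z_min,
        )
        self.significant_pairs_ = significant_pairs(self.association_)
        # module block means are reported on the original LFC scale
        self.modules_ = build_modules(
            self.significant_pairs_,
            self.gene_clusters_,
            self.condition_clusters_,
            self.association_,
            raw,
        )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the list of interacting modules."""
        return self.fit(X).modules_
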