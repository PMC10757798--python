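"""Synthetic LFC matrices with planted interacting modules.

The generator emulates the structure the method is built to find: a
Gaussian background (so planted blocks are the only non-Gaussian signal,
exactly what the K^2 machinery detects) plus additive mean shifts on
gene-set x condition-set blocks. Effect sizes, overlaps and signs are
configurable; overlapping blocks add. Defaults mirror a bacterial
compendium's aspect ratio (genes >> conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LFCMatrix
from .modules import InteractingModule

__all__ = [
    "ModuleSpec",
    "PlantedModule",
    "PlantedTruth",
    "RecoveryScores",
    "generate",
    "recovery_scores",
    "jaccard",
]


@dataclass
class ModuleSpec:
    """Requested planted block: sizes and signed effect, or explicit ids."""

    n_genes: int = 50
    n_conditions: int = 10
    delta: float = 3.0
    gene_ids: list[str] | None = None
    condition_ids: list[str] | None = None


@dataclass
class PlantedModule:
    gene_ids: set
    condition_ids: set
    delta: float


@dataclass
class PlantedTruth:
    """Ground truth of one generated matrix."""

    modules: list[PlantedModule]
    sigma: float
    seed: int


@dataclass
class RecoveryScores:
    """How well emitted modules recover the planted truth."""

    best_jaccard_genes: list[float]
    best_jaccard_conditions: list[float]
    best_match_labels: list[str | None]
    pair_recall: float
    pair_precision: float

    @property
    def mean_best_jaccard_genes(self) -> float:
        return float(np.mean(self.best_jaccard_genes)) if self.best_jaccard_genes else 0.0

    @property
    def mean_best_jaccard_conditions(self) -> float:
        return (
            float(np.mean(self.best_jaccard_conditions))
            if self.best_jaccard_conditions
            else 0.0
        )


def _labels(prefix: str, count: int, width: int) -> list[str]:
    width = max(width, len(str(count)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, count + 1)]


def generate(
    n_genes: int = 1000,
    n_conditions: int = 60,
    module_specs: list[ModuleSpec] | None = None,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[LFCMatrix, PlantedTruth]:
    """Gaussian background with additive planted blocks.

    Genes are labeled ``g0001...``, conditions ``c001...``. Specs without
    explicit ids are placed on disjoint consecutive blocks in order;
    explicit ids allow overlapping designs. Deterministic per seed.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    module_specs = list(module_specs or [])
    gene_ids = _labels("g", n_genes, 4)
    condition_ids = _labels("c", n_conditions, 3)
    g_index = {g: i for i, g in enumerate(gene_ids)}
    c_index = {c: i for i, c in enumerate(condition_ids)}

    rng = np.random.default_rng(int(seed))
    values = rng.normal(0.0, sigma, size=(n_genes, n_conditions))

    planted: list[PlantedModule] = []
    next_g = 0
    next_c = 0
    for spec in module_specs:
        if spec.gene_ids is not None:
            gset = [str(g) for g in spec.gene_ids]
        else:
            if next_g + spec.n_genes > n_genes:
                raise ValueError(
                    f"planted gene sets exceed n_genes={n_genes}"
                )
            gset = gene_ids[next_g : next_g + spec.n_genes]
            next_g += spec.n_genes
        if spec.condition_ids is not None:
            cset = [str(c) for c in spec.condition_ids]
        else:
            if next_c + spec.n_conditions > n_conditions:
                raise ValueError(
                    f"planted condition sets exceed n_conditions={n_conditions}"
                )
            cset = condition_ids[next_c : next_c + spec.n_conditions]
            next_c += spec.n_conditions
        unknown = [g for g in gset if g not in g_index] + [
            c for c in cset if c not in c_index
        ]
        if unknown:
            raise ValueError(f"planted ids outside the matrix: {unknown!r}")
        if not gset or not cset:
            raise ValueError("planted sets must be non-empty")
        if spec.delta == 0:
            raise ValueError("planted effect delta must be nonzero")
        gi = [g_index[g] for g in gset]
        ci = [c_index[c] for c in cset]
        values[np.ix_(gi, ci)] += spec.delta
        planted.append(
            PlantedModule(
                gene_ids=set(gset), condition_ids=set(cset), delta=spec.delta
            )
        )
    M = LFCMatrix(values=values, gene_ids=gene_ids, condition_ids=condition_ids)
    return M, PlantedTruth(modules=planted, sigma=float(sigma), seed=int(seed))


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recovery_scores(
    truth: PlantedTruth,
    modules: list[InteractingModule],
    match_threshold: float = 0.5,
) -> RecoveryScores:
    """Score emitted modules against the planted truth.

    For each planted module the best-matching emitted module (by mean of
    the gene and condition Jaccards) is recorded. A planted module is
    recovered when that mean Jaccard reaches ``match_threshold``; pair
    recall is the recovered fraction, and pair precision is the fraction
    of distinct significant (condition IC, gene IC) parent pairs among
    emitted modules that are the best match of some recovered planted
    module. With no emitted modules precision is vacuously 1.
    """
    best_jg: list[float] = []
    best_jc: list[float] = []
    best_labels: list[str | None] = []
    matched_pairs: set[tuple[int, int]] = set()
    recovered = 0
    for planted in truth.modules:
        best = None
        best_score = -1.0
        for mod in modules:
            jg = jaccard(planted.gene_ids, mod.gene_ids)
            jc = jaccard(planted.condition_ids, mod.condition_ids)
            score = 0.5 * (jg + jc)
            if score > best_score:
                best_score = score
                best = (mod, jg, jc)
        if best is None:
            best_jg.append(0.0)
            best_jc.append(0.0)
            best_labels.append(None)
            continue
        mod, jg, jc = best
        best_jg.append(jg)
        best_jc.append(jc)
        best_labels.append(mod.label)
        if best_score >= match_threshold:
            recovered += 1
            matched_pairs.add((mod.condition_ic, mod.gene_ic))

    emitted_pairs = {(m.condition_ic, m.gene_ic) for m in modules}
    recall = recovered / len(truth.modules) if truth.modules else 1.0
    precision = (
        len(matched_pairs & emitted_pairs) / len(emitted_pairs)
        if emitted_pairs
        else 1.0
    )
    return RecoveryScores(
        best_jaccard_genes=best_jg,
        best_jaccard_conditions=best_jc,
        best_match_labels=best_labels,
        pair_recall=recall,
        pair_precision=precision,
    )
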