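"""Assembly of interacting modules from significant IC pairs.

A significant (condition IC i, gene IC j) pair is instantiated into up to
four interacting modules — one per populated sign combination of the gene
clusters G_i+/G_i- and the condition clusters C_j+/C_j-. Each module pairs
a concrete gene set with a concrete condition set, carries the association
statistics of its parent IC pair, and summarizes its LFC block by the
arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationResult
from .data import LFCMatrix
from .extraction import SignedCluster

__all__ = [
    "InteractingModule",
    "build_modules",
    "module_mean_lfc",
    "reorder_for_heatmap",
    "modules_to_frame",
]


@dataclass
class InteractingModule:
    """A paired (gene cluster, condition cluster) with its statistics."""

    gene_cluster_label: str
    condition_cluster_label: str
    gene_ids: list[str]
    condition_ids: list[str]
    mean_lfc: float
    coefficient: float
    wald_p: float
    q_value: float
    z_score: float
    condition_ic: int
    gene_ic: int
    gene_sign: str
    condition_sign: str

    @property
    def label(self) -> str:
        return f"{self.condition_cluster_label} x {self.gene_cluster_label}"


def module_mean_lfc(gene_ids, condition_ids, M: LFCMatrix) -> float:
    """Arithmetic mean of M over the gene x condition block."""
    gi = [M.gene_index(g) for g in gene_ids]
    ci = [M.condition_index(c) for c in condition_ids]
    if not gi or not ci:
        raise ValueError("module block must be non-empty")
    return float(M.values[np.ix_(gi, ci)].mean())


def build_modules(
    sig: list[tuple[int, int]],
    gene_clusters: list[SignedCluster],
    condition_clusters: list[SignedCluster],
    result: AssociationResult,
    M: LFCMatrix,
) -> list[InteractingModule]:
    """Instantiate modules for every significant IC pair and sign combo.

    For each significant (condition IC i, gene IC j): emit one module per
    populated (gene sign, condition sign) combination — up to four. Pairs
    where either side yielded no clusters are skipped with a warning.
    Statistics are copied from cell (i, j) of the association result.
    """
    genes_by_ic: dict[int, list[SignedCluster]] = {}
    for c in gene_clusters:
        genes_by_ic.setdefault(c.source_ic, []).append(c)
    conds_by_ic: dict[int, list[SignedCluster]] = {}
    for c in condition_clusters:
        conds_by_ic.setdefault(c.source_ic, []).append(c)

    modules: list[InteractingModule] = []
    for i, j in sig:
        gcs = [c for c in genes_by_ic.get(i, []) if len(c)]
        ccs = [c for c in conds_by_ic.get(j, []) if len(c)]
        if not gcs or not ccs:
            warnings.warn(
                f"significant pair (condition IC {i}, gene IC {j}) has no "
                f"extracted {'gene' if not gcs else 'condition'} clusters; "
                "skipped",
                stacklevel=2,
            )
            continue
        for gc in gcs:
            for cc in ccs:
                modules.append(
                    InteractingModule(
                        gene_cluster_label=gc.label,
                        condition_cluster_label=cc.label,
                        gene_ids=list(gc.member_ids),
                        condition_ids=list(cc.member_ids),
                        mean_lfc=module_mean_lfc(
                            gc.member_ids, cc.member_ids, M
                        ),
                        coefficient=float(result.coefficients[i, j]),
                        wald_p=float(result.wald_p[i, j]),
                        q_value=float(result.q_values[i, j]),
                        z_score=float(result.z_scores[i, j]),
                        condition_ic=i,
                        gene_ic=j,
                        gene_sign=gc.sign,
                        condition_sign=cc.sign,
                    )
                )
    return modules


def reorder_for_heatmap(
    M: LFCMatrix, modules: list[InteractingModule]
) -> tuple[list[str], list[str], list[dict]]:
    """Group genes and conditions by module membership for plotting.

    Members are placed at their first module occurrence (first-module-first,
    stable), ordered within a group by their original matrix order;
    leftover genes/conditions follow in original order. Annotations record
    each module's row/column positions in the new order so overlapping
    blocks can be outlined.
    """
    if not modules:
        raise ValueError("need at least one module to reorder")
    gene_pos = {g: i for i, g in enumerate(M.gene_ids)}
    cond_pos = {c: i for i, c in enumerate(M.condition_ids)}

    gene_order: list[str] = []
    cond_order: list[str] = []
    seen_g: set[str] = set()
    seen_c: set[str] = set()
    for mod in modules:
        for g in sorted(mod.gene_ids, key=gene_pos.__getitem__):
            if g not in seen_g:
                gene_order.append(g)
                seen_g.add(g)
        for c in sorted(mod.condition_ids, key=cond_pos.__getitem__):
            if c not in seen_c:
                cond_order.append(c)
                seen_c.add(c)
    gene_order += [g for g in M.gene_ids if g not in seen_g]
    cond_order += [c for c in M.condition_ids if c not in seen_c]

    new_g = {g: i for i, g in enumerate(gene_order)}
    new_c = {c: i for i, c in enumerate(cond_order)}
    annotations = []
    for mod in modules:
        rows = sorted(new_g[g] for g in mod.gene_ids)
        cols = sorted(new_c[c] for c in mod.condition_ids)
        annotations.append(
            {
                "label": mod.label,
                "gene_rows": rows,
                "condition_cols": cols,
                "row_span": (rows[0], rows[-1]),
                "col_span": (cols[0], cols[-1]),
                "mean_lfc": mod.mean_lfc,
                "q_value": mod.q_value,
            }
        )
    return gene_order, cond_order, annotations


def modules_to_frame(modules: list[InteractingModule]) -> pd.DataFrame:
    """One row per module, member lists joined with ';'."""
    rows = []
    for mod in modules:
        rows.append(
            {
                "module": mod.label,
                "condition_cluster": mod.condition_cluster_label,
                "gene_cluster": mod.gene_cluster_label,
                "n_genes": len(mod.gene_ids),
                "n_conditions": len(mod.condition_ids),
                "mean_lfc": mod.mean_lfc,
                "coefficient": mod.coefficient,
                "wald_p": mod.wald_p,
                "q_value": mod.q_value,
                "z_score": mod.z_score,
                "gene_ids": ";".join(mod.gene_ids),
                "condition_ids": ";".join(mod.condition_ids),
            }
        )
    return pd.DataFrame(rows)
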