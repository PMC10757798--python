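"""Signed cluster extraction from independent components.

Genes (or conditions) that carry a component's signal sit in the tails of
the distribution of that component's coefficients. They are peeled off
greedily — always the largest |coefficient| first, into a positive or
negative set by its sign — until the remaining coefficients look normal to
the D'Agostino omnibus test (p >= alpha). A component whose coefficients
are normal from the start contributes no clusters; a one-sided tail yields
a single cluster.

Conditions left unclustered after extraction on every gene IC are assigned
to the component where they carry the largest absolute coefficient (the
orphan rule); genes may remain unclustered.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import ICADecomposition, dagostino_k2
from .exceptions import SampleTooSmallError

__all__ = [
    "SignedCluster",
    "ExtractionTrace",
    "extract_clusters_from_ic",
    "extract_all",
    "assign_orphan_conditions",
]

#: below this many remaining observations the trimming loop stops: the
#: D'Agostino test is unreliable under ~20 observations (and undefined < 8)
MIN_REMAINING = 20


@dataclass
class SignedCluster:
    """Members trimmed from one tail of one IC (e.g. ``G8+`` or ``C18-``)."""

    axis: str  # "gene" or "condition"
    source_ic: int
    sign: str  # "+" or "-"
    member_ids: list[str] = field(default_factory=list)
    member_coefficients: list[float] = field(default_factory=list)
    orphan_flags: list[bool] = field(default_factory=list)
    name: str | None = None  # optional explicit label (e.g. external clusters)

    @property
    def label(self) -> str:
        if self.name is not None:
            return self.name
        prefix = "G" if self.axis == "gene" else "C"
        return f"{prefix}{self.source_ic}{self.sign}"

    def __len__(self) -> int:
        return len(self.member_ids)

    def add(self, member_id: str, coefficient: float, orphan: bool = False) -> None:
        self.member_ids.append(member_id)
        self.member_coefficients.append(float(coefficient))
        self.orphan_flags.append(bool(orphan))


@dataclass
class ExtractionTrace:
    """Record of one trimming run on one IC.

    ``p_trajectory[0]`` is the p-value before any removal and each later
    entry follows one removal; ``floor_hit`` flags runs stopped by the
    minimum-remaining-sample floor rather than by reaching normality.
    """

    removed_count: int
    p_trajectory: list[float]
    final_p: float
    floor_hit: bool


def extract_clusters_from_ic(
    coefficients: pd.Series,
    alpha: float = 0.05,
    min_remaining: int = MIN_REMAINING,
    source_ic: int = 0,
    axis: str = "gene",
) -> tuple[SignedCluster, SignedCluster, ExtractionTrace]:
    """Trim one IC's tails until the remainder is D'Agostino-normal.

    Parameters
    ----------
    coefficients : pandas Series
        The IC's signal-matrix column, indexed by gene (or condition) ids.
    alpha : float
        Stop once the D'Agostino p-value of the remainder reaches alpha.

    Returns
    -------
    (positive, negative, trace)
        Signed clusters in removal order (most extreme member first);
        either may be empty.
    """
    if not isinstance(coefficients, pd.Series):
        coefficients = pd.Series(np.asarray(coefficients, dtype=float))
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values = coefficients.to_numpy(dtype=float)
    ids = [str(i) for i in coefficients.index]
    if values.size < 8:
        raise SampleTooSmallError(
            f"need >= 8 coefficients, got {values.size}"
        )

    pos = SignedCluster(axis=axis, source_ic=source_ic, sign="+")
    neg = SignedCluster(axis=axis, source_ic=source_ic, sign="-")
    remaining = np.ones(values.size, dtype=bool)
    trajectory: list[float] = []
    floor_hit = False

    _, p = dagostino_k2(values)
    trajectory.append(p)
    while p < alpha:
        if remaining.sum() <= min_remaining:
            floor_hit = True
            break
        live = np.flatnonzero(remaining)
        # argmax returns the first (lowest-index) maximum: deterministic ties
        worst = live[np.argmax(np.abs(values[live]))]
        target = pos if values[worst] >= 0 else neg
        target.add(ids[worst], values[worst])
        remaining[worst] = False
        _, p = dagostino_k2(values[remaining])
        trajectory.append(p)

    trace = ExtractionTrace(
        removed_count=len(pos) + len(neg),
        p_trajectory=trajectory,
        final_p=trajectory[-1],
        floor_hit=floor_hit,
    )
    return pos, neg, trace


def extract_all(
    decomp: ICADecomposition,
    axis: str,
    alpha: float = 0.05,
    min_remaining: int = MIN_REMAINING,
) -> list[SignedCluster]:
    """Run tail extraction on every component; drop empty clusters.

    At most ``2 * n_components`` clusters come back; clusters from
    different ICs may overlap.
    """
    if axis not in ("gene", "condition"):
        raise ValueError(f"axis must be 'gene' or 'condition', got {axis!r}")
    if decomp.row_ids is None:
        ids = [str(i) for i in range(decomp.signal.shape[0])]
    else:
        ids = decomp.row_ids
    clusters: list[SignedCluster] = []
    for ic in range(decomp.n_components):
        series = pd.Series(decomp.signal[:, ic], index=ids)
        pos, neg, _ = extract_clusters_from_ic(
            series,
            alpha=alpha,
            min_remaining=min_remaining,
            source_ic=ic,
            axis=axis,
        )
        for cluster in (pos, neg):
            if len(cluster):
                clusters.append(cluster)
    return clusters


def assign_orphan_conditions(
    gene_decomp: ICADecomposition,
    clusters: list[SignedCluster],
) -> list[SignedCluster]:
    """Attach every unclustered condition to its strongest component.

    Each orphan joins the signed cluster of the gene IC where it has the
    largest |coefficient| (the sign taken from that coefficient), creating
    the cluster if extraction produced none there. Orphan members are
    flagged. Applied to conditions only — the original procedure leaves
    genes unclustered.
    """
    clusters = copy.deepcopy(clusters)
    if gene_decomp.row_ids is None:
        ids = [str(i) for i in range(gene_decomp.signal.shape[0])]
    else:
        ids = gene_decomp.row_ids
    covered = set()
    for cluster in clusters:
        covered.update(cluster.member_ids)
    index: dict[tuple[int, str], SignedCluster] = {
        (c.source_ic, c.sign): c for c in clusters
    }
    for row, cond in enumerate(ids):
        if cond in covered:
            continue
        coefs = gene_decomp.signal[row, :]
        ic = int(np.argmax(np.abs(coefs)))
        sign = "+" if coefs[ic] >= 0 else "-"
        key = (ic, sign)
        if key not in index:
            fresh = SignedCluster(axis="condition", source_ic=ic, sign=sign)
            index[key] = fresh
            clusters.append(fresh)
        index[key].add(cond, coefs[ic], orphan=True)
    return clusters
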