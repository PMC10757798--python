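"""Fisher's exact gene-set enrichment of extracted gene clusters.

Each cluster is tested against each sufficiently large gene set (regulon,
pathway, ...) with a one-sided (greater) Fisher's exact test on the 2x2
membership table over a common gene universe, followed by BH adjustment
across the whole cluster x set family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .association import bh_adjust
from .exceptions import GMTParseError
from .extraction import SignedCluster

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "fisher_enrichment",
    "enrich_all",
]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a common universe.

    Members outside the universe are dropped at construction time with a
    single count warning.
    """

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if not uni:
            raise ValueError("universe must be non-empty")
        dropped = 0
        harmonized = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in uni]
            dropped += len(members) - len(kept)
            harmonized[name] = kept
        if dropped:
            warnings.warn(
                f"dropped {dropped} gene-set member(s) outside the universe",
                stacklevel=2,
            )
        self.sets = harmonized


@dataclass
class EnrichmentRecord:
    """One cluster x gene-set Fisher test."""

    cluster_label: str
    set_name: str
    overlap_count: int
    es: float  # fold enrichment: (overlap/cluster) / (set/universe)
    odds_ratio: float
    p: float
    q: float
    overlap_pct: float  # 100 * overlap / set size


def read_gmt(path, universe: list[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members; tab-separated).

    Duplicate members within a set are dropped with a warning. The
    universe defaults to the union of all set members when not supplied.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} field(s)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate members; "
                    "deduplicated",
                    stacklevel=2,
                )
            sets[name] = unique
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets=sets, universe=list(universe))


def fisher_enrichment(
    cluster,
    gene_set,
    universe,
    cluster_label: str = "",
    set_name: str = "",
) -> EnrichmentRecord:
    """One-sided Fisher's exact test for cluster/set overlap.

    The 2x2 table partitions the universe into (in cluster & set,
    in cluster only, in set only, in neither); p is the upper
    (hypergeometric) tail. ``es`` is fold enrichment of the observed over
    the expected overlap; ``overlap_pct`` uses the set size as denominator.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    cluster = set(cluster) & universe
    gene_set = set(gene_set) & universe
    a = len(cluster & gene_set)
    b = len(cluster) - a
    c = len(gene_set) - a
    d = len(universe) - a - b - c
    odds_ratio, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if cluster and gene_set:
        es = (a / len(cluster)) / (len(gene_set) / len(universe))
    else:
        es = 0.0
    overlap_pct = 100.0 * a / len(gene_set) if gene_set else 0.0
    return EnrichmentRecord(
        cluster_label=cluster_label,
        set_name=set_name,
        overlap_count=a,
        es=float(es),
        odds_ratio=float(odds_ratio),
        p=float(p),
        q=float("nan"),
        overlap_pct=float(overlap_pct),
    )


def enrich_all(
    clusters: list[SignedCluster],
    collection: GeneSetCollection,
    min_set_size: int = 10,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every cluster against every set with >= min_set_size members.

    BH adjustment spans the full cluster x set family in this call;
    records come back sorted by q (then p).
    """
    if min_set_size < 1:
        raise ValueError(f"min_set_size must be >= 1, got {min_set_size}")
    eligible = {
        name: members
        for name, members in collection.sets.items()
        if len(members) >= min_set_size
    }
    records: list[EnrichmentRecord] = []
    for cluster in clusters:
        for name, members in eligible.items():
            records.append(
                fisher_enrichment(
                    cluster.member_ids,
                    members,
                    collection.universe,
                    cluster_label=cluster.label,
                    set_name=name,
                )
            )
    if records:
        qs = bh_adjust([r.p for r in records])
        for rec, q in zip(records, qs):
            rec.q = float(q)
        records.sort(key=lambda r: (r.q, r.p, r.cluster_label, r.set_name))
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster_label,
                "gene_set": r.set_name,
                "overlap": r.overlap_count,
                "es": r.es,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "q": r.q,
                "overlap_pct": r.overlap_pct,
            }
            for r in records
        ]
    )
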