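"""Cluster and singleton assignment from ANI and shared-gene-content evidence.

Genomes are nodes; an edge joins two genomes when their symmetrized ANI and
aligned fraction clear the thresholds (optionally corroborated by shared
gene content). Clusters are connected components with >= 2 members; size-1
components are singletons. ANI is the primary evidence: phage pairs can
share an appreciable fraction of genes at the amino-acid level while their
nucleotide identity stays low, and such pairs must remain in separate
clusters under the defaults.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_io import Genome
from .pham_builder import PhamTable

__all__ = [
    "ClusteringParams",
    "ClusterAssignment",
    "SINGLETON",
    "shared_gene_fraction",
    "assign_clusters",
    "intra_cluster_ani_summary",
    "default_label_scheme",
]

SINGLETON = "SINGLETON"


def default_label_scheme(start: str = "AK") -> Iterable[str]:
    """Two-letter cluster labels AK, AL, AM, ... continuing through BA, BB, ..."""
    import string

    letters = string.ascii_uppercase
    started = False
    for first in letters:
        for second in letters:
            label = first + second
            if label == start:
                started = True
            if started:
                yield label


@dataclass(frozen=True)
class ClusteringParams:
    t_ani: float = 0.60  # minimum symmetrized ANI for an edge
    t_frac: float = 0.50  # minimum symmetrized aligned fraction
    t_gene: float | None = None  # optional shared-gene-fraction OR-criterion
    label_start: str = "AK"
    subdivision_floor: float = 0.70  # report-only intra-cluster ANI floor

    def __post_init__(self) -> None:
        for v in (self.t_ani, self.t_frac):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class ClusterAssignment:
    """genome id -> cluster label (or SINGLETON), with per-pair evidence."""

    labels: dict[str, str]
    clusters: dict[str, tuple[str, ...]]  # label -> members, size >= 2
    singletons: tuple[str, ...]
    evidence: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    params: ClusteringParams = field(default_factory=ClusteringParams)

    def members(self, label: str) -> tuple[str, ...]:
        return self.clusters[label]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"genome": gid, "cluster": label,
             "n_members": len(self.clusters[label]) if label != SINGLETON else 1}
            for gid, label in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows)


def shared_gene_fraction(a: Genome | str, b: Genome | str, phams: PhamTable) -> tuple[float, float, float]:
    """Directional and mean shared-gene fractions between two genomes.

    a->b is the fraction of a's genes whose pham also contains at least one
    gene of b. Raises for a genome with no genes in the pham table.
    """
    aid = a.id if isinstance(a, Genome) else a
    bid = b.id if isinstance(b, Genome) else b
    p2p = phams.protein_to_pham
    genes_a = [pid for pid, p in phams.proteins.items() if p.phage_id == aid]
    genes_b = [pid for pid, p in phams.proteins.items() if p.phage_id == bid]
    if not genes_a or not genes_b:
        raise ValueError(f"shared_gene_fraction undefined: {aid if not genes_a else bid} has no genes")
    phams_a = {p2p[pid] for pid in genes_a}
    phams_b = {p2p[pid] for pid in genes_b}
    ab = sum(1 for pid in genes_a if p2p[pid] in phams_b) / len(genes_a)
    ba = sum(1 for pid in genes_b if p2p[pid] in phams_a) / len(genes_b)
    return ab, ba, (ab + ba) / 2.0


def assign_clusters(
    genome_ids: Sequence[str] | Sequence[Genome],
    ani_results: Mapping[tuple[str, str], "AniResult"],
    phams: PhamTable | None = None,
    params: ClusteringParams = ClusteringParams(),
) -> ClusterAssignment:
    """Partition genomes into labelled clusters and singletons.

    ``ani_results`` maps unordered genome-id pairs to symmetrized
    :class:`~phamlin.nucleotide_compare.AniResult` objects. Labels are
    assigned to clusters by decreasing size, ties broken by the
    lexicographically smallest member id.
    """
    ids = [g.id if isinstance(g, Genome) else g for g in genome_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    lookup = {}
    for (x, y), res in ani_results.items():
        lookup[frozenset((x, y))] = res
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    evidence: dict[tuple[str, str], dict[str, float]] = {}
    for x, y in itertools.combinations(sorted(ids), 2):
        res = lookup.get(frozenset((x, y)))
        if res is None:
            raise ValueError(f"missing ANI result for pair ({x}, {y})")
        ev = {"ani": res.ani, "aligned_fraction": res.aligned_fraction}
        linked = res.ani >= params.t_ani and res.aligned_fraction >= params.t_frac
        if phams is not None and params.t_gene is not None:
            _, _, sym = shared_gene_fraction(x, y, phams)
            ev["shared_gene_fraction"] = sym
            linked = linked or sym >= params.t_gene
        evidence[(x, y)] = ev
        if linked:
            graph.add_edge(x, y)
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    labels: dict[str, str] = {}
    clusters: dict[str, tuple[str, ...]] = {}
    singletons: list[str] = []
    scheme = default_label_scheme(params.label_start)
    for comp in components:
        if len(comp) >= 2:
            label = next(scheme)
            clusters[label] = comp
            for gid in comp:
                labels[gid] = label
        else:
            singletons.append(comp[0])
            labels[comp[0]] = SINGLETON
    return ClusterAssignment(
        labels=labels,
        clusters=clusters,
        singletons=tuple(sorted(singletons)),
        evidence=evidence,
        params=params,
    )


def intra_cluster_ani_summary(
    members: Sequence[str],
    ani_results: Mapping[tuple[str, str], "AniResult"],
    subdivision_floor: float = 0.70,
) -> dict[str, float | bool]:
    """min/mean/max symmetrized ANI over all intra-cluster pairs.

    ``subdivision_warranted`` flags (report-only) a minimum below the floor.
    """
    if len(members) < 2:
        raise ValueError("intra-cluster summary requires a cluster with >= 2 members")
    lookup = {frozenset(k): v for k, v in ani_results.items()}
    values = [
        lookup[frozenset((x, y))].ani
        for x, y in itertools.combinations(sorted(members), 2)
    ]
    return {
        "min": min(values),
        "mean": sum(values) / len(values),
        "max": max(values),
        "subdivision_warranted": min(values) < subdivision_floor,
    }
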