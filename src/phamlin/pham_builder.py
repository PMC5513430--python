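"""Pham (protein phamily) construction by single-linkage sequence clustering.

Every predicted protein from every genome is compared all-vs-all by local
amino-acid alignment; pairs passing an identity-and-coverage criterion form
edges, and phams are the connected components of the resulting graph
(single linkage). Phams with one member gene in one phage and no match in an
attached external reference set are orphams.

The defaults (BLOSUM62, gap open 11 / extend 1, identity >= 32.5% with
coverage >= 0.5 of the shorter protein) follow the Phamerator-lineage
convention for actinobacteriophage pham building; both thresholds are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Protein",
    "PhamParams",
    "SimilarityEdge",
    "PhamTable",
    "protein_pairwise",
    "build_phams",
    "attach_external",
    "orphams",
]


@dataclass(frozen=True)
class Protein:
    """One protein sequence with its source phage (or external genus) tag."""

    protein_id: str
    phage_id: str
    sequence: str
    genus: str = ""  # host genus, used for external reference proteins

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty translation")


@dataclass(frozen=True)
class PhamParams:
    identity_min: float = 32.5  # percent identity over aligned columns
    coverage_min: float = 0.5  # aligned columns / shorter protein length
    score_min: float = 100.0  # significance floor on the raw alignment score
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    prefilter_word: int = 4  # shared k-mer prefilter word size
    prefilter_min_shared: int = 1  # 0 disables the prefilter


@dataclass(frozen=True)
class SimilarityEdge:
    """One pairwise local-alignment result, stored in canonical id order."""

    query_id: str
    subject_id: str
    percent_identity: float
    coverage: float
    score: float


@dataclass
class PhamTable:
    """A partition of proteins into phams, plus external-membership counts.

    ``phams`` maps pham id -> tuple of member protein ids; ids are assigned
    by decreasing pham size with ties broken by the lexicographically
    smallest member id, so the table is deterministic for a given input.
    """

    phams: dict[str, tuple[str, ...]]
    proteins: dict[str, Protein]
    params: PhamParams
    external_members: dict[str, int] = field(default_factory=dict)
    external_genera: dict[str, dict[str, int]] = field(default_factory=dict)
    external_attached: bool = False

    @property
    def protein_to_pham(self) -> dict[str, str]:
        return {pid: pham for pham, members in self.phams.items() for pid in members}

    def phages_of(self, pham_id: str) -> set[str]:
        return {self.proteins[pid].phage_id for pid in self.phams[pham_id]}

    def phams_of_phage(self, phage_id: str) -> set[str]:
        return {
            pham
            for pham, members in self.phams.items()
            if any(self.proteins[pid].phage_id == phage_id for pid in members)
        }

    def to_frame(self):
        import pandas as pd

        orp = orphams(self)
        rows = [
            {
                "protein_id": pid,
                "phage_id": self.proteins[pid].phage_id,
                "pham_id": pham,
                "is_orpham": pham in orp,
            }
            for pham, members in self.phams.items()
            for pid in members
        ]
        return pd.DataFrame(rows).sort_values(["pham_id", "protein_id"]).reset_index(drop=True)


def _aligner(params: PhamParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        open_gap_score=-abs(params.gap_open),
        extend_gap_score=-abs(params.gap_extend),
    )
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    return aligner


def protein_pairwise(
    a: Protein, b: Protein, params: PhamParams = PhamParams(), aligner: Align.PairwiseAligner | None = None
) -> SimilarityEdge:
    """Best local alignment of two proteins.

    Percent identity counts identical residue pairs over all alignment
    columns (gap columns included); coverage is alignment columns over the
    shorter protein's length, capped at 1.
    """
    if aligner is None:
        aligner = _aligner(params)
    qid, sid = sorted((a.protein_id, b.protein_id))
    alignments = aligner.align(a.sequence, b.sequence)
    if len(alignments) == 0 or alignments.score <= 0:
        return SimilarityEdge(qid, sid, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns if columns else 0.0
    shorter = min(len(a.sequence), len(b.sequence))
    coverage = min(1.0, columns / shorter)
    return SimilarityEdge(qid, sid, identity, coverage, float(aln.score))


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _candidate_pairs(proteins: Sequence[Protein], params: PhamParams):
    """All index pairs passing the shared-word prefilter.

    The prefilter is a cost optimization only: a pair sharing fewer than
    ``prefilter_min_shared`` words of length ``prefilter_word`` is assumed to
    fall below the edge thresholds and is not aligned.
    """
    n = len(proteins)
    if params.prefilter_min_shared <= 0:
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j
        return
    kmers = [_kmer_set(p.sequence, params.prefilter_word) for p in proteins]
    for i in range(n):
        ki = kmers[i]
        for j in range(i + 1, n):
            shared = len(ki & kmers[j])
            if shared >= params.prefilter_min_shared:
                yield i, j


def edge_passes(edge: SimilarityEdge, params: PhamParams) -> bool:
    """The pham edge criterion: identity, coverage, and score floor.

    Short local alignments between unrelated proteins reach the twilight
    zone (>= 30% identity over 40-60 columns) by chance; the raw-score
    floor plays the significance-guard role an E-value cutoff plays in
    BLAST-based pham assembly.
    """
    return (
        edge.percent_identity >= params.identity_min
        and edge.coverage >= params.coverage_min
        and edge.score >= params.score_min
    )


def _edges(proteins: Sequence[Protein], params: PhamParams) -> list[SimilarityEdge]:
    aligner = _aligner(params)
    edges = []
    for i, j in _candidate_pairs(proteins, params):
        edge = protein_pairwise(proteins[i], proteins[j], params, aligner)
        if edge_passes(edge, params):
            edges.append(edge)
    return edges


def build_phams(proteins: Iterable[Protein], params: PhamParams = PhamParams()) -> PhamTable:
    """Single-linkage clustering of proteins into phams.

    Edges are pairs with percent identity >= ``identity_min`` and coverage
    >= ``coverage_min``; phams are connected components. Pham ids are stable
    for identical inputs and parameters.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("build_phams requires at least one protein")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in input")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((e.query_id, e.subject_id) for e in _edges(proteins, params))
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    width = max(4, len(str(len(components))))
    phams = {f"pham_{i + 1:0{width}d}": members for i, members in enumerate(components)}
    return PhamTable(phams=phams, proteins={p.protein_id: p for p in proteins}, params=params)


def attach_external(phams: PhamTable, external: Iterable[Protein]) -> PhamTable:
    """Map external reference proteins onto existing phams.

    Each external protein joins the pham of the best internal protein it
    passes the edge thresholds against; external proteins matching nothing
    are dropped. The internal partition is never changed. Returns a new
    table with ``external_members`` / per-genus counts filled in.
    """
    params = phams.params
    aligner = _aligner(params)
    external = list(external)
    ext_counts: dict[str, int] = {}
    ext_genera: dict[str, dict[str, int]] = {}
    internal = list(phams.proteins.values())
    kmers_int = [_kmer_set(p.sequence, params.prefilter_word) for p in internal]
    p2p = phams.protein_to_pham
    for ext in external:
        kext = _kmer_set(ext.sequence, params.prefilter_word)
        best: tuple[float, str] | None = None
        for p, kp in zip(internal, kmers_int):
            if params.prefilter_min_shared > 0 and len(kext & kp) < params.prefilter_min_shared:
                continue
            edge = protein_pairwise(ext, p, params, aligner)
            if edge_passes(edge, params):
                if best is None or edge.score > best[0]:
                    best = (edge.score, p2p[p.protein_id])
        if best is not None:
            pham_id = best[1]
            ext_counts[pham_id] = ext_counts.get(pham_id, 0) + 1
            genus = ext.genus or "unknown"
            ext_genera.setdefault(pham_id, {})[genus] = ext_genera.setdefault(pham_id, {}).get(genus, 0) + 1
    return PhamTable(
        phams=dict(phams.phams),
        proteins=dict(phams.proteins),
        params=params,
        external_members=ext_counts,
        external_genera=ext_genera,
        external_attached=True,
    )


def orphams(phams: PhamTable) -> set[str]:
    """Phams with exactly one internal member gene, from a single phage, and
    no external members."""
    return {
        pham
        for pham, members in phams.phams.items()
        if len(members) == 1 and phams.external_members.get(pham, 0) == 0
    }
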