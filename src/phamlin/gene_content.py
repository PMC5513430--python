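"""Pham presence/absence matrices, gene-content distances, and phylogeny export.

The presence/absence matrix has one row per genome and one 0/1 column per
pham. Gene-content distances default to the Jaccard distance between pham
sets; an alternative "shared-fraction" distance (one minus the mean
directional shared-pham fraction) is selectable. Matrices and distances
export to NEXUS for split-network software, and a neighbor-joining tree can
be written as newick.
"""

from __future__ import annotations

import io
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd

from .cluster_assign import SINGLETON, ClusterAssignment
from .genome_io import Genome
from .pham_builder import PhamTable

__all__ = [
    "presence_matrix",
    "gene_content_distance",
    "export_nexus",
    "nj_tree",
    "representative_matrix",
]


def presence_matrix(phams: PhamTable, genomes: Sequence[Genome] | Sequence[str]) -> pd.DataFrame:
    """Binary genome x pham matrix; cell 1 iff the genome has a gene in the pham."""
    ids = [g.id if isinstance(g, Genome) else g for g in genomes]
    known = {p.phage_id for p in phams.proteins.values()}
    missing = [g for g in ids if g not in known]
    if missing:
        raise ValueError(f"genomes absent from the pham table: {missing}")
    pham_ids = sorted(phams.phams)
    mat = pd.DataFrame(0, index=ids, columns=pham_ids, dtype=np.int8)
    p2p = phams.protein_to_pham
    for pid, protein in phams.proteins.items():
        if protein.phage_id in mat.index:
            mat.loc[protein.phage_id, p2p[pid]] = 1
    return mat


def gene_content_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise gene-content distance matrix in [0, 1].

    ``jaccard``: 1 - |intersection| / |union| of the two pham sets.
    ``shared-fraction``: 1 - mean of the two directional shared fractions.
    """
    if matrix.empty:
        raise ValueError("empty presence/absence matrix")
    row_sums = matrix.sum(axis=1)
    empty = row_sums[row_sums == 0]
    if len(empty):
        raise ValueError(f"genomes with an empty pham set: {list(empty.index)}")
    bool_mat = matrix.to_numpy(dtype=bool)
    if metric == "jaccard":
        condensed = ssd.pdist(bool_mat, metric="jaccard")
        dist = ssd.squareform(condensed)
    elif metric == "shared-fraction":
        n = len(matrix)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                inter = np.logical_and(bool_mat[i], bool_mat[j]).sum()
                frac = (inter / bool_mat[i].sum() + inter / bool_mat[j].sum()) / 2.0
                dist[i, j] = dist[j, i] = 1.0 - frac
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = pd.DataFrame(dist, index=matrix.index, columns=matrix.index)
    out.attrs["metric"] = metric
    return out


def _check_taxa(names: Sequence[str]) -> None:
    if len(set(names)) != len(names):
        raise ValueError("taxa name collision in matrix")


def export_nexus(table: pd.DataFrame, path) -> None:
    """Write a NEXUS file from a presence/absence or distance matrix.

    A square matrix with a zero diagonal and identical index/columns is
    written as a DISTANCES block; anything else as a binary CHARACTERS
    block with symbols "01".
    """
    _check_taxa(list(table.index))
    is_dist = (
        table.shape[0] == table.shape[1]
        and list(table.index) == list(table.columns)
        and np.allclose(np.diag(table.to_numpy(float)), 0.0)
    )
    buf = io.StringIO()
    buf.write("#NEXUS\n\n")
    taxa = [str(t) for t in table.index]
    buf.write("BEGIN TAXA;\n")
    buf.write(f"    DIMENSIONS NTAX={len(taxa)};\n")
    buf.write("    TAXLABELS " + " ".join(taxa) + ";\nEND;\n\n")
    if is_dist:
        buf.write("BEGIN DISTANCES;\n")
        buf.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n    MATRIX\n")
        for t in taxa:
            row = " ".join(f"{v:.6f}" for v in table.loc[t])
            buf.write(f"    {t} {row}\n")
        buf.write("    ;\nEND;\n")
    else:
        buf.write("BEGIN CHARACTERS;\n")
        buf.write(f"    DIMENSIONS NCHAR={table.shape[1]};\n")
        buf.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n    MATRIX\n')
        for t in taxa:
            row = "".join(str(int(v)) for v in table.loc[t])
            buf.write(f"    {t} {row}\n")
        buf.write("    ;\nEND;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick) from a distance matrix.

    Canonical NJ with deterministic tie-breaking; negative branch lengths
    are clamped to zero.
    """
    _check_taxa(list(distances.index))
    csv = io.StringIO()
    distances.to_csv(csv)
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(csv, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def representative_matrix(
    assignment: ClusterAssignment,
    phams: PhamTable,
    genomes: Sequence[Genome],
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix over one representative genome per cluster
    plus all singletons.

    The default representative is the largest genome in the cluster;
    ``overrides`` maps cluster label -> genome id to force a choice.
    """
    overrides = dict(overrides or {})
    by_id = {g.id: g for g in genomes}
    chosen: list[str] = []
    for label, members in assignment.clusters.items():
        if label in overrides:
            rep = overrides[label]
            if rep not in members:
                raise ValueError(f"override {rep!r} is not a member of cluster {label}")
        else:
            rep = max(members, key=lambda gid: (len(by_id[gid].sequence), gid))
        chosen.append(rep)
    chosen.extend(assignment.singletons)
    return presence_matrix(phams, chosen)
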