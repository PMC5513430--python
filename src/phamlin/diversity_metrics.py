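"""Cluster diversity and gene-sharing statistics.

For each cluster of >= 2 phages, four percentages over the cluster's pham
universe (the distinct phams found across its members):

* cluster-identifier phams — present in every member and absent from all
  phages of other clusters (not computed for singletons);
* orphams — phams with one member gene in one phage and no homologue in
  the attached external reference set;
* phams shared with at least one phage of another cluster in the study set;
* phams shared with at least one phage infecting a different host genus
  (requires an attached external reference set).

Identifier phams and inter-cluster-shared phams are disjoint by
construction. All percentages use the pham universe as denominator;
gene-weighted variants are available via ``weight="genes"``.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import pandas as pd

from .cluster_assign import SINGLETON, ClusterAssignment
from .pham_builder import PhamTable, orphams

__all__ = [
    "cluster_pham_universe",
    "cluster_identifier_phams",
    "orpham_percent",
    "intercluster_shared_percent",
    "external_shared_percent",
    "pairwise_cluster_sharing_table",
    "diversity_report",
]

NOT_COMPUTED = float("nan")


def _pham_phages(phams: PhamTable) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {p: set() for p in phams.phams}
    for pid, protein in phams.proteins.items():
        out[phams.protein_to_pham[pid]].add(protein.phage_id)
    return out


def cluster_pham_universe(members: Iterable[str], phams: PhamTable) -> set[str]:
    """Distinct phams with at least one gene in any of the given genomes."""
    members = set(members)
    return {
        pham
        for pham, phages in _pham_phages(phams).items()
        if phages & members
    }


def cluster_identifier_phams(
    label: str, assignment: ClusterAssignment, phams: PhamTable
) -> tuple[set[str], float]:
    """Phams in every cluster member and in no other study genome, with the
    percent of the cluster's pham universe they represent."""
    members = set(assignment.clusters[label])
    if len(members) < 2:
        raise ValueError("identifier phams are not computed for singletons")
    others = set(assignment.labels) - members
    pham_phages = _pham_phages(phams)
    universe = {p for p, phages in pham_phages.items() if phages & members}
    idents = {
        p
        for p in universe
        if members <= pham_phages[p] and not (pham_phages[p] & others)
    }
    return idents, 100.0 * len(idents) / len(universe)


def orpham_percent(scope: Iterable[str] | str, phams: PhamTable) -> float:
    """Percent of the scope's pham universe that are orphams.

    ``scope`` is a genome id or an iterable of genome ids (e.g. a cluster's
    members). Without an attached external set, an orpham is simply an
    internal single-member pham.
    """
    members = {scope} if isinstance(scope, str) else set(scope)
    universe = cluster_pham_universe(members, phams)
    if not universe:
        raise ValueError("empty pham universe for scope")
    orp = orphams(phams)
    return 100.0 * len(universe & orp) / len(universe)


def intercluster_shared_percent(
    label: str, assignment: ClusterAssignment, phams: PhamTable
) -> float:
    """Percent of the cluster's phams also present in another study cluster
    or singleton."""
    members = set(assignment.clusters.get(label, (label,)) if label in assignment.clusters else [label])
    if label in assignment.clusters:
        members = set(assignment.clusters[label])
    others = set(assignment.labels) - members
    pham_phages = _pham_phages(phams)
    universe = {p for p, phages in pham_phages.items() if phages & members}
    shared = {p for p in universe if pham_phages[p] & others}
    return 100.0 * len(shared) / len(universe)


def external_shared_percent(members: Iterable[str] | str, phams: PhamTable) -> float:
    """Percent of the scope's phams with at least one external member."""
    if not phams.external_attached:
        raise ValueError("no external reference set attached; run attach_external first")
    members = {members} if isinstance(members, str) else set(members)
    universe = cluster_pham_universe(members, phams)
    shared = {p for p in universe if phams.external_members.get(p, 0) >= 1}
    return 100.0 * len(shared) / len(universe)


def pairwise_cluster_sharing_table(
    assignment: ClusterAssignment, phams: PhamTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-pham counts and row-normalized fractions between cluster pairs.

    Returns (counts, fractions): counts[i, j] is the number of phams with
    members in both groups; fractions[i, j] divides by group i's universe.
    Singletons are included as their own rows.
    """
    groups: dict[str, set[str]] = {
        label: set(members) for label, members in assignment.clusters.items()
    }
    for s in assignment.singletons:
        groups[s] = {s}
    if len(groups) < 2:
        raise ValueError("need at least two clusters/singletons")
    names = sorted(groups)
    universes = {name: cluster_pham_universe(groups[name], phams) for name in names}
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    fracs = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        shared = len(universes[a] & universes[b])
        counts.loc[a, b] = counts.loc[b, a] = shared
        fracs.loc[a, b] = shared / len(universes[a])
        fracs.loc[b, a] = shared / len(universes[b])
    for name in names:
        counts.loc[name, name] = len(universes[name])
        fracs.loc[name, name] = 1.0
    return counts, fracs


def diversity_report(assignment: ClusterAssignment, phams: PhamTable) -> pd.DataFrame:
    """One row per cluster (and singleton) with the headline percentages.

    Identifier-pham percent is NaN for singletons; the external column is
    NaN when no external reference set was attached.
    """
    rows = []
    groups = [(label, list(members)) for label, members in assignment.clusters.items()]
    groups += [(s, [s]) for s in assignment.singletons]
    for label, members in groups:
        universe = cluster_pham_universe(members, phams)
        row = {
            "cluster": label,
            "n_members": len(members),
            "n_phams": len(universe),
            "pct_identifier": NOT_COMPUTED,
            "pct_orpham": orpham_percent(members, phams),
            "pct_shared_other_cluster": intercluster_shared_percent(
                label if label in assignment.clusters else members[0], assignment, phams
            ),
            "pct_shared_other_host": NOT_COMPUTED,
        }
        if label in assignment.clusters:
            _, pct = cluster_identifier_phams(label, assignment, phams)
            row["pct_identifier"] = pct
        if phams.external_attached:
            row["pct_shared_other_host"] = external_shared_percent(members, phams)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
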