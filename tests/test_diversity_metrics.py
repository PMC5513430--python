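"""Cluster diversity statistics against brute-force set scans.

The constructed universe gives every metric a hand-checkable value and the
brute-force scan an independent recomputation path.
"""

import itertools

import pytest

from phamlin import (
    Protein,
    build_phams,
    attach_external,
    cluster_identifier_phams,
    cluster_pham_universe,
    diversity_report,
    external_shared_percent,
    intercluster_shared_percent,
    orpham_percent,
    pairwise_cluster_sharing_table,
)
from phamlin.cluster_assign import ClusterAssignment, ClusteringParams
from phamlin.synthetic_data import random_protein


def _constructed_universe(rng, n_phams=60):
    """Three clusters of phages with a fully known pham layout.

    Phams are planted as distinct random proteins; gene placement is by
    explicit (phage, pham) pairs so every metric has an enumerable truth.
    """
    pham_seqs = {f"P{i:03d}": random_protein(150, rng) for i in range(n_phams)}
    # cluster A: phages a1, a2 — 10 identifier phams P000-P009, plus shared
    # cluster B: phages b1, b2, b3 — identifiers P020-P024
    # cluster C (really a singleton genome): phage c1 — all its own phams
    layout = {
        "a1": [f"P{i:03d}" for i in range(0, 12)],          # P010, P011 shared with B
        "a2": [f"P{i:03d}" for i in range(0, 10)] + ["P010", "P011", "P030"],
        "b1": [f"P{i:03d}" for i in range(20, 25)] + ["P010", "P031"],
        "b2": [f"P{i:03d}" for i in range(20, 25)] + ["P011"],
        "b3": [f"P{i:03d}" for i in range(20, 25)] + ["P032"],
        "c1": [f"P{i:03d}" for i in range(40, 50)],
    }
    proteins = [
        Protein(f"{phage}_{pham}", phage, pham_seqs[pham])
        for phage, phams in layout.items()
        for pham in phams
    ]
    table = build_phams(proteins)
    # map planted pham name -> realized pham id via any member protein
    p2p = table.protein_to_pham
    realized = {pham: p2p[f"a1_{pham}"] for pham in layout["a1"]}
    for phage, phams in layout.items():
        for pham in phams:
            realized[pham] = p2p[f"{phage}_{pham}"]
    assignment = ClusterAssignment(
        labels={"a1": "AK", "a2": "AK", "b1": "AL", "b2": "AL", "b3": "AL", "c1": "SINGLETON"},
        clusters={"AK": ("a1", "a2"), "AL": ("b1", "b2", "b3")},
        singletons=("c1",),
        params=ClusteringParams(),
    )
    return table, assignment, layout, realized


def _brute_force(table, assignment, layout):
    """Exhaustive scan over (phage, pham) membership."""
    pham_phages = {}
    for pid, protein in table.proteins.items():
        pham_phages.setdefault(table.protein_to_pham[pid], set()).add(protein.phage_id)
    groups = {label: set(m) for label, m in assignment.clusters.items()}
    for s in assignment.singletons:
        groups[s] = {s}
    out = {}
    for label, members in groups.items():
        universe = {p for p, ph in pham_phages.items() if ph & members}
        others = set(assignment.labels) - members
        out[label] = {
            "universe": universe,
            "identifier": {
                p for p in universe
                if members <= pham_phages[p] and not pham_phages[p] & others
            },
            "orpham": {
                p for p in universe
                if len(table.phams[p]) == 1 and table.external_members.get(p, 0) == 0
            },
            "shared": {p for p in universe if pham_phages[p] & others},
            "external": {p for p in universe if table.external_members.get(p, 0) >= 1},
        }
    return out


class TestConstructedUniverse:
    def test_identifier_phams_match_brute_force(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        truth = _brute_force(table, assignment, layout)
        for label in ("AK", "AL"):
            idents, pct = cluster_identifier_phams(label, assignment, table)
            assert idents == truth[label]["identifier"]
            assert pct == pytest.approx(100 * len(idents) / len(truth[label]["universe"]))

    def test_identifier_not_computed_for_singletons(self, rng):
        table, assignment, _, _ = _constructed_universe(rng)
        with pytest.raises(ValueError):
            cluster_identifier_phams("AK", ClusterAssignment(
                labels={"a1": "AK"}, clusters={"AK": ("a1",)}, singletons=(),
            ), table)

    def test_orpham_percent_matches_brute_force(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        truth = _brute_force(table, assignment, layout)
        for label, members in (("AK", ["a1", "a2"]), ("AL", ["b1", "b2", "b3"]), ("c1", ["c1"])):
            expected = 100 * len(truth[label]["orpham"]) / len(truth[label]["universe"])
            assert orpham_percent(members, table) == pytest.approx(expected)

    def test_all_unique_genome_is_fully_orpham(self, rng):
        table, assignment, _, _ = _constructed_universe(rng)
        assert orpham_percent("c1", table) == 100.0

    def test_intercluster_shared_matches_brute_force(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        truth = _brute_force(table, assignment, layout)
        for label in ("AK", "AL"):
            expected = 100 * len(truth[label]["shared"]) / len(truth[label]["universe"])
            assert intercluster_shared_percent(label, assignment, table) == pytest.approx(expected)

    def test_hand_counted_values(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        # AK universe: P000-P011 + P030 = 13 phams; identifiers P000-P009 (10);
        # shared with AL: P010, P011 (2)
        _, pct_ident = cluster_identifier_phams("AK", assignment, table)
        assert pct_ident == pytest.approx(100 * 10 / 13)
        assert intercluster_shared_percent("AK", assignment, table) == pytest.approx(100 * 2 / 13)

    def test_identifier_and_shared_sets_disjoint(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        truth = _brute_force(table, assignment, layout)
        for label in ("AK", "AL"):
            assert not truth[label]["identifier"] & truth[label]["shared"]
            idents, pi = cluster_identifier_phams(label, assignment, table)
            ps = intercluster_shared_percent(label, assignment, table)
            assert pi + ps <= 100.0 + 1e-9

    def test_external_shared_percent(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        with pytest.raises(ValueError, match="external"):
            external_shared_percent(["a1", "a2"], table)
        # external set = copy of phage b2's proteome
        ext = [
            Protein(f"ext_{pid}", f"ext:{pid}", p.sequence, genus="Rhodococcus")
            for pid, p in table.proteins.items()
            if p.phage_id == "b2"
        ]
        table2 = attach_external(table, ext)
        truth = _brute_force(table2, assignment, layout)
        for label, members in (("AK", ["a1", "a2"]), ("AL", ["b1", "b2", "b3"])):
            expected = 100 * len(truth[label]["external"]) / len(truth[label]["universe"])
            assert external_shared_percent(members, table2) == pytest.approx(expected)
        # b2's own cluster now shows exactly b2's pham coverage
        al_universe = cluster_pham_universe(["b1", "b2", "b3"], table2)
        b2_phams = table2.phams_of_phage("b2")
        assert external_shared_percent(["b1", "b2", "b3"], table2) == pytest.approx(
            100 * len(b2_phams) / len(al_universe)
        )

    def test_pairwise_sharing_table_hand_enumerated(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        counts, fracs = pairwise_cluster_sharing_table(assignment, table)
        # AK & AL share exactly P010 and P011
        assert counts.loc["AK", "AL"] == 2
        assert counts.loc["AK", "c1"] == 0
        assert counts.loc["AL", "AK"] == counts.loc["AK", "AL"]
        assert fracs.loc["AK", "AL"] == pytest.approx(2 / 13)

    def test_metrics_invariant_to_genome_order(self, rng):
        table, assignment, layout, _ = _constructed_universe(rng)
        flipped = ClusterAssignment(
            labels=assignment.labels,
            clusters={"AK": ("a2", "a1"), "AL": ("b3", "b1", "b2")},
            singletons=("c1",),
        )
        for label in ("AK", "AL"):
            assert cluster_identifier_phams(label, assignment, table)[1] == pytest.approx(
                cluster_identifier_phams(label, flipped, table)[1]
            )


class TestDiversityReport:
    def test_report_shape_and_columns(self, rng):
        table, assignment, _, _ = _constructed_universe(rng)
        report = diversity_report(assignment, table)
        assert set(report.cluster) == {"AK", "AL", "c1"}
        import pandas as pd

        row = report.set_index("cluster").loc["c1"]
        assert row.pct_orpham == 100.0
        assert pd.isna(row.pct_identifier)  # not computed for singletons

    def test_report_percentages_in_range(self, small_sim):
        from phamlin.nucleotide_compare import ani_matrix
        from phamlin.cluster_assign import assign_clusters
        from phamlin.synthetic_data import proteins_from_genomes

        genomes, _ = small_sim
        table = build_phams(proteins_from_genomes(genomes))
        _, pairs = ani_matrix(genomes)
        assignment = assign_clusters([g.id for g in genomes], pairs)
        report = diversity_report(assignment, table)
        for col in ("pct_identifier", "pct_orpham", "pct_shared_other_cluster"):
            vals = report[col].dropna()
            assert ((vals >= 0) & (vals <= 100)).all()
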