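"""Presence/absence matrices, gene-content distances, NEXUS and NJ export."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phamlin import (
    build_phams,
    export_nexus,
    gene_content_distance,
    nj_tree,
    presence_matrix,
    representative_matrix,
)
from phamlin.cluster_assign import assign_clusters
from phamlin.synthetic_data import proteins_from_genomes


@pytest.fixture(scope="module")
def sim_matrix(request):
    small_sim = request.getfixturevalue("small_sim")
    genomes, _ = small_sim
    phams = build_phams(proteins_from_genomes(genomes))
    return genomes, phams, presence_matrix(phams, genomes)


class TestPresenceMatrix:
    def test_row_sums_equal_distinct_pham_counts(self, sim_matrix):
        genomes, phams, matrix = sim_matrix
        for g in genomes:
            assert matrix.loc[g.id].sum() == len(phams.phams_of_phage(g.id))

    def test_column_sums_recount(self, sim_matrix):
        _, phams, matrix = sim_matrix
        for pham in matrix.columns:
            assert matrix[pham].sum() == len(phams.phages_of(pham))

    def test_no_all_zero_rows(self, sim_matrix):
        _, _, matrix = sim_matrix
        assert (matrix.sum(axis=1) > 0).all()

    def test_unknown_genome_rejected(self, sim_matrix):
        _, phams, _ = sim_matrix
        with pytest.raises(ValueError, match="absent"):
            presence_matrix(phams, ["nope"])


def _matrix(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestGeneContentDistance:
    def test_hand_computed_jaccard(self):
        # pham sets {1,2,3} vs {2,3,4}: distance 1 - 2/4 = 0.5
        mat = _matrix({"a": [1, 1, 1, 0], "b": [0, 1, 1, 1]})
        dist = gene_content_distance(mat)
        assert dist.loc["a", "b"] == pytest.approx(0.5)

    def test_identical_rows_zero_disjoint_one(self):
        mat = _matrix({"a": [1, 1, 0, 0], "b": [1, 1, 0, 0], "c": [0, 0, 1, 1]})
        dist = gene_content_distance(mat)
        assert dist.loc["a", "b"] == 0.0
        assert dist.loc["a", "c"] == 1.0

    def test_shared_fraction_metric(self):
        # a has phams 0..9; b has phams 0..2 plus 10, 11
        mat = _matrix({"a": [1] * 10 + [0, 0], "b": [1] * 3 + [0] * 7 + [1, 1]})
        dist = gene_content_distance(mat, metric="shared-fraction")
        # a->b = 3/10, b->a = 3/5
        assert dist.loc["a", "b"] == pytest.approx(1 - (3 / 10 + 3 / 5) / 2)

    def test_empty_pham_set_rejected(self):
        with pytest.raises(ValueError, match="empty pham set"):
            gene_content_distance(_matrix({"a": [1, 0], "b": [0, 0]}))

    @given(
        st.integers(min_value=2, max_value=8).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(0, 1), min_size=12, max_size=12).filter(lambda r: any(r)),
                min_size=n,
                max_size=n,
            )
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_jaccard_is_a_metric(self, rows):
        mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        dist = gene_content_distance(mat).to_numpy()
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)
        n = len(rows)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-12

    def test_zero_distance_iff_identical_pham_sets(self):
        mat = _matrix({"a": [1, 0, 1], "b": [1, 0, 1], "c": [1, 1, 1]})
        dist = gene_content_distance(mat)
        assert dist.loc["a", "b"] == 0.0
        assert dist.loc["a", "c"] > 0.0


class TestNexusExport:
    def test_characters_block_dimensions(self, tmp_path, sim_matrix):
        _, _, matrix = sim_matrix
        path = tmp_path / "phams.nex"
        export_nexus(matrix, path)
        chars = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        assert len(chars.taxon_namespace) == matrix.shape[0]
        assert chars.max_sequence_size == matrix.shape[1]

    def test_distances_block_round_trip(self, tmp_path):
        mat = _matrix({"a": [1, 1, 0], "b": [1, 0, 1], "c": [0, 1, 1]})
        dist = gene_content_distance(mat)
        path = tmp_path / "dist.nex"
        export_nexus(dist, path)
        text = path.read_text()
        assert "BEGIN DISTANCES;" in text
        assert f"NTAX={len(dist)}" in text

    def test_taxa_collision_rejected(self):
        mat = pd.DataFrame([[1, 0], [0, 1]], index=["same", "same"])
        with pytest.raises(ValueError, match="collision"):
            export_nexus(mat, "/dev/null")


class TestNjTree:
    def test_three_taxon_star_is_additive(self):
        # all pairwise distances 0.5: the NJ tree must reproduce them
        # exactly as patristic distances (each unrooted pendant = 0.25)
        dist = pd.DataFrame(
            [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        newick = nj_tree(dist)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x in "abc":
            for y in "abc":
                if x != y:
                    assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(0.5)
        # the two leaves joined first carry the canonical 0.25 pendants
        lengths = sorted(leaf.edge.length for leaf in tree.leaf_node_iter())
        assert lengths[-2:] == [pytest.approx(0.25), pytest.approx(0.25)]

    def test_additive_distances_recover_topology(self):
        # quartet ((a,b),(c,d)) with internal branch 0.3
        tree0 = dendropy.Tree.get(data="((a:0.1,b:0.2):0.3,(c:0.15,d:0.25):0.0);", schema="newick")
        pdm = tree0.phylogenetic_distance_matrix()
        taxa = sorted(pdm.taxon_namespace, key=lambda t: t.label)
        dist = pd.DataFrame(
            [[pdm.distance(t1, t2) for t2 in taxa] for t1 in taxa],
            index=[t.label for t in taxa],
            columns=[t.label for t in taxa],
        )
        newick = nj_tree(dist)
        tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=dendropy.TaxonNamespace())
        ab = frozenset({"a", "b"})
        splits = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        }
        assert ab in splits or frozenset({"c", "d"}) in splits

    def test_no_negative_branch_lengths(self, sim_matrix):
        _, _, matrix = sim_matrix
        newick = nj_tree(gene_content_distance(matrix))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        for edge in tree.preorder_edge_iter():
            assert edge.length is None or edge.length >= 0


class TestRepresentativeMatrix:
    def _assignment(self, sim_matrix):
        genomes, phams, _ = sim_matrix
        from phamlin.nucleotide_compare import ani_matrix

        _, pairs = ani_matrix(genomes)
        return assign_clusters([g.id for g in genomes], pairs)

    def test_one_row_per_cluster_plus_singletons(self, sim_matrix):
        genomes, phams, _ = sim_matrix
        asg = self._assignment(sim_matrix)
        rep = representative_matrix(asg, phams, genomes)
        assert len(rep) == len(asg.clusters) + len(asg.singletons)

    def test_default_representative_is_largest_and_override_honored(self, sim_matrix):
        genomes, phams, _ = sim_matrix
        asg = self._assignment(sim_matrix)
        label, members = next(iter(asg.clusters.items()))
        by_id = {g.id: g for g in genomes}
        largest = max(members, key=lambda gid: (len(by_id[gid].sequence), gid))
        rep = representative_matrix(asg, phams, genomes)
        assert largest in rep.index
        other = next(m for m in members if m != largest)
        rep2 = representative_matrix(asg, phams, genomes, overrides={label: other})
        assert other in rep2.index and largest not in rep2.index
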