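import math

import numpy as np
import pytest
from skbio import TreeNode

from eprvscan import syngen
from eprvscan.phylo import (
    AgeEstimate,
    DistanceMatrix,
    assign_otu,
    assign_otu_clade,
    bootstrap_support,
    min_age,
    nj_tree,
    pairwise_distances,
    poisson_distance,
    sequence_distance,
    tree_splits,
)
from eprvscan.refdata import DivergenceTable, HostTaxonomy

from oracles import random_additive_tree


def make_host(species, genus=None, **kw):
    genus = genus or species.split()[0]
    defaults = dict(family="F", order="O", class_="C", kingdom="Plantae")
    defaults.update(kw)
    return HostTaxonomy(species=species, genus=genus, **defaults)


class TestDistances:
    def test_poisson_closed_form_at_ten_percent(self):
        assert poisson_distance(0.10) == pytest.approx(0.10536, abs=1e-5)

    def test_exact_count_mutant_pair(self, library, rng):
        base = library[0].aa_seq[:300]
        mutant = syngen.mutate_protein(base, 30, rng)  # p = 0.10 over 300 columns
        assert sequence_distance(base, mutant) == pytest.approx(-math.log(0.9), abs=1e-9)

    def test_identical_pair_distance_zero(self, library):
        assert sequence_distance(library[0].aa_seq, library[0].aa_seq) == 0.0

    def test_symmetry_over_random_pairs(self, library, rng):
        seqs = [r.aa_seq for r in library]
        for _ in range(50):
            i, j = rng.integers(0, len(seqs), size=2)
            assert sequence_distance(seqs[i], seqs[j]) == sequence_distance(seqs[j], seqs[i])

    def test_saturation_clamp(self):
        assert poisson_distance(0.99) == pytest.approx(-math.log(0.05))

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_pairwise_distances_requires_two(self, library):
        with pytest.raises(ValueError):
            pairwise_distances([("a", library[0].aa_seq)])


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxa_additive_recovery(self):
        # tree: (a:2, b:3)---1---(c:4, d:5)
        d = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        tree = nj_tree(dm)
        tt = tree.tip_tip_distances(endpoints=["a", "b", "c", "d"])
        recovered = np.array(tt.data)
        assert np.allclose(recovered, d, atol=1e-9)
        assert tree_splits(tree) == {frozenset({"c", "d"})}

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_random_additive_trees_recovered(self, n):
        rng = np.random.default_rng(n)
        labels, d, true_splits = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(labels, d))
        tt = tree.tip_tip_distances(endpoints=labels)
        assert np.allclose(np.array(tt.data), d, atol=1e-9)
        assert tree_splits(tree) == true_splits

    def test_agrees_with_skbio_nj(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        labels, d, _ = random_additive_tree(6, rng)
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        assert tree_splits(ours) == tree_splits(theirs)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])))


class TestBootstrap:
    def _two_clades(self, rng):
        base_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        base_b = syngen.mutate_protein(base_a, 80, rng)  # 40% between clades
        items = []
        for i in range(4):
            items.append((f"a{i}", syngen.mutate_protein(base_a, 4, rng)))
            items.append((f"b{i}", syngen.mutate_protein(base_b, 4, rng)))
        return items

    def test_separating_split_strongly_supported(self, rng):
        tree = bootstrap_support(self._two_clades(rng), n_reps=100, seed=5)
        split = frozenset({"b0", "b1", "b2", "b3"})
        supports = {
            frozenset(t.name for t in node.tips()): int(node.name)
            for node in tree.non_tips(include_self=False)
            if node.name is not None
        }
        universe = frozenset(n for n, _ in self._two_clades(np.random.default_rng(0)))
        value = supports.get(split) or supports.get(universe - split)
        assert value is not None and value >= 95

    def test_single_replicate_supports_are_binary(self, rng):
        tree = bootstrap_support(self._two_clades(rng), n_reps=1, seed=6)
        for node in tree.non_tips(include_self=False):
            if node.name is not None:
                assert int(node.name) in (0, 100)

    def test_reproducible_under_seed(self, rng):
        items = self._two_clades(rng)
        t1 = bootstrap_support(items, n_reps=20, seed=9)
        t2 = bootstrap_support(items, n_reps=20, seed=9)
        assert str(t1) == str(t2)

    def test_invalid_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "MK"), ("b", "MK")], n_reps=0)


class TestAssignOtu:
    def test_exact_reference_copy(self, library):
        ref = library[50]
        a = assign_otu("x", ref.aa_seq, library)
        assert a.otu == ref.otu
        assert a.support == pytest.approx(1.0)
        assert a.distance == 0.0

    def test_mutated_florendovirus_recovered(self, library, rng):
        ref = next(r for r in library if r.otu == "Florendovirus")
        pep = syngen.mutate_protein(ref.aa_seq, 17, rng)  # 5% divergence
        assert assign_otu("x", pep, library).otu == "Florendovirus"

    def test_random_peptides_unclassified(self, library, rng):
        for _ in range(10):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
            assert assign_otu("x", pep, library).otu == "unclassified"

    def test_clade_method_on_exact_copy(self, library):
        subset = [r for r in library if r.otu in ("Badnavirus", "Petuvirus", "Tekay")][:9]
        ref = subset[0]
        a = assign_otu_clade("x", ref.aa_seq, subset)
        assert a.method == "clade"
        assert a.otu == ref.otu

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            assign_otu("x", "M" * 300, [])


class TestMinAge:
    def test_single_genus_cluster_age_zero(self):
        hosts = [make_host("Dioscorea alata"), make_host("Dioscorea rotundata")]
        est = min_age("c1", hosts, DivergenceTable())
        assert est.age_my == 0.0 or est.flagged is False
        # same genus: both species pairs resolve through genus self-pair = 0
        assert est.age_my == 0.0

    def test_singleton_cluster_age_zero(self):
        est = min_age("c1", [make_host("Olea europaea")], DivergenceTable())
        assert est.age_my == 0.0
        assert est.species_pair == ("Olea", "Olea")

    def test_most_distant_pair_wins(self):
        table = DivergenceTable()
        table.add("Dioscorea", "Amborella", 191)
        table.add("Dioscorea", "Musa", 117)
        table.add("Amborella", "Musa", 191)
        hosts = [make_host("Dioscorea alata"), make_host("Amborella trichopoda"),
                 make_host("Musa acuminata")]
        est = min_age("c1", hosts, table)
        assert est.age_my == 191
        assert est.species_pair == ("Amborella", "Dioscorea")  # first in sorted order
        assert est.rank_used == "genus"

    def test_invariant_to_duplicates_and_order(self):
        table = DivergenceTable()
        table.add("Dioscorea", "Amborella", 191)
        a, b = make_host("Dioscorea alata"), make_host("Amborella trichopoda")
        e1 = min_age("c", [a, b], table)
        e2 = min_age("c", [b, a, a, b, b], table)
        assert (e1.age_my, e1.species_pair) == (e2.age_my, e2.species_pair)

    def test_species_rank_fallback(self):
        table = DivergenceTable()
        table.add("Olea europaea", "Musa acuminata", 150)
        est = min_age("c", [make_host("Olea europaea"), make_host("Musa acuminata")], table)
        assert est.age_my == 150
        assert est.rank_used == "species"

    def test_unresolvable_pair_flagged(self):
        table = DivergenceTable()
        table.add("Olea", "Musa", 150)
        hosts = [make_host("Olea europaea"), make_host("Musa acuminata"),
                 make_host("Zea mays")]
        est = min_age("c", hosts, table)
        assert est.flagged
        assert len(est.unresolved) == 2
        assert est.age_my == 150  # resolvable part still reported

    def test_no_hosts_rejected(self):
        with pytest.raises(ValueError):
            min_age("c", [], DivergenceTable())
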