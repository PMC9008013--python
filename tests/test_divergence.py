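import itertools

import dendropy
import numpy as np
import pytest

from conftest import random_seq
from oracles import p_distance_oracle

from cenfuse.core import NucSequence
from cenfuse.divergence import (
    DistanceMatrix,
    SubstitutionSpectrum,
    classify_substitution,
    distance_matrix,
    nj_tree,
    p_distance,
    round_pct,
    saturation_analysis,
    substitution_spectrum,
)
from cenfuse.simulate import mutate, simulate_divergence_ladder, simulate_monomer


class TestClassify:
    def test_transition(self):
        assert classify_substitution("A", "G") == "transition"

    def test_transversion(self):
        assert classify_substitution("C", "A") == "transversion"

    def test_all_12_pairs_symmetric(self):
        for a, b in itertools.permutations("ACGT", 2):
            assert classify_substitution(a, b) == classify_substitution(b, a)

    def test_same_base_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "N")


class TestSpectrum:
    def test_paper_proportions_from_counts(self):
        spec = SubstitutionSpectrum.from_counts(34, 71)
        assert spec.n_substitutions == 105
        assert spec.prop_transitions == 32.38
        assert spec.prop_transversions == 67.62

    def test_identical_sequences_sentinel(self):
        spec = substitution_spectrum("ACGT", "ACGT")
        assert spec.n_substitutions == 0
        assert spec.prop_transitions == 0.0 and spec.prop_transversions == 0.0

    def test_toy_alignment_column_enumeration(self):
        # columns: match, match, G/A ts, match, deletion, match, C/G tv
        spec = substitution_spectrum("ACGT-AC", "ACATTAG")
        assert spec.n_deletions == 1
        assert spec.n_substitutions == 2
        assert spec.n_transitions == 1
        assert spec.n_transversions == 1
        assert spec.pair_counts == {"A/G": 1, "C/G": 1}
        assert spec.n_sites_compared == 6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            substitution_spectrum("ACGT", "ACG")

    def test_column_accounting_invariant(self, rng):
        for _ in range(20):
            n = 60
            a = list(random_seq(rng, n))
            b = list(random_seq(rng, n))
            for p in rng.choice(n, size=5, replace=False):
                (a if rng.random() < 0.5 else b)[int(p)] = "-"
            a, b = "".join(a), "".join(b)
            spec = substitution_spectrum(a, b)
            identical = sum(
                1 for x, y in zip(a, b) if x == y and x != "-"
            )
            assert (
                spec.n_transitions + spec.n_transversions + identical + spec.n_deletions
                == len(a)
            )

    def test_proportions_sum_to_100(self, rng):
        for _ in range(20):
            a = random_seq(rng, 200)
            b, _ = mutate(a, 0.2, 1.5, rng)
            spec = substitution_spectrum(a, b)
            if spec.n_substitutions:
                assert abs(spec.prop_transitions + spec.prop_transversions - 100.0) <= 0.01

    def test_pair_counts_sum_to_class_totals(self, rng):
        a = random_seq(rng, 500)
        b, _ = mutate(a, 0.1, 2.0, rng)
        spec = substitution_spectrum(a, b)
        ts = spec.pair_counts.get("A/G", 0) + spec.pair_counts.get("C/T", 0)
        tv = sum(v for k, v in spec.pair_counts.items() if k not in ("A/G", "C/T"))
        assert ts == spec.n_transitions and tv == spec.n_transversions


def test_round_pct_half_up():
    assert round_pct(67.615) == 67.62
    assert round_pct(32.380952) == 32.38
    assert round_pct(2.005) == 2.01


class TestPDistance:
    def test_identical_zero(self, rng):
        s = NucSequence("a", random_seq(rng, 100))
        assert p_distance(s, NucSequence("b", s.seq)) == 0.0

    def test_two_differences_in_ten(self):
        a = NucSequence("a", "ACGTACGTAC")
        b = NucSequence("b", "ACGAACGTAT")
        assert p_distance(a, b) == pytest.approx(0.2)

    def test_symmetric(self, rng):
        a = NucSequence("a", random_seq(rng, 80))
        b = NucSequence("b", random_seq(rng, 85))
        assert p_distance(a, b) == pytest.approx(p_distance(b, a))

    def test_matches_planted_rate(self, rng):
        # equal-length, substitution-only pairs: estimate within 3 binomial SE
        rate = 0.05
        n = 1000
        estimates = []
        for _ in range(30):
            a = random_seq(rng, n)
            b, records = mutate(a, rate, 2.0, rng)
            estimates.append(p_distance(NucSequence("a", a), NucSequence("b", b)))
        se = np.sqrt(rate * (1 - rate) / n) / np.sqrt(30)
        assert abs(np.mean(estimates) - rate) <= 3 * se

    def test_matches_oracle_on_gap_free_pairs(self, rng):
        a = random_seq(rng, 300)
        b, _ = mutate(a, 0.08, 2.0, rng)
        assert p_distance(NucSequence("a", a), NucSequence("b", b)) == pytest.approx(
            p_distance_oracle(a, b)
        )


class TestDistanceMatrix:
    def test_invariants(self, rng):
        seqs = [NucSequence(f"s{i}", random_seq(rng, 60)) for i in range(4)]
        d = distance_matrix(seqs)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0)
        assert (d.matrix >= 0).all()

    def test_matches_per_pair(self, rng):
        seqs = [NucSequence(f"s{i}", random_seq(rng, 60)) for i in range(3)]
        d = distance_matrix(seqs)
        for i, j in itertools.combinations(range(3), 2):
            assert d.matrix[i, j] == pytest.approx(p_distance(seqs[i], seqs[j]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _patristic(newick: str) -> dict[frozenset, float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


class TestNJ:
    def test_four_taxon_additive_exact(self):
        labels = ["A", "B", "C", "D"]
        # unrooted tree: leaf edges 1, internal edge 2
        m = np.array(
            [
                [0, 2, 4, 4],
                [2, 0, 4, 4],
                [4, 4, 0, 2],
                [4, 4, 2, 0],
            ],
            dtype=float,
        )
        newick = nj_tree(DistanceMatrix(labels, m))
        got = _patristic(newick)
        for i, j in itertools.combinations(range(4), 2):
            assert got[frozenset((labels[i], labels[j]))] == pytest.approx(m[i, j], abs=1e-12)

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        newick = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        got = _patristic(newick)
        assert got[frozenset(("a", "b"))] == pytest.approx(3)
        assert got[frozenset(("a", "c"))] == pytest.approx(5)
        assert got[frozenset(("b", "c"))] == pytest.approx(4)

    def test_five_taxon_additive_exact(self):
        # caterpillar ((A:1,B:2):1,(C:3,(D:1,E:2):2):1) as an unrooted metric
        labels = ["A", "B", "C", "D", "E"]
        m = np.array(
            [
                [0, 3, 6, 6, 7],
                [3, 0, 7, 7, 8],
                [6, 7, 0, 6, 7],
                [6, 7, 6, 0, 3],
                [7, 8, 7, 3, 0],
            ],
            dtype=float,
        )
        newick = nj_tree(DistanceMatrix(labels, m))
        got = _patristic(newick)
        for i, j in itertools.combinations(range(5), 2):
            assert got[frozenset((labels[i], labels[j]))] == pytest.approx(m[i, j], abs=1e-12)

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_all_labels_present_once(self, rng):
        seqs = [NucSequence(f"s{i}", random_seq(rng, 50)) for i in range(6)]
        newick = nj_tree(distance_matrix(seqs))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == [f"s{i}" for i in range(6)]

    def test_label_sanitization(self):
        m = np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]], dtype=float)
        newick = nj_tree(DistanceMatrix(["a 1", "b\t2", "c"], m))
        assert "a_1" in newick and "b_2" in newick

    def test_simulated_source_monophyly(self, rng):
        from cenfuse.simulate import BlockSpec, SimConfig, simulate_array

        ok = 0
        reps = 20
        for seed in range(reps):
            cfg = SimConfig(
                blocks=(BlockSpec(3, "+", 0.0), BlockSpec(3, "+", 0.25), BlockSpec(3, "+", 0.5)),
                monomer_length=120,
                intra_block_divergence=0.02,
                insertion_length_range=(0, 0),
                flank_length=0,
                seed=seed,
            )
            _, truth = simulate_array(cfg)
            seqs = [
                NucSequence(f"b{m.block_id}m{i}", m.seq)
                for i, m in enumerate(truth.monomers)
            ]
            newick = nj_tree(distance_matrix(seqs))
            tree = dendropy.Tree.get(data=newick, schema="newick")
            tree.encode_bipartitions()
            splits = {
                frozenset(taxon.label for taxon in edge.bipartition.leafset_taxa(tree.taxon_namespace))
                for edge in tree.bipartition_edge_map.values()
            }
            all_labels = {s.id for s in seqs}
            good = True
            for b in range(3):
                group = frozenset(l for l in all_labels if l.startswith(f"b{b}"))
                if group not in splits and frozenset(all_labels - group) not in splits:
                    good = False
            ok += good
        assert ok / reps >= 0.95


class TestSaturation:
    def test_high_divergence_tv_saturated(self):
        seqs = simulate_divergence_ladder(2500, 8, 0.09, 2, ts_tv_ratio=0.1, seed=0)
        rep = saturation_analysis(seqs)
        assert rep.tv_saturated
        assert not rep.ts_saturated

    def test_low_divergence_nothing_saturated(self):
        seqs = simulate_divergence_ladder(4000, 5, 0.001, 2, ts_tv_ratio=0.5, seed=1)
        rep = saturation_analysis(seqs)
        assert not rep.ts_saturated and not rep.tv_saturated

    def test_identical_input_zero_slopes(self, rng):
        s = random_seq(rng, 200)
        seqs = [NucSequence(f"s{i}", s) for i in range(4)]
        rep = saturation_analysis(seqs)
        assert rep.ts_slope == 0.0 and rep.tv_slope == 0.0
        assert not rep.ts_saturated and not rep.tv_saturated

    def test_too_few_sequences(self, rng):
        seqs = [NucSequence(f"s{i}", random_seq(rng, 50)) for i in range(3)]
        with pytest.raises(ValueError):
            saturation_analysis(seqs)

    def test_pair_table_shape(self):
        seqs = simulate_divergence_ladder(400, 4, 0.02, 1, 2.0, seed=3)
        rep = saturation_analysis(seqs)
        assert len(rep.pair_table) == 10
        assert set(rep.pair_table.columns) >= {"p_distance", "ts_count", "tv_count"}
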