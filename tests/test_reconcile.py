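"""DTL reconciliation: worked examples, brute-force agreement, invariants."""

import random

import numpy as np
import pytest

from hgtrecon import (DTLCosts, extract_transfers, parse_newick, prune_to_taxa,
                      reconcile_rooted, reconcile_unrooted, unrooted_rf)

import dtl_oracle
from conftest import nested_to_tree, random_nested


def rooted(nested):
    return nested_to_tree(nested, rooted=True)


class TestWorkedExamples:
    def test_congruent_tree_costs_nothing(self):
        st = rooted((("A", "B"), ("C", "D")))
        rec = reconcile_rooted(rooted((("A", "B"), ("C", "D"))), st)
        assert rec.total_cost == 0
        assert rec.n_transfer == rec.n_duplication == rec.n_loss == 0
        assert set(rec.events.values()) <= {"speciation"}
        assert extract_transfers(rec) == []

    def test_single_transfer_example(self):
        st = rooted((("A", "B"), ("C", "D")))
        rec = reconcile_rooted(rooted((("A", "C"), "B")), st)
        assert rec.total_cost == 3
        assert rec.n_transfer == 1
        oracle = dtl_oracle.min_cost_rooted((("A", "C"), "B"),
                                            (("A", "B"), ("C", "D")))
        assert rec.total_cost == oracle
        (t,) = rec.transfers
        assert not (t.donor <= t.recipient or t.recipient <= t.donor)

    def test_root_duplication_example(self):
        st = rooted(("A", "B"))
        rec = reconcile_rooted(rooted((("A", "B"), ("A", "B"))), st)
        assert rec.total_cost == 2
        assert rec.n_duplication == 1
        assert rec.n_transfer == 0 and rec.n_loss == 0

    def test_leaves_map_to_their_species(self):
        st = rooted((("A", "B"), ("C", "D")))
        rec = reconcile_rooted(rooted((("A", "C"), "B")), st)
        for gid, leaves in rec.gene_leafsets.items():
            if len(leaves) == 1:
                assert rec.mapping[gid] == leaves


class TestBruteForceAgreement:
    @pytest.mark.parametrize("trial", range(40))
    def test_random_pairs_match_oracle(self, trial):
        rng = random.Random(1000 + trial)
        n = rng.randint(3, 5)
        labels = [f"L{i}" for i in range(n)]
        st_nested = random_nested(rng, labels)
        gt_labels = [rng.choice(labels) for _ in range(rng.randint(3, 5))]
        gt_nested = random_nested(rng, gt_labels)
        rec = reconcile_rooted(rooted(gt_nested), rooted(st_nested))
        oracle = dtl_oracle.min_cost_rooted(gt_nested, st_nested)
        assert rec.total_cost == pytest.approx(oracle)
        # cost identity under default costs
        assert rec.total_cost == pytest.approx(
            2 * rec.n_duplication + 3 * rec.n_transfer + rec.n_loss)

    @pytest.mark.parametrize("trial", range(4))
    def test_six_leaf_pairs_match_oracle(self, trial):
        rng = random.Random(7000 + trial)
        labels = [f"L{i}" for i in range(6)]
        st_nested = random_nested(rng, labels)
        gt_nested = random_nested(rng, list(labels))
        rec = reconcile_rooted(rooted(gt_nested), rooted(st_nested))
        assert rec.total_cost == pytest.approx(
            dtl_oracle.min_cost_rooted(gt_nested, st_nested))

    @pytest.mark.parametrize("trial", range(10))
    def test_nondefault_costs_match_oracle(self, trial):
        rng = random.Random(3000 + trial)
        labels = [f"L{i}" for i in range(4)]
        st_nested = random_nested(rng, labels)
        gt_nested = random_nested(rng, list(labels))
        d, t, l = rng.choice([(1, 1, 1), (5, 2, 1), (2, 10, 0.5)])
        rec = reconcile_rooted(rooted(gt_nested), rooted(st_nested),
                               DTLCosts(d, t, l))
        assert rec.total_cost == pytest.approx(
            dtl_oracle.min_cost_rooted(gt_nested, st_nested, d, t, l))


class TestUnrooted:
    @pytest.mark.parametrize("trial", range(15))
    def test_min_over_rootings_matches_oracle(self, trial):
        rng = random.Random(500 + trial)
        labels = [f"L{i}" for i in range(rng.randint(4, 5))]
        st_nested = random_nested(rng, labels)
        gt_nested = random_nested(rng, list(labels))
        gt = nested_to_tree(gt_nested, rooted=False)
        rec = reconcile_unrooted(gt, rooted(st_nested), seed=trial)
        assert rec.total_cost == pytest.approx(
            dtl_oracle.min_cost_unrooted(gt_nested, st_nested))

    def test_rooting_count(self):
        gt = nested_to_tree((("A", "B"), ("C", "D")), rooted=False)
        st = rooted((("A", "B"), ("C", "D")))
        rec = reconcile_unrooted(gt, st, seed=0)
        assert rec.n_rootings == 5  # 2n-3 edges of a 4-leaf unrooted tree

    def test_congruent_rooting_found(self):
        st = rooted((("A", "B"), ("C", "D")))
        gt = nested_to_tree((("A", "B"), ("C", "D")), rooted=False)
        rec = reconcile_unrooted(gt, st, seed=3)
        assert rec.total_cost == 0

    def test_seed_determinism(self):
        st = rooted((("A", "B"), ("C", "D")))
        gt = nested_to_tree((("A", "C"), ("B", "D")), rooted=False)
        r1 = reconcile_unrooted(gt, st, seed=42)
        r2 = reconcile_unrooted(gt, st, seed=42)
        assert r1.total_cost == r2.total_cost
        assert [ (t.donor, t.recipient) for t in r1.transfers ] == \
               [ (t.donor, t.recipient) for t in r2.transfers ]
        r3 = reconcile_unrooted(gt, st, seed=43)
        assert r3.total_cost == r1.total_cost  # cost invariant to seed


class TestInvariants:
    def test_cost_zero_iff_congruent(self):
        # the pipeline always prunes the species tree to the family's taxa;
        # against that pruned tree, cost is 0 exactly when the gene tree is
        # the homeomorphic restriction of the species tree
        rng = random.Random(9)
        labels = [f"L{i}" for i in range(6)]
        st = rooted(random_nested(rng, labels))
        for _ in range(15):
            sub = random.Random(rng.random()).sample(labels, 4)
            pruned = prune_to_taxa(st, sub)
            assert reconcile_rooted(pruned, pruned).total_cost == 0
            gt = rooted(random_nested(rng, list(sub)))
            rec = reconcile_rooted(gt, pruned)
            if unrooted_rf(gt, pruned) > 0:
                assert rec.total_cost > 0
            # rooted congruence against the pruned tree itself
        congruent = prune_to_taxa(st, labels[:4])
        assert reconcile_rooted(congruent, congruent).total_cost == 0

    @pytest.mark.parametrize("trial", range(10))
    def test_transfer_cost_monotonicity(self, trial):
        rng = random.Random(77 + trial)
        labels = [f"L{i}" for i in range(5)]
        st = rooted(random_nested(rng, labels))
        gt = rooted(random_nested(rng, list(labels)))
        costs = [reconcile_rooted(gt, st, DTLCosts(2, t, 1)).total_cost
                 for t in (1, 2, 3, 5, 10)]
        assert costs == sorted(costs)

    def test_infinite_transfer_cost_yields_duplication_loss_optimum(self):
        rng = random.Random(13)
        labels = [f"L{i}" for i in range(5)]
        st = rooted(random_nested(rng, labels))
        gt = rooted(random_nested(rng, list(labels)))
        rec = reconcile_rooted(gt, st, DTLCosts(2, 1e9, 1))
        assert rec.n_transfer == 0

    @pytest.mark.parametrize("trial", range(20))
    def test_donor_recipient_incomparable(self, trial):
        rng = random.Random(210 + trial)
        labels = [f"L{i}" for i in range(6)]
        st = rooted(random_nested(rng, labels))
        gt = nested_to_tree(random_nested(rng, list(labels)), rooted=False)
        rec = reconcile_unrooted(gt, st, seed=trial)
        for t in rec.transfers:
            assert not t.donor <= t.recipient
            assert not t.recipient <= t.donor

    def test_event_preference_speciation_first(self):
        # a congruent tree admits an all-speciation optimum; the backtrack
        # must choose it over cost-equivalent alternatives
        st = rooted(((("A", "B"), "C"), "D"))
        rec = reconcile_rooted(rooted(((("A", "B"), "C"), "D")), st)
        assert set(rec.events.values()) == {"speciation"}
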