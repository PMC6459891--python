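"""HGT indices, ratios, strata, identity, FTG/RTG, widespread/core/markers."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hgtrecon import (compare_groups, gene_hgt_index, genome_hgt_index,
                      hgt_ratio, marker_candidates, select_ftg, select_rtg,
                      stratify_event, transfer_pair_identity, widespread_genes)
from hgtrecon.classify import annotate_transfer
from hgtrecon.genesets import GeneSet, GeneSetMember
from hgtrecon.reconcile import TransferRecord
from hgtrecon.stats import (build_gene_profiles, build_genome_profiles,
                            core_genes, genome_participation)

from test_genesets import make_set


def make_event(set_id, donor, recipient, meta, scope="mixed"):
    return annotate_transfer(
        TransferRecord("g0", frozenset(donor), frozenset(recipient)),
        set_id, scope, meta)


class TestGeneIndex:
    @pytest.mark.parametrize("events,taxa,expected", [
        (383, 1030, 0.37),
        (0, 10, 0.0),
        (5, 10, 0.5),
    ])
    def test_values(self, events, taxa, expected):
        assert round(gene_hgt_index(events, taxa), 2) == expected

    def test_zero_taxa_error(self):
        with pytest.raises(ValueError):
            gene_hgt_index(1, 0)


class TestGenomeIndex:
    def test_uninvolved_genome_is_zero(self, meta6):
        assert genome_hgt_index("gF", [], meta6) == 0.0

    def test_hand_counted_participation(self, meta6):
        # gA is an endpoint descendant in sets s1 and s2 (of 4), gA has 100 genes
        events = [
            make_event("s1", {"gA"}, {"gC"}, meta6),
            make_event("s2", {"gA", "gB"}, {"gD"}, meta6),
            make_event("s3", {"gE"}, {"gF"}, meta6),
            make_event("s3", {"gE"}, {"gF"}, meta6),   # same set twice
        ]
        part = genome_participation(events)
        assert part["gA"] == {"s1", "s2"}
        assert part["gE"] == {"s3"}
        assert genome_hgt_index("gA", events, meta6) == pytest.approx(2 / 100)
        assert genome_hgt_index("gE", events, meta6) == pytest.approx(1 / 90)

    def test_profiles_frame(self, meta6):
        events = [make_event("s1", {"gA"}, {"gC"}, meta6)]
        prof = build_genome_profiles(events, meta6).set_index("genome_id")
        assert prof.loc["gA", "n_hgt_genes"] == 1
        assert prof.loc["gB", "n_hgt_genes"] == 0
        assert ((prof["hgt_index"] >= 0) & (prof["hgt_index"] <= 1)).all()


class TestHgtRatio:
    def test_ratios_sum_to_one_random_profiles(self):
        rng = random.Random(3)
        for _ in range(100):
            counts = [rng.randint(0, 10) for _ in range(3)]
            if sum(counts) == 0:
                counts[0] = 1
            prof = {"n_events": sum(counts), "one_to_one": counts[0],
                    "one_to_many": counts[1], "many_to_many": counts[2]}
            total = sum(hgt_ratio(prof, c) for c in
                        ("one_to_one", "one_to_many", "many_to_many"))
            assert abs(total - 1.0) < 1e-12

    def test_all_one_to_one(self):
        prof = {"n_events": 4, "one_to_one": 4, "one_to_many": 0,
                "many_to_many": 0}
        assert hgt_ratio(prof, "one_to_one") == 1.0

    def test_zero_events_undefined(self):
        prof = {"n_events": 0, "one_to_one": 0, "one_to_many": 0,
                "many_to_many": 0}
        with pytest.raises(ValueError):
            hgt_ratio(prof, "one_to_one")


class TestStratify:
    def test_strata(self, meta6):
        # gA,gB,gC share genus X; gD,gE,gF genus Y
        ps_sh = make_event("s", {"gA"}, {"gB"}, meta6)       # same genus, same site
        assert stratify_event(ps_sh) == ("PS", "SH")
        ps_dh = make_event("s", {"gA"}, {"gC"}, meta6)       # same genus, diff site
        assert stratify_event(ps_dh) == ("PS", "DH")
        pd_sh = make_event("s", {"gA"}, {"gD"}, meta6)       # diff genus, same site
        assert stratify_event(pd_sh) == ("PD", "SH")
        mixed_clade = make_event("s", {"gA", "gD"}, {"gB"}, meta6)
        assert stratify_event(mixed_clade)[0] == "PD"


class TestTransferPairIdentity:
    def test_identical_sequences(self, meta6):
        gs = make_set("s", ["gA", "gC"], seqs={"gA": "MKLV", "gC": "MKLV"})
        ev = make_event("s", {"gA"}, {"gC"}, meta6)
        assert transfer_pair_identity(ev, gs) == 100.0

    def test_one_mismatch_in_four(self, meta6):
        gs = make_set("s", ["gA", "gC"], seqs={"gA": "MKLV", "gC": "MKLA"})
        ev = make_event("s", {"gA"}, {"gC"}, meta6)
        assert transfer_pair_identity(ev, gs) == 75.0

    def test_mean_over_clade_pairs(self, meta6):
        seqs = {"gA": "AAAA", "gB": "AAAT", "gC": "AATT", "gD": "ATTT"}
        gs = make_set("s", list(seqs), seqs=seqs)
        ev = make_event("s", {"gA", "gB"}, {"gC", "gD"}, meta6)
        # pairs: A-C 50, A-D 25, B-C 75, B-D 50 -> mean 50
        assert transfer_pair_identity(ev, gs) == pytest.approx(50.0)

    def test_missing_sequence_errors(self, meta6):
        gs = make_set("s", ["gA", "gC"])
        ev = make_event("s", {"gA"}, {"gC"}, meta6)
        with pytest.raises(ValueError):
            transfer_pair_identity(ev, gs)


def profiles_from_indices(indices, **extra):
    rows = []
    for i, x in enumerate(indices):
        rows.append({"gene_set_id": f"s{i:03d}", "hgt_index": x,
                     "n_taxa": extra.get("n_taxa", 10),
                     "n_events": extra.get("n_events", 5),
                     "n_genera": extra.get("n_genera", 5),
                     "one_to_one_ratio": extra.get("ratio", 0.5)})
    return pd.DataFrame(rows)


class TestFTG:
    def test_ten_distinct_returns_max(self):
        prof = profiles_from_indices([0.1 * i for i in range(10)])
        assert select_ftg(prof) == ["s009"]

    def test_boundary_ties_included(self):
        vals = [0.1] * 17 + [0.5, 0.5, 0.5]   # n=20, k=2, cutoff 0.5 tied x3
        prof = profiles_from_indices(vals)
        assert len(select_ftg(prof)) == 3

    def test_uniform_degenerate_returns_all(self):
        prof = profiles_from_indices([0.3] * 12)
        assert len(select_ftg(prof)) == 12

    def test_size_between_decile_and_ties(self):
        rng = random.Random(8)
        vals = [round(rng.random(), 3) for _ in range(50)]
        prof = profiles_from_indices(vals)
        out = select_ftg(prof)
        assert 5 <= len(out) <= 5 + vals.count(sorted(vals, reverse=True)[4])


class TestRTG:
    def test_small_sets_filtered(self):
        prof = pd.concat([
            profiles_from_indices([0.5], n_events=4),            # <5 events
            profiles_from_indices([0.5], n_events=12, n_genera=4),  # <5 genera
            profiles_from_indices([0.5], n_taxa=9),              # <10 genomes
        ], ignore_index=True)
        prof["gene_set_id"] = ["a", "b", "c"]
        assert select_rtg(prof).empty

    def test_ranking_by_one_to_one_ratio(self):
        # the two worked families: 5/6 one-to-one outranks 8/12
        rows = []
        for sid, (k, n) in {"high": (5, 6), "low": (8, 12)}.items():
            rows.append({"gene_set_id": sid, "n_taxa": 12, "n_events": n,
                         "n_genera": 6, "hgt_index": n / 12,
                         "one_to_one_ratio": k / n})
        for i in range(18):   # filler to make the decile meaningful
            rows.append({"gene_set_id": f"f{i}", "n_taxa": 12, "n_events": 10,
                         "n_genera": 6, "hgt_index": 0.1,
                         "one_to_one_ratio": 0.1})
        out = select_rtg(pd.DataFrame(rows))
        assert list(out["gene_set_id"][:2]) == ["high", "low"]
        assert out["one_to_one_ratio"].is_monotonic_decreasing


class TestWidespreadCoreMarkers:
    def test_strict_threshold(self, meta6):
        # GI has 3 genomes (gA,gB,gD): presence 3/3 > 0.7 but 2/3 <= 0.7 is ok
        full = make_set("full", ["gA", "gB", "gD"])
        partial = make_set("partial", ["gA", "gB"])
        out = widespread_genes([full, partial], meta6, ["GI"])
        assert out == ["full"]   # 2/3 = 0.667 is not > 0.7

    def test_pooled_combination(self, meta6):
        # GI+oral pool = gA,gB,gD,gC,gF (5 genomes); 4/5 = 0.8 > 0.7
        gs = make_set("x", ["gA", "gB", "gC", "gD"])
        assert widespread_genes([gs], meta6, ["GI", "oral"]) == ["x"]

    def test_empty_sites_error(self, meta6):
        with pytest.raises(ValueError):
            widespread_genes([], meta6, [])

    def test_core_pools_all_genomes(self, meta6):
        allg = make_set("core", list(meta6.genome_ids))
        some = make_set("some", ["gA", "gB", "gC", "gD"])  # 4/6 < 0.7
        assert core_genes([allg, some], meta6) == ["core"]

    def test_marker_boundaries(self, meta6):
        sets = [make_set("m", list(meta6.genome_ids)),
                make_set("hot", list(meta6.genome_ids))]
        prof = pd.DataFrame([
            {"gene_set_id": "m", "hgt_index": 0.1},
            {"gene_set_id": "hot", "hgt_index": 0.2},   # not strictly < 0.2
        ])
        assert marker_candidates(prof, sets, meta6) == ["m"]


class TestCompareGroups:
    def test_identical_groups_rank_sum(self):
        p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        assert compare_groups(a, b) < 1e-3
        assert compare_groups(a, b, test="welch_t") < 1e-3

    def test_exact_u_against_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        p = compare_groups(a, b)
        # enumerate all 20 label assignments of the pooled sample
        pooled = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x > y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in ga for y in gb if x > y)
            total += 1
            if abs(u - 4.5) >= abs(u_obs - 4.5):   # two-sided around mean U
                count += 1
        assert p == pytest.approx(count / total)

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestSimulationMonotonicity:
    def test_higher_transfer_rate_raises_mean_gene_index(self):
        """Families simulated at a higher transfer rate show a higher mean
        gene HGT-index after reconciliation (paired families, sign test)."""
        from hgtrecon import (HGTAnalysis, SimulationConfig, simulate_dataset)

        res = {}
        for tau in (0.1, 0.8):
            cfg = SimulationConfig(n_leaves=12, n_families=40, seed=21,
                                   duplication_rate=0.0, transfer_rate=tau,
                                   loss_rate=0.0, n_sites=3)
            ds = simulate_dataset(cfg)
            fit = HGTAnalysis.from_dataset(ds).fit(seed=4)
            res[tau] = fit.gene_profiles["hgt_index"].mean()
        assert res[0.8] > res[0.1]
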