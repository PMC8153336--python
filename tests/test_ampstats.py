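import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from clampkit.ampstats import (
    APICOMPLEXA_CODE_BOOK,
    CommunityCountTable,
    DetectionTable,
    alpha_diversity_table,
    detection_summary,
    enrichment_table,
    enrichment_value,
    faith_pd,
    load_apicomplexa_detections,
    nonhost_proportion,
    observed_asvs,
    pairwise_prop_test,
    relative_intensity,
    shannon,
    top_taxa,
)
from clampkit.fixtures import HOST_LINEAGE_PREFIX, FixtureSpec, make_count_table


class TestProportions:
    def test_simple_fraction(self):
        counts = {"Host;A": 90, "Host;B": 7, "Fungi;X": 2, "SAR;Y": 1}
        assert nonhost_proportion(counts, "Host") == pytest.approx(0.03)

    def test_all_host(self):
        assert nonhost_proportion({"Host;A": 10}, "Host") == 0.0

    def test_empty_sample_is_nan(self):
        assert math.isnan(nonhost_proportion({"Host;A": 0, "Fungi;X": 0}, "Host"))


class TestEnrichmentValue:
    def test_identity(self):
        assert enrichment_value(0.03, 0.03) == pytest.approx(1.0)

    def test_ratio(self):
        assert enrichment_value(0.031, 0.0003) == pytest.approx(103.3333, rel=1e-4)

    def test_zero_control_is_nan(self):
        assert math.isnan(enrichment_value(0.05, 0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment_value(1.5, 0.1)


@pytest.fixture(scope="module")
def table_truth():
    return make_count_table(FixtureSpec(seed=11))


class TestEnrichmentTable:
    def test_recovers_generator_targets(self, table_truth):
        table, truth = table_truth
        df = enrichment_table(table, HOST_LINEAGE_PREFIX)
        kept = df[~df["excluded"]]
        for method, expected in truth["expected_enrichment"].items():
            vals = kept[kept["method"] == method]["enrichment"]
            # targets are exact multiples of 1/total_reads, so recovery is exact
            assert np.allclose(vals, expected)

    def test_zero_control_samples_flagged(self, table_truth):
        table, truth = table_truth
        df = enrichment_table(table, HOST_LINEAGE_PREFIX)
        zero = truth["zero_control_tick"]
        flagged = df[df["tick_id"] == zero]
        n_methods = len(truth["method_nonhost"]) - 1  # all but the control itself
        assert len(flagged) == n_methods
        assert flagged["excluded"].all()
        assert (flagged["reason"] == "control sample has no non-host reads").all()
        assert flagged["enrichment"].isna().all()
        assert not df[df["tick_id"] != zero]["excluded"].any()

    def test_validation(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["Host;A", "Fungi;X"])
        meta = pd.DataFrame({"tick_id": ["t1"], "method": ["PNA"]}, index=["s1"])
        with pytest.raises(ValueError, match="control"):
            CommunityCountTable(counts=counts, meta=meta)
        with pytest.raises(ValueError, match="metadata"):
            CommunityCountTable(counts=counts, meta=pd.DataFrame(index=[]))
        with pytest.raises(ValueError, match="non-negative"):
            CommunityCountTable(
                counts=pd.DataFrame({"s1": [-1]}, index=["Host;A"]),
                meta=pd.DataFrame({"tick_id": ["t1"], "method": ["control"]},
                                  index=["s1"]))


def yates_chi2_p(a, b, c, d):
    """Literal textbook Yates-corrected chi-square on [[a, b], [c, d]]."""
    n = a + b + c + d
    # the continuity correction never moves past the expected value
    num = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return float(sstats.chi2.sf(num / den, df=1))


class TestPairwisePropTest:
    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            t1, t2 = int(rng.integers(20, 500)), int(rng.integers(20, 500))
            s1, s2 = int(rng.integers(1, t1)), int(rng.integers(1, t2))
            mat = pairwise_prop_test({"a": s1, "b": s2}, {"a": t1, "b": t2},
                                     correction="none")
            assert mat.loc["a", "b"] == pytest.approx(
                yates_chi2_p(s1, t1 - s1, s2, t2 - s2), rel=1e-9)

    def test_bonferroni_multiplies_by_pair_count(self):
        succ = {"a": 10, "b": 20, "c": 30}
        tot = {"a": 100, "b": 100, "c": 100}
        raw = pairwise_prop_test(succ, tot, correction="none")
        adj = pairwise_prop_test(succ, tot, correction="bonferroni")
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):  # m = 3 pairs
            assert adj.loc[x, y] == pytest.approx(min(1.0, 3 * raw.loc[x, y]))

    def test_symmetric_with_nan_diagonal(self):
        mat = pairwise_prop_test({"a": 5, "b": 9}, {"a": 50, "b": 40})
        assert mat.loc["a", "b"] == mat.loc["b", "a"]
        assert math.isnan(mat.loc["a", "a"]) and math.isnan(mat.loc["b", "b"])

    def test_identical_proportions(self):
        mat = pairwise_prop_test({"a": 10, "b": 10}, {"a": 100, "b": 100},
                                 correction="none")
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_total_group_not_evaluable(self):
        mat = pairwise_prop_test({"a": 10, "b": 0}, {"a": 100, "b": 0})
        assert math.isnan(mat.loc["a", "b"])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pairwise_prop_test({"a": 10}, {"a": 5})
        with pytest.raises(ValueError):
            pairwise_prop_test({"a": 1}, {"a": 10}, correction="fdr")


class TestShannonObserved:
    def test_uniform_k_equals_ln_k(self):
        for k in (2, 4, 10):
            assert shannon([25] * k) == pytest.approx(math.log(k))

    def test_single_taxon_zero(self):
        assert shannon({"x": 100}) == 0.0

    def test_empty_is_nan(self):
        assert math.isnan(shannon([0, 0]))

    def test_matches_formula(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=8)
            if counts.sum() == 0:
                continue
            p = counts[counts > 0] / counts.sum()
            assert shannon(counts) == pytest.approx(-(p * np.log(p)).sum())

    def test_observed_asvs(self):
        assert observed_asvs({"a": 3, "b": 0, "c": 1}) == 2
        assert observed_asvs([]) == 0


TREE_NEWICK = "((A:1,B:2):3,(C:4,D:5):6):0;"


def _tree():
    return dendropy.Tree.get(data=TREE_NEWICK, schema="newick")


def oracle_faith_pd(present, tree, include_root):
    """Independent computation: sum edges subtending >=1 present tip, optionally
    restricted to proper descendants of the present tips' MRCA."""
    present = set(present)
    if not present:
        return 0.0
    taxa = [t for t in tree.taxon_namespace if t.label in present]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else next(
        l for l in tree.leaf_node_iter() if l.taxon.label in present)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        tips = {l.taxon.label for l in node.leaf_iter()}
        if not (tips & present):
            continue
        if not include_root:
            # keep only edges strictly below the MRCA
            anc = node.parent_node
            while anc is not None and anc is not mrca:
                anc = anc.parent_node
            if anc is None:
                continue
        total += node.edge.length or 0.0
    return total


class TestFaithPd:
    def test_single_tip_rooted(self):
        assert faith_pd(["A"], _tree()) == pytest.approx(4.0)  # 1 + 3 to the root

    def test_single_tip_unrooted_is_zero(self):
        assert faith_pd(["A"], _tree(), include_root=False) == 0.0

    def test_cherry(self):
        assert faith_pd(["A", "B"], _tree()) == pytest.approx(6.0)
        assert faith_pd(["A", "B"], _tree(), include_root=False) == pytest.approx(3.0)

    def test_spanning_pair(self):
        assert faith_pd(["A", "C"], _tree()) == pytest.approx(14.0)
        assert faith_pd(["A", "C"], _tree(), include_root=False) == pytest.approx(14.0)

    def test_empty_and_unknown(self):
        assert faith_pd([], _tree()) == 0.0
        with pytest.raises(ValueError, match="Z"):
            faith_pd(["Z"], _tree())

    def test_unit_star_tree_counts_tips(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1,E:1):0;", schema="newick")
        for k, tips in enumerate((["A"], ["A", "B"], ["A", "B", "E"]), start=1):
            assert faith_pd(tips, star) == pytest.approx(k)

    def test_matches_independent_traversal(self, rng):
        import random as pyrandom

        labels = list("ABCDEFGH")
        for _ in range(100):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                rng=pyrandom.Random(int(rng.integers(2**31))))
            for i, leaf in enumerate(tree.leaf_node_iter()):
                leaf.taxon.label = labels[i]
            k = int(rng.integers(1, 9))
            present = list(rng.choice(labels, size=k, replace=False))
            for include_root in (True, False):
                assert faith_pd(present, tree, include_root) == pytest.approx(
                    oracle_faith_pd(present, tree, include_root))

    def test_monotone_in_tip_set(self):
        tree = _tree()
        assert faith_pd(["A"], tree) <= faith_pd(["A", "B"], tree) \
            <= faith_pd(["A", "B", "C"], tree) <= faith_pd(list("ABCD"), tree)


def test_alpha_diversity_table():
    counts = pd.DataFrame(
        {"s1_control": [10, 10, 10, 10], "s1_PNA": [40, 0, 0, 0]},
        index=["A", "B", "C", "D"])
    meta = pd.DataFrame(
        {"tick_id": ["t1", "t1"], "method": ["control", "PNA"]},
        index=["s1_control", "s1_PNA"])
    table = CommunityCountTable(counts=counts, meta=meta)
    tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1):0;", schema="newick")
    df = alpha_diversity_table(table, tree)
    assert df.loc["s1_control", "shannon"] == pytest.approx(math.log(4))
    assert df.loc["s1_control", "observed_asvs"] == 4
    assert df.loc["s1_control", "faith_pd"] == pytest.approx(4.0)
    assert df.loc["s1_PNA", "observed_asvs"] == 1


class TestRelativeIntensity:
    def test_control_normalised_to_one(self):
        values = pd.DataFrame(
            {"0uM": [100.0, 200.0, 150.0], "2uM": [50.0, 100.0, 75.0]},
            index=["trial1", "trial2", "trial3"])
        out = relative_intensity(values, "0uM")
        assert out.loc["0uM", "mean"] == pytest.approx(1.0)
        assert out.loc["0uM", "sd"] == pytest.approx(0.0)
        assert out.loc["2uM", "mean"] == pytest.approx(0.5)
        assert (out["n"] == 3).all()

    def test_zero_control_trial_flagged_and_dropped(self):
        values = pd.DataFrame(
            {"0uM": [100.0, 0.0], "2uM": [60.0, 30.0]}, index=["ok", "bad"])
        out = relative_intensity(values, "0uM")
        assert out.attrs["flagged_trials"] == ["bad"]
        assert out.loc["2uM", "mean"] == pytest.approx(0.6)
        assert (out["n"] == 1).all()

    def test_all_controls_zero(self):
        values = pd.DataFrame({"0uM": [0.0], "2uM": [5.0]}, index=["t"])
        with pytest.raises(ValueError):
            relative_intensity(values, "0uM")

    def test_unknown_control_dose(self):
        values = pd.DataFrame({"2uM": [5.0]}, index=["t"])
        with pytest.raises(ValueError):
            relative_intensity(values, "0uM")


class TestDetectionGrid:
    def test_packaged_grid_shape(self):
        table = load_apicomplexa_detections()
        assert table.grid.shape == (17, 6)

    def test_summary_counts(self):
        summary = detection_summary(load_apicomplexa_detections())
        assert summary["G"] == 3
        for code in ("A", "Cr", "T", "N", "EU", "Co"):
            assert summary[code] == 1

    def test_gregarina_prevalence(self):
        table = load_apicomplexa_detections()
        summary = detection_summary(table)
        assert summary["G"] / len(table.grid) == pytest.approx(3 / 17)

    def test_permutation_invariance(self, rng):
        table = load_apicomplexa_detections()
        base = detection_summary(table)
        rows = list(rng.permutation(table.grid.index))
        cols = list(rng.permutation(table.grid.columns))
        shuffled = DetectionTable(grid=table.grid.loc[rows, cols])
        assert detection_summary(shuffled).equals(base)

    def test_unknown_code_rejected(self):
        grid = pd.DataFrame({"m1": [frozenset({"ZZ"})]}, index=["s1"])
        with pytest.raises(ValueError, match="ZZ"):
            DetectionTable(grid=grid)

    def test_tsv_parsing(self, tmp_path):
        p = tmp_path / "grid.tsv"
        p.write_text("sample\tm1\tm2\ns1\tG, T\t-\ns2\t\tCr\n")
        table = DetectionTable.from_tsv(p)
        assert table.grid.loc["s1", "m1"] == frozenset({"G", "T"})
        assert table.grid.loc["s1", "m2"] == frozenset()
        assert detection_summary(table)["Cr"] == 1

    def test_code_book_is_documented(self):
        assert APICOMPLEXA_CODE_BOOK["G"] == "Gregarina"
        assert len(APICOMPLEXA_CODE_BOOK) == 6 + 1


class TestTopTaxa:
    def test_exclusion_and_order(self):
        abundances = {
            "Host;Acari;Ixodes": 900.0,
            "Fungi;Asco": 50.0,
            "SAR;Gregarina": 30.0,
            "Unclassified;x": 15.0,
            "SAR;Colpoda": 5.0,
        }
        out = top_taxa(abundances, 2, exclude=("Host", "Unclassified"))
        assert list(out.index) == ["Fungi;Asco", "SAR;Gregarina"]

    def test_ties_break_lexicographically(self):
        out = top_taxa({"b": 1.0, "a": 1.0, "c": 2.0}, 3)
        assert list(out.index) == ["c", "a", "b"]

    def test_n_exceeds_available(self):
        assert len(top_taxa({"a": 1.0}, 5)) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            top_taxa({"a": -1.0}, 1)
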