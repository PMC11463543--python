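import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import endolyso as el


def make_ann(compartments, tm=1, cm=True):
    return pd.DataFrame({
        "compartments": [frozenset(c) for c in compartments],
        "tm_count": tm,
        "cell_membrane": cm,
        "gene_sets": [frozenset()] * len(compartments),
        "domains": [frozenset()] * len(compartments),
        "families": [frozenset()] * len(compartments),
    }, index=[f"p{i}" for i in range(len(compartments))])


def make_enrichment(lfc):
    return pd.DataFrame({"log2FC": lfc}, index=[f"p{i}" for i in range(len(lfc))])


def sort_quartiles(vals):
    """Independent sort-based quartiles with linear interpolation."""
    x = np.sort(np.asarray(vals, dtype=float))
    out = []
    for f in (0.25, 0.5, 0.75):
        h = (len(x) - 1) * f
        lo = int(np.floor(h))
        hi = min(lo + 1, len(x) - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return out


class TestCompartmentSummary:
    def test_single_compartment_single_record(self):
        enr = make_enrichment([1.0, 2.0, 3.0])
        ann = make_ann([{"lysosome"}] * 3)
        out = el.compartment_summary(enr, ann)
        assert len(out) == 1
        assert out.iloc[0]["count"] == 3

    def test_multilabel_contributes_to_each(self):
        enr = make_enrichment([1.0, 3.0])
        ann = make_ann([{"lysosome", "endosome"}, {"endosome"}])
        out = el.compartment_summary(enr, ann).set_index("compartment")
        assert out.at["lysosome", "count"] == 1
        assert out.at["endosome", "count"] == 2
        assert out.at["endosome", "mean_log2FC"] == pytest.approx(2.0)

    def test_zero_noise_lysosomal_mean_exact(self):
        cfg = el.SimConfig(n_proteins=150, noise_sd=1e-9, seed=13)
        matrix, design, truth = el.simulate_ip_experiment(cfg)
        res = el.EnrichmentModel(matrix, design, stratum=("lyso", "iNeuron")).fit()
        ann = el.simulate_annotations(truth)
        out = el.compartment_summary(res.table, ann).set_index("compartment")
        assert out.at["lysosome", "mean_log2FC"] == pytest.approx(2.5, abs=1e-6)

    def test_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=1000)
        enr = make_enrichment(vals)
        ann = make_ann([{"endosome"}] * 1000)
        row = el.compartment_summary(enr, ann).iloc[0]
        q1, med, q3 = sort_quartiles(vals)
        assert row["q1"] == pytest.approx(q1)
        assert row["median"] == pytest.approx(med)
        assert row["q3"] == pytest.approx(q3)


class TestOverlapSets:
    def test_identical_sets(self):
        out = el.overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts == {"A&B": 2, "A": 0, "B": 0}

    def test_disjoint_sets(self):
        out = el.overlap_sets({"A": {"x"}, "B": {"y"}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts["A&B"] == 0
        assert counts["A"] == 1 and counts["B"] == 1

    def test_more_than_three_sets_fatal(self):
        with pytest.raises(ValueError):
            el.overlap_sets({c: {c} for c in "ABCD"})

    def test_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(15)
        universe = [f"e{i}" for i in range(60)]
        for _ in range(20):
            sets = {n: set(rng.choice(universe, size=rng.integers(0, 40),
                                      replace=False)) for n in "ABC"}
            out = el.overlap_sets(sets)
            counts = dict(zip(out["region"], out["count"]))
            # brute force: classify every element of the union by membership
            brute = {}
            for e in set().union(*sets.values()):
                key = "&".join(n for n in "ABC" if e in sets[n])
                brute[key] = brute.get(key, 0) + 1
            for region, c in counts.items():
                assert brute.get(region, 0) == c
            assert sum(counts.values()) == len(set().union(*sets.values()))


class TestStateSelectivity:
    def test_all_equal(self):
        out = el.classify_state_selectivity({"a", "b"}, {"a": 0.0, "b": 0.0})
        assert out["proportions"]["equal"] == 1.0

    def test_direct_application(self):
        ratios = {"a": 2.0, "b": -2.0, "c": 0.0, "d": 0.0}
        out = el.classify_state_selectivity(set(ratios), ratios, tau=1.0)
        assert out["proportions"] == {"higher": 0.25, "equal": 0.5, "lower": 0.25}

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(16)
        ratios = {f"p{i}": float(r) for i, r in enumerate(rng.normal(size=50))}
        out = el.classify_state_selectivity(set(ratios), ratios)
        assert sum(out["proportions"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_unquantified_bin_and_coverage(self):
        ratios = {f"p{i}": 0.0 for i in range(8)}
        out = el.classify_state_selectivity(set(ratios) | {"p8", "p9"}, ratios)
        assert out["n_unquantified"] == 2
        with pytest.raises(ValueError, match="80%"):
            el.classify_state_selectivity({"a", "b", "c", "d", "e"}, {"a": 1.0})

    def test_empty_selective_fatal(self):
        with pytest.raises(ValueError):
            el.classify_state_selectivity(set(), {})


class TestGenesetEnrichment:
    def test_zero_overlap_p_is_one(self):
        universe = {f"p{i}" for i in range(10)}
        coll = el.GeneSetCollection(sets={"s": frozenset()})
        out = el.geneset_enrichment({"p0"}, universe, coll)
        assert out.iloc[0]["p"] == 1.0

    def test_hand_enumerated_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"p{i}" for i in range(10)}
        members = frozenset({f"p{i}" for i in range(5)})
        fg = {f"p{i}" for i in range(4)}
        out = el.geneset_enrichment(fg, universe, el.GeneSetCollection(sets={"s": members}))
        assert out.iloc[0]["p"] == pytest.approx(5 / 210)

    def test_matches_exhaustive_enumeration(self):
        """P[X >= k] equals direct enumeration of all C(N, n) draws, N <= 12."""
        rng = np.random.default_rng(17)
        for _ in range(15):
            N = int(rng.integers(4, 13))
            universe = [f"p{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            members = frozenset(rng.choice(universe, size=K, replace=False))
            fg = set(rng.choice(universe, size=n, replace=False))
            k = len(members & fg)
            out = el.geneset_enrichment(
                fg, set(universe), el.GeneSetCollection(sets={"s": members}))
            hits = sum(1 for draw in itertools.combinations(universe, n)
                       if len(members & set(draw)) >= k)
            total = sum(1 for _ in itertools.combinations(universe, n))
            assert out.iloc[0]["p"] == pytest.approx(hits / total)

    def test_p_monotone_decreasing_in_k(self):
        N, K, n = 40, 12, 10
        ps = [float(stats.hypergeom.sf(k - 1, N, K, n)) for k in range(0, n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_foreground_outside_universe_fatal(self):
        with pytest.raises(ValueError, match="universe"):
            el.geneset_enrichment({"x"}, {"y"}, el.GeneSetCollection(sets={}))
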