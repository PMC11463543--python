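import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import endolyso as el
from endolyso.enrichment import D0_MAX, fit_variance_prior
from tests.conftest import log2_matrix


def brute_force_bh(p):
    """O(n^2) step-up BH: q_i = min over thresholds t >= p_i of n*t/#{p <= t}."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    q = np.empty(n)
    for i in range(n):
        cands = [n * p[j] / np.sum(p <= p[j]) for j in range(n) if p[j] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q


class TestNormalize:
    def test_identical_columns_noop_up_to_transform(self, small_design):
        vals = np.tile(np.array([[4.0], [16.0], [64.0]]), (1, 6))
        m = el.IntensityMatrix(
            values=pd.DataFrame(vals, index=["a", "b", "c"],
                                columns=small_design.channels),
            design=small_design)
        out = el.normalize_log2(m)
        assert np.allclose(out.values, np.log2(vals))

    def test_constant_channel_scaling_removed(self, small_design):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.lognormal(10, 1, size=(50, 6)),
                            index=[f"p{i}" for i in range(50)],
                            columns=small_design.channels)
        scaled = vals.copy()
        scaled["tagged_2"] *= 8.0
        a = el.normalize_log2(el.IntensityMatrix(values=vals, design=small_design))
        b = el.normalize_log2(el.IntensityMatrix(values=scaled, design=small_design))
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_channel_medians_equal_grand_median(self, ip_sim):
        _, matrix, _, _ = ip_sim
        out = el.normalize_log2(matrix, scope="global")
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.median(), atol=1e-9)

    def test_group_medians_equal_group_grand_median(self, ip_sim):
        _, matrix, design, _ = ip_sim
        out = el.normalize_log2(matrix)
        medians = out.values.median(axis=0)
        groups = design.frame.groupby(["ip_type", "cell_state", "condition"])
        for _, grp in groups:
            med = medians[grp["channel"]]
            assert np.allclose(med, med.median(), atol=1e-9)

    def test_all_missing_channel_fatal(self, small_design):
        vals = pd.DataFrame(np.ones((5, 6)), index=[f"p{i}" for i in range(5)],
                            columns=small_design.channels)
        vals["control_1"] = np.nan
        with pytest.raises(ValueError, match="control_1"):
            el.normalize_log2(el.IntensityMatrix(values=vals, design=small_design))


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = el.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_equal_p_unchanged(self):
        q = el.bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = rng.random(rng.integers(1, 40))
            if rng.random() < 0.5:
                p = np.round(p, 1)  # force ties
            assert np.allclose(el.bh_adjust(p), brute_force_bh(p))

    def test_missing_propagates(self):
        q = el.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], brute_force_bh([0.01, 0.04]))

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            el.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p_and_is_monotone(self, p):
        p = np.asarray(p)
        q = el.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEBayes:
    def test_equal_variances_degenerate_prior(self):
        s2 = np.full(100, 0.09)
        m = fit_variance_prior(s2, np.full(100, 4.0))
        assert m.infinite
        assert abs(m.s0_sq - 0.09) < 1e-6

    def test_parameter_recovery_from_scaled_f(self):
        rng = np.random.default_rng(7)
        s2 = 0.09 * rng.f(4, 4, size=2000)
        m = fit_variance_prior(s2, np.full(2000, 4.0))
        assert 2.5 <= m.d0 <= 6.5
        assert abs(m.s0_sq - 0.09) / 0.09 < 0.20

    def test_fit_invariant_to_protein_order(self, ip_sim):
        _, matrix, design, _ = ip_sim
        log2m = el.normalize_log2(matrix)
        a = el.fit_ebayes(log2m, design, ("endo", "iNeuron"))
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(log2m.values))
        shuffled = el.IntensityMatrix(values=log2m.values.iloc[perm],
                                      design=design, log2=True)
        b = el.fit_ebayes(shuffled, design, ("endo", "iNeuron"))
        assert np.isclose(a.s0_sq, b.s0_sq)
        assert (a.infinite and b.infinite) or np.isclose(a.d0, b.d0)

    def test_few_proteins_falls_back_to_median(self, small_design, caplog):
        rng = np.random.default_rng(3)
        m = log2_matrix(rng.normal(20, 1, size=(10, 6)), small_design)
        with caplog.at_level("WARNING"):
            prior = el.fit_ebayes(m, small_design)
        assert prior.infinite
        assert "falling back" in caplog.text


class TestModeratedTest:
    def test_closed_form_single_protein(self, small_design):
        # tagged (8,8,8) vs control (4,4,4), d0 = inf with known s0^2
        m = log2_matrix([[8, 8, 8, 4, 4, 4]], small_design)
        model = el.EBayesModel(d0=np.inf, s0_sq=0.25)
        cfg = el.RunConfig(lfc_cutoff=1.0, q_cutoff=0.01)
        out = el.test_enrichment(m, small_design, model, cfg)
        row = out.iloc[0]
        assert row["log2FC"] == pytest.approx(4.0)
        t_expected = 4.0 / np.sqrt(0.25 * (1 / 3 + 1 / 3))
        assert row["t_mod"] == pytest.approx(t_expected)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(t_expected))
        assert bool(row["enriched"])

    def test_d0_zero_reduces_to_ordinary_t(self, small_design):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, size=(40, 6))
        m = log2_matrix(vals, small_design)
        model = el.EBayesModel(d0=0.0, s0_sq=1.0)
        out = el.test_enrichment(m, small_design, model, el.RunConfig())
        t_ref, p_ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1)
        assert np.allclose(out["t_mod"], t_ref)
        assert np.allclose(out["p"], p_ref)

    def test_underobserved_protein_untested(self, small_design):
        vals = np.full((25, 6), 20.0) + np.random.default_rng(5).normal(0, 1, (25, 6))
        m = log2_matrix(vals, small_design)
        m.values.iloc[0, [0, 1]] = np.nan  # only one tagged value left
        prior = el.fit_ebayes(m, small_design)
        out = el.test_enrichment(m, small_design, prior, el.RunConfig())
        assert np.isnan(out.iloc[0]["p"])
        assert not bool(out.iloc[0]["enriched"])

    def test_zero_noise_perfect_separation(self):
        cfg = el.SimConfig(n_proteins=150, noise_sd=1e-9, seed=12, ip_types=("endo",))
        matrix, design, truth = el.simulate_ip_experiment(cfg)
        res = el.EnrichmentModel(matrix).fit()
        truly = set(truth.proteins.index[truth.proteins["true_lfc_endo"] >= 1.0])
        assert res.enriched == truly

    def test_calls_monotone_in_cutoffs(self, ip_sim):
        _, matrix, design, _ = ip_sim
        model = el.EnrichmentModel(matrix, design, stratum=("endo", "iNeuron"))
        loose = model.fit(lfc_cutoff=1.0, q_cutoff=0.05).enriched
        tight_lfc = model.fit(lfc_cutoff=1.5, q_cutoff=0.05).enriched
        tight_q = model.fit(lfc_cutoff=1.0, q_cutoff=0.001).enriched
        assert tight_lfc <= loose
        assert tight_q <= loose

    def test_q_dominates_p(self, endo_results):
        t = endo_results.table.dropna(subset=["p"])
        assert (t["q"] >= t["p"] - 1e-12).all()

    def test_summary_mentions_counts(self, endo_results):
        text = endo_results.summary()
        assert str(endo_results.n_enriched) in text
        assert "endo" in text


class TestReplicateComparison:
    def test_identity_comparison(self, endo_results):
        rep = el.compare_replicate_datasets(endo_results.table, endo_results.table)
        assert rep["jaccard"] == 1.0
        assert rep["pearson_r"] == pytest.approx(1.0)

    def test_disjoint_proteins_warns_with_zeros(self, endo_results, caplog):
        other = endo_results.table.copy()
        other.index = ["X" + p for p in other.index]
        with caplog.at_level("WARNING"):
            rep = el.compare_replicate_datasets(endo_results.table, other)
        assert rep["n_shared"] == 0
        assert np.isnan(rep["pearson_r"])

    def test_independent_measurements_reproducible(self):
        """Two noise realizations of one truth give r >= 0.9 at default noise."""
        cfg = el.SimConfig(n_proteins=500, ip_types=("endo",), seed=11)
        m1, _, _ = el.simulate_ip_experiment(cfg, noise_seed=21)
        m2, _, _ = el.simulate_ip_experiment(cfg, noise_seed=22)
        r1 = el.EnrichmentModel(m1).fit()
        r2 = el.EnrichmentModel(m2).fit()
        rep = el.compare_replicate_datasets(r1.table, r2.table)
        assert rep["pearson_r"] >= 0.9
        assert rep["jaccard"] >= 0.8
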