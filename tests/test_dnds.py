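import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from escapesel import dnds
from escapesel.dnds import (
    ContextRateModel,
    ImpactMatrix,
    bh_adjust,
    bootstrap_global_dnds,
    call_drivers,
    compare_group_dnds,
    fit_context_rates,
    gene_dnds,
    global_dnds,
)
from conftest import make_catalog


def toy_impact(L_syn, L_mis, L_non=0, gene_id="G1"):
    """Opportunities concentrated in class 0 (uniform-rate toy gene)."""
    L = np.zeros((192, 3), dtype=np.int64)
    L[0, 0], L[0, 1], L[0, 2] = L_syn, L_mis, L_non
    return ImpactMatrix(gene_id=gene_id, L=L)


def toy_catalog(n_syn, n_mis, n_non=0, gene_id="G1"):
    rows = []
    for cls, n in (("synonymous", n_syn), ("missense", n_mis), ("nonsense", n_non)):
        rows += [{"gene_id": gene_id, "variant_class": cls, "position": i} for i in range(n)]
    return make_catalog(rows)


def grid_loglik(n_s, n_k, E_s, E_k, w):
    """Independent oracle: profile log-likelihood by dense grid over t."""
    t = np.linspace(1e-6, 5 * (n_s + n_k) / E_s, 200001)
    mu_s, mu_k = t * E_s, np.outer(t, [1]).ravel() * E_k * w
    ll = n_s * np.log(mu_s) - mu_s + (n_k * np.log(mu_k) - mu_k if n_k or w else 0)
    return ll.max()


class TestGeneDnDs:
    def test_counting_estimator_under_uniform_rates(self):
        """w_mis = (n_mis/L_mis)/(n_syn/L_syn) exactly when rates are uniform."""
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(5, 30), rates, toy_impact(100, 200))
        assert res.w_mis == pytest.approx((30 / 200) / (5 / 100), abs=1e-8)
        assert res.w_mis == pytest.approx(3.0, abs=1e-8)

    def test_symmetric_counts_give_w_one(self):
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(10, 10), rates, toy_impact(150, 150))
        assert res.w_mis == pytest.approx(1.0, abs=1e-12)

    def test_zero_missense_boundary(self):
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(10, 0), rates, toy_impact(100, 200))
        assert res.w_mis == 0.0
        assert res.ci_mis[0] == 0.0
        assert res.ci_mis[1] > 0.0

    def test_lrt_agrees_with_grid_search_oracle(self):
        """The LRT statistic matches brute-force likelihood maximization."""
        n_s, n_m, L_s, L_m = 5, 30, 100, 200
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(n_s, n_m), rates, toy_impact(L_s, L_m))
        # alternative: maximize over (t, w) via grid on t at w-hat (profile exact)
        ll_alt = grid_loglik(n_s, n_m, L_s, L_m, res.w_mis)
        ll_null = grid_loglik(n_s, n_m, L_s, L_m, 1.0)
        stat_oracle = 2 * (ll_alt - ll_null)
        stat_impl = chi2.isf(res.p_mis, 1)
        assert stat_impl == pytest.approx(stat_oracle, abs=1e-6)

    def test_profile_ci_bounds_bracket_estimate(self):
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(20, 60, 5), rates, toy_impact(100, 200, 20))
        lo, hi = res.ci_mis
        assert lo < res.w_mis < hi
        # at the CI bound the profile log-likelihood drops by chi2(0.95,1)/2
        def pll(w):
            t = (20 + 60) / (100 + w * 200)
            return 20 * np.log(t * 100) - t * 100 + 60 * np.log(w * t * 200) - w * t * 200
        drop = pll(res.w_mis) - pll(lo)
        assert drop == pytest.approx(chi2.ppf(0.95, 1) / 2, abs=1e-6)

    def test_no_synonymous_flagged(self):
        rates = ContextRateModel.uniform()
        res = gene_dnds("G1", toy_catalog(0, 10), rates, toy_impact(100, 200))
        assert res.flagged and np.isnan(res.w_mis)

    def test_monotonicity_adding_missense_never_decreases_w(self):
        rates = ContextRateModel.uniform()
        prev = -1.0
        for n_mis in range(0, 40, 3):
            res = gene_dnds("G1", toy_catalog(8, n_mis), rates, toy_impact(120, 260))
            assert res.w_mis >= prev
            prev = res.w_mis


class TestGlobalDnDs:
    def test_single_gene_reduction_matches_pooled_gene_omega(self):
        rates = ContextRateModel.uniform()
        im = toy_impact(100, 200, 50)
        cat = toy_catalog(10, 25, 5)
        g = global_dnds(["G1"], cat, rates, {"G1": im})
        res = gene_dnds("G1", cat, rates, im)
        pooled = (res.n_mis + res.n_non) / (res.E_mis + res.E_non)
        assert g.w == pytest.approx(pooled, abs=1e-12)

    def test_duplicating_catalog_keeps_w_and_narrows_ci(self):
        rates = ContextRateModel.uniform()
        im = toy_impact(100, 200, 50)
        cat = toy_catalog(10, 25, 5)
        g1 = global_dnds(["G1"], cat, rates, {"G1": im})
        g2 = global_dnds(["G1"], pd.concat([cat, cat], ignore_index=True), rates, {"G1": im})
        assert g2.w == pytest.approx(g1.w, abs=1e-12)
        assert (g2.ci[1] - g2.ci[0]) < (g1.ci[1] - g1.ci[0])

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            global_dnds(["NOPE"], toy_catalog(1, 1), ContextRateModel.uniform(), {})


class TestContextRates:
    def test_uniform_channels_give_equal_rates(self, default_genome):
        """Flat-signature synonymous mutations yield near-equal context rates."""
        from escapesel.simulate import CohortSimConfig, simulate_cohort

        cfg = CohortSimConfig(
            seed=2, n_genes=50, driver_genes={}, escape_genes=(),
            hotspot_spec={}, n_patients_escape_pos=50, n_patients_escape_neg=50,
            tmb_mean_pos=700, tmb_mean_neg=700,
            signature_mix_pos=(0.0, 1.0, 0.0, 0.0), signature_mix_neg=(0.0, 1.0, 0.0, 0.0),
        )
        c = simulate_cohort(default_genome, cfg, seed=4)
        impacts = dnds.build_impact_matrices(default_genome.genes)
        rates = fit_context_rates(c.catalog, impacts, default_genome.genes)
        L_syn = sum(im.L[:, 0] for im in impacts.values()).astype(float)
        n_syn = rates.r * L_syn
        # flat channel mix: per-site rate should be flat; allow 3 SE binomial noise
        per_site = rates.r[L_syn > 0]
        mean = np.average(per_site, weights=L_syn[L_syn > 0])
        n_tot = n_syn.sum()
        ok = 0
        for r_s, L_s in zip(per_site, L_syn[L_syn > 0]):
            exp = mean * L_s
            se = np.sqrt(exp)
            ok += abs(r_s * L_s - exp) <= 3 * se + 1e-9
        assert ok / len(per_site) >= 0.95

    def test_single_channel_carries_all_mass(self):
        im = ImpactMatrix("G1", np.ones((192, 3), dtype=np.int64) * 200)
        cat = make_catalog(
            [
                {"gene_id": "G1", "variant_class": "synonymous", "context": "ACA",
                 "ref_allele": "C", "alt_allele": "T"}
            ]
            * 5
        )
        gm = type("GM", (), {"strand": "+"})()
        rates = fit_context_rates(cat, {"G1": im}, {"G1": gm})
        nz = np.nonzero(rates.r)[0]
        assert len(nz) == 1
        assert rates.r[nz[0]] * im.L[nz[0], 0] == pytest.approx(5.0)

    def test_scale_invariance_of_relative_rates(self, default_cohort, default_genome):
        impacts = dnds.build_impact_matrices(default_genome.genes)
        cat = default_cohort.catalog
        r1 = fit_context_rates(cat, impacts, default_genome.genes).r
        r2 = fit_context_rates(
            pd.concat([cat, cat], ignore_index=True), impacts, default_genome.genes
        ).r
        nz = r1 > 0
        ratio = r2[nz] / r1[nz]
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_no_synonymous_mutations_raises(self):
        cat = make_catalog([{"variant_class": "missense"}])
        with pytest.raises(ValueError, match="synonymous"):
            fit_context_rates(cat, {}, {})


class TestDriverCalling:
    def test_bh_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_significance_rule(self):
        df = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "w_mis": [2.0, 0.5, 1.5],
                "p_mis": [0.001, 0.0001, 0.8],
                "w_non": [1.0, 1.0, 1.0],
                "p_non": [0.9, 0.9, 0.9],
            }
        )
        out = call_drivers(df, q_threshold=0.1)
        sig = dict(zip(out["gene_id"], out["significant_mis"]))
        assert sig["A"] and not sig["B"] and not sig["C"]

    def test_olfactory_exclusion_happens_before_bh(self):
        df = pd.DataFrame(
            {
                "gene_id": ["OR2T1", "A", "B"],
                "w_mis": [3.0, 2.0, 2.0],
                "p_mis": [0.5, 0.03, 0.04],
                "w_non": [1.0] * 3,
                "p_non": [0.9] * 3,
            }
        )
        out = call_drivers(df, exclude_olfactory=True)
        assert "OR2T1" not in set(out["gene_id"])
        # BH over 2 genes instead of 3: q = {0.06, 0.04->...}
        qs = dict(zip(out["gene_id"], out["q_mis"]))
        assert qs["A"] == pytest.approx(0.04 * 2 / 2)  # 0.04 after step-up
        assert qs["B"] == pytest.approx(0.04)


class TestGroupComparison:
    def test_identical_replicates_give_p_one(self):
        v = np.linspace(1, 2, 50)
        p, ci_a, ci_b, sep = compare_group_dnds(v, v)
        assert p == 1.0 and not sep

    def test_fully_separated_replicates(self):
        a = np.linspace(1.0, 1.1, 200)
        b = np.linspace(2.0, 2.1, 200)
        p, ci_a, ci_b, sep = compare_group_dnds(a, b)
        assert p < 1e-10 and sep

    def test_normal_replicate_vectors_detectable(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.2, 0.05, 200)
        b = rng.normal(1.6, 0.05, 200)
        p, *_ = compare_group_dnds(a, b)
        assert p < 1e-10

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="20"):
            compare_group_dnds(np.ones(10), np.ones(10))

    def test_bootstrap_omega_centered_on_point_estimate(self, default_cohort, default_genome, truth_groups):
        impacts = dnds.build_impact_matrices(default_genome.genes)
        cat = default_cohort.catalog
        neg = cat[cat["patient_id"].map(truth_groups) == "escape_neg"]
        rates = fit_context_rates(neg, impacts, default_genome.genes)
        drivers = ["DRV1", "DRV2", "DRV3"]
        point = global_dnds(drivers, neg, rates, impacts).w
        reps = bootstrap_global_dnds(
            neg, neg["patient_id"].unique(), drivers, rates, impacts, B=100, seed=3
        )
        assert np.percentile(reps, 2.5) <= point <= np.percentile(reps, 97.5)
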