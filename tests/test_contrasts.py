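import numpy as np
import pandas as pd
import pytest

from escapesel import dnds
from escapesel.contrasts import (
    _chi2_2x2,
    downsample,
    exclude_hotspots,
    onc_tsg_proportions,
    random_escape_null,
    site_concentration_test,
    pooled_concentration_test,
    vaf_compare,
)
from escapesel.simulate import CohortSimConfig, simulate_cohort, simulate_genome
from conftest import make_catalog


def hand_pearson_chi2(table):
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return ((table - expected) ** 2 / expected).sum()


class TestChi2:
    def test_proportional_rows_give_zero(self):
        res = _chi2_2x2(np.array([[10, 5], [20, 10]]), (("a", "b"), ("x", "y")))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_hand_computed_pearson(self):
        table = np.array([[100, 10], [20, 15]])
        res = _chi2_2x2(table, (("a", "b"), ("x", "y")))
        assert res.chi2 == pytest.approx(hand_pearson_chi2(table), abs=1e-10)

    def test_zero_marginal_flagged(self):
        res = _chi2_2x2(np.array([[0, 0], [5, 5]]), (("a", "b"), ("x", "y")))
        assert res.flagged and np.isnan(res.p)


@pytest.fixture(scope="module")
def hotspot_sim():
    cfg = CohortSimConfig(
        seed=17,
        driver_genes={"DRV1": (5.0, 1.0)},
        hotspot_spec={"DRV1": (40, 0.9)},
        escape_genes=("ESC1",),
        n_patients_escape_pos=150,
        n_patients_escape_neg=150,
        tmb_mean_pos=150,
        tmb_mean_neg=150,
        n_genes=30,
    )
    genome = simulate_genome(cfg)
    cohort = simulate_cohort(genome, cfg, seed=18)
    t = cohort.truth["patients"]
    labels = pd.DataFrame({"patient_id": t["patient_id"], "status": t["group"]})
    return genome, cohort, labels


class TestSiteConcentration:
    def test_hotspot_gene_detected(self, hotspot_sim):
        genome, cohort, labels = hotspot_sim
        res, lolli = site_concentration_test(cohort.catalog, "DRV1", labels)
        assert res.p < 0.01
        # escape- piles mutations on fewer sites: mut/site ratio higher
        ratio_neg = res.table[0, 0] / res.table[0, 1]
        ratio_pos = res.table[1, 0] / res.table[1, 1]
        assert ratio_neg > ratio_pos
        assert {"status", "position", "count"} <= set(lolli.columns)

    def test_pooled_single_gene_reduces_to_per_gene(self, hotspot_sim):
        genome, cohort, labels = hotspot_sim
        res, _ = site_concentration_test(cohort.catalog, "DRV1", labels)
        pooled = pooled_concentration_test(cohort.catalog, ["DRV1"], labels)
        np.testing.assert_array_equal(res.table, pooled.table)
        assert pooled.chi2 == pytest.approx(res.chi2)

    def test_pooled_is_elementwise_sum(self, hotspot_sim):
        genome, cohort, labels = hotspot_sim
        t1, _ = site_concentration_test(cohort.catalog, "DRV1", labels)
        t2, _ = site_concentration_test(cohort.catalog, "G001", labels)
        pooled = pooled_concentration_test(cohort.catalog, ["DRV1", "G001"], labels)
        np.testing.assert_array_equal(pooled.table, t1.table + t2.table)

    def test_codon_unit_requires_models_and_coarsens_sites(self, hotspot_sim):
        genome, cohort, labels = hotspot_sim
        with pytest.raises(ValueError, match="gene_models"):
            site_concentration_test(cohort.catalog, "DRV1", labels, unit="codon")
        by_pos, _ = site_concentration_test(cohort.catalog, "DRV1", labels)
        by_codon, _ = site_concentration_test(
            cohort.catalog, "DRV1", labels, unit="codon", gene_models=genome.genes
        )
        assert (by_codon.table[:, 1] <= by_pos.table[:, 1]).all()


class TestExcludeHotspots:
    def test_hand_fixture_counts(self, hotspot_sim):
        genome, _, _ = hotspot_sim
        gm = genome.genes["DRV1"]
        hot = gm.codon_genomic_positions(12)
        other = [int(gm.genomic_of_cds(i)) for i in range(40, 47)]
        rows = [{"gene_id": "DRV1", "position": int(p)} for p in list(hot) + other]
        cat = make_catalog(rows)
        kept, removed = exclude_hotspots(cat, {"DRV1": [12]}, genome.genes)
        assert removed == 3 and len(kept) == 7

    def test_codon_13_retained(self, hotspot_sim):
        genome, _, _ = hotspot_sim
        gm = genome.genes["DRV1"]
        cat = make_catalog(
            [{"gene_id": "DRV1", "position": int(gm.codon_genomic_positions(13)[1])}]
        )
        kept, removed = exclude_hotspots(cat, {"DRV1": [12]}, genome.genes)
        assert removed == 0 and len(kept) == 1

    def test_hotspot_beyond_protein_rejected(self, hotspot_sim):
        genome, _, _ = hotspot_sim
        with pytest.raises(ValueError):
            exclude_hotspots(make_catalog([{}]), {"DRV1": [10**6]}, genome.genes)

    def test_exclusion_removes_concentration_signal(self, hotspot_sim):
        genome, cohort, labels = hotspot_sim
        before, _ = site_concentration_test(cohort.catalog, "DRV1", labels)
        kept, _ = exclude_hotspots(cohort.catalog, {"DRV1": [40]}, genome.genes)
        after, _ = site_concentration_test(kept, "DRV1", labels)
        assert before.p < 0.01 < after.p


class TestDownsample:
    def labels(self, n_neg=7, n_pos=2):
        return pd.DataFrame(
            {
                "patient_id": [f"N{i}" for i in range(n_neg)] + [f"P{i}" for i in range(n_pos)],
                "status": ["escape_neg"] * n_neg + ["escape_pos"] * n_pos,
            }
        )

    def catalog(self, labels):
        rows = [
            {"patient_id": p, "position": i}
            for p in labels["patient_id"]
            for i in range(3)
        ]
        return make_catalog(rows)

    def test_patient_downsampling_equalizes(self):
        labels = self.labels(700 // 100, 200 // 100)  # 7 vs 2
        cat = self.catalog(labels)
        red = downsample(cat, labels, target="patients", seed=1)
        lab = labels.set_index("patient_id")["status"]
        counts = red.drop_duplicates("patient_id")["patient_id"].map(lab).value_counts()
        assert counts["escape_neg"] == counts["escape_pos"] == 2

    def test_same_seed_same_sample(self):
        labels = self.labels()
        cat = self.catalog(labels)
        a = downsample(cat, labels, seed=5)
        b = downsample(cat, labels, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_mutation_downsampling_equalizes_counts(self):
        labels = self.labels(4, 2)
        cat = self.catalog(labels)
        red = downsample(cat, labels, target="mutations", seed=2)
        lab = labels.set_index("patient_id")["status"]
        counts = red["patient_id"].map(lab).value_counts()
        assert counts["escape_neg"] == counts["escape_pos"]


class TestOncTsg:
    def test_equal_counts_p_one(self):
        rows = []
        for gene, n in (("ONC", 10), ("TSG1", 10)):
            for grp, pid in (("escape_neg", "N"), ("escape_pos", "P")):
                rows += [{"patient_id": pid, "gene_id": gene}] * n
        cat = make_catalog(rows)
        labels = pd.DataFrame(
            {"patient_id": ["N", "P"], "status": ["escape_neg", "escape_pos"]}
        )
        res = onc_tsg_proportions(cat, labels, {"ONC": "oncogene", "TSG1": "TSG"})
        assert res.p == 1.0

    def test_hand_computed_chi2(self):
        rows = []
        for gene, counts in (("ONC", (80, 20)), ("TSG1", (50, 50))):
            for pid, n in zip(("N", "P"), counts):
                rows += [{"patient_id": pid, "gene_id": gene}] * n
        cat = make_catalog(rows)
        labels = pd.DataFrame(
            {"patient_id": ["N", "P"], "status": ["escape_neg", "escape_pos"]}
        )
        res = onc_tsg_proportions(cat, labels, {"ONC": "oncogene", "TSG1": "TSG"})
        assert res.chi2 == pytest.approx(
            hand_pearson_chi2([[80, 20], [50, 50]]), abs=1e-10
        )

    def test_empty_tsg_row_flagged(self):
        cat = make_catalog([{"patient_id": "N", "gene_id": "ONC"}])
        labels = pd.DataFrame({"patient_id": ["N"], "status": ["escape_neg"]})
        res = onc_tsg_proportions(cat, labels, {"ONC": "oncogene", "TSG1": "TSG"})
        assert res.flagged


class TestVafCompare:
    def test_identical_multisets_u_is_half(self):
        vals = np.linspace(0.1, 0.9, 30)
        rows = [{"gene_id": "D1", "vaf": v} for v in vals]
        rows += [{"gene_id": "E1", "vaf": v} for v in vals]
        out = vaf_compare(make_catalog(rows), ["D1"], ["E1"])
        assert out.iloc[0]["U"] == pytest.approx(30 * 30 / 2)
        assert out.iloc[0]["p"] > 0.9

    def test_separated_beta_distributions(self):
        rng = np.random.default_rng(1)
        rows = [{"gene_id": "D1", "vaf": v} for v in rng.beta(8, 2, 100)]
        rows += [{"gene_id": "E1", "vaf": v} for v in rng.beta(2, 8, 100)]
        out = vaf_compare(make_catalog(rows), ["D1"], ["E1"])
        assert out.iloc[0]["p"] < 1e-10

    def test_insufficient_data_reported_missing(self):
        rows = [{"gene_id": "D1", "vaf": 0.5}] * 3 + [{"gene_id": "E1", "vaf": 0.4}] * 20
        out = vaf_compare(make_catalog(rows), ["D1"], ["E1"])
        assert np.isnan(out.iloc[0]["p"])

    def test_simulated_driver_vaf_exceeds_escape(self, default_cohort, default_config):
        out = vaf_compare(
            default_cohort.catalog,
            list(default_config.driver_genes),
            list(default_config.escape_genes),
        )
        assert out.iloc[0]["median_driver"] > out.iloc[0]["median_escape"]
        assert out.iloc[0]["p"] < 1e-4


class TestRandomEscapeNull:
    def test_reproducible_and_neutral_within_band(self):
        """Exchangeable escape labels: the observed omega sits in the null band.

        No group asymmetries and no causal escape labeling, so the true
        escape+ cohort (patients hitting the escape genes by chance) is
        statistically exchangeable with the pseudo cohorts drawn from random
        gene lists of the same size.
        """
        drv = [f"DRV{i}" for i in range(1, 7)]
        cfg = CohortSimConfig(
            seed=31,
            n_genes=300,
            cds_length_range=(900, 1500),
            driver_genes={d: (3.0, 2.0) for d in drv},
            escape_genes=("ESC1", "ESC2", "ESC3"),
            n_patients_escape_pos=1,
            n_patients_escape_neg=599,
            tmb_mean_pos=40,
            tmb_mean_neg=40,
            hotspot_spec={},
            escape_neg_block_prob=0.0,
            escape_mutation_prob=0.0,
            signature_mix_pos=(0.25, 0.25, 0.25, 0.25),
            signature_mix_neg=(0.25, 0.25, 0.25, 0.25),
        )
        genome = simulate_genome(cfg)
        cohort = simulate_cohort(genome, cfg, seed=44)
        impacts = dnds.build_impact_matrices(genome.genes)
        rates = dnds.fit_context_rates(cohort.catalog, impacts, genome.genes)
        kw = dict(
            catalog=cohort.catalog,
            all_genes=list(genome.genes),
            escape_genes=list(cfg.escape_genes),
            driver_genes=drv,
            rates=rates,
            impact_matrices=impacts,
            reps=30,
            seed=7,
        )
        a = random_escape_null(**kw)
        b = random_escape_null(**kw)
        np.testing.assert_array_equal(a.null_driver_w, b.null_driver_w)
        lo, hi = np.percentile(a.null_driver_w, [2.5, 97.5])
        assert lo <= a.observed_driver_w <= hi
        assert 1 / 31 <= a.empirical_p <= 1.0

    def test_pool_too_small_raises(self, default_cohort, default_genome):
        impacts = dnds.build_impact_matrices(default_genome.genes)
        rates = dnds.ContextRateModel.uniform()
        with pytest.raises(ValueError, match="non-escape"):
            random_escape_null(
                default_cohort.catalog,
                ["A", "B"],
                ["A"],
                ["B"],
                rates,
                impacts,
                k=5,
            )
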