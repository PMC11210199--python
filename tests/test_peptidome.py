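import numpy as np
import pandas as pd
import pytest

from escapesel.dnds import ContextRateModel
from escapesel.genome import make_gene_model
from escapesel.peptidome import (
    GenomicRegionSet,
    ProteinRegion,
    filter_by_regions,
    filtered_dnds,
    genomic_to_protein,
    protein_to_genomic,
    regions_from_table,
)
from conftest import make_catalog

CDS30 = "ATGGCTACCGGTCATATTCTGAAACCCTAA".replace("TAA", "TAC")  # 30 nt, no stop


def region(gene, start, end, patient="global"):
    return ProteinRegion(
        patient_id=patient, gene_id=gene.gene_id,
        transcript_id=gene.transcript_id, start_aa=start, end_aa=end,
    )


class TestProteinToGenomic:
    def test_plus_strand_single_exon(self):
        gene = make_gene_model("G", CDS30, cds_start=1001)
        out = protein_to_genomic(region(gene, 2, 3), gene)
        assert out.intervals["chr1"] == [(1004, 1009)]

    def test_minus_strand_single_exon(self):
        # CDS genomic span [s, s+29]; protein position 1 is the three
        # highest genomic coordinates
        gene = make_gene_model("G", CDS30, strand="-", cds_start=1971)
        out = protein_to_genomic(region(gene, 1, 1), gene)
        assert out.intervals["chr1"] == [(1998, 2000)]

    def test_exon_junction_split_conserves_length(self):
        gene = make_gene_model("G", CDS30, n_exons=2, cds_start=100)
        for start, end in [(1, 10), (4, 7), (5, 5)]:
            out = protein_to_genomic(region(gene, start, end), gene)
            assert out.total_length == 3 * (end - start + 1)

    def test_region_beyond_protein_rejected(self):
        gene = make_gene_model("G", CDS30)
        with pytest.raises(ValueError, match="beyond"):
            protein_to_genomic(region(gene, 9, 11), gene)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("n_exons", [1, 3])
    def test_round_trip_every_protein_position(self, strand, n_exons):
        gene = make_gene_model("G", CDS30, strand=strand, n_exons=n_exons, cds_start=400)
        for p in range(1, gene.protein_length + 1):
            gset = protein_to_genomic(region(gene, p, p), gene)
            covered = [
                pos
                for s, e in gset.intervals["chr1"]
                for pos in range(s, e + 1)
            ]
            assert len(covered) == 3
            assert {genomic_to_protein(pos, gene) for pos in covered} == {p}


class TestFilterByRegions:
    def cat(self):
        return make_catalog(
            [{"patient_id": "P1", "position": p} for p in range(1000, 1020)]
        )

    def regions(self, lo, hi):
        r = GenomicRegionSet()
        r.add("chr1", lo, hi)
        return {"global": r}

    def test_inside_excluded_boundary_inclusive(self):
        regions = self.regions(1004, 1009)
        out = filter_by_regions(self.cat(), regions, mode="exclude")
        assert 1005 not in set(out["position"])
        assert 1009 not in set(out["position"])
        assert 1010 in set(out["position"])

    def test_modes_partition_catalog(self):
        cat = self.cat()
        regions = self.regions(1004, 1010)
        excl = filter_by_regions(cat, regions, mode="exclude")
        rest = filter_by_regions(cat, regions, mode="restrict")
        assert len(excl) + len(rest) == len(cat)
        assert len(rest) == 7

    def test_patient_specific_regions(self):
        cat = make_catalog(
            [
                {"patient_id": "P1", "position": 1005},
                {"patient_id": "P2", "position": 1005},
            ]
        )
        r = GenomicRegionSet()
        r.add("chr1", 1000, 1010)
        out = filter_by_regions(cat, {"P1": r}, mode="exclude")
        assert list(out["patient_id"]) == ["P2"]

    def test_regions_from_table_merges_per_patient(self):
        gene = make_gene_model("G", CDS30, cds_start=1001)
        tbl = pd.DataFrame(
            {
                "patient_id": ["P1", "P1"],
                "transcript_id": ["G.t1", "G.t1"],
                "start_aa": [1, 2],
                "end_aa": [2, 4],
            }
        )
        regs = regions_from_table(tbl, {"G": gene})
        assert regs["P1"].intervals["chr1"] == [(1001, 1012)]


class TestFilteredDnds:
    def setup_sim(self):
        gene = make_gene_model("G", CDS30 * 20, cds_start=1001)  # 600 nt
        models = {"G": gene}
        rows = []
        rng = np.random.default_rng(4)
        # synonymous and missense mutations away from the first 10 codons
        from escapesel.genome import ImpactTable, SYN, MIS

        t = ImpactTable(gene)
        syn_sites = np.nonzero((t.impact == SYN).any(axis=1))[0]
        mis_sites = np.nonzero((t.impact == MIS).any(axis=1))[0]
        for sites, cls, n in ((syn_sites, "synonymous", 40), (mis_sites, "missense", 80)):
            use = sites[sites >= 60]
            for i in rng.choice(use, size=n):
                a = int(np.nonzero(t.impact[i] == (SYN if cls == "synonymous" else MIS))[0][0])
                rows.append(
                    {
                        "gene_id": "G",
                        "position": int(gene.genomic_of_cds(int(i))),
                        "variant_class": cls,
                        "context": t.contexts[i],
                    }
                )
        return models, make_catalog(rows)

    def test_empty_region_set_is_identity(self):
        models, cat = self.setup_sim()
        rates = ContextRateModel.uniform()
        orig, filt, ratio = filtered_dnds(cat, {}, ["G"], rates, models)
        assert filt.w == pytest.approx(orig.w, abs=1e-12)
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_masking_unmutated_opportunity_follows_counting_oracle(self):
        """Masking a mutation-free region leaves n unchanged, shrinks E, and
        shifts omega exactly as the masked counting estimator predicts."""
        from escapesel.genome import MIS, SYN, ImpactTable

        models, cat = self.setup_sim()
        gene = models["G"]
        rates = ContextRateModel.uniform()
        r = GenomicRegionSet()
        # first 20 codons carry no simulated mutations (sites < 60 unused)
        r.add("chr1", 1001, 1060)
        orig, filt, ratio = filtered_dnds(cat, {"global": r}, ["G"], rates, models)
        assert filt.n_mis == orig.n_mis and filt.n_syn == orig.n_syn
        assert filt.E_mis < orig.E_mis
        # oracle: counting estimator over the unmasked opportunity
        t = ImpactTable(gene)
        mask = np.ones(gene.cds_length, dtype=bool)
        mask[:60] = False
        L_all = t.opportunity_matrix().sum(axis=0)
        L_kept = t.opportunity_matrix(mask).sum(axis=0)
        expect_orig = (orig.n_mis / L_all[MIS]) / (orig.n_syn / L_all[SYN])
        expect_filt = (orig.n_mis / L_kept[MIS]) / (orig.n_syn / L_kept[SYN])
        assert orig.w_mis == pytest.approx(expect_orig, rel=1e-9)
        assert filt.w_mis == pytest.approx(expect_filt, rel=1e-9)

    def test_mutations_only_flag_keeps_opportunity(self):
        models, cat = self.setup_sim()
        rates = ContextRateModel.uniform()
        r = GenomicRegionSet()
        r.add("chr1", 1001, 1030)
        _, filt_masked, _ = filtered_dnds(cat, {"global": r}, ["G"], rates, models)
        _, filt_plain, _ = filtered_dnds(
            cat, {"global": r}, ["G"], rates, models, mask_opportunity=False
        )
        assert filt_plain.E_mis > filt_masked.E_mis
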