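"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes so every downstream
stage is testable without controlled-access tumor data:

* two patient groups (escape+ / escape-) with asymmetric mutation burden
  (defaults 426 vs 95 mutations per patient);
* mutations drawn from group-specific mixtures over an SBS signature catalog
  and placed on genomic sites whose reference triplet matches the drawn
  channel (per-channel opportunity is correct by construction);
* positive selection in driver genes implemented by a rejection step, so a
  gene simulated with multiplier ``w`` has dN/dS = w in expectation;
* hotspot concentration: a fraction ``rho`` of a driver gene's missense
  mutations in the escape- group is relocated to one hotspot codon
  (IDH1 R132 / KRAS G12 semantics, missense only);
* causal escape labels: escape+ patients carry a guaranteed non-silent
  escape-gene SNV; non-silent escape-gene substitutions are rejected for
  escape- patients (configurable), mirroring the fact that escape status is
  *defined* by such a mutation;
* clonality: VAFs drawn from role-specific Beta distributions (driver >
  escape > passenger);
* survival: exponential times with a hazard ratio applied only to escape+
  patients in immune category C3, uniform censoring at a horizon.

A truth ledger records every latent assignment (true group, per-gene
selection multipliers, hotspot relocations, mutation roles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._contexts import COLLAPSE_192_TO_96, COMPLEMENT, SBS96_LABELS
from .genome import MIS, NON, SYN, GeneModel, ImpactTable
from .io import IMMUNE_CATEGORIES, SignatureCatalog, write_fasta, write_gene_models, write_maf

_SENSE_CODONS = None


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortSimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the cohort asymmetries the analysis targets: a ~4.5x
    mutation-burden ratio between groups, a handful of positively selected
    driver genes, one escape- -only hotspot, group-differential signature
    mixtures, clonality ordering driver > escape > passenger, and a survival
    hazard ratio confined to immune category C3.
    """

    seed: int = 0
    genome_seed: int | None = None  # fix the genome across cohort replicates
    n_patients_escape_pos: int = 60
    n_patients_escape_neg: int = 200
    n_genes: int = 50
    cds_length_range: tuple[int, int] = (900, 1800)
    n_exons_range: tuple[int, int] = (1, 1)
    frac_minus_strand: float = 0.5
    driver_genes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"DRV1": (5.0, 3.0), "DRV2": (5.0, 1.0), "DRV3": (3.0, 3.0)}
    )
    #: optional per-group override of driver multipliers for escape+ patients
    driver_genes_escape_pos: dict[str, tuple[float, float]] | None = None
    escape_genes: tuple[str, ...] = ("ESC1", "ESC2", "ESC3", "ESC4", "ESC5")
    escape_mutation_prob: float = 1.0
    #: probability a non-silent escape-gene substitution is rejected for an
    #: escape- patient (1.0 makes the escape label causal and exactly
    #: recoverable by classification)
    escape_neg_block_prob: float = 1.0
    tmb_mean_pos: float = 426.0
    tmb_mean_neg: float = 95.0
    signature_mix_pos: tuple[float, ...] = (0.55, 0.15, 0.15, 0.15)
    signature_mix_neg: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    signature_catalog: SignatureCatalog | None = None  # default_signature_catalog()
    #: gene -> (1-based protein position, concentration rho in [0, 1])
    hotspot_spec: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"DRV1": (50, 0.9)}
    )
    hotspot_groups: tuple[str, ...] = ("escape_neg",)
    #: Beta(a, b) parameters per mutation role
    vaf_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"driver": (6.0, 3.0), "escape": (3.0, 6.0), "passenger": (2.0, 6.0)}
    )
    survival_params: dict[str, float] = field(
        default_factory=lambda: {
            "baseline_hazard": np.log(2) / 1000.0,  # median ~1000 days
            "hr_escape_pos_c3": 2.5,
            "censor_horizon": 3000.0,
        }
    )
    category_probs: tuple[float, ...] = (1 / 6,) * 6
    cancer_types: tuple[str, ...] = ("SIM",)
    cancer_type_probs: tuple[float, ...] = (1.0,)
    expression_lognorm: tuple[float, float] = (3.0, 1.0)
    cnv_del_probs: dict[str, float] = field(
        default_factory=lambda: {"hemi": 0.08, "homo": 0.02}
    )

    def __post_init__(self):
        cat = self.signature_catalog or default_signature_catalog()
        for mix in (self.signature_mix_pos, self.signature_mix_neg):
            if len(mix) != cat.n_signatures:
                raise ValueError("signature mix dimension != catalog K")
            if abs(sum(mix) - 1.0) > 1e-8 or any(w < 0 for w in mix):
                raise ValueError("signature mixes must be non-negative and sum to 1")
        for gene, (pos, rho) in self.hotspot_spec.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"hotspot rho for {gene} outside [0, 1]")
        if min(self.n_patients_escape_pos, self.n_patients_escape_neg, self.n_genes) < 1:
            raise ValueError("all counts must be positive")
        named = set(self.driver_genes) | set(self.escape_genes)
        if self.n_genes < len(named):
            raise ValueError("n_genes smaller than number of named driver+escape genes")
        for w in list(self.driver_genes.values()) + list(
            (self.driver_genes_escape_pos or {}).values()
        ):
            if min(w) < 0:
                raise ValueError("selection multipliers must be >= 0")


def default_signature_catalog() -> SignatureCatalog:
    """Four well-separated synthetic SBS signatures.

    SYN-CPG: clock-like C>T at NpCpG (deamination-style); SYN-FLAT: uniform;
    SYN-APOBEC: C>T/C>G at TpCpA and TpCpT; SYN-UV: C>T with a 5' pyrimidine.
    Pairwise cosine similarities are well below 0.9.
    """
    mats = []
    labels = list(SBS96_LABELS)

    def build(weight_fn):
        col = np.array([weight_fn(lab) for lab in labels], dtype=float)
        col += 1e-4  # small floor so every channel is reachable
        return col / col.sum()

    mats.append(build(lambda lab: 1.0 if lab[2:5] == "C>T" and lab[6] == "G" else 0.0))
    mats.append(build(lambda lab: 1.0))
    mats.append(
        build(
            lambda lab: 1.0
            if lab[0] == "T" and lab[2] == "C" and lab[4] in "TG" and lab[6] in "AT"
            else 0.0
        )
    )
    mats.append(
        build(lambda lab: 1.0 if lab[2:5] == "C>T" and lab[0] in "CT" and lab[6] != "G" else 0.0)
    )
    return SignatureCatalog(
        names=("SYN-CPG", "SYN-FLAT", "SYN-APOBEC", "SYN-UV"),
        matrix=np.column_stack(mats),
    )


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class SyntheticGenome:
    genes: dict[str, GeneModel]
    chromosome_name: str
    chromosome_seq: str
    _index: "GenomeIndex | None" = field(default=None, repr=False)

    @property
    def index(self) -> "GenomeIndex":
        if self._index is None:
            self._index = GenomeIndex(self.genes)
        return self._index

    def write(self, fasta_path, models_path) -> None:
        write_fasta({self.chromosome_name: self.chromosome_seq}, fasta_path)
        write_gene_models(self.genes, models_path)


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .genome import _CODON_TABLE

        _SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
    return _SENSE_CODONS


def _gene_names(config: CohortSimConfig) -> list[str]:
    names = list(config.escape_genes) + [
        g for g in config.driver_genes if g not in config.escape_genes
    ]
    filler = (f"G{i:03d}" for i in range(1, 10 * config.n_genes))
    while len(names) < config.n_genes:
        nm = next(filler)
        if nm not in names:
            names.append(nm)
    return names[: config.n_genes]


def simulate_genome(config: CohortSimConfig) -> SyntheticGenome:
    """Generate an intron-optional toy genome: CDS drawn codon-wise from the
    61 sense codons (no internal stops by construction), genes laid head to
    tail on one chromosome with random intergenic padding; deterministic
    under ``genome_seed`` (defaults to ``seed``)."""
    rng = np.random.default_rng(config.seed if config.genome_seed is None else config.genome_seed)
    codons = _sense_codons()
    lo, hi = config.cds_length_range
    if lo < 3 or hi < lo:
        raise ValueError("bad cds_length_range")
    chrom_parts: list[str] = []
    gpos = 1
    genes: dict[str, GeneModel] = {}
    pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    for name in _gene_names(config):
        spacer = pad(25)
        chrom_parts.append(spacer)
        gpos += len(spacer)
        L = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        cds = "".join(rng.choice(codons, size=L // 3))
        strand = "-" if rng.random() < config.frac_minus_strand else "+"
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        cuts = np.linspace(0, L, n_exons + 1).round().astype(int)
        gseq = cds if strand == "+" else _revcomp(cds)
        exons = []
        cursor = gpos
        for k in range(n_exons):
            elen = int(cuts[k + 1] - cuts[k])
            exons.append((cursor, cursor + elen - 1))
            chrom_parts.append(gseq[cuts[k] : cuts[k + 1]])
            cursor += elen
            if k < n_exons - 1:
                intron = pad(30)
                chrom_parts.append(intron)
                cursor += len(intron)
        gpos = cursor
        genes[name] = GeneModel(
            gene_id=name,
            transcript_id=f"{name}.t1",
            chromosome="chr1",
            strand=strand,
            exons=exons,
            cds_sequence=cds,
            flank5="A",
            flank3="A",
        )
    chrom_parts.append(pad(25))
    chrom = "".join(chrom_parts)
    # fill true flanking bases now that the chromosome exists
    for name, gm in list(genes.items()):
        left = chrom[gm.exons[0][0] - 2]
        right = chrom[gm.exons[-1][1]]
        if gm.strand == "+":
            f5, f3 = left, right
        else:
            f5, f3 = COMPLEMENT[right], COMPLEMENT[left]
        genes[name] = GeneModel(
            gene_id=gm.gene_id,
            transcript_id=gm.transcript_id,
            chromosome=gm.chromosome,
            strand=gm.strand,
            exons=gm.exons,
            cds_sequence=gm.cds_sequence,
            flank5=f5,
            flank3=f3,
        )
    return SyntheticGenome(genes=genes, chromosome_name="chr1", chromosome_seq=chrom)


def _revcomp(s: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# site index (shared across cohort replicates)


class GenomeIndex:
    """Flattened per-site annotation over all genes, CSR-indexed by SBS96 channel."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.gene_ids = list(genes)
        self.genes = genes
        self.tables = {g: ImpactTable(genes[g]) for g in self.gene_ids}
        lens = np.array([genes[g].cds_length for g in self.gene_ids])
        self.gene_offsets = np.concatenate([[0], np.cumsum(lens * 3)])
        imp, c192, gidx, cdsidx, altr = [], [], [], [], []
        for gi, g in enumerate(self.gene_ids):
            t = self.tables[g]
            L = genes[g].cds_length
            imp.append(t.impact.ravel())
            c192.append(t.cls192.ravel())
            gidx.append(np.full(L * 3, gi, dtype=np.int32))
            cdsidx.append(np.repeat(np.arange(L, dtype=np.int32), 3))
            altr.append(np.tile(np.arange(3, dtype=np.int8), L))
        self.site_impact = np.concatenate(imp)
        self.site_cls192 = np.concatenate(c192)
        self.site_cls96 = COLLAPSE_192_TO_96[self.site_cls192]
        self.site_gene = np.concatenate(gidx)
        self.site_cds = np.concatenate(cdsidx)
        self.site_alt = np.concatenate(altr)
        order = np.argsort(self.site_cls96, kind="stable")
        self.channel_sites = order
        self.channel_counts = np.bincount(self.site_cls96, minlength=96)
        self.channel_offsets = np.concatenate([[0], np.cumsum(self.channel_counts)])

    def flat_index(self, gene_idx, cds_idx, alt_rank):
        return self.gene_offsets[gene_idx] + cds_idx * 3 + alt_rank


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimulatedCohort:
    genome: SyntheticGenome
    catalog: pd.DataFrame
    clinical: pd.DataFrame
    expression: pd.DataFrame
    cnv: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        self.genome.write(outdir / "reference.fa", outdir / "gene_models.tsv")
        paths["reference"] = str(outdir / "reference.fa")
        paths["gene_models"] = str(outdir / "gene_models.tsv")
        write_maf(self.catalog, outdir / "mutations.maf")
        paths["maf"] = str(outdir / "mutations.maf")
        for name, df in [
            ("clinical", self.clinical),
            ("expression", self.expression),
            ("cnv", self.cnv),
        ]:
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = str(p)
        for name, df in self.truth.items():
            p = outdir / f"truth_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"truth_{name}"] = str(p)
        return paths


def _selection_factors(config: CohortSimConfig, gene_ids: list[str], group: str) -> np.ndarray:
    """Per-(gene, impact) acceptance probabilities implementing selection."""
    w = np.ones((len(gene_ids), 3))
    drivers = dict(config.driver_genes)
    if group == "escape_pos" and config.driver_genes_escape_pos is not None:
        drivers.update(config.driver_genes_escape_pos)
    for gi, g in enumerate(gene_ids):
        if g in drivers:
            w[gi, MIS], w[gi, NON] = drivers[g]
    if group == "escape_neg" and config.escape_neg_block_prob > 0:
        for gi, g in enumerate(gene_ids):
            if g in config.escape_genes:
                w[gi, MIS] *= 1.0 - config.escape_neg_block_prob
                w[gi, NON] *= 1.0 - config.escape_neg_block_prob
    return w / np.maximum(w.max(axis=1, keepdims=True), 1e-300)


def _draw_group_mutations(
    idx: GenomeIndex, config: CohortSimConfig, group: str, n_patients: int, rng
):
    """Vectorized accept/reject sampling of one group's mutation sites."""
    cat = config.signature_catalog or default_signature_catalog()
    mix = np.asarray(
        config.signature_mix_pos if group == "escape_pos" else config.signature_mix_neg
    )
    mix96 = cat.matrix @ mix
    mix96 = np.where(idx.channel_counts > 0, mix96, 0.0)
    if mix96.sum() <= 0:
        raise ValueError("no genomic site matches any channel of the signature mix")
    mix96 = mix96 / mix96.sum()
    tmb = config.tmb_mean_pos if group == "escape_pos" else config.tmb_mean_neg
    counts = rng.poisson(tmb, size=n_patients)
    need = int(counts.sum())
    acc = _selection_factors(config, idx.gene_ids, group)
    chosen = np.empty(need, dtype=np.int64)
    channels = np.empty(need, dtype=np.int16)
    filled = 0
    while filled < need:
        m = need - filled
        c = rng.choice(96, size=m, p=mix96)
        u = idx.channel_offsets[c] + (rng.random(m) * idx.channel_counts[c]).astype(np.int64)
        site = idx.channel_sites[u]
        p_acc = acc[idx.site_gene[site], idx.site_impact[site]]
        keep = rng.random(m) < p_acc
        k = int(keep.sum())
        chosen[filled : filled + k] = site[keep]
        channels[filled : filled + k] = c[keep]
        filled += k
    patient_of = np.repeat(np.arange(n_patients), counts)
    return patient_of, chosen, channels


def _hotspot_sites(idx: GenomeIndex, gene: str, protein_pos: int) -> np.ndarray:
    gm = idx.genes[gene]
    s, e = gm.codon_cds_range(protein_pos)
    gi = idx.gene_ids.index(gene)
    flat = []
    t = idx.tables[gene]
    for ci in range(s, e + 1):
        for a in range(3):
            if t.impact[ci, a] == MIS:
                flat.append(idx.flat_index(gi, ci, a))
    if not flat:
        raise ValueError(f"hotspot codon {protein_pos} of {gene} has no missense change")
    return np.asarray(flat, dtype=np.int64)


def simulate_clinical(patient_ids, groups, categories, cancer_types, config, rng):
    """Exponential survival with the hazard ratio applied only to escape+
    patients in immune category C3; uniform censoring at the horizon."""
    sp = config.survival_params
    groups = np.asarray(groups)
    categories = np.asarray(categories)
    n = len(patient_ids)
    hazard = np.full(n, sp["baseline_hazard"])
    hazard[(groups == "escape_pos") & (categories == "C3")] *= sp["hr_escape_pos_c3"]
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0, sp["censor_horizon"], size=n)
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "survival_time": np.maximum(np.minimum(t_event, t_cens), 1e-3),
            "event": (t_event <= t_cens).astype(int),
            "immune_category": categories,
            "cancer_type": cancer_types,
        }
    )
    return clinical, t_event


def simulate_cohort(
    genome: SyntheticGenome, config: CohortSimConfig, seed: int | None = None
) -> SimulatedCohort:
    """Draw a full synthetic cohort (mutations, clinical, expression, CNV, truth)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    idx = genome.index
    n_pos, n_neg = config.n_patients_escape_pos, config.n_patients_escape_neg
    n_pat = n_pos + n_neg
    patient_ids = np.array([f"S{i:05d}" for i in range(n_pat)])
    groups = np.array(["escape_pos"] * n_pos + ["escape_neg"] * n_neg)

    frames = []
    for group, n_g, off in (("escape_pos", n_pos, 0), ("escape_neg", n_neg, n_pos)):
        pat, site, chan = _draw_group_mutations(idx, config, group, n_g, rng)
        frames.append(
            pd.DataFrame(
                {
                    "pat": pat + off,
                    "site": site,
                    "drawn_channel": chan,
                    "group": group,
                    "relocated": False,
                    "guaranteed": False,
                }
            )
        )
    mut = pd.concat(frames, ignore_index=True)

    # hotspot relocation (missense only, configured groups)
    for gene, (ppos, rho) in config.hotspot_spec.items():
        if gene not in idx.genes or rho <= 0:
            continue
        hs = _hotspot_sites(idx, gene, ppos)
        gi = idx.gene_ids.index(gene)
        cand = (
            (idx.site_gene[mut["site"].to_numpy()] == gi)
            & (idx.site_impact[mut["site"].to_numpy()] == MIS)
            & mut["group"].isin(config.hotspot_groups).to_numpy()
        )
        move = cand & (rng.random(len(mut)) < rho)
        n_move = int(move.sum())
        if n_move:
            mut.loc[move, "site"] = rng.choice(hs, size=n_move)
            mut.loc[move, "relocated"] = True

    # guaranteed escape-gene mutation for escape+ patients
    esc_gidx = [idx.gene_ids.index(g) for g in config.escape_genes if g in idx.genes]
    esc_nonsil = np.nonzero(
        np.isin(idx.site_gene, esc_gidx) & (idx.site_impact != SYN)
    )[0]
    if n_pos and len(esc_nonsil):
        has = set(
            mut.loc[
                np.isin(idx.site_gene[mut["site"].to_numpy()], esc_gidx)
                & (idx.site_impact[mut["site"].to_numpy()] != SYN),
                "pat",
            ]
        )
        add_rows = []
        for p in range(n_pos):
            if p in has or rng.random() >= config.escape_mutation_prob:
                continue
            add_rows.append(
                {
                    "pat": p,
                    "site": int(rng.choice(esc_nonsil)),
                    "drawn_channel": -1,
                    "group": "escape_pos",
                    "relocated": False,
                    "guaranteed": True,
                }
            )
        if add_rows:
            mut = pd.concat([mut, pd.DataFrame(add_rows)], ignore_index=True)

    # de-duplicate repeated hits of the same genomic site within a patient
    site_arr = mut["site"].to_numpy()
    key = mut["pat"].to_numpy() * (idx.gene_offsets[-1] + 1) + (site_arr // 3) * 3
    _, first = np.unique(key, return_index=True)
    mut = mut.iloc[np.sort(first)].reset_index(drop=True)

    # materialize catalog columns
    site = mut["site"].to_numpy()
    gi = idx.site_gene[site]
    cds = idx.site_cds[site]
    altr = idx.site_alt[site]
    imp = idx.site_impact[site]
    cls96 = idx.site_cls96[site]
    gene_arr = np.array(idx.gene_ids, dtype=object)[gi]
    strands = np.array([idx.genes[g].strand for g in idx.gene_ids])[gi]
    gpos = np.empty(len(mut), dtype=np.int64)
    ctx = np.empty(len(mut), dtype="U3")
    ref_cod = np.empty(len(mut), dtype="U1")
    for k, g in enumerate(idx.gene_ids):
        m = gi == k
        if not m.any():
            continue
        gm = idx.genes[g]
        gpos[m] = gm.genomic_positions[cds[m]]
        t = idx.tables[g]
        ctx[m] = t.contexts[cds[m]]
        seq = np.frombuffer(gm.cds_sequence.encode(), dtype="S1").astype("U1")
        ref_cod[m] = seq[cds[m]]
    alt_cod = np.array(
        [sorted(set("ACGT") - {r})[a] for r, a in zip(ref_cod, altr)], dtype="U1"
    )
    minus = strands == "-"
    comp = np.vectorize(COMPLEMENT.get)
    ref_gen = np.where(minus, comp(ref_cod), ref_cod)
    alt_gen = np.where(minus, comp(alt_cod), alt_cod)

    gene_is_driver = {g: g in config.driver_genes for g in idx.gene_ids}
    gene_is_escape = {g: g in config.escape_genes for g in idx.gene_ids}
    role = np.where(
        (imp != SYN) & [gene_is_escape[g] for g in gene_arr],
        "escape",
        np.where((imp != SYN) & [gene_is_driver[g] for g in gene_arr], "driver", "passenger"),
    )
    vaf = np.empty(len(mut))
    for r, (a, b) in config.vaf_params.items():
        m = role == r
        vaf[m] = rng.beta(a, b, size=int(m.sum()))

    ctype = rng.choice(config.cancer_types, size=n_pat, p=config.cancer_type_probs)
    imp_name = np.array(["synonymous", "missense", "nonsense"])[imp]
    pat = mut["pat"].to_numpy()
    catalog = pd.DataFrame(
        {
            "patient_id": patient_ids[pat],
            "gene_id": gene_arr,
            "chromosome": genome.chromosome_name,
            "position": gpos,
            "ref_allele": ref_gen,
            "alt_allele": alt_gen,
            "variant_class": imp_name,
            "context": ctx,
            "vaf": vaf,
            "cancer_type": ctype[pat],
            "non_snv": False,
        }
    )

    # clinical
    cats = rng.choice(list(IMMUNE_CATEGORIES), size=n_pat, p=config.category_probs)
    clinical, t_event = simulate_clinical(patient_ids, groups, cats, ctype, config, rng)

    # expression (long) and CNV tables over all genes
    mu, sig = config.expression_lognorm
    expr = rng.lognormal(mu, sig, size=(n_pat, len(idx.gene_ids)))
    expression = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, len(idx.gene_ids)),
            "gene_id": np.tile(idx.gene_ids, n_pat),
            "fpkm": expr.ravel(),
        }
    )
    cn = np.full((n_pat, len(idx.gene_ids)), 2, dtype=int)
    for g in config.escape_genes:
        if g not in idx.genes:
            continue
        k = idx.gene_ids.index(g)
        u = rng.random(n_pat)
        cn[u < config.cnv_del_probs["homo"], k] = 0
        cn[(u >= config.cnv_del_probs["homo"])
           & (u < config.cnv_del_probs["homo"] + config.cnv_del_probs["hemi"]), k] = 1
    cnv = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, len(idx.gene_ids)),
            "gene_id": np.tile(idx.gene_ids, n_pat),
            "copy_number": cn.ravel(),
        }
    )

    # truth ledger
    truth_patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "group": groups,
            "immune_category": cats,
            "cancer_type": ctype,
            "true_event_time": t_event,
        }
    )
    grows = []
    for g in idx.gene_ids:
        w_neg = config.driver_genes.get(g, (1.0, 1.0))
        w_pos = (config.driver_genes_escape_pos or {}).get(g, w_neg)
        hp = config.hotspot_spec.get(g)
        grows.append(
            {
                "gene_id": g,
                "w_mis_neg": w_neg[0],
                "w_non_neg": w_neg[1],
                "w_mis_pos": w_pos[0],
                "w_non_pos": w_pos[1],
                "is_escape": g in config.escape_genes,
                "is_driver": g in config.driver_genes,
                "hotspot_protein_pos": hp[0] if hp else -1,
                "hotspot_rho": hp[1] if hp else 0.0,
            }
        )
    truth_genes = pd.DataFrame(grows)
    truth_mut = pd.DataFrame(
        {
            "patient_id": patient_ids[pat],
            "gene_id": gene_arr,
            "position": gpos,
            "drawn_channel": mut["drawn_channel"].to_numpy(),
            "channel96": cls96,
            "impact": imp_name,
            "role": role,
            "relocated": mut["relocated"].to_numpy(),
            "guaranteed": mut["guaranteed"].to_numpy(),
        }
    )
    return SimulatedCohort(
        genome=genome,
        catalog=catalog,
        clinical=clinical,
        expression=expression,
        cnv=cnv,
        truth={"patients": truth_patients, "genes": truth_genes, "mutations": truth_mut},
    )


def simulate(config: CohortSimConfig) -> SimulatedCohort:
    """Genome + cohort in one call (the `escapesel simulate` entry point)."""
    genome = simulate_genome(config)
    return simulate_cohort(genome, config)
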