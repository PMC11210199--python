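# escapesel

Tools for comparing the somatic selection landscape of tumors that escaped
the immune system (escape+) against tumors that did not (escape−).

Tumor cohorts are stratified by *immune-escape status*: a patient is
escape+ if they carry a non-silent point mutation in one of a configurable
list of escape genes (antigen-presentation machinery and other immune-evasion
genes), with alternative stratifications by escape-gene deletions (copy-number
categories A–F) and by PD-L1 (*CD274*) expression quartiles. The package then
quantifies, per group:

* **selection** — maximum-likelihood dN/dS with a trinucleotide-context
  mutation model (global, driver-gene-set and per-gene ω with confidence
  intervals, likelihood-ratio tests and BH-corrected driver calling);
* **burden confounding controls** — a randomized escape-gene null
  (resampling random gene lists and re-deriving pseudo-escape cohorts) and
  patient/mutation downsampling;
* **mutation placement** — hotspot concentration tests contrasting total
  mutation counts with distinct mutated sites, with hotspot exclusion;
* **mutational processes** — SBS96 spectrum tabulation and
  deconstructSigs-style forward-selection signature refitting, with
  per-signature group contrasts;
* **clonality** — Mann–Whitney comparison of variant allele frequencies of
  driver-gene vs escape-gene mutations;
* **outcome** — Kaplan–Meier curves and log-rank tests of escape+ vs
  escape− within immune categories C1–C6 (C3 = inflammatory).

A fully seeded synthetic-cohort generator (`escapesel.simulate`) produces
mutation catalogs, gene models, reference sequence, clinical, expression and
copy-number tables with the statistical structure these analyses assume —
group-asymmetric burden, positively selected drivers, group-specific
hotspots, signature mixtures, clonality ordering and a C3-confined survival
effect — plus a truth ledger of every latent assignment, so the entire
pipeline is testable end to end without access to controlled tumor data.

## The selection model

For each gene, all `3 × CDS-length` possible substitutions are enumerated
and binned into opportunity counts `L[s, k]` by strand-specific
trinucleotide class `s` (192 classes) and impact `k` (synonymous, missense,
nonsense). Relative context rates `r_s` are fit cohort-wide by a joint
Poisson maximum-likelihood model with global nuisance selection factors
(`n_sk ~ Pois(r_s · L_sk · w_k)`, `w_syn ≡ 1`). Per gene, observed counts
follow

```
n_k ~ Poisson(t · Σ_s r_s L_sk · w_k),      w_syn = 1
```

with gene mutation-rate factor `t`. MLEs are closed form
(`t̂ = n_syn / E_syn`, `ŵ_k = n_k / (t̂ E_k)`); significance is a 1-df
likelihood-ratio test of `w_k = 1` and 95% intervals come from the profile
likelihood. Pooled (global / driver-set) ω uses summed counts and summed
rate-weighted opportunities with a log-scale Wald interval. Drivers are
genes with `ω > 1` and BH `q < 0.1`. This is a deliberately simplified
dNdScv-style model: plain Poisson, no negative-binomial overdispersion, no
gene-level covariates.

## Worked example

```python
from escapesel import (CohortSimConfig, simulate, build_impact_matrices,
                       fit_context_rates, global_dnds)
from escapesel.stratify import classify_point_mutation

cfg = CohortSimConfig(
    seed=7,
    n_patients_escape_pos=60,
    n_patients_escape_neg=200,
    driver_genes={"DRV1": (5.0, 3.0), "DRV2": (5.0, 1.0), "DRV3": (3.0, 3.0)},
    escape_genes=("ESC1", "ESC2", "ESC3", "ESC4", "ESC5"),
)
cohort = simulate(cfg)
genes = cohort.genome.genes
impacts = build_impact_matrices(genes)
labels = classify_point_mutation(cohort.catalog, list(cfg.escape_genes))

for group in ("escape_neg", "escape_pos"):
    patients = set(labels.loc[labels["status"] == group, "patient_id"])
    sub = cohort.catalog[cohort.catalog["patient_id"].isin(patients)]
    rates = fit_context_rates(sub, impacts, genes)
    driver = global_dnds(["DRV1", "DRV2", "DRV3"], sub, rates, impacts)
    tmb = sub.groupby("patient_id").size().mean()
    print(f"{group}: n={len(patients)}  mean TMB={tmb:.0f}  "
          f"driver dN/dS={driver.w:.3f}  95% CI [{driver.ci[0]:.3f}, {driver.ci[1]:.3f}]")
```

prints

```
escape_neg: n=200  mean TMB=95  driver dN/dS=3.867  95% CI [3.126, 4.785]
escape_pos: n=60  mean TMB=422  driver dN/dS=4.211  95% CI [3.495, 5.073]
```

The classification recovers the simulated groups exactly (escape status is
causal in the generator), the mean burden ratio reproduces the configured
≈4.5× asymmetry, and the pooled driver ω in each group tracks the simulated
selection multipliers with calibrated intervals. Setting
`driver_genes_escape_pos` to weaker multipliers reproduces the
selection-buffering contrast (lower, closer-to-neutral driver ω in escape+).

The same pipeline runs from the shell:

```
escapesel simulate --config sim.yaml --out data/
escapesel dnds --maf data/mutations.maf --genes data/gene_models.tsv \
    --fasta data/reference.fa --gene-set drivers.txt --out dnds.tsv
escapesel classify --maf data/mutations.maf --escape-genes escape.txt --out labels.tsv
escapesel run --config run.yaml          # full pipeline + manifest.json
```

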