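# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `escapesel`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Escape stratification

A patient is **escape+** when they carry at least one SNV of a non-silent
class (default: missense, nonsense, essential splice, frameshift, other
non-silent; configurable) in an escape gene. Synonymous escape-gene
mutations never trigger. Two further schemes are provided:

* **Copy-number categories.** Over the escape genes: A = no point mutation
  and no deletion; B = ≥1 hemizygous deletion (CN = 1), no point mutation;
  C = any deletion (CN ≤ 1), no point mutation; D = point mutation or
  hemizygous deletion; F = any escape-gene alteration. These definitions
  overlap (C ⊇ B, F ⊇ D; there is no category E in this vocabulary), so
  membership is emitted as boolean flags, never as a partition.
* **PD-L1 strata.** Expression quartiles of *CD274* (configurable gene)
  computed **within cancer type** to avoid cross-type expression batch
  effects: bottom 25% = low, top 25% = high, remainder mid. Cut points use
  linear-interpolation (type-7) quantiles; values tied exactly at a cut go
  to the inner (mid) stratum. Fewer than 8 patients of a type, or
  all-identical values, yield missing/mid strata with a warning. Both
  strata are emitted; which stratum plays the "escaped" role in a contrast
  is the caller's choice.

## dN/dS model

**Opportunities.** For every gene, each of the `3 × CDS length` possible
single-base substitutions is classified by translating the mutated codon
(standard genetic code) and binned by impact `k ∈ {synonymous, missense,
nonsense}` and by strand-specific trinucleotide substitution class
`s ∈ 192` (5′ flank, ref, alt, 3′ flank on the coding strand). The total
over all classes is exactly `3 × CDS length`. Contexts are strand-specific
because mutational processes are; the collapse to the 96 pyrimidine-centered
COSMIC classes happens only in the signature module.

**Context rates.** The 192 relative rates are estimated cohort-wide by a
joint Poisson maximum-likelihood fit

```
n_sk ~ Pois(r_s · L_sk · w_k),   w_syn ≡ 1,
```

with two global nuisance selection factors (w_mis, w_non), by alternating
closed-form updates (converges in a handful of iterations; tolerance
1e−10, cap 50). Synonymous counts anchor the absolute scale through
`w_syn ≡ 1`. A synonymous-only estimator (`r_s = n_s^syn / L_s^syn`) was
rejected during development: 30 of the 192 classes have **zero synonymous
opportunity anywhere** — structural zeros of the genetic code, carrying
about 5% of nonsynonymous opportunity on the default toy genome — so a
syn-only fit assigns them zero rate, deflates every expected nonsynonymous
count and inflates the neutral pooled ω by ≈1.5%, which is enough to break
null confidence-interval coverage. Classes with no observed mutations and
fewer than 100 opportunities borrow the pyrimidine-collapsed estimate of
their reverse-complement partner.

**Gene-level estimates.** With rate-weighted opportunities
`E~_k = Σ_s r_s L_sk` and a free gene factor `t`:
`t̂ = n_syn / E~_syn`, `ŵ_k = n_k / (t̂ E~_k)`. With uniform rates this is
exactly the counting estimator `(n_k/L_k)/(n_syn/L_syn)` (verified to 1e−8
against that oracle). Significance is a likelihood-ratio test of `w_k = 1`
(χ², 1 df; the joint test of both classes uses 2 df); the statistic agrees
with brute-force grid maximization of the same likelihood to 1e−6. The 95%
CI solves the profile likelihood (drop χ²₀.₉₅(1)/2 = 1.9207) by bracketed
root finding; with `n_k = 0` the lower bound is exactly 0. Genes with zero
synonymous opportunity or zero observed synonymous mutations are flagged
rather than estimated.

**Pooled (global / driver) ω.** `ŵ = (Σn_N/ΣE~_N)/(Σn_S/ΣE~_S)` over the
gene set, reported for missense+nonsense combined and for each class alone;
CI is Wald on log ŵ with variance `1/Σn_N + 1/Σn_S`. When the gene set is a
single gene this equals the gene-level pooled estimate to machine precision.
Under 100 seeded neutral cohorts (200 patients, 50 genes) the 95% CI covers
1 at nominal rate and the gene-level LRT p-values are uniform (both
recomputed by `scripts/acceptance.py`).

**Driver calling.** Significant = `ω > 1` **and** BH `q < 0.1`, with BH
applied separately within the missense and truncating classes, after
optional removal of olfactory receptors (spuriously mutated in cancer;
default pattern `OR<number><letters><number>` or an explicit list).
Truncating = nonsense; the default synthetic genomes are intronless, so no
essential-splice class arises there.

**Group comparison.** Patient-level bootstrap (B ≥ 200 by default;
rejected below 20) of the pooled ω per group, compared by two-sided
Mann–Whitney, with the percentile bands and their non-overlap reported.

## Randomized escape-gene null

Per repetition, `k` genes are drawn uniformly from the non-escape genes,
truly escaped patients are removed, patients with a non-silent SNV in the
drawn set become pseudo-escape+, and the driver-set pooled ω of that pseudo
cohort is computed (cohort-wide rates held fixed). The empirical p of the
true escape+ ω is one-sided lower with the (r+1)/(B+1) convention, so it is
never zero. Repetitions yielding fewer than 5 pseudo patients or a
degenerate pooled estimate are redrawn with a bounded retry.

*Calibration caveat.* The pseudo cohorts of one replicate share patients
(high-burden patients enter nearly every draw) and always exclude the truly
escaped patients. The empirical 2.5–97.5 band of B correlated draws is
therefore mildly narrower than the observed cohort's own sampling spread
(shrinkage ≈ √(1−ρ) for null–null correlation ρ), so even under perfectly
exchangeable labels the observed ω falls inside the band somewhat less
than 95% of the time. The validation experiments accordingly check (i)
majority inside-band coverage and (ii) no systematic displacement of the
observed ω from the null mean; the buffered-selection experiment, where the
signal is a large downward shift of the escape+ ω, is unaffected by this
subtlety.

## Hotspot concentration

For a gene (or a pooled gene set), a 2×2 table of {total nonsynonymous SNV
count, distinct mutated sites} × {escape−, escape+} is tested by Pearson χ²
**without** continuity correction (declared choice; the proportional-rows
case returns χ² = 0, p = 1 exactly). "Distinct sites" counts genomic
positions by default — the stricter reading — with a codon-level switch
that maps positions through the gene model. Hotspot exclusion removes SNVs
in listed codons (protein coordinates mapped through the gene model).
Burden controls: downsampling to equal patient numbers or equal mutation
counts, seeded, with a repeated-draw mode for stability assessment. At high
mutation counts the site tally saturates (recurrent positions), which
itself produces a count/site asymmetry between groups of unequal burden;
the calibration experiments therefore run at burdens where saturation is
negligible, and real analyses should use the downsampling controls.

## Signature refitting

Spectra are 96-channel pyrimidine-centered counts in COSMIC order;
purine-reference records are reverse-complemented, and records with
inconsistent or ambiguous context are skipped, never corrected. Exposures
are refit deconstructSigs-style: normalize to proportions; start from the
single signature minimizing SSE; re-optimize non-negative weights (Σ ≤ 1)
by cyclic golden-section search per signature; add the next signature only
while the relative SSE improvement exceeds `stop_delta` (default 0.01);
zero weights below `threshold` (default 0.06) and rescale survivors to the
pre-zeroing total. Both defaults mirror the reference implementation's and
are configurable. Fitting is proportion-based, hence scale-invariant.
Cohort-level fits treat the pooled group spectrum as a single sample.
Group contrasts attribute `weight × group total` mutations to each
signature, test each 2×2 {this signature, rest} × {group} table by Pearson
χ², and BH-adjust across signatures. No exome/genome trinucleotide
abundance normalization is applied (exome-style input assumed; a switch
exists, default off).

## Survival

Product-limit curves and the two-group log-rank test are computed with
lifelines (verified in the tests against hand product-limit and O−E/V
computations to 1e−10). Overall survival is the default endpoint; other
endpoints enter via the column switch. Stratified contrasts (immune
category C1–C6 and/or cancer type) skip strata with fewer than 5 patients
per arm, recording the reason, and report both raw and BH-adjusted
p-values across strata.

## Immunopeptidome region filtering

Protein position `p` covers CDS nucleotides `[3p−2, 3p]`, projected
through the exon structure honoring strand; intervals are merged, and the
protein↔genome maps are exact inverses (tested exhaustively on both
strands with multi-exon models). Catalog filtering supports exclude and
restrict modes, which partition the catalog for a fixed region set;
patient-specific regions union with a shared "global" set. When
recomputing dN/dS on the filtered catalog, site opportunities are by
default recomputed over the unmasked complement, so observed and expected
counts describe the same genomic territory; a flag reproduces a
mutations-only filter. Note that masking shrinks the synonymous
denominator as well, so the direction of the ω change depends on the
masked region's impact composition — the implementation is tested against
the masked counting estimator rather than a fixed direction. BED export
converts to 0-based half-open coordinates at the file boundary only; all
in-memory coordinates are 1-based inclusive.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
dial. Defaults:

| parameter | default | meaning |
|---|---|---|
| `tmb_mean_pos` / `tmb_mean_neg` | 426 / 95 | mean mutations per patient per group (the ≈4.5× escape+ burden asymmetry) |
| `n_patients_escape_pos` / `_neg` | 60 / 200 | desk-scale cohort with the minority-escape+ composition |
| `n_genes`, `cds_length_range` | 50, (900, 1800) | toy genome; CDS drawn codon-wise from the 61 sense codons (no internal stops by construction), half the genes on the minus strand |
| `driver_genes` | 3 genes, (w_mis, w_non) up to (5, 3) | selection multipliers implemented by rejection, so simulated dN/dS = w in expectation |
| `driver_genes_escape_pos` | unset | optional weaker multipliers for escape+ patients (selection buffering) |
| `escape_genes` | 5 genes | desk-scale stand-in for an escape-gene list |
| `hotspot_spec` | one gene, codon 40, ρ = 0.9 | fraction of that gene's escape− missense mutations relocated to the hotspot codon (missense only, matching R132/G12-style semantics) |
| `signature_mix_pos` / `_neg` | differ by 0.3 in one signature | mixtures over a built-in 4-signature catalog (CpG-deamination-like, flat, APOBEC-like, UV-like; pairwise cosine < 0.9) |
| `vaf_params` | Beta(6,3) / Beta(3,6) / Beta(2,6) | driver / escape / passenger clonality ordering (drivers most clonal) |
| `survival_params` | median ≈ 1000 d, HR 2.5 in C3, censor horizon 3000 d | exponential times, uniform censoring; hazard ratio applied only to escape+ in C3 |

Mutations are drawn channel-first from the group's signature mixture, then
placed uniformly on a genomic site whose reference triplet matches the
channel (channels without a matching site are renormalized away), which
keeps per-channel opportunity correct without per-site bookkeeping.
Selection is a rejection step with per-gene acceptance
`w_k / max(1, w_mis, w_non)`. Repeated hits of one genomic position within
a patient are de-duplicated (at the default burdens this removes well under
1%; at very high per-gene rates it measurably truncates hot channels).
Escape labels are **causal**: escape+ patients receive a guaranteed
non-silent escape-gene SNV (probability `escape_mutation_prob`, default 1)
and non-silent escape-gene substitutions are rejected for escape− patients
(`escape_neg_block_prob`, default 1). This mirrors the fact that escape
status is *defined* by carrying such a mutation; at a 50-gene desk scale a
95-mutation patient would otherwise hit a 5-gene escape set almost surely
and the labels would be meaningless. Exchangeability experiments disable
both switches. The truth ledger records every latent assignment: per
patient the true group, category and uncensored event time; per gene the
selection multipliers and hotspot spec; per mutation the drawn channel,
relocation flag, role and whether it was the guaranteed escape mutation.

What the generator does **not** emulate: copy-number evolution and
subclonal phylogenies (CNV deletions are i.i.d. per escape gene), purity
and ploidy, per-site mutation-rate covariates (chromatin, replication
timing), overdispersed per-gene rates, and indel processes (non-SNV classes
appear in real MAF input but are never simulated). Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to those real-data features — in particular the
plain-Poisson model's null calibration would degrade under real per-gene
rate variation, which is why dNdScv adds gene-level covariates and
negative-binomial overdispersion for cohort-scale human exome analyses.

## Numerical and procedural choices

* Coordinates 1-based inclusive everywhere; BED conversion at the file
  boundary only. One canonical transcript per gene; unknown flanking bases
  default to 'A'.
* MAF rows are conserved: every input row is parsed or rejected with a
  reason; reference-allele disagreements with the gene model are rejected,
  never corrected. Non-SNV rows are retained (flagged) for burden and
  escape classification but excluded from dN/dS.
* Signature catalog columns must sum to 1 within 1e−3 (then renormalized);
  96 rows in any order, reindexed to canonical order on read.
* Dominant-signature ties break lexicographically and are flagged.
* Empirical p-values use (r+1)/(B+1). Pearson χ² is uncorrected
  throughout. BH via the standard step-up procedure; NaN p-values
  propagate.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical config + seed reproduces byte-identical outputs
  (pipeline manifests record SHA-256 content hashes).
* Validation experiment sizes (e.g. 100 neutral cohorts of 200 patients,
  50 stochastic replicates elsewhere) were chosen as the smallest runs
  whose binomial noise is well inside the property thresholds; where a
  rate is estimated from n replicates, the threshold incorporates the
  corresponding binomial slack.

## Known limitations

* The Poisson selection model has no overdispersion or covariates;
  per-gene rate heterogeneity beyond trinucleotide context will inflate
  driver false calls on real data.
* Negative selection is estimable (ω < 1 with the same machinery) but the
  per-gene power analysis here targets positive selection only.
* The randomization null's empirical band is mildly anti-conservative (see
  above); conclusions should rest on the magnitude of the observed-vs-null
  displacement, as in the buffered experiment.
* PD-L1 stratification assumes within-type expression comparability; no
  normalization across platforms is attempted.
* The immunopeptidome filter consumes per-patient protein regions as
  given; no HLA typing or binding prediction is performed.
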