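"""Maximum-likelihood dN/dS with trinucleotide-context rate correction.

Model
-----
For a gene with rate-weighted opportunities ``E~_k = sum_s r_s L_{s,k}``
(``s`` over 192 strand-specific context classes, ``k`` in {synonymous,
missense, nonsense}) and a gene-level mutation-rate factor ``t``, observed
counts are Poisson::

    n_k ~ Poisson(t * E~_k * w_k),   w_syn = 1

The relative rates ``r_s`` are calibrated cohort-wide by a joint Poisson
maximum-likelihood fit with global nuisance selection factors, anchored on
the synonymous counts through ``w_syn = 1`` (see
:func:`fit_context_rates`).  Closed-form
MLEs: ``t_hat = n_syn / E~_syn`` and ``w_hat_k = n_k / (t_hat * E~_k)``;
significance by likelihood-ratio test against ``w_k = 1`` (chi-square, 1 df);
confidence intervals by profile likelihood.  This is a deliberately
simplified dNdScv-style model: plain Poisson, no negative-binomial
overdispersion and no gene-level covariates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._contexts import COMPLEMENT, PARTNER_192, class192
from .genome import GeneModel, ImpactTable

IMPACTS = ("synonymous", "missense", "nonsense")
_IMPACT_CODE = {name: k for k, name in enumerate(IMPACTS)}

# chi2.ppf(0.95, 1) / 2 — profile-likelihood drop for a 95% CI
_CI_DROP = chi2.ppf(0.95, 1) / 2.0


# ---------------------------------------------------------------------------
# opportunities


@dataclass(frozen=True)
class ImpactMatrix:
    """Per-gene counts of possible substitutions by (192-class, impact)."""

    gene_id: str
    L: np.ndarray  # (192, 3) int

    def __post_init__(self):
        if self.L.shape != (192, 3):
            raise ValueError("ImpactMatrix.L must be (192, 3)")
        if (self.L < 0).any():
            raise ValueError("opportunities must be non-negative")


def build_impact_matrix(gene: GeneModel, site_mask: np.ndarray | None = None) -> ImpactMatrix:
    """Enumerate all 3 x CDS-length substitutions and bin by (context, impact)."""
    table = ImpactTable(gene)
    return ImpactMatrix(gene_id=gene.gene_id, L=table.opportunity_matrix(site_mask))


def build_impact_matrices(
    genes: dict[str, GeneModel], site_masks: dict[str, np.ndarray] | None = None
) -> dict[str, ImpactMatrix]:
    masks = site_masks or {}
    return {g: build_impact_matrix(gm, masks.get(g)) for g, gm in genes.items()}


# ---------------------------------------------------------------------------
# context rates


@dataclass(frozen=True)
class ContextRateModel:
    """192 relative context rates on an absolute per-opportunity scale
    (anchored so the synonymous expectation matches the calibration cohort)."""

    r: np.ndarray  # (192,)

    def __post_init__(self):
        if self.r.shape != (192,):
            raise ValueError("rates must have length 192")
        if (self.r < 0).any():
            raise ValueError("rates must be non-negative")

    @classmethod
    def uniform(cls, scale: float = 1.0) -> "ContextRateModel":
        return cls(r=np.full(192, scale))

    def weighted_opportunity(self, L: np.ndarray) -> np.ndarray:
        """``E~_k = sum_s r_s L_{s,k}`` for an (192, 3) opportunity matrix."""
        return self.r @ L


def catalog_class192(catalog: pd.DataFrame, gene_models: dict[str, GeneModel]) -> np.ndarray:
    """Strand-specific substitution class per SNV row (-1 where unavailable).

    The ``context`` column is coding-strand; genomic ref/alt are complemented
    for minus-strand genes before classification.
    """
    out = np.full(len(catalog), -1, dtype=np.int16)
    strands = {g: gm.strand for g, gm in gene_models.items()}
    for i, (gene, ctx, ref, alt, non_snv) in enumerate(
        zip(
            catalog["gene_id"],
            catalog["context"],
            catalog["ref_allele"],
            catalog["alt_allele"],
            catalog["non_snv"],
        )
    ):
        if non_snv or not isinstance(ctx, str) or gene not in strands:
            continue
        if strands[gene] == "-":
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        if ctx[1] != ref:
            raise ValueError(
                f"context middle base {ctx[1]} != coding-strand ref {ref} for {gene}"
            )
        out[i] = class192(ctx[0], ref, alt, ctx[2])
    return out


def fit_context_rates(
    catalog: pd.DataFrame,
    impact_matrices: dict[str, ImpactMatrix],
    gene_models: dict[str, GeneModel],
    max_iter: int = 50,
    tol: float = 1e-10,
) -> ContextRateModel:
    """Estimate 192 context rates by joint Poisson maximum likelihood.

    Counts per (class s, impact k) follow ``n_sk ~ Pois(r_s L_sk w_k)`` with
    ``w_syn = 1`` and shared cohort-wide selection factors ``w_mis, w_non``
    (nuisance parameters here). Alternating closed-form updates converge in a
    few iterations. Fitting on all impact classes, not synonymous counts
    alone, is essential: some substitution classes have zero synonymous
    opportunity anywhere in the genome (structural zeros of the genetic
    code), and a syn-only estimator would assign them zero rate and deflate
    every expected nonsynonymous count. The synonymous counts still anchor
    the absolute scale through ``w_syn = 1``. Sparse classes (no observed
    mutations and < 100 opportunities) borrow the pyrimidine-collapsed
    estimate of their reverse-complement partner.
    """
    snv = catalog[
        catalog["variant_class"].isin(("synonymous", "missense", "nonsense"))
        & (~catalog["non_snv"])
    ]
    if (snv["variant_class"] == "synonymous").sum() == 0:
        raise ValueError(
            "no synonymous mutations: pool cohorts or use ContextRateModel.uniform()"
        )
    cls = catalog_class192(snv, gene_models)
    imp = snv["variant_class"].map(_IMPACT_CODE).to_numpy()
    ok = cls >= 0
    n = np.zeros((192, 3))
    np.add.at(n, (cls[ok], imp[ok]), 1.0)
    L = sum(im.L for im in impact_matrices.values()).astype(float)  # (192, 3)

    w = np.array([1.0, 1.0, 1.0])
    n_tot = n.sum(axis=1)
    r = np.zeros(192)
    for _ in range(max_iter):
        denom = L @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            r_new = np.where(denom > 0, n_tot / denom, 0.0)
        col = r_new @ L  # expected counts per impact at w = 1
        w_new = w.copy()
        for k in (1, 2):
            w_new[k] = n[:, k].sum() / col[k] if col[k] > 0 else 0.0
        if np.abs(w_new - w).max() < tol and np.abs(r_new - r).max() < tol:
            r, w = r_new, w_new
            break
        r, w = r_new, w_new

    # pyrimidine-collapsed sharing for classes with no observed mutations
    n96 = n_tot + n_tot[PARTNER_192]
    denom = L @ w
    denom96 = denom + denom[PARTNER_192]
    with np.errstate(divide="ignore", invalid="ignore"):
        r96 = np.where(denom96 > 0, n96 / denom96, 0.0)
    sparse = (n_tot < 1) & (L.sum(axis=1) < 100)
    r = np.where(sparse, r96, r)
    if float(r @ L[:, 0]) <= 0:
        raise ValueError("degenerate rate fit: zero rate-weighted opportunity")
    return ContextRateModel(r=r)


# ---------------------------------------------------------------------------
# per-gene estimates


@dataclass
class GeneDnDsResult:
    gene_id: str
    n_syn: int
    n_mis: int
    n_non: int
    E_mis: float
    E_non: float
    w_mis: float
    w_non: float
    ci_mis: tuple[float, float]
    ci_non: tuple[float, float]
    p_mis: float
    p_non: float
    p_global: float
    flagged: bool = False
    q_mis: float = field(default=np.nan)
    q_non: float = field(default=np.nan)
    q_global: float = field(default=np.nan)


def _count_impacts(catalog: pd.DataFrame) -> np.ndarray:
    n = np.zeros(3, dtype=np.int64)
    snv = catalog[~catalog["non_snv"]]
    for name, k in _IMPACT_CODE.items():
        n[k] = int((snv["variant_class"] == name).sum())
    return n


def _poisson_ll(n: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood without the factorial constant; 0*log0 = 0."""
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(mu), 0.0)
    return float(term.sum() - mu.sum())


def _lrt_w_eq_1(n_s: float, n_k: float, E_s: float, E_k: float) -> float:
    """LRT p-value for w_k = 1 in the two-count Poisson model (chi2, 1 df)."""
    ll_alt = _poisson_ll(np.array([n_s, n_k]), np.array([max(n_s, 1e-300), max(n_k, 1e-300)]))
    t0 = (n_s + n_k) / (E_s + E_k)
    ll_null = _poisson_ll(np.array([n_s, n_k]), np.array([t0 * E_s, t0 * E_k]))
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(chi2.sf(stat, 1))


def _profile_ci(n_s: float, n_k: float, E_s: float, E_k: float, w_hat: float):
    """95% profile-likelihood CI for w_k, profiling out t."""

    def pll(w):
        t = (n_s + n_k) / (E_s + w * E_k)
        return _poisson_ll(np.array([n_s, n_k]), np.array([t * E_s, w * t * E_k]))

    ll_max = pll(w_hat) if w_hat > 0 else pll(1e-12)

    def drop(w):
        return ll_max - pll(w) - _CI_DROP

    if n_k == 0:
        lo = 0.0
    else:
        w_lo_bracket = w_hat
        lo_left = w_hat * 1e-6
        lo = brentq(drop, lo_left, w_lo_bracket) if drop(lo_left) > 0 else 0.0
    hi_guess = max(w_hat, 1e-6)
    hi_right = hi_guess * 2
    while drop(hi_right) < 0 and hi_right < 1e12:
        hi_right *= 4
    hi = brentq(drop, hi_guess, hi_right) if drop(hi_right) >= 0 else np.inf
    return lo, hi


def gene_dnds(
    gene: GeneModel | str,
    catalog: pd.DataFrame,
    rates: ContextRateModel,
    impact_matrix: ImpactMatrix | None = None,
    compute_ci: bool = True,
) -> GeneDnDsResult:
    """Per-gene dN/dS estimates with LRT p-values and profile-likelihood CIs."""
    if impact_matrix is None:
        if isinstance(gene, str):
            raise ValueError("need a GeneModel or an ImpactMatrix")
        impact_matrix = build_impact_matrix(gene)
    gene_id = impact_matrix.gene_id
    sub = catalog[catalog["gene_id"] == gene_id]
    n = _count_impacts(sub)
    E_tilde = rates.weighted_opportunity(impact_matrix.L)  # (3,)

    if E_tilde[0] <= 0 or n[0] == 0:
        # zero synonymous opportunity or zero observed synonymous: w undefined
        return GeneDnDsResult(
            gene_id=gene_id,
            n_syn=int(n[0]),
            n_mis=int(n[1]),
            n_non=int(n[2]),
            E_mis=np.nan,
            E_non=np.nan,
            w_mis=np.nan,
            w_non=np.nan,
            ci_mis=(np.nan, np.nan),
            ci_non=(np.nan, np.nan),
            p_mis=np.nan,
            p_non=np.nan,
            p_global=np.nan,
            flagged=True,
        )

    t_hat = n[0] / E_tilde[0]
    E = t_hat * E_tilde  # expected counts under neutrality
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(E[1:] > 0, n[1:] / E[1:], np.nan)

    p = [np.nan, np.nan]
    ci = [(np.nan, np.nan), (np.nan, np.nan)]
    for j, k in enumerate((1, 2)):
        if E_tilde[k] > 0:
            p[j] = _lrt_w_eq_1(n[0], n[k], E_tilde[0], E_tilde[k])
            if compute_ci:
                ci[j] = _profile_ci(n[0], n[k], E_tilde[0], E_tilde[k], w[j])

    # joint test of w_mis = w_non = 1 (2 df)
    if E_tilde[1] > 0 and E_tilde[2] > 0:
        ll_alt = _poisson_ll(n, np.maximum(n, 1e-300))
        t0 = n.sum() / E_tilde.sum()
        ll_null = _poisson_ll(n, t0 * E_tilde)
        p_global = float(chi2.sf(max(0.0, 2 * (ll_alt - ll_null)), 2))
    else:
        p_global = np.nan

    return GeneDnDsResult(
        gene_id=gene_id,
        n_syn=int(n[0]),
        n_mis=int(n[1]),
        n_non=int(n[2]),
        E_mis=float(E[1]),
        E_non=float(E[2]),
        w_mis=float(w[0]),
        w_non=float(w[1]),
        ci_mis=ci[0],
        ci_non=ci[1],
        p_mis=p[0],
        p_non=p[1],
        p_global=p_global,
    )


def gene_dnds_table(
    impact_matrices: dict[str, ImpactMatrix],
    catalog: pd.DataFrame,
    rates: ContextRateModel,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Gene-level dN/dS for every gene, with BH q-values per impact class."""
    rows = []
    by_gene = dict(tuple(catalog.groupby("gene_id", sort=False)))
    empty = catalog.iloc[0:0]
    for gene_id, im in impact_matrices.items():
        res = gene_dnds(
            gene_id,
            by_gene.get(gene_id, empty),
            rates,
            impact_matrix=im,
            compute_ci=compute_ci,
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "n_syn": res.n_syn,
                "n_mis": res.n_mis,
                "n_non": res.n_non,
                "E_mis": res.E_mis,
                "E_non": res.E_non,
                "w_mis": res.w_mis,
                "w_mis_lo": res.ci_mis[0],
                "w_mis_hi": res.ci_mis[1],
                "w_non": res.w_non,
                "w_non_lo": res.ci_non[0],
                "w_non_hi": res.ci_non[1],
                "p_mis": res.p_mis,
                "p_non": res.p_non,
                "p_global": res.p_global,
                "flagged": res.flagged,
            }
        )
    df = pd.DataFrame(rows)
    for cls in ("mis", "non", "global"):
        df[f"q_{cls}"] = bh_adjust(df[f"p_{cls}"].to_numpy())
    return df


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


_OLFACTORY_RE = re.compile(r"^OR\d+[A-Z]+\d*$")


def call_drivers(
    results: pd.DataFrame,
    q_threshold: float = 0.1,
    exclude_olfactory: bool = False,
    olfactory_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Flag significant drivers: w > 1 AND BH q < threshold, per impact class.

    BH is recomputed over all tested genes (after optional removal of
    olfactory receptors, which are spuriously mutated in cancer).
    """
    if results.empty:
        raise ValueError("empty results table")
    df = results.copy()
    if exclude_olfactory:
        if olfactory_genes is None:
            drop = df["gene_id"].map(lambda g: bool(_OLFACTORY_RE.match(g)))
        else:
            drop = df["gene_id"].isin(olfactory_genes)
        df = df[~drop].copy()
    for cls in ("mis", "non"):
        df[f"q_{cls}"] = bh_adjust(df[f"p_{cls}"].to_numpy())
        df[f"significant_{cls}"] = (df[f"w_{cls}"] > 1) & (df[f"q_{cls}"] < q_threshold)
    return df


# ---------------------------------------------------------------------------
# pooled (global / driver) estimates


@dataclass
class GlobalDnDs:
    gene_set_label: str
    w: float  # pooled missense+nonsense omega
    ci: tuple[float, float]
    w_mis: float
    ci_mis: tuple[float, float]
    w_non: float
    ci_non: tuple[float, float]
    n_syn: int
    n_mis: int
    n_non: int
    E_syn: float
    E_mis: float
    E_non: float


def _wald_ratio_ci(w: float, n_num: float, n_den: float) -> tuple[float, float]:
    if w <= 0 or n_num == 0 or n_den == 0:
        return (0.0, np.inf) if n_num == 0 else (np.nan, np.nan)
    se = np.sqrt(1.0 / n_num + 1.0 / n_den)
    return float(w * np.exp(-1.959963984540054 * se)), float(w * np.exp(1.959963984540054 * se))


def global_dnds(
    gene_set: list[str],
    catalog: pd.DataFrame,
    rates: ContextRateModel,
    impact_matrices: dict[str, ImpactMatrix],
    label: str = "custom",
) -> GlobalDnDs:
    """Pooled dN/dS over a gene set (global or known-driver style).

    ``w = (sum n_N / sum E~_N) / (sum n_S / sum E~_S)`` with rate-weighted
    opportunities summed over the set; Wald CI on log w with variance
    ``1/sum n_N + 1/sum n_S``.
    """
    genes = [g for g in gene_set if g in impact_matrices]
    if not genes:
        raise ValueError("gene set has no overlap with available impact matrices")
    sub = catalog[catalog["gene_id"].isin(genes)]
    n = _count_impacts(sub)
    L_sum = np.zeros((192, 3))
    for g in genes:
        L_sum += impact_matrices[g].L
    E = rates.weighted_opportunity(L_sum)
    if E[0] <= 0 or n[0] == 0:
        raise ValueError("no synonymous information in gene set")
    syn_rate = n[0] / E[0]

    def ratio(nk, Ek):
        return float((nk / Ek) / syn_rate) if Ek > 0 else np.nan

    w_all = ratio(n[1] + n[2], E[1] + E[2])
    w_mis = ratio(n[1], E[1])
    w_non = ratio(n[2], E[2])
    return GlobalDnDs(
        gene_set_label=label,
        w=w_all,
        ci=_wald_ratio_ci(w_all, n[1] + n[2], n[0]),
        w_mis=w_mis,
        ci_mis=_wald_ratio_ci(w_mis, n[1], n[0]),
        w_non=w_non,
        ci_non=_wald_ratio_ci(w_non, n[2], n[0]),
        n_syn=int(n[0]),
        n_mis=int(n[1]),
        n_non=int(n[2]),
        E_syn=float(E[0]),
        E_mis=float(E[1]),
        E_non=float(E[2]),
    )


def bootstrap_global_dnds(
    catalog: pd.DataFrame,
    patients: np.ndarray,
    gene_set: list[str],
    rates: ContextRateModel,
    impact_matrices: dict[str, ImpactMatrix],
    B: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Patient-level bootstrap replicates of the pooled omega.

    Because the rate-weighted opportunities are fixed, each replicate's omega
    is ``(sum n_N / E_N) / (sum n_S / E_S)`` with counts summed over the
    resampled patients.
    """
    genes = [g for g in gene_set if g in impact_matrices]
    sub = catalog[catalog["gene_id"].isin(genes) & ~catalog["non_snv"]]
    patients = np.asarray(patients)
    pat_index = pd.Index(patients)
    per_patient = np.zeros((len(patients), 2))  # syn, nonsyn columns
    is_syn = sub["variant_class"] == "synonymous"
    is_nonsyn = sub["variant_class"].isin(["missense", "nonsense"])
    for col, mask in enumerate((is_syn, is_nonsyn)):
        counts = sub[mask].groupby("patient_id").size()
        counts = counts.reindex(pat_index, fill_value=0)
        per_patient[:, col] = counts.to_numpy()
    E = np.zeros(3)
    for g in genes:
        E += rates.weighted_opportunity(impact_matrices[g].L)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(patients), size=(B, len(patients)))
    sums = per_patient[idx].sum(axis=1)  # (B, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (sums[:, 1] / (E[1] + E[2])) / (sums[:, 0] / E[0])
    return omega


def compare_group_dnds(replicates_a: np.ndarray, replicates_b: np.ndarray):
    """Mann-Whitney comparison of two patient-bootstrap omega vectors.

    Returns ``(p_value, ci_a, ci_b, ci_nonoverlap)`` where the CIs are the
    2.5-97.5 percentile bands of the replicate vectors.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if len(a) < 20 or len(b) < 20:
        raise ValueError("need at least 20 bootstrap replicates per group")
    if np.array_equal(a, b):
        p = 1.0
    else:
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    ci_a = tuple(np.percentile(a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(b, [2.5, 97.5]))
    nonoverlap = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
    return p, ci_a, ci_b, bool(nonoverlap)
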