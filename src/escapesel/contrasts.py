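"""Cohort-level contrasts between escape groups.

The randomized escape-gene null, mutation-vs-unique-site hotspot
concentration tests, downsampling controls, hotspot exclusion, the
oncogene/TSG split and VAF clonality comparisons. Chi-square tests are
Pearson without continuity correction throughout (declared choice, stated
in the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu

from .dnds import ContextRateModel, ImpactMatrix, bh_adjust, global_dnds
from .genome import GeneModel
from .io import DEFAULT_NONSILENT

logger = logging.getLogger(__name__)

NONSYN_SNV = ("missense", "nonsense")


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2
    chi2: float
    df: int
    p: float
    labels: tuple[tuple[str, str], tuple[str, str]]
    flagged: bool = False


@dataclass
class RandomNullResult:
    reps: int
    observed_driver_w: float
    null_driver_w: np.ndarray
    empirical_p: float


def _chi2_2x2(table: np.ndarray, labels) -> ContingencyResult:
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ContingencyResult(table, np.nan, 1, np.nan, labels, flagged=True)
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        # proportional rows: chi2 exactly 0 (avoid tiny float noise)
        return ContingencyResult(table, 0.0, 1, 1.0, labels)
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return ContingencyResult(table, float(chi2), 1, float(p), labels)


# ---------------------------------------------------------------------------
# randomized escape-gene null


def random_escape_null(
    catalog: pd.DataFrame,
    all_genes: list[str],
    escape_genes: list[str],
    driver_genes: list[str],
    rates: ContextRateModel,
    impact_matrices: dict[str, ImpactMatrix],
    k: int | None = None,
    reps: int = 100,
    seed: int = 0,
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
    min_pseudo: int = 5,
    max_retries: int = 20,
) -> RandomNullResult:
    """Null distribution of driver dN/dS under random escape-gene lists.

    Each rep draws ``k`` genes uniformly from non-escape genes, marks
    non-truly-escaped patients with a non-silent SNV in the drawn set as
    pseudo-escape+, and computes the pooled driver-set omega on that pseudo
    cohort. The observed value is the driver omega of the true escape+
    cohort; the empirical p is one-sided lower with the (r+1)/(B+1)
    convention.
    """
    k = k or len(escape_genes)
    pool = sorted(set(all_genes) - set(escape_genes))
    if len(pool) < k:
        raise ValueError(f"need >= {k} non-escape genes, have {len(pool)}")
    rng = np.random.default_rng(seed)

    nonsil = catalog[catalog["variant_class"].isin(nonsilent_classes)]
    true_pos = set(nonsil.loc[nonsil["gene_id"].isin(escape_genes), "patient_id"])
    eligible = nonsil[~nonsil["patient_id"].isin(true_pos)]
    # patient x gene non-silent incidence over the candidate pool
    inc = (
        eligible[eligible["gene_id"].isin(pool)]
        .groupby(["patient_id", "gene_id"])
        .size()
        .clip(upper=1)
        .unstack(fill_value=0)
        .reindex(columns=pool, fill_value=0)
    )

    observed = global_dnds(
        driver_genes,
        catalog[catalog["patient_id"].isin(true_pos)],
        rates,
        impact_matrices,
        label="true_escape_pos",
    ).w

    null = np.empty(reps)
    for r in range(reps):
        for attempt in range(max_retries):
            draw = rng.choice(len(pool), size=k, replace=False)
            pseudo = inc.index[inc.iloc[:, draw].to_numpy().any(axis=1)]
            if len(pseudo) < min_pseudo:
                logger.info(
                    "rep %d: only %d pseudo-escape patients, redrawing", r, len(pseudo)
                )
                continue
            try:
                null[r] = global_dnds(
                    driver_genes,
                    catalog[catalog["patient_id"].isin(pseudo)],
                    rates,
                    impact_matrices,
                    label=f"rep{r}",
                ).w
                break
            except ValueError:
                # pseudo cohort without synonymous driver mutations: redraw
                logger.info("rep %d: degenerate pseudo cohort, redrawing", r)
        else:
            raise RuntimeError(f"rep {r}: could not draw a usable pseudo cohort")
    emp_p = (1 + int((null <= observed).sum())) / (reps + 1)
    return RandomNullResult(
        reps=reps, observed_driver_w=observed, null_driver_w=null, empirical_p=emp_p
    )


# ---------------------------------------------------------------------------
# hotspot concentration


def _mut_site_counts(catalog: pd.DataFrame, unit: str = "position", gene_models=None):
    """Total nonsynonymous SNV count and distinct mutated sites.

    ``unit``: 'position' counts distinct genomic positions (default,
    stricter); 'codon' collapses the three positions of a codon and
    requires gene models for the protein-coordinate mapping.
    """
    sub = catalog[catalog["variant_class"].isin(NONSYN_SNV) & ~catalog["non_snv"]]
    if unit == "codon":
        if gene_models is None:
            raise ValueError("unit='codon' requires gene_models")
        codons = []
        for g, pos in zip(sub["gene_id"], sub["position"]):
            codons.append(f"{g}:{gene_models[g].cds_index_of(int(pos)) // 3}")
        sites = pd.Series(codons, index=sub.index, dtype=object)
    else:
        sites = sub["gene_id"].astype(str) + ":" + sub["position"].astype(str)
    return len(sub), sites.nunique(), sub


def site_concentration_test(
    catalog: pd.DataFrame,
    gene: str,
    labels: pd.DataFrame,
    unit: str = "position",
    gene_models=None,
) -> tuple[ContingencyResult, pd.DataFrame]:
    """Mutation count vs distinct mutated sites, escape- vs escape+.

    A hotspot-concentrated gene shows many mutations over few sites in one
    group. Also returns the per-position tally table (lolliplot export).
    """
    lab = labels.set_index("patient_id")["status"]
    sub = catalog[catalog["gene_id"] == gene].copy()
    sub["status"] = sub["patient_id"].map(lab)
    rows = []
    for grp in ("escape_neg", "escape_pos"):
        n_mut, n_sites, _ = _mut_site_counts(sub[sub["status"] == grp], unit, gene_models)
        rows.append([n_mut, n_sites])
    table = np.array(rows)
    res = _chi2_2x2(
        table, (("escape_neg", "escape_pos"), ("n_mutations", "n_unique_sites"))
    )
    nonsyn = sub[sub["variant_class"].isin(NONSYN_SNV)]
    lolli = (
        nonsyn.groupby(["status", "position", "variant_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .assign(gene=gene)
    )
    return res, lolli


def pooled_concentration_test(
    catalog: pd.DataFrame,
    gene_set: list[str],
    labels: pd.DataFrame,
    unit: str = "position",
    gene_models=None,
) -> ContingencyResult:
    """Element-wise sum of per-gene mutation/site tables, then chi-square."""
    if not gene_set:
        raise ValueError("empty gene set")
    total = np.zeros((2, 2), dtype=int)
    for g in gene_set:
        res, _ = site_concentration_test(catalog, g, labels, unit, gene_models)
        total += res.table.astype(int)
    return _chi2_2x2(
        total, (("escape_neg", "escape_pos"), ("n_mutations", "n_unique_sites"))
    )


# ---------------------------------------------------------------------------
# downsampling and hotspot exclusion


def downsample(
    catalog: pd.DataFrame,
    labels: pd.DataFrame,
    target: str = "patients",
    seed: int = 0,
    draws: int = 1,
):
    """Equalize group sizes by uniform sampling without replacement.

    ``target='patients'`` subsamples patients of the larger group;
    ``target='mutations'`` subsamples mutation rows. Returns one reduced
    catalog, or a list of ``draws`` catalogs for stability assessment.
    """
    lab = labels.set_index("patient_id")["status"]
    cat = catalog.copy()
    cat["_status"] = cat["patient_id"].map(lab)
    rng = np.random.default_rng(seed)

    def one_draw():
        if target == "patients":
            pats = {
                g: labels.loc[labels["status"] == g, "patient_id"].to_numpy()
                for g in ("escape_neg", "escape_pos")
            }
            sizes = {g: len(p) for g, p in pats.items()}
            big = max(sizes, key=sizes.get)
            small = min(sizes, key=sizes.get)
            if sizes[big] == sizes[small]:
                logger.warning("groups already equal; downsample is a no-op")
                return catalog.copy()
            keep = set(rng.choice(pats[big], size=sizes[small], replace=False))
            keep |= set(pats[small])
            return catalog[catalog["patient_id"].isin(keep)].copy()
        elif target == "mutations":
            sizes = cat["_status"].value_counts()
            if sizes.min() == sizes.max():
                logger.warning("groups already equal; downsample is a no-op")
                return catalog.copy()
            big = sizes.idxmax()
            idx_big = cat.index[cat["_status"] == big].to_numpy()
            keep = rng.choice(idx_big, size=int(sizes.min()), replace=False)
            idx = np.sort(np.concatenate([keep, cat.index[cat["_status"] != big].to_numpy()]))
            return catalog.loc[idx].copy()
        raise ValueError("target must be 'patients' or 'mutations'")

    if draws == 1:
        return one_draw()
    return [one_draw() for _ in range(draws)]


def exclude_hotspots(
    catalog: pd.DataFrame,
    hotspots: dict[str, list[int]],
    gene_models: dict[str, GeneModel],
) -> tuple[pd.DataFrame, int]:
    """Drop SNVs falling in listed hotspot codons (1-based protein positions).

    Returns the reduced catalog and the number of removed records.
    """
    remove = pd.Series(False, index=catalog.index)
    for gene, positions in hotspots.items():
        gm = gene_models[gene]
        gpos = np.concatenate([gm.codon_genomic_positions(p) for p in np.atleast_1d(positions)])
        remove |= (catalog["gene_id"] == gene) & catalog["position"].isin(gpos)
    kept = catalog[~remove].copy()
    return kept, int(remove.sum())


# ---------------------------------------------------------------------------
# oncogene / TSG proportions


def onc_tsg_proportions(
    catalog: pd.DataFrame, labels: pd.DataFrame, role_annotation: dict[str, str]
) -> ContingencyResult:
    """2x2 test of missense counts: {oncogene, TSG} x {escape-, escape+}.

    Genes annotated 'both' count in both rows (flagged); 'none' is excluded.
    """
    if not role_annotation:
        raise ValueError("empty role annotation")
    lab = labels.set_index("patient_id")["status"]
    mis = catalog[(catalog["variant_class"] == "missense") & ~catalog["non_snv"]].copy()
    mis["status"] = mis["patient_id"].map(lab)
    table = np.zeros((2, 2), dtype=int)
    has_both = False
    for gi, roles in (("oncogene", ("oncogene", "both")), ("TSG", ("TSG", "both"))):
        row = 0 if gi == "oncogene" else 1
        genes = [g for g, r in role_annotation.items() if r in roles]
        has_both |= any(role_annotation.get(g) == "both" for g in genes)
        sub = mis[mis["gene_id"].isin(genes)]
        for col, grp in enumerate(("escape_neg", "escape_pos")):
            table[row, col] = int((sub["status"] == grp).sum())
    res = _chi2_2x2(table, (("oncogene", "TSG"), ("escape_neg", "escape_pos")))
    res.flagged = res.flagged or has_both
    return res


# ---------------------------------------------------------------------------
# VAF clonality


def vaf_compare(
    catalog: pd.DataFrame,
    driver_genes: list[str],
    escape_genes: list[str],
    scope: str = "pancancer",
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
    min_n: int = 10,
) -> pd.DataFrame:
    """Mann-Whitney comparison of VAFs: driver vs escape non-silent SNVs.

    ``scope='per-type'`` runs per cancer type with BH adjustment across
    types. Strata with < ``min_n`` VAF values on either side are reported
    with missing results.
    """
    sub = catalog[
        catalog["variant_class"].isin(nonsilent_classes)
        & ~catalog["non_snv"]
        & catalog["vaf"].notna()
    ]
    drv = sub[sub["gene_id"].isin(driver_genes)]
    esc = sub[sub["gene_id"].isin(escape_genes)]
    strata = [("pancancer", drv, esc)]
    if scope == "per-type":
        strata = [
            (ct, drv[drv["cancer_type"] == ct], esc[esc["cancer_type"] == ct])
            for ct in sorted(sub["cancer_type"].unique())
        ]
    rows = []
    for name, d, e in strata:
        if len(d) < min_n or len(e) < min_n:
            rows.append(
                {"stratum": name, "n_driver": len(d), "n_escape": len(e),
                 "median_driver": np.nan, "median_escape": np.nan, "U": np.nan, "p": np.nan}
            )
            continue
        u = mannwhitneyu(d["vaf"], e["vaf"], alternative="two-sided")
        rows.append(
            {
                "stratum": name,
                "n_driver": len(d),
                "n_escape": len(e),
                "median_driver": float(d["vaf"].median()),
                "median_escape": float(e["vaf"].median()),
                "U": float(u.statistic),
                "p": float(u.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
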