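"""Escape-status stratification and cohort composition summaries.

Three schemes:

* point-mutation: escape+ iff the patient carries >= 1 non-silent SNV in an
  escape gene (the primary definition);
* CNV categories A-F over escape-gene deletions (overlapping flags, since
  the definitions are non-disjoint: C contains B, F contains D; there is no
  category E in this vocabulary);
* PD-L1 (CD274) expression quartiles within cancer type (bottom 25% low,
  top 25% high).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import DEFAULT_NONSILENT


def classify_point_mutation(
    catalog: pd.DataFrame,
    escape_genes: list[str],
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
) -> pd.DataFrame:
    """Escape labels from non-silent escape-gene mutations.

    Returns one row per patient in the catalog: ``status`` in
    {escape_pos, escape_neg} and the semicolon-joined ``triggering_genes``.
    Synonymous escape-gene mutations never trigger.
    """
    if not escape_genes:
        raise ValueError("escape gene list is empty")
    hits = catalog[
        catalog["gene_id"].isin(escape_genes)
        & catalog["variant_class"].isin(nonsilent_classes)
    ]
    trig = hits.groupby("patient_id")["gene_id"].agg(lambda g: ";".join(sorted(set(g))))
    patients = pd.Index(catalog["patient_id"].unique(), name="patient_id")
    trig = trig.reindex(patients, fill_value="")
    return pd.DataFrame(
        {
            "patient_id": patients,
            "status": np.where(trig.to_numpy() != "", "escape_pos", "escape_neg"),
            "triggering_genes": trig.to_numpy(),
        }
    ).reset_index(drop=True)


def classify_cnv_categories(
    catalog: pd.DataFrame, cnv_table: pd.DataFrame, escape_genes: list[str]
) -> pd.DataFrame:
    """Overlapping escape categories from point mutations and deletions.

    A: no escape point mutation and no escape-gene deletion (CN >= 2 in all).
    B: >= 1 hemizygous deletion (CN = 1), no point mutation.
    C: homo- or hemizygous deletion (CN <= 1), no point mutation (C contains B).
    D: point mutation or hemizygous deletion.
    F: any mutation (point or deletion) in an escape gene (F contains D).
    """
    if ((cnv_table["copy_number"] < 0) | (cnv_table["copy_number"] > 20)).any():
        raise ValueError("copy numbers outside [0, 20]")
    pm = classify_point_mutation(catalog, escape_genes).set_index("patient_id")
    esc_cnv = cnv_table[cnv_table["gene_id"].isin(escape_genes)]
    mins = esc_cnv.groupby("patient_id")["copy_number"].min()
    patients = pm.index.union(mins.index)
    has_pm = pm["status"].reindex(patients, fill_value="escape_neg") == "escape_pos"
    min_cn = mins.reindex(patients, fill_value=2)
    hemi = min_cn == 1
    any_del = min_cn <= 1
    return pd.DataFrame(
        {
            "patient_id": patients,
            "cat_A": (~has_pm & ~any_del).to_numpy(),
            "cat_B": (hemi & ~has_pm).to_numpy(),
            "cat_C": (any_del & ~has_pm).to_numpy(),
            "cat_D": (has_pm | hemi).to_numpy(),
            "cat_F": (has_pm | any_del).to_numpy(),
        }
    ).reset_index(drop=True)


def classify_pdl1(
    expression: pd.DataFrame,
    gene: str = "CD274",
    cancer_types: pd.Series | None = None,
) -> pd.DataFrame:
    """PD-L1 expression strata: within-cancer-type quartiles.

    ``expression`` is long (patient_id, gene_id, fpkm); ``cancer_types`` maps
    patient_id -> cancer type (single pooled type when absent). Bottom 25%
    -> low, top 25% -> high, remainder mid; ties at a cut go to mid.
    """
    expr = expression[expression["gene_id"] == gene][["patient_id", "fpkm"]].copy()
    if expr.empty:
        raise ValueError(f"gene {gene} absent from expression table")
    if cancer_types is not None:
        expr["cancer_type"] = expr["patient_id"].map(cancer_types)
    else:
        expr["cancer_type"] = "ALL"
    out = []
    for ct, grp in expr.groupby("cancer_type"):
        vals = grp["fpkm"].to_numpy(dtype=float)
        if len(vals) < 8:
            stratum = np.full(len(vals), "missing", dtype=object)
        elif np.allclose(vals, vals[0]):
            warnings.warn(f"all-identical PD-L1 expression in {ct}; everyone mid")
            stratum = np.full(len(vals), "mid", dtype=object)
        else:
            q1, q3 = np.quantile(vals, [0.25, 0.75])  # type-7 linear interpolation
            stratum = np.where(vals < q1, "low", np.where(vals > q3, "high", "mid"))
        out.append(
            pd.DataFrame(
                {"patient_id": grp["patient_id"], "pdl1_stratum": stratum}
            )
        )
    return pd.concat(out, ignore_index=True)


def cohort_summary(
    catalog: pd.DataFrame,
    labels: pd.DataFrame,
    escape_genes: list[str] | None = None,
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
) -> dict:
    """Per-group / per-cancer-type composition and escape-gene frequencies.

    Returns ``summary`` (patients, mean TMB, mean counts per variant class),
    ``frequency`` (gene x cancer type fraction of patients with a non-silent
    SNV), and average-linkage (Euclidean) leaf orders for genes and types.
    """
    lab = labels.set_index("patient_id")["status"]
    cat = catalog.copy()
    cat["status"] = cat["patient_id"].map(lab)
    per_pat = (
        cat.groupby(["patient_id", "status", "cancer_type"], observed=True)
        .size()
        .rename("tmb")
        .reset_index()
    )
    summary = (
        per_pat.groupby(["status", "cancer_type"])
        .agg(n_patients=("patient_id", "nunique"), mean_tmb=("tmb", "mean"))
        .reset_index()
    )
    class_counts = (
        cat.groupby(["status", "cancer_type", "variant_class"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    n_pat = per_pat.groupby(["status", "cancer_type"])["patient_id"].nunique()
    class_means = class_counts.div(n_pat, axis=0).reset_index()
    summary = summary.merge(class_means, on=["status", "cancer_type"], how="left")

    result = {"summary": summary}
    if escape_genes:
        hits = cat[
            cat["gene_id"].isin(escape_genes) & cat["variant_class"].isin(nonsilent_classes)
        ]
        pat_types = cat.drop_duplicates("patient_id").set_index("patient_id")["cancer_type"]
        n_per_type = pat_types.value_counts()
        freq = (
            hits.drop_duplicates(["patient_id", "gene_id"])
            .groupby(["gene_id", "cancer_type"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=sorted(escape_genes), fill_value=0)
        )
        freq = freq.div(n_per_type.reindex(freq.columns), axis=1).fillna(0.0)
        result["frequency"] = freq
        orders = {}
        for axis, mat in (("genes", freq.to_numpy()), ("types", freq.to_numpy().T)):
            if mat.shape[0] >= 2:
                Z = linkage(mat, method="average", metric="euclidean")
                orders[axis] = list(leaves_list(Z))
            else:
                orders[axis] = list(range(mat.shape[0]))
        result["gene_order"] = orders["genes"]
        result["type_order"] = orders["types"]
    return result
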