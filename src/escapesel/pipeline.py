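"""End-to-end orchestration: simulate or ingest -> classify -> per-group
dN/dS -> contrasts -> signatures -> survival, with a machine-readable run
manifest (content hashes for every output)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts as ct
from . import dnds, signatures, stratify, survival
from .io import (
    DEFAULT_NONSILENT,
    read_gene_list,
    read_gene_models,
    read_maf,
    read_signature_catalog,
    read_tables,
)
from .simulate import CohortSimConfig, default_signature_catalog, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-file configuration for `escapesel run`.

    Exactly one of ``inputs`` (paths to MAF/FASTA/models/clinical tables) or
    ``simulation`` (a CohortSimConfig) must be given.
    """

    outdir: str = "escapesel_run"
    seed: int = 0
    inputs: dict | None = None
    simulation: CohortSimConfig | None = None
    escape_genes: list[str] | None = None
    driver_genes: list[str] | None = None
    q_threshold: float = 0.1
    nonsilent_classes: tuple[str, ...] = tuple(sorted(DEFAULT_NONSILENT))
    randnull_reps: int = 100
    bootstrap_B: int = 200

    def __post_init__(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of inputs/simulation must be configured")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulation", None)
    if sim is not None:
        sim = CohortSimConfig(**sim)
    return RunConfig(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}" + (f" ({hint})" if hint else ""))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; completed outputs survive a
    failed later stage, and the manifest names the failed stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}, "failed_stage": None}

    def emit(name: str, df: pd.DataFrame):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(p)

    def finish(stage, err=None, hint=""):
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if err is not None:
            manifest["failed_stage"] = stage
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(stage, err, hint)

    # -- stage: ingest / simulate ----------------------------------------
    stage = "ingest"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate(sim)
            gene_models = cohort.genome.genes
            catalog = cohort.catalog
            clinical, expression, cnv = cohort.clinical, cohort.expression, cohort.cnv
            escape_genes = config.escape_genes or list(sim.escape_genes)
            driver_genes = config.driver_genes or list(sim.driver_genes)
            sig_catalog = sim.signature_catalog or default_signature_catalog()
            paths = cohort.write(outdir / "inputs")
            for k, p in paths.items():
                manifest["outputs"][f"inputs/{Path(p).name}"] = _sha256(Path(p))
        else:
            inp = config.inputs
            gene_models = read_gene_models(inp["fasta"], inp["gene_models"])
            catalog = read_maf(inp["maf"], gene_models).records
            clinical, expression, cnv = read_tables(
                inp["clinical"], inp.get("expression"), inp.get("cnv")
            )
            escape_genes = config.escape_genes or read_gene_list(inp["escape_genes"])
            driver_genes = config.driver_genes or read_gene_list(inp["driver_genes"])
            sig_catalog = (
                read_signature_catalog(inp["signature_catalog"])
                if inp.get("signature_catalog")
                else default_signature_catalog()
            )
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "check input paths and formats")

    nonsilent = frozenset(config.nonsilent_classes)

    # -- stage: classify ---------------------------------------------------
    stage = "classify"
    try:
        labels = stratify.classify_point_mutation(catalog, escape_genes, nonsilent)
        if cnv is not None:
            cats = stratify.classify_cnv_categories(catalog, cnv, escape_genes)
            labels = labels.merge(cats, on="patient_id", how="left")
        emit("labels.tsv", labels)
        summary = stratify.cohort_summary(catalog, labels, escape_genes, nonsilent)
        emit("cohort_summary.tsv", summary["summary"])
        if "frequency" in summary:
            emit("escape_gene_frequency.tsv", summary["frequency"].reset_index())
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "classification requires a parsed catalog")

    # -- stage: dnds -------------------------------------------------------
    stage = "dnds"
    try:
        impacts = dnds.build_impact_matrices(gene_models)
        pats = {
            g: set(labels.loc[labels["status"] == g, "patient_id"])
            for g in ("escape_neg", "escape_pos")
        }
        globals_rows = []
        rates_by_group = {}
        for grp, pset in pats.items():
            sub = catalog[catalog["patient_id"].isin(pset)]
            if sub.empty:
                continue
            rates = dnds.fit_context_rates(sub, impacts, gene_models)
            rates_by_group[grp] = (rates, sub)
            table = dnds.gene_dnds_table(impacts, sub, rates)
            table = dnds.call_drivers(table, q_threshold=config.q_threshold)
            emit(f"gene_dnds_{grp}.tsv", table)
            for label, gene_set in (
                ("all_genes", list(gene_models)),
                ("known_drivers", driver_genes),
            ):
                g = dnds.global_dnds(gene_set, sub, rates, impacts, label=label)
                globals_rows.append(
                    {
                        "group": grp,
                        "gene_set": label,
                        "w": g.w,
                        "ci_lo": g.ci[0],
                        "ci_hi": g.ci[1],
                        "w_mis": g.w_mis,
                        "w_non": g.w_non,
                        "n_syn": g.n_syn,
                        "n_mis": g.n_mis,
                        "n_non": g.n_non,
                    }
                )
        emit("global_dnds.tsv", pd.DataFrame(globals_rows))
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "dN/dS needs synonymous mutations in both groups")

    # -- stage: contrasts --------------------------------------------------
    stage = "contrasts"
    try:
        rates_all = dnds.fit_context_rates(catalog, impacts, gene_models)
        null = ct.random_escape_null(
            catalog,
            list(gene_models),
            escape_genes,
            driver_genes,
            rates_all,
            impacts,
            reps=config.randnull_reps,
            seed=config.seed,
            nonsilent_classes=nonsilent,
        )
        emit(
            "random_escape_null.tsv",
            pd.DataFrame(
                {
                    "rep": np.arange(null.reps),
                    "null_driver_w": null.null_driver_w,
                    "observed_driver_w": null.observed_driver_w,
                    "empirical_p": null.empirical_p,
                }
            ),
        )
        conc_rows, lollis = [], []
        for g in driver_genes:
            res, lolli = ct.site_concentration_test(catalog, g, labels)
            lollis.append(lolli)
            conc_rows.append(
                {
                    "gene": g,
                    "chi2": res.chi2,
                    "p": res.p,
                    "n_mut_neg": res.table[0, 0],
                    "n_sites_neg": res.table[0, 1],
                    "n_mut_pos": res.table[1, 0],
                    "n_sites_pos": res.table[1, 1],
                    "flagged": res.flagged,
                }
            )
        pooled = ct.pooled_concentration_test(catalog, driver_genes, labels)
        conc_rows.append(
            {
                "gene": "POOLED",
                "chi2": pooled.chi2,
                "p": pooled.p,
                "n_mut_neg": pooled.table[0, 0],
                "n_sites_neg": pooled.table[0, 1],
                "n_mut_pos": pooled.table[1, 0],
                "n_sites_pos": pooled.table[1, 1],
                "flagged": pooled.flagged,
            }
        )
        emit("site_concentration.tsv", pd.DataFrame(conc_rows))
        emit("lolliplot.tsv", pd.concat(lollis, ignore_index=True))
        emit("vaf_compare.tsv", ct.vaf_compare(catalog, driver_genes, escape_genes))
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "contrasts require both escape groups to be populated")

    # -- stage: signatures -------------------------------------------------
    stage = "signatures"
    try:
        spectra = signatures.tabulate_96(catalog, gene_models)
        exposures = {
            pid: signatures.fit_exposures(sp, sig_catalog) for pid, sp in spectra.items()
        }
        rows = []
        for pid, exp in exposures.items():
            for sig, w in exp.weights.items():
                rows.append(
                    {
                        "subject": pid,
                        "signature": sig,
                        "weight": w,
                        "residual_sse": exp.residual_sse,
                        "dominant_flag": sig == exp.dominant,
                    }
                )
        emit("exposures.tsv", pd.DataFrame(rows))
        emit("dominant_signatures.tsv", signatures.dominant_signature_profile(exposures, labels))
        group_exp, group_tot = {}, {}
        for grp, pset in pats.items():
            grp_sp = signatures.pooled_spectrum(
                {p: s for p, s in spectra.items() if p in pset}, subject=grp
            )
            if grp_sp.total == 0:
                continue
            group_exp[grp] = signatures.fit_exposures(grp_sp, sig_catalog)
            group_tot[grp] = grp_sp.total
        if len(group_exp) == 2:
            emit(
                "signature_comparison.tsv",
                signatures.compare_signature_proportions(group_exp, group_tot),
            )
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "signature refitting needs SNVs with contexts")

    # -- stage: survival ---------------------------------------------------
    stage = "survival"
    try:
        surv = survival.stratified_survival(clinical, labels, ["immune_category"])
        emit("survival_by_category.tsv", surv)
        emit("km_curves.tsv", survival.curve_table(clinical, labels))
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001
        finish(stage, e, "survival needs clinical records joined to labels")

    finish(None)
    return manifest
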