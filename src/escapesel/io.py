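"""Readers and writers for every external artifact.

All downstream modules operate on typed in-memory objects: mutation catalogs
are pandas DataFrames with a fixed column set, gene models are
:class:`~escapesel.genome.GeneModel` objects, signature catalogs are
:class:`SignatureCatalog`.  Coordinates are 1-based inclusive everywhere
(MAF convention); the only half-open conversion happens at the BED boundary
in :mod:`escapesel.peptidome`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._contexts import COMPLEMENT, SBS96_LABELS, revcomp
from .genome import GeneModel

logger = logging.getLogger(__name__)

#: Internal consequence vocabulary (configurable choice; MAF does not fix one).
VARIANT_CLASSES = (
    "synonymous",
    "missense",
    "nonsense",
    "essential_splice",
    "frameshift",
    "other_nonsilent",
    "noncoding",
)

#: Classes counting as "non-silent" for escape classification by default.
DEFAULT_NONSILENT = frozenset(
    {"missense", "nonsense", "essential_splice", "frameshift", "other_nonsilent"}
)

#: Classes entering dN/dS numerators/denominators (SNV point-mutation model).
DNDS_CLASSES = frozenset({"synonymous", "missense", "nonsense"})

MAF_CLASS_MAP = {
    "Silent": "synonymous",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "essential_splice",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "other_nonsilent",
    "In_Frame_Ins": "other_nonsilent",
    "Nonstop_Mutation": "other_nonsilent",
    "Translation_Start_Site": "other_nonsilent",
}

MAF_REQUIRED = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

CATALOG_COLUMNS = (
    "patient_id",
    "gene_id",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "context",
    "vaf",
    "cancer_type",
    "non_snv",
)


class MafReadResult(NamedTuple):
    records: pd.DataFrame  # accepted rows, CATALOG_COLUMNS
    rejected: pd.DataFrame  # rejected rows with a `reason` column


def _is_snv(ref: str, alt: str) -> bool:
    return ref in "ACGT" and alt in "ACGT" and ref != alt


def read_maf(path, gene_models: dict[str, GeneModel] | None = None) -> MafReadResult:
    """Parse a MAF-dialect TSV into a mutation catalog.

    Every input row is accounted for: SNVs become catalog records; non-SNV
    rows (indels, DNPs) are retained with ``non_snv=True`` so they still count
    for burden and escape classification; rows whose reference allele
    contradicts the gene model are rejected with a reason, never corrected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MAF_REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"MAF {path} missing mandatory column(s): {', '.join(missing)}")

    records, rejected = [], []
    for idx, row in raw.iterrows():
        ref = str(row["Reference_Allele"]).upper()
        alt = str(row["Tumor_Seq_Allele2"]).upper()
        gene = row["Hugo_Symbol"]
        try:
            pos = int(row["Start_Position"])
        except (TypeError, ValueError):
            rejected.append({**row, "reason": "non-integer Start_Position"})
            continue
        if pos < 1:
            rejected.append({**row, "reason": "position < 1"})
            continue
        snv = _is_snv(ref, alt)
        if snv:
            vclass = MAF_CLASS_MAP.get(row["Variant_Classification"], "noncoding")
        else:
            mc = row["Variant_Classification"]
            vclass = MAF_CLASS_MAP.get(mc, "other_nonsilent")
            if vclass in ("synonymous", "missense", "nonsense"):
                # a non-SNV cannot carry an SNV class; route to other_nonsilent
                vclass = "other_nonsilent"

        context = np.nan
        if snv and gene_models is not None and gene in gene_models:
            gm = gene_models[gene]
            try:
                ci = gm.cds_index_of(pos)
            except KeyError:
                ci = None
            if ci is not None:
                coding_ref = gm.cds_sequence[ci]
                expected = coding_ref if gm.strand == "+" else COMPLEMENT[coding_ref]
                if expected != ref:
                    rejected.append(
                        {**row, "reason": f"ref allele {ref} != gene model {expected}"}
                    )
                    continue
                context = gm.context_at(ci)

        vaf = np.nan
        if "VAF" in raw.columns and pd.notna(row.get("VAF")):
            vaf = float(row["VAF"])
        elif (
            "t_depth" in raw.columns
            and "t_alt_count" in raw.columns
            and pd.notna(row.get("t_depth"))
            and float(row["t_depth"]) > 0
        ):
            vaf = float(row["t_alt_count"]) / float(row["t_depth"])
        if not (np.isnan(vaf) or 0.0 <= vaf <= 1.0):
            rejected.append({**row, "reason": f"VAF {vaf} outside [0, 1]"})
            continue

        records.append(
            {
                "patient_id": row["Tumor_Sample_Barcode"],
                "gene_id": gene,
                "chromosome": row["Chromosome"],
                "position": pos,
                "ref_allele": ref,
                "alt_allele": alt,
                "variant_class": vclass,
                "context": context,
                "vaf": vaf,
                "cancer_type": row.get("Cancer_Type", "NA"),
                "non_snv": not snv,
            }
        )
    rec_df = pd.DataFrame(records, columns=CATALOG_COLUMNS)
    rej_df = pd.DataFrame(rejected)
    if len(rej_df):
        logger.warning("read_maf: rejected %d of %d rows", len(rej_df), len(raw))
    assert len(rec_df) + len(rej_df) == len(raw)
    return MafReadResult(rec_df, rej_df)


def write_maf(catalog: pd.DataFrame, path) -> None:
    """Write a catalog back to MAF columns (inverse of :func:`read_maf` for SNVs)."""
    inv = {v: k for k, v in MAF_CLASS_MAP.items() if not k.endswith(("Del", "Ins"))}
    inv["frameshift"] = "Frame_Shift_Ins"
    inv["noncoding"] = "RNA"
    out = pd.DataFrame(
        {
            "Hugo_Symbol": catalog["gene_id"],
            "Chromosome": catalog["chromosome"],
            "Start_Position": catalog["position"],
            "Reference_Allele": catalog["ref_allele"],
            "Tumor_Seq_Allele2": catalog["alt_allele"],
            "Variant_Classification": catalog["variant_class"].map(inv),
            "Tumor_Sample_Barcode": catalog["patient_id"],
            "VAF": catalog["vaf"],
            "Cancer_Type": catalog["cancer_type"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature catalogs


@dataclass(frozen=True)
class SignatureCatalog:
    """A COSMIC-style SBS catalog: 96 x K column-stochastic matrix."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (96, K), columns sum to 1
    context_order: tuple[str, ...] = SBS96_LABELS

    def __post_init__(self):
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("signature matrix must be 96 x K")
        if (self.matrix < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature columns must sum to 1")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC SBS TSV (context labels like ``A[C>T]G`` in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if len(df) != 96:
        raise ValueError(f"signature catalog must have 96 rows, found {len(df)}")
    unknown = set(df.index) - set(SBS96_LABELS)
    if unknown:
        raise ValueError(f"unrecognized context labels: {sorted(unknown)[:5]}")
    df = df.reindex(list(SBS96_LABELS))
    mat = df.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("signature catalog has negative entries")
    sums = mat.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        raise ValueError(
            f"signature column(s) {list(df.columns[bad])} sum to {sums[bad]}, "
            "outside 1 +/- 1e-3"
        )
    mat = mat / sums
    return SignatureCatalog(names=tuple(df.columns), matrix=mat)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    pd.DataFrame(
        catalog.matrix, index=list(catalog.context_order), columns=list(catalog.names)
    ).to_csv(path, sep="\t", index_label="context")


# ---------------------------------------------------------------------------
# clinical / expression / CNV tables

IMMUNE_CATEGORIES = ("C1", "C2", "C3", "C4", "C5", "C6")


def read_tables(clinical_path, expression_path=None, cnv_path=None):
    """Read clinical, expression (FPKM) and copy-number tables.

    Returns ``(clinical, expression, cnv)`` DataFrames; the latter two are
    ``None`` when no path is given.  Patients absent from a table are simply
    absent (downstream joins keep catalog patients with missing annotation).
    """
    clinical = pd.read_csv(clinical_path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "survival_time", "event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    if clinical["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    if (clinical["survival_time"] <= 0).any():
        raise ValueError("survival_time must be > 0")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if "immune_category" in clinical.columns:
        cats = clinical["immune_category"].dropna()
        bad = set(cats) - set(IMMUNE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown immune categories: {sorted(bad)}")
    else:
        clinical["immune_category"] = np.nan
    if "cancer_type" not in clinical.columns:
        clinical["cancer_type"] = "NA"

    expression = cnv = None
    if expression_path is not None:
        expression = pd.read_csv(expression_path, sep="\t", dtype={"patient_id": str})
        if expression.duplicated(["patient_id", "gene_id"]).any():
            raise ValueError("duplicate patient x gene keys in expression table")
    if cnv_path is not None:
        cnv = pd.read_csv(cnv_path, sep="\t", dtype={"patient_id": str})
        if cnv.duplicated(["patient_id", "gene_id"]).any():
            raise ValueError("duplicate patient x gene keys in CNV table")
        if ((cnv["copy_number"] < 0) | (cnv["copy_number"] > 20)).any():
            raise ValueError("copy numbers outside [0, 20]")
    return clinical, expression, cnv


# ---------------------------------------------------------------------------
# gene models + reference FASTA


def read_gene_models(fasta_path, models_path) -> dict[str, GeneModel]:
    """Load gene models from a GFF-like exon TSV plus a reference FASTA.

    The TSV has one row per exon: gene_id, transcript_id, chromosome, strand,
    exon_start, exon_end (1-based inclusive). The CDS sequence is extracted
    from the FASTA and reverse-complemented for minus-strand genes.
    """
    tbl = pd.read_csv(models_path, sep="\t", dtype={"chromosome": str})
    fasta = Fasta(str(fasta_path), as_raw=True, rebuild=False)
    models: dict[str, GeneModel] = {}
    for (gene_id, tx, chrom, strand), grp in tbl.groupby(
        ["gene_id", "transcript_id", "chromosome", "strand"], sort=False
    ):
        exons = sorted(zip(grp["exon_start"].astype(int), grp["exon_end"].astype(int)))
        seq = "".join(str(fasta[chrom][s - 1 : e]).upper() for s, e in exons)
        chrom_len = len(fasta[chrom])
        left = str(fasta[chrom][exons[0][0] - 2]) if exons[0][0] >= 2 else "N"
        right = str(fasta[chrom][exons[-1][1]]) if exons[-1][1] < chrom_len else "N"
        if strand == "-":
            seq = revcomp(seq)
            flank5, flank3 = COMPLEMENT[right.upper()], COMPLEMENT[left.upper()]
        else:
            flank5, flank3 = left.upper(), right.upper()
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript_id=tx,
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_sequence=seq,
            flank5=flank5,
            flank3=flank3,
        )
    return models


def write_gene_models(models: dict[str, GeneModel], path) -> None:
    rows = []
    for gm in models.values():
        for s, e in gm.exons:
            rows.append(
                {
                    "gene_id": gm.gene_id,
                    "transcript_id": gm.transcript_id,
                    "chromosome": gm.chromosome,
                    "strand": gm.strand,
                    "exon_start": s,
                    "exon_end": e,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; '#' comments and blanks ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out
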