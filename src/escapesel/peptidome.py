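"""Immunopeptidome region mapping and region-filtered dN/dS.

Protein-coordinate regions (patient-specific or global) are projected
through gene models into genomic intervals; mutation catalogs can then be
filtered to exclude (or restrict to) those intervals, and pooled dN/dS is
recomputed with the site opportunities consistently masked, so numerator
and denominator describe the same genomic territory. A flag disables the
opportunity masking to reproduce a mutations-only filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dnds import ContextRateModel, GlobalDnDs, build_impact_matrices, global_dnds
from .genome import GeneModel


@dataclass(frozen=True)
class ProteinRegion:
    patient_id: str  # or "global"
    gene_id: str
    transcript_id: str
    start_aa: int  # 1-based inclusive
    end_aa: int

    def __post_init__(self):
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError("need 1 <= start_aa <= end_aa")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


@dataclass
class GenomicRegionSet:
    """Merged, sorted 1-based inclusive intervals per chromosome."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def add(self, chromosome: str, start: int, end: int) -> None:
        self.intervals.setdefault(chromosome, []).append((start, end))
        self.intervals[chromosome] = merge_intervals(self.intervals[chromosome])

    def union(self, other: "GenomicRegionSet") -> "GenomicRegionSet":
        merged = GenomicRegionSet()
        for src in (self, other):
            for chrom, ivs in src.intervals.items():
                merged.intervals.setdefault(chrom, []).extend(ivs)
        for chrom in merged.intervals:
            merged.intervals[chrom] = merge_intervals(merged.intervals[chrom])
        return merged

    def contains(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership for 1-based positions."""
        positions = np.asarray(positions)
        mask = np.zeros(len(positions), dtype=bool)
        for s, e in self.intervals.get(chromosome, []):
            mask |= (positions >= s) & (positions <= e)
        return mask

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for ivs in self.intervals.values() for s, e in ivs)

    def to_bed(self, path) -> None:
        """BED export (the 0-based half-open conversion happens only here)."""
        rows = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                rows.append(f"{chrom}\t{s - 1}\t{e}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + ("\n" if rows else ""))


def protein_to_genomic(region: ProteinRegion, gene: GeneModel) -> GenomicRegionSet:
    """Project protein positions [start_aa, end_aa] to genomic intervals.

    Protein position p covers CDS nucleotides [3p-2, 3p] (1-based); the CDS
    range is carried through the exon structure honoring strand, possibly
    splitting across exon junctions; output intervals are merged.
    """
    if region.end_aa > gene.protein_length:
        raise ValueError(
            f"region {region.start_aa}-{region.end_aa} beyond protein length "
            f"{gene.protein_length} of {gene.gene_id}"
        )
    cds_lo = 3 * (region.start_aa - 1)  # 0-based inclusive
    cds_hi = 3 * region.end_aa - 1
    gpos = gene.genomic_positions[cds_lo : cds_hi + 1]
    out = GenomicRegionSet()
    lo = int(gpos.min())
    runs = []
    srt = np.sort(gpos)
    start = prev = int(srt[0])
    for x in srt[1:]:
        x = int(x)
        if x == prev + 1:
            prev = x
        else:
            runs.append((start, prev))
            start = prev = x
    runs.append((start, prev))
    for s, e in runs:
        out.add(gene.chromosome, s, e)
    return out


def genomic_to_protein(position: int, gene: GeneModel) -> int:
    """Inverse map: genomic position -> 1-based protein position."""
    return gene.cds_index_of(position) // 3 + 1


def regions_from_table(
    table: pd.DataFrame, gene_models: dict[str, GeneModel]
) -> dict[str, GenomicRegionSet]:
    """Build per-patient region sets from a SOPRANO-style TSV
    (patient_id, transcript_id, start_aa, end_aa)."""
    tx2gene = {gm.transcript_id: gm for gm in gene_models.values()}
    out: dict[str, GenomicRegionSet] = {}
    for _, row in table.iterrows():
        tx = row["transcript_id"]
        if tx not in tx2gene:
            raise KeyError(f"transcript {tx} absent from gene models")
        gm = tx2gene[tx]
        reg = ProteinRegion(
            patient_id=str(row.get("patient_id", "global")),
            gene_id=gm.gene_id,
            transcript_id=tx,
            start_aa=int(row["start_aa"]),
            end_aa=int(row["end_aa"]),
        )
        gset = protein_to_genomic(reg, gm)
        key = reg.patient_id
        out[key] = out[key].union(gset) if key in out else gset
    return out


def filter_by_regions(
    catalog: pd.DataFrame,
    regions: dict[str, GenomicRegionSet],
    mode: str = "exclude",
) -> pd.DataFrame:
    """Drop (exclude) or keep (restrict) SNVs inside each patient's regions.

    Regions keyed "global" apply to every patient; patient-specific regions
    are unioned with the global set. The two modes partition the catalog for
    a fixed region set.
    """
    if mode not in ("exclude", "restrict"):
        raise ValueError("mode must be 'exclude' or 'restrict'")
    glob = regions.get("global")
    inside = np.zeros(len(catalog), dtype=bool)
    for i, (pid, chrom, pos) in enumerate(
        zip(catalog["patient_id"], catalog["chromosome"], catalog["position"])
    ):
        rset = regions.get(pid, glob)
        if rset is None:
            continue
        if pid in regions and glob is not None:
            hit = bool(
                regions[pid].contains(chrom, np.array([pos]))[0]
                or glob.contains(chrom, np.array([pos]))[0]
            )
        else:
            hit = bool(rset.contains(chrom, np.array([pos]))[0])
        inside[i] = hit
    keep = ~inside if mode == "exclude" else inside
    return catalog[keep].copy()


def filtered_dnds(
    catalog: pd.DataFrame,
    regions: dict[str, GenomicRegionSet],
    gene_set: list[str],
    rates: ContextRateModel,
    gene_models: dict[str, GeneModel],
    mask_opportunity: bool = True,
) -> tuple[GlobalDnDs, GlobalDnDs, float]:
    """Pooled dN/dS before and after excluding immunopeptidome regions.

    With ``mask_opportunity`` (default) the site opportunities L are
    recomputed over the unmasked complement using the union of all region
    sets, so observed and expected counts are consistently region-masked;
    with the flag off only the observed mutations are filtered. Genes whose
    CDS is fully masked are dropped with a warning. Returns
    ``(original, filtered, ratio filtered/original)``.
    """
    import warnings

    original = global_dnds(
        gene_set, catalog, rates, build_impact_matrices(
            {g: gene_models[g] for g in gene_set if g in gene_models}
        ), label="original",
    )
    filtered_cat = filter_by_regions(catalog, regions, mode="exclude")

    union = GenomicRegionSet()
    for rset in regions.values():
        union = union.union(rset)

    masks = {}
    kept_genes = []
    for g in gene_set:
        if g not in gene_models:
            continue
        gm = gene_models[g]
        masked = union.contains(gm.chromosome, gm.genomic_positions)
        if mask_opportunity and masked.all():
            warnings.warn(f"{g}: CDS fully masked; dropped from filtered gene set")
            continue
        kept_genes.append(g)
        if mask_opportunity:
            masks[g] = ~masked
    impacts = build_impact_matrices({g: gene_models[g] for g in kept_genes}, masks or None)
    filtered = global_dnds(kept_genes, filtered_cat, rates, impacts, label="filtered")
    return original, filtered, filtered.w / original.w
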