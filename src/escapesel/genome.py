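"""Gene models: CDS structure, coordinate maps and per-site impact annotation.

A :class:`GeneModel` carries one canonical transcript per gene: ordered
genomic exon intervals (1-based inclusive), strand, and the coding-strand CDS
sequence.  Coordinate maps between genome, CDS and protein are exact inverses
of each other; every consequence annotation in the package is derived by
translating mutated codons against the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from ._contexts import BASES, BASE_INDEX

# impact codes
SYN, MIS, NON = 0, 1, 2
IMPACT_NAMES = {SYN: "synonymous", MIS: "missense", NON: "nonsense"}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@dataclass
class GeneModel:
    """One canonical coding transcript.

    ``exons`` are genomic intervals (1-based, inclusive) in ascending genomic
    order; ``cds_sequence`` is on the coding strand (reverse-complemented
    relative to the genome for minus-strand genes). ``flank5``/``flank3`` are
    the single reference bases immediately outside the CDS on the coding
    strand, used for edge trinucleotide contexts ('A' is assumed when the true
    flanking base is unavailable, e.g. at a chromosome edge).
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    flank5: str = "A"
    flank3: str = "A"

    _genomic_positions: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene_id}: exon lengths ({exon_len}) != CDS length "
                f"({len(self.cds_sequence)})"
            )
        prot = self.protein
        if "*" in prot:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")
        pos = np.concatenate(
            [np.arange(s, e + 1, dtype=np.int64) for s, e in self.exons]
        )
        if self.strand == "-":
            pos = pos[::-1]
        self._genomic_positions = pos

    # -- basic properties -------------------------------------------------
    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    @property
    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())

    # -- coordinate maps --------------------------------------------------
    @property
    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of each CDS index (0-based CDS -> 1-based genome)."""
        return self._genomic_positions

    def genomic_of_cds(self, cds_index):
        return self._genomic_positions[np.asarray(cds_index)]

    def cds_index_of(self, genomic_pos: int) -> int:
        """CDS index (0-based) of a genomic position; raises if non-coding."""
        hits = np.nonzero(self._genomic_positions == genomic_pos)[0]
        if hits.size == 0:
            raise KeyError(f"{self.gene_id}: position {genomic_pos} not in CDS")
        return int(hits[0])

    def codon_cds_range(self, protein_pos: int) -> tuple[int, int]:
        """0-based CDS index range [start, end] of a 1-based protein position."""
        if not 1 <= protein_pos <= self.protein_length:
            raise ValueError(
                f"{self.gene_id}: protein position {protein_pos} outside 1..{self.protein_length}"
            )
        return 3 * (protein_pos - 1), 3 * protein_pos - 1

    def codon_genomic_positions(self, protein_pos: int) -> np.ndarray:
        s, e = self.codon_cds_range(protein_pos)
        return self._genomic_positions[s : e + 1]

    def context_at(self, cds_index: int) -> str:
        """Coding-strand reference triplet centered on a CDS index."""
        s = self.cds_sequence
        left = s[cds_index - 1] if cds_index > 0 else self.flank5
        right = s[cds_index + 1] if cds_index < len(s) - 1 else self.flank3
        return left + s[cds_index] + right

    def coding_base(self, genomic_pos: int) -> str:
        return self.cds_sequence[self.cds_index_of(genomic_pos)]


# vectorized codon machinery: codon index = b0*16 + b1*4 + b2 with A,C,G,T = 0..3
_AA_CODE = np.empty(64, dtype=np.int8)
_AA_LETTERS = sorted(set(_CODON_TABLE.values()))
for _ci in range(64):
    _codon = BASES[_ci >> 4] + BASES[(_ci >> 2) & 3] + BASES[_ci & 3]
    _AA_CODE[_ci] = _AA_LETTERS.index(_CODON_TABLE[_codon])
_STOP_CODE = _AA_LETTERS.index("*")
#: alt base index for (ref index, alt rank among the 3 bases != ref, ACGT order)
_ALT_BASE = np.array([[b for b in range(4) if b != r] for r in range(4)], dtype=np.int8)

_BASE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes 0..3."""
    codes = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT bases")
    return codes


class ImpactTable:
    """Per-site consequence annotation for every possible SNV in one CDS.

    For CDS index ``i`` and alt rank ``a`` (the 3 bases != ref, in ACGT order),
    ``impact[i, a]`` holds SYN/MIS/NON from translating the mutated codon, and
    ``cls192[i, a]`` the strand-specific trinucleotide substitution class of
    that change (coding-strand orientation). ``contexts`` holds the reference
    triplet per CDS index.
    """

    def __init__(self, gene: GeneModel):
        self.gene = gene
        L = gene.cds_length
        seq = gene.cds_sequence
        c = encode_bases(seq)
        pos = np.arange(L)
        off = pos % 3
        cstart = pos - off
        codon_idx = c[cstart] * 16 + c[cstart + 1] * 4 + c[cstart + 2]
        aa = _AA_CODE[codon_idx]
        pow3 = np.array([16, 4, 1])[off]
        f5 = np.empty(L, dtype=np.int8)
        f3 = np.empty(L, dtype=np.int8)
        f5[1:], f5[0] = c[:-1], BASE_INDEX[gene.flank5]
        f3[:-1], f3[-1] = c[1:], BASE_INDEX[gene.flank3]
        self.impact = np.empty((L, 3), dtype=np.int8)
        self.cls192 = np.empty((L, 3), dtype=np.int16)
        for a in range(3):
            alt = _ALT_BASE[c, a]
            maa = _AA_CODE[codon_idx + (alt - c) * pow3]
            self.impact[:, a] = np.where(maa == aa, SYN, np.where(maa == _STOP_CODE, NON, MIS))
            self.cls192[:, a] = ((c.astype(np.int16) * 3 + a) * 4 + f5) * 4 + f3
        left = gene.flank5 + seq[:-1]
        right = seq[1:] + gene.flank3
        self.contexts = np.array(
            [left[i] + seq[i] + right[i] for i in range(L)], dtype="U3"
        )

    def opportunity_matrix(self, site_mask: np.ndarray | None = None) -> np.ndarray:
        """Counts of possible substitutions by (192-class, impact).

        ``site_mask`` (boolean over CDS indices) optionally restricts the
        opportunity to unmasked sites (used for region-filtered dN/dS).
        """
        L = np.zeros((192, 3), dtype=np.int64)
        imp = self.impact
        cls = self.cls192
        if site_mask is not None:
            imp = imp[site_mask]
            cls = cls[site_mask]
        np.add.at(L, (cls.ravel(), imp.ravel()), 1)
        return L


def make_gene_model(
    gene_id: str,
    cds_sequence: str,
    chromosome: str = "chr1",
    strand: str = "+",
    cds_start: int = 1,
    transcript_id: str | None = None,
    n_exons: int = 1,
    intron_length: int = 50,
    flank5: str = "A",
    flank3: str = "A",
) -> GeneModel:
    """Construct a gene model from a coding-strand CDS laid out on the genome.

    Exons split the CDS into ``n_exons`` near-equal pieces separated by
    ``intron_length``. For minus-strand genes the genomic sequence is the
    reverse complement of ``cds_sequence``; ``cds_start`` is always the
    leftmost genomic coordinate of the gene.
    """
    L = len(cds_sequence)
    cuts = np.linspace(0, L, n_exons + 1).round().astype(int)
    exons = []
    gpos = cds_start
    for k in range(n_exons):
        elen = int(cuts[k + 1] - cuts[k])
        exons.append((gpos, gpos + elen - 1))
        gpos += elen + intron_length
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id or f"{gene_id}.t1",
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        cds_sequence=cds_sequence,
        flank5=flank5,
        flank3=flank3,
    )
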