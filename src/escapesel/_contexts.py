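"""Trinucleotide substitution classes.

Two indexings are used throughout:

* 192 strand-specific classes ``(5'flank, ref, alt, 3'flank)`` on the coding
  strand — the resolution at which mutation-rate models are fit (rate models
  are strand-aware).
* 96 pyrimidine-centered classes ``X[P>Q]Y`` with P in {C, T} — the COSMIC
  SBS convention used by signature catalogs; purine-reference triplets are
  reverse-complemented into their pyrimidine partner.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CLASSES_192 = 192
N_CLASSES_96 = 96


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _alt_rank(ref: str, alt: str) -> int:
    """Rank of ``alt`` among the three bases different from ``ref``."""
    alts = [b for b in BASES if b != ref]
    return alts.index(alt)


def alt_from_rank(ref: str, rank: int) -> str:
    return [b for b in BASES if b != ref][rank]


def class192(f5: str, ref: str, alt: str, f3: str) -> int:
    """Index of a strand-specific trinucleotide substitution class."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return ((BASE_INDEX[ref] * 3 + _alt_rank(ref, alt)) * 4 + BASE_INDEX[f5]) * 4 + BASE_INDEX[f3]


def class192_label(idx: int) -> str:
    f3 = BASES[idx % 4]
    idx //= 4
    f5 = BASES[idx % 4]
    idx //= 4
    rank = idx % 3
    ref = BASES[idx // 3]
    return f"{f5}[{ref}>{alt_from_rank(ref, rank)}]{f3}"


# Canonical COSMIC ordering: substitution blocks C>A..T>G, within each block
# 5' flank A,C,G,T (outer) x 3' flank A,C,G,T (inner).
SBS96_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)
SBS96_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def class96(f5: str, ref: str, alt: str, f3: str) -> int:
    """COSMIC SBS96 class, collapsing purine-reference triplets by revcomp."""
    if ref not in PYRIMIDINES:
        f5, ref, alt, f3 = COMPLEMENT[f3], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[f5]
    return SBS96_INDEX[f"{f5}[{ref}>{alt}]{f3}"]


def parse_sbs_label(label: str) -> tuple[str, str, str, str]:
    """Parse ``"A[C>T]G"`` into ``(f5, ref, alt, f3)``."""
    f5, rest = label[0], label[2:-2]
    ref, alt = rest.split(">")
    return f5, ref, alt, label[-1]


def _build_collapse_map() -> np.ndarray:
    m = np.empty(N_CLASSES_192, dtype=np.intp)
    for idx in range(N_CLASSES_192):
        f5, ref, alt, f3 = parse_sbs_label(class192_label(idx))
        m[idx] = class96(f5, ref, alt, f3)
    return m


#: For each 192-class, the SBS96 class it collapses to. Each 96-class has
#: exactly two strand-specific parents (a pyrimidine- and a purine-reference one).
COLLAPSE_192_TO_96 = _build_collapse_map()


def partner192(idx: int) -> int:
    """The reverse-complement partner of a strand-specific class."""
    f5, ref, alt, f3 = parse_sbs_label(class192_label(idx))
    return class192(COMPLEMENT[f3], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[f5])


PARTNER_192 = np.array([partner192(i) for i in range(N_CLASSES_192)], dtype=np.intp)
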