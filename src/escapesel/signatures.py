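"""Mutational-signature tabulation and exposure refitting.

Spectra are 96-channel pyrimidine-centered trinucleotide substitution counts
in COSMIC order. Exposures are refit against a fixed catalog by the
forward-selection constrained least-squares scheme of deconstructSigs:
start from the best single signature, iteratively re-optimize non-negative
weights (sum <= 1) by per-signature golden-section search, add the next
signature only while the relative SSE improvement exceeds ``stop_delta``,
then zero weights below ``threshold``. Fitting is proportion-based, hence
invariant to scaling the input counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._contexts import SBS96_LABELS, class96
from .dnds import bh_adjust
from .genome import GeneModel
from .io import SignatureCatalog

DEFAULT_THRESHOLD = 0.06
DEFAULT_STOP_DELTA = 0.01


@dataclass
class Spectrum96:
    subject: str
    counts: np.ndarray  # (96,) non-negative integers, COSMIC order

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,) or (self.counts < 0).any():
            raise ValueError("counts must be 96 non-negative values")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("zero-total spectrum")
        return self.counts / self.counts.sum()


@dataclass
class ExposureResult:
    subject: str
    weights: dict[str, float]  # only weights >= threshold survive
    residual_sse: float

    @property
    def dominant(self) -> str | None:
        """Signature of maximal weight; ties broken lexicographically."""
        if not self.weights:
            return None
        return min(self.weights, key=lambda k: (-self.weights[k], k))

    @property
    def dominant_tied(self) -> bool:
        if not self.weights:
            return False
        top = max(self.weights.values())
        return sum(1 for v in self.weights.values() if v == top) > 1


def tabulate_96(
    catalog: pd.DataFrame,
    gene_models: dict[str, GeneModel] | None = None,
    by: str = "patient_id",
) -> dict[str, Spectrum96]:
    """96-channel spectra per subject (``by='patient_id'``) or pooled group.

    Requires the coding-strand ``context`` column; purine-reference changes
    are reverse-complemented into the pyrimidine-centered class. For
    minus-strand genes the stored genomic ref/alt are complemented back to
    the coding strand first (the class is strand-symmetric, so only internal
    consistency between context and alleles matters). Records with missing
    or ambiguous context are skipped.
    """
    strands = {g: gm.strand for g, gm in (gene_models or {}).items()}
    sub = catalog[~catalog["non_snv"]]
    out: dict[str, np.ndarray] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for subj, ctx, ref, alt, gene in zip(
        sub[by] if by in sub.columns else np.full(len(sub), "all"),
        sub["context"],
        sub["ref_allele"],
        sub["alt_allele"],
        sub["gene_id"],
    ):
        if not isinstance(ctx, str) or any(b not in "ACGT" for b in ctx):
            continue
        if strands.get(gene) == "-":
            ref, alt = comp[ref], comp[alt]
        if ctx[1] != ref:
            continue  # inconsistent record; skipped, not corrected
        arr = out.setdefault(subj, np.zeros(96, dtype=np.int64))
        arr[class96(ctx[0], ref, alt, ctx[2])] += 1
    return {s: Spectrum96(subject=s, counts=c) for s, c in out.items()}


def pooled_spectrum(spectra: dict[str, Spectrum96], subject: str = "pooled") -> Spectrum96:
    total = np.zeros(96, dtype=np.int64)
    for sp in spectra.values():
        total += sp.counts
    return Spectrum96(subject=subject, counts=total)


def _sse(p: np.ndarray, M: np.ndarray, w: np.ndarray) -> float:
    r = p - M @ w
    return float(r @ r)


def _optimize_weights(p: np.ndarray, M: np.ndarray, w: np.ndarray, iters: int = 10) -> np.ndarray:
    """Cyclic golden-section updates of each weight in [0, 1 - sum(others)]."""
    w = w.copy()
    for _ in range(iters):
        before = _sse(p, M, w)
        for j in range(len(w)):
            others = w.sum() - w[j]
            hi = max(0.0, 1.0 - others)
            res = minimize_scalar(
                lambda x: _sse(p, M, np.r_[w[:j], x, w[j + 1 :]]),
                bounds=(0.0, hi),
                method="bounded",
                options={"xatol": 1e-9},
            )
            w[j] = float(res.x)
        if before - _sse(p, M, w) < 1e-12:
            break
    return w


def fit_exposures(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    threshold: float = DEFAULT_THRESHOLD,
    stop_delta: float = DEFAULT_STOP_DELTA,
) -> ExposureResult:
    """Forward-selection constrained least-squares signature refit."""
    p = spectrum.proportions
    M = catalog.matrix
    K = catalog.n_signatures

    selected: list[int] = []
    weights = np.zeros(0)
    sse = float(p @ p)
    while len(selected) < K:
        best = None
        for j in range(K):
            if j in selected:
                continue
            cand = selected + [j]
            w = _optimize_weights(p, M[:, cand], np.r_[weights, 0.0])
            s = _sse(p, M[:, cand], w)
            if best is None or s < best[0]:
                best = (s, j, w)
        new_sse, j, w = best
        improvement = (sse - new_sse) / sse if sse > 0 else 0.0
        if selected and improvement <= stop_delta:
            break
        selected.append(j)
        weights = w
        sse = new_sse
        if sse <= 1e-16:
            break

    full = np.zeros(K)
    full[selected] = weights
    total_before = full.sum()
    full[full < threshold] = 0.0
    if full.sum() > 0 and total_before > 0:
        full *= total_before / full.sum()  # survivors keep the fitted scale
    kept = {catalog.names[j]: float(full[j]) for j in range(K) if full[j] > 0}
    return ExposureResult(
        subject=spectrum.subject, weights=kept, residual_sse=_sse(p, M, full)
    )


def dominant_signature_profile(
    exposures: dict[str, ExposureResult], labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-group frequency table of each patient's dominant signature."""
    lab = labels.set_index("patient_id")["status"]
    rows = []
    for pid, exp in exposures.items():
        if exp.dominant is None:
            continue
        rows.append(
            {
                "patient_id": pid,
                "status": lab.get(pid, "unknown"),
                "dominant": exp.dominant,
                "tie": exp.dominant_tied,
            }
        )
    df = pd.DataFrame(rows)
    freq = (
        df.groupby(["status", "dominant"]).size().rename("n").reset_index()
    )
    freq["frequency"] = freq["n"] / freq.groupby("status")["n"].transform("sum")
    return freq


def compare_signature_proportions(
    exposures_by_group: dict[str, ExposureResult],
    totals_by_group: dict[str, int],
) -> pd.DataFrame:
    """Per-signature chi-square of attributed mutation counts between groups.

    Attribution = group exposure weight x group total mutations (rounded);
    each signature is tested in a 2x2 {this signature, all other} x
    {escape-, escape+} table; BH across signatures.
    """
    from .contrasts import _chi2_2x2

    groups = sorted(exposures_by_group)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    sigs = sorted({s for e in exposures_by_group.values() for s in e.weights})
    rows = []
    for sig in sigs:
        attributed = {
            g: int(round(exposures_by_group[g].weights.get(sig, 0.0) * totals_by_group[g]))
            for g in groups
        }
        table = np.array(
            [
                [attributed[g], totals_by_group[g] - attributed[g]]
                for g in groups
            ]
        ).T  # rows: this-signature / other; cols: groups
        res = _chi2_2x2(table, (("attributed", "other"), tuple(groups)))
        rows.append(
            {
                "signature": sig,
                f"attributed_{groups[0]}": attributed[groups[0]],
                f"attributed_{groups[1]}": attributed[groups[1]],
                "chi2": res.chi2,
                "p": res.p,
                "flagged": res.flagged or min(attributed.values()) == 0,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def spectrum_table(spectra: dict[str, Spectrum96]) -> pd.DataFrame:
    """Long-format export of spectra (subject, context, count)."""
    rows = []
    for subj, sp in spectra.items():
        for lab, n in zip(SBS96_LABELS, sp.counts):
            rows.append({"subject": subj, "context": lab, "count": int(n)})
    return pd.DataFrame(rows)
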