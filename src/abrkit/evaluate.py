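"""Scoring of region annotations against observed binding residues.

The gold standard for one antibody is the set of residues that contact
the antigen in the crystal structure.  Precision = tp/(tp+fp) and
recall = tp/(tp+fn) over residue sets; methods are compared through
consensus and difference (Δ) sets, per-region statistics, and
method-unique binding residues.  Externally computed alanine-scan ΔΔG
values (kcal/mol) are classified into stabilizing / neutral /
destabilizing at ±0.25; no energies are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .regions import REGION_NAMES, RegionAnnotation

__all__ = [
    "EvaluationCounts",
    "MethodComparison",
    "score_annotation",
    "compare_methods",
    "per_region_stats",
    "find_unique_binding_residues",
    "classify_ddg",
    "macro_average",
]

ResidueKey = tuple[str, int]   # (chain role, residue index)


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None


@dataclass
class MethodComparison:
    """Consensus and method-specific residue sets of two annotations."""

    consensus: set[ResidueKey]
    delta_a: set[ResidueKey]
    delta_b: set[ResidueKey]
    gold: set[ResidueKey]

    def stats(self, which: str) -> dict:
        s = getattr(self, which)
        in_contact = len(s & self.gold)
        return {
            "set": which,
            "n_residues": len(s),
            "n_in_contact": in_contact,
            "coverage": in_contact / len(self.gold) if self.gold else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.stats(w)
                             for w in ("consensus", "delta_a", "delta_b")])


def _check_same_antibody(*annotations: RegionAnnotation):
    ids = {a.antibody_id for a in annotations}
    if len(ids) > 1:
        raise ValueError(f"annotations refer to different antibodies: {ids}")


def score_annotation(pred: RegionAnnotation, gold: set[ResidueKey],
                     ) -> tuple[EvaluationCounts, float | None, float | None]:
    """Precision and recall of an annotation against binding residues."""
    p = pred.residues()
    tp = len(p & gold)
    counts = EvaluationCounts(tp, len(p - gold), len(gold - p))
    recall = counts.recall
    if not p and gold:
        recall = 0.0
    return counts, counts.precision, recall


def compare_methods(a: RegionAnnotation, b: RegionAnnotation,
                    gold: set[ResidueKey]) -> MethodComparison:
    """Consensus (A∩B) and Δ sets (A\\B, B\\A) with binding coverage."""
    _check_same_antibody(a, b)
    ra, rb = a.residues(), b.residues()
    return MethodComparison(ra & rb, ra - rb, rb - ra, set(gold))


def per_region_stats(annotation: RegionAnnotation,
                     gold: set[ResidueKey]) -> pd.DataFrame:
    """Per-region residue counts, precision and recall contribution.

    Precision is the fraction of the region's residues that contact the
    antigen; recall is the fraction of *all* binding residues captured
    by the region, so disjoint regions' recalls sum to the whole-
    antibody recall.
    """
    rows = []
    for name in REGION_NAMES:
        res = annotation.region_residues(name)
        n_contact = len(res & gold)
        rows.append({
            "scheme": annotation.scheme,
            "region": name,
            "n_residues": len(res),
            "n_in_contact": n_contact,
            "precision": n_contact / len(res) if res else math.nan,
            "recall": n_contact / len(gold) if gold else math.nan,
        })
    return pd.DataFrame(rows)


def find_unique_binding_residues(paratome: RegionAnnotation,
                                 cdr_annotations: list[RegionAnnotation],
                                 gold: set[ResidueKey],
                                 ) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Binding residues unique to the consensus regions vs to the CDRs.

    ``paratome_unique`` = binding residues inside the ABRs missed by
    every CDR scheme; ``cdrs_unique`` = binding residues inside any CDR
    scheme's regions missed by the ABRs.
    """
    _check_same_antibody(paratome, *cdr_annotations)
    present = {a.scheme for a in cdr_annotations}
    for scheme in ("kabat", "chothia", "imgt"):
        if scheme not in present:
            raise ValueError(f"missing CDR scheme: {scheme}")
    cdr_union: set[ResidueKey] = set()
    for a in cdr_annotations:
        cdr_union |= a.residues()
    par = paratome.residues()
    paratome_unique = (gold & par) - cdr_union
    cdrs_unique = (gold & cdr_union) - par
    return paratome_unique, cdrs_unique


DDG_THRESHOLD = 0.25   # kcal/mol; neutral band is inclusive


def classify_ddg(ddg: float) -> str:
    """Ternary ΔΔG class: destabilizing > 0.25, stabilizing < −0.25,
    neutral in the closed band between."""
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if ddg > DDG_THRESHOLD:
        return "destabilizing"
    if ddg < -DDG_THRESHOLD:
        return "stabilizing"
    return "neutral"


def macro_average(values: list[float | None]) -> float | None:
    """Mean over antibodies, skipping undefined (None) entries."""
    present = [v for v in values if v is not None]
    return sum(present) / len(present) if present else None
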