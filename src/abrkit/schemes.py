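"""Antibody numbering schemes and CDR extraction.

Kabat, Chothia and IMGT each define a canonical position labelling of
antibody variable domains; CDRs are then fixed label intervals (e.g.
Kabat CDR-H2 = positions 50-65).  Numbering here is template transfer:
the query is globally aligned to a pre-numbered reference template of
the same chain type and labels are carried across, with insertions
relative to the template placed as lettered labels at each scheme's
insertion anchor.  Boundary tables and anchors are shipped as versioned
JSON config so alternate revisions can be pinned.

The shipped templates are synthetic, author-constructed canonical-length
VH/VL sequences with parallel labels under all three schemes; they are a
stand-in for service-derived numbering and are sufficient for boundary
extraction on antibodies without exotic indels.
"""

from __future__ import annotations

import functools
import json
import logging
import string
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .regions import HEAVY_REGIONS, LIGHT_REGIONS, RegionAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "NumberedSequence",
    "CdrBoundaryTable",
    "NumberingTemplate",
    "UnnumberableError",
    "load_templates",
    "load_boundary_table",
    "number_sequence",
    "extract_cdrs",
    "convert_numbering",
]

NUMBERING_SCHEMES = ("kabat", "chothia", "imgt")


@functools.total_ordering
@dataclass(frozen=True)
class Label:
    """A scheme position label: integer position plus insertion letters.

    Collation follows scheme convention: ``35 < 35A < 35B < 36``.
    """

    number: int
    insertion: str = ""

    @classmethod
    def parse(cls, text: str) -> "Label":
        text = text.strip()
        i = len(text)
        while i > 0 and text[i - 1].isalpha():
            i -= 1
        if i == 0:
            raise ValueError(f"unparseable label {text!r}")
        return cls(int(text[:i]), text[i:].upper())

    def _key(self):
        return (self.number, self.insertion)

    def __lt__(self, other: "Label"):
        return self._key() < other._key()

    def __str__(self):
        return f"{self.number}{self.insertion}"

    def with_letter(self, k: int) -> "Label":
        """k-th insertion letter on this base position (k=0 -> 'A')."""
        letters = ""
        k += 1
        while k:
            k, rem = divmod(k - 1, 26)
            letters = string.ascii_uppercase[rem] + letters
        return Label(self.number, self.insertion + letters)


@dataclass
class NumberedSequence:
    """A chain sequence with per-residue scheme labels.

    ``labels[i]`` is None for residues left unnumbered at the termini.
    """

    chain: str                      # 'heavy' | 'light'
    scheme: str
    sequence: str
    labels: list[Label | None]

    def __post_init__(self):
        if len(self.sequence) != len(self.labels):
            raise ValueError("label/sequence length mismatch")
        present = [l for l in self.labels if l is not None]
        for a, b in zip(present, present[1:]):
            if not a < b:
                raise ValueError(f"labels out of order: {a} !< {b}")

    def items(self):
        return list(zip(self.labels, self.sequence))

    def index_of(self, label: Label) -> int | None:
        for i, l in enumerate(self.labels):
            if l == label:
                return i
        return None


@dataclass
class CdrBoundaryTable:
    scheme: str
    rows: dict[str, tuple[Label, Label]]   # region -> (start, end)
    version: str = ""

    def __post_init__(self):
        for region, (s, e) in self.rows.items():
            if not (s < e or s == e):
                raise ValueError(f"{region}: start {s} > end {e}")


@dataclass
class NumberingTemplate:
    id: str
    chain: str
    sequence: str
    labels: dict[str, list[Label]]          # scheme -> per-residue label

    def framework_mask(self, scheme: str,
                       table: "CdrBoundaryTable") -> list[bool]:
        """True where the residue lies outside every CDR of ``scheme``."""
        mask = []
        for lab in self.labels[scheme]:
            in_cdr = any(s <= lab <= e for s, e in table.rows.values())
            mask.append(not in_cdr)
        return mask


class UnnumberableError(ValueError):
    """No reference template aligns well enough to number the query."""


# ---------------------------------------------------------------------------
# config loading


def _data_text(name: str) -> str:
    return resources.files("abrkit.data").joinpath(name).read_text()


@functools.lru_cache(maxsize=None)
def _tables_config() -> dict:
    return json.loads(_data_text("scheme_tables.json"))


@functools.lru_cache(maxsize=None)
def load_boundary_table(scheme: str, chain: str) -> CdrBoundaryTable:
    cfg = _tables_config()
    raw = cfg["boundaries"][scheme][chain]
    rows = {region: (Label.parse(s), Label.parse(e))
            for region, (s, e) in raw.items()}
    return CdrBoundaryTable(scheme, rows, cfg["version"])


@functools.lru_cache(maxsize=None)
def insertion_anchor(scheme: str, chain: str, region: str) -> Label:
    return Label.parse(_tables_config()["insertion_anchors"][scheme][chain][region])


@functools.lru_cache(maxsize=None)
def load_templates() -> tuple[NumberingTemplate, ...]:
    cfg = json.loads(_data_text("templates.json"))
    out = []
    for t in cfg["templates"]:
        labels = {scheme: [Label.parse(x) for x in labs]
                  for scheme, labs in t["labels"].items()}
        out.append(NumberingTemplate(t["id"], t["chain"], t["sequence"], labels))
    return tuple(out)


# ---------------------------------------------------------------------------
# numbering


def _global_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12
    al.extend_gap_score = -1
    # soft terminal gaps: variable domains may be embedded in longer chains
    al.open_end_gap_score = -2
    al.extend_end_gap_score = -1
    return al


def _aligned_pairs(alignment) -> list[tuple[int, int]]:
    pairs = []
    for (qs, qe), (rs, re) in zip(*alignment.aligned):
        pairs.extend((int(qs) + k, int(rs) + k) for k in range(int(qe - qs)))
    return pairs


def _best_template(seq: str, chain: str, scheme: str,
                   references: tuple[NumberingTemplate, ...],
                   min_fr_identity: float):
    table = load_boundary_table(scheme, chain)
    aligner = _global_aligner()
    best = None
    for ref in sorted(references, key=lambda r: r.id):
        if ref.chain != chain:
            continue
        aln = aligner.align(seq, ref.sequence)[0]
        pairs = _aligned_pairs(aln)
        fr_mask = ref.framework_mask(scheme, table)
        fr_pairs = [(q, r) for q, r in pairs if fr_mask[r]]
        n_fr = sum(fr_mask)
        ident = (sum(seq[q] == ref.sequence[r] for q, r in fr_pairs) / n_fr
                 if n_fr else 0.0)
        if best is None or ident > best[0]:
            best = (ident, ref, pairs)
    if best is None or best[0] < min_fr_identity:
        got = 0.0 if best is None else best[0]
        raise UnnumberableError(
            f"no reference aligns with >= {min_fr_identity:.0%} framework "
            f"identity (best {got:.0%})")
    return best


def _region_of(label: Label, table: CdrBoundaryTable) -> str | None:
    for region, (s, e) in table.rows.items():
        if s <= label <= e:
            return region
    return None


def _refill_region(labels: list[Label | None], idx: list[int],
                   table: CdrBoundaryTable, region: str, scheme: str,
                   chain: str) -> None:
    """Re-derive the labels of one CDR stretch after an indel.

    The region's residues are renumbered over the base label run between
    its first and last transferred label; surplus residues receive
    lettered labels at the scheme's insertion anchor; a deficit removes
    labels around the anchor.
    """
    present = [labels[i] for i in idx if labels[i] is not None]
    base = sorted(set(present))
    anchor = insertion_anchor(scheme, chain, region)
    m = len(idx)
    # base run of candidate labels, anchored on what the template offered
    if m <= len(base):
        k = sum(1 for b in base if b <= anchor)
        left = min(k, m)
        assigned = base[:left] + base[len(base) - (m - left):]
    else:
        k = sum(1 for b in base if b <= anchor)
        extra = m - len(base)
        anchor_base = base[k - 1] if k else anchor
        assigned = (base[:k]
                    + [anchor_base.with_letter(j) for j in range(extra)]
                    + base[k:])
    for i, lab in zip(idx, assigned):
        labels[i] = lab


def number_sequence(seq: str, chain: str, scheme: str,
                    references: tuple[NumberingTemplate, ...] | None = None,
                    min_fr_identity: float = 0.5) -> NumberedSequence:
    """Number a bare antibody chain sequence under a scheme.

    Labels are transferred from the best-matching pre-numbered template
    (highest framework identity); insertions relative to the template
    are placed as lettered labels at the scheme's anchor position for
    the enclosing CDR, or appended to the preceding label inside
    frameworks.  Terminal overhangs stay unnumbered.
    """
    seq = seq.upper()
    if chain not in ("heavy", "light"):
        raise ValueError("chain must be 'heavy' or 'light'")
    if scheme not in NUMBERING_SCHEMES:
        raise ValueError(f"unknown numbering scheme {scheme!r}")
    if len(seq) < 70:
        raise UnnumberableError(f"sequence too short to number ({len(seq)} aa)")
    references = references or load_templates()
    _, ref, pairs = _best_template(seq, chain, scheme, references,
                                   min_fr_identity)
    table = load_boundary_table(scheme, chain)

    labels: list[Label | None] = [None] * len(seq)
    for q, r in pairs:
        labels[q] = ref.labels[scheme][r]

    aligned_q = [q for q, _ in pairs]
    first_q, last_q = aligned_q[0], aligned_q[-1]

    # group CDR regions that received any label, pull interior gaps in,
    # and renumber each around the scheme anchor
    for region in table.rows:
        idx = [i for i, l in enumerate(labels)
               if l is not None and _region_of(l, table) == region]
        if not idx:
            continue
        full = list(range(idx[0], idx[-1] + 1))
        if len(full) != len(idx) or any(labels[i] is None for i in full) \
                or len(set(labels[i] for i in full)) != len(full):
            _refill_region(labels, full, table, region, scheme, chain)

    # interior framework insertions: letters on the preceding label
    run_start = None
    for i in range(first_q, last_q + 1):
        if labels[i] is None:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            prev = labels[run_start - 1]
            for j, pos in enumerate(range(run_start, i)):
                labels[pos] = prev.with_letter(j)
            run_start = None

    return NumberedSequence(chain, scheme, seq, labels)


# ---------------------------------------------------------------------------
# CDR extraction and conversion


def extract_cdrs(numbered: NumberedSequence,
                 table: CdrBoundaryTable | None = None,
                 antibody_id: str = "query") -> RegionAnnotation:
    """Slice CDRs out of a numbered sequence by the boundary table.

    Each CDR is the residues whose labels fall inclusively between the
    region's start and end labels, insertion-lettered labels included.
    A missing boundary label truncates the region at the nearest present
    label (logged).
    """
    if table is None:
        table = load_boundary_table(numbered.scheme, numbered.chain)
    if numbered.scheme != table.scheme:
        raise ValueError("scheme mismatch between sequence and table")
    names = HEAVY_REGIONS if numbered.chain == "heavy" else LIGHT_REGIONS
    spans: dict[str, tuple[int, int] | None] = {}
    for region in names:
        if region not in table.rows:
            spans[region] = None
            continue
        start, end = table.rows[region]
        idx = [i for i, l in enumerate(numbered.labels)
               if l is not None and start <= l <= end]
        if idx and not start.insertion and start not in numbered.labels:
            logger.warning("%s: start label %s absent; truncated at %s",
                           region, start, numbered.labels[idx[0]])
        if idx and not end.insertion and end not in numbered.labels:
            logger.warning("%s: end label %s absent; truncated at %s",
                           region, end, numbered.labels[idx[-1]])
        spans[region] = (idx[0], idx[-1]) if idx else None
    return RegionAnnotation(antibody_id, numbered.scheme, spans)


@functools.lru_cache(maxsize=None)
def _conversion_table(chain: str, source: str,
                      target: str) -> dict[Label, Label]:
    """Fixed label map derived from the parallel-numbered templates."""
    mapping: dict[Label, Label] = {}
    for t in load_templates():
        if t.chain != chain:
            continue
        for a, b in zip(t.labels[source], t.labels[target]):
            if a in mapping and mapping[a] != b:
                raise ValueError(f"ambiguous conversion for label {a}")
            mapping[a] = b
    return mapping


def convert_numbering(numbered: NumberedSequence,
                      target_scheme: str) -> NumberedSequence:
    """Re-express labels in another scheme via the fixed conversion map.

    Insertion-lettered labels convert through their base position with
    letters preserved; a base label absent from the map is an error.
    """
    if target_scheme not in NUMBERING_SCHEMES:
        raise ValueError(f"unknown scheme {target_scheme!r}")
    if target_scheme == numbered.scheme:
        return numbered
    mapping = _conversion_table(numbered.chain, numbered.scheme, target_scheme)
    out: list[Label | None] = []
    for lab in numbered.labels:
        if lab is None:
            out.append(None)
        elif lab in mapping:
            out.append(mapping[lab])
        elif lab.insertion and Label(lab.number) in mapping:
            base = mapping[Label(lab.number)]
            out.append(Label(base.number, base.insertion + lab.insertion))
        else:
            raise ValueError(f"unmappable label: {lab}")
    return NumberedSequence(numbered.chain, target_scheme,
                            numbered.sequence, out)
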