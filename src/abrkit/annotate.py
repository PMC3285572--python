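"""Transfer of ABR annotations to query antibodies.

A query antibody, given as bare heavy/light sequences or as a structure,
is annotated by finding its best hit in a non-redundant reference set of
ABR-annotated antibodies and carrying the hit's region boundaries
across.  Sequence transfer aligns only the framework segments — the
four conserved stretches between the regions — with Smith-Waterman
local alignment, because the hypervariable regions themselves would
misguide a global alignment.  Structure transfer superposes the query
onto the hit on framework Cα atoms and maps residues by proximity.

Best-hit search is a full Smith-Waterman scan of the reference set
(highest score standing in for lowest E-value); reference sets here are
at most a few hundred entries, so an indexed search tool buys nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .regions import HEAVY_REGIONS, LIGHT_REGIONS, RegionAnnotation
from .schemes import _aligned_pairs, _global_aligner
from .structure_io import Chain, ComplexStructure, superpose

logger = logging.getLogger(__name__)

__all__ = [
    "LocalAlignment",
    "ReferenceEntry",
    "AnnotatedReferenceSet",
    "AnnotationError",
    "smith_waterman",
    "find_best_hit",
    "infer_abrs_sequence",
    "infer_abrs_structure",
]


class AnnotationError(ValueError):
    pass


@dataclass
class LocalAlignment:
    """An optimal local alignment with affine gap penalties."""

    query_span: tuple[int, int] | None    # [start, end) in a
    hit_span: tuple[int, int] | None      # [start, end) in b
    pairs: list[tuple[int, int]]
    score: float
    identity: float

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")


@dataclass
class ReferenceEntry:
    id: str
    heavy_seq: str
    light_seq: str
    annotation: RegionAnnotation
    structure: ComplexStructure | None = None

    def chain_seq(self, role: str) -> str:
        return self.heavy_seq if role == "heavy" else self.light_seq

    def __post_init__(self):
        for region in LIGHT_REGIONS + HEAVY_REGIONS:
            if self.annotation.spans.get(region) is None:
                raise ValueError(
                    f"reference {self.id}: incomplete annotation ({region})")


@dataclass
class AnnotatedReferenceSet:
    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_json(self) -> str:
        return json.dumps({
            "entries": [{
                "id": e.id,
                "heavy_seq": e.heavy_seq,
                "light_seq": e.light_seq,
                "annotation": e.annotation.to_dict(),
            } for e in self.entries]
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnnotatedReferenceSet":
        d = json.loads(text)
        return cls([ReferenceEntry(
            x["id"], x["heavy_seq"], x["light_seq"],
            RegionAnnotation.from_dict(x["annotation"]))
            for x in d["entries"]])


# ---------------------------------------------------------------------------
# Smith-Waterman

_MAX_COOPT = 64   # co-optimal alignments examined for the tie-break


def _local_aligner(matrix: str | None, gap_open: float, gap_extend: float,
                   match: float, mismatch: float):
    al = Align.PairwiseAligner()
    al.mode = "local"
    if matrix is not None:
        al.substitution_matrix = substitution_matrices.load(matrix)
    else:
        al.match_score = match
        al.mismatch_score = mismatch
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def smith_waterman(a: str, b: str, matrix: str | None = "BLOSUM62",
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   match: float = 4.0,
                   mismatch: float = -4.0) -> LocalAlignment:
    """Optimal local alignment of ``a`` vs ``b`` under affine gaps.

    Scoring uses the named substitution matrix, or plain match/mismatch
    scores when ``matrix`` is None.  Ties between co-optimal alignments
    break deterministically: longest alignment first, then earliest
    start in ``a``, then in ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _local_aligner(matrix, gap_open, gap_extend, match, mismatch)
    score = aligner.score(a, b)
    if score <= 0:
        return LocalAlignment(None, None, [], 0.0, 0.0)
    alignments = aligner.align(a, b)
    best = None
    for i, aln in enumerate(alignments):
        if i >= _MAX_COOPT:
            break
        pairs = _aligned_pairs(aln)
        span_a = (pairs[0][0], pairs[-1][0] + 1)
        span_b = (pairs[0][1], pairs[-1][1] + 1)
        key = (-len(pairs), span_a[0], span_b[0])
        if best is None or key < best[0]:
            best = (key, pairs, span_a, span_b)
    _, pairs, span_a, span_b = best
    ident = sum(a[i] == b[j] for i, j in pairs) / len(pairs)
    return LocalAlignment(span_a, span_b, pairs, float(score), ident)


def find_best_hit(query: str, refs: AnnotatedReferenceSet, role: str,
                  score_floor: float | None = None,
                  matrix: str = "BLOSUM62", gap_open: float = 11.0,
                  gap_extend: float = 1.0,
                  ) -> tuple[ReferenceEntry, LocalAlignment]:
    """Highest-scoring reference entry for one chain (full-set scan).

    Score ties break by higher identity, then lexicographic id.
    """
    if len(refs) == 0:
        raise AnnotationError("reference set is empty")
    best = None
    for entry in sorted(refs, key=lambda e: e.id):
        aln = smith_waterman(query, entry.chain_seq(role), matrix,
                             gap_open, gap_extend)
        key = (-aln.score, -aln.identity, entry.id)
        if best is None or key < best[0]:
            best = (key, entry, aln)
    _, entry, aln = best
    if score_floor is not None and aln.score < score_floor:
        raise AnnotationError(
            f"no credible hit: best score {aln.score} below floor")
    return entry, aln


# ---------------------------------------------------------------------------
# sequence-route transfer


def _framework_segments(entry: ReferenceEntry, role: str) -> list[str]:
    """The four framework segments flanking the three regions."""
    seq = entry.chain_seq(role)
    names = HEAVY_REGIONS if role == "heavy" else LIGHT_REGIONS
    spans = [entry.annotation.spans[n] for n in names]
    cuts = [0]
    for s, e in spans:
        cuts.extend([s, e + 1])
    cuts.append(len(seq))
    return [seq[cuts[2 * k]:cuts[2 * k + 1]] for k in range(4)]


def _transfer_chain(query: str, entry: ReferenceEntry, role: str,
                    min_fr_identity: float, min_fr_length: int,
                    ) -> tuple[dict[str, tuple[int, int] | None], dict]:
    names = HEAVY_REGIONS if role == "heavy" else LIGHT_REGIONS
    frs = _framework_segments(entry, role)
    bounds: list[tuple[int, int]] = []   # aligned [start, end) per FR in query
    pos = 0
    identities = []
    for k, fr in enumerate(frs):
        if not fr:
            raise AnnotationError(
                f"reference {entry.id}: empty framework FR{k + 1}")
        aln = smith_waterman(fr, query[pos:])
        if aln.score <= 0 or aln.identity < min_fr_identity:
            raise AnnotationError(
                f"framework FR{k + 1} of {role} chain failed to align "
                f"(identity {aln.identity:.0%})")
        qs, qe = aln.hit_span
        # local alignment trims mismatching framework termini; the
        # segment's length is known, so reclaim the trimmed residues
        # (gap-free edge extension) instead of leaking them into ABRs
        fs, fe = aln.query_span
        left_floor = bounds[-1][1] - pos if bounds else 0
        qs -= min(fs, qs - max(left_floor, 0))
        qe += min(len(fr) - fe, len(query) - (pos + qe))
        bounds.append((pos + qs, pos + qe))
        identities.append(aln.identity)
        pos = pos + qe
    total_aligned = sum(e - s for s, e in bounds)
    if total_aligned < min_fr_length:
        raise AnnotationError(
            f"only {total_aligned} framework residues aligned on the "
            f"{role} chain (< {min_fr_length})")
    spans: dict[str, tuple[int, int] | None] = {}
    for k, name in enumerate(names):
        s = bounds[k][1]          # first residue after FR_k
        e = bounds[k + 1][0] - 1  # last residue before FR_{k+1}
        spans[name] = (s, e) if s <= e else None
    meta = {f"{role}_hit": entry.id,
            f"{role}_fr_identity": [round(x, 4) for x in identities]}
    return spans, meta


def infer_abrs_sequence(heavy_seq: str, light_seq: str,
                        refs: AnnotatedReferenceSet,
                        antibody_id: str = "query",
                        min_fr_identity: float = 0.4,
                        min_fr_length: int = 50) -> RegionAnnotation:
    """Sequence-route ABR transfer from the best reference hit.

    Each chain is annotated independently from its own best hit: the
    hit's four framework segments are locally aligned to the query in
    order, and each query region is the stretch strictly between the
    aligned end of one framework and the aligned start of the next.
    """
    spans: dict[str, tuple[int, int] | None] = {}
    meta: dict = {}
    hits = {}
    for role, seq in (("heavy", heavy_seq), ("light", light_seq)):
        if not seq:
            raise AnnotationError(f"missing {role} chain sequence")
        entry, _ = find_best_hit(seq, refs, role)
        hits[role] = entry.id
        s, m = _transfer_chain(seq, entry, role, min_fr_identity,
                               min_fr_length)
        spans.update(s)
        meta.update(m)
    if hits["heavy"] != hits["light"]:
        logger.info("best heavy hit (%s) and light hit (%s) differ",
                    hits["heavy"], hits["light"])
    return RegionAnnotation(antibody_id, "paratome", spans, meta)


# ---------------------------------------------------------------------------
# structure-route transfer


def _chain_pair(query, role: str) -> Chain:
    if isinstance(query, ComplexStructure):
        return query.chain(role)
    return query[0] if role == "heavy" else query[1]


def infer_abrs_structure(query, refs: AnnotatedReferenceSet,
                         antibody_id: str | None = None,
                         ca_match: float = 4.0,
                         max_fr_rmsd: float = 5.0) -> RegionAnnotation:
    """Structure-route ABR transfer via framework superposition.

    ``query`` is a :class:`ComplexStructure` or a ``(heavy, light)``
    pair of :class:`Chain`.  The query chain is superposed onto the best
    hit's chain on framework Cα pairs (sequence pre-anchored), residues
    are matched by nearest Cα within ``ca_match`` Å, and the hit's
    region spans are carried through the correspondence.
    """
    aligner = _global_aligner()
    spans: dict[str, tuple[int, int] | None] = {}
    meta: dict = {}
    if antibody_id is None:
        antibody_id = query.pdb_id if isinstance(query, ComplexStructure) \
            else "query"
    for role in ("heavy", "light"):
        chain = _chain_pair(query, role)
        entry, _ = find_best_hit(chain.sequence, refs, role)
        if entry.structure is None:
            raise AnnotationError(
                f"best hit {entry.id} carries no structure reference")
        hit_chain = entry.structure.chain(role)
        names = HEAVY_REGIONS if role == "heavy" else LIGHT_REGIONS
        region_idx = {i for n in names
                      for i in range(entry.annotation.spans[n][0],
                                     entry.annotation.spans[n][1] + 1)}
        aln = aligner.align(chain.sequence, hit_chain.sequence)[0]
        fr_pairs = [(q, r) for q, r in _aligned_pairs(aln)
                    if r not in region_idx
                    and chain.residues[q].ca is not None
                    and hit_chain.residues[r].ca is not None]
        if len(fr_pairs) < 3:
            raise AnnotationError(f"{role}: too few framework anchors")
        q_ca = chain.ca_coords()
        h_ca = hit_chain.ca_coords()
        hit_pts = np.array([h_ca[r] for _, r in fr_pairs])
        q_pts = np.array([q_ca[q] for q, _ in fr_pairs])
        R, t, rmsd = superpose(hit_pts, q_pts)
        if rmsd > max_fr_rmsd:
            raise AnnotationError(
                f"unreliable transfer: framework RMSD {rmsd:.2f} Å "
                f"> {max_fr_rmsd} Å on the {role} chain")
        moved = np.where(np.isnan(q_ca).any(axis=1)[:, None],
                         np.nan, q_ca @ R.T + t)
        ok = np.where(~np.isnan(moved).any(axis=1))[0]
        tree = cKDTree(moved[ok])
        meta[f"{role}_hit"] = entry.id
        meta[f"{role}_fr_rmsd"] = round(rmsd, 4)
        for name in names:
            s, e = entry.annotation.spans[name]
            matched = []
            for r in range(s, e + 1):
                if np.isnan(h_ca[r]).any():
                    continue
                d, j = tree.query(h_ca[r], distance_upper_bound=ca_match)
                if np.isfinite(d):
                    matched.append(int(ok[j]))
            spans[name] = (min(matched), max(matched)) if matched else None
    return RegionAnnotation(antibody_id, "paratome", spans, meta)
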