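"""Curation of a non-redundant annotated reference set.

Raw antibody-antigen complexes are screened (exactly one heavy, one
light and one protein antigen chain of at least five residues, with the
antibody actually touching the antigen), clustered by sequence
(identity >= 97%, both-ways coverage >= 95%, single linkage), and
de-redundanted *within* clusters by the similarity of their contact
lists: two complexes are redundant when the fraction of identical
contacts, relative to the shorter contact list, reaches 0.77.  Each
redundancy group keeps the member with the most contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import ComplexStructure, ContactSet, extract_contacts, \
    is_interacting, parse_complex, ComplexParseError

logger = logging.getLogger(__name__)

__all__ = [
    "CurationConfig",
    "ContactFingerprint",
    "classify_chain",
    "filter_complexes",
    "cluster_sequences",
    "contact_similarity",
    "remove_redundancy",
    "fingerprint",
]

ANTIBODY_CLASSES = ("antibody-heavy", "antibody-light")
EXCLUSION_CLASSES = ("mhc-1", "mhc-2", "tcr-a", "tcr-b")


@dataclass
class CurationConfig:
    """Thresholds of the screening and redundancy-removal pipeline."""

    class_score_thresholds: dict[str, float] = field(default_factory=dict)
    interaction_cutoff: float = 6.0
    min_antigen_length: int = 5
    identity_threshold: float = 0.97
    coverage_threshold: float = 0.95
    contact_similarity_cutoff: float = 0.77

    def __post_init__(self):
        for name, v in (("identity", self.identity_threshold),
                        ("coverage", self.coverage_threshold),
                        ("similarity", self.contact_similarity_cutoff)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} threshold must lie in (0, 1]")
        if self.interaction_cutoff <= 0:
            raise ValueError("interaction cutoff must be positive")


@dataclass(frozen=True)
class ContactFingerprint:
    """Identity-bearing contact list of one complex.

    Entries pair (antibody amino acid, position) with (antigen amino
    acid, position); positions are alignment columns when a multiple
    alignment is available, author numbering otherwise.
    """

    complex_id: str
    entries: frozenset[tuple[tuple[str, str], tuple[str, str]]]
    position_source: str = "author"


def fingerprint(cs: ContactSet, complex: ComplexStructure,
                columns: dict[str, list[int | None]] | None = None,
                ) -> ContactFingerprint:
    """Build a fingerprint from a contact set.

    ``columns`` maps chain role to alignment rows (column -> residue
    index); when given, antibody positions are alignment columns.
    """
    col_of: dict[tuple[str, int], str] = {}
    source = "author"
    if columns is not None:
        source = "alignment"
        for role, row in columns.items():
            for col, idx in enumerate(row):
                if idx is not None:
                    col_of[(role, idx)] = f"{role[0]}{col}"
    entries = set()
    for c in cs:
        if columns is not None:
            ab_pos = col_of.get((c.ab_role, c.ab_index))
            if ab_pos is None:
                continue
        else:
            ab_pos = f"{c.ab_role[0]}{c.ab_residue.resid}"
        entries.add(((c.ab_residue.aa, ab_pos),
                     (c.ag_residue.aa, c.ag_residue.resid)))
    return ContactFingerprint(cs.pdb_id, frozenset(entries), source)


# ---------------------------------------------------------------------------
# chain classification


def _sw_score(a: str, b: str) -> float:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12
    al.extend_gap_score = -1
    return float(al.score(a, b))


def classify_chain(seq: str, references: dict[str, str],
                   cfg: CurationConfig) -> str:
    """Classify a chain against per-class exemplar sequences.

    Returns the highest-scoring class whose score passes its threshold,
    or ``"other"``.  An antibody call is vetoed when any TCR/MHC class
    also passes — mirroring the discard-by-similarity rule used to keep
    receptors out of the antibody pool.
    """
    scores = {cls: _sw_score(seq, ref) for cls, ref in references.items()}
    passing = {cls for cls, sc in scores.items()
               if sc >= cfg.class_score_thresholds.get(cls, float("inf"))}
    if not passing:
        return "other"
    if passing & set(ANTIBODY_CLASSES) and passing & set(EXCLUSION_CLASSES):
        return "other"
    return max(passing, key=lambda cls: (scores[cls], cls))


# ---------------------------------------------------------------------------
# complex screening


def filter_complexes(pool, cfg: CurationConfig | None = None):
    """Screen a pool of complexes; returns (kept, report).

    ``pool`` items are either parsed :class:`ComplexStructure` objects
    or ``(pdb_id, pdb_text, role_map)`` tuples (parsed here so that
    malformed entries become logged rejections rather than exceptions).
    ``report`` rows are ``(pdb_id, decision, reason)``.
    """
    cfg = cfg or CurationConfig()
    kept: list[ComplexStructure] = []
    report: list[tuple[str, str, str]] = []
    seen: set[tuple[str, ...]] = set()
    for item in pool:
        if isinstance(item, ComplexStructure):
            pdb_id, cx = item.pdb_id, item
        else:
            pdb_id, text, role_map = item
            try:
                cx = parse_complex(text, role_map, pdb_id)
            except ComplexParseError as exc:
                report.append((pdb_id, "rejected", str(exc)))
                continue
        if len(cx.antigen) < cfg.min_antigen_length:
            report.append((pdb_id, "rejected", "antigen too short"))
            continue
        key = (pdb_id, cx.heavy.sequence, cx.light.sequence,
               cx.antigen.sequence)
        if key in seen:
            report.append((pdb_id, "rejected", "duplicate chains"))
            continue
        if not is_interacting(cx, cfg.interaction_cutoff):
            report.append((pdb_id, "rejected", "not interacting"))
            continue
        seen.add(key)
        kept.append(cx)
        report.append((pdb_id, "kept", ""))
    return kept, report


# ---------------------------------------------------------------------------
# sequence clustering


def _identity_coverage(a: str, b: str) -> tuple[float, float, float]:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12
    al.extend_gap_score = -1
    al.open_end_gap_score = 0
    al.extend_end_gap_score = 0
    aln = al.align(a, b)[0]
    pairs = []
    for (qs, qe), (rs, _) in zip(*aln.aligned):
        pairs.extend((int(qs) + k, int(rs) + k) for k in range(int(qe - qs)))
    if not pairs:
        return 0.0, 0.0, 0.0
    matches = sum(a[i] == b[j] for i, j in pairs)
    ident = matches / min(len(a), len(b))
    return ident, len(pairs) / len(a), len(pairs) / len(b)


def cluster_sequences(seqs: dict[str, str], identity: float = 0.97,
                      coverage: float = 0.95) -> list[list[str]]:
    """Greedy single-linkage clusters over global-alignment identity.

    Two sequences link when identity (matches over the shorter length)
    meets ``identity`` and the aligned fraction of *each* sequence
    meets ``coverage``.  Ordering is deterministic: longest first, then
    id.
    """
    ids = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i_pos, a in enumerate(ids):
        for b in ids[i_pos + 1:]:
            ident, cov_a, cov_b = _identity_coverage(seqs[a], seqs[b])
            if ident >= identity and cov_a >= coverage and cov_b >= coverage:
                parent[find(b)] = find(a)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


# ---------------------------------------------------------------------------
# redundancy removal


def contact_similarity(a: ContactFingerprint,
                       b: ContactFingerprint) -> float:
    """Shared contacts over the size of the shorter contact list."""
    if not a.entries or not b.entries:
        logger.warning("empty contact fingerprint (%s / %s)",
                       a.complex_id, b.complex_id)
        return 0.0
    return len(a.entries & b.entries) / min(len(a.entries), len(b.entries))


def remove_redundancy(members: list[ContactFingerprint],
                      cutoff: float = 0.77) -> list[str]:
    """Representatives of a cluster after contact-based deduplication.

    Members linked (single linkage) at similarity >= ``cutoff`` form a
    redundancy group represented by the member with the most contacts
    (ties by id); members below the cutoff to everything survive as-is.
    """
    ids = sorted(m.complex_id for m in members)
    by_id = {m.complex_id: m for m in members}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i_pos, a in enumerate(ids):
        for b in ids[i_pos + 1:]:
            if contact_similarity(by_id[a], by_id[b]) >= cutoff:
                parent[find(b)] = find(a)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    reps = [min(grp, key=lambda i: (-len(by_id[i].entries), i))
            for grp in groups.values()]
    return sorted(reps)
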