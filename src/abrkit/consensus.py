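"""Consensus derivation of antigen-binding regions (ABRs).

Across a multiple structure alignment of antibodies bound to their
antigens, certain aligned positions contact the antigen in many
different antibodies.  Maximal stretches of columns in which at least a
threshold fraction of the antibodies (10% by default) contact the
antigen form exactly six regions — three per chain — and those column
ranges are the ABR definition.  The definition is frozen at training
time and then projected onto individual antibodies through their
alignment rows.

The multiple alignment itself is a reference-anchored progressive
superposition: every antibody is rigidly fitted (Kabsch) onto the best
resolved structure of the set and residues are assigned to columns by
mutual-nearest Cα matching; residues without a counterpart open
insertion columns.  An externally computed alignment (e.g. from a
dedicated multiple-structure aligner) can be supplied instead via
:func:`aligned_set_from_rows` — the consensus logic is agnostic to the
alignment's origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from scipy.spatial import cKDTree

from .regions import HEAVY_REGIONS, LIGHT_REGIONS, RegionAnnotation
from .schemes import _global_aligner, _aligned_pairs
from .structure_io import ComplexStructure, ContactSet, extract_contacts, superpose

__all__ = [
    "AlignedAntibodySet",
    "ColumnProfile",
    "AbrDefinition",
    "ConsensusError",
    "align_antibody_set",
    "aligned_set_from_rows",
    "build_column_profiles",
    "derive_abr_boundaries",
    "map_abrs_to_antibody",
]

ROLES = ("light", "heavy")


class ConsensusError(ValueError):
    pass


@dataclass
class AlignedAntibodySet:
    """Per-chain alignment rows plus per-column contact flags.

    ``rows[role][ab_id][col]`` is the residue index occupying a column
    (None at gaps); ``contact_flags`` mirrors the shape and is False at
    every gap column.
    """

    ids: list[str]
    n_columns: dict[str, int]
    rows: dict[str, dict[str, list[int | None]]]
    contact_flags: dict[str, dict[str, list[bool]]]
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    reference_id: str | None = None

    def __post_init__(self):
        for role in ROLES:
            n = self.n_columns[role]
            for ab in self.ids:
                if len(self.rows[role][ab]) != n:
                    raise ValueError(f"row length mismatch for {ab}/{role}")
                for flag, res in zip(self.contact_flags[role][ab],
                                     self.rows[role][ab]):
                    if flag and res is None:
                        raise ValueError("contact flag set at a gap column")

    def gapped_fasta(self, role: str) -> str:
        out = []
        for ab in self.ids:
            seq = self.sequences.get(role, {}).get(ab, "")
            row = self.rows[role][ab]
            out.append(f">{ab}")
            out.append("".join("-" if r is None else (seq[r] if seq else "X")
                               for r in row))
        return "\n".join(out) + "\n"

    def contact_flags_tsv(self, role: str) -> str:
        lines = ["\t".join(["antibody"] +
                           [str(c) for c in range(self.n_columns[role])])]
        for ab in self.ids:
            lines.append("\t".join(
                [ab] + ["1" if f else "0" for f in self.contact_flags[role][ab]]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ColumnProfile:
    chain: str
    column: int
    contact_fraction: float
    occupancy: float

    def __post_init__(self):
        if not (0 <= self.contact_fraction <= 1 and 0 <= self.occupancy <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.contact_fraction > self.occupancy + 1e-12:
            raise ValueError("contact fraction exceeds occupancy")


@dataclass
class AbrDefinition:
    """The trained model: six ABR spans as inclusive column ranges."""

    spans: dict[str, tuple[int, int]]
    threshold: float
    gap_merge: int = 2
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for role, names in (("light", LIGHT_REGIONS), ("heavy", HEAVY_REGIONS)):
            prev = -1
            for name in names:
                if name not in self.spans:
                    raise ValueError(f"missing region {name}")
                s, e = self.spans[name]
                if not (prev < s <= e):
                    raise ValueError(f"spans unordered/overlapping at {name}")
                prev = e

    def to_json(self) -> str:
        return json.dumps({
            "spans": {k: list(v) for k, v in self.spans.items()},
            "threshold": self.threshold,
            "gap_merge": self.gap_merge,
            "provenance": self.provenance,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AbrDefinition":
        d = json.loads(text)
        return cls({k: tuple(v) for k, v in d["spans"].items()},
                   d["threshold"], d.get("gap_merge", 2),
                   d.get("provenance", {}))


# ---------------------------------------------------------------------------
# alignment


def _match_columns(ref_ca: np.ndarray, mov_ca: np.ndarray,
                   max_dist: float) -> dict[int, int]:
    """Mutual-nearest, order-consistent residue matching (mov -> ref)."""
    ref_ok = np.where(~np.isnan(ref_ca).any(axis=1))[0]
    mov_ok = np.where(~np.isnan(mov_ca).any(axis=1))[0]
    if len(ref_ok) == 0 or len(mov_ok) == 0:
        return {}
    tree = cKDTree(ref_ca[ref_ok])
    d, j = tree.query(mov_ca[mov_ok], distance_upper_bound=max_dist)
    candidates = [(float(di), int(mi), int(ref_ok[ji]))
                  for di, mi, ji in zip(d, mov_ok, j)
                  if np.isfinite(di)]
    candidates.sort()
    used_ref: set[int] = set()
    used_mov: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, mi, ri in candidates:       # greedy injective assignment
        if mi in used_mov or ri in used_ref:
            continue
        used_mov.add(mi)
        used_ref.add(ri)
        pairs.append((mi, ri))
    pairs.sort()
    # keep the longest order-consistent subset (LIS over ref indices)
    if not pairs:
        return {}
    ref_seq = [r for _, r in pairs]
    n = len(ref_seq)
    best_len = [1] * n
    back = [-1] * n
    for i in range(n):
        for k in range(i):
            if ref_seq[k] < ref_seq[i] and best_len[k] + 1 > best_len[i]:
                best_len[i] = best_len[k] + 1
                back[i] = k
    i = int(np.argmax(best_len))
    keep = []
    while i != -1:
        keep.append(pairs[i])
        i = back[i]
    return dict(reversed(keep))


def align_antibody_set(structures: list[ComplexStructure],
                       contact_sets: list[ContactSet] | None = None,
                       cutoff: float = 6.0,
                       ca_match: float = 4.0,
                       min_chain_length: int = 60) -> AlignedAntibodySet:
    """Reference-anchored progressive structural alignment of antibodies.

    The structure with the most resolved Cα positions across both
    antibody chains anchors the column system (ties broken by smallest
    id); every other antibody is superposed onto it chain by chain.
    """
    if len(structures) < 2:
        raise ConsensusError("at least 2 structures required")
    ids = [s.pdb_id for s in structures]
    if len(set(ids)) != len(ids):
        raise ConsensusError("duplicate structure ids")
    for s in structures:
        for role in ROLES:
            ch = s.chain(role)
            if len(ch) < min_chain_length:
                raise ConsensusError(
                    f"{s.pdb_id}/{role}: chain too short to anchor "
                    f"({len(ch)} < {min_chain_length})")
    if contact_sets is None:
        contact_sets = [extract_contacts(s, cutoff) for s in structures]
    by_id = dict(zip(ids, structures))
    contacts_by_id = dict(zip(ids, contact_sets))

    def resolved(s: ComplexStructure) -> int:
        return sum(int(r.ca is not None)
                   for role in ROLES for r in s.chain(role))

    ref_id = min(ids, key=lambda i: (-resolved(by_id[i]), i))
    aligner = _global_aligner()

    rows: dict[str, dict[str, list[int | None]]] = {}
    n_columns: dict[str, int] = {}
    sequences: dict[str, dict[str, str]] = {}
    for role in ROLES:
        ref_chain = by_id[ref_id].chain(role)
        ref_ca = ref_chain.ca_coords()
        # column keys: (preceding ref residue, 0 ref / 1 insertion, owner, k)
        keys: list[tuple] = [(i, 0, "", 0) for i in range(len(ref_chain))]
        assignment: dict[str, dict[int, tuple]] = {
            ref_id: {i: (i, 0, "", 0) for i in range(len(ref_chain))}}
        for ab in ids:
            if ab == ref_id:
                continue
            chain = by_id[ab].chain(role)
            aln = aligner.align(chain.sequence, ref_chain.sequence)[0]
            seq_pairs = [(q, r) for q, r in _aligned_pairs(aln)
                         if chain.residues[q].ca is not None
                         and ref_chain.residues[r].ca is not None]
            if len(seq_pairs) < 3:
                raise ConsensusError(
                    f"{ab}/{role}: fewer than 3 Cα anchor pairs")
            mov_ca = chain.ca_coords()
            ref_pts = np.array([ref_ca[r] for _, r in seq_pairs])
            mov_pts = np.array([mov_ca[q] for q, _ in seq_pairs])
            R, t, _ = superpose(ref_pts, mov_pts)
            moved = np.where(np.isnan(mov_ca).any(axis=1)[:, None],
                             np.nan, mov_ca @ R.T + t)
            match = _match_columns(ref_ca, moved, ca_match)
            amap: dict[int, tuple] = {}
            prev_ref = -1
            pending: list[int] = []
            for qi in range(len(chain)):
                if qi in match:
                    for k, p in enumerate(pending):
                        key = (prev_ref, 1, ab, k)
                        keys.append(key)
                        amap[p] = key
                    pending = []
                    prev_ref = match[qi]
                    amap[qi] = (prev_ref, 0, "", 0)
                else:
                    pending.append(qi)
            for k, p in enumerate(pending):
                key = (prev_ref, 1, ab, k)
                keys.append(key)
                amap[p] = key
            assignment[ab] = amap
        order = {key: c for c, key in enumerate(sorted(set(keys)))}
        n_columns[role] = len(order)
        rows[role] = {}
        sequences[role] = {}
        for ab in ids:
            row: list[int | None] = [None] * len(order)
            for qi, key in assignment[ab].items():
                row[order[key]] = qi
            rows[role][ab] = row
            sequences[role][ab] = by_id[ab].chain(role).sequence

    contact_flags = _flags_from_contacts(ids, rows, contacts_by_id)
    return AlignedAntibodySet(ids, n_columns, rows, contact_flags,
                              sequences, ref_id)


def _flags_from_contacts(ids, rows, contacts_by_id):
    flags: dict[str, dict[str, list[bool]]] = {}
    for role in ROLES:
        flags[role] = {}
        for ab in ids:
            touched = {i for r, i in contacts_by_id[ab].ab_residue_keys()
                       if r == role}
            flags[role][ab] = [res is not None and res in touched
                               for res in rows[role][ab]]
    return flags


def aligned_set_from_rows(ids: list[str],
                          rows: dict[str, dict[str, list[int | None]]],
                          contact_residues: dict[str, set[tuple[str, int]]],
                          sequences: dict[str, dict[str, str]] | None = None,
                          ) -> AlignedAntibodySet:
    """Build an aligned set from externally supplied alignment rows.

    ``contact_residues[ab]`` is a set of (role, residue index) keys.
    This is the ingestion hook for alignments computed outside the
    package (gapped-FASTA imports reduce to this form).
    """
    n_columns = {role: len(next(iter(rows[role].values()))) for role in ROLES}
    flags: dict[str, dict[str, list[bool]]] = {role: {} for role in ROLES}
    for role in ROLES:
        for ab in ids:
            touched = {i for r, i in contact_residues.get(ab, set())
                       if r == role}
            flags[role][ab] = [res is not None and res in touched
                               for res in rows[role][ab]]
    return AlignedAntibodySet(ids, n_columns, rows, flags, sequences or {})


# ---------------------------------------------------------------------------
# consensus profiles and boundaries


def build_column_profiles(aligned: AlignedAntibodySet) -> list[ColumnProfile]:
    """Per-column contact fraction and occupancy, over *all* antibodies.

    The denominator is the full antibody count, gapped rows included.
    """
    if not aligned.ids:
        raise ValueError("empty aligned set")
    n_abs = len(aligned.ids)
    profiles = []
    for role in ROLES:
        for col in range(aligned.n_columns[role]):
            n_contact = sum(aligned.contact_flags[role][ab][col]
                            for ab in aligned.ids)
            n_occ = sum(aligned.rows[role][ab][col] is not None
                        for ab in aligned.ids)
            profiles.append(ColumnProfile(role, col,
                                          n_contact / n_abs, n_occ / n_abs))
    return profiles


def _runs_above(fracs: list[float], theta: float) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, f in enumerate(fracs):
        if f >= theta:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(fracs) - 1))
    return runs


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def derive_abr_boundaries(profiles: list[ColumnProfile],
                          theta: float = 0.10,
                          gap_merge: int = 2,
                          regions_per_chain: int = 3,
                          provenance: dict | None = None) -> AbrDefinition:
    """Find the consensus stretches and freeze them as the ABR definition.

    Maximal runs of columns whose contact fraction is at least ``theta``
    (inclusive) are the candidate stretches; runs separated by at most
    ``gap_merge`` sub-threshold columns merge.  If more than
    ``regions_per_chain`` runs remain on a chain, the two closest runs
    merge iteratively; fewer is an error (lower the threshold or add
    training antibodies).
    """
    spans: dict[str, tuple[int, int]] = {}
    for role, names in (("light", LIGHT_REGIONS), ("heavy", HEAVY_REGIONS)):
        cols = sorted((p.column, p.contact_fraction)
                      for p in profiles if p.chain == role)
        if not cols:
            raise ConsensusError(f"no profiles for {role} chain")
        fracs = [f for _, f in cols]
        runs = _merge_runs(_runs_above(fracs, theta), gap_merge)
        if len(runs) < regions_per_chain:
            raise ConsensusError(
                f"{role}: only {len(runs)} consensus stretches found; "
                "lower the threshold or provide more antibodies")
        while len(runs) > regions_per_chain:
            gaps = [runs[i + 1][0] - runs[i][1] for i in range(len(runs) - 1)]
            i = int(np.argmin(gaps))      # ties: leftmost pair
            runs[i:i + 2] = [(runs[i][0], runs[i + 1][1])]
        spans.update(dict(zip(names, runs)))
    prov = {"date": date.today().isoformat()}
    prov.update(provenance or {})
    return AbrDefinition(spans, theta, gap_merge, prov)


def map_abrs_to_antibody(defn: AbrDefinition,
                         rows: dict[str, list[int | None]],
                         antibody_id: str,
                         n_columns: dict[str, int] | None = None,
                         ) -> RegionAnnotation:
    """Project frozen column spans onto one antibody's alignment rows."""
    expected = defn.provenance.get("n_columns")
    if expected:
        for role in ROLES:
            if len(rows[role]) != expected[role]:
                raise ConsensusError(
                    f"column count mismatch for {role}: "
                    f"{len(rows[role])} != {expected[role]}")
    spans: dict[str, tuple[int, int] | None] = {}
    empty = []
    for role, names in (("light", LIGHT_REGIONS), ("heavy", HEAVY_REGIONS)):
        row = rows[role]
        for name in names:
            c0, c1 = defn.spans[name]
            res = [row[c] for c in range(c0, min(c1 + 1, len(row)))
                   if row[c] is not None]
            if res:
                spans[name] = (min(res), max(res))
            else:
                spans[name] = None
                empty.append(name)
    meta = {"empty_regions": empty} if empty else {}
    return RegionAnnotation(antibody_id, "paratome", spans, meta)
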