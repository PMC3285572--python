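"""Synthetic antibody-like complexes with planted ground truth.

The generator emulates the shape of the training data — antibody-antigen
complexes whose binding residues cluster in six sequence stretches —
with fully known ground truth, so every pipeline stage is testable
without downloading structures.  Geometry is deliberately schematic: a
straight Cα trace with one dummy side-chain atom per residue, spaced so
that planted contacts sit well inside the contact cutoff (5.0 Å
atom-atom) and everything else sits well outside it (≥ 8 Å).  Sequences
default to the package's canonical-length VH/VL numbering templates, so
generated antibodies can also be numbered under Kabat/Chothia/IMGT.

Realistic immunoglobulin fold geometry is explicitly out of scope; the
contact logic, alignment transfer and consensus statistics are what the
fixtures exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .regions import REGION_ROLE, RegionAnnotation
from .schemes import load_templates
from .structure_io import ComplexStructure, parse_complex

__all__ = ["FixtureSpec", "FixtureComplex", "Family", "FamilyMember",
           "generate_complex", "generate_family"]

SPACING = 5.0        # Å between consecutive column positions
CONTACT_Y = 8.0      # antigen plane height; dummy side chain at y=3 -> 5 Å
CHAIN_Z = {"heavy": 0.0, "light": 30.0}
PAD_Y = 60.0         # padding antigen residues, far from everything

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _template_seq(chain: str) -> str:
    for t in load_templates():
        if t.chain == chain:
            return t.sequence
    raise RuntimeError("missing packaged template")


def _template_abrs(chain: str) -> dict[str, tuple[int, int]]:
    """Default planted ABR spans for the packaged templates.

    Consensus binding regions track the CDRs only roughly: most
    prominently, the light-chain second region extends several residues
    N-terminal of the Kabat CDR, while the heavy-chain second region
    stops short of Kabat's C-terminal boundary.  The defaults start
    from the template's Kabat CDR spans and plant those two deviations
    (L2 start - 4, H2 end - 2) so the ABR/CDR difference sets are
    non-trivial by construction.
    """
    from .schemes import extract_cdrs, number_sequence
    ns = number_sequence(_template_seq(chain), chain, "kabat")
    ann = extract_cdrs(ns)
    spans = {k: v for k, v in ann.spans.items()
             if v is not None and REGION_ROLE[k] == chain}
    if chain == "light":
        s, e = spans["L2"]
        spans["L2"] = (s - 4, e)
    else:
        s, e = spans["H2"]
        spans["H2"] = (s, e - 2)
    return spans


@dataclass
class FixtureSpec:
    """Recipe for one synthetic complex or family.

    Densities are the per-residue probability of a planted contact
    inside/outside the ABR spans; ``mutation_rate`` is the per-position
    substitution probability for family members; ``indel`` plants an
    insertion ``(region, length)`` in one member (``indel_member``).
    """

    seed: int = 0
    heavy_seq: str | None = None
    light_seq: str | None = None
    heavy_abrs: dict[str, tuple[int, int]] | None = None
    light_abrs: dict[str, tuple[int, int]] | None = None
    inside_density: float = 0.5
    outside_density: float = 0.02
    mutation_rate: float = 0.05
    indel: tuple[str, int] | None = None
    indel_member: int = 1

    def resolved(self) -> "FixtureSpec":
        out = replace(self)
        out.heavy_seq = self.heavy_seq or _template_seq("heavy")
        out.light_seq = self.light_seq or _template_seq("light")
        out.heavy_abrs = self.heavy_abrs or _template_abrs("heavy")
        out.light_abrs = self.light_abrs or _template_abrs("light")
        for d in (out.inside_density, out.outside_density,
                  out.mutation_rate):
            if not 0 <= d <= 1:
                raise ValueError("densities must lie in [0, 1]")
        for chain, seq, abrs in (("heavy", out.heavy_seq, out.heavy_abrs),
                                 ("light", out.light_seq, out.light_abrs)):
            prev = -1
            for name in sorted(abrs, key=lambda n: abrs[n][0]):
                s, e = abrs[name]
                if not (0 <= s <= e < len(seq)):
                    raise ValueError(f"{name} span outside {chain} chain")
                if s <= prev:
                    raise ValueError(f"overlapping planted spans at {name}")
                prev = e
        return out


@dataclass
class FixtureComplex:
    ab_id: str
    pdb_text: str
    structure: ComplexStructure
    contacts: set[tuple[str, int, int]]       # (role, ab index, ag index)
    annotation: RegionAnnotation              # planted ABR spans

    @property
    def contact_residues(self) -> set[tuple[str, int]]:
        return {(role, i) for role, i, _ in self.contacts}


@dataclass
class FamilyMember(FixtureComplex):
    rows: dict[str, list[int | None]] = field(default_factory=dict)


@dataclass
class Family:
    members: list[FamilyMember]
    column_spans: dict[str, tuple[int, int]]  # planted ABRs in column space
    n_columns: dict[str, int]

    @property
    def ids(self) -> list[str]:
        return [m.ab_id for m in self.members]


# ---------------------------------------------------------------------------


def _in_spans(col: int, spans) -> bool:
    return any(s <= col <= e for s, e in spans.values())


def _build_pdb(ab_id: str,
               chains: dict[str, tuple[str, list[int]]],
               contacts: list[tuple[str, int, int]],
               ag_len: int, rng: np.random.Generator) -> str:
    """Emit PDB text: chains H/L (Cα + CB) and antigen chain G."""
    st = gemmi.Structure()
    st.name = ab_id
    model = gemmi.Model("1")
    contact_keys = {(role, i) for role, i, _ in contacts}

    def add_atom(res, name, x, y, z, element="C"):
        a = gemmi.Atom()
        a.name = name
        a.pos = gemmi.Position(x, y, z)
        a.occ = 1.0
        a.b_iso = 0.0
        a.element = gemmi.Element(element)
        res.add_atom(a)

    # small z zig-zag keeps the trace non-collinear for superposition
    def zed(role, col):
        return CHAIN_Z[role] + 0.6 * (col % 2)

    for role, cid in (("heavy", "H"), ("light", "L")):
        seq, cols = chains[role]
        ch = gemmi.Chain(cid)
        for i, (aa, col) in enumerate(zip(seq, cols)):
            res = gemmi.Residue()
            res.name = AA3[aa]
            res.seqid = gemmi.SeqId(i + 1, " ")
            x = SPACING * col
            add_atom(res, "CA", x, 0.0, zed(role, col))
            cb_y = 3.0 if (role, i) in contact_keys else -1.5
            add_atom(res, "CB", x, cb_y, zed(role, col))
            ch.add_residue(res)
        model.add_chain(ch)

    ag = gemmi.Chain("G")
    ag_letters = rng.choice(list(ALPHABET), size=ag_len)
    num = 0
    for role, i, _ in contacts:
        seq, cols = chains[role]
        x = SPACING * cols[i]
        res = gemmi.Residue()
        res.name = AA3[ag_letters[num]]
        res.seqid = gemmi.SeqId(num + 1, " ")
        add_atom(res, "CA", x, CONTACT_Y, zed(role, cols[i]))
        ag.add_residue(res)
        num += 1
    pad = 0
    while num < ag_len:
        res = gemmi.Residue()
        res.name = AA3[ag_letters[num]]
        res.seqid = gemmi.SeqId(num + 1, " ")
        add_atom(res, "CA", SPACING * pad, PAD_Y, 0.0)
        ag.add_residue(res)
        num += 1
        pad += 1
    model.add_chain(ag)
    st.add_model(model)
    return st.make_pdb_string()


def _sample_contacts(rng, seq_cols, spans_by_role):
    contacts: list[tuple[str, int, int]] = []
    for role in ("heavy", "light"):
        seq, cols = seq_cols[role]
        spans = spans_by_role[role]
        for i, col in enumerate(cols):
            density = (spans_by_role["__inside"] if _in_spans(col, spans)
                       else spans_by_role["__outside"])
            if rng.random() < density:
                contacts.append((role, i, -1))
    return [(role, i, k) for k, (role, i, _) in enumerate(contacts)]


def _annotation(ab_id, spans_h, spans_l) -> RegionAnnotation:
    spans = {}
    spans.update(spans_l)
    spans.update(spans_h)
    return RegionAnnotation(ab_id, "paratome", dict(spans))


def generate_complex(spec: FixtureSpec, ab_id: str = "syn000") -> FixtureComplex:
    """One synthetic complex with planted contacts and known ABR spans."""
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    seq_cols = {
        "heavy": (spec.heavy_seq, list(range(len(spec.heavy_seq)))),
        "light": (spec.light_seq, list(range(len(spec.light_seq)))),
    }
    spans_by_role = {"heavy": spec.heavy_abrs, "light": spec.light_abrs,
                     "__inside": spec.inside_density,
                     "__outside": spec.outside_density}
    contacts = _sample_contacts(rng, seq_cols, spans_by_role)
    ag_len = max(5, len(contacts) + 5)
    pdb_text = _build_pdb(ab_id, seq_cols, contacts, ag_len, rng)
    structure = parse_complex(
        pdb_text, {"H": "heavy", "L": "light", "G": "antigen"}, ab_id)
    ann = _annotation(ab_id, spec.heavy_abrs, spec.light_abrs)
    return FixtureComplex(ab_id, pdb_text, structure, set(contacts), ann)


def generate_family(spec: FixtureSpec, n: int) -> Family:
    """A family of related synthetic complexes sharing planted ABR columns.

    Members differ by point mutations at ``spec.mutation_rate`` and an
    optional planted insertion inside one ABR of one member; contacts
    are sampled per member at the stated densities.  The ground-truth
    alignment (column of every residue) is returned alongside.
    """
    if n < 2:
        raise ValueError("family size must be >= 2")
    spec = spec.resolved()

    base = {"heavy": spec.heavy_seq, "light": spec.light_seq}
    abrs = {"heavy": dict(spec.heavy_abrs), "light": dict(spec.light_abrs)}

    # column system: base residue indices, plus insertion columns for the
    # planted indel (placed mid-span of the target region)
    ins_role = ins_pos = ins_len = None
    if spec.indel is not None:
        region, ins_len = spec.indel
        ins_role = REGION_ROLE[region]
        s, e = abrs[ins_role][region]
        ins_pos = (s + e) // 2          # insert after this base index
    col_of_base: dict[str, list[int]] = {}
    n_columns: dict[str, int] = {}
    for role in ("heavy", "light"):
        L = len(base[role])
        cols = list(range(L))
        if role == ins_role:
            cols = [c if c <= ins_pos else c + ins_len for c in cols]
            n_columns[role] = L + ins_len
        else:
            n_columns[role] = L
        col_of_base[role] = cols

    column_spans: dict[str, tuple[int, int]] = {}
    for role in ("heavy", "light"):
        for name, (s, e) in abrs[role].items():
            column_spans[name] = (col_of_base[role][s], col_of_base[role][e])

    # Outside-span contacts are *sporadic*: they do not recur at the same
    # aligned column across members (that non-recurrence is exactly what
    # separates them from the consensus regions), so they are drawn
    # without replacement from a family-wide pool of outside columns.
    pool_rng = np.random.default_rng([spec.seed, 10_000])
    outside_pool: dict[str, list[int]] = {}
    for role in ("heavy", "light"):
        inside = {c for name, (cs, ce) in column_spans.items()
                  if REGION_ROLE[name] == role for c in range(cs, ce + 1)}
        cols = [c for c in col_of_base[role] if c not in inside]
        pool_rng.shuffle(cols)
        outside_pool[role] = cols

    def draw_outside(role: str, k: int) -> list[int]:
        pool = outside_pool[role]
        take, outside_pool[role] = pool[:k], pool[k:]
        return take

    members: list[FamilyMember] = []
    for m in range(n):
        rng = np.random.default_rng([spec.seed, m])
        seq_cols: dict[str, tuple[str, list[int]]] = {}
        spans_m: dict[str, dict[str, tuple[int, int]]] = {}
        rows: dict[str, list[int | None]] = {}
        for role in ("heavy", "light"):
            seq = list(base[role])
            cols = list(col_of_base[role])
            if role == ins_role and m == spec.indel_member:
                extra = [str(rng.choice(list(ALPHABET)))
                         for _ in range(ins_len)]
                seq = seq[:ins_pos + 1] + extra + seq[ins_pos + 1:]
                cols = (cols[:ins_pos + 1]
                        + list(range(ins_pos + 1, ins_pos + 1 + ins_len))
                        + cols[ins_pos + 1:])
            for i in range(len(seq)):
                if rng.random() < spec.mutation_rate:
                    choices = [a for a in ALPHABET if a != seq[i]]
                    seq[i] = str(rng.choice(choices))
            seq_cols[role] = ("".join(seq), cols)
            row: list[int | None] = [None] * n_columns[role]
            for i, c in enumerate(cols):
                row[c] = i
            rows[role] = row
            # planted residue spans in this member's own coordinates
            spans_m[role] = {}
            for name, (cs, ce) in column_spans.items():
                if REGION_ROLE[name] != role:
                    continue
                idx = [i for i, c in enumerate(cols) if cs <= c <= ce]
                spans_m[role][name] = (min(idx), max(idx))
        # inside-span contacts recur independently per member; outside
        # contacts come from the family-wide sporadic pool
        picked: list[tuple[str, int]] = []
        for role in ("heavy", "light"):
            seq, cols = seq_cols[role]
            spans = spans_m[role]
            inside_idx = [i for i, c in enumerate(cols)
                          if _in_spans(c, spans)]
            outside_cols = {c: i for i, c in enumerate(cols)
                            if not _in_spans(c, spans)}
            for i in inside_idx:
                if rng.random() < spec.inside_density:
                    picked.append((role, i))
            k = rng.binomial(len(outside_cols), spec.outside_density)
            for c in draw_outside(role, int(k)):
                if c in outside_cols:
                    picked.append((role, outside_cols[c]))
        contacts = [(role, i, k) for k, (role, i) in enumerate(picked)]
        ab_id = f"syn{m:03d}"
        ag_len = max(5, len(contacts) + 5)
        pdb_text = _build_pdb(ab_id, seq_cols, contacts, ag_len, rng)
        structure = parse_complex(
            pdb_text, {"H": "heavy", "L": "light", "G": "antigen"}, ab_id)
        ann = _annotation(ab_id, spans_m["heavy"], spans_m["light"])
        members.append(FamilyMember(ab_id, pdb_text, structure,
                                    set(contacts), ann, rows))
    return Family(members, column_spans, n_columns)


def write_fixture_set(spec: FixtureSpec, n: int, out_dir) -> None:
    """Write a family as PDB files plus a ground-truth JSON (CLI helper)."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fam = generate_family(spec, n)
    truth = {"column_spans": {k: list(v) for k, v in fam.column_spans.items()},
             "members": {}}
    for mem in fam.members:
        (out / f"{mem.ab_id}.pdb").write_text(mem.pdb_text)
        truth["members"][mem.ab_id] = {
            "contacts": sorted([list(c) for c in mem.contacts]),
            "annotation": mem.annotation.to_dict(),
        }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
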