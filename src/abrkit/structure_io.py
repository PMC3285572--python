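"""Parsing of antibody-antigen complexes and geometric primitives.

A :class:`ComplexStructure` holds exactly three peptide chains — one
antibody heavy chain, one antibody light chain and one protein antigen —
with author residue numbering preserved.  Contacts between antibody and
antigen are defined at the residue level: two residues interact when any
atom-atom distance is at or below a cutoff (6 Angstrom by default).

PDB reading is delegated to :mod:`gemmi`; neighbour search to a scipy
k-d tree; rigid superposition to the Kabsch solution as provided by
:func:`scipy.spatial.transform.Rotation.align_vectors`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "Contact",
    "ContactSet",
    "ComplexParseError",
    "parse_complex",
    "extract_contacts",
    "is_interacting",
    "superpose",
    "contacts_to_tsv",
    "contacts_from_tsv",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Modified residues mapped to their parent amino acid; anything else
#: that gemmi recognises as an amino acid becomes X.
MODIFIED_PARENT = {
    "MSE": "M", "FME": "M", "HYP": "P", "PCA": "Q", "PTR": "Y",
    "SEP": "S", "TPO": "T", "CSO": "C", "CME": "C", "CSX": "C",
    "MLY": "K", "M3L": "K", "KCX": "K", "LLP": "K", "CGU": "E",
}

ROLE_NAMES = ("heavy", "light", "antigen")


class ComplexParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a valid complex."""


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One amino acid with its atoms, keyed by author numbering."""

    chain_id: str
    number: int
    icode: str
    aa: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"invalid amino-acid letter {self.aa!r}")
        if not self.atoms:
            raise ValueError("residue without atoms")
        for a in self.atoms:
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError("non-finite atom coordinate")

    @property
    def resid(self) -> str:
        """Author residue identifier, e.g. ``'100A'``."""
        return f"{self.number}{self.icode}".strip()

    @property
    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.xyz
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, one row per residue (NaN row when absent)."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca
            if ca is not None:
                out[i] = ca
        return out


@dataclass
class ComplexStructure:
    """An antibody-antigen complex: heavy + light + one protein antigen."""

    pdb_id: str
    heavy: Chain
    light: Chain
    antigen: Chain

    def __post_init__(self):
        if self.heavy.chain_id == self.light.chain_id:
            raise ComplexParseError("heavy and light share a chain id")
        if len(self.antigen) < 5:
            raise ComplexParseError(
                f"antigen too short: {len(self.antigen)} residues (< 5)")

    def chain(self, role: str) -> Chain:
        return getattr(self, role)

    @property
    def antibody_chains(self) -> dict[str, Chain]:
        return {"heavy": self.heavy, "light": self.light}


@dataclass(frozen=True)
class Contact:
    """One antibody-antigen residue pair within the distance cutoff."""

    ab_role: str          # 'heavy' | 'light'
    ab_index: int         # residue index within that chain
    ag_index: int
    ab_residue: Residue
    ag_residue: Residue
    min_atom_distance: float


@dataclass
class ContactSet:
    pdb_id: str
    cutoff: float
    contacts: list[Contact] = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.cutoff <= 10):
            raise ValueError("cutoff must be in (0, 10] Angstrom")
        pairs = [(c.ab_role, c.ab_index, c.ag_index) for c in self.contacts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def ab_residue_keys(self) -> set[tuple[str, int]]:
        """Antibody residues involved in any contact, as (role, index)."""
        return {(c.ab_role, c.ab_index) for c in self.contacts}

    def pairs(self) -> set[tuple[str, int, int]]:
        return {(c.ab_role, c.ab_index, c.ag_index) for c in self.contacts}


# ---------------------------------------------------------------------------
# parsing


def _collapse_altlocs(atoms: list[Atom]) -> tuple[Atom, ...]:
    # highest occupancy wins; ties resolved by file order
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or a.occupancy > prev.occupancy:
            by_name[a.name] = a
    return tuple(by_name.values())


def _one_letter(resname: str) -> str | None:
    """Parent one-letter code, X for unusual amino acids, None otherwise."""
    if resname in MODIFIED_PARENT:
        return MODIFIED_PARENT[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    one = info.one_letter_code.upper()
    return one if one in STANDARD_AA else "X"


def _convert_chain(ch: gemmi.Chain) -> Chain:
    residues: list[Residue] = []
    for res in ch:
        aa = _one_letter(res.name)
        if aa is None:       # waters, ligands, nucleotides: excluded
            continue
        atoms = [
            Atom(a.name, (a.pos.x, a.pos.y, a.pos.z), a.occ, a.altloc)
            for a in res
        ]
        if not atoms:
            continue
        icode = res.seqid.icode.strip()
        residues.append(
            Residue(ch.name, res.seqid.num, icode, aa,
                    _collapse_altlocs(atoms))
        )
    return Chain(ch.name, residues)


def _assembly_chain_sets(st: gemmi.Structure) -> list[set[str]]:
    out = []
    for asm in st.assemblies:
        names: set[str] = set()
        for gen in asm.generators:
            names.update(gen.chains)
            names.update(gen.subchains)
        if names:
            out.append(names)
    return out


def parse_complex(pdb_text: str, role_map: dict[str, str] | None = None,
                  pdb_id: str = "") -> ComplexStructure:
    """Parse PDB text into a three-chain antibody-antigen complex.

    Parameters
    ----------
    pdb_text:
        PDB-format text with ATOM/HETATM records.
    role_map:
        Mapping from author chain id to role (``heavy``/``light``/
        ``antigen``).  When omitted, the chain grouping of the first
        biological assembly (REMARK 350) that contains at least three
        peptide chains is used and roles must be resolved by the caller
        beforehand — without a role map the parse fails with a
        structured error listing candidate chains, since chain roles
        cannot be inferred from geometry alone.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if pdb_id:
        st.name = pdb_id
    name = (pdb_id or st.name or "complex").lower()
    if len(st) == 0:
        raise ComplexParseError("no models in PDB text")
    model = st[0]
    chains: dict[str, Chain] = {}
    for ch in model:   # gemmi splits polymer/non-polymer into subchains
        conv = _convert_chain(ch)
        if ch.name in chains:
            chains[ch.name].residues.extend(conv.residues)
        else:
            chains[ch.name] = conv
    chains = {cid: c for cid, c in chains.items() if len(c) > 0}

    if role_map is None:
        candidates = set(chains)
        for grp in _assembly_chain_sets(st):
            grp &= set(chains)
            if len(grp) >= 3:
                candidates = grp
                break
        raise ComplexParseError(
            "role_map required; candidate peptide chains: "
            + ",".join(sorted(candidates)))

    by_role: dict[str, Chain] = {}
    for cid, role in role_map.items():
        if role not in ROLE_NAMES:
            raise ComplexParseError(f"unknown role {role!r} for chain {cid}")
        if role in by_role:
            raise ComplexParseError(f"duplicate role {role!r}")
        if cid not in chains:
            raise ComplexParseError(f"missing role: {role} (chain {cid})")
        by_role[role] = chains[cid]
    for role in ROLE_NAMES:
        if role not in by_role:
            raise ComplexParseError(f"missing role: {role}")

    return ComplexStructure(name, by_role["heavy"], by_role["light"],
                            by_role["antigen"])


# ---------------------------------------------------------------------------
# contacts


def extract_contacts(complex: ComplexStructure,
                     cutoff: float = 6.0) -> ContactSet:
    """All antibody-antigen residue pairs with any atom pair <= ``cutoff``.

    The minimum atom-atom distance of each contacting pair is recorded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ag = complex.antigen
    ag_coords, ag_res_idx = [], []
    for j, res in enumerate(ag):
        for a in res.atoms:
            ag_coords.append(a.xyz)
            ag_res_idx.append(j)
    contacts: list[Contact] = []
    if ag_coords:
        ag_xyz = np.asarray(ag_coords)
        tree = cKDTree(ag_xyz)
        ag_res_idx = np.asarray(ag_res_idx)
        for role, chain in complex.antibody_chains.items():
            for i, res in enumerate(chain):
                coords = res.coords()
                hits_per_atom = tree.query_ball_point(coords, cutoff)
                best: dict[int, float] = {}
                for atom_xyz, hits in zip(coords, hits_per_atom):
                    if not hits:
                        continue
                    hit_d = np.linalg.norm(ag_xyz[hits] - atom_xyz, axis=1)
                    for j, d in zip(ag_res_idx[hits], hit_d):
                        j = int(j)
                        if d < best.get(j, np.inf):
                            best[j] = float(d)
                for j, d in sorted(best.items()):
                    contacts.append(Contact(role, i, j, res,
                                            ag.residues[j], d))
    return ContactSet(complex.pdb_id, cutoff, contacts)


def is_interacting(complex: ComplexStructure, cutoff: float = 6.0) -> bool:
    """True when any antibody atom lies within ``cutoff`` of any antigen atom."""
    return len(extract_contacts(complex, cutoff)) > 0


# ---------------------------------------------------------------------------
# superposition


def superpose(coords_a: np.ndarray,
              coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``coords_b`` onto ``coords_a`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    3x3 matrix (det +1) such that ``rotation @ b + translation``
    minimises the RMSD to ``coords_a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be n x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if min(np.linalg.matrix_rank(a0, tol=1e-8),
           np.linalg.matrix_rank(b0, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rot, _ = Rotation.align_vectors(a0, b0)
    R = rot.as_matrix()
    t = ca - R @ cb
    fitted = b @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# serialisation

_TSV_HEADER = ("pdb_id", "ab_chain", "ab_resnum", "ab_aa",
               "ag_resnum", "ag_aa", "min_dist")


def contacts_to_tsv(cs: ContactSet) -> str:
    lines = ["\t".join(_TSV_HEADER)]
    for c in cs:
        lines.append("\t".join([
            cs.pdb_id, c.ab_role, c.ab_residue.resid, c.ab_residue.aa,
            c.ag_residue.resid, c.ag_residue.aa,
            f"{c.min_atom_distance:.3f}",
        ]))
    return "\n".join(lines) + "\n"


def contacts_from_tsv(text: str, complex: ComplexStructure,
                      cutoff: float = 6.0) -> ContactSet:
    """Rehydrate a ContactSet against its parsed complex."""
    def index_of(chain: Chain, resid: str) -> int:
        for i, r in enumerate(chain):
            if r.resid == resid:
                return i
        raise ValueError(f"residue {resid} not in chain {chain.chain_id}")

    contacts = []
    reader = io.StringIO(text)
    header = reader.readline().rstrip("\n").split("\t")
    if tuple(header) != _TSV_HEADER:
        raise ValueError("unexpected contact TSV header")
    for line in reader:
        if not line.strip():
            continue
        (_, role, ab_resid, _, ag_resid, _, dist) = line.rstrip("\n").split("\t")
        chain = complex.chain(role)
        i = index_of(chain, ab_resid)
        j = index_of(complex.antigen, ag_resid)
        contacts.append(Contact(role, i, j, chain.residues[i],
                                complex.antigen.residues[j], float(dist)))
    return ContactSet(complex.pdb_id, cutoff, contacts)
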