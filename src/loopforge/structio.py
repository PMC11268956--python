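"""Protein structures as chains of residues of heavy atoms, plus PDB I/O.

The in-memory model is deliberately small: a :class:`ProteinStructure` is an
ordered map of chains, each a list of :class:`Residue` objects indexed
contiguously from 0.  Original PDB residue numbering (with insertion codes)
is retained only for round-tripping; all internal arithmetic — loop anchors,
masks, pocket membership — uses the 0-based indices.  Hydrogens, waters and
heteroatoms are dropped on parsing: "full-atom" here means all heavy atoms.

PDB reading and writing go through biotite; covalent bonds come from its
chemical-component bond templates with a distance fallback for atoms the
templates do not cover.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: fallback bond-length cutoff (Å) for atoms outside the residue templates;
#: long enough for any covalent heavy-atom bond, far below CA–CA (3.8 Å)
FALLBACK_BOND_CUTOFF = 1.9


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_backbone: bool = False
    residue_ref: int = -1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not (self.element.isalpha() and 1 <= len(self.element) <= 2):
            raise ValueError(f"atom {self.name}: invalid element symbol {self.element!r}")
        self.is_backbone = self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    auth_seq_id: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def centroid(self) -> np.ndarray:
        """Geometric centre of the heavy atoms (unit masses)."""
        return self.coords().mean(axis=0)

    def ca(self) -> np.ndarray:
        a = self.atom("CA")
        if a is None:
            raise ValueError(f"residue {self.chain_id}:{self.index} has no CA atom")
        return a.coords


@dataclass
class ProteinStructure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    title: str = ""

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()]).reshape(-1, 3)

    def set_atom_coords(self, coords: np.ndarray, mask: np.ndarray | None = None):
        """Write coordinates back, optionally only where ``mask`` is true."""
        atoms = list(self.atoms())
        if mask is None:
            targets = atoms
        else:
            targets = [a for a, m in zip(atoms, mask) if m]
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if len(targets) != len(coords):
            raise ValueError(f"{len(coords)} coords for {len(targets)} atoms")
        for a, c in zip(targets, coords):
            a.coords = c.copy()

    def copy(self) -> "ProteinStructure":
        out = ProteinStructure(title=self.title)
        for cid, chain in self.chains.items():
            out.chains[cid] = [
                Residue(
                    r.index,
                    r.name,
                    r.chain_id,
                    [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms],
                    r.auth_seq_id,
                )
                for r in chain
            ]
        return out

    def validate(self):
        for cid, chain in self.chains.items():
            for i, res in enumerate(chain):
                if res.index != i:
                    raise ValueError(f"chain {cid}: residue indices not contiguous at {i}")
                names = [a.name for a in res.atoms]
                if len(names) != len(set(names)):
                    raise ValueError(f"duplicate atom name in {cid}:{i}")


@dataclass(frozen=True)
class LoopSpec:
    """Loop residues ``start..end`` (0-based, inclusive) on one chain.

    The anchors — the nonloop residues immediately before and after the loop —
    must exist: the initialisation geometry interpolates between them.
    """

    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("loop end must be >= start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def anchors(self) -> tuple[int, int]:
        return (self.start - 1, self.end + 1)

    def validate(self, structure: ProteinStructure):
        if self.chain_id not in structure.chains:
            raise KeyError(f"chain {self.chain_id!r} not in structure")
        chain = structure.chains[self.chain_id]
        a0, a1 = self.anchors
        if a0 < 0 or a1 >= len(chain):
            raise ValueError(
                "loop must have a nonloop anchor residue on each side "
                f"(chain has {len(chain)} residues, loop {self.start}..{self.end})"
            )

    def loop_residues(self, structure: ProteinStructure) -> list[Residue]:
        return structure.chains[self.chain_id][self.start : self.end + 1]

    def anchor_residues(self, structure: ProteinStructure) -> tuple[Residue, Residue]:
        chain = structure.chains[self.chain_id]
        a0, a1 = self.anchors
        return chain[a0], chain[a1]


# -- parsing / writing -------------------------------------------------------


def parse_pdb(text: str, title: str = "") -> ProteinStructure:
    """Parse ATOM records into a :class:`ProteinStructure`.

    HETATM records, waters and hydrogens are skipped.  Alternate locations are
    resolved to the highest-occupancy conformer (first on ties).  Insertion
    codes are preserved in ``auth_seq_id``.
    """
    try:
        pdb_file = PDBFile.read(io.StringIO(text))
        array = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # locate the offending line for the caller
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field on line {lineno}: {line!r}"
                    ) from exc
        raise PDBParseError(str(exc)) from exc

    keep = (~array.hetero) & (array.res_name != "HOH") & (array.element != "H")
    array = array[keep]

    structure = ProteinStructure(title=title)
    for chain_id in np.unique(array.chain_id):
        sub = array[array.chain_id == chain_id]
        chain: list[Residue] = []
        for res_array in bst.residue_iter(sub):
            ins = res_array.ins_code[0]
            res = Residue(
                index=len(chain),
                name=str(res_array.res_name[0]),
                chain_id=str(chain_id),
                auth_seq_id=f"{int(res_array.res_id[0])}{ins}".strip(),
            )
            for i in range(res_array.array_length()):
                res.atoms.append(
                    Atom(
                        name=str(res_array.atom_name[i]),
                        element=str(res_array.element[i]).capitalize(),
                        coords=res_array.coord[i],
                    )
                )
            chain.append(res)
        structure.chains[str(chain_id)] = chain
    _assign_residue_refs(structure)
    return structure


def _assign_residue_refs(structure: ProteinStructure):
    for ridx, res in enumerate(structure.residues()):
        for atom in res.atoms:
            atom.residue_ref = ridx


def write_pdb(structure: ProteinStructure) -> str:
    """Serialise to fixed-column PDB ATOM/TER records (3-decimal coords)."""
    coords = [a.coords for a in structure.atoms()]
    if coords and np.abs(np.array(coords)).max() >= 10000:
        raise ValueError("coordinate magnitude >= 10000 Å cannot be formatted in PDB columns")

    n_total = structure.n_atoms
    array = bst.AtomArray(n_total)
    i = 0
    for cid, chain in structure.chains.items():
        for res in chain:
            auth = res.auth_seq_id or str(res.index + 1)
            if auth and auth[-1].isalpha():
                res_id, ins = int(auth[:-1]), auth[-1]
            else:
                res_id, ins = int(auth), ""
            for atom in res.atoms:
                array.coord[i] = atom.coords
                array.chain_id[i] = cid
                array.res_id[i] = res_id
                array.ins_code[i] = ins
                array.res_name[i] = res.name
                array.atom_name[i] = atom.name
                array.element[i] = atom.element.upper()
                array.hetero[i] = False
                i += 1
    pdb_file = PDBFile()
    if n_total:
        pdb_file.set_structure(array)
    lines = pdb_file.lines if n_total else []
    header = f"REMARK   1 {structure.title}".rstrip()
    return "\n".join([header] + list(lines)) + "\n"


# -- masks and bonds ---------------------------------------------------------


def loop_mask(structure: ProteinStructure, spec: LoopSpec) -> np.ndarray:
    """Boolean array over all atoms, true exactly for loop-residue atoms."""
    spec.validate(structure)
    mask = []
    for res in structure.residues():
        in_loop = res.chain_id == spec.chain_id and spec.start <= res.index <= spec.end
        mask.extend([in_loop] * len(res.atoms))
    return np.array(mask, dtype=bool)


def derive_covalent_bonds(structure: ProteinStructure) -> list[tuple[int, int]]:
    """Undirected covalent bonds as pairs of global atom indices.

    Bonds come from residue templates (via biotite's component dictionary),
    plus the inter-residue peptide bond C(i)–N(i+1).  Atoms the templates do
    not know fall back to a distance rule: bonded if closer than
    :data:`FALLBACK_BOND_CUTOFF`.
    """
    n = structure.n_atoms
    if n == 0:
        return []
    array = bst.AtomArray(n)
    i = 0
    for cid, chain in structure.chains.items():
        for res in chain:
            for atom in res.atoms:
                array.coord[i] = atom.coords
                array.chain_id[i] = cid
                array.res_id[i] = res.index + 1
                array.res_name[i] = res.name
                array.atom_name[i] = atom.name
                array.element[i] = atom.element.upper()
                i += 1
    bond_list = bst.connect_via_residue_names(array, inter_residue=True)
    pairs = {(min(a, b), max(a, b)) for a, b, _ in bond_list.as_array()}

    # distance fallback for atoms without any template bond
    bonded = np.zeros(n, dtype=bool)
    for a, b in pairs:
        bonded[a] = bonded[b] = True
    orphan = np.flatnonzero(~bonded)
    if orphan.size:
        coords = array.coord
        for a in orphan:
            d = np.linalg.norm(coords - coords[a], axis=1)
            for b in np.flatnonzero((d < FALLBACK_BOND_CUTOFF) & (d > 0)):
                pairs.add((min(a, int(b)), max(a, int(b))))
    return sorted(pairs)
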