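"""Synthetic full-backbone structures with known ground-truth loops.

Chains are built atom-by-atom in internal coordinates (the natural-extension
reference frame): each atom is placed from the previous three by a bond
length, bond angle and torsion.  Idealised bond geometry is used throughout —
these fixtures only need to be geometrically plausible, not crystallographic.
Helix segments use (phi, psi) = (-57, -47), strand segments (-139, 135), and
loop segments draw per-residue torsions from broad Ramachandran basins with a
caller-supplied seed, resampled until the chain is free of steric clashes.

The standard task generator produces a helix-loop-helix chain whose central
segment is the loop to be rebuilt, together with its ground-truth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, LoopSpec, ProteinStructure, Residue, loop_mask

# idealised internal-coordinate constants (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4
DIHEDRAL_C_N_CA_CB = -122.6  # L-amino-acid chirality

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

#: Ramachandran basins sampled for loop residues: (phi_lo, phi_hi, psi_lo, psi_hi)
LOOP_BASINS = (
    (-140.0, -55.0, -60.0, -10.0),  # alpha region
    (-170.0, -90.0, 90.0, 170.0),  # beta region
)

CLASH_CUTOFF = 1.5  # Å, between atoms of residues >= 2 apart in sequence
MAX_RESAMPLES = 100

# minimal side-chain recipes: atom -> (ref atoms a,b,c, bond, angle, torsion)
_LEU_SIDECHAIN = [
    ("CG", ("N", "CA", "CB"), 1.530, 116.3, -60.0),
    ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
    ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 60.0),
]
SIDE_CHAINS: dict[str, list] = {"ALA": [], "GLY": [], "LEU": _LEU_SIDECHAIN}


@dataclass
class ChainRecipe:
    """Segments of (kind, length, optional explicit per-residue torsions)."""

    segments: list[tuple] = field(default_factory=list)
    residue_name: str = "ALA"
    seed: int = 0

    def __post_init__(self):
        for seg in self.segments:
            kind, length = seg[0], seg[1]
            if kind not in ("helix", "strand", "loop"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValueError("segment length must be >= 1")
        if self.residue_name not in SIDE_CHAINS:
            raise ValueError(
                f"unsupported residue {self.residue_name!r}; choose from {sorted(SIDE_CHAINS)}"
            )


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a fourth atom given three reference atoms and internal coords."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _segment_torsions(recipe: ChainRecipe, rng: np.random.Generator) -> list[tuple]:
    """Per-residue (phi, psi, omega) for the whole chain."""
    torsions = []
    for seg in recipe.segments:
        kind, length = seg[0], seg[1]
        explicit = seg[2] if len(seg) > 2 and seg[2] is not None else None
        for i in range(length):
            if explicit is not None:
                torsions.append(tuple(explicit[i]))
            elif kind == "helix":
                torsions.append((*HELIX_PHI_PSI, 180.0))
            elif kind == "strand":
                torsions.append((*STRAND_PHI_PSI, 180.0))
            else:
                lo_hi = LOOP_BASINS[rng.integers(len(LOOP_BASINS))]
                phi = rng.uniform(lo_hi[0], lo_hi[1])
                psi = rng.uniform(lo_hi[2], lo_hi[3])
                torsions.append((phi, psi, 180.0))
    return torsions


def _build_backbone(torsions: list[tuple], residue_name: str) -> list[dict]:
    """Place N/CA/C/O (+ side chain) for each residue; returns atom dicts."""
    n_res = len(torsions)
    residues = []
    # bootstrap the first residue in the xy-plane
    N = np.zeros(3)
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi, omega = torsions[i]
        if i > 0:
            prev = residues[i - 1]
            phi_prev, psi_prev, _ = torsions[i - 1]
            N = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
            CA = place_atom(prev["CA"], prev["C"], N, BOND_N_CA, ANGLE_C_N_CA, omega)
            C = place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        res = {"N": N, "CA": CA, "C": C}
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        if residue_name != "GLY":
            res["CB"] = place_atom(
                res["C"], res["N"], res["CA"], BOND_CA_CB, ANGLE_N_CA_CB, DIHEDRAL_C_N_CA_CB
            )
            for name, refs, bond, angle, tors in SIDE_CHAINS[residue_name]:
                res[name] = place_atom(res[refs[0]], res[refs[1]], res[refs[2]], bond, angle, tors)
        residues.append(res)
    return residues


def _has_clash(residues: list[dict]) -> bool:
    coords, res_ids = [], []
    for i, res in enumerate(residues):
        for xyz in res.values():
            coords.append(xyz)
            res_ids.append(i)
    coords = np.array(coords)
    res_ids = np.array(res_ids)
    from scipy.spatial.distance import cdist

    d = cdist(coords, coords)
    sep = np.abs(res_ids[:, None] - res_ids[None, :])
    return bool(np.any((d < CLASH_CUTOFF) & (sep >= 2)))


_ELEMENTS = {"N": "N", "O": "O"}  # everything else placed here is carbon


def build_chain(recipe: ChainRecipe, chain_id: str = "A") -> ProteinStructure:
    """Build a poly-residue chain from a recipe; deterministic given its seed."""
    rng = np.random.default_rng(recipe.seed)
    has_loop = any(seg[0] == "loop" for seg in recipe.segments)
    for attempt in range(MAX_RESAMPLES):
        torsions = _segment_torsions(recipe, rng)
        placed = _build_backbone(torsions, recipe.residue_name)
        if not _has_clash(placed):
            break
        if not has_loop:
            raise ValueError("fixed-torsion recipe produced a clashing chain")
    else:
        raise RuntimeError(f"no clash-free loop conformation in {MAX_RESAMPLES} resamples")

    structure = ProteinStructure(title="loopforge fixture")
    chain: list[Residue] = []
    for i, placed_res in enumerate(placed):
        res = Residue(index=i, name=recipe.residue_name, chain_id=chain_id, auth_seq_id=str(i + 1))
        for name, xyz in placed_res.items():
            res.atoms.append(Atom(name=name, element=_ELEMENTS.get(name[0], "C"), coords=xyz))
        chain.append(res)
    structure.chains[chain_id] = chain
    for ridx, res in enumerate(structure.residues()):
        for atom in res.atoms:
            atom.residue_ref = ridx
    structure.validate()
    return structure


def make_loop_task(
    n_flank1: int, loop_len: int, n_flank2: int, seed: int, residue_name: str = "ALA"
) -> tuple[ProteinStructure, LoopSpec, np.ndarray]:
    """Helix-loop-helix chain plus its loop spec and ground-truth loop coords.

    Loops shorter than 4 residues are rejected: the loop definition used
    throughout this package requires at least 4 residues between the two
    flanking secondary-structure elements.
    """
    if loop_len < 4:
        raise ValueError("loop_len must be >= 4")
    if n_flank1 < 2 or n_flank2 < 2:
        raise ValueError("flanks must have >= 2 residues to provide anchors")
    recipe = ChainRecipe(
        segments=[("helix", n_flank1), ("loop", loop_len), ("helix", n_flank2)],
        residue_name=residue_name,
        seed=seed,
    )
    structure = build_chain(recipe)
    spec = LoopSpec(chain_id="A", start=n_flank1, end=n_flank1 + loop_len - 1)
    truth = structure.atom_coords()[loop_mask(structure, spec)]
    return structure, spec, truth.copy()
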