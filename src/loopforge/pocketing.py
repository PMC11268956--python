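"""Pocket selection and loop-coordinate initialisation.

Only a pocket of nonloop residues around the loop is modeled, not the whole
protein.  For reconstruction (no prior loop coordinates) the pocket is a
sphere around the midpoint of the two anchor residues, with a radius set by
the anchor separation and the loop length, followed by a direction-based
pruning of the outer shell.  For refinement (an approximate loop is given)
the pocket is simply every nonloop residue within a distance cutoff of the
raw loop atoms.

Loop coordinates start from isotropic Gaussians: for reconstruction each
loop residue's atoms are drawn around a center interpolated between the two
anchors (SD 1.75 Å, the value the model is trained with); for refinement all
atoms are drawn around the raw loop's center of mass (SD 4 Å); for
multi-conformation sampling the reconstruction scheme is used with SD 7 Å,
which trades single-shot accuracy for conformational diversity.

"Center of mass" is the geometric centroid of heavy atoms (unit masses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import LoopSpec, ProteinStructure, Residue

RADIUS_CAP = 16.0  # Å cap on the loop-length-derived radius
LARGE_POCKET_RADIUS = 20.0  # Å; above this, switch to pseudo-loop interpolation
PSEUDO_LOOP_CUTOFF = 12.0  # Å around pseudo-loop points
SHELL_EXTENSION = 12.0  # Å added to the sphere for the outer shell
DIRECTION_PRUNE_DEG = 15.0  # prune shell residues aligned with an inner one
AUGMENT_CUTOFF = 6.0  # Å; midpoint of the 5-7 Å neighbour augmentation band
REFINE_CUTOFF = 12.0  # Å around raw loop atoms in refinement mode

SD_RECONSTRUCTION = 1.75
SD_REFINEMENT = 4.0
SD_MULTICONF = 7.0


@dataclass
class PocketSelection:
    residue_ids: set  # of (chain_id, residue index)
    midpoint: np.ndarray
    radius: float

    def residues(self, structure: ProteinStructure) -> list[Residue]:
        out = [
            res
            for res in structure.residues()
            if (res.chain_id, res.index) in self.residue_ids
        ]
        return out


@dataclass
class LoopInit:
    coords: np.ndarray  # [n_loop_atoms, 3]
    mode: str  # reconstruction | refinement | multiconf
    sd: float
    seed: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be [n_atoms, 3]")


def _nonloop_residues(structure: ProteinStructure, spec: LoopSpec) -> list[Residue]:
    return [
        res
        for res in structure.residues()
        if not (res.chain_id == spec.chain_id and spec.start <= res.index <= spec.end)
    ]


def pocket_radius(anchor_separation: float, loop_len: int) -> float:
    """max(half the anchor separation, min(2 * loop_len, 16)) in Å."""
    return max(anchor_separation / 2.0, min(2.0 * loop_len, RADIUS_CAP))


def select_surface_pocket(structure: ProteinStructure, spec: LoopSpec) -> PocketSelection:
    """Deterministic anchor-sphere pocket for loop reconstruction."""
    spec.validate(structure)
    anchor1, anchor2 = spec.anchor_residues(structure)
    com1, com2 = anchor1.centroid(), anchor2.centroid()
    midpoint = 0.5 * (com1 + com2)
    separation = float(np.linalg.norm(com2 - com1))
    radius = pocket_radius(separation, spec.length)

    candidates = _nonloop_residues(structure, spec)
    centroids = np.array([r.centroid() for r in candidates])

    if radius > LARGE_POCKET_RADIUS:
        # pseudo-loop: L points interpolated between the anchors
        fracs = np.arange(1, spec.length + 1) / (spec.length + 1)
        pseudo = com1[None, :] + fracs[:, None] * (com2 - com1)[None, :]
        selected = set()
        for res in candidates:
            if cdist(res.coords(), pseudo).min() <= PSEUDO_LOOP_CUTOFF:
                selected.add((res.chain_id, res.index))
    else:
        dist_mid = np.linalg.norm(centroids - midpoint, axis=1)
        inner = dist_mid <= radius
        shell = (~inner) & (dist_mid <= radius + SHELL_EXTENSION)
        # prune shell residues whose direction from the midpoint is close to
        # the direction of some inner-sphere residue
        keep_shell = np.zeros(len(candidates), dtype=bool)
        if shell.any():
            dirs = (centroids - midpoint) / np.maximum(dist_mid[:, None], 1e-9)
            cos_thresh = np.cos(np.deg2rad(DIRECTION_PRUNE_DEG))
            if inner.any():
                cosines = dirs[shell] @ dirs[inner].T
                keep_shell[np.flatnonzero(shell)] = cosines.max(axis=1) < cos_thresh
            else:
                keep_shell[shell] = True
        selected = {
            (res.chain_id, res.index)
            for res, m in zip(candidates, inner | keep_shell)
            if m
        }
        # augment with near neighbours of the current pocket
        pocket_coords = np.concatenate(
            [r.coords() for r in candidates if (r.chain_id, r.index) in selected]
        ) if selected else np.zeros((0, 3))
        for res in candidates:
            if (res.chain_id, res.index) in selected or pocket_coords.size == 0:
                continue
            if cdist(res.coords(), pocket_coords).min() <= AUGMENT_CUTOFF:
                selected.add((res.chain_id, res.index))

    # the anchors define the geometry and are always part of the pocket
    selected.add((anchor1.chain_id, anchor1.index))
    selected.add((anchor2.chain_id, anchor2.index))
    return PocketSelection(residue_ids=selected, midpoint=midpoint, radius=radius)


def select_refinement_pocket(
    structure: ProteinStructure,
    spec: LoopSpec,
    raw_loop_coords: np.ndarray,
    cutoff: float = REFINE_CUTOFF,
) -> PocketSelection:
    """Nonloop residues with any heavy atom within ``cutoff`` of the raw loop."""
    raw = np.asarray(raw_loop_coords, dtype=np.float64).reshape(-1, 3)
    if raw.size == 0:
        raise ValueError("raw loop coordinates are empty")
    spec.validate(structure)
    selected = set()
    for res in _nonloop_residues(structure, spec):
        if cdist(res.coords(), raw).min() <= cutoff:
            selected.add((res.chain_id, res.index))
    if not selected:
        warnings.warn(
            "refinement pocket is empty: raw loop lies > "
            f"{cutoff} Å from every nonloop residue",
            stacklevel=2,
        )
    return PocketSelection(residue_ids=selected, midpoint=raw.mean(axis=0), radius=cutoff)


# -- initialisation ----------------------------------------------------------


def interpolated_residue_centers(
    structure: ProteinStructure, spec: LoopSpec
) -> np.ndarray:
    """Target center for loop residue i: anchor1 + i/(L+1) * (anchor2 - anchor1)."""
    anchor1, anchor2 = spec.anchor_residues(structure)
    com1, com2 = anchor1.centroid(), anchor2.centroid()
    fracs = np.arange(1, spec.length + 1) / (spec.length + 1)
    return com1[None, :] + fracs[:, None] * (com2 - com1)[None, :]


def init_loop_reconstruction(
    structure: ProteinStructure,
    spec: LoopSpec,
    sd: float = SD_RECONSTRUCTION,
    seed: int = 0,
    mode: str = "reconstruction",
) -> LoopInit:
    """Sample every atom of loop residue i around its interpolated center."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    centers = interpolated_residue_centers(structure, spec)
    rng = np.random.default_rng(seed)
    coords = []
    for center, res in zip(centers, spec.loop_residues(structure)):
        coords.append(center[None, :] + rng.normal(0.0, sd, size=(len(res.atoms), 3)))
    return LoopInit(coords=np.concatenate(coords), mode=mode, sd=sd, seed=seed)


def init_loop_refinement(
    raw_loop_coords: np.ndarray, sd: float = SD_REFINEMENT, seed: int = 0
) -> LoopInit:
    """Sample every loop atom around the raw loop's center of mass."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    raw = np.asarray(raw_loop_coords, dtype=np.float64).reshape(-1, 3)
    if raw.size == 0:
        raise ValueError("raw loop coordinates are empty")
    rng = np.random.default_rng(seed)
    com = raw.mean(axis=0)
    coords = com[None, :] + rng.normal(0.0, sd, size=raw.shape)
    return LoopInit(coords=coords, mode="refinement", sd=sd, seed=seed)


def init_multiconf(
    structure: ProteinStructure,
    spec: LoopSpec,
    n: int = 5,
    sd: float = SD_MULTICONF,
    seeds: list[int] | None = None,
) -> list[LoopInit]:
    """n independent reconstruction-mode initialisations with a wide SD."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seeds is None:
        seeds = list(range(n))
    if len(seeds) != n or len(set(seeds)) != n:
        raise ValueError("need n distinct seeds")
    return [
        init_loop_reconstruction(structure, spec, sd=sd, seed=s, mode="multiconf")
        for s in seeds
    ]
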