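"""End-to-end prediction pipeline: PDB in, loop conformations + scores out.

The pipeline is: pocket selection -> loop initialisation -> graph building ->
encoders -> hierarchical merge -> interaction graph -> equivariant generator
(with recycling) -> mixture-density confidence score.  Predicted loop
coordinates are spliced back into the input structure; nonloop atoms are
written back bit-identical.

Force-field post-processing is supported only as an optional external command
hook run on each output PDB; nothing is minimised in-process.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import LoopModel, LoopTask, prepare_task
from .pocketing import (
    SD_MULTICONF,
    SD_RECONSTRUCTION,
    SD_REFINEMENT,
    init_loop_reconstruction,
    init_loop_refinement,
)
from .scoring import mdn_score, pair_min_distances
from .structio import LoopSpec, ProteinStructure, loop_mask, parse_pdb, write_pdb

MODES = ("reconstruct", "refine", "multiconf")


@dataclass
class PredictRequest:
    pdb_path: str
    loop: str  # chain:start-end in author (PDB) numbering
    checkpoint: str
    mode: str = "reconstruct"
    n_conformations: int = 1
    seed: int = 0
    sd: float | None = None
    out_dir: str = "."
    postprocess_cmd: str | None = None  # e.g. "minimize.sh {pdb}"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_conformations < 1:
            raise ValueError("need at least one conformation")
        if self.mode == "multiconf" and self.n_conformations < 2:
            self.n_conformations = 5


def parse_loop_selector(structure: ProteinStructure, selector: str) -> LoopSpec:
    """``chain:start-end`` in the author's PDB numbering -> 0-based LoopSpec."""
    try:
        chain_id, span = selector.split(":")
        first, last = span.split("-")
    except ValueError as exc:
        raise ValueError(f"loop selector {selector!r} is not chain:start-end") from exc
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure")
    auth = {res.auth_seq_id: res.index for res in structure.chains[chain_id]}
    for key in (first, last):
        if key not in auth:
            raise KeyError(f"residue {key} not found in chain {chain_id}")
    spec = LoopSpec(chain_id=chain_id, start=auth[first], end=auth[last])
    spec.validate(structure)
    return spec


@dataclass
class PredictionResult:
    conformation_id: str
    pdb_path: str
    score: float
    rmsd_vs_reference: float | None = None


def predict_loops(request: PredictRequest) -> list[PredictionResult]:
    """Run the full pipeline; writes one PDB per conformation plus a TSV."""
    model = LoopModel.load(request.checkpoint)
    model.eval()
    text = Path(request.pdb_path).read_text()
    structure = parse_pdb(text, title=Path(request.pdb_path).stem)
    spec = parse_loop_selector(structure, request.loop)

    mask = loop_mask(structure, spec)
    if request.mode == "refine":
        raw = structure.atom_coords()[mask]
        task = prepare_task(structure, spec, mode="refinement", raw_loop_coords=raw)
    else:
        task = prepare_task(structure, spec)
    if not task.residue_graph.residue_ids:
        raise ValueError("empty pocket: no nonloop residues near the loop")

    sd_default = {
        "reconstruct": SD_RECONSTRUCTION,
        "refine": SD_REFINEMENT,
        "multiconf": SD_MULTICONF,
    }[request.mode]
    sd = request.sd or sd_default

    out_dir = Path(request.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[PredictionResult] = []
    pocket_residues = task.pocket_residues()
    for i in range(request.n_conformations):
        seed = request.seed + i
        if request.mode == "refine":
            init = init_loop_refinement(raw, sd=sd, seed=seed)
        else:
            mode = "multiconf" if request.mode == "multiconf" else "reconstruction"
            init = init_loop_reconstruction(structure, spec, sd=sd, seed=seed, mode=mode)
        outputs = model(task, loop_init=init)
        coords = outputs.loop_coords.data
        score = mdn_score(outputs.mdn, pair_min_distances(coords, pocket_residues))

        predicted = structure.copy()
        predicted.set_atom_coords(coords, mask=mask)
        conf_id = f"conf{i}"
        pdb_path = out_dir / f"{Path(request.pdb_path).stem}_{conf_id}.pdb"
        pdb_path.write_text(write_pdb(predicted))
        if request.postprocess_cmd:
            subprocess.run(
                request.postprocess_cmd.format(pdb=str(pdb_path)), shell=True, check=True
            )
        results.append(PredictionResult(conf_id, str(pdb_path), score))

    tsv = out_dir / f"{Path(request.pdb_path).stem}_scores.tsv"
    with tsv.open("w") as fh:
        fh.write("conformation_id\tscore\n")
        for r in results:
            fh.write(f"{r.conformation_id}\t{r.score:.4f}\n")
    return results
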