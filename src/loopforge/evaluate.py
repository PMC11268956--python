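"""Evaluation: full-atom loop RMSD, success rate, eCDF, best-of-N selection.

Loop accuracy is the heavy-atom RMSD over the loop region.  When predictions
live in a different frame than the reference (whole-structure predictors),
the structures are first superposed on the nonloop (framework) atoms with the
Kabsch algorithm, then the loop RMSD is measured.  A prediction counts as a
success when its loop RMSD is at most 2 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import LoopSpec, ProteinStructure

SUCCESS_THRESHOLD = 2.0  # Å


@dataclass
class EvalRecord:
    task_id: str
    conformation_id: str
    rmsd: float
    aligned: bool
    score: float = float("nan")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd-after-fit) with
    ``mobile @ rotation.T + translation ~= reference``.  The rotation is
    proper (determinant +1); reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=np.float64).reshape(-1, 3)
    reference = np.asarray(reference, dtype=np.float64).reshape(-1, 3)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need two matched point sets with >= 3 points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _matched_coords(
    pred: ProteinStructure, ref: ProteinStructure, selector
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms present in both structures, matched by
    (chain, residue index, atom name); unmatched reference atoms are an error."""
    pred_index = {}
    for res in pred.residues():
        for atom in res.atoms:
            pred_index[(res.chain_id, res.index, atom.name)] = atom.coords
    a, b, missing = [], [], []
    for res in ref.residues():
        if not selector(res):
            continue
        for atom in res.atoms:
            key = (res.chain_id, res.index, atom.name)
            if key in pred_index:
                a.append(pred_index[key])
                b.append(atom.coords)
            else:
                missing.append(key)
    if missing:
        raise ValueError(f"atoms missing from prediction: {missing[:10]}")
    return np.array(a), np.array(b)


def loop_rmsd(
    pred: ProteinStructure,
    ref: ProteinStructure,
    spec: LoopSpec,
    align: str = "none",
) -> float:
    """Heavy-atom RMSD over the loop region; ``align='framework'`` superposes
    on the nonloop atoms first."""
    if align not in ("none", "framework"):
        raise ValueError("align must be 'none' or 'framework'")

    def in_loop(res):
        return res.chain_id == spec.chain_id and spec.start <= res.index <= spec.end

    pred_loop, ref_loop = _matched_coords(pred, ref, in_loop)
    if align == "framework":
        pred_fw, ref_fw = _matched_coords(pred, ref, lambda r: not in_loop(r))
        R, t, _ = kabsch_superpose(pred_fw, ref_fw)
        pred_loop = pred_loop @ R.T + t
    return float(np.sqrt(((pred_loop - ref_loop) ** 2).sum(axis=1).mean()))


def success_rate(rmsds, threshold: float = SUCCESS_THRESHOLD) -> float:
    """Fraction of cases with RMSD <= threshold (boundary counts as success)."""
    rmsds = np.asarray(list(rmsds), dtype=np.float64)
    if rmsds.size == 0:
        raise ValueError("empty RMSD list")
    return float((rmsds <= threshold).mean())


def ecdf(rmsds) -> list[tuple[float, float]]:
    """Right-continuous empirical CDF: (x, fraction <= x) at unique values."""
    rmsds = np.sort(np.asarray(list(rmsds), dtype=np.float64))
    if rmsds.size == 0:
        raise ValueError("empty RMSD list")
    xs = np.unique(rmsds)
    return [(float(x), float((rmsds <= x).mean())) for x in xs]


def best_of_n(records: list[EvalRecord]) -> tuple[EvalRecord, EvalRecord]:
    """(oracle-best by min RMSD, confidence-selected by max score)."""
    if not records:
        raise ValueError("no conformations")
    by_rmsd = min(records, key=lambda r: r.rmsd)
    by_score = max(records, key=lambda r: (r.score if np.isfinite(r.score) else -np.inf))
    return by_rmsd, by_score
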