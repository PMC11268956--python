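"""Mixture-density network over loop-atom / pocket-residue pair distances.

For every (loop atom, pocket residue) pair the head predicts a 10-component
Gaussian mixture over their distance — where distance means the minimum over
the residue's heavy atoms of the distance to the loop atom.  The negative
log-likelihood of the ground-truth distances is the statistical-potential
training loss; the summed log-likelihood of a candidate conformation's
distances is its confidence score (higher is better).

Component means and SDs are kept positive by shifted ELUs (mu > 0,
sigma > 0.1); mixture weights come from a softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import nn
from .nn import Tensor, concat, gather

N_COMPONENTS = 10
NLL_DISTANCE_CUTOFF = 12.0  # Å; training pairs beyond this are uninformative
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MDNOutput:
    mu: Tensor  # [N_pairs, n_comp], Å
    sigma: Tensor  # [N_pairs, n_comp], Å
    log_pi: Tensor  # [N_pairs, n_comp]; rows of exp sum to 1
    pair_index: np.ndarray  # [N_pairs, 2] (loop atom id, residue id)

    @property
    def pi(self) -> np.ndarray:
        return np.exp(self.log_pi.data)


class MDNHead(nn.Module):
    def __init__(self, d_h: int, rng, d_pair: int = 64, n_comp: int = N_COMPONENTS, dropout: float = 0.1):
        super().__init__()
        self.n_comp = n_comp
        self.lin_pair = nn.Linear(2 * d_h, d_pair, rng)
        self.norm = nn.BatchNorm(d_pair)
        self.drop = nn.Dropout(dropout)
        self.lin_mu = nn.Linear(d_pair, n_comp, rng)
        self.lin_sigma = nn.Linear(d_pair, n_comp, rng)
        self.lin_pi = nn.Linear(d_pair, n_comp, rng)

    def __call__(self, h_loop: Tensor, h_res: Tensor) -> MDNOutput:
        L, P = h_loop.shape[0], h_res.shape[0]
        li, ri = np.meshgrid(np.arange(L), np.arange(P), indexing="ij")
        pair_index = np.stack([li.ravel(), ri.ravel()], axis=1)
        feats = concat(
            [gather(h_res, pair_index[:, 1]), gather(h_loop, pair_index[:, 0])], axis=-1
        )
        z = self.drop(nn.elu(self.norm(self.lin_pair(feats))))
        mu = nn.elu(self.lin_mu(z)) + 1.0
        sigma = nn.elu(self.lin_sigma(z)) + 1.1
        logits = self.lin_pi(z)
        log_pi = logits - _logsumexp(logits)
        return MDNOutput(mu=mu, sigma=sigma, log_pi=log_pi, pair_index=pair_index)


def _logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    return ((t - shift).exp().sum(axis=axis, keepdims=True)).log() + shift


def pair_min_distances(loop_coords: np.ndarray, residues) -> np.ndarray:
    """[L, P] matrix: min over residue heavy atoms of the atom-atom distance.

    ``residues`` is a sequence of objects exposing ``coords()`` (heavy-atom
    coordinate arrays), or plain arrays.
    """
    loop_coords = np.asarray(loop_coords, dtype=np.float64).reshape(-1, 3)
    cols = []
    for res in residues:
        atoms = res.coords() if hasattr(res, "coords") else np.asarray(res, dtype=np.float64)
        cols.append(cdist(loop_coords, atoms.reshape(-1, 3)).min(axis=1))
    return np.stack(cols, axis=1)


def _pair_log_likelihood(out: MDNOutput, distances: np.ndarray) -> Tensor:
    d = np.asarray(distances, dtype=np.float64).reshape(-1)[:, None]
    if d.shape[0] != out.mu.shape[0]:
        raise ValueError("distance count does not match MDN pair count")
    if np.any(out.sigma.data <= 0):
        raise ValueError("mixture SDs must be positive")
    z = (Tensor(d) - out.mu) / out.sigma
    log_n = z**2 * (-0.5) - out.sigma.log() - 0.5 * _LOG_2PI
    return _logsumexp(out.log_pi + log_n).reshape(-1)


def mdn_nll(
    out: MDNOutput, distances: np.ndarray, cutoff: float | None = NLL_DISTANCE_CUTOFF
) -> Tensor:
    """Mean negative log-likelihood over pairs with true distance <= cutoff."""
    ll = _pair_log_likelihood(out, distances)
    d = np.asarray(distances, dtype=np.float64).reshape(-1)
    if cutoff is not None:
        keep = np.flatnonzero(d <= cutoff)
        if keep.size == 0:
            raise ValueError("no pair distance below the cutoff")
        ll = gather(ll, keep)
    return -ll.mean()


def mdn_score(out: MDNOutput, distances: np.ndarray) -> float:
    """Summed log-likelihood of the observed distances; higher is better."""
    return float(_pair_log_likelihood(out, distances).sum().data)
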