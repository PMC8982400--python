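"""Sequence likelihood p(D | G) under the F84 mutation model.

The genealogy's migration and divergence events relabel populations only;
the substitution process along a branch depends on the branch length
alone.  The likelihood is computed with the phylogenetic pruning
(peeling) algorithm, vectorised over compressed site patterns.

F84 assigns every substitution a target-frequency factor ``pi_j`` and
boosts within-purine / within-pyrimidine changes (transitions) by
``1 + kappa / pi_group(j)``.  With equal base frequencies and
``kappa = 1.5`` the implied transition/transversion ratio is 2, the usual
default.  The rate matrix is normalised to one expected substitution per
unit branch length, so branch lengths share the mutation scale of Theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MutationModel", "CompressedAlignment", "f84_transition_matrix", "pruning_loglike"]

BASES = "ACGT"
_PURINE = (True, False, True, False)  # A, G

# IUPAC ambiguity -> partial-likelihood row
_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}


@dataclass(frozen=True)
class MutationModel:
    """F84 substitution model.

    Parameters
    ----------
    freqs : tuple of 4 floats
        Stationary base frequencies (A, C, G, T); must sum to 1.
    kappa : float
        Transition-boost parameter (>= 0).  At equal frequencies the
        transition/transversion ratio equals ``(1 + 2 kappa) / 2``.
    rate : float
        Per-locus rate scalar multiplying every branch length.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.5
    rate: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.kappa < 0 or self.rate <= 0:
            raise ValueError("kappa must be >= 0 and rate > 0")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))
        # build the normalised rate matrix and its spectral decomposition
        pi_r = f[0] + f[2]
        pi_y = f[1] + f[3]
        group = np.where(_PURINE, pi_r, pi_y)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = _PURINE[i] == _PURINE[j]
                q[i, j] = f[j] * (1.0 + self.kappa / group[j]) if transition else f[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(f, np.diag(q)))
        q /= mean_rate
        # reversible: symmetrise with pi^1/2 for a stable eigendecomposition
        s = np.sqrt(f)
        sym = (s[:, None] * q) / s[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2)
        # Q = S^-1 V W V^T S with S = diag(sqrt(pi)); P(t) = S^-1 V e^{Wt} V^T S
        object.__setattr__(self, "_eigvals", w)
        object.__setattr__(self, "_right", v / s[:, None])
        object.__setattr__(self, "_left", v.T * s[None, :])


def f84_transition_matrix(t: float, m: MutationModel) -> np.ndarray:
    """4x4 stochastic matrix of substitution probabilities over length ``t``."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    w = np.exp(m._eigvals * (t * m.rate))
    p = (m._right * w[None, :]) @ m._left
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def encode_alignment(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Map sequences to per-site partial-likelihood tensors.

    Returns tip names and an array of shape (n_tips, n_sites, 4); ambiguity
    codes and gaps become uniform rows (fully missing).
    """
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    n_sites = lengths.pop()
    arr = np.zeros((len(names), n_sites, 4))
    for r, name in enumerate(names):
        for c, ch in enumerate(seqs[name].upper()):
            allowed = _AMBIG.get(ch, "ACGT")
            for b in allowed:
                arr[r, c, BASES.index(b)] = 1.0
    return names, arr


def _compress_patterns(tips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical site columns; returns (patterns, counts)."""
    n_tips, n_sites, _ = tips.shape
    flat = tips.transpose(1, 0, 2).reshape(n_sites, n_tips * 4)
    uniq, inverse, counts = np.unique(flat, axis=0, return_inverse=True,
                                      return_counts=True)
    patterns = uniq.reshape(-1, n_tips, 4).transpose(1, 0, 2)
    return patterns, counts.astype(float)


class CompressedAlignment:
    """Alignment pre-encoded as collapsed site patterns.

    Building this once per locus makes repeated likelihood evaluations on
    changing genealogies (the MCMC inner loop) cheap.
    """

    def __init__(self, aln: dict[str, str]):
        names, arr = encode_alignment(aln)
        patterns, counts = _compress_patterns(arr)
        self.names = names
        self.row_of = {nm: i for i, nm in enumerate(names)}
        self.patterns = patterns
        self.counts = counts


def pruning_loglike(g, aln, m: MutationModel) -> float:
    """Log likelihood of alignment ``aln`` on genealogy ``g`` under F84.

    ``aln`` is a tip-name -> sequence mapping or a pre-built
    :class:`CompressedAlignment`.  Tip names of ``g`` must match the
    alignment exactly.  Sites are independent; identical site patterns are
    collapsed before the postorder pass.
    """
    if not isinstance(aln, CompressedAlignment):
        aln = CompressedAlignment(aln)
    tip_nodes = g.tips()
    tip_names = {n.name for n in tip_nodes}
    if tip_names != set(aln.names):
        missing = tip_names ^ set(aln.names)
        raise ValueError(f"tip/alignment name mismatch: {sorted(missing)}")
    row_of = aln.row_of
    patterns, counts = aln.patterns, aln.counts

    partials: dict[int, np.ndarray] = {}
    # postorder via iterative stack
    stack = [(g.root, False)]
    while stack:
        nid, done = stack.pop()
        node = g.nodes[nid]
        if not node.children:
            partials[nid] = patterns[row_of[node.name]]
            continue
        if not done:
            stack.append((nid, True))
            for c in node.children:
                stack.append((c, False))
            continue
        prod = None
        for c in node.children:
            t = node.time - g.nodes[c].time
            p = f84_transition_matrix(t, m)
            term = partials.pop(c) @ p.T
            prod = term if prod is None else prod * term
        partials[nid] = prod

    pi = np.asarray(m.freqs)
    site_like = partials[g.root] @ pi
    if np.any(site_like <= 0):
        return -math.inf
    return float(np.dot(np.log(site_like), counts))
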