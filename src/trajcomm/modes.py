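"""Collective-motion analysis: PCA modes, elastic-network normal modes,
variance fractions, subspace overlap, collectivity and resultant displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import StructureModel, TrajectoryEnsemble
from .errors import (
    ArgumentError,
    ConnectivityError,
    DegenerateError,
    InsufficientDataError,
    PreconditionError,
    SchemeError,
)
from .geometry import align_to_mean

_ZERO_MODE_TOL = 1e-8


@dataclass
class ModeSet:
    """Eigenvalues and unit-norm 3N displacement eigenvectors.

    ``eigenvectors`` has shape (n_modes, n_atoms, 3).  PCA eigenvalues are
    variances sorted descending; ENM eigenvalues are spring-Hessian
    eigenvalues sorted ascending with the six rigid-body modes removed.
    ``atom_indices`` maps mode components back to atoms of the source
    structure/ensemble selection.
    """

    source: str                 # "pca" | "enm-nma"
    eigenvalues: np.ndarray     # (n_modes,)
    eigenvectors: np.ndarray    # (n_modes, n_atoms, 3), unit Euclidean norm
    atom_indices: np.ndarray    # (n_atoms,)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        flat = self.eigenvectors.reshape(len(self.eigenvalues), -1)
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(len(flat)), atol=1e-8):
            raise DegenerateError("mode vectors not orthonormal to 1e-8")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def flat(self) -> np.ndarray:
        """Modes as (n_modes, 3N) row vectors."""
        return self.eigenvectors.reshape(self.n_modes, -1)

    def subset(self, n: int) -> "ModeSet":
        return ModeSet(self.source, self.eigenvalues[:n],
                       self.eigenvectors[:n], self.atom_indices)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # eigenvector sign is arbitrary: make the largest-|component| positive
    flat = vectors.reshape(len(vectors), -1)
    for row in flat:
        i = int(np.argmax(np.abs(row)))
        if row[i] < 0:
            row *= -1.0
    return flat.reshape(vectors.shape)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_modes(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    selection: str = "backbone",
    n_modes: int = 100,
) -> ModeSet:
    """PCA of the positional covariance after superposition onto the mean.

    Frames are restricted to ``selection``, iteratively aligned to their
    average, and the 3N x 3N covariance is diagonalized; the top ``n_modes``
    (or fewer if rank-limited) are returned with unit-norm eigenvectors.
    """
    sel = np.nonzero(structure.selection_mask(selection))[0]
    if len(sel) == 0:
        raise SchemeError(f"selection {selection!r} is empty")
    frames = ens.frames()[:, sel, :]
    if len(frames) < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    aligned = align_to_mean(frames)
    flat = aligned.reshape(len(aligned), -1)
    flat = flat - flat.mean(axis=0)
    # SVD of the centered data is cheaper and more stable than forming C
    _u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eigenvalues = (s ** 2) / len(flat)
    n_keep = min(n_modes, len(eigenvalues))
    vectors = vt[:n_keep].reshape(n_keep, len(sel), 3)
    return ModeSet(
        source="pca",
        eigenvalues=eigenvalues[:n_keep],
        eigenvectors=_fix_signs(vectors),
        atom_indices=sel,
    )


def modes_for_variance(modes: ModeSet, fraction: float = 0.8) -> int:
    """Smallest m with the first m eigenvalues covering >= ``fraction`` of the
    total spectrum (PCA convention: eigenvalues descending)."""
    if not (0.0 < fraction <= 1.0):
        raise ArgumentError("fraction must be in (0, 1]")
    total = modes.eigenvalues.sum()
    if total <= 0:
        raise DegenerateError("all-zero eigenvalue spectrum")
    cum = np.cumsum(modes.eigenvalues) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def subspace_overlap(v: np.ndarray, w: np.ndarray, atol: float = 1e-6) -> float:
    """Overlap of reference subspace V (n vectors) within subspace W (m
    vectors): (1/n) * sum_ij (v_i . w_j)^2, in [0, 1]; equals 1 when V is
    contained in span(W)."""
    v = np.asarray(v, dtype=float).reshape(len(v), -1)
    w = np.asarray(w, dtype=float).reshape(len(w), -1)
    for name, m in (("v", v), ("w", w)):
        gram = m @ m.T
        if not np.allclose(gram, np.eye(len(m)), atol=atol):
            raise DegenerateError(f"vector set {name} is not orthonormal")
    dots = v @ w.T
    return float((dots ** 2).sum() / len(v))


# ---------------------------------------------------------------------------
# Elastic-network normal modes (Calpha anisotropic network)
# ---------------------------------------------------------------------------

def enm_normal_modes(
    structure: StructureModel,
    cutoff_nm: float = 1.3,
    n_modes: int = 96,
) -> ModeSet:
    """Anisotropic-network normal modes on the Calpha trace.

    Unit springs connect Calpha pairs within ``cutoff_nm``; the 3N x 3N
    Hessian is diagonalized, the six rigid-body modes are dropped and the
    lowest ``n_modes`` are expanded to the full atom set by giving every atom
    its residue's Calpha displacement (rigid per-residue attribution), then
    renormalized to unit norm.
    """
    if cutoff_nm <= 0:
        raise ArgumentError("cutoff must be > 0")
    ca = np.nonzero(structure.selection_mask("calpha"))[0]
    if len(ca) < 2:
        raise PreconditionError("ENM needs at least 2 Calpha atoms")
    pos = structure.positions[ca]
    n = len(ca)
    dist = squareform(pdist(pos))
    contacts = (dist <= cutoff_nm) & ~np.eye(n, dtype=bool)
    if not _connected(contacts):
        raise ConnectivityError("ENM contact graph is disconnected at this cutoff")

    hessian = enm_hessian(pos, contacts)
    eigenvalues, vectors = np.linalg.eigh(hessian)
    nonzero = eigenvalues > _ZERO_MODE_TOL
    eigenvalues = eigenvalues[nonzero]
    vectors = vectors[:, nonzero]
    n_keep = min(n_modes, len(eigenvalues))
    eigenvalues = eigenvalues[:n_keep]
    ca_modes = vectors[:, :n_keep].T.reshape(n_keep, n, 3)

    # expand to all atoms: every atom inherits its residue's Calpha motion
    res_of_ca = {int(structure.residue_numbers[a]): k for k, a in enumerate(ca)}
    expanded = np.zeros((n_keep, structure.n_atoms, 3))
    for atom in range(structure.n_atoms):
        k = res_of_ca.get(int(structure.residue_numbers[atom]))
        if k is not None:
            expanded[:, atom, :] = ca_modes[:, k, :]
    flat = expanded.reshape(n_keep, -1)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    flat /= norms
    # re-orthonormalize: per-residue expansion preserves orthogonality only
    # when residues have equal atom counts; Gram-Schmidt fixes the rest
    q, _ = np.linalg.qr(flat.T)
    expanded = _fix_signs(q.T[:n_keep].reshape(n_keep, structure.n_atoms, 3))
    return ModeSet(
        source="enm-nma",
        eigenvalues=eigenvalues,
        eigenvectors=expanded,
        atom_indices=np.arange(structure.n_atoms),
    )


def enm_hessian(pos: np.ndarray, contacts: np.ndarray) -> np.ndarray:
    """3N x 3N anisotropic-network Hessian for unit springs on ``contacts``."""
    n = len(pos)
    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.nonzero(contacts[i])[0]:
            if j <= i:
                continue
            rij = pos[j] - pos[i]
            d2 = rij @ rij
            block = -np.outer(rij, rij) / d2
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hessian


def _connected(adj: np.ndarray) -> bool:
    n = len(adj)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i] & ~seen)[0]:
            seen[j] = True
            stack.append(int(j))
    return bool(seen.all())


# ---------------------------------------------------------------------------
# Mode metrics
# ---------------------------------------------------------------------------

def collectivity(mode: np.ndarray, atom_subset: np.ndarray | None = None) -> float:
    """Entropy-based degree of collectivity of one mode over an atom subset.

    With alpha_i the squared displacement amplitude of atom i normalized so
    sum(alpha) = 1 over the n subset atoms,
    kappa = (1/n) * exp(-sum alpha_i ln alpha_i), which is 1/n when a single
    atom moves and 1 when all atoms move with equal amplitude.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.ndim != 2 or mode.shape[1] != 3:
        raise ArgumentError("mode must have shape (n_atoms, 3)")
    if atom_subset is None:
        atom_subset = np.arange(mode.shape[0])
    atom_subset = np.asarray(atom_subset)
    if len(atom_subset) == 0:
        raise ArgumentError("atom subset is empty")
    alpha = (mode[atom_subset] ** 2).sum(axis=1)
    total = alpha.sum()
    if total <= 0:
        raise DegenerateError("mode is identically zero on the subset")
    alpha = alpha / total
    nonzero = alpha > 0
    entropy = -float((alpha[nonzero] * np.log(alpha[nonzero])).sum())
    return float(np.exp(entropy) / len(atom_subset))


def resultant_displacement(mode: np.ndarray, fragment: np.ndarray) -> float:
    """Norm of the vector sum of per-atom displacements over a fragment."""
    mode = np.asarray(mode, dtype=float)
    fragment = np.asarray(fragment)
    if len(fragment) == 0:
        raise ArgumentError("fragment is empty")
    return float(np.linalg.norm(mode[fragment].sum(axis=0)))
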