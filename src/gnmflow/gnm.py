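"""Gaussian network model: Kirchhoff matrix, normal modes, equilibrium observables.

The residue contact network is encoded in the Kirchhoff (graph Laplacian)
matrix Gamma: off-diagonal entries are -1 for residue pairs whose C-alpha
distance is within the cutoff (7.0 A by default, boundary inclusive) and 0
otherwise; each diagonal entry is the contact degree.  All springs share one
force constant gamma and all nodes one mass m; in the natural units gamma =
m = 1 the time unit of the dynamics is sqrt(m/gamma).

Equilibrium statistics follow from the pseudo-inverse of Gamma: the
mean-square fluctuation of residue i is (3 kB T / gamma) [Gamma^+]_ii and
the cross-correlation <dRi . dRj> is (3 kB T / gamma) [Gamma^+]_ij, both
evaluated here as sums over the non-zero normal modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.spatial.distance
from scipy.sparse.csgraph import connected_components

from gnmflow.errors import DisconnectedNetworkError, GnmflowError, InputError
from gnmflow.structures import StructureModel

__all__ = [
    "KirchhoffModel",
    "ModeBasis",
    "build_kirchhoff",
    "decompose",
    "mean_square_fluctuation",
    "cross_correlation",
]

#: eigenvalues below ZERO_TOL * max(eigenvalue) count as zero modes
ZERO_TOL = 1e-10


@dataclass
class KirchhoffModel:
    """Contact network of a structure at a given cutoff."""

    matrix: np.ndarray          # (N, N) symmetric graph Laplacian
    cutoff: float               # contact cutoff r_c in Angstrom
    structure_ref: str          # source label of the StructureModel
    n_components: int           # connected components of the contact graph

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean contact map (no self-contacts)."""
        return self.matrix < 0

    @property
    def degrees(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    def contact_graph(self):
        """The contact network as an unweighted :mod:`networkx` graph."""
        import networkx as nx

        return nx.from_numpy_array(self.adjacency.astype(int))


@dataclass
class ModeBasis:
    """Eigendecomposition of the Kirchhoff matrix, zero modes flagged.

    ``eigenvalues`` are ascending and ``eigenvectors`` columns are the
    orthonormal modes U.  The first ``n_zero_modes`` entries belong to the
    null space (overall translation for a connected network) and are
    excluded from every dynamical and thermodynamical sum.
    """

    eigenvalues: np.ndarray      # (N,) ascending, >= 0
    eigenvectors: np.ndarray     # (N, N) orthonormal, columns are modes
    n_zero_modes: int
    force_constant: float = 1.0  # gamma, energy / length^2
    mass: float = 1.0            # m, identical for all residues

    @property
    def n_residues(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes:]

    @property
    def nonzero_eigenvectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero_modes:]

    @property
    def omegas(self) -> np.ndarray:
        """Angular frequencies omega_k = sqrt((gamma/m) Lambda_kk), non-zero modes."""
        return np.sqrt(self.force_constant / self.mass * self.nonzero_eigenvalues)


def build_kirchhoff(structure: StructureModel, cutoff: float = 7.0) -> KirchhoffModel:
    """Build the Kirchhoff matrix of the residue contact network.

    Two residues are in contact when their C-alpha distance satisfies
    ``R_ij <= cutoff`` (boundary inclusive).  Contacts get Gamma_ij = -1 and
    the diagonal carries the contact degree, so all row sums vanish.
    """
    if not cutoff > 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    coords = structure.coords
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(coords)
    )
    contacts = dist <= cutoff
    np.fill_diagonal(contacts, False)
    gamma = -contacts.astype(float)
    np.fill_diagonal(gamma, contacts.sum(axis=1))
    n_comp, _ = connected_components(
        scipy.sparse.csr_matrix(contacts), directed=False
    )
    return KirchhoffModel(
        matrix=gamma,
        cutoff=float(cutoff),
        structure_ref=structure.source,
        n_components=int(n_comp),
    )


def decompose(kirchhoff: KirchhoffModel, gamma: float = 1.0,
              mass: float = 1.0) -> ModeBasis:
    """Full symmetric eigendecomposition Gamma = U Lambda U^T.

    Eigenvalues are returned ascending; those below ``ZERO_TOL * max`` are
    flagged as zero modes and removed from all downstream sums.  For a
    connected network exactly one zero mode (the uniform translation) exists;
    a second one means the contact graph is disconnected and transport
    between components would silently be ignored, so this is refused.
    """
    if gamma <= 0 or mass <= 0:
        raise InputError("force constant and mass must be positive")
    try:
        eigvals, eigvecs = scipy.linalg.eigh(kirchhoff.matrix)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise GnmflowError(f"eigendecomposition failed: {exc}") from exc

    scale = max(eigvals.max(), 1.0)
    n_zero = int(np.sum(np.abs(eigvals) < ZERO_TOL * scale))
    eigvals = eigvals.copy()
    eigvals[:n_zero] = 0.0

    if n_zero > 1:
        raise DisconnectedNetworkError(
            f"contact network of '{kirchhoff.structure_ref}' has {n_zero} "
            "zero modes (disconnected graph); increase the cutoff or restrict "
            "to one component"
        )

    # Deterministic sign convention: largest-magnitude entry of each mode
    # is positive.  Physical observables are sign-invariant; this only makes
    # serialized output reproducible.
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0),
                           np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip

    return ModeBasis(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        n_zero_modes=n_zero,
        force_constant=float(gamma),
        mass=float(mass),
    )


def mean_square_fluctuation(modes: ModeBasis, kBT: float = 1.0) -> np.ndarray:
    """Per-residue equilibrium mean-square fluctuation.

    <(dR_i)^2> = (3 kB T / gamma) sum_k U_ik^2 / Lambda_kk over non-zero
    modes, identical to (3 kB T / gamma) diag(Gamma^+).
    """
    u = modes.nonzero_eigenvectors
    lam = modes.nonzero_eigenvalues
    return 3.0 * kBT / modes.force_constant * (u ** 2 / lam).sum(axis=1)


def cross_correlation(modes: ModeBasis, kBT: float = 1.0,
                      normalized: bool = True) -> np.ndarray:
    """Equilibrium cross-correlation matrix of residue fluctuations.

    Unnormalized: <dRi . dRj> = (3 kB T / gamma) sum_k U_ik U_jk / Lambda_kk.
    Normalized: C_ij = <dRi . dRj> / sqrt(<dRi^2><dRj^2>), unit diagonal,
    entries in [-1, 1], independent of kBT and gamma.
    """
    u = modes.nonzero_eigenvectors
    lam = modes.nonzero_eigenvalues
    cov = (u / lam) @ u.T * (3.0 * kBT / modes.force_constant)
    cov = 0.5 * (cov + cov.T)
    if not normalized:
        return cov
    msf = np.sqrt(np.diag(cov))
    corr = cov / np.outer(msf, msf)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)
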