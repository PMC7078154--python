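"""Harmonic reference: geometry, masses, frequencies, normal-mode matrix.

The ground-state surface is a harmonic oscillator in dimensionless
mass-frequency scaled normal coordinates ``Q``,

    V0(Q) = sum_i  hbar*omega_i/2 * Q_i**2 ,

with the Cartesian-to-normal transform

    Q_i = sqrt(omega_i / hbar) * sum_alpha K_alpha,i * sqrt(M_alpha)
          * (r_alpha - r_ref_alpha)

evaluated in atomic units.  The ``sqrt(omega/hbar)`` prefactor is chosen so
that V0 takes the form above (the convention is ambiguous in some of the
literature; this one makes ``<Q^2> = 1/2`` in the vibrational ground state).

``K`` is the orthonormal mass-weighted eigenvector matrix (``K^T K = 1``):
its columns are the normal-mode directions in mass-weighted space, so the
formula above projects the mass-weighted displacement directly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import AMU_TO_ME, BOHR_TO_ANGSTROM, CM1_TO_HARTREE, EV_PER_CM1, HBAR_EVFS

__all__ = ["HarmonicReference", "to_normal_coordinates", "from_normal_coordinates"]

_ORTHO_TOL = 1e-8


@dataclass
class HarmonicReference:
    """Ground-state harmonic oscillator defining the nuclear coordinates.

    Parameters
    ----------
    r_ref : (n_atoms, 3) float array
        Reference geometry in Angstrom.
    masses : (n_atoms,) float array
        Atomic masses in amu.
    omega : (F,) float array
        Harmonic frequencies in cm^-1, all positive.
    K : (3*n_atoms, F) float array
        Cartesian-to-normal-mode matrix with orthonormal columns
        (mass-weighted convention).
    """

    r_ref: np.ndarray
    masses: np.ndarray
    omega: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.r_ref = np.asarray(self.r_ref, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        self.omega = np.asarray(self.omega, dtype=float).ravel()
        self.K = np.asarray(self.K, dtype=float)
        n = self.r_ref.shape[0]
        if self.masses.shape != (n,):
            raise ValueError(f"masses has shape {self.masses.shape}, expected ({n},)")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if np.any(self.omega <= 0):
            raise ValueError("all frequencies must be positive")
        f = self.omega.size
        if f > 3 * n:
            raise ValueError(f"mode count {f} exceeds 3*n_atoms = {3 * n}")
        if self.K.shape != (3 * n, f):
            raise ValueError(f"K has shape {self.K.shape}, expected ({3 * n}, {f})")
        gram = self.K.T @ self.K
        if not np.allclose(gram, np.eye(f), atol=_ORTHO_TOL):
            dev = np.abs(gram - np.eye(f)).max()
            raise ValueError(
                f"mass-weighted columns of K not orthonormal (max deviation {dev:.2e})"
            )

    @property
    def n_atoms(self) -> int:
        return self.r_ref.shape[0]

    @property
    def n_modes(self) -> int:
        return self.omega.size

    @property
    def mode_vectors(self) -> np.ndarray:
        """Orthonormal mass-weighted mode vectors, shape (3*n_atoms, F)."""
        return self.K

    @property
    def omega_ev(self) -> np.ndarray:
        """Vibrational quanta hbar*omega in eV."""
        return self.omega * EV_PER_CM1

    @property
    def omega_fs(self) -> np.ndarray:
        """Angular frequencies in rad/fs."""
        return self.omega_ev / HBAR_EVFS

    def ground_state_energy(self) -> float:
        """Zero-point energy sum_i hbar*omega_i/2 in eV."""
        return 0.5 * float(self.omega_ev.sum())


def to_normal_coordinates(reference: HarmonicReference, r: np.ndarray) -> np.ndarray:
    """Transform a Cartesian geometry (Angstrom) to dimensionless mode coordinates."""
    r = np.asarray(r, dtype=float).reshape(-1, 3)
    if r.shape != reference.r_ref.shape:
        raise ValueError(
            f"geometry has shape {r.shape}, expected {reference.r_ref.shape}"
        )
    dr_bohr = (r - reference.r_ref).ravel() / BOHR_TO_ANGSTROM
    m_au = np.repeat(reference.masses, 3) * AMU_TO_ME
    # mass-weighted displacement in a.u., projected on the orthonormal mode vectors
    x = reference.K.T @ (np.sqrt(m_au) * dr_bohr)
    omega_au = reference.omega * CM1_TO_HARTREE
    return np.sqrt(omega_au) * x


def from_normal_coordinates(reference: HarmonicReference, Q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_normal_coordinates` on the mode subspace.

    Returns the Cartesian geometry (Angstrom) displaced from the reference by
    the mode-subspace component encoded in ``Q``.
    """
    Q = np.asarray(Q, dtype=float).ravel()
    if Q.shape != (reference.n_modes,):
        raise ValueError(f"Q has length {Q.size}, expected {reference.n_modes}")
    omega_au = reference.omega * CM1_TO_HARTREE
    x = reference.K @ (Q / np.sqrt(omega_au))
    m_au = np.repeat(reference.masses, 3) * AMU_TO_ME
    dr_bohr = x / np.sqrt(m_au)
    return reference.r_ref + (dr_bohr * BOHR_TO_ANGSTROM).reshape(-1, 3)
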