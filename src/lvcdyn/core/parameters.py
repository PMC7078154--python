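"""Linear vibronic coupling parameter set and model container."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .basis import ElectronicBasis
from .reference import HarmonicReference

__all__ = ["LVCParameters", "LVCModel"]

_SOC_HERM_TOL = 1e-10


@dataclass
class LVCParameters:
    """Diabatic LVC model parameters.

    All energies in eV; ``kappa``/``lam`` are linear coefficients per unit
    dimensionless mode coordinate; dipole matrices in atomic units.

    Attributes
    ----------
    basis : ElectronicBasis
    epsilon : (n_sf,) vertical shifts of the spin-free diabatic states.
    kappa : (n_sf, F) intrastate gradients.
    lam : (n_sf, n_sf, F) interstate couplings, symmetric in the two state
        indices and zero between states of different multiplicity.
    soc : (D, D) complex Hermitian spin-orbit matrix over the spin-expanded
        basis.
    dipoles : (3, n_sf, n_sf) real symmetric dipole matrices (x, y, z).
    """

    basis: ElectronicBasis
    epsilon: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    soc: np.ndarray
    dipoles: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float).ravel()
        self.kappa = np.atleast_2d(np.asarray(self.kappa, dtype=float))
        self.lam = np.asarray(self.lam, dtype=float)
        self.soc = np.asarray(self.soc, dtype=complex)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.basis.n_spinfree

    @property
    def n_modes(self) -> int:
        return self.kappa.shape[1]

    def validate(self) -> None:
        n = self.basis.n_spinfree
        d = self.basis.dim
        f = self.kappa.shape[1] if self.kappa.ndim == 2 else 0
        if self.epsilon.shape != (n,):
            raise ValueError(f"epsilon has shape {self.epsilon.shape}, expected ({n},)")
        if self.kappa.shape != (n, f):
            raise ValueError(f"kappa has shape {self.kappa.shape}, expected ({n}, {f})")
        if self.lam.shape != (n, n, f):
            raise ValueError(
                f"lambda has shape {self.lam.shape}, expected ({n}, {n}, {f})"
            )
        if not np.allclose(self.lam, self.lam.transpose(1, 0, 2)):
            raise ValueError("lambda must be symmetric in the state indices")
        mult = self.basis.multiplicities
        cross = mult[:, None] != mult[None, :]
        if np.any(np.abs(self.lam[cross, :]) > 0):
            raise ValueError("lambda couples states of different multiplicity")
        if self.soc.shape != (d, d):
            raise ValueError(f"soc has shape {self.soc.shape}, expected ({d}, {d})")
        if np.abs(self.soc - self.soc.conj().T).max() > _SOC_HERM_TOL:
            raise ValueError("soc matrix is not Hermitian")
        if self.dipoles.shape != (3, n, n):
            raise ValueError(
                f"dipoles have shape {self.dipoles.shape}, expected (3, {n}, {n})"
            )
        if not np.allclose(self.dipoles, self.dipoles.transpose(0, 2, 1)):
            raise ValueError("dipole matrices must be symmetric")

    @classmethod
    def zeros(cls, basis: ElectronicBasis, n_modes: int) -> "LVCParameters":
        n, d = basis.n_spinfree, basis.dim
        return cls(
            basis=basis,
            epsilon=np.zeros(n),
            kappa=np.zeros((n, n_modes)),
            lam=np.zeros((n, n, n_modes)),
            soc=np.zeros((d, d), dtype=complex),
            dipoles=np.zeros((3, n, n)),
        )

    def copy(self) -> "LVCParameters":
        return LVCParameters(
            basis=ElectronicBasis(
                self.basis.n_singlets, self.basis.n_triplets, list(self.basis.labels)
            ),
            epsilon=self.epsilon.copy(),
            kappa=self.kappa.copy(),
            lam=self.lam.copy(),
            soc=self.soc.copy(),
            dipoles=self.dipoles.copy(),
        )

    def drop_ground_state_soc(self) -> None:
        """Zero the SOC rows/columns of the lowest singlet state, in place."""
        self.soc[0, :] = 0.0
        self.soc[:, 0] = 0.0


@dataclass
class LVCModel:
    """Bundle of a harmonic reference and an LVC parameter set."""

    reference: HarmonicReference
    params: LVCParameters
    ct_table: Optional[object] = field(default=None)

    def __post_init__(self) -> None:
        if self.params.n_modes != self.reference.n_modes:
            raise ValueError(
                f"parameter mode count {self.params.n_modes} != "
                f"reference mode count {self.reference.n_modes}"
            )

    @property
    def basis(self) -> ElectronicBasis:
        return self.params.basis
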