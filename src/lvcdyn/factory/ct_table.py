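"""Fragment charge-transfer number tables.

``omega[n, m, a, b]`` is the weight of the hole-on-fragment-``a`` /
electron-on-fragment-``b`` component of the (diabatic) state pair
``(n, m)``; diagonal entries (``n == m``) are ordinary charge-transfer
numbers, off-diagonal entries the transition charge-transfer numbers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core.basis import ElectronicBasis

__all__ = ["CTNumberTable", "DEFAULT_FRAGMENTS"]

DEFAULT_FRAGMENTS = ("Trp", "His", "Dmp", "Re(CO)3")


@dataclass
class CTNumberTable:
    fragments: tuple
    omega: np.ndarray  # (n_sf, n_sf, n_frag, n_frag)
    ground_state_index: int = 0

    def __post_init__(self) -> None:
        self.fragments = tuple(self.fragments)
        self.omega = np.asarray(self.omega, dtype=float)
        nf = len(self.fragments)
        if self.omega.ndim != 4 or self.omega.shape[2:] != (nf, nf):
            raise ValueError(
                f"omega has shape {self.omega.shape}, expected (n, n, {nf}, {nf})"
            )
        if self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be square in the state indices")
        if not np.allclose(self.omega, self.omega.transpose(1, 0, 2, 3)):
            raise ValueError("omega must be symmetric in the state pair")
        diag_sums = np.einsum("nnab->n", self.omega)
        for n, s in enumerate(diag_sums):
            if n == self.ground_state_index:
                continue  # the ground state carries no excitation
            if not (0.0 < s <= 1.0 + 1e-9):
                raise ValueError(
                    f"diagonal CT weights of state {n} sum to {s:.4f}, "
                    "expected a value in (0, 1]"
                )

    @property
    def n_states(self) -> int:
        return self.omega.shape[0]

    def diagonal(self, n: int) -> np.ndarray:
        """CT-number matrix of state ``n``, shape (n_frag, n_frag)."""
        return self.omega[n, n]

    def select_states(self, keep: np.ndarray) -> "CTNumberTable":
        keep = np.asarray(keep, dtype=bool)
        idx = np.where(keep)[0]
        gsi = self.ground_state_index
        new_gsi = int(np.searchsorted(idx, gsi)) if keep[gsi] else 0
        return CTNumberTable(
            fragments=self.fragments,
            omega=self.omega[np.ix_(idx, idx)].copy(),
            ground_state_index=new_gsi,
        )

    def of_coefficients(self, c_diab: np.ndarray, basis: ElectronicBasis) -> np.ndarray:
        """CT numbers of a wave function given by spin-expanded diabatic
        coefficients: Omega_AB = sum_nm c_n* c_m Omega_AB^(n,m).

        Cross terms between different multiplicities or M_S components vanish
        by spin orthogonality; the imaginary residue (below 1e-8 for valid
        tables) is discarded.
        """
        c_diab = np.asarray(c_diab)
        if c_diab.shape[-1] != basis.dim:
            raise ValueError("coefficient length does not match basis dimension")
        compat = basis.spin_compatible()
        rho = np.einsum("...i,...j->...ij", c_diab.conj(), c_diab) * compat
        # aggregate the spin-expanded density onto spin-free state pairs
        proj = np.zeros((basis.n_spinfree, basis.dim))
        proj[basis.spinfree_index, np.arange(basis.dim)] = 1.0
        rho_sf = np.einsum("nd,...de,me->...nm", proj, rho, proj)
        out = np.einsum("...nm,nmab->...ab", rho_sf, self.omega)
        return out.real
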