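"""Electronic state bookkeeping: spin-free states and spin expansion.

Spin-free states are ordered singlets first, then triplets.  The
spin-expanded basis (dimension ``D = n_singlets + 3*n_triplets``) replicates
each triplet for M_S in {-1, 0, +1}, grouped by M_S block:

    S0 .. S_{ns-1},  T(-1) block,  T(0) block,  T(+1) block.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectronicBasis"]


@dataclass
class ElectronicBasis:
    n_singlets: int
    n_triplets: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_singlets < 0 or self.n_triplets < 0:
            raise ValueError("state counts must be non-negative")
        if self.n_singlets + self.n_triplets == 0:
            raise ValueError("basis must contain at least one state")
        if not self.labels:
            self.labels = [f"S{i}" for i in range(self.n_singlets)] + [
                f"T{i + 1}" for i in range(self.n_triplets)
            ]
        if len(self.labels) != self.n_spinfree:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n_spinfree} spin-free states"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")

    @property
    def n_spinfree(self) -> int:
        return self.n_singlets + self.n_triplets

    @property
    def dim(self) -> int:
        """Spin-expanded dimension D."""
        return self.n_singlets + 3 * self.n_triplets

    @property
    def multiplicities(self) -> np.ndarray:
        """Multiplicity (1 or 3) per spin-free state."""
        return np.array([1] * self.n_singlets + [3] * self.n_triplets)

    @property
    def spinfree_index(self) -> np.ndarray:
        """Spin-free index of each spin-expanded state."""
        s = np.arange(self.n_singlets)
        t = self.n_singlets + np.arange(self.n_triplets)
        return np.concatenate([s, t, t, t])

    @property
    def ms(self) -> np.ndarray:
        """M_S value of each spin-expanded state (0 for singlets)."""
        return np.concatenate(
            [
                np.zeros(self.n_singlets, dtype=int),
                -np.ones(self.n_triplets, dtype=int),
                np.zeros(self.n_triplets, dtype=int),
                np.ones(self.n_triplets, dtype=int),
            ]
        )

    @property
    def is_singlet_expanded(self) -> np.ndarray:
        return np.arange(self.dim) < self.n_singlets

    def spin_compatible(self) -> np.ndarray:
        """(D, D) bool mask: pairs with equal spin quantum numbers.

        True for singlet-singlet pairs and triplet-triplet pairs within the
        same M_S block; spin-free operators only connect such pairs.
        """
        sing = self.is_singlet_expanded
        ms = self.ms
        both_singlet = sing[:, None] & sing[None, :]
        both_triplet = (~sing[:, None]) & (~sing[None, :])
        same_ms = ms[:, None] == ms[None, :]
        return both_singlet | (both_triplet & same_ms)

    def expand_matrix(self, a: np.ndarray) -> np.ndarray:
        """Expand a spin-free (n_sf, n_sf) operator to the (D, D) spin basis.

        Entries connecting incompatible spin components are zero.
        """
        a = np.asarray(a)
        n = self.n_spinfree
        if a.shape[-2:] != (n, n):
            raise ValueError(f"operator has shape {a.shape}, expected (..., {n}, {n})")
        idx = self.spinfree_index
        out = a[..., idx[:, None], idx[None, :]] * self.spin_compatible()
        return out

    def expand_vector(self, v: np.ndarray) -> np.ndarray:
        """Replicate a per-spin-free-state vector over the spin expansion."""
        v = np.asarray(v)
        return v[..., self.spinfree_index]

    def select(self, keep: np.ndarray) -> "ElectronicBasis":
        """Sub-basis retaining the spin-free states flagged in ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        mult = self.multiplicities
        ns = int(np.sum(keep & (mult == 1)))
        nt = int(np.sum(keep & (mult == 3)))
        labels = [l for l, k in zip(self.labels, keep) if k]
        return ElectronicBasis(ns, nt, labels)
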