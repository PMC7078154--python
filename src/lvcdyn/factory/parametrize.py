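"""Parametrization of kappa/lambda from external oracles.

``parametrize_kappa`` projects Cartesian excited-state gradients onto the
normal modes; ``parametrize_lambda`` estimates interstate couplings by
finite-difference diabatization from wave-function overlaps at displaced
geometries (overlap derivative times energy gap).
"""
from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence

import numpy as np

from ..constants import AMU_TO_ME, BOHR_TO_ANGSTROM, CM1_TO_HARTREE
from ..core.reference import HarmonicReference

__all__ = ["parametrize_kappa", "parametrize_lambda"]


def parametrize_kappa(
    gradient_oracle: Callable[[int], np.ndarray],
    reference: HarmonicReference,
    n_states: int,
    ground_state: int = 0,
) -> np.ndarray:
    """Recover kappa from Cartesian gradients at the reference geometry.

    Parameters
    ----------
    gradient_oracle : callable
        ``gradient_oracle(n) -> (n_atoms, 3)`` Cartesian gradient of state
        ``n`` at the reference geometry, in eV/Angstrom.
    n_states : int
        Number of spin-free states the oracle serves.
    ground_state : int
        Index whose mode-space gradient is subtracted from every state
        (kappa is defined relative to the shared ground-state oscillator).

    Returns
    -------
    (n_states, F) array of kappa values (eV per unit Q); the ground-state row
    is zero by construction.
    """
    f = reference.n_modes
    kappa = np.zeros((n_states, f))
    for n in range(n_states):
        try:
            g_cart = np.asarray(gradient_oracle(n), dtype=float).reshape(-1, 3)
        except Exception as exc:
            raise RuntimeError(f"gradient oracle failed for state {n}") from exc
        if g_cart.shape != reference.r_ref.shape:
            raise ValueError(
                f"oracle gradient for state {n} has shape {g_cart.shape}, "
                f"expected {reference.r_ref.shape}"
            )
        kappa[n] = _project_gradient(reference, g_cart)
    kappa -= kappa[ground_state][None, :]
    return kappa


def _project_gradient(reference: HarmonicReference, g_cart: np.ndarray) -> np.ndarray:
    """Project an eV/Angstrom Cartesian gradient to eV-per-Q mode space.

    dE/dQ_i = sum_alpha (dr_alpha/dQ_i) dE/dr_alpha with
    dr/dQ_i = K~_alpha,i / (sqrt(M_alpha) sqrt(omega_i)) in a.u.
    """
    g_bohr = g_cart.ravel() * BOHR_TO_ANGSTROM  # eV/bohr
    m_amu = np.repeat(reference.masses, 3)
    omega_au = reference.omega * CM1_TO_HARTREE
    dr_dq = reference.mode_vectors / np.sqrt(m_amu * AMU_TO_ME)[:, None] / np.sqrt(
        omega_au
    )[None, :]
    return dr_dq.T @ g_bohr


def parametrize_lambda(
    overlap_oracle: Callable[[np.ndarray, np.ndarray], np.ndarray],
    reference: HarmonicReference,
    energies: np.ndarray,
    multiplicities: Optional[Sequence[int]] = None,
    step: float = 0.05,
    two_sided: bool = True,
) -> np.ndarray:
    """Estimate lambda by finite-difference diabatization.

    For each mode ``i`` the oracle supplies the state-overlap matrix
    ``S(Q_a, Q_b)_{nm} = <psi_n(Q_a) | psi_m(Q_b)>`` between the reference
    and a displaced geometry.  To first order the off-diagonal overlap is
    ``lambda_i^(n,m) * dQ / (eps_m - eps_n)``, so

        lambda_i^(n,m) = (eps_m - eps_n) (S+_nm - S-_nm) / (2 step)

    (one-sided variant divides by ``step``).  The result is symmetrized over
    the state pair and zeroed between different multiplicities.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    energies = np.asarray(energies, dtype=float).ravel()
    n = energies.size
    f = reference.n_modes
    lam = np.zeros((n, n, f))
    q0 = np.zeros(f)
    gaps = energies[None, :] - energies[:, None]
    for i in range(f):
        dq = np.zeros(f)
        dq[i] = step
        s_plus = _checked_overlap(overlap_oracle, q0, dq, n, i)
        if two_sided:
            s_minus = _checked_overlap(overlap_oracle, q0, -dq, n, i)
            deriv = (s_plus - s_minus) / (2.0 * step)
        else:
            deriv = (s_plus - np.eye(n)) / step
        a = gaps * deriv
        lam[:, :, i] = 0.5 * (a + a.T)
        lam[np.arange(n), np.arange(n), i] = 0.0
    if multiplicities is not None:
        mult = np.asarray(multiplicities)
        lam[mult[:, None] != mult[None, :], :] = 0.0
    return lam


def _checked_overlap(oracle, q_a, q_b, n, mode):
    s = np.asarray(oracle(q_a, q_b), dtype=float)
    if s.shape != (n, n):
        raise ValueError(f"overlap matrix has shape {s.shape}, expected ({n}, {n})")
    dev = np.abs(s.T @ s - np.eye(n)).max()
    if dev > 0.1:
        warnings.warn(
            f"overlap matrix for mode {mode} deviates from orthogonality "
            f"by {dev:.3f}",
            stacklevel=3,
        )
    return s
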