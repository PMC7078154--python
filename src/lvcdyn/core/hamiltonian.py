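"""Evaluation of the LVC Hamiltonian and representation transforms.

Three electronic representations are used:

* *diabatic*: the basis in which the LVC parameters are defined,
* *MCH*: eigenbasis of the spin-free potential matrix ``V`` (per
  multiplicity block),
* *diagonal*: eigenbasis of the full spin-expanded Hamiltonian including
  spin-orbit coupling.

Conventions: coefficients transform as ``c_mch = U_diag @ c_diag`` and
``c_diab = U_expanded @ c_mch``; operators as ``A_mch = U^dag A_diab U``.
Eigenvector phases are fixed by non-negative (real) diagonal of the overlap
with a previous-step transform, which defaults to the identity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..constants import AMU_TO_ME, BOHR_TO_ANGSTROM, CM1_TO_HARTREE
from .basis import ElectronicBasis
from .parameters import LVCModel
from .reference import HarmonicReference

__all__ = [
    "PotentialEvaluation",
    "MCHResult",
    "evaluate_potential",
    "adiabatize",
    "build_diagonal",
    "transform_properties",
    "electronic_structure",
    "mch_gradients",
    "mch_gradient_and_nac",
    "mode_gradient_to_cartesian",
    "time_overlap",
]

#: energy-gap floor (eV) below which nonadiabatic couplings are capped
NAC_DEGENERACY_FLOOR = 1e-8


@dataclass
class PotentialEvaluation:
    """Spin-free diabatic potential matrix and its mode derivatives at Q."""

    Q: np.ndarray
    V0: float
    V: np.ndarray  # (n_sf, n_sf), eV
    dV: np.ndarray  # (F, n_sf, n_sf), eV per unit Q


@dataclass
class MCHResult:
    """MCH eigendecomposition plus the SOC-including diagonal representation."""

    E_mch: np.ndarray  # (n_sf,) eV, ascending within each multiplicity block
    U: np.ndarray  # (n_sf, n_sf) real block-orthogonal diabatic->MCH transform
    H_diag_inputs: np.ndarray  # (D, D) complex spin-expanded MCH Hamiltonian
    E_diag: np.ndarray  # (D,) eV ascending
    U_diag: np.ndarray  # (D, D) complex unitary MCH->diagonal transform


def evaluate_potential(model: LVCModel, Q: np.ndarray) -> PotentialEvaluation:
    """Evaluate ``V = V0*1 + W`` and its analytic mode derivatives."""
    Q = np.asarray(Q, dtype=float).ravel()
    ref = model.reference
    p = model.params
    if Q.shape != (ref.n_modes,):
        raise ValueError(f"Q has length {Q.size}, expected {ref.n_modes}")
    hw = ref.omega_ev
    v0 = 0.5 * float(np.dot(hw, Q * Q))
    n = p.n_states
    v = np.tensordot(p.lam, Q, axes=([2], [0]))
    np.fill_diagonal(v, p.epsilon + p.kappa @ Q + v0)
    dv = p.lam.transpose(2, 0, 1).copy()
    idx = np.arange(n)
    dv[:, idx, idx] += p.kappa.T
    dv[:, idx, idx] += (hw * Q)[:, None]
    return PotentialEvaluation(Q=Q, V0=v0, V=v, dV=dv)


def _phase_fix_real(u: np.ndarray, prev: Optional[np.ndarray]) -> np.ndarray:
    """Flip column signs so diag(prev^T u) >= 0 (prev defaults to identity)."""
    ov = u if prev is None else prev.T @ u
    signs = np.where(np.diag(ov) < 0.0, -1.0, 1.0)
    return u * signs[None, :]


def _order_degenerate(e: np.ndarray, u: np.ndarray, tol: float = 1e-12) -> Tuple[np.ndarray, np.ndarray]:
    """Within degenerate groups, order columns by dominant-component index."""
    order = np.arange(e.size)
    i = 0
    while i < e.size:
        j = i + 1
        while j < e.size and e[j] - e[i] <= tol:
            j += 1
        if j - i > 1:
            dom = np.argmax(np.abs(u[:, i:j]), axis=0)
            order[i:j] = order[i:j][np.argsort(dom, kind="stable")]
        i = j
    return e[order], u[:, order]


def adiabatize(
    evaluation: PotentialEvaluation,
    basis: ElectronicBasis,
    prev_U: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Diagonalize the spin-free potential per multiplicity block.

    Returns ``(E_mch, U)`` with ``V = U diag(E) U^T``; eigenvalues ascend
    within each block and eigenvector phases follow ``prev_U`` (or the
    identity).
    """
    v = evaluation.V
    n = v.shape[0]
    e = np.empty(n)
    u = np.zeros((n, n))
    mult = basis.multiplicities
    for m in np.unique(mult):
        sel = np.where(mult == m)[0]
        w, vec = np.linalg.eigh(v[np.ix_(sel, sel)])
        w, vec = _order_degenerate(w, vec)
        e[sel] = w
        u[np.ix_(sel, sel)] = vec
    u = _phase_fix_real(u, prev_U)
    return e, u


def transform_properties(
    U: np.ndarray,
    basis: ElectronicBasis,
    soc: Optional[np.ndarray] = None,
    dipoles: Optional[np.ndarray] = None,
) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Transform diabatic SOC / dipole matrices into the MCH basis.

    SOC (spin-expanded) transforms with the spin-expanded replica of ``U``;
    dipoles (spin-free) transform with ``U`` directly.  Hermiticity of the
    inputs is validated.
    """
    soc_mch = None
    dip_mch = None
    if soc is not None:
        soc = np.asarray(soc, dtype=complex)
        if np.abs(soc - soc.conj().T).max() > 1e-10:
            raise ValueError("SOC matrix must be Hermitian")
        u_exp = basis.expand_matrix(U)
        soc_mch = u_exp.conj().T @ soc @ u_exp
    if dipoles is not None:
        dipoles = np.asarray(dipoles, dtype=float)
        if not np.allclose(dipoles, np.swapaxes(dipoles, -1, -2)):
            raise ValueError("dipole matrices must be symmetric")
        dip_mch = np.einsum("in,aij,jm->anm", U, dipoles, U)
    return soc_mch, dip_mch


def _phase_fix_complex(u: np.ndarray, prev: Optional[np.ndarray]) -> np.ndarray:
    """Rotate column phases so diag(prev^dag u) is real non-negative."""
    ov = np.diag(u) if prev is None else np.einsum("ij,ij->j", prev.conj(), u)
    mag = np.abs(ov)
    phases = np.where(mag > 1e-14, ov / np.where(mag > 1e-14, mag, 1.0), 1.0)
    return u * phases.conj()[None, :]


def build_diagonal(
    H: np.ndarray, prev_U: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Diagonalize the full (SOC-including) Hermitian Hamiltonian.

    Returns ascending eigenvalues and the unitary ``U_diag`` with the same
    phase convention as :func:`adiabatize`.
    """
    H = np.asarray(H, dtype=complex)
    e, u = np.linalg.eigh(H)
    u = _phase_fix_complex(u, prev_U)
    return e, u


def electronic_structure(
    model: LVCModel,
    Q: np.ndarray,
    prev_U: Optional[np.ndarray] = None,
    prev_U_diag: Optional[np.ndarray] = None,
) -> Tuple[PotentialEvaluation, MCHResult]:
    """Full pipeline at one geometry: potential, MCH, and diagonal bases."""
    ev = evaluate_potential(model, Q)
    basis = model.basis
    e_mch, u = adiabatize(ev, basis, prev_U=prev_U)
    soc_mch, _ = transform_properties(u, basis, soc=model.params.soc)
    h_total = np.diag(basis.expand_vector(e_mch).astype(complex)) + soc_mch
    e_diag, u_diag = build_diagonal(h_total, prev_U=prev_U_diag)
    return ev, MCHResult(
        E_mch=e_mch, U=u, H_diag_inputs=h_total, E_diag=e_diag, U_diag=u_diag
    )


def mch_gradients(evaluation: PotentialEvaluation, U: np.ndarray) -> np.ndarray:
    """Mode-space gradients of all MCH states, shape (n_sf, F), eV per Q.

    Hellmann-Feynman: grad_i^(n) = (U^T dV_i U)_nn.
    """
    # diag(U^T dV_i U) without forming the full transformed matrices
    b = np.tensordot(evaluation.dV, U, axes=([2], [0]))  # (F, n, n)
    return np.einsum("jn,fjn->nf", U, b)


def mch_gradient_and_nac(
    evaluation: PotentialEvaluation,
    E_mch: np.ndarray,
    U: np.ndarray,
    n: int,
    m: Optional[int] = None,
    reference: Optional[HarmonicReference] = None,
) -> dict:
    """Gradient of MCH state ``n`` and (optionally) the NAC vector to ``m``.

    Returns a dict with mode-space quantities (``gradient``, ``nac``) and,
    when a reference is given, their Cartesian back-transforms in eV/Angstrom
    (``gradient_cart``, ``nac_cart``).  Near-degenerate NACs (gap below
    :data:`NAC_DEGENERACY_FLOOR` eV) are capped and flagged.
    """
    grads = mch_gradients(evaluation, U)
    out: dict = {"gradient": grads[n]}
    if reference is not None:
        out["gradient_cart"] = mode_gradient_to_cartesian(reference, grads[n])
    if m is not None:
        if m == n:
            raise ValueError("NAC requires two distinct states")
        coup = np.einsum("j,fjk,k->f", U[:, n], evaluation.dV, U[:, m])
        gap = E_mch[m] - E_mch[n]
        unreliable = abs(gap) < NAC_DEGENERACY_FLOOR
        denom = gap if not unreliable else np.sign(gap or 1.0) * NAC_DEGENERACY_FLOOR
        nac = coup / denom
        out["nac"] = nac
        out["nac_unreliable"] = bool(unreliable)
        if reference is not None:
            out["nac_cart"] = mode_gradient_to_cartesian(reference, nac)
    return out


def mode_gradient_to_cartesian(
    reference: HarmonicReference, g_mode: np.ndarray
) -> np.ndarray:
    """Back-transform a mode-space derivative (eV per Q) to eV/Angstrom.

    dE/dr_alpha = sum_i (dQ_i/dr_alpha) g_i with
    dQ_i/dr_alpha = sqrt(omega_i) * sqrt(M_alpha) * K~_alpha,i in a.u.
    """
    g_mode = np.asarray(g_mode, dtype=float).ravel()
    omega_au = reference.omega * CM1_TO_HARTREE
    m_amu = np.repeat(reference.masses, 3)
    # dQ/dr in 1/bohr
    dq_dr = (
        np.sqrt(omega_au)[None, :]
        * reference.mode_vectors
        * np.sqrt(m_amu * AMU_TO_ME)[:, None]
    )
    g_cart_bohr = dq_dr @ g_mode
    return (g_cart_bohr / BOHR_TO_ANGSTROM).reshape(-1, 3)


def time_overlap(U_prev: np.ndarray, U_curr: np.ndarray) -> np.ndarray:
    """Lowdin-orthonormalized wave-function overlap between two steps.

    ``S = U_prev^dag U_curr`` orthonormalized via SVD; columns are
    phase-aligned so the diagonal is real non-negative.
    """
    U_prev = np.asarray(U_prev)
    U_curr = np.asarray(U_curr)
    if U_prev.shape != U_curr.shape:
        raise ValueError("overlap requires transforms of equal shape")
    s = U_prev.conj().T @ U_curr
    w, sv, vh = np.linalg.svd(s)
    if sv.min() < 1e-10:
        raise np.linalg.LinAlgError(
            f"rank-deficient time overlap (min singular value {sv.min():.2e})"
        )
    s_orth = w @ vh
    return _phase_fix_complex(s_orth, None) if np.iscomplexobj(s_orth) else _phase_fix_real(s_orth, None)
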