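"""Single-trajectory surface hopping in the diagonal representation.

Nuclear motion: velocity Verlet in dimensionless mode coordinates on the
active diagonal state's gradient (diagonal approximation: MCH gradients
weighted by |U_diag|^2).  Electronic motion: local diabatization - the
coefficients are advanced through each nuclear step in the frozen MCH frame
of the step start, using Lowdin-orthonormalized time overlaps and a linearly
interpolated Hamiltonian split into short substeps.

Hop probabilities follow the fewest-switches idea expressed through the
propagated populations: the probability of leaving the active state equals
the relative decrease of its population over the nuclear step, distributed
among the states that gained population proportionally to their gain.  On an
accepted hop the full velocity vector is rescaled to conserve total energy;
hops without sufficient kinetic energy are frustrated (velocities kept, or
reversed if configured).  An energy-based decoherence correction damps
non-active amplitudes each nuclear step.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ..constants import HARTREE_TO_EV, HBAR_EVFS
from ..core.hamiltonian import electronic_structure, mch_gradients, time_overlap
from ..core.parameters import LVCModel
from .settings import PropagationSettings

__all__ = ["Trajectory", "propagate_trajectory", "hop_and_rescale", "apply_decoherence", "hop_probabilities"]


@dataclass
class Trajectory:
    """Recorded time series of one surface-hopping trajectory."""

    times: np.ndarray  # (T,) fs
    Q: np.ndarray  # (T, F)
    Qdot: np.ndarray  # (T, F) 1/fs
    c_diag: np.ndarray  # (T, D) complex
    active: np.ndarray  # (T,) diagonal-state index
    E_mch: np.ndarray  # (T, n_sf) eV
    E_diag: np.ndarray  # (T, D) eV
    U: np.ndarray  # (T, n_sf, n_sf)
    U_diag: np.ndarray  # (T, D, D) complex
    E_kin: np.ndarray  # (T,) eV
    E_total: np.ndarray  # (T,) eV
    hops: list = field(default_factory=list)  # (step, from, to, kind)
    valid: bool = True
    invalid_reason: str = ""
    initial_mch_state: int = -1
    seed: Optional[int] = None


def hop_probabilities(
    c_old: np.ndarray, c_new: np.ndarray, active: int
) -> np.ndarray:
    """Fewest-switches hop probabilities from propagated populations.

    P_leave = max(0, 1 - |c_a(t+dt)|^2 / |c_a(t)|^2), distributed over the
    population-gaining states proportionally to their gain.
    """
    p_old = np.abs(c_old) ** 2
    p_new = np.abs(c_new) ** 2
    probs = np.zeros(p_old.size)
    if p_old[active] <= 0:
        return probs
    p_leave = max(0.0, 1.0 - p_new[active] / p_old[active])
    if p_leave == 0.0:
        return probs
    gains = np.clip(p_new - p_old, 0.0, None)
    gains[active] = 0.0
    total = gains.sum()
    if total <= 0:
        return probs
    probs = p_leave * gains / total
    return probs


def hop_and_rescale(
    active: int,
    target: int,
    E_diag: np.ndarray,
    Qdot: np.ndarray,
    e_kin: float,
    frustrated_policy: str = "keep",
) -> Tuple[int, np.ndarray, str]:
    """Attempt a hop; rescale the full velocity vector to conserve energy.

    Scale factor sqrt(1 + (E_active - E_target)/E_kin).  A negative radicand
    frustrates the hop (active state kept; velocities kept or reversed per
    policy).  Returns (new_active, new_velocities, kind) with kind in
    {"hop", "frustrated"}.
    """
    gap = float(E_diag[active] - E_diag[target])  # >0 for a downhill hop
    if gap == 0.0:
        return target, Qdot, "hop"
    if e_kin <= 0.0:
        if gap > 0.0:
            # no kinetic energy to rescale but the hop is downhill: accept
            return target, Qdot, "hop"
        return active, Qdot, "frustrated"
    radicand = 1.0 + gap / e_kin
    if radicand < 0.0:
        if frustrated_policy == "reverse":
            return active, -Qdot, "frustrated"
        return active, Qdot, "frustrated"
    return target, Qdot * np.sqrt(radicand), "hop"


def apply_decoherence(
    c_diag: np.ndarray,
    active: int,
    E_diag: np.ndarray,
    e_kin: float,
    c_const_hartree: float,
    dt: float,
) -> np.ndarray:
    """Energy-based decoherence: damp non-active amplitudes with
    tau_j = (hbar/|E_j - E_a|) (1 + C/E_kin); the active amplitude is
    rescaled so the norm is restored.  Skipped when E_kin <= 0."""
    if e_kin <= 0.0:
        return c_diag
    c = c_diag.copy()
    gaps = np.abs(E_diag - E_diag[active])
    c_ev = c_const_hartree * HARTREE_TO_EV
    with np.errstate(divide="ignore"):
        rates = gaps / (HBAR_EVFS * (1.0 + c_ev / e_kin))
    factors = np.exp(-dt * rates)
    factors[active] = 1.0
    norm_before = float(np.sum(np.abs(c) ** 2))
    c *= factors
    others = float(np.sum(np.abs(np.delete(c, active)) ** 2))
    target_active = norm_before - others
    pa = float(np.abs(c[active]) ** 2)
    if pa > 0 and target_active >= 0:
        c[active] *= np.sqrt(target_active / pa)
    return c


def _ld_step_apply(
    h_old: np.ndarray,
    h_new: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
    n_sub: int,
    dt_el: float,
) -> np.ndarray:
    """Advance coefficients over one nuclear step by local diabatization.

    The Hamiltonian is linearly interpolated in the frozen frame of the step
    start (``H(tau) = H_old + tau * B`` with ``B = S H_new S^dag - H_old``)
    and each substep applies the Strang-split unitary
    ``exp(-i H_old dt/2) exp(-i tau_k B dt) exp(-i H_old dt/2)`` - the same
    order of accuracy as midpoint exponentials of the interpolated
    Hamiltonian, at two eigendecompositions per nuclear step.
    """
    h_new_frame = s @ h_new @ s.conj().T
    b = h_new_frame - h_old
    wa, va = np.linalg.eigh(h_old)
    wb, vb = np.linalg.eigh(b)
    half_a = np.exp(-0.5j * wa * dt_el / HBAR_EVFS)
    full_a = half_a * half_a
    taus = (np.arange(n_sub) + 0.5) / n_sub

    def apply_diag(vecs, phases, x):
        return vecs @ (phases * (vecs.conj().T @ x))

    out = apply_diag(va, half_a, c)
    for k in range(n_sub):
        phases_b = np.exp(-1j * wb * taus[k] * dt_el / HBAR_EVFS)
        out = apply_diag(vb, phases_b, out)
        out = apply_diag(va, full_a if k < n_sub - 1 else half_a, out)
    return out


def _active_gradient(
    grads_sf: np.ndarray, basis, u_diag: np.ndarray, active: int
) -> np.ndarray:
    """Mode-space gradient of a diagonal state: |U_diag|^2-weighted MCH
    gradients (diagonal approximation)."""
    weights = np.abs(u_diag[:, active]) ** 2  # (D,)
    g_exp = grads_sf[basis.spinfree_index, :]  # (D, F)
    return weights @ g_exp


def propagate_trajectory(
    model: LVCModel,
    Q0: np.ndarray,
    P0: np.ndarray,
    initial_mch_state: int,
    settings: PropagationSettings,
    rng: Optional[np.random.Generator] = None,
    initial_coeff: str = "diagonal",
) -> Trajectory:
    """Propagate one trajectory from a phase-space sample and an initial MCH
    state (spin-free index).  The initial diagonal state is the one of
    maximum overlap with the selected MCH state; the coefficient vector is
    that pure diagonal state (``initial_coeff="diagonal"``, default) or the
    pure MCH state expressed in the diagonal basis (``"mch"``)."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    ref = model.reference
    basis = model.basis
    p = model.params
    f = ref.n_modes
    d = basis.dim
    n_sf = basis.n_spinfree
    if not 0 <= initial_mch_state < n_sf:
        raise ValueError(
            f"initial MCH state {initial_mch_state} outside 0..{n_sf - 1}"
        )
    omega_ev = ref.omega_ev
    omega_fs = ref.omega_fs
    dt = settings.dt_nuc
    n_steps = settings.n_steps
    n_sub = settings.n_substeps

    def kinetic(qdot: np.ndarray) -> float:
        return float(0.5 * HBAR_EVFS**2 * np.sum(qdot**2 / omega_ev))

    Q = np.asarray(Q0, dtype=float).copy()
    Qdot = omega_fs * np.asarray(P0, dtype=float)

    ev, mch = electronic_structure(model, Q)
    # initial diagonal state: maximum overlap with the selected MCH state
    mch_expanded = initial_mch_state  # singlets keep their index in the expansion
    if basis.multiplicities[initial_mch_state] == 3:
        # use the M_S = 0 replica for triplet starts
        t_idx = initial_mch_state - basis.n_singlets
        mch_expanded = basis.n_singlets + basis.n_triplets + t_idx
    active = int(np.argmax(np.abs(mch.U_diag[mch_expanded, :])))
    if initial_coeff == "diagonal":
        c = np.zeros(d, dtype=complex)
        c[active] = 1.0
    elif initial_coeff == "mch":
        e_mch = np.zeros(d, dtype=complex)
        e_mch[mch_expanded] = 1.0
        c = mch.U_diag.conj().T @ e_mch
    else:
        raise ValueError("initial_coeff must be 'diagonal' or 'mch'")

    n_rec = n_steps + 1
    traj = Trajectory(
        times=np.arange(n_rec) * dt,
        Q=np.empty((n_rec, f)),
        Qdot=np.empty((n_rec, f)),
        c_diag=np.empty((n_rec, d), dtype=complex),
        active=np.empty(n_rec, dtype=np.int64),
        E_mch=np.empty((n_rec, n_sf)),
        E_diag=np.empty((n_rec, d)),
        U=np.empty((n_rec, n_sf, n_sf)),
        U_diag=np.empty((n_rec, d, d), dtype=complex),
        E_kin=np.empty(n_rec),
        E_total=np.empty(n_rec),
        initial_mch_state=initial_mch_state,
    )

    def record(k):
        traj.Q[k] = Q
        traj.Qdot[k] = Qdot
        traj.c_diag[k] = c
        traj.active[k] = active
        traj.E_mch[k] = mch.E_mch
        traj.E_diag[k] = mch.E_diag
        traj.U[k] = mch.U
        traj.U_diag[k] = mch.U_diag
        traj.E_kin[k] = kinetic(Qdot)
        traj.E_total[k] = traj.E_kin[k] + mch.E_diag[active]

    record(0)
    grads_sf = mch_gradients(ev, mch.U)
    accel = -omega_fs * _active_gradient(grads_sf, basis, mch.U_diag, active) / HBAR_EVFS

    for step in range(1, n_steps + 1):
        if settings.freeze_nuclei:
            ev_new, mch_new = ev, mch
            s_exp = np.eye(d, dtype=complex)
        else:
            qdot_half = Qdot + 0.5 * dt * accel
            Q = Q + dt * qdot_half
            if not np.all(np.isfinite(Q)):
                traj.valid = False
                traj.invalid_reason = f"non-finite coordinates at step {step}"
                _truncate(traj, step)
                return traj
            ev_new, mch_new = electronic_structure(
                model, Q, prev_U=mch.U, prev_U_diag=mch.U_diag
            )
            grads_sf = mch_gradients(ev_new, mch_new.U)
            accel = (
                -omega_fs
                * _active_gradient(grads_sf, basis, mch_new.U_diag, active)
                / HBAR_EVFS
            )
            Qdot = qdot_half + 0.5 * dt * accel
            s_sf = time_overlap(mch.U, mch_new.U)
            s_exp = basis.expand_matrix(s_sf).astype(complex)

        # electronic step: local diabatization in the old MCH frame
        c_mch_old = mch.U_diag @ c
        c_mch_prop = _ld_step_apply(
            mch.H_diag_inputs, mch_new.H_diag_inputs, s_exp, c_mch_old,
            n_sub, settings.dt_el,
        )
        c_mch_new = s_exp.conj().T @ c_mch_prop
        c_new = mch_new.U_diag.conj().T @ c_mch_new

        # stochastic hop
        if settings.hopping:
            probs = hop_probabilities(c, c_new, active)
            draw = rng.random()
            cum = np.cumsum(probs)
            hit = np.searchsorted(cum, draw)
            if hit < probs.size and probs[hit] > 0:
                new_active, Qdot, kind = hop_and_rescale(
                    active,
                    int(hit),
                    mch_new.E_diag,
                    Qdot,
                    kinetic(Qdot),
                    settings.frustrated_policy,
                )
                traj.hops.append((step, active, int(hit), kind))
                if kind == "hop":
                    active = new_active
                    grads_sf = mch_gradients(ev_new, mch_new.U)
                    accel = (
                        -omega_fs
                        * _active_gradient(grads_sf, basis, mch_new.U_diag, active)
                        / HBAR_EVFS
                    )

        c = c_new
        if settings.decoherence:
            c = apply_decoherence(
                c, active, mch_new.E_diag, kinetic(Qdot), settings.decoherence_c, dt
            )

        ev, mch = ev_new, mch_new
        record(step)

    # energy-drift audit over any 100-step window (between-hop segments)
    if not settings.freeze_nuclei:
        _audit_energy(traj, settings)
    return traj


def _truncate(traj: Trajectory, upto: int) -> None:
    for name in ("times", "Q", "Qdot", "c_diag", "active", "E_mch", "E_diag", "U", "U_diag", "E_kin", "E_total"):
        setattr(traj, name, getattr(traj, name)[:upto])


def _audit_energy(traj: Trajectory, settings: PropagationSettings) -> None:
    """Flag the trajectory if total energy drifts beyond the allowed bound
    over any 100-step window that contains no hop."""
    e = traj.E_total
    hop_steps = {h[0] for h in traj.hops if h[3] == "hop"}
    window = 100
    start = 0
    breaks = sorted(hop_steps) + [e.size]
    for b in breaks:
        seg = e[start:b]
        if seg.size > 1:
            w = min(window, seg.size)
            drift = np.abs(seg[w - 1 :] - seg[: seg.size - w + 1]).max() if seg.size >= w else np.abs(seg - seg[0]).max()
            if drift > settings.max_drift_ev:
                traj.valid = False
                traj.invalid_reason = (
                    f"energy drift {drift:.3e} eV over a {w}-step window"
                )
                return
        start = b
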