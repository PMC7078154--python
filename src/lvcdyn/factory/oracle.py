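"""Exact quantum-dynamics oracles for small models.

Two regimes are supported:

* frozen nuclei: unitary propagation of the full spin-expanded Hamiltonian
  at a fixed geometry (matrix exponential via eigendecomposition);
* moving nuclei: split-operator wavepacket propagation on a coordinate grid,
  limited to at most 3 spin-free states and 2 modes.

Both serve as independent references for the surface-hopping propagator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import HBAR_EVFS
from ..core.hamiltonian import evaluate_potential, transform_properties
from ..core.parameters import LVCModel

__all__ = ["QuantumResult", "exact_quantum_oracle", "rabi_period"]

_MAX_STATES = 3
_MAX_MODES = 2
_MAX_FROZEN_DIM = 64


@dataclass
class QuantumResult:
    times: np.ndarray  # (T,) fs
    populations: np.ndarray  # (T, D) diabatic spin-expanded populations
    norm: np.ndarray  # (T,)


def rabi_period(gap_ev: float, coupling_ev: float) -> float:
    """Period (fs) of the two-level population oscillation for a constant
    Hamiltonian with diagonal splitting ``gap`` and coupling ``v``:
    T = 2 pi hbar / sqrt(gap^2 + 4 v^2)."""
    return 2.0 * np.pi * HBAR_EVFS / np.sqrt(gap_ev**2 + 4.0 * coupling_ev**2)


def exact_quantum_oracle(
    model: LVCModel,
    c0: np.ndarray,
    times: np.ndarray,
    frozen_nuclei: bool = False,
    Q: np.ndarray | None = None,
    grid_points: int = 256,
    q_span: float = 8.0,
    center: np.ndarray | None = None,
    momentum: np.ndarray | None = None,
) -> QuantumResult:
    """Exact diabatic populations over a time grid (fs).

    ``c0`` are initial electronic coefficients in the spin-expanded diabatic
    basis.  With ``frozen_nuclei`` the geometry ``Q`` (default 0) is fixed;
    otherwise a wavepacket initialized as the ground-state Gaussian (optionally
    shifted by ``center`` / boosted by ``momentum``) is propagated with the
    split-operator method.
    """
    times = np.asarray(times, dtype=float)
    c0 = np.asarray(c0, dtype=complex).ravel()
    d = model.basis.dim
    if c0.shape != (d,):
        raise ValueError(f"c0 has length {c0.size}, expected {d}")
    if frozen_nuclei:
        if d > _MAX_FROZEN_DIM:
            raise ValueError(
                f"frozen-nuclei oracle limited to D <= {_MAX_FROZEN_DIM}, got {d}"
            )
        return _propagate_frozen(model, c0, times, Q)
    n_sf = model.basis.n_spinfree
    f = model.reference.n_modes
    if n_sf > _MAX_STATES or f > _MAX_MODES:
        raise ValueError(
            f"wavepacket oracle limited to <= {_MAX_STATES} spin-free states "
            f"and <= {_MAX_MODES} modes; got {n_sf} states, {f} modes"
        )
    return _propagate_wavepacket(
        model, c0, times, grid_points, q_span, center, momentum
    )


def _total_hamiltonian(model: LVCModel, Q: np.ndarray) -> np.ndarray:
    """Spin-expanded diabatic Hamiltonian V_expanded + SOC at one geometry."""
    ev = evaluate_potential(model, Q)
    return model.basis.expand_matrix(ev.V) + model.params.soc


def _propagate_frozen(model, c0, times, Q):
    f = model.reference.n_modes
    q = np.zeros(f) if Q is None else np.asarray(Q, dtype=float)
    h = _total_hamiltonian(model, q)
    w, v = np.linalg.eigh(h)
    a0 = v.conj().T @ c0
    phases = np.exp(-1j * np.outer(times, w) / HBAR_EVFS)
    c_t = (v @ (phases * a0[None, :]).T).T  # (T, D)
    pops = np.abs(c_t) ** 2
    return QuantumResult(times=times, populations=pops, norm=pops.sum(axis=1))


def _propagate_wavepacket(model, c0, times, grid_points, q_span, center, momentum):
    ref = model.reference
    f = ref.n_modes
    d = model.basis.dim
    omega_fs = ref.omega_fs
    center = np.zeros(f) if center is None else np.asarray(center, dtype=float)
    momentum = np.zeros(f) if momentum is None else np.asarray(momentum, dtype=float)

    axes = [np.linspace(-q_span, q_span, grid_points, endpoint=False) for _ in range(f)]
    dq = [ax[1] - ax[0] for ax in axes]
    mesh = np.meshgrid(*axes, indexing="ij")
    shape = mesh[0].shape
    npts = int(np.prod(shape))

    # potential matrices on the grid, diagonalized once (time independent)
    qpts = np.stack([m.ravel() for m in mesh], axis=1)  # (npts, F)
    vmat = np.empty((npts, d, d), dtype=complex)
    soc = model.params.soc
    basis = model.basis
    p = model.params
    hw = ref.omega_ev
    # vectorized diabatic potential over all grid points
    v0 = 0.5 * (qpts**2 @ hw)
    voff = np.einsum("nmf,pf->pnm", p.lam, qpts)
    diag = p.epsilon[None, :] + qpts @ p.kappa.T + v0[:, None]
    idx = np.arange(p.n_states)
    voff[:, idx, idx] = diag
    vexp = basis.expand_matrix(voff)  # (npts, D, D)
    vmat = vexp + soc[None, :, :]
    w_v, u_v = np.linalg.eigh(vmat)

    # kinetic phases in Fourier space: T = sum_i omega_i k_i^2 / 2 (hbar units)
    ks = [2.0 * np.pi * np.fft.fftfreq(grid_points, dqi) for dqi in dq]
    kmesh = np.meshgrid(*ks, indexing="ij")
    t_grid = sum(0.5 * omega_fs[i] * kmesh[i] ** 2 for i in range(f))

    # initial wavepacket: ground-state Gaussian product times c0
    g = np.ones(shape)
    for i in range(f):
        g = g * np.exp(-((mesh[i] - center[i]) ** 2) / 2.0)
    phase = np.zeros(shape)
    for i in range(f):
        phase = phase + momentum[i] * mesh[i]
    psi = (g * np.exp(1j * phase)).ravel()[:, None] * c0[None, :]
    cell = float(np.prod(dq))
    psi /= np.sqrt((np.abs(psi) ** 2).sum() * cell)

    if times.size < 2:
        pops = (np.abs(psi) ** 2).sum(axis=0) * cell
        return QuantumResult(times=times, populations=pops[None, :], norm=pops.sum()[None])
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt):
        raise ValueError("wavepacket oracle requires a uniform time grid")

    kin_half = np.exp(-1j * t_grid.ravel() * dt / 2.0)
    pot_phase = np.exp(-1j * w_v * dt / HBAR_EVFS)

    pops = np.empty((times.size, d))
    norm = np.empty(times.size)

    def record(k, psi):
        pk = (np.abs(psi) ** 2).sum(axis=0) * cell
        pops[k] = pk
        norm[k] = pk.sum()

    record(0, psi)
    fft_axes = tuple(range(f))
    for k in range(1, times.size):
        arr = psi.reshape(shape + (d,))
        arr = np.fft.fftn(arr, axes=fft_axes)
        arr = arr * kin_half.reshape(shape)[..., None]
        arr = np.fft.ifftn(arr, axes=fft_axes)
        flat = arr.reshape(npts, d)
        a = np.einsum("pji,pj->pi", u_v.conj(), flat)
        a = a * pot_phase
        flat = np.einsum("pij,pj->pi", u_v, a)
        arr = flat.reshape(shape + (d,))
        arr = np.fft.fftn(arr, axes=fft_axes)
        arr = arr * kin_half.reshape(shape)[..., None]
        arr = np.fft.ifftn(arr, axes=fft_axes)
        psi = arr.reshape(npts, d)
        record(k, psi)
    return QuantumResult(times=times, populations=pops, norm=norm)
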