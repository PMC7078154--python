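"""Trajectory ensembles: batch propagation and the in-memory archive."""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..core.parameters import LVCModel
from .settings import PropagationSettings
from .trajectory import Trajectory, propagate_trajectory

__all__ = ["Ensemble", "run_ensemble", "model_fingerprint"]

SCHEMA_VERSION = 1


def model_fingerprint(model: LVCModel) -> str:
    """Stable hash of the model arrays for provenance metadata."""
    h = hashlib.sha256()
    p = model.params
    for arr in (
        model.reference.r_ref,
        model.reference.masses,
        model.reference.omega,
        model.reference.K,
        p.epsilon,
        p.kappa,
        p.lam,
        p.soc.view(float),
        p.dipoles,
    ):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


@dataclass
class Ensemble:
    """Stacked trajectory data plus provenance metadata.

    All per-step arrays have leading dimensions (n_traj, n_times).  A *full*
    ensemble carries the U / U_diag transforms per step; a *reduced* ensemble
    (loaded from a compact "analysis" archive) carries precomputed
    representation data instead (``c_mch``, ``c_diab``, per-representation
    active-state columns and coefficient-diagonal contractions) and has
    ``U = U_diag = None``.
    """

    times: np.ndarray
    Q: np.ndarray
    c_diag: np.ndarray
    active: np.ndarray
    E_mch: np.ndarray
    E_diag: np.ndarray
    E_kin: np.ndarray
    E_total: np.ndarray
    n_singlets: int
    n_triplets: int
    valid: np.ndarray  # (n_traj,) bool
    invalid_reasons: list
    hops: list  # list (per trajectory) of (step, from, to, kind)
    initial_mch_states: np.ndarray
    Qdot: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    U_diag: Optional[np.ndarray] = None
    c_mch: Optional[np.ndarray] = None
    c_diab: Optional[np.ndarray] = None
    p_active_mch: Optional[np.ndarray] = None
    p_active_diab: Optional[np.ndarray] = None
    dterm_mch: Optional[np.ndarray] = None
    dterm_diab: Optional[np.ndarray] = None
    seed: int = 0
    model_hash: str = ""
    settings: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @property
    def is_reduced(self) -> bool:
        return self.U_diag is None

    @property
    def n_traj(self) -> int:
        return self.Q.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def dim(self) -> int:
        return self.c_diag.shape[2]

    @property
    def basis(self):
        from ..core.basis import ElectronicBasis

        return ElectronicBasis(self.n_singlets, self.n_triplets)


def run_ensemble(
    model: LVCModel,
    selections: Sequence,
    settings: PropagationSettings,
    wigner,
) -> Ensemble:
    """Propagate one trajectory per selection.

    Each trajectory receives an independent RNG stream spawned from the
    master seed; failed trajectories are recorded (``valid`` flag and
    reason), never silently dropped.
    """
    if len(selections) == 0:
        raise ValueError("no selections to propagate")
    ss = np.random.SeedSequence(settings.seed)
    streams = ss.spawn(len(selections))
    trajs: list[Trajectory] = []
    for sel, stream in zip(selections, streams):
        rng = np.random.default_rng(stream)
        traj = propagate_trajectory(
            model,
            wigner.Q[sel.sample_id],
            wigner.P[sel.sample_id],
            sel.mch_state,
            settings,
            rng=rng,
        )
        traj.seed = sel.sample_id
        trajs.append(traj)
    n_times = max(t.times.size for t in trajs)
    full = [t for t in trajs if t.times.size == n_times]
    if not full:
        raise RuntimeError("every trajectory aborted early")

    def stack(name):
        tmpl = getattr(full[0], name)
        out = np.zeros((len(trajs),) + (n_times,) + tmpl.shape[1:], dtype=tmpl.dtype)
        for i, t in enumerate(trajs):
            arr = getattr(t, name)
            out[i, : arr.shape[0]] = arr
        return out

    return Ensemble(
        times=full[0].times,
        Q=stack("Q"),
        Qdot=stack("Qdot"),
        c_diag=stack("c_diag"),
        active=stack("active"),
        E_mch=stack("E_mch"),
        E_diag=stack("E_diag"),
        U=stack("U"),
        U_diag=stack("U_diag"),
        E_kin=stack("E_kin"),
        E_total=stack("E_total"),
        n_singlets=model.basis.n_singlets,
        n_triplets=model.basis.n_triplets,
        valid=np.array([t.valid for t in trajs]),
        invalid_reasons=[t.invalid_reason for t in trajs],
        hops=[list(t.hops) for t in trajs],
        initial_mch_states=np.array([t.initial_mch_state for t in trajs]),
        seed=settings.seed,
        model_hash=model_fingerprint(model),
        settings=settings.to_dict(),
    )
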