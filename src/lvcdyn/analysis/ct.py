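"""Charge-transfer character evolution of the propagated wave function."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..dynamics.ensemble import Ensemble
from ..factory.ct_table import CTNumberTable
from .classify import CLASS_OF_PAIR
from .populations import diabatic_coefficients

__all__ = ["CTSeries", "ct_evolution", "ct_class_fractions", "final_character_split"]


@dataclass
class CTSeries:
    times: np.ndarray  # (T,)
    omega: np.ndarray  # (T, n_frag, n_frag) ensemble-averaged CT numbers
    fragments: tuple
    per_trajectory: np.ndarray  # (n_traj, T, n_frag, n_frag)


def ct_evolution(
    ens: Ensemble, ct_table: CTNumberTable, include_invalid: bool = False
) -> CTSeries:
    """Ensemble-averaged Omega_AB(t) from the diabatic coefficients.

    Omega_AB(t) = sum_nm c_n*(t) c_m(t) Omega_AB^(n,m), per trajectory, then
    averaged over the valid trajectories.  A table without transition CT
    numbers (all off-diagonal zero) yields the diagonal-only estimate - in
    that case a prominent warning is issued.
    """
    basis = ens.basis
    if ct_table.n_states != basis.n_spinfree:
        raise ValueError(
            f"CT table covers {ct_table.n_states} states, basis has {basis.n_spinfree}"
        )
    off = ct_table.omega.copy()
    idx = np.arange(ct_table.n_states)
    off[idx, idx] = 0.0
    if not np.any(off):
        warnings.warn(
            "CT table has no transition CT numbers; falling back to the "
            "diagonal-only estimate"
        )
    which = np.where(ens.valid | include_invalid)[0]
    nf = len(ct_table.fragments)
    per = np.zeros((ens.n_traj, ens.n_times, nf, nf))
    for i in which:
        c_diab = diabatic_coefficients(ens, i)
        per[i] = ct_table.of_coefficients(c_diab, basis)
    mean = per[which].mean(axis=0)
    return CTSeries(
        times=ens.times, omega=mean, fragments=ct_table.fragments, per_trajectory=per
    )


def ct_class_fractions(series: CTSeries) -> dict:
    """Normalized per-class fractions of the averaged CT numbers over time."""
    fragments = series.fragments
    total = series.omega.sum(axis=(1, 2))
    out: dict = {}
    safe = np.where(total > 0, total, 1.0)
    for (a, b), cls in CLASS_OF_PAIR.items():
        ia, ib = fragments.index(a), fragments.index(b)
        out[cls] = out.get(cls, 0.0) + series.omega[:, ia, ib] / safe
    known = sum(out.values())
    out["Others"] = np.where(total > 0, 1.0 - known, 0.0)
    return out


def final_character_split(
    series: CTSeries, threshold: float = 0.5, when: int = -1
) -> np.ndarray:
    """Boolean mask of trajectories whose CS fraction at time index ``when``
    exceeds ``threshold`` (default: more than 50% CS at the final frame)."""
    fragments = series.fragments
    ia, ib = fragments.index("Trp"), fragments.index("Dmp")
    omega_t = series.per_trajectory[:, when]
    total = omega_t.sum(axis=(1, 2))
    frac = np.where(total > 0, omega_t[:, ia, ib] / np.where(total > 0, total, 1.0), 0.0)
    return frac > threshold
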