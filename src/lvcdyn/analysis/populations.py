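"""Electronic population time series in three representations.

Estimators:

* ``active``: fraction of trajectories whose active diagonal state maps to
  each state of the requested representation through |T|^2;
* ``coefficient``: ensemble mean of the transformed |c|^2;
* ``mixed`` (default): per-trajectory density matrix whose diagonal comes
  from the active state and whose off-diagonals come from the coefficients,
  transformed and averaged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..dynamics.ensemble import Ensemble

__all__ = ["PopulationSeries", "populations", "multiplicity_totals", "diabatic_coefficients"]

REPRESENTATIONS = ("diagonal", "mch", "diabatic")
ESTIMATORS = ("active", "coefficient", "mixed")

_CLIP_FLOOR = -1e-3


@dataclass
class PopulationSeries:
    times: np.ndarray  # (T,)
    populations: np.ndarray  # (T, D)
    representation: str
    estimator: str

    def totals(self, indices: np.ndarray) -> np.ndarray:
        return self.populations[:, indices].sum(axis=1)


def _transforms(ens: Ensemble, representation: str, i: int) -> np.ndarray:
    """(T, D, D) transform with columns in the diagonal basis:
    c_rep = T @ c_diag."""
    if representation == "diagonal":
        d = ens.dim
        return np.broadcast_to(np.eye(d, dtype=complex), (ens.n_times, d, d))
    if representation == "mch":
        return ens.U_diag[i]
    if representation == "diabatic":
        u_exp = ens.basis.expand_matrix(ens.U[i])  # (T, D, D)
        return u_exp @ ens.U_diag[i]
    raise ValueError(f"unknown representation {representation!r}; use one of {REPRESENTATIONS}")


def reduce_ensemble_arrays(ens: Ensemble) -> dict:
    """Precompute the representation data a reduced archive stores:
    coefficients in the MCH/diabatic bases, the |T[:,active]|^2 columns, and
    the |T|^2 |c|^2 contraction used by the mixed estimator."""
    if ens.is_reduced:
        raise ValueError("ensemble is already reduced")
    n, T, d = ens.c_diag.shape
    out = {
        "c_mch": np.empty((n, T, d), dtype=complex),
        "c_diab": np.empty((n, T, d), dtype=complex),
        "p_active_mch": np.empty((n, T, d)),
        "p_active_diab": np.empty((n, T, d)),
        "dterm_mch": np.empty((n, T, d)),
        "dterm_diab": np.empty((n, T, d)),
    }
    for i in range(n):
        a = ens.active[i][:, None, None].astype(np.intp)
        c2 = np.abs(ens.c_diag[i]) ** 2
        for rep, tag in (("mch", "mch"), ("diabatic", "diab")):
            t = _transforms(ens, rep, i)
            out[f"c_{tag}"][i] = np.einsum("tij,tj->ti", t, ens.c_diag[i])
            t2 = np.abs(t) ** 2
            out[f"p_active_{tag}"][i] = np.take_along_axis(t2, a, axis=2)[:, :, 0]
            out[f"dterm_{tag}"][i] = np.einsum("tij,tj->ti", t2, c2)
    return out


def _populations_reduced(ens: Ensemble, representation: str, estimator: str, which) -> np.ndarray:
    d = ens.dim
    acc = np.zeros((ens.n_times, d))
    for i in which:
        onehot = np.zeros((ens.n_times, d))
        onehot[np.arange(ens.n_times), ens.active[i]] = 1.0
        if representation == "diagonal":
            if estimator == "coefficient":
                acc += np.abs(ens.c_diag[i]) ** 2
            else:  # active and mixed coincide in the hopping basis
                acc += onehot
            continue
        tag = "mch" if representation == "mch" else "diab"
        c_rep = getattr(ens, f"c_{tag}")
        pa = getattr(ens, f"p_active_{tag}")
        dt = getattr(ens, f"dterm_{tag}")
        if c_rep is None or pa is None or dt is None:
            raise ValueError(
                f"reduced ensemble lacks the data for representation "
                f"{representation!r}"
            )
        if estimator == "coefficient":
            acc += np.abs(c_rep[i]) ** 2
        elif estimator == "active":
            acc += pa[i]
        else:
            acc += np.abs(c_rep[i]) ** 2 - dt[i] + pa[i]
    return acc / len(which)


def populations(
    ens: Ensemble,
    representation: str = "diabatic",
    estimator: str = "mixed",
    include_invalid: bool = False,
    clip: bool = True,
) -> PopulationSeries:
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; use one of {ESTIMATORS}")
    if representation not in REPRESENTATIONS:
        raise ValueError(
            f"unknown representation {representation!r}; use one of {REPRESENTATIONS}"
        )
    which = np.where(ens.valid | include_invalid)[0]
    if which.size == 0:
        raise ValueError("no valid trajectories")
    if ens.is_reduced:
        pops = _populations_reduced(ens, representation, estimator, which)
        return _finalize(ens, pops, representation, estimator, clip)
    acc = np.zeros((ens.n_times, ens.dim))
    for i in which:
        t = _transforms(ens, representation, i)
        c = ens.c_diag[i]  # (T, D)
        a = ens.active[i]  # (T,)
        if estimator == "coefficient":
            acc += np.abs(np.einsum("tij,tj->ti", t, c)) ** 2
        elif estimator == "active":
            cols = np.take_along_axis(t, a[:, None, None].astype(np.intp), axis=2)[:, :, 0]
            acc += np.abs(cols) ** 2
        else:  # mixed
            coef = np.abs(np.einsum("tij,tj->ti", t, c)) ** 2
            t2 = np.abs(t) ** 2  # (T, D, D)
            diag_term = np.einsum("tij,tj->ti", t2, np.abs(c) ** 2)
            cols = np.take_along_axis(t, a[:, None, None].astype(np.intp), axis=2)[:, :, 0]
            acc += coef - diag_term + np.abs(cols) ** 2
    pops = acc / which.size
    return _finalize(ens, pops, representation, estimator, clip)


def _finalize(ens, pops, representation, estimator, clip) -> PopulationSeries:
    if clip:
        low = pops.min()
        if low < _CLIP_FLOOR:
            warnings.warn(
                f"population estimator produced values as low as {low:.2e}; clipping"
            )
        pops = np.clip(pops, 0.0, None)
    return PopulationSeries(
        times=ens.times, populations=pops, representation=representation, estimator=estimator
    )


def multiplicity_totals(series: PopulationSeries, ens: Ensemble) -> dict:
    """Singlet and triplet totals of a population series.

    For the diagonal representation the assignment of states to spin blocks
    is only meaningful through the basis the series was computed in; MCH or
    diabatic series use the spin expansion directly.
    """
    basis = ens.basis
    singlet_idx = np.where(basis.is_singlet_expanded)[0]
    triplet_idx = np.where(~basis.is_singlet_expanded)[0]
    return {
        "singlet": series.totals(singlet_idx),
        "triplet": series.totals(triplet_idx),
    }


def diabatic_coefficients(ens: Ensemble, i: int) -> np.ndarray:
    """(T, D) spin-expanded diabatic coefficients of trajectory ``i``:
    c_diab = U_expanded @ U_diag @ c_diag per step."""
    if ens.is_reduced:
        if ens.c_diab is None:
            raise ValueError("reduced ensemble lacks diabatic coefficients")
        return ens.c_diab[i]
    t = _transforms(ens, "diabatic", i)
    return np.einsum("tij,tj->ti", t, ens.c_diag[i])
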