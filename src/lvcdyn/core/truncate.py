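"""Model truncation: frequency cutoff, state removal, ground-state SOC zeroing."""
from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .basis import ElectronicBasis
from .parameters import LVCModel, LVCParameters
from .reference import HarmonicReference

__all__ = ["truncate_model"]


def truncate_model(
    model: LVCModel,
    omega_cut: float = 0.0,
    remove_states: Iterable[str] = (),
    drop_s0_soc: bool = False,
) -> LVCModel:
    """Return a truncated copy of the model.

    Parameters
    ----------
    omega_cut : float
        Frequency cutoff in cm^-1; modes with ``omega < omega_cut`` are
        removed from the reference and from kappa/lambda.
    remove_states : iterable of str
        Labels of spin-free states to delete from all electronic arrays
        (epsilon, kappa, lambda, SOC, dipoles, CT table).
    drop_s0_soc : bool
        Zero the SOC rows/columns of the lowest singlet.
    """
    if omega_cut < 0:
        raise ValueError("omega_cut must be non-negative")
    remove = set(remove_states)
    unknown = remove - set(model.basis.labels)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")

    ref = model.reference
    mode_keep = ref.omega >= omega_cut
    if not mode_keep.any():
        raise ValueError("frequency cutoff would remove every normal mode")
    new_ref = HarmonicReference(
        r_ref=ref.r_ref.copy(),
        masses=ref.masses.copy(),
        omega=ref.omega[mode_keep],
        K=ref.K[:, mode_keep],
    )

    basis = model.basis
    state_keep = np.array([l not in remove for l in basis.labels])
    mult = basis.multiplicities
    if not np.any(state_keep & (mult == 1)):
        raise ValueError("truncation would remove every singlet state")
    n_excited_left = int(state_keep.sum()) - 1
    if n_excited_left < 1:
        raise ValueError("truncation would remove every excited state")
    new_basis = basis.select(state_keep)

    # spin-expanded keep mask, in the same M_S-blocked ordering
    exp_keep = state_keep[basis.spinfree_index]

    p = model.params
    soc = p.soc[np.ix_(exp_keep, exp_keep)].copy()
    new_params = LVCParameters(
        basis=new_basis,
        epsilon=p.epsilon[state_keep].copy(),
        kappa=p.kappa[np.ix_(state_keep, mode_keep)].copy(),
        lam=p.lam[np.ix_(state_keep, state_keep, mode_keep)].copy(),
        soc=soc,
        dipoles=p.dipoles[:, state_keep][:, :, state_keep].copy(),
    )
    if drop_s0_soc:
        new_params.drop_ground_state_soc()

    new_ct: Optional[object] = None
    if model.ct_table is not None:
        new_ct = model.ct_table.select_states(state_keep)
    return LVCModel(reference=new_ref, params=new_params, ct_table=new_ct)
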