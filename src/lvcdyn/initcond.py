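"""Initial conditions: Wigner sampling, vertical excitations, absorption
spectrum with charge-transfer decomposition, and stochastic state selection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .analysis.classify import pair_fraction
from .constants import HARTREE_TO_EV
from .core.hamiltonian import adiabatize, evaluate_potential, transform_properties
from .core.parameters import LVCModel

__all__ = [
    "WignerEnsemble",
    "ExcitationRecord",
    "VerticalExcitationSet",
    "sample_wigner",
    "vertical_excitation",
    "vertical_excitations",
    "compute_spectrum",
    "Spectrum",
    "Selection",
    "select_initial_states",
]


@dataclass
class WignerEnsemble:
    """Batch of phase-space samples; rows of Q/P are individual samples."""

    Q: np.ndarray  # (n, F) dimensionless coordinates
    P: np.ndarray  # (n, F) dimensionless momenta
    seed: int

    def __len__(self) -> int:
        return self.Q.shape[0]

    @property
    def seed_ids(self) -> np.ndarray:
        return np.arange(len(self))


def sample_wigner(reference, n: int, seed: int) -> WignerEnsemble:
    """Sample the ground-state Wigner distribution of the harmonic oscillator.

    In the dimensionless mass-frequency-scaled convention each Q_i and P_i is
    an independent Gaussian with mean 0 and variance 1/2, giving a mean total
    energy of sum_i hbar*omega_i/2.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    f = reference.n_modes
    q = rng.normal(0.0, np.sqrt(0.5), size=(n, f))
    p = rng.normal(0.0, np.sqrt(0.5), size=(n, f))
    return WignerEnsemble(Q=q, P=p, seed=seed)


@dataclass
class ExcitationRecord:
    """Vertical excitation data of one geometry.

    Energies are MCH excitation energies relative to the lowest singlet at
    the same geometry; states are all spin-free MCH states except that lowest
    singlet, in spin-free ordering.
    """

    energies: np.ndarray  # (n_exc,) eV
    fosc: np.ndarray  # (n_exc,)
    cs_fraction: np.ndarray  # (n_exc,) charge-separated (Trp->Dmp) fraction
    mlct_il_fraction: np.ndarray  # (n_exc,) combined MLCT + IL fraction
    state_index: np.ndarray  # (n_exc,) spin-free MCH state index


def vertical_excitation(model: LVCModel, Q: np.ndarray) -> ExcitationRecord:
    """Vertical excitation calculation at one geometry.

    Oscillator strengths use f = (2/3) dE |mu|^2 in atomic units with the
    dipole matrices transformed to the MCH basis; CT fractions apply the
    CT-number transform to the pure-state MCH coefficient vectors.
    """
    ev = evaluate_potential(model, Q)
    basis = model.basis
    e_mch, u = adiabatize(ev, basis)
    _, dip_mch = transform_properties(u, basis, dipoles=model.params.dipoles)
    n_sf = basis.n_spinfree
    ground = int(np.argmin(e_mch[: basis.n_singlets]))
    others = np.array([i for i in range(n_sf) if i != ground])
    de = e_mch[others] - e_mch[ground]
    mu2 = (dip_mch[:, ground, others] ** 2).sum(axis=0)
    fosc = (2.0 / 3.0) * (de / HARTREE_TO_EV) * mu2
    # triplet states carry no spin-allowed dipole; zero them explicitly
    fosc = np.where(basis.multiplicities[others] == 1, fosc, 0.0)

    cs = np.zeros(others.size)
    mlct_il = np.zeros(others.size)
    ct = model.ct_table
    if ct is not None:
        mult = basis.multiplicities
        for k, idx in enumerate(others):
            sel = np.where(mult == mult[idx])[0]
            c_sf = np.zeros(n_sf)
            c_sf[sel] = u[sel, idx]
            om = np.einsum("n,m,nmab->ab", c_sf, c_sf, ct.omega)
            cs[k] = pair_fraction(om, ct.fragments, ("Trp", "Dmp"))
            mlct_il[k] = pair_fraction(
                om, ct.fragments, ("Re(CO)3", "Dmp")
            ) + pair_fraction(om, ct.fragments, ("Dmp", "Dmp"))
    return ExcitationRecord(
        energies=de, fosc=fosc, cs_fraction=cs, mlct_il_fraction=mlct_il,
        state_index=others,
    )


@dataclass
class VerticalExcitationSet:
    """Stacked vertical excitations for a Wigner batch."""

    energies: np.ndarray  # (n_samples, n_exc)
    fosc: np.ndarray
    cs_fraction: np.ndarray
    mlct_il_fraction: np.ndarray
    state_index: np.ndarray  # (n_exc,) spin-free MCH indices

    @property
    def n_samples(self) -> int:
        return self.energies.shape[0]


def vertical_excitations(model: LVCModel, wigner: WignerEnsemble) -> VerticalExcitationSet:
    recs = [vertical_excitation(model, q) for q in wigner.Q]
    return VerticalExcitationSet(
        energies=np.stack([r.energies for r in recs]),
        fosc=np.stack([r.fosc for r in recs]),
        cs_fraction=np.stack([r.cs_fraction for r in recs]),
        mlct_il_fraction=np.stack([r.mlct_il_fraction for r in recs]),
        state_index=recs[0].state_index,
    )


@dataclass
class Spectrum:
    grid: np.ndarray  # (n_grid,) eV
    total: np.ndarray  # (n_grid,) intensity
    bins: np.ndarray  # (n_bins + 1,) CT-fraction bin edges
    decomposition: np.ndarray  # (n_bins, n_grid), sums to total exactly
    fwhm: float


def compute_spectrum(
    records: VerticalExcitationSet,
    fwhm: float = 0.2,
    grid: Optional[np.ndarray] = None,
    ct_bins: Optional[Sequence[float]] = None,
    decompose_by: str = "cs",
) -> Spectrum:
    """Gaussian-convolved absorption spectrum with CT-class decomposition.

    Every line of every sampled geometry contributes a normalized Gaussian of
    the given FWHM weighted by its oscillator strength, assigned to a CT bin
    by its CS (or combined MLCT+IL) fraction; the bins partition the total
    spectrum exactly.
    """
    e = records.energies.ravel()
    f = records.fosc.ravel()
    if decompose_by == "cs":
        frac = records.cs_fraction.ravel()
    elif decompose_by == "mlct_il":
        frac = records.mlct_il_fraction.ravel()
    else:
        raise ValueError(f"unknown decomposition {decompose_by!r}")
    if e.size == 0:
        raise ValueError("no excitation records")
    if grid is None:
        grid = np.linspace(max(0.0, e.min() - 3 * fwhm), e.max() + 3 * fwhm, 600)
    grid = np.asarray(grid, dtype=float)
    if ct_bins is None:
        ct_bins = np.linspace(0.0, 1.0, 11)
    edges = np.asarray(ct_bins, dtype=float)
    n_bins = edges.size - 1
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    which = np.clip(np.digitize(frac, edges) - 1, 0, n_bins - 1)
    decomposition = np.zeros((n_bins, grid.size))
    if grid.size and (grid.min() > e.max() + 5 * fwhm or grid.max() < e.min() - 5 * fwhm):
        warnings.warn("spectrum window does not overlap any line; zero spectrum")
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        g = np.exp(-((grid[None, :] - e[sel][:, None]) ** 2) / (2 * sigma**2))
        decomposition[b] = (f[sel][:, None] * g).sum(axis=0) * norm
    total = decomposition.sum(axis=0)
    return Spectrum(grid=grid, total=total, bins=edges, decomposition=decomposition, fwhm=fwhm)


@dataclass
class Selection:
    sample_id: int
    mch_state: int  # spin-free MCH state index


def select_initial_states(
    records: VerticalExcitationSet,
    window: Tuple[float, float] = (2.8, 3.2),
    seed: int = 0,
    n_select: Optional[int] = None,
) -> Tuple[list, dict]:
    """Stochastic initial-state selection based on oscillator strengths.

    Default mode accepts each eligible (sample, state) pair with probability
    ``f / f_max`` over the eligible set (global f_max).  When ``n_select`` is
    given, exactly that many pairs are drawn without replacement with
    probability proportional to ``f`` instead.

    Returns the selections and a tally dict (per-state counts and totals).
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("energy window must be ordered")
    rng = np.random.default_rng(seed)
    e = records.energies
    f = records.fosc
    eligible = (e >= lo) & (e <= hi) & (f > 0)
    tallies: dict = {"n_eligible": int(eligible.sum()), "per_state": {}}
    if not eligible.any():
        warnings.warn("no eligible states inside the excitation window")
        return [], tallies
    samp_idx, state_pos = np.where(eligible)
    f_el = f[samp_idx, state_pos]
    if n_select is None:
        accept = rng.random(f_el.size) < f_el / f_el.max()
        chosen = np.where(accept)[0]
    else:
        if n_select > f_el.size:
            raise ValueError(
                f"cannot draw {n_select} from {f_el.size} eligible pairs"
            )
        chosen = rng.choice(
            f_el.size, size=n_select, replace=False, p=f_el / f_el.sum()
        )
        chosen = np.sort(chosen)
    selections = [
        Selection(sample_id=int(samp_idx[k]), mch_state=int(records.state_index[state_pos[k]]))
        for k in chosen
    ]
    for s in selections:
        key = int(s.mch_state)
        tallies["per_state"][key] = tallies["per_state"].get(key, 0) + 1
    tallies["n_selected"] = len(selections)
    return selections, tallies
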