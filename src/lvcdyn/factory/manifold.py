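"""Synthetic LVC model generator emulating a Re-azurin-like manifold.

The generator produces a harmonic reference, LVC parameters, and a CT-number
table with the phenomenology of the target system: low-lying charge-separated
(CS) states dominated by Trp->Dmp excitation with small oscillator strengths
and weak SOC, and higher MLCT/IL states with large SOC.  Everything is
reproducible from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Dict, Tuple

import numpy as np

from ..constants import HARTREE_TO_EV
from ..core.basis import ElectronicBasis
from ..core.parameters import LVCModel, LVCParameters
from ..core.reference import HarmonicReference
from .ct_table import CTNumberTable, DEFAULT_FRAGMENTS

__all__ = ["ManifoldSpec", "generate_synthetic_model", "azurin_like_spec"]

#: dominant hole->electron fragment pair per state class
CLASS_PAIRS: Dict[str, Tuple[str, str]] = {
    "CS": ("Trp", "Dmp"),
    "MLCT": ("Re(CO)3", "Dmp"),
    "LLCT": ("His", "Dmp"),
    "IL": ("Dmp", "Dmp"),
    "AC": ("Trp", "Trp"),
    "AMCS": ("Trp", "Re(CO)3"),
    "MC": ("Re(CO)3", "Re(CO)3"),
}


@dataclass
class ManifoldSpec:
    """Recipe for a synthetic manifold.

    Counts, energy ranges (eV), oscillator-strength ranges, and per-class SOC
    magnitude scales (eV); the SOC scale of a singlet-triplet pair is the
    geometric mean of the two class scales.
    """

    singlet_counts: Dict[str, int] = field(default_factory=lambda: {"CS": 2, "MLCT": 2})
    triplet_counts: Dict[str, int] = field(default_factory=lambda: {"CS": 2, "MLCT": 2})
    energy_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"CS": (2.6, 3.4), "MLCT": (3.1, 3.9)}
    )
    fosc_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"CS": (0.0, 0.01), "MLCT": (0.02, 0.12)}
    )
    soc_scales: Dict[str, float] = field(
        default_factory=lambda: {"CS": 2e-4, "MLCT": 0.04}
    )
    n_modes: int = 10
    freq_range: Tuple[float, float] = (300.0, 1700.0)
    kappa_scale: float = 0.06
    lambda_scale: float = 0.02
    transition_ct_scale: float = 0.03
    couple_ground_state: bool = False
    seed: int = 0
    fragments: Tuple[str, ...] = DEFAULT_FRAGMENTS

    def validate(self) -> None:
        n_exc = sum(self.singlet_counts.values()) + sum(self.triplet_counts.values())
        if n_exc < 1:
            raise ValueError("spec must request at least one excited state")
        if any(c < 0 for c in {**self.singlet_counts, **self.triplet_counts}.values()):
            raise ValueError("state counts must be non-negative")
        for cls in set(self.singlet_counts) | set(self.triplet_counts):
            if cls not in CLASS_PAIRS:
                raise ValueError(f"unknown state class {cls!r}")
            lo, hi = self.energy_ranges.get(cls, (None, None))
            if lo is None or hi < lo:
                raise ValueError(f"missing or unordered energy range for class {cls!r}")
        if self.n_modes < 1:
            raise ValueError("need at least one normal mode")
        if self.freq_range[1] < self.freq_range[0] or self.freq_range[0] <= 0:
            raise ValueError("frequency range must be positive and ordered")


def azurin_like_spec(seed: int = 0, n_modes: int = 30) -> ManifoldSpec:
    """A manifold resembling the Re-azurin model at configurable scale:
    ~20 singlets + ~17 triplets across the CS/MLCT/IL/LLCT/MC classes."""
    return ManifoldSpec(
        singlet_counts={"CS": 5, "MLCT": 7, "IL": 2, "LLCT": 2, "MC": 3},
        triplet_counts={"CS": 4, "MLCT": 6, "IL": 4, "LLCT": 1, "MC": 1, "AC": 1},
        energy_ranges={
            "CS": (2.6, 3.5),
            "MLCT": (3.1, 4.1),
            "IL": (2.9, 4.3),
            "LLCT": (3.6, 4.0),
            "MC": (3.8, 4.4),
            "AC": (3.3, 3.6),
        },
        fosc_ranges={
            "CS": (0.0005, 0.011),
            "MLCT": (0.003, 0.11),
            "IL": (0.001, 0.01),
            "LLCT": (0.0, 0.016),
            "MC": (0.001, 0.032),
            "AC": (0.0, 0.002),
        },
        soc_scales={
            "CS": 2e-4,
            "MLCT": 0.05,
            "IL": 0.02,
            "LLCT": 0.01,
            "MC": 0.04,
            "AC": 1e-4,
        },
        n_modes=n_modes,
        seed=seed,
    )


def _random_reference(spec: ManifoldSpec, rng: np.random.Generator) -> HarmonicReference:
    f = spec.n_modes
    n_atoms = ceil((f + 6) / 3)
    r_ref = rng.uniform(-3.0, 3.0, size=(n_atoms, 3))
    masses = rng.uniform(1.0, 30.0, size=n_atoms)
    raw = rng.standard_normal((3 * n_atoms, f))
    k, _ = np.linalg.qr(raw)
    k = k[:, :f]
    omega = np.sort(rng.uniform(*spec.freq_range, size=f))
    return HarmonicReference(r_ref=r_ref, masses=masses, omega=omega, K=k)


def generate_synthetic_model(spec: ManifoldSpec) -> LVCModel:
    """Generate a reproducible synthetic LVC model from a manifold spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    reference = _random_reference(spec, rng)
    f = spec.n_modes

    # draw states, sort by energy within each multiplicity, label S1../T1..
    def draw_states(counts: Dict[str, int]):
        energies, classes = [], []
        for cls in sorted(counts):
            for _ in range(counts[cls]):
                energies.append(rng.uniform(*spec.energy_ranges[cls]))
                classes.append(cls)
        order = np.argsort(energies)
        return [energies[i] for i in order], [classes[i] for i in order]

    s_e, s_cls = draw_states(spec.singlet_counts)
    t_e, t_cls = draw_states(spec.triplet_counts)
    ns, nt = 1 + len(s_e), len(t_e)
    labels = ["S0"] + [f"S{i + 1}" for i in range(len(s_e))] + [
        f"T{i + 1}" for i in range(nt)
    ]
    basis = ElectronicBasis(ns, nt, labels)
    classes = ["GS"] + s_cls + t_cls
    n_sf = basis.n_spinfree

    epsilon = np.array([0.0] + s_e + t_e)
    kappa = rng.normal(0.0, spec.kappa_scale, size=(n_sf, f))
    kappa[0, :] = 0.0  # the reference geometry is the ground-state minimum

    lam = np.zeros((n_sf, n_sf, f))
    mult = basis.multiplicities
    for n in range(n_sf):
        for m in range(n + 1, n_sf):
            if mult[n] != mult[m]:
                continue
            if not spec.couple_ground_state and 0 in (n, m):
                continue
            v = rng.normal(0.0, spec.lambda_scale, size=f)
            lam[n, m] = lam[m, n] = v

    # complex Hermitian SOC: fill singlet-triplet blocks, mirror-conjugate
    d = basis.dim
    soc = np.zeros((d, d), dtype=complex)
    sf_of = basis.spinfree_index
    for i in range(d):
        for j in range(i + 1, d):
            ni, nj = sf_of[i], sf_of[j]
            if mult[ni] == mult[nj]:
                continue  # only singlet-triplet SOC is generated
            if 0 in (ni, nj):
                continue  # ground-state SOC removed
            scale = float(
                np.sqrt(spec.soc_scales.get(classes[ni], 0.0) * spec.soc_scales.get(classes[nj], 0.0))
            )
            val = scale * (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
            soc[i, j] = val
            soc[j, i] = np.conj(val)

    # transition dipoles from per-class oscillator-strength ranges:
    # f_osc = (2/3) * dE[hartree] * |mu|^2  (atomic units)
    dipoles = np.zeros((3, n_sf, n_sf))
    for n in range(1, ns):
        lo, hi = spec.fosc_ranges.get(classes[n], (0.0, 0.0))
        fosc = rng.uniform(lo, hi)
        de_h = epsilon[n] / HARTREE_TO_EV
        mu = np.sqrt(1.5 * fosc / de_h) if de_h > 0 else 0.0
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dipoles[:, 0, n] = dipoles[:, n, 0] = mu * direction

    # CT-number table: dominant pair >= 0.9 for the class, remainder spread
    frag_idx = {fr: i for i, fr in enumerate(spec.fragments)}
    nf = len(spec.fragments)
    omega = np.zeros((n_sf, n_sf, nf, nf))
    for n in range(1, n_sf):
        a, b = CLASS_PAIRS[classes[n]]
        w = rng.uniform(0.90, 0.97)
        omega[n, n, frag_idx[a], frag_idx[b]] = w
        rest = rng.uniform(0.0, (1.0 - w) / 2, size=2)
        for r in rest:
            ra, rb = rng.integers(0, nf, size=2)
            omega[n, n, ra, rb] += r
    for n in range(1, n_sf):
        for m in range(n + 1, n_sf):
            if mult[n] != mult[m]:
                continue
            ra, rb = CLASS_PAIRS[classes[n]]
            val = rng.uniform(0.0, spec.transition_ct_scale)
            omega[n, m, frag_idx[ra], frag_idx[rb]] += val
            omega[m, n, frag_idx[ra], frag_idx[rb]] += val
    ct = CTNumberTable(fragments=spec.fragments, omega=omega, ground_state_index=0)

    params = LVCParameters(
        basis=basis, epsilon=epsilon, kappa=kappa, lam=lam, soc=soc, dipoles=dipoles
    )
    model = LVCModel(reference=reference, params=params, ct_table=ct)
    model.classes = classes  # type: ignore[attr-defined]
    return model
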