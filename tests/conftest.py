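"""Shared fixtures: toy references, synthetic models, crossing toys."""
from __future__ import annotations

import numpy as np
import pytest

from lvcdyn.core import (
    ElectronicBasis,
    HarmonicReference,
    LVCModel,
    LVCParameters,
)
from lvcdyn.factory import ManifoldSpec, generate_synthetic_model


def make_reference(n_atoms: int, n_modes: int, seed: int = 0) -> HarmonicReference:
    """Random but valid harmonic reference."""
    rng = np.random.default_rng(seed)
    masses = rng.uniform(1.0, 25.0, n_atoms)
    raw = rng.standard_normal((3 * n_atoms, n_modes))
    k, _ = np.linalg.qr(raw)
    k = k[:, :n_modes]
    return HarmonicReference(
        r_ref=rng.uniform(-2.0, 2.0, (n_atoms, 3)),
        masses=masses,
        omega=np.sort(rng.uniform(300.0, 1800.0, n_modes)),
        K=k,
    )


def single_mode_reference(omega_cm: float = 1200.0, mass: float = 6.0) -> HarmonicReference:
    return HarmonicReference(
        r_ref=[[0.0, 0.0, 0.0]],
        masses=[mass],
        omega=[omega_cm],
        K=[[1.0], [0.0], [0.0]],
    )


def crossing_toy(v_soc: float = 0.02) -> LVCModel:
    """1-mode singlet/triplet crossing in a single-passage regime:
    S1 tilted towards a crossing with T1 at Q ~ 0.67."""
    basis = ElectronicBasis(2, 1)
    ref = single_mode_reference(600.0)
    p = LVCParameters.zeros(basis, 1)
    p.epsilon = np.array([0.0, 2.2, 2.0])
    p.kappa[1, 0] = -0.25
    p.kappa[2, 0] = 0.05
    for ms_idx in (2, 3, 4):  # couple S1 to the three T1 components
        p.soc[1, ms_idx] = v_soc
        p.soc[ms_idx, 1] = v_soc
    return LVCModel(ref, p)


@pytest.fixture
def toy_reference() -> HarmonicReference:
    return make_reference(3, 3, seed=1)


@pytest.fixture
def small_model() -> LVCModel:
    return generate_synthetic_model(ManifoldSpec(seed=42))


@pytest.fixture
def gapped_model() -> LVCModel:
    """Three singlets with a 2 eV protected gap around the running surface."""
    basis = ElectronicBasis(3, 0)
    rng = np.random.default_rng(2)
    ref = make_reference(4, 6, seed=2)
    p = LVCParameters.zeros(basis, 6)
    p.epsilon = np.array([0.0, 2.0, 4.0])
    p.kappa[1] = rng.normal(0, 0.05, 6)
    p.kappa[2] = rng.normal(0, 0.05, 6)
    lam = rng.normal(0, 0.02, 6)
    p.lam[1, 2] = p.lam[2, 1] = lam
    return LVCModel(ref, p)
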