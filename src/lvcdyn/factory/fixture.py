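"""Packaged vertical-excitation fixture (energies, oscillator strengths,
fragment CT percentages) for the Trp/Re-complex model manifold.

The table was transcribed by hand once into a versioned CSV shipped with the
package; a checksum guards against accidental edits.  The fixture provides
an LVC parameter skeleton (vertical shifts filled, kappa/lambda/SOC zero)
plus the corresponding CT-number table and oscillator strengths.
"""
from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ..core.basis import ElectronicBasis
from ..core.parameters import LVCParameters
from .ct_table import CTNumberTable, DEFAULT_FRAGMENTS

__all__ = ["Table1Fixture", "load_table1_fixture"]

_FIXTURE_SHA256 = "bfe1476a170ec5ff590e49bc09287d5da3221913cea77390c5efc12f10bc6a6f"

# CSV column -> (hole fragment, electron fragment)
_PAIR_COLUMNS = {
    "trp_trp": ("Trp", "Trp"),
    "trp_dmp": ("Trp", "Dmp"),
    "trp_re": ("Trp", "Re(CO)3"),
    "his_dmp": ("His", "Dmp"),
    "dmp_dmp": ("Dmp", "Dmp"),
    "re_dmp": ("Re(CO)3", "Dmp"),
    "re_re": ("Re(CO)3", "Re(CO)3"),
}


@dataclass
class Table1Fixture:
    params: LVCParameters  # skeleton: epsilon filled, kappa/lambda/SOC zero
    ct_table: CTNumberTable
    fosc: np.ndarray  # (n_excited_singlets,) oscillator strengths
    characters: list  # published character label per spin-free state (S0: "GS")


def load_table1_fixture(n_modes: int = 0) -> Table1Fixture:
    """Load the packaged fixture.

    ``n_modes`` sets the mode dimension of the returned (zero) kappa/lambda
    arrays so the skeleton can be combined with a harmonic reference.
    """
    ref = resources.files("lvcdyn.data") / "vertical_excitations.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            "vertical_excitations.csv checksum mismatch - fixture was modified"
        )
    rows = [
        r
        for r in csv.DictReader(
            (l for l in raw.decode().splitlines() if not l.startswith("#"))
        )
    ]
    singlets = [r for r in rows if int(r["mult"]) == 1]
    triplets = [r for r in rows if int(r["mult"]) == 3]
    ns, nt = len(singlets) + 1, len(triplets)
    labels = ["S0"] + [r["label"] for r in singlets] + [r["label"] for r in triplets]
    basis = ElectronicBasis(ns, nt, labels)
    params = LVCParameters.zeros(basis, n_modes)
    params.epsilon = np.array(
        [0.0] + [float(r["E_eV"]) for r in singlets] + [float(r["E_eV"]) for r in triplets]
    )
    fosc = np.array([float(r["fosc"]) for r in singlets])

    fragments = DEFAULT_FRAGMENTS
    frag_idx = {f: i for i, f in enumerate(fragments)}
    n_sf = basis.n_spinfree
    omega = np.zeros((n_sf, n_sf, len(fragments), len(fragments)))
    characters = ["GS"]
    for k, r in enumerate(singlets + triplets, start=1):
        for col, (a, b) in _PAIR_COLUMNS.items():
            omega[k, k, frag_idx[a], frag_idx[b]] = float(r[col]) / 100.0
        characters.append(r["character"])
    # S0 is exempt from the positive-diagonal-sum invariant
    ct = CTNumberTable(fragments=fragments, omega=omega, ground_state_index=0)
    return Table1Fixture(params=params, ct_table=ct, fosc=fosc, characters=characters)
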