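"""State-character classification from fragment CT-number rows.

Hole->electron fragment pairs map onto seven character classes:

    Trp->Dmp        CS    (charge separated)
    Re(CO)3->Dmp    MLCT  (metal-to-ligand charge transfer)
    His->Dmp        LLCT  (ligand-ligand charge transfer)
    Dmp->Dmp        IL    (intraligand)
    Trp->Re(CO)3    AMCS  (amino acid - metal charge separated)
    Trp->Trp        AC    (amino acid centered)
    Re(CO)3->Re(CO)3 MC   (metal centered)

Any other pair, or an all-zero row, is labelled "Others".
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

__all__ = ["CLASS_OF_PAIR", "CLASS_PRECEDENCE", "classify_character", "class_fractions", "pair_fraction"]

CLASS_OF_PAIR = {
    ("Trp", "Dmp"): "CS",
    ("Re(CO)3", "Dmp"): "MLCT",
    ("His", "Dmp"): "LLCT",
    ("Dmp", "Dmp"): "IL",
    ("Trp", "Re(CO)3"): "AMCS",
    ("Trp", "Trp"): "AC",
    ("Re(CO)3", "Re(CO)3"): "MC",
}

#: tie-break order when two fragment pairs carry exactly equal weight
CLASS_PRECEDENCE = ["CS", "MLCT", "LLCT", "IL", "AMCS", "AC", "MC", "Others"]


def _pair_class(fragments: Sequence[str], a: int, b: int) -> str:
    return CLASS_OF_PAIR.get((fragments[a], fragments[b]), "Others")


def classify_character(ct_row: np.ndarray, fragments: Sequence[str]) -> str:
    """Class label of the largest fragment-pair weight in ``ct_row``.

    ``ct_row`` is an (n_frag, n_frag) CT-number matrix for one state; ties
    are broken by :data:`CLASS_PRECEDENCE`.
    """
    row = np.asarray(ct_row, dtype=float)
    nf = len(fragments)
    if row.shape != (nf, nf):
        raise ValueError(f"ct row has shape {row.shape}, expected ({nf}, {nf})")
    if np.all(row == 0):
        return "Others"
    if np.any(row < 0):
        raise ValueError("CT weights must be non-negative")
    best = row.max()
    candidates = [
        _pair_class(fragments, a, b)
        for a, b in zip(*np.where(np.isclose(row, best, rtol=0, atol=1e-12)))
    ]
    return min(candidates, key=CLASS_PRECEDENCE.index)


def pair_fraction(
    ct_row: np.ndarray, fragments: Sequence[str], pair: Tuple[str, str]
) -> float:
    """Weight of one hole->electron fragment pair normalized by the row total."""
    row = np.asarray(ct_row, dtype=float)
    total = row.sum()
    if total <= 0:
        return 0.0
    a = list(fragments).index(pair[0])
    b = list(fragments).index(pair[1])
    return float(row[a, b] / total)


def class_fractions(ct_row: np.ndarray, fragments: Sequence[str]) -> dict:
    """Normalized weight per character class (including "Others")."""
    row = np.asarray(ct_row, dtype=float)
    total = row.sum()
    out = {c: 0.0 for c in CLASS_PRECEDENCE}
    if total <= 0:
        return out
    nf = len(fragments)
    for a in range(nf):
        for b in range(nf):
            out[_pair_class(fragments, a, b)] += float(row[a, b] / total)
    return out
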