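"""Text format for LVC models and CT-number tables.

Key-block layout: a ``[header]`` with counts and unit declarations, geometry
/ frequency / mode-matrix blocks for the harmonic reference, then sparse
parameter records, one per line:

    [epsilon]   mult state value
    [kappa]     mult state mode value
    [lambda]    mult state1 state2 mode value
    [soc_real]  i j value      (spin-expanded indices, upper triangle)
    [soc_imag]  i j value
    [dm_x|y|z]  i j value      (spin-free indices, upper triangle)

State indices are 0-based within their multiplicity block; mode and matrix
indices are 0-based.  ``#`` starts a comment; blank lines are ignored.  The
writer emits canonical sorted order with 17-significant-digit floats, so
files round-trip byte-for-byte.  A missing SOC block yields a zero SOC
matrix with a warning.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from ..core.basis import ElectronicBasis
from ..core.parameters import LVCModel, LVCParameters
from ..core.reference import HarmonicReference
from ..factory.ct_table import CTNumberTable

__all__ = ["read_model", "write_model", "read_ct_table", "write_ct_table"]

_MAGIC = "# lvcdyn LVC model format v1"
_CT_MAGIC = "# lvcdyn CT table format v1"


class ModelFormatError(ValueError):
    """Malformed model file; message carries line number and block."""


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_model(model: LVCModel, path) -> None:
    """Serialize a model (reference + parameters) to the canonical text form."""
    ref = model.reference
    p = model.params
    basis = p.basis
    lines = [_MAGIC, "[header]"]
    lines += [
        f"n_atoms {ref.n_atoms}",
        f"n_modes {ref.n_modes}",
        f"n_singlets {basis.n_singlets}",
        f"n_triplets {basis.n_triplets}",
        "units energy=eV length=Angstrom mass=amu frequency=cm-1 dipole=au",
    ]
    lines.append("[geometry]")
    for a in range(ref.n_atoms):
        x, y, z = ref.r_ref[a]
        lines.append(f"{_fmt(ref.masses[a])} {_fmt(x)} {_fmt(y)} {_fmt(z)}")
    lines.append("[frequencies]")
    lines += [_fmt(w) for w in ref.omega]
    lines.append("[kmatrix]")
    for row in ref.K:
        lines.append(" ".join(_fmt(v) for v in row))
    lines.append("[labels]")
    lines += list(basis.labels)

    mult = basis.multiplicities
    offsets = {1: 0, 3: basis.n_singlets}

    def ms_idx(n):  # (mult, index within multiplicity block)
        m = int(mult[n])
        return m, n - offsets[m]

    lines.append("[epsilon]")
    for n in range(basis.n_spinfree):
        m, i = ms_idx(n)
        lines.append(f"{m} {i} {_fmt(p.epsilon[n])}")
    lines.append("[kappa]")
    for n in range(basis.n_spinfree):
        m, i = ms_idx(n)
        for k in range(ref.n_modes):
            if p.kappa[n, k] != 0.0:
                lines.append(f"{m} {i} {k} {_fmt(p.kappa[n, k])}")
    lines.append("[lambda]")
    for n in range(basis.n_spinfree):
        for mm in range(n + 1, basis.n_spinfree):
            if mult[n] != mult[mm]:
                continue
            m, i = ms_idx(n)
            _, j = ms_idx(mm)
            for k in range(ref.n_modes):
                if p.lam[n, mm, k] != 0.0:
                    lines.append(f"{m} {i} {j} {k} {_fmt(p.lam[n, mm, k])}")
    lines.append("[soc_real]")
    d = basis.dim
    for i in range(d):
        for j in range(i, d):
            if p.soc[i, j].real != 0.0:
                lines.append(f"{i} {j} {_fmt(p.soc[i, j].real)}")
    lines.append("[soc_imag]")
    for i in range(d):
        for j in range(i, d):
            if p.soc[i, j].imag != 0.0:
                lines.append(f"{i} {j} {_fmt(p.soc[i, j].imag)}")
    for comp, tag in enumerate(("dm_x", "dm_y", "dm_z")):
        lines.append(f"[{tag}]")
        for i in range(basis.n_spinfree):
            for j in range(i, basis.n_spinfree):
                if p.dipoles[comp, i, j] != 0.0:
                    lines.append(f"{i} {j} {_fmt(p.dipoles[comp, i, j])}")
    lines.append("[end]")
    Path(path).write_text("\n".join(lines) + "\n")


def _iter_blocks(text: str):
    """Yield (block_name, [(lineno, tokens), ...]) pairs."""
    block = None
    rows: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if block is not None:
                yield block, rows
            block = line[1:-1]
            rows = []
            continue
        if block is None:
            raise ModelFormatError(f"line {lineno}: data before any block header")
        rows.append((lineno, line.split()))
    if block is not None:
        yield block, rows


def _parse_floats(rows, block, n_cols):
    out = []
    for lineno, toks in rows:
        if len(toks) != n_cols:
            raise ModelFormatError(
                f"line {lineno} in [{block}]: expected {n_cols} fields, got {len(toks)}"
            )
        try:
            out.append([float(t) for t in toks])
        except ValueError as exc:
            raise ModelFormatError(f"line {lineno} in [{block}]: {exc}") from None
    return out


def read_model(path) -> LVCModel:
    """Read a model from the text format (CT table, if any, is separate)."""
    text = Path(path).read_text()
    blocks = {}
    for name, rows in _iter_blocks(text):
        if name in blocks:
            raise ModelFormatError(f"duplicate block [{name}]")
        blocks[name] = rows
    if "header" not in blocks:
        raise ModelFormatError("missing [header] block")
    header = {}
    for lineno, toks in blocks["header"]:
        if len(toks) < 2:
            raise ModelFormatError(f"line {lineno} in [header]: malformed entry")
        header[toks[0]] = toks[1]
    try:
        n_atoms = int(header["n_atoms"])
        n_modes = int(header["n_modes"])
        ns = int(header["n_singlets"])
        nt = int(header["n_triplets"])
    except KeyError as exc:
        raise ModelFormatError(f"[header] missing required count {exc}") from None

    for req in ("geometry", "frequencies", "kmatrix", "epsilon"):
        if req not in blocks:
            raise ModelFormatError(f"missing [{req}] block")

    geo = _parse_floats(blocks["geometry"], "geometry", 4)
    if len(geo) != n_atoms:
        raise ModelFormatError(
            f"[geometry] has {len(geo)} rows, header says {n_atoms} atoms"
        )
    geo = np.asarray(geo)
    masses, r_ref = geo[:, 0], geo[:, 1:]
    freq = _parse_floats(blocks["frequencies"], "frequencies", 1)
    if len(freq) != n_modes:
        raise ModelFormatError(
            f"[frequencies] has {len(freq)} rows, header says {n_modes} modes"
        )
    omega = np.asarray(freq).ravel()
    krows = _parse_floats(blocks["kmatrix"], "kmatrix", n_modes)
    if len(krows) != 3 * n_atoms:
        raise ModelFormatError(
            f"[kmatrix] has {len(krows)} rows, expected {3 * n_atoms}"
        )
    reference = HarmonicReference(r_ref=r_ref, masses=masses, omega=omega, K=np.asarray(krows))

    labels = [toks[0] for _, toks in blocks.get("labels", [])]
    basis = ElectronicBasis(ns, nt, labels)
    params = LVCParameters.zeros(basis, n_modes)
    offsets = {1: 0, 3: ns}
    counts = {1: ns, 3: nt}

    def state_index(lineno, block, m, i):
        m, i = int(m), int(i)
        if m not in offsets:
            raise ModelFormatError(f"line {lineno} in [{block}]: multiplicity {m} not 1 or 3")
        if not 0 <= i < counts[m]:
            raise ModelFormatError(
                f"line {lineno} in [{block}]: state index {i} out of range for multiplicity {m}"
            )
        return offsets[m] + i

    for lineno, toks in blocks["epsilon"]:
        if len(toks) != 3:
            raise ModelFormatError(f"line {lineno} in [epsilon]: expected 3 fields")
        n = state_index(lineno, "epsilon", toks[0], toks[1])
        params.epsilon[n] = float(toks[2])
    for lineno, toks in blocks.get("kappa", []):
        if len(toks) != 4:
            raise ModelFormatError(f"line {lineno} in [kappa]: expected 4 fields")
        n = state_index(lineno, "kappa", toks[0], toks[1])
        params.kappa[n, int(toks[2])] = float(toks[3])
    for lineno, toks in blocks.get("lambda", []):
        if len(toks) != 5:
            raise ModelFormatError(f"line {lineno} in [lambda]: expected 5 fields")
        n = state_index(lineno, "lambda", toks[0], toks[1])
        m = state_index(lineno, "lambda", toks[0], toks[2])
        v = float(toks[4])
        params.lam[n, m, int(toks[3])] = v
        params.lam[m, n, int(toks[3])] = v
    if "soc_real" not in blocks and "soc_imag" not in blocks:
        warnings.warn(f"{path}: no SOC block found; using zero SOC")
    for tag, part in (("soc_real", 1.0), ("soc_imag", 1.0j)):
        for lineno, toks in blocks.get(tag, []):
            if len(toks) != 3:
                raise ModelFormatError(f"line {lineno} in [{tag}]: expected 3 fields")
            i, j = int(toks[0]), int(toks[1])
            if not (0 <= i < basis.dim and 0 <= j < basis.dim):
                raise ModelFormatError(
                    f"line {lineno} in [{tag}]: index out of range for dimension {basis.dim}"
                )
            v = float(toks[2]) * part
            params.soc[i, j] += v
            if i != j:
                params.soc[j, i] += np.conj(v)
    for comp, tag in enumerate(("dm_x", "dm_y", "dm_z")):
        for lineno, toks in blocks.get(tag, []):
            if len(toks) != 3:
                raise ModelFormatError(f"line {lineno} in [{tag}]: expected 3 fields")
            i, j = int(toks[0]), int(toks[1])
            params.dipoles[comp, i, j] = params.dipoles[comp, j, i] = float(toks[2])
    params.validate()
    return LVCModel(reference=reference, params=params)


def write_ct_table(table: CTNumberTable, path) -> None:
    lines = [_CT_MAGIC, "[fragments]"]
    lines += list(table.fragments)
    lines += ["[ground_state]", str(table.ground_state_index), "[omega]"]
    n = table.n_states
    nf = len(table.fragments)
    for i in range(n):
        for j in range(i, n):
            for a in range(nf):
                for b in range(nf):
                    if table.omega[i, j, a, b] != 0.0:
                        lines.append(f"{i} {j} {a} {b} {_fmt(table.omega[i, j, a, b])}")
    lines.append("[end]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct_table(path, n_states: Optional[int] = None) -> CTNumberTable:
    text = Path(path).read_text()
    blocks = dict(_iter_blocks(text))
    if "fragments" not in blocks or "omega" not in blocks:
        raise ModelFormatError("CT table requires [fragments] and [omega] blocks")
    fragments = tuple(toks[0] for _, toks in blocks["fragments"])
    gsi = 0
    if "ground_state" in blocks and blocks["ground_state"]:
        gsi = int(blocks["ground_state"][0][1][0])
    entries = _parse_floats(blocks["omega"], "omega", 5)
    if n_states is None:
        n_states = int(max(e[1] for e in entries)) + 1 if entries else 1
    nf = len(fragments)
    omega = np.zeros((n_states, n_states, nf, nf))
    for i, j, a, b, v in entries:
        i, j, a, b = int(i), int(j), int(a), int(b)
        omega[i, j, a, b] = v
        omega[j, i, a, b] = v
    return CTNumberTable(fragments=fragments, omega=omega, ground_state_index=gsi)
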