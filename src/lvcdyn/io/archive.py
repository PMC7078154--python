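"""Ensemble archives: HDF5 (default) with a plain-JSON text fallback.

Complex arrays are stored as paired real/imaginary datasets for
portability.  The schema is versioned; loading an archive with an unknown
schema raises.  ``precision="single"`` downcasts the bulky transform
matrices (U, U_diag) to single precision to meet size budgets; the default
is lossless double precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..dynamics.ensemble import SCHEMA_VERSION, Ensemble

__all__ = ["save_ensemble", "load_ensemble"]

_COMMON_FIELDS = [
    "times", "Q", "c_diag", "active", "E_mch", "E_diag",
    "E_kin", "E_total", "valid", "initial_mch_states",
]
_FULL_FIELDS = _COMMON_FIELDS + ["Qdot", "U", "U_diag"]
_ANALYSIS_FIELDS = _COMMON_FIELDS + [
    "c_mch", "c_diab", "p_active_mch", "p_active_diab", "dterm_mch", "dterm_diab",
]
_BULKY = {
    "U", "U_diag", "Q", "Qdot", "c_diag", "c_mch", "c_diab",
    "p_active_mch", "p_active_diab", "dterm_mch", "dterm_diab",
    "E_mch", "E_diag", "E_kin", "E_total",
}


class ArchiveError(RuntimeError):
    pass


def save_ensemble(
    ens: Ensemble, path, precision: str = "double", mode: str = "full"
) -> None:
    """Write an ensemble archive; format chosen by extension
    (.h5/.hdf5 -> HDF5, anything else -> JSON text).

    ``mode="full"`` stores the per-step transforms losslessly;
    ``mode="analysis"`` stores precomputed representation data instead
    (several times smaller; sufficient for every analysis operation).
    ``precision="single"`` downcasts the bulky per-step arrays.
    """
    if precision not in ("double", "single"):
        raise ValueError("precision must be 'double' or 'single'")
    if mode not in ("full", "analysis"):
        raise ValueError("mode must be 'full' or 'analysis'")
    if mode == "analysis" and not ens.is_reduced:
        from ..analysis.populations import reduce_ensemble_arrays

        reduced = reduce_ensemble_arrays(ens)
        for key, val in reduced.items():
            setattr(ens, key, val)
    if mode == "full" and ens.is_reduced:
        raise ValueError("cannot write a full archive from a reduced ensemble")
    path = Path(path)
    meta = {
        "mode": mode,
        "schema_version": ens.schema_version,
        "seed": int(ens.seed),
        "model_hash": ens.model_hash,
        "settings": ens.settings,
        "n_singlets": int(ens.n_singlets),
        "n_triplets": int(ens.n_triplets),
        "invalid_reasons": list(ens.invalid_reasons),
        "hops": [[list(h) for h in traj_hops] for traj_hops in ens.hops],
        "precision": precision,
    }
    fields = _FULL_FIELDS if mode == "full" else _ANALYSIS_FIELDS
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(ens, path, meta, precision, fields)
    else:
        _save_json(ens, path, meta, precision, fields)


def _cast(name: str, arr: np.ndarray, precision: str) -> np.ndarray:
    if precision == "single" and name in _BULKY:
        if np.iscomplexobj(arr):
            return arr.astype(np.complex64)
        return arr.astype(np.float32)
    return arr


def _save_h5(ens, path, meta, precision, fields):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps(meta)
        f.attrs["schema_version"] = ens.schema_version
        for name in fields:
            arr = _cast(name, getattr(ens, name), precision)
            kw = {"compression": "gzip", "compression_opts": 4} if arr.ndim >= 2 else {}
            if np.iscomplexobj(arr):
                f.create_dataset(f"{name}_re", data=arr.real, **kw)
                f.create_dataset(f"{name}_im", data=arr.imag, **kw)
            else:
                f.create_dataset(name, data=arr, **kw)


def _save_json(ens, path, meta, precision, fields):
    payload = {"meta": meta}
    for name in fields:
        arr = _cast(name, getattr(ens, name), precision)
        if np.iscomplexobj(arr):
            payload[name] = {
                "re": arr.real.tolist(),
                "im": arr.imag.tolist(),
                "dtype": "complex",
            }
        else:
            payload[name] = {"data": arr.tolist(), "dtype": str(arr.dtype)}
    Path(path).write_text(json.dumps(payload))


def load_ensemble(path) -> Ensemble:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        meta, arrays = _load_h5(path)
    else:
        meta, arrays = _load_json(path)
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ArchiveError(
            f"archive schema version {version} not supported (expected {SCHEMA_VERSION})"
        )
    return Ensemble(
        n_singlets=meta["n_singlets"],
        n_triplets=meta["n_triplets"],
        invalid_reasons=meta["invalid_reasons"],
        hops=[[tuple(h) for h in traj] for traj in meta["hops"]],
        seed=meta["seed"],
        model_hash=meta["model_hash"],
        settings=meta["settings"],
        schema_version=version,
        **arrays,
    )


def _load_h5(path):
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ArchiveError(f"cannot open archive {path}: {exc}") from exc
    with f:
        meta = json.loads(f.attrs["meta"])
        fields = _FULL_FIELDS if meta.get("mode", "full") == "full" else _ANALYSIS_FIELDS
        arrays = {}
        for name in fields:
            try:
                if name in f:
                    arrays[name] = f[name][...]
                else:
                    arrays[name] = f[f"{name}_re"][...] + 1j * f[f"{name}_im"][...]
            except KeyError as exc:
                raise ArchiveError(f"archive missing dataset {name!r}") from exc
    arrays["valid"] = arrays["valid"].astype(bool)
    arrays["active"] = arrays["active"].astype(np.int64)
    return meta, arrays


def _load_json(path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ArchiveError(f"corrupt JSON archive {path}: {exc}") from exc
    meta = payload["meta"]
    fields = _FULL_FIELDS if meta.get("mode", "full") == "full" else _ANALYSIS_FIELDS
    arrays = {}
    for name in fields:
        if name not in payload:
            raise ArchiveError(f"archive missing dataset {name!r}")
        entry = payload[name]
        if entry.get("dtype") == "complex":
            arrays[name] = np.asarray(entry["re"]) + 1j * np.asarray(entry["im"])
        else:
            arrays[name] = np.asarray(entry["data"], dtype=entry["dtype"])
    arrays["valid"] = arrays["valid"].astype(bool)
    arrays["active"] = arrays["active"].astype(np.int64)
    return meta, arrays
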