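"""Snapshot containers, configuration files and run metadata.

Snapshots are NumPy ``.npz`` archives with a JSON sidecar (same stem,
``.json``) holding the grid spec, parameters, time and RNG seed; save/load
round-trips are bit-exact.  Run configurations are flat ``key = value``
text files; unknown keys are rejected (fail fast).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .grid import Grid2D
from .hydro import HydroState
from .mpf import MPFParams, TissueState
from .patic_core import MaterialParams

__all__ = ["save_state", "load_state", "read_config", "write_config"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_state(state, path, extra_meta: dict | None = None) -> Path:
    """Write a HydroState or TissueState to ``path`` (.npz + .json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"grid": {"nx": state.grid.nx, "ny": state.grid.ny,
                     "dx": state.grid.dx, "dy": state.grid.dy},
            "time": state.time, **(extra_meta or {})}
    if isinstance(state, HydroState):
        arrays = {"psi": state.psi, "zeta": state.zeta}
        if state.pinned is not None:
            arrays["pinned"] = state.pinned
        meta["kind"] = "hydro"
        meta["step_count"] = state.step_count
        meta["meta"] = _jsonable(state.meta)
    elif isinstance(state, TissueState):
        arrays = {"phi": state.phi, "thetas": state.thetas}
        meta["kind"] = "tissue"
        meta["meta"] = _jsonable(state.meta)
    else:
        raise TypeError(f"cannot save {type(state).__name__}")
    np.savez(path, **arrays)
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def load_state(path):
    """Load a snapshot written by :func:`save_state`.  Truncated or
    mismatched files raise with a clear message."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
    mpath = _meta_path(path)
    if not path.exists() or not mpath.exists():
        raise FileNotFoundError(f"snapshot incomplete: need {path} and {mpath}")
    try:
        meta = json.loads(mpath.read_text())
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
    except Exception as e:  # zipfile/json errors on truncation
        raise IOError(f"corrupt or truncated snapshot {path}: {e}") from e
    g = Grid2D(**meta["grid"])
    if meta["kind"] == "hydro":
        st = HydroState(g, arrays["psi"], arrays["zeta"], meta["time"],
                        meta.get("step_count", 0), arrays.get("pinned"),
                        meta.get("meta", {}))
    elif meta["kind"] == "tissue":
        st = TissueState(g, arrays["phi"], arrays["thetas"], meta["time"],
                         None, meta.get("meta", {}))
    else:
        raise ValueError(f"unknown snapshot kind {meta['kind']!r}")
    return st, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# flat key = value configuration files

_KNOWN_KEYS = (
    {f.name for f in dataclasses.fields(MaterialParams)}
    | {f.name for f in dataclasses.fields(MPFParams)}
    | {"nx", "ny", "dx", "dy", "seed", "preset", "n_cells", "steps",
       "sample_every", "ell", "R_D", "dx_sep", "dt", "out"}
)


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file.  ``#`` starts a comment
    (units annotations live there); unknown keys are an error."""
    out: dict = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _KNOWN_KEYS:
            raise KeyError(f"{path}:{ln}: unknown configuration key {key!r}")
        try:
            out[key] = json.loads(val)
        except json.JSONDecodeError:
            out[key] = val
    return out


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for k in sorted(cfg):
        if k not in _KNOWN_KEYS:
            raise KeyError(f"refusing to write unknown key {k!r}")
        lines.append(f"{k} = {json.dumps(cfg[k])}")
    path.write_text("\n".join(lines) + "\n")
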