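"""Trace CSV and configuration file I/O.

Trace dialect: comma-separated UTF-8, a mandatory header row
``t_s,<species...>[,A_<reactant>]``, values printed to 12 significant
digits, and optional ``# provenance:`` comment lines (JSON payload) that
the reader uses to restore metadata.  Writing a trace that was read back
reproduces the file byte-for-byte at the printed precision.

Configurations are YAML (JSON being a YAML subset) with the block described
in :func:`phikin.core.problem_from_dict`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .core import ConfigError, IrradiationSetup, SchemeSpec, SpeciesTable, problem_from_dict
from .numeric import KineticTrace

__all__ = ["write_trace", "read_trace", "load_config", "load_problem"]

_FLOAT_FMT = "%.12g"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN has no JSON literal
        return None
    return obj


def write_trace(trace: KineticTrace, path) -> None:
    """Write a trace as CSV with a ``# provenance:`` metadata header."""
    path = Path(path)
    frame = trace.to_frame()
    lines = ["# provenance: " + json.dumps(_jsonable(trace.metadata), sort_keys=True)]
    lines.append(",".join(frame.columns))
    for row in frame.itertuples(index=False):
        lines.append(",".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path) -> KineticTrace:
    """Read a trace CSV written by :func:`write_trace` (or any file in the
    same dialect).  Malformed rows raise ValueError naming the line number."""
    path = Path(path)
    metadata: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("provenance:"):
                try:
                    metadata = json.loads(body[len("provenance:"):].strip())
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: malformed provenance JSON: {exc}") from exc
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            if not header or header[0] != "t_s":
                raise ValueError(f"line {lineno}: header must start with 't_s', got {line!r}")
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise ValueError(
                f"line {lineno}: expected {len(header)} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric value: {exc}") from exc
    if header is None or not rows:
        raise ValueError("trace file contains no data rows")
    data = np.asarray(rows, dtype=float)
    t = data[:, 0]
    absorbance = None
    absorbance_col = metadata.get("absorbance_column")
    conc: dict[str, np.ndarray] = {}
    for j, name in enumerate(header[1:], start=1):
        if name == absorbance_col:
            absorbance = data[:, j]
        else:
            conc[name] = data[:, j]
    # reconstruct the reactant absorbance from Beer-Lambert metadata
    if absorbance is None:
        eps = metadata.get("epsilon_x")
        l_irr = metadata.get("l_irr")
        reactant = metadata.get("reactant")
        if eps and l_irr and reactant in conc:
            absorbance = eps * l_irr * conc[reactant]
    metadata.setdefault("noisy", bool(metadata.get("noise_sigma", 0)))
    return KineticTrace(t=t, concentrations=conc, absorbance=absorbance, metadata=metadata)


def load_config(path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError("config", f"cannot parse {path}: {exc}") from exc
    if not isinstance(payload, Mapping):
        raise ConfigError("config", f"{path} does not contain a mapping")
    return dict(payload)


def load_problem(path) -> tuple[SchemeSpec, SpeciesTable, IrradiationSetup]:
    """Load and validate a configuration file into domain objects."""
    return problem_from_dict(load_config(path))
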