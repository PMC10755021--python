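"""Tidy-CSV panel I/O and declarative constraint configuration.

Panel dialect (long format, one row per observation)::

    # sabrekit panel v1
    ligand,pathway,log_conc_M,response_pct,weight
    CpdTst1,P1,-10,0.31,1

``log_conc_M`` is log10 molar; ``response_pct`` is percent of the assay
maximum (fractions internally). ``weight`` is optional. Values are written
with 12 significant digits so a write/read round trip is lossless at that
precision.

Constraint files are YAML with one block per model parameter::

    log_kd:
      fixed: {CpdTst1: -7.0, CpdTst2: -6.5}
    efficacy:
      shared: per-ligand
    gain:
      shared: per-pathway
      bounds: [0.01, 1000]
    efficacy_r0: {fixed: 0}
    hill: {fixed: 1}
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .fitting import ConstraintSpec, Fixed, ResponseCurve, Shared, PARAM_NAMES

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "load_constraints",
    "constraints_from_dict",
    "write_json",
]

PANEL_HEADER_COMMENT = "# sabrekit panel v1"
REQUIRED_COLUMNS = ("ligand", "pathway", "log_conc_M", "response_pct")

_CONC_SCALES = {"log10M": None, "M": 0.0, "nM": -9.0}


class PanelFormatError(ValueError):
    """Malformed panel CSV (message carries the offending line number)."""


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_panel(panel: Sequence[ResponseCurve], path, overwrite: bool = True):
    """Write a panel in the tidy CSV dialect (responses as percent)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    has_weight = any(c.weight is not None for c in panel)
    cols = list(REQUIRED_COLUMNS) + (["weight"] if has_weight else [])
    with open(path, "w", newline="") as fh:
        fh.write(PANEL_HEADER_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for c in panel:
            w = c.weight if c.weight is not None else np.ones(len(c))
            for i in range(len(c)):
                row = [
                    c.ligand_id,
                    c.pathway_id,
                    _fmt(c.log_conc[i]),
                    _fmt(100.0 * c.response[i]),
                ]
                if has_weight:
                    row.append(_fmt(w[i]))
                writer.writerow(row)
    return path


def read_panel(path, conc_units: str = "log10M") -> list[ResponseCurve]:
    """Read a tidy panel CSV into ResponseCurve objects.

    ``conc_units`` selects how the concentration column is interpreted:
    ``log10M`` (default), ``M`` or ``nM`` (linear, converted to log10 molar).
    Schema and value errors carry 1-based line numbers.
    """
    if conc_units not in _CONC_SCALES:
        raise ValueError(
            f"conc_units must be one of {sorted(_CONC_SCALES)}, got {conc_units!r}"
        )
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        header = None
        idx = {}
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise PanelFormatError(
                        f"{path}:{lineno}: missing required column(s) "
                        f"{missing}; found {header}"
                    )
                idx = {c: header.index(c) for c in header}
                continue
            if len(fields) != len(header):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            rec = {"_line": lineno}
            rec["ligand"] = fields[idx["ligand"]].strip()
            rec["pathway"] = fields[idx["pathway"]].strip()
            for col in ("log_conc_M", "response_pct") + (
                ("weight",) if "weight" in idx else ()
            ):
                raw = fields[idx[col]].strip()
                try:
                    rec[col] = float(raw)
                except ValueError:
                    raise PanelFormatError(
                        f"{path}:{lineno}: column {col!r}: cannot parse "
                        f"{raw!r} as a number"
                    ) from None
            rows.append(rec)
    if not rows:
        raise PanelFormatError(f"{path}: no data rows")

    log_offset = _CONC_SCALES[conc_units]
    groups: dict[tuple[str, str], list] = {}
    order = []
    for rec in rows:
        key = (rec["ligand"], rec["pathway"])
        if key not in groups:
            groups[key] = []
            order.append(key)
        conc = rec["log_conc_M"]
        if log_offset is not None:
            if conc <= 0:
                raise PanelFormatError(
                    f"{path}:{rec['_line']}: linear concentration must be > 0 "
                    f"to take log10, got {conc}"
                )
            conc = np.log10(conc) + log_offset
        groups[key].append((conc, rec["response_pct"] / 100.0, rec.get("weight")))

    panel = []
    for key in order:
        pts = groups[key]
        logc = np.array([p[0] for p in pts])
        resp = np.array([p[1] for p in pts])
        weights = None
        if any(p[2] is not None for p in pts):
            weights = np.array([1.0 if p[2] is None else p[2] for p in pts])
        panel.append(
            ResponseCurve(
                ligand_id=key[0],
                pathway_id=key[1],
                log_conc=logc,
                response=resp,
                weight=weights,
            )
        )
    return panel


# ---------------------------------------------------------------------------
# constraints


def _rule_from_config(name: str, cfg) -> Fixed | Shared:
    if isinstance(cfg, (int, float)):
        return Fixed(float(cfg))
    if not isinstance(cfg, Mapping):
        raise ValueError(
            f"constraint for {name!r} must be a number or mapping, got {cfg!r}"
        )
    keys = set(cfg) - {"bounds", "initial"}
    if keys == {"fixed"}:
        v = cfg["fixed"]
        if isinstance(v, Mapping):
            return Fixed({str(k): float(x) for k, x in v.items()})
        return Fixed(float(v))
    if keys == {"shared"}:
        bounds = tuple(cfg["bounds"]) if "bounds" in cfg else None
        initial = cfg.get("initial")
        return Shared(str(cfg["shared"]), bounds=bounds, initial=initial)
    if keys == {"free"} and cfg.get("free") in (True, None):
        bounds = tuple(cfg["bounds"]) if "bounds" in cfg else None
        return Shared("per-curve", bounds=bounds, initial=cfg.get("initial"))
    raise ValueError(
        f"constraint for {name!r} must declare exactly one of "
        f"fixed/shared/free, got {sorted(cfg)}"
    )


def constraints_from_dict(cfg: Mapping) -> ConstraintSpec:
    """Build a ConstraintSpec from a parsed configuration mapping."""
    unknown = set(cfg) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(
            f"unknown parameter(s) in constraint config: {sorted(unknown)}; "
            f"valid names: {PARAM_NAMES}"
        )
    if "log_kd" not in cfg:
        raise ValueError("constraint config must declare a rule for log_kd")
    kwargs = {name: _rule_from_config(name, cfg[name]) for name in cfg}
    return ConstraintSpec(**kwargs)


def load_constraints(path) -> ConstraintSpec:
    """Load a YAML constraint file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: constraint file must be a YAML mapping")
    return constraints_from_dict(cfg)


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
    return path
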