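"""Plain-text table readers/writers with unit-tagged headers, plus run
configuration.

All files are UTF-8 text; lines starting with ``#`` are comments, except
``# key: value`` pairs which carry metadata (concentration, label, ...).
Columns are comma- or whitespace-separated.  Units are declared in the
header name — ``T_K``/``T_C`` for temperatures, ``conc_M``/``conc_uM``/
``conc_nM`` for concentrations — and converted to the canonical kelvin /
molar on load.  Round trips are stable to full double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .binding import BindingIsotherm, EmissionSpectrum
from .core_thermo import CpCurve
from .hydro import CsDistribution

__all__ = [
    "TableFormatError",
    "read_table",
    "write_table",
    "read_thermogram",
    "write_thermogram",
    "read_cs_distribution",
    "write_cs_distribution",
    "read_isotherm",
    "write_isotherm",
    "read_spectrum",
    "write_spectrum",
    "RunConfig",
    "load_config",
]


class TableFormatError(ValueError):
    """Malformed table, with the offending line number in the message."""


_UNIT_CONVERTERS = {
    "K": lambda v: v,
    "C": lambda v: v + 273.15,
    "M": lambda v: v,
    "mM": lambda v: v * 1e-3,
    "uM": lambda v: v * 1e-6,
    "nM": lambda v: v * 1e-9,
}


def _canonical_column(name: str):
    """(canonical name, converter) for a unit-tagged column header."""
    if "_" in name:
        stem, unit = name.rsplit("_", 1)
        if unit in _UNIT_CONVERTERS and stem.lower() in (
            "t", "temp", "temperature", "conc", "concentration", "c",
        ):
            canon = "T_K" if unit in ("K", "C") else "conc_M"
            return canon, _UNIT_CONVERTERS[unit]
    return name, _UNIT_CONVERTERS["K"]  # identity


def read_table(path) -> tuple[list[str], dict[str, str], np.ndarray]:
    """Parse a delimited text table.

    Returns (canonical column names, metadata dict from ``# key: value``
    comments, data array of shape (rows, columns)) with unit-tagged
    columns converted to kelvin / molar.  Raises
    :class:`TableFormatError` naming the line of the first malformed row.
    """
    path = Path(path)
    names: list[str] | None = None
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        fields = [f for f in s.replace(",", " ").split() if f]
        if names is None:
            try:
                [float(f) for f in fields]
            except ValueError:
                names = fields
                continue
            names = [f"col{i}" for i in range(len(fields))]
        try:
            values = [float(f) for f in fields]
        except ValueError as err:
            raise TableFormatError(
                f"{path.name}, line {lineno}: non-numeric field ({err})"
            ) from None
        if len(values) != len(names):
            raise TableFormatError(
                f"{path.name}, line {lineno}: expected {len(names)} columns, "
                f"got {len(values)}"
            )
        rows.append(values)
    if names is None or not rows:
        raise TableFormatError(f"{path.name}: no data rows")
    data = np.asarray(rows, dtype=float)
    canon = []
    for ci, name in enumerate(names):
        cname, conv = _canonical_column(name)
        canon.append(cname)
        data[:, ci] = conv(data[:, ci])
    return canon, meta, data


def write_table(path, names, data, meta: dict | None = None) -> None:
    """Write a table in the same dialect :func:`read_table` parses.

    Values are printed with 17 significant digits so a read-back
    reproduces them exactly.
    """
    path = Path(path)
    lines = []
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(" ".join(names))
    for row in np.atleast_2d(np.asarray(data, dtype=float)):
        lines.append(" ".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


# -- format-specific wrappers -----------------------------------------

def write_thermogram(path, curve: CpCurve) -> None:
    write_table(
        path, ["T_K", "cp_J_mol_K"], np.column_stack([curve.T_grid, curve.cp]),
        meta={"total_C_M": f"{curve.total_C:.17g}", "label": curve.params_label},
    )


def read_thermogram(path) -> CpCurve:
    names, meta, data = read_table(path)
    if "T_K" not in names:
        raise TableFormatError(f"{Path(path).name}: no temperature column")
    t = data[:, names.index("T_K")]
    cp_cols = [i for i, n in enumerate(names) if n != "T_K"]
    return CpCurve(
        T_grid=t, cp=data[:, cp_cols[0]],
        total_C=float(meta.get("total_C_M", "nan")),
        params_label=meta.get("label", ""),
    )


def write_cs_distribution(path, dist: CsDistribution) -> None:
    write_table(
        path, ["s_S", "c_of_s"], np.column_stack([dist.s_grid, dist.c_values]),
        meta={"total_C_M": f"{dist.total_C:.17g}", "label": dist.label},
    )


def read_cs_distribution(path) -> CsDistribution:
    names, meta, data = read_table(path)
    return CsDistribution(
        s_grid=data[:, 0], c_values=data[:, 1],
        total_C=float(meta.get("total_C_M", "nan")),
        label=meta.get("label", ""),
    )


def write_isotherm(path, iso: BindingIsotherm) -> None:
    write_table(
        path, ["conc_M", "signal"],
        np.column_stack([iso.titrant_conc, iso.signal]),
        meta={
            "fixed_conc_M": f"{iso.fixed_conc:.17g}",
            "temperature_K": f"{iso.temperature:.17g}",
            "ionic_strength": iso.ionic_strength_label,
        },
    )


def read_isotherm(path) -> BindingIsotherm:
    names, meta, data = read_table(path)
    if "conc_M" not in names:
        raise TableFormatError(f"{Path(path).name}: no concentration column")
    ci = names.index("conc_M")
    si = [i for i in range(len(names)) if i != ci][0]
    return BindingIsotherm(
        titrant_conc=data[:, ci], signal=data[:, si],
        fixed_conc=float(meta.get("fixed_conc_M", "nan")),
        temperature=float(meta.get("temperature_K", "nan")),
        ionic_strength_label=meta.get("ionic_strength", ""),
    )


def write_spectrum(path, spec: EmissionSpectrum) -> None:
    write_table(
        path, ["wavelength_nm", "intensity"],
        np.column_stack([spec.wavelength, spec.intensity]),
    )


def read_spectrum(path) -> EmissionSpectrum:
    _, _, data = read_table(path)
    return EmissionSpectrum(wavelength=data[:, 0], intensity=data[:, 1])


# -- run configuration -------------------------------------------------

_CONFIG_KEYS = {
    "inputs", "label", "temperature_K", "temperature_C", "ionic_strength",
    "concentrations_M", "concentrations_uM", "params", "seed", "output_dir",
}


@dataclass
class RunConfig:
    """Validated run configuration with canonical (K, M) units."""

    inputs: list[str] = field(default_factory=list)
    label: str = ""
    temperature_K: float = float("nan")
    ionic_strength: str = ""
    concentrations_M: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, units canonicalized."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    cfg.inputs = list(raw.get("inputs", []))
    cfg.label = str(raw.get("label", ""))
    if "temperature_C" in raw:
        cfg.temperature_K = float(raw["temperature_C"]) + 273.15
    if "temperature_K" in raw:
        cfg.temperature_K = float(raw["temperature_K"])
    cfg.ionic_strength = str(raw.get("ionic_strength", ""))
    concs = [float(c) for c in raw.get("concentrations_M", [])]
    concs += [float(c) * 1e-6 for c in raw.get("concentrations_uM", [])]
    cfg.concentrations_M = concs
    cfg.params = dict(raw.get("params", {}))
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = str(raw.get("output_dir", "."))
    return cfg
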