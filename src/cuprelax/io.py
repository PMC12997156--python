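"""Delimited-text readers/writers and run configuration.

All scientific I/O is plain text: profiles and spectra as whitespace-
delimited columns with '#' metadata/comment headers, run configuration as
YAML with explicit units on every physical quantity.  Write-then-read is
lossless on canonical form; malformed rows are reported with their line
numbers.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epr import Spectrum
from .nmrd import NMRDProfile
from .o17 import O17Dataset

__all__ = [
    "ParseError",
    "read_profile",
    "write_profile",
    "read_o17",
    "write_o17",
    "read_spectrum",
    "write_spectrum",
    "RunConfig",
    "read_config",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


def _read_table(path, n_cols_min: int):
    meta: dict = {}
    rows: list[list[float]] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            try:
                vals = [float(x) for x in parts]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from None
            if len(vals) < n_cols_min:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {n_cols_min} "
                    f"columns, got {len(vals)}"
                )
            rows.append(vals)
            linenos.append(lineno)
    return rows, meta, linenos


def write_profile(profile: NMRDProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# freq_MHz  temp_K  r1_mM_s  sigma\n")
        for _, row in profile.data.iterrows():
            fh.write(
                f"{row.freq_MHz:.17g}  {row.temp_K:.17g}  "
                f"{row.r1_mM_s:.17g}  {row.sigma:.17g}\n"
            )


def read_profile(path) -> NMRDProfile:
    rows, _, _ = _read_table(path, 3)
    df = pd.DataFrame(
        [r[:4] + [math.nan] * (4 - len(r[:4])) for r in rows],
        columns=list(NMRDProfile.COLUMNS),
    )
    return NMRDProfile(df)


def write_o17(ds: O17Dataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("# temp_K  R2r_s  dwr_rad_s  sigma_R2r  sigma_dwr\n")
        for _, row in ds.data.iterrows():
            fh.write(
                f"{row.temp_K:.17g}  {row.R2r_s:.17g}  {row.dwr_rad_s:.17g}  "
                f"{row.sigma_R2r:.17g}  {row.sigma_dwr:.17g}\n"
            )


def read_o17(path) -> O17Dataset:
    rows, _, _ = _read_table(path, 3)
    df = pd.DataFrame(
        [r[:5] + [math.nan] * (5 - len(r[:5])) for r in rows],
        columns=list(O17Dataset.COLUMNS),
    )
    return O17Dataset(df)


def write_spectrum(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        for key, val in spec.metadata.items():
            fh.write(f"# {key} = {val}\n")
        for x, y in zip(spec.abscissa, spec.ordinate):
            fh.write(f"{x:.17g}  {y:.17g}\n")


def read_spectrum(path) -> Spectrum:
    rows, meta, linenos = _read_table(path, 2)
    arr = np.asarray(rows, dtype=float)
    if len(arr) and not np.all(np.diff(arr[:, 0]) > 0):
        bad = linenos[int(np.nonzero(np.diff(arr[:, 0]) <= 0)[0][0]) + 1]
        raise ParseError(
            f"{path}: abscissa not strictly increasing at line {bad}"
        )
    return Spectrum(arr[:, 0], arr[:, 1], meta)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "command": None,
    "preset": None,
    "seed": None,
    "output_dir": None,
    "verbosity": None,
    "inputs": None,
    "noise_frac": None,
    "mw_freq_GHz": "GHz",
    "tau_R_ps": "ps",
    "free": None,
    "n_multistart": None,
}

#: accepted units per physical parameter in the parameter table
_UNIT_WHITELIST = {
    "tau_S": {"ns"},
    "tau_R_298": {"ps"},
    "tau_M_298": {"ns"},
    "E_R": {"kJ/mol"},
    "dH_M": {"kJ/mol"},
    "dS_M": {"J/mol/K"},
    "A_O": {"1e8 rad/s"},
    "A_H": {"1e6 rad/s"},
    "r_MH": {"A"},
    "a": {"A"},
    "D_298": {"1e-9 m2/s"},
    "E_D": {"kJ/mol"},
    "q": {"count"},
    "OH_conc": {"mol/L"},
    "B0": {"T"},
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``parameters`` maps a physical parameter name to a dict with keys
    ``value``, ``unit``, ``vary`` (bool), optional ``min``/``max`` and a
    free-text ``note`` (provenance/citation).  Unknown keys anywhere are
    rejected with the nearest valid key named; unit-less physical values
    are rejected.
    """

    command: str
    seed: int = 0
    preset: str | None = None
    output_dir: str = "."
    verbosity: int = 1
    inputs: dict = dc_field(default_factory=dict)
    parameters: dict = dc_field(default_factory=dict)
    extra: dict = dc_field(default_factory=dict)


def _reject_unknown(key: str, valid, context: str) -> None:
    match = difflib.get_close_matches(key, list(valid), n=1)
    hint = f"; did you mean {match[0]!r}?" if match else ""
    raise ParseError(f"unknown {context} key {key!r}{hint}")


def read_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "command" not in raw:
        raise ParseError(f"{path}: config must be a mapping with a 'command' key")
    params = raw.pop("parameters", {}) or {}
    known_top = set(_KNOWN_KEYS) | {"parameters"}
    extra = {}
    for key in list(raw):
        if key not in known_top:
            _reject_unknown(key, known_top | set(_UNIT_WHITELIST), "config")
    for name, spec in params.items():
        if name not in _UNIT_WHITELIST:
            _reject_unknown(name, _UNIT_WHITELIST, "parameter")
        if not isinstance(spec, dict) or "value" not in spec:
            raise ParseError(f"parameter {name!r} must be a mapping with 'value'")
        unit = spec.get("unit")
        if unit is None:
            raise ParseError(
                f"parameter {name!r} has no unit; accepted: "
                f"{sorted(_UNIT_WHITELIST[name])}"
            )
        if unit not in _UNIT_WHITELIST[name]:
            raise ParseError(
                f"parameter {name!r}: unit {unit!r} not in "
                f"{sorted(_UNIT_WHITELIST[name])}"
            )
    return RunConfig(
        command=str(raw["command"]),
        seed=int(raw.get("seed", 0)),
        preset=raw.get("preset"),
        output_dir=str(raw.get("output_dir", ".")),
        verbosity=int(raw.get("verbosity", 1)),
        inputs=raw.get("inputs") or {},
        parameters=params,
        extra=extra,
    )
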