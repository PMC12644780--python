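"""Reading and writing spectra, distributions and decompositions.

File conventions
----------------
* Spectrum CSV: columns ``frequency_hz, z_real_ohm, z_imag_ohm``. Other column
  names are mapped through a :class:`CsvDialect`; instruments that export
  ``-Im(Z)`` as positive numbers set ``imag_negated=True``.
* DRT CSV: ``tau_s, weight_ohm`` data columns preceded by ``#`` header lines
  carrying the grid bounds, R_inf and regularization metadata so the file
  round-trips to a full :class:`~tissuedrt.core.DRTResult`.
* Decomposition JSON: ``{"components": [{"a", "mu_s", "sigma", "R_pk"}, ...],
  "R_inf", "R_0"}``.

Both CSV writers emit 17 significant digits so read(write(x)) reproduces x
beyond 12 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DecompositionModel,
    DRTResult,
    GaussianComponent,
    ImpedanceSpectrum,
    RelaxationGrid,
    ValidationError,
)

__all__ = [
    "CsvDialect",
    "FormatError",
    "read_spectrum",
    "write_spectrum",
    "read_drt",
    "write_drt",
    "read_decomposition",
    "write_decomposition",
]


class FormatError(ValueError):
    """The file does not follow the expected column/field layout."""


@dataclass(frozen=True)
class CsvDialect:
    """Column-name mapping for spectrum CSV files."""

    frequency: str = "frequency_hz"
    real: str = "z_real_ohm"
    imag: str = "z_imag_ohm"
    #: True when the file stores -Im(Z) (i.e. capacitive points are positive).
    imag_negated: bool = False


DEFAULT_DIALECT = CsvDialect()


def read_spectrum(path: str | Path, dialect: CsvDialect = DEFAULT_DIALECT) -> ImpedanceSpectrum:
    """Read a spectrum CSV, sort by ascending frequency and validate it.

    Raises
    ------
    FormatError
        If a required column is missing or a cell is not numeric (the error
        names the column / 1-based data row).
    ValidationError
        For duplicate frequencies or other invariant violations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (dialect.frequency, dialect.real, dialect.imag):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    cols = {}
    for col in (dialect.frequency, dialect.real, dialect.imag):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(values.index[df[col].isna()])
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        cols[col] = values.to_numpy(dtype=float)
    f = cols[dialect.frequency]
    im = cols[dialect.imag]
    if dialect.imag_negated:
        im = -im
    z = cols[dialect.real] + 1j * im
    order = np.argsort(f, kind="stable")
    if np.any(np.diff(f[order]) == 0):
        raise ValidationError(f"{path}: duplicate frequency values")
    meta = {"source": str(path), "imag_negated_on_read": dialect.imag_negated}
    return ImpedanceSpectrum(f[order], z[order], meta)


def write_spectrum(spectrum: ImpedanceSpectrum, path: str | Path,
                   dialect: CsvDialect = DEFAULT_DIALECT) -> Path:
    """Write a spectrum CSV (always in the as-measured sign convention)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            dialect.frequency: spectrum.frequencies,
            dialect.real: spectrum.impedance.real,
            dialect.imag: spectrum.impedance.imag,
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:  # surface the offending path
        raise OSError(f"cannot write spectrum to {path}: {exc}") from exc
    return path


def write_drt(drt: DRTResult, path: str | Path) -> Path:
    """Write a DRT CSV with a ``#``-prefixed metadata header."""
    path = Path(path)
    grid = drt.grid
    header = (
        f"# tau_inf_s = {grid.tau_inf:.17g}\n"
        f"# tau_sup_s = {grid.tau_sup:.17g}\n"
        f"# m_bins = {grid.M}\n"
        f"# r_inf_ohm = {drt.R_inf:.17g}\n"
        f"# lambda_reg = {drt.lambda_reg:.17g}\n"
        f"# residual_norm_ohm = {drt.residual_norm:.17g}\n"
    )
    body = pd.DataFrame({"tau_s": grid.centers, "weight_ohm": drt.weights})
    try:
        with open(path, "w") as fh:
            fh.write(header)
            body.to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write DRT to {path}: {exc}") from exc
    return path


def read_drt(path: str | Path) -> DRTResult:
    """Read a DRT CSV produced by :func:`write_drt`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        try:
            key, value = line[1:].split("=", 1)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header line {line!r}") from exc
        meta[key.strip()] = float(value)
    required = {"tau_inf_s", "tau_sup_s", "m_bins", "r_inf_ohm"}
    missing = required - meta.keys()
    if missing:
        raise FormatError(f"{path}: missing header fields {sorted(missing)}")
    df = pd.read_csv(path, skiprows=n_header)
    for col in ("tau_s", "weight_ohm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    grid = RelaxationGrid(meta["tau_inf_s"], meta["tau_sup_s"], int(meta["m_bins"]))
    return DRTResult(
        grid,
        df["weight_ohm"].to_numpy(dtype=float),
        meta["r_inf_ohm"],
        meta.get("lambda_reg", float("nan")),
        meta.get("residual_norm_ohm", float("nan")),
    )


def write_decomposition(model: DecompositionModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "components": [
            {"a": c.a, "mu_s": c.mu, "sigma": c.sigma, "R_pk": c.R_pk}
            for c in model.components
        ],
        "R_inf": model.R_inf,
        "R_0": model.R_0,
        "rss": model.rss,
        "n": model.n,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_decomposition(path: str | Path) -> DecompositionModel:
    path = Path(path)
    payload = json.loads(path.read_text())
    try:
        components = [
            GaussianComponent(c["a"], c["mu_s"], c["sigma"])
            for c in payload["components"]
        ]
        return DecompositionModel(
            components,
            payload["R_inf"],
            payload.get("rss", float("nan")),
            payload.get("n", 0),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing decomposition field {exc}") from exc
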