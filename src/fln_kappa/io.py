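"""Readers and writers for the spectrum-file dialect, manifests and tables.

Spectrum files are plain delimited text: '#'-prefixed ``key: value`` header
lines (excitation_cm1, pressure_gpa, temperature_k, sample, effectors)
followed by two tab-separated numeric columns (wavenumber_cm1, intensity).
Floats are printed with repr precision so write -> read round-trips
bit-exactly.  Decimal point is '.'; no locale handling.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import EFFECTOR_LABELS, FLNSpectrum

__all__ = [
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "load_experiment",
    "write_results_table",
    "read_results_table",
    "config_hash",
]

_REQUIRED_KEYS = ("excitation_cm1", "pressure_gpa", "temperature_k", "sample", "effectors")
_FLOAT_KEYS = ("excitation_cm1", "pressure_gpa", "temperature_k")


class SpectrumParseError(ValueError):
    """A spectrum or manifest file violated the dialect."""


def write_spectrum(spectrum: FLNSpectrum, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "# fln-kappa spectrum v1",
        f"# excitation_cm1: {float(spectrum.excitation)!r}",
        f"# pressure_gpa: {float(spectrum.pressure)!r}",
        f"# temperature_k: {float(spectrum.temperature)!r}",
        f"# sample: {spectrum.sample}",
        f"# effectors: {spectrum.effectors}",
    ]
    lines.extend(
        f"{float(w)!r}\t{float(i)!r}"
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities)
    )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum(path: str | Path) -> FLNSpectrum:
    """Parse one spectrum file.

    A strictly descending wavenumber grid is accepted and re-sorted with a
    warning; any other grid disorder, ragged rows, non-numeric fields or
    missing header keys raise :class:`SpectrumParseError` naming the line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split()
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                wavenumbers.append(float(fields[0]))
                intensities.append(float(fields[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric field") from exc
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise SpectrumParseError(f"{path}: missing header key '{key}'")
    typed: dict[str, object] = dict(meta)
    for key in _FLOAT_KEYS:
        try:
            typed[key] = float(meta[key])
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path}: header key '{key}' is not numeric: {meta[key]!r}"
            ) from exc
    wn = np.asarray(wavenumbers)
    inten = np.asarray(intensities)
    if wn.size == 0:
        raise SpectrumParseError(f"{path}: no data rows")
    diffs = np.diff(wn)
    if wn.size >= 2 and not np.all(diffs > 0):
        if np.all(diffs < 0):
            warnings.warn(
                f"{path}: descending wavenumber grid, re-sorting ascending",
                stacklevel=2,
            )
            wn, inten = wn[::-1].copy(), inten[::-1].copy()
        else:
            bad = int(np.flatnonzero(diffs <= 0)[0])
            raise SpectrumParseError(
                f"{path}: wavenumber grid not monotone at data row {bad + 1}"
            )
    return FLNSpectrum(
        wavenumbers=wn,
        intensities=inten,
        excitation=typed["excitation_cm1"],
        pressure=typed["pressure_gpa"],
        temperature=typed["temperature_k"],
        sample=str(typed["sample"]),
        effectors=str(typed["effectors"]),
    )


def load_experiment(manifest_path: str | Path) -> dict[float, list[FLNSpectrum]]:
    """Load a manifest and all its spectra, grouped and sorted by pressure.

    Validates that every referenced file exists, that (pressure, excitation)
    pairs are unique, and that the effector label belongs to the closed
    vocabulary.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    entries = manifest.get("spectra", [])
    if not entries:
        raise SpectrumParseError(f"{manifest_path}: no spectra listed")
    effectors = manifest.get("effectors", "none")
    if effectors not in EFFECTOR_LABELS:
        raise SpectrumParseError(
            f"{manifest_path}: unknown effector label {effectors!r}"
        )
    base = manifest_path.parent
    seen: set[tuple[float, float]] = set()
    groups: dict[float, list[FLNSpectrum]] = {}
    for entry in entries:
        key = (float(entry["pressure_gpa"]), float(entry["excitation_cm1"]))
        if key in seen:
            raise SpectrumParseError(
                f"{manifest_path}: duplicate (pressure, excitation) {key}"
            )
        seen.add(key)
        spath = base / entry["path"]
        if not spath.exists():
            raise SpectrumParseError(f"{manifest_path}: missing file {spath}")
        groups.setdefault(key[0], []).append(read_spectrum(spath))
    for p in groups:
        groups[p].sort(key=lambda s: s.excitation)
    return dict(sorted(groups.items()))


def config_hash(payload: dict) -> str:
    """Short stable hash of a config dict, recorded in output table headers."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _package_version() -> str:
    from . import __version__

    return __version__


def write_results_table(
    df: pd.DataFrame, path: str | Path, config_hash_value: str = ""
) -> Path:
    """Write a TSV with '#' comment headers (config hash, package version)."""
    path = Path(path)
    header = [
        "# fln-kappa results",
        f"# version: {_package_version()}",
        f"# config_hash: {config_hash_value}",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
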