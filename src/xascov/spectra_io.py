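"""Containers and file I/O for XAS spectra and calculated stick spectra.

The :class:`Spectrum` is the universal currency of the pipeline: a strictly
increasing energy grid in eV with unitless absorption values, an edge label,
a normalization flag and free-form provenance metadata.  Every transforming
operation appends one entry to ``meta["history"]`` so a result is auditable
back to its source file.

Energies are eV everywhere.  Files whose energy column looks like keV
(maximum below 100) are rejected rather than silently converted, because a
silent unit change corrupts edge-position arithmetic downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    FormatError,
    GridError,
    RangeError,
    ValidationError,
)

EDGE_LABELS = ("S-K", "Cu-K", "other")
DIALECTS = ("two_column", "xdi_like", "csv")

#: Heuristic: an XAS energy axis in eV sits in the thousands; a maximum below
#: this value indicates a keV-scaled file.
_KEV_SUSPECT_MAX = 100.0

_MIN_POINTS = 8


@dataclass
class Spectrum:
    """An XAS spectrum on a strictly increasing energy grid (eV)."""

    energies: np.ndarray
    intensities: np.ndarray
    edge_label: str = "other"
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.edge_label not in EDGE_LABELS:
            raise ValidationError(
                f"edge_label must be one of {EDGE_LABELS}, got {self.edge_label!r}"
            )
        if self.energies.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("energies and intensities must be 1-D arrays")
        if self.energies.size < _MIN_POINTS:
            raise ValidationError(
                f"a spectrum needs at least {_MIN_POINTS} points, got {self.energies.size}"
            )
        if self.energies.size != self.intensities.size:
            raise ValidationError(
                f"length mismatch: {self.energies.size} energies vs "
                f"{self.intensities.size} intensities"
            )
        if not np.all(np.isfinite(self.energies)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValidationError("energies and intensities must be finite")
        if not np.all(np.diff(self.energies) > 0):
            raise ValidationError("energies must be strictly increasing")
        self.meta.setdefault("history", [])

    # -- provenance ---------------------------------------------------------

    @property
    def history(self) -> list:
        return self.meta["history"]

    def evolve(
        self,
        *,
        energies: np.ndarray | None = None,
        intensities: np.ndarray | None = None,
        normalized: bool | None = None,
        history_entry: str | None = None,
        **meta_updates,
    ) -> "Spectrum":
        """Return a copy with updated fields and an appended history entry."""
        meta = copy.deepcopy(self.meta)
        meta.update(meta_updates)
        if history_entry is not None:
            meta["history"] = list(meta["history"]) + [history_entry]
        return Spectrum(
            energies=self.energies.copy() if energies is None else np.asarray(energies, float),
            intensities=(
                self.intensities.copy() if intensities is None else np.asarray(intensities, float)
            ),
            edge_label=self.edge_label,
            normalized=self.normalized if normalized is None else normalized,
            meta=meta,
        )

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.energies >= lo) & (self.energies <= hi)


@dataclass
class StickSpectrum:
    """Calculated excitations as (energy eV, oscillator strength) pairs."""

    energies: np.ndarray
    strengths: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if self.energies.size != self.strengths.size:
            raise ValidationError("sticks: energy/strength length mismatch")
        if self.energies.size and not np.all(np.isfinite(self.energies)):
            raise ValidationError("stick energies must be finite")
        if self.energies.size and np.any(self.strengths < 0):
            bad = int(np.argmax(self.strengths < 0))
            raise ValidationError(
                f"negative oscillator strength {self.strengths[bad]} at entry {bad}"
            )

    def __len__(self) -> int:
        return int(self.energies.size)


# ---------------------------------------------------------------------------
# parsing


def _numeric_rows(path: Path, dialect: str) -> tuple[list[tuple[int, list[float]]], dict]:
    """Parse a file into (line_number, values) rows plus header metadata."""
    meta: dict = {}
    rows: list[tuple[int, list[float]]] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    lines = text.splitlines()
    start = 0
    if dialect == "csv":
        # skip a non-numeric header line such as "energy,intensity"
        if lines:
            first = lines[0].split(",")[0].strip()
            try:
                float(first)
            except ValueError:
                start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if dialect == "xdi_like":
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
            continue
        parts = stripped.split(",") if dialect == "csv" else stripped.split()
        try:
            values = [float(p) for p in parts if p.strip()]
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: non-numeric field ({exc})") from exc
        if values:
            rows.append((lineno, values))
    return rows, meta


def read_spectrum(
    path: str | Path,
    dialect: str = "two_column",
    edge_label: str = "other",
) -> Spectrum:
    """Read an XAS spectrum from a text file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``two_column`` (whitespace-separated, ``#`` comments), ``xdi_like``
        (``# key: value`` header then two columns) or ``csv`` (header
        ``energy,intensity``).
    edge_label
        One of ``S-K``, ``Cu-K``, ``other``.

    Rows are sorted ascending in energy if needed (recorded in history) and
    duplicate energies are collapsed by averaging their intensities.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    rows, header_meta = _numeric_rows(path, dialect)
    if len(rows) < _MIN_POINTS:
        raise FormatError(
            f"{path}: found {len(rows)} data rows, need at least {_MIN_POINTS}"
        )
    for lineno, values in rows:
        if len(values) < 2:
            raise FormatError(f"{path}, line {lineno}: fewer than 2 numeric columns")
        if not all(np.isfinite(v) for v in values[:2]):
            raise ValidationError(f"{path}, line {lineno}: non-finite value")

    energies = np.array([v[0] for _, v in rows])
    intensities = np.array([v[1] for _, v in rows])

    history = [f"read {path.name} ({dialect})"]
    order = np.argsort(energies, kind="stable")
    if not np.array_equal(order, np.arange(order.size)):
        energies = energies[order]
        intensities = intensities[order]
        history.append("reordered rows into ascending energy")

    uniq, inverse, counts = np.unique(energies, return_inverse=True, return_counts=True)
    if uniq.size != energies.size:
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, intensities)
        intensities = summed / counts
        energies = uniq
        ndup = int(energies.size - uniq.size) or int(np.sum(counts > 1))
        history.append(f"averaged {ndup} duplicated energy value(s)")

    if energies.max() < _KEV_SUSPECT_MAX:
        raise ValidationError(
            f"{path}: maximum energy {energies.max():g} looks like keV; "
            "convert the file to eV before loading"
        )

    meta = dict(header_meta)
    meta["source_file"] = str(path)
    meta["history"] = history
    return Spectrum(energies, intensities, edge_label=edge_label, meta=meta)


def write_spectrum(s: Spectrum, path: str | Path, dialect: str = "two_column") -> None:
    """Write a spectrum to disk at full float precision (round-trip safe)."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    lines = []
    if dialect == "csv":
        lines.append("energy,intensity")
        sep = ","
    else:
        if dialect == "xdi_like":
            for key, value in s.meta.items():
                if key == "history":
                    continue
                lines.append(f"# {key}: {value}")
        sep = " "
    for e, i in zip(s.energies, s.intensities):
        lines.append(f"{e:.17g}{sep}{i:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_sticks(path: str | Path) -> StickSpectrum:
    """Read a two-column (energy, oscillator strength) stick list.

    An empty file yields an empty (valid) :class:`StickSpectrum`; a negative
    strength raises :class:`~xascov.exceptions.ValidationError`.
    """
    path = Path(path)
    rows, _ = _numeric_rows(path, "two_column")
    if not rows:
        return StickSpectrum(np.empty(0), np.empty(0))
    for lineno, values in rows:
        if len(values) < 2:
            raise FormatError(f"{path}, line {lineno}: fewer than 2 numeric columns")
        if values[1] < 0:
            raise ValidationError(
                f"{path}, line {lineno}: negative oscillator strength {values[1]}"
            )
    return StickSpectrum(
        np.array([v[0] for _, v in rows]), np.array([v[1] for _, v in rows])
    )


def write_sticks(sticks: StickSpectrum, path: str | Path) -> None:
    lines = [f"{e:.17g} {f:.17g}" for e, f in zip(sticks.energies, sticks.strengths)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# resampling


def interpolate_to_grid(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly resample a spectrum onto ``grid``.

    Extrapolation is refused: the grid must lie within the spectrum's energy
    range.  Linear interpolation never overshoots near sharp edge features,
    which is why it is the default; callers needing smoother resampling can
    interpolate themselves (``scipy.interpolate``) and rebuild a Spectrum.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < _MIN_POINTS:
        raise ValidationError(f"target grid must be 1-D with >= {_MIN_POINTS} points")
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("target grid must be strictly increasing")
    eps = 1e-9 * max(1.0, abs(s.energies[0]), abs(s.energies[-1]))
    if grid[0] < s.energies[0] - eps or grid[-1] > s.energies[-1] + eps:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends outside spectrum range "
            f"[{s.energies[0]:g}, {s.energies[-1]:g}]; extrapolation is not supported"
        )
    values = np.interp(grid, s.energies, s.intensities)
    return s.evolve(
        energies=grid,
        intensities=values,
        history_entry=(
            f"linear interpolation onto {grid.size}-point grid "
            f"[{grid[0]:g}, {grid[-1]:g}] eV"
        ),
    )
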