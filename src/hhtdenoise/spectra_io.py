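"""Reading and writing one-dimensional spectra in plain tabular text.

A :class:`Spectrum` is the package's core container: an ordered sampling
axis (index, diffraction angle, binding energy, wavelength, ...) paired
with intensity values.  Files are simple one- or two-column text with an
optional single header line; the delimiter (comma, tab or whitespace) is
sniffed per file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_decomposition_table",
    "write_decomposition_table",
]

_DELIMITERS = (",", "\t", None)  # None → any whitespace


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed or validated."""


@dataclass(frozen=True)
class Spectrum:
    """A 1-D sampled signal with a strictly increasing axis.

    Parameters
    ----------
    axis
        Sampling positions, strictly increasing, length ``n >= 3``.
    intensity
        Intensity values (arbitrary units), same length as ``axis``,
        all finite.
    axis_label
        Free-form unit label for the axis (e.g. ``"index"``,
        ``"2theta_deg"``, ``"binding_energy_eV"``).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_label: str = "axis"

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise SpectrumFormatError("axis and intensity must be 1-D")
        if axis.size != intensity.size:
            raise SpectrumFormatError(
                f"axis length {axis.size} != intensity length {intensity.size}"
            )
        if axis.size < 3:
            raise SpectrumFormatError(f"a spectrum needs >= 3 points, got {axis.size}")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(intensity)):
            raise SpectrumFormatError("non-finite values in spectrum")
        if np.any(np.diff(axis) <= 0):
            raise SpectrumFormatError("axis must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.axis.size)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """New spectrum on the same axis with replaced intensities."""
        return Spectrum(self.axis.copy(), np.asarray(intensity, dtype=float),
                        self.axis_label)


def _split_line(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [f.strip() for f in line.split(delimiter)]


def _sniff_delimiter(lines: Sequence[str]) -> str | None:
    """Pick the delimiter whose field count is consistent and maximal."""
    best, best_count = None, 0
    for delim in _DELIMITERS:
        counts = {len(_split_line(ln, delim)) for ln in lines[:20] if ln.strip()}
        counts.discard(0)
        if len(counts) == 1:
            (c,) = counts
            if c > best_count:
                best, best_count = delim, c
    if best_count >= 2:
        return best
    # no delimiter splits every row consistently into columns: pick the one
    # splitting the first line the most, so the per-row field-count check
    # reports the offending line
    first = lines[0]
    ragged = max(_DELIMITERS, key=lambda d: len(_split_line(first, d)))
    if len(_split_line(first, ragged)) >= 2:
        return ragged
    return best


def _is_numeric_row(fields: Iterable[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return False
    return True


def read_spectrum(path: str | Path, dialect: str = "auto",
                  axis_label: str | None = None) -> Spectrum:
    """Read a spectrum from a one- or two-column text file.

    ``dialect`` may be ``"two_column"`` (axis, intensity), ``"single_column"``
    (intensity only; axis becomes 1..n) or ``"auto"`` (decide from the field
    count).  A single leading header line is detected by being non-numeric.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise SpectrumFormatError(f"{path}: empty file")

    delim = _sniff_delimiter([ln for _, ln in lines])
    header_label = None
    first_fields = _split_line(lines[0][1], delim)
    if not _is_numeric_row(first_fields):
        header_label = first_fields[0] if first_fields else None
        lines = lines[1:]
        if not lines:
            raise SpectrumFormatError(f"{path}: header but no data rows")

    ncols = len(_split_line(lines[0][1], delim))
    if dialect == "auto":
        dialect = "single_column" if ncols == 1 else "two_column"
    want = 1 if dialect == "single_column" else 2

    rows = np.empty((len(lines), want))
    for r, (lineno, ln) in enumerate(lines):
        fields = _split_line(ln, delim)
        if len(fields) != ncols:
            raise SpectrumFormatError(
                f"{path}: line {lineno}: expected {ncols} fields, got {len(fields)}"
            )
        if len(fields) < want:
            raise SpectrumFormatError(
                f"{path}: line {lineno}: need {want} columns for dialect {dialect}"
            )
        try:
            rows[r] = [float(f) for f in fields[:want]]
        except ValueError:
            raise SpectrumFormatError(
                f"{path}: line {lineno}: non-numeric value in {fields!r}"
            ) from None

    if rows.shape[0] < 3:
        raise SpectrumFormatError(f"{path}: fewer than 3 data points")

    label = axis_label or header_label or ("index" if want == 1 else "axis")
    if want == 1:
        axis = np.arange(1, rows.shape[0] + 1, dtype=float)
        return Spectrum(axis, rows[:, 0], label)
    return Spectrum(rows[:, 0], rows[:, 1], label)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a two-column CSV (axis, intensity) at full double precision."""
    path = Path(path)
    label = re.sub(r"[\s,]+", "_", spectrum.axis_label) or "axis"
    out = [f"{label},intensity"]
    out += [f"{a:.17g},{v:.17g}" for a, v in zip(spectrum.axis, spectrum.intensity)]
    path.write_text("\n".join(out) + "\n")


def write_decomposition_table(axis: np.ndarray, imfs: Sequence[np.ndarray],
                              residual: np.ndarray, path: str | Path) -> None:
    """Export a decomposition as CSV: axis, IMF_1..IMF_n, residual."""
    path = Path(path)
    header = ["axis"] + [f"IMF_{i + 1}" for i in range(len(imfs))] + ["residual"]
    cols = [np.asarray(axis, float)] + [np.asarray(c, float) for c in imfs]
    cols.append(np.asarray(residual, float))
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise SpectrumFormatError("decomposition columns have unequal lengths")
    rows = [",".join(header)]
    body = np.column_stack(cols)
    rows += [",".join(f"{v:.17g}" for v in row) for row in body]
    Path(path).write_text("\n".join(rows) + "\n")


def read_decomposition_table(path: str | Path):
    """Read a decomposition CSV back as ``(axis, imfs, residual)``."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise SpectrumFormatError(f"{path}: no decomposition rows")
    header = _split_line(lines[0], ",")
    if header[0] != "axis" or header[-1] != "residual":
        raise SpectrumFormatError(f"{path}: not a decomposition table")
    try:
        body = np.array([[float(f) for f in _split_line(ln, ",")] for ln in lines[1:]])
    except ValueError:
        raise SpectrumFormatError(f"{path}: non-numeric decomposition row") from None
    if body.shape[1] != len(header):
        raise SpectrumFormatError(f"{path}: ragged decomposition table")
    axis = body[:, 0]
    imfs = [body[:, j] for j in range(1, body.shape[1] - 1)]
    return axis, imfs, body[:, -1]
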