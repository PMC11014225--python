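"""Chromatogram container and plain-text I/O.

A chromatogram is one breath sample's detector trace: a uniform time grid in
seconds and one detector-intensity value per grid point.  The on-disk dialect
is a two-column CSV ``time_s,intensity`` with a single header line, one file
per sample, named ``<sample_id>.csv``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Stage", "Chromatogram", "read_chromatogram", "write_chromatogram"]

#: Minimum number of grid points for a trace to be analysable at all.
MIN_LENGTH = 16

#: Relative tolerance for grid-uniformity validation.
GRID_RTOL = 1e-9


class Stage(str, enum.Enum):
    """Processing stage of a trace."""

    RAW = "raw"
    DENOISED = "denoised"
    BASELINE_CORRECTED = "baseline_corrected"


class ChromatogramError(ValueError):
    """Raised for malformed traces or files."""


@dataclass(frozen=True)
class Chromatogram:
    """One detector trace on a strictly increasing, uniform time grid.

    Parameters
    ----------
    sample_id : str
        Identifier of the breath sample.
    times : ndarray of float
        Time grid in seconds, strictly increasing and uniform.
    intensities : ndarray of float
        Detector signal, same length as ``times``.
    stage : Stage
        Where in the pre-processing chain this trace sits.
    """

    sample_id: str
    times: np.ndarray
    intensities: np.ndarray
    stage: Stage = Stage.RAW
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "stage", Stage(self.stage))
        if t.ndim != 1 or x.ndim != 1:
            raise ChromatogramError("times and intensities must be 1-D")
        if t.size != x.size:
            raise ChromatogramError(
                f"length mismatch: {t.size} times vs {x.size} intensities"
            )
        if t.size < MIN_LENGTH:
            raise ChromatogramError(
                f"trace too short: {t.size} points (minimum {MIN_LENGTH})"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ChromatogramError("times must be strictly increasing")
        step = dt[0]
        if not np.allclose(dt, step, rtol=GRID_RTOL, atol=step * GRID_RTOL):
            raise ChromatogramError("time grid must be uniform")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ChromatogramError("non-finite values in trace")

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Grid spacing in seconds."""
        return float(self.times[1] - self.times[0])

    def with_intensities(self, intensities: np.ndarray, stage: Stage) -> "Chromatogram":
        """Copy of this trace with new intensities and stage (same grid)."""
        return replace(self, intensities=np.asarray(intensities, float), stage=stage)

    def total_signal(self) -> float:
        """Trapezoidal integral of the positive part, in detector*seconds."""
        return float(np.trapezoid(np.clip(self.intensities, 0.0, None), self.times))


def write_chromatogram(chrom: Chromatogram, directory: str | Path) -> Path:
    """Write ``<sample_id>.csv`` in the two-column dialect; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{chrom.sample_id}.csv"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,intensity\n")
        for t, x in zip(chrom.times, chrom.intensities):
            fh.write(f"{t:.6g},{x:.9g}\n")
    return path


def read_chromatogram(path: str | Path, stage: Stage = Stage.RAW) -> Chromatogram:
    """Read and validate a two-column ``time_s,intensity`` CSV.

    Raises
    ------
    ChromatogramError
        On ragged rows, non-numeric cells (naming the offending line),
        non-monotone times or a non-uniform grid.
    """
    path = Path(path)
    times: list[float] = []
    intensities: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if "time" not in header:
            raise ChromatogramError(f"{path}: line 1: missing 'time_s,intensity' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise ChromatogramError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
            try:
                times.append(float(cells[0]))
                intensities.append(float(cells[1]))
            except ValueError as exc:
                raise ChromatogramError(f"{path}: line {lineno}: non-numeric cell") from exc
    try:
        return Chromatogram(
            sample_id=path.stem,
            times=np.asarray(times),
            intensities=np.asarray(intensities),
            stage=stage,
        )
    except ChromatogramError as exc:
        raise ChromatogramError(f"{path}: {exc}") from exc
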