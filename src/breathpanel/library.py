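"""Compound library: retention-time -> compound-name records.

The default library ships with the package: the 61 breath VOCs identified by
mass spectrometry on the portable GC platform, keyed by retention time in
seconds.  Some compound names occur at two distinct retention times (isomer
pairs eluting twice); every row is treated as a distinct record keyed by its
retention time, and annotations disambiguate duplicates with an ``@<rt>s``
qualifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CompoundLibrary", "load_library", "load_default_library"]

#: Default retention-time match tolerance, seconds.  Half the smallest gap
#: between distinct library RTs in the crowded 190-280 s region is ~4 s.
DEFAULT_TOLERANCE = 3.0


@dataclass(frozen=True)
class CompoundLibrary:
    """Sorted records of (retention_time, name) plus a match tolerance."""

    records: pd.DataFrame  # columns: rt_s, name
    tolerance: float = DEFAULT_TOLERANCE
    duplicates: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        rec = self.records.reset_index(drop=True)
        if not {"rt_s", "name"} <= set(rec.columns):
            raise ValueError("library needs columns rt_s and name")
        if (rec["rt_s"] <= 0).any():
            raise ValueError("retention times must be positive")
        rec = rec.sort_values("rt_s", kind="stable").reset_index(drop=True)
        dup_names = rec["name"][rec["name"].duplicated(keep=False)].unique()
        object.__setattr__(self, "records", rec)
        object.__setattr__(self, "duplicates", tuple(dup_names))
        if len(dup_names):
            warnings.warn(
                f"library contains duplicate compound names: {list(dup_names)}",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rts(self) -> np.ndarray:
        return self.records["rt_s"].to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return self.records["name"].tolist()

    def qualified_names(self) -> list[str]:
        """Names with an ``@<rt>s`` qualifier appended for duplicated names."""
        out = []
        for rt, name in zip(self.rts, self.names):
            out.append(f"{name} @{rt:g}s" if name in self.duplicates else name)
        return out

    def lookup(self, rt: float) -> str | None:
        """Name of the nearest record within tolerance, else None."""
        idx = int(np.argmin(np.abs(self.rts - rt)))
        if abs(self.rts[idx] - rt) <= self.tolerance:
            return self.qualified_names()[idx]
        return None


def load_library(path: str | Path, tolerance: float = DEFAULT_TOLERANCE) -> CompoundLibrary:
    """Load a tab-separated ``rt_s<TAB>name`` library file."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate names in the default library are known
        df = pd.read_csv(path, sep="\t")
        return CompoundLibrary(records=df, tolerance=tolerance)


def load_default_library(tolerance: float = DEFAULT_TOLERANCE) -> CompoundLibrary:
    """The packaged 61-compound breath VOC library."""
    with resources.as_file(
        resources.files("breathpanel").joinpath("data/compound_library.tsv")
    ) as path:
        return load_library(path, tolerance=tolerance)
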