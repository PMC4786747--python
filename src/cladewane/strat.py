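"""Stratigraphic primitives: time bins, taxon ranges and age conventions.

Ages are in Ma and decrease toward the present.  Every per-bin count in the
pipeline uses the same half-open convention: a bin named ``(younger, older]``
covers ages ``a`` with ``older >= a > younger``, so a boundary age belongs to
the younger-side bin deterministically and every age inside the binned span
belongs to exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "BinSequence",
    "TaxonRange",
    "bin_membership",
    "apportion_to_substages",
    "read_ranges",
    "write_ranges",
    "read_bins",
    "write_bins",
]


@dataclass(frozen=True)
class TimeBin:
    """A named stratigraphic interval, closed at the older end.

    Parameters
    ----------
    name:
        Stage/substage label (e.g. ``"Cenomanian"``).
    older, younger:
        Boundary ages in Ma with ``older > younger >= 0``.
    """

    name: str
    older: float
    younger: float

    def __post_init__(self) -> None:
        if not (self.older > self.younger >= 0):
            raise ValueError(
                f"bin {self.name!r}: need older > younger >= 0, "
                f"got older={self.older}, younger={self.younger}"
            )

    @property
    def duration(self) -> float:
        """Bin length in My."""
        return self.older - self.younger

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)

    def contains(self, age: float) -> bool:
        """True iff ``age`` lies in ``(younger, older]``."""
        return self.older >= age > self.younger


class BinSequence(Sequence[TimeBin]):
    """An ordered, gap-free sequence of time bins, oldest first.

    Adjacent bins must abut exactly: the younger boundary of each bin is the
    older boundary of the next.  The sequence therefore covers the contiguous
    interval ``(youngest, oldest]``.
    """

    def __init__(self, bins: Iterable[TimeBin]):
        bins = list(bins)
        if not bins:
            raise ValueError("BinSequence requires at least one bin")
        for a, b in zip(bins, bins[1:]):
            if a.younger != b.older:
                raise ValueError(
                    f"bins {a.name!r} and {b.name!r} do not abut: "
                    f"{a.younger} != {b.older}"
                )
        self._bins = bins

    def __len__(self) -> int:
        return len(self._bins)

    def __getitem__(self, i):  # type: ignore[override]
        return self._bins[i]

    def __iter__(self) -> Iterator[TimeBin]:
        return iter(self._bins)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self._bins]

    @property
    def oldest(self) -> float:
        return self._bins[0].older

    @property
    def youngest(self) -> float:
        return self._bins[-1].younger

    @property
    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self._bins])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self._bins])

    def mean_duration(self) -> float:
        return float(self.durations.mean())

    def std_duration(self) -> float:
        return float(self.durations.std(ddof=1)) if len(self) > 1 else 0.0

    def index_of_age(self, age: float) -> int:
        """Index of the unique bin containing ``age``; ValueError outside span."""
        if not (self.oldest >= age > self.youngest):
            raise ValueError(f"age {age} outside binned span "
                             f"({self.youngest}, {self.oldest}]")
        for i, b in enumerate(self._bins):
            if b.contains(age):
                return i
        raise AssertionError("unreachable: bins are contiguous")

    def subset(self, names: Iterable[str]) -> "BinSequence":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"unknown bins: {sorted(missing)}")
        return BinSequence([b for b in self._bins if b.name in wanted])


@dataclass(frozen=True)
class TaxonRange:
    """Observed stratigraphic range of one taxon.

    The range is treated as the closed age interval ``[lad, fad]``; any
    Lazarus gaps inside it are implicitly ranged through.  ``in_phylogeny``
    flags whether the taxon is a tip of the cladogram under study (taxa that
    are valid but unplaced still contribute to diversity counts).
    """

    taxon: str
    fad: float
    lad: float
    in_phylogeny: bool = True

    def __post_init__(self) -> None:
        if self.fad < self.lad:
            raise ValueError(
                f"taxon {self.taxon!r}: FAD ({self.fad}) must be >= LAD ({self.lad})"
            )

    @property
    def duration(self) -> float:
        return self.fad - self.lad


def bin_membership(rng: TaxonRange, tbin: TimeBin) -> bool:
    """True iff the closed range ``[lad, fad]`` meets the half-open bin.

    The intersection of ``[lad, fad]`` with ``(younger, older]`` is nonempty
    exactly when ``fad > younger`` and ``lad <= older``.
    """
    return rng.fad > tbin.younger and rng.lad <= tbin.older


def interval_in_bin(older_end: float, younger_end: float, tbin: TimeBin) -> bool:
    """Membership test for a raw closed age interval ``[younger_end, older_end]``."""
    return older_end > tbin.younger and younger_end <= tbin.older


def apportion_to_substages(value: float, durations: Sequence[float]) -> np.ndarray:
    """Split a stage-level quantity across substages by relative duration.

    Used for per-bin sampling proxies that are only resolved at stage level:
    each substage receives ``value * duration_i / sum(durations)``, so the
    outputs always sum to the input.
    """
    d = np.asarray(durations, dtype=float)
    if np.any(d <= 0):
        raise ValueError("substage durations must be positive")
    total = d.sum()
    if total <= 0:
        raise ValueError("total substage duration must be positive")
    return value * d / total


# ---------------------------------------------------------------------------
# CSV readers/writers


def read_ranges(path) -> list[TaxonRange]:
    """Read a taxon range table (columns: taxon, fad, lad[, in_phylogeny])."""
    df = pd.read_csv(path)
    required = {"taxon", "fad", "lad"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"range table {path}: missing columns {sorted(missing)}")
    dupes = df["taxon"][df["taxon"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"range table {path}: duplicate taxa {dupes}")
    has_flag = "in_phylogeny" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TaxonRange(
                taxon=str(row.taxon),
                fad=float(row.fad),
                lad=float(row.lad),
                in_phylogeny=bool(row.in_phylogeny) if has_flag else True,
            )
        )
    return out


def write_ranges(ranges: Iterable[TaxonRange], path) -> None:
    pd.DataFrame(
        [(r.taxon, r.fad, r.lad, r.in_phylogeny) for r in ranges],
        columns=["taxon", "fad", "lad", "in_phylogeny"],
    ).to_csv(path, index=False)


def read_bins(path) -> BinSequence:
    """Read a bin table (columns: name, older, younger), oldest first."""
    df = pd.read_csv(path)
    required = {"name", "older", "younger"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin table {path}: missing columns {sorted(missing)}")
    return BinSequence(
        TimeBin(str(r.name), float(r.older), float(r.younger))
        for r in df.itertuples(index=False)
    )


def write_bins(bins: BinSequence, path) -> None:
    pd.DataFrame(
        [(b.name, b.older, b.younger) for b in bins],
        columns=["name", "older", "younger"],
    ).to_csv(path, index=False)
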