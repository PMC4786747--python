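"""Discrete morphological character matrices with missing data and ordering.

States are stored as a float array with ``nan`` marking missing cells.
Polymorphic and uncertain scorings (``{01}``-style) are conservatively mapped
to missing: no downstream distance or reconstruction step attempts to pick a
state from a polymorphic set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["CharacterMatrix", "read_nexus_matrix", "write_nexus_matrix"]

_SYMBOLS = "0123456789"


@dataclass
class CharacterMatrix:
    taxa: list[str]
    states: np.ndarray  # (n_taxa, n_characters) float, nan = missing
    ordered: np.ndarray  # (n_characters,) bool

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.ordered = np.asarray(self.ordered, dtype=bool)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D taxon x character grid")
        if len(self.taxa) != self.states.shape[0]:
            raise ValueError("taxon count does not match state grid")
        if self.ordered.shape != (self.states.shape[1],):
            raise ValueError("ordered flags must match character count")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        scored = self.states[~np.isnan(self.states)]
        if scored.size and (np.any(scored < 0) or np.any(scored != np.round(scored))):
            raise ValueError("states must be non-negative integers or missing")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.states).mean())

    @property
    def state_range(self) -> np.ndarray:
        """Per-character span (max - min) of observed states; 0 if unscored."""
        with np.errstate(invalid="ignore"):
            hi = np.nanmax(np.where(np.isnan(self.states), -np.inf, self.states), axis=0)
            lo = np.nanmin(np.where(np.isnan(self.states), np.inf, self.states), axis=0)
        span = hi - lo
        span[~np.isfinite(span)] = 0.0
        return span

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def equals(self, other: "CharacterMatrix") -> bool:
        return (
            self.taxa == other.taxa
            and bool(np.all(self.ordered == other.ordered))
            and bool(
                np.all(
                    (np.isnan(self.states) & np.isnan(other.states))
                    | (self.states == other.states)
                )
            )
        )


def _parse_typeset_ordered(text: str, n_characters: int) -> np.ndarray:
    """Extract 1-based ordered-character indices from an ASSUMPTIONS block.

    Recognises the ``TYPESET ... = ord: 33 34 78, unord: ...`` convention,
    including ``a-b`` ranges.  Absent a typeset, all characters are unordered.
    """
    ordered = np.zeros(n_characters, dtype=bool)
    m = re.search(r"typeset[^=;]*=\s*([^;]+);", text, flags=re.IGNORECASE)
    if not m:
        return ordered
    for group in m.group(1).split(","):
        if ":" not in group:
            continue
        kind, idx = group.split(":", 1)
        if kind.strip().lower() not in {"ord", "ordered"}:
            continue
        for tok in idx.split():
            if "-" in tok:
                a, b = tok.split("-")
                ordered[int(a) - 1 : int(b)] = True
            else:
                ordered[int(tok) - 1] = True
    return ordered


def read_nexus_matrix(path, ordered: list[int] | None = None) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`.

    ``?`` and ``-`` map to missing, as do polymorphic/uncertain state sets.
    Ordered characters are taken from an ASSUMPTIONS TYPESET if present, or
    from ``ordered`` (1-based indices), the latter winning if both are given.
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"failed to parse NEXUS matrix {path}: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise ValueError(f"duplicate taxon labels in {path}")
    n_char = max(len(dmat[t]) for t in dmat.taxon_namespace)
    grid = np.full((len(taxa), n_char), np.nan)
    for i, taxon in enumerate(dmat.taxon_namespace):
        for j, cell in enumerate(dmat[taxon]):
            symbols = cell.fundamental_symbols
            if len(symbols) == 1 and cell.symbol not in ("?", "-"):
                grid[i, j] = int(cell.symbol)
            # else: missing, gap, polymorphic or uncertain -> nan
    text = open(path).read()
    ordered_flags = _parse_typeset_ordered(text, n_char)
    if ordered is not None:
        ordered_flags = np.zeros(n_char, dtype=bool)
        ordered_flags[np.asarray(ordered) - 1] = True
    return CharacterMatrix(taxa=taxa, states=grid, ordered=ordered_flags)


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a matrix as NEXUS with a TYPESET recording ordered characters."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{_SYMBOLS}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.states):
        cells = "".join("?" if np.isnan(s) else _SYMBOLS[int(s)] for s in row)
        safe = f"'{taxon}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>~-]", taxon) else taxon
        lines.append(f"{safe:<{width}}{cells}")
    lines.append(";")
    lines.append("END;")
    ordered_idx = np.flatnonzero(matrix.ordered) + 1
    if ordered_idx.size:
        unord_idx = np.flatnonzero(~matrix.ordered) + 1
        parts = ["ord: " + " ".join(map(str, ordered_idx))]
        if unord_idx.size:
            parts.append("unord: " + " ".join(map(str, unord_idx)))
        lines += [
            "BEGIN ASSUMPTIONS;",
            "TYPESET * default = " + ", ".join(parts) + ";",
            "END;",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
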