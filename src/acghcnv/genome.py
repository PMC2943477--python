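"""Genome model: an ordered set of named chromosomes with integer lengths.

The chromosome order defines the concatenated ("circular") coordinate system
used by rotational permutation: chromosomes are laid end to end in the order
given, and the genome is treated as a circle of its total length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Genome:
    """Ordered chromosomes with lengths in bp.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Names must be unique and
        lengths strictly positive. Order is preserved and meaningful.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes) -> None:
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: l for n, l in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def offsets(self) -> dict[str, int]:
        """Start offset of each chromosome on the concatenated coordinate."""
        out, pos = {}, 0
        for n, l in self.chromosomes:
            out[n] = pos
            pos += l
        return out

    def boundaries(self) -> np.ndarray:
        """Concatenated-coordinate boundaries, ``[0, c1, c1+c2, ..., total]``."""
        return np.concatenate([[0], np.cumsum([l for _, l in self.chromosomes])])

    def to_absolute(self, chrom, start, end):
        """Map per-chromosome intervals to the concatenated coordinate."""
        off = self.offsets()
        o = np.asarray([off[c] for c in chrom], dtype=np.int64)
        return o + np.asarray(start, dtype=np.int64), o + np.asarray(end, dtype=np.int64)

    def from_absolute(self, abs_start: np.ndarray, abs_end: np.ndarray):
        """Map concatenated-coordinate intervals back, splitting any interval
        that straddles a chromosome boundary.

        Returns (chrom array, start array, end array, origin index array) where
        origin index says which input interval each output piece came from.
        """
        bounds = self.boundaries()
        names = self.names
        chroms, starts, ends, origin = [], [], [], []
        for k, (a, b) in enumerate(zip(np.asarray(abs_start), np.asarray(abs_end))):
            if b <= a:
                continue
            i = int(np.searchsorted(bounds, a, side="right")) - 1
            while a < b:
                piece_end = min(b, bounds[i + 1])
                chroms.append(names[i])
                starts.append(int(a - bounds[i]))
                ends.append(int(piece_end - bounds[i]))
                origin.append(k)
                a = piece_end
                i += 1
        return (
            np.asarray(chroms, dtype=object),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(origin, dtype=np.int64),
        )
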