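"""Telocentric chromosome coordinate system and overlapping window grids.

Mouse chromosomes are telocentric: the centromere sits at one end, so a
genomic coordinate doubles as the distance from the centromere.  Position 0
is the centromeric end, position ``L`` the distal telomere.  All coordinates
are 0-based half-open, matching BED/bedGraph conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout", "WindowGrid"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, centromere at coordinate 0.

    Parameters
    ----------
    chrom_names : tuple of str
        Chromosome identifiers in display order.
    lengths : dict
        Map chromosome name -> length ``L`` in bp.
    """

    chrom_names: tuple
    lengths: dict

    def __post_init__(self):
        names = tuple(self.chrom_names)
        object.__setattr__(self, "chrom_names", names)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c in names:
            if c not in self.lengths:
                raise ValueError(f"no length for chromosome {c!r}")
            if self.lengths[c] <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")

    @classmethod
    def from_dict(cls, lengths: dict) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeLayout":
        """Read a UCSC-style two-column chrom.sizes file."""
        lengths = {}
        order = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed chrom.sizes line: {line!r}")
                try:
                    L = int(parts[1])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: bad length {parts[1]!r}") from e
                order.append(parts[0])
                lengths[parts[0]] = L
        return cls(tuple(order), lengths)

    def __contains__(self, chrom) -> bool:
        return chrom in self.lengths and chrom in self.chrom_names

    def length(self, chrom) -> int:
        return self.lengths[chrom]

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chrom_names:
                fh.write(f"{c}\t{self.lengths[c]}\n")


@dataclass(frozen=True)
class WindowGrid:
    """Overlapping windows ``[k*s, k*s + w)`` clipped at chromosome length.

    ``w`` is the window size and ``s`` the step (``s <= w``; adjacent windows
    overlap by ``w - s``).  Every start ``k*s < L`` yields a window, so the
    grid tiles the chromosome and trailing windows are clipped.
    """

    layout: GenomeLayout
    window_size: int
    step: int
    _n: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window size")
        n = {
            c: int(np.ceil(self.layout.lengths[c] / self.step))
            for c in self.layout.chrom_names
        }
        object.__setattr__(self, "_n", n)

    def n_windows(self, chrom) -> int:
        return self._n[chrom]

    def starts(self, chrom) -> np.ndarray:
        return np.arange(self._n[chrom], dtype=np.int64) * self.step

    def ends(self, chrom) -> np.ndarray:
        return np.minimum(self.starts(chrom) + self.window_size, self.layout.lengths[chrom])

    def midpoints(self, chrom) -> np.ndarray:
        """Window midpoints in bp (clipped windows use their actual extent)."""
        return (self.starts(chrom) + self.ends(chrom)) / 2.0

    def windows_containing(self, chrom, pos: int) -> np.ndarray:
        """Indices of all windows whose half-open interval contains ``pos``."""
        w, s = self.window_size, self.step
        lo = max(0, (pos - w) // s + 1)
        hi = min(self._n[chrom] - 1, pos // s)
        return np.arange(lo, hi + 1, dtype=np.int64)
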