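"""Fragment input, filtering, window counting and track serialization.

Fragments are the spans bridged by a properly paired read pair.  The filters
follow the coverage-generation recipe for micronuclear libraries: proper
pairs only, mapping quality strictly greater than 20, PCR duplicates
removed, and an insert-size ceiling chosen from the library's insert-size
histogram.  A fragment is assigned to every overlapping window whose
half-open interval contains the midpoint of its left-end read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .genome import GenomeLayout, WindowGrid

log = logging.getLogger(__name__)

__all__ = [
    "FragmentRecord",
    "CoverageTrack",
    "read_fragments",
    "fragments_from_dataframe",
    "fragments_from_bam",
    "insert_size_histogram",
    "count_windows",
    "write_track",
    "read_track",
    "read_chrom_sizes",
    "DEFAULT_MIN_MAPQ",
]

DEFAULT_MIN_MAPQ = 20

FRAGMENT_COLUMNS = ["chrom", "start", "end", "left_read_mid", "mapq", "proper_pair", "duplicate"]


@dataclass(frozen=True)
class FragmentRecord:
    """One paired-end bridged fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    left_read_mid: int
    mapq: int
    proper_pair: bool = True
    duplicate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-window fragment counts for one blood fraction on a WindowGrid."""

    fraction: str
    grid: WindowGrid
    counts: dict  # chrom -> float array, len == grid.n_windows(chrom)
    total_fragments: int = 0

    def __post_init__(self):
        for c, arr in self.counts.items():
            if len(arr) != self.grid.n_windows(c):
                raise ValueError(f"counts length mismatch on {c}")

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.fraction, self.grid, {c: a.copy() for c, a in self.counts.items()}, self.total_fragments
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.grid.layout.chrom_names:
            if c not in self.counts:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": self.grid.starts(c),
                        "end": self.grid.ends(c),
                        "count": self.counts[c],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"# micseq coverage fraction={self.fraction} w={self.grid.window_size} "
                f"s={self.grid.step} total_fragments={self.total_fragments}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, layout: GenomeLayout) -> "CoverageTrack":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        w = int(meta.get("w", 0))
        s = int(meta.get("s", 0))
        if not w:
            # infer from the first chromosome's rows
            g = df[df.chrom == df.chrom.iloc[0]]
            w = int(g.end.iloc[0] - g.start.iloc[0])
            s = int(g.start.iloc[1] - g.start.iloc[0]) if len(g) > 1 else w
        grid = WindowGrid(layout, w, s)
        counts = {}
        for c, g in df.groupby("chrom", sort=False):
            counts[c] = g["count"].to_numpy(dtype=float)
        return cls(meta.get("fraction", "NA"), grid, counts, int(meta.get("total_fragments", 0)))


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a UCSC-style chrom.sizes file into a GenomeLayout."""
    return GenomeLayout.from_chrom_sizes(path)


# ---------------------------------------------------------------------------
# fragment streams


def fragments_from_dataframe(df: pd.DataFrame) -> Iterator[FragmentRecord]:
    """Yield FragmentRecords from a fragment interval table (alignment-free)."""
    for row in df.itertuples(index=False):
        yield FragmentRecord(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            left_read_mid=int(row.left_read_mid),
            mapq=int(row.mapq),
            proper_pair=bool(getattr(row, "proper_pair", True)),
            duplicate=bool(getattr(row, "duplicate", False)),
        )


def fragments_from_table(path) -> Iterator[FragmentRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    yield from fragments_from_dataframe(df)


def fragments_from_bam(path) -> Iterator[FragmentRecord]:
    """Yield bridged fragments from a coordinate-sorted paired-end SAM/BAM.

    Only the leftmost primary read of each pair emits a record (template
    length > 0), so each fragment appears once.  The pair-level flags and the
    left read's mapping quality are carried on the record; filtering happens
    downstream in :func:`read_fragments`.  Unsorted input is a fatal error.
    """
    import pysam

    last = (None, -1)
    with pysam.AlignmentFile(str(path), "r" if str(path).endswith(".sam") else "rb") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            pos = (rec.reference_name, rec.reference_start)
            if pos[0] == last[0] and pos[1] < last[1]:
                raise ValueError(
                    f"input not coordinate-sorted at {pos[0]}:{pos[1]} (previous {last[1]})"
                )
            last = pos
            tlen = rec.template_length
            if tlen <= 0:
                continue  # rightmost mate or undefined; fragment emitted from the left read
            start = rec.reference_start
            ref_end = rec.reference_end if rec.reference_end is not None else start + rec.query_length
            yield FragmentRecord(
                chrom=rec.reference_name,
                start=start,
                end=start + tlen,
                left_read_mid=(start + ref_end) // 2,
                mapq=rec.mapping_quality,
                proper_pair=rec.is_proper_pair,
                duplicate=rec.is_duplicate,
            )


def read_fragments(
    source: Iterable[FragmentRecord],
    layout: GenomeLayout,
    max_insert: Optional[int] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    rejected: Optional[dict] = None,
) -> Iterator[FragmentRecord]:
    """Filter a fragment stream to the retained set.

    Keeps records that are proper pairs, non-duplicate, have mapping quality
    strictly greater than ``min_mapq``, span at most ``max_insert`` bp, and
    whose coordinates are valid on ``layout``.  Records on unknown
    chromosomes are rejected (counted, not fatal).

    Parameters
    ----------
    rejected : dict, optional
        If given, per-reason rejection counts are accumulated into it
        (keys: unknown_chrom, improper, duplicate, mapq, insert, coords).
    """
    counts = rejected if rejected is not None else {}
    for key in ("unknown_chrom", "improper", "duplicate", "mapq", "insert", "coords"):
        counts.setdefault(key, 0)
    for frag in source:
        if frag.chrom not in layout:
            counts["unknown_chrom"] += 1
            continue
        if not frag.proper_pair:
            counts["improper"] += 1
            continue
        if frag.duplicate:
            counts["duplicate"] += 1
            continue
        if frag.mapq <= min_mapq:
            counts["mapq"] += 1
            continue
        if max_insert is not None and frag.length > max_insert:
            counts["insert"] += 1
            continue
        L = layout.length(frag.chrom)
        if not (0 <= frag.start < frag.end <= L and frag.start <= frag.left_read_mid < frag.end):
            counts["coords"] += 1
            continue
        yield frag
    total_rej = sum(counts.values())
    if total_rej:
        log.info("read_fragments: rejected %d records (%s)", total_rej, counts)


def insert_size_histogram(fragments: Iterable[FragmentRecord], quantile: float = 0.999):
    """Integer-binned insert-size histogram and the implied max insert.

    ``max_insert`` is the smallest length covering ``quantile`` of the
    fragments (the inverted-CDF quantile of the empirical lengths).
    """
    lengths = np.array([f.length for f in fragments], dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no fragments: cannot build insert-size histogram")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    values, freq = np.unique(lengths, return_counts=True)
    hist = dict(zip(values.tolist(), freq.tolist()))
    srt = np.sort(lengths)
    idx = int(np.ceil(quantile * srt.size)) - 1
    max_insert = int(srt[max(idx, 0)])
    return hist, max_insert


def count_windows(
    fragments,
    grid: WindowGrid,
    fraction: str = "NA",
    rejected: Optional[dict] = None,
) -> CoverageTrack:
    """Count fragments into overlapping windows by left-read midpoint.

    Each fragment increments every window whose half-open interval contains
    its ``left_read_mid`` (with 50% overlap that is two interior windows).
    Counting is order-independent by construction.  ``fragments`` may be a
    stream of FragmentRecords or a fragment DataFrame (vectorized path).
    """
    layout = grid.layout
    if isinstance(fragments, pd.DataFrame):
        df = fragments
        chroms = df["chrom"].to_numpy()
        mids = df["left_read_mid"].to_numpy(dtype=np.int64)
    else:
        rows = [(f.chrom, f.left_read_mid) for f in fragments]
        chroms = np.array([r[0] for r in rows], dtype=object)
        mids = np.array([r[1] for r in rows], dtype=np.int64)
    counts = {c: np.zeros(grid.n_windows(c)) for c in layout.chrom_names}
    w, s = grid.window_size, grid.step
    span = -(-w // s)  # max windows containing one midpoint
    n_out = 0
    total = 0
    for c in layout.chrom_names:
        sel = chroms == c
        if not sel.any():
            continue
        m = mids[sel]
        L = layout.length(c)
        ok = (m >= 0) & (m < L)
        n_out += int((~ok).sum())
        m = m[ok]
        total += m.size
        n = grid.n_windows(c)
        base = m // s
        for off in range(span):
            k = base - off
            valid = (k >= 0) & (k < n) & (m - k * s < w)
            counts[c] += np.bincount(k[valid], minlength=n)
    n_out += int((~np.isin(chroms, list(layout.chrom_names))).sum())
    if n_out:
        log.info("count_windows: %d fragments with midpoint outside the layout", n_out)
        if rejected is not None:
            rejected["midpoint_outside"] = rejected.get("midpoint_outside", 0) + n_out
    return CoverageTrack(fraction, grid, counts, total)


def filter_fragments_frame(
    df: pd.DataFrame,
    layout: GenomeLayout,
    max_insert: Optional[int] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> pd.DataFrame:
    """Vectorized equivalent of :func:`read_fragments` on a fragment table."""
    lens = df["chrom"].map(layout.lengths)
    keep = (
        df["proper_pair"].astype(bool)
        & ~df["duplicate"].astype(bool)
        & (df["mapq"] > min_mapq)
        & lens.notna()
        & (df["start"] >= 0)
        & (df["start"] < df["end"])
        & (df["end"] <= lens.fillna(0))
        & (df["left_read_mid"] >= df["start"])
        & (df["left_read_mid"] < df["end"])
    )
    if max_insert is not None:
        keep &= (df["end"] - df["start"]) <= max_insert
    return df.loc[keep]


# ---------------------------------------------------------------------------
# track serialization

_HEADER = "# micseq track w={w} s={s} representation=midpoint-interval"


def write_track(track: CoverageTrack, path, fmt: str = "bedGraph") -> None:
    """Write a track as bedGraph or fixedStep wiggle.

    Overlapping-window tracks are serialized in the step-``s``
    midpoint-interval representation: window ``[k*s, k*s+w)`` is written on
    the interval of width ``s`` centred on its midpoint.  For ``s == w``
    this is the window itself.  The representation is recorded in the file
    header so :func:`read_track` can reconstruct the grid exactly.
    """
    grid = track.grid
    w, s = grid.window_size, grid.step
    off = (w - s) // 2
    with open(path, "w") as fh:
        fh.write(_HEADER.format(w=w, s=s) + f" fraction={track.fraction} total_fragments={track.total_fragments}\n")
        if fmt == "bedGraph":
            for c in grid.layout.chrom_names:
                if c not in track.counts:
                    continue
                starts = grid.starts(c) + off
                for st, v in zip(starts, track.counts[c]):
                    fh.write(f"{c}\t{st}\t{st + s}\t{v:.10g}\n")
        elif fmt == "wiggle":
            for c in grid.layout.chrom_names:
                if c not in track.counts:
                    continue
                fh.write(f"fixedStep chrom={c} start={off + 1} step={s} span={s}\n")
                for v in track.counts[c]:
                    fh.write(f"{v:.10g}\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")


def read_track(path, layout: GenomeLayout, fmt: str = "bedGraph") -> CoverageTrack:
    """Read a track written by :func:`write_track` (round-trip inverse)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}:1: missing micseq track header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
        w, s = int(meta["w"]), int(meta["s"])
        grid = WindowGrid(layout, w, s)
        counts = {c: np.zeros(grid.n_windows(c)) for c in layout.chrom_names}
        off = (w - s) // 2
        if fmt == "bedGraph":
            for lineno, line in enumerate(fh, 2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
                c, st, _en, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                k = (st - off) // s
                counts[c][k] = v
        elif fmt == "wiggle":
            c = None
            k = 0
            for lineno, line in enumerate(fh, 2):
                line = line.strip()
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                    c, k = kv["chrom"], 0
                elif line:
                    if c is None:
                        raise ValueError(f"{path}:{lineno}: value before fixedStep header")
                    counts[c][k] = float(line)
                    k += 1
        else:
            raise ValueError(f"unknown track format {fmt!r}")
    return CoverageTrack(
        meta.get("fraction", "NA"), grid, counts, int(meta.get("total_fragments", 0))
    )
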