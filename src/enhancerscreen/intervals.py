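"""Genomic interval data model, BED/BEDPE I/O and the overlap engine.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; any 1-based dialect must be converted at the reader boundary.
Interval sets iterate in a deterministic order (chrom, start, end, name) so
that every downstream table is reproducible byte-for-byte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Sentinel MAPQ meaning "quality filtering already happened upstream".
MAPQ_PREFILTERED = -1

_BED_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """Raised for malformed BED/BEDPE lines; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ReadPair:
    """A properly-oriented sequencing read pair prior to fragment assembly."""

    read1: GenomicInterval
    read2: GenomicInterval
    mapq: int = MAPQ_PREFILTERED
    properly_paired: bool = True

    def __post_init__(self) -> None:
        if self.mapq < 0 and self.mapq != MAPQ_PREFILTERED:
            raise ValueError("mapq must be >= 0 or the prefiltered sentinel")


_CORE_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class IntervalSet:
    """An ordered, duplicate-aware collection of genomic intervals.

    Backed by a pandas DataFrame with at least the BED6 columns; arbitrary
    extra columns (summit, stage, gene ...) ride along through sorting and
    subsetting. The frame is always sorted by (chrom, start, end, name).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_CORE_COLS)
        df = df.copy()
        for col, default in (("name", None), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        if len(df):
            bad = df["end"] <= df["start"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"interval {i}: end <= start "
                    f"({df['start'].iat[i]}, {df['end'].iat[i]})"
                )
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
        sort_key = df["name"].astype(str) if len(df) else df["name"]
        df = (
            df.assign(_namekey=sort_key)
            .sort_values(["chrom", "start", "end", "_namekey"], kind="mergesort")
            .drop(columns="_namekey")
            .reset_index(drop=True)
        )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self._df = df

    # -- construction ---------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_CORE_COLS))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            score = getattr(row, "score", np.nan)
            yield GenomicInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                name=None if row.name is None or (isinstance(row.name, float) and np.isnan(row.name)) else str(row.name),
                score=None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score),
                strand=getattr(row, "strand", ".") or ".",
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._df[["chrom", "start", "end"]]
        b = other._df[["chrom", "start", "end"]]
        return a.equals(b)

    # -- operations -----------------------------------------------------
    def dedupe(self) -> "IntervalSet":
        """Keep one copy of each distinct (chrom, start, end). Idempotent."""
        df = self._df.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
        return IntervalSet(df)

    def centers(self) -> np.ndarray:
        return (self._df["start"].to_numpy() + self._df["end"].to_numpy()) / 2

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self._df.loc[np.asarray(mask)])

    def coordinate_tuples(self) -> set[tuple[str, int, int]]:
        return set(
            zip(self._df["chrom"], self._df["start"].astype(int), self._df["end"].astype(int))
        )


@dataclass
class Ledger:
    """Audit counter for filtering steps: input = retained + sum(removed)."""

    n_input: int = 0
    n_retained: int = 0
    removed: Counter = field(default_factory=Counter)

    def record(self, step: str, n: int) -> None:
        self.removed[step] += int(n)

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "removed": dict(self.removed),
        }


# ---------------------------------------------------------------------------
# BED / BEDPE I/O
# ---------------------------------------------------------------------------

def _parse_coords(chrom: str, s: str, e: str, lineno: int, path: str) -> tuple[int, int]:
    try:
        start, end = int(s), int(e)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or end <= start:
        raise BedParseError(
            f"{path}:{lineno}: invalid interval [{start}, {end}) (need 0 <= start < end)"
        )
    if not chrom:
        raise BedParseError(f"{path}:{lineno}: empty chromosome name")
    return start, end


def read_bed(path) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Coordinates are interpreted 0-based half-open. ``track``/``browser``/``#``
    lines are skipped. Malformed lines raise :class:`BedParseError` naming the
    line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            start, end = _parse_coords(fields[0], fields[1], fields[2], lineno, str(path))
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = np.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            rows.append((fields[0], start, end, name, score, strand))
    return IntervalSet(pd.DataFrame(rows, columns=_CORE_COLS))


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED; emits exactly as many columns as are informative."""
    df = intervals.df
    has_name = df["name"].notna().any()
    has_score = df["score"].notna().any()
    has_strand = (df["strand"] != ".").any()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            cols = [row.chrom, str(int(row.start)), str(int(row.end))]
            if has_name or has_score or has_strand:
                cols.append("." if pd.isna(row.name) or row.name is None else str(row.name))
            if has_score or has_strand:
                cols.append("." if pd.isna(row.score) else format(row.score, "g"))
            if has_strand:
                cols.append(row.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path) -> list[ReadPair]:
    """Read a BEDPE file (minimal 6-column or 10-column dialect).

    Ten-column files carry name/score/strands; the score column is taken as
    MAPQ. Six-column files get the :data:`MAPQ_PREFILTERED` sentinel. Pairs on
    different chromosomes are retained here — filtering is a later step.
    """
    pairs: list[ReadPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise BedParseError(
                    f"{path}:{lineno}: expected 6 or 10 columns, got {len(fields)}"
                )
            s1, e1 = _parse_coords(fields[0], fields[1], fields[2], lineno, str(path))
            s2, e2 = _parse_coords(fields[3], fields[4], fields[5], lineno, str(path))
            mapq = MAPQ_PREFILTERED
            strand1 = strand2 = "."
            if len(fields) == 10:
                if fields[7] not in (".", ""):
                    try:
                        mapq = int(fields[7])
                    except ValueError as exc:
                        raise BedParseError(f"{path}:{lineno}: bad mapq {fields[7]!r}") from exc
                strand1 = fields[8] if fields[8] in ("+", "-") else "."
                strand2 = fields[9] if fields[9] in ("+", "-") else "."
            pairs.append(
                ReadPair(
                    read1=GenomicInterval(fields[0], s1, e1, strand=strand1),
                    read2=GenomicInterval(fields[3], s2, e2, strand=strand2),
                    mapq=mapq,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Read-pair filtering and fragment assembly
# ---------------------------------------------------------------------------

def filter_read_pairs(
    pairs: Sequence[ReadPair], mapq_gt: int = 40, require_proper: bool = True
) -> tuple[list[ReadPair], Ledger]:
    """Keep properly-paired reads with MAPQ strictly above ``mapq_gt``.

    The MAPQ test is applied only to pairs that carry a real MAPQ; pairs with
    the prefiltered sentinel pass through.
    """
    ledger = Ledger(n_input=len(pairs))
    kept: list[ReadPair] = []
    for p in pairs:
        if require_proper and not p.properly_paired:
            ledger.record("not_properly_paired", 1)
        elif p.mapq != MAPQ_PREFILTERED and p.mapq <= mapq_gt:
            ledger.record("low_mapq", 1)
        else:
            kept.append(p)
    ledger.n_retained = len(kept)
    return kept, ledger


def pairs_to_fragments(
    pairs: Sequence[ReadPair], max_len: int = 600
) -> tuple[IntervalSet, Ledger]:
    """Assemble each read pair into one fragment spanning both mates.

    The fragment runs from the smaller mate start to the larger mate end, so
    reversed mate order is handled symmetrically. Pairs on different
    chromosomes or spanning more than ``max_len`` bp are dropped and counted
    in the returned ledger, never raised.
    """
    ledger = Ledger(n_input=len(pairs))
    rows = []
    for p in pairs:
        if p.read1.chrom != p.read2.chrom:
            ledger.record("inter_chrom", 1)
            continue
        start = min(p.read1.start, p.read2.start)
        end = max(p.read1.end, p.read2.end)
        if end - start > max_len:
            ledger.record("too_long", 1)
            continue
        if p.read1.start > p.read2.start:
            ledger.record("reversed_mate_order", 0)  # anomaly note, not a drop
        rows.append((p.read1.chrom, start, end, None, np.nan, "."))
    frags = IntervalSet(pd.DataFrame(rows, columns=_CORE_COLS))
    ledger.n_retained = len(frags)
    return frags, ledger


def dedupe_intervals(intervals: IntervalSet) -> IntervalSet:
    """Module-level alias for :meth:`IntervalSet.dedupe`."""
    return intervals.dedupe()


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def _build_trees(subject: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    df = subject.df
    for chrom, sub in df.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
            tree.addi(int(s), int(e), int(idx))
        trees[chrom] = tree
    return trees


def overlap_any(
    query: IntervalSet, subject: IntervalSet, min_bp: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Label each query interval that shares >= ``min_bp`` bases with a subject.

    Returns ``(hit, match_index)``: a boolean array over query rows and, for
    hits, the row index (in ``subject.df``) of the lowest-index overlapping
    subject interval (-1 for misses). Overlap length uses half-open
    arithmetic: ``max(0, min(ends) - max(starts))``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(subject)
    n = len(query)
    hit = np.zeros(n, dtype=bool)
    match = np.full(n, -1, dtype=np.int64)
    df = query.df
    for i, (chrom, qs, qe) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        best = -1
        for iv in tree.overlap(int(qs), int(qe)):
            if min(iv.end, qe) - max(iv.begin, qs) >= min_bp:
                if best < 0 or iv.data < best:
                    best = iv.data
        if best >= 0:
            hit[i] = True
            match[i] = best
    return hit, match


def overlap_join(
    query: IntervalSet, subject: IntervalSet, min_bp: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping (query_row, subject_row) index pairs with >= min_bp shared."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(subject)
    q_idx: list[int] = []
    s_idx: list[int] = []
    df = query.df
    for i, (chrom, qs, qe) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(int(qs), int(qe)):
            if min(iv.end, qe) - max(iv.begin, qs) >= min_bp:
                q_idx.append(i)
                s_idx.append(iv.data)
    order = np.lexsort((np.asarray(s_idx, dtype=np.int64), np.asarray(q_idx, dtype=np.int64)))
    return (
        np.asarray(q_idx, dtype=np.int64)[order],
        np.asarray(s_idx, dtype=np.int64)[order],
    )


def merge_overlapping(intervals: IntervalSet) -> tuple[IntervalSet, np.ndarray]:
    """Single-linkage merge of overlapping intervals into union spans.

    Returns the merged set and, for each input row (in sorted order of the
    input set), the row index of the merged interval it belongs to.
    """
    df = intervals.df
    n = len(df)
    assignment = np.full(n, -1, dtype=np.int64)
    merged_rows = []
    cur = None  # (chrom, start, end, member indices)
    members: list[int] = []
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        s, e = int(s), int(e)
        if cur is not None and chrom == cur[0] and s < cur[2]:
            cur = (chrom, cur[1], max(cur[2], e))
            members.append(i)
        else:
            if cur is not None:
                for m in members:
                    assignment[m] = len(merged_rows)
                merged_rows.append(cur)
            cur = (chrom, s, e)
            members = [i]
    if cur is not None:
        for m in members:
            assignment[m] = len(merged_rows)
        merged_rows.append(cur)
    merged = IntervalSet(
        pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    )
    return merged, assignment
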