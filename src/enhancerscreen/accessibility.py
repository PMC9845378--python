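"""Differential chromatin accessibility from per-site tag counts.

Workflow: merge the peak sets of the two conditions into a union (summit of
the taller peak wins), count tags in a 400 bp window centred on each summit,
normalize to counts-per-million, transform as log2(CPM + 1), average
replicates per condition after the transform, and call a site gained or lost
when the condition means differ by at least log2(fold) — i.e. a two-fold
change on the CPM + 1 scale by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_join


def peak_union(peaks_a: IntervalSet, peaks_b: IntervalSet) -> IntervalSet:
    """Merge two summit-carrying peak sets into union spans.

    Overlapping peaks merge to their union span; the merged summit is the
    summit of the higher peak (score column), ties resolved to the leftmost
    summit. Both inputs must carry ``summit`` and ``score`` columns.
    """
    frames = []
    for peaks in (peaks_a, peaks_b):
        df = peaks.df
        if "summit" not in df.columns:
            raise ValueError("peaks must carry a summit column")
        bad = (df["summit"] < df["start"]) | (df["summit"] >= df["end"])
        if bad.any():
            raise ValueError("summit outside its peak interval")
        frames.append(df[["chrom", "start", "end", "summit", "score"]])
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)

    merged_rows: list[tuple] = []
    cur = None  # chrom, start, end, summit, height
    for row in pooled.itertuples(index=False):
        h = row.score if not pd.isna(row.score) else 0.0
        if cur is not None and row.chrom == cur[0] and row.start < cur[2]:
            chrom, start, end, summit, height = cur
            end = max(end, row.end)
            if h > height or (h == height and row.summit < summit):
                summit, height = row.summit, h
            cur = (chrom, start, end, summit, height)
        else:
            if cur is not None:
                merged_rows.append(cur)
            cur = (row.chrom, row.start, row.end, row.summit, h)
    if cur is not None:
        merged_rows.append(cur)
    out = pd.DataFrame(
        merged_rows, columns=["chrom", "start", "end", "summit", "score"]
    )
    return IntervalSet(out)


def window_counts(
    union: IntervalSet,
    fragments: IntervalSet,
    width: int = 400,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Count fragments overlapping the ``width`` bp window around each summit.

    Windows are half-open [summit - width/2, summit + width/2); windows that
    would leave chromosome bounds are clipped and flagged, never dropped.
    """
    if width % 2:
        raise ValueError("width must be even")
    df = union.df
    if "summit" not in df.columns:
        raise ValueError("union peaks must carry a summit column")
    half = width // 2
    starts = df["summit"].to_numpy(np.int64) - half
    ends = df["summit"].to_numpy(np.int64) + half
    clipped = starts < 0
    starts = np.maximum(starts, 0)
    if chrom_lengths:
        lims = df["chrom"].map(chrom_lengths).to_numpy()
        clipped |= ends > lims
        ends = np.minimum(ends, lims)
    win_df = pd.DataFrame(
        {"chrom": df["chrom"], "start": starts, "end": ends, "name": np.arange(len(df))}
    )
    windows = IntervalSet(win_df)
    counts = np.zeros(len(df), dtype=np.int64)
    if len(fragments):
        qi, si = overlap_join(fragments, windows)
        # map back from sorted window order to union row order via the name col
        orig = windows.df["name"].to_numpy(np.int64)
        np.add.at(counts, orig[si], 1)
    out = df[["chrom", "start", "end", "summit"]].copy()
    out["count"] = counts
    out["window_clipped"] = clipped
    return out


def normalize(
    counts: pd.DataFrame,
    sample_cols: dict[str, list[str]],
) -> pd.DataFrame:
    """CPM-normalize, log2(CPM + 1)-transform and average replicates.

    ``sample_cols`` maps condition name -> list of replicate count columns.
    Returns per-replicate transformed columns plus a ``<condition>_mean``
    column per condition (mean taken after the log transform).
    """
    out = counts.copy()
    for cond, cols in sample_cols.items():
        transformed = []
        for col in cols:
            total = float(counts[col].sum())
            if total <= 0:
                raise ValueError(f"sample column {col!r} has zero total count")
            cpm = 1e6 * counts[col].to_numpy(float) / total
            tcol = f"{col}_log2cpm"
            out[tcol] = np.log2(cpm + 1.0)
            transformed.append(tcol)
        out[f"{cond}_mean"] = out[transformed].mean(axis=1)
    return out


def call_differential(
    mean_a: np.ndarray | pd.Series,
    mean_b: np.ndarray | pd.Series,
    fold: float = 2.0,
    scale: str = "log",
) -> np.ndarray:
    """Classify each site as gained / lost / unchanged in condition A vs B.

    With ``scale="log"`` (default) the two-fold rule is a difference of
    log2(fold) on the log2(CPM + 1) scale. ``scale="cpm"`` instead applies
    the fold rule to the raw back-transformed CPM ratio (2^x - 1), the
    alternative reading of a plain fold threshold; zero-CPM denominators make
    any positive numerator a gain.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition vectors differ in length")
    if scale == "log":
        delta = a - b
        thr = np.log2(fold)
        return np.where(
            delta >= thr, "gained", np.where(delta <= -thr, "lost", "unchanged")
        )
    if scale == "cpm":
        cpm_a = np.exp2(a) - 1.0
        cpm_b = np.exp2(b) - 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            gained = (cpm_a >= fold * cpm_b) & (cpm_a > 0)
            lost = (cpm_b >= fold * cpm_a) & (cpm_b > 0)
        return np.where(gained & ~lost, "gained", np.where(lost & ~gained, "lost", "unchanged"))
    raise ValueError("scale must be 'log' or 'cpm'")
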