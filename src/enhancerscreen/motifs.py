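"""Motif co-localization z-scores and relative motif enrichment.

Two statistics quantify transcription-factor motif grammar in enhancer sets:

* **Co-localization z-score.** For every unordered pair of motifs, count the
  instances found within a fixed center-to-center distance (50 bp default)
  inside a specific region set, then compare against a null built by
  repeatedly drawing an equal number of regions from the full distal
  open-chromatin universe and recounting. ``z = (x - mu) / sigma`` where
  ``mu``/``sigma`` are the resample mean and sample standard deviation. A
  positive z means the pair co-occurs more often than expected by chance in
  regions of that kind.

* **Relative enrichment score.** For motif *i* across peak sets *j*,
  ``S_ij = (n_ij / m_j) / (sum_j n_ij / sum_j m_j)`` — the per-set motif rate
  over the pooled rate, so the m_j-weighted mean of each row is exactly 1.

Helpers cover row/column z-scaling and complete-linkage Euclidean clustering
for heatmap ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .intervals import IntervalSet, overlap_join


@dataclass
class PairCounts:
    """Observed co-localized pair counts x(a, b) over a region set."""

    matrix: pd.DataFrame  # symmetric, motifs x motifs, integer
    n_regions: int
    window: int

    @property
    def motifs(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class NullDistribution:
    """Resampled null for pair counts: per-pair mean and sample sd."""

    mu: pd.DataFrame
    sigma: pd.DataFrame
    reps: int
    n_draw: int
    seed: int
    window: int


@dataclass
class ZScores:
    """Per-pair z-scores with flags where sigma was zero (capped values)."""

    matrix: pd.DataFrame
    capped: pd.DataFrame  # boolean

    def offdiag_values(self) -> np.ndarray:
        m = self.matrix.to_numpy(float)
        iu = np.triu_indices_from(m, k=1)
        return m[iu]


# ---------------------------------------------------------------------------
# Pair counting
# ---------------------------------------------------------------------------

def _hit_arrays(
    hits: Mapping[str, IntervalSet]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], dict[str, np.ndarray]]:
    """Flatten per-motif hit sets into sorted parallel arrays.

    Returns chrom codes, centers (float), starts, ends, motif ids sorted by
    (chrom, center) plus motif names and the chrom code lookup.
    """
    motif_names = sorted(hits)
    frames = []
    for mi, name in enumerate(motif_names):
        df = hits[name].df
        frames.append(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "motif": mi,
                }
            )
        )
    if frames:
        allhits = pd.concat(frames, ignore_index=True)
    else:
        allhits = pd.DataFrame(columns=["chrom", "start", "end", "motif"])
    chrom_codes, chrom_uniques = pd.factorize(allhits["chrom"], sort=True)
    centers = (allhits["start"].to_numpy(float) + allhits["end"].to_numpy(float)) / 2
    order = np.lexsort((centers, chrom_codes))
    return (
        chrom_codes[order],
        centers[order],
        allhits["start"].to_numpy(np.int64)[order],
        allhits["end"].to_numpy(np.int64)[order],
        allhits["motif"].to_numpy(np.int64)[order],
        motif_names,
        {},
    )


def _count_core(
    chrom: np.ndarray,
    center: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    motif: np.ndarray,
    n_motifs: int,
    window: float,
    include: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized unordered pair counting on (chrom, center)-sorted arrays.

    Counts every pair of distinct hit instances on the same chromosome with
    center distance <= window, excluding coordinate-identical interval pairs.
    Returns a dense symmetric count matrix.
    """
    if include is not None:
        chrom, center = chrom[include], center[include]
        start, end, motif = start[include], end[include], motif[include]
    counts = np.zeros((n_motifs, n_motifs), dtype=np.int64)
    n = len(center)
    if n < 2:
        return counts
    # arrays arrive sorted by (chrom, center); a combined monotonic key lets
    # one searchsorted find, per hit i, the run of partners j > i in range
    span = np.max(center) + 2 * window + 1.0
    combined = chrom * span + center
    hi = np.searchsorted(combined, combined + window, side="right")
    i_idx = np.arange(n)
    run = hi - (i_idx + 1)
    run = np.maximum(run, 0)
    total = int(run.sum())
    if total == 0:
        return counts
    ii = np.repeat(i_idx, run)
    jj = np.arange(total) - np.repeat(np.cumsum(run) - run, run) + np.repeat(i_idx + 1, run)
    # drop coordinate-identical interval pairs (100% mutual overlap)
    identical = (start[ii] == start[jj]) & (end[ii] == end[jj])
    keep = ~identical
    ii, jj = ii[keep], jj[keep]
    a = np.minimum(motif[ii], motif[jj])
    b = np.maximum(motif[ii], motif[jj])
    flat = np.bincount(a * n_motifs + b, minlength=n_motifs * n_motifs)
    upper = flat.reshape(n_motifs, n_motifs)
    counts = upper + np.triu(upper, k=1).T
    return counts


def count_pairs(
    hits: Mapping[str, IntervalSet],
    regions: IntervalSet,
    window: int = 50,
    anchor: str = "center",
) -> PairCounts:
    """Count co-localized motif pairs within a region set.

    Only hit instances overlapping >= 1 bp of ``regions`` are considered. An
    unordered pair of distinct instances is counted when their separation is
    at most ``window`` bp — measured center-to-center by default, or as the
    edge-to-edge gap with ``anchor="edge"``. Pairs of coordinate-identical
    intervals (100% mutual overlap, as arise from overlapping motif
    definitions) are excluded. Homotypic pairs land on the diagonal, so k
    mutually close instances of one motif contribute C(k, 2).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if anchor not in ("center", "edge"):
        raise ValueError("anchor must be 'center' or 'edge'")
    chrom, center, start, end, motif, names, _ = _hit_arrays(hits)
    n_motifs = len(names)
    if len(chrom):
        hit_df = pd.DataFrame({
            "chrom": _chrom_names(hits, chrom),
            "start": start,
            "end": end,
        })
        include = _overlap_mask(hit_df, regions)
    else:
        include = np.zeros(0, dtype=bool)
    if anchor == "edge":
        # effective distance between edges: gap = max(starts) - min(ends);
        # implemented by counting on center coordinates with a per-pair
        # width correction, so fall back to an exact quadratic scan
        counts = _count_edge(chrom, start, end, motif, n_motifs, window, include)
    else:
        counts = _count_core(chrom, center, start, end, motif, n_motifs, float(window), include)
    matrix = pd.DataFrame(counts, index=names, columns=names)
    return PairCounts(matrix=matrix, n_regions=len(regions), window=window)


def _chrom_names(hits: Mapping[str, IntervalSet], chrom_codes: np.ndarray) -> np.ndarray:
    # rebuild the chromosome name per sorted hit; codes were factorized with
    # sort=True over the pooled frame
    motif_names = sorted(hits)
    all_chroms = sorted(
        set().union(*[set(hits[m].df["chrom"].unique()) for m in motif_names])
        if motif_names
        else set()
    )
    lookup = np.asarray(all_chroms, dtype=object)
    return lookup[chrom_codes]


def _overlap_mask(hit_df: pd.DataFrame, regions: IntervalSet) -> np.ndarray:
    from .intervals import overlap_any

    order_iv = IntervalSet(hit_df.assign(name=np.arange(len(hit_df))))
    hit, _ = overlap_any(order_iv, regions)
    orig = order_iv.df["name"].to_numpy(np.int64)
    mask = np.zeros(len(hit_df), dtype=bool)
    mask[orig[hit]] = True
    return mask


def _count_edge(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    motif: np.ndarray,
    n_motifs: int,
    window: float,
    include: np.ndarray | None,
) -> np.ndarray:
    """Quadratic edge-gap pair counting (small inputs; optional anchor mode)."""
    if include is not None:
        chrom, start, end, motif = chrom[include], start[include], end[include], motif[include]
    counts = np.zeros((n_motifs, n_motifs), dtype=np.int64)
    n = len(start)
    for i in range(n):
        for j in range(i + 1, n):
            if chrom[i] != chrom[j]:
                continue
            if start[i] == start[j] and end[i] == end[j]:
                continue
            gap = max(start[i], start[j]) - min(end[i], end[j])
            if gap <= window:
                a, b = sorted((motif[i], motif[j]))
                counts[a, b] += 1
                if a != b:
                    counts[b, a] += 1
    return counts


# ---------------------------------------------------------------------------
# Resampled null and z-scores
# ---------------------------------------------------------------------------

def resample_null(
    hits: Mapping[str, IntervalSet],
    universe: IntervalSet,
    n_draw: int,
    reps: int = 1000,
    seed: int = 0,
    window: int = 50,
) -> NullDistribution:
    """Null pair-count distribution from repeated uniform region draws.

    Each rep draws ``n_draw`` regions from ``universe`` without replacement
    (draws independent across reps), recounts motif pairs on the drawn set,
    and accumulates. ``sigma`` is the sample standard deviation (ddof=1).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if n_draw > len(universe):
        raise ValueError(
            f"n_draw ({n_draw}) exceeds the universe size ({len(universe)})"
        )
    chrom, center, start, end, motif, names, _ = _hit_arrays(hits)
    n_motifs = len(names)
    rng = np.random.default_rng(seed)

    # map hits to the universe regions they overlap, once
    hit_df = pd.DataFrame({"chrom": _chrom_names(hits, chrom), "start": start, "end": end})
    order_iv = IntervalSet(hit_df.assign(name=np.arange(len(hit_df))))
    qi, si = overlap_join(order_iv, universe) if len(hit_df) else (np.array([], int), np.array([], int))
    orig = order_iv.df["name"].to_numpy(np.int64)
    hit_idx = orig[qi] if len(qi) else np.array([], dtype=np.int64)

    n_univ = len(universe)
    acc = np.zeros((n_motifs, n_motifs), dtype=np.float64)
    acc2 = np.zeros_like(acc)
    for _ in range(reps):
        drawn = rng.choice(n_univ, size=n_draw, replace=False)
        sampled = np.zeros(n_univ, dtype=bool)
        sampled[drawn] = True
        inc = np.zeros(len(chrom), dtype=bool)
        if len(hit_idx):
            take = sampled[si]
            inc[hit_idx[take]] = True
        c = _count_core(chrom, center, start, end, motif, n_motifs, float(window), inc)
        acc += c
        acc2 += c.astype(np.float64) ** 2
    mu = acc / reps
    var = (acc2 - reps * mu**2) / (reps - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))
    return NullDistribution(
        mu=pd.DataFrame(mu, index=names, columns=names),
        sigma=pd.DataFrame(sigma, index=names, columns=names),
        reps=reps,
        n_draw=n_draw,
        seed=seed,
        window=window,
    )


def zscore(x: PairCounts, null: NullDistribution, cap: float = 10.0) -> ZScores:
    """z = (x - mu) / sigma per motif pair, with zero-sigma handling.

    Where sigma is zero: z = 0 if the observed count equals the null mean,
    otherwise +/-cap with the ``capped`` flag set.
    """
    if list(x.matrix.index) != list(null.mu.index):
        raise ValueError("pair universes of counts and null differ")
    xm = x.matrix.to_numpy(float)
    mu = null.mu.to_numpy(float)
    sd = null.sigma.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (xm - mu) / sd
    capped = sd == 0
    z = np.where(capped & (xm == mu), 0.0, z)
    z = np.where(capped & (xm > mu), cap, z)
    z = np.where(capped & (xm < mu), -cap, z)
    capped = capped & (xm != mu)
    idx = x.matrix.index
    return ZScores(
        matrix=pd.DataFrame(z, index=idx, columns=idx),
        capped=pd.DataFrame(capped, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# Relative enrichment
# ---------------------------------------------------------------------------

def relative_enrichment(
    n: pd.DataFrame, m: pd.Series | Sequence[float]
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative motif enrichment S_ij = (n_ij/m_j) / (sum_j n_ij / sum_j m_j).

    ``n`` holds motif instance counts (motifs x peak sets) and ``m`` the peak
    set sizes. Rows with no instances anywhere are NaN and flagged undefined.
    The m_j-weighted mean of every defined row is exactly 1.
    """
    m = pd.Series(np.asarray(m, dtype=float), index=n.columns)
    if (m <= 0).any():
        raise ValueError("all peak set sizes m_j must be > 0")
    totals = n.sum(axis=1).to_numpy(float)
    pooled_rate = totals / float(m.sum())
    rates = n.to_numpy(float) / m.to_numpy(float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = rates / pooled_rate[:, None]
    undefined = pd.Series(totals == 0, index=n.index, name="undefined")
    s = pd.DataFrame(s, index=n.index, columns=n.columns)
    s[undefined.to_numpy()] = np.nan
    return s, undefined


# ---------------------------------------------------------------------------
# Scaling and clustering for heatmap ordering
# ---------------------------------------------------------------------------

def zscale(matrix: pd.DataFrame, axis: str = "column") -> tuple[pd.DataFrame, pd.Series]:
    """Standardize each row or column to mean 0, sd 1 (population sd).

    Constant vectors become all-zero and are flagged.
    """
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    arr = matrix.to_numpy(float)
    ax = 1 if axis == "row" else 0
    if arr.shape[ax] < 2:
        raise ValueError("scaled axis must have >= 2 entries")
    mean = arr.mean(axis=ax, keepdims=True)
    sd = arr.std(axis=ax, keepdims=True)
    const = sd == 0
    safe_sd = np.where(const, 1.0, sd)
    scaled = (arr - mean) / safe_sd
    scaled = np.where(np.broadcast_to(const, arr.shape), 0.0, scaled)
    flags = pd.Series(
        const.ravel(), index=matrix.index if axis == "row" else matrix.columns,
        name="constant",
    )
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), flags


def hcluster_order(matrix: pd.DataFrame, axis: str = "row") -> tuple[list, np.ndarray]:
    """Leaf order from complete-linkage clustering of Euclidean distances.

    Returns the ordered labels along the chosen axis plus the scipy linkage
    matrix (merge tree). Undefined (NaN) entries must be filtered first.
    """
    arr = matrix.to_numpy(float)
    if axis == "column":
        arr = arr.T
        labels = list(matrix.columns)
    elif axis == "row":
        labels = list(matrix.index)
    else:
        raise ValueError("axis must be 'row' or 'column'")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 vectors to cluster")
    if np.isnan(arr).any():
        raise ValueError(
            "matrix contains undefined entries; filter or flag rows before clustering"
        )
    Z = linkage(pdist(arr, metric="euclidean"), method="complete")
    order = leaves_list(Z)
    return [labels[i] for i in order], Z
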