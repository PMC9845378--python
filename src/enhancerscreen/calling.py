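"""Enhancer-positive site calling from filtered reporter fragments.

The calling chain mirrors the screen's filtering logic: deduplicate
fragments, drop any with a perfect coordinate match in the PCR background
library, keep only fragments in the open chromatin of their own stage,
classify promoter vs distal by the 1.5 kb TSS rule, call a site positive when
at least one positive-bin (low/medium/high YFP) fragment overlaps it, require
the call in both replicates, and binarize the consensus across stages into an
activity-pattern matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, Ledger, merge_overlapping, overlap_any, overlap_join
from .simulate import POSITIVE_BINS

_BIN_PRIORITY = {b: i for i, b in enumerate(("high", "medium", "low", "negative"))}


@dataclass
class FilterLedger:
    """Per stage x replicate audit of the filtering chain."""

    steps: dict[tuple[str, int], Ledger] = field(default_factory=dict)

    def ledger(self, stage: str, replicate: int) -> Ledger:
        return self.steps.setdefault((stage, replicate), Ledger())

    def reconciles(self) -> bool:
        return all(l.reconciles() for l in self.steps.values())

    def to_dict(self) -> dict:
        return {f"{s}_rep{r}": l.to_dict() for (s, r), l in sorted(self.steps.items())}


def dedupe_labelled(frags: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one record per distinct (chrom, start, end) coordinate tuple.

    When coordinate-identical records carry different YFP bins the
    highest-intensity bin wins (high > medium > low > negative), so a genuine
    sorting event is never masked by a coincidentally identical fragment.
    """
    prio = frags["yfp_bin"].map(_BIN_PRIORITY)
    ordered = frags.assign(_prio=prio).sort_values(
        ["chrom", "start", "end", "_prio"], kind="mergesort"
    )
    kept = ordered.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    kept = kept.drop(columns="_prio").reset_index(drop=True)
    return kept, len(frags) - len(kept)


def remove_background(
    fragments: pd.DataFrame | IntervalSet, background: IntervalSet
) -> tuple[pd.DataFrame | IntervalSet, int]:
    """Drop fragments with a perfect (chrom, start, end) match in the background.

    Only exact coordinate identity counts; partial overlaps are retained.
    """
    bg = background.coordinate_tuples()
    if isinstance(fragments, IntervalSet):
        df = fragments.df
        mask = [
            (c, int(s), int(e)) not in bg
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        kept = fragments.subset(np.asarray(mask))
        return kept, len(df) - len(kept)
    mask = [
        (c, int(s), int(e)) not in bg
        for c, s, e in zip(fragments["chrom"], fragments["start"], fragments["end"])
    ]
    kept = fragments[np.asarray(mask)].reset_index(drop=True)
    return kept, len(fragments) - len(kept)


def restrict_to_open_chromatin(
    fragments: pd.DataFrame, stage_sites: IntervalSet, stage: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Keep fragments overlapping (>= 1 bp) an open-chromatin site of their stage."""
    if stage is not None and len(fragments):
        if not (fragments["stage"] == stage).all():
            raise ValueError("fragment stage labels do not match the site set's stage")
    # sort the frame with the same stable key IntervalSet uses so the overlap
    # labels align row-for-row
    ordered = fragments.sort_values(["chrom", "start", "end"], kind="mergesort")
    frag_iv = IntervalSet(ordered[["chrom", "start", "end"]])
    hit, _ = overlap_any(frag_iv, stage_sites)
    kept = ordered.iloc[np.flatnonzero(hit)].reset_index(drop=True)
    return kept, len(fragments) - len(kept)


def classify_promoter_distal(
    intervals: IntervalSet, tss: IntervalSet, threshold: int = 1500
) -> np.ndarray:
    """Label each interval ``promoter`` or ``distal`` by center-to-TSS distance.

    Promoter iff the interval center lies within ``threshold`` bp (inclusive)
    of the nearest TSS on the same chromosome.
    """
    if not len(tss):
        raise ValueError("TSS set must be non-empty")
    tss_by_chrom = {
        chrom: np.sort(sub["start"].to_numpy())
        for chrom, sub in tss.df.groupby("chrom")
    }
    out = np.empty(len(intervals), dtype=object)
    df = intervals.df
    centers = intervals.centers()
    for i, chrom in enumerate(df["chrom"]):
        pos = tss_by_chrom.get(chrom)
        if pos is None:
            out[i] = "distal"
            continue
        j = np.searchsorted(pos, centers[i])
        d = min(
            abs(centers[i] - pos[j - 1]) if j > 0 else np.inf,
            abs(pos[j] - centers[i]) if j < len(pos) else np.inf,
        )
        out[i] = "promoter" if d <= threshold else "distal"
    return out


def call_sites(sites: IntervalSet, fragments: pd.DataFrame) -> pd.DataFrame:
    """Call each site positive iff >= 1 overlapping positive-bin fragment.

    ``fragments`` must carry ``yfp_bin``; only low/medium/high records count
    as evidence. Returns a table aligned to ``sites`` order with the call and
    the number of distinct positive fragments overlapping the site.
    """
    pos = fragments[fragments["yfp_bin"].isin(POSITIVE_BINS)]
    pos = pos.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    counts = np.zeros(len(sites), dtype=np.int64)
    if len(pos):
        pos_iv = IntervalSet(pos[["chrom", "start", "end"]])
        qi, si = overlap_join(pos_iv, sites)
        np.add.at(counts, si, 1)
    out = sites.df[["chrom", "start", "end"]].copy()
    if "name" in sites.df.columns:
        out["site"] = sites.df["name"]
    out["n_positive_fragments"] = counts
    out["call"] = np.where(counts >= 1, "positive", "negative_unknown")
    return out


def replicate_consensus(call_a: pd.DataFrame, call_b: pd.DataFrame) -> pd.DataFrame:
    """Consensus call: positive iff positive in both replicates."""
    key = ["chrom", "start", "end"]
    if not call_a[key].reset_index(drop=True).equals(call_b[key].reset_index(drop=True)):
        raise ValueError("replicate call tables cover different site universes")
    out = call_a[key].copy()
    if "site" in call_a.columns:
        out["site"] = call_a["site"].to_numpy()
    both = (call_a["call"].to_numpy() == "positive") & (
        call_b["call"].to_numpy() == "positive"
    )
    out["call"] = np.where(both, "positive", "negative_unknown")
    out["n_positive_fragments"] = np.minimum(
        call_a["n_positive_fragments"].to_numpy(),
        call_b["n_positive_fragments"].to_numpy(),
    )
    out["rep1_positive"] = call_a["call"].to_numpy() == "positive"
    out["rep2_positive"] = call_b["call"].to_numpy() == "positive"
    return out


def fragment_level_consensus(
    frags_a: pd.DataFrame, frags_b: pd.DataFrame
) -> pd.DataFrame:
    """Keep replicate-A fragments whose exact coordinates recur in replicate B.

    An alternative, stricter consensus that intersects at the fragment level
    before any site call; the default pipeline intersects at the site level.
    """
    in_b = set(zip(frags_b["chrom"], frags_b["start"].astype(int), frags_b["end"].astype(int)))
    mask = [
        (c, int(s), int(e)) in in_b
        for c, s, e in zip(frags_a["chrom"], frags_a["start"], frags_a["end"])
    ]
    return frags_a[np.asarray(mask, dtype=bool)].reset_index(drop=True)


def binarize_activity(
    stage_calls: Mapping[str, pd.DataFrame],
    stage_names: Sequence[str],
) -> pd.DataFrame:
    """Merge per-stage site calls into one binary activity matrix.

    Sites from all stages are merged by single-linkage overlap into union
    elements; a merged element is active (1) in a stage iff any constituent
    site of that stage was called positive there. Rows are sorted by pattern
    code (lexicographic) then coordinates.
    """
    pooled_rows = []
    for stage in stage_names:
        tab = stage_calls[stage]
        for row in tab.itertuples(index=False):
            pooled_rows.append(
                (row.chrom, int(row.start), int(row.end), stage, row.call == "positive")
            )
    pooled = pd.DataFrame(
        pooled_rows, columns=["chrom", "start", "end", "stage", "positive"]
    )
    pooled_iv = IntervalSet(pooled[["chrom", "start", "end"]])
    merged, assignment = merge_overlapping(pooled_iv)
    # align pooled rows with sorted IntervalSet order
    pooled_sorted = pooled.sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)
    mat = np.zeros((len(merged), len(stage_names)), dtype=int)
    stage_idx = {s: k for k, s in enumerate(stage_names)}
    for i, row in enumerate(pooled_sorted.itertuples(index=False)):
        if row.positive:
            mat[assignment[i], stage_idx[row.stage]] = 1
    out = merged.df[["chrom", "start", "end"]].copy()
    out["enhancer"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    for k, s in enumerate(stage_names):
        out[s] = mat[:, k]
    out["pattern"] = ["".join(map(str, r)) for r in mat]
    out = out.sort_values(
        ["pattern", "chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def stage_specific_sets(
    matrix: pd.DataFrame, stage_names: Sequence[str]
) -> dict[str, IntervalSet]:
    """Per-stage sets of elements active in exactly that one stage."""
    mat = matrix[list(stage_names)].to_numpy()
    exclusive = mat.sum(axis=1) == 1
    out = {}
    for k, stage in enumerate(stage_names):
        mask = exclusive & (mat[:, k] == 1)
        out[stage] = IntervalSet(matrix.loc[mask, ["chrom", "start", "end"]])
    return out


def median_positive_fragments(
    call_table: pd.DataFrame, classes: np.ndarray, cls: str = "distal"
) -> float:
    """Median positive-fragment count over positive sites of one class."""
    mask = (call_table["call"].to_numpy() == "positive") & (classes == cls)
    vals = call_table.loc[mask, "n_positive_fragments"].to_numpy()
    if not len(vals):
        return float("nan")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# End-to-end convenience pipeline
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    stage_calls: dict[str, pd.DataFrame]
    per_replicate_calls: dict[tuple[str, int], pd.DataFrame]
    activity: pd.DataFrame
    ledger: FilterLedger


def call_screen(
    fragments: pd.DataFrame,
    background: IntervalSet,
    stage_sites: Mapping[str, IntervalSet],
    stage_names: Sequence[str],
    replicates: Sequence[int] = (1, 2),
) -> CallResult:
    """Run the full filtering and calling chain over every stage.

    ``fragments`` is a long table with chrom/start/end/stage/yfp_bin/replicate.
    Returns consensus per-stage calls, per-replicate calls, the binarized
    activity matrix over the cross-stage site union, and a filter ledger that
    reconciles exactly at every step.
    """
    ledger = FilterLedger()
    per_rep: dict[tuple[str, int], pd.DataFrame] = {}
    stage_calls: dict[str, pd.DataFrame] = {}
    for stage in stage_names:
        sites = stage_sites[stage]
        rep_tables = []
        for rep in replicates:
            sample = fragments[
                (fragments["stage"] == stage) & (fragments["replicate"] == rep)
            ].reset_index(drop=True)
            led = ledger.ledger(stage, rep)
            led.n_input = len(sample)
            sample, n_dup = dedupe_labelled(sample)
            led.record("duplicates", n_dup)
            sample, n_bg = remove_background(sample, background)
            led.record("background_perfect_overlap", n_bg)
            sample, n_out = restrict_to_open_chromatin(sample, sites, stage=stage)
            led.record("outside_open_chromatin", n_out)
            led.n_retained = len(sample)
            calls = call_sites(sites, sample)
            per_rep[(stage, rep)] = calls
            rep_tables.append(calls)
        cons = rep_tables[0]
        for nxt in rep_tables[1:]:
            cons = replicate_consensus(cons, nxt)
        stage_calls[stage] = cons
    activity = binarize_activity(stage_calls, stage_names)
    return CallResult(
        stage_calls=stage_calls,
        per_replicate_calls=per_rep,
        activity=activity,
        ledger=ledger,
    )
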