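"""Synthetic enhancer-screen generator with known ground truth.

Emulates a chromatin-integrated reporter screen across five differentiation
stages (ES, HB, HE1, HE2, HP by default): stage-specific open-chromatin
sites, activity-labelled reporter fragments sorted into four YFP intensity
bins, PCR background artifacts, planted motif co-localizations, negative
binomial accessibility counts with planted fold changes, and a partial
enhancer-to-gene interaction map. Every emitted record is traceable to a
truth table, so downstream calling, statistics and linking can be scored
exactly.

Geometry is chosen so that noiseless settings allow exact recovery: candidate
loci sit on a slot grid with a configurable minimum gap (default 700 bp,
larger than the longest reporter fragment) and distal loci keep their edges
at least ``tss_exclusion`` bp away from every TSS, so a fragment can only
ever overlap its source locus and interaction anchors match uniquely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, write_bed

YFP_BINS = ("negative", "low", "medium", "high")
POSITIVE_BINS = ("low", "medium", "high")

DEFAULT_STAGES = ("ES", "HB", "HE1", "HE2", "HP")

DEFAULT_MOTIFS = (
    ("RUNX", 8),
    ("GATA", 6),
    ("ETS", 8),
    ("SOX", 7),
    ("TEAD", 8),
    ("AP1", 7),
    ("EBOX", 6),
    ("NFKB", 10),
)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedPair:
    """A motif pair co-localized above baseline in one stage's specific sites."""

    motif_a: str
    motif_b: str
    stage: str
    multiplier: float = 5.0
    max_dist: int = 40


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic screen.

    Defaults describe the study conditions the generator emulates: 350-650 bp
    size-selected reporter fragments, four YFP sort bins, two replicates,
    five differentiation stages, and a ~1% PCR-artifact rate.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_len: int = 10_000_000
    n_genes: int = 300
    tss_min_spacing: int = 5_000
    n_sites_per_stage: int = 500
    stage_names: tuple[str, ...] = DEFAULT_STAGES
    site_len_range: tuple[int, int] = (200, 1000)
    site_gap_min: int = 700
    tss_exclusion: int = 2_200
    promoter_site_fraction: float = 0.1
    site_sharing: float = 0.4
    frag_len_range: tuple[int, int] = (350, 650)
    frags_per_site_mean: float = 3.0
    n_replicates: int = 2
    true_positive_fraction: float = 0.3
    duplicate_rate: float = 0.1
    background_artifact_rate: float = 0.01
    n_background: int = 2_000
    motifs: tuple[tuple[str, int], ...] = DEFAULT_MOTIFS
    motif_baseline_rate: float = 1.0
    planted_pairs: tuple[PlantedPair, ...] = ()
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    diff_planted_fraction: float = 0.1
    diff_fold: float = 4.0
    interaction_coverage: float = 0.7
    n_candidate_genes: int = 3
    expr_high: float = 8.0
    expr_low: float = 2.0
    expr_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        rates = {
            "site_sharing": self.site_sharing,
            "promoter_site_fraction": self.promoter_site_fraction,
            "true_positive_fraction": self.true_positive_fraction,
            "duplicate_rate": self.duplicate_rate,
            "background_artifact_rate": self.background_artifact_rate,
            "diff_planted_fraction": self.diff_planted_fraction,
            "interaction_coverage": self.interaction_coverage,
        }
        for key, val in rates.items():
            if not 0.0 <= val <= 1.0:
                raise SimConfigError(f"{key} must be in [0, 1], got {val}")
        lo, hi = self.frag_len_range
        if not 0 < lo <= hi < self.chrom_len:
            raise SimConfigError(f"frag_len_range {self.frag_len_range} invalid")
        lo, hi = self.site_len_range
        if not 0 < lo <= hi:
            raise SimConfigError(f"site_len_range {self.site_len_range} invalid")
        if self.n_chroms < 1 or self.chrom_len < 10_000:
            raise SimConfigError("genome too small")
        motif_names = [m for m, _ in self.motifs]
        if len(set(motif_names)) != len(motif_names):
            raise SimConfigError("motif names must be unique")
        widths = dict(self.motifs)
        for name, w in widths.items():
            if w > self.site_len_range[0]:
                raise SimConfigError(f"motif {name} wider than the smallest site")
        for pp in self.planted_pairs:
            if pp.motif_a not in widths or pp.motif_b not in widths:
                raise SimConfigError(f"planted pair names unknown: {pp}")
            if pp.stage not in self.stage_names:
                raise SimConfigError(f"planted pair stage unknown: {pp.stage}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one operation stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# streams so each operation is deterministic on its own
_S_ANNOT, _S_SITES, _S_FRAGS, _S_MOTIF, _S_COUNT, _S_INTER = range(6)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    chroms: pd.DataFrame  # chrom, length
    tss: pd.DataFrame  # chrom, pos, gene

    @property
    def tss_intervals(self) -> IntervalSet:
        df = self.tss
        return IntervalSet(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["pos"],
                    "end": df["pos"] + 1,
                    "name": df["gene"],
                }
            )
        )


def gen_annotation(config: SimConfig) -> Annotation:
    """Place gene TSS uniformly per chromosome with a minimum spacing."""
    rng = config.rng(_S_ANNOT)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chroms = pd.DataFrame({"chrom": chrom_names, "length": config.chrom_len})
    per = np.full(config.n_chroms, config.n_genes // config.n_chroms, dtype=int)
    per[: config.n_genes % config.n_chroms] += 1
    rows = []
    gid = 0
    for chrom, n_g in zip(chrom_names, per):
        if n_g == 0:
            continue
        slack = config.chrom_len - n_g * config.tss_min_spacing
        if slack <= 0:
            raise SimConfigError(
                f"{n_g} genes with spacing {config.tss_min_spacing} do not fit on {chrom}"
            )
        offsets = np.sort(rng.uniform(0, slack, size=n_g))
        pos = (
            offsets
            + np.arange(n_g) * config.tss_min_spacing
            + config.tss_min_spacing / 2
        ).astype(np.int64)
        for p in pos:
            rows.append((chrom, int(p), f"gene{gid:05d}"))
            gid += 1
    tss = pd.DataFrame(rows, columns=["chrom", "pos", "gene"])
    return Annotation(chroms=chroms, tss=tss)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

@dataclass
class SiteCatalog:
    """Candidate open-chromatin loci with stage membership and true activity.

    ``table`` has one row per locus: chrom/start/end/summit/locus/cls plus
    per-stage boolean columns ``open_<stage>`` and ``active_<stage>`` and the
    truth-linked ``gene``.
    """

    table: pd.DataFrame
    stage_names: tuple[str, ...]

    def stage_sites(self, stage: str, cls: str | None = None) -> IntervalSet:
        df = self.table[self.table[f"open_{stage}"]]
        if cls is not None:
            df = df[df["cls"] == cls]
        return IntervalSet(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df["locus"],
                    "summit": df["summit"],
                }
            )
        )

    def union_sites(self, cls: str | None = None) -> IntervalSet:
        df = self.table if cls is None else self.table[self.table["cls"] == cls]
        return IntervalSet(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df["locus"],
                    "summit": df["summit"],
                }
            )
        )

    def truth_pattern(self, locus_order: Sequence[str] | None = None) -> pd.Series:
        """True activity pattern code (e.g. ``"00101"``) per locus."""
        df = self.table.set_index("locus")
        codes = df[[f"active_{s}" for s in self.stage_names]].astype(int).astype(str)
        return codes.agg("".join, axis=1)


def _slot_grid(config: SimConfig, ann: Annotation) -> pd.DataFrame:
    """All placement slots that avoid TSS exclusion zones.

    A slot is a window of ``max site length`` starting on a grid with pitch
    (max_len + site_gap_min); any locus placed at a slot start stays inside
    the slot, so distinct slots never come closer than the minimum gap.
    """
    max_len = config.site_len_range[1]
    pitch = max_len + config.site_gap_min
    rows = []
    for chrom, length in zip(ann.chroms["chrom"], ann.chroms["length"]):
        tss_pos = np.sort(
            ann.tss.loc[ann.tss["chrom"] == chrom, "pos"].to_numpy()
        )
        starts = np.arange(config.site_gap_min, length - max_len - 1, pitch)
        if len(tss_pos):
            lo = np.searchsorted(tss_pos, starts - config.tss_exclusion)
            hi = np.searchsorted(tss_pos, starts + max_len + config.tss_exclusion)
            starts = starts[lo == hi]  # no TSS within the exclusion margin
        for s in starts:
            rows.append((chrom, int(s)))
    return pd.DataFrame(rows, columns=["chrom", "slot_start"])


def gen_sites(config: SimConfig, ann: Annotation) -> SiteCatalog:
    """Generate candidate loci, stage membership, classes and true activity.

    A fraction ``site_sharing`` of each stage's sites is shared by all stages
    (constitutive loci); the rest are exclusive to one stage. A fraction
    ``promoter_site_fraction`` of loci is placed within 1.4 kb of a TSS so a
    promoter class exists; the remainder are distal by construction.
    """
    rng = config.rng(_S_SITES)
    n_shared = int(round(config.site_sharing * config.n_sites_per_stage))
    n_excl = config.n_sites_per_stage - n_shared
    n_stages = len(config.stage_names)
    n_total = n_shared + n_excl * n_stages
    n_prom = int(round(config.promoter_site_fraction * n_total))
    n_distal = n_total - n_prom

    slots = _slot_grid(config, ann)
    if len(slots) < n_distal:
        raise SimConfigError(
            f"genome holds only {len(slots)} distal slots, need {n_distal}; "
            "increase chrom_len or n_chroms"
        )
    take = rng.choice(len(slots), size=n_distal, replace=False)
    take.sort()
    chosen = slots.iloc[take]

    lo, hi = config.site_len_range
    rows = []
    for i, (chrom, slot_start) in enumerate(
        zip(chosen["chrom"], chosen["slot_start"])
    ):
        length = int(rng.integers(lo, hi + 1))
        start = int(slot_start)
        end = start + length
        summit = int(rng.integers(start + length // 4, end - length // 4 + 1))
        rows.append((chrom, start, end, summit, "distal"))

    # promoter-class loci: centered within 1.4 kb of distinct TSS
    if n_prom:
        if n_prom > len(ann.tss):
            raise SimConfigError("more promoter loci requested than genes")
        gene_rows = rng.choice(len(ann.tss), size=n_prom, replace=False)
        gene_rows.sort()
        for gi in gene_rows:
            chrom = ann.tss["chrom"].iat[gi]
            tpos = int(ann.tss["pos"].iat[gi])
            length = int(rng.integers(lo, min(hi, 1000) + 1))
            offset = int(rng.integers(-1400 + length // 2, 1400 - length // 2 + 1))
            center = tpos + offset
            start = max(0, center - length // 2)
            end = start + length
            summit = int(rng.integers(start + length // 4, end - length // 4 + 1))
            rows.append((chrom, start, end, summit, "promoter"))

    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "cls"])
    table = table.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    table["locus"] = [f"L{i:06d}" for i in range(len(table))]

    # stage membership: shuffle loci, first block shared, then per-stage blocks
    order = rng.permutation(len(table))
    for s in config.stage_names:
        table[f"open_{s}"] = False
    shared = order[:n_shared]
    pos = n_shared
    for col in (f"open_{s}" for s in config.stage_names):
        table.loc[table.index[shared], col] = True
    for s in config.stage_names:
        block = order[pos : pos + n_excl]
        pos += n_excl
        table.loc[table.index[block], f"open_{s}"] = True
    # remaining loci (promoter extras) join all stages so promoters are broadly open
    rest = order[pos:]
    for s in config.stage_names:
        table.loc[table.index[rest], f"open_{s}"] = True

    # true activity: among open loci of each stage, Bernoulli(true_positive_fraction)
    for s in config.stage_names:
        open_mask = table[f"open_{s}"].to_numpy()
        act = np.zeros(len(table), dtype=bool)
        act[open_mask] = rng.random(int(open_mask.sum())) < config.true_positive_fraction
        table[f"active_{s}"] = act

    # truth gene link: one of the k nearest TSS by center distance
    tss_by_chrom = {
        c: sub.sort_values("pos").reset_index(drop=True)
        for c, sub in ann.tss.groupby("chrom")
    }
    genes = []
    for chrom, start, end in zip(table["chrom"], table["start"], table["end"]):
        sub = tss_by_chrom.get(chrom)
        if sub is None or not len(sub):
            genes.append(None)
            continue
        center = (start + end) / 2
        d = np.abs(sub["pos"].to_numpy() - center)
        k = min(config.n_candidate_genes, len(sub))
        nearest = np.argsort(d, kind="stable")[:k]
        genes.append(sub["gene"].iat[int(rng.choice(nearest))])
    table["gene"] = genes

    return SiteCatalog(table=table, stage_names=config.stage_names)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class FragmentBundle:
    """Per-sample labelled fragments plus the standalone background library.

    ``fragments`` columns: chrom, start, end, stage, yfp_bin, replicate,
    source_locus (background spike-ins carry the locus value ``"background"``),
    is_duplicate, is_artifact.
    """

    fragments: pd.DataFrame
    background: pd.DataFrame  # chrom, start, end

    def sample(self, stage: str, replicate: int, bins: Sequence[str] | None = None) -> pd.DataFrame:
        df = self.fragments
        m = (df["stage"] == stage) & (df["replicate"] == replicate)
        if bins is not None:
            m &= df["yfp_bin"].isin(bins)
        return df[m]

    def background_intervals(self) -> IntervalSet:
        return IntervalSet(self.background[["chrom", "start", "end"]])


def _place_fragment(
    rng: np.random.Generator, chrom_len: int, site_start: int, site_end: int, lo: int, hi: int
) -> tuple[int, int]:
    length = int(rng.integers(lo, hi + 1))
    lo_start = max(0, site_start - (length - 1))
    hi_start = min(chrom_len - length, site_end - 1)
    start = int(rng.integers(lo_start, hi_start + 1))
    return start, start + length


def gen_fragments(config: SimConfig, catalog: SiteCatalog) -> FragmentBundle:
    """Emit per-sample reporter fragments and the PCR background library.

    Truly active loci emit at least one positive-bin fragment per replicate
    (low/medium/high chosen at random) plus Poisson extras; all open loci also
    emit negative-bin fragments. Exact duplicates are injected at
    ``duplicate_rate`` and background artifacts are both written to the
    standalone background library and spiked verbatim into samples at
    ``background_artifact_rate``.
    """
    rng = config.rng(_S_FRAGS)
    lo, hi = config.frag_len_range
    table = catalog.table
    rows: list[tuple] = []
    for stage in config.stage_names:
        open_mask = table[f"open_{stage}"].to_numpy()
        active_mask = table[f"active_{stage}"].to_numpy()
        idx = np.flatnonzero(open_mask)
        for rep in range(1, config.n_replicates + 1):
            for i in idx:
                chrom = table["chrom"].iat[i]
                s, e = int(table["start"].iat[i]), int(table["end"].iat[i])
                locus = table["locus"].iat[i]
                if active_mask[i]:
                    n_pos = 1 + rng.poisson(max(config.frags_per_site_mean - 1, 0.0))
                    for _ in range(n_pos):
                        fs, fe = _place_fragment(rng, config.chrom_len, s, e, lo, hi)
                        yfp = POSITIVE_BINS[int(rng.integers(0, 3))]
                        rows.append((chrom, fs, fe, stage, yfp, rep, locus, False, False))
                n_neg = rng.poisson(config.frags_per_site_mean)
                for _ in range(n_neg):
                    fs, fe = _place_fragment(rng, config.chrom_len, s, e, lo, hi)
                    rows.append((chrom, fs, fe, stage, "negative", rep, locus, False, False))

    cols = [
        "chrom", "start", "end", "stage", "yfp_bin", "replicate",
        "source_locus", "is_duplicate", "is_artifact",
    ]
    frags = pd.DataFrame(rows, columns=cols)

    # exact duplicates
    if config.duplicate_rate > 0 and len(frags):
        dup_mask = rng.random(len(frags)) < config.duplicate_rate
        dups = frags[dup_mask].copy()
        dups["is_duplicate"] = True
        frags = pd.concat([frags, dups], ignore_index=True)

    # background library: fragments independent of sites
    bg_rows = []
    chrom_names = sorted(table["chrom"].unique())
    for _ in range(config.n_background):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, config.chrom_len - length))
        bg_rows.append((chrom, start, start + length))
    background = pd.DataFrame(bg_rows, columns=["chrom", "start", "end"])

    # spike a fraction of artifacts verbatim into each stage x replicate sample
    if config.background_artifact_rate > 0 and len(background):
        spikes = []
        for stage in config.stage_names:
            for rep in range(1, config.n_replicates + 1):
                n_sample = int(
                    ((frags["stage"] == stage) & (frags["replicate"] == rep)).sum()
                )
                n_spike = int(round(config.background_artifact_rate * n_sample))
                if n_spike == 0:
                    continue
                pick = rng.integers(0, len(background), size=n_spike)
                for b in pick:
                    yfp = YFP_BINS[int(rng.integers(0, 4))]
                    spikes.append(
                        (
                            background["chrom"].iat[b],
                            int(background["start"].iat[b]),
                            int(background["end"].iat[b]),
                            stage, yfp, rep, "background", False, True,
                        )
                    )
        if spikes:
            frags = pd.concat(
                [frags, pd.DataFrame(spikes, columns=cols)], ignore_index=True
            )

    frags = frags.sort_values(
        ["stage", "replicate", "chrom", "start", "end", "yfp_bin"], kind="mergesort"
    ).reset_index(drop=True)
    return FragmentBundle(fragments=frags, background=background)


# ---------------------------------------------------------------------------
# Motif hits
# ---------------------------------------------------------------------------

def _pair_colocalization_expectation(
    rate_a: float, rate_b: float, site_len: int, max_dist: int, homotypic: bool
) -> float:
    """Expected pairs with center distance <= max_dist under uniform placement.

    For two independent uniforms on [0, L], P(|U - V| <= d) = (2dL - d^2)/L^2.
    Homotypic pairs count unordered distinct instances: E[C(K,2)] = rate^2/2
    for Poisson(rate).
    """
    L = max(site_len, 1)
    d = min(max_dist, L)
    p = (2 * d * L - d * d) / (L * L)
    if homotypic:
        return 0.5 * rate_a * rate_b * p
    return rate_a * rate_b * p


def gen_motif_hits(
    config: SimConfig, catalog: SiteCatalog
) -> tuple[dict[str, IntervalSet], pd.DataFrame]:
    """Scatter baseline motif hits per locus and plant co-localized pairs.

    Baseline: per locus and motif, Poisson(``motif_baseline_rate``) hits
    placed uniformly within the locus. Planting works by *repositioning*
    existing baseline hits rather than inserting new ones, so per-motif
    marginal hit counts are untouched and only the targeted pair's
    co-localization rate rises: in loci whose true activity is exclusive to
    the target stage, a randomly chosen hit of motif B is moved to within
    ``max_dist`` of a randomly chosen hit of motif A often enough that the
    expected per-site pair rate is ``multiplier`` times baseline.
    Returns per-motif hit sets plus the planted-pair truth table.
    """
    rng = config.rng(_S_MOTIF)
    widths = dict(config.motifs)
    names = list(widths)
    table = catalog.table

    # per-locus, per-motif center lists so planting can reposition in place
    locus_centers: list[dict[str, np.ndarray]] = []
    for start, end in zip(table["start"], table["end"]):
        length = int(end - start)
        per_motif = {}
        for name, w in widths.items():
            k = rng.poisson(config.motif_baseline_rate)
            per_motif[name] = (
                start + w / 2 + rng.random(k) * (length - w) if k else np.empty(0)
            )
        locus_centers.append(per_motif)

    truth_rows = []
    act_cols = [f"active_{s}" for s in config.stage_names]
    act = table[act_cols].to_numpy(bool)
    for pp in config.planted_pairs:
        if pp.multiplier <= 1.0:
            truth_rows.append((pp.motif_a, pp.motif_b, pp.stage, pp.multiplier, 0))
            continue
        stage_i = config.stage_names.index(pp.stage)
        exclusive = act[:, stage_i] & (act.sum(axis=1) == 1)
        target_idx = np.flatnonzero(exclusive & (table["cls"] == "distal").to_numpy())
        homotypic = pp.motif_a == pp.motif_b
        wa, wb = widths[pp.motif_a], widths[pp.motif_b]
        n_planted = 0
        for li in target_idx:
            start = int(table["start"].iat[li])
            end = int(table["end"].iat[li])
            length = end - start
            ca = locus_centers[li][pp.motif_a]
            cb = locus_centers[li][pp.motif_b]
            ka, kb = len(ca), len(cb)
            combos = ka * (ka - 1) / 2 if homotypic else ka * kb
            if combos == 0:
                continue
            L = max(length, 1)
            d = min(pp.max_dist, L)
            p0 = (2 * d * L - d * d) / (L * L)
            # each repositioning converts ~one non-co-located combo into a
            # co-located one; the Poisson rate is inflated to compensate for
            # truncation at the number of movable hits so the expected pair
            # rate scales by the multiplier
            target = (pp.multiplier - 1.0) * combos * p0 / max(1.0 - p0, 1e-9)
            max_moves = kb // 2 if homotypic else kb
            if max_moves == 0:
                continue
            if target >= max_moves:
                lam = 50.0 * max_moves  # effectively always saturate
            else:
                lam = -max_moves * np.log1p(-target / max_moves)
            r = min(int(rng.poisson(lam)), max_moves)
            if r == 0:
                continue
            if homotypic:
                movable = rng.permutation(kb)
                anchors, moved = movable[:r], movable[r : 2 * r]
            else:
                anchors = rng.integers(0, ka, size=r)
                moved = rng.permutation(kb)[:r]
            for ai, bi in zip(anchors, moved):
                anchor_c = ca[ai]
                delta = rng.uniform(-pp.max_dist, pp.max_dist)
                new_c = float(
                    np.clip(anchor_c + delta, start + wb / 2, end - wb / 2)
                )
                cb[bi] = new_c
                n_planted += 1
        truth_rows.append((pp.motif_a, pp.motif_b, pp.stage, pp.multiplier, n_planted))

    hits: dict[str, list[tuple]] = {name: [] for name in widths}
    for li, per_motif in enumerate(locus_centers):
        chrom = table["chrom"].iat[li]
        locus = table["locus"].iat[li]
        for name, centers in per_motif.items():
            w = widths[name]
            for c in centers:
                s = int(round(c - w / 2))
                hits[name].append((chrom, s, s + w, locus))

    hit_sets = {
        name: IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))
        for name, rows in hits.items()
    }
    truth = pd.DataFrame(
        truth_rows, columns=["motif_a", "motif_b", "stage", "multiplier", "n_planted"]
    )
    return hit_sets, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def gen_counts(
    config: SimConfig, site_union: IntervalSet | None = None, catalog: SiteCatalog | None = None
) -> pd.DataFrame:
    """Negative binomial count tables for two conditions x replicates.

    Variance model: var = mu + dispersion * mu^2 (dispersion -> 0 recovers
    Poisson). A random ``diff_planted_fraction`` of sites has its condition-B
    mean multiplied by ``diff_fold``; the truth fold is recorded per site.
    """
    if site_union is None:
        if catalog is None:
            raise ValueError("need site_union or catalog")
        site_union = catalog.union_sites()
    rng = config.rng(_S_COUNT)
    n = len(site_union)
    planted = rng.random(n) < config.diff_planted_fraction
    mu_a = np.full(n, config.nb_mean)
    mu_b = np.where(planted, config.nb_mean * config.diff_fold, config.nb_mean)

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion <= 1e-12:
            return rng.poisson(mu)
        shape = 1.0 / config.nb_dispersion
        p = shape / (shape + mu)
        return rng.negative_binomial(shape, p)

    df = site_union.df[["chrom", "start", "end", "name"]].copy()
    df = df.rename(columns={"name": "locus"})
    if "summit" in site_union.df.columns:
        df["summit"] = site_union.df["summit"].to_numpy()
    for rep in range(1, config.n_replicates + 1):
        df[f"A_rep{rep}"] = draw(mu_a)
        df[f"B_rep{rep}"] = draw(mu_b)
    df["true_fold"] = np.where(planted, config.diff_fold, 1.0)
    return df


# ---------------------------------------------------------------------------
# Interactions & expression
# ---------------------------------------------------------------------------

@dataclass
class InteractionData:
    interactions: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2,source
    expression: pd.DataFrame  # gene x stage
    covered_loci: pd.DataFrame  # locus, gene, covered


def gen_interactions(config: SimConfig, catalog: SiteCatalog, ann: Annotation) -> InteractionData:
    """Emit anchor pairs for a fraction of true enhancer-gene links.

    The enhancer-side anchor is the locus interval itself; the promoter-side
    anchor is the linked gene's TSS +/- 1500 bp window. Gene expression per
    stage is high (``expr_high``) when at least one truth-linked enhancer is
    active in that stage, low otherwise, plus Gaussian noise.
    """
    rng = config.rng(_S_INTER)
    distal = catalog.table[catalog.table["cls"] == "distal"].reset_index(drop=True)
    tss_pos = ann.tss.set_index("gene")[["chrom", "pos"]]

    covered = rng.random(len(distal)) < config.interaction_coverage
    rows = []
    for i in np.flatnonzero(covered):
        gene = distal["gene"].iat[i]
        if gene is None:
            continue
        gchrom, gpos = tss_pos.loc[gene, "chrom"], int(tss_pos.loc[gene, "pos"])
        rows.append(
            (
                distal["chrom"].iat[i],
                int(distal["start"].iat[i]),
                int(distal["end"].iat[i]),
                gchrom,
                max(0, gpos - 1500),
                gpos + 1500,
                "sim",
            )
        )
    interactions = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "source"],
    )

    # expression: high where any truth-linked enhancer is active
    genes = list(ann.tss["gene"])
    expr = pd.DataFrame(
        config.expr_low, index=pd.Index(genes, name="gene"), columns=list(config.stage_names)
    )
    for stage in config.stage_names:
        act = distal[distal[f"active_{stage}"]]
        hot = set(g for g in act["gene"] if g is not None)
        expr.loc[expr.index.isin(hot), stage] = config.expr_high
    expr = expr + rng.normal(0.0, config.expr_noise_sd, size=expr.shape)

    covered_loci = pd.DataFrame(
        {"locus": distal["locus"], "gene": distal["gene"], "covered": covered}
    )
    return InteractionData(interactions=interactions, expression=expr, covered_loci=covered_loci)


# ---------------------------------------------------------------------------
# Bundled generation and serialization
# ---------------------------------------------------------------------------

@dataclass
class ScreenData:
    """Everything one synthetic screen run produces, in memory."""

    config: SimConfig
    annotation: Annotation
    sites: SiteCatalog
    fragments: FragmentBundle
    motif_hits: dict[str, IntervalSet]
    motif_truth: pd.DataFrame
    counts: pd.DataFrame
    interactions: InteractionData


def simulate_screen(config: SimConfig) -> ScreenData:
    """Run every generator stage under one config; fully seed-deterministic."""
    ann = gen_annotation(config)
    sites = gen_sites(config, ann)
    frags = gen_fragments(config, sites)
    hits, motif_truth = gen_motif_hits(config, sites)
    counts = gen_counts(config, catalog=sites)
    inter = gen_interactions(config, sites, ann)
    return ScreenData(
        config=config,
        annotation=ann,
        sites=sites,
        fragments=frags,
        motif_hits=hits,
        motif_truth=motif_truth,
        counts=counts,
        interactions=inter,
    )


def write_screen(data: ScreenData, outdir) -> None:
    """Serialize a screen to plain-text files (BED/TSV/JSON), byte-stable."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(data.config)
    cfg["planted_pairs"] = [asdict(p) for p in data.config.planted_pairs]
    (out / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
    data.annotation.tss.to_csv(out / "tss.tsv", sep="\t", index=False)
    data.sites.table.to_csv(out / "sites.tsv", sep="\t", index=False)
    for stage in data.config.stage_names:
        write_bed(data.sites.stage_sites(stage), out / f"sites_{stage}.bed")
    frags = data.fragments.fragments
    for (stage, rep), sub in frags.groupby(["stage", "replicate"], sort=True):
        sub = sub.sort_values(["chrom", "start", "end", "yfp_bin"], kind="mergesort")
        path = out / f"frags_{stage}_rep{rep}.bed"
        with open(path, "w") as fh:
            for r in sub.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.yfp_bin}\n")
    data.fragments.background.to_csv(
        out / "background.bed", sep="\t", index=False, header=False
    )
    for name, iset in sorted(data.motif_hits.items()):
        write_bed(iset, out / f"motif_{name}.bed")
    data.motif_truth.to_csv(out / "motif_truth.tsv", sep="\t", index=False)
    data.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    data.interactions.interactions.to_csv(
        out / "interactions.bedpe", sep="\t", index=False, header=False
    )
    data.interactions.expression.to_csv(out / "expression.tsv", sep="\t")
    data.interactions.covered_loci.to_csv(out / "links_truth.tsv", sep="\t", index=False)
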