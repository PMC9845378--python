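"""Enhancer-to-gene assignment via interaction anchors with nearest-TSS fallback.

An enhancer is linked to a gene when it overlaps one anchor of a chromatin
interaction whose other anchor overlaps the gene's promoter window (TSS
+/- 1500 bp, the pipeline's promoter definition). Enhancers untouched by any
interaction fall back to the nearest TSS by center distance. The joined
activity/expression table and the responsive-enhancer linkage fraction build
on these links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_join

PROMOTER_WINDOW = 1500


def promoter_windows(tss: pd.DataFrame, half_width: int = PROMOTER_WINDOW) -> IntervalSet:
    """TSS +/- half_width windows carrying gene ids (columns chrom, pos, gene)."""
    return IntervalSet(
        pd.DataFrame(
            {
                "chrom": tss["chrom"],
                "start": np.maximum(0, tss["pos"].to_numpy(np.int64) - half_width),
                "end": tss["pos"].to_numpy(np.int64) + half_width,
                "name": tss["gene"],
            }
        )
    )


def link_by_interactions(
    enhancers: IntervalSet,
    interactions: pd.DataFrame,
    promoters: IntervalSet,
) -> tuple[pd.DataFrame, list[str]]:
    """Link enhancers to genes through interaction anchor pairs.

    ``interactions`` columns: chrom1,start1,end1,chrom2,start2,end2. An
    enhancer is linked to gene G iff it overlaps one anchor (>= 1 bp) and G's
    promoter window overlaps the other anchor, in either orientation.
    ``promoters`` must carry gene ids in its name column. Returns the link
    table (enhancer, gene, method, distance) and the list of unlinked
    enhancer ids.
    """
    enh_ids = enhancers.df["name"].astype(str).to_numpy()
    if len(set(enh_ids)) != len(enh_ids):
        raise ValueError("enhancer ids (name column) must be unique")
    links: set[tuple[str, str]] = set()
    for a, b in (("1", "2"), ("2", "1")):
        anchors_e = IntervalSet(
            interactions[[f"chrom{a}", f"start{a}", f"end{a}"]].rename(
                columns={f"chrom{a}": "chrom", f"start{a}": "start", f"end{a}": "end"}
            )
        )
        anchors_p = IntervalSet(
            interactions[[f"chrom{b}", f"start{b}", f"end{b}"]].rename(
                columns={f"chrom{b}": "chrom", f"start{b}": "start", f"end{b}": "end"}
            )
        )
        if not len(interactions):
            continue
        # IntervalSet sorts rows; recover the original interaction row id
        order_a = _sorted_order(interactions, a)
        order_b = _sorted_order(interactions, b)
        qe, se = overlap_join(enhancers, anchors_e)
        qp, sp = overlap_join(promoters, anchors_p)
        by_inter_e: dict[int, list[int]] = {}
        for q, s in zip(qe, order_a[se]):
            by_inter_e.setdefault(int(s), []).append(int(q))
        by_inter_p: dict[int, list[int]] = {}
        for q, s in zip(qp, order_b[sp]):
            by_inter_p.setdefault(int(s), []).append(int(q))
        gene_ids = promoters.df["name"].astype(str).to_numpy()
        for inter_row, e_rows in by_inter_e.items():
            p_rows = by_inter_p.get(inter_row)
            if not p_rows:
                continue
            for e in e_rows:
                for p in p_rows:
                    links.add((enh_ids[e], gene_ids[p]))
    rows = sorted(links)
    table = pd.DataFrame(rows, columns=["enhancer", "gene"])
    table["method"] = "interaction"
    table["distance"] = np.nan
    unlinked = sorted(set(enh_ids) - set(table["enhancer"]))
    return table, unlinked


def _sorted_order(interactions: pd.DataFrame, side: str) -> np.ndarray:
    sub = interactions[[f"chrom{side}", f"start{side}", f"end{side}"]].reset_index(drop=True)
    order = np.lexsort(
        (
            sub[f"end{side}"].to_numpy(np.int64),
            sub[f"start{side}"].to_numpy(np.int64),
            sub[f"chrom{side}"].astype(str).to_numpy(),
        )
    )
    return order


def nearest_gene(enhancers: IntervalSet, tss: pd.DataFrame) -> pd.DataFrame:
    """Link each enhancer to the gene with the nearest TSS by center distance.

    Ties break to the smaller TSS coordinate, then lexicographic gene id.
    ``tss`` columns: chrom, pos, gene.
    """
    if not len(tss):
        raise ValueError("TSS table must be non-empty")
    by_chrom = {
        c: sub.sort_values(["pos", "gene"], kind="mergesort").reset_index(drop=True)
        for c, sub in tss.groupby("chrom")
    }
    rows = []
    df = enhancers.df
    centers = enhancers.centers()
    for i, (chrom, name) in enumerate(zip(df["chrom"], df["name"])):
        sub = by_chrom.get(chrom)
        if sub is None:
            raise ValueError(f"no TSS on chromosome {chrom!r}; cannot assign a nearest gene")
        pos = sub["pos"].to_numpy(np.int64)
        d = np.abs(pos - centers[i])
        dmin = d.min()
        cands = np.flatnonzero(d == dmin)
        # smallest coordinate, then gene id (sub already sorted by pos, gene)
        pick = int(cands[0])
        rows.append((str(name), sub["gene"].iat[pick], "nearest", float(dmin)))
    return pd.DataFrame(rows, columns=["enhancer", "gene", "method", "distance"])


def link_enhancers(
    enhancers: IntervalSet,
    interactions: pd.DataFrame,
    tss: pd.DataFrame,
    extra_links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Interaction links plus nearest-TSS fallback; every enhancer gets >= 1 link.

    ``extra_links`` (enhancer, gene) rows — e.g. a co-regulation table from a
    prior study — are merged in with method ``coregulation`` before the
    fallback is computed.
    """
    table, unlinked = link_by_interactions(
        enhancers, interactions, promoter_windows(tss)
    )
    if extra_links is not None and len(extra_links):
        extra = extra_links[["enhancer", "gene"]].copy()
        extra["method"] = "coregulation"
        extra["distance"] = np.nan
        table = pd.concat([table, extra], ignore_index=True)
        unlinked = sorted(set(unlinked) - set(extra["enhancer"].astype(str)))
    if unlinked:
        mask = enhancers.df["name"].astype(str).isin(unlinked).to_numpy()
        fallback = nearest_gene(enhancers.subset(mask), tss)
        table = pd.concat([table, fallback], ignore_index=True)
    return table.sort_values(
        ["enhancer", "gene", "method"], kind="mergesort"
    ).reset_index(drop=True)


def activity_expression_table(
    activity: pd.DataFrame,
    links: pd.DataFrame,
    expression: pd.DataFrame,
    zscale_rows: bool = False,
) -> pd.DataFrame:
    """Join enhancer activity patterns with linked-gene expression.

    One row per enhancer-gene link, grouped and sorted by the enhancer's
    activity pattern code. ``activity`` must carry an ``enhancer`` id column
    and a ``pattern`` column; genes missing from ``expression`` are kept and
    flagged, never dropped. With ``zscale_rows`` an additional per-row
    standardized view of the expression columns (``exprz_*``) is appended
    (constant rows become zeros).
    """
    if "enhancer" not in activity.columns:
        raise ValueError("activity table needs an 'enhancer' id column")
    joined = links.merge(
        activity[["enhancer", "pattern"]], on="enhancer", how="inner"
    )
    expr = expression.copy()
    expr.index = expr.index.astype(str)
    missing = ~joined["gene"].astype(str).isin(expr.index)
    joined["expression_missing"] = missing
    for col in expr.columns:
        vals = np.full(len(joined), np.nan)
        ok = ~missing
        vals[ok.to_numpy()] = expr.loc[joined.loc[ok, "gene"].astype(str), col].to_numpy()
        joined[f"expr_{col}"] = vals
    if zscale_rows and len(joined) and len(expr.columns):
        block = joined[[f"expr_{c}" for c in expr.columns]].to_numpy(float)
        scaled = np.full_like(block, np.nan)
        any_data = np.isfinite(block).any(axis=1)
        if any_data.any():
            sub = block[any_data]
            mean = np.nanmean(sub, axis=1, keepdims=True)
            sd = np.nanstd(sub, axis=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
            scaled[any_data] = (sub - mean) / sd
        for k, c in enumerate(expr.columns):
            joined[f"exprz_{c}"] = scaled[:, k]
    return joined.sort_values(
        ["pattern", "enhancer", "gene"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class LinkageFraction:
    """Responsive-enhancer to responsive-gene linkage summary."""

    fraction: float | None
    n_responsive_linked: int  # responsive enhancers with >= 1 link
    n_cross_responsive: int  # of those, linked to >= 1 responsive gene
    contingency: dict


def responsive_linkage_fraction(
    responsive_enhancers: set[str],
    links: pd.DataFrame,
    responsive_genes: set[str],
) -> LinkageFraction:
    """Fraction of linked responsive enhancers tied to a responsive gene.

    Denominator: responsive enhancers with at least one link; numerator:
    those with at least one link into the responsive gene set. An empty
    denominator yields fraction None (explicitly undefined).
    """
    linked = links.groupby("enhancer")["gene"].agg(set)
    denom_ids = [e for e in responsive_enhancers if e in linked.index]
    num_ids = [e for e in denom_ids if linked[e] & responsive_genes]
    n_d, n_n = len(denom_ids), len(num_ids)
    fraction = (n_n / n_d) if n_d else None
    contingency = {
        "responsive_enhancers": len(responsive_enhancers),
        "responsive_with_link": n_d,
        "linked_to_responsive_gene": n_n,
        "linked_to_nonresponsive_only": n_d - n_n,
    }
    return LinkageFraction(
        fraction=fraction,
        n_responsive_linked=n_d,
        n_cross_responsive=n_n,
        contingency=contingency,
    )
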