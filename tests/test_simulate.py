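"""Ground-truth generator: determinism, geometry, marginals and planted effects."""

import numpy as np
import pandas as pd
import pytest

import enhancerscreen as es


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(duplicate_rate=1.5),
        dict(site_sharing=-0.1),
        dict(frag_len_range=(650, 350)),
        dict(motifs=(("A", 8), ("A", 6))),
        dict(planted_pairs=(es.PlantedPair("NOPE", "GATA", "HP"),)),
        dict(planted_pairs=(es.PlantedPair("RUNX", "GATA", "XX"),)),
        dict(motifs=(("WIDE", 500),)),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(es.SimConfigError):
        es.SimConfig(**kwargs)


def test_too_many_genes_for_spacing():
    with pytest.raises(es.SimConfigError):
        es.gen_annotation(es.SimConfig(n_genes=5000, n_chroms=1, chrom_len=1_000_000))


def test_too_many_sites_for_genome():
    cfg = es.SimConfig(n_sites_per_stage=5000, n_chroms=1, chrom_len=1_000_000, n_genes=10)
    ann = es.gen_annotation(cfg)
    with pytest.raises(es.SimConfigError):
        es.gen_sites(cfg, ann)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_annotation_zero_genes():
    ann = es.gen_annotation(es.SimConfig(n_genes=0))
    assert len(ann.tss) == 0


def test_annotation_bounds_spacing_determinism():
    cfg = es.SimConfig(seed=5, n_chroms=2, n_genes=100, chrom_len=2_000_000)
    ann = es.gen_annotation(cfg)
    assert len(ann.tss) == 100
    assert (ann.tss["pos"] >= 0).all() and (ann.tss["pos"] < cfg.chrom_len).all()
    for _, sub in ann.tss.groupby("chrom"):
        assert np.diff(np.sort(sub["pos"])).min() >= cfg.tss_min_spacing
    again = es.gen_annotation(cfg)
    pd.testing.assert_frame_equal(ann.tss, again.tss)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def test_site_sharing_extremes():
    base = dict(seed=3, n_sites_per_stage=60, n_genes=60, chrom_len=3_000_000,
                n_chroms=3, promoter_site_fraction=0.0)
    full = es.gen_sites(es.SimConfig(site_sharing=1.0, **base),
                        es.gen_annotation(es.SimConfig(site_sharing=1.0, **base)))
    sets = [full.stage_sites(s) for s in full.stage_names]
    assert all(s == sets[0] for s in sets[1:])

    cfgd = es.SimConfig(site_sharing=0.0, **base)
    disj = es.gen_sites(cfgd, es.gen_annotation(cfgd))
    tuples = [disj.stage_sites(s).coordinate_tuples() for s in disj.stage_names]
    for i in range(len(tuples)):
        for j in range(i + 1, len(tuples)):
            assert not (tuples[i] & tuples[j])


def test_sites_geometry_and_classes(small_screen):
    t = small_screen.sites.table
    lengths = t["end"] - t["start"]
    assert lengths.between(200, 1000).all()
    assert ((t["summit"] >= t["start"]) & (t["summit"] < t["end"])).all()
    assert set(t["cls"]) == {"promoter", "distal"}
    # per stage, site count matches config and sites are non-overlapping
    for s in small_screen.config.stage_names:
        sub = t[t[f"open_{s}"]].sort_values(["chrom", "start"])
        assert len(sub) == small_screen.config.n_sites_per_stage
        same = sub["chrom"].to_numpy()[1:] == sub["chrom"].to_numpy()[:-1]
        gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
        assert (gaps[same] >= 0).all()


def test_activity_marginals_binomial_bound():
    cfg = es.SimConfig(seed=13, n_sites_per_stage=2000, n_genes=800,
                       n_chroms=8, chrom_len=20_000_000, true_positive_fraction=0.3)
    cat = es.gen_sites(cfg, es.gen_annotation(cfg))
    p = cfg.true_positive_fraction
    for s in cfg.stage_names:
        sub = cat.table[cat.table[f"open_{s}"]]
        n = len(sub)
        frac = sub[f"active_{s}"].mean()
        bound = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < bound


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def test_fragment_lengths_bounded(small_screen):
    f = small_screen.fragments.fragments
    lengths = f["end"] - f["start"]
    lo, hi = small_screen.config.frag_len_range
    assert lengths.between(lo, hi).all()
    bg = small_screen.fragments.background
    assert (bg["end"] - bg["start"]).between(lo, hi).all()


def test_clean_fragments_unique_and_traceable(clean_screen):
    f = clean_screen.fragments.fragments
    assert not f["is_duplicate"].any() and not f["is_artifact"].any()
    # unique per sample
    for (_, _), sub in f.groupby(["stage", "replicate"]):
        assert not sub.duplicated(["chrom", "start", "end"]).any()
    # every fragment overlaps its source locus
    loci = clean_screen.sites.table.set_index("locus")
    src = loci.loc[f["source_locus"]]
    ov = np.minimum(f["end"].to_numpy(), src["end"].to_numpy()) - np.maximum(
        f["start"].to_numpy(), src["start"].to_numpy()
    )
    assert (ov >= 1).all() and (f["chrom"].to_numpy() == src["chrom"].to_numpy()).all()


def test_single_stage_activity_emits_no_positive_elsewhere(clean_screen):
    t = clean_screen.sites.table
    stages = clean_screen.config.stage_names
    act = t[[f"active_{s}" for s in stages]].to_numpy(bool)
    hp_only = act[:, -1] & (act.sum(axis=1) == 1)
    loci = set(t.loc[hp_only, "locus"])
    f = clean_screen.fragments.fragments
    offstage = f[
        f["source_locus"].isin(loci)
        & (f["stage"] != stages[-1])
        & f["yfp_bin"].isin(["low", "medium", "high"])
    ]
    assert len(offstage) == 0


def test_fragment_determinism(small_config):
    a = es.gen_fragments(small_config, es.gen_sites(small_config, es.gen_annotation(small_config)))
    b = es.gen_fragments(small_config, es.gen_sites(small_config, es.gen_annotation(small_config)))
    pd.testing.assert_frame_equal(a.fragments, b.fragments)
    pd.testing.assert_frame_equal(a.background, b.background)


# ---------------------------------------------------------------------------
# motif hits
# ---------------------------------------------------------------------------

def test_unit_multiplier_plants_nothing(small_config):
    cfg = es.SimConfig(
        **{**small_config.__dict__, "planted_pairs": (es.PlantedPair("RUNX", "GATA", "HP", 1.0),)}
    )
    cat = es.gen_sites(cfg, es.gen_annotation(cfg))
    _, truth = es.gen_motif_hits(cfg, cat)
    assert truth["n_planted"].sum() == 0


def test_motif_hits_deterministic(small_config):
    cat = es.gen_sites(small_config, es.gen_annotation(small_config))
    h1, _ = es.gen_motif_hits(small_config, cat)
    h2, _ = es.gen_motif_hits(small_config, cat)
    for m in h1:
        pd.testing.assert_frame_equal(h1[m].df, h2[m].df)


def test_planting_elevates_pair_rate_but_preserves_marginals():
    cfg = es.SimConfig(
        seed=21, n_sites_per_stage=1000, site_sharing=0.0, n_genes=400,
        n_chroms=10, chrom_len=45_000_000, promoter_site_fraction=0.0,
        true_positive_fraction=0.5,
        planted_pairs=(es.PlantedPair("RUNX", "GATA", "HP", 5.0),),
    )
    cat = es.gen_sites(cfg, es.gen_annotation(cfg))
    hits, truth = es.gen_motif_hits(cfg, cat)
    assert truth["n_planted"].iloc[0] > 50
    t = cat.table
    act = t[[f"active_{s}" for s in cfg.stage_names]].to_numpy(bool)
    target = act[:, -1] & (act.sum(axis=1) == 1) & (t["cls"] == "distal").to_numpy()
    other = ~target & (t["cls"] == "distal").to_numpy()

    def rate(mask):
        iv = es.IntervalSet(t.loc[mask, ["chrom", "start", "end"]])
        pc = es.count_pairs({"RUNX": hits["RUNX"], "GATA": hits["GATA"]}, iv, window=40)
        return pc.matrix.loc["RUNX", "GATA"] / mask.sum()

    # co-localization clearly elevated (design target 5x saturates at the
    # available partner-hit count, so require a conservative 2x floor)
    assert rate(target) / rate(other) > 2.0
    # marginal hit counts per site must be unchanged by planting
    for m in ("RUNX", "GATA"):
        qi_t, _ = es.overlap_join(hits[m], es.IntervalSet(t.loc[target, ["chrom", "start", "end"]]))
        qi_o, _ = es.overlap_join(hits[m], es.IntervalSet(t.loc[other, ["chrom", "start", "end"]]))
        rt, ro = len(qi_t) / target.sum(), len(qi_o) / other.sum()
        assert abs(rt - ro) < 0.15


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_counts_exchangeable_without_planting():
    cfg = es.SimConfig(seed=8, n_sites_per_stage=500, n_genes=200, n_chroms=4,
                       chrom_len=8_000_000, diff_planted_fraction=0.0)
    counts = es.gen_counts(cfg, catalog=es.gen_sites(cfg, es.gen_annotation(cfg)))
    assert (counts["true_fold"] == 1.0).all()
    ma = counts[["A_rep1", "A_rep2"]].to_numpy().mean()
    mb = counts[["B_rep1", "B_rep2"]].to_numpy().mean()
    assert abs(ma - mb) / cfg.nb_mean < 0.05


def test_planted_fold_recovered_in_means():
    cfg = es.SimConfig(seed=9, n_sites_per_stage=500, n_genes=200, n_chroms=4,
                       chrom_len=8_000_000, diff_planted_fraction=0.5,
                       diff_fold=4.0, nb_mean=100.0, nb_dispersion=0.02)
    counts = es.gen_counts(cfg, catalog=es.gen_sites(cfg, es.gen_annotation(cfg)))
    planted = counts["true_fold"] == 4.0
    ratio = (
        counts.loc[planted, ["B_rep1", "B_rep2"]].to_numpy().mean()
        / counts.loc[planted, ["A_rep1", "A_rep2"]].to_numpy().mean()
    )
    assert abs(ratio - 4.0) / 4.0 < 0.1


def test_zero_dispersion_limit_is_poisson():
    cfg = es.SimConfig(seed=10, n_sites_per_stage=1000, n_genes=400, n_chroms=8,
                       chrom_len=20_000_000, diff_planted_fraction=0.0,
                       nb_mean=100.0, nb_dispersion=0.0)
    counts = es.gen_counts(cfg, catalog=es.gen_sites(cfg, es.gen_annotation(cfg)))
    x = counts["A_rep1"].to_numpy(float)
    assert abs(x.var() / x.mean() - 1.0) < 0.15


# ---------------------------------------------------------------------------
# interactions & expression
# ---------------------------------------------------------------------------

def test_interaction_coverage_extremes(small_config):
    base = small_config.__dict__.copy()
    for cov, expect in ((1.0, True), (0.0, False)):
        cfg = es.SimConfig(**{**base, "interaction_coverage": cov})
        data = es.simulate_screen(cfg)
        n_distal = (data.sites.table["cls"] == "distal").sum()
        if expect:
            assert len(data.interactions.interactions) == n_distal
        else:
            assert len(data.interactions.interactions) == 0


def test_expression_tracks_enhancer_activity(small_screen):
    data = small_screen
    t = data.sites.table
    stages = data.config.stage_names
    act = t[[f"active_{s}" for s in stages]].to_numpy(bool)
    hp_only = act[:, -1] & (act.sum(axis=1) == 1) & (t["cls"] == "distal").to_numpy()
    es_only = act[:, 0] & (act.sum(axis=1) == 1) & (t["cls"] == "distal").to_numpy()
    expr = data.interactions.expression
    hp_genes = [g for g in t.loc[hp_only, "gene"] if g is not None]
    es_genes = [g for g in t.loc[es_only, "gene"] if g is not None]
    assert expr.loc[hp_genes, "HP"].mean() > expr.loc[es_genes, "HP"].mean() + 1.0


# ---------------------------------------------------------------------------
# whole-screen determinism
# ---------------------------------------------------------------------------

def test_write_screen_byte_identical(tmp_path, small_config):
    cfg = es.SimConfig(**{**small_config.__dict__, "n_sites_per_stage": 50, "n_genes": 50})
    d1, d2 = tmp_path / "a", tmp_path / "b"
    es.write_screen(es.simulate_screen(cfg), d1)
    es.write_screen(es.simulate_screen(cfg), d2)
    files1 = sorted(p.name for p in d1.iterdir())
    files2 = sorted(p.name for p in d2.iterdir())
    assert files1 == files2 and files1
    for name in files1:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
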