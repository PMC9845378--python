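import pandas as pd
import pytest
from hypothesis import settings

import enhancerscreen as es

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_intervals(rows):
    """rows: iterable of (chrom, start, end[, name])."""
    recs = []
    for r in rows:
        chrom, start, end = r[0], r[1], r[2]
        name = r[3] if len(r) > 3 else None
        recs.append((chrom, start, end, name))
    return es.IntervalSet(pd.DataFrame(recs, columns=["chrom", "start", "end", "name"]))


@pytest.fixture(scope="session")
def small_config():
    return es.SimConfig(
        seed=101, n_sites_per_stage=120, n_genes=120, chrom_len=3_000_000, n_chroms=3
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return es.simulate_screen(small_config)


@pytest.fixture(scope="session")
def clean_screen():
    """Noiseless screen: no duplicates, no background artifacts."""
    cfg = es.SimConfig(
        seed=77,
        n_sites_per_stage=100,
        n_genes=100,
        chrom_len=3_000_000,
        n_chroms=3,
        duplicate_rate=0.0,
        background_artifact_rate=0.0,
    )
    return es.simulate_screen(cfg)


def truth_vs_called(data, result):
    """Join called activity patterns against the generator's truth patterns."""
    act = result.activity
    truth = data.sites.table.copy()
    truth["pattern_true"] = data.sites.truth_pattern().to_numpy()
    merged = act.merge(
        truth[["chrom", "start", "end", "pattern_true"]],
        on=["chrom", "start", "end"],
        how="outer",
        indicator=True,
    )
    return merged


def run_calling(data):
    cfg = data.config
    return es.call_screen(
        data.fragments.fragments,
        data.fragments.background_intervals(),
        {s: data.sites.stage_sites(s) for s in cfg.stage_names},
        cfg.stage_names,
    )
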