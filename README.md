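# enhancerscreen

Analysis toolkit for genome-wide, chromatin-integrated enhancer reporter
screens across a differentiation time course.

In such a screen, open-chromatin (ATAC) fragments are cloned single-copy
upstream of a minimal-promoter YFP reporter at a defined genomic locus;
cells are differentiated through five stages (ES → HB → HE1 → HE2 → HP,
the endothelial-to-hematopoietic transition) and FACS-sorted into
negative/low/medium/high YFP bins. Each sequenced fragment plus its sort
bin is one functional measurement of enhancer activity in its native-like
chromatin context. This package provides the desk side of that experiment
for computational biologists:

* **Fragment processing** — BEDPE → fragment reconstruction, MAPQ > 40
  filtering, deduplication, perfect-overlap removal against a PCR
  background library, restriction to stage-matched open chromatin, and a
  conservation-checked filter ledger at every step.
* **Site calling** — an open-chromatin site is enhancer-positive iff ≥ 1
  overlapping fragment sorted into a positive YFP bin, in both replicates;
  cross-stage calls are binarized into activity-pattern codes
  (`00111` = active from HE1 onward).
* **Motif co-localization statistic** — for motif pair (a, b), count hit
  instances within 50 bp of each other in a specific enhancer set and
  compare with repeated equal-size draws from all distal open sites:
  `z = (x − μ) / σ` with μ, σ the resample mean and sd.
* **Relative motif enrichment** — `S_ij = (n_ij / m_j) / (Σ n_ij / Σ m_j)`,
  the per-set motif rate over the pooled rate, plus z-scaling and
  complete-linkage clustering for heatmap ordering.
* **Differential accessibility** — peak union, 400 bp summit windows,
  CPM → log2(CPM+1), replicate averaging, two-fold gained/lost calls.
* **Enhancer–gene linking** — interaction anchor pairs with nearest-TSS
  fallback, activity-vs-expression joins, responsive-linkage fractions.
* **Synthetic screens** — a seeded generator that emits the complete input
  universe (sites, labelled fragments, background, motif hits, counts,
  interactions, expression) with a ground-truth table, so every stage of
  the pipeline is testable without any download.

## Worked example

Simulate a small five-stage screen with a RUNX–GATA pair planted at 5× in
HP-specific enhancers, call sites, and test the pair:

```python
import numpy as np
import enhancerscreen as es

cfg = es.SimConfig(
    seed=7, n_sites_per_stage=300, n_genes=200, n_chroms=4, chrom_len=8_000_000,
    duplicate_rate=0.2, background_artifact_rate=0.02,
    planted_pairs=(es.PlantedPair("RUNX", "GATA", "HP", 5.0),),
)
data = es.simulate_screen(cfg)

result = es.call_screen(
    data.fragments.fragments,
    data.fragments.background_intervals(),
    {s: data.sites.stage_sites(s) for s in cfg.stage_names},
    cfg.stage_names,
)
print("activity matrix:", len(result.activity), "elements")
print(result.activity["pattern"].value_counts().head(4).to_string())
print("HP rep1 ledger:", result.ledger.ledger("HP", 1).to_dict())

specific = es.stage_specific_sets(result.activity, cfg.stage_names)["HP"]
universe = data.sites.union_sites(cls="distal")
x = es.count_pairs(data.motif_hits, specific)
null = es.resample_null(data.motif_hits, universe,
                        n_draw=len(specific), reps=200, seed=7)
z = es.zscore(x, null)
print(f"z(RUNX, GATA) = {z.matrix.loc['RUNX','GATA']:.1f}")
```

Output:

```
activity matrix: 1020 elements
pattern
00000    670
00010     62
00100     61
01000     60
HP rep1 ledger: {'input': 1503, 'retained': 1218, 'removed': {'duplicates': 257,
 'background_perfect_overlap': 28, 'outside_open_chromatin': 0}}
z(RUNX, GATA) = 4.5
```

Reading it: the 1500 sites across stages merge to 1020 distinct elements;
670 never score (the truth activity rate is 0.3 per stage). The ledger
accounts for every HP replicate-1 fragment — 257 duplicates and 28
PCR-background matches removed, everything else retained, input = retained
+ removed exactly. The planted RUNX–GATA co-localization stands out at
z = 4.5 against the resampled null (the median |z| of unplanted pairs in
this run is 0.68).

A command-line layer wraps the same operations:

```bash
enhancerscreen simulate --seed 7 --out screen/
enhancerscreen call --stage HP \
    --frags screen/frags_HP_rep1.bed --frags screen/frags_HP_rep2.bed \
    --background screen/background.bed --sites screen/sites_HP.bed \
    --out calls_HP.tsv
enhancerscreen coloc --hits screen/ --specific calls_positive.bed \
    --universe screen/sites_HP.bed --reps 1000 --seed 7 --out z.tsv
```

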