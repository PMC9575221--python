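# spatialcci

Benchmarking toolkit for cell-cell interaction (CCI) predictions, using
spatial transcriptomics (ST) as the yardstick.

## The problem

Many tools infer ligand-receptor (L-R) interactions between cell types from
annotated scRNA-seq data, but there is no experimental ground truth to score
them against. Tissue geometry offers an independent check: a contact-dependent
(juxtacrine-like) interaction is only plausible between cell types that sit
next to each other, while a secreted (paracrine-like) signal can act between
distant cell types. `spatialcci` turns that idea into a quantitative
benchmark for anyone comparing or developing CCI inference methods.

## The method

**Short- vs long-range interactions.** On an ST slide, a gene's expression
defines a spatial probability distribution (spot coordinates weighted by
expression). For an interaction with ligand distribution L and receptor
distribution R, the observed separation is the symmetrized
entropic-regularized Wasserstein distance

    d_real = W_LR = ( W(L, R) + W(R, L) ) / 2,

computed with a log-domain Sinkhorn solver (regularization `reg = 0.001`)
under the Euclidean ground metric. A permutation null re-assigns both
expression profiles to randomly permuted spot positions (1000 replicates by
default), giving `d_ratio = d_real / mean(d_simulation)` and one-sided
permutation P-values. Interactions in the smallest top 10% by both `d_ratio`
and left-sided P, with P < 0.01, are *short-range*; the analogous right tail
gives *long-range*; the rest are *medium*. Multi-subunit complexes are split
into all single-subunit combinations (originals retained), and only
interactions whose every subunit is detected in >= 10% of spots are scored.

**Near vs far cell-type pairs.** Spots are labeled by their largest
deconvolution proportion; the distance between two cell types is the
symmetrized mean of minimum Euclidean distances between their spot sets, and
1-D k-means (k = 3) labels pairs near / medium / far.

**Distance enrichment score (DES).** A GSEA-style running sum walks the
expected short-range list for each near pair (long-range list for each far
pair): a predicted interaction adds its normalized confidence `(1 - p)`, a
missed one subtracts `1 / (ns - nm)`; the DES is the maximum of the running
sum, in [0, 1]. A tool's score is the unweighted mean over near and far
pairs, and tools are ranked by mean DES.

**Consensus metrics.** Interactions predicted for the same directed
cell-type pair by >= 3 tools form a relative reference set, against which
each tool's precision, recall and F1 = 2PR/(P+R) are computed per pair and
macro-averaged. An `LR product` baseline (top 10 interactions per direction
by the product of mean ligand and receptor expression) is included.

**Simulator.** Paired scRNA-seq/ST datasets with *known* interactions:
cells are mapped 2-5 per spot onto a real or synthetic slide, 30 L-R pairs
per near/far cell-type pair are overexpressed by resampling counts from
high-expression donor genes, and a consistency filter keeps only plants
whose realized spatial range matches their pair's distance class. A
layered-tissue fixture (negative-binomial counts, mixed and segregated
cell-type domains) means no external data is ever needed.

## Worked example

Simulate a benchmark dataset, classify interaction ranges, and score the
built-in baseline predictor:

```python
from spatialcci import (
    SimulationConfig, make_fixture, simulate_dataset, normalize_counts,
    filter_by_coverage, compute_tendency, build_expected_lists,
    lr_product_baseline, tool_des, accuracy_vs_reference,
)
from spatialcci.tendency import tendency_frame

cfg = SimulationConfig(seed=1, n_lr_per_pair=10, n_perm=100)
template = make_fixture(seed=1, n_lr=60, n_complex=4)
ds, db = simulate_dataset(cfg, template=template)
kept = ds.truth[ds.truth.kept]
print(f"plants kept: {len(kept)} of {len(ds.truth)}")

st = normalize_counts(ds.st)
covered = filter_by_coverage(db, st)
tendency = compute_tendency(st, covered, n_perm=100, seed=2)
print(tendency_frame(tendency)["range_class"].value_counts().to_dict())

L_s, L_l = build_expected_lists(tendency)
baseline = lr_product_baseline(ds.sc_counts, ds.cell_annotation, db, top_n=10)
print(f"baseline mean DES: {tool_des(baseline, ds.pair_classes, L_s, L_l).mean_des:.3f}")

reference = kept[["source_celltype", "target_celltype", "ligand", "receptor"]]
m = accuracy_vs_reference(baseline, reference)
print(f"precision={m.precision:.3f} recall={m.recall:.3f} F1={m.f1:.3f}")
```

Output:

```
plants kept: 9 of 30
{'medium': 44, 'long': 5, 'short': 4}
baseline mean DES: 1.000
precision=0.180 recall=1.000 F1=0.294
```

Reading the numbers: of 30 planted interactions, 9 survived the consistency
filter (short-range plants in the near pair, long-range in far pairs); the
re-run tendency pass on the final slide classifies 4 + 5 of the 53 covered
interactions as short/long — dominated by the kept plants. The expression
product of the overexpressed ligand and receptor genes is enormous, so the
LR-product baseline recovers every planted interaction (recall 1.0, mean
DES 1.0) but pads each direction to its top-10 quota with noise pairs,
costing precision (0.18).

The same workflow is available from the shell:

```bash
spatialcci simulate --n-per-pair 30 --seed 1 --out-dir sim/
spatialcci tendency --st-counts sim/st_counts.tsv --st-coords sim/st_coords.tsv \
    --lr-db sim/lr_database.csv --n-perm 1000 --seed 1 --out tendency.tsv
spatialcci benchmark --config run.yaml --out results/
```

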