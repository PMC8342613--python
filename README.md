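# acaritax

Calibration of DNA-barcode similarity thresholds for assigning barcode
clusters (BINs) to higher taxa — order and family — with mites (Acari) as
the motivating fauna.

Most mite specimens collected in large-scale surveys belong to BINs that
no taxonomist has named. Their COI barcode can still place them in an
order or family by nearest-neighbour search against a reference library,
*if* one knows how similar a top hit must be before the assignment is
trustworthy. `acaritax` implements the full calibration pipeline for that
question:

1. **Library construction** — read aligned barcode FASTA + taxonomy TSV,
   keep barcode-compliant records (≥ 500 bp, < 1% ambiguous), select one
   representative per BIN (longest, fewest ambiguities).
2. **Distances** — uncorrected p-distances with pairwise deletion,
   `similarity = 100·(1 − p)`.
3. **Dilution** — single-linkage clustering at 5% then 10% divergence,
   with silhouette-optimal representatives, to emulate reference
   libraries of decreasing coverage (BIN → DIV5 → DIV10).
4. **Identification** — modified leave-one-out: each sequence queried
   against the library, excluding itself and everything within the
   coverage level's divergence radius (2%/5%/10%), scoring correctness at
   order and family rank.
5. **Calibration** — ROC curves and AUC, Youden's J threshold, and
   precision-based thresholds P100/P99/P95 (0%/1%/5% error tolerated
   among accepted assignments), globally and per order.
6. **Divergence analysis** — per-taxon max-intra / min-inter distances,
   barcode-gap flags, and the asymptotic regression of family divergence
   on BIN richness.
7. **Synthetic libraries** — a seeded generator with a known
   order→family→BIN hierarchy and controlled divergence structure, so the
   whole pipeline is testable end-to-end without any downloads.

At threshold *t* a query is assigned iff its top-hit similarity exceeds
*t*; TP/FP/FN/TN counts then give TPR = TP/(TP+FN), FPR = FP/(FP+TN),
precision = TP/(TP+FP), accuracy = (TP+TN)/n. P100 is the smallest
observed score above which precision is 100% everywhere (likewise P99 and
P95 at 99%/95%), and Youden's threshold maximizes TPR − FPR. See
`docs/methods.md` for conventions and edge cases.

## Worked example

```python
from acaritax import (
    LOOConfig, SyntheticConfig, calibrate, distance_matrix,
    generate_library, loo_identify, results_to_frame,
)

lib, truth = generate_library(SyntheticConfig(seed=1))
print(len(lib))                       # 1256 aligned records, 658 columns

from acaritax import filter_compliant, select_bin_representatives
bins = select_bin_representatives(filter_compliant(lib))
print(len(bins))                      # 314 BIN representatives

results = results_to_frame(loo_identify(bins, LOOConfig(exclusion_div=0.02)))
print(round(100 * results["correct_family"].mean(), 1))   # 99.0

report = calibrate(results, rank="family", scope="all")
print(round(report.auc, 3))                               # 0.979
print(round(report.p100.threshold, 1))                    # 82.5
print(round(100 * report.p100.assigned_fraction, 1))      # 95.9
```

Reading: of 314 BIN representatives queried leave-one-out (own BIN
excluded), 99.0% found a same-family top hit. Family-level correct and
incorrect hits are well separated by similarity (AUC 0.979), and
accepting only hits above 82.5% similarity (the P100 threshold) yields
zero false positives while still assigning 95.9% of queries.

The same pipeline runs from the shell:

```bash
acaritax simulate --seed 1 --out lib/
acaritax identify --library lib/library.fasta --taxonomy lib/library.taxonomy.tsv \
         --exclusion 0.02 --out results.tsv
acaritax calibrate --results results.tsv --out calibration
acaritax run-study --seed 1 --out study/      # the full six-dataset grid
```

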