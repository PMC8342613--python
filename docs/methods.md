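# Methods

`acaritax` evaluates how reliably a DNA-barcode reference library can
assign unknown barcode clusters (BINs) to higher taxa — order and family —
by nearest-neighbour similarity, and calibrates the similarity thresholds
at which such assignments should be accepted. This note records the model,
the numerical conventions, and the design choices made where several
defensible options existed.

## Distance model

All comparisons use the uncorrected p-distance with **pairwise deletion**:
for each pair of aligned sequences, alignment columns where either member
carries a gap (`-`) or any non-A/C/G/T character (N and all IUPAC
ambiguity codes) are removed, and the distance is the mismatch fraction
over the remaining "compared" sites. Ambiguity codes are treated as
missing rather than partially matched; this keeps the distance exact and
matches the conservative reading of pairwise deletion. A pair with zero
compared sites has an *undefined* distance, carried as NaN and never
silently treated as zero. Because the compared-site set differs per pair,
the triangle inequality is not guaranteed and is not asserted anywhere.

Percent similarity is `100·(1 − p)`. This is the closest reproducible
analogue of the similarity reported by online barcode identification
engines, whose internal formula is not public; all thresholds in this
package are on this scale.

The all-pairs matrix is computed with per-base indicator matrix products
(five (n×width)·(width×n) multiplications), which is exact in double
precision for any realistic library size and avoids a quadratic Python
loop. A character-level oracle in the test suite checks every entry.

## Library dilution

Sequence coverage is thinned by single-linkage clustering: clusters are
the connected components of the graph with an edge wherever `d < t`
(strict), so between-cluster divergence is always ≥ t ("at least t
divergence"). A pair at exactly t falls in different clusters. Undefined
distances contribute no edge — they are treated as "far", with a warning —
so no-overlap pairs cannot chain clusters together.

Each cluster is represented by the member with the highest silhouette
score, computed from the same matrix with the classic definition
(`a` = mean distance to own cluster excluding self, `b` = smallest mean
distance to another cluster, `s = (b−a)/max(a,b)`; singletons score 0; a
single-cluster partition scores all zeros with a warning). Silhouette
ties break by longest effective (non-gap) length, then smallest id; the
tie rules are package conventions, chosen to be deterministic.

The series is **sequential**: the 10% level clusters the 5% level's
representative library on that library's own distance matrix, not the
original matrix. An independent mode is available for sensitivity
analysis. On a single matrix, cuts are nested (10% clusters are unions of
5% clusters), which the suite asserts.

## Leave-one-out identification

Every sequence is queried against the library with eligibility rules that
emulate querying an external reference database without self-hits: a
candidate is eligible iff its distance to the query is **strictly
greater** than the exclusion radius (2%, 5%, 10% bound to the BIN, DIV5
and DIV10 coverage levels respectively), it carries a family label, and
its compared-site overlap is at least half the query's non-gap length
(the overlap denominator is a package decision; only the 50% figure is
prescribed). The top hit is the eligible candidate with maximal
similarity; exact ties go to the smallest id. Queries with no eligible
candidate are "unassignable": reported, but excluded from calibration
denominators.

With the exclusion radius at zero, the top hit reduces to the global
nearest neighbour (identical-sequence duplicates excepted, since the rule
stays strict); raising the radius can only lower a query's top-hit
similarity. Both properties are tested.

## Threshold calibration

Assignment at threshold t accepts a result iff `similarity > t`
(strict). Strictness matters at boundaries: an error observed *at* a
threshold value is excluded by that threshold. Candidate thresholds are
the observed similarity values (plus an assign-everything sentinel for
the ROC endpoint), so reported thresholds are always observed scores.

- **ROC/AUC**: TPR and FPR at every candidate; AUC by trapezoid, which on
  this candidate grid equals the concordance-pair (Mann–Whitney) statistic
  with ties counted ½ — asserted against an independent oracle and
  scikit-learn. With a single outcome class the AUC is undefined and
  flagged, never defaulted.
- **Youden**: the candidate maximizing J = TPR − FPR, ties resolved toward
  the largest (most conservative) threshold.
- **P100/P99/P95**: the smallest candidate t such that precision
  ≥ 100%/99%/95% holds at t *and at every higher candidate* (the
  "guarantee" form, which keeps the thresholds well defined when precision
  is non-monotone in t). Candidates at which nothing is assigned satisfy
  any criterion vacuously. If the criterion holds at every candidate the
  threshold falls to the minimum observed similarity, i.e. everything
  scoring above it is accepted. One corner case deserves note: when the
  single error outranks every correct hit, no threshold that assigns
  anything can meet the criterion, and the guarantee rule retreats to the
  maximum observed score (nothing assigned). This is the only behaviour
  consistent with the strict-`>` assignment rule and the zero-false-positive
  guarantee that P100 advertises.

Per-order calibration partitions queries by their *true* order and runs
the identical machinery per subset. Orders in which every hit is correct
get an undefined AUC (flagged) and precision thresholds equal to their
minimum observed similarity — the expected behaviour for a flawlessly
identified group.

## Divergence analysis

For each taxon at a rank, the maximum within-taxon and minimum
between-taxon p-distance are read off the matrix; monotypic taxa lack the
intra value and are excluded from the barcode-gap flag
(`gap_present = max_intra < min_inter`, strict). The relationship between
a family's maximum internal divergence and its BIN count is fitted with
three least-squares models: linear, logarithmic (`y ~ a + b·ln x`), and
asymptotic `y = A + (y0 − A)·exp(−k·x)` (standard asymptotic-regression
parameterisation; fitted by non-linear least squares with a multi-start
over k). Models are ranked by AIC under a Gaussian-error likelihood,
`n·ln(RSS/n) + 2p`, computed identically for all three so the comparison
is fair; RSE is `sqrt(RSS/(n−p))`. The half-asymptote point is
`x = ln((A−y0)/(A/2))/k`. Outliers use the boxplot rule with
linear-interpolation quartiles (numpy default, R type 7) — quartile
conventions differ between packages, so the choice is documented.

## Synthetic libraries

The generator evolves sequences down a star-within-star hierarchy (root →
order ancestors → family ancestors → BIN ancestors → members) with
independent per-site replacement by a uniformly drawn base. Repeated hits
at a site make realized p-distances saturate below 0.75, mirroring the
saturation that compresses deep COI divergences in real data. For a
pairwise divergence target t between two sister lineages, each branch
replaces sites with probability `q = 1 − sqrt(1 − t/0.75)`; a single
connecting branch uses `q = t/0.75`.

Default conditions (4 orders × 10 families, 1–14 BINs per family, 4
sequences per BIN ≈ 1200 records of 658 columns) follow the structure of
a continental mite barcode library: intra-BIN pairwise distances ~1%
(below the 2% ceiling), between-BIN within-family targets 4–25%,
interfamily ancestor divergence 10%, interorder 18%. A fraction
(`bin_sibling_prob = 0.45`) of BINs bud off an existing BIN at 2–5.5%
divergence, giving the allied-BIN (congeneric) structure that the 5%
dilution consumes; with these defaults roughly a quarter of BINs merge at
the 5% cut and a further quarter at 10%, matching the level-to-level
reductions of the real library (7021 → 5182 → 3948). Optional decoy
records (default 12 in the study configuration) emulate far outgroup
lineages: queries from decoy taxa are misassigned at low similarity,
populating the false-positive side of the order-level calibration the way
cross-phylum reference hits do in practice.

Two caveats on realism. Targets are expectations: each realized pairwise
distance carries binomial noise of order `sqrt(p(1−p)/width)` (≈1.2
points at p = 0.10 over 658 columns), so acceptance-style checks use
tolerance bands, never exact equality. And realized *minimum* interorder
distances run several points above the configured 18% ancestor
divergence, because within-order branches stack on top of it; the
configured value is a floor. Codon structure, indels, rate heterogeneity
and primer bias are not modelled, so passing tests demonstrate the
correctness of the pipeline's machinery and its behaviour under
controlled divergence structure — not performance on any real library.

## Study orchestration and problem sizes

`run_study` builds the six-dataset grid ({BIN, DIV5, DIV10} ×
{full-length, trimmed-to-463 bp}), binds the exclusion radius to the
coverage level, calibrates both ranks globally and per order, and emits
every table plus a manifest with SHA-256 digests of all outputs; a rerun
with the same seed and config reproduces every digest. The default grid
(~300 BIN representatives from ~1200 generated sequences) runs in a few
seconds; the test suite's randomized oracle checks use 20–50-sequence
instances, and seed-replicated calibration properties use 10–20 seeds —
sizes chosen to make the whole suite quick to run routinely while keeping
every check statistically meaningful.

## Known limitations

- The similarity an online identification engine reports is not publicly
  specified; `100·(1 − p)` on pairwise-deleted sites is a reproducible
  stand-in, so thresholds calibrated here transfer to other engines only
  to the extent their scores agree with it.
- The trimmed datasets use a fixed amplicon window (columns 196–658 of
  the 658-column barcode region by default); only primer names, not
  coordinates, are standard in the field, so the window is configurable.
- Single-linkage dilution and the LOO exclusion radius both key on raw
  p-distance; no model-corrected distances are offered (deliberately —
  the calibration target uses p-distances).
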