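# Methods

## Model and assumptions

`draftrank` assesses draft-genome assemblies without a reference. The
underlying assumption is ordinal: for a fixed dataset, "better assembly"
is well captured by an assembly's *rank position* on each of a panel of
metrics, not by the metric magnitudes themselves. Aggregation therefore
happens on ranks, through two nested weighted means — the group rank
R_j = (Σ w_i r_i)/n over a group's n metric ranks, and the overall
quality rank R = (Σ W_j R_j)/m over the m quality groups. Because the
mean divides by n (not by Σ w_i), weights are *not* normalized: a group
whose weights do not sum to n maps equal input ranks to a different
value, which is why the engine warns in that case. The conservation-group
defaults (0.76, 0.92, 1.04, 1.28) sum to exactly 4, preserving the fixed
point.

Quality group membership: g1 (largest contig, N50, L50) captures
contiguity; g2 (chaff percentage, N count) captures fragmentation debris
and gaps; g3 (csg1%–csg4%) captures completeness of the four core-gene
conservation classes, measured externally and supplied as a table.
Computational metrics (running time, peak memory) are ranked identically
but excluded from R: they describe cost, not output quality. A deposited
draft genome can join quality ranking as an ordinary item while being
excluded from computational ranking (it was never run here).

## Metric definitions and conventions

* **Chaff**: a record strictly shorter than 200 bp (configurable). The
  chaff percentage divides by the *pre-filter* total length; every other
  metric uses the post-chaff record set, including the N50 denominator.
* **N50 / L50**: N50 is the length at which the descending-sorted
  cumulative length first reaches half the (post-chaff) total; L50 is the
  size of that minimal covering prefix. When several records tie at the
  N50 length, an alternative convention counts every record ≥ N50;
  `l50_at_least_n50` provides it. The minimal-prefix default matches the
  QUAST behavior that most published assembly statistics derive from.
* **Uncalled bases**: only `N`/`n` count. Other IUPAC ambiguity codes are
  partial calls, not gaps.
* **Ranking ties**: competition ("1, 2, 2, 4") by default, dense
  ("1, 2, 2, 3") by flag. The default was chosen to match how published
  benchmark rank tables in this area are actually printed; the two
  conventions coincide whenever values are distinct.
* **Missing values**: an item missing a metric is dropped from that
  metric's ranking and the remaining items are ranked compactly (no slot
  reserved). An item missing any metric inside a quality group receives
  no R_j and no R and is reported as incomplete.
* **Scaffolds**: processed identically to contigs; the level is a label.
  No splitting at N runs is performed, so scaffold N50 refers to scaffold
  lengths.

## Classification

Per axis (time, memory, quality) each assembler gets one score — by
default its mean rank across datasets; for the quality axis, the
contigs-level R. 1-D K-means with k = 3 (time) or 4 (memory, quality)
partitions the scores, and clusters receive the axis vocabulary labels in
center order, best first.

K-means is run with a deterministic quantile initialization (centers at
the (2i−1)/2k quantiles) competing on inertia against 100 random-point
restarts under a fixed seed. One hundred restarts is deliberate: Lloyd's
algorithm stalls in local optima surprisingly often on 1-D data, and with
this budget the solution matched the exact dynamic-programming optimum on
every tested instance with n ≤ 12 (the DP oracle lives in the test
suite). The cost is negligible at these problem sizes.

The class labels themselves are a qualitative summary. Different choices
of clustering input (raw values vs mean ranks) or a single-run K-means
can produce different, locally optimal partitions of the same scores;
the classifier here always reports the best partition found, along with
cluster centers so users can judge separation.

## Synthetic data generator

The generator emulates what a cohort of assemblers produces on a
fungal-scale genome, at toy size: per-assembly FASTA with log-normal
contig lengths (heavy right tail, as in real assemblies; default 150
contigs, log-mean 8.5 ≈ 4.9 kb median, log-sd 0.6), a binomially
realized chaff fraction with chaff lengths uniform on [50, 200) bp, and
N's substituted at a per-base rate. Cohorts plant a total quality
ordering by degrading successive assemblies on every metric in
expectation: the length scale shrinks by 0.8 on the log scale (≈ 2.2×)
per step, while chaff fraction and N rate grow — separations well above
the sampling noise of the per-assembly statistics, which is what makes
planted-ordering recovery a sharp test. Conservation percentages are
generated as a monotone function of the planted order (6-point steps)
plus ±1-point noise, so g3 agrees with g1/g2 by construction;
computational values are drawn independently of quality.

Not emulated: read-level errors, repeat structure, real assembler
failure modes, or correlations between metrics beyond the planted trend.
Passing tests on these cohorts therefore demonstrates that the pipeline
recovers an ordering that is genuinely present in the data — not that
any particular real assembler ranks in any particular way.

## Numerical and interface choices

* TSV (UTF-8, header, empty cell = missing) is the canonical tabular
  format; ranks print with 2 decimals, raw percentages with 4, making
  repeated runs byte-identical.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical seeds give
  byte-identical FASTA fixtures.
* Degenerate inputs fail fast with named offenders: empty FASTA records,
  assemblies that are entirely chaff, all-missing metric columns,
  duplicate item labels, k exceeding the number of distinct scores.
* Problem sizes in the test and acceptance runs — 1,000 random length
  multisets for the contiguity oracle, 200 instances (n ≤ 12) for the
  clustering oracle, 20 four-assembly cohorts of 150 contigs for
  ordering recovery — were chosen so each check exercises its full
  combinatorial range while the whole suite completes in well under a
  minute.

## Known limitations

* Without a reference genome, none of the metrics detect misassemblies;
  an aggressively joined assembly can rank well on g1 while being wrong.
  The conservation group partially compensates, which is why it carries
  its own group.
* The rank aggregation is not a statistical test: nearby R values do not
  imply a significant quality difference.
* Completeness percentages are taken as given; the package does not run
  the core-gene mapping itself.
* Cross-dataset aggregation is a plain mean of ranks; no allowance is
  made for datasets of very different difficulty.
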