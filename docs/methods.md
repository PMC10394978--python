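# Methods

## Data model

A corpus is one bird's ordered songs; a song is an ordered, non-overlapping
sequence of syllable tokens, each a type label on a time interval (seconds,
stored at millisecond precision). Labels are case-sensitive opaque strings:
syllable classification happens upstream (visual inspection of
spectrograms) and two labels are either identical or maximally different —
no acoustic similarity is modelled.

Song segmentation, when the package does it (timed token streams without an
explicit song index), uses the standard operational song definition: a
vocalization at least 1 s long bounded by at least 0.4 s of silence. Both
thresholds are configurable in `split_songs`; when songs arrive
pre-segmented (a `song_index` column, or one TextGrid per song) the filters
are off, since segmentation was done upstream. Analyses use the first 30
songs per bird in recording order; birds with fewer are flagged, not
dropped.

## Diversity metrics

Per-song quantities (syllable count, type count, SVI = types/syllables,
types per second, syllables per second) are averaged over songs rather than
pooled, so each bird's value is a mean of 30 per-song values. Rates divide
by song duration = last offset − first onset and are reported as missing
for untimed data rather than guessed.

Two decisions the underlying quantities leave open:

* **Song type.** "Number of different song types" is under-defined for
  phrase-structured song, where raw syllable sequences are almost always
  unique. The default classifies a song by its phrase sequence — the
  syllable-type sequence after collapsing consecutive repeats — with an
  exact-sequence rule available (`song_type_rule="exact"`).
* **Levenshtein pairing and scale.** The distance is computed at
  whole-syllable granularity between *successive* songs (pairs 1–2, 2–3, …,
  29–30) and averaged, reading "variation between successive songs"
  literally; an all-pairs mode exists. The default reports the raw edit
  count; normalization by the longer sequence's length is optional.

The edit-distance implementation is a one-row dynamic program with the
in-row dependency resolved by a prefix-minimum, vectorized in numpy; it is
checked in the tests against an exhaustive recursive oracle (all pairs up
to length 4 over a 3-letter alphabet, plus seeded longer samples) and
against an independent alignment library on long random sequences.

## Transition networks

Each bird's 30 songs are concatenated into one syllable string; breaks
between songs are deliberately bridged so sparse corpora do not fragment
into disconnected fragments. Every adjacent pair is one first-order
transition. Metrics are computed on the undirected, unweighted simple
graph: immediate repeats are recorded as self-loop counts (they are real
transitions and are retained in totals and exports) but cannot shorten a
shortest path and are excluded from density's numerator and denominator,
matching the conventional simple-graph density. Directed,
frequency-weighted graphs are available only for export/visualization
(GraphML), never for metrics.

Average path length averages shortest-path lengths over mutually reachable
unordered node pairs; pairs in different components are excluded (the
conventional treatment of "ignoring dead ends" in disconnected graphs).
With no reachable pair the metric is undefined (`nan`), as is density below
two nodes. Birds whose network has ≤ 3 nodes (threshold configurable) get
missing network metrics and are logged: with so few pairs both metrics are
dominated by the node count itself.

## Statistics

* **Two-way ANOVA** (treatment × sex) uses Type III marginal sums of
  squares with sum-to-zero factor coding, appropriate for the unbalanced
  cells this design produces (15 vs 13 birds, further reduced for network
  rows); partial η² = SS_term / (SS_term + SS_residual). Birds missing
  network metrics are dropped listwise only for the network rows, so those
  rows carry a smaller residual df than the diversity rows. A constant
  response yields `nan` F (undefined) rather than floating-point noise.
  The implementation is cross-checked in the tests against frozen values
  from an independent sum-contrast Type III computation and, on balanced
  data, against the hand-computed classical SS decomposition (where Type
  III and sequential SS coincide).
* **PCA** standardizes each variable to mean 0 / SD 1 (sample SD) and
  eigendecomposes the correlation matrix — the "unrotated PCA of
  standardized measures" convention. Components are ordered by eigenvalue;
  each component's sign is fixed so its largest-magnitude loading is
  positive; scores are the standardized data projected on the eigenvectors,
  so their variances equal the eigenvalues. The first three components are
  selected by fixed count, not an eigenvalue threshold. By default the PCA
  uses the eight diversity metrics only: including the network metrics
  would silently drop every bird excluded by the ≤3-node rule from the PCA
  and the downstream regressions, and the reference per-sex regression
  sample sizes are not explained by that exclusion anyway; a flag
  (`include_network_in_pca`) switches to all ten.
* **Regressions** are per-sex OLS of each retained PC score on HVC, RA and
  Area X volumes with body mass as covariate, with intercept; run only when
  all four covariates are present and each sex keeps at least predictors+2
  rows. Rank-deficient designs fail loudly, naming the collinear columns.
* No multiple-testing correction anywhere: a single α = 0.05 convention.

## Synthetic corpora

The generator works at the phrase level because canary song is
phrase-structured: a song is `n_phrases` phrases, each one syllable type
repeated `n_repeats` times; counts are fixed or 1 + Poisson(mean − 1).
Phrase types follow a per-bird Markov chain whose transition matrix is
`s · C + (1 − s) · U`: `C` a fixed random cyclic permutation of the bird's
repertoire, `U` uniform over the other types, `s` the stereotypy in [0, 1].
Songs open with the bird's preferred phrase type with probability `s`
(uniform otherwise), so at `s = 1` with fixed counts every song is
identical — one song type — while at `s = 0` the chain is an unbiased walk.
Repertoire size and stereotypy are therefore independent dials, which is
exactly the two-axis sex difference the design probes.

Default parameter sets encode the study conditions: 15 males and 13
females across two treatments (treatment is a null factor: both groups
share their sex's parameters), 30 songs per bird; males repertoire 16,
~17 phrases/song of ~4 repeats, stereotypy 0.95; females repertoire 6,
~7 phrases/song of ~68/7 repeats, stereotypy 0.15. The repeat means are
chosen so the expected syllables per song is 68 in both sexes (≈ the ~69
syllables/song implied by 57 872 syllables in 840 songs) — song length and
syllable rate are matched between sexes by construction, making
`syllables_per_song` and `syllables_per_second` true null contrasts.
Male stereotypy 0.95 yields sparse, chain-like male networks (density
≈ 0.35–0.45, path length ≈ 1.6–1.7) against saturated female networks.
Per-bird multiplicative jitters on repertoire size (SD 12 %) and phrase
count (SD 8 %) supply the individual variability real corpora show.
Syllable duration 0.08 s and gap 0.03 s give ~9 syllables/s, a realistic
canary tempo; inter-song silence is 1 s.

What the generator does **not** emulate, hence what passing tests do not
show about real data:

* Transition preferences are uniform away from the cycle, so small female
  repertoires saturate: female networks are essentially complete (density
  1.0, path length 1.0) with near-zero variance, unlike real females whose
  uneven transition use keeps density below 1. Group contrasts are
  therefore sharper (larger F, η²) than in real corpora, and the
  within-female repertoire–path-length correlation is undefined in most
  synthetic studies.
* Song types: with stochastic phrase counts nearly every generated song is
  its own (collapsed) type, so `song_type_repertoire` sits near 30 for both
  sexes and carries little signal.
* Successive songs are conditionally independent given the bird, so the
  mean Levenshtein distance is close to song length for both sexes rather
  than reflecting shared song templates.
* No acoustic structure of any kind; labels are arbitrary symbols.

A second generator (`generate_metrics_table`) draws a per-bird metrics
table directly — independent normals around sex-specific means plus a
shared within-bird latent factor that correlates the repertoire-linked
metrics (and couples them positively to path length, negatively to
density) — so the statistics stages can be unit-tested in isolation from
the corpus stages. Its means follow the corpus generator's regime where a
regime value exists and plausible magnitudes otherwise; it is a synthetic
stand-in, not a reconstruction of any real dataset.

## Numerical choices and degenerate inputs

* Times rounded to 1 ms on read/write; interval ordering checked with a
  1 µs tolerance.
* Undefined quantities (rates without times, Levenshtein with one song,
  network metrics of excluded birds, path length with no reachable pair)
  are `nan`, never fabricated; structural violations (overlaps, empty
  labels, unknown factor levels, empty ANOVA cells, constant PCA columns)
  raise typed exceptions naming the offender.
* All generator randomness flows from one integer study seed through
  per-bird seeds (< 2³¹), so identical seeds byte-reproduce every output
  CSV.
* Test problem sizes: the replicated parameter-recovery check runs 100
  studies of 28 birds × 30 songs; the oracle checks cover all ≤4-length
  label-pair combinations over a 3-letter alphabet plus seeded longer
  samples, and 200 random graphs of ≤ 8 nodes.

## Known limitations

* The TextGrid reader covers the two text dialects (long and short) with
  interval tiers only; binary TextGrids are not supported.
* Sum-to-zero Type III is one convention for unbalanced marginal tests;
  other software may differ in pathological unbalanced cases.
* The small-network exclusion threshold interacts with PCA/regression
  sample sizes only through the optional all-ten-metric PCA; the default
  diversity-only PCA keeps every steroid-treated bird.
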