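# Methods

## Model

`phenovec` treats an individual's record as a *set of categorical facts*.
Flattening maps the hierarchical record to that set; one-hot encoding maps
the set to a fixed-layout binary vector; and all similarity statements are
statements about set overlap, computed on the vectors.

The consequences of this model are deliberate:

- **Exact-match semantics.** A variable key embeds both the path and the
  value (`sex.id.NCIT:C20197`), so two individuals agree on a variable only
  when they hold the identical value. There is no partial credit for
  ontologically related terms, and no terminology mapping across
  vocabularies.
- **Presence/absence, not counts.** Duplicate keys collapse; a feature
  recorded twice is one fact.
- **Missingness is silence.** A variable absent from a record contributes
  no key. In cohort mode both-absent positions agree (Hamming counts only
  differing positions), which can understate dissimilarity between two
  sparsely annotated records; the Jaccard index, computed on the pair
  union only, is co-reported because it behaves better under incomplete
  data.

## Flattening rules

Depth-first traversal, path segments joined with `.`; each scalar leaf
emits `path.value`. Leaf values are canonicalized (booleans `true`/`false`,
floats formatted with `%.12g` so `2.50` → `2.5`); `null` leaves emit
nothing. For a term holding an array of objects, the element's positional
index is replaced by the CURIE found at that term's configured identifier
path (`featureType.id` for BFF `phenotypicFeatures`, `type.id` for PXF,
...); elements lacking the CURIE fall back to the index with a warning.
The exact layout of array-substituted keys —
`term.CURIE.remaining-path.value` — is this package's dialect. Scalar array
elements (multivalued CSV cells) emit `path.value` with no index segment,
making them a value set. Nested arrays below the term level keep positional
indices; order sensitivity there is accepted and documented.

Default exclusions, expressed as glob-style dotted path patterns and fully
user-overridable via the format descriptor: the record id path, `label`
leaves (they duplicate their `id` sibling), `description`/`notes` free
text, and `date`/`Date`/`timestamp`-named leaves; PXF additionally drops
`metaData` and `files`. This is the package's own choice of
"non-informative" defaults.

## Vocabulary and encoding

The vocabulary is the byte-wise lexicographically sorted union of keys over
the reference cohort(s); sorting makes the vector layout deterministic
across platforms. `max_number_var` caps very wide vocabularies (e.g.
genomic variables) by drawing a uniform random subset with the run seed
*before* weighting. Integer weights `w ≥ 1` repeat a key's character `w`
times, so every downstream metric sees the weight as a multiplicity;
encoding a profile against a vocabulary silently drops keys outside it,
which is also how a patient is projected onto a pre-computed cohort space.

## Statistics

For one pair, with weighted union length `L`, distance `d` and Jaccard
`J`: `J = (L − d)/L` (defined as 1 when `L = 0`, i.e. two empty profiles
have nothing to disagree on).

Patient mode standardizes `d` and `J` against the patient's own
comparisons to **all** references — the population excludes nothing and
never includes a self-comparison — using the sample (n−1) standard
deviation; at cohort sizes of ~1000 the n vs n−1 choice is numerically
irrelevant. p-values are one-tailed standard-normal: lower tail for
distance, upper tail for Jaccard. A degenerate population (sd = 0) yields
Z = 0 at the mean and signed infinity elsewhere, flagged in the log. The
normal tail is an approximation: the distance distribution is discrete and
roughly bell-shaped under the simulator's designs, so extreme-tail
p-values should be read as orders of magnitude, not exact probabilities.

The random-model Z, `(2d − L)/√L`, standardizes `d` under a null in which
each of the `L` positions in the pair union differs independently with
probability ½ (`E[d] = L/2`, `sd = √L/2`). It needs no cohort and is
reported per pair; `z_rand(0, L) = −√L`, `z_rand(L, L) = +√L`. For
weighted vectors the weighted `L` is used, consistent with weights acting
position-wise.

Ranking sorts ascending by `d` (or descending by `J`), ties broken by
descending `J` then ascending reference id — stable and deterministic.
`top_n` defaults to 10.

## Synthetic cohort generator

The generator emulates designed simulation studies: per individual and per
clinical term (phenotypic features, diseases, treatments, exposures,
procedures), `k` distinct entries drawn uniformly **without replacement**
from a fixed pool of `P` fabricated CURIEs (`HP:SIM0001`, `OMIM:SIM0001`,
...), plus a uniform binary sex (real NCIt codes, so keys mirror
production data) and an ethnicity drawn from a pool of 100 — a default
chosen as a plausibly wide census-style category set. Defaults are
`k = 10`, `P = 100` for all five terms (a fully random cohort whose
pairwise distances concentrate near `2Σ k(1 − k/P) ≈ 93`); the small
designed experiments set `k` and `P` per term explicitly.

Under this design the per-term pairwise distance is `2(k − X)` with `X`
hypergeometric, so `E[d] = 2k(1 − k/P)` per term — a law the tests check
empirically — and the expected number of references exactly matching a
patient's `k`-subset is `N / C(P, k)`.

What the generator does **not** emulate: missing-at-random annotation
gaps, correlated variables (comorbidities), center effects, free-text
noise, or variable record depth. Passing tests on simulated cohorts
therefore demonstrate the correctness of the encoding and statistics under
a known sampling law, not robustness to real-world data quality.

## Numerical and design choices

- JSON/YAML inputs are sniffed by content, not extension; a single
  top-level object is promoted to a one-record cohort.
- Output formatting mirrors the ranking-table convention: Z-scores to 3
  decimals, the random-model Z to 4, p-values to 7, Jaccard to 3.
- Cohort-mode pair statistics are computed over the full shared
  vocabulary via Gram products on the 0/1 matrix; since both-zero
  positions never differ, the distances equal their pair-union-restricted
  values.
- Zero-distance clusters are connected components of the `d = 0` graph
  (for Hamming, `d = 0` is transitive, so components are cliques of
  identical vectors).
- CSV import drops missing-value cells (`NA`, empty, `unknown`,
  `missing` by default) rather than encoding them, splits multivalued
  cells on `;`, and warns on all-numeric columns, recommending binning —
  continuous values under exact-match semantics share nothing unless
  identical.
- Problem sizes in the test suite follow the designs they check: n = 1000
  cohorts for the ranking experiments, n = 100 for the cluster-progression
  runs (100 seeds), 150 individuals for the pairwise-distance law.

## Known limitations

- Exact matching only; no HPO ancestor expansion or cross-vocabulary
  term mapping.
- Jaccard p-values share the normal approximation of the distance
  p-values but the Jaccard distribution is more skewed; treat them as
  indicative.
- Case–control comparisons with systematically different record sizes
  bias Hamming upward for the richer records; prefer Jaccard, shared-term
  restriction (`--include-terms`), or weighting in that setting.
- Nested (below-term) array order affects keys when elements carry no
  identifying CURIE.
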