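# phenovec

Individual-level similarity analysis of hierarchical phenotypic records.

Clinical and phenotypic data shared through the GA4GH standards — the
Beacon v2 `individuals` entity (BFF) and Phenopackets v2 (PXF) — are deeply
nested JSON documents: diseases, phenotypic features, treatments and
exposures annotated with ontology CURIEs (HPO, OMIM, NCIt, ...). `phenovec`
compares such records directly, without forcing them into a pre-selected
ontology: it is aimed at researchers doing patient matchmaking, cohort
stratification and outlier detection on GA4GH-compliant (or arbitrary
JSON/YAML/CSV) data.

## Method

Each record is **flattened** to a set of variable keys: the dotted path to
every scalar leaf followed by its value (e.g. `sex.id.NCIT:C20197`), with
array indices replaced by each element's ontology CURIE so element order is
irrelevant. Identifiers, `label` leaves, free text and timestamps are
dropped by default. The sorted union of keys over the reference cohort(s)
forms a **global vocabulary** that fixes the layout of a **one-hot binary
vector** per individual; a variable with weight *w* occupies *w* repeated
positions. For two vectors with pair union length *L* (weighted count of
positions where either is 1):

- **Hamming distance** `d` — weighted count of differing positions
  (0 = identical profiles);
- **Jaccard index** `J = (L − d) / L` — intersection over union
  (1 = identical);
- **empirical Z-scores** `z = (x − μ)/σ` of `d` and `J` over a patient's
  comparisons to all references (sample sd), with one-tailed normal
  p-values (lower tail for `d`, upper for `J`);
- **random-model Z** `(2d − L)/√L` — the distance standardized under a
  null where each of the `L` informative positions differs independently
  with probability ½.

Two modes: **cohort** (all-to-all N×N matrix, Hamming by default) and
**patient** (rank one target against reference cohorts with the statistics
above). Matching is exact by design — no ontology-graph or fuzzy matching.

## Worked example

Simulate a reference cohort of 1000 individuals, each with 2 phenotypic
features drawn from a pool of 25, plus one patient built the same way, and
rank the patient:

```sh
phenovec simulate -n 1000 --phenotypic-features 2 --pool-size 25 \
    --diseases 0 --exposures 0 --procedures 0 --treatments 0 \
    --seed 42 -o cohort.json
phenovec simulate -n 1 --phenotypic-features 2 --pool-size 25 \
    --diseases 0 --exposures 0 --procedures 0 --treatments 0 \
    --seed 123 -o patient.json
phenovec patient -r cohort.json -t patient.json \
    --include-terms phenotypicFeatures --seed 1 -o rank.txt
```

`rank.txt` begins:

```
Reference(ID)  Length  Hamming-distance  Distance-Z-score  Distance-P-value  Distance-Z-score(rand)  Jaccard-index  Jaccard-Z-score  Jaccard-P-value
Beacon_639     2       0                 -5.055            0.0000002         -1.4142                 1.000          7.280            0.0000000
Beacon_737     2       0                 -5.055            0.0000002         -1.4142                 1.000          7.280            0.0000000
Beacon_790     2       0                 -5.055            0.0000002         -1.4142                 1.000          7.280            0.0000000
Beacon_808     2       0                 -5.055            0.0000002         -1.4142                 1.000          7.280            0.0000000
Beacon_109     3       2                 -2.325            0.0100229         0.5774                  0.333          2.168            0.0150943
```

Four references match the patient exactly (`d = 0`, `J = 1.000`) — close to
the 1000/C(25,2) ≈ 3.33 expected by chance, which is why the empirical
Z-score (−5.06, p ≈ 2·10⁻⁷) and not the raw distance carries the
significance. The next tier shares one feature of three in the pair union
(`d = 2`, `J = 0.333`); its random-model Z of 0.5774 says such a pair is
indistinguishable from coin-flipping the three informative positions.

Cohort mode writes a symmetric distance matrix instead:

```sh
phenovec cohort -r cohort.json --include-terms phenotypicFeatures \
    --seed 1 -o matrix.txt
```

The matrix feeds standard downstream tooling (hierarchical clustering,
MDS, graph analysis). `--export` dumps the vocabulary, per-individual key
sets and binary vectors as JSON; `--align` (patient mode) writes
per-reference alignment tables; `phenovec import-csv` converts a flat CSV
into comparable records plus an auto-generated format descriptor.

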