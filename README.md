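# linkcascade

Iterative deterministic record linkage for person-level administrative data,
built around inverted-index blocking with TF-IDF candidate retrieval, a
three-stage query cascade and a typed weighted similarity score.

## The problem

Epidemiological research on administrative data routinely needs to decide
which records in two databases — a social registry and a disease notification
system, a live-birth registry and a mortality registry — refer to the same
person, without any shared unique identifier. Comparing every pair is
quadratic and infeasible at registry scale, so a linkage engine needs a
*blocking* step that retrieves only plausible candidates, a *comparison* step
robust to typos, abbreviations and missing fields, and an *evaluation* step
that quantifies linkage errors, since false and missed matches bias any
downstream analysis.

`linkcascade` is aimed at biostatisticians and data engineers who link
Brazilian-style registries (names, mother's names, dates of birth, sex,
7-digit IBGE municipality codes) and need a transparent, fully deterministic
pipeline they can audit and evaluate.

## The method

**Blocking.** The larger dataset A is indexed in an inverted index: every
attribute value is tokenized (names split on spaces, dates on hyphens,
categorical values and municipality codes kept whole) and stored as
`(attribute, term) → postings`. A query record from the smaller dataset B is
scored against stored records by TF-IDF,

> tf(t, d) = count of t in d's field / field length,
> idf(t) = ln(N / df(t)),

used *only to rank* candidates, never to classify pairs.

**Query cascade.** Candidates are retrieved through three modes of
increasing permissiveness and cost: *exact* (every non-missing query
attribute equal), *semi-exact* (the union of the n−1 leave-one-out
arrangements: at most one attribute differs), and *fuzzy* (each name/date
term expanded to all vocabulary terms with normalized Damerau-Levenshtein
similarity ≥ 0.5). The cascade runs exact → semi-exact → fuzzy and stops at
the first stage whose best candidate clears the threshold.

**Scoring.** Each candidate pair is compared attribute by attribute with a
type-specific function — Jaro-Winkler for strings, digit-wise Hamming
agreement for dates (`1 − #differing digits / 8` over `YYYYMMDD`), exact
agreement for categorical values, and a tiered 1 / 0.5 / 0 rule for
municipality codes (same code / same state / different state). The final
score is the weighted mean

> S = Σᵢ wᵢ sᵢ / Σᵢ wᵢ over non-missing attributes,

with weights expressing each attribute's discriminatory power. Pairs with
S ≥ threshold are accepted; when several B records claim one A record, only
the highest-scoring link survives.

**Evaluation.** Ground truth from a shared unique key, per-B-record
confusion counts, sensitivity/specificity/PPV, threshold-analysis tables and
ROC/AUC with Youden-optimal cutoff selection.

**Synthetic data.** A generator produces paired datasets with known truth:
random Brazilian-style names, uniform dates of birth 1900–2010, sex in
{M, F}, IBGE-format municipality codes, with controlled overlap and
corruption (single-character typos and transpositions, missingness,
middle-name abbreviation, single-digit date errors).

## Worked example

```python
from linkcascade import LinkageConfig, classify_at_threshold, link_datasets, \
    metrics, roc_and_auc
from linkcascade.synthgen import CorruptionConfig, make_truthed_pair

pair = make_truthed_pair(1000, 300, overlap=0.7,
                         cfg=CorruptionConfig(typo_rate=0.3, missing_rate=0.1,
                                              seed=42))
result = link_datasets(pair.dataset_a, pair.dataset_b,
                       LinkageConfig(threshold=0.9))
counts = classify_at_threshold(result, pair.truth, 0.9)
print("sens/spec/ppv:", metrics(counts))
print("auc, youden cutoff:", roc_and_auc(result, pair.truth)[1:])
```

prints

```
sens/spec/ppv: (100.0, 100.0, 100.0)
auc, youden cutoff: (1.0, 0.9484386347131446)
```

i.e. on this synthetic pair — 210 of 300 B records are corrupted copies of A
records — every true pair is recovered at threshold 0.9 with no false links
(sensitivity, specificity and PPV all 100%), the score distribution
separates matches from non-matches perfectly (AUC 1.0), and the cutoff
maximizing Youden's J is ≈ 0.95.

The same pipeline is available from the shell:

```bash
linkcascade simulate --n-a 1000 --n-b 300 --overlap 0.7 --typo-rate 0.3 \
    --missing-rate 0.1 --seed 42 --out-dir sim/
linkcascade link --dataset-a sim/dataset_a.csv --dataset-b sim/dataset_b.csv \
    --config config.yaml --out-dir run/
linkcascade evaluate --pairs run/pairs.csv --truth sim/truth.csv \
    --cutoffs 0.86,0.90,0.93 --out-dir eval/
```

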