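# Methods

## Pipeline and assumptions

`linkcascade` performs iterative deterministic linkage of two person-level
datasets A and B sharing a small set of typed attributes. It assumes
|A| ≥ |B| (A is indexed, B is queried), that upstream cleaning has already
standardized obvious format problems (the package still normalizes case,
accents and whitespace defensively), and that duplicates within each
dataset are rare; residual duplicates are tolerated and resolved
deterministically rather than rejected.

Decisions are made per B record: each query record yields exactly one
best-match row, accepted or not. This makes sensitivity, specificity and
PPV all well defined at the record level and lets every threshold sweep be
computed from a single linkage run.

## Normalization

Values are uppercased, accent-folded to ASCII (NFKD), restricted to the
alphabet `A–Z 0–9 space hyphen` and whitespace-collapsed; dates are parsed
in a declared input dialect (default `DD-MM-YYYY`, ISO always accepted so
normalization is idempotent) and stored as `YYYY-MM-DD`. Unparseable dates
become missing rather than raising: in registry data a malformed date is
an absent signal, not an error condition. Missingness is uniformly the
empty string for every kind, which makes the weight-renormalization rule
(below) a single code path.

## Retrieval

The inverted index stores per-attribute postings with term counts and field
lengths. TF is count/field-length; IDF is ln(N/df) with df counted per
attribute field, since queries address named fields. The retrieval score of
a query is the sum of tf·idf over its terms divided by the query length.
The divisor is a presentation choice: any monotone normalization leaves the
*ranking* unchanged, and ranking is the only contract retrieval has to
honour — classification never uses TF-IDF. Ranking ties break by ascending
record id so runs are reproducible.

The three modes form a nested family (exact ⊆ semi-exact ⊆ fuzzy as id
sets, when the candidate cap covers A). Missing attributes of the query are
dropped from the predicate rather than required to match; with exactly one
non-missing attribute the semi-exact leave-one-out arrangement degenerates
to an unconstrained query, which is kept with its literal semantics (all
records eligible, ranked and capped) rather than special-cased. Fuzzy
expansion scans the attribute vocabulary with a length pre-filter
(|length difference| must not already exceed the edit budget); edit
tolerance applies only to string and date terms, because a single-token
categorical or municipality code within edit distance 1 is a *different*
category, not a typo of the same one. The similarity floor is
1 − DL/max(|a|,|b|) ≥ 0.5, measured against the longer term.

## Comparison and scoring

* **Strings** — Jaro-Winkler with the standard parameters (prefix scale
  0.1, prefix cap 4, no boost threshold).
* **Dates** — Hamming agreement over the 8 digits of `YYYYMMDD`:
  1 − differing/8. Digits, not characters: the separators carry no
  information, and digit positions give a uniform scale.
* **Categorical** — 1/0 agreement.
* **Municipality (IBGE)** — 1.0 identical, 0.5 same 2-digit state prefix,
  0.0 otherwise; the two-level tier is the minimal structure the code's
  digit layout supports, and the 0.5 middle tier is configurable.
  Malformed codes degrade to plain equality.
* **Edit distance** — optimal-string-alignment Damerau-Levenshtein
  (adjacent transpositions allowed, no substring edited twice), matching
  the semantics search engines use for fuzzy matching.

The pair score is the weighted mean of attribute scores with weights
renormalized over the attributes observed on both sides. Scoring a missing
attribute 0 would conflate absence with disagreement and systematically
punish incomplete records; renormalization instead judges a pair on the
evidence it actually carries. A consequence worth knowing: an exact-stage
match with missing attributes still scores 1.0 over the compared subset.
If every attribute is missing the pair is incomparable and excluded.

Acceptance uses score ≥ threshold (the non-strict reading; a strict
reading differs only on ties at the cutoff). Default threshold 0.9 and
candidate-list size 20 suit five-attribute schemas where names dominate
the weights; the operating cutoff should always be chosen from the
threshold table / ROC of a reviewed or synthetic sample.

## Cascade and post-processing

Stages run cheapest first with early exit. The cascade trades score
optimality for cost: a later stage maximizes over a superset of candidates,
so a fuzzy-only run can only match or exceed the cascade's accepted score —
the accepted pair is the best *within the accepting stage*, and the
exhaustive all-pairs optimum is an upper bound (both properties are
tested). Unaccepted records keep the best candidate, score and stage seen,
so ROC analysis sees the full score distribution.

Many-to-one resolution keeps, among accepted links claiming the same A
record, only the highest score (ties by ascending B id, as all ties in the
package break by ascending id). After resolution accepted links are an
injective map B → A.

## Evaluation

Ground truth is an exact join on a shared unique key; a B record yields TP
(linked to its true counterpart at the cutoff), FP (linked elsewhere, or
linked while having no counterpart), FN (counterpart exists, no link) or TN
(no counterpart, no link). TN is defined at the record level — a
correctly-unlinked B record — which is what makes specificity computable
for linkage at all. Threshold tables report true/false matches as
percentages of accepted matches and missed matches as a percentage of all
true pairs. The ROC sweeps all distinct observed scores, closes the curve
at (0,0) and (1,1), integrates by the trapezoidal rule, and reports the
cutoff maximizing Youden's J (sensitivity + specificity − 1) as the
operating-point suggestion; "best accuracy" has no unique formalization and
Youden's J is the standard symmetric choice.

## Synthetic data generator

The generator emulates simulated Brazilian registry extracts: three-token
names (given, middle, surname) drawn from bundled lists of ~200 common
given names and ~120 surnames, mother's names sharing the family surname,
dates of birth uniform over 1900–2010, sex uniform on {M, F}, and
municipality codes in the 7-digit IBGE layout built on the 27 real state
prefixes. The bundled lists are small fixtures; they do **not** reproduce
real Brazilian name *frequencies*, so synthetic vocabularies are far
smaller and more collision-prone per name than real registries — good for
stressing retrieval, not evidence about real-data error rates.

Corruption applies, per attribute and per configured rate: blanking;
exactly one single-character edit (substitution, insertion, deletion, or —
with configurable share — adjacent transposition) to one name token, so
each typo moves a token by exactly one DL unit and error counts stay
interpretable; middle-token abbreviation to an initial; and single-digit
date perturbations that preserve calendar validity. Categorical and code
attributes are only ever blanked: a wrong-but-valid code is a different
kind of error than a typo and is not part of this error model. Full
overlap means every B record is a (possibly corrupted) copy of a distinct
A record; non-overlap records are rejection-sampled to never coincide with
an A record on the full attribute tuple, keeping the truth unambiguous.
All generation is deterministic in a single seed, fanned out through
numpy `SeedSequence`.

Because corruption leaves most attributes intact, typical corrupted pairs
still score far above unrelated pairs; passing the recovery and ROC tests
shows the machinery is correct and well-separated under this error model,
not that real CadUnico/SINAN-scale accuracy would match.

## Numerical and design choices

* Natural log in IDF (base only rescales; ranking invariant).
* All ranking/selection ties break by ascending id; runs on identical
  inputs are byte-identical (timestamps appear only in logs, never in
  written artifacts).
* Candidate retrieval verifies predicates against the document store after
  postings-based seeding, so index pre-filters can never change semantics.
* The exhaustive-oracle and degradation test suites run at deliberately
  desk-scale sizes (hundreds × tens of records, 10 seeds), chosen so the
  whole suite exercises every path in well under a minute while the
  brute-force oracles stay tractable.
* Problem sizes in `scripts/acceptance.py` (2,000 × 500 clean, 1,000 × 300
  corrupted) are the package's reference demonstration sizes.

## Known limitations

* No parallel or distributed execution; the in-memory index targets
  desk-scale and moderate datasets.
* No privacy-preserving linkage (no hashing/Bloom-filter encodings); the
  package assumes a secure analysis environment.
* Weights are configuration, not learned; no probabilistic (Fellegi-Sunter)
  decision model, no clerical-review workflow.
* The fuzzy vocabulary scan is linear per term; a production system would
  use an automaton index, which changes speed, not results.
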