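# Methods

`textcal` scores region-labelled text corpora for "caloric input" (food
phrases) and "caloric output" (physical-activity phrases), and builds
comparative indices, decompositions, and indicator correlations on top of
those scores. This note records the model, its assumptions, the tunable
parameters, and the choices made where the design was open.

## Caloric scoring model

Each side of the instrument is a lexicon of phrases grouped into
*lemmas* — categorically equivalent phrases that share one caloric score.
Food lemmas carry the calories of 100 g of the item (kcal/100 g); no
serving-size model is attempted, as portion databases are too incomplete
to support one. Activity lemmas carry MET values (Metabolic Equivalent
of Task), converted to energy expenditure by the identity
1 MET = 1 kcal·kg⁻¹·h⁻¹ at a reference body mass:

    kcal/hour = MET × body mass (kg)

The default mass is 80.7 kg, the average North American adult; it is a
single configuration constant so sensitivity analyses can vary it.
Within a lemma the score must be *identical* across phrases — a mismatch
is rejected as a data error rather than averaged, because lemma grouping
is defined by shared score source (same nutrient-database code, same
compendium MET).

Given a text `T` (all messages of one region), the caloric input is the
score-weighted mean over food lemmas

    C_in(T) = Σ_s C_in(s) · p(s|T),

where `p(s|T)` is the normalized lemma frequency, and analogously
`C_out(T)` over activity lemmas. Both are convex combinations of lemma
scores, hence invariant to message volume and bounded by the lexicon's
score range. Two composites are derived:

* `C_rat = C_out / C_in` — dimensionless and comparative; the value 1 is
  *not* a meaningful balance point because the two sides' units (100 g
  of food, one hour of activity) are arbitrary conventions.
* `C_diff(α) = α·C_out − (1−α)·C_in`, 0 ≤ α ≤ 1. α can be set by
  *mean-matching* — solving α⟨C_out⟩ = (1−α)⟨C_in⟩ over unweighted
  regional means, which centres `C_diff` at zero across the panel — or
  by grid-searching the α whose `C_diff` best rank-correlates with a
  chosen indicator (step 0.001 by default; |ρ_s| is piecewise constant
  in α, so grid search is exact enough and deterministic; ties take the
  smallest α). Note the rank-plateau structure means indicator-tuned α
  is identified only up to a plateau, typically a few 10⁻³ wide on a
  49-region panel.

Absolute values of `C_in`/`C_out` are not meaningful (lexicons and
corpora are incomplete); the instrument's value is comparative, across
regions scored the same way.

## Phrase extraction by serial partitioning

Counting lexicon phrases naively over-counts: "apple" should not count
when it occurs inside "apple of my eye". Extraction therefore segments
each clause into multiword cells and counts a lexicon phrase only when a
cell equals it exactly.

**Clause segmentation.** Messages are lowercased; URLs, user mentions
(`@…`) and hashtags (`#…`) are removed; clauses break at `. ! ? ; :`
and at message boundaries; tokens are NFKC-normalized with
leading/trailing punctuation and symbol characters (including emoji)
stripped. Only lowercasing is essential to the model; the rest is fixed
here for determinism.

**Random-partition frequency.** Treating each clause of length `L` as
receiving boundaries independently with probability 1/2 at each internal
gap (edges always bound), the frequency `f(s)` of a phrase is its
expected cell count over the corpus. Each contiguous occurrence of an
`ℓ`-token phrase contributes `(1/2)^(ℓ−1)` times a further 1/2 per
clause-interior flank. This closed form is verified in the test suite
against exact enumeration of all `2^(L−1)` boundary configurations.
Phrases longer than `max_len` tokens (default 5; curated lexicon phrases
are ≤ 4 tokens) are not tracked.

**Context-local likelihood.** A phrase of length `ℓ` belongs to `ℓ`
one-wildcard context patterns. With `C_s` the likelihood-minimizing
context,

    L(s) = f(s) / Σ_{t ∈ C_s} f(t),

i.e. the phrase's share of its most prevalent context. `L` is zero on
the empty phrase, on unobserved phrases, and beyond the length cap;
otherwise it lies in (0, 1], reaching 1 only when the phrase is the sole
observed member of every one of its contexts. Argmin ties across
contexts do not affect the value (only the minimum is used); the
implementation scans wildcard positions left to right.

**Greedy segmentation.** Each clause is scanned left to right; the
current phrase absorbs the next token while `L` *strictly* increases and
is flushed as a cell otherwise (ties flush). The partition is lossless
by construction. Frequencies and contexts are corpus-level functions,
so the pipeline makes two passes: build `f` and the context index over
the whole corpus, then partition every clause against them.

**Counting.** Cells matching lexicon phrases roll up to lemma counts per
region. Lemmas seen fewer than `min_count` times corpus-wide (default
5, i.e. four or fewer occurrences) are dropped as noise. Regions with
no counted lemmas on a side are excluded from profiles with a logged
warning, since the weighted mean is undefined on empty support.

## Phrase shifts

The gap between a comparison text and a reference factors exactly over
lemmas (the reference-score offset cancels because usage deviations sum
to zero):

    C(comp) − C(ref) = Σ_s [C(s) − C_ref] · [p(s|comp) − p(s|ref)].

Contributions are normalized to percentages,

    δC(s) = 100 · [C(s) − C_ref] · [p_comp(s) − p_ref(s)] / |C(comp) − C_ref|,

so they sum to +100 when the comparison scores higher and −100 when
lower. The absolute-value denominator (rather than the signed
difference) is what makes the sum ±100 rather than always +100. Each
nonzero term falls in one of four categories by the sign of its score
deviation (+/−) and usage deviation (↑/↓); exactly-zero terms carry no
sign information and are omitted. The default reference is the pooled
panel: the unweighted mean of per-region usage distributions, so small
regions count as much as large ones. Reports are truncated to the top
23 terms by |δC| on export (full list by flag).

The "distinguishing" lemma of a region is the increased-usage term
(↑) with the largest |δC| among those aligned with the net shift — the
phrase whose *extra* usage most explains the region's departure from the
reference. When a region departs purely by abandoning phrases, no term
qualifies and the result is an explicit absence.

Numerical caveat: the ±100 identity is exact in real arithmetic; in
float64 it degrades when the two texts score within ~1 kcal of each
other, because individual δC terms grow like 1/|ΔC| and cancel. The
operation rejects exact equality, and tests exercise the identity (at
1e-9) away from that ill-conditioned neighbourhood. The net is
accumulated with compensated summation.

## Correlations

Each caloric measure is rank-correlated (Spearman's ρ_s, two-sided
p-values via the t-approximation on n−2 degrees of freedom, standard at
panel sizes near 50) against each indicator column; Pearson correlation
with an OLS line is available for scatter summaries. Multiple
comparisons are corrected with Benjamini–Hochberg step-up q-values
computed over the *whole* measure × indicator family at once (per-measure
families by flag). Missing indicator cells drop regions pairwise, with
the dropped count reported per row. Output tables are sorted by
ascending q for `C_rat` and banded at q < 0.01 and q < 0.05.

## Synthetic data generator

The generator emulates the instrument's inputs with known ground truth:

* **Lexicons** — hand-curated seed entries (including the decoy anchor
  "apple" and phrases of 2–4 tokens) extended with generated entries;
  food scores uniform on [20, 600] kcal/100 g, METs uniform on
  [0.95, 14].
* **Corpora** — per region and side, a Dirichlet-drawn multinomial over
  lemmas (symmetric concentration 1 by default: flat random usage
  mixes); each message embeds exactly one sampled phrase among filler
  tokens (filler fraction 0.6 by default, filler vocabulary of 40 tokens
  disjoint from lexicon tokens), with the message count per region/side
  a parameter (10,000 each by default, i.e. 20,000 messages per region).
  Exact planted counts are returned alongside.
* **Indicators** — noisy linear transforms of chosen caloric measures
  plus independent standard-normal null columns. To plant a target
  population Spearman correlation, noise is sized via the
  bivariate-normal identity ρ_s = (6/π)·asin(r/2).

Planted phrases are inserted as punctuation-delimited clauses of their
own rather than inline in filler text. This is deliberate: the
likelihood saturates at 1, so a ≥3-token phrase whose tokens are unique
to it would provably be split after two tokens, and inline unigrams can
be absorbed into chance bigram cells. Clause-isolated planting — plus
"confuser" clauses sharing the leading tokens of 3–4-token phrases,
which hold prefix likelihoods strictly below 1 so greedy growth runs to
the full phrase — makes extraction exactly invertible: pipeline counts
equal planted counts verbatim when no decoys are enabled. The decoy
idiom "apple of my eye" (present in corpora at a configurable rate,
absent from lexicons) checks the flip side: its partition cells are
multiword, so it contributes nothing to the "apple" lemma.

What passing tests therefore show: the extraction, scoring, shift, and
correlation machinery is correct on corpora whose phrase boundaries are
recoverable. What they do not show: performance on real social-media
text, where lexicon tokens collide with running prose, phrase boundaries
are ambiguous, and counts are systematically attenuated rather than
exact. The generator does not emulate message metadata, geocoding, or
author-level structure — region labels are taken as given.

## Default problem sizes and seeds

End-to-end checks use 10 regions × 20,000 messages (10,000 per side) and
a 12-lemma lexicon per side; statistical calibration uses a 49-region
panel, 100 replicates for recovery of a planted ρ_s ≈ 0.8 (tolerance
±0.1 on the mean), and 1000 replicates for the null false-discovery
calibration (≤ 5% of q < 0.05, binomial slack). All randomness flows
from one seed through named `numpy` substreams, so corpora are
byte-identical across runs.

## Known limitations

* Scores are crude equivalences: 100 g per food mention, one hour per
  activity mention, one national reference mass. The indices are
  comparative, not absolute.
* The two sides' dynamic ranges differ (activity is wider); no
  rescaling is applied, so `C_rat` is driven more by `C_out`.
* Indicator-tuned α is identified only up to a rank plateau.
* The extraction cap `max_len = 5` silently ignores longer lexicon
  phrases; validate lexicons against it.
* Correlations are observational panel associations; nothing causal is
  implied.
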