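# Methods

## Overview

`phenominer` treats an electronic patient record corpus as two parallel
evidence streams about each patient's morbidity: structured ICD10 code
assignments, and free-text notes mined for ICD10 terms. The level-3 code
(one letter + two digits, e.g. `F20`) is the unit of analysis
throughout: rounding every code and term to level 3 trades specificity
for robustness, since truncated term variants can no longer be trusted
to carry sub-level meaning.

## Dictionary construction

Terms from a `code<TAB>term` table are normalized (lowercase, collapsed
whitespace, boundary punctuation stripped; national characters kept; no
stemming — matching is exact by design) and augmented with rule-based
truncation variants: the prefix before a specifier phrase ("caused by",
"due to", "forårsaget af", …), the prefix before the first comma, and —
for parentheses — both the prefix before `(` and the term with the
parenthesized segment removed. Variants inherit their parent's level-3
code. The specifier list ships as an editable config file; any real
deployment should extend it for its language.

Two dialect details are deliberate choices. A leading `D` is stripped
only when followed by a letter, so Danish SKS codes (`DF20` → `F20`)
and genuine blood-chapter codes (`D64`) coexist. Variant generation runs
on lightly-normalized text (punctuation retained) because the comma and
parenthesis rules need punctuation that full normalization removes; full
normalization is applied to the emitted variants.

Chapters I–XXII are assigned from the standard WHO level-3 ranges
(A00–B99 → I, …, U00–U99 → XXII); codes in gaps of the
classification (e.g. `D49`) are rejected rather than guessed.

## Text mining

Notes are split into sentences on `. ! ?` and newlines (clinical notes
are line-structured) *before* normalization, so character spans always
refer to the original text. Within a sentence, tokens are normalized
with their offsets; a stepping scan tries windows of 10 down to 1 tokens
at each position, keeps the longest exact dictionary match and resumes
after it — accepted matches therefore never overlap.

Every candidate is classified with precedence blacklist > negation >
false subject > accepted. The negation/subject scope is the same
sentence, tokens strictly before the match — the narrower of the
plausible readings, chosen to minimize false disqualifications.
Disqualified candidates are retained with their status so
disqualification counts are reportable, and the blacklist is applied at
lookup time rather than by deleting dictionary entries for the same
reason.

## Association matrix

Cell counts are `tf = (1 if assigned else 0) + accepted mined
incidences`: repeated identical assignments of a code to a patient are
de-duplicated (structured fields repeat administratively), while every
mined incidence counts — the mined `tf` carries the signal the TF-IDF
weighting needs. `tfidf = tf · ln(N/df)` with `df` = patients carrying
the code and `N` = cohort size; no smoothing is needed because `df ≥ 1`
whenever `tf > 0`. The matrix is stored sparse with per-cell provenance
(assigned / mined / both).

## Comorbidity ranking

For each unordered pair the 2×2 contingency (A&B, A¬B, B¬A, ¬A¬B) is
tested one-sided for enrichment: `p = P(X ≥ Obs)` with `X`
hypergeometric — equal to Fisher's exact test with alternative
"greater". One-sidedness is a design choice: the score cutoff targets
over-co-occurrence only. The effect-size filter is the comorbidity
score `log2((Obs+1)/(Expt+1))`, `Expt = n_A·n_B/N`; the pseudo-count
damps the advantage of very rare codes, and a cutoff of 1.0 keeps pairs
co-occurring (approximately) more than twice as often as expected.

Selection is Benjamini–Hochberg step-up with `m` = the *full* pair
universe (not the post-score-filter count): corrected `p·m/rank`, made
monotone by the running-minimum-from-the-bottom rule so the "drops
below q" cutoff is well defined, selected while corrected p < 0.01 and
score ≥ 1.0. The scan is vectorised (sparse `BᵀB` for overlaps, a
single vectorised hypergeometric tail call), so a 226k-pair universe is
a sub-second operation.

The heatmap ordering clusters the top-k codes of the selected list
(sorted by score) with average linkage on distance `max_score − score`.

## Patient stratification

Patients need ≥ 3 distinct level-3 codes *after* removing an editable
list of trivial/symptom codes (defaults: pain R52, cough R05, itching
L29). Distance is `1 − CS` over TF-IDF vectors; clustering is UPGMA
(scipy's average linkage; its NN-chain algorithm is deterministic given
the input, and merge heights are tie-break-invariant, which is what the
small-n brute-force oracle checks). The tree is cut at CS = 0.6 and
clusters with ≥ 25 members are kept.

Cluster profiles pool member counts into one document and re-weight
with the *patient-level* idf and N, so profiles are comparable across
clusters; the profile reports each code's fraction of the pooled TF-IDF
vector. The patient network links kept-cluster members with pairwise
CS > 0.6.

## Disease-gene network overlap

Seed genes per code come from a plain `code<TAB>gene` table (curated
OMIM-style mappings are an input, not a concern of this package). A
disease network is its seeds plus their direct PPI neighbors. Candidates
for a pair are the shared non-seed members adjacent to ≥ 1 seed of each
disease; a candidate with degree `n`, `k` of whose partners lie in the
pair's seed union (size `K`), scores `P(X ≥ k)` hypergeometric with
population `M = |network| − 1`. The background `M` is a declared choice
(the natural "all possible partners" population); the seed union —
rather than per-disease seed sets — is used because the candidate
bridges both diseases. Seeds absent from the network are dropped with a
warning rather than failing the pair.

## Synthetic cohorts

The generator emulates exactly the features the pipeline reacts to:

* **Code truth** — independent Bernoulli draws per code prevalence;
  each planted pair's 2×2 is constructed directly with joint probability
  `lift·p_a·p_b` and preserved marginals (infeasible lifts are
  rejected); cluster members additionally receive a dominant plus
  support codes.
* **Text** — each true code is mentioned `Poisson(mention_rate)` times;
  a mention sentence is `[prefix] term [filler]`, where the prefix is a
  negation token, a subject token or neutral filler according to the
  configured rates, and the truth records the exact character span and
  label. Term words, filler words and lexicon words come from disjoint
  pseudo-word pools, so accidental matches cannot occur. Notes are
  synthetic token salad: the miner is exact-match and order-insensitive
  beyond the sentence, so grammar contributes nothing to what is being
  tested.
* **PPI** — Erdős–Rényi background plus planted seed–candidate–seed
  motifs whose genes are reserved so the motif is never accidental.

Defaults are calibrated to the corpus-level statistics a psychiatric
EPR corpus exhibits: `negation_rate = 0.10` (roughly one candidate
match in ten is negated), `false_subject_rate = 0.015` (other-subject
mentions are an order of magnitude rarer than negations),
`assigned_rate = 0.25` (structured assignments cover roughly a quarter
of a patient's combined codes), `mention_rate = 2.0` mentions per true
code. A single integer seed drives all randomness; identical config +
seed reproduces byte-identical files.

What passing tests on these cohorts does **not** show: robustness to
real clinical language (inflection, abbreviation, misspelling — exact
matching will under-recall there), to polysemy (the blacklist is an
editable stub), or to negation expressed after the term or across
clause boundaries. The generator writes negations the lexicon rule can
catch; the measured 100% disqualification rate is a correctness check
of the rule, not an estimate of real-world negation recall.

## Test and evaluation design

* Incidence precision judges every accepted hit; association precision
  counts each patient–code association once, correct if ≥ 1 incidence
  is correct. Negation-module precision is correct disqualifications
  over all disqualifications; recall is correct disqualifications over
  all matched truly-negated/other-subject mentions.
* Statistical primitives are checked against independent oracles:
  exhaustive hypergeometric summation (populations ≤ 60, tolerance
  1e-12), `scipy.stats.fisher_exact`, statsmodels' BH implementation,
  and an O(n³) brute-force UPGMA at n ≤ 8.
* Stochastic guarantees use fixed seeds and conditions chosen once:
  mean empirical FDR over 20 null cohorts (2,000 × 200, prevalence
  U[0.01, 0.2]) must stay ≤ 1%; pairs planted at lift 4 and prevalence
  0.08 in n = 2,000 must be selected in ≥ 95% of cases; well-separated
  planted clusters (within-CS ≈ 0.8, between-CS ≈ 0.01) must be
  recovered with ARI ≥ 0.9.
* Problem sizes in the default test run (cohorts of 120–2,000 patients,
  60–200 codes) keep the whole suite under a minute on one CPU while
  leaving the statistical assertions well-powered.

## Known limitations

* Exact matching only; no lemmatization, spelling correction or
  abbreviation expansion.
* The shipped negation/subject/specifier/blacklist lists are minimal
  English+Danish defaults meant to be replaced per deployment.
* Whether comma-truncated terms should also keep the post-comma part is
  unresolved in the underlying scheme; only the prefix is kept here.
* TF for mined codes counts incidences (not distinct notes); corpora
  with highly repetitive notes may want note-level de-duplication.
* The hypergeometric background for candidate scoring (`M = |network| −
  1`) makes scores comparable within one network but not across
  networks of different size.
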