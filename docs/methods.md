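# Methods

## The inference problem

A death certificate records an ordered *cause-of-death chain*: the direct
cause A that immediately produced death, followed by up to three
intermediate conditions B, C, D running backwards toward the originating
condition, all coded in ICD-10. Past-medical-history conditions E may sit
outside the chain yet still be the true origin of the fatal sequence. The
task is to select the single **underlying cause-of-death** from
chain ∪ history. Mortality statistics stand or fall on this selection,
and doing it manually is slow and rater-dependent.

## The sink rule

The decedent is modeled as a boat and each certificate cause as a stone
loaded into it; the boat sinks under all of them, and the underlying
cause is taken to be the heaviest stone. Weight is operationalized as the
**conditional death cause proportion**,

    CDCP(i | age group, gender) = P(i is the underlying cause | i appears on the certificate),

estimated per stratum from labeled records as

    raw:  (death_count[i][a][g] + α) / (occur_count[i][a][g] + 2α)
    log:  log2(raw × 10)

where `occur_count` counts decedents in stratum (a, g) whose certificate
carries cause i (at most once per decedent, even if i sits in both chain
and history) and `death_count` counts those for whom i is the labeled
underlying cause. Inference scores every candidate with its stratum CDCP
and predicts the argmax. Two rules wrap the argmax:

* **External-cause short-circuit** (default on): if the direct cause A is
  an ICD-10 Chapter XX code (leading letter V–Y), it is the underlying
  cause by coding convention — no lookup.
* **Fallback**: candidates with no defined CDCP are excluded; if none
  remains, the direct cause is predicted.

The companion **regional death cause proportion** RDCP(i, j) = n_ij / N_j
is the share of deaths in region j attributed to cause i as underlying;
it is purely descriptive here (regions do not enter the CDCP strata) and
normalizes to one per region by construction.

### Strata

Age groups are young (age ≤ 18), middle (18 < age < 55) and old
(age ≥ 55); genders are male and female. Both boundary ages are asserted
in tests (18 → young, 55 → old).

### Raw vs log transform

The log2(raw × 10) variant compresses the dynamic range of the raw
ratio. Because x ↦ log2(10x) is strictly increasing, both variants
induce the same within-stratum ranking, hence identical sink decisions
whenever every candidate cell is defined (guaranteed for α > 0); this
invariance is property-tested. `raw` is the default: it is a probability,
matches the scale of published worked-example tables, and keeps cells
with zero deaths defined (the log variant leaves them absent and logs a
warning). The constant 10 inside the log is kept verbatim in the log
variant.

### Smoothing

Additive smoothing (d + α)/(o + 2α) with α = 0 by default. α > 0 pulls
small-count cells toward 1/2 and makes every observed cell defined under
both transforms; it is exposed as an explicit knob rather than baked in,
since no principled value is forced by the method.

### Lookup fallback

A test-time (cause, stratum) cell can be absent. The `pooled` policy
(default) falls back to cells computed from *pooled counts* — pooled
over gender at fixed age group, then over age at fixed gender, then
globally — never from averaged proportions, which would weight strata
incorrectly. The `stratum`/`none` policy stops at the exact cell.

### Tie-breaking

Exact score ties are broken deterministically: latest chain position
first (the chain is ordered from direct cause backwards, so later
positions sit nearer the origin of the fatal sequence), chain before
history, then lexicographic code order. Results flag `tie_broken`.

## Evaluation protocol

k-fold cross-validation with k = 17 by default: a seeded shuffle
followed by round-robin assignment yields folds whose sizes differ by at
most one (optionally stratified by label to spread rare causes). For
each fold the count and CDCP tables are fitted strictly on the other
k − 1 folds; held-out predictions are pooled across folds before scoring
so rare-cause metrics stay defined (per-fold macro-F1 is available as an
option). Metrics are one-vs-rest precision/recall/F1 per cause, macro
averages over causes with support ≥ 1, micro averages (which coincide
with accuracy in this single-label setting), and the fraction of causes
with F1 above given thresholds.

Two reference baselines treat the task as ordinary classification:

* **Naive Bayes** — class = underlying cause; features = presence of
  each certificate cause, age group, gender, assumed independent given
  the class; additive smoothing (α = 1); argmax posterior restricted to
  the record's candidate set by default (unrestricted available).
* **KNN** — Hamming distance on (multi-hot cause vector, age group,
  gender); majority label among the k = 5 nearest; label ties go to the
  smaller summed distance then lexicographic order, and neighbor
  selection at equal distance is by record id, making predictions
  invariant to training-set order.

## The synthetic cohort generator

No registry extract ships with the package, so cohorts are simulated
with fully known structure and the whole pipeline is validated by
parameter recovery rather than against withheld real data.

Per record: region, age group (ages uniform within group), and gender
are sampled independently; a chain length L ∈ {1..4} is drawn; L
distinct internal causes are sampled without replacement proportional to
the region's prevalence vector (Gumbel top-k); a Poisson number of
distinct history codes follows from the same ranked draw. With
probability `external_fraction` the direct cause is replaced by an
external-chapter code and labeled underlying, mirroring the external
rule. Otherwise the underlying label is drawn from chain ∪ history with
probability proportional to the per-stratum **lethality** of each
candidate — the simplest mechanism under which "pick the largest CDCP"
is the Bayes decision rule, which makes the sink rule's optimality
testable. The induced cell probability
P(i underlying | i appears, stratum) differs from the raw lethality
because it marginalizes over co-occurring candidates; it is estimated by
the brute-force Monte-Carlo oracle (`induced_cdcp_oracle`, ≥ 10× the
cohort size) and is the recovery target for the fitted estimator.

Defaults emulate a mid-sized city registry at the ~50,000-record scale:
40 internal causes over 5 regions with sparse Dirichlet(0.8) prevalence
(a handful of causes dominate each region), lethalities Beta(0.6, 1.2)
clipped to (0.01, 0.99) — many causes rarely underlying, a few
near-certain killers, as real CDCP distributions show; chain-length
probabilities (0.10, 0.30, 0.35, 0.25); Poisson(0.5) history; 5%
external deaths; age-group weights (0.05, 0.25, 0.70) concentrating
deaths among the old; balanced gender. ICD-10 codes come from a fixed
syntactically valid pool (chapters A–U internal, V–Y external) so code
validation is exercised.

What the generator does *not* emulate: real ICD-10 disease frequencies,
comorbidity correlation between chain members, region-specific
lethality, coding errors, or temporal drift. Passing tests therefore
demonstrate correctness of the estimators and the decision rule under a
well-specified model — not clinical performance on any real registry.

## Numerical and design choices

* Counts are exact integers; CDCP/RDCP are double precision; RDCP
  normalization is asserted at 1e-9.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config seeds (child streams via `SeedSequence`), so cohorts,
  fold assignments and reports are byte-reproducible.
* Degenerate inputs: empty record lists yield empty tables; zero-
  occurrence cells are absent, not zero; unlabeled records are rejected
  by name; k > n folds is an error.
* Problem sizes used by the test suite: parameter recovery fits 100,000
  records against a 1,000,000-draw oracle (RMSE ≤ 0.02 on cells with
  ≥ 500 occurrences); the baseline comparison runs 17-fold CV on 20,000
  records; the count-accumulator oracle check runs at 10,000 records.
  These sizes give sub-minute runtimes while leaving the statistical
  bounds comfortably non-trivial.

## Known limitations

* The method assumes candidate causes act independently through their
  marginal CDCPs; certificates whose chain lacks any pathological
  causality (e.g. transcription artifacts) are outside the model, and
  co-occurrence structure is ignored by design.
* CDCP is not regionalized — regional variation enters only through
  RDCP, which the decision rule does not consume.
* The external rule keys on the direct cause only; an external code in a
  non-direct position does not trigger it.
* Syntactic ICD-10 validation only; no dictionary of assignable codes.
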