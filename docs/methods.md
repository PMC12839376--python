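# Methods

## Problem setting

In cardiovascular inpatient care, guideline-directed therapy routinely
stacks seven to ten concurrent medications.  Because the number of drug
pairs grows as n(n−1)/2, the potential drug–drug interaction (DDI)
burden grows combinatorially with regimen size, and a handful of
workhorse drugs (proton-pump inhibitors, loop diuretics,
mineralocorticoid-receptor antagonists) end up mediating a
disproportionate share of all flagged interactions.  `ddinet`
operationalises this analysis: per-patient interaction profiling against
a severity-annotated knowledge base, cohort-level burden/severity/risk
description, and a severity-weighted interaction network whose
centrality structure identifies hub drugs.

## Knowledge base and profiling model

The knowledge base (KB) is a local table of unordered interacting drug
pairs, each with one severity label: minor, moderate, major, or unknown.
Drug names are canonicalised (lower-cased, whitespace-collapsed) and
pairs stored lexicographically, so `(A, B)` and `(B, A)` are one record.
Two modelling commitments matter:

* **Closed world.** A pair absent from the KB means *no documented
  interaction*.  `unknown` is reserved for pairs the KB explicitly lists
  with undetermined severity — it carries an edge weight (0.5), so it
  must be a listed category, not the absence of a record.
* **One severity per pair.** Severity is a property of the pair, not of
  the patient-level event; multiplicity arises only across patients.

For each patient, all n(n−1)/2 pairs of their de-duplicated medication
set are screened once.  Each unordered pair contributes at most one
interaction per patient.  Derived per-patient measures use fixed
category cuts:

| measure | low | medium/moderate | high |
|---|---|---|---|
| medication burden (drugs) | 1–5 | 6–10 | ≥11 |
| interaction burden (interactions) | 0–10 | 11–30 | ≥31 |
| major-interaction risk (major count) | 0 | 1–2 | ≥3 |

A patient with zero interactions has an *absent* (not zero) major-
percentage, so means taken over patients with ≥1 interaction are
well-defined.

Inclusion screening at load time: adults (≥18 years) with ≥2 distinct
agents after canonicalisation; rows failing a rule are excluded and
itemised with a reason (strict mode aborts instead).  Age strata use
half-open bins [18,50), [50,65), [65,80), [80,∞).  Published analyses of
this kind print overlapping bin labels inconsistently; a single
half-open convention keeps assignment total and mutually exclusive, and
custom cut points can be supplied.

## Cohort statistics

Prevalence estimates carry exact Clopper–Pearson 95% intervals computed
from Beta quantiles (`scipy.stats.beta.ppf`); the unit tests verify them
against bisection on the exact binomial tail to 1e−9.  For 246/250 the
exact interval is (95.954%, 99.562%); note that displays that truncate
rather than round to one decimal will show 95.9–99.5.  Correlations are
Pearson product-moment coefficients, reported as absent (with a warning)
when an input is constant or a stratum has fewer than two patients — no
spurious values.  By design the layer is purely descriptive: no
hypothesis tests, no p-values.

Frequency tables are recomputed from the long-format interaction table
(one row per patient × interacting pair).  Each interaction contributes
one appearance to each of its two drugs, so per-drug counts sum to twice
the interaction total — an invariant the tests assert.  Ranked outputs
break ties lexicographically on drug name, after count descending.
Percentages are rounded to one decimal only on export; full precision is
kept internally.

## Network construction and metrics

Nodes are drugs, undirected edges are interacting pairs observed in at
least one patient.  An edge stores its KB severity, the number of
patients exhibiting the pair (`occurrence_count`), and the summed
severity weight (occurrences × weight, with major=3, moderate=2,
minor=1, unknown=0.5).  Drugs never involved in an interaction are
excluded by default (a flag retains them as isolated nodes).  The
hub subgraph is the induced subgraph on the k=25 nodes of highest raw
degree, lexicographic tie-break.

All centralities are computed from scratch on the **unweighted**
topology; severity weights are stored edge attributes and enter only the
optional weighted variants (node strength, weighted eigenvector).
Conventions:

* **Degree** is the raw neighbour count (hub rankings use it directly);
  the normalised form degree/(n−1) is also exported.
* **Betweenness** uses Brandes' dependency accumulation over hop-count
  shortest paths, endpoints excluded, normalised by (n−1)(n−2)/2.
* **Closeness** is component-scaled: ((k−1)/Σd)·((k−1)/(n−1)) for a node
  reaching k−1 others at total distance Σd, which reduces to the simple
  (n−1)/Σd form on connected graphs and handles disconnected synthetic
  graphs gracefully; isolated nodes score 0.
* **Eigenvector centrality** is power iteration on (A + I) — the
  identity shift removes period-two oscillation on bipartite
  components — converging when the L1 change between successive
  normalised iterates falls below n·tol (default tol 1e−8, max 1000
  iterations; non-convergence raises, and the CLI maps it to exit
  code 4).  Disconnected graphs are handled per component with a
  warning that cross-component values are not comparable; each
  component's sub-vector is non-negative with unit Euclidean norm.
* **Clustering** is the triangle fraction 2T(v)/(deg(v)(deg(v)−1)),
  zero below degree 2; the graph-level value is the mean over all
  nodes.  **Density** is 2m/(n(n−1)).

The test suite validates every metric on 200+ random graphs (n ≤ 30,
densities 0.05–0.7) against independent brute-force oracles (explicit
all-pairs shortest-path counting, BFS distance sums, cubic triangle
loops, union-find, dense eigendecomposition) and against networkx, which
serves only as a cross-check, never as the implementation.

## Synthetic cohort generator

The generator emulates a hospitalized cardiovascular cohort so that the
whole pipeline is exercisable without patient data.  Defaults define the
emulated study conditions and are not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| n_patients | 250 | typical single-centre retrospective cohort |
| n_drugs | 110 | formulary breadth observed in such cohorts |
| medication count | truncated NB, mean 7.7, range 2–16 | reported polypharmacy level; dispersion r=200 (near-Poisson) gives sd ≈ 2.7 after truncation |
| age | Normal(68.3, 12.8) truncated to [18,100] | elderly cardiovascular case mix; truncation by resampling avoids boundary spikes; integer years |
| sex | 55.6% male | reported cohort composition |
| severity_mix | (0.44, 0.44, 0.12, 0) | minor/moderate/major/unknown fractions of KB records |
| hub_skew | 1.0 | Zipf exponent of prescription prevalence |
| interaction_density (ρ) | 0.25 | baseline per-pair KB inclusion probability |
| kb_hub_skew (γ) | 0.45 | exponent of the rank-dependent interaction propensity |

Prescriptions are sampled without replacement with Zipf weights over a
prevalence-ordered formulary of real cardiovascular/comorbidity drug
names (extended with placeholder names beyond the built-in list).  The
KB lists pair (i, j) with probability min(1, ρ·s_i·s_j), where
s_k ∝ rank_k^(−γ) is normalised to mean 1.  A *uniform* fabric (γ=0)
cannot reproduce the observed regime: at any density matching a ~15%
network saturation it yields only ~5 interactions per patient, a
medication↔interaction correlation near 0.86, and no pronounced hubs.
The rank-propensity fabric concentrates interactions on the drugs that
are also most prescribed — pharmacologically plausible, since
promiscuous interactors (PPIs, diuretics, amiodarone) are exactly the
workhorse drugs — and with the defaults above a default cohort yields,
across seeds: network density ≈ 0.14–0.15 on ~110 nodes, average degree
≈ 16, ≈ 18–20 interactions per patient, ≥ 99% of patients with at least
one interaction, correlation(medications, interactions) ≈ 0.93, average
clustering ≈ 0.59 with a hub subgraph density ≈ 0.69.  These values were
fixed once, when the generator was designed, and the test bands assert
them as bands (e.g. r > 0.9, prevalence ≥ 90%), not points.

Severity is assigned per KB pair, so the *event-level* severity mix
observed in a cohort deviates from `severity_mix` in proportion to how
occurrence counts concentrate on hub pairs; the (0.44, 0.44, 0.12)
calibration is therefore stated on KB records, and event-level fractions
fluctuate a few points across seeds.  The default mix gives `unknown`
probability 0; tests exercising the 0.5 weight set it explicitly.

What the generator does **not** model: comorbidity-driven prescribing
correlations (drug co-occurrence beyond shared prevalence), dose, route,
exposure timing, severity–drug associations, or any clinical outcome.
Passing tests on synthetic cohorts therefore demonstrate that the
pipeline's accounting, statistics and graph algorithms are correct under
realistic marginal structure — not that any clinical conclusion
transfers to real data.

## Numerical and degenerate-input choices

* Duplicate KB pairs with agreeing severities collapse silently;
  conflicting duplicates are an error naming both severities.
* Self-pairs are rejected everywhere (lookup, records, edges).
* A cohort with zero interactions is valid end to end: empty severity
  distribution, empty graph, density 0, exit code 0.
* `density` of a graph with fewer than two nodes is 0 by convention.
* Male/female interaction ratio for a drug with zero female appearances
  is reported absent, not infinite.
* Deterministic outputs: all randomness flows from one seed through
  `numpy.random.default_rng`; identical configuration yields
  byte-identical files, with the wall-clock timestamp isolated to the
  run manifest.

## Problem sizes used in validation

The default test run uses synthetic cohorts of 25–250 patients, random
graphs up to 30 nodes for the oracle-equivalence backbone (200 graphs),
and one ≥10,000-record KB for the multinomial severity-mix check; the
acceptance script runs one full 250-patient default-condition pipeline.
These sizes keep the whole suite to a few seconds while leaving every
band statistically meaningful.

## Known limitations

* The KB stands in for a proprietary interaction checker; concordance
  between real checkers varies, and no mechanism or management text is
  modelled.
* Centralities are unweighted by design; there is no weighted-
  shortest-path variant, community detection, or layout computation.
* The cohort loader models admission snapshots only — no temporal
  exposure, dose, or outcome linkage.
* Eigenvector centrality across components of a disconnected graph is
  not comparable (flagged by a warning); the dominant component is the
  meaningful one.
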