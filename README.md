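# ddinet

Drug–drug interaction (DDI) profiling and severity-weighted network
analysis for polypharmacy cohorts.

Hospitalized cardiovascular patients routinely receive 7–10 concurrent
medications.  Because a regimen of *n* drugs contains *n*(*n*−1)/2
pairs, potential DDI burden grows combinatorially with medication
count, and a small set of workhorse drugs (proton-pump inhibitors, loop
diuretics, mineralocorticoid-receptor antagonists) mediates a
disproportionate share of all interactions.  `ddinet` is for
pharmacoepidemiologists and clinical-pharmacy researchers who want to
quantify that structure in their own cohorts:

* **Per-patient profiling** — every pair in a patient's medication list
  is screened against a severity-annotated interaction knowledge base
  (minor / moderate / major / unknown); per-patient burden and risk
  categories follow fixed cuts (medication burden 1–5 / 6–10 / ≥11;
  interaction burden 0–10 / 11–30 / ≥31; major-interaction risk 0 /
  1–2 / ≥3).
* **Cohort statistics** — prevalences with exact Clopper–Pearson 95%
  intervals, event-level severity distribution, per-drug and per-pair
  frequency tables, Pearson correlations, sex/age stratification.
  Purely descriptive; no p-values.
* **Interaction network** — drugs as nodes, interacting pairs as
  undirected edges weighted by summed severity (major = 3, moderate = 2,
  minor = 1, unknown = 0.5, summed over patients).  Degree, betweenness,
  closeness, eigenvector centrality, clustering, components and density
  are implemented from first principles and validated against
  brute-force oracles and networkx; a top-*k* hub subgraph isolates the
  densely interconnected core.  Network density is 2m/(n(n−1));
  betweenness uses Brandes accumulation normalised by (n−1)(n−2)/2;
  eigenvector centrality is power iteration with unit-Euclidean-norm
  output.
* **Synthetic cohorts** — a seeded generator produces realistic
  cohort/knowledge-base bundles (250 patients, ~7.7 medications each,
  hub-dominated interaction fabric), so the entire pipeline is testable
  and demonstrable with no patient data.

## Worked example

Generate a synthetic cohort, run the full pipeline, and print the
summary:

```sh
ddinet simulate --seed 7 --out demo
ddinet network --cohort demo/cohort.csv --kb demo/knowledge_base.tsv --out demo_run
ddinet report --out demo_run
```

```
Drug-drug interaction analysis summary
======================================
patients analysed: 250
total interactions: 4631
patients with >=1 interaction: 249 (99.6%; 95% CI 97.8-100.0%)
patients with >=1 major interaction: 210 (84.0%)
severity distribution (events): major 632 (13.6%), minor 1876 (40.5%), moderate 2123 (45.8%)
risk strata (patients): low 40 (16.0%), moderate 102 (40.8%), high 108 (43.2%)
mean medications/patient: 7.74
mean interactions/patient: 18.52
mean major interactions/patient: 2.53
meds vs total interactions r: 0.936

network: 110 nodes, 840 edges, density 0.140, avg clustering 0.616, 1 component(s)
top-25 hub subgraph: 25 nodes, 203 edges, density 0.677, avg clustering 0.759
```

Reading this: essentially every patient (99.6%) has at least one
potential interaction; burden tracks medication count almost linearly
(r = 0.936, the combinatorial n(n−1)/2 effect); and the 25 most
connected drugs form a near-clique (density 0.677 vs 0.140 overall).
The per-node ranking in `demo_run/node_metrics.tsv` puts pantoprazole
first (degree 99, betweenness 0.275), then furosemide and
spironolactone — the hub drugs that deprescribing or monitoring
strategies would target.

Every run emits machine-readable outputs next to the summary:
per-patient `profiles.tsv`, the long-format `interactions.tsv`,
`summary.json`, frequency and severity tables, `edge_list.tsv` +
`network.graphml`, node/graph metrics for the full network and the hub
subgraph, and a `manifest.json` with input hashes and the seed.  The
same pipeline runs on real data: a cohort CSV
(`patient_id,age,sex,residence,diagnosis,medications` with
semicolon-separated medications) plus a knowledge-base TSV
(`drug_a,drug_b,severity`).

Library use mirrors the CLI:

```python
from ddinet import GeneratorConfig, generate, profile_cohort, summarize_cohort
from ddinet import build_network, top_k_subgraph, graph_metrics

bundle = generate(GeneratorConfig(seed=7))
profiles = profile_cohort(bundle.cohort, bundle.kb)
summary = summarize_cohort(profiles)          # prevalences, CIs, correlations
graph = build_network(profiles)               # severity-weighted DrugGraph
hubs = top_k_subgraph(graph, 25)
print(round(graph_metrics(graph).density, 3))  # 0.14
```

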