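# Methods

## Decision procedure

The pipeline turns docking scores, descriptor tables and PPI edges into a
ranked candidate report in six stages:

1. **Descriptor screen.** A compound is retained iff its descriptor vector
   is complete, it passes at least one of five drug-likeness rule sets, and
   it carries at most one PAINS alert. The rule constants (pinned in
   `src/netpharm/data/druglikeness_rules.yaml`, all bounds inclusive) are:
   Lipinski with at most one violation of {MW ≤ 500, consensus log P ≤ 5,
   HBD ≤ 5, HBA ≤ 10}; Ghose 160 ≤ MW ≤ 480, −0.4 ≤ WLOGP ≤ 5.6,
   40 ≤ MR ≤ 130, 20 ≤ heavy atoms ≤ 70; Veber RotB ≤ 10 and TPSA ≤ 140;
   Egan WLOGP ≤ 5.88 and TPSA ≤ 131.6; Muegge 200 ≤ MW ≤ 600,
   −2 ≤ XLOGP ≤ 5, TPSA ≤ 150, rings ≤ 7, C > 4, heteroatoms > 1,
   RotB ≤ 15, HBA ≤ 10, HBD ≤ 5. Consensus log P feeds the Lipinski
   lipophilicity bound since it is the log P the rest of the pipeline
   reasons about. Each excluded compound is logged with exactly one primary
   reason, checked in the order missing → druglikeness → pains.
2. **Per-target thresholds.** For each target, binder and decoy mean
   docking scores define a ROC curve. Candidate thresholds are midpoints
   between consecutive distinct pooled scores plus finite sentinels one
   unit below the minimum and above the maximum (finite rather than ±∞ so
   emitted threshold tables stay numeric; the curve itself is unchanged).
   Orientation is fixed a priori — binder iff score < threshold — because
   docking affinities are lower-is-better by construction and automatic
   orientation detection can silently flip on degenerate samples. The
   default cutoff criterion is Youden's J, with best accuracy selectable;
   J-ties resolve toward the most negative (most stringent) threshold.
3. **Classification.** An interaction is a probable binder iff its mean
   affinity (arithmetic mean of exactly the docking trials provided,
   typically two) is strictly below its target's threshold; a mean exactly
   at the threshold is a probable nonbinder ("below" read strictly).
   Targets without thresholds leave their interactions unclassified.
4. **Ubiquity.** A compound is ubiquitous iff its species-occurrence count
   is ≥ the reference compound's count (quinic acid by convention — a
   shikimate-pathway precursor present in essentially all plants). The
   reference count is always an input, never a constant, since it depends
   on the occurrence-database snapshot. Compounds without counts are
   flagged `unknown` and retained with a warning rather than dropped,
   because occurrence lookups genuinely fail for some natural products.
5. **Network.** Probable-binder edges are merged with PPI edges into one
   undirected, unweighted typed graph; proteins named in the PPI list stay
   in the graph even with zero compound edges, so their degree reflects
   their PPI connectivity. Centralities: degree as incident-edge count;
   shortest-path betweenness with endpoints excluded, normalized by
   (n−1)(n−2)/2; closeness computed within each connected component as
   (reachable − 1)/Σdistances, 0 for isolated nodes (harmonic closeness is
   available but not default, to keep values comparable with the standard
   component-local convention). Dense ranks (ties share a rank; the next
   distinct value increments by one) are computed over protein nodes per
   measure.
6. **Report.** Candidate table A: probable binders of screened compounds
   with high predicted gastrointestinal absorption, grouped by target and
   sorted strongest affinity first. Candidate table B: the non-ubiquitous
   subset of A. Each row also carries a location-compatibility verdict:
   secreted/extracellular targets are reachable at any finite log P, while
   targets behind a membrane additionally require high GI absorption and a
   consensus log P neither above 5 (too lipophilic — likely retained in the
   bilayer) nor below −1 (too hydrophilic to partition into it); the
   optimal permeation window is taken as [−1, 2]. The location → policy
   matrix is config-overridable; unknown location strings error rather
   than guess. Bioavailability scores are binned for display as high
   (> 0.55), moderate [0.17, 0.55], low (< 0.17), the score's published
   tiering. GI filtering alone (not a bioavailability-score cutoff) defines
   table A; the bioavailability tier is reported, not filtered on.

Docking setup support is limited to the two computable pieces: the radius
of gyration (geometric by default; the mass-weighted variant is exposed
because conventions differ and the choice is rarely stated) and the cubic
search-box rule max(22.5 Å, 2.9 R_g). Receptor/ligand preparation and the
docking engine itself (exhaustiveness 16, energy range 4 kcal/mol in the
protocol these boxes feed) are out of scope.

## Synthetic data: what it emulates and what it does not

No docking-score, descriptor, interaction or PPI tables are bundled, so the
`synthetic` module generates all six inputs with the statistical structure
the analysis assumes:

- **Scores.** Gaussian binder and decoy populations (per-ligand population
  value + independent per-trial noise, recorded score = trial mean).
  Defaults: 25 ligands per class (design floor 20), μ_binder = −8.5,
  μ_decoy = −6.5, σ = 1, trial noise SD 0.25, two trials — a standardized
  separation d = −2.0, mid-range for a well-behaved decoy-controlled
  screen (reported screens span roughly −0.8 to −3.7). Real docking-score
  sets are typically non-normal; a shifted-lognormal family with matched
  mean/SD (fixed shape 0.75) is provided for skew-sensitive tests, but the
  Gaussian default is a modeling choice made for its closed-form recovery
  targets (threshold at the density crossing (μ_b+μ_d)/2, AUC =
  Φ(|μ_b−μ_d|/(σ√2))), not an empirical claim.
- **Cohort.** 150 compounds × 9 targets; each pair enters the interaction
  table with probability 0.13 (≈ 170 interactions, the scale of a
  single-plant screen) and is latently a binder with probability 0.3; the
  latent label is retained so threshold-recovery accuracy can be measured.
  PPI edges are Erdős–Rényi with p = 0.5 over the targets.
- **Descriptors.** Drawn from drug-like ranges, with disjoint engineered
  subsets that fail all five rule sets (25%), carry ≥ 2 PAINS alerts (5%),
  or have missing descriptors (12%) — together ≈ 42% excluded, the
  attrition a real single-plant screen shows. A non-engineered compound
  that by rare chance fails all five rules is nudged into the Egan window
  so the engineered fractions are exact. The GI-absorption class is
  assigned by a crude TPSA/WLOGP permeation rule; it stands in for a real
  absorption model's output, and no claim is made that its boundary matches
  one.
- **Ubiquity.** Occurrence counts are geometric on {1, 2, …} with success
  probability 0.2 (mean 5 species, heavy right tail, mimicking
  natural-product occurrence databases); the reference compound is inserted
  exactly once at 6 occurrences, which makes roughly a third of compounds
  ubiquitous so the filter is exercised in both directions.

Determinism: one global seed fans out to per-table child generators keyed
by CRC32 of a table tag, so any table regenerates independently and the
same seed reproduces every table bit for bit.

Passing tests on these synthetics show the decision procedure is correct
and deterministic under its own assumptions; they do not validate docking
accuracy, descriptor prediction, PPI completeness, or how well Gaussian
populations approximate any particular target's empirical score
distribution.

## Numerical choices

- AUC is accumulated in integer arithmetic (2·AUC·n₁n₂ as a sum of
  integer trapezoids) and agrees with the brute-force pair statistic to
  machine exactness; the two implementations are kept independent and
  cross-checked on random instances with and without ties.
- Threshold-objective ties within 1e−12 are treated as exact ties and
  resolve to the most negative candidate.
- Mann-Whitney uses the exact null distribution when n₁n₂ ≤ 400 with no
  ties, and the normal approximation with tie correction otherwise.
- Cohen's d uses sample variances (ddof = 1) in the pooled SD; zero pooled
  SD raises rather than returning ±∞.
- EF uses a ceiling top-set size; ties at the cut resolve by stable sort on
  (score, ligand id).
- Fewer than 2 scores in either class is an error for ROC analysis; fewer
  than 20 (the screen-design floor) warns but proceeds.

## Design choices where the design was open

- **Youden vs best accuracy.** Both appear in practice as "the optimal
  threshold". Youden's J is the default because it is prevalence-free;
  best accuracy is selectable per run and the two are compared in tests on
  a constructed unbalanced case where they disagree.
- **Whether protein degree counts PPI edges.** Yes: a protein with zero
  compound edges keeps its PPI degree, which is the only reading consistent
  with hub tables that list PPI-only proteins with nonzero degree.
- **Output directory naming.** Artifacts go into a caller-named directory
  and contain no timestamps, trading a conventional timestamped-run layout
  for byte-identical reruns of the same config + seed.
- **Interaction-count discrepancy.** Published summaries of this workflow
  have stated both "52 interactions between 40 phytochemicals" and "46
  interactions between 35 phytochemicals" for the same screen; the
  discrepancy is noted here and nothing in this package encodes either
  count as ground truth.

## Problem sizes

Default study: 9 targets × (25 + 25) ligands, 150 compounds, ≈ 170
sampled interactions. The closed-form recovery experiment uses 10⁴ ligands
per class; the AUC oracle sweep uses 1,000 random score sets of up to 30
per class; the centrality oracle suite uses 200 random graphs of ≤ 12
nodes against an independent Floyd–Warshall path-counting implementation.

## Known limitations

- Descriptors, PAINS alert counts, GI-absorption classes and occurrence
  counts are inputs; the package computes none of them from structures.
- Per-target thresholds assume the binder/decoy sets are representative of
  the score scale on which phytochemicals dock against that target; decoy
  bias propagates directly into the cutoff.
- The threshold is the Youden point of the decoy-controlled ROC, not a
  Bayes-optimal boundary for the (unknown) binder prevalence among real
  phytochemicals, so latent-label recovery on synthetic cohorts is bounded
  away from 100% whenever class overlap and unequal priors coexist.
- Centralities treat the merged graph as undirected and unweighted;
  affinity magnitudes annotate edges but do not weight paths.
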