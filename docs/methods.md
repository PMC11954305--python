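# Methods

This note records what each component computes, the assumptions and
parameter choices behind it, and the known limitations. Everything stated
here is testable against the package's own seeded fixtures.

## 1. Molecules and representations

- Molecules are identified by their **full 27-character InChIKey** after
  RDKit canonicalization. Full-key matching is the conservative choice for
  stock lookups: a stereoisomer of a stocked compound does not count as in
  stock.
- **Fingerprints** are bit-folded Morgan fingerprints. Two parameter sets
  are used deliberately: radius 3 / 2048 bits for scoring and novelty
  (higher resolution for a learned model), radius 2 / 1024 bits for
  clustering (cheaper at library scale). Tanimoto similarity of two empty
  fingerprints is defined as 1.0 — two featureless molecules are treated
  as indistinguishable — and the case is logged when it occurs.
- **Descriptors** (12): molecular weight, Crippen cLogP, HBD/HBA by the
  Lipinski convention (NHOH count / N+O count), TPSA, rotatable bonds,
  aromatic rings, heavy atoms, ring count, fraction Csp3, formal charge
  and assigned stereocenters.

## 2. Reaction system

Templates are retro-SMARTS rules (`product >> precursors`); the forward
direction is obtained by swapping the two sides of the same SMARTS, so
retro and forward are consistent by construction. Each template carries a
prior weight used to rank expansions. Retro application deduplicates
precursor sets by sorted InChIKeys and counts products that fail
sanitization instead of silently dropping them.

Stocks are InChIKey sets. `roundtrip_probe` checks on a probe molecule
that a retro disconnection can be replayed forward to regenerate the
probe; every fixture template family is validated this way at generation
time.

## 3. Retrosynthetic search

### MCTS planner

State is the sorted multiset of unsolved molecule InChIKeys; **depth is
the total number of reaction steps in the partial route** (not tree
levels). The same unit is used by `SearchConfig.max_depth`, the oracle
depth bound and `shortest_route_length`, so the two engines are directly
comparable.

Each iteration runs select → expand → evaluate → backpropagate:

- **Select** descends by UCB1 (exploration constant √2) to an unexpanded
  node.
- **Expand** applies the deterministic expansion policy: applicable
  (template, precursor-set) pairs ranked by template prior, ties broken by
  template id then sorted precursor keys. The policy is a stand-in for a
  learned single-step model and is the plug point for one.
- **Evaluate** scores a leaf as (fraction of leaf molecules in stock) ×
  0.95^depth; the depth discount prefers shorter routes among equally
  stocked states.
- Solved and depth-limited children are marked terminal at creation;
  `fully_explored` propagates upward so exhausted searches stop early.

Defaults (900 s, 1000 iterations, depth 8, expansion width 50) mirror a
production planning setup; the fixture tests use tighter budgets
(500 iterations, depth 4). The search is deterministic for a fixed
config: all tie-breaks are lexicographic and the time limit only binds
between iterations.

**Route validation is always on**: every returned route is forward-replayed
step by step (each reaction must regenerate its product from its
precursors) and all leaves must be in stock. A route that fails validation
is a hard error, not a warning.

### Exhaustive oracle

`bfs_oracle` computes the exact minimum total steps by memoized recursion
over (molecule, remaining budget), allocating the budget sequentially
across AND-branches. It either answers exactly or refuses explicitly
(`feasible=False`) when its node budget (default 200k) is exceeded — it
never returns a wrong answer. It is the arbiter for all fixture
certification.

## 4. Synthesizability score

Labels come from the planner (1 = route found under a given stock and
config; the dataset records the config digest for traceability). Features
are the radius-3/2048 fingerprint concatenated with the 12 descriptors
(2060 columns, float32).

Training pipeline: stratified holdout → seeded random-search
hyperparameter tuning (5-fold CV, mean F1) → final fit on the training
split → held-out evaluation. The search space is learning rate
[0.05, 0.4], max depth [1, 50], gamma [0, 10], 5–250 trees. Random search
was chosen over Bayesian optimization because the budget here is tens of
rounds, not thousands; a BOHB-class tuner can be slotted in behind the
same (train, space, budget, seed) → (params, log) contract.

Conventions: MCC is defined as 0 whenever a confusion-matrix marginal is
zero (degenerate folds stay comparable); retraining with the same seed and
data reproduces identical predictions (single-threaded `hist` XGBoost).

## 5. Library curation

Cleaning keeps the largest organic fragment, neutralizes charges,
enforces an element whitelist (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I)
and a 6–70 heavy-atom window, and deduplicates by InChIKey, with per-reason
rejection counts.

Butina sphere-exclusion clustering: neighbor lists at **distance**
(1 − Tanimoto) ≤ cutoff (default 0.6); the unassigned molecule with the
most unassigned neighbors becomes the next centroid (ties toward the
lowest index), absorbing its unassigned neighbors. Clusters are reported
by descending size. The implementation is checked for exact partition
equality against an independent brute-force reference.

## 6. Activity objective and multi-objective tools

- QSAR: model families (XGBoost, random forest, k-NN) are grid-searched
  with 5-fold CV under both a **scaffold split** (greedy largest-first
  Murcko assignment, 80/20) and a **time split** (records from 2018 onward
  form the test set); the winning family is refit on all data.
- The **complexity heuristic** scores fragment familiarity: mean
  log-relative-frequency of circular fragments in a built-in 40-molecule
  drug-like corpus, minus penalties for size, stereocenters, spiro/bridged
  atoms and macrocycles, plus a symmetry bonus, affinely mapped to
  [1, 10]. It imitates the shape of fragment-frequency synthetic
  accessibility scores; the corpus is deliberately tiny and the absolute
  values are only meaningful for ranking within this package.
- Desirability transforms are logistic with an explicit direction
  (midpoint 4.5, steepness 1.0 by default — chosen for the complexity
  scale, not a universal convention).
- `pareto_front` treats all objectives as maximized and returns the
  non-dominated indices; duplicates of a front point are kept.

## 7. Triage cascade

Five stages, in cost order: (1) strict probability thresholds
p(active) > 0.8 and p(synthesizable) > 0.8; (2) planner route found;
(3) route ≤ 5 steps; (4) rule-of-five, "classic" mode tolerating one
violation; (5) novelty: maximum Tanimoto to known ligands strictly
below 0.7 (radius 3 / 2048). The planner runs **only** for stage-1
survivors and the call count is reported, so route-search economy is
auditable. The shortlist is ranked by p(active) + p(synth), shorter routes
first — a pragmatic ordering, not a potency claim.

## 8. Synthetic fixtures and certification

- **Templates**: eight coupling families (amide, ester, Williamson ether,
  reductive amination, aryl–aryl, sulfonamide, N-alkylation, aryl ether).
  All disconnect acyclic bonds only (`-!@`), so retro application always
  fragments and route depth is well-founded. Priors vary with the seed.
- **Stock**: drawn from a curated pool; every member must match forward
  reactant slots of at least two templates, so each building block is
  combinatorially useful. Aldehydes and sulfonyl chlorides are excluded by
  this rule, leaving their templates as retro-only distractors.
- **Solvable molecules** are built by k forward steps from stock (k
  uniform on 1–3); k upper-bounds the true minimum and the oracle
  certifies `min_steps ≤ k`. A witness route is stored and validated.
- **Unsolvable molecules** carry a CF3 tag: no template detaches it and no
  stock member contains fluorine attached this way, confining it to an
  out-of-stock leaf in every route. Unsolvability is still certified by
  the oracle at depth 4, not assumed.
- **Planted activity**: molecules containing a pyridine ring draw pChEMBL
  from N(7.5, 0.5), others from N(5.0, 0.5); threshold 6.5 recovers the
  rule up to Gaussian tail crossings (< 2%). Label noise flips with
  probability ε; flip masks are drawn from the same uniform stream for
  every ε, so corruptions are nested across noise levels.
- The **triage fixture** engineers 20 candidates whose per-stage fate is
  certified during generation against the package's own oracles
  (planner oracle, rule-of-five, novelty), giving exact expected survivor
  counts 20 → 15 → 12 → 10 → 9 → 8.

## 9. Evaluation design choices

- Planner audits compare against the exhaustive oracle on 210 certified
  targets; agreement is required exactly for solved status and the planner
  may never undercut the oracle minimum (that would mean an invalid
  route).
- Stock-monotonicity checks use nested stocks (smaller ⊂ base ⊂ larger,
  built by dropping members / adding witness intermediates). Mean route
  lengths are compared **paired** — only over molecules solved under both
  stocks — because unpaired means suffer survivor bias.
- Noise-recovery evaluation uses a 20% holdout (100 molecules). With a 10%
  holdout the sampling noise of the realized flip rate (SD ≈ 0.057 at
  ε = 0.2) is comparable to the whole 0.07 tolerance band, so the
  measurement would be dominated by chance rather than model quality.
  Band-edge comparisons use a 1e-9 float tolerance.
- Result tables exclude wall times by default so artifacts are
  byte-reproducible; timings are opt-in.

## 10. Limitations

- The fixture universe is deliberately small and clean: ring-forming
  reactions, protecting groups, selectivity and yield are out of scope, so
  absolute solvability rates say nothing about real syntheses.
- The expansion policy is priors-only; with a learned single-step model
  the planner's search order (not its validity guarantees) would change.
- The complexity heuristic's corpus is 40 molecules; its scores are
  rank-stable within this package but not calibrated to any external
  scale.
- The oracle is exponential in the worst case; its node budget makes
  misuse loud rather than slow, and fixtures are sized to stay well within
  it.
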