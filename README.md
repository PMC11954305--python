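# insynth

A desk-scale toolkit for **building-block-constrained synthesizability** in
early drug discovery. It answers, on certified synthetic fixtures, the
question a chemistry-aware virtual screen keeps asking: *can this molecule
actually be made from the building blocks we have — and is it still worth
making?*

The workflow has four connected parts:

1. **Retrosynthetic planning under a stock constraint.** A Monte-Carlo tree
   search (`insynth.planner.mcts_search`) recursively disconnects a target
   with retro-reaction templates until every leaf is a purchasable building
   block. Routes are always validated by forward replay: each reaction step
   is re-run in the forward direction and must regenerate its product, and
   every leaf must be in stock. An exhaustive AND/OR oracle
   (`bfs_oracle`) returns the *exact* minimum step count on small instances
   and is used to certify every fixture and to audit the search.
2. **A learned synthesizability score.** Planning is expensive, so an
   XGBoost classifier (`insynth.scorer`) is trained on planner-labeled
   molecules (Morgan fingerprints + physchem descriptors) and predicts the
   probability that a route would be found, in milliseconds.
3. **Library curation.** `insynth.curation` cleans raw molecule libraries
   (salt stripping, uncharging, element and size filters), removes
   building-block stock members, and subsets by Butina sphere-exclusion
   clustering so a screening set covers chemical space instead of
   oversampling its dense regions.
4. **Candidate triage.** `insynth.triage` runs a five-stage funnel:
   predicted activity, route found, route short enough, rule-of-five,
   novelty against known ligands. The expensive planner is invoked only
   for molecules that already passed the cheap probability filter.

Because real reaction corpora and vendor stocks are enormous, everything is
exercised on **synthetic reaction universes with certified ground truth**
(`insynth.fixtures`): eight hand-curated coupling templates, a small
building-block stock, molecules *constructed* by forward template
application (solvable by construction, minimum steps certified by the
oracle) and molecules carrying a trifluoromethyl tag that no template can
detach and no stock member contains (certified unsolvable). Activity data
plants a pyridine substructure rule with controllable label noise, so
classifier recovery has an exact reference.

## Worked example

```python
from insynth.fixtures import FixtureSpec, gen_reaction_universe, gen_solvable
from insynth.planner import SearchConfig, bfs_oracle, mcts_search

spec = FixtureSpec(seed=0)
templates, stock, stock_records = gen_reaction_universe(spec)
print(f"{len(templates)} templates, {stock.size} building blocks")

solvable = gen_solvable(spec, templates, stock, stock_records)
target = next(s for s in solvable if s.built_steps == 2)
print("target:", target.record.smiles_canonical)

config = SearchConfig(iteration_limit=500, max_depth=4, seed=0)
result = mcts_search(target.record, stock, templates, config)
oracle = bfs_oracle(target.record, stock, templates, max_depth=4)
print(f"solved={result.solved} route_steps={result.shortest_route_length} "
      f"oracle_min={oracle.min_steps} routes_found={len(result.routes)}")
```

Output:

```text
8 templates, 30 building blocks
target: CC(C)NCCOc1ccc(F)cc1
solved=True route_steps=2 oracle_min=2 routes_found=2
```

The planner finds the two-step route (an aryl ether coupling of
4-bromofluorobenzene with ethanolamine, then N-alkylation with isopropyl
bromide) and its length matches the oracle's exact minimum.

The same flow is available from the command line:

```bash
insynth fixtures --seed 0 --out fixtures/
insynth plan --targets fixtures/solvable.smi --stock fixtures/stock.smi \
    --templates fixtures/templates.csv --seed 0 --out plan.csv
insynth curate --in library.smi --stocks fixtures/stock.smi --out centroids.smi
insynth train-score --molecules molecules.smi --stock fixtures/stock.smi \
    --templates fixtures/templates.csv --out score_model/
insynth triage --candidates candidates.smi --qsar qsar.joblib \
    --score score_model/ --stock fixtures/stock.smi \
    --templates fixtures/templates.csv --known known.smi --out triage/
insynth pipeline --config pipeline.yaml --out run/
```

Every verb is deterministic for a fixed seed and config: rerunning
produces byte-identical artifacts.

## Layout

```text
src/insynth/
  chem.py        molecules, fingerprints, descriptors, I/O
  reactions.py   reaction templates, stocks, retro/forward application
  planner.py     MCTS planner, exhaustive oracle, route validation
  curation.py    cleaning, stock removal, Butina clustering
  scorer.py      planner-labeled XGBoost synthesizability score
  objectives.py  QSAR activity, complexity heuristic, Pareto tools
  triage.py      five-stage candidate funnel and end-to-end pipeline
  fixtures.py    certified synthetic fixture generators
  cli.py         command-line interface (insynth ...)
tests/           unit, property and acceptance tests
scripts/         acceptance.py results script
docs/            methods notes
```
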