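# Methods

## Model layer and conventions

Models are `cobra.Model` objects; `gemble.model` fixes the contracts the
ensemble layer depends on rather than re-deriving constraint-based analysis.

**FBA.** Flux balance analysis solves max *c·v* s.t. *S v = 0*,
*l ≤ v ≤ u*, where *S* is the stoichiometric matrix, *v* the flux vector
(mmol gDW⁻¹ hr⁻¹ by convention) and *c* the objective (typically a biomass
pseudo-reaction with weight 1). Solutions report status
optimal/infeasible/unbounded; fluxes are only reported for optimal status.
FVA reports, per reaction, the flux minimum and maximum over the polytope
with the objective constrained to at least `fraction_of_optimum` × optimum
(default 1.0). Gene deletion clamps to (0, 0) the bounds of every reaction
whose gene rule evaluates false with the deleted gene set to false;
reaction deletion clamps that reaction directly. Bounds are restored
afterwards.

**Exchanges and media.** A reaction is a boundary/exchange reaction iff it
touches exactly one metabolite; uptake is negative flux, secretion
positive. `set_medium` sets the lower bound of each listed exchange to
−(uptake rate) and closes (lower bound 0) every exchange it does not list;
upper bounds are never touched. This "unlisted means absent" semantics is
what the gap-filling conditions rely on. A consequence of the
single-metabolite rule is that biomass/demand sinks count as boundary
reactions; their lower bounds are 0 anyway, so closing them is a no-op.

**Gene rules.** AND/OR expressions over gene ids with parentheses,
keywords case-insensitive, no NOT (it has no standard meaning in
gene-protein-reaction rules). The empty rule evaluates true, so
non-gene-associated reactions (biomass, exchanges, spontaneous reactions)
survive every gene deletion. The evaluator is a small recursive-descent
parser that reports the character position of a syntax error; the test
suite cross-checks it against COBRApy's independent GPR implementation on
randomized expression trees.

**I/O.** SBML is read and written at Level 3 with the flux-balance
constraints (fbc) package. Files whose reactions lack explicit fbc bounds
are rejected rather than patched with solver defaults: a model whose bounds
were guessed is not the model that was published. JSON uses the COBRA JSON
schema (ids, stoichiometry maps, bounds, rules, objective coefficients).

**Numerics.** One tolerance, 1e-6, is used for feasibility, flux-zero
calls and result comparisons throughout — the typical precision of the LP
solvers involved (GLPK here). No result in the package is meaningful below
that resolution.

## The ensemble representation

An `Ensemble` is a base model, a feature list and a member list. The base
model contains every reaction any member uses. A `Feature` is one varying
attribute of one base-model reaction — `lower_bound`, `upper_bound` or
`gene_rule` — with one recorded value per member; a `Member` is nothing but
its id, provenance string, and its column in that state matrix. Metabolite
or gene attributes are not feature-typed in this package; no supported
workflow varies them.

Design choices worth stating:

* **Absence is (0, 0).** A reaction missing from a member is kept in the
  base model and blocked by bounds, so *every* member is reachable by
  attribute assignment alone — the property that makes state switching
  (and therefore ensemble simulation) cheap and exact. Presence/absence of
  a reaction therefore always yields both bound features, even when one of
  them (typically the lower bound of an irreversible reaction, 0 in both
  states) is constant across members.
* **State switching is absolute, not incremental.** `set_member_state`
  writes every feature's value; the result never depends on which member
  was applied before. Both bounds of a reaction are assigned together so a
  transient lower > upper ordering cannot trip the underlying library's
  bound check.
* **Construction.** `build_from_models` unions reactions across sources
  (same id must mean same stoichiometry — a conflict is an error, not a
  merge), records per-member attribute values, and emits features only for
  attributes that vary. Loading from paths is batched: at most
  `batch_size` models are in memory at once, and the result is provably
  independent of batch size and of source order (up to member labels,
  which default to filename stems with numeric suffixes on collision).
* **Binarization.** The member × feature state table has a binarized
  variant for machine learning: a bound state maps to 1 iff nonzero (it
  permits flux in that direction), a gene-rule state to 1 iff the rule is
  non-empty. This is the deterministic, documented rule used by
  `rank_influential_features`; presence/absence features — the common case
  — binarize exactly to presence.

**Archives.** `save_ensemble` writes a zip holding `base.xml` (SBML L3 +
fbc) and `ensemble.json` (schema version 1: id, members with provenance,
features with full state maps). The state storage is exactly
|members| × |features| scalars; no per-member model copy exists anywhere in
the archive, which is where the order-of-magnitude disk savings over
individually serialized members comes from. Zip entries carry fixed (epoch
1980) timestamps and JSON keys are sorted, so equal ensembles produce
byte-identical archives — seeded pipelines are reproducible at the file
level. Version mismatches raise an explicit error rather than a guess.

## Ensemble simulation

`ensemble_fba`, `ensemble_fva` and `ensemble_deletions` lift the
single-model operations to member-indexed DataFrames (FVA with a
(reaction, minimum/maximum) column pair, matching the two-values-per-member
shape the analysis needs). Member selection is `"all"`, an explicit list,
or a fraction f ∈ (0, 1]: ⌈f·N⌉ members sampled without replacement from
the sorted id list with a seeded generator.

Every member is simulated on a **fresh extracted copy** of the base model,
in both the serial and the parallel path. That is marginally more work than
switching states in place, but it makes the central correctness property —
ensemble row m ≡ single-model result on `extract_member(m)` — hold by
construction, and it removes every channel (solver warm starts, member
order, worker count) through which scheduling could leak into results.
Parallel workers receive the base model as a JSON string plus each member's
state triples, never solver state; results are merged by member id. Tables
are therefore byte-identical for any `workers` value. Infeasible members
are flagged in a `status` column with NaN values, not dropped —
distribution analyses need to know the denominator.

## Gap-filling

Each gap-fill step is one LP on the draft with the full universal database
merged in (universal reactions absent from the draft are added; universal
reactions present but blocked are opened to their database bounds; both are
candidates):

1. apply the condition's medium (unlisted exchanges closed);
2. constrain the draft's own objective to ≥ `growth_threshold`;
3. minimize Σ |v_j| over candidate reactions j — linear because the solver
   represents each flux as a difference of two non-negative variables;
4. the solution is every candidate with |flux| > `flux_tolerance`.

This is the continuous flux-sum relaxation, not a MILP reaction-count
minimization: parsimony is measured in flux, and the LP solves in
polynomial time, which is what makes thousands of iterative steps
practical. If the draft already meets the threshold the minimum is 0 and
the returned set is empty. Infeasibility with the full universal set raises
an error naming the condition.

`iterative_gapfill` runs conditions sequentially, permanently inserting
each step's solution (with universal-database bounds) before the next
condition. Additions are monotone, so the final model grows on every
processed condition — asserted, not assumed, in the tests. Because earlier
additions are reusable at zero cost in the minimization, *condition order
matters*; `generate_gapfill_ensemble` exploits exactly that, sampling
⌈`condition_fraction` × #positive⌉ positive conditions per cycle in a
seeded random order, and compressing all unique added-reaction sets into an
ensemble (one member per unique set, provenance recording the first cycle
and condition order that produced it). No-growth conditions are carried in
phenotype tables for bookkeeping but are never gap-filled on. A single
generator seeded once drives subsampling and ordering, so one seed
reproduces an entire run bit-for-bit, archive included.

Defaults: `growth_threshold` 0.05 flux units — small enough to demand only
"some" growth, large enough to sit three orders of magnitude above solver
tolerance; `flux_tolerance` 1e-6 for membership in a solution. Both are
user-settable and both materially define what a "solution" is, so they are
stated here rather than buried.

## Statistics and curation

**Paired comparison.** Two member-indexed result columns are paired by
member id (unpaired members dropped with a count; fewer than 3 pairs is an
error). `paired_t` and `wilcoxon_signed_rank` delegate to scipy. An
all-zero difference vector — identical distributions — returns p = 1 with a
degenerate flag instead of the undefined statistic, so pipelines comparing
a condition against itself do not crash. Effect size is the mean paired
difference. No multiple-testing correction is applied by default when many
columns are compared; a Benjamini–Hochberg helper is provided.

**Feature ranking.** A regressor predicts the outcome column from the
binarized states; any object with `fit(X, y)` and `feature_importances_`
satisfies the contract, the default being a 200-tree random forest with
out-of-bag scoring as the model-quality estimate. Ranking is by importance
descending with id-order tie-breaks, so fixed seed ⇒ identical ranking. A
constant outcome yields all-zero importances with a `no_signal` flag. The
curation report joins the top-k features to their base-model reactions and
state frequencies, optionally attaching a mean/sd/quantile summary of the
outcome distribution; it deliberately does not modify the ensemble — the
decision to disable a feature everywhere
(`set_feature_across_members`) belongs to the human reading the report.

## Synthetic fixtures: what they emulate, and what they do not

The generators produce, deterministically per seed: linear-chain toy
models whose FBA optimum equals the summed uptake bounds (hand-checkable);
degraded draft/universal pairs whose ground-truth repair is recorded and
whose decoy reactions produce dead-end metabolites (steady state forces
zero flux through them, so they are provably never part of a minimal
solution); phenotype tables computed by simulating the complete model; a
two-pathway gap-fill instance whose two condition orders provably yield two
different reaction sets via a 2× stoichiometric coefficient that makes the
shared-pathway route cheaper only after its shared leg is already paid for
(the cost accounting is spelled out in the generator's docstring, with no
ties at any step); and a 100-member ensemble with one causal feature (a
bypass reaction that doubles the biomass optimum) among neutral dead-end
features. Each generator asserts its own ground truth at creation time.

These fixtures exercise every code path at sizes where independent oracles
are exhaustive: FBA against explicit vertex enumeration, gap-filling
against all-subsets enumeration solved with a second, unrelated LP stack
(scipy HiGHS vs. GLPK). What passing them does **not** show: behavior at
genome scale (thousands of reactions, degenerate alternative optima,
solver tolerance pressure), realistic universal databases with namespace
mismatches, or noisy phenotype data with inconsistent growth calls. The
problem sizes in the test suite and acceptance script (20–100-member
ensembles over ~10-reaction networks, universal databases of ≤ 7
candidates) were chosen so that the exhaustive oracles remain exact; the
algorithms themselves carry no small-size assumptions.

## Known limitations

* Features cover reaction bounds and gene rules only; gene-rule features
  are stored and switched correctly but no shipped workflow generates them.
* The gap-filler never uses no-growth conditions to *remove* reactions
  (consistency pruning is out of scope), and flux-sum parsimony can differ
  from reaction-count parsimony when stoichiometric coefficients differ
  wildly.
* Ensembles assume a shared metabolite namespace across sources; no id
  translation is attempted.
* Degenerate alternative FBA optima are resolved by the solver
  deterministically but arbitrarily; only objective values, not individual
  fluxes, should be over-interpreted — FVA exists for the rest.
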