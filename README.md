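# gemble

Compact ensembles of genome-scale metabolic models.

## The problem

Genome-scale metabolic network reconstructions (GENREs) are uncertain:
annotation gaps, ambiguous gene assignments and alternative gap-filling
solutions mean that many network structures are consistent with the same
evidence. Working with a single "best" model hides that uncertainty.
Working with hundreds of explicit model copies is expensive — most of the
network is identical in every copy — and turns every analysis into a
bookkeeping exercise.

`gemble` stores an ensemble of N model variants as **one base model plus an
N × F state matrix**: the base model is the union of every reaction any
variant uses, a *feature* is one attribute of one reaction that varies
across variants (a flux bound or a gene rule; reaction absence is encoded as
bounds (0, 0)), and a *member* is fully specified by its value for every
feature. Any member is reconstituted by attribute assignment alone, so
storage is a single model plus N × F scalars instead of N models, and any
constraint-based method can be lifted to ensemble scale by iterating
members.

It is aimed at people who build and curate metabolic reconstructions —
particularly for poorly characterized organisms, where growth phenotype
data and a universal reaction database are the main evidence and many
alternative gap-filled networks fit the data equally well.

## What it does

* **Single-model layer** (`gemble.model`, on top of
  [COBRApy](https://opencobra.github.io/cobrapy/)): SBML (Level 3 + fbc)
  and JSON I/O, medium handling with explicit semantics (listed exchanges
  opened to the uptake rate, unlisted exchanges closed), gene-rule
  evaluation, FBA, FVA, single gene/reaction deletions. FBA is the linear
  program max *c·v* subject to *S v = 0*, *l ≤ v ≤ u*.
* **Ensemble layer** (`gemble.ensemble`, `gemble.simulate`): build an
  ensemble from model collections (batched file loading), switch the base
  model into any member's state, extract standalone members, run ensemble
  FBA/FVA/deletions over all members, an explicit subset, or a seeded random
  fraction; results are member-indexed DataFrames, identical for any worker
  count. Archives (`save_ensemble`/`load_ensemble`) hold one SBML file plus
  one JSON state document.
* **Ensemble generation by iterative gap-filling** (`gemble.gapfill`):
  given a draft model, a universal reaction database and binary
  growth/no-growth calls on defined media, each step solves an LP — biomass
  constrained above a growth threshold, summed absolute flux through
  universal reactions minimized — and adds the flux-carrying universal
  reactions to the draft. Conditions are processed sequentially in shuffled
  (optionally subsampled) order over many cycles; because earlier additions
  are reusable at zero cost, the order shapes the outcome, and all unique
  resulting networks form the ensemble.
* **Statistics and ML-guided curation** (`gemble.stats`): paired t-test /
  Wilcoxon signed-rank between two member-indexed result columns, and a
  random-forest regressor that predicts a simulated outcome (e.g. biomass
  flux) from each member's binary feature states — its feature importances
  rank which uncertain network components drive prediction uncertainty, and
  a curation report hands the top candidates to the human curator.
* **Synthetic fixtures** (`gemble.fixtures`): deterministic toy networks,
  degraded draft/universal pairs with decoy reactions, phenotype tables,
  and ensembles with a planted causal feature — everything needed to test
  or demo the package without downloads.

## Worked example

```python
from gemble import build_from_models, ensemble_fba, rank_influential_features
from gemble.fixtures import FixtureSpec, make_synthetic_ensemble

# a 100-member ensemble over a toy network with one planted causal feature
ensemble, causal = make_synthetic_ensemble(FixtureSpec(seed=3))
print(ensemble)

biomass = ensemble_fba(ensemble)["BIOMASS"]
print(biomass.value_counts().to_dict())

states = ensemble.feature_state_table(binarize=True)
influence = rank_influential_features(states, biomass, seed=0)
print(influence.ranking[0])

ensemble.set_feature_across_members(causal, 0.0)   # curation edit
print(ensemble_fba(ensemble)["BIOMASS"].mean())
```

prints

```
<Ensemble synthetic_ensemble: 100 members, 12 features>
{10.0: 50, 5.0: 50}
('BYPASS__upper_bound', 1.0)
5.0
```

The biomass distribution is bimodal (10 with the bypass reaction, 5
without), the regressor attributes all of that variance to the bypass
feature (importance 1.0), and blocking the bypass in every member collapses
the mean predicted biomass flux from 7.5 to 5.0 — the ensemble analog of a
curation step that removes a reaction the organism is found not to have.

The command line mirrors the library:

```bash
gemble fixtures --make toy --seed 0 --out fixtures/
gemble gapfill --draft draft.xml --universal universal.xml \
    --phenotypes pheno.csv --cycles 20 --seed 1 --out E.zip
gemble simulate --archive E.zip --method fba --members all --out fba.csv
gemble compare --a fbaA.csv --b fbaB.csv --column BIOMASS --test wilcoxon
gemble rank-features --archive E.zip --results fba.csv --column BIOMASS --top 10
```

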