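"""Statistics over ensemble results and machine-learning-guided curation.

Ensemble simulations replace single values with distributions over members.
This module provides the two analysis steps that close the loop:

* paired comparison of two member-indexed result columns (paired t-test or
  Wilcoxon signed-rank), pairing by member id;
* attribution of simulation variance to network structure — a regressor
  (random forest by default) predicts a simulated outcome, e.g. biomass
  flux, from the binarized feature states of each member; its feature
  importances rank which uncertain network components drive the outcome,
  and a curation report hands the top candidates to the human curator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.ensemble import RandomForestRegressor

from .ensemble import Ensemble

PAIRED_TESTS = ("paired_t", "wilcoxon_signed_rank")


@dataclass
class ComparisonResult:
    """Outcome of a paired test between two member-indexed columns."""

    test_name: str
    statistic: float
    p_value: float
    n_pairs: int
    effect_estimate: float  # mean of (a - b) over paired members
    degenerate: bool = False
    n_dropped: int = 0


@dataclass
class FeatureInfluence:
    """Importance ranking of ensemble features for a simulated outcome."""

    ranking: List[Tuple[str, float]]
    model_quality: float
    seed: int
    no_signal: bool = False


def compare_member_distributions(
    a: pd.Series,
    b: pd.Series,
    test: str = "paired_t",
) -> ComparisonResult:
    """Paired test of two result columns, paired by member id.

    Members present in only one column are dropped (counted in
    ``n_dropped``); fewer than 3 common members is an error.  If every
    paired difference is exactly zero the result is flagged degenerate with
    p = 1 instead of failing.
    """
    if test not in PAIRED_TESTS:
        raise ValueError(f"test must be one of {PAIRED_TESTS}, got {test!r}")
    common = a.index.intersection(b.index)
    n_dropped = (len(a) - len(common)) + (len(b) - len(common))
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 common members, found {len(common)}"
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} unpaired member entries dropped from comparison",
            stacklevel=2,
        )
    paired_a = a.loc[common].astype(float)
    paired_b = b.loc[common].astype(float)
    diffs = paired_a - paired_b
    effect = float(diffs.mean())
    if (diffs == 0).all():
        return ComparisonResult(
            test_name=test,
            statistic=0.0,
            p_value=1.0,
            n_pairs=len(common),
            effect_estimate=effect,
            degenerate=True,
            n_dropped=n_dropped,
        )
    if test == "paired_t":
        statistic, p_value = scipy_stats.ttest_rel(paired_a, paired_b)
    else:
        statistic, p_value = scipy_stats.wilcoxon(paired_a, paired_b)
    return ComparisonResult(
        test_name=test,
        statistic=float(statistic),
        p_value=float(p_value),
        n_pairs=len(common),
        effect_estimate=effect,
        n_dropped=n_dropped,
    )


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional, not applied by default)."""
    p = p_values.astype(float)
    order = np.argsort(p.values)
    n = len(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = n - rank_from_last
        running = min(running, p.values[idx] * n / rank)
        adjusted[idx] = running
    return pd.Series(adjusted, index=p.index)


def rank_influential_features(
    states: pd.DataFrame,
    outcome: pd.Series,
    regressor=None,
    seed: int = 0,
) -> FeatureInfluence:
    """Rank features by how much they explain a simulated outcome.

    ``states`` is the binarized member x feature table, ``outcome`` a
    member-indexed result column (e.g. biomass flux from ensemble FBA).
    Any regressor exposing ``fit(X, y)`` and ``feature_importances_`` is
    accepted; the default is a random forest.  A constant outcome carries
    no signal and yields all-zero importances with ``no_signal`` set.
    """
    if states.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    if not states.index.equals(outcome.index):
        if set(states.index) != set(outcome.index):
            raise ValueError("states rows and outcome members are misaligned")
        outcome = outcome.loc[states.index]
    if len(states) < 10:
        raise ValueError("need at least 10 members to fit a regressor")
    y = outcome.astype(float).values
    if np.allclose(y, y[0]):
        return FeatureInfluence(
            ranking=[(fid, 0.0) for fid in states.columns],
            model_quality=0.0,
            seed=seed,
            no_signal=True,
        )
    if regressor is None:
        regressor = RandomForestRegressor(
            n_estimators=200, random_state=seed, oob_score=True
        )
    regressor.fit(states.values, y)
    importances = np.asarray(regressor.feature_importances_, dtype=float)
    quality = float(getattr(regressor, "oob_score_", regressor.score(states.values, y)))
    # sort by importance descending, ties broken by feature id for determinism
    order = sorted(
        zip(states.columns, importances), key=lambda item: (-item[1], item[0])
    )
    return FeatureInfluence(
        ranking=[(fid, float(imp)) for fid, imp in order],
        model_quality=quality,
        seed=seed,
    )


def curation_report(
    ensemble: Ensemble,
    influence: FeatureInfluence,
    top_k: int = 10,
    outcome: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Hand-off table for human curation of the most influential features.

    One row per top-ranked feature: the base-model reaction it varies, the
    varied attribute, the frequency of each state across members, and the
    importance score.  When an ``outcome`` column is given, its distribution
    summary (mean/std/quantiles) is attached as ``.attrs['outcome_summary']``.
    The ensemble is not modified — acting on the report (e.g. blocking a
    reaction in all members) is a separate, deliberate edit.
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    if top_k > len(influence.ranking):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(influence.ranking)} ranked "
            "features; truncating",
            stacklevel=2,
        )
        top_k = len(influence.ranking)
    rows = []
    n_members = len(ensemble.members)
    for fid, importance in influence.ranking[:top_k]:
        feature = ensemble.features[fid]
        reaction = ensemble.base_model.reactions.get_by_id(feature.component_id)
        counts = pd.Series(list(feature.states.values())).value_counts()
        frequencies = "; ".join(
            f"{value}: {count / n_members:.2f}" for value, count in counts.items()
        )
        rows.append(
            {
                "feature": fid,
                "reaction": feature.component_id,
                "reaction_name": reaction.name or "",
                "attribute": feature.attribute,
                "importance": importance,
                "state_frequencies": frequencies,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "reaction",
            "reaction_name",
            "attribute",
            "importance",
            "state_frequencies",
        ],
    )
    if outcome is not None:
        values = outcome.astype(float)
        report.attrs["outcome_summary"] = {
            "mean": float(values.mean()),
            "std": float(values.std()),
            "q05": float(values.quantile(0.05)),
            "q50": float(values.quantile(0.50)),
            "q95": float(values.quantile(0.95)),
        }
    report.attrs["model_quality"] = influence.model_quality
    return report
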