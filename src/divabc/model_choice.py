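"""Bayes-factor model comparison and its power/robustness diagnostics.

Candidate divergence models are compared through the marginal density of
the observed statistics under each model's GLM fit (the retained-average
Gaussian likelihood).  Retention uses PLS-space distances per model, but
the GLM for model comparison is fitted on *untransformed* statistics with
highly correlated columns removed, so that every model is scored in the
same statistic space.  Bayes factors are ratios of marginal densities and
posterior probabilities assume equal model priors.

The headline procedure is hierarchical: models compete first within their
migration scenario, then the scenario winners compete against each other.
A flat comparison of all admissible models and an alternative nesting (by
population-size dynamics instead of migration scenario) are provided as
robustness checks, as is a rerun under alternative prior ranges.  Power is
measured by feeding pseudo-observed datasets of known origin through the
full choice procedure and counting correct predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .abc_glm import (
    GLMFit,
    PLSModel,
    ReferenceTable,
    fit_glm,
    fit_pls,
    log_marginal_density,
    model_fit_pvalue,
    retain,
)
from .demographic_models import (
    MODELS,
    Prior,
    ScalingConvention,
    build_model,
    draw_model_parameters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelChoiceResult",
    "HierarchicalChoiceResult",
    "PowerReport",
    "exclude_correlated_stats",
    "posterior_probabilities",
    "ModelEvidence",
    "evaluate_model",
    "compare_models",
    "hierarchical_choice",
    "nest_by_scenario",
    "nest_by_size_dynamics",
    "power_analysis",
    "prior_sensitivity",
]


def exclude_correlated_stats(
    table: ReferenceTable, threshold: float = 0.95
) -> List[str]:
    """Statistic subset after greedy removal of highly correlated pairs.

    Walks the statistic manifest in order and keeps a statistic only if its
    absolute Pearson correlation with every already-kept statistic is at
    most ``threshold`` on the reference table; deterministic by
    construction (the earlier statistic in the manifest wins).
    """
    stats = table.stats()
    if stats.shape[1] < 2:
        raise ValueError("need at least two statistics")
    corr = np.corrcoef(stats, rowvar=False)
    kept: List[int] = []
    for j in range(stats.shape[1]):
        if all(abs(corr[j, i]) <= threshold for i in kept):
            kept.append(j)
    return [table.stat_names[j] for j in kept]


def posterior_probabilities(log_marginals: Dict[str, float]) -> Dict[str, float]:
    """Posterior model probabilities under equal model priors."""
    names = list(log_marginals)
    lm = np.array([log_marginals[n] for n in names], dtype=float)
    lm -= lm.max()
    w = np.exp(lm)
    w /= w.sum()
    return dict(zip(names, w))


@dataclass
class ModelEvidence:
    """Evidence and fit diagnostics of one model for one observation."""

    model: str
    log_marginal: float
    pvalue: float
    retention_count: int
    glm: GLMFit = field(repr=False, default=None)


@dataclass
class ModelChoiceResult:
    """A Bayes-factor comparison between candidate models."""

    log_marginals: Dict[str, float]
    posterior_probs: Dict[str, float]
    bayes_factors: pd.DataFrame
    pvalues: Dict[str, float]
    excluded_stats: List[str]
    chosen: str


@dataclass
class HierarchicalChoiceResult:
    """Two-stage (within-group, then across-group) model choice."""

    stage_one: Dict[str, ModelChoiceResult]
    stage_winners: Dict[str, str]
    stage_two: ModelChoiceResult
    chosen: str


@dataclass
class PowerReport:
    """Confusion matrix of the model-choice procedure on known-truth data."""

    confusion: pd.DataFrame
    power: Dict[str, float]
    n_pseudo: int


class _ModelContext:
    """Per-model precomputation reused across observations."""

    def __init__(
        self,
        table: ReferenceTable,
        model: str,
        stat_subset: Sequence[str],
        n_components: int,
    ):
        self.model = model
        self.table = table.subset(model)
        self.theta, self.param_names = self.table.params_estimation(model)
        stats_full = self.table.stats()
        self.pls = fit_pls(
            stats_full,
            self.theta,
            n_components=n_components,
            stat_names=self.table.stat_names,
        )
        self.transformed = self.pls.transform(stats_full)
        self.stat_subset = list(stat_subset)
        self.stats_subset = self.table.stats(self.stat_subset)
        self.seeds = self.table.seeds

    def evidence(
        self, observed_full: np.ndarray, observed_subset: np.ndarray, count: int
    ) -> ModelEvidence:
        ret = retain(
            self.transformed,
            self.pls.transform(observed_full).ravel(),
            self.seeds,
            count=count,
        )
        theta_r = self.theta[ret.indices]
        stats_r = self.stats_subset[ret.indices]
        glm = fit_glm(theta_r, stats_r)
        return ModelEvidence(
            model=self.model,
            log_marginal=log_marginal_density(glm, theta_r, observed_subset),
            pvalue=model_fit_pvalue(glm, theta_r, stats_r, observed_subset),
            retention_count=count,
            glm=glm,
        )


def _observed_arrays(
    observed, table: ReferenceTable, stat_subset: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    if hasattr(observed, "values") and hasattr(observed, "names"):
        full = np.asarray(observed.values, dtype=float)
        names = list(observed.names)
    else:
        full = np.asarray(observed, dtype=float).ravel()
        names = table.stat_names
    if list(names) != list(table.stat_names):
        raise ValueError("observed statistic manifest does not match the table")
    idx = [names.index(s) for s in stat_subset]
    return full, full[idx]


def evaluate_model(
    table: ReferenceTable,
    model: str,
    observed,
    stat_subset: Optional[Sequence[str]] = None,
    count: int = 500,
    n_components: int = 7,
) -> ModelEvidence:
    """Retention + GLM evidence of a single model for one observation."""
    subset = list(stat_subset or table.stat_names)
    ctx = _ModelContext(table, model, subset, n_components)
    full, sub = _observed_arrays(observed, table, subset)
    return ctx.evidence(full, sub, count)


def compare_models(
    table: ReferenceTable,
    observed,
    models: Optional[Sequence[str]] = None,
    stat_subset: Optional[Sequence[str]] = None,
    count: int = 500,
    n_components: int = 7,
    correlation_threshold: float = 0.95,
    contexts: Optional[Dict[str, _ModelContext]] = None,
) -> ModelChoiceResult:
    """Bayes-factor comparison of several models against one observation.

    All models are scored with the same retention count and in the same
    (decorrelated, untransformed) statistic space, so their marginal
    densities are directly comparable.
    """
    models = list(models or table.models)
    if stat_subset is None:
        stat_subset = exclude_correlated_stats(table, correlation_threshold)
    excluded = [s for s in table.stat_names if s not in stat_subset]
    full = None
    log_marginals: Dict[str, float] = {}
    pvalues: Dict[str, float] = {}
    for model in models:
        ctx = (contexts or {}).get(model)
        if ctx is None:
            ctx = _ModelContext(table, model, stat_subset, n_components)
            if contexts is not None:
                contexts[model] = ctx
        full, sub = _observed_arrays(observed, table, stat_subset)
        ev = ctx.evidence(full, sub, count)
        log_marginals[model] = ev.log_marginal
        pvalues[model] = ev.pvalue
    pp = posterior_probabilities(log_marginals)
    bf = pd.DataFrame(
        [
            [math.exp(log_marginals[a] - log_marginals[b]) for b in models]
            for a in models
        ],
        index=models,
        columns=models,
    )
    chosen = max(pp, key=pp.get)
    return ModelChoiceResult(
        log_marginals=log_marginals,
        posterior_probs=pp,
        bayes_factors=bf,
        pvalues=pvalues,
        excluded_stats=excluded,
        chosen=chosen,
    )


def nest_by_scenario(models: Sequence[str]) -> Dict[str, List[str]]:
    """Group model names by their migration scenario."""
    groups: Dict[str, List[str]] = {}
    for m in models:
        groups.setdefault(MODELS[m].scenario, []).append(m)
    return groups


def nest_by_size_dynamics(models: Sequence[str]) -> Dict[str, List[str]]:
    """Alternative nesting: group by population-size dynamics instead."""
    groups: Dict[str, List[str]] = {}
    for m in models:
        groups.setdefault(MODELS[m].size_mode, []).append(m)
    return groups


def hierarchical_choice(
    table: ReferenceTable,
    observed,
    scenario_map: Optional[Dict[str, Sequence[str]]] = None,
    stat_subset: Optional[Sequence[str]] = None,
    count: int = 500,
    n_components: int = 7,
    admissibility_floor: float = 0.01,
) -> HierarchicalChoiceResult:
    """Two-stage model choice: within groups, then across group winners.

    A model is admissible when its model-fit P-value is at least
    ``admissibility_floor`` (the observation lies within the cloud of its
    retained simulations).  Groups in which no model is admissible are
    dropped with a log message; it is an error if none survives anywhere.
    """
    if scenario_map is None:
        scenario_map = nest_by_scenario(table.models)
    if stat_subset is None:
        stat_subset = exclude_correlated_stats(table)
    contexts: Dict[str, _ModelContext] = {}
    stage_one: Dict[str, ModelChoiceResult] = {}
    winners: Dict[str, str] = {}
    for scenario, models in scenario_map.items():
        result = compare_models(
            table,
            observed,
            models=list(models),
            stat_subset=stat_subset,
            count=count,
            n_components=n_components,
            contexts=contexts,
        )
        admissible = [m for m in models if result.pvalues[m] >= admissibility_floor]
        if not admissible:
            logger.info("no admissible model in scenario %s; dropped", scenario)
            continue
        if set(admissible) != set(models):
            result = compare_models(
                table,
                observed,
                models=admissible,
                stat_subset=stat_subset,
                count=count,
                n_components=n_components,
                contexts=contexts,
            )
        stage_one[scenario] = result
        winners[scenario] = result.chosen
    if not winners:
        raise ValueError("no admissible model in any scenario")
    stage_two = compare_models(
        table,
        observed,
        models=list(winners.values()),
        stat_subset=stat_subset,
        count=count,
        n_components=n_components,
        contexts=contexts,
    )
    return HierarchicalChoiceResult(
        stage_one=stage_one,
        stage_winners=winners,
        stage_two=stage_two,
        chosen=stage_two.chosen,
    )


def power_analysis(
    table: ReferenceTable,
    locus_set,
    n_pseudo: int,
    root_seed: int,
    models: Optional[Sequence[str]] = None,
    stat_subset: Optional[Sequence[str]] = None,
    count: int = 500,
    n_components: int = 7,
    scaling: ScalingConvention = ScalingConvention(),
    min_called: int = 7,
) -> PowerReport:
    """Confusion matrix of Bayes-factor choice on pseudo-observed datasets.

    For each true model, ``n_pseudo`` datasets are simulated at fresh prior
    draws, summarised, and assigned to the candidate with the highest
    marginal density; the existing reference table provides the retained
    sets.  Seeded and reproducible row by row.
    """
    from .simulate import simulate_dataset
    from .sumstats import summarize_dataset

    models = list(models or table.models)
    if stat_subset is None:
        stat_subset = exclude_correlated_stats(table)
    contexts = {
        m: _ModelContext(table, m, stat_subset, n_components) for m in models
    }
    counts = pd.DataFrame(0.0, index=models, columns=models)
    for t_idx, true_model in enumerate(models):
        priors = table.priors[true_model]
        for i in range(n_pseudo):
            for attempt in range(10):
                ss = np.random.SeedSequence(
                    root_seed, spawn_key=(t_idx, i, attempt)
                )
                rng = np.random.default_rng(ss)
                try:
                    draw = draw_model_parameters(
                        true_model, rng, scaling, priors=priors
                    )
                    model_obj = build_model(true_model, draw, scaling)
                    dataset = simulate_dataset(
                        model_obj, locus_set, rng, min_called
                    )
                    observed = summarize_dataset(dataset)
                    break
                except ValueError:
                    # e.g. a dataset with no segregating sites; redraw
                    logger.info(
                        "pseudo-observed draw %d of %s failed; redrawing",
                        i,
                        true_model,
                    )
            else:
                raise RuntimeError(
                    f"pseudo-observed draw {i} of {true_model} kept failing"
                )
            full, sub = _observed_arrays(observed, table, stat_subset)
            lm = {
                m: contexts[m].evidence(full, sub, count).log_marginal
                for m in models
            }
            counts.loc[true_model, max(lm, key=lm.get)] += 1
    confusion = counts.div(counts.sum(axis=1), axis=0)
    power = {m: float(confusion.loc[m, m]) for m in models}
    return PowerReport(confusion=confusion, power=power, n_pseudo=n_pseudo)


def prior_sensitivity(
    model: str,
    alternative_priors: Sequence[Sequence[Prior]],
    base_table: ReferenceTable,
    locus_set,
    observed,
    n_sims: int,
    root_seed: int,
    competitors: Optional[Sequence[str]] = None,
    stat_subset: Optional[Sequence[str]] = None,
    count: int = 500,
    n_components: int = 7,
    scaling: ScalingConvention = ScalingConvention(),
) -> List[ModelChoiceResult]:
    """Re-run model choice with alternative prior ranges for one model.

    For each alternative prior set the model's reference table is rebuilt
    from scratch (same simulation budget, fresh sub-seed) while the
    competitors keep their original tables; the winner's stability across
    prior sets is the robustness check.
    """
    from .simulate import simulate_reference_table

    competitors = [m for m in (competitors or base_table.models) if m != model]
    results = []
    for k, priors in enumerate(alternative_priors):
        alt_table = simulate_reference_table(
            model,
            locus_set,
            n_sims,
            root_seed + 1000 * (k + 1),
            scaling=scaling,
            priors_map={model: list(priors)},
        )
        merged_df = pd.concat(
            [alt_table.df]
            + [base_table.subset(m).df for m in competitors],
            ignore_index=True,
        )
        merged = ReferenceTable(
            df=merged_df,
            param_names=base_table.param_names,
            stat_names=base_table.stat_names,
            priors={**{m: base_table.priors[m] for m in competitors},
                    model: list(priors)},
            scaling=scaling,
            locus_set_hash=base_table.locus_set_hash,
            root_seed=root_seed,
        )
        results.append(
            compare_models(
                merged,
                observed,
                models=[model] + competitors,
                stat_subset=stat_subset,
                count=count,
                n_components=n_components,
            )
        )
    return results
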