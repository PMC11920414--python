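"""Simulation-study helpers: one full fit-and-select replicate.

Used by the power/selection consistency studies: simulate a trio
dataset under a configured mechanism, fit the candidate ladder for the
trait, and run the decision algorithm.  Symptom-heterogeneity models
are fitted lazily — only when the domain-heterogeneity model wins the
second gate — mirroring how the procedure is run in practice; the
Bonferroni denominator then resolves by fixed-point over the realized
comparisons.
"""

from __future__ import annotations

import pandas as pd

from .selection import SelectionOutcome, run_selection
from .sem.fit import fit_dwls, fit_ml_continuous
from .sem.model_spec import ModelSpec, base_second_order
from .sem.polychoric import estimate_polychorics
from .structures import FactorStructure
from .synthetic_trios import ROLES, TrioConfig, simulate_dataset
from .trio_models import TrioModelSet, build_trio_model_set


def fit_ladder(
    models: TrioModelSet,
    items: pd.DataFrame,
    exog: pd.DataFrame,
    estimator: str = "ml_continuous",
    mode: str = "conditional",
    lazy_symptom: bool = True,
    alpha: float = 0.05,
    compute_se: bool = False,
) -> tuple[dict, SelectionOutcome]:
    """Fit the candidate ladder for one trait and run selection.

    ``exog`` holds the trait's PGS columns (plus any covariates) keyed
    by family_id alignment with ``items``.  Returns the fit table and
    the selection outcome.
    """
    poly = None
    data = None
    if estimator == "dwls_ordinal":
        poly = estimate_polychorics(items, exog)
    else:
        data = pd.concat(
            [items.reset_index(drop=True), exog.reset_index(drop=True)], axis=1
        )

    def fit_one(spec: ModelSpec):
        if estimator == "dwls_ordinal":
            return fit_dwls(spec, poly)
        return fit_ml_continuous(spec, data, compute_se=compute_se)

    fits = {}
    for model in ("null", "p_mediated", "domain_het"):
        fits[(model, mode)] = fit_one(models.spec(model, mode))
    if not lazy_symptom:
        for (model, md), spec in models.specs.items():
            if md == mode and model.startswith("symptom_het:"):
                fits[(model, md)] = fit_one(spec)
    outcome = run_selection(models, fits, alpha=alpha, mode=mode)
    if lazy_symptom and outcome.favoured == "domain_het":
        for (model, md), spec in models.specs.items():
            if md == mode and model.startswith("symptom_het:"):
                fits[(model, md)] = fit_one(spec)
        outcome = run_selection(models, fits, alpha=alpha, mode=mode)
    return fits, outcome


def selection_replicate(
    trait: str,
    effect_target: str,
    beta_child: float,
    beta_mother: float,
    beta_father: float,
    n_families: int,
    seed: int,
    structure: FactorStructure | None = None,
    estimator: str = "ml_continuous",
    alpha: float = 0.05,
) -> SelectionOutcome:
    """Simulate one dataset and run the full decision algorithm on it."""
    if structure is None:
        structure = FactorStructure()
    cfg = TrioConfig(
        n_families=n_families,
        traits=(trait,),
        beta_child=beta_child,
        beta_mother=beta_mother,
        beta_father=beta_father,
        effect_target=effect_target if effect_target != "null" else "general",
        seed=seed,
        sex_effect=0.0,
        birth_year_effect=0.0,
        covariate_confounding=0.0,
    )
    ordinal = estimator == "dwls_ordinal"
    trios, items = simulate_dataset(cfg, structure, ordinal=ordinal)
    base = base_second_order(structure, exog=())
    models = build_trio_model_set(base, trait, modes=("conditional",))
    cols = [f"{trait}_{r}" for r in ROLES]
    _, outcome = fit_ladder(
        models, items.drop(columns="family_id"), trios[cols],
        estimator=estimator, alpha=alpha,
    )
    return outcome


def expected_class(effect_target: str) -> tuple[str, str | None]:
    """(favoured model class, domain with symptom heterogeneity if any)
    implied by a generating mechanism string."""
    if effect_target == "null":
        return "null", None
    if effect_target == "general":
        return "p_mediated", None
    if effect_target.startswith("item:"):
        return "domain_het", None  # plus a symptom_het verdict in its domain
    return "domain_het", None
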