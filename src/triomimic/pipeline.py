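"""Config-driven end-to-end pipeline.

Stages: simulate -> PGS prep -> base-model fit (second-order vs
symmetric bifactor) -> per-trait trio model family -> Box-style
selection -> FDR adjustment -> shrinkage -> optional power grid.
Every stage writes flat-file outputs (tab-delimited tables, YAML
provenance) under the configured output directory; every random draw
derives from the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pgs_prep import multivariate_pgs, prepare_pgs
from .power import PowerScenario, run_power, summarize_power
from .selection import (
    SelectionOutcome,
    _inference_table,
    adjust_pvalues,
    select_traits,
    shrinkage_table,
)
from .sem.fit import FitResult, fit_dwls, fit_ml_continuous
from .sem.model_spec import base_bifactor, base_second_order
from .sem.polychoric import estimate_polychorics
from .structures import FactorStructure
from .synthetic_trios import (
    ROLES,
    TrioConfig,
    simulate_dataset,
    write_fixtures,
)
from .trio_models import build_trio_model_set

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, fully serializable pipeline configuration."""

    seed: int = 0
    out_dir: str = "triomimic_run"
    n_families: int = 2000
    traits: tuple[str, ...] = ("PGS1", "CONTROL")
    beta_child: dict = field(default_factory=lambda: {"PGS1": 0.04})
    beta_mother: dict = field(default_factory=lambda: {"PGS1": 0.03})
    beta_father: dict = field(default_factory=lambda: {"PGS1": 0.03})
    effect_target: str = "general"
    missing_rate: float = 0.0
    parental_pgs_correlation: float = 0.0
    estimator: str = "ml_continuous"
    covariates: tuple[str, ...] = ("sex", "birth_year", "pc1", "pc2", "pc3", "batch")
    item_covariates: tuple[str, ...] = ()
    structure: dict | None = None
    alpha: float = 0.05
    fdr_q: float = 0.05
    power_mechanisms: tuple[str, ...] = ()
    power_replicates: int = 100
    power_n_families: int = 15_000

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.covariates = tuple(self.covariates)
        self.item_covariates = tuple(self.item_covariates)
        self.power_mechanisms = tuple(self.power_mechanisms)
        if self.estimator not in ("ml_continuous", "dwls_ordinal"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        for c in self.item_covariates:
            if c not in ("sex", "birth_year"):
                raise ValueError("item covariates limited to sex, birth_year")

    def factor_structure(self) -> FactorStructure:
        if self.structure is None:
            return FactorStructure()
        return FactorStructure.from_dict(self.structure)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("traits", "covariates", "item_covariates", "power_mechanisms"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _fit(spec, estimator, data=None, poly=None) -> FitResult:
    if estimator == "dwls_ordinal":
        return fit_dwls(spec, poly)
    return fit_ml_continuous(spec, data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results.

    On stage failure a RuntimeError names the stage; outputs of earlier
    stages are kept on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    structure = config.factor_structure()
    results: dict = {"config": config}

    stage = "simulate"
    try:
        trio_cfg = TrioConfig(
            n_families=config.n_families,
            traits=config.traits,
            beta_child=config.beta_child,
            beta_mother=config.beta_mother,
            beta_father=config.beta_father,
            effect_target=config.effect_target,
            parental_pgs_correlation=config.parental_pgs_correlation,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        ordinal = config.estimator == "dwls_ordinal"
        trios, items = simulate_dataset(trio_cfg, structure, ordinal=ordinal)
        write_fixtures(trios, items, out / "data")
        results["trios"], results["items"] = trios, items

        stage = "prep"
        prepared = prepare_pgs(trios, covariates=config.covariates,
                               traits=list(config.traits))
        if len(config.traits) >= 2:
            prepared, loadings = multivariate_pgs(
                prepared, list(config.traits), name="polygenicP"
            )
            loadings.rename_axis("trait").reset_index().to_csv(
                out / "pc_loadings.tsv", sep="\t", index=False
            )
        results["prepared"] = prepared

        stage = "base_model"
        exog_cov = tuple(config.item_covariates)
        base2 = base_second_order(structure, exog=exog_cov,
                                  covariate_items=exog_cov)
        baseb = base_bifactor(structure, exog=exog_cov,
                              covariate_items=exog_cov)
        if ordinal:
            cov_df = prepared[list(exog_cov)] if exog_cov else None
            poly_base = estimate_polychorics(items, cov_df)
            fit2 = fit_dwls(base2, poly_base)
            fitb = fit_dwls(baseb, poly_base)
        else:
            data_base = items.join(
                prepared.set_index("family_id")[list(exog_cov)], on="family_id"
            ) if exog_cov else items
            fit2 = fit_ml_continuous(base2, data_base)
            fitb = fit_ml_continuous(baseb, data_base)
        # non-nested base-model choice: lower RMSEA, then lower SRMR
        chosen = "second_order" if (fit2.rmsea, fit2.srmr) <= (fitb.rmsea, fitb.srmr) \
            else "bifactor"
        base_report = pd.DataFrame(
            [
                {"model": "second_order", "stat": fit2.stat, "df": fit2.df,
                 "cfi": fit2.cfi, "rmsea": fit2.rmsea, "srmr": fit2.srmr,
                 "chosen": chosen == "second_order"},
                {"model": "bifactor", "stat": fitb.stat, "df": fitb.df,
                 "cfi": fitb.cfi, "rmsea": fitb.rmsea, "srmr": fitb.srmr,
                 "chosen": chosen == "bifactor"},
            ]
        )
        _write(base_report, out / "base_model_comparison.tsv")
        _write(fit2.param_table(), out / "base_model_params.tsv")
        results["base_fits"] = {"second_order": fit2, "bifactor": fitb}
        results["base_choice"] = chosen
        spec_base = base2  # trio ladder is built on the second-order base

        stage = "trio_models"
        trait_runs = []
        all_fits: dict[str, dict] = {}
        for trait in config.traits:
            models = build_trio_model_set(
                spec_base, trait,
                modes=("conditional", "child_only", "parents_only"),
            )
            fits = {}
            pgs_all = [f"{trait}_{r}" for r in ROLES]
            for (model, mode), spec in models.specs.items():
                if mode != "conditional" and model not in (
                    "p_mediated", "domain_het"
                ):
                    continue
                cols = list(exog_cov) + [
                    c for c in pgs_all if c in spec.exog
                ]
                if ordinal:
                    poly = estimate_polychorics(items, prepared[cols])
                    fits[(model, mode)] = fit_dwls(spec, poly)
                else:
                    data = items.join(
                        prepared.set_index("family_id")[cols], on="family_id"
                    )
                    fits[(model, mode)] = fit_ml_continuous(spec, data)
                _write(
                    fits[(model, mode)].param_table(),
                    out / f"params_{trait}_{model.replace(':', '_')}_{mode}.tsv",
                )
            trait_runs.append((models, fits))
            all_fits[trait] = fits
        results["fits"] = all_fits

        stage = "selection"
        outcomes = select_traits(
            [(m, f) for m, f in trait_runs], alpha=config.alpha
        )
        results["outcomes"] = outcomes
        sel_rows = []
        for oc in outcomes:
            for comp in oc.comparisons:
                sel_rows.append({"trait": oc.trait, **comp,
                                 "favoured": oc.favoured})
            if not oc.comparisons:
                sel_rows.append({"trait": oc.trait, "favoured": oc.favoured,
                                 "comparison": "excluded",
                                 "p": np.nan, "stat": np.nan, "df": 0,
                                 "alpha": np.nan, "significant": False})
        _write(pd.DataFrame(sel_rows), out / "selection_report.tsv")
        verdict_rows = [
            {"trait": oc.trait, "domain": d, "verdict": v}
            for oc in outcomes
            for d, v in oc.domain_verdicts.items()
        ]
        _write(pd.DataFrame(verdict_rows,
                            columns=["trait", "domain", "verdict"]),
               out / "symptom_verdicts.tsv")

        stage = "fdr"
        adjusted = adjust_pvalues(outcomes, n_pgs=len(config.traits),
                                  q=config.fdr_q)
        _write(adjusted["child"], out / "inference_child.tsv")
        _write(adjusted["parents"], out / "inference_parents.tsv")
        results["adjusted"] = adjusted

        stage = "shrinkage"
        shrink_tables = []
        for (models, fits), oc in zip(trait_runs, outcomes):
            if oc.favoured in (None, "null"):
                continue
            unc = SelectionOutcome(
                trait=models.trait,
                favoured=oc.favoured,
                inference=_inference_table(models, fits, "child_only"),
            )
            shrink_tables.append(shrinkage_table(oc, unc))
        shrink = (
            pd.concat(shrink_tables, ignore_index=True)
            if shrink_tables
            else pd.DataFrame(columns=["trait", "level", "std_unconditional",
                                       "std_conditional", "shrinkage_pct"])
        )
        _write(shrink, out / "shrinkage.tsv")
        results["shrinkage"] = shrink

        if config.power_mechanisms:
            stage = "power"
            tables = []
            for i, mech in enumerate(config.power_mechanisms):
                sc = PowerScenario(
                    mechanism=mech,
                    n_families=config.power_n_families,
                    n_replicates=config.power_replicates,
                    estimator="ml_continuous",
                    seed=config.seed + 10_000 * (i + 1),
                )
                tables.append(run_power(sc))
            power = summarize_power(tables)
            _write(power, out / "power.tsv")
            results["power"] = power
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return results
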