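"""Monte-Carlo power simulations for the trio MIMIC design.

A scenario fixes the data-generating mechanism (PGS effects on the
general factor, on every specific domain, or mixed: parental effects on
the general factor with the child effect on the specific domains), the
standardized effect sizes (defaults: child 0.04, mother 0.03, father
0.03), the number of families (default 15,000) and the estimator.  Each
replicate simulates a fresh trio dataset, fits the conditional model
matching the mechanism, and tests every PGS path at the nominal level;
power is the proportion of replicates with p below that level.

Replicate r uses seed ``scenario.seed + r``, so the power table is
bit-reproducible for a fixed seed and invariant to the worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .sem.fit import fit_dwls, fit_ml_continuous
from .sem.model_spec import ModelSpec, base_second_order
from .sem.polychoric import estimate_polychorics
from .structures import FactorStructure
from .synthetic_trios import ROLES, TrioConfig, simulate_dataset
from .trio_models import build_domain_het, build_p_mediated

logger = logging.getLogger(__name__)

MECHANISMS = ("general", "specific", "mixed")


@dataclass
class PowerScenario:
    """One cell of the power-simulation design."""

    mechanism: str = "general"
    beta_child: float = 0.04
    beta_mother: float = 0.03
    beta_father: float = 0.03
    n_families: int = 15_000
    n_replicates: int = 200
    alpha: float = 0.05
    estimator: str = "ml_continuous"
    seed: int = 0
    n_jobs: int = 1
    trait: str = "PGS1"
    structure: FactorStructure = field(default_factory=FactorStructure)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.estimator not in ("ml_continuous", "dwls_ordinal"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def _scenario_spec(scenario: PowerScenario) -> ModelSpec:
    """Conditional MIMIC model matching the generating mechanism."""
    trait = scenario.trait
    base = base_second_order(scenario.structure, exog=())
    if scenario.mechanism == "general":
        return build_p_mediated(base, trait)
    if scenario.mechanism == "specific":
        return build_domain_het(base, trait)
    # mixed: parental paths on P, child paths on the specific domains
    cols = [f"{trait}_{r}" for r in ROLES]
    spec = base.with_exog(cols)
    spec = spec.with_free([f"gp[{trait}_mother]", f"gp[{trait}_father]"])
    spec = spec.with_fixed([f"gp[{trait}_child]"], 0.0)
    return spec.with_free(
        [f"gd[{trait}_child,{d}]" for d in scenario.structure.domains]
    )


def _path_rows(scenario: PowerScenario, fit) -> list[dict]:
    """Per-path and per-role joint significance results of one fit."""
    rows = []
    joint: dict[str, list[str]] = {r: [] for r in ROLES}
    for name in fit.params["name"]:
        if name.startswith("gp[") or name.startswith("gd["):
            target = name.split("[")[1].rstrip("]")
            col = target.split(",")[0]
            level = "P" if name.startswith("gp") else target.split(",")[1]
            role = col.rsplit("_", 1)[1]
            joint[role].append(name)
            prow = fit.params.loc[fit.params["name"] == name].iloc[0]
            rows.append(
                {
                    "role": role,
                    "level": level,
                    "param": name,
                    "estimate": float(prow["estimate"]),
                    "std_estimate": float(prow["std_estimate"]),
                    "p": float(prow["pvalue"]),
                }
            )
    for role, names in joint.items():
        if len(names) > 1 and fit.vcov is not None:
            _, _, p = fit.wald_joint(names)
            rows.append(
                {"role": role, "level": "joint", "param": f"joint[{role}]",
                 "estimate": np.nan, "p": p}
            )
        elif len(names) == 1:
            prow = fit.params.loc[fit.params["name"] == names[0]].iloc[0]
            rows.append(
                {"role": role, "level": "joint", "param": f"joint[{role}]",
                 "estimate": float(prow["estimate"]),
                 "std_estimate": float(prow["std_estimate"]),
                 "p": float(prow["pvalue"])}
            )
    return rows


def _one_replicate(scenario: PowerScenario, spec: ModelSpec, r: int):
    cfg = TrioConfig(
        n_families=scenario.n_families,
        traits=(scenario.trait,),
        beta_child=scenario.beta_child,
        beta_mother=scenario.beta_mother,
        beta_father=scenario.beta_father,
        effect_target=scenario.mechanism,
        seed=scenario.seed + r,
        sex_effect=0.0,
        birth_year_effect=0.0,
        covariate_confounding=0.0,
    )
    ordinal = scenario.estimator == "dwls_ordinal"
    trios, items = simulate_dataset(cfg, scenario.structure, ordinal=ordinal)
    cols = [f"{scenario.trait}_{role}" for role in ROLES]
    if ordinal:
        poly = estimate_polychorics(items, trios[cols])
        fit = fit_dwls(spec, poly)
    else:
        data = items.join(trios.set_index("family_id")[cols], on="family_id")
        fit = fit_ml_continuous(spec, data)
    rows = _path_rows(scenario, fit)
    for row in rows:
        row["replicate"] = r
        row["converged"] = fit.converged
    return rows


def run_power(scenario: PowerScenario) -> pd.DataFrame:
    """Empirical power per PGS path under one scenario.

    Returns a table with one row per (role, level): the rejection rate
    at ``scenario.alpha`` among converged replicates, its Monte-Carlo
    standard error sqrt(p(1-p)/R), the mean estimate, and convergence
    bookkeeping.  Power is flagged unreliable when more than 5% of
    replicates fail to converge.
    """
    spec = _scenario_spec(scenario)
    reps = range(scenario.n_replicates)
    if scenario.n_jobs != 1:
        all_rows = Parallel(n_jobs=scenario.n_jobs)(
            delayed(_one_replicate)(scenario, spec, r) for r in reps
        )
    else:
        all_rows = [_one_replicate(scenario, spec, r) for r in reps]
    long = pd.DataFrame([row for rows in all_rows for row in rows])
    n_total = scenario.n_replicates
    conv_reps = long.groupby("replicate")["converged"].all()
    bad = int((~conv_reps).sum())
    if bad / n_total > 0.05:
        logger.warning(
            "%.0f%% of replicates failed to converge; power unreliable",
            100 * bad / n_total,
        )
    ok = long[long["converged"]]
    grp = ok.groupby(["role", "level"], sort=False)
    out = grp.agg(
        n_converged=("p", "size"),
        n_significant=("p", lambda p: int((p < scenario.alpha).sum())),
        mean_estimate=("estimate", "mean"),
        mean_std_estimate=("std_estimate", "mean"),
    ).reset_index()
    out["power"] = out["n_significant"] / out["n_converged"]
    out["mc_se"] = np.sqrt(out["power"] * (1 - out["power"]) / out["n_converged"])
    out["mechanism"] = scenario.mechanism
    out["beta_child"] = scenario.beta_child
    out["beta_mother"] = scenario.beta_mother
    out["beta_father"] = scenario.beta_father
    out["n_families"] = scenario.n_families
    out["alpha"] = scenario.alpha
    out["estimator"] = scenario.estimator
    out["unreliable"] = bad / n_total > 0.05
    return out


def father_beta_grid(
    scenario: PowerScenario, betas=(0.03, 0.01, 0.001)
) -> list[PowerScenario]:
    """The study's father-effect grid, holding the rest fixed."""
    return [replace(scenario, beta_father=b) for b in betas]


def summarize_power(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate scenario tables into one plot-ready long table."""
    if not tables:
        return pd.DataFrame(
            columns=["mechanism", "role", "level", "power", "mc_se",
                     "beta_child", "beta_mother", "beta_father",
                     "n_families", "alpha", "estimator"]
        )
    return pd.concat(tables, ignore_index=True)
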