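"""Model-selection algorithm, multiple-testing scheme, and shrinkage.

For each PGS trait the candidate ladder (null, P-mediated,
domain-heterogeneity, per-domain symptom-heterogeneity) is walked with
chi-square difference tests at a Bonferroni-adjusted level
``alpha / N`` where ``N`` is the realized number of nested comparisons
in the run (recomputed, never hard-coded; because symptom-level
comparisons are only made when the domain-heterogeneity model wins, the
count is resolved by fixed-point iteration, conservatively preferring
the larger ``N`` on a cycle).  Ties at exactly the threshold retain the
more restrictive model.

Inference p-values are then adjusted in two separate
Benjamini-Hochberg families: child direct effects over
``N_PGS x 7`` tests (P + 6 domains), and parental indirect effects over
``N_PGS x 7 x 2`` (mother and father).  The families are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem.fit import FitResult
from .sem.indices import chisq_diff
from .trio_models import TrioModelSet

logger = logging.getLogger(__name__)

_LADDER = ("null", "p_mediated", "domain_het")


@dataclass
class SelectionOutcome:
    """Decision trail and inference table for one PGS trait."""

    trait: str
    favoured: str | None  # null | p_mediated | domain_het | None (excluded)
    domain_verdicts: dict[str, str] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    inference: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha_nested: float = np.nan
    n_comparisons: int = 0
    excluded_reason: str | None = None


def _check_converged(fits, keys) -> str | None:
    for key in keys:
        fit = fits.get(key)
        if fit is None:
            return f"missing fit for {key}"
        if not fit.converged:
            return f"fit for {key} did not converge"
    return None


def _evaluate(
    models: TrioModelSet, fits, alpha_adj: float, mode: str = "conditional"
):
    """One pass of the decision algorithm at a given adjusted level."""
    comparisons: list[dict] = []

    def compare(name, restricted_key, general_key):
        stat, ddf, p = chisq_diff(fits[restricted_key], fits[general_key])
        rec = {
            "comparison": name,
            "stat": stat,
            "df": ddf,
            "p": p,
            "alpha": alpha_adj,
            "significant": bool(p < alpha_adj),
        }
        comparisons.append(rec)
        return rec["significant"]

    sig_pmed = compare("null_vs_p_mediated", ("null", mode), ("p_mediated", mode))
    sig_dhet = compare(
        "p_mediated_vs_domain_het", ("p_mediated", mode), ("domain_het", mode)
    )
    if not sig_pmed:
        return "null", {}, comparisons, 2
    if not sig_dhet:
        return "p_mediated", {}, comparisons, 2

    verdicts: dict[str, str] = {}
    n_sym = 0
    for dom in models.structure.domains:
        key = (f"symptom_het:{dom}", mode)
        if key not in fits:
            continue
        n_sym += 1
        sig = compare(f"domain_het_vs_symptom_het:{dom}", ("domain_het", mode), key)
        verdicts[dom] = "symptom_het" if sig else "domain_het"
    return "domain_het", verdicts, comparisons, 2 + n_sym


def run_selection(
    models: TrioModelSet,
    fits,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    mode: str = "conditional",
) -> SelectionOutcome:
    """Execute the decision algorithm for one trait.

    ``fits`` maps ``(model, mode)`` keys to FitResults; the algorithm is
    a pure function of this table.  With ``n_comparisons=None`` the
    Bonferroni denominator is the realized comparison count for this
    trait alone, resolved by fixed-point iteration.
    """
    reason = _check_converged(fits, [(m, mode) for m in _LADDER])
    if reason:
        logger.warning("trait %s excluded from selection: %s", models.trait, reason)
        return SelectionOutcome(
            trait=models.trait, favoured=None, excluded_reason=reason
        )

    if n_comparisons is not None:
        favoured, verdicts, comparisons, realized = _evaluate(
            models, fits, alpha / n_comparisons, mode
        )
        n_used = n_comparisons
    else:
        n_used = 2
        seen = set()
        while True:
            favoured, verdicts, comparisons, realized = _evaluate(
                models, fits, alpha / n_used, mode
            )
            if realized == n_used:
                break
            if realized in seen:  # cycle: keep the conservative (larger) N
                n_used = max(realized, n_used)
                favoured, verdicts, comparisons, realized = _evaluate(
                    models, fits, alpha / n_used, mode
                )
                break
            seen.add(n_used)
            n_used = realized

    inference = pd.DataFrame()
    if favoured not in (None, "null"):
        inference = _inference_table(models, fits, mode)
    return SelectionOutcome(
        trait=models.trait,
        favoured=favoured,
        domain_verdicts=verdicts,
        comparisons=comparisons,
        inference=inference,
        alpha_nested=alpha / n_used,
        n_comparisons=n_used,
    )


def _inference_table(models: TrioModelSet, fits, mode: str) -> pd.DataFrame:
    """Joint PGS effects over the general and specific domains.

    P paths come from the P-mediated fit; domain paths from the
    domain-heterogeneity fit — the 7 outcomes per family member that
    enter the FDR families.
    """
    rows = []
    pmed = fits[("p_mediated", mode)]
    dhet = fits[("domain_het", mode)]
    roles = {
        "conditional": ("mother", "father", "child"),
        "child_only": ("child",),
        "parents_only": ("mother", "father"),
    }[mode]
    for role in roles:
        col = f"{models.trait}_{role}"
        for fit, level, pname in [(pmed, "P", f"gp[{col}]")] + [
            (dhet, d, f"gd[{col},{d}]") for d in models.structure.domains
        ]:
            prow = fit.params.loc[fit.params["name"] == pname]
            if prow.empty:
                continue
            rows.append(
                {
                    "trait": models.trait,
                    "role": role,
                    "level": level,
                    "param": pname,
                    "estimate": float(prow["estimate"].iloc[0]),
                    "std_estimate": float(prow["std_estimate"].iloc[0]),
                    "se": float(prow["se"].iloc[0]),
                    "pvalue": float(prow["pvalue"].iloc[0]),
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


def select_traits(
    trait_runs: list[tuple[TrioModelSet, dict]],
    alpha: float = 0.05,
) -> list[SelectionOutcome]:
    """Run selection across traits with a shared Bonferroni denominator.

    ``N`` counts the nested comparisons realized across the whole run,
    resolved globally by fixed-point iteration.
    """
    runnable = []
    outcomes: dict[int, SelectionOutcome] = {}
    for idx, (models, fits) in enumerate(trait_runs):
        reason = _check_converged(fits, [(m, "conditional") for m in _LADDER])
        if reason:
            logger.warning("trait %s excluded: %s", models.trait, reason)
            outcomes[idx] = SelectionOutcome(
                trait=models.trait, favoured=None, excluded_reason=reason
            )
        else:
            runnable.append((idx, models, fits))

    n_total = 2 * len(runnable)
    seen = set()
    while runnable:
        realized_total = 0
        results = []
        for idx, models, fits in runnable:
            favoured, verdicts, comparisons, realized = _evaluate(
                models, fits, alpha / n_total
            )
            results.append((idx, models, fits, favoured, verdicts, comparisons))
            realized_total += realized
        if realized_total == n_total or realized_total in seen:
            n_final = max(n_total, realized_total)
            if realized_total != n_total:
                results = [
                    (idx, models, fits)
                    + _evaluate(models, fits, alpha / n_final)[:3]
                    for idx, models, fits in runnable
                ]
            for idx, models, fits, favoured, verdicts, comparisons in results:
                inference = (
                    _inference_table(models, fits, "conditional")
                    if favoured not in (None, "null")
                    else pd.DataFrame()
                )
                outcomes[idx] = SelectionOutcome(
                    trait=models.trait,
                    favoured=favoured,
                    domain_verdicts=verdicts,
                    comparisons=comparisons,
                    inference=inference,
                    alpha_nested=alpha / n_final,
                    n_comparisons=n_final,
                )
            break
        seen.add(n_total)
        n_total = realized_total
    return [outcomes[i] for i in range(len(trait_runs))]


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with an explicit
    family size ``m`` (which may exceed the number of p-values supplied,
    as when the family is defined by design rather than by data)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m smaller than number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = np.maximum(adj, p[order])  # adjusted p never below raw p
    return out


def adjust_pvalues(
    selection_outcomes: list[SelectionOutcome],
    n_pgs: int,
    q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Two separate FDR families over the traits passing the null gate.

    Child direct effects: ``m = n_pgs * 7``; parental indirect effects:
    ``m = n_pgs * 7 * 2``.  Returns dict with keys ``child`` and
    ``parents``; each table carries raw and adjusted p-values and a
    survival flag at level ``q``.
    """
    rows = []
    for out in selection_outcomes:
        if out.favoured in (None, "null") or out.inference.empty:
            continue
        rows.append(out.inference)
    if not rows:
        empty = pd.DataFrame(
            columns=["trait", "role", "level", "param", "estimate",
                     "std_estimate", "se", "pvalue", "mode", "p_fdr", "survives"]
        )
        return {"child": empty.copy(), "parents": empty.copy()}
    table = pd.concat(rows, ignore_index=True)
    n_levels = table["level"].nunique()
    child = table[table["role"] == "child"].copy()
    parents = table[table["role"].isin(["mother", "father"])].copy()
    child["p_fdr"] = bh_adjust(child["pvalue"].to_numpy(), m=n_pgs * n_levels)
    parents["p_fdr"] = bh_adjust(
        parents["pvalue"].to_numpy(), m=n_pgs * n_levels * 2
    )
    child["survives"] = child["p_fdr"] < q
    parents["survives"] = parents["p_fdr"] < q
    return {"child": child, "parents": parents}


# ---------------------------------------------------------------------------
# shrinkage


def shrinkage(unconditional_beta, conditional_beta):
    """Percent attenuation from the unconditional to the conditional
    standardized effect:

        (1 - |conditional| / |unconditional|) * sign(unconditional) * 100

    A zero unconditional beta leaves the quantity undefined (NaN, with a
    warning).  Accepts scalars or arrays.
    """
    u = np.asarray(unconditional_beta, dtype=float)
    c = np.asarray(conditional_beta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 - np.abs(c) / np.abs(u)) * np.sign(u) * 100.0
    bad = u == 0
    if np.any(bad):
        logger.warning("zero unconditional beta: shrinkage undefined, set to NaN")
        out = np.where(bad, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def shrinkage_table(
    cond_outcome: SelectionOutcome, uncond_outcome: SelectionOutcome
) -> pd.DataFrame:
    """Per-level shrinkage of child standardized effects, conditional vs
    child-only (unconditional) models."""
    cond = cond_outcome.inference
    unc = uncond_outcome.inference
    if cond.empty or unc.empty:
        return pd.DataFrame(
            columns=["trait", "level", "std_unconditional", "std_conditional",
                     "shrinkage_pct"]
        )
    c = cond[cond["role"] == "child"].set_index("level")
    u = unc[unc["role"] == "child"].set_index("level")
    levels = [lv for lv in u.index if lv in c.index]
    rows = []
    for lv in levels:
        su = float(u.loc[lv, "std_estimate"])
        sc = float(c.loc[lv, "std_estimate"])
        rows.append(
            {
                "trait": cond_outcome.trait,
                "level": lv,
                "std_unconditional": su,
                "std_conditional": sc,
                "shrinkage_pct": shrinkage(su, sc),
            }
        )
    return pd.DataFrame(rows)
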