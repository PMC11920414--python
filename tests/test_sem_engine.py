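"""SEM engine tests: gradients, recovery, nesting, indices, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from triomimic.sem import (
    base_second_order,
    chisq_diff,
    estimate_polychorics,
    fit_dwls,
    fit_indices,
    fit_ml_continuous,
)
from triomimic.sem.fit import CompiledModel, FitResult
from triomimic.sem.model_spec import ModelSpec, base_bifactor
from triomimic.sem.polychoric import PolychoricSet
from triomimic.structures import FactorStructure
from triomimic.trio_models import (
    build_domain_het,
    build_null,
    build_p_mediated,
    build_symptom_het,
)

from conftest import make_trio_data
from oracles import gaussian_deviance


def _num_grad(fun, theta, h=1e-6):
    g = np.empty_like(theta)
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (fun(tp)[0] - fun(tm)[0]) / (2 * h)
    return g


class TestGradients:
    def test_ml_gradient_matches_numeric(self, small_structure,
                                         capture_objective):
        _, _, _, data = make_trio_data(
            small_structure, n=1200, seed=3, betas=(0.2, 0.15, 0.1),
            effect_target="specific",
        )
        spec = base_second_order(
            small_structure, exog=("T1_mother", "T1_father", "T1_child")
        )
        spec = spec.with_free(
            [f"gd[T1_{r},{d}]" for r in ("mother", "father", "child")
             for d in ("A", "B")] + ["k[T1_child,A1]"]
        )
        fit_ml_continuous(spec, data)
        fun, cm = capture_objective["fun"], capture_objective["cm"]
        rng = np.random.default_rng(0)
        theta = cm.start + 0.05 * rng.standard_normal(cm.n_free)
        theta = np.maximum(theta, cm.lower + 1e-3)
        _, g = fun(theta)
        assert np.allclose(g, _num_grad(fun, theta), atol=1e-6)

    def test_dwls_gradient_matches_numeric(self, small_structure,
                                           capture_objective):
        _, trios, items, _ = make_trio_data(
            small_structure, n=900, seed=4, betas=(0.3, 0.2, 0.1),
            ordinal=True,
        )
        poly = estimate_polychorics(
            items, trios[["T1_mother", "T1_father", "T1_child"]]
        )
        spec = base_second_order(
            small_structure, exog=("T1_mother", "T1_father", "T1_child")
        )
        spec = spec.with_free(
            [f"gp[T1_{r}]" for r in ("mother", "father", "child")]
        )
        fit_dwls(spec, poly)
        fun, cm = capture_objective["fun"], capture_objective["cm"]
        rng = np.random.default_rng(1)
        theta = cm.start + 0.05 * rng.standard_normal(cm.n_free)
        _, g = fun(theta)
        assert np.allclose(g, _num_grad(fun, theta), atol=1e-6)


def test_saturated_single_domain_statistic_zero():
    """A one-factor model on 3 items is just-identified: discrepancy,
    statistic and df all vanish, and the fit indices sit at their
    perfect-fit values."""
    st = FactorStructure(domains=("A",), items_per_domain=(3,))
    _, _, _, data = make_trio_data(st, n=500, seed=5)
    spec = base_second_order(st, exog=())
    spec = spec.with_fixed(["l2[A]"], 1.0)
    fit = fit_ml_continuous(spec, data[list(st.item_names)])
    assert fit.df == 0
    assert fit.stat == pytest.approx(0.0, abs=1e-5)
    cfi, rmsea, srmr = fit_indices(fit)
    assert cfi == pytest.approx(1.0, abs=1e-9)
    assert rmsea == 0.0
    assert srmr < 1e-4


def test_ml_parameter_recovery(small_structure):
    """Estimates recover generating loadings and standardized paths."""
    _, _, _, data = make_trio_data(
        small_structure, n=12_000, seed=11, betas=(0.2, 0.1, 0.1),
    )
    spec = base_second_order(
        small_structure, exog=("T1_mother", "T1_father", "T1_child")
    )
    spec = spec.with_free(
        [f"gp[T1_{r}]" for r in ("mother", "father", "child")]
    )
    fit = fit_ml_continuous(spec, data)
    assert fit.converged
    p = fit.params.set_index("name")
    for item in small_structure.item_names:
        assert p.loc[f"l1[{item}]", "std_estimate"] == pytest.approx(0.6, abs=0.03)
    for dom in small_structure.domains:
        assert p.loc[f"l2[{dom}]", "std_estimate"] == pytest.approx(0.7, abs=0.04)
    q = 0.2**2 + 2 * 0.1**2 + 2 * 0.2 * 0.1 * 0.5 * 2
    assert p.loc["gp[T1_child]", "std_estimate"] == pytest.approx(
        0.2 / np.sqrt(1 + q), abs=3 * p.loc["gp[T1_child]", "se"]
    )


def test_nesting_monotonicity(small_structure):
    """Freeing parameters never increases the ML discrepancy."""
    _, _, _, data = make_trio_data(
        small_structure, n=2000, seed=7, betas=(0.2, 0.1, 0.1),
    )
    base = base_second_order(small_structure, exog=())
    ladder = [
        build_null(base, "T1"),
        build_p_mediated(base, "T1"),
        build_domain_het(base, "T1"),
    ]
    fits = [fit_ml_continuous(s, data, compute_se=False) for s in ladder]
    for restricted, general in zip(fits, fits[1:]):
        assert general.discrepancy <= restricted.discrepancy + 1e-9


def test_chisq_diff_identical_models(small_structure):
    _, _, _, data = make_trio_data(small_structure, n=500, seed=1)
    base = base_second_order(small_structure, exog=())
    fit = fit_ml_continuous(base, data[list(small_structure.item_names)])
    stat, df, p = chisq_diff(fit, fit)
    assert (stat, df, p) == (0.0, 0, 1.0)


def test_chisq_diff_rejects_non_nested(small_structure):
    _, _, _, data = make_trio_data(small_structure, n=400, seed=1)
    items = data[list(small_structure.item_names)]
    base = base_second_order(small_structure, exog=())
    bif = base_bifactor(small_structure, exog=())
    f1 = fit_ml_continuous(base, items, compute_se=False)
    f2 = fit_ml_continuous(bif, items, compute_se=False)
    with pytest.raises(ValueError, match="not nested"):
        chisq_diff(f1, f2)


def test_ml_chisq_diff_matches_loglik_oracle(small_structure):
    """ML difference statistics equal brute-force deviance differences
    computed from the multivariate-normal log-density."""
    _, _, _, data = make_trio_data(small_structure, n=300, seed=13)
    items = data[list(small_structure.item_names)]
    arr = items.to_numpy()
    arr = arr - arr.mean(axis=0)
    base = base_second_order(small_structure, exog=())
    restricted = base.with_fixed(["l1[A1]"], 0.45)
    f_gen = fit_ml_continuous(base, items, compute_se=False)
    f_res = fit_ml_continuous(restricted, items, compute_se=False)
    stat, ddf, _ = chisq_diff(f_res, f_gen)
    assert ddf == 1

    def implied_sigma(fit):
        cm = CompiledModel(fit.spec)
        theta = fit.params.set_index("name").loc[cm.names, "estimate"].to_numpy()
        L, B, G, K, th = cm.matrices(theta)
        M = np.eye(cm.nf) + B
        LM = L @ M
        return LM @ LM.T + np.diag(th)

    dev_res = gaussian_deviance(arr, implied_sigma(f_res))
    dev_gen = gaussian_deviance(arr, implied_sigma(f_gen))
    assert stat == pytest.approx(dev_res - dev_gen, abs=1e-6)


def test_df_bookkeeping_of_model_ladder(small_structure):
    base = base_second_order(small_structure, exog=())
    null = build_null(base, "T1")
    pmed = build_p_mediated(base, "T1")
    dhet = build_domain_het(base, "T1")
    shet = build_symptom_het(dhet, "T1", "B")
    assert null.n_free == base.n_free
    assert pmed.n_free - null.n_free == 3
    assert dhet.n_free - null.n_free == 3 * 3
    # symptom_het on B (4 items): +3*4 item paths, -3 factor paths
    assert shet.n_free - dhet.n_free == 3 * (4 - 1)


def test_fit_indices_formula_oracle():
    """Hand-computed CFI/RMSEA on a synthetic fit summary."""
    spec = base_second_order(FactorStructure(domains=("A",),
                                             items_per_domain=(3,)), exog=())
    dummy = dict(spec=spec, estimator="ml_continuous",
                 params=pd.DataFrame(columns=["name", "estimate", "se", "z",
                                              "pvalue", "std_estimate"]),
                 pvalue=0.0, n=100.0, converged=True, srmr=0.031)
    fit = FitResult(stat=50.0, df=20, baseline_stat=200.0, baseline_df=30,
                    **dummy)
    cfi, rmsea, srmr = fit_indices(fit)
    assert cfi == pytest.approx(1 - 30 / 170)
    assert rmsea == pytest.approx(np.sqrt(30 / (20 * 100)))
    assert srmr == 0.031
    # statistic at or below df: RMSEA exactly 0
    fit2 = FitResult(stat=20.0, df=20, baseline_stat=200.0, baseline_df=30,
                     **dummy)
    assert fit_indices(fit2)[1] == 0.0


def test_standardized_solution_identity(small_structure):
    """std = unstd * sd(source)/sd(target) with model-implied sds."""
    _, _, _, data = make_trio_data(
        small_structure, n=3000, seed=21, betas=(0.2, 0.1, 0.1),
    )
    spec = base_second_order(
        small_structure, exog=("T1_mother", "T1_father", "T1_child")
    )
    spec = spec.with_free(["gp[T1_child]", "gp[T1_mother]", "gp[T1_father]"])
    fit = fit_ml_continuous(spec, data, compute_se=False)
    cm = CompiledModel(spec)
    p = fit.params.set_index("name")
    theta = p.loc[cm.names, "estimate"].to_numpy()
    L, B, G, K, th = cm.matrices(theta)
    M = np.eye(cm.nf) + B
    cols = cm.items + cm.exog
    arr = data[cols].to_numpy()
    S = np.cov(arr, rowvar=False, ddof=0)
    Phi = S[len(cm.items):, len(cm.items):]
    Vf = M @ (G @ Phi @ G.T + np.eye(cm.nf)) @ M.T
    sd_p = np.sqrt(Vf[0, 0])
    est = p.loc["gp[T1_child]", "estimate"]
    std = p.loc["gp[T1_child]", "std_estimate"]
    sd_x = np.sqrt(Phi[-1, -1])
    assert std == pytest.approx(est * sd_x / sd_p, rel=1e-9)


class TestDwls:
    def test_recovery_against_generating_model(self, small_structure):
        _, trios, items, _ = make_trio_data(
            small_structure, n=6000, seed=17, betas=(0.3, 0.2, 0.1),
            ordinal=True,
        )
        poly = estimate_polychorics(
            items, trios[["T1_mother", "T1_father", "T1_child"]]
        )
        spec = base_second_order(
            small_structure, exog=("T1_mother", "T1_father", "T1_child")
        )
        spec = spec.with_free(
            [f"gp[T1_{r}]" for r in ("mother", "father", "child")]
        )
        fit = fit_dwls(spec, poly)
        assert fit.converged
        p = fit.params.set_index("name")
        for item in small_structure.item_names:
            assert p.loc[f"l1[{item}]", "std_estimate"] == pytest.approx(
                0.6, abs=0.05
            )
        q = 0.3**2 + 0.2**2 + 0.1**2 + 2 * 0.3 * (0.2 + 0.1) * 0.5
        assert p.loc["gp[T1_child]", "std_estimate"] == pytest.approx(
            0.3 / np.sqrt(1 + q), abs=0.06
        )

    def test_ml_and_dwls_loadings_agree(self, small_structure):
        """Same latent data: ML on liabilities vs DWLS on thresholded
        categories give matching standardized loadings."""
        cfg, trios, items_cont, data = make_trio_data(
            small_structure, n=8000, seed=19, betas=(0.0, 0.0, 0.0),
        )
        from triomimic import simulate_items

        items_ord = simulate_items(trios, small_structure, cfg, ordinal=True)
        spec = base_second_order(small_structure, exog=())
        fit_ml = fit_ml_continuous(
            spec, items_cont[list(small_structure.item_names)],
            compute_se=False,
        )
        poly = estimate_polychorics(items_ord)
        fit_dw = fit_dwls(spec, poly)
        pml = fit_ml.params.set_index("name")
        pdw = fit_dw.params.set_index("name")
        for item in small_structure.item_names:
            assert pml.loc[f"l1[{item}]", "std_estimate"] == pytest.approx(
                pdw.loc[f"l1[{item}]", "std_estimate"], abs=0.05
            )

    def test_heywood_case_flagged_and_bounded(self):
        st = FactorStructure(domains=("A",), items_per_domain=(3,))
        R = np.array(
            [
                [1.0, 0.9, 0.6],
                [0.9, 1.0, 0.3],
                [0.6, 0.3, 1.0],
            ]
        )
        poly = PolychoricSet(
            item_names=("A1", "A2", "A3"),
            exog_names=(),
            R=R,
            asyvar=np.where(np.eye(3), np.nan, 1e-4),
            n_pair=np.full((3, 3), 1000),
            thresholds={f"A{i}": np.array([0.0]) for i in (1, 2, 3)},
        )
        spec = base_second_order(st, exog=()).with_fixed(["l2[A]"], 1.0)
        fit = fit_dwls(spec, poly)
        assert "A1" in fit.heywood

    def test_pairwise_n_recorded(self, small_structure):
        _, trios, items, _ = make_trio_data(
            small_structure, n=700, seed=23, ordinal=True, missing_rate=0.1,
        )
        poly = estimate_polychorics(items)
        spec = base_second_order(small_structure, exog=())
        fit = fit_dwls(spec, poly)
        assert fit.n_pair is not None
        assert fit.n_pair.max() <= 700
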