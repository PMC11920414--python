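"""Generator tests: transmission algebra, effect injection, fixtures."""

import numpy as np
import pandas as pd
import pytest

from triomimic import (
    FactorStructure,
    TrioConfig,
    read_fixtures,
    simulate_dataset,
    simulate_items,
    simulate_trio_pgs,
    trio_pgs_covariance,
    write_fixtures,
)
from triomimic.sem.polychoric import polyserial_corr


@pytest.mark.parametrize("a", [0.0, 0.2, 0.5])
def test_child_parent_correlation_matches_transmission_algebra(a):
    """cor(child, mother) follows (1+a)/2 * sqrt(2/(2+2a)); 0.5 under
    random mating."""
    cfg = TrioConfig(n_families=200_000, parental_pgs_correlation=a, seed=11)
    trios = simulate_trio_pgs(cfg)
    r = np.corrcoef(trios["PGS1_child"], trios["PGS1_mother"])[0, 1]
    expected = (1 + a) / 2 * np.sqrt(2 / (2 + 2 * a))
    assert r == pytest.approx(expected, abs=0.01)
    # child variance is 1 for any assortment setting
    assert trios["PGS1_child"].var() == pytest.approx(1.0, abs=0.02)


def test_analytic_covariance_matches_samples():
    C = np.array([[1.0, 0.5], [0.5, 1.0]])
    cfg = TrioConfig(
        n_families=150_000, traits=("X", "Y"), pgs_cross_trait_corr=C,
        parental_pgs_correlation=0.3, seed=4, covariate_confounding=0.0,
    )
    trios = simulate_trio_pgs(cfg)
    names, cov = trio_pgs_covariance(cfg)
    emp = trios[list(names)].cov().to_numpy()
    assert np.max(np.abs(emp - cov)) < 0.02
    # child cross-trait correlation reproduces C
    r = np.corrcoef(trios["X_child"], trios["Y_child"])[0, 1]
    assert r == pytest.approx(0.5, abs=0.015)


def test_empty_table_has_full_schema():
    cfg = TrioConfig(n_families=0, traits=("X",))
    trios = simulate_trio_pgs(cfg)
    assert len(trios) == 0
    for col in ("family_id", "sex", "birth_year", "X_mother", "X_father",
                "X_child"):
        assert col in trios.columns


def test_non_psd_cross_trait_matrix_rejected():
    with pytest.raises(ValueError, match="pgs_cross_trait_corr"):
        TrioConfig(
            n_families=10, traits=("X", "Y"),
            pgs_cross_trait_corr=np.array([[1.0, 1.2], [1.2, 1.0]]),
        )


def test_invalid_config_values_rejected():
    with pytest.raises(ValueError, match="missing_rate"):
        TrioConfig(n_families=10, missing_rate=1.0)
    with pytest.raises(ValueError, match="unknown traits"):
        TrioConfig(n_families=10, beta_child={"NOPE": 0.1})
    with pytest.raises(ValueError, match="non-finite"):
        TrioConfig(n_families=10, beta_child=np.inf)


def test_null_generator_items_uncorrelated_with_pgs(small_structure):
    cfg = TrioConfig(n_families=30_000, seed=2, sex_effect=0.0,
                     birth_year_effect=0.0, covariate_confounding=0.0)
    trios, items = simulate_dataset(cfg, small_structure, ordinal=False)
    g = trios["PGS1_child"].to_numpy()
    for item in small_structure.item_names:
        r = np.corrcoef(items[item], g)[0, 1]
        assert abs(r) < 0.025


def test_category_frequencies_match_threshold_probabilities(small_structure):
    from scipy.stats import norm

    cfg = TrioConfig(n_families=60_000, seed=9, sex_effect=0.0,
                     birth_year_effect=0.0)
    _, items = simulate_dataset(cfg, small_structure, ordinal=True)
    tau = np.asarray(small_structure.thresholds[0])
    cum = np.concatenate([[0.0], norm.cdf(tau), [1.0]])
    probs = np.diff(cum)
    for item in small_structure.item_names:
        counts = items[item].value_counts().sort_index().to_numpy()
        obs = counts / counts.sum()
        se = np.sqrt(probs * (1 - probs) / counts.sum())
        assert np.all(np.abs(obs - probs) < 5 * se + 1e-3)


def test_item_target_has_largest_polyserial_association(small_structure):
    """A single-item effect shows up as that item's polyserial
    correlation with the child PGS exceeding every other item's."""
    cfg = TrioConfig(
        n_families=25_000, beta_child=0.25, effect_target="item:B2",
        seed=5, sex_effect=0.0, birth_year_effect=0.0,
        covariate_confounding=0.0,
    )
    trios, items = simulate_dataset(cfg, small_structure, ordinal=True)
    g = trios["PGS1_child"].to_numpy()
    rs = {}
    for item in small_structure.item_names:
        codes = items[item].to_numpy(dtype=float)
        rs[item], _, _ = polyserial_corr(g, codes)
    best = max(rs, key=rs.get)
    assert best == "B2"


def test_missingness_mcar_rate(small_structure):
    cfg = TrioConfig(n_families=6000, missing_rate=0.3, seed=3)
    _, items = simulate_dataset(cfg, small_structure, ordinal=True)
    obs = items.drop(columns="family_id").notna()
    rate = 1.0 - obs.to_numpy().mean()
    assert rate == pytest.approx(0.3, abs=0.02)


def test_min_one_observed_item_per_child(small_structure):
    """Mirrors the analysis inclusion criterion: even under extreme
    missingness every retained child has >= 1 observed item."""
    cfg = TrioConfig(n_families=4000, missing_rate=0.9, seed=3)
    _, items = simulate_dataset(cfg, small_structure, ordinal=True)
    obs = items.drop(columns="family_id").notna()
    assert obs.any(axis=1).all()


def test_effect_target_validation(small_structure):
    cfg = TrioConfig(n_families=50, effect_target="specific:NOPE")
    trios = simulate_trio_pgs(cfg)
    with pytest.raises(ValueError, match="NOPE"):
        simulate_items(trios, small_structure, cfg)
    cfg2 = TrioConfig(n_families=50, effect_target="item:Z9")
    with pytest.raises(ValueError, match="Z9"):
        simulate_items(simulate_trio_pgs(cfg2), small_structure, cfg2)


def test_determinism_from_seed(small_structure):
    cfg = TrioConfig(n_families=300, seed=42, missing_rate=0.1)
    t1, i1 = simulate_dataset(cfg, small_structure)
    t2, i2 = simulate_dataset(cfg, small_structure)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(i1, i2)


class TestFixtureRoundTrip:
    def test_lossless_including_missingness(self, small_structure, tmp_path):
        cfg = TrioConfig(n_families=200, seed=1, missing_rate=0.2)
        trios, items = simulate_dataset(cfg, small_structure)
        write_fixtures(trios, items, tmp_path)
        t2, i2 = read_fixtures(tmp_path, small_structure)
        pd.testing.assert_frame_equal(items, i2)
        pd.testing.assert_frame_equal(trios, t2, check_dtype=False)

    def test_unknown_item_column_named_in_error(self, small_structure, tmp_path):
        cfg = TrioConfig(n_families=20, seed=1)
        trios, items = simulate_dataset(cfg, small_structure)
        items["BOGUS"] = 0
        write_fixtures(trios, items, tmp_path)
        with pytest.raises(ValueError, match="BOGUS"):
            read_fixtures(tmp_path, small_structure)

    def test_missing_item_column_listed(self, small_structure, tmp_path):
        cfg = TrioConfig(n_families=20, seed=1)
        trios, items = simulate_dataset(cfg, small_structure)
        write_fixtures(trios, items.drop(columns=["A1"]), tmp_path)
        with pytest.raises(ValueError, match="A1"):
            read_fixtures(tmp_path, small_structure)

    def test_empty_tables_roundtrip(self, small_structure, tmp_path):
        cfg = TrioConfig(n_families=0, seed=1)
        trios, items = simulate_dataset(cfg, small_structure)
        write_fixtures(trios, items, tmp_path)
        t2, i2 = read_fixtures(tmp_path, small_structure)
        assert len(t2) == 0 and len(i2) == 0


def test_default_structure_is_62_items_across_six_scales():
    st = FactorStructure()
    assert st.n_items == 62
    assert st.domains == ("ODD", "CND", "HYP", "INA", "DEP", "ANX")
    assert st.items_per_domain == (8, 18, 9, 9, 13, 5)
    assert st.domain_of("DEP3") == "DEP"
    # default thresholds produce right-skewed categories
    assert st.thresholds[0][0] > 0
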