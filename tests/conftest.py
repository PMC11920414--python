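import numpy as np
import pandas as pd
import pytest

from triomimic import FactorStructure, TrioConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_structure() -> FactorStructure:
    """Reduced three-domain battery used by most unit tests (three
    domains keep the second-order loadings identified)."""
    return FactorStructure(domains=("A", "B", "C"), items_per_domain=(3, 4, 3))


@pytest.fixture
def capture_objective(monkeypatch):
    """Capture the (value, gradient) objective a fit function minimizes."""
    import triomimic.sem.fit as fitmod

    captured = {}
    orig = fitmod._minimize

    def wrapper(cm, fun, rng_seed=0):
        captured["fun"] = fun
        captured["cm"] = cm
        return orig(cm, fun, rng_seed)

    monkeypatch.setattr(fitmod, "_minimize", wrapper)
    return captured


def make_trio_data(
    structure,
    n=2000,
    seed=0,
    betas=(0.0, 0.0, 0.0),
    effect_target="general",
    ordinal=False,
    trait="T1",
    missing_rate=0.0,
    **kwargs,
):
    """Simulate a joined items+PGS table for fitting."""
    bc, bm, bf = betas
    cfg = TrioConfig(
        n_families=n,
        traits=(trait,),
        beta_child=bc,
        beta_mother=bm,
        beta_father=bf,
        effect_target=effect_target,
        seed=seed,
        missing_rate=missing_rate,
        sex_effect=kwargs.pop("sex_effect", 0.0),
        birth_year_effect=kwargs.pop("birth_year_effect", 0.0),
        covariate_confounding=kwargs.pop("covariate_confounding", 0.0),
        **kwargs,
    )
    trios, items = simulate_dataset(cfg, structure, ordinal=ordinal)
    cols = [f"{trait}_{r}" for r in ("mother", "father", "child")]
    data = items.join(trios.set_index("family_id")[cols], on="family_id")
    return cfg, trios, items, data
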