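"""Synthetic trio polygenic scores and ordinal symptom items.

The generator emulates the statistical structure that the trio MIMIC
analysis assumes: mother and father polygenic scores (PGS) with
configurable within-trait (assortment-style) and cross-trait
correlations, a child score built from the mid-parent value plus an
independent segregation deviation, and ordinal symptom items produced by
thresholding continuous liabilities generated from a second-order factor
model.  Direct (child) and indirect (parental) PGS effects are injected
on the general factor, on specific domain factors, or on individual
items.

Transmission algebra
--------------------
With parents standardized and within-trait mother-father correlation
``a``, the raw child score is ``(M + F)/2 + s`` with segregation variance
``var(s) = (1 + a)/2``; after standardization the child-parent
correlation is ``(1 + a)/2 * sqrt(2 / (2 + 2a))``, i.e. the Mendelian
0.5 under random mating.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import FactorStructure

logger = logging.getLogger(__name__)

ROLES: tuple[str, ...] = ("mother", "father", "child")

#: year of birth range of the simulated cohort (inclusive start, exclusive end)
BIRTH_YEARS = (2000, 2009)
_YEAR_SD = np.sqrt((BIRTH_YEARS[1] - BIRTH_YEARS[0]) ** 2 - 1) / np.sqrt(12)
_YEAR_MEAN = (BIRTH_YEARS[0] + BIRTH_YEARS[1] - 1) / 2

COVARIATE_COLUMNS = ("sex", "birth_year", "pc1", "pc2", "pc3", "batch")


def _as_trait_map(value, traits: tuple[str, ...], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(traits)
        if unknown:
            raise ValueError(f"{name} names unknown traits: {sorted(unknown)}")
        out = {t: float(value.get(t, 0.0)) for t in traits}
    else:
        out = {t: float(value) for t in traits}
    if not all(np.isfinite(v) for v in out.values()):
        raise ValueError(f"{name} contains non-finite values")
    return out


@dataclass
class TrioConfig:
    """Configuration of the synthetic trio generator.

    Betas are effects of standardized PGS on the standardized latent
    target (general factor, domain factor, or item liability), per trait.
    A scalar beta applies to every trait; a mapping assigns per trait,
    with omitted traits at 0 (a zero-effect trait is the negative-control
    stand-in for the hair-colour PGS).
    """

    n_families: int
    traits: tuple[str, ...] = ("PGS1",)
    beta_child: float | Mapping[str, float] = 0.0
    beta_mother: float | Mapping[str, float] = 0.0
    beta_father: float | Mapping[str, float] = 0.0
    effect_target: str = "general"
    parental_pgs_correlation: float = 0.0
    pgs_cross_trait_corr: np.ndarray | None = None
    missing_rate: float = 0.0
    seed: int = 0
    sex_effect: float = 0.10
    birth_year_effect: float = 0.03
    covariate_confounding: float = 0.05

    def __post_init__(self) -> None:
        if self.n_families < 0:
            raise ValueError("n_families must be non-negative")
        self.traits = tuple(self.traits)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1.0 < self.parental_pgs_correlation < 1.0:
            raise ValueError("parental_pgs_correlation must be in (-1, 1)")
        self.beta_child = _as_trait_map(self.beta_child, self.traits, "beta_child")
        self.beta_mother = _as_trait_map(self.beta_mother, self.traits, "beta_mother")
        self.beta_father = _as_trait_map(self.beta_father, self.traits, "beta_father")
        T = len(self.traits)
        if self.pgs_cross_trait_corr is None:
            self.pgs_cross_trait_corr = np.eye(T)
        C = np.asarray(self.pgs_cross_trait_corr, dtype=float)
        if C.shape != (T, T):
            raise ValueError("pgs_cross_trait_corr has wrong shape")
        if not np.allclose(C, C.T):
            raise ValueError("pgs_cross_trait_corr is not symmetric")
        if T and np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError("pgs_cross_trait_corr is not positive semi-definite")
        self.pgs_cross_trait_corr = C

    def pgs_column(self, trait: str, role: str) -> str:
        return f"{trait}_{role}"


def trio_pgs_covariance(config: TrioConfig) -> tuple[pd.Index, np.ndarray]:
    """Analytic covariance of all standardized PGS columns.

    Column order is ``(trait, role)`` nested with roles mother, father,
    child.  This is the population covariance the generator targets (and
    reaches as n grows).
    """
    a = config.parental_pgs_correlation
    C = config.pgs_cross_trait_corr
    cpm = np.sqrt(1.0 + a) / 2.0  # child-parent per unit cross-trait corr
    role_block = np.array(
        [
            [1.0, a, cpm],
            [a, 1.0, cpm],
            [cpm, cpm, 1.0],
        ]
    )
    full = np.kron(C, role_block)
    # within trait the diagonal must be exactly 1 regardless of C diagonal
    names = pd.Index(
        [config.pgs_column(t, r) for t in config.traits for r in ROLES]
    )
    return names, full


def simulate_trio_pgs(
    config: TrioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-family mother/father/child PGS plus covariate stand-ins."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_families
    T = len(config.traits)
    a = config.parental_pgs_correlation
    C = config.pgs_cross_trait_corr

    joint = np.block([[C, a * C], [a * C, C]])
    try:
        chol = np.linalg.cholesky(joint + 1e-12 * np.eye(2 * T))
    except np.linalg.LinAlgError:
        raise ValueError(
            "parental PGS covariance built from pgs_cross_trait_corr and "
            f"parental_pgs_correlation={a} is not positive semi-definite"
        ) from None
    parents = rng.standard_normal((n, 2 * T)) @ chol.T
    mother, father = parents[:, :T], parents[:, T:]

    seg_cov = (1.0 + a) / 2.0 * C
    seg_chol = np.linalg.cholesky(seg_cov + 1e-12 * np.eye(T))
    seg = rng.standard_normal((n, T)) @ seg_chol.T
    child = ((mother + father) / 2.0 + seg) / np.sqrt(1.0 + a)

    data: dict[str, np.ndarray] = {}
    data["family_id"] = np.arange(n)
    data["sex"] = rng.integers(0, 2, size=n)
    data["birth_year"] = rng.integers(*BIRTH_YEARS, size=n)
    for j in (1, 2, 3):
        data[f"pc{j}"] = rng.standard_normal(n)
    data["batch"] = rng.integers(0, 4, size=n)

    conf = config.covariate_confounding * data["pc1"] if n else 0.0
    for ti, trait in enumerate(config.traits):
        for role, mat in zip(ROLES, (mother, father, child)):
            data[config.pgs_column(trait, role)] = mat[:, ti] + conf

    df = pd.DataFrame(data)
    if n == 0:
        # preserve full schema on the degenerate case
        df = df.astype({c: float for c in df.columns if c != "family_id"})
    return df


def _parse_target(target: str, structure: FactorStructure):
    """Parse an effect target into atomic (kind, where) parts.

    Atomic targets: ``general``, ``specific`` (all domains),
    ``specific:<domain>``, ``item:<item-id>`` and ``mixed`` (parental
    effects on the general factor, child effect on every domain).
    Atomic targets may be combined with ``+`` (e.g.
    ``specific:DEP+item:DEP7``) to inject the effect at several levels
    at once.
    """
    parts = []
    for part in target.split("+"):
        if part == "general":
            parts.append(("general", None))
        elif part == "mixed":
            parts.append(("mixed", tuple(structure.domains)))
        elif part == "specific":
            parts.append(("specific", tuple(structure.domains)))
        elif part.startswith("specific:"):
            dom = part.split(":", 1)[1]
            if dom not in structure.domains:
                raise ValueError(
                    f"effect_target names unknown domain {dom!r}; "
                    f"known domains: {list(structure.domains)}"
                )
            parts.append(("specific", (dom,)))
        elif part.startswith("item:"):
            item = part.split(":", 1)[1]
            if item not in structure.item_names:
                raise ValueError(f"effect_target names unknown item {item!r}")
            parts.append(("item", (item,)))
        else:
            raise ValueError(f"unrecognized effect_target {part!r}")
    if len(parts) > 1 and any(k == "mixed" for k, _ in parts):
        raise ValueError("'mixed' cannot be combined with other targets")
    return parts


def _effect_arrays(config: TrioConfig, trios: pd.DataFrame, roles=ROLES):
    """Per-family combined PGS effect (over the given roles) and its
    population variance under the generator's analytic covariance."""
    names, cov = trio_pgs_covariance(config)
    role_beta = {
        "mother": config.beta_mother,
        "father": config.beta_father,
        "child": config.beta_child,
    }
    beta = np.zeros(len(names))
    cols = list(names)
    for ti, trait in enumerate(config.traits):
        for ri, role in enumerate(ROLES):
            if role in roles:
                beta[3 * ti + ri] = role_beta[role][trait]
    G = trios[cols].to_numpy(dtype=float)
    effect = G @ beta
    var = float(beta @ cov @ beta)
    return effect, var


def simulate_items(
    trios: pd.DataFrame,
    structure: FactorStructure,
    config: TrioConfig,
    rng: np.random.Generator | None = None,
    ordinal: bool = True,
) -> pd.DataFrame:
    """Generate symptom items from the latent hierarchy with PGS effects.

    With ``ordinal=False`` the continuous liabilities are returned
    instead of thresholded categories (the fast path used by the
    maximum-likelihood power simulations).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(trios)
    parts = _parse_target(config.effect_target, structure)
    mixed = parts[0][0] == "mixed"
    if mixed:
        effect_p, evar_p = _effect_arrays(config, trios, roles=("mother", "father"))
        effect, evar = _effect_arrays(config, trios, roles=("child",))
    else:
        effect, evar = _effect_arrays(config, trios)
    gen_domains = {d for k, w in parts if k in ("specific", "mixed") for d in (w or ())}
    gen_items = {it for k, w in parts if k == "item" for it in w}
    on_general = any(k == "general" for k, _ in parts)

    lam2 = np.asarray(structure.second_order_loadings)
    lam1 = np.asarray(structure.first_order_loadings)
    dom_idx = structure.item_domain_index

    # general factor
    zeta_p = rng.standard_normal(n)
    if on_general:
        P = (effect + zeta_p) / np.sqrt(1.0 + evar)
    elif mixed:
        P = (effect_p + zeta_p) / np.sqrt(1.0 + evar_p)
    else:
        P = zeta_p

    # domain factors
    eta = np.empty((n, len(structure.domains)))
    for d, dom in enumerate(structure.domains):
        resid = rng.standard_normal(n) * np.sqrt(1.0 - lam2[d] ** 2)
        e = lam2[d] * P + resid
        if dom in gen_domains:
            e = (e + effect) / np.sqrt(1.0 + evar)
        eta[:, d] = e

    # item liabilities
    sexc = trios["sex"].to_numpy(dtype=float) - 0.5 if n else np.empty(0)
    yearc = (
        (trios["birth_year"].to_numpy(dtype=float) - _YEAR_MEAN) / _YEAR_SD
        if n
        else np.empty(0)
    )
    ds, db = config.sex_effect, config.birth_year_effect
    cov_var = ds**2 * 0.25 + db**2
    liab = np.empty((n, structure.n_items))
    for i, item in enumerate(structure.item_names):
        extra = 0.0
        q_i = 0.0
        if item in gen_items:
            extra = effect
            q_i = evar
        resid_var = 1.0 - lam1[i] ** 2 - cov_var
        if resid_var <= 0:
            raise ValueError(
                f"item {item}: loadings and covariate effects imply "
                "non-positive residual variance"
            )
        y = (
            lam1[i] * eta[:, dom_idx[i]]
            + extra
            + ds * sexc
            + db * yearc
            + rng.standard_normal(n) * np.sqrt(resid_var)
        )
        liab[:, i] = y / np.sqrt(1.0 + q_i)

    out = pd.DataFrame({"family_id": trios["family_id"].to_numpy()})
    miss = (
        rng.random((n, structure.n_items)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, structure.n_items), dtype=bool)
    )
    # keep at least one observed item per child (inclusion criterion of
    # the analysis sample)
    all_missing = miss.all(axis=1)
    if all_missing.any():
        keep = rng.integers(0, structure.n_items, size=int(all_missing.sum()))
        miss[np.flatnonzero(all_missing), keep] = False

    if ordinal:
        for i, item in enumerate(structure.item_names):
            codes = np.searchsorted(np.asarray(structure.thresholds[i]), liab[:, i])
            col = pd.array(codes, dtype="Int64")
            col[miss[:, i]] = pd.NA
            out[item] = col
    else:
        for i, item in enumerate(structure.item_names):
            col = liab[:, i].copy()
            col[miss[:, i]] = np.nan
            out[item] = col
    return out


def simulate_dataset(
    config: TrioConfig,
    structure: FactorStructure | None = None,
    ordinal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trio PGS table and item table from a single seeded generator."""
    if structure is None:
        structure = FactorStructure()
    rng = np.random.default_rng(config.seed)
    trios = simulate_trio_pgs(config, rng)
    items = simulate_items(trios, structure, config, rng, ordinal=ordinal)
    return trios, items


# ---------------------------------------------------------------------------
# fixture round-trip


def write_fixtures(trios: pd.DataFrame, items: pd.DataFrame, path) -> None:
    """Write tab-delimited trio and item tables (missing encoded as NA)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trios.to_csv(path / "trios.tsv", sep="\t", index=False, na_rep="NA")
    items.to_csv(path / "items.tsv", sep="\t", index=False, na_rep="NA")


def read_fixtures(
    path, structure: FactorStructure | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read tables written by :func:`write_fixtures`.

    When a structure is given, the item table schema is validated: every
    structure item must be present and no unknown item columns allowed.
    """
    path = Path(path)
    trios = pd.read_csv(path / "trios.tsv", sep="\t", na_values="NA")
    items = pd.read_csv(path / "items.tsv", sep="\t", na_values="NA")
    if "family_id" not in trios.columns or "family_id" not in items.columns:
        raise ValueError("fixture tables must contain a family_id column")
    if structure is not None:
        expected = set(structure.item_names)
        present = set(items.columns) - {"family_id"}
        unknown = sorted(present - expected)
        missing = sorted(expected - present)
        if unknown:
            raise ValueError(f"unknown item columns in items table: {unknown}")
        if missing:
            raise ValueError(f"missing item columns in items table: {missing}")
    # restore nullable integer coding for ordinal items
    for c in items.columns:
        if c == "family_id":
            continue
        col = items[c]
        if col.dtype.kind in "fi":
            vals = col.dropna()
            if len(vals) == 0 or np.allclose(vals, np.round(vals)):
                if (col.dropna() == col.dropna().astype(int)).all():
                    items[c] = col.astype("Int64")
    return trios, items
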