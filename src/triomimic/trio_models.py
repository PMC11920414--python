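"""Per-trait model family: null, P-mediated, domain-heterogeneity and
symptom-heterogeneity MIMIC models, in conditional and unconditional
(child-only / parents-only) form.

The ladder is strictly nested:

* null — mother/father/child PGS regressors present but all paths to P
  fixed at 0 (covariates keep their free item paths);
* P-mediated — the three PGS -> P paths freed;
* domain-heterogeneity — 3 x D PGS -> specific-factor paths freed, with
  PGS -> P fixed at 0 so effects are expressed only through the specific
  factors (keeps the ladder nested and the paths interpretable);
* symptom-heterogeneity (per domain) — for one domain in turn, the
  factor-level PGS paths are replaced by direct PGS -> item paths for
  every item of that domain; other domains keep factor-level paths.

Unconditional variants restrict the exogenous PGS block to the child
(child_only) or to the two parents (parents_only); covariates stay in
every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sem.model_spec import ModelSpec
from .structures import FactorStructure
from .synthetic_trios import ROLES

MODES = ("conditional", "child_only", "parents_only")
_MODE_ROLES = {
    "conditional": ROLES,
    "child_only": ("child",),
    "parents_only": ("mother", "father"),
}


def _pgs_cols(trait: str, mode: str) -> tuple[str, ...]:
    return tuple(f"{trait}_{r}" for r in _MODE_ROLES[mode])


def _with_pgs_exog(spec_base: ModelSpec, cols) -> ModelSpec:
    new = [c for c in cols if c not in spec_base.exog]
    return spec_base.with_exog(tuple(spec_base.exog) + tuple(new))


def build_null(spec_base: ModelSpec, trait: str, mode: str = "conditional") -> ModelSpec:
    """PGS regressors included with all paths to P fixed at 0."""
    cols = _pgs_cols(trait, mode)
    spec = _with_pgs_exog(spec_base, cols)
    return spec.with_fixed([f"gp[{c}]" for c in cols], 0.0)


def build_p_mediated(
    spec_base: ModelSpec, trait: str, mode: str = "conditional"
) -> ModelSpec:
    """PGS effects fully mediated by the general factor P."""
    cols = _pgs_cols(trait, mode)
    spec = _with_pgs_exog(spec_base, cols)
    return spec.with_free([f"gp[{c}]" for c in cols])


def build_domain_het(
    spec_base: ModelSpec, trait: str, mode: str = "conditional"
) -> ModelSpec:
    """PGS effects freed on every specific domain factor; P paths at 0."""
    cols = _pgs_cols(trait, mode)
    spec = _with_pgs_exog(spec_base, cols)
    spec = spec.with_fixed([f"gp[{c}]" for c in cols], 0.0)
    names = [f"gd[{c},{d}]" for c in cols for d in spec.structure.domains]
    return spec.with_free(names)


def build_symptom_het(
    spec_domain_het: ModelSpec, trait: str, domain: str, mode: str = "conditional"
) -> ModelSpec:
    """For one domain, replace factor-level PGS paths by direct item paths."""
    st = spec_domain_het.structure
    if domain not in st.domains:
        raise ValueError(f"unknown domain {domain!r}")
    cols = _pgs_cols(trait, mode)
    spec = spec_domain_het.with_fixed([f"gd[{c},{domain}]" for c in cols], 0.0)
    d = st.domains.index(domain)
    items = [
        it for it, di in zip(st.item_names, st.item_domain_index) if di == d
    ]
    return spec.with_free([f"k[{c},{it}]" for c in cols for it in items])


@dataclass
class TrioModelSet:
    """All candidate ModelSpecs for one PGS trait.

    Keys of ``specs`` are ``(model, mode)`` with model in
    {null, p_mediated, domain_het, symptom_het:<domain>} and mode in
    {conditional, child_only, parents_only}.
    """

    trait: str
    structure: FactorStructure
    specs: dict[tuple[str, str], ModelSpec] = field(default_factory=dict)

    def spec(self, model: str, mode: str = "conditional") -> ModelSpec:
        return self.specs[(model, mode)]

    def verify_nesting(self) -> None:
        """Machine-check the nesting ladder for every mode present."""
        for mode in MODES:
            if ("null", mode) not in self.specs:
                continue
            null = self.specs[("null", mode)]
            pmed = self.specs[("p_mediated", mode)]
            dhet = self.specs[("domain_het", mode)]
            if not null.is_nested_in(pmed):
                raise AssertionError(f"null not nested in p_mediated ({mode})")
            if not pmed.is_nested_in(dhet):
                raise AssertionError(f"p_mediated not nested in domain_het ({mode})")
            for (model, m), spec in self.specs.items():
                if m == mode and model.startswith("symptom_het:"):
                    if not dhet.is_nested_in(spec):
                        raise AssertionError(
                            f"domain_het not nested in {model} ({mode})"
                        )


def build_trio_model_set(
    spec_base: ModelSpec,
    trait: str,
    modes=("conditional",),
    symptom_domains: tuple[str, ...] | None = None,
) -> TrioModelSet:
    """Construct the full candidate family for one trait."""
    st = spec_base.structure
    if symptom_domains is None:
        symptom_domains = st.domains
    out = TrioModelSet(trait=trait, structure=st)
    for mode in modes:
        out.specs[("null", mode)] = build_null(spec_base, trait, mode)
        out.specs[("p_mediated", mode)] = build_p_mediated(spec_base, trait, mode)
        dhet = build_domain_het(spec_base, trait, mode)
        out.specs[("domain_het", mode)] = dhet
        for dom in symptom_domains:
            out.specs[(f"symptom_het:{dom}", mode)] = build_symptom_het(
                dhet, trait, dom, mode
            )
    out.verify_nesting()
    return out
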