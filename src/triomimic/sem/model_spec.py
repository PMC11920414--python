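"""Symbolic specification of second-order / bifactor MIMIC models.

A :class:`ModelSpec` lists every free parameter (with a start value) and
every explicitly fixed parameter of a hierarchical MIMIC structural
equation model.  Parameters not mentioned are structurally fixed at 0.

Parameter naming
----------------
``l1[item]``        item -> its first-order domain loading
``lg[item]``        item -> general factor loading (bifactor only)
``l2[domain]``      domain -> P second-order loading
``gp[x]``           exogenous regressor x -> P
``gd[x,domain]``    x -> specific domain factor
``k[x,item]``       x -> item (direct path)
``th[item]``        item residual variance (free under ML; determined by
                    the unit-diagonal convention under DWLS)

Identification: all factor residual variances are fixed to 1
(unit-variance identification), so structural paths are directly
interpretable on the standardized-latent scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ..structures import FactorStructure

_NAME_RE = re.compile(r"^(l1|lg|l2|gp|gd|k|th)\[([^\]]*)\]$")


def parse_param(name: str) -> tuple[str, tuple[str, ...]]:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"malformed parameter name {name!r}")
    kind, args = m.group(1), tuple(m.group(2).split(","))
    expected = 2 if kind in ("gd", "k") else 1
    if len(args) != expected:
        raise ValueError(f"parameter {name!r} needs {expected} index(es)")
    return kind, args


@dataclass(frozen=True)
class ModelSpec:
    structure: FactorStructure
    exog: tuple[str, ...]
    bifactor: bool = False
    free: dict[str, float] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "exog", tuple(self.exog))
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        items = set(self.structure.item_names)
        domains = set(self.structure.domains)
        exog = set(self.exog)
        for name in list(self.free) + list(self.fixed):
            kind, args = parse_param(name)
            if kind in ("l1", "lg", "th") and args[0] not in items:
                raise ValueError(f"{name}: unknown item {args[0]!r}")
            if kind == "l2" and args[0] not in domains:
                raise ValueError(f"{name}: unknown domain {args[0]!r}")
            if kind == "gp" and args[0] not in exog:
                raise ValueError(f"{name}: unknown exogenous column {args[0]!r}")
            if kind == "gd" and (args[0] not in exog or args[1] not in domains):
                raise ValueError(f"{name}: unknown exog/domain pair")
            if kind == "k" and (args[0] not in exog or args[1] not in items):
                raise ValueError(f"{name}: unknown exog/item pair")
            if kind == "lg" and not self.bifactor:
                raise ValueError(f"{name}: general loadings need bifactor=True")
            if kind == "l2" and self.bifactor:
                raise ValueError(f"{name}: second-order loading in bifactor model")

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free)

    def value_of(self, name: str) -> float:
        """Declared value: start if free, fixed value, or structural 0."""
        if name in self.free:
            return self.free[name]
        return self.fixed.get(name, 0.0)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """Structural nesting check.

        Every free parameter of ``self`` must be free in ``other``, or be
        a factor-mediated path whose effect surface is contained in
        ``other``'s freed paths one level down the hierarchy: a free
        ``gp[x]`` is nested under free ``gd[x,d]`` for **all** domains
        (P-mediation constrains domain paths to be proportional to the
        second-order loadings), and a free ``gd[x,d]`` is nested under
        free ``k[x,item]`` for all of that domain's items.  Constraints
        fixed in both models must agree in value.
        """
        if (
            self.structure.item_names != other.structure.item_names
            or self.exog != other.exog
            or self.bifactor != other.bifactor
        ):
            return False
        st = self.structure
        dom_items = {
            d: [
                it
                for it, di in zip(st.item_names, st.item_domain_index)
                if st.domains[di] == d
            ]
            for d in st.domains
        }
        for name in self.free:
            if name in other.free:
                continue
            kind, args = parse_param(name)
            if kind == "gp":
                x = args[0]
                if all(f"gd[{x},{d}]" in other.free for d in st.domains):
                    continue
                if all(f"k[{x},{it}]" in other.free for it in st.item_names):
                    continue
            elif kind == "gd":
                x, d = args
                if all(f"k[{x},{it}]" in other.free for it in dom_items[d]):
                    continue
            return False
        for name, val in self.fixed.items():
            if name in other.free:
                continue
            if other.fixed.get(name, 0.0) != val and name not in self.free:
                return False
        for name, val in other.fixed.items():
            if name not in self.free and name not in self.fixed and val != 0.0:
                return False
        return True

    # -- editing ----------------------------------------------------------

    def with_free(self, names, start: float = 0.0) -> "ModelSpec":
        free = dict(self.free)
        fixed = dict(self.fixed)
        for n in names:
            fixed.pop(n, None)
            free.setdefault(n, start)
        return replace(self, free=free, fixed=fixed)

    def with_fixed(self, names, value: float = 0.0) -> "ModelSpec":
        free = dict(self.free)
        fixed = dict(self.fixed)
        for n in names:
            free.pop(n, None)
            fixed[n] = value
        return replace(self, free=free, fixed=fixed)

    def with_exog(self, exog) -> "ModelSpec":
        return replace(self, exog=tuple(exog))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "exog": list(self.exog),
            "bifactor": self.bifactor,
            "free": dict(self.free),
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            structure=FactorStructure.from_dict(d["structure"]),
            exog=tuple(d["exog"]),
            bifactor=bool(d.get("bifactor", False)),
            free=dict(d.get("free", {})),
            fixed=dict(d.get("fixed", {})),
        )


def base_second_order(
    structure: FactorStructure,
    exog=(),
    covariate_items=(),
    loading_start: float = 0.6,
    second_order_start: float = 0.7,
) -> ModelSpec:
    """Baseline second-order measurement model with optional covariate
    regressors on the items (sex, year of birth in the study design)."""
    free: dict[str, float] = {}
    for item in structure.item_names:
        free[f"l1[{item}]"] = loading_start
    for dom in structure.domains:
        free[f"l2[{dom}]"] = second_order_start
    for item in structure.item_names:
        free[f"th[{item}]"] = max(1.0 - loading_start**2, 0.1)
    for cov in covariate_items:
        if cov not in exog:
            raise ValueError(f"covariate {cov!r} not among exogenous columns")
        for item in structure.item_names:
            free[f"k[{cov},{item}]"] = 0.0
    return ModelSpec(structure=structure, exog=tuple(exog), free=free)


def base_bifactor(
    structure: FactorStructure,
    exog=(),
    covariate_items=(),
    loading_start: float = 0.45,
    general_start: float = 0.45,
) -> ModelSpec:
    """Symmetric bifactor baseline: every item loads on the general
    factor and on exactly one orthogonal specific factor."""
    free: dict[str, float] = {}
    for item in structure.item_names:
        free[f"lg[{item}]"] = general_start
        free[f"l1[{item}]"] = loading_start
        free[f"th[{item}]"] = max(1.0 - loading_start**2 - general_start**2, 0.1)
    for cov in covariate_items:
        if cov not in exog:
            raise ValueError(f"covariate {cov!r} not among exogenous columns")
        for item in structure.item_names:
            free[f"k[{cov},{item}]"] = 0.0
    return ModelSpec(structure=structure, exog=tuple(exog), bifactor=True, free=free)
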