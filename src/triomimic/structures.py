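"""Hierarchical factor structure of the child symptom battery.

The default structure mirrors a six-scale battery of maternal-rated
emotional and behavioural symptoms at age 8: oppositional-defiant
behaviour (ODD, 8 items), conduct problems (CND, 18), hyperactivity
(HYP, 9), inattention (INA, 9), depressive symptoms (DEP, 13) and
anxiety (ANX, 5) — 62 ordinal items in total.  Items load on one
first-order domain each; the six domains load on a single second-order
general factor P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DOMAINS: tuple[str, ...] = ("ODD", "CND", "HYP", "INA", "DEP", "ANX")
DEFAULT_ITEMS_PER_DOMAIN: tuple[int, ...] = (8, 18, 9, 9, 13, 5)

#: right-skewed default category split: most children endorse the lowest
#: category of a symptom item ("never/not true")
DEFAULT_CATEGORY_PROBS: tuple[float, ...] = (0.65, 0.20, 0.10, 0.05)


def _thresholds_from_probs(probs: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    cum = np.cumsum(probs)[:-1]
    return norm.ppf(cum)


@dataclass(frozen=True)
class FactorStructure:
    """Second-order measurement structure over ordinal symptom items.

    Parameters
    ----------
    domains:
        Ordered first-order domain labels.
    items_per_domain:
        Number of items measuring each domain.
    first_order_loadings:
        Item -> domain loading for every item (standardized latents).
    second_order_loadings:
        Domain -> P loading for every domain.
    thresholds:
        Per-item ordered cut-points on the standard-normal liability;
        ``len(thresholds[i]) + 1`` is the item's category count.
    """

    domains: tuple[str, ...] = DEFAULT_DOMAINS
    items_per_domain: tuple[int, ...] = DEFAULT_ITEMS_PER_DOMAIN
    first_order_loadings: tuple[float, ...] = ()
    second_order_loadings: tuple[float, ...] = ()
    thresholds: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.domains) != len(self.items_per_domain):
            raise ValueError("domains and items_per_domain lengths differ")
        n_items = sum(self.items_per_domain)
        if not self.first_order_loadings:
            object.__setattr__(self, "first_order_loadings", (0.6,) * n_items)
        if not self.second_order_loadings:
            object.__setattr__(
                self, "second_order_loadings", (0.7,) * len(self.domains)
            )
        if not self.thresholds:
            tau = tuple(_thresholds_from_probs(np.asarray(DEFAULT_CATEGORY_PROBS)))
            object.__setattr__(self, "thresholds", (tau,) * n_items)
        if len(self.first_order_loadings) != n_items:
            raise ValueError("need one first-order loading per item")
        if len(self.second_order_loadings) != len(self.domains):
            raise ValueError("need one second-order loading per domain")
        if len(self.thresholds) != n_items:
            raise ValueError("need one threshold vector per item")
        for lab, tau in zip(self.item_names, self.thresholds):
            t = np.asarray(tau, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds for item {lab} are not increasing")
        lam1 = np.asarray(self.first_order_loadings)
        lam2 = np.asarray(self.second_order_loadings)[self.item_domain_index]
        if np.any(lam1**2 > 1.0) or np.any(lam2**2 > 1.0):
            raise ValueError("loadings imply item variance above 1")

    @property
    def n_items(self) -> int:
        return sum(self.items_per_domain)

    @property
    def item_names(self) -> tuple[str, ...]:
        names = []
        for dom, k in zip(self.domains, self.items_per_domain):
            names.extend(f"{dom}{j + 1}" for j in range(k))
        return tuple(names)

    @property
    def item_domain_index(self) -> np.ndarray:
        """For each item, the index of its domain in ``domains``."""
        idx = np.repeat(np.arange(len(self.domains)), self.items_per_domain)
        return idx

    def domain_of(self, item: str) -> str:
        try:
            pos = self.item_names.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None
        return self.domains[self.item_domain_index[pos]]

    @property
    def n_categories(self) -> tuple[int, ...]:
        return tuple(len(t) + 1 for t in self.thresholds)

    def to_dict(self) -> dict:
        return {
            "domains": list(self.domains),
            "items_per_domain": list(self.items_per_domain),
            "first_order_loadings": list(self.first_order_loadings),
            "second_order_loadings": list(self.second_order_loadings),
            "thresholds": [list(t) for t in self.thresholds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorStructure":
        return cls(
            domains=tuple(d["domains"]),
            items_per_domain=tuple(d["items_per_domain"]),
            first_order_loadings=tuple(d.get("first_order_loadings") or ()),
            second_order_loadings=tuple(d.get("second_order_loadings") or ()),
            thresholds=tuple(tuple(t) for t in d.get("thresholds") or ()),
        )
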