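"""Polygenic-score pre-processing: covariate residualization,
standardization, and multivariate principal-component scores.

Each PGS column is replaced by the z-scored residual of its least-squares
regression on the covariates, separately within family role (mother,
father, child), since batch and ancestry structure can differ by
generation.  The multivariate scores ("polygenic-P" over the
neuropsychiatric subset, "PC1" over all traits) are the first unrotated
principal component of the standardized trait matrix; loadings are
estimated on the pooled parent+child matrix and the same loading vector
is applied to every role, so the score is commensurable across family
members.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic_trios import ROLES

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "birth_year", "pc1", "pc2", "pc3", "batch")


def _design(df: pd.DataFrame, covariates) -> np.ndarray:
    X = [np.ones(len(df))]
    kept = ["intercept"]
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("covariate %s is constant; dropped", c)
            continue
        X.append(v)
        kept.append(c)
    X = np.column_stack(X)
    # drop collinear columns via rank-revealing QR on the correlationised design
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        dropped = [kept[i] for i in np.flatnonzero(bad)]
        logger.warning("dropping collinear covariates: %s", dropped)
        X = X[:, ~bad]
    return X


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def prepare_pgs(
    raw: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize and z-score every PGS column, within role.

    Returns a copy of ``raw`` with PGS columns replaced by standardized
    residuals.  Columns whose residual variance collapses to ~0 (PGS
    exactly linear in covariates) are kept at 0 and flagged via warning.
    """
    out = raw.copy()
    if traits is None:
        suffix = tuple(f"_{r}" for r in ROLES)
        pgs_cols = [c for c in raw.columns if c.endswith(suffix)]
    else:
        pgs_cols = [f"{t}_{r}" for t in traits for r in ROLES]
    missing = [c for c in pgs_cols if c not in raw.columns]
    if missing:
        raise ValueError(f"PGS columns not found: {missing}")
    if len(raw) == 0:
        return out
    X = _design(raw, covariates)
    for c in pgs_cols:
        resid = _residualize(raw[c].to_numpy(dtype=float), X)
        sd = resid.std()
        if sd < 1e-10:
            logger.warning(
                "PGS column %s is fully explained by covariates; set to 0", c
            )
            out[c] = 0.0
        else:
            out[c] = (resid - resid.mean()) / sd
    return out


def multivariate_pgs(
    pgs: pd.DataFrame, trait_subset: list[str], name: str = "MVPGS"
) -> tuple[pd.DataFrame, pd.Series]:
    """First unrotated principal component over a trait subset.

    Loadings come from the eigendecomposition of the correlation matrix
    of the pooled (mother + father + child) standardized trait matrix;
    the sign is fixed so the loading sum is positive.  Returns the input
    table with three new score columns (one per role) and the loading
    vector.
    """
    if len(trait_subset) < 2:
        raise ValueError("need at least 2 traits for a principal component")
    blocks = []
    for role in ROLES:
        cols = [f"{t}_{role}" for t in trait_subset]
        missing = [c for c in cols if c not in pgs.columns]
        if missing:
            raise ValueError(f"PGS columns not found: {missing}")
        blocks.append(pgs[cols].to_numpy(dtype=float))
    pooled = np.vstack(blocks)
    sd = pooled.std(axis=0)
    if np.any(sd < 1e-10):
        bad = [t for t, s in zip(trait_subset, sd) if s < 1e-10]
        raise ValueError(f"constant PGS columns cannot enter the PCA: {bad}")
    Z = (pooled - pooled.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(R)
    v1 = V[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    loadings = pd.Series(v1, index=list(trait_subset), name=name)
    out = pgs.copy()
    for role, block in zip(ROLES, blocks):
        zb = (block - pooled.mean(axis=0)) / sd
        score = zb @ v1
        out[f"{name}_{role}"] = score
    return out, loadings
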