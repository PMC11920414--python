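"""Point estimation of hierarchical MIMIC models.

Two estimators share one compiled parametrization:

* :func:`fit_ml_continuous` — normal-theory maximum likelihood on
  continuous indicators, in the conditional (fixed-x) formulation: the
  exogenous block is saturated, so only the regression ``Pi`` and the
  conditional indicator covariance ``Omega`` are modelled.
* :func:`fit_dwls` — diagonally weighted least squares on a
  polychoric/polyserial correlation matrix (delta parameterization:
  item liabilities have unit variance, residual variances are derived,
  not free).

Model algebra (factors f = (P, eta_1..eta_D), exogenous x):

    f = B f + Gamma x + zeta,   zeta ~ (0, I)   (unit-variance id.)
    y = L f + K x + eps,        eps ~ (0, Theta diag)

``B`` carries the second-order loadings (domain <- P), so (I - B)^-1 =
I + B exactly.  Implied moments:

    Pi      = L (I+B) Gamma + K
    Omega   = L (I+B)(I+B)' L' + Theta
    Cov(y)  = Pi Phi Pi' + Omega,   Cov(y, x) = Pi Phi

Gradients of both discrepancy functions are analytic (matrix chain
rule); standard errors come from the observed information (ML) or the
weighted-least-squares information (DWLS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, norm

from .model_spec import ModelSpec, parse_param

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# compilation


class CompiledModel:
    """Index machinery mapping a ModelSpec to dense matrices."""

    def __init__(self, spec: ModelSpec, include_theta: bool = True):
        self.spec = spec
        st = spec.structure
        self.items = list(st.item_names)
        self.domains = list(st.domains)
        self.exog = list(spec.exog)
        self.p = len(self.items)
        self.k = len(self.exog)
        self.nf = 1 + len(self.domains)  # factor 0 is P
        self._item_ix = {n: i for i, n in enumerate(self.items)}
        self._dom_ix = {n: i for i, n in enumerate(self.domains)}
        self._exog_ix = {n: i for i, n in enumerate(self.exog)}
        dom_of_item = st.item_domain_index

        self.L0 = np.zeros((self.p, self.nf))
        self.B0 = np.zeros((self.nf, self.nf))
        self.G0 = np.zeros((self.nf, self.k))
        self.K0 = np.zeros((self.p, self.k))
        self.th0 = np.ones(self.p)

        self.names: list[str] = []
        self.slots: list[tuple[str, int, int]] = []
        start, lb = [], []
        for name, val in spec.free.items():
            kind, ij = self._locate(name, dom_of_item)
            if kind == "th" and not include_theta:
                continue
            self.names.append(name)
            self.slots.append((kind, *ij))
            start.append(val if kind != "th" or val > 0 else 0.5)
            lb.append(1e-6 if kind == "th" else -np.inf)
        for name, val in spec.fixed.items():
            kind, ij = self._locate(name, dom_of_item)
            self._assign(kind, ij, val)
        self.start = np.asarray(start, dtype=float)
        self.lower = np.asarray(lb, dtype=float)
        self.n_free = len(self.names)

    def _locate(self, name: str, dom_of_item) -> tuple[str, tuple[int, int]]:
        kind, args = parse_param(name)
        if kind == "l1":
            i = self._item_ix[args[0]]
            return "L", (i, 1 + dom_of_item[i])
        if kind == "lg":
            return "L", (self._item_ix[args[0]], 0)
        if kind == "l2":
            return "B", (1 + self._dom_ix[args[0]], 0)
        if kind == "gp":
            return "G", (0, self._exog_ix[args[0]])
        if kind == "gd":
            return "G", (1 + self._dom_ix[args[1]], self._exog_ix[args[0]])
        if kind == "k":
            return "K", (self._item_ix[args[1]], self._exog_ix[args[0]])
        if kind == "th":
            return "th", (self._item_ix[args[0]], 0)
        raise AssertionError(kind)

    def _assign(self, kind, ij, val) -> None:
        if kind == "L":
            self.L0[ij] = val
        elif kind == "B":
            self.B0[ij] = val
        elif kind == "G":
            self.G0[ij] = val
        elif kind == "K":
            self.K0[ij] = val
        elif kind == "th":
            self.th0[ij[0]] = val

    def matrices(self, theta: np.ndarray):
        L, B = self.L0.copy(), self.B0.copy()
        G, K, th = self.G0.copy(), self.K0.copy(), self.th0.copy()
        for val, (kind, i, j) in zip(theta, self.slots):
            if kind == "L":
                L[i, j] = val
            elif kind == "B":
                B[i, j] = val
            elif kind == "G":
                G[i, j] = val
            elif kind == "K":
                K[i, j] = val
            else:
                th[i] = val
        return L, B, G, K, th

    def extract(self, gL, gB, gG, gK, gth) -> np.ndarray:
        out = np.empty(self.n_free)
        for a, (kind, i, j) in enumerate(self.slots):
            if kind == "L":
                out[a] = gL[i, j]
            elif kind == "B":
                out[a] = gB[i, j]
            elif kind == "G":
                out[a] = gG[i, j]
            elif kind == "K":
                out[a] = gK[i, j]
            else:
                out[a] = gth[i]
        return out


# ---------------------------------------------------------------------------
# result container


@dataclass
class FitResult:
    """Estimates and diagnostics of one fitted model."""

    spec: ModelSpec
    estimator: str
    params: pd.DataFrame  # name, estimate, se, z, pvalue, std_estimate
    stat: float
    df: int
    pvalue: float
    n: float
    converged: bool
    stat_raw: float = None  # unscaled statistic (equals stat for ML)
    scale_factor: float = 1.0
    cfi: float = np.nan
    rmsea: float = np.nan
    srmr: float = np.nan
    baseline_stat: float = np.nan
    baseline_df: int = 0
    heywood: tuple[str, ...] = ()
    vcov: np.ndarray | None = None
    n_pair: np.ndarray | None = None
    discrepancy: float = np.nan

    def __post_init__(self):
        if self.stat_raw is None:
            self.stat_raw = self.stat

    def estimate(self, name: str) -> float:
        row = self.params.loc[self.params["name"] == name]
        if row.empty:
            return self.spec.value_of(name)
        return float(row["estimate"].iloc[0])

    def p_of(self, name: str) -> float:
        row = self.params.loc[self.params["name"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["pvalue"].iloc[0])

    def wald_joint(self, names: list[str]) -> tuple[float, int, float]:
        """Joint Wald test that the named free parameters are all 0."""
        if self.vcov is None:
            raise ValueError("no parameter covariance available")
        order = list(self.params["name"])
        ix = [order.index(n) for n in names]
        b = self.params["estimate"].to_numpy()[ix]
        V = self.vcov[np.ix_(ix, ix)]
        stat = float(b @ np.linalg.solve(V, b))
        return stat, len(ix), float(chi2.sf(stat, len(ix)))

    def param_table(self) -> pd.DataFrame:
        return self.params.copy()


def _param_frame(names, est, se, std) -> pd.DataFrame:
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    pv = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "name": names,
            "estimate": est,
            "se": se,
            "z": z,
            "pvalue": pv,
            "std_estimate": std,
        }
    )


def _standardize(cm: CompiledModel, L, B, G, K, th, Phi):
    """Standardized solution from model-implied (co)variances."""
    M = np.eye(cm.nf) + B
    Vf = M @ (G @ Phi @ G.T + np.eye(cm.nf)) @ M.T
    sd_f = np.sqrt(np.clip(np.diag(Vf), 1e-12, None))
    LM = L @ M
    Pi = LM @ G + K
    item_var = np.diag(Pi @ Phi @ Pi.T + LM @ LM.T) + th
    sd_y = np.sqrt(np.clip(item_var, 1e-12, None))
    sd_x = np.sqrt(np.clip(np.diag(Phi), 1e-12, None))

    def std_of(kind, i, j, val):
        if kind == "L":
            return val * sd_f[j] / sd_y[i]
        if kind == "B":
            return val * sd_f[j] / sd_f[i]
        if kind == "G":
            return val * sd_x[j] / sd_f[i]
        if kind == "K":
            return val * sd_x[j] / sd_y[i]
        return val / item_var[i]  # residual variance proportion

    return std_of


def _fit_measures(stat, df, base_stat, base_df, n):
    delta = max(stat - df, 0.0)
    delta_b = max(base_stat - base_df, 0.0)
    cfi = 1.0 - delta / max(delta_b, delta, 1e-12) if (delta_b or delta) else 1.0
    cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = float(np.sqrt(delta / (df * max(n, 2.0)))) if df > 0 else 0.0
    return cfi, rmsea


def _minimize(cm: CompiledModel, fun, rng_seed: int = 0):
    """L-BFGS with bounded residual variances and random restarts."""
    bounds = [(lo if np.isfinite(lo) else None, None) for lo in cm.lower]
    best = None
    theta0 = cm.start.copy()
    rng = np.random.default_rng(rng_seed)
    for attempt in range(4):
        res = optimize.minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 3000, "ftol": 1e-12, "gtol": 1e-7},
        )
        ok = res.success or res.status == 0 or np.max(np.abs(res.jac)) < 1e-4
        if best is None or res.fun < best.fun:
            best, best_ok = res, ok
        if ok:
            return res, True
        theta0 = cm.start + 0.1 * rng.standard_normal(cm.n_free)
        theta0 = np.maximum(theta0, cm.lower + 1e-3)
        logger.warning("optimizer restart %d", attempt + 1)
    return best, best_ok


def _numeric_hessian(fun_grad, theta, h: float = 1e-5) -> np.ndarray:
    _, g0 = fun_grad(theta)
    H = np.empty((theta.size, theta.size))
    for i in range(theta.size):
        step = h * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += step
        _, gp = fun_grad(tp)
        H[:, i] = (gp - g0) / step
    return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# maximum likelihood (continuous indicators, fixed-x)


def fit_ml_continuous(
    spec: ModelSpec,
    data: pd.DataFrame,
    compute_se: bool = True,
) -> FitResult:
    """Normal-theory ML fit on continuous indicators.

    ``data`` must contain every item column of the spec's structure and
    every exogenous column.  Rows with missing values are handled by
    pairwise-complete covariance; the effective n is the mean pairwise
    count.
    """
    cm = CompiledModel(spec, include_theta=True)
    cols = cm.items + cm.exog
    sub = data[cols].astype(float)
    if sub.isna().any().any():
        S_full = sub.cov(min_periods=2).to_numpy() * 1.0
        notna = (~sub.isna()).to_numpy().astype(float)
        n_eff = float((notna.T @ notna).mean())
    else:
        arr = sub.to_numpy()
        arr = arr - arr.mean(axis=0)
        S_full = arr.T @ arr / len(arr)
        n_eff = float(len(arr))
    p, k = cm.p, cm.k
    S_yy = S_full[:p, :p]
    S_yx = S_full[:p, p:]
    S_xx = S_full[p:, p:]
    if k:
        Sxx_inv = np.linalg.inv(S_xx)
        S_c = S_yy - S_yx @ Sxx_inv @ S_yx.T
    else:
        S_c = S_yy
    sign, logdet_Sc = np.linalg.slogdet(S_c)
    if sign <= 0:
        raise ValueError("sample conditional covariance is singular")

    I_nf = np.eye(cm.nf)

    def fun(theta):
        L, B, G, K, th = cm.matrices(theta)
        M = I_nf + B
        LM = L @ M
        MG = M @ G
        Pi = L @ MG + K
        Omega = LM @ LM.T + np.diag(th)
        try:
            c, low = cho_factor(Omega, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(cm.n_free)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Oi = cho_solve((c, low), np.eye(p), check_finite=False)
        if k:
            C = S_yy - Pi @ S_yx.T - S_yx @ Pi.T + Pi @ S_xx @ Pi.T
        else:
            C = S_yy
        F = logdet + float(np.sum(Oi * C)) - logdet_Sc - p
        Gm = Oi - Oi @ C @ Oi
        if k:
            Pg = 2.0 * Oi @ (Pi @ S_xx - S_yx)
        else:
            Pg = np.zeros((p, 0))
        gL = 2.0 * Gm @ LM @ M.T + Pg @ MG.T
        gB = 2.0 * L.T @ Gm @ LM + L.T @ Pg @ G.T
        gG = LM.T @ Pg
        gK = Pg
        gth = np.diag(Gm)
        return F, cm.extract(gL, gB, gG, gK, gth)

    res, converged = _minimize(cm, fun, rng_seed=p + k)
    theta = res.x
    L, B, G, K, th = cm.matrices(theta)
    heywood = tuple(
        name
        for name, (kind, i, j) in zip(cm.names, cm.slots)
        if kind == "th" and theta[cm.names.index(name)] <= 2e-6
    )
    if heywood:
        logger.warning("Heywood cases bounded at 0: %s", heywood)

    n = n_eff
    F_min = max(float(res.fun), 0.0)
    stat = n * F_min
    n_moments = p * (p + 1) // 2 + p * k
    df = n_moments - cm.n_free
    pvalue = float(chi2.sf(stat, df)) if df > 0 else 1.0

    # baseline independence model (diagonal Omega, Pi = 0)
    base_F = float(np.sum(np.log(np.diag(S_yy)))) - logdet_Sc
    base_stat = n * max(base_F, 0.0)
    base_df = n_moments - p

    # SRMR on the correlation-metric residuals of modelled moments
    Phi = S_xx
    M = I_nf + B
    LM = L @ M
    Pi = LM @ G + K
    Omega = LM @ LM.T + np.diag(th)
    imp_yy = Omega + (Pi @ Phi @ Pi.T if k else 0.0)
    imp_yx = Pi @ Phi if k else np.zeros((p, 0))
    sd = np.sqrt(np.clip(np.diag(S_yy), 1e-12, None))
    sdx = np.sqrt(np.clip(np.diag(S_xx), 1e-12, None)) if k else np.empty(0)
    ry = (S_yy - imp_yy) / np.outer(sd, sd)
    resids = [ry[np.tril_indices(p)]]
    if k:
        resids.append(((S_yx - imp_yx) / np.outer(sd, sdx)).ravel())
    srmr = float(np.sqrt(np.mean(np.concatenate(resids) ** 2)))

    if compute_se and cm.n_free:
        H = _numeric_hessian(fun, theta)
        try:
            vcov = 2.0 / n * np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            vcov = np.full((cm.n_free, cm.n_free), np.nan)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    else:
        vcov = None
        se = np.full(cm.n_free, np.nan)

    std_of = _standardize(cm, L, B, G, K, th, Phi if k else np.zeros((0, 0)))
    std = [std_of(kind, i, j, v) for v, (kind, i, j) in zip(theta, cm.slots)]
    params = _param_frame(cm.names, theta, se, std)

    cfi, rmsea = _fit_measures(stat, df, base_stat, base_df, n)
    return FitResult(
        spec=spec,
        estimator="ml_continuous",
        params=params,
        stat=stat,
        df=df,
        pvalue=pvalue,
        n=n,
        converged=bool(converged),
        cfi=cfi,
        rmsea=rmsea,
        srmr=srmr,
        baseline_stat=base_stat,
        baseline_df=base_df,
        heywood=heywood,
        vcov=vcov,
        discrepancy=F_min,
    )


# ---------------------------------------------------------------------------
# DWLS on polychoric correlations


def fit_dwls(spec: ModelSpec, poly) -> FitResult:
    """Diagonally weighted least squares on a PolychoricSet.

    The weight of each moment is the inverse of its estimated sampling
    variance (per-pair observed information), so the minimized
    discrepancy is already on the chi-square scale.  The asymptotic
    covariance of the moment vector is approximated by its diagonal;
    robust standard errors and the mean-and-variance adjustment are
    computed under that approximation.
    """
    cm = CompiledModel(spec, include_theta=False)
    poly_items = list(poly.item_names)
    poly_exog = list(poly.exog_names)
    if set(cm.items) - set(poly_items):
        raise ValueError("polychoric set lacks required items")
    if set(cm.exog) - set(poly_exog):
        raise ValueError("polychoric set lacks required exogenous columns")
    ix = [poly_items.index(i) for i in cm.items] + [
        len(poly_items) + poly_exog.index(e) for e in cm.exog
    ]
    R = poly.R[np.ix_(ix, ix)]
    W = poly.asyvar[np.ix_(ix, ix)]
    npair = poly.n_pair[np.ix_(ix, ix)]
    p, k = cm.p, cm.k
    R_yy, R_yx, Phi = R[:p, :p], R[:p, p:], R[p:, p:]
    Wyy_inv = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    Wyy_inv[iu] = 1.0 / W[:p, :p][iu]
    Wyy_inv = Wyy_inv + Wyy_inv.T
    Wyx_inv = 1.0 / W[:p, p:] if k else np.zeros((p, 0))

    I_nf = np.eye(cm.nf)

    def implied(theta):
        L, B, G, K, _ = cm.matrices(theta)
        M = I_nf + B
        LM = L @ M
        Pi = LM @ G + K
        Syy = LM @ LM.T + (Pi @ Phi @ Pi.T if k else 0.0)
        Syx = Pi @ Phi if k else np.zeros((p, 0))
        return Syy, Syx, (L, B, G, K, M, LM, Pi)

    def fun(theta):
        Syy, Syx, (L, B, G, K, M, LM, Pi) = implied(theta)
        Eyy = R_yy - Syy
        Eyx = R_yx - Syx
        F = 0.5 * float(np.sum(Wyy_inv * Eyy**2))
        if k:
            F += float(np.sum(Wyx_inv * Eyx**2))
        Gm = -Wyy_inv * Eyy  # symmetric, zero diagonal
        H = -2.0 * Wyx_inv * Eyx if k else np.zeros((p, 0))
        if k:
            Pg = 2.0 * Gm @ Pi @ Phi + H @ Phi
        else:
            Pg = np.zeros((p, 0))
        MG = M @ G
        gL = 2.0 * Gm @ LM @ M.T + Pg @ MG.T
        gB = 2.0 * L.T @ Gm @ LM + L.T @ Pg @ G.T
        gG = LM.T @ Pg
        gK = Pg
        return F, cm.extract(gL, gB, gG, gK, np.zeros(p))

    res, converged = _minimize(cm, fun, rng_seed=p + k + 1)
    theta = res.x
    L, B, G, K, _ = cm.matrices(theta)

    # derived residual variances (delta parameterization) + Heywood guard
    M = I_nf + B
    LM = L @ M
    Pi = LM @ G + K
    common = np.diag(LM @ LM.T + (Pi @ Phi @ Pi.T if k else 0.0))
    th = 1.0 - common
    heywood = tuple(
        item for item, t in zip(cm.items, th) if t < 0
    )
    if heywood:
        logger.warning("negative derived residual variances (Heywood): %s", heywood)
        th = np.clip(th, 0.0, None)

    # the minimized value already sums over unique moments (the 1/2 on the
    # yy block undoes the symmetric double count); recompute for clarity
    Syy, Syx, _ = implied(theta)
    F_unique = float(
        np.sum((Wyy_inv * (R_yy - Syy) ** 2)[iu])
    ) + (float(np.sum(Wyx_inv * (R_yx - Syx) ** 2)) if k else 0.0)
    stat = F_unique
    n_moments = p * (p - 1) // 2 + p * k
    df = n_moments - cm.n_free
    pvalue = float(chi2.sf(stat, df)) if df > 0 else 1.0
    n = float(npair[np.triu_indices(p + k, 1)].mean()) if p + k > 1 else 0.0

    base_stat = float(np.sum((Wyy_inv * R_yy**2)[iu])) + (
        float(np.sum(Wyx_inv * R_yx**2)) if k else 0.0
    )
    base_df = n_moments

    resids = [(R_yy - Syy)[iu]]
    if k:
        resids.append((R_yx - Syx).ravel())
    srmr = float(np.sqrt(np.mean(np.concatenate(resids) ** 2)))

    # WLS information under the diagonal-Gamma approximation
    if cm.n_free:
        Delta = _moment_jacobian(cm, implied, theta, iu, k)
        w_vec = np.concatenate(
            [W[:p, :p][iu]] + ([W[:p, p:].ravel()] if k else [])
        )
        A = Delta.T @ (Delta / w_vec[:, None])
        try:
            vcov = np.linalg.pinv(A)
        except np.linalg.LinAlgError:
            vcov = np.full((cm.n_free, cm.n_free), np.nan)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    else:
        vcov, se = None, np.empty(0)

    std_of = _standardize(cm, L, B, G, K, th, Phi if k else np.zeros((0, 0)))
    std = [std_of(kind, i, j, v) for v, (kind, i, j) in zip(theta, cm.slots)]
    params = _param_frame(cm.names, theta, se, std)

    cfi, rmsea = _fit_measures(stat, df, base_stat, base_df, n)
    return FitResult(
        spec=spec,
        estimator="dwls_ordinal",
        params=params,
        stat=stat,
        df=df,
        pvalue=pvalue,
        n=n,
        converged=bool(converged),
        cfi=cfi,
        rmsea=rmsea,
        srmr=srmr,
        baseline_stat=base_stat,
        baseline_df=base_df,
        heywood=heywood,
        vcov=vcov,
        n_pair=npair,
        discrepancy=float(res.fun),
    )


def _moment_jacobian(cm, implied, theta, iu, k) -> np.ndarray:
    """Finite-difference Jacobian of the unique implied moments."""

    def moments(t):
        Syy, Syx, _ = implied(t)
        parts = [Syy[iu]]
        if k:
            parts.append(Syx.ravel())
        return np.concatenate(parts)

    m0 = moments(theta)
    J = np.empty((m0.size, theta.size))
    h = 1e-6
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += h
        J[:, i] = (moments(tp) - m0) / h
    return J
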