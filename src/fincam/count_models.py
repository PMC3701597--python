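"""Factorial count models with a log-volume offset, and power analysis.

Fish counts per 10-minute tow are modelled on the log scale as a
function of the three two-level study factors — tide T (flood/ebb),
horizontal position H (center/side) and vertical stratum V
(upper/lower) — with log filtered volume as an offset, so coefficients
describe density rather than raw catch.  Four families are fitted:

* Poisson (Var = mu),
* quasi-Poisson (Var = phi * mu; same mean fit as Poisson, inflated
  standard errors, no likelihood and hence no AIC),
* negative binomial NB2 (Var = mu * (1 + mu / theta); the overdispersion
  multiplier conventionally reported is 1/theta),
* zero-inflated negative binomial (mixture pi * I{0} + (1 - pi) * NB2
  with an intercept-only logit for pi, so a single zero-inflation
  probability applies across treatments).

All likelihood fits are direct maximizations of the exact
log-likelihood written out in this module (Newton/IRLS for Poisson,
L-BFGS-B with analytic gradients for NB and ZINB); AIC = 2k - 2 logL
with k counting every estimated parameter.  Model choice uses the
smallest-AIC rule with differences of 2 or less flagged as negligible
(prefer the simpler model), and the (y - mu)^2 vs mu scatter is exposed
to distinguish the linear quasi-Poisson from the quadratic NB variance
function.

The power analysis reconstructs the design adequacy calculation for a
2^3 factorial with n replicates per cell: exact noncentral-t power for
pairwise count differences, plus a seeded Monte-Carlo power of the
global F-test for arbitrary cell-mean configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

FORMULAS = ("intercept", "main", "two_way", "three_way")
Family = Literal["poisson", "quasipoisson", "negbin", "zinb"]

#: reference levels: coefficients measure flood, side and lower effects
REFERENCE_LEVELS = {"T": "ebb", "H": "center", "V": "upper"}
_NONREF = {"T": "flood", "H": "side", "V": "lower"}

#: theta is capped here; hitting the cap flags Poisson-like data
THETA_CAP = 1e4

AIC_NEGLIGIBLE = 2.0


# -- design matrices --------------------------------------------------------

def _indicator(data: pd.DataFrame, factor: str) -> np.ndarray:
    col = data[factor].astype(str)
    levels = {REFERENCE_LEVELS[factor], _NONREF[factor]}
    unknown = set(col.unique()) - levels
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} for factor {factor}")
    return (col == _NONREF[factor]).to_numpy(dtype=float)


def design_matrix(data: pd.DataFrame, formula: str = "main",
                  drop_constant: bool = False):
    """Treatment-coded design matrix for the nested factorial formulas.

    ``main`` is H+V+T (4 columns incl. intercept), ``two_way`` adds the
    three pairwise interactions (7), ``three_way`` the triple (8);
    ``intercept`` is the null model.  Reference levels are ebb / center
    / upper, so e.g. the tide column is the flood effect.  With
    ``drop_constant`` a factor taking a single level in the data is
    excluded (together with its interactions) instead of producing a
    rank-deficient matrix; a full 2^3 design is never affected.
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    if formula == "intercept":
        return np.column_stack(cols), names
    ind = {f: _indicator(data, f) for f in ("H", "V", "T")}
    active = [f for f in ("H", "V", "T")
              if not (drop_constant and len(set(ind[f])) == 1)]
    label = {"H": "H[side]", "V": "V[lower]", "T": "T[flood]"}
    for f in active:
        cols.append(ind[f])
        names.append(label[f])
    if formula in ("two_way", "three_way"):
        for a, b in (("H", "V"), ("H", "T"), ("V", "T")):
            if a in active and b in active:
                cols.append(ind[a] * ind[b])
                names.append(f"{a}:{b}")
    if formula == "three_way" and len(active) == 3:
        cols.append(ind["H"] * ind["V"] * ind["T"])
        names.append("H:V:T")
    return np.column_stack(cols), names


# -- fit container ----------------------------------------------------------

@dataclass
class CountModelFit:
    family: str
    formula: str
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float | None
    k: int
    aic: float | None
    mu: np.ndarray
    n: int
    dispersion: float | None = None     # phi (quasi-Poisson only)
    theta: float | None = None          # NB / ZINB
    pi: float | None = None             # ZINB zero-inflation probability
    gamma: float | None = None          # ZINB logit intercept
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    data_signature: tuple = ()
    se_df: int | None = None            # t df for quasi Wald tests

    @property
    def overdispersion_multiplier(self) -> float | None:
        """1/theta, the conventionally reported NB variance multiplier."""
        return None if self.theta is None else 1.0 / self.theta

    def variance_form(self) -> str:
        if self.family == "poisson":
            return "mu"
        if self.family == "quasipoisson":
            return f"{self.dispersion:.1f}*mu"
        if self.family == "negbin":
            return f"mu*(1 + mu*{1 / self.theta:.1f})"
        return (f"{self.pi:.2f} zero-mass + "
                f"mu*(1 + mu*{1 / self.theta:.1f})")


def _signature(y: np.ndarray, volume: np.ndarray) -> tuple:
    return (len(y), int(y.sum()), float(np.round(volume.sum(), 6)))


def _prepare(data: pd.DataFrame, formula: str):
    y = data["y"].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integers")
    volume = data["volume_m3"].to_numpy(dtype=float)
    if (volume <= 0).any():
        raise ValueError("volumes must be positive")
    X, names = design_matrix(data, formula, drop_constant=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient for this formula")
    return y, np.log(volume), X, names


# -- Poisson ----------------------------------------------------------------

def _poisson_loglik(y, offset, X, beta):
    eta = offset + X @ beta
    mu = np.exp(eta)
    return float(np.sum(y * eta - mu - special.gammaln(y + 1)))


def fit_poisson(data: pd.DataFrame, formula: str = "main",
                tol: float = 1e-8, max_iter: int = 100) -> CountModelFit:
    """Log-linear Poisson MLE with log-volume offset (Newton iteration).

    Convergence is declared when the score norm drops below ``tol``.
    Degenerate data (e.g. all-zero counts, where the intercept diverges
    to -inf) are flagged rather than silently returned.
    """
    y, offset, X, names = _prepare(data, formula)
    n, p = X.shape
    beta = np.zeros(p)
    # sensible intercept start: overall log rate
    beta[0] = np.log(max(y.mean(), 1e-8)) - np.log(np.exp(offset).mean())
    flags, converged = [], False
    if y.sum() == 0:
        flags.append("divergence: all counts zero, intercept -> -inf")
    for _ in range(max_iter):
        mu = np.exp(offset + X @ beta)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        info = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        # dampen very large steps
        if np.max(np.abs(step)) > 10:
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            flags.append("divergence: coefficient escaping to +/- inf")
            break
    if not converged and not flags:
        flags.append("not converged")
    mu = np.exp(offset + X @ beta)
    info = X.T @ (X * mu[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    ll = _poisson_loglik(y, offset, X, beta)
    return CountModelFit(
        family="poisson", formula=formula,
        coef=dict(zip(names, beta)), se=dict(zip(names, se)),
        loglik=ll, k=p, aic=2 * p - 2 * ll, mu=mu, n=n,
        converged=converged, flags=flags,
        data_signature=_signature(y, np.exp(offset)),
    )


def fit_quasipoisson(data: pd.DataFrame, formula: str = "main") -> CountModelFit:
    """Quasi-Poisson: Poisson mean fit, Pearson dispersion, scaled SEs.

    beta is identical to the Poisson fit; phi = Pearson X^2 / (n - p);
    standard errors are the Poisson ones times sqrt(phi) and Wald tests
    use a t reference with n - p degrees of freedom.  No likelihood
    exists for the quasi family, so loglik and AIC are absent.
    """
    base = fit_poisson(data, formula)
    y = data["y"].to_numpy(dtype=float)
    n, p = base.n, base.k
    if n <= p:
        raise ValueError(f"need n > p for dispersion estimation (n={n}, p={p})")
    pearson = float(np.sum((y - base.mu) ** 2 / base.mu))
    phi = pearson / (n - p)
    return CountModelFit(
        family="quasipoisson", formula=formula,
        coef=dict(base.coef),
        se={k: v * np.sqrt(phi) for k, v in base.se.items()},
        loglik=None, k=p, aic=None, mu=base.mu, n=n,
        dispersion=phi, converged=base.converged, flags=list(base.flags),
        data_signature=base.data_signature, se_df=n - p,
    )


# -- negative binomial ------------------------------------------------------

def _nb_loglik_terms(y, mu, theta):
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu)))


def nb_loglik(y, offset, X, beta, theta) -> float:
    """NB2 log-likelihood at arbitrary parameters (for oracle checks)."""
    mu = np.exp(np.asarray(offset) + np.asarray(X) @ np.asarray(beta))
    return float(np.sum(_nb_loglik_terms(np.asarray(y, float), mu, theta)))


def _nb_negll_grad(params, y, offset, X):
    p = X.shape[1]
    beta, logtheta = params[:p], params[p]
    theta = np.exp(logtheta)
    mu = np.exp(offset + X @ beta)
    ll = np.sum(_nb_loglik_terms(y, mu, theta))
    gbeta = X.T @ ((y - mu) * theta / (theta + mu))
    glogtheta = theta * np.sum(
        special.digamma(y + theta) - special.digamma(theta)
        + np.log(theta / (theta + mu)) + 1 - (y + theta) / (theta + mu)
    )
    return -ll, -np.concatenate([gbeta, [glogtheta]])


def _numeric_hessian(fun, x, eps=1e-5):
    """Central-difference Hessian of a scalar function via its gradient."""
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps * max(1.0, abs(x[i]))
        _, gp = fun(x + e)
        _, gm = fun(x - e)
        H[i] = (gp - gm) / (2 * e[i])
    return (H + H.T) / 2


def fit_negbin(data: pd.DataFrame, formula: str = "main",
               tol: float = 1e-8) -> CountModelFit:
    """Joint MLE of (beta, theta) for NB2 with log-volume offset.

    Variance function mu * (1 + mu / theta); theta is capped at
    :data:`THETA_CAP` and a cap hit (or theta >= 100) flags the data as
    Poisson-like.  Standard errors come from the observed information.
    """
    y, offset, X, names = _prepare(data, formula)
    n, p = X.shape
    pois = fit_poisson(data, formula)
    mu0 = pois.mu
    # method-of-moments start for theta
    excess = max(np.mean((y - mu0) ** 2 - mu0), 1e-3)
    theta0 = float(np.clip(np.mean(mu0 ** 2) / excess, 1e-2, THETA_CAP / 10))
    x0 = np.concatenate([list(pois.coef.values()), [np.log(theta0)]])
    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(THETA_CAP))]
    res = optimize.minimize(
        _nb_negll_grad, x0, args=(y, offset, X), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": tol},
    )
    beta, theta = res.x[:p], float(np.exp(res.x[p]))
    flags = []
    if theta >= 0.99 * THETA_CAP:
        flags.append("theta capped: data are Poisson-like")
    elif theta >= 100:
        flags.append("theta large: data are Poisson-like")
    if not res.success and "theta capped" not in " ".join(flags):
        flags.append(f"optimizer: {res.message}")
    mu = np.exp(offset + X @ beta)
    H = _numeric_hessian(lambda x: _nb_negll_grad(x, y, offset, X), res.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    ll = float(-res.fun)
    k = p + 1
    return CountModelFit(
        family="negbin", formula=formula,
        coef=dict(zip(names, beta)), se=dict(zip(names, se)),
        loglik=ll, k=k, aic=2 * k - 2 * ll, mu=mu, n=n,
        theta=theta, converged=bool(res.success), flags=flags,
        data_signature=_signature(y, np.exp(offset)),
    )


# -- zero-inflated negative binomial ---------------------------------------

def zinb_loglik(y, offset, X, beta, theta, gamma) -> float:
    """ZINB mixture log-likelihood at arbitrary parameters."""
    y = np.asarray(y, float)
    mu = np.exp(np.asarray(offset) + np.asarray(X) @ np.asarray(beta))
    pi = special.expit(gamma)
    log_p0 = theta * np.log(theta / (theta + mu))
    zero = y == 0
    ll = 0.0
    if zero.any():
        ll += float(np.sum(np.logaddexp(np.log(pi + 1e-300),
                                        np.log1p(-pi) + log_p0[zero])))
    if (~zero).any():
        ll += float(np.sum(np.log1p(-pi)
                           + _nb_loglik_terms(y[~zero], mu[~zero], theta)))
    return ll


def _zinb_negll_grad(params, y, offset, X):
    p = X.shape[1]
    beta, logtheta, gamma = params[:p], params[p], params[p + 1]
    theta = np.exp(logtheta)
    pi = special.expit(gamma)
    mu = np.exp(offset + X @ beta)
    zero = y == 0
    log_p0 = theta * np.log(theta / (theta + mu))
    p0 = np.exp(log_p0)

    ll = 0.0
    gbeta = np.zeros(p)
    glogtheta = 0.0
    ggamma = 0.0

    if zero.any():
        mz, p0z = mu[zero], p0[zero]
        A = pi + (1 - pi) * p0z
        ll += float(np.sum(np.log(A)))
        # d log A / d beta_j
        dlnp0_dbeta = -theta * mz / (theta + mz)          # times x_ij
        w = (1 - pi) * p0z * dlnp0_dbeta / A
        gbeta += X[zero].T @ w
        dlnp0_dlogtheta = theta * (np.log(theta / (theta + mz))
                                   + 1 - theta / (theta + mz))
        glogtheta += float(np.sum((1 - pi) * p0z * dlnp0_dlogtheta / A))
        ggamma += float(np.sum(pi * (1 - pi) * (1 - p0z) / A))

    if (~zero).any():
        yp, mp = y[~zero], mu[~zero]
        ll += float(np.sum(np.log1p(-pi) + _nb_loglik_terms(yp, mp, theta)))
        gbeta += X[~zero].T @ ((yp - mp) * theta / (theta + mp))
        glogtheta += theta * float(np.sum(
            special.digamma(yp + theta) - special.digamma(theta)
            + np.log(theta / (theta + mp)) + 1 - (yp + theta) / (theta + mp)
        ))
        ggamma += -pi * float(np.sum(~zero))

    return -ll, -np.concatenate([gbeta, [glogtheta, ggamma]])


def fit_zinb(data: pd.DataFrame, formula: str = "main",
             tol: float = 1e-8) -> CountModelFit:
    """MLE of the ZINB mixture: NB2 counts + intercept-only logit zero
    model, maximized numerically from several starts.

    pi = expit(gamma) is the probability of the degenerate zero
    component; the total zero probability additionally includes NB
    zeros, pi + (1 - pi) * (theta/(theta+mu))^theta.
    """
    y, offset, X, names = _prepare(data, formula)
    n, p = X.shape
    zero_frac = float(np.mean(y == 0))
    if zero_frac == 1.0:
        raise ValueError("all counts are zero: ZINB mean model unidentifiable")
    no_zeros = zero_frac == 0.0

    nb = fit_negbin(data, formula)
    nb_beta = np.array(list(nb.coef.values()))
    nb_p0 = float(np.mean((nb.theta / (nb.theta + nb.mu)) ** nb.theta))
    excess = np.clip(zero_frac - nb_p0, 1e-3, 1 - 1e-3)
    starts = [
        np.concatenate([nb_beta, [np.log(nb.theta)], [special.logit(excess)]]),
        np.concatenate([nb_beta, [np.log(max(nb.theta / 5, 0.05))], [0.0]]),
        np.concatenate([nb_beta, [0.0], [-2.0]]),
    ]
    bounds = ([(None, None)] * p
              + [(np.log(1e-4), np.log(THETA_CAP)), (-20.0, 20.0)])
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _zinb_negll_grad, x0, args=(y, offset, X), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[:p]
    theta = float(np.exp(best.x[p]))
    gamma = float(best.x[p + 1])
    pi = float(special.expit(gamma))
    flags = []
    if no_zeros:
        flags.append("no zeros in data: pi driven to 0")
    if theta >= 0.99 * THETA_CAP:
        flags.append("theta capped: count component Poisson-like")
    if not best.success:
        flags.append(f"optimizer: {best.message}")
    mu = np.exp(offset + X @ beta)
    H = _numeric_hessian(lambda x: _zinb_negll_grad(x, y, offset, X), best.x)
    se_all = np.full(p + 2, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se_all = np.sqrt(np.clip(d, 0, None))
    except np.linalg.LinAlgError:
        pass
    ll = float(-best.fun)
    k = p + 2                   # beta, theta, gamma
    return CountModelFit(
        family="zinb", formula=formula,
        coef=dict(zip(names, beta)), se=dict(zip(names, se_all[:p])),
        loglik=ll, k=k, aic=2 * k - 2 * ll, mu=mu, n=n,
        theta=theta, pi=pi, gamma=gamma,
        converged=bool(best.success), flags=flags,
        data_signature=_signature(y, np.exp(offset)),
    )


FIT_FUNCTIONS = {
    "poisson": fit_poisson,
    "quasipoisson": fit_quasipoisson,
    "negbin": fit_negbin,
    "zinb": fit_zinb,
}


def fit_family(data: pd.DataFrame, family: Family,
               formula: str = "main") -> CountModelFit:
    if family not in FIT_FUNCTIONS:
        raise ValueError(f"unknown family {family!r}")
    return FIT_FUNCTIONS[family](data, formula)


# -- model comparison & diagnostics -----------------------------------------

@dataclass
class ModelRanking:
    order: list[CountModelFit]
    negligible_pairs: list[tuple[str, str, float]]
    excluded: list[str]

    def summary(self) -> str:
        lines = []
        for f in self.order:
            lines.append(f"{f.family:12s} {f.formula:9s} AIC={f.aic:8.1f}  "
                         f"Var={f.variance_form()}")
        for a, b, d in self.negligible_pairs:
            lines.append(f"  {a} vs {b}: dAIC={d:.2f} <= {AIC_NEGLIGIBLE} — "
                         "negligible difference, prefer the simpler model")
        for note in self.excluded:
            lines.append(f"  excluded: {note}")
        return "\n".join(lines)


def compare_models(fits: list[CountModelFit]) -> ModelRanking:
    """Rank likelihood fits by AIC; quasi fits are excluded with a note.

    Quasi-likelihood AIC surrogates are of use only for comparing
    different quasi-Poisson models, never across families, so quasi
    fits never enter the ranking.  Pairs within 2 AIC units are flagged
    as a negligible difference (prefer the simpler model).
    """
    if not fits:
        raise ValueError("no fits to compare")
    sigs = {f.data_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("fits were computed on different datasets")
    excluded = [
        f"{f.family}/{f.formula} (quasi-Poisson has no likelihood; its "
        "QAIC compares only quasi-Poisson models)"
        for f in fits if f.aic is None
    ]
    ranked = sorted((f for f in fits if f.aic is not None), key=lambda f: f.aic)
    pairs = []
    for i, a in enumerate(ranked):
        for b in ranked[i + 1:]:
            d = b.aic - a.aic
            if d <= AIC_NEGLIGIBLE:
                pairs.append((f"{a.family}/{a.formula}",
                              f"{b.family}/{b.formula}", float(d)))
    return ModelRanking(order=ranked, negligible_pairs=pairs, excluded=excluded)


def dispersion_diagnostic(fit: CountModelFit,
                          data: pd.DataFrame) -> list[tuple[float, float]]:
    """(y - mu)^2 against mu, one pair per observation in row order.

    Plotting these pairs distinguishes the quasi-Poisson (linear in mu)
    from the negative binomial (quadratic) variance function.
    """
    y = data["y"].to_numpy(dtype=float)
    if len(y) != len(fit.mu):
        raise ValueError("data length does not match fitted means")
    return [(float((yi - mi) ** 2), float(mi)) for yi, mi in zip(y, fit.mu)]


def wald_tests(fit: CountModelFit) -> pd.DataFrame:
    """Per-coefficient Wald statistics, two-sided p-values and codes.

    z reference for likelihood fits, t with n - p df for quasi-Poisson.
    Codes: ' at 0.10, * at 0.05, ** at 0.01 (p strictly below the
    level; a p-value printing as 0.010 gets ** only if p < 0.01).
    """
    rows = []
    for name in fit.coef:
        b, s = fit.coef[name], fit.se[name]
        if not np.isfinite(s) or s == 0:
            rows.append({"coef": name, "estimate": b, "se": s,
                         "stat": np.nan, "p": np.nan, "code": "undefined"})
            continue
        stat = b / s
        if fit.se_df is not None:
            p = 2 * stats.t.sf(abs(stat), df=fit.se_df)
        else:
            p = 2 * stats.norm.sf(abs(stat))
        code = "**" if p < 0.01 else "*" if p < 0.05 else "'" if p < 0.10 else ""
        rows.append({"coef": name, "estimate": b, "se": s,
                     "stat": stat, "p": p, "code": code})
    return pd.DataFrame(rows)


# -- synthetic counts -------------------------------------------------------

def full_factorial_design(n_per_cell: int) -> pd.DataFrame:
    """Balanced 2^3 design table with ``n_per_cell`` rows per cell."""
    rows = []
    for t in ("ebb", "flood"):
        for h in ("center", "side"):
            for v in ("upper", "lower"):
                rows += [{"T": t, "H": h, "V": v}] * n_per_cell
    return pd.DataFrame(rows)


def simulate_counts(family: Family, beta: np.ndarray, design: pd.DataFrame,
                    volumes: np.ndarray, seed: int, theta: float | None = None,
                    pi: float | None = None,
                    formula: str = "main") -> pd.DataFrame:
    """Draw a synthetic count dataset from known truth.

    mu_i = volume_i * exp(x_i' beta); NB draws use the gamma-Poisson
    mixture, ZINB additionally zeroes each row with probability pi.
    Returns a dataset in the same layout the trawl pipeline produces.
    """
    rng = np.random.default_rng(seed)
    design = design.reset_index(drop=True)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 1:
        volumes = np.full(len(design), float(volumes))
    X, _ = design_matrix(design, formula)
    beta = np.asarray(beta, dtype=float)
    if beta.size != X.shape[1]:
        raise ValueError(f"beta length {beta.size} != design columns {X.shape[1]}")
    mu = volumes * np.exp(X @ beta)
    if family == "poisson" or family == "quasipoisson":
        y = rng.poisson(mu)
    elif family in ("negbin", "zinb"):
        if theta is None or theta <= 0:
            raise ValueError("negbin/zinb simulation requires theta > 0")
        lam = rng.gamma(shape=theta, scale=mu / theta)
        y = rng.poisson(lam)
        if family == "zinb":
            if pi is None or not 0 <= pi <= 1:
                raise ValueError("zinb simulation requires pi in [0, 1]")
            y = np.where(rng.random(len(y)) < pi, 0, y)
    else:
        raise ValueError(f"unknown family {family!r}")
    out = design.copy()
    out.insert(0, "y", y.astype(int))
    out.insert(1, "volume_m3", volumes)
    return out


# -- power ------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    n_per_group: int
    sd: float
    delta: float
    alpha: float = 0.05
    sidedness: str = "one"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        if self.sidedness == "one" and self.delta < 0:
            raise ValueError("one-sided power needs delta >= 0")


def power_pairwise(spec: PowerSpec) -> float:
    """Exact power of a two-sample t-test for a mean difference.

    Noncentrality delta / (sd * sqrt(2/n)), df = 2n - 2, evaluated with
    the noncentral-t distribution.  The one-sided test is the default
    because it is the design calculation consistent with detecting an
    excess catch in one treatment.
    """
    n, df = spec.n_per_group, 2 * spec.n_per_group - 2
    ncp = spec.delta / (spec.sd * np.sqrt(2.0 / n))
    if spec.sidedness == "one":
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_pairwise_mc(spec: PowerSpec, reps: int = 200_000,
                      seed: int = 0) -> float:
    """Monte-Carlo check of :func:`power_pairwise` (seeded)."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    a = rng.normal(0.0, spec.sd, size=(reps, n))
    b = rng.normal(spec.delta, spec.sd, size=(reps, n))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2)
    tstat = (b.mean(axis=1) - a.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
    df = 2 * n - 2
    if spec.sidedness == "one":
        reject = tstat > stats.t.ppf(1 - spec.alpha, df)
    else:
        reject = np.abs(tstat) > stats.t.ppf(1 - spec.alpha / 2, df)
    return float(reject.mean())


def power_factorial(n_per_cell: int, sd: float, cell_effects: np.ndarray,
                    alpha: float = 0.05, reps: int = 5_000,
                    seed: int = 0) -> float:
    """Monte-Carlo power of the global F-test in the 2^3 factorial.

    ``cell_effects`` are the 8 cell means (a zero vector is the null);
    each replicate draws normal data, fits the full cell-means model
    against the grand mean, and rejects when the F p-value < alpha.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable estimate")
    cell_effects = np.asarray(cell_effects, dtype=float)
    if cell_effects.shape != (8,):
        raise ValueError("cell_effects must have 8 entries (one per cell)")
    if n_per_cell < 2:
        raise ValueError("non-estimable design: need >= 2 replicates per cell")
    rng = np.random.default_rng(seed)
    N = 8 * n_per_cell
    df1, df2 = 7, N - 8
    fcrit = stats.f.ppf(1 - alpha, df1, df2)
    rejections = 0
    means = np.repeat(cell_effects, n_per_cell)
    for _ in range(reps):
        ysim = means + rng.normal(0.0, sd, size=N)
        cells = ysim.reshape(8, n_per_cell)
        cell_means = cells.mean(axis=1)
        rss1 = float(((cells - cell_means[:, None]) ** 2).sum())
        rss0 = float(((ysim - ysim.mean()) ** 2).sum())
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        if F > fcrit:
            rejections += 1
    return rejections / reps


# -- reporting --------------------------------------------------------------

def fit_report_json(fit: CountModelFit) -> str:
    return json.dumps({
        "family": fit.family, "formula": fit.formula,
        "coef": fit.coef, "se": fit.se,
        "loglik": fit.loglik, "k": fit.k, "aic": fit.aic,
        "dispersion": fit.dispersion, "theta": fit.theta, "pi": fit.pi,
        "converged": fit.converged, "flags": fit.flags,
    }, indent=2)


def model_table(fits_by_formula: dict[str, list[CountModelFit]]) -> str:
    """Plain-text summary table: formula x family, AIC / variance form /
    significant factors."""
    lines = []
    header = f"{'Factors':12s}" + "".join(f"{fam:>22s}" for fam in
                                          ("poisson", "quasipoisson",
                                           "negbin", "zinb"))
    lines.append(header)
    for formula, fits in fits_by_formula.items():
        by_fam = {f.family: f for f in fits}
        lines.append(formula)
        aic_row, var_row, sig_row = "  AIC   ", "  Var   ", "  Signif"
        for fam in ("poisson", "quasipoisson", "negbin", "zinb"):
            f = by_fam.get(fam)
            if f is None:
                aic_row += f"{'—':>22s}"
                var_row += f"{'—':>22s}"
                sig_row += f"{'—':>22s}"
                continue
            aic_row += f"{f.aic:>22.1f}" if f.aic is not None else f"{'NA':>22s}"
            var_row += f"{f.variance_form():>22s}"
            wt = wald_tests(f)
            sig = ",".join(
                f"{r.coef}{r.code}" for r in wt.itertuples()
                if r.code in ("'", "*", "**") and r.coef != "(Intercept)"
            ) or "–"
            sig_row += f"{sig:>22s}"
        lines += [aic_row, var_row, sig_row]
    return "\n".join(lines)
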