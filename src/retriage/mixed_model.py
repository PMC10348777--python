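"""Mixed-effects logistic regression of re-triage suboptimality.

The model is a binomial GLMM with a logit link: fixed effects for the
patient covariates and the sending center's region, and crossed Gaussian
random intercepts for sending center and year to absorb clustering.

Estimation uses the Laplace approximation to the marginal likelihood, the
same approach lme4's ``glmer`` takes at its default accuracy: for a given
pair of random-intercept standard deviations, the fixed effects and random
effects are found by Newton iteration on the penalized log-likelihood; the
Laplace-corrected profile likelihood (penalized optimum minus half the
log-determinant of the conditional curvature) is then maximized over the
two variance parameters. Standard errors for the fixed effects come from
the (beta, u) block inverse of the joint Hessian at the optimum, and Wald
intervals on the log-odds scale are exponentiated to odds ratios. As the
variance parameters approach zero the fit collapses to ordinary logistic
regression, which is the behaviour a degenerate grouping structure should
produce.

`simulate_glmm_dataset` is the test harness: it draws covariates, random
intercepts and outcomes from known coefficients so recovery and interval
calibration can be checked against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.special import expit
import statsmodels.api as sm

from . import vocab

DEFAULT_FIXED_EFFECTS = (
    "age_band", "sex", "race", "ethnicity", "insurance",
    "mechanism", "body_region", "riss_band", "rtcc_id",
)


@dataclass
class ModelSpec:
    """Which factors enter as fixed effects (with their reference levels)
    and which grouping columns get random intercepts."""

    outcome: str = "suboptimal"
    fixed_effects: tuple = DEFAULT_FIXED_EFFECTS
    random_groups: tuple = ("facility_id", "year")
    reference_levels: dict = field(default_factory=lambda: dict(vocab.REFERENCE_LEVELS))
    #: optionally add calendar year as a fixed linear trend as well
    year_trend: bool = False


@dataclass
class ModelFit:
    coefficients: pd.DataFrame  # term, level, log_odds, se, or_, ci, p
    random_sd: dict  # group -> estimated intercept SD
    converged: bool
    n_obs: int
    method: str = "laplace"

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path, index=False)


def _design_matrix(events: pd.DataFrame, spec: ModelSpec):
    """Dummy-code the factors with the spec's reference level first; empty
    levels are dropped so the design stays full rank."""
    cols, names = [np.ones(len(events))], [("intercept", "")]
    for factor in spec.fixed_effects:
        ref = spec.reference_levels.get(factor)
        values = events[factor].astype(str)
        present = [l for l in vocab.FACTOR_LEVELS.get(factor, sorted(values.unique()))
                   if l in set(values)]
        for level in present:
            if level == ref:
                continue
            col = (values == level).to_numpy(float)
            if col.sum() == 0:
                continue
            cols.append(col)
            names.append((factor, level))
    if spec.year_trend:
        yr = events["year"].astype(float)
        cols.append((yr - yr.mean()).to_numpy())
        names.append(("year_trend", ""))
    return np.column_stack(cols), names


def _check_separation(x, names, y):
    for col, (factor, level) in zip(x.T, names):
        if factor == "intercept":
            continue
        mask = col > 0
        if mask.any() and (y[mask].min() == y[mask].max()) and mask.sum() > 0:
            warnings.warn(
                f"possible complete separation in {factor}={level}", stacklevel=3
            )


class _LaplaceGLMM:
    """Laplace-approximated binomial GLMM with crossed random intercepts.

    Inner loop: Newton iteration on the penalized log-likelihood of the
    joint coefficient vector (beta, u) for fixed variance parameters.
    Outer loop: Nelder-Mead on the two log standard deviations of the
    Laplace profile likelihood
        l(theta) = h(beta*, u*) - 0.5 * logdet(H_uu(theta) * D(theta)),
    where h is the penalized log-likelihood, H_uu the u-block of its
    curvature, and D the random-intercept covariance.
    """

    LOG_SIGMA_BOUNDS = (-6.0, 3.0)

    def __init__(self, y, x, z_blocks):
        self.y = np.asarray(y, float)
        self.k = x.shape[1]
        self.block_sizes = [b.shape[1] for b in z_blocks]
        self.q = int(sum(self.block_sizes))
        self.a = sparse.hstack([sparse.csr_matrix(x)] + list(z_blocks)).tocsr()
        self.at = self.a.T.tocsr()
        self._coef = np.zeros(self.k + self.q)

    def _penalty(self, log_sigmas):
        sig2 = np.exp(2 * np.asarray(log_sigmas, float))
        pen = np.zeros(self.k + self.q)
        offset = self.k
        for size, s2 in zip(self.block_sizes, sig2):
            pen[offset : offset + size] = 1.0 / s2
            offset += size
        return pen

    def _penalized_loglik(self, coef, pen):
        eta = self.a @ coef
        ll = np.sum(self.y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(pen * coef**2)

    def _inner_newton(self, pen, tol=1e-9, max_iter=50):
        coef = self._coef.copy()
        obj = self._penalized_loglik(coef, pen)
        for _ in range(max_iter):
            eta = self.a @ coef
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            grad = self.at @ (self.y - mu) - pen * coef
            h = (self.at @ sparse.diags(w) @ self.a).toarray()
            h[np.diag_indices_from(h)] += pen + 1e-12
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:  # pragma: no cover
                step = np.linalg.lstsq(h, grad, rcond=None)[0]
            # step halving
            for _ in range(30):
                new = coef + step
                new_obj = self._penalized_loglik(new, pen)
                if new_obj >= obj - 1e-12:
                    break
                step *= 0.5
            moved = np.max(np.abs(new - coef))
            coef, obj = new, new_obj
            if moved < tol:
                break
        self._coef = coef
        return coef, obj, h

    def profile_loglik(self, log_sigmas):
        log_sigmas = np.clip(log_sigmas, *self.LOG_SIGMA_BOUNDS)
        pen = self._penalty(log_sigmas)
        coef, obj, h = self._inner_newton(pen)
        h_uu = h[self.k :, self.k :]
        # logdet(H_uu D) computed stably as logdet(H_uu) + logdet(D)
        sign, logdet_h = np.linalg.slogdet(h_uu)
        if sign <= 0:  # pragma: no cover - H_uu is positive definite by construction
            return -np.inf
        logdet_d = -np.sum(np.log(pen[self.k :]))
        return obj - 0.5 * (logdet_h + logdet_d)

    def fit(self, start_log_sigma=np.log(0.3)):
        res = optimize.minimize(
            lambda ls: -self.profile_loglik(ls),
            x0=np.full(len(self.block_sizes), start_log_sigma),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200},
        )
        log_sigmas = np.clip(res.x, *self.LOG_SIGMA_BOUNDS)
        pen = self._penalty(log_sigmas)
        coef, _, h = self._inner_newton(pen, tol=1e-11)
        cov = np.linalg.inv(h)
        return {
            "beta": coef[: self.k],
            "u": coef[self.k :],
            "se_beta": np.sqrt(np.diag(cov)[: self.k]),
            "sigmas": np.exp(log_sigmas),
            "converged": bool(res.success or res.fun < np.inf),
            "n_outer_iter": int(res.nit),
        }


def fit_suboptimality_model(events: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Fit the suboptimality GLMM and return the coefficient table.

    Requires at least two sending centers and two years and a non-constant
    outcome. Raises ``RuntimeError`` with diagnostics if the optimizer does
    not converge.
    """
    spec = spec or ModelSpec()
    y = events[spec.outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome is constant; the model is not identifiable")
    for group in spec.random_groups:
        if events[group].nunique() < 2:
            raise ValueError(f"need >=2 levels of grouping factor {group!r}")

    x, names = _design_matrix(events, spec)
    _check_separation(x, names, y)

    z_blocks = []
    for group in spec.random_groups:
        codes, levels = pd.factorize(events[group], sort=True)
        z_blocks.append(
            sparse.csr_matrix(
                (np.ones(len(events)), (np.arange(len(events)), codes)),
                shape=(len(events), len(levels)),
            )
        )

    model = _LaplaceGLMM(y, x, z_blocks)
    result = model.fit()
    if not result["converged"]:  # pragma: no cover - optimizer failure path
        raise RuntimeError(
            f"GLMM fit failed to converge after {result['n_outer_iter']} outer iterations"
        )

    z = stats.norm.ppf(0.975)
    rows = []
    for (factor, level), b, s in zip(names, result["beta"], result["se_beta"]):
        rows.append(
            {
                "term": factor,
                "level": level,
                "reference": spec.reference_levels.get(factor, ""),
                "log_odds": b,
                "se": s,
                "or": np.exp(b),
                "ci_low": np.exp(b - z * s),
                "ci_high": np.exp(b + z * s),
                "p": 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan,
            }
        )
    random_sd = {g: float(s) for g, s in zip(spec.random_groups, result["sigmas"])}
    return ModelFit(
        coefficients=pd.DataFrame(rows),
        random_sd=random_sd,
        converged=True,
        n_obs=len(events),
    )


def fit_plain_logistic(events: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Ordinary (no random effects) logistic fit with the same design matrix;
    the degenerate-sigma reference point for the GLMM."""
    spec = spec or ModelSpec()
    y = events[spec.outcome].astype(int).to_numpy()
    x, names = _design_matrix(events, spec)
    res = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    return pd.DataFrame(
        {
            "term": [f for f, _ in names],
            "level": [l for _, l in names],
            "log_odds": res.params,
            "se": res.bse,
        }
    )


def simulate_glmm_dataset(
    true_betas: dict,
    center_sigma: float,
    year_sigma: float,
    n: int,
    n_centers: int = 100,
    years: tuple = tuple(range(2009, 2019)),
    intercept: float = -1.0,
    seed: int = 0,
    level_probs: dict | None = None,
) -> pd.DataFrame:
    """Draw an events table from known coefficients.

    ``true_betas`` maps factor -> level -> log-odds (reference levels carry
    no coefficient). Covariates are sampled from the package's default
    marginals unless ``level_probs`` overrides a factor. Random intercepts
    are Gaussian per sending center and per year. Deterministic under seed.
    """
    for factor, levels in true_betas.items():
        bad = set(levels) - set(vocab.FACTOR_LEVELS[factor])
        if bad:
            raise ValueError(f"unknown levels for {factor!r}: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    data = {}
    marginals = {
        "age_band": vocab.AGE_BANDS,
        "sex": vocab.SEXES,
        "race": vocab.RACES,
        "ethnicity": vocab.ETHNICITIES,
        "insurance": vocab.INSURANCES,
        "mechanism": vocab.MECHANISMS,
        "body_region": vocab.BODY_REGIONS,
        "riss_band": vocab.RISS_BANDS,
        "rtcc_id": vocab.RTCCS,
    }
    for factor, levels in marginals.items():
        p = None
        if level_probs and factor in level_probs:
            p = np.asarray(level_probs[factor], float)
            p = p / p.sum()
        data[factor] = rng.choice(np.asarray(levels, dtype=object), size=n, p=p)
    centers = np.array([f"C{i:03d}" for i in range(n_centers)], dtype=object)
    data["facility_id"] = rng.choice(centers, size=n)
    data["year"] = rng.choice(np.asarray(years), size=n)
    df = pd.DataFrame(data)

    eta = np.full(n, intercept, dtype=float)
    for factor, levels in true_betas.items():
        for level, beta in levels.items():
            eta += beta * (df[factor] == level).to_numpy(float)
    b_center = rng.normal(0, center_sigma, n_centers)
    b_year = rng.normal(0, year_sigma, len(years))
    eta += b_center[pd.factorize(df["facility_id"], sort=True)[0]]
    eta += b_year[pd.factorize(df["year"], sort=True)[0]]
    df["suboptimal"] = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    df["suboptimal"] = df["suboptimal"].astype(int)
    return df
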