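"""Bite-force scaling: OLS prechecks and the hierarchical Bayesian allometry.

The hierarchical model works on the natural-log scale:

    ln(bite) = alpha_species + beta_sex * male + beta_head * ln(head_length)
               [+ beta_size * ln(mass or forearm)] + eps

with alpha_s ~ N(mu_alpha, sigma_between^2) and half-Cauchy priors on both
standard deviations, sampled through the inverse-gamma parameter-expansion
identity so every full conditional stays conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gjam import ess, hpd, psrf
from .io import ValidationError

HALF_CAUCHY_SCALE = 25.0  # weakly informative on the log-Newton scale
SLOPE_PRIOR_PRECISION = 1e-6

SIZE_COVARIATES = ("none", "ln_mass", "ln_forearm")


def _size_column(data: pd.DataFrame, size_covariate: str) -> np.ndarray | None:
    if size_covariate == "none":
        return None
    col = {"ln_mass": "mass", "ln_forearm": "forearm"}[size_covariate]
    v = data[col].to_numpy(float)
    if np.isnan(v).any() or (v <= 0).any():
        raise ValidationError(f"{col} must be present and positive to take logs")
    return np.log(v)


def fit_ols_precheck(
    data: pd.DataFrame,
    species_intercepts: bool = False,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Least-squares precheck: bite force on sex + head length (optionally per-species
    intercepts); returns coef, se, t, two-sided p and residual df per term.

    Uses the natural-log scale by default for consistency with the hierarchical
    model (set ``log_scale=False`` for raw-scale regressions).
    """
    y = data["max_bite_force"].to_numpy(float)
    head = data["head_length"].to_numpy(float)
    if log_scale:
        if (y <= 0).any() or (head <= 0).any():
            raise ValidationError("bite force and head length must be positive to log")
        y, head = np.log(y), np.log(head)
    male = (data["sex"] == "male").astype(float).to_numpy()
    cols = {"sex_male": male, "head_length": head}
    if species_intercepts:
        for sp in sorted(data["species"].unique()):
            cols[f"intercept_{sp}"] = (data["species"] == sp).astype(float).to_numpy()
        X = pd.DataFrame(cols)
    else:
        X = sm.add_constant(pd.DataFrame(cols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("collinear predictors in precheck design")
    if len(y) <= X.shape[1]:
        raise ValidationError("not enough rows for the precheck regression")
    res = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
            "df_resid": int(res.df_resid),
        }
    )


@dataclass
class BiteForcePosterior:
    """Draws from the hierarchical bite-force model plus convergence summaries."""

    species: list[str]
    alpha: np.ndarray          # (S, n_species)
    beta_sex: np.ndarray       # (S,)
    beta_head: np.ndarray      # (S,)
    beta_size: np.ndarray | None
    mu_alpha: np.ndarray       # (S,)
    sigma_between: np.ndarray  # (S,)
    sigma_within: np.ndarray   # (S,)
    chain_ids: np.ndarray
    size_covariate: str = "none"
    diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.beta_head.size

    def parameter_draws(self) -> dict[str, np.ndarray]:
        out = {f"alpha_{sp}": self.alpha[:, j] for j, sp in enumerate(self.species)}
        out.update(
            beta_sex=self.beta_sex,
            beta_head=self.beta_head,
            mu_alpha=self.mu_alpha,
            sigma_between=self.sigma_between,
            sigma_within=self.sigma_within,
        )
        if self.beta_size is not None:
            out["beta_size"] = self.beta_size
        return out

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, draws in self.parameter_draws().items():
            lo, hi = hpd(draws, prob)
            rows.append(
                {"parameter": name, "median": float(np.median(draws)),
                 "mean": float(draws.mean()), "hpd_lo": lo, "hpd_hi": hi}
            )
        return pd.DataFrame(rows)


def fit_hierarchical(
    data: pd.DataFrame,
    size_covariate: str = "none",
    n_iterations: int = 20_000,
    n_burnin: int = 5_000,
    thin: int = 10,
    n_chains: int = 4,
    seed: int = 0,
    prior_only: bool = False,
    half_cauchy_scale: float = HALF_CAUCHY_SCALE,
    force_sigma_between: float | None = None,
) -> BiteForcePosterior:
    """Gibbs sampler for the hierarchical allometry.

    ``prior_only=True`` ignores the data entirely and returns draws from the
    prior (used to validate the half-Cauchy construction).
    ``force_sigma_between`` pins the between-species sd instead of sampling it:
    a huge value reproduces independent per-species intercepts, a tiny value
    complete pooling.
    """
    if size_covariate not in SIZE_COVARIATES:
        raise ValidationError(f"size_covariate must be one of {SIZE_COVARIATES}")
    if prior_only:
        return _prior_only_run(n_iterations, n_burnin, thin, n_chains, seed,
                               half_cauchy_scale)

    y_raw = data["max_bite_force"].to_numpy(float)
    head_raw = data["head_length"].to_numpy(float)
    if (y_raw <= 0).any() or (head_raw <= 0).any():
        raise ValidationError("bite force and head length must be positive to log")
    species = sorted(data["species"].unique())
    counts = data["species"].value_counts()
    if len(species) < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 species with >= 2 records each")
    y = np.log(y_raw)
    cols = [(data["sex"] == "male").astype(float).to_numpy(), np.log(head_raw)]
    size = _size_column(data, size_covariate)
    if size is not None:
        cols.append(size)
    Xf = np.column_stack(cols)  # fixed effects (no intercept; alphas carry it)
    sp_idx = np.array([species.index(s) for s in data["species"]])
    n, S_sp, Kf = len(y), len(species), Xf.shape[1]
    n_store = (n_iterations - n_burnin + thin - 1) // thin
    A2 = half_cauchy_scale**2

    tot = n_store * n_chains
    out = {
        "alpha": np.empty((tot, S_sp)),
        "beta": np.empty((tot, Kf)),
        "mu_alpha": np.empty(tot),
        "sigma_between": np.empty(tot),
        "sigma_within": np.empty(tot),
        "chain": np.empty(tot, dtype=int),
    }
    # joint design over (alpha_1..alpha_S, beta): blocked update avoids the
    # poor mixing of alternating intercepts and slopes (they are near-collinear
    # when head length varies mostly between species)
    Z = np.zeros((n, S_sp + Kf))
    for j in range(S_sp):
        Z[sp_idx == j, j] = 1.0
    Z[:, S_sp:] = Xf
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    s = 0
    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        alpha = np.full(S_sp, float(y.mean()))
        beta = np.zeros(Kf)
        mu_a = float(y.mean())
        sig2_b, sig2_w = 1.0, 1.0
        if force_sigma_between is not None:
            sig2_b = force_sigma_between**2
        a_b, a_w = 1.0, 1.0
        for it in range(n_iterations):
            # joint (alpha, beta, mu_alpha) draw: blocking the hyper-mean in
            # keeps mixing fast even when sigma_between is pinned near zero
            d = S_sp + Kf + 1
            Q = np.zeros((d, d))
            Q[:-1, :-1] = ZtZ / sig2_w
            Q[np.arange(S_sp), np.arange(S_sp)] += 1.0 / sig2_b
            Q[np.arange(S_sp, S_sp + Kf), np.arange(S_sp, S_sp + Kf)] += SLOPE_PRIOR_PRECISION
            Q[-1, -1] = S_sp / sig2_b + SLOPE_PRIOR_PRECISION
            Q[:S_sp, -1] = Q[-1, :S_sp] = -1.0 / sig2_b
            r = np.zeros(d)
            r[:-1] = Zty / sig2_w
            V = np.linalg.inv(Q)
            m = V @ r
            theta_full = rng.multivariate_normal(m, (V + V.T) / 2, method="cholesky")
            alpha, beta, mu_a = theta_full[:S_sp], theta_full[S_sp:-1], theta_full[-1]
            theta = theta_full[:-1]
            # between-species variance (half-Cauchy via PX)
            if force_sigma_between is None:
                ss_a = float(((alpha - mu_a) ** 2).sum())
                sig2_b = stats.invgamma.rvs((S_sp + 1) / 2, scale=ss_a / 2 + 1.0 / a_b,
                                            random_state=rng)
                a_b = stats.invgamma.rvs(1.0, scale=1.0 / A2 + 1.0 / sig2_b,
                                         random_state=rng)
            # within-species variance
            err = y - Z @ theta
            sig2_w = stats.invgamma.rvs((n + 1) / 2, scale=float(err @ err) / 2 + 1.0 / a_w,
                                        random_state=rng)
            a_w = stats.invgamma.rvs(1.0, scale=1.0 / A2 + 1.0 / sig2_w, random_state=rng)
            if it >= n_burnin and (it - n_burnin) % thin == 0:
                out["alpha"][s] = alpha
                out["beta"][s] = beta
                out["mu_alpha"][s] = mu_a
                out["sigma_between"][s] = np.sqrt(sig2_b)
                out["sigma_within"][s] = np.sqrt(sig2_w)
                out["chain"][s] = c
                s += 1
    post = BiteForcePosterior(
        species=species,
        alpha=out["alpha"],
        beta_sex=out["beta"][:, 0],
        beta_head=out["beta"][:, 1],
        beta_size=out["beta"][:, 2] if Kf == 3 else None,
        mu_alpha=out["mu_alpha"],
        sigma_between=out["sigma_between"],
        sigma_within=out["sigma_within"],
        chain_ids=out["chain"],
        size_covariate=size_covariate,
    )
    post.diagnostics = _diagnostics(post, n_chains, n_store)
    return post


def _prior_only_run(
    n_iterations: int, n_burnin: int, thin: int, n_chains: int, seed: int, scale: float
) -> BiteForcePosterior:
    A2 = scale**2
    n_store = (n_iterations - n_burnin + thin - 1) // thin
    tot = n_store * n_chains
    sb = np.empty(tot)
    sw = np.empty(tot)
    chain = np.empty(tot, dtype=int)
    s = 0
    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        sig2_b = sig2_w = 1.0
        a_b = a_w = 1.0
        for it in range(n_iterations):
            sig2_b = stats.invgamma.rvs(0.5, scale=1.0 / a_b, random_state=rng)
            a_b = stats.invgamma.rvs(1.0, scale=1.0 / A2 + 1.0 / sig2_b, random_state=rng)
            sig2_w = stats.invgamma.rvs(0.5, scale=1.0 / a_w, random_state=rng)
            a_w = stats.invgamma.rvs(1.0, scale=1.0 / A2 + 1.0 / sig2_w, random_state=rng)
            if it >= n_burnin and (it - n_burnin) % thin == 0:
                sb[s], sw[s], chain[s] = np.sqrt(sig2_b), np.sqrt(sig2_w), c
                s += 1
    z = np.zeros(tot)
    return BiteForcePosterior(
        species=[], alpha=np.zeros((tot, 0)), beta_sex=z, beta_head=z, beta_size=None,
        mu_alpha=z, sigma_between=sb, sigma_within=sw, chain_ids=chain,
    )


def _diagnostics(post: BiteForcePosterior, n_chains: int, n_store: int) -> pd.DataFrame:
    rows = []
    for name, draws in post.parameter_draws().items():
        per_chain = draws.reshape(n_chains, n_store)
        rows.append(
            {
                "parameter": name,
                "rhat": psrf(per_chain) if n_chains >= 2 else np.nan,
                "ess": float(sum(ess(ch) for ch in per_chain)),
            }
        )
    return pd.DataFrame(rows)


def variance_explained(post: BiteForcePosterior, data: pd.DataFrame) -> dict[str, float]:
    """Gelman-Pardoe variance explained at the data and species levels.

    R^2_level = 1 - E[var(level residuals)] / E[var(level data)], averaged over
    posterior draws; can be negative for a bad model, approaches 1 when the
    level is fully explained.
    """
    y = np.log(data["max_bite_force"].to_numpy(float))
    if y.var(ddof=1) == 0:
        raise ValidationError("response has zero variance")
    cols = [(data["sex"] == "male").astype(float).to_numpy(),
            np.log(data["head_length"].to_numpy(float))]
    if post.size_covariate != "none":
        cols.append(_size_column(data, post.size_covariate))
    Xf = np.column_stack(cols)
    sp_idx = np.array([post.species.index(s) for s in data["species"]])
    betas = [post.beta_sex, post.beta_head]
    if post.beta_size is not None:
        betas.append(post.beta_size)
    Bf = np.column_stack(betas)  # (S, Kf)
    fitted = post.alpha[:, sp_idx] + Bf @ Xf.T  # (S, n)
    resid = y[None, :] - fitted
    r2_data = 1.0 - resid.var(axis=1, ddof=1).mean() / y.var(ddof=1)
    if len(post.species) >= 2:
        alpha_resid = post.alpha - post.mu_alpha[:, None]
        r2_species = 1.0 - alpha_resid.var(axis=1, ddof=1).mean() / post.alpha.var(
            axis=1, ddof=1
        ).mean()
    else:
        r2_species = np.nan
    return {"data_level": float(r2_data), "species_level": float(r2_species)}


def pearson_with_t(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson R with its t statistic: t = R sqrt(n-2)/sqrt(1-R^2), df = n-2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)
        p = 2 * stats.t.sf(abs(t), df)
    return {"r": r, "t": float(t), "p": float(p), "df": df}
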