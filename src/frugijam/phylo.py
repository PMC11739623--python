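"""Phylogenetic regression of per-plant consumption indices on fruit/seed shape.

Model (per plant species p):

    index_p = beta0 + beta_fruit * fruit_shape_p + beta_seed * seed_shape_p
              + u_p + e_p,
    u ~ N(0, sigma2_phylo * C),  e ~ N(0, sigma2_res * I),

where C is the Brownian-motion covariance from the tree (shared root-to-tip
path length, scaled to unit height).  Gibbs sampling with an inverse-gamma
(0.5, 0.5) prior on the residual variance and a half-Cauchy prior (scale
sqrt(1000)) on the phylogenetic standard deviation via parameter expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gjam import ess, hpd
from .io import Phylogeny, PiperTraitRecord, ValidationError

PHYLO_HALF_CAUCHY_SCALE = float(np.sqrt(1000.0))
RESID_IG_SHAPE = 0.5  # inverse-gamma(nu/2, nu*V/2) with V=1, nu=1
RESID_IG_SCALE = 0.5
SLOPE_PRIOR_PRECISION = 1e-6

BATTERY_COVARIATES = ("forearm", "mass", "castanea", "perspicillata")


@dataclass
class PhyloCovariance:
    """Shared-path-length covariance between tips, scaled to unit tree height."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, float)
        if not np.allclose(C, C.T):
            raise ValidationError("phylogenetic covariance is not symmetric")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValidationError("phylogenetic covariance is not PSD")
        self.matrix = C


def phylo_covariance(tree: Phylogeny, labels: Sequence[str]) -> PhyloCovariance:
    """C[i,j] = branch length shared by the root paths of tips i and j.

    The matrix is scaled so the deepest tip has diagonal 1; inference is
    therefore invariant to overall tree rescaling.
    """
    tree.require_tips(labels)
    t = tree.tree
    # depth of every node from the root
    depth: dict[int, float] = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )
    leaves = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    # ancestor sets for MRCA lookup
    anc: dict[str, list] = {}
    for lab in labels:
        chain = []
        node = leaves[lab]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        anc[lab] = chain
    P = len(labels)
    C = np.zeros((P, P))
    for i, la in enumerate(labels):
        seen = set(anc[la])
        C[i, i] = depth[anc[la][0]]
        for j in range(i + 1, P):
            lb = labels[j]
            mrca = next(nid for nid in anc[lb] if nid in seen)
            C[i, j] = C[j, i] = depth[mrca]
    height = C.diagonal().max()
    if height <= 0:
        raise ValidationError("tree has zero height")
    return PhyloCovariance(C / height, list(labels))


@dataclass
class TraitModelPosterior:
    """Draws for the trait regression; flags mark HPDs excluding zero."""

    beta0: np.ndarray
    beta_fruit: np.ndarray
    beta_seed: np.ndarray
    sigma2_phylo: np.ndarray
    sigma2_res: np.ndarray
    response: str = ""
    hpd_prob: float = 0.95
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("beta0", "beta_fruit", "beta_seed", "sigma2_phylo", "sigma2_res"):
            draws = getattr(self, name)
            lo, hi = hpd(draws, self.hpd_prob)
            rows.append(
                {
                    "response": self.response,
                    "parameter": name,
                    "median": float(np.median(draws)),
                    "hpd_lo": lo,
                    "hpd_hi": hi,
                    "significant": bool(lo > 0 or hi < 0) if name.startswith("beta") else None,
                    "ess": ess(draws),
                }
            )
        return pd.DataFrame(rows)

    @property
    def flags(self) -> dict[str, bool]:
        out = {}
        for name in ("beta_fruit", "beta_seed"):
            lo, hi = hpd(getattr(self, name), self.hpd_prob)
            out[name] = lo > 0 or hi < 0
        return out


def _trait_design(
    traits: Sequence[PiperTraitRecord], labels: Sequence[str], standardize: bool
) -> tuple[np.ndarray, dict[str, float], dict[str, float]]:
    by_name = {t.plant_species: t for t in traits}
    missing = [lab for lab in labels if lab not in by_name]
    if missing:
        raise ValidationError(f"plants missing trait records: {missing}")
    fruit = np.array([by_name[lab].fruit_shape_index for lab in labels])
    seed = np.array([by_name[lab].seed_shape_index for lab in labels])
    means, sds = {}, {}
    cols = []
    for name, v in (("fruit_shape", fruit), ("seed_shape", seed)):
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"{name} is constant; trait design is singular")
        if standardize:
            means[name], sds[name] = float(v.mean()), float(sd)
            v = (v - v.mean()) / sd
        cols.append(v)
    T = np.column_stack([np.ones(len(labels))] + cols)
    return T, means, sds


def fit_trait_model(
    indices: np.ndarray,
    traits: Sequence[PiperTraitRecord],
    C: PhyloCovariance,
    n_iterations: int = 50_000,
    n_burnin: int = 5_000,
    thin: int = 100,
    seed: int = 0,
    response: str = "",
    standardize: bool = True,
    hpd_prob: float = 0.95,
) -> TraitModelPosterior:
    """Gibbs sampler for the phylogenetic trait regression (single chain)."""
    y = np.asarray(indices, float)
    P = y.size
    if P < 5:
        raise ValidationError("need >= 5 plant species with traits and an index")
    if not 0 <= n_burnin < n_iterations:
        raise ValidationError("need 0 <= n_burnin < n_iterations")
    if y.size != len(C.labels):
        raise ValidationError("index vector does not match covariance labels")
    T, means, sds = _trait_design(traits, C.labels, standardize)
    Cm = C.matrix + 1e-10 * np.eye(P)  # guard exact ties against singularity
    Cinv = linalg.inv(Cm)
    Cinv = (Cinv + Cinv.T) / 2
    A2 = PHYLO_HALF_CAUCHY_SCALE**2
    Kt = T.shape[1]
    TtT = T.T @ T

    rng = np.random.default_rng(seed)
    u = np.zeros(P)
    beta = np.zeros(Kt)
    sig2_p, sig2_r, a_p = 1.0, 1.0, 1.0
    n_store = (n_iterations - n_burnin + thin - 1) // thin
    out = np.empty((n_store, Kt + 2))
    s = 0
    for it in range(n_iterations):
        # slopes
        V = linalg.inv(TtT / sig2_r + SLOPE_PRIOR_PRECISION * np.eye(Kt))
        m = V @ (T.T @ (y - u) / sig2_r)
        beta = rng.multivariate_normal(m, (V + V.T) / 2, method="cholesky")
        # phylogenetic effects
        prec = Cinv / sig2_p + np.eye(P) / sig2_r
        Vu = linalg.inv(prec)
        Vu = (Vu + Vu.T) / 2
        mu_u = Vu @ ((y - T @ beta) / sig2_r)
        u = rng.multivariate_normal(mu_u, Vu, method="cholesky")
        # variances
        quad_u = float(u @ Cinv @ u)
        sig2_p = stats.invgamma.rvs((P + 1) / 2, scale=quad_u / 2 + 1.0 / a_p,
                                    random_state=rng)
        a_p = stats.invgamma.rvs(1.0, scale=1.0 / A2 + 1.0 / sig2_p, random_state=rng)
        e = y - T @ beta - u
        sig2_r = stats.invgamma.rvs(RESID_IG_SHAPE + P / 2,
                                    scale=RESID_IG_SCALE + float(e @ e) / 2,
                                    random_state=rng)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            out[s, :Kt] = beta
            out[s, Kt] = sig2_p
            out[s, Kt + 1] = sig2_r
            s += 1
    return TraitModelPosterior(
        beta0=out[:, 0],
        beta_fruit=out[:, 1],
        beta_seed=out[:, 2],
        sigma2_phylo=out[:, Kt],
        sigma2_res=out[:, Kt + 1],
        response=response,
        hpd_prob=hpd_prob,
        trait_means=means,
        trait_sds=sds,
    )


def run_trait_battery(
    index_table: pd.DataFrame,
    traits: Sequence[PiperTraitRecord],
    C: PhyloCovariance,
    covariates: Sequence[str] = BATTERY_COVARIATES,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[dict[str, TraitModelPosterior], pd.DataFrame]:
    """Fit one trait model per consumption-index covariate (default: the four
    responses forearm, mass, castanea, perspicillata).

    ``index_table`` is a consumption-index table with columns covariate, plant,
    median.  Returns the fitted posteriors and a joint significance report.
    """
    posteriors: dict[str, TraitModelPosterior] = {}
    reports = []
    for j, cov in enumerate(covariates):
        sub = index_table[index_table["covariate"] == cov]
        if sub.empty:
            raise ValidationError(f"no consumption indices for covariate {cov!r}")
        by_plant = dict(zip(sub["plant"], sub["median"]))
        missing = [lab for lab in C.labels if lab not in by_plant]
        if missing:
            raise ValidationError(f"covariate {cov!r} missing indices for {missing}")
        y = np.array([by_plant[lab] for lab in C.labels])
        post = fit_trait_model(y, traits, C, seed=seed + j, response=cov, **fit_kwargs)
        posteriors[cov] = post
        reports.append(post.summary())
    return posteriors, pd.concat(reports, ignore_index=True)
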