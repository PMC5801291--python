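"""Bayesian second-level inference with a global shrinkage prior.

The hierarchical model per in-mask voxel v:

    beta_v ~ N(0, cB)                      (global shrinkage prior)
    x_iv | beta_v ~ N(beta_v, sigma_v^2)   (subject contrast values)

cB — the prior variance of the per-voxel effect, shared across the brain —
is estimated from the data by a pooled method of moments.  The conjugate
posterior for each voxel is Gaussian; a voxel is declared active when the
posterior probability that the effect exceeds an effect-size threshold
gamma beats the log-odds threshold tau:

    ln [ P(beta_v > gamma | D) / P(beta_v <= gamma | D) ] > tau.

Under equal prior odds this log posterior odds equals the log Bayes factor
("logBF").  gamma is expressed in Cohen's-d units of the prior scale:
gamma = d * sqrt(cB), so sqrt(cB) itself corresponds to d = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classical import GroupGLMResult
from .volume_io import StatVolume, label_clusters

__all__ = [
    "ShrinkagePrior",
    "PosteriorMaps",
    "BayesSpec",
    "BayesActivation",
    "estimate_prior_variance",
    "es_threshold",
    "compute_posterior",
    "log_odds_map",
    "bayes_threshold",
    "LOG_ODDS_CLIP",
]

#: log-odds are clipped here; past this Phi saturates in double precision
LOG_ODDS_CLIP = 40.0


@dataclass(frozen=True)
class ShrinkagePrior:
    """Global prior variance cB of the per-voxel effect (contrast^2)."""

    cB: float
    method: str = "moments"
    V_used: int = 0

    def __post_init__(self):
        if self.cB < 0:
            raise ValueError("cB must be nonnegative")
        if self.method not in ("moments", "reml"):
            raise ValueError("method must be 'moments' or 'reml'")

    @property
    def sqrt_cB(self) -> float:
        """Prior SD — the effect size corresponding to Cohen's d = 1.0."""
        return math.sqrt(self.cB)


@dataclass
class PosteriorMaps:
    """Per-voxel conjugate Gaussian posterior (mean, variance).

    ``error_var`` records which error-variance model produced the update:
    ``"pooled"`` (one global residual variance, the in-mask mean — the
    default, mirroring globally pooled error hyperparameters) or
    ``"voxel"`` (each voxel's own unbiased sample variance).
    """

    post_mean: StatVolume
    post_var: StatVolume
    prior: ShrinkagePrior
    glm: GroupGLMResult
    error_var: str = "pooled"


@dataclass
class BayesSpec:
    """Joint effect-size + log-odds thresholding recipe.

    ``d`` multiplies sqrt(cB) to give the effect-size threshold gamma
    (conventional values 0.2/0.5/0.8/1.0); ``tau`` is the log-odds cut
    (3 strong, 5 very strong, 10 the tool default).  ``extent_voxels``
    defaults to 0 — no cluster-extent filtering on the Bayesian branch.
    """

    d: float = 0.5
    tau: float = 5.0
    gamma: float | None = None
    direction: int = 1
    extent_voxels: int = 0

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.extent_voxels < 0:
            raise ValueError("extent_voxels must be nonnegative")

    def resolve(self, prior: ShrinkagePrior) -> "BayesSpec":
        """Fix gamma = d * sqrt(cB) for the given prior."""
        return BayesSpec(self.d, self.tau, es_threshold(prior, self.d),
                         self.direction, self.extent_voxels)


@dataclass
class BayesActivation:
    """Thresholded log-odds map with its cluster table."""

    active: np.ndarray
    logodds: StatVolume
    spec: BayesSpec
    clusters: pd.DataFrame


def estimate_prior_variance(glm: GroupGLMResult) -> ShrinkagePrior:
    """Pooled method-of-moments estimate of the prior variance cB.

    Across in-mask voxels, Var(beta_hat) = cB + E[resid_var]/n under the
    hierarchical model, so cB = max(0, Var_v(beta_hat) - mean_v(resid_var)/n)
    with the between-voxel variance taken with divisor V-1.
    """
    usable = glm.mask.inside & np.isfinite(glm.beta_hat.values)
    V_used = int(usable.sum())
    if V_used < 2:
        raise ValueError("need at least 2 usable voxels to estimate cB")
    b = glm.beta_hat.values[usable]
    noise = np.mean(glm.resid_var.values[usable]) / glm.n
    cB = max(0.0, float(np.var(b, ddof=1) - noise))
    return ShrinkagePrior(cB=cB, method="moments", V_used=V_used)


def es_threshold(prior: ShrinkagePrior, d: float) -> float:
    """Effect-size threshold gamma = d * sqrt(cB) (contrast units)."""
    if d <= 0:
        raise ValueError("d must be positive")
    return d * prior.sqrt_cB


def compute_posterior(glm: GroupGLMResult, prior: ShrinkagePrior,
                      error_var: str = "pooled") -> PosteriorMaps:
    """Conjugate-normal update per voxel.

    With error variance sigma_v^2: posterior precision p = 1/cB +
    n/sigma_v^2; post_var = 1/p; post_mean = post_var * (n/sigma_v^2) *
    beta_hat.

    ``error_var="pooled"`` (default) uses one global sigma^2 — the mean
    in-mask residual variance — for every voxel; per-voxel sample
    variances have chi-square-heavy tails at small n that produce
    spuriously confident posteriors.  ``error_var="voxel"`` uses each
    voxel's own unbiased sample variance (voxels with zero variance are
    left NaN, flagged degenerate upstream).
    """
    if prior.cB <= 0:
        raise ValueError("degenerate prior; no Bayesian map (cB = 0)")
    if error_var not in ("pooled", "voxel"):
        raise ValueError("error_var must be 'pooled' or 'voxel'")
    grid = glm.mask.grid
    var = glm.resid_var.values
    beta = glm.beta_hat.values

    post_mean = np.full(grid.shape, np.nan)
    post_var = np.full(grid.shape, np.nan)
    ok = glm.mask.inside & (var > 0)
    if error_var == "pooled":
        sigma2 = float(np.mean(var[ok]))
        data_prec = np.full(int(ok.sum()), glm.n / sigma2)
    else:
        data_prec = glm.n / var[ok]
    pv = 1.0 / (1.0 / prior.cB + data_prec)
    post_var[ok] = pv
    post_mean[ok] = pv * data_prec * beta[ok]
    return PosteriorMaps(
        post_mean=StatVolume(grid, post_mean, "posterior_mean"),
        post_var=StatVolume(grid, post_var, "posterior_var"),
        prior=prior,
        glm=glm,
        error_var=error_var,
    )


def log_odds_map(post: PosteriorMaps, gamma: float, direction: int = 1) -> StatVolume:
    """Log posterior odds that the (signed) effect exceeds gamma.

    With z = (gamma - direction*post_mean)/sqrt(post_var),
    P1 = 1 - Phi(z) and logodds = ln(P1/(1-P1)), computed through the
    normal log-CDF for numerical stability and clipped to +/-LOG_ODDS_CLIP.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    pv = post.post_var.values
    pm = post.post_mean.values
    inside = post.glm.mask.inside
    if np.any(inside & (pv <= 0)):
        raise ValueError("nonpositive posterior variance at an in-mask voxel")

    out = np.full(pv.shape, np.nan)
    ok = inside & np.isfinite(pv) & (pv > 0)
    z = (gamma - direction * pm[ok]) / np.sqrt(pv[ok])
    lo = stats.norm.logsf(z) - stats.norm.logcdf(z)
    out[ok] = np.clip(lo, -LOG_ODDS_CLIP, LOG_ODDS_CLIP)
    return StatVolume(post.glm.mask.grid, out, "logodds")


def bayes_threshold(logodds: StatVolume, spec: BayesSpec,
                    mask=None, connectivity: int = 18) -> BayesActivation:
    """Threshold the log-odds map at tau (and optionally by cluster extent)."""
    if spec.gamma is None:
        raise ValueError("spec not resolved: gamma is unset (call spec.resolve)")
    vals = logodds.values
    inside = mask.inside if mask is not None else np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        active = inside & np.isfinite(vals) & (vals > spec.tau)
    labels, table = label_clusters(active, connectivity, logodds.grid, vals)
    if spec.extent_voxels > 0 and len(table):
        keep = table.cluster_id[table.size_voxels >= spec.extent_voxels]
        active = np.isin(labels, list(keep))
        table = table[table.cluster_id.isin(keep)].reset_index(drop=True)
        table = table.assign(cluster_id=np.arange(1, len(table) + 1))
    return BayesActivation(active=active, logodds=logodds, spec=spec, clusters=table)
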