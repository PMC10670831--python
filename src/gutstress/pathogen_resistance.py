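"""Pathogen-susceptibility classification and Bayesian mixed-model contrasts.

An animal is called susceptible to a pathogen genus at a site when its
relative abundance is at least ``factor`` (default 2.5, inclusive) times the
median relative abundance within its treatment group.  The treatment and
susceptibility effects on clr abundances are then summarised by a conjugate
Gibbs sampler for a Gaussian linear mixed model with a litter random
intercept, reporting posterior means, 95% credible intervals and Pr0, the
posterior probability that an effect is greater than zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PATHOGENS = ("Clostridium", "Treponema", "Streptococcus", "Campylobacter")
SUSCEPTIBILITY_FACTOR = 2.5


def normal_tail_probability(z: float) -> float:
    """One-sided standard-normal tail probability P(Z > z)."""
    return float(stats.norm.sf(z))


def classify_susceptibility(
    rel_abund: pd.DataFrame,
    treatment,
    pathogens=DEFAULT_PATHOGENS,
    factor: float = SUSCEPTIBILITY_FACTOR,
    site: str | None = None,
) -> pd.DataFrame:
    """Median-ratio susceptibility calls per sample x pathogen.

    Returns a frame with columns sample_id, pathogen, site, rel_abundance,
    group_median, ratio, label.  A group whose abundances are all zero yields
    undefined ratios and all-resistant labels (with a warning); a zero median
    with positive abundances gives an infinite ratio (susceptible).
    """
    treatment = np.asarray(treatment).astype(str)
    if treatment.size != rel_abund.shape[0]:
        raise ValueError("treatment length does not match abundance table")
    missing = [p for p in pathogens if p not in rel_abund.columns]
    if missing:
        raise ValueError(f"pathogen genera absent from table: {missing}")
    rows = []
    for pathogen in pathogens:
        x = rel_abund[pathogen].to_numpy(dtype=float)
        for g in np.unique(treatment):
            mask = treatment == g
            med = float(np.median(x[mask]))
            if med == 0.0 and not x[mask].any():
                warnings.warn(
                    f"all-zero {pathogen!r} abundances in group {g!r}; "
                    "ratios undefined, all animals called resistant",
                    stacklevel=2,
                )
                ratios = np.full(mask.sum(), np.nan)
                labels = np.full(mask.sum(), "resistant")
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios = np.where(med > 0, x[mask] / med, np.where(x[mask] > 0, np.inf, np.nan))
                labels = np.where(np.nan_to_num(ratios, nan=0.0) >= factor, "susceptible", "resistant")
            for sid, ab, r, lab in zip(rel_abund.index[mask], x[mask], ratios, labels):
                rows.append(
                    {
                        "sample_id": sid,
                        "pathogen": pathogen,
                        "site": site,
                        "treatment": g,
                        "rel_abundance": ab,
                        "group_median": med,
                        "ratio": r,
                        "label": lab,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian linear mixed model (conjugate Gibbs)
# ---------------------------------------------------------------------------


@dataclass
class EffectSummary:
    mean: float
    ci_low: float
    ci_high: float
    pr0: float  # posterior probability effect > 0


@dataclass
class PosteriorSummary:
    effects: dict[str, EffectSummary]
    rhat: dict[str, float]
    n_draws: int
    n_chains: int
    converged: bool
    draws: pd.DataFrame = field(repr=False, default=None)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (chains x draws)."""
    m, n = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    k, n2 = segs.shape
    means = segs.mean(axis=1)
    b = n2 * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def bayes_mixed_contrast(
    y,
    treatment,
    susceptibility,
    litter=None,
    n_iter: int = 2000,
    n_chains: int = 4,
    seed: int = 0,
    prior_nu: float = 3.0,
) -> PosteriorSummary:
    """Gibbs sampler for y = a + b1*stress + b2*susceptible + litter + e.

    Fixed effects get Normal(0, (10*sd(y))^2) priors; the litter and residual
    SDs get half-Student-t(3, sd(y)) priors via their inverse-gamma
    scale-mixture representation, keeping every update conjugate.  Half of
    each chain is discarded as warm-up.  Split-chain R-hat > 1.1 flags (but
    does not fail) the fit.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    treatment = np.asarray(treatment).astype(str)
    x1 = (treatment == "stress").astype(float)
    if susceptibility is not None:
        susc = np.asarray(susceptibility)
        if susc.dtype.kind in "OUS":
            x2 = (susc.astype(str) == "susceptible").astype(float)
        else:
            x2 = susc.astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        names = ["treatment", "susceptibility"]
    else:
        X = np.column_stack([np.ones(n), x1])
        names = ["treatment"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after coding")
    k = X.shape[1]

    if litter is not None:
        litter = np.asarray(litter).astype(str)
        lits, zidx = np.unique(litter, return_inverse=True)
        q = lits.size
        if q < 2:
            raise ValueError("need >= 2 litters (or pass litter=None)")
    else:
        q = 0
        zidx = None

    sd_y = float(y.std(ddof=1)) or 1.0
    tau2 = (10.0 * sd_y) ** 2  # fixed-effect prior variance
    A2 = sd_y**2  # half-t scale^2
    nu = prior_nu
    XtX = X.T @ X

    keep = n_iter // 2
    all_draws = np.empty((n_chains, keep, k))
    rng_master = np.random.default_rng(seed)
    for chain in range(n_chains):
        rng = np.random.default_rng(rng_master.integers(0, 2**63 - 1))
        beta = np.zeros(k)
        u = np.zeros(q)
        sig2_e = sd_y**2
        sig2_l = sd_y**2 / 4 if q else 0.0
        a_e = A2
        a_l = A2
        for it in range(n_iter):
            zu = u[zidx] if q else 0.0
            # fixed effects
            prec = XtX / sig2_e + np.eye(k) / tau2
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + cov.T)
            mean = cov @ (X.T @ (y - zu)) / sig2_e
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            resid_fe = y - X @ beta
            if q:
                # litter intercepts, one conjugate normal each
                for l in range(q):
                    mask = zidx == l
                    nl = int(mask.sum())
                    v = 1.0 / (nl / sig2_e + 1.0 / sig2_l)
                    m = v * resid_fe[mask].sum() / sig2_e
                    u[l] = rng.normal(m, np.sqrt(v))
                # litter variance: IG with half-t mixture
                sig2_l = 1.0 / rng.gamma((nu + q) / 2.0, 1.0 / (nu / a_l + 0.5 * (u @ u)))
                a_l = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sig2_l + 1.0 / A2))
                zu = u[zidx]
            resid = resid_fe - (zu if q else 0.0)
            sig2_e = 1.0 / rng.gamma((nu + n) / 2.0, 1.0 / (nu / a_e + 0.5 * (resid @ resid)))
            a_e = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sig2_e + 1.0 / A2))
            if it >= n_iter - keep:
                all_draws[chain, it - (n_iter - keep)] = beta

    effects: dict[str, EffectSummary] = {}
    rhat: dict[str, float] = {}
    for j, name in enumerate(names, start=1):
        d = all_draws[:, :, j].reshape(-1)
        effects[name] = EffectSummary(
            mean=float(d.mean()),
            ci_low=float(np.quantile(d, 0.025)),
            ci_high=float(np.quantile(d, 0.975)),
            pr0=float((d > 0).mean()),
        )
        rhat[name] = _split_rhat(all_draws[:, :, j]) if n_chains > 1 else 1.0
    converged = all(r <= 1.1 for r in rhat.values())
    if not converged:
        logger.warning("Gibbs sampler not converged: R-hat %s", rhat)
    draws = pd.DataFrame(
        all_draws.reshape(-1, k), columns=["intercept"] + names
    )
    return PosteriorSummary(
        effects=effects,
        rhat=rhat,
        n_draws=n_chains * keep,
        n_chains=n_chains,
        converged=converged,
        draws=draws,
    )


def resistance_analysis(
    rel_abund: pd.DataFrame,
    clr_mean: pd.DataFrame,
    meta: pd.DataFrame,
    pathogens=DEFAULT_PATHOGENS,
    factor: float = SUSCEPTIBILITY_FACTOR,
    n_iter: int = 2000,
    n_chains: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, PosteriorSummary]]:
    """Susceptibility calls + one Bayesian model per pathogen for one site."""
    site = meta["site"].iloc[0] if "site" in meta else None
    calls = classify_susceptibility(
        rel_abund, meta["treatment"].to_numpy(), pathogens, factor=factor, site=site
    )
    summaries: dict[str, PosteriorSummary] = {}
    for i, pathogen in enumerate(pathogens):
        sub = calls[calls["pathogen"] == pathogen].set_index("sample_id")
        sub = sub.loc[rel_abund.index]
        labels = sub["label"].to_numpy()
        if len(set(labels)) < 2:
            logger.info(
                "no susceptibility contrast for %s (all animals %s); "
                "fitting treatment-only model", pathogen, labels[0],
            )
            labels = None
        summaries[pathogen] = bayes_mixed_contrast(
            clr_mean[pathogen].to_numpy(),
            meta["treatment"].to_numpy(),
            labels,
            meta["litter"].to_numpy(),
            n_iter=n_iter,
            n_chains=n_chains,
            seed=seed + i,
        )
    return calls, summaries
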