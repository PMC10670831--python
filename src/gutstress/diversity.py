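"""Alpha/beta diversity and the shared mixed-model contrast.

Alpha diversity is computed on raw (pre-filter) counts: richness (number of
observed genera) and an adjusted Shannon index H/ln(G_obs), i.e. a
Pielou-type evenness bounded by [0, 1].  Beta diversity uses Bray-Curtis
dissimilarity with a sequential (litter-first) PERMANOVA.  The treatment
contrast on scalar responses is a one-random-intercept Gaussian mixed model
fit by REML with the litter/residual variance ratio profiled by 1-D
optimisation and a Wald t test with df = n - n_litters - 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and adjusted Shannon index.

    ``observed_genera`` counts genera with count > 0; ``adjusted_shannon`` is
    Shannon entropy over present genera divided by ln(richness), defined as 0
    when richness <= 1.
    """
    if hasattr(counts, "counts"):  # accept a GenusCountTable
        counts = counts.counts
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        empty = counts.index[arr.sum(axis=1) == 0].tolist()
        raise ValueError(f"empty samples: {empty}")
    rows = []
    for i in range(arr.shape[0]):
        x = arr[i][arr[i] > 0]
        g_obs = x.size
        p = x / x.sum()
        h = float(-(p * np.log(p)).sum())
        adj = h / np.log(g_obs) if g_obs > 1 else 0.0
        rows.append({"observed_genera": g_obs, "adjusted_shannon": adj})
    return pd.DataFrame(rows, index=counts.index)


# ---------------------------------------------------------------------------
# mixed-model contrast
# ---------------------------------------------------------------------------


@dataclass
class MixedContrast:
    estimate: float
    se: float
    pvalue: float
    df: float
    sigma_litter: float
    sigma_resid: float
    method: str  # "reml" or "ols"
    lsmeans: dict  # level -> (mean, se)


def _reml_criterion(lam: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> float:
    n, k = X.shape
    V = np.eye(n) + lam * Z @ Z.T
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    XtVX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0 or quad <= 0:
        return np.inf
    return logdet_v + logdet_xvx + (n - k) * np.log(quad)


def mixed_contrast(y, group, litter, contrast: tuple[str, str] = ("control", "stress")) -> MixedContrast:
    """Treatment contrast ``contrast[0] - contrast[1]`` with litter random intercept.

    Falls back to OLS (with a logged notice) when fewer than two litters are
    available or the fit is singular.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group).astype(str)
    litter = np.asarray(litter).astype(str)
    n = y.size
    levels = sorted(set(group))
    if set(levels) != set(contrast):
        raise ValueError(f"group levels {levels} do not match contrast {contrast}")
    x = (group == contrast[0]).astype(float)
    X = np.column_stack([np.ones(n), x])
    lits, zidx = np.unique(litter, return_inverse=True)
    q = lits.size

    use_ols = q < 2 or n - q - 1 < 1
    lam = 0.0
    if not use_ols:
        Z = np.zeros((n, q))
        Z[np.arange(n), zidx] = 1.0
        res = optimize.minimize_scalar(
            lambda t: _reml_criterion(np.exp(t), y, X, Z),
            bounds=(-12.0, 12.0),
            method="bounded",
        )
        lam = float(np.exp(res.x))
        # compare against the boundary (no litter variance)
        if _reml_criterion(0.0, y, X, Z) <= res.fun:
            lam = 0.0
        V = np.eye(n) + lam * Z @ Z.T
    else:
        logger.info("mixed_contrast: <2 litters; falling back to OLS")
        V = np.eye(n)

    Vinv_X = np.linalg.solve(V, X)
    XtVX = X.T @ Vinv_X
    try:
        beta = np.linalg.solve(XtVX, Vinv_X.T @ y)
        cov_unscaled = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        logger.warning("mixed_contrast: singular fit; falling back to OLS")
        return mixed_contrast(y, group, np.repeat("all", n), contrast)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    sigma2 = quad / (n - 2)
    cov = sigma2 * cov_unscaled
    est = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    df = float(n - 2) if use_ols else float(n - q - 1)
    t = est / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df))
    # LS means: baseline level mean = beta0, contrast[0] mean = beta0 + beta1
    m0 = float(beta[0])
    m1 = float(beta[0] + beta[1])
    se0 = float(np.sqrt(cov[0, 0]))
    se1 = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))
    return MixedContrast(
        estimate=est,
        se=se,
        pvalue=p,
        df=df,
        sigma_litter=float(np.sqrt(lam * sigma2)),
        sigma_resid=float(np.sqrt(sigma2)),
        method="ols" if use_ols else "reml",
        lsmeans={contrast[1]: (m0, se0), contrast[0]: (m1, se1)},
    )


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(abund) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC(x,y) = sum|x-y| / sum(x+y)."""
    if hasattr(abund, "relative_abundance"):
        abund = abund.relative_abundance()
    idx = abund.index if isinstance(abund, pd.DataFrame) else pd.RangeIndex(len(abund))
    arr = np.asarray(abund, dtype=float)
    d = squareform(pdist(arr, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero rows compare as identical
    return pd.DataFrame(d, index=idx, columns=idx)


def _hat(M: np.ndarray) -> np.ndarray:
    return M @ np.linalg.pinv(M.T @ M) @ M.T


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index: factors + Residual + Total; columns: df, ss, F, p
    n_perm: int

    def pseudo_f(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])

    def pvalue(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


def permanova(
    dist: pd.DataFrame | np.ndarray,
    treatment,
    litter=None,
    n_perm: int = 999,
    seed: int = 0,
    permutations: str = "random",
) -> PermanovaResult:
    """Sequential PERMANOVA on a distance matrix (litter entered first).

    The Gower-centred inner-product matrix ``G = -1/2 J D^2 J`` is partitioned
    into sequential factor sums of squares using hat matrices; p-values come
    from free permutation of sample labels with the (1+b)/(1+m) convention.
    ``permutations="exhaustive"`` enumerates all label permutations (n <= 8).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    treatment = np.asarray(treatment).astype(str)
    if treatment.size != n:
        raise ValueError("treatment length does not match distance matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J

    factors: list[tuple[str, np.ndarray, int]] = []
    design = [np.ones((n, 1))]
    if litter is not None:
        litter = np.asarray(litter).astype(str)
        lits = np.unique(litter)
        Zl = (litter[:, None] == lits[None, :]).astype(float)
        factors.append(("litter", Zl, lits.size - 1))
        design.append(Zl)
    t_levels = np.unique(treatment)
    Xt = (treatment[:, None] == t_levels[None, :]).astype(float)
    factors.append(("treatment", Xt, t_levels.size - 1))
    design.append(Xt)

    # nested hat matrices: intercept, +litter, +litter+treatment
    hats = []
    for k in range(1, len(design) + 1):
        hats.append(_hat(np.hstack(design[:k])))

    df_res = n - 1 - sum(df for _, _, df in factors)
    if df_res < 1:
        raise ValueError("not enough residual degrees of freedom")

    def stats_for(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_cum = [float((H * Gp).sum()) for H in hats]  # tr(H G), H symmetric
        ss = np.diff(ss_cum)  # per-factor sequential SS
        ss_total = float(np.trace(Gp))
        ss_res = ss_total - ss_cum[-1]
        dfs = np.array([df for _, _, df in factors], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):  # ss_res can be 0
            F = (ss / dfs) / (ss_res / df_res)
        return F, ss_res

    F_obs, ss_res = stats_for(G)
    ss_cum = [float((H * G).sum()) for H in hats]
    ss_obs = np.diff(ss_cum)

    if permutations == "exhaustive":
        perms = [np.array(p) for p in itertools.permutations(range(n))][1:]  # exclude identity
        n_perm_eff = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
        n_perm_eff = n_perm
    exceed = np.zeros(len(factors))
    for perm in perms:
        Gp = G[np.ix_(perm, perm)]
        Fp, _ = stats_for(Gp)
        exceed += Fp >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm_eff + 1.0)

    rows = []
    for (name, _, dfk), ssk, fk, pk in zip(factors, ss_obs, F_obs, pvals):
        rows.append({"factor": name, "df": dfk, "ss": float(ssk), "F": float(fk), "p": float(pk)})
    rows.append({"factor": "Residual", "df": df_res, "ss": ss_res, "F": np.nan, "p": np.nan})
    rows.append({"factor": "Total", "df": n - 1, "ss": float(np.trace(G)), "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("factor")
    return PermanovaResult(table=table, n_perm=n_perm_eff)


def within_group_dissimilarity(dist: pd.DataFrame | np.ndarray, groups) -> pd.Series:
    """Mean dissimilarity over all within-group sample pairs."""
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(groups).astype(str)
    out = {}
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        out[g] = float(sub[iu].mean())
    return pd.Series(out)


# ---------------------------------------------------------------------------
# site-level report
# ---------------------------------------------------------------------------


def diversity_report(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Alpha contrasts (mixed model) + Bray-Curtis PERMANOVA for one site."""
    alpha = alpha_diversity(counts)
    group = meta["treatment"].to_numpy()
    litter = meta["litter"].to_numpy()
    out: dict = {"per_sample": alpha, "alpha_contrasts": {}, "note": "PERMANOVA permutes sample labels freely; litter entered before treatment"}
    for metric in ("observed_genera", "adjusted_shannon"):
        mc = mixed_contrast(alpha[metric].to_numpy(), group, litter, contrast=("stress", "control"))
        out["alpha_contrasts"][metric] = {
            "estimate": mc.estimate,
            "se": mc.se,
            "p": mc.pvalue,
            "lsmeans": mc.lsmeans,
            "method": mc.method,
        }
    rel = counts.div(counts.sum(axis=1), axis=0)
    bc = bray_curtis(rel)
    perm = permanova(bc, group, litter, n_perm=n_perm, seed=seed)
    out["permanova"] = perm.table
    out["within_group_bc"] = within_group_dissimilarity(bc.to_numpy(), group)
    return out
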