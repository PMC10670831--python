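"""Sequential PLSDA-VIP biomarker discovery.

A single-response (PLS1) partial least squares discriminant model is fit by
NIPALS on column-centred clr data against a centred 0/1 class indicator
(stress = 1).  The number of latent components is chosen by leave-one-out
cross-validation (minimum classification error, ties to the smallest model).
Genera with VIP < 0.8 are removed and the model refit; the loop stops when the
candidate round's LOO error exceeds the previous round's, when no genus falls
below the cut, or when fewer than 3 genera would remain, returning the last
round before the stop condition.  Surviving genera are scored by a Welch
t-test averaged over the Monte-Carlo clr instances, BH-adjusted, with effect
sizes in pooled-SD units of the mean-instance clr.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ClrEnsemble

logger = logging.getLogger(__name__)

VIP_CUT = 0.8
CLASS_THRESHOLD = 0.5


@dataclass
class PlsdaModel:
    """Fitted PLS1 discriminant model (NIPALS, X deflated per component)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A) weight vectors w_a
    scores: np.ndarray  # (n, A) score vectors t_a
    x_loadings: np.ndarray  # (p, A) loadings p_a
    y_loadings: np.ndarray  # (A,) loadings q_a
    columns: list  # predictor ids in model order
    dropped: list = field(default_factory=list)  # zero-variance predictors

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b with y_hat = y_mean + (x - x_mean) . b."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.coef

    def classify(self, X) -> np.ndarray:
        return (self.predict(X) >= CLASS_THRESHOLD).astype(int)


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def fit_plsda(X, y, A: int) -> PlsdaModel:
    """NIPALS PLS1 with A latent components on centred X and centred 0/1 y."""
    Xm, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    sd = Xm.std(axis=0)
    dropped = [cols[j] for j in np.where(sd == 0)[0]]
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped}", stacklevel=2)
        keep = np.where(sd > 0)[0]
        Xm = Xm[:, keep]
        cols = [cols[j] for j in keep]
        p = Xm.shape[1]
    if A < 1 or A > min(n - 1, p):
        raise ValueError(f"A={A} out of range for X of shape {(n, p)}")
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xm - x_mean
    yc = y - y_mean
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    q = np.empty(A)
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"degenerate component {a + 1}: X carries no covariance with y")
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        q[a] = float(t @ yc) / tt
        pa = Xc.T @ t / tt
        Xc = Xc - np.outer(t, pa)
        W[:, a], T[:, a], P[:, a] = w, t, pa
    return PlsdaModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, scores=T, x_loadings=P,
        y_loadings=q, columns=cols, dropped=dropped,
    )


def vip_scores(model: PlsdaModel) -> pd.Series:
    """VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a).

    SSY_a = q_a^2 t_a.t_a is the y-variance captured by component a; squared
    VIPs sum to p.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = q**2 * np.einsum("na,na->a", T, T)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.columns)


def loo_error(X, y, A: int) -> float:
    """Leave-one-out classification error of an A-component model."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    wrong = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_plsda(Xm[mask], y[mask], A)
        # align held-out row to the columns surviving zero-variance dropping
        xi = Xm[i]
        if model.dropped:
            keep = [j for j in range(Xm.shape[1]) if j in model.columns]
            xi = xi[keep]
        wrong += int(model.classify(xi[None, :])[0] != int(y[i]))
    return wrong / n


def loo_select_components(X, y, A_max: int = 5) -> tuple[int, dict[int, float]]:
    """Pick the component count minimising LOO error (tie -> smallest A)."""
    Xm, _ = _as_matrix(X)
    n, p = Xm.shape
    upper = min(A_max, n - 2, p)
    errors = {A: loo_error(Xm, np.asarray(y, dtype=float), A) for A in range(1, upper + 1)}
    best = min(errors, key=lambda A: (errors[A], A))
    return best, errors


@dataclass
class EliminationRound:
    genera: list
    n_components: int
    loo_error: float
    vip: pd.Series


@dataclass
class EliminationResult:
    rounds: list[EliminationRound]
    final_genera: list
    final_model: PlsdaModel
    stop_reason: str

    @property
    def final_loo_error(self) -> float:
        return self.rounds[-1].loo_error

    @property
    def classification_rate(self) -> float:
        return 1.0 - self.final_loo_error


def sequential_elimination(
    X: pd.DataFrame, y, vip_cut: float = VIP_CUT, A_max: int = 5
) -> EliminationResult:
    """Recursive VIP-based feature elimination with a discrimination-loss stop.

    Always terminates: the retained set strictly shrinks each round or a stop
    condition fires.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 genera")
    y = np.asarray(y, dtype=float)

    def fit_round(cols) -> EliminationRound:
        Xr = X[cols]
        A, errs = loo_select_components(Xr, y, A_max)
        model = fit_plsda(Xr, y, A)
        return EliminationRound(list(cols), A, errs[A], vip_scores(model)), model

    current = list(X.columns)
    rnd, model = fit_round(current)
    rounds = [rnd]
    stop_reason = ""
    while True:
        below = rnd.vip.index[rnd.vip < vip_cut].tolist()
        if not below:
            stop_reason = "no genus below VIP cut"
            break
        candidate = [g for g in rnd.genera if g not in below]
        if len(candidate) < 3:
            stop_reason = "fewer than 3 genera would remain"
            break
        cand_rnd, cand_model = fit_round(candidate)
        if cand_rnd.loo_error > rnd.loo_error:
            stop_reason = "discrimination loss (LOO error increased)"
            break
        rnd, model = cand_rnd, cand_model
        rounds.append(rnd)
    return EliminationResult(
        rounds=rounds, final_genera=list(rnd.genera), final_model=model, stop_reason=stop_reason
    )


def welch_enrichment(
    ensemble: ClrEnsemble, labels, genus_set=None
) -> pd.DataFrame:
    """Welch t-test per genus, expected over Monte-Carlo clr instances.

    Reported p per genus is the arithmetic mean of the per-instance Welch
    p-values; q is the BH adjustment across the genus set; the effect size is
    the (stress - control) mean-instance clr difference in pooled-SD units.
    Direction is 'enriched'/'depleted' in the stress group ('none' when the
    difference is exactly zero).
    """
    labels = np.asarray(labels).astype(str)
    genus_set = list(genus_set) if genus_set is not None else list(ensemble.genus_ids)
    missing = [g for g in genus_set if g not in ensemble.genus_ids]
    if missing:
        raise ValueError(f"genera not in ensemble: {missing}")
    cols = [ensemble.genus_ids.index(g) for g in genus_set]
    s_mask = labels == "stress"
    c_mask = labels == "control"
    if s_mask.sum() < 2 or c_mask.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    inst = ensemble.instances[:, :, cols]  # (K, n, m)
    res = stats.ttest_ind(inst[:, s_mask, :], inst[:, c_mask, :], axis=1, equal_var=False)
    p_mean = np.asarray(res.pvalue).mean(axis=0)

    mean_inst = ensemble.mean.to_numpy()[:, cols]
    ms = mean_inst[s_mask].mean(axis=0)
    mc = mean_inst[c_mask].mean(axis=0)
    n1, n2 = int(s_mask.sum()), int(c_mask.sum())
    s1 = mean_inst[s_mask].var(axis=0, ddof=1)
    s2 = mean_inst[c_mask].var(axis=0, ddof=1)
    pooled_sd = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    diff = ms - mc
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(pooled_sd > 0, diff / pooled_sd, 0.0)
    direction = np.where(diff > 0, "enriched", np.where(diff < 0, "depleted", "none"))

    q = bh_adjust(p_mean)
    return pd.DataFrame(
        {
            "genus": genus_set,
            "direction": direction,
            "effect_sd": effect,
            "p_welch": p_mean,
            "q_bh": q,
        }
    ).set_index("genus")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def discover_biomarkers(
    ensemble: ClrEnsemble,
    labels,
    vip_cut: float = VIP_CUT,
    A_max: int = 5,
) -> tuple[pd.DataFrame, EliminationResult]:
    """Full per-site biomarker discovery: elimination loop + Welch report.

    The returned frame carries the final model's VIP per surviving genus and
    the elimination result exposes the final classification rate.
    """
    labels = np.asarray(labels).astype(str)
    y = (labels == "stress").astype(float)
    result = sequential_elimination(ensemble.mean, y, vip_cut=vip_cut, A_max=A_max)
    report = welch_enrichment(ensemble, labels, genus_set=result.final_genera)
    report.insert(1, "vip", vip_scores(result.final_model).reindex(report.index))
    return report, result
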