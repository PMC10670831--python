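"""Stress-phenotype layer: cortisol AUC, growth traits, lesions, contrasts.

Cortisol exposure per sampling day is the trapezoidal area under the 4-point
clock-time profile (07:00-16:00, a 9 h span).  ADG is total gain over trial
days; FCR is DFI/ADG.  Individual daily feed intake is apportioned from
pen-level totals proportionally to a metabolic-weight + gain prediction
``a * w^0.75 + b * ADG`` so that apportioned intakes sum to the pen total
exactly.  Group contrasts reuse the shared mixed-model operation with the
control-minus-stress sign convention.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import mixed_contrast

logger = logging.getLogger(__name__)

CORTISOL_TIMES = (7.0, 10.0, 13.0, 16.0)
#: default allocation coefficients: maintenance kg feed per kg^0.75 and kg feed per kg gain
DFI_MAINTENANCE_COEF = 0.033
DFI_GROWTH_COEF = 2.6
TRIAL_DAYS = 28


@dataclass
class PhenotypeRecord:
    """Derived per-animal phenotype summary."""

    animal_id: str
    pen: str
    adg: float
    dfi: float
    fcr: float  # NaN when ADG <= 0
    cortisol_auc: float  # mean over trial sampling weeks
    lesion_score: float  # mean weekly total over trial weeks


def cortisol_auc(values, times=CORTISOL_TIMES) -> float:
    """Trapezoidal AUC of a single day's cortisol profile over clock hours."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ValueError("need one concentration per time point")
    if np.isnan(values).any():
        raise ValueError("missing cortisol point; no imputation is performed")
    if (values < 0).any():
        raise ValueError("cortisol concentrations must be non-negative")
    return float(np.trapezoid(values, times))


def growth_traits(weights, days: float, dfi: float | None = None) -> tuple[float, float]:
    """(ADG, FCR) from first/last weights; FCR is NaN when ADG <= 0."""
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    adg = float((weights[-1] - weights[0]) / days)
    if dfi is None:
        return adg, np.nan
    if adg <= 0:
        warnings.warn("ADG <= 0; FCR undefined, reported missing", stacklevel=2)
        return adg, np.nan
    return adg, float(dfi / adg)


def estimate_individual_dfi(
    pen_totals: pd.Series | dict,
    weights: pd.Series,
    gains: pd.Series,
    pens: pd.Series,
    maintenance_coef: float = DFI_MAINTENANCE_COEF,
    growth_coef: float = DFI_GROWTH_COEF,
) -> pd.Series:
    """Apportion pen-level daily feed totals to animals.

    Predicted intake per animal is ``a * weight^0.75 + b * ADG``; each pen's
    total is split proportionally so per-pen sums match the total exactly.
    Animals in a pen with a missing total get NaN.
    """
    pen_totals = pd.Series(pen_totals, dtype=float)
    weights = pd.Series(weights, dtype=float)
    gains = pd.Series(gains, dtype=float)
    pens = pd.Series(pens)
    pred = maintenance_coef * weights**0.75 + growth_coef * gains
    if (pred <= 0).any():
        raise ValueError("predicted intakes must be positive")
    out = pd.Series(np.nan, index=weights.index)
    for pen, idx in pens.groupby(pens).groups.items():
        if pen not in pen_totals.index or pd.isna(pen_totals[pen]):
            warnings.warn(f"pen {pen!r} has no feed total; animals flagged missing", stacklevel=2)
            continue
        share = pred.loc[idx] / pred.loc[idx].sum()
        out.loc[idx] = share * pen_totals[pen]
    return out


def lesion_total(zone_counts) -> int:
    """Total lesion count over the six body zones."""
    counts = np.asarray(zone_counts)
    if counts.size != 6:
        raise ValueError("expected counts for 6 body zones")
    if (counts < 0).any():
        raise ValueError("lesion counts must be non-negative")
    return int(counts.sum())


def control_minus_stress(control_mean: float, stress_mean: float) -> float:
    """Table-style difference: control group mean minus stress group mean."""
    return control_mean - stress_mean


# ---------------------------------------------------------------------------
# assembling records from the phenotypes table
# ---------------------------------------------------------------------------

_WEIGHT_RE = re.compile(r"^weight_wk(\d+)$")
_LESION_RE = re.compile(r"^lesions_wk(\d+)_(\w+)$")
_CORTISOL_RE = re.compile(r"^cortisol_wk(\d+)_h(\d+)$")


def records_from_frame(phen: pd.DataFrame, trial_days: float = TRIAL_DAYS) -> pd.DataFrame:
    """Derive per-animal traits from the wide phenotype table.

    Cortisol AUC averages over trial sampling weeks only (week 0 is the
    pre-trial baseline); lesion score is the mean weekly total.
    """
    phen = phen.set_index("animal_id") if "animal_id" in phen.columns else phen
    weight_cols = sorted(
        (c for c in phen.columns if _WEIGHT_RE.match(c)),
        key=lambda c: int(_WEIGHT_RE.match(c).group(1)),
    )
    if len(weight_cols) < 2:
        raise ValueError("need at least two weekly weight columns")

    gains = (phen[weight_cols[-1]] - phen[weight_cols[0]]) / trial_days
    pen_totals = phen.groupby("pen")["pen_feed_daily_kg"].first()
    dfi = estimate_individual_dfi(pen_totals, phen[weight_cols[0]], gains, phen["pen"])
    with np.errstate(divide="ignore", invalid="ignore"):
        fcr = (dfi / gains).where(gains > 0)

    lesion_weeks: dict[int, list[str]] = {}
    for c in phen.columns:
        m = _LESION_RE.match(c)
        if m:
            lesion_weeks.setdefault(int(m.group(1)), []).append(c)
    weekly_totals = pd.DataFrame(
        {wk: phen[cols].sum(axis=1) for wk, cols in sorted(lesion_weeks.items())}
    )
    lesion_score = weekly_totals.mean(axis=1)

    cort_weeks: dict[int, list[str]] = {}
    for c in phen.columns:
        m = _CORTISOL_RE.match(c)
        if m:
            cort_weeks.setdefault(int(m.group(1)), []).append(c)
    trial_weeks = [wk for wk in sorted(cort_weeks) if wk > 0]
    aucs = pd.DataFrame(
        {
            wk: phen[sorted(cort_weeks[wk], key=lambda c: int(_CORTISOL_RE.match(c).group(2)))]
            .apply(lambda row: cortisol_auc(row.to_numpy()), axis=1)
            for wk in trial_weeks
        }
    )
    mean_auc = aucs.mean(axis=1)

    return pd.DataFrame(
        {
            "pen": phen["pen"],
            "adg": gains,
            "dfi": dfi,
            "fcr": fcr,
            "cortisol_auc": mean_auc,
            "lesion_score": lesion_score,
        }
    )


TRAITS = ("dfi", "adg", "fcr", "cortisol_auc", "lesion_score")


def phenotype_contrasts(
    phen: pd.DataFrame, meta: pd.DataFrame, traits=TRAITS
) -> pd.DataFrame:
    """Table-1-style report: per trait LS means, control-stress difference, p.

    ``meta`` is sample- or animal-level metadata with animal_id, treatment and
    litter; contrasts use the mixed model (treatment fixed, litter random).
    """
    records = records_from_frame(phen)
    animal_meta = meta.drop_duplicates("animal_id").set_index("animal_id")
    missing = [a for a in records.index if a not in animal_meta.index]
    if missing:
        raise ValueError(f"animals absent from metadata: {missing}")
    animal_meta = animal_meta.loc[records.index]
    rows = []
    for trait in traits:
        y = records[trait]
        ok = y.notna()
        if ok.sum() < len(y):
            logger.info("trait %s: dropping %d animals with missing values", trait, (~ok).sum())
        mc = mixed_contrast(
            y[ok].to_numpy(),
            animal_meta.loc[ok, "treatment"].to_numpy(),
            animal_meta.loc[ok, "litter"].to_numpy(),
            contrast=("control", "stress"),
        )
        rows.append(
            {
                "trait": trait,
                "control_mean": mc.lsmeans["control"][0],
                "control_se": mc.lsmeans["control"][1],
                "stress_mean": mc.lsmeans["stress"][0],
                "stress_se": mc.lsmeans["stress"][1],
                "difference": mc.estimate,
                "difference_se": mc.se,
                "p": mc.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
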