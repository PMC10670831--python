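"""Compositional preprocessing: prevalence search, abundance filter, Dirichlet clr.

The prevalence threshold is chosen by scanning a grid of per-group prevalence
cut-offs and scoring each retained genus set with the out-of-bag error of a
bagged decision-tree ensemble fit on relative abundances.  Remaining zeros are
replaced by Monte-Carlo draws from a per-sample Dirichlet posterior
(counts + prior mass), and every draw is centred-log-ratio transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .tables_io import GenusCountTable

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def clr(proportions: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform along the last axis.

    ``clr_j = ln(x_j) - mean_j ln(x_j)``; rows sum to zero.  Input must be
    strictly positive (scale-invariant, so unnormalised compositions work).
    """
    x = np.asarray(proportions, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive parts")
    logs = np.log(x)
    return logs - logs.mean(axis=-1, keepdims=True)


@dataclass
class PrevalenceSearchResult:
    threshold: float
    oob_table: pd.DataFrame  # columns: threshold, n_genera, oob_error
    retained: list[str]


def genus_prevalence(table: GenusCountTable, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Fraction of samples with count>0 per genus, within each label group."""
    labels = np.asarray(labels)
    present = table.counts > 0
    rows = {g: present[np.asarray(labels) == g].mean(axis=0) for g in np.unique(labels)}
    return pd.DataFrame(rows)


def prevalence_threshold_search(
    table: GenusCountTable,
    labels,
    grid=DEFAULT_GRID,
    n_trees: int = 500,
    seed: int = 0,
) -> PrevalenceSearchResult:
    """Pick the prevalence threshold minimising out-of-bag error (tie -> smallest).

    A genus survives a threshold if it is present (count>0) in at least that
    fraction of samples *within at least one* label group.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_samples:
        raise ValueError("labels length does not match number of samples")
    if len(np.unique(labels)) != 2:
        raise ValueError("prevalence search expects exactly two label groups")
    prev = genus_prevalence(table, labels).max(axis=1)
    rel = table.relative_abundance().to_numpy()
    records = []
    for thr in np.asarray(grid, dtype=float):
        keep = prev.index[prev >= thr].tolist()
        if not keep:
            logger.warning("prevalence threshold %.2f leaves no genera; skipped", thr)
            continue
        cols = [table.genus_ids.index(g) for g in keep]
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            clf.fit(rel[:, cols], labels)
        records.append(
            {"threshold": float(thr), "n_genera": len(keep), "oob_error": 1.0 - clf.oob_score_}
        )
    if not records:
        raise ValueError("every threshold in the grid left zero genera")
    oob = pd.DataFrame(records)
    best = oob.loc[oob["oob_error"].idxmin()]  # idxmin returns first minimum: smallest threshold
    thr = float(best["threshold"])
    retained = prev.index[prev >= thr].tolist()
    return PrevalenceSearchResult(threshold=thr, oob_table=oob, retained=retained)


def apply_prevalence_filter(table: GenusCountTable, threshold: float, labels) -> GenusCountTable:
    prev = genus_prevalence(table, labels).max(axis=1)
    keep = prev.index[prev >= threshold].tolist()
    if not keep:
        raise ValueError(f"prevalence threshold {threshold} leaves no genera")
    return table.subset_genera(keep)


def abundance_filter(
    table: GenusCountTable, min_mean_rel_abund: float = 0.001
) -> tuple[GenusCountTable, list[str]]:
    """Drop genera whose mean relative abundance is strictly below the cut-off.

    A genus at exactly the cut-off is retained.  Returns the filtered table and
    the list of dropped genus ids.
    """
    mean_rel = table.relative_abundance().mean(axis=0)
    keep = mean_rel.index[mean_rel >= min_mean_rel_abund].tolist()
    dropped = [g for g in table.genus_ids if g not in keep]
    if not keep:
        raise ValueError(
            "abundance filter removed every genus; review the threshold "
            f"(min_mean_rel_abund={min_mean_rel_abund})"
        )
    return table.subset_genera(keep), dropped


@dataclass
class ClrEnsemble:
    """K Monte-Carlo clr instances per sample plus their element-wise mean."""

    instances: np.ndarray  # (K, n_samples, n_genera)
    sample_ids: list[str]
    genus_ids: list[str]
    prior: float = 0.5
    mean: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.instances.ndim != 3:
            raise ValueError("instances must be a (K, n, p) array")
        if self.instances.shape[0] < 1:
            raise ValueError("need at least one Monte-Carlo instance")
        row_sums = self.instances.sum(axis=2)
        if not np.allclose(row_sums, 0.0, atol=1e-8):
            raise ValueError("clr instance rows must sum to zero")
        self.mean = pd.DataFrame(
            self.instances.mean(axis=0), index=self.sample_ids, columns=self.genus_ids
        )

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


def dirichlet_clr(
    table: GenusCountTable, K: int = 128, prior: float = 0.5, seed: int = 0
) -> ClrEnsemble:
    """Monte-Carlo Dirichlet zero replacement followed by clr transformation.

    For each sample, K compositions are drawn from Dirichlet(counts + prior)
    and clr-transformed; draws are strictly positive so the log is always
    defined.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if prior <= 0:
        raise ValueError("prior mass must be positive")
    counts = table.counts.to_numpy(dtype=float)
    zero_rows = np.where(counts.sum(axis=1) == 0)[0]
    if zero_rows.size:
        bad = [table.sample_ids[i] for i in zero_rows]
        raise ValueError(f"all-zero sample rows: {bad}")
    rng = np.random.default_rng(seed)
    n, p = counts.shape
    instances = np.empty((K, n, p))
    for i in range(n):
        draws = rng.dirichlet(counts[i] + prior, size=K)
        # numerical guard: dirichlet can underflow to exact zero for tiny alpha
        np.clip(draws, 1e-300, None, out=draws)
        instances[:, i, :] = clr(draws)
    return ClrEnsemble(instances, table.sample_ids, table.genus_ids, prior=prior)


@dataclass
class FilterReport:
    site: str | None
    prevalence_threshold: float
    oob_table: pd.DataFrame
    dropped_low_abundance: list[str]
    n_genera_in: int
    n_genera_out: int

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "prevalence_threshold": self.prevalence_threshold,
            "oob_table": self.oob_table.to_dict(orient="records"),
            "dropped_low_abundance": self.dropped_low_abundance,
            "n_genera_in": self.n_genera_in,
            "n_genera_out": self.n_genera_out,
        }


def preprocess_table(
    table: GenusCountTable,
    labels,
    grid=DEFAULT_GRID,
    n_trees: int = 500,
    K: int = 128,
    prior: float = 0.5,
    min_mean_rel_abund: float = 0.001,
    seed: int = 0,
) -> tuple[GenusCountTable, ClrEnsemble, FilterReport]:
    """Full preprocessing chain: prevalence search -> abundance filter -> clr ensemble."""
    search = prevalence_threshold_search(table, labels, grid=grid, n_trees=n_trees, seed=seed)
    filtered = table.subset_genera(search.retained)
    filtered, dropped = abundance_filter(filtered, min_mean_rel_abund)
    ensemble = dirichlet_clr(filtered, K=K, prior=prior, seed=seed)
    report = FilterReport(
        site=table.site,
        prevalence_threshold=search.threshold,
        oob_table=search.oob_table,
        dropped_low_abundance=dropped,
        n_genera_in=table.n_genera,
        n_genera_out=filtered.n_genera,
    )
    return filtered, ensemble, report
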