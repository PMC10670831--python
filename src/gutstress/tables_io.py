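"""Reading, writing and validating genus count tables and sample metadata.

Count tables are plain TSV/CSV matrices (samples as rows by default, genera as
columns).  A BIOM-style TSV dialect whose header starts with ``#OTU ID`` is
recognised and treated as genera-as-rows.  Genus identifiers may carry a
``;``-separated lineage string (phylum→genus); the last field is used as the
genus id and the full lineage is kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("stress", "control")
SITES = ("caecum", "colon", "feces")

METADATA_COLUMNS = ("sample_id", "animal_id", "treatment", "litter", "pen", "site")


class TableValidationError(ValueError):
    """Raised when a count table or metadata table violates its contract."""


@dataclass
class GenusCountTable:
    """A samples x genera matrix of non-negative integer counts for one site.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with genus ids as columns.
    site
        Optional sampling-site label (e.g. ``caecum``).
    lineages
        Optional mapping genus id -> lineage tuple (phylum ... genus).
    """

    counts: pd.DataFrame
    site: str | None = None
    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate genus ids: {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("count table contains non-numeric cells")
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise TableValidationError(
                f"missing count at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative count at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr.astype(float))):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr.astype(float))))[0]
            raise TableValidationError(
                f"non-integer count at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genera(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals (no rarefaction)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise TableValidationError(f"samples with zero total count: {empty}")
        return self.counts.div(totals, axis=0)

    def subset_genera(self, genus_ids) -> "GenusCountTable":
        genus_ids = list(genus_ids)
        missing = [g for g in genus_ids if g not in self.counts.columns]
        if missing:
            raise TableValidationError(f"unknown genus ids: {missing}")
        lineages = {g: self.lineages[g] for g in genus_ids if g in self.lineages}
        return GenusCountTable(self.counts[genus_ids].copy(), site=self.site, lineages=lineages)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(path, orientation: str = "samples", site: str | None = None) -> GenusCountTable:
    """Read a count table from TSV/CSV.

    ``orientation="samples"`` means samples are rows; ``"genera"`` means the
    file is transposed (genera as rows).  A leading ``#OTU ID`` header cell
    (BIOM TSV dialect) forces genera-as-rows.
    """
    path = Path(path)
    if orientation not in ("samples", "genera"):
        raise ValueError(f"orientation must be 'samples' or 'genera', got {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#OTU ID"):
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index.name = None
        orientation = "genera"
    else:
        df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genera":
        df = df.T
    df.index.name = None
    df.columns.name = None
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:1]
        raise TableValidationError(
            f"non-numeric count in column {col!r}" + (f", row {row[0]!r}" if row else "")
        )
    lineages: dict[str, tuple[str, ...]] = {}
    if any(";" in str(c) for c in df.columns):
        new_cols = []
        for c in df.columns:
            parts = tuple(p.strip() for p in str(c).split(";"))
            genus = parts[-1]
            lineages[genus] = parts
            new_cols.append(genus)
        df.columns = new_cols
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GenusCountTable(df, site=site, lineages=lineages)


def write_count_table(table: GenusCountTable, path) -> None:
    path = Path(path)
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    meta.to_csv(path, sep=_sep_for(path), index=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise TableValidationError(f"metadata missing columns: {missing_cols}")
    for col in ("treatment", "litter"):
        if meta[col].isna().any():
            rows = meta.loc[meta[col].isna(), "sample_id"].tolist()
            raise TableValidationError(f"missing {col} for samples: {rows}")
    bad_treat = sorted(set(meta["treatment"]) - set(TREATMENTS))
    if bad_treat:
        raise TableValidationError(f"unknown treatment levels: {bad_treat}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"duplicate sample ids in metadata: {dupes}")
    dup = meta.duplicated(subset=["animal_id", "site"], keep=False)
    if dup.any():
        pairs = meta.loc[dup, ["animal_id", "site"]].drop_duplicates().to_records(index=False)
        raise TableValidationError(f"animal mapped to >1 sample per site: {list(pairs)}")
    return meta


def join_metadata(table: GenusCountTable, meta: pd.DataFrame) -> tuple[GenusCountTable, pd.DataFrame]:
    """Align metadata rows to the count-table sample order.

    Returns the (unchanged) table and a metadata frame whose row order matches
    ``table.sample_ids`` exactly.  Samples without metadata raise.
    """
    meta = validate_metadata(meta)
    indexed = meta.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in indexed.index]
    if missing:
        raise TableValidationError(f"samples absent from metadata: {missing}")
    aligned = indexed.loc[table.sample_ids].reset_index()
    return table, aligned
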