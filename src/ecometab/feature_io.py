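"""Reading, writing and reshaping of LC-MS feature tables.

An untargeted LC-MS experiment exported MarkerLynx-style is a samples x
features matrix of ion abundances (areas/counts).  Each feature is an ion
identified by its mass-to-charge ratio and retention time, encoded in the
column header as an ``<mz>_<rt>`` token.  Treating every such feature as a
"species" and every biological replicate as a sampling unit turns the table
into a community-ecology data set; this module supplies the community
containers (abundance matrix, presence/absence incidence matrix) and the
pooling operations the ecological analyses downstream expect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONCENTRATIONS = ("C27", "C16", "C4")
TIMES = ("T0", "T7", "T14", "T21", "T28")
MODES = ("ESI+", "ESI-")

#: acquisition mass window (Da) used when feature-ID validation is enabled
MZ_MIN = 50.0
MZ_MAX = 1200.0

META_COLUMNS = ("concentration", "time", "replicate", "mode")

_NUMBER = re.compile(r"^\d+(\.\d+)?$")


class FeatureIDError(ValueError):
    """A feature label could not be parsed as an m/z_rt pair."""


@dataclass(frozen=True)
class FeatureID:
    """A detected ion feature: m/z (Th) plus retention time (minutes)."""

    mz: float
    rt: float
    label: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise FeatureIDError(f"non-positive m/z in {self.label!r}")
        if self.rt < 0:
            raise FeatureIDError(f"negative retention time in {self.label!r}")


def parse_feature_id(label: str, sep: str = "_", validate_range: bool = False) -> FeatureID:
    """Parse an ``<mz><sep><rt>`` feature label into a :class:`FeatureID`.

    Parameters
    ----------
    label:
        The original column-header token, e.g. ``"377.0844_2.9"``.
    sep:
        Separator between the m/z and rt fields (dialect dependent).
    validate_range:
        If true, require the m/z to lie inside the acquisition window
        (50-1200 Da).

    The original string is preserved on the returned object so labels
    round-trip exactly.
    """
    parts = str(label).split(sep)
    if len(parts) != 2:
        raise FeatureIDError(
            f"feature label {label!r} does not match '<mz>{sep}<rt>'"
        )
    mz_tok, rt_tok = parts
    for tok, name in ((mz_tok, "m/z"), (rt_tok, "rt")):
        if not _NUMBER.match(tok):
            raise FeatureIDError(f"malformed {name} token {tok!r} in {label!r}")
    fid = FeatureID(mz=float(mz_tok), rt=float(rt_tok), label=str(label))
    if validate_range and not (MZ_MIN < fid.mz < MZ_MAX):
        raise FeatureIDError(
            f"m/z {fid.mz} outside acquisition range ({MZ_MIN}-{MZ_MAX} Da)"
        )
    return fid


def format_feature_id(mz: float, rt: float, sep: str = "_") -> str:
    """Render an m/z_rt pair as a MarkerLynx-style label.

    m/z keeps 4 decimals; rt keeps up to 4 with trailing zeros trimmed
    (plain decimal notation, never scientific).
    """
    rt_tok = f"{rt:.4f}".rstrip("0").rstrip(".")
    if not rt_tok or rt_tok == "-0":
        rt_tok = "0"
    return f"{mz:.4f}{sep}{rt_tok}"


def _check_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    key = meta[list(META_COLUMNS)].apply(tuple, axis=1)
    if key.duplicated().any():
        dups = key[key.duplicated()].tolist()
        raise ValueError(f"duplicate (concentration,time,replicate,mode): {dups}")
    return meta


@dataclass
class FeatureMatrix:
    """Samples x features abundance matrix with sample metadata.

    ``abundance`` is indexed by sample ID with one column per feature
    label; ``meta`` is indexed the same way with columns
    concentration/time/replicate/mode.  ``allow_negative`` is set on
    matrices that have been centred/scaled, where raw-intensity
    invariants no longer apply.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            dups = self.abundance.columns[self.abundance.columns.duplicated()]
            raise ValueError(f"duplicate feature labels: {list(dups)[:5]}")
        if not self.abundance.index.equals(self.meta.index):
            missing = self.abundance.index.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"samples absent from metadata: {list(missing)[:5]}")
            self.meta = self.meta.loc[self.abundance.index]
        if not self.allow_negative and (self.abundance.values < 0).any():
            raise ValueError("negative abundances in raw feature matrix")
        _check_meta(self.meta)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    @property
    def feature_labels(self) -> list[str]:
        return list(self.abundance.columns)

    def feature_ids(self, sep: str = "_") -> list[FeatureID]:
        return [parse_feature_id(lbl, sep=sep) for lbl in self.abundance.columns]

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return replace(
            self,
            abundance=self.abundance.loc[list(sample_ids)],
            meta=self.meta.loc[list(sample_ids)],
        )

    def group_samples(self, by: Sequence[str] = ("concentration", "time")) -> dict[str, list[str]]:
        """Map group label (e.g. ``"C27_T14"``) -> member sample IDs."""
        out: dict[str, list[str]] = {}
        for key, sub in self.meta.groupby(list(by), sort=False, observed=True):
            if not isinstance(key, tuple):
                key = (key,)
            out["_".join(str(k) for k in key)] = list(sub.index)
        return out


@dataclass
class IncidenceMatrix:
    """Units x features presence/absence matrix (entries 0/1)."""

    presence: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.presence.values
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def n_units(self) -> int:
        return self.presence.shape[0]

    @property
    def unit_richness(self) -> pd.Series:
        return self.presence.sum(axis=1)

    @property
    def incidence_counts(self) -> pd.Series:
        """Per-feature number of units in which the feature occurs."""
        return self.presence.sum(axis=0)


def read_feature_table(
    path: str | Path,
    meta: str | Path | pd.DataFrame,
    mode: str | None = None,
    sep: str | None = None,
) -> FeatureMatrix:
    """Read a feature table (CSV/TSV/XLSX) plus sample metadata.

    The table must carry one header row of feature labels and one row per
    sample, with the sample ID in the first column.  Blank cells are the
    instrument's "not detected" code and are imputed as 0 (logged).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path, index_col=0)
    else:
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        table = pd.read_csv(path, sep=sep, index_col=0)
    if table.empty:
        raise ValueError(f"empty feature table: {path}")
    if table.columns.duplicated().any():
        dups = list(table.columns[table.columns.duplicated()])
        raise ValueError(f"duplicate feature labels in {path}: {dups[:5]}")
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        logger.warning("%d blank cells in %s imputed as 0 (absence)", n_missing, path)
        table = table.fillna(0.0)
    table = table.astype(float)

    if not isinstance(meta, pd.DataFrame):
        meta = pd.read_csv(meta)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.copy()
    missing = table.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples in table absent from metadata: {list(missing)[:5]}")
    meta = meta.loc[table.index]
    if mode is not None:
        keep = meta["mode"] == mode
        table, meta = table.loc[keep], meta.loc[keep]
    return FeatureMatrix(abundance=table, meta=meta)


def write_feature_table(
    fm: FeatureMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    fm.abundance.to_csv(path, sep=sep, index_label="sample_id")
    if meta_path is not None:
        fm.meta.to_csv(meta_path, index_label="sample_id")


def to_incidence(fm: FeatureMatrix, threshold: float = 0.0) -> IncidenceMatrix:
    """Binarize abundances: present iff abundance strictly exceeds ``threshold``.

    The default threshold 0 makes any positive ion area a detection, the
    convention for MarkerLynx-style exports in which zero codes absence.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    presence = (fm.abundance.values > threshold).astype(np.int8)
    return IncidenceMatrix(
        presence=pd.DataFrame(presence, index=fm.abundance.index, columns=fm.abundance.columns),
        meta=fm.meta,
    )


def pool_units(
    im: IncidenceMatrix, by: Sequence[str] = ("concentration", "time")
) -> IncidenceMatrix:
    """Pool sampling units by metadata keys with logical-OR presence.

    Pooling the three biological replicates of each treatment x time cell
    yields the per-condition incidence used for condition-level richness
    (e.g. the 15 units of a 3-concentration x 5-time design).
    """
    if im.meta is None:
        raise ValueError("incidence matrix has no metadata to pool by")
    by = list(by)
    missing = [k for k in by if k not in im.meta.columns]
    if missing:
        raise ValueError(f"grouping keys not in metadata: {missing}")
    groups = im.meta.groupby(by, sort=False, observed=True).groups
    if not groups:
        raise ValueError("no groups to pool")
    rows, labels, meta_rows = [], [], []
    for key, idx in groups.items():
        if not isinstance(key, tuple):
            key = (key,)
        labels.append("_".join(str(k) for k in key))
        rows.append(im.presence.loc[idx].max(axis=0))
        meta_rows.append(dict(zip(by, key)))
    pooled = pd.DataFrame(rows, index=labels)
    meta = pd.DataFrame(meta_rows, index=labels)
    return IncidenceMatrix(presence=pooled.astype(np.int8), meta=meta)
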