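"""Data model and I/O for multi-rater ordinal ratings.

Canonical format is a long (tidy) CSV with columns ``lesion_id, rater_id,
molem_class`` and an optional ``confidence`` column (1 = most confident,
5 = least).  Raters need not rate every lesion.  A wide lesions-by-raters
reader is provided for convenience; empty cells mean "did not rate".

All agreement statistics consume the :class:`CountMatrix` produced by
:func:`tally` — the per-lesion category tallies ``r_ik`` that are the
sufficient statistic for multi-rater chance-corrected agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .schema import CLASSES, MolemClass, parse_class

logger = logging.getLogger(__name__)

__all__ = ["RatingTable", "CountMatrix", "read_ratings", "read_wide", "tally"]

REQUIRED_COLUMNS = ("lesion_id", "rater_id", "molem_class")


@dataclass
class RatingTable:
    """Validated long-format ratings: one row per (lesion, rater).

    ``df`` holds columns ``lesion_id`` (str), ``rater_id`` (str),
    ``molem_class`` (:class:`MolemClass`) and ``confidence`` (nullable Int64,
    1..5 where 1 is most confident).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing required columns: {missing}")
        df = df.copy()
        df["lesion_id"] = df["lesion_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(str)
        bad = []
        parsed = []
        for idx, label in df["molem_class"].items():
            if isinstance(label, MolemClass):
                parsed.append(label)
                continue
            try:
                parsed.append(parse_class(label))
            except Exception:
                bad.append((idx, label))
        if bad:
            raise DataError(
                "unknown class labels at rows "
                + ", ".join(f"{i}: {l!r}" for i, l in bad[:10])
            )
        df["molem_class"] = parsed
        if "confidence" not in df.columns:
            df["confidence"] = pd.array([pd.NA] * len(df), dtype="Int64")
        else:
            conf = pd.to_numeric(df["confidence"], errors="coerce")
            raw_missing = df["confidence"].isna()
            if (conf.isna() & ~raw_missing).any():
                raise DataError("non-numeric confidence values present")
            out_of_range = conf.dropna()[(conf.dropna() < 1) | (conf.dropna() > 5)]
            if len(out_of_range):
                raise DataError(
                    f"confidence outside 1..5 at rows {list(out_of_range.index[:10])}"
                )
            if ((conf.dropna() % 1) != 0).any():
                raise DataError("confidence scores must be integers in 1..5")
            df["confidence"] = conf.astype("Int64")
        dup = df.duplicated(subset=["lesion_id", "rater_id"], keep=False)
        if dup.any():
            pairs = df.loc[dup, ["lesion_id", "rater_id"]].drop_duplicates()
            raise DataError(
                "duplicate (lesion_id, rater_id) pairs: "
                + ", ".join(f"({r.lesion_id}, {r.rater_id})" for r in pairs.itertuples())
            )
        self.df = df.reset_index(drop=True)

    @property
    def lesions(self) -> list[str]:
        return sorted(self.df["lesion_id"].unique())

    @property
    def raters(self) -> list[str]:
        return sorted(self.df["rater_id"].unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def ratings_of(self, lesion_id: str) -> list[MolemClass]:
        return list(self.df.loc[self.df["lesion_id"] == str(lesion_id), "molem_class"])

    def write_csv(self, path) -> None:
        out = self.df.copy()
        out["molem_class"] = [c.value for c in out["molem_class"]]
        out.to_csv(path, index=False)


def read_ratings(path, column_map: dict[str, str] | None = None) -> RatingTable:
    """Read a long-format ratings CSV into a validated :class:`RatingTable`.

    ``column_map`` renames input columns to the canonical names, e.g.
    ``{"slide": "lesion_id"}``.
    """
    df = pd.read_csv(path, dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    table = RatingTable(df)
    logger.info("read %d rating records (%d lesions, %d raters) from %s",
                table.n_records, len(table.lesions), len(table.raters), path)
    return table


def read_wide(path) -> RatingTable:
    """Read a wide lesions-by-raters matrix CSV; empty cells = not rated.

    First column is the lesion id; remaining column headers are rater ids.
    Confidence scores cannot be carried in this format.
    """
    df = pd.read_csv(path, dtype=str)
    lesion_col = df.columns[0]
    long = df.melt(id_vars=[lesion_col], var_name="rater_id", value_name="molem_class")
    long = long.rename(columns={lesion_col: "lesion_id"})
    long = long.dropna(subset=["molem_class"])
    long = long[long["molem_class"].astype(str).str.strip() != ""]
    return RatingTable(long.reset_index(drop=True))


@dataclass(frozen=True)
class CountMatrix:
    """Per-lesion category tallies r_ik.

    ``r[i, k]`` is the number of raters assigning category k (fixed order
    I, II, III, IV, V) to lesion i; ``r_i`` are the per-lesion rating totals.
    Lesions with a single rating are retained: they contribute to category
    prevalence but are excluded from percent-agreement averaging downstream.
    """

    lesion_ids: tuple[str, ...]
    r: np.ndarray  # (n_lesions, q) ints
    categories: tuple = CLASSES

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=int)
        if r.ndim != 2 or r.shape[0] != len(self.lesion_ids):
            raise DataError("count matrix shape mismatch")
        if (r < 0).any():
            raise DataError("negative rating counts")
        if (r.sum(axis=1) < 1).any():
            raise DataError("every lesion must carry at least one rating")
        object.__setattr__(self, "r", r)

    @property
    def r_i(self) -> np.ndarray:
        return self.r.sum(axis=1)

    @property
    def n_lesions(self) -> int:
        return self.r.shape[0]

    @property
    def n_ratings(self) -> int:
        return int(self.r.sum())

    @property
    def q(self) -> int:
        return self.r.shape[1]

    def subset(self, lesion_ids) -> "CountMatrix":
        wanted = [str(x) for x in lesion_ids]
        index = {lid: i for i, lid in enumerate(self.lesion_ids)}
        rows = [index[lid] for lid in wanted]
        return CountMatrix(tuple(wanted), self.r[rows], self.categories)


def tally(table: RatingTable) -> CountMatrix:
    """Tabulate a :class:`RatingTable` into its per-lesion count matrix.

    The category set is fixed to the five MOLEM classes even when some class
    never appears in the data — prevalence estimation needs the full simplex.
    """
    cat_index = {c: k for k, c in enumerate(CLASSES)}
    lesions = table.lesions
    lesion_index = {lid: i for i, lid in enumerate(lesions)}
    r = np.zeros((len(lesions), len(CLASSES)), dtype=int)
    for lid, cls in zip(table.df["lesion_id"], table.df["molem_class"]):
        r[lesion_index[lid], cat_index[cls]] += 1
    n_single = int((r.sum(axis=1) == 1).sum())
    if n_single:
        logger.warning(
            "%d lesion(s) have a single rating: retained for prevalence, "
            "excluded from percent-agreement averaging", n_single,
        )
    return CountMatrix(tuple(lesions), r)


def confidence_counts(table: RatingTable) -> CountMatrix:
    """Tally 1..5 confidence scores per lesion (records lacking one dropped)."""
    df = table.df.dropna(subset=["confidence"])
    if df.empty:
        raise DataError("no confidence scores present")
    lesions = sorted(df["lesion_id"].unique())
    lesion_index = {lid: i for i, lid in enumerate(lesions)}
    r = np.zeros((len(lesions), 5), dtype=int)
    for lid, score in zip(df["lesion_id"], df["confidence"]):
        r[lesion_index[lid], int(score) - 1] += 1
    return CountMatrix(tuple(lesions), r, categories=(1, 2, 3, 4, 5))
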