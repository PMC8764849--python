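"""Scoring and descriptive analysis of SDQ item-level cohorts.

A cohort lives in a pandas DataFrame with columns ``subject_id``,
``version`` (self | parent), ``item01`` .. ``item25`` (0/1/2 or NaN),
``age`` (integer years 12-17), ``gender`` (male | female),
``ethnic_background`` (majority | other) and ``maternal_education``
(low | medium | high). Scale scoring reverse-codes the five positively
worded items and sums; a score is prorated when a small number of item
responses is missing (see :func:`score_scales`).
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from sdqnorm.instrument import ALL_SCALES, N_ITEMS, Instrument, SDQ_INSTRUMENT

if TYPE_CHECKING:  # pragma: no cover
    from sdqnorm.tables import CutoffTable

logger = logging.getLogger(__name__)

ITEM_COLUMNS = tuple(f"item{i:02d}" for i in range(1, N_ITEMS + 1))
DEMOGRAPHIC_COLUMNS = ("age", "gender", "ethnic_background", "maternal_education")
GENDERS = ("male", "female")

DEFAULT_NA_VALUES = ("", "NA", "NaN", "nan")


class CohortValidationError(ValueError):
    """Raised when an input cohort violates the item/demographic contract."""


def item_column(i: int) -> str:
    """1-based item number -> column name."""
    return f"item{i:02d}"


def load_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read an item-level cohort from a delimited text file.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.
    schema : mapping, optional
        Maps canonical column names (``subject_id``, ``item01`` ...) to the
        names used in the file. Columns not mentioned keep their name.
    na_values : sequence of str
        Cell encodings treated as missing.
    delimiter : str, optional
        Field delimiter; sniffed by pandas when omitted.

    Raises
    ------
    CohortValidationError
        If mandatory columns are missing or an item cell holds a value
        outside {0, 1, 2}.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=list(na_values),
                     keep_default_na=False, engine="python")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    mandatory = ("subject_id",) + ITEM_COLUMNS
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing mandatory columns: {missing_cols}")
    for col in ITEM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (vals.isna() | ~vals.isin([0, 1, 2]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"item value {df[col].iloc[row]!r} outside {{0,1,2}} "
                f"in column {col}, row {row}"
            )
        df[col] = vals.astype(float)
    if "age" in df.columns:
        df["age"] = np.floor(pd.to_numeric(df["age"], errors="coerce"))
    n_cells = len(df) * N_ITEMS
    n_missing = int(df[list(ITEM_COLUMNS)].isna().sum().sum())
    logger.info("loaded %d records from %s (%.2f%% missing item cells)",
                len(df), path, 100.0 * n_missing / max(n_cells, 1))
    return df


def filter_complete_demographics(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep records with age, gender, ethnic background and maternal
    education all present (and gender in {male, female}); return the kept
    table and the number dropped."""
    mask = np.ones(len(table), dtype=bool)
    for col in DEMOGRAPHIC_COLUMNS:
        mask &= table[col].notna().to_numpy()
    n_othergender = int((table["gender"].notna() & ~table["gender"].isin(GENDERS)).sum())
    if n_othergender:
        logger.info("excluding %d records with gender outside %s", n_othergender, GENDERS)
        mask &= table["gender"].isin(GENDERS).to_numpy()
    kept = table.loc[mask].reset_index(drop=True)
    dropped = len(table) - len(kept)
    logger.info("demographic completeness filter: kept %d, dropped %d", len(kept), dropped)
    return kept, dropped


def reverse_code(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Recode 0/1/2 responses as 2 - value (an involution)."""
    return 2 - values


def score_scales(
    table: pd.DataFrame,
    instrument: Instrument = SDQ_INSTRUMENT,
    min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Compute the eight scale scores per subject.

    Reversed items are recoded as ``2 - value`` before summation. A scale
    score is computed when at least ``min_fraction`` of its member items
    (>= 4 of 5 for the base scales at the 0.8 default) are present; the sum
    of present items is then prorated to the full item count and rounded to
    the nearest integer (half away from zero). Otherwise the score is NaN.
    """
    out = table[[c for c in ("subject_id", "version") if c in table.columns]].copy()
    for col in DEMOGRAPHIC_COLUMNS:
        if col in table.columns:
            out[col] = table[col]
    items = table[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    for name in instrument.scale_names:
        sdef = instrument[name]
        idx = [m - 1 for m in sdef.member_items]
        vals = items[:, idx].copy()
        rev_pos = [sdef.member_items.index(m) for m in sdef.reversed_items]
        vals[:, rev_pos] = 2.0 - vals[:, rev_pos]
        n_present = np.sum(~np.isnan(vals), axis=1)
        raw_sum = np.nansum(vals, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prorated = raw_sum * sdef.n_items / n_present
        score = np.floor(prorated + 0.5)
        score[n_present < min_fraction * sdef.n_items] = np.nan
        out[name] = score
    return out


def classify_scores(scores: pd.DataFrame, cutoffs: "CutoffTable") -> pd.DataFrame:
    """Band each scale score as normal / borderline / abnormal.

    For difficulties scales: score >= abnormal cutoff -> ``abnormal``;
    borderline cutoff <= score < abnormal cutoff -> ``borderline``; else
    ``normal``. For the prosocial (strength) scale the comparisons reverse:
    score <= abnormal cutoff -> ``abnormal``; abnormal < score <= borderline
    -> ``borderline``. When the borderline cutoff is unavailable (skipped by
    a coarse, skewed score distribution) only abnormal/normal are assigned.

    Returns a long table (subject_id, scale, score, band).
    """
    from sdqnorm.instrument import SDQ_INSTRUMENT as inst

    rows = []
    scales = [s for s in ALL_SCALES if s in scores.columns]
    for _, rec in scores.iterrows():
        for scale in scales:
            score = rec[scale]
            if pd.isna(score):
                rows.append((rec["subject_id"], scale, np.nan, "unscored"))
                continue
            bord, abn = cutoffs.lookup(scale, age=rec.get("age"), gender=rec.get("gender"))
            if inst[scale].direction == "problem":
                if score >= abn:
                    band = "abnormal"
                elif bord is not None and score >= bord:
                    band = "borderline"
                else:
                    band = "normal"
            else:
                if score <= abn:
                    band = "abnormal"
                elif bord is not None and score <= bord:
                    band = "borderline"
                else:
                    band = "normal"
            rows.append((rec["subject_id"], scale, score, band))
    return pd.DataFrame(rows, columns=["subject_id", "scale", "score", "band"])


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(x)
    x, w = x[ok], w[ok]
    if len(x) == 0:
        return np.nan, np.nan
    m = np.average(x, weights=w)
    sw = w.sum()
    denom = sw - 1.0 if sw > 1.0 else sw
    sd = np.sqrt(np.sum(w * (x - m) ** 2) / denom)
    return float(m), float(sd)


def describe(
    scores: pd.DataFrame,
    weights: np.ndarray | pd.Series | None = None,
    cutoffs: "CutoffTable | None" = None,
) -> pd.DataFrame:
    """Per scale and group (female, male, total): (weighted) mean, sd and,
    when cutoffs are given, the percent classified abnormal."""
    w = np.ones(len(scores)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(scores):
        raise ValueError("weights not aligned with scores")
    banded = classify_scores(scores, cutoffs) if cutoffs is not None else None
    rows = []
    scales = [s for s in ALL_SCALES if s in scores.columns]
    for group in ("female", "male", "total"):
        mask = (
            np.ones(len(scores), dtype=bool)
            if group == "total"
            else (scores["gender"] == group).to_numpy()
        )
        for scale in scales:
            x = scores.loc[mask, scale].to_numpy(dtype=float)
            m, sd = _weighted_mean_sd(x, w[mask])
            row = {"group": group, "scale": scale, "n": int(np.sum(~np.isnan(x))),
                   "mean": m, "sd": sd}
            if banded is not None:
                sub = banded[
                    banded["subject_id"].isin(scores.loc[mask, "subject_id"])
                    & (banded["scale"] == scale)
                    & (banded["band"] != "unscored")
                ]
                row["pct_abnormal"] = (
                    100.0 * (sub["band"] == "abnormal").mean() if len(sub) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
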