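"""Norm tables and screening cutoffs.

A norm table holds, per (scale, group, age) and for each attainable score
s, the entry E(s): the percent of the reference distribution ranking
*strictly below* s for difficulties scales, and *strictly above* s for the
prosocial (strength) scale. Under this convention the "up to" cutoff rule —
abnormal cutoff = smallest score whose entry reaches the 90th percentile
level — guarantees that the flagged share 100 - E(cutoff) never exceeds the
nominal 10% on a discrete score scale, and the borderline rule (80th level)
likewise caps normal+borderline flagging at 20%. An alternative
"at-or-below" entry convention is available behind a flag for comparison
with published tables whose column alignment is ambiguous.

The borderline cutoff is reported as unavailable when a coarse, strongly
right-skewed score distribution jumps straight past the 80-90 band, making
the borderline and abnormal cutoffs coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sdqnorm.instrument import SDQ_INSTRUMENT
from sdqnorm.scoring import describe, classify_scores

#: sentinel written for an unavailable borderline cutoff
UNAVAILABLE = "-"


def _direction(scale: str) -> str:
    return SDQ_INSTRUMENT[scale].direction


@dataclass(frozen=True)
class CutoffPolicy:
    """Cutoff extraction rule.

    Levels are on the entry scale (80/90 correspond to the 80th/90th
    percentile for difficulties and, symmetrically, to the 20th/10th for
    the prosocial scale). ``mode`` "up_to" guarantees flagged shares at or
    below the nominal 10/20%; "approximately" picks the score whose flagged
    share is closest to nominal (ties to the smaller share).
    """

    abnormal_level: float = 90.0
    borderline_level: float = 80.0
    mode: str = "up_to"

    def __post_init__(self):
        if not 50.0 < self.borderline_level < self.abnormal_level:
            raise ValueError("need 50 < borderline_level < abnormal_level")
        if self.mode not in ("up_to", "approximately"):
            raise ValueError(f"unknown mode {self.mode!r}")


class NormTable:
    """Long-form percentile table: (scale, version, group, age, score, entry)."""

    def __init__(self, data: pd.DataFrame, convention: str = "below"):
        required = {"scale", "group", "age", "score", "entry"}
        if not required <= set(data.columns):
            raise ValueError(f"norm table needs columns {sorted(required)}")
        if convention not in ("below", "at_or_below"):
            raise ValueError(f"unknown convention {convention!r}")
        self.data = data.reset_index(drop=True)
        self.convention = convention

    def strata(self) -> list[tuple[str, str, int]]:
        cols = self.data[["scale", "group", "age"]].drop_duplicates()
        return [tuple(r) for r in cols.itertuples(index=False)]

    def row(self, scale: str, group: str, age: int) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[
            (self.data["scale"] == scale)
            & (self.data["group"] == group)
            & (self.data["age"] == age)
        ].sort_values("score")
        if sub.empty:
            raise KeyError(f"no norm row for ({scale}, {group}, {age})")
        return sub["score"].to_numpy(dtype=int), sub["entry"].to_numpy(dtype=float)

    def validate_monotone(self) -> None:
        for scale, group, age in self.strata():
            _, entries = self.row(scale, group, age)
            diffs = np.diff(entries)
            if _direction(scale) == "problem":
                if np.any(diffs < -1e-9):
                    raise ValueError(f"non-monotone entries for ({scale}, {group}, {age})")
            elif np.any(diffs > 1e-9):
                raise ValueError(f"non-monotone entries for ({scale}, {group}, {age})")

    def rounded(self, decimals: int = 1) -> "NormTable":
        out = self.data.copy()
        out["entry"] = out["entry"].round(decimals)
        return NormTable(out, self.convention)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.1f")

    def to_wide(self) -> pd.DataFrame:
        """Pivot to one row per (scale, group, age), score columns."""
        return self.data.pivot_table(
            index=["scale", "group", "age"], columns="score", values="entry"
        ).reset_index()

    @classmethod
    def from_csv(cls, path, convention: str = "below") -> "NormTable":
        return cls(pd.read_csv(path), convention)


def build_norm_table(
    model,
    scale: str,
    ages=range(12, 18),
    groups=("joint",),
    version: str | None = None,
    convention: str = "below",
) -> NormTable:
    """Evaluate a fitted model into a norm table.

    For each (age, group) the fitted score distribution is evaluated over
    the attainable scores; difficulties entries are 100*P(score < s)
    ("below"; E(0) = 0 by the empty lower tail) or 100*P(score <= s)
    ("at_or_below"); prosocial entries mirror (percent above / at-or-above).
    """
    direction = _direction(scale)
    rows = []
    for group in groups:
        for age in ages:
            if group in ("joint", "total") and model.spec.gender != "none":
                raise ValueError("joint norms require an age-only (genderless) model")
            cdf = model.score_cdf(age, gender=group)
            smax = model.score_max
            scores = np.arange(smax + 1)
            if direction == "problem":
                below = np.concatenate([[0.0], cdf[:-1]])
                entry = 100.0 * (below if convention == "below" else cdf)
            else:
                above = 1.0 - cdf
                above_or_at = np.concatenate([[1.0], above[:-1]])
                entry = 100.0 * (above if convention == "below" else above_or_at)
            for s, e in zip(scores, entry):
                rows.append({"scale": scale, "version": version, "group": group,
                             "age": int(age), "score": int(s), "entry": float(e)})
    return NormTable(pd.DataFrame(rows), convention)


class CutoffTable:
    """Borderline/abnormal cutoff scores per (scale, group, age).

    ``borderline`` may be NaN, the unavailable sentinel. Difficulties
    cutoffs flag scores >= cutoff; prosocial cutoffs flag scores <= cutoff.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"scale", "group", "age", "borderline", "abnormal"}
        if not required <= set(data.columns):
            raise ValueError(f"cutoff table needs columns {sorted(required)}")
        self.data = data.reset_index(drop=True)

    def lookup(self, scale: str, age=None, gender=None) -> tuple[float | None, float]:
        """Cutoff pair for a stratum; prefers the gender-matching group and
        falls back to joint norms. Raises KeyError when no row covers the
        stratum (a configuration error)."""
        sub = self.data[self.data["scale"] == scale]
        if age is not None and "age" in sub.columns and sub["age"].notna().any():
            with_age = sub[sub["age"] == int(age)]
            sub = with_age if not with_age.empty else sub[sub["age"].isna()]
        for group in ([gender] if gender is not None else []) + ["joint", "total", "any"]:
            hit = sub[sub["group"] == group]
            if not hit.empty:
                row = hit.iloc[0]
                bord = None if pd.isna(row["borderline"]) else float(row["borderline"])
                return bord, float(row["abnormal"])
        raise KeyError(f"no cutoff for scale={scale}, age={age}, gender={gender}")

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["borderline"] = out["borderline"].map(
            lambda v: UNAVAILABLE if pd.isna(v) else f"{v:g}")
        out.to_csv(path, index=False)

    @classmethod
    def from_config(cls, path) -> "CutoffTable":
        """Load an external (published) cutoff fixture from YAML/JSON:
        a list of records with scale, group, age (optional), borderline
        (optional or "-"), abnormal."""
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        rows = []
        for rec in doc:
            bord = rec.get("borderline")
            rows.append({
                "scale": rec["scale"],
                "group": rec.get("group", "joint"),
                "age": rec.get("age", np.nan),
                "borderline": np.nan if bord in (None, UNAVAILABLE) else float(bord),
                "abnormal": float(rec["abnormal"]),
            })
        return cls(pd.DataFrame(rows))


def _flagged_share(entries: np.ndarray, idx: int) -> float:
    # entries follow the mirrored convention, so the share of flagged
    # (extreme) scores is 100 - entry for both directions
    return 100.0 - entries[idx]


def extract_cutoffs(table: NormTable, policy: CutoffPolicy = CutoffPolicy()) -> CutoffTable:
    """Extract borderline/abnormal cutoffs from every row of a norm table."""
    table.validate_monotone()
    rows = []
    for scale, group, age in table.strata():
        scores, entries = table.row(scale, group, age)
        problem = _direction(scale) == "problem"

        def pick(level: float):
            meets = np.flatnonzero(entries >= level)
            if len(meets) == 0:
                return None
            return int(scores[meets[0]] if problem else scores[meets[-1]])

        if policy.mode == "up_to":
            abn = pick(policy.abnormal_level)
            bord = pick(policy.borderline_level)
        else:
            def closest(level: float):
                nominal = 100.0 - level
                shares = 100.0 - entries
                dist = np.abs(shares - nominal)
                # ties resolved toward the smaller flagged share
                order = np.lexsort((shares, dist))
                return int(scores[order[0]])
            abn = closest(policy.abnormal_level)
            bord = closest(policy.borderline_level)
        if bord is not None and abn is not None and bord == abn:
            bord = None  # skipped band: distribution jumps past the 80-90 range
        rows.append({"scale": scale, "group": group, "age": age,
                     "borderline": np.nan if bord is None else bord,
                     "abnormal": np.nan if abn is None else abn})
    return CutoffTable(pd.DataFrame(rows))


def detection_rate(table: NormTable, cutoffs: CutoffTable) -> pd.DataFrame:
    """Model-implied percent flagged abnormal when the given cutoffs are
    applied to each norm-table stratum (supports applying joint cutoffs to
    gender-specific tables): rate = 100 - E(abnormal cutoff)."""
    rows = []
    for scale, group, age in table.strata():
        scores, entries = table.row(scale, group, age)
        _, abn = cutoffs.lookup(scale, age=age, gender=group)
        if pd.isna(abn):
            # no attainable score keeps the flagged share within the nominal
            # level (top-score mass alone exceeds it): nobody is flagged
            rate = np.nan
        else:
            idx = int(np.flatnonzero(scores == int(abn))[0])
            rate = _flagged_share(entries, idx)
        rows.append({"scale": scale, "group": group, "age": age, "rate": rate})
    return pd.DataFrame(rows)


def apply_external_cutoffs(scores: pd.DataFrame, fixture: CutoffTable) -> pd.DataFrame:
    """Band a scored cohort with externally published cutoffs and summarize
    the percent abnormal per group (the comparison made against earlier
    UK/Dutch norms)."""
    return describe(scores, weights=None, cutoffs=fixture)


__all__ = [
    "NormTable", "CutoffTable", "CutoffPolicy", "UNAVAILABLE",
    "build_norm_table", "extract_cutoffs", "detection_rate",
    "apply_external_cutoffs", "classify_scores",
]
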