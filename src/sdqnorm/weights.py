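"""Post-stratification survey weights.

The norm groups overrepresent females and majority-background adolescents
relative to the national population, so norms are computed with
post-stratification weights: a record in sample cell *c* gets weight
(population share of *c*) / (sample share of *c*), rescaled to mean one so
that the effective sample size bookkeeping (e.g. the N in BIC) stays at the
raw subject count. Joint norms weight on gender x ethnic background;
gender-specific norms weight on ethnic background only.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

Margins = Mapping[str, Mapping[str, float]]


class WeightingError(ValueError):
    """Raised for empty or impossible post-stratification cells."""


def load_margins(path: str | Path) -> dict[str, dict[str, float]]:
    """Load population margins from a YAML/JSON document keyed
    variable -> category -> proportion."""
    doc = yaml.safe_load(Path(path).read_text())
    margins = {v: {str(k): float(p) for k, p in cats.items()} for v, cats in doc.items()}
    validate_margins(margins)
    return margins


def validate_margins(margins: Margins, tol: float = 1e-9) -> None:
    for var, cats in margins.items():
        total = sum(cats.values())
        if abs(total - 1.0) > tol:
            raise WeightingError(f"margins for {var!r} sum to {total}, not 1")
        if any(p < 0 for p in cats.values()):
            raise WeightingError(f"negative proportion in margins for {var!r}")


def compute_cell_weights(
    cohort: pd.DataFrame,
    margins: Margins,
    strata: Sequence[str],
) -> np.ndarray:
    """Cell post-stratification weights over the cross of ``strata``.

    Population cell proportions for multi-variable strata are formed as
    products of the per-variable margins (independence). Every record must
    have a non-missing value on each stratification variable. Returns a
    weight per record, all positive, rescaled to mean one.

    Raises
    ------
    WeightingError
        If a population cell with positive mass has no sample records, or
        sample records fall in a zero-mass population cell.
    """
    validate_margins(margins)
    for var in strata:
        if cohort[var].isna().any():
            raise WeightingError(f"missing values on stratification variable {var!r}")
        observed = set(cohort[var].unique())
        known = set(margins[var])
        if not observed <= known:
            raise WeightingError(
                f"categories {observed - known} of {var!r} absent from margins"
            )
    n = len(cohort)
    cells = list(itertools.product(*(sorted(margins[v]) for v in strata)))
    raw = np.empty(n, dtype=float)
    labels = cohort[list(strata)].astype(str)
    for cell in cells:
        pop = float(np.prod([margins[v][c] for v, c in zip(strata, cell)]))
        mask = np.ones(n, dtype=bool)
        for v, c in zip(strata, cell):
            mask &= (labels[v] == c).to_numpy()
        n_cell = int(mask.sum())
        if n_cell == 0:
            if pop > 0:
                raise WeightingError(f"population cell {dict(zip(strata, cell))} "
                                     f"(share {pop:.4f}) has no sample records")
            continue
        if pop == 0.0:
            raise WeightingError(f"{n_cell} sample records in zero-population cell "
                                 f"{dict(zip(strata, cell))}")
        raw[mask] = pop / (n_cell / n)
    weights = raw / raw.mean()
    logger.info("cell weights on %s: range [%.3f, %.3f]", list(strata),
                weights.min(), weights.max())
    return weights


def rake_weights(
    cohort: pd.DataFrame,
    margins: Margins,
    strata: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Raking (iterative proportional fitting) fallback for configurations
    where a full cross-classification is unavailable or has empty cells:
    weights are adjusted variable by variable until every one-way weighted
    margin matches the population margin."""
    validate_margins(margins)
    n = len(cohort)
    w = np.ones(n)
    labels = cohort[list(strata)].astype(str)
    for _ in range(max_iter):
        delta = 0.0
        for var in strata:
            for cat, pop in margins[var].items():
                mask = (labels[var] == cat).to_numpy()
                cur = w[mask].sum() / w.sum()
                if cur > 0 and pop > 0:
                    factor = pop / cur
                    w[mask] *= factor
                    delta = max(delta, abs(factor - 1.0))
                elif cur == 0 and pop > 0:
                    raise WeightingError(f"no sample records for {var}={cat}")
        if delta < tol:
            break
    return w / w.mean()


def weighted_margins(
    cohort: pd.DataFrame, weights: np.ndarray, variables: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Weighted category shares, for checking calibration."""
    out: dict[str, dict[str, float]] = {}
    total = weights.sum()
    for var in variables:
        labels = cohort[var].astype(str)
        out[var] = {
            cat: float(weights[(labels == cat).to_numpy()].sum() / total)
            for cat in sorted(labels.unique())
        }
    return out
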