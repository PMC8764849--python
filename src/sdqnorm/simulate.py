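"""Seeded synthetic SDQ cohorts.

The study data are not publicly available, so every stage of the norming
workflow is exercised on synthetic cohorts that emulate the structure the
analysis assumes: 25 ordinal items loading on five correlated latent scale
traits, age trends and gender effects on the trait means (females higher on
self-reported internalizing traits, males higher on externalizing traits,
parent-reported hyperactivity higher for males), overrepresentation of
females (53.1%) and majority-background respondents (89.1%) as in the norm
groups, and ~0.2% missing item responses.

Items are generated by a graded-threshold model: the item latent is
``lambda * trait + sqrt(1 - lambda^2) * noise`` and is cut at two increasing
thresholds into {0, 1, 2}. Reversed items are stored raw (2 - coded value)
so that the scoring module's reverse coding is genuinely exercised.

A separate direct beta-binomial sampler (:func:`sample_bb_scores`) provides
scale scores with known distribution parameters for parameter-recovery
tests of the fitting code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sdqnorm.distributions import BetaBinomial
from sdqnorm.instrument import BASE_SCALES, SDQ_INSTRUMENT, Instrument
from sdqnorm.scoring import DEMOGRAPHIC_COLUMNS, ITEM_COLUMNS

AGE_RANGE = tuple(range(12, 18))
_AGE_CENTER = 14.5

#: Age distribution of the self-report norm group (counts 82, 253, 249,
#: 151, 151, 107 of 993).
DEFAULT_AGE_DISTRIBUTION = {
    12: 82 / 993, 13: 253 / 993, 14: 249 / 993,
    15: 151 / 993, 16: 151 / 993, 17: 107 / 993,
}


@dataclass(frozen=True)
class TraitEffect:
    """Linear model for one latent scale trait (standard-normal residual).

    ``age_slope`` is per year of age centered at 14.5; ``gender_effect`` is
    the female-minus-male shift in trait standard deviations.
    """

    intercept: float = 0.0
    age_slope: float = 0.0
    gender_effect: float = 0.0


@dataclass(frozen=True)
class ItemModel:
    """Loading and category thresholds of one item on its scale trait."""

    loading: float = 0.6
    thresholds: tuple[float, float] = (0.8, 1.8)

    def __post_init__(self):
        if not -1.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [-1, 1]")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly increasing")


def _default_trait_model(version: str) -> dict[str, TraitEffect]:
    # Directions mirror the study's findings: self-reported internalizing
    # higher for females, externalizing higher for males; parent-reported
    # hyperactivity markedly higher for males. Magnitudes are modest trait-SD
    # shifts; age slopes are small, as the study found only minor age effects.
    if version == "self":
        return {
            "emotional": TraitEffect(0.0, 0.03, 0.55),
            "conduct": TraitEffect(0.0, 0.02, -0.30),
            "hyperactivity": TraitEffect(0.0, -0.02, -0.15),
            "social": TraitEffect(0.0, -0.02, 0.10),
            "prosocial": TraitEffect(0.0, 0.01, 0.40),
        }
    return {
        "emotional": TraitEffect(0.0, 0.03, 0.15),
        "conduct": TraitEffect(0.0, -0.02, -0.20),
        "hyperactivity": TraitEffect(0.0, -0.04, -0.50),
        "social": TraitEffect(0.0, -0.01, -0.15),
        "prosocial": TraitEffect(0.0, 0.02, 0.25),
    }


#: Per-scale default item thresholds, picked to give the right-skewed
#: difficulties distributions and high prosocial scores seen in community
#: samples (scale means roughly 1-4 of 10 for difficulties, ~8 for prosocial).
_DEFAULT_THRESHOLDS = {
    "emotional": (0.7, 1.7),
    "conduct": (1.0, 2.1),
    "hyperactivity": (0.35, 1.4),
    "social": (0.9, 2.0),
    "prosocial": (-1.7, -0.7),
}


def _default_item_model(instrument: Instrument) -> dict[int, ItemModel]:
    model: dict[int, ItemModel] = {}
    for scale in BASE_SCALES:
        for item in instrument[scale].member_items:
            model[item] = ItemModel(loading=0.6, thresholds=_DEFAULT_THRESHOLDS[scale])
    return model


def _default_trait_correlation() -> np.ndarray:
    # order: emotional, conduct, hyperactivity, social, prosocial
    r = np.full((5, 5), 0.40)
    r[:, 4] = r[4, :] = -0.25
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimulationConfig:
    """Generating model of one synthetic cohort.

    Defaults mirror the norm-group composition of the study population:
    n = 993 (self-report) or 736 (parent-report), 53.1% female, 89.1%
    majority ethnic background, education shares 24.0/41.4/34.6, the
    norm-group age distribution, and 0.2% missing items.
    """

    n_subjects: int = 993
    seed: int = 0
    version: str = "self"  # "self" | "parent"
    age_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION))
    gender_proportion_female: float = 0.531
    ethnicity_proportion_majority: float = 0.891
    education_proportions: dict[str, float] = field(
        default_factory=lambda: {"low": 0.240, "medium": 0.414, "high": 0.346})
    trait_model: dict[str, TraitEffect] | None = None
    trait_correlation: np.ndarray | None = None
    item_model: dict[int, ItemModel] | None = None
    missing_item_rate: float = 0.002
    missing_demographic_rate: float = 0.0

    def __post_init__(self):
        if self.version not in ("self", "parent"):
            raise ValueError("version must be 'self' or 'parent'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        probs = np.array(list(self.age_distribution.values()))
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("age_distribution must be a probability vector")
        for p in (self.gender_proportion_female, self.ethnicity_proportion_majority,
                  self.missing_item_rate, self.missing_demographic_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.trait_model is None:
            self.trait_model = _default_trait_model(self.version)
        if self.trait_correlation is None:
            self.trait_correlation = _default_trait_correlation()
        if self.item_model is None:
            self.item_model = _default_item_model(SDQ_INSTRUMENT)
        np.linalg.cholesky(self.trait_correlation)  # must be positive definite

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_correlation"] = np.asarray(self.trait_correlation).tolist()
        return d


@dataclass
class TrueParameterRecord:
    """The generating values behind a cohort, kept for oracle comparisons."""

    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.config.to_dict(), indent=2, default=str))

    def scale_score_pmf(
        self, scale: str, age: int, gender: str, n_mc: int = 200_000, seed: int = 12345,
    ) -> np.ndarray:
        """Generating distribution of a complete-scale score in one stratum,
        by large-sample simulation from the true parameters (no missingness)."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        inst = SDQ_INSTRUMENT
        traits = _draw_traits(cfg, rng, np.full(n_mc, age),
                              np.full(n_mc, gender == "female"))
        base = inst[scale]
        total = np.zeros(n_mc)
        for name in BASE_SCALES:
            members = set(inst[name].member_items) & set(base.member_items)
            if not members:
                continue
            for item in sorted(members):
                coded = _draw_item(cfg.item_model[item], traits[:, BASE_SCALES.index(name)], rng)
                total += coded
        pmf = np.bincount(total.astype(int), minlength=base.score_max + 1)
        return pmf / pmf.sum()


def _draw_traits(cfg: SimulationConfig, rng: np.random.Generator,
                 ages: np.ndarray, is_female: np.ndarray) -> np.ndarray:
    n = len(ages)
    chol = np.linalg.cholesky(np.asarray(cfg.trait_correlation, dtype=float))
    resid = rng.standard_normal((n, 5)) @ chol.T
    traits = np.empty((n, 5))
    for j, scale in enumerate(BASE_SCALES):
        eff = cfg.trait_model[scale]
        traits[:, j] = (eff.intercept + eff.age_slope * (ages - _AGE_CENTER)
                        + eff.gender_effect * is_female + resid[:, j])
    return traits


def _draw_item(model: ItemModel, trait: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lam = model.loading
    latent = lam * trait + np.sqrt(max(1.0 - lam * lam, 0.0)) * rng.standard_normal(len(trait))
    t1, t2 = model.thresholds
    return (latent > t1).astype(int) + (latent > t2).astype(int)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueParameterRecord]:
    """Draw one cohort; byte-identical for identical (config, seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    inst = SDQ_INSTRUMENT

    ages = rng.choice(list(cfg.age_distribution), size=n,
                      p=list(cfg.age_distribution.values()))
    is_female = rng.uniform(size=n) < cfg.gender_proportion_female
    ethnic = np.where(rng.uniform(size=n) < cfg.ethnicity_proportion_majority,
                      "majority", "other")
    edu = rng.choice(list(cfg.education_proportions), size=n,
                     p=list(cfg.education_proportions.values()))

    traits = _draw_traits(cfg, rng, ages.astype(float), is_female.astype(float))

    items = np.empty((n, len(ITEM_COLUMNS)), dtype=float)
    reversed_items = {
        i for s in inst.scales.values() if s.direction == "problem"
        for i in s.reversed_items
    }
    for j, scale in enumerate(BASE_SCALES):
        for item in inst[scale].member_items:
            coded = _draw_item(cfg.item_model[item], traits[:, j], rng)
            raw = 2 - coded if item in reversed_items else coded
            items[:, item - 1] = raw

    # item missingness, completely at random
    if cfg.missing_item_rate > 0:
        items[rng.uniform(size=items.shape) < cfg.missing_item_rate] = np.nan

    df = pd.DataFrame(items, columns=list(ITEM_COLUMNS))
    df.insert(0, "subject_id", [f"s{k:05d}" for k in range(n)])
    df.insert(1, "version", cfg.version)
    df["age"] = ages.astype(float)
    df["gender"] = np.where(is_female, "female", "male")
    df["ethnic_background"] = ethnic
    df["maternal_education"] = edu

    # demographic missingness: a record loses one randomly chosen field
    if cfg.missing_demographic_rate > 0:
        hit = rng.uniform(size=n) < cfg.missing_demographic_rate
        which = rng.integers(0, len(DEMOGRAPHIC_COLUMNS), size=n)
        for k, col in enumerate(DEMOGRAPHIC_COLUMNS):
            df.loc[hit & (which == k), col] = np.nan

    return df, TrueParameterRecord(config=cfg)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the delimited format load_cohort reads."""
    out = df.copy()
    for col in ITEM_COLUMNS:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def sample_bb_scores(
    n_per_stratum: int,
    params_by_stratum: dict[tuple[int, str], BetaBinomial],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw scale scores directly from beta-binomial strata.

    ``params_by_stratum`` maps (age, gender) to a BetaBinomial; the result
    has columns subject_id, age, gender, score. This is the recovery harness
    for the fitting code: the generating (mu, sigma) are known exactly.
    """
    rng = np.random.default_rng(seed)
    frames = []
    k = 0
    for (age, gender), dist in params_by_stratum.items():
        scores = dist.rvs(n_per_stratum, seed=rng.integers(0, 2**31))
        frames.append(pd.DataFrame({
            "subject_id": [f"b{k + i:07d}" for i in range(n_per_stratum)],
            "age": float(age),
            "gender": gender,
            "score": scores.astype(float),
        }))
        k += n_per_stratum
    return pd.concat(frames, ignore_index=True)
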