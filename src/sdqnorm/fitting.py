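"""Distributional regression of scale scores on age (and gender).

Each parameter of the response family (beta-binomial mu, sigma; BCPE mu,
sigma, nu, tau) is modelled on its link scale (logit for BB mu; log for
BCPE mu, both sigmas and tau; identity for nu) as a polynomial in age, with
an optional gender main effect and age x gender interaction. Coefficients
are estimated by weighted maximum likelihood; model complexity (polynomial
degree per parameter, gender terms) is chosen by BIC; fit adequacy is
inspected with worm plots of (randomized) quantile residuals.

Ages are standardized to [-1, 1] and expanded in Legendre polynomials: the
raw age^6 basis is numerically hostile, and the orthogonal basis keeps the
optimizer well-conditioned. The basis definition is stored with the fitted
model so predictions are basis-independent.

The total difficulties scale (0-40, discrete) is fitted with the continuous
BCPE family on scores shifted by +1 (BCPE needs y > 0 and 0 is attainable);
all percentile output is produced from a half-integer discretization of the
fitted density back onto the score grid, so downstream norm tables see one
uniform discrete interface for both families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import optimize, special, stats

from sdqnorm.distributions import bb_logpmf, bcpe_logpdf

logger = logging.getLogger(__name__)

AGE_LO, AGE_HI = 12.0, 17.0

_FAMILY_PARAMS = {"BB": ("mu", "sigma"), "BCPE": ("mu", "sigma", "nu", "tau")}
# link functions, applied to the natural parameter to get the linear predictor
_LINKS = {
    ("BB", "mu"): "logit", ("BB", "sigma"): "log",
    ("BCPE", "mu"): "log", ("BCPE", "sigma"): "log",
    ("BCPE", "nu"): "identity", ("BCPE", "tau"): "log",
}


def _link_inv(name: str, eta: np.ndarray) -> np.ndarray:
    if name == "logit":
        return special.expit(eta)
    if name == "log":
        return np.exp(np.clip(eta, -30.0, 30.0))
    return eta


def _link(name: str, x: float) -> float:
    if name == "logit":
        return float(special.logit(np.clip(x, 1e-6, 1 - 1e-6)))
    if name == "log":
        return float(np.log(max(x, 1e-10)))
    return float(x)


class FitError(RuntimeError):
    """Raised when the likelihood optimizer fails after the restart schedule."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: family, per-parameter age degree, gender terms."""

    family: str  # "BB" | "BCPE"
    degrees: dict[str, int]
    gender: str = "none"  # "none" | "main" | "main+interaction"
    n_trials: int | None = None  # BB scale maximum
    score_max: int | None = None  # BCPE score maximum (before shift)
    shift: float = 1.0  # BCPE support shift

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")
        for p in _FAMILY_PARAMS[self.family]:
            if not 0 <= self.degrees.get(p, 0) <= 6:
                raise ValueError(f"degree for {p} must be in 0..6")
        if self.gender not in ("none", "main", "main+interaction"):
            raise ValueError(f"unknown gender term {self.gender!r}")
        if self.family == "BB" and self.n_trials is None:
            raise ValueError("BB spec needs n_trials")
        if self.family == "BCPE" and self.score_max is None:
            raise ValueError("BCPE spec needs score_max")

    @property
    def params(self) -> tuple[str, ...]:
        return _FAMILY_PARAMS[self.family]

    def n_coef(self, param: str) -> int:
        d = self.degrees.get(param, 0)
        k = d + 1
        if self.gender in ("main", "main+interaction"):
            k += 1
        if self.gender == "main+interaction":
            k += d
        return k

    @property
    def k_total(self) -> int:
        return sum(self.n_coef(p) for p in self.params)


def standardize_age(age: np.ndarray) -> np.ndarray:
    return (np.asarray(age, dtype=float) - (AGE_LO + AGE_HI) / 2.0) / ((AGE_HI - AGE_LO) / 2.0)


def _design(spec: ModelSpec, param: str, age: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Design matrix: Legendre columns P0..Pd, [female], [female * P1..Pd]."""
    x = standardize_age(age)
    d = spec.degrees.get(param, 0)
    cols = [legendre.legval(x, np.eye(d + 1)[j]) for j in range(d + 1)]
    if spec.gender in ("main", "main+interaction"):
        cols.append(female.astype(float))
    if spec.gender == "main+interaction":
        for j in range(1, d + 1):
            cols.append(female.astype(float) * legendre.legval(x, np.eye(d + 1)[j]))
    return np.column_stack(cols)


@dataclass
class FittedNormModel:
    """A fitted distributional regression model for one scale.

    Coefficients are stored per distribution parameter on the link scale
    over the stored Legendre basis; ``bic = -2 logL + k log(N)`` with N the
    raw subject count (weights are mean-1 normalized).
    """

    spec: ModelSpec
    coefficients: dict[str, np.ndarray]
    log_likelihood: float
    n_obs: int
    converged: bool
    n_restarts: int = 0
    search_trace: list[tuple[dict, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.spec.k_total

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.k * np.log(self.n_obs)

    # -- prediction ---------------------------------------------------------
    def predict_params(self, age, gender) -> dict[str, np.ndarray]:
        """Distribution parameters at given ages/genders; ``gender`` may be
        category strings or a 0/1 female indicator."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        g = np.atleast_1d(np.asarray(gender))
        if g.dtype.kind in "USO":
            female = (g == "female").astype(float)
        else:
            female = g.astype(float)
        if len(female) == 1 and len(age) > 1:
            female = np.repeat(female, len(age))
        out = {}
        for p in self.spec.params:
            X = _design(self.spec, p, age, female)
            out[p] = _link_inv(_LINKS[(self.spec.family, p)], X @ self.coefficients[p])
        return out

    @property
    def score_max(self) -> int:
        return self.spec.n_trials if self.spec.family == "BB" else self.spec.score_max

    def score_pmf(self, age: float, gender: str = "none") -> np.ndarray:
        """Model-implied pmf over attainable scores 0..score_max at one
        (age, gender). For BCPE the fitted density (on shifted support) is
        discretized at half-integers, with the tails folded into the
        endpoint scores."""
        th = {k: float(v[0]) for k, v in self.predict_params([age], [gender == "female"]).items()}
        if self.spec.family == "BB":
            from sdqnorm.distributions import BetaBinomial
            return BetaBinomial(self.spec.n_trials, th["mu"], th["sigma"]).pmf_vector()
        from sdqnorm.distributions import BoxCoxPowerExponential
        dist = BoxCoxPowerExponential(th["mu"], th["sigma"], th["nu"], th["tau"])
        smax = self.spec.score_max
        edges = np.arange(smax + 1) + self.spec.shift + 0.5  # upper cell edges
        cdf_hi = dist.cdf(edges)
        cdf_lo = np.concatenate([[0.0], cdf_hi[:-1]])
        pmf = cdf_hi - cdf_lo
        pmf[-1] += max(1.0 - cdf_hi[-1], 0.0)
        return np.clip(pmf, 0.0, None) / np.clip(pmf.sum(), 1e-300, None)

    def score_cdf(self, age: float, gender: str = "none") -> np.ndarray:
        cum = np.cumsum(self.score_pmf(age, gender))
        cum[-1] = 1.0
        return cum

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "degrees": dict(self.spec.degrees),
            "gender": self.spec.gender,
            "n_trials": self.spec.n_trials,
            "score_max": self.spec.score_max,
            "shift": self.spec.shift,
            "basis": {"type": "legendre", "age_lo": AGE_LO, "age_hi": AGE_HI},
            "coefficients": {k: list(map(float, v)) for k, v in self.coefficients.items()},
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, spec: ModelSpec) -> dict[str, np.ndarray]:
    out, i = {}, 0
    for p in spec.params:
        k = spec.n_coef(p)
        out[p] = theta[i:i + k]
        i += k
    return out


def _neg_loglik(theta, spec, y, designs, w):
    coefs = _unpack(np.asarray(theta, dtype=float), spec)
    nat = {}
    for p in spec.params:
        nat[p] = _link_inv(_LINKS[(spec.family, p)], designs[p] @ coefs[p])
    if spec.family == "BB":
        mu = np.clip(nat["mu"], 1e-9, 1 - 1e-9)
        sig = np.clip(nat["sigma"], 1e-9, None)
        ll = bb_logpmf(y, spec.n_trials, mu, sig)
    else:
        ll = bcpe_logpdf(y + spec.shift, np.clip(nat["mu"], 1e-9, None),
                         np.clip(nat["sigma"], 1e-9, None),
                         np.clip(nat["nu"], -10.0, 10.0),
                         np.clip(nat["tau"], 0.05, 100.0))
    ll = np.where(np.isfinite(ll), ll, -1e10)
    return -float(np.sum(w * ll))


def _start_values(spec: ModelSpec, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Moment-based intercepts, zeros elsewhere."""
    theta = []
    if spec.family == "BB":
        n = spec.n_trials
        mu0 = float(np.clip(np.average(y, weights=w) / n, 0.02, 0.98))
        v = float(np.average((y - mu0 * n) ** 2, weights=w))
        ratio = v / max(n * mu0 * (1 - mu0), 1e-9)
        sig0 = float(np.clip((ratio - 1.0) / max(n - ratio, 1e-6), 5e-3, 5.0))
        inits = {"mu": _link("logit", mu0), "sigma": _link("log", sig0)}
    else:
        ys = y + spec.shift
        med = float(np.median(ys))
        cv = float(np.std(ys) / max(med, 1e-9))
        inits = {"mu": _link("log", med), "sigma": _link("log", max(cv, 1e-3)),
                 "nu": 1.0, "tau": _link("log", 2.0)}
    for p in spec.params:
        block = np.zeros(spec.n_coef(p))
        block[0] = inits[p]
        theta.extend(block)
    return np.asarray(theta)


def fit_norm_model(
    scores: pd.DataFrame,
    weights: np.ndarray | None,
    spec: ModelSpec,
    score_col: str = "score",
    max_restarts: int = 3,
) -> FittedNormModel:
    """Weighted maximum-likelihood fit of one ModelSpec.

    ``scores`` needs columns ``score_col``, ``age`` and (when the spec has
    gender terms) ``gender``. Deterministic given data and spec: the restart
    schedule perturbs the start with a fixed-seed generator.
    """
    w_full = np.ones(len(scores)) if weights is None else np.asarray(weights, dtype=float)
    if len(w_full) != len(scores):
        raise ValueError("weights not aligned with scores")
    mask = scores[score_col].notna().to_numpy()
    df = scores.loc[mask]
    w = w_full[mask]
    y = df[score_col].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    female = (
        (df["gender"] == "female").to_numpy(dtype=float)
        if "gender" in df.columns else np.zeros(len(df))
    )
    # canonical row order: the likelihood sum (and hence the optimizer path)
    # must not depend on how the input happens to be sorted
    order = np.lexsort((w, y, female, age))
    y, age, female, w = y[order], age[order], female[order], w[order]
    designs = {p: _design(spec, p, age, female) for p in spec.params}

    theta0 = _start_values(spec, y, w)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, size=len(theta0))
        res = optimize.minimize(
            _neg_loglik, start, args=(spec, y, designs, w),
            method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success and np.isfinite(res.fun):
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"optimizer failed for spec {spec}")
    converged = bool(best.success)
    if not converged:
        logger.warning("fit did not formally converge for %s (best nll %.4f)",
                       spec, best.fun)
    return FittedNormModel(
        spec=spec,
        coefficients=_unpack(best.x, spec),
        log_likelihood=-float(best.fun),
        n_obs=len(df),
        converged=converged,
        n_restarts=attempt,
    )


# ---------------------------------------------------------------------------
# BIC model search
# ---------------------------------------------------------------------------

def select_model(
    scores: pd.DataFrame,
    weights: np.ndarray | None,
    family: str,
    n_trials: int | None = None,
    score_max: int | None = None,
    gender_mode: str = "none",
    max_degree: int = 6,
    score_col: str = "score",
) -> FittedNormModel:
    """BIC search over polynomial degrees (and gender terms).

    BB: exhaustive grid over (mu-degree, sigma-degree). BCPE: staged — grid
    mu/sigma with nu, tau constant at degree 0, then expand nu and tau one
    parameter at a time holding the others at their current best, iterating
    until the BIC-optimal degrees stop changing. When ``gender_mode`` is
    "auto", degrees are selected with a gender main effect and the
    main-vs-interaction choice is then made by BIC at the selected degrees.

    Returns the BIC-minimal fitted model with the full search trace
    attached; raises FitError when every candidate fails.
    """
    gender = {"none": "none", "auto": "main"}.get(gender_mode, gender_mode)
    trace: list[tuple[dict, float]] = []
    best: FittedNormModel | None = None

    def try_spec(degrees: dict[str, int], gen: str) -> FittedNormModel | None:
        nonlocal best
        spec = ModelSpec(family=family, degrees=dict(degrees), gender=gen,
                         n_trials=n_trials, score_max=score_max)
        try:
            m = fit_norm_model(scores, weights, spec, score_col=score_col)
        except FitError:
            trace.append(({"degrees": dict(degrees), "gender": gen}, np.inf))
            return None
        trace.append(({"degrees": dict(degrees), "gender": gen}, float(m.bic)))
        if best is None or m.bic < best.bic - 1e-9:
            best = m
        return m

    if family == "BB":
        for dmu in range(max_degree + 1):
            for dsig in range(max_degree + 1):
                try_spec({"mu": dmu, "sigma": dsig}, gender)
    else:
        for dmu in range(max_degree + 1):
            for dsig in range(max_degree + 1):
                try_spec({"mu": dmu, "sigma": dsig, "nu": 0, "tau": 0}, gender)
        for _round in range(3):
            cur = dict(best.spec.degrees)
            for p in ("nu", "tau", "mu", "sigma"):
                for d in range(max_degree + 1):
                    cand = dict(best.spec.degrees)
                    if cand.get(p, 0) == d:
                        continue
                    cand[p] = d
                    try_spec(cand, gender)
            if dict(best.spec.degrees) == cur:
                break

    if best is None:
        raise FitError(f"all candidates failed; trace: {trace}")

    if gender_mode == "auto":
        # interaction considered at the selected degrees only
        try_spec(dict(best.spec.degrees), "main+interaction")

    best.search_trace = trace
    logger.info("selected %s degrees=%s gender=%s BIC=%.2f (%d candidates)",
                family, best.spec.degrees, best.spec.gender, best.bic, len(trace))
    return best


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def randomized_quantile_residuals(
    model: FittedNormModel,
    scores: pd.DataFrame,
    seed: int = 0,
    score_col: str = "score",
) -> np.ndarray:
    """Quantile residuals: probit of U ~ Uniform(F(y-1), F(y)) under the
    per-subject fitted discrete distribution (BB); probit of F(y) for the
    continuous BCPE. Standard normal under a correctly specified model."""
    df = scores.dropna(subset=[score_col])
    y = df[score_col].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    gender = df["gender"] if "gender" in df.columns else pd.Series(["none"] * len(df))
    th = model.predict_params(age, (gender == "female").to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    if model.spec.family == "BB":
        n = model.spec.n_trials
        ks = np.arange(n + 1)
        logp = bb_logpmf(ks[None, :], n, th["mu"][:, None], th["sigma"][:, None])
        cdf = np.cumsum(np.exp(logp), axis=1)
        cdf = np.clip(cdf / cdf[:, -1:], 0.0, 1.0)
        yi = y.astype(int)
        hi = cdf[np.arange(len(y)), yi]
        lo = np.where(yi > 0, cdf[np.arange(len(y)), np.maximum(yi - 1, 0)], 0.0)
        u = rng.uniform(lo, hi)
    else:
        ys = y + model.spec.shift
        from sdqnorm.distributions import BoxCoxPowerExponential
        u = np.array([
            BoxCoxPowerExponential(th["mu"][i], th["sigma"][i], th["nu"][i],
                                   th["tau"][i]).cdf(ys[i])
            for i in range(len(ys))
        ], dtype=float)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return stats.norm.ppf(u)


@dataclass
class WormPlotData:
    """Detrended QQ coordinates with pointwise 95% order-statistic bands."""

    theoretical: np.ndarray  # normal quantiles
    worm: np.ndarray  # empirical minus theoretical quantile deviation
    band: np.ndarray  # 95% half-widths, symmetric about 0

    @property
    def frac_inside(self) -> float:
        return float(np.mean(np.abs(self.worm) <= self.band))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theoretical": self.theoretical, "worm": self.worm,
                             "band": self.band})


def worm_plot(residuals: np.ndarray) -> WormPlotData:
    """Build worm-plot coordinates from quantile residuals (n >= 20)."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = len(r)
    if n < 20:
        raise ValueError("worm plot needs at least 20 residuals")
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    q = stats.norm.ppf(p)
    band = 1.96 * np.sqrt(p * (1.0 - p) / n) / stats.norm.pdf(q)
    return WormPlotData(theoretical=q, worm=r - q, band=band)


def render_worm_plot(data: WormPlotData, path) -> None:
    """Write a worm-plot figure (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(data.theoretical, data.worm, ".", ms=3, color="tab:blue")
    ax.plot(data.theoretical, data.band, "--", lw=1, color="tab:red")
    ax.plot(data.theoretical, -data.band, "--", lw=1, color="tab:red")
    ax.axhline(0.0, lw=0.8, color="grey")
    ax.set_xlabel("theoretical normal quantile")
    ax.set_ylabel("deviation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
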