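"""Synthetic inputs the analysis needs but no table prints.

Two things live here:

* a female background-mortality life table.  The model constrains it
  through one printed fact — remaining life expectancy at age 65 of
  roughly 20 years, matching Dutch women — so we generate a Gompertz table
  ``q(age) = min(1, a·exp(b·(age − start_age)))`` over ages 65–110.  The
  expectancy pins only one of the two Gompertz constants; the default
  slope (b = 0.185, with a = 0.002874 solved so that e(65) = 20.0) was
  calibrated jointly with the model's structural conventions against the
  published base-case outcomes, which an age-flat table cannot reproduce.
  A user life table can be supplied as a two-column CSV (age, qx).

* parameter distributions for the probabilistic sensitivity analysis:
  beta for probabilities and utilities, gamma for costs and durations,
  fitted by method of moments.  The spread comes from, in order of
  preference, a printed standard deviation, a printed (consistent) 95%
  interval, printed binomial counts, or a default 10% relative SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .parameters import MAPPING_TRIO, ParameterSet, ParamSpec

__all__ = [
    "LifeTable",
    "DistributionSpec",
    "make_life_table",
    "life_expectancy",
    "load_life_table",
    "fit_distribution",
    "sample_parameters",
]

GOMPERTZ_A = 0.002874  # baseline annual death probability at the start age
GOMPERTZ_B = 0.185     # log-hazard slope per year of age; pair gives e(65) = 20.0


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) for integer ages start_age..max_age.

    The table closes out: q(max_age) = 1.
    """

    start_age: int
    max_age: int
    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if len(q) != self.max_age - self.start_age + 1:
            raise ValueError("life table length does not match age range")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if np.any(np.diff(q) < -1e-12):
            raise ValueError("death probabilities must be non-decreasing in age")
        if q[-1] != 1.0:
            raise ValueError("life table must close out with q(max_age) = 1")
        object.__setattr__(self, "q", q)

    def q_at(self, age: int | np.ndarray) -> float | np.ndarray:
        age = np.asarray(age)
        if np.any(age < self.start_age) or np.any(age > self.max_age):
            raise ValueError(f"age outside table range [{self.start_age}, {self.max_age}]")
        out = self.q[age - self.start_age]
        return float(out) if out.ndim == 0 else out

    def to_csv(self, path) -> None:
        import pandas as pd

        ages = np.arange(self.start_age, self.max_age + 1)
        pd.DataFrame({"age": ages, "qx": self.q}).to_csv(path, index=False)


def make_life_table(
    a: float = GOMPERTZ_A,
    b: float = GOMPERTZ_B,
    start_age: int = 65,
    max_age: int = 110,
) -> LifeTable:
    """Gompertz life table q(age) = min(1, a·e^{b·(age − start_age)})."""
    if a <= 0:
        raise ValueError("baseline hazard a must be positive")
    if b < 0:
        raise ValueError("log-hazard slope b must be non-negative")
    if start_age >= max_age:
        raise ValueError("start_age must be below max_age")
    ages = np.arange(start_age, max_age + 1)
    q = np.minimum(1.0, a * np.exp(b * (ages - start_age)))
    q[-1] = 1.0
    return LifeTable(start_age, max_age, q)


def load_life_table(path) -> LifeTable:
    """Read a life table from CSV with header columns ``age`` and ``qx``."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"age", "qx"} <= set(df.columns):
        raise ValueError("life-table CSV must have 'age' and 'qx' columns")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    if np.any(np.diff(ages) != 1):
        raise ValueError("life-table ages must be consecutive integers")
    return LifeTable(int(ages[0]), int(ages[-1]), df["qx"].to_numpy(dtype=float))


def life_expectancy(lt: LifeTable, age: int) -> float:
    """Remaining life expectancy at ``age``, half-year convention.

    e(age) = Σ_{t≥1} S(t) + 0.5 with S(t) = Π_{k=0..t−1} (1 − q(age + k)).
    """
    if age < lt.start_age or age > lt.max_age:
        raise ValueError("age outside life table")
    q = lt.q[age - lt.start_age:]
    surv = np.cumprod(1.0 - q)
    return float(surv.sum() + 0.5)


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    family: str  # beta | gamma | fixed | normal-truncated
    params: tuple[float, ...]

    def mean(self) -> float:
        if self.family == "fixed":
            return self.params[0]
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "normal-truncated":
            mu, sd, lo, hi = self.params
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))
        raise ValueError(self.family)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            v = self.params[0]
            return v if size is None else np.full(size, v)
        if self.family == "beta":
            return rng.beta(*self.params, size=size)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=size)
        if self.family == "normal-truncated":
            mu, sd, lo, hi = self.params
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)
        raise ValueError(self.family)


DEFAULT_REL_SE = 0.10  # fallback when no SD, no usable CI and no counts


def _standard_error(spec: ParamSpec) -> float:
    """Best available SE for the parameter (0 means a point mass)."""
    if spec.sd is not None:
        return spec.sd
    if spec.ci_ok:
        if spec.high == spec.low:
            return 0.0
        return (spec.high - spec.low) / 3.92  # 95% normal interval
    if spec.events is not None and spec.trials:
        v = spec.value
        return float(np.sqrt(v * (1.0 - v) / spec.trials))
    return DEFAULT_REL_SE * abs(spec.value)


def fit_distribution(spec: ParamSpec) -> DistributionSpec:
    """Method-of-moments distribution whose mean equals the base value.

    Probabilities and utilities get a beta; costs and operating times a
    gamma.  Degenerate spread (or an explicitly fixed parameter) gives a
    point mass; infeasible beta moments fall back to a [0, 1]-truncated
    normal with a warning.
    """
    if spec.dist_family == "fixed" or spec.kind == "setting":
        return DistributionSpec("fixed", (spec.value,))
    se = _standard_error(spec)
    if se == 0.0:
        return DistributionSpec("fixed", (spec.value,))
    m, v = spec.value, se**2
    if spec.kind in ("probability", "utility"):
        if v >= m * (1.0 - m) or m <= 0.0 or m >= 1.0:
            warnings.warn(
                f"{spec.name}: beta moments infeasible (mean {m}, se {se}); "
                "using truncated normal",
                stacklevel=2,
            )
            return DistributionSpec("normal-truncated", (m, se, 0.0, 1.0))
        k = m * (1.0 - m) / v - 1.0
        return DistributionSpec("beta", (m * k, (1.0 - m) * k))
    # costs and minutes: gamma
    return DistributionSpec("gamma", (m * m / v, v / m))


def fit_all(ps: ParameterSet) -> dict[str, DistributionSpec]:
    return {spec.name: fit_distribution(spec) for spec in ps}


def sample_parameters(
    ps: ParameterSet,
    rng: int | np.random.Generator,
    dists: dict[str, DistributionSpec] | None = None,
) -> ParameterSet:
    """One joint, independent draw of every non-fixed parameter.

    The SLN-mapping outcome probabilities are drawn marginally and then
    renormalized to the simplex (Dirichlet-like).  Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if dists is None:
        dists = fit_all(ps)
    values = {}
    for spec in ps:
        if spec.kind == "setting":
            continue
        values[spec.name] = float(dists[spec.name].sample(rng))
    trio = np.array([values[n] for n in MAPPING_TRIO])
    trio /= trio.sum()
    values.update(dict(zip(MAPPING_TRIO, trio)))
    sampled = ps.with_values(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampled.validate()
    return sampled
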