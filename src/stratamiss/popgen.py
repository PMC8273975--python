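"""Finite-population generation for the survey simulation study.

The study population mirrors a single-center patient cohort: each of the
``N`` units carries a true race/ethnicity category ``X`` (five levels, White
as the reference), a binary low-income indicator generated from race, and a
binary outcome (trust in the healthcare system) generated from race and
income on the logit scale.  The recorded category ``X_star`` -- the value an
EHR system would hold, and the one sampling strata are built from -- starts
out equal to ``X`` and is perturbed later by the misclassification module.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


import numpy as np
import pandas as pd
from scipy.special import expit


RACE_LABELS: tuple[str, ...] = ("White", "Black", "Asian", "Other", "Hispanic")

#: Race/ethnicity distribution of the target population (survey-weighted
#: estimates from the motivating study), in RACE_LABELS order.
RACE_PROBS: tuple[float, ...] = (0.82, 0.10, 0.01, 0.05, 0.02)

#: Log-odds coefficients of the trust outcome model:
#: (intercept, Black, Asian, Other, Hispanic, low_income).
TRUST_COEFS: tuple[float, ...] = (-0.75, -0.25, -0.50, 1.25, -1.50, 1.00)

#: Log-odds coefficients of the low-income model:
#: (intercept, Black, Asian, Other, Hispanic).
INCOME_COEFS: tuple[float, ...] = (-2.00, 1.25, 0.25, 1.75, 0.50)

DEFAULT_POPULATION_SIZE = 100_000


class ConfigurationError(ValueError):
    """Raised when a population configuration violates its invariants."""


@dataclasses.dataclass(frozen=True)
class PopulationConfig:
    """Generative model for a finite population.

    Parameters
    ----------
    N
        Number of units (>= 1).
    race_probs
        Length-H probability vector over the categories, in ``labels`` order.
        Category 1 (first entry) is the reference level of the outcome model.
    trust_coefs
        ``(b0, b2, ..., bH, bL)``: intercept, one log-odds coefficient per
        non-reference category, and the low-income coefficient.
    income_coefs
        ``(g0, g2, ..., gH)``: intercept plus one coefficient per
        non-reference category for the low-income model.
    """

    N: int = DEFAULT_POPULATION_SIZE
    race_probs: tuple[float, ...] = RACE_PROBS
    trust_coefs: tuple[float, ...] = TRUST_COEFS
    income_coefs: tuple[float, ...] = INCOME_COEFS
    labels: tuple[str, ...] = RACE_LABELS

    def __post_init__(self) -> None:
        if int(self.N) < 1:
            raise ConfigurationError(f"population size must be >= 1, got {self.N}")
        p = np.asarray(self.race_probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ConfigurationError("race_probs must be a vector with H >= 2 entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"race_probs must be nonnegative and sum to 1, got sum {p.sum()!r}"
            )
        H = p.size
        if len(self.labels) != H:
            raise ConfigurationError("labels must match race_probs in length")
        if len(self.trust_coefs) != H + 1:
            raise ConfigurationError(
                f"trust_coefs needs H+1={H + 1} entries (intercept, H-1 dummies, income)"
            )
        if len(self.income_coefs) != H:
            raise ConfigurationError(
                f"income_coefs needs H={H} entries (intercept, H-1 dummies)"
            )

    @property
    def H(self) -> int:
        return len(self.race_probs)


@dataclasses.dataclass
class Population:
    """A finite cohort with true and recorded categories.

    ``X`` and ``X_star`` hold integer category codes ``1..H`` (1 = reference,
    White).  ``X_star`` equals ``X`` until a misclassification mechanism is
    applied.
    """

    X: np.ndarray
    X_star: np.ndarray
    low_income: np.ndarray
    Y: np.ndarray
    labels: tuple[str, ...] = RACE_LABELS

    def __post_init__(self) -> None:
        n = len(self.X)
        for name in ("X_star", "low_income", "Y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length != N")
        H = len(self.labels)
        for name in ("X", "X_star"):
            codes = getattr(self, name)
            if codes.min() < 1 or codes.max() > H:
                raise ValueError(f"{name} contains codes outside 1..{H}")

    @property
    def N(self) -> int:
        return len(self.X)

    @property
    def H(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.N),
                "X": self.X,
                "X_star": self.X_star,
                "low_income": self.low_income,
                "Y": self.Y,
            }
        )


def dummies(codes: np.ndarray, H: int) -> np.ndarray:
    """Dummy-encode integer codes 1..H, dropping category 1 (reference).

    Returns an ``(n, H-1)`` 0/1 array whose column ``j`` indicates category
    ``j + 2``.
    """
    return (codes[:, None] == np.arange(2, H + 1)[None, :]).astype(float)


def generate_population(
    config: PopulationConfig, rng: np.random.Generator | int
) -> Population:
    """Draw a finite population from the configured generative model.

    Generation order is race -> low-income -> outcome: category codes are
    i.i.d. categorical with ``race_probs``; low-income is Bernoulli with
    logit linear in the race dummies; the outcome is Bernoulli with logit
    linear in the race dummies and low-income.  Deterministic given the
    generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    N, H = int(config.N), config.H
    p = np.asarray(config.race_probs, dtype=float)

    cum = np.cumsum(p)
    cum[-1] = 1.0  # guard against float round-off at the top bin
    X = np.searchsorted(cum, rng.random(N), side="right").astype(np.int64) + 1

    # per-category linear predictors (reference category contributes 0)
    g = np.asarray(config.income_coefs, dtype=float)
    income_lp = g[0] + np.concatenate(([0.0], g[1:]))
    low_income = (rng.random(N) < expit(income_lp[X - 1])).astype(np.int64)

    b = np.asarray(config.trust_coefs, dtype=float)
    trust_lp = b[0] + np.concatenate(([0.0], b[1:H]))
    Y = (rng.random(N) < expit(trust_lp[X - 1] + b[H] * low_income)).astype(np.int64)

    return Population(X=X, X_star=X.copy(), low_income=low_income, Y=Y,
                      labels=tuple(config.labels))


def write_population_csv(pop: Population, path: str | Path) -> None:
    """Write a population as CSV plus a sidecar JSON label map."""
    path = Path(path)
    pop.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    label_map = {str(i + 1): lab for i, lab in enumerate(pop.labels)}
    sidecar.write_text(json.dumps({"labels": label_map}, indent=2))


def read_population_csv(path: str | Path) -> Population:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        label_map = json.loads(sidecar.read_text())["labels"]
        labels = tuple(label_map[str(i)] for i in sorted(map(int, label_map)))
    else:
        labels = RACE_LABELS
    return Population(
        X=df["X"].to_numpy(np.int64),
        X_star=df["X_star"].to_numpy(np.int64),
        low_income=df["low_income"].to_numpy(np.int64),
        Y=df["Y"].to_numpy(np.int64),
        labels=labels,
    )
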