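"""Misclassification mechanisms for the recorded sampling category.

Two families of mechanisms are provided:

* the *empirical* mechanism, built from the cross-tabulation of EHR-recorded
  against self-reported race/ethnicity among the 604 Vanderbilt University
  Medical Center survey respondents (overall, and stratified by the trust
  outcome to capture differential misclassification);
* a *degree-parameterized* family where a fraction ``d`` of units is
  misclassified, used to sweep misclassification severity from 0 to 0.5.

The empirical cross-tabulation has EHR-recorded category on the rows and
self-reported (taken as true) category on the columns.  Row-normalizing it
gives Pr(true | recorded); column-normalizing gives Pr(recorded | true),
which is the generator needed to corrupt a population whose true categories
are known.  Two readings are exposed through ``matrix_interpretation``:

* ``"bayes_inverted"`` (default): Bayes inversion of the row percentages
  with a uniform prior over the recorded categories — each column of the
  row-percentage matrix, renormalized, becomes the generator row for that
  true category.
* ``"direct"``: reuse the row percentages as generator probabilities,
  re-indexing rows as true categories.

Other priors (e.g. the respondent recorded-category margins, which amount
to column-normalizing the raw counts) can be expressed through
:func:`invert_direction`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .popgen import RACE_LABELS, Population

# Respondent counts, EHR-recorded category (rows) by self-reported category
# (columns), in (White, Black, Asian, Other, Hispanic) order.  604 VUMC
# respondents overall; the stratified tables split them by the trust outcome.
OVERALL_COUNTS = np.array(
    [
        [134, 1, 0, 6, 1],
        [0, 74, 0, 4, 1],
        [1, 1, 62, 14, 3],
        [59, 5, 16, 34, 9],
        [43, 29, 3, 9, 95],
    ],
    dtype=float,
)

TRUST0_COUNTS = np.array(
    [
        [35, 0, 0, 0, 1],
        [0, 20, 0, 2, 1],
        [0, 0, 25, 6, 1],
        [28, 1, 3, 14, 4],
        [11, 9, 1, 3, 37],
    ],
    dtype=float,
)

TRUST1_COUNTS = np.array(
    [
        [99, 1, 0, 6, 0],
        [0, 54, 0, 2, 0],
        [1, 1, 37, 8, 2],
        [31, 4, 13, 20, 5],
        [32, 20, 2, 6, 58],
    ],
    dtype=float,
)

ROW_TOL = 1e-9


class DegenerateRowError(ValueError):
    """A conditional row cannot be formed (zero-probability condition)."""


class DirectionError(ValueError):
    """Matrix supplied in the wrong conditioning direction."""


@dataclasses.dataclass(frozen=True)
class MisclassMatrix:
    """Row-stochastic conditional distribution(s) of one category given another.

    ``direction="generator"`` means row ``i`` is Pr(recorded = j | true = i)
    (optionally per outcome level); ``direction="inverse"`` means row ``i``
    is Pr(true = j | recorded = i).  ``mode="differential"`` carries one
    matrix per outcome level in ``P_by_y``; otherwise a single ``P``.
    """

    mode: str  # "non_differential" | "differential"
    direction: str  # "generator" | "inverse"
    P: np.ndarray | None = None
    P_by_y: Mapping[int, np.ndarray] | None = None
    labels: tuple[str, ...] = RACE_LABELS

    def __post_init__(self) -> None:
        if self.mode not in ("non_differential", "differential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in ("generator", "inverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mode == "non_differential":
            if self.P is None or self.P_by_y is not None:
                raise ValueError("non_differential mode requires P and no P_by_y")
            self._check_stochastic(self.P)
        else:
            if self.P_by_y is None or self.P is not None:
                raise ValueError("differential mode requires P_by_y and no P")
            if set(self.P_by_y) != {0, 1}:
                raise ValueError("differential mode carries exactly two matrices (y=0,1)")
            for m in self.P_by_y.values():
                self._check_stochastic(m)

    def _check_stochastic(self, P: np.ndarray) -> None:
        P = np.asarray(P, float)
        H = len(self.labels)
        if P.shape != (H, H):
            raise ValueError(f"matrix must be {H}x{H}, got {P.shape}")
        if np.any(P < -ROW_TOL) or np.any(P > 1 + ROW_TOL):
            raise ValueError("matrix entries must lie in [0, 1]")
        bad = np.abs(P.sum(axis=1) - 1.0) > ROW_TOL
        if bad.any():
            raise ValueError(f"rows {np.flatnonzero(bad).tolist()} do not sum to 1")

    @property
    def H(self) -> int:
        return len(self.labels)

    def matrix_for(self, y: int | None = None) -> np.ndarray:
        if self.mode == "non_differential":
            return np.asarray(self.P, float)
        if y is None:
            raise ValueError("differential matrix requires an outcome level")
        return np.asarray(self.P_by_y[int(y)], float)


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, float)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise DegenerateRowError("a row of the count table is all zero")
    return counts / sums


def respondent_counts() -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Raw VUMC respondent count tables: overall and per trust level."""
    return OVERALL_COUNTS.copy(), {0: TRUST0_COUNTS.copy(), 1: TRUST1_COUNTS.copy()}


def empirical_matrices(
    interpretation: str = "bayes_inverted",
) -> tuple[MisclassMatrix, MisclassMatrix]:
    """Build the empirical misclassification mechanisms, overall and by outcome.

    Returns ``(overall, stratified)`` in generator direction, ready for
    :func:`apply_misclassification`.  See the module docstring for the two
    interpretations; counts are embedded verbatim so the normalization is
    reproducible.
    """
    if interpretation == "direct":
        conv = _normalize_rows
    elif interpretation == "bayes_inverted":
        def conv(c: np.ndarray) -> np.ndarray:
            rp = _normalize_rows(c).T  # column i of Pr(true|recorded) per true i
            sums = rp.sum(axis=1, keepdims=True)
            if np.any(sums == 0):
                raise DegenerateRowError(
                    "a true category is never reported; cannot condition on it"
                )
            return rp / sums
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")

    overall = MisclassMatrix(
        mode="non_differential", direction="generator", P=conv(OVERALL_COUNTS)
    )
    stratified = MisclassMatrix(
        mode="differential",
        direction="generator",
        P_by_y={0: conv(TRUST0_COUNTS), 1: conv(TRUST1_COUNTS)},
    )
    return overall, stratified


def row_percentage_matrices() -> tuple[MisclassMatrix, MisclassMatrix]:
    """Row-normalized respondent tables: Pr(true | recorded), inverse direction."""
    overall = MisclassMatrix(
        mode="non_differential", direction="inverse", P=_normalize_rows(OVERALL_COUNTS)
    )
    stratified = MisclassMatrix(
        mode="differential",
        direction="inverse",
        P_by_y={
            0: _normalize_rows(TRUST0_COUNTS),
            1: _normalize_rows(TRUST1_COUNTS),
        },
    )
    return overall, stratified


def degree_matrix(
    d: float,
    H: int = 5,
    pattern: str = "uniform",
    profile: np.ndarray | None = None,
    labels: tuple[str, ...] | None = None,
) -> MisclassMatrix:
    """Non-differential mechanism misclassifying a fraction ``d`` of units.

    Every diagonal entry is ``1 - d``.  Off-diagonal mass ``d`` is spread
    uniformly (``d / (H-1)`` each) under ``pattern="uniform"``, or
    proportionally to the off-diagonal row profile of the empirical overall
    generator matrix under ``pattern="table_proportional"`` (rows with no
    off-diagonal mass fall back to uniform).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"degree must lie in [0, 1], got {d}")
    if H < 2:
        raise ValueError("need at least two categories")
    if labels is None:
        labels = RACE_LABELS if H == len(RACE_LABELS) else tuple(str(h) for h in range(1, H + 1))

    P = np.full((H, H), 0.0)
    np.fill_diagonal(P, 1.0 - d)
    if pattern == "uniform":
        off = d / (H - 1)
        P += off * (1 - np.eye(H))
    elif pattern == "table_proportional":
        if profile is None:
            profile = empirical_matrices("bayes_inverted")[0].P
        profile = np.asarray(profile, float)
        if profile.shape != (H, H):
            raise ValueError("profile matrix must be HxH")
        for i in range(H):
            row = profile[i].copy()
            row[i] = 0.0
            total = row.sum()
            if total <= 0:
                P[i] += (d / (H - 1)) * (np.arange(H) != i)
            else:
                P[i] += d * row / total
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return MisclassMatrix(mode="non_differential", direction="generator", P=P,
                          labels=labels)


def identity_matrix(H: int = 5, labels: tuple[str, ...] | None = None) -> MisclassMatrix:
    """No-misclassification mechanism (degree 0)."""
    return degree_matrix(0.0, H=H, labels=labels)


def apply_misclassification(
    pop: Population, m: MisclassMatrix, rng: np.random.Generator | int
) -> Population:
    """Draw the recorded category for every unit from its true category's row.

    Under a differential mechanism the row comes from the outcome-specific
    matrix.  The true category, income and outcome are untouched: only the
    label is corrupted.
    """
    if m.direction != "generator":
        raise DirectionError(
            "matrix conditions on the recorded category; convert it with "
            "invert_direction(m, category_probs) before applying"
        )
    if m.H != pop.H:
        raise ValueError("matrix and population have different category counts")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    x_star = np.empty(pop.N, dtype=np.int64)
    u = rng.random(pop.N)
    if m.mode == "non_differential":
        for h in range(1, pop.H + 1):
            idx = np.flatnonzero(pop.X == h)
            if idx.size == 0:
                continue
            cum = np.cumsum(m.P[h - 1])
            cum[-1] = 1.0
            x_star[idx] = np.searchsorted(cum, u[idx], side="right") + 1
    else:
        for y in (0, 1):
            P = m.matrix_for(y)
            for h in range(1, pop.H + 1):
                idx = np.flatnonzero((pop.X == h) & (pop.Y == y))
                if idx.size == 0:
                    continue
                cum = np.cumsum(P[h - 1])
                cum[-1] = 1.0
                x_star[idx] = np.searchsorted(cum, u[idx], side="right") + 1
    return Population(X=pop.X, X_star=x_star, low_income=pop.low_income, Y=pop.Y,
                      labels=pop.labels)


def invert_direction(m: MisclassMatrix, category_probs: np.ndarray) -> MisclassMatrix:
    """Flip the conditioning direction of a misclassification matrix.

    Given rows Pr(A = j | B = i) and the marginal of A, solves for the
    marginal of B consistent with that joint (``nu^T M = p_A``), builds the
    joint table, and renormalizes its columns to return rows
    Pr(B = j | A = i).  Applying the inversion twice with consistent
    marginals recovers the input.
    """
    p_a = np.asarray(category_probs, float)
    if p_a.shape != (m.H,):
        raise ValueError("category_probs must have one entry per category")
    if np.any(p_a <= 0):
        raise DegenerateRowError(
            "zero-probability target category: cannot condition on it"
        )

    def invert_one(M: np.ndarray) -> np.ndarray:
        nu = np.linalg.solve(M.T, p_a)
        if np.any(nu < -1e-10):
            raise ValueError(
                "supplied marginal is inconsistent with the matrix "
                "(implied conditioning-variable marginal has negative mass)"
            )
        nu = np.clip(nu, 0.0, None)
        joint = nu[:, None] * M  # joint[i, j] = Pr(B=i, A=j)
        cols = joint.sum(axis=0)
        if np.any(cols <= 0):
            raise DegenerateRowError("a target category receives no mass")
        return (joint / cols[None, :]).T

    new_dir = "inverse" if m.direction == "generator" else "generator"
    if m.mode == "non_differential":
        return MisclassMatrix(mode=m.mode, direction=new_dir, P=invert_one(m.P),
                              labels=m.labels)
    return MisclassMatrix(
        mode=m.mode,
        direction=new_dir,
        P_by_y={y: invert_one(m.matrix_for(y)) for y in (0, 1)},
        labels=m.labels,
    )


def write_matrix_csv(m: MisclassMatrix, path: str | Path) -> None:
    """Write matrices as CSV (one file per outcome level) plus a JSON descriptor."""
    path = Path(path)
    desc: dict = {"mode": m.mode, "direction": m.direction, "labels": list(m.labels)}
    if m.mode == "non_differential":
        pd.DataFrame(m.P, index=m.labels, columns=m.labels).to_csv(path)
        desc["files"] = {"all": path.name}
    else:
        desc["files"] = {}
        for y in (0, 1):
            p = path.with_name(f"{path.stem}_y{y}{path.suffix}")
            pd.DataFrame(m.matrix_for(y), index=m.labels, columns=m.labels).to_csv(p)
            desc["files"][str(y)] = p.name
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2))


def read_matrix_csv(descriptor_path: str | Path) -> MisclassMatrix:
    descriptor_path = Path(descriptor_path)
    desc = json.loads(descriptor_path.read_text())
    labels = tuple(desc["labels"])
    folder = descriptor_path.parent

    def load(name: str) -> np.ndarray:
        return pd.read_csv(folder / name, index_col=0).to_numpy(float)

    if desc["mode"] == "non_differential":
        return MisclassMatrix(mode="non_differential", direction=desc["direction"],
                              P=load(desc["files"]["all"]), labels=labels)
    return MisclassMatrix(
        mode="differential",
        direction=desc["direction"],
        P_by_y={int(y): load(f) for y, f in desc["files"].items()},
        labels=labels,
    )
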