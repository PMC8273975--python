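"""Monte-Carlo engine: scenarios, replication, summaries, degree sweeps.

A scenario fixes the generative population model, a misclassification
mechanism, a set of sampling designs and analysis methods, and a
replication count.  Each replicate draws a fresh population, corrupts the
recorded category, samples under every design and fits every method; the
per-replicate estimates are then summarized into the mean estimate,
empirical SE (standard deviation of estimates across replicates) and the
95% Wald coverage of the generating coefficients.

Randomness contract: replicate ``r`` of a scenario seeded with ``s`` uses
``numpy.random.SeedSequence((s, r))``, so any replicate is reproducible in
isolation and results are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import misclassify
from .estimators import METHODS, ModelSpec, fit_method
from .popgen import PopulationConfig, generate_population
from .sampling import dss, srs

logger = logging.getLogger(__name__)

FULL_COHORT = "full_cohort"


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """One sampling design: full_cohort, srs(n) or dss(quotas).

    ``methods`` optionally restricts which analysis methods run on this
    design (default: all methods of the scenario).
    """

    kind: str
    n: int | None = None
    quotas: tuple[int, ...] | None = None
    methods: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (FULL_COHORT, "srs", "dss"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "srs" and (self.n is None or self.n < 1):
            raise ValueError("srs design needs a positive sample size")
        if self.kind == "dss" and not self.quotas:
            raise ValueError("dss design needs per-stratum quotas")

    @property
    def label(self) -> str:
        return self.kind


@dataclasses.dataclass(frozen=True)
class MisclassSpec:
    """Which mechanism corrupts the recorded category.

    ``kind``: "none", "empirical_overall" (non-differential),
    "empirical_differential", or "degree" (uses ``degree``/``pattern``).
    ``interpretation`` picks how the empirical count table is turned into
    generator probabilities (see :mod:`stratamiss.misclassify`).
    """

    kind: str = "none"
    degree: float | None = None
    pattern: str = "uniform"
    interpretation: str = "bayes_inverted"

    def build(self, H: int) -> misclassify.MisclassMatrix | None:
        if self.kind == "none":
            return None
        if self.kind == "empirical_overall":
            return misclassify.empirical_matrices(self.interpretation)[0]
        if self.kind == "empirical_differential":
            return misclassify.empirical_matrices(self.interpretation)[1]
        if self.kind == "degree":
            if self.degree is None:
                raise ValueError("degree mechanism needs a degree value")
            return misclassify.degree_matrix(self.degree, H=H, pattern=self.pattern)
        raise ValueError(f"unknown misclassification kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class Scenario:
    name: str
    population: PopulationConfig = dataclasses.field(default_factory=PopulationConfig)
    misclassification: MisclassSpec = dataclasses.field(default_factory=MisclassSpec)
    designs: tuple[DesignSpec, ...] = (DesignSpec(FULL_COHORT),)
    methods: tuple[str, ...] = METHODS
    reps: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    variance: str = "unstratified"  # sandwich form for the design-based method

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def truth(self) -> pd.Series:
        """Generating coefficient for every structural parameter."""
        b = self.population.trust_coefs
        names = ["intercept", *self.population.labels[1:], "low_income"]
        return pd.Series(list(b), index=names)


@dataclasses.dataclass
class SimSummary:
    """Per (design, method, parameter) Monte-Carlo summary table."""

    scenario: str
    table: pd.DataFrame  # columns: design, method, parameter, truth,
    # mean_estimate, empirical_se, coverage, n_converged, n_total

    def cell(self, design: str, method: str, parameter: str) -> pd.Series:
        t = self.table
        m = (t.design == design) & (t.method == method) & (t.parameter == parameter)
        if not m.any():
            raise KeyError((design, method, parameter))
        return t.loc[m].iloc[0]


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(rep))))


def _fit_rows(pop, sample, method, spec, out, rep, design_label):
    fit = fit_method(pop, sample, spec)
    for name, est in fit.coefficients.items():
        out.append(
            (
                rep,
                design_label,
                method,
                name,
                est,
                fit.se[name],
                fit.ci_lower[name],
                fit.ci_upper[name],
                fit.converged,
            )
        )


def run_scenario(
    scn: Scenario, progress: bool = False
) -> tuple[SimSummary, pd.DataFrame]:
    """Run all replicates of a scenario and summarize.

    Returns the summary and the per-replicate long table ``(replicate,
    design, method, parameter, estimate, se, ci_lower, ci_upper,
    converged)``.  Full-cohort fits always use the design-agnostic model
    (there is no design to account for when the whole population is
    observed).
    """
    H = scn.population.H
    mech = scn.misclassification.build(H)
    rows: list[tuple] = []
    for r in range(scn.reps):
        rng = replicate_rng(scn.seed, r)
        pop = generate_population(scn.population, rng)
        if mech is not None:
            pop = misclassify.apply_misclassification(pop, mech, rng)
        for design in scn.designs:
            if design.kind == FULL_COHORT:
                spec = ModelSpec("design_agnostic", ci_level=scn.ci_level)
                _fit_rows(pop, None, "design_agnostic", spec, rows, r, FULL_COHORT)
                continue
            sample = (
                srs(pop, design.n, rng)
                if design.kind == "srs"
                else dss(pop, list(design.quotas), rng)
            )
            for method in design.methods or scn.methods:
                spec = ModelSpec(method, ci_level=scn.ci_level, variance=scn.variance)
                _fit_rows(pop, sample, method, spec, rows, r, design.label)
        if progress and (r + 1) % max(1, scn.reps // 20) == 0:
            logger.info("%s: replicate %d/%d", scn.name, r + 1, scn.reps)

    replicates = pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "design",
            "method",
            "parameter",
            "estimate",
            "se",
            "ci_lower",
            "ci_upper",
            "converged",
        ],
    )
    return summarize(replicates, scn), replicates


def summarize(replicates: pd.DataFrame, scn: Scenario) -> SimSummary:
    """Collapse a per-replicate table into Monte-Carlo summaries.

    Replicates flagged non-converged are dropped from the cell (method x
    design x parameter) they failed in only; the counts make the exclusion
    auditable.  Coverage is the fraction of converged replicates whose Wald
    interval contains the generating coefficient; parameters without a
    generating value (the recorded-category dummies) get NaN coverage.
    With a single converged replicate the empirical SE is undefined (NaN).
    """
    truth = scn.truth()
    out = []
    for (design, method, param), grp in replicates.groupby(
        ["design", "method", "parameter"], sort=False
    ):
        ok = grp[grp.converged]
        n_total = grp.replicate.nunique()
        n_conv = len(ok)
        t = truth.get(param, np.nan)
        if n_conv == 0:
            logger.warning("no converged replicates for %s/%s/%s", design, method, param)
            out.append((design, method, param, t, np.nan, np.nan, np.nan, 0, n_total))
            continue
        mean = ok.estimate.mean()
        emp_se = ok.estimate.std(ddof=1) if n_conv > 1 else np.nan
        if np.isnan(t):
            cov = np.nan
        else:
            cov = float(np.mean((ok.ci_lower <= t) & (t <= ok.ci_upper)))
        out.append((design, method, param, t, mean, emp_se, cov, n_conv, n_total))
    table = pd.DataFrame(
        out,
        columns=[
            "design",
            "method",
            "parameter",
            "truth",
            "mean_estimate",
            "empirical_se",
            "coverage",
            "n_converged",
            "n_total",
        ],
    )
    return SimSummary(scenario=scn.name, table=table)


def relative_uncertainty(
    dss_summary: SimSummary, srs_summary: SimSummary
) -> pd.DataFrame:
    """Empirical-SE ratio of each DSS method to the SRS baseline.

    The baseline is the design-agnostic fit on the SRS sample.  A ratio
    below one means the stratified design was more precise for that
    parameter; the log2 ratio is reported alongside.
    """
    srs_t = srs_summary.table
    base = srs_t[(srs_t.design == "srs") & (srs_t.method == "design_agnostic")]
    base = base.set_index("parameter").empirical_se
    d = dss_summary.table
    d = d[d.design == "dss"].copy()
    denom = d.parameter.map(base)
    ratio = d.empirical_se / denom
    ratio[denom <= 0] = np.nan
    d["relative_uncertainty"] = ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        d["log2_relative_uncertainty"] = np.log2(ratio)
    return d[["method", "parameter", "relative_uncertainty",
              "log2_relative_uncertainty"]].reset_index(drop=True)


@dataclasses.dataclass
class SweepResult:
    degrees: tuple[float, ...]
    table: pd.DataFrame  # columns: degree, method, parameter, ratio, log2_ratio


def sweep_degree(
    base: Scenario,
    degrees: Sequence[float],
    pattern: str = "uniform",
    progress: bool = False,
) -> SweepResult:
    """Re-run the scenario across misclassification degrees and form ratios.

    At each degree the scenario is run with both an SRS and a DSS design
    (taken from ``base.designs``; both must be present) and the empirical-SE
    ratio DSS/SRS computed per method and parameter.
    """
    degrees = tuple(float(d) for d in degrees)
    if not degrees:
        raise ValueError("degrees list is empty")
    if any(not 0 <= d <= 1 for d in degrees):
        raise ValueError("degrees must lie in [0, 1]")
    kinds = {d.kind for d in base.designs}
    if not {"srs", "dss"} <= kinds:
        raise ValueError("sweep needs both an srs and a dss design in the scenario")

    frames = []
    for d in degrees:
        scn = dataclasses.replace(
            base,
            name=f"{base.name}_d{d:g}",
            misclassification=MisclassSpec(kind="degree", degree=d, pattern=pattern),
        )
        summary, _ = run_scenario(scn, progress=progress)
        rel = relative_uncertainty(summary, summary)
        rel.insert(0, "degree", d)
        frames.append(rel)
        if progress:
            logger.info("sweep: finished degree %g", d)
    table = pd.concat(frames, ignore_index=True).rename(
        columns={
            "relative_uncertainty": "ratio",
            "log2_relative_uncertainty": "log2_ratio",
        }
    )
    return SweepResult(degrees=degrees, table=table)
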