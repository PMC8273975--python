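"""Survey sampling designs: SRS and disproportionate stratified sampling.

Strata for the stratified design are the *recorded* categories ``X_star``
(the EHR-derived values available at design time), not the true ones.
Sampling is without replacement; the weight attached to a unit is the
inverse of its realized selection probability, ``N*_h / n*_h`` for a unit
drawn from stratum ``h`` (``N / n`` under SRS), so Horvitz-Thompson totals
of the strata are reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import Population


@dataclasses.dataclass
class SurveySample:
    """A without-replacement sample with its design metadata.

    ``stratum`` holds the recorded category each unit was sampled from
    (``None`` for SRS).  ``stratum_pop_sizes`` / ``stratum_sample_sizes``
    map stratum code -> N*_h / realized n*_h.
    """

    unit_ids: np.ndarray
    weights: np.ndarray
    design: str  # "srs" | "dss"
    stratum: np.ndarray | None = None
    stratum_pop_sizes: dict[int, int] | None = None
    stratum_sample_sizes: dict[int, int] | None = None
    empty_strata: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids: sampling is without replacement")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 1.0 - 1e-12):
            raise ValueError("weights must be finite and >= 1")

    @property
    def n(self) -> int:
        return len(self.unit_ids)


def srs(pop: Population, n: int, rng: np.random.Generator | int) -> SurveySample:
    """Simple random sample of ``n`` units; every weight is ``N / n``."""
    if not 1 <= n <= pop.N:
        raise ValueError(f"sample size must lie in [1, {pop.N}], got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = rng.choice(pop.N, size=n, replace=False, shuffle=False)
    return SurveySample(
        unit_ids=np.sort(ids),
        weights=np.full(n, pop.N / n),
        design="srs",
    )


def dss(
    pop: Population,
    per_stratum: dict[int, int] | np.ndarray | list[int],
    rng: np.random.Generator | int,
) -> SurveySample:
    """Disproportionate stratified sample on the recorded category.

    ``per_stratum`` gives the quota for each stratum (dict keyed by category
    code, or a length-H sequence).  A quota exceeding the stratum size takes
    the whole stratum with weight 1; an empty stratum with a positive quota
    contributes no units and triggers a warning, recorded in
    ``empty_strata``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(per_stratum, dict):
        quotas = {int(h): int(q) for h, q in per_stratum.items()}
    else:
        quotas = {h + 1: int(q) for h, q in enumerate(per_stratum)}
    if any(q <= 0 for q in quotas.values()):
        raise ValueError("stratum quotas must be positive")

    ids, weights, strata = [], [], []
    pop_sizes: dict[int, int] = {}
    samp_sizes: dict[int, int] = {}
    empty: list[int] = []
    for h, quota in sorted(quotas.items()):
        members = np.flatnonzero(pop.X_star == h)
        pop_sizes[h] = int(members.size)
        if members.size == 0:
            warnings.warn(f"stratum {h} is empty; quota {quota} yields no units")
            empty.append(h)
            samp_sizes[h] = 0
            continue
        take = min(quota, members.size)
        if take < quota:
            warnings.warn(
                f"stratum {h} has only {members.size} units; taking all of them"
            )
        chosen = rng.choice(members, size=take, replace=False, shuffle=False)
        ids.append(np.sort(chosen))
        weights.append(np.full(take, members.size / take))
        strata.append(np.full(take, h, dtype=np.int64))
        samp_sizes[h] = take

    return SurveySample(
        unit_ids=np.concatenate(ids),
        weights=np.concatenate(weights),
        design="dss",
        stratum=np.concatenate(strata),
        stratum_pop_sizes=pop_sizes,
        stratum_sample_sizes=samp_sizes,
        empty_strata=tuple(empty),
    )


def truncate_weights(weights: np.ndarray, percentile: float) -> np.ndarray:
    """Cap weights at the given percentile of their distribution.

    The percentile is computed with linear interpolation between order
    statistics (the ``numpy.percentile`` default); weights above the cap are
    set equal to it.
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must lie in (0, 100], got {percentile}")
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    cap = np.percentile(w, percentile)
    return np.minimum(w, cap)


def write_sample_csv(sample: SurveySample, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "unit_id": sample.unit_ids,
            "stratum": sample.stratum if sample.stratum is not None else -1,
            "weight": sample.weights,
        }
    ).to_csv(path, index=False)
    desc = {
        "design": sample.design,
        "stratum_pop_sizes": sample.stratum_pop_sizes,
        "stratum_sample_sizes": sample.stratum_sample_sizes,
        "empty_strata": list(sample.empty_strata),
    }
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2))
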