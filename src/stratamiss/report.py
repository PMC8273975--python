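"""Human-readable rendering of simulation summaries and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

MAIN_PARAMETERS = ("intercept", "Black", "Asian", "Other", "Hispanic", "low_income")
_PARAM_DISPLAY = {"intercept": "Intercept", "low_income": "Low income"}
MISSING = "—"  # em dash for absent cells


def format_cell(mean: float, se: float, coverage: float) -> str:
    """Format one summary cell as ``mean (SE) coverage%``.

    Mean and SE carry two decimals, coverage one; rounding is
    round-half-even (IEEE 754, Python's default float formatting).
    Missing components render as an em dash.
    """
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return MISSING
    se_s = MISSING if se is None or np.isnan(se) else f"{se:.2f}"
    cov_s = MISSING if coverage is None or np.isnan(coverage) else f"{coverage * 100:.1f}"
    return f"{mean:.2f} ({se_s}){cov_s}"


def render_summary(summary: pd.DataFrame, title: str = "") -> str:
    """Render a summary table as markdown: rows = parameters, columns =
    design/method, cells = ``mean (SE) coverage%``."""
    cols: list[tuple[str, str]] = []
    for design, method in (
        summary[["design", "method"]].drop_duplicates().itertuples(index=False)
    ):
        cols.append((design, method))

    def header(design: str, method: str) -> str:
        if design == "full_cohort":
            return "Full cohort"
        if design == "srs":
            return "SRS"
        return f"DSS {method.replace('_', '-')}"

    params = [p for p in MAIN_PARAMETERS if (summary.parameter == p).any()]
    # keep any extra parameters (e.g. recorded-category dummies) at the end
    params += [p for p in summary.parameter.unique() if p not in params]

    lines = []
    if title:
        lines += [f"### {title}", ""]
    head = ["Parameter"] + [header(d, m) for d, m in cols]
    lines.append("| " + " | ".join(head) + " |")
    lines.append("|" + "---|" * len(head))
    for p in params:
        row = [_PARAM_DISPLAY.get(p, p)]
        for design, method in cols:
            m = (
                (summary.design == design)
                & (summary.method == method)
                & (summary.parameter == p)
            )
            if not m.any():
                row.append(MISSING)
                continue
            cell = summary.loc[m].iloc[0]
            row.append(
                format_cell(cell.mean_estimate, cell.empirical_se, cell.coverage)
            )
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_hash: str
    seed: int
    version: str
    timestamp: str
    outputs: dict[str, str]
    convergence: dict[str, dict[str, int]]

    @classmethod
    def create(
        cls,
        config_path: str | Path,
        seed: int,
        version: str,
        outputs: dict[str, str],
        convergence: dict[str, dict[str, int]],
    ) -> "RunManifest":
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        return cls(
            config_hash=digest,
            seed=seed,
            version=version,
            timestamp=datetime.now(timezone.utc).isoformat(),
            outputs=outputs,
            convergence=convergence,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with floats at six significant digits (deterministic)."""
    df.to_csv(path, index=False, float_format="%.6g")
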