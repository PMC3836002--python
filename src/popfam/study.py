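"""Type-I-error and power experiments for the combined test.

Reproduces the simulation study validating the method: rejection rates
of the combined statistic and of its two components (the trend test P
and the transmission Wald test F) under the null and under the six
penetrance scenarios, at 200 trios + 200 controls and 1000 replicates
per scenario by default.
"""

from __future__ import annotations

import io as _io
import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import core
from .simulate import (
    SCENARIOS,
    ControlMode,
    GeneticModel,
    simulate_alt_dataset,
    simulate_null_dataset,
)

__all__ = ["StudyConfig", "StudyResult", "run_type1", "run_power", "report_tables"]

logger = logging.getLogger(__name__)

METHODS = ("POPFAM", "P", "F")


@dataclass
class StudyConfig:
    """Configuration of a rejection-rate experiment.

    Defaults mirror the validating simulation study: the six scenarios,
    200 trios and 200 controls, 1000 replicates, two-sided levels 5% and
    1%, fixed weight w = ½ (cases and controls are balanced, so the two
    components have comparable power).
    """

    scenarios: dict[str, GeneticModel] = field(
        default_factory=lambda: dict(SCENARIOS)
    )
    n_trios: int = 200
    n_controls: int = 200
    n_reps: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.01)
    weight_mode: str = "half"
    variance_mode: str = "hwe"
    maf_source: str = "untransmitted"
    control_mode: ControlMode = "population"
    #: marker MAF(s) for the null experiment
    null_mafs: tuple[float, ...] = (0.2,)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not all(0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1]")


@dataclass
class StudyResult:
    """Rejection rates per (scenario, method, alpha), with provenance."""

    table: pd.DataFrame
    config: StudyConfig

    def proportion(self, scenario: str, method: str, alpha: float) -> float:
        t = self.table
        row = t[
            (t.scenario == scenario) & (t.method == method) & (t.alpha == alpha)
        ]
        if len(row) != 1:
            raise KeyError((scenario, method, alpha))
        return float(row.proportion.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _critical(alpha: float) -> float:
    return float(norm.isf(alpha / 2.0))


def _tally(rows: list[dict], scenario: str, stats: dict[str, np.ndarray],
           skipped_f: int, config: StudyConfig) -> None:
    n = config.n_reps
    for method in METHODS:
        vals = stats[method]
        n_eff = n - (skipped_f if method == "F" else 0)
        for alpha in config.alphas:
            crit = _critical(alpha)
            rej = int((np.abs(vals) >= crit).sum())
            prop = rej / n_eff if n_eff else math.nan
            rows.append(
                dict(
                    scenario=scenario,
                    method=method,
                    alpha=alpha,
                    n_reps=n_eff,
                    rejections=rej,
                    proportion=prop,
                    mc_se=math.sqrt(prop * (1 - prop) / n_eff) if n_eff else math.nan,
                    seed=config.base_seed,
                )
            )


def _replicate_stats(config: StudyConfig, make_dataset) -> tuple[dict, int]:
    """Run ``n_reps`` replicates; replicate r uses seed base_seed + r."""
    z = np.empty(config.n_reps)
    p = np.empty(config.n_reps)
    f = np.full(config.n_reps, np.nan)
    skipped_f = 0
    for r in range(config.n_reps):
        rng = np.random.default_rng(config.base_seed + r)
        ds = make_dataset(rng)
        res = core.popfam_test(
            ds,
            variance_mode=config.variance_mode,
            weight_mode=config.weight_mode,
            maf_source=config.maf_source,
        )
        z[r], p[r] = res.z, res.P_stat
        if res.H == 0:
            skipped_f += 1
            logger.warning("replicate %d has H = 0; excluded from F", r)
        else:
            f[r] = res.F_stat
    return {"POPFAM": z, "P": p, "F": f[~np.isnan(f)]}, skipped_f


def run_type1(config: StudyConfig) -> StudyResult:
    """Null rejection rates at each configured null MAF.

    Each replicate simulates trios and controls at the same marker MAF
    with no disease locus, runs the combined test, and records two-sided
    rejections of POPFAM, P and F at each alpha.
    """
    rows: list[dict] = []
    for maf in config.null_mafs:
        t0 = time.perf_counter()
        stats, skipped = _replicate_stats(
            config,
            lambda rng: simulate_null_dataset(
                maf, config.n_trios, config.n_controls, rng
            ),
        )
        _tally(rows, f"null_maf_{maf:g}", stats, skipped, config)
        logger.info(
            "null maf=%g: %d reps in %.1fs", maf, config.n_reps,
            time.perf_counter() - t0,
        )
    return StudyResult(pd.DataFrame(rows), config)


def run_power(config: StudyConfig) -> StudyResult:
    """Rejection rates under each alternative scenario."""
    rows: list[dict] = []
    for name, model in config.scenarios.items():
        t0 = time.perf_counter()
        stats, skipped = _replicate_stats(
            config,
            lambda rng: simulate_alt_dataset(
                model, config.n_trios, config.n_controls, rng,
                control_mode=config.control_mode,
            ),
        )
        _tally(rows, name, stats, skipped, config)
        logger.info(
            "scenario %s: %d reps in %.1fs", name, config.n_reps,
            time.perf_counter() - t0,
        )
    return StudyResult(pd.DataFrame(rows), config)


def report_tables(result: StudyResult, percent: bool = True) -> str:
    """Render a study result as fixed-width text (one row per scenario).

    Proportions are shown as percentages to one decimal when ``percent``
    (the power-table layout) and as raw proportions to three decimals
    otherwise (the type-I-error layout), each with its Monte-Carlo
    standard error.
    """
    t = result.table
    buf = _io.StringIO()
    header = ["scenario"] + [
        f"{m} @ {a:g}" for a in sorted(set(t.alpha), reverse=True) for m in METHODS
    ] if len(t) else ["scenario"]
    buf.write("\t".join(header) + "\n")
    for scenario in dict.fromkeys(t.scenario):
        cells = [scenario]
        for alpha in sorted(set(t.alpha), reverse=True):
            for m in METHODS:
                sub = t[(t.scenario == scenario) & (t.method == m) & (t.alpha == alpha)]
                prop = float(sub.proportion.iloc[0])
                se = float(sub.mc_se.iloc[0])
                if percent:
                    cells.append(f"{100 * prop:.1f} ± {100 * se:.1f}")
                else:
                    cells.append(f"{prop:.3f} ± {se:.3f}")
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()
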