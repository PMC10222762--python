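"""Taguchi L9(3^4) design construction, orthogonality checks and ANOVA.

The L9 orthogonal array screens four factors at three levels in nine runs:
each level appears three times in every column, and every ordered pair of
columns contains each of the nine level combinations exactly once.  Here the
four factors are the drug product, the dissolution medium, the apparatus and
the rotation speed, and the responses are the cumulative percent dissolved
at selected time points (Q%2h, Q%12h, Q%24h).

The analysis is a fixed-effects main-effects ANOVA
``response ~ product + medium + apparatus + speed`` (each factor 2 df).
An L9 cannot resolve interactions, so none are modelled; with n replicate
units per run the between-run stratum (8 df) is exactly the sum of the four
factor strata, and the residual is the within-run variation (9n - 9 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product as iproduct
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DOE_FACTORS, DOE_LEVELS

__all__ = ["TaguchiDesign", "l9_design", "check_orthogonality", "doe_anova"]

# Canonical L9 in {-1, 0, 1} coding.  With the level ordering of DOE_LEVELS
# this decodes exactly to the published run table (run 1 = Generic #1 /
# 0.9% NaCl / basket / 50 rpm, ..., run 9 = Generic #2 / water /
# paddle+sinker / 50 rpm).
_L9_CODES = np.array(
    [
        [-1, -1, -1, -1],
        [-1, 0, 0, 0],
        [-1, 1, 1, 1],
        [0, -1, 0, 1],
        [0, 0, 1, -1],
        [0, 1, -1, 0],
        [1, -1, 1, 0],
        [1, 0, -1, 1],
        [1, 1, 0, -1],
    ],
    dtype=int,
)


class DesignError(ValueError):
    """Invalid design construction request or design table."""


@dataclass(frozen=True)
class TaguchiDesign:
    factors: tuple[str, ...]
    levels: dict[str, tuple]
    runs: np.ndarray  # (9, 4) level codes in {-1, 0, 1}

    def decode(self) -> pd.DataFrame:
        """Run table with factor labels substituted for level codes."""
        rows = []
        for i, row in enumerate(self.runs, start=1):
            rows.append(
                {"run": i}
                | {f: self.levels[f][code + 1] for f, code in zip(self.factors, row)}
            )
        return pd.DataFrame(rows)


def l9_design(
    factors: Sequence[str] | None = None,
    levels: dict[str, Sequence] | None = None,
) -> TaguchiDesign:
    """Build the standard L9 orthogonal array for 4 factors at 3 levels.

    Level sequences are given in (-1, 0, 1) order.  Defaults reproduce the
    dissolution-method screening design for the desvenlafaxine ER products.
    """
    factors = tuple(factors if factors is not None else DOE_FACTORS)
    levels = {k: tuple(v) for k, v in (levels or DOE_LEVELS).items()}
    if len(factors) != 4:
        raise DesignError(f"L9 requires exactly 4 factors, got {len(factors)}")
    for f in factors:
        if f not in levels:
            raise DesignError(f"no levels given for factor {f!r}")
        if len(levels[f]) != 3:
            raise DesignError(f"factor {f!r} must have 3 levels, got {len(levels[f])}")
    return TaguchiDesign(factors=factors, levels=levels, runs=_L9_CODES.copy())


def check_orthogonality(design: TaguchiDesign | np.ndarray) -> tuple[bool, list[str]]:
    """Balance + pairwise-completeness check for a 3-level array.

    Returns ``(ok, violations)`` where violations name the offending column
    or column pair.  Any array whose columns are balanced and whose column
    pairs contain every level combination equally often passes (so the full
    3^k factorial passes too).
    """
    runs = design.runs if isinstance(design, TaguchiDesign) else np.asarray(design)
    if runs.ndim != 2:
        raise DesignError("design must be a rectangular run table")
    n_runs, n_cols = runs.shape
    violations: list[str] = []
    per_col = n_runs / 3
    for j in range(n_cols):
        counts = {lvl: int(np.sum(runs[:, j] == lvl)) for lvl in (-1, 0, 1)}
        if any(c != per_col for c in counts.values()):
            violations.append(f"column {j}: unbalanced level counts {counts}")
    per_pair = n_runs / 9
    for j, k in combinations(range(n_cols), 2):
        for a, b in iproduct((-1, 0, 1), repeat=2):
            count = int(np.sum((runs[:, j] == a) & (runs[:, k] == b)))
            if count != per_pair:
                violations.append(
                    f"columns ({j},{k}): combination ({a},{b}) occurs "
                    f"{count}x, expected {per_pair:g}"
                )
                break
    return (len(violations) == 0), violations


def doe_anova(design: TaguchiDesign, responses: pd.DataFrame) -> pd.DataFrame:
    """Main-effects ANOVA of replicate-unit responses over the L9 runs.

    ``responses`` must have a ``run`` column (1..9) plus one column per
    response; every run needs the same number n >= 2 of replicate rows.
    Returns a tidy frame with per-response, per-factor SS, df, F and p, and
    the residual (within-run) stratum.  Factor SS are computed from level
    means; because the array is orthogonal this equals the usual Type I/III
    decomposition and the four factor SS sum exactly to the between-run SS.
    """
    if "run" not in responses.columns:
        raise DesignError("responses need a 'run' column")
    decoded = design.decode()
    counts = responses.groupby("run").size()
    if len(counts) != len(decoded):
        raise DesignError("responses must cover all 9 runs")
    n_units = int(counts.iloc[0])
    if (counts != n_units).any():
        raise DesignError("all runs need the same number of replicate units")
    if n_units < 2:
        raise DesignError("need >= 2 units per run for a residual error term")
    data = responses.merge(decoded, on="run", validate="many_to_one")
    response_cols = [
        c
        for c in responses.columns
        if c not in ("run", "unit") and pd.api.types.is_numeric_dtype(responses[c])
    ]
    if not response_cols:
        raise DesignError("no numeric response columns found")

    df_resid = len(data) - len(decoded)  # 9n - 9
    rows = []
    for resp in response_cols:
        y = data[resp].to_numpy(dtype=float)
        grand = y.mean()
        ss_total = float(np.sum((y - grand) ** 2))
        run_means = data.groupby("run")[resp].transform("mean").to_numpy()
        ss_resid = float(np.sum((y - run_means) ** 2))
        ms_resid = ss_resid / df_resid
        for factor in design.factors:
            level_means = data.groupby(factor, observed=True)[resp].mean()
            level_n = data.groupby(factor, observed=True)[resp].size()
            ss_f = float(np.sum(level_n * (level_means - grand) ** 2))
            df_f = 2
            if ss_total <= 1e-12 * max(1.0, grand**2):
                f_stat, p = 0.0, 1.0  # all responses identical
            elif ms_resid == 0.0:
                f_stat, p = np.inf, 0.0
            else:
                f_stat = (ss_f / df_f) / ms_resid
                p = float(stats.f.sf(f_stat, df_f, df_resid))
            rows.append(
                {"response": resp, "term": factor, "ss": ss_f, "df": df_f,
                 "F": f_stat, "p": p}
            )
        rows.append(
            {"response": resp, "term": "residual", "ss": ss_resid,
             "df": df_resid, "F": np.nan, "p": np.nan}
        )
    return pd.DataFrame(rows)
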