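"""Batch-culture fermentation bookkeeping and summaries.

Degradability from residue masses, the microbial-protein estimate from
truly degraded substrate minus gas-associated substrate, factorial group
summaries (mean ± SEM), and the methanogen–protozoa Pearson correlation.
The mixed-model inference step (random run effect, multiple comparisons)
is deliberately not reimplemented: :func:`group_summaries` produces the
tidy table a mixed-model package consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default stoichiometric factor of gas-associated substrate, mg truly
#: degraded substrate per mL of gas.
DEFAULT_STOICH_FACTOR = 2.2


def degradability(substrate_in_mg: float, residue_mg: float) -> float:
    """Fraction of substrate disappearing during incubation: (in − residue)/in.

    Serves both dry-matter (DDM) and NDF (NDFD) degradability given the
    matching input/residue masses.
    """
    if substrate_in_mg <= 0:
        raise ValueError("substrate input must be positive")
    if residue_mg < 0 or residue_mg > substrate_in_mg:
        raise ValueError("residue must lie in [0, substrate input]")
    return (substrate_in_mg - residue_mg) / substrate_in_mg


def microbial_protein(
    truly_degraded_mg: float,
    gas_ml: float,
    stoich_factor: float = DEFAULT_STOICH_FACTOR,
) -> tuple[float, bool]:
    """Microbial biomass estimate: truly degraded substrate − gas × factor.

    The stoichiometric factor (mg substrate per mL gas) is explicit
    configuration.  A negative balance is floored at zero and flagged.
    """
    if truly_degraded_mg < 0 or gas_ml < 0 or stoich_factor < 0:
        raise ValueError("inputs must be non-negative")
    value = truly_degraded_mg - gas_ml * stoich_factor
    return (max(value, 0.0), value < 0)


@dataclass
class GroupSummary:
    factors: dict
    n: int
    mean: float | None
    sem: float | None


def _summarize(group: pd.Series) -> tuple[int, float | None, float | None]:
    vals = group.dropna().to_numpy(dtype=float)
    n = vals.size
    if n == 0:
        return 0, None, None
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else None
    return n, mean, sem


def group_summaries(
    records: pd.DataFrame,
    response: str,
    factors: list[str],
    levels: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Mean ± SEM per factor level and per full interaction cell.

    One row per level of each single factor, then one per interaction cell,
    ordered by the declared ``levels`` (defaults to order of appearance).
    Empty cells are reported with n=0 and no mean.
    """
    if response not in records.columns:
        raise KeyError(f"response {response!r} not in records")
    levels = levels or {}

    def ordered(f: str) -> list:
        if f in levels:
            return list(levels[f])
        return list(pd.unique(records[f]))

    rows = []
    for f in factors:
        for lv in ordered(f):
            n, mean, sem = _summarize(records.loc[records[f] == lv, response])
            rows.append({"term": f, **{f: lv}, "n": n, "mean": mean, "sem": sem})
    if len(factors) > 1:
        import itertools

        for combo in itertools.product(*(ordered(f) for f in factors)):
            mask = np.ones(len(records), dtype=bool)
            for f, lv in zip(factors, combo):
                mask &= (records[f] == lv).to_numpy()
            n, mean, sem = _summarize(records.loc[mask, response])
            rows.append(
                {"term": " x ".join(factors), **dict(zip(factors, combo)), "n": n, "mean": mean, "sem": sem}
            )
    out = pd.DataFrame(rows)
    cols = ["term", *factors, "n", "mean", "sem"]
    return out.reindex(columns=cols)


def population_correlation(
    methanogen_log10, protozoa_log10
) -> tuple[float, float]:
    """Pearson correlation between paired log10 population abundances.

    Returns (r, two-sided p) with p from the t transform on n−2 degrees of
    freedom.  Zero variance in either series is an error (r undefined).
    """
    x = np.asarray(methanogen_log10, dtype=float)
    y = np.asarray(protozoa_log10, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def add_derived_columns(records: pd.DataFrame, stoich_factor: float = DEFAULT_STOICH_FACTOR) -> pd.DataFrame:
    """Attach DDM, NDFD and the microbial-protein balance to a culture table."""
    out = records.copy()
    out["ddm"] = [
        degradability(i, r) for i, r in zip(out["substrate_in_mg"], out["residue_mg"])
    ]
    if {"ndf_in_mg", "ndf_residue_mg"}.issubset(out.columns):
        out["ndfd"] = [
            degradability(i, r) for i, r in zip(out["ndf_in_mg"], out["ndf_residue_mg"])
        ]
    if "gas_ml" in out.columns:
        mp = [
            microbial_protein(i - r, g, stoich_factor)
            for i, r, g in zip(out["substrate_in_mg"], out["residue_mg"], out["gas_ml"])
        ]
        out["mp_balance_mg"] = [v for v, _ in mp]
        out["mp_floored"] = [f for _, f in mp]
    return out
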