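"""Cumulative risk-genotype burden analysis.

Each subject's burden k is the number of risk genotypes carried over a
pool of markers, coded under the per-marker selected inheritance model.
The burden enters a linear logistic trend test (unconditional or
conditional on matched pairs), and compound-carrier odds-ratio curves
are built for every prefix pool of the markers sorted by ascending
single-marker P value.  The OR at each k compares the observed
case/control split of that carrier class against an expected 1:1 split
of the same total, which keeps curves comparable across populations and
pool sizes at some cost in power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CohortError
from .single_marker import (
    AssocResult,
    InheritanceModel,
    Z975,
    bonferroni,
    code_risk_genotype,
    fit_conditional_pairs,
    fit_unconditional,
)

logger = logging.getLogger(__name__)


def count_risk_genotypes(
    cohort: Cohort,
    models: dict[str, InheritanceModel],
    pool: list[str],
) -> pd.DataFrame:
    """Per-subject burden k over ``pool``, coded under ``models``.

    Returns a frame with columns ``subject_id, population, status,
    pair_id, k``; k is NaN (subject excluded downstream) when any pool
    genotype is missing.
    """
    for mid in pool:
        if mid not in cohort.marker_ids:
            raise CohortError(f"pool marker {mid} absent from cohort")
        if mid not in models:
            raise CohortError(f"no selected inheritance model for {mid}")
    out = cohort.data[["subject_id", "population", "status", "pair_id"]].copy()
    k = np.zeros(len(out))
    for mid in pool:
        mdef = cohort.marker(mid)
        ind = cohort.data[mid].map(
            lambda x: code_risk_genotype(x, mdef, models[mid])
        )
        k = k + ind.astype(float).to_numpy()
    out["k"] = k
    n_missing = int(np.isnan(k).sum())
    if n_missing:
        logger.warning("%d subjects lack a complete pool genotype", n_missing)
    return out


def cumulative_trend_test(
    profiles: pd.DataFrame,
    design: str = "unconditional",
    population: str = "",
    bonferroni_m: int = 2,
) -> AssocResult:
    """Linear logistic trend test of case status on the burden k.

    The per-risk-genotype OR is exp(beta) from a logistic regression with
    the integer burden as the only covariate — unconditional, or the
    matched-pair conditional likelihood when ``design='matched_pairs'``.
    """
    prof = profiles.dropna(subset=["k"])
    if prof["k"].nunique() <= 1:
        return AssocResult(
            "cumulative", population, None, design,
            math.nan, math.nan, math.nan, math.nan, math.nan, len(prof),
            ("constant_burden",),
        )
    if design == "matched_pairs":
        piv = prof.pivot(index="pair_id", columns="status", values="k")
        res = fit_conditional_pairs(
            piv[1].to_numpy(), piv[0].to_numpy(), "cumulative", population
        )
    else:
        res = fit_unconditional(
            prof["status"].to_numpy(), prof["k"].to_numpy(), "cumulative", population
        )
    res.method = design if design == "unconditional" else "conditional_pairs"
    return res.corrected(bonferroni_m) if res.defined else res


def order_markers(results: dict[str, AssocResult]) -> list[str]:
    """Markers sorted by ascending nominal P of the selected model.

    Ties broken by descending OR, then lexicographic marker id, so the
    ordering is deterministic.
    """
    defined = {mid: r for mid, r in results.items() if r.defined}
    if len(defined) < 2:
        raise CohortError("need at least two markers with a defined P value")
    return sorted(defined, key=lambda mid: (defined[mid].p_nominal, -defined[mid].or_hat, mid))


def or_vs_expected(n_cases_k: float, n_controls_k: float) -> tuple[float, float, float]:
    """Compound-carrier OR of a burden class against a 1:1 expected split.

    The reference row of the 2x2 table is the same total split evenly
    (n/2, n/2 — kept as real numbers for odd n), so the OR reduces to
    a/b.  The 95% CI uses the Woolf log-OR variance of that constructed
    table, SE = sqrt(1/a + 1/b + 4/n).  When either observed cell is
    empty the OR is undefined (NaN), not infinite.
    """
    a, b = float(n_cases_k), float(n_controls_k)
    n = a + b
    if n == 0 or a == 0 or b == 0:
        return math.nan, math.nan, math.nan
    beta = math.log(a / b)
    se = math.sqrt(1.0 / a + 1.0 / b + 4.0 / n)
    return math.exp(beta), math.exp(beta - Z975 * se), math.exp(beta + Z975 * se)


@dataclass
class PoolCurve:
    """Compound-carrier OR per burden class k for one prefix pool."""

    population: str
    pool: list[str]
    table: pd.DataFrame  # columns: k, n_cases, n_controls, or, ci_low, ci_high, p_nominal, p_corrected, defined
    aggregation: str = "exact_k"

    @property
    def pool_size(self) -> int:
        return len(self.pool)


def build_pool_curves(
    cohort: Cohort,
    ordered: list[str],
    models: dict[str, InheritanceModel],
    population: str,
    aggregation: str = "exact_k",
    bonferroni_m: int | None = None,
) -> list[PoolCurve]:
    """One OR curve per prefix pool of size 2..len(ordered).

    ``exact_k`` (default) reports each burden class separately;
    ``at_least_k`` aggregates tail sums (class k = subjects carrying at
    least k risk genotypes).  P values are two-sided Wald on the log OR
    against the 1:1 reference, Bonferroni-corrected over the number of
    pools tested (len(ordered) - 1 unless overridden).
    """
    if len(ordered) < 2:
        raise CohortError("ordered marker list must have length >= 2")
    if aggregation not in ("exact_k", "at_least_k"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    m_pools = bonferroni_m if bonferroni_m is not None else len(ordered) - 1
    sub = cohort.subset(population)
    curves = []
    for size in range(2, len(ordered) + 1):
        pool = ordered[:size]
        prof = count_risk_genotypes(sub, models, pool).dropna(subset=["k"])
        ks = np.arange(size + 1)
        n_cases = np.array([((prof["status"] == 1) & (prof["k"] == k)).sum() for k in ks])
        n_controls = np.array([((prof["status"] == 0) & (prof["k"] == k)).sum() for k in ks])
        if aggregation == "at_least_k":
            n_cases = n_cases[::-1].cumsum()[::-1]
            n_controls = n_controls[::-1].cumsum()[::-1]
        rows = []
        for k, a, b in zip(ks, n_cases, n_controls):
            or_k, lo, hi = or_vs_expected(a, b)
            if math.isfinite(or_k):
                se = math.sqrt(1.0 / a + 1.0 / b + 4.0 / (a + b))
                p = 2.0 * float(stats.norm.sf(abs(math.log(or_k)) / se))
                p_corr = bonferroni(p, m_pools)
            else:
                p = p_corr = math.nan
            rows.append(
                {
                    "k": int(k), "n_cases": int(a), "n_controls": int(b),
                    "or": or_k, "ci_low": lo, "ci_high": hi,
                    "p_nominal": p, "p_corrected": p_corr,
                    "defined": math.isfinite(or_k),
                }
            )
        curves.append(PoolCurve(population, list(pool), pd.DataFrame(rows), aggregation))
    return curves


def curves_to_frame(curves: list[PoolCurve]) -> pd.DataFrame:
    """Long-format export of the curve family behind the OR-vs-k figure."""
    frames = []
    for c in curves:
        df = c.table.copy()
        df.insert(0, "population", c.population)
        df.insert(1, "pool_size", c.pool_size)
        df.insert(2, "pool", "|".join(c.pool))
        df.insert(3, "aggregation", c.aggregation)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
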