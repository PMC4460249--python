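"""Per-marker case-control statistics.

Covers risk-genotype coding under dominant/recessive inheritance models,
the two-sided exact Hardy-Weinberg test, between-population genotype
heterogeneity, unconditional logistic regression (unmatched samples) and
the conditional likelihood for 1:1 matched pairs, Wald inference,
Bonferroni correction and inheritance-model selection.

Only the dominant and recessive codings are provided: with an a-priori
risk allele these map the three genotype classes to a binary exposure
(carrier of >= 1 risk allele, or homozygous risk carrier).  Additive and
codominant codings are out of scope.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, CohortError, CountTable, MarkerDef

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


class InheritanceModel(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


@dataclass
class AssocResult:
    """Odds ratio with Wald 95% CI and nominal/corrected P for one test.

    ``or_hat`` and the CI bounds are NaN when the estimate is undefined
    (e.g. no discordant pairs); degenerate fits carry explanatory flags
    rather than failing.
    """

    marker_id: str
    population: str
    model: InheritanceModel | None
    method: str  # "unconditional" | "conditional_pairs"
    or_hat: float
    ci_low: float
    ci_high: float
    p_nominal: float
    p_corrected: float
    n_effective: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.or_hat)

    def corrected(self, m: int) -> "AssocResult":
        """Copy with Bonferroni factor ``m`` applied to the nominal P."""
        out = AssocResult(**{**self.__dict__})
        out.p_corrected = bonferroni(self.p_nominal, m)
        return out


@dataclass(frozen=True)
class HWEResult:
    marker_id: str
    population: str
    status: int
    p_exact: float
    het_observed: float
    het_expected: float


# ---------------------------------------------------------------------------
# genotype coding
# ---------------------------------------------------------------------------

def code_risk_genotype(
    genotype: str | None, marker: MarkerDef, model: InheritanceModel
) -> int | None:
    """Binary risk-genotype indicator; ``None`` for a missing genotype.

    Dominant: 1 iff the subject carries at least one risk allele.
    Recessive: 1 iff the subject is homozygous for the risk allele.
    """
    n_risk = marker.risk_allele_count(marker.normalize_genotype(genotype))
    if n_risk is None:
        return None
    if InheritanceModel(model) is InheritanceModel.DOMINANT:
        return int(n_risk >= 1)
    return int(n_risk == 2)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(
    counts: tuple[int, int, int],
    marker_id: str = "",
    population: str = "",
    status: int = -1,
) -> HWEResult:
    """Two-sided exact Hardy-Weinberg test on (hom_a, het, hom_b) counts.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of the same parity; the P value is the sum of the
    conditional probabilities of all tables no more probable than the
    observed one.  Probabilities are accumulated in log space so large
    strata do not overflow.  A monomorphic marker yields P = 1 with a
    warning.
    """
    hom_a, het, hom_b = (int(c) for c in counts)
    if min(hom_a, het, hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_a + het + hom_b
    if n == 0:
        raise ValueError("empty stratum")
    na = 2 * hom_a + het
    nb = 2 * hom_b + het
    p_a = na / (2 * n)
    het_expected = 2 * p_a * (1 - p_a) * n
    if na == 0 or nb == 0:
        logger.warning("%s: monomorphic marker, exact HWE P set to 1", marker_id or "?")
        return HWEResult(marker_id, population, status, 1.0, float(het), het_expected)

    def log_prob(h: int) -> float:
        # P(h heterozygotes | allele counts na, nb) under random mating
        return (
            math.lgamma(n + 1)
            - math.lgamma((na - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((nb - h) // 2 + 1)
            + h * math.log(2.0)
            + math.lgamma(na + 1)
            + math.lgamma(nb + 1)
            - math.lgamma(2 * n + 1)
        )

    h_min = na % 2  # parity fixed by the odd/even allele count
    h_values = range(h_min, min(na, nb) + 1, 2)
    log_probs = np.array([log_prob(h) for h in h_values])
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[list(h_values).index(het)]
    p_exact = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return HWEResult(marker_id, population, status, min(p_exact, 1.0), float(het), het_expected)


# ---------------------------------------------------------------------------
# between-population heterogeneity
# ---------------------------------------------------------------------------

def heterogeneity_chisq(
    counts: CountTable,
    status: int,
    marker_id: str | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-squared for genotype-distribution differences between
    populations within one status group.

    With ``marker_id=None`` the three genotype rows of every marker are
    stacked into one table (each subject contributes one count per
    marker), so a six-marker panel over four populations gives an
    18 x 4 table with 51 degrees of freedom.  All-zero rows or columns
    are dropped with a warning.
    """
    pops = counts.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    markers = (
        [m for m in counts.panel if m.marker_id == marker_id]
        if marker_id
        else counts.panel
    )
    if not markers:
        raise KeyError(marker_id)
    rows = []
    for mdef in markers:
        per_pop = np.array([counts.counts(p, status, mdef.marker_id) for p in pops]).T
        rows.append(per_pop)  # 3 x n_pops
    table = np.vstack(rows).astype(float)
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.warning(
            "dropping %d zero rows / %d zero columns from heterogeneity table",
            int((~keep_rows).sum()),
            int((~keep_cols).sum()),
        )
        table = table[keep_rows][:, keep_cols]
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# logistic fits
# ---------------------------------------------------------------------------

def _wald(beta: float, se: float) -> tuple[float, float, float, float]:
    or_hat = math.exp(beta)
    ci_low = math.exp(beta - Z975 * se)
    ci_high = math.exp(beta + Z975 * se)
    p = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return or_hat, ci_low, ci_high, p


def fit_unconditional(
    status: np.ndarray,
    g: np.ndarray,
    marker_id: str = "",
    population: str = "",
    model: InheritanceModel | None = None,
) -> AssocResult:
    """Unconditional logistic regression of case status on one covariate.

    ``g`` may be a binary indicator or an integer count (the cumulative
    test).  Inference is Wald throughout.  For a binary covariate with an
    empty 2x2 cell the Haldane-Anscombe 0.5 continuity correction is used
    for the reported OR/CI/P and the result is flagged ``separation``.
    """
    status = np.asarray(status, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~np.isnan(g)
    status, g = status[keep], g[keep]
    n = len(status)
    flags: list[str] = []
    if n == 0 or len(np.unique(status)) < 2:
        raise CohortError("both cases and controls are required")
    if np.ptp(g) == 0:
        return AssocResult(
            marker_id, population, model, "unconditional",
            math.nan, math.nan, math.nan, math.nan, math.nan, n,
            ("constant_covariate",),
        )

    binary = set(np.unique(g)) <= {0.0, 1.0}
    if binary:
        a = float(((status == 1) & (g == 1)).sum())  # case carriers
        b = float(((status == 1) & (g == 0)).sum())
        c = float(((status == 0) & (g == 1)).sum())
        d = float(((status == 0) & (g == 0)).sum())
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            flags.append("separation")
        if flags:
            beta = math.log(a * d / (b * c))
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            or_hat, lo, hi, p = _wald(beta, se)
            return AssocResult(
                marker_id, population, model, "unconditional",
                or_hat, lo, hi, p, p, n, tuple(flags),
            )
    try:
        fit = sm.Logit(status, sm.add_constant(g)).fit(disp=0, maxiter=50, tol=1e-10)
        if not fit.mle_retvals.get("converged", True):
            flags.append("not_converged")
        beta, se = float(fit.params[1]), float(fit.bse[1])
    except Exception:  # perfect separation on a non-binary covariate
        return AssocResult(
            marker_id, population, model, "unconditional",
            math.nan, math.nan, math.nan, math.nan, math.nan, n,
            ("separation",),
        )
    or_hat, lo, hi, p = _wald(beta, se)
    return AssocResult(
        marker_id, population, model, "unconditional",
        or_hat, lo, hi, p, p, n, tuple(flags),
    )


def _pair_loglik(beta: float, d: np.ndarray) -> float:
    # sum log sigma(beta * d) over informative (discordant) pairs
    return float(-np.logaddexp(0.0, -beta * d).sum())


def fit_conditional_pairs(
    g_case: np.ndarray,
    g_control: np.ndarray,
    marker_id: str = "",
    population: str = "",
    model: InheritanceModel | None = None,
) -> AssocResult:
    """Conditional logistic regression for 1:1 matched case-control pairs.

    The conditional likelihood of pair *i* depends only on the within-pair
    covariate difference d_i = g_case - g_control, reducing to a
    one-dimensional logistic likelihood sum log sigma(beta * d_i) that is
    maximized by Newton iteration (gradient inf-norm <= 1e-10, <= 50
    steps).  Concordant pairs (d = 0) contribute nothing.  For a binary
    exposure the MLE is the discordant-pair ratio log(n10/n01) with
    SE = sqrt(1/n10 + 1/n01); a zero discordant cell falls back to the
    0.5 continuity correction and is flagged, and with no discordant
    pairs at all the OR is undefined.
    """
    g_case = np.asarray(g_case, dtype=float)
    g_control = np.asarray(g_control, dtype=float)
    keep = ~(np.isnan(g_case) | np.isnan(g_control))
    d = (g_case - g_control)[keep]
    n_pairs = len(d)
    d_inf = d[d != 0]
    flags: list[str] = []
    if len(d_inf) == 0:
        return AssocResult(
            marker_id, population, model, "conditional_pairs",
            math.nan, math.nan, math.nan, math.nan, math.nan, 0,
            ("no_discordant_pairs",),
        )

    if set(np.unique(np.abs(d_inf))) == {1.0}:
        n10 = float((d_inf > 0).sum())  # case exposed only
        n01 = float((d_inf < 0).sum())
        if n10 == 0 or n01 == 0:
            n10, n01 = n10 + 0.5, n01 + 0.5
            flags.append("separation")
        beta = math.log(n10 / n01)
        se = math.sqrt(1 / n10 + 1 / n01)
    else:
        beta, se, newton_flags = _newton_pairs(d_inf)
        flags.extend(newton_flags)
        if not math.isfinite(beta):
            return AssocResult(
                marker_id, population, model, "conditional_pairs",
                math.nan, math.nan, math.nan, math.nan, math.nan, len(d_inf),
                tuple(flags) or ("separation",),
            )
    or_hat, lo, hi, p = _wald(beta, se)
    return AssocResult(
        marker_id, population, model, "conditional_pairs",
        or_hat, lo, hi, p, p, len(d_inf), tuple(flags),
    )


def _newton_pairs(d: np.ndarray) -> tuple[float, float, list[str]]:
    # all differences positive (or all negative) => likelihood is monotone
    if (d > 0).all() or (d < 0).all():
        return math.inf * np.sign(d[0]), math.nan, ["separation"]
    beta = 0.0
    for _ in range(50):
        expit = 1.0 / (1.0 + np.exp(-beta * d))
        grad = float((d * (1.0 - expit)).sum())
        hess = float(-(d * d * expit * (1.0 - expit)).sum())
        if abs(grad) <= 1e-10:
            break
        beta -= grad / hess
    else:
        return beta, math.sqrt(-1.0 / hess), ["not_converged"]
    expit = 1.0 / (1.0 + np.exp(-beta * d))
    hess = float(-(d * d * expit * (1.0 - expit)).sum())
    return beta, math.sqrt(-1.0 / hess), []


# ---------------------------------------------------------------------------
# multiple testing and model selection
# ---------------------------------------------------------------------------

def bonferroni(p: float, m: int) -> float:
    """min(1, m*p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def select_model(
    result_dominant: AssocResult,
    result_recessive: AssocResult,
    criterion: str = "lowest_p",
) -> AssocResult:
    """Pick the inheritance model for one marker/population.

    ``lowest_p`` (default) selects the model with the smaller nominal P,
    ties broken by the larger OR; ``max_or`` selects the model whose
    estimated OR for the risk allele is larger.  Returns the winning fit;
    raises if both fits are degenerate.
    """
    candidates = [r for r in (result_dominant, result_recessive) if r.defined]
    if not candidates:
        raise CohortError(
            f"{result_dominant.marker_id}/{result_dominant.population}: "
            "both inheritance-model fits degenerate"
        )
    if criterion == "lowest_p":
        return min(candidates, key=lambda r: (r.p_nominal, -r.or_hat))
    if criterion == "max_or":
        return max(candidates, key=lambda r: r.or_hat)
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def fit_marker(
    cohort: Cohort,
    population: str,
    marker_id: str,
    model: InheritanceModel,
    bonferroni_m: int = 2,
) -> AssocResult:
    """Fit one marker under one inheritance model for one population,
    choosing the regression method from the population's design."""
    mdef = cohort.marker(marker_id)
    sub = cohort.data[cohort.data["population"] == population]
    g = sub[marker_id].map(lambda x: code_risk_genotype(x, mdef, model))
    g = g.astype(float).to_numpy()
    design = cohort.design.get(population, "unconditional")
    if design == "matched_pairs":
        wide = pd.DataFrame({"status": sub["status"], "pair": sub["pair_id"], "g": g})
        piv = wide.pivot(index="pair", columns="status", values="g")
        res = fit_conditional_pairs(
            piv[1].to_numpy(), piv[0].to_numpy(), marker_id, population, model
        )
    else:
        res = fit_unconditional(
            sub["status"].to_numpy(), g, marker_id, population, model
        )
    return res.corrected(bonferroni_m) if res.defined else res


def analyze_population(
    cohort: Cohort,
    population: str,
    criterion: str = "lowest_p",
    bonferroni_m: int = 2,
) -> dict[str, AssocResult]:
    """Selected-model association result per marker for one population.

    Markers whose fits are degenerate under both models are excluded with
    a log message (they cannot enter downstream pools).
    """
    out: dict[str, AssocResult] = {}
    for mid in cohort.marker_ids:
        fits = {
            m: fit_marker(cohort, population, mid, m, bonferroni_m)
            for m in InheritanceModel
        }
        try:
            out[mid] = select_model(
                fits[InheritanceModel.DOMINANT], fits[InheritanceModel.RECESSIVE], criterion
            )
        except CohortError:
            logger.warning("%s/%s: excluded (degenerate fits)", mid, population)
    return out


def hwe_by_stratum(counts: CountTable) -> list[HWEResult]:
    """Exact HWE test for every (population, status, marker) stratum."""
    out = []
    for pop in counts.populations:
        for status in (1, 0):
            for mdef in counts.panel:
                trip = counts.counts(pop, status, mdef.marker_id)
                out.append(hwe_exact_test(trip, mdef.marker_id, pop, status))
    return out


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Long-format export mirroring the per-marker results table layout."""
    return pd.DataFrame(
        [
            {
                "marker": r.marker_id,
                "population": r.population,
                "model": r.model.value if r.model else "",
                "method": r.method,
                "or": r.or_hat,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_nominal": r.p_nominal,
                "p_corrected": r.p_corrected,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
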