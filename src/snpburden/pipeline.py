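"""End-to-end report assembly and simulation calibration harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    STUDY_DESIGN,
    load_fixture,
    read_genotype_table,
    read_marker_panel,
    tabulate_counts,
)
from .cumulative import (
    build_pool_curves,
    count_risk_genotypes,
    cumulative_trend_test,
    curves_to_frame,
    order_markers,
)
from .simulate import SimSpec, margin_exact_cohort, simulate_cohort, simulate_matched_pairs
from .single_marker import (
    analyze_population,
    heterogeneity_chisq,
    hwe_by_stratum,
    results_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str  # path to a genotype TSV, or the keyword "fixture"
    panel_path: str | None = None
    design: dict[str, str] = field(default_factory=dict)
    criterion: str = "lowest_p"
    aggregation: str = "exact_k"
    bonferroni_single: int = 2
    bonferroni_cumulative: int = 2
    bonferroni_pools: int | None = None
    rng_seed: int = 0
    out_dir: str = "snpburden_out"


def _load_input(config: RunConfig) -> Cohort:
    if config.input_path == "fixture":
        counts = load_fixture()
        design = config.design or STUDY_DESIGN
        return margin_exact_cohort(counts, rng_seed=config.rng_seed, design=design)
    if config.panel_path is None:
        raise ValueError("a panel file is required for non-fixture input")
    panel = read_marker_panel(config.panel_path)
    return read_genotype_table(config.input_path, panel, design=config.design)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write per-population report CSVs.

    Emits: exact-HWE table, between-population heterogeneity tests,
    per-marker selected-model association results, the cumulative burden
    trend test, and the prefix-pool OR curve table, plus a run log.
    Deterministic given (input bytes, config, seed).
    """
    cohort = _load_input(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"snpburden {__version__}", f"seed {config.rng_seed}"]

    counts = tabulate_counts(cohort)
    log_lines += [
        f"{pop}: {cohort.n_cases(pop)} cases / {cohort.n_controls(pop)} controls "
        f"({cohort.design.get(pop, 'unconditional')})"
        for pop in cohort.populations
    ]
    log_lines += [
        f"call rate {mid}: {cohort.call_rate(mid):.4f}" for mid in cohort.marker_ids
    ]

    # exact HWE per stratum
    hwe = pd.DataFrame(
        [
            {
                "marker": r.marker_id, "population": r.population, "status": r.status,
                "p_exact": r.p_exact, "het_observed": r.het_observed,
                "het_expected": r.het_expected,
            }
            for r in hwe_by_stratum(counts)
        ]
    )

    # between-population heterogeneity (all markers stacked + per marker)
    het_rows = []
    if len(cohort.populations) >= 2:
        for status in (1, 0):
            for mid in [None, *cohort.marker_ids]:
                chi2, df, p = heterogeneity_chisq(counts, status, mid)
                het_rows.append(
                    {"status": status, "marker": mid or "all", "chi2": chi2, "df": df, "p": p}
                )
    heterogeneity = pd.DataFrame(het_rows)

    # per-population single-marker analysis, cumulative test, pool curves
    single_results = []
    cumulative_rows = []
    curve_frames = []
    for pop in cohort.populations:
        selected = analyze_population(
            cohort, pop, criterion=config.criterion, bonferroni_m=config.bonferroni_single
        )
        single_results += list(selected.values())
        models = {mid: r.model for mid, r in selected.items()}
        design = cohort.design.get(pop, "unconditional")
        sub = cohort.subset(pop)

        profiles = count_risk_genotypes(sub, models, list(selected))
        trend = cumulative_trend_test(
            profiles, design, pop, bonferroni_m=config.bonferroni_cumulative
        )
        cumulative_rows.append(
            {
                "population": pop, "method": trend.method, "or": trend.or_hat,
                "ci_low": trend.ci_low, "ci_high": trend.ci_high,
                "p_nominal": trend.p_nominal, "p_corrected": trend.p_corrected,
                "flags": ";".join(trend.flags),
            }
        )
        ordered = order_markers(selected)
        log_lines.append(f"{pop} marker order: {', '.join(ordered)}")
        curves = build_pool_curves(
            cohort, ordered, models, pop,
            aggregation=config.aggregation, bonferroni_m=config.bonferroni_pools,
        )
        curve_frames.append(curves_to_frame(curves))
        for r in single_results:
            if r.flags and r.population == pop:
                log_lines.append(f"flagged: {r.marker_id}/{pop} {';'.join(r.flags)}")

    reports = {
        "genotype_counts": counts.with_percent(),
        "hwe": hwe,
        "heterogeneity": heterogeneity,
        "single_marker": results_to_frame(single_results),
        "cumulative": pd.DataFrame(cumulative_rows),
        "pool_curves": pd.concat(curve_frames, ignore_index=True),
    }
    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return reports


# ---------------------------------------------------------------------------
# calibration harness
# ---------------------------------------------------------------------------

def run_calibration(
    spec: SimSpec,
    replicates: int,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Repeated simulate-then-analyze runs for type-I error / power / bias.

    Each replicate draws a fresh seeded cohort from ``spec``, runs the
    cumulative trend test and (for the first marker) the single-marker
    fit, and records the estimates.  Returns a per-replicate frame; use
    :func:`summarize_calibration` for the aggregate.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    base = np.random.SeedSequence(spec.rng_seed)
    child_seeds = base.generate_state(replicates)
    models = {ms.marker.marker_id: ms.model for ms in spec.markers}
    for i in range(replicates):
        rep_spec = SimSpec(
            spec.markers, spec.populations, spec.alpha, spec.design,
            rng_seed=int(child_seeds[i] % (2**31)),
        )
        cohort = (
            simulate_matched_pairs(rep_spec)
            if spec.design == "matched_pairs"
            else simulate_cohort(rep_spec)
        )
        for pop in cohort.populations:
            sub = cohort.subset(pop)
            design = cohort.design[pop]
            profiles = count_risk_genotypes(sub, models, list(models))
            trend = cumulative_trend_test(profiles, design, pop)
            from .single_marker import fit_marker  # local import to avoid cycle noise

            first = spec.markers[0]
            single = fit_marker(cohort, pop, first.marker.marker_id, first.model)
            rows.append(
                {
                    "replicate": i, "population": pop,
                    "trend_or": trend.or_hat, "trend_p": trend.p_nominal,
                    "trend_reject": bool(trend.defined and trend.p_nominal < alpha_level),
                    "single_or": single.or_hat,
                    "single_ci_low": single.ci_low, "single_ci_high": single.ci_high,
                    "single_covers_truth": bool(
                        single.defined
                        and single.ci_low <= np.exp(first.beta) <= single.ci_high
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_calibration(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a calibration frame: rejection rate, mean OR, CI coverage."""
    return (
        per_rep.groupby("population")
        .agg(
            replicates=("replicate", "count"),
            trend_rejection_rate=("trend_reject", "mean"),
            mean_single_or=("single_or", "mean"),
            ci_coverage=("single_covers_truth", "mean"),
        )
        .reset_index()
    )
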