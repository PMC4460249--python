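"""Synthetic case-control cohorts with known truth.

Two generation modes:

* **Model-based simulation** — genotypes are drawn at Hardy-Weinberg
  proportions in the source population, independently across markers
  (linkage equilibrium), and disease status follows the logistic model

      logit P(case) = alpha + sum_j beta_j * g_j

  where g_j is the binary risk-genotype indicator under marker j's true
  inheritance model.  Case-control ascertainment is retrospective: the
  population is oversampled and thinned by status until the requested
  numbers of cases and controls are reached.  Because the odds ratio is
  invariant to this ascertainment, the baseline log-odds ``alpha`` is a
  nuisance parameter (default 0).

* **Margin-exact reconstruction** — given a published genotype count
  table, individual genotype vectors are built with exactly the printed
  per-marker class counts; the joint assignment across markers is an
  independent seeded permutation per marker, since count margins
  constrain nothing else.

Both modes are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortError, CountTable, MarkerDef
from .single_marker import InheritanceModel

_MAX_BATCHES = 1000


@dataclass(frozen=True)
class MarkerSim:
    """True data-generating parameters for one simulated marker."""

    marker: MarkerDef
    risk_allele_freq: float
    model: InheritanceModel
    beta: float  # true log-OR of the risk genotype

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(
                f"{self.marker.marker_id}: risk allele frequency must be in (0,1)"
            )


@dataclass
class SimSpec:
    """Full specification of a simulated multi-population study."""

    markers: list[MarkerSim]
    populations: dict[str, tuple[int, int]]  # name -> (n_cases, n_controls)
    alpha: float = 0.0
    design: str = "unconditional"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for pop, (nca, nco) in self.populations.items():
            if nca < 0 or nco < 0:
                raise ValueError(f"{pop}: negative sample size")
        if self.design not in ("unconditional", "matched_pairs"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def is_null(self) -> bool:
        return all(ms.beta == 0.0 for ms in self.markers)

    @property
    def panel(self) -> list[MarkerDef]:
        return [ms.marker for ms in self.markers]

    @classmethod
    def from_yaml(cls, path) -> "SimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        markers = [
            MarkerSim(
                MarkerDef(
                    m["marker_id"], m["allele_a"], m["allele_b"], m["risk_allele"]
                ),
                float(m["risk_allele_freq"]),
                InheritanceModel(m["model"]),
                float(m["beta"]),
            )
            for m in raw["markers"]
        ]
        pops = {
            name: (int(v["n_cases"]), int(v["n_controls"]))
            for name, v in raw["populations"].items()
        }
        return cls(
            markers,
            pops,
            alpha=float(raw.get("alpha", 0.0)),
            design=raw.get("design", "unconditional"),
            rng_seed=int(raw.get("rng_seed", 0)),
        )


def _draw_genotypes(ms: MarkerSim, n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotype strings for n subjects at HWE (p^2, 2pq, q^2)."""
    p = ms.risk_allele_freq
    classes = np.array(ms.marker.genotype_classes())  # (hom non-risk, het, hom risk)
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    return classes[rng.choice(3, size=n, p=probs)]


def _risk_indicator(ms: MarkerSim, genotypes: np.ndarray) -> np.ndarray:
    risk_hom = ms.marker.risk_allele * 2
    if ms.model is InheritanceModel.DOMINANT:
        other_hom = ms.marker.other_allele * 2
        return (genotypes != other_hom).astype(float)
    return (genotypes == risk_hom).astype(float)


def _sample_status_stratum(
    spec: SimSpec, n_cases: int, n_controls: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Rejection-sample genotype rows until both status strata are filled."""
    need = {1: n_cases, 0: n_controls}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    batch = max(256, 2 * (n_cases + n_controls))
    for _ in range(_MAX_BATCHES):
        if all(sum(len(a) for a in got[s]) >= need[s] for s in (0, 1)):
            break
        genos = np.column_stack([_draw_genotypes(ms, batch, rng) for ms in spec.markers])
        eta = spec.alpha + sum(
            ms.beta * _risk_indicator(ms, genos[:, j])
            for j, ms in enumerate(spec.markers)
        )
        status = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        for s in (0, 1):
            short = need[s] - sum(len(a) for a in got[s])
            if short > 0:
                rows = genos[status == s][:short]
                if len(rows):
                    got[s].append(rows)
    else:
        raise CohortError(
            "could not sample the requested case/control counts; "
            "check alpha/beta for a degenerate disease model"
        )
    return {
        "cases": np.vstack(got[1]) if got[1] else np.empty((0, len(spec.markers)), dtype=object),
        "controls": np.vstack(got[0]) if got[0] else np.empty((0, len(spec.markers)), dtype=object),
    }


def _assemble(
    spec: SimSpec,
    per_pop: Mapping[str, dict[str, np.ndarray]],
    matched: bool,
) -> Cohort:
    rows = []
    for pop, strata in per_pop.items():
        for status, key in ((1, "cases"), (0, "controls")):
            genos = strata[key]
            for i in range(len(genos)):
                pair = f"{pop}-p{i:05d}" if matched else None
                rows.append(
                    {
                        "subject_id": f"{pop}-{'ca' if status else 'co'}{i:05d}",
                        "population": pop,
                        "status": status,
                        "pair_id": pair,
                        **{
                            ms.marker.marker_id: genos[i, j]
                            for j, ms in enumerate(spec.markers)
                        },
                    }
                )
    cols = ["subject_id", "population", "status", "pair_id"] + [
        ms.marker.marker_id for ms in spec.markers
    ]
    df = pd.DataFrame(rows, columns=cols)
    design = {
        pop: ("matched_pairs" if matched else "unconditional") for pop in per_pop
    }
    cohort = Cohort(spec.panel, df, design)
    cohort.truth = spec  # type: ignore[attr-defined]
    return cohort


def simulate_cohort(spec: SimSpec) -> Cohort:
    """Simulate an unmatched case-control cohort from ``spec``.

    Deterministic for a fixed ``spec.rng_seed``; the spec is attached to
    the returned cohort as ``cohort.truth``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    per_pop = {
        pop: _sample_status_stratum(spec, nca, nco, rng)
        for pop, (nca, nco) in spec.populations.items()
    }
    return _assemble(spec, per_pop, matched=False)


def simulate_matched_pairs(spec: SimSpec) -> Cohort:
    """Simulate a 1:1 matched cohort: each case is paired with one control
    from the same population stratum (matching covariates themselves are
    not modelled; pairing is exchangeable within population)."""
    if spec.design != "matched_pairs":
        raise ValueError("spec.design must be 'matched_pairs'")
    for pop, (nca, nco) in spec.populations.items():
        if nca != nco:
            raise CohortError(f"{pop}: matched pairs require n_cases == n_controls")
    rng = np.random.default_rng(spec.rng_seed)
    per_pop = {
        pop: _sample_status_stratum(spec, nca, nco, rng)
        for pop, (nca, nco) in spec.populations.items()
    }
    return _assemble(spec, per_pop, matched=True)


def margin_exact_cohort(
    counts: CountTable,
    rng_seed: int = 0,
    design: Mapping[str, str] | None = None,
) -> Cohort:
    """Individual-level cohort whose per-marker genotype counts equal
    ``counts`` exactly.

    Within each (population, status) stratum, each marker's genotype
    vector is an independent seeded permutation of the exact class
    counts; the joint distribution across markers is otherwise
    uninformative because a count table constrains only margins.  Under a
    matched design, cases and controls of a population are paired in
    (arbitrary) index order.
    """
    rng = np.random.default_rng(rng_seed)
    design = dict(design or {})
    rows = []
    for pop in counts.populations:
        sizes = {s: counts.stratum_size(pop, s) for s in (1, 0)}
        matched = design.get(pop) == "matched_pairs"
        if matched and sizes[1] != sizes[0]:
            raise CohortError(f"{pop}: cannot 1:1-match {sizes[1]} cases to {sizes[0]} controls")
        for status in (1, 0):
            n = sizes[status]
            columns = {}
            for mdef in counts.panel:
                trip = counts.counts(pop, status, mdef.marker_id)
                vec = np.repeat(np.array(mdef.genotype_classes()), trip)
                rng.shuffle(vec)
                columns[mdef.marker_id] = vec
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{pop}-{'ca' if status else 'co'}{i:05d}",
                        "population": pop,
                        "status": status,
                        "pair_id": f"{pop}-p{i:05d}" if matched else None,
                        **{mid: columns[mid][i] for mid in columns},
                    }
                )
    cols = ["subject_id", "population", "status", "pair_id"] + [
        m.marker_id for m in counts.panel
    ]
    df = pd.DataFrame(rows, columns=cols)
    full_design = {
        pop: design.get(pop, "unconditional") for pop in counts.populations
    }
    return Cohort(counts.panel, df, full_design)
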