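import math

import pandas as pd
import pytest

import snpburden as sb
from snpburden.simulate import MarkerSim, SimSpec


@pytest.fixture(scope="session")
def fixture_counts():
    return sb.load_fixture()


@pytest.fixture(scope="session")
def fixture_cohort(fixture_counts):
    """Margin-exact individual-level reconstruction of the study counts."""
    return sb.margin_exact_cohort(fixture_counts, rng_seed=7, design=sb.STUDY_DESIGN)


@pytest.fixture
def toy_panel():
    return [
        sb.MarkerDef("rsA", "A", "C", "C"),
        sb.MarkerDef("rsB", "G", "T", "T"),
    ]


@pytest.fixture
def toy_cohort(toy_panel):
    """Four hand-written subjects, one missing genotype at rsA."""
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3", "s4"],
            "population": ["X"] * 4,
            "status": [1, 1, 0, 0],
            "pair_id": [None] * 4,
            "rsA": ["AC", "CC", None, "AA"],
            "rsB": ["GG", "GT", "TT", "GG"],
        }
    )
    return sb.Cohort(toy_panel, df, {"X": "unconditional"})


def null_spec(n_cases, n_controls, seed, n_markers=1, design="unconditional"):
    markers = [
        MarkerSim(
            sb.MarkerDef(f"rs{i}", "A", "C", "C"),
            0.3 + 0.05 * i,
            sb.InheritanceModel.DOMINANT,
            0.0,
        )
        for i in range(n_markers)
    ]
    return SimSpec(markers, {"Pop": (n_cases, n_controls)}, design=design, rng_seed=seed)


def effect_spec(beta, model, p, n_cases, n_controls, seed, design="unconditional"):
    mk = MarkerSim(sb.MarkerDef("rsE", "A", "G", "G"), p, model, beta)
    return SimSpec([mk], {"Pop": (n_cases, n_controls)}, design=design, rng_seed=seed)
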