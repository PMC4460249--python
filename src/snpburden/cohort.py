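"""Data model and I/O for case-control SNP genotype cohorts.

A cohort is a table of subjects (case/control status, population label,
optional 1:1 matched-pair id) with unphased genotypes at a panel of
biallelic markers.  Genotypes are unordered allele pairs stored as
two-character strings in a canonical (alphabetical) order, so ``"AC"``
and ``"CA"`` denote the same genotype; missing calls are ``None`` in
memory and ``NA`` on disk.

The on-disk dialect is plain UTF-8 TSV:

    subject_id  population  status  pair_id  <marker_1> ... <marker_k>

with ``status`` in {0, 1} (1 = case) and ``pair_id`` ``NA`` when
unmatched.  A marker panel is a four-column TSV
``marker_id  allele_a  allele_b  risk_allele``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "NA"

#: designs supported for the case-control comparison
DESIGNS = ("unconditional", "matched_pairs")


class CohortError(ValueError):
    """Raised on malformed cohort data (unknown alleles, broken pairing...)."""


@dataclass(frozen=True)
class MarkerDef:
    """A biallelic SNP with its a-priori risk allele."""

    marker_id: str
    allele_a: str
    allele_b: str
    risk_allele: str

    def __post_init__(self) -> None:
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise CohortError(
                f"{self.marker_id}: risk allele {self.risk_allele!r} is not "
                f"one of the declared alleles {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise CohortError(f"{self.marker_id}: alleles must differ")

    @property
    def other_allele(self) -> str:
        """The non-risk allele."""
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))

    def genotype_classes(self) -> tuple[str, str, str]:
        """Canonical genotype strings ordered (hom non-risk, het, hom risk)."""
        o, r = self.other_allele, self.risk_allele
        return (o + o, "".join(sorted((o, r))), r + r)

    def normalize_genotype(self, raw: str | None) -> str | None:
        """Canonicalize a genotype cell; ``None``/``NA`` stays missing."""
        if raw is None or raw in (MISSING, "") or (isinstance(raw, float) and pd.isna(raw)):
            return None
        if not isinstance(raw, str) or len(raw) != 2:
            raise CohortError(f"{self.marker_id}: malformed genotype {raw!r}")
        for a in raw:
            if a not in self.alleles:
                raise CohortError(
                    f"{self.marker_id}: allele {a!r} not in declared alleles "
                    f"{self.allele_a!r}/{self.allele_b!r}"
                )
        return "".join(sorted(raw))

    def risk_allele_count(self, genotype: str | None) -> int | None:
        if genotype is None:
            return None
        return sum(1 for a in genotype if a == self.risk_allele)


@dataclass
class Cohort:
    """Individual-level genotypes with status, population and optional pairing.

    ``data`` holds one row per subject with columns ``subject_id``,
    ``population``, ``status``, ``pair_id`` plus one column per marker
    (canonical genotype strings or ``None``).  ``design`` maps each
    population to ``"unconditional"`` or ``"matched_pairs"``.
    """

    markers: list[MarkerDef]
    data: pd.DataFrame
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["subject_id", "population", "status", "pair_id"]
        missing_cols = [c for c in required if c not in self.data.columns]
        if missing_cols:
            raise CohortError(f"cohort table lacks columns {missing_cols}")
        for m in self.markers:
            if m.marker_id not in self.data.columns:
                raise CohortError(f"no genotype column for marker {m.marker_id}")
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortError(f"duplicated subject_id {dup!r}")
        if len(df) and not df["status"].isin([0, 1]).all():
            raise CohortError("status must be 0 (control) or 1 (case)")
        for pop, dsn in self.design.items():
            if dsn not in DESIGNS:
                raise CohortError(f"unknown design {dsn!r} for {pop!r}")
            if dsn == "matched_pairs":
                self._check_pairing(pop)

    def _check_pairing(self, population: str) -> None:
        sub = self.data[self.data["population"] == population]
        if sub["pair_id"].isna().any():
            raise CohortError(f"{population}: matched_pairs design requires pair_id")
        for pid, grp in sub.groupby("pair_id"):
            if len(grp) != 2 or set(grp["status"]) != {0, 1}:
                raise CohortError(
                    f"{population}: pair {pid!r} is not one case plus one control"
                )

    # -- convenience --------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def marker(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def n_cases(self, population: str | None = None) -> int:
        df = self._pop(population)
        return int((df["status"] == 1).sum())

    def n_controls(self, population: str | None = None) -> int:
        df = self._pop(population)
        return int((df["status"] == 0).sum())

    def _pop(self, population: str | None) -> pd.DataFrame:
        if population is None:
            return self.data
        return self.data[self.data["population"] == population]

    def call_rate(self, marker_id: str) -> float:
        """Fraction of non-missing genotype calls for a marker."""
        col = self.data[marker_id]
        if len(col) == 0:
            return float("nan")
        return float(col.notna().sum() / len(col))

    def subset(self, population: str) -> "Cohort":
        df = self.data[self.data["population"] == population].reset_index(drop=True)
        dsn = {population: self.design.get(population, "unconditional")}
        return Cohort(self.markers, df, dsn)


@dataclass
class CountTable:
    """Genotype-class counts per (population, status, marker).

    Stored long: columns ``population, status, marker, genotype, count``.
    """

    panel: list[MarkerDef]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["count"] < 0).any():
            raise CohortError("negative genotype count")
        by_id = {m.marker_id: m for m in self.panel}
        self.table = self.table.assign(
            genotype=[
                by_id[m].normalize_genotype(g)
                for m, g in zip(self.table["marker"], self.table["genotype"])
            ]
        )

    def counts(self, population: str, status: int, marker_id: str) -> tuple[int, int, int]:
        """Counts ordered (hom non-risk, het, hom risk)."""
        mdef = next(m for m in self.panel if m.marker_id == marker_id)
        sub = self.table[
            (self.table["population"] == population)
            & (self.table["status"] == status)
            & (self.table["marker"] == marker_id)
        ]
        lookup = dict(zip(sub["genotype"], sub["count"]))
        return tuple(int(lookup.get(g, 0)) for g in mdef.genotype_classes())

    def stratum_size(self, population: str, status: int) -> int:
        sizes = {
            m.marker_id: sum(self.counts(population, status, m.marker_id))
            for m in self.panel
        }
        vals = set(sizes.values())
        if len(vals) > 1:
            raise CohortError(
                f"inconsistent stratum totals for ({population}, status={status}): {sizes}"
            )
        return vals.pop() if vals else 0

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def with_percent(self) -> pd.DataFrame:
        """Long table with a ``percent`` column (1 decimal, of stratum size)."""
        df = self.table.copy()
        totals = df.groupby(["population", "status", "marker"])["count"].transform("sum")
        df["percent"] = (100.0 * df["count"] / totals).round(1)
        return df

    def to_csv(self, path) -> None:
        self.with_percent().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_marker_panel(path) -> list[MarkerDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["marker_id", "allele_a", "allele_b", "risk_allele"]
    if list(df.columns) != expected:
        raise CohortError(f"panel header must be {expected}, got {list(df.columns)}")
    panel = [MarkerDef(**row) for row in df.to_dict("records")]
    ids = [m.marker_id for m in panel]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate marker_id in panel")
    return panel


def write_marker_panel(panel: Iterable[MarkerDef], path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "allele_a": m.allele_a,
                "allele_b": m.allele_b,
                "risk_allele": m.risk_allele,
            }
            for m in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genotype_table(
    path,
    panel: list[MarkerDef],
    design: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from the TSV dialect and validate it against ``panel``.

    Raises :class:`CohortError` naming the offending row/column on unknown
    alleles, duplicated subject ids, or pairing violations under a
    ``matched_pairs`` design.  Logs the per-marker call rate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["subject_id", "population", "status", "pair_id"]
    head = list(df.columns[:4])
    if head != required:
        raise CohortError(f"genotype table header must start {required}, got {head}")
    panel_ids = [m.marker_id for m in panel]
    extra = [c for c in df.columns[4:] if c not in panel_ids]
    if extra:
        raise CohortError(f"marker columns {extra} not declared in panel")
    absent = [mid for mid in panel_ids if mid not in df.columns]
    if absent:
        raise CohortError(f"panel markers {absent} missing from table")

    if len(df):
        df["status"] = df["status"].astype(int)
    else:
        df["status"] = df["status"].astype(object)
    df["pair_id"] = df["pair_id"].replace(MISSING, None)
    by_id = {m.marker_id: m for m in panel}
    for mid in panel_ids:
        try:
            df[mid] = df[mid].map(by_id[mid].normalize_genotype)
        except CohortError as err:
            raise CohortError(f"column {mid}: {err}") from err
    cohort = Cohort(panel, df, dict(design or {}))
    for mid in panel_ids:
        logger.info("call rate %s: %.4f", mid, cohort.call_rate(mid))
    return cohort


def write_genotype_table(cohort: Cohort, path) -> None:
    df = cohort.data.copy()
    df["pair_id"] = df["pair_id"].fillna(MISSING)
    for mid in cohort.marker_ids:
        df[mid] = df[mid].fillna(MISSING)
    cols = ["subject_id", "population", "status", "pair_id", *cohort.marker_ids]
    df[cols].to_csv(path, sep="\t", index=False)


def tabulate_counts(cohort: Cohort) -> CountTable:
    """Genotype-class counts per (population, status, marker).

    Missing genotypes are excluded from that marker's denominator with a
    logged warning.
    """
    if len(cohort.data) == 0:
        raise CohortError("cannot tabulate an empty cohort")
    rows = []
    for mdef in cohort.markers:
        mid = mdef.marker_id
        n_missing = int(cohort.data[mid].isna().sum())
        if n_missing:
            logger.warning("%s: %d missing genotypes excluded", mid, n_missing)
        grp = (
            cohort.data.dropna(subset=[mid])
            .groupby(["population", "status", mid], observed=True)
            .size()
        )
        for pop in cohort.populations:
            for status in (1, 0):
                for geno in mdef.genotype_classes():
                    rows.append(
                        {
                            "population": pop,
                            "status": status,
                            "marker": mid,
                            "genotype": geno,
                            "count": int(grp.get((pop, status, geno), 0)),
                        }
                    )
    return CountTable(cohort.markers, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# packaged fixture: published genotype counts of the four-population
# colorectal-cancer case-control panel (six GWAS risk SNPs)
# ---------------------------------------------------------------------------

#: the six-marker panel with a-priori risk alleles
STUDY_PANEL: list[MarkerDef] = [
    MarkerDef("rs3802842", "A", "C", "C"),
    MarkerDef("rs4464148", "T", "C", "C"),
    MarkerDef("rs4779584", "C", "T", "T"),
    MarkerDef("rs4939827", "C", "T", "T"),
    MarkerDef("rs6983267", "T", "G", "G"),
    MarkerDef("rs10795668", "A", "G", "A"),
]

#: study design per population: Estonian and Polish controls were 1:1
#: matched, Latvian and Lithuanian controls were unmatched newborns
STUDY_DESIGN: dict[str, str] = {
    "Estonia": "matched_pairs",
    "Latvia": "unconditional",
    "Lithuania": "unconditional",
    "Poland": "matched_pairs",
}


def load_fixture() -> CountTable:
    """The packaged published genotype counts (4 populations x 6 markers)."""
    with resources.files("snpburden.data").joinpath("study_genotype_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return CountTable(STUDY_PANEL, df)
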