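"""Packaged range-wide sampling table and derived presets.

The bundled CSV transcribes the range-wide O. nerka sampling table:
49 population rows (47 genotyped in the focal survey plus the two
Redfish Lake rows whose allele frequencies come from a prior study,
flagged ``prior-study``), each with waterbody, region, catchment,
migratory and reproductive ecotype, sample size and G-allele frequency.

The Tchesinkut Lake Drew Creek row is kept with its printed values
(G = 1.00 despite the stream label); field evidence suggests the lake
may not hold distinct reproductive ecotypes, so reports annotate the row
rather than excluding it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .simulate import PopulationSpec

__all__ = [
    "Table1Fixture",
    "load_table1",
    "five_system_counts",
    "table1_population_specs",
    "FIVE_SYSTEM_SHORE",
    "FIVE_SYSTEM_STREAM",
]

# The five within-lake ecotype pairs with >99% Mendelian-rule concordance:
# Okanagan, Christina, Anderson/Portage, Seton/Portage, Redfish/Fishhook.
FIVE_SYSTEM_SHORE = (
    "Okanagan Lake",
    "Christina Lake",
    "Anderson Lake",
    "Seton Lake",
    "Redfish Lake",
)
FIVE_SYSTEM_STREAM = (
    "Mission Creek",
    "Sanders Creek",
    "Portage Creek",
    "Fishhook Creek",
)

_COLUMNS = {
    "map": int,
    "waterbody": str,
    "population": str,
    "region": str,
    "catchment": str,
    "migratory_ecotype": str,
    "reproductive_ecotype": str,
    "n": int,
    "p_G": float,
    "source": str,
}

ANNOTATED_POPULATIONS = {
    "Drew Creek": "printed G frequency 1.00 in a stream-labelled row; the lake "
    "likely lacks distinct reproductive ecotypes",
}


@dataclass
class Table1Fixture:
    rows: pd.DataFrame

    @property
    def n_populations(self) -> int:
        return len(self.rows)

    @property
    def n_this_study(self) -> int:
        return int((self.rows["source"] == "this-study").sum())

    @property
    def total_sample_size(self) -> int:
        return int(self.rows["n"].sum())

    @property
    def this_study_sample_size(self) -> int:
        return int(self.rows.loc[self.rows["source"] == "this-study", "n"].sum())

    def population(self, name: str) -> pd.Series:
        hit = self.rows[self.rows["population"] == name]
        if hit.empty:
            raise KeyError(f"population not in fixture: {name!r}")
        return hit.iloc[0]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixture lacks columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if not (0.0 <= row["p_G"] <= 1.0):
            raise ValueError(f"row {i} ({row['population']}): p_G outside [0, 1]")
        if row["n"] < 1:
            raise ValueError(f"row {i} ({row['population']}): sample size not positive")
        if row["reproductive_ecotype"] not in ("shore", "stream"):
            raise ValueError(
                f"row {i} ({row['population']}): column reproductive_ecotype "
                f"has invalid value {row['reproductive_ecotype']!r}"
            )
        if row["source"] not in ("this-study", "prior-study"):
            raise ValueError(f"row {i} ({row['population']}): column source invalid")
    redfish = df[df["waterbody"] == "Redfish Lake"]
    if not (redfish["source"] == "prior-study").all():
        raise ValueError("Redfish Lake rows must carry the prior-study flag")
    return df


def load_table1(path=None) -> Table1Fixture:
    """Load and validate the packaged sampling table (or a CSV at ``path``)."""
    if path is None:
        ref = resources.files("nerkasweep").joinpath("data/table1.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype={k: v for k, v in _COLUMNS.items()})
    else:
        df = pd.read_csv(path, dtype={k: v for k, v in _COLUMNS.items()})
    return Table1Fixture(rows=_validate(df))


def five_system_counts(
    fixture: Table1Fixture,
    shore_populations: tuple[str, ...] = FIVE_SYSTEM_SHORE,
    stream_populations: tuple[str, ...] = FIVE_SYSTEM_STREAM,
) -> tuple[int, int]:
    """Pooled (shore_n, stream_n) over the named five-system populations."""
    shore_n = 0
    for name in shore_populations:
        shore_n += int(fixture.population(name)["n"])
    stream_n = 0
    for name in stream_populations:
        stream_n += int(fixture.population(name)["n"])
    return shore_n, stream_n


def table1_population_specs(fixture: Table1Fixture | None = None) -> list[PopulationSpec]:
    """PopulationSpecs for simulating genotype tables at the printed frequencies."""
    fixture = fixture or load_table1()
    return [
        PopulationSpec(
            name=row["population"],
            ecotype_label=row["reproductive_ecotype"],
            n_individuals=int(row["n"]),
            p_g=float(row["p_G"]),
        )
        for _, row in fixture.rows.iterrows()
    ]
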