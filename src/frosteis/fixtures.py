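"""Packaged reference LT50 table.

The package ships the published semi-lethal temperature (LT50) table for
pine and poplar sapwood — 2 species x 2 cooling rates x 6 moisture-content
levels x 2 freezing durations = 48 condition cells, each a mean +/- SE in
deg C.  It serves two purposes: summary statistics are recomputed from it
directly, and the synthetic study plants its ground-truth LT50 values from
it so parameter-recovery tests exercise realistic effect sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureIntegrityError

#: SHA-256 of the packaged CSV; guards against silent corruption of the
#: transcribed values.
_FIXTURE_SHA256 = "fbc8fd1c4b8f0529fd7e09dfb8cc2a0387adef1a4e713694b0a589c0a198f2dd"

_FIXTURE_NAME = "table2_lt50.csv"

N_RECORDS = 48

COOLING_RATE_LABELS = ("Slow", "Fast")
#: deg C / min behind each label.
COOLING_RATE_C_PER_MIN = {"Slow": 2.0, "Fast": 10.0}
MC_LEVELS_PCT = (200.0, 150.0, 100.0, 80.0, 30.0, 10.0)
DURATIONS_H = (0.5, 1.0)


@dataclass(frozen=True)
class LT50Record:
    """One condition cell of the reference table."""

    species: str
    cooling_rate_label: str
    moisture_content: float
    duration: float
    lt50_mean: float
    lt50_se: float

    def __post_init__(self) -> None:
        if self.lt50_mean >= 0:
            raise ValueError("lt50_mean must be negative (a freezing temperature)")
        if self.lt50_se < 0:
            raise ValueError("lt50_se must be >= 0")
        if self.cooling_rate_label not in COOLING_RATE_LABELS:
            raise ValueError(f"unknown cooling rate label {self.cooling_rate_label!r}")


def _fixture_text() -> str:
    return (
        resources.files("frosteis.data").joinpath(_FIXTURE_NAME).read_text("utf-8")
    )


def load_table2_fixture() -> list[LT50Record]:
    """Load the packaged LT50 reference table as 48 validated records.

    Raises
    ------
    FixtureIntegrityError
        If the packaged file does not match its recorded checksum or does
        not contain exactly 48 records.
    """
    text = _fixture_text()
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"packaged LT50 table checksum mismatch ({digest[:12]}...)"
        )
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("species,"):
            continue
        sp, rate, mc, dur, mean, se = [p.strip() for p in line.split(",")]
        records.append(
            LT50Record(
                species=sp,
                cooling_rate_label=rate,
                moisture_content=float(mc),
                duration=float(dur),
                lt50_mean=float(mean),
                lt50_se=float(se),
            )
        )
    if len(records) != N_RECORDS:
        raise FixtureIntegrityError(
            f"expected {N_RECORDS} records, found {len(records)}"
        )
    return records


def table2_dataframe() -> pd.DataFrame:
    """The reference table as a DataFrame (one row per condition cell)."""
    recs = load_table2_fixture()
    return pd.DataFrame(
        {
            "species": [r.species for r in recs],
            "cooling_rate_label": [r.cooling_rate_label for r in recs],
            "mc_pct": [r.moisture_content for r in recs],
            "duration_h": [r.duration for r in recs],
            "lt50_c": [r.lt50_mean for r in recs],
            "lt50_se_c": [r.lt50_se for r in recs],
        }
    )


def lookup_lt50(
    species: str, cooling_rate_label: str, mc_pct: float, duration_h: float
) -> LT50Record:
    """Return the record for one condition cell; KeyError if absent."""
    for r in load_table2_fixture():
        if (
            r.species == species
            and r.cooling_rate_label == cooling_rate_label
            and r.moisture_content == mc_pct
            and r.duration == duration_h
        ):
            return r
    raise KeyError(
        f"no LT50 record for ({species}, {cooling_rate_label}, {mc_pct}%, {duration_h} h)"
    )
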