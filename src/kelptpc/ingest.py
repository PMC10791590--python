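"""Derive physiological response variables from raw chamber measurements.

Raw inputs are per-individual tables from a factorial CO2 x temperature
culture experiment: hole-punch distances on day 1 and day 21 (linear blade
extension), wet weights (percentage weight change), and oxygen
concentrations at the start and end of a 3 h sealed-chamber incubation
(net photosynthesis, blank-corrected and normalised to wet weight).
Individuals with negative net photosynthesis AND substantial tissue loss
are flagged dead and excluded from net-photosynthesis datasets only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, SchemaError

CO2_LEVELS = ("current", "future")
RESPONSES = ("growth", "net_photosynthesis", "weight_change_pct", "d13c")

RESPONSE_UNITS = {
    "growth": "mm day^-1",
    "net_photosynthesis": "umol O2 g^-1 h^-1",
    "weight_change_pct": "%",
    "d13c": "permil",
}

#: responses for which a fitted curve predicting negative values is
#: biologically non-sensical (blade extension cannot run backwards at the
#: population level; weight loss and net O2 consumption are physical)
NON_NEGATIVE_RESPONSES = frozenset({"growth"})

#: responses where negative values are physical, so model curves keep their
#: negative branch beyond critical limits instead of being truncated to zero
NEGATIVE_ALLOWED_RESPONSES = frozenset({"net_photosynthesis", "weight_change_pct", "d13c"})

EXPERIMENT_COLUMNS = [
    "individual_id", "temp_treatment_c", "co2_level",
    "hole_dist_d1_mm", "hole_dist_d21_mm",
    "wet_wt_d1_g", "wet_wt_d21_g",
    "o2_t0_umol_l", "o2_t3_umol_l",
    "d13c_permil", "pct_c", "pct_n",
]
OPTIONAL_COLUMNS = {"d13c_permil", "pct_c", "pct_n"}
BLANK_COLUMNS = ["temp_treatment_c", "co2_level", "o2_delta_umol_l"]


@dataclass(frozen=True)
class IngestConfig:
    """Constants used when deriving rates from raw measurements.

    elapsed_days: interval between the day-1 and day-21 photographs/weighings.
    tissue_loss_threshold_pct: weight change at or below which tissue loss
        counts as "substantial" for the mortality rule.
    chamber_vol_l: incubation chamber volume (260 ml glass chambers).
    incubation_hours: sealed-chamber incubation duration.
    """

    elapsed_days: float = 20.0
    tissue_loss_threshold_pct: float = -50.0
    chamber_vol_l: float = 0.26
    incubation_hours: float = 3.0


@dataclass
class ResponseDataset:
    """(temperature, value) observations for one response at one CO2 level."""

    response: str
    co2_level: str
    temps_c: np.ndarray
    values: np.ndarray
    individual_ids: list[str]
    units: str = ""

    def __post_init__(self) -> None:
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temps_c.shape != self.values.shape:
            raise ValueError("temps and values must have equal length")
        if np.unique(self.temps_c).size < 2:
            raise ValueError("a response dataset needs >= 2 distinct temperatures")
        if not self.units:
            self.units = RESPONSE_UNITS.get(self.response, "")

    @property
    def n(self) -> int:
        return int(self.temps_c.size)


# ---------------------------------------------------------------------------
# elementary derivations
# ---------------------------------------------------------------------------

def linear_extension(hole_d1_mm: float, hole_d21_mm: float, elapsed_days: float) -> float:
    """Blade linear extension, mm/day: hole displacement over the interval.

    Negative values (measurement noise, erosion past the hole) are retained.
    """
    if elapsed_days <= 0:
        raise InvalidInputError(f"elapsed_days must be > 0, got {elapsed_days}")
    return (hole_d21_mm - hole_d1_mm) / elapsed_days


def weight_change_pct(wt_d1_g: float, wt_d21_g: float) -> float:
    """Percentage change in wet weight from the day-1 weight."""
    if wt_d1_g <= 0:
        raise InvalidInputError(f"initial weight must be > 0, got {wt_d1_g}")
    return 100.0 * (wt_d21_g - wt_d1_g) / wt_d1_g


def net_photosynthesis(
    o2_t0_umol_l: float,
    o2_t3_umol_l: float,
    blank_deltas_umol_l: Sequence[float],
    chamber_vol_l: float,
    wet_wt_g: float,
    hours: float,
) -> float:
    """Blank-corrected net photosynthesis, umol O2 per g wet weight per hour.

    The mean O2 drift of alga-free blank chambers is subtracted from the
    sample's O2 change before scaling by chamber volume and normalising to
    incubation time and wet weight; net O2 consumption gives a negative rate.
    """
    if wet_wt_g <= 0:
        raise InvalidInputError(f"wet weight must be > 0, got {wet_wt_g}")
    if hours <= 0:
        raise InvalidInputError(f"hours must be > 0, got {hours}")
    if chamber_vol_l <= 0:
        raise InvalidInputError(f"chamber volume must be > 0, got {chamber_vol_l}")
    blanks = np.asarray(blank_deltas_umol_l, dtype=float)
    if blanks.size == 0:
        raise InvalidInputError("blank_deltas must be non-empty")
    corrected = (o2_t3_umol_l - o2_t0_umol_l) - blanks.mean()
    return corrected * chamber_vol_l / (hours * wet_wt_g)


def flag_mortality(
    np_rate: float,
    weight_change: float,
    tissue_loss_threshold_pct: float = -50.0,
) -> bool:
    """Dead iff net photosynthesis is negative AND weight change is at or
    below the tissue-loss threshold — both conditions are required."""
    if not (np.isfinite(np_rate) and np.isfinite(weight_change)):
        raise InvalidInputError("mortality flag needs finite inputs")
    return bool(np_rate < 0 and weight_change <= tissue_loss_threshold_pct)


# ---------------------------------------------------------------------------
# table validation and dataset assembly
# ---------------------------------------------------------------------------

def _validate_experiment(df: pd.DataFrame) -> None:
    missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns and c not in OPTIONAL_COLUMNS]
    if missing:
        raise SchemaError(f"experiment table missing columns: {missing}")
    if df.empty:
        raise SchemaError("experiment table is empty")
    problems: list[str] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1 in the CSV
        if row["co2_level"] not in CO2_LEVELS:
            problems.append(f"row {rowno}: co2_level {row['co2_level']!r} not in {CO2_LEVELS}")
        numeric = [
            "temp_treatment_c", "hole_dist_d1_mm", "hole_dist_d21_mm",
            "wet_wt_d1_g", "wet_wt_d21_g", "o2_t0_umol_l", "o2_t3_umol_l",
        ]
        vals = {}
        for c in numeric:
            try:
                vals[c] = float(row[c])
            except (TypeError, ValueError):
                problems.append(f"row {rowno}: {c} is not numeric ({row[c]!r})")
        if len(vals) == len(numeric):
            if not 0.0 <= vals["temp_treatment_c"] <= 35.0:
                problems.append(f"row {rowno}: temperature {vals['temp_treatment_c']} outside [0, 35]")
            if vals["wet_wt_d1_g"] <= 0 or vals["wet_wt_d21_g"] <= 0:
                problems.append(f"row {rowno}: non-positive wet weight")
            if vals["hole_dist_d1_mm"] < 0 or vals["hole_dist_d21_mm"] < 0:
                problems.append(f"row {rowno}: negative hole distance")
    if problems:
        raise SchemaError("experiment table validation failed:\n" + "\n".join(problems))


def blank_lookup(blanks: pd.DataFrame) -> dict[tuple[float, str], np.ndarray]:
    """Group the long-format blank table into per-treatment O2 drift triplets."""
    missing = [c for c in BLANK_COLUMNS if c not in blanks.columns]
    if missing:
        raise SchemaError(f"blank table missing columns: {missing}")
    out: dict[tuple[float, str], np.ndarray] = {}
    for (t, co2), grp in blanks.groupby(["temp_treatment_c", "co2_level"]):
        deltas = grp["o2_delta_umol_l"].to_numpy(dtype=float)
        if deltas.size != 3:
            raise SchemaError(
                f"treatment ({t} C, {co2}): expected exactly 3 blanks, got {deltas.size}"
            )
        out[(round(float(t), 6), str(co2))] = deltas
    return out


def derive_responses(
    records: pd.DataFrame,
    blanks: pd.DataFrame,
    config: IngestConfig | None = None,
) -> pd.DataFrame:
    """Per-individual derived responses with mortality flags.

    Returns a long-format table (response, co2_level, temperature, value,
    individual_id, excluded_flag); excluded_flag is True only on
    net-photosynthesis rows of flagged-dead individuals.
    """
    config = config or IngestConfig()
    _validate_experiment(records)
    lookup = blank_lookup(blanks)

    rows = []
    for _, rec in records.iterrows():
        temp = float(rec["temp_treatment_c"])
        co2 = str(rec["co2_level"])
        key = (round(temp, 6), co2)
        if key not in lookup:
            raise ConfigurationError(
                f"no blank chambers for treatment ({temp} C, {co2})"
            )
        growth = linear_extension(
            float(rec["hole_dist_d1_mm"]), float(rec["hole_dist_d21_mm"]),
            config.elapsed_days,
        )
        wchange = weight_change_pct(float(rec["wet_wt_d1_g"]), float(rec["wet_wt_d21_g"]))
        # normalised to the day-21 wet weight: the incubation is run on day 21
        nprate = net_photosynthesis(
            float(rec["o2_t0_umol_l"]), float(rec["o2_t3_umol_l"]), lookup[key],
            config.chamber_vol_l, float(rec["wet_wt_d21_g"]), config.incubation_hours,
        )
        dead = flag_mortality(nprate, wchange, config.tissue_loss_threshold_pct)
        iid = str(rec["individual_id"])
        rows.append(("growth", co2, temp, growth, iid, False))
        rows.append(("weight_change_pct", co2, temp, wchange, iid, False))
        rows.append(("net_photosynthesis", co2, temp, nprate, iid, dead))
        if "d13c_permil" in rec.index and pd.notna(rec["d13c_permil"]):
            rows.append(("d13c", co2, temp, float(rec["d13c_permil"]), iid, False))
    return pd.DataFrame(
        rows,
        columns=["response", "co2_level", "temperature", "value",
                 "individual_id", "excluded_flag"],
    )


def build_response_datasets(
    records: pd.DataFrame,
    blanks: pd.DataFrame,
    config: IngestConfig | None = None,
) -> list[ResponseDataset]:
    """One ResponseDataset per response x CO2 level.

    Flagged-dead individuals are dropped from net-photosynthesis datasets
    only; growth and weight-change datasets keep every individual.
    """
    table = derive_responses(records, blanks, config)
    datasets = []
    for response in RESPONSES:
        for co2 in CO2_LEVELS:
            sub = table[(table["response"] == response) & (table["co2_level"] == co2)]
            sub = sub[~sub["excluded_flag"]]
            if sub.empty:
                continue
            datasets.append(
                ResponseDataset(
                    response=response,
                    co2_level=co2,
                    temps_c=sub["temperature"].to_numpy(),
                    values=sub["value"].to_numpy(),
                    individual_ids=list(sub["individual_id"]),
                )
            )
    return datasets


def read_experiment_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def read_blanks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
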