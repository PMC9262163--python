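"""Reading and writing the tabular inputs and outputs of the pipeline.

All on-disk formats are plain CSV with fixed, documented column names:

``individuals.csv``
    ``id, sex, birth_date`` — one row per individual; ``sex`` is ``F`` or ``M``
    (immatures are identified by age, not by a separate code); dates ISO-8601.
``membership.csv``
    ``id, group, entry, exit`` — group-residence intervals, non-overlapping
    per individual.
``follows.csv``
    ``follow_id, focal, group, start, duration_min`` — 10-minute focal follows.
``grooming.csv``
    ``follow_id, groomer, groomee, time`` — grooming events tied to a follow.
``aggression.csv``
    ``time, group, aggressor, target`` — time-stamped aggressive acts.
``scans.csv``
    ``scan_id, time, group, subject, activity`` — instantaneous group scans.
``scan_neighbors.csv``
    ``scan_id, neighbor, distance_bl`` — neighbors within 10 body lengths of
    the scan subject.
``covariates.csv``
    ``id, year, rank, group_size, group`` — annual female covariates; rank in
    [0, 1] with 1 the highest rank.
``demography.csv``
    ``id, death_date, censor_date`` — at most one of the two dates set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_DATE_COLS = {
    "individuals": ["birth_date"],
    "membership": ["entry", "exit"],
    "follows": ["start"],
    "grooming": ["time"],
    "aggression": ["time"],
    "scans": ["time"],
    "scan_neighbors": [],
    "covariates": [],
    "demography": ["death_date", "censor_date"],
}

REQUIRED_COLUMNS = {
    "individuals": ["id", "sex", "birth_date"],
    "membership": ["id", "group", "entry", "exit"],
    "follows": ["follow_id", "focal", "group", "start", "duration_min"],
    "grooming": ["follow_id", "groomer", "groomee", "time"],
    "aggression": ["time", "group", "aggressor", "target"],
    "scans": ["scan_id", "time", "group", "subject", "activity"],
    "scan_neighbors": ["scan_id", "neighbor", "distance_bl"],
    "covariates": ["id", "year", "rank", "group_size", "group"],
    "demography": ["id", "death_date", "censor_date"],
}


@dataclass
class EventBundle:
    """The full set of input tables for one study (real or simulated)."""

    individuals: pd.DataFrame
    membership: pd.DataFrame
    follows: pd.DataFrame
    grooming: pd.DataFrame
    aggression: pd.DataFrame
    scans: pd.DataFrame
    scan_neighbors: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    demography: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        """Check referential integrity and the documented invariants."""
        ind = self.individuals
        if ind["id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        known = set(ind["id"])
        for name, cols in [
            ("membership", ["id"]),
            ("follows", ["focal"]),
            ("grooming", ["groomer", "groomee"]),
            ("aggression", ["aggressor", "target"]),
            ("scans", ["subject"]),
        ]:
            df = getattr(self, name)
            for col in cols:
                unknown = set(df[col]) - known
                if unknown:
                    raise ValueError(
                        f"{name}.{col} references unknown ids: {sorted(unknown)[:5]}"
                    )
        mem = self.membership.sort_values(["id", "entry"])
        if (mem["exit"] < mem["entry"]).any():
            raise ValueError("membership interval with exit < entry")
        by_id = mem.groupby("id")
        for iid, g in by_id:
            if (g["entry"].values[1:] < g["exit"].values[:-1]).any():
                raise ValueError(f"overlapping membership intervals for {iid}")
        if (self.grooming["groomer"] == self.grooming["groomee"]).any():
            raise ValueError("self-grooming event")
        if (self.aggression["aggressor"] == self.aggression["target"]).any():
            raise ValueError("self-directed aggression event")


def _read_csv(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS[table]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in _DATE_COLS[table]:
        df[col] = pd.to_datetime(df[col])
    return df


def read_bundle(events_dir: str | Path) -> EventBundle:
    """Load a full input bundle from a directory of CSVs."""
    d = Path(events_dir)
    tables = {}
    for name in REQUIRED_COLUMNS:
        path = d / f"{name}.csv"
        if path.exists():
            tables[name] = _read_csv(path, name)
        elif name in ("covariates", "demography"):
            tables[name] = pd.DataFrame(columns=REQUIRED_COLUMNS[name])
        else:
            raise FileNotFoundError(f"required input table not found: {path}")
    return EventBundle(**tables)


def write_bundle(bundle: EventBundle, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name in REQUIRED_COLUMNS:
        df = getattr(bundle, name)
        df.to_csv(d / f"{name}.csv", index=False)


def write_table(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.10g") -> None:
    """Write a result table with a fixed float format so reruns are byte-identical."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_fmt)
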