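"""Delimited-text readers and writers for the interchange tables.

All artifacts are plain CSV/TSV: animals, bouts, feeding events
(ISO-8601 timestamps), weights, hierarchy assignments, genus abundance
(genera x samples TSV, a BIOM-style ``#OTU ID`` header is tolerated on
read) and sample metadata.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ANIMAL_COLUMNS = ["animal_id", "sex", "pen_id", "treatment", "latent_ability"]
BOUT_COLUMNS = ["pen_id", "phase", "day", "animal_a", "animal_b", "outcome", "winner", "confirmed"]
EVENT_COLUMNS = ["animal_id", "start_time", "duration_s", "intake_g"]
WEIGHT_COLUMNS = ["animal_id", "day", "weight_kg"]
HIERARCHY_COLUMNS = ["animal_id", "pen_id", "class", "ranking_score"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_animals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ANIMAL_COLUMNS, "animals table")
    return df


def write_animals(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_bouts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, BOUT_COLUMNS, "bouts table")
    df["winner"] = df["winner"].where(df["winner"].notna(), None)
    df["confirmed"] = df["confirmed"].astype(bool)
    return df


def write_bouts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feeding_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start_time"])
    _require(df, EVENT_COLUMNS, "feeding events table")
    return df


def write_feeding_events(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start_time"] = pd.to_datetime(out["start_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, WEIGHT_COLUMNS, "weights table")
    return df


def write_weights(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Genus abundance TSV (genera rows x sample columns, integer counts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "genus"
    return df.astype(int)


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "genus")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["sample_id"], "sample metadata")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_hierarchy(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["animal_id", "class"], "hierarchy table")
    return df
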