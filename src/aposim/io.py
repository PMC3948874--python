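"""CSV serialization of run time series.

The on-disk format is a tidy long table with columns
``update, class, abundance, displayed_as, count, replicate, treatment, seed``
preceded by comment lines (``#``) echoing each replicate's configuration as
JSON, so every file is self-describing.  Abundance rows (three prey classes
plus ``predator``) leave ``displayed_as``/``count`` empty; display rows
(mimic-class organisms by displayed class) leave ``abundance`` empty.
Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import RunRecord
from .world import CLASS_NAMES

COLUMNS = ["update", "class", "abundance", "displayed_as", "count",
           "replicate", "treatment", "seed"]


def records_to_frame(records: list[RunRecord]) -> pd.DataFrame:
    frames = []
    for rep, rec in enumerate(records):
        df = rec.to_frame()
        df["replicate"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def write_run_csv(records: list[RunRecord] | RunRecord, path: str | Path) -> None:
    """Write one or more run records as a tidy CSV with config-echo header."""
    if isinstance(records, RunRecord):
        records = [records]
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for rep, rec in enumerate(records):
            fh.write(f"# config[{rep}]: {json.dumps(rec.config, sort_keys=True)}\n")
        records_to_frame(records).to_csv(fh, index=False)


def read_run_csv(path: str | Path) -> list[RunRecord]:
    """Read a tidy run CSV back into :class:`RunRecord` objects (inverse of
    :func:`write_run_csv`)."""
    path = Path(path)
    configs: dict[int, dict] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, payload = line[1:].partition(":")
            key = key.strip()
            if key.startswith("config[") and key.endswith("]"):
                configs[int(key[7:-1])] = json.loads(payload)
    try:
        df = pd.read_csv(path, skiprows=header_lines,
                         dtype={"class": str, "displayed_as": str})
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from None
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks column(s): {', '.join(sorted(missing))}")
    df["displayed_as"] = df["displayed_as"].fillna("")
    return frame_to_records(df, configs)


def frame_to_records(df: pd.DataFrame, configs: dict[int, dict] | None = None) -> list[RunRecord]:
    """Rebuild records from a tidy frame (tolerates shuffled row order)."""
    configs = configs or {}
    out = []
    for rep, g in df.groupby("replicate", sort=True):
        updates = np.sort(g["update"].unique()).astype(np.int64)
        index = {u: t for t, u in enumerate(updates)}
        n = len(updates)
        abundance = np.zeros((n, 3), dtype=np.int64)
        predators = np.zeros(n, dtype=np.int64)
        displays = np.zeros((n, 3), dtype=np.int64)
        cls_idx = {name: c for c, name in enumerate(CLASS_NAMES)}
        cols = zip(g["update"].to_numpy(), g["class"].to_numpy(),
                   g["abundance"].to_numpy(), g["displayed_as"].to_numpy(),
                   g["count"].to_numpy())
        for upd, cls, ab, disp_as, cnt in cols:
            t = index[upd]
            if disp_as:
                displays[t, cls_idx[disp_as]] = int(cnt)
            elif cls == "predator":
                predators[t] = int(ab)
            else:
                abundance[t, cls_idx[cls]] = int(ab)
        out.append(RunRecord(
            treatment=str(g["treatment"].iloc[0]), seed=int(g["seed"].iloc[0]),
            updates=updates, abundance=abundance, predators=predators,
            displays=displays, config=configs.get(int(rep), {}),
        ))
    return out
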