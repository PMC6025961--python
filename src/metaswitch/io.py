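"""File dialects: lineage TSV, environment CSV, snapshot CSV (long format),
metabolite CSV (long format) and YAML/JSON scenario configs.

All round trips are lossless for the declared columns; unknown columns are
preserved on read.  Line endings (LF/CRLF) are normalised by the parsers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import yaml

from .metabolites import MetaboliteSeries
from .params import ScenarioConfig, SwitchParams, default_params
from .snapshots import SnapshotSample

__all__ = [
    "write_lineage", "read_lineage",
    "write_environment", "read_environment",
    "write_snapshots", "read_snapshots",
    "write_metabolites", "read_metabolites",
    "write_events", "read_events",
    "read_config", "write_config",
]

LINEAGE_COLUMNS = ["cell_id", "parent_id", "channel_id", "frame", "t_min",
                   "length_um", "f_sucC", "f_alsS", "state_sucC",
                   "state_alsS", "fate"]
ENV_COLUMNS = ["t_min", "biomass", "glucose_mM", "malate_mM", "acetate_mM",
               "acetoin_mM"]
SNAPSHOT_COLUMNS = ["t_min", "od", "reporter", "value"]
METABOLITE_COLUMNS = ["t_min", "analyte", "concentration_mM"]


def _require(df: pd.DataFrame, columns: List[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): "
                         + ", ".join(missing))


def write_lineage(lineage: pd.DataFrame, path) -> None:
    _require(lineage, LINEAGE_COLUMNS, "lineage table")
    lineage.to_csv(path, sep="\t", index=False)


def read_lineage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, LINEAGE_COLUMNS, path)
    return df


def write_environment(env: pd.DataFrame, path) -> None:
    _require(env, ENV_COLUMNS, "environment trajectory")
    env.to_csv(path, index=False)


def read_environment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ENV_COLUMNS, path)
    return df


def write_snapshots(samples: List[SnapshotSample], path) -> None:
    frames = []
    for s in samples:
        frames.append(pd.DataFrame({
            "t_min": s.t, "od": s.od, "reporter": s.reporter_name,
            "value": s.values}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_snapshots(path) -> List[SnapshotSample]:
    df = pd.read_csv(path)
    _require(df, SNAPSHOT_COLUMNS, path)
    out = []
    for (t, od, rep), sub in df.groupby(["t_min", "od", "reporter"], sort=True):
        out.append(SnapshotSample(t=float(t), od=float(od),
                                  values=sub["value"].to_numpy(dtype=float),
                                  reporter_name=str(rep)))
    out.sort(key=lambda s: (s.t, s.reporter_name))
    return out


def write_metabolites(series: List[MetaboliteSeries], path) -> None:
    frames = [pd.DataFrame({"t_min": s.t, "analyte": s.analyte,
                            "concentration_mM": s.concentration})
              for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_metabolites(path) -> List[MetaboliteSeries]:
    df = pd.read_csv(path)
    _require(df, METABOLITE_COLUMNS, path)
    out = []
    for analyte, sub in df.groupby("analyte", sort=True):
        sub = sub.sort_values("t_min")
        out.append(MetaboliteSeries(t=sub["t_min"].to_numpy(dtype=float),
                                    concentration=sub["concentration_mM"].to_numpy(dtype=float),
                                    analyte=str(analyte)))
    return out


def environment_to_series(env: pd.DataFrame) -> List[MetaboliteSeries]:
    """Split an environment trajectory into per-analyte series."""
    t = env["t_min"].to_numpy(dtype=float)
    return [MetaboliteSeries(t=t, concentration=env[col].to_numpy(dtype=float),
                             analyte=name)
            for name, col in (("glucose", "glucose_mM"), ("malate", "malate_mM"),
                              ("acetate", "acetate_mM"), ("acetoin", "acetoin_mM"))]


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path) -> tuple[SwitchParams, ScenarioConfig]:
    """Load a scenario config (YAML or JSON).

    Layout: an optional ``switch_params`` mapping of parameter overrides
    and a ``scenario`` mapping with :class:`ScenarioConfig` fields.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "scenario" not in data:
        raise ValueError(f"{path}: config must contain a 'scenario' mapping")
    params = default_params(**data.get("switch_params", {}))
    config = ScenarioConfig(**data["scenario"])
    return params, config


def write_config(params: SwitchParams, config: ScenarioConfig, path) -> None:
    path = Path(path)
    data = {"switch_params": params.to_dict(), "scenario": config.to_dict()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
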