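"""Plain-text interchange formats (CSV with header, UTF-8, '.' decimal).

Trajectory CSV    time_s, fish_id, x_bl, y_bl
Bout CSV          fish_id, bout_index, start_frame, end_frame, L_bl, theta_deg
Flake CSV         flake_id, x_bl, y_bl, t_appear_s, t_consumed_s, parent_flake_id
Event CSV         fish_id, time_s, x_bl, y_bl, kind
Record CSV        tick, fish_id, x_bl, y_bl, heading_deg, event
Fit-surface CSV   model, df, dn, e_cons, e_pol, e_dnn, e_combined, is_best
Config YAML       mirrors SimulationConfig field names
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environments import FlakeField
from .kinematics import TrajectoryRecording
from .simulate import SimulationConfig, SimulationRecord


def write_trajectory_csv(rec: TrajectoryRecording, path) -> None:
    rows = []
    for j in range(rec.n_fish):
        rows.append(pd.DataFrame({
            "time_s": rec.times, "fish_id": j,
            "x_bl": rec.positions[:, j, 0], "y_bl": rec.positions[:, j, 1],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path, arena_radius: float | None = None) -> TrajectoryRecording:
    df = pd.read_csv(path)
    required = {"time_s", "fish_id", "x_bl", "y_bl"}
    if missing := required - set(df.columns):
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    fish = np.sort(df["fish_id"].unique())
    times = np.sort(df["time_s"].unique())
    pos = np.full((times.size, fish.size, 2), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    f_index = {f: i for i, f in enumerate(fish)}
    for _, row in df.iterrows():
        pos[t_index[row["time_s"]], f_index[row["fish_id"]]] = (row["x_bl"], row["y_bl"])
    kwargs = {} if arena_radius is None else {"arena_radius": arena_radius}
    return TrajectoryRecording(times=times, positions=pos, **kwargs)


def write_bouts_csv(bout_sequences, path) -> None:
    rows = []
    for bouts in bout_sequences:
        for i in range(len(bouts)):
            rows.append({
                "fish_id": bouts.fish_id, "bout_index": i,
                "start_frame": int(bouts.start_frames[i]),
                "end_frame": int(bouts.end_frames[i]),
                "L_bl": bouts.lengths[i], "theta_deg": bouts.thetas[i],
            })
    pd.DataFrame(rows, columns=["fish_id", "bout_index", "start_frame",
                                "end_frame", "L_bl", "theta_deg"]).to_csv(path, index=False)


def write_flakes_csv(field: FlakeField, path) -> None:
    df = pd.DataFrame({
        "flake_id": np.arange(field.n_flakes),
        "x_bl": field.x, "y_bl": field.y,
        "t_appear_s": field.t_appear,
        "t_consumed_s": field.t_consumed,
        "parent_flake_id": [p if p >= 0 else None for p in field.parent],
    })
    df.to_csv(path, index=False)


def read_flakes_csv(path, arena_radius: float | None = None) -> FlakeField:
    df = pd.read_csv(path)
    parent = df["parent_flake_id"].fillna(-1).astype(int).to_numpy() \
        if "parent_flake_id" in df else None
    kwargs = {} if arena_radius is None else {"arena_radius": arena_radius}
    return FlakeField(
        x=df["x_bl"].to_numpy(), y=df["y_bl"].to_numpy(),
        t_appear=df.get("t_appear_s", pd.Series(np.zeros(len(df)))).fillna(0).to_numpy(),
        t_consumed=df.get("t_consumed_s", pd.Series(np.full(len(df), np.nan))).to_numpy(),
        parent=parent, **kwargs,
    )


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_record_csv(record: SimulationRecord, path) -> None:
    if record.positions is None:
        raise ValueError("record was run without trajectory recording")
    consum = {(c.tick, c.agent): c for c in record.consumptions}
    rows = []
    for t in range(record.positions.shape[0]):
        for j in range(record.config.k):
            c = consum.get((t, j))
            rows.append({
                "tick": t, "fish_id": j,
                "x_bl": record.positions[t, j, 0],
                "y_bl": record.positions[t, j, 1],
                "heading_deg": math.degrees(math.atan2(
                    record.headings[t, j, 1], record.headings[t, j, 0])),
                "event": f"consume:{c.flake}" if c else "none",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_surface_csv(surface, path) -> None:
    out = surface.table.copy()
    out.insert(0, "model", surface.model)
    cols = ["model", "df", "dn", "e_cons", "e_pol", "e_dnn", "e_combined", "is_best"]
    out[cols].to_csv(path, index=False)


def save_config_yaml(config: SimulationConfig, path) -> None:
    data = asdict(config)
    for key in ("step_dists", "initial_positions"):
        value = data.pop(key, None)
        if key == "initial_positions" and value is not None:
            data[key] = np.asarray(value).tolist()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config_yaml(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if data.get("initial_positions") is not None:
        data["initial_positions"] = np.asarray(data["initial_positions"], dtype=float)
    return SimulationConfig(**data)
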