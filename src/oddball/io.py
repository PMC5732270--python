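"""File schemas: spike-event tables, LFP tables, and config round trips.

Interchange is plain CSV at desk scale.  Spike events are one row per
spike; a companion trials table carries every trial (including zero-spike
trials) with its sequence position, tone, and deviant flag, so rasters
round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .response import TrialRaster
from .simulate import SimulatedRecording

__all__ = [
    "SPIKE_COLUMNS",
    "TRIAL_COLUMNS",
    "recordings_to_tables",
    "tables_to_recordings",
    "write_events",
    "read_events",
    "write_lfp",
    "read_lfp",
]

SPIKE_COLUMNS = [
    "neuron_id",
    "station",
    "nucleus",
    "hierarchy",
    "sequence_id",
    "condition",
    "position",
    "tone_index",
    "spike_time_ms",
]

TRIAL_COLUMNS = [
    "neuron_id",
    "station",
    "sequence_id",
    "condition",
    "position",
    "tone_index",
    "is_deviant",
]


def _raster_items(rec: SimulatedRecording | dict[str, TrialRaster]):
    rasters = rec.rasters if isinstance(rec, SimulatedRecording) else rec
    return rasters.items()


def recordings_to_tables(
    recordings: list[SimulatedRecording | dict[str, TrialRaster]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten recordings into (spikes, trials) tables."""
    spike_rows, trial_rows = [], []
    for rec in recordings:
        for seq_id, raster in _raster_items(rec):
            station = raster.station or ""
            nucleus, _, hierarchy = station.partition("_")
            pos = (
                raster.positions
                if raster.positions is not None
                else np.arange(raster.n_trials)
            )
            tones = raster.tone_indices
            devs = raster.is_deviant
            for i, trial in enumerate(raster.trials):
                tone = int(tones[i]) if tones is not None else (raster.tone_index or 0)
                trial_rows.append(
                    (
                        raster.neuron_id,
                        station,
                        seq_id,
                        raster.condition,
                        int(pos[i]),
                        tone,
                        int(bool(devs[i])) if devs is not None else 0,
                    )
                )
                for t in trial:
                    spike_rows.append(
                        (
                            raster.neuron_id,
                            station,
                            nucleus,
                            hierarchy,
                            seq_id,
                            raster.condition,
                            int(pos[i]),
                            tone,
                            float(t),
                        )
                    )
    spikes = pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS)
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    return spikes, trials


def write_events(
    recordings: list[SimulatedRecording | dict[str, TrialRaster]],
    spikes_path: str | Path,
    trials_path: str | Path,
) -> None:
    spikes, trials = recordings_to_tables(recordings)
    spikes.to_csv(spikes_path, index=False)
    trials.to_csv(trials_path, index=False)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings

        warnings.warn(f"{what} table has unknown columns {extra}; ignored")


def tables_to_recordings(
    spikes: pd.DataFrame, trials: pd.DataFrame
) -> list[dict[str, TrialRaster]]:
    """Rebuild per-neuron raster dictionaries from the two tables."""
    _check_columns(trials, TRIAL_COLUMNS, "trials")
    _check_columns(spikes, SPIKE_COLUMNS, "spikes")
    bad = spikes.index[pd.to_numeric(spikes["spike_time_ms"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"malformed spike_time_ms in rows {list(bad[:5])}")
    spikes = spikes.assign(spike_time_ms=spikes["spike_time_ms"].astype(float))

    out: list[dict[str, TrialRaster]] = []
    spike_groups = {
        k: g for k, g in spikes.groupby(["neuron_id", "sequence_id"], sort=False)
    }
    for nid, neuron_trials in trials.groupby("neuron_id", sort=False):
        rasters: dict[str, TrialRaster] = {}
        for seq_id, seq_trials in neuron_trials.groupby("sequence_id", sort=False):
            seq_trials = seq_trials.sort_values("position")
            sg = spike_groups.get((nid, seq_id))
            by_pos: dict[int, np.ndarray] = {}
            if sg is not None:
                for p, g in sg.groupby("position", sort=False):
                    by_pos[int(p)] = np.sort(g["spike_time_ms"].to_numpy())
            trials_list = [
                by_pos.get(int(p), np.empty(0)) for p in seq_trials["position"]
            ]
            rasters[str(seq_id)] = TrialRaster(
                trials=trials_list,
                neuron_id=nid,
                station=str(seq_trials["station"].iloc[0]),
                condition=str(seq_trials["condition"].iloc[0]),
                positions=seq_trials["position"].to_numpy(dtype=int),
                is_deviant=seq_trials["is_deviant"].to_numpy().astype(bool),
                tone_indices=seq_trials["tone_index"].to_numpy(dtype=int),
            )
        out.append(rasters)
    return out


def read_events(
    spikes_path: str | Path, trials_path: str | Path
) -> list[dict[str, TrialRaster]]:
    return tables_to_recordings(pd.read_csv(spikes_path), pd.read_csv(trials_path))


LFP_COLUMNS = ["site_id", "condition", "trial", "time_ms", "voltage"]


def write_lfp(
    path: str | Path,
    time_ms: np.ndarray,
    traces: dict[tuple[str, str], np.ndarray],
) -> None:
    """Write per-trial LFP traces keyed by (site_id, condition)."""
    rows = []
    for (site, cond), arr in traces.items():
        arr = np.atleast_2d(arr)
        for k, tr in enumerate(arr):
            rows.extend(
                (site, cond, k, float(t), float(v)) for t, v in zip(time_ms, tr)
            )
    pd.DataFrame(rows, columns=LFP_COLUMNS).to_csv(path, index=False)


def read_lfp(
    path: str | Path,
) -> tuple[np.ndarray, dict[tuple[str, str], np.ndarray]]:
    df = pd.read_csv(path)
    _check_columns(df, LFP_COLUMNS, "lfp")
    time_ms = np.sort(df["time_ms"].unique())
    out: dict[tuple[str, str], np.ndarray] = {}
    for (site, cond), g in df.groupby(["site_id", "condition"], sort=False):
        mat = (
            g.pivot_table(index="trial", columns="time_ms", values="voltage")
            .sort_index()
            .to_numpy()
        )
        out[(str(site), str(cond))] = mat
    return time_ms, out
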