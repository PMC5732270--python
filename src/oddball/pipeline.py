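"""End-to-end orchestration: simulate → quantify → decompose → summarize.

The unit of analysis is the *point*: one neuron/tone combination with its
(DEV, STD, CTR) response triplet.  A neuron tested with one adjacent tone
pair contributes up to two points (the ascending and the descending
deviant), each evaluated against the direction-matched cascade control and
against the many-standards control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import response as rq
from .indices import decompose
from .response import TrialRaster
from .simulate import (
    STATIONS,
    SimulatedRecording,
    default_lfp_components,
    simulate_lfp,
    simulate_population,
    simulate_waveforms,
)
from .stats import friedman_conditions, min_sample_size
from .stimgen import Condition
from .quality import isi_violations, mahalanobis_profile, snr

__all__ = [
    "RunConfig",
    "condition_rasters",
    "analyze_recording",
    "analyze_population",
    "station_summary",
    "run_pipeline",
]


def _by_condition(rasters: dict[str, TrialRaster]) -> dict[str, TrialRaster]:
    out = {}
    for r in rasters.values():
        if r.condition in out:
            raise ValueError(f"duplicate sequence for condition {r.condition}")
        out[r.condition] = r
    return out


def _subset(
    raster: TrialRaster, idx: np.ndarray, condition: str, tone: int
) -> TrialRaster:
    return replace(
        raster,
        trials=[raster.trials[i] for i in idx],
        condition=condition,
        tone_index=int(tone),
        positions=raster.positions[idx] if raster.positions is not None else None,
        is_deviant=raster.is_deviant[idx] if raster.is_deviant is not None else None,
        tone_indices=raster.tone_indices[idx] if raster.tone_indices is not None else None,
    )


def condition_rasters(
    rasters: dict[str, TrialRaster],
) -> list[dict]:
    """Split a neuron's sequence rasters into per-tone condition rasters.

    Expects one raster per condition (two oddballs, two cascades, one
    many-standards), each carrying per-trial ``tone_indices`` and, for
    oddballs, deviant flags.  Returns one record per deviant tone with its
    DEV, last-standard STD, and control rasters plus the deviant direction.
    """
    by_cond = _by_condition(rasters)
    for need in (Condition.ODD_ASC.value, Condition.ODD_DESC.value):
        if need not in by_cond:
            raise ValueError(f"missing {need} sequence")
    points = []
    for odd_name, ctr_name, direction in (
        (Condition.ODD_ASC.value, Condition.CAS_ASC.value, "ascending"),
        (Condition.ODD_DESC.value, Condition.CAS_DESC.value, "descending"),
    ):
        odd = by_cond[odd_name]
        other = by_cond[
            Condition.ODD_DESC.value if direction == "ascending" else Condition.ODD_ASC.value
        ]
        if odd.tone_indices is None or odd.is_deviant is None:
            raise ValueError("oddball raster needs tone_indices and deviant flags")
        dev_idx = np.flatnonzero(odd.is_deviant)
        if dev_idx.size == 0:
            continue
        tone = int(odd.tone_indices[dev_idx[0]])
        rec = {
            "tone_index": tone,
            "direction": direction,
            "DEV": _subset(odd, dev_idx, "DEV", tone),
            "STD": rq.select_std_trials(other),
        }
        rec["STD"].tone_index = tone
        cas = by_cond.get(ctr_name)
        if cas is not None:
            idx = np.flatnonzero(cas.tone_indices == tone)
            rec["CTR_CASCADE"] = _subset(cas, idx, "CTR_CASCADE", tone)
        mstd = by_cond.get(Condition.MSTD.value)
        if mstd is not None:
            idx = np.flatnonzero(mstd.tone_indices == tone)
            rec["CTR_MSTD"] = _subset(mstd, idx, "CTR_MSTD", tone)
        points.append(rec)
    return points


def analyze_recording(
    recording: SimulatedRecording | dict[str, TrialRaster],
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    controls: tuple[str, ...] = ("cascade", "many_standards"),
) -> pd.DataFrame:
    """Response measures, inclusion filtering, and indices for one neuron.

    Returns one row per (tone, control_type) with the raw triplet, the
    normalized responses, the indices, and the inclusion verdict.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rasters = recording.rasters if isinstance(recording, SimulatedRecording) else recording
    first = next(iter(rasters.values()))
    neuron_id, station = first.neuron_id, first.station
    nucleus, hierarchy = (station.split("_") + [""])[:2] if station else ("", "")
    rows = []
    wanted = {"cascade": "CTR_CASCADE", "many_standards": "CTR_MSTD"}
    keys = ("DEV", "STD") + tuple(wanted[c] for c in controls)
    spont_hz = rq.pooled_baseline_rate(rasters.values())
    for point in condition_rasters(rasters):
        measures = {}
        for key in keys:
            r = point.get(key)
            if r is not None and r.n_trials > 0:
                measures[key] = rq.measure_response(
                    r, n_null=n_null, seed=rng, null_rate_hz=spont_hz
                )
        if "DEV" not in measures or "STD" not in measures:
            continue
        for control_type, key in (("cascade", "CTR_CASCADE"), ("many_standards", "CTR_MSTD")):
            if key not in measures:
                continue
            dev_m, std_m, ctr_m = measures["DEV"], measures["STD"], measures[key]
            included = rq.inclusion_filter(dev_m, std_m, ctr_m, alpha=alpha)
            idx = decompose((dev_m.bcsc, std_m.bcsc, ctr_m.bcsc))
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "station": station,
                    "nucleus": nucleus,
                    "hierarchy": hierarchy,
                    "tone_index": point["tone_index"],
                    "direction": point["direction"],
                    "control_type": control_type,
                    "dev": dev_m.bcsc,
                    "std": std_m.bcsc,
                    "ctr": ctr_m.bcsc,
                    "p_dev": dev_m.p_value,
                    "p_std": std_m.p_value,
                    "p_ctr": ctr_m.p_value,
                    "included": included,
                    "dev_n": idx.dev_n,
                    "std_n": idx.std_n,
                    "ctr_n": idx.ctr_n,
                    "imm": idx.imm,
                    "irs": idx.irs,
                    "ipe": idx.ipe,
                    "ssa_index": idx.ssa,
                    "defined": idx.defined,
                }
            )
    return pd.DataFrame(rows)


def analyze_population(
    recordings: list[SimulatedRecording],
    n_null: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    controls: tuple[str, ...] = ("cascade", "many_standards"),
) -> pd.DataFrame:
    """Index table over a population: one row per neuron/tone/control."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for rec, child in zip(recordings, ss.spawn(len(recordings))):
        frames.append(
            analyze_recording(
                rec, n_null=n_null, seed=np.random.default_rng(child),
                alpha=alpha, controls=controls,
            )
        )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def station_summary(
    points: pd.DataFrame,
    control_type: str = "cascade",
    included_only: bool = True,
) -> pd.DataFrame:
    """Per-station medians and tests, mirroring the standard summary table.

    Rows: number of neurons and analyzable points, median raw responses,
    median indices, Friedman pairwise p-values (DEV−STD, CTR−STD,
    DEV−CTR), and the minimum sample size for 0.8 power on the
    prediction-error index.
    """
    df = points[points["control_type"] == control_type]
    if included_only and "included" in df.columns:
        df = df[df["included"] & df["defined"]]
    rows = []
    for st in STATIONS:
        sub = df[df["station"] == st]
        if sub.empty:
            continue
        row = {
            "station": st,
            "n_neurons": sub["neuron_id"].nunique(),
            "n_points": len(sub),
            "dev_median": sub["dev"].median(),
            "std_median": sub["std"].median(),
            "ctr_median": sub["ctr"].median(),
            "imm_median": sub["imm"].median(),
            "irs_median": sub["irs"].median(),
            "ipe_median": sub["ipe"].median(),
        }
        if len(sub) >= 2:
            fr = friedman_conditions(
                sub["dev"].to_numpy(), sub["std"].to_numpy(), sub["ctr"].to_numpy()
            )
            row["friedman_p"] = fr.p_value
            row["p_dev_std"] = fr.pairwise_p[("DEV", "STD")]
            row["p_ctr_std"] = fr.pairwise_p[("CTR", "STD")]
            row["p_dev_ctr"] = fr.pairwise_p[("DEV", "CTR")]
            ipe = sub["ipe"].to_numpy()
            if np.std(ipe) > 0:
                row["min_sample_size"] = min_sample_size(ipe).n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Every stochastic stage receives a seed spawned from ``seed``, so the
    same config yields byte-identical tables.
    """

    scenario: str = "predictive_coding"  # ssa_only | predictive_coding | from_files
    n_neurons_per_station: int = 10
    n_tones: int = 400
    n_null: int = 200
    control: str = "cascade"  # cascade | many_standards
    correction: str = "fdr"  # fdr | bonferroni
    fdr_q: float = 0.1
    alpha: float = 0.05
    include_lfp: bool = True
    n_lfp_sites: int = 12
    seed: int = 0
    events_path: str | None = None  # for scenario == from_files
    trials_path: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            import warnings

            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items() if k in known})


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run simulate → quantify → decompose → summarize and write artifacts.

    Emits the spike-event tables, the per-point index table, the station
    summary, LFP difference-wave results (when enabled), a QC report, and
    a manifest with seeds and stage counts.
    """
    from . import io as oio
    from .lfp import pe_lfp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_analysis, s_lfp, s_qc = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    ]
    manifest: dict = {"config": asdict(config), "stages": {}}

    if config.scenario == "from_files":
        if not config.events_path or not config.trials_path:
            raise ValueError("from_files scenario needs events_path and trials_path")
        recordings = oio.read_events(config.events_path, config.trials_path)
    else:
        recordings = simulate_population(
            config.scenario,
            n_neurons_per_station=config.n_neurons_per_station,
            seed=s_sim,
            n_tones=config.n_tones,
        )
        spikes, trials = oio.recordings_to_tables(recordings)
        spikes.to_csv(outdir / "spikes.csv", index=False)
        trials.to_csv(outdir / "trials.csv", index=False)
    manifest["stages"]["simulate"] = {"n_recordings": len(recordings), "seed": s_sim}

    points = analyze_population(
        recordings, n_null=config.n_null, seed=s_analysis, alpha=config.alpha
    )
    points.to_csv(outdir / "points.csv", index=False)
    summary = station_summary(points, control_type=config.control)
    summary.to_csv(outdir / "station_summary.csv", index=False)
    manifest["stages"]["analyze"] = {
        "n_points": len(points),
        "n_included": int(points["included"].sum()) if len(points) else 0,
        "seed": s_analysis,
    }

    result = {"points": points, "summary": summary, "manifest": manifest}

    if config.include_lfp and config.scenario != "from_files":
        rng = np.random.default_rng(s_lfp)
        comps = default_lfp_components()
        dev_sites, ctr_sites, t = [], [], None
        for _ in range(config.n_lfp_sites):
            t, dev_tr = simulate_lfp(comps, "DEV", seed=rng)
            _, ctr_tr = simulate_lfp(comps, "CTR", seed=rng)
            dev_sites.append(dev_tr.mean(axis=0))
            ctr_sites.append(ctr_tr.mean(axis=0))
        res = pe_lfp(
            np.asarray(dev_sites), np.asarray(ctr_sites), t,
            correction=config.correction, q=config.fdr_q, alpha=config.alpha,
        )
        lfp_df = pd.DataFrame(
            {
                "time_ms": res.time_ms,
                "pe_lfp": res.difference,
                "p_value": res.p_values,
                "significant": res.mask.astype(int),
            }
        )
        lfp_df.to_csv(outdir / "pe_lfp.csv", index=False)
        manifest["stages"]["lfp"] = {
            "n_sites": config.n_lfp_sites,
            "intervals_ms": res.intervals,
            "seed": s_lfp,
        }
        result["pe_lfp"] = res

    # QC on simulated waveform sets and pooled spike times per neuron
    rng = np.random.default_rng(s_qc)
    qc_rows = []
    for rec in recordings[: min(len(recordings), 50)]:
        if isinstance(rec, SimulatedRecording):
            nid = next(iter(rec.rasters.values())).neuron_id
            rasters = rec.rasters
        else:
            nid = next(iter(rec.values())).neuron_id
            rasters = rec
        waves = simulate_waveforms(n=300, seed=rng)
        all_times = []
        offset = 0.0
        for r in rasters.values():
            for tr in r.trials:
                all_times.extend(tr + offset)
                offset += 1000.0
        prof = mahalanobis_profile(waves)
        qc_rows.append(
            {
                "neuron_id": nid,
                "snr": snr(waves),
                "isi_violation_fraction": isi_violations(np.asarray(all_times)),
                "mahalanobis_median_sq": prof.median_sq,
                "mahalanobis_reference_sq": prof.reference_median_sq,
            }
        )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc_report.csv", index=False)
    manifest["stages"]["qc"] = {"n_units": len(qc), "seed": s_qc}
    result["qc"] = qc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
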