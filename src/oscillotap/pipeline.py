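"""End-to-end orchestration: simulate -> preprocess -> epoch -> TFR -> inference.

One :class:`RunConfig` drives the whole analysis for a cohort: per
participant a session is simulated (or loaded), conditioned, segmented
around EMG-detected movement onsets per condition x rate, decomposed into
baselined dB maps at the electrodes of interest, and finally each condition
pair is tested with the cluster-based permutation model.  The bundle written
to disk contains per-comparison JSON reports, a machine-readable summary
grid (electrode x comparison x rate -> effect sign), t-map TSVs and a
reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusterstats import ClusterPermutationTest, zscore_normalize
from .epochs import baseline_window_for, detect_emg_onsets, reject_artifacts, segment
from .montage import standard_positions
from .preprocess import preprocess_pipeline
from .simulate import ContinuousRecording, EffectSpec, SimConfig, generate_session
from .tfr import ANALYSIS_WINDOW_MS, average_trials, build_wavelet_bank, divisive_baseline_db, transform
from . import io as io_mod

__all__ = ["RunConfig", "PipelineError", "run"]

DEFAULT_ELECTRODES = ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "T7", "T8")
DEFAULT_COMPARISONS = (
    ("Activating", "ToneOnly"),
    ("Relaxing", "ToneOnly"),
    ("Activating", "Relaxing"),
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one cohort analysis."""

    sim: SimConfig = field(default_factory=SimConfig)
    recordings: tuple[str, ...] = ()          # optional pre-recorded session files
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    bad_channels: tuple[str, ...] = ()
    target_fs: float = 256.0
    passband: tuple[float, float] = (0.1, 30.0)
    notch: float | None = 60.0
    grad_limit: float = 30.0
    abs_limit: float = 150.0
    alpha_cell: float = 0.05
    n_permutations: int = 1000
    zscore_reporting: bool = False
    seed: int = 0

    def validate(self) -> None:
        positions = standard_positions()
        missing = [e for e in self.electrodes if e not in positions]
        if missing:
            raise PipelineError("config", f"electrodes not in montage: {missing}")
        not_sim = [e for e in self.electrodes if e not in self.sim.eeg_labels]
        if not_sim and not self.recordings:
            raise PipelineError("config", f"electrodes not in simulated montage: {not_sim}")
        for a, b in self.comparisons:
            for cond in (a, b):
                if cond not in self.sim.conditions:
                    raise PipelineError("config", f"comparison references unknown condition {cond!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {}) or {}
        effects = tuple(EffectSpec(**{**e, "band": tuple(e["band"]),
                                      "window": tuple(e["window"]),
                                      "channels": tuple(e.get("channels", ("C3", "Cz", "FCz")))})
                        for e in sim_raw.pop("erd_spec", []))
        sim = SimConfig(**{**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in sim_raw.items()}, "erd_spec": effects})
        cleaned = {}
        for k, v in raw.items():
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            cleaned[k] = v
        return cls(sim=sim, **cleaned)


def _participant_maps(recording: ContinuousRecording, config: RunConfig,
                      bank, log_sink: dict) -> dict:
    """condition -> rate -> electrode -> (freqs x times) dB map for one participant."""
    try:
        clean, plog = preprocess_pipeline(
            recording,
            bad_channels=config.bad_channels,
            target_fs=config.target_fs,
            passband=config.passband,
            notch=config.notch,
        )
    except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
        raise PipelineError("preprocess", str(exc)) from exc
    log_sink["preprocess"] = {
        "stages": plog["stages"],
        "ica_flagged": plog["ica_flagged"],
        "ica_converged": plog["ica_converged"],
        "bad_channels": plog["bad_channels"],
    }

    emg_idx = clean.emg_index
    if emg_idx is None:
        raise PipelineError("epochs", "no EMG channel available for onset detection")
    onsets = detect_emg_onsets(clean.data[emg_idx], clean.fs)
    # attribute each detected onset to the nearest known tap event
    event_samples = np.array([ev.sample for ev in clean.events])
    maps: dict = {}
    log_sink["rejection"] = {}
    for condition in {a for pair in config.comparisons for a in pair}:
        maps[condition] = {}
        for rate in config.sim.rates:
            sel = [ev for ev in clean.events
                   if ev.condition == condition and ev.rate == rate]
            if not sel:
                continue
            sel_samples = np.array([ev.sample for ev in sel])
            tol = int(round(0.100 * clean.fs))
            matched = []
            for onset in onsets:
                j = np.argmin(np.abs(sel_samples - onset))
                if abs(sel_samples[j] - onset) <= tol:
                    matched.append(onset)
            if not matched:
                continue
            try:
                es = segment(clean, matched, condition=condition, rate=rate,
                             baseline_window=baseline_window_for(rate))
                es = reject_artifacts(es, config.grad_limit, config.abs_limit)
                if not es.retained.any():
                    raise PipelineError("epochs", f"all trials rejected for "
                                                  f"{condition} @ {rate} BPM")
                raw = transform(es, bank)
                db = divisive_baseline_db(raw, baseline_window_for(rate))
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("tfr", str(exc)) from exc
            log_sink["rejection"][f"{condition}@{rate:g}"] = es.rejection_fraction
            db = db.crop(*ANALYSIS_WINDOW_MS)
            maps[condition][rate] = {
                e: db.power[db.channel_labels.index(e)] for e in config.electrodes
            }
    return maps


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bank = build_wavelet_bank(config.target_fs)

    manifest: dict = {
        "oscillotap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "participants": {},
    }

    per_participant: list[dict] = []
    if config.recordings:
        sessions = [io_mod.read_recording(p) for p in config.recordings]
    else:
        sessions = [generate_session(config.sim, pid)
                    for pid in range(config.sim.n_participants)]
    for pid, recording in enumerate(sessions):
        sink: dict = {}
        per_participant.append(_participant_maps(recording, config, bank, sink))
        manifest["participants"][str(pid)] = sink

    grid_rows = []
    reports: dict = {}
    for rate in config.sim.rates:
        for a, b in config.comparisons:
            stack_a, stack_b = [], []
            for maps in per_participant:
                if rate in maps.get(a, {}) and rate in maps.get(b, {}):
                    stack_a.append(maps[a][rate])
                    stack_b.append(maps[b][rate])
            if len(stack_a) < 2:
                raise PipelineError("clusterstats",
                                    f"fewer than 2 participants for {a}-{b} @ {rate:g}")
            for electrode in config.electrodes:
                arr_a = np.stack([m[electrode] for m in stack_a])
                arr_b = np.stack([m[electrode] for m in stack_b])
                n_times = arr_a.shape[2]
                times = ANALYSIS_WINDOW_MS[0] + np.arange(n_times) * 1000.0 / config.target_fs
                model = ClusterPermutationTest(arr_a, arr_b,
                                               frequencies=bank.frequencies, times=times)
                res = model.fit(n_permutations=config.n_permutations,
                                alpha_cell=config.alpha_cell,
                                seed=_comparison_seed(config.seed, rate, a, b, electrode))
                key = f"{a}-{b}_{electrode}_{rate:g}bpm"
                reports[key] = res.to_report()
                sig = res.significant_clusters
                sign = 0
                if sig:
                    sign = int(np.sign(max(sig, key=lambda c: abs(c.mass)).mass))
                grid_rows.append({"electrode": electrode, "comparison": f"{a}-{b}",
                                  "rate_bpm": rate, "effect_sign": sign})
                np.savetxt(out_dir / f"tmap_{key}.tsv", res.tmap, delimiter="\t")

    (out_dir / "reports.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    grid = pd.DataFrame(grid_rows)
    grid.to_csv(out_dir / "summary_grid.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"reports": reports, "summary_grid": grid, "manifest": manifest}


def _comparison_seed(seed: int, rate: float, a: str, b: str, electrode: str) -> int:
    tag = zlib.crc32(f"{a}|{b}|{electrode}".encode())
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, int(rate), tag & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(d)
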