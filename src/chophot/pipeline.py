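"""End-to-end session pipeline: preprocess → pupil → coupling → behavior →
metrics → decoding → summaries.

The pipeline runs either on a synthetic session (a :class:`SimConfig`) or on
recorded files (per-fiber fluorescence CSV, pupil CSV, events JSON).  Every
stage writes its artifacts into the output directory, a manifest records the
parameters and the stages completed, and re-running an identical
configuration reproduces byte-identical metric outputs.  A missing pupil
input skips the coupling stage gracefully (noted in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import find_intertrial_bouts, go_probability_curve, score_session
from .coupling import coherence_spectrum, estimate_lag, resample_to_common
from .decoding import DecodingConfig, build_feature_matrix, decode_session
from .metrics import NAMED_CONFIGS, event_amplitude
from .photometry import compute_dff, lowpass_zero_lag, zscore_to_baseline
from .pupil import preprocess_pupil_trace
from .stats import summarize
from .synth import SimConfig, simulate_session

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("chophot.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "chophot_out"
    seed: int = 0
    # input: either a simulation config or file paths
    sim: SimConfig | None = None
    fluo_paths: dict[str, str] = field(default_factory=dict)
    pupil_path: str | None = None
    events_path: str | None = None
    # processing parameters
    median_window_s: float = 60.0
    lowpass_hz: float = 7.0
    baseline_pre_s: float = 2.0
    coherence_window: int = 1500
    coherence_overlap: int = 1400
    fs_common: float = 30.0
    decode_iterations: int = 50
    decode_windows: tuple[str, ...] = ("pre_1s", "post_400ms")

    def to_json(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=_default, sort_keys=True, indent=1)


def _setup_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Raises on stage failure with a stage-attributed message; artifacts of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    manifest: dict = {"seed": config.seed, "stages": [], "skipped": []}
    t_start = time.time()
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        if config.sim is not None:
            fluo, pupil, events, truth = simulate_session(config.sim)
            for region, tr in fluo.items():
                cio.write_fluorescence(out / f"fluo_{_slug(region)}.csv", tr)
            cio.write_pupil(out / "pupil_raw.csv", pupil)
            cio.write_events(out / "events.json", events)
        else:
            fluo = {k: cio.read_fluorescence(v) for k, v in config.fluo_paths.items()}
            pupil = cio.read_pupil(config.pupil_path) if config.pupil_path else None
            events = cio.read_events(config.events_path)
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        onsets = [o for o, _, _ in events.stim_onsets]
        base_windows = [(o - config.baseline_pre_s, o) for o in onsets]
        dffs = {}
        for region, tr in fluo.items():
            z = zscore_to_baseline(
                lowpass_zero_lag(
                    compute_dff(tr, window_s=config.median_window_s),
                    cutoff_hz=config.lowpass_hz,
                ),
                base_windows,
            )
            dffs[region] = z
            cio.write_dff(
                out / f"dff_{_slug(region)}.csv", z,
                params={"median_window_s": config.median_window_s,
                        "lowpass_hz": config.lowpass_hz,
                        "baseline_pre_s": config.baseline_pre_s},
            )
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

        # ------------------------------------------------------------- pupil
        stage = "pupil"
        if pupil is not None:
            pupil = preprocess_pupil_trace(pupil)
            cio.write_pupil(out / "pupil.csv", pupil)
            manifest["stages"].append(stage)
        else:
            manifest["skipped"].append(stage)
        log.info("stage %s done", stage)

        # ---------------------------------------------------------- coupling
        stage = "coupling"
        if pupil is not None:
            rows = []
            lags = {}
            for region, z in dffs.items():
                x, y, fsc = resample_to_common(z, pupil, config.fs_common)
                coh = coherence_spectrum(
                    x, y, fsc, config.coherence_window, config.coherence_overlap
                )
                lag = estimate_lag(x, y, fsc)
                lags[region] = {"lag_s": lag.lag_s, "tie": lag.tie}
                rows.append(pd.DataFrame(
                    {"fiber": region, "freq_hz": coh.freqs, "coherence": coh.coherence}
                ))
            pd.concat(rows).to_csv(out / "coherence.csv", index=False, float_format="%.8g")
            (out / "lag.json").write_text(json.dumps(lags, sort_keys=True, indent=1))
            manifest["stages"].append(stage)
        else:
            manifest["skipped"].append(stage)
        log.info("stage %s done", stage)

        # ---------------------------------------------------------- behavior
        stage = "behavior"
        rmap = config.sim.trial_schedule.reinforcement_map if config.sim else None
        trials = score_session(events, reinforcement_map=rmap)
        cio.write_trials(out / "trials.csv", trials)
        windows = [(t.onset_s - 2.0, t.onset_s + 3.0) for t in trials]
        bouts = find_intertrial_bouts(events.licks, windows)
        pd.DataFrame([vars(b) for b in bouts]).to_csv(out / "bouts.csv", index=False)
        go = go_probability_curve(trials)
        pd.DataFrame(go).to_csv(out / "go_probability.csv", index=False, float_format="%.8g")
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

        # ----------------------------------------------------------- metrics
        stage = "metrics"
        long_rows = []
        scored = [t for t in trials if t.outcome != "aborted"]
        def _row(region, t_rec, metric, resp):
            return dict(mouse=events.mouse_id, fiber=region,
                        session=events.session_id, trial=t_rec.onset_s,
                        outcome=t_rec.outcome, reinforcement=t_rec.reinforcement_type,
                        metric=metric, value=resp.amplitude)

        for region, z in dffs.items():
            for metric in ("tone_operant", "baseline_1s"):
                cfg_m = NAMED_CONFIGS[metric]
                for t_rec in scored:
                    resp = event_amplitude(z, t_rec.onset_s, cfg_m)
                    if resp is not None:
                        long_rows.append(_row(region, t_rec, metric, resp))
            cfg_r = NAMED_CONFIGS["reinforcement"]
            for t_rec in scored:
                if not (t_rec.go and t_rec.seventh_lick_s is not None):
                    continue
                resp = event_amplitude(
                    z, t_rec.seventh_lick_s, cfg_r, baseline_event_s=t_rec.onset_s
                )
                if resp is not None:
                    long_rows.append(_row(region, t_rec, "reinforcement", resp))
        metrics_df = pd.DataFrame(long_rows)
        metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.8g")
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

        # ---------------------------------------------------------- decoding
        stage = "decoding"
        decode_out = {}
        fibers = tuple(dffs)
        for window in config.decode_windows:
            for randomize in (False, True):
                cfg = DecodingConfig(
                    window=window, fibers=fibers, randomize_labels=randomize,
                    n_iterations=config.decode_iterations, seed=config.seed,
                )
                try:
                    X, y = build_feature_matrix(dffs, trials, cfg)
                except ValueError as exc:
                    decode_out[f"{window}_rand{int(randomize)}"] = {"skipped": str(exc)}
                    continue
                res = decode_session(X, y, cfg)
                decode_out[f"{window}_rand{int(randomize)}"] = {
                    "accuracy": res.accuracy, "n_trials_used": res.n_trials_used,
                }
        (out / "decoding.json").write_text(json.dumps(decode_out, sort_keys=True, indent=1))
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

        # ----------------------------------------------------------- summary
        stage = "summary"
        if not metrics_df.empty:
            summ = summarize(metrics_df, ["fiber", "metric", "outcome"])
            summ.to_csv(out / "summary.csv", index=False, float_format="%.8g")
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        manifest["config"] = json.loads(config.to_json())
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        log.info("pipeline finished in %.1f s", time.time() - t_start)
        log.removeHandler(handler)
        handler.close()
    return out


def _slug(region: str) -> str:
    return region.replace("/", "-").replace(" ", "_")
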