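"""End-to-end analysis pipeline and canonical fixture generation.

`run_full_analysis` ties the modules together for a batch of simulated
trials (one or more per baseline force): wave segmentation, behaviour
matching, bout grouping, the six wave metrics with rescaled series,
direction-effect fractions, and per-trial behaviour-force coupling.
Every output table carries the seed and configuration it came from, and
rerunning with the same configuration reproduces the files byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, detection, metrics, synthetic
from .detection import PeakParams
from .errors import InputError
from .io import ForceTrace, BehaviorTrack
from .synthetic import CleftGeometry, LarvaParams, LocomotionPolicy, SimulatedTrial

log = logging.getLogger(__name__)

#: the standard ladder of baseline confinement forces (mN)
BASELINE_FORCES = (25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "larvaforce_run"
    k: float = 100.0  # elastic coefficient, mN/mm
    baseline_forces: tuple[float, ...] = BASELINE_FORCES
    trials_per_baseline: int = 1
    seed: int = 0
    duration_s: float = 120.0
    sample_rate_hz: float = 100.0
    noise_sd: float = 0.5
    alignment_tolerance_s: float = 0.5
    peak_params: PeakParams = field(default_factory=PeakParams)

    def __post_init__(self):
        if self.k <= 0:
            raise InputError("k must be > 0")
        if self.trials_per_baseline < 0:
            raise InputError("trials_per_baseline must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "k" not in raw:
            raise InputError(f"{path}: config must set the elastic coefficient k")
        if "peak_params" in raw:
            raw["peak_params"] = PeakParams(**raw["peak_params"])
        if "baseline_forces" in raw:
            raw["baseline_forces"] = tuple(float(b) for b in raw["baseline_forces"])
        return cls(**raw)


def analyze_trial(
    trace: ForceTrace,
    track: BehaviorTrack,
    k: float,
    peak_params: PeakParams | None = None,
    tolerance_s: float = 0.5,
) -> dict:
    """Run the full single-trial analysis.

    Returns a dict with keys ``waves`` (matched ForceWave list),
    ``bouts``, ``metrics`` (DataFrame), ``fractions`` (forward/backward
    direction-effect fractions) and ``coupling`` (CouplingResult).
    """
    waves = detection.segment_waves(trace, peak_params)
    matched = detection.match_to_behavior(waves, track, tolerance_s)
    bouts = detection.group_bouts(matched)
    table = metrics.metrics_table(bouts, trace, k)
    all_metrics = [m for b in bouts for m in metrics.compute_metrics(b, trace, k)]
    fractions = metrics.direction_effect_fractions(all_metrics)
    coup = coupling.coupling_analysis(trace, track, tolerance_s)
    return {
        "waves": matched,
        "bouts": bouts,
        "metrics": table,
        "fractions": fractions,
        "coupling": coup,
    }


def _waves_frame(waves, bouts) -> pd.DataFrame:
    bout_of = {}
    for b in bouts:
        for w in b.waves:
            bout_of[(w.peak_time)] = b.bout_id
    rows = []
    for i, w in enumerate(waves):
        rows.append(
            {
                "wave_id": i,
                "direction": w.direction,
                "start_s": w.start_time,
                "peak_s": w.peak_time,
                "end_s": w.end_time,
                "start_mN": w.start_value,
                "peak_mN": w.peak_value,
                "end_mN": w.end_value,
                "prominence_mN": w.prominence,
                "bout_id": bout_of.get(w.peak_time, -1),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Simulate and analyse the configured batch of trials.

    Writes per-trial wave tables and metrics, a coupling summary
    stratified by baseline force, and direction-effect fractions pooled
    over trials, all under ``config.out_dir``; returns the in-memory
    summary tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    coupling_rows = []
    fraction_rows = []
    for baseline in config.baseline_forces:
        for rep in range(config.trials_per_baseline):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            params = LarvaParams(
                elastic_coefficient_k=config.k, noise_sd=config.noise_sd
            )
            geometry = CleftGeometry(baseline_force=baseline)
            trial = synthetic.simulate_trial(
                params, geometry, config.duration_s, config.sample_rate_hz, trial_seed
            )
            res = analyze_trial(
                trial.force_trace, trial.behavior, config.k,
                config.peak_params, config.alignment_tolerance_s,
            )
            stem = f"baseline{int(baseline)}_rep{rep}"
            _waves_frame(res["waves"], res["bouts"]).to_csv(
                out / f"{stem}_waves.csv", index=False, float_format="%.9g"
            )
            res["metrics"].to_csv(
                out / f"{stem}_metrics.csv", index=False, float_format="%.9g"
            )
            c = res["coupling"]
            coupling_rows.append(
                {
                    "baseline_mN": baseline,
                    "rep": rep,
                    "seed": trial_seed,
                    "r_pb_forward": c.r_pb_forward,
                    "r_pb_backward": c.r_pb_backward,
                    "n_forward_samples": c.forward.n_active,
                    "n_backward_samples": c.backward.n_active,
                }
            )
            f_frac, b_frac = res["fractions"]
            fraction_rows.append(
                {
                    "baseline_mN": baseline,
                    "rep": rep,
                    "seed": trial_seed,
                    "forward_increase_fraction": f_frac,
                    "backward_decrease_fraction": b_frac,
                }
            )

    coupling_df = pd.DataFrame(coupling_rows)
    fractions_df = pd.DataFrame(fraction_rows)
    coupling_df.to_csv(out / "coupling_by_baseline.csv", index=False, float_format="%.9g")
    fractions_df.to_csv(out / "direction_fractions.csv", index=False, float_format="%.9g")
    provenance = {
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "peak_params"},
            "peak_params": dataclasses.asdict(config.peak_params),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return {"coupling": coupling_df, "fractions": fractions_df, "out_dir": out}


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def noiseless_params(k: float = 100.0, policy: LocomotionPolicy | None = None) -> LarvaParams:
    """Fully deterministic larva: fixed increments, durations and delays."""
    return LarvaParams(
        elastic_coefficient_k=k,
        forward_wave_duration_sd=0.0,
        backward_wave_duration_sd=0.0,
        inter_wave_delay_mean=8.0,
        inter_wave_delay_sd=0.0,
        forward_increment_sd=0.0,
        backward_increment_sd=0.0,
        peak_excursion_sd=0.0,
        noise_sd=0.0,
        policy=policy or LocomotionPolicy(),
    )


def make_fixture_suite(seed: int = 0, directory=None) -> dict[str, SimulatedTrial]:
    """The canonical synthetic trials exercised by the test-suite.

    noiseless / noisy / crowded-waves (short delays) / early-termination
    / one trial per baseline force.  With ``directory`` given, each
    trial is also written as CSV + JSON sidecar and a manifest is
    produced; regeneration with the same seed is byte-identical.
    """
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in
             ("noiseless", "noisy", "crowded", "early_termination",
              "baseline25", "baseline50", "baseline75", "baseline100")}
    trials: dict[str, SimulatedTrial] = {}

    trials["noiseless"] = synthetic.simulate_trial(
        noiseless_params(), CleftGeometry(baseline_force=25.0), seed=seeds["noiseless"]
    )
    trials["noisy"] = synthetic.simulate_trial(
        LarvaParams(noise_sd=0.5), CleftGeometry(baseline_force=25.0), seed=seeds["noisy"]
    )
    crowded = LarvaParams(inter_wave_delay_mean=2.0, inter_wave_delay_sd=0.5, noise_sd=0.0)
    trials["crowded"] = synthetic.simulate_trial(
        crowded, CleftGeometry(baseline_force=50.0), seed=seeds["crowded"]
    )
    plunge = LarvaParams(
        backward_increment_mean=-30.0, backward_increment_sd=0.0, noise_sd=0.0,
        policy=LocomotionPolicy(p_forward=0.0, p_pause=0.0),
    )
    trials["early_termination"] = synthetic.simulate_trial(
        plunge, CleftGeometry(baseline_force=25.0), seed=seeds["early_termination"]
    )
    for b in BASELINE_FORCES:
        name = f"baseline{int(b)}"
        trials[name] = synthetic.simulate_trial(
            LarvaParams(noise_sd=0.5), CleftGeometry(baseline_force=b), seed=seeds[name]
        )

    if directory is not None:
        directory = Path(directory)
        manifest = {}
        for name, trial in trials.items():
            paths = synthetic.trial_to_files(trial, directory, stem=name)
            manifest[name] = {role: str(p.name) for role, p in paths.items()}
        (directory / "manifest.json").write_text(
            json.dumps({"seed": seed, "trials": manifest}, indent=2, sort_keys=True)
        )
    return trials
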