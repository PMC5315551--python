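"""End-to-end pipeline: simulate -> behavior -> ERP -> stats -> BMS.

A single master seed drives every random draw; per-stage seeds are derived
by stable hashing of (master seed, stage name), so adding a stage never
perturbs the draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import cohort_behavior
from .connectivity_bms import (
    bma,
    build_model_space,
    family_bms,
    simulate_connection_params,
    simulate_evidences,
)
from .erp import DEFAULT_PEAK_WINDOWS, compute_gfp, go_correction, measure_peaks
from .group_stats import paired_compare
from .io import (
    race_params_from_dict,
    race_params_to_dict,
    task_config_from_dict,
    task_config_to_dict,
    write_trials_csv,
)
from .task_sim import (
    RaceParams,
    TaskConfig,
    default_templates,
    simulate_cohort,
    synthesize_eeg,
)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-stage seed below 2**31, independent across stage names."""
    digest = hashlib.blake2b(f"{master_seed}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    seed: int = 0
    n_subjects: int = 12
    task: TaskConfig = field(default_factory=TaskConfig)
    off_params: RaceParams = field(default_factory=RaceParams)
    on_effects: dict = field(default_factory=lambda: {"rt_shift": 50.0, "ssrt_shift": 53.0})
    noise_sd: float = 1.0
    n_channels: int = 96
    stat_measures: tuple[str, ...] = ("ssrt", "gort", "mean_ssd", "pc", "oe")
    bms_true_model: str = "both_efferent"
    bms_effect_nats: float = 5.0
    bms_noise_nats: float = 1.0
    bms_on_scaling: dict = field(default_factory=lambda: {"BG->R_IFG": 0.7})
    bms_n_samples: int = 100_000
    out_dir: str = "sstdbs_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = task_config_to_dict(self.task)
        d["off_params"] = race_params_to_dict(self.off_params)
        d["stat_measures"] = list(self.stat_measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d:
            d["task"] = task_config_from_dict(d["task"])
        if "off_params" in d:
            d["off_params"] = race_params_from_dict(d["off_params"])
        if "stat_measures" in d:
            d["stat_measures"] = tuple(d["stat_measures"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write all outputs.

    Produces, under ``config.out_dir``: the trial table, behavior summary,
    per-subject GFP peak table, paired statistics for behavioral and ERP
    measures, the BMS/BMA JSON, the resolved configuration, and a manifest
    with SHA-256 hashes of every output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- behavior ---------------------------------------------------------
    pairs = simulate_cohort(
        config.n_subjects,
        config.task,
        config.off_params,
        config.on_effects,
        derive_seed(config.seed, "cohort"),
    )
    sessions = [s for pair in pairs for s in pair]
    trials_path = out / "trials.csv"
    write_trials_csv(trials_path, sessions)

    summary = cohort_behavior(sessions)
    summary_path = out / "behavior_summary.csv"
    summary.to_csv(summary_path, index=False)

    stats_rows = []
    wide = summary.pivot(index="subject_id", columns="condition")
    for m in config.stat_measures:
        on, off = wide[(m, "ON")], wide[(m, "OFF")]
        ok = on.notna() & off.notna()
        if ok.sum() >= 2:
            r = paired_compare(on[ok], off[ok], test="paired_t", measure=m)
            stats_rows.append(dataclasses.asdict(r))

    # --- ERP --------------------------------------------------------------
    templates = default_templates(n_channels=config.n_channels)
    peak_rows = []
    for on_sess, off_sess in pairs:
        for sess in (on_sess, off_sess):
            eeg = synthesize_eeg(
                sess,
                templates,
                config.noise_sd,
                derive_seed(config.seed, f"eeg:{sess.subject_id}:{sess.condition}"),
            )
            erps = go_correction(eeg["STOP"], eeg["GO"], sess)
            for cls in ("erp_ss", "erp_us"):
                gfp = compute_gfp(erps[cls])
                for pk in measure_peaks(gfp, windows=DEFAULT_PEAK_WINDOWS,
                                        polarities={k: 1 for k in DEFAULT_PEAK_WINDOWS}):
                    peak_rows.append(
                        {
                            "subject": sess.subject_id,
                            "condition": sess.condition,
                            "trial_class": cls.removeprefix("erp_").upper(),
                            "component": pk.component,
                            "latency_ms": pk.latency,
                            "gfp_amplitude": pk.amplitude,
                            "at_edge": pk.at_edge,
                        }
                    )
    peaks = pd.DataFrame(peak_rows)
    peaks_path = out / "gfp_peaks.csv"
    peaks.to_csv(peaks_path, index=False)

    ss = peaks[peaks.trial_class == "SS"]
    for comp in ("N200", "P300"):
        for col, label in (("gfp_amplitude", "amp"), ("latency_ms", "lat")):
            p = ss[ss.component == comp].pivot(
                index="subject", columns="condition", values=col
            )
            r = paired_compare(
                p["ON"], p["OFF"], test="paired_t", measure=f"gfp_{comp}_{label}"
            )
            stats_rows.append(dataclasses.asdict(r))

    stats_path = out / "paired_stats.csv"
    pd.DataFrame(stats_rows).to_csv(stats_path, index=False)

    # --- connectivity BMS -------------------------------------------------
    space = build_model_space()
    ev, gen_models = simulate_evidences(
        space,
        config.bms_true_model,
        config.bms_effect_nats,
        config.bms_noise_nats,
        config.n_subjects,
        seed=derive_seed(config.seed, "evidence"),
    )
    fam = family_bms(
        ev, space.families, n_samples=config.bms_n_samples,
        seed=derive_seed(config.seed, "bms"),
    )
    best_family = fam.family_ids[int(np.argmax(fam.family_exceedance))]
    params = simulate_connection_params(
        space,
        config.n_subjects,
        on_scaling=config.bms_on_scaling,
        seed=derive_seed(config.seed, "params"),
    )
    avg = bma(
        params, ev, space.families[best_family], space.connection_names,
        family=best_family,
    )
    bms_doc = {
        "model_ids": list(ev.model_ids),
        "generating_models": gen_models,
        "alpha": fam.model_result.alpha.tolist(),
        "expected_freq": fam.model_result.expected_freq.tolist(),
        "model_exceedance": fam.model_result.exceedance.tolist(),
        "family_ids": list(fam.family_ids),
        "family_exceedance": fam.family_exceedance.tolist(),
        "best_family": best_family,
        "bma_group_summary": {
            name: dict(zip(avg.conditions, avg.group_summary[j].tolist()))
            for j, name in enumerate(avg.connection_names)
        },
        "bma_paired_tests": [dataclasses.asdict(t) for t in avg.paired_tests],
    }
    bms_path = out / "bms.json"
    bms_path.write_text(json.dumps(bms_doc, indent=2, allow_nan=True))

    config_path = out / "config.json"
    config_path.write_text(json.dumps(config.to_dict(), indent=2))

    from . import __version__ as version

    outputs = [trials_path, summary_path, stats_path, peaks_path, bms_path, config_path]
    manifest = {
        "version": version,
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
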