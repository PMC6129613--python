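"""End-to-end orchestration: stimuli -> covariates -> behavior -> models.

Each stage writes plain CSV/WAV intermediates so it can be re-run and
inspected independently; a run log records the configuration, seed, and
per-stage timing.  The whole run is deterministic given (config, seed).
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

from . import audio, models, mouse_metrics, stimuli, surrogates, synthetic_data
from .multifractal import CJConfig, cj_spectrum, default_q_grid

__all__ = [
    "PipelineConfig",
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_CONTEXT_COVARIATES",
    "reference_token_covariates",
    "run_pipeline",
    "reproduce_table1",
]

log = logging.getLogger("speechmf")

# Multifractal coefficient block (B_W, B_t, B_Wt) reported for the
# cumulative-"GA" Poisson model in the original behavioral study.
REFERENCE_COEFFICIENTS = (-0.34, 0.06, -0.39)

# Per-context multifractal covariates (w_MF, t_MF) reported for the
# original context stimuli, with the published model-predicted percent
# probability of one more "GA" response where available.
REFERENCE_CONTEXT_COVARIATES = pd.DataFrame(
    [
        ("real_speech", "al", 0.1463, -14.77, 91.10),
        ("real_speech", "ar", 0.1018, -16.76, None),
        ("tone", "al", 0.0096, -5.94, 71.36),
        ("tone", "ar", 0.0141, -17.99, 37.33),
    ],
    columns=["context", "precursor", "w_mf", "t_mf", "published_percent"],
)


# Published (w_MF, t_MF) ranges over the eight simulated-speech variants
# per precursor; variants are spread evenly across each range.
_SS_COVARIATE_RANGES = {
    "al": ((0.1467, 0.1472), (-14.01, -12.31)),
    "ar": ((0.1017, 0.1020), (-15.67, -15.03)),
}


def reference_token_covariates() -> pd.DataFrame:
    """Covariates (w_mf, t_mf) for all 20 context tokens, precursor coded 1/2.

    Real-speech and tone tokens carry their published values; the eight
    simulated-speech variants per precursor are spread evenly over the
    published ranges.  This is the stimulus-covariate input used by the
    behavioral forward model when the audio pipeline is not run.
    """
    rows = []
    for rec in REFERENCE_CONTEXT_COVARIATES.itertuples():
        rows.append((rec.context, rec.precursor, 0, rec.w_mf, rec.t_mf))
    for precursor, ((w_lo, w_hi), (t_lo, t_hi)) in _SS_COVARIATE_RANGES.items():
        ws = np.linspace(w_lo, w_hi, 8)
        ts = np.linspace(t_lo, t_hi, 8)
        for v in range(8):
            rows.append(("simulated_speech", precursor, v + 1, ws[v], ts[v]))
    df = pd.DataFrame(rows, columns=["context", "precursor", "variant",
                                     "w_mf", "t_mf"])
    df["precursor"] = df["precursor"].map({"al": 1, "ar": 2})
    return df


@dataclass
class PipelineConfig:
    """Serializable settings for a full pipeline run."""

    out_dir: str = "speechmf_run"
    seed: int = 1
    rate: int = 22050
    n_participants: int = 42
    n_surrogates: int = 50
    n_iter: int = 1000
    q_step: int = 5
    r_min: float = 0.995
    context: str = "mixed"
    coefficients: dict | None = None
    rt_mean_ms: float = 650.0
    jitter_px: float = 3.0
    entropy_bins: int = 16
    verbosity: int = logging.INFO

    def cj_config(self) -> CJConfig:
        return CJConfig(q_grid=default_q_grid(self.q_step), r_min=self.r_min)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s done in %.2f s", name, t1 - t0)
    return t1


def synthesize_stimuli(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Targets, contexts, and shuffled variants; WAVs plus a manifest."""
    manifest = []
    targets = stimuli.synthesize_continuum(
        stimuli.ContinuumSpec(rate=cfg.rate)
    )
    for step, w in enumerate(targets):
        audio.write_wav(out / f"{w.label}.wav", w)
        manifest.append((f"{w.label}.wav", "target", "", step, ""))

    for precursor in ("al", "ar"):
        speech = stimuli.synthesize_context(
            stimuli.ContextSpec(kind="real_speech_like", precursor=precursor,
                                rate=cfg.rate)
        )
        tone = stimuli.synthesize_context(
            stimuli.ContextSpec(kind="tone", precursor=precursor, rate=cfg.rate)
        )
        audio.write_wav(out / f"ctx_speech_{precursor}.wav", speech)
        audio.write_wav(out / f"ctx_tone_{precursor}.wav", tone)
        f3 = stimuli.F3_OFFSET_BY_PRECURSOR[precursor]
        manifest.append((f"ctx_speech_{precursor}.wav", "real_speech", precursor, 0, f3))
        manifest.append((f"ctx_tone_{precursor}.wav", "tone", precursor, 0, f3))

        spec = stimuli.ContextSpec(kind="real_speech_like", precursor=precursor,
                                   rate=cfg.rate)
        plan = stimuli.plan_shuffle(speech, spec.vowel_region, seed=cfg.seed)
        for v, variant in enumerate(stimuli.shuffle_resynthesize(speech, plan), 1):
            name = f"ctx_ss{v}_{precursor}.wav"
            audio.write_wav(out / name, variant)
            manifest.append((name, "simulated_speech", precursor, v, f3))

    df = pd.DataFrame(
        manifest, columns=["filename", "kind", "precursor", "variant", "f3_offset"]
    )
    df.to_csv(out / "manifest.csv", index=False)
    return df


def compute_covariates(cfg: PipelineConfig, out: Path,
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """(w_MF, t_MF) for every context token in the manifest."""
    cj = cfg.cj_config()
    rows = []
    contexts = manifest[manifest["kind"] != "target"]
    for i, rec in enumerate(contexts.itertuples()):
        w = audio.read_wav(out / rec.filename)
        mag = audio.magnitude_series(w)
        spectrum = cj_spectrum(mag, cj)
        result = surrogates.t_mf(
            w, cj, n_surrogates=cfg.n_surrogates, n_iter=cfg.n_iter,
            seed=cfg.seed + 1000 * (i + 1),
        )
        rows.append((rec.kind, rec.precursor, rec.variant,
                     spectrum.width, result.t_statistic))
    df = pd.DataFrame(rows, columns=["context", "precursor", "variant",
                                     "w_mf", "t_mf"])
    df.to_csv(out / "covariates.csv", index=False)
    return df


def simulate_behavior(cfg: PipelineConfig, out: Path,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Trial schedule, responses, RTs, trajectories, and metrics."""
    cov = covariates.copy()
    cov["precursor"] = cov["precursor"].map({"al": 1, "ar": 2})
    spec = synthetic_data.BehaviorSimSpec(
        n_participants=cfg.n_participants, context=cfg.context,
        rt_mean_ms=cfg.rt_mean_ms, seed=cfg.seed,
    )
    if cfg.coefficients:
        spec.coefficients.update(cfg.coefficients)
    schedule = synthetic_data.generate_trial_schedule(spec)
    trials = synthetic_data.simulate_responses(schedule, spec, cov)

    params = synthetic_data.TrajectoryParams(jitter_px=cfg.jitter_px)
    metric_rows = []
    for i, trial in enumerate(trials.to_dict("records")):
        traj, k = synthetic_data.simulate_trajectory(
            trial, params, seed=cfg.seed + 7_000_000 + i
        )
        m = mouse_metrics.compute_metrics(traj, n_bins=cfg.entropy_bins)
        metric_rows.append((trial["participant"], trial["trial_overall"],
                            m.x_flips, m.md, m.auc, m.psi, m.xi, k))
    metrics = pd.DataFrame(
        metric_rows,
        columns=["participant", "trial_overall", "x_flips", "md", "auc",
                 "psi", "xi", "k_injected"],
    )
    metrics.to_csv(out / "metrics.csv", index=False)
    trials = trials.merge(metrics.drop(columns="k_injected"),
                          on=["participant", "trial_overall"])
    trials.to_csv(out / "trials.csv", index=False)
    return trials


def fit_response_models(cfg: PipelineConfig, out: Path,
                        trials: pd.DataFrame) -> dict:
    """The cumulative-count Poisson fit and the trialwise logistic fit."""
    # context is between-participant: with per-participant fixed intercepts
    # its dummies would be aliased, so these demonstration fits pool over
    # participants instead of absorbing them
    shared_terms = ["linear_step", "precursor", "context",
                    "block", "trial_in_block", "w_mf × t_mf"]
    tables = {}
    for name, spec in {
        "poisson": models.ModelSpec("poisson_log", "cum_ga", shared_terms),
        "logistic": models.ModelSpec("binomial_logit", "ga_response", shared_terms),
    }.items():
        table = models.fit_model(spec, trials)
        table.to_csv(out / f"coefficients_{name}.csv", index=False)
        tables[name] = table
    return tables


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict of the produced artifacts."""
    logging.basicConfig(level=cfg.verbosity, format="%(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")

    t0 = time.perf_counter()
    stage = "synthesize"
    try:
        manifest = synthesize_stimuli(cfg, out)
        t0 = _stage(stage, t0)
        stage = "covariates"
        covariates = compute_covariates(cfg, out, manifest)
        t0 = _stage(stage, t0)
        stage = "behavior"
        trials = simulate_behavior(cfg, out, covariates)
        t0 = _stage(stage, t0)
        stage = "models"
        tables = fit_response_models(cfg, out, trials)
        _stage(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "out_dir": str(out),
        "seed": cfg.seed,
        "n_stimuli": len(manifest),
        "n_context_tokens": len(covariates),
        "n_trials": len(trials),
        "files": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_log.json").write_text(json.dumps(summary, indent=2))
    return summary


def reproduce_table1(
    coeff_source=REFERENCE_COEFFICIENTS,
    wt_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Closed-form model-predicted percent for each (w_MF, t_MF) row.

    Applies ``predicted_event_probability`` with the supplied
    multifractal coefficient block to each row of ``wt_table``
    (defaulting to the published context covariates) and, where a
    published percent is supplied, reports the difference.
    """
    table = (wt_table if wt_table is not None
             else REFERENCE_CONTEXT_COVARIATES).copy()
    table["predicted_percent"] = [
        round(models.predicted_event_probability(coeff_source, w, t), 2)
        for w, t in zip(table["w_mf"], table["t_mf"])
    ]
    if "published_percent" in table.columns:
        table["difference"] = table["predicted_percent"] - table["published_percent"]
    return table
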