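"""Config-driven experiment harness.

One named experiment per analysis family, each run over ``n_seeds``
independent initial conditions (default 5) and reported as per-seed tables
plus mean +/- s.e.m. aggregates.  Every run's resolved configuration is
persisted next to its outputs.

Registry
--------
``gabor_prediction``   next-input decoding from the L2/3 output and
                       current-input decoding from L5, with shuffled-label
                       chance (intact model, contextual Gabor task).
``collapse_check``     training without the reconstruction cost collapses
                       the across-stimulus variance of L5.
``ablations``          decoding of current/past input from L2/3 and L5
                       under each knockout and feedback regime.
``feedback_sweep``     decoding accuracy and 90%-variance PC count vs.
                       feedback connection probability and mode.
``sparsity``           layer sparseness: intact ordering, size sweep with
                       sparseness-accuracy correlations, noise-input
                       condition, knockout-during-learning conditions.
``mismatch``           closed-loop mismatch errors, speed scaling,
                       open-loop inversion probe and the stimulation
                       (gain-scaling) conditions.
``robustness``         noise-residual curves (intact vs. prediction-
                       ablated vs. denoising autoencoder), occlusion and
                       positional-shift decoding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import KnockoutFlags
from .metrics import (
    across_stimulus_variance,
    collect_activations,
    denoising_autoencoder_baseline,
    linear_decode,
    mismatch_window_table,
    _error_signals_over_stream,
)
from .model import Microcircuit, MicrocircuitResults
from .plasticity import FeedbackSpec, LearningConfig
from .plasticity import train as _train_loop
from .tasks import (
    GaborTaskSpec,
    VisuomotorSpec,
    corrupt_noise,
    gabor_sequence,
    occlude,
    shift_position,
    visuomotor_stream,
)

log = logging.getLogger("laminar")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"n_l4", "n_l23", "n_l5", "alpha", "feedback_mode", "p_connectivity"}
_TRAIN_KEYS = {"steps", "eta", "lambda_p", "lambda_r", "optimizer", "literal_eq9"}
_TASK_KEYS = {
    "train_len", "eval_len", "noise_sd", "coupling", "n_dims", "speed_max",
    "mismatch_len", "mismatch_rate", "probe_len", "probe_rate", "probe_rate_open",
    "sizes", "probabilities", "gains", "levels", "patch_size", "shift_range",
}


@dataclass
class ExperimentConfig:
    """Resolved, schema-checked configuration of one experiment run."""

    experiment: str
    n_seeds: int = 5
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    task: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"registered: {sorted(EXPERIMENTS)}"
            )
        for sub, valid in (("model", _MODEL_KEYS), ("train", _TRAIN_KEYS),
                           ("task", _TASK_KEYS)):
            unknown = set(getattr(self, sub)) - valid
            if unknown:
                raise ValueError(f"unknown {sub} config keys: {sorted(unknown)}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def seeds(self) -> list[int]:
        return [self.seed + 1000 * k for k in range(self.n_seeds)]

    def learning(self, **overrides) -> LearningConfig:
        kw = dict(self.train)
        kw.pop("steps", None)
        kw.update(overrides)
        return LearningConfig(**kw)

    def feedback(self) -> FeedbackSpec:
        return FeedbackSpec(
            mode=self.model.get("feedback_mode", "symmetric"),
            p_connectivity=self.model.get("p_connectivity", 1.0),
        )

    def model_kwargs(self) -> dict:
        return {
            k: self.model[k]
            for k in ("n_l4", "n_l23", "n_l5", "alpha")
            if k in self.model
        }


@dataclass
class ExperimentReport:
    experiment: str
    per_seed: pd.DataFrame
    aggregate: pd.DataFrame
    meta: dict
    extras: dict = field(default_factory=dict)  # named auxiliary tables

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_seed.to_csv(out / "per_seed.csv", index=False)
        self.aggregate.to_csv(out / "aggregate.csv", index=False)
        for name, table in self.extras.items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as f:
            json.dump(self.meta, f, indent=2, default=str)


def _aggregate(per_seed: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    value_cols = [
        c for c in per_seed.columns
        if c not in group_cols + ["seed"] and pd.api.types.is_numeric_dtype(per_seed[c])
    ]
    if group_cols:
        g = per_seed.groupby(group_cols)[value_cols]
    else:
        g = per_seed[value_cols]
        mean = g.mean().to_frame().T.add_suffix("_mean")
        sem = (g.std(ddof=1) / np.sqrt(len(per_seed))).to_frame().T.add_suffix("_sem")
        return pd.concat([mean, sem], axis=1)
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()


def _meta(config: ExperimentConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(blob).hexdigest()[:12],
        "seeds": config.seeds(),
        "version": __version__,
    }


# ---------------------------------------------------------------------------
# shared training helpers
# ---------------------------------------------------------------------------

def train_gabor_model(
    seed: int,
    config: ExperimentConfig,
    flags: KnockoutFlags | None = None,
    feedback: FeedbackSpec | None = None,
    learning: LearningConfig | None = None,
    noise_input: bool = False,
    noise_level: float = 0.0,
):
    """Train one circuit on the contextual Gabor task; returns the results
    object plus a held-out evaluation sequence.

    ``noise_input`` replaces the frames with structureless Gaussian noise
    (the sparsity control condition); ``noise_level`` adds additive
    Gaussian corruption to the training stream (the robustness protocol).
    """
    steps = config.train.get("steps", 20000)
    eval_len = config.task.get("eval_len", 1500)
    spec = GaborTaskSpec(seed=seed)
    seq = gabor_sequence(spec, steps + 1)
    m = Microcircuit(
        seq, seed=seed, feedback=feedback or config.feedback(), **config.model_kwargs()
    )
    frames = None
    if noise_input:
        rng = np.random.default_rng(seed + 77)
        frames = np.clip(
            0.5 + 0.25 * rng.standard_normal(seq.frames.shape), 0.0, 1.0
        )
    elif noise_level > 0:
        frames = corrupt_noise(seq.frames, noise_level, seed=seed + 50)
    if frames is not None:
        stream = m.scaler.stream(seq.triples(frames=frames))
        lcfg = learning or config.learning()
        tr = _train_loop(m.weights, stream, lcfg, flags or KnockoutFlags())
        res = MicrocircuitResults(m, tr.weights, tr.costs, lcfg, flags)
    else:
        res = m.fit(learning or config.learning(), flags=flags)
    eval_seq = gabor_sequence(replace(spec, seed=seed + 9999), eval_len)
    return res, eval_seq


def train_visuomotor_model(
    seed: int,
    config: ExperimentConfig,
    loop_mode: str = "closed",
):
    steps = config.train.get("steps", 30000)
    spec = VisuomotorSpec(
        seed=seed,
        loop_mode=loop_mode,
        noise_sd=config.task.get("noise_sd", 0.1),
        coupling=config.task.get("coupling", "linear"),
        n_dims=config.task.get("n_dims", 10),
        speed_max=config.task.get("speed_max", 8.0),
        mismatch_rate=config.task.get("mismatch_rate", 0.0005 if loop_mode == "closed" else 0.0),
    )
    stream = visuomotor_stream(spec, steps + 1)
    m = Microcircuit(stream, seed=seed, feedback=config.feedback(), **config.model_kwargs())
    res = m.fit(config.learning())
    return res, spec


def make_probe(spec: VisuomotorSpec, config: ExperimentConfig, seed: int,
               open_probe: bool = False, T: int = 15001):
    """Evaluation stream with frequent mismatch windows (closed: 600-step
    halts; open: short flow-on probes after a zero stretch)."""
    if open_probe:
        return visuomotor_stream(
            replace(
                spec,
                seed=seed,
                mismatch_len=config.task.get("probe_len", 60),
                mismatch_rate=config.task.get("probe_rate_open", 0.01),
            ),
            T,
        )
    return visuomotor_stream(
        replace(spec, seed=seed, mismatch_rate=config.task.get("probe_rate", 0.004)),
        T,
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_gabor_prediction(config: ExperimentConfig) -> ExperimentReport:
    rows = []
    for seed in config.seeds():
        res, ev = train_gabor_model(seed, config)
        acc23 = res.decode("l23_output", "current", task=ev).accuracy
        acc5 = res.decode("l5", "current", task=ev).accuracy
        chance = res.chance_level("l5", "current", task=ev)
        rows.append(
            {"seed": seed, "acc_l23_next": acc23, "acc_l5_current": acc5,
             "chance": chance}
        )
        log.info("gabor_prediction seed=%d l23=%.3f l5=%.3f", seed, acc23, acc5)
    per_seed = pd.DataFrame(rows)
    return ExperimentReport(
        "gabor_prediction", per_seed, _aggregate(per_seed, []), _meta(config)
    )


def run_collapse_check(config: ExperimentConfig) -> ExperimentReport:
    rows = []
    for seed in config.seeds():
        intact, ev = train_gabor_model(seed, config)
        bare, _ = train_gabor_model(
            seed, config, learning=config.learning(lambda_r=0.0)
        )
        _, acts_i = intact.activations(ev)
        _, acts_b = bare.activations(ev)
        v_i = across_stimulus_variance(acts_i["z_l5"])
        v_b = across_stimulus_variance(acts_b["z_l5"])
        rows.append(
            {"seed": seed, "var_intact": v_i, "var_no_recon": v_b,
             "ratio": v_b / v_i, "collapsed": v_b < 0.01 * v_i}
        )
    per_seed = pd.DataFrame(rows)
    return ExperimentReport(
        "collapse_check", per_seed, _aggregate(per_seed, []), _meta(config)
    )


KNOCKOUTS = ("none", "ko_l23_l5", "ko_thal_l5", "ko_topdown", "ko_delay", "ko_l4_l23")


def run_ablations(config: ExperimentConfig) -> ExperimentReport:
    conditions = [(k, None) for k in KNOCKOUTS] + [
        ("feedback_none", FeedbackSpec("none")),
        ("feedback_random", FeedbackSpec("random")),
    ]
    rows = []
    for seed in config.seeds():
        for name, fb in conditions:
            flags = KnockoutFlags.from_name(name if name.startswith("ko_") else "none")
            res, ev = train_gabor_model(seed, config, flags=flags, feedback=fb)
            row = {"seed": seed, "condition": name}
            for source in ("l23_output", "l23", "l5"):
                for target in ("current", "past"):
                    acc = res.decode(source, target, task=ev, flags=flags).accuracy
                    row[f"acc_{source}_{target}"] = acc
            rows.append(row)
            log.info("ablations seed=%d %s done", seed, name)
    per_seed = pd.DataFrame(rows)
    return ExperimentReport(
        "ablations", per_seed, _aggregate(per_seed, ["condition"]), _meta(config)
    )


def run_feedback_sweep(config: ExperimentConfig) -> ExperimentReport:
    probabilities = config.task.get("probabilities", [0.0, 0.25, 0.5, 0.75, 1.0])
    rows = []
    for seed in config.seeds():
        for mode in ("symmetric", "random"):
            for p in probabilities:
                fb = FeedbackSpec(mode=mode, p_connectivity=p, mask_seed=seed)
                res, ev = train_gabor_model(seed, config, feedback=fb)
                rows.append(
                    {
                        "seed": seed, "mode": mode, "p_connectivity": p,
                        "acc_l23_next": res.decode("l23_output", "current", task=ev).accuracy,
                        "acc_l5_current": res.decode("l5", "current", task=ev).accuracy,
                        "n90_l23": res.explained_variance("l23", task=ev).n_components_90,
                        "n90_l5": res.explained_variance("l5", task=ev).n_components_90,
                    }
                )
    per_seed = pd.DataFrame(rows)
    return ExperimentReport(
        "feedback_sweep", per_seed,
        _aggregate(per_seed, ["mode", "p_connectivity"]), _meta(config),
    )


def run_sparsity(config: ExperimentConfig) -> ExperimentReport:
    """Layer sparseness battery: size sweep with sparseness-accuracy
    correlation, noise-input condition and knockouts during learning."""
    sizes = config.task.get("sizes", [16, 32, 64, 128])
    rows = []
    for seed in config.seeds():
        for size in sizes:
            cfg = dataclasses.replace(config)
            cfg.model = dict(config.model, n_l4=size, n_l23=size, n_l5=size)
            res, ev = train_gabor_model(seed, cfg)
            sp = res.sparseness(task=ev).set_index("layer")
            rows.append(
                {
                    "seed": seed, "size": size,
                    "sparseness_l23": sp.loc["l23", "sparseness"],
                    "sparseness_l4": sp.loc["l4", "sparseness"],
                    "sparseness_l5": sp.loc["l5", "sparseness"],
                    "s_l23": sp.loc["l23", "treves_rolls_s"],
                    "s_l4": sp.loc["l4", "treves_rolls_s"],
                    "s_l5": sp.loc["l5", "treves_rolls_s"],
                    "acc_l23_next": res.decode("l23_output", "current", task=ev).accuracy,
                    "acc_l5_current": res.decode("l5", "current", task=ev).accuracy,
                }
            )
            log.info("sparsity seed=%d size=%d done", seed, size)
    per_seed = pd.DataFrame(rows)

    corr = pd.DataFrame(
        [
            {
                "layer": "l23",
                "pearson_r": float(np.corrcoef(per_seed.sparseness_l23,
                                               per_seed.acc_l23_next)[0, 1]),
            },
            {
                "layer": "l5",
                "pearson_r": float(np.corrcoef(per_seed.sparseness_l5,
                                               per_seed.acc_l5_current)[0, 1]),
            },
        ]
    )

    cond_rows = []
    for seed in config.seeds():
        for cond in ("noise_input", "ko_topdown", "ko_thal_l5", "ko_l23_l5", "ko_delay"):
            if cond == "noise_input":
                res, ev = train_gabor_model(seed, config, noise_input=True)
                flags = None
            else:
                flags = KnockoutFlags.from_name(cond)
                res, ev = train_gabor_model(seed, config, flags=flags)
            sp = res.sparseness(task=ev, flags=flags).set_index("layer")
            cond_rows.append(
                {
                    "seed": seed, "condition": cond,
                    **{f"sparseness_{L}": sp.loc[L, "sparseness"] for L in ("l4", "l23", "l5")},
                }
            )
    conditions = pd.DataFrame(cond_rows)
    return ExperimentReport(
        "sparsity", per_seed, _aggregate(per_seed, ["size"]), _meta(config),
        extras={"correlation": corr, "conditions": conditions},
    )


def run_mismatch(config: ExperimentConfig) -> ExperimentReport:
    gains = config.task.get("gains", [1.0, 2.0, 4.0, 8.0])
    rows, window_rows, stim_rows = [], [], []
    for seed in config.seeds():
        res, spec = train_visuomotor_model(seed, config, loop_mode="closed")
        probe = make_probe(spec, config, seed + 555)
        reps = res.mismatch(probe)
        row = {"seed": seed}
        for L in ("l23", "l5"):
            row[f"me_{L}"] = float(reps[L].me.mean())
            row[f"frac_pos_{L}"] = reps[L].sign_fractions[0]
            row[f"frac_neg_{L}"] = reps[L].sign_fractions[1]

        e23, e5 = _error_signals_over_stream(
            res.weights, probe, res.config, res.model.scaler
        )
        wt = mismatch_window_table(probe, e23, e5)
        wt.insert(0, "seed", seed)
        window_rows.append(wt)
        row["speed_corr_me_l23"] = float(np.corrcoef(wt.speed, wt.me_l23)[0, 1])
        row["speed_corr_abs_me_l23"] = float(np.corrcoef(wt.speed, wt.abs_me_l23)[0, 1])

        # open-loop probe after open-loop training
        res_o, spec_o = train_visuomotor_model(seed, config, loop_mode="open")
        probe_o = make_probe(spec_o, config, seed + 777, open_probe=True)
        reps_o = res_o.mismatch(probe_o)
        for L in ("l23", "l5"):
            row[f"me_{L}_open"] = float(reps_o[L].me.mean())
        rows.append(row)

        for layer, subset in (("l5", "all"), ("l5", "negative_me"),
                              ("l23", "all"), ("l23", "positive_me")):
            other = "l23" if layer == "l5" else "l5"
            for gain in gains:
                before, after = res.stimulate(probe, layer, gain, subset)
                stim_rows.append(
                    {
                        "seed": seed, "stim_layer": layer, "subset": subset,
                        "gain": gain,
                        f"me_{other}_before": float(before[other].me.mean()),
                        f"me_{other}_after": float(after[other].me.mean()),
                        "flip_frac": float(
                            ((before[other].me > 0) & (after[other].me < 0)).mean()
                        ),
                    }
                )
        log.info("mismatch seed=%d done", seed)
    per_seed = pd.DataFrame(rows)
    return ExperimentReport(
        "mismatch", per_seed, _aggregate(per_seed, []), _meta(config),
        extras={
            "windows": pd.concat(window_rows, ignore_index=True),
            "stimulation": pd.DataFrame(stim_rows),
        },
    )


def _noise_residual(res, ev, level: int, seed: int) -> float:
    """Mean squared residual of the L5 reconstruction of noise-corrupted
    input against the clean input."""
    noisy = corrupt_noise(ev.frames, level, seed=seed + 7)
    sc = res.model.scaler
    acts = collect_activations(res.weights, sc.stream(ev.triples(frames=noisy)))
    clean = (ev.frames[1:] - sc.x_shift) / sc.x_scale
    return float(np.mean((acts["xhat"] - clean) ** 2))


def run_robustness(config: ExperimentConfig) -> ExperimentReport:
    """Noise, occlusion and positional-shift robustness.

    For each noise level the intact and prediction-ablated circuits are
    trained on the corrupted stream (the circuit only ever sees ``x + level
    * eps``) and their L5 reconstructions are scored against the clean
    input.  Disabling the self-supervised cost freezes the whole L2/3
    pathway at its random initial state, so the ablated circuit keeps an
    untrained prediction drive.  Occlusion and shift tests use circuits
    trained on clean input.
    """
    levels = config.task.get("levels", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    patch = config.task.get("patch_size", 10)
    shift = config.task.get("shift_range", 4.0)
    rows, curve_rows = [], []
    for seed in config.seeds():
        intact, ev = train_gabor_model(seed, config)
        for level in levels:
            for label, lp in (("intact", None), ("ablated", 0.0)):
                learning = None if lp is None else config.learning(lambda_p=lp)
                res, _ = train_gabor_model(
                    seed, config, learning=learning, noise_level=level
                )
                curve_rows.append(
                    {"seed": seed, "model": label, "level": level,
                     "mse": _noise_residual(res, ev, level, seed)}
                )
        dae = denoising_autoencoder_baseline(ev.frames, levels=levels, seed=seed)
        for _, r in dae.iterrows():
            curve_rows.append(
                {"seed": seed, "model": "dae", "level": r["level"], "mse": r["mse"]}
            )

        # occlusion: SVM classification of layer outputs on occluded input
        occ_frames, _ = occlude(ev.frames, patch_size=patch, seed=seed)
        row = {"seed": seed}
        acts_occ = collect_activations(
            intact.weights,
            intact.model.scaler.stream(ev.triples(frames=occ_frames)),
        )
        labels = ev.orientation_labels[1:]
        for source, key in (("l23_output", "zhat_l5"), ("l5", "z_l5")):
            row[f"occ_acc_{source}"] = linear_decode(
                acts_occ[key], labels, decoder="svm", seed=seed
            ).accuracy
        # positional shifts
        shifted = shift_position(
            replace(ev.spec, seed=seed + 31), len(ev), shift_range=shift
        )
        acts_sh = collect_activations(
            intact.weights, intact.model.scaler.stream(shifted.triples())
        )
        row["shift_acc_l23_output"] = linear_decode(
            acts_sh["zhat_l5"], shifted.orientation_labels[1:], seed=seed
        ).accuracy
        rows.append(row)
        log.info("robustness seed=%d done", seed)
    per_seed = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_rows)
    return ExperimentReport(
        "robustness", per_seed, _aggregate(per_seed, []), _meta(config),
        extras={"residual_curves": curves},
    )


EXPERIMENTS = {
    "gabor_prediction": run_gabor_prediction,
    "collapse_check": run_collapse_check,
    "ablations": run_ablations,
    "feedback_sweep": run_feedback_sweep,
    "sparsity": run_sparsity,
    "mismatch": run_mismatch,
    "robustness": run_robustness,
}


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute a registered experiment; persist tables if an outdir is set."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = EXPERIMENTS[config.experiment](config)
    if config.outdir:
        report.save(config.outdir)
        with open(Path(config.outdir) / "config.yaml", "w") as f:
            yaml.safe_dump(config.to_dict(), f)
    return report
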