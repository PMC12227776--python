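"""Model/Results objects wrapping the microcircuit.

:class:`Microcircuit` is constructed from a task (a
:class:`~laminar.tasks.GaborSequence` or
:class:`~laminar.tasks.VisuomotorStream`); :meth:`Microcircuit.fit` trains
the circuit online over the task stream and returns a
:class:`MicrocircuitResults` carrying the trained weights, the cost
trajectory and the analysis battery (decoding, sparseness, mismatch
errors, robustness curves).

Inputs are affinely standardized before they reach the circuit (Gabor
pixels are centred at 0.5; visual flow is mapped to [-1, 1] and locomotion
speed to [0, 1]).  With logistic units and no bias terms, a positive-mean
input forces the prediction weights to acquire a coherent mean component
whose feedback silences L2/3; centring removes that failure mode without
touching the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuit import KnockoutFlags, MicrocircuitWeights
from .metrics import (
    DecodeResult,
    collect_activations,
    explained_variance_profile,
    linear_decode,
    mismatch_errors,
    reconstruction_residual,
    shuffled_chance,
    stimulation_experiment,
    trial_sparseness,
)
from .plasticity import FeedbackSpec, LearningConfig, make_feedback, train
from .tasks import (
    GaborSequence,
    GaborTaskSpec,
    VisuomotorSpec,
    VisuomotorStream,
    gabor_sequence,
    visuomotor_stream,
)

LAYERS = ("l4", "l23", "l5")


@dataclass
class InputScaler:
    """Affine standardization applied to inputs before the circuit."""

    x_shift: float = 0.0
    x_scale: float = 1.0
    td_shift: float = 0.0
    td_scale: float = 1.0

    def __call__(self, x_prev, x_t, i_td):
        return (
            (x_prev - self.x_shift) / self.x_scale,
            (x_t - self.x_shift) / self.x_scale,
            (i_td - self.td_shift) / self.td_scale,
        )

    def stream(self, triples):
        for tr in triples:
            yield self(*tr)


def default_scaler(task) -> InputScaler:
    if isinstance(task, GaborSequence):
        return InputScaler(x_shift=0.5)
    if isinstance(task, VisuomotorStream):
        spec = task.spec
        if spec.coupling == "linear":
            # flow stays non-negative (zero flow maps to zero input)
            return InputScaler(x_scale=spec.speed_max / 2.0, td_scale=spec.speed_max)
        return InputScaler(td_scale=spec.speed_max)  # sine flow already in [-1,1]
    raise TypeError(f"unsupported task type {type(task).__name__}")


#: excitatory forward pathways subject to the optional Dale sign constraint
FORWARD_PATHWAYS = ("W_thal_l4", "W_thal_l5", "W_l4_l23", "W_l23_l5")


class Microcircuit:
    """Three-layer cortical microcircuit model bound to a task stream.

    Parameters
    ----------
    task : GaborSequence or VisuomotorStream
        The training stream; input and top-down dimensions are inferred.
    n_l4, n_l23, n_l5 : int
        Layer sizes (default 128 each).
    alpha : float
        Dendritic-to-somatic attenuation of the L2/3 -> L5 drive.
    feedback : FeedbackSpec
        L5 -> L2/3 error pathway (symmetric / random / none, with optional
        connection probability).
    seed : int
        Weight-initialisation seed.
    sign_constrained : bool, optional
        Keep the four excitatory forward pathways (thalamus->L4,
        thalamus->L5, L4->L2/3, L2/3->L5) non-negative, as glutamatergic
        projections are.  Defaults to True for visuomotor streams — the
        mismatch-error analysis concerns signed responses around a resting
        state, and the constraint pins the emergent population code to be
        flow-excited (as in visual cortex) — and False for the Gabor task,
        whose analyses (decodability, sparseness) are sign-free.
    """

    def __init__(
        self,
        task,
        n_l4: int = 128,
        n_l23: int = 128,
        n_l5: int = 128,
        alpha: float = 0.3,
        feedback: FeedbackSpec | None = None,
        seed: int = 0,
        scaler: InputScaler | None = None,
        sign_constrained: bool | None = None,
    ):
        self.task = task
        self.scaler = scaler or default_scaler(task)
        if isinstance(task, GaborSequence):
            self.n_in = task.frames.shape[1]
            self.n_td = 3
        else:
            self.n_in = task.flow.shape[1]
            self.n_td = 1
        if sign_constrained is None:
            sign_constrained = isinstance(task, VisuomotorStream)
        self.sign_constrained = sign_constrained
        self.seed = seed
        self.feedback = feedback or FeedbackSpec()
        self.weights = MicrocircuitWeights.initialize(
            self.n_in, n_l4, n_l23, n_l5, self.n_td, alpha=alpha, seed=seed
        )
        if sign_constrained:
            for name in FORWARD_PATHWAYS:
                setattr(self.weights, name, np.abs(getattr(self.weights, name)))
        make_feedback(self.weights, self.feedback)

    def fit(
        self,
        config: LearningConfig | None = None,
        flags: KnockoutFlags | None = None,
        steps: int | None = None,
        record_every: int = 10,
    ) -> "MicrocircuitResults":
        """Train online over the task stream and return a results object.

        ``flags`` applies knockouts *during learning*; ``steps`` caps the
        number of timesteps (default: the full stream).
        """
        config = config or LearningConfig()
        flags = flags or KnockoutFlags()
        stream = self.scaler.stream(self.task.triples())
        if steps is not None:
            import itertools

            stream = itertools.islice(stream, steps)
        nonneg = FORWARD_PATHWAYS if self.sign_constrained else ()
        res = train(self.weights, stream, config, flags, record_every, nonneg=nonneg)
        return MicrocircuitResults(self, res.weights, res.costs, config, flags)


class MicrocircuitResults:
    """Trained-circuit results: weights, cost trajectory and diagnostics."""

    def __init__(self, model, weights, costs, config, train_flags):
        self.model = model
        self.weights = weights
        self.costs = costs
        self.config = config
        self.train_flags = train_flags
        self._eval_cache: dict = {}

    # -- evaluation streams ------------------------------------------------
    def make_eval_task(self, T: int = 1500, seed_offset: int = 9999):
        """A fresh task from the same spec with a shifted seed."""
        task = self.model.task
        if isinstance(task, GaborSequence):
            spec = replace(task.spec, seed=task.spec.seed + seed_offset)
            return gabor_sequence(spec, T)
        spec = replace(task.spec, seed=task.spec.seed + seed_offset)
        return visuomotor_stream(spec, T)

    def activations(self, task=None, flags: KnockoutFlags | None = None):
        """Layer activations over ``task`` (default: a held-out stream)."""
        key = (id(task), repr(flags))
        if key not in self._eval_cache:
            task = task if task is not None else self.make_eval_task()
            self._eval_cache[key] = (
                task,
                collect_activations(
                    self.weights, self.model.scaler.stream(task.triples()), flags
                ),
            )
        return self._eval_cache[key]

    # -- decoding ----------------------------------------------------------
    def decode(
        self,
        source: str = "l23_output",
        target: str = "current",
        task=None,
        flags: KnockoutFlags | None = None,
        decoder: str = "logistic",
        seed: int = 0,
    ) -> DecodeResult:
        """Linear decoding of the orientation class from a layer's output.

        ``source``: ``l23_output`` (the prediction vector, the circuit's
        definition of L2/3 output), ``l23`` (the L2/3 activation), ``l4``
        or ``l5``.  ``target``: ``current`` (the orientation of x_t),
        ``past`` (x_{t-1}) or ``next`` (x_{t+1}).  Because the L2/3 output
        at t is formed from x_{t-1} and the context only, decoding the
        *current* orientation from ``l23_output`` measures next-input
        prediction; under the delay knockout the circuit sits at t, so
        ``next`` probes its (absent) one-step-ahead prediction.
        """
        task, acts = self.activations(task, flags)
        if not isinstance(task, GaborSequence):
            raise TypeError("decoding targets require a Gabor task")
        field = {"l23_output": "zhat_l5", "l23": "z_l23", "l4": "z_l4", "l5": "z_l5"}[
            source
        ]
        feats = acts[field]
        if target == "current":
            labels = task.orientation_labels[1:]
        elif target == "past":
            labels = task.orientation_labels[:-1]
        elif target == "next":
            labels = task.orientation_labels[2:]
            feats = feats[:-1]
        else:
            raise ValueError(f"unknown target {target!r}")
        return linear_decode(
            feats, labels, seed=seed, decoder=decoder,
            target=f"{target}_input", source_layer=source,
        )

    def chance_level(self, source="l5", target="current", task=None, seed=0) -> float:
        task, acts = self.activations(task)
        field = {"l23_output": "zhat_l5", "l23": "z_l23", "l4": "z_l4", "l5": "z_l5"}[
            source
        ]
        labels = (
            task.orientation_labels[1:]
            if target == "current"
            else task.orientation_labels[:-1]
        )
        return shuffled_chance(acts[field], labels, seed=seed)

    # -- sparseness --------------------------------------------------------
    def sparseness(self, task=None, flags=None) -> pd.DataFrame:
        """Treves–Rolls S and normalized sparseness per layer."""
        _, acts = self.activations(task, flags)
        rows = []
        for layer in LAYERS:
            res = trial_sparseness(acts[f"z_{layer}"], layer)
            rows.append(
                {
                    "layer": layer,
                    "treves_rolls_s": res.s_mean,
                    "sparseness": res.normalized_sparseness,
                    "n_neurons": res.n_neurons,
                }
            )
        return pd.DataFrame(rows)

    def explained_variance(self, source="l23", task=None):
        _, acts = self.activations(task)
        field = {"l23_output": "zhat_l5", "l23": "z_l23", "l4": "z_l4", "l5": "z_l5"}[
            source
        ]
        return explained_variance_profile(acts[field])

    # -- visuomotor analyses -------------------------------------------------
    def mismatch(self, stream=None, margin: int = 10):
        """Per-neuron baseline-subtracted mismatch errors (L2/3 and L5)."""
        if stream is None:
            task = self.model.task
            if not isinstance(task, VisuomotorStream):
                raise TypeError("mismatch analysis requires a visuomotor stream")
            stream = task
        return mismatch_errors(
            self.weights, stream, self.config, self.model.scaler, margin
        )

    def stimulate(self, stream, layer: str, gain: float, subset: str = "all"):
        return stimulation_experiment(
            self.weights, stream, layer, gain, subset, self.config, self.model.scaler
        )

    # -- robustness ----------------------------------------------------------
    def residual_curve(self, task=None, levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                       route="l5", seed=0):
        task = task if task is not None else self.make_eval_task()
        return reconstruction_residual(
            self.weights, task, levels=levels, seed=seed,
            center=self.model.scaler.x_shift, route=route,
        )

    # -- summary -------------------------------------------------------------
    def summary(self) -> str:
        w = self.weights
        last = self.costs.iloc[-1]
        first = self.costs.iloc[0]
        lines = [
            "Microcircuit results",
            "=" * 52,
            f"layers (L4/L2/3/L5):      {w.n_l4}/{w.n_l23}/{w.n_l5}",
            f"input / top-down dims:    {w.n_in}/{w.n_td}",
            f"attenuation alpha:        {w.alpha}",
            f"feedback mode:            {w.feedback_mode}"
            + (
                f" (p={self.model.feedback.p_connectivity})"
                if self.model.feedback.p_connectivity < 1
                else ""
            ),
            f"optimizer / eta:          {self.config.optimizer}/{self.config.eta}",
            f"lambda_p / lambda_r:      {self.config.lambda_p}/{self.config.lambda_r}",
            f"steps trained:            {int(self.costs['step'].iloc[-1]) + 1}",
            f"predictive cost:          {first['c_pred']:.4f} -> {last['c_pred']:.4f}",
            f"reconstruction cost:      {first['c_recon']:.4f} -> {last['c_recon']:.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def save_weights(self, path):
        self.weights.save(path)

    # -- plots ---------------------------------------------------------------
    def plot_costs(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.costs["step"], self.costs["c_pred"], label="predictive")
        ax.plot(self.costs["step"], self.costs["c_recon"], label="reconstruction")
        ax.set_xlabel("step")
        ax.set_ylabel("cost")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def plot_confusion(self, result: DecodeResult, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frac = result.confusion / result.confusion.sum(axis=1, keepdims=True)
        im = ax.imshow(frac, cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("decoded class")
        ax.set_ylabel("true class")
        ax.set_title(f"{result.source_layer} -> {result.target}")
        plt.colorbar(im, ax=ax)
        return ax
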