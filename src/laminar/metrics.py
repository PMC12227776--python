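"""Evaluation battery: decoding, PCA profiles, population sparseness,
mismatch errors, simulated stimulation, and robustness curves.

Conventions
-----------
* "Output of L2/3" for decoding is the prediction vector
  ``zhat_l5 = W_l23_l5 @ z_l23`` (the circuit's own definition of L2/3
  output); a flag allows decoding from ``z_l23`` instead.
* Population sparseness is the Treves–Rolls statistic
  ``S = (sum r_i / N)^2 / sum(r_i^2 / N)`` computed on sigmoid activations
  (non-negative by construction) and averaged over a trial.  ``S`` lies in
  (1/N, 1]; *smaller* S means sparser activity.  Layer comparisons are
  reported on the normalized sparseness ``(1 - S) / (1 - 1/N)`` so that
  larger values mean sparser codes.
* A mismatch error (ME) is the per-neuron gradient of the total cost with
  respect to that neuron's activity, averaged over mismatch windows minus
  its average over baseline windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.svm import LinearSVC

from .circuit import (
    KnockoutFlags,
    MicrocircuitWeights,
    dsigmoid_from_z,
    forward_step,
)
from .plasticity import LearningConfig
from .tasks import VisuomotorStream, corrupt_noise, occlude

LAYER_FIELDS = {"l4": "z_l4", "l23": "z_l23", "l5": "z_l5", "l23_output": "zhat_l5"}


def collect_activations(
    weights: MicrocircuitWeights,
    triples,
    flags: KnockoutFlags | None = None,
) -> dict[str, np.ndarray]:
    """Run the circuit over a stream and stack every activation field."""
    out: dict[str, list] = {k: [] for k in ("z_l4", "z_l23", "z_l5", "zhat_l5", "xhat")}
    for x_prev, x_t, i_td in triples:
        a = forward_step(x_prev, x_t, i_td, weights, flags)
        for k in out:
            out[k].append(getattr(a, k))
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    accuracy: float
    confusion: np.ndarray  # K x K counts, rows = true class
    target: str  # current_input / past_input / next_input
    source_layer: str

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())


def linear_decode(
    features: np.ndarray,
    labels: np.ndarray,
    split_fraction: float = 0.2,
    seed: int = 0,
    decoder: str = "logistic",
    target: str = "current_input",
    source_layer: str = "",
) -> DecodeResult:
    """Fit a linear classifier on a stratified train split and report
    held-out accuracy plus the confusion matrix.

    ``decoder`` is multinomial logistic regression by default; ``"svm"``
    selects a linear support-vector machine (used for the occlusion test).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes to decode")
    Xtr, Xte, ytr, yte = train_test_split(
        features, labels, test_size=split_fraction, random_state=seed, stratify=labels
    )
    if decoder == "svm":
        clf = LinearSVC(random_state=seed)
    elif decoder == "logistic":
        clf = LogisticRegression(max_iter=3000)
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    k = classes.size
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(yte, pred):
        confusion[idx[t], idx[p]] += 1
    acc = float(np.trace(confusion) / confusion.sum())
    return DecodeResult(acc, confusion, target, source_layer)


def shuffled_chance(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, n_shuffles: int = 3
) -> float:
    """Empirical chance level: decoding accuracy under label permutation."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(labels))
        accs.append(linear_decode(features, np.asarray(labels)[perm], seed=seed).accuracy)
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# PCA explained-variance profile
# ---------------------------------------------------------------------------

@dataclass
class EVProfile:
    cumulative: np.ndarray  # cumulative explained-variance fractions
    n_components_90: int
    degenerate: bool = False


def explained_variance_profile(features: np.ndarray) -> EVProfile:
    """Cumulative PCA explained-variance curve of mean-centred features and
    the component count needed to reach 90%."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = X - X.mean(axis=0)
    total = np.var(X, axis=0).sum()
    if total <= 0:
        return EVProfile(np.zeros(1), 0, degenerate=True)
    sv = np.linalg.svd(X, compute_uv=False)
    var = sv**2
    cum = np.cumsum(var) / var.sum()
    n90 = int(np.searchsorted(cum, 0.9) + 1)
    return EVProfile(cum, n90)


# ---------------------------------------------------------------------------
# sparseness
# ---------------------------------------------------------------------------

@dataclass
class SparsenessResult:
    s_per_stimulus: np.ndarray
    s_mean: float
    layer: str
    n_neurons: int

    @property
    def normalized_sparseness(self) -> float:
        """(1 - S) / (1 - 1/N): 0 for uniform rates, 1 for a one-hot code."""
        n = self.n_neurons
        return float((1.0 - self.s_mean) / (1.0 - 1.0 / n))


def population_sparseness(rates: np.ndarray) -> float:
    """Treves–Rolls S = (sum r_i/N)^2 / sum(r_i^2/N) for one stimulus."""
    r = np.asarray(rates, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    denom = np.mean(r**2)
    if denom == 0:
        raise ValueError("all-zero rate vector has undefined sparseness")
    return float(np.mean(r) ** 2 / denom)


def trial_sparseness(activations: np.ndarray, layer: str = "") -> SparsenessResult:
    """Per-timestep Treves–Rolls S averaged over a trial."""
    Z = np.asarray(activations, dtype=float)
    s = (Z.mean(axis=1) ** 2) / (Z**2).mean(axis=1)
    return SparsenessResult(s, float(s.mean()), layer, Z.shape[1])


# ---------------------------------------------------------------------------
# mismatch errors
# ---------------------------------------------------------------------------

@dataclass
class MismatchReport:
    me_baseline: np.ndarray
    me_mismatch: np.ndarray
    me: np.ndarray  # me_mismatch - me_baseline, per neuron
    layer: str
    sign_fractions: tuple[float, float]  # (positive, negative)

    @classmethod
    def build(cls, signals, mm_mask, bl_mask, layer):
        bl = signals[bl_mask].mean(axis=0)
        mm = signals[mm_mask].mean(axis=0)
        me = mm - bl
        pos = float((me > 0).mean())
        neg = float((me < 0).mean())
        return cls(bl, mm, me, layer, (pos, neg))


def _error_signals_over_stream(
    weights: MicrocircuitWeights,
    stream: VisuomotorStream,
    config: LearningConfig,
    scaler=None,
    stim: tuple[str, float, np.ndarray | None] | None = None,
):
    """Per-step L2/3 and L5 error signals over a visuomotor stream.

    ``stim = (layer, gain, subset_mask)`` multiplies the chosen layer's
    activation by ``gain`` (restricted to ``subset_mask`` if given) during
    mismatch steps only, before downstream propagation.  The sigmoid
    derivative gate keeps the unstimulated operating point (the boost is an
    additive response change, not a re-squashed drive).
    """
    T = len(stream)
    e23 = np.empty((T - 1, weights.n_l23))
    e5 = np.empty((T - 1, weights.n_l5))
    mm = stream.mismatch_mask[1:]
    for k, (x_prev, x_t, i_td) in enumerate(stream.triples()):
        if scaler is not None:
            x_prev, x_t, i_td = scaler(x_prev, x_t, i_td)
        a = forward_step(x_prev, x_t, i_td, weights)
        z23, z5, zhat, xhat = a.z_l23, a.z_l5, a.zhat_l5, a.xhat
        gate5 = 1.0 - weights.alpha * dsigmoid_from_z(z5)
        if stim is not None and mm[k]:
            layer, gain, subset = stim
            scale = np.ones(z23.shape[0] if layer == "l23" else z5.shape[0])
            if subset is None:
                scale[:] = gain
            else:
                scale[subset] = gain
            if layer == "l23":
                z23 = z23 * scale
                zhat = weights.W_l23_l5 @ z23
                u5 = weights.alpha * zhat + weights.W_thal_l5 @ x_t
                z5 = expit(u5)
                gate5 = 1.0 - weights.alpha * dsigmoid_from_z(z5)
                xhat = weights.W_decoder @ z5
            else:
                z5 = z5 * scale
                xhat = weights.W_decoder @ z5
        e = zhat - z5
        r = x_t - xhat
        e5[k] = -config.lambda_p * e - config.lambda_r * (weights.W_decoder.T @ r)
        e23[k] = weights.W_l23_l5.T @ (config.lambda_p * e * gate5)
    return e23, e5


def baseline_mask(stream: VisuomotorStream, margin: int = 10) -> np.ndarray:
    """Baseline steps: everything outside mismatch windows, excluding a
    ``margin``-step guard band around each window (and any steps the stream
    itself marks as unfit, e.g. the zero-flow stretch of open-loop probes)."""
    mm = stream.mismatch_mask
    bad = mm.copy()
    idx = np.flatnonzero(mm)
    for i in idx:
        lo = max(0, i - margin)
        hi = min(len(mm), i + margin + 1)
        bad[lo:hi] = True
    if stream.baseline_exclude is not None:
        bad |= stream.baseline_exclude
    return ~bad


def mismatch_errors(
    weights: MicrocircuitWeights,
    stream: VisuomotorStream,
    config: LearningConfig | None = None,
    scaler=None,
    margin: int = 10,
    stim=None,
) -> dict[str, MismatchReport]:
    """Baseline-subtracted per-neuron mismatch errors for L2/3 and L5.

    Positive ME is the depolarisation analogue, negative ME the
    hyperpolarisation analogue.
    """
    config = config or LearningConfig()
    if not stream.mismatch_mask.any():
        raise ValueError("stream contains no mismatch windows")
    e23, e5 = _error_signals_over_stream(weights, stream, config, scaler, stim)
    mm = stream.mismatch_mask[1:]
    bl = baseline_mask(stream, margin)[1:]
    return {
        "l23": MismatchReport.build(e23, mm, bl, "l23"),
        "l5": MismatchReport.build(e5, mm, bl, "l5"),
    }


def stimulation_experiment(
    weights: MicrocircuitWeights,
    stream: VisuomotorStream,
    layer: str,
    gain: float,
    subset: str = "all",
    config: LearningConfig | None = None,
    scaler=None,
    margin: int = 10,
) -> tuple[dict[str, MismatchReport], dict[str, MismatchReport]]:
    """Scale one layer's output during mismatch windows and recompute MEs.

    ``subset`` restricts the gain to the neurons whose baseline ME was
    positive (``"positive_me"``) or negative (``"negative_me"``).  Returns
    the (before, after) report pairs.
    """
    if gain < 1:
        raise ValueError("gain must be >= 1 (stimulation boosts responses)")
    if layer not in ("l23", "l5"):
        raise ValueError("layer must be 'l23' or 'l5'")
    config = config or LearningConfig()
    before = mismatch_errors(weights, stream, config, scaler, margin)
    if subset == "all":
        subset_mask = None
    elif subset == "positive_me":
        subset_mask = before[layer].me > 0
    elif subset == "negative_me":
        subset_mask = before[layer].me < 0
    else:
        raise ValueError(f"unknown subset {subset!r}")
    after = mismatch_errors(
        weights, stream, config, scaler, margin, stim=(layer, gain, subset_mask)
    )
    return before, after


def mismatch_window_table(
    stream: VisuomotorStream,
    e23: np.ndarray,
    e5: np.ndarray,
) -> pd.DataFrame:
    """Per-window summary: held speed vs. mean (and mean |.|) ME per layer."""
    mm = stream.mismatch_mask[1:]
    # contiguous runs of the mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mm.view(np.int8), [0]))))
    rows = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        rows.append(
            {
                "speed": float(stream.speed[1:][lo:hi].mean()),
                "me_l23": float(e23[lo:hi].mean()),
                "me_l5": float(e5[lo:hi].mean()),
                "abs_me_l23": float(np.abs(e23[lo:hi].mean(axis=0)).mean()),
                "abs_me_l5": float(np.abs(e5[lo:hi].mean(axis=0)).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def reconstruction_residual(
    weights: MicrocircuitWeights,
    sequence,
    levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    corruption: str = "noise",
    seed: int = 0,
    center: float = 0.5,
    route: str = "l5",
) -> pd.DataFrame:
    """Mean squared residual between the reconstruction of corrupted input
    and the *clean* input, per corruption level.

    ``route="l5"`` reads the reconstruction off ``W_decoder @ z_l5``;
    ``route="l23"`` reads it off the L2/3 prediction, ``W_decoder @ zhat``.
    """
    clean = sequence.frames
    rows = []
    for level in levels:
        if corruption == "noise":
            frames = corrupt_noise(clean, level, seed=seed)
        elif corruption == "occlusion":
            frames = occlude(clean, patch_size=int(level), seed=seed)[0] if level else clean.copy()
        else:
            raise ValueError(f"unknown corruption {corruption!r}")
        sq = 0.0
        n = 0
        for k, (x_prev, x_t, i_td) in enumerate(sequence.triples(frames=frames)):
            a = forward_step(x_prev - center, x_t - center, i_td, weights)
            if route == "l23":
                recon = weights.W_decoder @ a.zhat_l5
            else:
                recon = a.xhat
            target = clean[k + 1] - center
            sq += float(np.mean((recon - target) ** 2))
            n += 1
        rows.append({"level": level, "mse": sq / n, "route": route})
    return pd.DataFrame(rows)


def denoising_autoencoder_baseline(
    frames: np.ndarray,
    levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
    hidden: int = 128,
    max_iter: int = 60,
) -> pd.DataFrame:
    """Single-hidden-layer autoencoder trained explicitly to denoise.

    Trained on (corrupted -> clean) pairs pooled over all levels; its
    residual curve is the near-optimal reference for the circuit's implicit
    denoising.
    """
    rng = np.random.default_rng(seed)
    X, Y = [], []
    for level in levels:
        X.append(corrupt_noise(frames, level, seed=int(rng.integers(2**31))))
        Y.append(frames)
    X = np.vstack(X)
    Y = np.vstack(Y)
    net = MLPRegressor(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        max_iter=max_iter,
        random_state=seed,
    )
    net.fit(X, Y)
    rows = []
    for level in levels:
        corrupted = corrupt_noise(frames, level, seed=seed + 12345)
        pred = net.predict(corrupted)
        rows.append(
            {"level": level, "mse": float(np.mean((pred - frames) ** 2)), "route": "dae"}
        )
    return pd.DataFrame(rows)


def across_stimulus_variance(activations: np.ndarray) -> float:
    """Mean per-neuron variance across stimuli; near zero under collapse."""
    return float(np.asarray(activations).var(axis=0).mean())
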