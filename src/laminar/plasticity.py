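"""Costs and learning rules of the self-supervised microcircuit.

The circuit minimises a joint cost

    C_total = lambda_p * C_pred + lambda_r * C_recon

where ``C_pred = 1/2 ||W_l23_l5 @ z_l23 - z_l5||^2`` is the temporal
self-supervised cost (L2/3's prediction of the latent L5 encoding of the
incoming input, against L5's actual activity) and
``C_recon = 1/2 ||x_t - W_decoder @ z_l5||^2`` is a reconstruction cost on
L5 alone that prevents representational collapse.

All updates are manually specified gradients with one deliberate deviation
from plain gradient descent: the reconstruction gradient is *blocked* from
every matrix upstream of L5 (W_l23_l5, W_l4_l23, W_thal_l4, W_td_l23), so
the L2/3 pathway learns only from prediction error.  The error reaching
L2/3 travels through an explicit feedback pathway which can be the live
transpose of the forward weights (weight mirroring), a fixed random matrix
(feedback alignment), or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import (
    KnockoutFlags,
    MicrocircuitWeights,
    StepActivations,
    dsigmoid_from_z,
    forward_step,
)


@dataclass
class LearningConfig:
    """Hyperparameters of the plasticity rules.

    lambda_p, lambda_r : scales of the predictive and reconstruction costs.
    eta : learning rate.
    optimizer : ``"adam"`` or ``"sgd"``.
    literal_eq9 : if True, the thalamus->L5 update drops the sigmoid
        derivative factor, reproducing a published closed form that omits
        it; the default keeps the factor so the update matches the true
        gradient (finite-difference validated).
    """

    lambda_p: float = 1.0
    lambda_r: float = 1.0
    eta: float = 1e-3
    optimizer: str = "adam"
    literal_eq9: bool = False

    def __post_init__(self) -> None:
        if self.lambda_p < 0 or self.lambda_r < 0:
            raise ValueError("cost scales must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeedbackSpec:
    """Configuration of the L5->L2/3 error-feedback pathway.

    ``p_connectivity`` applies only to the feedback matrix (entries are
    removed with probability 1 - p); forward connections stay dense.
    """

    mode: str = "symmetric"
    p_connectivity: float = 1.0
    mask_seed: int = 0
    random_scale: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "random", "none"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if not 0.0 <= self.p_connectivity <= 1.0:
            raise ValueError("p_connectivity must lie in [0, 1]")


def make_feedback(weights: MicrocircuitWeights, spec: FeedbackSpec) -> np.ndarray:
    """Configure the feedback pathway on ``weights`` and return the matrix.

    In ``random`` mode a Gaussian matrix is drawn once (fan-in scaled unless
    ``random_scale`` overrides); a Bernoulli(p_connectivity) mask is drawn
    once and fixed thereafter.
    """
    weights.feedback_mode = spec.mode
    weights.mask_seed = spec.mask_seed
    rng = np.random.default_rng(spec.mask_seed)
    if spec.mode == "random":
        scale = spec.random_scale
        if scale is None:
            scale = 1.0 / np.sqrt(weights.n_l5)
        weights.W_feedback_fixed = rng.normal(
            0.0, scale, size=(weights.n_l23, weights.n_l5)
        )
    else:
        weights.W_feedback_fixed = None
    if spec.p_connectivity < 1.0:
        weights.feedback_mask = (
            rng.random((weights.n_l23, weights.n_l5)) < spec.p_connectivity
        ).astype(float)
    else:
        weights.feedback_mask = None
    return weights.W_feedback


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

@dataclass
class CostBreakdown:
    c_pred: float
    c_recon: float
    c_total: float
    lambda_p: float
    lambda_r: float

    @classmethod
    def from_acts(cls, acts: StepActivations, config: LearningConfig) -> "CostBreakdown":
        cp = predictive_cost(acts)
        cr = reconstruction_cost(acts)
        return cls(
            c_pred=cp,
            c_recon=cr,
            c_total=config.lambda_p * cp + config.lambda_r * cr,
            lambda_p=config.lambda_p,
            lambda_r=config.lambda_r,
        )


def predictive_cost(acts: StepActivations) -> float:
    """1/2 sum_i (zhat_l5_i - z_l5_i)^2."""
    d = acts.zhat_l5 - acts.z_l5
    return 0.5 * float(d @ d)


def reconstruction_cost(acts: StepActivations) -> float:
    """1/2 sum_j (x_t_j - xhat_j)^2."""
    d = acts.x_t - acts.xhat
    return 0.5 * float(d @ d)


# ---------------------------------------------------------------------------
# error signals (mismatch-error proxies)
# ---------------------------------------------------------------------------

def l5_error_signal(
    acts: StepActivations, weights: MicrocircuitWeights, config: LearningConfig
) -> np.ndarray:
    """dC_total/dz_l5: -lambda_p (zhat - z_l5) - lambda_r W_decoder^T (x - xhat)."""
    e = acts.zhat_l5 - acts.z_l5
    r = acts.x_t - acts.xhat
    return -config.lambda_p * e - config.lambda_r * (weights.W_decoder.T @ r)


def l23_error_signal(
    acts: StepActivations, weights: MicrocircuitWeights, config: LearningConfig
) -> np.ndarray:
    """dC_total/dz_l23 with the reconstruction term blocked by construction.

    Equals [W_l23_l5 - alpha diag(s'(u_l5)) W_l23_l5]^T applied to the
    prediction error lambda_p (zhat - z_l5): the direct route through the
    prediction minus the indirect route through L5's dendritic drive.
    """
    e = config.lambda_p * (acts.zhat_l5 - acts.z_l5)
    gate = 1.0 - weights.alpha * dsigmoid_from_z(acts.z_l5)
    return weights.W_l23_l5.T @ (e * gate)


# ---------------------------------------------------------------------------
# raw gradients (dC/dW, with reconstruction blocking)
# ---------------------------------------------------------------------------

def _l23_delta(
    acts: StepActivations,
    weights: MicrocircuitWeights,
    config: LearningConfig,
    flags: KnockoutFlags,
) -> np.ndarray:
    """Error at L2/3 somata (dC/du_l23) routed through the feedback pathway."""
    if flags.ko_l23_l5:
        return np.zeros(weights.n_l23)
    e = config.lambda_p * (acts.zhat_l5 - acts.z_l5)
    gate = 1.0 - weights.alpha * dsigmoid_from_z(acts.z_l5)
    back = weights.W_feedback @ (e * gate)
    return back * dsigmoid_from_z(acts.z_l23)


def raw_gradients(
    acts: StepActivations,
    weights: MicrocircuitWeights,
    config: LearningConfig,
    flags: KnockoutFlags | None = None,
) -> dict[str, np.ndarray]:
    """All six dC/dW matrices with the blocking rules applied.

    The reconstruction gradient reaches only W_thal_l5 and W_decoder; the
    L2/3-pathway matrices see the prediction error alone, routed through
    whatever feedback pathway ``weights`` carries.  Knocked-out connections
    receive zero updates.
    """
    flags = flags or KnockoutFlags()
    sd5 = dsigmoid_from_z(acts.z_l5)
    e = acts.zhat_l5 - acts.z_l5
    grads: dict[str, np.ndarray] = {}

    # W_l23_l5: prediction error through both the readout and L5's drive
    if flags.ko_l23_l5:
        grads["W_l23_l5"] = np.zeros_like(weights.W_l23_l5)
    else:
        gate = 1.0 - weights.alpha * sd5
        grads["W_l23_l5"] = config.lambda_p * np.outer(e * gate, acts.z_l23)

    delta23 = _l23_delta(acts, weights, config, flags)

    if flags.ko_l4_l23:
        grads["W_l4_l23"] = np.zeros_like(weights.W_l4_l23)
        delta4 = np.zeros(weights.n_l4)
    else:
        grads["W_l4_l23"] = np.outer(delta23, acts.z_l4)
        delta4 = (weights.W_l4_l23.T @ delta23) * dsigmoid_from_z(acts.z_l4)

    x_l4 = acts.x_t if flags.ko_delay else acts.x_prev
    grads["W_thal_l4"] = np.outer(delta4, x_l4)

    if flags.ko_topdown:
        grads["W_td_l23"] = np.zeros_like(weights.W_td_l23)
    else:
        grads["W_td_l23"] = np.outer(delta23, acts.i_td)

    # W_thal_l5: full cost (prediction + reconstruction)
    if flags.ko_thal_l5:
        grads["W_thal_l5"] = np.zeros_like(weights.W_thal_l5)
    else:
        # with the L2/3->L5 projection removed there is no prediction to
        # compare against, so only the reconstruction error remains
        err5 = np.zeros_like(e) if flags.ko_l23_l5 else -config.lambda_p * e
        err5 = err5 - config.lambda_r * (weights.W_decoder.T @ (acts.x_t - acts.xhat))
        if not config.literal_eq9:
            err5 = err5 * sd5
        grads["W_thal_l5"] = np.outer(err5, acts.x_t)

    grads["W_decoder"] = config.lambda_r * np.outer(acts.xhat - acts.x_t, acts.z_l5)
    return grads


# public single-matrix update rules (already scaled by -eta)

def grad_w_l23_l5(
    acts: StepActivations, weights: MicrocircuitWeights, config: LearningConfig
) -> np.ndarray:
    """Update of the L2/3->L5 prediction weights: -eta lambda_p
    outer(e * (1 - alpha s'(u_l5)), z_l23), reconstruction blocked."""
    return -config.eta * raw_gradients(acts, weights, config)["W_l23_l5"]


def grad_w_l4_l23(
    acts: StepActivations,
    weights: MicrocircuitWeights,
    config: LearningConfig,
    feedback: FeedbackSpec | None = None,
) -> np.ndarray:
    """Update of the L4->L2/3 weights via the feedback pathway.

    If a FeedbackSpec is given the pathway is (re)built first; with mode
    ``none`` the update is exactly zero.
    """
    if feedback is not None:
        make_feedback(weights, feedback)
    return -config.eta * raw_gradients(acts, weights, config)["W_l4_l23"]


def grad_w_thal_l5(
    acts: StepActivations, weights: MicrocircuitWeights, config: LearningConfig
) -> np.ndarray:
    """Update of the thalamus->L5 weights from the full (pred + recon) error."""
    return -config.eta * raw_gradients(acts, weights, config)["W_thal_l5"]


def grad_upstream(
    acts: StepActivations,
    weights: MicrocircuitWeights,
    config: LearningConfig,
    feedback: FeedbackSpec | None = None,
) -> dict[str, np.ndarray]:
    """Updates for W_thal_l4, W_td_l23 (chain rule through the L2/3 error)
    and W_decoder (reconstruction readout)."""
    if feedback is not None:
        make_feedback(weights, feedback)
    g = raw_gradients(acts, weights, config)
    return {k: -config.eta * g[k] for k in ("W_thal_l4", "W_td_l23", "W_decoder")}


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

try:  # fused elementwise kernel; the update is memory-bound in pure numpy
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_kernel(W, g, m, v, eta, b1, b2, bc1, bc2, eps):  # pragma: no cover
        for i in range(W.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            W[i] -= eta * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class _Adam:
    """Per-matrix Adam accumulators (beta1=0.9, beta2=0.999)."""

    def __init__(self, names, shapes, eta, beta1=0.9, beta2=0.999, eps=1e-8):
        self.eta, self.beta1, self.beta2, self.eps = eta, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros(s) for n, s in zip(names, shapes)}
        self.v = {n: np.zeros(s) for n, s in zip(names, shapes)}

    def step(self, weights: MicrocircuitWeights, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, g in grads.items():
            m, v = self.m[name], self.v[name]
            W = getattr(weights, name)
            if _HAVE_NUMBA:
                _adam_kernel(
                    W.ravel(), np.ascontiguousarray(g).ravel(), m.ravel(),
                    v.ravel(), self.eta, b1, b2, bc1, bc2, self.eps,
                )
            else:
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * np.square(g)
                W -= self.eta * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class _SGD:
    def __init__(self, eta):
        self.eta = eta

    def step(self, weights, grads):
        for name, g in grads.items():
            getattr(weights, name)[...] -= self.eta * g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    weights: MicrocircuitWeights
    costs: pd.DataFrame  # columns: step, c_pred, c_recon, c_total


def train(
    weights: MicrocircuitWeights,
    stream,
    config: LearningConfig | None = None,
    flags: KnockoutFlags | None = None,
    record_every: int = 10,
    nonneg: tuple[str, ...] = (),
) -> TrainResult:
    """Online training over a stream of ``(x_prev, x_t, i_td)`` triples.

    Weights are updated in place, one gradient step per timestep; the cost
    trajectory is recorded every ``record_every`` steps.  A non-finite cost
    aborts with a diagnostic.  Matrices named in ``nonneg`` are kept
    non-negative by projection after every update (Dale-type sign
    constraint for excitatory pathways).
    """
    config = config or LearningConfig()
    flags = flags or KnockoutFlags()
    shapes = [getattr(weights, n).shape for n in weights.TRAINABLE]
    if config.optimizer == "adam":
        opt = _Adam(weights.TRAINABLE, shapes, config.eta)
    else:
        opt = _SGD(config.eta)

    steps, cps, crs, cts = [], [], [], []
    for step, (x_prev, x_t, i_td) in enumerate(stream):
        acts = forward_step(x_prev, x_t, i_td, weights, flags)
        grads = raw_gradients(acts, weights, config, flags)
        opt.step(weights, grads)
        for name in nonneg:
            W = getattr(weights, name)
            np.clip(W, 0.0, None, out=W)
        if step % record_every == 0:
            cp = predictive_cost(acts)
            cr = reconstruction_cost(acts)
            ct = config.lambda_p * cp + config.lambda_r * cr
            if not np.isfinite(ct):
                raise RuntimeError(
                    f"training diverged at step {step}: "
                    f"c_pred={cp:.3g}, c_recon={cr:.3g}"
                )
            steps.append(step)
            cps.append(cp)
            crs.append(cr)
            cts.append(ct)
    costs = pd.DataFrame(
        {"step": steps, "c_pred": cps, "c_recon": crs, "c_total": cts}
    )
    return TrainResult(weights=weights, costs=costs)


# ---------------------------------------------------------------------------
# plasticity-curve experiment
# ---------------------------------------------------------------------------

def plasticity_curve(
    n_samples: int = 200,
    seed: int = 0,
    n_l23: int = 10,
    eta: float = 1e-3,
    alpha: float = 0.3,
    lambda_p: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Mean L2/3->L5 weight update as a function of postsynaptic L5 activity.

    For randomly drawn presynaptic L2/3 activity and postsynaptic L5 rates,
    the update rule produces depression at low L5 activity and potentiation
    at high activity; the returned slope of a linear fit is positive.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        z23 = rng.uniform(0.1, 0.9, size=n_l23)
        # non-negative presynaptic weights so the sampled predictions span
        # the (0, 1) activity range like real L5 targets
        w_row = rng.uniform(0.0, 2.0 / n_l23, size=(1, n_l23))
        z5 = rng.uniform(0.05, 0.95, size=1)
        u5 = np.log(z5 / (1.0 - z5))  # consistent pre-activation
        e = (w_row @ z23) - z5
        gate = 1.0 - alpha * z5 * (1.0 - z5)
        dw = -eta * lambda_p * np.outer(e * gate, z23)
        rows.append({"z_l5": float(z5[0]), "mean_update": float(dw.mean())})
    table = pd.DataFrame(rows)
    slope = float(np.polyfit(table["z_l5"], table["mean_update"], 1)[0])
    return table, slope
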