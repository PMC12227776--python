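"""Forward dynamics of the three-layer cortical microcircuit.

The circuit mirrors the laminar organisation of a sensory cortical column:
thalamic input reaches layer 4 (L4) and, in parallel, layer 5 (L5); layer 2/3
(L2/3) integrates the *delayed* L4 encoding of the previous input with
top-down context and projects to L5.  All units are rate neurons with a
logistic nonlinearity and no bias terms:

    z_L4(t-1)  = sigma(W_thal_l4 @ x(t-1))
    z_L2/3(t)  = sigma(W_l4_l23 @ z_L4(t-1) + W_td_l23 @ i_td(t))
    z_L5(t)    = sigma(alpha * W_l23_l5 @ z_L2/3(t) + W_thal_l5 @ x(t))

where ``alpha`` models dendritic-to-somatic attenuation of the L2/3 drive.
Two linear readouts are defined on top of the dynamics: the L2/3 *prediction*
of L5 activity, ``zhat_l5 = W_l23_l5 @ z_l23`` (raw product, neither
attenuated nor squashed), and the L5 *reconstruction* of its own thalamic
input, ``xhat = W_decoder @ z_l5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.special import expit as sigmoid


def dsigmoid_from_z(z: np.ndarray) -> np.ndarray:
    """Derivative of the logistic sigmoid expressed through its output."""
    return z * (1.0 - z)


def _check_shape(name: str, W: np.ndarray, v: np.ndarray) -> None:
    if W.shape[1] != v.shape[0]:
        raise ValueError(
            f"shape mismatch: {name} has shape {W.shape} but operand has "
            f"length {v.shape[0]}"
        )


@dataclass
class KnockoutFlags:
    """Switches that silence individual circuit components.

    All flags ``False`` corresponds to the intact model.  ``ko_delay``
    replaces the L4-mediated one-step delay by feeding L2/3 the L4 encoding
    of the *current* input.
    """

    ko_l23_l5: bool = False
    ko_thal_l5: bool = False
    ko_topdown: bool = False
    ko_delay: bool = False
    ko_l4_l23: bool = False

    @classmethod
    def from_name(cls, name: str) -> "KnockoutFlags":
        """Build flags from a registry name (``"none"`` = intact)."""
        if name in ("none", "intact", ""):
            return cls()
        valid = {"ko_l23_l5", "ko_thal_l5", "ko_topdown", "ko_delay", "ko_l4_l23"}
        if name not in valid:
            raise ValueError(f"unknown knockout {name!r}; valid: {sorted(valid)}")
        return cls(**{name: True})


@dataclass
class MicrocircuitWeights:
    """All trainable matrices plus the attenuation constant and feedback
    configuration; the model's state.

    ``feedback_mode`` selects how the L5->L2/3 error pathway is built:
    ``symmetric`` uses the live transpose of ``W_l23_l5`` (weight mirroring),
    ``random`` a fixed Gaussian matrix drawn once (feedback alignment), and
    ``none`` an all-zero pathway.  An optional Bernoulli mask models feedback
    connection probability; forward connections are always dense.
    """

    W_thal_l4: np.ndarray
    W_l4_l23: np.ndarray
    W_td_l23: np.ndarray
    W_l23_l5: np.ndarray
    W_thal_l5: np.ndarray
    W_decoder: np.ndarray
    alpha: float = 0.3
    feedback_mode: str = "symmetric"
    W_feedback_fixed: np.ndarray | None = None
    feedback_mask: np.ndarray | None = None
    mask_seed: int | None = None

    TRAINABLE = (
        "W_thal_l4",
        "W_l4_l23",
        "W_td_l23",
        "W_l23_l5",
        "W_thal_l5",
        "W_decoder",
    )

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be strictly positive")
        if self.feedback_mode not in ("symmetric", "random", "none"):
            raise ValueError(f"unknown feedback_mode {self.feedback_mode!r}")
        n_l4, n_in = self.W_thal_l4.shape
        n_l23 = self.W_l4_l23.shape[0]
        n_l5 = self.W_l23_l5.shape[0]
        expected = {
            "W_l4_l23": (n_l23, n_l4),
            "W_td_l23": (n_l23, self.W_td_l23.shape[1]),
            "W_l23_l5": (n_l5, n_l23),
            "W_thal_l5": (n_l5, n_in),
            "W_decoder": (n_in, n_l5),
        }
        for name, shape in expected.items():
            W = getattr(self, name)
            if W.shape != shape:
                raise ValueError(
                    f"shape mismatch: {name} has shape {W.shape}, expected {shape}"
                )
        for name in self.TRAINABLE:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    # -- sizes -------------------------------------------------------------
    @property
    def n_in(self) -> int:
        return self.W_thal_l4.shape[1]

    @property
    def n_l4(self) -> int:
        return self.W_thal_l4.shape[0]

    @property
    def n_l23(self) -> int:
        return self.W_l4_l23.shape[0]

    @property
    def n_l5(self) -> int:
        return self.W_l23_l5.shape[0]

    @property
    def n_td(self) -> int:
        return self.W_td_l23.shape[1]

    @property
    def W_feedback(self) -> np.ndarray:
        """Current L5->L2/3 feedback matrix (n_l23 x n_l5).

        In ``symmetric`` mode this is a fresh read of the transpose of the
        current forward weights, never a stale copy.
        """
        if self.feedback_mode == "none":
            B = np.zeros((self.n_l23, self.n_l5))
        elif self.feedback_mode == "symmetric":
            B = self.W_l23_l5.T
        else:
            if self.W_feedback_fixed is None:
                raise ValueError("random feedback requested but no fixed matrix set")
            B = self.W_feedback_fixed
        if self.feedback_mask is not None:
            B = B * self.feedback_mask
        return B

    # -- construction ------------------------------------------------------
    @classmethod
    def initialize(
        cls,
        n_in: int,
        n_l4: int,
        n_l23: int,
        n_l5: int,
        n_td: int,
        alpha: float = 0.3,
        feedback_mode: str = "symmetric",
        seed: int | None = None,
    ) -> "MicrocircuitWeights":
        """Zero-mean Gaussian initialisation scaled by 1/sqrt(fan-in)."""
        rng = np.random.default_rng(seed)

        def draw(n_out: int, n_inp: int) -> np.ndarray:
            return rng.normal(0.0, 1.0 / np.sqrt(n_inp), size=(n_out, n_inp))

        return cls(
            W_thal_l4=draw(n_l4, n_in),
            W_l4_l23=draw(n_l23, n_l4),
            W_td_l23=draw(n_l23, n_td),
            W_l23_l5=draw(n_l5, n_l23),
            W_thal_l5=draw(n_l5, n_in),
            W_decoder=draw(n_in, n_l5),
            alpha=alpha,
            feedback_mode=feedback_mode,
        )

    def copy(self) -> "MicrocircuitWeights":
        return MicrocircuitWeights(
            **{name: getattr(self, name).copy() for name in self.TRAINABLE},
            alpha=self.alpha,
            feedback_mode=self.feedback_mode,
            W_feedback_fixed=(
                None if self.W_feedback_fixed is None else self.W_feedback_fixed.copy()
            ),
            feedback_mask=(
                None if self.feedback_mask is None else self.feedback_mask.copy()
            ),
            mask_seed=self.mask_seed,
        )

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Serialize to HDF5: one dataset per matrix, scalars as attributes.

        Round-trips bit-exactly.
        """
        with h5py.File(path, "w") as f:
            for name in self.TRAINABLE:
                f.create_dataset(name, data=getattr(self, name))
            if self.W_feedback_fixed is not None:
                f.create_dataset("W_feedback_fixed", data=self.W_feedback_fixed)
            if self.feedback_mask is not None:
                f.create_dataset("feedback_mask", data=self.feedback_mask)
            f.attrs["alpha"] = self.alpha
            f.attrs["feedback_mode"] = self.feedback_mode
            if self.mask_seed is not None:
                f.attrs["mask_seed"] = self.mask_seed

    @classmethod
    def load(cls, path) -> "MicrocircuitWeights":
        with h5py.File(path, "r") as f:
            kwargs = {name: f[name][()] for name in cls.TRAINABLE}
            if "W_feedback_fixed" in f:
                kwargs["W_feedback_fixed"] = f["W_feedback_fixed"][()]
            if "feedback_mask" in f:
                kwargs["feedback_mask"] = f["feedback_mask"][()]
            kwargs["alpha"] = float(f.attrs["alpha"])
            kwargs["feedback_mode"] = str(f.attrs["feedback_mode"])
            if "mask_seed" in f.attrs:
                kwargs["mask_seed"] = int(f.attrs["mask_seed"])
        return cls(**kwargs)


@dataclass
class StepActivations:
    """One timestep's activations and derived quantities.

    ``zhat_l5`` is the raw product ``W_l23_l5 @ z_l23`` — unattenuated and
    unsquashed — which is the quantity the predictive cost compares against
    ``z_l5``.  Pre-activations (``u_*``) are kept because the learning rules
    need the sigmoid derivative at the operating point.
    """

    x_prev: np.ndarray
    x_t: np.ndarray
    i_td: np.ndarray
    u_l4: np.ndarray
    z_l4: np.ndarray
    u_l23: np.ndarray
    z_l23: np.ndarray
    u_l5: np.ndarray
    z_l5: np.ndarray
    zhat_l5: np.ndarray
    xhat: np.ndarray


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def l4_encode(x: np.ndarray, weights: MicrocircuitWeights) -> np.ndarray:
    """L4 encoding of a thalamic input: sigma(W_thal_l4 @ x)."""
    _check_shape("W_thal_l4", weights.W_thal_l4, x)
    return sigmoid(weights.W_thal_l4 @ x)


def l23_integrate(
    z_l4_prev: np.ndarray,
    i_td: np.ndarray,
    weights: MicrocircuitWeights,
    flags: KnockoutFlags | None = None,
) -> np.ndarray:
    """L2/3 activation from delayed L4 drive plus top-down context.

    The caller controls whether ``z_l4_prev`` encodes x(t-1) (intact) or
    x(t) (delay knockout).
    """
    flags = flags or KnockoutFlags()
    if flags.ko_l4_l23:
        drive = np.zeros(weights.n_l23)
    else:
        _check_shape("W_l4_l23", weights.W_l4_l23, z_l4_prev)
        drive = weights.W_l4_l23 @ z_l4_prev
    if not flags.ko_topdown:
        _check_shape("W_td_l23", weights.W_td_l23, i_td)
        drive = drive + weights.W_td_l23 @ i_td
    return sigmoid(drive)


def l5_integrate(
    z_l23: np.ndarray,
    x_t: np.ndarray,
    weights: MicrocircuitWeights,
    flags: KnockoutFlags | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L5 pre-activation and activation from attenuated L2/3 drive plus
    direct thalamic input.  Returns ``(u_l5, z_l5)``."""
    flags = flags or KnockoutFlags()
    if flags.ko_l23_l5:
        u = np.zeros(weights.n_l5)
    else:
        _check_shape("W_l23_l5", weights.W_l23_l5, z_l23)
        u = weights.alpha * (weights.W_l23_l5 @ z_l23)
    if not flags.ko_thal_l5:
        _check_shape("W_thal_l5", weights.W_thal_l5, x_t)
        u = u + weights.W_thal_l5 @ x_t
    return u, sigmoid(u)


def predict_l5(z_l23: np.ndarray, weights: MicrocircuitWeights) -> np.ndarray:
    """L2/3's prediction of L5 activity: the raw product W_l23_l5 @ z_l23.

    Deliberately neither alpha-scaled nor squashed — distinct from the L5
    dendritic drive.
    """
    _check_shape("W_l23_l5", weights.W_l23_l5, z_l23)
    return weights.W_l23_l5 @ z_l23


def reconstruct_input(z_l5: np.ndarray, weights: MicrocircuitWeights) -> np.ndarray:
    """Linear readout of L5 reconstructing its thalamic input."""
    _check_shape("W_decoder", weights.W_decoder, z_l5)
    return weights.W_decoder @ z_l5


def forward_step(
    x_prev: np.ndarray,
    x_t: np.ndarray,
    i_td: np.ndarray,
    weights: MicrocircuitWeights,
    flags: KnockoutFlags | None = None,
) -> StepActivations:
    """Run one timestep of the circuit and collect every derived quantity.

    Under ``ko_delay`` L2/3 receives the L4 encoding of x(t) instead of
    x(t-1); everything else follows the intact dynamics.
    """
    flags = flags or KnockoutFlags()
    x_prev = np.asarray(x_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    i_td = np.asarray(i_td, dtype=float)
    if x_prev.shape != x_t.shape:
        raise ValueError("x_prev and x_t must have the same length")

    x_for_l4 = x_t if flags.ko_delay else x_prev
    _check_shape("W_thal_l4", weights.W_thal_l4, x_for_l4)
    u_l4 = weights.W_thal_l4 @ x_for_l4
    z_l4 = sigmoid(u_l4)

    if flags.ko_l4_l23:
        u_l23 = np.zeros(weights.n_l23)
    else:
        u_l23 = weights.W_l4_l23 @ z_l4
    if not flags.ko_topdown:
        _check_shape("W_td_l23", weights.W_td_l23, i_td)
        u_l23 = u_l23 + weights.W_td_l23 @ i_td
    z_l23 = sigmoid(u_l23)

    u_l5, z_l5 = l5_integrate(z_l23, x_t, weights, flags)
    zhat_l5 = predict_l5(z_l23, weights)
    xhat = reconstruct_input(z_l5, weights)

    return StepActivations(
        x_prev=x_prev,
        x_t=x_t,
        i_td=i_td,
        u_l4=u_l4,
        z_l4=z_l4,
        u_l23=u_l23,
        z_l23=z_l23,
        u_l5=u_l5,
        z_l5=z_l5,
        zhat_l5=zhat_l5,
        xhat=xhat,
    )
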