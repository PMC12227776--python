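"""Synthetic stimulus generators.

Two task families drive the microcircuit:

* a contextual Gabor task — 28x28 Gabor patches whose orientation walks on
  an 18-degree grid under a three-valued top-down context (rotate -18, stay,
  rotate +18), with optional corruptions (additive noise, occluding patches,
  positional shifts);
* a visuomotor task — a random-walk locomotion speed paired with a visual
  flow vector coupled to it (linearly or through a sinusoid), with optional
  mismatch windows during which the flow is halted.

All generators are pure functions of their spec, length and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

N_CONTEXTS = 3  # rotate -18 deg, stay, rotate +18 deg


# ---------------------------------------------------------------------------
# Gabor task
# ---------------------------------------------------------------------------

@dataclass
class GaborTaskSpec:
    """Parameters of the contextual Gabor sequence.

    Spatial frequency is drawn per frame from N(freq_mean, freq_sd) in
    cycles/pixel (truncated below at ``freq_min`` to avoid degenerate
    gratings) and the elliptical Gaussian envelope widths per axis from
    U(*envelope_range*) pixels.  Orientations live on a 10-class grid
    0, 18, ..., 162 degrees.
    """

    image_size: int = 28
    freq_mean: float = 0.2
    freq_sd: float = 0.1
    freq_min: float = 0.02
    envelope_range: tuple[float, float] = (3.0, 8.0)
    theta_step: float = 18.0
    n_classes: int = 10
    seed: int = 0

    @property
    def theta_grid(self) -> np.ndarray:
        return np.arange(self.n_classes) * self.theta_step


@dataclass
class GaborSequence:
    """Frames plus the orientation/context bookkeeping of one episode.

    ``context_labels[t]`` (0 = -18 deg, 1 = 0 deg, 2 = +18 deg) is the
    top-down cue sampled at t that determines ``orientation_labels[t+1]``.
    """

    frames: np.ndarray  # (T, image_size**2), values in [0, 1]
    orientation_labels: np.ndarray  # (T,) int class indices
    context_labels: np.ndarray  # (T,) int in {0, 1, 2}
    spec: GaborTaskSpec

    def __len__(self) -> int:
        return self.frames.shape[0]

    def context_onehot(self, t: int) -> np.ndarray:
        v = np.zeros(N_CONTEXTS)
        v[self.context_labels[t]] = 1.0
        return v

    def triples(self, frames: np.ndarray | None = None):
        """Yield ``(x_prev, x_t, i_td)`` training triples.

        The top-down input at step t is the context sampled at t-1, i.e. the
        cue that generated the transition to the current frame.  Passing
        ``frames`` substitutes corrupted frames while keeping the labels.
        """
        F = self.frames if frames is None else frames
        eye = np.eye(N_CONTEXTS)
        for t in range(1, len(self)):
            yield F[t - 1], F[t], eye[self.context_labels[t - 1]]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames)
            f.create_dataset("orientation_labels", data=self.orientation_labels)
            f.create_dataset("context_labels", data=self.context_labels)
            f.attrs["spec_json"] = json.dumps(asdict(self.spec))

    @classmethod
    def load(cls, path) -> "GaborSequence":
        with h5py.File(path, "r") as f:
            spec_dict = json.loads(f.attrs["spec_json"])
            spec_dict["envelope_range"] = tuple(spec_dict["envelope_range"])
            return cls(
                frames=f["frames"][()],
                orientation_labels=f["orientation_labels"][()],
                context_labels=f["context_labels"][()],
                spec=GaborTaskSpec(**spec_dict),
            )


def render_gabor(
    theta: float,
    freq: float,
    sigma_x: float,
    sigma_y: float,
    size: int = 28,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render one Gabor patch as a flat image vector rescaled to [0, 1].

    An oriented cosine grating (phase 0) under an elliptical Gaussian
    envelope, centred unless ``center`` overrides.  Deterministic in its
    arguments; because the carrier is even, theta and theta+180 produce the
    same image.
    """
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("envelope sigmas must be positive")
    if center is None:
        c = (size - 1) / 2.0
        center = (c, c)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xx -= center[0]
    yy -= center[1]
    th = np.deg2rad(theta)
    xr = xx * np.cos(th) + yy * np.sin(th)
    yr = -xx * np.sin(th) + yy * np.cos(th)
    img = np.exp(-0.5 * ((xr / sigma_x) ** 2 + (yr / sigma_y) ** 2)) * np.cos(
        2.0 * np.pi * freq * xr
    )
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img.ravel()


def admissible_contexts(label: int, n_classes: int) -> np.ndarray:
    """Context indices allowed at a boundary-aware orientation class."""
    out = []
    for ctx, shift in enumerate((-1, 0, 1)):
        if 0 <= label + shift < n_classes:
            out.append(ctx)
    return np.asarray(out)


def _draw_frame_params(spec: GaborTaskSpec, rng: np.random.Generator):
    freq = max(rng.normal(spec.freq_mean, spec.freq_sd), spec.freq_min)
    sx = rng.uniform(*spec.envelope_range)
    sy = rng.uniform(*spec.envelope_range)
    return freq, sx, sy


def gabor_sequence(
    spec: GaborTaskSpec,
    T: int,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
) -> GaborSequence:
    """Generate a contextual Gabor episode of length ``T``.

    The orientation class performs a context-driven walk on the grid; at the
    boundary classes the context is resampled uniformly from the two
    admissible options.  Frequency and envelope are redrawn per frame.
    """
    if T < 2:
        raise ValueError("sequence length must be >= 2")
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_classes
    labels = np.empty(T, dtype=int)
    contexts = np.empty(T, dtype=int)
    frames = np.empty((T, spec.image_size**2))

    labels[0] = rng.integers(n)
    for t in range(T):
        freq, sx, sy = _draw_frame_params(spec, rng)
        center = None if centers is None else tuple(centers[t])
        frames[t] = render_gabor(
            labels[t] * spec.theta_step, freq, sx, sy, spec.image_size, center
        )
        ctx = rng.choice(admissible_contexts(labels[t], n))
        contexts[t] = ctx
        if t + 1 < T:
            labels[t + 1] = labels[t] + (ctx - 1)
    return GaborSequence(frames, labels, contexts, spec)


def corrupt_noise(
    frames: np.ndarray, noise_level: float, seed: int = 0
) -> np.ndarray:
    """Additive Gaussian corruption x* = x + level * eps, eps ~ N(0, I)."""
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    if noise_level == 0:
        return frames.copy()
    rng = np.random.default_rng(seed)
    return frames + noise_level * rng.standard_normal(frames.shape)


def occlude(
    frames: np.ndarray, patch_size: int = 10, seed: int = 0, image_size: int = 28
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out one uniformly placed square patch per frame.

    Returns the corrupted frames and the (row, col) patch corners.
    """
    if patch_size > image_size:
        raise ValueError("patch larger than image")
    rng = np.random.default_rng(seed)
    out = frames.reshape(-1, image_size, image_size).copy()
    hi = image_size - patch_size + 1
    coords = rng.integers(0, hi, size=(out.shape[0], 2))
    for k, (r, c) in enumerate(coords):
        out[k, r : r + patch_size, c : c + patch_size] = 0.0
    return out.reshape(frames.shape[0], -1), coords


def shift_position(
    spec: GaborTaskSpec, T: int, shift_range: float, seed: int | None = None
) -> GaborSequence:
    """Gabor sequence with the patch centre jittered uniformly per frame.

    ``shift_range`` is the maximum displacement (pixels) along each axis;
    label bookkeeping is identical to :func:`gabor_sequence`.
    """
    c = (spec.image_size - 1) / 2.0
    if shift_range < 0 or c - shift_range < 0:
        raise ValueError("shift_range keeps the centre off the canvas")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if shift_range == 0:
        return gabor_sequence(spec, T, rng)
    # draw centres from a separate stream so labels stay comparable
    centers = c + np.random.default_rng(
        (spec.seed if seed is None else seed) + 1
    ).uniform(-shift_range, shift_range, size=(T, 2))
    return gabor_sequence(spec, T, rng, centers=centers)


# ---------------------------------------------------------------------------
# visuomotor task
# ---------------------------------------------------------------------------

@dataclass
class VisuomotorSpec:
    """Parameters of the visuomotor stream.

    Speed follows a random walk with increments drawn uniformly from
    {-1, 0, +1}, reflected into [0, speed_max] (locomotion speed is a
    bounded magnitude).  Flow is f(speed) broadcast over ``n_dims`` plus
    Gaussian noise; in mismatch windows (closed loop) the flow is forced to
    exactly zero for ``mismatch_len`` consecutive steps.  In open-loop mode
    the flow is driven by an independent random walk, decoupled from speed.
    """

    n_dims: int = 10
    coupling: str = "linear"  # or "sine"
    noise_sd: float = 0.1
    walk_step: float = 1.0
    speed_max: float = 8.0
    mismatch_len: int = 600
    mismatch_rate: float = 0.0005
    loop_mode: str = "closed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling not in ("linear", "sine"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.loop_mode not in ("closed", "open"):
            raise ValueError(f"unknown loop_mode {self.loop_mode!r}")

    def f(self, s: np.ndarray) -> np.ndarray:
        return np.sin(s) if self.coupling == "sine" else s


@dataclass
class VisuomotorStream:
    """Speed trace, flow vectors and mismatch-window annotations."""

    speed: np.ndarray  # (T,)
    flow: np.ndarray  # (T, n_dims)
    mismatch_mask: np.ndarray  # (T,) bool
    spec: VisuomotorSpec
    baseline_exclude: np.ndarray | None = None  # extra steps unfit as baseline

    def __len__(self) -> int:
        return self.speed.shape[0]

    def triples(self):
        """Yield ``(x_prev, x_t, i_td)`` with the speed as top-down input."""
        for t in range(1, len(self)):
            yield self.flow[t - 1], self.flow[t], np.array([self.speed[t]])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("speed", data=self.speed)
            f.create_dataset("flow", data=self.flow)
            f.create_dataset("mismatch_mask", data=self.mismatch_mask)
            if self.baseline_exclude is not None:
                f.create_dataset("baseline_exclude", data=self.baseline_exclude)
            f.attrs["spec_json"] = json.dumps(asdict(self.spec))


def _random_walk(
    T: int, rng: np.random.Generator, step: float, s_max: float
) -> np.ndarray:
    s = np.empty(T)
    s[0] = rng.uniform(0, s_max)
    incs = rng.integers(-1, 2, size=T - 1) * step
    for t in range(1, T):
        v = s[t - 1] + incs[t - 1]
        # reflect into [0, s_max]
        if v < 0:
            v = -v
        elif v > s_max:
            v = 2 * s_max - v
        s[t] = v
    return s


def _draw_windows(
    T: int, length: int, rate: float, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping window starts with >= length gap between windows."""
    starts: list[int] = []
    t = length  # leave a clean head segment
    while t < T - length:
        if rng.random() < rate:
            starts.append(t)
            t += 2 * length  # window plus a clean gap
        else:
            t += 1
    return starts


def visuomotor_stream(spec: VisuomotorSpec, T: int) -> VisuomotorStream:
    """Generate a visuomotor stream of length ``T``.

    Closed loop: flow = f(speed) + noise outside mismatch windows and
    exactly zero inside.  Open loop: flow is driven by an independent
    random walk; mismatch windows are flow-on probes, each preceded by a
    zero-flow stretch of the same length (marked in ``baseline_exclude``).
    """
    if T <= spec.mismatch_len:
        raise ValueError("T must exceed mismatch_len")
    rng = np.random.default_rng(spec.seed)
    speed = _random_walk(T, rng, spec.walk_step, spec.speed_max)
    noise = spec.noise_sd * rng.standard_normal((T, spec.n_dims))
    mask = np.zeros(T, dtype=bool)
    starts = _draw_windows(T, spec.mismatch_len, spec.mismatch_rate, rng)

    if spec.loop_mode == "closed":
        flow = spec.f(speed)[:, None] + noise
        for s0 in starts:
            mask[s0 : s0 + spec.mismatch_len] = True
        flow[mask] = 0.0
        return VisuomotorStream(speed, flow, mask, spec)

    # open loop: flow decoupled from locomotion
    indep = _random_walk(T, rng, spec.walk_step, spec.speed_max)
    flow = spec.f(indep)[:, None] + noise
    exclude = np.zeros(T, dtype=bool)
    for s0 in starts:
        pre = max(0, s0 - spec.mismatch_len)
        flow[pre:s0] = 0.0  # zero-flow stretch before the probe
        exclude[pre:s0] = True
        mask[s0 : s0 + spec.mismatch_len] = True
    return VisuomotorStream(speed, flow, mask, spec, baseline_exclude=exclude)
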