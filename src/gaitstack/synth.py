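"""Synthetic rider-motion generator for the four horse gaits.

Real rider recordings come from a full-body inertial motion-capture suit and
are not publicly deposited, so this module emulates their statistical
structure: each of the 8 channels (hip height, backbone angle, elbow/knee
joint angles, elbow/knee distances) oscillates periodically with the horse's
stride, with a gait-specific cycle length and amplitude range, plus additive
Gaussian sensor noise.

Amplitude ranges for rising trot and canter follow the expert-rider
reference min/max table for those two gaits; walk and sitting trot are
documented constants chosen so the four classes overlap but remain
distinguishable (walk has the smallest amplitude spans and the longest
cycle, canter the shortest cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "GAIT_NAMES",
    "GaitSpec",
    "MotionRecording",
    "default_gait_specs",
    "generate_recording",
    "generate_dataset",
]

#: Fixed channel order used by every recording and feature table.
CHANNEL_NAMES: tuple[str, ...] = (
    "hip_y",
    "backbone_angle",
    "right_elbow_angle",
    "left_elbow_angle",
    "right_knee_angle",
    "left_knee_angle",
    "elbow_distance",
    "knee_distance",
)

#: The four gait classes, in canonical order.
GAIT_NAMES: tuple[str, ...] = ("walk", "sitting_trot", "rising_trot", "canter")

#: Fixed per-channel phase offsets (radians). Left/right joint angles are in
#: antiphase, as they are for a rider posting or absorbing the stride.
_PHASE_OFFSETS: tuple[float, ...] = (
    0.0,
    0.5,
    1.0,
    1.0 + np.pi,
    1.5,
    1.5 + np.pi,
    2.0,
    2.5,
)

#: Default harmonic mixture: a dominant fundamental plus two weaker
#: overtones, mimicking the non-sinusoidal but strongly periodic joint traces
#: of a rider.
_DEFAULT_HARMONICS: tuple[float, ...] = (1.0, 0.35, 0.15)

#: Fraction of each channel's half-span used as the default noise s.d.
_NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class GaitSpec:
    """Parameters of the periodic signal model for one gait.

    Parameters
    ----------
    gait_name
        One of :data:`GAIT_NAMES`.
    period_frames
        Fundamental cycle length in frames (no wall-clock rate is modelled).
    channel_bounds
        Mapping channel name -> (min, max) in the channel's native units
        (cm for hip height and the two distances, degrees for angles).
    harmonic_weights
        Nonnegative weights of harmonics 1, 2, ... of the fundamental.
    noise_std
        Per-channel additive Gaussian noise s.d., same order as
        :data:`CHANNEL_NAMES`.
    phase_offsets
        Per-channel phase in [0, 2*pi).
    """

    gait_name: str
    period_frames: int
    channel_bounds: dict[str, tuple[float, float]]
    harmonic_weights: tuple[float, ...] = _DEFAULT_HARMONICS
    noise_std: tuple[float, ...] = ()
    phase_offsets: tuple[float, ...] = field(
        default_factory=lambda: tuple(p % (2 * np.pi) for p in _PHASE_OFFSETS)
    )

    def __post_init__(self) -> None:
        if self.gait_name not in GAIT_NAMES:
            raise ValueError(f"unknown gait {self.gait_name!r}")
        if self.period_frames <= 0:
            raise ValueError("period_frames must be positive")
        if set(self.channel_bounds) != set(CHANNEL_NAMES):
            raise ValueError("channel_bounds must cover exactly the 8 channels")
        for name, (lo, hi) in self.channel_bounds.items():
            if not lo < hi:
                raise ValueError(f"channel {name}: min must be < max, got ({lo}, {hi})")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic_weights must be nonnegative")
        if not self.noise_std:
            object.__setattr__(
                self,
                "noise_std",
                tuple(
                    _NOISE_FRACTION * (hi - lo) / 2.0
                    for lo, hi in (self.channel_bounds[c] for c in CHANNEL_NAMES)
                ),
            )
        if any(s < 0 for s in self.noise_std):
            raise ValueError("noise_std must be nonnegative")


@dataclass(frozen=True)
class MotionRecording:
    """A frames x 8 rider-motion time series with its gait label."""

    values: np.ndarray
    gait_label: str
    seed: int
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(CHANNEL_NAMES):
            raise ValueError("values must be a frames x 8 matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


# Rising-trot and canter bounds as printed for the expert rider; the canter
# elbow-distance pair appears transposed in print (min > max) and is swapped.
_RISING_TROT_BOUNDS: dict[str, tuple[float, float]] = {
    "hip_y": (32.08, 38.79),
    "backbone_angle": (171.39, 176.47),
    "right_elbow_angle": (127.59, 151.82),
    "left_elbow_angle": (127.59, 151.82),
    "right_knee_angle": (123.92, 172.20),
    "left_knee_angle": (123.92, 172.20),
    "elbow_distance": (23.02, 27.02),
    "knee_distance": (14.93, 16.42),
}

_CANTER_BOUNDS: dict[str, tuple[float, float]] = {
    "hip_y": (31.87, 38.31),
    "backbone_angle": (170.77, 176.34),
    "right_elbow_angle": (124.98, 159.24),
    "left_elbow_angle": (124.98, 159.24),
    "right_knee_angle": (119.50, 135.80),
    "left_knee_angle": (119.50, 135.80),
    "elbow_distance": (25.78, 25.87),
    "knee_distance": (15.52, 18.59),
}

# Walk and sitting trot are not tabulated for the expert rider. They are
# fixed as scaled variants of the rising-trot ranges: walk keeps the
# rising-trot midpoint with 35% of the span — capped per channel by 35% of
# the canter span so walk always has the smallest amplitudes of the four
# gaits; sitting trot sits slightly below the midpoint with 60% of the span.
_WALK_SPAN_FRACTION = 0.35
_SITTING_SPAN_FRACTION = 0.60
_SITTING_CENTER_SHIFT = -0.05  # fraction of the rising-trot span

#: Default fundamental cycle lengths (frames). Canter is the shortest and
#: walk the longest, matching the qualitative ordering of real strides.
DEFAULT_PERIODS: dict[str, int] = {
    "walk": 120,
    "sitting_trot": 70,
    "rising_trot": 60,
    "canter": 45,
}


def _scaled_bounds(
    base: dict[str, tuple[float, float]], span_fraction: float, center_shift: float
) -> dict[str, tuple[float, float]]:
    out = {}
    for name, (lo, hi) in base.items():
        mid = (lo + hi) / 2.0 + center_shift * (hi - lo)
        half = span_fraction * (hi - lo) / 2.0
        out[name] = (mid - half, mid + half)
    return out


def default_gait_specs() -> dict[str, GaitSpec]:
    """Return the default :class:`GaitSpec` for each of the four gaits."""
    walk_base = {
        name: (mid - span / 2.0, mid + span / 2.0)
        for name, mid, span in (
            (
                name,
                (lo + hi) / 2.0,
                min(hi - lo, _CANTER_BOUNDS[name][1] - _CANTER_BOUNDS[name][0]),
            )
            for name, (lo, hi) in _RISING_TROT_BOUNDS.items()
        )
    }
    bounds = {
        "walk": _scaled_bounds(walk_base, _WALK_SPAN_FRACTION, 0.0),
        "sitting_trot": _scaled_bounds(
            _RISING_TROT_BOUNDS, _SITTING_SPAN_FRACTION, _SITTING_CENTER_SHIFT
        ),
        "rising_trot": dict(_RISING_TROT_BOUNDS),
        "canter": dict(_CANTER_BOUNDS),
    }
    specs = {
        name: GaitSpec(
            gait_name=name,
            period_frames=DEFAULT_PERIODS[name],
            channel_bounds=bounds[name],
        )
        for name in GAIT_NAMES
    }
    assert specs["canter"].period_frames < specs["walk"].period_frames
    return specs


def generate_recording(spec: GaitSpec, n_frames: int, seed: int) -> MotionRecording:
    """Synthesize one labelled recording from a gait's signal model.

    Each channel c is a weighted harmonic series around the channel midpoint::

        c(t) = mid + half_span * sum_k w_k sin(2*pi*(k+1)*t/P + phi_c) / sum_k w_k
               + N(0, noise_std_c)

    so with zero noise every sample lies inside the channel bounds.
    Identical ``(spec, n_frames, seed)`` give bit-identical output.
    """
    if n_frames < 2 * spec.period_frames:
        raise ValueError(
            "recording too short for one full cycle: need n_frames >= "
            f"2 * period_frames = {2 * spec.period_frames}, got {n_frames}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)[:, None]  # frames x 1
    weights = np.asarray(spec.harmonic_weights, dtype=float)
    phases = np.asarray(spec.phase_offsets, dtype=float)[None, :]  # 1 x 8
    osc = np.zeros((n_frames, len(CHANNEL_NAMES)))
    for k, w in enumerate(weights):
        osc += w * np.sin(2 * np.pi * (k + 1) * t / spec.period_frames + phases)
    osc /= weights.sum()

    lo = np.array([spec.channel_bounds[c][0] for c in CHANNEL_NAMES])
    hi = np.array([spec.channel_bounds[c][1] for c in CHANNEL_NAMES])
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    noise = rng.standard_normal(osc.shape) * np.asarray(spec.noise_std)
    values = mid + half * osc + noise
    return MotionRecording(values=values, gait_label=spec.gait_name, seed=seed)


def generate_dataset(
    specs: dict[str, GaitSpec] | None = None,
    n_frames_per_gait: int = 12_000,
    seed: int = 0,
) -> list[MotionRecording]:
    """Generate one recording per gait with seeds derived from ``seed``.

    Per-gait seeds come from ``numpy.random.SeedSequence(seed).spawn``, so the
    whole dataset is reproducible from the single master seed.
    """
    if specs is None:
        specs = default_gait_specs()
    max_period = max(s.period_frames for s in specs.values())
    if n_frames_per_gait < 2 * max_period:
        raise ValueError(
            f"n_frames_per_gait must be >= 2 * max period = {2 * max_period}"
        )
    children = np.random.SeedSequence(seed).spawn(len(specs))
    recordings = []
    for child, name in zip(children, sorted(specs)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        recordings.append(generate_recording(specs[name], n_frames_per_gait, child_seed))
    return recordings
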