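"""Domain types shared across the toolkit.

Units are fixed throughout the package: positions in micrometres (um),
times in seconds (s), speeds in um/min, transition rates in 1/min, and
B-tubule coordinates in nanometres (nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GROWTH = "growth"
SHRINK = "shrink"
PAUSE = "pause"
PHASES = (GROWTH, SHRINK, PAUSE)

#: seconds per minute; rates are per minute, event times are in seconds
S_PER_MIN = 60.0


@dataclass
class DynParams:
    """Rates and speeds of the three-state dynamic-instability model.

    The microtubule end alternates between growth, shrinkage and pause
    phases.  Transitions are Markovian with per-minute rates:

    - ``f_cat``: growth -> shrink (catastrophe)
    - ``f_res``: shrink -> growth (rescue)
    - ``f_gp`` / ``f_pg`` / ``f_ps``: growth -> pause, pause -> growth,
      pause -> shrink

    Speeds ``v_g`` and ``v_s`` are magnitudes in um/min; the end moves at
    ``+v_g`` during growth and ``-v_s`` during shrinkage.
    """

    v_g: float = 1.2
    v_s: float = 18.0
    f_cat: float = 0.4
    f_res: float = 6.0
    f_gp: float = 0.0
    f_pg: float = 0.0
    f_ps: float = 0.0
    end: str = "plus"

    def __post_init__(self) -> None:
        for name in ("v_g", "v_s", "f_cat", "f_res", "f_gp", "f_pg", "f_ps"):
            val = float(getattr(self, name))
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val!r}")
            setattr(self, name, val)
        if self.end not in ("plus", "minus"):
            raise ValueError(f"end must be 'plus' or 'minus', got {self.end!r}")
        if self.v_s == 0 and (self.f_cat > 0 or self.f_ps > 0):
            raise ValueError("v_s must be > 0 when shrink phases are reachable")


@dataclass
class PhaseSegment:
    """One contiguous phase of an end trajectory (piecewise-linear)."""

    t_start: float
    t_end: float
    x_start: float
    x_end: float
    phase: str

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def dx(self) -> float:
        return self.x_end - self.x_start

    @property
    def slope(self) -> float:
        """Velocity in um/min (positive = growth direction)."""
        return self.dx / self.duration * S_PER_MIN


@dataclass
class EndTrace:
    """Sampled position-versus-time of one microtubule end.

    ``truth`` carries the exact generating phase segments when the trace
    was simulated; analysis code never looks at it.
    """

    times: np.ndarray
    positions: np.ndarray
    end: str = "plus"
    truth: Optional[list] = None
    junction_x: Optional[float] = None
    t_switch: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != self.times.shape:
            raise ValueError("times and positions must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        finite = self.positions[np.isfinite(self.positions)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("positions must be >= 0 (seed is an absorbing floor)")
        if self.end not in ("plus", "minus"):
            raise ValueError("end must be 'plus' or 'minus'")


@dataclass
class KymoSpec:
    """Geometry, calibration and photon model of a rendered kymograph."""

    pixel_size: float = 0.107      # um / px
    frame_interval: float = 2.0    # s
    duration: float = 1800.0       # s
    psf_sigma: float = 1.2         # px
    signal: float = 170.0          # expected counts/px on the lattice
    background: float = 40.0       # expected counts/px off the lattice
    seed_length: float = 1.5       # um of stable seed
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("pixel_size, frame_interval and duration must be > 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if not (self.signal > self.background >= 0):
            raise ValueError("need signal > background >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def snr(self) -> float:
        return (self.signal - self.background) / np.sqrt(self.signal)


@dataclass
class Kymograph:
    """Space x time raster: rows = frames (time downward), columns = space."""

    image: np.ndarray
    spec: KymoSpec
    seed_span: tuple  # half-open column interval occupied by the seed

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D")
        if self.image.min() < 0:
            raise ValueError("pixel values must be >= 0")
        if self.image.shape[0] != self.spec.n_frames:
            raise ValueError("row count must equal round(duration / frame_interval)")


@dataclass
class ArcSpec:
    """Synthetic circular-arc B-tubule trace specification (nm)."""

    radius_true: float = 13.5
    arc_span: float = 270.0        # degrees
    n_points: int = 10
    jitter_sigma: float = 0.0      # nm
    pose_angle: float = 0.0        # degrees
    pose_shift: tuple = (0.0, 0.0)  # nm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_true <= 0:
            raise ValueError("radius_true must be > 0")
        if not (0 < self.arc_span <= 360):
            raise ValueError("arc_span must lie in (0, 360] degrees")
        if self.n_points < 3:
            raise ValueError("need at least 3 points")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class ProfileSpec:
    """Synthetic two-channel ciliary intensity profile specification."""

    length: float = 5.0            # um
    n_samples: int = 100
    proximal_fraction: float = 0.5
    enrichment_ratio: float = 4.0  # proximal / distal mean of channel A
    noise_sigma: float = 0.0       # relative (multiplicative) noise
    step_softness: float = 0.0     # logistic width as fraction of length (0 = hard step)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (0 < self.proximal_fraction < 1):
            raise ValueError("proximal_fraction must lie in (0, 1)")
        if self.enrichment_ratio <= 0:
            raise ValueError("enrichment_ratio must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.step_softness < 0:
            raise ValueError("step_softness must be >= 0")


@dataclass
class TubuleTrace:
    """Ordered 2-D B-tubule coordinates (nm) with O/X landmarks.

    ``O`` is the A-tubule centre and ``X`` the outer junction where the
    B-tubule attaches; the first trace point is the end nearest X.
    """

    points: np.ndarray
    O: np.ndarray
    X: np.ndarray
    label: str = ""
    group: Optional[str] = None
    radius_true: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.O = np.asarray(self.O, dtype=float).reshape(2)
        self.X = np.asarray(self.X, dtype=float).reshape(2)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 3:
            raise ValueError("points must be an (n >= 3, 2) array")
        if np.allclose(self.O, self.X):
            raise ValueError("O and X must be distinct landmarks")


@dataclass
class AlignedTrace:
    """A TubuleTrace in the canonical O-X frame (X at origin, O on -x axis)."""

    points: np.ndarray
    angle: float        # rotation applied, radians
    shift: np.ndarray   # translation applied after rotation, nm
    source: Optional[TubuleTrace] = None


@dataclass
class CurvatureResult:
    """Local (per-triplet circumradius) and mean curvature radii of a trace."""

    local_radii: np.ndarray
    mean_radius: float
    method: str = "triplet_mean"
    label: str = ""
    group: Optional[str] = None


@dataclass
class RawProfile:
    """Intensity profile(s) along a cilium, proximal end at arclength 0."""

    positions: np.ndarray            # um, strictly increasing from 0
    intensities: np.ndarray          # (n, n_channels), arbitrary units >= 0
    channel_names: Sequence[str] = ("A", "B")
    width: float = 0.17              # um, averaging width used
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[0] == 1 and self.positions.size > 1:
            self.intensities = self.intensities.T
        if self.positions.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.intensities.shape[0] != self.positions.size:
            raise ValueError("intensities must have one row per position")
        if np.nanmin(self.intensities) < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class NormalizedProfile:
    """Profile resampled to 0-100 %length, channels scaled to %max."""

    positions: np.ndarray            # 0..100
    intensities: np.ndarray          # (n_bins, n_channels), 0..100
    channel_names: Sequence[str] = ("A", "B")
    flags: dict = field(default_factory=dict)
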