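"""Radial-frequency pattern stimuli and the block-design timeline.

Radial-frequency (RF) patterns are closed contours obtained by sinusoidally
modulating the radius of a circle,

    r(theta) = r0 * (1 + A * sin(omega * theta + phi)),

where ``omega`` counts cycles per revolution, ``A`` sets the modulation depth
and ``phi`` rotates the pattern.  RF0 (a circle) carries pure curvature; RF4
(a rounded square) carries straight segments plus corners.  The rendered
stimuli are concentric rings of alternating contrast, each ring centred on a
scaled copy of the RF contour, shown on a mean-gray background.

The block timeline alternates stimulus and rest blocks of equal duration after
an initial fixation period and drives both the acquisition simulator and the
GLM design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RFPatternSpec",
    "BlockTimeline",
    "rf_radius",
    "render_rf_stimulus",
    "build_block_timeline",
    "count_trials",
    "timeline_to_frame",
]

REST = "rest"
RF0 = "RF0"
RF4 = "RF4"


@dataclass(frozen=True)
class RFPatternSpec:
    """Parameters of a radial-frequency contour.

    Attributes
    ----------
    omega : int
        Radial frequency in cycles per revolution (>= 0).
    amplitude : float
        Modulation amplitude ``A`` (dimensionless, 0 <= A < 1; A >= 1 would
        self-intersect).
    phase : float
        Rotation phase ``phi`` in radians.
    r0 : float
        Base radius in degrees of visual angle (> 0).
    max_extent : float
        Maximum radial extent of the rendered pattern in degrees.
    """

    omega: int = 0
    amplitude: float = 0.0
    phase: float = 0.0
    r0: float = 1.0
    max_extent: float = 9.0

    def __post_init__(self) -> None:
        if self.omega < 0 or int(self.omega) != self.omega:
            raise ValueError("omega must be a non-negative integer")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude >= 1:
            raise ValueError("amplitude >= 1 gives a self-intersecting contour")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.max_extent <= 0:
            raise ValueError("max_extent must be positive")


def rf_radius(theta, spec: RFPatternSpec):
    """Radius of the RF contour at polar angle ``theta`` (radians).

    Returns ``r0 * (1 + A * sin(omega*theta + phi))``; 2*pi-periodic in theta
    for integer ``omega``.
    """
    theta = np.asarray(theta, dtype=float)
    return spec.r0 * (1.0 + spec.amplitude * np.sin(spec.omega * theta + spec.phase))


def render_rf_stimulus(
    spec: RFPatternSpec,
    image_size: int,
    deg_per_pixel: float,
    polarity: int = 1,
    ring_period_deg: float = 2.0,
) -> np.ndarray:
    """Render a concentric RF pattern as a 2D contrast image in [-1, 1].

    Rings of alternating contrast are centred on scaled copies of the RF
    contour, spaced ``ring_period_deg / 2`` apart along the direction where
    the contour attains its maximum radius; the outermost copy is scaled so
    the maximum radius equals ``spec.max_extent``.  Pixels beyond the pattern
    are 0 (mean gray).  ``polarity=-1`` returns the contrast-reversed image.
    """
    if image_size <= 0:
        raise ValueError("image_size must be positive")
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    half = image_size * deg_per_pixel / 2.0
    coords = (np.arange(image_size) + 0.5) * deg_per_pixel - half
    x, y = np.meshgrid(coords, coords, indexing="xy")
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    # Unit contour, normalised so its maximum radius is 1.
    c_hat = (1.0 + spec.amplitude * np.sin(spec.omega * theta + spec.phase)) / (
        1.0 + spec.amplitude
    )
    rho = r / c_hat  # normalised radial coordinate
    band = np.round(rho / (ring_period_deg / 2.0)).astype(int)
    img = np.where(band % 2 == 0, 1.0, -1.0) * polarity
    img[rho > spec.max_extent] = 0.0
    return img


@dataclass(frozen=True)
class BlockTimeline:
    """Block-design timeline with per-volume-pair condition labels.

    ``labels`` holds one entry per volume pair ({'rest', 'RF0', 'RF4'});
    ``block_onsets``/``block_conditions`` describe the stimulus blocks.
    """

    tr_pair: float
    n_initial_rest: int
    block_dur: float
    n_blocks: int
    condition_order: tuple
    reversal_interval: float
    labels: np.ndarray = field(repr=False)
    block_onsets: np.ndarray = field(repr=False)
    block_conditions: tuple = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.labels)

    @property
    def pairs_per_block(self) -> int:
        return int(round(self.block_dur / self.tr_pair))

    @property
    def times(self) -> np.ndarray:
        """Start time (s) of each volume pair."""
        return np.arange(self.n_pairs) * self.tr_pair

    @property
    def run_duration(self) -> float:
        return self.n_pairs * self.tr_pair

    @property
    def initial_rest_duration(self) -> float:
        return self.n_initial_rest * self.tr_pair


def build_block_timeline(
    tr_pair: float = 2.610,
    n_initial_rest: int = 33,
    block_dur: float = 31.32,
    n_blocks: int = 14,
    condition_order: tuple = (RF0, RF4),
    reversal_interval: float = 0.522,
) -> BlockTimeline:
    """Build the block timeline: initial rest, then ``n_blocks`` repetitions
    of (stimulus block, rest block) with conditions cycling through
    ``condition_order``.

    Raises
    ------
    ValueError
        If ``block_dur`` is not an integer multiple of ``tr_pair``.
    """
    vpb = block_dur / tr_pair
    if abs(vpb - round(vpb)) > 1e-6:
        raise ValueError(
            f"block_dur ({block_dur}) must be an integer multiple of tr_pair ({tr_pair})"
        )
    vpb = int(round(vpb))
    if not set(condition_order) <= {RF0, RF4}:
        raise ValueError("conditions must be drawn from {RF0, RF4}")
    labels = [REST] * n_initial_rest
    onsets = []
    conditions = []
    for b in range(n_blocks):
        cond = condition_order[b % len(condition_order)]
        onsets.append(len(labels) * tr_pair)
        conditions.append(cond)
        labels.extend([cond] * vpb)
        labels.extend([REST] * vpb)
    return BlockTimeline(
        tr_pair=tr_pair,
        n_initial_rest=n_initial_rest,
        block_dur=block_dur,
        n_blocks=n_blocks,
        condition_order=tuple(condition_order),
        reversal_interval=reversal_interval,
        labels=np.array(labels),
        block_onsets=np.array(onsets),
        block_conditions=tuple(conditions),
    )


def count_trials(n_participants: int, n_runs: int, n_blocks: int) -> int:
    """Total number of stimulus trials across a study (simple product)."""
    for name, v in (
        ("n_participants", n_participants),
        ("n_runs", n_runs),
        ("n_blocks", n_blocks),
    ):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer")
    return int(n_participants) * int(n_runs) * int(n_blocks)


def timeline_to_frame(timeline: BlockTimeline) -> pd.DataFrame:
    """Timeline as a 3-column table (volume_index, time_s, condition)."""
    return pd.DataFrame(
        {
            "volume_index": np.arange(timeline.n_pairs),
            "time_s": timeline.times,
            "condition": timeline.labels,
        }
    )
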