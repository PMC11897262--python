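"""Block hemodynamic response models for CBV (VASO) and BOLD contrast.

For a sustained visual block the response rises to an early peak about 6 s
after onset, relaxes to a plateau that holds until offset, and then returns
to baseline — with the CBV response returning more slowly than BOLD (delayed
vascular compliance: vessel volume relaxes slowly after expansion).  The model
is a piecewise half-cosine curve with the peak normalised to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HemodynamicParams", "hemodynamic_response"]


@dataclass(frozen=True)
class HemodynamicParams:
    """Shape parameters of the block response.

    Attributes
    ----------
    onset_delay : float
        Latency (s) between stimulus onset and the start of the rise.
    time_to_peak : float
        Time (s) from response onset to the peak (default 6).
    plateau : float
        Plateau level relative to the peak (0 < plateau <= 1).
    settle_s : float
        Duration (s) of the peak-to-plateau relaxation.
    fall_s : float
        Return-to-baseline duration (s) after offset for BOLD.
    vaso_extra_lag_s : float
        Additional return-to-baseline duration (s) for the CBV response.
    """

    onset_delay: float = 0.0
    time_to_peak: float = 6.0
    plateau: float = 0.8
    settle_s: float = 4.0
    fall_s: float = 6.0
    vaso_extra_lag_s: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.plateau <= 1.0):
            raise ValueError("plateau must be in (0, 1]")
        if min(self.time_to_peak, self.settle_s, self.fall_s) <= 0:
            raise ValueError("durations must be positive")
        if self.onset_delay < 0 or self.vaso_extra_lag_s < 0:
            raise ValueError("delays must be non-negative")


def hemodynamic_response(
    t_grid,
    onset: float,
    duration: float,
    params: HemodynamicParams = HemodynamicParams(),
    contrast: str = "CBV",
) -> np.ndarray:
    """Evaluate the block response (peak-normalised) on ``t_grid``.

    The curve is zero before ``onset + onset_delay``, rises along a half
    cosine to 1 at ``time_to_peak``, settles to ``plateau`` over ``settle_s``,
    holds until stimulus offset (``onset + duration``) and then falls to zero
    along a half cosine lasting ``fall_s`` (BOLD) or
    ``fall_s + vaso_extra_lag_s`` (CBV).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if contrast not in ("CBV", "BOLD"):
        raise ValueError("contrast must be 'CBV' or 'BOLD'")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim and np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be non-decreasing")
    s = t - onset - params.onset_delay
    offset = duration - params.onset_delay  # offset relative to response start
    fall = params.fall_s + (params.vaso_extra_lag_s if contrast == "CBV" else 0.0)

    def envelope(si):
        """Pre-offset envelope: rise then settle to plateau."""
        ttp, settle, plat = params.time_to_peak, params.settle_s, params.plateau
        out = np.zeros_like(si)
        rise = (si >= 0) & (si < ttp)
        out[rise] = 0.5 * (1.0 - np.cos(np.pi * si[rise] / ttp))
        settling = (si >= ttp) & (si < ttp + settle)
        out[settling] = 1.0 - (1.0 - plat) * 0.5 * (
            1.0 - np.cos(np.pi * (si[settling] - ttp) / settle)
        )
        out[si >= ttp + settle] = plat
        return out

    resp = envelope(np.atleast_1d(s).astype(float))
    s1 = np.atleast_1d(s)
    level_at_offset = float(envelope(np.array([offset]))[0])
    post = s1 >= offset
    uu = np.clip((s1[post] - offset) / fall, 0.0, 1.0)
    resp[post] = level_at_offset * 0.5 * (1.0 + np.cos(np.pi * uu))
    resp[s1 < 0] = 0.0
    return resp.reshape(np.shape(t)) if np.ndim(t) else float(resp[0])
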