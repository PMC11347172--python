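"""Line-profile analysis: the manual cross-check on the automated pipeline.

Replicates the by-hand analysis typically done in an image viewer: a line is
drawn across a nucleus through the center of one nucleolus, the intensity
along the line is sampled in every channel at identical positions, each
channel is normalized to its maximum at reference time points, and the
change of the chromatin-stain profile is summarized as the ratio of the
areas under the normalized curves at the end versus the start of the movie.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import ImageStack

__all__ = ["LineProfile", "sample_profile", "normalize_profile", "auc_ratio"]


@dataclass
class LineProfile:
    """Intensities sampled along a segment, per channel.

    ``positions`` are distances in px from the first endpoint at unit
    spacing; ``raw`` is a (C, N) array in the stack's channel order;
    ``normalized`` (same shape) is filled by :func:`normalize_profile`,
    as fractions of the reference maximum (1.0 = 100%).
    """

    positions: np.ndarray  # (N,)
    raw: np.ndarray  # (C, N)
    channel_roles: dict[str, int]
    frame: int
    normalized: np.ndarray | None = None

    def channel(self, role: str, normalized: bool = False) -> np.ndarray:
        arr = self.normalized if normalized else self.raw
        if arr is None:
            raise ValueError("profile has not been normalized yet")
        return arr[self.channel_roles[role]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (position, channel, raw, normalized)."""
        rows = []
        for role, c in self.channel_roles.items():
            for i, pos in enumerate(self.positions):
                rows.append(
                    (float(pos), role, float(self.raw[c, i]),
                     float(self.normalized[c, i]) if self.normalized is not None else np.nan)
                )
        return pd.DataFrame(rows, columns=["position_px", "channel", "raw", "normalized"])


def sample_profile(
    stack: ImageStack, p0: tuple[float, float], p1: tuple[float, float], frame: int
) -> LineProfile:
    """Sample all channels along the segment p0 -> p1 ((y, x), px units).

    Bilinear interpolation at unit-px spacing; every channel is sampled at
    exactly the same positions, so profiles are directly comparable across
    channels and frames.
    """
    h, w = stack.pixels.shape[2:]
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {p} outside image of shape {(h, w)}")
    y0, x0 = p0
    y1, x1 = p1
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = max(2, int(round(length)) + 1)
    tt = np.linspace(0.0, 1.0, n)
    ys = y0 + tt * (y1 - y0)
    xs = x0 + tt * (x1 - x0)
    raw = np.stack(
        [
            ndi.map_coordinates(
                stack.pixels[frame, c].astype(np.float64), [ys, xs], order=1
            )
            for c in range(stack.pixels.shape[1])
        ]
    )
    return LineProfile(
        positions=tt * length,
        raw=raw,
        channel_roles=dict(stack.channel_roles),
        frame=frame,
    )


def normalize_profile(
    profile: LineProfile, reference: LineProfile | list[LineProfile] | None = None
) -> LineProfile:
    """Normalize each channel to its maximum over the reference profile(s).

    With ``reference=None`` each channel uses its own maximum in this
    profile (value 1.0 = 100% at the peak).  Passing the t=0 profile as the
    reference implements the convention where the start-of-movie maximum is
    set to 100% and later frames are expressed relative to it.  Passing a
    list of profiles uses the joint maximum over all of them.
    """
    refs = (
        [profile] if reference is None
        else [reference] if isinstance(reference, LineProfile)
        else list(reference)
    )
    maxima = np.max([r.raw.max(axis=1) for r in refs], axis=0)
    if np.any(maxima <= 0):
        raise ValueError("reference maximum is zero for at least one channel")
    return replace(profile, normalized=profile.raw / maxima[:, None])


def auc_ratio(
    profile_t0: LineProfile, profile_tend: LineProfile, role: str = "nuclear_stain"
) -> float:
    """AUC(t_end) / AUC(t0) of the normalized profiles of one channel.

    Trapezoidal integration over the (identical) sampling positions.  Both
    profiles must have been normalized first; normalizing both against the
    t0 profile makes the ratio a direct measure of the intensity change.
    """
    if profile_t0.normalized is None or profile_tend.normalized is None:
        raise ValueError("normalize both profiles before computing the AUC ratio")
    if profile_t0.positions.shape != profile_tend.positions.shape or not np.allclose(
        profile_t0.positions, profile_tend.positions
    ):
        raise ValueError("profiles must share identical sampling positions")
    a0 = float(np.trapezoid(profile_t0.channel(role, normalized=True), profile_t0.positions))
    a1 = float(np.trapezoid(profile_tend.channel(role, normalized=True), profile_tend.positions))
    if a0 == 0:
        raise ValueError("AUC at t0 is zero")
    return a1 / a0
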