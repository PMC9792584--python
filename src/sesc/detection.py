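"""Static-posture selection from continuous joint-angle and CoP streams.

A window counts as static when, over its duration, every joint-angle channel
has a standard deviation below the angle threshold and both CoP axes stay
below the CoP-displacement threshold.  Consecutive static windows are merged
into maximal static regions, each summarized by its per-channel mean — one
candidate posture per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaticPostureCriteria",
    "DetectedPosture",
    "SelectionReport",
    "detect_static_postures",
    "summarize_selection",
    "wrapped_angle_sd",
]


@dataclass(frozen=True)
class StaticPostureCriteria:
    """Stillness thresholds: 1 s windows, angle SD < 1.5 deg, CoP SD < 6 mm."""

    window_s: float = 1.0
    angle_sd_max_deg: float = 1.5
    cop_sd_max_mm: float = 6.0
    sample_rate_hz: float = 60.0
    cop_resultant: bool = False  # SD of resultant displacement instead of per axis
    sliding: bool = False  # stride of 1 sample with greedy non-overlap resolution

    def __post_init__(self) -> None:
        if min(self.window_s, self.angle_sd_max_deg, self.cop_sd_max_mm,
               self.sample_rate_hz) <= 0:
            raise ValueError("all criteria must be positive")
        if self.window_samples < 2:
            raise ValueError("window must contain at least 2 samples")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))


@dataclass(frozen=True)
class DetectedPosture:
    """One maximal static region with its per-channel mean values."""

    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    mean_angles_deg: np.ndarray
    mean_cop_mm: np.ndarray


@dataclass(frozen=True)
class SelectionReport:
    n_detected: int
    n_requested: int
    n_windows_total: int
    n_rejected_angle: int
    n_rejected_cop: int
    yield_percent: float = field(init=False)

    def __post_init__(self) -> None:
        y = 100.0 * self.n_detected / self.n_requested if self.n_requested else 0.0
        object.__setattr__(self, "yield_percent", y)


def wrapped_angle_sd(channel_deg: np.ndarray) -> float:
    """SD of an angle channel using wrapped differences from its first sample.

    Avoids spurious dispersion when a steady channel sits at the +/-180 deg
    seam of the Euler-angle range.
    """
    d = np.asarray(channel_deg, dtype=float) - channel_deg[0]
    d = (d + 180.0) % 360.0 - 180.0
    return float(np.std(d))


def _window_is_static(angles, cop, criteria) -> tuple[bool, bool]:
    """(angles pass, cop passes) for one window of samples."""
    angles_ok = all(
        wrapped_angle_sd(angles[:, j]) < criteria.angle_sd_max_deg
        for j in range(angles.shape[1])
    )
    if criteria.cop_resultant:
        centered = cop - cop.mean(axis=0)
        cop_ok = float(np.std(np.linalg.norm(centered, axis=1))) < criteria.cop_sd_max_mm
    else:
        cop_ok = bool(np.all(np.std(cop, axis=0) < criteria.cop_sd_max_mm))
    return angles_ok, cop_ok


def detect_static_postures(
    angles_deg: np.ndarray,
    cop_mm: np.ndarray,
    criteria: StaticPostureCriteria = StaticPostureCriteria(),
) -> tuple[list[DetectedPosture], SelectionReport]:
    """Find maximal static regions in synchronized angle and CoP streams.

    Parameters
    ----------
    angles_deg
        (T, n_channels) joint-angle samples in degrees.
    cop_mm
        (T, 2) CoP samples in millimeters (AP, ML).
    criteria
        Stillness thresholds and windowing mode.

    Returns the detected postures (non-overlapping, each the merge of
    consecutive static windows) and a selection report with per-criterion
    rejection tallies.
    """
    angles_deg = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    if angles_deg.shape[0] == 1 and angles_deg.shape[1] > 1:
        angles_deg = angles_deg.T
    cop_mm = np.asarray(cop_mm, dtype=float).reshape(-1, 2)
    if angles_deg.shape[0] != cop_mm.shape[0]:
        raise ValueError(
            f"angle stream has {angles_deg.shape[0]} samples but CoP has {cop_mm.shape[0]}"
        )
    w = criteria.window_samples
    T = angles_deg.shape[0]
    stride = 1 if criteria.sliding else w

    static_windows: list[tuple[int, int]] = []
    n_total = n_rej_angle = n_rej_cop = 0
    last_end = 0
    for start in range(0, T - w + 1, stride):
        if criteria.sliding and start < last_end:
            continue  # greedy non-overlap
        n_total += 1
        a_ok, c_ok = _window_is_static(
            angles_deg[start: start + w], cop_mm[start: start + w], criteria
        )
        if a_ok and c_ok:
            static_windows.append((start, start + w))
            last_end = start + w
        else:
            n_rej_angle += not a_ok
            n_rej_cop += not c_ok

    # merge runs of contiguous static windows into maximal regions
    detected: list[DetectedPosture] = []
    i = 0
    while i < len(static_windows):
        start, stop = static_windows[i]
        j = i + 1
        while j < len(static_windows) and static_windows[j][0] == stop:
            stop = static_windows[j][1]
            j += 1
        detected.append(
            DetectedPosture(
                start, stop,
                angles_deg[start:stop].mean(axis=0),
                cop_mm[start:stop].mean(axis=0),
            )
        )
        i = j

    report = SelectionReport(
        n_detected=len(detected),
        n_requested=len(detected),  # overwritten by summarize_selection
        n_windows_total=n_total,
        n_rejected_angle=n_rej_angle,
        n_rejected_cop=n_rej_cop,
    )
    return detected, report


def summarize_selection(
    detected: list[DetectedPosture] | SelectionReport, requested: int
) -> SelectionReport:
    """Selection report against the number of postures that were requested."""
    if isinstance(detected, SelectionReport):
        base = detected
        return SelectionReport(
            base.n_detected, requested, base.n_windows_total,
            base.n_rejected_angle, base.n_rejected_cop,
        )
    return SelectionReport(len(detected), requested, 0, 0, 0)
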