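"""Droplet classification: fluorescence thresholds and positive/negative counts.

The vendor rule implemented here places the per-channel threshold at the
amplitude of lowest droplet density between the two clusters. Density is a
256-bin histogram smoothed with a 5-bin moving average; modes are local
maxima with density above 1% of the global peak, ties broken toward the
lower amplitude. When only one mode is found the threshold falls back to
either the midpoint of the configured cluster means (overlapping clusters)
or mode + 7 robust SD (no positive cluster — the normal situation for a
blank channel, where any droplet above the threshold still counts positive
so that sparse positives below the mode-detection limit are not lost).

Well-level QC excludes wells with fewer than 10,000 accepted droplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .config import AssayConfig
from .errors import ExcludedWellError, InsufficientDataError

MIN_ACCEPTED_EVENTS = 10_000
MIN_DROPLETS_FOR_THRESHOLD = 100


class ThresholdMethod(str, Enum):
    VALLEY = "valley"
    FALLBACK_MIDPOINT = "fallback_midpoint"
    FALLBACK_NO_POSITIVE = "fallback_no_positive"


@dataclass(frozen=True)
class WellQC:
    accepted_events: int
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class ChannelCall:
    """Positive/negative droplet counts for one channel of one well."""

    well_id: str
    channel: int  # 1..4
    threshold: float
    n_positive: int
    n_negative: int
    method: ThresholdMethod


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    method: ThresholdMethod


def qc_well(well, min_events: int = MIN_ACCEPTED_EVENTS) -> WellQC:
    """Accepted-event QC: wells with fewer than ``min_events`` droplets fail."""
    n = well.accepted_events
    if n >= min_events:
        return WellQC(accepted_events=n, passed=True)
    return WellQC(
        accepted_events=n,
        passed=False,
        reason=f"accepted events {n} < {min_events}",
    )


def _robust_spread(x: np.ndarray) -> float:
    """1.4826 × MAD, falling back to SD then to 1.0 for degenerate data."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    spread = 1.4826 * mad
    if spread <= 0:
        spread = float(np.std(x))
    if spread <= 0:
        spread = 1.0
    return float(spread)


def _find_modes(density: np.ndarray, peak_frac: float) -> list[int]:
    """Indices of local maxima with density >= peak_frac × max density.

    Plateaus collapse to their first (lowest-amplitude) bin.
    """
    floor = peak_frac * density.max()
    modes: list[int] = []
    n = len(density)
    i = 0
    while i < n:
        # extent of plateau starting at i
        j = i
        while j + 1 < n and density[j + 1] == density[i]:
            j += 1
        left_ok = i == 0 or density[i - 1] < density[i]
        right_ok = j == n - 1 or density[j + 1] < density[i]
        if left_ok and right_ok and density[i] >= floor and density[i] > 0:
            modes.append(i)
        i = j + 1
    return modes


def estimate_threshold(
    amplitudes: np.ndarray,
    neg_mean_hint: Optional[float] = None,
    pos_mean_hint: Optional[float] = None,
    n_bins: int = 256,
    smooth_window: int = 5,
    peak_frac: float = 0.01,
    valley_depth_frac: float = 0.5,
    no_positive_k: float = 7.0,
) -> ThresholdEstimate:
    """Place the threshold at the lowest-density amplitude between clusters.

    Parameters
    ----------
    amplitudes
        1-D fluorescence amplitudes of one channel (>= 100 droplets).
    neg_mean_hint, pos_mean_hint
        Expected cluster centres, used only by the fallbacks when fewer than
        two modes are detected.

    Raises
    ------
    InsufficientDataError
        With fewer than 100 droplets.
    """
    amps = np.asarray(amplitudes, dtype=float).ravel()
    if amps.size < MIN_DROPLETS_FOR_THRESHOLD:
        raise InsufficientDataError(
            f"threshold estimation needs >= {MIN_DROPLETS_FOR_THRESHOLD} droplets, "
            f"got {amps.size}"
        )

    counts, edges = np.histogram(amps, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_window) / smooth_window
    density = np.convolve(counts.astype(float), kernel, mode="same")

    modes = _find_modes(density, peak_frac)
    if len(modes) >= 2:
        # two dominant modes = highest smoothed density; ties -> lower amplitude
        ranked = sorted(modes, key=lambda i: (-density[i], i))
        lo, hi = sorted(ranked[:2])
        if hi - lo > 1:
            interior = density[lo + 1 : hi]
            min_val = interior.min()
            # a real inter-cluster valley dips well below both peaks; local
            # maxima on the flank of one cluster do not
            if min_val < valley_depth_frac * min(density[lo], density[hi]):
                tied = np.flatnonzero(interior == min_val)
                valley = lo + 1 + int(tied[len(tied) // 2])  # middle of flat run
                return ThresholdEstimate(
                    float(centers[valley]), ThresholdMethod.VALLEY
                )
        # adjacent bins or no true valley: effectively a single mode
        modes = [max(modes, key=lambda i: (density[i], -i))]

    mode_amp = float(centers[modes[0]]) if modes else float(np.median(amps))
    if (
        neg_mean_hint is not None
        and pos_mean_hint is not None
        and abs(mode_amp - pos_mean_hint) < abs(mode_amp - neg_mean_hint)
    ):
        # the single mode sits at the positive level: clusters have merged
        return ThresholdEstimate(
            0.5 * (neg_mean_hint + pos_mean_hint), ThresholdMethod.FALLBACK_MIDPOINT
        )
    return ThresholdEstimate(
        mode_amp + no_positive_k * _robust_spread(amps),
        ThresholdMethod.FALLBACK_NO_POSITIVE,
    )


def call_channel(
    amplitudes: np.ndarray,
    well_id: str,
    channel: int,
    neg_mean_hint: Optional[float] = None,
    pos_mean_hint: Optional[float] = None,
) -> ChannelCall:
    est = estimate_threshold(amplitudes, neg_mean_hint, pos_mean_hint)
    n_pos = int(np.sum(np.asarray(amplitudes, dtype=float) > est.threshold))
    return ChannelCall(
        well_id=well_id,
        channel=channel,
        threshold=est.threshold,
        n_positive=n_pos,
        n_negative=int(len(amplitudes) - n_pos),
        method=est.method,
    )


def call_well(
    well,
    cfg: Optional[AssayConfig] = None,
    min_events: int = MIN_ACCEPTED_EVENTS,
    override_qc: bool = False,
) -> list[ChannelCall]:
    """Call all four channels of a well; counts partition accepted events.

    Raises
    ------
    ExcludedWellError
        If the well fails accepted-event QC and ``override_qc`` is False.
    """
    qc = qc_well(well, min_events=min_events)
    if not qc.passed and not override_qc:
        raise ExcludedWellError(f"well {well.well_id}: {qc.reason}")
    if cfg is None:
        cfg = AssayConfig()
    calls = []
    for ch in range(1, 5):
        calls.append(
            call_channel(
                well.amplitudes[:, ch - 1],
                well_id=well.well_id,
                channel=ch,
                neg_mean_hint=cfg.negative_amplitude_mean[ch - 1],
                pos_mean_hint=cfg.positive_amplitude_mean[ch - 1],
            )
        )
    return calls
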