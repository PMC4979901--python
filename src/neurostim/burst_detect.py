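"""Burst detection from spike trains.

Offline path (multi-channel): per-channel burstlets are maximal runs of
spikes with inter-spike intervals (ISIs) <= 100 ms, extended once by a
trailing interval <= 200 ms, with at least three spikes; burstlets whose
onsets co-occur on at least three recording sites within 100 ms (one
larger gap <= 200 ms allowed) form a network burst.

Online path (single channel): a data-driven ISI threshold is taken at the
valley between the intra-burst and inter-burst modes of the (typically
bimodal) ISI histogram; a burst end is declared one threshold after the
last spike of a run of >= 3 sub-threshold-ISI spikes.  That one-threshold
lag is the detector dead time, which bounds the earliest state available
for stimulation in the closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks


class ThresholdEstimationError(RuntimeError):
    """Raised when the ISI histogram has no usable bimodal structure."""


@dataclass(frozen=True)
class OfflineDetectionParams:
    max_intra_isi: float = 0.1    # s, rule (a)
    max_end_isi: float = 0.2      # s, rule (b): one trailing interval
    min_spikes: int = 3           # rule (c)
    min_sites: int = 3            # network rule: sites with synchronous onsets
    onset_sync_window: float = 0.1  # s, network rule

    def __post_init__(self) -> None:
        if min(self.max_intra_isi, self.max_end_isi, self.onset_sync_window) <= 0:
            raise ValueError("all windows must be positive")
        if self.max_end_isi < self.max_intra_isi:
            raise ValueError("max_end_isi must be >= max_intra_isi")
        if self.min_spikes < 1 or self.min_sites < 1:
            raise ValueError("min_spikes and min_sites must be >= 1")


@dataclass(frozen=True)
class BurstEvent:
    onset: float
    offset: float
    participating_channels: frozenset
    spike_count: int

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")


def detect_single_channel_bursts(
    spikes: np.ndarray, params: OfflineDetectionParams | None = None
) -> list[tuple[float, float, int]]:
    """Per-channel burstlets as ``(onset, offset, n_spikes)`` tuples.

    Maximal runs of consecutive ISIs <= ``max_intra_isi``, extended by at
    most one trailing interval <= ``max_end_isi`` (non-recursive), with
    runs of fewer than ``min_spikes`` spikes discarded.
    """
    params = params or OfflineDetectionParams()
    t = np.asarray(spikes, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    bursts: list[tuple[float, float, int]] = []
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] <= params.max_intra_isi:
            j += 1
        # one trailing interval <= max_end_isi may close the burst
        if j + 1 < n and t[j + 1] - t[j] <= params.max_end_isi:
            j += 1
        count = j - i + 1
        if count >= params.min_spikes:
            bursts.append((float(t[i]), float(t[j]), count))
        i = j + 1
    return bursts


def detect_network_bursts(
    spikes: pd.DataFrame, params: OfflineDetectionParams | None = None
) -> list[BurstEvent]:
    """Network bursts from a multi-channel spike table.

    Burstlet onsets are chained while consecutive inter-onset gaps are
    <= ``onset_sync_window``; within one chain a single larger gap up to
    ``max_end_isi`` is tolerated.  A chain with burstlets from at least
    ``min_sites`` distinct channels becomes a network burst spanning from
    its earliest onset to the latest offset of its members.  Overlapping
    events are merged so the output intervals are disjoint and sorted.
    """
    params = params or OfflineDetectionParams()
    burstlets: list[tuple[float, float, int, int]] = []  # onset, offset, n, chan
    for ch, grp in spikes.groupby("channel"):
        for onset, offset, count in detect_single_channel_bursts(
            grp["time_s"].to_numpy(), params
        ):
            burstlets.append((onset, offset, count, ch))
    burstlets.sort()
    events: list[BurstEvent] = []
    i = 0
    while i < len(burstlets):
        chain = [burstlets[i]]
        large_gap_used = False
        j = i + 1
        while j < len(burstlets):
            gap = burstlets[j][0] - chain[-1][0]
            if gap <= params.onset_sync_window:
                chain.append(burstlets[j])
            elif not large_gap_used and gap <= params.max_end_isi:
                large_gap_used = True
                chain.append(burstlets[j])
            else:
                break
            j += 1
        channels = frozenset(b[3] for b in chain)
        if len(channels) >= params.min_sites:
            events.append(
                BurstEvent(
                    onset=min(b[0] for b in chain),
                    offset=max(b[1] for b in chain),
                    participating_channels=channels,
                    spike_count=sum(b[2] for b in chain),
                )
            )
        i = j
    # merge any overlap so detected intervals are disjoint
    merged: list[BurstEvent] = []
    for ev in sorted(events, key=lambda e: e.onset):
        if merged and ev.onset <= merged[-1].offset:
            prev = merged.pop()
            merged.append(
                BurstEvent(
                    onset=prev.onset,
                    offset=max(prev.offset, ev.offset),
                    participating_channels=prev.participating_channels
                    | ev.participating_channels,
                    spike_count=prev.spike_count + ev.spike_count,
                )
            )
        else:
            merged.append(ev)
    return merged


def ibis_from_bursts(bursts: list[BurstEvent] | pd.DataFrame) -> np.ndarray:
    """Inter-burst intervals, measured burst end to next burst onset."""
    if isinstance(bursts, pd.DataFrame):
        onsets = bursts["onset_s"].to_numpy()
        offsets = bursts["offset_s"].to_numpy()
    else:
        onsets = np.array([b.onset for b in bursts])
        offsets = np.array([b.offset for b in bursts])
    if onsets.size < 2:
        return np.empty(0)
    ibis = onsets[1:] - offsets[:-1]
    return ibis[ibis > 0]


def estimate_online_isi_threshold(
    spikes: np.ndarray,
    n_bins: int = 80,
    smooth_decades: float = 0.15,
) -> float:
    """Data-driven ISI threshold separating intra- from inter-burst modes.

    A histogram of log10(ISI) is smoothed with a Gaussian kernel of
    ``smooth_decades`` bandwidth; the threshold is the ISI at the minimum
    between the two highest peaks.  Raises ThresholdEstimationError when
    no bimodal structure is found (e.g. pure background activity).
    """
    t = np.asarray(spikes, dtype=float)
    isis = np.diff(t)
    isis = isis[isis > 0]
    if isis.size < 10:
        raise ThresholdEstimationError("too few ISIs to estimate a threshold")
    log_isi = np.log10(isis)
    lo, hi = log_isi.min(), log_isi.max()
    if hi - lo < 1e-6:
        raise ThresholdEstimationError("degenerate ISI distribution")
    counts, edges = np.histogram(log_isi, bins=n_bins, range=(lo, hi))
    bin_width = edges[1] - edges[0]
    smooth = gaussian_filter1d(counts.astype(float), smooth_decades / bin_width)
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=1.0)
    peaks -= 1
    if peaks.size < 2:
        raise ThresholdEstimationError("ISI histogram is unimodal; supply a threshold")
    top2 = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
    left, right = int(top2[0]), int(top2[1])
    if right - left < 2:
        raise ThresholdEstimationError("ISI modes are not separated")
    valley = left + int(np.argmin(smooth[left : right + 1]))
    # a genuine inter-mode valley dips well below the smaller mode;
    # wiggles on a unimodal histogram do not
    if smooth[valley] > 0.5 * min(smooth[left], smooth[right]):
        raise ThresholdEstimationError("ISI histogram is unimodal; supply a threshold")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(10.0 ** centers[valley])


def detect_burst_end_online(
    spikes: np.ndarray, threshold: float, min_spikes: int = 3
) -> list[float]:
    """Causal burst-end detector on a single-channel spike stream.

    After at least ``min_spikes`` spikes with ISIs below ``threshold``, a
    silent interval of one threshold declares a burst end; the emission
    time is last spike time + threshold (the detector dead time).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(spikes, dtype=float)
    ends: list[float] = []
    run = 1 if t.size else 0
    for k in range(1, t.size):
        isi = t[k] - t[k - 1]
        if isi < threshold:
            run += 1
        else:
            if run >= min_spikes:
                ends.append(float(t[k - 1] + threshold))
            run = 1
    if run >= min_spikes and t.size:
        ends.append(float(t[-1] + threshold))
    return ends
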