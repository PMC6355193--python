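"""Cycle detection, phase differences, gait classification and histograms.

The locomotor rhythm is read off the four flexor-centre (RG-F) output
traces.  The left hind RG-F is the reference limb: each upward crossing of
its output through the onset threshold starts a cycle.  Within every
reference cycle the onsets of the other three limbs define four normalised
phase differences -- hind left-right, fore left-right, homolateral (left
fore vs left hind) and diagonal (right fore vs left hind) -- each in [0, 1),
where 0.5 means alternation and 0 or 1 synchronisation.  Gaits are
categorical patterns of these phase differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GAITS",
    "GaitWindows",
    "CycleRecord",
    "HistogramResult",
    "detect_onsets",
    "phase_difference",
    "cycle_frequency",
    "circular_distance",
    "circular_mean",
    "circular_std",
    "classify_gait",
    "cycles_from_traces",
    "records_to_frame",
    "phase_frequency_histogram",
    "gait_probability_map",
]

GAITS = ("walk", "trot", "gallop", "bound", "unclassified", "quiescent")

#: Limb order used for phase tuples throughout the package.
PHASE_NAMES = ("hind_lr", "fore_lr", "homolateral", "diagonal")

ONSET_THRESHOLD = 0.1
REFRACTORY_MS = 20.0


@dataclass(frozen=True)
class GaitWindows:
    """Circular tolerance windows defining the gait categories.

    ``sync`` bounds the distance from 0 (synchronisation) for bound;
    ``alt`` bounds the distance from 0.5 (alternation) for walk/trot;
    ``diag_sync`` separates trot (diagonal synchronised) from walk.
    Phase values in between the synchronous and alternating windows are the
    intermediate left-right band characteristic of gallop.
    """

    sync: float = 0.15
    alt: float = 0.1
    diag_sync: float = 0.15


def detect_onsets(
    trace: np.ndarray,
    dt: float = 1.0,
    threshold: float = ONSET_THRESHOLD,
    refractory: float = REFRACTORY_MS,
    t0: float = 0.0,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings of an activity trace.

    Crossing times are linearly interpolated between samples; crossings
    closer than ``refractory`` ms to the previous accepted onset are
    suppressed.  A constant trace yields an empty array.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    below = x[:-1] < threshold
    above = x[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - x[idx]) / (x[idx + 1] - x[idx])
    times = t0 + (idx + frac) * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def phase_difference(reference: float, other: float, period: float) -> float:
    """Normalised phase of ``other`` relative to ``reference``: ((other-ref)/T) mod 1."""
    if period <= 0:
        raise ValueError("period must be > 0")
    return float(np.mod((other - reference) / period, 1.0))


def cycle_frequency(onsets: np.ndarray):
    """Per-cycle frequency (Hz) from consecutive onset times in ms.

    Returns an array of length ``len(onsets) - 1``; with fewer than two
    onsets the frequency is undefined and an empty array is returned.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        return np.empty(0)
    return 1000.0 / np.diff(onsets)


def circular_distance(phi, centre):
    """Distance on the unit circle: min(|phi - c|, 1 - |phi - c|)."""
    d = np.abs(np.mod(phi, 1.0) - np.mod(centre, 1.0))
    return np.minimum(d, 1.0 - d)


def circular_mean(phi) -> float:
    """Mean of phases on [0, 1) via the resultant vector."""
    phi = np.asarray(phi, dtype=float)
    z = np.exp(2j * np.pi * phi).mean()
    return float(np.mod(np.angle(z) / (2 * np.pi), 1.0))


def circular_std(phi) -> float:
    """Circular standard deviation of phases on [0, 1), in cycle units."""
    phi = np.asarray(phi, dtype=float)
    r = np.abs(np.exp(2j * np.pi * phi).mean())
    if r >= 1.0:
        return 0.0
    if r <= 0.0:
        return np.inf
    return float(math.sqrt(-2.0 * math.log(r)) / (2 * np.pi))


def classify_gait(phases, windows: GaitWindows | None = None) -> str:
    """Gait label from the (hind L-R, fore L-R, homolateral, diagonal) tuple.

    Bound: both left-right pairs synchronised (within ``sync`` of 0).
    Trot/walk: both left-right pairs alternating (within ``alt`` of 0.5),
    split by whether a diagonal limb pair is synchronised (trot) or not
    (walk); both diagonals are checked -- the second is the first under the
    left-right limb relabelling -- so the label carries no side preference.
    Gallop: either left-right pair in the intermediate band between
    synchronisation and alternation.  Anything else is unclassified.
    """
    w = windows or GaitWindows()
    phases = np.asarray(phases, dtype=float)
    if phases.shape != (4,):
        raise ValueError("expected four phase differences")
    if np.any(np.isnan(phases)):
        return "unclassified"
    if np.any((phases < 0) | (phases >= 1)):
        raise ValueError(f"phase differences must lie in [0, 1): {phases}")
    hind, fore, homo, diag = phases
    hind_sync = circular_distance(hind, 0.0) <= w.sync
    fore_sync = circular_distance(fore, 0.0) <= w.sync
    hind_alt = circular_distance(hind, 0.5) <= w.alt
    fore_alt = circular_distance(fore, 0.5) <= w.alt
    if hind_sync and fore_sync:
        return "bound"
    if hind_alt and fore_alt:
        diag_dist = min(
            circular_distance(diag, 0.0),
            circular_distance((homo - hind) % 1.0, 0.0),
        )
        return "trot" if diag_dist <= w.diag_sync else "walk"
    if (not hind_sync and not hind_alt) or (not fore_sync and not fore_alt):
        return "gallop"
    return "unclassified"


@dataclass(frozen=True)
class CycleRecord:
    """One locomotor cycle of the reference limb (left hind RG-F)."""

    index: int
    onset: float  # ms
    period: float  # ms
    frequency: float  # Hz
    phases: tuple  # (hind L-R, fore L-R, homolateral, diagonal), nan where undefined
    gait: str
    alpha: float = np.nan


def cycles_from_traces(
    time: np.ndarray,
    f_lh: np.ndarray,
    f_rh: np.ndarray,
    f_lf: np.ndarray,
    f_rf: np.ndarray,
    threshold: float = ONSET_THRESHOLD,
    windows: GaitWindows | None = None,
    alpha: float = np.nan,
) -> list[CycleRecord]:
    """Cycle records from the four flexor-centre output traces.

    ``time`` must be a uniform grid in ms.  Each reference (left hind) cycle
    contributes one record; a limb with no onset inside the reference cycle
    gets a nan phase and the cycle is labelled from the remaining phases
    (nan-containing tuples classify as unclassified).
    """
    time = np.asarray(time, dtype=float)
    dt = time[1] - time[0]
    onsets = {
        limb: detect_onsets(trace, dt=dt, threshold=threshold, t0=time[0])
        for limb, trace in (("lh", f_lh), ("rh", f_rh), ("lf", f_lf), ("rf", f_rf))
    }
    ref = onsets["lh"]
    records: list[CycleRecord] = []
    for k in range(len(ref) - 1):
        t0, t1 = ref[k], ref[k + 1]
        period = t1 - t0
        raw: dict[str, float] = {}
        for limb in ("rh", "lf", "rf"):
            times = onsets[limb]
            inside = times[(times >= t0) & (times < t1)]
            if inside.size:
                raw[limb] = phase_difference(t0, inside[0], period)
            else:
                # near-synchronous limbs can jitter just ahead of the
                # reference onset; fold such an onset into this cycle
                early = times[(times >= t0 - 0.25 * period) & (times < t0)]
                raw[limb] = (
                    phase_difference(t0, early[-1], period) if early.size else np.nan
                )
        fore_lr = (
            np.mod(raw["rf"] - raw["lf"], 1.0)
            if not (np.isnan(raw["rf"]) or np.isnan(raw["lf"]))
            else np.nan
        )
        phases = (raw["rh"], fore_lr, raw["lf"], raw["rf"])
        records.append(
            CycleRecord(
                index=k,
                onset=float(t0),
                period=float(period),
                frequency=1000.0 / period,
                phases=phases,
                gait=classify_gait(phases, windows),
                alpha=alpha,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Cycle records as a tidy table."""
    return pd.DataFrame(
        {
            "cycle": [r.index for r in records],
            "alpha": [r.alpha for r in records],
            "onset_ms": [r.onset for r in records],
            "period_ms": [r.period for r in records],
            "frequency_hz": [r.frequency for r in records],
            "phase_hind_lr": [r.phases[0] for r in records],
            "phase_fore_lr": [r.phases[1] for r in records],
            "phase_homolateral": [r.phases[2] for r in records],
            "phase_diagonal": [r.phases[3] for r in records],
            "gait": [r.gait for r in records],
        }
    )


@dataclass(frozen=True)
class HistogramResult:
    """Bivariate relative-frequency histogram over (phase, frequency) bins."""

    values: np.ndarray  # (n_phase_bins, n_freq_bins) relative frequencies
    phase_edges: np.ndarray
    freq_edges: np.ndarray
    total_cycles: int
    out_of_range: float  # fraction of cycles outside the axes' ranges


def phase_frequency_histogram(
    records,
    phase: str = "hind_lr",
    n_phase_bins: int = 65,
    freq_bin_width: float = 0.25,
    freq_max: float = 14.0,
) -> HistogramResult:
    """Relative frequency of (phase difference, cycle frequency) pairs.

    Counts per 2D bin are divided by the *total* number of cycles, so the
    entries sum to 1 minus the out-of-range fraction.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    i_phase = PHASE_NAMES.index(phase)
    phi = np.array([r.phases[i_phase] for r in records], dtype=float)
    freq = np.array([r.frequency for r in records], dtype=float)
    phase_edges = np.linspace(0.0, 1.0, n_phase_bins + 1)
    freq_edges = np.arange(0.0, freq_max + freq_bin_width / 2, freq_bin_width)
    valid = ~np.isnan(phi) & (freq >= 0) & (freq <= freq_max)
    counts, _, _ = np.histogram2d(
        phi[valid], freq[valid], bins=(phase_edges, freq_edges)
    )
    total = len(records)
    return HistogramResult(
        values=counts / total,
        phase_edges=phase_edges,
        freq_edges=freq_edges,
        total_cycles=total,
        out_of_range=1.0 - counts.sum() / total,
    )


def gait_probability_map(
    records,
    freq_bin_width: float = 0.25,
    freq_max: float = 14.0,
) -> pd.DataFrame:
    """Per-frequency-bin relative frequencies of gait expression.

    Gallop and bound are grouped into a single category.  Counts are divided
    by the total number of cycles (same normalisation as the bivariate
    histogram), so the table sums to 1 minus the out-of-range/unclassified
    fraction stored in the ``unbinned`` attribute of the result.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    freq_edges = np.arange(0.0, freq_max + freq_bin_width / 2, freq_bin_width)
    centres = (freq_edges[:-1] + freq_edges[1:]) / 2
    groups = {"walk": ("walk",), "trot": ("trot",), "gallop/bound": ("gallop", "bound")}
    total = len(records)
    table = {}
    for label, members in groups.items():
        freqs = np.array(
            [r.frequency for r in records if r.gait in members], dtype=float
        )
        counts, _ = np.histogram(freqs[freqs <= freq_max], bins=freq_edges)
        table[label] = counts / total
    frame = pd.DataFrame(table, index=pd.Index(centres, name="frequency_hz"))
    frame.attrs["total_cycles"] = total
    frame.attrs["unbinned"] = 1.0 - float(frame.to_numpy().sum())
    return frame
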