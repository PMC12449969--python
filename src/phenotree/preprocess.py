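"""ECG preprocessing: filtering, resampling, median-beat construction,
QRS-duration measurement and broad-QRS cohort selection.

The preprocessing chain mirrors common clinical-ECG practice: a 0.5–100 Hz
bandpass removes baseline wander and high-frequency noise, a 60 Hz notch
suppresses mains interference, and all records are resampled to 400 Hz.
Median beats are built by detecting R peaks on lead II, extracting a fixed
window around each fiducial, and taking the per-sample, per-lead median
across beats; only the 8 informative leads (I, II, V1–V6) are retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import LEADS_8, EcgRecord, MedianBeat

__all__ = [
    "filter_and_resample",
    "build_median_beat",
    "measure_qrs_duration",
    "apply_selection",
    "FlatlineError",
    "InsufficientBeatsError",
]


class FlatlineError(ValueError):
    """Raised when a measurement is undefined on a flat-line signal."""


class InsufficientBeatsError(ValueError):
    """Raised when fewer than the minimum number of beats are detectable."""


def filter_and_resample(
    rec: EcgRecord,
    band: tuple[float, float] = (0.5, 100.0),
    notch_hz: float = 60.0,
    target_fs: float = 400.0,
) -> EcgRecord:
    """Bandpass + notch filter a record and resample it to ``target_fs``.

    Filtering is zero-phase (forward–backward), so fiducial points such as
    the R peak are not shifted by group delay.

    Parameters
    ----------
    rec : EcgRecord
    band : (low_hz, high_hz)
        Bandpass corner frequencies; default (0.5, 100).
    notch_hz : float
        Mains notch frequency; default 60.  Set to 0 to disable.
    target_fs : float
        Output sampling rate; default 400.

    Returns
    -------
    EcgRecord at ``target_fs`` with the same leads and metadata.
    """
    low, high = band
    if not 0 < low < high:
        raise ValueError("require 0 < low_hz < high_hz")
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {high} Hz bandpass "
            "edge (need fs > 2*high_hz)"
        )
    x = rec.signal
    sos = sps.butter(3, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=1)
    if notch_hz and notch_hz < rec.fs / 2:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        y = sps.filtfilt(b, a, y, axis=1)
    if not math.isclose(rec.fs, target_fs):
        n_out = int(round(rec.n_samples * target_fs / rec.fs))
        y = sps.resample_poly(
            y, *_resample_ratio(target_fs, rec.fs), axis=1
        )[:, :n_out]
        if y.shape[1] < n_out:  # pad a trailing sample if rounding fell short
            y = np.pad(y, ((0, 0), (0, n_out - y.shape[1])), mode="edge")
    return EcgRecord(
        signal=y, fs=target_fs, lead_names=rec.lead_names,
        meta=dict(rec.meta), record_id=rec.record_id,
    )


def _resample_ratio(target: float, source: float) -> tuple[int, int]:
    # rational approximation kept small so polyphase filters stay cheap
    from fractions import Fraction

    f = Fraction(target / source).limit_denominator(1000)
    return f.numerator, f.denominator


def detect_r_peaks(rec: EcgRecord, ref_lead: str = "II") -> np.ndarray:
    """Detect R-peak sample indices on a reference lead (default II).

    Peaks are found on the squared, smoothed reference lead with a minimum
    separation of 300 ms and a prominence threshold relative to the largest
    peak, then refined to the local extremum of the raw absolute signal.
    """
    x = rec.lead(ref_lead) if ref_lead in rec.lead_names else rec.signal[0]
    if np.allclose(x, 0):
        return np.array([], dtype=int)
    win = max(3, int(round(0.05 * rec.fs)))
    energy = np.convolve(x**2, np.ones(win) / win, mode="same")
    min_dist = int(round(0.3 * rec.fs))
    cand, props = sps.find_peaks(energy, distance=min_dist, height=0.0)
    if len(cand) == 0:
        return np.array([], dtype=int)
    # two-stage height gate: drop noise bumps (below 5% of the largest
    # peak), then gate against the median of the survivors so one
    # high-amplitude artifact cannot mask the true beats
    h = props["peak_heights"]
    keep = h >= 0.05 * h.max()
    peaks = cand[keep][h[keep] >= 0.25 * np.median(h[keep])]
    # refine to raw |x| extremum within +-50 ms
    half = int(round(0.05 * rec.fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return np.unique(refined)


def build_median_beat(
    rec: EcgRecord,
    window_s: float = 1.2,
    ref_lead: str = "II",
    min_beats: int = 3,
) -> MedianBeat:
    """Collapse a rhythm strip into one 8-lead median beat.

    R peaks are detected on ``ref_lead``; a ``window_s`` window centred on
    each fiducial is extracted per lead, and the per-sample median across
    beats is taken.  The 8 leads I, II, V1–V6 are retained in fixed order.

    Raises
    ------
    InsufficientBeatsError
        If fewer than ``min_beats`` complete beats are detectable.
    """
    missing = [l for l in LEADS_8 if l not in rec.lead_names]
    if missing:
        raise ValueError(f"record lacks required leads: {missing}")
    peaks = detect_r_peaks(rec, ref_lead=ref_lead)
    half = int(round(window_s * rec.fs / 2))
    peaks = peaks[(peaks >= half) & (peaks + half < rec.n_samples)]
    if len(peaks) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(peaks)} complete beats detected (need {min_beats})"
        )
    rows = [rec.lead_names.index(l) for l in LEADS_8]
    stacks = np.stack(
        [rec.signal[rows][:, p - half: p + half] for p in peaks], axis=0
    )  # (n_beats, 8, T)
    med = np.median(stacks, axis=0)
    return MedianBeat(
        beats=med, fs=rec.fs, fiducial_index=half, source_id=rec.record_id
    )


def qrs_energy_envelope(
    beat: MedianBeat, smooth_ms: float = 20.0
) -> np.ndarray:
    """Smoothed multi-lead energy envelope (mean of squared leads)."""
    env = np.mean(beat.beats**2, axis=0)
    win = max(1, int(round(smooth_ms * beat.fs / 1000.0)))
    return np.convolve(env, np.ones(win) / win, mode="same")


def measure_qrs_duration(
    beat: MedianBeat,
    threshold_frac: float = 0.10,
    smooth_ms: float = 20.0,
) -> float:
    """Measure QRS duration (ms) from the multi-lead energy envelope.

    Onset/offset are the edges of the contiguous run, containing the
    envelope maximum, where the smoothed energy envelope exceeds
    ``threshold_frac`` of its peak.  The energy (squared-amplitude)
    envelope keeps lower-amplitude ST/T deflections below threshold.

    Raises
    ------
    FlatlineError
        If the beat is (numerically) flat.
    """
    env = qrs_energy_envelope(beat, smooth_ms=smooth_ms)
    peak = env.max()
    if peak <= 0 or np.allclose(beat.beats, beat.beats[:, :1]):
        raise FlatlineError("QRS duration undefined on a flat-line beat")
    above = env >= threshold_frac * peak
    i_peak = int(np.argmax(env))
    onset = i_peak
    while onset > 0 and above[onset - 1]:
        onset -= 1
    offset = i_peak
    while offset < len(env) - 1 and above[offset + 1]:
        offset += 1
    return (offset - onset + 1) / beat.fs * 1000.0


@dataclass
class SelectionAudit:
    """Per-rule exclusion counts produced by :func:`apply_selection`."""

    n_input: int = 0
    excluded_qrs_le_120: int = 0
    excluded_paced: int = 0
    excluded_cied: int = 0
    excluded_chb: int = 0
    excluded_missing_qrs: int = 0
    n_retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("input records", self.n_input),
            ("excluded: QRS <= 120 ms", self.excluded_qrs_le_120),
            ("excluded: paced", self.excluded_paced),
            ("excluded: CIED", self.excluded_cied),
            ("excluded: complete heart block", self.excluded_chb),
            ("excluded: QRS unmeasurable", self.excluded_missing_qrs),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def apply_selection(
    records: list[EcgRecord],
    use_metadata_qrs: bool = True,
) -> tuple[list[EcgRecord], SelectionAudit]:
    """Apply the broad-QRS selection gate.

    Keeps records with QRS duration strictly greater than 120 ms and none
    of the paced / CIED / complete-heart-block flags set.  A record failing
    several rules is counted once under the first failing rule, in the
    order listed in :class:`SelectionAudit` (mirroring a flow chart).

    Parameters
    ----------
    records : list of EcgRecord
    use_metadata_qrs : bool
        If True (default) the metadata ``qrs_ms`` field is used; otherwise
        the QRS duration is measured from the waveform via a median beat.

    Returns
    -------
    (retained_records, audit)
    """
    audit = SelectionAudit(n_input=len(records))
    kept: list[EcgRecord] = []
    for rec in records:
        qrs = rec.meta.get("qrs_ms") if use_metadata_qrs else None
        if qrs is None and not use_metadata_qrs:
            try:
                beat = build_median_beat(rec)
                qrs = measure_qrs_duration(beat)
            except (InsufficientBeatsError, FlatlineError, ValueError):
                qrs = None
        if qrs is None or not np.isfinite(qrs):
            audit.excluded_missing_qrs += 1
            continue
        if not qrs > 120.0:
            audit.excluded_qrs_le_120 += 1
            continue
        if rec.meta.get("paced_flag", False):
            audit.excluded_paced += 1
            continue
        if rec.meta.get("cied_flag", False):
            audit.excluded_cied += 1
            continue
        if rec.meta.get("chb_flag", False):
            audit.excluded_chb += 1
            continue
        kept.append(rec)
    audit.n_retained = len(kept)
    return kept, audit
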