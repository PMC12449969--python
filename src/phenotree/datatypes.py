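"""Core in-memory containers shared across the pipeline.

An :class:`EcgRecord` holds a raw multi-lead rhythm strip plus per-record
metadata; a :class:`MedianBeat` holds one representative cardiac cycle as an
8-lead matrix sampled at a fixed rate (400 Hz by default).  Leads are always
ordered I, II, V1..V6 — the augmented limb leads and lead III are linear
combinations of I and II and carry no extra information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: canonical 8-lead order used throughout the package
LEADS_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: standard 12-lead order accepted on input
LEADS_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class EcgRecord:
    """A multi-lead ECG waveform with sampling rate and metadata.

    Parameters
    ----------
    signal : ndarray, shape (n_leads, n_samples)
        Waveform in millivolts.
    fs : float
        Sampling frequency in Hz.
    lead_names : tuple of str
        Unique lead labels, one per signal row.
    meta : dict
        Per-record metadata.  Keys used downstream include ``age``, ``sex``,
        ``heart_rate``, ``qrs_ms``, ``qtc_ms``, ``pr_ms``, ``morphology``
        (one of ``LBBB``/``RBBB``/``NSIVCD``), ``axis_class``, and the
        selection flags ``paced_flag``, ``cied_flag``, ``chb_flag``.
    record_id : str
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    meta: dict[str, Any] = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (leads x samples)")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples by name."""
        try:
            return self.signal[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name!r} not present") from None


@dataclass
class MedianBeat:
    """One representative cardiac cycle: an 8 x T matrix at a fixed rate."""

    beats: np.ndarray
    fs: float = 400.0
    fiducial_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        if self.beats.ndim != 2 or self.beats.shape[0] != 8:
            raise ValueError("median beat must be an 8 x T matrix")
        if not np.all(np.isfinite(self.beats)):
            raise ValueError("median beat contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.beats.shape[1]
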