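"""Synthetic broad-QRS ECG cohort generator.

This module generates reproducible synthetic cohorts — 8-lead median beats
and 10 s rhythm strips at 400 Hz, demographics, and linked outcomes — with
the statistical structure the downstream analysis assumes:

* a continuous morphology/risk latent (``severity`` in [0, 1]) that drives
  QRS duration, waveform shape, survival hazard, disease prevalence and
  CRT response, so that recovery of this axis can be tested end to end;
* three broad-QRS morphology classes (LBBB-like, RBBB-like, NSIVCD-like)
  whose lead patterns follow the classic electrocardiographic signatures:
  LBBB-like beats show a deep S in V1–V2 with a broad notched R and
  discordant ST in the lateral leads; RBBB-like beats show an rsR' in V1
  and a broad slurred S in V6;
* survival outcomes from an exponential proportional-hazards model with a
  competing risk of death and independent exponential censoring, chosen so
  every recovery test has a closed-form target.

Each beat is a per-lead sum of Gaussian lobes placed inside a QRS support
window whose realized (envelope-measured) width matches the requested QRS
duration to within +-10 ms; a lower-amplitude T wave and a small P wave are
added outside the QRS support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import LEADS_8, EcgRecord, MedianBeat

__all__ = [
    "MorphologyParams",
    "SyntheticOutcomeSpec",
    "generate_median_beat",
    "generate_rhythm_strip",
    "generate_cohort",
    "MORPHOLOGY_CLASSES",
]

MORPHOLOGY_CLASSES = ("LBBB-like", "RBBB-like", "NSIVCD-like")

#: map generator class label -> clinical morphology label used in metadata
CLASS_TO_MORPHOLOGY = {
    "LBBB-like": "LBBB",
    "RBBB-like": "RBBB",
    "NSIVCD-like": "NSIVCD",
}


@dataclass
class MorphologyParams:
    """Ground-truth parameters of one synthetic beat.

    ``severity`` is the single continuous risk/morphology latent: it
    deepens notching and fractionation, shifts amplitudes, and (at cohort
    level) lengthens the QRS.  It is the axis downstream models are asked
    to rediscover.
    """

    class_label: str = "LBBB-like"
    qrs_duration_ms: float = 140.0
    axis_deg: float = -30.0
    severity: float = 0.5
    amplitude_scale: float = 1.0
    heart_rate_bpm: float = 70.0

    def __post_init__(self) -> None:
        if self.class_label not in MORPHOLOGY_CLASSES:
            raise ValueError(
                f"unknown class_label {self.class_label!r}; "
                f"expected one of {MORPHOLOGY_CLASSES}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")
        if not -180.0 < self.axis_deg <= 180.0:
            raise ValueError("axis_deg must lie in (-180, 180]")


@dataclass
class SyntheticOutcomeSpec:
    """Rates and slopes of the synthetic outcome model.

    Hazards are per day.  The nonfatal event hazard is
    ``baseline_hazard_event * exp(log_hr_per_severity * severity)``; death
    is an independent competing exponential; censoring is independent
    exponential plus an administrative cap.  Prevalent disease follows a
    logistic model in severity.  CRT response follows a logistic model in
    the (standardized) severity axis — the generator's stand-in for tree
    dimension 1, which the fitted tree is expected to recover.
    """

    baseline_hazard_event: float = 1.0 / 3000.0
    baseline_hazard_death: float = 1.0 / 4000.0
    log_hr_per_severity: float = 0.7
    censoring_rate: float = 1.0 / 1400.0
    admin_censor_days: float = 2000.0
    prevalence_logit_intercept: float = -1.5
    prevalence_logit_slope_severity: float = 1.5
    crt_response_logit: tuple[float, float] = (0.2, -0.7)

    def __post_init__(self) -> None:
        for name in ("baseline_hazard_event", "baseline_hazard_death",
                     "censoring_rate", "admin_censor_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------
# Each lead is a sum of 4 Gaussian lobes on fixed slots in normalized QRS
# time u = (t - t_R) / qrs_duration, QRS support u in [-0.5, 0.5].  Slots
# overlap enough that the multi-lead energy envelope stays above 10% of its
# peak across the whole complex, and the outer slots sit so the 10% energy
# crossing lands near +-0.5 (i.e. measured width ~ qrs_duration).

_SLOTS = np.array([-0.35, -0.12, 0.12, 0.35])
_SIGMA_U = 0.11
#: small per-lead timing stagger (fraction of QRS) emulating the activation
#: wavefront sweeping across leads; also prevents synchronized zero-crossings
_LEAD_STAGGER = {
    "I": 0.0, "II": 0.015, "V1": -0.02, "V2": -0.01,
    "V3": 0.0, "V4": 0.01, "V5": 0.02, "V6": 0.025,
}


def _lbbb_amps(v: float) -> dict[str, list[float]]:
    """LBBB-like: QS in V1-V2, broad notched R in I/V5/V6."""
    lateral = [0.5, 0.9, 0.35 - 0.55 * v, 0.8]  # notch deepens with severity
    return {
        "I": lateral,
        "II": [0.3, 0.5, 0.3, 0.45],
        "V1": [-0.6, -1.0, -0.6 + 0.3 * v, -0.9],
        "V2": [-0.66, -1.1, -0.66 + 0.33 * v, -1.0],
        "V3": [-0.5, -0.6, -0.2, -0.3 + 0.3 * v],
        "V4": [-0.2, -0.3, 0.2, 0.4],
        "V5": [0.9 * a for a in lateral],
        "V6": lateral,
    }


def _rbbb_amps(v: float) -> dict[str, list[float]]:
    """RBBB-like: rsR' in V1, broad slurred S in I/V6."""
    rsr = [0.35, -0.5, 0.4, 1.0 + 0.35 * v]
    slurred = [0.5, 0.9, -0.1 - 0.2 * v, -0.6 - 0.2 * v]
    return {
        "I": slurred,
        "II": [0.4, 0.55, 0.1, -0.35],
        "V1": rsr,
        "V2": [0.8 * a for a in rsr],
        "V3": [0.4, 0.5, 0.3, 0.3],
        "V4": [0.5, 0.6, 0.1, -0.2],
        "V5": [0.9 * a for a in slurred],
        "V6": slurred,
    }


def _nsivcd_amps(v: float) -> dict[str, list[float]]:
    """NSIVCD-like: broad fractionated mid-amplitude complexes."""
    frac = [0.6, -(0.1 + 0.35 * v), 0.55, 0.45]
    return {
        "I": frac,
        "II": [0.4, 0.45, 0.3, 0.35],
        "V1": [-0.5, -0.45, 0.2 * v, -0.5],
        "V2": [-0.5, -0.55, -0.35, -0.4],
        "V3": [-0.3, -0.3, 0.25, 0.3],
        "V4": [0.35, 0.4, 0.3, 0.35],
        "V5": [0.9 * a for a in frac],
        "V6": frac,
    }


_TEMPLATES = {
    "LBBB-like": _lbbb_amps,
    "RBBB-like": _rbbb_amps,
    "NSIVCD-like": _nsivcd_amps,
}

#: default electrical axis per class (degrees)
_CLASS_AXIS = {"LBBB-like": -30.0, "RBBB-like": 100.0, "NSIVCD-like": 20.0}


def _axis_factors(params: MorphologyParams) -> dict[str, float]:
    """Limb-lead scaling implementing a crude electrical-axis rotation."""
    d = math.radians(params.axis_deg - _CLASS_AXIS[params.class_label])
    return {"I": math.cos(d), "II": math.cos(d / 2.0)}


def beat_waveform(params: MorphologyParams, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless 8-lead beat at times ``t_ms`` relative to R.

    Returns an array of shape (8, len(t_ms)) in mV.
    """
    d = params.qrs_duration_ms
    v = params.severity
    amps = _TEMPLATES[params.class_label](v)
    ax = _axis_factors(params)
    out = np.zeros((8, len(t_ms)))
    qrs_end = 0.5 * d
    s = _SIGMA_U * d
    for i, lead in enumerate(LEADS_8):
        y = np.zeros_like(t_ms, dtype=float)
        centers = (_SLOTS + _LEAD_STAGGER[lead]) * d
        for c, amp in zip(centers, amps[lead]):
            y += amp * np.exp(-0.5 * ((t_ms - c) / s) ** 2)
        y *= ax.get(lead, 1.0)
        # discordant T wave: sign opposite the terminal QRS deflection,
        # amplitude kept below the 10% energy threshold of the envelope
        term_sign = math.copysign(1.0, amps[lead][-1])
        y += -term_sign * 0.22 * np.exp(
            -0.5 * ((t_ms - (qrs_end + 160.0)) / 60.0) ** 2
        )
        # small P wave before QRS onset
        y += 0.08 * np.exp(-0.5 * ((t_ms + qrs_end + 120.0) / 25.0) ** 2)
        out[i] = y
    return params.amplitude_scale * out


def generate_median_beat(
    params: MorphologyParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 400.0,
    window_s: float = 1.2,
) -> MedianBeat:
    """Generate one synthetic 8-lead median beat.

    Parameters
    ----------
    params : MorphologyParams
    noise_sd : float
        SD of additive white Gaussian noise (mV); must be >= 0.
    seed : int
        Seed for the noise stream; the noiseless waveform is deterministic.
    fs, window_s :
        Sampling rate (default 400 Hz) and window length (default 1.2 s)
        centred on the R fiducial.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(window_s * fs))
    t_ms = (np.arange(n) - n // 2) / fs * 1000.0
    y = beat_waveform(params, t_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return MedianBeat(beats=y, fs=fs, fiducial_index=n // 2)


def generate_rhythm_strip(
    params: MorphologyParams,
    duration_s: float = 10.0,
    fs: float = 400.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    rr_jitter_frac: float = 0.02,
    record_id: str = "",
) -> EcgRecord:
    """Generate a rhythm strip of repeated beats at ``heart_rate_bpm``.

    Beats are placed at RR intervals with multiplicative Gaussian jitter
    (``rr_jitter_frac`` of the RR interval) and additive white noise.  With
    jitter and noise both zero, every beat is identical to the
    :func:`generate_median_beat` waveform.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t_ms = np.arange(n) / fs * 1000.0
    rr_ms = 60000.0 / params.heart_rate_bpm
    sig = np.zeros((8, n))
    # first R placed one half RR in; support extends ~0.6 s around each R
    center = rr_ms / 2.0
    while center < duration_s * 1000.0 + 300.0:
        rel = t_ms - center
        mask = np.abs(rel) <= 650.0
        if mask.any():
            sig[:, mask] += beat_waveform(params, rel[mask])
        step = rr_ms * (1.0 + rr_jitter_frac * rng.normal())
        center += max(step, 0.3 * rr_ms)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return EcgRecord(
        signal=sig, fs=fs, lead_names=LEADS_8,
        meta={"heart_rate": params.heart_rate_bpm}, record_id=record_id,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    n: int,
    spec: SyntheticOutcomeSpec | None = None,
    class_mix: tuple[float, float, float] = (0.35, 0.45, 0.20),
    seed: int = 0,
    ineligible_fraction: float = 0.15,
    crt_fraction_of_lbbb: float = 0.4,
    noise_sd: float = 0.02,
    return_waveforms: bool = True,
    rhythm_strips: bool = False,
) -> tuple[list[EcgRecord] | list[MedianBeat], pd.DataFrame]:
    """Generate a synthetic broad-QRS cohort with linked outcomes.

    Parameters
    ----------
    n : int
        Number of records (including the ineligible fraction).
    spec : SyntheticOutcomeSpec
        Outcome-model rates and slopes (defaults above).
    class_mix : 3-tuple of probabilities
        Mix over (LBBB-like, RBBB-like, NSIVCD-like); must sum to 1.
    seed : int
    ineligible_fraction : float
        Fraction of records made ineligible for the broad-QRS cohort
        (narrow QRS, or a paced/CIED/complete-heart-block flag set), so the
        selection gate has work to do.
    crt_fraction_of_lbbb : float
        Fraction of eligible LBBB records given pre/post CRT echo pairs.
    noise_sd : float
        Waveform noise SD in mV.
    return_waveforms : bool
        If False, the first return value is an empty list (metadata only);
        useful for statistical tests that never touch waveforms.
    rhythm_strips : bool
        If True return 10 s :class:`EcgRecord` strips; otherwise return
        :class:`MedianBeat` objects directly.

    Returns
    -------
    (records, outcomes)
        ``outcomes`` is one row per record with the column dictionary
        documented in :data:`OUTCOME_COLUMNS`; all generator ground-truth
        parameters (severity, responder status, spec values) are persisted
        for recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.sum() <= 0:
        raise ValueError("class_mix is degenerate (sums to zero)")
    if not math.isclose(mix.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("class_mix must sum to 1")
    spec = spec or SyntheticOutcomeSpec()
    rng = np.random.default_rng(seed)

    classes = rng.choice(len(MORPHOLOGY_CLASSES), size=n, p=mix)
    severity = rng.uniform(0.0, 1.0, size=n)
    qrs = np.clip(122.0 + 50.0 * severity + rng.normal(0, 4, n), 121.0, 180.0)
    hr = np.clip(rng.normal(75, 12, n), 40.0, 120.0)
    amp = np.exp(rng.normal(0.0, 0.15, n))
    age = np.clip(rng.normal(70, 10, n), 18, 95)
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    qtc = np.clip(400.0 + 60.0 * severity + rng.normal(0, 15, n), 330, 600)
    pr = np.clip(rng.normal(165, 20, n), 100, 300)
    axis = np.array([
        _CLASS_AXIS[MORPHOLOGY_CLASSES[c]] + rng.normal(0, 15)
        for c in classes
    ])
    axis = ((axis + 180.0) % 360.0) - 180.0
    axis[axis == -180.0] = 180.0

    # ineligible records: narrow QRS or an exclusion flag
    elig = rng.random(n) >= ineligible_fraction
    paced = np.zeros(n, bool)
    cied = np.zeros(n, bool)
    chb = np.zeros(n, bool)
    for i in np.flatnonzero(~elig):
        mode = rng.integers(0, 4)
        if mode == 0:
            qrs[i] = rng.uniform(80.0, 120.0)
        elif mode == 1:
            paced[i] = True
        elif mode == 2:
            cied[i] = True
        else:
            chb[i] = True

    # survival: exponential PH for the nonfatal event; competing death;
    # independent censoring + administrative cap
    lam_event = spec.baseline_hazard_event * np.exp(
        spec.log_hr_per_severity * severity
    )
    t_event = rng.exponential(1.0 / lam_event)
    t_death = rng.exponential(1.0 / spec.baseline_hazard_death, size=n)
    t_cens = np.minimum(
        rng.exponential(1.0 / spec.censoring_rate, size=n),
        spec.admin_censor_days,
    )
    time = np.minimum.reduce([t_event, t_death, t_cens])
    indicator = np.select(
        [time == t_event, time == t_death], [1, 2], default=0
    )
    time = np.maximum(time, 0.5)  # times strictly > 0

    prevalent = rng.random(n) < _logistic(
        spec.prevalence_logit_intercept
        + spec.prevalence_logit_slope_severity * severity
    )

    # CRT subset: eligible LBBB records; response driven by the severity
    # axis (the generator's proxy for tree dimension 1)
    is_lbbb = classes == 0
    crt = is_lbbb & elig & (rng.random(n) < crt_fraction_of_lbbb)
    sev_std = (severity - 0.5) / np.sqrt(1.0 / 12.0)
    b0, b1 = spec.crt_response_logit
    responder = rng.random(n) < _logistic(b0 + b1 * sev_std)

    echo = _echo_pairs(rng, n, responder)
    echo_offset = rng.integers(-30, 31, size=n)

    ids = [f"S{seed:04d}-{i:05d}" for i in range(n)]
    outcomes = pd.DataFrame({
        "id": ids,
        "class_label": [MORPHOLOGY_CLASSES[c] for c in classes],
        "morphology": [CLASS_TO_MORPHOLOGY[MORPHOLOGY_CLASSES[c]]
                       for c in classes],
        "severity": severity,
        "age": age,
        "sex": sex,
        "heart_rate": hr,
        "qrs_ms": qrs,
        "qtc_ms": qtc,
        "pr_ms": pr,
        "axis_deg": axis,
        "paced_flag": paced,
        "cied_flag": cied,
        "chb_flag": chb,
        "eligible": elig & (qrs > 120.0),
        "time_to_event": time,
        "event_indicator": indicator,
        "prevalent_disease": prevalent,
        "crt": crt,
        "crt_responder_truth": np.where(crt, responder, pd.NA),
        "echo_offset_days": echo_offset,
    })
    for k, v in echo.items():
        outcomes[k] = np.where(crt, v, np.nan)
    outcomes.attrs["generator"] = {
        "seed": seed, "n": n, "class_mix": list(mix),
        "noise_sd": noise_sd, "spec": asdict(spec),
    }

    records: list = []
    if return_waveforms:
        child = rng.spawn(1)[0]
        for i in range(n):
            p = MorphologyParams(
                class_label=MORPHOLOGY_CLASSES[classes[i]],
                qrs_duration_ms=float(np.clip(qrs[i], 121, 180)),
                axis_deg=float(axis[i]),
                severity=float(severity[i]),
                amplitude_scale=float(amp[i]),
                heart_rate_bpm=float(hr[i]),
            )
            s = int(child.integers(0, 2**31 - 1))
            if rhythm_strips:
                rec = generate_rhythm_strip(
                    p, duration_s=10.0, fs=400.0, seed=s,
                    noise_sd=noise_sd, record_id=ids[i],
                )
                rec.meta.update(outcomes.iloc[i].to_dict())
                records.append(rec)
            else:
                mb = generate_median_beat(p, noise_sd=noise_sd, seed=s)
                mb.source_id = ids[i]
                records.append(mb)
    return records, outcomes


def _echo_pairs(
    rng: np.random.Generator, n: int, responder: np.ndarray
) -> dict[str, np.ndarray]:
    """Pre/post echo pairs consistent with drawn responder status.

    Responders improve past every endpoint threshold (LVEF +10 points
    absolute; LVESD/LVESV -15% relative); non-responders stay short of all
    of them.  A single responder draw drives all three endpoints.
    """
    lvef_pre = np.clip(rng.normal(27, 5, n), 10, 40)
    lvesd_pre = np.clip(rng.normal(55, 6, n), 35, 80)
    lvesv_pre = np.clip(rng.normal(160, 30, n), 80, 300)
    d_lvef = np.where(responder, 10 + rng.exponential(4, n),
                      np.clip(rng.normal(3, 3, n), -8, 9))
    f_lvesd = np.where(responder, 0.15 + 0.1 * rng.random(n),
                       np.clip(rng.normal(0.05, 0.05, n), -0.1, 0.14))
    f_lvesv = np.where(responder, 0.15 + 0.15 * rng.random(n),
                       np.clip(rng.normal(0.05, 0.06, n), -0.1, 0.14))
    return {
        "lvef_pre": lvef_pre,
        "lvef_post": np.clip(lvef_pre + d_lvef, 5, 75),
        "lvesd_pre": lvesd_pre,
        "lvesd_post": lvesd_pre * (1 - f_lvesd),
        "lvesv_pre": lvesv_pre,
        "lvesv_post": lvesv_pre * (1 - f_lvesv),
    }


#: column dictionary for the outcome table written by :func:`generate_cohort`
OUTCOME_COLUMNS = {
    "id": "record identifier",
    "class_label": "generator morphology class (ground truth)",
    "morphology": "clinical morphology label (LBBB/RBBB/NSIVCD)",
    "severity": "continuous risk latent in [0,1] (ground truth)",
    "age": "years",
    "sex": "M/F",
    "heart_rate": "bpm",
    "qrs_ms": "QRS duration, ms",
    "qtc_ms": "corrected QT, ms",
    "pr_ms": "PR interval, ms",
    "axis_deg": "frontal-plane QRS axis, degrees",
    "paced_flag": "ventricular pacing present",
    "cied_flag": "implanted device present",
    "chb_flag": "complete heart block",
    "eligible": "passes broad-QRS selection",
    "time_to_event": "observed follow-up, days",
    "event_indicator": "0 censored / 1 event / 2 competing death",
    "prevalent_disease": "prevalent-disease flag",
    "crt": "record belongs to the CRT echo subset",
    "crt_responder_truth": "generator responder status (CRT subset)",
    "echo_offset_days": "echo date minus ECG date, days",
    "lvef_pre": "pre-CRT LVEF, %",
    "lvef_post": "6-month post-CRT LVEF, %",
    "lvesd_pre": "pre-CRT LV end-systolic diameter, mm",
    "lvesd_post": "post-CRT LVESD, mm",
    "lvesv_pre": "pre-CRT LV end-systolic volume, mL",
    "lvesv_post": "post-CRT LVESV, mL",
}
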