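"""Cardiac resynchronization therapy (CRT) response analysis.

Response is judged on echocardiographic change between the pre-implant
and 6-month post-implant studies, on three endpoints:

* LVEF:  an increase of >= 10 percentage points (absolute difference);
* LVESD: a decrease of >= 15% (relative difference);
* LVESV: a decrease of >= 15% (relative difference).

A missing member of a pre/post pair leaves that endpoint undefined (not
"no response"); undefined endpoints are excluded from response models.
Endpoints are pure functions of the echo pair — no tree variable enters
their definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcomes import ModelResult, fit_adjusted_model

__all__ = ["compute_crt_endpoints", "link_echo_to_ecg",
           "model_crt_response"]

ENDPOINTS = ("resp_lvef", "resp_lvesd", "resp_lvesv")


def _endpoint_absolute(pre: float, post: float,
                       threshold: float) -> bool | None:
    if pre is None or post is None or np.isnan(pre) or np.isnan(post):
        return None
    return bool(post - pre >= threshold)


def _endpoint_relative(pre: float, post: float,
                       threshold: float) -> bool | None:
    if pre is None or post is None or np.isnan(pre) or np.isnan(post):
        return None
    if pre == 0:
        raise ValueError(
            "relative endpoint undefined: pre-CRT value is zero"
        )
    return bool((pre - post) / pre >= threshold)


def compute_crt_endpoints(rec: dict | pd.Series) -> dict[str, bool | None]:
    """Responder status for the three endpoints of one record.

    ``rec`` must carry (some of) ``lvef_pre``/``lvef_post``,
    ``lvesd_pre``/``lvesd_post``, ``lvesv_pre``/``lvesv_post``.
    Returns None for an endpoint whose pair is incomplete.
    """
    get = rec.get if isinstance(rec, dict) else \
        (lambda k, d=None: rec[k] if k in rec.index else d)
    out = {
        "resp_lvef": _endpoint_absolute(
            get("lvef_pre", np.nan), get("lvef_post", np.nan), 10.0),
        "resp_lvesd": _endpoint_relative(
            get("lvesd_pre", np.nan), get("lvesd_post", np.nan), 0.15),
        "resp_lvesv": _endpoint_relative(
            get("lvesv_pre", np.nan), get("lvesv_post", np.nan), 0.15),
    }
    if all(v is None for v in out.values()):
        raise ValueError("no paired pre/post echo measure present")
    return out


def add_crt_endpoints(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized endpoint computation over a CRT table."""
    out = df.copy()
    out["resp_lvef"] = (df["lvef_post"] - df["lvef_pre"] >= 10.0) \
        .where(df[["lvef_pre", "lvef_post"]].notna().all(axis=1), other=pd.NA)
    out["resp_lvesd"] = (
        (df["lvesd_pre"] - df["lvesd_post"]) / df["lvesd_pre"] >= 0.15
    ).where(df[["lvesd_pre", "lvesd_post"]].notna().all(axis=1), other=pd.NA)
    out["resp_lvesv"] = (
        (df["lvesv_pre"] - df["lvesv_post"]) / df["lvesv_pre"] >= 0.15
    ).where(df[["lvesv_pre", "lvesv_post"]].notna().all(axis=1), other=pd.NA)
    return out


def link_echo_to_ecg(
    ecgs: pd.DataFrame,
    echos: pd.DataFrame,
    window_days: int = 60,
    ecg_date_col: str = "ecg_date",
    echo_date_col: str = "echo_date",
) -> pd.DataFrame:
    """Link each ECG to its nearest echo within ``window_days``.

    One echo may serve several ECGs.  Ties (two echos equidistant from an
    ECG) go to the earlier echo.  Returns the ECG table joined with the
    linked echo columns plus ``link_distance_days``; unlinked ECGs keep
    NaN echo fields.
    """
    e_dates = pd.to_numeric(pd.Series(echos[echo_date_col])).to_numpy()
    order = np.argsort(e_dates, kind="stable")
    rows = []
    for _, ecg in ecgs.iterrows():
        t = float(ecg[ecg_date_col])
        dist = np.abs(e_dates - t)
        ok = dist <= window_days
        if not ok.any():
            rows.append((None, np.nan))
            continue
        best = np.min(dist[ok])
        cand = np.flatnonzero((dist == best) & ok)
        # tie-break: earlier echo date
        chosen = cand[np.argmin(e_dates[cand])]
        rows.append((chosen, float(best)))
    linked = ecgs.copy().reset_index(drop=True)
    idx = [r[0] for r in rows]
    linked["link_distance_days"] = [r[1] for r in rows]
    echo_cols = [c for c in echos.columns if c != echo_date_col]
    for c in echo_cols:
        linked[c] = [
            echos.iloc[i][c] if i is not None else np.nan for i in idx
        ]
    linked["linked_echo_index"] = [i if i is not None else -1 for i in idx]
    return linked


def model_crt_response(
    records: pd.DataFrame,
    endpoint: str = "resp_lvef",
    predictors: list[str] | None = None,
    covariates: list[str] | None = None,
    lbbb_only: bool = True,
    morphology_col: str = "morphology",
    min_records: int = 20,
) -> ModelResult:
    """Logistic model of a CRT endpoint on tree variables.

    Adjusted for age, sex and QRS duration by default, and restricted to
    LBBB-labelled records unless ``lbbb_only=False``.  Records with an
    undefined endpoint are excluded.

    Raises
    ------
    ValueError if fewer than ``min_records`` rows have a defined endpoint.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    predictors = predictors or ["dim1"]
    covariates = covariates if covariates is not None \
        else ["age", "sex", "qrs_ms"]
    df = records
    if lbbb_only and morphology_col in df.columns:
        df = df[df[morphology_col] == "LBBB"]
    df = df[df[endpoint].notna()].copy()
    if len(df) < min_records:
        raise ValueError(
            f"only {len(df)} records with defined {endpoint} "
            f"(need {min_records})"
        )
    df[endpoint] = df[endpoint].astype(int)
    return fit_adjusted_model(
        df, endpoint, predictors, covariates, kind="logistic",
        reference_phenogroup=None,
    )
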