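"""Statistical overlays on the tree: prevalent-disease regression,
incident-disease survival modeling with competing risks, per-sample risk
surfaces, spatial autocorrelation, explainability, and prognostic-model
comparison.

Model kinds
-----------
* ``logistic`` / ``linear`` — statsmodels GLM/OLS fits for prevalent
  (binary) and continuous outcomes.
* ``cox`` — Cox proportional hazards via lifelines (fatal outcomes).
  The proportional-hazards assumption is deliberately not tested; the
  hazard ratio is read as an average effect over follow-up.
* ``fine_gray`` — Fine–Gray subdistribution hazard for nonfatal outcomes
  with death as the competing event.  Implemented by expanding subjects
  with a competing event into counting-process rows that remain in the
  risk set with inverse-probability-of-censoring weights (Kaplan–Meier of
  the censoring distribution), then fitting a weighted Cox partial
  likelihood.  With no competing events the expansion is the identity and
  the fit reduces exactly to Cox.

Event coding: 0 = censored, 1 = event of interest, 2 = competing death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from patsy import dmatrix
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .tree import TreeModel

__all__ = [
    "ModelResult",
    "fit_adjusted_model",
    "finegray_expand",
    "risk_surface",
    "morans_i",
    "explain_phenogroups",
    "compare_prognostic_models",
    "adjust_pvalues",
]


class ModelFitError(RuntimeError):
    """Raised on separation, singularity or convergence failure."""


@dataclass
class ModelResult:
    """Tidy regression output.

    ``table`` columns: term, estimate (log scale where applicable),
    exp_estimate (OR/HR/SHR; equals estimate for linear models), ci_low,
    ci_high (on the exponentiated scale for log-link models), p, and
    optionally q after :func:`adjust_pvalues`.
    """

    table: pd.DataFrame
    model_kind: str
    n: int
    events: int | None = None

    def term(self, name: str) -> pd.Series:
        hit = self.table[self.table["term"].str.contains(name, regex=False)]
        if len(hit) == 0:
            raise KeyError(f"no term matching {name!r}")
        return hit.iloc[0]


def _design(data: pd.DataFrame, terms: list[str],
            reference_phenogroup: int | None) -> pd.DataFrame:
    """Patsy design matrix (no intercept column) for the given terms."""
    parts = []
    for t in terms:
        if t == "phenogroup" and reference_phenogroup is not None:
            parts.append(
                f"C(phenogroup, Treatment(reference={reference_phenogroup}))"
            )
        elif data[t].dtype == object or isinstance(
            data[t].dtype, pd.CategoricalDtype
        ) or data[t].dtype == bool:
            parts.append(f"C({t})")
        else:
            parts.append(t)
    X = dmatrix(" + ".join(parts), data, return_type="dataframe")
    X = X.drop(columns="Intercept")
    X.columns = [_clean_term(c) for c in X.columns]
    return X


def _clean_term(c: str) -> str:
    import re

    c = re.sub(r"C\(phenogroup, Treatment\(reference=\d+\)\)\[T\.([^\]]+)\]",
               r"phenogroup=\1", c)
    c = re.sub(r"C\(([^)]+)\)\[T\.([^\]]+)\]", r"\1=\2", c)
    return c


def fit_adjusted_model(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] | None = None,
    kind: str = "logistic",
    duration_col: str = "time_to_event",
    event_col: str = "event_indicator",
    reference_phenogroup: int | None = 4,
) -> ModelResult:
    """Fit an adjusted association model of tree variables on an outcome.

    Parameters
    ----------
    data : one row per ECG; complete cases for the named columns are used
        (dropped-row count recorded in the result table attrs).
    outcome : column name (binary/continuous) for logistic/linear; for
        cox/fine_gray the ``duration_col``/``event_col`` pair is used and
        ``outcome`` is only a label.
    predictors, covariates : column names entering the linear predictor;
        categorical columns are dummy-coded, phenogroup against
        ``reference_phenogroup``.
    kind : {"logistic", "linear", "cox", "fine_gray"}

    Raises
    ------
    ModelFitError on separation, singularity, or convergence failure.
    """
    covariates = covariates or []
    terms = list(predictors) + list(covariates)
    need = terms + ([outcome] if kind in ("logistic", "linear")
                    else [duration_col, event_col])
    df = data.dropna(subset=[c for c in need if c in data.columns]).copy()
    n_dropped = len(data) - len(df)
    X = _design(df, terms, reference_phenogroup)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelFitError("design matrix is singular")

    if kind in ("logistic", "linear"):
        y = df[outcome].astype(float).to_numpy()
        Xc = sm.add_constant(X)
        try:
            if kind == "logistic":
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            else:
                fit = sm.OLS(y, Xc).fit()
        except Exception as e:  # separation surfaces as warnings/errors
            raise ModelFitError(f"{kind} fit failed: {e}") from e
        if kind == "logistic" and not fit.mle_retvals.get("converged", True):
            raise ModelFitError("logistic fit did not converge")
        params = fit.params.drop("const")
        ci = fit.conf_int().drop(index="const")
        pvals = fit.pvalues.drop("const")
        expit = np.exp if kind == "logistic" else (lambda v: v)
        table = pd.DataFrame({
            "term": params.index,
            "estimate": params.to_numpy(),
            "exp_estimate": expit(params.to_numpy()),
            "ci_low": expit(ci[0].to_numpy()),
            "ci_high": expit(ci[1].to_numpy()),
            "p": pvals.to_numpy(),
        })
        events = int(y.sum()) if kind == "logistic" else None
    elif kind == "cox":
        work = X.copy()
        work["_T"] = df[duration_col].to_numpy()
        work["_E"] = (df[event_col].to_numpy() == 1).astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(work, duration_col="_T", event_col="_E",
                    fit_options={"precision": 1e-10})
        except Exception as e:
            raise ModelFitError(f"cox fit failed: {e}") from e
        s = cph.summary
        table = pd.DataFrame({
            "term": s.index,
            "estimate": s["coef"].to_numpy(),
            "exp_estimate": s["exp(coef)"].to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(s["coef upper 95%"].to_numpy()),
            "p": s["p"].to_numpy(),
        })
        events = int(work["_E"].sum())
    elif kind == "fine_gray":
        expanded = finegray_expand(
            df.assign(**{c: X[c] for c in X.columns}),
            duration_col, event_col, X.columns.tolist(),
        )
        ctv = CoxTimeVaryingFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctv.fit(expanded[
                    ["_id", "_start", "_stop", "_event", "_w"]
                    + X.columns.tolist()],
                    id_col="_id", start_col="_start", stop_col="_stop",
                    event_col="_event", weights_col="_w",
                    fit_options={"precision": 1e-10},
                )
        except Exception as e:
            raise ModelFitError(f"fine_gray fit failed: {e}") from e
        s = ctv.summary
        table = pd.DataFrame({
            "term": s.index,
            "estimate": s["coef"].to_numpy(),
            "exp_estimate": s["exp(coef)"].to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(s["coef upper 95%"].to_numpy()),
            "p": s["p"].to_numpy(),
        })
        events = int((df[event_col] == 1).sum())
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    table.attrs["n_dropped_incomplete"] = n_dropped
    return ModelResult(table=table, model_kind=kind, n=len(df),
                       events=events)


# ---------------------------------------------------------------------------
# Fine–Gray expansion
# ---------------------------------------------------------------------------

def finegray_expand(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    keep_cols: list[str],
) -> pd.DataFrame:
    """Expand competing-event subjects into weighted risk-set rows.

    Subjects censored (0) or with the event of interest (1) contribute one
    unit-weight row over (0, T].  Subjects with the competing event (2)
    remain in the subdistribution risk set after T with weight
    G(t)/G(T) — G the Kaplan–Meier survival of the censoring
    distribution — piecewise constant between subsequent event times.
    """
    T = df[duration_col].to_numpy(float)
    E = df[event_col].to_numpy(int)

    km = KaplanMeierFitter()
    km.fit(T, event_observed=(E == 0).astype(int))

    def G(t: np.ndarray) -> np.ndarray:
        return km.survival_function_at_times(t).to_numpy()

    event_times = np.unique(T[E == 1])
    rows = []
    base = df[keep_cols].reset_index(drop=True)
    for i in range(len(df)):
        if E[i] != 2:
            rows.append((i, 0.0, T[i], int(E[i] == 1), 1.0))
        else:
            later = event_times[event_times > T[i]]
            if len(later) == 0:
                rows.append((i, 0.0, T[i], 0, 1.0))
                continue
            gi = max(float(G(np.array([T[i]]))[0]), 1e-12)
            cuts = np.concatenate([[T[i]], later])
            w = np.clip(G(later) / gi, 0.0, 1.0)
            rows.append((i, 0.0, T[i], 0, 1.0))
            for a, b, wt in zip(cuts[:-1], cuts[1:], w):
                rows.append((i, a, b, 0, max(float(wt), 1e-12)))
    out = pd.DataFrame(rows,
                       columns=["_row", "_start", "_stop", "_event", "_w"])
    out = out.join(base, on="_row")
    out["_id"] = out["_row"]
    return out


# ---------------------------------------------------------------------------
# risk surfaces
# ---------------------------------------------------------------------------

def risk_surface(
    tree: TreeModel,
    data: pd.DataFrame,
    outcome: str = "event",
    horizon: float | None = None,
    duration_col: str = "time_to_event",
    event_col: str = "event_indicator",
) -> np.ndarray:
    """Per-sample predicted event probability at a horizon.

    Fits a survival model on (dim1, dim2, pseudotime) — Cox for the fatal
    outcome (``outcome="death"``), Fine–Gray for the nonfatal outcome with
    death competing (``outcome="event"``) — and returns each sample's
    predicted cumulative incidence at ``horizon`` (default: median
    follow-up).
    """
    if tree.pseudotime_global is None:
        raise ValueError("tree has no pseudotime; run compute_pseudotime")
    df = pd.DataFrame({
        "dim1": tree.Z[:, 0], "dim2": tree.Z[:, 1],
        "pseudotime": tree.pseudotime_global,
        "_T": data[duration_col].to_numpy(float),
        "_ind": data[event_col].to_numpy(int),
    })
    if horizon is None:
        horizon = float(np.median(df["_T"]))
    elif horizon > df["_T"].max():
        warnings.warn("horizon beyond observed follow-up; extrapolating")
    feats = ["dim1", "dim2", "pseudotime"]

    if outcome == "death":
        work = df[feats].copy()
        work["_T"] = df["_T"]
        work["_E"] = (df["_ind"] == 2).astype(int)
        cph = CoxPHFitter()
        cph.fit(work, duration_col="_T", event_col="_E")
        surv = cph.predict_survival_function(work[feats],
                                             times=[horizon])
        return 1.0 - surv.iloc[0].to_numpy()

    expanded = finegray_expand(df, "_T", "_ind", feats)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(expanded[["_id", "_start", "_stop", "_event", "_w"] + feats],
                id_col="_id", start_col="_start", stop_col="_stop",
                event_col="_event", weights_col="_w")
    H0 = ctv.baseline_cumulative_hazard_
    h0 = float(np.interp(horizon, H0.index.to_numpy(),
                         H0.iloc[:, 0].to_numpy()))
    lp = ctv.predict_log_partial_hazard(df[feats]).to_numpy()
    return 1.0 - np.exp(-h0 * np.exp(lp))


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    k_neighbors: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Global Moran's I over a row-standardized k-NN weight graph.

    Returns the observed statistic, its analytic null mean −1/(N−1), and
    a two-sided permutation p-value from ``n_perm`` shuffles.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.allclose(x, x[0]):
        raise ValueError("Moran's I undefined for constant values")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, nbrs = nn.kneighbors(coords)
    nbrs = nbrs[:, 1:]  # drop self
    w = 1.0 / k_neighbors

    z = x - x.mean()
    denom = np.sum(z**2)

    # with row-standardized weights S0 = n, so I = num / sum(z^2)
    def stat(zv: np.ndarray) -> float:
        return float(np.sum(zv[:, None] * zv[nbrs] * w) / denom)

    obs = stat(z)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(z))
    p = (np.sum(np.abs(perms - perms.mean())
                >= abs(obs - perms.mean())) + 1) / (n_perm + 1)
    return {"I": obs, "expected_I": -1.0 / (n - 1), "p_perm": float(p)}


# ---------------------------------------------------------------------------
# explainability
# ---------------------------------------------------------------------------

def explain_phenogroups(
    latents: np.ndarray,
    phenogroup: np.ndarray,
    C_grid: tuple[float, ...] | None = None,
    l1_ratios: tuple[float, ...] = (0.2, 0.5, 0.8),
    n_top: int = 3,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Elastic-net logistic regression of latent features on phenogroups.

    One-vs-rest per phenogroup, features standardized; penalty strength
    and L1/L2 mixing selected by 5-fold cross-validation over ``C_grid``
    and ``l1_ratios`` (a single grid value skips CV and fits directly).
    Returns, per phenogroup, the ``n_top`` features ranked by |coefficient|
    (all coefficients included in the frame; zero-coefficient features
    rank last).
    """
    X = np.asarray(latents, dtype=float)
    y = np.asarray(phenogroup)
    if len(np.unique(y)) < 2:
        raise ValueError("phenogroup labels are degenerate (single class)")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    out: dict[int, pd.DataFrame] = {}
    for g in np.unique(y):
        yb = (y == g).astype(int)
        if C_grid is not None and len(C_grid) == 1 and len(l1_ratios) == 1:
            clf = LogisticRegression(
                solver="saga", C=C_grid[0], l1_ratio=l1_ratios[0],
                max_iter=5000, random_state=seed,
            ).fit(Xs, yb)
        else:
            clf = LogisticRegressionCV(
                Cs=list(C_grid) if C_grid else 5, solver="saga",
                l1_ratios=list(l1_ratios), cv=5,
                max_iter=5000, random_state=seed, n_jobs=1,
            ).fit(Xs, yb)
        coef = clf.coef_.ravel()
        order = np.argsort(-np.abs(coef))
        frame = pd.DataFrame({
            "feature": order,
            "coef": coef[order],
        })
        frame["rank"] = np.arange(1, len(coef) + 1)
        out[int(g)] = frame.head(n_top).reset_index(drop=True) \
            if n_top else frame
        out[int(g)].attrs["all_coefs"] = coef
    return out


# ---------------------------------------------------------------------------
# prognostic model comparison
# ---------------------------------------------------------------------------

def _cox_fit(df: pd.DataFrame, terms: list[str], duration_col: str,
             event_col: str) -> tuple[CoxPHFitter, pd.DataFrame]:
    work = df[terms].copy()
    work["_T"] = df[duration_col].to_numpy(float)
    work["_E"] = df[event_col].to_numpy(int)
    if work["_E"].sum() == 0:
        raise ModelFitError("no events; cannot fit Cox model")
    cph = CoxPHFitter()
    cph.fit(work, duration_col="_T", event_col="_E")
    return cph, work


def _per_subject_logpl(lp: np.ndarray, T: np.ndarray,
                       E: np.ndarray) -> np.ndarray:
    """Per-event-subject Breslow log-partial-likelihood contributions."""
    order = np.argsort(-T)  # descending: risk set = prefix
    lp_o, T_o, E_o = lp[order], T[order], E[order]
    run = np.logaddexp.accumulate(lp_o)
    contrib = np.full(len(lp), np.nan)
    for pos in np.flatnonzero(E_o == 1):
        # risk set: all with T >= T_event (handle ties by extending prefix)
        hi = np.searchsorted(-T_o, -T_o[pos], side="right") - 1
        contrib[order[pos]] = lp_o[pos] - run[hi]
    return contrib


def compare_prognostic_models(
    data: pd.DataFrame,
    model_a_terms: list[str],
    model_b_terms: list[str],
    duration_col: str = "time_to_event",
    event_col: str = "event_observed",
    n_boot: int = 1000,
    seed: int = 0,
    reference_phenogroup: int | None = 4,
    return_samples: bool = False,
) -> dict:
    """Compare two Cox models: bootstrapped C-index and a Vuong-type test.

    Both models are fitted on identical rows.  Harrell's C-index is
    bootstrapped (resampling rows, fixed coefficients) to give a mean and
    SD per model; goodness of fit is compared with a Vuong-type z-statistic
    on per-event-subject log-partial-likelihood contributions (suitable
    for non-nested models).
    """
    need = sorted(set(model_a_terms) | set(model_b_terms))
    df = data.dropna(subset=need + [duration_col, event_col]).copy()
    Xa = _design(df, model_a_terms, reference_phenogroup)
    Xb = _design(df, model_b_terms, reference_phenogroup)
    dfa = pd.concat([Xa, df[[duration_col, event_col]]], axis=1)
    dfb = pd.concat([Xb, df[[duration_col, event_col]]], axis=1)
    ca, wa = _cox_fit(dfa, Xa.columns.tolist(), duration_col, event_col)
    cb, wb = _cox_fit(dfb, Xb.columns.tolist(), duration_col, event_col)
    T = df[duration_col].to_numpy(float)
    E = df[event_col].to_numpy(int)
    lpa = ca.predict_log_partial_hazard(wa).to_numpy()
    lpb = cb.predict_log_partial_hazard(wb).to_numpy()

    rng = np.random.default_rng(seed)
    n = len(df)
    cis_a = np.empty(n_boot)
    cis_b = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        cis_a[b] = concordance_index(T[idx], -lpa[idx], E[idx])
        cis_b[b] = concordance_index(T[idx], -lpb[idx], E[idx])

    da = _per_subject_logpl(lpa, T, E)
    db = _per_subject_logpl(lpb, T, E)
    d = da[~np.isnan(da)] - db[~np.isnan(db)]
    if np.allclose(d, 0.0):
        z, p = 0.0, 1.0
    else:
        z = float(np.sqrt(len(d)) * d.mean() / d.std(ddof=1))
        p = float(2 * stats.norm.sf(abs(z)))
    out = {
        "c_index_A": float(cis_a.mean()), "sd_A": float(cis_a.std()),
        "c_index_B": float(cis_b.mean()), "sd_B": float(cis_b.std()),
        "z": z, "p": p,
    }
    if return_samples:
        out["samples_A"] = cis_a
        out["samples_B"] = cis_b
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_pvalues(results: list[ModelResult] | pd.DataFrame,
                   method: str = "fdr_bh"):
    """Benjamini–Hochberg (default) q-values across a set of results.

    Accepts a list of :class:`ModelResult` (their tables gain a ``q``
    column, pooled across all terms) or a bare DataFrame with a ``p``
    column.
    """
    if isinstance(results, pd.DataFrame):
        q = multipletests(results["p"].to_numpy(), method=method)[1]
        out = results.copy()
        out["q"] = q
        return out
    pvals = np.concatenate([r.table["p"].to_numpy() for r in results])
    q = multipletests(pvals, method=method)[1]
    pos = 0
    for r in results:
        k = len(r.table)
        r.table["q"] = q[pos: pos + k]
        pos += k
    return results
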