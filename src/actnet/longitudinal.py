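"""Longitudinal differential analysis of expression time courses.

Centerpiece: a two-condition quadratic regression per feature,

    y = (b0_C + b0_TvsC * D) + (b1_C + b1_TvsC * D) t + (b2_C + b2_TvsC * D) t^2 + eps,

with D = 1 for treated samples, fitted in raw hours. A feature is a *dynamic
response feature* when the Benjamini-Hochberg q-value of the joint F-test of
the three treatment-vs-control terms is <= 0.05, the model R^2 is >= 0.7 and
at least 10 observations were used. Per-coefficient two-sided t-test p-values
(p0, p1, p2) feed the downstream network node scoring.

Also here: median-of-medians proteome normalization against the control arm
and per-time-point two-sample t-tests (treated vs time-matched control, or
each later time point vs the earliest one).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import OmicsTimeCourse

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10(p) finite in downstream scoring

Q_THRESH = 0.05
R2_THRESH = 0.7
MIN_OBS = 10


# ---------------------------------------------------------------------------
# proteome normalization
# ---------------------------------------------------------------------------

def normalize_proteome(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    control_time: pd.Series,
    treated_time: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-of-medians shifting of log2 intensities onto the control arm.

    (i) controls are shifted so each control sample's median over the proteins
    present in *all* control samples equals the median of those per-sample
    medians; (ii)-(iv) per time point, the common protein set between controls
    and treated samples defines a reference median-of-medians of the
    (normalized) controls, and each treated sample at that time point is
    shifted onto it.
    """
    ref_proteins = control.dropna(axis=0, how="any").index
    if len(ref_proteins) == 0:
        raise ValueError("no protein present in all control samples")
    ctrl_medians = control.loc[ref_proteins].median(axis=0)
    target = float(ctrl_medians.median())
    control_norm = control + (target - ctrl_medians)

    treated_norm = treated.copy()
    for t in sorted(treated_time.unique()):
        t_samples = treated_time.index[treated_time == t]
        c_samples = control_time.index[control_time == t]
        if len(c_samples) == 0:
            raise ValueError(f"no control samples at time point {t}")
        block_c = control_norm[c_samples]
        block_t = treated[t_samples]
        common = block_c.dropna(how="any").index.intersection(
            block_t.dropna(how="any").index
        )
        if len(common) == 0:
            raise ValueError(f"empty common protein set at time point {t}")
        ref = float(block_c.loc[common].median(axis=0).median())
        t_medians = block_t.loc[common].median(axis=0)
        treated_norm[t_samples] = block_t + (ref - t_medians)
    return control_norm, treated_norm


# ---------------------------------------------------------------------------
# per-feature quadratic regression
# ---------------------------------------------------------------------------

@dataclass
class DynamicFit:
    """Regression output for one feature in one (drug, dose, layer) stratum."""

    feature: str
    beta_C: tuple[float, float, float]
    beta_TvsC: tuple[float, float, float]
    p_TvsC: tuple[float, float, float]
    global_p: float
    r_squared: float
    n_obs: int
    residual_sd: float
    q_value: float = np.nan  # set by call_dynamic_features
    is_dynamic: bool = False
    failed: bool = False

    @classmethod
    def failed_fit(cls, feature: str, n_obs: int) -> "DynamicFit":
        nan3 = (np.nan, np.nan, np.nan)
        return cls(
            feature=feature,
            beta_C=nan3,
            beta_TvsC=nan3,
            p_TvsC=(1.0, 1.0, 1.0),
            global_p=1.0,
            r_squared=0.0,
            n_obs=n_obs,
            residual_sd=np.nan,
            failed=True,
        )


def _design(t: np.ndarray, d: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(t), d]
    for k in range(1, degree + 1):
        cols.append(t**k)
        cols.append(d * t**k)
    return np.column_stack(cols)


def fit_dynamic_model(
    y: np.ndarray | pd.Series,
    condition: np.ndarray | pd.Series,
    time_h: np.ndarray | pd.Series,
    feature: str = "",
    degree: int = 2,
) -> DynamicFit:
    """Least-squares fit of the two-condition polynomial model for one feature.

    Missing observations are dropped listwise. Coefficient p-values come from
    two-sided t-tests in the full model; the global treatment-effect p-value
    from the F-test of the full model against the control-shape-only reduced
    model. Features with fewer than 2*degree + 2 usable observations are
    returned with ``failed=True`` rather than raising.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(y, dtype=float)
    d = np.asarray([1.0 if c == "T" else 0.0 for c in np.asarray(condition)])
    t = np.asarray(time_h, dtype=float)
    keep = ~np.isnan(y)
    y, d, t = y[keep], d[keep], t[keep]
    n = len(y)
    n_params = 2 * (degree + 1)
    if n < n_params or len(np.unique(t[d == 0])) < 2 or len(np.unique(t[d == 1])) < 2:
        return DynamicFit.failed_fit(feature, n)

    X = _design(t, d, degree)
    # column scaling keeps raw-hour powers well conditioned; estimates are
    # rescaled back so coefficients stay in the raw-time parameterization
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Q, R = np.linalg.qr(X / scale)
    beta_s, *_ = np.linalg.lstsq(R, Q.T @ y, rcond=None)
    beta = beta_s / scale
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = n - n_params
    if dof <= 0:
        return DynamicFit.failed_fit(feature, n)
    if tss <= 1e-300:
        # constant response: R^2 defined as 0, nothing to test
        return DynamicFit(
            feature=feature,
            beta_C=_pad3(beta[0::2][: degree + 1]),
            beta_TvsC=_pad3(beta[1::2][: degree + 1]),
            p_TvsC=(1.0, 1.0, 1.0),
            global_p=1.0,
            r_squared=0.0,
            n_obs=n,
            residual_sd=0.0,
        )
    sigma2 = rss / dof
    Rinv = np.linalg.inv(R)
    cov = (Rinv @ Rinv.T) * sigma2 / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)

    # reduced model: control shape only (drop D and its interactions)
    ctrl_cols = [0] + [2 + 2 * k for k in range(degree)]
    Xr = X[:, ctrl_cols]
    beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    rss_r = float(((y - Xr @ beta_r) ** 2).sum())
    df_num = degree + 1
    if rss <= 1e-300:
        global_p = 0.0 if rss_r > 1e-10 else 1.0
    else:
        f_stat = max(0.0, (rss_r - rss) / df_num) / (rss / dof)
        global_p = float(stats.f.sf(f_stat, df_num, dof))

    beta_c = beta[0::2][: degree + 1]
    beta_tc = beta[1::2][: degree + 1]
    p_tc = np.maximum(pvals[1::2][: degree + 1], P_FLOOR)
    return DynamicFit(
        feature=feature,
        beta_C=_pad3(beta_c),
        beta_TvsC=_pad3(beta_tc),
        p_TvsC=_pad3(p_tc, fill=1.0),
        global_p=max(float(global_p), P_FLOOR),
        r_squared=1.0 - rss / tss,
        n_obs=n,
        residual_sd=float(np.sqrt(sigma2)),
    )


def _pad3(v: np.ndarray, fill: float = 0.0) -> tuple[float, float, float]:
    out = list(np.asarray(v, dtype=float)) + [fill] * 3
    return tuple(out[:3])


def fit_timecourse(tc: OmicsTimeCourse, degree: int = 2) -> dict[str, DynamicFit]:
    """Fit every feature of one stratum's time course."""
    cond = tc.sample_meta["condition"].to_numpy()
    time_h = tc.sample_meta["time_h"].to_numpy(dtype=float)
    values = tc.values.to_numpy(dtype=float)
    return {
        f: fit_dynamic_model(values[i], cond, time_h, feature=f, degree=degree)
        for i, f in enumerate(tc.values.index)
    }


def call_dynamic_features(
    fits: dict[str, DynamicFit],
    q_thresh: float = Q_THRESH,
    r2_thresh: float = R2_THRESH,
    min_obs: int = MIN_OBS,
) -> set[str]:
    """BH-correct global p-values across one stratum and apply the dynamic
    thresholds (q <= q_thresh, R^2 >= r2_thresh, n_obs >= min_obs).

    Mutates the fits (sets q_value and is_dynamic) and returns the dynamic
    feature set. Failed fits are excluded from the BH family.
    """
    usable = [f for f in fits.values() if not f.failed]
    if not usable:
        warnings.warn("no usable fits; returning empty dynamic set", stacklevel=2)
        return set()
    pvec = np.array([f.global_p for f in usable])
    _, qvec, _, _ = multipletests(pvec, method="fdr_bh")
    dynamic: set[str] = set()
    for fit, q in zip(usable, qvec):
        fit.q_value = float(q)
        fit.is_dynamic = (
            q <= q_thresh and fit.r_squared >= r2_thresh and fit.n_obs >= min_obs
        )
        if fit.is_dynamic:
            dynamic.add(fit.feature)
    return dynamic


def fits_to_frame(fits: dict[str, DynamicFit]) -> pd.DataFrame:
    rows = []
    for f in fits.values():
        rows.append(
            {
                "feature": f.feature,
                "b0_C": f.beta_C[0], "b1_C": f.beta_C[1], "b2_C": f.beta_C[2],
                "b0_TvsC": f.beta_TvsC[0], "b1_TvsC": f.beta_TvsC[1],
                "b2_TvsC": f.beta_TvsC[2],
                "p0_TvsC": f.p_TvsC[0], "p1_TvsC": f.p_TvsC[1], "p2_TvsC": f.p_TvsC[2],
                "global_p": f.global_p, "r_squared": f.r_squared,
                "n_obs": f.n_obs, "residual_sd": f.residual_sd,
                "q_value": f.q_value, "is_dynamic": f.is_dynamic,
                "failed": f.failed,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def frame_to_fits(df: pd.DataFrame) -> dict[str, DynamicFit]:
    fits = {}
    for feature, r in df.iterrows():
        fits[feature] = DynamicFit(
            feature=feature,
            beta_C=(r.b0_C, r.b1_C, r.b2_C),
            beta_TvsC=(r.b0_TvsC, r.b1_TvsC, r.b2_TvsC),
            p_TvsC=(r.p0_TvsC, r.p1_TvsC, r.p2_TvsC),
            global_p=r.global_p,
            r_squared=r.r_squared,
            n_obs=int(r.n_obs),
            residual_sd=r.residual_sd,
            q_value=r.q_value,
            is_dynamic=bool(r.is_dynamic),
            failed=bool(r.failed),
        )
    return fits


def write_fit_table(fits: dict[str, DynamicFit], path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, sep="\t")


def read_fit_table(path: str | Path) -> dict[str, DynamicFit]:
    return frame_to_fits(pd.read_csv(path, sep="\t", index_col="feature"))


# ---------------------------------------------------------------------------
# per-time-point two-sample t-tests
# ---------------------------------------------------------------------------

def _ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance); returns (log2fc, p).

    Degenerate zero-variance comparisons resolve to p=1 for equal means and
    p=0 otherwise.
    """
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        return diff, (1.0 if diff == 0 else 0.0)
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return diff, float(p)


def timepoint_tests(tc: OmicsTimeCourse, mode: str = "vs_control") -> pd.DataFrame:
    """Per-feature, per-time-point differential tests.

    mode="vs_control": treated vs time-matched control at every time point.
    mode="vs_baseline": each later time point vs the earliest one, within the
    treated arm. Comparisons with fewer than 2 non-missing replicates on
    either side are reported with ``testable=False``. BH is applied across all
    testable comparisons of the mode (one family).
    """
    if mode not in ("vs_control", "vs_baseline"):
        raise ValueError("mode must be 'vs_control' or 'vs_baseline'")
    meta = tc.sample_meta
    times = sorted(meta["time_h"].unique())
    rows = []
    values = tc.values
    if mode == "vs_control":
        pairs = [
            (t, tc.samples_where(condition="T", time_h=t), tc.samples_where(condition="C", time_h=t))
            for t in times
        ]
    else:
        t0 = times[0]
        base = tc.samples_where(condition="T", time_h=t0)
        pairs = [(t, tc.samples_where(condition="T", time_h=t), base) for t in times[1:]]

    for t, group_a, group_b in pairs:
        block_a = values[group_a].to_numpy(dtype=float)
        block_b = values[group_b].to_numpy(dtype=float)
        for i, feature in enumerate(values.index):
            a = block_a[i][~np.isnan(block_a[i])]
            b = block_b[i][~np.isnan(block_b[i])]
            if len(a) < 2 or len(b) < 2:
                rows.append((feature, t, np.nan, np.nan, False))
                continue
            fc, p = _ttest(a, b)
            rows.append((feature, t, fc, p, True))
    out = pd.DataFrame(
        rows, columns=["feature", "time_h", "log2fc", "p", "testable"]
    )
    out["q"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        _, q, _, _ = multipletests(out.loc[testable, "p"], method="fdr_bh")
        out.loc[testable, "q"] = q
    return out
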