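"""Agreement and repeatability statistics for multi-device VLD tables.

Implements the analysis layer of a multi-instrument reliability study:

* coefficients of variation — between subjects (100 * SD/mean) and per
  eye between a pair of instruments (two-value SD over the pair mean,
  summarized as mean +/- SD across eyes);
* intraclass correlation — by default the two-way random-effects,
  absolute-agreement, single-measurement form ICC(2,1), computed from
  the mean squares of the two-way ANOVA decomposition with an
  F-distribution 95% CI (consistency form ICC(3,1) and average-measure
  variants selectable);
* a repeated-measures general linear model with two within-subject
  factors (instrument, location), one between-subject factor (axial
  length group, cut at 25.5 mm), estimated marginal means and pairwise
  EMM comparisons with per-comparison (LSD-style) p-values;
* Pearson / Spearman correlations.

The GLM uses the standard univariate approach via orthonormal within-
subject contrasts: each within effect is an orthonormal transform of the
16 instrument x location cells; its F statistic compares the trace of
the hypothesis SSCP for the (effect-coded) intercept against the trace
of the residual SSCP.  With one between factor this reproduces the
classical split-plot Type III sums of squares, also for unbalanced
groups.  No sphericity correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


# ---------------------------------------------------------------------------
# coefficients of variation


@dataclass
class CVResult:
    context: str  # "within_subjects" | "pairwise"
    mean_cv_percent: float
    sd_cv_percent: float | None
    n: int


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * SD / mean (report-layer rounding is separate)."""
    if not mean > 0:
        raise ValueError("mean must be positive for a CV")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return 100.0 * sd / mean


def cv_of_sample(values) -> float:
    """Between-subject CV of a sample (n-1 denominator SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return cv_percent(float(v.mean()), float(v.std(ddof=1)))


def pairwise_cv(values_a, values_b) -> CVResult:
    """Per-eye CV between two paired instruments, summarized mean +/- SD.

    For each eye the CV is 100 * SD(a_i, b_i; n-1 denominator) / mean(a_i, b_i).
    Eyes with non-positive pair means are excluded with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    means = (a + b) / 2.0
    sds = np.abs(a - b) / np.sqrt(2.0)  # two-value sample SD
    good = means > 0
    if not good.all():
        warnings.warn(f"{int((~good).sum())} pair(s) with non-positive mean excluded")
    cvs = 100.0 * sds[good] / means[good]
    if cvs.size == 0:
        raise ValueError("no valid pairs")
    sd_cv = float(cvs.std(ddof=1)) if cvs.size > 1 else 0.0
    return CVResult("pairwise", float(cvs.mean()), sd_cv, int(cvs.size))


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int


def _anova_mean_squares(y: np.ndarray):
    n, k = y.shape
    gm = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - gm) ** 2).sum())
    ss_cols = n * float(((col_means - gm) ** 2).sum())
    ss_total = float(((y - gm) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(table, model: str = "ICC2", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation of a complete subjects x raters table.

    ``model``: 'ICC2' (two-way random, absolute agreement, single
    measurement; default), 'ICC3' (two-way mixed, consistency, single),
    or their average-measure forms 'ICC2k'/'ICC3k'.  The 95% CI uses the
    standard F-distribution formulas.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a complete table with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(y)):
        raise ValueError("table contains missing values; ICC needs complete cases")
    n, k = y.shape
    if np.allclose(y, y.mean()):
        raise ValueError("degenerate table: zero total variance")
    msr, msc, mse = _anova_mean_squares(y)
    model = model.upper()
    df_err = (n - 1) * (k - 1)

    if model in ("ICC2", "ICC2K"):
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est1 = (msr - mse) / denom if denom > 0 else 1.0
        # McGraw & Wong CI for ICC(A,1), Satterthwaite df
        if est1 >= 1.0 or mse == 0 and msc == 0:
            lo1, hi1 = est1, est1
        else:
            a_ = k * est1 / (n * (1 - est1))
            b_ = 1 + k * est1 * (n - 1) / (n * (1 - est1))
            num = (a_ * msc + b_ * mse) ** 2
            den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / df_err
            v = num / den if den > 0 else df_err
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        if model == "ICC2":
            est, lo, hi = est1, lo1, hi1
        else:
            to_k = lambda r: k * r / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0
            est, lo, hi = to_k(est1), to_k(lo1), to_k(hi1)
    elif model in ("ICC3", "ICC3K"):
        est1 = (msr - mse) / (msr + (k - 1) * mse) if (msr + (k - 1) * mse) > 0 else 1.0
        if mse == 0:
            lo1 = hi1 = est1
        else:
            fstat = msr / mse
            fl = fstat / sps.f.ppf(1 - alpha / 2, n - 1, df_err)
            fu = fstat * sps.f.ppf(1 - alpha / 2, df_err, n - 1)
            lo1 = (fl - 1) / (fl + k - 1)
            hi1 = (fu - 1) / (fu + k - 1)
        if model == "ICC3":
            est, lo, hi = est1, lo1, hi1
        else:
            to_k = lambda r: k * r / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0
            est, lo, hi = to_k(est1), to_k(lo1), to_k(hi1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return ICCResult(float(est), float(lo), float(hi), model, n, k)


# ---------------------------------------------------------------------------
# repeated-measures GLM


@dataclass
class GLMResult:
    """RM-GLM output: ANOVA table, estimated marginal means, design arrays."""

    anova: pd.DataFrame  # effect, F, p, df1, df2
    emm_cells: pd.DataFrame  # device x location EMMs
    emm_device: pd.Series
    emm_location: pd.Series
    n_complete: int
    devices: list[str] = field(default_factory=list)
    locations: list[str] = field(default_factory=list)
    # subject-level data retained for pairwise contrasts
    _Y: np.ndarray | None = None  # (N, a*b) cell matrix
    _groups: np.ndarray | None = None  # group code per subject


def _complete_case_pivot(df: pd.DataFrame):
    devices = list(pd.unique(df["device"]))
    locations = list(pd.unique(df["location"]))
    wide = df.pivot_table(
        index="eye_id", columns=["device", "location"], values="vld", aggfunc="first"
    )
    counts = df.groupby(["eye_id", "device", "location"]).size()
    if (counts > 1).any():
        raise ValueError(
            "multiple values per eye x device x location; select one scan first"
        )
    full_cols = pd.MultiIndex.from_product([devices, locations])
    wide = wide.reindex(columns=full_cols)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} eye(s) with incomplete cells")
    return complete, devices, locations


def rm_glm(measurements: pd.DataFrame, between: str | None = "al_group") -> GLMResult:
    """Repeated-measures GLM on a long table (eye_id, device, location, vld).

    Within-subject effects: instrument, location and their interaction,
    each tested against its own subject-interaction error stratum; the
    optional between-subject factor (default the axial-length group
    column, used only when both groups have >= 2 subjects) is tested on
    subject means, and each within effect gains a group-interaction term.
    Incomplete eyes are dropped (complete-case analysis).
    """
    df = measurements.copy()
    wide, devices, locations = _complete_case_pivot(df)
    if len(wide) < 2:
        raise ValueError("need >= 2 complete-case subjects")
    Y = wide.to_numpy(dtype=float)  # (N, a*b), cells ordered device-major
    N = len(wide)
    a, b = len(devices), len(locations)

    groups = None
    if between is not None and between in df.columns:
        gmap = df.drop_duplicates("eye_id").set_index("eye_id")[between]
        g = gmap.reindex(wide.index).to_numpy()
        levels, counts = np.unique(g, return_counts=True)
        if len(levels) == 2 and counts.min() >= 2:
            groups = np.where(g == levels[0], 1.0, -1.0)  # effect coding
        elif len(levels) > 1:
            warnings.warn("between factor needs two groups with >= 2 subjects each; ignored")
    if groups is None:
        X = np.ones((N, 1))
    else:
        X = np.column_stack([np.ones(N), groups])
    p_rank = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)

    Ca = helmert(a, full=False)  # (a-1, a) orthonormal contrasts
    Cb = helmert(b, full=False)
    ones_a = np.full((1, a), 1 / np.sqrt(a))
    ones_b = np.full((1, b), 1 / np.sqrt(b))
    effects = {
        "instrument": np.kron(Ca, ones_b),
        "location": np.kron(ones_a, Cb),
        "instrument x location": np.kron(Ca, Cb),
    }

    rows = []

    def add_row(effect, F, df1, df2):
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if F == 0.0:
            p = 1.0
        rows.append({"effect": effect, "F": F, "df1": df1, "df2": df2, "p": p})

    for name, M in effects.items():
        Z = Y @ M.T  # (N, r)
        r = M.shape[0]
        B = XtX_inv @ X.T @ Z  # (p, r)
        E = Z.T @ Z - (X @ B).T @ Z  # residual SSCP; symmetric psd
        tr_e = float(np.trace(E))
        df2 = r * (N - p_rank)
        # intercept hypothesis (the within effect itself)
        tr_h0 = float(B[0] @ B[0]) / XtX_inv[0, 0]
        if tr_e <= 1e-12 * max(tr_h0, 1.0):
            F0 = np.inf if tr_h0 > 1e-12 else 0.0
        else:
            F0 = (tr_h0 / r) / (tr_e / df2)
        add_row(name, F0, r, df2)
        if groups is not None:
            tr_h1 = float(B[1] @ B[1]) / XtX_inv[1, 1]
            if tr_e <= 1e-12 * max(tr_h1, 1.0):
                F1 = np.inf if tr_h1 > 1e-12 else 0.0
            else:
                F1 = (tr_h1 / r) / (tr_e / df2)
            add_row(f"{name} x group", F1, r, df2)

    # between-subjects test on subject means
    if groups is not None:
        z0 = Y.mean(axis=1)
        B0 = XtX_inv @ X.T @ z0
        res = z0 - X @ B0
        sse = float(res @ res)
        ss_g = float(B0[1] ** 2) / XtX_inv[1, 1]
        if sse <= 1e-12 * max(ss_g, 1.0):
            Fg = np.inf if ss_g > 1e-12 else 0.0
        else:
            Fg = ss_g / (sse / (N - 2))
        add_row("al_group", Fg, 1, N - 2)

    # EMMs: unweighted over groups (Type III style)
    if groups is None:
        cell_means = Y.mean(axis=0)
    else:
        m1 = Y[groups > 0].mean(axis=0)
        m2 = Y[groups < 0].mean(axis=0)
        cell_means = (m1 + m2) / 2.0
    cells = pd.DataFrame(
        cell_means.reshape(a, b), index=list(devices), columns=list(locations)
    )
    return GLMResult(
        anova=pd.DataFrame(rows),
        emm_cells=cells,
        emm_device=cells.mean(axis=1),
        emm_location=cells.mean(axis=0),
        n_complete=N,
        devices=list(devices),
        locations=list(locations),
        _Y=Y,
        _groups=groups,
    )


def pairwise_emm(glm: GLMResult) -> pd.DataFrame:
    """All pairwise EMM differences among devices and among locations.

    Each comparison is a within-subject contrast: the per-subject score
    is the difference of the two factor-level means (averaged over the
    other factor); the difference reported is the (group-unweighted) mean
    score and the p-value comes from the t test of that score against
    zero (per-comparison, no multiplicity correction).  Differences are
    antisymmetric by construction.
    """
    if glm._Y is None:
        raise ValueError("GLMResult lacks subject-level data")
    Y, groups = glm._Y, glm._groups
    N = Y.shape[0]
    a, b = len(glm.devices), len(glm.locations)
    dev_scores = Y.reshape(N, a, b).mean(axis=2)  # (N, a)
    loc_scores = Y.reshape(N, a, b).mean(axis=1)  # (N, b)

    if groups is None:
        X = np.ones((N, 1))
    else:
        X = np.column_stack([np.ones(N), groups])
    XtX_inv = np.linalg.inv(X.T @ X)
    df_err = N - X.shape[1]

    def compare(scores, names, factor):
        out = []
        for i in range(len(names)):
            for j in range(len(names)):
                if i == j:
                    continue
                d = scores[:, i] - scores[:, j]
                beta = XtX_inv @ X.T @ d
                res = d - X @ beta
                mse = float(res @ res) / df_err if df_err > 0 else 0.0
                diff = float(beta[0])
                se = float(np.sqrt(mse * XtX_inv[0, 0]))
                if se == 0:
                    t = np.inf if diff != 0 else 0.0
                    p = 0.0 if diff != 0 else 1.0
                else:
                    t = diff / se
                    p = float(2 * sps.t.sf(abs(t), df_err))
                out.append(
                    {
                        "factor": factor,
                        "level_1": names[i],
                        "level_2": names[j],
                        "difference": diff,
                        "se": se,
                        "t": t,
                        "p": p,
                    }
                )
        return out

    rows = compare(dev_scores, glm.devices, "instrument") + compare(
        loc_scores, glm.locations, "location"
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r.statistic), float(r.pvalue)
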