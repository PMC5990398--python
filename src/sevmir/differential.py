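"""Donor-blocked differential analysis with moderated t-statistics.

Per miRNA a least-squares linear model ``value ~ donor + day + condition``
is fit (``day`` drops out when a single day is analysed). Residual
variances are shrunk toward a common prior estimated by method of
moments on log s^2 — the scaled-F / inverse-chi-square empirical-Bayes
scheme — and the moderated t uses the augmented degrees of freedom.
Raw p-values are adjusted by the Benjamini-Hochberg step-up.

Effects are always reported as abundance log2 fold changes of
``contrast[0]`` over ``contrast[1]``: on Ct scales the fitted condition
coefficient is negated (lower Ct = more abundant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import SampleSheet, ValidationError
from .normalize import NormalizedMatrix


@dataclass(frozen=True)
class ModelFit:
    """Per-miRNA condition effect, residual variance and residual df."""

    frame: pd.DataFrame  # columns: effect, s2, df
    se_factor: float  # contrast standard-error factor c: SE = s * c
    scheme: str
    n_samples: int


def _design_matrix(
    sub: pd.DataFrame, test: str, pooled_days: bool
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    donors = sorted(sub["donor"].unique())
    for d in donors[1:]:
        cols.append((sub["donor"] == d).to_numpy(dtype=float))
        names.append(f"donor[{d}]")
    if pooled_days:
        days = sorted(sub["day"].unique())
        for dy in days[1:]:
            cols.append((sub["day"] == dy).to_numpy(dtype=float))
            names.append(f"day[{dy}]")
    cols.append((sub["condition"] == test).to_numpy(dtype=float))
    names.append("condition")
    return np.column_stack(cols), names


def fit_blocked_model(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] = ("SIPS", "Q"),
    day: str | None = None,
) -> ModelFit:
    """Least-squares fit of value ~ donor (+ day) + condition per miRNA.

    ``day=None`` pools both days with ``day`` as a two-level factor;
    ``day="D7"``/``"D21"`` subsets to that day. miRNAs with any missing
    value among the used samples are dropped (complete-dataset rule).
    """
    test, ref = contrast
    sheet.require_covers(norm.sample_ids)
    sub = sheet.frame.loc[norm.sample_ids]
    if day is not None:
        sub = sub[sub["day"] == day]
    sub = sub[sub["condition"].isin([test, ref])]
    if (sub["condition"] == test).sum() == 0 or (sub["condition"] == ref).sum() == 0:
        raise ValidationError(f"both contrast groups {contrast} must be present")

    X, names = _design_matrix(sub, test, pooled_days=day is None)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify the offending factor by dropping columns one at a time
        for j in range(k - 1, 0, -1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                raise ValidationError(f"design is rank-deficient at factor {names[j]!r}")
        raise ValidationError("design is rank-deficient")
    if n <= k:
        raise ValidationError(
            f"no residual degrees of freedom: {n} samples, {k} coefficients"
        )

    Y = norm.values[list(sub.index)].to_numpy(dtype=float)
    complete = np.isfinite(Y).all(axis=1)
    ids = np.asarray(norm.values.index)[complete]
    Y = Y[complete]

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (XtX_inv @ X.T).T  # (m, k)
    resid = Y - beta @ X.T
    df = n - k
    s2 = (resid**2).sum(axis=1) / df

    c = np.zeros(k)
    c[-1] = 1.0  # condition coefficient
    se_factor = float(np.sqrt(c @ XtX_inv @ c))

    effect = beta[:, -1]
    if norm.is_ct_scale:
        effect = -effect

    frame = pd.DataFrame(
        {"effect": effect, "s2": s2, "df": float(df)}, index=pd.Index(ids, name="mirna_id")
    )
    return ModelFit(frame=frame, se_factor=se_factor, scheme=norm.scheme, n_samples=n)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-9, 1e9
    f = lambda x: special.polygamma(1, x) - y
    if f(lo) < 0:  # y above trigamma(lo): x below lo
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the mean and variance of log s^2 (corrected per-feature for
    the chi-square sampling moments) to the prior implied by
    s^2 | s0^2, d0. Returns ``(d0, s0_sq)``; ``d0`` is ``inf`` when the
    observed spread of log s^2 does not exceed pure sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValidationError("variance prior estimation needs >=2 positive variances")
    s2, df = s2[ok], df[ok]
    if np.ptp(s2) == 0:  # degenerate: every variance identical
        return np.inf, float(s2[0])
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(e_mean))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderate_and_test(fit: ModelFit, prior_df: float | None = None) -> pd.DataFrame:
    """Moderated t-test per miRNA.

    ``prior_df`` overrides the estimated d0 (``0`` reproduces the
    ordinary t-test exactly; ``inf`` pools all variances). Posterior
    variance: s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); t uses d + d0 df.
    """
    frame = fit.frame
    if len(frame) < 2:
        raise ValidationError("moderation needs at least 2 features")
    s2 = frame["s2"].to_numpy()
    df = frame["df"].to_numpy()
    if prior_df is None:
        if len(frame) < 10:
            raise ValidationError(
                "estimating the variance prior needs >=10 features; pass prior_df explicitly"
            )
        d0, s0_sq = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValidationError("prior_df must be >= 0")
        if d0 == 0:
            s0_sq = float("nan")  # unused: no shrinkage
        else:
            ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
            e = (
                np.log(s2[ok])
                - special.digamma(df[ok] / 2.0)
                + np.log(df[ok] / 2.0)
            )
            if np.isinf(d0):
                s0_sq = float(np.exp(e.mean()))
            else:
                s0_sq = float(
                    np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
                )

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post) * fit.se_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = frame["effect"].to_numpy() / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = frame.copy()
    out["s2_post"] = s2_post
    out["prior_df"] = d0
    out["prior_s2"] = s0_sq
    out["t"] = t
    out["p"] = p
    out["q"] = bh_adjust(p)
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_classify(
    result: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    criterion: str = "p",
) -> pd.Series:
    """Label each miRNA up / down / ns from effect size and significance."""
    if criterion not in ("p", "q"):
        raise ValidationError("criterion must be 'p' or 'q'")
    sig = result[criterion] < p_threshold
    labels = pd.Series("ns", index=result.index, name="volcano_class")
    labels[sig & (result["effect"] > fc_threshold)] = "up"
    labels[sig & (result["effect"] < -fc_threshold)] = "down"
    return labels


def differential_table(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] = ("SIPS", "Q"),
    day: str | None = None,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    criterion: str = "p",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Fit, moderate, adjust and classify in one call."""
    fit = fit_blocked_model(norm, sheet, contrast=contrast, day=day)
    result = moderate_and_test(fit, prior_df=prior_df)
    result["volcano_class"] = volcano_classify(
        result, fc_threshold=fc_threshold, p_threshold=p_threshold, criterion=criterion
    )
    return result
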