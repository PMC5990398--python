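"""Selective-secretion scoring from paired intracellular / vesicular data.

The pipeline restricts both platforms to a co-measured, well-detected
miRNA set, then scores each miRNA twice per condition:

* rank scores — rank 1 = most abundant on each platform; the
  intracellular-minus-vesicular rank difference is positive when a miRNA
  is relatively enriched outside the cell. The condition difference of
  those differences (SIPS minus Q) is the rank-based selectivity score.
* ratio scores — vesicular abundance (arbitrary units derived from Ct)
  divided by intracellular abundance (TPM), per condition; the SIPS/Q
  quotient, normalized to its global arithmetic mean, is the ratio-based
  selectivity score.

Note on direction: the ratio is vesicular/intracellular so that *high*
values of both scores mean senescence-selective secretion and the two
score vectors correlate positively; only the condition-quotient is
unit-free.

Classification requires concordance: a miRNA is called selectively
secreted only above the upper percentile of BOTH scores, retained only
below the lower percentile of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, SampleSheet, ValidationError
from .normalize import NormalizedMatrix


def au_transform(
    ct: float | np.ndarray | pd.Series,
    anchor_ct: float = 40.0,
    anchor_au: float = 10.0,
    efficiency: float = 1.0,
) -> float | np.ndarray | pd.Series:
    """Ct to arbitrary units: AU = anchor_au * base**(anchor_ct - ct).

    base = 1 + efficiency (2 at 100% PCR efficiency), so Ct 40 -> 10 AU
    and each cycle below 40 doubles the abundance. ND (NaN) input is an
    error: callers must filter or impute first.
    """
    arr = np.asarray(ct, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("au_transform requires finite Ct (no ND)")
    base = 1.0 + efficiency
    au = anchor_au * np.power(base, anchor_ct - arr)
    if isinstance(ct, pd.Series):
        return pd.Series(au, index=ct.index)
    if np.isscalar(ct):
        return float(au)
    return au


# ---------------------------------------------------------------------------
# Filtering


@dataclass(frozen=True)
class FilterReport:
    kept: list[str]
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def step_counts(self) -> list[int]:
        return [n for _, n in self.steps]


def correlation_filter(
    panel_mirnas: list[str],
    tpm: NormalizedMatrix,
    ct: NormalizedMatrix,
    quartile_rule: str = "and",
) -> FilterReport:
    """Restrict to the co-measured, well-detected miRNA set.

    Ordered steps, each reported with the remaining count:

    1. intersect the qPCR panel ids with the NGS-measured ids;
    2. drop miRNAs in the bottom abundance quartile (cross-sample mean)
       on both platforms (``quartile_rule="and"``; ``"or"`` drops when
       low on either);
    3. drop miRNAs with TPM = 0 in any sample;
    4. drop miRNAs not detected (ND) in any Ct sample.

    Vesicular abundance for the quartile step is the mean of per-well
    arbitrary units with ND counted as 0 (no signal = lowest abundance).
    """
    if quartile_rule not in ("and", "or"):
        raise ValidationError("quartile_rule must be 'and' or 'or'")
    tpm_v = tpm.values
    ct_v = ct.values

    ids = [m for m in panel_mirnas if m in tpm_v.index and m in ct_v.index]
    steps = [("panel ∩ ngs", len(ids))]
    if not ids:
        raise ValidationError("no miRNAs shared between panel and NGS data")

    mean_tpm = tpm_v.loc[ids].mean(axis=1)
    au = pd.DataFrame(
        np.where(
            ct_v.loc[ids].notna(), 10.0 * np.power(2.0, 40.0 - ct_v.loc[ids]), 0.0
        ),
        index=ids,
        columns=ct_v.columns,
    )
    mean_au = au.mean(axis=1)
    q25_tpm = np.percentile(mean_tpm, 25)
    q25_au = np.percentile(mean_au, 25)
    low_tpm = mean_tpm < q25_tpm
    low_au = mean_au < q25_au
    low = (low_tpm & low_au) if quartile_rule == "and" else (low_tpm | low_au)
    ids = [m for m in ids if not low[m]]
    steps.append(("low-abundance quartile", len(ids)))
    if not ids:
        raise ValidationError("no miRNAs left after quartile exclusion")

    zero = (tpm_v.loc[ids] == 0).any(axis=1)
    ids = [m for m in ids if not zero[m]]
    steps.append(("tpm zero", len(ids)))
    if not ids:
        raise ValidationError("no miRNAs left after TPM-zero exclusion")

    nd = ct_v.loc[ids].isna().any(axis=1)
    ids = [m for m in ids if not nd[m]]
    steps.append(("ct completeness", len(ids)))
    if not ids:
        raise ValidationError("no miRNAs left after Ct completeness filter")

    return FilterReport(kept=ids, steps=steps)


# ---------------------------------------------------------------------------
# Correlation input


@dataclass(frozen=True)
class CorrelationInput:
    """Per-miRNA, per-condition mean abundances on both platforms.

    Columns: intra_Q, intra_SIPS (mean TPM over donors and days),
    extra_ct_Q, extra_ct_SIPS (mean normalized Ct), extra_au_Q,
    extra_au_SIPS (AU of the mean Ct).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {
            "intra_Q",
            "intra_SIPS",
            "extra_ct_Q",
            "extra_ct_SIPS",
            "extra_au_Q",
            "extra_au_SIPS",
        }
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValidationError(f"correlation input missing columns: {sorted(missing)}")


def build_correlation_input(
    ids: list[str],
    tpm: NormalizedMatrix,
    ct: NormalizedMatrix,
    tpm_sheet: SampleSheet,
    ct_sheet: SampleSheet,
    day: str | None = None,
) -> CorrelationInput:
    """Average each platform per condition (pooling donors and days).

    ``day`` restricts the averaging to a single time point. Requires a
    filtered id set with no ND left in the Ct matrix.
    """
    tpm_sheet.require_covers(tpm.sample_ids)
    ct_sheet.require_covers(ct.sample_ids)
    cols = {}
    for cond in ("Q", "SIPS"):
        ngs_cols = [
            s for s in tpm_sheet.samples_for(condition=cond, day=day) if s in tpm.values.columns
        ]
        qpcr_cols = [
            s for s in ct_sheet.samples_for(condition=cond, day=day) if s in ct.values.columns
        ]
        if not ngs_cols or not qpcr_cols:
            raise ValidationError(f"no samples for condition {cond!r} (day={day!r})")
        cols[f"intra_{cond}"] = tpm.values.loc[ids, ngs_cols].mean(axis=1)
        mean_ct = ct.values.loc[ids, qpcr_cols].mean(axis=1)
        if mean_ct.isna().any():
            bad = list(mean_ct.index[mean_ct.isna()])[:5]
            raise ValidationError(f"ND left after filtering, e.g. {bad}")
        cols[f"extra_ct_{cond}"] = mean_ct
        cols[f"extra_au_{cond}"] = au_transform(mean_ct)
    return CorrelationInput(frame=pd.DataFrame(cols, index=pd.Index(ids, name="mirna_id")))


# ---------------------------------------------------------------------------
# Scores


def _rank_descending(abundance: pd.Series) -> pd.Series:
    """Rank 1 = most abundant; ties get average ranks."""
    return pd.Series(
        stats.rankdata(-abundance.to_numpy(), method="average"), index=abundance.index
    )


def rank_scores(ci: CorrelationInput) -> pd.DataFrame:
    """Rank-difference scores per condition and their SIPS-minus-Q shift."""
    f = ci.frame
    if len(f) < 3:
        raise ValidationError("rank scoring needs >=3 miRNAs")
    out = pd.DataFrame(index=f.index)
    for cond in ("Q", "SIPS"):
        out[f"rank_intra_{cond}"] = _rank_descending(f[f"intra_{cond}"])
        out[f"rank_extra_{cond}"] = _rank_descending(f[f"extra_au_{cond}"])
        out[f"drank_{cond}"] = out[f"rank_intra_{cond}"] - out[f"rank_extra_{cond}"]
    out["ddrank"] = out["drank_SIPS"] - out["drank_Q"]
    return out


def ratio_scores(ci: CorrelationInput) -> pd.DataFrame:
    """Vesicular/intracellular abundance ratios and the normalized SIPS/Q quotient.

    dratio_c = extra_au_c / intra_c; ddratio_raw = dratio_SIPS / dratio_Q;
    ddratio = ddratio_raw / arithmetic mean of ddratio_raw over scorable
    miRNAs. Zero denominators flag the miRNA (NaN) and exclude it from
    the global mean.
    """
    f = ci.frame
    out = pd.DataFrame(index=f.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for cond in ("Q", "SIPS"):
            intra = f[f"intra_{cond}"].to_numpy(dtype=float)
            au = f[f"extra_au_{cond}"].to_numpy(dtype=float)
            ratio = np.where(intra > 0, au / intra, np.nan)
            out[f"dratio_{cond}"] = ratio
        raw = np.where(
            (out["dratio_Q"] > 0) & np.isfinite(out["dratio_Q"]) & np.isfinite(out["dratio_SIPS"]),
            out["dratio_SIPS"] / out["dratio_Q"],
            np.nan,
        )
    out["ddratio_raw"] = raw
    mean_raw = np.nanmean(raw)
    if not np.isfinite(mean_raw) or mean_raw <= 0:
        raise ValidationError("global mean of ratio quotients is not positive")
    out["ddratio"] = out["ddratio_raw"] / mean_raw
    return out


def abundance_quartiles(ci: CorrelationInput) -> pd.Series:
    """1..4 quartile of overall vesicular abundance (4 = most abundant)."""
    mean_au = ci.frame[["extra_au_Q", "extra_au_SIPS"]].mean(axis=1)
    edges = np.percentile(mean_au, [25, 50, 75])
    return pd.Series(
        1 + np.searchsorted(edges, mean_au.to_numpy(), side="right"),
        index=ci.frame.index,
        name="abundance_quartile",
    )


def compute_scores(ci: CorrelationInput) -> pd.DataFrame:
    """Full score table: ranks, ratios and the abundance quartile."""
    out = rank_scores(ci).join(ratio_scores(ci))
    out["abundance_quartile"] = abundance_quartiles(ci)
    return out


# ---------------------------------------------------------------------------
# Classification and concordance


def classify_selective(
    scores: pd.DataFrame, lower_pct: float = 25.0, upper_pct: float = 75.0
) -> pd.Series:
    """secreted / retained / neutral by dual percentile cut-offs.

    secreted: above the upper percentile of BOTH score vectors;
    retained: below the lower percentile of both; otherwise neutral.
    Percentiles use linear interpolation between order statistics;
    NaN ratio scores are never labeled non-neutral.
    """
    if len(scores) < 4:
        raise ValidationError("classification needs >=4 miRNAs")
    ddrank = scores["ddrank"].to_numpy(dtype=float)
    ddratio = scores["ddratio"].to_numpy(dtype=float)
    ok = np.isfinite(ddratio)
    lo_rank, hi_rank = np.percentile(ddrank, [lower_pct, upper_pct])
    lo_ratio, hi_ratio = np.percentile(ddratio[ok], [lower_pct, upper_pct])
    labels = np.full(len(scores), "neutral", dtype=object)
    labels[ok & (ddrank > hi_rank) & (ddratio > hi_ratio)] = "secreted"
    labels[ok & (ddrank < lo_rank) & (ddratio < lo_ratio)] = "retained"
    return pd.Series(labels, index=scores.index, name="label")


def single_score_labels(
    scores: pd.DataFrame, column: str, lower_pct: float = 25.0, upper_pct: float = 75.0
) -> pd.Series:
    """Auxiliary one-method labels (percentile cut on a single score)."""
    v = scores[column].to_numpy(dtype=float)
    ok = np.isfinite(v)
    lo, hi = np.percentile(v[ok], [lower_pct, upper_pct])
    labels = np.full(len(scores), "neutral", dtype=object)
    labels[ok & (v > hi)] = "secreted"
    labels[ok & (v < lo)] = "retained"
    return pd.Series(labels, index=scores.index, name=f"label_{column}")


@dataclass(frozen=True)
class Concordance:
    rho: float
    pvalue: float
    top_secreted_overlap: int
    top_retained_overlap: int
    k: int


def method_concordance(scores: pd.DataFrame, k: int = 20) -> Concordance:
    """Spearman correlation of the two score vectors plus top-k overlaps.

    Overlaps compare the top-k most-secreted (highest score) and top-k
    most-retained (lowest score) sets of each method. A constant vector
    makes the correlation undefined (NaN).
    """
    sub = scores[["ddrank", "ddratio"]].dropna()
    if len(sub) < 5:
        raise ValidationError("concordance needs >=5 scorable miRNAs")
    x = sub["ddrank"].to_numpy()
    y = sub["ddratio"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(x, y)
    top_rank = set(sub["ddrank"].nlargest(k).index)
    top_ratio = set(sub["ddratio"].nlargest(k).index)
    bot_rank = set(sub["ddrank"].nsmallest(k).index)
    bot_ratio = set(sub["ddratio"].nsmallest(k).index)
    return Concordance(
        rho=float(rho),
        pvalue=float(pval),
        top_secreted_overlap=len(top_rank & top_ratio),
        top_retained_overlap=len(bot_rank & bot_ratio),
        k=k,
    )
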