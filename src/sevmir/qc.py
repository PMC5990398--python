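"""Panel quality control: spike-in robustness and detection summaries.

A spike-in is "robust" when the range of its Ct across all samples
(max - min, here ``ct_range``) stays below one cycle. Detection bins use
the per-assay average Ct over detected wells: <31, 31-35, 35-38, and
>38/ND. Boundary convention: a value equal to a bin's lower edge belongs
to that bin (31.0 -> "31-35"), except the detection limit itself, which
counts as detected (38.0 -> "35-38").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleSheet

DETECTION_CATEGORIES = ("<31", "31-35", "35-38", ">38/ND")


@dataclass(frozen=True)
class QcReport:
    """Spike-in robustness plus per-miRNA detection summaries."""

    spikeins: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per-miRNA: mean_ct, category, donor_detection_count
    detection: pd.DataFrame = field(default_factory=pd.DataFrame)
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def all_spikeins_pass(self) -> bool:
        return bool(self.spikeins["pass"].all()) if len(self.spikeins) else False


def spikein_qc(ct: CtMatrix, threshold: float = 1.0, ipc_threshold: float = 1.0) -> pd.DataFrame:
    """Per-spike-in Ct range across samples and a pass flag.

    A spike-in missing (ND) in any sample yields a failure record with
    ``ct_range`` NaN rather than an exception. The interplate calibrator
    (any id containing "IPC" or "UniSp3") is judged against
    ``ipc_threshold``; its observed range is also reported as a plain
    statistic.
    """
    rows = []
    for sid in ct.spikein_ids:
        vals = ct.values.loc[sid]
        is_ipc = "IPC" in sid.upper() or "UNISP3" in sid.upper()
        thr = ipc_threshold if is_ipc else threshold
        if vals.isna().any():
            rows.append(
                {
                    "spikein": sid,
                    "ct_range": np.nan,
                    "threshold": thr,
                    "pass": False,
                    "note": f"not detected in {int(vals.isna().sum())} sample(s)",
                }
            )
            continue
        rng = float(vals.max() - vals.min())
        rows.append(
            {
                "spikein": sid,
                "ct_range": rng,
                "threshold": thr,
                "pass": rng < thr,
                "note": "",
            }
        )
    return pd.DataFrame(rows, columns=["spikein", "ct_range", "threshold", "pass", "note"]).set_index("spikein")


def categorize_mean_ct(mean_ct: float) -> str:
    if np.isnan(mean_ct) or mean_ct > 38.0:
        return ">38/ND"
    if mean_ct < 31.0:
        return "<31"
    if mean_ct < 35.0:
        return "31-35"
    return "35-38"


def detection_summary(
    ct: CtMatrix,
    sheet: SampleSheet,
    limit: float | None = None,
    average_days: bool = True,
) -> QcReport:
    """Detection bins and donor-overlap counts for every panel miRNA.

    * ``mean_ct``: average Ct over detected wells (ND excluded, not
      imputed); miRNAs with no detected well fall in ">38/ND".
    * ``donor_detection_count``: number of donors in which the miRNA is
      detected (Ct <= limit) under BOTH conditions. With
      ``average_days`` the per-donor/condition Ct is first averaged over
      days (ND excluded), mirroring a D7/D21-averaged presentation;
      otherwise every sample of the donor/condition must be detected.
    """
    if limit is None:
        limit = ct.detection_limit
    sheet.require_covers(ct.sample_ids)
    values = ct.mirna_values
    mean_ct = values.mean(axis=1)

    categories = mean_ct.apply(categorize_mean_ct)

    donors = sheet.donors
    conditions = sorted(sheet.frame.loc[values.columns, "condition"].unique())
    detected_per_donor = pd.DataFrame(False, index=values.index, columns=donors)
    for donor in donors:
        per_cond = []
        for cond in conditions:
            cols = [
                s
                for s in sheet.samples_for(condition=cond, donor=donor)
                if s in values.columns
            ]
            if not cols:
                per_cond.append(pd.Series(False, index=values.index))
                continue
            if average_days:
                avg = values[cols].mean(axis=1)
                per_cond.append(avg.notna() & (avg <= limit))
            else:
                per_cond.append((values[cols] <= limit).all(axis=1))
        detected_per_donor[donor] = np.logical_and.reduce(per_cond)
    donor_counts = detected_per_donor.sum(axis=1).astype(int)

    detection = pd.DataFrame(
        {
            "mean_ct": mean_ct,
            "category": categories,
            "donor_detection_count": donor_counts,
        }
    )
    counts = {cat: int((categories == cat).sum()) for cat in DETECTION_CATEGORIES}
    return QcReport(detection=detection, category_counts=counts)


def run_qc(
    ct: CtMatrix,
    sheet: SampleSheet,
    threshold: float = 1.0,
    ipc_threshold: float = 1.0,
    limit: float | None = None,
) -> QcReport:
    spike = spikein_qc(ct, threshold=threshold, ipc_threshold=ipc_threshold)
    summary = detection_summary(ct, sheet, limit=limit)
    return QcReport(
        spikeins=spike,
        detection=summary.detection,
        category_counts=summary.category_counts,
    )
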