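"""Normalization schemes for the two platforms.

Three schemes are provided:

* ``per_cell_ct`` — vesicular Ct shifted by log2(cells / ref_cells), so
  that linear abundance per cell is comparable across samples that used
  different cell inputs for secretion.
* ``mcr_ct`` — mean-centering restricted (global mean) normalization:
  subtract each sample's mean Ct over detected assays.
* ``tpm`` / ``log2_tpm`` — intracellular counts scaled to tags per
  million, with the detection filter "at least ``min_tpm`` TPM in (all
  samples of) at least one donor".

Ct conventions: lower Ct = more abundant; ND (NaN) propagates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import CountMatrix, CtMatrix, SampleSheet, ValidationError

Scheme = Literal["per_cell_ct", "mcr_ct", "tpm", "log2_tpm"]


@dataclass(frozen=True)
class NormalizedMatrix:
    """A miRNA x sample matrix tagged with the scheme that produced it."""

    values: pd.DataFrame
    scheme: Scheme
    meta: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def is_ct_scale(self) -> bool:
        return self.scheme in ("per_cell_ct", "mcr_ct")


def per_cell_normalize(
    ct: CtMatrix, sheet: SampleSheet, ref_cells: float | None = None
) -> NormalizedMatrix:
    """Shift each sample's Ct by log2(cells / ref_cells).

    Adding log2(cells/ref) to Ct is algebraically identical to dividing
    the linear abundance by the cell count (up to the common factor
    ``ref_cells``): 2**-(Ct + log2(c/r)) = 2**-Ct * r / c. By default
    ``ref_cells`` is the largest cell count in the run, so normalized Ct
    never decreases. ND stays ND.
    """
    sheet.require_covers(ct.sample_ids)
    cells = np.array([sheet.cells(s) for s in ct.sample_ids], dtype=float)
    if (cells <= 0).any():
        raise ValidationError("cells_for_secretion must be positive")
    if ref_cells is None:
        ref_cells = float(cells.max())
    if ref_cells <= 0:
        raise ValidationError("ref_cells must be positive")
    shift = np.log2(cells / ref_cells)
    values = ct.mirna_values + shift  # broadcasts over columns
    return NormalizedMatrix(
        values=values,
        scheme="per_cell_ct",
        meta={"ref_cells": float(ref_cells), "detection_limit": ct.detection_limit},
    )


def global_mean_normalize(ct: CtMatrix, limit: float | None = None) -> NormalizedMatrix:
    """Subtract each sample's mean Ct over detected assays (Ct <= limit).

    ND values are excluded from the mean and remain ND; values above the
    limit are still centered (they simply do not contribute to the mean).
    """
    if limit is None:
        limit = ct.detection_limit
    values = ct.mirna_values
    detected = values.where(values <= limit)
    n_det = detected.notna().sum(axis=0)
    if (n_det < 2).any():
        bad = list(n_det.index[n_det < 2])
        raise ValidationError(
            f"global mean normalization needs >=2 detected miRNAs; failing samples: {bad}"
        )
    sample_means = detected.mean(axis=0)
    return NormalizedMatrix(
        values=values - sample_means,
        scheme="mcr_ct",
        meta={
            "limit": float(limit),
            "sample_means": {k: float(v) for k, v in sample_means.items()},
        },
    )


def tpm_normalize(counts: CountMatrix, log2: bool = False, pseudocount: float = 1.0) -> NormalizedMatrix:
    tpm = counts.tpm
    if log2:
        return NormalizedMatrix(
            values=np.log2(tpm + pseudocount),
            scheme="log2_tpm",
            meta={"pseudocount": pseudocount},
        )
    return NormalizedMatrix(values=tpm, scheme="tpm", meta={})


def tpm_and_filter(
    counts: CountMatrix,
    sheet: SampleSheet,
    min_tpm: float = 5.0,
    tpm_rule: Literal["all_samples_of_donor", "any_sample"] = "all_samples_of_donor",
) -> tuple[NormalizedMatrix, list[str]]:
    """TPM-normalize and return the abundance-filtered miRNA set.

    A miRNA is kept if it reaches >= ``min_tpm`` in every sample of at
    least one donor (``all_samples_of_donor``, the stricter reading) or
    in at least one sample anywhere (``any_sample``).
    """
    sheet.require_covers(counts.sample_ids)
    norm = tpm_normalize(counts)
    tpm = norm.values
    if tpm_rule == "any_sample":
        kept_mask = (tpm >= min_tpm).any(axis=1)
    elif tpm_rule == "all_samples_of_donor":
        kept_mask = pd.Series(False, index=tpm.index)
        for donor in sheet.donors:
            cols = [s for s in sheet.samples_for(donor=donor) if s in tpm.columns]
            if not cols:
                continue
            kept_mask |= (tpm[cols] >= min_tpm).all(axis=1)
    else:
        raise ValueError(f"unknown tpm_rule {tpm_rule!r}")
    kept = list(tpm.index[kept_mask])
    norm = NormalizedMatrix(
        values=tpm, scheme="tpm", meta={"min_tpm": min_tpm, "tpm_rule": tpm_rule}
    )
    return norm, kept


def log2fc(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] = ("SIPS", "Q"),
    day: str | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-miRNA log2 fold change of ``contrast[0]`` over ``contrast[1]``.

    Samples are paired by donor (mean within donor/group first, then the
    per-donor differences are averaged). On Ct scales the fold change is
    mean(Ct_ref) - mean(Ct_test) because lower Ct = more abundant; on the
    tpm scale log2(tpm + pseudocount) is contrasted directly.
    """
    test, ref = contrast
    sheet.require_covers(norm.sample_ids)
    if norm.scheme == "tpm":
        values = np.log2(norm.values + pseudocount)
    else:
        values = norm.values
    diffs = {}
    for donor in sheet.donors:
        cols_t = [
            s for s in sheet.samples_for(condition=test, day=day, donor=donor)
            if s in values.columns
        ]
        cols_r = [
            s for s in sheet.samples_for(condition=ref, day=day, donor=donor)
            if s in values.columns
        ]
        if not cols_t or not cols_r:
            raise ValidationError(
                f"donor {donor!r} lacks samples for one side of contrast {contrast}"
            )
        diff = values[cols_t].mean(axis=1) - values[cols_r].mean(axis=1)
        if norm.is_ct_scale:
            diff = -diff
        diffs[donor] = diff
    return pd.DataFrame(diffs).mean(axis=1)
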