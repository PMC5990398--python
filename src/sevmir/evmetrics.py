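"""Vesicle summaries from nanoparticle tracking, plus apoptosis arithmetic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParticleTable, SampleSheet, ValidationError

DEFAULT_SIZE_BINS = tuple(float(x) for x in range(0, 420, 30))


@dataclass(frozen=True)
class EvSummary:
    """Per-sample size histogram (% of tracks), median size and folds."""

    histogram: pd.DataFrame  # rows: samples, columns: bin labels, values: %
    x50: pd.Series  # median tracked size per sample (nm)
    fold_change: pd.DataFrame | None = None


def size_summary(
    particles: ParticleTable, bin_edges: tuple[float, ...] = DEFAULT_SIZE_BINS
) -> EvSummary:
    """Binned size percentages and the median tracked diameter (X50).

    X50 is the empirical median of the tracked sizes (a documented
    substitute for the instrument's proprietary peak analysis).
    Percentages sum to 100 per sample; sizes beyond the last edge land
    in an overflow bin.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be increasing with >=2 values")
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g}")
    rows, medians = {}, {}
    for sid in particles.sample_ids:
        sizes = np.asarray(particles.sizes.get(sid, ()), dtype=float)
        if sizes.size == 0:
            raise ValidationError(f"sample {sid!r} has no tracked particles")
        counts, _ = np.histogram(sizes, bins=edges)
        overflow = int((sizes > edges[-1]).sum())  # histogram's last bin is closed
        pct = np.append(counts, overflow) * (100.0 / sizes.size)
        rows[sid] = pct
        medians[sid] = float(np.median(sizes))
    histogram = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    histogram.index.name = "sample_id"
    return EvSummary(histogram=histogram, x50=pd.Series(medians, name="x50_nm"))


def particles_per_cell_fold(
    particles: ParticleTable,
    sheet: SampleSheet,
    reference: tuple[str, str] = ("Q", "D7"),
) -> pd.DataFrame:
    """Group-mean particles per cell, as fold over the reference group.

    Per sample: concentration / cells; per (condition, day) group: mean;
    folds divide by the reference (condition, day) group mean. Invariant
    to any common rescaling of the concentration units.
    """
    sheet.require_covers(particles.sample_ids)
    frame = particles.frame
    ppc = frame["concentration"].astype(float) / frame["cells_for_secretion"].astype(float)
    anno = sheet.frame.loc[particles.sample_ids]
    grouped = ppc.groupby([anno["condition"], anno["day"]]).mean()
    ref_cond, ref_day = reference
    if (ref_cond, ref_day) not in grouped.index:
        raise ValidationError(f"reference group {reference} has no samples")
    ref = grouped.loc[(ref_cond, ref_day)]
    out = grouped.rename("particles_per_cell").to_frame()
    out["fold_vs_reference"] = grouped / ref
    out.index.names = ["condition", "day"]
    return out.reset_index()


def apoptosis_total(annexin_pct: float, double_pct: float, pi_pct: float) -> float:
    """Total apoptotic fraction: sum of the three gated percentages."""
    parts = (annexin_pct, double_pct, pi_pct)
    for x in parts:
        if not np.isfinite(x) or x < 0 or x > 100:
            raise ValidationError(f"percentage out of [0, 100]: {x!r}")
    total = float(sum(parts))
    if total > 100:
        raise ValidationError(f"gated percentages sum to {total} > 100")
    return total
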