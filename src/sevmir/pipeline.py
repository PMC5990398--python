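"""End-to-end orchestration: run the full chain on a dataset directory.

Inputs are the five standard files (``ct.tsv``, ``counts.tsv``,
``samples.tsv``, ``particles.tsv``, optional ``truth.tsv``); outputs are
result TSVs plus one machine-readable ``summary.json`` holding every
statistic the acceptance checks need. Deterministic given inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, evmetrics, io, normalize, qc, secretion, simulate

log = logging.getLogger("sevmir")

INPUT_FILES = {
    "ct": "ct.tsv",
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "particles": "particles.tsv",
    "truth": "truth.tsv",
}


@dataclass(frozen=True)
class RunConfig:
    """Every pipeline parameter, defaulting to the study-matching values."""

    indir: Path
    outdir: Path
    detection_limit: float = 38.0
    spikein_threshold: float = 1.0
    ipc_threshold: float = 1.0
    min_tpm: float = 5.0
    tpm_rule: str = "all_samples_of_donor"
    ref_cells: float | None = None
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    criterion: str = "p"
    lower_pct: float = 25.0
    upper_pct: float = 75.0
    top_k: int = 20
    quartile_rule: str = "and"
    seed: int = 0


@dataclass
class Dataset:
    ct: io.CtMatrix
    counts: io.CountMatrix
    sheet: io.SampleSheet
    particles: io.ParticleTable | None = None
    truth: simulate.GroundTruth | None = None


def load_dataset(indir: str | Path, detection_limit: float = 38.0) -> Dataset:
    indir = Path(indir)
    for key in ("ct", "counts", "samples"):
        if not (indir / INPUT_FILES[key]).exists():
            raise io.ParseError(f"stage 'io': missing input file {INPUT_FILES[key]!r} in {indir}")
    ct = io.read_ct_matrix(indir / INPUT_FILES["ct"], detection_limit=detection_limit)
    counts = io.read_count_matrix(indir / INPUT_FILES["counts"])
    sheet = io.read_sample_sheet(indir / INPUT_FILES["samples"])
    sheet.require_covers(ct.sample_ids)
    sheet.require_covers(counts.sample_ids)
    particles = None
    if (indir / INPUT_FILES["particles"]).exists():
        particles = io.read_particle_table(indir / INPUT_FILES["particles"])
    truth = None
    truth_path = indir / INPUT_FILES["truth"]
    if truth_path.exists():
        frame = pd.read_csv(truth_path, sep="\t", index_col=0)
        mult = float(frame.attrs.get("secretion_multiplier", np.nan)) if frame.attrs else np.nan
        if "secretion_multiplier" in frame.columns:
            mult = float(frame["secretion_multiplier"].iloc[0])
            frame = frame.drop(columns=["secretion_multiplier"])
        truth = simulate.GroundTruth(frame=frame, secretion_multiplier=mult)
    return Dataset(ct=ct, counts=counts, sheet=sheet, particles=particles, truth=truth)


def write_dataset(exp: simulate.SimulatedExperiment, outdir: str | Path) -> None:
    """Write a simulated experiment in the standard on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_ct_matrix(exp.ct, outdir / INPUT_FILES["ct"])
    io.write_count_matrix(exp.counts, outdir / INPUT_FILES["counts"])
    io.write_sample_sheet(exp.sheet, outdir / INPUT_FILES["samples"])
    io.write_particle_table(exp.particles, outdir / INPUT_FILES["particles"])
    truth = exp.truth.frame.copy()
    truth["secretion_multiplier"] = exp.truth.secretion_multiplier
    io.write_results(truth, outdir / INPUT_FILES["truth"])


def analyse(data: Dataset, config: RunConfig) -> dict:
    """Run QC, normalizations, differential testing, secretion scoring
    and EV metrics; return the result bundle as in-memory tables plus a
    JSON-ready summary dict."""
    results: dict[str, pd.DataFrame] = {}
    summary: dict = {"parameters": _params_dict(config)}

    ct, counts, sheet = data.ct, data.counts, data.sheet
    qpcr_sheet = sheet.subset([s for s in ct.sample_ids])
    ngs_sheet = sheet.subset([s for s in counts.sample_ids])

    # QC ---------------------------------------------------------------
    report = qc.run_qc(
        ct, sheet,
        threshold=config.spikein_threshold,
        ipc_threshold=config.ipc_threshold,
        limit=config.detection_limit,
    )
    results["qc_spikeins"] = report.spikeins
    results["qc_detection"] = report.detection
    summary["qc"] = {
        "spikeins_pass": bool(report.spikeins["pass"].all()),
        "category_counts": report.category_counts,
        "n_detected": int(
            sum(v for k, v in report.category_counts.items() if k != ">38/ND")
        ),
        "donor_detection_counts": {
            str(k): int(v)
            for k, v in report.detection["donor_detection_count"]
            .value_counts()
            .sort_index()
            .items()
        },
    }

    # Normalization -----------------------------------------------------
    per_cell = normalize.per_cell_normalize(ct, sheet, ref_cells=config.ref_cells)
    mcr = normalize.global_mean_normalize(ct, limit=config.detection_limit)
    tpm, kept = normalize.tpm_and_filter(
        counts, sheet, min_tpm=config.min_tpm, tpm_rule=config.tpm_rule
    )
    log2tpm = normalize.NormalizedMatrix(
        values=np.log2(tpm.values.loc[kept] + 1.0), scheme="log2_tpm", meta={}
    )
    summary["tpm_filter"] = {"n_total": len(tpm.values), "n_kept": len(kept)}

    # Differential ------------------------------------------------------
    de_counts: dict = {}
    for label, matrix, sh in (
        ("per_cell", per_cell, qpcr_sheet),
        ("mcr", mcr, qpcr_sheet),
        ("log2_tpm", log2tpm, ngs_sheet),
    ):
        de_counts[label] = {}
        for day in ("D7", "D21"):
            table = differential.differential_table(
                matrix,
                sh,
                day=day,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
                criterion=config.criterion,
            )
            results[f"diff_{label}_{day}"] = table
            pos_sig = int(((table["effect"] > 0) & (table["p"] < config.p_threshold)).sum())
            de_counts[label][day] = {
                "n_tested": int(len(table)),
                "up": int((table["volcano_class"] == "up").sum()),
                "down": int((table["volcano_class"] == "down").sum()),
                "positive_significant": pos_sig,
                "positive_significant_frac": pos_sig / len(table) if len(table) else float("nan"),
            }
    summary["differential"] = de_counts

    # Secretion correlation --------------------------------------------
    filt = secretion.correlation_filter(
        ct.mirna_ids, tpm, per_cell, quartile_rule=config.quartile_rule
    )
    ci = secretion.build_correlation_input(
        filt.kept, tpm, per_cell, ngs_sheet, qpcr_sheet
    )
    scores = secretion.compute_scores(ci)
    scores["label"] = secretion.classify_selective(
        scores, lower_pct=config.lower_pct, upper_pct=config.upper_pct
    )
    scores["label_rank_only"] = secretion.single_score_labels(
        scores, "ddrank", config.lower_pct, config.upper_pct
    )
    scores["label_ratio_only"] = secretion.single_score_labels(
        scores, "ddratio", config.lower_pct, config.upper_pct
    )
    results["secretion_scores"] = scores
    conc = secretion.method_concordance(scores, k=config.top_k)
    label_counts = scores["label"].value_counts()
    summary["secretion"] = {
        "filter_steps": [[name, int(nk)] for name, nk in filt.steps],
        "n_scored": int(len(scores)),
        "labels": {k: int(v) for k, v in sorted(label_counts.items())},
        "median_ddratio": float(np.nanmedian(scores["ddratio"])),
        "spearman_rho": _nan_to_none(conc.rho),
        "spearman_p": _nan_to_none(conc.pvalue),
        "top_k": conc.k,
        "top_secreted_overlap": conc.top_secreted_overlap,
        "top_retained_overlap": conc.top_retained_overlap,
    }

    # EV metrics --------------------------------------------------------
    if data.particles is not None:
        ev = evmetrics.size_summary(data.particles)
        folds = evmetrics.particles_per_cell_fold(data.particles, sheet)
        results["ev_size_histogram"] = ev.histogram
        results["ev_folds"] = folds
        sips = folds[folds["condition"] == "SIPS"]["fold_vs_reference"]
        summary["ev"] = {
            "x50_nm_mean": float(ev.x50.mean()),
            "sips_fold_mean": float(sips.mean()),
            "folds": {
                f"{r.condition}_{r.day}": float(r.fold_vs_reference)
                for r in folds.itertuples()
            },
        }

    # Truth recovery ----------------------------------------------------
    if data.truth is not None:
        confusion = simulate.truth_report(data.truth, scores["label"])
        results["truth_confusion"] = confusion
        summary["truth_recovery"] = {
            cls: {
                "sensitivity": _nan_to_none(confusion.at[cls, "sensitivity"]),
                "specificity": _nan_to_none(confusion.at[cls, "specificity"]),
                "n_true": int(confusion.at[cls, "n_true"]),
                "n_pred": int(confusion.at[cls, "n_pred"]),
            }
            for cls in confusion.index
        }

    return {"results": results, "summary": summary}


def score_secretion(
    exp: "simulate.SimulatedExperiment",
    lower_pct: float = 25.0,
    upper_pct: float = 75.0,
    quartile_rule: str = "and",
) -> pd.DataFrame:
    """Filter, score and classify one (simulated) experiment end to end."""
    sheet = exp.sheet
    per_cell = normalize.per_cell_normalize(exp.ct, sheet)
    tpm = normalize.tpm_normalize(exp.counts)
    filt = secretion.correlation_filter(
        exp.ct.mirna_ids, tpm, per_cell, quartile_rule=quartile_rule
    )
    ci = secretion.build_correlation_input(
        filt.kept, tpm, per_cell,
        sheet.subset(exp.counts.sample_ids), sheet.subset(exp.ct.sample_ids),
    )
    scores = secretion.compute_scores(ci)
    scores["label"] = secretion.classify_selective(scores, lower_pct, upper_pct)
    return scores


def run_report(config: RunConfig) -> dict:
    """Load inputs, analyse, and write all tables plus summary.json."""
    try:
        data = load_dataset(config.indir, detection_limit=config.detection_limit)
    except (io.ParseError, io.ValidationError, FileNotFoundError) as err:
        raise io.ParseError(f"stage 'io': {err}") from err
    log.info("loaded dataset from %s (%d qPCR assays, %d NGS miRNAs)",
             config.indir, len(data.ct.values), len(data.counts.counts))
    bundle = analyse(data, config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in bundle["results"].items():
        io.write_results(table, outdir / f"{name}.tsv")
    (outdir / "summary.json").write_text(
        json.dumps(bundle["summary"], indent=2, sort_keys=True, allow_nan=False,
                   default=_json_default)
        + "\n"
    )
    log.info("wrote %d result tables to %s", len(bundle["results"]), outdir)
    return bundle["summary"]


def _params_dict(config: RunConfig) -> dict:
    # paths are run-specific, not analysis parameters; keep summaries
    # byte-identical across output locations
    return {
        key: value
        for key, value in vars(config).items()
        if not isinstance(value, Path) and key not in ("indir", "outdir")
    }


def _nan_to_none(x: float):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    raise TypeError(f"not JSON serializable: {type(obj)}")
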