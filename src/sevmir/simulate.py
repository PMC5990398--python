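"""Synthetic experiment generator with planted, recoverable effects.

The generative model mirrors the measurement structure of the analysis:

1. latent per-miRNA cellular abundance, log-normal across miRNAs, with a
   condition multiplier for the planted intracellular DE sets and a
   per-donor strain factor shared between platforms;
2. per-vesicle loading proportional to cellular abundance times a
   condition-dependent packaging bias (planted secreted/retained sets)
   and a composition factor (planted per-vesicle composition sets);
3. vesicular signal per sample = loading x vesicles-per-cell (the
   senescent condition secretes ``secretion_multiplier`` times more per
   cell) x cells used for secretion — senescent preps use ~10x fewer
   cells, so per-cell normalization is genuinely exercised;
4. Ct = 40 - log_base(AU / 10) + noise, censored to ND above 40
   (base 2 at the default 100% PCR efficiency);
5. intracellular counts ~ negative binomial around library-scaled
   relative abundance;
6. spike-ins constant across samples plus N(0, 0.1) cycles;
7. tracked particle sizes log-normal (median ~70 nm); per-sample totals
   = cells x base rate x multiplier (senescent) x log-normal noise,
   averaged over technical triplicates.

The same config and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    DAYS,
    CountMatrix,
    CtMatrix,
    ParticleTable,
    SampleSheet,
    ValidationError,
)

SPIKEIN_BASE_CT = {
    "UniSp2": 20.0,
    "UniSp4": 27.0,
    "UniSp5": 33.0,
    "UniSp6": 21.5,
    "cel-miR-39-3p": 24.0,
    "UniSp3_IPC": 19.0,
}


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Effect sizes and noise levels of the synthetic experiment.

    Defaults reproduce the study's reported scale: 375-assay panel,
    3 donor strains x {Q, SIPS} x {D7, D21}, a 4-fold vesicles-per-cell
    increase in senescence, ~10-fold lower cell input for senescent
    vesicle preps, ~85% of cargo miRNAs secreted more per cell, planted
    per-vesicle composition changes (2 up / 5 down) and packaging-bias
    sets (~12% secreted, ~12% retained), and intracellular DE sets of
    46 up / 36 down. Composition and packaging effect sizes are
    order-of-magnitude choices (the study does not quantify them).
    """

    n_mirna: int = 375
    n_donors: int = 3
    secretion_multiplier: float = 4.0
    frac_cargo_increased: float = 0.85
    n_composition_up: int = 2
    n_composition_down: int = 5
    n_packaging_secreted: int = 45
    n_packaging_retained: int = 45
    intra_de_up: int = 46
    intra_de_down: int = 36
    cells_q: float = 1.5e7
    cells_sips: float = 1.65e6
    ct_noise_sd: float = 0.25
    nb_dispersion: float = 0.05
    library_size_mean: float = 1.0e6
    seed: int = 0
    # secondary knobs
    abundance_sigma: float = 2.5  # log-normal sigma of latent abundance
    donor_sd: float = 0.15  # per-donor, per-miRNA strain factor (log scale)
    bio_sd: float = 0.12  # per-sample biological noise (log scale)
    intra_de_effect: float = 2.5  # fold change of planted intracellular DE
    composition_effect: float = 4.0  # per-vesicle fold of composition sets
    packaging_effect: float = 6.0  # loading fold of packaging-bias sets
    au_scale: float = 1.0e4  # overall vesicular signal scale (median Ct ~30)
    ct_max: float = 40.0  # censoring limit (ND above)
    pcr_efficiency: float = 1.0
    size_median_nm: float = 70.0
    size_sigma: float = 0.35
    n_tracks: int = 300
    particles_per_cell_base: float = 1000.0
    nta_noise_sd: float = 0.15
    n_tech_nta: int = 3

    def validate(self) -> None:
        planted = (
            self.n_composition_up
            + self.n_composition_down
            + self.n_packaging_secreted
            + self.n_packaging_retained
            + self.intra_de_up
            + self.intra_de_down
        )
        if planted > self.n_mirna:
            raise ConfigError(
                f"planted subsets ({planted}) exceed n_mirna ({self.n_mirna})"
            )
        if not 0 <= self.frac_cargo_increased <= 1:
            raise ConfigError("frac_cargo_increased must lie in [0, 1]")
        for name in ("secretion_multiplier", "intra_de_effect", "composition_effect",
                     "packaging_effect", "cells_q", "cells_sips", "au_scale",
                     "library_size_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_mirna < 1 or self.n_donors < 1:
            raise ConfigError("n_mirna and n_donors must be >= 1")
        if self.pcr_efficiency <= 0:
            raise ConfigError("pcr_efficiency must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-miRNA effects, the recovery oracle for the pipeline.

    ``frame`` columns: intracellular_de in {+1, -1, 0},
    composition_change in {+1, -1, 0}, packaging_class in
    {secreted, retained, neutral}.
    """

    frame: pd.DataFrame
    secretion_multiplier: float

    @property
    def packaging_class(self) -> pd.Series:
        return self.frame["packaging_class"]


class SimulatedExperiment(NamedTuple):
    ct: CtMatrix
    counts: CountMatrix
    sheet: SampleSheet
    particles: ParticleTable
    truth: GroundTruth


def _sample_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for donor_i in range(config.n_donors):
        donor = f"HDF{donor_i + 1}"
        for cond in CONDITIONS:
            for day in DAYS:
                cells = config.cells_sips if cond == "SIPS" else config.cells_q
                for platform, tag in (("qpcr", "EV"), ("ngs", "IC")):
                    rows.append(
                        {
                            "sample_id": f"{donor}_{cond}_{day}_{tag}",
                            "donor": donor,
                            "condition": cond,
                            "day": day,
                            "cells_for_secretion": cells,
                            "platform": platform,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_experiment(config: GeneratorConfig) -> SimulatedExperiment:
    """Generate matched qPCR, NGS, sample-sheet, NTA and truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mirna
    mirnas = pd.Index([f"syn-miR-{i + 1:04d}" for i in range(n)], name="mirna_id")

    # --- planted subsets (disjoint) ------------------------------------
    perm = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor : cursor + k]
        cursor += k
        return out

    idx_de_up = take(config.intra_de_up)
    idx_de_down = take(config.intra_de_down)
    idx_comp_up = take(config.n_composition_up)
    idx_comp_down = take(config.n_composition_down)
    idx_pack_sec = take(config.n_packaging_secreted)
    idx_pack_ret = take(config.n_packaging_retained)

    intra_de = np.zeros(n, dtype=int)
    intra_de[idx_de_up] = 1
    intra_de[idx_de_down] = -1
    comp = np.zeros(n, dtype=int)
    comp[idx_comp_up] = 1
    comp[idx_comp_down] = -1
    pack = np.full(n, "neutral", dtype=object)
    pack[idx_pack_sec] = "secreted"
    pack[idx_pack_ret] = "retained"

    truth = GroundTruth(
        frame=pd.DataFrame(
            {
                "intracellular_de": intra_de,
                "composition_change": comp,
                "packaging_class": pack,
            },
            index=mirnas,
        ),
        secretion_multiplier=config.secretion_multiplier,
    )

    # --- latent abundances ---------------------------------------------
    base = rng.lognormal(mean=np.log(50.0), sigma=config.abundance_sigma, size=n)
    donor_names = [f"HDF{i + 1}" for i in range(config.n_donors)]
    donor_factor = {
        d: rng.lognormal(0.0, config.donor_sd, size=n) for d in donor_names
    }

    intra_mult = {
        "Q": np.ones(n),
        "SIPS": config.intra_de_effect ** intra_de.astype(float),
    }
    loading_mult = {
        "Q": np.ones(n),
        "SIPS": (
            (config.composition_effect ** comp.astype(float))
            * np.where(
                pack == "secreted",
                config.packaging_effect,
                np.where(pack == "retained", 1.0 / config.packaging_effect, 1.0),
            )
        ),
    }

    sheet_frame = _sample_frame(config)
    sheet = SampleSheet(sheet_frame)
    qpcr_ids = [s for s in sheet_frame.index if sheet_frame.at[s, "platform"] == "qpcr"]
    ngs_ids = [s for s in sheet_frame.index if sheet_frame.at[s, "platform"] == "ngs"]

    base_log = 1.0 + config.pcr_efficiency

    # --- vesicular Ct matrix -------------------------------------------
    ct_cols = {}
    for sid in qpcr_ids:
        row = sheet_frame.loc[sid]
        cond, donor = row["condition"], row["donor"]
        cells = float(row["cells_for_secretion"])
        cellular = base * donor_factor[donor] * intra_mult[cond]
        loading = cellular * loading_mult[cond]
        ves_per_cell = config.secretion_multiplier if cond == "SIPS" else 1.0
        bio = rng.lognormal(0.0, config.bio_sd, size=n)
        au = config.au_scale * loading * bio * ves_per_cell * (cells / config.cells_q) / 50.0
        ct = (
            40.0
            - np.log(au / 10.0) / np.log(base_log)
            + rng.normal(0.0, config.ct_noise_sd, size=n)
        )
        ct_cols[sid] = np.where(ct > config.ct_max, np.nan, ct)
    ct_values = pd.DataFrame(ct_cols, index=mirnas)

    spike = pd.DataFrame(
        {
            name: SPIKEIN_BASE_CT[name] + rng.normal(0.0, 0.1, size=len(qpcr_ids))
            for name in SPIKEIN_BASE_CT
        },
        index=qpcr_ids,
    ).T
    ct_full = pd.concat([ct_values, spike])
    ct_full.index.name = "mirna_id"
    ct = CtMatrix(
        values=ct_full,
        detection_limit=38.0,
        spikein_ids=tuple(SPIKEIN_BASE_CT),
    )

    # --- intracellular counts ------------------------------------------
    count_cols = {}
    for sid in ngs_ids:
        row = sheet_frame.loc[sid]
        cond, donor = row["condition"], row["donor"]
        cellular = base * donor_factor[donor] * intra_mult[cond]
        bio = rng.lognormal(0.0, config.bio_sd, size=n)
        rel = cellular * bio
        lib = rng.lognormal(np.log(config.library_size_mean), 0.2)
        mean = rel / rel.sum() * lib
        if config.nb_dispersion > 0:
            size = 1.0 / config.nb_dispersion
            p = size / (size + mean)
            count_cols[sid] = rng.negative_binomial(size, p)
        else:
            count_cols[sid] = rng.poisson(mean)
    counts = CountMatrix(counts=pd.DataFrame(count_cols, index=mirnas, dtype=np.int64))

    # --- NTA particle table --------------------------------------------
    sizes = {}
    conc_rows = {}
    for sid in qpcr_ids:
        row = sheet_frame.loc[sid]
        cond = row["condition"]
        cells = float(row["cells_for_secretion"])
        sizes[sid] = rng.lognormal(
            np.log(config.size_median_nm), config.size_sigma, size=config.n_tracks
        )
        mult = config.secretion_multiplier if cond == "SIPS" else 1.0
        reps = cells * config.particles_per_cell_base * mult * rng.lognormal(
            0.0, config.nta_noise_sd, size=config.n_tech_nta
        )
        conc_rows[sid] = float(np.mean(reps))
    particles = ParticleTable(
        frame=pd.DataFrame(
            {
                "concentration": pd.Series(conc_rows),
                "cells_for_secretion": sheet_frame.loc[qpcr_ids, "cells_for_secretion"].astype(float),
            }
        ),
        sizes=sizes,
    )

    return SimulatedExperiment(ct=ct, counts=counts, sheet=sheet, particles=particles, truth=truth)


# ---------------------------------------------------------------------------
# Truth recovery report


def truth_report(truth: GroundTruth, predictions: pd.Series) -> pd.DataFrame:
    """Per-class sensitivity/specificity of predicted packaging labels.

    ``predictions`` maps miRNA id -> label in {secreted, retained,
    neutral} over the same miRNA universe (a subset is allowed when the
    pipeline filtered miRNAs out; truth is then restricted to it).
    """
    unknown = [m for m in predictions.index if m not in truth.frame.index]
    if unknown:
        raise ValidationError(f"predicted ids not in ground truth: {unknown[:5]}")
    actual = truth.packaging_class.loc[predictions.index]
    rows = []
    for cls in ("secreted", "retained", "neutral"):
        is_true = actual == cls
        is_pred = predictions == cls
        tp = int((is_true & is_pred).sum())
        tn = int((~is_true & ~is_pred).sum())
        n_true = int(is_true.sum())
        n_false = int((~is_true).sum())
        rows.append(
            {
                "class": cls,
                "n_true": n_true,
                "n_pred": int(is_pred.sum()),
                "tp": tp,
                "sensitivity": tp / n_true if n_true else float("nan"),
                "specificity": tn / n_false if n_false else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> GeneratorConfig:
    known = {f for f in GeneratorConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
    return GeneratorConfig(**data)
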