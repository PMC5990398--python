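"""Tabular domain objects and plain-text readers/writers.

All on-disk formats are delimited text: TSV by default, CSV for ``.csv``
paths. Matrices are miRNA x sample with the feature id in the first
column and sample ids in the header. Not-detected qPCR wells are encoded
as ``ND`` (or an empty cell) on disk and as ``NaN`` in memory — a
deliberate distinction from a numeric Ct of 40, so that every consumer
must state whether it drops or bounds undetected assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("Q", "SIPS")
DAYS = ("D7", "D21")
PLATFORMS = ("qpcr", "ngs")

#: Synthetic control assays: extraction (UniSp2/4/5), RT (UniSp6,
#: cel-miR-39-3p) and the interplate calibrator (UniSp3 IPC).
DEFAULT_SPIKEINS = (
    "UniSp2",
    "UniSp4",
    "UniSp5",
    "UniSp6",
    "cel-miR-39-3p",
    "UniSp3_IPC",
)

#: Cell tokens (lower-cased) interpreted as "not detected".
ND_TOKENS = frozenset({"", "nd", "n.d.", "na", "nan", "undetermined"})

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "donor",
    "condition",
    "day",
    "cells_for_secretion",
    "platform",
)


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Annotations keying both matrices: one row per biological sample.

    ``frame`` is indexed by ``sample_id`` with columns donor, condition,
    day, cells_for_secretion and platform. ``(donor, condition, day,
    platform)`` uniquely identifies a sample.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"donor", "condition", "day", "cells_for_secretion", "platform"}
        missing = required - set(f.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(f["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
            )
        bad = set(f["day"]) - set(DAYS)
        if bad:
            raise ValidationError(f"unknown day labels {sorted(bad)}; expected {DAYS}")
        bad = set(f["platform"]) - set(PLATFORMS)
        if bad:
            raise ValidationError(
                f"unknown platform labels {sorted(bad)}; expected {PLATFORMS}"
            )
        cells = pd.to_numeric(f["cells_for_secretion"], errors="coerce")
        if cells.isna().any() or (cells <= 0).any():
            raise ValidationError("cells_for_secretion must be positive numbers")
        key = f[["donor", "condition", "day", "platform"]]
        if key.duplicated().any():
            raise ValidationError(
                "(donor, condition, day, platform) does not uniquely identify samples"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def donors(self) -> list[str]:
        return sorted(self.frame["donor"].unique())

    def samples_for(
        self,
        condition: str | None = None,
        day: str | None = None,
        platform: str | None = None,
        donor: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given (non-None) annotation."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in (
            ("condition", condition),
            ("day", day),
            ("platform", platform),
            ("donor", donor),
        ):
            if val is not None:
                mask &= self.frame[col] == val
        return list(self.frame.index[mask])

    def cells(self, sample_id: str) -> float:
        return float(self.frame.at[sample_id, "cells_for_secretion"])

    def require_covers(self, columns: Iterable[str]) -> None:
        """Raise unless every matrix column is annotated in the sheet."""
        missing = [c for c in columns if c not in self.frame.index]
        if missing:
            raise ValidationError(
                f"samples not annotated in sample sheet: {missing}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        self.require_covers(sample_ids)
        return SampleSheet(self.frame.loc[list(sample_ids)].copy())


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    frame = frame.set_index("sample_id")
    frame["cells_for_secretion"] = pd.to_numeric(
        frame["cells_for_secretion"], errors="coerce"
    )
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    path = Path(path)
    sheet.frame.to_csv(path, sep=_sep_for(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# Ct matrix


@dataclass(frozen=True)
class CtMatrix:
    """Vesicular qPCR panel: Ct per assay per sample, NaN = not detected.

    Spike-in control rows live in the same table; ``mirna_values``
    excludes them so downstream analyses never mix controls with cargo.
    """

    values: pd.DataFrame
    detection_limit: float = 38.0
    spikein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate assay ids: {dups}")
        arr = v.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite <= 0).any():
            raise ValidationError("Ct values must be positive")
        unknown = [s for s in self.spikein_ids if s not in v.index]
        if unknown:
            raise ValidationError(f"spike-in ids not in matrix: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return [m for m in self.values.index if m not in set(self.spikein_ids)]

    @property
    def mirna_values(self) -> pd.DataFrame:
        return self.values.loc[self.mirna_ids]

    @property
    def spikein_values(self) -> pd.DataFrame:
        return self.values.loc[list(self.spikein_ids)]


def _read_numeric_matrix(path: Path, allow_nd: bool) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected an id column plus >=1 sample column")
    id_col = raw.columns[0]
    raw = raw.set_index(id_col)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids {dups}")
    out = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        if allow_nd:
            cells = cells.mask(cells.str.lower().isin(ND_TOKENS))
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = cells.notna() & numeric.isna()
        if bad.any():
            row = raw.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric value {cells[bad].iloc[0]!r} "
                f"in row {row!r}, column {col!r}"
            )
        out[col] = numeric
    return pd.DataFrame(out, index=raw.index)


def read_ct_matrix(
    path: str | Path,
    detection_limit: float = 38.0,
    spikein_ids: Sequence[str] = DEFAULT_SPIKEINS,
) -> CtMatrix:
    """Read a Ct table; ND/empty cells become NaN.

    ``spikein_ids`` is a candidate list — only ids actually present in
    the table are recorded as spike-in rows.
    """
    path = Path(path)
    values = _read_numeric_matrix(path, allow_nd=True)
    present = tuple(s for s in spikein_ids if s in values.index)
    return CtMatrix(values=values, detection_limit=detection_limit, spikein_ids=present)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    path = Path(path)
    out = ct.values.astype(object)
    out = out.where(ct.values.notna(), "ND")
    out.to_csv(path, sep=_sep_for(path), index_label="mirna_id")


# ---------------------------------------------------------------------------
# Count matrix


@dataclass(frozen=True)
class CountMatrix:
    """Intracellular small-RNA-seq raw counts (miRNA x sample)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate miRNA ids: {dups}")
        arr = c.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("counts must be finite")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if np.any(arr != np.round(arr)):
            raise ValidationError("counts must be integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tpm(self) -> pd.DataFrame:
        """Tags per million: counts scaled to 1e6 per sample."""
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            zero = list(totals.index[totals <= 0])
            raise ValidationError(f"all-zero sample columns: {zero}")
        return self.counts * (1e6 / totals)


def read_count_matrix(path: str | Path) -> CountMatrix:
    path = Path(path)
    values = _read_numeric_matrix(path, allow_nd=False)
    if values.isna().any().any():
        raise ParseError(f"{path}: missing values are not allowed in count matrices")
    return CountMatrix(counts=values.round().astype(np.int64))


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    counts.counts.to_csv(path, sep=_sep_for(path), index_label="mirna_id")


# ---------------------------------------------------------------------------
# NTA particle table


@dataclass(frozen=True)
class ParticleTable:
    """Nanoparticle-tracking summaries per sample.

    ``sizes`` maps sample id -> array of tracked particle diameters (nm);
    ``frame`` holds per-sample total particle concentration and the cell
    count used for secretion.
    """

    frame: pd.DataFrame  # columns: concentration, cells_for_secretion
    sizes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if (pd.to_numeric(f["concentration"]) < 0).any():
            raise ValidationError("particle concentrations must be >= 0")
        if (pd.to_numeric(f["cells_for_secretion"]) <= 0).any():
            raise ValidationError("cell counts must be > 0")
        for sid, arr in self.sizes.items():
            if np.asarray(arr, dtype=float).size and np.min(arr) <= 0:
                raise ValidationError(f"non-positive particle size in sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)


def read_particle_table(path: str | Path) -> ParticleTable:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample_id", "concentration", "cells_for_secretion", "sizes_nm"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    frame = frame.set_index("sample_id")
    sizes = {}
    for sid, cell in frame["sizes_nm"].items():
        if isinstance(cell, str) and cell.strip():
            sizes[sid] = np.array([float(x) for x in cell.split(";")], dtype=float)
        else:
            sizes[sid] = np.array([], dtype=float)
    return ParticleTable(frame=frame.drop(columns=["sizes_nm"]), sizes=sizes)


def write_particle_table(particles: ParticleTable, path: str | Path) -> None:
    path = Path(path)
    frame = particles.frame.copy()
    frame["sizes_nm"] = [
        ";".join(repr(float(x)) for x in particles.sizes.get(sid, ()))
        for sid in frame.index
    ]
    frame.to_csv(path, sep=_sep_for(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# Generic results writer


def write_results(table: pd.DataFrame, path: str | Path, index_label: str = "mirna_id") -> None:
    """Write a result table as delimited text with stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), index_label=index_label)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)
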