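"""Core data model: expression matrices, study design, readers/writers, transforms.

Abundance matrices are features x samples. Protein abundance is label-free
quantification (LFQ) intensity, where a stored zero means "not detected";
transcript abundance is TPM. Both are nonnegative on the linear scale.
The study design binds each sample column to a muscle region (LD or SD),
an ordered developmental stage (E57 < E73 < E90 < P1 < P28 < P120 by
default) and a biological replicate number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STAGES",
    "DEFAULT_REGIONS",
    "ExpressionMatrix",
    "StudyDesign",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_study_design",
    "write_study_design",
    "log2_transform",
    "stage_mean_profiles",
]

logger = logging.getLogger(__name__)

#: Developmental stages in chronological order: embryonic days 57/73/90,
#: postnatal days 1/28/120.
DEFAULT_STAGES: tuple[str, ...] = ("E57", "E73", "E90", "P1", "P28", "P120")

#: Muscle regions: longissimus dorsi (fast-twitch dominant) and
#: semitendinosus (slow-twitch enriched).
DEFAULT_REGIONS: tuple[str, ...] = ("LD", "SD")

MODALITIES = ("protein", "transcript")
SCALES = ("linear", "log2")


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix tagged with modality and scale.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.
    modality
        ``"protein"`` (LFQ intensity; zero = not detected) or
        ``"transcript"`` (TPM).
    scale
        ``"linear"`` (values must be >= 0) or ``"log2"``.
    """

    data: pd.DataFrame
    modality: str
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if self.scale == "linear" and values.size and np.nanmin(values) < 0:
            raise FormatError("negative values in linear-scale matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.modality, self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.modality, self.scale)


@dataclass
class StudyDesign:
    """Sample annotations: one row per sample with region, stage, replicate.

    ``stages`` fixes the total stage ordering used everywhere downstream
    (adjacent-stage contrasts, trend profiles, presence transitions).
    """

    table: pd.DataFrame
    stages: tuple[str, ...] = DEFAULT_STAGES
    regions: tuple[str, ...] = field(default=DEFAULT_REGIONS)

    REQUIRED_COLUMNS = ("sample_id", "region", "stage", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in design")
        triples = t[["region", "stage", "replicate"]]
        if triples.duplicated().any():
            raise FormatError("duplicate (region, stage, replicate) triple in design")
        bad_stage = sorted(set(t["stage"]) - set(self.stages))
        if bad_stage:
            raise FormatError(
                f"unknown stage labels {bad_stage}; expected one of {list(self.stages)}"
            )
        bad_region = sorted(set(t["region"]) - set(self.regions))
        if bad_region:
            raise FormatError(
                f"unknown region labels {bad_region}; expected one of {list(self.regions)}"
            )
        if (t["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be >= 1")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, region: str | None = None, stage: str | None = None) -> list[str]:
        """Sample ids matching the given region and/or stage (None = all)."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if region is not None:
            mask &= t["region"] == region
        if stage is not None:
            mask &= t["stage"] == stage
        return list(t.loc[mask, "sample_id"])

    def stage_index(self, stage: str) -> int:
        return self.stages.index(stage)

    def adjacent_transitions(self) -> list[tuple[str, str]]:
        """Chronologically ordered (from_stage, to_stage) pairs."""
        return list(zip(self.stages[:-1], self.stages[1:]))

    def validate_against(self, m: ExpressionMatrix) -> None:
        """Every sample column of ``m`` must have exactly one design row."""
        design_ids = set(self.sample_ids)
        unmapped = [s for s in m.sample_ids if s not in design_ids]
        if unmapped:
            raise FormatError(f"samples without design rows: {unmapped[:5]}")


# ---------------------------------------------------------------------------
# File I/O (tab-separated, provenance header line starting with '#')
# ---------------------------------------------------------------------------

def _provenance_line(command: str = "") -> str:
    from . import __version__

    return f"# omnifiber {__version__} {command}".rstrip()


def read_expression_matrix(path: str | Path, modality: str) -> ExpressionMatrix:
    """Read a tab-separated features x samples matrix.

    First column holds feature ids, the header row holds sample ids.
    Missing cells are stored as 0 (for proteins this is the "not detected"
    convention). Lines starting with ``#`` are provenance comments.
    """
    path = Path(path)
    # check header duplicates before pandas mangles them
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    columns = header.rstrip("\n").split("\t")[1:]
    if len(columns) != len(set(columns)):
        raise FormatError(f"duplicate sample ids in header of {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids in {path}: {dups[:5]}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise FormatError(f"non-numeric cells in columns {non_numeric} of {path}")
    df = df.fillna(0.0).astype(float)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, modality=modality, scale="linear")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, command: str = ""
) -> None:
    """Write a matrix as tab-separated text with a provenance header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(command) + "\n")
        m.data.to_csv(fh, sep="\t", index_label="feature_id")


def read_study_design(
    path: str | Path, stages: Sequence[str] = DEFAULT_STAGES,
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return StudyDesign(df, stages=tuple(stages), regions=tuple(regions))


def write_study_design(d: StudyDesign, path: str | Path, command: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(command) + "\n")
        d.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on every cell; tags the result as log2 scale.

    With the default pseudocount of 1, a zero (protein "not detected")
    maps to exactly 0 on the log scale, preserving absence semantics.
    """
    if m.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and (m.values == 0).any():
        raise ValueError("pseudocount 0 with zero values would produce -inf")
    out = np.log2(m.data + pseudocount)
    return ExpressionMatrix(out, modality=m.modality, scale="log2")


def stage_mean_profiles(
    m: ExpressionMatrix, d: StudyDesign, pool_regions: bool = True
) -> ExpressionMatrix:
    """Average replicates into one column per stage (or region x stage).

    Means are arithmetic on the matrix's current scale. With
    ``pool_regions=False`` columns are labeled ``"<region>:<stage>"`` in
    region-major, stage-chronological order.
    """
    d.validate_against(m)
    groups: list[tuple[str, list[str]]] = []
    if pool_regions:
        for stage in d.stages:
            samples = [s for s in d.samples_for(stage=stage) if s in m.data.columns]
            groups.append((stage, samples))
    else:
        for region in d.regions:
            for stage in d.stages:
                samples = [
                    s for s in d.samples_for(region=region, stage=stage)
                    if s in m.data.columns
                ]
                groups.append((f"{region}:{stage}", samples))
    cols = {}
    for label, samples in groups:
        if not samples:
            raise ValueError(f"no samples for stage group {label!r}")
        cols[label] = m.data[samples].mean(axis=1)
    out = pd.DataFrame(cols, index=m.data.index)
    return ExpressionMatrix(out, modality=m.modality, scale=m.scale)
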