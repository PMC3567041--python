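"""Reading, binning, aligning and noise-filtering T-RFLP peak data.

A T-RFLP run yields, per sample, a list of detected fragment peaks: a
fragment size in (fractional) base pairs and a fluorescence intensity.
This module turns raw peak tables into an analysis-ready samples x T-RFs
matrix:

1. :func:`read_peak_table` parses tab/comma-delimited peak exports,
2. :func:`bin_peaks` rounds fragment sizes to integer T-RF lengths and
   restricts them to the retained size range (default 34-600 bp),
3. :func:`align_profiles` merges near-identical T-RF columns across
   samples (a deterministic surrogate for manual alignment),
4. :func:`vpt_filter` removes noise peaks with the variable percentage
   threshold method: the relative-fluorescence cutoff is chosen to
   decorrelate retained peak counts from total signal strength.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_MIN_BP = 34
DEFAULT_MAX_BP = 600

#: Column-name dialects for peak tables. "genemapper" mirrors the export
#: of ABI GeneMapper fragment analysis software.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {"sample": "sample", "size": "size", "intensity": "intensity"},
    "genemapper": {"sample": "Sample File", "size": "Size", "intensity": "Height"},
}


class PeakTableFormatError(ValueError):
    """A peak table is missing a mandatory column or is otherwise malformed."""


class EmptyInputError(ValueError):
    """No data rows were found in the input."""


def round_half_up(x: float) -> int:
    """Round a positive value to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PeakRecord:
    """One detected fragment peak of one sample."""

    sample_id: str
    fragment_size: float  # fractional base pairs, > 0
    intensity: float  # fluorescence, arbitrary units (height or area), >= 0

    def __post_init__(self) -> None:
        if not self.fragment_size > 0:
            raise ValueError(
                f"fragment_size must be > 0, got {self.fragment_size!r} "
                f"(sample {self.sample_id!r})"
            )
        if self.intensity < 0:
            raise ValueError(
                f"intensity must be >= 0, got {self.intensity!r} "
                f"(sample {self.sample_id!r})"
            )


@dataclass
class TRFProfile:
    """One sample's mapping of integer T-RF length (bp) to summed intensity."""

    sample_id: str
    abundances: dict[int, float]

    def total(self) -> float:
        return float(sum(self.abundances.values()))


@dataclass
class ProfileMatrix:
    """Samples x T-RFs abundance matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by sample id with integer T-RF
    lengths (bp) as columns, in strictly increasing order. ``metadata``
    (optional) is indexed by the same sample ids and typically carries
    ``station``, ``date`` and ``condition`` columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        cols = list(self.values.columns)
        if any(int(c) != c for c in cols):
            raise ValueError("T-RF columns must be integer base-pair lengths")
        self.values.columns = [int(c) for c in cols]
        if sorted(self.values.columns) != list(self.values.columns):
            self.values = self.values.sort_index(axis=1)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        zero = self.values.sum(axis=1) <= 0
        if zero.any():
            raise ValueError(
                f"all-zero sample rows: {list(self.values.index[zero])}"
            )
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trf_lengths(self) -> list[int]:
        return [int(c) for c in self.values.columns]

    def subset(self, sample_ids: Sequence[str]) -> "ProfileMatrix":
        meta = self.metadata.loc[list(sample_ids)] if self.metadata is not None else None
        return ProfileMatrix(self.values.loc[list(sample_ids)].copy(), meta)

    # -- serialization (TSV matrix + CSV metadata sidecar) -------------------

    def to_tsv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        if metadata_path is not None and self.metadata is not None:
            meta = self.metadata.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path)

    @classmethod
    def from_tsv(
        cls, path: str | Path, metadata_path: str | Path | None = None
    ) -> "ProfileMatrix":
        values = pd.read_csv(path, sep="\t", index_col="sample_id")
        values.index.name = None
        values.columns = [int(c) for c in values.columns]
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, index_col="sample_id")
            meta.index.name = None
        return cls(values, meta)


@dataclass
class VptResult:
    """Outcome of variable percentage threshold filtering."""

    chosen_percentage: float
    correlation_at_choice: float
    grid: list[tuple[float, float]]  # (percentage, Pearson r)
    filtered: ProfileMatrix
    dropped_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading


def read_peak_table(
    source,
    dialect: str = "generic",
    sample_col: str | None = None,
    size_col: str | None = None,
    intensity_col: str | None = None,
    sep: str | None = None,
) -> list[PeakRecord]:
    """Parse a delimited peak table into :class:`PeakRecord` objects.

    ``source`` is a path or open text handle with a header row. Column
    names come from ``dialect`` (see :data:`DIALECTS`) unless overridden
    explicitly. Delimiter is sniffed unless ``sep`` is given. Rows with
    non-numeric size or intensity are dropped with a warning; negative
    intensities raise.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    names = dict(DIALECTS[dialect])
    if sample_col:
        names["sample"] = sample_col
    if size_col:
        names["size"] = size_col
    if intensity_col:
        names["intensity"] = intensity_col

    try:
        df = pd.read_csv(
            source, sep=sep, engine="python", skipinitialspace=True
        )
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError("peak table contains no data") from exc

    for key, col in names.items():
        if col not in df.columns:
            raise PeakTableFormatError(
                f"missing mandatory column {col!r} (role: {key}); "
                f"found columns {list(df.columns)}"
            )
    if len(df) == 0:
        raise EmptyInputError("peak table has a header but no data rows")

    sizes = pd.to_numeric(df[names["size"]], errors="coerce")
    intens = pd.to_numeric(df[names["intensity"]], errors="coerce")
    bad = sizes.isna() | intens.isna()
    if bad.any():
        log.warning("dropping %d rows with non-numeric size/intensity", int(bad.sum()))
    records = [
        PeakRecord(str(s), float(z), float(h))
        for s, z, h in zip(df[names["sample"]][~bad], sizes[~bad], intens[~bad])
    ]
    if not records:
        raise EmptyInputError("no parseable data rows in peak table")
    return records


# ---------------------------------------------------------------------------
# binning


def bin_peaks(
    records: Iterable[PeakRecord],
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> list[TRFProfile]:
    """Round fragment sizes to integer T-RFs and restrict to [min_bp, max_bp].

    Rounding is half-up (113.5 -> 114). Records rounding to the same
    integer within a sample have their intensities summed; records
    outside the range after rounding are dropped. A sample whose peaks
    are all out of range is omitted with a logged warning. Samples keep
    their order of first appearance.
    """
    per_sample: dict[str, dict[int, float]] = {}
    order: list[str] = []
    for rec in records:
        if rec.sample_id not in per_sample:
            per_sample[rec.sample_id] = {}
            order.append(rec.sample_id)
        bp = round_half_up(rec.fragment_size)
        if bp < min_bp or bp > max_bp:
            continue
        bins = per_sample[rec.sample_id]
        bins[bp] = bins.get(bp, 0.0) + rec.intensity

    profiles = []
    for sid in order:
        if not per_sample[sid]:
            log.warning("sample %r has no peaks in [%d, %d] bp; omitted", sid, min_bp, max_bp)
            continue
        profiles.append(TRFProfile(sid, dict(sorted(per_sample[sid].items()))))
    return profiles


# ---------------------------------------------------------------------------
# alignment


def profiles_to_matrix(
    profiles: Sequence[TRFProfile], metadata: pd.DataFrame | None = None
) -> ProfileMatrix:
    """Stack profiles into a ProfileMatrix over the union of their T-RFs."""
    all_bp = sorted({bp for p in profiles for bp in p.abundances})
    data = np.zeros((len(profiles), len(all_bp)))
    col = {bp: i for i, bp in enumerate(all_bp)}
    for r, p in enumerate(profiles):
        for bp, v in p.abundances.items():
            data[r, col[bp]] = v
    values = pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=all_bp)
    return ProfileMatrix(values, metadata)


def align_profiles(
    profiles: Sequence[TRFProfile] | ProfileMatrix,
    tolerance_bp: int = 1,
    metadata: pd.DataFrame | None = None,
) -> ProfileMatrix:
    """Merge T-RF columns that differ by at most ``tolerance_bp`` across samples.

    Deterministic surrogate for manual alignment of fragment calls:
    columns are visited greedily in descending total-intensity order
    (ties broken by smaller bp); each unvisited column absorbs all other
    unvisited columns within the tolerance. The merged column is keyed
    by the intensity-weighted modal length, i.e. the member with the
    largest total intensity (the seed). ``tolerance_bp=0`` is the
    identity on columns.
    """
    if isinstance(profiles, ProfileMatrix):
        matrix = profiles
        if metadata is None:
            metadata = matrix.metadata
    else:
        if len(profiles) < 2:
            raise ValueError("alignment needs at least 2 profiles")
        matrix = profiles_to_matrix(profiles, metadata)

    if tolerance_bp == 0:
        return matrix

    totals = matrix.values.sum(axis=0)
    # descending total intensity, then ascending bp for determinism
    seeds = sorted(matrix.values.columns, key=lambda bp: (-totals[bp], bp))
    unassigned = set(matrix.values.columns)
    groups: dict[int, list[int]] = {}
    for seed in seeds:
        if seed not in unassigned:
            continue
        members = [bp for bp in sorted(unassigned) if abs(bp - seed) <= tolerance_bp]
        for bp in members:
            unassigned.discard(bp)
        groups[seed] = members

    merged = pd.DataFrame(
        {seed: matrix.values[members].sum(axis=1) for seed, members in groups.items()},
        index=matrix.values.index,
    )
    return ProfileMatrix(merged, metadata)


# ---------------------------------------------------------------------------
# variable percentage threshold filtering


def default_vpt_grid(start: float = 0.01, stop: float = 5.0, step: float = 0.01) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


def vpt_filter(
    matrix: ProfileMatrix,
    percentage_grid: Sequence[float] | None = None,
    min_trfs: int = 2,
) -> VptResult:
    """Variable percentage threshold noise filtering.

    For each candidate percentage q, peaks with intensity below q% of
    their sample's total fluorescence are removed and the Pearson
    correlation between per-sample total fluorescence and per-sample
    retained-peak count is computed. The chosen q minimizes |r| (a
    correlation between counts and signal strength indicates that noise
    peaks are still being retained); zero-variance counts give r = 0,
    and ties are broken toward the smaller percentage (retaining more
    data). Samples with fewer than ``min_trfs`` retained T-RFs at the
    chosen threshold are dropped with a warning.
    """
    grid = np.asarray(
        default_vpt_grid() if percentage_grid is None else list(percentage_grid), dtype=float
    )
    if len(grid) == 0:
        raise ValueError("empty percentage grid")
    if np.any(np.diff(grid) <= 0) and len(grid) > 1:
        raise ValueError("percentage grid must be strictly increasing")

    values = matrix.values.to_numpy()
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("matrix rows must have positive totals")

    evaluated: list[tuple[float, float]] = []
    for q in grid:
        thresh = totals * (q / 100.0)
        kept = (values > 0) & (values >= thresh[:, None])
        counts = kept.sum(axis=1).astype(float)
        if np.std(counts) == 0 or np.std(totals) == 0:
            r = 0.0  # zero-variance convention: uniform counts stay eligible
        else:
            r = float(np.corrcoef(totals, counts)[0, 1])
        evaluated.append((float(q), r))

    chosen_q, chosen_r = min(evaluated, key=lambda qr: (abs(qr[1]), qr[0]))

    thresh = totals * (chosen_q / 100.0)
    filtered_values = np.where(values >= thresh[:, None], values, 0.0)
    filtered = pd.DataFrame(filtered_values, index=matrix.values.index, columns=matrix.values.columns)

    n_trfs = (filtered > 0).sum(axis=1)
    dropped = list(filtered.index[n_trfs < min_trfs])
    if dropped:
        if len(dropped) == len(filtered):
            raise ValueError(
                f"VPT filtering at {chosen_q}% leaves no usable samples: {dropped}"
            )
        log.warning(
            "dropping %d samples with < %d retained T-RFs at %.3g%%: %s",
            len(dropped), min_trfs, chosen_q, dropped,
        )
        filtered = filtered.drop(index=dropped)
    filtered = filtered.loc[:, (filtered > 0).any(axis=0)]

    meta = matrix.metadata.loc[filtered.index] if matrix.metadata is not None else None
    return VptResult(
        chosen_percentage=chosen_q,
        correlation_at_choice=chosen_r,
        grid=evaluated,
        filtered=ProfileMatrix(filtered, meta),
        dropped_samples=dropped,
    )


# ---------------------------------------------------------------------------
# simple transforms


def to_relative(matrix: ProfileMatrix) -> ProfileMatrix:
    """Scale each sample (row) to relative abundances summing to 1."""
    totals = matrix.values.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero rows cannot be scaled to relative abundance")
    return ProfileMatrix(matrix.values.div(totals, axis=0), matrix.metadata)


def occupancy(matrix: ProfileMatrix, fraction: float) -> list[int]:
    """T-RFs detected (intensity > 0) in at least ``fraction`` of samples."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    presence = (matrix.values > 0).mean(axis=0)
    return [int(bp) for bp in matrix.values.columns if presence[bp] >= fraction - 1e-12]
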