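"""Reading and writing beta-value matrices, probe annotations and sample groups.

All on-disk formats are plain delimited text. A beta matrix file has a header
row of column identifiers and a first column of row identifiers; missing
entries may be written as an empty cell, ``NA`` or ``NaN`` (case-insensitive).
On output missing entries are always written as ``NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "SampleGrouping",
    "LoadReport",
    "BetaMatrixError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "read_sample_grouping",
]

#: Missing-value tokens accepted on input (matched case-insensitively).
NA_TOKENS = (
    "",
    "NA", "Na", "nA", "na",
    "NaN", "NAN", "nan", "naN", "NAn", "nAn", "nAN", "Nan",
)

_RANGE_SLACK = 1e-9


class BetaMatrixError(ValueError):
    """Raised on malformed or inconsistent beta-matrix input."""


@dataclass
class LoadReport:
    """Bookkeeping for one :func:`read_beta_matrix` call."""

    n_clamped: int = 0
    n_missing: int = 0


@dataclass
class BetaMatrix:
    """An n samples x m probes matrix of methylation beta-values in [0, 1].

    Missing entries are stored as ``numpy.nan``. Rows are samples, columns
    are CpG probes; ``sample_ids`` and ``probe_ids`` label the axes.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    load_report: LoadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.probe_ids) != m:
            raise BetaMatrixError(
                f"identifier counts ({len(self.sample_ids)}, {len(self.probe_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise BetaMatrixError("duplicate sample identifiers")
        if len(set(self.probe_ids)) != m:
            raise BetaMatrixError("duplicate probe identifiers")

    # -- basic queries -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean n x m array, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def validate_range(self) -> None:
        v = self.values
        with np.errstate(invalid="ignore"):
            bad = (v < 0.0) | (v > 1.0)
        if bool(np.any(bad & ~np.isnan(v))):
            raise BetaMatrixError("beta values outside [0, 1]")

    # -- construction / conversion ----------------------------------------

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "BetaMatrix":
        """Build from a samples x probes DataFrame (index = sample ids)."""
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            probe_ids=[str(c) for c in frame.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.probe_ids)
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            probe_ids=list(self.probe_ids),
        )

    def select_probes(self, col_idx: np.ndarray | list[int]) -> "BetaMatrix":
        col_idx = np.asarray(col_idx, dtype=int)
        return BetaMatrix(
            values=self.values[:, col_idx],
            sample_ids=list(self.sample_ids),
            probe_ids=[self.probe_ids[j] for j in col_idx],
        )

    def select_samples(self, row_idx: np.ndarray | list[int]) -> "BetaMatrix":
        row_idx = np.asarray(row_idx, dtype=int)
        return BetaMatrix(
            values=self.values[row_idx, :],
            sample_ids=[self.sample_ids[i] for i in row_idx],
            probe_ids=list(self.probe_ids),
        )

    def equals(self, other: "BetaMatrix", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """True if ids match, masks are identical and values agree within tol."""
        if self.sample_ids != other.sample_ids or self.probe_ids != other.probe_ids:
            return False
        a, b = self.values, other.values
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        obs = ~np.isnan(a)
        if rtol == 0.0 and atol == 0.0:
            return bool(np.array_equal(a[obs], b[obs]))
        return bool(np.allclose(a[obs], b[obs], rtol=rtol, atol=atol))


@dataclass
class ProbeAnnotation:
    """Mapping probe identifier -> chromosome label."""

    entries: dict[str, str]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.entries

    def chromosome_of(self, probe_id: str) -> str | None:
        return self.entries.get(probe_id)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.entries.values():
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class SampleGrouping:
    """Mapping sample identifier -> group label."""

    entries: dict[str, str]

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.entries.values():
            seen.setdefault(g, None)
        return list(seen)


# ---------------------------------------------------------------------------
# beta matrix I/O
# ---------------------------------------------------------------------------


def read_beta_matrix(
    path,
    orientation: str = "samples_by_probes",
    delimiter: str = "\t",
    clamp_out_of_range: bool = False,
) -> BetaMatrix:
    """Read a delimited beta-value matrix.

    Parameters
    ----------
    path
        File with a header row of column ids and row ids in the first column.
    orientation
        ``samples_by_probes`` (rows are samples, the in-memory convention) or
        ``probes_by_samples`` (the common GEO layout; the matrix is transposed
        on load).
    delimiter
        Field separator, tab by default.
    clamp_out_of_range
        If set, values outside [0, 1] are clamped into range and counted in
        the load report instead of raising.
    """
    if orientation not in ("samples_by_probes", "probes_by_samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            na_values=list(NA_TOKENS),
            keep_default_na=False,
            engine="c",
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise BetaMatrixError(f"cannot parse beta matrix {path}: {exc}") from exc

    bad_cols = [c for c in frame.columns if frame[c].dtype == object]
    if bad_cols:
        raise BetaMatrixError(
            f"non-numeric cells in column(s) {bad_cols[:5]} of {path}"
        )
    if orientation == "probes_by_samples":
        frame = frame.T

    if frame.index.has_duplicates:
        raise BetaMatrixError(f"duplicate sample identifiers in {path}")
    if frame.columns.has_duplicates:
        raise BetaMatrixError(f"duplicate probe identifiers in {path}")

    values = frame.to_numpy(dtype=float)
    report = LoadReport(n_missing=int(np.isnan(values).sum()))
    with np.errstate(invalid="ignore"):
        out_low = values < 0.0
        out_high = values > 1.0
        far_out = (values < -_RANGE_SLACK) | (values > 1.0 + _RANGE_SLACK)
    if np.any(far_out):
        if not clamp_out_of_range:
            i, j = np.argwhere(far_out)[0]
            raise BetaMatrixError(
                f"value {values[i, j]!r} at ({frame.index[i]!r}, {frame.columns[j]!r}) "
                "outside [0, 1]; pass clamp_out_of_range to clamp"
            )
        report.n_clamped = int(np.count_nonzero(far_out))
    # values within numerical slack of the boundary are snapped silently
    values = np.where(out_low & ~np.isnan(values), 0.0, values)
    values = np.where(out_high & ~np.isnan(values), 1.0, values)

    return BetaMatrix(
        values=values,
        sample_ids=[str(i) for i in frame.index],
        probe_ids=[str(c) for c in frame.columns],
        load_report=report,
    )


def write_beta_matrix(X: BetaMatrix, path, delimiter: str = "\t") -> None:
    """Write a beta matrix so that re-reading reproduces it.

    Values are written with 17 significant digits (round-trip exact for
    float64); missing entries are written as ``NA``.
    """
    if X.n_samples == 0 or X.n_probes == 0:
        raise BetaMatrixError("refusing to write an empty beta matrix")
    X.to_dataframe().to_csv(path, sep=delimiter, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# probe annotation / sample grouping I/O
# ---------------------------------------------------------------------------


def read_probe_annotation(path, format: str = "two_column", delimiter: str = "\t") -> ProbeAnnotation:
    """Read a probe -> chromosome mapping.

    ``two_column`` is a header-less file of ``probe_id<sep>chromosome`` lines.
    ``bed`` is standard BED: chromosome in column 1, probe id in the name
    field (column 4); coordinates are parsed but only chromosome and name are
    retained.
    """
    if format not in ("two_column", "bed"):
        raise ValueError(f"unknown annotation format: {format!r}")
    entries: dict[str, str] = {}
    n_dupes = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split(delimiter if format == "two_column" else "\t")
            if format == "two_column":
                if len(fields) < 2:
                    raise BetaMatrixError(
                        f"{path}:{lineno}: expected probe_id{delimiter!r}chromosome"
                    )
                probe, chrom = fields[0].strip(), fields[1].strip()
            else:
                if len(fields) < 4:
                    raise BetaMatrixError(
                        f"{path}:{lineno}: BED line needs >=4 fields for a probe name"
                    )
                chrom, probe = fields[0].strip(), fields[3].strip()
            if probe in entries:
                if entries[probe] != chrom:
                    raise BetaMatrixError(
                        f"{path}:{lineno}: probe {probe!r} annotated to both "
                        f"{entries[probe]!r} and {chrom!r}"
                    )
                n_dupes += 1
                continue
            entries[probe] = chrom
    if n_dupes:
        warnings.warn(
            f"{n_dupes} duplicate probe annotation line(s) in {path} (identical chromosome; deduplicated)",
            stacklevel=2,
        )
    return ProbeAnnotation(entries=entries)


def read_sample_grouping(path, delimiter: str = "\t") -> SampleGrouping:
    """Read a header-less two-column ``sample_id<sep>group`` file."""
    entries: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise BetaMatrixError(f"{path}:{lineno}: expected sample_id{delimiter!r}group")
            sample, group = fields[0].strip(), fields[1].strip()
            if sample in entries and entries[sample] != group:
                raise BetaMatrixError(f"{path}:{lineno}: sample {sample!r} labelled twice")
            entries[sample] = group
    return SampleGrouping(entries=entries)
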