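"""Core containers, beta/M transforms and file I/O.

DNA methylation at a CpG site is summarised as a *beta value*, the fraction
of methylated alleles, bounded in [0, 1]. Statistical operations (noise
models, variance estimation) are better behaved on the *M-value* scale, the
log2 odds ``M = log2(beta / (1 - beta))``, which is unbounded and
approximately variance-stabilised. This module holds the thin validated
containers the rest of the package passes around, the transforms between the
two scales, and readers/writers for the plain-text formats the toolkit
touches (beta matrices as TSV/CSV, DNase-hypersensitive-site intervals as
BED, CpG position maps as TSV, CpG id lists as plain text).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Default clipping constant keeping beta values away from {0, 1} so that the
#: M-value transform stays finite.
DEFAULT_EPS = 1e-6

_LN2 = np.log(2.0)


def _first_bad(df: pd.DataFrame, mask: np.ndarray) -> str:
    """Return a 'CpG x / sample y' location string for the first True in mask."""
    i, j = np.argwhere(mask)[0]
    return f"row {df.index[i]!r} / column {df.columns[j]!r}"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values in [0, 1].

    ``data`` is indexed by CpG id with one column per sample. Matrices are
    complete: rows with missing values are dropped (and counted in
    ``n_dropped``) at load time, never carried through.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(
                "missing value at " + _first_bad(self.data, np.isnan(vals))
            )
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            raise ValueError(
                "beta value outside [0, 1] at " + _first_bad(self.data, bad)
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class MValueMatrix:
    """CpG x sample matrix of M-values (log2 methylation odds), finite reals."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(
                "non-finite M-value at "
                + _first_bad(self.data, ~np.isfinite(vals))
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ReferenceMatrix:
    """CpG x cell-type matrix of centroid beta values (the deconvolution basis)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG")
        _check_unique(self.data.columns, "cell type")
        if self.data.shape[1] < 2:
            raise ValueError("a reference needs at least 2 cell types")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(
                "missing value at " + _first_bad(self.data, np.isnan(vals))
            )
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            raise ValueError(
                "centroid beta outside [0, 1] at " + _first_bad(self.data, bad)
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class CellFractions:
    """Sample x cell-type matrix of estimated weights: non-negative, row sums <= 1.

    ``degenerate`` flags samples where every raw weight was non-positive and
    an all-zero row was returned instead of a simplex point.
    """

    data: pd.DataFrame
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals < -1e-9).any():
            raise ValueError(
                "negative weight at " + _first_bad(self.data, vals < -1e-9)
            )
        # forgive solver-level negative dust
        self.data = self.data.clip(lower=0.0)
        sums = self.data.sum(axis=1).to_numpy()
        if (sums > 1.0 + 1e-8).any():
            bad = self.data.index[sums > 1.0 + 1e-8][0]
            raise ValueError(f"weights of sample {bad!r} sum to more than 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class CpGMap:
    """Genomic location of each CpG: chromosome and 1-based position."""

    data: pd.DataFrame  # index: CpG id; columns: chrom (str), pos (int, 1-based)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG")
        missing = {"chrom", "pos"} - set(self.data.columns)
        if missing:
            raise ValueError(f"CpG map missing columns: {sorted(missing)}")
        if (self.data["pos"].to_numpy() < 1).any():
            bad = self.data.index[self.data["pos"] < 1][0]
            raise ValueError(f"CpG {bad!r} has position < 1")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class DHSCatalog:
    """Per-cell-type sets of open-chromatin intervals, 0-based half-open."""

    intervals: dict[str, list[tuple[str, int, int]]]
    _trees: dict[str, dict[str, IntervalTree]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for ct, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                if start >= end:
                    raise ValueError(
                        f"empty/inverted interval {chrom}:{start}-{end} for {ct!r}"
                    )

    @property
    def cell_types(self) -> list[str]:
        return list(self.intervals)

    def _tree(self, cell_type: str) -> dict[str, IntervalTree]:
        if cell_type not in self._trees:
            per_chrom: dict[str, IntervalTree] = {}
            for chrom, start, end in self.intervals[cell_type]:
                per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees[cell_type] = per_chrom
        return self._trees[cell_type]

    def covers(self, cell_type: str, chrom: str, pos0: int) -> bool:
        """Whether 0-based position ``pos0`` falls in an interval of ``cell_type``."""
        tree = self._tree(cell_type).get(chrom)
        return bool(tree is not None and tree[pos0])


# ---------------------------------------------------------------------------
# beta <-> M transforms


def beta_to_m(beta: BetaMatrix, eps: float = DEFAULT_EPS) -> MValueMatrix:
    """Convert beta values to M-values, ``M = log2(b / (1 - b))``.

    Beta values are clipped into ``[eps, 1 - eps]`` first so boundary values
    map to finite M-values.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    vals = beta.data.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(
            "non-finite beta value at " + _first_bad(beta.data, ~np.isfinite(vals))
        )
    b = np.clip(vals, eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.data.index, columns=beta.data.columns))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Convert M-values back to beta values, ``b = 2^M / (1 + 2^M)``."""
    vals = m.data.to_numpy(dtype=float)
    b = expit(vals * _LN2)  # numerically stable logistic
    return BetaMatrix(pd.DataFrame(b, index=m.data.index, columns=m.data.columns))


def beta_to_m_array(b: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Array version of :func:`beta_to_m` for internal numeric pipelines."""
    b = np.clip(np.asarray(b, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta_array(m: np.ndarray) -> np.ndarray:
    """Array version of :func:`m_to_beta`."""
    return expit(np.asarray(m, dtype=float) * _LN2)


# ---------------------------------------------------------------------------
# file I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _load_matrix_frame(path: str | Path) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    _check_unique(df.index, "CpG")
    incomplete = df.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        logger.info("dropped %d rows with missing values from %s", n_dropped, path)
        df = df.loc[~incomplete]
    return df, n_dropped


def load_beta_matrix(path: str | Path) -> BetaMatrix:
    """Load a CpG x sample beta matrix from TSV (or CSV by extension).

    The first column holds CpG ids, the header row sample ids. Rows with any
    missing value are dropped and counted (``n_dropped``).
    """
    df, n_dropped = _load_matrix_frame(path)
    return BetaMatrix(df, n_dropped=n_dropped)


def save_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="CpG")


def load_reference_matrix(path: str | Path) -> ReferenceMatrix:
    """Load a CpG x cell-type centroid matrix (same layout as beta matrices)."""
    df, _ = _load_matrix_frame(path)
    return ReferenceMatrix(df)


def save_reference_matrix(ref: ReferenceMatrix, path: str | Path) -> None:
    path = Path(path)
    ref.data.to_csv(path, sep=_sep_for(path), index_label="CpG")


def save_cell_fractions(fracs: CellFractions, path: str | Path) -> None:
    path = Path(path)
    fracs.data.to_csv(path, sep=_sep_for(path), index_label="sample")


def load_cpg_map(path: str | Path) -> CpGMap:
    """Load a CpG position table: columns CpG, chrom, pos (1-based)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.rename(columns={df.columns[0]: "CpG"}).set_index("CpG")
    df["pos"] = df["pos"].astype(int)
    return CpGMap(df[["chrom", "pos"]])


def save_cpg_map(cpg_map: CpGMap, path: str | Path) -> None:
    path = Path(path)
    cpg_map.data.to_csv(path, sep=_sep_for(path), index_label="CpG")


def load_cpg_list(path: str | Path) -> frozenset[str]:
    """Load a plain-text list of CpG ids, one per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def load_dhs_catalog(paths_by_celltype: Mapping[str, str | Path]) -> DHSCatalog:
    """Load BED3+ interval files, one per cell type (0-based half-open).

    Columns beyond chrom/start/end are ignored; an empty file yields an empty
    interval set for that cell type.
    """
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for cell_type, path in paths_by_celltype.items():
        ivs: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: start >= end ({start} >= {end})"
                    )
                ivs.append((chrom, start, end))
        intervals[cell_type] = ivs
    return DHSCatalog(intervals)


def save_dhs_catalog(catalog: DHSCatalog, out_dir: str | Path) -> dict[str, Path]:
    """Write one BED3 file per cell type under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cell_type, ivs in catalog.intervals.items():
        path = out_dir / f"dhs_{cell_type}.bed"
        with open(path, "w") as fh:
            for chrom, start, end in sorted(ivs):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        paths[cell_type] = path
    return paths


def cpgs_in_dhs(
    cpg_map: CpGMap, catalog: DHSCatalog, cell_types: Iterable[str]
) -> set[str]:
    """CpGs falling in a DHS of *any* of the listed cell types (union rule).

    A CpG with 1-based position ``p`` overlaps a 0-based half-open interval
    ``[start, end)`` when ``start <= p - 1 < end``.
    """
    cell_types = list(cell_types)
    unknown = set(cell_types) - set(catalog.intervals)
    if unknown:
        raise KeyError(f"cell types without DHS data: {sorted(unknown)}")
    hits: set[str] = set()
    chroms = cpg_map.data["chrom"].to_numpy()
    positions = cpg_map.data["pos"].to_numpy()
    for cpg, chrom, pos in zip(cpg_map.data.index, chroms, positions):
        pos0 = int(pos) - 1
        if any(catalog.covers(ct, chrom, pos0) for ct in cell_types):
            hits.add(cpg)
    return hits
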