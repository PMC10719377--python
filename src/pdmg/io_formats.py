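"""Readers and writers for every on-disk format the pipeline touches.

Counts travel as MatrixMarket coordinate-integer files with ``genes.tsv`` /
``samples.tsv`` sidecars (one identifier per line), or as dense TSV for small
bulk tables.  Spatial transcripts are a three-column CSV (``x,y,gene``),
segmentations are single-plane unsigned-integer TIFF label masks, gene-set
collections are GMT-like TSV, and consensus signatures are JSON.

All readers validate strictly and raise :class:`FormatError` naming the
offending record rather than silently coercing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile
import yaml

__all__ = [
    "FormatError",
    "CountMatrix",
    "SpatialTranscriptTable",
    "LabelMask",
    "GeneSet",
    "SignatureEntry",
    "ConsensusSignature",
    "read_count_matrix",
    "write_count_matrix",
    "read_spatial",
    "write_spatial",
    "read_mask",
    "write_mask",
    "read_gene_sets",
    "write_gene_sets",
    "read_signature",
    "write_signature",
    "read_config",
]


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen[i] = 1
    if dupes:
        raise FormatError(f"duplicate {what} identifiers: {sorted(set(dupes))[:10]}")


@dataclass
class CountMatrix:
    """Dense genes x columns matrix of non-negative integer counts.

    Columns are samples (bulk) or cells (single-nucleus).  ``column_meta``
    optionally carries per-column annotations (condition, donor, cell_type)
    indexed by column id.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    column_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.column_ids = list(self.column_ids)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                bad = np.argwhere(np.mod(self.values, 1) != 0)[0]
                raise FormatError(
                    f"fractional count at gene {self.gene_ids[bad[0]]}, "
                    f"column {self.column_ids[bad[1]]}"
                )
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[bad[0]]}, "
                f"column {self.column_ids[bad[1]]}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if self.column_meta is not None:
            missing = set(self.column_ids) - set(self.column_meta.index)
            if missing:
                raise FormatError(f"column_meta missing entries for {sorted(missing)[:10]}")
            self.column_meta = self.column_meta.loc[self.column_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(float)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return CountMatrix(self.values[rows], list(genes), self.column_ids, self.column_meta)

    def subset_columns(self, columns: Sequence[str]) -> "CountMatrix":
        idx = {c: i for i, c in enumerate(self.column_ids)}
        cols = [idx[c] for c in columns]
        meta = self.column_meta.loc[list(columns)] if self.column_meta is not None else None
        return CountMatrix(self.values[:, cols], self.gene_ids, list(columns), meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class SpatialTranscriptTable:
    """Detected transcripts as (x, y, gene) rows; coordinates in pixels.

    Pixel convention: 0-based, x rightward, y downward; a transcript at
    (x, y) falls in mask pixel (row floor(y), col floor(x)).
    """

    data: pd.DataFrame
    pixel_size_um: float = 0.138

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols[:3] != ["x", "y", "gene"]:
            raise FormatError(f"transcript table must have columns x,y,gene; got {cols}")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("non-finite transcript coordinate")
        if np.any(xy < 0):
            i = int(np.argwhere((xy < 0).any(axis=1))[0][0])
            raise FormatError(f"negative coordinate in transcript row {i}")
        gene = self.data["gene"]
        if gene.isna().any() or (gene.astype(str).str.len() == 0).any():
            raise FormatError("empty gene name in transcript table")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Series:
        return self.data["gene"]


@dataclass
class LabelMask:
    """Integer segmentation image: 0 = background, k > 0 = cell k."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise FormatError("label mask must be a single 2-D plane")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise FormatError("label mask must have an integer dtype")
        if np.any(self.grid < 0):
            raise FormatError("label mask contains negative labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        u = np.unique(self.grid)
        return u[u > 0]


@dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.members, f"gene-set '{self.name}' member")
        if not self.members:
            warnings.warn(f"gene set '{self.name}' is empty", stacklevel=2)


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    direction: int  # +1 up in disease, -1 down
    support: tuple[str, ...]  # subset of ("bulk", "sn")
    sets: tuple[str, ...]  # contributing gene-set names


@dataclass
class ConsensusSignature:
    """Directional gene list with per-gene modality support."""

    entries: list[SignatureEntry]
    alpha_used: float = 0.05
    provenance: dict = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        _check_unique(genes, "signature gene")
        for e in self.entries:
            if e.direction not in (+1, -1):
                raise FormatError(f"signature direction for {e.gene} must be +1 or -1")
            if not e.support:
                raise FormatError(f"signature entry {e.gene} has empty modality support")
            if not e.sets:
                raise FormatError(f"signature entry {e.gene} has no contributing set")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def directions(self) -> dict[str, int]:
        return {e.gene: e.direction for e in self.entries}


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(
    path: str | Path,
    format: str = "mtx",
    genes_path: str | Path | None = None,
    columns_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (+ id sidecars) or dense TSV.

    For ``format='mtx'`` the sidecars default to ``genes.tsv`` and
    ``samples.tsv`` next to the matrix file.  For ``format='tsv'`` the file is
    a dense table with gene ids in the first column and column ids in the
    header.  ``meta_path`` optionally points to a CSV of per-column metadata
    indexed by its first column.
    """
    path = Path(path)
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        columns_path = Path(columns_path) if columns_path else path.parent / "samples.tsv"
        gene_ids = genes_path.read_text().split()
        column_ids = columns_path.read_text().split()
        mat = scipy.io.mmread(path)
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if arr.shape != (len(gene_ids), len(column_ids)):
            raise FormatError(
                f"matrix shape {arr.shape} inconsistent with sidecars "
                f"({len(gene_ids)} genes, {len(column_ids)} columns)"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.mod(arr, 1) != 0
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise FormatError(f"fractional count in MTX at entry ({i + 1}, {j + 1})")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {gene_ids[i]} / column {column_ids[j]}"
            )
        values = arr
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        column_ids = [str(c) for c in df.columns]
        if len(set(gene_ids)) != len(gene_ids):
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene row ids in TSV: {dupes}")
        values = df.to_numpy()
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
    return CountMatrix(values, gene_ids, column_ids, meta)


def write_count_matrix(
    m: CountMatrix,
    path: str | Path,
    format: str = "mtx",
    genes_path: str | Path | None = None,
    columns_path: str | Path | None = None,
) -> None:
    """Write ``m`` so that :func:`read_count_matrix` reproduces it exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        columns_path = Path(columns_path) if columns_path else path.parent / "samples.tsv"
        genes_path.write_text("\n".join(m.gene_ids) + "\n")
        columns_path.write_text("\n".join(m.column_ids) + "\n")
        coo = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(str(path), coo, field="integer")
    elif format == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


# ---------------------------------------------------------------------------
# spatial


def read_spatial(path: str | Path, pixel_size_um: float = 0.138) -> SpatialTranscriptTable:
    df = pd.read_csv(path)
    if list(df.columns) != ["x", "y", "gene"]:
        raise FormatError(
            f"spatial CSV header must be exactly x,y,gene; got {list(df.columns)}"
        )
    df["gene"] = df["gene"].astype(str)
    return SpatialTranscriptTable(df, pixel_size_um=pixel_size_um)


def write_spatial(t: SpatialTranscriptTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    t.data[["x", "y", "gene"]].to_csv(path, index=False)


def read_mask(path: str | Path) -> LabelMask:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"label-mask TIFF must be single-plane; got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.unsignedinteger):
        raise FormatError(f"label-mask TIFF must be unsigned integer; got {arr.dtype}")
    # widen losslessly so downstream arithmetic cannot overflow
    return LabelMask(arr.astype(np.int64))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    hi = int(mask.grid.max(initial=0))
    if hi > np.iinfo(np.uint16).max:
        raise FormatError(f"mask label {hi} exceeds 16-bit range")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.grid.astype(np.uint16))


# ---------------------------------------------------------------------------
# gene sets / signatures / config


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT-like TSV: name <tab> description <tab> member genes..."""
    sets: list[GeneSet] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"gene-set line {ln} has fewer than 2 fields")
        name, desc, *members = parts
        members = [g for g in members if g]
        sets.append(GeneSet(name=name, description=desc, members=members))
    _check_unique([s.name for s in sets], "gene-set")
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join([s.name, s.description, *s.members]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature(path: str | Path) -> ConsensusSignature:
    obj = json.loads(Path(path).read_text())
    entries = [
        SignatureEntry(
            gene=e["gene"],
            direction=int(e["direction"]),
            support=tuple(e["support"]),
            sets=tuple(e["sets"]),
        )
        for e in obj["entries"]
    ]
    return ConsensusSignature(
        entries=entries,
        alpha_used=float(obj.get("alpha_used", 0.05)),
        provenance=obj.get("provenance", {}),
        conflicts=list(obj.get("conflicts", [])),
    )


def write_signature(sig: ConsensusSignature, path: str | Path) -> None:
    obj = {
        "entries": [
            {
                "gene": e.gene,
                "direction": e.direction,
                "support": list(e.support),
                "sets": list(e.sets),
            }
            for e in sig.entries
        ],
        "alpha_used": sig.alpha_used,
        "provenance": sig.provenance,
        "conflicts": sig.conflicts,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise FormatError("config YAML must be a mapping")
    return dict(cfg)
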