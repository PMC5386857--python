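"""Expression-matrix containers and delimited-text I/O.

The central object is :class:`ExpressionMatrix`: a gene × sample table of
non-negative abundances (raw fragment counts or FPKM) together with
per-sample metadata (species, tissue, batch, optional library size).
Everything downstream — the minimum-expression filter, the CV and
fold-change stability screens, the cross-batch concordance analytics —
consumes this container.

Files are plain delimited text: the matrix has gene ids in the first
column and one column per sample; the metadata table is long-format with
one row per sample. Only tab and comma dialects are accepted, and an
ambiguous header (containing both) is rejected rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNIT_COUNTS",
    "UNIT_FPKM",
    "SampleMeta",
    "ExpressionMatrix",
    "HomeologMap",
    "ExpressionIOError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "read_homeolog_map",
    "counts_to_fpkm",
    "average_homeologs",
]

UNIT_COUNTS = "COUNTS"
UNIT_FPKM = "FPKM"

#: metadata columns required in every sample table
_META_REQUIRED = ("sample_id", "species", "tissue", "batch")


class ExpressionIOError(ValueError):
    """Raised for malformed matrices, metadata, or homeolog maps."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq library / biological sample.

    ``batch`` identifies the biological replicate set (the study design is
    two transcriptome sets, T1 and T2, of four tissues each); ``library_size``
    is the number of assigned fragments and may be None for FPKM input.
    """

    sample_id: str
    species: str
    tissue: str
    batch: str
    library_size: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ExpressionIOError("sample_id must be non-empty")
        if not self.tissue or not self.batch:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: tissue and batch must be non-empty"
            )
        if self.library_size is not None and self.library_size < 0:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: negative library_size"
            )


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        Sample metadata in the same order as the columns of ``values``.
    unit
        Either ``"COUNTS"`` (raw fragment counts) or ``"FPKM"``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    unit: str = UNIT_FPKM

    def __post_init__(self) -> None:
        if self.unit not in (UNIT_COUNTS, UNIT_FPKM):
            raise ExpressionIOError(f"unknown unit {self.unit!r}")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ExpressionIOError(
                "sample metadata order does not match matrix columns: "
                f"{ids} vs {list(self.values.columns)}"
            )
        if len(set(ids)) != len(ids):
            raise ExpressionIOError("duplicate sample ids")
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise ExpressionIOError(f"duplicate gene ids: {', '.join(map(str, dup))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("non-numeric values in expression matrix")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ExpressionIOError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": [s.species for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "library_size": [s.library_size for s in self.samples],
            }
        ).set_index("sample_id")

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise ExpressionIOError(f"gene ids absent from matrix: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[gene_ids], list(self.samples), self.unit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        by_id = {s.sample_id: s for s in self.samples}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise ExpressionIOError(f"sample ids absent from matrix: {missing}")
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)],
            [by_id[s] for s in sample_ids],
            self.unit,
        )


@dataclass
class HomeologMap:
    """Pairs of duplicated gene copies (homeologs) in an allopolyploid.

    Each gene id may appear in at most one pair.
    """

    pairs: list[tuple[str, str]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            for g in (a, b):
                if g in seen:
                    raise ExpressionIOError(f"gene {g!r} appears in more than one pair")
                seen.add(g)
        if self.labels and len(self.labels) != len(self.pairs):
            raise ExpressionIOError("labels length must match pairs length")

    def __len__(self) -> int:
        return len(self.pairs)

    def gene_ids(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


# ---------------------------------------------------------------------------
# reading / writing


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    has_tab, has_comma = "\t" in header, "," in header
    if has_tab and has_comma:
        raise ExpressionIOError(
            f"{path}: header contains both tabs and commas; ambiguous delimiter"
        )
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise ExpressionIOError(f"{path}: could not detect a tab or comma delimiter")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a long-format sample metadata table (TSV or CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, comment="#")
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ExpressionIOError(f"{path}: missing metadata columns {missing}")
    metas = []
    for _, row in df.iterrows():
        libsize = None
        if "library_size" in df.columns and pd.notna(row["library_size"]):
            libsize = int(float(row["library_size"]))
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                species=row["species"],
                tissue=row["tissue"],
                batch=row["batch"],
                library_size=libsize,
            )
        )
    return metas


def read_expression_matrix(
    path: str | Path, meta_path: str | Path, unit: str = UNIT_FPKM
) -> ExpressionMatrix:
    """Read a gene × sample matrix plus its sample metadata.

    The first column of the matrix file holds gene ids; the header row holds
    sample ids. Every sample column must have a metadata row; extra metadata
    rows are ignored. Sample order follows the matrix file.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ExpressionIOError(f"{path}: duplicate gene ids: {', '.join(map(str, dup))}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ExpressionIOError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    metas = {m.sample_id: m for m in read_sample_metadata(meta_path)}
    missing = [c for c in df.columns if c not in metas]
    if missing:
        raise ExpressionIOError(f"{meta_path}: no metadata for sample columns {missing}")
    samples = [metas[c] for c in df.columns]
    return ExpressionMatrix(df.astype(float), samples, unit)


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    meta_path: str | Path | None = None,
    sep: str = "\t",
    float_format: str | None = None,
) -> None:
    """Write the matrix (and optionally its metadata) as delimited text."""
    m.values.to_csv(path, sep=sep, index_label="gene_id", float_format=float_format)
    if meta_path is not None:
        m.meta_frame().to_csv(meta_path, sep=sep)


def read_homeolog_map(path: str | Path) -> HomeologMap:
    """Read a two-column (plus optional label) homeolog pairing table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: homeolog map needs at least two columns")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    labels = list(df.iloc[:, 2]) if df.shape[1] > 2 else []
    return HomeologMap(pairs=pairs, labels=labels)


# ---------------------------------------------------------------------------
# transformations


def counts_to_fpkm(
    m: ExpressionMatrix,
    gene_lengths: Mapping[str, float],
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Convert raw fragment counts to FPKM.

    FPKM[g, s] = count[g, s] / (length_g / 1e3) / (libsize_s / 1e6).

    Library sizes come from, in order of preference: the ``library_sizes``
    argument, the per-sample metadata, or the matrix column sums.
    """
    if m.unit != UNIT_COUNTS:
        raise ExpressionIOError("counts_to_fpkm requires a COUNTS matrix")
    missing = [g for g in m.gene_ids if g not in gene_lengths]
    if missing:
        raise ExpressionIOError(f"missing gene lengths for: {missing[:5]}")
    lengths = np.array([float(gene_lengths[g]) for g in m.gene_ids])
    if (lengths <= 0).any():
        raise ExpressionIOError("gene lengths must be positive")

    libsizes = []
    for s in m.samples:
        if library_sizes is not None and s.sample_id in library_sizes:
            n = float(library_sizes[s.sample_id])
        elif s.library_size is not None:
            n = float(s.library_size)
        else:
            n = float(m.values[s.sample_id].sum())
        if n <= 0:
            raise ExpressionIOError(f"sample {s.sample_id!r}: zero library size")
        libsizes.append(n)

    fpkm = m.values.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (
        np.array(libsizes)[None, :] / 1e6
    )
    out = pd.DataFrame(fpkm, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, list(m.samples), UNIT_FPKM)


def average_homeologs(m: ExpressionMatrix, hmap: HomeologMap) -> ExpressionMatrix:
    """Collapse each homeolog pair to one row of per-sample arithmetic means.

    The merged row is named ``"A|B"`` after its members; unpaired genes pass
    through unchanged, keeping their original relative order.
    """
    absent = sorted(hmap.gene_ids() - set(m.gene_ids))
    if absent:
        raise ExpressionIOError(f"homeolog map ids absent from matrix: {absent}")
    if not hmap.pairs:
        return ExpressionMatrix(m.values.copy(), list(m.samples), m.unit)

    paired = hmap.gene_ids()
    rows: list[pd.Series] = []
    names: list[str] = []
    merged_emitted: set[str] = set()
    pair_of = {}
    for a, b in hmap.pairs:
        pair_of[a] = (a, b)
        pair_of[b] = (a, b)
    for g in m.gene_ids:
        if g in paired:
            a, b = pair_of[g]
            name = f"{a}|{b}"
            if name in merged_emitted:
                continue
            merged_emitted.add(name)
            rows.append((m.values.loc[a] + m.values.loc[b]) / 2.0)
            names.append(name)
        else:
            rows.append(m.values.loc[g])
            names.append(g)
    out = pd.DataFrame(rows, index=pd.Index(names, name=m.values.index.name))
    return ExpressionMatrix(out, list(m.samples), m.unit)
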