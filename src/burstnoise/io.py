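"""Readers, writers, and validated containers for the pipeline's external formats.

All genomic coordinates are zero-based, half-open internally. On-disk gene
annotations are 1-based inclusive and converted at the boundary (logged at
DEBUG). broadPeak files are already zero-based half-open and read as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "PeakSet",
    "TwoColorTable",
    "MidpointTrack",
    "GeneLabels",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_broadpeak",
    "write_broadpeak",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_two_color",
    "write_two_color",
    "read_midpoint_track",
    "write_midpoint_track",
    "read_gene_labels",
    "write_gene_labels",
]


class FormatError(ValueError):
    """A file does not conform to its declared schema."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with a cell -> group (embryo/passage) map.

    ``values`` is a DataFrame indexed by gene id with one column per cell, in
    RPKM-like (or fluorescence) arbitrary units. ``cell_group`` maps every
    cell id to its group label.
    """

    values: pd.DataFrame
    cell_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (v.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.cell_group = pd.Series(self.cell_group)
        missing = [c for c in v.columns if c not in self.cell_group.index]
        if missing:
            raise ValueError(f"cells without a group label: {missing[:5]}")
        self.cell_group = self.cell_group.loc[v.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.cell_group))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.cell_group)


@dataclass
class GeneAnnotation:
    """Per-gene chromosome, strand-aware TSS/TES, and strand.

    ``tss`` and ``tes`` are positions on the zero-based half-open axis; for a
    minus-strand gene tss > tes.
    """

    table: pd.DataFrame  # index gene_id; columns chrom, tss, tes, strand

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "tss", "tes", "strand"}
        if not required.issubset(t.columns):
            raise FormatError(f"annotation missing columns {required - set(t.columns)}")
        if not t.index.is_unique:
            raise ValueError("duplicate gene ids in annotation")
        if (t["tss"] == t["tes"]).any():
            bad = t.index[t["tss"] == t["tes"]].tolist()
            raise ValueError(f"tss == tes for genes {bad[:5]}")
        if (t[["tss", "tes"]].to_numpy() < 0).any():
            raise ValueError("negative coordinates in annotation")
        bad = ~t["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand for genes {t.index[bad][:5].tolist()}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakSet:
    """Intervals with signal values for one histone mark (zero-based half-open)."""

    table: pd.DataFrame  # columns chrom, start, end, signal

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "signal"}
        if not required.issubset(t.columns):
            raise FormatError(f"peak table missing columns {required - set(t.columns)}")
        if len(t) and (t["end"] <= t["start"]).any():
            raise ValueError("peak with end <= start")
        if len(t) and (t["signal"] < 0).any():
            raise ValueError("negative peak signal")
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.table)

    def index(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval index (built lazily, cached)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.table.groupby("chrom", sort=False):
                trees[chrom] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub["signal"])
                )
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, float]]:
        """Peaks overlapping [start, end) as (start, end, signal) tuples."""
        tree = self.index().get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in sorted(tree.overlap(start, end))]


@dataclass
class TwoColorTable:
    """Paired per-cell green/red fluorescence intensities."""

    table: pd.DataFrame  # columns cell, g, r, strain, reporter, replicate

    def __post_init__(self) -> None:
        required = {"cell", "g", "r", "strain", "reporter", "replicate"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"two-color table missing columns {required - set(self.table.columns)}")
        if self.table[["g", "r"]].isna().any().any():
            raise ValueError("missing fluorescence values")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def g(self) -> np.ndarray:
        return self.table["g"].to_numpy(float)

    @property
    def r(self) -> np.ndarray:
        return self.table["r"].to_numpy(float)


@dataclass
class MidpointTrack:
    """Per-gene MNase read-midpoint counts at offsets 1..W upstream of TSS."""

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for gid, x in self.counts.items():
            x = np.asarray(x)
            if x.size and ((x < 0).any() or not np.allclose(x, np.round(x))):
                raise ValueError(f"non-count values in midpoint track for {gid}")
            self.counts[gid] = x.astype(int)

    def __len__(self) -> int:
        return len(self.counts)

    def window(self, gene_id: str) -> int:
        return len(self.counts[gene_id])


@dataclass
class GeneLabels:
    """Boolean gene annotations (TATA, dosage sensitivity, ...) plus pathway sets.

    ``table`` is indexed by gene id with boolean columns ``tata``,
    ``dosage_sensitive``, ``essential``, ``complex_subunit`` and a ``pathways``
    column holding a frozenset of pathway names per gene. Genes absent from
    the table are simply unlabeled: analyses exclude them, never impute.
    """

    table: pd.DataFrame
    unmatched: list[str] = field(default_factory=list)

    BOOL_COLS = ("tata", "dosage_sensitive", "essential", "complex_subunit")

    def __post_init__(self) -> None:
        for col in self.BOOL_COLS:
            if col not in self.table.columns:
                raise FormatError(f"labels missing column {col!r}")
            if self.table[col].isna().any():
                raise ValueError(f"missing values in label column {col!r}")
        if "pathways" not in self.table.columns:
            self.table["pathways"] = [frozenset()] * len(self.table)

    def pathway_genes(self, pathway: str) -> list[str]:
        mask = self.table["pathways"].apply(lambda s: pathway in s)
        return self.table.index[mask].tolist()

    def match(self, gene_ids) -> "GeneLabels":
        """Restrict to ``gene_ids``; unmatched label rows are kept in the report."""
        known = self.table.index.intersection(gene_ids)
        unmatched = self.table.index.difference(gene_ids).tolist()
        if unmatched:
            logger.info("%d labeled genes not present in the dataset", len(unmatched))
        return GeneLabels(self.table.loc[known].copy(), unmatched=unmatched)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path, group_map_path) -> ExpressionMatrix:
    """Read a genes x cells TSV plus a cell -> group map TSV."""
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene_id", na_filter=False)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from exc
    gm = pd.read_csv(group_map_path, sep="\t", header=None, names=["cell_id", "group"])
    group = pd.Series(gm["group"].to_numpy(), index=gm["cell_id"])
    return ExpressionMatrix(df, group)


def write_expression_matrix(em: ExpressionMatrix, path, group_map_path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")
    em.cell_group.rename_axis("cell_id").to_csv(
        group_map_path, sep="\t", header=False
    )


# ---------------------------------------------------------------------------
# broadPeak


def read_broadpeak(path) -> PeakSet:
    """Read a BED6+3 broadPeak file; column 7 (signalValue) is the intensity."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: broadPeak needs >= 7 columns, got {len(fields)}"
                )
            rows.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[6]))
            )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])
    return PeakSet(table)


def write_broadpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for row in peaks.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t.\t{row.signal:g}\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a 1-based inclusive TSV (gene_id chrom start end strand).

    Coordinates are converted to the zero-based half-open axis; the TSS of a
    minus-strand gene is its larger coordinate.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    logger.debug("%s: converting 1-based inclusive coordinates to 0-based half-open", path)
    start0 = df["start"].to_numpy() - 1
    end0 = df["end"].to_numpy()
    plus = (df["strand"] == "+").to_numpy()
    tss = np.where(plus, start0, end0)
    tes = np.where(plus, end0, start0)
    table = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "tss": tss, "tes": tes,
         "strand": df["strand"].to_numpy()},
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    return GeneAnnotation(table)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    t = ann.table
    plus = (t["strand"] == "+").to_numpy()
    start0 = np.where(plus, t["tss"], t["tes"])
    end0 = np.where(plus, t["tes"], t["tss"])
    out = pd.DataFrame(
        {"gene_id": t.index, "chrom": t["chrom"].to_numpy(),
         "start": start0 + 1, "end": end0, "strand": t["strand"].to_numpy()}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# two-color FACS


def read_two_color(path) -> TwoColorTable:
    df = pd.read_csv(path)
    return TwoColorTable(df)


def write_two_color(tc: TwoColorTable, path) -> None:
    tc.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# midpoint track


def read_midpoint_track(path) -> MidpointTrack:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "offset", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    counts: dict[str, np.ndarray] = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        w = int(sub["offset"].max())
        x = np.zeros(w, dtype=int)
        x[sub["offset"].to_numpy() - 1] = sub["count"].to_numpy()
        counts[gid] = x
    return MidpointTrack(counts)


def write_midpoint_track(track: MidpointTrack, path) -> None:
    rows = []
    for gid, x in track.counts.items():
        for i, c in enumerate(x, 1):
            rows.append((gid, i, int(c)))
    pd.DataFrame(rows, columns=["gene_id", "offset", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene labels


def read_gene_labels(path) -> GeneLabels:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'gene_id'")
    df = df.set_index("gene_id")
    for col in GeneLabels.BOOL_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        df[col] = df[col].astype(bool)
    if "pathways" in df.columns:
        df["pathways"] = [
            frozenset(p for p in str(s).split(";") if p and p != "nan")
            for s in df["pathways"].fillna("")
        ]
    return GeneLabels(df)


def write_gene_labels(labels: GeneLabels, path) -> None:
    df = labels.table.copy()
    df["pathways"] = df["pathways"].apply(lambda s: ";".join(sorted(s)))
    for col in GeneLabels.BOOL_COLS:
        df[col] = df[col].astype(bool)
    df.to_csv(path, sep="\t", index_label="gene_id")
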