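"""Containers and file I/O for count matrices, gene annotation and sample metadata.

The pipeline's universal currency is an HTSeq-style gene-level count table:
non-negative integer counts, genes in rows, sample replicates in columns.
Gene-to-chromosome assignment comes from a tab-separated table or a GTF
subset (``gene`` features only).  Chromosome labels are compared after
stripping an optional ``chr`` prefix, so mixed annotation conventions mix
safely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


class ValidationError(ValueError):
    """An in-memory object violates a pipeline invariant."""


def normalize_chromosome(label: str) -> str:
    """Strip an optional ``chr``/``Chr`` prefix from a chromosome label."""
    label = str(label).strip()
    if label.lower().startswith("chr") and len(label) > 3:
        return label[3:]
    return label


# ---------------------------------------------------------------------------
# CountMatrix


def infer_sample_meta(samples) -> pd.DataFrame:
    """Derive a minimal sample-metadata table from ``<line>_r<k>`` sample ids.

    Samples without a recognizable replicate suffix become single-replicate
    lines named after the full sample id.
    """
    lines, reps = [], []
    for s in samples:
        if "_r" in s and s.rsplit("_r", 1)[1].isdigit():
            line, rep = s.rsplit("_r", 1)
            lines.append(line)
            reps.append(int(rep))
        else:
            lines.append(s)
            reps.append(1)
    return pd.DataFrame({"line": lines, "replicate": reps}, index=pd.Index(samples, name="sample"))


@dataclass
class CountMatrix:
    """Gene x sample read-count matrix plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids, columns =
        sample-replicate ids.
    sample_meta
        DataFrame indexed by sample id with at least a ``line`` column
        (cell-line identity shared by replicates).  Optional columns:
        ``replicate``, ``reported_sex``, ``cell_type``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.sample_meta is None:
            self.sample_meta = infer_sample_meta(self.counts.columns)
        _validate_counts_frame(self.counts)
        meta = self.sample_meta
        if "line" not in meta.columns:
            raise ValidationError("sample_meta must contain a 'line' column")
        missing = [s for s in self.counts.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"samples missing from sample_meta: {missing}")
        if meta["line"].isna().any():
            bad = meta.index[meta["line"].isna()].tolist()
            raise ValidationError(f"samples without a line id: {bad}")

    # -- basic views -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lines(self) -> list[str]:
        """Line ids in first-appearance order of their samples."""
        seen = dict.fromkeys(self.sample_meta.loc[self.samples, "line"])
        return list(seen)

    def totals(self) -> pd.Series:
        """Total (library) counts per sample."""
        return self.counts.sum(axis=0)

    def samples_of(self, line: str) -> list[str]:
        sel = self.sample_meta.loc[self.samples]
        out = [s for s in self.samples if sel.loc[s, "line"] == line]
        if not out:
            raise ValidationError(f"no samples for line {line!r}")
        return out

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples].copy(), self.sample_meta.loc[samples].copy())

    def subset_lines(self, lines) -> "CountMatrix":
        keep = [s for line in lines for s in self.samples_of(line)]
        return self.subset_samples(keep)


def _validate_counts_frame(df: pd.DataFrame, source: str = "count matrix") -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate gene ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate sample ids {dup}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]].tolist()
        raise ParseError(f"{source}: non-numeric cells in column(s) {bad}")
    if np.isnan(values.astype(float)).any():
        r, c = np.argwhere(np.isnan(values.astype(float)))[0]
        raise ParseError(f"{source}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{source}: negative count {df.iat[r, c]} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if np.any(values != np.floor(values)):
        r, c = np.argwhere(values != np.floor(values))[0]
        raise ValidationError(
            f"{source}: fractional count {df.iat[r, c]} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )


def read_counts(path, format: str = "tsv", sample_meta_path=None) -> CountMatrix:
    """Read a count matrix from ``tsv`` or ``mtx`` (MatrixMarket + sidecars).

    For MatrixMarket, row and column labels are read from ``<path>.rows`` and
    ``<path>.cols`` (one id per line).  If ``sample_meta_path`` is given it is
    read as a tab-separated table indexed by sample id; otherwise line ids are
    inferred from ``<line>_r<k>`` sample names.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:  # ragged rows etc. — keep line info
            raise ParseError(f"{path}: {exc}") from exc
        # object columns mean non-numeric cells somewhere: locate the first one
        for col in df.columns:
            if df[col].dtype == object:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                if len(bad):
                    line_no = df.index.get_loc(bad[0]) + 2  # header line is 1
                    raise ParseError(
                        f"{path}:{line_no}: non-numeric count {df.loc[bad[0], col]!r} "
                        f"at gene {bad[0]!r}, sample {col!r}"
                    )
                df[col] = coerced
    elif format == "mtx":
        from scipy import io as spio

        matrix = spio.mmread(path).toarray()
        rows = Path(f"{path}.rows").read_text().split()
        cols = Path(f"{path}.cols").read_text().split()
        df = pd.DataFrame(matrix, index=pd.Index(rows, name="gene_id"), columns=cols)
    else:
        raise ValueError(f"unknown count format {format!r}")
    _validate_counts_frame(df, source=str(path))
    meta = read_sample_meta(sample_meta_path) if sample_meta_path else None
    return CountMatrix(df.astype(np.int64), meta)


def write_counts(cm: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        from scipy import io as spio
        from scipy.sparse import csr_matrix

        spio.mmwrite(path, csr_matrix(cm.counts.to_numpy()))
        Path(f"{path}.rows").write_text("\n".join(cm.genes) + "\n")
        Path(f"{path}.cols").write_text("\n".join(cm.samples) + "\n")
    else:
        raise ValueError(f"unknown count format {format!r}")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "line" not in meta.columns:
        raise ParseError(f"{path}: sample metadata must have a 'line' column")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GeneAnnotation


@dataclass
class GeneAnnotation:
    """Gene -> chromosome assignment with optional coordinates and marker panels.

    ``chromosome`` maps gene id to a normalized chromosome label ("chr"
    prefixes stripped).  ``xist_gene`` names the XIST long non-coding RNA,
    required for X-inactivation analysis; ``marker_panels`` holds named gene
    lists (e.g. pluripotency, naive/primed markers) used for reporting.
    """

    chromosome: pd.Series
    coords: pd.DataFrame | None = None
    xist_gene: str | None = None
    marker_panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.chromosome = self.chromosome.map(normalize_chromosome)
        self.chromosome.index.name = "gene_id"
        if self.chromosome.index.has_duplicates:
            dup = self.chromosome.index[self.chromosome.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in annotation: {dup}")
        if self.xist_gene is None and "XIST" in self.chromosome.index:
            self.xist_gene = "XIST"
        if self.xist_gene is not None:
            if self.xist_gene not in self.chromosome.index:
                raise ValidationError(f"declared XIST gene {self.xist_gene!r} absent from annotation")
            if self.chromosome[self.xist_gene] != "X":
                raise ValidationError(
                    f"XIST gene {self.xist_gene!r} must lie on chromosome X, "
                    f"found {self.chromosome[self.xist_gene]!r}"
                )

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in first-appearance order."""
        return list(dict.fromkeys(self.chromosome))

    def genes_on(self, chromosome: str) -> pd.Index:
        chromosome = normalize_chromosome(chromosome)
        return self.chromosome.index[self.chromosome == chromosome]

    def x_genes(self, exclude_xist: bool = True) -> pd.Index:
        genes = self.genes_on("X")
        if exclude_xist and self.xist_gene is not None:
            genes = genes[genes != self.xist_gene]
        return genes

    def assigned(self, genes) -> pd.Index:
        """Genes from ``genes`` that carry a chromosome assignment."""
        return pd.Index(genes).intersection(self.chromosome.index)

    def unassigned(self, genes) -> pd.Index:
        return pd.Index(genes).difference(self.chromosome.index)

    def require_xist(self) -> str:
        if self.xist_gene is None:
            raise ValidationError("no XIST gene declared in annotation; pass xist_gene=")
        return self.xist_gene


def read_annotation(path, format: str = "tsv", xist_gene: str | None = None,
                    counts: CountMatrix | None = None) -> GeneAnnotation:
    """Read gene annotation from a TSV table or a GTF subset (gene features).

    TSV columns: ``gene_id``, ``chromosome`` and optional ``start``, ``end``,
    ``strand`` (1-based inclusive coordinates).  If ``counts`` is supplied the
    overlap of gene ids is checked; zero overlap is an error.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        for col in ("gene_id", "chromosome"):
            if col not in df.columns:
                raise ParseError(f"{path}: annotation is missing column {col!r}")
        chrom = pd.Series(df["chromosome"].to_numpy(), index=pd.Index(df["gene_id"], name="gene_id"))
        coords = None
        if {"start", "end"}.issubset(df.columns):
            coords = df.set_index("gene_id")[[c for c in ("start", "end", "strand") if c in df.columns]]
    elif format == "gtf":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        ids, chroms, rows = [], [], []
        for feat in db.features_of_type("gene", order_by="start"):
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            ids.append(gid)
            chroms.append(feat.seqid)
            rows.append((feat.start, feat.end, feat.strand))
        if not ids:
            raise ParseError(f"{path}: no gene features found in GTF")
        chrom = pd.Series(chroms, index=pd.Index(ids, name="gene_id"))
        coords = pd.DataFrame(rows, index=chrom.index, columns=["start", "end", "strand"])
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    ann = GeneAnnotation(chrom, coords=coords, xist_gene=xist_gene)
    if counts is not None and len(ann.assigned(counts.genes)) == 0:
        raise ValidationError(f"{path}: no gene ids shared between annotation and count matrix")
    return ann


def write_annotation(ann: GeneAnnotation, path) -> None:
    df = pd.DataFrame({"chromosome": ann.chromosome})
    if ann.coords is not None:
        df = df.join(ann.coords)
    df.to_csv(path, sep="\t", index_label="gene_id")
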