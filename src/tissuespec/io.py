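"""Reading, writing and aggregating multi-tissue FPKM expression data.

The on-disk formats are deliberately plain: a gene x sample FPKM matrix as
TSV (header row of sample ids, first column of gene ids), a sample metadata
TSV mapping each sample to a tissue (and optionally a donor), and a gene
annotation as an Ensembl-style GTF or a BED6 file. In memory the matrix and
the tissue-level profile are ordinary :class:`pandas.DataFrame` objects
(genes as rows), metadata is a DataFrame indexed by sample id, and gene
annotations are :class:`GeneAnnotation` records with 0-based half-open
coordinates regardless of the input dialect.

Expression values are FPKM (fragments per kilobase of exon model per million
mapped reads), a length- and depth-normalised abundance where 1 FPKM roughly
corresponds to one transcript per average cell. Replicate samples of the same
tissue are aggregated to tissue-level profiles by the arithmetic mean of
their FPKM values; the median is available as an explicit option but is
never the default.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__

#: biotypes recognised as long non-coding RNA. Ensembl dialects that split
#: lncRNA into lincRNA/antisense/... must extend this set explicitly; silent
#: aliasing would change downstream counts.
DEFAULT_LNCRNA_ALIASES = frozenset({"lncRNA"})

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
OTHER = "other"


class ExpressionIOError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: interval (0-based half-open), strand and biotype.

    ``exons``, when present, are the union of the gene's transcript exons,
    sorted and non-overlapping, each within ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = OTHER
    symbol: str = ""
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ExpressionIOError(
                f"gene {self.gene_id}: empty interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ExpressionIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.exons is not None:
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end):
                    raise ExpressionIOError(
                        f"gene {self.gene_id}: exon [{s}, {e}) outside gene body"
                    )
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
                if s2 < e1:
                    raise ExpressionIOError(
                        f"gene {self.gene_id}: overlapping exons after sorting"
                    )

    @property
    def length(self) -> int:
        return self.end - self.start

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (empty if <2 exons or no exon data)."""
        if not self.exons or len(self.exons) < 2:
            return ()
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


def _header_comment(config_hash: str | None = None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# tissuespec v{__version__}{tag}\n"


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample FPKM matrix from TSV.

    The first column holds gene ids, the header row sample ids. Row and
    column order are preserved. Duplicate ids, negative, non-numeric or
    missing cells are rejected with the offending row/column named.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionIOError(f"{path}: empty FPKM matrix")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ExpressionIOError(f"{path}: duplicate gene id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ExpressionIOError(f"{path}: duplicate sample id {dup!r}")
    try:
        matrix = raw.astype(float)
    except ValueError:
        matrix = raw.apply(pd.to_numeric, errors="coerce")
        bad = matrix.isna() & raw.notna()
        r, c = _first_true_cell(bad)
        raise ExpressionIOError(
            f"{path}: non-numeric cell at gene {r!r}, sample {c!r}"
        ) from None
    _validate_matrix(matrix, str(path))
    matrix.index.name = "gene_id"
    return matrix


def _first_true_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    r, c = stacked[stacked].index[0]
    return str(r), str(c)


def _validate_matrix(matrix: pd.DataFrame, label: str) -> None:
    values = matrix.to_numpy()
    if np.isnan(values).any():
        r, c = _first_true_cell(matrix.isna())
        raise ExpressionIOError(f"{label}: missing cell at gene {r!r}, sample {c!r}")
    if not np.isfinite(values).all():
        r, c = _first_true_cell(~np.isfinite(matrix))
        raise ExpressionIOError(f"{label}: non-finite cell at gene {r!r}, sample {c!r}")
    if (values < 0).any():
        r, c = _first_true_cell(matrix < 0)
        raise ExpressionIOError(f"{label}: negative FPKM at gene {r!r}, sample {c!r}")


def write_fpkm_tsv(
    matrix: pd.DataFrame, path: str | Path, config_hash: str | None = None
) -> None:
    """Write a matrix TSV with a commented provenance header line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config_hash))
        out = matrix.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, tissue[, individual].

    Tissue names are normalised by whitespace trimming and case folding only
    (exact matching; no synonym dictionary).
    """
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "tissue"):
        if col not in meta.columns:
            raise ExpressionIOError(f"{path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ExpressionIOError(f"{path}: duplicate sample_id {dup!r}")
    meta["tissue"] = meta["tissue"].astype(str).str.strip().str.casefold()
    if (meta["tissue"] == "").any() or meta["tissue"].isna().any():
        raise ExpressionIOError(f"{path}: empty tissue name")
    if "individual" not in meta.columns:
        meta["individual"] = ""
    meta = meta[["sample_id", "tissue", "individual"]].set_index("sample_id")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment())
        meta.reset_index().to_csv(fh, sep="\t", index=False, lineterminator="\n")


def aggregate_by_tissue(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    statistic: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Collapse replicate samples to a gene x tissue profile.

    Per gene and tissue the value is the arithmetic mean (optionally the
    median) of the tissue's sample FPKMs. Tissues are ordered by first
    appearance in the metadata. Samples absent from the metadata are an
    error listing the offending ids.
    """
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ExpressionIOError(f"samples without metadata: {missing}")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    tissue_of = meta["tissue"]
    tissue_order = list(dict.fromkeys(tissue_of.loc[list(meta.index)]))
    tissue_order = [
        t for t in tissue_order if t in set(tissue_of.loc[list(matrix.columns)])
    ]
    cols = {}
    for tissue in tissue_order:
        samples = [s for s in matrix.columns if tissue_of[s] == tissue]
        block = matrix[samples]
        cols[tissue] = block.mean(axis=1) if statistic == "mean" else block.median(axis=1)
    profile = pd.DataFrame(cols, index=matrix.index)
    profile.index.name = "gene_id"
    profile.columns.name = "tissue"
    return profile


def log2_pseudocount(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform; the +1 pseudocount keeps zeros at zero."""
    if (matrix.to_numpy() < 0).any():
        raise ExpressionIOError("negative values in matrix")
    return np.log2(matrix + 1.0)


def sample_correlation(
    matrix: pd.DataFrame,
    a: str,
    b: str,
    method: Literal["spearman"] = "spearman",
) -> float:
    """Spearman rank correlation between two sample columns.

    Ties receive average ranks. A constant column has no defined rank
    correlation; NaN is returned (flagged, never silently 0).
    """
    if method != "spearman":
        raise ValueError(f"unsupported method {method!r}")
    for sid in (a, b):
        if sid not in matrix.columns:
            raise KeyError(f"unknown sample id {sid!r}")
    if matrix.shape[0] < 3:
        raise ExpressionIOError("need at least 3 genes for a correlation")
    x = matrix[a].to_numpy()
    y = matrix[b].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlation of samples on log2(x+1) values.

    Symmetric with unit diagonal. Constant columns yield NaN rows/columns.
    """
    if matrix.shape[0] < 3:
        raise ExpressionIOError("need at least 3 genes for correlations")
    log = log2_pseudocount(matrix)
    corr = log.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Gene annotation (GTF / BED6)
# ---------------------------------------------------------------------------


def read_gene_annotation(
    path: str | Path,
    dialect: Literal["gtf", "bed6"],
    lncrna_aliases: frozenset[str] = DEFAULT_LNCRNA_ALIASES,
) -> list[GeneAnnotation]:
    """Read gene annotations from GTF (1-based inclusive) or BED6 (0-based).

    All intervals are stored 0-based half-open. For GTF, the biotype comes
    from the ``gene_biotype`` attribute: ``protein_coding`` maps to itself,
    members of ``lncrna_aliases`` map to lncRNA, everything else to "other".
    Exon records are merged per gene into a union of non-overlapping
    intervals. BED6 carries no biotype; an optional seventh column supplies
    one, otherwise genes are biotype "other".
    """
    if dialect == "gtf":
        return _read_gtf(Path(path), lncrna_aliases)
    if dialect == "bed6":
        return _read_bed6(Path(path), lncrna_aliases)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _map_biotype(raw: str, lncrna_aliases: frozenset[str]) -> str:
    if raw == PROTEIN_CODING:
        return PROTEIN_CODING
    if raw in lncrna_aliases:
        return LNCRNA
    return OTHER


def _read_gtf(path: Path, lncrna_aliases: frozenset[str]) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        # GTF is 1-based inclusive; internal is 0-based half-open
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))
    genes: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ExpressionIOError(f"{path}: gene feature without gene_id")
        raw_biotype = gene.attributes.get("gene_biotype", [OTHER])[0]
        symbol = gene.attributes.get("gene_name", [""])[0]
        exons = merge_intervals(exons_by_gene.get(gid, []))
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                biotype=_map_biotype(raw_biotype, lncrna_aliases),
                symbol=symbol,
                exons=exons if exons else None,
            )
        )
    return genes


def _read_bed6(path: Path, lncrna_aliases: frozenset[str]) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ExpressionIOError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            biotype = fields[6] if len(fields) > 6 else OTHER
            genes.append(
                GeneAnnotation(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    biotype=_map_biotype(biotype, lncrna_aliases),
                )
            )
    return genes


def write_gtf(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write gene (and exon) features as Ensembl-style GTF (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment())
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol or g.gene_id}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\ttissuespec\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons or ():
                fh.write(
                    f"{g.chrom}\ttissuespec\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent half-open intervals into a union."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_tf_list(path: str | Path) -> frozenset[str]:
    """Read a transcription-factor gene list, one id per line."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )
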