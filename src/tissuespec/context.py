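"""Genomic context of lncRNAs: nearest coding neighbor, orientation, clusters.

For every long non-coding RNA gene this module finds the nearest
protein-coding gene on the same chromosome (gap distance between gene
bodies, 0 for overlap, capped at 1 Mb by default) and classifies the
mutual orientation of the pair:

* overlapping, opposite strands — genic antisense, split into *exonic*
  (the lncRNA intersects an exon of the neighbor) and *intronic* (it lies
  entirely between exons); without exon data the call is flagged
  unresolved rather than guessed;
* overlapping, same strand — genic sense overlap;
* disjoint, same strand — intergenic sense;
* disjoint, opposite strands — *divergent* when the two gap-adjacent gene
  ends are both 5' ends (transcription pointing away from the shared
  region, compatible with a shared bidirectional promoter), *convergent*
  when both are 3' ends.

The neighbor's expression category and transcription-factor status are
attached so that lncRNAs flanking tissue-elevated coding genes can be
counted. A simple window chain finds chromosomal clusters of elevated
genes ("hot spots").
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import Category, ELEVATED_CATEGORIES
from .io import GeneAnnotation, LNCRNA, PROTEIN_CODING

DEFAULT_NEIGHBOR_CAP = 1_000_000  # base pairs, exclusive


class Relation(str, enum.Enum):
    GENIC_INTRONIC_ANTISENSE = "genic_intronic_antisense"
    GENIC_EXONIC_ANTISENSE = "genic_exonic_antisense"
    GENIC_SENSE_OVERLAP = "genic_sense_overlap"
    GENIC_ANTISENSE_UNRESOLVED = "genic_antisense_unresolved"
    INTERGENIC_SENSE = "intergenic_sense"
    INTERGENIC_ANTISENSE_DIVERGENT = "intergenic_antisense_divergent"
    INTERGENIC_ANTISENSE_CONVERGENT = "intergenic_antisense_convergent"
    NO_NEIGHBOR_WITHIN_CAP = "no_neighbor_within_cap"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class NeighborReport:
    lncrna_id: str
    neighbor_id: str | None
    distance: int | None
    relation: Relation
    neighbor_category: Category | None
    neighbor_is_tf: bool


def gap_distance(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Base pairs between two gene bodies under half-open arithmetic; 0 if overlapping."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def _overlap_length(a: GeneAnnotation, b: GeneAnnotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def nearest_coding_neighbor(
    lnc: GeneAnnotation,
    genes: Sequence[GeneAnnotation],
    cap: int = DEFAULT_NEIGHBOR_CAP,
) -> tuple[GeneAnnotation, int] | None:
    """Nearest protein-coding gene on the lncRNA's chromosome, within the cap.

    Distance is the gap between gene bodies (0 for overlap). Among
    overlapping candidates the largest overlap wins; remaining ties go to
    the smaller start coordinate, then the lexicographically smaller id.
    The cap is exclusive: a neighbor exactly ``cap`` away is rejected.
    """
    if lnc.biotype != LNCRNA:
        raise ValueError(f"{lnc.gene_id} is not an lncRNA (biotype {lnc.biotype})")
    if not genes:
        raise ValueError("empty annotation set")
    candidates = [
        g for g in genes if g.biotype == PROTEIN_CODING and g.chrom == lnc.chrom
    ]
    if not candidates:
        return None
    best = min(
        candidates,
        key=lambda g: (
            gap_distance(lnc, g),
            -_overlap_length(lnc, g),
            g.start,
            g.gene_id,
        ),
    )
    d = gap_distance(lnc, best)
    if d >= cap:
        return None
    return best, d


def classify_relation(lnc: GeneAnnotation, neighbor: GeneAnnotation) -> Relation:
    """Orientation relation between an lncRNA and a coding gene (same chromosome)."""
    if lnc.chrom != neighbor.chrom:
        raise ValueError(
            f"{lnc.gene_id} and {neighbor.gene_id} lie on different chromosomes"
        )
    overlapping = _overlap_length(lnc, neighbor) > 0
    same_strand = lnc.strand == neighbor.strand
    if overlapping:
        if same_strand:
            return Relation.GENIC_SENSE_OVERLAP
        if not neighbor.exons:
            return Relation.GENIC_ANTISENSE_UNRESOLVED
        hits_exon = any(
            min(lnc.end, e) > max(lnc.start, s) for s, e in neighbor.exons
        )
        if hits_exon:
            return Relation.GENIC_EXONIC_ANTISENSE
        return Relation.GENIC_INTRONIC_ANTISENSE
    if same_strand:
        return Relation.INTERGENIC_SENSE
    # disjoint, opposite strands: inspect the two gap-adjacent gene ends.
    # The end abutting the gap is the 5' end when transcription points away
    # from the gap; with opposite strands both gap ends are 5' (divergent)
    # or both 3' (convergent).
    lnc_is_left = lnc.end <= neighbor.start
    if lnc_is_left:
        lnc_gap_end_is_5prime = lnc.strand == "-"
        nbr_gap_end_is_5prime = neighbor.strand == "+"
    else:
        lnc_gap_end_is_5prime = lnc.strand == "+"
        nbr_gap_end_is_5prime = neighbor.strand == "-"
    if lnc_gap_end_is_5prime and nbr_gap_end_is_5prime:
        return Relation.INTERGENIC_ANTISENSE_DIVERGENT
    return Relation.INTERGENIC_ANTISENSE_CONVERGENT


def annotate_neighbors(
    lncs: Sequence[GeneAnnotation],
    genes: Sequence[GeneAnnotation],
    classifications: Mapping[str, Category] | pd.DataFrame | None = None,
    tf_list: Iterable[str] = (),
    cap: int = DEFAULT_NEIGHBOR_CAP,
) -> tuple[list[NeighborReport], dict]:
    """Build one neighbor report per lncRNA plus an aggregate summary.

    ``classifications`` maps coding gene ids to their expression category
    (a mapping or a classify_matrix frame); genes without a classification
    get category None. The summary counts relations, neighbor categories,
    neighbors elevated in the target tissue (enriched, highly enriched,
    group enriched or enhanced) and transcription-factor neighbors.
    """
    if isinstance(classifications, pd.DataFrame):
        cat_of = {g: Category(c) for g, c in classifications["category"].items()}
    else:
        cat_of = {g: Category(c) for g, c in (classifications or {}).items()}
    tf_set = frozenset(tf_list)
    coding = [g for g in genes if g.biotype == PROTEIN_CODING]
    reports: list[NeighborReport] = []
    for lnc in lncs:
        hit = nearest_coding_neighbor(lnc, coding, cap=cap) if coding else None
        if hit is None:
            reports.append(
                NeighborReport(
                    lncrna_id=lnc.gene_id,
                    neighbor_id=None,
                    distance=None,
                    relation=Relation.NO_NEIGHBOR_WITHIN_CAP,
                    neighbor_category=None,
                    neighbor_is_tf=False,
                )
            )
            continue
        neighbor, d = hit
        reports.append(
            NeighborReport(
                lncrna_id=lnc.gene_id,
                neighbor_id=neighbor.gene_id,
                distance=d,
                relation=classify_relation(lnc, neighbor),
                neighbor_category=cat_of.get(neighbor.gene_id),
                neighbor_is_tf=neighbor.gene_id in tf_set,
            )
        )
    n = len(reports)
    relation_counts = Counter(r.relation.value for r in reports)
    category_counts = Counter(
        r.neighbor_category.value if r.neighbor_category else "none" for r in reports
    )
    n_elevated = sum(
        1
        for r in reports
        if r.neighbor_category is not None
        and r.neighbor_category in ELEVATED_CATEGORIES
    )
    summary = {
        "n_lncrnas": n,
        "relation_counts": dict(relation_counts),
        "neighbor_category_counts": dict(category_counts),
        "n_elevated_neighbors": n_elevated,
        "elevated_neighbor_fraction": (n_elevated / n) if n else 0.0,
        "n_tf_neighbors": sum(r.neighbor_is_tf for r in reports),
    }
    return reports, summary


@dataclass(frozen=True)
class GeneCluster:
    chrom: str
    start: int
    end: int
    members: tuple[str, ...]

    @property
    def span(self) -> int:
        return self.end - self.start


def find_gene_clusters(
    genes: Sequence[GeneAnnotation],
    classifications: Mapping[str, Category] | pd.DataFrame,
    window: int,
    min_elevated: int = 3,
) -> list[GeneCluster]:
    """Chromosomal runs of elevated genes (coding or not) within a window.

    Elevated genes on a chromosome are sorted by start; consecutive genes at
    most ``window`` bp apart (gap between gene bodies, overlap counts as 0)
    extend the current run. Maximal runs with at least ``min_elevated``
    members are reported with their genomic span.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(classifications, pd.DataFrame):
        cat_of = {g: Category(c) for g, c in classifications["category"].items()}
    else:
        cat_of = {g: Category(c) for g, c in classifications.items()}
    elevated = [
        g for g in genes if cat_of.get(g.gene_id) in ELEVATED_CATEGORIES
    ]
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in elevated:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, members in sorted(by_chrom.items()):
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        run: list[GeneAnnotation] = []
        run_end = None
        for g in members:
            if run and g.start - run_end <= window:
                run.append(g)
                run_end = max(run_end, g.end)
            else:
                if len(run) >= min_elevated:
                    clusters.append(_make_cluster(chrom, run))
                run = [g]
                run_end = g.end
        if len(run) >= min_elevated:
            clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, run: Sequence[GeneAnnotation]) -> GeneCluster:
    return GeneCluster(
        chrom=chrom,
        start=min(g.start for g in run),
        end=max(g.end for g in run),
        members=tuple(g.gene_id for g in run),
    )


def write_neighbors_tsv(reports: Sequence[NeighborReport], path,
                        config_hash: str | None = None) -> None:
    from .io import _header_comment

    frame = pd.DataFrame(
        {
            "lncrna_id": [r.lncrna_id for r in reports],
            "neighbor_id": [r.neighbor_id or "" for r in reports],
            "distance_bp": [r.distance if r.distance is not None else "" for r in reports],
            "relation": [r.relation.value for r in reports],
            "neighbor_category": [
                r.neighbor_category.value if r.neighbor_category else "" for r in reports
            ],
            "neighbor_is_tf": [r.neighbor_is_tf for r in reports],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config_hash))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_cluster_bed(clusters: Sequence[GeneCluster], path) -> None:
    """BED: chrom, span start/end, cluster name, member count, strand '.'."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, c in enumerate(clusters, 1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i}\t{len(c.members)}\t.\n"
            )
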