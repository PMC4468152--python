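"""Synthetic FPKM matrices and genome annotations with planted ground truth.

The generator emulates the statistical shape of a 27-tissue bulk RNA-seq
body atlas: one target tissue (frontal cortex by default) with three
biological replicates, 26 peripheral tissues with one to six replicates
each (~95 samples in total), heavy-tailed non-negative FPKM values, and
multiplicative lognormal replicate noise. Every gene is constructed to
belong to a known expression category, and every synthetic lncRNA is
placed on a chromosome so as to realise a known orientation relation to a
coding gene — so classifier and neighbor analyses can be scored against
the planted truth without any external data.

Planted tissue-mean constructions (defaults, detection threshold 1 FPKM,
high threshold 10, fold rules 5x/50x):

* not_detected — all tissues uniform in [0, 0.5);
* expressed_all_low — all tissues uniform in [2, 8];
* expressed_all_high — all tissues uniform in [20, 60];
* mixed — target plus half the tissues uniform in [3, 7], the rest in
  [0.1, 0.5]: detected in many but not all tissues, elevated nowhere;
* enriched / highly_enriched — lognormal baseline elsewhere, target set
  to fold_low (10x) resp. fold_high (100x) the maximum baseline;
* group_enriched — a random group of 2-7 tissues including the target
  jointly raised to fold_low x the maximum outside baseline;
* enhanced — seven "blocker" tissues uniform in [8, 12], the rest in
  [0.2, 0.5], target 3x the top blocker: ~7.5-8.7-fold above the grand
  mean, yet below 5x the top blocker (so not enriched) and unable to form
  any passing group of <=7 tissues (the blockers guard every group size).

Fold margins are at least ~1.5x the rule thresholds in either direction,
so classification survives lognormal replicate noise up to sigma ~0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, ClassificationConfig
from .context import Relation
from .io import GeneAnnotation, LNCRNA, PROTEIN_CODING

#: the 27 organ and tissue types of the emulated body atlas
DEFAULT_TISSUES: tuple[str, ...] = (
    "frontal cortex",
    "testis",
    "bone marrow",
    "kidney",
    "liver",
    "esophagus",
    "skin",
    "heart",
    "adrenal gland",
    "adipose tissue",
    "endometrium",
    "ovary",
    "pancreas",
    "thyroid gland",
    "prostate",
    "salivary gland",
    "stomach",
    "colon",
    "small intestine",
    "duodenum",
    "placenta",
    "spleen",
    "lymph node",
    "appendix",
    "lung",
    "gall bladder",
    "urinary bladder",
)

#: planted category mix for a 2,000-gene default simulation, proportioned
#: after a whole-body atlas: ~30% undetected, ~31% detected everywhere at
#: low level, ~14% everywhere high, ~17% mixed, ~6% enhanced and ~3%
#: enriched in the target tissue.
DEFAULT_CATEGORY_COUNTS: dict[Category, int] = {
    Category.NOT_DETECTED: 600,
    Category.EXPRESSED_ALL_LOW: 620,
    Category.EXPRESSED_ALL_HIGH: 270,
    Category.MIXED: 345,
    Category.ENHANCED: 110,
    Category.GROUP_ENRICHED: 24,
    Category.ENRICHED: 29,
    Category.HIGHLY_ENRICHED: 2,
}


@dataclass(frozen=True)
class SimulationDesign:
    """Conditions of a synthetic multi-tissue expression study."""

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    target_tissue: str = "frontal cortex"
    category_counts: Mapping[Category, int] | None = None
    replicates_per_tissue: Mapping[str, int] | None = None  # None: target 3, others 1-6
    fold_low: float = 10.0
    fold_high: float = 100.0
    baseline_log_mean: float = math.log(2.0)
    baseline_log_sd: float = 0.5
    noise_sigma: float = 0.2
    seed: int = 0
    classification: ClassificationConfig | None = None

    def resolved_counts(self) -> dict[Category, int]:
        counts = dict(self.category_counts or DEFAULT_CATEGORY_COUNTS)
        if any(v < 0 for v in counts.values()):
            raise ValueError("category counts must be >= 0")
        return counts

    def resolved_config(self) -> ClassificationConfig:
        return self.classification or ClassificationConfig(
            target_tissue=self.target_tissue
        )

    def __post_init__(self) -> None:
        if self.target_tissue not in self.tissues:
            raise ValueError("target tissue must be among the tissues")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("duplicate tissue names")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        cfg = self.resolved_config()
        if self.fold_low <= cfg.enrichment_fold:
            raise ValueError("fold_low must exceed the enrichment fold")
        if self.fold_high <= cfg.high_enrichment_fold:
            raise ValueError("fold_high must exceed the high enrichment fold")
        if len(self.tissues) < cfg.group_size_max + 2:
            raise ValueError("too few tissues for the group-size range")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside synthetic data."""

    categories: dict[str, Category] = field(default_factory=dict)
    groups: dict[str, frozenset[str]] = field(default_factory=dict)
    relations: dict[str, Relation] = field(default_factory=dict)
    neighbors: dict[str, str | None] = field(default_factory=dict)


def _planted_means(
    design: SimulationDesign,
    category: Category,
    rng: np.random.Generator,
) -> tuple[np.ndarray, frozenset[str] | None]:
    """Tissue means for one gene of the given planted category."""
    cfg = design.resolved_config()
    tissues = design.tissues
    n = len(tissues)
    t_idx = tissues.index(design.target_tissue)
    other_idx = [i for i in range(n) if i != t_idx]
    det = cfg.detection_threshold
    high = cfg.high_expression_threshold
    means = np.empty(n)

    if category is Category.NOT_DETECTED:
        # half the threshold keeps replicate noise from crossing detection
        means[:] = rng.uniform(0.0, 0.5 * det, size=n)
        return means, None
    if category is Category.EXPRESSED_ALL_LOW:
        means[:] = rng.uniform(2.0 * det, 0.8 * high, size=n)
        return means, None
    if category is Category.EXPRESSED_ALL_HIGH:
        means[:] = rng.uniform(2.0 * high, 6.0 * high, size=n)
        return means, None
    if category is Category.MIXED:
        means[:] = rng.uniform(0.1 * det, 0.5 * det, size=n)
        n_on = (n - 1) // 2
        on = rng.choice(other_idx, size=n_on, replace=False)
        means[on] = rng.uniform(3.0 * det, 7.0 * det, size=n_on)
        means[t_idx] = rng.uniform(3.0 * det, 7.0 * det)
        return means, None
    if category in (Category.ENRICHED, Category.HIGHLY_ENRICHED):
        baseline = rng.lognormal(
            design.baseline_log_mean, design.baseline_log_sd, size=n - 1
        )
        fold = design.fold_low if category is Category.ENRICHED else design.fold_high
        means[other_idx] = baseline
        means[t_idx] = fold * baseline.max()
        return means, None
    if category is Category.GROUP_ENRICHED:
        k = int(rng.integers(cfg.group_size_min, cfg.group_size_max + 1))
        partners = rng.choice(other_idx, size=k - 1, replace=False)
        group_idx = [t_idx, *partners.tolist()]
        outside_idx = [i for i in range(n) if i not in set(group_idx)]
        baseline = rng.lognormal(
            design.baseline_log_mean, design.baseline_log_sd, size=len(outside_idx)
        )
        means[outside_idx] = baseline
        means[group_idx] = design.fold_low * baseline.max()
        return means, frozenset(tissues[i] for i in group_idx)
    if category is Category.ENHANCED:
        n_blockers = cfg.group_size_max
        blockers = rng.choice(other_idx, size=n_blockers, replace=False)
        means[:] = rng.uniform(0.2 * det, 0.5 * det, size=n)
        means[blockers] = rng.uniform(0.8 * high, 1.2 * high, size=n_blockers)
        means[t_idx] = 3.0 * means[blockers].max()
        return means, None
    raise ValueError(f"cannot plant category {category}")


def _replicate_counts(
    design: SimulationDesign, rng: np.random.Generator
) -> dict[str, int]:
    if design.replicates_per_tissue is not None:
        counts = dict(design.replicates_per_tissue)
        for t in design.tissues:
            if counts.get(t, 0) < 1:
                raise ValueError(f"tissue {t!r} needs at least one replicate")
        return counts
    counts = {
        t: int(rng.integers(1, 7)) for t in design.tissues if t != design.target_tissue
    }
    counts[design.target_tissue] = 3
    return counts


def simulate_matrix(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate (FPKM matrix, sample metadata, planted truth).

    Replicate values are tissue mean x exp(N(0, noise_sigma^2)); with
    noise_sigma=0 and one replicate per tissue the matrix equals the
    planted means exactly. Output is bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    counts = design.resolved_counts()
    rep_counts = _replicate_counts(design, rng)
    tissues = design.tissues

    sample_ids: list[str] = []
    sample_tissue: list[str] = []
    for t in tissues:
        slug = t.replace(" ", "_")
        for r in range(1, rep_counts[t] + 1):
            sample_ids.append(f"{slug}-{r}")
            sample_tissue.append(t)

    truth = PlantedTruth()
    gene_ids: list[str] = []
    mean_rows: list[np.ndarray] = []
    i = 0
    for category in Category:  # deterministic order
        for _ in range(counts.get(category, 0)):
            i += 1
            gid = f"SYN{i:06d}"
            means, group = _planted_means(design, category, rng)
            gene_ids.append(gid)
            mean_rows.append(means)
            truth.categories[gid] = category
            if group is not None:
                truth.groups[gid] = group
    means = (
        np.vstack(mean_rows) if mean_rows else np.empty((0, len(tissues)))
    )

    tissue_index = {t: j for j, t in enumerate(tissues)}
    col_of_sample = np.array([tissue_index[t] for t in sample_tissue])
    values = means[:, col_of_sample]
    if design.noise_sigma > 0:
        noise = rng.normal(0.0, design.noise_sigma, size=values.shape)
        values = values * np.exp(noise)

    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    matrix.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": sample_tissue,
            "individual": [f"donor-{j + 1}" for j in range(len(sample_ids))],
        }
    ).set_index("sample_id")
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Genome annotation with planted lncRNA-neighbor relations
# ---------------------------------------------------------------------------

_GENE_SPACING = 2_500_000  # start-to-start distance between coding genes
_MIN_GENE_LEN = 10_000
_MAX_GENE_LEN = 50_000


def _make_exons(start: int, end: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """2-5 equal-width exons separated by introns of the same width."""
    n_exons = int(rng.integers(2, 6))
    w = (end - start) // (2 * n_exons)
    return tuple(
        (start + 2 * j * w, start + 2 * j * w + w) for j in range(n_exons)
    )


def simulate_annotation(
    n_coding: int,
    n_lnc: int | None = None,
    relation_mix: Mapping[Relation, int] | None = None,
    chrom_length: int | None = None,
    seed: int = 0,
    cap: int = 1_000_000,
) -> tuple[list[GeneAnnotation], PlantedTruth]:
    """Coding genes plus lncRNAs placed to realise planted orientation relations.

    Coding genes (2-5 exons each) sit on "chr1" at 2.5 Mb spacing so each
    lncRNA, placed within ~200 kb of its assigned host gene, has that gene
    as unambiguous nearest coding neighbor. Planted
    ``no_neighbor_within_cap`` lncRNAs get their own gene-free chromosome.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    relation_mix = dict(relation_mix or {})
    if any(v < 0 for v in relation_mix.values()):
        raise ValueError("relation counts must be >= 0")
    wanted = sum(relation_mix.values())
    if n_lnc is None:
        n_lnc = wanted
    if wanted > n_lnc:
        raise ValueError("relation_mix requests more lncRNAs than n_lnc")
    hosted = [
        (rel, cnt)
        for rel, cnt in relation_mix.items()
        if rel is not Relation.NO_NEIGHBOR_WITHIN_CAP
    ]
    n_hosted = sum(cnt for _, cnt in hosted) + (n_lnc - wanted)
    if n_hosted > n_coding:
        raise ValueError(
            f"infeasible packing: {n_hosted} hosted lncRNAs need {n_hosted} "
            f"distinct coding genes, have {n_coding}"
        )
    needed_length = (n_coding + 1) * _GENE_SPACING
    if chrom_length is None:
        chrom_length = needed_length
    elif chrom_length < needed_length:
        raise ValueError(
            f"infeasible packing: {n_coding} coding genes need a chromosome of "
            f">= {needed_length} bp"
        )

    genes: list[GeneAnnotation] = []
    for i in range(n_coding):
        length = int(rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1))
        start = (i + 1) * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"CODING{i + 1:05d}",
                chrom="chr1",
                start=start,
                end=start + length,
                strand=strand,
                biotype=PROTEIN_CODING,
                exons=_make_exons(start, start + length, rng),
            )
        )

    truth = PlantedTruth()
    lncs: list[GeneAnnotation] = []
    host_iter = iter(genes)
    orphan_chrom = 0
    plan: list[Relation] = []
    for rel, cnt in sorted(relation_mix.items(), key=lambda rc: rc[0].value):
        plan.extend([rel] * cnt)
    plan.extend([Relation.INTERGENIC_SENSE] * (n_lnc - wanted))

    for j, rel in enumerate(plan, 1):
        lid = f"LNC{j:05d}"
        if rel is Relation.NO_NEIGHBOR_WITHIN_CAP:
            orphan_chrom += 1
            start = int(rng.integers(10_000, 100_000))
            length = int(rng.integers(1_000, 10_000))
            lncs.append(
                GeneAnnotation(
                    lid, f"chrU{orphan_chrom}", start, start + length,
                    "+" if rng.random() < 0.5 else "-", LNCRNA,
                )
            )
            truth.relations[lid] = rel
            truth.neighbors[lid] = None
            continue
        host = next(host_iter)
        lnc = _place_lnc(lid, rel, host, rng, cap)
        lncs.append(lnc)
        truth.relations[lid] = rel
        truth.neighbors[lid] = host.gene_id
    return genes + lncs, truth


def _opposite(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_lnc(
    lid: str,
    rel: Relation,
    host: GeneAnnotation,
    rng: np.random.Generator,
    cap: int,
) -> GeneAnnotation:
    length = int(rng.integers(1_000, 10_000))
    exons = host.exons or ()
    if rel is Relation.GENIC_INTRONIC_ANTISENSE:
        intron = host.introns()[0]
        width = intron[1] - intron[0]
        s = intron[0] + width // 4
        e = min(intron[1] - width // 4, s + length)
        return GeneAnnotation(lid, host.chrom, s, max(e, s + 10), _opposite(host.strand), LNCRNA)
    if rel is Relation.GENIC_EXONIC_ANTISENSE:
        ex = exons[1]
        s = (ex[0] + ex[1]) // 2
        e = min(host.end, s + length)
        return GeneAnnotation(lid, host.chrom, s, max(e, s + 10), _opposite(host.strand), LNCRNA)
    if rel is Relation.GENIC_SENSE_OVERLAP:
        s = host.start + host.length // 4
        e = min(host.end, s + length)
        return GeneAnnotation(lid, host.chrom, s, max(e, s + 10), host.strand, LNCRNA)

    gap = int(rng.integers(2_000, min(cap // 5, 200_000)))
    if rel is Relation.INTERGENIC_SENSE:
        side = "right" if rng.random() < 0.5 else "left"
        strand = host.strand
    elif rel is Relation.INTERGENIC_ANTISENSE_DIVERGENT:
        # both gap-adjacent ends must be 5' ends
        side = "left" if host.strand == "+" else "right"
        strand = _opposite(host.strand)
    elif rel is Relation.INTERGENIC_ANTISENSE_CONVERGENT:
        # both gap-adjacent ends must be 3' ends
        side = "right" if host.strand == "+" else "left"
        strand = _opposite(host.strand)
    else:  # pragma: no cover - exhaustive
        raise ValueError(f"cannot place relation {rel}")
    if side == "left":
        e = host.start - gap
        s = e - length
    else:
        s = host.end + gap
        e = s + length
    return GeneAnnotation(lid, host.chrom, s, e, strand, LNCRNA)


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    """Persist planted truth as TSV (gene_id, kind, value columns)."""
    rows = []
    for gid, cat in truth.categories.items():
        rows.append((gid, "category", cat.value))
    for gid, group in truth.groups.items():
        rows.append((gid, "group", ";".join(sorted(group))))
    for lid, rel in truth.relations.items():
        rows.append((lid, "relation", rel.value))
    for lid, nbr in truth.neighbors.items():
        rows.append((lid, "neighbor", nbr or ""))
    pd.DataFrame(rows, columns=["gene_id", "kind", "value"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
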