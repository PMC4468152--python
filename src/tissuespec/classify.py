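"""Eight-category tissue-specificity classification of expression profiles.

Every gene is assigned exactly one category relative to a target tissue,
based on its mean FPKM across tissues:

* ``highly_enriched`` — target >= 50x the highest other tissue
* ``enriched`` — target >= 5x the highest other tissue
* ``group_enriched`` — mean FPKM of a group of 2-7 tissues including the
  target is >= 5x the highest tissue outside the group
* ``enhanced`` — target >= 5x the mean FPKM over all tissues
* ``expressed_all_high`` — detected everywhere, all tissues >= 10 FPKM
* ``expressed_all_low`` — detected (>= 1 FPKM) in every tissue
* ``not_detected`` — below 1 FPKM in every tissue
* ``mixed`` — everything else (detected in some tissues, elevated nowhere)

Rules are evaluated in that precedence order, making the categories
mutually exclusive and exhaustive: a 50-fold gene also passes the 5-fold
test but is reported only as highly enriched, and an enriched gene is
never double-counted as enhanced. All fold comparisons use >=. The
elevated rules additionally require the gene to be detected (>= the
detection threshold) in the target tissue: "not detected" dominates.

The group-enrichment search is exact despite only inspecting prefixes of
the FPKM-sorted tissue list: for fixed group size k the top-k tissues
simultaneously maximise the group mean and minimise the maximum outside
the group, so if the top-k prefix fails no other k-subset can succeed.
:func:`brute_force_group_oracle` enumerates all subsets and exists to
verify this equivalence independently.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Category(str, enum.Enum):
    """Mutually exclusive expression categories, in precedence order."""

    HIGHLY_ENRICHED = "highly_enriched"
    ENRICHED = "enriched"
    GROUP_ENRICHED = "group_enriched"
    ENHANCED = "enhanced"
    EXPRESSED_ALL_HIGH = "expressed_all_high"
    EXPRESSED_ALL_LOW = "expressed_all_low"
    NOT_DETECTED = "not_detected"
    MIXED = "mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: categories counting as "elevated" in the target tissue
ELEVATED_CATEGORIES = frozenset(
    {
        Category.ENHANCED,
        Category.GROUP_ENRICHED,
        Category.ENRICHED,
        Category.HIGHLY_ENRICHED,
    }
)

#: cap on tissue count for the exhaustive subset oracle
ORACLE_MAX_TISSUES = 12


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the classification scheme.

    detection_threshold
        FPKM below which a gene counts as not detected in a tissue (1 FPKM,
        roughly one transcript per average cell).
    high_expression_threshold
        FPKM above which expression counts as high (10 FPKM).
    enrichment_fold / high_enrichment_fold
        fold ratios for enriched (5x) and highly enriched (50x).
    group_size_min / group_size_max
        allowed sizes of the enriched tissue group (2-7).
    enhanced_denominator
        mean over ``all_tissues`` (default, includes the target) or over
        ``other_tissues`` only.
    """

    target_tissue: str
    detection_threshold: float = 1.0
    high_expression_threshold: float = 10.0
    enrichment_fold: float = 5.0
    high_enrichment_fold: float = 50.0
    group_size_min: int = 2
    group_size_max: int = 7
    enhanced_denominator: str = "all_tissues"

    def __post_init__(self) -> None:
        if not (0 < self.detection_threshold <= self.high_expression_threshold):
            raise ValueError("need 0 < detection_threshold <= high_expression_threshold")
        if not (1 < self.enrichment_fold < self.high_enrichment_fold):
            raise ValueError("need 1 < enrichment_fold < high_enrichment_fold")
        if not (2 <= self.group_size_min <= self.group_size_max):
            raise ValueError("need 2 <= group_size_min <= group_size_max")
        if self.enhanced_denominator not in ("all_tissues", "other_tissues"):
            raise ValueError(f"bad enhanced_denominator {self.enhanced_denominator!r}")


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    category: Category
    target_fpkm: float
    max_other_fpkm: float
    fold_vs_max_other: float  # may be math.inf (max other = 0) or NaN (0/0)
    fold_vs_mean: float
    enriched_group: frozenset[str] = frozenset()
    target_in_group: bool = False


def _as_dict(row: Mapping[str, float]) -> dict[str, float]:
    """Normalise a profile row (dict or pandas Series) to tissue -> FPKM."""
    if isinstance(row, pd.Series):
        return {str(t): float(v) for t, v in row.items()}
    return {str(t): float(v) for t, v in dict(row).items()}


def _check_row(row: Mapping[str, float], config: ClassificationConfig) -> None:
    if config.target_tissue not in row:
        raise KeyError(
            f"target tissue {config.target_tissue!r} absent from profile "
            f"(tissues: {sorted(row)})"
        )
    if len(row) < config.group_size_max + 1:
        raise ValueError(
            f"need at least group_size_max+1 = {config.group_size_max + 1} tissues, "
            f"got {len(row)}"
        )


def _passing_group(
    members: Sequence[float], outside_max: float, fold: float
) -> bool:
    mean = float(np.mean(members))
    if mean <= 0:
        return False
    return outside_max == 0 or mean >= fold * outside_max


def find_enriched_group(
    row: Mapping[str, float], config: ClassificationConfig
) -> frozenset[str] | None:
    """Smallest tissue group whose mean is >= fold x the max outside it.

    Only prefixes of the tissues sorted by descending FPKM (ties broken by
    tissue name) need checking; for each size k the top-k prefix dominates
    every other k-subset in both the group mean and the outside maximum.
    Returns the winning prefix as a set, or None.
    """
    row = _as_dict(row)
    _check_row(row, config)
    ranked = sorted(row, key=lambda t: (-row[t], t))
    values = [row[t] for t in ranked]
    for k in range(config.group_size_min, config.group_size_max + 1):
        if k >= len(ranked):
            break
        outside_max = max(values[k:])
        if _passing_group(values[:k], outside_max, config.enrichment_fold):
            return frozenset(ranked[:k])
    return None


def brute_force_group_oracle(
    row: Mapping[str, float], config: ClassificationConfig
) -> frozenset[str] | None:
    """Exhaustive reference for the group search (small tissue counts only).

    Enumerates every subset of allowed size and returns a smallest
    satisfying one, preferring larger summed FPKM then lexicographically
    smaller tissue tuples among equals.
    """
    row = _as_dict(row)
    _check_row(row, config)
    if len(row) > ORACLE_MAX_TISSUES:
        raise ValueError(f"oracle capped at {ORACLE_MAX_TISSUES} tissues")
    tissues = sorted(row)
    for k in range(config.group_size_min, config.group_size_max + 1):
        if k >= len(tissues):
            break
        winners = []
        for combo in itertools.combinations(tissues, k):
            inside = set(combo)
            outside_max = max(row[t] for t in tissues if t not in inside)
            if _passing_group([row[t] for t in combo], outside_max, config.enrichment_fold):
                winners.append(combo)
        if winners:
            # tie-break: highest summed FPKM, then lexicographically smallest
            best = min(winners, key=lambda c: (-sum(row[t] for t in c), c))
            return frozenset(best)
    return None


def classify_gene(
    row: Mapping[str, float], config: ClassificationConfig
) -> GeneClassification:
    """Assign one category to a single gene's tissue profile."""
    gene_id = str(row.name) if isinstance(row, pd.Series) and row.name else ""
    row = _as_dict(row)
    _check_row(row, config)
    target = float(row[config.target_tissue])
    others = {t: float(v) for t, v in row.items() if t != config.target_tissue}
    all_values = np.array([target, *others.values()])
    max_other = max(others.values())
    detected = target >= config.detection_threshold

    if max_other > 0:
        fold_vs_max_other = target / max_other
    elif target > 0:
        fold_vs_max_other = math.inf
    else:
        fold_vs_max_other = math.nan

    if config.enhanced_denominator == "all_tissues":
        denom_mean = float(all_values.mean())
    else:
        denom_mean = float(np.mean(list(others.values())))
    fold_vs_mean = target / denom_mean if denom_mean > 0 else math.nan

    def result(category: Category, group: frozenset[str] = frozenset(),
               in_group: bool = False) -> GeneClassification:
        return GeneClassification(
            gene_id=gene_id,
            category=category,
            target_fpkm=target,
            max_other_fpkm=max_other,
            fold_vs_max_other=fold_vs_max_other,
            fold_vs_mean=fold_vs_mean,
            enriched_group=group,
            target_in_group=in_group,
        )

    ratio_passes = (
        lambda fold: max_other == 0 or target >= fold * max_other
    )
    if detected and target > 0:
        if ratio_passes(config.high_enrichment_fold):
            return result(Category.HIGHLY_ENRICHED)
        if ratio_passes(config.enrichment_fold):
            return result(Category.ENRICHED)
        group = find_enriched_group(row, config)
        if group is not None:
            in_group = config.target_tissue in group
            if in_group:
                return result(Category.GROUP_ENRICHED, group=group, in_group=True)
            # valid group excluding the target: fall through, keep diagnostics
        if denom_mean > 0 and target >= config.enrichment_fold * denom_mean:
            return result(Category.ENHANCED)

    if (all_values >= config.high_expression_threshold).all():
        return result(Category.EXPRESSED_ALL_HIGH)
    if (all_values >= config.detection_threshold).all():
        return result(Category.EXPRESSED_ALL_LOW)
    if (all_values < config.detection_threshold).all():
        return result(Category.NOT_DETECTED)
    return result(Category.MIXED)


def classify_matrix(
    profile: pd.DataFrame, config: ClassificationConfig
) -> pd.DataFrame:
    """Classify every gene of a tissue profile.

    Returns a DataFrame indexed by gene id with columns category,
    target_fpkm, max_other_fpkm, fold_vs_max_other, fold_vs_mean,
    enriched_group (frozenset) and target_in_group. Deterministic and
    independent of gene order.
    """
    records = []
    for gene_id, row in profile.iterrows():
        c = classify_gene(row, config)
        records.append(
            {
                "gene_id": gene_id,
                "category": c.category,
                "target_fpkm": c.target_fpkm,
                "max_other_fpkm": c.max_other_fpkm,
                "fold_vs_max_other": c.fold_vs_max_other,
                "fold_vs_mean": c.fold_vs_mean,
                "enriched_group": c.enriched_group,
                "target_in_group": c.target_in_group,
            }
        )
    columns = [
        "gene_id",
        "category",
        "target_fpkm",
        "max_other_fpkm",
        "fold_vs_max_other",
        "fold_vs_mean",
        "enriched_group",
        "target_in_group",
    ]
    frame = pd.DataFrame(records, columns=columns)
    return frame.set_index("gene_id")


def summarize_categories(
    classifications: pd.DataFrame,
    profile: pd.DataFrame,
    config: ClassificationConfig,
) -> dict:
    """Per-category gene counts, gene fractions and mRNA mass fractions.

    The mass fraction of a category is the share of summed target-tissue
    FPKM carried by its genes — i.e. the fraction of the tissue's mRNA
    molecules attributable to that category. If the target tissue has zero
    total FPKM, mass fractions are undefined and flagged None.
    """
    missing = profile.index.difference(classifications.index)
    if len(missing):
        raise ValueError(f"classifications missing for genes: {list(missing)[:5]}")
    n = len(profile)
    target = profile[config.target_tissue]
    total_mass = float(target.sum())
    counts = {c.value: 0 for c in Category}
    mass = {c.value: 0.0 for c in Category}
    cats = classifications.loc[profile.index, "category"]
    for gene_id, cat in cats.items():
        key = Category(cat).value
        counts[key] += 1
        mass[key] += float(target.loc[gene_id])
    summary = {
        "n_genes": n,
        "target_tissue": config.target_tissue,
        "counts": counts,
        "gene_fraction": {k: (v / n if n else 0.0) for k, v in counts.items()},
        "mass_fraction": (
            {k: v / total_mass for k, v in mass.items()} if total_mass > 0 else None
        ),
        "mass_fraction_defined": total_mass > 0,
        "n_expressed_in_target": int(
            (target >= config.detection_threshold).sum()
        ),
        "n_elevated": int(
            sum(counts[c.value] for c in ELEVATED_CATEGORIES)
        ),
    }
    return summary


def elevated_set(classifications: pd.DataFrame) -> set[str]:
    """Genes elevated in the target tissue (enhanced or any enriched flavour)."""
    mask = classifications["category"].map(
        lambda c: Category(c) in ELEVATED_CATEGORIES
    )
    return set(classifications.index[mask])


def write_classifications_tsv(
    classifications: pd.DataFrame, path, config_hash: str | None = None
) -> None:
    """Per-gene classification TSV; the enriched group is semicolon-joined."""
    from .io import _header_comment

    out = classifications.copy()
    out["category"] = out["category"].map(lambda c: Category(c).value)
    out["enriched_group"] = out["enriched_group"].map(
        lambda g: ";".join(sorted(g)) if g else ""
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(config_hash))
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_classifications_tsv(path) -> pd.DataFrame:
    """Read a classification TSV back into classify_matrix's frame layout."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame["category"] = frame["category"].map(Category)
    frame["enriched_group"] = frame["enriched_group"].map(
        lambda g: frozenset(str(g).split(";")) if isinstance(g, str) and g else frozenset()
    )
    return frame
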