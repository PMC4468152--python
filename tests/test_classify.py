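"""Eight-category classification, group search and summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissuespec import (
    Category,
    ClassificationConfig,
    ELEVATED_CATEGORIES,
    brute_force_group_oracle,
    classify_gene,
    classify_matrix,
    elevated_set,
    find_enriched_group,
    summarize_categories,
)
from tissuespec.classify import read_classifications_tsv, write_classifications_tsv

from conftest import atlas_row, make_profile


class TestClassifyGene:
    def test_brain_enriched_against_heart(self, brain_config):
        """A gene at 49 FPKM in brain and 8 in heart is enriched (49 >= 5x8)."""
        row = atlas_row(49.0, {"heart": 8.0}, fill=1.0)
        c = classify_gene(row, brain_config)
        assert c.category is Category.ENRICHED
        assert c.fold_vs_max_other == pytest.approx(49 / 8)

    def test_all_zero_is_not_detected(self, brain_config):
        c = classify_gene(atlas_row(0.0, fill=0.0), brain_config)
        assert c.category is Category.NOT_DETECTED
        assert math.isnan(c.fold_vs_max_other)

    def test_uniform_high_expression(self, brain_config):
        c = classify_gene(atlas_row(15.0, fill=15.0), brain_config)
        assert c.category is Category.EXPRESSED_ALL_HIGH

    def test_uniform_low_expression(self, brain_config):
        c = classify_gene(atlas_row(2.0, fill=2.0), brain_config)
        assert c.category is Category.EXPRESSED_ALL_LOW

    def test_group_beats_enhanced_in_precedence(self):
        """A=100,B=30,C=D=2: not enriched (100 < 5x30) but {A,B} is a group."""
        cfg = ClassificationConfig(target_tissue="A", group_size_min=2, group_size_max=2)
        c = classify_gene({"A": 100.0, "B": 30.0, "C": 2.0, "D": 2.0}, cfg)
        assert c.category is Category.GROUP_ENRICHED
        assert c.enriched_group == frozenset({"A", "B"})
        assert c.target_in_group

    def test_enriched_with_fold_eight(self):
        cfg = ClassificationConfig(target_tissue="A", group_size_min=2, group_size_max=2)
        c = classify_gene({"A": 12.0, "B": 1.5, "C": 1.5, "D": 1.5}, cfg)
        assert c.category is Category.ENRICHED
        assert c.fold_vs_max_other == pytest.approx(8.0)

    def test_fifty_fold_is_highly_enriched(self, brain_config):
        c = classify_gene(atlas_row(60.0, fill=1.0), brain_config)
        assert c.category is Category.HIGHLY_ENRICHED

    def test_sole_expression_gives_infinite_fold(self, brain_config):
        c = classify_gene(atlas_row(3.0, fill=0.0), brain_config)
        assert c.category is Category.HIGHLY_ENRICHED
        assert math.isinf(c.fold_vs_max_other)

    def test_detection_dominates_ratio_rules(self, brain_config):
        """Below 1 FPKM everywhere stays not_detected despite a huge ratio."""
        c = classify_gene(atlas_row(0.9, fill=0.001), brain_config)
        assert c.category is Category.NOT_DETECTED

    def _enhanced_row(self) -> dict[str, float]:
        # 7 tissues at 10 FPKM block both the enriched rule (30 < 5x10) and
        # every 2-7 group (each group's outside max stays 10), yet the grand
        # mean (30+70+19*0.3)/27 ~ 3.91 leaves the 5x enhanced rule passing.
        row = atlas_row(30.0, {f"blocker{j}": 10.0 for j in range(7)}, fill=0.3)
        return row

    def test_enhanced_over_grand_mean(self, brain_config):
        c = classify_gene(self._enhanced_row(), brain_config)
        assert c.category is Category.ENHANCED

    def test_enhanced_denominator_variants(self):
        row = self._enhanced_row()
        incl = classify_gene(
            row, ClassificationConfig(target_tissue="brain",
                                      enhanced_denominator="all_tissues")
        )
        excl = classify_gene(
            row, ClassificationConfig(target_tissue="brain",
                                      enhanced_denominator="other_tissues")
        )
        assert incl.fold_vs_mean == pytest.approx(30 / ((30 + 70 + 19 * 0.3) / 27))
        assert excl.fold_vs_mean == pytest.approx(30 / ((70 + 19 * 0.3) / 26))

    def test_detected_in_some_tissues_is_mixed(self, brain_config):
        row = atlas_row(2.0, {"liver": 3.0, "lung": 0.2}, fill=2.0)
        row["tissue00"] = 0.1
        c = classify_gene(row, brain_config)
        assert c.category is Category.MIXED

    def test_target_missing_rejected(self, brain_config):
        with pytest.raises(KeyError, match="brain"):
            classify_gene({f"t{i}": 1.0 for i in range(10)}, brain_config)

    def test_too_few_tissues_rejected(self, brain_config):
        with pytest.raises(ValueError, match="tissues"):
            classify_gene({"brain": 5.0, "liver": 1.0}, brain_config)


class TestGroupSearch:
    def test_constant_vector_has_no_group(self, brain_config):
        assert find_enriched_group(atlas_row(5.0, fill=5.0), brain_config) is None

    def test_smallest_sufficient_prefix_wins(self, brain_config):
        """50,40,30 over a floor of 5: the pair fails (45 < 5x30), the triple passes."""
        row = atlas_row(50.0, {"a": 40.0, "b": 30.0}, fill=5.0)
        group = find_enriched_group(row, brain_config)
        assert group == frozenset({"brain", "a", "b"})

    def test_smooth_decay_has_no_group(self, brain_config):
        values = {f"t{i:02d}": 10.0 - 0.25 * i for i in range(27)}
        cfg = ClassificationConfig(target_tissue="t00")
        assert find_enriched_group(values, cfg) is None
        small = {f"t{i}": 10.0 - i for i in range(9)}
        cfg_small = ClassificationConfig(target_tissue="t0")
        assert brute_force_group_oracle(small, cfg_small) is None

    def test_oracle_enumerates_the_pair(self):
        cfg = ClassificationConfig(target_tissue="A", group_size_min=2, group_size_max=2)
        row = {"A": 100.0, "B": 30.0, "C": 2.0, "D": 2.0}
        assert brute_force_group_oracle(row, cfg) == frozenset({"A", "B"})

    def test_oracle_rejects_large_profiles(self, brain_config):
        with pytest.raises(ValueError, match="capped"):
            brute_force_group_oracle(atlas_row(1.0, fill=1.0), brain_config)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(
        values=st.lists(
            st.floats(0.0, 1000.0, allow_nan=False), min_size=4, max_size=10
        ),
        gmin=st.integers(2, 3),
        gmax=st.integers(3, 7),
    )
    def test_prefix_search_matches_exhaustive_oracle(self, values, gmin, gmax):
        """The sorted-prefix search agrees with subset enumeration."""
        gmax = min(gmax, len(values) - 1)
        if gmin > gmax:
            return
        row = {f"t{i:02d}": v for i, v in enumerate(values)}
        cfg = ClassificationConfig(
            target_tissue="t00", group_size_min=gmin, group_size_max=gmax
        )
        fast = find_enriched_group(row, cfg)
        slow = brute_force_group_oracle(row, cfg)
        assert (fast is None) == (slow is None)
        if fast is not None:
            assert len(fast) == len(slow)
            members = [row[t] for t in fast]
            outside = [row[t] for t in row if t not in fast]
            assert np.mean(members) >= cfg.enrichment_fold * max(outside) or max(outside) == 0


class TestMatrixAndSummary:
    def test_composition_of_single_gene_examples(self, brain_config):
        profile = make_profile(
            {
                "necab1": atlas_row(49.0, {"heart": 8.0}, fill=1.0),
                "silent": atlas_row(0.0, {"heart": 0.0}, fill=0.0),
                "ubiquitous": atlas_row(15.0, {"heart": 15.0}, fill=15.0),
            }
        )
        result = classify_matrix(profile, brain_config)
        assert result.loc["necab1", "category"] is Category.ENRICHED
        assert result.loc["silent", "category"] is Category.NOT_DETECTED
        assert result.loc["ubiquitous", "category"] is Category.EXPRESSED_ALL_HIGH

    def test_empty_profile_gives_empty_frame(self, brain_config):
        profile = make_profile({}).reindex(columns=list(atlas_row(1.0)))
        assert len(classify_matrix(profile, brain_config)) == 0

    def test_gene_order_invariance(self, brain_config):
        rng = np.random.default_rng(3)
        profile = make_profile(
            {
                f"g{i}": atlas_row(
                    float(rng.lognormal(2, 1.5)),
                    {f"o{j}": float(rng.lognormal(0, 1.5)) for j in range(26)},
                )
                for i in range(30)
            }
        )
        forward = classify_matrix(profile, brain_config)
        backward = classify_matrix(profile.iloc[::-1], brain_config)
        assert (forward["category"] == backward["category"].reindex(forward.index)).all()

    def test_partition_and_mass_conservation(self, brain_config):
        rng = np.random.default_rng(7)
        profile = make_profile(
            {
                f"g{i}": atlas_row(
                    float(rng.lognormal(1, 2)),
                    {f"o{j}": float(rng.lognormal(0, 2)) for j in range(26)},
                )
                for i in range(120)
            }
        )
        result = classify_matrix(profile, brain_config)
        summary = summarize_categories(result, profile, brain_config)
        assert sum(summary["counts"].values()) == 120
        assert sum(summary["gene_fraction"].values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(summary["mass_fraction"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_mass_fraction_hand_example(self):
        cfg = ClassificationConfig(target_tissue="brain")
        profile = make_profile(
            {
                "e": atlas_row(30.0, fill=1.0),  # enriched, 30 FPKM in target
                "h": atlas_row(70.0, fill=70.0),  # expressed everywhere, 70 FPKM
            }
        )
        result = classify_matrix(profile, cfg)
        summary = summarize_categories(result, profile, cfg)
        assert summary["mass_fraction"]["enriched"] == pytest.approx(0.30)

    def test_zero_target_mass_flagged(self, brain_config):
        profile = make_profile({"g": atlas_row(0.0, fill=0.0)})
        result = classify_matrix(profile, brain_config)
        summary = summarize_categories(result, profile, brain_config)
        assert summary["mass_fraction"] is None
        assert not summary["mass_fraction_defined"]

    def test_elevated_set_cardinality(self):
        """21 highly + 302 enriched + 248 group + 542 enhanced = 1,113 elevated."""
        labels = (
            [Category.HIGHLY_ENRICHED] * 21
            + [Category.ENRICHED] * 302
            + [Category.GROUP_ENRICHED] * 248
            + [Category.ENHANCED] * 542
            + [Category.MIXED] * 100
        )
        frame = pd.DataFrame(
            {"category": labels}, index=[f"g{i}" for i in range(len(labels))]
        )
        elevated = elevated_set(frame)
        assert len(elevated) == 1113
        assert elevated_set(frame.loc[sorted(elevated)]) == elevated  # idempotent

    def test_classification_tsv_round_trip(self, tmp_path, brain_config):
        profile = make_profile(
            {
                "g1": atlas_row(49.0, {"heart": 8.0}, fill=1.0),
                "g2": atlas_row(100.0, {"a": 30.0}, fill=1.0),
            }
        )
        result = classify_matrix(profile, brain_config)
        p = tmp_path / "clf.tsv"
        write_classifications_tsv(result, p)
        back = read_classifications_tsv(p)
        assert list(back["category"]) == list(result["category"])
        assert list(back["enriched_group"]) == list(result["enriched_group"])


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        values=st.lists(st.floats(0.0, 500.0, allow_nan=False), min_size=9, max_size=12),
        scale=st.floats(1.0, 50.0),
    )
    def test_scaling_up_preserves_elevated_status(self, values, scale):
        """Fold-ratio rules are scale-free; scaling by c >= 1 keeps detection."""
        row = {f"t{i:02d}": v for i, v in enumerate(values)}
        cfg = ClassificationConfig(target_tissue="t00")
        before = classify_gene(row, cfg)
        after = classify_gene({t: v * scale for t, v in row.items()}, cfg)
        assert (before.category in ELEVATED_CATEGORIES) == (
            after.category in ELEVATED_CATEGORIES
        )
        if before.category in ELEVATED_CATEGORIES:
            assert before.category is after.category

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        values=st.lists(st.floats(0.0, 100.0, allow_nan=False), min_size=9, max_size=12),
        boost=st.floats(1.0, 1000.0),
    )
    def test_raising_target_never_demotes_enrichment(self, values, boost):
        row = {f"t{i:02d}": v for i, v in enumerate(values)}
        cfg = ClassificationConfig(target_tissue="t00")
        before = classify_gene(row, cfg)
        if before.category not in (Category.ENRICHED, Category.HIGHLY_ENRICHED):
            return
        row["t00"] += boost
        after = classify_gene(row, cfg)
        assert after.category in (Category.ENRICHED, Category.HIGHLY_ENRICHED)

    def test_every_gene_gets_exactly_one_category(self, brain_config, random_profiles):
        for i, values in enumerate(random_profiles(100, seed=11)):
            padded = atlas_row(values[next(iter(values))], dict(list(values.items())[1:]))
            c = classify_gene(padded, brain_config)
            assert isinstance(c.category, Category)
            if c.category is Category.GROUP_ENRICHED:
                assert 2 <= len(c.enriched_group) <= 7
                assert c.target_in_group
            else:
                assert c.enriched_group == frozenset() or not c.target_in_group


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"detection_threshold": 0.0},
            {"detection_threshold": 20.0},  # above the high threshold
            {"enrichment_fold": 0.5},
            {"enrichment_fold": 60.0},  # above the high fold
            {"group_size_min": 1},
            {"group_size_min": 8, "group_size_max": 7},
            {"enhanced_denominator": "median"},
        ],
    )
    def test_inconsistent_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassificationConfig(target_tissue="brain", **kwargs)
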