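"""Selection cascade: thresholds, clumping, strength metrics, screens."""

import numpy as np
import pandas as pd
import pytest

from mrpipe.iv_selection import (ThresholdProfile, f_statistic, filter_by_pvalue,
                                 filter_pqtl_instruments, filter_weak_instruments,
                                 ld_clump, screen_confounders, select_instruments,
                                 supplement_eaf, variance_explained)
from mrpipe.sumstats_io import AnnotationCatalog
from mrpipe.synthetic import SimulationConfig, simulate_pair, simulate_panel

from conftest import make_sumstats


def make_catalog(rows) -> AnnotationCatalog:
    cols = ["SNP", "TRAIT", "P", "IS_EQTL", "REGULOME_ANNOTATED", "EAF_REF", "EA_REF"]
    df = pd.DataFrame(rows, columns=cols)
    return AnnotationCatalog(df)


class TestProfiles:
    def test_named_profiles_carry_printed_thresholds(self):
        loose, strict = ThresholdProfile.loose(), ThresholdProfile.strict()
        assert (loose.p_threshold, loose.clump_r2, loose.clump_window_kb) == (1e-5, 0.01, 10_000)
        assert (strict.p_threshold, strict.clump_r2, strict.clump_window_kb) == (5e-6, 0.001, 10_000)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ThresholdProfile.named("medium")


class TestPvalueFilter:
    def test_keeps_only_sub_threshold(self):
        stats = make_sumstats([{"pval": 1e-6}, {"pval": 2e-5}])
        out = filter_by_pvalue(stats, ThresholdProfile.loose())
        assert list(out.table["variant_id"]) == ["rs0"]

    def test_all_above_gives_empty(self):
        stats = make_sumstats([{"pval": 0.5}, {"pval": 0.5}])
        assert len(filter_by_pvalue(stats, ThresholdProfile.loose())) == 0

    def test_boundary_pval_excluded_strict_inequality(self):
        stats = make_sumstats([{"pval": 1e-5}])
        assert len(filter_by_pvalue(stats, ThresholdProfile.loose())) == 0

    def test_idempotent(self):
        stats = make_sumstats([{"pval": 1e-6}, {"pval": 2e-5}, {"pval": 1e-8}])
        once = filter_by_pvalue(stats, ThresholdProfile.loose())
        twice = filter_by_pvalue(once, ThresholdProfile.loose())
        assert once.table.equals(twice.table)


class TestStrengthMetrics:
    @pytest.mark.parametrize("beta, se, expected", [
        (0.1, 0.0316, 10.012), (0.0, 0.1, 0.0), (-0.2, 0.05, 16.0)])
    def test_f_statistic(self, beta, se, expected):
        assert f_statistic((beta, se)) == pytest.approx(expected, rel=1e-3)

    def test_f_statistic_requires_positive_se(self):
        with pytest.raises(ValueError):
            f_statistic((0.1, 0.0))

    @pytest.mark.parametrize("eaf, beta, expected", [
        (0.5, 1.0, 0.5), (0.0, 1.0, 0.0), (0.2, 0.3, 0.0288)])
    def test_variance_explained(self, eaf, beta, expected):
        assert variance_explained((eaf, beta)) == pytest.approx(expected, rel=1e-12)

    def test_variance_explained_missing_eaf_instructs_supplement(self):
        with pytest.raises(ValueError, match="supplement_eaf"):
            variance_explained((float("nan"), 0.3))

    def test_variance_explained_maximal_at_half(self):
        grid = np.linspace(0.01, 0.99, 99)
        values = [variance_explained((f, 0.3)) for f in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.011)


class TestWeakInstrumentFilter:
    def test_boundary_inclusive(self):
        stats = make_sumstats([
            {"beta": 0.0995, "se": 0.0316},   # F ~ 9.9
            {"beta": 0.1, "se": 0.0316227766},  # F = 10.0
            {"beta": 0.224, "se": 0.0316},    # F ~ 50
        ])
        out = filter_weak_instruments(stats, min_f=10.0)
        assert list(out.table["variant_id"]) == ["rs1", "rs2"]

    def test_all_weak_gives_empty(self):
        stats = make_sumstats([{"beta": 0.01, "se": 0.1}])
        assert len(filter_weak_instruments(stats)) == 0

    def test_min_f_zero_is_identity(self):
        stats = make_sumstats([{"beta": 0.0}, {"beta": 0.01, "se": 1.0}])
        assert filter_weak_instruments(stats, min_f=0).table.equals(stats.table)


class TestLdClump:
    def test_perfect_ld_keeps_smaller_pval(self):
        cfg = SimulationConfig(n_variants=3, ld_blocks=({"size": 2, "r2": 1.0},),
                               n_panel=200, seed=21)
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        table = exposure.table.copy()
        table.loc[0, "pval"], table.loc[1, "pval"] = 1e-6, 1e-8
        out = ld_clump(exposure.replace_table(table), panel, ThresholdProfile.loose())
        kept = set(out.table["variant_id"])
        assert "rs100001" in kept and "rs100000" not in kept

    def test_different_chromosomes_both_retained(self):
        # two singleton regions land on chromosomes 1 and 2
        cfg = SimulationConfig(n_variants=3, n_panel=100, seed=22)
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        chroms = exposure.table["chrom"]
        assert chroms.nunique() == 3
        out = ld_clump(exposure, panel, ThresholdProfile.loose())
        assert len(out) == 3

    def test_block_structured_panel_retains_one_per_block(self):
        """Blocks of 5 at r2~0.9 collapse to their best variant each.

        Oracle: the greedy procedure on the realized r2 matrix retains
        exactly one variant per block under clump_r2=0.01."""
        cfg = SimulationConfig(n_variants=10, n_panel=2000, seed=23,
                               ld_blocks=({"size": 5, "r2": 0.9}, {"size": 5, "r2": 0.9}))
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        out = ld_clump(exposure, panel, ThresholdProfile.loose())
        assert len(out) == 2
        blocks = {0: exposure.table["variant_id"][:5], 1: exposure.table["variant_id"][5:]}
        for k, members in blocks.items():
            kept = [v for v in out.table["variant_id"] if v in set(members)]
            assert len(kept) == 1
            # retained variant is the block's smallest p-value
            pv = exposure.table.set_index("variant_id").loc[members, "pval"]
            assert kept[0] == pv.idxmin()

    def test_clumped_output_pairwise_independent(self):
        cfg = SimulationConfig(n_variants=12, n_panel=1000, seed=24,
                               ld_blocks=({"size": 4, "r2": 0.8}, {"size": 4, "r2": 0.8}))
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        profile = ThresholdProfile.loose()
        out = ld_clump(exposure, panel, profile)
        t = out.table
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                a, b = t.iloc[i], t.iloc[j]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= profile.clump_window_kb * 1000:
                    assert panel.r2(a["variant_id"], b["variant_id"]) <= profile.clump_r2

    def test_variant_absent_from_panel_dropped_with_warning(self):
        cfg = SimulationConfig(n_variants=3, n_panel=100, seed=25)
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        table = pd.concat([exposure.table, exposure.table.iloc[[0]].assign(
            variant_id="rs_not_in_panel")], ignore_index=True)
        with pytest.warns(UserWarning, match="absent from reference panel"):
            out = ld_clump(exposure.replace_table(table), panel, ThresholdProfile.loose())
        assert "rs_not_in_panel" not in set(out.table["variant_id"])

    def test_idempotent(self):
        cfg = SimulationConfig(n_variants=10, n_panel=500, seed=26,
                               ld_blocks=({"size": 5, "r2": 0.9},))
        exposure, _, _ = simulate_pair(cfg)
        panel = simulate_panel(cfg)
        once = ld_clump(exposure, panel, ThresholdProfile.loose())
        twice = ld_clump(once, panel, ThresholdProfile.loose())
        assert once.table.equals(twice.table)


class TestConfounderScreen:
    def test_confounder_hit_removed(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs0", "lung cancer", 1e-9, False, True, None, None)])
        assert len(screen_confounders(stats, cat)) == 0

    def test_above_threshold_retained(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs0", "lung cancer", 1e-6, False, True, None, None)])
        assert len(screen_confounders(stats, cat)) == 1

    def test_absent_from_catalog_retained(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs999", "melanoma tumor", 1e-10, False, True, None, None)])
        assert len(screen_confounders(stats, cat)) == 1

    def test_matching_is_case_insensitive_substring(self):
        stats = make_sumstats([{}, {}])
        cat = make_catalog([("rs0", "Malignant Tumour of colon", 1e-9, False, True, None, None),
                            ("rs1", "body height", 1e-9, False, True, None, None)])
        out = screen_confounders(stats, cat)
        assert list(out.table["variant_id"]) == ["rs1"]


class TestSupplementEaf:
    def test_fills_from_matching_effect_allele(self):
        stats = make_sumstats([{"eaf": np.nan, "effect_allele": "A", "other_allele": "G"}])
        cat = make_catalog([("rs0", None, None, False, True, 0.3, "A")])
        out = supplement_eaf(stats, cat)
        assert out.table.loc[0, "eaf"] == pytest.approx(0.3)

    def test_complements_when_stored_for_other_allele(self):
        stats = make_sumstats([{"eaf": np.nan, "effect_allele": "A", "other_allele": "G"}])
        cat = make_catalog([("rs0", None, None, False, True, 0.3, "G")])
        out = supplement_eaf(stats, cat)
        assert out.table.loc[0, "eaf"] == pytest.approx(0.7)

    def test_absent_variant_stays_missing_and_flagged(self):
        stats = make_sumstats([{"eaf": np.nan}])
        cat = make_catalog([("rs999", None, None, False, True, 0.3, "A")])
        log = []
        out = supplement_eaf(stats, cat, log)
        assert np.isnan(out.table.loc[0, "eaf"])
        assert "rs0" in log[-1].removed_ids  # flagged, not removed

    def test_present_eaf_untouched(self):
        stats = make_sumstats([{"eaf": 0.25}])
        cat = make_catalog([("rs0", None, None, False, True, 0.4, "A")])
        assert supplement_eaf(stats, cat).table.loc[0, "eaf"] == 0.25


class TestPqtlFilter:
    def test_annotated_non_eqtl_retained(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs0", None, None, False, True, None, None)])
        assert len(filter_pqtl_instruments(stats, cat)) == 1

    def test_annotated_eqtl_removed(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs0", None, None, True, True, None, None)])
        assert len(filter_pqtl_instruments(stats, cat)) == 0

    def test_unannotated_removed(self):
        stats = make_sumstats([{}])
        cat = make_catalog([("rs0", None, None, False, False, None, None)])
        assert len(filter_pqtl_instruments(stats, cat)) == 0


class TestSelectInstruments:
    def test_cascade_logs_provenance(self):
        cfg = SimulationConfig(n_variants=30, causal_beta=0.3, seed=27)
        exposure, _, _ = simulate_pair(cfg)
        iv = select_instruments(exposure, ThresholdProfile.loose())
        steps = [rec.step for rec in iv.provenance]
        assert any(s.startswith("pvalue") for s in steps)
        assert any(s.startswith("F>=") for s in steps)
        for rec in iv.provenance:
            assert rec.n_before - rec.n_after == len(rec.removed_ids)

    def test_strength_metrics_cover_selected_variants(self):
        cfg = SimulationConfig(n_variants=30, causal_beta=0.3, seed=28)
        exposure, _, _ = simulate_pair(cfg)
        iv = select_instruments(exposure, ThresholdProfile.loose())
        assert set(iv.f_stats.index) == set(iv.stats.table["variant_id"])
        assert (iv.f_stats >= 10).all()
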