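"""Instrument curation: QC, LD pruning, merging, orientation, scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcox.exceptions import (
    DegenerateRegressionError,
    EmptyInstrumentError,
    HarmonizationError,
)
from mrcox.instruments import (
    build_genetic_score,
    exclude_pleiotropic,
    f_statistic,
    merge_studies,
    orient_effect_alleles,
    prune_ld,
    qc_filter,
    read_instruments_tsv,
    rescale_gs,
    write_instruments_tsv,
)

from conftest import make_variant


class TestQCFilter:
    def test_exact_hwe_proportions_retained(self):
        dosages = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        geno = pd.DataFrame({"v1": dosages})
        retained, report = qc_filter(geno)
        assert retained == ["v1"]
        assert report.loc["v1", "hwe_chi2"] == pytest.approx(0.0)
        assert report.loc["v1", "hwe_p"] == pytest.approx(1.0)

    def test_total_heterozygote_deficit_removed(self):
        # AA=50, aa=50, no hets: chi-square equals n=100, p << 1e-4
        geno = pd.DataFrame({"v1": np.repeat([0.0, 2.0], [50, 50])})
        retained, report = qc_filter(geno)
        assert retained == []
        assert report.loc["v1", "hwe_chi2"] == pytest.approx(100.0)
        assert report.loc["v1", "hwe_p"] < 1e-4

    def test_missingness_removes_regardless_of_hwe(self, rng):
        d = rng.binomial(2, 0.4, size=1000).astype(float)
        d[:30] = np.nan  # 3% missing
        retained, report = qc_filter(pd.DataFrame({"v1": d}))
        assert retained == []
        assert report.loc["v1", "missing_rate"] == pytest.approx(0.03)

    def test_imputation_quality_threshold(self, rng):
        d = rng.binomial(2, 0.4, size=500).astype(float)
        geno = pd.DataFrame({"good": d, "bad": d})
        meta = pd.DataFrame({"impute_r2": [0.95, 0.4]}, index=["good", "bad"])
        retained, _ = qc_filter(geno, meta)
        assert retained == ["good"]

    def test_variant_without_quality_treated_as_genotyped(self, rng):
        d = rng.binomial(2, 0.4, size=500).astype(float)
        retained, _ = qc_filter(pd.DataFrame({"v1": d}), pd.DataFrame({"impute_r2": []}))
        assert retained == ["v1"]

    def test_thresholds_monotone(self, rng):
        """Loosening any threshold never removes a retained variant."""
        geno = pd.DataFrame(
            {f"v{j}": rng.binomial(2, rng.uniform(0.05, 0.5), size=200).astype(float) for j in range(8)}
        )
        for col in geno.columns[:4]:
            miss = rng.random(200) < rng.uniform(0, 0.05)
            geno.loc[miss, col] = np.nan
        strict, _ = qc_filter(geno, max_missing=0.01, hwe_p_min=0.05)
        loose, _ = qc_filter(geno, max_missing=0.05, hwe_p_min=1e-6)
        assert set(strict) <= set(loose)


class TestPruneLD:
    def _oracle(self, variants, corr, threshold):
        """Independent re-statement: walk rank order, keep if compatible."""
        ranked = sorted(variants, key=lambda v: (-abs(v.gamma_hat / v.se_gamma), v.variant_id))
        kept = []
        for v in ranked:
            if all(corr.loc[v.variant_id, k.variant_id] ** 2 < threshold for k in kept):
                kept.append(v)
        return [v.variant_id for v in kept]

    def test_uncorrelated_all_retained(self):
        vs = [make_variant(f"rs{j}", gamma=0.1 * (j + 1)) for j in range(4)]
        corr = pd.DataFrame(np.eye(4), index=[v.variant_id for v in vs], columns=[v.variant_id for v in vs])
        assert len(prune_ld(vs, corr=corr)) == 4

    def test_perfect_correlation_keeps_stronger(self):
        a = make_variant("rsA", gamma=0.30)
        b = make_variant("rsB", gamma=0.10)
        corr = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["rsA", "rsB"], columns=["rsA", "rsB"])
        kept = prune_ld([a, b], corr=corr)
        assert [v.variant_id for v in kept] == ["rsA"]

    def test_matches_rank_order_oracle(self, rng):
        ids = [f"rs{j}" for j in range(5)]
        vs = [make_variant(i, gamma=float(rng.uniform(0.01, 0.3))) for i in ids]
        A = rng.uniform(-1, 1, size=(5, 5))
        c = np.corrcoef(A @ A.T + 5 * np.eye(5))
        corr = pd.DataFrame(c, index=ids, columns=ids)
        kept = [v.variant_id for v in prune_ld(vs, corr=corr, threshold=0.3)]
        assert kept == self._oracle(vs, corr, 0.3)

    def test_greedy_output_is_maximal(self, rng):
        ids = [f"rs{j}" for j in range(6)]
        vs = [make_variant(i, gamma=float(rng.uniform(0.01, 0.3))) for i in ids]
        geno = pd.DataFrame(rng.binomial(2, 0.3, size=(300, 6)).astype(float), columns=ids)
        geno["rs1"] = geno["rs0"] + rng.normal(0, 0.2, 300)  # plant LD
        kept = prune_ld(vs, genotypes=geno, threshold=0.3)
        kept_ids = {v.variant_id for v in kept}
        corr = geno.corr()
        for v in vs:
            if v.variant_id not in kept_ids:
                assert any(corr.loc[v.variant_id, k] ** 2 >= 0.3 for k in kept_ids)

    def test_constant_dosage_excluded(self):
        vs = [make_variant("rsA", gamma=0.2), make_variant("rsB", gamma=0.1)]
        geno = pd.DataFrame({"rsA": [1.0] * 50, "rsB": [0, 1, 2] * 16 + [1, 2]})
        kept = prune_ld(vs, genotypes=geno)
        assert [v.variant_id for v in kept] == ["rsB"]


class TestMergeStudies:
    def test_most_recent_study_wins(self):
        old = make_variant("rs1", gamma=0.1, source_study="old", publication_year=2011)
        new = make_variant("rs1", gamma=0.2, source_study="new", publication_year=2018)
        merged = merge_studies([old, new])
        assert len(merged) == 1 and merged[0].source_study == "new"

    def test_no_duplicates_identity(self):
        vs = [make_variant(f"rs{j}") for j in range(3)]
        assert merge_studies(vs) == vs

    def test_swapped_alleles_reconciled_by_flip(self):
        a = make_variant("rs1", gamma=0.1, eaf=0.3, publication_year=2018)
        b = make_variant(
            "rs1", gamma=-0.1, eaf=0.7, publication_year=2011,
            effect_allele="G", other_allele="A",
        )
        merged = merge_studies([a, b])
        assert len(merged) == 1
        kept = merged[0]
        assert (kept.effect_allele, kept.other_allele) == ("A", "G")
        assert kept.gamma_hat == pytest.approx(0.1)

    def test_irreconcilable_alleles_raise(self):
        a = make_variant("rs1", effect_allele="A", other_allele="G")
        b = make_variant("rs1", effect_allele="C", other_allele="T")
        with pytest.raises(HarmonizationError):
            merge_studies([a, b])

    def test_year_tie_broken_by_precision(self):
        a = make_variant("rs1", se=0.05, source_study="noisy", publication_year=2018)
        b = make_variant("rs1", se=0.01, source_study="precise", publication_year=2018)
        assert merge_studies([a, b])[0].source_study == "precise"


class TestPleiotropyExclusion:
    def test_tagged_removed_untagged_kept(self):
        tagged = make_variant("rs1", pleiotropy_tags={"T2DM"})
        clean = make_variant("rs2")
        assert exclude_pleiotropic([tagged, clean]) == [clean]

    def test_empty_exclusion_set_is_identity(self):
        vs = [make_variant("rs1", pleiotropy_tags={"T2DM"})]
        assert exclude_pleiotropic(vs, excluded_traits=frozenset()) == vs

    def test_four_of_sixty_tagged_leaves_fifty_six(self):
        vs = [
            make_variant(f"rs{j}", pleiotropy_tags={"BMI"} if j < 4 else set())
            for j in range(60)
        ]
        assert len(exclude_pleiotropic(vs)) == 56


class TestOrientation:
    def test_negative_effect_flipped(self):
        v = make_variant("rs1", gamma=-0.1, eaf=0.3)
        (o,) = orient_effect_alleles([v])
        assert o.gamma_hat == pytest.approx(0.1)
        assert o.eaf == pytest.approx(0.7)
        assert (o.effect_allele, o.other_allele) == ("G", "A")

    @given(st.floats(-0.5, 0.5), st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_nonnegative(self, gamma, eaf):
        v = make_variant("rs1", gamma=gamma, eaf=eaf)
        once = orient_effect_alleles([v])
        twice = orient_effect_alleles(once)
        assert once == twice
        assert once[0].gamma_hat >= 0


class TestFStatistic:
    def test_zero_r2_is_weak(self):
        f, weak = f_statistic(0.0, 100, 5)
        assert f == 0 and weak

    def test_published_strength_formula(self):
        # R^2=6%, n=10,179 with ~6 instrument-score terms: F near 108
        f, weak = f_statistic(0.06, 10_179, 6)
        assert f == pytest.approx(108.2, abs=0.1)
        assert not weak

    def test_exact_threshold(self):
        f, weak = f_statistic(0.5, 12, 1)
        assert f == pytest.approx(10.0)
        assert not weak  # the weak flag is strictly F < 10

    def test_monotonicity(self):
        base, _ = f_statistic(0.1, 500, 5)
        assert f_statistic(0.2, 500, 5)[0] > base
        assert f_statistic(0.1, 1000, 5)[0] > base
        assert f_statistic(0.1, 500, 10)[0] < base

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 5), (0.1, 6, 5), (0.1, 100, 0)])
    def test_invalid_arguments(self, r2, n, k):
        with pytest.raises(ValueError):
            f_statistic(r2, n, k)


class TestGeneticScore:
    def test_single_variant_scaling(self):
        v = make_variant("rs1", gamma=0.1)
        geno = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]})
        gs = build_genetic_score(geno, [v])
        assert gs.values.tolist() == pytest.approx([0.0, 0.1, 0.2])

    def test_zero_weights_zero_scores(self):
        vs = [make_variant(f"rs{j}", gamma=0.0) for j in range(3)]
        geno = pd.DataFrame({f"rs{j}": [0.0, 1.0, 2.0] for j in range(3)})
        assert build_genetic_score(geno, vs).values.tolist() == [0, 0, 0]

    def test_matches_matrix_vector_product(self, rng):
        weights = [0.05, 0.2, 0.11]
        vs = [make_variant(f"rs{j}", gamma=w) for j, w in enumerate(weights)]
        dos = rng.binomial(2, 0.4, size=(4, 3)).astype(float)
        geno = pd.DataFrame(dos, columns=[v.variant_id for v in vs])
        gs = build_genetic_score(geno, vs)
        np.testing.assert_allclose(gs.values.to_numpy(), dos @ np.array(weights))

    def test_linear_in_weights(self, rng):
        vs = [make_variant(f"rs{j}", gamma=0.1 * (j + 1)) for j in range(3)]
        scaled = [make_variant(f"rs{j}", gamma=0.3 * (j + 1)) for j in range(3)]
        geno = pd.DataFrame(rng.binomial(2, 0.4, size=(10, 3)).astype(float),
                            columns=[v.variant_id for v in vs])
        np.testing.assert_allclose(
            3 * build_genetic_score(geno, vs).values,
            build_genetic_score(geno, scaled).values,
        )

    def test_missing_dosages_mean_imputed(self):
        v = make_variant("rs1", gamma=1.0, eaf=0.25)
        geno = pd.DataFrame({"rs1": [np.nan, 2.0]})
        gs = build_genetic_score(geno, [v])
        assert gs.values.iloc[0] == pytest.approx(0.5)  # 2 * eaf
        assert gs.n_imputed_dosages == 1

    def test_no_overlap_raises(self):
        with pytest.raises(EmptyInstrumentError):
            build_genetic_score(pd.DataFrame({"other": [0.0]}), [make_variant("rs1")])


class TestRescaleGS:
    def test_identity_regression(self):
        v = make_variant("rs1", gamma=1.0)
        geno = pd.DataFrame({"rs1": [0.0, 1.0, 2.0, 1.0, 0.0]})
        gs = build_genetic_score(geno, [v])
        rescaled, (b0, b1) = rescale_gs(gs, gs.values.copy(), np.ones(5, bool))
        assert b0 == pytest.approx(0.0, abs=1e-12)
        assert b1 == pytest.approx(1.0)

    def test_ols_recovery(self, rng):
        gs_vals = pd.Series(rng.normal(size=10_000))
        v = make_variant("rs1")
        from mrcox.instruments import GeneticScore
        gs = GeneticScore(values=gs_vals, variant_ids=["rs1"], weights=np.array([0.1]))
        exposure = 2.0 + 0.5 * gs_vals + rng.normal(0, 0.5, size=10_000)
        _, (b0, b1) = rescale_gs(gs, exposure, np.ones(10_000, bool))
        assert b0 == pytest.approx(2.0, abs=0.05)
        assert b1 == pytest.approx(0.5, abs=0.03)

    def test_rescaled_score_perfectly_correlated(self, rng):
        from mrcox.instruments import GeneticScore
        gs = GeneticScore(values=pd.Series(rng.normal(size=500)), variant_ids=["rs1"], weights=np.array([0.1]))
        exposure = 1 + 0.3 * gs.values + rng.normal(0, 1, 500)
        mask = rng.random(500) > 0.05
        rescaled, _ = rescale_gs(gs, exposure, mask)
        r = np.corrcoef(gs.values, rescaled.values)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_score_raises(self):
        from mrcox.instruments import GeneticScore
        gs = GeneticScore(values=pd.Series(np.ones(10)), variant_ids=["rs1"], weights=np.array([0.1]))
        with pytest.raises(DegenerateRegressionError):
            rescale_gs(gs, pd.Series(np.arange(10.0)), np.ones(10, bool))


def test_instruments_tsv_round_trip(tmp_path):
    vs = [
        make_variant("rs1", pleiotropy_tags={"BMI", "LDL"}, source_study="A", publication_year=2016),
        make_variant("rs2", gamma=0.05, exposure_scale="binary-logodds"),
    ]
    path = tmp_path / "instruments.tsv"
    write_instruments_tsv(vs, path)
    back = read_instruments_tsv(path)
    assert back == vs
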