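"""Synthetic cohort generator: HWE, LD block, outcome model, trajectories."""

import numpy as np
import pytest
import statsmodels.api as sm

from toxsae.endpoints import ENDPOINT_SPECS, derive_labels
from toxsae.simulate import (
    ExclusionRates,
    GenotypeMatrix,
    planted_scenario,
    read_genotypes,
    simulate_genotypes,
    simulate_longitudinal,
    simulate_outcome,
    solve_intercept,
    write_genotypes,
    write_vcf,
)

BLEED = ENDPOINT_SPECS["rectal_bleeding"]


def test_column_means_match_binomial_expectation(panel):
    gm, truth = simulate_genotypes(10_000, panel, maf_range=(0.5, 0.5), seed=3)
    # Binomial(2, 0.5): mean 1, SE of the column mean ~ 0.007
    assert np.allclose(gm.dosages.mean(axis=0), 1.0, atol=0.03)


def test_hardy_weinberg_homozygote_frequency(panel):
    n = 50_000
    gm, truth = simulate_genotypes(n, panel, maf_range=(0.2, 0.4), seed=4)
    ungrouped = [k for k, e in enumerate(panel) if not e.ld_group]
    for k in ungrouped[:10]:
        maf = truth.mafs[k]
        hom = (gm.dosages[:, k] == 2).mean()
        se = np.sqrt(maf**2 * (1 - maf**2) / n)
        assert abs(hom - maf**2) < 3 * se + 1e-9


def test_ld_block_correlation_approximates_target(panel):
    gm, truth = simulate_genotypes(20_000, panel, ld_r2=0.8, seed=5)
    block = [k for k, e in enumerate(panel) if e.ld_group]
    r2s = []
    for i in block:
        for j in block:
            if i < j:
                r = np.corrcoef(gm.dosages[:, i], gm.dosages[:, j])[0, 1]
                r2s.append(r**2)
    assert np.mean(r2s) == pytest.approx(0.8, abs=0.08)


def test_perfect_ld_gives_identical_columns(panel):
    gm, _ = simulate_genotypes(500, panel, ld_r2=1.0, seed=6)
    block = [k for k, e in enumerate(panel) if e.ld_group]
    for k in block[1:]:
        assert np.array_equal(gm.dosages[:, block[0]], gm.dosages[:, k])


def test_zero_maf_gives_monomorphic_column(panel):
    gm, _ = simulate_genotypes(200, panel, maf_range=(0.0, 0.0), seed=7)
    assert not gm.dosages.any()


def test_continuous_dosages_stay_in_range(panel):
    gm, _ = simulate_genotypes(500, panel, seed=8, integer_dosages=False)
    assert gm.dosages.min() >= 0 and gm.dosages.max() <= 2
    assert not np.allclose(gm.dosages, np.round(gm.dosages))


def test_empty_panel_rejected():
    with pytest.raises(ValueError):
        simulate_genotypes(100, [], seed=0)


def test_intercept_closed_form_null_effects(panel):
    gm, _ = simulate_genotypes(100, panel, seed=9)
    zero = np.zeros(gm.j)
    assert solve_intercept(zero, gm, 0.1) == pytest.approx(np.log(0.1 / 0.9), abs=1e-8)
    assert solve_intercept(zero, gm, 0.5) == pytest.approx(0.0, abs=1e-8)


def test_intercept_controls_realized_prevalence(panel):
    gm, y, truth = planted_scenario(panel, n=100_000, prevalence=0.1, seed=10)
    assert abs(y.mean() - 0.1) < 0.005


def test_nonfinite_effects_rejected(panel):
    gm, _ = simulate_genotypes(50, panel, seed=0)
    bad = np.zeros(gm.j)
    bad[0] = np.inf
    with pytest.raises(ValueError):
        solve_intercept(bad, gm, 0.1)


def test_null_outcome_uncorrelated_with_dosage(panel):
    gm, truth = simulate_genotypes(20_000, panel, seed=12)
    truth.intercept = solve_intercept(truth.planted_effects, gm, 0.2)
    truth.target_prevalence = 0.2
    y = simulate_outcome(gm, truth)
    n = len(y)
    for k in range(0, gm.j, 7):
        r = np.corrcoef(gm.dosages[:, k], y)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


def test_logistic_refit_recovers_planted_log_or(panel):
    gm, truth = simulate_genotypes(100_000, panel, seed=13)
    betas = np.zeros(gm.j)
    betas[0] = np.log(3.0)
    truth.planted_effects = betas
    truth.intercept = solve_intercept(betas, gm, 0.15)
    y = simulate_outcome(gm, truth)
    fit = sm.Logit(y, sm.add_constant(gm.dosages[:, 0])).fit(disp=0)
    assert fit.params[1] == pytest.approx(np.log(3.0), abs=0.1)


def test_outcome_reproducible_under_seed(panel):
    gm, y1, truth = planted_scenario(panel, n=500, seed=14)
    gm2, y2, _ = planted_scenario(panel, n=500, seed=14)
    assert np.array_equal(y1, y2)
    assert np.array_equal(gm.dosages, gm2.dosages)


@pytest.mark.parametrize("endpoint", sorted(ENDPOINT_SPECS))
def test_longitudinal_round_trip_at_zero_rates(endpoint):
    spec = ENDPOINT_SPECS[endpoint]
    rng = np.random.default_rng(15)
    y = (rng.random(400) < 0.12).astype(int)
    records = simulate_longitudinal(y, spec, seed=16)
    labels = derive_labels(records, spec)
    assert labels.n_excluded == 0
    assert np.array_equal(labels.binary().to_numpy(), y)


def test_all_controls_zero_rates_prevalence_zero():
    records = simulate_longitudinal(np.zeros(50, int), BLEED, seed=17)
    labels = derive_labels(records, BLEED)
    assert labels.n_cases == 0 and labels.n_controls == 50


def test_hemorrhoid_rate_one_excludes_everyone():
    records = simulate_longitudinal(
        np.ones(20, int), BLEED, rates=ExclusionRates(hemorrhoids=1.0), seed=18
    )
    labels = derive_labels(records, BLEED)
    assert labels.n_excluded == 20


def test_baseline_prevalent_controls_recode_consistently():
    """With baseline-prevalent non-worsening controls, the two baseline
    policies agree on the case set and differ only control-vs-excluded."""
    rng = np.random.default_rng(19)
    y = (rng.random(300) < 0.15).astype(int)
    records = simulate_longitudinal(
        y, BLEED, rates=ExclusionRates(baseline_prevalent=0.3), seed=20
    )
    excl = derive_labels(records, BLEED)
    recode = derive_labels(records, BLEED.with_policy("recode_control"))
    assert (excl.status == "case").equals(recode.status == "case")
    assert excl.n_excluded > 0 and recode.n_excluded == 0


def test_genotype_tsv_round_trip(panel, tmp_path):
    gm, _ = simulate_genotypes(30, panel, seed=21)
    path = tmp_path / "geno.tsv"
    write_genotypes(gm, path)
    back = read_genotypes(path)
    assert back.rsids == gm.rsids
    assert back.patient_ids == gm.patient_ids
    assert np.allclose(back.dosages, gm.dosages)


def test_vcf_dosage_round_trip(panel, tmp_path):
    cyvcf2 = pytest.importorskip("cyvcf2")
    from toxsae.simulate import read_vcf_dosages

    gm, _ = simulate_genotypes(10, panel, seed=22)
    path = tmp_path / "geno.vcf"
    write_vcf(gm, path)
    back = read_vcf_dosages(path)
    assert back.rsids == gm.rsids
    assert np.allclose(back.dosages, gm.dosages, atol=1e-5)


def test_dosage_matrix_validation():
    with pytest.raises(ValueError):
        GenotypeMatrix(np.array([[3.0]]), ["rs1"], ["p1"])  # out of range
    with pytest.raises(ValueError):
        GenotypeMatrix(np.array([[np.nan]]), ["rs1"], ["p1"])
    with pytest.raises(ValueError):
        GenotypeMatrix(np.ones((2, 2)), ["rs1"], ["p1", "p2"])
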