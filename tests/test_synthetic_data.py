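"""Generator correctness: allele-frequency draws, the inbreeding-adjusted
genotype law, survival structure, missingness and determinism."""

import numpy as np
import pandas as pd
import pytest

from hetsurv import survival as sv
from hetsurv import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(11)


class TestAlleleFrequencies:
    def test_degenerate_range_is_constant(self, rng):
        freqs = sd.simulate_allele_frequencies(5, (0.3, 0.3), rng)
        assert np.all(freqs == 0.3)

    def test_empty_and_invalid_inputs_raise(self, rng):
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_allele_frequencies(0, (0.1, 0.5), rng)
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_allele_frequencies(10, (0.0, 0.5), rng)
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_allele_frequencies(10, (0.2, 0.6), rng)

    def test_uniform_mean(self, rng):
        freqs = sd.simulate_allele_frequencies(10_000, (0.1, 0.5), rng)
        se = np.sqrt((0.4 ** 2 / 12) / 10_000)
        assert abs(freqs.mean() - 0.3) < 3 * se


class TestGenotypeLaw:
    @pytest.mark.parametrize("p,f", [(0.5, 0.0), (0.2, 0.0), (0.5, 0.5),
                                     (0.3, 0.2)])
    def test_class_frequencies_match_law(self, rng, p, f):
        n, m = 100, 1000  # 100k draws
        G = sd.simulate_genotypes(np.full(m, p), np.full(n, f), rng)
        # G counts the "freqs" allele, here at frequency p; code 0 means
        # zero copies of it
        expected = {0: (1 - p) ** 2 + p * (1 - p) * f,
                    1: 2 * p * (1 - p) * (1 - f),
                    2: p ** 2 + p * (1 - p) * f}
        for code, prob in expected.items():
            frac = (G == code).mean()
            se = np.sqrt(prob * (1 - prob) / (n * m))
            assert abs(frac - prob) < 3 * se, (code, frac, prob)

    def test_no_hets_at_near_total_inbreeding(self, rng):
        G = sd.simulate_genotypes(np.full(1000, 0.5), np.full(50, 0.999), rng)
        assert (G == 1).mean() < 0.005

    def test_invalid_inbreeding_raises(self, rng):
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_genotypes(np.array([0.3]), np.array([1.0]), rng)
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_genotypes(np.array([0.0]), np.array([0.1]), rng)


class TestMissingness:
    def test_zero_rate_is_identity(self, rng):
        G = sd.simulate_genotypes(np.full(50, 0.3), np.zeros(20), rng)
        assert sd.inject_missingness(G, 0.0, rng) is G

    def test_rate_recovered(self, rng):
        G = sd.simulate_genotypes(np.full(100, 0.3), np.zeros(100), rng)
        Gm = sd.inject_missingness(G, 0.5, rng)
        frac = (Gm == sd.MISSING).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / G.size)

    def test_rate_one_rejected(self, rng):
        G = np.zeros((2, 2), dtype=np.int8)
        with pytest.raises(sd.InvalidConfigError):
            sd.inject_missingness(G, 1.0, rng)


class TestSurvivalGenerator:
    def test_null_effect_uncorrelated(self, rng):
        n = 5000
        z = rng.standard_normal(n)
        entry = rng.uniform(50, 70, n)
        out = sd.simulate_survival(z, np.zeros(n), 0.0, 0.02, entry, 95.0, rng)
        dead = out["dead"] == 1
        r = np.corrcoef(z[dead], (out["exit_age"] - out["entry_age"])[dead])[0, 1]
        assert abs(r) < 3 / np.sqrt(dead.sum())

    def test_immediate_censoring(self, rng):
        n = 500
        entry = np.full(n, 60.0)
        out = sd.simulate_survival(np.zeros(n), np.zeros(n), 0.0, 0.02,
                                   entry, 60.001, rng)
        assert out["dead"].mean() < 0.01
        assert (out["exit_age"] > out["entry_age"]).all()

    def test_structure_and_cause_labels(self, rng):
        n = 2000
        entry = rng.uniform(50, 70, n)
        out = sd.simulate_survival(rng.standard_normal(n), np.zeros(n),
                                   -0.1, 0.02, entry, 95.0, rng)
        assert (out["exit_age"] > out["entry_age"]).all()
        dead = out["dead"] == 1
        assert set(out.loc[dead, "cause"]) <= {"cancer", "cvd", "other"}
        assert (out.loc[~dead, "cause"] == "NA").all()

    def test_exponential_survivor_function(self, rng):
        # beta = 0, entry at age ~0, no censoring: exit age is Exp(rate)
        n, rate = 20000, 0.05
        entry = np.full(n, 1e-6)
        out = sd.simulate_survival(np.zeros(n), np.zeros(n), 0.0, rate,
                                   entry, 1e9, rng)
        assert out["dead"].all()  # no censoring: KM reduces to the ECDF
        for age in (5.0, 15.0, 40.0):
            s_hat = (out["exit_age"] > age).mean()
            s_true = np.exp(-rate * age)
            assert abs(s_hat - s_true) < 3 * np.sqrt(s_true * (1 - s_true) / n)

    def test_invalid_baseline_rate(self, rng):
        with pytest.raises(sd.InvalidConfigError):
            sd.simulate_survival(np.zeros(5), np.zeros(5), 0.0, 0.0,
                                 np.full(5, 50.0), 95.0, rng)


def test_cox_recovery_oracle(rng):
    """Fitting the generator's own output recovers the planted log-HR
    within 2 reported SEs (no censoring, exponential baseline)."""
    n, beta = 20000, np.log(0.8)
    z = rng.standard_normal(n)
    entry = rng.uniform(50, 70, n)
    out = sd.simulate_survival(z, np.zeros(n), beta, 0.05, entry, 1e9, rng)
    df = out.assign(x=z)
    fit = sv.cox_fit(df, ["x"])
    assert abs(fit.beta["x"] - beta) < 2 * fit.se["x"]


class TestCohortAssembly:
    def test_determinism(self, tiny_sim_config):
        a = sd.simulate_study(tiny_sim_config, seed=5)
        b = sd.simulate_study(tiny_sim_config, seed=5)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.genotypes, cb.genotypes)
            pd.testing.assert_frame_equal(ca.phenotypes, cb.phenotypes)
            assert np.array_equal(ca.truth.het_z, cb.truth.het_z)

    def test_ancestry_mix_assignment(self, tiny_study):
        ancestries = [c.ancestry for c in tiny_study]
        assert ancestries.count("EUR") == 2 and ancestries.count("AFR") == 1

    def test_phenotype_schema(self, tiny_cohort):
        assert list(tiny_cohort.phenotypes.columns) == sd.PHENOTYPE_COLUMNS
        assert len(tiny_cohort.phenotypes) == int(tiny_cohort.study_mask.sum())

    def test_invalid_configs_rejected(self):
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(n_cohorts=0).validate()
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(ancestry_mix={"EUR": 1.0}).validate()
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(cause_mix={"cancer": 0.9, "cvd": 0.3,
                                    "other": 0.1}).validate()


class TestWriteReadRoundTrip:
    @pytest.mark.parametrize("fmt", sd.FORMATS)
    def test_round_trip_identity(self, tmp_path, fmt):
        cfg = sd.SimConfig(n_cohorts=2, n_individuals=10, n_snps=10,
                           n_chromosomes=2, n_reference_per_pop=5,
                           missing_rate=0.1)
        cohort = sd.simulate_study(cfg, seed=3)[0]
        out = sd.write_cohort(cohort, tmp_path / fmt, fmt)
        back = sd.read_cohort(out)
        assert np.array_equal(back.genotypes, cohort.genotypes)
        assert back.sample_ids == cohort.sample_ids
        assert back.snp_ids == cohort.snp_ids
        assert np.array_equal(np.asarray(back.chrom, int), cohort.chrom)
        pd.testing.assert_frame_equal(
            back.phenotypes, cohort.phenotypes, check_exact=False, rtol=1e-12)
        assert np.allclose(back.truth.het_z, cohort.truth.het_z)

    def test_unknown_format_lists_supported(self, tiny_cohort, tmp_path):
        with pytest.raises(ValueError, match="tsv"):
            sd.write_cohort(tiny_cohort, tmp_path, "bgen")

    def test_vcf_reparses_with_independent_reader(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        cfg = sd.SimConfig(n_cohorts=2, n_individuals=8, n_snps=12,
                           n_chromosomes=3, n_reference_per_pop=4)
        cohort = sd.simulate_study(cfg, seed=9)[0]
        sd.write_cohort(cohort, tmp_path, "vcf")
        recs = list(pysam.VariantFile(str(tmp_path / "genotypes.vcf")))
        assert len(recs) == 12
        for j, rec in enumerate(recs):
            assert rec.id == cohort.snp_ids[j]
            assert rec.ref == "A" and rec.alts == ("C",)
            alt_counts = [
                sum(1 for a in s["GT"] if a == 1) if None not in s["GT"]
                else sd.MISSING
                for s in rec.samples.values()]
            assert alt_counts == list(cohort.genotypes[:, j])
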