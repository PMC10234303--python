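import numpy as np
import pandas as pd
import pytest

from mutaccum import genome_context as gcm
from mutaccum import snm_spectrum as sp
from mutaccum.genome_context import SNM_CLASSES, TRINUC_CLASSES
from mutaccum.ma_rates import ExperimentDesign

FAST = dict(chains=2, warmup=300, draws=800)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _make_spec(counts_by_class, at_pairs=1_000_000, cg_pairs=1_000_000,
               stratum="genome"):
    counts = pd.DataFrame([counts_by_class], index=[stratum],
                          columns=list(SNM_CLASSES))
    pairs = pd.DataFrame({"at_pairs": [at_pairs], "cg_pairs": [cg_pairs]},
                         index=[stratum])
    return sp.SpectrumCounts(counts=counts, pairs=pairs)


class TestClassify:
    @pytest.mark.parametrize("ref,alt,cls", [
        ("C", "T", "C:G→T:A"),
        ("G", "A", "C:G→T:A"),
        ("A", "C", "A:T→C:G"),
        ("T", "A", "A:T→T:A"),
    ])
    def test_examples(self, ref, alt, cls):
        assert sp.classify_snm(ref, alt) == cls

    def test_strand_involution_for_all_substitutions(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert sp.classify_snm(ref, alt) == \
                    sp.classify_snm(_COMP[ref], _COMP[alt])

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_snm("A", "A")
        with pytest.raises(ValueError):
            sp.classify_snm("N", "A")


class TestRelativeRates:
    def test_equal_counts_at_even_composition_give_one_sixth(self):
        spec = _make_spec([120] * 6)
        rel = sp.relative_rates(spec, exposure=1e6, seed=0, **FAST)
        for _, row in rel.table.iterrows():
            assert row["hpdi_low"] < 1 / 6 < row["hpdi_high"]
            assert row["median"] == pytest.approx(1 / 6, abs=0.03)
        assert rel.table["median"].sum() == pytest.approx(1.0, abs=0.02)

    def test_single_hot_class_takes_nearly_all_mass(self):
        spec = _make_spec([300, 0, 0, 0, 0, 0])
        rel = sp.relative_rates(spec, exposure=1e6, seed=1, **FAST)
        assert rel.table.loc[0, "median"] > 0.95
        assert rel.table["median"][1:].max() < 0.05

    def test_uniform_composition_reduces_to_count_proportions(self):
        # frequency-correction identity: equal censuses cancel, so the
        # normalized rates track count shares (Poisson-mean limit)
        counts = [400, 250, 120, 90, 80, 60]
        spec = _make_spec(counts)
        rel = sp.relative_rates(spec, exposure=1e6, seed=2, **FAST)
        props = np.array(counts) / sum(counts)
        assert np.allclose(rel.table["median"], props, atol=0.02)

    def test_zero_census_with_count_is_error(self):
        spec = _make_spec([5, 0, 0, 0, 0, 0], cg_pairs=0)
        with pytest.raises(ValueError, match="zero census"):
            sp.relative_rates(spec, exposure=1e6, seed=3, **FAST)


class TestTsTv:
    def test_equal_rates_give_half(self):
        # two transitions vs four transversions at equal per-class rates
        spec = _make_spec([100] * 6)
        r = sp.ts_tv(spec, exposure=1e6, seed=4, **FAST)
        assert r.hpdi_low < 0.5 < r.hpdi_high

    def test_balanced_ts_tv_counts_give_one(self):
        spec = _make_spec([200, 200, 100, 100, 100, 100])
        r = sp.ts_tv(spec, exposure=1e6, seed=5, **FAST)
        assert r.hpdi_low < 1.0 < r.hpdi_high
        assert r.median == pytest.approx(1.0, abs=0.1)

    def test_doubling_counts_narrows_interval_keeps_median(self):
        a = sp.ts_tv(_make_spec([150, 150, 80, 80, 80, 80]),
                     exposure=1e6, seed=6, **FAST)
        b = sp.ts_tv(_make_spec([300, 300, 160, 160, 160, 160]),
                     exposure=1e6, seed=7, **FAST)
        assert (b.hpdi_high - b.hpdi_low) < (a.hpdi_high - a.hpdi_low)
        assert b.median == pytest.approx(a.median, rel=0.1)

    def test_zero_transversions_is_error(self):
        with pytest.raises(ValueError, match="Ts/Tv undefined"):
            sp.ts_tv(_make_spec([50, 50, 0, 0, 0, 0]), exposure=1e6)


class TestDomainSpectrumRatio:
    def _two_domain_spec(self, counts_a, counts_b, pairs_a=None, pairs_b=None):
        counts = pd.DataFrame([counts_a, counts_b], index=["A", "B"],
                              columns=list(SNM_CLASSES))
        pa = pairs_a or (1e6, 1e6)
        pb = pairs_b or (1e6, 1e6)
        pairs = pd.DataFrame({"at_pairs": [pa[0], pb[0]],
                              "cg_pairs": [pa[1], pb[1]]}, index=["A", "B"])
        return sp.SpectrumCounts(counts=counts, pairs=pairs)

    def test_identical_spectra_give_unit_ratios(self):
        spec = self._two_domain_spec([90, 80, 40, 40, 40, 40],
                                     [90, 80, 40, 40, 40, 40])
        out = sp.domain_spectrum_ratio(spec, "A", "B", exposure=1e6, seed=8,
                                       **FAST)
        assert not out["different"].any()
        assert np.allclose(out["median"], 1.0, atol=0.25)

    def test_enriched_class_is_flagged(self):
        spec = self._two_domain_spec([90, 80, 40, 150, 40, 40],
                                     [90, 80, 40, 40, 40, 40])
        out = sp.domain_spectrum_ratio(spec, "A", "B", exposure=1e6, seed=9,
                                       **FAST)
        flagged = out.set_index("class")["different"]
        assert flagged["C:G→G:C"]

    def test_double_zero_class_marked_undefined(self):
        spec = self._two_domain_spec([90, 80, 40, 40, 40, 0],
                                     [90, 80, 40, 40, 40, 0])
        out = sp.domain_spectrum_ratio(spec, "A", "B", exposure=1e6, seed=10,
                                       **FAST)
        assert out.set_index("class").loc["A:T→T:A", "undefined"]

    def test_correction_switch_only_changes_census_terms(self, sim_composition):
        # closed-form Poisson-mean check: the ratio of normalized corrected
        # rates at fixed counts shifts by the ratio of offset ratios
        counts_a = np.array([60, 50, 30, 30, 30, 30])
        counts_b = np.array([50, 60, 30, 30, 30, 30])
        spec = self._two_domain_spec(
            list(counts_a), list(counts_b),
            pairs_a=(2e6, 1e6), pairs_b=(1e6, 2e6))
        out = sp.domain_spectrum_ratio(spec, "A", "B", exposure=1e6, seed=11,
                                       **FAST)
        # Poisson-mean oracle: corrected rate ~ count / (pair census)
        def oracle(counts, pairs):
            rates = np.array([
                c / (pairs[0] if cls.startswith("A:T") else pairs[1])
                for c, cls in zip(counts, SNM_CLASSES)])
            return rates / rates.sum()
        expected = oracle(counts_a, (2e6, 1e6)) / oracle(counts_b, (1e6, 2e6))
        assert np.allclose(out["median"], expected, rtol=0.15)


class TestTrinucModel:
    def test_nested_single_domain_fit_matches_per_class_rates(self):
        rng = np.random.default_rng(12)
        census = pd.DataFrame(
            [np.full(32, 400_000.0)], index=["euchromatin"],
            columns=TRINUC_CLASSES)
        true_rate = 2e-9
        design = ExperimentDesign()
        exposure = design.n_lines * design.t_transfers * design.m_median
        counts = pd.DataFrame(
            [rng.poisson(true_rate * 400_000 * exposure, size=32)],
            index=["euchromatin"], columns=TRINUC_CLASSES)
        fit = sp.trinuc_model(counts, census, design, seed=13, **FAST)
        # flat simulation: relative rates hover near 1/32 and most
        # class intervals overlap the flat value
        assert fit.table["median"].median() == pytest.approx(1 / 32, rel=0.1)
        covered = sum(row["hpdi_low"] <= 1 / 32 <= row["hpdi_high"]
                      for _, row in fit.table.iterrows())
        assert covered >= 28

    def test_hot_class_ranks_first(self):
        rng = np.random.default_rng(14)
        strata = ["euchromatin", "H3K9me3_ex_cen"]
        census = pd.DataFrame(np.full((2, 32), 100_000.0), index=strata,
                              columns=TRINUC_CLASSES)
        design = ExperimentDesign()
        exposure = design.n_lines * design.t_transfers * design.m_median
        rates = np.full(32, 1e-9)
        hot = TRINUC_CLASSES.index("AGA:TCT")
        rates[hot] = 6e-9
        lam = rates * 100_000 * exposure
        counts = pd.DataFrame(
            [rng.poisson(lam), rng.poisson(8 * lam)],
            index=strata, columns=TRINUC_CLASSES)
        fit = sp.trinuc_model(counts, census, design, seed=15, **FAST)
        top = fit.table.sort_values("median", ascending=False).iloc[0]
        assert top["class"] == "AGA:TCT"
        k9 = fit.domain_effects["k9"]
        assert k9.hpdi_low < 8.0 < k9.hpdi_high


class TestFlankingModel:
    def test_equal_responses_give_null_coefficients(self):
        z = np.zeros(32)
        sd = np.full(32, 0.1)
        fit = sp.flanking_regression(TRINUC_CLASSES, z, sd, seed=16, **FAST)
        for name in ("beta_b", "beta_5", "beta_3", "beta_I5", "beta_I3"):
            assert not fit.significant[name]
            assert abs(fit.coefficients[name].median) < 0.15

    def test_inflating_measurement_sd_widens_intervals(self):
        rng = np.random.default_rng(17)
        X = sp.flanking_design(TRINUC_CLASSES)
        beta = np.array([0.0, 0.3, -0.5, 0.0, 0.0, 0.0])
        z = X[sp.FLANKING_COEFS].to_numpy() @ beta + rng.normal(0, 0.05, 32)
        narrow = sp.flanking_regression(TRINUC_CLASSES, z, np.full(32, 0.05),
                                        seed=18, **FAST)
        wide = sp.flanking_regression(TRINUC_CLASSES, z, np.full(32, 0.5),
                                      seed=19, **FAST)
        for name in sp.FLANKING_COEFS[1:]:
            wn = (narrow.coefficients[name].hpdi_high
                  - narrow.coefficients[name].hpdi_low)
            ww = (wide.coefficients[name].hpdi_high
                  - wide.coefficients[name].hpdi_low)
            assert ww > wn

    def test_pyrimidine_orientation_of_design(self):
        des = sp.flanking_design(["AGA:TCT", "ACT:AGT"])
        # TCT: focal C, both flanks A:T
        assert des.loc["AGA:TCT", "beta_b"] == 1.0
        assert des.loc["AGA:TCT", "beta_5"] == 0.0
        assert des.loc["AGA:TCT", "beta_3"] == 0.0


class TestSpectrumCountsFromAnnotated:
    def test_counts_partition_snms_by_stratum(self, sim_annotated,
                                              sim_composition):
        spec = sp.spectrum_counts(sim_annotated, sim_composition)
        n_snm = int((sim_annotated["kind"] == "SNM").sum())
        assert spec.total("genome") == n_snm
        assert (spec.counts.loc["euchromatin"].sum()
                + spec.counts.loc["H3K9me3"].sum()
                + spec.counts.loc["H3K27me3"].sum()) == n_snm
        assert (spec.counts.loc["H3K9me3_ex_cen"]
                + spec.counts.loc["centromeric"]).equals(
                    spec.counts.loc["H3K9me3"])
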