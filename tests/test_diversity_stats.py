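"""Diversity statistics against closed forms and a naive counting oracle."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import rubuspanel as rp


def _gm(columns, samples=None):
    columns = [np.asarray(c, dtype=float) for c in columns]
    n = len(columns[0])
    samples = samples or [f"s{i}" for i in range(n)]
    return rp.GenotypeMatrix(samples, [f"m{j}" for j in range(len(columns))], np.array(columns).T)


class TestPerLocus:
    def test_allele_freq_examples(self):
        gm = _gm([[0, 1, 2, 2], [1, 1, 1, 1]])
        np.testing.assert_allclose(rp.allele_freq(gm), [0.625, 0.5])

    def test_all_missing_locus_undefined(self):
        gm = _gm([[np.nan] * 4, [0, 1, 2, 1]])
        p = rp.allele_freq(gm)
        assert np.isnan(p[0]) and p[1] == 0.5

    def test_empty_subset_rejected(self):
        gm = _gm([[0, 1]])
        with pytest.raises(rp.PanelError):
            rp.allele_freq(gm, samples=["nope"])

    @pytest.mark.parametrize(
        "p,expected", [(0.8, 0.2), (0.5, 0.5), (0.0, 0.0), (0.32, 0.32)]
    )
    def test_maf(self, p, expected):
        assert rp.maf(p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.375), (0.0, 0.0), (0.1, 0.1638)]
    )
    def test_pic_closed_form(self, p, expected):
        assert rp.pic(p) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("p,expected", [(0.5, 0.5), (0.1, 0.18), (0.0, 0.0)])
    def test_gd_closed_form(self, p, expected):
        assert rp.gd(p) == pytest.approx(expected)

    def test_ho_examples(self):
        gm = _gm([[0, 1, 2, 1], [1, 1, 1, 1]])
        per_locus, per_ind = rp.observed_het(gm)
        np.testing.assert_allclose(per_locus, [0.5, 1.0])
        np.testing.assert_allclose(per_ind, [0.5, 1.0, 0.5, 1.0])

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_gd_dominates_pic(self, p):
        assert rp.gd(p) >= rp.pic(p) - 1e-12

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bounds(self, p):
        assert 0.0 <= rp.maf(p) <= 0.5
        # closed forms are exact in exact arithmetic; allow float round-off
        assert -1e-12 <= rp.pic(p) <= 0.375 + 1e-12
        assert -1e-12 <= rp.gd(p) <= 0.5 + 1e-12


class TestInbreeding:
    def test_extremes_allele_identity(self):
        gm = _gm([[0, 1], [2, 1], [0, 1]])  # s0 fully hom, s1 fully het
        f = rp.inbreeding_fej(gm, "allele_identity")
        np.testing.assert_allclose(f, [1.0, 0.0])

    def test_mode_reductions_at_ho_054(self):
        # an individual heterozygous at 54 of 100 loci
        col = [1.0] * 54 + [0.0] * 46
        gm = rp.GenotypeMatrix(["j"], [f"m{i}" for i in range(100)], np.array([col]))
        assert rp.inbreeding_fej(gm, "allele_identity")[0] == pytest.approx(0.46)
        assert rp.inbreeding_fej(gm, "het_indicator_literal")[0] == pytest.approx(0.08)

    def test_unknown_mode_rejected(self):
        with pytest.raises(rp.PanelError):
            rp.inbreeding_fej(_gm([[0, 1]]), "bogus")

    @pytest.mark.parametrize(
        "f,ne", [(0.25, 2.0), (0.5, 1.0), (0.0029, 172.41379)]
    )
    def test_effective_size(self, f, ne):
        assert rp.effective_size(f) == pytest.approx(ne, rel=1e-6)

    def test_effective_size_nonpositive_warns_not_crashes(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert rp.effective_size(0.0) == np.inf
        with pytest.warns(UserWarning):
            assert rp.effective_size(-0.1) == np.inf


def naive_stats(dosage):
    """Genotype-counting oracle, one locus/individual at a time."""
    n, m = dosage.shape
    p = np.full(m, np.nan)
    ho_locus = np.full(m, np.nan)
    for j in range(m):
        alt = tot = het = called = 0
        for i in range(n):
            d = dosage[i, j]
            if np.isnan(d):
                continue
            called += 1
            tot += 2
            alt += int(d)
            het += int(d == 1)
        if called:
            p[j] = alt / tot
            ho_locus[j] = het / called
    ho_ind = np.full(n, np.nan)
    f_ind = np.full(n, np.nan)
    for i in range(n):
        het = called = hom = 0
        for j in range(m):
            d = dosage[i, j]
            if np.isnan(d):
                continue
            called += 1
            het += int(d == 1)
            hom += int(d != 1)
        if called:
            ho_ind[i] = het / called
            f_ind[i] = hom / called
    return p, ho_locus, ho_ind, f_ind


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_counting_exactly(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(50, 200)).astype(float)
        dosage[rng.random((50, 200)) < 0.1] = np.nan
        gm = rp.GenotypeMatrix(
            [f"s{i}" for i in range(50)], [f"m{j}" for j in range(200)], dosage
        )
        p_n, hol_n, hoi_n, f_n = naive_stats(dosage)
        p = rp.allele_freq(gm)
        hol, hoi = rp.observed_het(gm)
        f = rp.inbreeding_fej(gm, "allele_identity")
        np.testing.assert_allclose(p, p_n, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(hol, hol_n, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(hoi, hoi_n, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(f, f_n, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rp.maf(p), np.minimum(p_n, 1 - p_n), atol=1e-12)

    def test_identity_f_plus_ho_is_one(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(30, 80)).astype(float)
        dosage[rng.random((30, 80)) < 0.2] = np.nan
        gm = rp.GenotypeMatrix(
            [f"s{i}" for i in range(30)], [f"m{j}" for j in range(80)], dosage
        )
        _, ho_ind = rp.observed_het(gm)
        f = rp.inbreeding_fej(gm, "allele_identity")
        np.testing.assert_allclose(f + ho_ind, 1.0, atol=1e-15)

    def test_mean_locus_ho_equals_mean_individual_ho_when_complete(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(25, 60)).astype(float)
        gm = rp.GenotypeMatrix(
            [f"s{i}" for i in range(25)], [f"m{j}" for j in range(60)], dosage
        )
        hol, hoi = rp.observed_het(gm)
        assert hol.mean() == pytest.approx(hoi.mean(), abs=1e-12)

    def test_coding_invariance_exact(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(20, 50)).astype(float)
        dosage[rng.random((20, 50)) < 0.1] = np.nan
        gm = _flip = rp.GenotypeMatrix(
            [f"s{i}" for i in range(20)], [f"m{j}" for j in range(50)], dosage
        )
        flipped = rp.GenotypeMatrix(gm.samples, gm.loci, 2.0 - dosage)
        p, q = rp.allele_freq(gm), rp.allele_freq(flipped)
        np.testing.assert_allclose(rp.maf(p), rp.maf(q), atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rp.pic(p), rp.pic(q), atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rp.gd(p), rp.gd(q), atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(
            rp.observed_het(gm)[0], rp.observed_het(flipped)[0], atol=1e-15
        )
        np.testing.assert_allclose(
            rp.inbreeding_fej(gm), rp.inbreeding_fej(flipped), atol=1e-15
        )


class TestGroupReport:
    def test_single_group_equals_all(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(10, 40)).astype(float)
        gm = rp.GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"m{j}" for j in range(40)], dosage
        )
        design = rp.PanelDesign({s: "JG" for s in gm.samples})
        with pytest.warns(UserWarning):  # empty groups skipped
            report = rp.group_report(gm, design)
        row_all = report.summary.loc["ALL"].drop("n")
        row_jg = report.summary.loc["JG"].drop("n")
        np.testing.assert_allclose(row_all.values.astype(float), row_jg.values.astype(float))

    def test_progeny_ho_matches_mendelian_truth(self, default_sim):
        panel, design, truth = (
            default_sim["panel"], default_sim["design"], default_sim["truth"],
        )
        report = rp.group_report(panel, design)
        for fam in ("JG", "JT", "JS"):
            n_fam = design.group_sizes()[fam]
            expected = truth.expected_het[fam].mean()
            observed = report.summary.loc[fam, "Ho"]
            # mean over loci of binomial proportions; conservative SE bound
            se = np.sqrt(0.25 / (n_fam * len(truth.expected_het)))
            assert abs(observed - expected) < 5 * se

    def test_mode_recorded_and_written(self, tmp_path, default_sim):
        report = rp.group_report(
            default_sim["panel"], default_sim["design"], "het_indicator_literal"
        )
        report.write(tmp_path)
        text = (tmp_path / "table1_mirror.tsv").read_text()
        assert "inbreeding_mode=het_indicator_literal" in text
        assert (tmp_path / "per_locus.tsv").exists()
        assert (tmp_path / "per_individual.tsv").exists()
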