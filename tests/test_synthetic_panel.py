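"""Generator correctness: Mendelian segregation, dual-call-set emulation, determinism."""
import hashlib

import numpy as np
import pytest

import rubuspanel as rp
from rubuspanel.synthetic_panel import (
    FAMILY_DONOR,
    add_genotype_noise,
    expected_offspring_het,
    simulate_parents,
    simulate_testcross,
)


def _cfg(**kw):
    kw.setdefault("n_loci", 400)
    return rp.SimulationConfig(**kw)


class TestParents:
    def test_full_divergence_no_het(self):
        cfg = _cfg(fixed_divergence_rate=1.0, tester_het_rate=0.0, donor_het_rate=0.0)
        gm, _ = simulate_parents(cfg)
        assert (gm.dosage[0] == 0).all()  # tester hom-REF
        assert (gm.dosage[1:] == 2).all()  # donors hom-ALT

    def test_fully_heterozygous_tester(self):
        cfg = _cfg(tester_het_rate=1.0, fixed_divergence_rate=0.0)
        gm, _ = simulate_parents(cfg)
        assert (gm.dosage[0] == 1).all()

    def test_realized_tester_het_rate(self):
        cfg = _cfg(n_loci=5000, fixed_divergence_rate=0.0, seed=2)
        gm, _ = simulate_parents(cfg)
        rate = (gm.dosage[0] == 1).mean()
        se = np.sqrt(0.77 * 0.23 / 5000)
        assert abs(rate - 0.77) < 3 * se

    def test_loci_sorted_and_unique(self):
        _, loci = simulate_parents(_cfg(n_loci=2000, seed=3))
        keys = [(l.seq_name, l.pos) for l in loci]
        assert keys == sorted(keys)
        assert len({l.locus_id for l in loci}) == len(loci)


class TestTestcross:
    def test_fixed_cross_gives_all_het(self):
        cfg = _cfg(fixed_divergence_rate=1.0, tester_het_rate=0.0, donor_het_rate=0.0)
        parents, _ = simulate_parents(cfg)
        panel, design, _ = simulate_testcross(parents, cfg)
        hyb = [s for s, g in design.assignments.items() if g in ("JG", "JT", "JS")]
        assert (panel.subset_samples(hyb).dosage == 1).all()

    def test_het_by_het_offspring_ho(self):
        # Aa x Aa at every locus: offspring het with probability 1/2
        cfg = rp.SimulationConfig(
            n_loci=50,
            tester_het_rate=1.0,
            donor_het_rate=1.0,
            fixed_divergence_rate=0.0,
            family_sizes={"JG": 10_000, "JT": 0, "JS": 0},
            seed=5,
        )
        parents, _ = simulate_parents(cfg)
        panel, design, _ = simulate_testcross(parents, cfg)
        hyb = [s for s, g in design.assignments.items() if g == "JG"]
        ho_locus, _ = rp.observed_het(panel.subset_samples(hyb))
        se = np.sqrt(0.25 / 10_000)
        assert (np.abs(ho_locus - 0.5) < 3 * se).mean() >= 0.99

    def test_default_family_sizes_give_116_hybrids(self, default_sim):
        sizes = default_sim["design"].group_sizes()
        assert sizes["JG"] + sizes["JT"] + sizes["JS"] == 116
        assert default_sim["panel"].n_samples == 121  # + 4 parents + check

    def test_mendelian_allele_frequency_conservation(self):
        # pooled offspring ALT frequency = (tester + donor dosage)/4 in expectation
        cfg = rp.SimulationConfig(
            n_loci=200, family_sizes={"JG": 10_000, "JT": 0, "JS": 0}, seed=8
        )
        parents, _ = simulate_parents(cfg)
        panel, design, _ = simulate_testcross(parents, cfg)
        hyb = [s for s, g in design.assignments.items() if g == "JG"]
        p_obs = rp.allele_freq(panel, samples=hyb)
        d = dict(zip(parents.samples, parents.dosage))
        p_exp = (d["Jewel"] + d[FAMILY_DONOR["JG"]]) / 4.0
        se = np.sqrt(np.maximum(p_exp * (1 - p_exp), 1e-12) / (2 * 10_000))
        ok = np.abs(p_obs - p_exp) <= 3 * se + 1e-12
        assert ok.mean() >= 0.99

    def test_missing_parent_propagates(self):
        cfg = _cfg(n_loci=10, family_sizes={"JG": 5, "JT": 0, "JS": 0})
        parents, _ = simulate_parents(cfg)
        dosage = parents.dosage.copy()
        dosage[0, 3] = np.nan  # tester missing at locus 3
        parents = rp.GenotypeMatrix(parents.samples, parents.loci, dosage)
        panel, design, _ = simulate_testcross(parents, cfg)
        hyb = [s for s, g in design.assignments.items() if g == "JG"]
        assert np.isnan(panel.subset_samples(hyb).dosage[:, 3]).all()

    def test_expected_het_table(self):
        t = np.array([0.0, 1.0, 0.0, 1.0, 2.0])
        d = np.array([2.0, 1.0, 0.0, 0.0, 2.0])
        np.testing.assert_allclose(
            expected_offspring_het(t, d), [1.0, 0.5, 0.0, 0.5, 0.0]
        )

    def test_interspecific_signature_raises_panel_ho(self):
        # with equal parent het rates the divergence term is what pushes the
        # panel's mean Ho above the mid-parent mean
        cfg = rp.SimulationConfig(
            n_loci=2000,
            tester_het_rate=0.5,
            donor_het_rate=0.5,
            fixed_divergence_rate=0.3,
            seed=13,
        )
        parents, _ = simulate_parents(cfg)
        panel, design, _ = simulate_testcross(parents, cfg)
        _, ho_ind = rp.observed_het(panel)
        parent_idx = panel.sample_indices(parents.samples)
        mid_parent = ho_ind[parent_idx].mean()
        assert ho_ind.mean() > mid_parent


class TestDualCallsets:
    def test_clean_emulation_shared_columns_identical(self):
        cfg = _cfg(missing_rate=0.0, genotype_error_rate=0.0, coding_flip_prob=0.0, seed=4)
        sim = rp.simulate_panel(cfg)
        moc, mid = sim["gm_moc"], sim["gm_mid"]
        for m, d, flip in sim["truth"].pairing.values:
            a = moc.dosage[:, moc.locus_indices([m])[0]]
            b = mid.dosage[:, mid.locus_indices([d])[0]]
            assert not flip
            np.testing.assert_array_equal(a, b)

    def test_full_flip_emulation(self):
        cfg = _cfg(missing_rate=0.0, genotype_error_rate=0.0, coding_flip_prob=1.0, seed=4)
        sim = rp.simulate_panel(cfg)
        moc, mid = sim["gm_moc"], sim["gm_mid"]
        for m, d, flip in sim["truth"].pairing.values:
            a = moc.dosage[:, moc.locus_indices([m])[0]]
            b = mid.dosage[:, mid.locus_indices([d])[0]]
            assert flip
            np.testing.assert_array_equal(a, 2.0 - b)

    def test_overlap_fraction_and_privacy(self, default_sim):
        moc, mid = default_sim["gm_moc"], default_sim["gm_mid"]
        pairing = default_sim["truth"].pairing
        assert len(pairing) == round(0.40 * 1200)
        # private loci appear in exactly one set
        assert not (set(moc.loci) & set(mid.loci))

    def test_mid_sorted_by_scaffold(self, default_sim):
        keys = [(l.seq_name, l.pos) for l in default_sim["loci_mid"]]
        assert keys == sorted(keys)

    def test_noise_is_single_step(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(200, 50)).astype(float)
        noisy = add_genotype_noise(dosage, missing_rate=0.0, error_rate=0.5, rng=rng)
        diff = np.abs(noisy - dosage)
        assert diff.max() == 1.0  # never 0 <-> 2 in one step
        assert set(np.unique(noisy)) <= {0.0, 1.0, 2.0}


def _sim_checksum(seed):
    sim = rp.simulate_panel(rp.SimulationConfig(n_loci=300, seed=seed))
    h = hashlib.sha256()
    for key in ("panel", "gm_moc", "gm_mid"):
        h.update(np.nan_to_num(sim[key].dosage, nan=-1.0).tobytes())
        h.update("".join(sim[key].loci).encode())
    h.update(sim["truth"].pairing.to_csv().encode())
    return h.hexdigest()


def test_same_seed_bit_identical_different_seed_not():
    assert _sim_checksum(42) == _sim_checksum(42)
    assert _sim_checksum(42) != _sim_checksum(43)


def test_invalid_config_rejected():
    with pytest.raises(rp.PanelError):
        rp.SimulationConfig(missing_rate=1.5)
    with pytest.raises(rp.PanelError):
        rp.SimulationConfig(n_loci=0)
    with pytest.raises(rp.PanelError):
        rp.SimulationConfig(family_sizes={"JG": -1, "JT": 0, "JS": 0})
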