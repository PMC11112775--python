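import numpy as np
import pandas as pd
import pytest

from admixsib import (
    PhenotypeGenConfig,
    make_family,
    make_founder,
    meiosis,
    simulate_ancestral_freqs,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_population,
)


class TestAncestralFreqs:
    def test_zero_fst_gives_identical_frequencies(self, gmap_small):
        fr = simulate_ancestral_freqs(200, 0.0, gmap_small, seed=1)
        assert np.array_equal(fr.f1, fr.f2)

    def test_balding_nichols_variance(self, gmap_small):
        """With a fixed base frequency p, Var(f) = fst * p * (1 - p)."""
        fr = simulate_ancestral_freqs(
            50_000, 0.1, gmap_small, base_freq_dist=(0.5, 0.5), seed=2
        )
        assert fr.f1.var() == pytest.approx(0.1 * 0.25, rel=0.05)
        assert fr.f2.var() == pytest.approx(0.1 * 0.25, rel=0.05)

    def test_construction_invariants(self, gmap_small):
        fr = simulate_ancestral_freqs(500, 0.3, gmap_small, seed=3)
        assert np.all((fr.f1 >= 0) & (fr.f1 <= 1))
        order = np.lexsort((fr.pos, fr.chrom))
        assert np.array_equal(order, np.arange(len(order)))

    def test_invalid_fst_rejected(self, gmap_small):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                simulate_ancestral_freqs(10, bad, gmap_small)


class TestFounders:
    def test_unadmixed_founder_is_single_ancestry(self, gmap_small):
        f = make_founder(1.0, 5, gmap_small, seed=1)
        assert f.q_true(gmap_small) == 1.0
        f0 = make_founder(0.0, 5, gmap_small, seed=1)
        assert f0.q_true(gmap_small) == 0.0

    def test_founder_mean_ancestry(self, gmap_small):
        rng = np.random.default_rng(4)
        qs = [make_founder(0.75, 5, gmap_small, rng).q_true(gmap_small) for _ in range(800)]
        assert np.mean(qs) == pytest.approx(0.75, abs=0.01)

    def test_founder_breakpoint_rate(self, gmap_full):
        """Poisson tract process: ~ admix_generations * map length switches per haplotype."""
        rng = np.random.default_rng(5)
        n_bp = [
            make_founder(0.5, 5, gmap_full, rng).hap_pat.n_breakpoints()
            for _ in range(60)
        ]
        # label switches occur at a Poisson(5/M) boundary only when the new
        # segment's ancestry draw differs: rate is 5 * P(switch) = 5 * 2*q*(1-q)
        expected = 5 * gmap_full.total_length * 2 * 0.5 * 0.5
        assert np.mean(n_bp) == pytest.approx(expected, rel=0.1)

    def test_tracts_tile_and_q_consistent(self, gmap_small):
        rng = np.random.default_rng(6)
        for _ in range(20):
            f = make_founder(float(rng.uniform()), 5, gmap_small, rng)
            f.hap_pat.validate(gmap_small)
            f.hap_mat.validate(gmap_small)
            assert 0 <= f.q_true(gmap_small) <= 1


class TestMeiosis:
    def test_uniform_parent_gives_uniform_gamete(self, gmap_small):
        p = make_founder(1.0, 5, gmap_small, seed=1)
        gam = meiosis(p, gmap_small, seed=2)
        gam.validate(gmap_small)
        assert gam.label_fraction(gmap_small, 1) == 1.0

    def test_f1_parent_gamete_mean_half(self, gmap_small):
        rng = np.random.default_rng(7)
        f1_parent = make_family("F", 1.0, 0.0, 1, gmap_small, rng)[2]
        fracs = [
            meiosis(f1_parent, gmap_small, rng).label_fraction(gmap_small, 1)
            for _ in range(500)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)

    def test_sibling_dq_sd_matches_grid_oracle(self, gmap_small):
        """Tract-based sibling ancestry differences agree with a tract-free
        locus-by-locus Markov-walk simulation of recombination."""
        rng = np.random.default_rng(8)
        n_pairs = 400

        # package path: both parents F1 (pure-1 x pure-2 cross), two kids each
        f1_parents = make_family("A", 1.0, 0.0, 2, gmap_small, rng)[2:]
        p1, p2 = f1_parents
        dq_pkg = []
        for _ in range(n_pairs):
            kids = []
            for _k in range(2):
                hp = meiosis(p1, gmap_small, rng)
                hm = meiosis(p2, gmap_small, rng)
                kids.append(
                    0.5 * (hp.label_fraction(gmap_small, 1) + hm.label_fraction(gmap_small, 1))
                )
            dq_pkg.append(kids[0] - kids[1])

        # oracle: Haldane two-state Markov walk on a dense marker grid, no
        # tract bookkeeping at all (an F1 gamete's local ancestry flips at
        # rate 1 per Morgan; marker spacing `step`)
        step = 0.01
        grid = int(1.0 / step)
        p_switch = 0.5 * (1 - np.exp(-2 * step))

        def gamete_anc_fraction() -> float:
            frac = 0.0
            for _c in range(4):
                start = int(rng.integers(2))
                switches = rng.random(grid - 1) < p_switch
                states = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
                frac += float(np.mean(states))
            return frac / 4.0

        dq_oracle = []
        for _ in range(n_pairs):
            kids = [
                0.5 * (gamete_anc_fraction() + gamete_anc_fraction()) for _k in range(2)
            ]
            dq_oracle.append(kids[0] - kids[1])

        sd_pkg = np.std(dq_pkg)
        sd_oracle = np.std(dq_oracle)
        assert sd_pkg == pytest.approx(sd_oracle, rel=0.2)


class TestPopulation:
    def test_unadmixed_family_offspring(self, gmap_small):
        rng = np.random.default_rng(9)
        fam = make_family("F", 1.0, 1.0, 3, gmap_small, rng)
        for kid in fam[2:]:
            assert kid.q_true(gmap_small) == 1.0

    def test_f1_offspring_exactly_half(self, gmap_small):
        rng = np.random.default_rng(10)
        fam = make_family("F", 1.0, 0.0, 4, gmap_small, rng)
        for kid in fam[2:]:
            assert kid.q_true(gmap_small) == pytest.approx(0.5, abs=1e-12)

    def test_default_population_dq_mostly_small(self):
        pop = simulate_population(300, seed=20)
        ped = pop.pedigree_frame()
        dq = []
        for a, b in pop.sibling_pairs():
            qa, qb = ped.loc[a, "q_true"], ped.loc[b, "q_true"]
            if 0.05 < qa < 0.95 or 0.05 < qb < 0.95:  # admixed pairs only
                dq.append(abs(qa - qb))
        dq = np.array(dq)
        assert (dq < 0.05).mean() > 0.8
        assert dq.max() < 0.2

    def test_population_mean_ancestry_near_071(self):
        pop = simulate_population(300, seed=21)
        q = pop.pedigree_frame()["q_true"]
        assert q.mean() == pytest.approx(0.71, abs=0.03)

    def test_degenerate_sibs_per_family_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(5, sibs_per_family={1: 1.0})

    def test_q_true_matches_tracts(self, small_population):
        pop, _, _ = small_population
        ped = pop.pedigree_frame()
        for ind in pop.individuals[:20]:
            recomputed = 0.5 * (
                ind.hap_pat.label_fraction(pop.gmap, 1)
                + ind.hap_mat.label_fraction(pop.gmap, 1)
            )
            assert ped.loc[ind.iid, "q_true"] == pytest.approx(recomputed, abs=1e-12)


class TestGenotypes:
    def test_fixed_loci_give_fixed_genotypes(self, gmap_small):
        from admixsib.simpop import AncestralFreqs

        f = make_founder(1.0, 5, gmap_small, seed=1)
        freqs = AncestralFreqs(
            chrom=np.zeros(10, dtype=int), pos=np.linspace(0.05, 0.95, 10),
            f1=np.ones(10), f2=np.zeros(10), fst=0.0, gmap=gmap_small,
        )
        G = simulate_genotypes([f], freqs, seed=2)
        assert np.all(G == 2)

    def test_unadmixed_sample_frequency_matches_f1(self, gmap_small):
        rng = np.random.default_rng(30)
        inds = [make_founder(1.0, 5, gmap_small, rng, iid=f"i{k}") for k in range(300)]
        freqs = simulate_ancestral_freqs(60, 0.25, gmap_small, seed=31)
        G = simulate_genotypes(inds, freqs, seed=32)
        sample_freq = G.mean(axis=0) / 2
        se = np.sqrt(freqs.f1 * (1 - freqs.f1) / (2 * 300))
        assert np.all(np.abs(sample_freq - freqs.f1) < 5 * np.maximum(se, 0.005))

    def test_sibling_genotypes_share_ibd_alleles(self, small_population):
        """Sibling genotype concordance exceeds that of unrelated individuals."""
        pop, freqs, G = small_population
        ids = [i.iid for i in pop.individuals]
        loc = {x: i for i, x in enumerate(ids)}
        sib_agree = np.mean(
            [(G[loc[a]] == G[loc[b]]).mean() for a, b in pop.sibling_pairs()[:20]]
        )
        off = pop.offspring
        unrel = [
            (off[i], off[j])
            for i in range(0, 20, 2)
            for j in (i + 1,)
            if off[i].fid != off[j].fid
        ]
        unrel_agree = np.mean(
            [(G[loc[a.iid]] == G[loc[b.iid]]).mean() for a, b in unrel]
        )
        assert sib_agree > unrel_agree + 0.05

    def test_missing_rate(self, small_population):
        pop, freqs, _ = small_population
        G = simulate_genotypes(pop, freqs, seed=40, missing_rate=0.1)
        assert (G == -1).mean() == pytest.approx(0.1, abs=0.01)


class TestPhenotypes:
    @staticmethod
    def _sib_table(seed=50):
        pop = simulate_population(40, seed=seed)
        ped = pop.pedigree_frame()
        off = [i.iid for i in pop.offspring]
        return ped.loc[off].copy()

    def test_noiseless_is_linear_in_q(self):
        sibs = self._sib_table()
        cfg = PhenotypeGenConfig(dg=2.5, sigma=0.0, seed=1)
        out = simulate_phenotypes(sibs, cfg)
        assert np.allclose(out["y"], 2.5 * out["q_true"])

    def test_individual_mode_pair_difference_identity(self):
        """With no noise, within-pair differences are (dG + E_anc) * dQ exactly."""
        sibs = self._sib_table()
        cfg = PhenotypeGenConfig(
            dg=1.0, sigma=0.0, e_anc=0.7, e_anc_mode="individual", seed=2
        )
        out = simulate_phenotypes(sibs, cfg).set_index("iid")
        for fid, grp in out.groupby("fid"):
            ids = list(grp.index)
            dy = out.loc[ids[0], "y"] - out.loc[ids[1], "y"]
            dq = out.loc[ids[0], "q_true"] - out.loc[ids[1], "q_true"]
            assert dy == pytest.approx(1.7 * dq, abs=1e-12)

    def test_family_mode_adds_family_level_term(self):
        sibs = self._sib_table()
        cfg = PhenotypeGenConfig(dg=1.0, sigma=0.0, e_anc=3.0, e_anc_mode="family", seed=3)
        out = simulate_phenotypes(sibs, cfg)
        qbar = out.groupby("fid")["q_true"].transform("mean")
        assert np.allclose(out["y"], out["q_true"] + 3.0 * qbar)

    def test_mode_coefficient_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeGenConfig(e_anc=1.0, e_anc_mode="none")

    def test_environment_independent_of_dq(self):
        """Family random effects and family-mode environment cancel in pair
        differences, so they cannot correlate with sibling ancestry contrasts."""
        sibs = self._sib_table(seed=51)
        cfg = PhenotypeGenConfig(
            dg=0.0, sigma=0.0, sigma_family=2.0, e_anc=2.0, e_anc_mode="family", seed=4
        )
        out = simulate_phenotypes(sibs, cfg).set_index("iid")
        dys, dqs = [], []
        for fid, grp in out.groupby("fid"):
            ids = sorted(grp.index)
            dys.append(out.loc[ids[0], "y"] - out.loc[ids[1], "y"])
            dqs.append(out.loc[ids[0], "q_true"] - out.loc[ids[1], "q_true"])
        assert np.allclose(dys, 0.0)  # exact cancellation within families
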