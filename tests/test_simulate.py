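"""Tetrasomic meiosis, crossing, phenotype simulation and the breeding program."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from tetragp.heritability import anova_ems_components
from tetragp.simulate import (
    MAX_ALPHA_DR,
    SimConfig,
    cross,
    gamete_dosage_pmf,
    make_gamete,
    simulate_breeding_program,
    simulate_phenotypes,
)


def constant_parent(dosage: int, m: int) -> np.ndarray:
    """(4, m) parent with the same dosage at every locus."""
    col = np.array([1] * dosage + [0] * (4 - dosage), dtype=np.int8)
    return np.tile(col[:, None], (1, m))


class TestMakeGamete:
    def test_homozygote_parent_fixed_gamete(self, rng):
        for dosage, expect in ((4, 2), (0, 0)):
            parent = constant_parent(dosage, 500)
            gam = make_gamete(parent, MAX_ALPHA_DR, rng)
            assert gam.shape == (2, 500)
            assert (gam.sum(axis=0) == expect).all()

    def test_simplex_alpha0_never_produces_aa(self, rng):
        # without double reduction a single A copy cannot be duplicated
        parent = constant_parent(1, 50_000)
        gam = make_gamete(parent, 0.0, rng)
        assert gam.sum(axis=0).max() <= 1

    def test_duplex_alpha0_aa_frequency_one_sixth(self, rng):
        # 2 of 4 without replacement from AAOO: P(AA) = 1/C(4,2) = 1/6
        parent = constant_parent(2, 50_000)
        counts = np.bincount(make_gamete(parent, 0.0, rng).sum(axis=0), minlength=3)
        assert chisquare(counts, 50_000 * np.array([1 / 6, 4 / 6, 1 / 6])).pvalue > 0.01

    def test_simplex_aa_frequency_alpha_over_four(self, rng):
        # AA from AOOO only via duplicating the single A: P = alpha * 1/4
        alpha = MAX_ALPHA_DR
        parent = constant_parent(1, 200_000)
        dosages = make_gamete(parent, alpha, rng).sum(axis=0)
        counts = np.bincount(dosages, minlength=3)
        p2 = alpha / 4
        p0 = (1 - alpha) / 2 + alpha * 3 / 4
        p1 = 1 - p0 - p2
        assert chisquare(counts, 200_000 * np.array([p0, p1, p2])).pvalue > 0.01

    def test_alpha_out_of_range_rejected(self, rng):
        parent = constant_parent(2, 5)
        with pytest.raises(ValueError, match="1/6"):
            make_gamete(parent, 0.2, rng)
        with pytest.raises(ValueError):
            make_gamete(parent, -0.01, rng)

    @given(
        dosage=st.integers(min_value=0, max_value=4),
        alpha=st.floats(min_value=0.0, max_value=MAX_ALPHA_DR),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    @settings(max_examples=40, deadline=None)
    def test_gamete_conserves_parental_alleles(self, dosage, alpha, seed):
        """A gamete only carries alleles the parent has: without double
        reduction its A count is bounded by sampling 2 of the parent's 4
        copies; with it, at most one parental copy can be doubled."""
        parent = constant_parent(dosage, 200)
        gam = make_gamete(parent, alpha, np.random.default_rng(seed)).sum(axis=0)
        if dosage == 0:
            assert (gam == 0).all()
        elif dosage == 4:
            assert (gam == 2).all()
        elif alpha == 0.0:
            assert gam.max() <= min(2, dosage)
            assert gam.min() >= max(0, dosage - 2)
        else:
            assert gam.max() <= 2

    def test_pmf_oracle_sums_to_one(self):
        for d in range(5):
            pmf = gamete_dosage_pmf(d, 0.1)
            assert pmf.sum() == pytest.approx(1.0)
            assert (pmf >= 0).all()


class TestCross:
    def test_homozygote_cross_gives_duplex_offspring(self, rng):
        p1, p2 = constant_parent(4, 100), constant_parent(0, 100)
        offs = cross(p1, p2, 20, MAX_ALPHA_DR, rng)
        assert offs.shape == (20, 4, 100)
        assert (offs.sum(axis=1) == 2).all()

    def test_zero_offspring_gives_empty_family(self, rng):
        offs = cross(constant_parent(2, 10), constant_parent(2, 10), 0, 0.0, rng)
        assert offs.shape == (0, 4, 10)

    def test_mismatched_marker_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="10.*12|12.*10"):
            cross(constant_parent(2, 10), constant_parent(2, 12), 5, 0.0, rng)

    @pytest.mark.parametrize("alpha", [0.0, MAX_ALPHA_DR])
    def test_duplex_duplex_offspring_distribution(self, alpha, rng):
        """Offspring dosage from AAOO x AAOO follows the convolution of the
        two gamete A-count distributions (chi-square non-rejection)."""
        parent = constant_parent(2, 50_000)
        offs = cross(parent, parent, 1, alpha, rng)[0]
        dosage = offs.sum(axis=0)
        gam = gamete_dosage_pmf(2, alpha)
        expected = np.convolve(gam, gam)  # dosage 0..4
        counts = np.bincount(dosage, minlength=5)
        assert chisquare(counts, 50_000 * expected).pvalue > 0.01


class TestSimulatePhenotypes:
    def test_exact_when_only_genetics(self, rng):
        g = pd.Series([1.0, -2.0, 0.5], index=["a", "b", "c"])
        design = pd.DataFrame(
            [(i, loc, 2) for i in g.index for loc in ("L1", "L2")],
            columns=["genotype", "location", "n_reps"],
        )
        ph = simulate_phenotypes(g, design, mu=10.0, rng=rng)
        merged = ph.merge(g.rename("g"), left_on="genotype", right_index=True)
        assert np.allclose(merged["value"], 10.0 + merged["g"])

    def test_negative_variance_rejected(self, rng):
        g = pd.Series([0.0], index=["a"])
        design = pd.DataFrame([("a", "L1", 1)], columns=["genotype", "location", "n_reps"])
        with pytest.raises(ValueError, match="sigma2_e"):
            simulate_phenotypes(g, design, sigma2_e=-1.0, rng=rng)

    def test_component_recovery_by_moments(self, rng):
        """2,000 genotypes x 3 locations x 2 reps: ANOVA moment estimates of
        the simulated components land within 10% of the inputs."""
        n = 2000
        ids = [f"g{i}" for i in range(n)]
        g = pd.Series(rng.normal(0, 1, n), index=ids)
        design = pd.DataFrame(
            [(i, loc, 2) for i in ids for loc in ("A", "B", "C")],
            columns=["genotype", "location", "n_reps"],
        )
        ph = simulate_phenotypes(
            g, design, mu=5, sigma2_loc=0.5, sigma2_gxe=0.5, sigma2_e=1.0, rng=rng
        )
        est = anova_ems_components(ph, "TW")
        assert est.sigma2_g == pytest.approx(float(g.var()), rel=0.10)
        assert est.sigma2_gxe == pytest.approx(0.5, rel=0.10)
        assert est.sigma2_E == pytest.approx(1.0, rel=0.10)

    def test_no_genetic_signal_gives_null_correlation(self, rng):
        n = 500
        ids = [f"g{i}" for i in range(n)]
        zero_g = pd.Series(np.zeros(n), index=ids)
        design = pd.DataFrame(
            [(i, "A", 2) for i in ids], columns=["genotype", "location", "n_reps"]
        )
        ph = simulate_phenotypes(zero_g, design, sigma2_e=1.0, rng=rng)
        means = ph.groupby("genotype")["value"].mean()
        independent_g = pd.Series(rng.normal(0, 1, n), index=ids)
        r = np.corrcoef(means.loc[ids], independent_g)[0, 1]
        assert abs(r) < 3.5 / np.sqrt(n)


class TestBreedingProgram:
    def test_default_config_matches_published_cohort_sizes(self):
        cfg = SimConfig()
        assert sum(cfg.family_sizes) == 465
        assert cfg.generation_sizes == (138, 62)

    def test_generation_labels_partition_samples(self, small_sim):
        all_ids = [i for ids in small_sim.populations.values() for i in ids]
        assert sorted(all_ids) == sorted(small_sim.genotypes.sample_ids)
        assert len(all_ids) == len(set(all_ids))

    def test_pedigree_every_nonfounder_has_two_parents(self, small_sim):
        ped = small_sim.pedigree.set_index("id")
        founders_checks = set(small_sim.populations["parent"]) | set(
            small_sim.populations["check"]
        )
        for sid in small_sim.genotypes.sample_ids:
            p1, p2 = ped.loc[sid, ["parent1", "parent2"]]
            if sid in founders_checks:
                assert p1 == "NA" and p2 == "NA"
            else:
                assert p1 != "NA" and p2 != "NA"

    def test_checks_phenotyped_at_every_location(self, small_sim):
        ph = small_sim.phenotypes
        locs = set(ph["location"])
        for c in small_sim.populations["check"]:
            assert set(ph[ph["genotype"] == c]["location"]) == locs

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(
            n_markers=120, family_sizes=(8, 8, 10, 10, 8),
            generation_sizes=(12, 5), seed=77,
        )
        a = simulate_breeding_program(cfg)
        b = simulate_breeding_program(cfg)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_series_equal(a.true_values, b.true_values)

    def test_truncation_selection_raises_genetic_mean(self):
        """Selected T2 exceeds unselected T1 in mean true genetic value when
        selection bites (fraction 0.3, heritable trait), averaged over 50
        seeded replicates; at fraction 1 the differential vanishes."""
        diffs = {0.3: [], 1.0: []}
        for frac in diffs:
            for seed in range(50):
                cfg = SimConfig(
                    n_markers=100,
                    family_sizes=(6, 6, 8, 8, 6),
                    generation_sizes=(10, 4),
                    selection_fraction=frac,
                    seed=seed,
                )
                sim = simulate_breeding_program(cfg)
                t1 = [i for f in ("T1-A", "T1-B", "T1-C", "T1-D", "T1-E")
                      for i in sim.populations[f]]
                d = sim.true_values[sim.populations["T2"]].mean() - sim.true_values[t1].mean()
                diffs[frac].append(d)
        assert np.mean(diffs[0.3]) > 0.2
        assert abs(np.mean(diffs[1.0])) < np.mean(diffs[0.3]) / 2

    def test_missing_rate_masks_calls(self):
        cfg = SimConfig(
            n_markers=200, family_sizes=(8, 8, 10, 10, 8),
            generation_sizes=(10, 4), missing_rate=0.05, seed=3,
        )
        sim = simulate_breeding_program(cfg)
        rate = sim.genotypes.dosages.isna().to_numpy().mean()
        assert 0.03 < rate < 0.07

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(alpha_dr=0.5)
        with pytest.raises(ValueError):
            SimConfig(sigma2_g=-1)
        with pytest.raises(ValueError):
            SimConfig(family_sizes=(0, 1, 1, 1, 1))
        with pytest.raises(ValueError):
            SimConfig(selection_fraction=0.0)
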