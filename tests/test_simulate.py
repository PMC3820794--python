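"""Coalescent engine, masking/haploidization and reference-table assembly."""

import numpy as np
import pytest

from divabc.demographic_models import (
    ParameterDraw,
    ScalingConvention,
    build_model,
)
from divabc.simulate import (
    MISSING,
    DatasetRates,
    HaplotypeMatrix,
    LocusEngine,
    LocusSpec,
    LocusSet,
    apply_mask_and_haploidize,
    draw_locus_rates,
    simulate_dataset,
    simulate_locus,
    simulate_reference_table,
)

SCALING = ScalingConvention()


def panmictic_model(n=20_000.0, t_split=1.0):
    """Effectively one population: split one generation ago, equal sizes."""
    draw = ParameterDraw(
        "ICS",
        {
            "N_coll": n,
            "N_pied": n,
            "N_anc": n,
            "T_split": t_split,
            "mu": 1e-8,
            "r": 5.3e-8,
            "alpha": 3.0,
        },
    )
    return build_model("ICS", draw, SCALING)


def split_model(t_split, n=20_000.0, mu=1e-8):
    draw = ParameterDraw(
        "ICS",
        {
            "N_coll": n,
            "N_pied": n,
            "N_anc": n,
            "T_split": t_split,
            "mu": mu,
            "r": 5.3e-8,
            "alpha": 3.0,
        },
    )
    return build_model("ICS", draw, SCALING)


class TestEnginePaths:
    def test_fast_path_ancestry_identical_to_public_api(self):
        """The cached low-level path reproduces msprime.sim_ancestry exactly."""
        model = split_model(3e5)
        fast = LocusEngine(model, 500, use_fast_path=True)
        slow = LocusEngine(model, 500, use_fast_path=False)
        assert fast.use_fast_path  # the low-level interface is available
        for seed in (11, 5123, 999_983):
            t_fast = fast.sim_ancestry(5.3e-8, seed).dump_tables()
            t_slow = slow.sim_ancestry(5.3e-8, seed).dump_tables()
            t_fast.provenances.clear()
            t_slow.provenances.clear()
            assert t_fast == t_slow

    def test_mutation_counts_match_poisson_expectation(self):
        """Fast-path mutation totals track theta within Monte-Carlo error."""
        model = panmictic_model()
        engine = LocusEngine(model, 500)
        mu = 1e-8
        counts = [engine.simulate(mu, 0.0, s + 1)[0].shape[1] for s in range(800)]
        # Watterson: E[S] = 4*N*mu*L * a1(n) for n=40 lineages
        a1 = np.sum(1.0 / np.arange(1, 40))
        expected = 4 * 20_000 * mu * 500 * a1
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_zero_recombination_yields_single_genealogy(self):
        model = panmictic_model()
        engine = LocusEngine(model, 500)
        ts = engine.sim_ancestry(0.0, 42)
        assert ts.num_trees == 1

    def test_negative_rates_rejected(self):
        engine = LocusEngine(panmictic_model(), 100)
        with pytest.raises(ValueError):
            engine.simulate(-1e-9, 0.0, 1)


class TestNeutralityProperties:
    def test_mean_tajimas_d_near_zero_under_constant_size(self):
        """Neutral constant-size coalescent: E[D] ~ 0 across replicate loci."""
        from divabc.sumstats import tajimas_d

        model = panmictic_model()
        engine = LocusEngine(model, 500)
        values = []
        for seed in range(1, 1001):
            alleles, _ = engine.simulate(1e-8, 5.3e-8, seed)
            if alleles.shape[1] == 0:
                continue
            ok = np.ones(alleles.shape[1], dtype=bool)
            d = tajimas_d(alleles, ok)
            if not np.isnan(d):
                values.append(d)
        values = np.array(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean()) < 3 * se

    def test_fst_approaches_one_for_deep_splits(self):
        from divabc.sumstats import fst

        model = split_model(4e6, n=5_000.0)
        engine = LocusEngine(model, 500)
        values = []
        for seed in range(1, 201):
            alleles, _ = engine.simulate(1e-8, 0.0, seed)
            if alleles.shape[1] == 0:
                continue
            ok = np.ones(alleles.shape[1], dtype=bool)
            f = fst(alleles[:20], alleles[20:], ok)
            if not np.isnan(f):
                values.append(f)
        assert np.mean(values) > 0.9

    def test_fst_monotone_in_split_time(self):
        """Mean F_ST rises with divergence time on a three-point grid."""
        from divabc.sumstats import fst

        means = []
        for t_split in (2e4, 2e5, 2e6):
            model = split_model(t_split)
            engine = LocusEngine(model, 500)
            values = []
            for seed in range(1, 301):
                alleles, _ = engine.simulate(1e-8, 5.3e-8, seed)
                if alleles.shape[1] == 0:
                    continue
                ok = np.ones(alleles.shape[1], dtype=bool)
                f = fst(alleles[:20], alleles[20:], ok)
                if not np.isnan(f):
                    values.append(f)
            means.append(np.mean(values))
        assert means[0] < means[1] < means[2]


class TestLocusRates:
    def test_gamma_concentrates_at_large_shape(self, rng):
        rates = DatasetRates(mean_mu=1.4e-9, mean_r=5.3e-8, alpha=1e6)
        locus = LocusSpec("l0", 500)
        draws = np.array(
            [draw_locus_rates(rates, locus, rng)[0] for _ in range(1000)]
        )
        assert np.all(np.abs(draws / 1.4e-9 - 1) < 0.01)

    def test_gamma_mean_and_variance(self, rng):
        rates = DatasetRates(mean_mu=1.4e-9, mean_r=5.3e-8, alpha=2.0)
        locus = LocusSpec("l0", 500)
        draws = np.array(
            [draw_locus_rates(rates, locus, rng)[0] for _ in range(100_000)]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 1.4e-9) < 3 * se
        assert draws.var(ddof=1) == pytest.approx(1.4e-9**2 / 2.0, rel=0.05)

    def test_local_recombination_mean_rescaled(self, rng):
        # a locus with twice the genome-wide mean keeps its relative rate
        rates = DatasetRates(mean_mu=1.4e-9, mean_r=5.3e-8, alpha=1e6)
        locus = LocusSpec("l0", 500, local_r_mean=1.06e-7)
        _, r = draw_locus_rates(rates, locus, rng)
        assert r == pytest.approx(1.06e-7, rel=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            DatasetRates(mean_mu=0.0, mean_r=5.3e-8, alpha=2.0)


class TestMaskAndHaploidize:
    @staticmethod
    def _raw_matrix(rng, n_ind=10, n_sites=6, length=50):
        alleles = rng.integers(0, 2, size=(2 * n_ind, n_sites)).astype(np.int8)
        positions = np.sort(
            rng.choice(length, size=n_sites, replace=False)
        ).astype(np.int64)
        return HaplotypeMatrix(
            alleles=alleles,
            positions=positions,
            length=length,
            n_per_species=(n_ind // 2, n_ind - n_ind // 2),
            haploid=False,
            n_assayable={"coll": length, "pied": length, "joint": length},
        )

    def test_allfalse_mask_keeps_everything(self, rng):
        raw = self._raw_matrix(rng)
        locus = LocusSpec("l0", 50, n_per_species=(5, 5))
        out = apply_mask_and_haploidize(raw, locus, rng, min_called=2)
        assert out.haploid
        assert out.alleles.shape == (10, 6)
        assert not np.any(out.alleles == MISSING)
        # each output allele is one of the individual's two input alleles
        for ind in range(10):
            for col in range(6):
                assert out.alleles[ind, col] in (
                    raw.alleles[2 * ind, col],
                    raw.alleles[2 * ind + 1, col],
                )

    def test_homozygous_site_is_deterministic(self, rng):
        raw = self._raw_matrix(rng)
        raw.alleles[0, :] = raw.alleles[1, :] = 1  # individual 0 homozygous
        locus = LocusSpec("l0", 50, n_per_species=(5, 5))
        results = {
            apply_mask_and_haploidize(
                raw, locus, np.random.default_rng(s), min_called=2
            ).alleles[0].tobytes()
            for s in range(5)
        }
        assert len(results) == 1

    def test_masked_cells_become_missing(self, rng):
        raw = self._raw_matrix(rng, n_ind=20, n_sites=4, length=30)
        mask = np.zeros((20, 30), dtype=bool)
        # hide the first variant site for 4 of the 10 coll individuals
        site = int(raw.positions[0])
        mask[0:4, site] = True
        locus = LocusSpec("l0", 30, mask=mask, n_per_species=(10, 10))
        out = apply_mask_and_haploidize(raw, locus, rng, min_called=7)
        assert np.all(out.alleles[0:4, 0] == MISSING)
        called_coll = (out.alleles[:10, 0] != MISSING).sum()
        assert called_coll == 6  # below the 7-called threshold
        ok = locus.assayable_sites(7)
        assert not ok["coll"][site]
        assert out.n_assayable["coll"] == 29

    def test_dimension_mismatch_rejected(self, rng):
        raw = self._raw_matrix(rng)
        locus = LocusSpec("l0", 49, n_per_species=(5, 5))
        with pytest.raises(ValueError):
            apply_mask_and_haploidize(raw, locus, rng)

    def test_double_haploidization_rejected(self, rng):
        raw = self._raw_matrix(rng)
        locus = LocusSpec("l0", 50, n_per_species=(5, 5))
        out = apply_mask_and_haploidize(raw, locus, rng, min_called=2)
        with pytest.raises(ValueError):
            apply_mask_and_haploidize(out, locus, rng)


class TestReferenceTable:
    def test_same_seed_reproduces_table_exactly(self, tiny_locus_set):
        t1 = simulate_reference_table("ICS", tiny_locus_set, 8, root_seed=3)
        t2 = simulate_reference_table("ICS", tiny_locus_set, 8, root_seed=3)
        assert t1.df.equals(t2.df)

    def test_rows_depend_only_on_their_index(self, tiny_locus_set):
        """Counter-based seeding: a prefix run equals the full run's prefix."""
        small = simulate_reference_table("ICS", tiny_locus_set, 3, root_seed=3)
        big = simulate_reference_table("ICS", tiny_locus_set, 6, root_seed=3)
        assert small.df.equals(big.df.iloc[:3].reset_index(drop=True))

    def test_round_trip_through_tsv(self, tiny_locus_set, tmp_path):
        from divabc.abc_glm import ReferenceTable

        table = simulate_reference_table("ICS", tiny_locus_set, 5, root_seed=9)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = ReferenceTable.from_tsv(path)
        assert back.stat_names == table.stat_names
        assert np.allclose(back.stats(), table.stats())
        assert back.priors["ICS"] == table.priors["ICS"]

    def test_checkpoint_resume_reproduces_the_full_table(
        self, tiny_locus_set, tmp_path
    ):
        """Interrupted-and-resumed builds equal a single fresh build."""
        ckpt = tmp_path / "partial.tsv"
        partial = simulate_reference_table(
            "ICS", tiny_locus_set, 4, root_seed=3,
            checkpoint_path=ckpt, checkpoint_every=2,
        )
        assert ckpt.exists()  # flushed at least once
        resumed = simulate_reference_table(
            "ICS", tiny_locus_set, 8, root_seed=3,
            checkpoint_path=ckpt, checkpoint_every=2,
        )
        fresh = simulate_reference_table("ICS", tiny_locus_set, 8, root_seed=3)
        np.testing.assert_allclose(
            resumed.df[fresh.stat_names].to_numpy(float),
            fresh.df[fresh.stat_names].to_numpy(float),
            rtol=1e-12,
        )
        assert resumed.df["seed"].tolist() == fresh.df["seed"].tolist()

    def test_masked_dataset_statistics_use_mask_denominators(
        self, tiny_locus_set, rng
    ):
        """The mask transplant changes assayable-site totals, not just SNPs."""
        model = split_model(3e5)
        ds = simulate_dataset(model, tiny_locus_set, rng)
        for locus, matrix in zip(tiny_locus_set, ds.loci):
            expected = {
                k: int(v.sum()) for k, v in locus.assayable_sites(7).items()
            }
            assert matrix.n_assayable == expected
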