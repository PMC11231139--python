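"""Generator correctness: reproducibility, limits, sampling distributions."""

import numpy as np
import pytest

from phylosdm import popgen, seqio, synthetic
from phylosdm.errors import ParameterError
from phylosdm.sdm import write_ascii_grid, read_ascii_grid


class TestAlignmentSimulation:
    def test_bit_reproducible(self):
        cfg = synthetic.SimConfig(seed=5, n_populations=2,
                                  samples_per_population=8)
        a1, p1, t1 = synthetic.simulate_alignment(cfg)
        a2, p2, t2 = synthetic.simulate_alignment(cfg)
        assert a1 == a2 and t1 == t2

    def test_theta_zero_limit_is_monomorphic(self):
        cfg = synthetic.SimConfig(seed=1, n_populations=1,
                                  samples_per_population=10, theta=1e-8)
        aln, _, _ = synthetic.simulate_alignment(cfg)
        assert len(set(aln.sequences)) == 1

    def test_watterson_recovery(self):
        # mean S/a1 over replicates must approach theta (single population)
        theta, n, reps = 5.0, 12, 120
        a1 = popgen._tajima_constants(n)["a1"]
        ests = []
        for rep in range(reps):
            cfg = synthetic.SimConfig(
                seed=100 + rep, n_populations=1, samples_per_population=n,
                theta=theta, locus_length_bp=2000,
            )
            aln, _, _ = synthetic.simulate_alignment(cfg)
            S, _, _ = seqio.count_site_classes(
                aln, seqio.build_site_mask(aln)
            )
            ests.append(S / a1)
        se = np.std(ests, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ests) - theta) < 3 * se + 0.3

    def test_mean_tmrca_matches_msprime_oracle(self):
        """Pair coalescence times agree with an independent simulator."""
        msprime = pytest.importorskip("msprime")
        d, m = 3, 1.0
        cfg = synthetic.SimConfig(
            seed=0, n_populations=d, samples_per_population=2,
            theta=1e-6, migration_rate=m,
        )
        rng = np.random.default_rng(0)
        mine = []
        for _ in range(400):
            parent, time, deme = synthetic.simulate_genealogy(cfg, rng)
            anc = set()
            v = 0
            while v != -1:
                anc.add(v)
                v = parent[v]
            v = 1
            while v not in anc:
                v = parent[v]
            mine.append(time[v])
        demog = msprime.Demography.island_model([1] * d, migration_rate=m)
        theirs = [
            ts.first().tmrca(0, 1)
            for ts in msprime.sim_ancestry(
                samples={0: 2}, demography=demog, ploidy=1,
                num_replicates=400, random_seed=11,
            )
        ]
        se = np.sqrt(
            np.var(mine) / len(mine) + np.var(theirs) / len(theirs)
        )
        assert abs(np.mean(mine) - np.mean(theirs)) < 3.5 * se

    def test_expansion_negative_tajima_d(self):
        ds = []
        for rep in range(40):
            cfg = synthetic.SimConfig(
                seed=300 + rep, n_populations=1, samples_per_population=20,
                theta=10.0, demography="sudden_expansion",
                growth_factor=100.0, expansion_time=0.125,
            )
            aln, _, _ = synthetic.simulate_alignment(cfg)
            mask = seqio.build_site_mask(aln)
            S, _, _ = seqio.count_site_classes(aln, mask)
            diffs, _ = popgen.pairwise_difference_matrix(aln, mask)
            kbar = float(diffs[np.triu_indices(aln.n, 1)].mean())
            if S > 0:
                ds.append(popgen.tajimas_d(S, kbar, aln.n))
        assert np.median(ds) < 0


class TestRasterSimulation:
    def test_zero_deltas_future_equals_current(self):
        cfg = synthetic.SimConfig(
            seed=2, n_layers=3, future_deltas=(0.0, 0.0, 0.0),
            future_noise_sd=0.0,
        )
        cur, futs = synthetic.simulate_rasters(cfg)
        fut = futs["scenario1"]
        for name in cur.layer_names:
            np.testing.assert_array_equal(
                cur.layers[name], fut.layers[name]
            )

    def test_high_correlation_target_triggers_filter(self):
        from phylosdm.sdm import correlation_filter

        cfg = synthetic.SimConfig(seed=3, n_layers=4, layer_correlation=0.95)
        cur, _ = synthetic.simulate_rasters(cfg)
        mask = cur.mask
        rs = [
            abs(np.corrcoef(
                cur.layers[a][mask], cur.layers[b][mask]
            )[0, 1])
            for i, a in enumerate(cur.layer_names)
            for b in cur.layer_names[i + 1:]
        ]
        assert max(rs) > 0.8
        assert len(correlation_filter(cur, r_max=0.8)) < 4

    def test_io_roundtrip_of_generated_stack(self, tmp_path):
        cfg = synthetic.SimConfig(seed=4, n_layers=2, grid_rows=12,
                                  grid_cols=10)
        cur, _ = synthetic.simulate_rasters(cfg)
        for name, arr in cur.layers.items():
            p = tmp_path / f"{name}.asc"
            write_ascii_grid(p, cur.geometry, arr, fmt="%.10e")
            g, back, _ = read_ascii_grid(p)
            assert g == cur.geometry
            np.testing.assert_allclose(back, arr, rtol=1e-9)


class TestOccurrenceSampling:
    def test_point_mass_concentrates(self):
        cfg = synthetic.SimConfig(seed=5, grid_rows=10, grid_cols=10,
                                  n_layers=2)
        cur, _ = synthetic.simulate_rasters(cfg)
        suit = np.zeros((10, 10))
        suit[4, 7] = 1.0
        occ = synthetic.sample_occurrences(suit, cur, 15, seed=1)
        cells = {tuple(c) for c in occ.snap_to_cells(cur)}
        assert cells == {(4, 7)}

    def test_uniform_suitability_spreads(self):
        from scipy.stats import chisquare

        cfg = synthetic.SimConfig(seed=6, grid_rows=10, grid_cols=10,
                                  n_layers=2)
        cur, _ = synthetic.simulate_rasters(cfg)
        suit = np.full((10, 10), 0.01)
        occ = synthetic.sample_occurrences(suit, cur, 100, seed=2)
        quadrants = np.zeros(4)
        for lon, lat in occ.points:
            r, c = cur.geometry.cell_of(lon, lat)
            quadrants[(r >= 5) * 2 + (c >= 5)] += 1
        # chi-square sanity on the 4 quadrants: no gross non-uniformity
        stat, p = chisquare(quadrants)
        assert p > 1e-4

    def test_requested_count_on_valid_cells(self):
        cfg = synthetic.SimConfig(seed=7)
        cur, _ = synthetic.simulate_rasters(cfg)
        suit = synthetic.true_suitability(cfg, cur)
        occ = synthetic.sample_occurrences(suit, cur, 28, seed=3)
        assert occ.n == 28
        occ.snap_to_cells(cur)  # raises if any point is off-grid/nodata

    def test_too_many_points_rejected(self):
        cfg = synthetic.SimConfig(seed=8, grid_rows=3, grid_cols=3,
                                  n_layers=2)
        cur, _ = synthetic.simulate_rasters(cfg)
        with pytest.raises(ParameterError):
            synthetic.sample_occurrences(np.ones((3, 3)), cur, 10, seed=0)


class TestFixtures:
    def test_cer1502_like_diversity(self, cer1502_like):
        aln, pm = cer1502_like["alignment"], cer1502_like["popmap"]
        mask = seqio.build_site_mask(aln)
        tab = seqio.collapse_haplotypes(aln, mask, pm)
        assert tab.global_counts().tolist() == [3, 1, 1]
        hd, _ = popgen.haplotype_diversity(tab.global_counts())
        assert hd == pytest.approx(0.7)

    def test_unknown_fixture(self):
        with pytest.raises(ParameterError):
            synthetic.make_fixture("missing")
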