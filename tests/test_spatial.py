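"""Spatial autocorrelation: distance metrics, the per-class r coefficient
against a literal double-loop oracle, bootstrap and permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from gnis.dataset import MISSING
from gnis.spatial import (
    Correlogram,
    DistanceClassSpec,
    autocorrelation_r,
    bootstrap_r_ci,
    correlogram,
    correlogram_from_matrices,
    detect_positive_structure,
    genetic_distance_matrix,
    geo_distance_matrix,
    permutation_null_ci,
)
from gnis.synthetic import PopulationSpec, generate_population

from conftest import make_dataset, random_dataset

# ---------------------------------------------------------------------------
# brute-force oracles: explicit loops, no matrix identities


def _oracle_genetic_d2(geno):
    n, L = geno.shape
    d2 = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            shared = 0
            total = 0.0
            for j in range(L):
                gi, gk = geno[i, j], geno[k, j]
                if gi == MISSING or gk == MISSING:
                    continue
                shared += 1
                total += float(gi - gk) ** 2
            d2[i, k] = total * L / shared if shared else np.nan
    return d2


def _oracle_r(d2, geo, width, max_dist):
    n = len(d2)
    # double-centering by explicit loops
    row = [sum(d2[i]) / n for i in range(n)]
    grand = sum(sum(r) for r in d2) / n**2
    c = [
        [-0.5 * (d2[i][k] - row[i] - row[k] + grand) for k in range(n)]
        for i in range(n)
    ]
    n_classes = int(np.ceil(max_dist / width))
    rs = []
    for h in range(n_classes):
        num = den = 0.0
        count = 0
        for i in range(n):
            for k in range(i + 1, n):
                d = geo[i][k]
                if d >= max_dist or int(d // width) != h:
                    continue
                num += c[i][k]
                den += (c[i][i] + c[k][k]) / 2
                count += 1
        rs.append(num / den if count else np.nan)
    return np.array(rs)


# ---------------------------------------------------------------------------


class TestGeoDistance:
    def test_known_distances(self):
        coords = np.array([[0.0, 0.0], [300.0, 0.0], [0.0, 0.0]])
        d = geo_distance_matrix(coords)
        assert d[0, 1] == pytest.approx(300.0)
        assert d[0, 2] == 0.0
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_pythagorean_triangle(self):
        coords = np.array([[0.0, 0.0], [300.0, 0.0], [0.0, 400.0]])
        d = geo_distance_matrix(coords)
        assert sorted([d[0, 1], d[0, 2], d[1, 2]]) == pytest.approx(
            [300.0, 400.0, 500.0]
        )


class TestGeneticDistance:
    def test_identical_individuals_at_zero(self):
        ds = make_dataset([[0, 1, 2], [0, 1, 2]])
        assert genetic_distance_matrix(ds)[0, 1] == 0.0

    @pytest.mark.parametrize("g1, g2, expected", [(0, 2, 4.0), (0, 1, 1.0), (1, 2, 1.0)])
    def test_single_locus_metric_table(self, g1, g2, expected):
        ds = make_dataset([[g1], [g2]])
        assert genetic_distance_matrix(ds)[0, 1] == pytest.approx(expected)

    def test_matches_loop_oracle_with_missingness(self, rng):
        ds = random_dataset(rng, n=10, n_loci=20, missing_rate=0.2)
        d2 = genetic_distance_matrix(ds)
        oracle = _oracle_genetic_d2(ds.genotypes)
        assert np.allclose(d2, oracle, atol=1e-10, equal_nan=True)

    def test_missingness_scaling_extrapolates_shared_sum(self):
        # same per-shared-locus divergence, half the loci shared -> same d2
        full = make_dataset([[0, 0], [2, 2]])
        half = make_dataset([[0, MISSING], [2, 2]])
        d_full = genetic_distance_matrix(full)[0, 1]
        d_half = genetic_distance_matrix(half)[0, 1]
        assert d_full == pytest.approx(8.0)
        assert d_half == pytest.approx(8.0)


class TestAutocorrelationR:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n=12, n_loci=30, missing_rate=0.0)
        gd = genetic_distance_matrix(ds)
        geo = geo_distance_matrix(ds.coordinates)
        spec = DistanceClassSpec(class_width=3.0, max_distance=12.0)
        mine = autocorrelation_r(gd, geo, spec)
        oracle = _oracle_r(gd, geo, 3.0, 12.0)
        assert np.allclose(mine, oracle, atol=1e-10, equal_nan=True)

    def test_two_cluster_sign_structure(self):
        # two spatial clusters with distinct fixed genotype pools:
        # similarity within clusters, divergence between
        geno = np.array(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 1, 0, 0],
             [2, 2, 2, 2], [2, 2, 2, 1], [2, 1, 2, 2]],
            dtype=np.int8,
        )
        coords = np.array(
            [[0, 0], [10, 0], [0, 10], [1000, 0], [1010, 0], [1000, 10]], float
        )
        ds = make_dataset(geno, coords=coords)
        gd = genetic_distance_matrix(ds)
        geo = geo_distance_matrix(coords)
        spec = DistanceClassSpec(class_width=100.0, max_distance=1100.0)
        r = autocorrelation_r(gd, geo, spec)
        assert r[0] > 0  # within-cluster class
        assert r[-1] < 0  # between-cluster class

    def test_duplicated_individuals_make_first_class_maximal(self, rng):
        ds = random_dataset(rng, n=8, n_loci=40, missing_rate=0.0)
        geno = np.vstack([ds.genotypes, ds.genotypes])
        coords = np.vstack([ds.coordinates, ds.coordinates])
        dup = make_dataset(geno, coords=coords)
        gd = genetic_distance_matrix(dup)
        geo = geo_distance_matrix(coords)
        spec = DistanceClassSpec(class_width=200.0, max_distance=1400.0)
        r = autocorrelation_r(gd, geo, spec)
        finite = r[np.isfinite(r)]
        assert r[0] == np.nanmax(finite)

    def test_r_within_unit_interval(self, ibd_population):
        gd = genetic_distance_matrix(ibd_population)
        geo = geo_distance_matrix(ibd_population.coordinates)
        r = autocorrelation_r(gd, geo, DistanceClassSpec(250.0, 3000.0))
        finite = r[np.isfinite(r)]
        assert np.all(finite >= -1 - 1e-9) and np.all(finite <= 1 + 1e-9)


class TestBootstrap:
    def _matrices(self, rng, n=15):
        ds = random_dataset(rng, n=n, n_loci=30, missing_rate=0.0)
        return (
            genetic_distance_matrix(ds),
            geo_distance_matrix(ds.coordinates),
            DistanceClassSpec(class_width=5.0, max_distance=15.0),
        )

    def test_exactly_n_boot_resamples_per_class(self, rng):
        gd, geo, spec = self._matrices(rng)
        _, samples = bootstrap_r_ci(
            gd, geo, spec, n_boot=999, seed=1, return_samples=True
        )
        for s in samples:
            if s.size:
                assert len(s) == 999

    def test_degenerate_class_of_identical_pairs_zero_width(self):
        # four copies of the same genotype at mutual distance < width:
        # every within-class pair has identical c values -> CI width 0
        geno = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (4, 1))
        extra = np.array([[2, 1, 0, 1], [2, 2, 0, 0]], dtype=np.int8)
        coords = np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1], [500, 0], [800, 0]], float
        )
        ds = make_dataset(np.vstack([geno, extra]), coords=coords)
        gd = genetic_distance_matrix(ds)
        geo = geo_distance_matrix(coords)
        spec = DistanceClassSpec(class_width=10.0, max_distance=900.0)
        ci = bootstrap_r_ci(gd, geo, spec, n_boot=99, seed=1)
        assert ci[0, 1] - ci[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_ci_contains_point_estimate_in_most_instances(self):
        hits = trials = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gd, geo, spec = self._matrices(rng)
            r = autocorrelation_r(gd, geo, spec)
            ci = bootstrap_r_ci(gd, geo, spec, n_boot=499, seed=seed)
            for h in range(spec.n_classes):
                if np.isfinite(r[h]) and np.isfinite(ci[h, 0]):
                    trials += 1
                    hits += ci[h, 0] <= r[h] <= ci[h, 1]
        assert hits / trials >= 0.95

    def test_deterministic_given_seed(self, rng):
        gd, geo, spec = self._matrices(rng)
        a = bootstrap_r_ci(gd, geo, spec, n_boot=99, seed=3)
        b = bootstrap_r_ci(gd, geo, spec, n_boot=99, seed=3)
        assert np.allclose(a, b, equal_nan=True)


class TestPermutationNull:
    def test_deterministic_given_seed(self, rng):
        ds = random_dataset(rng, n=15, n_loci=30)
        gd = genetic_distance_matrix(ds)
        geo = geo_distance_matrix(ds.coordinates)
        spec = DistanceClassSpec(class_width=5.0, max_distance=15.0)
        a = permutation_null_ci(gd, geo, spec, n_perm=99, seed=5)
        b = permutation_null_ci(gd, geo, spec, n_perm=99, seed=5)
        assert np.allclose(a, b, equal_nan=True)

    def test_null_covers_observed_r_without_structure(self):
        # location-independent genotypes: observed first-class r should fall
        # inside the null band in the vast majority of draws
        inside = 0
        for seed in range(20):
            pop = generate_population(
                PopulationSpec(
                    n_individuals=60, n_loci=150, n_contigs=120,
                    ibd_sigma=0.0, seed=300 + seed,
                )
            )
            gd = genetic_distance_matrix(pop)
            geo = geo_distance_matrix(pop.coordinates)
            spec = DistanceClassSpec(class_width=500.0, max_distance=3500.0)
            r = autocorrelation_r(gd, geo, spec)
            null = permutation_null_ci(gd, geo, spec, n_perm=199, seed=seed)
            inside += null[0, 0] <= r[0] <= null[0, 1]
        assert inside >= 16

    def test_strong_ibd_exceeds_null_upper_bound(self, ibd_population):
        gd = genetic_distance_matrix(ibd_population)
        geo = geo_distance_matrix(ibd_population.coordinates)
        spec = DistanceClassSpec(class_width=250.0, max_distance=2000.0)
        r = autocorrelation_r(gd, geo, spec)
        null = permutation_null_ci(gd, geo, spec, n_perm=199, seed=1)
        assert r[0] > null[0, 1]


class TestDetection:
    def _corr(self, r, low, high):
        table = pd.DataFrame(
            {
                "class_lower": [0.0], "class_upper": [250.0], "n_pairs": [10],
                "r": [r], "boot_low": [low], "boot_high": [high],
                "null_low": [np.nan], "null_high": [np.nan],
                "significant_positive": [r > 0 and low > 0],
            }
        )
        return Correlogram(table)

    @pytest.mark.parametrize(
        "r, low, high, expected",
        [
            (0.05, 0.01, 0.09, True),
            (0.05, -0.01, 0.11, False),
            (-0.02, -0.04, -0.01, False),
        ],
    )
    def test_positive_structure_rule(self, r, low, high, expected):
        assert detect_positive_structure(self._corr(r, low, high), 0) is expected


class TestCorrelogramGrouping:
    def test_single_sex_dataset_yields_one_correlogram(self, rng):
        ds = random_dataset(rng, n=12, n_loci=20)
        ds.individuals["sex"] = "female"
        groups = correlogram(
            ds, DistanceClassSpec(250.0, 1500.0), grouping="by_sex", n_boot=49
        )
        assert list(groups) == ["female"]

    def test_symmetric_sexes_give_matching_correlograms(self, ibd_population):
        # duplicate the same individuals as male and female at the same
        # locations: both correlograms estimate the same structure
        sub = ibd_population.take_individuals(np.arange(60))
        geno = np.vstack([sub.genotypes, sub.genotypes])
        coords = np.vstack([sub.coordinates, sub.coordinates])
        ds = make_dataset(geno, coords=coords, sexes=["male"] * 60 + ["female"] * 60)
        spec = DistanceClassSpec(250.0, 2000.0)
        groups = correlogram(ds, spec, grouping="by_sex", n_boot=49, seed=1)
        rm = groups["male"].table["r"].to_numpy()
        rf = groups["female"].table["r"].to_numpy()
        ok = np.isfinite(rm) & np.isfinite(rf)
        assert np.allclose(rm[ok], rf[ok], atol=1e-9)

    def test_tiny_group_skipped_with_warning(self, rng, caplog):
        ds = random_dataset(rng, n=10, n_loci=20)
        ds.individuals["sex"] = ["male"] * 2 + ["female"] * 8
        with caplog.at_level("WARNING"):
            groups = correlogram(
                ds, DistanceClassSpec(250.0, 1500.0), grouping="by_sex", n_boot=49
            )
        assert "male" not in groups and "female" in groups

    def test_full_chain_flags_structure_on_ibd_population(self, ibd_population):
        spec = DistanceClassSpec(250.0, 2000.0)
        corr = correlogram(ibd_population, spec, n_boot=199, seed=2)["all"]
        assert corr.significant_positive(0)
        assert corr.table["n_pairs"].sum() > 0
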