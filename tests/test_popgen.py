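"""AMOVA, PCoA, Mantel, Evanno delta-K."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from germdiv.errors import (AlignmentError, DegenerateDataError, DesignError,
                            FormatError)
from germdiv.io import DistanceMatrix, PopulationMap
from germdiv.popgen import amova, best_k, evanno_delta_k, mantel, pcoa
from germdiv.synthetic import simulate_lnpd_profile


def coord_setup(rng, n=12, n_pops=3, dim=3):
    pts = rng.random((n, dim))
    labels = [f"A{i}" for i in range(n)]
    groups = np.repeat(np.arange(n_pops), n // n_pops)
    dm = DistanceMatrix(tuple(labels), squareform(pdist(pts)))
    pm = PopulationMap({l: f"P{g}" for l, g in zip(labels, groups)})
    return pts, groups, dm, pm


class TestAmova:
    def test_all_between_no_within(self):
        # two point-clouds collapsed to two distinct points
        vals = np.array([[0, 0, 1, 1],
                         [0, 0, 1, 1],
                         [1, 1, 0, 0],
                         [1, 1, 0, 0]], float)
        dm = DistanceMatrix(("A", "B", "C", "D"), vals)
        pm = PopulationMap({"A": "P1", "B": "P1", "C": "P2", "D": "P2"})
        res = amova(dm, pm, n_permutations=29, seed=0)
        assert res.percent_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_coordinate_anova_oracle(self, rng):
        """Sums of squares equal deviations-from-centroid ANOVA in the
        embedding space when distances are Euclidean."""
        for _ in range(10):
            pts, groups, dm, pm = coord_setup(rng)
            res = amova(dm, pm, n_permutations=9, seed=0)
            grand = pts.mean(axis=0)
            ss_tot = ((pts - grand) ** 2).sum()
            ss_w = sum(((pts[groups == g] - pts[groups == g].mean(axis=0)) ** 2).sum()
                       for g in range(3))
            assert res.ss_within == pytest.approx(ss_w, abs=1e-9)
            assert res.ss_among == pytest.approx(ss_tot - ss_w, abs=1e-9)
            assert res.df_among == 2 and res.df_within == 9
            assert res.percent_among + res.percent_within == pytest.approx(100.0)

    def test_scale_invariance_of_phi(self, rng):
        _, _, dm, pm = coord_setup(rng)
        r1 = amova(dm, pm, 9, seed=1)
        dm2 = DistanceMatrix(dm.labels, dm.values * 7.5)
        r2 = amova(dm2, pm, 9, seed=1)
        assert r1.phi_st == pytest.approx(r2.phi_st, abs=1e-12)

    def test_permutation_p_reproducible(self, rng):
        _, _, dm, pm = coord_setup(rng)
        assert amova(dm, pm, 99, seed=5).p_value == amova(dm, pm, 99, seed=5).p_value

    def test_singleton_population_rejected(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        pm = PopulationMap({"A": "P1", "B": "P1", "C": "P2"})
        with pytest.raises(DesignError, match="singleton"):
            amova(dm, pm, 9, seed=0)

    def test_unmapped_accession_rejected(self, rng):
        _, _, dm, _ = coord_setup(rng)
        pm = PopulationMap({"A0": "P1"})
        with pytest.raises(AlignmentError):
            amova(dm, pm, 9, seed=0)

    def test_all_zero_distances_undefined(self):
        dm = DistanceMatrix(("A", "B", "C", "D"), np.zeros((4, 4)))
        pm = PopulationMap({"A": "P1", "B": "P1", "C": "P2", "D": "P2"})
        with pytest.raises(DegenerateDataError):
            amova(dm, pm, 9, seed=0)


class TestPcoa:
    def test_recovers_planted_plane(self, rng):
        pts = rng.random((5, 2))
        dm = DistanceMatrix(tuple("ABCDE"), squareform(pdist(pts)))
        res = pcoa(dm)
        assert res.percent_variance[:2].sum() == pytest.approx(100.0)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts - pts.mean(0),
                                     res.coordinates.to_numpy()[:, :2])
        assert disparity < 1e-16

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(("A", "B", "C"), np.zeros((3, 3))))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_collinear_points_one_positive_eigenvalue(self):
        x = np.array([[0.0], [1.0], [2.5], [4.0]])
        dm = DistanceMatrix(("A", "B", "C", "D"), squareform(pdist(x)))
        res = pcoa(dm)
        assert (res.eigenvalues > 1e-9).sum() == 1

    def test_euclidean_input_no_negative_eigenvalues(self, rng):
        pts = rng.random((10, 4))
        dm = DistanceMatrix(tuple(f"A{i}" for i in range(10)),
                            squareform(pdist(pts)))
        assert pcoa(dm).negative_eigenvalues.size == 0

    def test_matches_skbio_percent_variance(self, rng):
        import skbio
        pts = rng.random((8, 3))
        labs = tuple(f"A{i}" for i in range(8))
        dm = DistanceMatrix(labs, squareform(pdist(pts)))
        mine = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.values, ids=labs))
        np.testing.assert_allclose(
            mine.percent_variance[:3],
            100 * ref.proportion_explained.to_numpy()[:3], atol=1e-6)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = DistanceMatrix(tuple(f"A{i}" for i in range(8)),
                            squareform(pdist(rng.random((8, 2)))))
        r, p = mantel(dm, dm, 99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        labs = tuple(f"A{i}" for i in range(8))
        v = squareform(pdist(rng.random((8, 2))))
        d1 = DistanceMatrix(labs, v)
        w = 2.0 * v + 0.3
        np.fill_diagonal(w, 0.0)
        r, _ = mantel(d1, DistanceMatrix(labs, w), 99, seed=0)
        assert r == pytest.approx(1.0)

    def test_independent_matrices_nonsignificant(self, rng):
        labs = tuple(f"A{i}" for i in range(24))
        d1 = DistanceMatrix(labs, squareform(pdist(rng.random((24, 3)))))
        d2 = DistanceMatrix(labs, squareform(pdist(rng.random((24, 3)))))
        r, p = mantel(d1, d2, 999, seed=1)
        assert r ** 2 < 0.1 and p > 0.05

    def test_matches_skbio_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        labs = tuple(f"A{i}" for i in range(12))
        a = squareform(pdist(rng.random((12, 2))))
        b = squareform(pdist(rng.random((12, 2))))
        r, _ = mantel(DistanceMatrix(labs, a), DistanceMatrix(labs, b), 99, 0)
        r_ref, _, _ = sk_mantel(SkDM(a, ids=labs), SkDM(b, ids=labs),
                                permutations=0)
        assert r == pytest.approx(float(r_ref), abs=1e-12)

    def test_zero_variance_rejected(self):
        labs = ("A", "B", "C")
        flat = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(DegenerateDataError):
            mantel(DistanceMatrix(labs, flat), DistanceMatrix(labs, flat), 9, 0)


def lnpd_table(means: dict[int, float], sd_offset: float = np.sqrt(2)) -> pd.DataFrame:
    rows = []
    for k, m in means.items():
        rows += [(k, 1, m + sd_offset), (k, 2, m - sd_offset)]
    return pd.DataFrame(rows, columns=["K", "run", "lnpd"])


class TestEvanno:
    def test_hand_worked_table(self):
        # means (-100, -80, -75, -74), sd = 2 at every K
        dk = evanno_delta_k(lnpd_table({1: -100, 2: -80, 3: -75, 4: -74}))
        row3 = dk[dk["K"] == 3].iloc[0]
        assert row3["lprime"] == pytest.approx(5.0)
        assert row3["lsecond_abs"] == pytest.approx(4.0)
        assert row3["delta_k"] == pytest.approx(2.0)

    def test_linear_profile_gives_zero_delta(self):
        dk = evanno_delta_k(lnpd_table({k: -100 + 10 * k for k in range(1, 6)}))
        interior = dk.dropna(subset=["delta_k"])
        np.testing.assert_allclose(interior["delta_k"].to_numpy(), 0.0, atol=1e-12)

    def test_shift_and_scale_invariance(self):
        base = lnpd_table({1: -100, 2: -80, 3: -75, 4: -74})
        dk0 = evanno_delta_k(base)
        shifted = base.assign(lnpd=base["lnpd"] + 500.0)
        scaled = base.assign(lnpd=base["lnpd"] * 3.0)
        for other in (shifted, scaled):
            dk = evanno_delta_k(other)
            np.testing.assert_allclose(dk["delta_k"].to_numpy(),
                                       dk0["delta_k"].to_numpy(), atol=1e-9)

    def test_planted_two_cluster_profile_peaks_at_two(self):
        dk = evanno_delta_k(simulate_lnpd_profile(seed=5))
        assert best_k(dk) == 2

    def test_noncontiguous_grid_rejected(self):
        with pytest.raises(FormatError, match="contiguous"):
            evanno_delta_k(lnpd_table({1: -10, 2: -8, 4: -7}))

    def test_single_run_rejected(self):
        df = pd.DataFrame({"K": [1, 2, 3], "run": [1, 1, 1],
                           "lnpd": [-10.0, -8.0, -7.0]})
        with pytest.raises(FormatError, match="runs"):
            evanno_delta_k(df)
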