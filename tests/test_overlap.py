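import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phyloniche import envspace as es
from phyloniche import overlap as ov
from phyloniche import synthetic as syn
from phyloniche.envspace import SpeciesNiche


def _niche(points, species="sp"):
    points = np.asarray(points, float)
    return SpeciesNiche(
        species=species, scores=points,
        identity=points.mean(0), breadth=points.std(0, ddof=1),
        range=np.column_stack([points.min(0), points.max(0)]),
        n_pixels=len(points))


def _grid(z, corrected=False):
    z = np.asarray(z, float)
    return ov.OccupancyGrid(extent=np.array([[0.0, 1.0], [0.0, 1.0]]),
                            z=z / z.sum(), resolution=z.shape[0],
                            corrected=corrected)


class TestOccupancyGrid:
    def test_normalization_contract(self, small_space):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 2))
        for corrected in (False, True):
            g = ov.occupancy_grid(_niche(pts), small_space,
                                  corrected=corrected)
            assert np.isclose(g.z.sum(), 1.0, atol=1e-9)
            assert (g.z >= 0).all()

    def test_point_mass_concentrates_locally(self, small_space):
        pts = np.tile([[0.3, -0.2]], (12, 1))
        g = ov.occupancy_grid(_niche(pts), small_space, corrected=False)
        i, j = np.unravel_index(np.argmax(g.z), g.z.shape)
        lo_i, lo_j = max(i - 1, 0), max(j - 1, 0)
        mass = g.z[lo_i:i + 2, lo_j:j + 2].sum()
        assert mass >= 0.99

    def test_availability_correction_flattens_background(self, small_raster,
                                                         small_space):
        # a species occupying every background pixel has (corrected) density
        # close to uniform over well-available cells
        niche = _niche(np.asarray(small_space.background_scores))
        bg = ov.background_availability(small_space)
        g = ov.occupancy_grid(niche, small_space, corrected=True,
                              background=bg)
        avail = bg[1]
        cells = g.z[avail > 0.25 * avail.max()]
        assert cells.max() / cells.min() < 1.5


class TestSchoenerD:
    def test_identical_grids_give_one(self):
        z = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert ov.schoener_D(_grid(z), _grid(z)) == pytest.approx(1.0)

    def test_disjoint_and_half_overlap_hand_cases(self):
        z1 = np.array([[0.5, 0.5], [0.0, 0.0]])
        z2 = np.array([[0.0, 0.0], [0.5, 0.5]])
        z3 = np.array([[0.5, 0.0], [0.5, 0.0]])
        assert ov.schoener_D(_grid(z1), _grid(z2)) == pytest.approx(0.0)
        assert ov.schoener_D(_grid(z1), _grid(z3)) == pytest.approx(0.5)

    def test_mismatched_grids_rejected(self):
        g1 = _grid(np.ones((2, 2)))
        g2 = ov.OccupancyGrid(extent=np.array([[0., 2.], [0., 1.]]),
                              z=np.ones((2, 2)) / 4, resolution=2,
                              corrected=False)
        with pytest.raises(ValueError):
            ov.schoener_D(g1, g2)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.random((3, 3)), rng.random((3, 3))
        d12 = ov.schoener_D(_grid(z1), _grid(z2))
        d21 = ov.schoener_D(_grid(z2), _grid(z1))
        assert d12 == pytest.approx(d21)
        assert 0.0 <= d12 <= 1.0

    def test_translation_monotonicity(self, small_space):
        rng = np.random.default_rng(3)
        base = rng.normal(scale=0.5, size=(60, 2))
        bg = ov.background_availability(small_space)
        g0 = ov.occupancy_grid(_niche(base), small_space, corrected=False,
                               background=bg)
        ds = []
        for shift in (0.0, 0.5, 1.0, 1.5, 2.0):
            g = ov.occupancy_grid(_niche(base + [shift, 0.0]), small_space,
                                  corrected=False, background=bg)
            ds.append(ov.schoener_D(g0, g))
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))


@pytest.fixture(scope="module")
def pairs(small_raster, small_space):
    centers = {f"s{i}": (0.3 * i - 0.6, 0.2 * i - 0.4) for i in range(4)}
    sds = dict.fromkeys(centers, 1.0)
    occ = syn.generate_occurrences(small_raster, small_space, centers,
                                   sds, 60, 8)
    meta = pd.DataFrame({
        "species": list(centers),
        "pollination_mode": ["bat", "bat", "hummingbird", "unknown"],
        "mode_status": ["observed"] * 3 + ["unknown"],
        "islands": ["Cuba;Hispaniola", "Hispaniola", "Jamaica", "Cuba"],
    })
    table = es.dedupe_per_pixel(es.OccurrenceTable(occ, meta))
    niches = es.species_niche(table, small_space, small_raster)
    return ov.pairwise_overlap(niches, meta, small_space)


class TestPairwise:
    def test_all_unordered_pairs_present(self, pairs):
        assert len(pairs) == 4 * 3 // 2
        assert pairs["D"].between(0, 1).all()

    def test_pair_covariates(self, pairs):
        p = pairs.set_index(["species_a", "species_b"])
        assert p.loc[("s0", "s1"), "same_pollination"] == True  # noqa: E712
        assert p.loc[("s0", "s2"), "same_pollination"] == False  # noqa: E712
        assert pd.isna(p.loc[("s0", "s3"), "same_pollination"])
        # shared island via set intersection: {Cuba,Hispaniola} vs {Hispaniola}
        assert p.loc[("s0", "s1"), "same_island"] == True  # noqa: E712
        assert p.loc[("s1", "s2"), "same_island"] == False  # noqa: E712


def _synthetic_pairs(rng, n_species=35, intercept=0.15, island_effect=0.16,
                     noise=0.18):
    n = n_species * (n_species - 1) // 2
    same_island = rng.random(n) < 0.3
    same_mode = rng.random(n) < 0.4
    D = intercept + island_effect * same_island + noise * rng.standard_normal(n)
    return pd.DataFrame({"species_a": "a", "species_b": "b", "D": D,
                         "same_pollination": same_mode,
                         "same_island": same_island})


class TestOverlapModels:
    def test_coefficients_match_normal_equations(self):
        pairs = _synthetic_pairs(np.random.default_rng(0))
        fits = {f.label: f for f in ov.fit_overlap_models(pairs)}
        X = np.column_stack([np.ones(len(pairs)),
                             pairs["same_pollination"].astype(float),
                             pairs["same_island"].astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ pairs["D"].to_numpy())
        got = fits["D ~ pollination + island"].coefficients
        assert abs(got["const"] - beta[0]) < 1e-10
        assert abs(got["group"] - beta[1]) < 1e-10
        assert abs(got["island"] - beta[2]) < 1e-10

    def test_island_effect_recovery(self):
        pairs = _synthetic_pairs(np.random.default_rng(1))
        fits = {f.label: f for f in ov.fit_overlap_models(pairs)}
        island = fits["D ~ island"]
        coef = island.coefficients["island"]
        # 3 SE of the OLS slope
        se = 0.18 / np.sqrt(len(pairs) * 0.3 * 0.7)
        assert abs(coef - 0.16) < 3 * se
        assert island.aic < fits["D ~ 1"].aic
        assert island.pvalues["island"] < 0.001

    def test_exactly_one_best_and_within2_flags(self):
        pairs = _synthetic_pairs(np.random.default_rng(2))
        fits = ov.fit_overlap_models(pairs)
        assert sum(f.is_best for f in fits) == 1
        best = min(f.aic for f in fits)
        for f in fits:
            assert f.within_2_aic == (f.aic <= best + 2.0)

    def test_constant_response_prefers_intercept(self):
        pairs = _synthetic_pairs(np.random.default_rng(3), noise=1e-300)
        pairs["D"] = 0.4
        fits = ov.fit_overlap_models(pairs)
        best = [f for f in fits if f.is_best][0]
        assert best.label == "D ~ 1"
        assert best.r_squared == 0.0

    def test_degenerate_predictor_dropped_with_warning(self):
        pairs = _synthetic_pairs(np.random.default_rng(4))
        pairs["same_island"] = True
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            fits = ov.fit_overlap_models(pairs)
        assert any("degenerate" in str(w.message) for w in rec)
        labels = {f.label for f in fits}
        assert "D ~ island" not in labels
        assert "D ~ 1" in labels

    def test_aic_ordering_invariant_to_predictor_column_order(self):
        pairs = _synthetic_pairs(np.random.default_rng(5))
        swapped = pairs[["species_a", "species_b", "same_island",
                         "same_pollination", "D"]].copy()
        a1 = [f.aic for f in ov.fit_overlap_models(pairs)]
        a2 = [f.aic for f in ov.fit_overlap_models(swapped)]
        assert np.allclose(a1, a2)


class TestRangeInclusion:
    def test_included_with_margins(self):
        plant = _niche([[0.0, 0.0], [1.0, 1.0]])
        group = [_niche([[-1.0, -1.0], [2.0, 2.0]])]
        out = ov.range_inclusion(plant, group)
        assert out["included"]
        assert out["PC1"]["margin_low"] == pytest.approx(1.0)
        assert out["PC1"]["margin_high"] == pytest.approx(1.0)

    def test_excess_reported_as_negative_margin(self):
        plant = _niche([[0.0, 0.0], [2.1, 1.0]])
        group = [_niche([[-1.0, -1.0], [2.0, 2.0]])]
        out = ov.range_inclusion(plant, group)
        assert not out["included"]
        assert out["PC1"]["margin_high"] == pytest.approx(-0.1)

    def test_inclusion_monotone_under_group_growth(self):
        plant = _niche([[0.0, 0.0], [1.0, 1.0]])
        group = [_niche([[-0.5, -0.5], [1.5, 1.5]])]
        base = ov.range_inclusion(plant, group)["included"]
        grown = ov.range_inclusion(
            plant, group + [_niche([[5.0, 5.0], [6.0, 6.0]])])["included"]
        assert base
        assert grown

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ov.range_inclusion(_niche([[0, 0], [1, 1]]), [])
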