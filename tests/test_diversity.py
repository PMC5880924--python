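import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from betashift.diversity import (
    PairComponents,
    functional_components,
    functional_richness,
    hull_volume,
    jaccard_partition,
    pairwise_beta,
    species_richness,
    taxonomic_beta_matrices,
    taxonomic_components,
)
from betashift.exceptions import EmptyPairError
from betashift.functional_space import FunctionalSpace, build_functional_space


def _space_from_points(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(points))]
    cols = [f"PcoA{k + 1}" for k in range(points.shape[1])]
    return FunctionalSpace(pd.DataFrame(points, index=labels, columns=cols),
                           np.ones(points.shape[1]))


CUBE = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                dtype=float)


class TestRichnessAndHulls:
    def test_species_richness_counts_ones(self):
        assert species_richness([1, 0, 1, 1]) == 3
        assert species_richness(np.zeros(5)) == 0
        assert species_richness(np.ones(275)) == 275

    def test_unit_cube_volume(self):
        assert hull_volume(CUBE) == pytest.approx(1.0)

    def test_tetrahedron_volume(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                       dtype=float)
        assert hull_volume(tet) == pytest.approx(1 / 6)

    def test_degenerate_point_sets_are_zero(self):
        assert hull_volume(CUBE[:3]) == 0.0  # too few points in 3-D
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                             [0.5, 0.5, 0]], dtype=float)
        assert hull_volume(coplanar) == 0.0

    def test_functional_richness_ratio(self):
        space = _space_from_points(CUBE)
        full = pd.Series(1, index=space.species_ids)
        assert functional_richness(full, space, 1.0) == pytest.approx(1.0)
        single = pd.Series(0, index=space.species_ids)
        single.iloc[0] = 1
        assert functional_richness(single, space, 1.0) == 0.0
        # half-cube: x in [0, 0.5]
        half = _space_from_points(CUBE * [0.5, 1, 1])
        sub = pd.Series(1, index=half.species_ids)
        assert functional_richness(sub, half, 1.0) == pytest.approx(0.5)


class TestComponents:
    def test_taxonomic_components_example(self):
        x = [1, 1, 1, 1, 1, 0]
        y = [0, 0, 0, 1, 1, 1]
        comp = taxonomic_components(x, y)
        assert (comp.a, comp.b, comp.c) == (2, 3, 1)

    def test_identical_and_disjoint_rows(self):
        r = [1, 0, 1, 1]
        same = taxonomic_components(r, r)
        assert (same.a, same.b, same.c) == (3, 0, 0)
        dis = taxonomic_components([1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1])
        assert (dis.a, dis.b, dis.c) == (0, 3, 3)

    def test_identical_point_sets_share_all_volume(self):
        space = _space_from_points(CUBE)
        x = pd.Series(1, index=space.species_ids)
        comp = functional_components(x, x, space)
        assert comp.a == pytest.approx(1.0, rel=1e-9)
        assert comp.b == pytest.approx(0.0, abs=1e-9)
        assert comp.c == pytest.approx(0.0, abs=1e-9)

    def test_offset_cubes_overlap_eighth(self):
        pts = np.vstack([CUBE, CUBE + 0.5])
        space = _space_from_points(pts)
        x = pd.Series([1] * 8 + [0] * 8, index=space.species_ids)
        y = pd.Series([0] * 8 + [1] * 8, index=space.species_ids)
        comp = functional_components(x, y, space)
        assert comp.a == pytest.approx(0.125, rel=1e-9)
        assert comp.b == pytest.approx(0.875, rel=1e-9)
        assert comp.c == pytest.approx(0.875, rel=1e-9)

    def test_disjoint_tetrahedra_do_not_overlap(self):
        t1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                      dtype=float)
        t2 = t1 + 5.0
        space = _space_from_points(np.vstack([t1, t2]))
        x = pd.Series([1] * 4 + [0] * 4, index=space.species_ids)
        y = pd.Series([0] * 4 + [1] * 4, index=space.species_ids)
        comp = functional_components(x, y, space)
        assert comp.a == 0.0

    def test_degenerate_hull_flags_pair_missing(self):
        space = _space_from_points(CUBE)
        x = pd.Series(1, index=space.species_ids)
        y = pd.Series(0, index=space.species_ids)
        y.iloc[:3] = 1  # three points cannot span 3-D
        assert functional_components(x, y, space) is None


class TestJaccardPartition:
    def test_worked_example(self):
        part = jaccard_partition(PairComponents(2, 3, 1))
        assert part.total == pytest.approx(2 / 3)
        assert part.turnover == pytest.approx(0.5)
        assert part.nestedness == pytest.approx(1 / 6)
        assert part.turnover_contribution == pytest.approx(0.75)

    def test_pure_nestedness(self):
        part = jaccard_partition(PairComponents(3, 4, 0))
        assert part.turnover == 0.0
        assert part.nestedness == pytest.approx(4 / 7)
        assert part.total == pytest.approx(4 / 7)

    def test_complete_turnover(self):
        part = jaccard_partition(PairComponents(0, 5, 5))
        assert part.total == 1.0
        assert part.turnover == 1.0
        assert part.nestedness == pytest.approx(0.0)

    def test_empty_pair_raises(self):
        with pytest.raises(EmptyPairError):
            jaccard_partition(PairComponents(0, 0, 0))

    def test_identical_assemblages_have_undefined_contributions(self):
        part = jaccard_partition(PairComponents(4, 0, 0))
        assert part.total == 0.0
        assert np.isnan(part.turnover_contribution)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(
        a=st.integers(min_value=0, max_value=500),
        b=st.integers(min_value=0, max_value=500),
        c=st.integers(min_value=0, max_value=500),
        family=st.sampled_from(["jaccard", "sorensen"]),
    )
    def test_partition_identity_property(self, a, b, c, family):
        """D = D_tu + D_ne, 0 <= D_tu <= D <= 1, contributions sum to 1."""
        if a + b + c == 0:
            return
        part = jaccard_partition(PairComponents(a, b, c), family)
        assert abs(part.total - part.turnover - part.nestedness) < 1e-10
        assert -1e-12 <= part.turnover <= part.total <= 1 + 1e-12
        if part.total > 0:
            assert (part.turnover_contribution
                    + part.nestedness_contribution) == pytest.approx(1.0)


class TestPairwiseBeta:
    def test_pair_count_and_ratio(self, tiny_paired, tiny_traits):
        space = build_functional_space(tiny_traits)
        table = pairwise_beta(tiny_paired.historical, space)
        assert len(table) == 3  # 3 sites -> 3 pairs
        row = table.set_index(["site_i", "site_j"]).loc[("L1", "L3")]
        assert row["richness_ratio"] == pytest.approx(4 / 5)

    def test_partition_identity_on_synthetic_pairs(self, small_dataset):
        space = build_functional_space(small_dataset.traits)
        table = pairwise_beta(small_dataset.paired.historical, space)
        for facet in ("tax", "fun"):
            sub = table.dropna(subset=[f"{facet}_D"])
            resid = (sub[f"{facet}_D"] - sub[f"{facet}_Dtu"]
                     - sub[f"{facet}_Dne"])
            assert np.abs(resid).max() < 1e-10

    def test_species_order_invariance(self, tiny_paired):
        t1 = pairwise_beta(tiny_paired.historical, include_functional=False)
        shuffled = tiny_paired.historical
        cols = list(shuffled.data.columns)[::-1]
        from betashift.io import AssemblageMatrix
        t2 = pairwise_beta(AssemblageMatrix(shuffled.data[cols], "h"),
                           include_functional=False)
        assert np.allclose(t1["tax_D"], t2["tax_D"])

    def test_rotation_invariance_of_functional_beta(self, small_dataset):
        space = build_functional_space(small_dataset.traits)
        mat = small_dataset.paired.historical
        t1 = pairwise_beta(mat, space)
        # rigid rotation of the coordinate frame
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = FunctionalSpace(
            pd.DataFrame(space.coordinates.to_numpy() @ Q,
                         index=space.coordinates.index,
                         columns=space.coordinates.columns),
            space.eigenvalues)
        t2 = pairwise_beta(mat, rotated)
        ok = t1["fun_D"].notna()
        assert np.allclose(t1.loc[ok, "fun_D"], t2.loc[ok, "fun_D"],
                           atol=1e-8)

    def test_adding_shared_interior_species_monotone(self):
        # interior point of both hulls: taxonomic D cannot increase and
        # functional components are unchanged
        pts = np.vstack([CUBE, CUBE + 0.5, [[0.75, 0.75, 0.75]]])
        space = _space_from_points(pts)
        base_x = [1] * 8 + [0] * 8 + [0]
        base_y = [0] * 8 + [1] * 8 + [0]
        x0 = pd.Series(base_x, index=space.species_ids)
        y0 = pd.Series(base_y, index=space.species_ids)
        x1, y1 = x0.copy(), y0.copy()
        x1.iloc[-1] = 1
        y1.iloc[-1] = 1
        d0 = jaccard_partition(taxonomic_components(x0, y0)).total
        d1 = jaccard_partition(taxonomic_components(x1, y1)).total
        assert d1 <= d0
        f0 = functional_components(x0, y0, space)
        f1 = functional_components(x1, y1, space)
        assert f1.a == pytest.approx(f0.a, rel=1e-9)
        assert f1.b == pytest.approx(f0.b, rel=1e-9)

    def test_monte_carlo_intersection_oracle(self):
        """Half-space intersection volumes match rejection sampling."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            px = rng.uniform(0, 1, size=(8, 3))
            py = rng.uniform(0, 1, size=(8, 3)) + rng.uniform(-0.3, 0.3, 3)
            space = _space_from_points(np.vstack([px, py]))
            x = pd.Series([1] * 8 + [0] * 8, index=space.species_ids)
            y = pd.Series([0] * 8 + [1] * 8, index=space.species_ids)
            comp = functional_components(x, y, space)
            hx, hy = ConvexHull(px), ConvexHull(py)
            lo = np.maximum(px.min(0), py.min(0))
            hi = np.minimum(px.max(0), py.max(0))
            if np.any(hi <= lo):
                mc, se = 0.0, 0.0
            else:
                pts = rng.uniform(lo, hi, size=(100000, 3))
                inside = np.ones(len(pts), dtype=bool)
                for h in (hx, hy):
                    inside &= np.all(
                        pts @ h.equations[:, :3].T + h.equations[:, 3]
                        <= 1e-12, axis=1)
                box = float(np.prod(hi - lo))
                frac = inside.mean()
                mc = frac * box
                se = box * np.sqrt(frac * (1 - frac) / len(pts))
            assert abs(comp.a - mc) <= 3 * max(se, 1e-12)

    def test_vectorized_matrices_match_pair_loop(self, small_dataset):
        mat = small_dataset.paired.current
        table = pairwise_beta(mat, include_functional=False)
        mats = taxonomic_beta_matrices(mat)
        sites = mat.site_ids
        idx = {s: k for k, s in enumerate(sites)}
        for _, row in table.iterrows():
            i, j = idx[row["site_i"]], idx[row["site_j"]]
            assert mats["D"][i, j] == pytest.approx(row["tax_D"], nan_ok=True)
            assert mats["Dne"][i, j] == pytest.approx(row["tax_Dne"],
                                                      nan_ok=True)
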