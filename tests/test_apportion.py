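"""Areal apportionment: weights, profiles, conservation laws."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from holcwells import Grade, Neighborhood, apportion_profile, intersection_weights
from holcwells.apportion import DEFAULT_SPECS, VariableSpec, apportion_table
from holcwells.types import COVARIATE_NAMES

import oracles


def _nb(geom, nid="n1"):
    return Neighborhood(nid, "c", Grade.B, geom, 1937)


def _attrs(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    base = {name: 0.5 if name.startswith("prop_") else 100.0 for name in COVARIATE_NAMES}
    return pd.DataFrame(
        {tid: {**base, **vals} for tid, vals in rows.items()}
    ).T


class TestIntersectionWeights:
    def test_identical_polygons_give_unit_weight(self):
        g = box(0, 0, 1000, 1000)
        w = intersection_weights(g, [("t1", box(0, 0, 1000, 1000))])
        assert set(w) == {"t1"}
        assert w["t1"][0] == pytest.approx(1.0)
        assert w["t1"][1] == pytest.approx(1e6)

    def test_half_coverage_of_two_equal_tracts(self):
        nb = box(0, 500, 2000, 1500)  # covers upper half of t1, lower half of t2? no:
        tracts = [("t1", box(0, 0, 2000, 1000)), ("t2", box(0, 1000, 2000, 2000))]
        w = intersection_weights(nb, tracts)
        assert w["t1"][0] == pytest.approx(0.5)
        assert w["t2"][0] == pytest.approx(0.5)

    def test_disjoint_tracts_omitted(self):
        w = intersection_weights(box(0, 0, 10, 10), [("far", box(100, 100, 200, 200))])
        assert w == {}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_raster_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ox, oy = rng.uniform(50, 450, 2)
        nb = box(0, 0, 1000, 1000)
        tracts = [
            (f"t{i}{j}", box(ox + 500 * i - 500, oy + 500 * j - 500,
                             ox + 500 * i, oy + 500 * j))
            for i in range(4)
            for j in range(4)
        ]
        got = intersection_weights(nb, tracts)
        want = oracles.raster_intersection_weights(nb, tracts, cell_m=1.0)
        assert set(got) == set(want)
        for tid in got:
            assert got[tid][1] == pytest.approx(want[tid][1], rel=5e-3)
            assert got[tid][0] == pytest.approx(want[tid][0], rel=5e-3)


class TestApportionProfile:
    def test_identity_returns_tract_row(self):
        g = box(0, 0, 1000, 1000)
        attrs = _attrs({"t1": {"total_population": 1234.0, "prop_black": 0.37}})
        prof = apportion_profile(_nb(g), [("t1", g)], attrs)
        assert prof["coverage_frac"] == pytest.approx(1.0)
        for name in COVARIATE_NAMES:
            assert prof[name] == pytest.approx(attrs.loc["t1", name])

    def test_extensive_split_and_intensive_average(self):
        nb = _nb(box(0, 500, 2000, 1500))
        tracts = [("t1", box(0, 0, 2000, 1000)), ("t2", box(0, 1000, 2000, 2000))]
        attrs = _attrs({
            "t1": {"total_population": 100.0, "prop_black": 0.1},
            "t2": {"total_population": 300.0, "prop_black": 0.3},
        })
        prof = apportion_profile(nb, tracts, attrs)
        assert prof["total_population"] == pytest.approx(200.0)  # 0.5*100 + 0.5*300
        assert prof["prop_black"] == pytest.approx(0.2)  # equal area weights

    def test_population_basis_weighting(self):
        nb = _nb(box(0, 500, 2000, 1500))
        tracts = [("t1", box(0, 0, 2000, 1000)), ("t2", box(0, 1000, 2000, 2000))]
        attrs = _attrs({
            "t1": {"total_population": 100.0, "prop_black": 0.1},
            "t2": {"total_population": 300.0, "prop_black": 0.3},
        })
        specs = tuple(
            VariableSpec(s.name, s.kind, "population") if s.name == "prop_black" else s
            for s in DEFAULT_SPECS
        )
        prof = apportion_profile(nb, tracts, attrs, specs)
        # weights 0.5*100 vs 0.5*300 → (50*0.1 + 150*0.3) / 200
        assert prof["prop_black"] == pytest.approx(0.25)

    def test_no_overlap_flags_nan_and_exclusion(self):
        nb = _nb(box(0, 0, 100, 100))
        tracts = [("far", box(10_000, 10_000, 11_000, 11_000))]
        attrs = _attrs({"far": {}})
        df = apportion_table([nb], tracts, attrs)
        assert df.loc["n1", "coverage_frac"] == 0.0
        assert not df.loc["n1", "included"]
        assert np.isnan(df.loc["n1", "prop_black"])


class TestConservationLaws:
    def _tiling(self):
        # 4x4 tract grid of 500 m cells; 2x2 neighborhoods of 1000 m cells
        tracts = [
            (f"t{i}{j}", box(500 * i, 500 * j, 500 * (i + 1), 500 * (j + 1)))
            for i in range(4)
            for j in range(4)
        ]
        rng = np.random.default_rng(7)
        attrs = pd.DataFrame(
            {
                name: rng.uniform(0.1, 0.9, 16)
                if name.startswith("prop_")
                else rng.uniform(50, 500, 16)
                for name in COVARIATE_NAMES
            },
            index=[tid for tid, _ in tracts],
        )
        nbs = [
            _nb(box(1000 * i, 1000 * j, 1000 * (i + 1), 1000 * (j + 1)), f"n{i}{j}")
            for i in range(2)
            for j in range(2)
        ]
        return nbs, tracts, attrs

    def test_extensive_totals_conserved_on_tiling(self):
        nbs, tracts, attrs = self._tiling()
        df = apportion_table(nbs, tracts, attrs)
        for name in ("total_population", "n_homes"):
            assert df[name].sum() == pytest.approx(attrs[name].sum(), rel=1e-6)

    def test_intensive_values_bounded_by_contributing_tracts(self):
        nbs, tracts, attrs = self._tiling()
        for nb in nbs:
            prof = apportion_profile(nb, tracts, attrs)
            contributing = list(intersection_weights(nb.geometry, tracts))
            for spec in DEFAULT_SPECS:
                if spec.kind != "intensive":
                    continue
                vals = attrs.loc[contributing, spec.name]
                assert vals.min() - 1e-9 <= prof[spec.name] <= vals.max() + 1e-9

    def test_refinement_invariance(self):
        nbs, tracts, attrs = self._tiling()
        before = [apportion_profile(nb, tracts, attrs) for nb in nbs]
        # split tract t00 into left/right halves, extensive values halved
        split = [t for t in tracts if t[0] != "t00"]
        split += [("t00a", box(0, 0, 250, 500)), ("t00b", box(250, 0, 500, 500))]
        attrs2 = attrs.drop(index="t00")
        row = attrs.loc["t00"].copy()
        half = row.copy()
        for name in ("total_population", "n_homes"):
            half[name] = row[name] / 2
        attrs2 = pd.concat([attrs2, half.rename("t00a").to_frame().T,
                            half.rename("t00b").to_frame().T])
        after = [apportion_profile(nb, split, attrs2) for nb in nbs]
        for b, a in zip(before, after):
            for name in COVARIATE_NAMES:
                assert a[name] == pytest.approx(b[name], rel=1e-9)
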