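import warnings

import numpy as np
import pandas as pd
import pytest

from serosom.somscape import (
    OVER,
    UNDER,
    MetageneLandscape,
    SOMLandscape,
    classify_metagenes,
    detect_spots,
    spot_summary,
)


def flood_fill_components(mask, adjacency):
    """Brute-force connected components by iterative flood fill."""
    rows, cols = mask.shape
    if adjacency == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    cr, cc = stack.pop()
                    comp.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


def toy_model(rows=3, cols=3, n_genes=45, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SOMLandscape(rows=rows, cols=cols, n_epochs=5, random_state=seed,
                             clip=None).fit(X)
    return model, X


class TestTraining:
    def test_duplicated_genes_share_a_unit(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 5))
        X = np.vstack([base, base])  # every gene duplicated
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = SOMLandscape(rows=4, cols=4, n_epochs=5, random_state=0).fit(X)
        assert (m.labels_[:30] == m.labels_[30:]).all()

    def test_same_seed_identical_codebook(self, small_logtpm):
        X = small_logtpm.values.iloc[:300]
        m1 = SOMLandscape(rows=5, cols=5, n_epochs=3, random_state=9).fit(X)
        m2 = SOMLandscape(rows=5, cols=5, n_epochs=3, random_state=9).fit(X)
        assert np.array_equal(m1.codebook_, m2.codebook_)
        assert np.array_equal(m1.labels_, m2.labels_)

    def test_two_separated_clouds_occupy_disjoint_units(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(40, 3))
        b = rng.normal(5, 0.05, size=(40, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = SOMLandscape(rows=2, cols=2, n_epochs=10, random_state=0,
                             scale="none").fit(np.vstack([a, b]))
        assert not (set(m.labels_[:40]) & set(m.labels_[40:]))

    def test_quantization_error_does_not_increase(self, small_logtpm):
        # tested with genes >> units; with nearly as many units as genes a
        # random-data-row init is already near-optimal quantization
        m = SOMLandscape(rows=10, cols=10, n_epochs=5, random_state=0).fit(
            small_logtpm.values
        )
        assert m.quantization_error_ <= m.initial_quantization_error_

    def test_topographic_ordering(self, small_logtpm):
        # lattice-adjacent codebooks are closer than random unit pairs
        m = SOMLandscape(rows=10, cols=10, n_epochs=5, random_state=0).fit(
            small_logtpm.values
        )
        cb = m.codebook_.reshape(10, 10, -1)
        adj = []
        for r in range(10):
            for c in range(9):
                adj.append(np.linalg.norm(cb[r, c] - cb[r, c + 1]))
                adj.append(np.linalg.norm(cb[c, r] - cb[c + 1, r]))
        rng = np.random.default_rng(0)
        rand = [
            np.linalg.norm(m.codebook_[i] - m.codebook_[j])
            for i, j in rng.integers(0, 100, size=(500, 2))
            if i != j
        ]
        assert np.mean(adj) < np.mean(rand)

    def test_nan_input_rejected(self):
        X = np.full((30, 3), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            SOMLandscape(rows=2, cols=2).fit(X)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            SOMLandscape(rows=2, cols=2).fit(np.zeros((30, 1)))

    def test_predict_is_argmin_assignment(self):
        m, X = toy_model()
        d = ((m._scaled(X.to_numpy())[:, None, :] - m.codebook_[None]) ** 2).sum(axis=2)
        assert np.array_equal(m.predict(X), d.argmin(axis=1))


class TestLandscape:
    def test_unit_mean_closed_form(self):
        m, X = toy_model()
        ls = m.landscape("s0")
        unit = m.labels_[0]
        members = np.nonzero(m.labels_ == unit)[0]
        expected = m._scaled(X.to_numpy())[members, 0].mean()
        assert ls.grid.flat[unit] == pytest.approx(expected)

    def test_grid_matches_groupby_oracle(self):
        m, X = toy_model(rows=4, cols=4, n_genes=120, seed=3)
        scaled = m._scaled(X.to_numpy())
        for j, s in enumerate(m.sample_ids_):
            ls = m.landscape(s)
            df = pd.DataFrame({"unit": m.labels_, "val": scaled[:, j]})
            means = df.groupby("unit")["val"].mean()
            for u, v in means.items():
                assert ls.grid.flat[u] == pytest.approx(v)

    def test_bounds_track_occupied_extremes(self):
        m, _ = toy_model()
        ls = m.landscape("s1")
        occ = ls.grid[~ls.empty]
        assert ls.min_exp == occ.min() and ls.max_exp == occ.max()
        assert ls.min_exp <= ls.max_exp

    def test_unknown_sample_rejected(self):
        m, _ = toy_model()
        with pytest.raises(KeyError):
            m.landscape("nope")


def make_ls(grid, empty=None):
    grid = np.asarray(grid, dtype=float)
    empty = np.zeros_like(grid, dtype=bool) if empty is None else empty
    return MetageneLandscape("s", grid, empty)


class TestClassification:
    def test_strict_upper_boundary(self):
        # MaxEXP = 10: 9.5 is over, exactly 9.0 is not (strict >)
        ls = make_ls([[10.0, 9.5], [9.0, -10.0]])
        out = classify_metagenes(ls, factor=0.9)
        assert out[0, 0] == OVER and out[0, 1] == OVER and out[1, 0] == 0

    def test_strict_lower_boundary(self):
        ls = make_ls([[10.0, -9.5], [-9.0, -10.0]])
        out = classify_metagenes(ls, factor=0.9)
        assert out[1, 1] == UNDER and out[0, 1] == UNDER and out[1, 0] == 0

    def test_degenerate_factor_zero(self):
        ls = make_ls([[3.0, -2.0], [0.5, -0.1]])
        out = classify_metagenes(ls, factor=0.0)
        assert (out[np.asarray(ls.grid) > 0] == OVER).all()
        assert (out[np.asarray(ls.grid) < 0] == UNDER).all()

    def test_constant_grid_all_none(self):
        assert (classify_metagenes(make_ls(np.full((3, 3), 2.0))) == 0).all()

    def test_ill_posed_sign_regime_warns_and_returns_none(self):
        ls = make_ls([[5.0, 4.0], [3.0, 2.0]])  # MinEXP > 0
        with pytest.warns(UserWarning, match="ill-posed"):
            out = classify_metagenes(ls)
        assert (out == 0).all()

    def test_empty_units_never_classified(self):
        empty = np.array([[False, True], [False, False]])
        ls = make_ls([[10.0, 20.0], [-10.0, 1.0]], empty)
        out = classify_metagenes(ls, factor=0.9)
        assert out[0, 1] == 0
        assert ls.max_exp == 10.0  # empty unit excluded from MaxEXP


class TestSpots:
    def test_single_over_unit(self):
        m, _ = toy_model()
        grid = np.zeros((3, 3), dtype=np.int8)
        grid[1, 1] = OVER
        spots = detect_spots(grid, m, "s0")
        assert len(spots) == 1
        assert spots[0].units == frozenset({(1, 1)})
        assert spots[0].size == len(m.unit_genes(1 * 3 + 1))

    def test_diagonal_connectivity_semantics(self):
        m, _ = toy_model()
        grid = np.zeros((3, 3), dtype=np.int8)
        grid[0, 0] = grid[1, 1] = OVER
        assert len(detect_spots(grid, m, "s0", adjacency=4)) == 2
        assert len(detect_spots(grid, m, "s0", adjacency=8)) == 1

    @pytest.mark.parametrize("adjacency", [4, 8])
    def test_matches_flood_fill_oracle(self, adjacency, rng):
        m, _ = toy_model(rows=6, cols=6, n_genes=200)
        for _ in range(30):
            grid = rng.choice([0, OVER, UNDER], size=(6, 6), p=[0.6, 0.2, 0.2]).astype(np.int8)
            spots = detect_spots(grid, m, "s0", adjacency=adjacency)
            for cls_val, cls_name in ((OVER, "over"), (UNDER, "under")):
                got = {s.units for s in spots if s.spot_class == cls_name}
                assert got == flood_fill_components(grid == cls_val, adjacency)

    def test_partition_property(self, rng):
        m, _ = toy_model(rows=5, cols=5, n_genes=150)
        grid = rng.choice([0, OVER], size=(5, 5), p=[0.5, 0.5]).astype(np.int8)
        spots = detect_spots(grid, m, "s0")
        over_units = [u for s in spots if s.spot_class == "over" for u in s.units]
        assert len(over_units) == len(set(over_units)) == int((grid == OVER).sum())

    def test_ordering_by_size_then_anchor(self, rng):
        m, _ = toy_model(rows=6, cols=6, n_genes=200)
        grid = rng.choice([0, OVER], size=(6, 6), p=[0.4, 0.6]).astype(np.int8)
        spots = detect_spots(grid, m, "s0")
        keys = [(-s.size, s.anchor) for s in spots]
        assert keys == sorted(keys)

    def test_summary_bookkeeping(self):
        m, _ = toy_model()
        grid = np.zeros((3, 3), dtype=np.int8)
        grid[0, 0] = OVER
        grid[2, 2] = UNDER
        spots = detect_spots(grid, m, "s0") + detect_spots(grid, m, "s1")
        table, incidence = spot_summary(spots)
        assert len(table) == 4
        # each gene's row sum counts its spot memberships
        for g in incidence.index:
            n_member = sum(1 for s in spots if g in s.genes)
            assert incidence.loc[g].sum() == n_member

    def test_empty_grid_gives_no_spots(self):
        m, _ = toy_model()
        table, incidence = spot_summary(detect_spots(np.zeros((3, 3), np.int8), m, "s0"))
        assert len(table) == 0 and incidence.shape[1] == 0
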