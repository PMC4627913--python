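"""Recipient-area elimination model: rules, patches, order invariance."""

import numpy as np
import pytest

from transloc.suitability import (
    DEFAULT_MIN_PATCH_KM2,
    LEVEL_CODE,
    ExclusionRule,
    MissingLayerError,
    SuitabilityStack,
    apply_exclusions,
    default_rules,
    filter_by_patch_size,
    label_patches,
    read_ascii_grid,
    run_model,
    write_ascii_grid,
)


def make_stack(
    shape=(10, 10),
    cell=2.0,
    pa=None,
    cheetah="low",
    lion="none",
    hyaena="none",
    urban_km=1000.0,
):
    full = np.ones(shape, dtype=np.int8)
    return SuitabilityStack(
        pa_mask=np.ones(shape, bool) if pa is None else pa,
        occurrence={
            "cheetah": full * LEVEL_CODE[cheetah],
            "lion": full * LEVEL_CODE[lion],
            "hyaena": full * LEVEL_CODE[hyaena],
        },
        urban_distance_km=np.full(shape, urban_km, float),
        cell_size_km=cell,
    )


def random_stack(rng, shape=(15, 15)):
    return SuitabilityStack(
        pa_mask=rng.random(shape) < 0.7,
        occurrence={
            sp: rng.integers(0, 4, shape).astype(np.int8)
            for sp in ("cheetah", "lion", "hyaena")
        },
        urban_distance_km=rng.uniform(0, 120, shape),
        cell_size_km=2.0,
    )


def flood_fill_labels(mask, connectivity=8):
    """Brute-force connected components (oracle)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nxt = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    a, b = stack.pop()
                    for da, db in nbrs:
                        x, y = a + da, b + db
                        if (
                            0 <= x < mask.shape[0]
                            and 0 <= y < mask.shape[1]
                            and mask[x, y]
                            and labels[x, y] == 0
                        ):
                            labels[x, y] = nxt
                            stack.append((x, y))
    return labels, nxt


class TestApplyExclusions:
    def test_all_permissive_stack_keeps_whole_pa(self):
        st = make_stack()
        mask, impact = apply_exclusions(st, default_rules())
        assert mask.all()
        assert all(v == 0.0 for v in impact.values())

    def test_high_lion_everywhere_eliminates_everything(self):
        st = make_stack(lion="high")
        mask, impact = apply_exclusions(st, default_rules())
        assert not mask.any()
        assert impact["lion_occurrence"] == 100.0

    def test_no_cheetah_occurrence_excluded(self):
        st = make_stack(cheetah="none")
        mask, _ = apply_exclusions(st, default_rules())
        assert not mask.any()

    def test_urban_buffer_is_50_km(self):
        near = make_stack(urban_km=50.0)  # boundary: excluded (<= 50)
        far = make_stack(urban_km=50.001)
        assert not apply_exclusions(near, default_rules())[0].any()
        assert apply_exclusions(far, default_rules())[0].all()

    def test_hand_constructed_grid_matches_enumeration(self):
        rng = np.random.default_rng(3)
        st = random_stack(rng, (10, 10))
        mask, _ = apply_exclusions(st, default_rules())
        for i in range(10):
            for j in range(10):
                expect = (
                    st.pa_mask[i, j]
                    and st.occurrence["cheetah"][i, j] in (1, 2)
                    and st.occurrence["hyaena"][i, j] in (0, 1)
                    and st.occurrence["lion"][i, j] in (0, 1)
                    and st.urban_distance_km[i, j] > 50.0
                )
                assert mask[i, j] == expect, (i, j)

    def test_missing_layer_is_named(self):
        st = make_stack()
        st = SuitabilityStack(
            pa_mask=st.pa_mask,
            occurrence={"cheetah": st.occurrence["cheetah"]},
            urban_distance_km=st.urban_distance_km,
            cell_size_km=st.cell_size_km,
        )
        with pytest.raises(MissingLayerError, match="lion"):
            apply_exclusions(st, default_rules())

    def test_suitable_area_monotone_in_rules(self):
        rng = np.random.default_rng(8)
        st = random_stack(rng)
        rules = default_rules()
        prev = st.shape[0] * st.shape[1]
        for k in range(1, len(rules) + 1):
            mask, _ = apply_exclusions(st, rules[:k])
            assert mask.sum() <= prev
            prev = mask.sum()

    def test_rule_order_invariance_on_random_stacks(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            st = random_stack(rng)
            rules = default_rules()
            base, _ = apply_exclusions(st, rules)
            perm = [rules[k] for k in rng.permutation(len(rules))]
            permuted, _ = apply_exclusions(st, perm)
            assert np.array_equal(base, permuted)


class TestLabelPatches:
    def test_single_rectangle_one_patch(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:8] = True
        rep = label_patches(mask, cell_size_km=2.0)
        assert rep.n_patches == 1
        assert rep.patches[0].area_km2 == pytest.approx(15 * 4.0)

    def test_diagonal_blocks_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[:2, :2] = True
        mask[2:, 2:] = True
        assert label_patches(mask, 1.0, connectivity=8).n_patches == 1
        assert label_patches(mask, 1.0, connectivity=4).n_patches == 2

    def test_empty_mask_zero_patches(self):
        rep = label_patches(np.zeros((5, 5), bool), 1.0)
        assert rep.n_patches == 0 and rep.suitable_area_km2 == 0.0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(19)
        for _ in range(15):
            mask = rng.random((20, 20)) < 0.45
            rep = label_patches(mask, 1.0, connectivity=connectivity)
            oracle_labels, oracle_n = flood_fill_labels(mask, connectivity)
            assert rep.n_patches == oracle_n
            # same partition up to label permutation
            for k in range(1, oracle_n + 1):
                cells = rep.labels[oracle_labels == k]
                assert len(set(cells.tolist())) == 1 and cells[0] != 0

    def test_patch_areas_conserve_suitable_area(self):
        rng = np.random.default_rng(20)
        mask = rng.random((30, 30)) < 0.5
        rep = label_patches(mask, 2.0)
        assert sum(p.area_km2 for p in rep.patches) == pytest.approx(
            rep.suitable_area_km2
        )


class TestPatchFilter:
    def _patchy_report(self):
        mask = np.zeros((20, 20), bool)
        mask[0:5, 0:5] = True  # 25 cells = 100 km2 at 2 km cells
        mask[10:12, 10:12] = True  # 4 cells = 16 km2
        return label_patches(mask, 2.0)

    def test_zero_minimum_is_identity(self):
        rep = self._patchy_report()
        out = filter_by_patch_size(rep, 0.0)
        assert out.n_patches == rep.n_patches

    def test_minimum_above_largest_empties_report(self):
        out = filter_by_patch_size(self._patchy_report(), 101.0)
        assert out.n_patches == 0 and out.suitable_area_km2 == 0.0

    def test_exploratory_movement_bound_eliminates_all_small_patches(self):
        """With the observed 19,743 km^2 exploration bound, any landscape of
        smaller patches yields no suitable areas (the full-model outcome)."""
        out = filter_by_patch_size(self._patchy_report(), DEFAULT_MIN_PATCH_KM2)
        assert out.n_patches == 0


class TestRunModel:
    def test_full_mode_keeps_large_compliant_patch_only(self):
        pa = np.zeros((40, 40), bool)
        pa[0:30, 0:30] = True  # 900 cells * 4 km2 = 3600 km2
        st = make_stack((40, 40), pa=pa)
        kept = run_model(st, mode="full", min_patch_area_km2=3000.0)
        assert kept.n_patches == 1
        dropped = run_model(st, mode="full", min_patch_area_km2=4000.0)
        assert dropped.n_patches == 0
        no_fid = run_model(st, mode="no_site_fidelity", min_patch_area_km2=4000.0)
        assert no_fid.n_patches == 1

    def test_engineered_patch_sizes_are_recovered(self):
        pa = np.zeros((90, 90), bool)
        sizes = []
        r = 0
        for side in [2, 3, 4, 5, 6, 7, 8, 9, 10, 12]:
            pa[r : r + side, r : r + side] = True  # diagonal, 2-cell spacing
            sizes.append(side * side * 4.0)
            r += side + 2
        st = make_stack((90, 90), pa=pa)
        rep = run_model(st, mode="no_site_fidelity")
        assert rep.n_patches == 10
        assert sorted(rep.areas()) == sorted(sizes)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            run_model(make_stack(), mode="banana")


class TestAsciiGridIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 4, (12, 9)).astype(float)
        p = tmp_path / "occ.asc"
        write_ascii_grid(p, grid, 2.0)
        back, cell = read_ascii_grid(p)
        assert cell == 2.0
        assert np.array_equal(back, grid)
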