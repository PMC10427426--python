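"""Tissue detection, patching, descriptors, clustering and the
cluster-proportion association statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from trialomics import her2_spatial as hs
from trialomics import synthetic_data as sd

from conftest import textured_disc_slide


class TestDetectTissue:
    def test_uniform_image_gives_empty_mask(self):
        img = np.full((1024, 1024, 3), 128, dtype=np.uint8)
        mask = hs.detect_tissue(hs.SlideImage(pixels=img, slide_id="flat"))
        assert not mask.mask.any()

    def test_textured_disc_recovered(self):
        slide, disc, _ = textured_disc_slide(seed=3)
        mask = hs.detect_tissue(slide)
        truth = disc.reshape(128, 8, 128, 8).mean(axis=(1, 3)) > 0.5
        iou = (mask.mask & truth).sum() / (mask.mask | truth).sum()
        assert iou >= 0.90

    def test_small_speck_removed(self):
        # speck of ~100 downsampled px (radius 45 full-res -> ~80 down px)
        slide, disc, speck = textured_disc_slide(seed=3, speck=45)
        mask = hs.detect_tissue(slide)
        speck_down = speck.reshape(128, 8, 128, 8).mean(axis=(1, 3)) > 0.5
        assert not (mask.mask & speck_down).any()

    def test_mask_dims_are_ceil_of_downsample(self):
        img = np.full((1000, 520, 3), 128, dtype=np.uint8)
        mask = hs.detect_tissue(hs.SlideImage(pixels=img, slide_id="odd"))
        assert mask.mask.shape == (125, 65)

    def test_degenerate_size_error(self):
        img = np.zeros((80, 80, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            hs.detect_tissue(hs.SlideImage(pixels=img, slide_id="tiny"))


def _full_mask(shape_px):
    return hs.TissueMask(mask=np.ones((shape_px[0] // 8, shape_px[1] // 8), bool))


class TestExtractPatches:
    def test_full_tissue_exact_tiling(self):
        img = np.full((128, 128, 3), 128, dtype=np.uint8)
        slide = hs.SlideImage(pixels=img, slide_id="s")
        patches = hs.extract_patches(slide, _full_mask((128, 128)))
        assert len(patches) == 4
        origins = {p.origin for p in patches}
        assert origins == {(0, 0), (0, 64), (64, 0), (64, 64)}

    def test_all_black_slide_yields_nothing(self):
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        slide = hs.SlideImage(pixels=img, slide_id="b")
        assert hs.extract_patches(slide, _full_mask((128, 128))) == []

    def test_black_fraction_strict_inequality(self):
        """A tile at/below 70% black values is retained; above is not."""
        n_vals = 64 * 64 * 3
        for count, kept in [(8601, True), (8603, False)]:  # 0.69995 / 0.70011
            flat = np.full(n_vals, 128, dtype=np.uint8)
            flat[:count] = 0
            img = flat.reshape(64, 64, 3)
            slide = hs.SlideImage(pixels=img, slide_id="t")
            got = hs.extract_patches(slide, _full_mask((64, 64)))
            assert (len(got) == 1) == kept

    def test_patches_do_not_overlap(self, small_ihc_cohort):
        slide = small_ihc_cohort.slides[0]
        patches = hs.extract_patches(slide, hs.detect_tissue(slide))
        origins = [p.origin for p in patches]
        assert len(origins) == len(set(origins))
        assert all(r % 64 == 0 and c % 64 == 0 for r, c in origins)

    def test_roi_restricts_patches(self):
        img = np.full((256, 256, 3), 128, dtype=np.uint8)
        roi = [(0.0, 0.0), (128.0, 0.0), (128.0, 128.0), (0.0, 128.0)]
        slide = hs.SlideImage(pixels=img, slide_id="r", rois=[roi])
        patches = hs.extract_patches(slide, _full_mask((256, 256)))
        assert {p.origin for p in patches} == {(0, 0), (0, 64), (64, 0), (64, 64)}


class TestDescriptors:
    def test_identical_patches_identical_rows(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        patches = [hs.Patch(slide_id="s", origin=(0, 0), pixels=tile) for _ in range(2)]
        f = hs.compute_descriptors(patches)
        assert np.allclose(f.features[0], f.features[1])

    def test_dab_monotone_in_staining(self):
        """Forward Beer-Lambert mixing: a DAB-stained tile must score a
        strictly larger raw mean DAB OD than an unstained one."""
        basis = sd.SyntheticCohortConfig().stain_basis.matrix()
        ext = hs.HandcraftedDescriptor()
        tiles = []
        for dab in (0.0, 0.8):
            od = 0.1 * basis[:, 0] + dab * basis[:, 1]
            rgb = np.clip(245 * np.power(10.0, -od), 0, 255).astype(np.uint8)
            tiles.append(np.tile(rgb, (64, 64, 1)))
        raw_unstained = ext(tiles[0])
        raw_stained = ext(tiles[1])
        assert raw_stained[0] > raw_unstained[0] + 0.5

    def test_shape_contract(self, small_cohort_patches):
        patches, _ = small_cohort_patches
        f = hs.compute_descriptors(patches)
        assert f.features.shape[0] == len(patches)
        assert np.isfinite(f.features).all()
        # z-scoring: kept features have mean ~0, sd ~1 across all patches
        assert np.allclose(f.features.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(f.features.std(axis=0), 1.0, atol=1e-6)

    def test_dimension_mismatch_error(self):
        class Broken:
            dim = 5

            def __call__(self, pixels):
                return np.zeros(3)

        tile = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="dimension mismatch"):
            hs.compute_descriptors(
                [hs.Patch(slide_id="s", origin=(0, 0), pixels=tile)], extractor=Broken()
            )


def _blobs(k, n_per, dim=5, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(k, dim))
    x = np.concatenate([c + rng.normal(0, 1, size=(n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return x, labels


def davies_bouldin_direct(x, labels):
    """Direct implementation of the Davies-Bouldin formula."""
    ks = np.unique(labels)
    cents = np.stack([x[labels == c].mean(axis=0) for c in ks])
    scatter = np.array(
        [np.mean(np.linalg.norm(x[labels == c] - cents[i], axis=1)) for i, c in enumerate(ks)]
    )
    total = 0.0
    for i in range(len(ks)):
        ratios = [
            (scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(ks))
            if j != i
        ]
        total += max(ratios)
    return total / len(ks)


class TestClustering:
    def test_separated_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        x, truth = _blobs(3, 60)
        model = hs.fit_clusters(x, 3, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_identical_rows_flagged_degenerate(self):
        x = np.ones((30, 4))
        model = hs.fit_clusters(x, 2, seed=0)
        assert model.degenerate or len(np.unique(model.labels)) == 1

    def test_same_seed_same_labels(self):
        x, _ = _blobs(4, 50, seed=3)
        a = hs.fit_clusters(x, 4, seed=9)
        b = hs.fit_clusters(x, 4, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_k_bounds(self):
        x, _ = _blobs(2, 3)
        with pytest.raises(ValueError):
            hs.fit_clusters(x, 1, seed=0)
        with pytest.raises(ValueError):
            hs.fit_clusters(x, 7, seed=0)

    def test_select_k_recovers_planted_two(self):
        x, _ = _blobs(2, 80, seed=5)
        k_best, model = hs.select_k(x, range(2, 5), seed=5)
        assert k_best == 2
        assert model.db_index == pytest.approx(
            davies_bouldin_direct(x, model.labels), rel=1e-9
        )

    def test_select_k_recovers_planted_eight_blobs(self):
        x, _ = _blobs(8, 60, dim=6, sep=10.0, seed=2)
        k_best, _ = hs.select_k(x, range(7, 13), seed=2)
        assert k_best == 8


class TestSlideProfile:
    def test_direct_count(self):
        prof = hs.slide_profile([0, 0, 1, 3], 4)
        assert np.allclose(prof.v, [0.5, 0.25, 0.0, 0.25])

    def test_one_hot(self):
        prof = hs.slide_profile([2] * 7, 5)
        assert np.allclose(prof.v, [0, 0, 1, 0, 0])

    def test_random_labels_properties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 10))
            n = int(rng.integers(1, 50))
            labels = rng.integers(0, k, size=n)
            prof = hs.slide_profile(labels, k)
            assert prof.v.sum() == pytest.approx(1.0, abs=1e-9)
            counts = prof.v * prof.n_patches
            assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_empty_slide_error(self):
        with pytest.raises(ValueError):
            hs.slide_profile([], 4)


def _profiles_from_matrix(v, ids=None):
    ids = ids or [f"s{i}" for i in range(len(v))]
    return [
        hs.SlideClusterProfile(slide_id=i, v=np.asarray(row, float), n_patches=100)
        for i, row in zip(ids, v)
    ]


class TestAssociation:
    def test_identical_proportions_p_one(self):
        v = [[0.5, 0.5]] * 8
        assoc = hs.associate_clusters(_profiles_from_matrix(v), [True] * 4 + [False] * 4)
        assert all(a.p_value == 1.0 for a in assoc)

    def test_exact_p_matches_permutation_enumeration(self):
        """For groups of 3 vs 3, the exact Mann-Whitney p equals full
        enumeration over all 20 group assignments."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=3)
        y = rng.normal(loc=1.2, size=3)
        u_obs, p = hs.mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        center = 3 * 3 / 2
        stat_obs = abs(u_obs - center)
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(6) if i not in idx]]
            u = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
            count += abs(u - center) >= stat_obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_bh_arithmetic_example(self):
        ps = [0.011, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        qs = hs.benjamini_hochberg(ps)
        assert min(qs) == pytest.approx(0.088, abs=1e-12)

    def test_bh_matches_independent_step_up(self):
        """Package BH equals a hand-written step-up on 1,000 random
        p-vectors."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            got = hs.benjamini_hochberg(p)
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            want = np.empty(m)
            want[order] = np.minimum(adj, 1.0)
            assert np.max(np.abs(got - want)) < 1e-12

    def test_single_group_error(self):
        v = [[0.5, 0.5]] * 4
        with pytest.raises(ValueError):
            hs.associate_clusters(_profiles_from_matrix(v), [True, True, True, False])

    def test_direction_sign(self):
        rng = np.random.default_rng(5)
        hi = 0.6 + 0.01 * rng.uniform(size=(4, 1))
        lo = 0.4 + 0.01 * rng.uniform(size=(4, 1))
        v = np.hstack([np.vstack([hi, lo]), 1 - np.vstack([hi, lo])])
        assoc = hs.associate_clusters(
            _profiles_from_matrix(v.tolist()), [True] * 4 + [False] * 4
        )
        assert assoc[0].direction == 1
        assert assoc[1].direction == -1


def test_pipeline_invariant_to_slide_ordering(small_ihc_cohort):
    """Reversing slide order leaves labels, profiles and p-values
    unchanged (descriptor rows are canonically sorted)."""

    def run(slides):
        patches = []
        for s in slides:
            patches.extend(hs.extract_patches(s, hs.detect_tissue(s)))
        feats = hs.compute_descriptors(patches)
        model = hs.fit_clusters(feats, 4, seed=0)
        profiles = hs.profiles_from_labels(model.labels, feats.slide_ids, 4)
        return {p.slide_id: p.v for p in profiles}

    fwd = run(small_ihc_cohort.slides)
    rev = run(small_ihc_cohort.slides[::-1])
    assert fwd.keys() == rev.keys()
    for sid in fwd:
        assert np.allclose(fwd[sid], rev[sid])
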