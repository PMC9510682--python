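"""Scan-specific thresholds, region growing, lesion extraction, FP reduction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from cacuda.io_ct import LesionLabelMap
from cacuda.phantom import PhantomParams, generate_phantom
from cacuda.scoring import (
    AORTA_MEAN_PLUS_3SD,
    Lesion,
    ScanThreshold,
    ScoringError,
    compute_scan_threshold,
    extract_lesions,
    fixed_threshold,
    fp_reduction,
    grow_lesions,
    lesions_to_label_map,
    make_heart_mask,
    score_scan,
)
from conftest import make_volume


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def two_pass_mean_sd(values):
    vals = [float(v) for v in np.asarray(values).ravel()]
    m = sum(vals) / len(vals)
    var = sum((v - m) ** 2 for v in vals) / len(vals)
    return m, var ** 0.5


def bfs_grow(detected, voxels, threshold):
    """Flood-fill oracle for region growing, including majority conflicts."""
    shape = detected.shape
    supra = voxels > threshold
    out = np.zeros_like(detected)
    seeds = list(map(tuple, np.argwhere(detected > 0)))
    visited = np.zeros(shape, dtype=bool)
    for start in seeds:
        if not supra[start] or visited[start]:
            continue
        comp, stack = [], [start]
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)):
                nb = tuple(np.add(v, d))
                if all(0 <= nb[i] < shape[i] for i in range(3)) \
                        and supra[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        votes = [detected[v] for v in comp if detected[v] > 0]
        counts = [votes.count(k) for k in (1, 2, 3)]
        lab = int(np.argmax(counts)) + 1  # ties to lower class id
        for v in comp:
            out[v] = lab
    for s in seeds:
        if not supra[s]:
            out[s] = detected[s]
    return out


class UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[ra] = rb


def union_find_components(labels):
    """Per-class 6-connected component sizes, via union-find."""
    idx = {tuple(v): i for i, v in enumerate(np.argwhere(labels > 0))}
    uf = UnionFind(len(idx))
    for v, i in idx.items():
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if nb in idx and labels[nb] == labels[v]:
                uf.union(i, idx[nb])
    sizes = {}
    for v, i in idx.items():
        root = uf.find(i)
        key = (int(labels[v]), root)
        sizes[key] = sizes.get(key, 0) + 1
    out = {}
    for (cls, _), n in sizes.items():
        out.setdefault(cls, []).append(n)
    return {cls: sorted(v) for cls, v in out.items()}


# ---------------------------------------------------------------------------
# Scan-specific threshold
# ---------------------------------------------------------------------------

class TestScanThreshold:
    def test_constant_roi_gives_threshold_equal_to_mean(self):
        vol = make_volume(np.full((10, 10, 10), 400.0))
        thr = compute_scan_threshold(vol, ((2, 2, 2), (6, 6, 6)))
        assert thr.threshold_hu == pytest.approx(400.0)
        assert thr.roi_sd_hu == pytest.approx(0.0)

    def test_two_value_roi_closed_form(self):
        arr = np.full((4, 4, 4), 300.0)
        arr[:2] = 500.0  # half 300, half 500 -> mean 400, population sd 100
        vol = make_volume(arr)
        thr = compute_scan_threshold(vol, ((0, 0, 0), (4, 4, 4)))
        assert thr.roi_mean_hu == pytest.approx(400.0)
        assert thr.roi_sd_hu == pytest.approx(100.0)
        assert thr.threshold_hu == pytest.approx(700.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = make_volume(rng.uniform(100, 900, (9, 9, 9)))
        thr = compute_scan_threshold(vol, ((1, 2, 3), (7, 8, 9)))
        m, sd = two_pass_mean_sd(vol.voxels[1:7, 2:8, 3:9])
        assert thr.roi_mean_hu == pytest.approx(m, abs=1e-9)
        assert thr.roi_sd_hu == pytest.approx(sd, abs=1e-9)
        assert thr.threshold_hu == pytest.approx(m + 3 * sd, abs=1e-9)

    def test_roi_outside_volume_rejected(self):
        vol = make_volume(np.zeros((8, 8, 8)))
        with pytest.raises(ScoringError):
            compute_scan_threshold(vol, ((0, 0, 0), (9, 4, 4)))

    def test_threshold_invariant_enforced(self):
        with pytest.raises(ScoringError):
            ScanThreshold(500.0, 400.0, 10.0, AORTA_MEAN_PLUS_3SD)


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

class TestGrowLesions:
    def test_empty_detection_grows_nothing(self):
        vol = make_volume(np.full((6, 6, 6), 500.0))
        out = grow_lesions(np.zeros((6, 6, 6), dtype=np.uint8), vol,
                           fixed_threshold())
        assert not out.labels.any()

    def test_single_seed_fills_blob(self):
        arr = np.zeros((8, 8, 8), dtype=np.float32)
        arr[2:4, 2:4, 2:4] = 300.0  # hot blob, 8 voxels
        arr[2, 2, 4] = arr[2, 2, 5] = 300.0  # appendage -> 10 voxels total
        det = np.zeros((8, 8, 8), dtype=np.uint8)
        det[2, 2, 2] = 1
        out = grow_lesions(det, make_volume(arr), fixed_threshold())
        assert (out.labels == 1).sum() == 10

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 300, (12, 12, 12)).astype(np.float32)
        det = np.where(rng.random((12, 12, 12)) < 0.04,
                       rng.integers(1, 4, (12, 12, 12)), 0).astype(np.uint8)
        vol = make_volume(arr)
        got = grow_lesions(det, vol, fixed_threshold())
        assert np.array_equal(got.labels, bfs_grow(det, arr, 130.0))

    def test_conflict_resolved_by_seed_majority_then_lower_id(self):
        arr = np.zeros((10, 4, 4), dtype=np.float32)
        arr[1:9, 1, 1] = 300.0  # one 8-voxel supra-threshold strip
        det = np.zeros((10, 4, 4), dtype=np.uint8)
        det[1, 1, 1] = 3
        det[2, 1, 1] = 3
        det[8, 1, 1] = 1  # minority seed
        out = grow_lesions(det, make_volume(arr), fixed_threshold())
        assert set(np.unique(out.labels[arr > 130.0])) == {3}
        det[7, 1, 1] = 1  # now tied 2 vs 2 -> lower class id wins
        out = grow_lesions(det, make_volume(arr), fixed_threshold())
        assert set(np.unique(out.labels[arr > 130.0])) == {1}

    def test_idempotent_on_its_own_output(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 300, (10, 10, 10)).astype(np.float32)
        det = np.where(rng.random((10, 10, 10)) < 0.05,
                       rng.integers(1, 4, (10, 10, 10)), 0).astype(np.uint8)
        vol = make_volume(arr)
        once = grow_lesions(det, vol, fixed_threshold())
        twice = grow_lesions(once, vol, fixed_threshold())
        assert np.array_equal(once.labels, twice.labels)


# ---------------------------------------------------------------------------
# Lesion extraction
# ---------------------------------------------------------------------------

class TestExtractLesions:
    def test_edge_adjacent_voxels_are_two_lesions(self):
        lab = np.zeros((5, 5, 5), dtype=np.uint8)
        lab[1, 1, 1] = 1
        lab[2, 2, 1] = 1  # touches only along an edge, not a face
        lesions = extract_lesions(lab, (1, 1, 1))
        assert len(lesions) == 2

    def test_single_voxel_volume(self):
        lab = np.zeros((4, 4, 4), dtype=np.uint8)
        lab[1, 2, 3] = 2
        [les] = extract_lesions(lab, (1.5, 1.5, 1.5))
        assert les.volume_mm3 == pytest.approx(3.375)
        assert les.artery_name == "LCX"

    def test_touching_lesions_of_different_arteries_stay_distinct(self):
        lab = np.zeros((5, 5, 5), dtype=np.uint8)
        lab[1, 1, 1] = 1
        lab[2, 1, 1] = 2  # face-adjacent but different artery
        assert len(extract_lesions(lab, (1, 1, 1))) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.where(rng.random((20, 20, 20)) < 0.15,
                       rng.integers(1, 4, (20, 20, 20)), 0).astype(np.uint8)
        lesions = extract_lesions(lab, (1, 1, 1))
        got = {}
        for les in lesions:
            got.setdefault(les.artery, []).append(les.n_voxels)
        got = {cls: sorted(v) for cls, v in got.items()}
        assert got == union_find_components(lab)

    def test_peak_hu_and_ordering(self):
        lab = np.zeros((6, 6, 6), dtype=np.uint8)
        lab[1, 1, 1] = lab[4, 4, 4] = 1
        hu = np.zeros((6, 6, 6))
        hu[1, 1, 1], hu[4, 4, 4] = 320.0, 510.0
        lesions = extract_lesions(lab, (1, 1, 1), hu=hu)
        assert [l.peak_hu for l in lesions] == [320.0, 510.0]
        assert lesions[0].centroid_mm < lesions[1].centroid_mm


# ---------------------------------------------------------------------------
# Heart mask dilation and FP reduction
# ---------------------------------------------------------------------------

class TestHeartMask:
    def test_zero_diameter_is_identity(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        out = make_heart_mask(mask, (1, 1, 1), 0.0)
        assert np.array_equal(out, mask)

    def test_single_voxel_dilates_to_euclidean_ball(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[5, 5, 5] = True
        out = make_heart_mask(mask, (1.0, 1.0, 1.0), 10.0)
        g = np.indices((11, 11, 11)) - 5
        ball = (g ** 2).sum(axis=0) <= 25.0 + 1e-9
        assert np.array_equal(out, ball)

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1.5, 1.5, 3.0)])
    def test_matches_distance_transform_oracle(self, spacing):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12, 12)) < 0.03
        mask[6, 6, 6] = True
        out = make_heart_mask(mask, spacing, 10.0)
        assert np.all(out[mask])  # superset of the input
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        assert np.array_equal(out, dist <= 5.0 + 1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ScoringError):
            make_heart_mask(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))


def _lesion(artery, volume, centroid=(5.0, 5.0, 5.0)):
    return Lesion(artery, np.array([[5, 5, 5]]), volume, centroid)


class TestFpReduction:
    def test_published_rules(self):
        """<1 mm^3 and >500 mm^3 are discarded, as is anything outside the
        dilated heart; a typical 7.1 mm^3 lesion survives."""
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[3:9, 3:9, 3:9] = True
        lesions = [
            _lesion(1, 0.5),
            _lesion(2, 7.1),
            _lesion(3, 625.0),
            _lesion(1, 40.0, centroid=(11.0, 11.0, 11.0)),  # outside mask
        ]
        kept, removed = fp_reduction(lesions, mask, (1, 1, 1))
        assert [l.volume_mm3 for l in kept] == [7.1]
        reasons = {l.volume_mm3: why for l, why in removed}
        assert reasons == {0.5: "too_small", 625.0: "too_large",
                           40.0: "outside_heart"}

    def test_boundary_volumes_are_kept(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        kept, removed = fp_reduction([_lesion(1, 1.0), _lesion(2, 500.0)],
                                     mask, (1, 1, 1))
        assert len(kept) == 2 and not removed

    @given(st.lists(st.tuples(st.integers(1, 3), st.floats(0.1, 1000)),
                    max_size=12))
    def test_partition_property(self, spec):
        mask = np.ones((12, 12, 12), dtype=bool)
        lesions = [_lesion(a, v) for a, v in spec]
        kept, removed = fp_reduction(lesions, mask, (1, 1, 1))
        assert len(kept) + len(removed) == len(lesions)
        assert set(map(id, kept)).isdisjoint(id(l) for l, _ in removed)


# ---------------------------------------------------------------------------
# score_scan
# ---------------------------------------------------------------------------

class TestScoreScan:
    def test_no_detections_give_zero_report(self):
        vol = make_volume(np.full((8, 8, 8), 40.0))
        mask = np.ones((8, 8, 8), dtype=bool)
        report, lesions = score_scan(vol, np.zeros((8, 8, 8), dtype=np.uint8),
                                     fixed_threshold(), mask)
        assert report.total_volume_mm3 == 0.0 and not lesions

    def test_ten_voxel_lad_lesion_volume(self):
        arr = np.full((8, 8, 8), 40.0, dtype=np.float32)
        arr[2:4, 2:4, 2:4] = 300.0
        arr[2, 2, 4] = arr[2, 2, 5] = 300.0  # 10 supra-threshold voxels
        det = np.zeros((8, 8, 8), dtype=np.uint8)
        det[2, 2, 2] = 1
        vol = make_volume(arr, spacing=(1.5, 1.5, 1.5))
        mask = np.ones((8, 8, 8), dtype=bool)
        report, _ = score_scan(vol, det, fixed_threshold(), mask)
        assert report.volume_mm3["LAD"] == pytest.approx(33.75)
        assert report.total_volume_mm3 == pytest.approx(33.75)

    def test_total_equals_sum_of_arteries(self):
        s = generate_phantom(PhantomParams(lesion_count_range=(2, 5), seed=17))
        report, _ = score_scan(s.volume, s.labels, fixed_threshold(),
                               s.heart_mask)
        assert report.total_volume_mm3 == pytest.approx(
            sum(report.volume_mm3.values()), abs=1e-9)

    def test_reference_detections_reproduce_reference_totals(self):
        """Scoring the reference labels themselves returns the reference
        per-artery volumes (self-consistency on a phantom without outliers)."""
        s = generate_phantom(PhantomParams(lesion_count_range=(2, 5), seed=21))
        thr = fixed_threshold()
        report, _ = score_scan(s.volume, s.labels, thr, s.heart_mask)
        for name, ref in s.reference_volume_mm3.items():
            removed_here = [l for l, why in report.removed
                            if l.artery_name == name]
            if not removed_here:
                assert report.volume_mm3[name] == pytest.approx(ref)

    def test_fp_reduction_never_increases_total(self):
        s = generate_phantom(PhantomParams(lesion_count_range=(2, 6), seed=23))
        thr = fixed_threshold()
        with_fp, _ = score_scan(s.volume, s.labels, thr, s.heart_mask,
                                apply_fp_reduction=True)
        without, _ = score_scan(s.volume, s.labels, thr, s.heart_mask,
                                apply_fp_reduction=False)
        assert with_fp.total_volume_mm3 <= without.total_volume_mm3 + 1e-9

    def test_lesions_to_label_map_round_trip(self):
        lab = np.zeros((6, 6, 6), dtype=np.uint8)
        lab[1:3, 1, 1] = 1
        lab[4, 4, 4] = 3
        lesions = extract_lesions(lab, (1, 1, 1))
        back = lesions_to_label_map(lesions, (6, 6, 6))
        assert np.array_equal(back.labels, lab)
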