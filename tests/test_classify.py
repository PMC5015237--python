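import numpy as np
import pytest

from hotnode import ClassifierConfig, HUThresholds, Modality, Volume
from hotnode.classify import (FALSE_FINDING, TRUE_FINDING, Finding,
                              apply_expert_corrections, assign_side_region, classify,
                              detect_injection_site, extract_features, rank_findings)
from hotnode.hotspots import HotSpot, Seed
from hotnode.tissue import BONE, FAT, MUSCLE, TissueMap


def make_spot(label, voxels, peak, total=None, centroid=(0.0, 0.0, 0.0)):
    voxels = frozenset(voxels)
    seed = Seed(min(voxels), peak)
    return HotSpot(label=label, seed=seed, voxels=voxels, peak_value=peak,
                   total_counts=total if total is not None else peak * len(voxels),
                   centroid_mm=centroid)


def uniform_map(shape, label):
    return TissueMap(labels=np.full(shape, label, dtype=np.uint8), spacing_mm=(1, 1, 1),
                     origin_mm=(0, 0, 0), thresholds=HUThresholds())


def cube(center, r):
    return {(center[0] + dx, center[1] + dy, center[2] + dz)
            for dx in range(-r, r + 1) for dy in range(-r, r + 1)
            for dz in range(-r, r + 1)}


CFG = ClassifierConfig(landmark_plane_z_mm=10.0)


class TestExtractFeatures:
    def test_fat_embedded_shell_is_pure_fat(self):
        m = uniform_map((15, 15, 15), FAT)
        body = np.ones((15, 15, 15), dtype=bool)
        h = make_spot(1, cube((7, 7, 7), 2), peak=50.0)
        feats = extract_features(h, m, body, CFG, spect_max=100.0, spect_total=1e4)
        assert feats["shell_fat"] == 1.0
        assert feats["shell_muscle"] == feats["shell_bone"] == feats["shell_air"] == 0.0
        assert feats["inside_body_fraction"] == 1.0
        assert feats["normalized_peak"] == 0.5
        assert feats["volume_mm3"] == 125.0

    def test_shell_fractions_hand_computed(self):
        # 7^3 grid, single-voxel spot at the centre, shell thickness 1 mm:
        # the shell is the 6-face neighbourhood (ball r=1 minus the voxel)
        labels = np.full((7, 7, 7), FAT, dtype=np.uint8)
        labels[4, 3, 3] = MUSCLE
        labels[3, 4, 3] = BONE
        m = TissueMap(labels=labels, spacing_mm=(1, 1, 1), origin_mm=(0, 0, 0),
                      thresholds=HUThresholds())
        body = np.ones((7, 7, 7), dtype=bool)
        h = make_spot(1, {(3, 3, 3)}, peak=10.0)
        cfg = ClassifierConfig(shell_thickness_mm=1.0)
        feats = extract_features(h, m, body, cfg, spect_max=10.0, spect_total=10.0)
        assert feats["shell_fat"] == pytest.approx(4 / 6)
        assert feats["shell_muscle"] == pytest.approx(1 / 6)
        assert feats["shell_bone"] == pytest.approx(1 / 6)
        # fractions always sum to one
        s = sum(feats[k] for k in ("shell_fat", "shell_muscle", "shell_bone", "shell_air"))
        assert s == pytest.approx(1.0)

    def test_spot_filling_grid_has_no_shell(self):
        m = uniform_map((4, 4, 4), FAT)
        h = make_spot(1, {(x, y, z) for x in range(4) for y in range(4) for z in range(4)},
                      peak=5.0)
        with pytest.raises(ValueError, match="shell"):
            extract_features(h, m, np.ones((4, 4, 4), bool), CFG,
                             spect_max=5.0, spect_total=5.0)


class TestInjectionSite:
    def test_auto_picks_max_total_counts(self):
        spots = [make_spot(1, cube((5, 5, 5), 1), peak=100.0, total=1e6),
                 make_spot(2, cube((10, 10, 10), 1), peak=80.0, total=2e3)]
        assert detect_injection_site(spots, CFG) == {1}

    def test_empty_list(self):
        assert detect_injection_site([], CFG) == set()

    def test_tie_goes_to_lower_label(self):
        spots = [make_spot(1, cube((5, 5, 5), 1), peak=100.0, total=500.0),
                 make_spot(2, cube((10, 10, 10), 1), peak=80.0, total=500.0)]
        assert detect_injection_site(spots, CFG) == {1}

    def test_coordinate_mode_flags_within_radius(self):
        cfg = ClassifierConfig(injection_site_mode="given_coordinate",
                               injection_coordinate_mm=(0.0, 0.0, 0.0),
                               injection_exclusion_radius_mm=30.0)
        spots = [make_spot(1, cube((5, 5, 5), 1), peak=10.0, centroid=(10.0, 0, 0)),
                 make_spot(2, cube((10, 10, 10), 1), peak=10.0, centroid=(50.0, 0, 0))]
        assert detect_injection_site(spots, cfg) == {1}

    def test_coordinate_mode_requires_coordinate(self):
        cfg = ClassifierConfig(injection_site_mode="given_coordinate")
        with pytest.raises(ValueError, match="coordinate"):
            detect_injection_site([make_spot(1, {(0, 0, 0)}, 1.0)], cfg)


class TestClassify:
    def _spect(self, shape=(20, 20, 20)):
        vals = np.zeros(shape)
        vals[1, 1, 1] = 100.0
        return Volume(vals, (1, 1, 1), Modality.SPECT)

    def test_extracorporal_spot_is_false(self):
        m = uniform_map((20, 20, 20), FAT)
        body = np.zeros((20, 20, 20), dtype=bool)
        body[:10] = True
        spots = [make_spot(1, cube((15, 10, 10), 2), peak=50.0)]
        out = classify(spots, m, body, CFG, self._spect())
        assert out[0].verdict == FALSE_FINDING
        assert "extracorporal" in out[0].reasons

    def test_soft_tissue_node_is_true_and_bone_decoy_false(self):
        labels = np.full((30, 30, 30), MUSCLE, dtype=np.uint8)
        labels[18:30, :, :] = BONE
        m = TissueMap(labels=labels, spacing_mm=(1, 1, 1), origin_mm=(0, 0, 0),
                      thresholds=HUThresholds())
        body = np.ones((30, 30, 30), dtype=bool)
        node = make_spot(1, cube((8, 8, 8), 2), peak=60.0)
        decoy = make_spot(2, cube((24, 15, 15), 2), peak=40.0)
        out = classify([node, decoy], m, body, CFG, self._spect((30, 30, 30)))
        # spot 1 carries max total counts -> injection flag; check spot 2's rules
        assert "bone_context" in out[1].reasons and out[1].verdict == FALSE_FINDING
        # re-run with the decoy dominating so the node is unflagged
        node2 = make_spot(1, cube((8, 8, 8), 2), peak=60.0, total=10.0)
        out2 = classify([node2, decoy], m, body, CFG, self._spect((30, 30, 30)))
        assert out2[0].verdict == TRUE_FINDING and out2[0].reasons == []

    def test_below_min_volume_is_false(self):
        m = uniform_map((10, 10, 10), FAT)
        body = np.ones((10, 10, 10), dtype=bool)
        spots = [make_spot(1, {(5, 5, 5)}, peak=50.0, total=1.0),
                 make_spot(2, cube((3, 3, 3), 1), peak=60.0, total=1e6)]
        out = classify(spots, m, body, CFG, self._spect((10, 10, 10)))
        assert "below_min_volume" in out[0].reasons

    def test_every_spot_gets_exactly_one_finding(self):
        m = uniform_map((20, 20, 20), FAT)
        body = np.ones((20, 20, 20), dtype=bool)
        spots = [make_spot(i, cube((4 * i, 4, 4), 1), peak=10.0 * i) for i in (1, 2, 3)]
        out = classify(spots, m, body, CFG, self._spect())
        assert [f.label for f in out] == [1, 2, 3]

    def test_probability_monotone_in_soft_tissue_fraction(self):
        # same spot, shell flipped from air to fat: probability must not drop
        body = np.ones((12, 12, 12), dtype=bool)
        spot = make_spot(1, cube((6, 6, 6), 1), peak=10.0)
        spect = self._spect((12, 12, 12))
        p_air = classify([spot], uniform_map((12, 12, 12), 0), body, CFG, spect)[0].probability
        p_fat = classify([spot], uniform_map((12, 12, 12), FAT), body, CFG, spect)[0].probability
        assert p_fat >= p_air


class TestSideRegion:
    def test_sides_and_regions_from_geometry(self):
        body = np.ones((20, 20, 20), dtype=bool)
        cfg = ClassifierConfig(landmark_plane_z_mm=10.0, midline_x_mm=10.0)
        f = Finding(hotspot=make_spot(1, {(0, 0, 0)}, 1.0, centroid=(15.0, 5.0, 4.0)))
        g = assign_side_region(f, body, cfg)
        assert (g.side, g.region) == ("left", "inguinal")
        f2 = Finding(hotspot=make_spot(2, {(0, 0, 0)}, 1.0, centroid=(5.0, 5.0, 14.0)))
        g2 = assign_side_region(f2, body, cfg)
        assert (g2.side, g2.region) == ("right", "secondary")

    def test_exact_midline_is_right(self):
        body = np.ones((20, 20, 20), dtype=bool)
        cfg = ClassifierConfig(landmark_plane_z_mm=10.0, midline_x_mm=10.0)
        f = Finding(hotspot=make_spot(1, {(0, 0, 0)}, 1.0, centroid=(10.0, 5.0, 4.0)))
        assert assign_side_region(f, body, cfg).side == "right"

    def test_auto_midline_uses_body_centroid(self):
        body = np.zeros((20, 20, 20), dtype=bool)
        body[12:20] = True  # body centred at x=15.5
        cfg = ClassifierConfig(landmark_plane_z_mm=10.0)
        f = Finding(hotspot=make_spot(1, {(0, 0, 0)}, 1.0, centroid=(14.0, 5.0, 4.0)))
        assert assign_side_region(f, body, cfg, spacing_mm=(1, 1, 1),
                                  origin_mm=(0, 0, 0)).side == "right"


class TestRanking:
    def _finding(self, label, verdict, prob, peak):
        return Finding(hotspot=make_spot(label, {(label, 0, 0)}, peak),
                       verdict=verdict, probability=prob)

    def test_empty(self):
        assert rank_findings([]) == ([], [])

    def test_tie_broken_by_peak_then_label(self):
        fs = [self._finding(1, TRUE_FINDING, 0.9, 10.0),
              self._finding(2, TRUE_FINDING, 0.7, 50.0),
              self._finding(3, TRUE_FINDING, 0.7, 80.0)]
        true_list, _ = rank_findings(fs)
        assert [f.label for f in true_list] == [1, 3, 2]

    def test_false_list_ascending_probability(self):
        fs = [self._finding(1, FALSE_FINDING, 0.6, 1.0),
              self._finding(2, FALSE_FINDING, 0.1, 1.0)]
        _, false_list = rank_findings(fs)
        assert [f.label for f in false_list] == [2, 1]

    def test_conservation(self):
        fs = [self._finding(i, TRUE_FINDING if i % 2 else FALSE_FINDING, i / 10, 1.0)
              for i in range(1, 8)]
        t, f = rank_findings(fs)
        assert len(t) + len(f) == len(fs)
        assert {x.label for x in t + f} == {x.label for x in fs}


class TestCorrections:
    def _lists(self):
        fs = [Finding(hotspot=make_spot(i, {(i, 0, 0)}, float(i)),
                      verdict=TRUE_FINDING if i <= 2 else FALSE_FINDING,
                      probability=i / 10) for i in (1, 2, 3, 4)]
        return rank_findings(fs)

    def test_no_moves_unchanged(self):
        lists = self._lists()
        (t, f), tally = apply_expert_corrections(lists, [])
        assert [x.label for x in t] == [x.label for x in lists[0]]
        assert tally == {"fp_corrections": 0, "fn_corrections": 0, "noop": 0}

    def test_true_to_false_is_fp_correction(self):
        (t, f), tally = apply_expert_corrections(self._lists(), [(1, "false")])
        assert tally["fp_corrections"] == 1
        assert 1 in {x.label for x in f} and 1 not in {x.label for x in t}

    def test_roundtrip_restores_lists_with_two_moves(self):
        lists = self._lists()
        (t, f), tally = apply_expert_corrections(lists, [(2, "false"), (2, "true")])
        assert {x.label for x in t} == {x.label for x in lists[0]}
        assert tally["fp_corrections"] == 1 and tally["fn_corrections"] == 1

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            apply_expert_corrections(self._lists(), [(99, "true")])

    def test_move_to_current_list_is_noop(self):
        (t, f), tally = apply_expert_corrections(self._lists(), [(1, "true")])
        assert tally["noop"] == 1 and 1 in {x.label for x in t}

    def test_corrections_conserve_findings(self):
        (t, f), _ = apply_expert_corrections(self._lists(), [(1, "false"), (4, "true")])
        assert {x.label for x in t + f} == {1, 2, 3, 4}
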