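"""Enclosed volume, mesh topology and breath endpoint detection."""
import numpy as np
import pytest
from scipy.spatial import ConvexHull

from cwmorph import (BreathSignal, MeshTopology, default_topology,
                     detect_endpoints, enclosed_volume, extract_breath_configs,
                     simulate_cohort, volume_signal)
from cwmorph.errors import (DetectionError, InvalidParameterError,
                            MissingLandmarkError)
from cwmorph.synthetic import CohortSpec

from conftest import random_rotation

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
UNIT_TET_TRIS = MeshTopology(np.array([
    [0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3],
]))


def unit_cube():
    v = np.array([[x, y, z] for z in (0, 1) for y in (0, 1) for x in (0, 1)], float)
    tris = np.array([
        [0, 2, 1], [1, 2, 3],  # bottom (z=0), outward = -z
        [4, 5, 6], [5, 7, 6],  # top
        [0, 1, 4], [1, 5, 4],  # y=0
        [2, 6, 3], [3, 6, 7],  # y=1
        [0, 4, 2], [2, 4, 6],  # x=0
        [1, 3, 5], [3, 7, 5],  # x=1
    ])
    return v, MeshTopology(tris)


class TestTopology:
    def test_default_topology_is_closed_with_euler_2(self, template, topology):
        assert topology.n_vertices == 89
        assert topology.euler_characteristic() == 2
        assert topology.is_closed()

    def test_template_signed_volume_positive(self, template, topology):
        assert enclosed_volume(template, topology) > 0

    def test_non_template_marker_set_rejected(self, rng):
        from cwmorph.datatypes import LandmarkConfiguration
        cfg = LandmarkConfiguration(rng.normal(size=(10, 3)),
                                    tuple(f"m{i}" for i in range(10)))
        with pytest.raises(InvalidParameterError):
            default_topology(cfg)

    def test_topology_json_round_trip(self, topology, tmp_path):
        path = tmp_path / "topo.json"
        topology.to_json(path)
        back = MeshTopology.from_json(path)
        np.testing.assert_array_equal(back.triangles, topology.triangles)


class TestEnclosedVolume:
    def test_unit_tetrahedron_is_one_sixth(self):
        assert enclosed_volume(UNIT_TET, UNIT_TET_TRIS) == pytest.approx(1 / 6, rel=1e-12)

    def test_unit_cube_is_one(self):
        v, topo = unit_cube()
        assert enclosed_volume(v, topo) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("s", [0.5, 2.0, 7.3])
    def test_scales_as_s_cubed(self, template, topology, s):
        v0 = enclosed_volume(template, topology)
        assert enclosed_volume(template.coords * s, topology) == pytest.approx(
            s**3 * v0, rel=1e-12)

    def test_rigid_motion_invariance(self, template, topology, rng):
        v0 = enclosed_volume(template, topology)
        moved = template.coords @ random_rotation(rng).T + rng.normal(size=3) * 500
        assert enclosed_volume(moved, topology) == pytest.approx(v0, rel=1e-9)

    def test_matches_convex_hull_oracle_on_random_points(self, rng):
        # 89 points on a random ellipsoid: the hull triangulation is a closed
        # mesh whose signed-tetrahedron volume must equal the hull volume
        pts = rng.normal(size=(89, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= np.array([3.0, 2.0, 1.5])
        hull = ConvexHull(pts)
        tris = hull.simplices.copy()
        # orient every hull facet outward from the centroid
        c = pts.mean(axis=0)
        for t in tris:
            n = np.cross(pts[t[1]] - pts[t[0]], pts[t[2]] - pts[t[0]])
            if np.dot(n, pts[t[0]] - c) < 0:
                t[[1, 2]] = t[[2, 1]]
        vol = enclosed_volume(pts, MeshTopology(tris))
        assert vol == pytest.approx(hull.volume, rel=1e-9)

    def test_missing_marker_raises_with_guidance(self, template, topology):
        coords = template.coords.copy()
        coords[5] = np.nan
        cfg = template.with_coords(coords)
        with pytest.raises(MissingLandmarkError, match="estimate"):
            enclosed_volume(cfg, topology)


def sinusoid_signal(f=0.25, fs=60.0, duration=24.0, amp=1e5, offset=2e7):
    t = np.arange(int(duration * fs)) / fs
    return BreathSignal(time_s=t, volume_mm3=offset + amp * np.sin(2 * np.pi * f * t))


class TestDetectEndpoints:
    def test_sinusoid_extrema_at_quarter_phases(self):
        sig = sinusoid_signal()
        ep = detect_endpoints(sig, min_period_s=2.0)
        # maxima at t = 1 s + 4k, minima at t = 3 s + 4k (f = 0.25 Hz)
        assert len(ep.in_frames) == 2 and len(ep.ex_frames) == 2
        for fr in ep.in_frames:
            assert min((sig.time_s[fr] - 1.0) % 4.0, 4.0 - (sig.time_s[fr] - 1.0) % 4.0) <= 1 / 60
        for fr in ep.ex_frames:
            assert min((sig.time_s[fr] - 3.0) % 4.0, 4.0 - (sig.time_s[fr] - 3.0) % 4.0) <= 1 / 60
        for fr_in in ep.in_frames:
            prev_ex = [e for e in ep.ex_frames if e < fr_in]
            next_ex = [e for e in ep.ex_frames if e > fr_in]
            for e in prev_ex[-1:] + next_ex[:1]:
                assert sig.volume_mm3[fr_in] > sig.volume_mm3[e]

    def test_ripple_matches_exhaustive_prominence_oracle(self):
        sig = sinusoid_signal()
        y = sig.volume_mm3 + 2e3 * np.sin(2 * np.pi * 3.1 * sig.time_s)
        noisy = BreathSignal(time_s=sig.time_s, volume_mm3=y)
        ep = detect_endpoints(noisy, min_period_s=2.0)

        # oracle: enumerate every local maximum, rank by brute-force prominence
        def brute_peaks(v):
            cands = [i for i in range(1, len(v) - 1) if v[i - 1] < v[i] >= v[i + 1]]
            proms = []
            for i in cands:
                left = v[:i][::-1]
                right = v[i + 1:]
                lmin = rmin = v[i]
                for seg, acc in ((left, "l"), (right, "r")):
                    run = v[i]
                    for x in seg:
                        if x > v[i]:
                            break
                        run = min(run, x)
                    if acc == "l":
                        lmin = run
                    else:
                        rmin = run
                proms.append(v[i] - max(lmin, rmin))
            order = sorted(range(len(cands)), key=lambda j: (-proms[j], cands[j]))
            return sorted(cands[j] for j in order[:2])

        assert list(ep.in_frames) == brute_peaks(y)
        assert list(ep.ex_frames) == brute_peaks(-y)

    def test_constant_signal_raises(self):
        t = np.arange(600) / 60
        with pytest.raises(DetectionError):
            detect_endpoints(BreathSignal(time_s=t, volume_mm3=np.full(600, 5.0)))

    def test_invariant_to_constant_offset(self):
        sig = sinusoid_signal()
        shifted = BreathSignal(time_s=sig.time_s, volume_mm3=sig.volume_mm3 + 123456.0)
        a = detect_endpoints(sig, min_period_s=2.0)
        b = detect_endpoints(shifted, min_period_s=2.0)
        np.testing.assert_array_equal(a.in_frames, b.in_frames)
        np.testing.assert_array_equal(a.ex_frames, b.ex_frames)

    def test_consecutive_policy_takes_first_cycles(self):
        sig = sinusoid_signal(duration=32.0)
        ep = detect_endpoints(sig, min_period_s=2.0, policy="consecutive")
        assert sig.time_s[ep.in_frames[0]] == pytest.approx(1.0, abs=0.05)
        assert sig.time_s[ep.in_frames[1]] == pytest.approx(5.0, abs=0.05)


class TestVolumeSignalAndExtraction:
    def test_static_subject_gives_constant_signal(self, topology):
        spec = CohortSpec(n_subjects=1, amp_thoracic_QB=0, amp_abdominal_QB=0,
                          amp_thoracic_REC=0, amp_abdominal_REC=0, noise_sd=0,
                          dropout_prob=0, duration_s=16, seed=2)
        trajs, _ = simulate_cohort(spec)
        sig = volume_signal(trajs[0], topology)
        assert np.ptp(sig.volume_mm3) == pytest.approx(0.0, abs=1e-6)

    def test_dropout_frames_flagged_not_fabricated(self, topology):
        spec = CohortSpec(n_subjects=1, dropout_prob=0.05, duration_s=16, seed=6)
        trajs, _ = simulate_cohort(spec)
        traj = trajs[0]
        sig = volume_signal(traj, topology)
        assert sig.n_flagged == int(traj.missing_mask.any(axis=1).sum())

    def test_eight_configs_per_subject_across_conditions(self, clean_cohort, topology):
        trajs, _ = clean_cohort
        subject = trajs[0].subject_id
        configs = []
        for traj in trajs:
            if traj.subject_id != subject:
                continue
            ep = detect_endpoints(volume_signal(traj, topology), min_period_s=1.5)
            configs.extend(extract_breath_configs(traj, ep))
        assert len(configs) == 8
        assert {(c.condition, c.instant, c.cycle_index) for c in configs} == {
            (cond, inst, cyc) for cond in ("QB", "REC")
            for inst in ("EX", "IN") for cyc in (1, 2)
        }

    def test_noise_free_extraction_recovers_ground_truth(self, clean_cohort, topology):
        trajs, truth = clean_cohort
        traj = trajs[0]
        ep = detect_endpoints(volume_signal(traj, topology), min_period_s=1.5)
        configs = extract_breath_configs(traj, ep)
        key = (traj.subject_id, traj.condition)
        for c in configs:
            ref = truth.in_configs[key] if c.instant == "IN" else truth.ex_configs[key]
            np.testing.assert_allclose(c.coords, ref.coords, atol=1e-9)

    def test_missing_marker_at_endpoint_respects_policy(self, topology):
        from cwmorph import interpolate_gaps
        spec = CohortSpec(n_subjects=1, dropout_prob=0.25, duration_s=16, seed=8)
        trajs, _ = simulate_cohort(spec)
        traj = trajs[0]
        ep = detect_endpoints(volume_signal(interpolate_gaps(traj), topology),
                              min_period_s=1.5)
        configs = extract_breath_configs(traj, ep, on_missing="keep")
        assert any(not c.is_complete for c in configs)
        with pytest.raises(MissingLandmarkError):
            extract_breath_configs(traj, ep, on_missing="error")
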