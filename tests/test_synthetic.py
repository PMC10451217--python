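import numpy as np
import pytest

from onstrain import synthetic as syn


@pytest.fixture(scope="module")
def scene():
    return syn.Scene(syn.SceneConfig())


def finite_difference_strain(displacement, X, h=1e-5):
    n = len(X)
    G = np.zeros((n, 3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        G[:, :, j] = (displacement(X + e) - displacement(X - e)) / (2 * h)
    return 0.5 * (G + np.transpose(G, (0, 2, 1)) + np.einsum("nki,nkj->nij", G, G))


class TestConfigValidation:
    def test_bad_sheath_order_rejected(self):
        with pytest.raises(ValueError):
            syn.SceneConfig(sheath_inner_radius=3.0, sheath_outer_radius=2.5)

    def test_noise_bounded_by_inplane_spacing(self):
        with pytest.raises(ValueError):
            syn.SceneConfig(noise_sd=0.5)

    def test_self_intersecting_sinuosity_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            syn.Scene(syn.SceneConfig(sinuosity_amplitude=4.2))

    def test_rigid_mode_requires_zero_magnitude(self):
        with pytest.raises(ValueError):
            syn.GazeState(deformation_mode="rigid_only", mode_magnitude=1.0)


class TestReferenceGeometry:
    def test_tortuosity_in_reported_regime(self, scene):
        tort = scene.path.length / scene.chord
        assert 1.02 < tort < 1.03

    def test_constant_slope_helix(self, scene):
        sp = scene.path.speed(np.linspace(0, 1, 100))
        assert np.ptp(sp) / sp.mean() < 1e-9

    def test_path_ends_at_junction_and_apex(self, scene):
        assert np.allclose(scene.path.point(0.0), scene.j0, atol=1e-12)
        assert np.allclose(scene.path.point(1.0), scene.apex, atol=1e-9)


class TestGroundTruthMaps:
    @pytest.mark.parametrize(
        "gaze",
        [
            syn.GazeState(duction_deg=0.0),
            syn.GazeState(duction_deg=-20.0, translation_mm=(0.5, 0.1, -0.2)),
            syn.GazeState(duction_deg=-28.0, deformation_mode="uniform_stretch",
                          mode_magnitude=0.05),
            syn.GazeState(duction_deg=30.0, deformation_mode="cantilever_bend",
                          mode_magnitude=1.8),
        ],
        ids=["identity", "rigid", "stretch", "bend"],
    )
    def test_strain_map_is_exact_gradient_of_displacement_map(self, scene, gaze):
        d = scene.deformation(gaze)
        rng = np.random.default_rng(0)
        xi = rng.uniform(0.03, 0.97, 400)
        _, N, B = scene.path.frames(xi)
        X = (scene.path.point(xi)
             + rng.uniform(-0.9, 0.9, (400, 1)) * N
             + rng.uniform(-0.9, 0.9, (400, 1)) * B)
        E_fd = finite_difference_strain(d.displacement, X)
        E_an = d.strain(X)
        scale = max(np.abs(E_an).max(), 1e-3)
        assert np.abs(E_fd - E_an).max() / scale < 1e-5

    def test_identity_gaze_zero_displacement(self, scene):
        d = scene.deformation(syn.GazeState())
        X = scene.path.point(np.linspace(0.1, 0.9, 20))
        assert np.abs(d.displacement(X)).max() < 1e-9

    def test_rigid_mode_zero_strain_and_exact_rigidity(self, scene):
        gaze = syn.GazeState(duction_deg=25.0, translation_mm=(0.3, 0.0, -0.1))
        d = scene.deformation(gaze)
        xi = np.linspace(0.02, 0.98, 50)
        X = scene.path.point(xi)
        assert np.abs(d.strain(X)).max() == 0.0
        # the map is the stored rigid swing, exactly
        assert np.abs(d.phi(X) - d.T_on.apply(X)).max() < 1e-12
        # globe transform reproduces the deformed junction
        assert np.linalg.norm(
            d.globe_transform.apply(scene.j0) - d.junction_deformed
        ) < 1e-9

    def test_uniform_stretch_centerline_closed_form(self, scene):
        d = scene.deformation(
            syn.GazeState(duction_deg=-28.0, deformation_mode="uniform_stretch",
                          mode_magnitude=0.05)
        )
        xi = np.linspace(0.02, 0.98, 60)
        P = scene.path.point(xi)
        T = scene.path.tangent(xi)
        ezz = np.einsum("ni,nij,nj->n", T, d.strain(P), T)
        assert np.abs(ezz - 0.05125).max() < 1e-9

    def test_bend_region_means_monotone_with_small_anterior_strain(self, scene):
        d = scene.deformation(
            syn.GazeState(duction_deg=30.0, deformation_mode="cantilever_bend",
                          mode_magnitude=1.8)
        )
        xi = np.linspace(0.002, 0.998, 2000)
        P = scene.path.point(xi)
        T = scene.path.tangent(xi)
        ezz = np.einsum("ni,nij,nj->n", T, d.strain(P), T)
        means = [ezz[(xi >= k * 0.2) & (xi < (k + 1) * 0.2)].mean() for k in range(5)]
        assert all(b > a for a, b in zip(means, means[1:]))
        assert means[0] < 0.5 * means[4]

    def test_apex_fixed_in_all_modes(self, scene):
        for gaze in (
            syn.GazeState(duction_deg=20.0),
            syn.GazeState(duction_deg=-28.0, deformation_mode="uniform_stretch",
                          mode_magnitude=0.05),
            syn.GazeState(duction_deg=30.0, deformation_mode="cantilever_bend",
                          mode_magnitude=1.8),
        ):
            d = scene.deformation(gaze)
            assert np.linalg.norm(d.phi(scene.apex[None])[0] - scene.apex) < 1e-9


class TestAnalyticStrainAccessor:
    def test_rigid_zero_and_outside_flagging(self, scene):
        gaze = syn.GazeState(duction_deg=10.0)
        d = scene.deformation(gaze)
        gt = syn.GroundTruth(
            config=scene.config, gaze=gaze, frame_transforms={},
            globe_transform=d.globe_transform,
            globe_translation=d.globe_translation,
            displacement_map=d.displacement, strain_map=d.strain,
            junction_point=scene.j0, junction_deformed=d.junction_deformed,
            apex_point=scene.apex, path=scene.path,
        )
        inside = scene.path.point(np.linspace(0.2, 0.8, 5))
        outside = inside + np.array([0, 10.0, 0])
        E, mask = syn.analytic_strain_at(gt, np.vstack([inside, outside]))
        assert mask[:5].all() and not mask[5:].any()
        assert np.abs(E).max() == 0.0


class TestSceneSampling:
    def test_same_seed_bit_identical(self):
        cfg = syn.SceneConfig(coronal_inplane_spacing=0.6,
                              coronal_slice_thickness=2.5,
                              axial_inplane_spacing=0.7,
                              axial_slice_thickness=2.5, seed=7)
        gaze = syn.GazeState(duction_deg=-20.0)
        a, _ = syn.generate_scene(cfg, gaze)
        b, _ = syn.generate_scene(cfg, gaze)
        for tag in syn.TAGS:
            assert np.array_equal(a[tag].points, b[tag].points)
            assert np.array_equal(a[tag].labels, b[tag].labels)

    def test_different_seeds_differ_same_schema(self):
        mk = lambda s: syn.generate_scene(
            syn.SceneConfig(coronal_inplane_spacing=0.6,
                            coronal_slice_thickness=2.5,
                            axial_inplane_spacing=0.7,
                            axial_slice_thickness=2.5, seed=s),
            syn.GazeState(duction_deg=-20.0),
        )[0]
        a, b = mk(1), mk(2)
        assert set(a) == set(b) == set(syn.TAGS)
        assert not np.array_equal(a["coronal_central"].points,
                                  b["coronal_central"].points)

    def test_all_labels_present_and_frames_valid(self):
        cfg = syn.SceneConfig(coronal_inplane_spacing=0.6,
                              coronal_slice_thickness=2.5,
                              axial_inplane_spacing=0.7,
                              axial_slice_thickness=2.5)
        clouds, gt = syn.generate_scene(cfg, syn.GazeState(duction_deg=-15.0))
        for tag in syn.TAGS:
            present = set(np.unique(clouds[tag].labels))
            assert {1, 2, 3, 4, 5, 6} <= present
        for T in gt.frame_transforms.values():
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_coronal_and_axial_overlap_after_frame_transforms(self):
        from onstrain.registration import chamfer_distance

        cfg = syn.SceneConfig(coronal_inplane_spacing=0.6,
                              coronal_slice_thickness=2.5,
                              axial_inplane_spacing=0.7,
                              axial_slice_thickness=2.5)
        clouds, gt = syn.generate_scene(cfg, syn.GazeState())
        cor = gt.frame_transforms["coronal_central"].apply(
            clouds["coronal_central"].points
        )
        axi = gt.frame_transforms["axial_central"].apply(
            clouds["axial_central"].points
        )
        # the two acquisitions sample the same anatomy: Chamfer below twice
        # the coarser voxel spacing
        assert chamfer_distance(cor, axi) < 2 * 2.5
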