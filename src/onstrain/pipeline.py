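"""End-to-end orchestration: from acquisitions to strain tables.

Stage order per orbit: slice interpolation -> mask-to-point conversion ->
coronal/axial fusion (ON+LR+MR registration) -> gaze-to-gaze registration
(orbital wall) -> head frame (medial plane + ethmoid-recess landmarks) ->
globe kinematics -> nerve parameterization in both configurations ->
material matching -> displacements -> Green-Lagrange strain -> regional
summaries. All analysis happens in the central-gaze coronal frame; reported
vectors/angles are expressed in the head frame.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ongeometry as og
from . import strain as st
from .frames import (
    Frame,
    duction_angle,
    duction_change_from_insertions,
    globe_center,
    globe_translation,
    muscle_insertion,
    ocular_axis,
    torsion_angle,  # noqa: F401 - re-exported for callers
    torsion_change_about_head,
    build_head_frame,
)
from .pointcloud import (
    ImageStack,
    Label,
    LabeledPointCloud,
    interpolate_slices,
    masks_to_points,
    read_cloud,
    read_stack,
    write_cloud,
)
from .registration import (
    PlaneParams,
    RegistrationResult,
    find_medial_plane,
    register_acquisitions,
    register_gazes,
)
from .transforms import RigidTransform

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable parameters of the measurement pipeline (defaults in mm/deg)."""

    interp_factor: int = 6
    bin_width: float = 0.35
    min_bin_points: int = 40
    n_sections: int = 50
    n_angles: int = 36
    n_grid_angles: int = 12
    n_radii: int = 3
    min_section_points: int = 6
    max_section_radius: float = 4.0
    end_margin_stations: int = 3
    hull_denoise_voxel: float = 0.5
    registration_denoise_voxel: float = 0.45
    max_points_per_label: int = 30000
    straight_line_rms: float = 0.5
    theta_anchor: str = "lab"  # "lab" or "junction"
    clamp_junction_tangent: bool = False
    smooth_boundary: bool = True
    displacement_smoothing_window: int = 21
    compat_strain_formula: bool = False
    head_pitch_deg: float = 10.0
    seed: int = 0


from .registration import _voxel_mean  # noqa: E402  (shared helper)


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageError(stage, str(exc)) from exc


# ---------------------------------------------------------------------------
# acquisition fusion
# ---------------------------------------------------------------------------


def _as_cloud(
    obj: ImageStack | LabeledPointCloud, params: PipelineParams, rng
) -> LabeledPointCloud:
    """Stacks are slice-interpolated and converted to points; big labels are
    subsampled to the per-label budget (seeded, uniform)."""
    if isinstance(obj, ImageStack):
        if params.interp_factor >= 2:
            obj = interpolate_slices(obj, params.interp_factor)
        cloud = masks_to_points(obj)
    else:
        cloud = obj
    keep_parts = []
    for lab in np.unique(cloud.labels):
        idx = np.flatnonzero(cloud.labels == lab)
        if len(idx) > params.max_points_per_label:
            idx = rng.choice(idx, params.max_points_per_label, replace=False)
        keep_parts.append(idx)
    keep = np.sort(np.concatenate(keep_parts))
    return LabeledPointCloud(cloud.points[keep], cloud.labels[keep], cloud.frame)


@dataclass
class FusedState:
    """One gaze state fused into its coronal acquisition frame.

    ``coronal`` keeps the quasicoronal points separately: the globe's
    minimal bounding sphere is defined from quasicoronal data only, whose
    anterior clipping excludes the protruding cornea.
    """

    cloud: LabeledPointCloud
    coronal: LabeledPointCloud
    acquisition_registration: RegistrationResult

    def transformed(self, transform, frame: str) -> "FusedState":
        return FusedState(
            self.cloud.transformed(transform, frame),
            self.coronal.transformed(transform, frame),
            self.acquisition_registration,
        )


def fuse_acquisitions(
    coronal: ImageStack | LabeledPointCloud,
    axial: ImageStack | LabeledPointCloud,
    params: PipelineParams,
) -> FusedState:
    """Interpolate/convert both acquisitions and merge the axial cloud into
    the coronal frame via ON+LR+MR rigid registration."""
    rng = np.random.default_rng(params.seed)
    cor = _stage("interpolate/points", _as_cloud, coronal, params, rng)
    axi = _stage("interpolate/points", _as_cloud, axial, params, rng)
    reg = _stage("register_acquisitions", register_acquisitions, cor, axi,
                 seed=params.seed,
                 denoise_voxel=params.registration_denoise_voxel)
    merged = LabeledPointCloud.concatenate(
        [cor, axi.transformed(reg.transform, frame=cor.frame)]
    )
    return FusedState(merged, cor, reg)


def align_to_central(
    central: FusedState, deformed: FusedState, params: PipelineParams
) -> tuple[FusedState, RegistrationResult]:
    """Map a deformed-gaze session into the central session frame (wall
    registration); all later comparisons happen in that common frame.

    Only the quasicoronal wall clouds are compared: registering a session's
    coronal data against the other session's coronal data keeps the raster
    reconstruction systematics common to both sides, where they cancel.
    """
    reg = _stage("register_gazes", register_gazes, central.coronal,
                 deformed.coronal, seed=params.seed,
                 denoise_voxel=params.registration_denoise_voxel)
    return deformed.transformed(reg.transform, central.cloud.frame), reg


# ---------------------------------------------------------------------------
# per-configuration geometry
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """Parameterized nerve + globe data of one gaze state (common frame)."""

    cloud: LabeledPointCloud
    globe_center: np.ndarray
    globe_radius: float
    junction: np.ndarray
    junction_tangent: np.ndarray
    path: og.ONPath
    sections: list[og.CrossSection]
    junction_x: np.ndarray
    apex: np.ndarray

    @property
    def on_configuration(self) -> st.ONConfiguration:
        return st.ONConfiguration(self.path, self.sections)

    @property
    def tortuosity(self) -> float:
        return og.tortuosity(self.path)


def parameterize_configuration(
    state: FusedState | LabeledPointCloud,
    apex: np.ndarray,
    params: PipelineParams,
    shared_sphere_radius: float | None = None,
    junction_override: np.ndarray | None = None,
) -> Configuration:
    """Full nerve parameterization of one gaze state.

    The globe sphere is fit to quasicoronal points when per-acquisition
    provenance is available (the coronal stack excludes the cornea, which
    must not inflate the minimal bounding sphere). The ON centroid bins run
    along the globe-center-to-apex axis; the junction comes from the
    ray/hull construction; junction + centroids + apex are the spline
    knots. The junction-frame X axis (corneal-antipode to junction
    direction) seeds the in-plane axes of every station frame.
    """
    if isinstance(state, FusedState):
        cloud = state.cloud
        sphere_pts = state.coronal.select(Label.GLOBE)
        # cross-section boundaries come from quasicoronal data only: its
        # fine in-plane raster samples the tube surface directly, whereas
        # the axial acquisition cuts the nerve lengthwise and its
        # interpolated surface carries orientation-dependent fattening
        section_pts = state.coronal.select(Label.ON)
    else:
        cloud = state
        sphere_pts = cloud.select(Label.GLOBE)
        section_pts = cloud.select(Label.ON)
    globe_pts = cloud.select(Label.GLOBE)
    on_pts = cloud.select(Label.ON)
    if len(globe_pts) == 0 or len(on_pts) == 0:
        raise StageError("parameterize", "missing globe or ON points")
    center, radius = measure_globe_center(sphere_pts, params)
    long_axis = np.asarray(apex, float) - center
    long_axis /= np.linalg.norm(long_axis)
    cents = _stage(
        "on_centroids", og.on_centroids, on_pts,
        long_axis=long_axis, bin_width=params.bin_width, anterior_point=center,
        min_points=params.min_bin_points,
    )
    if junction_override is not None:
        # deformed-gaze junction propagated kinematically from the central
        # one (rigid globe): avoids the per-gaze ray/surface bias, which
        # grows with the nerve's incidence angle on the rotated globe
        junction = np.asarray(junction_override, float)
        tangent = np.asarray(apex, float) - junction
        tangent /= np.linalg.norm(tangent)
    else:
        hull_pts = _voxel_mean(globe_pts, params.hull_denoise_voxel)
        junction, tangent = _stage("find_on_junction", og.find_on_junction,
                                   hull_pts, cents, surface="sphere",
                                   sphere_radius=shared_sphere_radius)
    # keep knots strictly between junction and apex along the chord
    chord = np.asarray(apex, float) - junction
    L = np.linalg.norm(chord)
    u = chord / L
    proj = (cents - junction) @ u
    good = (proj > 0.25) & (proj < L - 0.25)
    # anchor the posterior end at the shared apex's position *along* the
    # nerve: projecting the apex onto the line of the last centroids removes
    # the lateral component of the apex estimate's error, which would
    # otherwise hook the fitted curve over the final fraction of arc length
    tail = cents[good][-8:]
    p_t, d_t, _ = og.fit_line(tail)
    if d_t @ u < 0:
        d_t = -d_t
    apex_knot = p_t + ((np.asarray(apex, float) - p_t) @ d_t) * d_t
    knots = np.vstack([junction, cents[good], apex_knot])
    # under large duction the nerve meets the rotated globe obliquely, so the
    # hull normal need not align with the initial path direction; clamping
    # the end tangent to it would hook the fitted curve (config switch)
    clamp = tangent if params.clamp_junction_tangent else None
    path = _stage("fit_on_curve", og.fit_on_curve, knots, junction_tangent=clamp)

    # angular origin of the polar parameterization: ocular torsion during
    # horizontal duction is negligible, so a fixed lab direction projected
    # into each section plane anchors theta identically in both
    # configurations; the globe-borne junction-frame X (antipode-junction
    # line) would rotate with duction and twist the correspondence
    if params.theta_anchor == "junction":
        _, antipode, _ = ocular_axis(globe_pts, center=center)
        jx = junction - antipode
    else:
        jx = np.array([0.0, 1.0, 0.0])
    jx = jx - (jx @ tangent) * tangent
    n = np.linalg.norm(jx)
    if n < 1e-6:
        raise StageError("parameterize", "theta anchor parallel to tangent")
    jx /= n
    # stations at equal normalized *chord* position: the material
    # correspondence across gaze states pairs stations of equal chordwise
    # coordinate (the co-registered imaging planes), so both configurations
    # must be sectioned on that grid
    s_dense = np.linspace(0.0, 1.0, 1001)
    axis_u = apex_knot - junction
    axis_u /= np.linalg.norm(axis_u)
    c_dense = ((path.point(s_dense) - junction) @ axis_u) / (
        (apex_knot - junction) @ axis_u
    )
    c_dense = np.maximum.accumulate(c_dense)
    c_targets = (np.arange(params.n_sections) + 0.5) / params.n_sections
    s_stations = np.interp(c_targets, c_dense, s_dense)
    sections = _stage(
        "cross_sections", og.cross_sections, path, section_pts,
        n_angles=params.n_angles,
        junction_x=jx, min_points=params.min_section_points,
        max_radius=params.max_section_radius, s_values=s_stations,
    )
    return Configuration(cloud, center, radius, junction, tangent, path,
                         sections, jx, np.asarray(apex, float))


def measure_globe_center(
    coronal_globe_points: np.ndarray, params: PipelineParams
) -> tuple[np.ndarray, float]:
    """Robust globe center from quasicoronal (cornea-free) points.

    The minimal bounding sphere seeds the estimate, but on anteriorly
    clipped, noisy clouds its center is weakly constrained along the clip
    axis (it rests on a few extreme points). A least-squares sphere fit to
    the surface shell, iterated twice, pins the center to the whole sampled
    surface instead.
    """
    pts = _voxel_mean(np.asarray(coronal_globe_points, float),
                      params.hull_denoise_voxel)
    c0, r0 = _stage("globe_center", globe_center, pts)
    # r0 (minimal enclosing) bounds the outer surface; the window below is
    # anchored to it so the fit cannot walk into the solid interior
    c = c0
    for _ in range(3):
        rad = np.linalg.norm(pts - c, axis=1)
        shell = (rad > r0 - 1.0) & (rad < r0 + 0.4)
        if shell.sum() < 50:
            break
        c_new, _ = og._fit_sphere(pts[shell])
        if np.linalg.norm(c_new - c) < 1e-6:
            c = c_new
            break
        c = c_new
    return c, float(r0)


def propagate_junction(
    central: Configuration,
    deformed_state: FusedState | LabeledPointCloud,
    head: Frame,
    params: PipelineParams,
) -> np.ndarray:
    """Deformed-gaze junction via rigid-globe kinematics.

    The junction is a material point of the rigid globe; with the globe
    center measured per state and the duction change measured from the
    horizontal rotation of the LR-MR insertion chord, the central junction
    carries over as
    ``center1 + R(duction change about head Y) (junction0 - center0)``.
    Torsion is negligible during horizontal duction, and this estimate is
    immune to the incidence-angle bias of per-gaze surface intersection.
    """
    if isinstance(deformed_state, FusedState):
        cloud1 = deformed_state.cloud
        sphere1 = deformed_state.coronal.select(Label.GLOBE)
    else:
        cloud1 = deformed_state
        sphere1 = deformed_state.select(Label.GLOBE)
    center1, radius1 = measure_globe_center(sphere1, params)
    ins = {}
    for key, cloud, cen, rad in (("0", central.cloud, central.globe_center,
                                  central.globe_radius),
                                 ("1", cloud1, center1, radius1)):
        for lab in (Label.LR, Label.MR):
            ins[f"{lab.name}{key}"] = muscle_insertion(
                cloud.select(lab), cen, rad
            )
    dduc = duction_change_from_insertions(ins["LR0"], ins["MR0"],
                                          ins["LR1"], ins["MR1"], head)
    R = RigidTransform.from_axis_angle(head.Y, dduc)
    return center1 + R.apply(central.junction - central.globe_center)


def globe_surface_radius(
    state: FusedState | LabeledPointCloud, params: PipelineParams
) -> float:
    """Globe surface-sphere radius from one session, to be shared by all
    gaze states of the orbit (the globe is rigid, so a single estimate
    cancels out of cross-state comparisons)."""
    from scipy.spatial import ConvexHull

    cloud = state.cloud if isinstance(state, FusedState) else state
    pts = _voxel_mean(cloud.select(Label.GLOBE), params.hull_denoise_voxel)
    hull = ConvexHull(pts)
    _, r = og._fit_sphere(hull.points[hull.vertices])
    return float(r)


def find_apex_from_adduction(
    adduction: "FusedState | LabeledPointCloud", params: PipelineParams
) -> np.ndarray:
    """Pseudo orbital apex from a large-adduction session (straight nerve),
    in the frame of the given cloud; reused for every gaze of the orbit."""
    adduction_cloud = adduction.cloud if isinstance(adduction, FusedState) else adduction
    on_pts = adduction_cloud.select(Label.ON)
    cents = og.on_centroids(on_pts, bin_width=params.bin_width)
    p, d, rms = og.fit_line(cents)
    if rms > params.straight_line_rms:
        raise StageError(
            "find_pseudo_apex",
            f"adduction ON is not straight (line fit RMS {rms:.2f} mm)",
        )
    globe_pts = adduction_cloud.select(Label.GLOBE)
    center, _ = globe_center(globe_pts)
    if d @ (on_pts.mean(axis=0) - center) < 0:
        d = -d  # point posteriorly, away from the globe
    wall = adduction_cloud.select(Label.ORBITAL_WALL)
    if len(wall) == 0:
        raise StageError("find_pseudo_apex", "missing orbital wall points")
    return _stage("find_pseudo_apex", og.find_pseudo_apex, p, d, wall)


# ---------------------------------------------------------------------------
# kinematics and strain
# ---------------------------------------------------------------------------


def head_frame_from_landmarks(
    plane: PlaneParams,
    recess_a: np.ndarray,
    recess_b: np.ndarray,
    globe_center_: np.ndarray,
    params: PipelineParams,
) -> Frame:
    lateral = globe_center_ - plane.normal * plane.offset
    anterior = np.asarray(recess_b, float) - np.asarray(recess_a, float)
    return _stage(
        "head_frame", build_head_frame, plane, recess_a, recess_b,
        pitch_deg=params.head_pitch_deg,
        lateral_hint=lateral, anterior_hint=anterior,
    )


def measure_kinematics(
    central: Configuration,
    deformed: Configuration,
    head: Frame,
) -> dict:
    """Duction change, torsion change and globe translation between states."""
    duc0 = duction_angle(central.cloud.select(Label.GLOBE), head,
                         center=central.globe_center)
    duc1 = duction_angle(deformed.cloud.select(Label.GLOBE), head,
                         center=deformed.globe_center)
    translation, mag = globe_translation(central.globe_center,
                                         deformed.globe_center, head)
    tors = duc_chord = np.nan
    try:
        ins = {}
        for key, cfgn in (("0", central), ("1", deformed)):
            for lab in (Label.LR, Label.MR):
                ins[f"{lab.name}{key}"] = muscle_insertion(
                    cfgn.cloud.select(lab), cfgn.globe_center, cfgn.globe_radius
                )
        # the insertion chord spans the equator: its horizontal rotation is
        # the steadiest duction-change estimate, and its elevation change
        # isolates torsion independently of the duction estimate
        duc_chord = duction_change_from_insertions(
            ins["LR0"], ins["MR0"], ins["LR1"], ins["MR1"], head
        )
        tors = torsion_change_about_head(
            ins["LR0"], ins["MR0"], ins["LR1"], ins["MR1"], head
        )
    except ValueError as exc:
        logger.warning("insertion markers unavailable: %s", exc)
    return {
        "duction_central_deg": duc0,
        "duction_deformed_deg": duc1,
        "duction_change_deg": duc_chord if np.isfinite(duc_chord) else duc1 - duc0,
        "duction_change_axis_deg": duc1 - duc0,
        "torsion_change_deg": tors,
        "tx": translation[0],
        "ty": translation[1],
        "tz": translation[2],
        "t_mag": mag,
    }


@dataclass
class StrainResult:
    summary: pd.DataFrame
    matched: st.MatchedPoints
    e_zz: np.ndarray
    u: np.ndarray
    gradient_report: st.GradientReport
    n_excluded: int


def measure_strain(
    central: Configuration,
    deformed: Configuration,
    params: PipelineParams,
) -> StrainResult:
    """Material matching, 6-NN gradients, Green-Lagrange strain, summary."""
    cfg0 = central.on_configuration
    cfg1 = deformed.on_configuration
    m = params.end_margin_stations
    if m > 0:
        # junction/apex neighborhoods suffer partial-volume truncation; the
        # outermost stations are excluded from the material grid
        for cfg in (cfg0, cfg1):
            for sec in cfg.sections[:m] + cfg.sections[-m:]:
                sec.valid = False
    matched = _stage(
        "match_points", st.match_points, cfg0, cfg1,
        n_radii=params.n_radii, n_grid_angles=params.n_grid_angles,
        smooth_boundary=params.smooth_boundary,
    )
    u = st.displacement_field(matched)
    u_s = st.smooth_displacements(matched, u, params.displacement_smoothing_window)
    grads, report = _stage("displacement_gradient", st.displacement_gradient,
                           matched.reference, u_s)
    E = st.green_lagrange(grads, compat_no_half=params.compat_strain_formula)
    e_zz = st.tangential_strain(E, matched.tangent)
    valid = ~report.flagged
    summary = st.regional_summary(matched.s, u, e_zz, valid=valid)
    return StrainResult(summary, matched, e_zz, u, report, int(report.flagged.sum()))


# ---------------------------------------------------------------------------
# file-based run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run description (usually loaded from YAML).

    ``states`` maps a state name to {"coronal": path, "axial": path}; the
    ``central`` state is required. ``apex_state`` names the large-adduction
    state used to define the pseudo apex. The medial plane and recess
    landmarks are given in the central coronal frame (single-orbit mode);
    alternatively ``right_wall`` may name a mirrored wall cloud for
    Chamfer-based plane estimation.
    """

    states: dict[str, dict[str, str]]
    apex_state: str
    output_dir: str = "onstrain_out"
    medial_plane: dict | None = None
    right_wall: str | None = None
    recess_points: list | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        p = d.pop("params", {})
        return cls(params=PipelineParams(**p), **d)


def _load_input(path: str) -> ImageStack | LabeledPointCloud:
    p = Path(path)
    if not p.exists():
        raise StageError("inputs", f"missing input file {p}")
    if p.suffix in (".nii", ".gz"):
        return read_stack(p)
    return read_cloud(p)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes CSV/JSON reports, returns manifest."""
    params = config.params
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "central" not in config.states:
        raise StageError("inputs", "missing required 'central' state")
    if config.apex_state not in config.states:
        raise StageError("inputs", f"apex state {config.apex_state!r} not in states")

    fused: dict[str, FusedState] = {}
    for name, files in config.states.items():
        for key in ("coronal", "axial"):
            if key not in files:
                raise StageError("inputs", f"state {name!r}: missing {key} input")
        fused[name] = fuse_acquisitions(
            _load_input(files["coronal"]), _load_input(files["axial"]), params
        )

    central = fused["central"]
    aligned: dict[str, FusedState] = {}
    gaze_reg: dict[str, RegistrationResult] = {}
    for name, state in fused.items():
        if name == "central":
            aligned[name] = state
            continue
        aligned[name], gaze_reg[name] = align_to_central(central, state, params)

    # head frame
    c_globe, _ = globe_center(central.cloud.select(Label.GLOBE))
    if config.medial_plane is not None:
        plane = PlaneParams.from_dict(config.medial_plane)
    elif config.right_wall is not None:
        right = read_cloud(config.right_wall).select(Label.ORBITAL_WALL)
        plane = _stage("find_medial_plane", find_medial_plane,
                       central.cloud.select(Label.ORBITAL_WALL), right)
    else:
        raise StageError("head_frame", "need medial_plane or right_wall")
    if config.recess_points is None:
        raise StageError("head_frame", "need recess_points landmarks")
    ra, rb = (np.asarray(q, float) for q in config.recess_points)
    head = head_frame_from_landmarks(plane, ra, rb, c_globe, params)

    apex = find_apex_from_adduction(aligned[config.apex_state], params)

    configs = {"central": parameterize_configuration(aligned["central"], apex, params)}
    for name, state in aligned.items():
        if name == "central":
            continue
        j1 = propagate_junction(configs["central"], state, head, params)
        configs[name] = parameterize_configuration(state, apex, params,
                                                   junction_override=j1)

    kin_rows, tort_rows, manifests = [], [], {}
    for name, cfg in configs.items():
        tort_rows.append({"state": name, "tortuosity": cfg.tortuosity,
                          "arc_length_mm": cfg.path.length})
        if name == "central":
            continue
        kin = measure_kinematics(configs["central"], cfg, head)
        kin["state"] = name
        kin_rows.append(kin)
        res = measure_strain(configs["central"], cfg, params)
        res.summary.insert(0, "state", name)
        res.summary.to_csv(out / f"strain_{name}.csv", index=False)
        manifests[name] = {
            "n_samples": len(res.matched),
            "n_flagged_gradients": res.n_excluded,
            "dropped_stations": res.matched.dropped_stations,
            "gaze_registration_residual_mm": gaze_reg[name].residual,
        }
    pd.DataFrame(kin_rows).to_csv(out / "kinematics.csv", index=False)
    pd.DataFrame(tort_rows).to_csv(out / "tortuosity.csv", index=False)

    manifest = {
        "params": asdict(params),
        "states": {k: v for k, v in manifests.items()},
        "acquisition_residuals_mm": {
            k: s.acquisition_registration.residual for k, s in fused.items()
        },
        "head_frame": {"X": head.X.tolist(), "Y": head.Y.tolist(),
                       "Z": head.Z.tolist(), "origin": head.origin.tolist()},
        "apex_common_frame": np.asarray(apex, float).tolist(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, out_dir: str | Path, max_total_points: int = 20000) -> dict:
    """Write a small deterministic scene bundle for tests and demos.

    The scene is sampled on a coarse near-isotropic grid (so cloud input
    needs no slice interpolation), large labels are thinned to keep the
    whole bundle under ``max_total_points``, and a ready-to-run pipeline
    configuration (run.yaml) is written alongside. Regenerating with the
    same seed is bit-identical; the manifest records per-file SHA256
    hashes.
    """
    from .synthetic import GazeState, SceneConfig, generate_scene

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SceneConfig(
        coronal_inplane_spacing=0.55,
        coronal_slice_thickness=0.55,
        axial_inplane_spacing=0.65,
        axial_slice_thickness=0.65,
        noise_sd=0.1,
        seed=int(seed) % 2**31,
    )
    gaze = GazeState(duction_deg=-28.0, deformation_mode="uniform_stretch",
                     mode_magnitude=0.05)
    clouds, gt = generate_scene(config, gaze)

    caps = {int(Label.GLOBE): 1600, int(Label.ORBITAL_WALL): 1000,
            int(Label.LR): 400, int(Label.MR): 400, int(Label.ONS): 500}
    rng = np.random.default_rng(int(seed) % 2**31)
    files = {}
    total = 0
    for tag, cloud in clouds.items():
        keep = []
        for lab in np.unique(cloud.labels):
            idx = np.flatnonzero(cloud.labels == lab)
            cap = caps.get(int(lab))
            if cap is not None and len(idx) > cap:
                idx = np.sort(rng.choice(idx, cap, replace=False))
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        thin = LabeledPointCloud(cloud.points[keep], cloud.labels[keep], tag)
        path = out / f"{tag}.ply"
        write_cloud(thin, path)
        total += len(thin)
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    # operator-style landmarks in the central coronal frame
    Ti = gt.frame_transforms["coronal_central"].inverse()
    n = Ti.rotation @ gt.medial_plane.normal
    point_on_plane = Ti.apply(gt.medial_plane.normal * gt.medial_plane.offset)
    ra, rb = (Ti.apply(q) for q in gt.recess_points)
    run_cfg = {
        "states": {
            "central": {"coronal": "coronal_central.ply", "axial": "axial_central.ply"},
            "adduction_large": {"coronal": "coronal_gaze.ply", "axial": "axial_gaze.ply"},
        },
        "apex_state": "adduction_large",
        "output_dir": "out",
        "medial_plane": {"normal": n.tolist(), "offset": float(n @ point_on_plane)},
        "recess_points": [ra.tolist(), rb.tolist()],
        "params": {"n_sections": 30, "min_bin_points": 15, "bin_width": 0.6,
                   "seed": int(seed) % 2**31},
    }
    yaml_text = yaml.safe_dump(run_cfg, sort_keys=True)
    (out / "run.yaml").write_text(yaml_text)
    files["run.yaml"] = hashlib.sha256(yaml_text.encode()).hexdigest()

    meta = {
        "seed": int(seed),
        "config": config.to_dict(),
        "gaze": asdict(gaze),
        "total_points": total,
        "files": files,
    }
    (out / "fixture_manifest.json").write_text(json.dumps(meta, indent=2))
    return meta
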