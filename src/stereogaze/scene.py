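"""Rig geometry: cameras, infrared light sources, screen.

The default scene reproduces the validated desktop rig: two cameras on a
rail 150 mm below the bottom edge of a 24-inch monitor and 40 mm in front
of it, +/-60 mm from the screen's vertical midline, with the two IR light
sources 60 mm further out; the subject sits 650 mm from the screen centre
on its z-axis and is sampled at 50 Hz.

Everything is expressed in the right-handed screen coordinate system
(origin at screen centre, +z toward the subject, +x subject-left,
+y down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraModel, look_at_pose
from .geometry import Plane, RigidTransform, as_vec3, normalize


@dataclass
class Screen:
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    x_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    width_mm: float = 527.0
    height_mm: float = 296.0

    def __post_init__(self):
        self.center = as_vec3(self.center)
        self.normal = normalize(self.normal)
        x = as_vec3(self.x_axis)
        self.x_axis = normalize(x - self.normal * np.dot(x, self.normal))

    @property
    def y_axis(self) -> np.ndarray:
        return np.cross(self.normal, self.x_axis)

    @property
    def plane(self) -> Plane:
        return Plane(self.center, self.normal)

    def to_screen_xy(self, p) -> np.ndarray:
        d = as_vec3(p) - self.center
        return np.array([np.dot(d, self.x_axis), np.dot(d, self.y_axis)])

    def from_screen_xy(self, x_mm: float, y_mm: float) -> np.ndarray:
        return self.center + x_mm * self.x_axis + y_mm * self.y_axis


@dataclass
class SceneGeometry:
    camera1: CameraModel
    camera2: CameraModel
    light1: np.ndarray  # mm; light1.x < light2.x
    light2: np.ndarray
    screen: Screen = field(default_factory=Screen)
    sampling_rate: float = 50.0  # Hz

    def __post_init__(self):
        self.light1 = as_vec3(self.light1)
        self.light2 = as_vec3(self.light2)
        if self.light1[0] >= self.light2[0]:
            raise ValueError("light1 must have the smaller x-coordinate")

    @property
    def cameras(self) -> tuple[CameraModel, CameraModel]:
        return (self.camera1, self.camera2)

    @property
    def lights(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.light1, self.light2)


# pixel pitch 2.4 um, 16-mm lens
_DEFAULT_FOCAL_PX = 16.0 / 0.0024
_DEFAULT_RES = (1420, 1420)


def default_scene(
    viewing_distance: float = 650.0, light_drop_mm: float = 30.0
) -> SceneGeometry:
    """The rig with its hardware defaults; cameras aimed at the expected
    cyclopean eye position ``(0, 0, viewing_distance)``.

    The LED-board centres sit ``light_drop_mm`` below the camera optical
    centres: with lights exactly collinear with the cameras the two
    reflection planes of each camera would coincide and the corneal-centre
    reconstruction would be geometrically degenerate, so the rig (like any
    physical mounting of finite-size boards) keeps them off the camera
    axis."""
    screen = Screen()
    y_rig = screen.height_mm / 2.0 + 150.0  # below the monitor's bottom edge
    z_rig = 40.0  # in front of the screen plane
    aim = np.array([0.0, 0.0, viewing_distance])
    cams = []
    for x in (-60.0, 60.0):
        pose = look_at_pose([x, y_rig, z_rig], aim)
        cams.append(
            CameraModel(
                pose=pose,
                focal=_DEFAULT_FOCAL_PX,
                principal_point=(_DEFAULT_RES[0] / 2, _DEFAULT_RES[1] / 2),
                resolution=_DEFAULT_RES,
            )
        )
    return SceneGeometry(
        camera1=cams[0],
        camera2=cams[1],
        light1=np.array([-120.0, y_rig + light_drop_mm, z_rig]),
        light2=np.array([120.0, y_rig + light_drop_mm, z_rig]),
        screen=screen,
    )


# ---------------------------------------------------------------------------
# serialization (JSON / YAML; chosen by file extension)

def scene_to_dict(scene: SceneGeometry) -> dict:
    def cam(c: CameraModel) -> dict:
        return {
            "K": c.K.tolist(),
            "distortion": c.distortion.tolist(),
            "R": c.pose.rotation.tolist(),  # camera-to-scene
            "t": c.pose.translation.tolist(),
            "resolution": list(c.resolution),
        }

    return {
        "cameras": [cam(scene.camera1), cam(scene.camera2)],
        "lights": [scene.light1.tolist(), scene.light2.tolist()],
        "screen": {
            "center": scene.screen.center.tolist(),
            "normal": scene.screen.normal.tolist(),
            "x_axis": scene.screen.x_axis.tolist(),
            "width_mm": scene.screen.width_mm,
            "height_mm": scene.screen.height_mm,
        },
        "sampling_rate_hz": scene.sampling_rate,
    }


def scene_from_dict(d: dict) -> SceneGeometry:
    def cam(cd: dict) -> CameraModel:
        K = np.asarray(cd["K"], dtype=float)
        return CameraModel(
            pose=RigidTransform(np.asarray(cd["R"], dtype=float), np.asarray(cd["t"], dtype=float)),
            focal=float(K[0, 0]),
            principal_point=(float(K[0, 2]), float(K[1, 2])),
            resolution=tuple(cd.get("resolution", _DEFAULT_RES)),
            distortion=np.asarray(cd.get("distortion", np.zeros(5)), dtype=float),
        )

    sd = d["screen"]
    return SceneGeometry(
        camera1=cam(d["cameras"][0]),
        camera2=cam(d["cameras"][1]),
        light1=np.asarray(d["lights"][0], dtype=float),
        light2=np.asarray(d["lights"][1], dtype=float),
        screen=Screen(
            center=np.asarray(sd["center"], dtype=float),
            normal=np.asarray(sd["normal"], dtype=float),
            x_axis=np.asarray(sd["x_axis"], dtype=float),
            width_mm=float(sd["width_mm"]),
            height_mm=float(sd["height_mm"]),
        ),
        sampling_rate=float(d.get("sampling_rate_hz", 50.0)),
    )


def save_scene(scene: SceneGeometry, path) -> None:
    path = Path(path)
    d = scene_to_dict(scene)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_scene(path) -> SceneGeometry:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return scene_from_dict(d)
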