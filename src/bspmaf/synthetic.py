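"""Synthetic torso geometry, electrode vests and multichannel body-surface recordings.

Clinical body-surface potential maps (BSPMs) of atrial-fibrillation patients are
not publicly available, so this module generates stand-in data with the same
structural properties the rest of the pipeline assumes:

* a parametric torso surface (elliptic cylinder with squashed spherical caps),
* a 128-electrode vest (74 anterior / 54 posterior, 3.5 cm within-column
  spacing) plus a 3-electrode Wilson-central-terminal reference triangle,
* multichannel unipolar recordings driven by a moving ventricular current
  dipole whose wavefront travels along a configurable cardiac-axis direction,
  with class-dependent irregular atrial activity superimposed for AF-like
  signals.

Everything is deterministic for a fixed seed; per-patient sub-seeds are derived
from the master seed so cohorts are reproducible patient by patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import GeometryError, InvalidParameterError

# Coordinates: +x toward the patient's left, +y up, +z anterior (all cm).
# The 2D anterior projection uses (u = x, v = distance down from the torso top).

LABEL_RECURRENCE = "recurrence"
LABEL_NON_RECURRENCE = "non-recurrence"
LABEL_UNLABELED = "unlabeled"

#: anterior grid: 10 columns (patient's right to left), rows top-aligned
_ANTERIOR_ROWS = (7, 7, 7, 8, 8, 8, 8, 7, 7, 7)  # sums to 74
_POSTERIOR_COLS = 9
_POSTERIOR_ROWS = 6  # 9 * 6 = 54
_COLUMN_SPACING_CM = 3.5

# Channel labels with a fixed anatomical meaning.  The vest's channel map is a
# convention; this one places the labels used by the approximate limb-lead
# derivation (29, 93, 37) and the activation-sequence reference set
# (93, 112, 3, 5, 25, 36) so that lead I = U29 - U93 points toward the
# patient's left and lead III = U37 - U29 points down-and-right, a
# near-equilateral chest triangle matching the Einthoven frontal-plane lead
# directions (0 deg and ~120 deg).
_SPECIAL_LABELS = {
    (2, 1): 93,
    (4, 1): 112,
    (5, 2): 3,
    (6, 3): 5,
    (7, 4): 25,
    (8, 5): 36,
    (9, 1): 29,
    (6, 8): 37,
}

DEFAULT_AXIS_ANGLE_DEG = 48.0


@dataclass
class TorsoMesh:
    """Closed triangulated torso surface with a tagged anterior region."""

    vertices: np.ndarray  # (V, 3) cm
    faces: np.ndarray  # (F, 3) int vertex indices
    front_mask: np.ndarray  # (V,) bool, True on the anterior surface

    def validate(self) -> None:
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise GeometryError("face indices out of range")
        if not self.front_mask.any():
            raise GeometryError("front region is empty")


@dataclass
class ElectrodeLayout:
    """128 recording electrodes plus the Wilson-central-terminal triangle.

    ``positions_2d`` holds the orthographic frontal projection (cm; u toward
    the patient's left, v down from the torso top) and is NaN for posterior
    electrodes, which are never rasterized.
    """

    names: list[str]  # 128 labels, "1".."128" in vest order
    positions_3d: np.ndarray  # (128, 3)
    positions_2d: np.ndarray  # (128, 2), NaN rows for posterior electrodes
    side: np.ndarray  # (128,) "A" (anterior) or "P" (posterior)
    ref_names: list[str]  # 3 reference electrode labels
    ref_positions_3d: np.ndarray  # (3, 3)

    def index(self, name: str | int) -> int:
        return self.names.index(str(name))

    @property
    def anterior_mask(self) -> np.ndarray:
        return self.side == "A"

    @property
    def anterior_names(self) -> list[str]:
        return [n for n, s in zip(self.names, self.side) if s == "A"]

    def validate(self) -> None:
        n_ant = int((self.side == "A").sum())
        n_post = int((self.side == "P").sum())
        if len(self.names) != 128 or n_ant != 74 or n_post != 54:
            raise GeometryError(
                f"expected 74 anterior + 54 posterior electrodes, got {n_ant}+{n_post}"
            )
        if len(self.ref_names) != 3 or set(self.ref_names) & set(self.names):
            raise GeometryError("need exactly 3 reference electrodes disjoint from vest")


@dataclass
class BspmRecording:
    """channels x samples voltage array (mV) with channel map and label."""

    data: np.ndarray
    fs: float
    patient_id: str
    label: str = LABEL_UNLABELED
    channel_names: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise InvalidParameterError("recording contains NaN/Inf")
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise InvalidParameterError("channel_names does not match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str | int) -> np.ndarray:
        return self.data[self.channel_names.index(str(name))]


@dataclass
class AtrialClassParams:
    """Parameters of the irregular atrial oscillator for one outcome class.

    dominant_rate_hz
        centre of the fibrillatory (f-wave) dominant frequency, Hz.
    organization_hz
        standard deviation of the slow frequency jitter around the dominant
        rate; small values mean highly organized atrial activity.
    amplitude_mv
        peak f-wave amplitude at the chest electrodes, mV.
    """

    dominant_rate_hz: float = 5.0
    organization_hz: float = 0.5
    amplitude_mv: float = 0.25


#: Study-condition class parameters.  Higher dominant frequency and lower
#: organization of atrial activity are the features the recurrence-prone class
#: carries; amplitudes are typical f-wave sizes on the chest.
DEFAULT_CLASS_PARAMS: dict[str, AtrialClassParams] = {
    LABEL_NON_RECURRENCE: AtrialClassParams(4.5, 0.3, 0.25),
    LABEL_RECURRENCE: AtrialClassParams(7.0, 1.2, 0.30),
}


@dataclass
class CohortSpec:
    """Description of a labeled synthetic patient cohort."""

    n_patients: int = 14
    recurrence_fraction: float = 4.0 / 14.0
    duration_s: float = 180.0
    fs: float = 1000.0
    axis_angle_deg: float = DEFAULT_AXIS_ANGLE_DEG
    class_params: dict[str, AtrialClassParams] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InvalidParameterError("n_patients must be >= 1")
        if not 0.0 <= self.recurrence_fraction <= 1.0:
            raise InvalidParameterError("recurrence_fraction must be in [0, 1]")
        if self.duration_s <= 0 or self.fs <= 0:
            raise InvalidParameterError("duration and fs must be positive")


# ---------------------------------------------------------------------------
# Torso mesh
# ---------------------------------------------------------------------------

def generate_torso_mesh(
    height_cm: float = 60.0,
    width_cm: float = 36.0,
    depth_cm: float = 24.0,
    resolution: int = 24,
) -> TorsoMesh:
    """Parametric torso: elliptic cylinder with squashed spherical caps.

    ``resolution`` sets the number of vertices per ring and the number of
    rings along the straight section; the construction is deterministic.
    """
    if height_cm <= 0 or width_cm <= 0 or depth_cm <= 0:
        raise InvalidParameterError("torso dimensions must be positive")
    if resolution < 8:
        raise InvalidParameterError("resolution must be >= 8")

    a, b = width_cm / 2.0, depth_cm / 2.0
    cap = min(0.12 * height_cm, a)
    straight = height_cm - 2.0 * cap
    n_theta = int(resolution)
    n_rings = int(resolution)
    n_cap = max(2, resolution // 4)

    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    rings: list[np.ndarray] = []

    def ellipse_ring(scale: float, y: float) -> np.ndarray:
        return np.column_stack(
            [a * scale * np.sin(theta), np.full(n_theta, y), b * scale * np.cos(theta)]
        )

    # bottom pole, bottom cap, straight section, top cap, top pole
    y0, y1 = -height_cm / 2.0, height_cm / 2.0
    verts = [np.array([[0.0, y0, 0.0]])]
    for k in range(1, n_cap + 1):
        phi = 0.5 * math.pi * k / (n_cap + 1)
        verts.append(ellipse_ring(math.sin(phi), y0 + cap * (1 - math.cos(phi))))
    for k in range(n_rings):
        y = (y0 + cap) + straight * k / (n_rings - 1)
        verts.append(ellipse_ring(1.0, y))
    for k in range(n_cap, 0, -1):
        phi = 0.5 * math.pi * k / (n_cap + 1)
        verts.append(ellipse_ring(math.sin(phi), y1 - cap * (1 - math.cos(phi))))
    verts.append(np.array([[0.0, y1, 0.0]]))
    vertices = np.concatenate(verts, axis=0)

    faces: list[tuple[int, int, int]] = []
    ring_starts = [1 + r * n_theta for r in range(2 * n_cap + n_rings)]
    # bottom fan
    first = ring_starts[0]
    for i in range(n_theta):
        faces.append((0, first + (i + 1) % n_theta, first + i))
    # strips
    for r0, r1 in zip(ring_starts[:-1], ring_starts[1:]):
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append((r0 + i, r0 + j, r1 + i))
            faces.append((r0 + j, r1 + j, r1 + i))
    # top fan
    last = ring_starts[-1]
    top = len(vertices) - 1
    for i in range(n_theta):
        faces.append((top, last + i, last + (i + 1) % n_theta))

    mesh = TorsoMesh(
        vertices=vertices,
        faces=np.asarray(faces, dtype=np.int64),
        front_mask=vertices[:, 2] > 0.0,
    )
    mesh.validate()
    if len(vertices) < 100:
        raise InvalidParameterError("resolution yields fewer than 100 vertices")
    return mesh


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------

def _mesh_extents(mesh: TorsoMesh) -> tuple[float, float, float, float]:
    v = mesh.vertices
    a = (v[:, 0].max() - v[:, 0].min()) / 2.0
    b = (v[:, 2].max() - v[:, 2].min()) / 2.0
    return a, b, float(v[:, 1].min()), float(v[:, 1].max())


def generate_electrode_layout(mesh: TorsoMesh | None = None) -> ElectrodeLayout:
    """Place the 128-electrode vest on the torso surface.

    Electrodes sit on the elliptic cross-section fitted to the mesh's bounding
    box, in vertical columns with exactly 3.5 cm between same-column
    neighbours.  Labels follow the package's fixed channel map (see module
    notes); three reference electrodes form the Wilson-central-terminal
    triangle.
    """
    if mesh is None:
        mesh = generate_torso_mesh()
    a, b, y_min, y_max = _mesh_extents(mesh)

    grid_extent = (max(_ANTERIOR_ROWS) - 1) * _COLUMN_SPACING_CM
    y_top = y_max - 0.18 * (y_max - y_min)
    if y_top - grid_extent < y_min:
        raise GeometryError("mesh too small to host the electrode grid")
    if a < 10.0 or b < 5.0:
        raise GeometryError("torso cross-section too small for the vest")

    def on_surface(theta_deg: float, y: float) -> np.ndarray:
        t = math.radians(theta_deg)
        return np.array([a * math.sin(t), y, b * math.cos(t)])

    positions: list[np.ndarray] = []
    side: list[str] = []
    grid_index: list[tuple[int, int]] = []  # (column, row) for anterior
    ant_thetas = np.linspace(-70.0, 70.0, len(_ANTERIOR_ROWS))
    for c, (th, n_rows) in enumerate(zip(ant_thetas, _ANTERIOR_ROWS), start=1):
        for r in range(1, n_rows + 1):
            positions.append(on_surface(th, y_top - (r - 1) * _COLUMN_SPACING_CM))
            side.append("A")
            grid_index.append((c, r))
    post_thetas = np.linspace(110.0, 250.0, _POSTERIOR_COLS)
    for th in post_thetas:
        for r in range(1, _POSTERIOR_ROWS + 1):
            positions.append(on_surface(th, y_top - (r - 1) * _COLUMN_SPACING_CM))
            side.append("P")
            grid_index.append((-1, r))

    pos3d = np.asarray(positions)
    side_arr = np.asarray(side)

    # label assignment: anatomically pinned labels first, remaining labels in
    # vest order (anterior column-major, then posterior)
    labels = np.zeros(len(pos3d), dtype=np.int64)
    used = set()
    for i, key in enumerate(grid_index):
        if side_arr[i] == "A" and key in _SPECIAL_LABELS:
            labels[i] = _SPECIAL_LABELS[key]
            used.add(labels[i])
    pool = iter(x for x in range(1, 129) if x not in used)
    for i in range(len(labels)):
        if labels[i] == 0:
            labels[i] = next(pool)

    pos2d = np.full((len(pos3d), 2), np.nan)
    ant = side_arr == "A"
    pos2d[ant, 0] = pos3d[ant, 0]
    pos2d[ant, 1] = y_top - pos3d[ant, 1]  # v grows downward from the grid top

    ref_positions = np.stack(
        [
            on_surface(-85.0, y_top + 2.0),  # right shoulder
            on_surface(85.0, y_top + 2.0),  # left shoulder
            on_surface(0.0, y_top - grid_extent - 4.0),  # lower abdomen
        ]
    )
    layout = ElectrodeLayout(
        names=[str(x) for x in labels],
        positions_3d=pos3d,
        positions_2d=pos2d,
        side=side_arr,
        ref_names=["WCT1", "WCT2", "WCT3"],
        ref_positions_3d=ref_positions,
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _dipole_potential(obs: np.ndarray, src: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Infinite-medium current-dipole potential  p . r / |r|^3  (unnormalized)."""
    r = obs - src
    d3 = np.maximum(np.linalg.norm(r, axis=-1), 1.0) ** 3
    return (r @ moment) / d3


def _frontal_direction(angle_deg: float) -> np.ndarray:
    """Unit vector in the frontal plane; 0 deg = patient's left, +90 deg = down."""
    t = math.radians(angle_deg)
    return np.array([math.cos(t), -math.sin(t), 0.0])


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance low-frequency noise (white noise low-passed at cutoff)."""
    w = rng.standard_normal(n)
    if n > 18:
        sos = scipy.signal.butter(2, cutoff_hz, "lowpass", fs=fs, output="sos")
        w = scipy.signal.sosfiltfilt(sos, w)
    s = w.std()
    return w / s if s > 0 else w


def simulate_recording(
    layout: ElectrodeLayout,
    class_params: AtrialClassParams | None = None,
    duration_s: float = 10.0,
    fs: float = 1000.0,
    seed: int = 0,
    rhythm: str = "af",
    axis_angle_deg: float = DEFAULT_AXIS_ANGLE_DEG,
    heart_rate_bpm: float = 75.0,
    qrs_amplitude_mv: float = 1.5,
    sensor_noise_mv: float = 0.02,
    patient_id: str = "P00",
    label: str = LABEL_UNLABELED,
) -> BspmRecording:
    """Simulate one 128+3 channel unipolar recording.

    The ventricular complex is a traveling wavefront along the configured
    frontal-plane cardiac axis: each electrode sees a QRS-like deflection
    whose amplitude is the projection of the electrode's displacement from
    the heart centre onto the axis direction (a uniform lead field) and whose
    arrival is delayed by that same projection divided by the conduction
    velocity, so the potential pattern sweeps across the grid in the axis
    direction.  ``rhythm="sinus"`` adds P and T waves with regular beats;
    ``rhythm="af"`` replaces the P wave with an irregular atrial oscillator
    (a rotating current dipole in the atrial region) parameterized by
    ``class_params`` and makes the beat intervals irregular.  The three
    Wilson reference electrodes are appended as extra channels.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    if rhythm not in ("af", "sinus"):
        raise InvalidParameterError(f"unknown rhythm {rhythm!r}")
    if class_params is None:
        class_params = AtrialClassParams()

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    obs = np.concatenate([layout.positions_3d, layout.ref_positions_3d], axis=0)
    ant = layout.positions_3d[layout.anterior_mask]
    heart = np.array([4.0, float(ant[:, 1].mean()), 2.0])
    d_axis = _frontal_direction(axis_angle_deg)
    d_perp = _frontal_direction(axis_angle_deg + 90.0)

    volts = np.zeros((len(obs), n))

    # beat times
    beats = []
    tk = float(rng.uniform(0.1, 0.5))
    while tk < duration_s:
        beats.append(tk)
        if rhythm == "sinus":
            rr = 60.0 / heart_rate_bpm + rng.normal(0.0, 0.02)
        else:
            rr = float(np.clip(rng.normal(60.0 / heart_rate_bpm, 0.12), 0.45, 1.3))
        tk += max(rr, 0.3)

    # uniform lead field along the axis: per-electrode amplitude and arrival
    # delay are both set by the projection of the electrode displacement onto
    # the axis direction (conduction velocity 10 m/s => 1 cm per ms)
    proj = (obs - heart) @ d_axis  # cm, signed
    qrs_gain = qrs_amplitude_mv / np.abs(proj[: len(layout.names)]).max()
    # the Wilson terminal approximates a zero reference: the synthetic
    # reference electrodes carry no ventricular lead-field pickup
    proj[len(layout.names) :] = 0.0
    velocity_cm_per_s = 1000.0
    delays = proj / velocity_cm_per_s
    sigma_q = 0.020

    def add_wave(center: float, amp_scale: float, sigma: float, delayed: bool) -> None:
        d = delays if delayed else np.zeros_like(delays)
        lo, hi = center + d.min() - 5 * sigma, center + d.max() + 5 * sigma
        w = (t > lo) & (t < hi)
        if not w.any():
            return
        arg = (t[w][None, :] - center - d[:, None]) / sigma
        volts[:, w] += amp_scale * qrs_gain * proj[:, None] * np.exp(-0.5 * arg**2)

    for tk in beats:
        amp = 1.0 + float(rng.normal(0.0, 0.05))
        add_wave(tk, amp, sigma_q, delayed=True)
        if rhythm == "sinus":
            add_wave(tk + 0.30, 0.25 * amp, 0.055, delayed=True)  # T wave
            add_wave(tk - 0.18, 0.10 * amp, 0.030, delayed=True)  # P wave

    if rhythm == "af":
        atrium = heart + np.array([0.0, 5.0, -1.0])
        c1 = _dipole_potential(obs, atrium, d_axis)
        c2 = _dipole_potential(obs, atrium, d_perp)
        gain_a = class_params.amplitude_mv / max(
            np.sqrt(c1**2 + c2**2)[: len(layout.names)][layout.anterior_mask].max(), 1e-12
        )
        jitter = _smooth_noise(rng, n, fs, 1.0) * class_params.organization_hz
        freq = np.maximum(class_params.dominant_rate_hz + jitter, 0.5)
        phase = 2.0 * math.pi * np.cumsum(freq) / fs
        am = 1.0 + 0.2 * _smooth_noise(rng, n, fs, 0.5) * 0.5
        volts += gain_a * am * (np.outer(c1, np.cos(phase)) + np.outer(c2, np.sin(phase)))

    volts += rng.normal(0.0, sensor_noise_mv, volts.shape)

    rec = BspmRecording(
        data=volts,
        fs=float(fs),
        patient_id=patient_id,
        label=label,
        channel_names=list(layout.names) + list(layout.ref_names),
    )
    rec.validate()
    return rec


def generate_cohort(
    spec: CohortSpec, layout: ElectrodeLayout | None = None
) -> list[BspmRecording]:
    """Generate ``spec.n_patients`` labeled recordings.

    The first ``ceil(n * recurrence_fraction)`` patients carry the recurrence
    label.  Each patient gets an independent sub-seed derived from
    ``spec.seed`` plus patient-level variability in heart rate, cardiac-axis
    angle, atrial rate and amplitude, so inter-patient splits face genuine
    between-subject differences.
    """
    spec.validate()
    if layout is None:
        layout = generate_electrode_layout()
    params = dict(DEFAULT_CLASS_PARAMS)
    if spec.class_params:
        params.update(spec.class_params)

    n_rec = math.ceil(spec.n_patients * spec.recurrence_fraction)
    recordings = []
    for i in range(spec.n_patients):
        label = LABEL_RECURRENCE if i < n_rec else LABEL_NON_RECURRENCE
        ss = np.random.SeedSequence([int(spec.seed), i])
        child = int(ss.generate_state(1)[0] % (2**31))
        prng = np.random.default_rng(child + 1)
        base = params[label]
        indiv = AtrialClassParams(
            dominant_rate_hz=base.dominant_rate_hz + float(prng.normal(0.0, 0.15)),
            organization_hz=max(base.organization_hz * float(prng.uniform(0.8, 1.2)), 0.05),
            amplitude_mv=base.amplitude_mv * float(prng.uniform(0.9, 1.1)),
        )
        recordings.append(
            simulate_recording(
                layout,
                class_params=indiv,
                duration_s=spec.duration_s,
                fs=spec.fs,
                seed=child,
                rhythm="af",
                axis_angle_deg=spec.axis_angle_deg + float(prng.normal(0.0, 3.0)),
                heart_rate_bpm=float(np.clip(prng.normal(78.0, 6.0), 55.0, 110.0)),
                sensor_noise_mv=0.02,
                patient_id=f"P{i + 1:02d}",
                label=label,
            )
        )
    return recordings
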