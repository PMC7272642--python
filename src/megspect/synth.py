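"""Synthetic resting-state MEG cohorts with known ground truth.

Because no raw cohort recordings are publicly deposited, the pipeline is
exercised on simulated data whose statistical structure matches the
analysis assumptions: a spherical conductor head with a parcellated
source shell, a helmet of point magnetometers, band-limited Gaussian
source activity whose regional amplitudes differ by group (AD vs NC) and
condition (eyes closed vs eyes open), white sensor noise, and occasional
large-amplitude boxcar artifacts that exercise threshold rejection.

Everything is a pure function of the cohort specification and its seeds:
the same spec always reproduces the same cohort, and the drawn per-subject
regional amplitudes are kept as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import preproc
from .atlas import BAND_NAMES, CONDITIONS, GROUPS, region_labels
from .preproc import BandSpec, RawRecording, default_bands
from .sourceest import LeadFieldMatrix

# Default desk-scale simulation sizes (paper-scale 160 ch / 15000 vtx /
# 1000 Hz / 120 s is available through the run configuration).
DESK_N_CHANNELS = 64
DESK_N_VERTICES = 500
DESK_SAMPLING_RATE = 250.0
DESK_DURATION = 30.0

#: The cell carrying the default AD-vs-NC amplitude effect.
DESIGNATED_REGION = "rh_supramarginal"
DESIGNATED_BAND = "alpha1"

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SensorArrayGeometry:
    """Helmet of point magnetometers outside the conductor sphere."""

    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (n, 3) metres
    orientations: np.ndarray  # (n, 3) unit sensing directions

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sensor orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass
class HeadModelGeometry:
    """Spherical conductor with a parcellated source shell inside it."""

    sphere_center: np.ndarray
    sphere_radius: float
    vertices: np.ndarray  # (n, 3) metres, strictly inside the sphere
    normals: np.ndarray  # (n, 3) unit source orientations
    region_names: tuple[str, ...]
    vertex_region: np.ndarray  # (n,) int index into region_names

    def __post_init__(self) -> None:
        self.sphere_center = np.asarray(self.sphere_center, float)
        self.vertices = np.asarray(self.vertices, float)
        self.normals = np.asarray(self.normals, float)
        self.vertex_region = np.asarray(self.vertex_region, int)
        radii = np.linalg.norm(self.vertices - self.sphere_center, axis=1)
        if np.any(radii >= self.sphere_radius):
            raise ValueError("every vertex must lie strictly inside the sphere")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("normals must be unit vectors")
        counts = np.bincount(self.vertex_region, minlength=len(self.region_names))
        if np.any(counts == 0):
            empty = [self.region_names[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty regions: {empty}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def region_vertices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.vertex_region == self.region_names.index(label))


@dataclass
class SourceActivityMatrix:
    """Source current time courses, (vertices x samples) in A*m."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("source activity contains non-finite values")


@dataclass
class ArtifactEvent:
    channel: int
    onset_sample: int
    n_samples: int
    amplitude: float


@dataclass
class CohortSpec:
    """Study conditions of a simulated cohort.

    Cohort sizes default to 20 AD / 27 NC.  ``amplitude_table`` holds the
    group x condition x band x region mean source amplitudes (A*m); the
    per-subject realization is a shared log-normal multiplier per
    (band, region) with coefficient of variation ``between_subject_cv``,
    drawn once per subject, so a subject's EC and EO amplitudes move
    together as a stable individual trait.
    """

    n_ad: int = 20
    n_nc: int = 27
    sampling_rate: float = DESK_SAMPLING_RATE
    duration: float = DESK_DURATION
    amplitude_table: pd.Series | None = None  # index (group, condition, band, region)
    between_subject_cv: float = 0.2
    source_floor_rms: float = 0.3e-9  # A*m, 1/f broadband floor per vertex
    sensor_noise_sd: float = 5e-14  # tesla
    artifact_rate: float = 1.0  # events per minute
    artifact_amplitude: float = 12e-12  # tesla
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 2 or self.n_nc < 2:
            raise ValueError("need at least 2 subjects per group")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling_rate must be integral")
        if self.sensor_noise_sd < 0 or self.source_floor_rms < 0:
            raise ValueError("noise levels must be non-negative")
        if self.amplitude_table is not None and (self.amplitude_table < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def table_for(self, regions: tuple[str, ...]) -> pd.Series:
        if self.amplitude_table is None:
            return default_amplitude_table(regions)
        return self.amplitude_table


# Mean source amplitude per vertex (A*m) by band and condition.  Alpha
# dominates and reacts strongly to eye opening (alpha blocking); the other
# bands are mildly higher under EC so that absolute power is generally
# higher eyes-closed across the spectrum.
_BASE_AMPLITUDES = {
    #            EC        EO
    "theta1": (0.80e-9, 0.72e-9),
    "theta2": (0.80e-9, 0.72e-9),
    "alpha1": (2.00e-9, 1.00e-9),
    "alpha2": (1.50e-9, 0.85e-9),
    "beta": (0.60e-9, 0.55e-9),
}


def default_amplitude_table(
    regions: tuple[str, ...],
    ad_effects: dict[tuple[str, str], float] | None = None,
) -> pd.Series:
    """Group x condition x band x region mean amplitude table.

    ``ad_effects`` maps (band, region) to a multiplier applied to the AD
    group in both conditions.  The default raises alpha1 in the right
    supramarginal region by a factor 1.4 -- about +2 between-subject SD at
    the default CV of 0.2 -- mirroring a parietal alpha elevation in AD.
    """
    if ad_effects is None:
        effect_region = (
            DESIGNATED_REGION if DESIGNATED_REGION in regions else regions[-1]
        )
        ad_effects = {(DESIGNATED_BAND, effect_region): 1.4}
    idx = pd.MultiIndex.from_product(
        [GROUPS, CONDITIONS, BAND_NAMES, list(regions)],
        names=["group", "condition", "band", "region"],
    )
    table = pd.Series(0.0, index=idx, name="amplitude")
    for band, (ec, eo) in _BASE_AMPLITUDES.items():
        table.loc[(slice(None), "EC", band, slice(None))] = ec
        table.loc[(slice(None), "EO", band, slice(None))] = eo
    for (band, region), mult in ad_effects.items():
        for cond in CONDITIONS:
            table.loc[("AD", cond, band, region)] *= mult
    return table


def _fibonacci_sphere(n: int, z_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical zone z in z_range."""
    i = np.arange(n)
    z = z_range[1] - (i + 0.5) * (z_range[1] - z_range[0]) / n
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _parcellate(
    directions: np.ndarray, centers: np.ndarray, n_regions: int
) -> np.ndarray:
    """Assign vertices to nearest region center, guaranteeing no empty region.

    Each region first claims its single nearest unclaimed vertex (so even
    n_regions == n_vertices yields exactly one vertex per region); the
    remaining vertices then go to their nearest center, which produces
    contiguous Voronoi-style patches.
    """
    sim = directions @ centers.T  # cosine similarity, (n_vtx, n_regions)
    assignment = np.full(directions.shape[0], -1, int)
    for r in range(n_regions):
        order = np.argsort(-sim[:, r])
        for v in order:
            if assignment[v] < 0:
                assignment[v] = r
                break
    free = assignment < 0
    assignment[free] = np.argmax(sim[free], axis=1)
    return assignment


def make_geometry(
    n_channels: int = DESK_N_CHANNELS,
    n_vertices: int = DESK_N_VERTICES,
    n_regions: int = 68,
    seed: int = 0,
    sphere_radius: float = 0.09,
    shell_fraction: float = 0.8,
    sensor_radius: float = 0.12,
    cortex_z_min: float = -0.35,
    normal_radial_sd: float = 0.3,
) -> tuple[SensorArrayGeometry, HeadModelGeometry]:
    """Build a helmet array and a parcellated spherical head model.

    Vertices sit quasi-uniformly on the helmet-covered zone
    (z/r > ``cortex_z_min``) of an inner shell at
    ``shell_fraction * sphere_radius`` -- the cortex occupies the upper
    head, not a full sphere.  Source orientations are tangentially
    biased (random tangential direction plus a Gaussian radial component
    of SD ``normal_radial_sd``), as MEG-visible cortical currents mostly
    are.  A seeded azimuthal rotation and the seeded orientations make
    distinct seeds produce distinct but reproducible geometries.  With
    ``n_regions`` even the parcellation is left/right symmetric; 68
    regions get Desikan-Killiany labels.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if n_regions > n_vertices:
        raise ValueError(
            f"n_regions ({n_regions}) must not exceed n_vertices ({n_vertices})"
        )
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)  # azimuthal jitter keeps cortex upright
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )

    directions = _fibonacci_sphere(n_vertices, z_range=(cortex_z_min, 1.0)) @ rot.T
    vertices = shell_fraction * sphere_radius * directions
    rand = rng.standard_normal((n_vertices, 3))
    tangential = rand - np.sum(rand * directions, axis=1, keepdims=True) * directions
    tangential /= np.linalg.norm(tangential, axis=1, keepdims=True)
    normals = tangential + normal_radial_sd * rng.standard_normal(
        (n_vertices, 1)
    ) * directions
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    labels = region_labels(n_regions)
    if n_regions % 2 == 0:
        half = n_regions // 2
        centers_lh = _fibonacci_sphere(half, z_range=(cortex_z_min, 1.0))
        centers_lh[:, 0] = -np.abs(centers_lh[:, 0]) - 1e-6
        centers_lh /= np.linalg.norm(centers_lh, axis=1, keepdims=True)
        centers_rh = centers_lh * np.array([-1.0, 1.0, 1.0])
        centers = np.vstack([centers_lh, centers_rh]) @ rot.T
    else:
        centers = _fibonacci_sphere(n_regions, z_range=(cortex_z_min, 1.0)) @ rot.T
    assignment = _parcellate(directions, centers, n_regions)

    head = HeadModelGeometry(
        sphere_center=np.zeros(3),
        sphere_radius=sphere_radius,
        vertices=vertices,
        normals=normals,
        region_names=labels,
        vertex_region=assignment,
    )

    # Helmet: quasi-uniform cap covering the crown down past the ears,
    # radial sensing directions.
    sensor_dirs = _fibonacci_sphere(n_channels, z_range=(-0.45, 1.0))
    sensors = SensorArrayGeometry(
        channel_ids=tuple(f"MEG{i:03d}" for i in range(n_channels)),
        positions=sensor_radius * sensor_dirs,
        orientations=sensor_dirs,
    )
    return sensors, head


def _spectrum_power(s: np.ndarray) -> np.ndarray:
    """Time-domain variance produced by rFFT amplitude shaping ``s``.

    For x = irfft(W * s) with W the rFFT of unit-variance white noise,
    var(x) = (s_0^2 + 2 sum_mid s_k^2 + s_nyq^2) / n  (n even).
    """
    n = 2 * (s.shape[-1] - 1)
    w = np.full(s.shape[-1], 2.0)
    w[0] = 1.0
    w[-1] = 1.0
    return np.sum(w * s**2, axis=-1) / n


def _unit_rms_shapes(
    bands: tuple[preproc.BandSpec, ...], sampling_rate: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """rFFT amplitude shapes with unit output RMS: one per band, plus 1/f."""
    n_freq = n_samples // 2 + 1
    shapes = np.empty((len(bands), n_freq))
    for i, band in enumerate(bands):
        shapes[i] = preproc.zero_phase_band_response(band, sampling_rate, n_samples)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    pink = np.zeros(n_freq)
    pink[1:] = 1.0 / np.sqrt(freqs[1:])
    shapes = np.vstack([shapes, pink])
    return shapes / np.sqrt(_spectrum_power(shapes))[:, None]


def draw_subject_amplitudes(
    spec: CohortSpec,
    regions: tuple[str, ...],
    subject_group: str,
    subject_seed: int,
) -> pd.Series:
    """Per-subject (condition, band, region) amplitudes, drawn once.

    A log-normal multiplier with mean 1 and CV ``between_subject_cv`` is
    drawn per (band, region) and applied to the group's table means under
    both conditions; amplitudes are therefore positive whenever the mean
    is, and zero-mean cells stay exactly zero.
    """
    if subject_group not in GROUPS:
        raise ValueError(f"unknown group {subject_group!r}")
    regions = tuple(regions)
    table = spec.table_for(regions)
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed), 0]))
    cv = spec.between_subject_cv
    n_cells = len(BAND_NAMES) * len(regions)
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        mult = np.exp(
            rng.standard_normal(n_cells) * np.sqrt(sigma2) - sigma2 / 2
        )
    else:
        mult = np.ones(n_cells)
    cell_index = pd.MultiIndex.from_product(
        [BAND_NAMES, list(regions)], names=["band", "region"]
    )
    mult_series = pd.Series(mult, index=cell_index)
    parts = {}
    for cond in CONDITIONS:
        means = table.loc[(subject_group, cond)].reindex(cell_index)
        parts[cond] = means * mult_series
    out = pd.concat(parts, names=["condition"]).sort_index()
    out.name = "amplitude"
    return out


_COND_STREAM = {"EC": 1, "EO": 2}


def simulate_source_timecourses(
    spec: CohortSpec,
    geom: HeadModelGeometry,
    subject_group: str,
    condition: str,
    subject_seed: int,
    amplitudes: pd.Series | None = None,
) -> SourceActivityMatrix:
    """Band-structured Gaussian source activity for one subject x condition.

    Each vertex carries, summed over the five analysis bands, a
    band-limited Gaussian process with RMS equal to the region's drawn
    amplitude, plus a broadband 1/f floor of RMS
    ``spec.source_floor_rms``.  Band limiting uses the squared magnitude
    response of the same zero-phase Butterworth filters the analysis
    applies, so synthesis and analysis band edges and roll-offs agree
    exactly; the independent band processes are synthesized jointly as
    one Gaussian spectrum per vertex (equal in distribution to their
    sum).
    """
    if subject_group not in GROUPS:
        raise ValueError(f"unknown group {subject_group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if amplitudes is None:
        amplitudes = draw_subject_amplitudes(
            spec, geom.region_names, subject_group, subject_seed
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(subject_seed), _COND_STREAM[condition]])
    )
    n_vtx, n_samp = geom.n_vertices, spec.n_samples
    n_freq = n_samp // 2 + 1
    region_order = list(geom.region_names)
    bands = default_bands()
    shapes = _unit_rms_shapes(bands, spec.sampling_rate, n_samp)

    # (vertices x bands+floor) RMS targets.
    amps = np.empty((n_vtx, len(bands) + 1))
    for i, band in enumerate(bands):
        amps[:, i] = (
            amplitudes.loc[(condition, band.name)]
            .reindex(region_order)
            .to_numpy()[geom.vertex_region]
        )
    amps[:, -1] = spec.source_floor_rms

    # Combined per-vertex amplitude spectrum: independent Gaussian bands
    # sum to a Gaussian with root-sum-square spectrum.
    spectrum = np.sqrt((amps**2) @ (shapes**2))
    # rFFT of unit-variance white noise: complex N(0, n/2) bins, real
    # N(0, n) at DC and (n even) Nyquist.
    w = np.sqrt(n_samp / 2.0) * (
        rng.standard_normal((n_vtx, n_freq))
        + 1j * rng.standard_normal((n_vtx, n_freq))
    )
    w[:, 0] = np.sqrt(2.0) * w[:, 0].real
    if n_samp % 2 == 0:
        w[:, -1] = np.sqrt(2.0) * w[:, -1].real
    values = np.fft.irfft(w * spectrum, n=n_samp, axis=1)
    return SourceActivityMatrix(values=values, sampling_rate=spec.sampling_rate)


def project_to_sensors(
    src: SourceActivityMatrix,
    geom: HeadModelGeometry,
    sensors: SensorArrayGeometry,
    leadfield: LeadFieldMatrix,
) -> RawRecording:
    """Forward-project source activity: sensor data = L x sources (tesla)."""
    if leadfield.values.shape != (sensors.n_channels, geom.n_vertices):
        raise ValueError(
            f"lead field shape {leadfield.values.shape} does not match "
            f"{sensors.n_channels} sensors x {geom.n_vertices} vertices"
        )
    if src.values.shape[0] != geom.n_vertices:
        raise ValueError("source matrix vertex count does not match geometry")
    return RawRecording(
        values=leadfield.values @ src.values, sampling_rate=src.sampling_rate
    )


ARTIFACT_DURATION_S = 0.1


def add_noise_and_artifacts(
    rec: RawRecording,
    noise_sd: float,
    artifact_rate: float,
    artifact_amplitude: float,
    seed: int,
) -> tuple[RawRecording, list[ArtifactEvent]]:
    """Add white sensor noise and Poisson-timed boxcar artifacts.

    Artifacts are 100-ms constant-offset segments of the given amplitude
    (random sign) on a single random channel, with Poisson-distributed
    count at ``artifact_rate`` events/minute.  Returns the noisy recording
    and the event log.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    values = rec.values.copy()
    if noise_sd > 0:
        values += noise_sd * rng.standard_normal(values.shape)
    events: list[ArtifactEvent] = []
    if artifact_rate > 0 and artifact_amplitude != 0:
        n_events = rng.poisson(artifact_rate * rec.duration / 60.0)
        width = max(1, int(round(ARTIFACT_DURATION_S * rec.sampling_rate)))
        for _ in range(n_events):
            ch = int(rng.integers(rec.n_channels))
            onset = int(rng.integers(max(1, rec.n_samples - width)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[ch, onset : onset + width] += sign * artifact_amplitude
            events.append(
                ArtifactEvent(
                    channel=ch,
                    onset_sample=onset,
                    n_samples=width,
                    amplitude=sign * artifact_amplitude,
                )
            )
    return replace(rec, values=values), events


def _cohort_roster(
    spec: CohortSpec,
) -> tuple[list[str], list[str], np.ndarray]:
    groups = ["AD"] * spec.n_ad + ["NC"] * spec.n_nc
    ids = [f"AD{i + 1:02d}" for i in range(spec.n_ad)] + [
        f"NC{i + 1:02d}" for i in range(spec.n_nc)
    ]
    master = np.random.default_rng(spec.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=len(ids))
    return ids, groups, subject_seeds


def draw_cohort_truth(
    spec: CohortSpec, regions: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth amplitude draws for a whole cohort, no recordings.

    Returns (subjects, truth) exactly as :func:`generate_cohort` would
    store them; used for fast statistical calibration studies where the
    forward/inverse stages are not under test.
    """
    ids, groups, subject_seeds = _cohort_roster(spec)
    rows = []
    for sid, group, sseed in zip(ids, groups, subject_seeds):
        amp = draw_subject_amplitudes(spec, regions, group, sseed)
        t = amp.rename("amplitude").reset_index()
        t.insert(0, "subject_id", sid)
        t.insert(1, "group", group)
        rows.append(t)
    subjects = pd.DataFrame({"subject_id": ids, "group": groups})
    return subjects, pd.concat(rows, ignore_index=True)


@dataclass
class Cohort:
    """Simulated cohort: recordings plus ground truth for recovery tests."""

    spec: CohortSpec
    sensors: SensorArrayGeometry
    head: HeadModelGeometry
    leadfield: LeadFieldMatrix
    subjects: pd.DataFrame  # columns subject_id, group
    recordings: dict[tuple[str, str], RawRecording] = field(default_factory=dict)
    true_amplitudes: pd.DataFrame | None = None  # per subject x cond x band x region
    artifact_log: dict[tuple[str, str], list[ArtifactEvent]] = field(
        default_factory=dict
    )


def generate_cohort(
    spec: CohortSpec,
    sensors: SensorArrayGeometry | None = None,
    head: HeadModelGeometry | None = None,
    leadfield: LeadFieldMatrix | None = None,
    geometry_kwargs: dict | None = None,
) -> Cohort:
    """Simulate the full cohort: EC and EO recordings for every subject.

    Subject ids are AD01.., NC01..; all randomness derives from
    ``spec.seed``.  The drawn per-subject amplitudes are returned as the
    ground-truth table (rows: subject x condition x band, columns: regions).
    """
    from .sourceest import compute_lead_field

    if (sensors is None) != (head is None):
        raise ValueError("provide both sensors and head geometry or neither")
    if sensors is None:
        sensors, head = make_geometry(seed=spec.seed, **(geometry_kwargs or {}))
    if leadfield is None:
        leadfield = compute_lead_field(head, sensors)

    ids, groups, subject_seeds = _cohort_roster(spec)

    cohort = Cohort(
        spec=spec,
        sensors=sensors,
        head=head,
        leadfield=leadfield,
        subjects=pd.DataFrame({"subject_id": ids, "group": groups}),
    )
    truth_rows = []
    for sid, group, sseed in zip(ids, groups, subject_seeds):
        amplitudes = draw_subject_amplitudes(spec, head.region_names, group, sseed)
        for cond in CONDITIONS:
            src = simulate_source_timecourses(
                spec, head, group, cond, sseed, amplitudes=amplitudes
            )
            rec = project_to_sensors(src, head, sensors, leadfield)
            rec.subject_id, rec.condition = sid, cond
            rec, events = add_noise_and_artifacts(
                rec,
                spec.sensor_noise_sd,
                spec.artifact_rate,
                spec.artifact_amplitude,
                seed=int(sseed) + _COND_STREAM[cond] * 7919,
            )
            rec.subject_id, rec.condition = sid, cond
            cohort.recordings[(sid, cond)] = rec
            cohort.artifact_log[(sid, cond)] = events
        t = amplitudes.rename("amplitude").reset_index()
        t.insert(0, "subject_id", sid)
        t.insert(1, "group", group)
        truth_rows.append(t)
    cohort.true_amplitudes = pd.concat(truth_rows, ignore_index=True)
    return cohort
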