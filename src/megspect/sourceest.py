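"""Spherical-conductor forward model and regularized minimum-norm inverse.

The forward model is the closed-form magnetic field of a current dipole in
a homogeneous conducting sphere (Sarvas solution).  Two of its exact
properties anchor the test suite: a dipole at the sphere center, and any
radially oriented dipole, produce no external field.

The inverse is a depth-weighted, Tikhonov-regularized minimum-norm
operator with fixed source orientations along the vertex normals:

    K = W L' (L W L' + lambda^2 I)^{-1}

with diagonal weights W_v = ||L_v||^(-2 * depth_exponent) and
lambda^2 = trace(L W L') / (n_channels * snr^2).

Region-level "absolute power" is the time-averaged absolute value of the
estimated source current, averaged over the vertices of each region --
an amplitude in A*m, not a squared spectral density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .preproc import EpochSet

MU0_OVER_4PI = 1e-7  # T*m/A


@dataclass
class LeadFieldMatrix:
    """Linear map from unit dipole currents at vertices to sensor readings.

    ``values`` is (channels x vertices), tesla per (A*m).
    """

    values: np.ndarray
    n_channels: int = 0
    n_vertices: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("lead field must be 2-D (channels x vertices)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lead field contains non-finite entries")
        self.n_channels, self.n_vertices = self.values.shape


@dataclass
class InverseOperator:
    """Minimum-norm inverse ``values`` (vertices x channels), (A*m)/T."""

    values: np.ndarray
    lambda2: float
    weights: np.ndarray

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Map sensor data (channels x samples) to source estimates."""
        return self.values @ data


def dipole_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
    sphere_center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (tesla) of a current dipole in a conducting sphere.

    Closed-form Sarvas solution; positions in metres relative to any origin,
    ``sphere_center`` shifts them into the sphere frame.  ``sensor_pos`` may
    be (3,) or (n, 3); returns field vectors of matching shape.
    """
    center = np.zeros(3) if sphere_center is None else np.asarray(sphere_center, float)
    r0 = np.asarray(dipole_pos, float) - center
    q = np.asarray(dipole_moment, float)
    r = np.atleast_2d(np.asarray(sensor_pos, float) - center)

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("sensor coincides with dipole position")
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - r0_dot_r)
    grad_f = (
        (a**2 / rn + a_dot_r / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + a_dot_r / a)[:, None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0 - ((r @ q_x_r0))[:, None] * grad_f
    )
    if np.asarray(sensor_pos).ndim == 1:
        return b[0]
    return b


def compute_lead_field(geom, sensors) -> LeadFieldMatrix:
    """Lead field of unit dipoles along the vertex normals.

    Column v is the sensing-direction projection of the field of a unit
    (1 A*m) dipole at vertex v oriented along its normal.  Raises if any
    vertex lies on or outside the conductor sphere.
    """
    center = np.asarray(geom.sphere_center, float)
    verts = np.asarray(geom.vertices, float)
    radii = np.linalg.norm(verts - center, axis=1)
    if np.any(radii >= geom.sphere_radius):
        bad = int(np.argmax(radii))
        raise ValueError(
            f"vertex {bad} at radius {radii[bad]:.4g} m is not strictly "
            f"inside the sphere (radius {geom.sphere_radius:g} m)"
        )
    pos = np.asarray(sensors.positions, float)
    ori = np.asarray(sensors.orientations, float)
    cols = np.empty((pos.shape[0], verts.shape[0]))
    for v in range(verts.shape[0]):
        b = dipole_field(verts[v], geom.normals[v], pos, sphere_center=center)
        cols[:, v] = np.einsum("ij,ij->i", b, ori)
    return LeadFieldMatrix(values=cols)


def compute_inverse_operator(
    L: LeadFieldMatrix, snr: float = 3.0, depth_exponent: float = 0.5
) -> InverseOperator:
    """Depth-weighted Tikhonov-regularized minimum-norm inverse.

    ``snr`` sets the regularization through
    lambda^2 = trace(L W L')/(n_channels * snr^2); ``depth_exponent`` = 0
    disables depth weighting.  Numerically silent vertices (zero lead-field
    column, e.g. radial sources) receive zero weight and thus zero
    estimates.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    G = L.values
    col_norms = np.linalg.norm(G, axis=0)
    silent = col_norms <= 1e-12 * max(col_norms.max(), 1e-300)
    w = np.zeros_like(col_norms)
    w[~silent] = col_norms[~silent] ** (-2.0 * depth_exponent)
    GW = G * w[None, :]
    gram = GW @ G.T
    lam2 = np.trace(gram) / (L.n_channels * snr**2)
    reg = gram + lam2 * np.eye(L.n_channels)
    try:
        cho = linalg.cho_factor(reg)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "regularized Gram matrix is singular (rank-deficient lead field "
            "with lambda^2 = 0)"
        ) from exc
    # K = W L' (gram + lam2 I)^-1  computed via the Cholesky factor.
    K = linalg.cho_solve(cho, GW).T
    return InverseOperator(values=K, lambda2=float(lam2), weights=w)


def extract_region_power(
    epochs: EpochSet, inv: InverseOperator, geom
) -> pd.Series:
    """Mean absolute source amplitude per region for one band's epochs.

    Per vertex: the mean over all epochs and samples of the absolute value
    of the source estimate.  Per region: the unweighted mean over its
    member vertices.  Returns a Series indexed by region label, in A*m.
    """
    n_vertices = inv.values.shape[0]
    if len(geom.vertex_region) != n_vertices:
        raise ValueError("geometry and inverse operator vertex counts differ")
    abs_sum = np.zeros(n_vertices)
    n_samples_total = 0
    for e in range(epochs.n_epochs):
        est = inv.apply(epochs.epochs[e])
        abs_sum += np.abs(est).sum(axis=1)
        n_samples_total += est.shape[1]
    if n_samples_total == 0:
        raise ValueError("epoch set is empty")
    vertex_mean = abs_sum / n_samples_total
    labels = list(geom.region_names)
    values = np.empty(len(labels))
    for i in range(len(labels)):
        members = geom.vertex_region == i
        if not np.any(members):
            raise ValueError(f"region {labels[i]!r} has no vertices")
        values[i] = vertex_mean[members].mean()
    return pd.Series(values, index=pd.Index(labels, name="region"), name="power")
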