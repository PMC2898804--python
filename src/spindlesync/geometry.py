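"""Head, sensor, and source-space geometry.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) — an analytic stand-in for a subject-specific boundary-element model
that preserves the physics the downstream analysis depends on: the silence
of radially oriented dipoles in MEG, and signal cancellation between
opposed dipoles on a folded cortical surface.

Sensor layouts follow the whole-head convention of a 60-electrode EEG
montage plus a 306-channel MEG array (102 sites, each carrying one radial
magnetometer and two orthogonal tangential planar gradiometers).  The
cortical source space is a quasi-uniform sampling of a radially folded
sphere, so that neighbouring surface normals can oppose each other the way
they do across a sulcus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ChannelKind",
    "Modality",
    "SphericalHeadModel",
    "SensorChannel",
    "SensorArray",
    "SourceSpace",
    "build_sensor_array",
    "build_source_space",
]

#: default two-point baseline of a planar gradiometer, metres
GRADIOMETER_BASELINE = 0.0168


class ChannelKind(str, enum.Enum):
    EEG = "EEG"
    MAG = "MAG"
    GRAD1 = "GRAD1"
    GRAD2 = "GRAD2"


class Modality(str, enum.Enum):
    EEG = "EEG"
    MEG = "MEG"
    COMBINED = "combined"


@dataclass(frozen=True)
class SphericalHeadModel:
    """Three-shell concentric-sphere volume conductor.

    Parameters
    ----------
    center : (3,) array
        Sphere centre in head coordinates, metres.
    shell_radii : (3,) array
        Inner-skull, outer-skull and scalp radii, metres, strictly
        increasing.
    conductivities : (3,) array
        Brain, skull and scalp conductivities, S/m.
    legendre_order : int
        Truncation order of the Legendre series used for the EEG forward
        solution.  The default resolves superficial sources (dipole radius
        up to ~0.84 of the scalp radius) to a relative series tail below
        1e-6.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    shell_radii: tuple[float, float, float] = (0.080, 0.085, 0.092)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    legendre_order: int = 120

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        r = np.asarray(self.shell_radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("head center must be a 3-vector")
        if r.shape != (3,) or not np.all(np.diff(r) > 0):
            raise ValueError("shell_radii must be three strictly increasing radii")
        if c.shape != (3,) or not np.all(c > 0):
            raise ValueError("conductivities must be three positive values")
        if self.legendre_order < 20:
            raise ValueError("legendre_order must be >= 20")

    @property
    def inner_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.shell_radii[2])


@dataclass(frozen=True)
class SensorChannel:
    """One recording channel.

    ``orientation`` is the coil normal for EEG/magnetometer channels and
    the (tangential) derivative direction for planar gradiometers; the
    measured field component of a gradiometer is the radial one at its
    site.
    """

    name: str
    kind: ChannelKind
    position: np.ndarray
    orientation: np.ndarray
    baseline: float = 0.0
    unit: str = "V"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if not np.isclose(np.linalg.norm(self.orientation), 1.0, atol=1e-9):
            raise ValueError(f"channel {self.name}: orientation must be unit-norm")
        if self.kind in (ChannelKind.GRAD1, ChannelKind.GRAD2) and self.baseline <= 0:
            raise ValueError(f"channel {self.name}: gradiometer baseline must be > 0")


@dataclass
class SensorArray:
    channels: list[SensorChannel]
    modality: Modality

    def __post_init__(self) -> None:
        if self.modality == Modality.EEG and len(self.channels) != 60:
            raise ValueError("EEG array must have 60 channels")
        if self.modality == Modality.MEG and len(self.channels) != 306:
            raise ValueError("MEG array must have 306 channels (102 sites x 3)")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    @property
    def positions(self) -> np.ndarray:
        return np.array([ch.position for ch in self.channels])

    @property
    def orientations(self) -> np.ndarray:
        return np.array([ch.orientation for ch in self.channels])

    @property
    def kinds(self) -> list[ChannelKind]:
        return [ch.kind for ch in self.channels]


@dataclass
class SourceSpace:
    """Dipole sampling of a folded-sphere cortical surrogate.

    positions : (n, 3) metres; orientations : (n, 3) unit outward normals
    of the folded surface; hemisphere : (n,) labels 'L'/'R' by the sign of
    the x coordinate; nominal_spacing : median nearest-neighbour distance.
    """

    positions: np.ndarray
    orientations: np.ndarray
    hemisphere: np.ndarray
    nominal_spacing: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have the same shape")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit-norm")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


def _fibonacci_band(n: int, z_min: float, z_max: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical band z in [z_min, z_max].

    Fibonacci lattice in (z, azimuth), with a random azimuthal rotation so
    different seeds give distinct but equally uniform layouts.
    """
    i = np.arange(n) + 0.5
    z = z_min + (z_max - z_min) * i / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n) + rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangential directions perpendicular to ``normal``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    t2 /= np.linalg.norm(t2)
    return t1, t2


def build_sensor_array(
    modality: Modality | str,
    head: SphericalHeadModel,
    seed: int = 0,
    meg_offset: float = 0.025,
    gradiometer_baseline: float = GRADIOMETER_BASELINE,
) -> SensorArray:
    """Construct a quasi-uniform sensor layout on / around the head.

    EEG: 60 electrodes on the upper hemisphere of the scalp shell, radial
    orientations.  MEG: 102 sites on a sphere ``meg_offset`` outside the
    scalp covering the helmet region, each with one radial magnetometer
    and two orthogonal tangential planar gradiometers.
    """
    modality = Modality(modality)
    rng = np.random.default_rng(seed)
    if modality == Modality.EEG:
        dirs = _fibonacci_band(60, 0.0, 1.0, rng)
        channels = [
            SensorChannel(
                name=f"EEG{i + 1:03d}",
                kind=ChannelKind.EEG,
                position=head.center + head.scalp_radius * d,
                orientation=d,
                unit="V",
            )
            for i, d in enumerate(dirs)
        ]
        return SensorArray(channels, Modality.EEG)
    if modality == Modality.MEG:
        # helmet extends below the equator, down to z ~ -0.35
        dirs = _fibonacci_band(102, -0.35, 1.0, rng)
        radius = head.scalp_radius + meg_offset
        channels: list[SensorChannel] = []
        for i, d in enumerate(dirs):
            pos = head.center + radius * d
            t1, t2 = _tangent_basis(d)
            channels.append(
                SensorChannel(f"MEG{i + 1:03d}1", ChannelKind.MAG, pos, d, 0.0, "T")
            )
            channels.append(
                SensorChannel(
                    f"MEG{i + 1:03d}2", ChannelKind.GRAD1, pos, t1, gradiometer_baseline, "T/m"
                )
            )
            channels.append(
                SensorChannel(
                    f"MEG{i + 1:03d}3", ChannelKind.GRAD2, pos, t2, gradiometer_baseline, "T/m"
                )
            )
        return SensorArray(channels, Modality.MEG)
    raise ValueError(f"unknown modality: {modality!r}")


def _fold_field(points: np.ndarray, amplitude: float, wavenumber: int):
    """Radial fold pattern f and its angular gradients on unit vectors.

    r(theta, phi) = r0 * (1 + a * sin(w*theta) * cos(w*phi)).  Returns
    (f, df_dtheta, df_dphi_over_sin) evaluated at each point, the last
    already divided by sin(theta) (finite at the poles for integer w).
    """
    x, y, z = points.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    w = wavenumber
    f = np.sin(w * theta) * np.cos(w * phi)
    df_dtheta = w * np.cos(w * theta) * np.cos(w * phi)
    sin_theta = np.sin(theta)
    # sin(w*theta)/sin(theta) -> w as theta -> 0 or pi
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sin_theta > 1e-8, np.sin(w * theta) / np.where(sin_theta > 1e-8, sin_theta, 1.0), w * np.cos(w * theta) * 0 + w)
    df_dphi_over_sin = -w * ratio * np.sin(w * phi)
    return f, df_dtheta, df_dphi_over_sin, theta, phi


def build_source_space(
    n_per_hemisphere: int,
    fold_amplitude: float = 0.1,
    fold_wavenumber: int = 12,
    seed: int = 0,
    radius: float = 0.070,
) -> SourceSpace:
    """Sample ``2*n_per_hemisphere`` dipoles on a radially folded sphere.

    The surface is r(theta, phi) = radius * (1 + a*f(theta, phi)) with a
    smooth fold pattern f; dipole orientations are the outward normals of
    that surface, so neighbouring normals can oppose (emulating opposite
    sulcal walls).  ``fold_amplitude = 0`` gives a perfect sphere with
    purely radial orientations.
    """
    if n_per_hemisphere < 40:
        raise ValueError("n_per_hemisphere must be >= 40")
    if fold_amplitude >= 0.5:
        raise ValueError("fold_amplitude >= 0.5 risks self-intersection")
    if fold_amplitude < 0:
        raise ValueError("fold_amplitude must be >= 0")
    n = 2 * n_per_hemisphere
    rng = np.random.default_rng(seed)
    unit = _fibonacci_band(n, -1.0, 1.0, rng)
    f, df_dtheta, df_dphi_over_sin, theta, phi = _fold_field(
        unit, fold_amplitude, fold_wavenumber
    )
    r = radius * (1.0 + fold_amplitude * f)
    positions = unit * r[:, None]

    # outward normal of the implicit surface F(r,theta,phi) = r - R(theta,phi):
    # grad F = r_hat - (R_theta / r) theta_hat - (R_phi / (r sin theta)) phi_hat
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    r_hat = unit
    theta_hat = np.column_stack([ct * cp, ct * sp, -st])
    phi_hat = np.column_stack([-sp, cp, np.zeros_like(sp)])
    R_theta = radius * fold_amplitude * df_dtheta
    R_phi_over_sin = radius * fold_amplitude * df_dphi_over_sin
    grad = r_hat - (R_theta / r)[:, None] * theta_hat - (R_phi_over_sin / r)[:, None] * phi_hat
    orientations = grad / np.linalg.norm(grad, axis=1, keepdims=True)

    hemisphere = np.where(positions[:, 0] < 0, "L", "R")
    tree = cKDTree(positions)
    dists, _ = tree.query(positions, k=2)
    nominal_spacing = float(np.median(dists[:, 1]))
    return SourceSpace(positions, orientations, hemisphere, nominal_spacing)
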