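"""Analytic forward solutions and gain-matrix assembly.

EEG: potential of a current dipole inside three concentric conducting
spherical shells, by a truncated Legendre series.  The per-degree radial
transfer coefficients are obtained by solving the interface continuity
conditions (potential and radial current continuous, outer surface
insulating) as a small linear system per degree, so the same code covers
any conductivity profile; with equal conductivities it reduces to the
classical homogeneous-sphere coefficients (2n+1)/n.

MEG: magnetic field outside a spherically symmetric conductor by the
Sarvas closed form

    B(r) = (mu0 / 4 pi F^2) * (F Q x r0 - (Q x r0 . r) grad F)

with a = r - r0, F = a (r a + r^2 - r0.r).  Volume currents contribute
nothing for radial dipoles (radial silence).  Magnetometers read the field
component along their (radial) coil normal; planar gradiometers read a
two-point finite difference of the radial field component along their
tangential derivative direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    ChannelKind,
    Modality,
    SensorArray,
    SensorChannel,
    SourceSpace,
    SphericalHeadModel,
)

__all__ = [
    "GainMatrix",
    "eeg_forward",
    "meg_forward",
    "assemble_gain",
    "sarvas_field",
]

MU0_OVER_4PI = 1e-7


class ForwardError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# EEG: three-shell Legendre series
# ---------------------------------------------------------------------------

def _shell_coefficients(head: SphericalHeadModel, n_max: int) -> np.ndarray:
    """Surface-potential transfer coefficients v_n, n = 1..n_max.

    In scalp-radius units, the degree-n surface potential generated by the
    exterior-harmonic dipole source term ``S * r^-(n+1)`` in the innermost
    compartment (S = 1/(4 pi sigma_brain)) is ``v_n``; the physical scalp
    potential is sum_n b^(n-1) v_n B_n(geometry) / R_scalp^2 with b the
    scaled dipole radius.
    """
    s1, s2, s3 = head.conductivities
    rho1, rho2 = (
        head.shell_radii[0] / head.scalp_radius,
        head.shell_radii[1] / head.scalp_radius,
    )
    S = 1.0 / (4.0 * np.pi * s1)
    v = np.empty(n_max + 1)
    v[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: a1, a2, b2, a3, b3 (r^n and r^-(n+1) coefficients)
        p1, q1 = rho1**n, rho1 ** -(n + 1)
        p2, q2 = rho2**n, rho2 ** -(n + 1)
        A = np.array(
            [
                [p1, -p1, -q1, 0.0, 0.0],
                [s1 * n * p1, -s2 * n * p1, s2 * (n + 1) * q1, 0.0, 0.0],
                [0.0, p2, q2, -p2, -q2],
                [0.0, s2 * n * p2, -s2 * (n + 1) * q2, -s3 * n * p2, s3 * (n + 1) * q2],
                [0.0, 0.0, 0.0, n, -(n + 1)],
            ]
        )
        rhs = np.array(
            [-S * q1, S * s1 * (n + 1) * q1, 0.0, 0.0, 0.0]
        )
        sol = np.linalg.solve(A, rhs)
        v[n] = sol[3] + sol[4]  # a3 + b3 at rho = 1
    return v


def _eeg_potentials_raw(
    dipole_positions: np.ndarray,
    electrode_dirs: np.ndarray,
    head: SphericalHeadModel,
) -> np.ndarray:
    """Per-electrode potential kernels K such that V = K . m.

    Returns array (n_electrodes, n_dipoles, 3); not yet average-referenced.
    """
    R = head.scalp_radius
    n_max = head.legendre_order
    v = _shell_coefficients(head, n_max)

    pos = (np.atleast_2d(dipole_positions) - head.center) / R  # scaled
    b = np.linalg.norm(pos, axis=1)
    if np.any(b * R >= head.inner_radius):
        raise ForwardError("dipole outside the inner shell")
    deep = b < 1e-12
    r0_hat = np.where(deep[:, None], np.array([0.0, 0.0, 1.0]), pos / np.where(deep, 1.0, b)[:, None])

    e_hat = electrode_dirs  # (m, 3) unit vectors
    u = np.clip(e_hat @ r0_hat.T, -1.0, 1.0)  # (m, d)

    # Legendre recurrences: P_n and P'_n via P'_n = u P'_{n-1} + n P_{n-1}
    P_prev = np.ones_like(u)      # P_0
    P_cur = u.copy()              # P_1
    dP_prev = np.zeros_like(u)    # P'_0
    dP_cur = np.ones_like(u)      # P'_1
    K = np.zeros(u.shape + (3,))
    bpow = np.ones_like(b)        # b^(n-1) at n = 1
    tail = np.zeros(u.shape)
    for n in range(1, n_max + 1):
        if n > 1:
            P_next = ((2 * n - 1) * u * P_cur - (n - 1) * P_prev) / n
            dP_next = u * dP_cur + n * P_cur
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next
            bpow = bpow * b
        # vector kernel: n P_n r0_hat + P'_n (e_hat - u r0_hat)
        w = v[n] * bpow  # (d,)
        term = (
            (n * P_cur * w)[:, :, None] * r0_hat[None, :, :]
            + (dP_cur * w)[:, :, None]
            * (e_hat[:, None, :] - u[:, :, None] * r0_hat[None, :, :])
        )
        K += term
        tail = np.abs(term).sum(axis=2)
    scale = np.abs(K).sum(axis=2)
    bad = tail > 1e-6 * np.maximum(scale, 1e-300)
    if np.any(bad & (scale > 0)):
        raise ForwardError(
            "Legendre series not converged at order "
            f"{n_max}: increase legendre_order (max relative tail "
            f"{float(np.max(tail / np.maximum(scale, 1e-300))):.2e})"
        )
    return K / R**2


def eeg_forward(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    head: SphericalHeadModel,
    array: SensorArray,
) -> np.ndarray:
    """Average-referenced scalp potentials (V) of one dipole (A*m)."""
    if array.modality != Modality.EEG:
        raise ValueError("eeg_forward requires an EEG sensor array")
    e_dirs = (array.positions - head.center) / head.scalp_radius
    K = _eeg_potentials_raw(np.atleast_2d(dipole_position), e_dirs, head)
    V = K[:, 0, :] @ np.asarray(dipole_moment, dtype=float)
    return V - V.mean()


# ---------------------------------------------------------------------------
# MEG: Sarvas closed form
# ---------------------------------------------------------------------------

def sarvas_field(
    dipole_positions: np.ndarray,
    field_points: np.ndarray,
    center: np.ndarray,
) -> np.ndarray:
    """Magnetic field transfer tensors outside a spherical conductor.

    Returns T with shape (n_points, n_dipoles, 3, 3) such that the field
    at point p from a dipole Q at position d is ``T[p, d] @ Q`` (tesla per
    A*m).  Positions are absolute; ``center`` is the conductor centre.
    """
    r = np.atleast_2d(field_points) - center  # (m, 3)
    r0 = np.atleast_2d(dipole_positions) - center  # (d, 3)
    a = r[:, None, :] - r0[None, :, :]  # (m, d, 3)
    an = np.linalg.norm(a, axis=2)
    rn = np.linalg.norm(r, axis=1)[:, None]
    if np.any(an < 1e-12):
        raise ForwardError("field point coincides with a dipole")
    adotr = np.einsum("mdk,mk->md", a, r)
    F = an * (rn * an + rn**2 - np.einsum("dk,mk->md", r0, r))
    coef_r = an**2 / rn + adotr / an + 2.0 * an + 2.0 * rn
    coef_r0 = an + 2.0 * rn + adotr / an
    gradF = coef_r[:, :, None] * r[:, None, :] - coef_r0[:, :, None] * r0[None, :, :]
    # (Q x r0) = -skew(r0) @ Q ; build A[d] = -skew(r0_d)
    d = r0.shape[0]
    A = np.zeros((d, 3, 3))
    A[:, 0, 1], A[:, 0, 2] = r0[:, 2], -r0[:, 1]
    A[:, 1, 0], A[:, 1, 2] = -r0[:, 2], r0[:, 0]
    A[:, 2, 0], A[:, 2, 1] = r0[:, 1], -r0[:, 0]
    # c[m, d, :] = A[d].T @ r[m]  so that (Q x r0).r = c . Q
    c = np.einsum("dkj,mk->mdj", A, r)
    T = (
        F[:, :, None, None] * A[None, :, :, :]
        - gradF[:, :, :, None] * c[:, :, None, :]
    ) * (MU0_OVER_4PI / F[:, :, None, None] ** 2)
    return T


def _check_meg_geometry(
    dipole_position: np.ndarray, channel: SensorChannel, head: SphericalHeadModel
) -> None:
    if np.linalg.norm(np.asarray(dipole_position) - head.center) >= head.inner_radius:
        raise ForwardError("dipole outside the inner shell")
    if np.linalg.norm(channel.position - head.center) <= head.scalp_radius:
        raise ForwardError(f"sensor {channel.name} inside the scalp shell")


def meg_forward(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    head: SphericalHeadModel,
    channel: SensorChannel,
) -> float:
    """Reading of one MEG channel (T or T/m) for one dipole (A*m)."""
    if channel.kind == ChannelKind.EEG:
        raise ValueError("meg_forward requires a MAG or GRAD channel")
    _check_meg_geometry(dipole_position, channel, head)
    Q = np.asarray(dipole_moment, dtype=float)
    if channel.kind == ChannelKind.MAG:
        T = sarvas_field(dipole_position, channel.position, head.center)
        return float(channel.orientation @ (T[0, 0] @ Q))
    # planar gradiometer: finite difference of the radial field component
    radial = channel.position - head.center
    radial = radial / np.linalg.norm(radial)
    step = 0.5 * channel.baseline * channel.orientation
    pts = np.array([channel.position + step, channel.position - step])
    T = sarvas_field(dipole_position, pts, head.center)
    b_plus = radial @ (T[0, 0] @ Q)
    b_minus = radial @ (T[1, 0] @ Q)
    return float((b_plus - b_minus) / channel.baseline)


# ---------------------------------------------------------------------------
# Gain assembly
# ---------------------------------------------------------------------------

@dataclass
class GainMatrix:
    """Forward operator: channels x (3 * n_sources).

    Column triplet ``3j..3j+2`` holds the sensor patterns of unit dipoles
    along the three global axes at source j.  EEG gains are
    average-referenced (each source's pattern sums to zero over channels).
    """

    values: np.ndarray
    channel_order: list[str]
    source_order: np.ndarray
    modality: Modality

    @property
    def n_sources(self) -> int:
        return self.values.shape[1] // 3

    def along_normals(self, source_space: SourceSpace) -> np.ndarray:
        """Collapse to channels x n_sources for dipoles along local normals."""
        G = self.values.reshape(self.values.shape[0], -1, 3)
        return np.einsum("cjk,jk->cj", G, source_space.orientations)


def assemble_gain(
    source_space: SourceSpace,
    array: SensorArray,
    head: SphericalHeadModel,
) -> GainMatrix:
    """Forward gain for every source (3 orthogonal unit dipoles each)."""
    pos = source_space.positions
    radii = np.linalg.norm(pos - head.center, axis=1)
    if np.any(radii >= head.inner_radius):
        bad = int(np.argmax(radii))
        raise ForwardError(f"source {bad} outside the inner shell (r={radii[bad]:.4f} m)")
    n = source_space.n_sources

    if array.modality == Modality.EEG:
        e_dirs = (array.positions - head.center) / head.scalp_radius
        K = _eeg_potentials_raw(pos, e_dirs, head)  # (ch, n, 3)
        G = K.reshape(len(array), 3 * n)
        G = G - G.mean(axis=0, keepdims=True)  # average reference
        return GainMatrix(G, array.names, np.arange(n), Modality.EEG)

    if array.modality == Modality.MEG:
        # evaluation points: one per magnetometer, two per gradiometer
        points: list[np.ndarray] = []
        for ch in array.channels:
            if ch.kind == ChannelKind.MAG:
                points.append(ch.position)
            else:
                step = 0.5 * ch.baseline * ch.orientation
                points.append(ch.position + step)
                points.append(ch.position - step)
        pts = np.array(points)
        if np.any(np.linalg.norm(pts - head.center, axis=1) <= head.scalp_radius):
            raise ForwardError("MEG sensor inside the scalp shell")
        T = sarvas_field(pos, pts, head.center)  # (pts, n, 3, 3)
        G = np.empty((len(array), 3 * n))
        ip = 0
        for ic, ch in enumerate(array.channels):
            if ch.kind == ChannelKind.MAG:
                row = np.einsum("k,dkj->dj", ch.orientation, T[ip])
                ip += 1
            else:
                radial = ch.position - head.center
                radial = radial / np.linalg.norm(radial)
                row = (
                    np.einsum("k,dkj->dj", radial, T[ip])
                    - np.einsum("k,dkj->dj", radial, T[ip + 1])
                ) / ch.baseline
                ip += 2
            G[ic] = row.reshape(-1)
        return GainMatrix(G, array.names, np.arange(n), Modality.MEG)

    raise ValueError(f"cannot assemble gain for modality {array.modality!r}")
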