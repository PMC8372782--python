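"""Exact piecewise-constant propagator and Euler-angle extraction.

A shaped pulse is approximated by a train of short rectangular segments.
Each segment generates an SU(2) rotation about its tilted effective field;
the time-ordered product (right to left) gives the net propagator

    U = exp(-i gamma Iz) exp(-i beta Ix) exp(-i alpha Iz),

from whose matrix elements the Euler angles (alpha, beta, gamma) are
recovered.  This module is the numerical oracle against which every
homotopy-series approximation in :mod:`hampulse.ham_core` is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveforms import SegmentParams, Waveform

__all__ = [
    "EulerAngles",
    "segment_propagator",
    "propagate",
    "euler_angles_exact",
    "euler_profile",
    "unitary_from_euler",
    "euler_from_unitary",
]

#: |U11| below which the extraction switches to the U21 phase reference.
_PHASE_TIE_BREAK = 1e-12
#: sin(beta/2) / cos(beta/2) below which the (alpha, gamma) split is gauge.
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class EulerAngles:
    """Net-rotation Euler angles of a pulse (z-, x-, z-rotation convention).

    ``beta`` lies in [0, pi]; ``alpha`` and ``gamma`` are principal values
    in (-pi, pi].  At the degenerate orientations beta = 0 (only the sum
    alpha + gamma defined) and beta = pi (only alpha - gamma defined) the
    defined combination is stored in ``alpha`` with ``gamma = 0`` as gauge,
    and ``degenerate`` names the case.
    """

    alpha: float
    beta: float
    gamma: float
    degenerate: str | None = None

    @property
    def chi_plus(self) -> float:
        return 0.5 * (self.alpha + self.gamma)

    @property
    def chi_minus(self) -> float:
        return 0.5 * (self.alpha - self.gamma)


def segment_propagator(p: SegmentParams) -> np.ndarray:
    """SU(2) propagator of one rectangular segment.

    Built from ``kappa = cos(omega_e dt/2) + i cos(theta) sin(omega_e dt/2)``
    and ``eta = exp(i phi) sin(theta) sin(omega_e dt/2)`` as
    ``[[kappa*, -i eta*], [-i eta, kappa]]``; |kappa|^2 + |eta|^2 = 1.
    """
    half = 0.5 * p.omega_e * p.dt
    c, s = np.cos(half), np.sin(half)
    theta = p.theta
    kappa = c + 1j * np.cos(theta) * s
    eta = np.exp(1j * p.phase) * np.sin(theta) * s
    return np.array([[np.conj(kappa), -1j * np.conj(eta)],
                     [-1j * eta, kappa]])


def _segment_arrays(w: Waveform, offset: float) -> tuple[np.ndarray, ...]:
    """Midpoint-averaged segment parameters for the K-1 segments."""
    ox = 0.5 * (w.omega_x[:-1] + w.omega_x[1:])
    oy = 0.5 * (w.omega_y[:-1] + w.omega_y[1:])
    om = 0.5 * (w.offset_law[:-1] + w.offset_law[1:]) + offset
    w1 = np.hypot(ox, oy)
    phase = np.arctan2(oy, ox)
    return w1, phase, om


def _su2_product(w: Waveform, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Entries (U11, U21) of the time-ordered product, vectorized over offsets.

    Each segment matrix has the form [[a, b], [-conj(b), conj(a)]] with
    a = kappa*, b = -i eta*; only two complex numbers per offset are carried
    through the product.
    """
    dt = w.dt
    w1, phase, law = _segment_arrays(w, 0.0)
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    u11 = np.ones(offsets.size, dtype=complex)
    u21 = np.zeros(offsets.size, dtype=complex)
    for k in range(w1.size):
        om = law[k] + offsets
        we = np.hypot(w1[k], om)
        half = 0.5 * we * dt
        c, s = np.cos(half), np.sin(half)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.where(we > 0.0, om / np.where(we > 0.0, we, 1.0), 0.0)
            sin_t = np.where(we > 0.0, w1[k] / np.where(we > 0.0, we, 1.0), 0.0)
        kappa = c + 1j * cos_t * s
        eta = np.exp(1j * phase[k]) * sin_t * s
        a = np.conj(kappa)
        b = -1j * np.conj(eta)
        # left-multiply the accumulated (u11, u21) column by the new segment
        u11, u21 = a * u11 + b * u21, -np.conj(b) * u11 + np.conj(a) * u21
    return u11, u21


def propagate(w: Waveform, offset: float = 0.0) -> np.ndarray:
    """Net 2x2 propagator of the full waveform at one constant offset."""
    u11, u21 = _su2_product(w, np.array([offset]))
    a, c = u11[0], u21[0]
    return np.array([[a, -np.conj(c)], [c, np.conj(a)]])


def _angles_from_entries(u11: complex, u21: complex) -> EulerAngles:
    beta = 2.0 * np.arctan2(np.abs(u21), np.abs(u11))
    half = 0.5 * beta
    if np.sin(half) < _DEGENERATE_TOL:
        # beta ~ 0: only chi_plus = -(arg U11) is defined -> alpha + gamma
        return EulerAngles(_wrap(-2.0 * np.angle(u11)), beta, 0.0, degenerate="beta=0")
    if np.cos(half) < _DEGENERATE_TOL:
        # beta ~ pi: only chi_minus is defined -> alpha - gamma
        return EulerAngles(_wrap(-2.0 * (np.angle(u21) + 0.5 * np.pi)), beta, 0.0,
                           degenerate="beta=pi")
    if np.abs(u11) < _PHASE_TIE_BREAK:
        chi_minus = -(np.angle(u21) + 0.5 * np.pi)
        chi_plus = 0.0
    else:
        chi_plus = -np.angle(u11)
        chi_minus = -(np.angle(u21) + 0.5 * np.pi)
    return EulerAngles(_wrap(chi_plus + chi_minus), beta, _wrap(chi_plus - chi_minus))


def _wrap(angle: float | np.ndarray):
    """Principal value in (-pi, pi]."""
    return -np.remainder(-np.asarray(angle) + np.pi, 2.0 * np.pi) + np.pi


def euler_angles_exact(w: Waveform, offset: float = 0.0) -> EulerAngles:
    """Euler angles of the exact segment-product propagator."""
    u11, u21 = _su2_product(w, np.array([offset]))
    return _angles_from_entries(complex(u11[0]), complex(u21[0]))


def euler_profile(w: Waveform, offsets: np.ndarray, *, unwrap: bool = False) -> dict:
    """Exact Euler angles over an offset grid (rad/s).

    Returns arrays ``alpha``, ``beta``, ``gamma`` plus a boolean
    ``degenerate`` mask.  With ``unwrap=True``, alpha and gamma are made
    continuous across the sweep instead of principal-valued.
    """
    u11, u21 = _su2_product(w, offsets)
    angles = [_angles_from_entries(complex(a), complex(c)) for a, c in zip(u11, u21)]
    alpha = np.array([a.alpha for a in angles])
    beta = np.array([a.beta for a in angles])
    gamma = np.array([a.gamma for a in angles])
    if unwrap:
        alpha = np.unwrap(alpha)
        gamma = np.unwrap(gamma)
    return {"alpha": alpha, "beta": beta, "gamma": gamma,
            "degenerate": np.array([a.degenerate is not None for a in angles])}


def unitary_from_euler(ang: EulerAngles) -> np.ndarray:
    """Reconstruct U from (alpha, beta, gamma)."""
    cp, cm = ang.chi_plus, ang.chi_minus
    c, s = np.cos(0.5 * ang.beta), np.sin(0.5 * ang.beta)
    return np.array([[np.exp(-1j * cp) * c, -1j * np.exp(1j * cm) * s],
                     [-1j * np.exp(-1j * cm) * s, np.exp(1j * cp) * c]])


def euler_from_unitary(u: np.ndarray) -> EulerAngles:
    """Euler angles of an arbitrary SU(2) matrix (up to global phase)."""
    det = np.linalg.det(u)
    u = u / np.sqrt(det)
    return _angles_from_entries(complex(u[0, 0]), complex(u[1, 0]))
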