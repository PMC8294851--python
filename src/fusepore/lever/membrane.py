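"""Axisymmetric fusion-pore shapes under Helfrich energetics.

The fusion pore connects a nanodisc membrane (edge held by the scaffold
ring at radius ``disc_radius``, height ``h`` above the cell membrane) to
the flat cell membrane, through a waist of radius ``r``.  The
energy-minimizing profile for a given (r, h) is found variationally: the
tangent angle along the arc-length-parameterized meridian is expanded in
a sine series on two segments meeting at the waist, and the Helfrich
energy

    E = integral (kappa/2) (2H - c0)^2 dA  +  gamma * (excess area)

is minimized by SLSQP collocation subject to the waist-radius and
height constraints.  Heights are midplane-to-midplane; the profile ends
with zero slope where it joins the flat cell membrane, taken as a
remote location (the endpoint radius is free, so the result is exactly
insensitive to pushing the nominal remote boundary further out).

Geometry conventions: the meridian runs from the disc edge
(x = disc_radius, z = h) inward and downward through the waist
(x = r, vertical tangent) and back out to the flat membrane (z = 0).
With phi the turning angle (0 at a clamped disc edge, pi/2 at the
waist, pi at the flat end), dx/ds = -cos(phi), dz/ds = -sin(phi) and
2H = dphi/ds - sin(phi)/x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MembraneParams",
    "ScaffoldParams",
    "PoreShape",
    "GeometryError",
    "solve_shape",
]


class GeometryError(ValueError):
    """Raised when no smooth profile can satisfy the requested geometry."""


@dataclass(frozen=True)
class MembraneParams:
    """Helfrich membrane parameters.

    kappa: bending modulus (kT); gamma: tension (kT/nm^2);
    spontaneous_curvature: c0 (1/nm); remote_boundary_radius: maximum
    radial extent allowed for the profile before it is considered to
    have joined the flat cell membrane (nm).
    """

    kappa: float = 10.0
    gamma: float = 10.0 / 169.0  # kappa/lambda^2 with lambda = 13 nm
    spontaneous_curvature: float = 0.0
    remote_boundary_radius: float = 50.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("bending modulus kappa must be positive")
        if self.gamma < 0:
            raise ValueError("membrane tension gamma must be non-negative")


@dataclass(frozen=True)
class ScaffoldParams:
    """ApoE nanodisc scaffold: the ring holds the disc edge at
    ``disc_radius``; ``edge_condition`` is 'clamped_ring' (membrane meets
    the ring flat) or 'elastic_ring' (a torsional stiffness
    ``ring_stretch_modulus`` per unit ring length penalizes the meeting
    angle; 0 recovers a freely hinged edge)."""

    disc_radius: float = 12.5
    edge_condition: str = "clamped_ring"
    ring_stretch_modulus: float = 0.0  # kT/nm per rad^2, elastic_ring only

    def __post_init__(self) -> None:
        if self.disc_radius <= 0:
            raise ValueError("disc_radius must be positive")
        if self.edge_condition not in ("clamped_ring", "elastic_ring"):
            raise ValueError("edge_condition must be clamped_ring or elastic_ring")


@dataclass
class PoreShape:
    """Energy-minimizing axisymmetric profile for one (r, h).

    ``x``/``z`` are the meridian coordinates (nm) sampled along arc
    length ``s``; ``phi`` is the turning angle.  ``waist_index`` marks
    the waist sample.  Energies in kT.
    """

    r: float
    h: float
    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    waist_index: int
    energy: float
    bending_energy: float
    tension_energy: float
    converged: bool
    message: str = ""
    opt_vector: np.ndarray | None = None  # solver unknowns, for warm starts

    def surfaces(self):
        """(x_upper, z_upper, x_lower, z_lower): disc-side and cell-side
        sheets split at the waist, each ordered by increasing radius."""
        i = self.waist_index
        xu, zu = self.x[: i + 1][::-1], self.z[: i + 1][::-1]
        xl, zl = self.x[i:], self.z[i:]
        return xu, zu, xl, zl


_NQ = 41  # quadrature points per segment (Simpson)


def _simpson_w(n: int) -> np.ndarray:
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0


def _segment_arrays(phi0, phi1, coeffs, tt, sinbasis):
    """Angle profile on one segment: linear ramp + sine series."""
    return phi0 + (phi1 - phi0) * tt + sinbasis @ coeffs


class _ShapeProblem:
    """Ritz collocation problem for one (r, h)."""

    def __init__(self, r, h, mem: MembraneParams, scaf: ScaffoldParams, m=5, nq=_NQ):
        self.r, self.h = float(r), float(h)
        self.mem, self.scaf = mem, scaf
        self.m = m
        self.nq = nq
        self.tt = np.linspace(0.0, 1.0, nq)
        self.w = _simpson_w(nq) * (1.0 / (nq - 1))
        self.sinbasis = np.sin(np.pi * np.outer(self.tt, np.arange(1, m + 1)))
        self.hinged = scaf.edge_condition == "elastic_ring"

    # unknown vector: [a_1..a_m, b_1..b_m, L1, L2, (phi_edge if hinged)]
    def unpack(self, u):
        m = self.m
        a = u[:m]
        b = u[m : 2 * m]
        L1, L2 = u[2 * m], u[2 * m + 1]
        phi_edge = u[2 * m + 2] if self.hinged else 0.0
        return a, b, L1, L2, phi_edge

    def profile(self, u):
        a, b, L1, L2, phi_edge = self.unpack(u)
        tt, sb = self.tt, self.sinbasis
        phi1 = _segment_arrays(phi_edge, np.pi / 2, a, tt, sb)
        phi2 = _segment_arrays(np.pi / 2, np.pi, b, tt, sb)
        # derivative of the sine series
        k = np.arange(1, self.m + 1)
        cosbasis = np.cos(np.pi * np.outer(tt, k)) * (np.pi * k)
        dphi1 = (np.pi / 2 - phi_edge) + cosbasis @ a
        dphi2 = (np.pi / 2) + cosbasis @ b
        # integrate x, z along each segment (cumulative Simpson via trapezoid)
        x1 = self.scaf.disc_radius - L1 * _cumtrap(np.cos(phi1), tt)
        z1 = self.h - L1 * _cumtrap(np.sin(phi1), tt)
        x2 = x1[-1] - L2 * _cumtrap(np.cos(phi2), tt)
        z2 = z1[-1] - L2 * _cumtrap(np.sin(phi2), tt)
        return (phi1, dphi1, x1, z1, L1), (phi2, dphi2, x2, z2, L2)

    def energy(self, u):
        seg1, seg2 = self.profile(u)
        e = 0.0
        pen = 0.0
        for phi, dphi, x, z, L in (seg1, seg2):
            xs = np.maximum(x, 1e-3)
            two_h = dphi / L - np.sin(phi) / xs
            dA = 2.0 * np.pi * xs * L
            integrand = (
                0.5 * self.mem.kappa * (two_h - self.mem.spontaneous_curvature) ** 2
                + self.mem.gamma * (1.0 - np.abs(np.cos(phi)))
            ) * dA
            e += float(self.w @ integrand)
            # keep x positive, inside the remote boundary, and phi within
            # its bracket (soft barriers)
            pen += 1e4 * float(self.w @ np.square(np.minimum(x - 0.5 * self.r, 0.0)))
            pen += 1e3 * float(
                self.w @ np.square(np.maximum(x - self.mem.remote_boundary_radius, 0.0))
            )
        phi1 = seg1[0]
        phi2 = seg2[0]
        pen += 1e3 * float(np.sum(np.square(np.minimum(phi1 + 0.3, 0.0))))
        pen += 1e3 * float(np.sum(np.square(np.maximum(phi1 - np.pi / 2 - 0.3, 0.0))))
        pen += 1e3 * float(np.sum(np.square(np.minimum(phi2 - np.pi / 2 + 0.3, 0.0))))
        pen += 1e3 * float(np.sum(np.square(np.maximum(phi2 - np.pi - 0.3, 0.0))))
        # the profile stays between the cell plane and the disc level
        z1, z2 = seg1[3], seg2[3]
        pen += 1e4 * float(np.sum(np.square(np.minimum(z2 + 0.05, 0.0))))
        pen += 1e4 * float(np.sum(np.square(np.minimum(z1 + 0.05, 0.0))))
        pen += 1e4 * float(np.sum(np.square(np.maximum(z1 - self.h - 0.5, 0.0))))
        if self.hinged and self.scaf.ring_stretch_modulus > 0:
            phi_edge = self.unpack(u)[4]
            e += (
                0.5
                * self.scaf.ring_stretch_modulus
                * (2 * np.pi * self.scaf.disc_radius)
                * phi_edge**2
            )
        return e + pen

    def constraints(self, u):
        seg1, seg2 = self.profile(u)
        x_w = seg1[2][-1]
        z_end = seg2[3][-1]
        return np.array([x_w - self.r, z_end])

    def component_energies(self, u) -> tuple[float, float]:
        """(bending, tension) energies of the profile, no penalties."""
        e_bend = e_tens = 0.0
        for phi, dphi, x, z, L in self.profile(u):
            xs = np.maximum(x, 1e-3)
            two_h = dphi / L - np.sin(phi) / xs
            dA = 2.0 * np.pi * xs * L
            e_bend += float(
                self.w
                @ (
                    0.5
                    * self.mem.kappa
                    * (two_h - self.mem.spontaneous_curvature) ** 2
                    * dA
                )
            )
            e_tens += float(
                self.w @ (self.mem.gamma * (1.0 - np.abs(np.cos(phi))) * dA)
            )
        return e_bend, e_tens

    def initial_guess(self):
        """Flat-disc-then-quarter-bend profile, projected onto the sine
        basis.  The disc stays flat from the scaffold edge, turns down
        over a bend of radius ~h/2 into the waist, and the cell-side
        sheet mirrors it before flattening out."""
        m = self.m
        c1 = max(min(0.5 * self.h, 0.45 * (self.scaf.disc_radius - self.r)), 0.3)
        flat1 = max(self.scaf.disc_radius - self.r - c1, 0.1)
        L1 = flat1 + 0.5 * np.pi * c1
        t0 = flat1 / L1
        c2 = max(self.h - c1, 0.3)
        bend2 = 0.5 * np.pi * c2
        L2 = bend2 + 8.0
        t1 = bend2 / L2
        tt = self.tt
        phi1_t = np.where(tt < t0, 0.0, (np.pi / 2) * (tt - t0) / max(1 - t0, 1e-6))
        phi2_t = np.pi / 2 + (np.pi / 2) * np.minimum(tt / max(t1, 1e-6), 1.0)
        u0 = np.zeros(2 * m + 2 + (1 if self.hinged else 0))
        # least-squares projection of the target onto the sine corrections
        resid1 = phi1_t - (np.pi / 2) * tt
        resid2 = phi2_t - (np.pi / 2 + (np.pi / 2) * tt)
        u0[:m], *_ = np.linalg.lstsq(self.sinbasis, resid1, rcond=None)
        u0[m : 2 * m], *_ = np.linalg.lstsq(self.sinbasis, resid2, rcond=None)
        u0[2 * m] = L1
        u0[2 * m + 1] = L2
        return u0


def _cumtrap(y, t):
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t), out=out[1:])
    return out


def solve_shape(
    r: float,
    h: float,
    mem: MembraneParams = MembraneParams(),
    scaf: ScaffoldParams = ScaffoldParams(),
    m: int = 5,
    nq: int = _NQ,
    x0: np.ndarray | None = None,
    maxiter: int = 200,
) -> PoreShape:
    """Minimum-energy axisymmetric fusion-pore profile for waist radius
    ``r`` and membrane separation ``h`` (both nm).

    Raises :class:`GeometryError` for infeasible requests; solver
    non-convergence is returned as a flagged (``converged=False``)
    result with the optimizer message.
    """
    if r <= 0:
        raise GeometryError("waist radius must be positive")
    if h <= 0:
        raise GeometryError("membrane separation must be positive")
    if r >= scaf.disc_radius - 0.5:
        raise GeometryError(
            f"waist radius {r} does not fit inside the scaffold disc "
            f"(radius {scaf.disc_radius})"
        )
    prob = _ShapeProblem(r, h, mem, scaf, m=m, nq=nq)
    u0 = prob.initial_guess() if x0 is None else np.asarray(x0, dtype=float)
    # generous but finite arc lengths: pathological long-skirt local
    # minima are excluded outright
    l1_max = 1.5 * (scaf.disc_radius - r) + 2.0 * h + 20.0
    l2_max = 2.0 * h + 0.5 * mem.remote_boundary_radius + 40.0
    bounds = [(-2.0, 2.0)] * (2 * m) + [(0.5, l1_max), (0.5, l2_max)]
    if prob.hinged:
        bounds += [(-1.2, 1.2)]
    u0 = np.clip(u0, [b[0] for b in bounds], [b[1] for b in bounds])

    def _attempt(start):
        return minimize(
            prob.energy,
            start,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": prob.constraints}],
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-8},
        )

    def _sane(result) -> bool:
        # a legitimate profile has a dimensionless bending integral of
        # order one to ten; hundreds signal a curled-up local minimum
        return prob.component_energies(result.x)[0] / mem.kappa < 30.0

    res = _attempt(u0)
    if (not res.success) or not _sane(res):
        # multi-start fallback: rescaled arc-length guesses escape the
        # curled local minima that occasionally trap small waists
        candidates = [res] if res.success and _sane(res) else []
        base = prob.initial_guess()
        for f1, f2 in ((0.6, 0.6), (1.5, 1.5), (1.0, 2.0)):
            alt = base.copy()
            alt[2 * m] = np.clip(base[2 * m] * f1, 0.5, l1_max)
            alt[2 * m + 1] = np.clip(base[2 * m + 1] * f2, 0.5, l2_max)
            trial = _attempt(alt)
            if trial.success and _sane(trial):
                candidates.append(trial)
        if candidates:
            res = min(candidates, key=lambda t: prob.energy(t.x))
    seg1, seg2 = prob.profile(res.x)
    (phi1, dphi1, x1, z1, L1), (phi2, dphi2, x2, z2, L2) = seg1, seg2
    s1 = prob.tt * L1
    s2 = L1 + prob.tt * L2
    s = np.r_[s1, s2[1:]]
    x = np.r_[x1, x2[1:]]
    z = np.r_[z1, z2[1:]]
    phi = np.r_[phi1, phi2[1:]]
    e_bend, e_tens = prob.component_energies(res.x)
    constraint_ok = bool(np.all(np.abs(prob.constraints(res.x)) < 1e-3 * max(1.0, h)))
    converged = (
        bool(res.success or (res.status == 9 and constraint_ok))
        and constraint_ok
        and _sane(res)
    )
    if np.any(x[5:-5] > mem.remote_boundary_radius):
        converged = False
    return PoreShape(
        r=r,
        h=h,
        s=s,
        x=x,
        z=z,
        phi=phi,
        waist_index=nq - 1,
        energy=e_bend + e_tens,
        bending_energy=e_bend,
        tension_energy=e_tens,
        converged=converged,
        message=str(res.message),
        opt_vector=res.x.copy(),
    )
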