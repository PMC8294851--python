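"""Statistical mechanics of SNARE complexes and the Syt1 C2B lever.

N SNARE complexes are each either *trans* (partially zippered, free to
roam an area ``trans_area``) or *cis* (fully zippered, confined to the
pore waist).  Zippering gains ``dG_zip`` (kT) per complex; zippered
complexes crowd each other as one-dimensional hard rods (a Tonks gas)
on the waist circumference, an entropic effect that favours partial
unzippering and pushes the waist open.

Each zippered complex carries a C2B domain whose calcium-binding loops
are buried in the cell membrane with Hill probability p(Ca); a buried
C2B tilts the whole SNARE-C2B rod upward by ``tilt_angle``, which
demands extra membrane separation (the lever).  Geometric clearance of
the rigid SNARE-C2B capsule between the two membrane surfaces is
checked against the solved pore shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .membrane import PoreShape

__all__ = [
    "SnareParams",
    "C2BParams",
    "tonks_ring_integral",
    "snare_free_energy",
    "buried_probability",
    "clearance_ok",
    "min_separation_flat",
    "state_log_weights",
]

#: reference microscale (nm) absorbing translational measure units into dG_zip
REF_LENGTH_NM = 1.0


@dataclass(frozen=True)
class SnareParams:
    """SNARE subsystem parameters.

    N: number of SNARE complexes; dG_zip: free-energy gain of full
    zippering, kT (cis relative to trans); rod_footprint: in-plane width
    (nm) a zippered SNARE-C2B rod occupies on the waist circumference;
    trans_area: membrane area (nm^2) available to an unzippered complex.
    """

    N: int = 4
    dG_zip: float = 18.0
    rod_footprint: float = 3.7
    trans_area: float = 450.0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be non-negative")
        if self.rod_footprint <= 0:
            raise ValueError("rod_footprint must be positive")
        if self.trans_area <= 0:
            raise ValueError("trans_area must be positive")


@dataclass(frozen=True)
class C2BParams:
    """Calcium sensing and lever geometry of the SNARE-C2B complex.

    hill_n/hill_K: Hill law of loop burial vs [Ca2+] (K in uM; ~20 uM,
    the C2AB-PI(4,5)P2 membrane affinity); tilt_angle: upward tilt of
    the buried-state rod, degrees (~15); loop_depth: penetration of the
    calcium-binding loops into the cell membrane, nm; patch_height:
    resting height of the polybasic patch above the membrane surface,
    nm; complex_length/complex_diameter: rigid-capsule dimensions of the
    SNARE-C2B complex, nm; bilayer_half_thickness: midplane-to-surface
    offset per membrane, nm (steric clearances are measured between
    leaflet surfaces while shapes track bilayer midplanes).
    """

    hill_n: float = 2.3
    hill_K: float = 20.0
    tilt_angle: float = 15.0
    loop_depth: float = 1.0
    patch_height: float = 0.5
    complex_length: float = 14.0
    complex_diameter: float = 4.0
    bilayer_half_thickness: float = 2.0
    # whether the parallel (unburied) rod also enforces its thickness as
    # a minimum separation; the calibrated default treats the untilted
    # complex as imposing no shape constraint
    untilted_sets_separation: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.tilt_angle < 90:
            raise ValueError("tilt_angle must be in (0, 90) degrees")
        if self.loop_depth < 0 or self.patch_height < 0:
            raise ValueError("depths must be non-negative")
        if self.complex_length <= self.complex_diameter:
            raise ValueError("complex_length must exceed complex_diameter")


def buried_probability(calcium, c2b: C2BParams = C2BParams()):
    """Hill probability that the C2B calcium-binding loops are buried.

    p = 1/(1+(K/Ca)^n); p(0) = 0 (without calcium the loops are
    unburied) and p -> 1 at saturating calcium.
    """
    calcium = np.asarray(calcium, dtype=float)
    if np.any(calcium < 0):
        raise ValueError("calcium must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(
            calcium > 0,
            (c2b.hill_K / np.where(calcium > 0, calcium, 1.0)) ** c2b.hill_n,
            np.inf,
        )
    p = 1.0 / (1.0 + ratio)
    return p if p.ndim else float(p)


def tonks_ring_integral(n: int, circumference: float, rod: float) -> float:
    """Configuration integral of n labelled hard rods of length ``rod``
    on a ring of circumference ``circumference``:
    Z_n = l*(l - n*b)^(n-1), zero when the rods do not fit (excluded
    volume), 1 for n = 0."""
    if n == 0:
        return 1.0
    free = circumference - n * rod
    if free <= 0:
        return 0.0
    return circumference * free ** (n - 1)


def snare_free_energy(r: float, snares: SnareParams = SnareParams()) -> float:
    """Free energy (kT) of the SNARE subsystem at waist radius ``r``,
    ignoring C2B clearance constraints:

    F = -ln sum_{n=0..N} C(N,n) exp(n dG_zip) Z_ring(n, 2*pi*r) Z_trans^(N-n)

    with translational measures per REF_LENGTH_NM.  Returns 0 for N=0.
    """
    if r <= 0:
        raise ValueError("waist radius must be positive")
    if snares.N == 0:
        return 0.0
    lw = _zip_log_weights(r, snares)
    m = lw.max()
    if not np.isfinite(m):
        raise ValueError("no accessible SNARE state at this radius")
    return float(-(m + math.log(np.exp(lw - m).sum())))


def _zip_log_weights(r: float, snares: SnareParams) -> np.ndarray:
    """log of the (unnormalized) weight of each zippering number n=0..N,
    burial/clearance factors excluded."""
    ell = 2.0 * math.pi * r
    b = snares.rod_footprint
    a_tr = snares.trans_area / REF_LENGTH_NM**2
    out = np.full(snares.N + 1, -np.inf)
    for n in range(snares.N + 1):
        z_ring = tonks_ring_integral(n, ell, b) / REF_LENGTH_NM**n
        if z_ring <= 0:
            continue
        out[n] = (
            math.log(math.comb(snares.N, n))
            + n * snares.dG_zip
            + math.log(z_ring)
            + (snares.N - n) * math.log(a_tr)
        )
    return out


# ---------------------------------------------------------------------------
# lever clearance geometry
# ---------------------------------------------------------------------------


def min_separation_flat(tilted: bool, c2b: C2BParams) -> float:
    """Closed-form midplane separation needed between two flat parallel
    membranes for the SNARE-C2B capsule to fit.

    Untilted: the rod lies parallel at ``patch_height`` above the cell
    leaflet surface, so the steric gap must be at least
    patch_height + complex_diameter.  Tilted: the anchor end is held
    ``loop_depth`` into the cell membrane and the axis rises at
    ``tilt_angle``, so the gap must be at least
    complex_diameter - loop_depth + (complex_length - complex_diameter)
    * sin(tilt_angle).  Midplane separation adds one bilayer
    half-thickness per membrane.
    """
    t = 2.0 * c2b.bilayer_half_thickness
    if not tilted:
        return t + c2b.patch_height + c2b.complex_diameter
    axis = c2b.complex_length - c2b.complex_diameter
    theta = math.radians(c2b.tilt_angle)
    return t + c2b.complex_diameter - c2b.loop_depth + axis * math.sin(theta)


def _capsule_axis_points(x_anchor, z_anchor, tilted, c2b: C2BParams, n_pts=15):
    """Sample the capsule axis: anchored at radial ``x_anchor``, running
    along the waist chord (tangentially), rising at the tilt angle when
    ``tilted``.  Returns (radial distance, height) arrays."""
    theta = math.radians(c2b.tilt_angle) if tilted else 0.0
    axis = c2b.complex_length - c2b.complex_diameter
    u = np.linspace(0.0, axis, n_pts)
    radial = np.sqrt(x_anchor**2 + (u * math.cos(theta)) ** 2)
    height = z_anchor + u * math.sin(theta)
    return radial, height


def clearance_ok(
    shape: PoreShape,
    tilted: bool,
    c2b: C2BParams = C2BParams(),
    n_anchor: int = 12,
) -> bool:
    """Does the rigid SNARE-C2B capsule fit between the two membrane
    surfaces of ``shape``?

    The capsule (length ``complex_length``, diameter ``complex_diameter``)
    is anchored near the waist with its axis along the waist chord.
    Untilted: axis parallel to the cell membrane with the polybasic
    patch ``patch_height`` above the lower leaflet surface.  Tilted: the
    C2B end is held ``loop_depth`` into the cell membrane and the axis
    rises at ``tilt_angle``.  The check passes if any anchor radius
    between the waist and the scaffold edge admits the capsule without
    crossing either leaflet surface.
    """
    if not shape.converged:
        return False
    xu, zu, xl, zl = shape.surfaces()
    t_half = c2b.bilayer_half_thickness
    rad = c2b.complex_diameter / 2.0

    def lower_surface(x):  # top leaflet surface of the cell membrane
        return np.interp(x, xl, zl, left=zl[0], right=zl[-1]) + t_half

    def upper_surface(x):  # bottom leaflet surface of the disc membrane;
        # beyond the scaffold rim the belt blocks escape, so the disc
        # level is continued rather than opened to infinity
        return np.interp(x, xu, zu, left=zu[0], right=zu[-1]) - t_half

    # the cis SNARE-C2B rod is anchored at the waist; allow a little
    # lateral slack along the funnel mouth
    anchors = np.linspace(shape.r, shape.r + 3.0, n_anchor)
    for x_a in anchors:
        base = lower_surface(np.array([x_a]))[0]
        if tilted:
            z_anchor = base - c2b.loop_depth + rad
        else:
            z_anchor = base + c2b.patch_height + rad
        radial, height = _capsule_axis_points(x_a, z_anchor, tilted, c2b)
        lo = lower_surface(radial)
        hi = upper_surface(radial)
        if tilted:
            # the anchored (C2B) end penetrates the cell membrane by up
            # to loop_depth; the rising body must stay above the surface
            below_ok = height - rad >= lo - c2b.loop_depth - 1e-9
        else:
            below_ok = height - rad >= lo - 1e-9
        above_ok = height + rad <= hi + 1e-9
        if bool(np.all(below_ok & above_ok)):
            return True
    return False


def state_log_weights(
    r: float,
    shape_untilted_ok: bool,
    shape_tilted_ok: bool,
    p_buried: float,
    snares: SnareParams,
) -> np.ndarray:
    """log-weights of the zippering states n = 0..N with burial patterns
    and clearance folded in.

    Burial is independent Bernoulli(p) across the n zippered complexes;
    a state requires the tilted clearance iff at least one zippered
    complex is buried (the strongest constraint dominates), otherwise
    the untilted clearance.  States whose clearance fails get zero
    weight.  n = 0 states impose no constraint.
    """
    lw = _zip_log_weights(r, snares).copy()
    for n in range(1, snares.N + 1):
        w_unburied = (1.0 - p_buried) ** n if shape_untilted_ok else 0.0
        w_buried = (1.0 - (1.0 - p_buried) ** n) if shape_tilted_ok else 0.0
        factor = w_unburied + w_buried
        lw[n] += math.log(factor) if factor > 0 else -np.inf
    return lw
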