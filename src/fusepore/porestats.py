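"""Pore-size statistics from single-pore conductances.

Converts open-pore conductances to pore radii with a cylindrical pore
model, estimates pore-size probability densities, inverts them to
apparent free-energy profiles (Boltzmann inversion, U = -kT ln P), turns
free-energy differences into dilation forces, and fits Hill titration
curves of any per-pore signal against free calcium.

The Hill fit follows the statsmodels convention: ``HillModel(x, y)`` is
built from data and ``fit()`` returns a :class:`HillFitResults` carrying
estimates, 95% confidence bounds, R^2 and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import (
    DEFAULT_CONDUCTIVITY_S_PER_M,
    DEFAULT_PORE_LENGTH_NM,
    KT_PN_NM,
)

__all__ = [
    "ConductanceModel",
    "FreeEnergyProfile",
    "HillModel",
    "HillFitResults",
    "conductance_to_radius",
    "radius_to_conductance",
    "estimate_pdf",
    "boltzmann_invert",
    "barrier_force",
    "fit_hill",
]


@dataclass(frozen=True)
class ConductanceModel:
    """Cylindrical pore conductance model G = sigma*pi*r^2/L.

    Parameters
    ----------
    L : float
        Pore length (membrane-spanning cylinder), nm.
    sigma : float
        Solution conductivity, S/m.
    include_access_resistance : bool
        If True, add the access (convergence) resistance 1/(2*sigma*r)
        in series with the cylinder resistance.  Off by default: the
        published radius/conductance correspondences are mutually
        consistent only for the cylinder-only form.
    """

    L: float = DEFAULT_PORE_LENGTH_NM
    sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M
    include_access_resistance: bool = False

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"pore length must be positive, got L={self.L}")
        if self.sigma <= 0:
            raise ValueError(f"conductivity must be positive, got sigma={self.sigma}")


# Unit bookkeeping for G = sigma*pi*r^2/L with r, L in nm and G in pS:
# sigma[S/m] * r^2[nm^2] / L[nm] = sigma * r^2 / L * 1e-9 S = that * 1e3 pS.
_PS_PER_SI = 1e3


def radius_to_conductance(r, model: ConductanceModel = ConductanceModel()):
    """Conductance (pS) of a pore of radius ``r`` (nm).

    Cylinder-only: G = sigma*pi*r^2/L.  With access resistance:
    1/G = L/(sigma*pi*r^2) + 1/(2*sigma*r).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pore radius must be non-negative")
    g_cyl = model.sigma * np.pi * r**2 / model.L * _PS_PER_SI
    if not model.include_access_resistance:
        return g_cyl if g_cyl.ndim else float(g_cyl)
    with np.errstate(divide="ignore"):
        g_acc = 2.0 * model.sigma * r * _PS_PER_SI
        g = np.where(r > 0, 1.0 / (1.0 / np.where(g_cyl > 0, g_cyl, 1) + 1.0 / np.where(g_acc > 0, g_acc, 1)), 0.0)
    return g if g.ndim else float(g)


def conductance_to_radius(G, model: ConductanceModel = ConductanceModel()):
    """Pore radius (nm) from conductance ``G`` (pS); inverse of
    :func:`radius_to_conductance`.

    Cylinder-only inversion is closed-form, r = sqrt(G*L/(pi*sigma)).
    With access resistance the relation 1/G = L/(sigma*pi*r^2) +
    1/(2*sigma*r) is a quadratic in r with a unique positive root.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("conductance must be non-negative")
    if not model.include_access_resistance:
        r = np.sqrt(G / _PS_PER_SI * model.L / (np.pi * model.sigma))
        return r if r.ndim else float(r)
    # sigma*r^2/G_SI - r/2 - L/pi = 0  (from multiplying 1/G by sigma*r^2)
    g_si = G / _PS_PER_SI
    a = np.where(g_si > 0, model.sigma / np.where(g_si > 0, g_si, 1), np.inf)
    r = np.where(
        g_si > 0,
        (0.5 + np.sqrt(0.25 + 4.0 * a * model.L / np.pi)) / (2.0 * a),
        0.0,
    )
    return r if r.ndim else float(r)


@dataclass
class FreeEnergyProfile:
    """Binned pore-size distribution and its Boltzmann inversion.

    ``U = -ln(P/P_max)`` in kT units, shifted so the minimum is 0; bins
    where the density is zero (or under the count floor) are excluded
    from the support.
    """

    r: np.ndarray  # bin centres, nm (or pS when built from conductances)
    P: np.ndarray  # probability density over the retained bins
    U: np.ndarray  # apparent free energy, kT, min-shifted to 0
    counts: np.ndarray | None = None

    def plot(self, ax=None, **kwargs):
        """Plot the apparent free-energy profile U(r) in kT."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r, self.U, **kwargs)
        ax.set_xlabel("pore radius [nm]")
        ax.set_ylabel("apparent free energy [kT]")
        return ax

    def energy_at(self, x) -> np.ndarray | float:
        """Linear interpolation of U at ``x`` within the support."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.r[0], self.r[-1]
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"requested point outside profile support [{lo:.3g}, {hi:.3g}]"
            )
        out = np.interp(x, self.r, self.U)
        return out if out.ndim else float(out)


def estimate_pdf(samples, bin_width: float, range_: tuple[float, float] | None = None):
    """Normalized histogram density of a sample vector.

    Radius PDFs are obtained by mapping conductance samples through
    :func:`conductance_to_radius` *before* binning (transform the
    samples, not the binned densities).

    Returns ``(centers, density, counts)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot estimate a density from an empty sample vector")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if range_ is None:
        lo = np.floor(samples.min() / bin_width) * bin_width
        hi = np.ceil(samples.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = range_
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, counts


def boltzmann_invert(
    centers, density, counts=None, min_count: int = 5
) -> FreeEnergyProfile:
    """Apparent free energy U(r) = -ln(P/P_max) in kT from a binned density.

    Bins with zero density are excluded from the support; when bin
    ``counts`` are supplied, bins with fewer than ``min_count`` samples
    are also excluded to bound inversion noise.  The vertical shift
    (min U = 0) is a reporting convention.
    """
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    keep = density > 0
    if counts is not None:
        keep &= np.asarray(counts) >= min_count
    if not np.any(keep):
        raise ValueError("no bins with positive density (and enough counts)")
    P = density[keep]
    U = -np.log(P / P.max())
    return FreeEnergyProfile(
        r=centers[keep],
        P=P,
        U=U,
        counts=None if counts is None else np.asarray(counts)[keep],
    )


def barrier_force(
    profile: FreeEnergyProfile, r1: float, r2: float
) -> tuple[float, float]:
    """Energy difference and mean opposing force between two radii.

    Returns ``(dU, F)`` with dU = U(r2) - U(r1) in kT and
    F = dU/(r2 - r1) converted to pN via kT = 4.114 pN*nm (298 K).
    """
    if not r1 < r2:
        raise ValueError("need r1 < r2")
    dU = float(profile.energy_at(r2) - profile.energy_at(r1))
    F = dU * KT_PN_NM / (r2 - r1)
    return dU, F


# ---------------------------------------------------------------------------
# Hill titration fitting
# ---------------------------------------------------------------------------


def _hill(x, a, c, n, K):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (K / np.where(x > 0, x, 1.0)) ** n, np.inf)
    return c + a / (1.0 + ratio)


@dataclass
class HillFitResults:
    """Point estimates, 95% confidence bounds and fit diagnostics for a
    Hill titration f(x) = a/(1+(K/x)^n) + c."""

    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    rsquared: float
    fixed: tuple[str, ...] = ()
    lmfit_result: object = field(default=None, repr=False)

    @property
    def a(self) -> float:
        return self.params["a"]

    @property
    def c(self) -> float:
        return self.params["c"]

    @property
    def n(self) -> float:
        return self.params["n"]

    @property
    def K(self) -> float:
        return self.params["K"]

    def predict(self, x):
        return _hill(x, self.a, self.c, self.n, self.K)

    def summary(self) -> str:
        lines = [
            "Hill titration fit: f(x) = a/(1+(K/x)^n) + c",
            f"{'param':>6} {'value':>12} {'95% CI low':>12} {'95% CI high':>12}",
        ]
        for name in ("a", "c", "n", "K"):
            lo, hi = self.conf_int[name]
            tag = " (fixed)" if name in self.fixed else ""
            lines.append(
                f"{name:>6} {self.params[name]:>12.4g} {lo:>12.4g} {hi:>12.4g}{tag}"
            )
        lines.append(f"R^2 = {self.rsquared:.4f}")
        return "\n".join(lines)


class HillModel:
    """Least-squares Hill model of a calcium titration.

    Parameters
    ----------
    x : array
        Free calcium concentrations, uM (x >= 0; x = 0 contributes the
        baseline ``c`` exactly).
    y : array
        Signal values (e.g. mean open-pore conductance in pS, or
        expansion rate in nS/s).
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if np.any(self.x < 0):
            raise ValueError("calcium concentrations must be non-negative")

    def fit(
        self,
        fix_n: float | None = None,
        fix_K: float | None = None,
        start: dict[str, float] | None = None,
    ) -> HillFitResults:
        n_free_shape = sum(v is None for v in (fix_n, fix_K))
        if np.unique(self.x).size < 2 + n_free_shape:
            raise ValueError(
                "non-identifiable design: need at least "
                f"{2 + n_free_shape} distinct x values"
            )
        pars = lmfit.Parameters()
        y = self.y
        x = self.x
        span = max(y.max() - y.min(), 1e-12)
        xpos = x[x > 0]
        guess = {
            "a": span,
            "c": float(y.min()),
            "n": 2.0,
            "K": float(np.median(xpos)) if xpos.size else 1.0,
        }
        if start:
            guess.update(start)
        pars.add("a", value=guess["a"], min=0)
        pars.add("c", value=guess["c"], min=0)
        if fix_n is None:
            pars.add("n", value=guess["n"], min=0.1, max=10)
        else:
            pars.add("n", value=fix_n, vary=False)
        if fix_K is None:
            pars.add("K", value=max(guess["K"], 1e-6), min=1e-6)
        else:
            pars.add("K", value=fix_K, vary=False)

        def resid(p):
            return _hill(x, p["a"], p["c"], p["n"], p["K"]) - y

        out = lmfit.minimize(resid, pars, method="leastsq")
        est = {k: float(out.params[k].value) for k in ("a", "c", "n", "K")}
        ss_res = float(np.sum(out.residual**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        # 95% bounds from the asymptotic covariance (t distribution)
        from scipy import stats

        dof = max(out.nfree, 1)
        tcrit = stats.t.ppf(0.975, dof)
        ci = {}
        fixed = tuple(k for k, v in (("n", fix_n), ("K", fix_K)) if v is not None)
        for k in ("a", "c", "n", "K"):
            se = out.params[k].stderr
            if k in fixed or se is None or not np.isfinite(se):
                ci[k] = (est[k], est[k])
            else:
                ci[k] = (est[k] - tcrit * se, est[k] + tcrit * se)
        return HillFitResults(
            params=est, conf_int=ci, rsquared=r2, fixed=fixed, lmfit_result=out
        )


def fit_hill(
    x,
    y,
    fix_n: float | None = None,
    fix_K: float | None = None,
    start: dict[str, float] | None = None,
) -> HillFitResults:
    """Functional wrapper: ``HillModel(x, y).fit(fix_n, fix_K, start)``."""
    return HillModel(x, y).fit(fix_n=fix_n, fix_K=fix_K, start=start)
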