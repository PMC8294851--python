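"""The mechanical lever model of calcium-triggered fusion-pore dilation.

For each pore radius the total free energy sums the Helfrich membrane
energy of the solved pore shape, the SNARE zippering/crowding free
energy, and the calcium-dependent C2B burial statistics, with states
failing the SNARE-C2B clearance excluded; the pore height takes the
value that minimizes the free energy at that radius.  Boltzmann
statistics over the radius grid then give the pore-size distribution,
its free-energy profile, and mean radius/height/conductance versus
calcium.

Radius conventions: the *pore radius* r_po is the aqueous lumen radius
(the one conductance measures); the membrane midplane waist is wider by
one monolayer thickness, r_waist = r_po + bilayer_half_thickness.
Heights are midplane-to-midplane.

The model object follows the statsmodels convention:
``FusionPoreLeverModel(params...)`` is cheap to construct; the expensive
shape-landscape scan happens once, lazily; ``evaluate(calcium)`` returns
a :class:`LeverEnsemble` with the estimates and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..porestats import ConductanceModel, radius_to_conductance
from .membrane import GeometryError, MembraneParams, PoreShape, ScaffoldParams, solve_shape
from .snares import C2BParams, SnareParams, buried_probability, clearance_ok, state_log_weights

__all__ = [
    "FusionPoreLeverModel",
    "LeverEnsemble",
    "default_model",
]


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(a - m))))


@dataclass
class LeverEnsemble:
    """Boltzmann ensemble of the lever model at one calcium concentration.

    ``r`` is the lumen radius grid (nm); ``U`` the total free energy
    (kT, min-shifted); ``P`` the normalized pore-size distribution on
    the grid; ``h_opt`` the minimizing height per radius (nm,
    midplane-to-midplane).
    """

    calcium: float
    r: np.ndarray
    U: np.ndarray
    P: np.ndarray
    h_opt: np.ndarray
    mean_r: float
    mean_h: float
    mean_G: float
    var_r: float

    def energy_between(self, r1: float, r2: float) -> float:
        """U(r2) - U(r1) by linear interpolation on the grid (kT)."""
        return float(np.interp(r2, self.r, self.U) - np.interp(r1, self.r, self.U))

    def summary(self) -> str:
        lines = [
            "Fusion-pore lever model ensemble",
            f"  [Ca2+]        : {self.calcium:g} uM",
            f"  <r_po>        : {self.mean_r:.3f} nm",
            f"  sd(r_po)      : {np.sqrt(self.var_r):.3f} nm",
            f"  <h>           : {self.mean_h:.3f} nm",
            f"  <G>           : {self.mean_G:.1f} pS",
            f"  grid          : {self.r[0]:.2f}-{self.r[-1]:.2f} nm "
            f"({self.r.size} radii)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, what: str = "U", **kwargs):
        """Plot U(r) (kT), P(r), or h*(r) against the lumen radius."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = {"U": self.U, "P": self.P, "h": self.h_opt}[what]
        label = {"U": "U(r) [kT]", "P": "P(r)", "h": "h*(r) [nm]"}[what]
        ax.plot(self.r, y, label=f"[Ca2+] = {self.calcium:g} uM", **kwargs)
        ax.set_xlabel("pore radius r_po [nm]")
        ax.set_ylabel(label)
        return ax


class FusionPoreLeverModel:
    """Helfrich pore + SNARE statistical mechanics + C2B lever.

    Parameters are grouped as in the physical model: ``mem`` (bending
    modulus, tension), ``scaf`` (nanodisc scaffold), ``snares``
    (zippering and crowding), ``c2b`` (calcium sensing and lever
    geometry), ``conductance`` (lumen-radius-to-pS map).  The default
    parameter set is calibrated so the zero-calcium ensemble reproduces
    the no-calcium anchors (mean radius ~0.9 nm, mean height ~9 nm,
    6-7 kT resistance from 1 to 2.5 nm); with-calcium behaviour is then
    a prediction.
    """

    def __init__(
        self,
        mem: MembraneParams = None,
        scaf: ScaffoldParams = None,
        snares: SnareParams = None,
        c2b: C2BParams = None,
        conductance: ConductanceModel = None,
        r_grid: np.ndarray | None = None,
        h_grid: np.ndarray | None = None,
    ):
        self.mem = mem or MembraneParams()
        self.scaf = scaf or ScaffoldParams()
        self.snares = snares or SnareParams()
        self.c2b = c2b or C2BParams()
        self.conductance = conductance or ConductanceModel()
        # lumen radius grid: 0.3-4 nm (larger pores are rarely sampled
        # experimentally), 0.05 nm steps; height grid 0.25 nm steps
        self.r_grid = (
            np.round(np.arange(0.30, 4.0001, 0.05), 4) if r_grid is None else np.asarray(r_grid)
        )
        self.h_grid = (
            np.round(np.arange(5.0, 16.0001, 0.25), 4) if h_grid is None else np.asarray(h_grid)
        )
        self._landscape = None

    # ------------------------------------------------------------------
    # membrane landscape (calcium independent, computed once)
    # ------------------------------------------------------------------

    @property
    def landscape(self) -> dict:
        if self._landscape is None:
            self._landscape = self._compute_landscape()
        return self._landscape

    def _compute_landscape(self) -> dict:
        nr, nh = self.r_grid.size, self.h_grid.size
        E = np.full((nr, nh), np.nan)
        ok_untilted = np.zeros((nr, nh), dtype=bool)
        ok_tilted = np.zeros((nr, nh), dtype=bool)
        t_half = self.c2b.bilayer_half_thickness
        for i, r_po in enumerate(self.r_grid):
            r_mid = r_po + t_half
            warm = None
            prev_e = np.nan
            for j, h in enumerate(self.h_grid):
                try:
                    shape = solve_shape(r_mid, h, self.mem, self.scaf, x0=warm)
                    # warm starts occasionally ride a bad local minimum;
                    # E(h) is smooth, so a jump triggers a cold re-solve
                    suspicious = (
                        not shape.converged
                        or (np.isfinite(prev_e) and shape.energy > prev_e + 8.0)
                    )
                    if suspicious and warm is not None:
                        cold = solve_shape(r_mid, h, self.mem, self.scaf)
                        if cold.converged and (
                            not shape.converged or cold.energy < shape.energy
                        ):
                            shape = cold
                except GeometryError:
                    continue
                if not shape.converged:
                    warm = None
                    continue
                warm = shape.opt_vector
                prev_e = shape.energy
                E[i, j] = shape.energy
                ok_untilted[i, j] = clearance_ok(shape, tilted=False, c2b=self.c2b)
                ok_tilted[i, j] = clearance_ok(shape, tilted=True, c2b=self.c2b)
        return {"E": E, "untilted": ok_untilted, "tilted": ok_tilted}

    # ------------------------------------------------------------------
    # statistical mechanics
    # ------------------------------------------------------------------

    def total_free_energy(self, r_po: float, calcium: float) -> tuple[float, float]:
        """Total free energy (kT) and the minimizing height (nm) at one
        lumen radius.

        Raises ValueError when no feasible state exists at any height
        (the radius is then excluded from the profile).
        """
        i = int(np.argmin(np.abs(self.r_grid - r_po)))
        if abs(self.r_grid[i] - r_po) > 0.5 * (self.r_grid[1] - self.r_grid[0]) + 1e-9:
            raise ValueError(f"radius {r_po} not on the model grid")
        F_h = self._free_energy_over_h(i, calcium)
        if not np.any(np.isfinite(F_h)):
            raise ValueError(f"no feasible state at any height for r_po={r_po}")
        j = int(np.nanargmin(F_h))
        return float(F_h[j]), float(self.h_grid[j])

    def _free_energy_over_h(self, i: int, calcium: float) -> np.ndarray:
        land = self.landscape
        p = buried_probability(calcium, self.c2b)
        F = np.full(self.h_grid.size, np.inf)
        for j in range(self.h_grid.size):
            e_mem = land["E"][i, j]
            if not np.isfinite(e_mem):
                continue
            unt_ok = (
                land["untilted"][i, j] if self.c2b.untilted_sets_separation else True
            )
            lw = state_log_weights(
                self.r_grid[i] + self.c2b.bilayer_half_thickness,
                unt_ok,
                land["tilted"][i, j],
                p,
                self.snares,
            )
            lse = _logsumexp(lw)
            if not np.isfinite(lse):
                continue
            F[j] = e_mem - lse
        return F

    def evaluate(self, calcium: float) -> LeverEnsemble:
        """Boltzmann ensemble (U, P, h*, moments) at one [Ca2+] (uM)."""
        U = np.full(self.r_grid.size, np.nan)
        H = np.full(self.r_grid.size, np.nan)
        for i, r_po in enumerate(self.r_grid):
            F_h = self._free_energy_over_h(i, calcium)
            if np.any(np.isfinite(F_h)):
                j = int(np.nanargmin(np.where(np.isfinite(F_h), F_h, np.inf)))
                U[i] = F_h[j]
                H[i] = self.h_grid[j]
        keep = np.isfinite(U)
        if not np.any(keep):
            raise ValueError("no feasible radius anywhere on the grid")
        r = self.r_grid[keep]
        u = U[keep] - np.nanmin(U[keep])
        h = H[keep]
        w = np.exp(-u)
        P = w / w.sum()
        mean_r = float(P @ r)
        mean_h = float(P @ h)
        G = radius_to_conductance(r, self.conductance)
        mean_G = float(P @ G)
        var_r = float(P @ (r - mean_r) ** 2)
        return LeverEnsemble(
            calcium=calcium, r=r, U=u, P=P, h_opt=h,
            mean_r=mean_r, mean_h=mean_h, mean_G=mean_G, var_r=var_r,
        )

    def titrate(self, calcium_grid) -> pd.DataFrame:
        """Ensemble statistics across a calcium grid, with fold changes
        relative to zero calcium."""
        base = self.evaluate(0.0)
        rows = []
        for ca in np.asarray(calcium_grid, dtype=float):
            ens = self.evaluate(ca)
            rows.append(
                {
                    "calcium_uM": ca,
                    "mean_r_nm": ens.mean_r,
                    "mean_h_nm": ens.mean_h,
                    "mean_G_pS": ens.mean_G,
                    "sd_r_nm": float(np.sqrt(ens.var_r)),
                    "fold_r": ens.mean_r / base.mean_r,
                    "fold_G": ens.mean_G / base.mean_G,
                }
            )
        return pd.DataFrame(rows)


def default_model(**overrides) -> FusionPoreLeverModel:
    """The calibrated default model (see lever.calibrated defaults)."""
    from .calibrated import CALIBRATED

    kw = dict(CALIBRATED)
    kw.update(overrides)
    return FusionPoreLeverModel(**kw)
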