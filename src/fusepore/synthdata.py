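"""Synthetic single-pore patch recordings.

Generates conductance time series with the statistical structure the
downstream analysis assumes for nanodisc-cell fusion assays: Poisson
pore nucleation per patch, exponential burst lifetimes T_o, geometric
flicker counts N_flickers (support {0, 1, ...}), Gaussian point noise
around a condition-dependent mean open-pore conductance, and a
calcium-dependent mean following a Hill law.

Every recording carries a ground-truth annotation table (burst onsets,
offsets, per-dwell idealization) so idealization code can be tested
against a known answer.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HillLaw",
    "GeneratorParams",
    "ConditionPreset",
    "CurrentTrace",
    "PatchRecording",
    "PRESETS",
    "hill_conductance",
    "simulate_burst",
    "simulate_patch_recording",
    "write_trace",
    "read_trace",
    "write_trace_hdf5",
    "read_trace_hdf5",
]


@dataclass(frozen=True)
class HillLaw:
    """Hill dependence of mean open-pore conductance on free calcium.

    f(x) = a/(1+(K/x)^n) + c, so f(0) = c and f(inf) = a + c.

    Defaults are the published titration fit of mean open-pore
    conductance against [Ca2+]_free (a = 343.7 pS, c = 164.2 pS,
    n = 2.3, K = 23 uM).
    """

    a: float = 343.7
    c: float = 164.2
    n: float = 2.3
    K: float = 23.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 0:
            raise ValueError("Hill amplitudes a, c must be non-negative")
        if self.n <= 0 or self.K <= 0:
            raise ValueError("Hill n and K must be positive")


def hill_conductance(calcium, law: HillLaw = HillLaw()):
    """Mean open-pore conductance (pS) at free [Ca2+] ``calcium`` (uM)."""
    calcium = np.asarray(calcium, dtype=float)
    if np.any(calcium < 0):
        raise ValueError("calcium concentration must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(calcium > 0, (law.K / np.where(calcium > 0, calcium, 1.0)) ** law.n, np.inf)
    out = law.c + law.a / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic patch generator.

    Durations in ms, rates per minute, conductances in pS.  The burst
    lifetime T_o is drawn exponential(``burst_mean_duration``) and the
    flicker count geometric(``flicker_success_prob``) on {0, 1, ...};
    ``open_mean_dwell`` only weights how the open time is split between
    flickers.
    """

    nucleation_rate: float = 0.4  # pores per minute per patch
    burst_mean_duration: float = 2000.0  # ms, exponential mean of T_o
    flicker_success_prob: float = 0.25  # geometric p; mean N = (1-p)/p = 3
    flicker_mean_closed: float = 15.0  # ms
    open_mean_dwell: float = 500.0  # ms, relative weighting of open dwells
    mean_open_conductance: float | None = None  # pS; None -> Hill law
    conductance_noise_sd: float = 20.0  # pS, on open-pore points
    baseline_noise_sd: float = 4.0  # pS, everywhere
    sample_interval: float = 0.1  # ms (10 kHz)
    holding_potential: float = 15.0  # mV (the assay holds below 20 mV)
    patch_duration: float = 10.0  # minutes
    max_pores_per_patch: int = 3  # per-patch censoring cap
    seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        v = []
        for name in (
            "nucleation_rate",
            "burst_mean_duration",
            "flicker_mean_closed",
            "open_mean_dwell",
            "sample_interval",
            "patch_duration",
        ):
            if getattr(self, name) < 0 or (
                name != "nucleation_rate" and getattr(self, name) == 0
            ):
                v.append(f"{name} must be positive")
        if not 0 < self.flicker_success_prob <= 1:
            v.append("flicker_success_prob must be in (0, 1]")
        if self.conductance_noise_sd < 0 or self.baseline_noise_sd < 0:
            v.append("noise SDs must be non-negative")
        min_dwell = min(
            self.burst_mean_duration, self.flicker_mean_closed, self.open_mean_dwell
        )
        if self.sample_interval >= min_dwell / 5:
            v.append("sample_interval must be < all mean dwells / 5")
        if self.max_pores_per_patch < 1:
            v.append("max_pores_per_patch must be >= 1")
        return v

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class ConditionPreset:
    """Experimental condition emulated by the generator.

    ``hill_active`` selects whether the mean open conductance follows
    the calcium Hill law (functional Syt1 C2AB with PI(4,5)P2) or stays
    at the SNARE-alone mean (~200 pS) regardless of calcium.
    ``conductance_scale`` and ``nucleation_scale`` are multiplicative
    condition effects.
    """

    label: str
    calcium: float = 0.0  # uM free calcium
    pip2_present: bool = True
    hill_active: bool = True
    conductance_scale: float = 1.0
    nucleation_scale: float = 1.0
    snare_alone_conductance: float = 200.0  # pS

    def __post_init__(self) -> None:
        if self.conductance_scale <= 0 or self.nucleation_scale <= 0:
            raise ValueError("preset scales must be positive")
        if self.calcium < 0:
            raise ValueError("calcium must be non-negative")

    def mean_conductance(self, law: HillLaw) -> float:
        base = (
            hill_conductance(self.calcium, law)
            if self.hill_active and self.pip2_present
            else self.snare_alone_conductance
        )
        return base * self.conductance_scale


def _preset(label, **kw) -> ConditionPreset:
    return ConditionPreset(label=label, **kw)


#: Condition presets reproducing the direction of the published effects:
#: wild-type C2AB / full-length Syt1 follow the Hill law (3x larger pores
#: at 100 uM calcium); calcium-binding (D309N), SNARE-binding
#: (R398Q/R399Q) and loop-insertion (4A) mutants collapse to the
#: SNARE-alone mean; the polybasic mutant is strongly reduced; 4W
#: behaves like wild type.
PRESETS: dict[str, ConditionPreset] = {
    "no_syt": _preset("no_syt", hill_active=False, calcium=100.0),
    "syt1_full": _preset("syt1_full", calcium=100.0, nucleation_scale=3.0),
    "c2ab_wt": _preset("c2ab_wt", calcium=100.0, nucleation_scale=3.0),
    "c2ab_D309N": _preset("c2ab_D309N", calcium=100.0, hill_active=False),
    "c2ab_K326A_K327A": _preset(
        "c2ab_K326A_K327A", calcium=100.0, conductance_scale=0.45
    ),
    "c2ab_R398Q_R399Q": _preset("c2ab_R398Q_R399Q", calcium=100.0, hill_active=False),
    "c2ab_4A": _preset("c2ab_4A", calcium=100.0, hill_active=False),
    "c2ab_4W": _preset("c2ab_4W", calcium=100.0, nucleation_scale=3.0),
}


@dataclass
class CurrentTrace:
    """Uniformly sampled single-patch conductance record.

    ``conductance`` is in pS (current/holding potential when recorded
    as current); ``time`` in ms, strictly increasing.
    """

    time: np.ndarray
    conductance: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def sample_interval(self) -> float:
        return float(self.metadata.get("sample_interval", self.time[1] - self.time[0]))

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PatchRecording:
    """A trace plus its ground-truth burst annotations and dwell table."""

    trace: CurrentTrace
    annotations: pd.DataFrame  # burst_id, t_on_ms, t_off_ms, n_flickers_true, mean_G_true
    dwells: pd.DataFrame  # burst_id, state, t_start_ms, duration_ms, level_pS
    n_candidate_pores: int  # Poisson count before censoring/thinning


# ---------------------------------------------------------------------------
# burst-level simulation
# ---------------------------------------------------------------------------


def simulate_burst(
    params: GeneratorParams,
    law: HillLaw,
    calcium: float,
    rng: np.random.Generator,
    mean_conductance: float | None = None,
) -> list[tuple[str, float, float]]:
    """Draw one burst as a dwell list ``[(state, duration_ms, level_pS), ...]``.

    The burst lifetime T_o is exponential(``burst_mean_duration``); the
    number of transient full closures (flickers) is geometric
    (``flicker_success_prob``) on {0, 1, 2, ...}; the open-level
    conductance is the condition mean plus Gaussian noise applied later
    point-wise.  States alternate open/blocked, beginning and ending
    open; the burst ends in permanent closure.
    """
    if mean_conductance is None:
        mean_conductance = (
            params.mean_open_conductance
            if params.mean_open_conductance is not None
            else hill_conductance(calcium, law)
        )
    t_o = rng.exponential(params.burst_mean_duration)
    # numpy's geometric counts trials (support {1, ...}); shift to {0, ...}
    n_flickers = int(rng.geometric(params.flicker_success_prob) - 1)
    closed = rng.exponential(params.flicker_mean_closed, size=n_flickers)
    # keep closures a minority of the burst so T_o stays the dominant span
    total_closed = closed.sum()
    if total_closed > 0.5 * t_o:
        closed *= 0.5 * t_o / total_closed
        total_closed = closed.sum()
    open_total = t_o - total_closed
    weights = rng.exponential(params.open_mean_dwell, size=n_flickers + 1)
    open_dwells = open_total * weights / weights.sum()
    dwells: list[tuple[str, float, float]] = []
    for i, od in enumerate(open_dwells):
        dwells.append(("open", float(od), float(mean_conductance)))
        if i < n_flickers:
            dwells.append(("blocked", float(closed[i]), 0.0))
    return dwells


def _simulate_patch_events(
    params: GeneratorParams,
    preset: ConditionPreset,
    law: HillLaw,
    rng: np.random.Generator,
    refractory_ms: float = 1000.0,
):
    """Event-level patch simulation (no rasterization).

    Pore onsets follow a Poisson process at nucleation_rate *
    nucleation_scale, truncated at ``max_pores_per_patch``; candidate
    onsets that fall inside an active burst (or its refractory gap) are
    thinned so bursts never overlap.

    Returns ``(bursts, n_candidates)`` where each burst is
    ``(t_on_ms, dwell_list)``.
    """
    duration_ms = params.patch_duration * 60e3
    rate_per_ms = params.nucleation_rate * preset.nucleation_scale / 60e3
    mean_g = preset.mean_conductance(law)
    bursts = []
    n_candidates = 0
    t = 0.0
    busy_until = -np.inf
    while True:
        if rate_per_ms <= 0:
            break
        t += rng.exponential(1.0 / rate_per_ms)
        if t >= duration_ms:
            break
        n_candidates += 1
        if t < busy_until:
            continue  # a pore is already open in this patch; thinned
        dwells = simulate_burst(params, law, preset.calcium, rng, mean_conductance=mean_g)
        span = sum(d for _, d, _ in dwells)
        if t + span > duration_ms:  # truncate at end of recording
            clipped = []
            remaining = duration_ms - t
            for state, d, g in dwells:
                if remaining <= 0:
                    break
                dd = min(d, remaining)
                clipped.append((state, dd, g))
                remaining -= dd
            dwells = [d for d in clipped if d[1] > 0]
            if not dwells or all(s != "open" for s, _, _ in dwells):
                break
        bursts.append((t, dwells))
        span = sum(d for _, d, _ in dwells)
        busy_until = t + span + refractory_ms
        if len(bursts) >= params.max_pores_per_patch:
            break
    return bursts, n_candidates


def simulate_patch_recording(
    params: GeneratorParams,
    preset: ConditionPreset,
    law: HillLaw = HillLaw(),
    rng: np.random.Generator | None = None,
) -> PatchRecording:
    """Simulate one patch: trace + ground-truth annotations.

    Identical ``params.seed`` (when ``rng`` is not supplied) gives a
    bit-identical recording.
    """
    if params.patch_duration <= 0:
        raise ValueError("patch_duration must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bursts, n_candidates = _simulate_patch_events(params, preset, law, rng)

    dt = params.sample_interval
    n = int(round(params.patch_duration * 60e3 / dt))
    time = np.arange(n) * dt
    g = rng.normal(0.0, params.baseline_noise_sd, size=n)

    ann_rows = []
    dwell_rows = []
    for burst_id, (t_on, dwells) in enumerate(bursts):
        t_cursor = t_on
        open_levels = []
        n_flick = sum(1 for s, _, _ in dwells if s == "blocked")
        for state, dur, level in dwells:
            i0 = int(math.ceil(t_cursor / dt))
            i1 = int(math.ceil((t_cursor + dur) / dt))
            i1 = min(i1, n)
            if state == "open" and i1 > i0:
                g[i0:i1] += level + rng.normal(
                    0.0, params.conductance_noise_sd, size=i1 - i0
                )
                open_levels.append(level)
            dwell_rows.append(
                {
                    "burst_id": burst_id,
                    "state": state,
                    "t_start_ms": t_cursor,
                    "duration_ms": dur,
                    "level_pS": level,
                }
            )
            t_cursor += dur
        ann_rows.append(
            {
                "burst_id": burst_id,
                "t_on_ms": t_on,
                "t_off_ms": t_cursor,
                "n_flickers_true": n_flick,
                "mean_G_true": float(np.mean(open_levels)) if open_levels else np.nan,
            }
        )

    metadata = {
        "condition": preset.label,
        "calcium_uM": preset.calcium,
        "seed": params.seed,
        "sample_interval": dt,
        "holding_potential_mV": params.holding_potential,
        "patch_duration_min": params.patch_duration,
    }
    ann_cols = ["burst_id", "t_on_ms", "t_off_ms", "n_flickers_true", "mean_G_true"]
    dwell_cols = ["burst_id", "state", "t_start_ms", "duration_ms", "level_pS"]
    return PatchRecording(
        trace=CurrentTrace(time=time, conductance=g, metadata=metadata),
        annotations=pd.DataFrame(ann_rows, columns=ann_cols),
        dwells=pd.DataFrame(dwell_rows, columns=dwell_cols),
        n_candidate_pores=n_candidates,
    )


# ---------------------------------------------------------------------------
# trace I/O: two-column delimited text with key=value header, and HDF5
# ---------------------------------------------------------------------------


def write_trace(trace: CurrentTrace, path) -> None:
    """Write a trace as tab-delimited text with a ``# key = value`` header."""
    with open(path, "w") as fh:
        for k, v in trace.metadata.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("time_ms\tconductance_pS\n")
        # time needs full precision: %.6g would alias late samples of a
        # minutes-long recording onto each other
        np.savetxt(fh, np.column_stack([trace.time, trace.conductance]),
                   fmt=["%.10g", "%.6g"], delimiter="\t")


def read_trace(path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`."""
    metadata: dict = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                key = k.strip()
                val = v.strip()
                try:
                    metadata[key] = float(val) if "." in val or "e" in val.lower() else int(val)
                except ValueError:
                    metadata[key] = val
            else:
                body_lines.append(line)
    data = np.loadtxt(io.StringIO("".join(body_lines)), skiprows=1, delimiter="\t")
    data = np.atleast_2d(data)
    return CurrentTrace(time=data[:, 0], conductance=data[:, 1], metadata=metadata)


def write_trace_hdf5(trace: CurrentTrace, path) -> None:
    """Write a trace to an HDF5 container (binary equivalent of the text form)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_ms", data=trace.time)
        h5.create_dataset("conductance_pS", data=trace.conductance)
        for k, v in trace.metadata.items():
            h5.attrs[k] = v


def read_trace_hdf5(path) -> CurrentTrace:
    import h5py

    with h5py.File(path, "r") as h5:
        time = h5["time_ms"][:]
        g = h5["conductance_pS"][:]
        metadata = {k: (v.item() if hasattr(v, "item") else v) for k, v in h5.attrs.items()}
    return CurrentTrace(time=time, conductance=g, metadata=metadata)


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    """Copy of ``params`` with a new master seed."""
    return replace(params, seed=seed)
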