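"""Synthetic-data generators with known ground truth.

Every measurement class the pipeline consumes can be generated here with
known parameters, so each analysis stage has an independent oracle:

* :func:`simulate_dual_pulse` — an agent-level cell-cycle simulator that
  re-creates the EdU/BrdU dual-pulse experiment (plus pHH3 and CC3
  co-stains) and emits count tables for the kinetics estimators;
* :func:`simulate_teb_forward` — a discrete-time stochastic realization of
  the compartment model (division / death / migration / downstream
  eviction with fixed region sizes) whose empirical duct-deposition rate
  is an independent check on the analytic fluxes;
* :func:`generate_duct_path` — a 2-D piecewise path with bifurcation
  deflections and heading noise, the oracle for the tortuosity module;
* :func:`generate_gland_course` — linear gland growth plus noise for the
  displacement module.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .elongation import BASAL_REGIONS, LUMINAL_REGIONS, RegionParams
from .errors import ConfigError, DataError
from .geometry import RegionId
from .kinetics import PulseRecord, PulseTimeCourse
from .displacement import GlandRecord, GlandTimeCourse
from .tortuosity import PathMeasurements

__all__ = [
    "SimCellCycleConfig",
    "SimTEBConfig",
    "SimPathConfig",
    "ForwardSimResult",
    "DuctPath",
    "simulate_dual_pulse",
    "simulate_teb_forward",
    "generate_duct_path",
    "generate_gland_course",
    "turning_noise_for_underestimate",
]


# ---------------------------------------------------------------------------
# Dual-pulse cell-cycle simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimCellCycleConfig:
    """Ground truth for the dual-pulse experiment.

    Default phase durations are the reference kinetics: G1 = 8 h, S = 6 h,
    G2/M = 2 h (16 h cycle).  ``jitter_sigma`` is the log-SD of a per-cell
    lognormal factor applied to all phases jointly.  Pulses follow the
    reference protocol: an effectively instantaneous EdU pulse at time zero
    and a BrdU window covering the 2 h before each harvest.
    """

    n_cells: int = 2000
    g1_h: float = 8.0
    s_h: float = 6.0
    g2m_h: float = 2.0
    jitter_sigma: float = 0.05
    fraction_cycling: float = 1.0
    edu_pulse_h: float = 0.25
    brdu_pulse_h: float = 2.0
    brdu_offset_h: float = 2.0
    cc3_window_h: float = 8.0
    death_rate_per_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.g1_h, self.s_h, self.g2m_h) <= 0:
            raise ConfigError("phase durations must be > 0")
        if not 0 <= self.fraction_cycling <= 1:
            raise ConfigError("fraction_cycling must lie in [0, 1]")

    @property
    def cycle_h(self) -> float:
        return self.g1_h + self.s_h + self.g2m_h


def _in_s_during(u, g1, s, c, a: float, b: float) -> np.ndarray:
    """Whether each cell occupies S phase at any time in [a, b].

    A cell at cycle position ``u`` (time since cycle start at t = 0) enters
    S at times ``g1 - u + k c`` for integer k.  The window is shorter than
    one cycle in all protocols here, so checking the three entries nearest
    the window suffices.
    """
    entry0 = g1 - u
    k = np.floor((b - entry0) / c)
    hit = np.zeros(u.shape, dtype=bool)
    for dk in (0.0, -1.0, -2.0):
        e = entry0 + (k + dk) * c
        hit |= (e < b) & (e + s > a)
    return hit


def _in_phase_at(u, lo, hi, c, t: float) -> np.ndarray:
    pos = np.mod(u + t, c)
    return (pos >= lo) & (pos < hi)


def simulate_dual_pulse(
    cfg: SimCellCycleConfig,
    chase_times_h: Optional[Sequence[float]] = None,
    region: int = 1,
) -> PulseTimeCourse:
    """Simulate one region's dual-pulse count table.

    Each cell carries a jittered cycle clock at a uniform random position.
    EdU marks cells in S during the initial pulse; BrdU marks cells in S
    during the window preceding each harvest; pHH3 marks cells in G2/M at
    harvest; CC3 marks cell slots whose occupant died within the visibility
    window before harvest (dead cells are replaced, keeping the population
    size constant, as in the fixed-size region of the compartment model).
    """
    if chase_times_h is None:
        chase_times_h = np.arange(0.0, 26.0, 2.0)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    factor = np.exp(rng.normal(0.0, cfg.jitter_sigma, size=n)) if cfg.jitter_sigma > 0 else np.ones(n)
    g1 = cfg.g1_h * factor
    s = cfg.s_h * factor
    g2m = cfg.g2m_h * factor
    c = g1 + s + g2m
    u = rng.uniform(0.0, c)
    cycling = rng.uniform(size=n) < cfg.fraction_cycling

    edu = _in_s_during(u, g1, s, c, -cfg.edu_pulse_h, 0.0) & cycling

    # renewal death process per cell slot; exponential lifetimes make it a
    # Poisson process, so starting one CC3 window before t = 0 gives the
    # stationary stream the harvested tissue would show
    horizon = float(max(chase_times_h)) + 1.0
    death_times: list[np.ndarray] = []
    if cfg.death_rate_per_h > 0:
        pending = -cfg.cc3_window_h + rng.exponential(1.0 / cfg.death_rate_per_h, size=n)
        while np.any(pending <= horizon):
            live = pending <= horizon
            death_times.append(pending[live].copy())
            nxt = np.full(n, np.inf)
            nxt[live] = pending[live] + rng.exponential(1.0 / cfg.death_rate_per_h, size=int(live.sum()))
            pending = nxt
    all_deaths = np.concatenate(death_times) if death_times else np.empty(0)

    records = []
    for t in chase_times_h:
        t = float(t)
        brdu = _in_s_during(u, g1, s, c, t - cfg.brdu_pulse_h, t) & cycling
        phh3 = _in_phase_at(u, g1 + s, c, c, t) & cycling
        n_cc3 = int(np.sum((all_deaths > t - cfg.cc3_window_h) & (all_deaths <= t)))
        n_cc3 = min(n_cc3, n)
        edu_frac = float(np.mean(edu))
        n_cc3_edu = int(rng.binomial(n_cc3, edu_frac)) if n_cc3 else 0
        records.append(
            PulseRecord(
                chase_time_h=t,
                n_total=n,
                n_edu=int(np.sum(edu)),
                n_brdu=int(np.sum(brdu)),
                n_double=int(np.sum(edu & brdu)),
                n_phh3_edu=int(np.sum(edu & phh3)),
                n_cc3=n_cc3,
                n_cc3_edu=n_cc3_edu,
            )
        )
    return PulseTimeCourse(RegionId(region), records, brdu_offset_h=cfg.brdu_offset_h)


# ---------------------------------------------------------------------------
# Forward compartment simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimTEBConfig:
    """Ground truth for the forward compartment simulation."""

    params: tuple[RegionParams, ...]
    X_true: float = 0.0
    delta_true: float = 0.0
    donor_regions: tuple[int, ...] = (1, 2)
    timestep_h: float = 0.1
    horizon_h: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [max(p.r_per_h, p.d_per_h * (1 + self.delta_true)) for p in self.params]
        if self.timestep_h * max(rates) > 0.1:
            raise ConfigError("timestep too coarse: event probabilities must stay below 0.1")
        if not 0 <= self.X_true <= 1:
            raise ConfigError("X_true must lie in [0, 1]")


@dataclass
class ForwardSimResult:
    phi_hat_basal: float
    phi_hat_luminal: float
    phi_se_basal: float
    phi_se_luminal: float
    division_counts: dict[int, int]
    death_counts: dict[int, int]
    migration_count: int
    horizon_h: float

    def empirical_rates(self, params: Sequence[RegionParams]) -> dict[int, tuple[float, float]]:
        """Observed per-region (r_hat, d_hat) from event counts."""
        out = {}
        for p in params:
            i = p.region.index
            denom = p.N * self.horizon_h
            out[i] = (self.division_counts[i] / denom, self.death_counts[i] / denom)
        return out


def simulate_teb_forward(cfg: SimTEBConfig) -> ForwardSimResult:
    """Stochastic forward run of the fixed-region-size compartment model.

    Per step each cell independently divides (probability ``r dt``) or dies
    (``d dt``, luminal death inflated by ``1 + delta``); the events are
    mutually exclusive within a step.  Newborns in donor regions migrate to
    the maturity-paired body region with probability ``X``.  Each region
    then evicts its surplus downstream so its size never changes; cells
    evicted from the last pre-mature regions (3 basal, 7 luminal) are
    deposited in the mature duct.  The empirical deposition rates are the
    stochastic counterpart of the analytic layer fluxes.
    """
    rng = np.random.default_rng(cfg.seed)
    by = {p.region.index: p for p in cfg.params}
    dt = cfg.timestep_h
    n_steps = int(round(cfg.horizon_h / dt))
    donors = set(cfg.donor_regions)

    div_counts = {i: 0 for i in by}
    death_counts = {i: 0 for i in by}
    migration = 0
    dep_bas = np.zeros(n_steps)
    dep_lum = np.zeros(n_steps)

    for step in range(n_steps):
        births = {}
        deaths = {}
        migrants = {i: 0 for i in BASAL_REGIONS}
        for i, p in by.items():
            d_eff = p.d_per_h * (1 + cfg.delta_true) if i in LUMINAL_REGIONS else p.d_per_h
            n_div, n_die, _ = rng.multinomial(int(p.N), [p.r_per_h * dt, d_eff * dt,
                                                         1 - (p.r_per_h + d_eff) * dt])
            births[i] = int(n_div)
            deaths[i] = int(n_die)
            div_counts[i] += int(n_div)
            death_counts[i] += int(n_die)
            if i in donors and n_div:
                m = int(rng.binomial(n_div, cfg.X_true))
                migrants[i] = m
                migration += m

        influx = 0
        for i in BASAL_REGIONS:
            surplus = influx + births[i] - migrants.get(i, 0) - deaths[i]
            if by[i].N + surplus < 0:
                raise DataError(f"region {i} went extinct at t={step * dt:.1f} h")
            influx = surplus
        dep_bas[step] = influx
        influx = 0
        for i in LUMINAL_REGIONS:
            surplus = influx + births[i] + migrants.get(i - 4, 0) - deaths[i]
            if by[i].N + surplus < 0:
                raise DataError(f"region {i} went extinct at t={step * dt:.1f} h")
            influx = surplus
        dep_lum[step] = influx

    def rate_and_se(dep: np.ndarray) -> tuple[float, float]:
        per_h = dep / dt
        return float(np.mean(per_h)), float(np.std(per_h, ddof=1) / math.sqrt(n_steps))

    phi_b, se_b = rate_and_se(dep_bas)
    phi_l, se_l = rate_and_se(dep_lum)
    return ForwardSimResult(
        phi_hat_basal=phi_b, phi_hat_luminal=phi_l,
        phi_se_basal=se_b, phi_se_luminal=se_l,
        division_counts=div_counts, death_counts=death_counts,
        migration_count=migration, horizon_h=cfg.horizon_h,
    )


# ---------------------------------------------------------------------------
# Branching-path generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimPathConfig:
    """Ground truth for a 2-D tracked-tip growth path.

    Defaults emulate the whole-mount summary statistics: mean deflection
    35.5 deg, mean inter-bifurcation path 1141 um, and heading noise sized
    to a 6.1% path-vs-displacement underestimate.
    """

    mean_branch_angle_deg: float = 35.5
    sd_branch_angle_deg: float = 1.9
    mean_inter_bifurcation_um: float = 1141.0
    sd_inter_bifurcation_um: float = 99.1
    # calibrated so a 1141/10-step segment under-reports its path by 6.1%
    turning_noise_rad: float = 0.0827
    n_branches: int = 23
    step_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mean_branch_angle_deg < 90:
            raise ConfigError("mean branch angle must lie in [0, 90) deg")


def turning_noise_for_underestimate(
    u: float, mean_inter_bifurcation_um: float = 1141.0, step_um: float = 10.0
) -> float:
    """Per-step heading SD (rad) whose expected segment underestimate is u.

    With Brownian heading (per-step SD sigma) over n unit steps, the
    squared end-to-end displacement has expectation
    ``E|sum e^{i theta_k}|^2 = sum_{j,k} rho^{|j-k|}`` with
    ``rho = e^{-sigma^2/2}``, so the RMS displacement/path ratio is
    ``sqrt(S2)/n``; solve ``sqrt(S2)/n = 1 - u`` for sigma.
    """
    if not 0 <= u < 1:
        raise DataError("u must lie in [0, 1)")
    if u == 0:
        return 0.0
    n = mean_inter_bifurcation_um / step_um

    def ratio(sigma: float) -> float:
        rho = math.exp(-sigma**2 / 2.0)
        s2 = n * (1 + rho) / (1 - rho) - 2 * rho * (1 - rho**n) / (1 - rho) ** 2
        return math.sqrt(s2) / n

    return brentq(lambda s: ratio(s) - (1.0 - u), 1e-6, 1.5)


@dataclass
class DuctPath:
    measurements: PathMeasurements
    total_path_um: float
    total_displacement_um: float
    vertices: np.ndarray  # (k, 2) sampled positions


def generate_duct_path(cfg: SimPathConfig) -> DuctPath:
    """Grow a piecewise path: noisy straight runs punctuated by bifurcation
    deflections of random sign; the tracked tip follows a single branch.

    Returns the measurement table (per-bifurcation angle, per-segment path
    length and (path, displacement) pair) together with the exact total
    path length and end-to-end displacement.
    """
    rng = np.random.default_rng(cfg.seed)
    heading = 0.0
    pos = np.zeros(2)
    vertices = [pos.copy()]
    angles, seg_lengths, pairs = [], [], []
    total_path = 0.0

    for _ in range(cfg.n_branches):
        seg_target = max(rng.normal(cfg.mean_inter_bifurcation_um, cfg.sd_inter_bifurcation_um),
                         10 * cfg.step_um)
        n_steps = max(int(round(seg_target / cfg.step_um)), 1)
        start = pos.copy()
        seg_path = 0.0
        for _ in range(n_steps):
            if cfg.turning_noise_rad > 0:
                heading += rng.normal(0.0, cfg.turning_noise_rad)
            pos = pos + cfg.step_um * np.array([math.cos(heading), math.sin(heading)])
            seg_path += cfg.step_um
            vertices.append(pos.copy())
        disp = float(np.linalg.norm(pos - start))
        seg_lengths.append(seg_path)
        pairs.append((seg_path, disp))
        total_path += seg_path
        angle = min(max(rng.normal(cfg.mean_branch_angle_deg, cfg.sd_branch_angle_deg), 0.0), 89.9)
        angles.append(angle)
        heading += math.radians(angle) * rng.choice([-1.0, 1.0])

    measurements = PathMeasurements(
        deflection_angles_deg=tuple(angles),
        inter_bifurcation_path_um=tuple(seg_lengths),
        path_displacement_pairs=tuple(pairs),
    )
    return DuctPath(
        measurements=measurements,
        total_path_um=total_path,
        total_displacement_um=float(np.linalg.norm(pos)),
        vertices=np.array(vertices),
    )


# ---------------------------------------------------------------------------
# Gland displacement series
# ---------------------------------------------------------------------------


def generate_gland_course(
    true_rate_mm_day: float,
    noise_sd_mm: float = 0.0,
    ages_weeks: Sequence[float] = (5, 6, 7, 8),
    n_glands: int = 18,
    seed: int = 0,
    start_mm: float = 10.0,
) -> GlandTimeCourse:
    """Linear gland growth plus per-measurement normal noise, seeded."""
    if true_rate_mm_day < 0:
        raise DataError("growth rate must be >= 0")
    rng = np.random.default_rng(seed)
    a0 = float(min(ages_weeks))
    records = []
    for g in range(n_glands):
        for age in ages_weeks:
            d = start_mm + true_rate_mm_day * (age - a0) * 7.0
            if noise_sd_mm > 0:
                d += rng.normal(0.0, noise_sd_mm)
            records.append(GlandRecord(float(age), max(d, 0.0), gland_id=f"g{g + 1}"))
    return GlandTimeCourse(records)
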