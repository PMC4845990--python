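"""Compartmental flux-balance model of ductal elongation.

The terminal end bud holds a time-invariant cell number ``N_i`` in each of
its eight regions, so every cell born in excess of local death is pushed
downstream.  For region ``i`` with proliferation rate ``r_i`` and death rate
``d_i`` (both per cell per hour), stationarity reads

    0 = influx - outflux + (r_i - d_i) N_i

Summing along each layer, the net flux of cells deposited into the mature
duct is

    Phi_bas = sum_{i in 1..3} (r_i - d_i) N_i        (basal / cap layer)
    Phi_lum = sum_{i in 5..7} (r_i - d_i) N_i        (luminal / body layer)

and since a duct of length ``L`` exposes ``N = 2 L / l`` monolayer cells in
a 2-D longitudinal section, each layer elongates at

    lambda = (l / 2) Phi            [um/h; x 0.024 -> mm/day]

Four nested model variants refine this base model:

1. base model (above);
2. cap-cell flux: a fraction ``X`` of newborn basal cells migrates into the
   body layer, moving ``phi_bas->lum = X sum_{donors} r_i N_i`` cells/h from
   the basal to the luminal flux;
3. apoptotic correction: measured luminal death is underdetected, so
   ``d_i -> d_i (1 + delta)`` in regions 5-7;
4. tortuosity: the duct path winds, so linear elongation is divided by the
   tortuosity ``T`` to give the straight-line displacement rate.

Because the two layers adhere, they must elongate at the same rate; the
matching condition ``lambda_bas = lambda_lum`` is linear in ``X`` and is
solved in closed form.  Uncertainty on every input propagates by seeded
Monte Carlo with independent zero-truncated normal draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, DataError, FluxError
from .geometry import RegionId

__all__ = [
    "RegionParams",
    "ModelConfig",
    "FluxSet",
    "ElongationEstimate",
    "UM_PER_H_TO_MM_PER_DAY",
    "balance_residual",
    "compute_fluxes",
    "elongation_rate",
    "run_model",
    "solve_matching_X",
    "minimal_delta",
    "cap_fraction_from_counts",
    "propagate_uncertainty",
    "TEBElongationModel",
    "ElongationResults",
]

#: 1 um/h = 24/1000 mm/day
UM_PER_H_TO_MM_PER_DAY = 0.024

BASAL_REGIONS = (1, 2, 3)
LUMINAL_REGIONS = (5, 6, 7)
#: basal region i leaks migrating newborns into its maturity-paired body region
PAIRED_LUMINAL = {1: 5, 2: 6, 3: 7}


@dataclass(frozen=True)
class RegionParams:
    """Time-invariant cell number and per-hour vital rates of one region."""

    region: RegionId
    N: float
    r_per_h: float
    d_per_h: float
    N_se: float = 0.0
    r_se: float = 0.0
    d_se: float = 0.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise DataError(f"region {self.region.index}: N must be > 0")
        if self.r_per_h < 0 or self.d_per_h < 0:
            raise DataError(f"region {self.region.index}: rates must be >= 0")
        if min(self.N_se, self.r_se, self.d_se) < 0:
            raise DataError("standard errors must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Layer cell lengths and the variant parameters (X, delta, T)."""

    cell_length_basal_um: float
    cell_length_luminal_um: float
    delta: Optional[float] = None
    X: Optional[float] = None
    donor_regions: tuple[int, ...] = (1, 2)
    T: Optional[float] = None
    pulse_window_h: float = 2.0
    s_phase_h: float = 6.0
    cc3_window_h: float = 8.0

    def __post_init__(self) -> None:
        if self.cell_length_basal_um <= 0 or self.cell_length_luminal_um <= 0:
            raise ConfigError("cell lengths must be > 0")
        if self.delta is not None and self.delta < 0:
            raise ConfigError("delta must be >= 0")
        if self.X is not None and not 0 <= self.X <= 1:
            raise ConfigError("X must lie in [0, 1]")
        if self.T is not None and self.T < 1:
            raise ConfigError("tortuosity T must be >= 1")
        if not set(self.donor_regions) <= set(BASAL_REGIONS):
            raise ConfigError("donor regions must be a subset of {1, 2, 3}")


@dataclass(frozen=True)
class FluxSet:
    """Net layer fluxes and the region-chain fluxes they decompose into (cells/h)."""

    phi_basal: float
    phi_luminal: float
    phi_bas_to_lum: float
    chain: dict[str, float]
    shrinking_layer: bool = False  # negative net flux is representable, just flagged


@dataclass(frozen=True)
class ElongationEstimate:
    """Per-layer elongation rate for one model variant (mm/day)."""

    model_variant: int
    lambda_basal: float
    lambda_luminal: float
    config: ModelConfig
    lambda_basal_halfwidth: float = 0.0
    lambda_luminal_halfwidth: float = 0.0
    fluxes: Optional[FluxSet] = None


def _params_by_region(params: Sequence[RegionParams]) -> dict[int, RegionParams]:
    by = {p.region.index: p for p in params}
    missing = set(range(1, 9)) - set(by)
    if missing:
        raise DataError(f"missing region parameters: {sorted(missing)}")
    return by


def balance_residual(p: RegionParams, influx_per_h: float, outflux_per_h: float) -> float:
    """Stationarity residual for one region: influx - outflux + (r - d) N."""
    return influx_per_h - outflux_per_h + (p.r_per_h - p.d_per_h) * p.N


def compute_fluxes(
    params: Sequence[RegionParams],
    cfg: ModelConfig,
    apply_delta: bool = False,
) -> FluxSet:
    """Net layer fluxes and chain fluxes under a given configuration.

    The basal->luminal leak ``X sum_donors r_i N_i`` is removed from the
    basal chain region-wise, each donor contributing in proportion to its
    own newborn production, and injected into the maturity-paired luminal
    region.  ``apply_delta`` inflates luminal death to ``d (1 + delta)``.
    """
    by = _params_by_region(params)
    x = cfg.X or 0.0
    delta = (cfg.delta or 0.0) if apply_delta else 0.0

    leak = {i: (x * by[i].r_per_h * by[i].N if i in cfg.donor_regions else 0.0) for i in BASAL_REGIONS}
    phi_bas_to_lum = sum(leak.values())

    def net(i: int) -> float:
        p = by[i]
        d = p.d_per_h * (1.0 + delta) if i in LUMINAL_REGIONS else p.d_per_h
        return (p.r_per_h - d) * p.N

    chain: dict[str, float] = {}
    acc = 0.0
    for i in BASAL_REGIONS:
        acc += net(i) - leak[i]
        chain[f"phi_{i}->{i + 1}"] = acc
    phi_basal = acc
    acc = 0.0
    for i in LUMINAL_REGIONS:
        acc += net(i) + leak[i - 4]
        chain[f"phi_{i}->{i + 1}"] = acc
    phi_luminal = acc

    return FluxSet(
        phi_basal=phi_basal,
        phi_luminal=phi_luminal,
        phi_bas_to_lum=phi_bas_to_lum,
        chain=chain,
        shrinking_layer=(phi_basal < 0 or phi_luminal < 0),
    )


def elongation_rate(phi_cells_per_h: float, cell_length_um: float) -> float:
    """mm/day elongation of a monolayer fed ``Phi`` cells/h: (l/2) Phi x 0.024."""
    if cell_length_um <= 0:
        raise ConfigError("cell length must be > 0")
    return cell_length_um / 2.0 * phi_cells_per_h * UM_PER_H_TO_MM_PER_DAY


def _require(cfg: ModelConfig, variant: int) -> None:
    if variant not in (1, 2, 3, 4):
        raise ConfigError(f"variant must be 1..4, got {variant}")
    if variant >= 2 and cfg.X is None:
        raise ConfigError(f"variant {variant} requires the cap-cell fraction X")
    if variant >= 3 and cfg.delta is None:
        raise ConfigError(f"variant {variant} requires the apoptotic correction delta")
    if variant >= 4 and cfg.T is None:
        raise ConfigError("variant 4 requires the tortuosity T")


def run_model(params: Sequence[RegionParams], cfg: ModelConfig, variant: int) -> ElongationEstimate:
    """Elongation (variants 1-3) or displacement (variant 4) rates in mm/day."""
    _require(cfg, variant)
    eff = cfg
    if variant == 1:
        eff = replace(cfg, X=0.0, delta=None, T=None)
    fluxes = compute_fluxes(
        [p for p in _params_by_region(params).values()], eff, apply_delta=(variant >= 3)
    )
    lam_bas = elongation_rate(fluxes.phi_basal, cfg.cell_length_basal_um)
    lam_lum = elongation_rate(fluxes.phi_luminal, cfg.cell_length_luminal_um)
    if variant == 4:
        lam_bas /= cfg.T  # type: ignore[operator]
        lam_lum /= cfg.T  # type: ignore[operator]
    return ElongationEstimate(
        model_variant=variant, lambda_basal=lam_bas, lambda_luminal=lam_lum,
        config=eff if variant == 1 else cfg, fluxes=fluxes,
    )


def solve_matching_X(params: Sequence[RegionParams], cfg: ModelConfig) -> tuple[float, bool]:
    """Cap-cell fraction X at which both layers elongate equally.

    With delta fixed, both rates are linear in X and the matching condition
    ``lambda_bas(X) = lambda_lum(X)`` solves in closed form:

        X = (l_bas Phi_bas - l_lum Phi_lum^delta) / ((l_bas + l_lum) P)

    where ``P = sum_donors r_i N_i`` and ``Phi_lum^delta`` uses the corrected
    luminal death rates.  Tortuosity cancels.  Returns ``(X, in_range)``;
    out-of-range solutions are clipped to [0, 1] and flagged rather than
    raised, since wide admissible ranges are part of the fit analysis.
    """
    by = _params_by_region(params)
    production = sum(by[i].r_per_h * by[i].N for i in cfg.donor_regions)
    if production <= 0:
        raise FluxError("donor regions produce no newborn cells; X is undefined")
    base = replace(cfg, X=0.0)
    f = compute_fluxes(list(by.values()), base, apply_delta=cfg.delta is not None)
    l_b, l_l = cfg.cell_length_basal_um, cfg.cell_length_luminal_um
    x = (l_b * f.phi_basal - l_l * f.phi_luminal) / ((l_b + l_l) * production)
    in_range = 0.0 <= x <= 1.0
    return (float(min(max(x, 0.0), 1.0)), in_range) if not in_range else (float(x), True)


def minimal_delta(measured_luminal_index: float, corrected_index: float) -> float:
    """Apoptotic correction factor from measured vs corrected luminal indices.

    The correction is multiplicative on death rates, ``d -> d (1 + delta)``,
    hence on indices: ``corrected = measured (1 + delta)`` and
    ``delta = corrected / measured - 1``.  A corrected index below the
    measured one yields a negative delta (returned as-is; caller may warn).
    """
    if measured_luminal_index <= 0:
        raise DataError("measured index must be > 0")
    return corrected_index / measured_luminal_index - 1.0


def cap_fraction_from_counts(
    sma_counts_by_region: dict[int, float],
    params: Sequence[RegionParams],
    donor_regions: Sequence[int] = (1, 2),
    residence_time_h: float = 8.0,
) -> float:
    """Experimentally-grounded cap-cell migration fraction X*.

    Cap (SMA+) cells resident in body regions 5-6 die there and are replaced;
    at steady state the replacement flux is their standing number divided by
    their residence time (defaulting to the apoptosis-marker window).  X* is
    that flux over the newborn-cap production of the donor regions,
    ``sum_donors r_i N_i``.
    """
    by = _params_by_region(params)
    production = sum(by[i].r_per_h * by[i].N for i in donor_regions)
    if production <= 0:
        raise FluxError("zero newborn-cap production; X* undefined")
    if residence_time_h <= 0:
        raise DataError("residence time must be > 0")
    resident = sum(v for k, v in sma_counts_by_region.items() if k in LUMINAL_REGIONS)
    return (resident / residence_time_h) / production


def propagate_uncertainty(
    params: Sequence[RegionParams],
    cfg: ModelConfig,
    variant: int,
    n_draws: int = 2000,
    seed: int | None = None,
) -> ElongationEstimate:
    """Monte-Carlo error propagation through a model variant.

    Every uncertain input (N, r, d with non-zero standard errors) is drawn
    independently from a normal truncated at zero; the model is re-run per
    draw and the standard deviation of each layer's rate is reported as its
    half-width.
    """
    if n_draws < 100:
        raise ConfigError("n_draws must be >= 100")
    _require(cfg, variant)
    rng = np.random.default_rng(seed)
    point = run_model(params, cfg, variant)
    if all(p.N_se == p.r_se == p.d_se == 0.0 for p in params):
        return point  # no uncertain inputs: half-widths are exactly zero

    def draw(mean: float, se: float) -> np.ndarray:
        if se == 0:
            return np.full(n_draws, mean)
        a = (0.0 - mean) / se  # truncate at zero
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=se, size=n_draws, random_state=rng)

    draws = {
        p.region.index: (draw(p.N, p.N_se), draw(p.r_per_h, p.r_se), draw(p.d_per_h, p.d_se))
        for p in params
    }
    lam_b = np.empty(n_draws)
    lam_l = np.empty(n_draws)
    for k in range(n_draws):
        sampled = [
            RegionParams(p.region, draws[p.region.index][0][k],
                         draws[p.region.index][1][k], draws[p.region.index][2][k])
            for p in params
        ]
        est = run_model(sampled, cfg, variant)
        lam_b[k] = est.lambda_basal
        lam_l[k] = est.lambda_luminal
    return replace(
        point,
        lambda_basal_halfwidth=float(np.std(lam_b, ddof=1)),
        lambda_luminal_halfwidth=float(np.std(lam_l, ddof=1)),
    )


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class TEBElongationModel:
    """Flux-balance elongation model over an eight-region parameter set.

    Parameters
    ----------
    params
        Eight :class:`RegionParams`, one per region.
    config
        Layer cell lengths and the variant parameters.

    Examples
    --------
    >>> model = TEBElongationModel.from_dataframe(df, config)
    >>> res = model.fit(variant=4, n_draws=2000, seed=0)
    >>> print(res.summary())
    """

    def __init__(self, params: Sequence[RegionParams], config: ModelConfig):
        self.params = list(_params_by_region(params).values())
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ModelConfig) -> "TEBElongationModel":
        """Build from a frame with columns region, N, r_per_h, d_per_h [, *_se]."""
        params = []
        for _, row in df.iterrows():
            params.append(
                RegionParams(
                    RegionId(int(row["region"])), float(row["N"]),
                    float(row["r_per_h"]), float(row["d_per_h"]),
                    float(row.get("N_se", 0.0) or 0.0),
                    float(row.get("r_se", 0.0) or 0.0),
                    float(row.get("d_se", 0.0) or 0.0),
                )
            )
        return cls(params, config)

    @classmethod
    def from_param_file(cls, path: str | Path) -> "TEBElongationModel":
        """Load a YAML parameter file (see the packaged fixture for the layout)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cfg = ModelConfig(
            cell_length_basal_um=float(doc["cell_length_basal_um"]),
            cell_length_luminal_um=float(doc["cell_length_luminal_um"]),
            delta=doc.get("delta"),
            X=doc.get("X"),
            donor_regions=tuple(doc.get("donor_regions", (1, 2))),
            T=doc.get("T"),
        )
        params = [
            RegionParams(
                RegionId(int(i)), float(entry["N"]), float(entry["r"]), float(entry["d"]),
                float(entry.get("N_se", 0.0)), float(entry.get("r_se", 0.0)),
                float(entry.get("d_se", 0.0)),
            )
            for i, entry in doc["regions"].items()
        ]
        return cls(params, cfg)

    def fit(
        self,
        variant: int = 4,
        solve_x: bool = False,
        n_draws: int = 0,
        seed: int | None = None,
    ) -> "ElongationResults":
        """Evaluate the requested variant; optionally solve the matching condition.

        ``solve_x`` replaces the configured X by the matching-condition
        solution before evaluating.  ``n_draws > 0`` adds Monte-Carlo
        half-widths on both rates.
        """
        cfg = self.config
        x_matched = None
        x_in_range = True
        if solve_x:
            x_matched, x_in_range = solve_matching_X(self.params, cfg)
            cfg = replace(cfg, X=x_matched)
        if n_draws:
            est = propagate_uncertainty(self.params, cfg, variant, n_draws=n_draws, seed=seed)
        else:
            est = run_model(self.params, cfg, variant)
        return ElongationResults(self, est, x_matched=x_matched, x_in_range=x_in_range)


class ElongationResults:
    """Fitted elongation rates with uncertainties and flux diagnostics."""

    def __init__(
        self,
        model: TEBElongationModel,
        estimate: ElongationEstimate,
        x_matched: float | None = None,
        x_in_range: bool = True,
    ):
        self.model = model
        self.estimate = estimate
        self.x_matched = x_matched
        self.x_in_range = x_in_range

    @property
    def lambda_basal(self) -> float:
        return self.estimate.lambda_basal

    @property
    def lambda_luminal(self) -> float:
        return self.estimate.lambda_luminal

    @property
    def fluxes(self) -> FluxSet:
        assert self.estimate.fluxes is not None
        return self.estimate.fluxes

    def residuals(self) -> dict[int, float]:
        """Stationarity residual per region given the fitted chain fluxes.

        Exactly zero by construction; a reusable self-check when parameters
        or fluxes are edited by hand.
        """
        by = {p.region.index: p for p in self.model.params}
        cfg = self.estimate.config
        delta = (cfg.delta or 0.0) if self.estimate.model_variant >= 3 else 0.0
        x = cfg.X or 0.0
        chain = self.fluxes.chain
        out: dict[int, float] = {}
        for layer in (BASAL_REGIONS, LUMINAL_REGIONS):
            influx = 0.0
            for i in layer:
                p = by[i]
                d_eff = p.d_per_h * (1.0 + delta) if i in LUMINAL_REGIONS else p.d_per_h
                outflux = chain[f"phi_{i}->{i + 1}"]
                if i in BASAL_REGIONS and i in cfg.donor_regions:
                    outflux += x * p.r_per_h * p.N
                if i in LUMINAL_REGIONS:
                    influx += x * by[i - 4].r_per_h * by[i - 4].N if (i - 4) in cfg.donor_regions else 0.0
                peff = RegionParams(p.region, p.N, p.r_per_h, d_eff)
                out[i] = balance_residual(peff, influx, outflux)
                influx = chain[f"phi_{i}->{i + 1}"]
        return out

    def to_dict(self) -> dict:
        e = self.estimate
        return {
            "variant": e.model_variant,
            "lambda_basal_mm_day": e.lambda_basal,
            "lambda_luminal_mm_day": e.lambda_luminal,
            "lambda_basal_halfwidth": e.lambda_basal_halfwidth,
            "lambda_luminal_halfwidth": e.lambda_luminal_halfwidth,
            "phi_basal_per_h": self.fluxes.phi_basal,
            "phi_luminal_per_h": self.fluxes.phi_luminal,
            "phi_bas_to_lum_per_h": self.fluxes.phi_bas_to_lum,
            "X": e.config.X,
            "x_matched": self.x_matched,
            "x_in_range": self.x_in_range,
            "delta": e.config.delta,
            "T": e.config.T,
        }

    def summary(self) -> str:
        e = self.estimate
        lines = [
            f"TEB elongation model — variant {e.model_variant}",
            "=" * 46,
            f"{'rate kind':<24}{'displacement' if e.model_variant == 4 else 'linear elongation'}",
            f"{'lambda basal':<24}{e.lambda_basal:.2f} ± {e.lambda_basal_halfwidth:.2f} mm/day",
            f"{'lambda luminal':<24}{e.lambda_luminal:.2f} ± {e.lambda_luminal_halfwidth:.2f} mm/day",
            f"{'Phi basal':<24}{self.fluxes.phi_basal:.3f} cells/h",
            f"{'Phi luminal':<24}{self.fluxes.phi_luminal:.3f} cells/h",
            f"{'phi bas->lum':<24}{self.fluxes.phi_bas_to_lum:.3f} cells/h",
        ]
        if e.config.X is not None:
            lines.append(f"{'X (cap-cell fraction)':<24}{e.config.X:.2f}"
                         + ("  [matching condition]" if self.x_matched is not None else ""))
        if self.x_matched is not None and not self.x_in_range:
            lines.append("warning: matching X outside [0, 1]; clipped")
        if e.config.delta is not None:
            lines.append(f"{'delta (apoptotic corr.)':<24}{e.config.delta:.2f}")
        if e.config.T is not None:
            lines.append(f"{'T (tortuosity)':<24}{e.config.T:.2f}")
        if self.fluxes.shrinking_layer:
            lines.append("warning: a layer has negative net flux (shrinking)")
        return "\n".join(lines)
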