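"""Synthetic data emulating calibration and batch-growth experiments.

The generators reproduce the statistical structure of two measurement
systems and one cultivation experiment so that the whole toolchain can be
exercised without instrument data:

* a glucose assay (absorbance at 365 nm vs. concentration): saturating
  asymmetric-logistic trend, Student-t noise whose scale grows linearly
  with the location, 96 standards log-evenly spaced 0.075-50 g/L;
* a biomass/backscatter relation (microbioreactor scattered-light readout
  vs. cell dry weight): asymmetric logistic in log10(CDW), 48 standards;
* a 28-well batch-growth experiment following Monod kinetics: each well is
  inoculated at X0_well = X0_mu * F_offset (lognormal pipetting offsets),
  backscatter is sampled on a 4-minute cycle until the well is sacrificed,
  and a single glucose observation is taken at the sacrifice time
  (wells are harvested, so the series ends there).

Default true parameters (mu_max=0.42 1/h, Y_XS=0.6, S0=20 g/L,
X0_mu=0.25 g/L, offset sd 0.2, K_S=0.02 g/L) are the experiment scale the
priors in :mod:`biocal.bayes` describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calibration import CalibrationModel, NoiseSpec
from .curves import AsymLogisticParams
from .multirep import Dataset, Replicate, Timeseries, make_monod_template, solve_replicate

__all__ = [
    "GLUCOSE_TREND",
    "BIOMASS_TREND",
    "true_glucose_model",
    "true_biomass_model",
    "generate_calibration_data",
    "glucose_standards",
    "biomass_standards",
    "GrowthExperimentConfig",
    "generate_growth_dataset",
]

# true measurement-system parameters used by the generators
GLUCOSE_TREND = AsymLogisticParams(L_L=0.14, L_U=1.90, I_x=8.0, S=0.3, c=-1.0)
GLUCOSE_SCALE = (0.002, 0.01)  # scale = 0.002 + 0.01*mu (~1-3% relative)
GLUCOSE_NU = 8.0
BIOMASS_TREND = AsymLogisticParams(L_L=1.2, L_U=42.0, I_x=0.35, S=30.0, c=-0.5)
BIOMASS_SCALE = (0.3, 0.015)  # ~20% relative spread at low CDW, ~2% above 10 g/L
BIOMASS_NU = 6.0


def glucose_standards(n: int = 96, lo: float = 0.075, hi: float = 50.0) -> np.ndarray:
    """Concentrations log-evenly spaced across the assay range [g/L]."""
    return np.geomspace(lo, hi, n)


def biomass_standards(n: int = 48, lo: float = 0.015, hi: float = 15.0) -> np.ndarray:
    """Cell-dry-weight standards log-evenly spaced [g/L]."""
    return np.geomspace(lo, hi, n)


def _true_model(trend, scale, nu, trend_type, independent_key, dependent_key, x_range):
    theta = np.concatenate([trend.as_array(), scale, [nu]])
    return CalibrationModel(
        independent_key=independent_key,
        dependent_key=dependent_key,
        noise=NoiseSpec(family="student_t", trend=trend_type, scale_degree=1),
        theta=theta,
        cal_x=np.asarray(x_range, dtype=float),
        cal_y=np.zeros(len(x_range)),
    )


def true_glucose_model() -> CalibrationModel:
    """The generating glucose-assay model (not fitted; exact parameters)."""
    return _true_model(
        GLUCOSE_TREND,
        GLUCOSE_SCALE,
        GLUCOSE_NU,
        "asymmetric_logistic",
        "S",
        "absorbance",
        glucose_standards(),
    )


def true_biomass_model() -> CalibrationModel:
    """The generating biomass/backscatter model (logistic in log10 CDW)."""
    return _true_model(
        BIOMASS_TREND,
        BIOMASS_SCALE,
        BIOMASS_NU,
        "log_independent_asymmetric_logistic",
        "X",
        "backscatter",
        biomass_standards(),
    )


def generate_calibration_data(
    model: CalibrationModel,
    x_targets,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw calibration responses from a model's predicted distributions."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x_targets, dtype=float)
    d = model.predict_dependent(x)
    if d.nu is not None:
        y = stats.t.rvs(df=d.nu, loc=d.mu, scale=d.scale, random_state=rng)
    else:
        y = stats.norm.rvs(loc=d.mu, scale=d.scale, random_state=rng)
    return x, np.asarray(y)


def _well_ids(n: int) -> list:
    rows = "ABCDEFGH"
    ids = []
    c = 2
    while len(ids) < n:
        for r in rows[:4]:
            ids.append(f"{r}{c:02d}")
            if len(ids) == n:
                break
        c += 1
    return ids


@dataclass
class GrowthExperimentConfig:
    """Design + true parameters of the synthetic batch-growth experiment."""

    n_wells: int = 28
    mu_max: float = 0.42  # 1/h
    Y_XS: float = 0.6  # gCDW/gglucose
    S0: float = 20.0  # g/L
    X0_mu: float = 0.25  # g/L
    offset_sd: float = 0.2  # lognormal sd of per-well inoculum offsets
    K_S: float = 0.02  # g/L
    dt: float = 4.0 / 60.0  # h; backscatter cycle time
    t_max: float = 15.0  # h; experiment horizon
    sacrifice_times: Optional[Sequence[float]] = None  # default: spread over 1..t_max
    cal_biomass: CalibrationModel = field(default_factory=true_biomass_model)
    cal_glucose: CalibrationModel = field(default_factory=true_glucose_model)
    seed: int = 0

    def resolved_sacrifice_times(self) -> np.ndarray:
        if self.sacrifice_times is not None:
            t = np.asarray(self.sacrifice_times, dtype=float)
            if t.size != self.n_wells:
                raise ValueError("need one sacrifice time per well")
        else:
            t = np.linspace(1.0, self.t_max, self.n_wells)
        if np.any(t < 0) or np.any(t > self.t_max + 1e-9):
            raise ValueError("sacrifice times must lie within [0, t_max]")
        # snap onto the measurement grid
        return np.round(t / self.dt).astype(int) * self.dt


def generate_growth_dataset(cfg: GrowthExperimentConfig, return_truth: bool = False):
    """Simulate the multi-well growth experiment as a :class:`Dataset`.

    Per well: the latent Monod trajectory is solved with the well-specific
    inoculum X0_well, backscatter responses are drawn from the biomass
    calibration model on the measurement grid up to the sacrifice time, and
    one glucose response is drawn at the sacrifice time.  With
    ``return_truth=True`` the realized latent parameters are also returned.
    """
    if cfg.n_wells < 1:
        raise ValueError("need at least one well")
    rng = np.random.default_rng(cfg.seed)
    template = make_monod_template()
    t_sac = cfg.resolved_sacrifice_times()
    rids = _well_ids(cfg.n_wells)
    offsets = np.exp(rng.normal(0.0, cfg.offset_sd, size=cfg.n_wells)) if cfg.offset_sd > 0 else np.ones(cfg.n_wells)
    ds = Dataset()
    truth = {
        "mu_max": cfg.mu_max,
        "Y_XS": cfg.Y_XS,
        "S0": cfg.S0,
        "X0_mu": cfg.X0_mu,
        "F_offset": dict(zip(rids, offsets)),
        "sacrifice_times": dict(zip(rids, t_sac)),
    }
    bs_key = cfg.cal_biomass.dependent_key
    glc_key = cfg.cal_glucose.dependent_key
    for rid, f_w, ts in zip(rids, offsets, t_sac):
        x0_w = cfg.X0_mu * f_w
        n_steps = int(round(ts / cfg.dt))
        grid = np.arange(n_steps + 1) * cfg.dt
        params = np.array([cfg.S0, x0_w, cfg.mu_max, cfg.K_S, cfg.Y_XS])
        latent = solve_replicate(template, grid, params, rid=rid)
        X = latent["X"].y
        S = max(float(latent["S"].y[-1]), 0.0)
        d_bs = cfg.cal_biomass.predict_dependent(np.maximum(X, 1e-12))
        y_bs = stats.t.rvs(df=d_bs.nu, loc=d_bs.mu, scale=d_bs.scale, random_state=rng)
        d_glc = cfg.cal_glucose.predict_dependent(S)
        y_glc = stats.t.rvs(df=d_glc.nu, loc=d_glc.mu, scale=d_glc.scale, random_state=rng)
        rep = Replicate(rid=rid)
        rep.add(Timeseries(t=grid, y=np.atleast_1d(y_bs), independent_key="X", dependent_key=bs_key))
        rep.add(
            Timeseries(
                t=[grid[-1]], y=[float(y_glc)], independent_key="S", dependent_key=glc_key
            )
        )
        ds.add(rep)
    return (ds, truth) if return_truth else ds
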