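"""Multi-replicate time-series datasets and templated ODE process models.

Experimental data from parallel reaction vessels is heterogeneous: each
vessel (replicate) carries several time series of different lengths and
observation types.  The containers here mirror that structure in three
levels: :class:`Timeseries` (one observed or predicted variable),
:class:`Replicate` (one vessel) and :class:`Dataset` (the whole experiment).

A :class:`ParameterMapping` table translates a single flat parameter vector
into per-replicate parameter vectors, expressing which parameters are shared
across replicates, local to one, or fixed constants.  Combined with an ODE
template (e.g. Monod growth kinetics) and calibration models for each
observation type, :func:`objective_for_dataset` builds the summed
log-likelihood over the entire dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .calibration import CalibrationModel

__all__ = [
    "Timeseries",
    "Replicate",
    "Dataset",
    "ParameterMapping",
    "ODEModelTemplate",
    "MonodParams",
    "monod_dydt",
    "make_monod_template",
    "solve_replicate",
    "objective_for_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class Timeseries:
    """Time/value vectors of one state variable or observation series."""

    t: np.ndarray
    y: np.ndarray
    independent_key: str
    dependent_key: str

    def __post_init__(self) -> None:
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("t must be nondecreasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class Replicate:
    """Observations (or predictions) from a single reaction vessel."""

    rid: str
    series: Dict[str, Timeseries] = field(default_factory=dict)

    def add(self, ts: Timeseries) -> None:
        if ts.dependent_key in self.series:
            raise ValueError(f"duplicate dependent_key {ts.dependent_key!r} in {self.rid!r}")
        self.series[ts.dependent_key] = ts

    def __getitem__(self, key: str) -> Timeseries:
        return self.series[key]

    def __iter__(self):
        return iter(self.series.values())


@dataclass
class Dataset:
    """Replicates of multiple reaction vessels, keyed by replicate id."""

    replicates: Dict[str, Replicate] = field(default_factory=dict)

    def add(self, rep: Replicate) -> None:
        if rep.rid in self.replicates:
            raise ValueError(f"duplicate replicate id {rep.rid!r}")
        self.replicates[rep.rid] = rep

    def __getitem__(self, rid: str) -> Replicate:
        return self.replicates[rid]

    def __iter__(self):
        return iter(self.replicates.values())

    def __len__(self) -> int:
        return len(self.replicates)


class ParameterMapping:
    """Table translating a flat parameter vector into per-replicate vectors.

    Rows are replicate ids, columns are the ODE template's parameter names.
    A cell holds either a symbolic parameter name (shared when it appears in
    several rows, local when unique) or a numeric constant excluded from
    estimation.  The flat vector is ordered by the lexicographically sorted
    unique symbolic names.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        bounds: Dict[str, tuple],
        guesses: Dict[str, float],
    ):
        self.table = table.copy()
        self.bounds = dict(bounds)
        self.guesses = dict(guesses)
        names_by_col: Dict[str, set] = {}
        for col in table.columns:
            for cell in table[col]:
                if self._as_number(cell) is None:
                    names_by_col.setdefault(str(cell), set()).add(col)
        for name, cols in names_by_col.items():
            if len(cols) > 1:
                raise ValueError(
                    f"parameter name {name!r} appears in multiple columns: {sorted(cols)}"
                )
            if name not in self.bounds:
                raise ValueError(f"no bounds for parameter {name!r}")
            if name not in self.guesses:
                raise ValueError(f"no guess for parameter {name!r}")
        self.free_names: List[str] = sorted(names_by_col)

    @staticmethod
    def _as_number(cell) -> Optional[float]:
        if isinstance(cell, (int, float, np.floating, np.integer)):
            return float(cell)
        try:
            return float(str(cell))
        except ValueError:
            return None

    @property
    def ndim(self) -> int:
        return len(self.free_names)

    @property
    def bounds_list(self) -> List[tuple]:
        return [self.bounds[n] for n in self.free_names]

    @property
    def guess_vector(self) -> np.ndarray:
        return np.array([self.guesses[n] for n in self.free_names], dtype=float)

    def repmap(self, full_vector) -> Dict[str, np.ndarray]:
        """Expand the flat vector into per-replicate parameter vectors."""
        if isinstance(full_vector, dict):
            missing = set(self.free_names) - set(full_vector)
            extra = set(full_vector) - set(self.free_names)
            if missing or extra:
                raise ValueError(f"missing={sorted(missing)} extra={sorted(extra)}")
            values = dict(full_vector)
        else:
            full_vector = np.asarray(full_vector, dtype=float)
            if full_vector.size != self.ndim:
                raise ValueError(
                    f"full vector has {full_vector.size} entries, mapping needs {self.ndim}"
                )
            values = dict(zip(self.free_names, full_vector))
        out = {}
        for rid, row in self.table.iterrows():
            vec = []
            for cell in row:
                num = self._as_number(cell)
                vec.append(num if num is not None else values[str(cell)])
            out[str(rid)] = np.array(vec, dtype=float)
        return out

    @classmethod
    def from_csv(cls, path, bounds, guesses) -> "ParameterMapping":
        table = pd.read_csv(path, index_col=0)
        return cls(table, bounds, guesses)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="rid")


@dataclass
class ODEModelTemplate:
    """Names + right-hand side of an ODE process model for one replicate."""

    parameter_names: Sequence[str]
    state_names: Sequence[str]
    dydt: Callable  # (state, t, params) -> derivatives
    initial_state: Callable  # (params) -> y0


@dataclass(frozen=True)
class MonodParams:
    """Monod batch-growth parameters; all strictly positive.

    S0 [g/L] initial substrate, X0 [g/L] initial biomass, mu_max [1/h]
    maximum specific growth rate, K_S [g/L] half-saturation substrate
    concentration, Y_XS [gCDW/gglucose] biomass yield on substrate.
    """

    S0: float
    X0: float
    mu_max: float
    K_S: float
    Y_XS: float

    def __post_init__(self) -> None:
        for name in ("S0", "X0", "mu_max", "K_S", "Y_XS"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.X0, self.mu_max, self.K_S, self.Y_XS])


def monod_dydt(state, t, p: MonodParams):
    """Monod kinetics: dX/dt = mu_max*X*S/(K_S+S), dS/dt = -dX/dt / Y_XS."""
    return _monod_rhs(state, t, p.as_array())


def _monod_rhs(state, t, params):
    # params ordered (S0, X0, mu_max, K_S, Y_XS); states clipped at 0 to
    # protect against integrator undershoot near substrate depletion
    X = max(state[0], 0.0)
    S = max(state[1], 0.0)
    mu_max, K_S, Y_XS = params[2], params[3], params[4]
    dX = mu_max * X * S / (K_S + S)
    return np.array([dX, -dX / Y_XS])


def make_monod_template() -> ODEModelTemplate:
    """Monod growth template with parameters (S0, X0, mu_max, K_S, Y_XS)."""
    return ODEModelTemplate(
        parameter_names=("S0", "X0", "mu_max", "K_S", "Y_XS"),
        state_names=("X", "S"),
        dydt=_monod_rhs,
        initial_state=lambda p: np.array([p[1], p[0]]),  # (X0, S0)
    )


def solve_replicate(
    template: ODEModelTemplate,
    t_out,
    params,
    y0=None,
    rid: str = "prediction",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Replicate:
    """Integrate the template's ODE and sample the states exactly at t_out."""
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    if np.any(np.diff(t_out) < 0):
        raise ValueError("t_out must be nondecreasing")
    params = np.asarray(params, dtype=float)
    if y0 is None:
        y0 = template.initial_state(params)
    y0 = np.asarray(y0, dtype=float)
    if t_out[-1] > t_out[0]:
        sol = solve_ivp(
            lambda t, y: template.dydt(y, t, params),
            (t_out[0], t_out[-1]),
            y0,
            t_eval=t_out,
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed for replicate {rid!r}: {sol.message}")
        states = sol.y
    else:
        states = np.tile(y0[:, None], (1, t_out.size))
    rep = Replicate(rid=rid)
    for i, name in enumerate(template.state_names):
        rep.add(Timeseries(t=t_out, y=states[i], independent_key=name, dependent_key=name))
    return rep


def objective_for_dataset(
    dataset: Dataset,
    template: ODEModelTemplate,
    mapping: ParameterMapping,
    cal_models: Dict[str, CalibrationModel],
    cal_overrides: Optional[Dict[str, Dict[str, CalibrationModel]]] = None,
):
    """Build full_vector -> total log-likelihood over all replicates.

    Each replicate is solved once on the union of its observed time grids;
    every observed series is scored with the calibration model registered
    for its dependent_key (``cal_overrides[rid]`` takes precedence over the
    global map).  Parameter vectors outside the feasible region (e.g.
    non-positive predicted concentrations under a log trend) score -inf.
    """
    cal_overrides = cal_overrides or {}
    plan = []  # (rid, t_union, [(state_idx, obs_idx, y_obs, cal_model)])
    for rep in dataset:
        entries = []
        t_all = []
        for ts in rep:
            cal = cal_overrides.get(rep.rid, {}).get(ts.dependent_key) or cal_models.get(
                ts.dependent_key
            )
            if cal is None:
                raise KeyError(f"no calibration model for dependent_key {ts.dependent_key!r}")
            if cal.independent_key not in template.state_names:
                raise KeyError(
                    f"calibration model independent_key {cal.independent_key!r} "
                    f"is not a state of the process model"
                )
            t_all.append(ts.t)
            entries.append((ts, cal))
        if not entries:
            continue
        t_union = np.unique(np.concatenate(t_all))
        if t_union[0] > 0:
            # initial conditions are parametrized at t=0 (inoculation), so
            # integration starts there even when observations begin later
            t_union = np.concatenate([[0.0], t_union])
        compiled = []
        for ts, cal in entries:
            state_idx = list(template.state_names).index(cal.independent_key)
            obs_idx = np.searchsorted(t_union, ts.t)
            compiled.append((state_idx, obs_idx, ts.y, cal))
        plan.append((rep.rid, t_union, compiled))

    def objective(full_vector) -> float:
        per_rep = mapping.repmap(full_vector)
        total = 0.0
        for rid, t_union, compiled in plan:
            rep_pred = solve_replicate(template, t_union, per_rep[rid], rid=rid)
            states = np.vstack([rep_pred[k].y for k in template.state_names])
            for state_idx, obs_idx, y_obs, cal in compiled:
                x_pred = states[state_idx, obs_idx]
                try:
                    total += cal.loglikelihood(x_pred, y_obs)
                except ValueError:
                    return -np.inf
        return float(total)

    return objective


# -- persistence -------------------------------------------------------------------


def save_dataset(dataset: Dataset, path) -> None:
    """Write the dataset to HDF5: /replicates/{rid}/{dependent_key}/{t,y}."""
    import h5py

    with h5py.File(path, "w") as f:
        root = f.create_group("replicates")
        for rep in dataset:
            g = root.create_group(rep.rid)
            for ts in rep:
                sg = g.create_group(ts.dependent_key)
                sg.create_dataset("t", data=ts.t)
                sg.create_dataset("y", data=ts.y)
                sg.attrs["independent_key"] = ts.independent_key
                sg.attrs["dependent_key"] = ts.dependent_key


def load_dataset(path) -> Dataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    import h5py

    ds = Dataset()
    with h5py.File(path, "r") as f:
        if "replicates" not in f:
            raise ValueError(f"malformed dataset file: missing /replicates in {path}")
        for rid, g in f["replicates"].items():
            rep = Replicate(rid=rid)
            for key, sg in g.items():
                if "t" not in sg or "y" not in sg:
                    raise ValueError(f"malformed dataset file at /replicates/{rid}/{key}")
                rep.add(
                    Timeseries(
                        t=np.asarray(sg["t"]),
                        y=np.asarray(sg["y"]),
                        independent_key=sg.attrs.get("independent_key", key),
                        dependent_key=sg.attrs.get("dependent_key", key),
                    )
                )
            ds.add(rep)
    return ds
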