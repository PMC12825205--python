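"""Post-fit analyses: knockout sensitivity, perturbation-robustness
ensembles, and the gestational prolactin dose scan.

All three analyses start from a fitted parameter set and the 120 ng/mL
late-pregnancy dose (the dose scan sweeps the gestational serum levels
instead).  Knockouts set exactly one of the 49 kinetic parameters to zero
— or to 1e-6 for the two Michaelis constants that appear in a denominator
— and score the perturbed normalized readouts against the fitted baseline
by RMSE over the full 60-s output grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .fitting import DEFAULT_VARIED, PerturbationSpec, rmse, \
    sample_parameters
from .metrics import RegressionResult, endpoint_regression
from .network import DENOMINATOR_PARAMS, PARAM_NAMES, ReactionNetwork
from .simulate import normalize_trajectory, simulate

__all__ = [
    "SensitivityRow", "GestationalPoint", "GESTATIONAL_DOSES",
    "knockout_sensitivity", "robustness_ensemble", "gestational_scan",
]

#: Gestational-week labels and mean serum PRL (ng/mL): recorded minimum,
#: every 4 weeks from week 8 to week 36, and recorded maximum.
GESTATIONAL_DOSES: tuple[tuple[str, Optional[int], float], ...] = (
    ("minimum", None, 10.0),
    ("week8", 8, 19.0),
    ("week12", 12, 27.0),
    ("week16", 16, 35.0),
    ("week20", 20, 47.0),
    ("week24", 24, 63.0),
    ("week28", 28, 84.0),
    ("week32", 32, 113.0),
    ("week36", 36, 123.0),
    ("maximum", None, 180.0),
)

SENSITIVITY_DOSE = 120.0


@dataclass(frozen=True)
class SensitivityRow:
    """RMSE impact of knocking out one kinetic parameter."""

    parameter: str
    knockout_value: float
    rmse_pstat3: float
    rmse_jag1: float

    @property
    def joint_rmse(self) -> float:
        return math.hypot(self.rmse_pstat3, self.rmse_jag1)


@dataclass(frozen=True)
class GestationalPoint:
    label: str
    week: Optional[int]
    prl_ng_ml: float
    peak_pstat3_fold: float
    peak_jag1_fold: float


def _baseline(network: ReactionNetwork, fitted: Mapping[str, float],
              prl_dose: float):
    p_over, ic_over = network.split_overrides(dict(fitted))
    params = network.params_array(p_over)
    initial = network.state_array(ic_over)
    tc = simulate(network, params=params, initial=initial, prl_dose=prl_dose)
    return params, initial, tc


def knockout_sensitivity(network: ReactionNetwork,
                         fitted_params: Mapping[str, float],
                         prl_dose: float = SENSITIVITY_DOSE
                         ) -> list[SensitivityRow]:
    """Single-parameter knockout analysis over all 49 kinetic parameters.

    Each parameter is set to 0 (1e-6 for the denominator constants) while
    all others stay at their fitted values; the perturbed normalized
    pSTAT3/JAG1 trajectories are scored by RMSE against the fitted
    baseline over the full output grid.  Integrator failures flag the row
    with infinite RMSEs and the analysis continues.
    """
    params, initial, base_tc = _baseline(network, fitted_params, prl_dose)
    base_ps, base_jg = normalize_trajectory(base_tc)
    rows = []
    for name in PARAM_NAMES:
        ko_value = 1e-6 if name in DENOMINATOR_PARAMS else 0.0
        p = params.copy()
        p[network.param_index[name]] = ko_value
        try:
            tc = simulate(network, params=p, initial=initial,
                          prl_dose=prl_dose)
            ps, jg = normalize_trajectory(tc)
            row = SensitivityRow(parameter=name, knockout_value=ko_value,
                                 rmse_pstat3=rmse(ps, base_ps),
                                 rmse_jag1=rmse(jg, base_jg))
        except SimulationError:
            row = SensitivityRow(parameter=name, knockout_value=ko_value,
                                 rmse_pstat3=math.inf, rmse_jag1=math.inf)
        rows.append(row)
    return rows


def sensitivity_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": r.parameter, "knockout_value": r.knockout_value,
          "rmse_pstat3": r.rmse_pstat3, "rmse_jag1": r.rmse_jag1,
          "joint_rmse": r.joint_rmse} for r in rows])


@dataclass
class EnsembleSummary:
    """Spread of one perturbation-tolerance ensemble."""

    c_max: float
    n: int
    rmse_to_baseline: np.ndarray          # per member, both readouts pooled
    peak_pstat3: np.ndarray               # per member, fold
    peak_jag1: np.ndarray
    pstat3_band: tuple[np.ndarray, np.ndarray]   # central-50% band
    jag1_band: tuple[np.ndarray, np.ndarray]
    t: np.ndarray

    @property
    def median_rmse(self) -> float:
        finite = self.rmse_to_baseline[np.isfinite(self.rmse_to_baseline)]
        return float(np.median(finite))


def robustness_ensemble(network: ReactionNetwork,
                        fitted_params: Mapping[str, float],
                        c_max_levels: Sequence[float] = (1.0, 0.5, 0.1, 0.02),
                        n: int = 10_000, seed: int = 0,
                        prl_dose: float = SENSITIVITY_DOSE,
                        varied_names: Sequence[str] = DEFAULT_VARIED,
                        dt_out: float = 600.0) -> list[EnsembleSummary]:
    """Sample parameter sets around the fitted values at each tolerance
    level, re-simulate, and summarize the spread of the normalized
    readouts (RMSE to baseline pooled over both readouts, peak
    distributions, central-50% trajectory bands).

    ``dt_out`` controls the comparison grid (10 min by default; the
    solution is still integrated adaptively).  Deterministic given seed.
    """
    params, initial, base_tc = _baseline(network, fitted_params, prl_dose)
    base_full = simulate(network, params=params, initial=initial,
                         prl_dose=prl_dose, dt_out=dt_out)
    base_ps, base_jg = normalize_trajectory(base_full)
    summaries = []
    fitted = dict(fitted_params)
    # ensure every varied name has an anchor value
    for name in varied_names:
        if name not in fitted:
            if name in network.param_index:
                fitted[name] = network.param_value(params, name)
            else:
                fitted[name] = float(
                    initial[network.species_index[name]])
    for level_idx, c_max in enumerate(c_max_levels):
        spec = PerturbationSpec(p_init=fitted, c_max=c_max,
                                n_iterations=max(n, 1),
                                seed=seed + 1000 * level_idx,
                                varied_names=tuple(varied_names),
                                stage=f"cmax_{c_max}")
        rmses = np.empty(n)
        peak_ps = np.empty(n)
        peak_jg = np.empty(n)
        ps_all = np.empty((n, len(base_ps)))
        jg_all = np.empty((n, len(base_jg)))
        for it in range(n):
            values = sample_parameters(spec, it)
            p_over, ic_over = network.split_overrides(values)
            try:
                tc = simulate(network, params=network.params_array(p_over),
                              initial=network.state_array(ic_over),
                              prl_dose=prl_dose, dt_out=dt_out)
                ps, jg = normalize_trajectory(tc)
            except SimulationError:
                rmses[it] = np.inf
                peak_ps[it] = peak_jg[it] = np.nan
                ps_all[it] = jg_all[it] = np.nan
                continue
            rmses[it] = rmse(np.concatenate([ps, jg]),
                             np.concatenate([base_ps, base_jg]))
            peak_ps[it], peak_jg[it] = ps.max(), jg.max()
            ps_all[it], jg_all[it] = ps, jg
        ps_band = (np.nanpercentile(ps_all, 25, axis=0),
                   np.nanpercentile(ps_all, 75, axis=0))
        jg_band = (np.nanpercentile(jg_all, 25, axis=0),
                   np.nanpercentile(jg_all, 75, axis=0))
        summaries.append(EnsembleSummary(
            c_max=c_max, n=n, rmse_to_baseline=rmses, peak_pstat3=peak_ps,
            peak_jag1=peak_jg, pstat3_band=ps_band, jag1_band=jg_band,
            t=base_full.t))
    return summaries


def gestational_scan(network: ReactionNetwork,
                     fitted_params: Mapping[str, float],
                     dose_table: Sequence[tuple[str, Optional[int], float]]
                     = GESTATIONAL_DOSES
                     ) -> tuple[list[GestationalPoint], RegressionResult,
                                RegressionResult]:
    """Simulate the gestational PRL series plus a 0 ng/mL control and
    regress the peak readouts on gestational week (weeks 8-36).

    Returns ``(points, pstat3_regression, jag1_regression)``; the control
    is included in ``points`` with label ``control``.  Fully
    deterministic.
    """
    p_over, ic_over = network.split_overrides(dict(fitted_params))
    params = network.params_array(p_over)
    initial = network.state_array(ic_over)
    points = []
    for label, week, dose in (("control", None, 0.0), *dose_table):
        tc = simulate(network, params=params, initial=initial, prl_dose=dose)
        ps, jg = normalize_trajectory(tc)
        points.append(GestationalPoint(
            label=label, week=week, prl_ng_ml=dose,
            peak_pstat3_fold=float(ps.max()),
            peak_jag1_fold=float(jg.max())))
    weekly = [p for p in points if p.week is not None]
    weeks = [p.week for p in weekly]
    reg_ps = endpoint_regression(weeks, [p.peak_pstat3_fold for p in weekly])
    reg_jg = endpoint_regression(weeks, [p.peak_jag1_fold for p in weekly])
    return points, reg_ps, reg_jg


def gestational_frame(points: Sequence[GestationalPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": p.label, "week": p.week, "prl_ng_ml": p.prl_ng_ml,
          "peak_pstat3_fold": p.peak_pstat3_fold,
          "peak_jag1_fold": p.peak_jag1_fold} for p in points])
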