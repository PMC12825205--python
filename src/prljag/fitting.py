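"""Two-stage Monte Carlo fitting of the pathway model to fold-change data.

Candidate parameter sets are drawn around an anchor vector ``P_init`` by

    P_rand = | P_init - C_max * P_init * Z / 3 |,   Z ~ N(0, 1)

so that ~99.7% of draws fall within ±C_max of the anchor (the ±C_max band
sits at 3 sigma) and the absolute value keeps every draw nonnegative.
Each candidate is scored by simulating the three treatment doses and
computing a root-mean-square error per readout against the observation
grid: pSTAT3 fold-change at 5/15/30/60 min and JAG1 fold-change at
12/24/48 h (replicate means by default; 12 and 9 residuals).  The winner
minimizes the Euclidean distance of (RMSE_pSTAT3, RMSE_JAG1) from the
origin; ties break toward the lower iteration index.

The search runs in two stages: a coarse pass (default 10,000 iterations at
C_max = 1.0) anchored on the initial guesses, then a fine pass (default
30,000 iterations at C_max = 0.3) anchored on the coarse winner.  Draws
are keyed by (seed, iteration), so any execution order reproduces the
identical ranked list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SimulationError, ValidationError
from .network import ReactionNetwork
from .simulate import normalize_trajectory, simulate

__all__ = [
    "DOSES_NG_ML", "PSTAT3_TIMES_MIN", "JAG1_TIMES_H", "DEFAULT_VARIED",
    "PerturbationSpec", "ObservationSet", "FitResult", "TwoStageResult",
    "sample_parameters", "rmse", "score_iteration", "run_stage",
    "two_stage_fit", "default_stage_specs",
]

DOSES_NG_ML: tuple[float, ...] = (20.0, 60.0, 120.0)
PSTAT3_TIMES_MIN: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0)
JAG1_TIMES_H: tuple[float, ...] = (12.0, 24.0, 48.0)

#: Names varied by the fit: four initial conditions plus sixteen kinetic
#: constants (receptor dynamics, degradation, phosphorylation, regulatory
#: modules, transcription, JAG1 expression).
DEFAULT_VARIED: tuple[str, ...] = (
    "RJ", "PPX", "S3c", "S3n",
    "k2f", "k2r", "k4", "k5f", "k6", "deg_ratio", "k8f", "k11f", "k12",
    "k23", "k25_1", "k30_1", "k28", "k31", "k33", "k34",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Sampler configuration for one Monte Carlo stage."""

    p_init: Mapping[str, float]
    c_max: float
    n_iterations: int
    seed: int
    varied_names: tuple[str, ...] = DEFAULT_VARIED
    stage: str = "stage1"

    def __post_init__(self):
        if self.c_max < 0:
            raise ValidationError(f"c_max must be >= 0, got {self.c_max}")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        missing = [n for n in self.varied_names if n not in self.p_init]
        if missing:
            raise ValidationError(
                f"varied names missing from p_init: {missing}")


def sample_parameters(spec: PerturbationSpec, iteration: int
                      ) -> dict[str, float]:
    """Draw one perturbed parameter vector (Gaussian, ±C_max at 3 sigma).

    Reproducible given (seed, iteration) regardless of execution order;
    unvaried entries of ``p_init`` are returned unchanged.
    """
    if iteration >= spec.n_iterations:
        raise ValidationError(
            f"iteration {iteration} >= n_iterations {spec.n_iterations}")
    rng = np.random.default_rng([spec.seed, iteration])
    z = rng.standard_normal(len(spec.varied_names))
    out = dict(spec.p_init)
    for name, zi in zip(spec.varied_names, z):
        p0 = spec.p_init[name]
        out[name] = abs(p0 - spec.c_max * p0 * zi / 3.0)
    return out


def rmse(model_values: Sequence[float], observed_values: Sequence[float]
         ) -> float:
    """Root-mean-square error between two equal-length vectors."""
    a = np.asarray(model_values, dtype=float)
    b = np.asarray(observed_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValidationError("rmse needs at least one point")
    return float(np.sqrt(np.mean((a - b) ** 2)))


class ObservationSet:
    """Normalized in-vitro fold-changes on the fitting grid.

    Wraps a tidy table with columns ``readout`` (pSTAT3 | JAG1),
    ``dose_ng_ml``, ``time_h``, ``replicate``, ``fold_change`` and
    validates that every readout x dose x timepoint cell of the comparison
    grid is present.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"readout", "dose_ng_ml", "time_h", "replicate",
                    "fold_change"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"observation table missing columns: "
                            f"{sorted(missing)}")
        frame = frame.copy()
        if (frame["fold_change"] <= 0).any():
            raise DataError("fold-changes must be positive")
        self.frame = frame
        missing_cells = [c for c in self.grid_cells()
                         if self._cell(*c).empty]
        if missing_cells:
            raise DataError(
                f"observation grid incomplete; missing cells "
                f"(readout, dose, time_h): {missing_cells}")

    @staticmethod
    def grid_cells() -> list[tuple[str, float, float]]:
        cells = [("pSTAT3", d, m / 60.0) for d in DOSES_NG_ML
                 for m in PSTAT3_TIMES_MIN]
        cells += [("JAG1", d, h) for d in DOSES_NG_ML for h in JAG1_TIMES_H]
        return cells

    def _cell(self, readout: str, dose: float, time_h: float) -> pd.DataFrame:
        f = self.frame
        return f[(f["readout"] == readout)
                 & (np.isclose(f["dose_ng_ml"], dose))
                 & (np.isclose(f["time_h"], time_h))]

    def cell_values(self, readout: str, dose: float, time_h: float
                    ) -> np.ndarray:
        return self._cell(readout, dose, time_h)["fold_change"].to_numpy()

    def cell_mean(self, readout: str, dose: float, time_h: float) -> float:
        return float(self.cell_values(readout, dose, time_h).mean())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSet":
        """Build from a Data-S1-dialect table (``protein`` column accepted
        as an alias of ``readout``), keeping only the fitting grid."""
        f = frame.rename(columns={"protein": "readout"}).copy()
        keep = pd.Series(False, index=f.index)
        for readout, dose, time_h in cls.grid_cells():
            keep |= ((f["readout"] == readout)
                     & np.isclose(f["dose_ng_ml"], dose)
                     & np.isclose(f["time_h"], time_h))
        return cls(f[keep])


@dataclass(frozen=True)
class FitResult:
    """One scored Monte Carlo iteration."""

    iteration: int
    stage: str
    values: Mapping[str, float]
    rmse_pstat3: float
    rmse_jag1: float

    @property
    def distance(self) -> float:
        return math.hypot(self.rmse_pstat3, self.rmse_jag1)


def _grid_times_s() -> np.ndarray:
    times = {0.0}
    times.update(m * 60.0 for m in PSTAT3_TIMES_MIN)
    times.update(h * 3600.0 for h in JAG1_TIMES_H)
    return np.array(sorted(times))


def model_grid_folds(values: Mapping[str, float], network: ReactionNetwork,
                     rtol: float = 1e-6):
    """Simulate the three doses and return fold-changes on the fitting grid.

    Returns ``(pstat3, jag1)`` dicts keyed by (dose, time_h).
    """
    t_eval = _grid_times_s()
    p_over, ic_over = network.split_overrides(dict(values))
    params = network.params_array(p_over)
    initial = network.state_array(ic_over)
    ps_out, jg_out = {}, {}
    for dose in DOSES_NG_ML:
        tc = simulate(network, params=params, initial=initial,
                      prl_dose=dose, t_eval=t_eval, rtol=rtol)
        ps, jg = normalize_trajectory(tc)
        for m in PSTAT3_TIMES_MIN:
            idx = int(np.argmin(np.abs(t_eval - m * 60.0)))
            ps_out[(dose, m / 60.0)] = float(ps[idx])
        for h in JAG1_TIMES_H:
            idx = int(np.argmin(np.abs(t_eval - h * 3600.0)))
            jg_out[(dose, h)] = float(jg[idx])
    return ps_out, jg_out


def score_iteration(values: Mapping[str, float], network: ReactionNetwork,
                    observations: ObservationSet, iteration: int = 0,
                    stage: str = "manual", per_replicate: bool = False
                    ) -> FitResult:
    """Simulate one candidate at all three doses and score both RMSEs.

    Residuals are taken against replicate means by default (12 pSTAT3 and
    9 JAG1 residuals); ``per_replicate=True`` uses every replicate point
    instead.  Integrator failures yield an infinite-distance result rather
    than aborting a run.
    """
    try:
        ps_model, jg_model = model_grid_folds(values, network)
    except SimulationError:
        return FitResult(iteration=iteration, stage=stage,
                         values=dict(values), rmse_pstat3=math.inf,
                         rmse_jag1=math.inf)
    ps_m, ps_o, jg_m, jg_o = [], [], [], []
    for dose in DOSES_NG_ML:
        for m in PSTAT3_TIMES_MIN:
            cell = observations.cell_values("pSTAT3", dose, m / 60.0)
            if per_replicate:
                ps_m.extend([ps_model[(dose, m / 60.0)]] * len(cell))
                ps_o.extend(cell)
            else:
                ps_m.append(ps_model[(dose, m / 60.0)])
                ps_o.append(cell.mean())
        for h in JAG1_TIMES_H:
            cell = observations.cell_values("JAG1", dose, h)
            if per_replicate:
                jg_m.extend([jg_model[(dose, h)]] * len(cell))
                jg_o.extend(cell)
            else:
                jg_m.append(jg_model[(dose, h)])
                jg_o.append(cell.mean())
    return FitResult(iteration=iteration, stage=stage, values=dict(values),
                     rmse_pstat3=rmse(ps_m, ps_o), rmse_jag1=rmse(jg_m, jg_o))


def _ranked(results: list[FitResult]) -> list[FitResult]:
    return sorted(results, key=lambda r: (r.distance, r.iteration))


def run_stage(spec: PerturbationSpec, network: ReactionNetwork,
              observations: ObservationSet, per_replicate: bool = False,
              resume_from: Optional[list[FitResult]] = None,
              include_anchor: bool = True, progress=None
              ) -> list[FitResult]:
    """Score every iteration of one stage; returns results ranked by
    distance (ascending, ties to the earlier iteration).

    The stage's anchor vector ``P_init`` competes as a reference member
    (iteration -1), so the stage winner can never be worse than its
    starting point — in particular the fine stage can never lose to the
    coarse winner it is centered on.  ``resume_from`` accepts the results
    of a partial run; completed iterations are not recomputed.
    """
    done = {r.iteration: r for r in (resume_from or [])}
    results = []
    if include_anchor:
        if -1 in done:
            results.append(done[-1])
        else:
            results.append(score_iteration(
                dict(spec.p_init), network, observations, iteration=-1,
                stage=spec.stage, per_replicate=per_replicate))
    for it in range(spec.n_iterations):
        if it in done:
            results.append(done[it])
            continue
        values = sample_parameters(spec, it)
        results.append(score_iteration(values, network, observations,
                                       iteration=it, stage=spec.stage,
                                       per_replicate=per_replicate))
        if progress is not None:
            progress(it, spec.n_iterations, results[-1])
    return _ranked(results)


@dataclass
class TwoStageResult:
    """Winner of the fine stage plus the full audit trail."""

    winner: FitResult
    stage1_winner: FitResult
    stage1_results: list[FitResult]
    stage2_results: list[FitResult]
    stage1_seed: int
    stage2_seed: int

    @property
    def audit_frame(self) -> pd.DataFrame:
        rows = [{"stage": r.stage, "iteration": r.iteration,
                 "rmse_pstat3": r.rmse_pstat3, "rmse_jag1": r.rmse_jag1,
                 "distance": r.distance}
                for r in (*self.stage1_results, *self.stage2_results)]
        return pd.DataFrame(rows)

    def percent_change(self, p_init: Mapping[str, float]) -> pd.DataFrame:
        """Percent change of each fitted value vs its initial value
        (positive = increase, negative = decrease)."""
        rows = []
        for name, v0 in p_init.items():
            v1 = self.winner.values.get(name, v0)
            pct = float("nan") if v0 == 0 else 100.0 * (v1 - v0) / v0
            rows.append({"name": name, "initial": v0, "fitted": v1,
                         "percent_change": pct})
        return pd.DataFrame(rows)


def default_stage_specs(p_init: Mapping[str, float], seed: int,
                        budget_scale: float = 1.0
                        ) -> tuple[PerturbationSpec, PerturbationSpec]:
    """The canonical two-stage budgets: 10,000 iterations at C_max = 1.0
    then 30,000 at C_max = 0.3, optionally scaled down for desk runs."""
    n1 = max(1, int(round(10_000 * budget_scale)))
    n2 = max(1, int(round(30_000 * budget_scale)))
    s1 = PerturbationSpec(p_init=dict(p_init), c_max=1.0, n_iterations=n1,
                          seed=seed, stage="stage1")
    s2 = PerturbationSpec(p_init=dict(p_init), c_max=0.3, n_iterations=n2,
                          seed=seed + 1, stage="stage2")
    return s1, s2


def two_stage_fit(observations: ObservationSet, network: ReactionNetwork,
                  stage1_spec: PerturbationSpec,
                  stage2_spec: PerturbationSpec,
                  per_replicate: bool = False, progress=None
                  ) -> TwoStageResult:
    """Run the coarse and fine Monte Carlo stages in series.

    The fine stage is re-anchored on the coarse winner: whatever
    ``p_init`` the supplied ``stage2_spec`` carries is replaced by the
    stage-1 winning vector.
    """
    stage1 = run_stage(stage1_spec, network, observations,
                       per_replicate=per_replicate, progress=progress)
    s1_win = stage1[0]
    stage2_spec = replace(stage2_spec, p_init=dict(s1_win.values))
    stage2 = run_stage(stage2_spec, network, observations,
                       per_replicate=per_replicate, progress=progress)
    s2_win = stage2[0]
    winner = s2_win if s2_win.distance <= s1_win.distance else s1_win
    return TwoStageResult(winner=winner, stage1_winner=s1_win,
                          stage1_results=stage1, stage2_results=stage2,
                          stage1_seed=stage1_spec.seed,
                          stage2_seed=stage2_spec.seed)
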