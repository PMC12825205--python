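"""Time integration of the pathway model and readout extraction.

Simulations run the stiff mass-action system with an adaptive implicit
solver (LSODA, rtol 1e-6, atol 1e-9 nM) and sample the solution on a
uniform output grid — 60 s steps over 0-48 h by default (2881 samples),
mirroring how the model trajectories are reported.  Readouts are the total
phospho-STAT3 monomer-equivalent pool (pSTAT3_total) and membrane JAG1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _rhs
from .errors import NormalizationError, SimulationError, ValidationError
from .network import PSTAT3_MULTIPLICITY, ReactionNetwork
from .units import prl_dose_to_nm

__all__ = ["TimeCourse", "simulate", "normalize_trajectory"]

T_END_DEFAULT = 48 * 3600.0
DT_OUT_DEFAULT = 60.0
RTOL = 1e-6
ATOL = 1e-9


@dataclass
class TimeCourse:
    """Simulated trajectories sampled on a uniform time grid."""

    t: np.ndarray                 # seconds
    y: np.ndarray                 # species x time, nM
    species: tuple[str, ...]
    prl_dose: float               # ng/mL

    @property
    def pstat3_total(self) -> np.ndarray:
        """Total phospho-STAT3 (monomer equivalents, nM) over time."""
        idx = {s: i for i, s in enumerate(self.species)}
        total = np.zeros_like(self.t, dtype=float)
        for name, mult in PSTAT3_MULTIPLICITY.items():
            total += mult * self.y[idx[name]]
        return total

    @property
    def jag1(self) -> np.ndarray:
        """Membrane JAG1 (nM) over time."""
        return self.y[self.species.index("JAG1")]

    def series(self, name: str) -> np.ndarray:
        return self.y[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time_s, species, concentration_nM."""
        n_t = len(self.t)
        return pd.DataFrame({
            "time_s": np.tile(self.t, len(self.species)),
            "species": np.repeat(self.species, n_t),
            "concentration_nM": self.y.ravel(),
        })

    def readouts_frame(self) -> pd.DataFrame:
        """Readout export: time_s, pstat3_fold, jag1_fold."""
        ps, jg = normalize_trajectory(self)
        return pd.DataFrame({"time_s": self.t, "pstat3_fold": ps,
                             "jag1_fold": jg})


def simulate(network: ReactionNetwork,
             params: Mapping[str, float] | np.ndarray | None = None,
             initial: Mapping[str, float] | np.ndarray | None = None,
             prl_dose: float = 0.0,
             t_end: float = T_END_DEFAULT,
             dt_out: float = DT_OUT_DEFAULT,
             t_eval: np.ndarray | None = None,
             rtol: float = RTOL,
             atol: float = ATOL) -> TimeCourse:
    """Integrate the network from its initial state under a PRL dose.

    Parameters
    ----------
    params, initial
        Full parameter/state vectors (canonical order) or partial
        name->value overrides of the network defaults.
    prl_dose
        Prolactin dose in ng/mL, converted to nM (23 kDa) and *added* to
        the basal PRL initial condition at t = 0.  No pre-equilibration
        phase is run: the shipped initial conditions are the pre-stimulus
        state.
    t_eval
        Optional explicit sample times (seconds); overrides the uniform
        ``dt_out`` grid.  The solution is computed adaptively either way,
        so the grid only controls sampling.
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be positive, got {t_end}")
    if isinstance(params, np.ndarray):
        p = np.asarray(params, dtype=float)
    else:
        p = network.params_array(params or {})
    if isinstance(initial, np.ndarray):
        y0 = np.asarray(initial, dtype=float).copy()
    else:
        y0 = network.state_array(initial or {})
    if "PRL" in network.species_index:
        y0[network.species_index["PRL"]] += prl_dose_to_nm(prl_dose)
    elif prl_dose != 0:
        raise ValidationError("network has no PRL species; dose must be 0")

    if t_eval is None:
        n = int(round(t_end / dt_out))
        t_eval = np.linspace(0.0, n * dt_out, n + 1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    k_eff, km = network.effective_rates(p)
    args = (k_eff, km, network._km_idx, network._driver_idx,
            network._n_reac, network._reac_idx, network._reac_st,
            network._stoich)

    sol = solve_ivp(lambda t, y: _rhs.rhs_flat(y, *args),
                    (0.0, float(t_eval[-1])), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}", params=p)
    y = sol.y
    undershoot = y.min()
    if undershoot < -10 * max(atol, 1e-12) * max(1.0, np.abs(y).max()):
        raise SimulationError(
            f"negative concentration beyond tolerance ({undershoot:.3e} nM)",
            params=p)
    y = np.clip(y, 0.0, None)
    return TimeCourse(t=sol.t, y=y, species=network.species,
                      prl_dose=prl_dose)


def normalize_trajectory(tc: TimeCourse):
    """Fold-change readouts relative to each trajectory's own t = 0 value.

    Returns ``(pstat3_fold, jag1_fold)``.  Model concentrations become
    comparable with background-subtracted in-vitro fold-changes only as
    ratios to baseline, so a nonzero basal phospho-STAT3 pool and basal
    membrane JAG1 are required.
    """
    ps = tc.pstat3_total
    jg = tc.jag1
    if ps[0] <= 0 or jg[0] <= 0:
        raise NormalizationError(
            "fold-change baseline is zero; supply nonzero basal "
            "phospho-STAT3 and JAG1 initial conditions")
    return ps / ps[0], jg / jg[0]
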