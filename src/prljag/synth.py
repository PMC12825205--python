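"""Synthetic input generation: in-vitro-shaped observation tables,
ground-truth datasets for parameter recovery, viability tables, and the
clinical cohort fixture.

Two observation modes exist.  *Phenomenological* mode draws replicate
fold-changes around smooth templates shaped like the in-vitro dynamics:
a biphasic pSTAT3 response (sharp 5-min peak, decayed by 30 min, slow
secondary rise around 12 h), a delayed dose-dependent JAG1 rise at 12 h
whose dose differences equalize by 24 h, EMT marker drift (vimentin up,
E-cadherin down at the two pregnancy doses), a strong CD44 rise at the
late-pregnancy dose and flat CD133.  *Model-based* mode simulates the
pathway model under supplied ground-truth parameters and samples noisy
fold-changes from it — the route used for parameter-recovery experiments.

Replicate noise is multiplicative log-normal: each value is the template
times exp(eps), eps ~ N(0, sd) with sd = 0.1 by default, n = 3 replicates.
All outputs are deterministic given the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .metrics import CohortRecord, ViabilityRecord
from .network import ReactionNetwork, build_network
from .simulate import normalize_trajectory, simulate

__all__ = [
    "SyntheticDesign", "generate_observations", "generate_viability_table",
    "generate_cohort_fixture", "pstat3_template", "jag1_template",
    "marker_template", "PSTAT3_TIMES_H", "MARKER_TIMES_H",
]

#: Timepoints measured for STAT3 phosphorylation (hours).
PSTAT3_TIMES_H: tuple[float, ...] = (5 / 60, 15 / 60, 30 / 60, 1.0, 3.0, 12.0)
#: Timepoints measured for every other protein (hours).
MARKER_TIMES_H: tuple[float, ...] = (12.0, 24.0, 48.0)

MARKER_PROTEINS = ("JAG1", "NICD", "CD44", "CD133", "vimentin", "E-cadherin")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for the synthetic observation generator."""

    doses_ng_ml: tuple[float, ...] = (20.0, 60.0, 120.0)
    pstat3_times_h: tuple[float, ...] = PSTAT3_TIMES_H
    marker_times_h: tuple[float, ...] = MARKER_TIMES_H
    n_replicates: int = 3
    noise_sd: float = 0.1
    seed: int = 0
    mode: str = "phenomenological"      # or "model-based"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigurationError("replicate count must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.mode not in ("phenomenological", "model-based"):
            raise ConfigurationError(
                f"unknown generator mode {self.mode!r}; use "
                f"'phenomenological' or 'model-based'")


# ---------------------------------------------------------------------------
# Phenomenological templates.  The shape constants below are fixtures tuned
# to the qualitative dose/time orderings of the in-vitro readouts; they are
# generator configuration, not biological claims.

PSTAT3_PEAK_H = 5 / 60            # early peak position
PSTAT3_PEAK_WIDTH = 0.7           # log-time width of the early peak
PSTAT3_AMP_MAX = 1.5              # peak amplitude at saturating dose
PSTAT3_AMP_K = 60.0               # half-max dose of the peak amplitude
PSTAT3_LATE_RISE = 0.6            # secondary rise plateau (+60%)
PSTAT3_LATE_MID_H = 9.0
PSTAT3_LATE_WIDTH_H = 1.5

JAG1_RISE_MAX = 1.6
JAG1_RISE_MID_H = 10.0
JAG1_RISE_WIDTH_H = 3.0
JAG1_DOSE_K = 50.0                # half-max dose (quartic Hill)
JAG1_EQUALIZE_START_H = 12.0
JAG1_EQUALIZE_END_H = 24.0


def _hill(d: float, k: float, n: float) -> float:
    return d ** n / (d ** n + k ** n)


def pstat3_template(time_h: float, dose_ng_ml: float) -> float:
    """Noise-free pSTAT3 fold-change: biphasic, dose-dependent early peak."""
    if time_h <= 0:
        return 1.0
    amp = PSTAT3_AMP_MAX * _hill(dose_ng_ml, PSTAT3_AMP_K, 2)
    early = amp * math.exp(-(math.log(time_h / PSTAT3_PEAK_H)) ** 2
                           / (2 * PSTAT3_PEAK_WIDTH ** 2))
    late = PSTAT3_LATE_RISE / (
        1 + math.exp(-(time_h - PSTAT3_LATE_MID_H) / PSTAT3_LATE_WIDTH_H))
    return 1.0 + early + late


def jag1_template(time_h: float, dose_ng_ml: float) -> float:
    """Noise-free JAG1 fold-change: delayed rise, dose differences at 12 h
    that equalize by 24 h."""
    rise = JAG1_RISE_MAX / (
        1 + math.exp(-(time_h - JAG1_RISE_MID_H) / JAG1_RISE_WIDTH_H))
    dose_factor = _hill(dose_ng_ml, JAG1_DOSE_K, 4)
    span = JAG1_EQUALIZE_END_H - JAG1_EQUALIZE_START_H
    w = min(max((JAG1_EQUALIZE_END_H - time_h) / span, 0.0), 1.0)
    return 1.0 + rise * (dose_factor * w + (1.0 - w))


def marker_template(protein: str, time_h: float, dose_ng_ml: float) -> float:
    """Noise-free fold-change templates for the downstream markers."""
    d, t = dose_ng_ml, time_h
    if protein == "JAG1":
        return jag1_template(t, d)
    if protein == "NICD":
        return 1.0 + 0.8 * (t / 48.0)
    if protein == "CD44":
        amp = 5.0 * _hill(d, 90.0, 3)
        return 1.0 + amp * (t / 48.0) ** 0.6
    if protein == "CD133":
        return 1.0
    if protein == "vimentin":
        return 1.0 + (0.3 + 0.5 * _hill(d, 80.0, 2)) * (t / 48.0) ** 0.8
    if protein == "E-cadherin":
        return 1.0 - 0.5 * _hill(d, 40.0, 4) * min(t / 12.0, 1.0)
    raise ConfigurationError(f"no template for protein {protein!r}")


def _noisy(rng: np.random.Generator, value: float, sd: float, n: int
           ) -> np.ndarray:
    if sd == 0:
        return np.full(n, value)
    return value * np.exp(rng.normal(0.0, sd, size=n))


def generate_observations(design: SyntheticDesign,
                          truth: Optional[Mapping[str, float]] = None,
                          network: Optional[ReactionNetwork] = None
                          ) -> pd.DataFrame:
    """Generate a Data-S1-dialect observation table.

    Columns: protein, dose_ng_ml, time_h, replicate, fold_change.  In
    model-based mode the pathway model is simulated at each design dose
    under the ``truth`` overrides (defaults if ``None``) and only the two
    modeled readouts (pSTAT3, JAG1) are emitted; phenomenological mode
    covers all measured proteins.
    """
    rng = np.random.default_rng(design.seed)
    rows = []

    def emit(protein, dose, time_h, clean):
        for rep, v in enumerate(
                _noisy(rng, clean, design.noise_sd, design.n_replicates),
                start=1):
            rows.append({"protein": protein, "dose_ng_ml": dose,
                         "time_h": time_h, "replicate": rep,
                         "fold_change": float(v)})

    if design.mode == "model-based":
        net = network if network is not None else build_network()
        overrides = dict(truth) if truth else {}
        p_over, ic_over = net.split_overrides(overrides)
        params = net.params_array(p_over)
        initial = net.state_array(ic_over)
        times_h = sorted(set(design.pstat3_times_h)
                         | set(design.marker_times_h))
        t_eval = np.array([0.0] + [h * 3600.0 for h in times_h])
        for dose in design.doses_ng_ml:
            tc = simulate(net, params=params, initial=initial,
                          prl_dose=dose, t_eval=t_eval)
            ps, jg = normalize_trajectory(tc)
            for h in design.pstat3_times_h:
                idx = int(np.argmin(np.abs(t_eval - h * 3600.0)))
                emit("pSTAT3", dose, h, float(ps[idx]))
            for h in design.marker_times_h:
                idx = int(np.argmin(np.abs(t_eval - h * 3600.0)))
                emit("JAG1", dose, h, float(jg[idx]))
        return pd.DataFrame(rows)

    for dose in design.doses_ng_ml:
        for h in design.pstat3_times_h:
            emit("pSTAT3", dose, h, pstat3_template(h, dose))
        for protein in MARKER_PROTEINS:
            for h in design.marker_times_h:
                emit(protein, dose, h, marker_template(protein, h, dose))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Viability / TRAIL sensitization table (Data-S3 dialect)

TRAIL_DOSES = (0.1, 1.0, 10.0, 100.0, 1000.0)
CONTROL_VIABILITY = 80.0
LIPOSOME_ARMS = ("no treatment", "soluble TRAIL", "TRAIL liposome",
                 "aCSV/TRAIL liposome", "ES/TRAIL liposome", "DA liposome")
#: Viability multipliers for the liposome arms under flow in whole blood,
#: without and with 3-day PRL pre-exposure.  The PRL + DA-liposome arm is
#: pinned so that its sensitization vs the untreated control is 0.45.
LIPOSOME_EFFECT = {
    ("no treatment", False): 1.0, ("no treatment", True): 1.0,
    ("soluble TRAIL", False): 0.97, ("soluble TRAIL", True): 0.87,
    ("TRAIL liposome", False): 0.95, ("TRAIL liposome", True): 0.75,
    ("aCSV/TRAIL liposome", False): 0.94, ("aCSV/TRAIL liposome", True): 0.70,
    ("ES/TRAIL liposome", False): 0.93, ("ES/TRAIL liposome", True): 0.66,
    ("DA liposome", False): 0.92, ("DA liposome", True): 0.55,
}


def _soluble_viability(trail: float, prl: bool, shear: bool) -> float:
    """Smooth viability surface for the soluble-TRAIL dose response."""
    kill_sat = 0.08 + (0.22 if prl else 0.0) + (0.10 if shear else 0.0)
    half = 200.0 if not (prl or shear) else 30.0
    kill = kill_sat * _hill(trail, half, 1) if trail > 0 else 0.0
    return CONTROL_VIABILITY * (1.0 - kill)


def generate_viability_table(design: SyntheticDesign = SyntheticDesign()
                             ) -> list[ViabilityRecord]:
    """Emit the treatment-group viability table (percent viable, apoptotic
    and necrotic per group) with a liposome-treatment effect.

    Contains the soluble-TRAIL dose-response arms (static/FSS x +/-PRL)
    and the whole-blood liposome arms; the PRL-pre-exposed DA-liposome
    arm loses ~45% viability vs the untreated static control.  Seeded and
    deterministic.
    """
    rng = np.random.default_rng([design.seed, 1301])
    records = []

    def emit(treatment, viable, prl, shear, trail):
        noise = rng.normal(0.0, 0.8)
        viable = min(max(viable + noise, 0.0), 100.0)
        dead = 100.0 - viable
        apop_frac = 0.7 + 0.05 * rng.normal()
        apop_frac = min(max(apop_frac, 0.0), 1.0)
        records.append(ViabilityRecord(
            treatment=treatment, pct_viable=round(viable, 2),
            pct_apoptotic=round(dead * apop_frac, 2),
            pct_necrotic=round(dead * (1 - apop_frac), 2),
            prl_pre_exposed=prl, shear=shear, trail_dose_ng_ml=trail))

    # untreated static control is emitted noise-free: it anchors Eq.-5
    records.append(ViabilityRecord(
        treatment="control static", pct_viable=CONTROL_VIABILITY,
        pct_apoptotic=14.0, pct_necrotic=6.0))
    for shear in (False, True):
        for prl in (False, True):
            for trail in TRAIL_DOSES:
                label = (f"soluble TRAIL {trail:g} ng/mL"
                         f"{' +PRL' if prl else ''}"
                         f"{' FSS' if shear else ' static'}")
                emit(label, _soluble_viability(trail, prl, shear),
                     prl, shear, trail)
    for arm in LIPOSOME_ARMS:
        for prl in (False, True):
            label = f"{arm}{' +PRL' if prl else ''} FSS whole blood"
            trail = 0.0 if arm == "no treatment" else 590.0
            viable = CONTROL_VIABILITY * LIPOSOME_EFFECT[(arm, prl)]
            if arm == "DA liposome" and prl:
                # pin the headline arm exactly: 45% viability loss
                records.append(ViabilityRecord(
                    treatment=label, pct_viable=44.0, pct_apoptotic=42.0,
                    pct_necrotic=14.0, prl_pre_exposed=True, shear=True,
                    trail_dose_ng_ml=trail))
            else:
                emit(label, viable, prl, True, trail)
    return records


# ---------------------------------------------------------------------------
# Clinical cohort fixture (Table-1 dialect)

def generate_cohort_fixture() -> list[CohortRecord]:
    """The packaged 12-patient cohort table: 5 patients pregnant at
    diagnosis and 7 age-/stage-matched non-pregnant patients, with missing
    tumor sizes kept missing."""
    from .io_utils import read_cohort_csv
    path = resources.files("prljag").joinpath("data", "cohort_table1.csv")
    return read_cohort_csv(str(path))
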