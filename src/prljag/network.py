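"""Reaction network for prolactin-activated JAK2/STAT3 signaling ending in JAG1.

The model follows the canonical JAK/STAT activation cascade: JAK2 binds the
intracellular domain of the prolactin receptor (R1) to form the RJ complex;
prolactin binds RJ (R2) and two ligand-bound complexes pair into the
receptor dimer (R3) which trans-activates (R4); cytosolic STAT3 docks on the active receptor (R5), is phosphorylated
(R6), dimerizes (R8), enters the nucleus (R14) and binds DNA (R24) where it
drives transcription of JAG1 mRNA (R30).  The transcript exits the nucleus
(R31), is translated (R33) and the protein is trafficked to the membrane
(R34), the model's terminal readout.  Three negative-feedback modules shape
the response: SHP2 (R9-R10), the cytosolic/nuclear phosphatases PPX/PPN
(R11-R17), and STAT3-induced SOCS (R18-R24), which binds and silences the
active receptor.

Kinetics are mass action throughout, except the two transcription-like
induction steps (SOCS induction and JAG1 transcription) which saturate in
the DNA-bound dimer with Michaelis constants ``k25_2`` and ``k30_2`` — the
only "denominator" parameters of the model.  First-order decay of JAG1
mRNA and protein is scaled by the dimensionless ``deg_ratio``.

Rate-constant naming follows the historical numbering of the source
lineage of JAK/STAT models rather than the reaction labels one-to-one:
``k25_1``/``k25_2`` belong to the SOCS induction step labeled R18, and
``k30a`` is accepted as an alias of ``k30_1`` (JAG1 transcription Vmax).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "ode_rhs",
    "SPECIES",
    "PARAM_NAMES",
    "PARAM_ALIASES",
    "DENOMINATOR_PARAMS",
    "PSTAT3_MULTIPLICITY",
    "STAT3_MOIETY",
    "load_default_parameters",
    "load_default_initials",
]


@dataclass(frozen=True)
class Reaction:
    """One elementary (or lumped saturable) reaction step.

    ``reactants``/``products`` are (species, stoichiometry) pairs.  When
    ``km_constant`` is set the reaction is a saturable induction driven by
    ``driver``: rate = k * [driver] / (km + [driver]); the driver itself is
    not consumed.  ``deg_scaled`` marks first-order decays whose effective
    rate is multiplied by ``deg_ratio``.
    """

    label: str
    description: str
    rate_constant: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    km_constant: str | None = None
    driver: str | None = None
    deg_scaled: bool = False


#: Species registry (fixed at network construction; order defines the state
#: vector).  Concentrations in nM.
SPECIES: tuple[str, ...] = (
    "PRLR",            # free prolactin receptor (pre-stimulus pool, default 0)
    "JAK2",            # free Janus kinase 2 (pre-stimulus pool, default 0)
    "RJ",              # receptor-JAK2 complex
    "PRL",             # free prolactin (set from the dose)
    "PRL_RJ",          # single-bound ligand-receptor complex
    "PRL_RJ2",         # ligand bridging two RJ complexes (inactive)
    "PRL_RJ2a",        # activated (trans-phosphorylated) receptor complex
    "S3c",             # cytosolic STAT3
    "PRL_RJ2a_S3c",    # STAT3 docked on the active receptor
    "pS3c",            # cytosolic phospho-STAT3 monomer
    "PRL_RJ2a_pS3c",   # phospho-STAT3 re-bound to the active receptor
    "pS3c_dim",        # cytosolic phospho-STAT3 dimer
    "pS3n_dim",        # nuclear phospho-STAT3 dimer
    "pS3n",            # nuclear phospho-STAT3 monomer
    "S3n",             # nuclear (unphosphorylated) STAT3
    "PPX",             # cytosolic phosphatase
    "PPX_pS3c",        # phosphatase-substrate complex (cytosol)
    "PPN",             # nuclear phosphatase
    "PPN_pS3n",        # phosphatase-substrate complex (nucleus)
    "SOCS",            # suppressor of cytokine signaling
    "PRL_RJ2a_SOCS",   # SOCS-silenced receptor complex
    "SHP2",            # SH2-domain phosphatase 2
    "PRL_RJ2a_SHP2",   # SHP2 bound to the active receptor
    "DNAdim",          # promoter-bound nuclear dimer
    "mRNAn",           # nuclear JAG1 mRNA
    "mRNAc",           # cytosolic JAG1 mRNA
    "JAG1c",           # cytosolic (immature) JAG1 protein
    "JAG1",            # membrane JAG1 (terminal readout)
)


def _ma(label, desc, k, reac, prod, deg=False):
    return Reaction(label, desc, k, tuple(reac), tuple(prod), deg_scaled=deg)


REACTIONS: tuple[Reaction, ...] = (
    _ma("R1", "JAK2 binds the PRLR intracellular domain", "k1f",
        [("PRLR", 1), ("JAK2", 1)], [("RJ", 1)]),
    _ma("R1", "RJ complex dissociation", "k1r", [("RJ", 1)],
        [("PRLR", 1), ("JAK2", 1)]),
    _ma("R2", "PRL binds RJ", "k2f", [("PRL", 1), ("RJ", 1)], [("PRL_RJ", 1)]),
    _ma("R2", "PRL unbinds RJ", "k2r", [("PRL_RJ", 1)], [("PRL", 1), ("RJ", 1)]),
    _ma("R3", "two ligand-bound complexes pair (receptor dimerization)",
        "k3f", [("PRL_RJ", 2)], [("PRL_RJ2", 1)]),
    _ma("R3", "receptor dimer dissociation", "k3r", [("PRL_RJ2", 1)],
        [("PRL_RJ", 2)]),
    _ma("R4", "receptor complex trans-activation", "k4", [("PRL_RJ2", 1)],
        [("PRL_RJ2a", 1)]),
    _ma("R4", "receptor complex deactivation", "k4r", [("PRL_RJ2a", 1)],
        [("PRL_RJ2", 1)]),
    _ma("R5", "STAT3 docks on active receptor", "k5f",
        [("PRL_RJ2a", 1), ("S3c", 1)], [("PRL_RJ2a_S3c", 1)]),
    _ma("R5", "STAT3 undocks", "k5r", [("PRL_RJ2a_S3c", 1)],
        [("PRL_RJ2a", 1), ("S3c", 1)]),
    _ma("R6", "STAT3 phosphorylation and release", "k6", [("PRL_RJ2a_S3c", 1)],
        [("PRL_RJ2a", 1), ("pS3c", 1)]),
    _ma("R7", "phospho-STAT3 re-binds active receptor", "k7f",
        [("PRL_RJ2a", 1), ("pS3c", 1)], [("PRL_RJ2a_pS3c", 1)]),
    _ma("R7", "phospho-STAT3 release", "k7r", [("PRL_RJ2a_pS3c", 1)],
        [("PRL_RJ2a", 1), ("pS3c", 1)]),
    _ma("R8", "cytosolic phospho-STAT3 dimerization", "k8f", [("pS3c", 2)],
        [("pS3c_dim", 1)]),
    _ma("R8", "cytosolic dimer dissociation", "k8r", [("pS3c_dim", 1)],
        [("pS3c", 2)]),
    _ma("R9", "SHP2 binds active receptor", "k9f",
        [("PRL_RJ2a", 1), ("SHP2", 1)], [("PRL_RJ2a_SHP2", 1)]),
    _ma("R9", "SHP2 unbinds", "k9r", [("PRL_RJ2a_SHP2", 1)],
        [("PRL_RJ2a", 1), ("SHP2", 1)]),
    _ma("R10", "SHP2-mediated receptor deactivation/disassembly", "k10",
        [("PRL_RJ2a_SHP2", 1)], [("RJ", 2), ("PRL", 2), ("SHP2", 1)]),
    _ma("R11", "PPX binds cytosolic phospho-STAT3", "k11f",
        [("PPX", 1), ("pS3c", 1)], [("PPX_pS3c", 1)]),
    _ma("R11", "PPX-substrate complex dissociation", "k11r", [("PPX_pS3c", 1)],
        [("PPX", 1), ("pS3c", 1)]),
    _ma("R12", "PPX-mediated dephosphorylation", "k12", [("PPX_pS3c", 1)],
        [("PPX", 1), ("S3c", 1)]),
    _ma("R13", "nuclear dimer dissociation", "k13", [("pS3n_dim", 1)],
        [("pS3n", 2)]),
    _ma("R14", "nuclear import of the phospho-STAT3 dimer", "k14",
        [("pS3c_dim", 1)], [("pS3n_dim", 1)]),
    _ma("R15", "PPN binds nuclear phospho-STAT3", "k15f",
        [("PPN", 1), ("pS3n", 1)], [("PPN_pS3n", 1)]),
    _ma("R15", "PPN-mediated dephosphorylation", "k15r", [("PPN_pS3n", 1)],
        [("PPN", 1), ("S3n", 1)]),
    _ma("R16", "nuclear export of STAT3", "k16", [("S3n", 1)], [("S3c", 1)]),
    _ma("R17", "basal nuclear import of STAT3", "k17", [("S3c", 1)],
        [("S3n", 1)]),
    Reaction("R18", "STAT3-induced SOCS expression (saturable)", "k25_1",
             (), (("SOCS", 1),), km_constant="k25_2", driver="DNAdim"),
    _ma("R19", "SOCS binds active receptor", "k19f",
        [("SOCS", 1), ("PRL_RJ2a", 1)], [("PRL_RJ2a_SOCS", 1)]),
    _ma("R19", "SOCS unbinds receptor", "k19r", [("PRL_RJ2a_SOCS", 1)],
        [("SOCS", 1), ("PRL_RJ2a", 1)]),
    _ma("R20", "SOCS turnover", "k20", [("SOCS", 1)], []),
    _ma("R21", "turnover of SOCS-silenced receptor complex", "k21",
        [("PRL_RJ2a_SOCS", 1)], [("RJ", 2), ("PRL", 2), ("SOCS", 1)]),
    _ma("R22", "SOCS degradation on the receptor", "k22",
        [("PRL_RJ2a_SOCS", 1)], [("PRL_RJ2a", 1)]),
    _ma("R23", "SHP2 disassembles SOCS-silenced receptor", "k23",
        [("PRL_RJ2a_SOCS", 1), ("SHP2", 1)],
        [("RJ", 2), ("PRL", 2), ("SOCS", 1), ("SHP2", 1)]),
    _ma("R24", "nuclear dimer binds DNA", "k24f", [("pS3n_dim", 1)],
        [("DNAdim", 1)]),
    _ma("R24", "dimer unbinds DNA", "k24r", [("DNAdim", 1)],
        [("pS3n_dim", 1)]),
    _ma("R26", "cytosolic JAG1 decay", "k26", [("JAG1c", 1)], [], deg=True),
    _ma("R27", "membrane JAG1 decay", "k27", [("JAG1", 1)], [], deg=True),
    _ma("R28", "nuclear JAG1 mRNA decay", "k28", [("mRNAn", 1)], [], deg=True),
    _ma("R29", "spontaneous receptor-complex deactivation", "k29",
        [("PRL_RJ2a", 1)], [("RJ", 2), ("PRL", 2)]),
    Reaction("R30", "JAG1 mRNA transcription (saturable)", "k30_1",
             (), (("mRNAn", 1),), km_constant="k30_2", driver="DNAdim"),
    _ma("R31", "JAG1 mRNA nuclear export", "k31", [("mRNAn", 1)],
        [("mRNAc", 1)]),
    _ma("R32", "cytosolic JAG1 mRNA decay", "k32", [("mRNAc", 1)], [], deg=True),
    Reaction("R33", "JAG1 translation", "k33", (), (("JAG1c", 1),),
             km_constant=None, driver="mRNAc"),
    _ma("R34", "JAG1 trafficking to the membrane", "k34", [("JAG1c", 1)],
        [("JAG1", 1)]),
    _ma("R34", "membrane JAG1 internalization", "k34r", [("JAG1", 1)],
        [("JAG1c", 1)]),
)

#: The 49 tunable parameters exposed to the knockout sensitivity analysis:
#: 48 rate constants plus the degradation scaling factor.
PARAM_NAMES: tuple[str, ...] = (
    "k1f", "k1r", "k2f", "k2r", "k3f", "k3r", "k4", "k4r", "k5f", "k5r",
    "k6", "k7f", "k7r", "k8f", "k8r", "k9f", "k9r", "k10", "k11f", "k11r",
    "k12", "k13", "k14", "k15f", "k15r", "k16", "k17", "k19f", "k19r",
    "k20", "k21", "k22", "k23", "k24f", "k24r", "k25_1", "k25_2", "k26",
    "k27", "k28", "k29", "k30_1", "k30_2", "k31", "k32", "k33", "k34",
    "k34r", "deg_ratio",
)

#: Historical aliases accepted on input.
PARAM_ALIASES: Mapping[str, str] = {"k30a": "k30_1", "k25a": "k25_1"}

#: Parameters appearing in a denominator of a rational rate law; the
#: knockout analysis sets these to 1e-6 instead of 0.
DENOMINATOR_PARAMS: tuple[str, ...] = ("k25_2", "k30_2")

#: Phospho-STAT3 monomer-equivalents carried by each species (dimers count
#: twice); used for the pSTAT3_total readout.
PSTAT3_MULTIPLICITY: Mapping[str, int] = {
    "pS3c": 1, "PRL_RJ2a_pS3c": 1, "pS3c_dim": 2, "pS3n_dim": 2,
    "pS3n": 1, "PPN_pS3n": 1, "PPX_pS3c": 1, "DNAdim": 2,
}

#: STAT3 monomer-equivalents (phosphorylated or not) per species; the total
#: is conserved by every reaction in the network.
STAT3_MOIETY: Mapping[str, int] = dict(
    PSTAT3_MULTIPLICITY, S3c=1, PRL_RJ2a_S3c=1, S3n=1,
)

#: Conserved moieties used by the consistency checks: name -> per-species
#: monomer counts.  SOCS is conserved only with its synthesis (R18) and
#: decay (R20) disabled.
MOIETIES: Mapping[str, Mapping[str, int]] = {
    "STAT3": STAT3_MOIETY,
    "receptor": {"RJ": 1, "PRL_RJ": 1, "PRL_RJ2": 2, "PRL_RJ2a": 2,
                 "PRL_RJ2a_S3c": 2, "PRL_RJ2a_pS3c": 2, "PRL_RJ2a_SOCS": 2,
                 "PRL_RJ2a_SHP2": 2},
    "PPX": {"PPX": 1, "PPX_pS3c": 1},
    "PPN": {"PPN": 1, "PPN_pS3n": 1},
    "SHP2": {"SHP2": 1, "PRL_RJ2a_SHP2": 1},
    "SOCS": {"SOCS": 1, "PRL_RJ2a_SOCS": 1},
    "PRL": {"PRL": 1, "PRL_RJ": 1, "PRL_RJ2": 2, "PRL_RJ2a": 2,
            "PRL_RJ2a_S3c": 2, "PRL_RJ2a_pS3c": 2, "PRL_RJ2a_SOCS": 2,
            "PRL_RJ2a_SHP2": 2},
}


class ReactionNetwork:
    """A validated reaction network with a compiled mass-action RHS.

    Construct through :func:`build_network`; the constructor checks that
    every reaction references registered species and rate constants and
    that the supplied default tables are complete and nonnegative.
    """

    def __init__(self, parameters: Mapping[str, float],
                 initials: Mapping[str, float],
                 reactions: Sequence[Reaction] = REACTIONS,
                 species: Sequence[str] = SPECIES,
                 param_names: Sequence[str] = PARAM_NAMES):
        self.species: tuple[str, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.param_names: tuple[str, ...] = tuple(param_names)
        self.species_index = {s: i for i, s in enumerate(self.species)}
        self.param_index = {p: i for i, p in enumerate(self.param_names)}

        for rx in self.reactions:
            for name, _ in (*rx.reactants, *rx.products):
                if name not in self.species_index:
                    raise ConfigurationError(
                        f"reaction {rx.label} references unknown species "
                        f"{name!r}")
            if rx.driver is not None and rx.driver not in self.species_index:
                raise ConfigurationError(
                    f"reaction {rx.label} references unknown driver "
                    f"{rx.driver!r}")
            for kname in filter(None, (rx.rate_constant, rx.km_constant)):
                if kname not in self.param_index and kname != "deg_ratio":
                    raise ConfigurationError(
                        f"reaction {rx.label} references unknown rate "
                        f"constant {kname!r}")

        self.default_params = self.params_array(parameters, complete=True)
        self.default_initials = self.state_array(initials, complete=True)
        self._compile()

    # -- table handling -------------------------------------------------
    def params_array(self, table: Mapping[str, float],
                     complete: bool = False) -> np.ndarray:
        """Convert a name->value mapping to the canonical parameter vector.

        With ``complete=True`` every parameter must be present; otherwise
        missing entries fall back to the network defaults.
        """
        table = {PARAM_ALIASES.get(k, k): v for k, v in table.items()}
        unknown = set(table) - set(self.param_names)
        if unknown:
            raise ConfigurationError(
                f"unknown kinetic constant(s): {sorted(unknown)}")
        if complete:
            missing = set(self.param_names) - set(table)
            if missing:
                raise ConfigurationError(
                    f"missing kinetic constant(s): {sorted(missing)}")
            base = np.empty(len(self.param_names))
        else:
            base = self.default_params.copy()
        for name, value in table.items():
            value = float(value)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"rate constant {name} must be finite and >= 0, "
                    f"got {value}")
            base[self.param_index[name]] = value
        return base

    def state_array(self, table: Mapping[str, float],
                    complete: bool = False) -> np.ndarray:
        """Convert a name->value mapping to a state vector (nM)."""
        unknown = set(table) - set(self.species)
        if unknown:
            raise ConfigurationError(f"unknown species: {sorted(unknown)}")
        if complete:
            missing = set(self.species) - set(table)
            if missing:
                raise ConfigurationError(
                    f"missing initial condition(s): {sorted(missing)}")
            base = np.empty(len(self.species))
        else:
            base = self.default_initials.copy()
        for name, value in table.items():
            value = float(value)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"concentration {name} must be finite and >= 0, "
                    f"got {value}")
            base[self.species_index[name]] = value
        return base

    def split_overrides(self, table: Mapping[str, float]):
        """Split a mixed name->value mapping into (params, initials)."""
        params, initials = {}, {}
        for name, value in table.items():
            canon = PARAM_ALIASES.get(name, name)
            if canon in self.param_index:
                params[canon] = value
            elif name in self.species_index:
                initials[name] = value
            else:
                raise ConfigurationError(
                    f"{name!r} is neither a kinetic constant nor a species")
        return params, initials

    # -- compiled right-hand side ---------------------------------------
    def _compile(self):
        n_rx = len(self.reactions)
        max_reac = max((len(rx.reactants) for rx in self.reactions), default=1)
        max_reac = max(max_reac, 1)
        self._k_idx = np.empty(n_rx, dtype=np.int64)
        self._km_idx = np.full(n_rx, -1, dtype=np.int64)
        self._driver_idx = np.full(n_rx, -1, dtype=np.int64)
        self._deg = np.zeros(n_rx, dtype=np.bool_)
        self._n_reac = np.zeros(n_rx, dtype=np.int64)
        self._reac_idx = np.zeros((n_rx, max_reac), dtype=np.int64)
        self._reac_st = np.zeros((n_rx, max_reac), dtype=np.int64)
        stoich = np.zeros((len(self.species), n_rx))
        for j, rx in enumerate(self.reactions):
            self._k_idx[j] = self.param_index[rx.rate_constant]
            if rx.km_constant is not None:
                self._km_idx[j] = self.param_index[rx.km_constant]
            if rx.driver is not None:
                self._driver_idx[j] = self.species_index[rx.driver]
            self._deg[j] = rx.deg_scaled
            self._n_reac[j] = len(rx.reactants)
            for i, (name, st) in enumerate(rx.reactants):
                self._reac_idx[j, i] = self.species_index[name]
                self._reac_st[j, i] = st
                stoich[self.species_index[name], j] -= st
            for name, st in rx.products:
                stoich[self.species_index[name], j] += st
        self._stoich = stoich
        self._deg_idx = self.param_index.get("deg_ratio", -1)

    def effective_rates(self, params: np.ndarray):
        """Per-reaction rate constants with deg_ratio folded in, plus Km."""
        k_eff = params[self._k_idx].astype(float).copy()
        deg = params[self._deg_idx] if self._deg_idx >= 0 else 1.0
        k_eff[self._deg] *= deg
        km = np.where(self._km_idx >= 0, params[np.maximum(self._km_idx, 0)],
                      0.0)
        return k_eff, km

    def rhs(self, state: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Mass-action derivative d[state]/dt in nM/s."""
        if state.shape != (len(self.species),):
            raise ValidationError(
                f"state has shape {state.shape}, expected "
                f"({len(self.species)},)")
        k_eff, km = self.effective_rates(params)
        from ._rhs import reaction_rates
        rates = reaction_rates(np.asarray(state, dtype=float), k_eff, km,
                               self._km_idx, self._driver_idx, self._n_reac,
                               self._reac_idx, self._reac_st)
        return self._stoich @ rates

    def moiety_total(self, state: np.ndarray, moiety: str) -> float:
        weights = MOIETIES[moiety]
        return float(sum(state[self.species_index[s]] * w
                         for s, w in weights.items()))

    def param_value(self, params: np.ndarray, name: str) -> float:
        return float(params[self.param_index[PARAM_ALIASES.get(name, name)]])


def ode_rhs(state: np.ndarray, params: Mapping[str, float] | np.ndarray,
            network: ReactionNetwork) -> np.ndarray:
    """Derivative of the species state under mass-action kinetics (nM/s)."""
    if not isinstance(params, np.ndarray):
        params = network.params_array(params)
    return network.rhs(np.asarray(state, dtype=float), params)


def _load_table(source) -> dict[str, float]:
    """Load a name->value table from a mapping, JSON path or CSV path."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return {k: float(v) for k, v in source.items()}
    text = None
    path = str(source)
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        raw = json.loads(text)
        # accept both {"name": value} and {"name": {"value": v, "units": u}};
        # keys starting with "_" are comments
        return {k: float(v["value"] if isinstance(v, Mapping) else v)
                for k, v in raw.items() if not k.startswith("_")}
    # flat CSV dialect: name,value[,units]
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith("name,"):
            continue
        parts = line.split(",")
        table[parts[0]] = float(parts[1])
    return table


def _packaged(name: str) -> str:
    return str(resources.files("prljag").joinpath("data", name))


def load_default_parameters() -> dict[str, float]:
    """Initial-guess kinetic constants (packaged fixture)."""
    return _load_table(_packaged("kinetic_parameters.json"))


def load_default_initials() -> dict[str, float]:
    """Initial species concentrations in nM (packaged fixture)."""
    return _load_table(_packaged("initial_conditions.json"))


def load_fitted_parameters() -> dict[str, float]:
    """Best-fit parameter/initial-condition overrides from the packaged
    two-stage Monte Carlo fit (see its embedded provenance metadata)."""
    path = _packaged("fitted_parameters.json")
    with open(path) as fh:
        raw = json.load(fh)
    return {k: float(v) for k, v in raw["values"].items()}


def build_network(parameter_table=None, initial_table=None) -> ReactionNetwork:
    """Build and validate the PRL/JAK2/STAT3/JAG1 reaction network.

    Parameters
    ----------
    parameter_table, initial_table
        Optional name->value mappings, or paths to the JSON/CSV fixture
        dialects.  Omitted entries are not tolerated: the fixtures must
        supply every rate constant and every species.  When ``None`` the
        packaged default fixtures are used.
    """
    params = _load_table(parameter_table) if parameter_table is not None \
        else load_default_parameters()
    initials = _load_table(initial_table) if initial_table is not None \
        else load_default_initials()
    return ReactionNetwork(params, initials)
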