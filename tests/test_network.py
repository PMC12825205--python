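"""Network construction, mass-action right-hand side, and conservation."""

import numpy as np
import pytest

from prljag.errors import ConfigurationError, ValidationError
from prljag.network import (DENOMINATOR_PARAMS, MOIETIES, PARAM_NAMES,
                            REACTIONS, SPECIES, Reaction, ReactionNetwork,
                            build_network, load_default_parameters,
                            load_default_initials, ode_rhs)
from prljag.simulate import simulate


def test_exactly_49_tunable_parameters(net):
    assert len(net.param_names) == 49
    assert "deg_ratio" in net.param_names


def test_fitter_required_names_exist(net):
    required = ["k2f", "k2r", "k4", "k5f", "k6", "k8f", "k11f", "k12",
                "k23", "k25_1", "k30_1", "k28", "k31", "k33", "k34",
                "deg_ratio"]
    for name in required:
        assert name in net.param_index


def test_species_registry_fixed(net):
    assert net.species == SPECIES
    with pytest.raises(ValidationError):
        net.rhs(np.zeros(len(SPECIES) - 1), net.default_params)


def test_reaction_labels_partition_into_modules(net):
    labels = {rx.label for rx in net.reactions}
    modules = {
        "receptor": {"R1", "R2", "R3", "R4", "R5", "R6"},
        "dimerization": {"R8"},
        "shp2": {"R9", "R10"},
        "phosphatases": {"R11", "R12", "R13", "R15", "R16", "R17"},
        "nuclear_import_dna": {"R14", "R24"},
        "socs": {"R18", "R19", "R20", "R21", "R22", "R23"},
        "expression": {"R30", "R31", "R32", "R33", "R34"},
    }
    for member in modules.values():
        assert member <= labels
    # every label is an R1..R34 tag
    for rx in net.reactions:
        assert rx.label.startswith("R")
        assert 1 <= int(rx.label[1:]) <= 34


def test_missing_rate_constant_rejected_by_name():
    params = load_default_parameters()
    params.pop("k14")
    with pytest.raises(ConfigurationError, match="k14"):
        build_network(params, load_default_initials())


def test_negative_rate_constant_rejected():
    params = load_default_parameters()
    params["k6"] = -1.0
    with pytest.raises(ValidationError, match="k6"):
        build_network(params, load_default_initials())


def test_unknown_species_in_reaction_rejected():
    bad = Reaction("R99", "bogus", "k1f", (("NOPE", 1),), ())
    with pytest.raises(ConfigurationError, match="NOPE"):
        ReactionNetwork(load_default_parameters(), load_default_initials(),
                        reactions=(*REACTIONS, bad))


def test_alias_k30a_accepted(net):
    p = net.params_array({"k30a": 0.123})
    assert p[net.param_index["k30_1"]] == 0.123


def test_zero_state_gives_zero_derivative(net):
    dy = ode_rhs(np.zeros(len(net.species)), net.default_params, net)
    assert np.all(dy == 0.0)


def test_bimolecular_rate_arithmetic():
    """A + B -> C with k = 1 nM^-1 s^-1, A = 2, B = 3 gives dC/dt = 6."""
    toy = ReactionNetwork(
        {"k": 1.0}, {"A": 2.0, "B": 3.0, "C": 0.0},
        reactions=(Reaction("R1", "binding", "k",
                            (("A", 1), ("B", 1)), (("C", 1),)),),
        species=("A", "B", "C"), param_names=("k",))
    dy = toy.rhs(toy.default_initials, toy.default_params)
    assert dy[toy.species_index["C"]] == pytest.approx(6.0)
    assert dy[toy.species_index["A"]] == pytest.approx(-6.0)


def test_first_order_decay_matches_exponential():
    """Two-species toy A ->k B reproduces A0 * exp(-k t)."""
    k = 3.7e-4
    toy = ReactionNetwork(
        {"k": k}, {"A": 5.0, "B": 0.0},
        reactions=(Reaction("R1", "decay", "k", (("A", 1),), (("B", 1),)),),
        species=("A", "B"), param_names=("k",))
    tc = simulate(toy, t_end=10_000.0, dt_out=500.0, rtol=1e-9, atol=1e-12)
    expected = 5.0 * np.exp(-k * tc.t)
    np.testing.assert_allclose(tc.series("A"), expected, rtol=1e-6,
                               atol=1e-9)


def test_reversible_isomerization_matches_closed_form():
    """A <-> B relaxes as A_eq + (A0 - A_eq) exp(-(kf + kr) t)."""
    kf, kr, a0 = 2e-3, 5e-4, 8.0
    toy = ReactionNetwork(
        {"kf": kf, "kr": kr}, {"A": a0, "B": 0.0},
        reactions=(Reaction("R1", "fwd", "kf", (("A", 1),), (("B", 1),)),
                   Reaction("R1", "rev", "kr", (("B", 1),), (("A", 1),))),
        species=("A", "B"), param_names=("kf", "kr"))
    tc = simulate(toy, t_end=5000.0, dt_out=100.0, rtol=1e-9, atol=1e-12)
    a_eq = a0 * kr / (kf + kr)
    expected = a_eq + (a0 - a_eq) * np.exp(-(kf + kr) * tc.t)
    np.testing.assert_allclose(tc.series("A"), expected, rtol=1e-6,
                               atol=1e-9)


def test_reversible_binding_reaches_analytic_equilibrium():
    """A + B <-> C approaches the root of kf*a*(a + d) = kr*(a0 - a)."""
    kf, kr = 1e-3, 2e-3
    a0, b0 = 10.0, 6.0
    toy = ReactionNetwork(
        {"kf": kf, "kr": kr}, {"A": a0, "B": b0, "C": 0.0},
        reactions=(Reaction("R1", "bind", "kf", (("A", 1), ("B", 1)),
                            (("C", 1),)),
                   Reaction("R1", "unbind", "kr", (("C", 1),),
                            (("A", 1), ("B", 1)))),
        species=("A", "B", "C"), param_names=("kf", "kr"))
    tc = simulate(toy, t_end=50_000.0, dt_out=1000.0)
    # independent oracle: quadratic equilibrium condition
    d = b0 - a0
    disc = (kf * d + kr) ** 2 + 4 * kf * kr * a0
    a_eq = (-(kf * d + kr) + np.sqrt(disc)) / (2 * kf)
    assert tc.series("A")[-1] == pytest.approx(a_eq, rel=1e-5)
    np.testing.assert_allclose(tc.series("A") - tc.series("B"),
                               a0 - b0, rtol=0, atol=1e-6)


def test_rhs_matches_finite_difference_of_simulation(net):
    """The central difference of a tightly integrated trajectory matches
    the analytic RHS evaluated at the midpoint state to ~1e-6 relative."""
    rng = np.random.default_rng(42)
    y0 = net.default_initials.copy()
    y0 += rng.uniform(0, 1.0, size=y0.shape)
    h = 1e-3
    tc = simulate(net, initial=y0, t_end=2 * h, dt_out=h,
                  rtol=1e-12, atol=1e-13)
    fd = (tc.y[:, 2] - tc.y[:, 0]) / (2 * h)  # central difference at t = h
    dy = net.rhs(tc.y[:, 1], net.default_params)
    scale = np.abs(dy).max()
    np.testing.assert_allclose(fd, dy, rtol=1e-6, atol=1e-6 * scale)


@pytest.mark.parametrize("moiety", ["STAT3", "receptor", "PPX", "PPN",
                                    "SHP2", "PRL"])
def test_moiety_conservation_over_48h(net, moiety):
    """Totals of conserved moieties drift < 0.1% over 48 h at 120 ng/mL.

    STAT3, the receptor units, both phosphatases, SHP2 and prolactin have
    no synthesis or decay reactions, so their totals are exact invariants
    of the dynamics (SOCS, mRNA and JAG1 are excluded: they carry the
    model's explicit production/degradation terms).
    """
    tc = simulate(net, prl_dose=120.0, dt_out=600.0)
    totals = np.array([net.moiety_total(tc.y[:, i], moiety)
                       for i in range(len(tc.t))])
    assert totals[0] > 0
    drift = np.abs(totals - totals[0]) / totals[0]
    assert drift.max() < 1e-3


def test_socs_conserved_with_its_source_and_sink_disabled(net):
    # k25_1: induction; k20: free-SOCS turnover; k22: on-receptor decay
    params = net.params_array({"k25_1": 0.0, "k20": 0.0, "k22": 0.0})
    initial = net.state_array({"SOCS": 5.0})
    tc = simulate(net, params=params, initial=initial, prl_dose=120.0,
                  dt_out=600.0)
    totals = np.array([net.moiety_total(tc.y[:, i], "SOCS")
                       for i in range(len(tc.t))])
    assert np.abs(totals - totals[0]).max() / totals[0] < 1e-3


def test_denominator_parameter_classification(net):
    assert set(DENOMINATOR_PARAMS) == {"k25_2", "k30_2"}
    saturable = {rx.km_constant for rx in net.reactions if rx.km_constant}
    assert saturable == set(DENOMINATOR_PARAMS)


def test_fixture_roundtrip_json_csv(tmp_path, net):
    from prljag.io_utils import (read_params, write_params_csv,
                                 write_params_json)
    table = load_default_parameters()
    jpath, cpath = tmp_path / "p.json", tmp_path / "p.csv"
    write_params_json(table, jpath)
    write_params_csv(table, cpath)
    assert read_params(str(jpath)) == table
    assert read_params(str(cpath)) == table
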