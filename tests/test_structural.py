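from fractions import Fraction

import numpy as np
import pytest

from tumorflux.structural import (
    elementary_flux_modes,
    essential_reactions,
    minimal_cut_sets,
    write_cut_set_report,
)

from conftest import make_net


def chain_net():
    # A(blood) -> B(cell) -> C(blood)
    return make_net(
        [("A", "blood"), ("B", "cell"), ("C", "blood")],
        [("r1", {"A": -1, "B": 1}, False),
         ("r2", {"B": -1, "C": 1}, False)],
        biomass_id="r2",
    )


def diamond_net():
    # A -> B -> D and A -> C -> D; A, D boundary
    return make_net(
        [("A", "blood"), ("B", "cell"), ("C", "cell"), ("D", "blood")],
        [("rAB", {"A": -1, "B": 1}, False),
         ("rAC", {"A": -1, "C": 1}, False),
         ("rBD", {"B": -1, "D": 1}, False),
         ("rCD", {"C": -1, "D": 1}, False)],
        biomass_id="rBD",
    )


def diamond_with_sink():
    # A -> B -> D, A -> C -> D, D -> out; boundary A only
    return make_net(
        [("A", "blood"), ("B", "cell"), ("C", "cell"), ("D", "cell")],
        [("rAB", {"A": -1, "B": 1}, False),
         ("rAC", {"A": -1, "C": 1}, False),
         ("rBD", {"B": -1, "D": 1}, False),
         ("rCD", {"C": -1, "D": 1}, False),
         ("sink", {"D": -1}, False)],
        biomass_id="sink",
    )


class TestElementaryFluxModes:
    def test_linear_chain_single_mode(self):
        efms = elementary_flux_modes(chain_net())
        assert len(efms) == 1
        assert efms[0].support == {"r1", "r2"}

    def test_diamond_two_modes(self):
        efms = elementary_flux_modes(diamond_net())
        assert len(efms) == 2
        supports = {frozenset(m.support) for m in efms}
        assert supports == {frozenset({"rAB", "rBD"}),
                            frozenset({"rAC", "rCD"})}

    def test_reversible_isomerase_two_directions(self):
        net = make_net(
            [("A", "blood"), ("B", "blood")],
            [("r1", {"A": -1, "B": 1}, True)],
            biomass_id="r1",
        )
        efms = elementary_flux_modes(net)
        assert len(efms) == 2
        signs = sorted(m.coefficient("r1") for m in efms)
        assert signs[0] < 0 < signs[1]

    def test_modes_satisfy_steady_state(self, net, efms):
        """Every packaged-network EFM is an exact kernel vector of S_m."""
        S = net.S_m
        for mode in efms[::25]:
            v = np.zeros(len(net.reactions))
            for rid, coef in mode.coefficients:
                v[net.reaction_index(rid)] = float(coef)
            np.testing.assert_allclose(S @ v, 0.0, atol=1e-9)

    def test_supports_are_minimal(self, efms):
        supports = [m.support for m in efms[::40]]
        all_supports = [m.support for m in efms]
        for s in supports:
            assert not any(o < s for o in all_supports)

    def test_unconstrained_irreversible_reaction_is_one_mode(self):
        net = make_net(
            [("A", "blood"), ("B", "blood")],
            [("r1", {"A": -1, "B": 1}, False)],
            biomass_id="r1",
        )
        efms = elementary_flux_modes(net)
        assert len(efms) == 1
        assert efms[0].coefficient("r1") > 0

    def test_deterministic_order(self):
        e1 = elementary_flux_modes(diamond_net())
        e2 = elementary_flux_modes(diamond_net())
        assert [m.coefficients for m in e1] == [m.coefficients for m in e2]


class TestMinimalCutSets:
    def test_chain_every_step_cuts(self):
        cuts = minimal_cut_sets(chain_net(), "r2")
        assert {c.reactions for c in cuts} == {frozenset({"r1"}),
                                               frozenset({"r2"})}

    def test_diamond_sink_target(self):
        cuts = minimal_cut_sets(diamond_with_sink(), "sink")
        got = {c.reactions for c in cuts}
        assert frozenset({"sink"}) in got
        assert frozenset({"rAB", "rAC"}) in got  # both branches at the source
        assert frozenset({"rBD", "rCD"}) in got  # both branches at the sink

    def test_blocked_target_returns_empty(self):
        # B is produced but its consumer is the only producer's twin: make a
        # dead-end target (consumes an internal metabolite nothing produces)
        net = make_net(
            [("A", "blood"), ("B", "cell"), ("Z", "cell")],
            [("r1", {"A": -1, "B": 1}, False),
             ("r2", {"B": -1, "A": 1}, False),
             ("dead", {"Z": -1}, False)],
            biomass_id="dead",
        )
        assert minimal_cut_sets(net, "dead") == []

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            minimal_cut_sets(chain_net(), "nope")

    def test_report_format(self, tmp_path):
        cuts = minimal_cut_sets(chain_net(), "r2")
        path = tmp_path / "cuts.tsv"
        write_cut_set_report(cuts, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "size\treaction_ids"
        assert lines[1:] == ["1\tr1", "1\tr2"]


class TestEssentialReactions:
    def test_chain_all_essential(self):
        assert essential_reactions(chain_net(), "r2") == ["r1", "r2"]

    def test_target_always_essential(self):
        for net, tgt in [(chain_net(), "r1"), (diamond_with_sink(), "rAB")]:
            assert tgt in essential_reactions(net, tgt)

    def test_diamond_branches_not_essential(self):
        ess = essential_reactions(diamond_with_sink(), "sink")
        assert ess == ["sink"]


# ---------------------------------------------------------------------------
# LP-based soundness/minimality on the packaged reconstruction
# ---------------------------------------------------------------------------


def _max_target_flux(net, target, knocked=frozenset()):
    from scipy.optimize import linprog

    n = len(net.reactions)
    lb = [-1000.0 if r.reversible else 0.0 for r in net.reactions]
    ub = [1000.0] * n
    for rid in knocked:
        j = net.reaction_index(rid)
        lb[j] = ub[j] = 0.0
    c = np.zeros(n)
    c[net.reaction_index(target)] = -1.0
    res = linprog(c, A_eq=net.S_m, b_eq=np.zeros(net.S_m.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    assert res.status == 0
    return -res.fun


class TestPackagedNetworkCuts:
    def test_cut_sets_block_growth(self, net, efms):
        cuts = minimal_cut_sets(net, "Vgrowth", efms)
        sample = [c for c in cuts if c.size <= 2] + cuts[::40]
        for cut in sample:
            assert _max_target_flux(net, "Vgrowth", cut.reactions) < 1e-9

    def test_cut_sets_are_minimal(self, net, efms):
        cuts = minimal_cut_sets(net, "Vgrowth", efms)
        for cut in [c for c in cuts if 2 <= c.size <= 3][:10]:
            for leave_out in cut.reactions:
                rest = cut.reactions - {leave_out}
                assert _max_target_flux(net, "Vgrowth", rest) > 1e-6
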