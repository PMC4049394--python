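"""Flip-flop construction, clocked latch behaviour, and frequency division.

Functional tests drive the circuits either with an idealized square clock
(external drive) or with the real shaped clock-pulse cascade; the digital JK
oracle in conftest provides the expected state sequences.
"""
import numpy as np
import pytest

from geneclock import (
    GateKind,
    SolverSettings,
    build_binary_counter,
    build_jk_falling,
    build_jk_rising,
    build_mod3_counter,
    build_pwm_circuit,
    cascade,
    d10_design,
    d90_design,
    measure_period,
    period_from_edges,
    simulate,
    square_wave,
    steady_window,
)
from geneclock.sequential_logic import CounterDesign

from conftest import digital_jk


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


def test_rising_flip_flop_structure():
    ff = build_jk_rising(prefix="ff.")
    assert len(ff.species) == 6
    kinds = {g.output: g.kind for g in ff.gates}
    assert sum(k is GateKind.AND for k in kinds.values()) == 4
    assert kinds["ff.Q"] is GateKind.NOR and kinds["ff.Qbar"] is GateKind.NOR
    # Qbar seeds at its maximal level, everything else at zero
    initials = {s.name: s.initial for s in ff.species}
    assert initials["ff.Qbar"] == pytest.approx(1.0)
    assert initials["ff.Q"] == 0.0


def test_falling_flip_flop_structure():
    ff = build_jk_falling(prefix="ff.")
    assert len(ff.species) == 6
    assert all(g.kind is GateKind.NAND for g in ff.gates)


def test_binary_counter_structure():
    c2 = build_binary_counter(2)
    assert len(c2.species) == 12  # two flip-flops, no carry genes
    assert not any(s.name.startswith("G") for s in c2.species)
    c3 = build_binary_counter(3)
    carry = next(g for g in c3.gates if g.output == "G1")
    assert carry.kind is GateKind.AND
    assert [r.source for r in carry.regulators] == ["ff1.Q", "ff2.Q"]
    ff3_w = next(g for g in c3.gates if g.output == "ff3.W")
    assert ff3_w.regulators[0].source == "G1"
    with pytest.raises(ValueError):
        build_binary_counter(0)


def test_mod3_counter_structure():
    c = build_mod3_counter()
    assert len(c.species) == 19  # 3 flip-flops + output gene
    out = next(g for g in c.gates if g.output == "G1")
    assert out.kind is GateKind.OR
    assert [r.source for r in out.regulators] == ["ff2.Q", "ff3.Q"]
    # wiring: J1 = Qbar2, J2 = Q1, J3 = Q2, K3 = Qbar2, K1 = K2 = logic 1
    reg = {g.output: [r.source for r in g.regulators] for g in c.gates}
    assert reg["ff1.V"][0] == "ff2.Qbar"
    assert reg["ff2.V"][0] == "ff1.Q"
    assert reg["ff3.V"][0] == "ff2.Q"
    assert reg["ff3.W"][0] == "ff2.Qbar"
    assert reg["ff1.W"][0] == "one" and reg["ff2.W"][0] == "one"
    # unbound clock references surface as diagnostics until composed
    assert any("clk1" in d for d in c.validate())


def test_counter_design_convenience():
    with pytest.raises(ValueError):
        CounterDesign(kind="binary")
    with pytest.raises(ValueError):
        CounterDesign(kind="gray", delta=2)
    c = CounterDesign(kind="mod3").build()
    assert len(c.species) == 19


# ---------------------------------------------------------------------------
# Clocked behaviour (idealized square clock)
# ---------------------------------------------------------------------------


def _edge_times(drive, t_end, falling=False):
    t = np.arange(0.0, t_end, 0.01)
    v = np.array([drive(x) for x in t])
    above = v > 0.5
    if falling:
        idx = np.where(above[:-1] & ~above[1:])[0]
    else:
        idx = np.where(~above[:-1] & above[1:])[0]
    return t[idx]


def _run_flip_flop(edge, j, k, cycles=8):
    period, duty = 32.0, (0.1 if edge == "rising" else 0.9)
    clk = square_wave(period, duty, high=1.0)
    build = build_jk_rising if edge == "rising" else build_jk_falling
    circ = (
        build(j_src="J", k_src="K", clk_src="CLK", prefix="ff.")
        .with_source("J", 1.0 if j else 0.0)
        .with_source("K", 1.0 if k else 0.0)
        .with_drive("CLK", clk)
    )
    t_end = (cycles + 2) * period
    trace = simulate(circ, SolverSettings(t_end=t_end))
    edges = _edge_times(clk, t_end, falling=(edge == "falling"))[:cycles]
    # sample the settled state half a cycle after each trigger edge
    q = trace["ff.Q"]
    got = [bool(q[int((te + period / 2) / 0.01)] > 0.5) for te in edges]
    state, expected = False, []
    for _ in edges:
        state = digital_jk(state, bool(j), bool(k))
        expected.append(state)
    return got, expected


@pytest.mark.parametrize("j,k", [(0, 0), (0, 1), (1, 0), (1, 1)])
def test_rising_flip_flop_truth_table(j, k):
    """The rising-edge flip-flop reproduces hold/reset/set/toggle against
    the digital JK oracle over eight clock cycles."""
    got, expected = _run_flip_flop("rising", j, k)
    assert got == expected


def test_falling_flip_flop_toggles_on_falling_edges():
    """With J=K=1 the all-NAND flip-flop toggles once per falling edge of a
    wide clock pulse (its outputs alternate with twice the clock period)."""
    got, _ = _run_flip_flop("falling", 1, 1)
    assert all(a != b for a, b in zip(got, got[1:]))


def test_falling_flip_flop_static_clock_holds():
    """With the clock held constant the latch settles and stays put."""
    circ = (
        build_jk_falling(j_src="J", k_src="K", clk_src="CLK", prefix="ff.")
        .with_source("J", 1.0)
        .with_source("K", 0.0)
        .with_source("CLK", 1.0)
    )
    trace = simulate(circ, SolverSettings(t_end=100.0))
    tail = steady_window(trace, 0.5)["ff.Q"]
    assert tail.max() - tail.min() < 1e-6


def test_toggle_outputs_are_complementary():
    """While toggling, whenever Q sits in its upper quarter Qbar sits in its
    lower quarter, and vice versa."""
    period = 32.0
    clk = square_wave(period, 0.1, high=1.0)
    circ = (
        build_jk_rising(j_src="J", k_src="K", clk_src="CLK", prefix="ff.")
        .with_source("J", 1.0)
        .with_source("K", 1.0)
        .with_drive("CLK", clk)
    )
    trace = simulate(circ, SolverSettings(t_end=320.0))
    w = steady_window(trace, 0.3)
    q, qbar = w["ff.Q"], w["ff.Qbar"]
    swing_q = q.max() - q.min()
    swing_b = qbar.max() - qbar.min()
    upper_q = q > q.min() + 0.75 * swing_q
    lower_b = qbar < qbar.min() + 0.25 * swing_b
    assert np.all(lower_b[upper_q])
    upper_b = qbar > qbar.min() + 0.75 * swing_b
    lower_q = q < q.min() + 0.25 * swing_q
    assert np.all(lower_q[upper_b])


def test_single_flip_flop_divides_by_two():
    """A delta=1 counter (J=K=1) halves the clock frequency."""
    clk = square_wave(32.0, 0.1, high=1.0)
    circ = build_binary_counter(1, clk_src="CLK").with_drive("CLK", clk)
    trace = simulate(circ, SolverSettings(t_end=640.0))
    assert period_from_edges(trace, "ff1.Q") == pytest.approx(64.0, rel=0.05)


# ---------------------------------------------------------------------------
# Frequency division with the real clock-pulse chain
# ---------------------------------------------------------------------------


def _clock_chain(rep_circuit, with_wide=False):
    chain = build_pwm_circuit(rep_circuit, "p_cI", d10_design(), prefix="clkA_")
    if with_wide:
        chain = build_pwm_circuit(chain, "p_cI", d90_design(), prefix="clkB_")
    return chain


def test_buffered_binary_counter_divides_by_four(rep_circuit):
    """With relay Buffers on the inter-flip-flop links, the two-stage counter
    driven by the shaped clock pulse yields Q1 at twice and Q2 at four times
    the clock period."""
    chain = _clock_chain(rep_circuit)
    counter = build_binary_counter(2, buffered_wiring=True)
    circ = cascade(chain, counter, wiring={"clk": "clkA_6"})
    trace = simulate(circ, SolverSettings(t_end=900.0))
    t_clk = measure_period(trace, "clkA_6")
    assert period_from_edges(trace, "ff1.Q") == pytest.approx(2 * t_clk, rel=0.05)
    assert period_from_edges(trace, "ff2.Q") == pytest.approx(4 * t_clk, rel=0.05)


def test_buffered_mod3_counter_divides_by_three(rep_circuit):
    """The buffered mod-3 counter's OR output completes one cycle per three
    clock pulses."""
    chain = _clock_chain(rep_circuit, with_wide=True)
    counter = build_mod3_counter(buffered_wiring=True)
    circ = cascade(chain, counter, wiring={"clk1": "clkA_6", "clk2": "clkB_6"})
    trace = simulate(circ, SolverSettings(t_end=900.0))
    t_clk = measure_period(trace, "clkA_6")
    assert period_from_edges(trace, "G1") == pytest.approx(3 * t_clk, rel=0.05)
    # exactly one G1 cycle per three clock pulses in the steady window
    from geneclock import detect_edges

    g_edges, _ = detect_edges(trace, "G1", discard_fraction=0.3)
    clk_edges, _ = detect_edges(trace, "clkA_6", discard_fraction=0.3)
    assert len(clk_edges) == pytest.approx(3 * len(g_edges), abs=2)
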