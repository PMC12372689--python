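"""Deterministic recursions for SLR-expanding inversions."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import invfate as iv
from invfate import ModelParams, SLRState

Q0 = 2e-4
N_LOCI = 2000  # ntot * x for the benchmark parameters


def test_initial_state(params25):
    st_ = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0)
    assert st_.qXfW == st_.qXmW == st_.qYW == pytest.approx(8e-4, rel=1e-12)
    assert st_.qYIW == 0.0
    assert st_.YI == Q0


def test_initial_state_no_mutation(make_params):
    p = ModelParams(mu=0.0, s=0.01, h=0.25, ntot=10_000, x=0.2, N=10_000)
    st_ = iv.make_initial_slr_state(p, d=0, n=N_LOCI, q0=Q0)
    assert all(q == 0.0 for q in st_.freqs()[1:])


def test_initial_state_equilibrated(params25):
    st_ = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0, equilibrate=True)
    assert st_.qXfW == pytest.approx(params25.q_hat, abs=1e-5)
    # and it is an actual fixed point of the full step (inversion absent)
    frozen = dataclasses.replace(st_, YI=1e-300, qYIW=st_.qXfW)
    nxt = iv.slr_step(frozen, params25)
    dev = max(abs(a - b) for a, b in zip(nxt.freqs()[1:], frozen.freqs()[1:]))
    assert dev < 1e-12


def test_invalid_load_raises(params25):
    with pytest.raises(ValueError):
        iv.make_initial_slr_state(params25, d=3, n=2, q0=Q0)


def test_neutral_identity_step():
    """mu=0 and all frequencies 0: every fitness is 1, nothing moves."""
    p = ModelParams(mu=0.0, s=0.01, h=0.25, ntot=10_000, x=0.2, N=10_000)
    st_ = SLRState(YI=0.37, qXfD=0, qXmD=0, qYD=0, qXfW=0, qXmW=0, qYW=0, qYIW=0,
                   d=0, n=N_LOCI)
    nxt = iv.slr_step(st_, p)
    assert nxt == st_


def test_step_matches_direct_equation_evaluation(params25):
    """The life-cycle YI update equals the inversion-frequency recursion
    written out literally, evaluated at the post-mutation state."""
    state = iv.make_initial_slr_state(params25, d=1, n=N_LOCI, q0=Q0)
    s, h = params25.s, params25.h
    for _ in range(50):
        m = iv.mutate_slr_state(state, params25)
        # independent transcription of the recursion
        pXfD, qXfD = 1 - m.qXfD, m.qXfD
        pXfW, qXfW = 1 - m.qXfW, m.qXfW
        pYD, qYD = 1 - m.qYD, m.qYD
        pYW, qYW = 1 - m.qYW, m.qYW
        pYIW, qYIW = 1 - m.qYIW, m.qYIW
        num = (1 - s * (h * pXfD + qXfD)) ** m.d * (
            1 - s * (h * (pYIW * qXfW + qYIW * pXfW) + qYIW * qXfW)
        ) ** (m.n - m.d)
        alt = (1 - s * (h * (pXfD * qYD + qXfD * pYD) + qXfD * qYD)) ** m.d * (
            1 - s * (h * (pXfW * qYW + qXfW * pYW) + qXfW * qYW)
        ) ** (m.n - m.d)
        wbar = m.YI * num + (1 - m.YI) * alt
        expected_yi = m.YI * num / wbar
        state = iv.slr_step(state, params25)
        assert state.YI == pytest.approx(expected_yi, abs=1e-14)


def test_relative_fitness_symmetric_state(params25):
    """All classes equal (including the inverted Y) and d=0: wYI == wY."""
    q = params25.q_hat
    st_ = SLRState(YI=0.1, qXfD=q, qXmD=q, qYD=q, qXfW=q, qXmW=q, qYW=q, qYIW=q,
                   d=0, n=N_LOCI)
    wYI, wY, wbar = iv.slr_relative_fitness(st_, params25)
    assert wYI == pytest.approx(wY, rel=1e-14)
    assert wYI / wbar == pytest.approx(1.0, rel=1e-14)


def test_relative_fitness_single_locus_substitution(params25):
    """d=1, n=1: matches direct substitution into the per-locus factors."""
    q = params25.q_hat
    st_ = SLRState(YI=Q0, qXfD=q, qXmD=q, qYD=q, qXfW=q, qXmW=q, qYW=q, qYIW=0.0,
                   d=1, n=1)
    s, h = params25.s, params25.h
    wYI, wY, wbar = iv.slr_relative_fitness(st_, params25)
    assert wYI == pytest.approx(1 - s * (h * (1 - q) + q), rel=1e-14)
    assert wY == pytest.approx(1 - s * (2 * h * q * (1 - q) + q * q), rel=1e-14)


def test_first_generation_fitness_near_one_plus_ux(params25):
    st_ = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0)
    m = iv.mutate_slr_state(st_, params25)
    wYI, _, wbar = iv.slr_relative_fitness(m, params25)
    assert wYI / wbar == pytest.approx(1.004, rel=0.1)


class TestTrajectory:
    def test_unloaded_converges_to_q_star(self, params25):
        init = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0)
        tr = iv.slr_trajectory(init, params25, max_generations=50_000)
        q_star = iv.effective_initial_frequency(params25, Q0)
        assert tr.converged
        assert tr.metadata["final_YI"] == pytest.approx(q_star, rel=0.1)
        # fitness approaches neutrality from above
        assert tr["w_rel"][0] > 1.0
        assert tr["w_rel"][-1] == pytest.approx(1.0, abs=1e-6)

    def test_loaded_becomes_deleterious_and_extinct(self, params25):
        init = iv.make_initial_slr_state(params25, d=1, n=N_LOCI, q0=Q0)
        tr = iv.slr_trajectory(init, params25, max_generations=50_000)
        assert tr.extinct
        assert tr.metadata["final_YI"] < 1e-5
        w = tr["w_rel"]
        assert w[0] > 1.0          # initially beneficial
        assert w[-1] < 1.0         # permanent load dominates at the end
        # the crossing below 1 happens at some finite generation
        assert any(a >= 1.0 > b for a, b in zip(w, w[1:]))

    def test_recessive_loaded_rises_then_crashes(self, params05):
        init = iv.make_initial_slr_state(params05, d=2, n=N_LOCI, q0=Q0)
        tr = iv.slr_trajectory(init, params05, max_generations=300_000)
        assert tr.extinct
        assert max(tr["YI"]) > 10 * Q0

    def test_perturbation_signs(self, params25):
        """During the rise of a d=1 inversion (relative to a matched
        inversion-free twin run): qYIW climbs monotonically from 0, qXfD is
        driven below its equilibrium, and qXfW is pushed above it."""
        init = iv.make_initial_slr_state(params25, d=1, n=N_LOCI, q0=Q0,
                                         equilibrate=True)
        twin = dataclasses.replace(init, YI=1e-300)
        a, b = init, twin
        pert_w, pert_d, qyiw = [], [], []
        for _ in range(1500):
            a = iv.slr_step(a, params25)
            b = iv.slr_step(b, params25)
            pert_w.append(a.qXfW - b.qXfW)
            pert_d.append(a.qXfD - b.qXfD)
            qyiw.append(a.qYIW)
        assert all(y2 >= y1 for y1, y2 in zip(qyiw, qyiw[1:]))
        assert min(pert_d) < -1e-9
        assert max(pert_w) > 1e-12
        assert max(pert_w) < abs(min(pert_d))  # the W effect is much smaller

    def test_max_generations_stop(self, params25):
        init = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0)
        tr = iv.slr_trajectory(init, params25, max_generations=10)
        assert len(tr) == 10 and tr.stop_reason == "max_generations"

    def test_csv_roundtrip(self, params25, tmp_path):
        init = iv.make_initial_slr_state(params25, d=0, n=N_LOCI, q0=Q0)
        tr = iv.slr_trajectory(init, params25, max_generations=5)
        tr.write(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").exists()
        assert (tmp_path / "traj.json").exists()
        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.csv")
        assert list(df["generation"]) == [1, 2, 3, 4, 5]
        assert set(df.columns) >= {"YI", "qYIW", "w_rel"}


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    h=st.floats(0.05, 0.5),
    s=st.floats(1e-3, 0.5),
    mu=st.floats(1e-8, 1e-5),
    yi=st.floats(1e-6, 0.9),
    d=st.integers(0, 3),
)
def test_frequencies_stay_in_unit_interval(h, s, mu, yi, d):
    """Every state component stays within [0, 1] along the recursion."""
    p = ModelParams(mu=mu, s=s, h=h, ntot=10_000, x=0.2, N=1000)
    q = min(p.q_hat, 0.5)
    state = SLRState(YI=yi, qXfD=q, qXmD=q, qYD=q, qXfW=q, qXmW=q, qYW=q,
                     qYIW=0.0, d=d, n=50)
    for _ in range(30):
        state = iv.slr_step(state, p)  # SLRState validates bounds on build
    assert all(0.0 <= v <= 1.0 for v in state.freqs())


def test_r_affects_only_transients(params25):
    """At the inversion-free equilibrium every class sits at the same q
    regardless of the X/Y recombination rate r."""
    q = iv.inversion_free_equilibrium(params25)
    st_ = SLRState(YI=1e-300, qXfD=q, qXmD=q, qYD=q, qXfW=q, qXmW=q, qYW=q,
                   qYIW=q, d=0, n=N_LOCI)
    for r in (0.0, 0.1, 0.5):
        nxt = iv.slr_step(st_, params25, r=r)
        dev = max(abs(a - b) for a, b in zip(nxt.freqs()[1:], st_.freqs()[1:]))
        assert dev < 1e-12
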