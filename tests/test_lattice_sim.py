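"""13-PF lattice: energies, Brownian stepping, kinetic layer,
detachment, cap initialization, rate measurement, bookkeeping."""

import math

import numpy as np
import pytest

from mtflare import constants
from mtflare._mt_kernel import make_bond_tables, mt_forces
from mtflare.energetics import InteractionParams, MechanicalParams
from mtflare.lattice_sim import (Event, KineticParams, MicrotubuleState,
                                 NucleotideEffect, Protocol,
                                 brownian_substep, detach_oligomers,
                                 init_capped_mt, kinetic_step, measure_rate,
                                 mt_length, run_mt, total_energy)
from mtflare.pf_mechanics import (PFChain, SimulationConfig,
                                  simulate_single_pf)


class TestTotalEnergy:
    def test_straight_lattice_closed_form(self, mech, inter):
        # all lateral sites in contact, all springs unstretched,
        # every hinge paying the straightness cost B/2 theta0^2
        st = MicrotubuleState.straight_lattice(10, "GTP", mech,
                                               mobile_dimers=5)
        terms = total_energy(st, mech, inter, decompose=True)
        K = 20
        assert terms["lateral"] == pytest.approx(13 * K * -inter.b_lat)
        assert terms["longitudinal"] == pytest.approx(
            13 * (K // 2 - 1) * -inter.b_long)
        assert terms["spring"] == pytest.approx(0.0, abs=1e-12)
        assert terms["bending"] == pytest.approx(
            13 * (K - 1) * 0.5 * mech.B_bend * mech.theta0 ** 2)

    def test_empty_lattice_zero(self, mech, inter):
        st = MicrotubuleState(capacity=8)
        assert total_energy(st, mech, inter) == 0.0

    def test_axial_translation_invariance(self, mech, inter, rng):
        st = MicrotubuleState.straight_lattice(6, "GDP", mech)
        st.x[:, :12] += rng.normal(0, 0.2, (13, 12))
        e0 = total_energy(st, mech, inter)
        st.z[:, :12] += 17.3
        assert total_energy(st, mech, inter) == pytest.approx(e0)

    def test_kernel_energy_matches_numpy(self, mech, inter, rng):
        st = MicrotubuleState.straight_lattice(6, "GTP", mech,
                                               mobile_dimers=6)
        st.x[:, :12] += rng.normal(0, 0.3, (13, 12))
        st.tau[:, :12] += rng.normal(0, 0.1, (13, 12))
        effect = NucleotideEffect(b_lat_GTP=inter.b_lat,
                                  b_lat_GDP=inter.b_lat,
                                  B_GTP=mech.B_bend, B_GDP=mech.B_bend)
        blat_m, Bm = st.monomer_arrays(effect)
        tables = make_bond_tables(inter.a_lat, inter.r_lat, inter.a_long,
                                  inter.b_long, inter.r_long)
        cap = st.capacity
        fz = np.empty((13, cap)); fx = np.empty((13, cap))
        ftau = np.empty((13, cap))
        U = mt_forces(st.z, st.x, st.tau, np.cos(st.tau), np.sin(st.tau),
                      st.K, st.mstart, 13, st.rho0,
                      math.cos(2 * math.pi / 13), math.sin(2 * math.pi / 13),
                      mech.r_tub, mech.k_intra, Bm, mech.theta0, blat_m,
                      *tables, fz, fx, ftau)
        assert U == pytest.approx(total_energy(st, mech, inter), abs=0.05)


class TestBrownianLayer:
    def test_zero_temperature_energy_descent(self, mech, inter, rng):
        st = MicrotubuleState.straight_lattice(8, "GTP", mech,
                                               mobile_dimers=4)
        st.x[:, 8:16] += rng.normal(0, 0.3, (13, 8))
        energies = [total_energy(st, mech, inter)]
        for _ in range(4):
            brownian_substep(st, mech, inter, n_steps=200, T=0.0,
                             rng=np.random.default_rng(0))
            energies.append(total_energy(st, mech, inter))
        assert all(e1 <= e0 + 1e-9 for e0, e1 in zip(energies,
                                                     energies[1:]))

    def test_frozen_boundary_immobile(self, mech, inter):
        st = MicrotubuleState.straight_lattice(8, "GTP", mech,
                                               mobile_dimers=2)
        frozen = st.z[:, :8].copy()
        brownian_substep(st, mech, inter, n_steps=500,
                         rng=np.random.default_rng(1))
        assert np.array_equal(st.z[:, :8], frozen)
        assert not np.array_equal(st.z[:, 14:16],
                                  MicrotubuleState.straight_lattice(
                                      8, "GTP", mech).z[:, 14:16])

    def test_single_pf_degenerate_state_matches_chain_kernel(self, mech,
                                                             inter):
        # a 1-PF lattice with breakable inter-dimer bonds must step
        # exactly like the chain kernel in breakable mode at T = 0
        from mtflare._pf_kernel import pf_bd_steps

        n = 16
        chain = PFChain.equilibrium(n, mech)
        chain.tau[4:] += 0.05
        st = MicrotubuleState(n_pf=1, mech=mech, mobile_dimers=7,
                              capacity=32)
        st.K[0] = n
        st.z[0, :n] = chain.positions[:, 1]
        st.x[0, :n] = chain.positions[:, 0]
        st.tau[0, :n] = chain.tau
        brownian_substep(st, mech, inter, n_steps=200, T=0.0,
                         rng=np.random.default_rng(0))

        x = chain.positions[:, 0].copy()
        y = chain.positions[:, 1].copy()
        tau = chain.tau.copy()
        ct, st_ = np.cos(tau), np.sin(tau)
        gq = constants.gamma_translation(mech.r_tub)
        gt = constants.gamma_rotation(mech.r_tub)
        noise = np.zeros((200, 3 * (n - 2) + 1))
        hyst = np.zeros(2, dtype=np.int64)
        pf_bd_steps(x, y, tau, ct, st_, 2, noise, 0,
                    2e-12, gq, gt, 0.0, 0.0,
                    mech.k_intra, mech.B_bend, mech.theta0, mech.r_tub,
                    True, inter.a_long, inter.b_long, inter.r_long,
                    False, 0.0, np.zeros(1), 0.0, mech.k_rep, 3.0, 1.0, 0.0,
                    2, 0.15, 0.05, hyst,
                    10**9, np.empty((0, n)), np.empty((0, n)),
                    np.empty((0, n)), np.empty(0))
        assert st.z[0, :n] == pytest.approx(y, abs=1e-6)
        assert st.x[0, :n] == pytest.approx(x, abs=1e-6)
        assert st.tau[0, :n] == pytest.approx(tau, abs=1e-6)

    def test_free_monomer_diffusion_variance(self, mech, inter):
        # a bond-free monomer diffuses with var = 2 kB T dt / gamma_q
        # per coordinate per step
        st = MicrotubuleState(n_pf=1, mech=mech, mobile_dimers=4,
                              capacity=8)
        st.K[0] = 1
        n_steps = 20000
        zs = np.empty(n_steps + 1)
        xs = np.empty(n_steps + 1)
        rng = np.random.default_rng(42)
        eng_rng = np.random.default_rng(7)
        zs[0], xs[0] = st.z[0, 0], st.x[0, 0]
        for i in range(n_steps):
            brownian_substep(st, mech, inter, n_steps=1, rng=eng_rng)
            zs[i + 1], xs[i + 1] = st.z[0, 0], st.x[0, 0]
        steps = np.concatenate([np.diff(zs), np.diff(xs)])
        kT = constants.KB * constants.T_DEFAULT
        gq = constants.gamma_translation(mech.r_tub)
        expected = 2 * kT * 2e-12 / gq
        assert np.var(steps) == pytest.approx(expected, rel=0.03)


class TestKineticLayer:
    def test_addition_probability_arithmetic(self):
        kin = KineticParams(k_on=0.26, c_tub=10.0, t_kin=0.013)
        assert kin.p_add() == pytest.approx(0.0338)
        with pytest.raises(ValueError, match="> 1"):
            KineticParams(k_on=10.0, c_tub=10.0, t_kin=0.013).p_add()

    def test_zero_concentration_never_adds(self, mech):
        st = MicrotubuleState.straight_lattice(4, "GTP", mech)
        kin = KineticParams(c_tub=0.0, k_hydr=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert kinetic_step(st, kin, rng) == []
        assert int(st.K.sum()) == 13 * 8

    def test_no_hydrolysis_conserves_nucleotide(self, mech):
        st = MicrotubuleState.straight_lattice(6, "GTP", mech)
        kin = KineticParams(c_tub=10.0, k_hydr=0.0)
        rng = np.random.default_rng(1)
        before = st.n_gtp()
        events = kinetic_step(st, kin, rng)
        adds = sum(1 for e in events if e.kind == "add")
        assert st.n_gtp() == before + adds
        assert all(e.kind == "add" for e in events)

    def test_hydrolysis_events_flip_dimers(self, mech):
        st = MicrotubuleState.straight_lattice(6, "GTP", mech)
        kin = KineticParams(c_tub=0.0, k_hydr=20.0)  # fast for the test
        rng = np.random.default_rng(2)
        before = st.n_gtp()
        events = kinetic_step(st, kin, rng)
        hyd = sum(1 for e in events if e.kind == "hydrolysis")
        assert hyd > 0
        assert st.n_gtp() == before - hyd

    def test_new_dimer_continues_tip_tangent(self, mech):
        st = MicrotubuleState.straight_lattice(4, "GTP", mech)
        st.tau[0, :8] = 0.3  # tilted tip
        k = int(st.K[0])
        st.append_dimer(0, gtp=True, theta0=mech.theta0)
        assert st.tau[0, k] == pytest.approx(0.3 + mech.theta0)
        assert st.tau[0, k + 1] == pytest.approx(0.3 + 2 * mech.theta0)
        # unstretched longitudinal site contact
        rt = mech.r_tub
        site_gap = np.hypot(
            (st.z[0, k] - rt * np.cos(st.tau[0, k]))
            - (st.z[0, k - 1] + rt * np.cos(st.tau[0, k - 1])),
            (st.x[0, k] - rt * np.sin(st.tau[0, k]))
            - (st.x[0, k - 1] + rt * np.sin(st.tau[0, k - 1])))
        assert site_gap == pytest.approx(0.0, abs=1e-12)


class TestDetachment:
    def test_intact_lattice_keeps_everything(self, mech, inter):
        st = MicrotubuleState.straight_lattice(8, "GDP", mech,
                                               mobile_dimers=4)
        assert detach_oligomers(st, inter) == []

    def test_displaced_terminal_dimer_removed(self, mech, inter):
        st = MicrotubuleState.straight_lattice(8, "GDP", mech,
                                               mobile_dimers=4)
        st.z[3, 14:16] += 25.0  # far beyond the bond range
        events = detach_oligomers(st, inter)
        assert len(events) == 1
        assert events[0].pf == 3 and events[0].size == 1
        assert st.K[3] == 14

    def test_broken_basal_bond_removes_whole_curl(self, mech, inter):
        st = MicrotubuleState.straight_lattice(8, "GDP", mech,
                                               mobile_dimers=6)
        st.z[5, 10:16] += 25.0  # 3-dimer oligomer, basal bond broken
        events = detach_oligomers(st, inter)
        assert len(events) == 1
        assert events[0].size == 3
        assert st.K[5] == 10

    def test_stretched_but_bonded_dimer_stays(self, mech, inter):
        st = MicrotubuleState.straight_lattice(8, "GDP", mech,
                                               mobile_dimers=4)
        st.z[2, 14:16] += 1.0  # strained, still inside the well region
        assert detach_oligomers(st, inter) == []


class TestCapInitialization:
    def test_zero_cap_is_pure_gdp(self, mech):
        st = init_capped_mt(30, 0, 110.0, np.random.default_rng(0), mech)
        assert st.n_gtp() == 0

    def test_expected_cap_size(self, mech):
        target = 225
        counts = [init_capped_mt(50, target, 110.0,
                                 np.random.default_rng(s), mech).n_gtp()
                  for s in range(100)]
        assert np.mean(counts) == pytest.approx(
            target, abs=3 * math.sqrt(target))

    def test_gtp_fraction_decays_from_plus_end(self, mech):
        acc = np.zeros(50)
        for s in range(60):
            st = init_capped_mt(50, 225, 110.0,
                                np.random.default_rng(s), mech)
            acc += st.nuc[:, :50].mean(axis=0)
        frac = acc[::-1] / 60  # index 0 = plus end
        assert frac[0] > 0.9
        smoothed = np.convolve(frac, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smoothed) <= 0.02)

    def test_oversized_cap_rejected(self, mech):
        with pytest.raises(ValueError, match="larger"):
            init_capped_mt(10, 200, 110.0, np.random.default_rng(0), mech)


class TestRateMeasurement:
    def test_linear_trace_recovers_slope(self):
        t = np.linspace(0, 1, 50)
        assert measure_rate(t, 100 + 20 * t) == pytest.approx(20.0)

    def test_constant_trace_zero(self):
        t = np.linspace(0, 1, 50)
        assert measure_rate(t, np.full(50, 7.0)) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_trace_sampling_distribution(self, rng):
        t = np.linspace(0, 1, 78)
        slopes = [measure_rate(t, -400 * t + rng.normal(0, 5, t.size))
                  for _ in range(100)]
        assert np.mean(slopes) == pytest.approx(-400, abs=2)

    def test_burn_in_shorter_trace_errors(self):
        with pytest.raises(ValueError, match="burn-in"):
            measure_rate(np.array([0.0, 0.1]), np.array([0.0, 1.0]),
                         burn_in=0.5)


class TestRunMT:
    def test_no_source_never_gains_mass(self, mech, inter):
        proto = Protocol(mech=mech, inter=inter,
                         kin=KineticParams(k_on=0.0, c_tub=0.0),
                         effect=NucleotideEffect(),
                         duration=0.13, bd_window=5e-9, seed=0,
                         hydrolysis=False)
        st = MicrotubuleState.straight_lattice(6, "GDP", mech,
                                               mobile_dimers=3)
        run = run_mt(st, proto)
        assert np.all(np.diff(run.lengths_flux) <= 1e-12)

    def test_seeded_determinism(self, mech, inter):
        def go():
            proto = Protocol(mech=mech, inter=inter,
                             kin=KineticParams(), effect=NucleotideEffect(),
                             duration=0.065, bd_window=2e-9, seed=9)
            st = MicrotubuleState.straight_lattice(6, "GTP", mech,
                                                   mobile_dimers=3)
            return run_mt(st, proto)

        r1, r2 = go(), go()
        assert np.array_equal(r1.lengths, r2.lengths)
        assert np.array_equal(r1.lengths_flux, r2.lengths_flux)
        assert len(r1.events) == len(r2.events)

    def test_subunit_conservation_replay(self, mech, inter):
        proto = Protocol(mech=mech, inter=inter,
                         kin=KineticParams(c_tub=40.0),
                         effect=NucleotideEffect(),
                         duration=0.26, bd_window=2e-9, seed=4)
        st = MicrotubuleState.straight_lattice(6, "GTP", mech,
                                               mobile_dimers=3)
        k0 = st.n_dimers.copy()
        run = run_mt(st, proto)
        replay = k0.copy()
        for e in run.events:
            if e.kind == "add":
                replay[e.pf] += 1
            elif e.kind == "detach":
                replay[e.pf] -= e.size
        assert np.array_equal(replay, run.state.n_dimers)

    def test_dilution_flag_blocks_additions(self, mech, inter):
        proto = Protocol(mech=mech, inter=inter,
                         kin=KineticParams(c_tub=40.0),
                         effect=NucleotideEffect(),
                         duration=0.13, bd_window=2e-9, seed=5,
                         dilution=True)
        st = init_capped_mt(8, 30, 40.0, np.random.default_rng(0), mech,
                            mobile_dimers=3)
        run = run_mt(st, proto)
        assert not any(e.kind == "add" for e in run.events)

    def test_length_of_blunt_lattice_is_tip_height(self, mech):
        st = MicrotubuleState.straight_lattice(10, "GTP", mech)
        assert mt_length(st) == pytest.approx(
            float(st.z[0, 19]), abs=1e-9)
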