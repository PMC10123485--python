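"""Stochastic engine: propagation laws, binding rules, event statistics,
conservation, and determinism."""

import numpy as np
import pytest

import prebcr._kernel as K
from prebcr.dynamics import (
    InvariantError,
    detect_and_bind,
    fire_first_order,
    first_order_probability,
    initialize_state,
    propagate,
    rms_displacement,
    run_simulation,
    step,
)


@pytest.fixture(scope="module")
def base(preset_697):
    # receptors only, no binding, chosen for per-op unit checks
    return preset_697.replace(sigma_rec=0.0, n_syk_cell=0, lyn_fraction=0.0)


def _make_chain(state, ids):
    """Link receptors ``ids`` into one chain sharing a position."""
    for a, b in zip(ids, ids[1:]):
        state.rec_i[a, K.R_RIGHT] = b
        state.rec_i[b, K.R_LEFT] = a
    state.rec_f[ids] = state.rec_f[ids[0]]


class TestClosedForms:
    def test_first_order_probability_values(self):
        assert first_order_probability(0.0, 1e-5) == 0.0
        assert first_order_probability(1.14, 1e-5) == \
            pytest.approx(1.139994e-5, rel=1e-5)
        assert first_order_probability(1e12, 1e-5) == pytest.approx(1.0)

    def test_first_order_probability_validation(self):
        with pytest.raises(ValueError):
            first_order_probability(-1.0, 1e-5)
        with pytest.raises(ValueError):
            first_order_probability(1.0, 0.0)

    def test_rms_displacement_values(self):
        assert rms_displacement(0.16, 1, 1e-5) == \
            pytest.approx(1.78885e-3, rel=1e-5)
        # D_agg = D/M: tetramer jumps at half the monomer RMS
        assert rms_displacement(0.16, 4, 1e-5) == \
            pytest.approx(0.5 * rms_displacement(0.16, 1, 1e-5))
        assert rms_displacement(0.0, 1, 1e-5) == 0.0

    def test_rms_displacement_validation(self):
        with pytest.raises(ValueError):
            rms_displacement(0.16, 0, 1e-5)


def _step_msd(state, n_steps, box=1.5):
    prev = state.rec_f.copy()
    sq = []
    for _ in range(n_steps):
        propagate(state)
        d = state.rec_f - prev
        d -= np.round(d / box) * box
        sq.append((d ** 2).sum(axis=1))
        prev = state.rec_f.copy()
    sq = np.concatenate(sq)
    return sq.mean(), sq.std() / np.sqrt(len(sq))


class TestPropagation:
    def test_monomer_msd_matches_4_d_dt(self, base):
        st = initialize_state(base, seed=3, n_receptors=300)
        msd, se = _step_msd(st, 150)
        assert abs(msd - 4 * 0.16 * 1e-5) < 3 * se

    def test_tetramer_msd_scales_inversely_with_size(self, base):
        st = initialize_state(base, seed=4, n_receptors=400)
        for i in range(0, 400, 4):
            _make_chain(st, [i, i + 1, i + 2, i + 3])
        msd, se = _step_msd(st, 200)
        assert abs(msd - 4 * (0.16 / 4) * 1e-5) < 3 * se

    def test_chain_members_comove(self, base):
        st = initialize_state(base, seed=5, n_receptors=6)
        _make_chain(st, [0, 1, 2])
        for _ in range(20):
            propagate(st)
        assert np.allclose(st.rec_f[0], st.rec_f[1])
        assert np.allclose(st.rec_f[1], st.rec_f[2])


class TestDetectAndBind:
    def test_monomers_inside_radius_merge(self, preset_697):
        st = initialize_state(preset_697, seed=6, n_receptors=2,
                              n_lyn=0, n_syk=0)
        st.rec_f[0] = (0.5, 0.5)
        st.rec_f[1] = (0.5 + 0.5e-4, 0.5)
        detect_and_bind(st)
        assert sorted(map(len, st.chains())) == [2]

    def test_monomers_outside_radius_do_not_merge(self, preset_697):
        st = initialize_state(preset_697, seed=7, n_receptors=2,
                              n_lyn=0, n_syk=0)
        st.rec_f[0] = (0.5, 0.5)
        st.rec_f[1] = (0.5 + 2e-4, 0.5)
        detect_and_bind(st)
        assert sorted(map(len, st.chains())) == [1, 1]

    def test_syk_never_docks_on_unphosphorylated_itam(self, preset_697):
        st = initialize_state(preset_697, seed=8, n_receptors=1,
                              n_lyn=0, n_syk=1)
        st.rec_f[0] = (0.5, 0.5)
        st.syk_f[0] = (0.5, 0.5, 0.0)  # zero distance
        detect_and_bind(st)
        assert st.syk_i[0, K.S_REC] == -1

    def test_syk_docks_on_phosphorylated_itam(self, preset_697):
        st = initialize_state(preset_697, seed=9, n_receptors=1,
                              n_lyn=0, n_syk=1)
        st.rec_f[0] = (0.5, 0.5)
        st.rec_i[0, K.R_IGA] = 2
        st.syk_f[0] = (0.5 + 1e-4, 0.5, 0.0)  # inside the Igα status-2 radius
        detect_and_bind(st)
        assert st.syk_i[0, K.S_REC] == 0
        assert st.rec_i[0, K.R_AK] == K.OCC_SYK

    def test_lyn_unique_domain_binds_unphosphorylated_iga(self, preset_697):
        st = initialize_state(preset_697, seed=10, n_receptors=1,
                              n_lyn=1, n_syk=0)
        st.rec_f[0] = (0.5, 0.5)
        st.lyn_f[0] = (0.5 + 1e-4, 0.5)
        detect_and_bind(st)
        assert st.lyn_i[0, K.L_REC] == 0
        assert st.lyn_i[0, K.L_SITE] == 0  # Igα, via unique domain
        assert st.lyn_i[0, K.L_MODE] == 1

    def test_occupied_site_excludes_second_kinase(self, preset_697):
        st = initialize_state(preset_697, seed=11, n_receptors=1,
                              n_lyn=2, n_syk=0)
        st.rec_f[0] = (0.5, 0.5)
        st.lyn_f[:] = (0.5, 0.5)
        st.rec_i[0, K.R_IGB] = 0  # Igβ unbindable for Lyn at status 0
        detect_and_bind(st)
        assert np.count_nonzero(st.lyn_i[:, K.L_REC] >= 0) == 1


class TestFirstOrder:
    def test_isolated_receptor_with_docked_lyn_never_phosphorylates(
            self, preset_697):
        # trans-only rule: a monomer has no adjacent receptor to act on
        st = initialize_state(preset_697.replace(sigma_rec=0.0), seed=12,
                              n_receptors=1, n_lyn=1, n_syk=0)
        st.rec_f[0] = (0.5, 0.5)
        st.lyn_f[0] = (0.5, 0.5)
        detect_and_bind(st)
        assert st.lyn_i[0, K.L_REC] == 0
        for _ in range(3000):
            fire_first_order(st)
            if st.lyn_i[0, K.L_REC] < 0:  # re-dock if released
                st.lyn_f[0] = st.rec_f[0]
                detect_and_bind(st)
        assert st.rec_i[0, K.R_IGA] == 0
        assert st.rec_i[0, K.R_IGB] == 0
        assert st.lyn_i[0, K.L_Y397] == 0

    def test_dimer_partner_iga_first_phospho_time_is_exponential(
            self, preset_697):
        # docked unactivated Lyn phosphorylates the neighbour's Igα at 30/s
        params = preset_697.replace(sigma_rec=0.0, k_off_dimer=0.0, dt=1e-3)
        n_dimers = 300
        st = initialize_state(params, seed=13, n_receptors=2 * n_dimers,
                              n_lyn=n_dimers, n_syk=0)
        for i in range(n_dimers):
            _make_chain(st, [2 * i, 2 * i + 1])
            # dock Lyn i on receptor 2i's Igα by hand
            st.rec_i[2 * i, K.R_AK] = K.OCC_LYN
            st.rec_i[2 * i, K.R_AID] = i
            st.lyn_i[i, K.L_REC] = 2 * i
            st.lyn_i[i, K.L_SITE] = 0
            st.lyn_i[i, K.L_MODE] = 1
        # Lyn release is much slower (20/s) than the 30/s substrate rate;
        # freeze release and Lyn-activation noise by zeroing those draws
        st.rates.p_lyn_unbind[:] = 0.0
        st.rates.pb_lyny[:] = 0.0
        partner = np.arange(n_dimers) * 2 + 1
        first_step = np.full(n_dimers, -1)
        for s in range(400):
            fire_first_order(st)
            hit = (st.rec_i[partner, K.R_IGA] > 0) & (first_step < 0)
            first_step[hit] = s
        done = first_step >= 0
        assert done.mean() > 0.99
        mean_t = float(np.mean((first_step[done] + 0.5) * params.dt))
        se = mean_t / np.sqrt(done.sum())
        assert abs(mean_t - 1.0 / 30.0) < 3 * se

    def test_released_partners_do_not_instantly_rebind(self, preset_697):
        params = preset_697.replace(k_off_dimer=1e4)  # break fast
        st = initialize_state(params, seed=14, n_receptors=2, n_lyn=0,
                              n_syk=0)
        _make_chain(st, [0, 1])
        fired = False
        for _ in range(200):
            fire_first_order(st)
            if st.rec_i[0, K.R_RIGHT] == -1:
                fired = True
                break
        assert fired
        d = np.linalg.norm(st.rec_f[0] - st.rec_f[1])
        assert d == pytest.approx(1.1 * params.sigma_rec, rel=1e-9)


class TestStepAndRun:
    def test_zero_molecules_only_clock_advances(self, base):
        st = initialize_state(base, seed=15, n_receptors=0, n_lyn=0, n_syk=0)
        step(st)
        assert st.clock == pytest.approx(base.dt)

    def test_counts_conserved_through_steps(self, preset_697):
        st = initialize_state(preset_697, seed=16)
        for _ in range(50):
            step(st)
        assert st.n_receptors == 71
        assert sum(map(len, st.chains())) == 71
        assert st.n_lyn == 7 and st.n_syk == 169
        st.check_invariants()

    def test_fixed_seed_reproducible(self, preset_697):
        p = preset_697.replace(t_total=0.05, t_ini=0.0, sample_interval=0.005)
        a = run_simulation(p, seed=17)
        b = run_simulation(p, seed=17)
        assert a.timeseries.equals(b.timeseries)
        assert np.array_equal(a.final_state.rec_f, b.final_state.rec_f)

    def test_zero_binding_radius_keeps_pure_monomers(self, preset_697):
        p = preset_697.replace(sigma_rec=0.0, t_total=0.05, t_ini=0.0,
                               sample_interval=0.005)
        res = run_simulation(p, seed=18)
        assert (res.timeseries["pct_monomer"] == 100.0).all()

    def test_invariant_checker_flags_ring(self, base):
        st = initialize_state(base, seed=19, n_receptors=3)
        _make_chain(st, [0, 1, 2])
        st.rec_i[2, K.R_RIGHT] = 0
        st.rec_i[0, K.R_LEFT] = 2  # close the ring
        with pytest.raises(InvariantError):
            st.check_invariants()

    def test_snapshot_round_trip(self, preset_697, tmp_path):
        from prebcr.dynamics import restore_snapshot
        p = preset_697.replace(t_total=0.02, t_ini=0.0, sample_interval=0.002)
        res = run_simulation(p, seed=23)
        path = tmp_path / "snap.json"
        res.final_state.save_snapshot(path)
        back = restore_snapshot(p, path)
        assert np.array_equal(back.rec_i, res.final_state.rec_i)
        assert np.allclose(back.rec_f, res.final_state.rec_f)
        assert back.clock == res.final_state.clock
        step(back)  # restored state is steppable

    def test_dt_change_without_recalibration_warns(self, preset_697):
        p = preset_697.replace(dt=1e-4, t_total=1e-3, t_ini=0.0,
                               sample_interval=1e-3)
        with pytest.warns(UserWarning, match="re-calibrate"):
            run_simulation(p, seed=20)


class TestMonotonicity:
    def test_mean_aggregate_size_decreases_with_off_rate(self, preset_697):
        sizes = []
        for k_off in (0.5, 2.0, 8.0):
            p = preset_697.replace(
                box_x=0.5, box_y=0.5, sigma_rec=1e-3, dt=1e-4,
                k_off_dimer=k_off, t_total=40.0, t_ini=8.0,
                n_receptors_cell=round(40 * 315.7 / 0.25),
                n_syk_cell=0, lyn_fraction=0.0, sample_interval=0.05)
            res = run_simulation(p, seed=21)
            post = res.timeseries[res.timeseries.t >= 8.0]
            sizes.append(post.mean_agg_size.mean())
        assert sizes[0] > sizes[1] > sizes[2]

    def test_mean_aggregate_size_increases_with_density(self, preset_697):
        sizes = []
        for n in (10, 30, 90):
            p = preset_697.replace(
                box_x=0.5, box_y=0.5, sigma_rec=1e-3, dt=1e-4,
                k_off_dimer=2.0, t_total=40.0, t_ini=8.0,
                n_receptors_cell=round(n * 315.7 / 0.25),
                n_syk_cell=0, lyn_fraction=0.0, sample_interval=0.05)
            res = run_simulation(p, seed=22)
            post = res.timeseries[res.timeseries.t >= 8.0]
            sizes.append(post.mean_agg_size.mean())
        assert sizes[0] < sizes[1] < sizes[2]
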