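"""Trajectory analysis: clustering, profiles, diffusion, unbound fractions."""

import numpy as np
import pytest

from condex import (
    SimState,
    Trajectory,
    brownian_trajectory,
    cluster_polymers,
    density_profile,
    msd_diffusion,
    slab_configuration,
    unbound_fractions,
)
from condex.analysis import polymer_com
from condex.params import per_nm3_to_millimolar


def _dimer_state(positions, box=(50.0, 50.0, 50.0)):
    """AB dimers at given per-polymer anchor positions (B 0.5 nm from A)."""
    anchors = np.asarray(positions, dtype=float)
    n = len(anchors)
    pos = np.empty((2 * n, 3))
    pos[0::2] = anchors
    pos[1::2] = anchors + np.array([0.5, 0.0, 0.0])
    return SimState(
        positions=pos,
        velocities=np.zeros_like(pos),
        types=np.tile(np.array([0, 1], dtype=np.int8), n),
        mol=np.repeat(np.arange(n), 2),
        bonds=np.array([[2 * i, 2 * i + 1] for i in range(n)], dtype=np.int64),
        box=np.asarray(box, dtype=float),
        sequence="AB",
    )


def _brute_force_labels(state, cutoff=1.0):
    """O(N^2) union-find oracle for the clustering rule."""
    n_poly = state.n_polymers
    parent = list(range(n_poly))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pos, mol, box = state.positions, state.mol, state.box
    for a in range(len(pos)):
        for b in range(a + 1, len(pos)):
            if mol[a] == mol[b]:
                continue
            d = pos[a] - pos[b]
            d -= box * np.round(d / box)
            if np.dot(d, d) < cutoff**2:
                ra, rb = find(mol[a]), find(mol[b])
                if ra != rb:
                    parent[ra] = rb
    roots = [find(i) for i in range(n_poly)]
    uniq, inv, counts = np.unique(roots, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[inv]


class TestClustering:
    def test_isolated_polymers_are_singletons(self):
        st = _dimer_state([[5, 5, 5], [20, 20, 20], [35, 35, 35]])
        labels = cluster_polymers(st)
        assert len(set(labels)) == 3

    def test_single_contact_merges_two_polymers(self):
        # one A-B contact at 0.9 nm joins the pair into one cluster
        st = _dimer_state([[5, 5, 5], [5.5 + 0.9, 5, 5]])
        labels = cluster_polymers(st)
        assert labels[0] == labels[1]

    def test_contact_beyond_cutoff_does_not_merge(self):
        st = _dimer_state([[5, 5, 5], [5.5 + 1.1, 5, 5]])
        labels = cluster_polymers(st)
        assert labels[0] != labels[1]

    def test_periodic_contact_across_boundary(self):
        st = _dimer_state([[0.2, 5, 5], [49.0, 5, 5]], box=(50.0, 50.0, 50.0))
        # polymer 1's B sticker at x=49.5 wraps to within 1 nm of A at 0.2
        labels = cluster_polymers(st)
        assert labels[0] == labels[1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(4):
            st = _dimer_state(rng.uniform(0, 30, (25, 3)), box=(30.0, 30.0, 30.0))
            np.testing.assert_array_equal(
                cluster_polymers(st), _brute_force_labels(st)
            )

    def test_labels_sorted_by_cluster_size(self):
        st = _dimer_state(
            [[5, 5, 5], [6.5, 5, 5], [8, 5, 5], [30, 30, 30], [20, 40, 10]]
        )
        labels = cluster_polymers(st)
        # the three connected dimers form cluster 0
        assert list(labels[:3]) == [0, 0, 0]
        assert set(labels[3:]) == {1, 2}


class TestDensityProfile:
    def test_uniform_gas_is_flat_and_flagged(self):
        traj = brownian_trajectory(400, 0.5, n_frames=4, box=(60, 60, 60),
                                   seed=5)
        with pytest.warns(UserWarning):
            prof = density_profile(traj, kind="axis")
        assert not prof.phase_separated
        assert prof.c_dil == pytest.approx(400 / 60.0**3, rel=1e-9)

    def test_slab_fixture_concentrations_recovered(self):
        c_den, c_dil = 4.878e-3, 3.0e-5
        st = slab_configuration(c_den, c_dil, box=(600.0, 60.0, 60.0),
                                slab_width=80.0, seed=1)
        traj = Trajectory(
            times=np.array([0.0]), positions=st.positions[None],
            types=st.types, mol=st.mol, bonds=st.bonds, box=st.box,
            sequence=st.sequence,
        )
        prof = density_profile(traj, kind="axis")
        assert prof.c_den == pytest.approx(c_den, rel=0.03)
        assert prof.c_dil == pytest.approx(c_dil, rel=0.03)
        assert prof.d_half == pytest.approx((600 - 80) / 2, rel=0.02)

    def test_translation_invariance_of_recentering(self):
        # shifting all coordinates (with wrap) must not change the profile
        c_den, c_dil = 4.878e-3, 3.0e-5
        st = slab_configuration(c_den, c_dil, seed=2)
        shift = np.array([123.4, 7.0, -9.0])
        traj1 = Trajectory(
            times=np.array([0.0]), positions=st.positions[None],
            types=st.types, mol=st.mol, bonds=st.bonds, box=st.box,
        )
        traj2 = Trajectory(
            times=np.array([0.0]), positions=(st.positions + shift)[None],
            types=st.types, mol=st.mol, bonds=st.bonds, box=st.box,
        )
        p1 = density_profile(traj1, kind="axis")
        p2 = density_profile(traj2, kind="axis")
        np.testing.assert_allclose(p1.concentration, p2.concentration,
                                   rtol=1e-9, atol=1e-12)

    def test_concentration_bookkeeping_closes(self):
        # c_den*V_den + c_dil*V_dil ~ N_total within 2%
        st = slab_configuration(4.878e-3, 3.0e-5, box=(600.0, 60.0, 60.0),
                                slab_width=80.0, seed=3)
        traj = Trajectory(
            times=np.array([0.0]), positions=st.positions[None],
            types=st.types, mol=st.mol, bonds=st.bonds, box=st.box,
        )
        prof = density_profile(traj, kind="axis")
        area = st.box[1] * st.box[2]
        slab_w = st.box[0] - 2 * prof.d_half
        n_est = prof.c_den * slab_w * area + prof.c_dil * (
            st.box[0] - slab_w) * area
        assert n_est == pytest.approx(st.n_polymers, rel=0.02)

    def test_unit_conversion(self):
        assert per_nm3_to_millimolar(8e-4) == pytest.approx(1.33, abs=0.01)


class TestMSD:
    def test_static_trajectory_gives_zero(self):
        traj = brownian_trajectory(20, 1.0, n_frames=40, seed=3)
        traj.positions[:] = traj.positions[0]
        assert msd_diffusion(traj) == 0.0

    def test_brownian_diffusion_recovered(self):
        traj = brownian_trajectory(200, 0.5, n_frames=300, seed=4)
        D, t_lag, msd = msd_diffusion(traj, return_msd=True)
        assert D == pytest.approx(0.5, rel=0.05)
        # linearity of the time-averaged MSD
        fit = np.polyfit(t_lag, msd, 1)
        resid = msd - np.polyval(fit, t_lag)
        r2 = 1 - np.sum(resid**2) / np.sum((msd - msd.mean()) ** 2)
        assert r2 > 0.98

    def test_too_short_trajectory_rejected(self):
        traj = brownian_trajectory(5, 1.0, n_frames=8, seed=5)
        with pytest.raises(ValueError):
            msd_diffusion(traj)

    def test_polymer_com_averages_stickers(self):
        st = _dimer_state([[5, 5, 5]])
        com = polymer_com(st)
        np.testing.assert_allclose(com[0], [5.25, 5, 5])


class TestUnboundFractions:
    def test_tight_pairs_all_bound(self):
        st = _dimer_state([[5, 5, 5], [20, 20, 20]])  # B is 0.5 nm from A
        out = unbound_fractions(st)
        vals = [v for v in out.values() if not np.isnan(v)]
        assert all(v == 0.0 for v in vals)

    def test_no_contacts_all_unbound(self):
        # separate A and B beyond the attraction range within each dimer
        st = _dimer_state([[5, 5, 5], [20, 20, 20]])
        st.positions[1::2] += np.array([3.0, 0, 0])
        out = unbound_fractions(st)
        vals = [v for v in out.values() if not np.isnan(v)]
        assert all(v == 1.0 for v in vals)

    def test_matches_brute_force_pair_scan(self, rng):
        st = _dimer_state(rng.uniform(0, 12, (30, 3)), box=(12.0, 12.0, 12.0))
        out = unbound_fractions(st)
        # brute force: a sticker is bound iff an opposite-type sticker is
        # within 1 nm (periodic)
        pos, types, box = st.positions, st.types, st.box
        bound = np.zeros(len(pos), dtype=bool)
        for a in range(len(pos)):
            for b in range(len(pos)):
                if a == b or types[a] == types[b]:
                    continue
                d = pos[a] - pos[b]
                d -= box * np.round(d / box)
                if np.dot(d, d) < 1.0:
                    bound[a] = True
        labels = cluster_polymers(st)
        dense = (labels == 0)[st.mol]
        for phase, pmask in (("den", dense), ("dil", ~dense)):
            for tname, tval in (("A", 0), ("B", 1)):
                m = pmask & (types == tval)
                if m.any():
                    assert out[f"f_{phase}_{tname}"] == pytest.approx(
                        np.mean(~bound[m])
                    )
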