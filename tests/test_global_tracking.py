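import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from paintract.bundles import select_combinations
from paintract.global_tracking import (AnnealSchedule, EnergyModel,
                                       ProposalWeights, Segment, SegmentState,
                                       _Chain, accumulate, anneal, energy,
                                       extract_streamlines)
from paintract.phantom import build_phantom, single_bundle_config, synthesize_dwi


def make_state(segments, links=None, half_length=1.005):
    segs = {}
    for i, (c, n) in enumerate(segments):
        n = np.asarray(n, dtype=float)
        segs[i] = Segment(center=np.asarray(c, dtype=float),
                          orientation=n / np.linalg.norm(n),
                          half_length=half_length)
    st = SegmentState(segments=segs, links={}, half_length=half_length)
    for lid, (epa, epb) in enumerate(links or []):
        st.links[lid] = (epa, epb)
        st.segments[epa[0]].links[epa[1]] = lid
        st.segments[epb[0]].links[epb[1]] = lid
    return st


@pytest.fixture(scope="module")
def anneal_result(dwi_single, scheme_track, phantom_single):
    """One reproducible desk-scale annealing run on the straight bundle."""
    sched = AnnealSchedule(n_iter=80_000)
    state, (e0, e1) = anneal(dwi_single, scheme_track, phantom_single.wm_mask, sched,
                             seed=1, affine=phantom_single.affine, return_trace=True)
    return state, e0, e1


class TestEnergy:
    def test_link_bookkeeping_identity(self, dwi_single, scheme_track, phantom_single):
        """Linking two collinear touching segments lowers the energy by exactly
        the link bonus plus two endpoint penalties (zero curvature)."""
        m = EnergyModel()
        L = m.half_length_factor * 1.5
        c = np.array([30.0, 20.0, 30.0])
        x = np.array([1.0, 0.0, 0.0])
        seg_a = (c - L * x, x)
        seg_b = (c + L * x, x)
        unlinked = make_state([seg_a, seg_b], half_length=L)
        linked = make_state([seg_a, seg_b], links=[((0, 1), (1, 0))], half_length=L)
        kw = dict(mask=phantom_single.wm_mask, affine=phantom_single.affine, model=m)
        e_unl = energy(unlinked, dwi_single, scheme_track, **kw)
        e_lnk = energy(linked, dwi_single, scheme_track, **kw)
        expected_drop = m.link_bonus + 2 * m.endpoint_penalty
        assert e_unl - e_lnk == pytest.approx(expected_drop, abs=1e-9)

    def test_any_segment_raises_energy_on_isotropic_data(self, scheme_track):
        ph = build_phantom(single_bundle_config(with_bundles=False))
        dwi = synthesize_dwi(ph, scheme_track)
        empty = make_state([])
        kw = dict(mask=ph.wm_mask, affine=ph.affine)
        e_empty = energy(empty, dwi, scheme_track, **kw)
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = np.array([30.0, 20.0, 30.0]) + rng.uniform(-5, 5, 3)
            n = rng.standard_normal(3)
            st = make_state([(c, n)])
            assert energy(st, dwi, scheme_track, **kw) > e_empty

    def test_aligned_beats_perpendicular(self, dwi_single, scheme_track, phantom_single):
        c = np.array([30.0, 20.0, 30.0])  # on the straight +x bundle
        kw = dict(mask=phantom_single.wm_mask, affine=phantom_single.affine)
        e_par = energy(make_state([(c, [1.0, 0, 0])]), dwi_single, scheme_track, **kw)
        e_perp = energy(make_state([(c, [0.0, 1.0, 0])]), dwi_single, scheme_track, **kw)
        assert e_par < e_perp

    def test_incremental_energy_matches_from_scratch(self, anneal_result, dwi_single,
                                                     scheme_track, phantom_single):
        state, _, e1 = anneal_result
        e_scratch = energy(state, dwi_single, scheme_track, phantom_single.wm_mask,
                           affine=phantom_single.affine)
        assert e1 == pytest.approx(e_scratch, rel=1e-9)


class TestExtractStreamlines:
    def chain_of(self, k, L=1.0):
        x = np.array([1.0, 0.0, 0.0])
        segs = [(np.array([(2 * i + 1) * L, 0.0, 0.0]), x) for i in range(k)]
        links = [(((i, 1), (i + 1, 0))) for i in range(k - 1)]
        return make_state(segs, links=links, half_length=L)

    def test_three_collinear_segments_one_polyline(self):
        t = extract_streamlines(self.chain_of(3), min_points=3)
        assert len(t) == 1
        s = t.streamlines[0]
        assert len(s) == 4
        # perfectly straight
        assert np.allclose(s[:, 1:], 0.0)

    def test_chain_arc_length_equals_sum_of_segment_lengths(self):
        for k in (2, 5, 9):
            t = extract_streamlines(self.chain_of(k, L=0.7), min_points=2)
            arc = np.linalg.norm(np.diff(t.streamlines[0], axis=0), axis=1).sum()
            assert arc == pytest.approx(k * 2 * 0.7, abs=1e-9)

    def test_unlinked_state_empty(self):
        st = make_state([(np.array([1.0, 0, 0]), [1.0, 0, 0]),
                         (np.array([8.0, 0, 0]), [1.0, 0, 0])])
        assert len(extract_streamlines(st, min_points=2)) == 0

    def test_cycle_broken_with_warning(self):
        # four segments around a square, linked into a closed loop
        segs = [(np.array([0.0, -1.0, 0]), [0.0, 1, 0]),
                (np.array([1.0, 0.0, 0]), [1.0, 0, 0]),
                (np.array([0.0, 1.0, 0]), [0.0, 1, 0]),
                (np.array([-1.0, 0.0, 0]), [1.0, 0, 0])]
        links = [((0, 1), (1, 0)), ((1, 1), (2, 1)), ((2, 0), (3, 1)), ((3, 0), (0, 0))]
        st = make_state(segs, links=links, half_length=1.0)
        with pytest.warns(UserWarning, match="cyclic"):
            t = extract_streamlines(st, min_points=2)
        assert len(t) == 1


class TestDetailedBalance:
    def test_link_unlink_boltzmann_on_toy_chain(self, dwi_single, scheme_track,
                                                phantom_single):
        """Restricted to link/unlink moves on three fixed collinear segments,
        the empirical state distribution matches exp(-E/T): detailed balance.

        The expected probabilities come from exhaustive enumeration of the
        four admissible link-sets ({}, {AB}, {BC}, {AB, BC}).
        """
        pw = ProposalWeights(birth=0, death=0, move=0, link=0.5, unlink=0.5,
                             extend=0, retract=0)
        chain = _Chain(dwi_single, scheme_track, phantom_single.wm_mask,
                       affine=phantom_single.affine, proposal_weights=pw, seed=123)
        L = chain.half_length
        x = np.array([1.0, 0.0, 0.0])
        base = np.array([22.0, 20.0, 30.0])
        ids = [chain.insert_segment(base + (2 * i * L + 0.4 * i) * x, x)
               for i in range(3)]
        m = chain.model
        # state energies relative to the no-link state
        def link_energy():
            return -m.link_bonus - 2 * m.endpoint_penalty  # collinear: no curvature
        states = {frozenset(): 0.0,
                  frozenset([(0, 1)]): link_energy(),
                  frozenset([(1, 2)]): link_energy(),
                  frozenset([(0, 1), (1, 2)]): 2 * link_energy()}
        T = 0.3
        z = {k: np.exp(-v / T) for k, v in states.items()}
        tot = sum(z.values())
        expect = {k: v / tot for k, v in z.items()}

        def current_state():
            out = []
            for (sa, ea), (sb, eb) in chain.links.values():
                pair = tuple(sorted((ids.index(sa), ids.index(sb))))
                out.append(pair)
            return frozenset(out)

        counts = {k: 0 for k in states}
        n_steps = 100_000
        thin = 20
        kept = 0
        for i in range(n_steps):
            chain.step(T)
            if i % thin == 0:
                counts[current_state()] += 1
                kept += 1
        for k, p in expect.items():
            got = counts[k] / kept
            sigma = np.sqrt(p * (1 - p) / kept)
            assert abs(got - p) < 3 * max(sigma, 1e-3), (k, got, p)


class TestAnneal:
    def test_energy_decreases_and_segments_in_tube(self, anneal_result,
                                                   phantom_single):
        state, e0, e1 = anneal_result
        assert e1 < e0
        assert len(state.segments) > 100
        cl = phantom_single.bundles["AP"].centerline
        tree = cKDTree(cl)
        centers = np.array([s.center for s in state.segments.values()])
        d, near = tree.query(centers)
        frac_in = (d <= phantom_single.bundles["AP"].radius).mean()
        assert frac_in >= 0.9
        tang = phantom_single.bundles["AP"].tangents()[near]
        ors = np.array([s.orientation for s in state.segments.values()])
        ang = np.degrees(np.arccos(np.clip(np.abs((ors * tang).sum(1)), 0, 1)))
        assert np.median(ang) < 15.0

    def test_same_seed_identical_state(self, dwi_single, scheme_track, phantom_single):
        sched = AnnealSchedule(n_iter=20_000)
        kw = dict(schedule=sched, seed=7, affine=phantom_single.affine)
        s1 = anneal(dwi_single, scheme_track, phantom_single.wm_mask, **kw)
        s2 = anneal(dwi_single, scheme_track, phantom_single.wm_mask, **kw)
        assert len(s1.segments) == len(s2.segments)
        assert all(np.array_equal(a.center, b.center)
                   and np.array_equal(a.orientation, b.orientation)
                   for a, b in zip(s1.segments.values(), s2.segments.values()))

    def test_isotropic_phantom_near_empty(self, dwi_single, scheme_track,
                                          phantom_single):
        ph_iso = build_phantom(single_bundle_config(with_bundles=False))
        dwi_iso = synthesize_dwi(ph_iso, scheme_track)
        sched = AnnealSchedule(n_iter=60_000)
        st_b = anneal(dwi_single, scheme_track, phantom_single.wm_mask, sched,
                      seed=2, affine=phantom_single.affine)
        st_i = anneal(dwi_iso, scheme_track, ph_iso.wm_mask, sched,
                      seed=2, affine=ph_iso.affine)
        assert len(st_i.segments) < 0.05 * len(st_b.segments)

    def test_empty_mask_raises(self, dwi_single, scheme_track):
        with pytest.raises(ValueError):
            anneal(dwi_single, scheme_track, np.zeros((40, 40, 40), dtype=bool))


class TestAccumulate:
    def test_rounds_concatenate(self, dwi_single, scheme_track, phantom_single):
        sched1 = AnnealSchedule(n_iter=30_000, reheat_iter=10_000, rounds=1)
        sched3 = AnnealSchedule(n_iter=30_000, reheat_iter=10_000, rounds=3)
        t1 = accumulate(dwi_single, scheme_track, phantom_single.wm_mask, sched1,
                        seed=5, affine=phantom_single.affine)
        t3 = accumulate(dwi_single, scheme_track, phantom_single.wm_mask, sched3,
                        seed=5, affine=phantom_single.affine)
        # the first round of the 3-round run is the 1-round run
        assert len(t3) > len(t1)
        assert all(np.array_equal(a, b)
                   for a, b in zip(t1.streamlines, t3.streamlines[:len(t1)]))

    def test_rounds_one_equals_anneal_plus_extract(self, dwi_single, scheme_track,
                                                   phantom_single):
        sched = AnnealSchedule(n_iter=20_000, rounds=1)
        t = accumulate(dwi_single, scheme_track, phantom_single.wm_mask, sched,
                       seed=9, affine=phantom_single.affine)
        st = anneal(dwi_single, scheme_track, phantom_single.wm_mask, sched,
                    seed=9, affine=phantom_single.affine)
        t2 = extract_streamlines(st, min_points=3)
        assert len(t) == len(t2)
        assert all(np.array_equal(a, b) for a, b in zip(t, t2))

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=0.001, t_end=0.1)
        with pytest.raises(ValueError):
            AnnealSchedule(rounds=0)
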