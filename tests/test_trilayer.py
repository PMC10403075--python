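"""Trajectory statistics vs brute-force oracles, closed forms, invariances."""

import math

import numpy as np
import pytest

from conftest import make_random_frame
from staplekit.trilayer import (CoordinationParams, DegenerateGeometryError,
                                HBondCriterion, TrilayerFrame,
                                TrilayerTrajectory, assign_leaflets,
                                coordination_term, hbond_series,
                                insertion_depth, tg_contact_count,
                                tg_coordination)

# ---------------------------------------------------------------------------
# brute-force oracles: explicit python loops, raw formulas


def oracle_min_image(d, box):
    return [di - bi * round(di / bi) for di, bi in zip(d, box)]


def oracle_dist(a, b, box):
    d = oracle_min_image([a[0] - b[0], a[1] - b[1], a[2] - b[2]], box)
    return math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)


def oracle_switch_term(r, r0):
    """Raw ratio (1-(r/r0)^6)/(1-(r/r0)^12) with the continuity limit."""
    x = r / r0
    if abs(x - 1.0) < 1e-12:
        return 0.5
    return (1.0 - x ** 6) / (1.0 - x ** 12)


def oracle_leaflets(frame):
    pz = [frame.coords[k][2] for k in range(frame.n_atoms)
          if frame.is_phosphorus[k]]
    mid = (max(pz) + min(pz)) / 2.0
    upper = [z for z in pz if z >= mid]
    lower = [z for z in pz if z < mid]
    return sum(upper) / len(upper), sum(lower) / len(lower)


def oracle_depth(traj, pid):
    per_res = {}
    for frame in traj:
        up, lo = oracle_leaflets(frame)
        ca = [(int(frame.residue_index[k]), frame.coords[k][2])
              for k in range(frame.n_atoms)
              if frame.mol_id[k] == pid and frame.is_calpha[k]]
        zbar = sum(z for _, z in ca) / len(ca)
        if abs(zbar - up) <= abs(zbar - lo):
            plane, sign = up, 1.0
        else:
            plane, sign = lo, -1.0
        for r, z in ca:
            per_res.setdefault(r, []).append(sign * (z - plane))
    return {r: sum(v) / len(v) for r, v in per_res.items()}


def oracle_hbond_count(frame, pid, crit):
    count = 0
    for h in range(frame.n_atoms):
        d = frame.donor_parent[h]
        if d < 0 or frame.mol_id[h] != pid:
            continue
        for a in range(frame.n_atoms):
            if not (frame.is_acceptor[a] and frame.mol_class[a] == "TO"):
                continue
            r = oracle_dist(frame.coords[a], frame.coords[d], frame.box)
            dh = oracle_min_image(frame.coords[h] - frame.coords[d], frame.box)
            da = oracle_min_image(frame.coords[a] - frame.coords[d], frame.box)
            dot = sum(x * y for x, y in zip(dh, da))
            norm = (math.sqrt(sum(x * x for x in dh))
                    * math.sqrt(sum(x * x for x in da)))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, dot / norm))))
            if r <= crit.r_max0 - crit.curvature * theta ** 2:
                count += 1
    return count


def oracle_residue_coordination(frame, pid, r0):
    """Exhaustive double loop: per residue, max over TO of the pair sum."""
    residues = sorted({int(frame.residue_index[k]) for k in range(frame.n_atoms)
                       if frame.mol_id[k] == pid})
    to_ids = sorted({int(frame.mol_id[k]) for k in range(frame.n_atoms)
                     if frame.mol_class[k] == "TO"})
    out = {}
    for r in residues:
        best = 0.0
        for m in to_ids:
            s = 0.0
            for i in range(frame.n_atoms):
                if frame.mol_id[i] != pid or frame.residue_index[i] != r:
                    continue
                for j in range(frame.n_atoms):
                    if frame.mol_id[j] != m or frame.mol_class[j] != "TO":
                        continue
                    s += oracle_switch_term(
                        oracle_dist(frame.coords[i], frame.coords[j], frame.box), r0)
            best = max(best, s)
        out[r] = best
    return out


# ---------------------------------------------------------------------------


class TestCoordinationTerm:
    def test_limit_at_r0_is_half(self):
        assert coordination_term(0.4, 0.4) == pytest.approx(0.5, abs=1e-15)

    def test_direct_evaluation_at_3r0(self):
        # ri = 1.2 nm, r0 = 0.4 -> (1-3^6)/(1-3^12)
        expected = (1 - 3.0 ** 6) / (1 - 3.0 ** 12)
        assert coordination_term(1.2, 0.4) == pytest.approx(expected, rel=1e-12)

    def test_term_in_unit_interval_strictly_decreasing_continuous(self):
        r = np.linspace(1e-3, 2.0, 4001)
        t = coordination_term(r, 0.4)
        assert np.all(t > 0) and np.all(t <= 1)
        assert np.all(np.diff(t) < 0)
        # continuity across r0 on a fine grid
        assert np.max(np.abs(np.diff(t))) < 0.01

    def test_matches_raw_ratio_form_on_grid(self):
        for r in np.linspace(0.05, 1.5, 97):
            assert coordination_term(r, 0.4) == pytest.approx(
                oracle_switch_term(r, 0.4), rel=1e-12)


class TestLeafletAssignment:
    def test_symmetric_planes_split_equally(self):
        rng = np.random.default_rng(0)
        frame = make_random_frame(rng)
        a = assign_leaflets(frame)
        vals = list(a.pl_leaflet.values())
        assert vals.count("upper") == vals.count("lower") == 4

    def test_single_plane_is_degenerate(self):
        rng = np.random.default_rng(1)
        frame = make_random_frame(rng)
        frame.coords[frame.is_phosphorus, 2] = 1.5
        with pytest.raises(DegenerateGeometryError):
            assign_leaflets(frame)

    def test_fewer_than_two_phosphorus_rejected(self):
        rng = np.random.default_rng(2)
        frame = make_random_frame(rng)
        keep = ~frame.is_phosphorus
        keep[np.flatnonzero(frame.is_phosphorus)[0]] = True
        sub = TrilayerFrame(frame.coords[keep], frame.box,
                            frame.mol_class[keep], frame.mol_id[keep],
                            frame.residue_index[keep], frame.element[keep],
                            frame.atom_name[keep], frame.is_phosphorus[keep],
                            frame.is_calpha[keep], frame.is_acceptor[keep],
                            np.full(keep.sum(), -1))
        with pytest.raises(DegenerateGeometryError):
            assign_leaflets(sub)


N_ORACLE_FRAMES = 110


@pytest.fixture(scope="module")
def random_frames():
    rng = np.random.default_rng(1234)
    return [make_random_frame(rng) for _ in range(N_ORACLE_FRAMES)]


class TestOracleEquivalence:
    """Vectorized statistics agree with exhaustive loops on random frames."""

    N_FRAMES = N_ORACLE_FRAMES

    def test_insertion_depth_matches_per_frame_average(self, random_frames):
        for chunk in range(0, self.N_FRAMES, 10):
            traj = TrilayerTrajectory(random_frames[chunk:chunk + 10])
            pid = int(traj[0].peptide_ids()[0])
            prof = insertion_depth(traj)
            expected = oracle_depth(traj, pid)
            got = {}
            for leaf in prof.residues:
                for r, m in zip(prof.residues[leaf], prof.mean[leaf]):
                    got.setdefault(int(r), []).append(
                        (m, prof.n_frames[leaf]))
            for r, exp in expected.items():
                vals = got[r]
                pooled = sum(m * n for m, n in vals) / sum(n for _, n in vals)
                assert pooled == pytest.approx(exp, rel=1e-9, abs=1e-12)

    def test_hbond_counts_match_exhaustive_loops(self, random_frames):
        crit = HBondCriterion(r_max0=1.2, curvature=0.00005)  # permissive: exercise hits
        traj = TrilayerTrajectory(random_frames)
        series = hbond_series(traj, crit)
        total = series.total_counts
        pid = int(random_frames[0].peptide_ids()[0])
        for t, frame in enumerate(random_frames):
            assert total[t] == oracle_hbond_count(frame, pid, crit)
        assert total.sum() > 0  # the permissive criterion must actually fire

    def test_residue_coordination_matches_double_loop(self, random_frames):
        params = CoordinationParams(r0=0.4)
        for frame in random_frames[:30]:
            traj = TrilayerTrajectory([frame])
            pid = int(frame.peptide_ids()[0])
            residues, values = tg_coordination(traj, params=params)
            expected = oracle_residue_coordination(frame, pid, params.r0)
            for r, v in zip(residues, values):
                assert v == pytest.approx(expected[int(r)], rel=1e-9)

    def test_contact_count_matches_threshold_on_whole_peptide_sum(self, random_frames):
        params = CoordinationParams(r0=0.4)
        threshold = 1.0
        for frame in random_frames[:20]:
            traj = TrilayerTrajectory([frame])
            pid = int(frame.peptide_ids()[0])
            got = tg_contact_count(traj, threshold=threshold, params=params)
            to_ids = sorted({int(frame.mol_id[k]) for k in range(frame.n_atoms)
                             if frame.mol_class[k] == "TO"})
            count = 0
            for m in to_ids:
                s = 0.0
                for i in range(frame.n_atoms):
                    if frame.mol_id[i] != pid:
                        continue
                    for j in range(frame.n_atoms):
                        if frame.mol_id[j] != m or frame.mol_class[j] != "TO":
                            continue
                        s += oracle_switch_term(
                            oracle_dist(frame.coords[i], frame.coords[j],
                                        frame.box), params.r0)
                count += s > threshold
            assert got == pytest.approx(count, rel=1e-12)


class TestInvariances:
    def test_statistics_invariant_under_rigid_translation(self):
        rng = np.random.default_rng(7)
        frames = [make_random_frame(rng) for _ in range(5)]
        traj = TrilayerTrajectory(frames)
        shift = np.array([1.3, -0.7, 0.0])  # in-plane shift (z shifts both planes)
        shifted = TrilayerTrajectory([f.translated(shift) for f in frames])
        d0 = insertion_depth(traj)
        d1 = insertion_depth(shifted)
        for leaf in d0.residues:
            assert np.allclose(d0.mean[leaf], d1.mean[leaf], atol=1e-9)
        crit = HBondCriterion(r_max0=1.2, curvature=0.00005)
        assert np.array_equal(hbond_series(traj, crit).total_counts,
                              hbond_series(shifted, crit).total_counts)
        _, c0 = tg_coordination(traj)
        _, c1 = tg_coordination(shifted)
        assert np.allclose(c0, c1, atol=1e-9)

    def test_depth_invariant_under_z_translation_too(self):
        rng = np.random.default_rng(8)
        frames = [make_random_frame(rng) for _ in range(3)]
        traj = TrilayerTrajectory(frames)
        shifted = TrilayerTrajectory([f.translated([0, 0, 0.9]) for f in frames])
        d0, d1 = insertion_depth(traj), insertion_depth(shifted)
        for leaf in d0.residues:
            assert np.allclose(d0.mean[leaf], d1.mean[leaf], atol=1e-9)

    def test_to_relabeling_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(9)
        frame = make_random_frame(rng, n_to=4)
        to_ids = np.unique(frame.mol_id[frame.mol_class == "TO"])
        remap = dict(zip(to_ids, np.roll(to_ids, 1)))
        new_ids = np.array([remap.get(int(m), int(m)) for m in frame.mol_id])
        relabeled = TrilayerFrame(frame.coords, frame.box, frame.mol_class,
                                  new_ids, frame.residue_index, frame.element,
                                  frame.atom_name, frame.is_phosphorus,
                                  frame.is_calpha, frame.is_acceptor,
                                  frame.donor_parent)
        t0 = TrilayerTrajectory([frame])
        t1 = TrilayerTrajectory([relabeled])
        _, c0 = tg_coordination(t0)
        _, c1 = tg_coordination(t1)
        assert np.allclose(c0, c1, atol=1e-12)
        assert tg_contact_count(t0) == tg_contact_count(t1)


class TestHBondCriterion:
    def test_close_collinear_pair_is_bonded(self):
        crit = HBondCriterion()
        assert 0.28 <= crit.r_max0 - crit.curvature * 0.0 ** 2

    def test_r_040_never_bonded(self):
        crit = HBondCriterion()
        thetas = np.linspace(0, 90, 91)
        assert np.all(crit.r_max0 - crit.curvature * thetas ** 2 < 0.40)

    def test_percent_bonded_equals_time_average_of_indicator(self):
        rng = np.random.default_rng(11)
        frames = [make_random_frame(rng) for _ in range(20)]
        traj = TrilayerTrajectory(frames)
        crit = HBondCriterion(r_max0=1.2, curvature=0.00005)
        series = hbond_series(traj, crit)
        assert series.percent_bonded == pytest.approx(
            100.0 * np.mean(series.total_counts >= 1))

    def test_empty_acceptor_set_warns_and_returns_empty_series(self):
        rng = np.random.default_rng(12)
        frame = make_random_frame(rng, n_to=0)
        with pytest.warns(UserWarning):
            series = hbond_series(TrilayerTrajectory([frame]))
        assert series.status == "empty"
        assert series.percent_bonded == 0.0


class TestContactEdgeCases:
    def test_no_to_means_zero_contacts(self):
        rng = np.random.default_rng(13)
        frame = make_random_frame(rng, n_to=0)
        assert tg_contact_count(TrilayerTrajectory([frame])) == 0.0

    def test_infinite_threshold_gives_zero(self):
        rng = np.random.default_rng(14)
        frame = make_random_frame(rng, n_to=3)
        assert tg_contact_count(TrilayerTrajectory([frame]),
                                threshold=1e12) == 0.0

    def test_nonpositive_threshold_rejected(self):
        rng = np.random.default_rng(15)
        frame = make_random_frame(rng)
        with pytest.raises(ValueError):
            tg_contact_count(TrilayerTrajectory([frame]), threshold=0.0)
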