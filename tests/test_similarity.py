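import numpy as np
import pytest

from pbptraj import similarity
from pbptraj.similarity import (ContactSet, build_contacts, density_map, q_nc,
                                q_similarity, similarity_series)
from pbptraj.model_io import Trajectory
from pbptraj.synthetic import generate_trajectory

from conftest import ca_chain, random_rigid, transform_structure


def naive_q_nc(frame, reference, cutoff=8.0, separation=2, normalization="unit_identity"):
    """Independent double-loop oracle for the native-contact score."""
    ref_ca = {r: reference.coords[i] for r, i in reference.ca_by_residue().items()}
    frm_ca = {r: frame.coords[i] for r, i in frame.ca_by_residue().items()}
    residues = sorted(ref_ca)
    terms = []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            i, j = residues[a], residues[b]
            if j - i < separation:
                continue
            r_nat = float(np.linalg.norm(ref_ca[i] - ref_ca[j]))
            if r_nat > cutoff:
                continue
            r_comp = float(np.linalg.norm(frm_ca[i] - frm_ca[j]))
            sig = abs(i - j) ** 0.15
            terms.append(np.exp(-((r_nat - r_comp) ** 2) / (2 * sig ** 2)))
    if normalization == "unit_identity":
        return sum(terms) / len(terms)
    n = len(terms)
    return sum(terms) / ((n - 1) * (n - 2))


def naive_q_similarity(frame, reference, separation=2, normalization="unit_identity"):
    ref_ca = {r: reference.coords[i] for r, i in reference.ca_by_residue().items()}
    frm_ca = {r: frame.coords[i] for r, i in frame.ca_by_residue().items()}
    residues = sorted(ref_ca)
    terms = []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            i, j = residues[a], residues[b]
            if j - i < separation:
                continue
            r_ref = float(np.linalg.norm(ref_ca[i] - ref_ca[j]))
            r_comp = float(np.linalg.norm(frm_ca[i] - frm_ca[j]))
            sig = abs(i - j) ** 0.15
            terms.append(np.exp(-((r_ref - r_comp) ** 2) / (sig ** 2)))
    if normalization == "unit_identity":
        return sum(terms) / len(terms)
    n = len(residues)
    return sum(terms) / ((n - 1) * (n - 2))


class TestBuildContacts:
    def test_collinear_boundary_inclusive(self):
        st = ca_chain([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        cs = build_contacts(st, cutoff=8.0, separation=2)
        assert cs.pairs == ((1, 3),)
        assert cs.native_distances[0] == pytest.approx(8.0)

    def test_no_contacts_is_error(self):
        st = ca_chain([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        with pytest.raises(ValueError, match="no contacts"):
            build_contacts(st, cutoff=7.9)

    def test_matches_double_loop_oracle(self, rng):
        st = ca_chain(rng.normal(size=(10, 3)) * 4)
        cs = build_contacts(st)
        want = set()
        res = sorted(st.ca_by_residue())
        coords = {r: st.coords[i] for r, i in st.ca_by_residue().items()}
        for a in range(len(res)):
            for b in range(a + 1, len(res)):
                i, j = res[a], res[b]
                if j - i >= 2 and np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                    want.add((i, j))
        assert set(cs.pairs) == want

    def test_contact_set_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            ContactSet(((1, 3), (1, 3)), np.array([4.0, 4.0]), "x", 8.0, 2)
        with pytest.raises(ValueError, match="separation"):
            ContactSet(((1, 2),), np.array([4.0]), "x", 8.0, 2)
        with pytest.raises(ValueError, match="exceeds cutoff"):
            ContactSet(((1, 3),), np.array([9.0]), "x", 8.0, 2)


class TestQnc:
    def test_identity_is_one(self, small_refs):
        open_ref, _ = small_refs
        cs = build_contacts(open_ref)
        assert q_nc(open_ref, cs) == 1.0

    def test_far_limit(self, small_refs):
        open_ref, _ = small_refs
        cs = build_contacts(open_ref)
        blown = open_ref.with_coords(open_ref.coords * 50.0)
        assert q_nc(blown, cs) < 1e-6

    def test_hand_oracle_five_residues(self, rng):
        ref = ca_chain([(0, 0, 0), (3.8, 0, 0), (5.0, 3.0, 0), (2.0, 5.5, 0), (-1.5, 4.0, 1.0)])
        frame = ca_chain(ref.coords + rng.normal(scale=0.4, size=ref.coords.shape))
        cs = build_contacts(ref)
        assert q_nc(frame, cs) == pytest.approx(naive_q_nc(frame, ref), abs=1e-10)
        assert q_nc(frame, cs, "printed") == pytest.approx(
            naive_q_nc(frame, ref, normalization="printed"), abs=1e-10)

    def test_matches_oracle_twenty_residues(self, rng):
        ref = ca_chain(np.cumsum(rng.normal(scale=2.2, size=(20, 3)), axis=0))
        frame = ca_chain(ref.coords + rng.normal(scale=0.5, size=(20, 3)))
        cs = build_contacts(ref)
        assert q_nc(frame, cs) == pytest.approx(naive_q_nc(frame, ref), abs=1e-12)

    def test_missing_ca_error(self, small_refs):
        open_ref, _ = small_refs
        cs = build_contacts(open_ref)
        short = ca_chain(open_ref.coords[:5])
        with pytest.raises(ValueError, match="missing CA"):
            q_nc(short, cs)


class TestQSimilarity:
    def test_identity_is_one(self, small_refs):
        open_ref, _ = small_refs
        assert q_similarity(open_ref, open_ref) == 1.0

    def test_symmetry(self, small_refs):
        open_ref, closed_ref = small_refs
        assert q_similarity(open_ref, closed_ref) == pytest.approx(
            q_similarity(closed_ref, open_ref), abs=1e-12)

    def test_matches_oracle(self, rng):
        ref = ca_chain(np.cumsum(rng.normal(scale=2.0, size=(15, 3)), axis=0))
        frame = ca_chain(ref.coords + rng.normal(scale=0.6, size=(15, 3)))
        assert q_similarity(frame, ref) == pytest.approx(naive_q_similarity(frame, ref), abs=1e-12)
        assert q_similarity(frame, ref, "printed") == pytest.approx(
            naive_q_similarity(frame, ref, normalization="printed"), abs=1e-12)

    def test_printed_identity_is_half(self, small_refs):
        open_ref, _ = small_refs
        n = len(open_ref.ca_by_residue())
        n_pairs = (n - 1) * (n - 2) / 2
        assert q_similarity(open_ref, open_ref, "printed") == pytest.approx(
            n_pairs / ((n - 1) * (n - 2)))

    def test_open_frame_prefers_open_reference(self, small_refs):
        open_ref, closed_ref = small_refs
        assert q_similarity(open_ref, open_ref) > q_similarity(open_ref, closed_ref)

    def test_rigid_invariance(self, small_refs, rng):
        open_ref, closed_ref = small_refs
        base = q_similarity(open_ref, closed_ref)
        R, t = random_rigid(rng)
        moved = transform_structure(open_ref, R, t)
        assert q_similarity(moved, closed_ref) == pytest.approx(base, abs=1e-9)

    def test_monotone_under_uniform_scaling(self, small_refs):
        open_ref, _ = small_refs
        scores = [q_similarity(open_ref.with_coords(open_ref.coords * s), open_ref)
                  for s in (1.0, 1.05, 1.1, 1.3, 1.6)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestSimilaritySeries:
    def test_constant_trajectory_equal_to_closed(self, small_refs):
        open_ref, closed_ref = small_refs
        coords = np.repeat(closed_ref.coords[None], 4, axis=0)
        traj = Trajectory(closed_ref.atoms, coords, 20.0)
        ss = similarity_series(traj, open_ref, closed_ref)
        np.testing.assert_allclose(ss.q_closed, 1.0)
        assert np.all(ss.q_open < 1.0)
        assert np.ptp(ss.q_open) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_ops(self, small_cfg, small_refs):
        open_ref, closed_ref = small_refs
        (traj,), _ = generate_trajectory(small_cfg)
        ss = similarity_series(traj, open_ref, closed_ref, "q_similarity")
        qn = similarity_series(traj, open_ref, closed_ref, "Q_NC")
        cs_open = build_contacts(open_ref)
        for i in (0, traj.n_frames - 1):
            frame = traj.frame(i)
            assert ss.q_open[i] == pytest.approx(q_similarity(frame, open_ref), abs=1e-12)
            assert qn.q_open[i] == pytest.approx(q_nc(frame, cs_open), abs=1e-12)

    def test_unit_range_enforced(self):
        with pytest.raises(ValueError, match="length"):
            similarity.SimilaritySeries(np.zeros(3), np.zeros(4), "Q_NC", "unit_identity")
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            similarity.SimilaritySeries(np.array([1.5]), np.array([0.5]),
                                        "Q_NC", "unit_identity")


class TestDensityMap:
    def test_single_point(self):
        dm = density_map(np.array([0.7]), np.array([0.7]))
        assert (dm.counts > 0).sum() == 1
        assert dm.n_dropped == 0

    def test_out_of_range_dropped(self):
        x = np.full(9, 0.2)
        dm = density_map(x, x)
        assert dm.counts.sum() == 0
        assert dm.n_dropped == 9

    def test_count_conservation(self, rng):
        x = rng.uniform(0.3, 1.05, size=500)
        y = rng.uniform(0.3, 1.05, size=500)
        dm = density_map(x, y)
        assert dm.counts.sum() + dm.n_dropped == 500
        np.testing.assert_allclose(dm.log10_counts, np.log10(1 + dm.counts))

    def test_shape_and_range(self, rng):
        dm = density_map(rng.uniform(0.4, 1.0, 50), rng.uniform(0.4, 1.0, 50))
        assert dm.counts.shape == (100, 100)
        assert dm.x_edges[0] == 0.4 and dm.x_edges[-1] == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            density_map(np.zeros(3), np.zeros(4))
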