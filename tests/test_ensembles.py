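import numpy as np
import pytest

from ppiconserve import ensembles as ens
from ppiconserve.synthetic import _helix, _random_rotation


def rigid(coords, rng, scale=10.0):
    rot = _random_rotation(rng)
    return coords @ rot.T + rng.normal(scale=scale, size=3)


def make_ensemble(coords_stack, chain="A"):
    n = coords_stack.shape[1]
    return ens.Ensemble(
        chains=(chain,),
        residues=tuple((chain, i + 1) for i in range(n)),
        coords=coords_stack,
    )


class TestKabsch:
    def test_identical_coords(self):
        ref = _helix(10)
        sup = ens.kabsch_superpose(ref, ref)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_recovers_rigid_motion(self):
        ref = _helix(12)
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mov = ref @ rot90.T + np.array([5.0, -3.0, 2.0])
        sup = ens.kabsch_superpose(ref, mov)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(sup.apply(mov), ref, atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_beats_random_rotation_oracle(self, rng):
        for _ in range(10):
            ref = rng.normal(size=(10, 3)) * 5
            mov = rigid(ref + rng.normal(scale=0.5, size=(10, 3)), rng)
            sup = ens.kabsch_superpose(ref, mov)
            ref_c = ref - ref.mean(axis=0)
            mov_c = mov - mov.mean(axis=0)
            best_random = min(
                np.sqrt(((mov_c @ _random_rotation(rng).T - ref_c) ** 2)
                        .sum(axis=1).mean())
                for _ in range(1000)
            )
            assert sup.rmsd <= best_random + 1e-9

    def test_orthonormal_rotation(self, rng):
        ref = rng.normal(size=(8, 3))
        mov = rng.normal(size=(8, 3))
        sup = ens.kabsch_superpose(ref, mov)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ens.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            ens.kabsch_superpose(line, line)


class TestRmsf:
    def test_identical_conformations_zero(self, rng):
        base = _helix(20)
        stack = np.stack([rigid(base, rng) for _ in range(5)])
        assert ens.rmsf(make_ensemble(stack)).max() < 1e-6

    def test_single_displaced_residue(self, rng):
        base = _helix(30)
        stack = []
        for m in range(20):
            frame = base.copy()
            frame[15, 0] += 1.0 if m % 2 == 0 else -1.0
            stack.append(rigid(frame, rng))
        core = [i for i in range(30) if i != 15]
        values = ens.rmsf(make_ensemble(np.stack(stack)), fit_selection=core)
        assert values[15] == pytest.approx(1.0, rel=0.02)
        assert values[core].max() < 0.05

    def test_invariant_under_global_rigid_motion(self, rng):
        base = _helix(15)
        stack = np.stack([base + rng.normal(scale=0.3, size=base.shape)
                          for _ in range(8)])
        moved = np.stack([rigid(f, np.random.default_rng(7)) for f in stack])
        a = ens.rmsf(make_ensemble(stack))
        b = ens.rmsf(make_ensemble(moved))
        assert np.allclose(a, b, atol=1e-6)

    def test_requires_two_models(self):
        with pytest.raises(ValueError):
            ens.rmsf(make_ensemble(_helix(10)[None]))


def two_chain_ensemble(stack_a, stack_b):
    na, nb = stack_a.shape[1], stack_b.shape[1]
    residues = tuple([("A", i + 1) for i in range(na)]
                     + [("B", i + 1) for i in range(nb)])
    return ens.Ensemble(("A", "B"), residues,
                        np.concatenate([stack_a, stack_b], axis=1))


class TestContactFrequency:
    def test_distant_chains_all_zero(self):
        a = np.stack([_helix(5)] * 4)
        b = np.stack([_helix(5) + np.array([100.0, 0, 0])] * 4)
        cm = ens.contact_frequency(two_chain_ensemble(a, b), "A", "B")
        assert cm.freq.max() == 0.0

    def test_persistent_contact_is_one(self):
        a = np.stack([_helix(5)] * 4)
        b = a + np.array([3.0, 0.0, 0.0])
        cm = ens.contact_frequency(two_chain_ensemble(a, b), "A", "B", cutoff=8.0)
        assert cm.freq[0, 0] == 1.0

    def test_partial_occupancy_fraction(self):
        a = np.stack([_helix(5)] * 10)
        b = np.stack(
            [_helix(5) + np.array([4.0 if m < 3 else 50.0, 0.0, 0.0])
             for m in range(10)]
        )
        cm = ens.contact_frequency(two_chain_ensemble(a, b), "A", "B", cutoff=8.0)
        assert cm.freq[0, 0] == pytest.approx(0.3)

    def test_missing_chain_error(self):
        a = np.stack([_helix(5)] * 2)
        e = make_ensemble(a)
        with pytest.raises(KeyError):
            ens.contact_frequency(e, "A", "Z")


class TestTmScore:
    def test_d0_arithmetic(self):
        assert ens.tm_d0(21) == pytest.approx(1.24 * 6 ** (1 / 3) - 1.8, abs=1e-4)
        assert ens.tm_d0(21) == pytest.approx(0.4533, abs=1e-3)

    def test_identical_structures_score_one(self):
        ref = _helix(30)
        assert ens.tm_score(ref, ref) == pytest.approx(1.0, abs=1e-9)

    def test_all_residues_at_d0_scores_half(self):
        # paired coincident reference points displaced +/-d0: every
        # least-squares fit is the identity, so each term is 1/(1+1)
        n = 32
        d0 = ens.tm_d0(n)
        theta = 2 * np.pi * np.arange(n // 2) / (n // 2)
        locs = np.column_stack(
            [8 * np.cos(theta), 8 * np.sin(theta), np.zeros(n // 2)]
        )
        ref = np.repeat(locs, 2, axis=0)
        model = ref.copy()
        model[0::2, 2] = d0
        model[1::2, 2] = -d0
        assert ens.tm_score(model, ref) == pytest.approx(0.5, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        ref = _helix(40)
        model = ref + rng.normal(scale=1.0, size=ref.shape)
        moved = rigid(model, rng)
        assert ens.tm_score(model, ref) == pytest.approx(
            ens.tm_score(moved, ref), abs=1e-6
        )

    def test_score_bounded_and_decreasing_with_noise(self):
        ref = _helix(40)
        means = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            scores = [
                ens.tm_score(
                    ref + np.random.default_rng(100 + s).normal(
                        scale=sigma, size=ref.shape
                    ),
                    ref,
                )
                for s in range(10)
            ]
            assert max(scores) <= 1.0 + 1e-12
            means.append(np.mean(scores))
        assert means == sorted(means, reverse=True)

    def test_short_reference_rejected(self):
        ref = _helix(15)
        with pytest.raises(ValueError):
            ens.tm_score(ref, ref)

    def test_explicit_correspondence(self):
        ref = _helix(30)
        model = ref[5:]
        corr = np.column_stack([np.arange(25), np.arange(5, 30)])
        assert ens.tm_score(model, ref, corr) == pytest.approx(25 / 30, abs=1e-9)


class TestFoldConsistency:
    def test_reference_copies_score_one(self):
        ref = _helix(25)
        stack = np.stack([ref] * 4)
        assert ens.fold_consistency([make_ensemble(stack)], ref) == [1.0]

    def test_random_coordinates_lose_the_fold(self, rng):
        ref = _helix(25)
        stack = rng.normal(scale=10.0, size=(5, 25, 3))
        scores = [ens.tm_score(stack[m], ref) for m in range(5)]
        assert np.mean(scores) < 0.3
        assert ens.fold_consistency([make_ensemble(stack)], ref) == [0.0]

    def test_mixed_three_of_four(self, rng):
        ref = _helix(25)
        good = [ref + rng.normal(scale=0.1, size=ref.shape) for _ in range(3)]
        bad = [rng.normal(scale=10.0, size=ref.shape)]
        stack = np.stack(good + bad)
        assert ens.fold_consistency([make_ensemble(stack)], ref) == [0.75]
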