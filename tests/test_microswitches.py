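import numpy as np
import pytest

from gpcrswitch.geometry import DihedralSeries, DistanceSeries
from gpcrswitch.microswitches import (
    CB1_CHI1_REFERENCES,
    ModalityCall,
    ReferenceStateSet,
    RotamerBasins,
    activation_fingerprint,
    circular_mean,
    classify_modality,
    dominant_basin_angle,
    lock_analysis,
    nearest_reference_state,
    rotamer_distribution,
)
from gpcrswitch.synthetic_data import (
    LockSwitchConfig,
    simulate_lock_series,
    stationary_distribution,
)

CB1_REFS = ReferenceStateSet(states=CB1_CHI1_REFERENCES)


def series(angles):
    return DihedralSeries(residue_id=1, atom_names=("N", "CA", "CB", "CG"),
                          angles=np.asarray(angles, dtype=float))


def dseries(values):
    return DistanceSeries(endpoint_a=(1, "CZ"), endpoint_b=(2, "CG"),
                          values=np.asarray(values, dtype=float))


class TestRotamerBasins:
    def test_default_partition(self):
        b = RotamerBasins()
        assert b.names == ("gauche-", "trans", "gauche+")

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            RotamerBasins(intervals=(("a", 0.0, 100.0), ("b", 150.0, 360.0)))

    def test_wrapping_interval_allowed(self):
        b = RotamerBasins(intervals=(("low", 300.0, 60.0), ("high", 60.0, 300.0)))
        assert b.assign(np.array([350.0, 10.0, 100.0])).tolist() == [0, 0, 1]


class TestRotamerDistribution:
    def test_all_frames_gauche_plus(self):
        r = rotamer_distribution(series([300.0] * 10))
        assert r.occupancy["gauche+"] == 1.0

    def test_uniform_280_320_is_gauche_plus(self):
        rng = np.random.default_rng(1)
        r = rotamer_distribution(series(rng.uniform(280.0, 320.0, 500)))
        assert r.occupancy["gauche+"] == 1.0
        assert classify_modality(r).label == "unimodal"

    def test_von_mises_mixture_occupancy_recovered(self):
        # 70/30 mixture at 180deg/290deg, kappa=50: generator ground truth
        rng = np.random.default_rng(42)
        n = 5000
        which = rng.random(n) < 0.70
        angles = np.where(
            which,
            np.degrees(rng.vonmises(np.radians(180.0), 50.0, n)) % 360,
            np.degrees(rng.vonmises(np.radians(290.0), 50.0, n)) % 360,
        )
        r = rotamer_distribution(series(angles))
        assert r.occupancy["trans"] == pytest.approx(0.70, abs=0.02)
        assert r.occupancy["gauche+"] == pytest.approx(0.30, abs=0.02)

    def test_histogram_mass_equals_frames(self):
        r = rotamer_distribution(series([10.0, 200.0, 300.0]), bin_width=30.0)
        assert int(r.histogram.sum()) == 3

    def test_bad_bin_width(self):
        with pytest.raises(ValueError, match="divide"):
            rotamer_distribution(series([10.0]), bin_width=7.0)

    def test_occupancy_invariant_to_rotated_origin(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 360, 1000)
        shift = 73.0
        base = rotamer_distribution(series(angles))
        shifted_basins = RotamerBasins(
            intervals=(
                ("gauche-", shift, (120 + shift) % 360),
                ("trans", (120 + shift) % 360, (240 + shift) % 360),
                ("gauche+", (240 + shift) % 360, shift),
            )
        )
        rot = rotamer_distribution(series((angles + shift) % 360), shifted_basins)
        for name in base.occupancy:
            assert rot.occupancy[name] == pytest.approx(base.occupancy[name])


class TestClassifyModality:
    @pytest.mark.parametrize(
        "angles,expected",
        [
            ([150.0] * 95 + [50.0] * 5, "unimodal"),
            ([150.0] * 70 + [300.0] * 30, "bimodal"),
            ([50.0] * 20 + [150.0] * 30 + [300.0] * 50, "multimodal"),
        ],
    )
    def test_rule_forced_labels(self, angles, expected):
        r = rotamer_distribution(series(angles))
        assert classify_modality(r, min_occupancy=0.10).label == expected

    def test_monotone_in_min_occupancy(self):
        r = rotamer_distribution(series([50.0] * 20 + [150.0] * 30 + [300.0] * 50))
        counts = [
            len(classify_modality(r, m).occupied_basins)
            for m in (0.05, 0.25, 0.40, 0.60)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_basin_reaches_threshold_warns_indeterminate(self):
        r = rotamer_distribution(series([50.0, 150.0, 300.0]))
        with pytest.warns(UserWarning):
            call = classify_modality(r, min_occupancy=0.9)
        assert call.label == "indeterminate"


class TestNearestReference:
    def test_near_inactive(self):
        assert nearest_reference_state(185.0, CB1_REFS) == "inactive"

    def test_near_active(self):
        assert nearest_reference_state(275.0, CB1_REFS) == "active"

    def test_circular_wrap(self):
        refs = ReferenceStateSet(states=(("a", 350.0), ("b", 180.0)))
        assert nearest_reference_state(5.0, refs) == "a"

    def test_tie_lexicographic(self):
        refs = ReferenceStateSet(states=(("b", 90.0), ("a", 270.0)))
        assert nearest_reference_state(0.0, refs) == "a"

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ReferenceStateSet(states=(("a", 10.0), ("a", 20.0)))


class TestCircularMean:
    def test_wraps_correctly(self):
        assert circular_mean([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)

    def test_plain_mean_when_clustered(self):
        assert circular_mean([280.0, 300.0]) == pytest.approx(290.0)

    def test_dominant_basin_angle(self):
        r = rotamer_distribution(series([180.0] * 30 + [280.0, 300.0] * 35))
        assert dominant_basin_angle(r) == pytest.approx(290.0)


class TestLockAnalysis:
    def test_all_formed(self):
        lock = lock_analysis(dseries([4.0] * 8), threshold_formed=4.7)
        assert lock.formed_fraction == 1.0

    def test_all_broken(self):
        lock = lock_analysis(dseries([9.0, 9.5, 10.0]), threshold_formed=4.7)
        assert lock.formed_fraction == 0.0

    def test_threshold_inclusive(self):
        lock = lock_analysis(dseries([4.7]), threshold_formed=4.7)
        assert lock.formed_fraction == 1.0

    def test_bad_threshold(self):
        with pytest.raises(ValueError, match="positive"):
            lock_analysis(dseries([4.0]), threshold_formed=0.0)

    def test_markov_stationary_recovered(self):
        # two-state generator with stationary formed probability 0.6
        t = ((0.8, 0.2), (0.3, 0.7))
        pi = stationary_distribution(np.array(t))
        assert pi[0] == pytest.approx(0.6)
        cfg = LockSwitchConfig(
            mean_formed=4.5, mean_broken=9.5, noise_sd=0.3,
            transition=t, n_frames=10_000, seed=123,
        )
        values, _ = simulate_lock_series(cfg)
        lock = lock_analysis(dseries(values), threshold_formed=7.0)
        assert lock.formed_fraction == pytest.approx(0.60, abs=0.03)


class TestFingerprint:
    def _lock(self, fraction):
        n = 20
        k = int(round(fraction * n))
        return lock_analysis(dseries([4.0] * k + [9.0] * (n - k)), 4.7)

    def _modality(self, label):
        return ModalityCall(label=label, occupied_basins=("trans",), min_occupancy=0.1)

    def test_bimodal_broken_lock_is_agonist_like(self):
        fp = activation_fingerprint(self._modality("bimodal"), "inactive", self._lock(0.1))
        assert fp.overall == "agonist-like"

    def test_unimodal_inactive_formed_lock_is_antagonist_like(self):
        fp = activation_fingerprint(self._modality("unimodal"), "inactive", self._lock(0.95))
        assert fp.overall == "antagonist-like"

    def test_unimodal_active_formed_lock_is_tie(self):
        fp = activation_fingerprint(self._modality("unimodal"), "active", self._lock(0.9))
        assert fp.overall == "indeterminate"

    def test_call_reproducible_from_votes(self):
        fp = activation_fingerprint(self._modality("bimodal"), None, self._lock(0.2))
        n_ago = sum(1 for v in fp.votes.values() if v == "agonist-like")
        n_ant = sum(1 for v in fp.votes.values() if v == "antagonist-like")
        expected = (
            "agonist-like" if n_ago > n_ant
            else "antagonist-like" if n_ant > n_ago else "indeterminate"
        )
        assert fp.overall == expected

    def test_thresholds_echoed(self):
        fp = activation_fingerprint(self._modality("unimodal"), None, self._lock(1.0))
        assert set(fp.thresholds) == {
            "min_occupancy", "lock_threshold_formed", "lock_agonist_below",
        }
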