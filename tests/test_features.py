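import math

import numpy as np
import pytest

from conftest import make_fragment
from oracles import brute_background, brute_pwm
from metalbind.features import (
    PWMSet,
    TRACKS,
    TRACK_CLASSES,
    background_probs,
    composition_features,
    conservation_features,
    encode,
    encode_fragments,
    entropy_features,
    feature_dim,
    feature_names,
    fit_pwm,
)


class TestComposition:
    def test_homopolymer_concentrates_on_one_class(self):
        v = composition_features(make_fragment("AAAAAAAAA"))
        aa = v[:21]
        assert aa[TRACK_CLASSES["aa"].index("A")] == 1.0
        assert aa.sum() == 1.0 and np.count_nonzero(aa) == 1

    def test_terminal_fragment_counts_pads_as_x(self):
        v = composition_features(make_fragment("XXXXMKVAA"))
        assert v[TRACK_CLASSES["aa"].index("X")] == pytest.approx(4 / 9)
        ss = v[21:25]
        assert ss[TRACK_CLASSES["ss"].index("PAD")] == pytest.approx(4 / 9)

    def test_subblocks_sum_to_one(self, worked_fragments):
        bounds = np.cumsum([0] + [len(TRACK_CLASSES[t]) for t in TRACKS])
        for frag in worked_fragments[::17]:
            v = composition_features(frag)
            for lo, hi in zip(bounds, bounds[1:]):
                assert v[lo:hi].sum() == pytest.approx(1.0)
            assert v.sum() == pytest.approx(len(TRACKS))


class TestPWM:
    def test_pseudocount_probability_hand_value(self):
        # 100 single-site fragments, 5 of class 'A': p = (5 + 10/21) / 110
        frags = [make_fragment("A") for _ in range(5)] + \
                [make_fragment("G") for _ in range(95)]
        pwm = fit_pwm(frags, "aa")
        j = TRACK_CLASSES["aa"].index("A")
        assert pwm.p[0, j] == pytest.approx((5 + 10 / 21) / 110)
        assert pwm.p[0, j] == pytest.approx(0.0497835, abs=1e-6)

    def test_rows_sum_to_one_exactly(self, worked_pwms):
        for table in (worked_pwms.positive, worked_pwms.negative):
            for pwm in table.values():
                assert np.allclose(pwm.p.sum(axis=1), 1.0, atol=1e-12)
                assert abs(pwm.p0.sum() - 1.0) < 1e-12

    def test_matches_brute_force_oracle_on_random_sets(self, worked_fragments):
        rng = np.random.default_rng(42)
        for _ in range(5):
            idx = rng.choice(len(worked_fragments), size=10, replace=False)
            sample = [worked_fragments[i] for i in idx]
            for track in TRACKS:
                pwm = fit_pwm(sample, track)
                p, m = brute_pwm(sample, track)
                assert np.allclose(pwm.p, p, atol=1e-14)
                assert np.allclose(pwm.m, m, atol=1e-14)
                # empirical background variant
                p0 = background_probs(sample, track)
                assert np.allclose(p0, brute_background(sample, track), atol=1e-14)
                pwm_e = fit_pwm(sample, track, p0=p0)
                _, m_e = brute_pwm(sample, track, p0=list(p0))
                assert np.allclose(pwm_e.m, m_e, atol=1e-13)

    def test_zero_log_odds_when_p_equals_background(self):
        frags = [make_fragment("AAAAAAAAA")]
        probe = fit_pwm(frags, "aa")
        refit = fit_pwm(frags, "aa", p0=probe.p[0])
        assert np.allclose(refit.m[0], 0.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_pwm([], "aa")


class TestConservation:
    def test_single_training_fragment_closed_form(self):
        """With one positive fragment, its own aa scores are ln(11) everywhere.

        N = 1 and n = 1 at the observed symbol give p = (1 + 1/21)/2 = 11/21;
        against the uniform background 1/21 the log-odds is ln(11).
        """
        pos = make_fragment("ACDEFGHIK", label=True)
        neg = make_fragment("LMNPQRSTV", label=False)
        pwms = PWMSet(
            positive={t: fit_pwm([pos], t, "positive") for t in TRACKS},
            negative={t: fit_pwm([neg], t, "negative") for t in TRACKS},
            L=9, background="uniform")
        v = conservation_features(pos, pwms)
        assert np.allclose(v[:9], math.log(11.0))

    def test_dimension_is_2_l_5(self, worked_fragments, worked_pwms):
        v = conservation_features(worked_fragments[0], worked_pwms)
        assert v.shape == (2 * 9 * 5,)

    def test_swapping_training_classes_swaps_score_halves(self, worked_fragments, worked_pwms):
        swapped = PWMSet(positive=worked_pwms.negative, negative=worked_pwms.positive,
                         L=worked_pwms.L, background=worked_pwms.background)
        for frag in worked_fragments[::31]:
            a = conservation_features(frag, worked_pwms).reshape(5, 2, 9)
            b = conservation_features(frag, swapped).reshape(5, 2, 9)
            assert np.array_equal(a[:, 0], b[:, 1])
            assert np.array_equal(a[:, 1], b[:, 0])

    def test_window_mismatch_rejected(self, worked_pwms):
        with pytest.raises(ValueError):
            conservation_features(make_fragment("ACD"), worked_pwms)


class TestEntropy:
    @pytest.mark.parametrize("residues,charge_h", [
        ("KKKDDDGGG", math.log2(3)),                       # uniform over 3 classes
        ("KKKKKDDDD", -(5 / 9) * math.log2(5 / 9) - (4 / 9) * math.log2(4 / 9)),
        ("LLLLLLLLL", 0.0),                                # single class
    ])
    def test_charge_entropy_hand_values(self, residues, charge_h):
        assert entropy_features(make_fragment(residues))[1] == pytest.approx(charge_h)

    def test_hydropathy_entropy_of_single_class_is_zero(self):
        assert entropy_features(make_fragment("LIVAMFLIV"))[0] == 0.0

    def test_pads_are_excluded_from_the_distribution(self):
        # real residues K,D,G -> uniform over 3 charge classes despite 6 pads
        v = entropy_features(make_fragment("XXXKDGXXX"))
        assert v[1] == pytest.approx(math.log2(3))

    def test_bounds(self, worked_fragments):
        for frag in worked_fragments[::13]:
            h_hydro, h_charge = entropy_features(frag)
            assert 0.0 <= h_hydro <= math.log2(6)
            assert 0.0 <= h_charge <= math.log2(3)


class TestEncode:
    def test_total_dimension(self, worked_fragments, worked_pwms):
        v = encode(worked_fragments[0], worked_pwms)
        assert v.shape == (129,)
        assert feature_dim(9) == 129
        assert len(feature_names(9)) == 129
        assert len(set(feature_names(9))) == 129

    def test_layout_blocks(self, worked_fragments, worked_pwms):
        frag = worked_fragments[5]
        v = encode(frag, worked_pwms)
        assert np.array_equal(v[:37], composition_features(frag))
        assert np.array_equal(v[37:127], conservation_features(frag, worked_pwms))
        assert np.array_equal(v[127:], entropy_features(frag))

    def test_identical_fragments_encode_identically(self, worked_fragments, worked_pwms):
        a = encode(worked_fragments[3], worked_pwms)
        b = encode(worked_fragments[3], worked_pwms)
        assert np.array_equal(a, b)

    def test_encode_fragments_matrix(self, worked_fragments, worked_pwms):
        X, y = encode_fragments(worked_fragments[:20], worked_pwms)
        assert X.shape == (20, 129)
        assert set(np.unique(y)) <= {0, 1}
        X0, y0 = encode_fragments([], worked_pwms)
        assert X0.shape == (0, 129) and y0.shape == (0,)
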