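import numpy as np
import pytest

from sapnet import (
    CalibrationConfig,
    CalibrationModel,
    FormatError,
    InterfaceMap,
    InterfaceRecord,
    PpiNetwork,
    ScoreVector,
    TNormalizer,
    calibrate,
    component_weight,
    score_sap,
    tail_probability,
    was,
)
from conftest import make_sap


def brute_tail(sample, x):
    return sum(1 for v in sample if v > x) / len(sample)


class TestTailProbability:
    def test_counting_examples(self):
        assert tail_probability([0.1, 0.5, 0.9], 0.5) == pytest.approx(1 / 3)
        assert tail_probability([0.1, 0.5, 0.9], 1.0) == 0.0
        assert tail_probability([0.1, 0.5, 0.9], 0.0) == 1.0

    def test_ties_use_strict_inequality(self):
        assert tail_probability([0.5, 0.5], 0.5) == 0.0

    def test_empty_sample_is_error(self):
        with pytest.raises(FormatError):
            tail_probability([], 0.5)

    def test_matches_brute_force_on_tie_heavy_samples(self, rng):
        for _ in range(30):
            sample = np.sort(rng.choice([0.0, 0.25, 0.5, 0.5, 1.0],
                                        size=rng.integers(1, 200)))
            for x in rng.uniform(-0.1, 1.1, size=10):
                assert tail_probability(sample, x) == pytest.approx(
                    brute_tail(sample, x), abs=1e-12)


def model_from_samples(neutral, deleterious, cutoffs=None,
                       components=("S", "T", "I")):
    return CalibrationModel(
        samples={c: {"neutral": np.sort(np.asarray(neutral, float)),
                     "deleterious": np.sort(np.asarray(deleterious, float))}
                 for c in components},
        cutoffs=cutoffs or {"S": 0.95, "T": 0.9, "I": 0.5},
        t_normalizer=None,
    )


class TestComponentWeight:
    def test_absent_score_weighs_zero(self):
        model = model_from_samples([0.1], [0.9])
        assert component_weight(None, "S", model) == 0.0

    def test_deleterious_call_against_low_neutral_sample(self):
        model = model_from_samples(neutral=[0.1, 0.3, 0.5],
                                   deleterious=[0.8, 0.9],
                                   cutoffs={"S": 0.9, "T": 0.9, "I": 0.5})
        assert component_weight(0.99, "S", model) == 1.0

    def test_neutral_call_against_high_deleterious_sample(self):
        model = model_from_samples(neutral=[0.1], deleterious=[0.8, 0.9, 1.0],
                                   cutoffs={"S": 0.9, "T": 0.9, "I": 0.5})
        assert component_weight(0.2, "S", model) == 0.0

    def test_oracle_equivalence_on_random_samples(self, rng):
        """Weight must equal 1 - brute-force strict-count tail probability of
        the class opposite the component-level call."""
        for _ in range(20):
            neutral = rng.choice(np.round(rng.uniform(0, 1, 40), 2), 200)
            deleterious = rng.choice(np.round(rng.uniform(0, 1, 40), 2), 200)
            model = model_from_samples(neutral, deleterious)
            theta = model.cutoffs["S"]
            for x in rng.uniform(0, 1, size=25):
                expected = (1 - brute_tail(neutral, x) if x >= theta
                            else 1 - brute_tail(deleterious, x))
                got = component_weight(float(x), "S", model)
                assert got == pytest.approx(expected, abs=1e-12)


class TestWas:
    def test_weighted_average(self):
        score, flag = was({"S": (0.8, 0.5), "T": (0.6, 0.5)})
        assert score == pytest.approx(0.7) and not flag

    def test_single_component_identity(self):
        score, flag = was({"T": (0.93, 0.4)})
        assert score == pytest.approx(0.93) and not flag

    def test_unanimity(self):
        score, _ = was({"S": (1.0, 1.0), "T": (1.0, 1.0), "I": (1.0, 1.0)})
        assert score == 1.0

    def test_all_zero_weights_flag_unscorable(self):
        score, flag = was({"S": (0.8, 0.0), "T": (0.6, 0.0)})
        assert score == 0.0 and flag

    def test_bounding_and_permutation_invariance(self, rng):
        for _ in range(200):
            k = rng.integers(1, 4)
            comps = {c: (rng.uniform(), rng.uniform(0.01, 1))
                     for c in ("S", "T", "I")[: k]}
            score, flag = was(comps)
            values = [s for s, _ in comps.values()]
            assert min(values) - 1e-12 <= score <= max(values) + 1e-12
            shuffled = dict(reversed(list(comps.items())))
            assert was(shuffled)[0] == pytest.approx(score)


def scored_vector(label, s=None, t=None, i=None):
    sv = ScoreVector(sap=make_sap("P", 1, "G", "D", label=label))
    sv.s_score, sv.t_norm, sv.i_score = s, t, i
    return sv


class TestCalibrate:
    def toy_training(self):
        rows = []
        for s, t, i in [(0.99, 0.95, 1), (0.9, 0.8, 1), (0.85, 0.9, 0),
                        (0.97, 0.7, 1), (0.8, 0.85, 0)]:
            rows.append(scored_vector("deleterious", s, t, i))
        for s, t, i in [(0.1, 0.2, 0), (0.3, 0.1, 0), (0.2, 0.4, 0),
                        (0.4, 0.3, 1), (0.15, 0.25, 0)]:
            rows.append(scored_vector("neutral", s, t, i))
        return rows

    def test_tail_probabilities_match_hand_counts(self):
        model = calibrate(self.toy_training())
        neutral_s = model.samples["S"]["neutral"]
        # S neutral sample is {0.1, 0.15, 0.2, 0.3, 0.4}
        for probe, expected in [(0.05, 1.0), (0.15, 3 / 5), (0.25, 2 / 5),
                                (0.35, 1 / 5), (0.5, 0.0)]:
            assert tail_probability(neutral_s, probe) == pytest.approx(expected)

    def test_single_class_is_error(self):
        rows = [scored_vector("deleterious", 0.9, 0.9, 1)]
        with pytest.raises(FormatError):
            calibrate(rows)

    def test_row_order_invariance(self, rng):
        rows = self.toy_training()
        m1 = calibrate(rows)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        m2 = calibrate(shuffled)
        for c in ("S", "T", "I"):
            for lbl in ("neutral", "deleterious"):
                assert np.array_equal(m1.samples[c][lbl], m2.samples[c][lbl])
        assert m1.cutoffs == m2.cutoffs

    def test_youden_theta_t_separates_bimodal_modes(self, rng):
        rows = [scored_vector("deleterious", t=float(t))
                for t in rng.uniform(0.7, 1.0, 30)]
        rows += [scored_vector("neutral", t=float(t))
                 for t in rng.uniform(0.0, 0.3, 30)]
        model = calibrate(rows, config=CalibrationConfig(youden_t_cutoff=True))
        del_scores = [sv.t_norm for sv in rows if sv.sap.label == "deleterious"]
        neu_scores = [sv.t_norm for sv in rows if sv.sap.label == "neutral"]
        # perfect separation: the chosen cutoff attains J = 1 and, under the
        # ties-to-higher rule, equals the smallest deleterious score
        assert max(neu_scores) < model.cutoffs["T"] <= min(del_scores)
        assert model.cutoffs["T"] == pytest.approx(min(del_scores))

    def test_explicit_theta_override_is_stored(self):
        config = CalibrationConfig(cutoffs={"S": 0.95, "T": 0.9, "I": 0.5})
        model = calibrate(self.toy_training(), config=config)
        assert model.cutoffs["T"] == 0.9

    def test_json_round_trip(self, tmp_path):
        model = calibrate(self.toy_training(),
                          t_normalizer=TNormalizer(0.9, 1.2))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CalibrationModel.from_json(path)
        assert loaded.cutoffs == model.cutoffs
        assert loaded.meta_cutoff == model.meta_cutoff
        assert loaded.t_normalizer == model.t_normalizer
        for c in ("S", "T", "I"):
            for lbl in ("neutral", "deleterious"):
                assert np.array_equal(loaded.samples[c][lbl],
                                      model.samples[c][lbl])


class TestScoreSap:
    def fixture_model(self):
        model = model_from_samples(
            neutral=[0.0, 0.1, 0.2, 0.3], deleterious=[0.7, 0.8, 0.9, 1.0])
        model.t_normalizer = TNormalizer(0.5, 1.5)
        return model

    def test_off_network_off_interface_no_sift(self):
        """A SAP with no evidence beyond topology fallbacks: T-raw is the
        off-network value 1, I is 0, S is absent; meta uses T and I only."""
        model = self.fixture_model()
        net = PpiNetwork([("A", "B")], cancer_nodes={"B"})
        imap = InterfaceMap([])
        sv = score_sap(make_sap("GHOST", 5), net, imap, None, model)
        assert sv.t_raw == 1.0
        assert sv.t_norm == pytest.approx(0.5)
        assert sv.i_score == 0 and sv.s_score is None
        assert sv.w_s == 0.0
        present = sv.present_scores()
        assert set(present) == {"T", "I"}
        assert min(present.values()) <= sv.meta_score <= max(present.values())

    def test_all_components_at_maximum(self):
        model = self.fixture_model()
        net = PpiNetwork([("P", "B")], cancer_nodes={"B"})
        imap = InterfaceMap([InterfaceRecord("P", "B", "P", ((1, 50),))])
        sap = make_sap("P", 5, "G", "D", sift_score=0.0)
        # force T to the top of the normalization range
        model.t_normalizer = TNormalizer(0.0, 1.0)
        sv = score_sap(sap, net, imap, None, model)
        assert sv.s_score == 1.0 and sv.i_score == 1 and sv.t_norm == 1.0
        assert sv.meta_score == pytest.approx(1.0)
        assert sv.predicted_class == "deleterious"
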