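"""Product utilities and share-of-preference simulation."""

import itertools

import numpy as np
import pytest

import opendce as od


@pytest.fixture(scope="module")
def india_cm():
    spec, _, _ = od.study_preset("india")
    return od.CodedMatrix.from_spec(spec)


IDEAL = {"size": "small", "duration": "6 months", "pain": "no pain",
         "rash": "one-day rash", "location": "foot", "menstruation": "irregular"}
REFERENCE = {"size": "medium", "duration": "3 months", "pain": "light prick",
             "rash": "three-day rash", "location": "wrist",
             "menstruation": "irregular"}


class TestProductUtility:
    def test_published_duration_contrast(self, india_cm):
        """Two profiles differing only in duration (6 vs 1 month) differ by
        29.7 - (-30.3) = 60.0 under the published India means (menstruation
        held at the reference level so no interaction contribution)."""
        spec, truth, _ = od.study_preset("india", scale=1.0)
        beta = truth.theta[0]
        base = dict(IDEAL, menstruation="amenorrhea")
        six = od.ProductProfile("six", dict(base, duration="6 months"))
        one = od.ProductProfile("one", dict(base, duration="1 month"))
        diff = (od.product_utility(beta, six, india_cm)
                - od.product_utility(beta, one, india_cm))
        # remove the interaction contribution of the two cells involved
        from opendce.coding import expand_utilities
        grid = expand_utilities(beta, india_cm)
        inter = grid[grid["attribute"] == "duration x menstruation"].set_index("level")
        diff -= (inter.loc["6 months x amenorrhea", "utility"]
                 - inter.loc["1 month x amenorrhea", "utility"])
        # published rows are rounded to 0.1 and do not sum exactly to zero,
        # so the expanded reference level can differ by one rounding unit
        assert diff == pytest.approx(60.0, abs=0.2)

    def test_interaction_term_enters_profile_utility(self, india_cm):
        """The 1-month x amenorrhea combination adds the published +34.0."""
        spec, truth, _ = od.study_preset("india", scale=1.0)
        beta_main_only = truth.theta[0].copy()
        sl = india_cm.interaction_slices[("duration", "menstruation")]
        beta_main_only[sl] = 0.0
        prof = od.ProductProfile("p", dict(IDEAL, duration="1 month",
                                           menstruation="amenorrhea"))
        with_inter = od.product_utility(truth.theta[0], prof, india_cm)
        without = od.product_utility(beta_main_only, prof, india_cm)
        assert with_inter - without == pytest.approx(34.0, abs=1e-9)

    def test_unknown_level_rejected(self, india_cm):
        prof = od.ProductProfile("bad", dict(IDEAL, size="enormous"))
        with pytest.raises(ValueError, match="unknown level"):
            od.product_utility(np.zeros(india_cm.n_params), prof, india_cm)

    def test_missing_attribute_rejected(self, india_cm):
        levels = {k: v for k, v in IDEAL.items() if k != "size"}
        with pytest.raises(ValueError, match="missing level"):
            od.ProductProfile("bad", levels).validate(india_cm.spec)


class TestShares:
    def test_identical_profiles_split_under_both_rules(self, india_cm):
        rng = np.random.default_rng(0)
        beta = rng.standard_normal((7, india_cm.n_params))
        p1 = od.ProductProfile("p1", IDEAL)
        p2 = od.ProductProfile("p2", dict(IDEAL))
        for rule in ("first-choice", "logit"):
            res = od.share_of_preference(beta, [p1, p2], india_cm, rule=rule)
            np.testing.assert_allclose(res.shares, [0.5, 0.5], atol=1e-12)

    def test_dominated_profile_gets_zero_first_choice(self, india_cm):
        spec, truth, _ = od.study_preset("india")
        _, beta = od.generate_population(truth, 50, seed=1)
        good = od.ProductProfile("good", dict(REFERENCE, menstruation="regular",
                                              pain="no pain"))
        # dominated: worse or equal on every attribute for any beta is hard to
        # construct in general; use a clone with strictly worse utility by
        # subtracting a constant via an always-worse level set chosen per the
        # population's uniform preference direction instead: verify dominance
        # numerically before asserting.
        bad = od.ProductProfile("bad", REFERENCE)
        u_good = od.product_utility(beta, good, india_cm)
        u_bad = od.product_utility(beta, bad, india_cm)
        if (u_good > u_bad).all():
            res = od.share_of_preference(beta, [good, bad], india_cm)
            assert res.share("bad") == 0.0

    def test_single_respondent_logit_closed_form(self, india_cm):
        """Utility gap of ln 2 gives shares (2/3, 1/3) under the logit rule."""
        spec = od.StudySpec(attributes=(od.AttributeSpec("a", ("hi", "lo")),))
        cm = od.CodedMatrix.from_spec(spec)
        beta = np.array([np.log(2.0) / 2.0])  # u(hi)=ln2/2, u(lo)=-ln2/2
        res = od.share_of_preference(
            beta, [od.ProductProfile("hi", {"a": "hi"}),
                   od.ProductProfile("lo", {"a": "lo"})], cm, rule="logit")
        np.testing.assert_allclose(res.shares, [2 / 3, 1 / 3], atol=1e-12)

    def test_matches_brute_force_enumeration(self, india_cm):
        """First-choice and logit shares equal explicit per-respondent
        enumeration on small instances."""
        rng = np.random.default_rng(3)
        profiles = [
            od.ProductProfile("p1", IDEAL),
            od.ProductProfile("p2", REFERENCE),
            od.ProductProfile("p3", dict(IDEAL, size="large")),
        ]
        for n in (1, 2, 4):
            beta = rng.standard_normal((n, india_cm.n_params))
            U = np.array([[od.product_utility(b, p, india_cm) for p in profiles]
                          for b in beta])
            fc = np.zeros(3)
            for row in U:
                winners = np.nonzero(row == row.max())[0]
                fc[winners] += 1.0 / (len(winners) * n)
            lg = np.mean(np.exp(U) / np.exp(U).sum(axis=1, keepdims=True), axis=0)
            res_fc = od.share_of_preference(beta, profiles, india_cm)
            res_lg = od.share_of_preference(beta, profiles, india_cm, rule="logit")
            np.testing.assert_allclose(res_fc.shares, fc, atol=1e-9)
            np.testing.assert_allclose(res_lg.shares, lg, atol=1e-9)
            assert res_fc.shares.sum() == pytest.approx(1.0)

    def test_permuting_profiles_permutes_shares(self, india_cm):
        rng = np.random.default_rng(5)
        beta = rng.standard_normal((6, india_cm.n_params))
        profiles = [od.ProductProfile("p1", IDEAL),
                    od.ProductProfile("p2", REFERENCE),
                    od.ProductProfile("p3", dict(IDEAL, pain="hard prick"))]
        base = od.share_of_preference(beta, profiles, india_cm)
        perm = od.share_of_preference(beta, profiles[::-1], india_cm)
        np.testing.assert_allclose(base.shares, perm.shares[::-1])

    def test_clone_splits_share_merger_consistency(self, india_cm):
        rng = np.random.default_rng(6)
        beta = rng.standard_normal((4, india_cm.n_params))
        p1 = od.ProductProfile("p1", IDEAL)
        p2 = od.ProductProfile("p2", REFERENCE)
        clone = od.ProductProfile("clone", dict(IDEAL))
        two = od.share_of_preference(beta, [p1, p2], india_cm)
        three = od.share_of_preference(beta, [p1, p2, clone], india_cm)
        np.testing.assert_allclose(three.share("p1") + three.share("clone"),
                                   two.share("p1"), atol=1e-9)
        np.testing.assert_allclose(three.share("p2"), two.share("p2"), atol=1e-9)

    def test_empty_or_singleton_profile_list_rejected(self, india_cm):
        with pytest.raises(ValueError):
            od.share_of_preference(np.zeros((2, india_cm.n_params)), [], india_cm)


class TestPreferenceGain:
    def test_gain_arithmetic(self, india_cm):
        res = od.SimulationResult(profiles=["t", "r"],
                                  shares=np.array([0.6, 0.4]),
                                  rule="first-choice")
        assert od.preference_gain(res, "t", "r") == pytest.approx(50.0)
        res_eq = od.SimulationResult(profiles=["t", "r"],
                                     shares=np.array([0.5, 0.5]),
                                     rule="first-choice")
        assert od.preference_gain(res_eq, "t", "r") == pytest.approx(0.0)

    def test_zero_reference_share_rejected(self):
        res = od.SimulationResult(profiles=["t", "r"],
                                  shares=np.array([1.0, 0.0]),
                                  rule="first-choice")
        with pytest.raises(ZeroDivisionError):
            od.preference_gain(res, "t", "r")
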