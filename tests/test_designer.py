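import numpy as np
import pytest

from dsrnakit.designer import (
    DEFAULT_WEIGHTS,
    ScoreProfile,
    build_insertion_construct,
    combined_scores,
    efficacy_scores,
    normalize_features,
    select_window,
)
from dsrnakit.fixtures import gen_transcriptome
from dsrnakit.seqio import Interval, Transcript
from dsrnakit.sirna_features import FeatureVector

from conftest import random_dna


def fv(asym=0.0, fold=0.0, acc=0.5, gc_full=50.0, gc914=50.0, a10=False, be=-20.0):
    return FeatureVector(
        thermo_asymmetry=asym,
        self_fold_mfe=fold,
        accessibility=acc,
        gc_full=gc_full,
        gc_9_14=gc914,
        a10=a10,
        region="UTR",
        binding_energy=be,
    )


def profile_from_scores(scores, k=21):
    scores = np.asarray(scores, dtype=float)
    return ScoreProfile(
        positions=list(range(len(scores))),
        k=k,
        normalized={},
        efficacy=scores,
    )


class TestEfficacyScores:
    def test_upper_bound(self, stack_table):
        hi_asym = 3 * stack_table.max_stack - 3 * stack_table.min_stack
        feats = [
            fv(asym=hi_asym, fold=0.0, gc914=100.0, a10=True),
            fv(asym=0.0, fold=-5.0, gc914=0.0, a10=False),
        ]
        scores = efficacy_scores(feats)
        assert scores[0] == pytest.approx(100.0)

    def test_lower_bound(self, stack_table):
        lo_asym = 3 * stack_table.min_stack - 3 * stack_table.max_stack
        feats = [
            fv(asym=lo_asym, fold=-5.0, gc914=0.0, a10=False),
            fv(asym=0.0, fold=0.0, gc914=50.0, a10=True),
        ]
        assert efficacy_scores(feats)[0] == pytest.approx(0.0)

    def test_degenerate_weights_equal_normalized_asymmetry(self):
        feats = [fv(asym=a) for a in (-3.0, 0.0, 2.0, 5.0)]
        scores = efficacy_scores(feats, weights={"thermo_asymmetry": 1.0})
        norm = normalize_features(feats)["thermo_asymmetry"]
        assert np.allclose(scores, norm)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            efficacy_scores([fv()], weights={"thermo_asymmetry": 0.0})

    def test_negative_weight_error(self):
        with pytest.raises(ValueError):
            efficacy_scores([fv()], weights={"thermo_asymmetry": -1.0})

    def test_bounded(self, rng):
        feats = [
            fv(
                asym=float(rng.uniform(-15, 15)),
                fold=float(rng.uniform(-20, 0)),
                gc914=float(rng.uniform(0, 100)),
                a10=bool(rng.random() < 0.5),
            )
            for _ in range(50)
        ]
        scores = efficacy_scores(feats)
        assert ((0 <= scores) & (scores <= 100)).all()

    def test_default_weights_are_the_four_significant_features(self):
        assert set(DEFAULT_WEIGHTS) == {"thermo_asymmetry", "self_fold", "gc_9_14", "a10"}

    def test_all_equal_feature_normalizes_to_100(self):
        feats = [fv(fold=-3.0), fv(fold=-3.0)]
        norm = normalize_features(feats)
        assert np.allclose(norm["self_fold"], 100.0)


class TestCombinedScores:
    def test_average_at_50(self):
        assert combined_scores([80.0], [40.0], 50.0)[0] == pytest.approx(60.0)

    def test_4_to_1_at_80(self):
        assert combined_scores([80.0], [40.0], 80.0)[0] == pytest.approx(72.0)

    def test_priority_100_is_efficacy(self, rng):
        E = rng.uniform(0, 100, 10)
        S = rng.uniform(0, 100, 10)
        assert np.allclose(combined_scores(E, S, 100.0), E)

    def test_monotone_in_priority_when_E_above_S(self, rng):
        E = rng.uniform(50, 100, 5)
        S = E - rng.uniform(1, 40, 5)
        prev = combined_scores(E, S, 0.0)
        for p in range(10, 101, 10):
            cur = combined_scores(E, S, float(p))
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            combined_scores([1.0, 2.0], [1.0])


class TestSelectWindow:
    @staticmethod
    def exhaustive(profile, transcript, W, restrict_to_orf=False, objective="max"):
        """Independent sliding-window oracle (mask per start)."""
        allowed = (
            transcript.orf
            if restrict_to_orf and transcript.orf is not None
            else Interval(0, len(transcript.seq))
        )
        k = profile.k
        width = min(W, len(allowed))
        pos = np.asarray(profile.positions)
        scores = np.asarray(profile.window_scores, dtype=float)
        best = None
        for start in range(allowed.start, allowed.end - width + 1):
            inside = (pos >= start) & (pos + k <= start + width)
            if not inside.any():
                continue
            mean = float(scores[inside].mean())
            if best is None or mean > best[0] + 1e-12:
                best = (mean, start)
        return best

    def test_uniform_scores_leftmost(self, rng):
        t = Transcript(id="t", seq=random_dna(rng, 500))
        profile = profile_from_scores(np.full(480, 55.0))
        res = select_window(profile, t, W=100)
        assert res.window.start == 0
        assert res.mean_score == pytest.approx(55.0)

    def test_planted_high_block(self, rng):
        L, W = 2000, 300
        scores = np.full(L - 20, 10.0)
        block = 700
        scores[block : block + W - 20] = 90.0
        t = Transcript(id="t", seq=random_dna(rng, L))
        profile = profile_from_scores(scores)
        res = select_window(profile, t, W=W)
        oracle = self.exhaustive(profile, t, W)
        assert res.window.start == oracle[1]
        assert res.mean_score == pytest.approx(oracle[0])
        assert res.window.start == block

    @pytest.mark.parametrize("W", [100, 300])
    def test_matches_exhaustive_on_random_profiles(self, W, rng):
        for _ in range(100):
            L = int(rng.integers(400, 3000))
            t = Transcript(id="t", seq="A" * L)
            profile = profile_from_scores(rng.uniform(0, 100, L - 20))
            res = select_window(profile, t, W=W)
            oracle = self.exhaustive(profile, t, W)
            assert res.mean_score == pytest.approx(oracle[0], abs=1e-9)

    def test_min_objective(self, rng):
        L = 800
        scores = np.array(rng.uniform(40, 60, L - 20))
        scores[100:180] = 1.0
        t = Transcript(id="t", seq="A" * L)
        profile = profile_from_scores(scores)
        res = select_window(profile, t, W=100, objective="min")
        assert scores[res.site_positions].mean() == pytest.approx(res.mean_score)
        # the minimum window must cover the low block
        assert res.mean_score < 30

    def test_orf_restriction(self, rng):
        t = Transcript(id="t", seq=random_dna(rng, 1000))
        t.orf = Interval(300, 600)
        profile = profile_from_scores(rng.uniform(0, 100, 980))
        res = select_window(profile, t, W=150, restrict_to_orf=True)
        assert res.window.start >= 300 and res.window.end <= 600
        assert all(p >= 300 and p + 21 <= 600 for p in res.site_positions)

    def test_short_region_truncates_with_flag(self, rng):
        t = Transcript(id="t", seq=random_dna(rng, 120))
        profile = profile_from_scores(rng.uniform(0, 100, 100))
        res = select_window(profile, t, W=300)
        assert res.truncated
        assert len(res.window) == 120

    def test_mean_is_mean_of_inside_sites(self, rng):
        t = Transcript(id="t", seq=random_dna(rng, 600))
        scores = rng.uniform(0, 100, 580)
        profile = profile_from_scores(scores)
        res = select_window(profile, t, W=200)
        assert res.mean_score == pytest.approx(
            float(np.mean([scores[p] for p in res.site_positions]))
        )
        assert len(res.site_positions) == 200 - 21 + 1


class TestConstructBuilder:
    def test_231_bp_template(self, rng):
        backbone = Transcript(id="b", seq=random_dna(rng, 210))
        c = build_insertion_construct(backbone, random_dna(rng, 21))
        assert len(c.template) == 231
        assert c.insertion_offset == 105

    def test_insert_verbatim_at_midpoint(self, rng):
        backbone = random_dna(rng, 210)
        site = random_dna(rng, 21)
        c = build_insertion_construct(backbone, site)
        assert c.template[105 : 105 + 21] == site

    def test_excision_reproduces_backbone(self, rng):
        backbone = random_dna(rng, 137)
        site = random_dna(rng, 21)
        c = build_insertion_construct(backbone, site)
        off = c.insertion_offset
        assert c.template[:off] + c.template[off + 21 :] == backbone
        assert len(c.template) == len(backbone) + 21

    def test_ambiguous_site_errors(self, rng):
        with pytest.raises(ValueError):
            build_insertion_construct(random_dna(rng, 50), "N" * 21)
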