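"""Score reconstruction, E-values and segment-wise dissection."""

import math

import numpy as np
import pytest

from hmmdissect import fixtures as fx
from hmmdissect.alignment_io import AlignmentPath, State, Step
from hmmdissect.model_io import NEG_INF, XT_FIELDS, HmmModel
from hmmdissect.segmentation import FOLD, REMNANT, Segmentation
from hmmdissect.dissection import (
    DEFAULT_DB_SIZE,
    PathModelError,
    dissect,
    evalue,
    evalue_ratio,
    ratio_verdict,
    reconstruct_score,
)


def tiny_model(K=2, **overrides):
    """Hand-set model whose score terms can be summed on paper."""
    kwargs = dict(
        name="tiny",
        match_emission=np.zeros((K, 20)),
        insert_emission=np.zeros((K, 20)),
        transition=np.zeros((K, 9)),
        xt={f: 0.0 for f in XT_FIELDS},
        null_transition=(0.0, 0.0),
        null_emission=np.zeros(20),
        b_to_m1=0.0,
        b_to_d1=NEG_INF,
        evd_mu=0.0,
        evd_lambda=0.5,
    )
    kwargs.update(overrides)
    return HmmModel(**kwargs)


class TestReconstructScore:
    def test_empty_path_scores_fixed_alone(self):
        model = tiny_model(xt={f: -0.1 for f in XT_FIELDS})
        path = AlignmentPath("h", [])
        assert reconstruct_score(path, model) == pytest.approx(model.fixed_score)
        assert model.fixed_score == pytest.approx(-0.3)

    def test_hand_summed_two_state_alignment(self):
        """Emissions 1.0 + 2.0, entry 0.5, M1->M2 0.25, exit 0.0, f -0.25 -> 3.5."""
        model = tiny_model(K=2)
        model.match_emission[0, 0] = 1.0  # A at state 1
        model.match_emission[1, 2] = 2.0  # D at state 2
        model.b_to_m1 = 0.5
        model.transition[0, 0] = 0.25  # M1 -> M2
        model.transition[1, 8] = 0.0   # M2 -> E
        model.xt["NB"] = -0.25
        path = AlignmentPath(
            "h", [[Step(State.MATCH, 1, 1, "A"), Step(State.MATCH, 2, 2, "D")]]
        )
        assert reconstruct_score(path, model) == pytest.approx(3.5)

    def test_impossible_emission_propagates(self):
        model = tiny_model(K=2)
        model.match_emission[0, 0] = NEG_INF
        path = AlignmentPath(
            "h", [[Step(State.MATCH, 1, 1, "A"), Step(State.MATCH, 2, 2, "A")]]
        )
        assert reconstruct_score(path, model) == NEG_INF

    def test_path_beyond_model_rejected(self, model):
        path = AlignmentPath("h", [[Step(State.MATCH, model.length_K + 1, 1, "A")]])
        with pytest.raises(PathModelError, match="outside"):
            reconstruct_score(path, model)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle(self, seed):
        spec = fx.FixtureSpec(seed=seed, model_length=12)
        model, _ = fx.make_model(spec)
        path, hand = fx.make_alignment_with_truth(spec, model)
        assert reconstruct_score(path, model) == pytest.approx(float(hand), abs=1e-9)

    def test_delete_path_drops_skipped_emission(self):
        """Deleting state 2 removes its emission and swaps in D transitions."""
        model = tiny_model(K=3)
        model.match_emission[:, 0] = [1.0, 5.0, 2.0]
        model.transition[:, 0] = -0.1   # MM
        model.transition[:, 2] = -0.7   # MD
        model.transition[:, 5] = -0.3   # DM
        model.transition[2, 8] = 0.0
        full = AlignmentPath("h", [[Step(State.MATCH, k, k, "A") for k in (1, 2, 3)]])
        dele = AlignmentPath(
            "h",
            [[Step(State.MATCH, 1, 1, "A"), Step(State.DELETE, 2), Step(State.MATCH, 3, 2, "A")]],
        )
        v_full = reconstruct_score(full, model)
        v_del = reconstruct_score(dele, model)
        # drop emission 5.0 and the two -0.1 MM transitions; add MD + DM
        assert v_full - v_del == pytest.approx(5.0 + 2 * (-0.1) - (-0.7 - 0.3))


class TestEvalue:
    def test_at_location_parameter(self):
        N = 1000
        assert evalue(0.0, mu=0.0, lam=0.5, db_size=N) == pytest.approx(
            N * (1 - math.exp(-1))
        )

    def test_limits(self):
        assert evalue(1e9, mu=0.0, lam=0.5, db_size=100) == pytest.approx(0.0, abs=1e-300)
        assert evalue(-1e9, mu=0.0, lam=0.5, db_size=100) == pytest.approx(100.0)
        assert evalue(NEG_INF, mu=0.0, lam=0.5, db_size=100) == 100.0

    def test_against_high_precision_reference(self):
        # reference computed with 50-digit arbitrary-precision arithmetic
        assert evalue(10.0, mu=0.0, lam=0.7, db_size=540261) == pytest.approx(
            492.4297095842, rel=1e-10
        )

    def test_large_score_avoids_premature_underflow(self):
        e = evalue(200.0, mu=0.0, lam=0.7, db_size=DEFAULT_DB_SIZE)
        assert e == pytest.approx(DEFAULT_DB_SIZE * math.exp(-140.0), rel=1e-12)
        assert e > 0

    def test_strictly_decreasing_in_score_increasing_in_db(self):
        # below mu - 30/lambda the survival probability saturates at 1 in
        # double precision, so strict monotonicity is asserted above it
        scores = np.linspace(2, 120, 60)
        es = [evalue(v, mu=10.0, lam=0.4, db_size=1000) for v in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert evalue(5.0, mu=0.0, lam=0.5, db_size=2000) == pytest.approx(
            2 * evalue(5.0, mu=0.0, lam=0.5, db_size=1000)
        )

    def test_uncalibrated_model_requires_override(self, model):
        model.evd_mu = None
        model.evd_lambda = None
        with pytest.raises(ValueError, match="uncalibrated"):
            evalue(1.0, model)
        assert evalue(1.0, model, mu=0.0, lam=0.5) > 0

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            evalue(1.0, mu=0.0, lam=0.0)


class TestEvalueRatio:
    def test_table_examples_two_significant_figures(self):
        assert float(f"{evalue_ratio(7.6e-1, 6.7e-6):.1e}") == 1.1e5
        assert float(f"{evalue_ratio(2.2e-6, 1.4e2):.1e}") == 1.6e-8

    def test_equal_evalues_ratio_one(self):
        assert evalue_ratio(3.3, 3.3) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            evalue_ratio(1.0, 0.0)

    def test_verdict_bands(self):
        assert ratio_verdict(1e-5) == "homology-supporting"
        assert ratio_verdict(1.0) == "on-par"
        assert ratio_verdict(1e4) == "spurious"


class TestDissect:
    def test_all_fold_puts_everything_in_fold(self, spec, model):
        path = fx.make_path(spec, model)
        seg = Segmentation(classes=[FOLD] * model.length_K)
        d = dissect(path, model, seg)
        v = reconstruct_score(path, model)
        assert d.remnant_score == 0.0
        assert d.fold_score == pytest.approx(v - model.fixed_score)
        assert d.total_score == pytest.approx(v)

    def test_hand_partitioned_four_state_model(self):
        """FOLD=[1,2], REMNANT=[3,4]: each term goes to its anchor's class."""
        model = tiny_model(K=4)
        model.match_emission[:, 0] = [1.0, 2.0, 4.0, 8.0]
        model.b_to_m1 = 0.5           # entry, anchored at 1 (FOLD)
        model.transition[:, 0] = 0.25  # MM into 2 (FOLD), 3, 4 (REMNANT)
        model.transition[3, 8] = 0.125  # M4 -> E, anchored at 4
        model.xt["NB"] = -0.25
        path = AlignmentPath(
            "h", [[Step(State.MATCH, k, k, "A") for k in range(1, 5)]]
        )
        seg = Segmentation(classes=[FOLD, FOLD, REMNANT, REMNANT])
        d = dissect(path, model, seg)
        assert d.fold_score == pytest.approx(0.5 + 1.0 + 0.25 + 2.0)
        assert d.remnant_score == pytest.approx(0.25 + 4.0 + 0.25 + 8.0 + 0.125)
        assert d.fixed_score == pytest.approx(-0.25)
        assert d.total_score == pytest.approx(d.fold_score + d.remnant_score - 0.25)

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_under_random_segmentation(self, seed):
        spec = fx.FixtureSpec(seed=seed, model_length=10)
        model, _ = fx.make_model(spec)
        path = fx.make_path(spec, model)
        rng = np.random.default_rng(seed)
        classes = [FOLD if rng.random() < 0.5 else REMNANT for _ in range(10)]
        d = dissect(path, model, Segmentation(classes=classes))
        assert d.fold_score + d.remnant_score + d.fixed_score == d.total_score
        assert d.total_score == pytest.approx(reconstruct_score(path, model), abs=1e-9)

    def test_insert_terms_follow_last_match_position(self):
        model = tiny_model(K=2)
        model.insert_emission[0, 0] = 3.0
        model.transition[0, 1] = -0.5  # M1 -> I1
        model.transition[0, 3] = -0.5  # I1 -> M2
        model.transition[1, 8] = 0.0
        path = AlignmentPath(
            "h",
            [[
                Step(State.MATCH, 1, 1, "A"),
                Step(State.INSERT, 1, 2, "A"),
                Step(State.MATCH, 2, 3, "A"),
            ]],
        )
        seg = Segmentation(classes=[FOLD, REMNANT])
        d = dissect(path, model, seg)
        # insert emission (3.0) and M1->I1 anchor at position 1 => FOLD;
        # I1->M2 enters position 2 => REMNANT
        assert d.fold_score == pytest.approx(3.0 - 0.5)
        assert d.remnant_score == pytest.approx(-0.5)

    def test_fragment_scores_sum_to_positional_total(self, model):
        f1 = [Step(State.MATCH, k, k, "A") for k in range(1, 4)]
        f2 = [Step(State.MATCH, k, k + 40, "C") for k in range(5, model.length_K + 1)]
        path = AlignmentPath("h", [f1, f2])
        seg = Segmentation(classes=fx.FixtureSpec(seed=0, model_length=model.length_K).planted_classes())
        d = dissect(path, model, seg)
        assert len(d.fragment_scores) == 2
        assert sum(d.fragment_scores) + d.fixed_score == pytest.approx(d.total_score)

    def test_splitting_intervals_leaves_dissection_unchanged(self, spec, model):
        """Dissection depends only on per-position classes, not interval shape."""
        path = fx.make_path(spec, model)
        classes = spec.planted_classes()
        a = dissect(path, model, Segmentation(classes=classes))
        tsv = Segmentation(classes=classes).to_tsv()
        # split every interval into single positions; classes identical
        refined = Segmentation.from_tsv(
            "model_start\tmodel_end\tclass\n"
            + "".join(f"{k}\t{k}\t{c}\n" for k, c in enumerate(classes, 1))
        )
        b = dissect(path, model, refined)
        assert (a.fold_score, a.remnant_score) == (b.fold_score, b.remnant_score)

    def test_conservation_for_arbitrary_segmentations(self, spec, model):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        path = fx.make_path(spec, model)
        v = reconstruct_score(path, model)

        @settings(max_examples=60, derandomize=True, deadline=None)
        @given(st.lists(st.sampled_from([FOLD, REMNANT]),
                        min_size=model.length_K, max_size=model.length_K))
        def check(classes):
            d = dissect(path, model, Segmentation(classes=classes))
            assert d.fold_score + d.remnant_score + d.fixed_score == d.total_score
            assert d.total_score == pytest.approx(v, abs=1e-9)

        check()

    def test_segmentation_length_mismatch_rejected(self, spec, model):
        path = fx.make_path(spec, model)
        with pytest.raises(ValueError, match="segmentation"):
            dissect(path, model, Segmentation(classes=[FOLD] * (model.length_K + 1)))
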