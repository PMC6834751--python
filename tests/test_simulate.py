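import numpy as np
import pandas as pd
import pytest

from fmpmaze import (
    CohortSpec,
    TurnModelParams,
    estimate_turn_model,
    expected_tetragram_freqs,
    simulate_cohort,
    simulate_conditioning_trajectory,
    simulate_tank_trajectory,
    simulate_tokens,
    simulate_turn_sequence,
    tetragram_freq_std,
)
from fmpmaze.laterality import TETRAGRAMS, count_tetragrams


def eight_state_expected_freqs(params):
    """Independent oracle: stationary law of the chain lifted to 3-token
    histories (8 states, via numpy eigendecomposition), then
    P(w) = pi3(w1 w2 w3) * P(w4 | w3)."""
    P2 = params.transition_matrix  # (L, R)
    idx = {"l": 0, "r": 1}
    words3 = [a + b + c for a in "lr" for b in "lr" for c in "lr"]
    T = np.zeros((8, 8))
    for i, w in enumerate(words3):
        for nxt in "lr":
            j = words3.index(w[1:] + nxt)
            T[i, j] = P2[idx[w[2]], idx[nxt]]
    vals, vecs = np.linalg.eig(T.T)
    k = np.argmin(np.abs(vals - 1.0))
    pi3 = np.real(vecs[:, k])
    pi3 = pi3 / pi3.sum()
    out = {}
    for w in TETRAGRAMS:
        out[w] = pi3[words3.index(w[:3])] * P2[idx[w[2]], idx[w[3]]]
    return out


class TestTurnModel:
    def test_absorbing_chain_is_all_R(self):
        tokens = simulate_tokens(TurnModelParams(a=1.0, b=1.0), 50, seed=0)
        assert (tokens == "R").all()

    def test_deterministic_alternation(self):
        tokens = simulate_tokens(TurnModelParams(a=1.0, b=0.0), 50, seed=0)
        pairs = set(zip(tokens[:-1], tokens[1:]))
        assert pairs <= {("L", "R"), ("R", "L")}

    def test_iid_special_case_when_a_equals_b(self):
        p = TurnModelParams(a=0.3, b=0.3)
        assert p.stationary_R == pytest.approx(0.3)

    def test_stationary_solve_matches_eigenvector_and_simulation(self):
        p = TurnModelParams(a=0.6, b=0.7)
        assert p.stationary_R == pytest.approx(2.0 / 3.0)
        vals, vecs = np.linalg.eig(p.transition_matrix.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        pi /= pi.sum()
        assert pi[1] == pytest.approx(p.stationary_R, abs=1e-12)
        n = 10_000
        tokens = simulate_tokens(p, n, seed=17)
        # SE of the mean of a 2-state chain: binomial times (1+lam)/(1-lam)
        lam = p.b - p.a
        se = np.sqrt(p.stationary_R * (1 - p.stationary_R) / n * (1 + lam) / (1 - lam))
        assert abs(np.mean(tokens == "R") - 2.0 / 3.0) < 3 * se

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="turn_rate"):
            TurnModelParams(turn_rate_per_min=0.0)

    def test_poisson_clock_mean_turn_count(self):
        counts = [
            simulate_turn_sequence(
                TurnModelParams(turn_rate_per_min=6.0), seed=s
            ).n_turns
            for s in range(30)
        ]
        # expected 360 turns/session; 3 SE of the mean over 30 sessions
        assert abs(np.mean(counts) - 360.0) < 3 * np.sqrt(360.0 / 30)


class TestExpectedTetragramFreqs:
    def test_fair_coin_is_uniform(self):
        freqs = expected_tetragram_freqs(TurnModelParams(a=0.5, b=0.5))
        assert all(v == pytest.approx(1.0 / 16.0) for v in freqs.values())

    def test_absorbing_chain_concentrates_on_rrrr(self):
        freqs = expected_tetragram_freqs(
            TurnModelParams(a=1.0, b=1.0, initial_R_prob=1.0)
        )
        assert freqs["rrrr"] == pytest.approx(1.0)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_reducible_chain_uses_initial_law(self):
        freqs = expected_tetragram_freqs(
            TurnModelParams(a=0.0, b=1.0, initial_R_prob=0.25)
        )
        assert freqs["rrrr"] == pytest.approx(0.25)
        assert freqs["llll"] == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "a,b", [(0.6, 0.7), (0.5, 0.5), (0.72, 0.72), (0.2, 0.9), (0.9, 0.1)]
    )
    def test_matches_eight_state_enumeration_oracle(self, a, b):
        p = TurnModelParams(a=a, b=b)
        closed = expected_tetragram_freqs(p)
        oracle = eight_state_expected_freqs(p)
        assert sum(closed.values()) == pytest.approx(1.0, abs=1e-12)
        for w in TETRAGRAMS:
            assert closed[w] == pytest.approx(oracle[w], abs=1e-12)

    def test_overlap_aware_std_matches_monte_carlo(self):
        # self-overlapping words (llll/rrrr) have super-binomial sampling
        # noise; verify the closed-form SD against 300 replicate streams
        p = TurnModelParams(a=0.6, b=0.7)
        n_tok, reps = 1000, 300
        rng = np.random.default_rng(3)
        freqs = np.empty((reps, 16))
        for r in range(reps):
            prof = count_tetragrams(simulate_tokens(p, n_tok, rng))
            freqs[r] = [prof.rel_freq[w] for w in TETRAGRAMS]
        emp = freqs.std(axis=0, ddof=1)
        pred = tetragram_freq_std(p, n_tok - 3)
        for w, e in zip(TETRAGRAMS, emp):
            # SD of an SD estimate over 300 reps is ~4-6 % for these skewed
            # counts; 25 % headroom keeps the check sharp but stable
            assert e == pytest.approx(pred[w], rel=0.25), w


class TestEstimateTurnModel:
    def test_recovers_parameters_at_2000_turns(self):
        p = TurnModelParams(a=0.6, b=0.7)
        hits = 0
        rng = np.random.default_rng(12)
        for _ in range(40):
            a_hat, b_hat = estimate_turn_model(simulate_tokens(p, 2000, rng))
            hits += abs(a_hat - 0.6) < 0.05 and abs(b_hat - 0.7) < 0.05
        assert hits >= 39

    def test_degenerate_stream_gives_nan(self):
        a_hat, b_hat = estimate_turn_model(np.array(list("RRRR"), dtype="<U1"))
        assert np.isnan(a_hat) and b_hat == 1.0


class TestSimulateCohort:
    def test_minimal_cohort_has_three_subjects(self):
        cohort = simulate_cohort(CohortSpec(n_left=1, n_right=1, n_non=1, random_seed=5))
        assert len(cohort.events) == 3
        assert len(cohort.truth) == 3
        assert set(cohort.truth["true_class"]) == {
            "left_biased",
            "right_biased",
            "non_biased",
        }

    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = CohortSpec(n_left=2, n_right=2, n_non=3, random_seed=9)
        simulate_cohort(spec).write(tmp_path / "a")
        simulate_cohort(spec).write(tmp_path / "b")
        for name in ("arm_entries.csv", "ground_truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            CohortSpec(n_left=0, n_right=0, n_non=0)


class TestTankTrajectory:
    def test_zero_biases_occupy_thirds_evenly(self, cfg):
        # unbiased reflected walk: stationary depth law is uniform; average
        # the thirds over 10 replicates and allow Monte-Carlo wobble
        fracs = np.zeros(3)
        for s in range(10):
            front, _ = simulate_tank_trajectory(
                0.0, 0.0, speed_cm_s=6.0, duration_s=300, sample_hz=10, cfg=cfg, seed=s
            )
            z = front["v"].to_numpy()
            third = cfg.tank_height_cm / 3.0
            fracs += [
                np.mean(z < third),
                np.mean((z >= third) & (z < 2 * third)),
                np.mean(z >= 2 * third),
            ]
        fracs /= 10
        assert np.all(np.abs(fracs - 1.0 / 3.0) < 0.06)

    def test_strong_bottom_bias_dominates(self, cfg):
        wins = 0
        for s in range(20):
            front, _ = simulate_tank_trajectory(
                1.0, 0.0, duration_s=300, sample_hz=10, cfg=cfg, seed=s
            )
            z = front["v"].to_numpy()
            wins += np.mean(z < cfg.tank_height_cm / 3.0) > 0.8
        assert wins >= 19

    def test_zero_speed_freezes_the_fish(self, cfg):
        front, top = simulate_tank_trajectory(
            0.5, 0.5, speed_cm_s=0.0, duration_s=10, sample_hz=5, cfg=cfg, seed=1
        )
        assert front["u"].nunique() == 1 and front["v"].nunique() == 1
        assert np.hypot(np.diff(top["u"]), np.diff(top["v"])).sum() == 0.0

    def test_views_share_time_base_and_horizontal_axis(self, cfg):
        front, top = simulate_tank_trajectory(
            0.2, 0.1, duration_s=10, sample_hz=5, cfg=cfg, seed=2
        )
        assert np.array_equal(front["time_s"], top["time_s"])
        assert np.array_equal(front["u"], top["u"])


class TestConditioningTrajectory:
    def test_null_strength_paired_difference_centred_on_zero(self):
        from fmpmaze import ConditioningSchedule, score_conditioning

        schedule = ConditioningSchedule()
        deltas = []
        for s in range(60):
            traj = simulate_conditioning_trajectory(0.0, schedule, seed=s)
            res = score_conditioning(traj, schedule)
            deltas.append(res.delta_pref)
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se + 1e-9

    def test_extreme_strength_pins_probe_preference_near_zero(self):
        from fmpmaze import ConditioningSchedule, score_conditioning

        schedule = ConditioningSchedule()
        prefs = [
            score_conditioning(
                simulate_conditioning_trajectory(20.0, schedule, seed=s), schedule
            ).probe_pref
            for s in range(10)
        ]
        assert np.mean(prefs) < 0.1
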