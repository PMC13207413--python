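"""Enrichment metrics: EF, cutoff rounding, ROC-AUC, RIE, BEDROC."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenvalid import screen_eval as se
from screenvalid import synthetic_data as sd
from tests.conftest import random_screen

# the two published validation screens: (A, n_decoy, printed active counts per fraction)
MAOB = dict(A=1352, D=2080, counts={0.01: 23, 0.05: 117, 0.10: 226},
            efs={0.01: 1.72, 0.05: 1.73, 0.10: 1.67})
GSK3B = dict(A=1389, D=2162, counts={0.01: 16, 0.05: 92, 0.10: 189},
             efs={0.01: 1.14, 0.05: 1.32, 0.10: 1.36})


def screen_with_counts(A, D, counts):
    """Deterministic screen whose top-fraction active counts match `counts`."""
    N = A + D
    cuts = sorted(counts)
    labels = []
    prev_n = prev_a = 0
    for f in cuts:
        n = se.topk_count(N, f)
        a = counts[f]
        block = ["active"] * (a - prev_a) + ["decoy"] * ((n - prev_n) - (a - prev_a))
        labels.extend(block)
        prev_n, prev_a = n, a
    rest_a = A - prev_a
    rest_d = D - labels.count("decoy")
    labels.extend(["active"] * rest_a + ["decoy"] * rest_d)
    assert len(labels) == N and labels.count("active") == A
    return se.rank_screen(
        [se.RankedEntry(id=f"m{i}", score=float(N - i), label=lab) for i, lab in enumerate(labels)]
    )


class TestRankScreen:
    def test_descending_order(self):
        rs = se.rank_screen([se.RankedEntry("a", 1.0, "active"), se.RankedEntry("b", 2.0, "decoy")])
        assert [e.id for e in rs.entries] == ["b", "a"]

    def test_tie_groups(self):
        rs = se.rank_screen(
            [se.RankedEntry(i, s, "active" if i == "a" else "decoy")
             for i, s in [("a", 1.0), ("b", 1.0), ("c", 1.0), ("d", 0.5)]]
        )
        assert rs.tie_groups == [(0, 3)]

    def test_matches_independent_sort_oracle(self):
        rng = random.Random(7)
        entries = [se.RankedEntry(f"m{i}", rng.gauss(0, 1), rng.choice(["active", "decoy"]))
                   for i in range(1000)]
        rs = se.rank_screen(entries)
        oracle = sorted(entries, key=lambda e: e.score, reverse=True)
        assert [e.score for e in rs.entries] == [e.score for e in oracle]

    def test_degenerate_label_refusal(self):
        rs = se.rank_screen([se.RankedEntry("a", 1.0, "active"), se.RankedEntry("b", 0.5, "active")])
        assert rs.degenerate
        for op in (se.roc_auc, se.rie, se.bedroc):
            with pytest.raises(ValueError, match="degenerate_labels"):
                op(rs)


class TestTopkCount:
    @pytest.mark.parametrize(
        "N, f, expected",
        [
            (3432, 0.01, 34),   # printed top-1% cutoff, MAOB set
            (3551, 0.01, 36),   # printed top-1% cutoff, GSK-3beta set
            (3432, 0.05, 172),
            (3551, 0.05, 178),
            (3432, 0.10, 343),
            (3551, 0.10, 355),
            (100, 0.005, 1),    # clamped to >= 1
            (10, 0.25, 3),      # 2.5 rounds half-up
        ],
    )
    def test_nearest_integer_half_up(self, N, f, expected):
        assert se.topk_count(N, f) == expected

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_domain(self, f):
        with pytest.raises(ValueError):
            se.topk_count(100, f)


class TestEnrichmentFactor:
    @pytest.mark.parametrize("sets", [MAOB, GSK3B])
    def test_published_values_reproduce(self, sets):
        N = sets["A"] + sets["D"]
        for f, a in sets["counts"].items():
            n = se.topk_count(N, f)
            assert round(se.enrichment_factor(a, n, sets["A"], N), 2) == sets["efs"][f]

    def test_no_enrichment_gives_one(self):
        assert se.enrichment_factor(5, 10, 50, 100) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            se.enrichment_factor(1, 0, 10, 100)
        with pytest.raises(ValueError):
            se.enrichment_factor(5, 4, 10, 100)


class TestRocAuc:
    def test_perfect_separation(self):
        ents = [se.RankedEntry(f"a{i}", 10 + i, "active") for i in range(5)]
        ents += [se.RankedEntry(f"d{i}", -float(i), "decoy") for i in range(20)]
        assert se.roc_auc(se.rank_screen(ents)) == 1.0

    def test_equals_brute_force_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            rs = random_screen(rng, 5, 120)
            act = [e.score for e in rs.entries if e.label == "active"]
            dec = [e.score for e in rs.entries if e.label == "decoy"]
            wins = sum((a > d) + 0.5 * (a == d) for a in act for d in dec)
            assert se.roc_auc(rs) == pytest.approx(wins / (len(act) * len(dec)))

    def test_equals_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            rs = random_screen(rng, 10, 200)
            y = [1 if e.label == "active" else 0 for e in rs.entries]
            s = [e.score for e in rs.entries]
            assert se.roc_auc(rs) == pytest.approx(roc_auc_score(y, s))

    def test_mirror_antisymmetry(self):
        rng = np.random.default_rng(5)
        rs = random_screen(rng, 20, 100)
        mirror = se.rank_screen(
            [se.RankedEntry(e.id, -e.score, e.label) for e in rs.entries]
        )
        assert se.roc_auc(rs) + se.roc_auc(mirror) == pytest.approx(1.0)

    def test_random_labels_average_half(self):
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(60):
            scores = rng.normal(size=400)
            labels = np.array(["active"] * 120 + ["decoy"] * 280)
            rng.shuffle(labels)
            rs = se.rank_screen(
                [se.RankedEntry(f"m{i}", float(scores[i]), str(labels[i])) for i in range(400)]
            )
            aucs.append(se.roc_auc(rs))
        mean = float(np.mean(aucs))
        sem = float(np.std(aucs) / math.sqrt(len(aucs)))
        assert abs(mean - 0.5) < 3 * sem + 1e-12


class TestRieBedroc:
    def test_perfect_early_recognition_limit(self):
        ents = [se.RankedEntry(f"a{i}", 1000.0 - i, "active") for i in range(10)]
        ents += [se.RankedEntry(f"d{i}", -float(i), "decoy") for i in range(990)]
        assert se.bedroc(se.rank_screen(ents), 20.0) == pytest.approx(1.0, abs=1e-3)

    def test_random_permutation_mean_rie_is_one(self):
        rng = np.random.default_rng(21)
        N, A = 300, 60
        ries = []
        for _ in range(300):
            labels = np.array(["active"] * A + ["decoy"] * (N - A))
            rng.shuffle(labels)
            rs = se.rank_screen(
                [se.RankedEntry(f"m{i}", float(N - i), str(labels[i])) for i in range(N)]
            )
            ries.append(se.rie(rs, 20.0))
        mean = float(np.mean(ries))
        sem = float(np.std(ries) / math.sqrt(len(ries)))
        assert abs(mean - 1.0) < 3 * sem

    def test_small_alpha_limit_is_auc(self):
        rng = np.random.default_rng(8)
        rs = random_screen(rng, 30, 80)
        assert se.bedroc(rs, 1e-3) == pytest.approx(se.roc_auc(rs), abs=1e-3)

    def test_alpha_domain(self):
        rng = np.random.default_rng(1)
        rs = random_screen(rng)
        for op in (se.rie, se.bedroc):
            with pytest.raises(ValueError):
                op(rs, 0.0)

    def test_perfect_screen_maximizes_bedroc_exhaustively(self):
        # every label permutation at N=8, A=3: the perfect screen wins
        from itertools import permutations

        scores = [8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        best = None
        values = []
        for perm in set(permutations(["active"] * 3 + ["decoy"] * 5)):
            rs = se.rank_screen(
                [se.RankedEntry(f"m{i}", scores[i], perm[i]) for i in range(8)]
            )
            b = se.bedroc(rs, 5.0)
            values.append(b)
            if perm == ("active", "active", "active", "decoy", "decoy", "decoy", "decoy", "decoy"):
                best = b
        assert best == max(values)
        assert all(0.0 <= v <= 1.0 for v in values)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bedroc_bounded_and_rie_positive(self, seed):
        rng = np.random.default_rng(seed)
        rs = random_screen(rng)
        assert 0.0 <= se.bedroc(rs, 20.0) <= 1.0
        assert se.rie(rs, 20.0) > 0.0


class TestEvaluateScreen:
    @pytest.mark.parametrize("sets", [MAOB, GSK3B])
    def test_published_worked_examples(self, sets):
        rs = screen_with_counts(sets["A"], sets["D"], sets["counts"])
        report = se.evaluate_screen(rs)
        for f, ef in sets["efs"].items():
            assert round(report.ef[f], 2) == ef
            assert report.a_f[f] == sets["counts"][f]
        assert report.n_f[0.01] == se.topk_count(sets["A"] + sets["D"], 0.01)
        assert 0 <= report.bedroc_alpha <= 1 and report.rie_alpha > 0

    def test_counts_consistent_with_ranked_list(self):
        rng = np.random.default_rng(17)
        rs = random_screen(rng, 50, 300)
        report = se.evaluate_screen(rs)
        prev = 0
        for f in report.fractions:
            recount = sum(1 for e in rs.entries[: report.n_f[f]] if e.label == "active")
            assert report.a_f[f] == recount
            assert report.a_f[f] >= prev
            prev = report.a_f[f]
            bound = min(report.n_f[f], report.A) / report.n_f[f] * report.N / report.A
            assert 0 <= report.ef[f] <= bound + 1e-12

    def test_balanced_random_screen_ef_near_one(self):
        rng = np.random.default_rng(4)
        efs = []
        for _ in range(50):
            labels = np.array(["active"] * 200 + ["decoy"] * 200)
            rng.shuffle(labels)
            scores = rng.normal(size=400)
            rs = se.rank_screen(
                [se.RankedEntry(f"m{i}", float(scores[i]), str(labels[i])) for i in range(400)]
            )
            efs.append(se.evaluate_screen(rs).ef[0.10])
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)

    def test_scores_csv_roundtrip_with_numeric_labels(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text("id,score,label\nm1,2.5,2\nm2,1.5,1\nm3,0.5,1\n")
        entries = se.read_scores_csv(path)
        assert [e.label for e in entries] == ["active", "decoy", "decoy"]
        se.write_scores_csv(entries, tmp_path / "out.csv")
        assert se.read_scores_csv(tmp_path / "out.csv") == entries

    def test_boundary_tie_warning(self):
        ents = [se.RankedEntry(f"m{i}", 1.0, "active" if i % 2 else "decoy") for i in range(10)]
        ents += [se.RankedEntry(f"z{i}", -float(i + 1), "decoy") for i in range(90)]
        rs = se.rank_screen(ents)
        assert se.boundary_tie_warning(rs, 5) is not None
        assert se.boundary_tie_warning(rs, 50) is None
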