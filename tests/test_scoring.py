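"""Post filtering, segmentation, weighted-frequency scoring with negation
reversal, and daily aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from emoprosocial import (
    Lexicon,
    LexiconEntry,
    Post,
    aggregate_daily,
    filter_posts,
    score_tokens,
    tokenize,
)
from emoprosocial.scoring import (
    PostScores,
    SCORE_CATEGORIES,
    ScoringError,
    read_posts_csv,
    read_posts_jsonl,
    read_scores_csv,
    read_severity_csv,
    write_posts_csv,
    write_posts_jsonl,
    write_scores_csv,
    write_severity_csv,
)

D = dt.date(2020, 1, 25)


def post(text, **kw):
    defaults = dict(post_id="p1", user_id="u1", date=D, text=text)
    defaults.update(kw)
    return Post(**defaults)


class TestFilterPosts:
    def test_inclusion_rules_and_drop_counts(self):
        posts = [
            post("ordinary text", post_id="a"),
            post("official notice", post_id="b", is_official=True),
            post("reposted body", post_id="c", is_repost=True, repost_comment="加油"),
            post("reposted body", post_id="d", is_repost=True, repost_comment=None),
        ]
        kept, drops = filter_posts(posts)
        assert [p.post_id for p in kept] == ["a", "c"]
        assert kept[0].text == "ordinary text"
        # repost keeps only the attached comment
        assert kept[1].text == "加油"
        assert drops == {"official": 1, "empty_repost": 1, "keyword_miss": 0}

    def test_users_are_pseudonymized_one_way(self):
        kept, _ = filter_posts([post("t", user_id="alice"), post("t", user_id="alice")])
        assert kept[0].user_id == kept[1].user_id != "alice"
        other, _ = filter_posts([post("t", user_id="bob")])
        assert other[0].user_id != kept[0].user_id

    def test_keyword_prefilter(self):
        posts = [post("肺炎 related", post_id="a"), post("unrelated", post_id="b")]
        kept, drops = filter_posts(posts, keyword="肺炎")
        assert [p.post_id for p in kept] == ["a"]
        assert drops["keyword_miss"] == 1


class TestTokenize:
    def test_exact_lexicon_term_is_single_token(self):
        assert tokenize("捐赠", {"捐赠"}).tokens == ["捐赠"]

    def test_negator_then_term_longest_match(self):
        assert tokenize("不捐赠", {"不", "捐赠"}).tokens == ["不", "捐赠"]

    def test_empty_text(self):
        assert tokenize("", {"x"}).tokens == []

    def test_longest_match_wins_over_prefix(self):
        # "志愿者" must come out whole, not as "志愿" + "者"
        assert tokenize("志愿者加油", {"志愿", "志愿者"}).tokens == ["志愿者", "加", "油"]

    def test_every_contiguous_vocab_occurrence_survives(self):
        vocab = {"helpword", "не", "rage"}
        text = "xx helpword yy rage helpword"
        toks = tokenize(text, vocab).tokens
        assert toks.count("helpword") == 2 and toks.count("rage") == 1

    def test_whitespace_separates_and_is_dropped(self):
        assert tokenize("a  b\tc", {"a", "b", "c"}).tokens == ["a", "b", "c"]


def brute_force_scores(tokens, emotion_lex, prosocial_lex, negators, window=1):
    """Independent oracle: enumerate every (occurrence, category) pair."""
    neg = set(negators)
    out = {c: 0.0 for c in SCORE_CATEGORIES}
    entries = list(emotion_lex.entries) + list(prosocial_lex.entries)
    for i, tok in enumerate(tokens):
        negated = any(
            0 <= j < len(tokens) and tokens[j] in neg
            for j in range(i - window, i)
        )
        for e in entries:
            if e.term == tok:
                out[e.category] += (-1.0 if negated else 1.0) * e.weight
    return out


class TestScoreTokens:
    def test_single_prosocial_term(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        scores = score_tokens(["helpword"], emo, pro, neg)
        assert scores["prosocial"] == pytest.approx(8.2)
        assert all(scores[c] == 0.0 for c in SCORE_CATEGORIES if c != "prosocial")

    def test_negator_reverses_immediately_following_term(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        assert score_tokens(["not", "helpword"], emo, pro, neg)["prosocial"] == pytest.approx(-8.2)

    def test_two_terms_accumulate(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        scores = score_tokens(["giveword", "zz", "careword"], emo, pro, neg)
        assert scores["prosocial"] == pytest.approx(12.0)

    def test_multicategory_term_contributes_to_each(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        scores = score_tokens(["bothword"], emo, pro, neg)
        assert scores["sadness"] == pytest.approx(2.0)
        assert scores["fear"] == pytest.approx(4.0)

    def test_reversal_is_a_flag_not_a_product(self, toy_lexicons):
        # Two negators inside the window still flip the sign exactly once.
        emo, pro, neg = toy_lexicons
        scores = score_tokens(["not", "never", "helpword"], emo, pro, neg, window=2)
        assert scores["prosocial"] == pytest.approx(-8.2)

    def test_double_negation_window_one(self, toy_lexicons):
        # With window 1 only the immediately preceding token is checked:
        # "not not helpword" scores -weight (the decided semantics).
        emo, pro, neg = toy_lexicons
        scores = score_tokens(["not", "not", "helpword"], emo, pro, neg, window=1)
        assert scores["prosocial"] == pytest.approx(-8.2)

    def test_no_lexicon_terms_scores_zero_everywhere(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        assert all(v == 0.0 for v in score_tokens(["xx", "yy"], emo, pro, neg).values())

    def test_additive_over_concatenation_without_boundary_negator(self, toy_lexicons):
        emo, pro, neg = toy_lexicons
        rng = np.random.default_rng(5)
        pool = ["helpword", "giveword", "rageword", "joyword", "zz", "not", "bothword"]
        for _ in range(200):
            a = list(rng.choice(pool, size=rng.integers(0, 8)))
            b = list(rng.choice(pool, size=rng.integers(1, 8)))
            if a and a[-1] in ("not", "never"):
                a[-1] = "zz"  # no negator may span the boundary
            sa = score_tokens(a, emo, pro, neg)
            sb = score_tokens(b, emo, pro, neg)
            sab = score_tokens(a + b, emo, pro, neg)
            for c in SCORE_CATEGORIES:
                assert sab[c] == pytest.approx(sa[c] + sb[c])

    @pytest.mark.parametrize("window", [1, 2, 3])
    def test_matches_bruteforce_enumeration(self, toy_lexicons, window):
        emo, pro, neg = toy_lexicons
        rng = np.random.default_rng(window)
        pool = ["helpword", "giveword", "careword", "rageword", "joyword",
                "bothword", "not", "never", "zz", "qq"]
        for _ in range(300):
            toks = list(rng.choice(pool, size=rng.integers(0, 15)))
            got = score_tokens(toks, emo, pro, neg, window=window)
            want = brute_force_scores(toks, emo, pro, neg, window=window)
            assert got == pytest.approx(want)


class TestAggregateDaily:
    def scores(self, day, **vals):
        s = {c: 0.0 for c in SCORE_CATEGORIES}
        s.update(vals)
        return PostScores(post_id="x", date=day, scores=s)

    def test_single_and_multi_post_means(self):
        d0, d1 = dt.date(2020, 1, 20), dt.date(2020, 1, 21)
        scored = [
            self.scores(d0, prosocial=2.0),
            self.scores(d0, prosocial=4.0),
            self.scores(d1, prosocial=5.0),
        ]
        sev = {d0: 100, d1: 150}
        panel = aggregate_daily(scored, sev, (d0, d1))
        assert panel.loc[d0, "prosocial"] == pytest.approx(3.0)
        assert panel.loc[d1, "prosocial"] == pytest.approx(5.0)
        assert list(panel["n_posts"]) == [2, 1]
        assert list(panel["new_cases"]) == [100, 150]

    def test_window_day_without_posts_names_the_date(self):
        d0 = dt.date(2020, 1, 20)
        scored = [self.scores(d0)]
        sev = {d0: 10, dt.date(2020, 1, 21): 11}
        with pytest.raises(ScoringError, match="2020-01-21"):
            aggregate_daily(scored, sev, (d0, dt.date(2020, 1, 21)))

    def test_missing_severity_names_the_date(self):
        d0, d1 = dt.date(2020, 1, 20), dt.date(2020, 1, 21)
        scored = [self.scores(d0), self.scores(d1)]
        with pytest.raises(ScoringError, match="2020-01-21"):
            aggregate_daily(scored, {d0: 10}, (d0, d1))

    def test_mass_conservation(self):
        # sum over days of (mean * n_posts) must equal the total score.
        rng = np.random.default_rng(9)
        days = [dt.date(2020, 1, 20) + dt.timedelta(days=i) for i in range(7)]
        scored = []
        for d in days:
            for _ in range(int(rng.integers(1, 9))):
                scored.append(self.scores(d, prosocial=float(rng.normal()), anger=float(rng.normal())))
        sev = {d: 1 for d in days}
        panel = aggregate_daily(scored, sev, (days[0], days[-1]))
        for cat in ("prosocial", "anger"):
            total = sum(s.scores[cat] for s in scored)
            assert float((panel[cat] * panel["n_posts"]).sum()) == pytest.approx(total)

    def test_full_window_length(self, tiny_dataset, tiny_config, study_window):
        from emoprosocial import score_posts

        scored = score_posts(
            tiny_dataset.posts,
            tiny_dataset.emotion_lexicon,
            tiny_dataset.prosocial_lexicon,
            tiny_dataset.negators,
        )
        panel = aggregate_daily(scored, tiny_dataset.severity, study_window)
        assert len(panel) == 41


class TestIO:
    def make_posts(self):
        return [
            post("你好 world", post_id="a", is_repost=True, repost_comment="评论"),
            post("second", post_id="b", user_id="u2"),
        ]

    def test_jsonl_roundtrip(self, tmp_path):
        p = tmp_path / "posts.jsonl"
        write_posts_jsonl(self.make_posts(), p)
        assert read_posts_jsonl(p) == self.make_posts()

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "posts.csv"
        write_posts_csv(self.make_posts(), p)
        assert read_posts_csv(p) == self.make_posts()

    def test_severity_roundtrip(self, tmp_path):
        sev = {dt.date(2020, 1, 20): 77, dt.date(2020, 1, 21): 149}
        p = tmp_path / "severity.csv"
        write_severity_csv(sev, p)
        assert read_severity_csv(p) == sev

    def test_scores_roundtrip(self, tmp_path):
        s = {c: float(i) for i, c in enumerate(SCORE_CATEGORIES)}
        scored = [PostScores(post_id="a", date=D, scores=s)]
        p = tmp_path / "scores.csv"
        write_scores_csv(scored, p)
        assert read_scores_csv(p) == scored
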