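"""Post filtering, tokenization, weighted-frequency scoring, daily panel.

Each post is segmented into tokens and every occurrence of a lexicon term
contributes its weight to the term's category; occurrences preceded by a
negator token (within a configurable window, default the single preceding
token) contribute with reversed sign.  Reversal is a flag, not a product:
several negators in the window still flip the sign exactly once.  Per-post
category scores are then averaged within calendar days and joined with the
daily count of newly confirmed cases to form the analysis panel.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicons import ALL_CATEGORIES, Lexicon, canonicalize

SCORE_CATEGORIES = ALL_CATEGORIES  # six emotions + prosocial


class ScoringError(ValueError):
    pass


@dataclass
class Post:
    post_id: str
    user_id: str
    date: _dt.date
    text: str
    is_official: bool = False
    is_repost: bool = False
    repost_comment: str | None = None


@dataclass
class TokenSequence:
    tokens: list[str]
    post_id: str = ""


@dataclass
class PostScores:
    post_id: str
    date: _dt.date
    scores: dict[str, float]


def anonymize_user(user_id: str, salt: str = "emoprosocial") -> str:
    """One-way, stable pseudonym for a user identifier."""
    return hashlib.sha1((salt + ":" + user_id).encode("utf-8")).hexdigest()[:12]


def filter_posts(
    posts: Iterable[Post],
    *,
    keyword: str | None = None,
    salt: str = "emoprosocial",
) -> tuple[list[Post], dict[str, int]]:
    """Apply the corpus inclusion rules and de-identify users.

    Posts from official verified accounts are dropped.  For reposts only
    the attached comment is retained as the text (reposts with no comment
    are dropped, as the reposted body does not express the reposting
    user's own view).  An optional keyword substring filter emulates
    crawl-time topic selection.  Returns the retained posts and a count
    of drops per reason.
    """
    kept: list[Post] = []
    drops = {"official": 0, "empty_repost": 0, "keyword_miss": 0}
    for p in posts:
        if p.is_official:
            drops["official"] += 1
            continue
        if p.is_repost:
            if not (p.repost_comment and p.repost_comment.strip()):
                drops["empty_repost"] += 1
                continue
            p = replace(p, text=p.repost_comment)
        if keyword is not None and keyword not in p.text:
            drops["keyword_miss"] += 1
            continue
        kept.append(replace(p, user_id=anonymize_user(p.user_id, salt=salt)))
    return kept, drops


class LongestMatchTokenizer:
    """Greedy longest-match segmentation against a known vocabulary.

    Every vocabulary term occurring contiguously in the text is emitted as
    a single token; characters not starting a vocabulary match fall back
    to single-character tokens.  Whitespace separates tokens and is not
    emitted.  This is the built-in default segmenter; any callable
    ``text -> list[str]`` (for example an external Chinese segmenter) can
    be passed wherever a tokenizer is accepted.
    """

    def __init__(self, vocab: Iterable[str]):
        self.vocab = {canonicalize(v) for v in vocab if canonicalize(v)}
        if not self.vocab:
            raise ScoringError("tokenizer vocabulary must be nonempty")
        self.maxlen = max(len(v) for v in self.vocab)

    def __call__(self, text: str) -> list[str]:
        text = canonicalize(text)
        tokens: list[str] = []
        i, n = 0, len(text)
        while i < n:
            if text[i].isspace():
                i += 1
                continue
            match = None
            for length in range(min(self.maxlen, n - i), 1, -1):
                cand = text[i : i + length]
                if cand in self.vocab:
                    match = cand
                    break
            if match is None:
                match = text[i]  # single-character fallback
            tokens.append(match)
            i += len(match)
        return tokens


def tokenize(
    text: str,
    vocab: Iterable[str],
    post_id: str = "",
    tokenizer: Callable[[str], list[str]] | None = None,
) -> TokenSequence:
    tok = tokenizer if tokenizer is not None else LongestMatchTokenizer(vocab)
    return TokenSequence(tokens=tok(text), post_id=post_id)


def score_tokens(
    tokens: Sequence[str],
    emotion_lex: Lexicon,
    prosocial_lex: Lexicon,
    negators: Iterable[str],
    window: int = 1,
    *,
    length_normalize: bool = False,
) -> dict[str, float]:
    """Accumulate weighted frequencies per category with negation reversal.

    Each lexicon occurrence contributes its weight; if any token in the
    ``window`` positions before it is a negator the contribution's sign
    is flipped (once).  A term listed in several categories contributes
    to each.  With ``length_normalize`` the accumulated sums are divided
    by the token count.
    """
    if window < 1:
        raise ScoringError("negation window must be >= 1")
    term_map: dict[str, list[tuple[str, float]]] = {}
    for lex in (emotion_lex, prosocial_lex):
        for term, pairs in lex.term_weights().items():
            term_map.setdefault(term, []).extend(pairs)
    neg = {canonicalize(n) for n in negators}
    scores = {c: 0.0 for c in SCORE_CATEGORIES}
    for i, tok in enumerate(tokens):
        pairs = term_map.get(tok)
        if not pairs:
            continue
        reversed_flag = any(
            tokens[j] in neg for j in range(max(0, i - window), i)
        )
        sign = -1.0 if reversed_flag else 1.0
        for category, weight in pairs:
            scores[category] += sign * weight
    if length_normalize and tokens:
        scores = {c: v / len(tokens) for c, v in scores.items()}
    return scores


def score_post(
    post: Post,
    emotion_lex: Lexicon,
    prosocial_lex: Lexicon,
    negators: Iterable[str],
    window: int = 1,
    tokenizer: Callable[[str], list[str]] | None = None,
    *,
    length_normalize: bool = False,
) -> PostScores:
    """Tokenize one post and score it against both lexicons."""
    vocab = emotion_lex.terms() | prosocial_lex.terms() | {canonicalize(n) for n in negators}
    seq = tokenize(post.text, vocab, post_id=post.post_id, tokenizer=tokenizer)
    scores = score_tokens(
        seq.tokens, emotion_lex, prosocial_lex, negators, window=window,
        length_normalize=length_normalize,
    )
    return PostScores(post_id=post.post_id, date=post.date, scores=scores)


def score_posts(
    posts: Iterable[Post],
    emotion_lex: Lexicon,
    prosocial_lex: Lexicon,
    negators: Iterable[str],
    window: int = 1,
    *,
    length_normalize: bool = False,
) -> list[PostScores]:
    """Score a corpus, building the longest-match tokenizer once."""
    negs = [canonicalize(n) for n in negators]
    vocab = emotion_lex.terms() | prosocial_lex.terms() | set(negs)
    tok = LongestMatchTokenizer(vocab)
    out = []
    for p in posts:
        scores = score_tokens(
            tok(p.text), emotion_lex, prosocial_lex, negs, window=window,
            length_normalize=length_normalize,
        )
        out.append(PostScores(post_id=p.post_id, date=p.date, scores=scores))
    return out


def aggregate_daily(
    scored: Iterable[PostScores],
    severity: Mapping[_dt.date, int],
    window: tuple[_dt.date, _dt.date],
) -> pd.DataFrame:
    """Daily mean category scores joined with the severity series.

    Returns one row per calendar day of ``window`` (inclusive), columns
    ``n_posts``, the seven category means, and ``new_cases``.  A day with
    no posts or no severity value is an error naming the date.
    """
    start, end = window
    if start > end:
        raise ScoringError(f"window start {start} after end {end}")
    rows = [
        {"date": s.date, **s.scores}
        for s in scored
        if start <= s.date <= end
    ]
    if not rows:
        raise ScoringError("no scored posts fall inside the study window")
    df = pd.DataFrame(rows)
    grouped = df.groupby("date")
    means = grouped[list(SCORE_CATEGORIES)].mean()
    means.insert(0, "n_posts", grouped.size())
    days = pd.date_range(start, end, freq="D").date
    for day in days:
        if day not in means.index:
            raise ScoringError(f"no posts on {day.isoformat()} within the study window")
        if day not in severity:
            raise ScoringError(f"no severity value for {day.isoformat()}")
    panel = means.loc[list(days)].copy()
    panel["new_cases"] = [int(severity[d]) for d in days]
    panel.index = pd.Index(days, name="date")
    return panel


# ---------------------------------------------------------------------------
# I/O dialects: posts as JSON-lines or CSV; severity as CSV date,new_cases;
# panel as CSV with the documented column order.

_POST_FIELDS = ["post_id", "user_id", "date", "text", "is_official", "is_repost", "repost_comment"]


def _post_to_record(p: Post) -> dict:
    return {
        "post_id": p.post_id,
        "user_id": p.user_id,
        "date": p.date.isoformat(),
        "text": p.text,
        "is_official": p.is_official,
        "is_repost": p.is_repost,
        "repost_comment": p.repost_comment,
    }


def _post_from_record(r: Mapping) -> Post:
    comment = r.get("repost_comment")
    if isinstance(comment, float) and np.isnan(comment):
        comment = None
    if comment == "":
        comment = None
    return Post(
        post_id=str(r["post_id"]),
        user_id=str(r["user_id"]),
        date=_dt.date.fromisoformat(str(r["date"])),
        text="" if r.get("text") is None or (isinstance(r.get("text"), float) and np.isnan(r["text"])) else str(r["text"]),
        is_official=_as_bool(r.get("is_official", False)),
        is_repost=_as_bool(r.get("is_repost", False)),
        repost_comment=None if comment is None else str(comment),
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().casefold() in ("1", "true", "yes")
    return bool(v)


def write_posts_jsonl(posts: Iterable[Post], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps(_post_to_record(p), ensure_ascii=False) + "\n")


def read_posts_jsonl(path) -> list[Post]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_post_from_record(json.loads(line)))
    return out


def write_posts_csv(posts: Iterable[Post], path) -> None:
    pd.DataFrame([_post_to_record(p) for p in posts], columns=_POST_FIELDS).to_csv(
        path, index=False
    )


def read_posts_csv(path) -> list[Post]:
    df = pd.read_csv(path, dtype={"post_id": str, "user_id": str})
    return [_post_from_record(r) for r in df.to_dict("records")]


def read_posts(path) -> list[Post]:
    """Dispatch on extension: .jsonl/.ndjson -> JSON-lines, else CSV."""
    s = str(path)
    if s.endswith((".jsonl", ".ndjson")):
        return read_posts_jsonl(path)
    return read_posts_csv(path)


def write_scores_csv(scored: Iterable[PostScores], path) -> None:
    rows = [
        {"post_id": s.post_id, "date": s.date.isoformat(), **{c: s.scores[c] for c in SCORE_CATEGORIES}}
        for s in scored
    ]
    pd.DataFrame(rows, columns=["post_id", "date", *SCORE_CATEGORIES]).to_csv(path, index=False)


def read_scores_csv(path) -> list[PostScores]:
    df = pd.read_csv(path, dtype={"post_id": str})
    return [
        PostScores(
            post_id=str(r["post_id"]),
            date=_dt.date.fromisoformat(str(r["date"])),
            scores={c: float(r[c]) for c in SCORE_CATEGORIES},
        )
        for _, r in df.iterrows()
    ]


def read_severity_csv(path) -> dict[_dt.date, int]:
    df = pd.read_csv(path)
    if not {"date", "new_cases"}.issubset(df.columns):
        raise ScoringError(f"{path}: severity CSV needs columns date,new_cases")
    return {
        _dt.date.fromisoformat(str(r["date"])): int(r["new_cases"])
        for _, r in df.iterrows()
    }


def write_severity_csv(severity: Mapping[_dt.date, int], path) -> None:
    pd.DataFrame(
        {"date": [d.isoformat() for d in sorted(severity)],
         "new_cases": [int(severity[d]) for d in sorted(severity)]}
    ).to_csv(path, index=False)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    cols = ["n_posts", *SCORE_CATEGORIES, "new_cases"]
    panel[cols].to_csv(path, index_label="date")


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = [_dt.date.fromisoformat(str(d)) for d in df["date"]]
    return df.set_index("date")
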