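"""Weighted emotion and prosocial lexicons: construction, validation, I/O.

An emotion lexicon assigns each term one of Ekman's six basic-emotion
categories (happiness, anger, sadness, fear, disgust, surprise) and an
intensity weight on a 1–9 scale.  A prosocial lexicon assigns terms a
prosociality weight on the same scale, obtained by having human raters
score candidate words on a 9-point Likert scale, filtering out words
rated low or inconsistently, and min–max rescaling the surviving mean
ratings back onto [1, 9].
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EMOTION_CATEGORIES = ("happiness", "anger", "sadness", "fear", "disgust", "surprise")
PROSOCIAL_CATEGORY = "prosocial"
ALL_CATEGORIES = EMOTION_CATEGORIES + (PROSOCIAL_CATEGORY,)

WEIGHT_LO = 1.0
WEIGHT_HI = 9.0


class LexiconError(ValueError):
    """Raised for invalid lexicon entries, files or rating tables."""


def canonicalize(term: str) -> str:
    """NFC-normalize, strip surrounding whitespace and case-fold a term.

    ``str.casefold`` is the identity on CJK characters, so Chinese terms
    are untouched while Latin-script terms become case-insensitive.
    """
    return unicodedata.normalize("NFC", term).strip().casefold()


@dataclass(frozen=True)
class LexiconEntry:
    """One scored term: the unit of lexicon-based scoring."""

    term: str
    category: str
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", canonicalize(self.term))
        if not self.term:
            raise LexiconError("lexicon term must be nonempty")
        if self.category not in ALL_CATEGORIES:
            raise LexiconError(
                f"unknown category {self.category!r}; expected one of {ALL_CATEGORIES}"
            )
        w = float(self.weight)
        if not np.isfinite(w) or not (WEIGHT_LO <= w <= WEIGHT_HI):
            raise LexiconError(f"weight {self.weight!r} outside [{WEIGHT_LO}, {WEIGHT_HI}]")
        object.__setattr__(self, "weight", w)


@dataclass
class Lexicon:
    """A set of weighted terms of a single kind (``emotion`` or ``prosocial``)."""

    entries: list[LexiconEntry] = field(default_factory=list)
    kind: str = "emotion"

    def __post_init__(self) -> None:
        if self.kind not in ("emotion", "prosocial"):
            raise LexiconError(f"kind must be 'emotion' or 'prosocial', got {self.kind!r}")
        allowed = (
            set(EMOTION_CATEGORIES) if self.kind == "emotion" else {PROSOCIAL_CATEGORY}
        )
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.category not in allowed:
                raise LexiconError(
                    f"category {e.category!r} not allowed in a {self.kind} lexicon"
                )
            key = (e.term, e.category)
            if key in seen:
                raise LexiconError(f"duplicate (term, category) pair {key!r}")
            seen.add(key)

    def terms(self) -> set[str]:
        return {e.term for e in self.entries}

    def term_weights(self) -> dict[str, list[tuple[str, float]]]:
        """Map term -> list of (category, weight) pairs it contributes to."""
        out: dict[str, list[tuple[str, float]]] = {}
        for e in self.entries:
            out.setdefault(e.term, []).append((e.category, e.weight))
        return out

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RatingTable:
    """Complete terms × raters table of integer 1–9 prosociality ratings."""

    ratings: pd.DataFrame  # index = terms, columns = rater ids

    def __post_init__(self) -> None:
        df = self.ratings
        if df.isna().any().any():
            raise LexiconError("rating table has missing cells; every cell must be rated")
        vals = df.to_numpy()
        if vals.size and (
            (vals < 1).any() or (vals > 9).any() or not np.allclose(vals, np.round(vals))
        ):
            raise LexiconError("ratings must be integers on the 9-point scale [1, 9]")

    @property
    def terms(self) -> list[str]:
        return list(self.ratings.index)

    @property
    def raters(self) -> list[str]:
        return list(self.ratings.columns)


def aggregate_ratings(table: RatingTable) -> pd.DataFrame:
    """Per-term mean and sample standard deviation (n−1) across raters.

    Returns a DataFrame indexed by term with columns ``mean`` and ``sd``,
    preserving the table's term order.
    """
    if len(table.terms) == 0:
        raise LexiconError("rating table has no candidate terms")
    df = table.ratings
    return pd.DataFrame({"mean": df.mean(axis=1), "sd": df.std(axis=1, ddof=1)})


def filter_candidates(
    stats: pd.DataFrame, mean_min: float = 6.0, sd_max: float = 2.0
) -> list[str]:
    """Retain terms rated high and consistently.

    Deletion is strict — mean *below* ``mean_min`` or SD *above* ``sd_max``
    drops a term — so boundary values (mean exactly 6, SD exactly 2) are
    kept.  Input order is preserved.
    """
    if len(stats) == 0:
        raise LexiconError("no candidate statistics to filter")
    keep = (stats["mean"] >= mean_min) & (stats["sd"] <= sd_max)
    return list(stats.index[keep])


def minmax_normalize(
    means: Mapping[str, float] | pd.Series,
    lo: float = WEIGHT_LO,
    hi: float = WEIGHT_HI,
    *,
    constant_fallback: bool = False,
) -> pd.Series:
    """Affinely rescale per-term mean ratings onto [lo, hi].

    The minimum-scoring term maps to ``lo`` and the maximum to ``hi``;
    rank order is preserved.  All-identical means leave the scaling
    undefined: that raises unless ``constant_fallback`` explicitly maps
    every term to the interval midpoint.
    """
    s = pd.Series(means, dtype=float)
    if s.empty:
        raise LexiconError("no means to normalize")
    mn, mx = float(s.min()), float(s.max())
    if mx == mn:
        if constant_fallback:
            return pd.Series((lo + hi) / 2.0, index=s.index)
        raise LexiconError("all means identical: min-max scaling undefined")
    return lo + (hi - lo) * (s - mn) / (mx - mn)


def interrater_reliability(table: RatingTable, method: str = "icc2k") -> float:
    """Agreement among raters over the candidate terms.

    ``icc2k``: two-way random-effects, average-measures intraclass
    correlation ICC(2,k).  ``mean_pairwise_r``: mean Pearson correlation
    over all rater pairs.  Both lie in [−1, 1].
    """
    df = table.ratings
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise LexiconError("reliability needs at least 2 raters and 2 terms")
    if np.allclose(df.mean(axis=1).var(ddof=1), 0.0) and np.allclose(
        df.to_numpy().var(axis=0).sum(), 0.0
    ):
        raise LexiconError("zero between-term variance: ratings are degenerate")
    if method == "icc2k":
        import warnings

        import pingouin as pg

        long = df.reset_index(names="term").melt(
            id_vars="term", var_name="rater", value_name="rating"
        )
        with warnings.catch_warnings():
            # degenerate error variance makes the (unused) F-based CIs warn
            warnings.simplefilter("ignore", RuntimeWarning)
            icc = pg.intraclass_corr(
                data=long, targets="term", raters="rater", ratings="rating"
            )
        # two-way random, average measures: labelled ICC2k (Shrout-Fleiss)
        # or ICC(A,k) (McGraw-Wong) depending on pingouin version
        row = icc[icc["Type"].isin(("ICC2k", "ICC(A,k)"))]
        value = float(row["ICC"].iloc[0])
        if not np.isfinite(value):
            raise LexiconError("ICC undefined for this table (degenerate variance)")
        return value
    if method == "mean_pairwise_r":
        cols = df.to_numpy(dtype=float)
        k = cols.shape[1]
        rs = []
        for i in range(k):
            for j in range(i + 1, k):
                if cols[:, i].std() == 0 or cols[:, j].std() == 0:
                    raise LexiconError("a rater gave constant ratings: correlation undefined")
                rs.append(np.corrcoef(cols[:, i], cols[:, j])[0, 1])
        return float(np.mean(rs))
    raise LexiconError(f"unknown reliability method {method!r}")


def lexicon_overlap(a: Lexicon, b: Lexicon) -> float:
    """Fraction of a's terms that also occur in b (after canonicalization)."""
    ta = a.terms()
    if not ta:
        raise LexiconError("overlap undefined for an empty reference lexicon")
    return len(ta & b.terms()) / len(ta)


def build_prosocial_lexicon(
    table: RatingTable,
    mean_min: float = 6.0,
    sd_max: float = 2.0,
    lo: float = WEIGHT_LO,
    hi: float = WEIGHT_HI,
) -> Lexicon:
    """Rating table -> filtered, min–max-weighted prosocial lexicon."""
    stats = aggregate_ratings(table)
    kept = filter_candidates(stats, mean_min=mean_min, sd_max=sd_max)
    if not kept:
        raise LexiconError("no terms survive the rating filters")
    weights = minmax_normalize(stats.loc[kept, "mean"], lo=lo, hi=hi)
    entries = [
        LexiconEntry(term=t, category=PROSOCIAL_CATEGORY, weight=float(w))
        for t, w in weights.items()
    ]
    return Lexicon(entries=entries, kind="prosocial")


# ---------------------------------------------------------------------------
# File I/O.  Lexicons are UTF-8 TSV with header term<TAB>category<TAB>weight;
# '#' lines are comments.  Rating tables are CSV: first column term, one
# column per rater.


def read_lexicon(path, kind: str) -> Lexicon:
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                if [c.strip().casefold() for c in row[:3]] != ["term", "category", "weight"]:
                    raise LexiconError(
                        f"{path}:{lineno}: expected header 'term\\tcategory\\tweight'"
                    )
                header_seen = True
                continue
            if len(row) < 3:
                raise LexiconError(f"{path}:{lineno}: expected 3 tab-separated fields")
            term, category, weight = row[0], row[1].strip(), row[2].strip()
            try:
                entries.append(LexiconEntry(term=term, category=category, weight=float(weight)))
            except (LexiconError, ValueError) as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    try:
        return Lexicon(entries=entries, kind=kind)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


def write_lexicon(lex: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "category", "weight"])
        for e in lex.entries:
            writer.writerow([e.term, e.category, repr(e.weight)])


def read_rating_table(path) -> RatingTable:
    df = pd.read_csv(path, index_col=0)
    return RatingTable(ratings=df)


def write_rating_table(table: RatingTable, path) -> None:
    table.ratings.to_csv(path)


def read_negators(path) -> list[str]:
    """One negator per line; '#' comments and blank lines ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(canonicalize(line))
    return out


def write_negators(negators: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in negators:
            fh.write(n + "\n")
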