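"""Synthetic social-media panel generator with planted ground truth.

Emulates the study conditions the pipeline targets: a 41-day epidemic
window, hundreds to thousands of posts per day, weighted-lexicon words
embedded in free text, negators, a unimodal daily confirmed-case curve,
and a planted emotion x severity interaction driving prosocial word
emission.  The synthetic "language" is token-separable (whitespace), with
filler vocabulary disjoint from every lexicon, so the built-in tokenizer
is exact on it and statistical tests are decoupled from segmentation
fidelity.

Generation model, per day d:
  e_{c,d} ~ Normal(mu_c, sigma_c) latent intensity per emotion category,
            sample-standardized across days to z_{c,d};
  s_d     = daily new confirmed cases (log-normal-shaped pulse + Poisson
            noise, floored), sample-standardized to zs_d;
  p_d     = b0 + b1*z_{e,d} + b2*zs_d + b3*z_{e,d}*zs_d + eps_d, where e is
            the designated driving emotion and eps ~ Normal(0, noise_sd);
  each post mixes filler tokens with per-category lexicon-term counts drawn
  Poisson(rate_c * exp(gain * latent)), a log-linear emission link chosen
  for positivity; negators are inserted immediately before a configurable
  fraction of lexicon-term occurrences.

With the default ``noise_sd=None`` the residual SD is set to
sqrt(1 - b1^2 - b2^2 - b3^2) so the latent prosocial series has unit
variance and the planted (b1, b2, b3) are recovered on the standardized
scale the analysis uses.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lexicons import EMOTION_CATEGORIES, PROSOCIAL_CATEGORY, Lexicon, LexiconEntry
from .moderation import standardize
from .scoring import Post

_PREFIX = {
    "happiness": "hp", "anger": "ag", "sadness": "sd", "fear": "fr",
    "disgust": "dg", "surprise": "sp", "prosocial": "pr",
}
_NEGATOR_PREFIX = "ng"
_FILLER_PREFIX = "zz"

# Per-post expected lexicon-term counts per category, set so that mean
# per-post weighted scores land near the magnitudes daily Weibo panels
# show (rare anger/surprise, frequent fear/disgust/prosocial mentions).
DEFAULT_BASE_RATES = {
    "happiness": 0.40, "anger": 0.04, "sadness": 0.20, "fear": 0.70,
    "disgust": 0.60, "surprise": 0.03, "prosocial": 0.75,
}


class SynthError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator; a seed is passed per call."""

    n_days: int = 41
    start_date: _dt.date = _dt.date(2020, 1, 20)
    posts_per_day: tuple[int, int] = (800, 2000)
    emotion_vocab_size: int = 40       # terms per emotion category
    prosocial_vocab_size: int = 155
    n_negators: int = 5
    n_fillers: int = 300
    filler_per_post: tuple[int, int] = (5, 20)
    base_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    emission_gain: float = 0.5         # log-linear link gain on latents
    negator_fraction: float = 0.1      # fraction of lexicon occurrences negated
    driving_emotion: str = "anger"
    daily_latent_mean: float = 0.0
    daily_latent_sd: float = 1.0
    b0: float = 0.0
    b1: float = 0.3                    # emotion -> prosocial emission
    b2: float = 0.3                    # severity -> prosocial emission
    b3: float = 0.4                    # interaction
    noise_sd: float | None = None      # None => sqrt(1 - b1^2 - b2^2 - b3^2)
    severity_peak_day: int = 20        # 1-based day of the pulse maximum
    severity_peak_height: float = 3500.0
    severity_log_width: float = 0.5
    severity_floor: int = 77
    severity_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_days < 5:
            raise SynthError("n_days must be >= 5")
        if self.posts_per_day[0] < 1 or self.posts_per_day[0] > self.posts_per_day[1]:
            raise SynthError("posts_per_day must be a nonempty (lo, hi) range")
        if self.driving_emotion not in EMOTION_CATEGORIES:
            raise SynthError(f"driving_emotion must be one of {EMOTION_CATEGORIES}")
        if min(self.emotion_vocab_size, self.prosocial_vocab_size, self.n_negators,
               self.n_fillers) < 1:
            raise SynthError("all vocabulary sizes must be >= 1")
        if not (0.0 <= self.negator_fraction <= 1.0):
            raise SynthError("negator_fraction must lie in [0, 1]")

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        return float(np.sqrt(max(1.0 - self.b1**2 - self.b2**2 - self.b3**2, 0.04)))

    @property
    def dates(self) -> list[_dt.date]:
        return [self.start_date + _dt.timedelta(days=i) for i in range(self.n_days)]

    def config_hash(self) -> str:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["posts_per_day"] = list(self.posts_per_day)
        d["filler_per_post"] = list(self.filler_per_post)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["start_date"] = _dt.date.fromisoformat(d["start_date"])
        d["posts_per_day"] = tuple(d["posts_per_day"])
        d["filler_per_post"] = tuple(d["filler_per_post"])
        return cls(**d)


@dataclass
class GroundTruth:
    """The planted quantities a generated dataset was built from."""

    dates: list[_dt.date]
    emotion_latents_z: pd.DataFrame   # days x six categories, standardized
    prosocial_latent: np.ndarray      # p_d series
    severity: np.ndarray              # raw daily cases
    severity_z: np.ndarray
    coefficients: dict[str, float]    # b0..b3
    noise_sd: float
    driving_emotion: str
    config_hash: str


def generate_lexicons(
    config: SimulationConfig, seed: int
) -> tuple[Lexicon, Lexicon, list[str]]:
    """Collision-free synthetic lexicons with Uniform[1, 9] weights."""
    rng = np.random.default_rng([int(seed), 101])
    emo_entries = []
    for cat in EMOTION_CATEGORIES:
        weights = rng.uniform(1.0, 9.0, size=config.emotion_vocab_size)
        emo_entries.extend(
            LexiconEntry(term=f"{_PREFIX[cat]}{i:04d}", category=cat, weight=float(w))
            for i, w in enumerate(weights)
        )
    pro_weights = rng.uniform(1.0, 9.0, size=config.prosocial_vocab_size)
    pro_entries = [
        LexiconEntry(term=f"{_PREFIX[PROSOCIAL_CATEGORY]}{i:04d}",
                     category=PROSOCIAL_CATEGORY, weight=float(w))
        for i, w in enumerate(pro_weights)
    ]
    negators = [f"{_NEGATOR_PREFIX}{i:03d}" for i in range(config.n_negators)]
    return (
        Lexicon(entries=emo_entries, kind="emotion"),
        Lexicon(entries=pro_entries, kind="prosocial"),
        negators,
    )


def filler_vocabulary(config: SimulationConfig) -> list[str]:
    return [f"{_FILLER_PREFIX}{i:04d}" for i in range(config.n_fillers)]


def generate_severity(config: SimulationConfig, seed: int) -> dict[_dt.date, int]:
    """Daily new confirmed cases: floored log-normal pulse + Poisson noise."""
    rng = np.random.default_rng([int(seed), 202])
    days = np.arange(1, config.n_days + 1, dtype=float)
    base = config.severity_peak_height * np.exp(
        -(np.log(days / config.severity_peak_day) ** 2)
        / (2.0 * config.severity_log_width**2)
    )
    if config.severity_noise:
        pulse = rng.poisson(base)
    else:
        pulse = np.round(base).astype(int)
    cases = config.severity_floor + pulse
    return {d: int(c) for d, c in zip(config.dates, cases)}


def _latents(
    config: SimulationConfig, severity: Mapping[_dt.date, int], rng: np.random.Generator
) -> GroundTruth:
    dates = sorted(severity)
    if dates != config.dates:
        raise SynthError("severity dates do not match the configured study window")
    raw = rng.normal(
        config.daily_latent_mean, config.daily_latent_sd,
        size=(config.n_days, len(EMOTION_CATEGORIES)),
    )
    z = np.column_stack([standardize(raw[:, j]).values for j in range(raw.shape[1])])
    ez = pd.DataFrame(z, index=pd.Index(dates, name="date"), columns=EMOTION_CATEGORIES)
    sev = np.array([severity[d] for d in dates], dtype=float)
    sz = standardize(sev).values
    noise_sd = config.resolved_noise_sd
    drive = ez[config.driving_emotion].to_numpy()
    p = (
        config.b0
        + config.b1 * drive
        + config.b2 * sz
        + config.b3 * drive * sz
        + rng.normal(0.0, noise_sd, size=config.n_days)
    )
    return GroundTruth(
        dates=dates,
        emotion_latents_z=ez,
        prosocial_latent=p,
        severity=sev,
        severity_z=sz,
        coefficients={"b0": config.b0, "b1": config.b1, "b2": config.b2, "b3": config.b3},
        noise_sd=noise_sd,
        driving_emotion=config.driving_emotion,
        config_hash=config.config_hash(),
    )


def generate_latent_panel(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Day-level panel of latent intensities, skipping text emission.

    Columns: the six emotion latents (standardized), ``prosocial`` (the
    latent p_d series) and ``new_cases`` (raw severity).  This is the fast
    surface for statistical experiments on the moderation stage — the
    planted coefficients act on these latents exactly, with no
    text-emission sampling noise on top.
    """
    severity = generate_severity(config, seed)
    rng = np.random.default_rng([int(seed), 303])
    gt = _latents(config, severity, rng)
    panel = gt.emotion_latents_z.copy()
    panel["prosocial"] = gt.prosocial_latent
    panel["new_cases"] = gt.severity.astype(int)
    return panel, gt


def generate_posts(
    config: SimulationConfig,
    lexicons: tuple[Lexicon, Lexicon, list[str]],
    severity: Mapping[_dt.date, int],
    seed: int,
) -> tuple[list[Post], GroundTruth]:
    """Emit the synthetic corpus: one whitespace-separated text per post.

    Three independent child RNG streams (latents, content, negation) keep
    the emitted token content identical across runs that differ only in
    ``negator_fraction`` — the basis of the sign-flip oracle.
    """
    emotion_lex, prosocial_lex, negators = lexicons
    rng_latent = np.random.default_rng([int(seed), 1])
    rng_content = np.random.default_rng([int(seed), 2])
    rng_neg = np.random.default_rng([int(seed), 3])

    gt = _latents(config, severity, rng_latent)
    cat_vocab = {cat: [] for cat in EMOTION_CATEGORIES}
    for e in emotion_lex.entries:
        cat_vocab[e.category].append(e.term)
    cat_vocab[PROSOCIAL_CATEGORY] = [e.term for e in prosocial_lex.entries]
    lex_terms = set().union(*(set(v) for v in cat_vocab.values()))
    fillers = filler_vocabulary(config)
    gain = config.emission_gain
    rates = config.base_rates

    posts: list[Post] = []
    lo, hi = config.posts_per_day
    flo, fhi = config.filler_per_post
    for di, day in enumerate(gt.dates):
        day_rates = {
            cat: rates[cat] * np.exp(gain * gt.emotion_latents_z.iloc[di][cat])
            for cat in EMOTION_CATEGORIES
        }
        day_rates[PROSOCIAL_CATEGORY] = rates[PROSOCIAL_CATEGORY] * np.exp(
            gain * gt.prosocial_latent[di]
        )
        n_posts = int(rng_content.integers(lo, hi + 1))
        for j in range(n_posts):
            n_fill = int(rng_content.integers(flo, fhi + 1))
            tokens = list(rng_content.choice(fillers, size=n_fill))
            for cat, rate in day_rates.items():
                count = int(rng_content.poisson(rate))
                if count:
                    tokens.extend(rng_content.choice(cat_vocab[cat], size=count))
            rng_content.shuffle(tokens)
            if config.negator_fraction > 0.0:
                with_neg: list[str] = []
                for tok in tokens:
                    if tok in lex_terms and rng_neg.random() < config.negator_fraction:
                        with_neg.append(str(rng_neg.choice(negators)))
                    with_neg.append(tok)
                tokens = with_neg
            posts.append(
                Post(
                    post_id=f"p{di:02d}-{j:05d}",
                    user_id=f"u{int(rng_content.integers(0, 1_000_000)):06d}",
                    date=day,
                    text=" ".join(tokens),
                )
            )
    return posts, gt


@dataclass
class SyntheticDataset:
    """A complete generated study: corpus, lexicons, severity, truth."""

    posts: list[Post]
    emotion_lexicon: Lexicon
    prosocial_lexicon: Lexicon
    negators: list[str]
    severity: dict[_dt.date, int]
    ground_truth: GroundTruth
    config: SimulationConfig
    seed: int


def generate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Lexicons + severity + corpus from one master seed."""
    lexicons = generate_lexicons(config, seed)
    severity = generate_severity(config, seed)
    posts, gt = generate_posts(config, lexicons, severity, seed)
    return SyntheticDataset(
        posts=posts,
        emotion_lexicon=lexicons[0],
        prosocial_lexicon=lexicons[1],
        negators=lexicons[2],
        severity=severity,
        ground_truth=gt,
        config=config,
        seed=int(seed),
    )
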