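"""End-to-end orchestration: ingest -> filter -> score -> aggregate -> analyze.

`run_pipeline` turns raw post/lexicon/severity files into the daily panel,
the descriptive/correlation table, six per-emotion moderation fits with
simple slopes at the pick-a-point severity levels, and a fully
serializable JSON report.  `replay_table2` is the desk-scale companion:
it recomputes conditional slopes from a published coefficient table alone
(slope = B1 + B3*z), needing no raw data.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scoring
from .lexicons import EMOTION_CATEGORIES, read_lexicon, read_negators
from .moderation import (
    CorrelationReport,
    ModerationFit,
    SimpleSlope,
    correlation_report,
    fit_moderation,
    low_level_rule,
    probe_levels,
    simple_slopes,
    zscore_with,
)

logger = logging.getLogger("emoprosocial")

PACKAGE_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    posts_path: str
    emotion_lexicon_path: str
    prosocial_lexicon_path: str
    negators_path: str
    severity_path: str
    out_dir: str | None = None
    window_start: _dt.date = _dt.date(2020, 1, 20)
    window_end: _dt.date = _dt.date(2020, 2, 29)
    negation_window: int = 1
    n_boot: int = 5000
    seed: int = 20200120
    emotions: tuple[str, ...] = EMOTION_CATEGORIES
    keyword: str | None = None
    length_normalize: bool = False
    anonymize_salt: str = "emoprosocial"

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise PipelineError("study window start is after its end")
        unknown = [e for e in self.emotions if e not in EMOTION_CATEGORIES]
        if unknown:
            raise PipelineError(f"unknown emotions requested: {unknown}")

    def config_hash(self) -> str:
        d = asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Typed, fully serializable record of one pipeline run."""

    drop_counts: dict[str, int]
    panel: pd.DataFrame
    correlations: CorrelationReport
    fits: dict[str, ModerationFit]
    slopes: dict[str, list[SimpleSlope]]
    provenance: dict[str, object]

    def to_dict(self) -> dict:
        var_summary = {
            v: {
                "mean": float(self.correlations.means[v]),
                "sd": float(self.correlations.sds[v]),
            }
            for v in self.correlations.means.index
        }
        models = {}
        for emo, fit in self.fits.items():
            models[emo] = {
                "coef": fit.coef,
                "se": fit.se,
                "t": fit.t,
                "p": fit.p,
                "ci_analytic": {k: list(v) for k, v in fit.ci_analytic.items()},
                "ci_boot": (
                    {k: list(v) for k, v in fit.ci_boot.items()} if fit.ci_boot else None
                ),
                "r2": fit.r2,
                "f": fit.f,
                "f_p": fit.f_p,
                "n": fit.n,
                "n_boot": fit.n_boot,
                "seed": fit.seed,
                "simple_slopes": [
                    {
                        "label": s.label,
                        "moderator_level_raw": s.moderator_level_raw,
                        "moderator_level_z": s.moderator_level_z,
                        "slope": s.slope,
                        "se": s.se,
                        "t": s.t,
                        "p": s.p,
                    }
                    for s in self.slopes[emo]
                ],
            }
        return {
            "provenance": self.provenance,
            "drop_counts": self.drop_counts,
            "panel": {
                "n_days": int(len(self.panel)),
                "start": self.panel.index[0].isoformat(),
                "end": self.panel.index[-1].isoformat(),
                "n_posts_total": int(self.panel["n_posts"].sum()),
                "variables": var_summary,
            },
            "correlations": {
                "r": {a: {b: float(self.correlations.r.loc[a, b]) for b in self.correlations.r.columns} for a in self.correlations.r.index},
                "p": {a: {b: float(self.correlations.p.loc[a, b]) for b in self.correlations.p.columns} for a in self.correlations.p.index},
            },
            "models": models,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=False, indent=2)


def analyze_panel(
    panel: pd.DataFrame,
    emotions: Sequence[str] = EMOTION_CATEGORIES,
    n_boot: int = 5000,
    seed: int = 0,
) -> tuple[CorrelationReport, dict[str, ModerationFit], dict[str, list[SimpleSlope]]]:
    """Correlation table plus one moderation model per requested emotion.

    Each emotion is fitted independently (y = prosocial, x = the emotion,
    m = daily new cases) with a child seed derived deterministically from
    the master seed; simple slopes are probed at M + 1SD and at the
    low level (M − 1SD, floored at the observed minimum).
    """
    report = correlation_report(panel)
    m_raw = panel["new_cases"].to_numpy(dtype=float)
    levels = probe_levels(m_raw)
    children = np.random.SeedSequence(int(seed)).spawn(len(emotions))
    fits: dict[str, ModerationFit] = {}
    slopes: dict[str, list[SimpleSlope]] = {}
    for emo, child in zip(emotions, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        t0 = time.perf_counter()
        fit = fit_moderation(
            y=panel["prosocial"].to_numpy(dtype=float),
            x=panel[emo].to_numpy(dtype=float),
            m=m_raw,
            n_boot=n_boot,
            seed=child_seed,
        )
        fits[emo] = fit
        slopes[emo] = simple_slopes(
            fit,
            m_levels_raw=[levels["high"], levels["low"]],
            labels=["high (M+1SD)", "low"],
        )
        logger.info(
            "model %-9s fitted in %.2fs (B3=%.3f, p=%.3f)",
            emo, time.perf_counter() - t0, fit.coef["x:m"], fit.p["x:m"],
        )
    return report, fits, slopes


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and (optionally) write the report files."""
    t0 = time.perf_counter()
    emotion_lex = read_lexicon(config.emotion_lexicon_path, kind="emotion")
    prosocial_lex = read_lexicon(config.prosocial_lexicon_path, kind="prosocial")
    negators = read_negators(config.negators_path)
    posts = scoring.read_posts(config.posts_path)
    severity = scoring.read_severity_csv(config.severity_path)
    logger.info("ingest: %d posts, %d emotion terms, %d prosocial terms (%.2fs)",
                len(posts), len(emotion_lex), len(prosocial_lex), time.perf_counter() - t0)

    t1 = time.perf_counter()
    kept, drops = scoring.filter_posts(
        posts, keyword=config.keyword, salt=config.anonymize_salt
    )
    logger.info("filter: kept %d, dropped %s (%.2fs)", len(kept), drops,
                time.perf_counter() - t1)

    t2 = time.perf_counter()
    scored = scoring.score_posts(
        kept, emotion_lex, prosocial_lex, negators,
        window=config.negation_window, length_normalize=config.length_normalize,
    )
    logger.info("score: %d posts (%.2fs)", len(scored), time.perf_counter() - t2)

    panel = scoring.aggregate_daily(
        scored, severity, window=(config.window_start, config.window_end)
    )
    report, fits, slopes = analyze_panel(
        panel, emotions=config.emotions, n_boot=config.n_boot, seed=config.seed
    )
    run = RunReport(
        drop_counts=drops,
        panel=panel,
        correlations=report,
        fits=fits,
        slopes=slopes,
        provenance={
            "package_version": PACKAGE_VERSION,
            "config_hash": config.config_hash(),
            "seed": int(config.seed),
        },
    )
    if config.out_dir is not None:
        write_report_files(run, config.out_dir)
    logger.info("pipeline complete (%.2fs total)", time.perf_counter() - t0)
    return run


def write_report_files(run: RunReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scoring.write_panel_csv(run.panel, out / "panel.csv")
    # Table-1-shaped: M, SD and the correlation matrix.
    t1 = pd.concat(
        [run.correlations.means.rename("M"), run.correlations.sds.rename("SD"),
         run.correlations.r], axis=1
    )
    t1.to_csv(out / "table1_descriptives.csv", index_label="variable")
    # Table-2-shaped: one row per coefficient per model.
    rows = []
    term_label = {"intercept": "Intercept", "x": "emotion", "m": "severity", "x:m": "emotion x severity"}
    for emo, fit in run.fits.items():
        for term in fit.coef:
            rows.append(
                {
                    "model": emo, "term": term_label[term], "B": fit.coef[term],
                    "SE": fit.se[term], "t": fit.t[term], "p": fit.p[term],
                    "ci_lo": fit.ci_analytic[term][0], "ci_hi": fit.ci_analytic[term][1],
                    "boot_ci_lo": fit.ci_boot[term][0] if fit.ci_boot else None,
                    "boot_ci_hi": fit.ci_boot[term][1] if fit.ci_boot else None,
                    "R2": fit.r2, "F": fit.f, "n": fit.n,
                }
            )
    pd.DataFrame(rows).to_csv(out / "table2_models.csv", index=False)
    (out / "report.json").write_text(run.to_json(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Printed-coefficient replay


def load_published_models() -> dict:
    """The packaged published coefficient table (standardized B1/B3 per
    emotion plus the severity moments), for desk-scale slope replay."""
    ref = importlib.resources.files("emoprosocial.data") / "published_models.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def replay_table2(source: str | Path | Mapping | None = None) -> pd.DataFrame:
    """Recompute high/low conditional slopes from printed coefficients.

    ``source`` is a coefficient JSON (path or mapping) with a
    ``moderator`` block (mean, sd, min) and per-emotion ``models`` blocks
    carrying standardized b1 and b3; ``None`` uses the packaged published
    table.  Slopes are B1 + B3*z with z = +1 at the high level (M + 1SD)
    and z = (low_raw − M)/SD at the low level, where low_raw is M − 1SD
    floored at the observed minimum.  SE/t are computed only when a model
    supplies the coefficient (co)variances, and omitted otherwise.
    """
    if source is None:
        spec = load_published_models()
    elif isinstance(source, Mapping):
        spec = dict(source)
    else:
        spec = json.loads(Path(source).read_text(encoding="utf-8"))
    mod = spec.get("moderator") or {}
    if not {"mean", "sd"}.issubset(mod):
        raise PipelineError("coefficient file lacks moderator moments (mean, sd)")
    mean, sd = float(mod["mean"]), float(mod["sd"])
    mn = float(mod.get("min", mean - sd))
    n = int(mod.get("n", 0)) or None
    high_raw = mean + sd
    low_raw = max(mean - sd, mn)
    rows = []
    for emo, m in spec["models"].items():
        b1, b3 = float(m["b1"]), float(m["b3"])
        for label, raw in (("high (M+1SD)", high_raw), ("low", low_raw)):
            z = zscore_with(raw, mean, sd)
            slope = b1 + b3 * z
            se = t = p = None
            if {"var_b1", "var_b3", "cov_b1_b3"}.issubset(m) and n and n > 4:
                var = m["var_b1"] + z * z * m["var_b3"] + 2 * z * m["cov_b1_b3"]
                if var >= 0:
                    from scipy import stats as sps

                    se = float(np.sqrt(var))
                    t = slope / se if se > 0 else None
                    p = float(2 * sps.t.sf(abs(t), df=n - 4)) if t is not None else None
            rows.append(
                {"emotion": emo, "level": label, "moderator_raw": raw,
                 "moderator_z": z, "slope": slope, "se": se, "t": t, "p": p}
            )
    return pd.DataFrame(rows)
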