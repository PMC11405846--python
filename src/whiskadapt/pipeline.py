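"""End-to-end orchestration: inclusion filters, report generation, recovery.

``run_pipeline`` takes a session (tables from disk or a generated
:class:`~whiskadapt.synthetic.Session`), screens units for touch
responsiveness, applies the session-inclusion criteria (enough Go trials
and responsive units), and writes the full report bundle: touch
statistics, per-order responses and normalised attenuation, ROC
discriminability, tuning curves, the attenuation decomposition (alpha),
whisker-specific adaptation (index I), and a machine-readable summary
carrying a provenance block (config hash, seed, code version).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import (
    attenuation_from_touches,
    fit_tuning_curve,
    per_order_prediction_ratio,
    wsa_analysis,
)
from .neural_metrics import (
    is_touch_responsive,
    noise_window_starts,
    per_order_mean_counts,
    roc_auc,
    window_counts,
)
from .synthetic import Session, SessionConfig, generate_session, implied_alpha
from .touch_events import select_wsa_trials, touch_statistics

__all__ = [
    "PipelineConfig",
    "InclusionResult",
    "include_session",
    "run_pipeline",
    "recovery_experiment",
]


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults follow the standard protocol."""

    response_window_ms: float = 30.0
    strength_window_ms: float = 5.0
    later_threshold: int = 2        # "later touch" = order >= this
    wsa_later_threshold: int = 3    # adapted-state fit for the WSA analysis
    asymptote_min_order: int = 5    # adapted asymptote = order > 4
    outlier_fraction: float = 0.05
    n_bins: int = 4
    min_go_trials: int = 40
    min_responsive_units: int = 2
    max_order: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.response_window_ms <= 0 or self.strength_window_ms <= 0:
            raise ValueError("windows must be positive")
        if not 0.0 < self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data.get("pipeline", data))
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InclusionResult:
    """Session-inclusion decision with itemised reasons."""

    include: bool
    reasons: list[str]
    n_go_trials: int
    n_responsive_units: int


def include_session(
    trials: pd.DataFrame,
    responsive_units: int,
    config: PipelineConfig,
) -> InclusionResult:
    """Apply the session-inclusion criteria: enough Go trials and enough
    touch-responsive single units."""
    n_go = int((trials["kind"] == "go").sum())
    reasons = []
    if n_go < config.min_go_trials:
        reasons.append("min_go_trials")
    if responsive_units < config.min_responsive_units:
        reasons.append("min_units")
    return InclusionResult(
        include=not reasons,
        reasons=reasons,
        n_go_trials=n_go,
        n_responsive_units=int(responsive_units),
    )


def _log(stage: str, t0: float) -> None:
    print(f"[whiskadapt] {stage}: {time.perf_counter() - t0:.2f}s",
          file=sys.stderr)


def _config_hash(*dicts) -> str:
    blob = json.dumps(dicts, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _count_matrix(session: Session, config: PipelineConfig):
    """Per-touch per-unit counts plus responsiveness screening.

    Prefers spike trains (counts measured in the response window, includes
    background activity); falls back to the session's count table when no
    spike data is present, in which case responsiveness reduces to a
    nonzero mean evoked count.
    """
    touches = session.touches
    onsets = touches["onset_ms"].to_numpy(dtype=float)
    trains = session.spike_trains()
    if trains:
        cm = pd.DataFrame(
            {
                tr.unit_id: window_counts(
                    tr, onsets, config.response_window_ms
                )
                for tr in trains
            }
        )
        resp = {
            tr.unit_id: is_touch_responsive(
                tr, onsets, config.response_window_ms
            )
            for tr in trains
        }
        responsive = [u for u, r in resp.items() if r.responsive]
        resp_table = pd.DataFrame(
            {
                "unit_id": list(resp),
                "responsive": [r.responsive for r in resp.values()],
                "effect": [r.effect for r in resp.values()],
                "p_value": [r.p_value for r in resp.values()],
                "n_touches": [r.n_touches for r in resp.values()],
            }
        )
        return cm, responsive, resp_table, trains
    cm = session.count_matrix()
    responsive = [u for u in cm.columns if cm[u].mean() > 0]
    resp_table = pd.DataFrame(
        {
            "unit_id": list(cm.columns),
            "responsive": [u in responsive for u in cm.columns],
            "effect": [float(cm[u].mean()) for u in cm.columns],
            "p_value": np.nan,
            "n_touches": len(cm),
        }
    )
    return cm, responsive, resp_table, []


def _roc_table(session, trains, config) -> pd.DataFrame:
    """Per-unit AUC of touch detection, first vs later x hit vs miss.

    Noise windows tile the touch-free periods of each Go trial (before the
    first touch, anchored at pole presentation, and inter-touch gaps);
    all available non-overlapping windows are used, deterministically.
    """
    touches = session.touches
    trials = session.trials
    outcome = trials.set_index("trial_id")["outcome"]
    rows = []
    win = config.response_window_ms
    sig = {("first", "hit"): [], ("first", "miss"): [],
           ("later", "hit"): [], ("later", "miss"): []}
    noi = {("first", "hit"): [], ("first", "miss"): [],
           ("later", "hit"): [], ("later", "miss"): []}
    for trial, g in touches.groupby("trial_id"):
        oc = outcome.loc[trial]
        if oc not in ("hit", "miss"):
            continue
        onsets = np.sort(g["onset_ms"].to_numpy(dtype=float))
        anchor = float(
            trials.loc[trials["trial_id"] == trial, "pole_up_ms"].iloc[0]
        )
        first_noise, later_noise = noise_window_starts(anchor, onsets, win)
        sig[("first", oc)].append(onsets[:1])
        sig[("later", oc)].append(onsets[1:])
        noi[("first", oc)].extend(first_noise)
        noi[("later", oc)].extend(later_noise)
    for tr in trains:
        for (cls, oc), onset_list in sig.items():
            onsets = (
                np.concatenate(onset_list) if onset_list else np.array([])
            )
            starts = np.asarray(noi[(cls, oc)], dtype=float)
            if len(onsets) == 0 or len(starts) == 0:
                auc = np.nan
            else:
                auc = roc_auc(
                    window_counts(tr, onsets, win),
                    window_counts(tr, starts, win),
                )
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "touch_class": cls,
                    "outcome": oc,
                    "auc": auc,
                    "n_signal": len(onsets),
                    "n_noise": len(starts),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(session: Session, config: PipelineConfig, out_dir) -> dict:
    """Run all analysis stages on one session and write the report bundle.

    Deterministic and idempotent: identical inputs yield byte-identical
    reports.  Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    trials, touches = session.trials, session.touches

    cm, responsive, resp_table, trains = _count_matrix(session, config)
    resp_table.to_csv(out / "responsiveness.csv", index=False)
    inclusion = include_session(trials, len(responsive), config)
    _log("screening", t0)

    summary: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(
                config.to_dict(),
                session.config.to_dict() if session.config else {},
            ),
        },
        "session_id": session.session_id,
        "thresholds": {
            "later_threshold": config.later_threshold,
            "wsa_later_threshold": config.wsa_later_threshold,
            "asymptote_min_order": config.asymptote_min_order,
        },
        "inclusion": asdict(inclusion),
    }

    stats = touch_statistics(trials, touches)
    stats.summary().to_csv(out / "touch_stats.csv")
    stats.by_outcome.to_csv(out / "touch_stats_by_outcome.csv")
    summary["touch_stats"] = {
        "n_touches": int(len(touches)),
        "mean_touches_per_trial": float(stats.touches_per_trial.mean()),
        "by_outcome": stats.by_outcome.to_dict(orient="index"),
    }
    _log("touch statistics", t0)

    if not inclusion.include:
        summary["note"] = "session excluded; analyses skipped"
        _write_summary(summary, out)
        return summary

    orders = touches["order"].to_numpy()
    # per-order responses and normalised attenuation (per unit)
    att_rows = []
    for unit in cm.columns:
        means = per_order_mean_counts(
            cm[unit].to_numpy(float), orders, config.max_order
        )
        row = {"unit_id": unit}
        row.update(
            {f"order_{k + 1}": means[k] for k in range(config.max_order)}
        )
        if np.isfinite(means[0]) and means[0] > 0:
            row.update(
                {
                    f"norm_{k + 1}": means[k] / means[0]
                    for k in range(config.max_order)
                }
            )
        att_rows.append(row)
    pd.DataFrame(att_rows).to_csv(out / "attenuation.csv", index=False)
    _log("attenuation curves", t0)

    if trains:
        _roc_table(session, trains, config).to_csv(
            out / "roc.csv", index=False
        )
        _log("roc", t0)

    # per-unit tuning curves per touch-order class
    tc_rows = []
    abs_strength = touches["strength"].abs().to_numpy(dtype=float)
    classes = [(str(k), orders == k) for k in range(1, 5)]
    classes.append(
        (f"later(>={config.later_threshold})", orders >= config.later_threshold)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for unit in cm.columns:
            c = cm[unit].to_numpy(dtype=float)
            for label, mask in classes:
                if mask.sum() < config.n_bins:
                    continue
                tc = fit_tuning_curve(
                    abs_strength[mask], c[mask], label,
                    n_bins=config.n_bins,
                    outlier_fraction=config.outlier_fraction,
                )
                row = {
                    "unit_id": unit,
                    "order_label": label,
                    "slope": tc.slope,
                    "intercept": tc.intercept,
                    "n_samples": tc.n_samples,
                    "degenerate": tc.degenerate,
                }
                row.update(
                    {
                        f"bin{b}_strength": tc.bin_mean_strength[b]
                        for b in range(config.n_bins)
                    }
                )
                row.update(
                    {
                        f"bin{b}_count": tc.bin_mean_count[b]
                        for b in range(config.n_bins)
                    }
                )
                tc_rows.append(row)
    pd.DataFrame(tc_rows).to_csv(out / "tuning_curves.csv", index=False)
    _log("tuning curves", t0)

    # attenuation decomposition on the population response
    pop = cm.sum(axis=1).to_numpy(dtype=float)
    alpha_res = attenuation_from_touches(
        touches, pop,
        later_threshold=config.later_threshold,
        n_bins=config.n_bins,
        outlier_fraction=config.outlier_fraction,
    )
    pd.DataFrame(
        [
            {
                "session_id": session.session_id,
                "FR1": alpha_res.fr1,
                "FR_later": alpha_res.fr_later,
                "FR1_pred": alpha_res.fr1_pred,
                "alpha": alpha_res.alpha,
            }
        ]
    ).to_csv(out / "alpha.csv", index=False)
    summary["alpha"] = {
        "FR1": alpha_res.fr1,
        "FR_later": alpha_res.fr_later,
        "FR1_pred": alpha_res.fr1_pred,
        "alpha": alpha_res.alpha,
    }
    _log("alpha", t0)

    # adapted-asymptote prediction ratios (population response)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios = per_order_prediction_ratio(
                touches["strength"].to_numpy(float), pop, orders,
                fit_min_order=config.asymptote_min_order,
                max_order=config.max_order,
                n_bins=config.n_bins,
                outlier_fraction=config.outlier_fraction,
            )
        summary["prediction_ratio_by_order"] = {
            str(k): v for k, v in ratios.items()
        }
    except ValueError:
        summary["prediction_ratio_by_order"] = {}

    # whisker-specific adaptation
    selections = select_wsa_trials(trials, touches)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wsa_results = wsa_analysis(
            touches, cm, selections,
            later_min_order=config.wsa_later_threshold,
            n_bins=config.n_bins,
            outlier_fraction=config.outlier_fraction,
        )
    wsa_df = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "FR_test": r.fr_test,
                "FR_predicted": r.fr_predicted,
                "I": r.index,
                "n_test": r.n_test,
            }
            for r in wsa_results
        ]
    )
    wsa_df.to_csv(out / "wsa.csv", index=False)
    idx = wsa_df["I"].to_numpy(dtype=float) if len(wsa_df) else np.array([])
    summary["wsa"] = {
        "n_selected_trials": len(selections),
        "n_units": int(len(wsa_df)),
        "mean_index": float(np.nanmean(idx)) if len(idx) else None,
        "frac_positive": (
            float(np.mean(idx > 0)) if len(idx) else None
        ),
    }
    if not selections:
        summary["wsa"]["note"] = "no eligible trials"
    _log("wsa", t0)

    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=str) + "\n"
    )


def recovery_experiment(
    seeds,
    base_config: SessionConfig,
    later_threshold: int = 2,
    n_bins: int = 4,
    outlier_fraction: float = 0.05,
) -> pd.DataFrame:
    """Parameter recovery across seeds: intercept ratio and alpha.

    For each seed, a session is generated from ``base_config`` and the
    injected quantities are re-estimated from the evoked count table:
    the later/first tuning intercept ratio from population tuning curves,
    and alpha from the attenuation decomposition, alongside the
    closed-form implied alpha of the generative model.
    """
    rows = []
    for seed in seeds:
        cfg = replace(base_config, seed=int(seed))
        sess = generate_session(cfg)
        touches = sess.touches
        pop = sess.count_matrix().sum(axis=1).to_numpy(dtype=float)
        orders = touches["order"].to_numpy()
        strengths = touches["strength"].abs().to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tc_first = fit_tuning_curve(
                strengths[orders == 1], pop[orders == 1], "first",
                n_bins=n_bins, outlier_fraction=outlier_fraction,
            )
            tc_later = fit_tuning_curve(
                strengths[orders >= later_threshold],
                pop[orders >= later_threshold],
                "later", n_bins=n_bins, outlier_fraction=outlier_fraction,
            )
            res = attenuation_from_touches(
                touches, pop, later_threshold=later_threshold,
                n_bins=n_bins, outlier_fraction=outlier_fraction,
            )
        gt = sess.ground_truth
        rows.append(
            {
                "seed": int(seed),
                "intercept_first": tc_first.intercept,
                "intercept_later": tc_later.intercept,
                "intercept_ratio": tc_later.intercept / tc_first.intercept,
                "true_intercept_ratio": cfg.sa_intercept_ratio,
                "slope_ratio": tc_later.slope / tc_first.slope,
                "alpha": res.alpha,
                "implied_alpha": (
                    gt.implied_alpha if gt is not None
                    else implied_alpha(cfg)
                ),
                "n_touches": len(touches),
            }
        )
    return pd.DataFrame(rows)
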