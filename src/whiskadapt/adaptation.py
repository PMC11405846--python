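"""Tuning curves, attenuation decomposition (alpha) and whisker-specific
adaptation (index I).

Core analysis: spike counts are linearly tuned to touch strength
``|delta kappa_3D|``.  Per touch order, a tuning curve is fitted by OLS to
the mean spike count in 4 equipopulated strength bins (the 5% of touches
with largest absolute strength are first discarded as outliers).  Feeding
first-touch strengths through the *later*-touch tuning curve predicts what
the first-touch response would have been had the neurons already been in
the adapted state; comparing this prediction with the observed responses
separates sensory adaptation (changed neuronal sensitivity) from motor
adaptation (weaker touches):

    alpha = (FR_1 - FR_1') / (FR_1 - FR_later)

where FR_1 / FR_later are the median observed population responses to
first / later touches and FR_1' is the median prediction.  alpha = 0 means
the attenuation is fully explained by weaker touches; alpha = 1 means it is
fully explained by a change in sensitivity.

Whisker-specific adaptation is quantified per unit as

    I = (FR_test - FR_predicted) / (FR_test + FR_predicted)

where FR_test is the mean response to "test" touches (first touch of a
previously untouched whisker after another whisker adapted the circuit) and
FR_predicted is the response predicted for those touch strengths by the
test whisker's adapted-state tuning curve (test touches excluded from the
fit).  I > 0 indicates that adaptation is specific to the adapting whisker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .touch_events import WsaSelection

__all__ = [
    "TuningCurve",
    "AlphaResult",
    "WsaResult",
    "filter_outliers",
    "equipopulated_bins",
    "fit_tuning_curve",
    "predict_response",
    "loo_predictions",
    "per_order_prediction_ratio",
    "alpha_index",
    "attenuation_decomposition",
    "attenuation_from_touches",
    "wsa_index",
    "wsa_analysis",
]


@dataclass
class TuningCurve:
    """Linear response model: spike count vs touch strength, one order class.

    ``slope`` has units of counts per (1/mm); ``intercept`` is counts at
    zero strength.  ``degenerate`` marks fits where all strengths (or all
    bin means) coincide; the slope is then undefined (NaN) and the
    intercept is the mean count.
    """

    order_label: str
    bin_edges: np.ndarray
    bin_mean_strength: np.ndarray
    bin_mean_count: np.ndarray
    slope: float
    intercept: float
    n_samples: int
    degenerate: bool = False

    def predict(self, strengths) -> np.ndarray:
        return predict_response(self, strengths)


def filter_outliers(
    strengths, fraction: float = 0.05, min_n: int = 20
) -> np.ndarray:
    """Indices retained after discarding the strongest-|strength| outliers.

    Removes the ``ceil(fraction * n)`` samples of largest absolute value;
    the rest are returned as sorted (original-order) indices.  Ties are
    broken by index: among equal values the last ones are removed.  Inputs
    with fewer than ``min_n`` samples are returned unfiltered with a
    warning.
    """
    s = np.abs(np.asarray(strengths, dtype=float))
    n = len(s)
    if n < min_n:
        warnings.warn(
            f"only {n} touches (< {min_n}); outlier filter not applied"
        )
        return np.arange(n)
    n_remove = int(np.ceil(fraction * n))
    order = np.argsort(s, kind="stable")
    return np.sort(order[: n - n_remove])


def equipopulated_bins(
    values, n_bins: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Discretise values into ``n_bins`` equipopulated bins.

    Assignment is by sorted rank (stable over duplicates), so bin counts
    differ by at most 1 even with ties spanning a quantile.  Returns
    ``(edges, assignment)`` with edges at empirical quantiles.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values; got {n}")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    assignment = (ranks * n_bins) // n
    edges = np.quantile(v, np.linspace(0.0, 1.0, n_bins + 1))
    return edges, assignment


def fit_tuning_curve(
    strengths,
    counts,
    order_label: str = "later",
    n_bins: int = 4,
    outlier_fraction: float = 0.05,
    apply_outlier_filter: bool = True,
) -> TuningCurve:
    """Fit a linear tuning curve on equipopulated bin means.

    After optional outlier filtering, strengths are discretised into
    ``n_bins`` equipopulated bins and an OLS line is fitted to the
    (bin mean strength, bin mean count) points; fitting on bin means rather
    than raw samples follows the standard tuning-curve recipe (raw-sample
    OLS can be emulated by passing ``n_bins = len(strengths)``).
    All-equal strengths give a degenerate curve (slope NaN, intercept =
    mean count) with a warning.
    """
    s = np.asarray(strengths, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(s) != len(c):
        raise ValueError("strengths and counts must have equal length")
    if apply_outlier_filter:
        keep = filter_outliers(s, outlier_fraction)
        s, c = s[keep], c[keep]
    if len(s) < n_bins:
        raise ValueError(
            f"need at least {n_bins} samples after filtering; got {len(s)}"
        )
    edges, assignment = equipopulated_bins(s, n_bins)
    bin_s = np.array([s[assignment == b].mean() for b in range(n_bins)])
    bin_c = np.array([c[assignment == b].mean() for b in range(n_bins)])
    if np.ptp(bin_s) <= 1e-12 * max(1.0, float(np.abs(bin_s).max())):
        warnings.warn(
            f"all touch strengths identical in {order_label!r} fit; "
            "slope undefined, intercept set to mean count"
        )
        return TuningCurve(
            order_label, edges, bin_s, bin_c,
            slope=float("nan"), intercept=float(c.mean()),
            n_samples=len(s), degenerate=True,
        )
    slope, intercept = np.polyfit(bin_s, bin_c, 1)
    return TuningCurve(
        order_label, edges, bin_s, bin_c,
        slope=float(slope), intercept=float(intercept),
        n_samples=len(s),
    )


def predict_response(tc: TuningCurve, strengths) -> np.ndarray:
    """Predicted spike counts ``slope * strength + intercept``, floored at 0.

    Negative firing is unphysical, so extrapolations below zero are clipped.
    A degenerate curve yields a constant prediction (its intercept) with a
    warning.
    """
    s = np.asarray(strengths, dtype=float)
    if tc.degenerate or not np.isfinite(tc.slope):
        warnings.warn(
            f"tuning slope undefined for {tc.order_label!r}; "
            "constant prediction"
        )
        pred = np.full(s.shape, tc.intercept, dtype=float)
    else:
        pred = tc.slope * s + tc.intercept
    return np.maximum(pred, 0.0)


def loo_predictions(
    strengths, counts, order_label: str = "later", **fit_kwargs
) -> np.ndarray:
    """Leave-one-out predictions within a fit set.

    Each sample is predicted from a tuning curve refitted without it,
    including re-application of the outlier filter and re-binning, so a
    queried touch never contributes to the curve that predicts it.
    """
    s = np.asarray(strengths, dtype=float)
    c = np.asarray(counts, dtype=float)
    out = np.empty(len(s))
    idx = np.arange(len(s))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(s)):
            mask = idx != i
            tc = fit_tuning_curve(s[mask], c[mask], order_label, **fit_kwargs)
            out[i] = predict_response(tc, s[i : i + 1])[0]
    return out


def per_order_prediction_ratio(
    strengths,
    counts,
    orders,
    fit_min_order: int = 5,
    max_order: int = 8,
    **fit_kwargs,
) -> dict[int, float]:
    """Ratio of adapted-state-predicted to observed mean response per order.

    A tuning curve is fitted on touches of order >= ``fit_min_order``
    (the asymptotically adapted state); every touch is then predicted from
    it, with leave-one-out refits for touches inside the fit set.  The
    per-order ratio mean(predicted)/mean(observed) converges towards 1 as
    the response adapts.
    """
    s = np.abs(np.asarray(strengths, dtype=float))
    c = np.asarray(counts, dtype=float)
    orders = np.asarray(orders)
    fit_mask = orders >= fit_min_order
    if fit_mask.sum() < 4:
        raise ValueError(
            f"fewer than 4 touches with order >= {fit_min_order}"
        )
    tc = fit_tuning_curve(
        s[fit_mask], c[fit_mask], f"order>={fit_min_order}", **fit_kwargs
    )
    pred = np.empty(len(s))
    pred[~fit_mask] = predict_response(tc, s[~fit_mask])
    pred[fit_mask] = loo_predictions(
        s[fit_mask], c[fit_mask], f"order>={fit_min_order}", **fit_kwargs
    )
    ratios: dict[int, float] = {}
    for k in range(1, max_order + 1):
        mask = orders == k
        if mask.any() and c[mask].mean() > 0:
            ratios[k] = float(pred[mask].mean() / c[mask].mean())
    return ratios


def alpha_index(fr1: float, fr1_pred: float, fr_later: float) -> float:
    """Fraction of first-to-later attenuation attributable to sensory
    adaptation: ``(FR_1 - FR_1') / (FR_1 - FR_later)``.

    0 means no sensory-adaptation contribution (the later-touch tuning
    already accounts for the first-touch response); 1 means the attenuation
    is entirely a sensitivity change.  Undefined (NaN, with a warning) when
    there is no attenuation (FR_1 == FR_later).
    """
    if fr1 == fr_later:
        warnings.warn("no attenuation (FR1 == FR_later); alpha undefined")
        return float("nan")
    return (fr1 - fr1_pred) / (fr1 - fr_later)


@dataclass
class AlphaResult:
    """Attenuation decomposition of one population's touch responses."""

    fr1: float        # median population response to first touch
    fr_later: float   # median population response to later touch
    fr1_pred: float   # median later-tuning prediction at first-touch strengths
    alpha: float
    tuning: TuningCurve | None = None


def attenuation_decomposition(
    first_strengths,
    first_responses,
    later_strengths,
    later_responses,
    n_bins: int = 4,
    outlier_fraction: float = 0.05,
) -> AlphaResult:
    """Decompose first-to-later response attenuation into motor vs sensory.

    Medians (robust to count outliers) of the observed population responses
    give FR_1 and FR_later; the later-touch tuning curve (fitted on
    ``|strength|`` of later touches) evaluated at the first-touch strengths
    gives FR_1'; alpha follows from :func:`alpha_index`.  First touches do
    not contribute to the later-touch fit, so no cross-validation exclusion
    is needed here.
    """
    fs = np.abs(np.asarray(first_strengths, dtype=float))
    fr = np.asarray(first_responses, dtype=float)
    ls = np.abs(np.asarray(later_strengths, dtype=float))
    lr = np.asarray(later_responses, dtype=float)
    if len(fs) < 1:
        raise ValueError("need at least one first touch")
    if len(fs) != len(fr) or len(ls) != len(lr):
        raise ValueError("strengths and responses must have equal length")
    tc = fit_tuning_curve(
        ls, lr, "later", n_bins=n_bins, outlier_fraction=outlier_fraction
    )
    fr1 = float(np.median(fr))
    fr_later = float(np.median(lr))
    fr1_pred = float(np.median(predict_response(tc, fs)))
    return AlphaResult(
        fr1=fr1,
        fr_later=fr_later,
        fr1_pred=fr1_pred,
        alpha=alpha_index(fr1, fr1_pred, fr_later),
        tuning=tc,
    )


def attenuation_from_touches(
    touches: pd.DataFrame,
    pop_responses,
    later_threshold: int = 2,
    n_bins: int = 4,
    outlier_fraction: float = 0.05,
) -> AlphaResult:
    """:func:`attenuation_decomposition` driven by an ordered touches table.

    ``pop_responses`` must be aligned row-for-row with ``touches``.
    "Later" touches are those with order >= ``later_threshold``.
    """
    orders = touches["order"].to_numpy()
    strengths = touches["strength"].to_numpy(dtype=float)
    resp = np.asarray(pop_responses, dtype=float)
    if len(resp) != len(touches):
        raise ValueError("pop_responses must align with touches rows")
    first = orders == 1
    later = orders >= later_threshold
    return attenuation_decomposition(
        strengths[first], resp[first], strengths[later], resp[later],
        n_bins=n_bins, outlier_fraction=outlier_fraction,
    )


def wsa_index(fr_test: float, fr_predicted: float) -> float:
    """Whisker-specific adaptation index
    ``I = (FR_test - FR_predicted) / (FR_test + FR_predicted)``.

    Zero when adaptation spreads across whiskers; positive when the test
    whisker evokes an unadapted response.  Bounded in [-1, 1] for
    non-negative rates; undefined (NaN) when the denominator is not
    positive.
    """
    denom = fr_test + fr_predicted
    if denom <= 0:
        warnings.warn("FR_test + FR_predicted <= 0; WSA index undefined")
        return float("nan")
    return (fr_test - fr_predicted) / denom


@dataclass
class WsaResult:
    """Whisker-specific adaptation outcome for one unit."""

    unit_id: str
    fr_test: float
    fr_predicted: float
    index: float
    n_test: int


def wsa_analysis(
    touches: pd.DataFrame,
    count_matrix: pd.DataFrame,
    selections: list[WsaSelection],
    later_min_order: int = 3,
    n_bins: int = 4,
    outlier_fraction: float = 0.05,
) -> list[WsaResult]:
    """Per-unit whisker-specific adaptation indices.

    ``count_matrix`` holds one column per unit with rows aligned to
    ``touches``.  For each unit, the test whisker's adapted-state tuning
    curve is fitted on that whisker's touches of order >=
    ``later_min_order`` pooled over all trials of the session, excluding
    the test touches themselves (cross-validation), and evaluated at the
    test touches' absolute strengths.  Returns an empty list when no trial
    qualifies.
    """
    if len(count_matrix) != len(touches):
        raise ValueError("count_matrix rows must align with touches rows")
    if not selections:
        return []
    key = {
        (row.trial_id, row.order): i
        for i, row in enumerate(touches.itertuples(index=False))
    }
    test_idx = np.array(
        sorted(
            key[(sel.trial_id, order)]
            for sel in selections
            for order in sel.test_orders
        ),
        dtype=int,
    )
    abs_strength = touches["strength"].abs().to_numpy(dtype=float)
    whisker = touches["whisker_id"].to_numpy()
    orders = touches["order"].to_numpy()
    in_test = np.zeros(len(touches), dtype=bool)
    in_test[test_idx] = True
    results = []
    for unit in count_matrix.columns:
        c = count_matrix[unit].to_numpy(dtype=float)
        pred = np.full(len(test_idx), np.nan)
        for w in np.unique(whisker[test_idx]):
            sel_rows = np.flatnonzero(whisker[test_idx] == w)
            fit_mask = (
                (whisker == w) & (orders >= later_min_order) & ~in_test
            )
            if fit_mask.sum() < n_bins:
                continue
            tc = fit_tuning_curve(
                abs_strength[fit_mask],
                c[fit_mask],
                f"{w} order>={later_min_order}",
                n_bins=n_bins,
                outlier_fraction=outlier_fraction,
            )
            pred[sel_rows] = predict_response(
                tc, abs_strength[test_idx[sel_rows]]
            )
        valid = np.isfinite(pred)
        if not valid.any():
            continue
        fr_test = float(c[test_idx[valid]].mean())
        fr_pred = float(pred[valid].mean())
        results.append(
            WsaResult(
                unit_id=str(unit),
                fr_test=fr_test,
                fr_predicted=fr_pred,
                index=wsa_index(fr_test, fr_pred),
                n_test=int(valid.sum()),
            )
        )
    return results
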