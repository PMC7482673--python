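"""Flagging features that deviate from a reference condition.

Two complementary screens are provided, matching two study scales.  For
small-N exploratory designs, a percentile over-representation analysis
(ORA): the reference group's feature distributions are bootstrap-resampled
and a group is called *over* when its lower percentile (25th, or 10th under
the conservative rule) exceeds the reference's 95th percentile, *under*
when its upper percentile (75th/90th) falls below the reference's 5th.
For larger-N designs, a bootstrap test of the group-vs-reference median
difference with a two-sided p-value.  Quantiles use linear interpolation
(type 7), which matters at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import PhenoplastError
from .features import FeatureTable

ORA_RULES = {"p25_75": (0.25, 0.75), "p10_90": (0.10, 0.90)}


@dataclass
class ComparisonResult:
    """Per (group × feature) calls from ORA or bootstrap comparison."""

    calls: pd.DataFrame  # groups x features, strings
    p_values: pd.DataFrame | None  # bootstrap only
    reference: str
    params: dict


def _group_values(features: FeatureTable, group_field: str, label: str) -> np.ndarray:
    block = features.data[features.data[group_field].astype(str) == str(label)]
    if block.empty:
        raise PhenoplastError(f"empty group: {label!r}")
    return block[features.feature_names].to_numpy(dtype=float)


def reference_bounds(
    ref_values: np.ndarray,
    n_sims: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap 5th/95th percentile bounds of each reference feature.

    Reference rows are resampled with replacement ``n_sims`` times; the
    resampled values are pooled and the pooled 5th and 95th percentiles
    (linear interpolation) reported per feature.
    """
    values = np.asarray(ref_values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, m = values.shape
    if n < 3:
        raise PhenoplastError(f"need at least 3 reference samples, got {n}")
    rng = np.random.default_rng(seed)
    bounds = np.empty((m, 2))
    for j in range(m):
        col = values[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise PhenoplastError(f"reference feature column {j} is all-missing")
        pooled = rng.choice(col, size=(n_sims, col.size), replace=True).ravel()
        bounds[j] = np.quantile(pooled, [0.05, 0.95])
    return pd.DataFrame(bounds, columns=["q05", "q95"])


def ora_classify(
    group_values: np.ndarray,
    bounds: pd.DataFrame,
    rule: str = "p25_75",
) -> list[str]:
    """Percentile calls per feature: over / under / none.

    over  ⇔ group's lower percentile > reference q95
    under ⇔ group's upper percentile < reference q05
    """
    if rule not in ORA_RULES:
        raise PhenoplastError(f"unknown ORA rule: {rule}")
    lo_q, hi_q = ORA_RULES[rule]
    values = np.asarray(group_values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 2:
        warnings.warn("group has a single sample; percentiles collapse to that value")
    calls = []
    for j in range(values.shape[1]):
        col = values[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            calls.append("none")
            continue
        lo, hi = np.quantile(col, [lo_q, hi_q])
        if lo > bounds.iloc[j]["q95"]:
            calls.append("over")
        elif hi < bounds.iloc[j]["q05"]:
            calls.append("under")
        else:
            calls.append("none")
    return calls


def ora_compare(
    features: FeatureTable,
    group_field: str,
    reference_label: str,
    rule: str = "p25_75",
    n_sims: int = 10_000,
    seed: int = 0,
    group_order: list[str] | None = None,
) -> ComparisonResult:
    """ORA of every non-reference group against the reference bounds."""
    ref = _group_values(features, group_field, reference_label)
    bounds = reference_bounds(ref, n_sims=n_sims, seed=seed)
    labels = group_order or [
        g for g in features.data[group_field].astype(str).unique()
        if g != str(reference_label)
    ]
    rows = {}
    for label in labels:
        rows[label] = ora_classify(_group_values(features, group_field, label), bounds, rule)
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=features.feature_names)
    return ComparisonResult(
        calls=calls,
        p_values=None,
        reference=str(reference_label),
        params={"rule": rule, "n_sims": n_sims, "seed": seed},
    )


def bootstrap_compare(
    features: FeatureTable,
    group_field: str,
    reference_label: str,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "median",
    group_order: list[str] | None = None,
) -> ComparisonResult:
    """Bootstrap test of each group's feature medians against the reference.

    For each (group, feature): resample both groups with replacement
    ``n_boot`` times, form the difference of group statistics (group −
    reference), and compute the two-sided p-value
    2·min(P(diff* ≤ 0), P(diff* ≥ 0)) with a +1/(n_boot+1) continuity
    correction.  Calls are ``greater``/``less`` when p < alpha, signed by
    the observed difference, else ``none``.
    """
    if statistic not in ("median", "mean"):
        raise PhenoplastError(f"unknown statistic: {statistic}")
    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} < 1000: p-values will be unstable")
    stat = np.median if statistic == "median" else np.mean
    ref = _group_values(features, group_field, reference_label)
    if ref.shape[0] < 3:
        raise PhenoplastError("reference group needs at least 3 samples")
    labels = group_order or [
        g for g in features.data[group_field].astype(str).unique()
        if g != str(reference_label)
    ]
    rng = np.random.default_rng(seed)
    names = features.feature_names
    calls = pd.DataFrame("none", index=labels, columns=names)
    pvals = pd.DataFrame(np.nan, index=labels, columns=names)
    for label in labels:
        grp = _group_values(features, group_field, label)
        if grp.shape[0] < 3:
            raise PhenoplastError(f"group {label!r} needs at least 3 samples")
        for j, name in enumerate(names):
            g = grp[:, j]
            r = ref[:, j]
            g = g[np.isfinite(g)]
            r = r[np.isfinite(r)]
            if g.size < 3 or r.size < 3:
                continue
            g_star = rng.choice(g, size=(n_boot, g.size), replace=True)
            r_star = rng.choice(r, size=(n_boot, r.size), replace=True)
            diff = stat(g_star, axis=1) - stat(r_star, axis=1)
            p_le = (np.count_nonzero(diff <= 0) + 1) / (n_boot + 1)
            p_ge = (np.count_nonzero(diff >= 0) + 1) / (n_boot + 1)
            p = min(1.0, 2.0 * min(p_le, p_ge))
            pvals.loc[label, name] = p
            if p < alpha:
                observed = stat(g) - stat(r)
                calls.loc[label, name] = "greater" if observed > 0 else "less"
    return ComparisonResult(
        calls=calls,
        p_values=pvals,
        reference=str(reference_label),
        params={
            "n_boot": n_boot,
            "alpha": alpha,
            "seed": seed,
            "statistic": statistic,
        },
    )
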