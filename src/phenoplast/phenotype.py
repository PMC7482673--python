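"""Phenotype profiles: group medians and their color-coded bar stack.

A plasticity phenotype is the ordered vector of per-group feature medians,
displayed as a stack of horizontal bars — a gray ramp for the sum features
and a diverging red–yellow–green map for the bounded indices (yellow is
anchored at 0, i.e. at excitatory/inhibitory balance).  In ``absolute``
mode every profile passed in one call shares a single color scale, which is
what makes phenotypes comparable across datasets (e.g. two species); in
``local`` mode each profile is scaled on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .expression_io import PhenoplastError
from .features import FeatureSpec, FeatureTable

# Diverging index anchors (overridable): red at -L, yellow at 0, green at +L.
INDEX_ANCHORS = {
    "negative": (1.0, 0.0, 0.0),
    "zero": (1.0, 1.0, 0.0),
    "positive": (0.0, 1.0, 0.0),
}
# Gray ramp for sums: white at 0 to near-black at the largest sum median.
SUM_ANCHORS = {"low": (1.0, 1.0, 1.0), "high": (0.1, 0.1, 0.1)}


@dataclass
class PhenotypeProfile:
    """Per-group feature medians plus (after colorize) an RGB matrix."""

    group_labels: list[str]
    medians: pd.DataFrame  # groups x features
    specs: list[FeatureSpec]
    colors: np.ndarray | None = None  # g x m x 3 in [0, 1]
    scale_mode: str | None = None
    group_field: str = "group"
    index_limit: float | None = None
    sum_limit: float | None = None

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def sum_columns(self) -> list[int]:
        return [i for i, s in enumerate(self.specs) if s.kind == "sum"]

    def index_columns(self) -> list[int]:
        return [i for i, s in enumerate(self.specs) if s.kind == "index"]

    def hex_colors(self) -> pd.DataFrame:
        if self.colors is None:
            raise PhenoplastError("profile not colorized yet")
        hexes = np.empty(self.colors.shape[:2], dtype=object)
        for g in range(self.colors.shape[0]):
            for m in range(self.colors.shape[1]):
                r, gg, b = (np.round(self.colors[g, m] * 255)).astype(int)
                hexes[g, m] = f"#{r:02x}{gg:02x}{b:02x}"
        return pd.DataFrame(hexes, index=self.group_labels, columns=self.feature_names)


def aggregate_profile(
    features: FeatureTable,
    group_field: str,
    group_order: list[str],
) -> PhenotypeProfile:
    """Per-group, per-feature medians (missing values excluded), rows in group_order."""
    if group_field not in features.data.columns:
        raise PhenoplastError(f"group field absent: {group_field}")
    rows = []
    for label in group_order:
        block = features.data[features.data[group_field].astype(str) == str(label)]
        if block.empty:
            raise PhenoplastError(f"empty group: {label!r}")
        rows.append(block[features.feature_names].median(skipna=True))
    medians = pd.DataFrame(rows, index=list(map(str, group_order)))
    unknown = set(features.data[group_field].astype(str)) - set(medians.index)
    if unknown:
        raise PhenoplastError(f"samples with group labels outside group_order: {sorted(unknown)}")
    return PhenotypeProfile(
        group_labels=list(map(str, group_order)),
        medians=medians,
        specs=list(features.specs),
        group_field=group_field,
    )


def _lerp(c0, c1, t: float) -> np.ndarray:
    return (1 - t) * np.asarray(c0) + t * np.asarray(c1)


def _index_color(value: float, limit: float) -> np.ndarray:
    if not np.isfinite(value) or limit == 0:
        return np.asarray(INDEX_ANCHORS["zero"])
    t = float(np.clip(value / limit, -1.0, 1.0))
    if t >= 0:
        return _lerp(INDEX_ANCHORS["zero"], INDEX_ANCHORS["positive"], t)
    return _lerp(INDEX_ANCHORS["zero"], INDEX_ANCHORS["negative"], -t)


def _sum_color(value: float, limit: float) -> np.ndarray:
    if not np.isfinite(value) or limit <= 0:
        return np.asarray(SUM_ANCHORS["low"])
    t = float(np.clip(value / limit, 0.0, 1.0))
    return _lerp(SUM_ANCHORS["low"], SUM_ANCHORS["high"], t)


def colorize(profiles: list[PhenotypeProfile], mode: str = "absolute") -> list[PhenotypeProfile]:
    """Attach RGB matrices, sharing one scale across profiles in absolute mode.

    Index limit L = max |index median| over the span (all supplied profiles
    for ``absolute``, each profile alone for ``local``); the map runs
    red(−L) → yellow(0) → green(+L) with linear RGB interpolation.  Sums use
    a white→near-black ramp over [0, max sum median] of the same span.
    """
    if mode not in ("absolute", "local"):
        raise PhenoplastError(f"unknown color mode: {mode}")
    if not profiles:
        return []
    base = [s.member_key() for s in profiles[0].specs]
    for p in profiles[1:]:
        if [s.member_key() for s in p.specs] != base:
            raise PhenoplastError("profiles do not share feature specs")

    def limits(span: list[PhenotypeProfile]) -> tuple[float, float]:
        idx_vals, sum_vals = [], []
        for p in span:
            vals = p.medians.to_numpy(dtype=float)
            idx_vals.append(vals[:, p.index_columns()])
            sum_vals.append(vals[:, p.sum_columns()])
        idx = np.concatenate([v.ravel() for v in idx_vals]) if idx_vals else np.array([])
        sm = np.concatenate([v.ravel() for v in sum_vals]) if sum_vals else np.array([])
        L = float(np.nanmax(np.abs(idx))) if idx.size and np.isfinite(idx).any() else 0.0
        S = float(np.nanmax(sm)) if sm.size and np.isfinite(sm).any() else 0.0
        return L, S

    if mode == "absolute":
        shared = limits(profiles)
    for profile in profiles:
        L, S = shared if mode == "absolute" else limits([profile])
        if L == 0 and profile.index_columns():
            warnings.warn("all index medians are 0; index bars rendered all-yellow")
        vals = profile.medians.to_numpy(dtype=float)
        colors = np.zeros((*vals.shape, 3))
        for m, spec in enumerate(profile.specs):
            for g in range(vals.shape[0]):
                if spec.kind == "sum":
                    colors[g, m] = _sum_color(vals[g, m], S)
                else:
                    colors[g, m] = _index_color(vals[g, m], L)
        profile.colors = colors
        profile.scale_mode = mode
        profile.index_limit = L
        profile.sum_limit = S
    return profiles


def normalize_sums_to_reference(
    features: FeatureTable, group_field: str, reference_group: str
) -> FeatureTable:
    """Divide each sum feature by the reference group's median of that feature.

    Index features are untouched.  Used to express developmental sums
    relative to the youngest group before boxplotting.
    """
    block = features.data[features.data[group_field].astype(str) == str(reference_group)]
    if block.empty:
        raise PhenoplastError(f"empty reference group: {reference_group!r}")
    data = features.data.copy()
    for spec in features.specs:
        if spec.kind != "sum":
            continue
        ref = float(block[spec.name].median(skipna=True))
        if not np.isfinite(ref) or ref <= 0:
            raise PhenoplastError(
                f"reference median of sum {spec.name!r} must be > 0, got {ref}"
            )
        data[spec.name] = data[spec.name] / ref
    return FeatureTable(
        data=data, specs=list(features.specs), metadata_fields=list(features.metadata_fields)
    )


# ---------------------------------------------------------------------------
# Rendering


def _deterministic_savefig(fig, path) -> None:
    plt.rcParams["svg.hashsalt"] = "phenoplast"
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def render_phenotype(profiles: list[PhenotypeProfile], path, annotations=None) -> None:
    """Bar-stack figure: one row per feature (sums above indices, spec order),
    one column per group; one panel per profile.

    ``annotations`` optionally maps profile index -> {(group, feature): call}
    with calls in {over, under, greater, less}; annotated cells get a marker
    edge (yellow/purple for ORA, red/blue for bootstrap overlays).
    """
    if any(p.colors is None for p in profiles):
        raise PhenoplastError("colorize profiles before rendering")
    ncols = len(profiles)
    widths = [max(1, len(p.group_labels)) for p in profiles]
    fig, axes = plt.subplots(
        1, ncols, figsize=(1 + 0.6 * sum(widths), 1 + 0.45 * len(profiles[0].specs)),
        squeeze=False, gridspec_kw={"width_ratios": widths},
    )
    edge_colors = {"over": "#ffd700", "under": "#800080", "greater": "#d62728", "less": "#1f77b4"}
    for pi, (ax, profile) in enumerate(zip(axes[0], profiles)):
        order = profile.sum_columns() + profile.index_columns()
        ann = (annotations or {}).get(pi, {})
        for row, m in enumerate(order):
            for g, label in enumerate(profile.group_labels):
                cell = plt.Rectangle(
                    (g, len(order) - 1 - row), 1, 1,
                    facecolor=profile.colors[g, m], edgecolor="black", linewidth=0.4,
                )
                ax.add_patch(cell)
                call = ann.get((label, profile.feature_names[m]))
                if call in edge_colors:
                    ax.add_patch(
                        plt.Rectangle(
                            (g + 0.15, len(order) - 1 - row + 0.15), 0.7, 0.7,
                            facecolor="none", edgecolor=edge_colors[call], linewidth=1.6,
                        )
                    )
        ax.set_xlim(0, len(profile.group_labels))
        ax.set_ylim(0, len(order))
        ax.set_xticks(np.arange(len(profile.group_labels)) + 0.5)
        ax.set_xticklabels(profile.group_labels, rotation=90, fontsize=7)
        ax.set_yticks(np.arange(len(order)) + 0.5)
        ax.set_yticklabels([profile.feature_names[m] for m in reversed(order)], fontsize=7)
        ax.set_aspect("equal")
    fig.tight_layout()
    _deterministic_savefig(fig, path)


def render_boxplots(
    features: FeatureTable,
    profile: PhenotypeProfile,
    path,
    seed: int = 0,
    whisker: float = 1.5,
) -> None:
    """Grid of per-feature boxplots (1.5·IQR whiskers, seeded jitter),
    each panel filled with that feature's phenotype color at the group median."""
    if profile.colors is None:
        raise PhenoplastError("colorize the profile before rendering boxplots")
    rng = np.random.default_rng(seed)
    m = len(profile.specs)
    ncols = 3
    nrows = int(np.ceil(m / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    order = profile.sum_columns() + profile.index_columns()
    for slot, mi in enumerate(order):
        spec = profile.specs[mi]
        ax = axes[slot // ncols][slot % ncols]
        data, positions = [], []
        for g, label in enumerate(profile.group_labels):
            block = features.data[
                features.data[profile.group_field].astype(str) == label
            ][spec.name].dropna()
            data.append(block.to_numpy())
            positions.append(g)
        bp = ax.boxplot(
            data, positions=positions, whis=whisker, patch_artist=True,
            showfliers=False, widths=0.7,
        )
        for g, patch in enumerate(bp["boxes"]):
            patch.set_facecolor(profile.colors[g, mi])
        for g, vals in enumerate(data):
            jitter = rng.uniform(-0.18, 0.18, size=len(vals))
            ax.plot(g + jitter, vals, "o", ms=2, color="black", alpha=0.6)
        ax.set_title(spec.name, fontsize=8)
        ax.set_xticks(positions)
        ax.set_xticklabels(profile.group_labels, rotation=90, fontsize=6)
    for slot in range(m, nrows * ncols):
        axes[slot // ncols][slot % ncols].axis("off")
    fig.tight_layout()
    _deterministic_savefig(fig, path)
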