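"""Synthetic expression panels with known ground truth.

The generator emulates the statistical structure the workflow assumes:
positive, right-skewed densitometry values with replicate western-blot
runs, produced as

    value = baseline · group_effect · region_effect
            · exp(N(0, bio_sigma)) · exp(N(0, global_sigma)) + run noise

where the biological (per-protein) and global (per-sample loading)
lognormal factors are drawn once per tissue sample and the additive
Gaussian run noise once per replicate run.  Because the lognormal median
is 1, group medians of each protein sit exactly at baseline × effects, so
planted effects propagate to the feature level in closed form.  Ground
truth is recorded at the feature level — the sums and contrast indices the
downstream analysis works with — as the noiseless feature shift of each
group against the design's reference group.

Presets mirror the three study designs the workflow was built around:
cross-sectional development panels (cat, human), a recovery-treatment
panel with six rearing conditions, and a four-condition drug study
(monocular deprivation and fluoxetine) with 5 / 1 / 3 planted feature
effects for MD / flx+MD / flx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionTable, PhenoplastError
from .features import FeatureSpec, preset_specs

#: Noiseless feature shifts below these margins are not recorded as planted.
SUM_RATIO_TOL = 0.08
INDEX_DELTA_TOL = 0.05

CAT_PROTEINS = ["Synapsin", "GluN1", "GluN2A", "GluN2B", "GluA2", "GABAAa1", "GABAAa3"]
RAT_PROTEINS = [
    "GluA2", "GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3",
    "Gephyrin", "PSD95", "VGLUT1", "VGAT",
]


@dataclass
class GroupDesign:
    label: str
    kind: str  # "age" | "condition"
    n_cases: int
    effects: dict[str, float] = field(default_factory=dict)  # protein -> multiplier


@dataclass
class PanelDesign:
    proteins: list[str]
    baselines: dict[str, float]
    groups: list[GroupDesign]
    regions: dict[str, float]  # region -> multiplicative effect
    runs: int = 2
    bio_sigma: float = 0.12
    global_sigma: float = 0.10
    run_noise_sd: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    reference_group: str | None = None
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    group_kind: str = "condition"

    def __post_init__(self) -> None:
        if any(self.baselines[p] <= 0 for p in self.proteins):
            raise PhenoplastError("baseline means must be positive")
        if not (0 <= self.missing_rate < 1):
            raise PhenoplastError("missing_rate must be in [0, 1)")

    def group_field(self) -> str:
        return "age_label" if self.group_kind == "age" else "condition"

    def scaled(self, strength: float) -> "PanelDesign":
        """Scale every planted log-multiplier by ``strength`` (1 = as designed)."""
        groups = [
            GroupDesign(
                label=g.label,
                kind=g.kind,
                n_cases=g.n_cases,
                effects={p: float(m**strength) for p, m in g.effects.items()},
            )
            for g in self.groups
        ]
        return PanelDesign(
            proteins=list(self.proteins),
            baselines=dict(self.baselines),
            groups=groups,
            regions=dict(self.regions),
            runs=self.runs,
            bio_sigma=self.bio_sigma,
            global_sigma=self.global_sigma,
            run_noise_sd=self.run_noise_sd,
            missing_rate=self.missing_rate,
            seed=self.seed,
            reference_group=self.reference_group,
            feature_specs=list(self.feature_specs),
            group_kind=self.group_kind,
        )


def _expected_proteins(design: PanelDesign, group: GroupDesign) -> dict[str, float]:
    return {
        p: design.baselines[p] * group.effects.get(p, 1.0) for p in design.proteins
    }


def _feature_value(spec: FeatureSpec, proteins: dict[str, float]) -> float:
    num = sum(proteins[p] for p in spec.numerator)
    if spec.kind == "sum":
        return num
    den = sum(proteins[p] for p in spec.denominator)
    return (num - den) / (num + den)


def planted_truth(design: PanelDesign) -> dict:
    """Noiseless feature-level effects of each group vs the reference group.

    A sum is planted when its expected ratio to the reference leaves
    [1−tol, 1+tol]; an index when its expected shift exceeds the index
    margin.  Groups matching the reference (or the reference itself) have
    empty entries.
    """
    if design.reference_group is None or not design.feature_specs:
        return {}
    ref = next(g for g in design.groups if g.label == design.reference_group)
    ref_proteins = _expected_proteins(design, ref)
    truth: dict = {}
    for group in design.groups:
        if group.label == ref.label:
            continue
        entry = {}
        grp_proteins = _expected_proteins(design, group)
        for spec in design.feature_specs:
            expected = _feature_value(spec, grp_proteins)
            baseline = _feature_value(spec, ref_proteins)
            if spec.kind == "sum":
                ratio = expected / baseline
                if abs(ratio - 1.0) > SUM_RATIO_TOL:
                    entry[spec.name] = {
                        "direction": "greater" if ratio > 1 else "less",
                        "magnitude": float(ratio),
                        "kind": "sum_ratio",
                    }
            else:
                delta = expected - baseline
                if abs(delta) > INDEX_DELTA_TOL:
                    entry[spec.name] = {
                        "direction": "greater" if delta > 0 else "less",
                        "magnitude": float(delta),
                        "kind": "index_shift",
                    }
        truth[group.label] = entry
    return truth


def generate_panel(design: PanelDesign) -> tuple[ExpressionTable, dict]:
    """Draw a replicate-run expression table from the design; seeded, deterministic."""
    rng = np.random.default_rng(design.seed)
    group_field = design.group_field()
    rows = []
    for group in design.groups:
        for case in range(1, group.n_cases + 1):
            case_id = f"{group.label}-{case:02d}"
            for region, region_eff in design.regions.items():
                expected = np.array(
                    [
                        design.baselines[p] * group.effects.get(p, 1.0) * region_eff
                        for p in design.proteins
                    ]
                )
                bio = np.exp(rng.normal(0.0, design.bio_sigma, size=len(expected)))
                load = np.exp(rng.normal(0.0, design.global_sigma))
                sample = expected * bio * load
                for run in range(1, design.runs + 1):
                    noise = rng.normal(0.0, design.run_noise_sd, size=len(sample))
                    values = np.clip(sample + noise * expected, 1e-9, None)
                    if design.missing_rate > 0:
                        mask = rng.random(len(values)) < design.missing_rate
                        values = np.where(mask, np.nan, values)
                    rows.append(
                        {
                            "case_id": case_id,
                            group_field: group.label,
                            "region": region,
                            "run": str(run),
                            **dict(zip(design.proteins, values)),
                        }
                    )
    data = pd.DataFrame(rows)
    table = ExpressionTable(
        data=data,
        protein_names=list(design.proteins),
        metadata_fields=["case_id", group_field, "region", "run"],
    )
    return table, planted_truth(design)


def write_panel(design: PanelDesign, csv_path, truth_path=None) -> None:
    import json

    table, truth = generate_panel(design)
    table.data.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)


# ---------------------------------------------------------------------------
# Presets

EFFECT_STRENGTH = {"weak": 0.4, "moderate": 0.7, "strong": 1.0}

# Developmental trajectory for the cat panel: protein sums rise toward the
# critical-period peak (4-6 wk) while receptor subunits swap isoforms
# (GluN2B->GluN2A, GABA_A a3->a1) and NMDA gives way to AMPA.
_CAT_DEV_AGES: list[tuple[str, float, dict[str, float]]] = [
    ("2wk", 0.45, {"GluN2A": 0.55, "GluN2B": 1.45, "GABAAa1": 0.55, "GABAAa3": 1.45, "GluA2": 0.70}),
    ("3wk", 0.60, {"GluN2A": 0.70, "GluN2B": 1.35, "GABAAa1": 0.70, "GABAAa3": 1.30, "GluA2": 0.80}),
    ("4wk", 0.85, {"GluN2A": 0.90, "GluN2B": 1.20, "GABAAa1": 0.85, "GABAAa3": 1.15, "GluA2": 0.95}),
    ("5wk", 1.05, {"GluN2A": 1.10, "GluN2B": 1.00, "GABAAa1": 1.00, "GABAAa3": 1.00, "GluA2": 1.10}),
    ("6wk", 1.15, {"GluN2A": 1.30, "GluN2B": 0.85, "GABAAa1": 1.15, "GABAAa3": 0.90, "GluA2": 1.20}),
    ("8wk", 1.10, {"GluN2A": 1.30, "GluN2B": 0.80, "GABAAa1": 1.25, "GABAAa3": 0.80, "GluA2": 1.25}),
    ("12wk", 1.05, {"GluN2A": 1.25, "GluN2B": 0.75, "GABAAa1": 1.30, "GABAAa3": 0.75, "GluA2": 1.25}),
    ("16wk", 1.00, {"GluN2A": 1.25, "GluN2B": 0.75, "GABAAa1": 1.30, "GABAAa3": 0.75, "GluA2": 1.25}),
    ("24wk", 1.00, {"GluN2A": 1.20, "GluN2B": 0.75, "GABAAa1": 1.30, "GABAAa3": 0.75, "GluA2": 1.20}),
]

# Rearing-condition signatures for the recovery panel: each condition pairs
# an overall expression scale with a distinct receptor-balance swap, so the
# conditions separate along several feature axes at once at full strength.
_CAT_RECOVERY_CONDITIONS: dict[str, tuple[float, dict[str, float]]] = {
    "normal": (1.00, {}),
    "MD": (0.70, {"GluN2A": 0.45, "GluN2B": 1.60, "GABAAa1": 0.55, "GABAAa3": 1.50}),
    "RO": (1.35, {"GluN2A": 1.90, "GluA2": 1.70, "GABAAa1": 0.50, "GABAAa3": 0.60}),
    "BD": (0.85, {"GABAAa1": 2.00, "GABAAa3": 1.35, "GluN1": 0.55, "GluN2A": 0.55}),
    "ST-BV": (1.15, {"GluN2B": 1.60, "GluA2": 0.55, "Synapsin": 1.55}),
    "LT-BV": (1.00, {"GluN2A": 1.50, "GluA2": 1.50, "Synapsin": 0.50, "GABAAa3": 1.40}),
}

# Drug-study signatures: multipliers chosen so that exactly 5 (MD),
# 1 (flx+MD) and 3 (flx) of the nine rat features shift beyond the truth
# margins while the remaining features stay flat by construction.
_RAT_FLX_CONDITIONS: dict[str, dict[str, float]] = {
    "normal": {},
    "1wk MD": {
        "GluA2": 1.15, "GluN1": 1.15, "GluN2A": 1.50, "GluN2B": 0.70,
        "GABAAa1": 0.70, "GABAAa3": 0.70, "Gephyrin": 0.75, "PSD95": 0.75,
        "VGLUT1": 1.70,
    },
    "flx+1wk MD": {"GluN2A": 1.35, "GluN2B": 0.65},
    "flx": {
        "GluA2": 1.04, "GluN1": 1.04, "GluN2A": 1.32, "GluN2B": 0.72,
        "GABAAa1": 1.04, "GABAAa3": 1.04, "Gephyrin": 1.04, "PSD95": 1.04,
        "VGLUT1": 0.70,
    },
}

_CAT_BASELINES = {
    "Synapsin": 1.4, "GluN1": 1.0, "GluN2A": 0.8, "GluN2B": 0.9,
    "GluA2": 1.1, "GABAAa1": 0.9, "GABAAa3": 0.8,
}
_RAT_BASELINES = {p: 1.0 for p in RAT_PROTEINS}


def preset(name: str, seed: int = 0, effect_strength: str = "strong") -> PanelDesign:
    """Named panel designs emulating the workflow's three study shapes.

    cat_dev      : 9 age groups, 24 cases, 16 regions, 2 runs (768 rows)
    cat_recovery : 6 rearing conditions x 6 cases x 3 regions x 2 runs
    human_dev    : 30 cases in 6 age bins, 1 region, 3 runs (90 rows)
    rat_flx      : conditions normal/1wk MD/flx+1wk MD/flx of 6/6/8/8 animals, 3 runs
    """
    strength = EFFECT_STRENGTH.get(effect_strength)
    if strength is None:
        raise PhenoplastError(f"unknown effect strength: {effect_strength}")
    if name == "cat_dev":
        case_counts = [3, 3, 3, 3, 3, 3, 2, 2, 2]  # sums to 24
        # combine the overall maturation scale with per-protein subunit swaps
        groups = []
        for (age, scale, swaps), ncase in zip(_CAT_DEV_AGES, case_counts):
            effects = {p: scale for p in CAT_PROTEINS}
            for prot, mult in swaps.items():
                effects[prot] = scale * mult
            groups.append(GroupDesign(label=age, kind="age", n_cases=ncase, effects=effects))
        regions = {f"R{i:02d}": 1.0 - 0.01 * i for i in range(16)}
        design = PanelDesign(
            proteins=CAT_PROTEINS,
            baselines=dict(_CAT_BASELINES),
            groups=groups,
            regions=regions,
            runs=2,
            seed=seed,
            reference_group="2wk",
            feature_specs=preset_specs("cat9"),
            group_kind="age",
        )
    elif name == "cat_recovery":
        groups = []
        for cond, (scale, swaps) in _CAT_RECOVERY_CONDITIONS.items():
            effects = {p: scale for p in CAT_PROTEINS}
            for prot, mult in swaps.items():
                effects[prot] = scale * mult
            groups.append(
                GroupDesign(label=cond, kind="condition", n_cases=12, effects=effects)
            )
        design = PanelDesign(
            proteins=CAT_PROTEINS,
            baselines=dict(_CAT_BASELINES),
            groups=groups,
            regions={"central": 1.0, "peripheral": 0.95, "monocular": 0.90},
            runs=2,
            bio_sigma=0.10,
            global_sigma=0.05,
            run_noise_sd=0.04,
            seed=seed,
            reference_group="normal",
            feature_specs=preset_specs("cat9"),
        )
    elif name == "human_dev":
        bins = [
            ("<1yr", 1.00, {"GluN2A": 0.80, "GluN2B": 1.20, "GABAAa1": 0.85, "GABAAa3": 1.15}),
            ("1-4yr", 1.05, {"GluN2A": 0.95, "GluN2B": 1.10, "GABAAa1": 0.95, "GABAAa3": 1.05}),
            ("5-11yr", 1.10, {"GluN2A": 1.05, "GluN2B": 1.00, "GABAAa1": 1.05, "GABAAa3": 0.95}),
            ("12-20yr", 1.10, {"GluN2A": 1.15, "GluN2B": 0.90, "GABAAa1": 1.15, "GABAAa3": 0.90}),
            ("21-55yr", 1.05, {"GluN2A": 1.20, "GluN2B": 0.85, "GABAAa1": 1.20, "GABAAa3": 0.85}),
            (">55yr", 1.00, {"GluN2A": 1.20, "GluN2B": 0.85, "GABAAa1": 1.20, "GABAAa3": 0.85}),
        ]
        groups = []
        for label, scale, swaps in bins:
            effects = {p: scale for p in CAT_PROTEINS}
            for prot, mult in swaps.items():
                effects[prot] = scale * mult
            groups.append(GroupDesign(label=label, kind="age", n_cases=5, effects=effects))
        design = PanelDesign(
            proteins=CAT_PROTEINS,
            baselines=dict(_CAT_BASELINES),
            groups=groups,
            regions={"V1": 1.0},
            runs=3,
            seed=seed,
            reference_group="<1yr",
            feature_specs=preset_specs("cat9"),
            group_kind="age",
        )
    elif name == "rat_flx":
        sizes = {"normal": 6, "1wk MD": 6, "flx+1wk MD": 8, "flx": 8}
        groups = [
            GroupDesign(label=cond, kind="condition", n_cases=sizes[cond], effects=dict(eff))
            for cond, eff in _RAT_FLX_CONDITIONS.items()
        ]
        design = PanelDesign(
            proteins=RAT_PROTEINS,
            baselines=dict(_RAT_BASELINES),
            groups=groups,
            regions={"V1": 1.0},
            runs=3,
            seed=seed,
            reference_group="normal",
            feature_specs=preset_specs("rat9"),
        )
    else:
        raise PhenoplastError(f"unknown preset: {name}")
    if strength != 1.0:
        design = design.scaled(strength)
    return design
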