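"""Plasticity features: proposal, evaluation, and validation.

A plasticity feature is either a **sum** over a protein set or a bounded
**contrast index** (A−B)/(A+B) between the sums of two disjoint protein
sets: 0 means balance, ±1 exclusive dominance, and the value is invariant
to rescaling the whole panel.  Candidate features come from three
heuristics over the PCA diagnostics — strongly loading protein classes are
summed, a-priori protein pairs become indices, and novel pairs with large
opposite-sign amplitudes on one retained dimension become indices.
Candidates are validated by Bonferroni- (or FDR-) corrected Pearson
correlation against the retained principal-component scores.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionTable, PhenoplastError
from .pca import PCAModel


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative definition of a sum or contrast-index feature."""

    name: str
    kind: str  # "sum" | "index"
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()
    provenance: str = "user"  # high_amplitude | a_priori | novel_pair | user

    def __post_init__(self) -> None:
        if self.kind not in ("sum", "index"):
            raise PhenoplastError(f"unknown feature kind: {self.kind}")
        if not self.numerator:
            raise PhenoplastError(f"feature {self.name}: empty numerator")
        if self.kind == "sum" and self.denominator:
            raise PhenoplastError(f"sum feature {self.name} has a denominator")
        if self.kind == "index" and not self.denominator:
            raise PhenoplastError(f"index feature {self.name} lacks a denominator")
        if set(self.numerator) & set(self.denominator):
            raise PhenoplastError(
                f"feature {self.name}: numerator and denominator overlap"
            )

    def proteins(self) -> set[str]:
        return set(self.numerator) | set(self.denominator)

    def member_key(self) -> tuple[frozenset, frozenset]:
        """Unordered identity used for deduplication."""
        return frozenset(self.numerator), frozenset(self.denominator)

    def check_panel(self, protein_names) -> None:
        unknown = self.proteins() - set(protein_names)
        if unknown:
            raise PhenoplastError(
                f"feature {self.name} references unknown proteins: {sorted(unknown)}"
            )


@dataclass
class FeatureTable:
    """Evaluated per-sample feature values plus sample metadata."""

    data: pd.DataFrame  # metadata columns + one column per feature
    specs: list[FeatureSpec]
    metadata_fields: list[str]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def feature_matrix(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    def spec_by_name(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise PhenoplastError(f"unknown feature: {name}")


@dataclass
class ValidationMatrix:
    """Feature-vs-PC-score correlations with multiplicity correction."""

    r: pd.DataFrame  # d x m
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    method: str

    def validated_features(self) -> list[str]:
        """Features significant on at least one retained dimension."""
        return [c for c in self.significant.columns if self.significant[c].any()]


def contrast_index(a, b):
    """Normalized contrast (a−b)/(a+b) for nonnegative a, b; NaN when a+b=0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = a + b
    out = np.full(np.broadcast(a, b).shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(a - b, total, out=out, where=total > 0)
    if np.any(total == 0):
        warnings.warn("contrast index undefined where a + b == 0; set to missing")
    if out.ndim == 0:
        return float(out)
    return out


def evaluate_features(table: ExpressionTable, specs: list[FeatureSpec]) -> FeatureTable:
    """Evaluate each spec per sample: sums of proteins, or contrasts of sums.

    A sample's feature is missing when any referenced protein cell is
    missing.  Unknown proteins fail at spec-build time via ``check_panel``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise PhenoplastError("duplicate feature names")
    for spec in specs:
        spec.check_panel(table.protein_names)
    out = table.data[table.metadata_fields].copy()
    for spec in specs:
        num = table.data[list(spec.numerator)].to_numpy(dtype=float).sum(axis=1)
        if spec.kind == "sum":
            out[spec.name] = num
        else:
            den = table.data[list(spec.denominator)].to_numpy(dtype=float).sum(axis=1)
            out[spec.name] = contrast_index(num, den)
    return FeatureTable(
        data=out, specs=list(specs), metadata_fields=list(table.metadata_fields)
    )


def propose_features(
    model: PCAModel,
    ndims: int,
    apriori_pairs: list[tuple] = (),
    amplitude_quantile: float = 0.75,
    protein_classes: dict | None = None,
) -> list[FeatureSpec]:
    """Propose candidate features from the PCA diagnostics.

    Three heuristics, deduplicated by unordered protein-set identity:

    1. sums — the all-protein sum, plus a sum for every declared protein
       class with at least one member whose |var_coord| reaches the
       per-dimension amplitude threshold (the ``amplitude_quantile``
       quantile of that dimension's |var_coord| values) on some retained
       dimension — a class is worth summing when any of its members drives
       a retained component;
    2. a-priori pair indices — every declared pair present in the panel;
    3. novel pair indices — protein pairs that on some retained dimension
       both reach the amplitude threshold with opposite signs.  The
       positively loading protein on that dimension is the numerator.
    """
    proteins = model.protein_names
    coords = model.var_coords[:, :ndims]
    thresholds = np.quantile(np.abs(coords), amplitude_quantile, axis=0)
    strong = np.abs(coords) >= thresholds[None, :]  # p x ndims

    specs: list[FeatureSpec] = []
    seen: set = set()

    def add(spec: FeatureSpec) -> None:
        key = spec.member_key()
        mirror = (key[1], key[0])
        if key in seen or mirror in seen:
            return
        seen.add(key)
        specs.append(spec)

    add(
        FeatureSpec(
            name="Protein Sum",
            kind="sum",
            numerator=tuple(proteins),
            provenance="high_amplitude",
        )
    )
    for cls_name, members in (protein_classes or {}).items():
        members = [m for m in members if m in proteins]
        if not members:
            continue
        idx = [proteins.index(m) for m in members]
        if any(strong[i].any() for i in idx):
            add(
                FeatureSpec(
                    name=f"{cls_name} Sum",
                    kind="sum",
                    numerator=tuple(members),
                    provenance="high_amplitude",
                )
            )
    for a, b in apriori_pairs:
        if a in proteins and b in proteins:
            add(
                FeatureSpec(
                    name=f"{a}:{b}",
                    kind="index",
                    numerator=(a,),
                    denominator=(b,),
                    provenance="a_priori",
                )
            )
    for i, j in itertools.combinations(range(len(proteins)), 2):
        for d in range(ndims):
            if (
                strong[i, d]
                and strong[j, d]
                and coords[i, d] * coords[j, d] < 0
            ):
                hi, lo = (i, j) if coords[i, d] > 0 else (j, i)
                add(
                    FeatureSpec(
                        name=f"{proteins[hi]}:{proteins[lo]}",
                        kind="index",
                        numerator=(proteins[hi],),
                        denominator=(proteins[lo],),
                        provenance="novel_pair",
                    )
                )
                break
    return specs


def validate_features(
    features: FeatureTable,
    scores: np.ndarray,
    ndims: int,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> ValidationMatrix:
    """Correlate each feature with each retained PC dimension.

    Pearson r with two-sided p-values, adjusted over all d×m tests by
    Bonferroni (default) or Benjamini–Hochberg FDR; a feature is validated
    when significant on at least one retained dimension.  Constant feature
    columns are reported as r=NaN, not significant, with a warning.
    """
    if method not in ("bonferroni", "fdr"):
        raise PhenoplastError(f"unknown correction method: {method}")
    scores = np.asarray(scores, dtype=float)
    if ndims > scores.shape[1]:
        raise PhenoplastError("ndims exceeds available score columns")
    if scores.shape[0] != len(features.data):
        raise PhenoplastError("features and scores have different sample counts")
    values = features.feature_matrix()
    dims = [f"Dim{d + 1}" for d in range(ndims)]
    m = values.shape[1]
    r = np.full((ndims, m), np.nan)
    p = np.full((ndims, m), np.nan)
    for jj in range(m):
        col = values[:, jj]
        mask = np.isfinite(col)
        if np.nanstd(col) == 0 or mask.sum() < 3:
            warnings.warn(
                f"feature {features.feature_names[jj]!r} is constant or too sparse; "
                "correlation undefined, reported as not significant"
            )
            continue
        for d in range(ndims):
            res = stats.pearsonr(scores[mask, d], col[mask])
            r[d, jj] = res.statistic
            p[d, jj] = res.pvalue
    flat = p.ravel()
    finite = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if finite.any():
        sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
        adj[finite] = multipletests(flat[finite], method=sm_method)[1]
    p_adj = adj.reshape(p.shape)
    with np.errstate(invalid="ignore"):
        sig = p_adj < alpha
    cols = features.feature_names
    return ValidationMatrix(
        r=pd.DataFrame(r, index=dims, columns=cols),
        p_adjusted=pd.DataFrame(p_adj, index=dims, columns=cols),
        significant=pd.DataFrame(sig, index=dims, columns=cols),
        alpha=alpha,
        method=method,
    )


# ---------------------------------------------------------------------------
# Packaged feature presets


def load_spec_json(source) -> list[FeatureSpec]:
    """Load FeatureSpec definitions from a JSON list of objects."""
    if hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    specs = []
    for item in raw:
        specs.append(
            FeatureSpec(
                name=item["name"],
                kind=item["kind"],
                numerator=tuple(item["numerator"]),
                denominator=tuple(item.get("denominator", ())),
                provenance=item.get("provenance", "user"),
            )
        )
    return specs


def save_spec_json(specs: list[FeatureSpec], path) -> None:
    payload = [
        {
            "name": s.name,
            "kind": s.kind,
            "numerator": list(s.numerator),
            "denominator": list(s.denominator),
            "provenance": s.provenance,
        }
        for s in specs
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def preset_specs(name: str) -> list[FeatureSpec]:
    """Packaged feature panels: ``cat9`` (cat/human) or ``rat9``."""
    ref = resources.files("phenoplast").joinpath("presets", f"{name}.json")
    if not ref.is_file():
        raise PhenoplastError(f"unknown feature preset: {name}")
    with ref.open() as fh:
        return load_spec_json(fh)
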