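"""Phenotype preprocessing: log transform, normal scores, design adjustment,
standardization.

The canonical order of operations is

    log -> normal_score -> design_adjust -> standardize

and every stage records itself in the table's provenance; a stage refuses to
run after a later one has already been applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_STAGE_RANK = {"log": 0, "normal_score": 1, "design_adjust": 2, "standardize": 3}

#: Traits the study log-transforms.
LOG_TRAITS = ("DECL", "LIMO", "T_MONO")


class PreprocessError(ValueError):
    pass


@dataclass
class TraitTable:
    """Tree ids, trait columns (missing allowed) and design factor columns."""

    data: pd.DataFrame
    trait_names: list[str]
    design_cols: list[str] = field(default_factory=lambda: ["rep", "set"])
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise PreprocessError("trait table needs an 'id' column")
        missing = [t for t in self.trait_names if t not in self.data.columns]
        if missing:
            raise PreprocessError(f"trait columns absent: {missing}")
        self.data = self.data.reset_index(drop=True)
        self.data["id"] = self.data["id"].astype(str)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    def values(self) -> np.ndarray:
        """Trait matrix (trees x traits) with NaN for missing."""
        return self.data[self.trait_names].to_numpy(dtype=float)

    def copy(self) -> "TraitTable":
        return TraitTable(
            self.data.copy(), list(self.trait_names), list(self.design_cols),
            [dict(p) for p in self.provenance],
        )

    def _check_stage(self, stage: str) -> None:
        applied = [p["stage"] for p in self.provenance]
        if applied and max(_STAGE_RANK[s] for s in applied) > _STAGE_RANK[stage]:
            raise PreprocessError(
                f"stage '{stage}' cannot follow {applied}: pipeline order is "
                "log -> normal_score -> design_adjust -> standardize"
            )


def log_transform(table: TraitTable, traits: tuple[str, ...] = LOG_TRAITS) -> TraitTable:
    """Natural log of the targeted trait columns; missing values preserved.

    Raises on non-positive values, naming the offending tree and trait.
    """
    table._check_stage("log")
    out = table.copy()
    present = [t for t in traits if t in out.trait_names]
    for t in present:
        col = out.data[t].to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(col) & (col <= 0.0))[0]
        if bad.size:
            tree = out.data["id"].iloc[bad[0]]
            raise PreprocessError(
                f"non-positive value for trait {t} of tree {tree}: "
                f"{col[bad[0]]!r} cannot be log-transformed"
            )
        out.data[t] = np.log(col)
    out.provenance.append({"stage": "log", "traits": list(present)})
    return out


def normal_score(table: TraitTable, trait: str = "WGR", n_categories: int = 4) -> TraitTable:
    """Map an ordered categorical trait to expected standard-normal scores.

    Category c (1..K) with empirical cumulative proportions F_{c-1}, F_c is
    assigned the mean of a standard normal truncated to its probability band:

        z(c) = (phi(Phi^-1(F_{c-1})) - phi(Phi^-1(F_c))) / (F_c - F_{c-1})

    Scores are strictly increasing in c and average to zero over the sample.
    """
    table._check_stage("normal_score")
    out = table.copy()
    col = out.data[trait].to_numpy(dtype=float)
    obs = col[~np.isnan(col)]
    cats = np.arange(1, n_categories + 1)
    if not np.isin(obs, cats).all():
        raise PreprocessError(
            f"trait {trait} holds values outside ordered categories 1..{n_categories}"
        )
    counts = np.array([(obs == c).sum() for c in cats], dtype=float)
    total = counts.sum()
    F = np.concatenate([[0.0], np.cumsum(counts) / total])
    scores = {}
    for k, c in enumerate(cats):
        if counts[k] == 0:
            continue
        lo, hi = F[k], F[k + 1]
        num = stats.norm.pdf(stats.norm.ppf(lo)) - stats.norm.pdf(stats.norm.ppf(hi))
        scores[c] = num / (hi - lo)
    out.data[trait] = np.array(
        [scores[v] if not np.isnan(v) else np.nan for v in col]
    )
    out.provenance.append(
        {"stage": "normal_score", "trait": trait, "scores": {int(c): float(s) for c, s in scores.items()}}
    )
    return out


def design_adjust(table: TraitTable) -> TraitTable:
    """Remove replication and set-within-replication fixed effects per trait.

    Fits ordinary least squares with sum-to-zero factor effects on the
    non-missing records of each trait and subtracts the fitted effects,
    retaining the grand mean. Factor levels with no records simply do not
    enter the fit; a factor with a single observed level is skipped.
    """
    table._check_stage("design_adjust")
    out = table.copy()
    rep_col, set_col = out.design_cols[0], out.design_cols[1]
    if rep_col not in out.data.columns or set_col not in out.data.columns:
        raise PreprocessError(f"design columns {out.design_cols} absent")
    rep = out.data[rep_col].astype(str).to_numpy()
    rep_set = rep + ":" + out.data[set_col].astype(str).to_numpy()
    for t in out.trait_names:
        y = out.data[t].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            continue
        X_parts = [np.ones((obs.sum(), 1))]
        for factor in (rep[obs], rep_set[obs]):
            levels = np.unique(factor)
            if len(levels) < 2:
                continue
            # sum-to-zero coding: last level = -(sum of others)
            Z = (factor[:, None] == levels[None, :-1]).astype(float)
            Z[factor == levels[-1], :] = -1.0
            X_parts.append(Z)
        if len(X_parts) == 1:
            continue  # nothing adjustable
        X = np.hstack(X_parts)
        coef, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        fitted_effects = X[:, 1:] @ coef[1:]
        adjusted = y.copy()
        adjusted[obs] = y[obs] - fitted_effects
        out.data[t] = adjusted
    out.provenance.append({"stage": "design_adjust", "factors": [rep_col, set_col]})
    return out


def standardize(table: TraitTable) -> TraitTable:
    """Z-score each trait over its non-missing records (n-1 denominator).

    The centering and scaling constants are stored in the provenance so the
    transformation can be undone.
    """
    table._check_stage("standardize")
    out = table.copy()
    constants = {}
    for t in out.trait_names:
        y = out.data[t].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            raise PreprocessError(f"trait {t} has fewer than 2 records")
        mu = float(y[obs].mean())
        sd = float(y[obs].std(ddof=1))
        if sd == 0.0:
            raise PreprocessError(f"trait {t} has zero variance")
        out.data[t] = (y - mu) / sd
        constants[t] = {"mean": mu, "sd": sd}
    out.provenance.append({"stage": "standardize", "constants": constants})
    return out


def preprocess_pipeline(
    table: TraitTable,
    log_traits: tuple[str, ...] = LOG_TRAITS,
    score_trait: str | None = "WGR",
    n_categories: int = 4,
) -> TraitTable:
    """Apply the full chain in canonical order.

    Stages whose target columns are absent, or whose input is evidently not
    on the expected scale (e.g. a score trait that is already continuous),
    are skipped with a warning rather than failing the pipeline.
    """
    out = table
    targets = [t for t in log_traits if t in out.trait_names]
    if targets:
        col = out.data[targets].to_numpy(dtype=float)
        if np.nanmin(col) > 0:
            out = log_transform(out, tuple(targets))
        else:
            warnings.warn("log stage skipped: non-positive values present")
    if score_trait and score_trait in out.trait_names:
        col = out.data[score_trait].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        if np.isin(obs, np.arange(1, n_categories + 1)).all():
            out = normal_score(out, score_trait, n_categories)
        else:
            warnings.warn(f"normal-score stage skipped: {score_trait} not categorical")
    out = design_adjust(out)
    out = standardize(out)
    return out
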