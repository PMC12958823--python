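"""Model comparison: breeding-value agreement, elite-ranking stability,
DIC differences and k-fold cross-validated predictive ability."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import RelationshipMatrix
from .mtm import McmcChain, MtmSpec, PosteriorSummary, fit_mtm
from .preprocess import TraitTable
from .sem import SemSpec, fit_sem


class EvaluationError(ValueError):
    pass


@dataclass
class BvComparison:
    """Per-trait agreement between two sets of predicted breeding values."""

    table: pd.DataFrame   # trait, pearson, slope, intercept, r2, spearman_top
    top_fraction: float
    top_size: int
    labels: tuple[str, str]


@dataclass
class CvResult:
    """Cross-validated predictive ability of one model."""

    model: str
    folds: pd.Series                    # tree id -> fold
    per_fold: pd.DataFrame              # trait x fold Pearson correlations
    per_trait: pd.Series                # mean over folds

    def gain_over(self, other: "CvResult") -> pd.Series:
        """Percent gain of this model's mean predictive ability over
        another's, per trait."""
        return 100.0 * (self.per_trait - other.per_trait) / other.per_trait.abs()


def compare_bvs(
    chain_a: McmcChain,
    chain_b: McmcChain,
    top_fraction: float = 0.10,
) -> BvComparison:
    """Agreement of posterior-mean breeding values between two fits.

    Reports, per trait, the Pearson correlation, the least-squares
    regression of model B on model A (slope, intercept, R^2), and the
    Spearman rank correlation over the elite set: the top
    floor(fraction * n) trees of model A, ranked by both models.
    """
    if set(chain_a.traits) != set(chain_b.traits):
        raise EvaluationError("chains carry different traits")
    if set(chain_a.ids) != set(chain_b.ids):
        raise EvaluationError("chains carry different trees")
    A = chain_a.bv_mean
    B = chain_b.bv_mean.loc[A.index, chain_a.traits]  # align order by name
    n = len(A)
    top = int(np.floor(top_fraction * n))
    rows = []
    for trait in chain_a.traits:
        x, y = A[trait].to_numpy(), B[trait].to_numpy()
        pearson = float(np.corrcoef(x, y)[0, 1])
        slope, intercept = np.polyfit(x, y, 1)
        elite = np.argsort(-x)[:top]
        if np.std(x[elite]) == 0 or np.std(y[elite]) == 0:
            spear = 1.0 if np.allclose(x[elite], y[elite]) else np.nan
        else:
            spear = float(stats.spearmanr(x[elite], y[elite]).statistic)
        rows.append({
            "trait": trait, "pearson": pearson, "slope": float(slope),
            "intercept": float(intercept), "r2": pearson ** 2,
            "spearman_top": spear,
        })
    return BvComparison(
        pd.DataFrame(rows), top_fraction, top,
        (chain_a.model, chain_b.model),
    )


def _make_folds(ids: list[str], k: int, rng: np.random.Generator) -> pd.Series:
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[perm] = np.arange(len(ids)) % k
    return pd.Series(folds, index=ids)


def kfold_predictive_ability(
    traits: TraitTable,
    kinship: RelationshipMatrix,
    model_spec: MtmSpec | SemSpec,
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Cross-validated predictive ability of one model specification.

    Trees are partitioned into k folds; each fold in turn has all its trait
    records masked, the model is refit, and validation trees' breeding
    values are predicted through their kinship with the training trees.
    Predictive ability is the Pearson correlation between the
    design-adjusted phenotypes of the validation trees and their predicted
    BVs, computed per fold and averaged per trait.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    ids = traits.ids
    folds = _make_folds(ids, k, rng)
    Y = traits.values()
    is_sem = isinstance(model_spec, SemSpec)
    per_fold = np.full((len(traits.trait_names), k), np.nan)
    trait_names = (list(model_spec.lambda_matrix.trait_order)
                   if is_sem else list(traits.trait_names))
    col_of = {t: traits.trait_names.index(t) for t in trait_names}
    for fold in range(k):
        mask = (folds == fold).to_numpy()
        masked = traits.copy()
        masked.data.loc[mask, traits.trait_names] = np.nan
        chain = (fit_sem(masked, kinship, model_spec) if is_sem
                 else fit_mtm(masked, kinship, model_spec))
        bv = chain.bv_mean
        for j, t in enumerate(trait_names):
            obs = Y[mask, col_of[t]]
            pred = bv.loc[np.array(ids)[mask], t].to_numpy()
            ok = ~np.isnan(obs)
            if ok.sum() < 3:
                warnings.warn(
                    f"fold {fold}: fewer than 3 records for {t}; skipped"
                )
                continue
            per_fold[j, fold] = np.corrcoef(obs[ok], pred[ok])[0, 1]
    pf = pd.DataFrame(per_fold, index=trait_names,
                      columns=[f"fold{f}" for f in range(k)])
    return CvResult(
        model="SEM" if is_sem else "MTM",
        folds=folds,
        per_fold=pf,
        per_trait=pf.mean(axis=1),
    )


def compare_dic(
    summary_mtm: PosteriorSummary,
    summary_sem: PosteriorSummary,
) -> pd.DataFrame:
    """DIC(MTM) - DIC(SEM); positive favors the structural model."""
    rows = [{
        "model": "MTM",
        "pD": summary_mtm.dic_components["pD"],
        "DIC": summary_mtm.dic_components["DIC"],
    }, {
        "model": "SEM",
        "pD": summary_sem.dic_components["pD"],
        "DIC": summary_sem.dic_components["DIC"],
    }]
    out = pd.DataFrame(rows)
    out.attrs["difference"] = (
        summary_mtm.dic_components["DIC"] - summary_sem.dic_components["DIC"]
    )
    return out
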