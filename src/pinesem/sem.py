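"""Recursive structural equation model with the causal structure fixed to a
learned DAG.

The model adds a strictly-lower-triangular (in causal order) coefficient
matrix Lambda to the multitrait model: (I - Lambda) y = X beta* + a* + e*.
Entries of Lambda are free exactly where the DAG has an edge parent -> child
and are sampled jointly with the genetic effects and covariances. With an
empty mask the sampler reduces to the plain multitrait model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import GibbsError, run_chain
from .bn import DagStructure
from .kinship import RelationshipMatrix
from .mtm import McmcChain, MtmSpec, hpd_interval
from .preprocess import TraitTable

__all__ = ["LambdaMatrix", "SemSpec", "build_lambda_mask", "fit_sem",
           "structural_summary"]


class SemError(ValueError):
    pass


@dataclass
class LambdaMatrix:
    """Structural coefficients on a fixed sparsity mask in causal order."""

    trait_order: tuple[str, ...]
    mask: np.ndarray                 # (t, t) bool, entry (child, parent)
    values: np.ndarray | None = None  # point values aligned with mask

    def __post_init__(self) -> None:
        t = len(self.trait_order)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (t, t):
            raise SemError("mask shape does not match trait order")
        if self.mask.diagonal().any():
            raise SemError("mask diagonal must be zero")
        if np.triu(self.mask).any():
            raise SemError(
                "mask must be strictly lower-triangular in the causal order"
            )
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if (~self.mask & (self.values != 0.0)).any():
                raise SemError("values outside the mask must be zero")

    @property
    def n_free(self) -> int:
        return int(self.mask.sum())

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs of the free entries."""
        out = []
        for r, j in zip(*np.nonzero(self.mask)):
            out.append((self.trait_order[j], self.trait_order[r]))
        return sorted(out)


def build_lambda_mask(dag: DagStructure, trait_order: tuple[str, ...] | None = None
                      ) -> LambdaMatrix:
    """Sparsity mask from a DAG: entry (child, parent) free iff the DAG has
    the edge parent -> child.

    If `trait_order` is not a topological order of the DAG (or not given),
    a topological order is derived, so the mask is always strictly
    lower-triangular.
    """
    topo = dag.topological_order()
    if trait_order is None:
        trait_order = tuple(topo)
    else:
        pos = {v: i for i, v in enumerate(trait_order)}
        if any(pos[p] > pos[c] for p, c in dag.edges):
            trait_order = tuple(topo)
    idx = {v: i for i, v in enumerate(trait_order)}
    t = len(trait_order)
    mask = np.zeros((t, t), dtype=bool)
    for p, c in dag.edges:
        mask[idx[c], idx[p]] = True
    return LambdaMatrix(tuple(trait_order), mask)


@dataclass
class SemSpec(MtmSpec):
    """Multitrait spec plus the structural-coefficient block."""

    lambda_matrix: LambdaMatrix | None = None
    v_lambda: float = 1.0            # N(0, v_lambda) prior per free entry
    residual_structure: str = "unstructured"   # or "diagonal"

    def __post_init__(self) -> None:
        if self.v_lambda <= 0:
            raise SemError("v_lambda must be positive")
        if self.residual_structure not in ("unstructured", "diagonal"):
            raise SemError("residual_structure must be unstructured|diagonal")


def fit_sem(
    traits: TraitTable,
    kinship: RelationshipMatrix,
    spec: SemSpec,
) -> McmcChain:
    """Fit the recursive SEM by Gibbs sampling.

    Traits are internally reordered to the causal order of the Lambda mask;
    outputs are reported in that order.
    """
    if spec.lambda_matrix is None:
        raise SemError("SemSpec.lambda_matrix is required (may be empty mask)")
    lam = spec.lambda_matrix
    missing_traits = set(lam.trait_order) - set(traits.trait_names)
    if missing_traits:
        raise SemError(f"traits absent from table: {sorted(missing_traits)}")
    ordered = TraitTable(
        traits.data, list(lam.trait_order), traits.design_cols,
        [dict(p) for p in traits.provenance],
    )
    ids = ordered.ids
    K = kinship.subset(ids)
    X, _ = spec.design_matrix(ordered)
    tr = run_chain(
        ordered.values(), X, K.values, spec.chain,
        lambda_mask=lam.mask, prior_df=spec.prior_df,
        prior_scale=spec.prior_scale, v_lambda=spec.v_lambda,
        diagonal_r0=(spec.residual_structure == "diagonal"),
    )
    return McmcChain(
        list(lam.trait_order), ids, kinship.kind, spec.chain, tr,
        model="SEM", lambda_mask=lam.mask,
    )


def lambda_table(chain: McmcChain, hpd: float = 0.95) -> pd.DataFrame:
    """Posterior summary of each free structural coefficient."""
    if chain.traces.Lambda is None:
        raise SemError("chain was not fitted with a structural block")
    mask = chain.lambda_mask
    rows = []
    for r, j in zip(*np.nonzero(mask)):
        s = chain.traces.Lambda[:, r, j]
        lo, hi = hpd_interval(s, hpd)
        rows.append({
            "from": chain.traits[j], "to": chain.traits[r],
            "mean": float(s.mean()), "sd": float(s.std(ddof=1)),
            "hpd_low": lo, "hpd_high": hi,
        })
    return pd.DataFrame(rows, columns=["from", "to", "mean", "sd",
                                       "hpd_low", "hpd_high"])


def reduced_form_correlations(chain: McmcChain) -> pd.DataFrame:
    """Posterior mean correlations of the reduced-form genetic effects
    (I - Lambda)^-1 a*, which include effects mediated through other traits."""
    if chain.traces.Lambda is None:
        raise SemError("chain was not fitted with a structural block")
    t = len(chain.traits)
    I_t = np.eye(t)
    acc = np.zeros((t, t))
    for Sa, Lam in zip(chain.traces.Sigma_a, chain.traces.Lambda):
        inv = np.linalg.inv(I_t - Lam)
        S = inv @ Sa @ inv.T
        sd = np.sqrt(np.diag(S))
        acc += S / np.outer(sd, sd)
    acc /= chain.n_retained
    return pd.DataFrame(acc, index=chain.traits, columns=chain.traits)


def structural_summary(chain: McmcChain, hpd: float = 0.95) -> dict:
    """Coefficient and parameter tables of a fitted SEM chain.

    Returns a dict with the lambda posterior table, the variance/heritability
    table, direct-effect genetic correlations (from Sigma_a*), and
    reduced-form correlations (propagated through (I - Lambda)^-1).
    """
    from .mtm import summarize

    if chain.n_retained == 0:
        raise GibbsError("empty chain")
    base = summarize(chain, hpd)
    return {
        "lambda": lambda_table(chain, hpd),
        "variances": base.variance_table,
        "correlations_direct": base.correlations,
        "correlations_reduced_form": reduced_form_correlations(chain),
        "dic": base.dic_components,
    }
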