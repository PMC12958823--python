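"""Multitrait individual-tree mixed model fitted by Gibbs sampling.

Phenotypes of all traits are modeled jointly with genetic-group fixed
effects, additive tree effects with covariance Sigma_a (x) K (K the
pedigree A or genomic G relationship matrix) and unstructured residual
covariance R0. Heritability per trait is sigma2_a / (sigma2_a + sigma2_e)
on the design-adjusted, standardized scale; genetic correlations come from
the off-diagonals of Sigma_a. Point estimates are posterior means of the
per-sample quantities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import (
    CHAIN_PRESETS,
    ChainSettings,
    GibbsError,
    GibbsTraces,
    retained_samples,
    run_chain,
)
from .kinship import RelationshipMatrix
from .preprocess import TraitTable

__all__ = [
    "MtmSpec", "McmcChain", "PosteriorSummary", "fit_mtm", "summarize",
    "dic", "convergence_report", "ChainSettings", "CHAIN_PRESETS",
    "retained_samples",
]


@dataclass
class MtmSpec:
    """Model specification: fixed effects, priors and chain plan.

    `fixed_effect` names the genetic-group column; `design_factors` lists
    further factor columns (e.g. replication and set-within-replication)
    to absorb in the model jointly instead of pre-adjusting the phenotypes.
    The special factor name "rep:set" builds the nested interaction of the
    table's design columns.
    """

    fixed_effect: str | None = "group"
    design_factors: tuple[str, ...] = ()
    chain: ChainSettings = field(default_factory=ChainSettings)
    prior_df: float | None = None     # default: n_traits + 2
    prior_scale: float = 0.5          # inverse-Wishart scale multiplier

    def design_matrix(self, table: TraitTable) -> tuple[np.ndarray, list[str]]:
        """One-hot genetic-group design (falls back to a global intercept),
        plus drop-first coding for any additional factor columns."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        if self.fixed_effect and self.fixed_effect in table.data.columns:
            g = table.data[self.fixed_effect].astype(str)
            levels = sorted(g.unique())
            X = (g.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
            keep = X.sum(axis=0) > 0
            cols.append(X[:, keep])
            names += [f"{self.fixed_effect}={lv}"
                      for lv, k in zip(levels, keep) if k]
        else:
            cols.append(np.ones((len(table.data), 1)))
            names.append("intercept")
        for factor in self.design_factors:
            if factor == "rep:set":
                rc, sc = table.design_cols[0], table.design_cols[1]
                vals = (table.data[rc].astype(str) + ":"
                        + table.data[sc].astype(str)).to_numpy()
            else:
                vals = table.data[factor].astype(str).to_numpy()
            levels = sorted(np.unique(vals))
            Z = (vals[:, None] == np.array(levels[1:])[None, :]).astype(float)
            cols.append(Z)
            names += [f"{factor}={lv}" for lv in levels[1:]]
        X = np.hstack(cols)
        if X.shape[1] > 1:
            # drop collinear columns (realized factor cells can alias the
            # group or replication indicators); pivoted QR keeps a full-rank,
            # deterministic subset
            from scipy.linalg import qr

            _, R, piv = qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            keep = sorted(piv[: int((diag > 1e-8 * diag[0]).sum())])
            X = X[:, keep]
            names = [names[k] for k in keep]
        return X, names


@dataclass
class McmcChain:
    """Retained, thinned post-burn-in samples of one Gibbs chain."""

    traits: list[str]
    ids: list[str]
    kinship_kind: str
    settings: ChainSettings
    traces: GibbsTraces
    model: str = "MTM"          # or "SEM"
    lambda_mask: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.traces.Sigma_a.shape[0]

    @property
    def bv_mean(self) -> pd.DataFrame:
        return pd.DataFrame(self.traces.bv_mean, index=self.ids, columns=self.traits)

    def h2_samples(self) -> np.ndarray:
        """(m, t) heritability per retained sample."""
        va = np.einsum("mii->mi", self.traces.Sigma_a)
        ve = np.einsum("mii->mi", self.traces.R0)
        return va / (va + ve)

    def genetic_correlation_samples(self) -> np.ndarray:
        """(m, t, t) genetic correlation matrices per retained sample."""
        Sa = self.traces.Sigma_a
        sd = np.sqrt(np.einsum("mii->mi", Sa))
        return Sa / (sd[:, :, None] * sd[:, None, :])


@dataclass
class PosteriorSummary:
    """Posterior means/SDs/HPDs plus heritability, correlation and DIC."""

    variance_table: pd.DataFrame
    correlations: pd.DataFrame
    dic_components: dict[str, float]
    hpd_level: float
    model: str
    kinship_kind: str


def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """Narrow-sense heritability sigma2_a / (sigma2_a + sigma2_e)."""
    return sigma2_a / (sigma2_a + sigma2_e)


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `level` posterior mass."""
    x = np.sort(np.asarray(samples).ravel())
    m = len(x)
    k = max(int(np.ceil(level * m)), 2)
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: m - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def fit_mtm(
    traits: TraitTable,
    kinship: RelationshipMatrix,
    spec: MtmSpec | None = None,
) -> McmcChain:
    """Fit the multitrait model; see the module docstring for the model.

    Trees are matched to the kinship by id; every phenotyped tree must be
    present in the relationship matrix. Missing trait records are imputed
    by Gibbs data augmentation.
    """
    spec = spec or MtmSpec()
    ids = traits.ids
    K = kinship.subset(ids)
    X, _ = spec.design_matrix(traits)
    tr = run_chain(
        traits.values(), X, K.values, spec.chain,
        lambda_mask=None, prior_df=spec.prior_df, prior_scale=spec.prior_scale,
    )
    return McmcChain(
        list(traits.trait_names), ids, kinship.kind, spec.chain, tr, model="MTM",
    )


def summarize(chain: McmcChain, hpd: float = 0.95) -> PosteriorSummary:
    """Posterior means, SDs and shortest HPD intervals of the key parameters.

    Heritabilities and correlations are computed per retained sample and then
    averaged, so the point estimate is the posterior mean of the ratio.
    """
    if chain.n_retained == 0:
        raise GibbsError("empty chain")
    t = len(chain.traits)
    va = np.einsum("mii->mi", chain.traces.Sigma_a)
    ve = np.einsum("mii->mi", chain.traces.R0)
    h2 = chain.h2_samples()
    rows = []
    for j, name in enumerate(chain.traits):
        row = {"trait": name}
        for label, s in (("va", va[:, j]), ("ve", ve[:, j]), ("h2", h2[:, j])):
            lo, hi = hpd_interval(s, hpd)
            row[f"{label}_mean"] = float(s.mean())
            row[f"{label}_sd"] = float(s.std(ddof=1))
            row[f"{label}_hpd_low"] = lo
            row[f"{label}_hpd_high"] = hi
        rows.append(row)
    var_table = pd.DataFrame(rows)
    corr = chain.genetic_correlation_samples().mean(axis=0)
    corr_table = pd.DataFrame(corr, index=chain.traits, columns=chain.traits)
    dbar, pd_eff, dic_val = dic(chain)
    return PosteriorSummary(
        variance_table=var_table,
        correlations=corr_table,
        dic_components={"Dbar": dbar, "pD": pd_eff, "DIC": dic_val},
        hpd_level=hpd,
        model=chain.model,
        kinship_kind=chain.kinship_kind,
    )


def dic(chain: McmcChain) -> tuple[float, float, float]:
    """Deviance information criterion (Spiegelhalter form).

    Returns (Dbar, pD, DIC) with Dbar the posterior mean deviance,
    pD = Dbar - D(posterior-mean parameters) and DIC = Dbar + pD.
    Lower DIC indicates a preferred model.
    """
    dev = chain.traces.deviance
    if dev.size == 0:
        raise GibbsError("chain carries no deviance trace")
    dbar = float(dev.mean())
    pd_eff = dbar - chain.traces.deviance_at_mean
    return dbar, pd_eff, dbar + pd_eff


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single scalar chain (arviz implementation)."""
    import arviz as az

    return float(az.ess(np.asarray(x)[None, :]))


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of a scalar chain."""
    import arviz as az

    x = np.asarray(x)
    half = len(x) // 2
    return float(az.rhat(np.stack([x[:half], x[half: 2 * half]])))


def convergence_report(chain: McmcChain, outdir: str | None = None) -> pd.DataFrame:
    """ESS and split-chain shrink factor per variance parameter, with
    optional trace and posterior-density plot files."""
    if chain.n_retained == 0:
        raise GibbsError("empty chain")
    va = np.einsum("mii->mi", chain.traces.Sigma_a)
    ve = np.einsum("mii->mi", chain.traces.R0)
    rows = []
    for j, name in enumerate(chain.traits):
        for label, s in (("va", va[:, j]), ("ve", ve[:, j])):
            rows.append({
                "parameter": f"{label}_{name}",
                "ess": effective_sample_size(s),
                "rhat": split_rhat(s),
                "mean": float(s.mean()),
            })
    report = pd.DataFrame(rows)
    if outdir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        os.makedirs(outdir, exist_ok=True)
        fig, axes = plt.subplots(len(chain.traits), 2,
                                 figsize=(9, 2 * len(chain.traits)),
                                 squeeze=False)
        for j, name in enumerate(chain.traits):
            axes[j, 0].plot(va[:, j], lw=0.3)
            axes[j, 0].set_ylabel(f"va {name}", fontsize=7)
            axes[j, 1].hist(va[:, j], bins=40, density=True)
        fig.tight_layout()
        path = os.path.join(outdir, f"trace_{chain.model.lower()}.png")
        fig.savefig(path, dpi=80)
        plt.close(fig)
        report.attrs["plot_file"] = path
        report.to_csv(os.path.join(outdir, f"convergence_{chain.model.lower()}.csv"),
                      index=False)
    return report
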