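"""Synthetic study generator: pedigrees, gene-dropped genotypes and trait
phenotypes with the statistical structure the downstream analysis assumes.

The generator emulates an open-pollinated conifer progeny trial: ~50
maternal half-sib families from ~52 founder parents, a dense biallelic SNP
panel, and nine standardized traits produced from a recursive causal system

    y_i = (I - Lambda)^-1 (x_i' beta + a_i + e_i)

with a ~ N(0, Sigma_a (x) K), e ~ N(0, R0 (x) I). The default truth is the
reference 12-edge network and its published structural coefficients and
variance components (see `pinesem.reference`). Replication and
set-within-replication shifts are added (and recorded) so the design
adjustment stage has something real to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .bn import DagStructure
from .kinship import GenotypeMatrix, build_A
from .pedigree import Pedigree, UNKNOWN
from .preprocess import TraitTable
from .sem import LambdaMatrix


class SimulationError(ValueError):
    pass


def reference_network(approach: str = "GBLUP") -> tuple[DagStructure, LambdaMatrix]:
    """The 12-edge consensus causal network with its published coefficients.

    Returns the DAG over the nine traits and the structural-coefficient
    matrix (strictly lower-triangular in the causal ordering
    WGR, LIMO, HT, CAR, RES, WD, T_MONO, DECL, C13).
    """
    edges = frozenset(ref.NETWORK_EDGES)
    dag = DagStructure(ref.TRAIT_ORDER, edges)
    lam_values = ref.lambda_true(approach)
    mask = lam_values != 0.0
    return dag, LambdaMatrix(ref.TRAIT_ORDER, mask, lam_values)


def _default_group_means(n_groups: int = 5, n_traits: int = 9) -> np.ndarray:
    # provenance-level fixed effects spanning one phenotypic SD
    return np.outer(np.linspace(-0.5, 0.5, n_groups), np.ones(n_traits))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trial.

    Defaults emulate the reference trial: ~400 offspring in 50
    open-pollinated families from 52 founders across 5 provenance groups,
    a 25K SNP panel, and the published causal network as the generative
    truth. `offspring_per_family` may be an int, an inclusive (low, high)
    range, or an explicit per-family size list.
    """

    n_founders: int = 52
    n_families: int = 50
    offspring_per_family: int | tuple[int, int] | list[int] = 8
    n_full_sib_families: int = 0
    full_sib_family_size: int = 2
    n_genetic_groups: int = 5
    n_snps: int = 25_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    missing_genotype_rate: float = 0.10
    trait_names: tuple[str, ...] = ref.TRAIT_ORDER
    Sigma_a_true: np.ndarray = field(default_factory=ref.sigma_a_true)
    R0_true: np.ndarray = field(default_factory=ref.r0_true)
    Lambda_true: np.ndarray = field(default_factory=ref.lambda_true)
    group_means: np.ndarray = field(default_factory=_default_group_means)
    design: tuple[int, int] = (5, 21)        # replications x sets
    rep_effect_sd: float = 0.5
    set_effect_sd: float = 0.3
    trait_missing_rates: dict[str, float] = field(
        default_factory=ref.trait_missing_rates
    )
    raw_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders <= 0 or self.n_families <= 0:
            raise SimulationError("founder and family counts must be positive")
        if self.n_founders < self.n_families:
            raise SimulationError("need at least one founder dam per family")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie in (0, 0.5]")
        for rate in [self.missing_genotype_rate,
                     *self.trait_missing_rates.values()]:
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("rates must be in [0, 1]")
        t = len(self.trait_names)
        self.Sigma_a_true = np.asarray(self.Sigma_a_true, dtype=float)
        self.R0_true = np.asarray(self.R0_true, dtype=float)
        self.Lambda_true = np.asarray(self.Lambda_true, dtype=float)
        for name, M in (("Sigma_a_true", self.Sigma_a_true),
                        ("R0_true", self.R0_true)):
            if M.shape != (t, t) or not np.allclose(M, M.T):
                raise SimulationError(f"{name} must be symmetric {t}x{t}")
            if np.linalg.eigvalsh(M)[0] <= 0:
                raise SimulationError(f"{name} must be positive definite")
        if self.Lambda_true.shape != (t, t) or np.triu(self.Lambda_true).any():
            raise SimulationError(
                "Lambda_true must be strictly lower-triangular in causal order"
            )
        self.group_means = np.asarray(self.group_means, dtype=float)
        if self.group_means.shape != (self.n_genetic_groups, t):
            raise SimulationError("group_means must be n_groups x n_traits")

    def family_sizes(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.offspring_per_family
        if isinstance(spec, int):
            sizes = np.full(self.n_families, spec)
        elif isinstance(spec, tuple):
            lo, hi = spec
            sizes = rng.integers(lo, hi + 1, size=self.n_families)
        else:
            sizes = np.asarray(list(spec), dtype=int)
            if len(sizes) != self.n_families:
                raise SimulationError("per-family size list length mismatch")
        if (sizes < 1).any():
            raise SimulationError("family sizes must be >= 1")
        return sizes


def lodgepole_scale_config(**overrides) -> SimulationConfig:
    """Conditions matching the reference trial's counts: 52 founder parents,
    47 open-pollinated families totalling 392 offspring, 25K SNPs."""
    base = 392 // 47
    sizes = [base + (1 if i < 392 - 47 * base else 0) for i in range(47)]
    defaults = dict(n_founders=52, n_families=47, offspring_per_family=sizes,
                    n_snps=25_000)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset plus the truth that generated it."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix | None
    traits: TraitTable
    true_bvs: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self) -> None:
        ped_ids = set(self.pedigree.ids)
        missing = [i for i in self.traits.ids if i not in ped_ids]
        if missing:
            raise SimulationError(f"phenotyped trees not in pedigree: {missing[:5]}")
        if len(self.true_bvs) != len(self.traits.ids):
            raise SimulationError("true BV rows must match phenotyped trees")


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Founders plus open-pollinated (and optional full-sib) families.

    Founders have unknown parents and carry a genetic-group label assigned
    round-robin across provenance groups; offspring inherit the dam's group.
    Open-pollinated offspring have a known dam and an unknown sire, which
    the A-matrix treats as a distinct unrelated male per mating — the
    classical half-sib assumption.
    """
    rng = np.random.default_rng(config.seed)
    founders = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    groups = [str(i % config.n_genetic_groups + 1) for i in range(config.n_founders)]
    rows = [
        {"id": f, "sire": UNKNOWN, "dam": UNKNOWN, "group": g}
        for f, g in zip(founders, groups)
    ]
    sizes = config.family_sizes(rng)
    dams = founders[: config.n_families]
    counter = 1
    for dam, size, g in zip(dams, sizes, groups):
        for _ in range(size):
            rows.append({"id": f"T{counter:04d}", "sire": UNKNOWN,
                         "dam": dam, "group": g})
            counter += 1
    if config.n_full_sib_families:
        sires = founders[config.n_families:]
        if len(sires) < 1:
            raise SimulationError("no founders left to act as full-sib sires")
        for k in range(config.n_full_sib_families):
            dam = dams[k % len(dams)]
            sire = sires[k % len(sires)]
            g = groups[founders.index(dam)]
            for _ in range(config.full_sib_family_size):
                rows.append({"id": f"T{counter:04d}", "sire": sire,
                             "dam": dam, "group": g})
                counter += 1
    return Pedigree(pd.DataFrame(rows))


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Mendelian gene drop through the pedigree.

    Founder allele counts are Binomial(2, p_k) with p_k uniform on
    `maf_range` per locus; offspring receive one uniformly chosen allele
    from each parent, and an unknown parent contributes a population draw
    Bernoulli(p_k). Missing entries are masked completely at random.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    order = pedigree.topological_order
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    haplo = np.zeros((n, 2, m), dtype=np.int8)
    parents = {row.id: (row.sire, row.dam) for row in pedigree.table.itertuples()}
    for ind in order:
        k = pos[ind]
        for slot, parent in enumerate(parents[ind]):
            if parent == UNKNOWN:
                haplo[k, slot] = rng.random(m) < p
            else:
                ph = haplo[pos[parent]]
                pick = rng.integers(0, 2, size=m)
                haplo[k, slot] = ph[pick, np.arange(m)]
    dosages = haplo.sum(axis=1).astype(float)
    if config.missing_genotype_rate > 0:
        mask = rng.random((n, m)) < config.missing_genotype_rate
        dosages[mask] = np.nan
    ids = [order[i] for i in range(n)]
    # report in pedigree input order
    perm = [pos[i] for i in pedigree.ids]
    return GenotypeMatrix(
        pedigree.ids, [f"snp{j + 1}" for j in range(m)], dosages[perm]
    )


def _raw_scale(y: np.ndarray, names: tuple[str, ...],
               rng: np.random.Generator) -> np.ndarray:
    """Map analysis-scale traits back to a field-like scale: exponentiate the
    log traits and bin the rust score into four ordered categories."""
    out = y.copy()
    idx = {n: i for i, n in enumerate(names)}
    for t in ("DECL", "LIMO", "T_MONO"):
        if t in idx:
            out[:, idx[t]] = np.exp(out[:, idx[t]])
    if "WGR" in idx:
        col = out[:, idx["WGR"]]
        qs = np.nanquantile(col, [0.25, 0.5, 0.75])
        out[:, idx["WGR"]] = 1.0 + np.searchsorted(qs, col)
    return out


def simulate_traits(
    pedigree_or_K,
    config: SimulationConfig,
    genotypes: GenotypeMatrix | None = None,
    kinship=None,
) -> SimulatedStudy:
    """Generate phenotypes for the pedigree's offspring via the reduced form.

    Additive effects are drawn with covariance Sigma_a (x) K, where K is
    the pedigree numerator matrix, a supplied relationship matrix, or (via
    the `kinship` keyword, e.g. a realized genomic G alongside a pedigree
    for groups and design) any positive-definite relationship over the
    phenotyped trees. Structural residuals are i.i.d. with covariance R0;
    phenotypes follow y = (I - Lambda)^-1 (X beta + a + e) plus design
    effects. Per-trait records are then masked completely at random at the
    configured rates.
    """
    if isinstance(pedigree_or_K, Pedigree):
        pedigree = pedigree_or_K
        kin = kinship if kinship is not None else build_A(pedigree)
        offspring = [
            row.id for row in pedigree.table.itertuples()
            if row.dam != UNKNOWN or row.sire != UNKNOWN
        ]
        group = pedigree.table.set_index("id").loc[offspring, "group"].astype(str)
    else:
        kin = pedigree_or_K
        offspring = list(kin.ids)
        group = pd.Series(["1"] * len(offspring), index=offspring)
        pedigree = Pedigree(pd.DataFrame({
            "id": offspring, "sire": UNKNOWN, "dam": UNKNOWN, "group": "1",
        }))
    rng = np.random.default_rng(config.seed + 2)
    t = len(config.trait_names)
    ids = kin.ids
    n_all = len(ids)
    Kv = kin.values + 1e-9 * np.eye(n_all)
    L_K = np.linalg.cholesky(Kv)
    L_Sa = np.linalg.cholesky(config.Sigma_a_true)
    a_all = L_K @ rng.standard_normal((n_all, t)) @ L_Sa.T

    pos = {ind: k for k, ind in enumerate(ids)}
    off_idx = np.array([pos[i] for i in offspring])
    n = len(offspring)
    a = a_all[off_idx]

    levels = sorted(group.unique())
    Xg = (group.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    beta = config.group_means[[int(lv) - 1 for lv in levels], :]
    L_R = np.linalg.cholesky(config.R0_true)
    e = rng.standard_normal((n, t)) @ L_R.T
    u = Xg @ beta + a + e
    inv = np.linalg.inv(np.eye(t) - config.Lambda_true)
    y = u @ inv.T

    # design layout and effects
    n_rep, n_set = config.design
    rep = rng.integers(1, n_rep + 1, size=n)
    set_ = rng.integers(1, n_set + 1, size=n)
    rep_eff = rng.normal(0.0, config.rep_effect_sd, size=(n_rep, t))
    set_eff = rng.normal(0.0, config.set_effect_sd, size=(n_rep, n_set, t))
    y = y + rep_eff[rep - 1] + set_eff[rep - 1, set_ - 1]

    if config.raw_scale:
        y = _raw_scale(y, config.trait_names, rng)

    for j, name in enumerate(config.trait_names):
        rate = config.trait_missing_rates.get(name, 0.0)
        if rate > 0:
            y[rng.random(n) < rate, j] = np.nan

    data = pd.DataFrame({"id": offspring, "group": group.to_numpy(),
                         "rep": rep, "set": set_})
    for j, name in enumerate(config.trait_names):
        data[name] = y[:, j]
    traits = TraitTable(data, list(config.trait_names))
    true_bvs = pd.DataFrame(a, index=offspring, columns=config.trait_names)
    study = SimulatedStudy(pedigree, genotypes, traits, true_bvs, config)
    return study


def simulate_study(config: SimulationConfig,
                   with_genotypes: bool = True) -> SimulatedStudy:
    """Pedigree + (optional) genotypes + traits in one call."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config) if with_genotypes else None
    study = simulate_traits(ped, config, genotypes=geno)
    return study
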