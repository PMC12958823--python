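"""Reference values for the nine-trait interior lodgepole pine study system.

The package's synthetic-data generator and its acceptance checks are anchored
to the published genomic evaluation of an open-pollinated lodgepole pine
progeny trial: nine productivity, defense and climate-adaptability traits,
a 12-edge recursive causal network among them, and the multitrait (MTM) and
structural-equation (SEM) variance-component estimates obtained under
pedigree-based (ABLUP) and marker-based (GBLUP) relationship matrices.

All traits are on the analysis scale: log-transformed where applicable,
design-adjusted and standardized to zero mean, unit variance.

Trait abbreviations
-------------------
HT      total tree height (age 30)
WGR     western gall rust infection severity (4-category normal score)
WD      whole-tree wood density
RES     short-term drought resistance
DECL    long-term growth decline index (log scale)
C13     stable carbon isotope ratio of tree rings
LIMO    limonene concentration in phloem (log scale)
T_MONO  total monoterpene concentration in phloem (log scale)
CAR     mass-based carbon assimilation rate
"""

from __future__ import annotations

import numpy as np

#: Causal ordering of the nine traits: upstream (unconditioned) traits first.
#: Any strictly-lower-triangular structural coefficient matrix in this order
#: is acyclic by construction.
TRAIT_ORDER: tuple[str, ...] = (
    "WGR", "LIMO", "HT", "CAR", "RES", "WD", "T_MONO", "DECL", "C13",
)

#: Order in which the descriptive and variance-component tables list traits.
TABLE_ORDER: tuple[str, ...] = (
    "HT", "WGR", "WD", "RES", "DECL", "C13", "LIMO", "T_MONO", "CAR",
)

#: The 12 directed edges of the consensus causal network (Hill-Climbing,
#: 5,000 bootstrap replicates, 95% strength threshold), with the posterior
#: means of the structural coefficients lambda under each relationship matrix.
#: Keys are (parent, child); values are (ABLUP, GBLUP).
NETWORK_EDGES: dict[tuple[str, str], tuple[float, float]] = {
    ("HT", "WD"): (0.263, 0.413),
    ("HT", "C13"): (0.422, 0.565),
    ("HT", "CAR"): (-0.110, -0.254),
    ("WGR", "C13"): (0.011, 0.097),
    ("WGR", "CAR"): (-0.048, -0.195),
    ("WD", "DECL"): (0.117, 0.096),
    ("WD", "T_MONO"): (0.069, 0.086),
    ("RES", "DECL"): (-0.359, -0.509),
    ("LIMO", "RES"): (0.111, 0.205),
    ("LIMO", "T_MONO"): (0.252, 0.119),
    ("LIMO", "CAR"): (0.194, 0.368),
    ("T_MONO", "C13"): (0.159, 0.140),
}

#: Posterior means (posterior SDs) of additive and residual variances and
#: heritability per trait, for each model x relationship-matrix combination.
#: Layout: {model: {trait: {"ABLUP": (va, ve, h2), "GBLUP": (va, ve, h2)}}}.
VARIANCE_COMPONENTS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "MTM": {
        "HT":     {"ABLUP": (0.69, 0.28, 0.71), "GBLUP": (0.48, 0.47, 0.50)},
        "WGR":    {"ABLUP": (0.58, 0.49, 0.54), "GBLUP": (0.68, 0.40, 0.63)},
        "WD":     {"ABLUP": (0.62, 0.43, 0.59), "GBLUP": (0.60, 0.44, 0.58)},
        "RES":    {"ABLUP": (0.43, 0.63, 0.40), "GBLUP": (0.30, 0.75, 0.28)},
        "DECL":   {"ABLUP": (0.54, 0.59, 0.47), "GBLUP": (0.41, 0.70, 0.37)},
        "C13":    {"ABLUP": (0.64, 0.38, 0.63), "GBLUP": (0.53, 0.48, 0.52)},
        "LIMO":   {"ABLUP": (0.40, 0.65, 0.38), "GBLUP": (0.33, 0.73, 0.31)},
        "T_MONO": {"ABLUP": (0.31, 0.72, 0.30), "GBLUP": (0.29, 0.73, 0.28)},
        "CAR":    {"ABLUP": (0.27, 0.79, 0.25), "GBLUP": (0.25, 0.80, 0.24)},
    },
    "SEM": {
        "HT":     {"ABLUP": (0.59, 0.35, 0.63), "GBLUP": (0.51, 0.44, 0.53)},
        "WGR":    {"ABLUP": (0.75, 0.36, 0.67), "GBLUP": (0.74, 0.36, 0.67)},
        "WD":     {"ABLUP": (0.84, 0.25, 0.77), "GBLUP": (0.80, 0.28, 0.74)},
        "RES":    {"ABLUP": (0.47, 0.60, 0.43), "GBLUP": (0.44, 0.62, 0.42)},
        "DECL":   {"ABLUP": (0.43, 0.68, 0.38), "GBLUP": (0.48, 0.62, 0.44)},
        "C13":    {"ABLUP": (0.85, 0.21, 0.80), "GBLUP": (0.72, 0.34, 0.68)},
        "LIMO":   {"ABLUP": (0.54, 0.54, 0.49), "GBLUP": (0.38, 0.67, 0.36)},
        "T_MONO": {"ABLUP": (0.43, 0.63, 0.40), "GBLUP": (0.39, 0.65, 0.37)},
        "CAR":    {"ABLUP": (0.61, 0.54, 0.52), "GBLUP": (0.49, 0.63, 0.43)},
    },
}

#: Genetic correlations between traits under GBLUP: MTM in the upper triangle,
#: SEM in the lower triangle, keyed (row trait, column trait) in TABLE_ORDER.
#: Stored here as two separate symmetric lookups.
CORRELATIONS_MTM_GBLUP: dict[tuple[str, str], float] = {
    ("HT", "WGR"): 0.01, ("HT", "WD"): 0.47, ("HT", "RES"): -0.01,
    ("HT", "DECL"): -0.01, ("HT", "C13"): 0.49, ("HT", "LIMO"): 0.11,
    ("HT", "T_MONO"): 0.24, ("HT", "CAR"): -0.19,
    ("WGR", "WD"): -0.07, ("WGR", "RES"): 0.00, ("WGR", "DECL"): 0.16,
    ("WGR", "C13"): 0.29, ("WGR", "LIMO"): -0.11, ("WGR", "T_MONO"): -0.14,
    ("WGR", "CAR"): -0.25,
    ("WD", "RES"): -0.07, ("WD", "DECL"): 0.19, ("WD", "C13"): 0.21,
    ("WD", "LIMO"): 0.06, ("WD", "T_MONO"): 0.23, ("WD", "CAR"): 0.04,
    ("RES", "DECL"): -0.48, ("RES", "C13"): -0.12, ("RES", "LIMO"): 0.17,
    ("RES", "T_MONO"): -0.13, ("RES", "CAR"): 0.04,
    ("DECL", "C13"): 0.18, ("DECL", "LIMO"): 0.08, ("DECL", "T_MONO"): -0.05,
    ("DECL", "CAR"): -0.02,
    ("C13", "LIMO"): 0.00, ("C13", "T_MONO"): 0.20, ("C13", "CAR"): -0.11,
    ("LIMO", "T_MONO"): 0.04, ("LIMO", "CAR"): 0.17,
    ("T_MONO", "CAR"): 0.05,
}

CORRELATIONS_SEM_GBLUP: dict[tuple[str, str], float] = {
    ("WGR", "HT"): 0.00,
    ("WD", "HT"): 0.32, ("WD", "WGR"): 0.00,
    ("RES", "HT"): 0.00, ("RES", "WGR"): 0.00, ("RES", "WD"): 0.00,
    ("DECL", "HT"): 0.03, ("DECL", "WGR"): 0.00, ("DECL", "WD"): 0.12,
    ("DECL", "RES"): -0.49,
    ("C13", "HT"): 0.46, ("C13", "WGR"): 0.09, ("C13", "WD"): 0.15,
    ("C13", "RES"): 0.00, ("C13", "DECL"): 0.01,
    ("LIMO", "HT"): 0.00, ("LIMO", "WGR"): 0.00, ("LIMO", "WD"): 0.00,
    ("LIMO", "RES"): 0.17, ("LIMO", "DECL"): -0.08, ("LIMO", "C13"): 0.02,
    ("T_MONO", "HT"): 0.04, ("T_MONO", "WGR"): 0.00, ("T_MONO", "WD"): 0.11,
    ("T_MONO", "RES"): 0.03, ("T_MONO", "DECL"): 0.00, ("T_MONO", "C13"): 0.13,
    ("T_MONO", "LIMO"): 0.20,
    ("CAR", "HT"): -0.25, ("CAR", "WGR"): -0.22, ("CAR", "WD"): -0.08,
    ("CAR", "RES"): 0.06, ("CAR", "DECL"): -0.03, ("CAR", "C13"): -0.13,
    ("CAR", "LIMO"): 0.31, ("CAR", "T_MONO"): 0.05,
}

#: Effective number of parameters (pD) and DIC per model x approach.
DIC_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "MTM": {"ABLUP": (588.7, 6090.8), "GBLUP": (698.0, 6630.5)},
    "SEM": {"ABLUP": (1160.1, 5783.7), "GBLUP": (1189.7, 6415.9)},
}

#: Gibbs chain settings of the published analysis:
#: (total iterations, burn-in, thinning interval).
FULL_CHAIN: tuple[int, int, int] = (510_000, 10_000, 2)

#: Number of trees with records per trait, out of 392 genotyped trees.
RECORD_COUNTS: dict[str, int] = {
    "HT": 392, "WGR": 392, "WD": 367, "RES": 368, "DECL": 328,
    "C13": 392, "LIMO": 391, "T_MONO": 391, "CAR": 378,
}

N_TREES: int = 392
N_SNPS: int = 25_099


def trait_index(order: tuple[str, ...] = TRAIT_ORDER) -> dict[str, int]:
    """Map trait name -> position in `order`."""
    return {name: i for i, name in enumerate(order)}


def lambda_true(approach: str = "GBLUP",
                order: tuple[str, ...] = TRAIT_ORDER) -> np.ndarray:
    """Structural coefficient matrix with the published posterior means.

    Entry (r, j) is the coefficient of parent trait j in child trait r's
    equation; strictly lower-triangular when `order` is the causal ordering.
    """
    col = {"ABLUP": 0, "GBLUP": 1}[approach]
    idx = trait_index(order)
    lam = np.zeros((len(order), len(order)))
    for (parent, child), values in NETWORK_EDGES.items():
        lam[idx[child], idx[parent]] = values[col]
    return lam


def sigma_a_reduced(order: tuple[str, ...] = TRAIT_ORDER) -> np.ndarray:
    """Reduced-form (whole-effect) genetic covariance under GBLUP.

    Built from the MTM-GBLUP additive variances and genetic correlations;
    this is the covariance of the total genetic effects, causal mediation
    included. Symmetric positive definite.
    """
    idx = trait_index(order)
    t = len(order)
    corr = np.eye(t)
    for (a, b), r in CORRELATIONS_MTM_GBLUP.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    sd = np.sqrt([VARIANCE_COMPONENTS["MTM"][n]["GBLUP"][0] for n in order])
    return corr * np.outer(sd, sd)


def sigma_a_true(order: tuple[str, ...] = TRAIT_ORDER) -> np.ndarray:
    """Structural (direct-effect) genetic covariance under GBLUP.

    Derived from the reduced-form covariance and the causal structure as
    (I - Lambda) Sigma_red (I - Lambda)'. Its diagonal reproduces the
    published SEM additive variances closely for the upstream traits, where
    structural and reduced-form effects coincide; together with `r0_true`
    it implies marginal phenotype variances of ~1, matching the
    standardized analysis scale.
    """
    lam = lambda_true("GBLUP", order)
    IL = np.eye(len(order)) - lam
    return IL @ sigma_a_reduced(order) @ IL.T


def r0_true(order: tuple[str, ...] = TRAIT_ORDER) -> np.ndarray:
    """Structural residual covariance (diagonal) under GBLUP.

    The diagonal solves [ (I-Lambda)^-1 R0 (I-Lambda)^-T ]_jj = ve_j for
    the MTM-GBLUP residual variances ve, so that reduced-form residual
    variances match the published whole-effect values.
    """
    lam = lambda_true("GBLUP", order)
    inv = np.linalg.inv(np.eye(len(order)) - lam)
    ve_red = np.array([VARIANCE_COMPONENTS["MTM"][n]["GBLUP"][1] for n in order])
    return np.diag(np.linalg.solve(inv ** 2, ve_red))


def trait_missing_rates(order: tuple[str, ...] = TRAIT_ORDER) -> dict[str, float]:
    """Per-trait missing-record proportions implied by the record counts."""
    return {n: 1.0 - RECORD_COUNTS[n] / N_TREES for n in order}
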