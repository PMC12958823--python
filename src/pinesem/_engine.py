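"""Gibbs sampling engine for the multitrait and structural-equation models.

Model (structural scale; Lambda = 0 recovers the plain multitrait model):

    (I - Lambda) y_i = B' x_i + a_i + e_i
    a ~ N(0, Sigma_a (x) K),  e ~ N(0, R0 (x) I_q)

The kinship K is eigendecomposed once, K = U D U'; rotating trees by U'
diagonalizes the additive-effect prior so every tree's effect vector has an
independent conditional, while the i.i.d.-across-trees error term and the
fixed-effect cross-products are invariant under the rotation. Missing
phenotypes are imputed each sweep from their conditional normal on the
observed (reduced-form) scale, grouped by missingness pattern.

Full conditionals: matrix-normal for B (flat prior), per-tree multivariate
normal for a, inverse-Wishart for Sigma_a and R0 (or per-trait scaled
inverse-chi-squared when R0 is restricted to diagonal), and multivariate
normal for each child trait's row of free structural coefficients with a
N(0, v_lambda) prior.

The deviance traced for DIC is the observed-data multivariate normal
log-likelihood conditional on the tree effects (residual-level focus),
evaluated on the reduced-form mean and covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GibbsError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChainSettings:
    """Iteration plan of a single Gibbs chain."""

    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn-in must be smaller than total iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: Chain presets: the published full-length chain and desk-scale defaults.
CHAIN_PRESETS: dict[str, ChainSettings] = {
    "full": ChainSettings(510_000, 10_000, 2),
    "desk": ChainSettings(60_000, 10_000, 5),
    "cv": ChainSettings(8_000, 2_000, 4),
}


def retained_samples(iterations: int, burn_in: int, thin: int) -> int:
    """Number of post-burn-in, thinned samples a chain retains."""
    return ChainSettings(iterations, burn_in, thin).retained


@dataclass
class GibbsTraces:
    """Raw output of one chain run."""

    Sigma_a: np.ndarray          # (m, t, t)
    R0: np.ndarray               # (m, t, t)
    beta: np.ndarray             # (m, p, t)
    Lambda: np.ndarray | None    # (m, t, t) or None for the MTM
    deviance: np.ndarray         # (m,)
    bv_mean: np.ndarray          # (n, t) posterior mean additive effects
    bv_sd: np.ndarray            # (n, t)
    deviance_at_mean: float
    seed: int


def _rinvwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition."""
    t = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((t, t))
    A[np.tril_indices(t, -1)] = rng.standard_normal(t * (t - 1) // 2)
    A[np.diag_indices(t)] = np.sqrt(rng.chisquare(df - np.arange(t)))
    F = L @ A
    W = F @ F.T  # Wishart(df, scale^-1)
    return np.linalg.inv(W)


def _tril_indices(t: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(t)


def _log_prior_chol(L: np.ndarray, prior_df: float, prior_scale: float) -> float:
    """Log density of the inverse-Wishart prior expressed in Cholesky
    coordinates Sigma = L L' (absolute diagonals; includes the Jacobian
    2^t prod |l_ii|^(t-i+1))."""
    t = L.shape[0]
    diag = np.abs(np.diag(L))
    logdet_sigma = 2.0 * np.sum(np.log(diag))
    Linv = np.linalg.inv(L)
    tr_term = prior_scale * np.sum(Linv * Linv)
    log_jac = float(np.sum((t - np.arange(t)) * np.log(diag)))
    return (-0.5 * (prior_df + t + 1) * logdet_sigma - 0.5 * tr_term
            + log_jac)


def _asis_rescale_genetic(
    Astar, Sa, resid, R0inv, d, prior_df, prior_scale, rng,
):
    """Ancillarity-sufficiency interweaving move for (a, Sigma_a).

    Holding the whitened effects h = L^-1 a*_i / sqrt(d_i) fixed, the
    Cholesky factor L of Sigma_a has an exactly Gaussian likelihood
    conditional (resid_i = sqrt(d_i) L h_i + e_i); proposing from it makes
    the Metropolis correction the prior-times-Jacobian ratio alone. The
    move slides (a, Sigma_a) jointly along the genetic/residual scale
    ridge that single-block updates cross only by a random walk.

    Returns (Astar, Sa, accepted).
    """
    n, t = Astar.shape
    Lsa = np.linalg.cholesky(Sa)
    sq = np.sqrt(d)
    from scipy.linalg import solve_triangular

    h = solve_triangular(Lsa, (Astar / sq[:, None]).T, lower=True).T
    Hs = h * sq[:, None]
    M = Hs.T @ Hs
    C = Hs.T @ resid                       # C[k, j] = sum_i sqrt(d) h_ik r_ij
    rows, cols = _tril_indices(t)
    # precision of vec_lower(L): P[(j,k),(j',k')] = R0inv[j,j'] M[k,k']
    P = (R0inv[rows[:, None], rows[None, :]]
         * M[cols[:, None], cols[None, :]])
    rhs = (C @ R0inv)[cols, rows]
    try:
        Lp_chol = np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        return Astar, Sa, False
    mean = np.linalg.solve(P, rhs)
    draw = mean + np.linalg.solve(Lp_chol.T, rng.standard_normal(len(rhs)))
    L_prop = np.zeros((t, t))
    L_prop[rows, cols] = draw
    if np.any(np.abs(np.diag(L_prop)) < 1e-10):
        return Astar, Sa, False
    log_accept = (_log_prior_chol(L_prop, prior_df, prior_scale)
                  - _log_prior_chol(Lsa, prior_df, prior_scale))
    if np.log(rng.random()) >= log_accept:
        return Astar, Sa, False
    Astar_new = (h @ L_prop.T) * sq[:, None]
    # canonicalize signs so Sa's Cholesky has a positive diagonal
    flip = np.sign(np.diag(L_prop))
    L_prop = L_prop * flip[None, :]
    return Astar_new, L_prop @ L_prop.T, True


def _pattern_groups(missing: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by identical missingness pattern."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(missing):
        groups.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, rows in groups.items():
        pat = np.frombuffer(key, dtype=bool)
        out.append((np.array(rows), pat))
    return out


def _deviance(Yobs, groups, M, V) -> float:
    """-2 log of the observed-data normal likelihood given tree effects."""
    dev = 0.0
    for rows, pat in groups:
        o = ~pat
        no = int(o.sum())
        if no == 0:
            continue
        Voo = V[np.ix_(o, o)]
        L = np.linalg.cholesky(Voo)
        resid = Yobs[np.ix_(rows, o)] - M[np.ix_(rows, o)]
        z = np.linalg.solve(L, resid.T)
        quad = float(np.sum(z * z))
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        dev += len(rows) * (no * np.log(2.0 * np.pi) + logdet) + quad
    return dev


def run_chain(
    Y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    settings: ChainSettings,
    lambda_mask: np.ndarray | None = None,
    prior_df: float | None = None,
    prior_scale: float = 0.5,
    v_lambda: float = 1.0,
    diagonal_r0: bool = False,
    init: dict | None = None,
) -> GibbsTraces:
    """Sample the model; see module docstring for the update scheme.

    Parameters
    ----------
    Y : (n, t) phenotypes with NaN for missing records.
    X : (n, p) fixed-effect design (full column rank).
    K : (n, n) positive-definite kinship aligned with Y's rows.
    lambda_mask : (t, t) boolean, entry (r, j) True when trait j is a causal
        parent of trait r; None fits the plain multitrait model.
    prior_df, prior_scale : inverse-Wishart prior df (default t + 2) and
        scale multiplier for Sigma_a and R0.
    v_lambda : prior variance of each free structural coefficient.
    diagonal_r0 : restrict the residual covariance to a diagonal matrix.
    """
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    p = X.shape[1]
    if prior_df is None:
        prior_df = t + 2.0
    S0 = prior_scale * np.eye(t)
    rng = np.random.default_rng(settings.seed)

    d, U = np.linalg.eigh(K)
    if d.min() <= 1e-10:
        raise GibbsError(
            f"kinship smallest eigenvalue {d.min():.3e} <= 0; add diagonal "
            "regularization before fitting"
        )
    XtX = X.T @ X
    try:
        Cx = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as exc:
        raise GibbsError("fixed-effect design is rank deficient") from exc
    Xs = U.T @ X

    missing = np.isnan(Y)
    groups = _pattern_groups(missing)
    any_missing = bool(missing.any())
    sem = lambda_mask is not None
    if sem:
        lambda_mask = np.asarray(lambda_mask, dtype=bool)
        if lambda_mask.shape != (t, t) or lambda_mask.diagonal().any():
            raise GibbsError("lambda mask must be t x t with a zero diagonal")
        child_parents = [np.nonzero(lambda_mask[r])[0] for r in range(t)]

    # initial state (overridable for warm starts)
    init = init or {}
    col_mean = np.nanmean(Y, axis=0)
    Ycomp = np.where(missing, col_mean, Y)
    obs_var = np.nanvar(Y, axis=0, ddof=1)
    Sa = np.asarray(init.get("Sigma_a", np.diag(0.5 * obs_var + 1e-3)), dtype=float)
    R0 = np.asarray(init.get("R0", np.diag(0.5 * obs_var + 1e-3)), dtype=float)
    B = np.asarray(init.get("beta", np.zeros((p, t))), dtype=float)
    Astar = np.zeros((n, t))
    Lam = np.asarray(init.get("Lambda", np.zeros((t, t))), dtype=float).copy()
    I_t = np.eye(t)

    m = settings.retained
    tr_Sa = np.empty((m, t, t))
    tr_R0 = np.empty((m, t, t))
    tr_B = np.empty((m, p, t))
    tr_Lam = np.empty((m, t, t)) if sem else None
    tr_dev = np.empty(m)
    A_sum = np.zeros((n, t))
    A_sq = np.zeros((n, t))
    B_sum = np.zeros((p, t))
    Lam_sum = np.zeros((t, t))
    Vinv_sum = np.zeros((t, t))  # reduced-form precision, for the DIC plug-in

    kept = 0
    for sweep in range(1, settings.iterations + 1):
        IL = I_t - Lam
        invIL = np.linalg.inv(IL) if sem else I_t
        A_orig = U @ Astar
        Mu_struct = X @ B + A_orig            # structural-scale mean
        M_red = Mu_struct @ invIL.T            # reduced-form mean
        V_red = invIL @ R0 @ invIL.T if sem else R0

        # --- impute missing phenotypes from their conditional normal
        if any_missing:
            for rows, pat in groups:
                if not pat.any():
                    continue
                o, mm = ~pat, pat
                if o.any():
                    Voo = V_red[np.ix_(o, o)]
                    W = np.linalg.solve(Voo, V_red[np.ix_(o, mm)])
                    cond_cov = V_red[np.ix_(mm, mm)] - V_red[np.ix_(mm, o)] @ W
                    cond_mean = (M_red[np.ix_(rows, mm)]
                                 + (Ycomp[np.ix_(rows, o)] - M_red[np.ix_(rows, o)]) @ W)
                else:
                    cond_cov = V_red
                    cond_mean = M_red[rows]
                Lc = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(int(mm.sum())))
                z = rng.standard_normal((len(rows), int(mm.sum())))
                Ycomp[np.ix_(rows, mm)] = cond_mean + z @ Lc.T

        # --- rotate to the eigenbasis of K (structural scale)
        Ys = U.T @ Ycomp
        Zs = Ys @ IL.T if sem else Ys

        # --- fixed effects: matrix-normal full conditional, flat prior
        Bhat = np.linalg.solve(XtX, Xs.T @ (Zs - Astar))
        noise = np.linalg.solve(Cx.T, rng.standard_normal((p, t)))
        B = Bhat + noise @ np.linalg.cholesky(R0).T

        # --- structural coefficients: drawn with the tree effects
        # integrated out (marginal per-tree covariance d_i Sigma_a + R0),
        # which decouples lambda from the weakly identified genetic
        # covariance ridge; a is then redrawn below (blocked update)
        if sem:
            Vi = d[:, None, None] * Sa[None, :, :] + R0[None, :, :]
            Gi = np.linalg.inv(Vi)
            Mu_s = Xs @ B
            for r in range(t):
                P = child_parents[r]
                if P.size == 0:
                    continue
                Wr = Ys[:, P]
                res0 = Zs - Mu_s
                res0[:, r] = Ys[:, r] - Mu_s[:, r]
                q = np.einsum("ijk,ik->ij", Gi, res0)[:, r]
                prec_l = ((Wr * Gi[:, r, r][:, None]).T @ Wr
                          + np.eye(P.size) / v_lambda)
                Ll = np.linalg.cholesky(prec_l)
                mean_l = np.linalg.solve(prec_l, Wr.T @ q)
                lam_r = mean_l + np.linalg.solve(
                    Ll.T, rng.standard_normal(P.size))
                Lam[r, P] = lam_r
                Zs[:, r] = Ys[:, r] - Wr @ lam_r

        # --- tree effects: independent per tree in the rotated basis
        R0inv = np.linalg.inv(R0)
        Sainv = np.linalg.inv(Sa)
        resid = Zs - Xs @ B
        prec = R0inv[None, :, :] + Sainv[None, :, :] / d[:, None, None]
        Lp = np.linalg.cholesky(prec)
        rhs = resid @ R0inv
        y1 = np.linalg.solve(Lp, rhs[:, :, None])
        z2 = rng.standard_normal((n, t, 1))
        Astar = np.linalg.solve(np.transpose(Lp, (0, 2, 1)), y1 + z2)[:, :, 0]

        # --- interweaving move on the genetic scale (see _asis_rescale_genetic)
        Astar, Sa, _ = _asis_rescale_genetic(
            Astar, Sa, resid, R0inv, d, prior_df, prior_scale, rng)

        # --- covariance components
        scale_a = S0 + Astar.T @ (Astar / d[:, None])
        Sa = _rinvwishart(prior_df + n, scale_a, rng)
        E = resid - Astar
        if diagonal_r0:
            # per-trait scaled inverse-chi-squared matching the marginal of
            # the inverse-Wishart prior: shape (prior_df - t + 1)/2, scale S0_jj
            ss = prior_scale + np.einsum("ij,ij->j", E, E)
            R0 = np.diag(ss / rng.chisquare(prior_df - t + 1 + n, size=t))
        else:
            R0 = _rinvwishart(prior_df + n, S0 + E.T @ E, rng)
        if not np.all(np.isfinite(Sa)) or not np.all(np.isfinite(R0)):
            raise GibbsError(f"non-finite covariance draw at iteration {sweep}")

        # --- retain
        if sweep > settings.burn_in and (sweep - settings.burn_in) % settings.thin == 0:
            IL = I_t - Lam
            invIL = np.linalg.inv(IL) if sem else I_t
            A_orig = U @ Astar
            M_red = (X @ B + A_orig) @ invIL.T
            V_red = invIL @ R0 @ invIL.T if sem else R0
            tr_dev[kept] = _deviance(Y, groups, M_red, V_red)
            tr_Sa[kept] = Sa
            tr_R0[kept] = R0
            tr_B[kept] = B
            if sem:
                tr_Lam[kept] = Lam
            A_sum += A_orig
            A_sq += A_orig ** 2
            B_sum += B
            Lam_sum += Lam
            Vinv_sum += np.linalg.inv(V_red)
            kept += 1

    if kept == 0:
        raise GibbsError("chain retained no samples")
    bv_mean = A_sum / kept
    bv_sd = np.sqrt(np.maximum(A_sq / kept - bv_mean ** 2, 0.0))
    B_mean = B_sum / kept
    Lam_mean = Lam_sum / kept
    ILm = I_t - Lam_mean
    invILm = np.linalg.inv(ILm) if sem else I_t
    M_red = (X @ B_mean + bv_mean) @ invILm.T
    # plug-in covariance summarized on the precision scale: the deviance is
    # convex there, keeping the effective parameter count non-negative
    V_plug = np.linalg.inv(Vinv_sum / kept)
    dev_at_mean = _deviance(Y, groups, M_red, V_plug)

    return GibbsTraces(
        Sigma_a=tr_Sa, R0=tr_R0, beta=tr_B, Lambda=tr_Lam,
        deviance=tr_dev, bv_mean=bv_mean, bv_sd=bv_sd,
        deviance_at_mean=float(dev_at_mean), seed=settings.seed,
    )
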