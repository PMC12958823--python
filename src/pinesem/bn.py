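"""Gaussian Bayesian-network structure learning over decorrelated breeding
values.

Scores
------
Both scores are decomposable over node families and are computed from the
sufficient statistics (sample size, mean vector, centered cross-product
matrix) of the data, so a single pass over the data supports any number of
candidate structures.

* BIC: penalized Gaussian log-likelihood, ``logL - (d/2) log n`` per node
  with ``d = |parents| + 2`` (intercept, coefficients, residual SD). Larger
  is better.
* BGe: the Bayesian Gaussian equivalent marginal likelihood, computed as a
  ratio of subset marginal likelihoods so that Markov-equivalent DAGs score
  identically. Hyperparameters: prior mean zero, prior parametric matrix
  ``t * I``, imaginary sample sizes ``alpha_mu`` for the mean and
  ``alpha_w`` for the precision.

Search
------
Greedy hill climbing and tabu search over single-arc additions, deletions
and reversals, with deterministic lexicographic tie-breaking, plus
exhaustive enumeration for small node sets (the oracle for the heuristics)
and nonparametric bootstrap model averaging with arc strength/direction
summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import multigammaln

from .kinship import RelationshipMatrix


class BnError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data containers


@dataclass
class GaussianData:
    """Complete continuous data with cached sufficient statistics."""

    X: np.ndarray  # n x t
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise BnError("data shape does not match variable names")
        if np.isnan(self.X).any():
            raise BnError("structure learning requires complete data")
        self.n = self.X.shape[0]
        self.mean = self.X.mean(axis=0)
        centered = self.X - self.mean
        self.ssp = centered.T @ centered  # centered cross-products
        self.index = {v: i for i, v in enumerate(self.names)}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GaussianData":
        return cls(frame.to_numpy(dtype=float), tuple(frame.columns))


@dataclass(frozen=True)
class DagStructure:
    """Directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]  # (parent, child)

    def __post_init__(self) -> None:
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise BnError(f"edge ({p}, {c}) references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise BnError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DecorrelatedBvMatrix:
    """Breeding values transformed to remove kinship-induced row dependence."""

    values: pd.DataFrame  # trees x traits
    kinship_kind: str
    cholesky_note: str = "a* = L^{-1} a with K = L L'"

    def to_data(self) -> GaussianData:
        return GaussianData.from_frame(self.values)


@dataclass
class AveragedNetwork:
    """Bootstrap-averaged network: per-arc strength and direction confidence."""

    arcs: pd.DataFrame  # columns: from, to, strength, direction
    threshold: float
    consensus: DagStructure
    n_boot: int = 0

    def strength(self, a: str, b: str) -> float:
        """Presence frequency of the edge, in either orientation."""
        m = self.arcs[((self.arcs["from"] == a) & (self.arcs["to"] == b))
                      | ((self.arcs["from"] == b) & (self.arcs["to"] == a))]
        return float(m["strength"].iloc[0]) if len(m) else 0.0


# ---------------------------------------------------------------------------
# decorrelation


def decorrelate_bvs(
    bv: pd.DataFrame, kinship: RelationshipMatrix
) -> DecorrelatedBvMatrix:
    """Pre-multiply breeding values by the inverse Cholesky factor of K.

    With a ~ N(0, Sigma_a (x) K) and K = L L', the transformed values
    a* = L^{-1} a are independent across trees while the trait covariance
    Sigma_a is retained, which is the exchangeability the BN learners assume.
    """
    sub = kinship.subset([str(i) for i in bv.index])
    try:
        L = np.linalg.cholesky(sub.values)
    except np.linalg.LinAlgError as exc:
        raise BnError(
            "kinship is not positive definite; regularize before decorrelating"
        ) from exc
    transformed = solve_triangular(L, bv.to_numpy(dtype=float), lower=True)
    out = pd.DataFrame(transformed, index=bv.index, columns=bv.columns)
    return DecorrelatedBvMatrix(out, kinship.kind)


# ---------------------------------------------------------------------------
# scores


class _Scorer:
    """Cached decomposable local scores over one dataset."""

    def __init__(self, data: GaussianData, kind: str = "bic",
                 alpha_mu: float = 1.0, alpha_w: float | None = None,
                 prior_scale: float = 1.0):
        self.data = data
        self.kind = kind
        d = len(data.names)
        self.alpha_mu = alpha_mu
        self.alpha_w = alpha_w if alpha_w is not None else d + 2.0
        if self.alpha_w <= d - 1:
            raise BnError("alpha_w must exceed n_variables - 1")
        self.prior_scale = prior_scale
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        self._subset_cache: dict[frozenset[int], float] = {}
        if kind == "bge":
            n = data.n
            xbar = data.mean
            shrink = alpha_mu * n / (alpha_mu + n)
            self._R = (prior_scale * np.eye(d) + data.ssp
                       + shrink * np.outer(xbar, xbar))  # prior mean zero

    def local(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        if key not in self._cache:
            if self.kind == "bic":
                val = self._local_bic(node, parents)
            else:
                val = (self._log_subset_marginal(parents | {node})
                       - self._log_subset_marginal(parents))
            self._cache[key] = val
        return self._cache[key]

    def _resid_var(self, node: int, parents: tuple[int, ...]) -> float:
        ssp, n = self.data.ssp, self.data.n
        if not parents:
            return max(ssp[node, node] / n, 1e-300)
        P = list(parents)
        Spp = ssp[np.ix_(P, P)]
        spv = ssp[P, node]
        try:
            beta = np.linalg.solve(Spp, spv)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(Spp, spv, rcond=None)[0]
        return max((ssp[node, node] - spv @ beta) / n, 1e-300)

    def _local_bic(self, node: int, parents: frozenset[int]) -> float:
        n = self.data.n
        if len(parents) + 1 >= n:
            raise BnError(
                f"node has {len(parents)} parents but only {n} observations"
            )
        s2 = self._resid_var(node, tuple(sorted(parents)))
        loglik = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
        d_node = len(parents) + 2
        return loglik - 0.5 * d_node * np.log(n)

    def _log_subset_marginal(self, subset: frozenset[int]) -> float:
        """log marginal likelihood of the data restricted to `subset` under
        the projected normal-Wishart prior; local BGe scores are differences
        of these, so scores telescope to the joint marginal on complete DAGs.
        """
        if not subset:
            return 0.0
        key = subset
        if key in self._subset_cache:
            return self._subset_cache[key]
        Q = sorted(subset)
        ell = len(Q)
        n, d = self.data.n, len(self.data.names)
        aw, am, t = self.alpha_w, self.alpha_mu, self.prior_scale
        df = aw - d + ell
        TQ_logdet = ell * np.log(t)
        RQ = self._R[np.ix_(Q, Q)]
        sign, RQ_logdet = np.linalg.slogdet(RQ)
        if sign <= 0:
            raise BnError("posterior scatter matrix not positive definite")
        val = (
            -0.5 * ell * n * np.log(np.pi)
            + 0.5 * ell * np.log(am / (am + n))
            + multigammaln(0.5 * (n + df), ell)
            - multigammaln(0.5 * df, ell)
            + 0.5 * df * TQ_logdet
            - 0.5 * (n + df) * RQ_logdet
        )
        self._subset_cache[key] = val
        return val

    def total(self, dag: DagStructure) -> float:
        idx = self.data.index
        fams = {}
        for p, c in dag.edges:
            fams.setdefault(idx[c], set()).add(idx[p])
        return sum(
            self.local(i, frozenset(fams.get(i, ())))
            for i in range(len(self.data.names))
        )


def bic_score(data: GaussianData, dag: DagStructure) -> float:
    """Penalized-likelihood network score; larger is better."""
    return _Scorer(data, "bic").total(dag)


def bge_score(data: GaussianData, dag: DagStructure,
              alpha_mu: float = 1.0, alpha_w: float | None = None,
              prior_scale: float = 1.0) -> float:
    """Bayesian Gaussian equivalent score; equal on Markov-equivalent DAGs."""
    return _Scorer(data, "bge", alpha_mu, alpha_w, prior_scale).total(dag)


# ---------------------------------------------------------------------------
# search


def _has_path(children: dict[int, set[int]], src: int, dst: int) -> bool:
    stack = [src]
    seen = set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(children[u])
    return False


class _Graph:
    def __init__(self, t: int):
        self.parents = {i: set() for i in range(t)}
        self.children = {i: set() for i in range(t)}
        self.t = t

    def has_edge(self, p: int, c: int) -> bool:
        return c in self.children[p]

    def add(self, p: int, c: int) -> None:
        self.children[p].add(c)
        self.parents[c].add(p)

    def remove(self, p: int, c: int) -> None:
        self.children[p].discard(c)
        self.parents[c].discard(p)

    def would_cycle_add(self, p: int, c: int) -> bool:
        return _has_path(self.children, c, p)

    def would_cycle_reverse(self, p: int, c: int) -> bool:
        # reversing p->c to c->p cycles iff another p..c path exists
        self.remove(p, c)
        cyc = _has_path(self.children, p, c)
        self.add(p, c)
        return cyc

    def edge_list(self) -> list[tuple[int, int]]:
        return [(p, c) for p in range(self.t) for c in self.children[p]]


def _candidate_moves(g: _Graph):
    """Yield (child, parent, kind) moves in deterministic lexicographic
    order by (parent, child, kind). Enumerating parent-major means a tied
    pair of Markov-equivalent orientations resolves to the arc leaving the
    lower-indexed node, which keeps v-structures reachable by greedy search
    (and, on the trait panel, favors the upstream-first causal ordering)."""
    for p in range(g.t):
        for c in range(g.t):
            if p == c:
                continue
            if g.has_edge(p, c):
                yield (c, p, "delete")
                if not g.would_cycle_reverse(p, c):
                    yield (c, p, "reverse")
            elif not g.has_edge(c, p) and not g.would_cycle_add(p, c):
                yield (c, p, "add")


def _move_delta(scorer: _Scorer, g: _Graph, move: tuple[int, int, str]) -> float:
    c, p, kind = move
    pc = frozenset(g.parents[c])
    if kind == "add":
        return scorer.local(c, pc | {p}) - scorer.local(c, pc)
    if kind == "delete":
        return scorer.local(c, pc - {p}) - scorer.local(c, pc)
    pp = frozenset(g.parents[p])
    return (scorer.local(c, pc - {p}) - scorer.local(c, pc)
            + scorer.local(p, pp | {c}) - scorer.local(p, pp))


def _apply(g: _Graph, move: tuple[int, int, str]) -> None:
    c, p, kind = move
    if kind == "add":
        g.add(p, c)
    elif kind == "delete":
        g.remove(p, c)
    else:
        g.remove(p, c)
        g.add(c, p)


def _to_dag(g: _Graph, names: tuple[str, ...]) -> DagStructure:
    return DagStructure(
        names, frozenset((names[p], names[c]) for p, c in g.edge_list())
    )


def _make_scorer(data: GaussianData, score) -> _Scorer:
    if isinstance(score, _Scorer):
        return score
    if score in ("bic", "bge"):
        return _Scorer(data, score)
    raise BnError(f"unknown score {score!r}; use 'bic' or 'bge'")


def hill_climb(
    data: GaussianData,
    score: str = "bic",
    max_iter: int = 200,
    restarts: int = 0,
    seed: int | None = None,
) -> DagStructure:
    """Greedy search: apply the best strictly-improving single-arc move.

    Ties are broken by the lexicographic enumeration order
    (child, parent, move-type), making the no-restart search deterministic.
    Optional random restarts perturb the empty start with random arc
    additions and keep the best local optimum found.
    """
    scorer = _make_scorer(data, score)
    t = len(data.names)
    rng = np.random.default_rng(seed)

    def run(g: _Graph) -> tuple[_Graph, float]:
        for _ in range(max_iter):
            best, best_delta = None, 1e-10
            for move in _candidate_moves(g):
                delta = _move_delta(scorer, g, move)
                if delta > best_delta + 1e-12:  # ties keep the first move
                    best, best_delta = move, delta
            if best is None:
                break
            _apply(g, best)
        return g, scorer.total(_to_dag(g, data.names))

    g, best_score = run(_Graph(t))
    best_g = g
    for _ in range(restarts):
        g2 = _Graph(t)
        for _ in range(rng.integers(1, 2 * t)):
            p, c = rng.integers(0, t, size=2)
            if p != c and not g2.has_edge(p, c) and not g2.has_edge(c, p) \
                    and not g2.would_cycle_add(p, c):
                g2.add(p, c)
        g2, s2 = run(g2)
        if s2 > best_score:
            best_g, best_score = g2, s2
    return _to_dag(best_g, data.names)


def tabu_search(
    data: GaussianData,
    score: str = "bic",
    tabu_len: int = 10,
    max_iter: int = 100,
    seed: int | None = None,
) -> DagStructure:
    """Tabu search: best admissible move each step, improving or not.

    The inverse of each applied move is forbidden for `tabu_len` steps
    (aspiration: a tabu move is allowed if it beats the best score seen).
    Because strictly-improving moves are always preferred, the search visits
    the hill-climbing optimum before exploring, so the best structure
    returned scores at least as high.
    """
    scorer = _make_scorer(data, score)
    t = len(data.names)
    g = _Graph(t)
    current = scorer.total(_to_dag(g, data.names))
    best_edges = g.edge_list()
    best_score = current
    tabu: list[tuple[int, int, str]] = []
    stall = 0
    while stall < max_iter:
        best_move, best_delta = None, -np.inf
        for move in _candidate_moves(g):
            delta = _move_delta(scorer, g, move)
            if move in tabu and current + delta <= best_score + 1e-10:
                continue
            if delta > best_delta + 1e-12:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        _apply(g, best_move)
        current += best_delta
        c, p, kind = best_move
        inverse = {
            "add": (c, p, "delete"),
            "delete": (c, p, "add"),
            "reverse": (p, c, "reverse"),
        }[kind]
        tabu.append(inverse)
        if len(tabu) > tabu_len:
            tabu.pop(0)
        if current > best_score + 1e-10:
            best_score = current
            best_edges = g.edge_list()
            stall = 0
        else:
            stall += 1
    return DagStructure(
        data.names,
        frozenset((data.names[p], data.names[c]) for p, c in best_edges),
    )


def exhaustive_search(data: GaussianData, score: str = "bic") -> tuple[DagStructure, float]:
    """Score every DAG (feasible up to ~5 nodes) and return the maximum."""
    scorer = _make_scorer(data, score)
    t = len(data.names)
    if t > 5:
        raise BnError("exhaustive enumeration is limited to 5 nodes")
    pairs = list(itertools.combinations(range(t), 2))
    best_edges, best_val = None, -np.inf
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = _Graph(t)
        ok = True
        for (i, j), s in zip(pairs, states):
            if s == 0:
                continue
            p, c = (i, j) if s == 1 else (j, i)
            if g.would_cycle_add(p, c):
                ok = False
                break
            g.add(p, c)
        if not ok:
            continue
        val = sum(
            scorer.local(i, frozenset(g.parents[i])) for i in range(t)
        )
        if val > best_val:
            best_val, best_edges = val, g.edge_list()
    return (
        DagStructure(
            data.names,
            frozenset((data.names[p], data.names[c]) for p, c in best_edges),
        ),
        float(best_val),
    )


# ---------------------------------------------------------------------------
# bootstrap model averaging


def bootstrap_average(
    data: GaussianData,
    learner=None,
    n_boot: int = 5000,
    threshold: float = 0.95,
    seed: int | None = None,
) -> AveragedNetwork:
    """Nonparametric bootstrap of the structure learner.

    Arc strength is the fraction of replicates containing the edge in either
    orientation; direction confidence is the fraction of the reported
    orientation among replicates containing the edge. The consensus keeps
    arcs with strength >= threshold, oriented by majority; if majority
    orientations form a cycle, the arc with the lowest direction confidence
    is dropped until the graph is acyclic.
    """
    if n_boot < 1:
        raise BnError("n_boot must be >= 1")
    if learner is None:
        learner = hill_climb
    rng = np.random.default_rng(seed)
    names = data.names
    t = len(names)
    pair_ids = {frozenset((a, b)): k
                for k, (a, b) in enumerate(itertools.combinations(names, 2))}
    present = np.zeros(len(pair_ids))
    directed: dict[tuple[str, str], int] = {}
    n = data.n
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        boot = GaussianData(data.X[rows], names)
        dag = learner(boot)
        for p, c in dag.edges:
            present[pair_ids[frozenset((p, c))]] += 1
            directed[(p, c)] = directed.get((p, c), 0) + 1
    records = []
    for pair, k in pair_ids.items():
        if present[k] == 0:
            continue
        a, b = sorted(pair)
        n_ab = directed.get((a, b), 0)
        n_ba = directed.get((b, a), 0)
        frm, to = (a, b) if n_ab >= n_ba else (b, a)
        records.append({
            "from": frm,
            "to": to,
            "strength": present[k] / n_boot,
            "direction": max(n_ab, n_ba) / max(n_ab + n_ba, 1),
        })
    arcs = pd.DataFrame(records, columns=["from", "to", "strength", "direction"])
    arcs = arcs.sort_values("strength", ascending=False).reset_index(drop=True)
    keep = arcs[arcs["strength"] >= threshold].copy()
    keep = keep.sort_values("direction").reset_index(drop=True)
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(zip(keep["from"], keep["to"]))
        if nx.is_directed_acyclic_graph(g):
            break
        keep = keep.iloc[1:].reset_index(drop=True)  # lowest direction first
    consensus = DagStructure(names, frozenset(zip(keep["from"], keep["to"])))
    return AveragedNetwork(arcs, threshold, consensus, n_boot)


def arc_removal_delta(
    data: GaussianData, dag: DagStructure, score: str = "bic"
) -> pd.DataFrame:
    """Change in network score from removing each arc, sorted descending.

    Only the child's local score changes (decomposability), so the delta is
    local(child | parents) - local(child | parents - {arc parent}). Large
    positive values mark arcs the network cannot spare.
    """
    if not dag.edges:
        raise BnError("dag has no arcs")
    scorer = _make_scorer(data, score)
    idx = data.index
    rows = []
    for p, c in sorted(dag.edges):
        pc = frozenset(idx[q] for q in dag.parents(c))
        delta = scorer.local(idx[c], pc) - scorer.local(idx[c], pc - {idx[p]})
        rows.append({"from": p, "to": c, "delta": delta})
    out = pd.DataFrame(rows).sort_values("delta", ascending=False)
    return out.reset_index(drop=True)
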