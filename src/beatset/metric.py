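"""Mahalanobis metric learning to rank (MLR).

Learns a symmetric PSD matrix w so that, for each training query q,
sorting corpus samples by the similarity score

    g_w(q, x) = <w, phi(q, x)>,   phi(q, x) = -(q - x)(q - x)^T

(i.e. by ascending Mahalanobis distance) places same-class samples above
different-class ones.  A ranking y of the corpus is summarised by the
partial-order feature

    psi(q, y, X) = (1 / |X+||X-|) * sum_{i in X+} sum_{j in X-}
                   sign_ij * (phi_i - phi_j),

with sign_ij = +1 when relevant i precedes irrelevant j in y.  Training
minimises a regularized structural objective with one slack per query,

    min_w  R(w) + (C/|Q|) sum_q xi_q
    s.t.   <w, psi(q, y*)> >= <w, psi(q, y)> + Delta(y*, y) - xi_q
           for all q and all rankings y,    w PSD,

where Delta is the truncated reciprocal-rank loss: Delta = 1 - 1/r when
the first relevant item sits at position r <= k, else 1.  The
exponentially large constraint set is handled by cutting planes: a
separation oracle returns each query's loss-augmented most-violated
ranking, and the working-set problem is re-solved after each sweep.

The working-set subproblem is solved exactly in its dual by accelerated
projected gradient ascent (FISTA): with R(w) = a*tr(w) + (b/2)||w||_F^2
the inner minimiser over the PSD cone is w(alpha) =
Pi_PSD((A(alpha) - a I)/b) in closed form, so the PSD constraint lives
inside the subproblem and the returned metric is always PSD.  Frobenius
regularization ('frobenius', a=0, b=1) needs no perturbation; trace
regularization ('trace') takes a small quadratic damping
b = trace_smoothing to make the dual well-posed.

The learned metric factors as w = l'l (eigendecomposition), so measuring
Mahalanobis distance under w equals Euclidean distance after projecting
every vector with l.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable

__all__ = [
    "MetricModel",
    "RankingInstance",
    "Ranking",
    "mahal_score",
    "partial_order_feature",
    "ranking_score_sort",
    "query_loss",
    "separation_oracle",
    "train",
    "factorize",
]


@dataclass
class RankingInstance:
    """One query with its relevant (same-class) and irrelevant corpus samples."""

    query: np.ndarray
    relevant: np.ndarray
    irrelevant: np.ndarray

    def __post_init__(self) -> None:
        self.query = np.asarray(self.query, dtype=float)
        self.relevant = np.atleast_2d(np.asarray(self.relevant, dtype=float))
        self.irrelevant = np.atleast_2d(np.asarray(self.irrelevant, dtype=float))
        if self.relevant.shape[0] == 0 or self.irrelevant.shape[0] == 0:
            raise ValueError("relevant and irrelevant sets must both be non-empty")
        d = self.query.shape[0]
        if self.relevant.shape[1] != d or self.irrelevant.shape[1] != d:
            raise ValueError("query/corpus dimension mismatch")

    @property
    def n_relevant(self) -> int:
        return self.relevant.shape[0]

    @property
    def n_irrelevant(self) -> int:
        return self.irrelevant.shape[0]

    def items(self) -> np.ndarray:
        """Corpus items stacked: relevant rows first, then irrelevant."""
        return np.vstack([self.relevant, self.irrelevant])


@dataclass
class Ranking:
    """A total order over an instance's corpus items.

    ``order[p]`` is the item index (0..P+N-1, relevant first) placed at
    position p; position 0 is the top of the ranking.
    """

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)


def _check_ranking(instance: RankingInstance, ranking: Ranking) -> np.ndarray:
    n = instance.n_relevant + instance.n_irrelevant
    order = ranking.order
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError(
            f"ranking must be a permutation of the instance's {n} corpus items"
        )
    return order


def mahal_score(w: np.ndarray, q: np.ndarray, x: np.ndarray) -> float:
    """Similarity score <w, phi(q, x)> = -(q-x)' w (q-x); higher = more similar."""
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if q.shape != x.shape or w.shape != (q.shape[0], q.shape[0]):
        raise ValueError("dimension mismatch between w, q and x")
    u = q - x
    return float(-(u @ w @ u))


def _scores(w: np.ndarray, instance: RankingInstance) -> np.ndarray:
    u = instance.items() - instance.query
    return -np.einsum("ij,jk,ik->i", u, w, u)


def partial_order_feature(instance: RankingInstance, ranking: Ranking) -> np.ndarray:
    """The (symmetric, d x d) partial-order feature psi of a ranking.

    Each (relevant, irrelevant) pair contributes sign * (phi_i - phi_j)
    with sign +1 when the relevant item precedes the irrelevant one; the
    sum is normalised by |X+||X-|.  The ground-truth ranking (all relevant
    first) makes every sign +1.
    """
    order = _check_ranking(instance, ranking)
    P, N = instance.n_relevant, instance.n_irrelevant
    pos = np.empty(P + N, dtype=int)
    pos[order] = np.arange(P + N)
    sign = np.where(pos[:P, None] < pos[P:, None].T, 1.0, -1.0)  # (P, N)
    gamma = np.concatenate([sign.sum(axis=1), -sign.sum(axis=0)])
    u = instance.items() - instance.query
    # psi = sum_m gamma_m * phi_m / (P N), phi_m = -u_m u_m'
    return -(u * gamma[:, None]).T @ u / (P * N)


def ranking_score_sort(w: np.ndarray, instance: RankingInstance) -> Ranking:
    """The ranking maximising <w, psi>: items sorted by descending score.

    Ties break stably by original item index, so w = 0 returns the input
    order (relevant block first).
    """
    s = _scores(np.asarray(w, dtype=float), instance)
    return Ranking(order=np.argsort(-s, kind="stable"))


def query_loss(instance: RankingInstance, ranking: Ranking, k: int = 3) -> float:
    """Truncated reciprocal-rank loss 1 - S of a ranking, in [0, 1].

    S = 1/r when the first relevant item sits at (1-based) position
    r <= k, else S = 0.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    order = _check_ranking(instance, ranking)
    rel_positions = np.nonzero(order < instance.n_relevant)[0]
    if rel_positions.size == 0:
        raise ValueError("ranking contains no relevant item")
    r = int(rel_positions[0]) + 1
    return 1.0 - (1.0 / r if r <= k else 0.0)


def _loss_of_rank(r: int, k: int) -> float:
    return 1.0 - (1.0 / r if r <= k else 0.0)


def separation_oracle(
    w: np.ndarray, instance: RankingInstance, k: int = 3
) -> tuple[Ranking, float]:
    """Loss-augmented most-violated ranking and its constraint violation.

    Returns argmax over rankings y of ``Delta(y*, y) + <w, psi(y)>`` and
    ``violation = Delta + <w, psi(y)> - <w, psi(y*)>`` (the per-query
    slack is subtracted by the caller).  Exact for the truncated
    reciprocal-rank loss: with relevant and irrelevant items each sorted
    by descending score, the pair term decomposes over irrelevant items
    given how many relevant items precede each, and the loss depends only
    on how many irrelevant items precede all relevant ones; both parts
    are optimised jointly in closed form.
    """
    w = np.asarray(w, dtype=float)
    P, N = instance.n_relevant, instance.n_irrelevant
    s = _scores(w, instance)
    a_order = np.argsort(-s[:P], kind="stable")  # relevant, desc score
    b_order = np.argsort(-s[P:], kind="stable")  # irrelevant, desc score
    a = s[:P][a_order]
    b = s[P:][b_order]

    # M[j, t]: unnormalised pair contribution of irrelevant j when exactly
    # the t top relevant items precede it.
    pref = np.concatenate([[0.0], np.cumsum(a)])
    t_grid = np.arange(P + 1)
    M = (2.0 * pref - pref[P])[None, :] - np.outer(b, 2.0 * t_grid - P)

    c0 = M[:, 0]
    best_pos_t = np.argmax(M[:, 1:], axis=1) + 1
    best_pos_val = M[np.arange(N), best_pos_t]
    gains = c0 - best_pos_val
    gain_order = np.argsort(-gains, kind="stable")
    gain_csum = np.concatenate([[0.0], np.cumsum(gains[gain_order])])

    scale = 1.0 / (P * N)
    base = best_pos_val.sum()
    totals = np.array(
        [
            _loss_of_rank(1 + n0, k) + scale * (base + gain_csum[n0])
            for n0 in range(N + 1)
        ]
    )
    n0 = int(np.argmax(totals))

    t_assign = best_pos_t.copy()
    t_assign[gain_order[:n0]] = 0
    # Build the permutation: for t = 0..P, irrelevant items assigned t go
    # right after the t-th relevant item (within-block order: desc score).
    order: list[int] = []
    for t in range(P + 1):
        if t > 0:
            order.append(int(a_order[t - 1]))
        order.extend(int(P + b_order[j]) for j in range(N) if t_assign[j] == t)
    ranking = Ranking(order=np.array(order))

    psi_y_inner = scale * float(M[np.arange(N), t_assign].sum())
    psi_star_inner = float(a.mean() - b.mean())
    delta = _loss_of_rank(1 + n0, k)
    violation = delta + psi_y_inner - psi_star_inner
    return ranking, float(violation)


# ---------------------------------------------------------------------------
# Metric model and factorization
# ---------------------------------------------------------------------------

@dataclass
class MetricModel:
    """A learned Mahalanobis metric w, its factor l and training diagnostics."""

    w: np.ndarray
    l: np.ndarray
    C: float = 1.0
    regularizer: str = "frobenius"
    k: int = 3
    history: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    final_violation: float = 0.0

    def to_json(self, path: str) -> None:
        payload = {
            "w": self.w.tolist(),
            "l": self.l.tolist(),
            "C": self.C,
            "regularizer": self.regularizer,
            "k": self.k,
            "history": list(self.history),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_violation": self.final_violation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "MetricModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            w=np.array(payload["w"], dtype=float),
            l=np.array(payload["l"], dtype=float),
            C=payload["C"],
            regularizer=payload["regularizer"],
            k=payload["k"],
            history=payload["history"],
            converged=payload["converged"],
            n_iter=payload["n_iter"],
            final_violation=payload.get("final_violation", 0.0),
        )


def factorize(w: np.ndarray, rank_tol: float = 1e-8) -> np.ndarray:
    """Eigendecomposition-based factor l with w = l'l.

    Rows of l correspond to eigenvalues above ``rank_tol``; for any u, v
    the quadratic form (u-v)' w (u-v) equals ||l u - l v||^2.  Raises if w
    has an eigenvalue below -1e-6 times the largest (not PSD).
    """
    w = np.asarray(w, dtype=float)
    eigval, eigvec = np.linalg.eigh(0.5 * (w + w.T))
    max_eig = max(float(eigval.max(initial=0.0)), 0.0)
    if eigval.min(initial=0.0) < -1e-6 * max(max_eig, 1e-30):
        raise ValueError(
            f"matrix is not PSD: min eigenvalue {eigval.min():.3e} "
            f"(max eigenvalue {max_eig:.3e})"
        )
    keep = eigval > rank_tol
    return (eigvec[:, keep] * np.sqrt(eigval[keep])).T


# ---------------------------------------------------------------------------
# Working-set dual solver
# ---------------------------------------------------------------------------

def _project_psd(v: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(0.5 * (v + v.T))
    pos = eigval > 0
    if not pos.any():
        return np.zeros_like(v)
    return (eigvec[:, pos] * eigval[pos]) @ eigvec[:, pos].T


class _GroupProjector:
    """Vectorized projection onto {alpha >= 0, per-query block sums <= bound}.

    Blocks are padded into one (groups x max_block) matrix; rows whose sum
    exceeds the bound get the standard sorted-threshold simplex
    projection.  Padding zeros never receive mass, so they are harmless.
    """

    def __init__(self, qidx: np.ndarray, bound: float):
        uq, inv = np.unique(qidx, return_inverse=True)
        counts = np.bincount(inv)
        self.bound = bound
        self.rows = inv
        self.cols = np.zeros(len(qidx), dtype=int)
        seen = np.zeros(len(uq), dtype=int)
        for i, g in enumerate(inv):
            self.cols[i] = seen[g]
            seen[g] += 1
        self.shape = (len(uq), int(counts.max()))

    def __call__(self, alpha: np.ndarray) -> np.ndarray:
        out = np.maximum(alpha, 0.0)
        M = np.zeros(self.shape)
        M[self.rows, self.cols] = out
        over = M.sum(axis=1) > self.bound
        if over.any():
            sub = M[over]
            u = np.sort(sub, axis=1)[:, ::-1]
            css = np.cumsum(u, axis=1) - self.bound
            j = np.arange(1, self.shape[1] + 1)
            cond = u - css / j > 0
            rho = self.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)
            tau = css[np.arange(len(sub)), rho] / (rho + 1)
            M[over] = np.maximum(sub - tau[:, None], 0.0)
        return M[self.rows, self.cols]


class _WorkingSet:
    """Accumulated constraints and the exact FISTA dual solver."""

    def __init__(self, d: int, a_reg: float, b_reg: float, C_over_m: float):
        self.d = d
        self.a_reg = a_reg
        self.b_reg = b_reg
        self.bound = C_over_m
        self.psi_rows: list[np.ndarray] = []  # flattened delta-psi = psi* - psi_y
        self.deltas: list[float] = []
        self.qidx: list[int] = []
        self.alpha = np.zeros(0)

    def add(self, dpsi: np.ndarray, delta: float, q: int) -> None:
        self.psi_rows.append(dpsi.ravel())
        self.deltas.append(delta)
        self.qidx.append(q)
        self.alpha = np.concatenate([self.alpha, [0.0]])

    def slacks(self, w: np.ndarray, n_queries: int) -> np.ndarray:
        """Per-query slack xi_q(w) = max(0, max_c Delta_c - <dpsi_c, w>)."""
        xi = np.zeros(n_queries)
        if not self.psi_rows:
            return xi
        margins = np.asarray(self.deltas) - np.asarray(self.psi_rows) @ w.ravel()
        np.maximum.at(xi, np.asarray(self.qidx), margins)
        return np.maximum(xi, 0.0)

    def primal(self, w: np.ndarray, n_queries: int, C: float) -> float:
        reg = self.a_reg * np.trace(w) + 0.5 * self.b_reg * float(np.sum(w * w))
        return reg + (C / n_queries) * float(self.slacks(w, n_queries).sum())

    def _w_of_alpha(self, psi_mat: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        A = (psi_mat.T @ alpha).reshape(self.d, self.d)
        return _project_psd((A - self.a_reg * np.eye(self.d)) / self.b_reg)

    def solve(
        self,
        n_queries: int,
        C: float,
        max_fista: int = 20000,
        gap_tol: float = 1e-9,
    ) -> tuple[np.ndarray, float]:
        """Maximise the dual D(alpha) = Delta'alpha - (b/2)||w(alpha)||^2.

        Warm-started FISTA with per-query box/simplex projections; stops
        on a small primal-dual gap.  Returns the PSD primal metric and
        the primal working-set objective at it.
        """
        if not self.psi_rows:
            w = np.zeros((self.d, self.d))
            return w, self.primal(w, n_queries, C)
        psi_mat = np.asarray(self.psi_rows)
        deltas = np.asarray(self.deltas)
        project = _GroupProjector(np.asarray(self.qidx), self.bound)

        # Lipschitz constant of grad D: ||Psi||_2^2 / b  (power iteration).
        v = np.ones(psi_mat.shape[1])
        v /= np.linalg.norm(v)
        for _ in range(30):
            v = psi_mat.T @ (psi_mat @ v)
            nrm = np.linalg.norm(v)
            if nrm == 0:
                break
            v /= nrm
        lam = float(v @ (psi_mat.T @ (psi_mat @ v)))
        L = max(lam, 1e-12) / self.b_reg * 1.05
        step = 1.0 / L

        alpha = project(self.alpha)
        y = alpha.copy()
        t_mom = 1.0
        w = self._w_of_alpha(psi_mat, alpha)
        for it in range(1, max_fista + 1):
            w_y = self._w_of_alpha(psi_mat, y)
            grad = deltas - psi_mat @ w_y.ravel()
            alpha_new = project(y + step * grad)
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            y = alpha_new + ((t_mom - 1.0) / t_new) * (alpha_new - alpha)
            alpha, t_mom = alpha_new, t_new
            if it % 25 == 0 or it == max_fista:
                w = self._w_of_alpha(psi_mat, alpha)
                dual = float(deltas @ alpha) - 0.5 * self.b_reg * float(np.sum(w * w))
                prim = self.primal(w, n_queries, C)
                if prim - dual <= gap_tol * (1.0 + abs(prim)):
                    break
        self.alpha = alpha
        return w, self.primal(w, n_queries, C)


# ---------------------------------------------------------------------------
# Cutting-plane training loop
# ---------------------------------------------------------------------------

def train(
    features: FeatureTable,
    C: float = 1.0,
    regularizer: str = "frobenius",
    k: int = 3,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    trace_smoothing: float = 0.05,
) -> MetricModel:
    """Learn the metric by cutting planes over leave-one-out ranking queries.

    Every training sample serves once as the query, with all remaining
    training samples as its corpus.  Each outer iteration sweeps the
    queries, asks the separation oracle for the most-violated ranking,
    adds constraints violated by more than ``tol`` beyond the current
    slack, and re-solves the working-set dual exactly.  Stops when no
    query violates by more than ``tol``; if ``max_iter`` is reached first
    the best model is returned with ``converged=False`` and a warning.

    ``seed`` only fixes the query sweep order (the procedure is otherwise
    deterministic).
    """
    if regularizer not in ("trace", "frobenius"):
        raise ValueError(f"regularizer must be 'trace' or 'frobenius', got {regularizer!r}")
    X = np.asarray(features.matrix, dtype=float)
    labels = np.asarray(features.labels)
    m, d = X.shape
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(
            "training needs >= 2 classes with >= 2 samples each "
            f"(got {len(classes)} classes, min count {counts.min() if len(counts) else 0})"
        )

    a_reg, b_reg = (1.0, trace_smoothing) if regularizer == "trace" else (0.0, 1.0)
    ws = _WorkingSet(d, a_reg, b_reg, C / m)

    rng = np.random.default_rng(seed)
    sweep = rng.permutation(m)

    rel_masks = [np.delete(labels == labels[q], q) for q in range(m)]
    psi_star_flat = np.empty((m, d * d))
    instances: list[RankingInstance] = []
    for q in range(m):
        corpus = np.delete(X, q, axis=0)
        rel = rel_masks[q]
        inst = RankingInstance(
            query=X[q], relevant=corpus[rel], irrelevant=corpus[~rel]
        )
        instances.append(inst)
        P, N = inst.n_relevant, inst.n_irrelevant
        u_rel = inst.relevant - inst.query
        u_irr = inst.irrelevant - inst.query
        psi_star = -(u_rel.T @ u_rel) / P + (u_irr.T @ u_irr) / N
        psi_star_flat[q] = psi_star.ravel()

    w = np.zeros((d, d))
    history: list[float] = []
    max_violation = np.inf
    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        xi = ws.slacks(w, m)
        added = 0
        max_violation = -np.inf
        for q in sweep:
            inst = instances[q]
            ranking, raw_violation = separation_oracle(w, inst, k)
            violation = raw_violation - xi[q]
            max_violation = max(max_violation, violation)
            if violation > tol:
                psi_y = partial_order_feature(inst, ranking)
                dpsi = psi_star_flat[q].reshape(d, d) - psi_y
                delta = query_loss(inst, ranking, k)
                ws.add(dpsi, delta, int(q))
                added += 1
        if added == 0:
            converged = True
            break
        w, objective = ws.solve(m, C)
        history.append(objective)

    if not converged:
        warnings.warn(
            f"MLR training hit max_iter={max_iter} with max constraint "
            f"violation {max_violation:.3e} > tol={tol}; returning best model",
            RuntimeWarning,
        )
    l = factorize(w, rank_tol=1e-12)
    return MetricModel(
        w=w,
        l=l,
        C=C,
        regularizer=regularizer,
        k=k,
        history=history,
        converged=converged,
        n_iter=n_outer,
        final_violation=float(max_violation),
    )
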