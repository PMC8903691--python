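"""Effective-connectivity graph construction from virtual-sensor signals.

The effective-connectivity estimate proceeds in three stages:

1. **Correlation.**  Pearson correlation R(X_a, X_b) = C(X_a, X_b) /
   (S_a S_b) between every pair of virtual sensors.
2. **Thresholding.**  Each correlation is converted to a t value,
   ``Tp = R * sqrt((K - 2) / (1 - R^2))`` with K the number of data points,
   and a pair is retained only when the two-sided p-value of Tp under a
   Student t distribution with K - 2 degrees of freedom is below ``alpha``
   (default 0.01).
3. **Direction.**  For every retained pair, multivariate Granger causality
   decides directivity: source a drives b when a's past improves the
   prediction of b (log residual-variance ratio of the reduced vs full MVAR
   model, F-tested).  Exactly one significant direction gives a directed
   edge, both give a bidirectional edge, neither leaves the edge undirected.

Edges are signed by the correlation (positive = excitatory, negative =
inhibitory) and nodes are labelled driver / driven / mixed / isolated from
their directed degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .preprocessing import BandDefinition
from .source_reconstruction import VirtualSensorSet

__all__ = [
    "Direction",
    "ConnectivityEdge",
    "ConnectivityGraph",
    "pairwise_correlation",
    "t_threshold",
    "fit_mvar",
    "select_order_bic",
    "granger_direction",
    "classify_edges_and_nodes",
    "detect_pattern",
    "build_graph",
]


class Direction(str, Enum):
    A_TO_B = "a->b"
    B_TO_A = "b->a"
    BIDIRECTIONAL = "bidirectional"
    UNDIRECTED = "undirected"


@dataclass
class ConnectivityEdge:
    a: int
    b: int
    R: float
    Tp: float
    p_corr: float
    direction: Direction = Direction.UNDIRECTED
    gc_stat_ab: float = np.nan
    gc_stat_ba: float = np.nan

    @property
    def sign(self) -> str:
        """Excitatory for positively correlated source pairs, else inhibitory."""
        return "excitatory" if self.R > 0 else "inhibitory"


@dataclass
class ConnectivityGraph:
    n_sources: int
    edges: list[ConnectivityEdge]
    band: BandDefinition | None = None
    subject_id: str = ""
    region_labels: tuple[str, ...] | None = None
    node_roles: list[str] = field(default_factory=list)

    def adjacency(self) -> np.ndarray:
        """Binary undirected adjacency over retained edges."""
        adj = np.zeros((self.n_sources, self.n_sources), dtype=bool)
        for e in self.edges:
            adj[e.a, e.b] = adj[e.b, e.a] = True
        return adj

    def weight_matrix(self) -> np.ndarray:
        """Symmetric matrix of retained-edge correlations (0 where no edge)."""
        w = np.zeros((self.n_sources, self.n_sources))
        for e in self.edges:
            w[e.a, e.b] = w[e.b, e.a] = e.R
        return w


# ---------------------------------------------------------------------------
# correlation + thresholding


def pairwise_correlation(vs: VirtualSensorSet | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over sources (symmetric, unit diagonal).

    Sources with zero variance cannot be correlated; their off-diagonal
    entries are set to 0 with a warning instead of propagating NaN.
    """
    signals = vs.signals if isinstance(vs, VirtualSensorSet) else np.asarray(vs, float)
    signals = np.atleast_2d(signals)
    if signals.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = signals.std(axis=1)
    valid = sd > 0
    n = signals.shape[0]
    R = np.eye(n)
    if not np.all(valid):
        warnings.warn(
            f"sources {np.nonzero(~valid)[0].tolist()} have zero variance; "
            "excluded from correlation",
            stacklevel=2,
        )
    if valid.sum() >= 2:
        sub = np.corrcoef(signals[valid])
        R[np.ix_(valid, valid)] = sub
    np.fill_diagonal(R, 1.0)
    return R


def t_threshold(
    R: np.ndarray, K: int, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold a correlation matrix by the t value of each correlation.

    Returns (adjacency, Tp, p): ``Tp = R sqrt((K-2)/(1-R^2))`` and a pair is
    retained when the two-sided p-value of Tp with K - 2 degrees of freedom
    is below ``alpha``.  The diagonal is never retained.
    """
    if K <= 2:
        raise ValueError("K must exceed 2")
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Tp = R * np.sqrt((K - 2) / (1.0 - R**2))
        Tp = np.where(np.abs(R) >= 1.0, np.sign(R) * np.inf, Tp)
    p = 2.0 * stats.t.sf(np.abs(Tp), df=K - 2)
    adjacency = p < alpha
    np.fill_diagonal(adjacency, False)
    np.fill_diagonal(Tp, np.inf)
    np.fill_diagonal(p, 0.0)
    return adjacency, Tp, p


# ---------------------------------------------------------------------------
# MVAR fitting / Granger causality


def _as_segments(signals) -> list[np.ndarray]:
    if isinstance(signals, np.ndarray):
        return [np.atleast_2d(np.asarray(signals, float))]
    return [np.atleast_2d(np.asarray(s, float)) for s in signals]


def _design(segments: list[np.ndarray], order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stacked lagged design (rows x [n*order + 1]) and targets (rows x n).

    Each segment contributes its samples from ``order`` onward as targets;
    segment boundaries never leak lags across trials.
    """
    zs, ys = [], []
    for seg in segments:
        n, T = seg.shape
        if T <= order:
            raise ValueError("segment shorter than the model order")
        lags = [seg[:, order - k : T - k].T for k in range(1, order + 1)]
        z = np.hstack(lags + [np.ones((T - order, 1))])
        zs.append(z)
        ys.append(seg[:, order:].T)
    return np.vstack(zs), np.vstack(ys)


def fit_mvar(signals, order: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares MVAR fit over one array or a list of trial segments.

    Returns (coefficients with shape (order, n, n), innovation covariance,
    effective sample count).  The intercept is fitted but not returned.
    """
    segments = _as_segments(signals)
    n = segments[0].shape[0]
    Z, Y = _design(segments, order)
    n_eff = Z.shape[0]
    if n_eff < 10 * order * n:
        raise ValueError(
            f"too few samples ({n_eff}) for order {order} with {n} sources; "
            f"need >= {10 * order * n}"
        )
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    sigma = resid.T @ resid / n_eff
    coef = beta[:-1].T.reshape(n, order, n).transpose(1, 0, 2)
    return coef, sigma, n_eff


def select_order_bic(signals, max_order: int) -> int:
    """BIC model-order selection for the full MVAR system.

    All candidate orders are compared on the common sample base of the
    largest feasible order (each order's design is a column subset of the
    max-order design), which makes the comparison well-posed and cheap.
    """
    segments = _as_segments(signals)
    n = segments[0].shape[0]
    # largest order that still satisfies the sample-size precondition
    feasible = max_order
    while feasible > 1:
        n_eff = sum(max(s.shape[1] - feasible, 0) for s in segments)
        if n_eff >= 10 * feasible * n:
            break
        feasible -= 1
    Z, Y = _design(segments, feasible)
    n_eff = Z.shape[0]
    G = Z.T @ Z
    B = Z.T @ Y
    YtY = Y.T @ Y
    best, best_bic = 1, np.inf
    for p in range(1, feasible + 1):
        cols = np.concatenate([np.arange(p * n), [feasible * n]])
        try:
            beta = np.linalg.solve(G[np.ix_(cols, cols)], B[cols])
        except np.linalg.LinAlgError:
            continue
        sigma = (YtY - B[cols].T @ beta) / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k = n * (n * p + 1)
        bic = n_eff * logdet + k * np.log(n_eff)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def _rss_columns(G: np.ndarray, b: np.ndarray, yty: float, cols: np.ndarray) -> float:
    """RSS of OLS restricted to ``cols`` of the design, from normal equations."""
    Gs = G[np.ix_(cols, cols)]
    bs = b[cols]
    try:
        beta = np.linalg.solve(Gs, bs)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Gs, bs, rcond=None)
    return float(max(yty - bs @ beta, 0.0))


def granger_direction(
    signals,
    pairs: list[tuple[int, int]] | None = None,
    model_order_max: int = 5,
    conditional: bool = True,
    alpha: float = 0.05,
    order: int | None = None,
) -> dict[tuple[int, int], dict]:
    """Granger-causal direction for each source pair.

    ``signals`` is a sources x samples array or a list of per-trial segments
    (lags never cross trial boundaries).  For each unordered pair (a, b) the
    GC statistic a->b is ``ln(RSS_reduced / RSS_full)`` for predicting b with
    and without a's lags; significance is an F-test at ``alpha``.  With
    ``conditional=True`` the models condition on every other source in
    ``signals`` (multivariate GC); pairwise and conditional GC coincide
    exactly on two-source systems.

    Returns a dict mapping (a, b) to {direction, gc_ab, gc_ba, p_ab, p_ba,
    order}.  Rank-deficient regressions flag the pair undirected rather than
    failing.
    """
    segments = _as_segments(signals)
    n = segments[0].shape[0]
    if pairs is None:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    if order is None:
        order = select_order_bic(segments, model_order_max)

    results: dict[tuple[int, int], dict] = {}

    # cache one stacked design per source-index tuple: the conditional model
    # shares a single design across all pairs, the pairwise model one per pair
    design_cache: dict[tuple[int, ...], tuple] = {}

    def _system(idx: tuple[int, ...]):
        if idx not in design_cache:
            sub = segments if len(idx) == n else [seg[list(idx)] for seg in segments]
            Z, Y = _design(sub, order)
            G = Z.T @ Z
            B = Z.T @ Y
            yty = np.einsum("ij,ij->j", Y, Y)
            design_cache[idx] = (G, B, yty, Z.shape)
        return design_cache[idx]

    def _one_sided(idx: tuple[int, ...], src: int, dst: int) -> tuple[float, float]:
        """GC statistic and p-value for src -> dst within the model over idx."""
        G, B, yty, (n_eff, k_full) = _system(idx)
        m = len(idx)
        all_cols = np.arange(k_full)
        rss_full = _rss_columns(G, B[:, dst], float(yty[dst]), all_cols)
        src_cols = np.array([k * m + src for k in range(order)])
        red_cols = np.setdiff1d(all_cols, src_cols)
        rss_red = _rss_columns(G, B[:, dst], float(yty[dst]), red_cols)
        df2 = n_eff - k_full
        if rss_full <= 0 or df2 <= 0:
            raise np.linalg.LinAlgError("rank-deficient GC regression")
        gc = float(np.log(max(rss_red / rss_full, 1.0)))
        f_stat = ((rss_red - rss_full) / order) / (rss_full / df2)
        p = float(stats.f.sf(max(f_stat, 0.0), order, df2))
        return gc, p

    for a, b in pairs:
        if conditional:
            idx = tuple(range(n))
            ia, ib = a, b
        else:
            idx = (a, b)
            ia, ib = 0, 1
        try:
            gc_ab, p_ab = _one_sided(idx, ia, ib)
            gc_ba, p_ba = _one_sided(idx, ib, ia)
        except np.linalg.LinAlgError:
            results[(a, b)] = {
                "direction": Direction.UNDIRECTED,
                "gc_ab": np.nan,
                "gc_ba": np.nan,
                "p_ab": np.nan,
                "p_ba": np.nan,
                "order": order,
                "degenerate": True,
            }
            continue
        sig_ab, sig_ba = p_ab < alpha, p_ba < alpha
        if sig_ab and sig_ba:
            direction = Direction.BIDIRECTIONAL
        elif sig_ab:
            direction = Direction.A_TO_B
        elif sig_ba:
            direction = Direction.B_TO_A
        else:
            direction = Direction.UNDIRECTED
        results[(a, b)] = {
            "direction": direction,
            "gc_ab": gc_ab,
            "gc_ba": gc_ba,
            "p_ab": p_ab,
            "p_ba": p_ba,
            "order": order,
        }
    return results


# ---------------------------------------------------------------------------
# graph assembly


def classify_edges_and_nodes(graph: ConnectivityGraph) -> ConnectivityGraph:
    """Assign driver / driven / mixed / isolated roles from directed degrees.

    A node is a driver when its out-degree over directed edges exceeds its
    in-degree, driven when the reverse holds, mixed when both are equal and
    nonzero, isolated when it touches no retained edge.  Bidirectional edges
    count in both directions.
    """
    out_deg = np.zeros(graph.n_sources, dtype=int)
    in_deg = np.zeros(graph.n_sources, dtype=int)
    touched = np.zeros(graph.n_sources, dtype=bool)
    for e in graph.edges:
        touched[e.a] = touched[e.b] = True
        if e.direction in (Direction.A_TO_B, Direction.BIDIRECTIONAL):
            out_deg[e.a] += 1
            in_deg[e.b] += 1
        if e.direction in (Direction.B_TO_A, Direction.BIDIRECTIONAL):
            out_deg[e.b] += 1
            in_deg[e.a] += 1
    roles = []
    for i in range(graph.n_sources):
        if not touched[i]:
            roles.append("isolated")
        elif out_deg[i] > in_deg[i]:
            roles.append("driver")
        elif in_deg[i] > out_deg[i]:
            roles.append("driven")
        else:
            roles.append("mixed")
    graph.node_roles = roles
    return graph


def detect_pattern(
    graph: ConnectivityGraph,
    src_region: str = "PFC",
    dst_region: str = "TL",
    min_edges: int = 1,
) -> bool:
    """True when >= ``min_edges`` directed edges run src_region -> dst_region.

    A bidirectional edge contains the src->dst direction and counts; an
    undirected edge does not (direction matters).
    """
    if graph.region_labels is None:
        raise ValueError("graph has no region labels")
    labels = graph.region_labels
    count = 0
    for e in graph.edges:
        ab = labels[e.a] == src_region and labels[e.b] == dst_region
        ba = labels[e.b] == src_region and labels[e.a] == dst_region
        if e.direction == Direction.BIDIRECTIONAL and (ab or ba):
            count += 1
        elif e.direction == Direction.A_TO_B and ab:
            count += 1
        elif e.direction == Direction.B_TO_A and ba:
            count += 1
    return count >= min_edges


def build_graph(
    vs: VirtualSensorSet,
    gc_signals=None,
    alpha: float = 0.01,
    gc_alpha: float = 0.05,
    model_order_max: int = 5,
    gc_max_system: int = 20,
) -> ConnectivityGraph:
    """Full graph construction: correlate, threshold, direct, classify.

    Correlation and thresholding use ``vs.signals`` (typically the averaged
    evoked window, K = its sample count); Granger direction uses
    ``gc_signals`` when given (typically the per-trial windows, as a list of
    segments) and falls back to ``vs.signals``.  Systems larger than
    ``gc_max_system`` downgrade from conditional (multivariate) to pairwise
    GC with a warning.
    """
    R = pairwise_correlation(vs)
    K = vs.signals.shape[1]
    adjacency, Tp, p = t_threshold(R, K, alpha=alpha)
    pairs = [
        (a, b)
        for a in range(vs.n_sources)
        for b in range(a + 1, vs.n_sources)
        if adjacency[a, b]
    ]
    conditional = vs.n_sources <= gc_max_system
    if not conditional:
        warnings.warn(
            f"{vs.n_sources} sources exceed gc_max_system={gc_max_system}; "
            "downgrading to pairwise GC",
            stacklevel=2,
        )
    gc = {}
    if pairs:
        gc = granger_direction(
            gc_signals if gc_signals is not None else vs.signals,
            pairs=pairs,
            model_order_max=model_order_max,
            conditional=conditional,
            alpha=gc_alpha,
        )
    edges = [
        ConnectivityEdge(
            a=a,
            b=b,
            R=float(R[a, b]),
            Tp=float(Tp[a, b]),
            p_corr=float(p[a, b]),
            direction=gc[(a, b)]["direction"],
            gc_stat_ab=gc[(a, b)]["gc_ab"],
            gc_stat_ba=gc[(a, b)]["gc_ba"],
        )
        for a, b in pairs
    ]
    graph = ConnectivityGraph(
        n_sources=vs.n_sources,
        edges=edges,
        band=vs.band,
        subject_id=vs.subject_id,
        region_labels=tuple(vs.grid.region_labels),
    )
    return classify_edges_and_nodes(graph)
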