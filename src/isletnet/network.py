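"""Sparse-PLS pairwise omics integration and per-condition network assembly.

For one condition, the three layer pairs (transcript-protein,
transcript-metabolite, protein-metabolite) are each integrated by sparse
partial least squares: feature sets are first capped at 30% of each layer by
relative standard deviation, latent components are extracted from the
cross-covariance of the standardized blocks (at most ten, stopped by
leave-one-out Q^2), and a feature-feature association score is formed from
correlations with the latent variates.  Scores passing |r| >= 0.5 with raw
p < 0.05 (treated as Pearson correlations with n-2 df) become signed edges
of one union graph per condition, on which multilevel (Louvain) communities
and eigenvector centralities are computed.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import OmicsMatrix, ValidationError

__all__ = [
    "PlsModel",
    "AssociationNetwork",
    "rsd_cap_select",
    "fit_pls_pair",
    "association_matrix",
    "edge_filter",
    "assemble_network",
    "detect_communities",
    "eigenvector_centrality",
    "build_condition_network",
    "RSD_CAP",
    "EDGE_THRESHOLD",
    "EDGE_ALPHA",
    "MAX_COMPONENTS",
    "Q2_LIMIT",
]

logger = logging.getLogger(__name__)

RSD_CAP = 0.30
EDGE_THRESHOLD = 0.5
EDGE_ALPHA = 0.05
MAX_COMPONENTS = 10
Q2_LIMIT = 0.0975  # conventional Q^2 significance limit; minimum one component


# --------------------------------------------------------------------------
# feature capping
# --------------------------------------------------------------------------

def rsd_cap_select(m: OmicsMatrix, cap_fraction: float = RSD_CAP) -> OmicsMatrix:
    """Keep the top floor(cap_fraction * N) features by relative standard
    deviation (sd / |mean|); ties break to the smaller feature id.

    Features with mean exactly zero have no defined RSD and are excluded
    from the ranking with a warning.
    """
    if not (0 < cap_fraction <= 1):
        raise ValidationError(f"cap_fraction must be in (0,1], got {cap_fraction}")
    vals = m.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero_mean = mean == 0
    if zero_mean.all():
        raise ValidationError("all feature means are zero; RSD undefined")
    if zero_mean.any():
        logger.warning("rsd_cap_select: %d zero-mean features excluded", int(zero_mean.sum()))
    rsd = (sd / mean.abs()).where(~zero_mean)
    n_keep = int(np.floor(cap_fraction * m.n_features))
    n_keep = max(min(n_keep, int((~zero_mean).sum())), 0)
    ranking = rsd.dropna().rename("rsd").rename_axis("fid").reset_index()
    # ties break to the smaller feature id (stable sort)
    ranking = ranking.sort_values(["rsd", "fid"], ascending=[False, True], kind="mergesort")
    kept = set(ranking["fid"].head(n_keep))
    keep_ids = [f for f in m.feature_ids if f in kept]  # preserve original order
    logger.info("rsd_cap_select(%s): kept %d / %d", m.layer, len(keep_ids), m.n_features)
    return m.subset_features(keep_ids)


# --------------------------------------------------------------------------
# sparse PLS
# --------------------------------------------------------------------------

@dataclass
class PlsModel:
    """Fitted pairwise PLS model.

    ``x_loadings``/``y_loadings`` are (features x components) arrays,
    ``x_scores`` the (samples x components) latent variates of the X block,
    ``q2`` the per-component leave-one-out Q^2 used for stopping.
    """

    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    q2: list[float]
    x_ids: list[str] = field(default_factory=list)
    y_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.x_scores.shape[1]


def _standardize(a: np.ndarray) -> np.ndarray:
    """Column center/scale; zero-variance columns become all zeros."""
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (a - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def _soft_keep(w: np.ndarray, keep: int | None) -> np.ndarray:
    """Soft-threshold a weight vector to its ``keep`` largest entries."""
    if keep is None or keep >= w.size:
        return w
    thresh = np.sort(np.abs(w))[-keep - 1] if keep < w.size else 0.0
    out = np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)
    return out


def _dominant_pair(c: np.ndarray, keep_x: int | None, keep_y: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Dominant (optionally sparse) singular vector pair of a cross-covariance
    matrix, by alternating power iteration with a deterministic start."""
    p, q = c.shape
    v = np.ones(q) / np.sqrt(q)
    u = np.zeros(p)
    for _ in range(500):
        u_new = c @ v
        u_new = _soft_keep(u_new, keep_x)
        norm = np.linalg.norm(u_new)
        if norm == 0:
            break
        u_new /= norm
        v_new = c.T @ u_new
        v_new = _soft_keep(v_new, keep_y)
        norm = np.linalg.norm(v_new)
        if norm == 0:
            break
        v_new /= norm
        if np.linalg.norm(u_new - u) < 1e-12 and np.linalg.norm(v_new - v) < 1e-12:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    # deterministic sign: largest-magnitude X loading positive
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u, v = -u, -v
    return u, v


def _component_q2(xr: np.ndarray, yr: np.ndarray, keep_x, keep_y) -> float:
    """Leave-one-out Q^2 of the next component: 1 - PRESS/RSS.

    The component direction is taken from the full residual matrices and
    each fold refits only the variate-to-Y regression coefficient.  Refitting
    the direction per fold is unstable when two latent factors of similar
    strength compete for the dominant singular pair (the extracted direction
    then flips between folds and PRESS collapses to the baseline), whereas
    the fixed-direction form stays well calibrated on pure noise.
    """
    n = xr.shape[0]
    rss = float((yr**2).sum())
    if rss == 0:
        return -np.inf
    c = xr.T @ yr / (n - 1)
    u, _ = _dominant_pair(c, keep_x, keep_y)
    press = 0.0
    for i in range(n):
        idx = np.arange(n) != i
        t = xr[idx] @ u
        tt = float(t @ t)
        if tt == 0:
            continue
        coef = (t @ yr[idx]) / tt  # regression of Y residual on the variate
        y_hat = (xr[i] @ u) * coef
        press += float(((yr[i] - y_hat) ** 2).sum())
    return 1.0 - press / rss


def fit_pls_pair(
    x: OmicsMatrix,
    y: OmicsMatrix,
    max_components: int = MAX_COMPONENTS,
    keep_x: int | None = None,
    keep_y: int | None = None,
) -> PlsModel:
    """Fit a pairwise (sparse) PLS model between two layers.

    Both matrices must share sample columns (intersection is used, in X's
    order); blocks are standardized internally.  Components are extracted
    from the cross-covariance of the running residuals and deflated on the
    X variate; extraction continues while leave-one-out Q^2 >= 0.0975, at
    least one and at most ``max_components`` components.
    """
    shared = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared samples, got {len(shared)}")
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    xm = _standardize(x.values[shared].to_numpy(dtype=float).T)  # n x p
    ym = _standardize(y.values[shared].to_numpy(dtype=float).T)  # n x q
    n = xm.shape[0]

    xr, yr = xm.copy(), ym.copy()
    us, vs, ts, q2s = [], [], [], []
    for h in range(max_components):
        q2 = _component_q2(xr, yr, keep_x, keep_y)
        if h >= 1 and q2 < Q2_LIMIT:
            break
        c = xr.T @ yr / (n - 1)
        u, v = _dominant_pair(c, keep_x, keep_y)
        t = xr @ u
        tt = float(t @ t)
        if tt <= 1e-12 * n:
            break  # rank exhausted
        us.append(u)
        vs.append(v)
        ts.append(t)
        q2s.append(q2)
        # deflate both blocks on the X variate (regression-mode deflation)
        xr = xr - np.outer(t, (t @ xr) / tt)
        yr = yr - np.outer(t, (t @ yr) / tt)
    if not ts:
        raise ValidationError("could not extract any PLS component")
    return PlsModel(
        x_loadings=np.column_stack(us),
        y_loadings=np.column_stack(vs),
        x_scores=np.column_stack(ts),
        q2=q2s,
        x_ids=x.feature_ids,
        y_ids=y.feature_ids,
        sample_ids=shared,
    )


def _safe_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of each column of ``block`` with each score column;
    zero-variance columns get correlation 0."""
    bs = _standardize(block)
    ss = _standardize(scores)
    n = block.shape[0]
    return bs.T @ ss / (n - 1)


def association_matrix(model: PlsModel, x: OmicsMatrix, y: OmicsMatrix) -> pd.DataFrame:
    """Feature-feature association scores from latent-variate correlations.

    ``score(i, j) = sum_h cor(x_i, t_h) * cor(y_j, t_h)`` over the retained
    components' X variates ``t_h``, clipped to [-1, 1].  In the full-rank
    limit this reproduces the pairwise Pearson correlation between blocks.
    """
    shared = model.sample_ids
    xm = x.values[shared].to_numpy(dtype=float).T
    ym = y.values[shared].to_numpy(dtype=float).T
    zero_x = xm.std(axis=0) == 0
    zero_y = ym.std(axis=0) == 0
    if zero_x.any() or zero_y.any():
        logger.warning(
            "association_matrix: %d zero-variance features scored 0",
            int(zero_x.sum() + zero_y.sum()),
        )
    rx = _safe_corr(xm, model.x_scores)  # p x H
    ry = _safe_corr(ym, model.x_scores)  # q x H
    scores = np.clip(rx @ ry.T, -1.0, 1.0)
    scores[zero_x, :] = 0.0
    scores[:, zero_y] = 0.0
    return pd.DataFrame(scores, index=x.feature_ids, columns=y.feature_ids)


def correlation_p(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n_samples - 2
    denom = 1.0 - r**2
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(df / np.where(denom <= 0, np.inf, denom))
    p = 2 * sps.t.sf(t, df)
    return np.where(denom <= 0, 0.0, p)


def edge_filter(
    scores: pd.DataFrame,
    n_samples: int,
    threshold: float = EDGE_THRESHOLD,
    alpha: float = EDGE_ALPHA,
) -> pd.DataFrame:
    """Edges passing |score| >= threshold and correlation p < alpha.

    Returns a DataFrame with ``source``, ``target``, ``weight`` (signed
    score) and ``p`` columns, sorted by (source, target).
    """
    if n_samples < 3:
        raise ValidationError("edge p-values need n_samples >= 3")
    r = scores.to_numpy(dtype=float)
    p = correlation_p(r, n_samples)
    keep = (np.abs(r) >= threshold) & (p < alpha)
    si, ti = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "source": scores.index.to_numpy()[si],
            "target": scores.columns.to_numpy()[ti],
            "weight": r[si, ti],
            "p": p[si, ti],
        }
    )
    return out.sort_values(["source", "target"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# graph assembly and analysis
# --------------------------------------------------------------------------

@dataclass
class AssociationNetwork:
    """One condition's tri-omics association graph.

    Nodes carry ``layer`` (and later ``community``/``centrality``); edges
    carry signed ``weight`` in [-1, 1] and ``p``.  All edges are inter-layer
    by construction.
    """

    graph: ig.Graph
    condition: str = ""

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.vs["name"]) if self.graph.vcount() else []

    def nodes_table(self) -> pd.DataFrame:
        if self.graph.vcount() == 0:
            return pd.DataFrame(columns=["layer", "community", "centrality"]).rename_axis("node")
        data = {"layer": self.graph.vs["layer"]}
        for attr in ("community", "centrality"):
            if attr in self.graph.vs.attributes():
                data[attr] = self.graph.vs[attr]
        return pd.DataFrame(data, index=pd.Index(self.graph.vs["name"], name="node"))

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": self.graph.vs[e.source]["name"],
                "target": self.graph.vs[e.target]["name"],
                "weight": e["weight"],
                "p": e["p"],
            }
            for e in self.graph.es
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "p"])

    def write_graphml(self, path) -> None:
        self.graph.write_graphml(str(path))

    def write_edges_tsv(self, path) -> None:
        self.edges_table().to_csv(path, sep="\t", index=False)


def assemble_network(
    edge_lists: dict[tuple[str, str], pd.DataFrame],
    condition: str = "",
) -> AssociationNetwork:
    """Union graph over the three inter-layer edge lists.

    ``edge_lists`` maps (layer_of_source, layer_of_target) to an edge-filter
    output.  The node set is exactly the endpoints of retained edges.
    """
    node_layer: dict[str, str] = {}
    edges = []
    seen_pairs: set[tuple[str, str]] = set()
    for (lx, ly), df in edge_lists.items():
        if lx == ly:
            raise ValidationError("intra-layer edge blocks are not allowed")
        for row in df.itertuples(index=False):
            s, t = str(row.source), str(row.target)
            for node, layer in ((s, lx), (t, ly)):
                prior = node_layer.setdefault(node, layer)
                if prior != layer:
                    raise ValidationError(f"node {node!r} assigned to layers {prior} and {layer}")
            pair = (s, t) if s <= t else (t, s)
            assert pair not in seen_pairs, f"duplicate edge {pair} across blocks"
            seen_pairs.add(pair)
            edges.append((s, t, float(row.weight), float(row.p)))

    names = sorted(node_layer)
    g = ig.Graph()
    g.add_vertices(len(names))
    if names:
        g.vs["name"] = names
        g.vs["layer"] = [node_layer[n] for n in names]
    if edges:
        index = {n: i for i, n in enumerate(names)}
        g.add_edges([(index[s], index[t]) for s, t, _, _ in edges])
        g.es["weight"] = [w for _, _, w, _ in edges]
        g.es["p"] = [p for _, _, _, p in edges]
    return AssociationNetwork(graph=g, condition=condition)


def detect_communities(net: AssociationNetwork, seed: int = 0) -> pd.Series:
    """Multilevel (Louvain) modularity communities on absolute edge weights.

    Labels are stored on the graph and returned as node -> community id;
    deterministic under ``seed``.
    """
    g = net.graph
    if g.vcount() == 0:
        raise ValidationError("cannot detect communities on an empty graph")
    ig.set_random_number_generator(random.Random(seed))
    weights = [abs(w) for w in g.es["weight"]] if g.ecount() else None
    clustering = g.community_multilevel(weights=weights)
    g.vs["community"] = clustering.membership
    return pd.Series(clustering.membership, index=g.vs["name"], name="community")


def modularity(net: AssociationNetwork, membership) -> float:
    weights = [abs(w) for w in net.graph.es["weight"]] if net.graph.ecount() else None
    return float(net.graph.modularity(list(membership), weights=weights))


def eigenvector_centrality(
    net: AssociationNetwork,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> pd.Series:
    """Eigenvector centrality on the |weight| adjacency, by power iteration.

    Computed per connected component (with a +I spectral shift so bipartite
    components converge), each component's vector normalized to max 1 and
    scaled by the ratio of its principal eigenvalue to the graph's largest,
    so the overall maximum is exactly 1.  Stored on the graph and returned
    as node -> centrality.
    """
    g = net.graph
    if g.vcount() == 0:
        raise ValidationError("cannot compute centrality of an empty graph")
    n = g.vcount()
    adj = np.zeros((n, n))
    for e in g.es:
        w = abs(e["weight"])
        adj[e.source, e.target] = w
        adj[e.target, e.source] = w
    cent = np.zeros(n)
    eigvals = []
    components = list(g.connected_components())
    for comp in components:
        idx = np.array(comp)
        a = adj[np.ix_(idx, idx)]
        if len(idx) == 1 or a.sum() == 0:
            cent[idx] = 0.0
            eigvals.append(0.0)
            continue
        v = np.ones(len(idx)) / np.sqrt(len(idx))
        shifted = a + np.eye(len(idx))  # Perron vector unchanged; kills periodicity
        for it in range(max_iter):
            v_new = shifted @ v
            v_new /= np.linalg.norm(v_new)
            resid = np.max(np.abs(v_new - v))
            v = v_new
            if resid < tol:
                break
        else:
            raise ValidationError(f"power iteration did not converge; residual {resid:.2e}")
        lam = float(v @ a @ v)
        v = np.abs(v)
        cent[idx] = v / v.max()
        eigvals.append(lam)
    lam_max = max(eigvals) if eigvals else 0.0
    if lam_max > 0:
        for comp, lam in zip(components, eigvals):
            cent[np.array(comp)] *= lam / lam_max
    g.vs["centrality"] = cent.tolist()
    return pd.Series(cent, index=g.vs["name"], name="centrality")


def build_condition_network(
    matrices: dict[str, OmicsMatrix],
    condition: str,
    cap_fraction: float = RSD_CAP,
    threshold: float = EDGE_THRESHOLD,
    alpha: float = EDGE_ALPHA,
    max_components: int = MAX_COMPONENTS,
    seed: int = 0,
) -> AssociationNetwork:
    """Full per-condition pipeline: cap features, integrate the three layer
    pairs, filter edges, assemble the union graph, and attach communities
    and centralities.

    Block orientation is fixed: X = transcripts for transcript pairs, X =
    proteins for the protein-metabolite pair.
    """
    capped = {layer: rsd_cap_select(m, cap_fraction) for layer, m in matrices.items()}
    pairs = [("rna", "protein"), ("rna", "metabolite"), ("protein", "metabolite")]
    edge_lists: dict[tuple[str, str], pd.DataFrame] = {}
    for lx, ly in pairs:
        x, y = capped[lx], capped[ly]
        try:
            model = fit_pls_pair(x, y, max_components=max_components)
        except ValidationError as exc:
            logger.warning("skipping %s-%s block (%s)", lx, ly, exc)
            edge_lists[(lx, ly)] = pd.DataFrame(columns=["source", "target", "weight", "p"])
            continue
        scores = association_matrix(model, x, y)
        edge_lists[(lx, ly)] = edge_filter(
            scores, n_samples=len(model.sample_ids), threshold=threshold, alpha=alpha
        )
    net = assemble_network(edge_lists, condition=condition)
    if net.graph.vcount():
        detect_communities(net, seed=seed)
        eigenvector_centrality(net)
    return net
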