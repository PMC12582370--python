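"""Layer-by-layer sublineage calling.

Layer 0 clusters all elements: hierarchical clustering over angular
distances (when the radial assumption holds) and over module distances is
cut at the strongest merge-height jump, every cluster pair must pass a
fold-change/rank-sum soundness check, and an elastic principal tree fitted
to the 3D embedding refines labels along the trajectory layout. Final
clusters are validated by comparing inter- vs intra-cluster nucleotide
distances with a Wilcoxon rank-sum test; clusters that fail validation
against a sibling and are large enough are re-embedded and re-clustered in
isolation, down to a maximum depth or until the radial assumption of the
sub-embedding breaks down. Labels concatenate across layers ("A.2" =
second sub-cluster of layer-0 cluster A).
"""

from __future__ import annotations

import string
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .config import RunConfig
from .embedding import (
    EmbedParams,
    angular_matrix,
    deduplicate_sequences,
    embed_3d,
    levenshtein_matrix,
)
from .homology_graph import build_graph, call_modules, connected_components
from .io_formats import AlignmentHit, ElementRecord, truncate_hits
from .modseq import ModuleSequence, coverage_curve, encode

__all__ = [
    "ClusterAssignment",
    "PairValidation",
    "ValidationReport",
    "PrincipalTree",
    "PipelineResult",
    "agglomerative_cluster",
    "principal_tree_refine",
    "iterate_layers",
    "validate_clusters",
    "pairwise_identity",
]


@dataclass
class ClusterAssignment:
    element_id: str
    label: str  # sublineage ("A", "B.2", ...) or "unassigned"
    layer: int = 0
    confidence: str = "high"  # {"high", "low"}


@dataclass
class PairValidation:
    cluster_a: str
    cluster_b: str
    fold_change: float  # mean inter-cluster distance / mean intra-cluster distance
    p_value: float
    n_intra: int
    n_inter: int


@dataclass
class ValidationReport:
    pairs: list[PairValidation] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # singleton clusters, with note

    def failing(self, alpha: float) -> set[str]:
        bad: set[str] = set()
        for p in self.pairs:
            if p.fold_change <= 1.0 or p.p_value >= alpha:
                bad.add(p.cluster_a)
                bad.add(p.cluster_b)
        return bad

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_a\tcluster_b\tfold_change\tp_value\tn_intra\tn_inter\n")
            for p in self.pairs:
                fh.write(
                    f"{p.cluster_a}\t{p.cluster_b}\t{p.fold_change:.4g}\t"
                    f"{p.p_value:.4g}\t{p.n_intra}\t{p.n_inter}\n"
                )


@dataclass
class PrincipalTree:
    nodes: np.ndarray  # (k, 3) node positions
    edges: list[tuple[int, int]]
    node_labels: list[str]  # cluster label carried by each node

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.nodes.tolist(),
            "edges": [list(e) for e in self.edges],
            "node_labels": self.node_labels,
        }


@dataclass
class PipelineResult:
    assignments: list[ClusterAssignment]
    coords: dict[str, tuple[float, float, float]]
    tree: PrincipalTree | None
    validation: ValidationReport
    modules: list
    sequences: list[ModuleSequence]
    coverage: list[tuple[int, float]]
    radial_corr_by_layer: dict[str, float]

    def labels_dict(self) -> dict[str, str]:
        return {a.element_id: a.label for a in self.assignments}


# ---------------------------------------------------------------------------
# angular agglomerative clustering


def agglomerative_cluster(
    angles: np.ndarray,
    k_range: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
    linkage: str = "average",
) -> np.ndarray:
    """Cluster points by their pairwise angular distances.

    k is chosen within ``k_range`` by maximum mean silhouette on the angular
    metric. Degenerate inputs (all points in one direction) return a single
    cluster with a warning.
    """
    A = np.asarray(angles, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-8, equal_nan=True):
        raise ValueError("angle matrix must be square and symmetric")
    if np.isnan(A).any():
        raise ValueError("angle matrix contains NaN; exclude center points first")
    feasible = [k for k in k_range if 2 <= k <= n - 1]
    if not feasible:
        if any(k <= 1 for k in k_range) or n == 1:
            return np.zeros(n, dtype=int)
        raise ValueError(f"no feasible k in {list(k_range)} for n={n} points")
    if np.allclose(A, 0.0, atol=1e-6):
        warnings.warn("degenerate angular matrix (all points co-directional); one cluster")
        return np.zeros(n, dtype=int)
    best_labels, best_score = None, -np.inf
    for k in feasible:
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage=linkage)
        labels = model.fit_predict(A)
        if len(set(labels)) < 2:
            continue
        try:
            score = silhouette_score(A, labels, metric="precomputed")
        except ValueError:
            continue
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None:
        warnings.warn("silhouette degenerate for all k; returning a single cluster")
        return np.zeros(n, dtype=int)
    return best_labels


# ---------------------------------------------------------------------------
# elastic principal tree refinement


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distances from points to segment [a, b] and projection parameter t."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(len(points))
    else:
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1), t


def fit_principal_tree(
    points: np.ndarray,
    init_nodes: np.ndarray,
    stretch: float = 0.05,
    n_iter: int = 30,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Elastic principal tree: nodes initialized at cluster centroids, edges
    from the minimum spanning tree on centroids; node positions iteratively
    minimize squared point-to-node distance plus an edge-stretch penalty."""
    nodes = init_nodes.astype(float).copy()
    k = nodes.shape[0]
    D = np.linalg.norm(nodes[:, None, :] - nodes[None, :, :], axis=2)
    mst = minimum_spanning_tree(D).tocoo()
    edges = sorted((min(int(i), int(j)), max(int(i), int(j))) for i, j in zip(mst.row, mst.col))
    neighbors: list[list[int]] = [[] for _ in range(k)]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    lam = stretch * len(points) / max(k, 1)
    for _ in range(n_iter):
        d = np.linalg.norm(points[:, None, :] - nodes[None, :, :], axis=2)
        assign = d.argmin(axis=1)
        new_nodes = nodes.copy()
        for v in range(k):
            pts = points[assign == v]
            nb = neighbors[v]
            denom = len(pts) + lam * len(nb)
            if denom == 0:
                continue
            total = pts.sum(axis=0) + lam * nodes[nb].sum(axis=0)
            new_nodes[v] = total / denom
        shift = np.linalg.norm(new_nodes - nodes, axis=1).max()
        nodes = new_nodes
        if shift < tol:
            break
    return nodes, edges


def principal_tree_refine(
    points: np.ndarray, labels: np.ndarray, label_names: list[str] | None = None
) -> tuple[np.ndarray, PrincipalTree]:
    """Refine cluster labels along the fitted principal tree: each point is
    reassigned to the cluster of its nearest tree branch (nearest segment;
    the closer endpoint's cluster wins)."""
    labels = np.asarray(labels)
    uniq = sorted(set(int(x) for x in labels))
    if label_names is None:
        label_names = [str(u) for u in uniq]
    if len(uniq) < 2:
        tree = PrincipalTree(
            nodes=points.mean(axis=0, keepdims=True), edges=[], node_labels=[label_names[0]]
        )
        return labels.copy(), tree
    centroids = np.vstack([points[labels == u].mean(axis=0) for u in uniq])
    nodes, edges = fit_principal_tree(points, centroids)
    n = len(points)
    best_d = np.full(n, np.inf)
    best_node = np.zeros(n, dtype=int)
    if not edges:  # k nodes but MST empty can only mean k == 1, handled above
        edges = []
    for i, j in edges:
        d, t = _point_segment_distance(points, nodes[i], nodes[j])
        endpoint = np.where(t <= 0.5, i, j)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_node[upd] = endpoint[upd]
    # isolated nodes (no edges) still attract their own points
    if not edges:
        d = np.linalg.norm(points[:, None, :] - nodes[None, :, :], axis=2)
        best_node = d.argmin(axis=1)
    refined = np.array([uniq[v] for v in best_node])
    tree = PrincipalTree(nodes=nodes, edges=edges, node_labels=[label_names[u] for u in range(len(uniq))])
    return refined, tree


# ---------------------------------------------------------------------------
# pairwise nucleotide identity and cluster validation


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity over aligned columns of a global alignment (matches / columns)."""
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cigar = res["cigar"]
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            cols += ln
            if ch == "=":
                matches += ln
    return matches / cols if cols else 0.0


def validate_clusters(
    assignments: Sequence[ClusterAssignment],
    elements: Sequence[ElementRecord],
    n_sample: int = 20,
    seed: int = 42,
    max_pairs: int = 60,
) -> ValidationReport:
    """Compare inter- vs intra-cluster nucleotide distances (1 - identity).

    From each cluster, up to ``n_sample`` elements are drawn (low-confidence
    origin-proximal elements excluded first; clusters smaller than the sample
    use all members). For each cluster pair a rank-sum test asks whether
    inter-cluster distances exceed intra-cluster ones; the fold change of
    their means is reported.
    """
    if n_sample < 2:
        raise ValueError("n_sample must be >= 2")
    rng = np.random.default_rng(seed)
    seq_of = {e.element_id: e.seq for e in elements}
    members: dict[str, list[str]] = {}
    for a in assignments:
        if a.label == "unassigned":
            continue
        if a.confidence == "low":
            continue
        members.setdefault(a.label, []).append(a.element_id)
    # fall back to low-confidence members for clusters entirely near the origin
    lows: dict[str, list[str]] = {}
    for a in assignments:
        if a.label != "unassigned" and a.confidence == "low":
            lows.setdefault(a.label, []).append(a.element_id)
    for lab, ids in lows.items():
        members.setdefault(lab, ids)

    report = ValidationReport()
    samples: dict[str, list[str]] = {}
    for lab in sorted(members):
        ids = sorted(members[lab])
        if len(ids) < 2:
            report.excluded.append(f"{lab}: fewer than 2 members, excluded")
            continue
        if len(ids) > n_sample:
            ids = [ids[i] for i in rng.choice(len(ids), size=n_sample, replace=False)]
        samples[lab] = ids

    def _dists(pairs: list[tuple[str, str]]) -> np.ndarray:
        if len(pairs) > max_pairs:
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
        return np.array([1.0 - pairwise_identity(seq_of[a], seq_of[b]) for a, b in pairs])

    intra_cache: dict[str, np.ndarray] = {}
    labs = sorted(samples)
    for lab in labs:
        ids = samples[lab]
        intra_cache[lab] = _dists([(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))])
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            inter = _dists([(a, b) for a in samples[la] for b in samples[lb]])
            intra = np.concatenate([intra_cache[la], intra_cache[lb]])
            mean_intra = float(intra.mean()) if len(intra) else np.nan
            fold = float(inter.mean() / mean_intra) if mean_intra and mean_intra > 0 else np.inf
            if len(inter) and len(intra) and (inter.std() > 0 or intra.std() > 0):
                p = float(stats.mannwhitneyu(inter, intra, alternative="greater").pvalue)
            else:
                p = 1.0 if fold <= 1.0 else 0.0
            report.pairs.append(
                PairValidation(
                    cluster_a=la,
                    cluster_b=lb,
                    fold_change=fold,
                    p_value=p,
                    n_intra=len(intra),
                    n_inter=len(inter),
                )
            )
    return report


# ---------------------------------------------------------------------------
# layered pipeline


def _letters(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... deterministic cluster letters."""
    out = []
    for i in range(n):
        s = ""
        x = i
        while True:
            s = string.ascii_uppercase[x % 26] + s
            x = x // 26 - 1
            if x < 0:
                break
        out.append(s)
    return out


def _partition_sound(
    D: np.ndarray, labels: np.ndarray, alpha: float
) -> tuple[bool, float]:
    """Check a candidate partition against the fold-change/rank-sum protocol
    applied to the module-sequence distance matrix.

    Every cluster pair must show inter-cluster distances exceeding
    intra-cluster distances (fold change > 1, one-sided rank-sum p < alpha).
    Returns (sound, minimum fold change over pairs).
    """
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        return False, 0.0
    idx = {u: np.flatnonzero(labels == u) for u in uniq}
    min_fold = np.inf
    for a_i, a in enumerate(uniq):
        for b in uniq[a_i + 1 :]:
            ia, ib = idx[a], idx[b]
            inter = D[np.ix_(ia, ib)].ravel()
            intra_parts = []
            for ii in (ia, ib):
                if len(ii) > 1:
                    sub = D[np.ix_(ii, ii)]
                    intra_parts.append(sub[np.triu_indices(len(ii), 1)])
            if not intra_parts or not len(inter):
                return False, 0.0
            intra = np.concatenate(intra_parts)
            mi = intra.mean()
            fold = float(inter.mean() / mi) if mi > 0 else np.inf
            min_fold = min(min_fold, fold)
            if fold <= 1.0:
                return False, min_fold
            if intra.std() > 0 or inter.std() > 0:
                p = stats.mannwhitneyu(inter, intra, alternative="greater").pvalue
                if p >= alpha:
                    return False, min_fold
            # zero-variance case: fold > 1 already implies clean separation
    return True, float(min_fold)


def _jump_partition(
    M: np.ndarray, k_range: Sequence[int], split_jump: float, linkage_method: str
) -> np.ndarray | None:
    """Cut a hierarchical dendrogram at its strongest natural scale.

    The jump ratio at k is the merge height that reduces k clusters to k-1
    divided by the height of the preceding merge; a large ratio marks a gap
    between within-group and between-group scales. The largest k in range
    whose jump ratio reaches ``split_jump`` is chosen — the finest scale
    still showing a clear separation. Returns None when no scale qualifies.
    """
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    n = M.shape[0]
    if n < 3 or not k_range:
        return None
    Z = scipy_linkage(squareform(M, checks=False), method=linkage_method)
    h = Z[:, 2]
    best_k = None
    for k in k_range:
        if n - k - 1 < 0:
            continue
        below = h[n - k - 1]
        ratio = np.inf if below <= 0 else h[n - k] / below
        if ratio >= split_jump:
            best_k = k  # k_range ascending: keeps the largest qualifying k
    if best_k is None:
        return None
    return np.asarray(fcluster(Z, t=best_k, criterion="maxclust")) - 1


def _cluster_once(
    sequences: list[ModuleSequence],
    config: RunConfig,
    seed: int,
) -> tuple[dict[str, int], dict[str, tuple[float, float, float]], dict[str, str], float, np.ndarray | None, PrincipalTree | None, list[str]]:
    """One clustering pass over a set of module sequences.

    Candidate partitions are generated over both distance views — angular
    distances in the 3D embedding (the primary view, meaningful when the
    radial assumption holds) and the raw module-sequence distances — and
    over the whole k range. The finest candidate whose every cluster pair
    passes the fold-change/rank-sum soundness check on module distances is
    kept; when no candidate validates, the silhouette optimum over angular
    distances is used. This automates the manual adjust-and-refine loop that
    the identity validation is meant to support.

    Returns (cluster index per element, coords per element, confidence per
    element, radial correlation, point labels, tree, label names); elements
    with empty module sequences are absent from the cluster map.
    """
    usable = [s for s in sequences if len(s) > 0]
    uniq, groups = deduplicate_sequences(usable)
    n_pts = len(uniq)
    coords: dict[str, tuple[float, float, float]] = {}
    confidence: dict[str, str] = {}
    if n_pts < 3:
        cluster_of = {s.element_id: 0 for s in usable}
        for s in usable:
            coords[s.element_id] = (0.0, 0.0, 0.0)
            confidence[s.element_id] = "low"
        return cluster_of, coords, confidence, 0.0, None, None, ["A"]

    D = levenshtein_matrix([list(u) for u in uniq])
    # neighborhoods of roughly n/8 points keep local branch structure visible
    perplexity = min(config.perplexity, max(5.0, n_pts / 8.0), (n_pts - 1) / 3.0)
    params = EmbedParams(
        perplexity=perplexity,
        early_exaggeration=config.early_exaggeration,
        learning_rate=config.learning_rate,
        seed=seed,
    )
    lengths = np.array([len(u) for u in uniq], dtype=float)
    emb = embed_3d(D, params, seq_lengths=lengths)
    angles, valid = angular_matrix(emb)
    norms = emb.norms
    # origin-proximity low-confidence flag: lowest origin_quantile of norms
    cutoff = np.quantile(norms, config.origin_quantile) if config.origin_quantile > 0 else -1.0
    low_mask = norms <= cutoff if config.origin_quantile > 0 else np.zeros(n_pts, bool)

    idx_valid = np.flatnonzero(valid)
    sub_angles = angles[np.ix_(idx_valid, idx_valid)]
    D_valid = D[np.ix_(idx_valid, idx_valid)]
    k_range = [k for k in range(config.k_min, config.k_max + 1) if 2 <= k <= len(idx_valid) - 1]

    # candidate sources: angular distances (the primary view when the radial
    # assumption holds) and the module-sequence distances themselves
    radial_ok = (emb.radial_corr or 0.0) >= config.assumption_min_corr
    degenerate_angles = bool(np.allclose(sub_angles, 0.0, atol=1e-6))
    sources: list[tuple[int, np.ndarray, str]] = []
    if radial_ok and not degenerate_angles:
        sources.append((1, sub_angles, config.linkage))
    sources.append((0, D_valid, "ward"))

    best = None  # ((sound, k, min_fold, pref), labels)
    for pref, M, link in sources:
        cand = _jump_partition(M, k_range, config.split_jump, link)
        if cand is None:
            continue
        sound, min_fold = _partition_sound(D_valid, cand, config.alpha)
        # among validated candidates prefer the finest resolution: soundness
        # already guards every pair of the finer partition
        key = (sound, len(set(cand.tolist())), min_fold, pref)
        if best is None or key > best[0]:
            best = (key, cand)
    if best is not None and best[0][0]:
        labels_valid = best[1]
        base_fold = best[0][2]
    else:
        # no source shows a validated multi-cluster scale: leave unsplit
        labels_valid = np.zeros(len(idx_valid), dtype=int)
        base_fold = 0.0

    point_labels = np.zeros(n_pts, dtype=int)
    point_labels[idx_valid] = labels_valid
    tree: PrincipalTree | None = None
    if len(set(labels_valid.tolist())) >= 2:
        names = _letters(int(labels_valid.max()) + 1)
        refined, tree = principal_tree_refine(emb.coords[idx_valid], labels_valid, names)
        # trajectory refinement is accepted only when it keeps the partition
        # sound without weakening the validated separation
        if np.any(refined != labels_valid):
            sound, fold_ref = _partition_sound(D_valid, refined, config.alpha)
            if sound and fold_ref >= base_fold:
                point_labels[idx_valid] = refined
            else:
                point_labels[idx_valid] = labels_valid
        else:
            point_labels[idx_valid] = refined
    # center points (invalid for angles) adopt the nearest cluster centroid
    if (~valid).any() and len(idx_valid):
        cents = {
            lab: emb.coords[idx_valid][point_labels[idx_valid] == lab].mean(axis=0)
            for lab in set(point_labels[idx_valid].tolist())
        }
        for i in np.flatnonzero(~valid):
            dists = {lab: np.linalg.norm(emb.coords[i] - c) for lab, c in cents.items()}
            point_labels[i] = min(dists, key=dists.get)
            low_mask[i] = True

    cluster_of: dict[str, int] = {}
    for pt_idx, members in enumerate(groups):
        for orig_idx in members:
            eid = usable[orig_idx].element_id
            cluster_of[eid] = int(point_labels[pt_idx])
            coords[eid] = tuple(float(x) for x in emb.coords[pt_idx])
            confidence[eid] = "low" if low_mask[pt_idx] else "high"
    names = _letters(int(point_labels.max()) + 1)
    return cluster_of, coords, confidence, emb.radial_corr or 0.0, point_labels, tree, names


def iterate_layers(
    elements: Sequence[ElementRecord],
    hits: Sequence[AlignmentHit],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Full sublineage pipeline from elements and alignment hits.

    Layer 0 segments all elements into modules, encodes module sequences,
    embeds and clusters them. Clusters that fail pairwise validation against
    a sibling (fold change <= 1 or p >= alpha) and have at least
    ``min_split_size`` members are re-encoded against the modules present in
    the subset, re-embedded and re-clustered, until ``max_depth``, until the
    sub-embedding violates the radial assumption, or until clusters get too
    small.
    """
    config = config or RunConfig()
    elements = list(elements)
    hits = truncate_hits(list(hits), config.max_hits_per_query)
    graph = build_graph(
        hits,
        evalue_max=config.evalue_max,
        min_mutual_overlap=config.min_mutual_overlap,
        min_section_len=config.min_section_len,
    )
    comps = connected_components(graph)
    modules = call_modules(comps, config.min_members, config.min_mutual_overlap)
    sequences = encode(modules, elements, config.top_mod_num)
    cov = coverage_curve(sequences, list(range(1, 11))) if sequences else []

    seq_of = {s.element_id: s for s in sequences}
    radial_by_layer: dict[str, float] = {}
    final: dict[str, ClusterAssignment] = {}
    coords: dict[str, tuple[float, float, float]] = {}
    tree0: PrincipalTree | None = None
    validation0: ValidationReport | None = None

    def _process(eids: list[str], prefix: str, depth: int, seed: int) -> None:
        nonlocal tree0, validation0
        subset = [seq_of[e] for e in eids]
        nonempty = [s for s in subset if len(s) > 0]
        for s in subset:
            if len(s) == 0:
                final[s.element_id] = ClusterAssignment(s.element_id, "unassigned", depth, "low")
        if len(nonempty) < 2:
            for s in nonempty:
                lab = prefix or "A"
                final[s.element_id] = ClusterAssignment(s.element_id, lab, depth, "low")
            return
        if depth > 0:
            # re-encode: module spread recomputed within the subset, so the
            # retained top modules are the ones that discriminate inside it
            sub_elements = [e for e in elements if e.element_id in {s.element_id for s in nonempty}]
            re_encoded = encode(modules, sub_elements, config.top_mod_num)
            nonempty = [s for s in re_encoded if len(s) > 0]
            for s in re_encoded:
                if len(s) == 0:
                    final[s.element_id] = ClusterAssignment(s.element_id, prefix, depth - 1, "low")
            if len(nonempty) < 2:
                for s in nonempty:
                    final[s.element_id] = ClusterAssignment(s.element_id, prefix, depth - 1, "low")
                return
        cluster_of, sub_coords, conf, radial, _, tree, names = _cluster_once(
            nonempty, config, seed
        )
        radial_by_layer[prefix or "<root>"] = radial
        if depth == 0:
            coords.update(sub_coords)
            tree0 = tree
        if depth > 0 and radial < config.assumption_min_corr:
            # sub-embedding no longer fits the radial assumption: keep the
            # parent cluster whole
            for s in nonempty:
                final[s.element_id] = ClusterAssignment(
                    s.element_id, prefix, depth - 1, conf.get(s.element_id, "high")
                )
            return
        distinct = sorted(set(cluster_of.values()))
        k = len(distinct)
        if depth > 0 and k < 2:
            # no validated sub-scale: the parent cluster stays whole
            for s in nonempty:
                final[s.element_id] = ClusterAssignment(
                    s.element_id, prefix, depth - 1, conf.get(s.element_id, "high")
                )
            return
        if depth > 0:
            name_of = {c: f"{prefix}.{i + 1}" for i, c in enumerate(distinct)}
        else:
            letters = _letters(len(distinct))
            name_of = {c: letters[i] for i, c in enumerate(distinct)}
        by_label: dict[str, list[str]] = {}
        for s in nonempty:
            lab = name_of[cluster_of[s.element_id]]
            final[s.element_id] = ClusterAssignment(
                s.element_id, lab, depth, conf.get(s.element_id, "high")
            )
            by_label.setdefault(lab, []).append(s.element_id)
        if k < 2:
            return
        report = validate_clusters(
            [final[e] for ids in by_label.values() for e in ids],
            [e for e in elements if e.element_id in cluster_of],
            n_sample=config.n_sample,
            seed=seed,
        )
        if depth == 0:
            validation0 = report
        if depth >= config.max_depth:
            return
        for lab in sorted(report.failing(config.alpha)):
            ids = by_label.get(lab, [])
            if len(ids) >= config.min_split_size:
                child_seed = (seed + 1 + zlib.crc32(lab.encode()) % 1000) % (2**31)
                _process(ids, lab, depth + 1, child_seed)

    _process([e.element_id for e in elements], "", 0, config.seed)

    assignments = [final[e.element_id] for e in elements]
    return PipelineResult(
        assignments=assignments,
        coords=coords,
        tree=tree0,
        validation=validation0 or ValidationReport(),
        modules=modules,
        sequences=sequences,
        coverage=cov,
        radial_corr_by_layer=radial_by_layer,
    )
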