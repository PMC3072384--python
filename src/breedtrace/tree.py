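"""Breed decision tree: recursive clustering and hierarchical 5-NN assignment.

The full classification task is decomposed into a tree of nested breed
groups.  At each internal node, PCA is fitted to the node's training
individuals, breeds are grouped by k-means on the significant-PC
coordinates (each breed assigned whole to the cluster holding the
plurality of its members — breeds are atomic), and the procedure recurses
into each group until single-breed leaves.  The number of clusters, when
not given, maximises the mean silhouette over 2..min(6, #breeds),
automating what inspection of a PC scatter plot does.

Classification descends the tree: at each node the sample is projected
into the node's PC space (full-SNP or a panel tier; panel tiers use a
basis refit on the panel SNPs, since a deployed assay only measures those
markers) and voted on by its five nearest training neighbours.  A child
receiving at least three of the five neighbours wins; otherwise the
sample is left unassigned and the descent stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._voting import majority_label, neighbor_order
from .encoding import GenotypeMatrix, center_impute, filter_missing
from .pca import PCBasis, PCCoordinates, _svd, choose_num_pcs, fit_pca, numerical_rank, project
from .selection import SnpPanel, build_panels, pcaim_scores, top_candidates

FULL_MODE = "full"
CANDIDATE_MODE = "candidates"
TIER_MODES = ("P1", "P2", "P3")

# Reference hierarchy of the 19-breed worldwide cattle panel: zebu
# (B. indicus), taurine (B. taurus) and zebu-taurine hybrid groups at the
# root, with the taurine clade resolved over four further levels down to
# the recently diverged Angus / Red Angus pair.
PAPER_TOPOLOGY: dict = {
    "World": {
        "Bos indicus": ["Brahman", "Gir", "Nelore"],
        "Bos taurus": {
            "NDama": None,
            "European taurine": {
                "Holstein": None,
                "Hereford": None,
                "Jersey": None,
                "Brown Swiss": None,
                "Romagnola": None,
                "7 taurine": {
                    "Guernsey": None,
                    "Limousin": None,
                    "Charolais": None,
                    "Norwegian Red": None,
                    "Piedmontese": None,
                    "Angus-Red Angus": {"Angus": None, "Red Angus": None},
                },
            },
        },
        "Hybrid breeds": ["Beefmaster", "Santa Gertrudis", "Sheko"],
    }
}

# Per-node significant-PC counts and P1 panel sizes of the reference
# 19-breed configuration (P2 = 2*P1, P3 = 3*P1).
PAPER_NODE_K: dict[str, int] = {
    "World": 2,
    "Bos taurus": 1,
    "Bos indicus": 3,
    "Hybrid breeds": 3,
    "European taurine": 4,
    "7 taurine": 4,
    "Angus-Red Angus": 3,
}
PAPER_P1_SIZES: dict[str, int] = {
    "World": 100,
    "Bos taurus": 10,
    "Bos indicus": 50,
    "Hybrid breeds": 25,
    "European taurine": 100,
    "7 taurine": 150,
    "Angus-Red Angus": 25,
}
# Alternative small-panel configuration: 10/25/50 markers at every node.
SMALL_TIER_SIZES: tuple[int, int, int] = (10, 25, 50)


@dataclass
class TreeConfig:
    """Knobs for building (and later refitting) the decision tree.

    ``topology`` is a nested mapping like :data:`PAPER_TOPOLOGY`
    (``None`` = discover by recursive clustering).  ``node_k`` is "auto",
    an int, or a per-node mapping; likewise ``p1_size`` and
    ``n_clusters``.  ``n_top`` defaults to min(2000, n_snps // 3).
    ``tier_sizes`` overrides the 1:2:3 tier ratio (e.g. 10/25/50).
    """

    topology: Mapping | None = None
    node_k: int | str | Mapping[str, int] = "auto"
    p1_size: int | Mapping[str, int] = 50
    tier_sizes: tuple[int, int, int] | None = None
    n_top: int | None = None
    n_clusters: int | str | Mapping[str, int] = "auto"
    k_candidates: Sequence[int] = tuple(range(1, 9))
    n_neighbors: int = 5
    seed: int = 0
    build_panels: bool = True
    max_auto_clusters: int = 6

    @classmethod
    def paper_preset(cls, **kw) -> "TreeConfig":
        return cls(topology=PAPER_TOPOLOGY, node_k=dict(PAPER_NODE_K), p1_size=dict(PAPER_P1_SIZES), **kw)

    @classmethod
    def small_preset(cls, **kw) -> "TreeConfig":
        return cls(
            topology=PAPER_TOPOLOGY,
            node_k=dict(PAPER_NODE_K),
            p1_size=SMALL_TIER_SIZES[0],
            tier_sizes=SMALL_TIER_SIZES,
            **kw,
        )

    def resolve_k(self, node_name: str) -> int | None:
        if self.node_k == "auto":
            return None
        if isinstance(self.node_k, Mapping):
            return int(self.node_k[node_name])
        return int(self.node_k)

    def resolve_p1(self, node_name: str) -> int:
        if isinstance(self.p1_size, Mapping):
            return int(self.p1_size[node_name])
        return int(self.p1_size)

    def resolve_n_top(self, n_snps: int) -> int:
        return int(self.n_top) if self.n_top is not None else min(2000, n_snps // 3)


@dataclass
class NodeDecision:
    """Outcome of one 5-NN vote at one tree node."""

    node: str
    predicted: str  # child name or "unassigned"
    neighbor_ids: np.ndarray
    neighbor_dists: np.ndarray
    n_correct_breed: int  # neighbours whose reference breed equals the test breed


@dataclass
class ClassificationResult:
    """Root-to-final path of node decisions for one sample."""

    sample_id: str
    decisions: list[NodeDecision]
    final: str  # predicted breed or "unassigned"


@dataclass
class TreeNode:
    """One node of the breed decision tree."""

    name: str
    breeds: tuple[str, ...]
    children: list["TreeNode"] = field(default_factory=list)
    k: int | None = None
    basis: PCBasis | None = None  # full-SNP basis at this node
    panel: SnpPanel | None = None
    bases: dict[str, PCBasis] = field(default_factory=dict)  # mode -> basis
    train_coords: dict[str, PCCoordinates] = field(default_factory=dict)
    child_of_breed: dict[str, str] = field(default_factory=dict)
    cluster_purity: dict[str, float] | None = None
    sample_ids: np.ndarray | None = None
    train_breeds: np.ndarray | None = None  # breed per training sample, row order

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def find(self, name: str) -> "TreeNode":
        for node in self.iter_nodes():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def path_for_breed(self, breed: str) -> list["TreeNode"]:
        """Internal nodes visited by a sample of this breed, root first."""
        if breed not in self.breeds:
            raise KeyError(f"breed {breed!r} not under node {self.name!r}")
        path, node = [], self
        while not node.is_leaf:
            path.append(node)
            node = next(c for c in node.children if breed in c.breeds)
        return path

    def child_named(self, name: str) -> "TreeNode":
        for c in self.children:
            if c.name == name:
                return c
        raise KeyError(f"node {self.name!r} has no child {name!r}")


def cluster_breeds_at_node(
    coords: PCCoordinates,
    labels: Sequence[str],
    n_clusters: int,
    seed: int = 0,
) -> tuple[list[tuple[str, ...]], dict[str, float]]:
    """Group breeds by k-means on PC coordinates of training individuals.

    Breeds are atomic: each breed joins the cluster holding the plurality
    of its members (ties toward the lower cluster index).  Clusters left
    without a breed are dropped.  Returns the breed partition (each part a
    sorted tuple) and the per-breed purity fraction.
    """
    X = coords.coords
    labels = np.asarray(labels, dtype=str)
    breeds = sorted({str(b) for b in labels})
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds to cluster")
    if not 2 <= n_clusters <= len(breeds):
        raise ValueError(f"n_clusters={n_clusters} outside [2, {len(breeds)}]")
    if len(np.unique(X, axis=0)) < n_clusters:
        raise ValueError("fewer distinct coordinate points than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=20, random_state=seed)
    assign = km.fit_predict(X)
    parts: dict[int, list[str]] = {}
    purity: dict[str, float] = {}
    for breed in breeds:
        counts = np.bincount(assign[labels == breed], minlength=n_clusters)
        cluster = int(counts.argmax())  # argmax ties -> lower index
        parts.setdefault(cluster, []).append(breed)
        purity[breed] = counts[cluster] / counts.sum()
    partition = [tuple(sorted(parts[c])) for c in sorted(parts)]
    return partition, purity


def _dominant_dims(sigma: np.ndarray, k: int) -> int:
    """Leading PC block before the largest spectral gap, within the top k.

    A node is split along its dominant axes of variation; finer structure
    is left to the recursion.  The block size is the position of the
    largest ratio σ_i/σ_{i+1} for i ≤ k (σ_{k+1} is consulted when
    available), so one dominant axis yields a binary-style split and a
    flat leading block yields a multi-way split.
    """
    upper = min(k, len(sigma) - 1)
    if upper < 1:
        return max(1, k)
    ratios = sigma[:upper] / sigma[1 : upper + 1]
    return int(np.argmax(ratios)) + 1


def _auto_n_clusters(coords: PCCoordinates, labels, max_clusters: int, seed: int) -> int:
    """Mean-silhouette choice of the cluster count (ties toward fewer)."""
    X = coords.coords
    n_breeds = len(set(labels))
    upper = min(max_clusters, n_breeds, len(np.unique(X, axis=0)))
    if upper < 2:
        raise ValueError("degenerate coordinates: cannot cluster")
    best_c, best_s = 2, -np.inf
    for c in range(2, upper + 1):
        assign = KMeans(n_clusters=c, n_init=20, random_state=seed).fit_predict(X)
        if len(set(assign)) < 2:
            continue
        s = silhouette_score(X, assign)
        if s > best_s + 1e-12:
            best_c, best_s = c, s
    return best_c


def node_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, GenotypeMatrix]:
    """Node-level QC + centring: drop unusable columns, centre and impute."""
    usable = filter_missing(gm, max_missing_fraction=1.0 - 1e-12)  # drops monomorphic/all-missing only
    X, means = center_impute(usable)
    return X, means, usable


def _fit_mode_basis(X: np.ndarray, means: np.ndarray, snp_ids: np.ndarray, subset: np.ndarray, k: int):
    """Refit a basis on a column subset of the node matrix."""
    pos = {s: i for i, s in enumerate(snp_ids)}
    idx = np.array([pos[s] for s in subset], dtype=int)
    Xs = X[:, idx]
    _, s, _ = _svd(Xs)
    k_eff = min(k, numerical_rank(s))
    basis, coords = fit_pca(Xs, k_eff, subset, means[idx])
    return basis, coords


def build_tree(gm: GenotypeMatrix, config: TreeConfig) -> TreeNode:
    """Build (and fit) the breed decision tree on QC'd genotype data."""
    breeds = tuple(sorted(set(gm.labels)))
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds to build a tree")
    topo = _normalize_topology(config.topology) if config.topology is not None else None
    if topo is not None:
        if len(topo) != 1:
            raise ValueError("topology must have a single root")
        root_name = next(iter(topo))
        root = _build_node(gm, config, root_name, topo[root_name])
    else:
        root = _build_node(gm, config, "root", None)
    return root


def _normalize_topology(topo: Mapping) -> dict:
    out = {}
    for name, sub in topo.items():
        if sub is None:
            out[str(name)] = None
        elif isinstance(sub, Mapping):
            out[str(name)] = _normalize_topology(sub)
        elif isinstance(sub, (list, tuple)):
            out[str(name)] = {str(b): None for b in sub}
        else:
            raise ValueError(f"cannot interpret topology under {name!r}")
    return out


def _topology_breeds(sub: dict | None, name: str) -> tuple[str, ...]:
    if sub is None:
        return (name,)
    out: list[str] = []
    for child, csub in sub.items():
        out.extend(_topology_breeds(csub, child))
    return tuple(sorted(out))


def _build_node(gm: GenotypeMatrix, config: TreeConfig, name: str, topo_sub: dict | None) -> TreeNode:
    breeds = _topology_breeds(topo_sub, name) if topo_sub is not None else tuple(sorted(set(gm.labels)))
    present = tuple(sorted(set(gm.labels)))
    if topo_sub is not None:
        missing = [b for b in breeds if b not in present]
        if missing:
            raise ValueError(f"topology names breeds absent from data: {missing}")
    if len(breeds) == 1:
        return TreeNode(name=name, breeds=breeds)

    sub = gm.restrict_samples(np.asarray(gm.labels.isin(breeds)))
    X, means, usable = node_matrix(sub)
    labels = usable.labels.to_numpy(dtype=str)
    node = TreeNode(name=name, breeds=breeds, sample_ids=usable.sample_ids, train_breeds=labels)

    U, s, Vt = _svd(X)
    rank = numerical_rank(s)
    k = config.resolve_k(name)
    if k is None:
        k = choose_num_pcs(X, labels, config.k_candidates, usable.sample_ids, config.n_neighbors)
    if not 1 <= k <= rank:
        raise ValueError(f"node {name!r}: k={k} outside [1, rank={rank}]")
    basis = PCBasis(V=Vt[:k].T, sigma=s[:k], column_means=means, snp_ids=usable.snp_ids)
    coords = PCCoordinates(U[:, :k] * s[:k][None, :], usable.sample_ids)
    node.k = k
    node.basis = basis
    node.bases[FULL_MODE] = basis
    node.train_coords[FULL_MODE] = coords

    # child grouping: explicit topology or k-means on PC coordinates
    if topo_sub is not None:
        groups = [(child, csub, _topology_breeds(csub, child)) for child, csub in topo_sub.items()]
    else:
        # split along the dominant axes only; recursion resolves the rest
        d = _dominant_dims(s[: min(rank, k + 1)], k)
        dom = PCCoordinates(coords.coords[:, :d], usable.sample_ids)
        if isinstance(config.n_clusters, Mapping):
            n_clusters = int(config.n_clusters[name])
        elif config.n_clusters == "auto":
            n_clusters = _auto_n_clusters(dom, labels, config.max_auto_clusters, config.seed)
        else:
            n_clusters = int(config.n_clusters)
        partition, purity = cluster_breeds_at_node(dom, labels, n_clusters, config.seed)
        node.cluster_purity = purity
        if len(partition) == 1:
            # plurality voting collapsed every breed into one cluster;
            # fall back to one leaf per breed to guarantee termination
            partition = [(b,) for b in breeds]
        groups = []
        for i, part in enumerate(sorted(partition)):
            gname = part[0] if len(part) == 1 else f"{name}/g{i + 1}"
            groups.append((gname, None if len(part) == 1 else {b: None for b in part}, part))

    for child_name, child_sub, child_breeds in groups:
        for b in child_breeds:
            node.child_of_breed[b] = child_name
        child_gm = gm.restrict_samples(np.asarray(gm.labels.isin(child_breeds)))
        node.children.append(_build_node(child_gm, config, child_name, child_sub))

    seen = sorted(b for c in node.children for b in c.breeds)
    if seen != sorted(breeds):
        raise RuntimeError(f"children do not partition node {name!r}")

    if config.build_panels:
        n_top = config.resolve_n_top(usable.n_snps)
        p1 = config.resolve_p1(name)
        tiers = config.tier_sizes
        node.panel = build_panels(X, usable.snp_ids, basis, n_top, p1, node_name=name, tier_sizes=tiers)
        cands = top_candidates(pcaim_scores(basis), n_top)
        b_c, c_c = _fit_mode_basis(X, means, usable.snp_ids, cands, k)
        node.bases[CANDIDATE_MODE] = b_c
        node.train_coords[CANDIDATE_MODE] = PCCoordinates(c_c.coords, usable.sample_ids)
        for tier in TIER_MODES:
            ids = node.panel.tier_ids(tier)
            b_t, c_t = _fit_mode_basis(X, means, usable.snp_ids, ids, k)
            node.bases[tier] = b_t
            node.train_coords[tier] = PCCoordinates(c_t.coords, usable.sample_ids)
    return node


def knn_vote(
    test_coord: np.ndarray,
    train_coords: np.ndarray,
    train_ids,
    train_child_labels,
    train_breed_labels,
    test_breed: str | None = None,
    n_neighbors: int = 5,
    node_name: str = "",
) -> NodeDecision:
    """Vote among the nearest training neighbours in PC space.

    The sample is assigned to the child group holding a strict majority of
    the ``n_neighbors`` nearest training samples (three of five in the
    standard configuration); otherwise it is "unassigned".  Also records
    how many neighbours share the test sample's reference breed.
    """
    train_coords = np.asarray(train_coords, dtype=np.float64)
    if train_coords.shape[0] == 0:
        raise ValueError("empty training set")
    train_ids = np.asarray(train_ids, dtype=str)
    child_labels = np.asarray(train_child_labels, dtype=str)
    breed_labels = np.asarray(train_breed_labels, dtype=str)
    d = np.sqrt(((train_coords - np.asarray(test_coord)[None, :]) ** 2).sum(axis=1))
    order = neighbor_order(d, train_ids)
    nn = order[: min(n_neighbors, len(order))]
    predicted = majority_label(child_labels[nn])
    n_correct = int((breed_labels[nn] == test_breed).sum()) if test_breed is not None else 0
    return NodeDecision(
        node=node_name,
        predicted=predicted if predicted is not None else "unassigned",
        neighbor_ids=train_ids[nn],
        neighbor_dists=d[nn][np.argsort(d[nn], kind="stable")],
        n_correct_breed=n_correct,
    )


def classify_sample(
    tree: TreeNode,
    values,
    missing,
    snp_ids,
    mode: str = FULL_MODE,
    n_neighbors: int = 5,
    true_breed: str | None = None,
) -> ClassificationResult:
    """Descend the tree with per-node 5-NN votes until a leaf or "unassigned".

    ``mode`` selects the marker set at every node: "full", "candidates",
    or a panel tier "P1"/"P2"/"P3" (projected with the node's
    panel-refit basis).
    """
    node = tree
    decisions: list[NodeDecision] = []
    sample_id = "sample"
    while not node.is_leaf:
        basis = node.bases[mode]
        coord = project(basis, values, missing, snp_ids)
        train = node.train_coords[mode]
        breed_labels = node.train_breeds
        child_labels = np.array([node.child_of_breed[b] for b in breed_labels], dtype=str)
        decision = knn_vote(
            coord,
            train.coords,
            train.sample_ids,
            child_labels,
            breed_labels,
            test_breed=true_breed,
            n_neighbors=n_neighbors,
            node_name=node.name,
        )
        decisions.append(decision)
        if decision.predicted == "unassigned":
            return ClassificationResult(sample_id, decisions, "unassigned")
        node = node.child_named(decision.predicted)
    return ClassificationResult(sample_id, decisions, node.breeds[0])
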