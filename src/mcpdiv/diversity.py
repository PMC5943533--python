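"""Alpha and beta diversity: rarefaction, Good's coverage, distance trees,
UniFrac, PCoA, and jackknife-supported sample clustering.

Alpha diversity uses the exact hypergeometric rarefaction expectation

    E[S_n] = sum_i ( 1 - C(N - N_i, n) / C(N, n) )

computed in log-gamma arithmetic so it stays stable at the 10^5-read depths
of deep amplicon sequencing, and Good's coverage C = 1 - F1/n, the estimated
probability that the next read belongs to an already-observed OTU.

Beta diversity uses UniFrac on a tree over OTU representatives.  Trees are
built from global-alignment distances (d = 1 - identity) by UPGMA or
neighbor joining; maximum-likelihood phylogenetics is deliberately out of
scope — cluster topology and UniFrac, not phylogeny estimation, are the
analysis surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln
from scipy.spatial.distance import squareform

from .otu_cluster import OtuTable, pairwise_identity
from .seqio import SequenceRecord

__all__ = [
    "TreeNode",
    "DistanceMatrix",
    "AlphaDiversityResult",
    "OrdinationResult",
    "parse_newick",
    "rarefaction_curve",
    "goods_coverage",
    "build_tree",
    "unifrac",
    "pcoa",
    "sample_upgma_with_jackknife",
]


# ---------------------------------------------------------------------------
# Tree model


class TreeNode:
    """Rooted tree node; leaves carry labels, every non-root branch a length."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        children: list["TreeNode"] | None = None,
        support: float | None = None,
    ) -> None:
        if length < 0 or not np.isfinite(length):
            raise ValueError(f"branch length must be finite and >= 0, got {length}")
        self.name = name
        self.length = float(length)
        self.children = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        return names

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.name] = acc
            for child in node.children:
                walk(child, acc)

        walk(self, -self.length)  # root branch does not count
        return depths

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.10g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.children)
        label = self.name or ""
        return f"({inner}){label};"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` (labels and lengths)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {text[pos]!r} at {pos}")
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if text[pos] != ";":
        raise ValueError(f"trailing characters after position {pos}")
    return root


# ---------------------------------------------------------------------------
# Distance matrix


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-10):
            raise ValueError("diagonal is not zero")
        if (self.data < -1e-10).any():
            raise ValueError("negative distances")
        self.data = (self.data + self.data.T) / 2
        np.fill_diagonal(self.data, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.data, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label=""
        )


# ---------------------------------------------------------------------------
# Alpha diversity


@dataclass
class AlphaDiversityResult:
    """Richness and coverage of one sample at one subsampling depth."""

    sample: str
    depth: int
    observed_otus: float
    goods_coverage: float


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _exact_expected_richness(counts: np.ndarray, n: int) -> float:
    """E[number of OTUs seen] in a hypergeometric subsample of size n."""
    N = counts.sum()
    # P(OTU i absent) = C(N - N_i, n) / C(N, n); zero when N - N_i < n
    with np.errstate(invalid="ignore"):
        log_p_absent = _log_choose(N - counts, n) - _log_choose(N, n)
    p_absent = np.where(N - counts >= n, np.exp(log_p_absent), 0.0)
    return float(np.sum(1.0 - p_absent))


def _exact_expected_singletons(counts: np.ndarray, n: int) -> float:
    """E[number of OTUs with exactly one read] in a subsample of size n."""
    N = counts.sum()
    with np.errstate(invalid="ignore"):
        log_p1 = (
            np.log(counts.astype(float))
            + _log_choose(N - counts, n - 1)
            - _log_choose(N, n)
        )
    ok = N - counts >= n - 1
    return float(np.sum(np.where(ok, np.exp(log_p1), 0.0)))


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=int)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("counts must be a 1-D non-negative integer vector")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("community is empty")
    return arr


def _subsample(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw without replacement: multivariate hypergeometric subsample."""
    return rng.multivariate_hypergeometric(counts, depth)


def rarefaction_curve(
    counts,
    depths: list[int],
    mode: str = "exact",
    reps: int = 100,
    seed: int | None = None,
    sample: str = "",
) -> list[AlphaDiversityResult]:
    """Expected (or Monte-Carlo) OTU richness and Good's coverage per depth.

    Exact mode evaluates the closed-form hypergeometric expectations;
    Monte-Carlo mode averages over ``reps`` subsamples drawn without
    replacement.  Depths must not exceed the total read count.
    """
    arr = _validate_counts(counts)
    N = int(arr.sum())
    if mode not in ("exact", "montecarlo"):
        raise ValueError(f"mode must be 'exact' or 'montecarlo', got {mode!r}")
    results = []
    rng = np.random.default_rng(seed)
    for n in depths:
        if n <= 0:
            raise ValueError(f"depth must be positive, got {n}")
        if n > N:
            raise ValueError(f"depth {n} exceeds total count {N}")
        if mode == "exact":
            s = _exact_expected_richness(arr, n)
            c = 1.0 - _exact_expected_singletons(arr, n) / n
        else:
            s_draws, c_draws = [], []
            for _ in range(reps):
                sub = _subsample(arr, n, rng)
                s_draws.append(np.count_nonzero(sub))
                c_draws.append(1.0 - np.count_nonzero(sub == 1) / n)
            s, c = float(np.mean(s_draws)), float(np.mean(c_draws))
        results.append(
            AlphaDiversityResult(sample=sample, depth=n, observed_otus=s, goods_coverage=c)
        )
    return results


def goods_coverage(
    counts,
    depth: int | None = None,
    mode: str = "exact",
    reps: int = 100,
    seed: int | None = None,
) -> float:
    """Good's coverage C = 1 - F1/n, the estimated probability that the next
    read belongs to an already-seen OTU.

    At full depth (``depth=None`` or equal to the total) this uses the
    observed singleton count; at lower depths the community is rarefied
    (exact expectation or Monte-Carlo average).
    """
    arr = _validate_counts(counts)
    N = int(arr.sum())
    if depth is None:
        depth = N
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if depth > N:
        raise ValueError(f"depth {depth} exceeds total count {N}")
    if depth == N:
        return 1.0 - np.count_nonzero(arr == 1) / N
    if mode == "exact":
        return 1.0 - _exact_expected_singletons(arr, depth) / depth
    rng = np.random.default_rng(seed)
    draws = [
        1.0 - np.count_nonzero(_subsample(arr, depth, rng) == 1) / depth
        for _ in range(reps)
    ]
    return float(np.mean(draws))


# ---------------------------------------------------------------------------
# Tree construction


def _upgma_from_distance(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree; ultrametric with node height = merge/2."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    Z = linkage(dm.condensed(), method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=dm.labels[i]), 0.0) for i in range(n)
    }
    for k, (i, j, height, _) in enumerate(Z):
        left, h_left = nodes.pop(int(i))
        right, h_right = nodes.pop(int(j))
        h = height / 2.0
        left.length = h - h_left
        right.length = h - h_right
        nodes[n + k] = (TreeNode(children=[left, right]), h)
    root, _ = nodes.popitem()[1]
    return root


def _nj_from_distance(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining, midpoint-rooted so UniFrac has a root."""
    labels = list(dm.labels)
    d = dm.data.copy()
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new = TreeNode(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.delete(np.delete(d, (i, j), axis=0), (i, j), axis=1)
        dk = np.delete(dk, (i, j))
        d = np.vstack([np.hstack([d, dk[:, None]]), np.append(dk, 0.0)[None, :]])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [new]
    nodes[0].length = max(float(d[0, 1]), 0.0)
    root = TreeNode(children=nodes) if len(nodes) == 2 else nodes[0]
    return _midpoint_root(root)


def _midpoint_root(root: TreeNode) -> TreeNode:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    The tree is flattened to an undirected weighted graph, the diameter path
    is found, and a new root node is inserted on the edge containing the
    midpoint.
    """
    # flatten to an undirected graph over node ids
    adj: dict[int, list[tuple[int, float]]] = {}
    objs: dict[int, TreeNode] = {}

    def collect(node: TreeNode) -> None:
        objs[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((id(child), child.length))
            adj[id(child)].append((id(node), child.length))
            collect(child)

    collect(root)
    leaves = [id(n) for n in root.postorder() if n.is_leaf]
    if len(leaves) < 3:
        return root

    def farthest(start: int) -> tuple[int, dict[int, float], dict[int, int]]:
        dist = {start: 0.0}
        prev: dict[int, int] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        end = max(leaves, key=lambda l: dist[l])
        return end, dist, prev

    a, _, _ = farthest(leaves[0])
    b, dist, prev = farthest(a)
    # path from b back to a
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    half = dist[b] / 2.0
    # walk from b toward a accumulating distance until the midpoint edge
    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = next(wt for nb, wt in adj[u] if nb == v)
        if acc + w >= half - 1e-12:
            lower_u, upper_v, from_u = u, v, half - acc
            break
        acc += w
    else:  # pragma: no cover - midpoint always on the path
        return root
    # remove the midpoint edge and hang both halves from a new root
    w = next(wt for nb, wt in adj[lower_u] if nb == upper_v)
    adj[lower_u] = [(nb, wt) for nb, wt in adj[lower_u] if nb != upper_v]
    adj[upper_v] = [(nb, wt) for nb, wt in adj[upper_v] if nb != lower_u]

    def rebuild(u: int, parent: int | None, parent_len: float) -> TreeNode:
        old = objs[u]
        kids = [rebuild(v, u, wt) for v, wt in adj[u] if v != parent]
        if not kids:
            return TreeNode(name=old.name, length=parent_len)
        if len(kids) == 1:  # splice unary pass-through nodes
            kids[0].length += parent_len
            return kids[0]
        return TreeNode(name=None, length=parent_len, children=kids)

    left = rebuild(lower_u, upper_v, from_u)
    right = rebuild(upper_v, lower_u, w - from_u)
    return TreeNode(children=[left, right])


def build_tree(
    representatives: list[SequenceRecord],
    method: str = "upgma",
    end_gaps_free: bool = False,
) -> TreeNode:
    """Distance tree over OTU representatives from alignment identity.

    Pairwise distance d = 1 - identity; UPGMA gives an ultrametric rooted
    tree, NJ an additive tree midpoint-rooted for UniFrac.
    """
    if len(representatives) < 2:
        raise ValueError("need at least 2 representatives")
    labels = [r.id for r in representatives]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate representative labels")
    if method not in ("upgma", "nj"):
        raise ValueError(f"method must be 'upgma' or 'nj', got {method!r}")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(
                representatives[i].seq, representatives[j].seq, end_gaps_free
            )
    dm = DistanceMatrix(labels=labels, data=d)
    return _upgma_from_distance(dm) if method == "upgma" else _nj_from_distance(dm)


# ---------------------------------------------------------------------------
# UniFrac


def _branch_table(tree: TreeNode, otu_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch leaf-membership indicator matrix.

    Returns (lengths[k], member[k, o]) over all non-root branches k and
    OTU columns o; member[k, o] is True when OTU o is a leaf of the subtree
    below branch k.  Leaves of the tree that are not in `otu_ids` are carried
    with all-zero membership so their branches still count only when shared.
    """
    col = {o: i for i, o in enumerate(otu_ids)}
    lengths: list[float] = []
    members: list[np.ndarray] = []

    def walk(node: TreeNode, is_root: bool) -> np.ndarray:
        mask = np.zeros(len(otu_ids), dtype=bool)
        if node.is_leaf:
            if node.name in col:
                mask[col[node.name]] = True
        else:
            for child in node.children:
                mask |= walk(child, False)
        if not is_root:
            lengths.append(node.length)
            members.append(mask)
        return mask

    walk(tree, True)
    return np.array(lengths), np.array(members)


def unifrac(
    table: OtuTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """UniFrac distances between all sample pairs of an OTU table.

    Unweighted: unique branch length / total branch length on the union of
    the two communities.  Weighted (raw): sum_k b_k |p_kA - p_kB| over
    branches, with p the fraction of a sample's reads below branch k;
    normalized weighted divides by sum_j d_j (p_jA + p_jB) over leaves j,
    where d_j is the root-to-leaf distance, bounding the result to [0, 1].
    """
    leaf_names = tree.leaf_names()
    missing = [o for o in table.otu_ids if o not in set(leaf_names)]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing}")
    lengths, members = _branch_table(tree, table.otu_ids)
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    # per-sample branch presence / proportions: branch k x sample i
    branch_counts = members @ counts.T  # (branches, samples)
    props = branch_counts / totals[None, :]
    present = branch_counts > 0

    n = table.n_samples
    out = np.zeros((n, n))
    if weighted:
        depths = tree.leaf_depths()
        leaf_d = np.array([depths[o] for o in table.otu_ids])
        leaf_props = counts / totals[:, None]  # (samples, otus)
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                raw = float(np.sum(lengths * np.abs(props[:, i] - props[:, j])))
                if normalized:
                    denom = float(np.sum(leaf_d * (leaf_props[i] + leaf_props[j])))
                    raw = raw / denom if denom > 0 else 0.0
                out[i, j] = out[j, i] = raw
            else:
                union = present[:, i] | present[:, j]
                unique = present[:, i] ^ present[:, j]
                total = float(np.sum(lengths[union]))
                out[i, j] = out[j, i] = (
                    float(np.sum(lengths[unique])) / total if total > 0 else 0.0
                )
    return DistanceMatrix(labels=list(table.sample_ids), data=out)


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        axes = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, index=self.sample_ids, columns=axes)
        with open(path, "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(f"{e:.8g}" for e in self.eigenvalues) + "\n")
            fh.write(
                "# proportion_explained\t"
                + "\t".join(f"{p:.8g}" for p in self.proportion_explained)
                + "\n"
            )
            df.to_csv(fh, sep="\t", index_label="sample")


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps positive-eigenvalue
    axes for the coordinates.  Negative eigenvalues (non-Euclidean input)
    are reported in the eigenvalue list, not silently dropped.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    proportion = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(
        sample_ids=list(dm.labels),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# Jackknifed sample clustering


def _clades(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf-sets of all internal, non-root nodes."""
    out = set()
    all_leaves = frozenset(tree.leaf_names())

    def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        acc = frozenset().union(*(walk(c, False) for c in node.children))
        if not is_root and 1 < len(acc) < len(all_leaves):
            out.add(acc)
        return acc

    walk(tree, True)
    return out


def sample_upgma_with_jackknife(
    table: OtuTable,
    tree: TreeNode,
    reps: int = 1000,
    depth_fraction: float = 0.75,
    seed: int | None = None,
    weighted: bool = False,
) -> TreeNode:
    """UPGMA clustering of samples on UniFrac distances with jackknife support.

    The full-data tree is annotated, per internal node, with the percentage
    of jackknife replicates (each sample rarefied without replacement to a
    common depth, UniFrac and UPGMA recomputed) that recover the same leaf
    bipartition.  ``reps=0`` returns the tree without support values.
    Default depth is 75% of the smallest sample total.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    full_dm = unifrac(table, tree, weighted=weighted)
    sample_tree = _upgma_from_distance(full_dm)
    if reps == 0:
        return sample_tree
    min_total = int(table.sample_totals().min())
    depth = int(np.floor(depth_fraction * min_total))
    if depth < 1 or depth > min_total:
        raise ValueError(
            f"jackknife depth {depth} invalid for smallest sample total {min_total}"
        )
    rng = np.random.default_rng(seed)
    clade_hits: dict[frozenset[str], int] = {c: 0 for c in _clades(sample_tree)}
    import copy

    for _ in range(reps):
        sub_counts = np.array(
            [rng.multivariate_hypergeometric(row, depth) for row in table.counts]
        )
        keep = sub_counts.sum(axis=0) > 0
        sub_table = OtuTable(
            otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
            sample_ids=list(table.sample_ids),
            counts=sub_counts[:, keep],
            representatives={
                o: table.representatives[o]
                for o, k in zip(table.otu_ids, keep)
                if k
            },
            threshold=table.threshold,
        )
        rep_dm = unifrac(sub_table, tree, weighted=weighted)
        rep_clades = _clades(_upgma_from_distance(rep_dm))
        for clade in clade_hits:
            if clade in rep_clades:
                clade_hits[clade] += 1

    def annotate(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        acc = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_root and acc in clade_hits:
            node.support = 100.0 * clade_hits[acc] / reps
        return acc

    annotate(sample_tree, True)
    return sample_tree
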