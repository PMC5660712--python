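"""Watershed over-segmentation and learned hierarchical agglomeration.

The boundary probability map is treated as a landscape: shallow regional
minima (depth < h) are suppressed with an H-minima transform and a seeded
watershed produces supervoxels.  Adjacent supervoxels are then merged by
a learned policy — a random-forest classifier over moment and histogram
features of the BPM and image intensity, evaluated over each body and the
contact interface — agglomerating greedily from the most merge-worthy
edge and recording every merge in a hierarchical segmentation tree whose
levels at thresholds 0.1..0.9 are nested coarsenings.

Body and interface statistics are carried as additive sufficient
statistics (voxel count, raw moment sums, histogram counts), so merging
two regions is O(1) and the features after any merge are exact.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import local_minima, reconstruction
from skimage.segmentation import watershed
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "SuperVoxels",
    "SegTree",
    "MergePolicy",
    "oversegment",
    "edge_features",
    "train_merge_policy",
    "collect_training_examples",
    "build_hierarchy",
    "DEFAULT_THRESHOLDS",
    "FEATURE_LENGTH",
]

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_H_MIN = 0.01

_NBINS = 10
_SUFF = 5 + _NBINS  # per map: n, s1..s4, hist10
#: interface block + min/max body blocks (2 maps x 14 each) + contact area
FEATURE_LENGTH = 3 * 2 * 14 + 1


@dataclass
class SuperVoxels:
    """Watershed supervoxels: a dense partition of the image grid."""

    labels: np.ndarray  # int array, labels 1..count
    count: int

    def node_indices(self) -> dict[int, np.ndarray]:
        """Flat voxel indices per supervoxel."""
        flat = self.labels.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        bounds = np.searchsorted(sorted_labels, np.arange(1, self.count + 2))
        return {
            lab: order[bounds[lab - 1]: bounds[lab]]
            for lab in range(1, self.count + 1)
        }


def oversegment(bpm: np.ndarray, h_min: float = DEFAULT_H_MIN) -> SuperVoxels:
    """H-minima suppression (depth ``h_min``) followed by seeded watershed.

    Regional minima shallower than ``h_min`` are removed by morphological
    reconstruction; the surviving minima seed a 6-connected watershed of
    the filled landscape.  Every voxel is assigned to exactly one
    supervoxel.
    """
    bpm = np.asarray(bpm, dtype=np.float64)
    if bpm.min() < 0 or bpm.max() > 1:
        raise ValueError("bpm must lie in [0, 1]")
    if h_min > 0:
        filled = reconstruction(bpm + h_min, bpm, method="erosion")
    else:
        filled = bpm
    minima = local_minima(filled, connectivity=1)
    markers, n = ndimage.label(minima, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:  # constant landscape: a single plateau minimum
        return SuperVoxels(labels=np.ones(bpm.shape, dtype=np.int32), count=1)
    labels = watershed(filled, markers, connectivity=1)
    return SuperVoxels(labels=labels.astype(np.int32), count=int(labels.max()))


# ---------------------------------------------------------------------------
# sufficient statistics


def _suff_from_values(values: np.ndarray, binned: np.ndarray) -> np.ndarray:
    s = np.empty(_SUFF)
    s[0] = values.size
    v = values
    s[1] = v.sum()
    v2 = v * v
    s[2] = v2.sum()
    s[3] = (v2 * v).sum()
    s[4] = (v2 * v2).sum()
    s[5:] = np.bincount(binned, minlength=_NBINS)
    return s


def _moments_from_suff(s: np.ndarray) -> np.ndarray:
    """mean, sd, skew, excess kurtosis, normalized 10-bin histogram (14,)."""
    n = s[0]
    if n == 0:
        return np.zeros(4 + _NBINS)
    mu = s[1] / n
    m2 = max(s[2] / n - mu**2, 0.0)
    m3 = s[3] / n - 3 * mu * s[2] / n + 2 * mu**3
    m4 = s[4] / n - 4 * mu * s[3] / n + 6 * mu**2 * s[2] / n - 3 * mu**4
    sd = np.sqrt(m2)
    if sd > 1e-12:
        skew = m3 / sd**3
        kurt = m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    return np.concatenate([[mu, sd, skew, kurt], s[5:] / n])


def _feature_block(suff2: np.ndarray) -> np.ndarray:
    """(2 * _SUFF,) stacked bpm+img sufficient stats -> (28,) moment features."""
    return np.concatenate(
        [_moments_from_suff(suff2[:_SUFF]), _moments_from_suff(suff2[_SUFF:])]
    )


def _face_pairs(labels: np.ndarray):
    """(u, v, flat_a, flat_b) for every face-adjacent voxel pair with u != v."""
    flat_index = np.arange(labels.size).reshape(labels.shape)
    out = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = labels[tuple(sl_a)].ravel()
        b = labels[tuple(sl_b)].ravel()
        ia = flat_index[tuple(sl_a)].ravel()
        ib = flat_index[tuple(sl_b)].ravel()
        sel = a != b
        out.append((a[sel], b[sel], ia[sel], ib[sel]))
    u = np.concatenate([o[0] for o in out])
    v = np.concatenate([o[1] for o in out])
    ia = np.concatenate([o[2] for o in out])
    ib = np.concatenate([o[3] for o in out])
    swap = u > v
    u2 = np.where(swap, v, u)
    v2 = np.where(swap, u, v)
    return u2, v2, ia, ib


class RegionGraph:
    """Supervoxel adjacency with exact per-node / per-edge statistics."""

    def __init__(self, supervoxels: SuperVoxels, bpm: np.ndarray, image: np.ndarray):
        self.bpm = np.asarray(bpm, dtype=np.float64).ravel()
        img = np.asarray(image, dtype=np.float64)
        lo, hi = img.min(), img.max()
        self.img = ((img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)).ravel()
        self.bpm_bin = np.minimum((self.bpm * _NBINS).astype(np.int64), _NBINS - 1)
        self.img_bin = np.minimum((self.img * _NBINS).astype(np.int64), _NBINS - 1)
        self.supervoxels = supervoxels
        self.nodes = supervoxels.node_indices()

        # per-node sufficient stats, vectorized over the whole volume
        flat = supervoxels.labels.ravel()
        nmax = supervoxels.count + 1
        self.node_suff: dict[int, np.ndarray] = {}
        per_label = []
        for values, binned in ((self.bpm, self.bpm_bin), (self.img, self.img_bin)):
            cols = [
                np.bincount(flat, minlength=nmax),
                np.bincount(flat, weights=values, minlength=nmax),
                np.bincount(flat, weights=values**2, minlength=nmax),
                np.bincount(flat, weights=values**3, minlength=nmax),
                np.bincount(flat, weights=values**4, minlength=nmax),
            ]
            hist = np.bincount(
                flat * _NBINS + binned, minlength=nmax * _NBINS
            ).reshape(nmax, _NBINS)
            per_label.append(np.column_stack(cols + [hist]))
        suff_all = np.hstack(per_label)  # (nmax, 2*_SUFF)
        for lab in range(1, nmax):
            self.node_suff[lab] = suff_all[lab].astype(float)

        # edges: interface index arrays (both flanks of every face)
        u, v, ia, ib = _face_pairs(supervoxels.labels)
        self.edges: dict[tuple[int, int], np.ndarray] = {}
        key = u.astype(np.int64) * nmax + v
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        ia_s, ib_s = ia[order], ib[order]
        starts = np.flatnonzero(np.diff(key_s, prepend=-1))
        starts = np.append(starts, key_s.size)
        for s, e in zip(starts[:-1], starts[1:]):
            ku, kv = int(key_s[s] // nmax), int(key_s[s] % nmax)
            self.edges[(ku, kv)] = np.concatenate([ia_s[s:e], ib_s[s:e]])
        self.neighbors: dict[int, set[int]] = {n: set() for n in self.nodes}
        for (a, b) in self.edges:
            self.neighbors[a].add(b)
            self.neighbors[b].add(a)

    def suff_at(self, idx: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [
                _suff_from_values(self.bpm[idx], self.bpm_bin[idx]),
                _suff_from_values(self.img[idx], self.img_bin[idx]),
            ]
        )


def edge_features(
    graph: RegionGraph,
    idx_u: np.ndarray,
    idx_v: np.ndarray,
    interface: np.ndarray,
) -> np.ndarray:
    """Symmetric feature vector for a candidate merge (length FEATURE_LENGTH).

    For the BPM and the (normalized) image: 4 central moments and a
    10-bin histogram over the contact interface and over each body; the
    two body blocks enter as elementwise (min, max) so the vector is
    invariant to swapping the pair.  The log contact area is appended.
    """
    fi = _feature_block(graph.suff_at(interface))
    fu = _feature_block(graph.suff_at(idx_u))
    fv = _feature_block(graph.suff_at(idx_v))
    return np.concatenate(
        [fi, np.minimum(fu, fv), np.maximum(fu, fv), [np.log1p(interface.size / 2.0)]]
    )


class MergePolicy:
    """Random-forest merge classifier over edge features."""

    def __init__(self, clf: RandomForestClassifier):
        self.clf = clf

    def merge_probability(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(features)
        proba = self.clf.predict_proba(f)
        if proba.shape[1] == 1:  # degenerate single-class training set
            p = float(self.clf.classes_[0])
            return np.full(len(f), p)
        return proba[:, list(self.clf.classes_).index(1)]


class _AggloState:
    """Mutable merge state: additive statistics, O(1) merges."""

    def __init__(self, graph: RegionGraph):
        self.graph = graph
        self.node_suff = dict(graph.node_suff)
        self.node_feat = {n: _feature_block(s) for n, s in self.node_suff.items()}
        self.edge_suff = {k: graph.suff_at(idx) for k, idx in graph.edges.items()}
        self.neighbors = {n: set(s) for n, s in graph.neighbors.items()}

    def edge_key(self, a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def features(self, a: int, b: int) -> np.ndarray:
        es = self.edge_suff[self.edge_key(a, b)]
        fi = _feature_block(es)
        fu, fv = self.node_feat[a], self.node_feat[b]
        contact = es[0]  # interface voxel count (both flanks)
        return np.concatenate(
            [fi, np.minimum(fu, fv), np.maximum(fu, fv), [np.log1p(contact / 2.0)]]
        )

    def merge(self, a: int, b: int, new_id: int) -> None:
        self.node_suff[new_id] = self.node_suff.pop(a) + self.node_suff.pop(b)
        self.node_feat[new_id] = _feature_block(self.node_suff[new_id])
        del self.node_feat[a], self.node_feat[b]
        nbrs = (self.neighbors[a] | self.neighbors[b]) - {a, b}
        self.neighbors[new_id] = nbrs
        for n in nbrs:
            parts = None
            for old in (a, b):
                k = self.edge_key(old, n)
                if k in self.edge_suff:
                    s = self.edge_suff.pop(k)
                    parts = s if parts is None else parts + s
            self.edge_suff[self.edge_key(new_id, n)] = parts
            self.neighbors[n].discard(a)
            self.neighbors[n].discard(b)
            self.neighbors[n].add(new_id)
        self.edge_suff.pop(self.edge_key(a, b), None)
        for old in (a, b):
            del self.neighbors[old]


def _majority_gt(node_idx: dict[int, np.ndarray], gt_flat: np.ndarray) -> dict[int, int]:
    out = {}
    for n, idx in node_idx.items():
        out[n] = int(np.bincount(gt_flat[idx]).argmax())
    return out


def collect_training_examples(
    supervoxels: SuperVoxels,
    bpm: np.ndarray,
    image: np.ndarray,
    gt_labels: np.ndarray,
    n_rounds: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """(features, labels) pairs from iterative true-merge agglomeration.

    In each round, every current edge contributes an example whose target
    is whether the two bodies share the same majority ground-truth label;
    all true merges are then applied and features re-collected, so the
    classifier sees agglomeration-stage statistics, not only leaf-level
    ones.
    """
    graph = RegionGraph(supervoxels, bpm, image)
    state = _AggloState(graph)
    node_idx = dict(graph.nodes)
    gt_flat = np.asarray(gt_labels).ravel()
    next_id = supervoxels.count + 1
    X, y = [], []
    for _ in range(max(1, n_rounds)):
        maj = _majority_gt(node_idx, gt_flat)
        to_merge = []
        for (a, b) in list(state.edge_suff):
            X.append(state.features(a, b))
            same = maj[a] == maj[b]
            y.append(int(same))
            if same:
                to_merge.append((a, b))
        if not to_merge:
            break
        parent: dict[int, int] = {}

        def find(n):
            while parent.get(n, n) != n:
                parent[n] = parent.get(parent[n], parent[n])
                n = parent[n]
            return n

        for a, b in to_merge:
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            state.merge(ra, rb, next_id)
            node_idx[next_id] = np.concatenate([node_idx.pop(ra), node_idx.pop(rb)])
            parent[ra] = next_id
            parent[rb] = next_id
            next_id += 1
    return np.asarray(X), np.asarray(y)


def train_merge_policy(
    supervoxels: SuperVoxels,
    bpm: np.ndarray,
    image: np.ndarray,
    gt_labels: np.ndarray,
    seed: int = 0,
    n_rounds: int = 3,
    extra_examples: tuple[np.ndarray, np.ndarray] | None = None,
) -> MergePolicy:
    """Learn the merge policy by iterative agglomerative training."""
    if supervoxels.count < 2:
        raise ValueError("training requires at least two supervoxels")
    X, y = collect_training_examples(supervoxels, bpm, image, gt_labels, n_rounds)
    if extra_examples is not None:
        X = np.vstack([X, extra_examples[0]])
        y = np.concatenate([y, extra_examples[1]])
    clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return MergePolicy(clf)


@dataclass
class SegTree:
    """Hierarchical segmentation: leaves are supervoxels, nodes are merges.

    ``children[node]`` lists the node's children; ``threshold[node]`` is
    the agglomeration cost (1 - merge probability) at which the node
    formed, made non-decreasing from leaves to root.  ``level(t)`` returns
    the partition formed by all merges with threshold <= t.
    """

    n_leaves: int
    children: dict[int, tuple[int, ...]] = field(default_factory=dict)
    threshold: dict[int, float] = field(default_factory=dict)
    root: int = 0

    def leaves_under(self, node: int) -> list[int]:
        if node <= self.n_leaves:
            return [node]
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n <= self.n_leaves:
                out.append(n)
            else:
                stack.extend(self.children[n])
        return out

    def all_nodes(self) -> list[int]:
        return list(range(1, self.n_leaves + 1)) + sorted(self.children)

    def node_threshold(self, node: int) -> float:
        return 0.0 if node <= self.n_leaves else self.threshold[node]

    def level(self, t: float) -> np.ndarray:
        """leaf -> segment-id lookup table (index 0 unused) at threshold ``t``."""
        rep = np.arange(self.n_leaves + 1, dtype=np.int64)
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n <= self.n_leaves:
                continue
            if self.threshold[n] <= t:
                for leaf in self.leaves_under(n):
                    rep[leaf] = n
            else:
                stack.extend(self.children[n])
        return rep

    def level_volume(self, t: float, supervoxel_labels: np.ndarray) -> np.ndarray:
        return self.level(t)[supervoxel_labels]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_leaves": self.n_leaves,
                "root": self.root,
                "children": {str(k): list(v) for k, v in self.children.items()},
                "threshold": {str(k): v for k, v in self.threshold.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SegTree":
        d = json.loads(text)
        return cls(
            n_leaves=d["n_leaves"],
            children={int(k): tuple(v) for k, v in d["children"].items()},
            threshold={int(k): float(v) for k, v in d["threshold"].items()},
            root=d["root"],
        )


def build_hierarchy(
    supervoxels: SuperVoxels,
    policy: MergePolicy,
    bpm: np.ndarray,
    image: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> SegTree:
    """Greedy agglomeration into a full merge tree.

    Edges are merged in ascending cost = 1 - P(merge), recomputing the
    costs of edges incident to each new node (lazy invalidation on a
    heap).  Each internal node is tagged with max(cost, child thresholds)
    so thresholds are non-decreasing toward the root; disconnected
    components, if any, are joined under a root tagged above every
    requested threshold.
    """
    graph = RegionGraph(supervoxels, bpm, image)
    state = _AggloState(graph)
    tree = SegTree(n_leaves=supervoxels.count)
    version = {n: 0 for n in state.node_suff}
    heap: list[tuple[float, int, int, int, int]] = []

    def push_many(pairs: list[tuple[int, int]]) -> None:
        if not pairs:
            return
        feats = np.stack([state.features(a, b) for a, b in pairs])
        costs = 1.0 - policy.merge_probability(feats)
        for (a, b), cost in zip(pairs, costs):
            heapq.heappush(heap, (float(cost), a, b, version[a], version[b]))

    push_many(list(state.edge_suff))

    next_id = supervoxels.count + 1
    node_thr: dict[int, float] = {n: 0.0 for n in state.node_suff}
    while heap and len(state.node_suff) > 1:
        cost, a, b, va, vb = heapq.heappop(heap)
        if version.get(a) != va or version.get(b) != vb:
            continue
        thr = max(cost, node_thr[a], node_thr[b])
        state.merge(a, b, next_id)
        tree.children[next_id] = (a, b)
        tree.threshold[next_id] = thr
        node_thr[next_id] = thr
        version.pop(a), version.pop(b)
        version[next_id] = 0
        push_many([(next_id, n) for n in state.neighbors[next_id]])
        next_id += 1

    remaining = sorted(state.node_suff)
    if len(remaining) > 1:  # disconnected image graph: join under a far root
        tree.children[next_id] = tuple(remaining)
        tree.threshold[next_id] = max([1.000001] + [node_thr[n] for n in remaining])
        tree.root = next_id
    else:
        tree.root = remaining[0]
    return tree
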