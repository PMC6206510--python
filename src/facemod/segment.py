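"""Hierarchical facial segmentation.

Landmarks are grouped by the strength of their co-variation, measured with
Escoufier's RV coefficient between the two (n, 3) coordinate blocks. The
resulting L x L structural similarity matrix is split recursively by
normalized spectral bisection (sign of the Fiedler vector), producing a
strictly bifurcating module tree: 1, 2, 4, ... modules per level, 63 modules
at depth 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FaceModule",
    "ModuleTree",
    "rv_coefficient",
    "landmark_rv_matrix",
    "spectral_bisect",
    "hierarchical_segment",
    "segment_similarity",
    "knn_adjacency",
]


@dataclass(frozen=True)
class FaceModule:
    module_id: int
    level: int
    parent_id: int | None
    landmark_indices: np.ndarray  # sorted int array

    @property
    def size(self) -> int:
        return len(self.landmark_indices)


@dataclass
class ModuleTree:
    """Strictly bifurcating hierarchy of landmark subsets.

    Heap-style ids: the full face is module 1 at level 0; module ``i`` has
    children ``2i`` and ``2i + 1``. A depth-5 tree has 63 modules.
    """

    modules: list[FaceModule]
    n_landmarks: int

    def __post_init__(self):
        self._by_id = {m.module_id: m for m in self.modules}

    def get(self, module_id: int) -> FaceModule:
        return self._by_id[module_id]

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def depth(self) -> int:
        return max(m.level for m in self.modules)

    def at_level(self, level: int) -> list[FaceModule]:
        return [m for m in self.modules if m.level == level]

    def level_counts(self) -> list[int]:
        return [len(self.at_level(lv)) for lv in range(self.depth + 1)]

    def children(self, module_id: int) -> list[FaceModule]:
        return [m for m in self.modules if m.parent_id == module_id]

    def validate(self) -> None:
        root = self.get(1)
        if not np.array_equal(root.landmark_indices, np.arange(self.n_landmarks)):
            raise ValueError("root module must cover all landmarks")
        for m in self.modules:
            if m.size == 0:
                raise ValueError(f"module {m.module_id} is empty")
            kids = self.children(m.module_id)
            if kids:
                merged = np.sort(np.concatenate([k.landmark_indices for k in kids]))
                if not np.array_equal(merged, m.landmark_indices):
                    raise ValueError(
                        f"children of module {m.module_id} do not partition it"
                    )

    def best_match(self, indices: np.ndarray) -> tuple[int, float]:
        """Module id with maximal Jaccard overlap to a landmark set."""
        target = set(np.asarray(indices).tolist())
        best, best_j = -1, -1.0
        for m in self.modules:
            s = set(m.landmark_indices.tolist())
            j = len(s & target) / len(s | target)
            if j > best_j:
                best, best_j = m.module_id, j
        return best, best_j

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_id": [m.module_id for m in self.modules],
                "level": [m.level for m in self.modules],
                "parent_id": [
                    -1 if m.parent_id is None else m.parent_id for m in self.modules
                ],
                "landmark_indices": [
                    ",".join(map(str, m.landmark_indices)) for m in self.modules
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModuleTree":
        df = pd.read_csv(path, sep="\t")
        modules = [
            FaceModule(
                module_id=int(r.module_id),
                level=int(r.level),
                parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
                landmark_indices=np.array(
                    [int(t) for t in str(r.landmark_indices).split(",")]
                ),
            )
            for r in df.itertuples()
        ]
        n_landmarks = max(int(m.landmark_indices.max()) for m in modules) + 1
        return cls(modules=modules, n_landmarks=n_landmarks)


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Escoufier's RV coefficient between two blocks of variables.

    RV = tr(Sxy Syx) / sqrt(tr(Sxx^2) tr(Syy^2)) on column-centered blocks;
    a matrix generalization of the squared correlation, in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("blocks must be 2-D with a shared subject axis")
    if x.shape[0] < 3:
        raise ValueError("RV requires at least 3 observations")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = np.sum((xc.T @ xc) ** 2)
    syy = np.sum((yc.T @ yc) ** 2)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero-variance block: RV undefined")
    sxy = np.sum((xc.T @ yc) ** 2)
    return float(sxy / np.sqrt(sxx * syy))


def landmark_rv_matrix(shapes: np.ndarray) -> np.ndarray:
    """L x L structural similarity matrix of per-landmark RV coefficients.

    ``shapes`` is (n, L, 3); entry (i, j) is the RV coefficient between the
    two (n, 3) landmark coordinate blocks. Computed from the full 3L x 3L
    cross-product matrix in one pass.
    """
    shapes = np.asarray(shapes, dtype=float)
    n, n_landmarks, _ = shapes.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    flat = shapes.reshape(n, -1)
    flat = flat - flat.mean(axis=0)
    cross = flat.T @ flat  # (3L, 3L)
    blocks = cross.reshape(n_landmarks, 3, n_landmarks, 3)
    frob = np.einsum("iajb,iajb->ij", blocks, blocks)
    diag = np.diagonal(frob).copy()
    if np.any(diag <= 0):
        bad = np.flatnonzero(diag <= 0)
        raise ValueError(f"zero-variance landmark block(s): {bad.tolist()}")
    rv = frob / np.sqrt(np.outer(diag, diag))
    rv = 0.5 * (rv + rv.T)
    np.fill_diagonal(rv, 1.0)
    return np.clip(rv, 0.0, 1.0)


def spectral_bisect(
    similarity: np.ndarray, min_size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Split an index set in two by the sign of the Fiedler vector.

    Uses the symmetric normalized Laplacian of the similarity submatrix. The
    eigenvector sign is fixed so the first index has a non-negative loading;
    exact zeros join the smaller side. If one side would fall below
    ``min_size``, the entries with smallest |Fiedler| loading are moved over.
    Falls back to a connected-component split when the graph is disconnected.
    """
    s = np.asarray(similarity, dtype=float)
    m = s.shape[0]
    if s.shape != (m, m) or m < 2:
        raise ValueError("similarity must be a square matrix over >= 2 indices")
    if 2 * min_size > m:
        raise ValueError(f"cannot split {m} indices with min_size={min_size}")
    if m == 2:
        return np.array([0]), np.array([1])

    # perfectly covarying indices (e.g. mirror pairs of symmetrized faces,
    # similarity exactly 1) must never be separated by eigenvector tie-breaks:
    # bisect the quotient graph of such groups, then expand
    n_groups, group_of = connected_components(s > 1.0 - 1e-9, directed=False)
    if 1 < n_groups < m:
        members = [np.flatnonzero(group_of == g) for g in range(n_groups)]
        quotient = np.empty((n_groups, n_groups))
        for a in range(n_groups):
            for b in range(n_groups):
                quotient[a, b] = s[np.ix_(members[a], members[b])].mean()
        np.fill_diagonal(quotient, 1.0)
        sizes = np.array([len(g) for g in members])
        ql, qr = _bisect_connected(quotient, min_size=1)
        try:
            # rebalance whole groups if a side falls below min_size
            ql, qr = _repair_group_sizes(quotient, ql, qr, sizes, min_size)
        except RuntimeError:
            # indivisible groups cannot honour min_size; split them as a
            # last resort
            return _bisect_connected(s, min_size)
        left = np.sort(np.concatenate([members[g] for g in ql]))
        right = np.sort(np.concatenate([members[g] for g in qr]))
        return left, right

    return _bisect_connected(s, min_size)


def _bisect_connected(s: np.ndarray, min_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Fiedler-sign bisection with undersized sides repaired by moving the
    weakest loadings across."""
    m = s.shape[0]
    if m == 2:
        return np.array([0]), np.array([1])
    n_comp, labels = connected_components(s > 1e-12, directed=False)
    if n_comp > 1:
        # disconnected: peel off the smallest component
        counts = np.bincount(labels)
        small = np.argmin(counts)
        left = np.flatnonzero(labels == small)
        right = np.flatnonzero(labels != small)
        fiedler = np.where(labels == small, -1.0, 1.0)
    else:
        deg = s.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(deg)
        lap = np.eye(m) - inv_sqrt[:, None] * s * inv_sqrt[None, :]
        lap = 0.5 * (lap + lap.T)
        _, vecs = np.linalg.eigh(lap)
        fiedler = vecs[:, 1]
        if fiedler[0] < 0:
            fiedler = -fiedler
        pos = fiedler > 0
        neg = fiedler < 0
        zero = ~(pos | neg)
        if zero.any():
            if pos.sum() <= neg.sum():
                pos |= zero
            else:
                neg |= zero
        left = np.flatnonzero(pos)
        right = np.flatnonzero(neg)

    order = np.argsort(np.abs(fiedler), kind="stable")
    left_set = set(left.tolist())
    need = max(min_size, 1)
    for idx in order:
        if len(left_set) < need and idx not in left_set:
            left_set.add(int(idx))
        elif m - len(left_set) < need and idx in left_set:
            left_set.remove(int(idx))
    left = np.array(sorted(left_set), dtype=int)
    right = np.array(sorted(set(range(m)) - left_set), dtype=int)
    if len(left) == 0 or len(right) == 0:
        raise RuntimeError("bisection produced an empty side")
    return left, right


def _repair_group_sizes(
    quotient: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    sizes: np.ndarray,
    min_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Move whole groups between the sides of a quotient bisection until both
    expanded sides reach ``min_size`` landmarks; the group most similar to the
    receiving side moves first."""
    left_set, right_set = set(left.tolist()), set(right.tolist())

    def expanded(side):
        return int(sizes[list(side)].sum()) if side else 0

    for _ in range(len(sizes)):
        if expanded(left_set) >= min_size and expanded(right_set) >= min_size:
            break
        receiver, donor = (
            (left_set, right_set)
            if expanded(left_set) < min_size
            else (right_set, left_set)
        )
        deficit = min_size - expanded(receiver)
        surplus = expanded(donor) - min_size
        legal = [g for g in donor if sizes[g] <= surplus or len(donor) > 1]
        # prefer groups that fix the deficit without starving the donor
        fitting = [g for g in legal if sizes[g] <= max(deficit, 1) + 1
                   and expanded(donor) - sizes[g] >= min_size]
        pool = fitting or [g for g in legal if expanded(donor) - sizes[g] >= min_size]
        if not pool:
            raise RuntimeError("cannot satisfy min_size with indivisible groups")
        cand = max(
            pool,
            key=lambda g: quotient[g, sorted(receiver)].mean() if receiver else 0.0,
        )
        donor.remove(cand)
        receiver.add(cand)
    if expanded(left_set) < min_size or expanded(right_set) < min_size:
        raise RuntimeError("cannot satisfy min_size with indivisible groups")
    return (
        np.array(sorted(left_set), dtype=int),
        np.array(sorted(right_set), dtype=int),
    )


def segment_similarity(
    similarity: np.ndarray, depth: int, min_size: int = 1
) -> ModuleTree:
    """Recursive spectral bisection of a precomputed similarity matrix."""
    s = np.asarray(similarity, dtype=float)
    n_landmarks = s.shape[0]
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if n_landmarks < 2**depth * max(min_size, 1):
        raise ValueError(
            f"{n_landmarks} landmarks cannot support depth {depth} "
            f"(min module size {min_size}); lower the depth"
        )
    modules: list[FaceModule] = []

    def recurse(indices: np.ndarray, module_id: int, level: int, parent: int | None):
        modules.append(
            FaceModule(
                module_id=module_id,
                level=level,
                parent_id=parent,
                landmark_indices=np.sort(indices),
            )
        )
        if level == depth:
            return
        sub = s[np.ix_(indices, indices)]
        left, right = spectral_bisect(sub, min_size=min_size * 2 ** (depth - level - 1))
        recurse(indices[left], 2 * module_id, level + 1, module_id)
        recurse(indices[right], 2 * module_id + 1, level + 1, module_id)

    recurse(np.arange(n_landmarks), 1, 0, None)
    modules.sort(key=lambda mod: mod.module_id)
    tree = ModuleTree(modules=modules, n_landmarks=n_landmarks)
    tree.validate()
    return tree


def knn_adjacency(template: np.ndarray, k: int = 8) -> np.ndarray:
    """Symmetric k-nearest-neighbour adjacency mask on template coordinates."""
    t = np.asarray(template, dtype=float)
    d = np.linalg.norm(t[:, None] - t[None, :], axis=2)
    order = np.argsort(d, axis=1)
    mask = np.zeros_like(d, dtype=bool)
    rows = np.arange(len(t))[:, None]
    mask[rows, order[:, 1 : k + 1]] = True
    mask |= mask.T
    np.fill_diagonal(mask, True)
    return mask


def hierarchical_segment(
    shapes: np.ndarray,
    depth: int = 5,
    min_size: int = 1,
    adjacency: np.ndarray | None = None,
) -> ModuleTree:
    """Build the module tree from aligned, adjusted shapes.

    ``shapes`` is (n, L, 3); the RV similarity matrix is optionally masked by
    a spatial adjacency matrix (contiguity constraint, off by default) before
    recursive spectral bisection. ``depth=5`` yields the 63-module hierarchy.
    """
    sim = landmark_rv_matrix(shapes)
    if adjacency is not None:
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.shape != sim.shape:
            raise ValueError("adjacency mask shape mismatch")
        sim = sim * adjacency
        np.fill_diagonal(sim, 1.0)
    return segment_similarity(sim, depth=depth, min_size=min_size)
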