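"""Grouping structures and intersection blocks of the coefficient matrix.

Predictors and responses each carry a (possibly overlapping) grouping, e.g.
CpG sites grouped by harboring gene pathway and genes grouped by Gene
Ontology pathway.  Crossing the P predictor groups with the Q response
groups yields G = P*Q intersection blocks of the p-by-q coefficient matrix;
these blocks are the unit on which the group-L2 penalty acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupStructure",
    "Block",
    "BlockSet",
    "build_intersection_blocks",
]


class GroupStructure:
    """Named partition (or cover, when overlapping) of an axis into groups.

    Parameters
    ----------
    labels
        Ordered feature names along the axis (predictor or response names).
    groups
        Mapping ``group name -> iterable of member labels or integer
        indices``.  Every label must belong to at least one group; group
        member sets must be non-empty and within range.
    """

    def __init__(self, labels, groups):
        self.labels = [str(x) for x in labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("axis labels are not unique")
        self._index = {name: i for i, name in enumerate(self.labels)}
        self.groups: dict[str, np.ndarray] = {}
        for gname, members in groups.items():
            idx = self._to_indices(members, gname)
            if idx.size == 0:
                raise ValueError(f"group {gname!r} is empty")
            self.groups[str(gname)] = idx
        covered = np.zeros(len(self.labels), dtype=bool)
        for idx in self.groups.values():
            covered[idx] = True
        if not covered.all():
            missing = [self.labels[i] for i in np.flatnonzero(~covered)]
            raise ValueError(
                "features belong to no group: " + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else "")
            )
        # membership lists per feature, used for block lookup under overlap
        memb: list[list[int]] = [[] for _ in self.labels]
        for gi, idx in enumerate(self.groups.values()):
            for i in idx:
                memb[i].append(gi)
        self._membership = [np.asarray(m, dtype=np.int64) for m in memb]

    def _to_indices(self, members, gname) -> np.ndarray:
        out = []
        seen = set()
        for m in members:
            if isinstance(m, (int, np.integer)):
                i = int(m)
                if not 0 <= i < len(self.labels):
                    raise ValueError(
                        f"group {gname!r}: index {i} out of range [0, {len(self.labels)})"
                    )
            else:
                if m not in self._index:
                    raise KeyError(f"group {gname!r}: unknown feature {m!r}")
                i = self._index[m]
            if i in seen:
                raise ValueError(f"group {gname!r}: duplicate member {m!r}")
            seen.add(i)
            out.append(i)
        return np.asarray(sorted(out), dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @property
    def overlapping(self) -> bool:
        return sum(idx.size for idx in self.groups.values()) > self.n_features

    def membership(self, i: int) -> np.ndarray:
        """Group indices containing feature ``i``."""
        return self._membership[i]

    def group_sizes(self) -> dict[str, int]:
        return {name: int(idx.size) for name, idx in self.groups.items()}

    # ------------------------------------------------------------------
    @classmethod
    def from_sizes(cls, sizes, labels=None, group_prefix="G"):
        """Contiguous non-overlapping groups of the given sizes."""
        sizes = [int(s) for s in sizes]
        p = sum(sizes)
        if labels is None:
            labels = [f"f{i + 1:04d}" for i in range(p)]
        if len(labels) != p:
            raise ValueError("group sizes do not sum to the number of labels")
        groups, start = {}, 0
        for gi, s in enumerate(sizes):
            groups[f"{group_prefix}{gi + 1}"] = list(range(start, start + s))
            start += s
        return cls(labels, groups)

    @classmethod
    def from_tsv(cls, path, labels):
        """Load a two-column membership file ``feature<TAB>group``.

        A feature listed under several groups creates overlap; duplicate
        (feature, group) rows are rejected.  Every label must appear, and
        every feature in the file must be a known label.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        if len(df.columns) < 2 or cols[:2] != ["feature", "group"]:
            raise ValueError(
                f"{path}: expected header 'feature<TAB>group', got {list(df.columns)!r}"
            )
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValueError(f"{path}: duplicate (feature, group) pair {dup!r}")
        known = set(str(x) for x in labels)
        unknown = sorted({f for f, _ in pairs if str(f) not in known})
        if unknown:
            raise ValueError(
                f"{path}: features not present in the matrix: " + ", ".join(unknown[:10])
            )
        groups: dict[str, list[str]] = {}
        for f, g in pairs:
            groups.setdefault(str(g), []).append(str(f))
        return cls(labels, groups)

    def to_tsv(self, path) -> None:
        rows = [
            (self.labels[i], gname)
            for gname, idx in self.groups.items()
            for i in idx
        ]
        pd.DataFrame(rows, columns=["feature", "group"]).to_csv(
            path, sep="\t", index=False
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GroupStructure({self.n_features} features, {self.n_groups} groups"
            + (", overlapping)" if self.overlapping else ")")
        )


@dataclass(frozen=True)
class Block:
    """One intersection block: predictor rows x response columns of B."""

    id: int
    name: str
    rows: np.ndarray
    cols: np.ndarray

    @property
    def size(self) -> int:
        return int(self.rows.size * self.cols.size)


@dataclass
class BlockSet:
    """The G = P*Q intersection blocks with their per-block weights w_g.

    Default weights satisfy w_g**2 = number of coefficient entries in the
    block.  With non-overlapping groupings the blocks tile the p-by-q
    coefficient grid exactly once.
    """

    blocks: list[Block]
    weights: np.ndarray
    n_predictors: int
    n_responses: int
    _x_membership: list[np.ndarray] = field(repr=False, default=None)
    _y_membership: list[np.ndarray] = field(repr=False, default=None)
    _csr_cache: dict = field(repr=False, default_factory=dict)

    @property
    def G(self) -> int:
        return len(self.blocks)

    def blocks_containing(self, j: int, k: int) -> list[int]:
        """All block ids whose predictor set contains ``j`` and response set
        contains ``k`` (exactly one for non-overlapping groupings)."""
        if not (0 <= j < self.n_predictors and 0 <= k < self.n_responses):
            raise IndexError(
                f"coefficient ({j}, {k}) outside the "
                f"{self.n_predictors}x{self.n_responses} matrix"
            )
        Q = len(self._y_membership_groups)
        return sorted(
            int(gi) * Q + int(hj)
            for gi in self._x_membership[j]
            for hj in self._y_membership[k]
        )

    # internal: number of response groups, needed to map (xg, yg) -> block id
    @property
    def _y_membership_groups(self):
        return self._q_groups

    def total_entries(self) -> int:
        return sum(b.size for b in self.blocks)

    # ------------------------------------------------------------------
    # flat CSR views used by the coordinate-descent kernel
    def rows_csr(self):
        if "rows" not in self._csr_cache:
            ptr = np.zeros(self.G + 1, dtype=np.int64)
            for g, b in enumerate(self.blocks):
                ptr[g + 1] = ptr[g] + b.rows.size
            idx = np.concatenate([b.rows for b in self.blocks]).astype(np.int64)
            self._csr_cache["rows"] = (ptr, idx)
        return self._csr_cache["rows"]

    def cols_csr(self):
        if "cols" not in self._csr_cache:
            ptr = np.zeros(self.G + 1, dtype=np.int64)
            for g, b in enumerate(self.blocks):
                ptr[g + 1] = ptr[g] + b.cols.size
            idx = np.concatenate([b.cols for b in self.blocks]).astype(np.int64)
            self._csr_cache["cols"] = (ptr, idx)
        return self._csr_cache["cols"]

    def membership_csr(self):
        """CSR arrays mapping flattened coefficient index j*q + k to the
        ids of the blocks containing it."""
        if "memb" not in self._csr_cache:
            p, q = self.n_predictors, self.n_responses
            Q = len(self._q_groups)
            lists = []
            counts = np.zeros(p * q, dtype=np.int64)
            for j in range(p):
                xg = self._x_membership[j]
                for k in range(q):
                    ids = [int(gi) * Q + int(hj) for gi in xg for hj in self._y_membership[k]]
                    lists.append(ids)
                    counts[j * q + k] = len(ids)
            ptr = np.zeros(p * q + 1, dtype=np.int64)
            np.cumsum(counts, out=ptr[1:])
            idx = np.fromiter(
                (g for ids in lists for g in ids), dtype=np.int64, count=int(ptr[-1])
            )
            self._csr_cache["memb"] = (ptr, idx)
        return self._csr_cache["memb"]


def build_intersection_blocks(
    xg: GroupStructure, yg: GroupStructure, weights=None
) -> BlockSet:
    """Cross predictor and response groupings into P*Q intersection blocks.

    Parameters
    ----------
    xg, yg
        Validated predictor / response grouping structures.
    weights
        Optional per-block weights (length P*Q, block order is row-major in
        (predictor group, response group)).  Defaults to
        ``sqrt(block entry count)`` so that w_g**2 equals the number of
        coefficient entries in the block.
    """
    blocks = []
    xnames, ynames = xg.group_names, yg.group_names
    for gi, gx in enumerate(xnames):
        for hj, gy in enumerate(ynames):
            rows, cols = xg.groups[gx], yg.groups[gy]
            blocks.append(
                Block(
                    id=gi * yg.n_groups + hj,
                    name=f"{gx}:{gy}",
                    rows=rows,
                    cols=cols,
                )
            )
    if weights is None:
        w = np.sqrt([float(b.size) for b in blocks])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(blocks),):
            raise ValueError(f"weights must have length {len(blocks)}")
        if (w < 0).any():
            raise ValueError("block weights must be non-negative")
    bs = BlockSet(
        blocks=blocks,
        weights=w,
        n_predictors=xg.n_features,
        n_responses=yg.n_features,
    )
    bs._x_membership = xg._membership
    bs._y_membership = yg._membership
    bs._q_groups = yg.group_names
    return bs
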