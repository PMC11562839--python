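"""Synthetic data with the statistical structure of the simulation study.

Rows of X are i.i.d. multivariate normal with a block-diagonal covariance:
predictors within a group follow a compound-symmetry (CS) or first-order
autoregressive (AR1) correlation with coefficient rho_x and unit marginal
variances; predictors in different groups are independent.  Errors E follow
the same construction over the response groups with coefficient rho_e, so
the true error covariance Sigma is block-diagonal by response group.  The
coefficient matrix B is group-sparse: a random fifth of the P*Q
intersection blocks is nonzero by default, half of the entries inside a
nonzero block are zeroed, and the remaining entries are drawn uniformly
from +/-[1, 3] with equal sign probability.  Y = XB + E, and samples are
split into train/validation/test sets of the configured sizes.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .groups import GroupStructure, BlockSet, build_intersection_blocks

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "ar1_cov",
    "cs_cov",
    "simulate_coefficients",
    "simulate_dataset",
    "perturb_groups",
]


def ar1_cov(size: int, rho: float) -> np.ndarray:
    """AR1 correlation block: entry (a, b) = rho**|a-b|."""
    if not -1.0 < rho < 1.0:
        raise ValueError("AR1 requires |rho| < 1")
    idx = np.arange(int(size))
    return rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)


def cs_cov(size: int, rho: float) -> np.ndarray:
    """Compound-symmetry block: 1 on the diagonal, rho elsewhere.

    Positive definiteness requires rho > -1/(size-1) (eigenvalues are
    1 + (size-1)*rho and 1 - rho).
    """
    size = int(size)
    if size > 1 and not (-1.0 / (size - 1) < rho < 1.0):
        raise ValueError(
            f"CS({size}, {rho}) is not positive definite: need "
            f"-1/{size - 1} < rho < 1"
        )
    return np.full((size, size), float(rho)) + (1.0 - rho) * np.eye(size)


_COV_BUILDERS = {"AR1": ar1_cov, "CS": cs_cov}


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the study conditions
    (n 200/100/100, p = 500 in 10 groups of 50, q = 100 in 4 groups of 25,
    AR1 correlations with rho_x = 0.5)."""

    n_train: int = 200
    n_val: int = 100
    n_test: int = 100
    x_group_sizes: tuple = (50,) * 10
    y_group_sizes: tuple = (25,) * 4
    x_cov: str = "AR1"
    rho_x: float = 0.5
    e_cov: str = "AR1"
    rho_e: float = 0.5
    nonzero_block_frac: float = 0.2
    within_nonzero_frac: float = 0.5
    coef_low: float = 1.0
    coef_high: float = 3.0
    literal_interval: bool = False
    seed: int = 0

    def __post_init__(self):
        for name, rho in (("rho_x", self.rho_x), ("rho_e", self.rho_e)):
            if not -1.0 < rho < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for name, frac in (
            ("nonzero_block_frac", self.nonzero_block_frac),
            ("within_nonzero_frac", self.within_nonzero_frac),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.x_cov not in _COV_BUILDERS or self.e_cov not in _COV_BUILDERS:
            raise ValueError("covariance type must be 'AR1' or 'CS'")

    @property
    def p(self) -> int:
        return int(sum(self.x_group_sizes))

    @property
    def q(self) -> int:
        return int(sum(self.y_group_sizes))

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_val + self.n_test

    def to_dict(self) -> dict:
        d = asdict(self)
        d["x_group_sizes"] = list(self.x_group_sizes)
        d["y_group_sizes"] = list(self.y_group_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("x_group_sizes", "y_group_sizes"):
            if key in d:
                d[key] = tuple(int(s) for s in d[key])
        return cls(**d)


def _block_diag_cov(sizes, kind, rho) -> np.ndarray:
    builder = _COV_BUILDERS[kind]
    total = int(sum(sizes))
    cov = np.zeros((total, total))
    start = 0
    for s in sizes:
        cov[start : start + s, start : start + s] = builder(s, rho)
        start += s
    return cov


def _sample_block_mvn(n, sizes, kind, rho, rng) -> np.ndarray:
    """Rows i.i.d. N(0, block-diag cov); sampled block-wise via Cholesky."""
    builder = _COV_BUILDERS[kind]
    cols = []
    for s in sizes:
        L = np.linalg.cholesky(builder(s, rho))
        cols.append(rng.standard_normal((n, s)) @ L.T)
    return np.concatenate(cols, axis=1)


def simulate_coefficients(
    bs: BlockSet,
    nonzero_block_frac: float,
    within_nonzero_frac: float,
    magnitude=(1.0, 3.0),
    rng=None,
    literal_interval: bool = False,
) -> np.ndarray:
    """Group-sparse true coefficient matrix.

    ``round(frac * G)`` blocks are selected uniformly without replacement;
    within each, ``round(within_nonzero_frac * size)`` entries are nonzero,
    drawn uniformly from +/-[low, high] with random sign (or from the
    literal interval [-3, 1) U (1, 3] when ``literal_interval``); all other
    entries are exactly zero.
    """
    rng = np.random.default_rng(rng)
    B = np.zeros((bs.n_predictors, bs.n_responses))
    n_sel = int(round(nonzero_block_frac * bs.G))
    chosen = rng.choice(bs.G, size=n_sel, replace=False)
    low, high = float(magnitude[0]), float(magnitude[1])
    for g in chosen:
        blk = bs.blocks[g]
        size = blk.size
        n_nz = int(round(within_nonzero_frac * size))
        flat = rng.choice(size, size=n_nz, replace=False)
        rows = blk.rows[flat // blk.cols.size]
        cols = blk.cols[flat % blk.cols.size]
        if literal_interval:
            # total mass of [-3, 1) U (1, 3]: 4 + 2
            u = rng.uniform(0.0, 6.0, size=n_nz)
            vals = np.where(u < 4.0, -3.0 + u, 1.0 + (u - 4.0))
        else:
            vals = rng.uniform(low, high, size=n_nz) * rng.choice([-1.0, 1.0], size=n_nz)
        B[rows, cols] = vals
    return B


@dataclass
class SimulatedData:
    """One replicate: data matrices, ground truth, and the sample split."""

    X: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    Sigma_x: np.ndarray
    x_groups: GroupStructure
    y_groups: GroupStructure
    splits: dict[str, np.ndarray]
    sample_ids: list[str]
    config: SimulationConfig = field(repr=False, default=None)

    def split(self, name: str):
        idx = self.splits[name]
        return self.X[idx], self.Y[idx]

    def frames(self, name: str):
        idx = self.splits[name]
        ids = [self.sample_ids[i] for i in idx]
        Xdf = pd.DataFrame(self.X[idx], index=ids, columns=self.x_groups.labels)
        Ydf = pd.DataFrame(self.Y[idx], index=ids, columns=self.y_groups.labels)
        return Xdf, Ydf


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Generate one replicate of the study design (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    p, q, n = cfg.p, cfg.q, cfg.n_total
    x_names = [f"x{j + 1:04d}" for j in range(p)]
    y_names = [f"y{k + 1:03d}" for k in range(q)]
    xg = GroupStructure.from_sizes(cfg.x_group_sizes, labels=x_names, group_prefix="XG")
    yg = GroupStructure.from_sizes(cfg.y_group_sizes, labels=y_names, group_prefix="YG")
    bs = build_intersection_blocks(xg, yg)

    B = simulate_coefficients(
        bs,
        cfg.nonzero_block_frac,
        cfg.within_nonzero_frac,
        magnitude=(cfg.coef_low, cfg.coef_high),
        rng=rng,
        literal_interval=cfg.literal_interval,
    )
    X = _sample_block_mvn(n, cfg.x_group_sizes, cfg.x_cov, cfg.rho_x, rng)
    E = _sample_block_mvn(n, cfg.y_group_sizes, cfg.e_cov, cfg.rho_e, rng)
    Y = X @ B + E

    splits = {
        "train": np.arange(0, cfg.n_train),
        "val": np.arange(cfg.n_train, cfg.n_train + cfg.n_val),
        "test": np.arange(cfg.n_train + cfg.n_val, n),
    }
    ids = [f"s{i + 1:05d}" for i in range(n)]
    return SimulatedData(
        X=X,
        Y=Y,
        B=B,
        Sigma=_block_diag_cov(cfg.y_group_sizes, cfg.e_cov, cfg.rho_e),
        Sigma_x=_block_diag_cov(cfg.x_group_sizes, cfg.x_cov, cfg.rho_x),
        x_groups=xg,
        y_groups=yg,
        splits=splits,
        sample_ids=ids,
        config=cfg,
    )


def perturb_groups(gs: GroupStructure, mode: str, fraction: float, rng=None) -> GroupStructure:
    """Derive an overlapping or misspecified grouping from a clean one.

    ``overlap``: each group additionally absorbs ``ceil(fraction * size)``
    features from the next group (cyclically), creating overlap while
    keeping the original memberships.  ``misspecify``: ``round(fraction *
    n_features)`` randomly chosen features are reassigned to a uniformly
    chosen *different* group, preserving the partition.
    """
    rng = np.random.default_rng(rng)
    names = gs.group_names
    if mode == "overlap":
        if fraction < 0:
            raise ValueError("fraction must be >= 0")
        groups = {}
        for gi, gname in enumerate(names):
            own = list(gs.groups[gname])
            nxt = gs.groups[names[(gi + 1) % len(names)]]
            extra = int(np.ceil(fraction * len(own)))
            borrowed = [i for i in nxt[:extra] if i not in set(own)]
            groups[gname] = own + borrowed
        return GroupStructure(gs.labels, groups)
    if mode == "misspecify":
        if gs.overlapping:
            raise ValueError("misspecification is defined for partitions only")
        assign = np.empty(gs.n_features, dtype=int)
        for gi, gname in enumerate(names):
            assign[gs.groups[gname]] = gi
        n_move = int(round(fraction * gs.n_features))
        movers = rng.choice(gs.n_features, size=n_move, replace=False)
        for i in movers:
            others = [gi for gi in range(len(names)) if gi != assign[i]]
            assign[i] = rng.choice(others)
        groups = {g: np.flatnonzero(assign == gi) for gi, g in enumerate(names)}
        groups = {g: idx for g, idx in groups.items() if idx.size > 0}
        return GroupStructure(gs.labels, groups)
    raise ValueError("mode must be 'overlap' or 'misspecify'")
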