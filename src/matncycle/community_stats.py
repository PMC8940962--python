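"""PRIMER-style multivariate layer analysis.

Sample-total standardization, Bray-Curtis resemblance on the 0-100
similarity scale, unweighted group-average clustering with the SIMPROF
permutation test for multivariate structure, non-metric MDS ordination
(Kruskal stress-1), and Spearman rank correlation matrices with ordination
vector overlays.

Similarities follow the PRIMER convention: 100 = identical samples, 0 =
disjoint supports. Internally, clustering and ordination operate on the
dissimilarity (100 - similarity) / 100.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import MDS


@dataclass
class DendrogramNode:
    members: tuple                      # sample ids under this node
    height: float = 0.0                 # merge dissimilarity (0-100 scale)
    children: list = field(default_factory=list)
    simprof_pi: float | None = None
    simprof_p: float | None = None
    significant: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        def rec(node, parent_height):
            length = (parent_height - node.height) / 2
            if node.is_leaf:
                return f"{node.members[0]}:{parent_height / 2:.6g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k, centered
    stress: float              # Kruskal stress-1 of the best restart
    n_restarts: int
    seed: int
    restart_stresses: list = field(default_factory=list)


def standardize_samples(data: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample row by its total and scale to percentages."""
    if (data.to_numpy() < 0).any():
        raise ValueError("standardization requires nonnegative values")
    totals = data.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    return data.div(totals, axis=0) * 100


def _bc_similarity(x: np.ndarray, y: np.ndarray, zero_pair: float, warn: bool) -> float:
    den = float(np.sum(x + y))
    if den == 0:
        if warn:
            warnings.warn("both samples all-zero; Bray-Curtis undefined, using convention")
        return zero_pair
    return 100.0 * (1.0 - np.sum(np.abs(x - y)) / den)


def bray_curtis(data: pd.DataFrame, zero_pair: float = 0.0) -> pd.DataFrame:
    """Bray-Curtis similarity matrix (0-100) between sample rows."""
    if (data.to_numpy() < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    ids = list(data.index)
    x = data.to_numpy(dtype=float)
    n = len(ids)
    sim = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _bc_similarity(x[i], x[j], zero_pair, warn=True)
    return pd.DataFrame(sim, index=ids, columns=ids)


def cluster_group_average(resemblance: pd.DataFrame) -> DendrogramNode:
    """Agglomerative clustering with unweighted average linkage.

    Operates on dissimilarity (100 - similarity). Inter-cluster distance is
    the mean of the *original* pairwise dissimilarities across the two member
    sets, so heights are monotone non-decreasing root-ward. Ties break
    lexicographically on the sorted member-id tuples of the candidate pair.
    """
    ids = list(resemblance.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    d0 = (100.0 - resemblance).to_dict()  # d0[col][row]
    nodes = {(i,): DendrogramNode(members=(i,)) for i in ids}
    while len(nodes) > 1:
        best = None
        for ka, kb in itertools.combinations(sorted(nodes), 2):
            dist = float(np.mean([d0[a][b] for a in ka for b in kb]))
            key = (dist, tuple(sorted((ka, kb))))
            if best is None or key < best:
                best = key
        dist, (ka, kb) = best
        merged = tuple(sorted(ka + kb))
        nodes[merged] = DendrogramNode(
            members=merged, height=dist, children=[nodes.pop(ka), nodes.pop(kb)]
        )
    return next(iter(nodes.values()))


def _sorted_profiles(batch: np.ndarray) -> np.ndarray:
    """Ordered Bray-Curtis similarity profiles for a (B, n, p) batch."""
    diff = np.abs(batch[:, :, None, :] - batch[:, None, :, :]).sum(axis=-1)
    summ = (batch[:, :, None, :] + batch[:, None, :, :]).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 100.0 * (1.0 - diff / summ)
    sim = np.nan_to_num(sim, nan=0.0)
    n = batch.shape[1]
    iu = np.triu_indices(n, k=1)
    profiles = sim[:, iu[0], iu[1]]
    profiles.sort(axis=1)
    return profiles


def simprof(
    data: pd.DataFrame,
    tree: DendrogramNode,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> DendrogramNode:
    """Similarity-profile permutation test, applied root-down on the tree.

    At each internal node with >= 3 samples: the observed profile is the
    ordered vector of pairwise Bray-Curtis similarities among the node's
    samples; one batch of permutations (values shuffled independently within
    each variable across the node's samples) gives the mean null profile, a
    second batch gives the null distribution of the departure statistic
    pi = sum |profile - mean profile|. p is the proportion of permuted
    pi* >= pi; the node is significant iff p <= alpha, and only significant
    nodes are descended into. Smaller nodes are untested with p = 1.
    """
    rng = np.random.default_rng(seed)

    def test(node: DendrogramNode):
        if node.is_leaf:
            return
        if len(node.members) < 3:
            node.simprof_p, node.significant = 1.0, False
            return
        x = data.loc[list(node.members)].to_numpy(dtype=float)
        obs = _sorted_profiles(x[None])[0]
        perm_a = rng.permuted(
            np.broadcast_to(x, (n_permutations, *x.shape)).copy(), axis=1
        )
        mean_profile = _sorted_profiles(perm_a).mean(axis=0)
        pi = float(np.abs(obs - mean_profile).sum())
        perm_b = rng.permuted(
            np.broadcast_to(x, (n_permutations, *x.shape)).copy(), axis=1
        )
        pi_null = np.abs(_sorted_profiles(perm_b) - mean_profile).sum(axis=1)
        p = float(np.mean(pi_null >= pi))
        node.simprof_pi, node.simprof_p = pi, p
        node.significant = p <= alpha
        if node.significant:
            for child in node.children:
                test(child)

    test(tree)
    return tree


def nmds(
    resemblance: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS by iterative Kruskal stress-1 minimization.

    Monotone (isotonic) regression of distances on dissimilarities via
    SMACOF; the best of ``n_restarts`` random initializations is returned,
    with coordinates centered and all restart stresses recorded.
    """
    ids = list(resemblance.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples")
    diss = (100.0 - resemblance.to_numpy(dtype=float)) / 100.0
    rng = np.random.default_rng(seed)
    best = None
    stresses = []
    restart_states = rng.integers(0, 2**31 - 1, size=n_restarts)
    for state in restart_states:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = MDS(
                n_components=k,
                metric_mds=False,
                n_init=1,
                init="random",
                max_iter=max_iter,
                eps=eps,
                dissimilarity="precomputed",
                normalized_stress=True,
                random_state=int(state),
            )
            coords = model.fit_transform(diss)
        stresses.append(float(model.stress_))
        if best is None or model.stress_ < best[0]:
            best = (float(model.stress_), coords)
    stress, coords = best
    coords = coords - coords.mean(axis=0)
    cols = [f"axis{i + 1}" for i in range(k)]
    return NmdsResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        stress=stress,
        n_restarts=n_restarts,
        seed=seed,
        restart_stresses=stresses,
    )


def spearman_matrix(
    biotic: pd.DataFrame, env: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Spearman rank correlations among markers and against environment.

    Inputs are layers x variables tables aligned on their index. Returns the
    tidy pair table (var_a, var_b, r, p, n); pairs with fewer than 3 complete
    observations are skipped with a warning.
    """
    table = biotic if env is None else biotic.join(env, how="inner")
    cols = list(table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            paired = table[[a, b]].dropna() if a != b else table[[a]].dropna()
            if len(paired) < 3:
                warnings.warn(f"pair ({a}, {b}): <3 complete observations, skipped")
                continue
            if a == b:
                rows.append((a, b, 1.0, 0.0, len(paired)))
                continue
            r, p = stats.spearmanr(paired[a], paired[b])
            rows.append((a, b, float(r), float(p), len(paired)))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "n"])


def vector_overlay(result: NmdsResult, variables: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each variable with each ordination axis.

    The vector for a variable is (r_axis1, r_axis2, ...), rescaled so the
    longest vector touches the unit circle. Constant variables are skipped.
    """
    coords = result.coordinates
    axes = list(coords.columns)
    rows = []
    for var in variables.columns:
        joined = coords.join(variables[[var]], how="inner").dropna()
        if joined[var].nunique() <= 1:
            warnings.warn(f"variable {var!r} is constant; skipped from overlay")
            continue
        rs = [float(stats.spearmanr(joined[var], joined[ax])[0]) for ax in axes]
        rows.append([var] + rs)
    out = pd.DataFrame(rows, columns=["variable"] + [f"r_{ax}" for ax in axes])
    if len(out):
        norms = np.sqrt((out[[f"r_{ax}" for ax in axes]] ** 2).sum(axis=1))
        scale = norms.max()
        for ax in axes:
            out[f"v_{ax}"] = out[f"r_{ax}"] / scale if scale > 0 else 0.0
    return out
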