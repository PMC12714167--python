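"""Network-based statistic (NBS) for differential structural subnetworks.

A two-sample t-test is run at every edge of the stacked connectomes; edges
exceeding a primary component-forming threshold (two-sided p below
``primary_p``, uncorrected) define a suprathreshold graph whose connected
components are the candidate subnetworks. Family-wise error is controlled
by permuting group labels and comparing each observed component's size
(edge count) with the permutation null distribution of the *maximum*
component size:

    p_FWER = (1 + #{permutations with max size >= observed}) / (n_perm + 1),

which is never zero and is exact under exchangeability. Components carry
the sign of their mean edge t so "reduced connectivity in patients" is
recoverable from the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ctrlcircuit.io import StructuralNetwork
from ctrlcircuit.stats import partial_correlation

__all__ = [
    "Component",
    "NBSResult",
    "edgewise_tstats",
    "threshold_components",
    "permutation_fwer",
    "component_mean_strength",
    "behavior_partial_correlation",
]


@dataclass
class Component:
    """One connected suprathreshold subnetwork."""

    edges: list[tuple[int, int]]
    nodes: list[int]
    size: int  # edge count ("extent")
    mean_t: float
    fwer_p: float | None = None

    @property
    def sign(self) -> int:
        return int(np.sign(self.mean_t))


@dataclass
class NBSResult:
    tstats: np.ndarray  # full symmetric N x N map, 0 where untestable
    primary_p: float
    df: int
    components: list[Component]
    n_permutations: int
    seed: int | None
    region_labels: list[str] | None = None
    null_max_sizes: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.fwer_p is not None and c.fwer_p < 0.05]


def _stack(networks: Sequence[StructuralNetwork]) -> tuple[np.ndarray, int]:
    n = networks[0].n_regions
    for net in networks:
        if net.n_regions != n:
            raise ValueError("networks differ in parcellation size")
    iu = np.triu_indices(n, k=1)
    X = np.stack([net.A[iu] for net in networks])
    return X, n


def _pooled_t(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; 0 where variance is 0."""
    na = int(mask_a.sum())
    nb = X.shape[0] - na
    a, b = X[mask_a], X[~mask_a]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(denom)
    np.divide(ma - mb, denom, out=t, where=denom > 0)
    return t


def edgewise_tstats(
    networks_a: Sequence[StructuralNetwork],
    networks_b: Sequence[StructuralNetwork],
) -> tuple[np.ndarray, int]:
    """Two-sample t statistic at every edge (group a minus group b).

    Returns the full symmetric t map and the degrees of freedom
    ``n_a + n_b - 2``. Edges with zero pooled variance (including edges
    absent in every subject) get statistic 0.
    """
    if len(networks_a) < 3 or len(networks_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    X, n = _stack(list(networks_a) + list(networks_b))
    mask_a = np.zeros(X.shape[0], dtype=bool)
    mask_a[: len(networks_a)] = True
    t = _pooled_t(X, mask_a)
    tmap = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    tmap[iu] = t
    tmap += tmap.T
    return tmap, X.shape[0] - 2


def _components_from_edges(
    edge_idx: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> list[np.ndarray]:
    """Connected components of the edge set, via union-find on nodes.

    Returns, per component, the positions into ``edge_idx``.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(rows[edge_idx], cols[edge_idx]):
        for v in (int(i), int(j)):
            parent.setdefault(v, v)
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj

    roots = np.array([find(int(i)) for i in rows[edge_idx]])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def threshold_components(
    tmap: np.ndarray, df: int, primary_p: float = 0.001
) -> list[Component]:
    """Connected components of the suprathreshold edge graph.

    An edge is suprathreshold when its two-sided p (from t with ``df``
    degrees of freedom) is below ``primary_p``. Single-edge components are
    allowed; an empty result is valid.
    """
    tcrit = stats.t.isf(primary_p / 2.0, df)
    n = tmap.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    tvals = tmap[rows, cols]
    supra = np.flatnonzero(np.abs(tvals) > tcrit)
    comps = []
    for pos in _components_from_edges(supra, rows, cols):
        idx = supra[pos]
        edges = [(int(rows[e]), int(cols[e])) for e in idx]
        nodes = sorted({v for e in edges for v in e})
        comps.append(
            Component(
                edges=edges,
                nodes=nodes,
                size=len(edges),
                mean_t=float(tvals[idx].mean()),
            )
        )
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps


def _max_component_size(supra_mask: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> int:
    idx = np.flatnonzero(supra_mask)
    if idx.size == 0:
        return 0
    return max(len(pos) for pos in _components_from_edges(idx, rows, cols))


def permutation_fwer(
    networks: Sequence[StructuralNetwork],
    labels: Sequence[str],
    primary_p: float = 0.001,
    n_perm: int = 5000,
    seed: int | None = None,
    region_labels: list[str] | None = None,
) -> NBSResult:
    """Run the full NBS: edge tests, components, max-size permutation FWER.

    ``labels`` must take exactly two values; permutations shuffle them
    uniformly with the given seed, never replaying the observed labeling.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    mask_a = labels == groups[0]
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    if min(na, nb) < 3:
        raise ValueError("need at least 3 subjects per group")
    n_distinct = math.comb(na + nb, na)
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments exist; "
            f"permutation p-values are granular",
            stacklevel=2,
        )

    X, n = _stack(networks)
    df = na + nb - 2
    tcrit = stats.t.isf(primary_p / 2.0, df)
    rows, cols = np.triu_indices(n, k=1)

    t_obs = _pooled_t(X, mask_a)
    tmap = np.zeros((n, n))
    tmap[rows, cols] = t_obs
    tmap += tmap.T
    comps = threshold_components(tmap, df, primary_p)

    # vectorized permutation t-stats: per-permutation group sums via an
    # indicator matrix; edges absent in every subject are excluded (their
    # pooled variance is 0, the t undefined)
    rng = np.random.default_rng(seed)
    nsub = na + nb
    testable = X.any(axis=0)
    Xt = X[:, testable]
    rows_t, cols_t = rows[testable], cols[testable]
    X2 = Xt**2
    S, Q = Xt.sum(axis=0), X2.sum(axis=0)
    null_max = np.empty(n_perm, dtype=int)
    batch = max(1, min(n_perm, int(2e7 // max(Xt.shape[1], 1))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = np.zeros((b, nsub))
        for r in range(b):
            P[r, rng.permutation(nsub)[:na]] = 1.0
        sa = P @ Xt
        qa = P @ X2
        ma, mb = sa / na, (S - sa) / nb
        ssa = qa - na * ma**2
        ssb = (Q - qa) - nb * mb**2
        sp2 = (ssa + ssb) / df
        denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / na + 1.0 / nb))
        tp = np.zeros_like(denom)
        np.divide(ma - mb, denom, out=tp, where=denom > 0)
        supra = np.abs(tp) > tcrit
        for r in range(b):
            null_max[done + r] = _max_component_size(supra[r], rows_t, cols_t)
        done += b

    for comp in comps:
        exceed = int((null_max >= comp.size).sum())
        comp.fwer_p = (1 + exceed) / (n_perm + 1)

    return NBSResult(
        tstats=tmap,
        primary_p=primary_p,
        df=df,
        components=comps,
        n_permutations=n_perm,
        seed=seed,
        region_labels=region_labels or networks[0].region_labels,
        null_max_sizes=null_max,
    )


def component_mean_strength(
    network: StructuralNetwork, component: Component | Sequence[tuple[int, int]]
) -> float:
    """Mean FA weight of one subject over a component's edges."""
    edges = component.edges if isinstance(component, Component) else list(component)
    if not edges:
        raise ValueError("empty component")
    n = network.n_regions
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"edge ({i}, {j}) outside network of {n} regions")
    return float(np.mean([network.A[i, j] for i, j in edges]))


def behavior_partial_correlation(
    strengths: Sequence[float],
    scale_scores: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Partial correlation of subnetwork strength with each behavioral scale.

    Both variables are residualized on the nuisance covariates (age, sex
    coded numerically, education, medication load); p-values are Bonferroni
    adjusted across the battery of scales tested.
    """
    strengths = np.asarray(strengths, dtype=float)
    if len(strengths) < 10:
        raise ValueError("need at least 10 complete cases")
    rows = []
    for scale in scale_scores.columns:
        r, p = partial_correlation(
            strengths, scale_scores[scale].to_numpy(float), covariates
        )
        rows.append((scale, r, p))
    out = pd.DataFrame(rows, columns=["scale", "r", "p"]).set_index("scale")
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
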