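"""Average network controllability of structural connectomes.

The brain is modelled as a discrete, noise-free linear time-invariant
system ``x(t+1) = A x(t) + B_k u_k(t)`` whose system matrix ``A`` is the
(stabilized) FA-weighted structural connectome. For a single control region
``k`` (``B = e_k``), average controllability is the trace of the
infinite-horizon controllability Gramian

    W_k = sum_{t>=0} A^t e_k e_k' (A')^t,

the unique solution of the discrete Lyapunov equation
``W = A W A' + e_k e_k'``. The trace equals ``sum_t ||A^t e_k||^2`` and is
at least 1 (the t = 0 term), with larger values at regions from which input
energy spreads widely; it quantifies how easily input at that region drives
the network to nearby states on average.

Raw FA matrices have spectral radius well above 1, so the Gramian series
diverges; following the network-control literature, ``A`` is first
normalized to ``A / (1 + lambda_max(A))``, which places the spectral radius
at ``lambda_max / (1 + lambda_max) < 1``. Absolute controllability values
depend on this convention; group contrasts and rankings do not depend on
the pre-scaling of the raw matrix.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ctrlcircuit.io import StructuralNetwork
from ctrlcircuit.stats import compare_groups

__all__ = [
    "stabilize",
    "average_controllability",
    "node_controllability",
    "cohort_controllability",
    "compare_anc",
]


def stabilize(A_raw: np.ndarray) -> np.ndarray:
    """Normalize a symmetric nonnegative matrix to spectral radius < 1.

    Returns ``A_raw / (1 + lambda_max)`` where ``lambda_max`` is the largest
    eigenvalue; for a symmetric nonnegative matrix this equals the spectral
    radius, so the result has spectral radius ``lambda_max/(1+lambda_max)``.
    The zero matrix is returned unchanged.
    """
    A_raw = np.asarray(A_raw, dtype=float)
    if not np.all(np.isfinite(A_raw)):
        raise ValueError("non-finite entries in adjacency matrix")
    if not np.allclose(A_raw, A_raw.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    if not A_raw.any():
        return A_raw.copy()
    lam_max = linalg.eigvalsh(A_raw)[-1]
    return A_raw / (1.0 + lam_max)


def _check_stable(A: np.ndarray) -> None:
    rho = np.max(np.abs(linalg.eigvalsh(A)))
    if rho >= 1.0:
        raise ValueError(
            f"spectral radius {rho:.4f} >= 1; stabilize() the matrix first"
        )


def average_controllability(A: np.ndarray, k: int) -> float:
    """Average controllability of node ``k``: trace of the Gramian with B = e_k.

    Solves the discrete Lyapunov fixed point ``W = A W A' + e_k e_k'``
    directly. ``A`` must already be stable (spectral radius < 1).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if not 0 <= k < n:
        raise IndexError(f"control node {k} out of range for N={n}")
    _check_stable(A)
    e = np.zeros(n)
    e[k] = 1.0
    W = linalg.solve_discrete_lyapunov(A, np.outer(e, e))
    return float(np.trace(W))


def node_controllability(A: np.ndarray) -> np.ndarray:
    """Average controllability of every node of a stable symmetric system.

    For symmetric ``A = V diag(lam) V'`` the Gramian trace has the closed
    form ``a_c(k) = sum_i V[k,i]^2 / (1 - lam_i^2)``, so all N values come
    from one eigendecomposition. Agrees with the per-node Lyapunov solve to
    machine precision.
    """
    A = np.asarray(A, dtype=float)
    lam, V = linalg.eigh(A)
    if np.max(np.abs(lam)) >= 1.0:
        raise ValueError("spectral radius >= 1; stabilize() the matrix first")
    return (V**2 / (1.0 - lam**2)).sum(axis=1)


def cohort_controllability(networks: Sequence[StructuralNetwork]) -> pd.DataFrame:
    """Per-subject, per-region average controllability table.

    Each subject's raw FA matrix is stabilized independently, then all
    regions' values are computed. Region order follows the shared label
    list; a label mismatch across subjects is an error.
    """
    if not networks:
        raise ValueError("no networks supplied")
    labels = networks[0].region_labels
    rows = {}
    for net in networks:
        if net.region_labels != labels:
            diff = next(
                (a, b) for a, b in zip(net.region_labels, labels) if a != b
            )
            raise ValueError(
                f"region labels of {net.subject_id} differ from the first "
                f"subject (first mismatch: {diff[0]!r} vs {diff[1]!r})"
            )
        rows[net.subject_id] = node_controllability(stabilize(net.A))
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def compare_anc(
    anc: pd.DataFrame,
    phenotypes: pd.DataFrame,
    region_subset: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of average controllability, region by region.

    For each region a Shapiro-Wilk normality gate selects one-way ANOVA
    (all groups normal) or Kruskal-Wallis; pairwise post hocs run only
    where the omnibus is significant, and omnibus p-values are
    Benjamini-Hochberg adjusted across regions. Returns one row per region
    with the test used, statistic, raw p, adjusted p and the post-hoc table.
    """
    pheno = phenotypes.set_index("subject_id").loc[anc.index]
    labels = pheno["group"].to_numpy()
    regions = list(region_subset) if region_subset is not None else list(anc.columns)
    missing = set(regions) - set(anc.columns)
    if missing:
        raise KeyError(f"regions not in table: {sorted(missing)}")

    records = []
    for region in regions:
        res = compare_groups(anc[region].to_numpy(), labels, posthoc=False)
        records.append(
            {"region": region, "test": res.test, "statistic": res.statistic,
             "p": res.p}
        )
    out = pd.DataFrame.from_records(records).set_index("region")
    out["p_adj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out["significant"] = out["p_adj"] < alpha

    posthocs = {}
    for region in out.index[out["significant"]]:
        res = compare_groups(anc[region].to_numpy(), labels, posthoc=True)
        posthocs[region] = res.posthoc
    out.attrs["posthoc"] = posthocs
    return out
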