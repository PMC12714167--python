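"""Pathway over-representation and expression-weighted cell-type enrichment.

ORA tests each gene set with the hypergeometric upper tail (probability of
drawing at least the observed overlap when sampling the list from the
universe) and applies the reporting filters p < 0.01, overlap >= 3 and
enrichment factor > 1. EWCE asks whether a target gene list's mean
cell-type specificity exceeds that of random same-length lists drawn from
the background, with a bootstrap p of the form (1 + exceedances) /
(n_boot + 1) and BH-FDR across cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ctrlcircuit.io import GeneSetCollection

__all__ = ["ora", "specificity", "ewce_bootstrap"]


def ora(
    gene_list,
    gene_sets: GeneSetCollection | dict[str, set[str]],
    universe,
    p_threshold: float = 0.01,
    min_overlap: int = 3,
    min_enrichment: float = 1.0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    With universe size N, term size K, list size n and overlap x, the
    p-value is ``P[X >= x]`` for ``X ~ Hypergeom(N, K, n)`` and the
    enrichment factor is ``(x/n) / (K/N)``. A term passes when
    ``p < p_threshold``, ``x >= min_overlap`` and factor
    ``> min_enrichment``. Rows are sorted by p; ``top_n`` limits the
    *passing* rows reported (top-5 reporting mode by default upstream).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    n = len(gene_list)
    N = len(universe)
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else gene_sets
    rows = []
    for name, members in sets.items():
        term = set(members) & universe
        K = len(term)
        if K == 0:
            continue
        x = len(term & gene_list)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if n else 1.0
        factor = (x / n) / (K / N) if n else 0.0
        rows.append(
            {
                "term": name,
                "overlap": x,
                "term_size": K,
                "list_size": n,
                "universe_size": N,
                "p": p,
                "enrichment_factor": factor,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["pass_p"] = out["p"] < p_threshold
    out["pass_overlap"] = out["overlap"] >= min_overlap
    out["pass_enrichment"] = out["enrichment_factor"] > min_enrichment
    out["selected"] = out[["pass_p", "pass_overlap", "pass_enrichment"]].all(axis=1)
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    if top_n is not None:
        keep = out.index[out["selected"]][:top_n]
        out["selected"] = out.index.isin(keep)
    return out


def specificity(celltype_expression: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize mean expression to per-gene cell-type proportions.

    ``s_gc = E_gc / sum_c E_gc``; each retained row sums to 1. Genes with
    zero total expression are dropped with a warning; negative values are
    an error.
    """
    vals = celltype_expression.to_numpy(float)
    if np.any(vals < 0):
        raise ValueError("negative expression values")
    totals = vals.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero genes dropped from specificity",
            stacklevel=2,
        )
    out = celltype_expression.loc[~zero].div(totals[~zero], axis=0)
    return out


@dataclass
class EwceResult:
    table: pd.DataFrame  # per cell type: observed, boot mean/sd, z, p, p_adj
    n_boot: int
    seed: int | None


def ewce_bootstrap(
    target_genes,
    spec: pd.DataFrame,
    n_boot: int = 10000,
    seed: int | None = None,
) -> EwceResult:
    """Bootstrap cell-type enrichment of a target list's mean specificity.

    The observed statistic per cell type is the mean specificity of the
    target genes; ``n_boot`` random gene lists of the same length are drawn
    uniformly without replacement from the background (all genes in the
    specificity matrix), and ``p = (1 + #{boot >= observed})/(n_boot + 1)``.
    Also reports the standard-deviations-from-the-mean z score and BH-FDR
    across cell types.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    target = [g for g in target_genes if g in spec.index]
    if not target:
        raise ValueError("no target genes present in the specificity matrix")
    m = len(target)
    if m > spec.shape[0]:
        raise ValueError("target list longer than the background")
    vals = spec.to_numpy(float)
    observed = spec.loc[target].mean(axis=0).to_numpy()

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, spec.shape[1]))
    n_genes = spec.shape[0]
    # without-replacement lists in batches: the m smallest random keys per row
    batch = max(1, int(2e7 // n_genes))
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        keys = rng.random((b, n_genes))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        boot[done : done + b] = vals[idx].mean(axis=1)
        done += b

    exceed = (boot >= observed).sum(axis=0)
    p = (1 + exceed) / (n_boot + 1)
    sd = boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - boot.mean(axis=0)) / sd, 0.0)
    table = pd.DataFrame(
        {
            "observed": observed,
            "boot_mean": boot.mean(axis=0),
            "boot_sd": sd,
            "z": z,
            "p": p,
            "p_adj": stats.false_discovery_control(p, method="bh"),
        },
        index=spec.columns,
    )
    return EwceResult(table=table, n_boot=n_boot, seed=seed)
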