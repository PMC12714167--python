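"""Regional expression-atlas preparation.

Mirrors the standard microarray-atlas workflow at gene level: tissue
samples are assigned to the nearest parcel centroid within a distance
threshold (2 mm default), expression is normalized per gene within donor
by a scaled robust sigmoid, genes whose regional profiles disagree across
donors are filtered by differential stability, and surviving samples are
pooled across donors into a genes x regions matrix. Probe-level processing
is upstream of this module's input boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TissueSample",
    "assign_samples",
    "scaled_robust_sigmoid",
    "differential_stability",
    "filter_inconsistent_genes",
    "aggregate",
    "prepare_atlas",
]


@dataclass
class TissueSample:
    donor_id: str
    coordinates: np.ndarray  # (3,) in atlas space, mm
    expression: pd.Series  # per-gene values

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(
            np.isfinite(self.coordinates)
        ):
            raise ValueError("coordinates must be a finite 3-vector")


def assign_samples(
    samples: list[TissueSample],
    region_centroids: pd.DataFrame,
    max_distance_mm: float = 2.0,
) -> pd.Series:
    """Map each sample to its nearest region centroid within the threshold.

    ``region_centroids`` is regions x (x, y, z). Samples farther than
    ``max_distance_mm`` from every centroid are dropped (logged); exact
    ties go to the lower region index (deterministic).
    """
    if region_centroids.empty:
        raise ValueError("empty centroid set")
    cent = region_centroids[["x", "y", "z"]].to_numpy(float)
    assigned: dict[int, str] = {}
    n_dropped = 0
    for i, s in enumerate(samples):
        d = np.linalg.norm(cent - s.coordinates, axis=1)
        j = int(np.argmin(d))  # argmin takes the first (lowest index) on ties
        if d[j] <= max_distance_mm:
            assigned[i] = region_centroids.index[j]
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d samples beyond %.2f mm", n_dropped, max_distance_mm)
    return pd.Series(assigned, name="region")


def scaled_robust_sigmoid(values) -> np.ndarray:
    """Scaled robust sigmoid normalization of one gene's values within a donor.

    ``x' = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))`` followed by
    min-max rescaling to [0, 1]. IQR/1.35 approximates a robust standard
    deviation; a constant gene (IQR = 0) maps to 0.5 everywhere. The
    transform is rank-preserving.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples per donor")
    med = np.median(x)
    iqr = stats.iqr(x)
    if iqr == 0:
        return np.full_like(x, 0.5)
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (s - lo) / (hi - lo)


def differential_stability(donor_profiles: dict[str, pd.DataFrame]) -> pd.Series:
    """Mean pairwise Spearman correlation of donor region-profiles per gene.

    ``donor_profiles`` maps donor id to a genes x regions frame; only
    regions present for both donors of a pair enter each correlation.
    """
    donors = list(donor_profiles)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")
    genes = donor_profiles[donors[0]].index
    sums = pd.Series(0.0, index=genes)
    counts = pd.Series(0, index=genes)
    for a in range(len(donors)):
        for b in range(a + 1, len(donors)):
            pa, pb = donor_profiles[donors[a]], donor_profiles[donors[b]]
            common = pa.columns.intersection(pb.columns)
            if len(common) < 3:
                continue
            xa = pa[common].to_numpy(float)
            xb = pb[common].to_numpy(float)
            ra = stats.rankdata(xa, axis=1)
            rb = stats.rankdata(xb, axis=1)
            ra = ra - ra.mean(axis=1, keepdims=True)
            rb = rb - rb.mean(axis=1, keepdims=True)
            denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(denom > 0, (ra * rb).sum(axis=1) / denom, 0.0)
            sums += rho
            counts += 1
    if (counts == 0).all():
        raise ValueError("no donor pair shares enough regions")
    return sums / counts.replace(0, np.nan)


def filter_inconsistent_genes(
    donor_profiles: dict[str, pd.DataFrame], min_consistency: float = 0.1
) -> list[str]:
    """Genes whose cross-donor differential stability reaches the threshold."""
    ds = differential_stability(donor_profiles)
    keep = list(ds.index[ds >= min_consistency])
    logger.info("consistency filter retained %d / %d genes", len(keep), len(ds))
    return keep


def aggregate(
    assignments: pd.Series,
    samples: list[TissueSample],
    expression: pd.DataFrame | None = None,
    region_order=None,
) -> pd.DataFrame:
    """Pool assigned samples across donors into a genes x regions matrix.

    Region value = mean over all samples assigned to the region. Regions
    with no assigned sample are present as NaN columns (never silently
    zero-filled) when ``region_order`` lists them.
    """
    if expression is None:
        expression = pd.DataFrame({i: s.expression for i, s in enumerate(samples)})
    cols: dict[object, np.ndarray] = {}
    for region in pd.unique(assignments):
        idx = assignments.index[assignments == region]
        cols[region] = expression[list(idx)].mean(axis=1).to_numpy()
    out = pd.DataFrame(cols, index=expression.index)
    if region_order is not None:
        out = out.reindex(columns=list(region_order))
    return out


def prepare_atlas(
    samples: list[TissueSample],
    region_centroids: pd.DataFrame,
    max_distance_mm: float = 2.0,
    min_consistency: float = 0.1,
    region_filter=None,
) -> tuple[pd.DataFrame, dict]:
    """Full preparation chain: assign, normalize, consistency-filter, pool.

    ``region_filter`` optionally restricts to a label subset (e.g. the left
    hemisphere). Returns the atlas and a provenance record of every filter
    applied.
    """
    centroids = region_centroids
    if region_filter is not None:
        centroids = centroids.loc[[r for r in centroids.index if r in set(region_filter)]]
    assignments = assign_samples(samples, centroids, max_distance_mm)

    # per-donor scaled robust sigmoid across that donor's assigned samples
    donors = sorted({samples[i].donor_id for i in assignments.index})
    gene_index = samples[0].expression.index
    norm = pd.DataFrame(
        index=gene_index, columns=list(assignments.index), dtype=float
    )
    for donor in donors:
        idx = [i for i in assignments.index if samples[i].donor_id == donor]
        raw = np.column_stack([samples[i].expression.to_numpy(float) for i in idx])
        normed = np.apply_along_axis(scaled_robust_sigmoid, 1, raw)
        norm.loc[:, idx] = normed

    donor_profiles = {}
    for donor in donors:
        idx = [i for i in assignments.index if samples[i].donor_id == donor]
        donor_profiles[donor] = aggregate(
            assignments.loc[idx], samples, expression=norm[idx]
        )
    if len(donors) >= 2:
        kept = filter_inconsistent_genes(donor_profiles, min_consistency)
    else:
        kept = list(gene_index)
    atlas = aggregate(assignments, samples, expression=norm.loc[kept],
                      region_order=centroids.index)
    provenance = {
        "n_samples_in": len(samples),
        "n_samples_assigned": int(len(assignments)),
        "n_genes_in": int(len(gene_index)),
        "n_genes_retained": len(kept),
        "max_distance_mm": max_distance_mm,
        "min_consistency": min_consistency,
        "donors": donors,
        "missing_regions": [c for c in atlas.columns if atlas[c].isna().all()],
    }
    return atlas, provenance
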