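"""Readers and writers for the pipeline's external formats.

Structural networks are tab-delimited square matrices with a header row of
region labels; phenotypes are CSV; gene sets use the GMT dialect; subnetwork
exports use the BrainNet Viewer ``.node``/``.edge`` text formats.
Every reader validates before returning, so a failed load never yields a
partially constructed object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("HC", "MDDNSI", "MDDSI", "MDDSB")

#: Clinical scale columns expected in a phenotype table.
SCALE_COLUMNS = (
    "HAMD17",
    "HAMA",
    "CTQ",
    "RSES",
    "MoCA",
    "ERQ_CR",
    "ERQ_ES",
    "RFQ_promote",
    "RFQ_prevent",
)

#: Nuisance covariates used for partial correlations.
COVARIATE_COLUMNS = ("age", "sex", "education", "medication_load")

SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


@dataclass
class StructuralNetwork:
    """One subject's FA-weighted structural connectome.

    ``A`` is the symmetric nonnegative adjacency over ``region_labels``; it
    is also the system matrix of the linear network-dynamics model used for
    controllability.
    """

    subject_id: str
    region_labels: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.region_labels)
        if self.A.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.A.shape} does not match "
                f"{n} region labels"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValidationError("non-finite edge weight")
        if np.any(self.A < 0):
            i, j = np.unravel_index(np.argmin(self.A), self.A.shape)
            raise ValidationError(f"negative weight at cell ({i}, {j})")
        asym = np.abs(self.A - self.A.T)
        worst = np.unravel_index(np.argmax(asym), asym.shape)
        if asym[worst] > SYMMETRY_TOL:
            raise ValidationError(
                f"asymmetry {asym[worst]:.3g} at cell {tuple(int(x) for x in worst)} "
                f"exceeds tolerance {SYMMETRY_TOL:g}"
            )
        # text round-trips introduce float noise below the tolerance
        self.A = (self.A + self.A.T) / 2.0
        np.fill_diagonal(self.A, 0.0)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_connectome(path: str | Path) -> StructuralNetwork:
    """Load a tab-delimited square FA matrix with a region-label header.

    The subject id is taken from the file stem. Asymmetry beyond 1e-9 or a
    negative weight raises :class:`ValidationError`; a non-square matrix
    raises :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=None)
    labels = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(
            f"{path.name}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square"
        )
    return StructuralNetwork(subject_id=path.stem, region_labels=labels, A=mat)


def write_connectome(network: StructuralNetwork, path: str | Path) -> None:
    """Write a network in the same tab-delimited format ``read_connectome`` reads."""
    df = pd.DataFrame(network.A, columns=network.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load and validate a phenotype CSV.

    Requires unique subject ids, group labels from the closed set
    ``HC / MDDNSI / MDDSI / MDDSB``, sex in ``{F, M}`` and nonnegative ages.
    """
    df = pd.read_csv(path)
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "group", "age", "sex", "education", "medication_load"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    if (df["age"] < 0).any():
        raise ValidationError("negative age")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"sex must be F or M, got {sorted(bad_sex)}")
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are dropped with a warning; a duplicate
    set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "gene set %s: %d duplicate members removed",
                    name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_brainnet(
    coordinates: np.ndarray,
    colors: Sequence[float],
    sizes: Sequence[float],
    labels: Sequence[str],
    edges: np.ndarray,
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Emit BrainNet Viewer ``.node`` and ``.edge`` files for a subnetwork.

    The ``.node`` file has six whitespace-delimited columns
    (x y z color size label); the ``.edge`` file is the full symmetric N x N
    weight matrix.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    edges = np.asarray(edges, dtype=float)
    n = coordinates.shape[0]
    if coordinates.shape != (n, 3):
        raise ValidationError("coordinates must be N x 3")
    if edges.shape != (n, n):
        raise ValidationError(
            f"edge matrix {edges.shape} does not match {n} nodes"
        )
    if not (len(colors) == len(sizes) == len(labels) == n):
        raise ValidationError("colors, sizes and labels must have one entry per node")
    prefix = Path(path_prefix)
    node_path = prefix.with_suffix(".node")
    edge_path = prefix.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for (x, y, z), c, s, lab in zip(coordinates, colors, sizes, labels):
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t{c:g}\t{s:g}\t{lab}\n")
    np.savetxt(edge_path, (edges + edges.T) / 2.0, fmt="%.6g", delimiter="\t")
    return node_path, edge_path


def read_expression_atlas(path: str | Path) -> pd.DataFrame:
    """Load a genes x regions expression TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression atlas")
    return df


def write_expression_atlas(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.8g")
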