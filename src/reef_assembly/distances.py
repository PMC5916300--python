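"""Species x species dissimilarity matrices.

Builders for the three matrix families consumed by the quadratic-entropy
machinery: Gower mixed-trait distance, raw pairwise nucleotide p-distance
(per gene or over a concatenation, with pairwise deletion of gaps and
ambiguous bases), and patristic distance on a tree.  A Euclidean-
embeddability check guards the non-negativity of beta components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import GeneAlignment, normalize_label
from .tree import PhyloTree

__all__ = [
    "DistanceMatrix",
    "TraitSpec",
    "gower_distance",
    "p_distance",
    "concat_p_distance",
    "patristic_distance",
    "is_euclidean",
]

_SYM_TOL = 1e-12


@dataclass
class TraitSpec:
    """How one trait enters the Gower distance."""

    name: str
    kind: str  # "quantitative" | "nominal"
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("quantitative", "nominal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("trait weight must be >= 0")


class DistanceMatrix:
    """Symmetric nonnegative dissimilarities with labels and provenance.

    ``source`` is one of ``gower``, ``pdist:<gene>``, ``pdist:concat``,
    ``patristic``.  For p-distances ``n_sites[i, j]`` stores how many
    alignment columns the pair was compared at.
    """

    def __init__(
        self,
        labels: Sequence[str],
        values: np.ndarray,
        source: str = "unknown",
        n_sites: np.ndarray | None = None,
        allow_missing: bool = False,
    ):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        finite = np.isfinite(values)
        if not allow_missing and not finite.all():
            raise ValueError(f"{(~finite).sum()} missing entries in {source} matrix")
        if np.nanmax(np.abs(values - values.T)) > _SYM_TOL:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(values)).max() > _SYM_TOL:
            raise ValueError("distance matrix diagonal is not zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(values) < -_SYM_TOL:
                raise ValueError("negative distances")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.labels = list(labels)
        self.values = values
        self.source = source
        self.n_sites = n_sites

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        ii, jj = np.nonzero(np.isnan(np.triu(self.values, 1)))
        for i, j in zip(ii, jj):
            out.append((self.labels[i], self.labels[j]))
        return out

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Submatrix/reordering aligned to ``labels``."""
        labels = [normalize_label(l) for l in labels]
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in matrix: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        ns = self.n_sites[np.ix_(idx, idx)] if self.n_sites is not None else None
        return DistanceMatrix(
            labels, self.values[np.ix_(idx, idx)], self.source, ns,
            allow_missing=True,
        )

    # -- serialization -------------------------------------------------
    def to_csv(self, path, meta_path=None) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)
        if meta_path is not None:
            with open(meta_path, "w", encoding="utf-8") as fh:
                json.dump({"source": self.source, "n": self.n}, fh, indent=2)

    @classmethod
    def from_csv(cls, path, source: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [normalize_label(l) for l in df.index]
        return cls(labels, df.to_numpy(dtype=float), source=source)

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n}, source={self.source!r})"


# ----------------------------------------------------------------------
# Gower
# ----------------------------------------------------------------------

def gower_distance(
    species_trait_means: pd.DataFrame,
    trait_spec: Sequence[TraitSpec],
) -> DistanceMatrix:
    """Gower mixed-trait distance on a species-level table.

    Quantitative traits contribute range-scaled absolute differences,
    nominal traits 0/1 mismatch; traits missing for either member of a
    pair are excluded and the weights renormalized for that pair.
    Constant quantitative traits (zero range) are dropped with a warning.
    """
    if not trait_spec:
        raise ValueError("need at least one trait")
    df = species_trait_means
    if len(df) < 2:
        raise ValueError("need at least 2 species")
    labels = [normalize_label(l) for l in df.index]
    n = len(labels)

    per_trait_s = []   # (n, n) contribution, NaN where undefined
    weights = []
    for spec in trait_spec:
        col = df[spec.name]
        if spec.kind == "quantitative":
            x = col.to_numpy(dtype=float)
            valid = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if valid.any() else np.nan
            if not np.isfinite(rng) or rng == 0:
                warnings.warn(
                    f"dropping constant/empty quantitative trait {spec.name!r}",
                    stacklevel=2,
                )
                continue
            s = np.abs(x[:, None] - x[None, :]) / rng
            s[~valid, :] = np.nan
            s[:, ~valid] = np.nan
        else:
            vals = col.to_numpy(dtype=object)
            valid = np.array([v is not None and v == v for v in vals])
            s = (vals[:, None] != vals[None, :]).astype(float)
            s[~valid, :] = np.nan
            s[:, ~valid] = np.nan
        per_trait_s.append(s)
        weights.append(spec.weight)

    if not per_trait_s:
        raise ValueError("no usable traits after dropping constant ones")

    S = np.stack(per_trait_s)                     # (T, n, n)
    W = np.asarray(weights)[:, None, None]
    avail = np.isfinite(S)
    wsum = (W * avail).sum(axis=0)
    if (wsum == 0).any():
        ii, jj = np.nonzero(np.triu(wsum == 0, 1))
        pairs = [(labels[i], labels[j]) for i, j in zip(ii, jj)]
        raise ValueError(f"pairs share no non-missing trait: {pairs}")
    num = np.nansum(W * np.where(avail, S, 0.0), axis=0)
    d = num / wsum
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, source="gower")


# ----------------------------------------------------------------------
# p-distances
# ----------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T(U) -> 0..3; gaps, N and IUPAC ambiguity codes -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = _BASE_CODE.get(ch, -1)
    return out


def _pdist_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-deletion p-distance for rows of an (n, L) code matrix."""
    n = codes.shape[0]
    valid = codes >= 0
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = both & (codes[i] != codes[i + 1:])
        m = both.sum(axis=1)
        k = diff.sum(axis=1)
        sites[i, i + 1:] = m
        sites[i + 1:, i] = m
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(m > 0, k / np.maximum(m, 1), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
        sites[i, i] = valid[i].sum()
    return d, sites


def p_distance(alignment: GeneAlignment) -> DistanceMatrix:
    """Proportion of differing nucleotides among mutually unambiguous sites.

    Sites where either sequence has a gap, ``N`` or an IUPAC ambiguity code
    are deleted pairwise.  A pair with zero comparable sites is flagged
    missing (NaN); downstream use on a matrix with missing entries errors.
    """
    species = alignment.species
    if len(species) < 2:
        raise ValueError("need >= 2 species for p-distance")
    codes = np.stack([_encode(alignment.sequences[s]) for s in species])
    d, sites = _pdist_from_codes(codes)
    return DistanceMatrix(
        species, d, source=f"pdist:{alignment.gene_name}", n_sites=sites,
        allow_missing=True,
    )


def concat_p_distance(alignments: Sequence[GeneAlignment]) -> DistanceMatrix:
    """p-distance over the concatenation of several genes.

    Species missing a gene contribute no comparable sites for that gene;
    the distance for each pair is pooled over all concatenated columns.
    """
    if not alignments:
        raise ValueError("need >= 1 alignment")
    species = sorted({s for aln in alignments for s in aln.species})
    if len(species) < 2:
        raise ValueError("need >= 2 species for p-distance")
    blocks = []
    for aln in alignments:
        blk = np.full((len(species), aln.length), -1, dtype=np.int8)
        for i, sp in enumerate(species):
            if sp in aln.sequences:
                blk[i] = _encode(aln.sequences[sp])
        blocks.append(blk)
    codes = np.concatenate(blocks, axis=1)
    d, sites = _pdist_from_codes(codes)
    return DistanceMatrix(
        species, d, source="pdist:concat", n_sites=sites, allow_missing=True
    )


# ----------------------------------------------------------------------
# patristic
# ----------------------------------------------------------------------

def patristic_distance(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along each tip-to-tip path."""
    if not tree.has_branch_lengths:
        raise ValueError("tree lacks branch lengths")
    return DistanceMatrix(tree.tip_labels, tree.patristic(), source="patristic")


# ----------------------------------------------------------------------
# Euclidean check
# ----------------------------------------------------------------------

def is_euclidean(D: DistanceMatrix | np.ndarray, tol: float = 1e-9):
    """Whether the points are embeddable in Euclidean space.

    Checks positive semidefiniteness of the doubly-centered Gower matrix
    of ``-d_ij^2 / 2``.  Returns ``(bool, smallest_eigenvalue)``.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = d.shape[0]
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eig = np.linalg.eigvalsh((G + G.T) / 2.0)
    lam_min = float(eig[0])
    scale = max(1.0, float(eig[-1]))
    return lam_min >= -tol * scale, lam_min
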