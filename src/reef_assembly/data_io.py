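"""Readers, writers and cross-validation for the pipeline's input artifacts.

Four artifacts flow in: a rooted Newick tree, one or more aligned FASTA
gene files, a per-individual trait CSV, and a nested community CSV with
columns ``atoll,site,colony,species,count``.  ``validate_dataset`` makes
them mutually consistent and reports (never silently applies) exclusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .tree import PhyloTree, TreeError, _normalize_label

__all__ = [
    "GeneAlignment",
    "NestedCommunity",
    "ValidationReport",
    "normalize_label",
    "read_tree",
    "read_alignments",
    "read_alignment",
    "read_community",
    "read_traits",
    "write_community",
    "validate_dataset",
    "HABITAT_CATEGORIES",
]

HABITAT_CATEGORIES = ("hard_coral", "free_living", "semi_symbiotic", "sessile_invert")


def normalize_label(label: str) -> str:
    """Canonical species identifier: trimmed, underscores as spaces."""
    return _normalize_label(str(label))


# ----------------------------------------------------------------------
# tree
# ----------------------------------------------------------------------

def read_tree(path) -> PhyloTree:
    """Read and validate a rooted Newick tree.

    Polytomies are preserved; zero-length branches trigger a warning
    (inside :class:`PhyloTree`); duplicate tips raise.
    """
    return PhyloTree.from_file(path)


# ----------------------------------------------------------------------
# alignments
# ----------------------------------------------------------------------

@dataclass
class GeneAlignment:
    """An aligned set of nucleotide sequences for one gene, keyed by species."""

    gene_name: str
    sequences: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"alignment {self.gene_name!r} is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            bad = {k: len(v) for k, v in self.sequences.items()}
            raise ValueError(
                f"ragged alignment {self.gene_name!r}: lengths {bad}"
            )
        self.length = lengths.pop()
        if self.length == 0:
            raise ValueError(f"alignment {self.gene_name!r} has zero columns")

    @property
    def species(self) -> list[str]:
        return list(self.sequences)


def read_alignment(path, gene_name: str | None = None) -> GeneAlignment:
    """Read one aligned FASTA file; species = first token of each header."""
    path = Path(path)
    name = gene_name or path.stem
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = normalize_label(rec.id.split()[0] if rec.id else rec.description)
        if sp in seqs:
            raise ValueError(f"duplicate species {sp!r} in {path}")
        seqs[sp] = str(rec.seq).upper()
    return GeneAlignment(name, seqs)


def read_alignments(paths: Sequence) -> list[GeneAlignment]:
    """Read several gene alignments; species sets may differ between genes."""
    return [read_alignment(p) for p in paths]


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------

def _parse_diam_list(cell) -> list[float] | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return None
    vals = [float(x) for x in str(cell).split(";") if x.strip()]
    if any(v <= 0 for v in vals):
        raise ValueError(f"non-positive egg diameter in {cell!r}")
    return vals


def read_traits(path) -> pd.DataFrame:
    """Read the per-individual trait table.

    Required columns: ``species, carapace_length, habitat_assoc``.
    Optional gravid-female columns: ``egg_count`` plus semicolon-separated
    ``egg_long_diams`` / ``egg_short_diams``.
    """
    df = pd.read_csv(path)
    required = {"species", "carapace_length", "habitat_assoc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    df = df.copy()
    df["species"] = df["species"].map(normalize_label)
    if (df["carapace_length"] <= 0).any():
        raise ValueError("carapace_length must be > 0")
    bad_hab = set(df["habitat_assoc"].dropna()) - set(HABITAT_CATEGORIES)
    if bad_hab:
        raise ValueError(f"unknown habitat categories: {sorted(bad_hab)}")
    nun = df.groupby("species")["habitat_assoc"].nunique()
    inconsistent = nun[nun > 1].index.tolist()
    if inconsistent:
        raise ValueError(
            f"habitat_assoc varies within species: {inconsistent}"
        )
    if "egg_long_diams" in df.columns:
        df["egg_long_diams"] = df["egg_long_diams"].map(_parse_diam_list)
        df["egg_short_diams"] = df["egg_short_diams"].map(_parse_diam_list)
        for _, row in df.iterrows():
            L, S = row.get("egg_long_diams"), row.get("egg_short_diams")
            if L is not None and S is not None:
                if len(L) != len(S):
                    raise ValueError(
                        f"unequal numbers of long/short egg diameters for "
                        f"{row['species']!r}"
                    )
                if any(l < s for l, s in zip(L, S)):
                    raise ValueError(
                        f"long diameter < short diameter for {row['species']!r}"
                    )
    return df


# ----------------------------------------------------------------------
# community
# ----------------------------------------------------------------------

class NestedCommunity:
    """Abundance counts over the nested (atoll, site, colony, species) design.

    Exposes both a tidy record table (``records``) and a dense view used by
    the diversity code: a colonies x species count matrix plus the
    colony->site and site->atoll assignment arrays.  Colony identifiers are
    made globally unique internally as atoll/site/colony triples.
    """

    def __init__(self, records: pd.DataFrame):
        req = ["atoll", "site", "colony", "species", "count"]
        missing = set(req) - set(records.columns)
        if missing:
            raise ValueError(f"community table missing columns: {sorted(missing)}")
        df = records[req].copy()
        df["species"] = df["species"].map(normalize_label)
        for col in ("atoll", "site", "colony"):
            df[col] = df[col].astype(str)
        counts = df["count"]
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("fractional counts are not allowed")
        df["count"] = counts.astype(np.int64)
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0]
            raise ValueError(f"negative counts:\n{bad}")
        # aggregate duplicate rows
        df = (
            df.groupby(["atoll", "site", "colony", "species"], as_index=False)["count"]
            .sum()
        )
        # drop empty colonies
        totals = df.groupby(["atoll", "site", "colony"])["count"].transform("sum")
        if (totals == 0).any():
            dropped = (
                df.loc[totals == 0, ["atoll", "site", "colony"]]
                .drop_duplicates()
                .itertuples(index=False)
            )
            warnings.warn(
                "dropping empty colonies: "
                + ", ".join("/".join(t) for t in dropped),
                stacklevel=2,
            )
            df = df.loc[totals > 0]
        df = df.loc[df["count"] > 0].reset_index(drop=True)
        if df.empty:
            raise ValueError("community table has no positive counts")
        self.records = df
        self._build_dense()

    def _build_dense(self) -> None:
        df = self.records
        self.species = sorted(df["species"].unique())
        sp_idx = {s: i for i, s in enumerate(self.species)}
        atolls = sorted(df["atoll"].unique())
        site_keys = sorted(set(zip(df["atoll"], df["site"])))
        colony_keys = sorted(set(zip(df["atoll"], df["site"], df["colony"])))
        a_idx = {a: i for i, a in enumerate(atolls)}
        s_idx = {k: i for i, k in enumerate(site_keys)}
        c_idx = {k: i for i, k in enumerate(colony_keys)}
        X = np.zeros((len(colony_keys), len(self.species)), dtype=np.int64)
        for row in df.itertuples(index=False):
            X[c_idx[(row.atoll, row.site, row.colony)], sp_idx[row.species]] += row.count
        self.atolls = atolls
        self.site_keys = site_keys
        self.colony_keys = colony_keys
        self.X = X
        self.site_of_colony = np.array(
            [s_idx[(a, s)] for a, s, _ in colony_keys], dtype=np.int64
        )
        self.atoll_of_site = np.array(
            [a_idx[a] for a, _ in site_keys], dtype=np.int64
        )

    # -- derived dims --------------------------------------------------
    @property
    def n_atolls(self) -> int:
        return len(self.atolls)

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    @property
    def n_colonies(self) -> int:
        return len(self.colony_keys)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def sites_per_atoll(self) -> np.ndarray:
        return np.bincount(self.atoll_of_site, minlength=self.n_atolls)

    def colonies_per_site(self) -> np.ndarray:
        return np.bincount(self.site_of_colony, minlength=self.n_sites)

    # ------------------------------------------------------------------
    def subset_species(self, keep: Iterable[str]) -> "NestedCommunity":
        keep = {normalize_label(s) for s in keep}
        df = self.records[self.records["species"].isin(keep)]
        if df.empty:
            raise ValueError("no records left after species subset")
        return NestedCommunity(df)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "NestedCommunity":
        df = pd.DataFrame(rows, columns=["atoll", "site", "colony", "species", "count"])
        return cls(df)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        site_of_colony: np.ndarray,
        atoll_of_site: np.ndarray,
        species: Sequence[str],
    ) -> "NestedCommunity":
        rows = []
        for c in range(X.shape[0]):
            s = int(site_of_colony[c])
            a = int(atoll_of_site[s])
            for j in np.nonzero(X[c])[0]:
                rows.append(
                    (f"atoll{a}", f"site{s}", f"colony{c}", species[j], int(X[c, j]))
                )
        return cls.from_records(rows)

    def __repr__(self) -> str:
        return (
            f"NestedCommunity(A={self.n_atolls}, sites={self.n_sites}, "
            f"colonies={self.n_colonies}, species={self.n_species})"
        )


def read_community(path) -> NestedCommunity:
    """Read the nested community CSV and aggregate/validate it."""
    df = pd.read_csv(path)
    nc = NestedCommunity(df)
    return nc


def write_community(nc: NestedCommunity, path) -> None:
    nc.to_csv(path)


# ----------------------------------------------------------------------
# cross validation
# ----------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of cross-referencing tree, genes, traits and community."""

    missing_from_tree: list[str] = field(default_factory=list)
    missing_from_traits: list[str] = field(default_factory=list)
    missing_per_gene: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "missing_from_tree": self.missing_from_tree,
            "missing_from_traits": self.missing_from_traits,
            "missing_per_gene": self.missing_per_gene,
            "excluded": self.excluded,
            "retained": self.retained,
        }


def validate_dataset(
    tree: PhyloTree | None,
    alignments: Sequence[GeneAlignment] | None,
    traits: pd.DataFrame | None,
    community: NestedCommunity,
    drop_missing: bool = True,
) -> tuple[NestedCommunity, ValidationReport]:
    """Cross-reference the four artifacts and build a consistent dataset.

    Species present in the community but absent from the tree or the trait
    table are listed and (when ``drop_missing``) removed from the returned
    community.  Species missing from individual genes only are retained but
    flagged per gene.  Nothing is ever dropped silently.
    """
    community_sp = set(community.species)
    report = ValidationReport()
    if tree is not None:
        report.missing_from_tree = sorted(community_sp - set(tree.tip_labels))
    if traits is not None:
        report.missing_from_traits = sorted(
            community_sp - set(traits["species"].unique())
        )
    if alignments:
        for aln in alignments:
            miss = sorted(community_sp - set(aln.species))
            if miss:
                report.missing_per_gene[aln.gene_name] = miss

    to_exclude = set(report.missing_from_tree) | set(report.missing_from_traits)
    report.excluded = sorted(to_exclude)
    report.retained = sorted(community_sp - to_exclude)
    if drop_missing and to_exclude:
        community = community.subset_species(report.retained)
    return community, report
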