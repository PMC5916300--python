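"""End-to-end orchestration.

Reads the four input artifacts, builds the trait and genetic distance
matrices, runs the quadratic-entropy apportionment with SES tests at the
three spatial scales for every distance source, the per-gene robustness
summary, and the phylogenetic-signal battery (global and per atoll), and
writes a consolidated JSON/CSV report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import data_io, distances, diversity, signal, traits
from .data_io import NestedCommunity
from .distances import DistanceMatrix, TraitSpec
from .diversity import LEVELS

__all__ = [
    "PipelineConfig",
    "run_full_analysis",
    "gene_robustness_summary",
    "species_trait_means",
]

logger = logging.getLogger("reef_assembly")

ALPHA = 0.05


@dataclass
class PipelineConfig:
    tree: str
    traits: str
    community: str
    alignments: Sequence[str] = field(default_factory=list)
    n_perm: int = 999
    seed: int = 0
    halve_distances: bool = False
    fecundity_mode: str = "both"  # measured | interpolated | both
    levels: Sequence[str] = LEVELS
    out_dir: str | None = None

    def __post_init__(self):
        if self.fecundity_mode not in ("measured", "interpolated", "both"):
            raise ValueError(f"unknown fecundity mode {self.fecundity_mode!r}")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, (tuple, list)) else v
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


# ----------------------------------------------------------------------
# trait summaries
# ----------------------------------------------------------------------

def species_trait_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Species-level summary: mean carapace length, habitat, fecundity.

    Fecundity comes from gravid-female records when present (egg volume
    from the diameter lists, count rescaled against the cohort mean
    volume), averaged per species.
    """
    g = trait_table.groupby("species")
    out = pd.DataFrame(
        {
            "carapace_length": g["carapace_length"].mean(),
            "habitat_assoc": g["habitat_assoc"].first(),
        }
    )
    recs = []
    if "egg_count" in trait_table.columns:
        for idx, row in trait_table.iterrows():
            L = row.get("egg_long_diams")
            S = row.get("egg_short_diams")
            cnt = row.get("egg_count")
            if L is None or S is None or cnt is None or pd.isna(cnt):
                continue
            recs.append(
                traits.FecundityRecord(
                    species=row["species"],
                    female_id=str(idx),
                    carapace_length=row["carapace_length"],
                    egg_count=int(cnt),
                    mean_egg_volume=traits.egg_volume(L, S),
                )
            )
    out["fecundity"] = np.nan
    fec_diag: dict = {}
    if len(recs) >= 2:
        table, fec_diag = traits.fecundity_cohort(recs)
        means = table.loc[~table["excluded"]].groupby("species")[
            "adjusted_fecundity"
        ].mean()
        out.loc[means.index, "fecundity"] = means
    out.attrs["fecundity_diagnostics"] = fec_diag
    return out


def _trait_distance_rows(
    means: pd.DataFrame, fecundity_mode: str
) -> dict[str, DistanceMatrix]:
    rows: dict[str, DistanceMatrix] = {}
    body = TraitSpec("carapace_length", "quantitative")
    habitat = TraitSpec("habitat_assoc", "nominal")
    fec = TraitSpec("fecundity", "quantitative")

    have_fec = means["fecundity"].notna()
    total_specs = [body, fec, habitat] if have_fec.any() else [body, habitat]
    rows["total_traits"] = distances.gower_distance(means, total_specs)
    rows["body_size"] = distances.gower_distance(means, [body])
    rows["habitat_association"] = distances.gower_distance(means, [habitat])

    if fecundity_mode in ("interpolated", "both") and have_fec.sum() >= 3:
        interp = traits.interpolate_fecundity(
            means.loc[have_fec, "fecundity"].to_dict(),
            means["carapace_length"].to_dict(),
        )
        mi = means.copy()
        mi["fecundity"] = interp.set_index("species")["fecundity"]
        rows["total_traits_interpolated_fecundity"] = distances.gower_distance(
            mi, [body, fec, habitat]
        )
    return rows


# ----------------------------------------------------------------------
# signal battery
# ----------------------------------------------------------------------

def _signal_report(
    tree,
    trait_table: pd.DataFrame,
    means: pd.DataFrame,
    community: NestedCommunity,
    n_perm: int,
    seed: int,
) -> dict:
    report: dict = {}
    sp = [s for s in tree.tip_labels]

    indiv = {
        s: trait_table.loc[trait_table["species"] == s, "carapace_length"].to_numpy()
        for s in sp
    }
    k_me = signal.blomberg_k_me(tree, indiv, n_perm=n_perm, seed=seed)
    k_plain = signal.blomberg_k(
        tree, means.loc[sp, "carapace_length"], n_perm=n_perm, seed=seed
    )
    report["body_size"] = {
        "with_measurement_error": k_me.to_dict(),
        "without_measurement_error": k_plain.to_dict(),
    }

    have_fec = means["fecundity"].notna()
    if have_fec.reindex(sp).fillna(False).sum() >= 4:
        sub = tree.prune_to(means.index[have_fec & means.index.isin(sp)])
        kf = signal.blomberg_k(
            sub, means.loc[sub.tip_labels, "fecundity"], n_perm=n_perm, seed=seed
        )
        report["fecundity"] = {"without_measurement_error": kf.to_dict()}
    else:
        report["fecundity"] = {"note": "not testable: fewer than 4 measured species"}

    ms = signal.maddison_slatkin(
        tree, means.loc[sp, "habitat_assoc"].to_dict(), n_perm=n_perm, seed=seed
    )
    report["habitat_association"] = ms.to_dict()

    # per-atoll body-size K on the pruned tree
    per_atoll = {}
    pooled = diversity.pool_evenly(community)
    for a, atoll in enumerate(community.atolls):
        present = [
            community.species[j]
            for j in np.nonzero(pooled.atoll[a] > 0)[0]
            if community.species[j] in sp
        ]
        if len(present) < 4:
            per_atoll[atoll] = {"note": "not testable: fewer than 4 species"}
            continue
        sub = tree.prune_to(present)
        indiv_a = {s: indiv[s] for s in sub.tip_labels}
        try:
            ka = signal.blomberg_k_me(sub, indiv_a, n_perm=n_perm, seed=seed)
            per_atoll[atoll] = ka.to_dict()
        except ValueError as exc:
            per_atoll[atoll] = {"note": f"not testable: {exc}"}
    report["body_size_per_atoll"] = per_atoll
    return report


# ----------------------------------------------------------------------
# robustness
# ----------------------------------------------------------------------

def gene_robustness_summary(report: dict, alpha: float = ALPHA) -> dict:
    """Concordance of per-gene apportionment rows with the consensus row.

    Per gene and level: SES sign agreement and significance agreement at
    ``alpha``; per gene: Spearman rank correlation of SES across levels.
    """
    rows = report["rows"]
    gene_names = [r for r in rows if r.startswith("gene:")]
    if "consensus" not in rows or len(gene_names) < 1:
        raise ValueError("need a consensus row and >= 1 gene rows")
    cons = rows["consensus"]["levels"]
    out = {}
    for g in gene_names:
        lv = rows[g]["levels"]
        per_level = {}
        c_ses, g_ses = [], []
        for level in report["level_order"]:
            cs, gs = cons[level]["SES"], lv[level]["SES"]
            cp, gp = cons[level]["p_value"], lv[level]["p_value"]
            sign_agree = (
                None if cs is None or gs is None else bool(np.sign(cs) == np.sign(gs))
            )
            sig_agree = bool((cp < alpha) == (gp < alpha))
            per_level[level] = {
                "sign_agreement": sign_agree,
                "significance_agreement": sig_agree,
            }
            if cs is not None and gs is not None:
                c_ses.append(cs)
                g_ses.append(gs)
        if len(c_ses) < 2:
            rho = None
        elif np.allclose(c_ses, g_ses):
            rho = 1.0
        else:
            rho = float(stats.spearmanr(c_ses, g_ses).statistic)
            if np.isnan(rho):
                rho = None
        out[g] = {"levels": per_level, "ses_rank_correlation": rho}
    return out


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the whole analysis and return the consolidated report dict."""
    stage = "load"
    try:
        tree = data_io.read_tree(config.tree)
        trait_table = data_io.read_traits(config.traits)
        community = data_io.read_community(config.community)
        alignments = data_io.read_alignments(config.alignments)
        logger.info("loaded %s", community)

        stage = "validate"
        community, validation = data_io.validate_dataset(
            tree, alignments, trait_table, community
        )
        tree_c = tree.prune_to(community.species)
        trait_table = trait_table[trait_table["species"].isin(community.species)]

        stage = "traits"
        means = species_trait_means(trait_table).loc[community.species]

        stage = "distances"
        rows = _trait_distance_rows(means, config.fecundity_mode)
        if alignments:
            rows["consensus"] = distances.concat_p_distance(alignments)
            for aln in alignments:
                rows[f"gene:{aln.gene_name}"] = distances.p_distance(aln)
        else:
            rows["consensus"] = distances.patristic_distance(tree_c)

        stage = "apportionment"
        qe_report = diversity.tqe_pqe_report(
            community,
            rows,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "qe"),
            halve=config.halve_distances,
        )
        # significance flags, plus Holm-corrected extension column
        flat = []
        for rname, row in qe_report["rows"].items():
            for level in LEVELS:
                flat.append((rname, level, row["levels"][level]["p_value"]))
        pvals = np.array([f[2] for f in flat])
        order = np.argsort(pvals)
        holm = np.empty_like(pvals)
        mprev = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (len(pvals) - rank) * pvals[idx])
            mprev = max(mprev, adj)
            holm[idx] = mprev
        for (rname, level, p), ph in zip(flat, holm):
            cell = qe_report["rows"][rname]["levels"][level]
            cell["significant"] = bool(p < ALPHA)
            cell["p_holm"] = float(ph)

        stage = "robustness"
        robustness = None
        if sum(1 for r in qe_report["rows"] if r.startswith("gene:")) >= 1:
            robustness = gene_robustness_summary(qe_report)

        stage = "signal"
        signal_report = _signal_report(
            tree_c,
            trait_table,
            means,
            community,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "signal"),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "config": {**{k: (list(v) if isinstance(v, (tuple, list)) else v)
                      for k, v in config.__dict__.items()},
                   "hash": config.digest()},
        "level_order": list(LEVELS),
        "alpha": ALPHA,
        "validation": validation.to_dict(),
        "quadratic_entropy": qe_report,
        "gene_robustness": robustness,
        "phylogenetic_signal": signal_report,
    }
    if config.out_dir:
        _write_outputs(report, Path(config.out_dir))
    return report


def _qe_table(report: dict) -> pd.DataFrame:
    rows = []
    for rname, row in report["quadratic_entropy"]["rows"].items():
        rec: dict = {"source": rname}
        for level in report["level_order"]:
            cell = row["levels"][level]
            rec[f"{level}_SES"] = cell["SES"]
            rec[f"{level}_p"] = cell["p_value"]
        rows.append(rec)
    return pd.DataFrame(rows)


def _signal_table(report: dict) -> pd.DataFrame:
    rows = []
    for atoll, cell in report["phylogenetic_signal"]["body_size_per_atoll"].items():
        rows.append(
            {
                "atoll": atoll,
                "K": cell.get("K"),
                "sigma": cell.get("sigma"),
                "p": cell.get("p"),
                "note": cell.get("note"),
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    _qe_table(report).to_csv(out_dir / "table1.csv", index=False)
    _signal_table(report).to_csv(out_dir / "table2.csv", index=False)
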