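"""Rao quadratic entropy, its even-weighted hierarchical apportionment over
the unbalanced atoll/site/colony design, and per-level permutation tests.

The decomposition is additive: with every colony weighted ``1/(A S_a C_as)``,
every site ``1/(A S_a)`` and every atoll ``1/A``,

    gamma = alpha_within_colony
          + beta_colonies_within_sites
          + beta_sites_within_atolls
          + beta_atolls

exactly (to floating point).  Each level's permutation null breaks structure
only at that level:

* ``colonies_within_sites`` — individuals pooled per site and reallocated at
  random to the site's colonies, preserving colony sizes (multivariate
  hypergeometric draws);
* ``sites_within_atolls`` — colonies reassigned at random to sites within
  their atoll, preserving each site's colony count;
* ``atolls`` — whole sites (with their colonies) reassigned at random to
  atolls, preserving each atoll's site count.

Standardized effect size SES = (observed - null mean) / null sd; positive
SES indicates clustering (lower beta locally than under the null pushes the
sign the other way, see the report caption), negative over-dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import NestedCommunity
from .distances import DistanceMatrix

__all__ = [
    "LEVELS",
    "PooledAbundances",
    "LevelTest",
    "ApportionmentResult",
    "quadratic_entropy",
    "pool_evenly",
    "apportion_qe",
    "ses_test",
    "tqe_pqe_report",
]

LEVELS = ("atolls", "sites_within_atolls", "colonies_within_sites")

_BETA_KEY = {
    "atolls": "beta_atolls",
    "sites_within_atolls": "beta_sites_within_atolls",
    "colonies_within_sites": "beta_colonies_within_sites",
}


# ----------------------------------------------------------------------
# QE primitives
# ----------------------------------------------------------------------

def quadratic_entropy(
    p: np.ndarray, D: DistanceMatrix | np.ndarray, halve: bool = False
) -> float:
    """Rao's quadratic entropy ``sum_ij d_ij p_i p_j``.

    ``p`` must be a relative-abundance vector aligned to ``D``'s labels.
    With ``halve`` the distances are divided by two first.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.shape[0] != d.shape[0]:
        raise ValueError(f"abundance vector length {p.shape} != matrix {d.shape}")
    if (p < -1e-12).any():
        raise ValueError("negative abundances")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances sum to {p.sum()}, not 1")
    if np.isnan(d[np.ix_(p > 0, p > 0)]).any():
        raise ValueError("distance matrix has missing entries within support")
    q = float(p @ d @ p)
    return q / 2.0 if halve else q


def _qe_rows(P: np.ndarray, d: np.ndarray) -> np.ndarray:
    """QE of each row of a stack of abundance vectors."""
    return np.einsum("ij,jk,ik->i", P, d, P)


# ----------------------------------------------------------------------
# pooling
# ----------------------------------------------------------------------

@dataclass
class PooledAbundances:
    """Even-weight pooled relative abundances at the four levels."""

    colony: np.ndarray          # (C, n_sp) within-colony relative abundances
    site: np.ndarray            # (S, n_sp)
    atoll: np.ndarray           # (A, n_sp)
    archipelago: np.ndarray     # (n_sp,)
    colony_weights: np.ndarray  # 1 / (A * S_a * C_as)
    site_weights: np.ndarray    # 1 / (A * S_a)
    atoll_weights: np.ndarray   # 1 / A
    site_of_colony: np.ndarray
    atoll_of_site: np.ndarray
    species: list[str]


def _pool_arrays(
    X: np.ndarray, site_of_colony: np.ndarray, atoll_of_site: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(colony P, site P, atoll P, archipelago p) with even weights."""
    n_sites = atoll_of_site.shape[0]
    n_atolls = int(atoll_of_site.max()) + 1 if n_sites else 0
    tot = X.sum(axis=1, keepdims=True)
    if (tot == 0).any():
        raise ValueError("empty colony in abundance matrix")
    P = X / tot
    n_sp = X.shape[1]
    Psite = np.zeros((n_sites, n_sp))
    np.add.at(Psite, site_of_colony, P)
    c_per_s = np.bincount(site_of_colony, minlength=n_sites)
    if (c_per_s == 0).any():
        raise ValueError("site with no colonies")
    Psite /= c_per_s[:, None]
    Patoll = np.zeros((n_atolls, n_sp))
    np.add.at(Patoll, atoll_of_site, Psite)
    s_per_a = np.bincount(atoll_of_site, minlength=n_atolls)
    Patoll /= s_per_a[:, None]
    p = Patoll.mean(axis=0)
    return P, Psite, Patoll, p


def pool_evenly(community: NestedCommunity) -> PooledAbundances:
    """Pooled abundance vectors at colony/site/atoll/archipelago levels.

    Colonies within a site, sites within an atoll and atolls are averaged
    with equal weight, regardless of sample sizes (the design is
    unbalanced).
    """
    if community.n_atolls == 0:
        raise ValueError("community has no atolls")
    X = community.X.astype(float)
    soc, aos = community.site_of_colony, community.atoll_of_site
    P, Psite, Patoll, p = _pool_arrays(X, soc, aos)
    A = community.n_atolls
    s_per_a = community.sites_per_atoll()
    c_per_s = community.colonies_per_site()
    site_w = 1.0 / (A * s_per_a[aos])
    colony_w = site_w[soc] / c_per_s[soc]
    return PooledAbundances(
        colony=P,
        site=Psite,
        atoll=Patoll,
        archipelago=p,
        colony_weights=colony_w,
        site_weights=site_w,
        atoll_weights=np.full(A, 1.0 / A),
        site_of_colony=soc,
        atoll_of_site=aos,
        species=list(community.species),
    )


# ----------------------------------------------------------------------
# apportionment
# ----------------------------------------------------------------------

def _apportion_arrays(
    X: np.ndarray,
    site_of_colony: np.ndarray,
    atoll_of_site: np.ndarray,
    d: np.ndarray,
    halve: bool = False,
) -> dict[str, float]:
    P, Psite, Patoll, p = _pool_arrays(X, site_of_colony, atoll_of_site)
    if halve:
        d = d / 2.0
    n_sites = Psite.shape[0]
    n_atolls = Patoll.shape[0]
    qe_col = _qe_rows(P, d)
    qe_site = _qe_rows(Psite, d)
    qe_atoll = _qe_rows(Patoll, d)
    gamma = float(p @ d @ p)

    c_per_s = np.bincount(site_of_colony, minlength=n_sites)
    s_per_a = np.bincount(atoll_of_site, minlength=n_atolls)
    # mean colony QE per site
    mean_qe_col = np.zeros(n_sites)
    np.add.at(mean_qe_col, site_of_colony, qe_col)
    mean_qe_col /= c_per_s
    # mean site QE per atoll
    mean_qe_site = np.zeros(n_atolls)
    np.add.at(mean_qe_site, atoll_of_site, qe_site)
    mean_qe_site /= s_per_a

    site_w = 1.0 / (n_atolls * s_per_a[atoll_of_site])   # per site
    alpha = float(site_w @ mean_qe_col)
    beta_col = float(site_w @ (qe_site - mean_qe_col))
    beta_site = float((qe_atoll - mean_qe_site).sum() / n_atolls)
    beta_atoll = float(gamma - qe_atoll.sum() / n_atolls)
    return {
        "alpha_within_colony": alpha,
        "beta_colonies_within_sites": beta_col,
        "beta_sites_within_atolls": beta_site,
        "beta_atolls": beta_atoll,
        "gamma": gamma,
    }


@dataclass
class LevelTest:
    level: str
    observed_beta: float
    null_mean: float
    null_sd: float
    ses: float | None
    p_value: float
    n_perm: int
    seed: int
    null_sample: np.ndarray | None = None

    def to_dict(self, keep_null: bool = False) -> dict:
        out = {
            "level": self.level,
            "observed_beta": self.observed_beta,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "SES": self.ses,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        if keep_null and self.null_sample is not None:
            out["null_sample"] = self.null_sample.tolist()
        return out


@dataclass
class ApportionmentResult:
    """Gamma QE, its four additive components and optional per-level tests."""

    gamma: float
    components: dict[str, float]
    tests: dict[str, LevelTest] = field(default_factory=dict)

    def to_dict(self, keep_null: bool = False) -> dict:
        return {
            "gamma": self.gamma,
            "components": self.components,
            "tests": {k: t.to_dict(keep_null) for k, t in self.tests.items()},
        }


def _aligned(D: DistanceMatrix | np.ndarray, community: NestedCommunity) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        D = D.reorder(community.species)
        if D.has_missing:
            raise ValueError(
                f"distance matrix has missing pairs: {D.missing_pairs()}"
            )
        return D.values
    d = np.asarray(D, dtype=float)
    if d.shape != (community.n_species,) * 2:
        raise ValueError("bare matrix shape does not match community species")
    return d


def apportion_qe(
    community: NestedCommunity,
    D: DistanceMatrix | np.ndarray,
    halve: bool = False,
) -> ApportionmentResult:
    """Additive decomposition of archipelago QE across the three scales."""
    d = _aligned(D, community)
    comp = _apportion_arrays(
        community.X.astype(float),
        community.site_of_colony,
        community.atoll_of_site,
        d,
        halve=halve,
    )
    gamma = comp.pop("gamma")
    return ApportionmentResult(gamma=gamma, components=comp)


# ----------------------------------------------------------------------
# permutation nulls
# ----------------------------------------------------------------------

def _null_colonies(X, soc, aos, rng):
    """Reallocate each site's individuals to its colonies, sizes preserved."""
    Xn = np.empty_like(X)
    n_sites = aos.shape[0]
    for s in range(n_sites):
        rows = np.nonzero(soc == s)[0]
        pool = X[rows].sum(axis=0)
        sizes = X[rows].sum(axis=1)
        remaining = pool.copy()
        for k, r in enumerate(rows[:-1]):
            draw = rng.multivariate_hypergeometric(remaining, int(sizes[k]))
            Xn[r] = draw
            remaining -= draw
        Xn[rows[-1]] = remaining
    return Xn, soc, aos


def _null_sites(X, soc, aos, rng):
    """Permute colony->site assignment within each atoll."""
    soc_new = soc.copy()
    n_atolls = int(aos.max()) + 1
    for a in range(n_atolls):
        cols = np.nonzero(aos[soc] == a)[0]
        soc_new[cols] = soc[cols][rng.permutation(cols.shape[0])]
    return X, soc_new, aos


def _null_atolls(X, soc, aos, rng):
    """Permute site->atoll assignment, preserving per-atoll site counts."""
    return X, soc, aos[rng.permutation(aos.shape[0])]


_NULLS = {
    "colonies_within_sites": _null_colonies,
    "sites_within_atolls": _null_sites,
    "atolls": _null_atolls,
}


def ses_test(
    community: NestedCommunity,
    D: DistanceMatrix | np.ndarray,
    level: str,
    n_perm: int = 999,
    seed: int = 0,
    halve: bool = False,
    keep_null: bool = True,
) -> LevelTest:
    """Permutation SES test of the beta component at one spatial level.

    Two-sided p-value with the +1 correction:
    ``p = (1 + #{|null - null_mean| >= |obs - null_mean|}) / (n_perm + 1)``.
    When the null has zero spread the SES is undefined and reported as
    ``None`` (never coerced to zero).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d = _aligned(D, community)
    X = community.X.astype(float)
    soc, aos = community.site_of_colony, community.atoll_of_site
    key = _BETA_KEY[level]
    observed = _apportion_arrays(X, soc, aos, d, halve=halve)[key]
    rng = np.random.default_rng(seed)
    null_fn = _NULLS[level]
    Xi = community.X  # integer counts for hypergeometric draws
    null = np.empty(n_perm)
    for b in range(n_perm):
        Xb, socb, aosb = null_fn(Xi, soc, aos, rng)
        null[b] = _apportion_arrays(
            Xb.astype(float), socb, aosb, d, halve=halve
        )[key]
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    dev_obs = abs(observed - mu)
    p = (1.0 + int((np.abs(null - mu) >= dev_obs - 1e-12).sum())) / (n_perm + 1.0)
    ses = (observed - mu) / sd if sd > 0 else None
    return LevelTest(
        level=level,
        observed_beta=observed,
        null_mean=mu,
        null_sd=sd,
        ses=ses,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        null_sample=null if keep_null else None,
    )


def apportion_with_tests(
    community: NestedCommunity,
    D: DistanceMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    halve: bool = False,
    levels: Sequence[str] = LEVELS,
) -> ApportionmentResult:
    """Full apportionment plus SES tests at the requested levels."""
    res = apportion_qe(community, D, halve=halve)
    for level in levels:
        res.tests[level] = ses_test(
            community, D, level, n_perm=n_perm, seed=seed, halve=halve,
            keep_null=False,
        )
    return res


# ----------------------------------------------------------------------
# report
# ----------------------------------------------------------------------

def tqe_pqe_report(
    community: NestedCommunity,
    distance_rows: Mapping[str, DistanceMatrix | np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    halve: bool = False,
) -> dict:
    """Grid report: one row per distance source, SES and p at each level.

    Every row uses the same seed so that identical distance matrices yield
    identical rows.  Sign convention: negative SES = over-dispersed,
    positive = clustered.
    """
    rows = {}
    for name, D in distance_rows.items():
        res = apportion_with_tests(
            community, D, n_perm=n_perm, seed=seed, halve=halve
        )
        rows[name] = {
            "gamma": res.gamma,
            "components": res.components,
            "levels": {
                level: {
                    "SES": res.tests[level].ses,
                    "p_value": res.tests[level].p_value,
                }
                for level in LEVELS
            },
        }
    return {
        "level_order": list(LEVELS),
        "sign_convention": "negative SES = over-dispersed, positive = clustered",
        "n_perm": n_perm,
        "seed": seed,
        "rows": rows,
    }
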