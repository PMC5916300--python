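"""Phylogenetic-signal statistics.

Blomberg's K for quantitative traits — optionally with intraspecific
sampling error folded in via a one-parameter ML fit — and the
Maddison–Slatkin parsimony randomization test for nominal traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .tree import PhyloTree

__all__ = [
    "KResult",
    "DiscreteSignalResult",
    "phylo_vcv",
    "blomberg_k",
    "blomberg_k_me",
    "fitch_steps",
    "maddison_slatkin",
]


def phylo_vcv(tree: PhyloTree) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    Tips are ordered as in ``tree.tip_labels``.
    """
    return tree.vcv()


@dataclass
class KResult:
    K: float
    sigma: float | None
    p: float | None
    n_perm: int
    seed: int | None
    used_measurement_error: bool

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "sigma": self.sigma,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "used_measurement_error": self.used_measurement_error,
        }


@dataclass
class DiscreteSignalResult:
    observed_steps: int
    null_steps: np.ndarray
    p: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_steps": self.observed_steps,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_mean": float(self.null_steps.mean()) if self.null_steps.size else None,
        }


# ----------------------------------------------------------------------
# Blomberg's K
# ----------------------------------------------------------------------

def _as_vector(tree: PhyloTree, values) -> np.ndarray:
    if isinstance(values, Mapping):
        from .data_io import normalize_label

        vals = {normalize_label(k): v for k, v in values.items()}
        missing = [l for l in tree.tip_labels if l not in vals]
        if missing:
            raise ValueError(f"no trait value for tips: {missing}")
        return np.array([float(vals[l]) for l in tree.tip_labels])
    x = np.asarray(values, dtype=float)
    if x.shape != (tree.n_tips,):
        raise ValueError("trait vector length does not match tip count")
    return x


def _k_statistic(x: np.ndarray, C: np.ndarray, Cinv: np.ndarray, denom: float) -> float:
    n = x.shape[0]
    one = np.ones(n)
    a = (one @ Cinv @ x) / (one @ Cinv @ one)
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    if mse0 == 0:
        raise ValueError("no variance in trait values")
    return (mse0 / mse) / denom


def _k_setup(C: np.ndarray):
    n = C.shape[0]
    one = np.ones(n)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Cinv = np.linalg.inv(C + 1e-10 * np.eye(n))
        warnings.warn("covariance matrix singular; jittered by 1e-10 I", stacklevel=3)
    denom = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    return Cinv, denom


def blomberg_k(
    tree: PhyloTree,
    species_values,
    n_perm: int = 999,
    seed: int | None = 0,
) -> KResult:
    """Blomberg's K with a tip-permutation p-value (one-tailed on large K).

    K = 1 is the Brownian-motion expectation; K < 1 means less similarity
    among relatives than Brownian motion predicts.
    """
    x = _as_vector(tree, species_values)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    C = phylo_vcv(tree)
    Cinv, denom = _k_setup(C)
    k_obs = _k_statistic(x, C, Cinv, denom)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            k_b = _k_statistic(x[rng.permutation(n)], C, Cinv, denom)
            if k_b >= k_obs - 1e-12:
                ge += 1
        p = (1.0 + ge) / (n_perm + 1.0)
    return KResult(
        K=float(k_obs), sigma=None, p=p, n_perm=n_perm, seed=seed,
        used_measurement_error=False,
    )


def _neg_profile_loglik(log_sigma2: float, C: np.ndarray, m: np.ndarray, x: np.ndarray):
    sigma2 = np.exp(log_sigma2)
    n = x.shape[0]
    V = sigma2 * C + np.diag(m)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e300
    one = np.ones(n)
    iv1 = np.linalg.solve(L.T, np.linalg.solve(L, one))
    ivx = np.linalg.solve(L.T, np.linalg.solve(L, x))
    a = (one @ ivx) / (one @ iv1)
    r = x - a
    ivr = np.linalg.solve(L.T, np.linalg.solve(L, r))
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return 0.5 * (logdet + r @ ivr + n * np.log(2 * np.pi))


def _fit_sigma2(C: np.ndarray, m: np.ndarray, x: np.ndarray) -> float:
    scale = max(float(np.var(x)), 1e-12)
    lo, hi = np.log(1e-8 * scale), np.log(1e8 * scale)
    res = optimize.minimize_scalar(
        _neg_profile_loglik,
        bounds=(lo, hi),
        args=(C, m, x),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ValueError("non-finite likelihood optimum in measurement-error fit")
    return float(np.exp(res.x))


def blomberg_k_me(
    tree: PhyloTree,
    individual_values_by_species: Mapping[str, Sequence[float]],
    n_perm: int = 999,
    seed: int | None = 0,
) -> KResult:
    """Blomberg's K incorporating intraspecific sampling error.

    Species means get sampling variances ``m_i = s_i^2 / n_i``; the
    among-species Brownian rate ``sigma^2`` is fit by ML under
    ``xbar ~ N(a 1, sigma^2 C + diag(m))`` and K is computed with the
    error-inflated covariance ``C + diag(m) / sigma^2``.  ``sigma`` in the
    result is the fitted rate.  Species observed once borrow the pooled
    within-species variance.  With all ``m_i = 0`` this reduces exactly to
    :func:`blomberg_k` on species means.
    """
    from .data_io import normalize_label

    vals = {
        normalize_label(k): np.asarray(v, dtype=float)
        for k, v in individual_values_by_species.items()
    }
    missing = [l for l in tree.tip_labels if l not in vals]
    if missing:
        raise ValueError(f"no individuals for tips: {missing}")
    xbar = np.array([vals[l].mean() for l in tree.tip_labels])
    n_i = np.array([vals[l].size for l in tree.tip_labels])
    s2 = np.array(
        [vals[l].var(ddof=1) if vals[l].size > 1 else np.nan for l in tree.tip_labels]
    )
    if np.isnan(s2).any():
        pooled_num = np.nansum(s2 * (n_i - 1))
        pooled_den = np.sum(n_i - 1)
        pooled = pooled_num / pooled_den if pooled_den > 0 else 0.0
        s2 = np.where(np.isnan(s2), pooled, s2)
    m = s2 / n_i

    n = xbar.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    C = phylo_vcv(tree)

    if np.all(m == 0):
        warnings.warn(
            "all sampling variances are zero; falling back to blomberg_k",
            stacklevel=2,
        )
        base = blomberg_k(tree, xbar, n_perm=n_perm, seed=seed)
        return KResult(
            K=base.K, sigma=None, p=base.p, n_perm=n_perm, seed=seed,
            used_measurement_error=False,
        )

    def k_with_me(x: np.ndarray, mm: np.ndarray) -> tuple[float, float]:
        sigma2 = _fit_sigma2(C, mm, x)
        Ce = C + np.diag(mm) / sigma2
        Cinv, denom = _k_setup(Ce)
        return _k_statistic(x, Ce, Cinv, denom), sigma2

    k_obs, sigma2_hat = k_with_me(xbar, m)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            k_b, _ = k_with_me(xbar[perm], m[perm])
            if k_b >= k_obs - 1e-12:
                ge += 1
        p = (1.0 + ge) / (n_perm + 1.0)
    return KResult(
        K=float(k_obs), sigma=float(sigma2_hat), p=p, n_perm=n_perm, seed=seed,
        used_measurement_error=True,
    )


# ----------------------------------------------------------------------
# discrete signal
# ----------------------------------------------------------------------

def fitch_steps(tree: PhyloTree, tip_states) -> int:
    """Minimum number of state changes of a discrete character on the tree.

    Hartigan's generalization of the Fitch pass handles polytomies: at each
    internal node keep the states held by the maximal number of children
    and add (#children - that maximum) changes.
    """
    if isinstance(tip_states, Mapping):
        from .data_io import normalize_label

        states = {normalize_label(k): v for k, v in tip_states.items()}
        missing = [l for l in tree.tip_labels if l not in states]
        if missing:
            raise ValueError(f"unlabeled tips: {missing}")
        tip_vec = [states[l] for l in tree.tip_labels]
    else:
        tip_vec = list(tip_states)
        if len(tip_vec) != tree.n_tips:
            raise ValueError("state vector length does not match tip count")
    alphabet = {s: i for i, s in enumerate(dict.fromkeys(tip_vec))}
    masks = np.zeros(tree.n_nodes, dtype=np.int64)
    steps = 0
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            masks[i] = 1 << alphabet[tip_vec[i]]
            continue
        counts: dict[int, int] = {}
        for c in kids:
            mk = int(masks[c])
            b = 0
            while mk:
                if mk & 1:
                    counts[b] = counts.get(b, 0) + 1
                mk >>= 1
                b += 1
        mx = max(counts.values())
        mask = 0
        for b, cnt in counts.items():
            if cnt == mx:
                mask |= 1 << b
        masks[i] = mask
        steps += len(kids) - mx
    return steps


def maddison_slatkin(
    tree: PhyloTree,
    tip_states,
    n_perm: int = 999,
    seed: int | None = 0,
) -> DiscreteSignalResult:
    """Parsimony-steps randomization test for a discrete trait.

    The observed Fitch step count is compared to counts on random
    permutations of the tip states (state frequencies preserved);
    ``p = (1 + #{null <= observed}) / (n_perm + 1)``, one-tailed on few
    steps (signal = fewer changes than expected).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(tip_states, Mapping):
        from .data_io import normalize_label

        states = {normalize_label(k): v for k, v in tip_states.items()}
        vec = [states[l] for l in tree.tip_labels]
    else:
        vec = list(tip_states)
    if len(set(vec)) < 2:
        warnings.warn("single-state trait: degenerate test", stacklevel=2)
        return DiscreteSignalResult(0, np.array([]), 1.0, n_perm, seed)
    observed = fitch_steps(tree, vec)
    rng = np.random.default_rng(seed)
    arr = np.array(vec, dtype=object)
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        null[b] = fitch_steps(tree, arr[rng.permutation(arr.shape[0])])
    p = (1.0 + int((null <= observed).sum())) / (n_perm + 1.0)
    return DiscreteSignalResult(
        observed_steps=int(observed), null_steps=null, p=p, n_perm=n_perm, seed=seed
    )
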