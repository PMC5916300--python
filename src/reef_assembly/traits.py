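"""Fecundity trait construction.

Egg volumes from paired long/short diameters (prolate spheroid), egg
counts rescaled by relative egg volume into a size-adjusted fecundity,
and a log-log power-law interpolation of fecundity from body size for
species without gravid females.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FecundityRecord",
    "egg_volume",
    "adjusted_fecundity",
    "fecundity_cohort",
    "interpolate_fecundity",
]


@dataclass
class FecundityRecord:
    species: str
    female_id: str
    carapace_length: float
    egg_count: int
    mean_egg_volume: float
    adjusted_fecundity: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


def egg_volume(long_diams: Sequence[float], short_diams: Sequence[float]) -> float:
    """Mean prolate-spheroid volume of a clutch sample.

    Per egg ``V = (pi / 6) * L * S**2`` with the third axis assumed equal
    to the short one; returns the mean over the measured eggs.  At least
    three eggs are required.
    """
    L = np.asarray(long_diams, dtype=float)
    S = np.asarray(short_diams, dtype=float)
    if L.shape != S.shape:
        raise ValueError("long/short diameter lists differ in length")
    if L.size < 3:
        raise ValueError("need at least 3 measured eggs")
    if (L <= 0).any() or (S <= 0).any():
        raise ValueError("egg diameters must be positive")
    if (L < S).any():
        raise ValueError("long diameter smaller than short diameter")
    return float(np.mean(np.pi / 6.0 * L * S**2))


def adjusted_fecundity(
    egg_count: int, mean_egg_volume: float, cohort_volumes: Sequence[float]
) -> float:
    """Egg number rescaled by relative egg volume.

    ``adjusted = egg_count * (mean_egg_volume / cohort mean volume)`` —
    the clutch's reproductive volume expressed in units of average-sized
    eggs, so the value is invariant to the volume unit.
    """
    vols = np.asarray(cohort_volumes, dtype=float)
    if vols.size < 2:
        raise ValueError("cohort must contain at least 2 females")
    if egg_count <= 0 or mean_egg_volume <= 0:
        raise ValueError("egg count and volume must be positive")
    return float(egg_count * mean_egg_volume / vols.mean())


def fecundity_cohort(records: Sequence[FecundityRecord]) -> tuple[pd.DataFrame, dict]:
    """Adjust every retained female's fecundity against the cohort mean.

    Excluded records (damaged sacs etc.) are kept in the table with their
    reason but do not enter the reference volume.  Also returns simple
    diagnostic regressions of egg number on egg volume and on body size
    (slopes, p-values); these describe the trade-off but do not alter the
    adjustment.
    """
    retained = [r for r in records if not r.excluded]
    if len(retained) < 2:
        raise ValueError("need at least 2 retained gravid females")
    vols = [r.mean_egg_volume for r in retained]
    rows = []
    for r in records:
        adj = (
            adjusted_fecundity(r.egg_count, r.mean_egg_volume, vols)
            if not r.excluded
            else np.nan
        )
        rows.append(
            {
                "species": r.species,
                "female_id": r.female_id,
                "carapace_length": r.carapace_length,
                "egg_count": r.egg_count,
                "mean_egg_volume": r.mean_egg_volume,
                "adjusted_fecundity": adj,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
        )
    table = pd.DataFrame(rows)

    kept = table.loc[~table["excluded"]]
    diagnostics = {}
    for xcol, name in (
        ("mean_egg_volume", "egg_number_vs_egg_volume"),
        ("carapace_length", "egg_number_vs_body_size"),
    ):
        if kept[xcol].nunique() > 1:
            fit = stats.linregress(kept[xcol], kept["egg_count"])
            diagnostics[name] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.rvalue,
                "p_value": fit.pvalue,
                "stderr": fit.stderr,
            }
    diagnostics["note"] = (
        "linear diagnostics only; a smoother is under-determined at this "
        "sample size and the adjustment itself is volume rescaling"
    )
    return table, diagnostics


def interpolate_fecundity(
    species_means: Mapping[str, float],
    body_sizes_all_species: Mapping[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Predict fecundity from body size for unmeasured species.

    Fits ``log(fecundity) ~ log(body size)`` by least squares on the
    measured species and predicts the rest; measured species keep their
    observed means.  Deterministic — the ``seed`` slot is reserved.

    Returns a table with columns ``species, body_size, fecundity, origin``
    (``measured`` or ``interpolated``) plus fit attributes in ``.attrs``.
    """
    measured = {k: float(v) for k, v in species_means.items()}
    if len(measured) < 3:
        raise ValueError("interpolation unidentifiable: need >= 3 measured species")
    sizes = {k: float(v) for k, v in body_sizes_all_species.items()}
    missing_size = [s for s in measured if s not in sizes]
    if missing_size:
        raise ValueError(f"no body size for measured species: {missing_size}")
    if any(v <= 0 for v in measured.values()) or any(v <= 0 for v in sizes.values()):
        raise ValueError("fecundity and body size must be positive for log-log fit")

    xs = np.log([sizes[s] for s in measured])
    ys = np.log([measured[s] for s in measured])
    if np.unique(xs).size < 2:
        raise ValueError("measured species have identical body sizes")
    fit = stats.linregress(xs, ys)

    rows = []
    for sp, size in sizes.items():
        if sp in measured:
            rows.append((sp, size, measured[sp], "measured"))
        else:
            pred = float(np.exp(fit.intercept + fit.slope * np.log(size)))
            rows.append((sp, size, pred, "interpolated"))
    out = pd.DataFrame(rows, columns=["species", "body_size", "fecundity", "origin"])
    out.attrs["fit"] = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "stderr": fit.stderr,
        "r": fit.rvalue,
        "p_value": fit.pvalue,
        "n_measured": len(measured),
    }
    return out
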