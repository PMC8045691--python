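"""Derived genetic summaries: breed-group variances, heritability, repeatability.

Given posterior-mean variance components, the additive variance of a
synthetic-derivative cross type is the f-weighted sum of the pure-breed
variances, the segregation variance is the coefficient-weighted sum of the
two segregation components, and their sum is the total additive variance.
Narrow-sense heritability and line-mean repeatability follow as

    h2   = sigma2_A / (sigma2_A + sigma2_GE + sigma2_e)            (plot basis)
    H2_LM = sigma2_A / (sigma2_A + sigma2_GE/yl + sigma2_e/(yl*b))

with yl = n_GYL / n_G the average number of year-location combinations per
genotype and b = n / n_GYL the average number of replications per cell.

Narrow-sense heritability is computed on the plot basis (no yl, b divisors):
that is the reading that reproduces the published per-group values
(0.47/0.52/0.44/0.35 and 0.13 for the one-breed model); the replication
divisors enter the line-mean repeatability only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import VarianceComponents, build_partial_matrices
from .pedigree import backcross_chain, breed_fractions

#: Cross types of the standard backcross scheme and their chain depth.
CROSS_TYPES = ("F1", "BC1", "BC2", "BC3")

#: Published posterior-mean variance components for SAWYT grain yield
#: (multi-breed model), used as worked-example inputs throughout the docs
#: and tests: D, T, V, DV, TV, GxE, error, in (t/ha)^2.
SAWYT_GRAIN_YIELD_MULTIBREED = VarianceComponents(
    sigma2_D=0.616, sigma2_T=0.613, sigma2_V=0.182,
    sigma2_DV=0.161, sigma2_TV=0.327,
    sigma2_GE=0.105, sigma2_e=0.682,
)

#: Published one-breed (homogeneous) counterparts: genotype, GxE, error.
SAWYT_GRAIN_YIELD_ONEBREED = {
    "genotype": 0.122, "ge": 0.127, "error": 0.670,
}

#: Replication structure of the SAWYT grain-yield data: 4590 records on 88
#: genotypes over 2200 genotype-by-year-by-location cells.
SAWYT_REPLICATION = None  # set below, after ReplicationSummary is defined


@dataclass(frozen=True)
class ReplicationSummary:
    """Counts defining the average replication divisors yl and b."""

    n: int
    n_G: int
    n_GYL: int

    def __post_init__(self) -> None:
        if not (self.n >= self.n_GYL >= self.n_G > 0):
            raise ValueError("need n >= n_GYL >= n_G > 0")

    @property
    def yl(self) -> float:
        return self.n_GYL / self.n_G

    @property
    def b(self) -> float:
        return self.n / self.n_GYL


SAWYT_REPLICATION = ReplicationSummary(n=4590, n_G=88, n_GYL=2200)


def narrow_sense_h2(total_additive: float, sigma2_GE: float,
                    sigma2_e: float) -> float:
    """Plot-basis narrow-sense heritability sigma2_A / sigma2_P."""
    for v in (total_additive, sigma2_GE, sigma2_e):
        if v < 0:
            raise ValueError("variances must be non-negative")
    denom = total_additive + sigma2_GE + sigma2_e
    if denom == 0:
        raise ValueError("all variance components are zero")
    return total_additive / denom


def line_mean_repeatability(total_additive: float, sigma2_GE: float,
                            sigma2_e: float,
                            rs: ReplicationSummary) -> float:
    """Line-mean repeatability with GxE and error shrunk by replication."""
    denom = total_additive + sigma2_GE / rs.yl + sigma2_e / (rs.yl * rs.b)
    if denom == 0:
        raise ValueError("zero denominator")
    return total_additive / denom


def group_variances(
    vc: VarianceComponents,
    cross_types: Sequence[str] = CROSS_TYPES,
    replication: Optional[ReplicationSummary] = None,
) -> pd.DataFrame:
    """Per-cross-type variance table (layout mirrors the published summary).

    Rows: percent synthetic genome, additive variance, segregation variance,
    total additive variance, narrow-sense heritability and (if a replication
    summary is given) line-mean repeatability.  Columns: cross types.
    Coefficients come from the partial-relationship diagonals of a canonical
    non-inbred representative of each cross type with unrelated parents.
    """
    unknown = [c for c in cross_types if c not in CROSS_TYPES]
    if unknown:
        raise ValueError(f"unknown cross types {unknown}; "
                         f"expected a subset of {CROSS_TYPES}")
    ped = backcross_chain(depth=3)
    fr = breed_fractions(ped)
    pk = build_partial_matrices(ped, fr)
    sig = vc.genetic
    table: dict[str, dict[str, float]] = {}
    for ct in cross_types:
        additive = sum(pk.coefficient(q, ct) * sig[q] for q in ("D", "T", "V"))
        segregation = (pk.coefficient("DV", ct) * sig["DV"]
                       + pk.coefficient("TV", ct) * sig["TV"])
        total = additive + segregation
        degenerate = total + vc.sigma2_GE + vc.sigma2_e == 0
        col = {
            "percent_synthetic": 100.0 * fr.loc[ct, "f_D"],
            "additive_variance": additive,
            "segregation_variance": segregation,
            "total_additive_variance": total,
            "narrow_sense_heritability": np.nan if degenerate else
            narrow_sense_h2(total, vc.sigma2_GE, vc.sigma2_e),
        }
        if replication is not None:
            col["line_mean_repeatability"] = np.nan if degenerate else \
                line_mean_repeatability(total, vc.sigma2_GE, vc.sigma2_e,
                                        replication)
        table[ct] = col
    return pd.DataFrame(table)


def compare_blups(x: pd.Series, y: pd.Series) -> float:
    """Pearson correlation of two breeding-value columns on shared genotypes."""
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared genotypes")
    xv = x.loc[common].to_numpy(float)
    yv = y.loc[common].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant breeding-value column")
    return float(stats.pearsonr(xv, yv).statistic)
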