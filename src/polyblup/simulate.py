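"""Synthetic pedigrees, phenotypes and a gene-dropping oracle.

The generators emulate the structure of a semi-arid wheat yield trial
programme: diploid *Ae. tauschii* (D) and tetraploid *T. turgidum* (T)
founders crossed and doubled into synthetics (S), synthetics crossed to
hexaploid *T. aestivum* (V) and backcrossed up to three more times, with
phenotypes observed over location-by-cycle environments with replication,
iid genotype-by-environment effects and Gaussian errors.

The gene-dropping oracle is a brute-force check of the partial relationship
matrices: founder alleles at unlinked biallelic loci are sampled from
breed-specific frequencies, transmitted by independent meiosis per subgenome
(allopolyploid subgenomes behave as independent diploids), doubled literally
at S nodes (the two homologs are identical copies of one gamete), and summed
into genotypic values.  Empirical covariances across replicates are compared
with sum_Q a_Q(i,j) * sigma2_Q, where the component variances follow
analytically from the configured frequencies and effects:

    sigma2_B  = ploidy_B * sum_l e_l^2 p_Bl (1 - p_Bl)      (B = D, T, V)
    sigma2_BV = (1/2) * sum_l e_l^2 (p_Bl - p_Vl)^2          (B = D, T)

Because the doubling is literal, the oracle agrees with the "literal"
tabular rule everywhere and with the default "printed" rule on every pair
whose shared ancestry does not pass through an S doubling; disagreeing pairs
are reported both ways rather than silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .kinship import (
    COMPONENTS,
    PartialKinship,
    VarianceComponents,
    build_partial_matrices,
)
from .pedigree import Individual, Pedigree

#: Subgenomes carried by each breed group: 0, 1 are the tetraploid (A, B)
#: genomes, 2 is the diploid (D) genome.  Hexaploids carry all three.
_SUBGENOMES = {"D": (2,), "T": (0, 1), "V": (0, 1, 2),
               "S": (0, 1, 2), "SD": (0, 1, 2)}


@dataclass(frozen=True)
class SimScheme:
    """Breeding-scheme and trial dimensions for the synthetic generators.

    Defaults mirror the published trial database: 10 D, 21 T and 105 V
    founders, 16 synthetics, and (12, 45, 24, 7) cross terminals at the
    F1/BC1/BC2/BC3 levels (152 parents, 88 crosses); 5 locations x 4 cycles
    with 2 replicates per genotype-environment cell.
    """

    n_diploid: int = 10
    n_tetraploid: int = 21
    n_hexaploid: int = 105
    n_synthetic: int = 16
    crosses_by_depth: tuple[int, ...] = (12, 45, 24, 7)
    n_locations: int = 5
    n_cycles: int = 4
    n_reps: int = 2
    env_presence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_diploid, self.n_tetraploid, self.n_hexaploid,
                  self.n_synthetic, self.n_locations, self.n_cycles,
                  self.n_reps)
        if any(c < 1 for c in counts):
            raise ValueError("all scheme counts must be positive")
        if not 1 <= len(self.crosses_by_depth) <= 4:
            raise ValueError("crosses_by_depth supports depths F1..BC3")
        if any(c < 1 for c in self.crosses_by_depth):
            raise ValueError("cross counts must be positive")
        if not 0 < self.env_presence <= 1:
            raise ValueError("env_presence must be in (0, 1]")

    @property
    def n_parents(self) -> int:
        return (self.n_diploid + self.n_tetraploid + self.n_hexaploid
                + self.n_synthetic)

    @property
    def n_crosses(self) -> int:
        return int(sum(self.crosses_by_depth))

    @classmethod
    def recovery_template(cls, **overrides) -> "SimScheme":
        """Scaled scheme with 300 phenotyped crosses (41/153/82/24),
        keeping the founder structure and 20 environments x 2 reps."""
        kw = dict(crosses_by_depth=(41, 153, 82, 24))
        kw.update(overrides)
        return cls(**kw)


def simulate_pedigree(scheme: SimScheme, seed: Optional[int] = None
                      ) -> Pedigree:
    """Generate a grammar-valid pedigree following the backcross scheme.

    Deeper crosses reuse randomly chosen shallower crosses as their
    synthetic-derivative parent, so the pedigree holds exactly
    ``scheme.n_parents`` founders/synthetics plus ``scheme.n_crosses``
    derivative lines.
    """
    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    inds: list[Individual] = []
    d_ids = [f"D{i + 1}" for i in range(scheme.n_diploid)]
    t_ids = [f"T{i + 1}" for i in range(scheme.n_tetraploid)]
    v_ids = [f"V{i + 1}" for i in range(scheme.n_hexaploid)]
    inds += [Individual(i, None, None, "D") for i in d_ids]
    inds += [Individual(i, None, None, "T") for i in t_ids]
    inds += [Individual(i, None, None, "V") for i in v_ids]
    s_ids = [f"S{i + 1}" for i in range(scheme.n_synthetic)]
    for sid in s_ids:
        inds.append(Individual(sid, rng.choice(d_ids), rng.choice(t_ids), "S"))
    previous = s_ids
    for depth, count in enumerate(scheme.crosses_by_depth):
        label = "F1" if depth == 0 else f"BC{depth}"
        level = []
        for k in range(count):
            cid = f"{label}_{k + 1:03d}"
            inds.append(Individual(cid, rng.choice(v_ids),
                                   rng.choice(previous), "SD"))
            level.append(cid)
        previous = level
    return Pedigree(inds)


def simulate_phenotypes(
    ped: Pedigree,
    pk: PartialKinship,
    vc: VarianceComponents,
    scheme: SimScheme,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw phenotypes from the generative model behind the Bayesian fit.

    Breeding values a_Q ~ N(0, A_Q sigma2_Q) on each full support,
    ge ~ N(0, I sigma2_GE) per observed genotype-environment cell,
    e ~ N(0, I sigma2_e) per record, and fixed environment means drawn once
    from N(4, 1) (t/ha, the scale of semi-arid wheat yields).  Phenotyped
    genotypes are the synthetic-derivative (SD) lines.

    Returns the record table and a ``truth`` dict holding the simulated
    effect vectors, per-genotype total breeding values, environment means
    and the generating variance components, for recovery scoring.
    """
    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    sig = vc.genetic

    effects: dict[str, pd.Series] = {}
    total = pd.Series(0.0, index=ped.ids)
    for q in COMPONENTS:
        mask = pk.support(q)
        ids = [i for i, m in zip(ped.ids, mask) if m]
        if not ids or sig[q] == 0:
            effects[q] = pd.Series(0.0, index=ids, dtype=float)
            continue
        sub = pk.components[q][np.ix_(mask, mask)]
        jitter = 1.0e-10 * float(np.mean(np.diag(sub)))
        l = np.linalg.cholesky(sub + jitter * np.eye(len(ids)))
        a = np.sqrt(sig[q]) * (l @ rng.standard_normal(len(ids)))
        effects[q] = pd.Series(a, index=ids)
        total = total.add(effects[q], fill_value=0.0)

    env_labels = [f"L{i + 1}:C{j + 1}" for i in range(scheme.n_locations)
                  for j in range(scheme.n_cycles)]
    env_mean = pd.Series(rng.normal(4.0, 1.0, len(env_labels)),
                         index=env_labels)

    genotypes = [i.id for i in ped.individuals if i.group == "SD"]
    rows_g, rows_e = [], []
    for g in genotypes:
        for e in env_labels:
            if scheme.env_presence >= 1.0 or \
                    rng.random() < scheme.env_presence:
                rows_g.append(g)
                rows_e.append(e)
    n_cells = len(rows_g)
    ge = rng.normal(0.0, np.sqrt(vc.sigma2_GE), n_cells) \
        if vc.sigma2_GE > 0 else np.zeros(n_cells)

    rec_g, rec_e, rec_y = [], [], []
    for k, (g, e) in enumerate(zip(rows_g, rows_e)):
        base = env_mean[e] + total[g] + ge[k]
        errs = rng.normal(0.0, np.sqrt(vc.sigma2_e), scheme.n_reps) \
            if vc.sigma2_e > 0 else np.zeros(scheme.n_reps)
        for r in range(scheme.n_reps):
            rec_g.append(g)
            rec_e.append(e)
            rec_y.append(base + errs[r])
    loc = [e.split(":")[0] for e in rec_e]
    cyc = [e.split(":")[1] for e in rec_e]
    data = pd.DataFrame({
        "genotype": rec_g, "location": loc, "cycle": cyc,
        "environment": rec_e, "value": rec_y,
    })
    truth = {
        "effects": effects,
        "total_breeding_value": total.loc[genotypes],
        "environment_means": env_mean,
        "variance_components": vc,
    }
    return data, truth


# ---------------------------------------------------------------- gene drop


@dataclass
class GeneDropConfig:
    """Loci, breed allele frequencies and effects for the gene-drop oracle.

    If frequencies are not given they are generated from ``seed``: a shared
    base frequency per locus plus an independent per-breed deviation scaled
    by ``divergence``.  ``divergence = 0`` makes all three breeds share
    frequencies, so both segregation variances vanish.
    """

    n_loci: int = 16
    freqs: Optional[dict[str, np.ndarray]] = None
    effects: Optional[np.ndarray] = None
    n_replicates: int = 1_000_000
    divergence: float = 1.0
    seed: int = 0
    batch_size: int = 50_000

    def __post_init__(self) -> None:
        if self.n_replicates < 10_000:
            raise ValueError("need at least 1e4 replicates for stable "
                             "Monte-Carlo covariances")
        rng = np.random.default_rng(self.seed)
        if self.freqs is None:
            base = rng.uniform(0.25, 0.75, self.n_loci)
            self.freqs = {
                b: np.clip(base + self.divergence
                           * rng.uniform(-0.2, 0.2, self.n_loci), 0.05, 0.95)
                for b in ("D", "T", "V")
            }
        for b, p in self.freqs.items():
            p = np.asarray(p, float)
            if p.shape != (self.n_loci,) or np.any(p <= 0) or np.any(p >= 1):
                raise ValueError(f"freqs[{b}] must be {self.n_loci} values "
                                 "strictly inside (0, 1)")
            self.freqs[b] = p
        if self.effects is None:
            self.effects = rng.normal(0.0, 0.3, self.n_loci)
        self.effects = np.asarray(self.effects, float)
        if self.effects.shape != (self.n_loci,):
            raise ValueError("effects must have one value per locus")
        if not np.any(self.effects != 0):
            raise ValueError("degenerate configuration: all locus effects "
                             "are zero")

    def analytic_components(self) -> VarianceComponents:
        """Component variances implied by the frequencies and effects."""
        e2 = self.effects ** 2
        var_allele = {b: float(np.sum(e2 * p * (1 - p)))
                      for b, p in self.freqs.items()}
        return VarianceComponents(
            sigma2_D=2 * var_allele["D"],
            sigma2_T=4 * var_allele["T"],
            sigma2_V=6 * var_allele["V"],
            sigma2_DV=0.5 * float(np.sum(
                e2 * (self.freqs["D"] - self.freqs["V"]) ** 2)),
            sigma2_TV=0.5 * float(np.sum(
                e2 * (self.freqs["T"] - self.freqs["V"]) ** 2)),
        )


@dataclass
class GeneDropResult:
    """Empirical vs tabular covariances from a gene-drop run."""

    ids: list[str]
    empirical: np.ndarray
    se: np.ndarray
    predicted: np.ndarray
    predicted_literal: np.ndarray
    vc: VarianceComponents
    n_replicates: int

    def report(self) -> pd.DataFrame:
        """One row per unordered pair: empirical, both predictions, z-scores,
        and whether the pair is sensitive to the S-doubling rule."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1):
                emp = self.empirical[i, j]
                se = self.se[i, j]
                pred = self.predicted[i, j]
                lit = self.predicted_literal[i, j]
                rows.append({
                    "id_1": self.ids[i],
                    "id_2": self.ids[j],
                    "empirical": emp,
                    "se": se,
                    "predicted": pred,
                    "z": (emp - pred) / se,
                    "predicted_literal": lit,
                    "z_literal": (emp - lit) / se,
                    "doubling_sensitive": not np.isclose(pred, lit),
                })
        return pd.DataFrame(rows)


def _meiosis(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per replicate from a (rep, 2, loci) genotype block."""
    choice = rng.integers(0, 2, size=(parent.shape[0], parent.shape[2]))
    return np.take_along_axis(parent, choice[:, None, :], axis=1)[:, 0, :]


def gene_drop(ped: Pedigree, config: GeneDropConfig) -> GeneDropResult:
    """Monte-Carlo transmission of founder alleles down the pedigree.

    Each subgenome segregates as an independent diploid; S nodes carry two
    identical copies of the transmitted gamete (literal doubling).
    """
    rng = np.random.default_rng(config.seed)
    n = ped.n
    s1 = np.zeros(n)
    s2 = np.zeros((n, n))
    total = 0
    effects = config.effects
    while total < config.n_replicates:
        b = min(config.batch_size, config.n_replicates - total)
        values = np.zeros((b, n))
        genomes: list[dict[int, np.ndarray]] = [None] * n  # type: ignore
        for k, ind in enumerate(ped.individuals):
            subgenomes = _SUBGENOMES[ind.group]
            geno: dict[int, np.ndarray] = {}
            if ind.is_founder:
                p = config.freqs[ind.group]
                for s in subgenomes:
                    geno[s] = (rng.random((b, 2, config.n_loci))
                               < p).astype(np.int8)
            elif ind.group == "S":
                si, di = ped.sire_idx[k], ped.dam_idx[k]
                for parent in (si, di):
                    for s, block in genomes[parent].items():
                        gam = _meiosis(block, rng)
                        geno[s] = np.stack([gam, gam], axis=1)
            else:
                si, di = ped.sire_idx[k], ped.dam_idx[k]
                for s in subgenomes:
                    geno[s] = np.stack(
                        [_meiosis(genomes[si][s], rng),
                         _meiosis(genomes[di][s], rng)], axis=1)
            genomes[k] = geno
            allele_sum = sum(block.sum(axis=1) for block in geno.values())
            values[:, k] = allele_sum @ effects
        s1 += values.sum(axis=0)
        s2 += values.T @ values
        total += b
    mean = s1 / total
    cov = (s2 - total * np.outer(mean, mean)) / (total - 1)
    var = np.diag(cov)
    se = np.sqrt((np.outer(var, var) + cov ** 2) / (total - 1))

    vc = config.analytic_components()
    sig = vc.genetic
    fr = None
    pk_printed = build_partial_matrices(ped, fr, s_doubling="printed")
    pk_literal = build_partial_matrices(ped, fr, s_doubling="literal")
    predicted = sum(pk_printed.components[q] * sig[q] for q in COMPONENTS)
    predicted_literal = sum(pk_literal.components[q] * sig[q]
                            for q in COMPONENTS)
    return GeneDropResult(
        ids=ped.ids, empirical=cov, se=se, predicted=predicted,
        predicted_literal=predicted_literal, vc=vc, n_replicates=total,
    )
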