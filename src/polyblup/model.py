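"""Hierarchical Bayesian multi-breed mixed model, estimated by Gibbs sampling.

The observation model for a phenotype record on genotype g in environment
(location x cycle) k is

    y = X b + sum_Q Z_Q a_Q + Z_GE ge + e,

with fixed environment effects ``b`` under a proper, very flat Normal prior
N(0, K), K = diag(k_i), k_i > 1e7 (which regularises the intercept/indicator
singularity without dropping columns); breeding values by breed of origin
a_Q ~ N(0, A_Q sigma2_Q) on the support of each partial relationship matrix
A_Q; iid genotype-by-environment effects ge ~ N(0, I sigma2_GE); and iid
Gaussian residuals.  Every variance component carries a scaled inverse
chi-square prior with degrees of freedom ``nu`` and scale ``S2``.

All full conditionals are conjugate, so a standard Gibbs sampler applies:
each effect block from its Normal full conditional (the conditional
mixed-model equations), each variance from its scaled inverse chi-square
full conditional, e.g.

    sigma2_Q | .  ~  ScaledInvChi2(nu + q_Q, (a_Q' A_Q^-1 a_Q + nu S2) / (nu + q_Q)).

Breeding values are sampled on the phenotyped part of each support;
unphenotyped relatives (founders, intermediate crosses) are integrated out
of the likelihood, which leaves every variance posterior unchanged, and
their breeding values are recovered afterwards as exact multivariate-Normal
conditional means (the regression A_anc,phen A_phen^-1 does not depend on
the variance scale).  Because the likelihood involves the breed-of-origin
effects only through the total genetic value u = sum_Q a_Q of each
phenotyped genotype, all genetic blocks are drawn jointly each iteration:
first u from its Gaussian conditional under the collapsed prior
u ~ N(0, G), G = sum_Q A_Q sigma2_Q (via Matheron's conditioning rule),
then the decomposition (a_Q | u) from the conditional of independent prior
draws.  The joint draw removes the severe autocorrelation a per-component
sampler shows when two origins are nearly collinear on the phenotyped
genotypes (as D and T are in a doubled-synthetic scheme, where f_D = f_T
for every derivative line).

Usage follows the Model/Results convention::

    model = MultibreedModel.from_files("pedigree.csv", "phenotypes.csv")
    res = model.fit(ChainSettings(n_iter=20_000, n_burnin=10_000), seed=1)
    res.summary()          # component, nu, S2, mean, SD, HPD95, ESS
    res.blup()             # per-origin breeding values and their sum
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .kinship import (
    COMPONENTS,
    ONE_BREED,
    PartialKinship,
    build_partial_matrices,
)
from .pedigree import Pedigree, read_pedigree

logger = logging.getLogger(__name__)

#: Row labels mirroring the published variance-table layout.
ERROR = "error"
GE = "ge"
GENOTYPE = "genotype"  # the one-breed genetic term

_MIN_FIXED_PRIOR_VARIANCE = 1.0e7
_DIVERGENCE_LIMIT = 1.0e14


class ModelDataError(ValueError):
    """Phenotype records inconsistent with the pedigree or design."""


@dataclass(frozen=True)
class Prior:
    """Scaled inverse chi-square prior: df ``nu`` > 0 and scale ``S2`` > 0."""

    nu: float
    S2: float

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.S2 <= 0:
            raise ValueError("prior nu and S2 must be strictly positive")

    @property
    def mean(self) -> float:
        """Prior mean nu*S2/(nu-2) (finite for nu > 2)."""
        if self.nu <= 2:
            return np.inf
        return self.nu * self.S2 / (self.nu - 2.0)


@dataclass
class PriorSpec:
    """Priors for every variance component plus the fixed-effect prior variance."""

    variances: dict[str, Prior]
    fixed_effect_variance: float = 1.0e8

    def __post_init__(self) -> None:
        if self.fixed_effect_variance <= _MIN_FIXED_PRIOR_VARIANCE:
            raise ValueError(
                "fixed-effect prior variance must exceed 1e7 to act as a "
                "proper but effectively flat prior"
            )

    @classmethod
    def default(cls, y: np.ndarray, component_names: Sequence[str],
                nu: float = 5.0) -> "PriorSpec":
        """Weakly informative default: nu = 5 for every component and a scale
        S2 chosen so the prior mode nu*S2/(nu+2) equals an equal partition of
        the phenotypic variance across all variance components."""
        if len(y) < 2:
            raise ValueError(
                "default priors need phenotype records; pass an explicit "
                "PriorSpec for prior-only runs"
            )
        vy = float(np.var(y, ddof=1))
        k = len(component_names)
        s2 = (nu + 2.0) / nu * vy / k
        return cls({name: Prior(nu, s2) for name in component_names})


@dataclass(frozen=True)
class ChainSettings:
    """Gibbs chain length controls (defaults follow the 10k/10k convention)."""

    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


def load_phenotypes(path) -> pd.DataFrame:
    """Read a delimited phenotype file.

    Accepts either ``genotype,location,cycle,value`` (environment formed as
    ``location:cycle``) or ``genotype,environment,value``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return normalise_phenotypes(df)


def normalise_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "environment" not in df.columns:
        if not {"location", "cycle"} <= set(df.columns):
            raise ModelDataError(
                "phenotype table needs either an 'environment' column or "
                "'location' and 'cycle' columns"
            )
        df["environment"] = (
            df["location"].astype(str) + ":" + df["cycle"].astype(str)
        )
    if not {"genotype", "value"} <= set(df.columns):
        raise ModelDataError("phenotype table needs 'genotype' and 'value'")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        logger.info("dropping %d records with missing trait values", n_missing)
        df = df.dropna(subset=["value"])
    return df[["genotype", "environment", "value"]].reset_index(drop=True)


@dataclass
class _GeneticTerm:
    """Precomputed design for one breed-of-origin random effect."""

    name: str
    support_ids: list[str]          # full support, pedigree order
    phen_ids: list[str]             # phenotyped members of the support
    u_pos: np.ndarray               # positions of phen_ids in the u vector
    a_sub: np.ndarray               # A restricted to phen_ids
    a_chol: np.ndarray              # lower Cholesky factor of a_sub
    a_inv: np.ndarray               # a_sub^-1 (possibly ridged)
    m_anc: np.ndarray               # A_anc,phen @ a_sub^-1

    @property
    def q(self) -> int:
        return len(self.phen_ids)


def _factor_with_ridge(a: np.ndarray, name: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor and inverse of a PSD matrix, with a small ridge if
    factorisation fails."""
    if a.size == 0:
        return a.copy(), a.copy()
    try:
        l = cholesky(a, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        ridge = 1.0e-8 * float(np.mean(np.diag(a)))
        logger.warning(
            "A_%s not factorizable on its support; adding ridge %.3e", name,
            ridge,
        )
        l = cholesky(a + ridge * np.eye(a.shape[0]), lower=True,
                     check_finite=False)
    inv = cho_solve((l, True), np.eye(a.shape[0]), check_finite=False)
    return l, inv


class MultibreedModel:
    """Multi-breed pedigree BLUP model for wheat synthetics.

    Parameters
    ----------
    data:
        Phenotype records with columns ``genotype``, ``environment`` (or
        ``location`` + ``cycle``) and ``value``.  Records with missing values
        are dropped with a logged count.
    pedigree:
        A validated :class:`~polyblup.pedigree.Pedigree`; every phenotyped
        genotype must appear in it.
    kinship:
        Optional precomputed :class:`~polyblup.kinship.PartialKinship`.
    components:
        Breed-of-origin terms to include (default all five).  Ignored when
        ``one_breed`` is set.
    one_breed:
        Fit the homogeneous comparison model: a single genetic term
        ("genotype") with the classical numerator relationship matrix.
    include_environment, include_ge:
        Switch the fixed environment block and the iid genotype-by-environment
        block on or off.
    """

    def __init__(
        self,
        data: Optional[pd.DataFrame],
        pedigree: Pedigree,
        kinship: Optional[PartialKinship] = None,
        components: Sequence[str] = COMPONENTS,
        one_breed: bool = False,
        include_environment: bool = True,
        include_ge: bool = True,
        priors: Optional[PriorSpec] = None,
    ):
        self.pedigree = pedigree
        self.kinship = kinship if kinship is not None else \
            build_partial_matrices(pedigree)
        if one_breed:
            self._terms_spec = [(GENOTYPE, ONE_BREED)]
        else:
            bad = [c for c in components if c not in COMPONENTS]
            if bad:
                raise ValueError(f"unknown components {bad}")
            self._terms_spec = [(c, c) for c in components]
        self.one_breed = one_breed
        self.include_environment = include_environment
        self.include_ge = include_ge

        if data is None:
            data = pd.DataFrame(columns=["genotype", "environment", "value"])
        data = normalise_phenotypes(pd.DataFrame(data))
        missing = sorted(set(data["genotype"]) - set(pedigree.index))
        if missing:
            raise ModelDataError(
                f"genotypes absent from the pedigree: {', '.join(missing[:5])}"
                + (" ..." if len(missing) > 5 else "")
            )
        self.data = data
        self._build_design()

        names = [ERROR] + ([GE] if self.include_ge else []) \
            + [name for name, _ in self._terms_spec]
        self.component_names = names
        if priors is None:
            priors = PriorSpec.default(self._y, names)
        missing_priors = [c for c in names if c not in priors.variances]
        if missing_priors:
            raise ValueError(f"priors missing for components {missing_priors}")
        self.priors = priors

    # ------------------------------------------------------------------ setup

    @classmethod
    def from_files(cls, pedigree_path, phenotype_path, **kwargs
                   ) -> "MultibreedModel":
        return cls(load_phenotypes(phenotype_path),
                   read_pedigree(pedigree_path), **kwargs)

    def _build_design(self) -> None:
        data = self.data
        self._y = data["value"].to_numpy(float)
        n = len(self._y)
        self.nobs = n

        if self.include_environment and n > 0:
            env_labels = sorted(data["environment"].unique())
            env_idx = data["environment"].map(
                {e: k for k, e in enumerate(env_labels)}).to_numpy()
            self.env_labels = env_labels
            self._env_idx = env_idx
            p = 1 + len(env_labels)
            xtx = np.zeros((p, p))
            counts = np.bincount(env_idx, minlength=len(env_labels))
            xtx[0, 0] = n
            xtx[0, 1:] = counts
            xtx[1:, 0] = counts
            xtx[np.arange(1, p), np.arange(1, p)] = counts
            self._xtx = xtx
            self._p = p
        else:
            self.env_labels = []
            self._env_idx = np.zeros(n, dtype=np.int64)
            self._p = 0

        ped = self.pedigree
        geno_ped_idx = data["genotype"].map(ped.index).to_numpy(np.int64) \
            if n else np.zeros(0, dtype=np.int64)
        self._geno_ped_idx = geno_ped_idx
        observed = np.zeros(ped.n, dtype=bool)
        observed[geno_ped_idx] = True

        union = np.zeros(ped.n, dtype=bool)
        supports = {}
        for name, q in self._terms_spec:
            supports[name] = self.kinship.support(q)
            union |= supports[name] & observed
        u_ped_idx = np.flatnonzero(union)  # phenotyped, in >= 1 support
        u_pos_of = np.full(ped.n, -1, dtype=np.int64)
        u_pos_of[u_ped_idx] = np.arange(len(u_ped_idx))
        self._n_u = len(u_ped_idx)
        self._u_cols = u_pos_of[geno_ped_idx] if n else \
            np.zeros(0, dtype=np.int64)
        self._u_counts = np.bincount(
            self._u_cols[self._u_cols >= 0], minlength=self._n_u
        ).astype(float)

        self._terms: list[_GeneticTerm] = []
        ids = ped.ids
        for name, q in self._terms_spec:
            matrix = self.kinship.matrix(q)
            support = supports[name]
            support_idx = np.flatnonzero(support)
            phen_idx = np.flatnonzero(support & observed)
            anc_idx = np.flatnonzero(support & ~observed)
            a_sub = matrix[np.ix_(phen_idx, phen_idx)]
            a_chol, a_inv = _factor_with_ridge(a_sub, name)
            m_anc = matrix[np.ix_(anc_idx, phen_idx)] @ a_inv \
                if len(anc_idx) and len(phen_idx) else \
                np.zeros((len(anc_idx), len(phen_idx)))
            self._terms.append(_GeneticTerm(
                name=name,
                support_ids=[ids[i] for i in support_idx],
                phen_ids=[ids[i] for i in phen_idx],
                u_pos=u_pos_of[phen_idx],
                a_sub=a_sub,
                a_chol=a_chol,
                a_inv=a_inv,
                m_anc=m_anc,
            ))

        if self.include_ge and n > 0:
            cells, cell_idx = np.unique(
                np.stack([geno_ped_idx, self._env_idx]), axis=1,
                return_inverse=True)
            self._ge_idx = cell_idx
            self._ge_counts = np.bincount(cell_idx).astype(float)
            self.n_ge_cells = cells.shape[1]
        else:
            self._ge_idx = np.zeros(n, dtype=np.int64)
            self._ge_counts = np.zeros(0)
            self.n_ge_cells = 0

        if self.include_environment and n > 0:
            for k, c in enumerate(np.bincount(self._env_idx,
                                              minlength=len(self.env_labels))):
                if c == 0:
                    raise ModelDataError(
                        f"environment {self.env_labels[k]!r} has no records")

    # -------------------------------------------------------------------- fit

    def fit(self, chain: Optional[ChainSettings] = None,
            seed: Optional[int] = None) -> "MultibreedResults":
        """Run the Gibbs sampler and return a results object."""
        if chain is None:
            chain = ChainSettings()
        if seed is not None:
            chain = replace(chain, seed=seed)
        rng = np.random.default_rng(chain.seed)

        n = self.nobs
        priors = self.priors
        terms = self._terms
        k_fix = priors.fixed_effect_variance

        # initial state: effects at zero, variances at their prior scales
        sigma2 = {name: priors.variances[name].S2
                  for name in self.component_names}
        b = np.zeros(self._p)
        a = [np.zeros(t.q) for t in terms]
        ge = np.zeros(self.n_ge_cells)
        r = self._y.copy()

        n_kept = chain.n_kept
        var_draws = {name: np.empty(n_kept) for name in self.component_names}
        b_sum = np.zeros(self._p)
        a_sum = [np.zeros(t.q) for t in terms]
        kept = 0

        env_idx = self._env_idx
        ge_idx = self._ge_idx
        has_env = self._p > 0
        has_ge = self.n_ge_cells > 0
        n_u = self._n_u
        u_cols = self._u_cols
        u_mask = u_cols >= 0
        u_cols_obs = u_cols[u_mask]
        u = np.zeros(n_u)

        for it in range(chain.n_iter):
            if has_env:
                r += b[0] + b[1 + env_idx]
                rhs = np.empty(self._p)
                rhs[0] = r.sum()
                rhs[1:] = np.bincount(env_idx, weights=r,
                                      minlength=self._p - 1)
                rhs /= sigma2[ERROR]
                c = self._xtx / sigma2[ERROR]
                c[np.diag_indices_from(c)] += 1.0 / k_fix
                l = cholesky(c, lower=True, check_finite=False)
                mean = cho_solve((l, True), rhs, check_finite=False)
                b = mean + solve_triangular(
                    l.T, rng.standard_normal(self._p), lower=False,
                    check_finite=False)
                r -= b[0] + b[1 + env_idx]

            if n_u > 0:
                # joint draw of all breed-of-origin effects: first the total
                # genetic value u | . under the collapsed prior N(0, G),
                # G = sum_Q sigma2_Q A_Q (Matheron's conditioning rule), then
                # the decomposition (a_Q | u) via conditioned prior draws.
                r[u_mask] += u[u_cols_obs]
                m = np.bincount(u_cols_obs, weights=r[u_mask],
                                minlength=n_u) / self._u_counts
                g = np.zeros((n_u, n_u))
                for t in terms:
                    if t.q:
                        g[np.ix_(t.u_pos, t.u_pos)] += sigma2[t.name] * t.a_sub
                g_chol = cholesky(g, lower=True, check_finite=False)
                u_prior = g_chol @ rng.standard_normal(n_u)
                noise_var = sigma2[ERROR] / self._u_counts
                eta = np.sqrt(noise_var) * rng.standard_normal(n_u)
                s = g + np.diag(noise_var)
                sw = cho_solve(
                    (cholesky(s, lower=True, check_finite=False), True),
                    m - u_prior - eta, check_finite=False)
                u = u_prior + g @ sw
                u_tilde = np.zeros(n_u)
                a_prior = []
                for t in terms:
                    at = np.sqrt(sigma2[t.name]) \
                        * (t.a_chol @ rng.standard_normal(t.q))
                    a_prior.append(at)
                    if t.q:
                        u_tilde[t.u_pos] += at
                gw = cho_solve((g_chol, True), u - u_tilde,
                               check_finite=False)
                for t, ai, at in zip(terms, a, a_prior):
                    if t.q:
                        ai[:] = at + sigma2[t.name] * (t.a_sub @ gw[t.u_pos])
                r[u_mask] -= u[u_cols_obs]

            if has_ge:
                r += ge[ge_idx]
                rhs = np.bincount(ge_idx, weights=r,
                                  minlength=self.n_ge_cells) / sigma2[ERROR]
                prec = self._ge_counts / sigma2[ERROR] + 1.0 / sigma2[GE]
                ge = rhs / prec + rng.standard_normal(self.n_ge_cells) \
                    / np.sqrt(prec)
                r -= ge[ge_idx]

            for t, ai in zip(terms, a):
                pr = priors.variances[t.name]
                quad = float(ai @ (t.a_inv @ ai)) if t.q else 0.0
                sigma2[t.name] = (quad + pr.nu * pr.S2) \
                    / rng.chisquare(pr.nu + t.q)
            if self.include_ge:
                pr = priors.variances[GE]
                sigma2[GE] = (float(ge @ ge) + pr.nu * pr.S2) \
                    / rng.chisquare(pr.nu + self.n_ge_cells)
            pr = priors.variances[ERROR]
            sigma2[ERROR] = (float(r @ r) + pr.nu * pr.S2) \
                / rng.chisquare(pr.nu + n)

            for name, v in sigma2.items():
                if not np.isfinite(v) or v > _DIVERGENCE_LIMIT:
                    raise RuntimeError(
                        f"divergent chain: sigma2[{name}] = {v!r} at "
                        f"iteration {it}; current variances: {sigma2}"
                    )

            if it >= chain.n_burnin and (it - chain.n_burnin) % chain.thin == 0:
                for name in self.component_names:
                    var_draws[name][kept] = sigma2[name]
                b_sum += b
                for s, ai in zip(a_sum, a):
                    s += ai
                kept += 1

        b_mean = b_sum / max(kept, 1)
        effect_means: dict[str, pd.Series] = {}
        for t, s in zip(terms, a_sum):
            phen_mean = s / max(kept, 1)
            phen_set = set(t.phen_ids)
            anc_ids = [i for i in t.support_ids if i not in phen_set]
            series = pd.Series(phen_mean, index=t.phen_ids, dtype=float)
            if anc_ids:
                anc_mean = t.m_anc @ phen_mean
                series = pd.concat(
                    [series, pd.Series(anc_mean, index=anc_ids, dtype=float)])
            effect_means[t.name] = series
        return MultibreedResults(
            model=self,
            chain=chain,
            variance_draws={k: v[:kept] for k, v in var_draws.items()},
            fixed_effect_means=pd.Series(
                b_mean,
                index=(["intercept"] + list(self.env_labels))[:self._p]),
            effect_means=effect_means,
        )


def hpd_interval(draws: np.ndarray, prob: float = 0.95
                 ) -> tuple[float, float]:
    """Shortest empirical interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    k = int(np.ceil(prob * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_summary(samples: Mapping[str, np.ndarray],
                      min_draws: int = 200) -> pd.DataFrame:
    """Mean, SD and shortest 95% interval per parameter."""
    rows = []
    for name, draws in samples.items():
        draws = np.asarray(draws, float)
        if len(draws) < min_draws:
            raise ValueError(
                f"{name}: only {len(draws)} draws; need >= {min_draws} for a "
                "stable posterior summary"
            )
        lo, hi = hpd_interval(draws)
        rows.append({
            "component": name,
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "hpd_lower": lo,
            "hpd_upper": hi,
        })
    return pd.DataFrame(rows).set_index("component")


@dataclass
class MultibreedResults:
    """Posterior draws and summaries from a fitted multi-breed model."""

    model: MultibreedModel
    chain: ChainSettings
    variance_draws: dict[str, np.ndarray]
    fixed_effect_means: pd.Series
    effect_means: dict[str, pd.Series]

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.variance_draws.values())))

    def summary(self, min_draws: int = 200) -> pd.DataFrame:
        """Posterior summary table: component, nu, S2, mean, SD, HPD95, ESS."""
        base = posterior_summary(self.variance_draws, min_draws=min_draws)
        pri = self.model.priors.variances
        base.insert(0, "nu", [pri[c].nu for c in base.index])
        base.insert(1, "S2", [pri[c].S2 for c in base.index])
        base["ess"] = [
            _effective_sample_size(self.variance_draws[c]) for c in base.index
        ]
        return base

    def blup(self, one_breed: Optional["MultibreedResults"] = None
             ) -> pd.DataFrame:
        """Posterior-mean breeding values per origin and their per-genotype sum.

        Genotypes outside a component's support contribute 0 for that origin.
        When a one-breed fit is supplied its breeding values are reported
        side by side in an ``onebreed`` column.
        """
        ids = self.model.pedigree.ids
        out = pd.DataFrame(index=pd.Index(ids, name="genotype"))
        for name, means in self.effect_means.items():
            out[name] = means.reindex(ids).fillna(0.0).to_numpy()
        out["total"] = out.sum(axis=1)
        if one_breed is not None:
            ob = one_breed.effect_means[GENOTYPE]
            out["onebreed"] = ob.reindex(ids).fillna(0.0).to_numpy()
        return out

    def plot_trace(self, path=None):
        """Trace plots of the variance-component chains (one axis each)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = list(self.variance_draws)
        fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)),
                                 sharex=True)
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, names):
            ax.plot(self.variance_draws[name], lw=0.5)
            ax.set_ylabel(name)
        axes[-1].set_xlabel("retained draw")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig


def _effective_sample_size(draws: np.ndarray) -> float:
    try:
        import arviz as az

        return float(az.ess(np.asarray(draws)[None, :]))
    except Exception:  # pragma: no cover - arviz should be present
        return float(len(draws))
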