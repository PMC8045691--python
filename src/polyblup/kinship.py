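"""Partial numerator relationship matrices for multi-breed wheat pedigrees.

The additive covariance between two synthetic-wheat genotypes splits by
breed of origin into five components,

    Cov(G_i, G_i') = sum_Q a_Q(i, i') * sigma2_Q,
    Q in {D, T, V, DV, TV},

where ``D``, ``T``, ``V`` index alleles originating in *Ae. tauschii*,
*T. turgidum* and *T. aestivum*, and ``DV``/``TV`` are segregation terms:
the extra additive variance a segregating backcross shows over the F1,
arising from allele-frequency differences between the parental populations.

Each partial matrix ``A_Q`` is built by the tabular method.  Off-diagonals
follow the purebred recursion a_Q(i, j) = [a_Q(sire_i, j) + a_Q(dam_i, j)]/2
(unknown parents contribute zero).  Diagonals follow the breed-group rules:
pure founders have 1 on their own component; a doubled synthetic has
f_D = f_T = 1; the generic non-founder diagonal is

    a_Q(i, i)  = f_i^Q + a_Q(sire, dam)/2                      (Q = D, T, V)
    a_DV(i, i) = 2 (f_s^D f_s^V + f_d^D f_d^V) + a_DV(sire, dam)/2
    a_TV(i, i) = 4 (f_s^T f_s^V + f_d^T f_d^V) + a_TV(sire, dam)/2

The segregation diagonals sum over both parents: with one parent always a
pure hexaploid (the usual backcross scheme) the second product vanishes and
the rule reduces to the single-parent form, but the symmetric version
removes any dependence on which parent is listed first.

Doubled synthetics are handled two ways (``s_doubling``): ``"printed"``
treats the doubled copies like an ordinary inbred genotype (the tabular rule
above, the default used throughout the package); ``"literal"`` propagates
the fact that the two homologs of an S line are byte-identical copies of one
gamete, which doubles the S diagonal and its covariances.  Gene-dropping
simulation agrees with ``"literal"``; the two rules differ only on pairs
whose shared ancestry passes through the doubling step.  See
:mod:`polyblup.simulate` and the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import PURE_BREEDS, Pedigree, breed_fractions

logger = logging.getLogger(__name__)

#: Breed-of-origin components, in fixed model order.
COMPONENTS = ("D", "T", "V", "DV", "TV")

#: Name used for the homogeneous (single relationship matrix) comparison model.
ONE_BREED = "onebreed"

_SUPPORT_TOL = 1e-12


@dataclass
class VarianceComponents:
    """The seven dispersion parameters of the multi-breed model (trait units^2).

    ``sigma2_D/T/V`` are pure-breed additive variances (ploidy times the
    allele-effect variance), ``sigma2_DV/TV`` segregation variances,
    ``sigma2_GE`` the iid genotype-by-environment variance and ``sigma2_e``
    the residual variance.
    """

    sigma2_D: float
    sigma2_T: float
    sigma2_V: float
    sigma2_DV: float = 0.0
    sigma2_TV: float = 0.0
    sigma2_GE: float = 0.0
    sigma2_e: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_D": self.sigma2_D,
            "sigma2_T": self.sigma2_T,
            "sigma2_V": self.sigma2_V,
            "sigma2_DV": self.sigma2_DV,
            "sigma2_TV": self.sigma2_TV,
            "sigma2_GE": self.sigma2_GE,
            "sigma2_e": self.sigma2_e,
        }

    @property
    def genetic(self) -> dict[str, float]:
        """Genetic components keyed by breed-of-origin label."""
        return {
            "D": self.sigma2_D,
            "T": self.sigma2_T,
            "V": self.sigma2_V,
            "DV": self.sigma2_DV,
            "TV": self.sigma2_TV,
        }


@dataclass
class PartialKinship:
    """The five partial matrices plus the one-breed numerator matrix.

    Matrices are dense, symmetric, in pedigree order.  ``support(Q)`` gives
    the individuals with a nonzero diagonal in component ``Q``; restricted to
    its support each matrix is positive semi-definite.
    """

    ids: list[str]
    components: dict[str, np.ndarray]
    onebreed: np.ndarray
    s_doubling: str = "printed"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def matrix(self, q: str) -> np.ndarray:
        if q == ONE_BREED:
            return self.onebreed
        return self.components[q]

    def support(self, q: str) -> np.ndarray:
        """Boolean mask of individuals with nonzero diagonal in ``q``."""
        return np.diag(self.matrix(q)) > _SUPPORT_TOL

    def restricted(self, q: str) -> tuple[list[str], np.ndarray]:
        """Component matrix restricted to its support, with matching ids."""
        mask = self.support(q)
        ids = [i for i, m in zip(self.ids, mask) if m]
        return ids, self.matrix(q)[np.ix_(mask, mask)]

    def coefficient(self, q: str, i: str, j: Optional[str] = None) -> float:
        a, b = self._index[i], self._index[j if j is not None else i]
        return float(self.matrix(q)[a, b])

    # -- sparse triplet I/O --------------------------------------------------

    def write(self, outdir) -> None:
        """Write one lower-triangle triplet file per component plus the id list."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.ids, name="id").to_csv(outdir / "individuals.txt",
                                              index=False)
        for q in COMPONENTS + (ONE_BREED,):
            _write_triplets(self.matrix(q), self.ids, outdir / f"A_{q}.txt")

    @classmethod
    def read(cls, indir) -> "PartialKinship":
        indir = Path(indir)
        ids = pd.read_csv(indir / "individuals.txt", dtype=str)["id"].tolist()
        comps = {q: _read_triplets(indir / f"A_{q}.txt", ids)
                 for q in COMPONENTS}
        onebreed = _read_triplets(indir / f"A_{ONE_BREED}.txt", ids)
        return cls(ids=ids, components=comps, onebreed=onebreed)


def _write_triplets(a: np.ndarray, ids: list[str], path: Path) -> None:
    rows, cols = np.nonzero(np.tril(a))
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for r, c in zip(rows, cols):
            fh.write(f"{ids[r]},{ids[c]},{float(a[r, c])!r}\n")


def _read_triplets(path: Path, ids: list[str]) -> np.ndarray:
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    df = pd.read_csv(path, dtype={"row": str, "col": str, "value": float})
    for rec in df.itertuples(index=False):
        if rec.row not in index:
            raise ValueError(f"triplet row id {rec.row!r} absent from id list")
        if rec.col not in index:
            raise ValueError(f"triplet col id {rec.col!r} absent from id list")
        r, c = index[rec.row], index[rec.col]
        if r < c:
            raise ValueError(
                f"triplet ({rec.row}, {rec.col}) is in the upper triangle; "
                "files must store the lower triangle"
            )
        a[r, c] = rec.value
        a[c, r] = rec.value
    return a


def build_partial_matrices(
    ped: Pedigree,
    fractions: Optional[pd.DataFrame] = None,
    s_doubling: str = "printed",
) -> PartialKinship:
    """Tabular construction of A_D, A_T, A_V, A_DV, A_TV and the one-breed A.

    Individuals are processed in pedigree (topological) order; see the module
    docstring for the recursion.  ``s_doubling`` selects how doubled
    synthetics are treated ("printed" or "literal").
    """
    if s_doubling not in ("printed", "literal"):
        raise ValueError("s_doubling must be 'printed' or 'literal'")
    if fractions is None:
        fractions = breed_fractions(ped)
    f = fractions[["f_D", "f_T", "f_V"]].to_numpy()
    n = ped.n
    sire, dam = ped.sire_idx, ped.dam_idx
    is_s = ped.groups == "S"

    comps: dict[str, np.ndarray] = {}
    fcol = {"D": 0, "T": 1, "V": 2}
    for q in PURE_BREEDS:
        a = np.zeros((n, n))
        qc = fcol[q]
        for i in range(n):
            s, d = sire[i], dam[i]
            if s < 0:
                a[i, i] = f[i, qc]  # non-inbred pure founder: 1 + F = 1
                continue
            if s_doubling == "literal" and is_s[i] and q in ("D", "T"):
                # the doubled gamete is counted twice
                a[i, :i] = a[s, :i] + a[d, :i]
                a[:i, i] = a[i, :i]
                a[i, i] = 2.0 * (f[i, qc] + 0.5 * a[s, d])
            else:
                a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
                a[:i, i] = a[i, :i]
                a[i, i] = f[i, qc] + 0.5 * a[s, d]
        comps[q] = a

    for q, (c1, c2, w) in {"DV": (0, 2, 2.0), "TV": (1, 2, 4.0)}.items():
        a = np.zeros((n, n))
        for i in range(n):
            s, d = sire[i], dam[i]
            if s < 0:
                continue
            a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
            a[:i, i] = a[i, :i]
            a[i, i] = (
                w * (f[s, c1] * f[s, c2] + f[d, c1] * f[d, c2])
                + 0.5 * a[s, d]
            )
        comps[q] = a

    onebreed = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0:
            onebreed[i, i] = 1.0
            continue
        onebreed[i, :i] = 0.5 * (onebreed[s, :i] + onebreed[d, :i])
        onebreed[:i, i] = onebreed[i, :i]
        onebreed[i, i] = 1.0 + 0.5 * onebreed[s, d]

    return PartialKinship(ids=ped.ids, components=comps, onebreed=onebreed,
                          s_doubling=s_doubling)


def genotypic_variance(
    ped: Pedigree,
    vc: VarianceComponents,
    pk: Optional[PartialKinship] = None,
    fractions: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-individual genotypic variance split into additive and segregation parts.

    ``additive`` weights the three pure-breed variances by the diagonal
    coefficients (which embody both the f fractions and the (1 + F) inbreeding
    forms for pure and synthetic lines); ``segregation`` weights the two
    segregation variances; ``total`` is their sum, i.e.
    ``sum_Q a_Q(i, i) * sigma2_Q``.
    """
    if pk is None:
        pk = build_partial_matrices(ped, fractions)
    sig = vc.genetic
    diag = {q: np.diag(pk.components[q]) for q in COMPONENTS}
    additive = sum(diag[q] * sig[q] for q in PURE_BREEDS)
    segregation = diag["DV"] * sig["DV"] + diag["TV"] * sig["TV"]
    return pd.DataFrame(
        {
            "additive": additive,
            "segregation": segregation,
            "total": additive + segregation,
        },
        index=pd.Index(ped.ids, name="id"),
    )


def write_matrices(pk: PartialKinship, outdir) -> None:
    pk.write(outdir)


def read_matrices(indir) -> PartialKinship:
    return PartialKinship.read(indir)
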