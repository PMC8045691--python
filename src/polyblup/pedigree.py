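"""Multi-breed, variable-ploidy pedigrees for synthetic hexaploid wheat.

Synthetic hexaploid wheat (SHW) is produced by crossing tetraploid *Triticum
turgidum* (breed group ``T``, two subgenomes) with diploid *Aegilops tauschii*
(``D``, one subgenome) and doubling the chromosomes of the triploid hybrid.
The synthetic (``S``) is then crossed and repeatedly backcrossed to hexaploid
bread wheat *T. aestivum* (``V``, three subgenomes), giving synthetic
derivative lines (``SD``) carrying 50, 25, 12.5, 6.25 ... percent of the
synthetic genome.

This module reads, validates and topologically orders such pedigrees, and
computes per-individual breed-composition coefficients (the variance weights
``f_D``, ``f_T``, ``f_V``) and within-subgenome inbreeding coefficients.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of independent subgenomes contributed per gamete by each breed group.
#: Allopolyploid subgenomes pair independently at meiosis, so each behaves as
#: a diploid; a gamete carries one allele per subgenome the group possesses.
PLOIDY_GENOMES = {"D": 1, "T": 2, "V": 3, "S": 3, "SD": 3}

GROUPS = ("D", "T", "V", "S", "SD")
PURE_BREEDS = ("D", "T", "V")

#: Tokens accepted as "parent unknown" in pedigree files.
MISSING_TOKENS = ("", "0", "NA", ".")


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """An individual id occurs more than once."""


class UnknownParentError(PedigreeError):
    """A referenced parent id does not exist in the pedigree."""


class PartialParentageError(PedigreeError):
    """Exactly one parent is known; the averaging recursion for breed
    fractions is ill-defined in that case, so it is rejected."""


class PedigreeCycleError(PedigreeError):
    """An individual appears among its own ancestors."""


class BreedGrammarError(PedigreeError):
    """The breed-group label is incompatible with the parents' labels."""


class UnknownGroupError(PedigreeError):
    """Breed-group label outside {D, T, V, S, SD}."""


@dataclass(frozen=True)
class BreedGroup:
    """A breed group label together with its subgenome count."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in GROUPS:
            raise UnknownGroupError(f"unknown breed group {self.label!r}")

    @property
    def ploidy_genomes(self) -> int:
        return PLOIDY_GENOMES[self.label]


@dataclass(frozen=True)
class Individual:
    """One pedigree member. ``sire``/``dam`` are ``None`` for founders."""

    id: str
    sire: Optional[str]
    dam: Optional[str]
    group: str

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


def _check_grammar(ind: Individual, group_of: dict) -> None:
    if ind.is_founder:
        if ind.group not in PURE_BREEDS:
            raise BreedGrammarError(
                f"founder {ind.id!r} has group {ind.group!r}; founders must "
                f"be pure-breed (one of {PURE_BREEDS})"
            )
        return
    gs, gd = group_of[ind.sire], group_of[ind.dam]
    pair = frozenset((gs, gd)) if gs != gd else frozenset((gs,))
    if ind.group == "S":
        if pair != frozenset(("D", "T")):
            raise BreedGrammarError(
                f"synthetic {ind.id!r} needs one D and one T parent, "
                f"got ({gs}, {gd})"
            )
    elif ind.group == "SD":
        if "V" not in pair or not (pair & {"S", "SD"}):
            raise BreedGrammarError(
                f"synthetic derivative {ind.id!r} needs one V parent and one "
                f"S or SD parent, got ({gs}, {gd})"
            )
    elif ind.group in PURE_BREEDS:
        if gs != ind.group or gd != ind.group:
            raise BreedGrammarError(
                f"pure-breed {ind.id!r} ({ind.group}) needs both parents in "
                f"group {ind.group}, got ({gs}, {gd})"
            )
    else:  # pragma: no cover - caught earlier by UnknownGroupError
        raise UnknownGroupError(f"unknown breed group {ind.group!r}")


class Pedigree:
    """A validated, topologically ordered multi-breed pedigree.

    Parents always precede offspring.  Ordering uses Kahn's algorithm with
    ties broken by input order, so matrix layouts are reproducible.
    """

    def __init__(self, individuals: Iterable[Individual]):
        inds = list(individuals)
        self._validate_ids(inds)
        inds = self._toposort(inds)
        group_of = {i.id: i.group for i in inds}
        for ind in inds:
            _check_grammar(ind, group_of)
        self.individuals: list[Individual] = inds
        self.index: dict[str, int] = {ind.id: k for k, ind in enumerate(inds)}
        n = len(inds)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for k, ind in enumerate(inds):
            if not ind.is_founder:
                self.sire_idx[k] = self.index[ind.sire]
                self.dam_idx[k] = self.index[ind.dam]
        self.groups = np.array([i.group for i in inds], dtype=object)
        counts = self.group_counts()
        logger.info(
            "pedigree with %d individuals: %s",
            n,
            ", ".join(f"{g}={counts.get(g, 0)}" for g in GROUPS),
        )

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _validate_ids(inds: Sequence[Individual]) -> None:
        seen: set[str] = set()
        for ind in inds:
            if ind.id in seen:
                raise DuplicateIdError(f"duplicate id {ind.id!r}")
            seen.add(ind.id)
        for ind in inds:
            known = [p for p in (ind.sire, ind.dam) if p is not None]
            if len(known) == 1:
                raise PartialParentageError(
                    f"{ind.id!r} has exactly one known parent; parents must "
                    "be both known or both unknown"
                )
            for p in known:
                if p not in seen:
                    raise UnknownParentError(
                        f"{ind.id!r} references missing parent {p!r}"
                    )
            if ind.id in known:
                raise PedigreeCycleError(f"{ind.id!r} is its own parent")
            BreedGroup(ind.group)  # raises UnknownGroupError

    @staticmethod
    def _toposort(inds: Sequence[Individual]) -> list[Individual]:
        pos = {ind.id: k for k, ind in enumerate(inds)}
        children: dict[str, list[str]] = {ind.id: [] for ind in inds}
        n_pending = {}
        for ind in inds:
            parents = {p for p in (ind.sire, ind.dam) if p is not None}
            n_pending[ind.id] = len(parents)
            for p in parents:
                children[p].append(ind.id)
        ready = [pos[i] for i, d in n_pending.items() if d == 0]
        heapq.heapify(ready)
        by_pos = list(inds)
        out: list[Individual] = []
        while ready:
            k = heapq.heappop(ready)
            ind = by_pos[k]
            out.append(ind)
            for child in children[ind.id]:
                n_pending[child] -= 1
                if n_pending[child] == 0:
                    heapq.heappush(ready, pos[child])
        if len(out) != len(inds):
            cycle = sorted(i for i, d in n_pending.items() if d > 0)
            raise PedigreeCycleError(
                f"pedigree contains a cycle through: {', '.join(cycle)}"
            )
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        required = {"id", "sire", "dam", "group"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")

        def _parent(v) -> Optional[str]:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip()
            return None if s in MISSING_TOKENS else s

        inds = [
            Individual(
                id=str(r.id).strip(),
                sire=_parent(r.sire),
                dam=_parent(r.dam),
                group=str(r.group).strip(),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(inds)

    @classmethod
    def from_file(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls.from_dataframe(df)

    # -- basic queries -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ind in self.individuals:
            counts[ind.group] = counts.get(ind.group, 0) + 1
        return counts

    def founder_mask(self) -> np.ndarray:
        return self.sire_idx < 0

    # -- I/O -----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [i.sire or "" for i in self.individuals],
                "dam": [i.dam or "" for i in self.individuals],
                "group": [i.group for i in self.individuals],
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (columns id, sire, dam, group)."""
    return Pedigree.from_file(path)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.write(path)


def breed_fractions(ped: Pedigree) -> pd.DataFrame:
    """Breed-composition coefficients ``f_D``, ``f_T``, ``f_V`` per individual.

    Founders are indicators of their own breed.  A doubled synthetic carries a
    complete diploid genome from each parent species, so ``f_D = f_T = 1``.
    Every other non-founder averages its parents:
    ``f_i = (f_sire + f_dam) / 2``.  ``100 * f_D`` is the familiar
    "percent synthetic genome" label of derivative lines.
    """
    n = ped.n
    f = np.zeros((n, 3))
    col = {"D": 0, "T": 1, "V": 2}
    for k, ind in enumerate(ped.individuals):
        if ind.is_founder:
            f[k, col[ind.group]] = 1.0
        elif ind.group == "S":
            f[k, 0] = 1.0
            f[k, 1] = 1.0
        else:
            f[k] = 0.5 * (f[ped.sire_idx[k]] + f[ped.dam_idx[k]])
    return pd.DataFrame(f, index=pd.Index(ped.ids, name="id"),
                        columns=["f_D", "f_T", "f_V"])


def inbreeding(ped: Pedigree) -> pd.DataFrame:
    """Within-subgenome inbreeding coefficients ``F_D``, ``F_T``, ``F_V``.

    Because allopolyploid subgenomes pair independently, inbreeding is
    defined per pure-breed component as half the parents' partial
    relationship restricted to that component; founders are non-inbred.
    """
    from .kinship import build_partial_matrices

    pk = build_partial_matrices(ped)
    n = ped.n
    F = np.zeros((n, 3))
    for k in range(n):
        s, d = ped.sire_idx[k], ped.dam_idx[k]
        if s >= 0:
            for j, q in enumerate(PURE_BREEDS):
                F[k, j] = 0.5 * pk.components[q][s, d]
    return pd.DataFrame(F, index=pd.Index(ped.ids, name="id"),
                        columns=["F_D", "F_T", "F_V"])


def backcross_chain(depth: int = 3, prefix: str = "") -> Pedigree:
    """Canonical single-line crossing scheme used for worked examples.

    Builds ``D1 x T1 -> S1`` (doubled synthetic), ``S1 x V0 -> F1`` (50 %
    synthetic), then ``depth`` successive backcrosses to fresh, unrelated,
    non-inbred *T. aestivum* lines: ``BCk = Vk x BC(k-1)`` (25, 12.5,
    6.25 % ... synthetic).
    """
    if not 0 <= depth <= 8:
        raise ValueError("depth must be between 0 and 8")
    p = prefix
    inds = [
        Individual(f"{p}D1", None, None, "D"),
        Individual(f"{p}T1", None, None, "T"),
        Individual(f"{p}S1", f"{p}D1", f"{p}T1", "S"),
        Individual(f"{p}V0", None, None, "V"),
        Individual(f"{p}F1", f"{p}S1", f"{p}V0", "SD"),
    ]
    previous = f"{p}F1"
    for g in range(1, depth + 1):
        inds.append(Individual(f"{p}V{g}", None, None, "V"))
        inds.append(Individual(f"{p}BC{g}", f"{p}V{g}", previous, "SD"))
        previous = f"{p}BC{g}"
    return Pedigree(inds)


#: Representative individual of each cross type in :func:`backcross_chain`.
CROSS_TYPE_IDS = {"F1": "F1", "BC1": "BC1", "BC2": "BC2", "BC3": "BC3"}
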