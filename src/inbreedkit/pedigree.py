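"""Pedigree-based inbreeding and kinship, and design-expectation calculus.

Implements the tabular (recursive) method for the coancestry f(x, y) and the
inbreeding coefficient F of pedigree members, plus the expectation calculus
for the fraction of the pedigree inbreeding-depression rate that a regression
on molecular F can capture when only a subset of the parents contributing to
a trait is genotyped.

The capture fraction for a trait measured on a group of contributing parents,
of whom one is genotyped, is

    fraction = (sum over contributors of r_i) / (number of contributors),

where r_i is the expected fraction of the genome that contributor i shares
with the genotyped individual (r = 1 for the genotyped individual itself,
r = 2 f for a relative with coancestry f), assuming all contributors weigh
equally on the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Pedigree",
    "DesignSpec",
    "pedigree_f",
    "kinship",
    "genome_sharing",
    "expected_fraction",
    "expected_molecular_id",
    "trait_attached_f",
]

Id = Hashable


class Pedigree:
    """Ordered pedigree records; founders have ``None`` parents.

    Records must list parents before offspring and contain no cycles (both
    enforced at construction).
    """

    def __init__(self, records: Iterable[tuple[Id, Id | None, Id | None]]):
        self._sire: dict[Id, Id | None] = {}
        self._dam: dict[Id, Id | None] = {}
        for iid, sire, dam in records:
            if iid in self._sire:
                raise ValueError(f"duplicate pedigree id {iid!r}")
            for parent in (sire, dam):
                if parent is not None and parent not in self._sire:
                    raise ValueError(
                        f"parent {parent!r} of {iid!r} not listed before offspring"
                    )
            if iid in (sire, dam):
                raise ValueError(f"individual {iid!r} is its own parent")
            self._sire[iid] = sire
            self._dam[iid] = dam
        self._order = {iid: i for i, iid in enumerate(self._sire)}
        self._kinship_cache: dict[tuple[Id, Id], Fraction] = {}

    def __contains__(self, iid: Id) -> bool:
        return iid in self._sire

    def __len__(self) -> int:
        return len(self._sire)

    @property
    def ids(self) -> list[Id]:
        return list(self._sire)

    def parents(self, iid: Id) -> tuple[Id | None, Id | None]:
        self._check(iid)
        return self._sire[iid], self._dam[iid]

    def _check(self, iid: Id) -> None:
        if iid not in self._sire:
            raise KeyError(f"unknown pedigree id {iid!r}")

    # tabular method -----------------------------------------------------
    def kinship(self, a: Id, b: Id) -> Fraction:
        """Coancestry f(a, b) by the recursive tabular method (exact rational)."""
        self._check(a)
        self._check(b)
        return self._kinship(a, b)

    def _kinship(self, a: Id, b: Id) -> Fraction:
        # Order the pair so each unordered pair is cached once. Ids sorted by
        # insertion order, which also guarantees the second member never
        # precedes the first in the pedigree.
        if self._order[a] > self._order[b]:
            a, b = b, a
        key = (a, b)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        if a == b:
            f = Fraction(1, 2) * (1 + self.inbreeding(a))
        else:
            # b does not precede a, so recurse on b's parents.
            sire, dam = self._sire[b], self._dam[b]
            f = Fraction(0)
            if sire is not None:
                f += Fraction(1, 2) * self._kinship(a, sire)
            if dam is not None:
                f += Fraction(1, 2) * self._kinship(a, dam)
        self._kinship_cache[key] = f
        return f

    def inbreeding(self, iid: Id) -> Fraction:
        """F(individual) = f(sire, dam); founders and half-founders get 0."""
        self._check(iid)
        sire, dam = self._sire[iid], self._dam[iid]
        if sire is None or dam is None:
            return Fraction(0)
        return self._kinship(sire, dam)

    def genome_sharing(self, a: Id, b: Id) -> Fraction:
        """Expected shared genome fraction, 2 f(a, b), clipped to [0, 1]."""
        return min(Fraction(1), 2 * self.kinship(a, b))

    # IO -----------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns id, sire, dam (0/NA = founder)."""
        def norm(v):
            if pd.isna(v) or v in (0, "0", "", "NA"):
                return None
            return v

        return cls(
            (row["id"], norm(row["sire"]), norm(row["dam"]))
            for _, row in frame.iterrows()
        )

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def pedigree_f(pedigree: Pedigree, iid: Id) -> Fraction:
    return pedigree.inbreeding(iid)


def kinship(pedigree: Pedigree, a: Id, b: Id) -> Fraction:
    return pedigree.kinship(a, b)


def genome_sharing(pedigree: Pedigree, a: Id, b: Id) -> Fraction:
    return pedigree.genome_sharing(a, b)


# design expectations ----------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Which parents contribute to a trait and what each shares with the
    genotyped individual.

    ``contributors`` maps contributor id -> expected genome sharing r with the
    measured (genotyped) individual; the measured individual itself must
    appear with r = 1.
    """

    measured_id: Id
    contributors: Mapping[Id, Rational | float]
    trait: str = ""

    def __post_init__(self) -> None:
        if len(self.contributors) == 0:
            raise ValueError("contributor list must be non-empty")
        rs = list(self.contributors.values())
        if any(not 0 <= r <= 1 for r in rs):
            raise ValueError("genome sharing r must lie in [0, 1]")
        if self.measured_id not in self.contributors:
            raise ValueError("measured individual must be among contributors")
        if self.contributors[self.measured_id] != 1:
            raise ValueError("measured individual must have r = 1")


def expected_fraction(design: DesignSpec):
    """Fraction of the full-design ID slope recoverable from the genotyped
    individual's F, assuming equal trait contribution of all contributors.

    Returns an exact :class:`fractions.Fraction` when all sharings are
    rational, else a float.
    """
    rs = list(design.contributors.values())
    if all(isinstance(r, Rational) for r in rs):
        return sum((Fraction(r) for r in rs), Fraction(0)) / len(rs)
    return float(sum(rs)) / len(rs)


def expected_molecular_id(id_ped: float, design: DesignSpec) -> float:
    """Expected marker-based ID slope: capture fraction times the pedigree ID."""
    import math

    if not math.isfinite(id_ped):
        raise ValueError("pedigree ID must be finite")
    return float(expected_fraction(design)) * id_ped


def trait_attached_f(
    parent_f: Rational | float,
    progeny_f: Rational | float,
    weights: Sequence[Rational | float] = (Fraction(1, 2), Fraction(1, 2)),
):
    """Effective F attached to a trait that depends on both the parents'
    inbreeding and that of their progeny: the weighted mean of the two."""
    if len(weights) != 2:
        raise ValueError("exactly two weights (parents, progeny) expected")
    if sum(weights) != 1:
        raise ValueError("weights must sum to 1")
    values = (parent_f, progeny_f)
    if all(isinstance(v, Rational) for v in (*values, *weights)):
        return sum(Fraction(w) * Fraction(v) for w, v in zip(weights, values))
    return float(sum(w * v for w, v in zip(weights, values)))


def standard_designs(pedigree_sharing: Mapping[str, float] | None = None) -> dict[str, DesignSpec]:
    """The four measured-male designs of the full-sib breeding experiment.

    Productivity is a pair trait (2 contributing parents); competitive
    fitness pools four pairs (8 contributing parents), with one wild-type
    female in the inbred scheme being a cousin of the genotyped male
    (f = 0.25, r = 0.5).
    """
    half = Fraction(1, 2)
    mate_inbred = Fraction(3, 4)  # full sibs of full-sib parents: f = 3/8
    return {
        "noninbred_productivity": DesignSpec(
            "male", {"male": 1, "mate": 0}, trait="P"
        ),
        "inbred_productivity": DesignSpec(
            "male", {"male": 1, "mate": mate_inbred}, trait="P"
        ),
        "noninbred_fitness": DesignSpec(
            "male",
            {"male": 1, "mate": 0, **{f"other{i}": 0 for i in range(6)}},
            trait="W",
        ),
        "inbred_fitness": DesignSpec(
            "male",
            {
                "male": 1,
                "mate": mate_inbred,
                "cousin_female": half,
                **{f"other{i}": 0 for i in range(5)},
            },
            trait="W",
        ),
    }
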