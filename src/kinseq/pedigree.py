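"""Pedigrees: structure, kinship coefficients and expected relationships.

A pedigree is a DAG of individuals with either both parents present or both
absent (founders).  Expected relatedness between members is computed with
the classic recursive kinship coefficient

    phi(i, j) = ( phi(father_i, j) + phi(mother_i, j) ) / 2,
    phi(i, i) = ( 1 + phi(father_i, mother_i) ) / 2,

taking the recursion on whichever argument is in the later generation, with
founders unrelated and non-inbred.  The expected relationship *class*
(parent-offspring, full-sibling, second-degree, third-degree, unrelated)
follows from the degree ``round(-log2(2 phi))`` plus the direct parent-link
check that separates parent-offspring from full siblings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "Individual", "Pedigree", "pedigree_preset", "PRESET_NAMES",
    "pedigree_expected_relationship",
]

SEXES = ("male", "female", "unknown")
_FAM_SEX = {"male": 1, "female": 2, "unknown": 0}
_FAM_SEX_INV = {1: "male", 2: "female"}


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"


class Pedigree:
    """Validated pedigree with kinship/relationship queries."""

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        ids = [m.iid for m in members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        self._members = {m.iid: m for m in members}
        self._order = ids
        for m in members:
            if (m.father is None) != (m.mother is None):
                raise ValueError(f"{m.iid}: both parents must be present or both absent")
            for p in (m.father, m.mother):
                if p is not None and p not in self._members:
                    raise ValueError(f"{m.iid}: unknown parent {p}")
            if m.sex not in SEXES:
                raise ValueError(f"{m.iid}: sex must be one of {SEXES}")
        self._rank: dict[str, int] = {}
        for iid in self._toposort():
            m = self._members[iid]
            self._rank[iid] = 0 if m.father is None else 1 + max(
                self._rank[m.father], self._rank[m.mother])
        self._phi_cache: dict[tuple[str, str], float] = {}

    # -- structure ---------------------------------------------------------

    def _toposort(self) -> list[str]:
        out: list[str] = []
        state: dict[str, int] = {}

        def visit(iid: str, stack: tuple[str, ...]) -> None:
            if iid in stack:
                raise ValueError(f"pedigree cycle involving {iid}")
            if state.get(iid):
                return
            m = self._members[iid]
            if m.father is not None:
                visit(m.father, stack + (iid,))
                visit(m.mother, stack + (iid,))
            state[iid] = 1
            out.append(iid)

        for iid in self._order:
            visit(iid, ())
        return out

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def founders(self) -> list[str]:
        return [i for i in self._order if self._members[i].father is None]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self._order if self._members[i].father is not None]

    def topological_order(self) -> list[str]:
        return sorted(self._order, key=self._rank.get)

    def sexes(self) -> dict[str, str]:
        return {i: self._members[i].sex for i in self._order}

    def with_extra_founders(self, n: int, prefix: str = "U") -> "Pedigree":
        """Append ``n`` unrelated founder individuals (alternating sex)."""
        extra = [Individual(f"{prefix}{k + 1}", sex="male" if k % 2 == 0 else "female")
                 for k in range(n)]
        return Pedigree(list(self._members.values()) + extra)

    # -- kinship -----------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b)."""
        if a not in self or b not in self:
            raise KeyError(f"unknown individual in pair ({a}, {b})")
        return self._phi(a, b)

    def _phi(self, a: str, b: str) -> float:
        if self._rank[a] < self._rank[b] or (self._rank[a] == self._rank[b] and a > b):
            a, b = b, a
        key = (a, b)
        if key in self._phi_cache:
            return self._phi_cache[key]
        ma = self._members[a]
        if a == b:
            val = 0.5 if ma.father is None else 0.5 * (1.0 + self._phi(ma.father, ma.mother))
        elif ma.father is None:
            val = 0.0  # both founders (equal rank 0)
        else:
            val = 0.5 * (self._phi(ma.father, b) + self._phi(ma.mother, b))
        self._phi_cache[key] = val
        return val

    def is_inbred(self, iid: str) -> bool:
        m = self._members[iid]
        return m.father is not None and self._phi(m.father, m.mother) > 0.0

    def is_parent_offspring(self, a: str, b: str) -> bool:
        return (self._members[a].father in (b,) or self._members[a].mother in (b,)
                or self._members[b].father in (a,) or self._members[b].mother in (a,))

    def are_full_siblings(self, a: str, b: str) -> bool:
        ma, mb = self._members[a], self._members[b]
        return (a != b and ma.father is not None
                and ma.father == mb.father and ma.mother == mb.mother)

    def expected_relationship(self, a: str, b: str) -> "ExpectedRelationship":
        return pedigree_expected_relationship(self, a, b)

    def pairs(self) -> list[tuple[str, str]]:
        ids = self._order
        return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    # -- FAM I/O -----------------------------------------------------------

    def to_fam(self, path, family_id: str = "FAM1") -> None:
        rows = []
        for iid in self._order:
            m = self._members[iid]
            rows.append([family_id, iid, m.father or "0", m.mother or "0",
                         _FAM_SEX[m.sex], -9])
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["fid", "iid", "father", "mother", "sex", "pheno"],
                         dtype=str)
        members = []
        for _, r in df.iterrows():
            members.append(Individual(
                r["iid"],
                None if r["father"] in ("0", "NA") else r["father"],
                None if r["mother"] in ("0", "NA") else r["mother"],
                _FAM_SEX_INV.get(int(float(r["sex"])), "unknown"),
            ))
        return cls(members)


@dataclass(frozen=True)
class ExpectedRelationship:
    """Pedigree-derived truth for one pair: kinship, relatedness, class."""

    kinship: float            # phi
    relatedness: float        # 2 phi; equals expected PI_HAT for non-inbred pairs
    degree: float             # 0 duplicates, 1 PO/FS, 2, 3, ... ; inf if unrelated
    relationship: str         # classifier vocabulary (see classify module)
    approximate: bool = False  # True when inbreeding makes the class mapping loose


def pedigree_expected_relationship(ped: Pedigree, a: str, b: str) -> ExpectedRelationship:
    """Expected kinship and relationship class for a pair of members.

    Degrees beyond the third are mapped to ``unrelated``: the estimator
    cannot separate them from true non-relatives, and the classifier
    vocabulary stops at third degree.
    """
    phi = ped.kinship(a, b)
    approx = ped.is_inbred(a) or ped.is_inbred(b)
    if a == b or (phi >= 0.5 * (1 - 1e-12)):
        return ExpectedRelationship(phi, 2 * phi, 0.0, "duplicate", approx)
    if phi == 0.0:
        return ExpectedRelationship(0.0, 0.0, math.inf, "unrelated", approx)
    degree = round(-math.log2(2.0 * phi))
    if degree <= 1:
        cls = "parent-offspring" if ped.is_parent_offspring(a, b) else "full-sibling"
        degree = 1
    elif degree == 2:
        cls = "second-degree"
    elif degree == 3:
        cls = "third-degree"
    else:
        cls = "unrelated"
    return ExpectedRelationship(phi, 2 * phi, float(degree), cls, approx)


def _couple(prefix: str) -> list[Individual]:
    return [Individual(prefix + "F", sex="male"), Individual(prefix + "M", sex="female")]


def _preset_type1() -> Pedigree:
    """16 members: two founder couples, one parental couple, ten children.

    Mirrors a three-generation family with a large sibship: parent-offspring,
    full-sibling, grandparental (second degree) and unrelated pairs.
    """
    members = _couple("GP1") + _couple("GP2")
    members += [Individual("FA", "GP1F", "GP1M", "male"),
                Individual("MO", "GP2F", "GP2M", "female")]
    members += [Individual(f"C{k:02d}", "FA", "MO",
                           "male" if k % 2 else "female") for k in range(1, 11)]
    return Pedigree(members)


def _preset_type2() -> Pedigree:
    """16 members, first and second degree relationships only.

    One grandparental couple with a three-child sibship; one child founds a
    six-child sibship whose members have grandparents, aunts/uncles and,
    via their father's second partnership, half-siblings - every first and
    second degree relationship without creating cousins.
    """
    members = _couple("GP")
    members += [Individual("A1", "GPF", "GPM", "male"),
                Individual("A2", "GPF", "GPM", "female"),
                Individual("A3", "GPF", "GPM", "male"),
                Individual("S1", sex="female"),
                Individual("S2", sex="male")]
    members += [Individual(f"B{k}", "A1", "S1",
                           "male" if k % 2 else "female") for k in range(1, 7)]
    members += [Individual(f"H{k}", "S2", "S1",
                           "female" if k % 2 else "male") for k in range(1, 4)]
    return Pedigree(members)


def _preset_type3() -> Pedigree:
    """16 members: two five-child sibships of first cousins (25 third-degree
    pairs) plus parents and grandparents."""
    members = _couple("GP")
    members += [Individual("A1", "GPF", "GPM", "female"),
                Individual("A2", "GPF", "GPM", "male"),
                Individual("S1", sex="male"), Individual("S2", sex="female")]
    members += [Individual(f"B{k}", "S1", "A1",
                           "male" if k % 2 else "female") for k in range(1, 6)]
    members += [Individual(f"C{k}", "A2", "S2",
                           "female" if k % 2 else "male") for k in range(1, 6)]
    return Pedigree(members)


def _preset_type4() -> Pedigree:
    """12 members over four generations: great-grandparental and first-cousin
    (third degree) pairs plus a cousin-once-removed (fourth degree) pair."""
    members = _couple("GP")
    members += [Individual("A1", "GPF", "GPM", "male"),
                Individual("A2", "GPF", "GPM", "female"),
                Individual("S1", sex="female"), Individual("S2", sex="male"),
                Individual("B1", "A1", "S1", "male"),
                Individual("B2", "A1", "S1", "female"),
                Individual("B3", "S2", "A2", "male"),
                Individual("B4", "S2", "A2", "female"),
                Individual("S3", sex="female"),
                Individual("C1", "B1", "S3", "male")]
    return Pedigree(members)


def _preset_trio() -> Pedigree:
    return Pedigree([Individual("FA", sex="male"), Individual("MO", sex="female"),
                     Individual("CH", "FA", "MO", "female")])


def _preset_pair_unrelated() -> Pedigree:
    """A parent-offspring pair plus unrelated individuals, echoing small
    published datasets (a first-degree pair among non-relatives)."""
    return Pedigree([Individual("FA", sex="male"), Individual("MO", sex="female"),
                     Individual("CH", "FA", "MO", "male"),
                     Individual("U1", sex="female"), Individual("U2", sex="male")])


_PRESETS = {
    "type1": _preset_type1,
    "type2": _preset_type2,
    "type3": _preset_type3,
    "type4": _preset_type4,
    "trio": _preset_trio,
    "pair_unrelated": _preset_pair_unrelated,
}

PRESET_NAMES = tuple(_PRESETS)


def pedigree_preset(name: str) -> Pedigree:
    """Built-in pedigree structures (``type1`` .. ``type4``, ``trio``,
    ``pair_unrelated``)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown pedigree preset {name!r}; "
                         f"available: {', '.join(_PRESETS)}") from None
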