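"""Pedigree data model, canonical study structures, and inheritance vectors.

A pedigree here is a directed family graph of fully specified individuals.
Each non-founder contributes two meioses (one per parent); an inheritance
vector assigns one transmission bit per meiosis (0 = the parent passed the
allele on its own paternally derived haplotype, 1 = the maternally derived
one).  For ``m`` meioses there are ``2**m`` vectors, uniform a priori, and
the map from vectors to founder-haplotype origins is the basis of both the
allele-sharing statistics and the two-point likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "SampleSpec",
    "InheritanceVector",
    "STRUCTURE_CODES",
    "MIXTURE_SPEC",
    "build_structure",
    "build_mixture_spec",
    "enumerate_inheritance_vectors",
]

UNKNOWN, UNAFFECTED, AFFECTED = "unknown", "unaffected", "affected"
_AFFECTIONS = (UNKNOWN, UNAFFECTED, AFFECTED)
_SEXES = ("male", "female")


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Founders have both parent ids ``None``; non-founders have both set.
    """

    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    affection: str = UNKNOWN

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError(
                f"individual {self.id!r}: either both parents or neither"
            )
        if self.sex not in _SEXES:
            raise ValueError(f"individual {self.id!r}: sex must be male/female")
        if self.affection not in _AFFECTIONS:
            raise ValueError(
                f"individual {self.id!r}: affection must be one of {_AFFECTIONS}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree: acyclic, topologically ordered, sex-consistent.

    ``meioses`` lists ``(child_id, parent_id)`` pairs, two per non-founder,
    in member order (father meiosis first).  Bit ``j`` of an inheritance
    vector refers to ``meioses[j]``.
    """

    family_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"family {self.family_id!r}: duplicate member ids")
        by_id = {ind.id: ind for ind in self.members}
        seen: set[str] = set()
        for ind in self.members:
            if not ind.is_founder:
                for pid, sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                    if pid not in by_id:
                        raise ValueError(
                            f"family {self.family_id!r}: parent {pid!r} of "
                            f"{ind.id!r} is not a member"
                        )
                    if pid not in seen:
                        raise ValueError(
                            f"family {self.family_id!r}: member order is not "
                            f"topological ({pid!r} after {ind.id!r})"
                        )
                    if by_id[pid].sex != sex:
                        raise ValueError(
                            f"family {self.family_id!r}: parents of {ind.id!r} "
                            "must have opposite sexes (father male, mother female)"
                        )
            seen.add(ind.id)

    # -- basic views ---------------------------------------------------
    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.members)

    def member_index(self, member_id: str) -> int:
        return self.member_ids.index(member_id)

    @property
    def founders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.members if ind.is_founder)

    @property
    def nonfounders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.members if not ind.is_founder)

    @property
    def meioses(self) -> tuple[tuple[str, str], ...]:
        out: list[tuple[str, str]] = []
        for ind in self.nonfounders:
            out.append((ind.id, ind.father_id))  # paternal meiosis
            out.append((ind.id, ind.mother_id))  # maternal meiosis
        return tuple(out)

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.nonfounders)

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.members if ind.affection == AFFECTED)

    # -- founder-haplotype bookkeeping ---------------------------------
    def founder_hap_ids(self) -> dict[str, tuple[int, int]]:
        """Assign each founder's two haplotypes consecutive integer ids."""
        out: dict[str, tuple[int, int]] = {}
        k = 0
        for ind in self.founders:
            out[ind.id] = (k, k + 1)
            k += 2
        return out

    def founder_hap_map(self) -> np.ndarray:
        """Founder-haplotype origin of every (member, slot) under every vector.

        Returns an int8 array of shape ``(2**m, n_members, 2)`` where slot 0
        is the paternally and slot 1 the maternally derived allele.  Entry
        ``[v, i, s]`` is the founder-haplotype id that member ``i``'s slot
        ``s`` descends from under inheritance vector ``v``.
        """
        m = self.n_meioses
        if m > 24:
            raise ValueError("too many meioses for dense enumeration")
        nv = 1 << m
        fh = np.zeros((nv, self.n_members, 2), dtype=np.int8)
        hap_ids = self.founder_hap_ids()
        vv = np.arange(nv)
        idx = {mid: i for i, mid in enumerate(self.member_ids)}
        j = 0
        for ind in self.members:
            i = idx[ind.id]
            if ind.is_founder:
                fh[:, i, 0] = hap_ids[ind.id][0]
                fh[:, i, 1] = hap_ids[ind.id][1]
            else:
                for slot, pid in ((0, ind.father_id), (1, ind.mother_id)):
                    bits = (vv >> j) & 1
                    fh[:, i, slot] = fh[vv, idx[pid], bits]
                    j += 1
        return fh


@dataclass(frozen=True)
class InheritanceVector:
    """Transmission bits, one per meiosis, in the pedigree's meiosis order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("inheritance vector bits must be 0/1")

    @property
    def index(self) -> int:
        """Integer encoding with meiosis ``j`` at bit position ``j``."""
        return sum(b << j for j, b in enumerate(self.bits))

    @classmethod
    def from_index(cls, v: int, m: int) -> "InheritanceVector":
        return cls(tuple((v >> j) & 1 for j in range(m)))


@dataclass(frozen=True)
class SampleSpec:
    """A sample composition: list of (structure code, pedigree count)."""

    parts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for code, count in self.parts:
            if code not in STRUCTURE_CODES:
                raise ValueError(
                    f"unknown structure code {code!r}; valid: {STRUCTURE_CODES}"
                )
            if count < 0:
                raise ValueError("pedigree counts must be nonnegative")

    @property
    def n_pedigrees(self) -> int:
        return sum(c for _, c in self.parts)

    @classmethod
    def homogeneous(cls, code: str, count: int = 500) -> "SampleSpec":
        return cls(((code, count),))


STRUCTURE_CODES = ("ASP", "AST", "ASQ", "DST", "DSQ", "A3G", "D3G")

#: The mixed sample evaluated in the study: 400 pedigrees of four types.
MIXTURE_SPEC = SampleSpec((("AST", 100), ("ASQ", 100), ("DST", 100), ("DSQ", 100)))


def build_mixture_spec() -> SampleSpec:
    return MIXTURE_SPEC


def _nuclear(code: str, n_affected: int, n_unaffected: int) -> Pedigree:
    members = [
        Individual("1", None, None, "male", UNKNOWN),
        Individual("2", None, None, "female", UNKNOWN),
    ]
    k = 3
    for _ in range(n_affected):
        members.append(Individual(str(k), "1", "2", "male", AFFECTED))
        k += 1
    for _ in range(n_unaffected):
        members.append(Individual(str(k), "1", "2", "female", UNAFFECTED))
        k += 1
    return Pedigree(code, tuple(members))


def _three_generation(
    code: str, descendant_affection: Sequence[str]
) -> Pedigree:
    """Three-generation family: grandparents, one of their children plus a
    married-in spouse, and two grandchildren.

    ``descendant_affection`` gives the status of (child-of-grandparents,
    spouse, grandchild 1, grandchild 2).
    """
    if len(descendant_affection) != 4:
        raise ValueError("descendant_affection needs 4 entries")
    a = list(descendant_affection)
    members = (
        Individual("1", None, None, "male", UNKNOWN),
        Individual("2", None, None, "female", UNKNOWN),
        Individual("3", "1", "2", "male", a[0]),
        Individual("4", None, None, "female", a[1]),
        Individual("5", "3", "4", "male", a[2]),
        Individual("6", "3", "4", "female", a[3]),
    )
    return Pedigree(code, members)


def build_structure(
    code: str,
    three_gen_affection: Optional[Sequence[str]] = None,
) -> Pedigree:
    """Build one of the seven canonical pedigree structures.

    Nuclear codes: ASP (2 affected sibs), AST (3), ASQ (4), DST (ASP + 1
    unaffected sib), DSQ (ASP + 2 unaffected sibs).  Parents are genotyped
    but phenotypically unknown.  A3G/D3G are three-generation families; the
    default affection placement (all four descendants affected for A3G, two
    affected / two unaffected for D3G) can be overridden with
    ``three_gen_affection``.
    """
    if code == "ASP":
        return _nuclear(code, 2, 0)
    if code == "AST":
        return _nuclear(code, 3, 0)
    if code == "ASQ":
        return _nuclear(code, 4, 0)
    if code == "DST":
        return _nuclear(code, 2, 1)
    if code == "DSQ":
        return _nuclear(code, 2, 2)
    if code == "A3G":
        aff = three_gen_affection or (AFFECTED,) * 4
        return _three_generation(code, aff)
    if code == "D3G":
        # the affected pair are the two grandchildren (sibs, variable IBD);
        # their parents are the unaffected descendants
        aff = three_gen_affection or (UNAFFECTED, UNAFFECTED, AFFECTED, AFFECTED)
        return _three_generation(code, aff)
    raise ValueError(f"unknown structure code {code!r}; valid: {STRUCTURE_CODES}")


def enumerate_inheritance_vectors(
    ped: Pedigree, max_meioses: int = 20
) -> list[InheritanceVector]:
    """All ``2**m`` inheritance vectors of a pedigree.

    Raises if the meiosis count exceeds ``max_meioses``; for such pedigrees
    use the peeling likelihood path instead of dense enumeration.
    """
    m = ped.n_meioses
    if m > max_meioses:
        raise ValueError(
            f"{m} meioses exceed the enumeration cap ({max_meioses}); "
            "use likelihood peeling instead"
        )
    return [InheritanceVector.from_index(v, m) for v in range(1 << m)]
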