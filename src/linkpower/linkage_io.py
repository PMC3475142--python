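"""LINKAGE pre-makeped pedigree file I/O (one marker).

Whitespace-delimited records: family id, individual id, father id, mother
id (0 = founder), sex (1 male / 2 female), affection (0 unknown /
1 unaffected / 2 affected), then the marker's two allele columns
(0 = missing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_drop import GenotypeTable
from .pedigree import Individual, Pedigree

__all__ = ["read_linkage_ped", "write_linkage_ped"]

_SEX = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2"}
_AFF = {"0": "unknown", "1": "unaffected", "2": "affected"}
_AFF_OUT = {v: k for k, v in _AFF.items()}


def write_linkage_ped(
    peds: Sequence[Pedigree],
    genotypes: Sequence[GenotypeTable],
    path: str | Path,
) -> None:
    lines = []
    for ped, gt in zip(peds, genotypes, strict=True):
        for ind in ped.members:
            a1, a2 = gt.pair(ind.id)
            lines.append(
                " ".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _AFF_OUT[ind.affection],
                        str(a1),
                        str(a2),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_linkage_ped(
    path: str | Path,
) -> tuple[list[Pedigree], list[GenotypeTable]]:
    """Parse a pre-makeped file; returns pedigrees with aligned genotype
    tables, members reordered topologically (parents before children)."""
    fams: dict[str, list[tuple[Individual, tuple[int, int]]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 8:
            raise ValueError(f"line {ln}: expected 8 fields, got {len(parts)}")
        fam, iid, fa, mo, sex, aff, a1, a2 = parts
        if sex not in _SEX:
            raise ValueError(f"line {ln}: sex code must be 1 or 2")
        if aff not in _AFF:
            raise ValueError(f"line {ln}: affection code must be 0, 1 or 2")
        if (fa == "0") != (mo == "0"):
            raise ValueError(f"line {ln}: either both parents or neither")
        alleles = (int(a1), int(a2))
        if min(alleles) < 0:
            raise ValueError(f"line {ln}: negative allele code")
        ind = Individual(
            iid,
            None if fa == "0" else fa,
            None if mo == "0" else mo,
            _SEX[sex],
            _AFF[aff],
        )
        fams.setdefault(fam, []).append((ind, alleles))

    peds, gts = [], []
    for fam, rows in fams.items():
        ordered = _topological(fam, rows)
        ped = Pedigree(fam, tuple(ind for ind, _ in ordered))
        gt = GenotypeTable(
            ped.member_ids,
            np.array([alle for _, alle in ordered], dtype=np.int16),
        )
        peds.append(ped)
        gts.append(gt)
    return peds, gts


def _topological(fam, rows):
    by_id = {ind.id: (ind, alle) for ind, alle in rows}
    for ind, _ in rows:
        if not ind.is_founder:
            for pid in (ind.father_id, ind.mother_id):
                if pid not in by_id:
                    raise ValueError(
                        f"family {fam!r}: parent {pid!r} of {ind.id!r} "
                        "is not a member"
                    )
    ordered, placed = [], set()
    pending = list(rows)
    while pending:
        progressed = False
        rest = []
        for ind, alle in pending:
            if ind.is_founder or (
                ind.father_id in placed and ind.mother_id in placed
            ):
                ordered.append((ind, alle))
                placed.add(ind.id)
                progressed = True
            else:
                rest.append((ind, alle))
        if not progressed:
            raise ValueError(f"family {fam!r}: cyclic parentage")
        pending = rest
    return ordered
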