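"""Nonparametric allele-sharing statistics: S_pairs, NPL, and KC-LOD.

Per pedigree, the single-marker posterior over inheritance vectors gives
the expected pairwise IBD sharing among affected members, standardized by
the "perfect data" null moments (mean and SD of the score under the
uniform inheritance-vector prior).  Per-pedigree z scores are combined
with equal weights 1/sqrt(n) into the sample NPL, and enter the Kong-Cox
one-parameter linear likelihood whose maximized log10 ratio is the KC-LOD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .gene_drop import GenotypeTable, MarkerModel, _phased_tables
from .pedigree import InheritanceVector, Pedigree
from .likelihood import marker_vector

__all__ = [
    "SharingScore",
    "KcFit",
    "ibd_posterior",
    "s_pairs",
    "s_pairs_vector",
    "null_sharing_moments",
    "sharing_score",
    "npl_scores",
    "kc_lod",
    "kc_lod_from_z",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharingScore:
    """Per-pedigree sharing summary: E[S_pairs | data], null moments, z."""

    expected: float
    mean: float
    sd: float

    @property
    def z(self) -> float:
        return (self.expected - self.mean) / self.sd


@dataclass(frozen=True)
class KcFit:
    """Kong-Cox linear-model fit: sharing parameter and log10 score."""

    delta: float
    kc_lod: float


def ibd_posterior(
    ped: Pedigree, genotypes: GenotypeTable, marker: MarkerModel
) -> np.ndarray:
    """P(v | marker data) over all 2**m inheritance vectors.

    Uniform prior on v; raises on Mendelian-inconsistent genotypes.
    """
    A = marker_vector(ped, genotypes, marker)
    total = A.sum()
    if total <= 0:
        raise ValueError(
            f"family {ped.family_id!r}: Mendelian-inconsistent marker data"
        )
    return A / total


@lru_cache(maxsize=64)
def _s_pairs_vector_cached(members: tuple) -> np.ndarray:
    ped = Pedigree("_cache", members)
    fh, _, _ = _phased_tables(ped)
    aff = [ped.member_index(mid) for mid in ped.affected_ids]
    s = np.zeros(fh.shape[0])
    for a in range(len(aff)):
        for b in range(a + 1, len(aff)):
            fa, fb = fh[:, aff[a], :], fh[:, aff[b], :]
            s += (
                (fa[:, 0] == fb[:, 0]).astype(int)
                + (fa[:, 0] == fb[:, 1])
                + (fa[:, 1] == fb[:, 0])
                + (fa[:, 1] == fb[:, 1])
            )
    return s


def s_pairs_vector(ped: Pedigree) -> np.ndarray:
    """S_pairs for every inheritance vector: total IBD allele count over
    all unordered pairs of affected members (0, 1 or 2 per pair)."""
    if len(ped.affected_ids) < 2:
        raise ValueError("S_pairs needs at least two affected members")
    return _s_pairs_vector_cached(ped.members)


def s_pairs(ped: Pedigree, v: InheritanceVector | int) -> float:
    idx = v.index if isinstance(v, InheritanceVector) else int(v)
    return float(s_pairs_vector(ped)[idx])


def null_sharing_moments(ped: Pedigree) -> tuple[float, float]:
    """Mean and SD of S_pairs under the uniform inheritance-vector prior."""
    s = s_pairs_vector(ped)
    mu = float(s.mean())
    sd = float(s.std())
    if sd <= 0:
        raise ValueError("degenerate sharing distribution (sd = 0)")
    return mu, sd


def sharing_score(
    ped: Pedigree, genotypes: GenotypeTable, marker: MarkerModel
) -> SharingScore:
    q = ibd_posterior(ped, genotypes, marker)
    s = s_pairs_vector(ped)
    mu, sd = null_sharing_moments(ped)
    return SharingScore(float(q @ s), mu, sd)


def npl_scores(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    marker: MarkerModel = MarkerModel(),
) -> tuple[np.ndarray, float]:
    """Per-pedigree z scores and the combined NPL = sum(z_i) / sqrt(n).

    Pedigrees with fewer than two affected members carry no pairwise
    sharing information; they contribute z = 0 (with a logged warning) but
    still count toward n.
    """
    if not sample:
        raise ValueError("empty sample")
    zs = []
    for ped, gt in sample:
        if len(ped.affected_ids) < 2:
            logger.warning(
                "family %r has <2 affected members; scored as z=0", ped.family_id
            )
            zs.append(0.0)
        else:
            zs.append(sharing_score(ped, gt, marker).z)
    z = np.asarray(zs)
    return z, float(z.sum() / math.sqrt(len(z)))


def structural_min_z(ped: Pedigree) -> float:
    """Smallest achievable per-pedigree z (most negative sharing)."""
    s = s_pairs_vector(ped)
    mu, sd = null_sharing_moments(ped)
    return float((s.min() - mu) / sd)


def kc_lod_from_z(
    z: np.ndarray,
    min_z: Optional[np.ndarray] = None,
    xatol: float = 1e-8,
) -> KcFit:
    """Maximize the Kong-Cox linear likelihood ratio over delta >= 0.

    Score: sum_i log10(1 + delta * gamma_i * z_i) with equal weights
    gamma_i = 1/sqrt(n).  The upper bound on delta keeps every observed
    term positive; when no observed z is negative, the bound from the
    smallest achievable z per pedigree (``min_z``) is used instead.  The
    objective is concave in delta, so a nonpositive derivative at 0
    (i.e. sum(z) <= 0) pins the maximum at delta = 0.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("empty z vector")
    gamma = 1.0 / math.sqrt(n)
    if z.sum() <= 0.0:
        return KcFit(0.0, 0.0)
    neg = z[z < 0]
    if neg.size:
        dmax = float(np.min(-1.0 / (gamma * neg)))
    else:
        if min_z is None:
            raise ValueError(
                "all z nonnegative: need min_z to bound delta"
            )
        mz = np.asarray(min_z, dtype=float)
        dmax = float(np.min(-1.0 / (gamma * mz)))
    dmax *= 1.0 - 1e-12

    def neg_score(d: float) -> float:
        return -np.log10(1.0 + d * gamma * z).sum()

    res = minimize_scalar(
        neg_score, bounds=(0.0, dmax), method="bounded",
        options={"xatol": xatol},
    )
    best = max(0.0, -float(res.fun))
    delta = float(res.x) if best > 0 else 0.0
    return KcFit(delta, best)


def kc_lod(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    marker: MarkerModel = MarkerModel(),
) -> KcFit:
    """Kong-Cox LOD for a sample, from its per-pedigree NPL z scores."""
    z, _ = npl_scores(sample, marker)
    min_z = np.array(
        [structural_min_z(ped) for ped, _ in sample if len(ped.affected_ids) >= 2]
    )
    return kc_lod_from_z(z, min_z=min_z if min_z.size else None)
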