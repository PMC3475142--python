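"""Two-point pedigree likelihood for one marker and one trait locus.

Two independent engines compute ``P(marker genotypes, affection pattern |
trait model, marker model, theta)``:

* an inheritance-vector factorization,
      L(theta) = sum_{v_m, v_t} P(M | v_m) * P(Phi | v_t) * P(v_m, v_t; theta),
  where the meiosis-wise coupling ``P(v_m, v_t; theta)`` is applied as a
  sequence of per-bit 2x2 transition maps (all terms nonnegative, so no
  cancellation), and

* a genotype-elimination (Elston-Stewart) peeling over joint ordered
  two-locus genotypes, which scales to pedigrees whose meiosis count makes
  dense vector enumeration infeasible.

Both engines are exact; their agreement is part of the test suite.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .gene_drop import GenotypeTable, MarkerModel, _penetrance_weights, _phased_tables
from .pedigree import Pedigree
from .trait_models import TraitModel

__all__ = [
    "marker_vector",
    "trait_vector",
    "loglik_iv",
    "loglik_peeling",
    "fwht",
    "popcounts",
]

LOG_FLOOR = 1e-300  # probabilities below this are clamped in log-domain


def popcounts(n: int) -> np.ndarray:
    """Bit counts of 0..n-1 (n a power of two)."""
    v = np.arange(n, dtype=np.uint32)
    pc = np.zeros(n, dtype=np.int8)
    while v.any():
        pc += (v & 1).astype(np.int8)
        v >>= 1
    return pc


def fwht(x: np.ndarray) -> np.ndarray:
    """Walsh-Hadamard transform (Sylvester order) along the last axis."""
    y = np.array(x, dtype=float, copy=True)
    n = y.shape[-1]
    h = 1
    while h < n:
        y = y.reshape(y.shape[:-1] + (n // (2 * h), 2, h))
        a = y[..., 0, :] + y[..., 1, :]
        b = y[..., 0, :] - y[..., 1, :]
        y = np.stack([a, b], axis=-2).reshape(y.shape[:-3] + (n,))
        h *= 2
    return y


def _aligned_alleles(ped: Pedigree, genotypes: GenotypeTable) -> np.ndarray:
    order = [genotypes.member_ids.index(mid) for mid in ped.member_ids]
    alle = genotypes.alleles[order]
    if np.any(alle <= 0):
        raise ValueError("likelihood requires fully genotyped members")
    return alle


def marker_vector(
    ped: Pedigree, genotypes: GenotypeTable, marker: MarkerModel
) -> np.ndarray:
    """Unnormalized P(marker data | v) for every inheritance vector.

    Sums over the phase of each heterozygous member; each consistent phase
    assignment contributes the product of the allele frequencies of the
    founder haplotypes it pins down (unconstrained founder haplotypes are
    marginalized out).
    """
    fh, _, _ = _phased_tables(ped)
    nv = fh.shape[0]
    nhap = 2 * len(ped.founders)
    freqs = marker.frequencies
    alle = _aligned_alleles(ped, genotypes)
    het = np.where(alle[:, 0] != alle[:, 1])[0]
    A = np.zeros(nv)
    rows = np.arange(nv)
    for phase in range(1 << len(het)):
        slot = alle.copy()
        for b, i in enumerate(het):
            if (phase >> b) & 1:
                slot[i] = slot[i, ::-1]
        reg = np.full((nv, nhap), -1, dtype=np.int16)
        ok = np.ones(nv, dtype=bool)
        for i in range(ped.n_members):
            for s in (0, 1):
                f = fh[:, i, s]
                a = int(slot[i, s])
                cur = reg[rows, f]
                fresh = cur < 0
                ok &= fresh | (cur == a)
                reg[rows[fresh], f[fresh]] = a
        assigned = reg >= 0
        w = np.prod(
            np.where(assigned, freqs[np.clip(reg - 1, 0, None)], 1.0), axis=1
        )
        A += ok * w
    return A


def trait_vector(ped: Pedigree, model: TraitModel) -> np.ndarray:
    """Unnormalized P(affection pattern | v) for every inheritance vector,
    summing over founder-haplotype disease indicators with HWE priors."""
    _, abits, counts = _phased_tables(ped)
    nhap = abits.shape[1]
    k = abits.sum(axis=1)
    prior = model.p**k * (1.0 - model.p) ** (nhap - k)
    penw = _penetrance_weights(ped, model)
    like = np.ones(counts.shape[:2])
    for i in range(ped.n_members):
        like *= penw[i, counts[:, :, i]]
    return prior @ like


def _theta_transform(b: np.ndarray, theta: float) -> np.ndarray:
    """Apply the meiosis-wise recombination coupling to a vector over
    inheritance vectors: one [[1-t, t], [t, 1-t]] map per bit."""
    y = np.array(b, dtype=float, copy=True)
    n = y.size
    h = 1
    while h < n:
        y = y.reshape(n // (2 * h), 2, h)
        a0 = (1.0 - theta) * y[:, 0, :] + theta * y[:, 1, :]
        a1 = theta * y[:, 0, :] + (1.0 - theta) * y[:, 1, :]
        y = np.stack([a0, a1], axis=1).reshape(n)
        h *= 2
    return y


def loglik_iv(
    ped: Pedigree,
    genotypes: GenotypeTable,
    model: TraitModel,
    marker: MarkerModel,
    theta: float,
) -> float:
    """Natural-log two-point likelihood via inheritance-vector enumeration.

    Mendelian-inconsistent marker data yields ``-inf``.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    A = marker_vector(ped, genotypes, marker)
    if A.sum() == 0.0:
        return -math.inf
    B = trait_vector(ped, model)
    m = ped.n_meioses
    L = float(A @ _theta_transform(B, theta)) / (1 << m)
    return math.log(max(L, LOG_FLOOR))


# ---------------------------------------------------------------------------
# Elston-Stewart peeling over joint two-locus ordered genotypes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _state_space(n_alleles: int):
    """Index grids for ordered joint genotypes (mp, mm, tp, tm)."""
    K = n_alleles
    mp, mm, tp, tm = np.meshgrid(
        np.arange(K), np.arange(K), np.arange(2), np.arange(2), indexing="ij"
    )
    return mp.ravel(), mm.ravel(), tp.ravel(), tm.ravel()


@lru_cache(maxsize=32)
def _gamete_matrix(n_alleles: int, theta: float) -> np.ndarray:
    """P(gamete (marker allele, trait allele) | parent state), shape (S, 2K)."""
    K = n_alleles
    mp, mm, tp, tm = _state_space(K)
    S = mp.size
    F = np.zeros((S, 2 * K))
    half = 0.5
    for ma, ta, pr in (
        (mp, tp, half * (1 - theta)),
        (mm, tm, half * (1 - theta)),
        (mp, tm, half * theta),
        (mm, tp, half * theta),
    ):
        np.add.at(F, (np.arange(S), ma * 2 + ta), pr)
    return F


@lru_cache(maxsize=32)
def _child_state_index(n_alleles: int) -> np.ndarray:
    """Child state index from (father gamete, mother gamete), shape (2K, 2K)."""
    K = n_alleles
    gf = np.arange(2 * K)
    gm = np.arange(2 * K)
    fm, ft = gf[:, None] // 2, gf[:, None] % 2
    mm_, mt = gm[None, :] // 2, gm[None, :] % 2
    return ((fm * K + mm_) * 2 + ft) * 2 + mt


def loglik_peeling(
    ped: Pedigree,
    genotypes: GenotypeTable,
    model: TraitModel,
    marker: MarkerModel,
    theta: float,
) -> float:
    """Natural-log two-point likelihood by genotype-elimination peeling.

    Handles tree pedigrees in which every individual parents at most one
    sibship and every married-in spouse is a founder (true for all study
    structures).  Exact for any theta in [0, 0.5].
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    K = marker.n_alleles
    freqs = marker.frequencies
    mp, mm, tp, tm = _state_space(K)
    alle = _aligned_alleles(ped, genotypes)
    penw = _penetrance_weights(ped, model)
    p, q = model.p, 1.0 - model.p

    idx = {mid: i for i, mid in enumerate(ped.member_ids)}

    def node_factor(mid: str) -> np.ndarray:
        """Observation x penetrance factor over states for one member."""
        i = idx[mid]
        a1, a2 = sorted(alle[i])
        lo = np.minimum(mp, mm) + 1
        hi = np.maximum(mp, mm) + 1
        obs = (lo == a1) & (hi == a2)
        return obs * penw[i, tp + tm]

    def founder_prior() -> np.ndarray:
        happ = np.where(tp == 1, p, q) * np.where(tm == 1, p, q)
        return freqs[mp] * freqs[mm] * happ

    couples: dict[tuple[str, str], list[str]] = {}
    for ind in ped.nonfounders:
        couples.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
    child_in = {c for kids in couples.values() for c in kids}
    parent_of: dict[str, tuple[str, str]] = {}
    for fa_mo in couples:
        for pid in fa_mo:
            if pid in parent_of:
                raise ValueError("peeling supports one sibship per parent")
            parent_of[pid] = fa_mo

    F = _gamete_matrix(K, float(theta))
    cidx = _child_state_index(K)
    prior = founder_prior()

    def descendant_factor(mid: str) -> np.ndarray:
        """Likelihood of everything below ``mid`` given its state."""
        if mid not in parent_of:
            return np.ones(mp.size)
        fa, mo = parent_of[mid]
        spouse = mo if mid == fa else fa
        if spouse in child_in:
            raise ValueError("peeling requires married-in spouses to be founders")
        cf = couple_factor(fa, mo)  # [S_father, S_mother]
        sp_term = prior * node_factor(spouse)
        if mid == fa:
            return cf @ sp_term
        return cf.T @ sp_term

    def couple_factor(fa: str, mo: str) -> np.ndarray:
        out = np.ones((mp.size, mp.size))
        for c in couples[(fa, mo)]:
            w = node_factor(c) * descendant_factor(c)
            wmat = w[cidx]
            out *= F @ wmat @ F.T
        return out

    roots = [cp for cp in couples if cp[0] not in child_in and cp[1] not in child_in]
    if len(roots) != 1:
        raise ValueError("peeling expects a single founder couple at the top")
    fa, mo = roots[0]
    cf = couple_factor(fa, mo)
    vf = prior * node_factor(fa)
    vm = prior * node_factor(mo)
    L = float(vf @ cf @ vm)
    if L <= 0.0:
        return -math.inf if L == 0.0 else math.log(LOG_FLOOR)
    return math.log(max(L, LOG_FLOOR))
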