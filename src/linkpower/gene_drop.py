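"""Marker-data simulation conditional on the affection pattern.

Under the null hypothesis the marker segregates independently of the trait:
founder alleles are drawn i.i.d. from the marker allele frequencies and
dropped through the pedigree along a uniformly random inheritance vector.

Under the alternative of complete linkage (recombination fraction 0) the
marker rides the trait haplotypes: a phased trait-locus configuration —
founder-haplotype disease indicators plus an inheritance vector — is drawn
from its exact posterior given the pedigree's affection pattern, and marker
alleles are transmitted along exactly the same meiotic paths.  The
posterior is computed by full enumeration over founder-haplotype indicator
patterns and inheritance vectors, which is exact and avoids the vanishing
acceptance rates a rejection sampler would face for multi-sib affection
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, Pedigree, SampleSpec, build_structure
from .trait_models import TraitModel

__all__ = [
    "MarkerModel",
    "GenotypeTable",
    "TraitGenotypePosterior",
    "conditional_trait_posterior",
    "simulate_marker_h0",
    "simulate_marker_h1",
    "simulate_replicate",
]

_ENUMERATION_CAP = 12  # members; beyond this the exact posterior is refused


@dataclass(frozen=True)
class MarkerModel:
    """A single codominant marker with ``n_alleles`` alleles."""

    n_alleles: int = 8
    freqs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError("need at least 2 marker alleles")
        if self.freqs is not None:
            if len(self.freqs) != self.n_alleles:
                raise ValueError("freqs length must equal n_alleles")
            if any(f <= 0 for f in self.freqs) or abs(sum(self.freqs) - 1) > 1e-9:
                raise ValueError("freqs must be positive and sum to 1")

    @property
    def frequencies(self) -> np.ndarray:
        if self.freqs is None:
            return np.full(self.n_alleles, 1.0 / self.n_alleles)
        return np.asarray(self.freqs, dtype=float)

    @property
    def is_equifrequent(self) -> bool:
        return self.freqs is None or np.allclose(
            self.freqs, 1.0 / self.n_alleles
        )


@dataclass
class GenotypeTable:
    """Ordered marker genotypes, one ``(paternal, maternal)`` pair per member.

    Alleles are 1-based; 0 encodes missing (supported on file input only,
    simulated data is always complete).
    """

    member_ids: tuple[str, ...]
    alleles: np.ndarray  # shape (n_members, 2), int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        if self.alleles.shape != (len(self.member_ids), 2):
            raise ValueError("alleles must have shape (n_members, 2)")

    def pair(self, member_id: str) -> tuple[int, int]:
        i = self.member_ids.index(member_id)
        return (int(self.alleles[i, 0]), int(self.alleles[i, 1]))

    @property
    def fully_genotyped(self) -> bool:
        return bool(np.all(self.alleles > 0))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.member_ids == other.member_ids
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(frozen=True)
class TraitGenotypePosterior:
    """Exact posterior over per-member disease-allele counts given phenotypes.

    ``support[k]`` is a tuple with one entry in {0, 1, 2} per member (in
    pedigree member order); ``probs[k]`` its posterior probability.
    """

    member_ids: tuple[str, ...]
    support: tuple[tuple[int, ...], ...]
    probs: np.ndarray

    def prob_of(self, counts: tuple[int, ...]) -> float:
        try:
            return float(self.probs[self.support.index(counts)])
        except ValueError:
            return 0.0


# ---------------------------------------------------------------------------
# exact phased trait-locus tables
# ---------------------------------------------------------------------------

def _phased_tables(ped: Pedigree):
    """Founder-haplotype map and per-configuration disease-allele counts.

    Returns ``(fh, abits, counts)`` with ``fh`` the (2**m, n, 2)
    founder-haplotype origin map and ``counts`` the (2**nhap, 2**m, n) array
    of disease-allele counts per member for every founder-indicator pattern
    ``a`` and inheritance vector ``v``.  Cached on the member tuple so that
    replicates of the same structure share tables.
    """
    return _phased_tables_cached(ped.members)


@lru_cache(maxsize=64)
def _phased_tables_cached(members: tuple):
    ped = Pedigree("_cache", members)
    fh = ped.founder_hap_map()
    nhap = 2 * len(ped.founders)
    na = 1 << nhap
    abits = ((np.arange(na)[:, None] >> np.arange(nhap)[None, :]) & 1).astype(
        np.int8
    )
    counts = abits[:, fh[:, :, 0]] + abits[:, fh[:, :, 1]]
    return fh, abits, counts


def _penetrance_weights(ped: Pedigree, model: TraitModel) -> np.ndarray:
    """(n_members, 3) phenotype likelihood per disease-allele count."""
    f = np.asarray(model.penetrances)
    w = np.ones((ped.n_members, 3))
    for i, ind in enumerate(ped.members):
        if ind.affection == AFFECTED:
            w[i] = f
        elif ind.affection == UNAFFECTED:
            w[i] = 1.0 - f
    return w


def _joint_posterior(ped: Pedigree, model: TraitModel) -> np.ndarray:
    """Posterior P(a, v | affection pattern) over founder-indicator patterns
    ``a`` and inheritance vectors ``v`` (uniform prior on ``v``)."""
    return _joint_posterior_cached(ped.members, model)


@lru_cache(maxsize=128)
def _joint_posterior_cached(members: tuple, model: TraitModel) -> np.ndarray:
    ped = Pedigree("_cache", members)
    if ped.n_members > _ENUMERATION_CAP:
        raise ValueError(
            f"pedigree has {ped.n_members} members; exact enumeration is "
            f"capped at {_ENUMERATION_CAP}"
        )
    _, abits, counts = _phased_tables(ped)
    nhap = abits.shape[1]
    k = abits.sum(axis=1)
    hap_prior = model.p**k * (1.0 - model.p) ** (nhap - k)  # [na]
    penw = _penetrance_weights(ped, model)
    like = np.ones(counts.shape[:2])
    for i in range(ped.n_members):
        like *= penw[i, counts[:, :, i]]
    joint = hap_prior[:, None] * like
    total = joint.sum()
    if total <= 0:
        raise ValueError("affection pattern has probability zero under model")
    return joint / total


def conditional_trait_posterior(
    ped: Pedigree, model: TraitModel
) -> TraitGenotypePosterior:
    """Exact posterior of per-member trait genotypes given the phenotypes.

    Members with unknown affection contribute a flat phenotype factor, so
    with a constant penetrance the posterior reduces to the unconditional
    Mendelian/Hardy-Weinberg distribution.
    """
    joint = _joint_posterior(ped, model)
    _, _, counts = _phased_tables(ped)
    flat_counts = counts.reshape(-1, ped.n_members)
    flat_probs = joint.reshape(-1)
    agg: dict[tuple[int, ...], float] = {}
    for cvec, pr in zip(map(tuple, flat_counts.tolist()), flat_probs):
        if pr > 0:
            agg[cvec] = agg.get(cvec, 0.0) + float(pr)
    support = tuple(sorted(agg))
    probs = np.array([agg[s] for s in support])
    return TraitGenotypePosterior(ped.member_ids, support, probs)


def sample_phased_trait_configs(
    ped: Pedigree, model: TraitModel, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` (founder-indicator pattern, inheritance vector) pairs
    from the exact conditional posterior."""
    joint = _joint_posterior(ped, model)
    na, nv = joint.shape
    flat = rng.choice(na * nv, size=size, p=joint.reshape(-1))
    return flat // nv, flat % nv


# ---------------------------------------------------------------------------
# marker simulation
# ---------------------------------------------------------------------------

def _drop_marker(
    ped: Pedigree,
    v: np.ndarray,
    marker: MarkerModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign i.i.d. marker alleles to founder haplotypes and transmit them
    along inheritance vector(s) ``v``.  Returns (len(v), n_members, 2)."""
    fh, _, _ = _phased_tables(ped)
    nhap = 2 * len(ped.founders)
    falleles = rng.choice(
        marker.n_alleles, size=(len(v), nhap), p=marker.frequencies
    ).astype(np.int16) + 1
    return falleles[np.arange(len(v))[:, None, None], fh[v]]


def simulate_marker_h0(
    ped: Pedigree, marker: MarkerModel, rng: np.random.Generator
) -> GenotypeTable:
    """Gene-drop one marker with segregation independent of the trait."""
    v = rng.integers(0, 1 << ped.n_meioses, size=1)
    geno = _drop_marker(ped, v, marker, rng)[0]
    return GenotypeTable(ped.member_ids, geno)


def simulate_marker_h1(
    ped: Pedigree,
    model: TraitModel,
    marker: MarkerModel,
    rng: np.random.Generator,
    _return_detail: bool = False,
):
    """Simulate the marker under complete linkage with the trait locus.

    The inheritance vector is drawn jointly with the founder disease
    indicators from the conditional posterior given the affection pattern;
    the marker alleles then follow exactly the same meiotic paths
    (recombination fraction 0).
    """
    a, v = sample_phased_trait_configs(ped, model, rng, 1)
    geno = _drop_marker(ped, v, marker, rng)[0]
    gt = GenotypeTable(ped.member_ids, geno)
    if _return_detail:
        return gt, int(v[0]), int(a[0])
    return gt


def simulate_replicate(
    spec: SampleSpec,
    hypothesis: str,
    model: Optional[TraitModel],
    marker: MarkerModel,
    rng: np.random.Generator,
) -> list[tuple[Pedigree, GenotypeTable]]:
    """One sample of pedigrees with genotypes per the sample spec."""
    if hypothesis not in ("H0", "H1"):
        raise ValueError("hypothesis must be 'H0' or 'H1'")
    if hypothesis == "H1" and model is None:
        raise ValueError("H1 simulation requires a trait model")
    out: list[tuple[Pedigree, GenotypeTable]] = []
    fam = 1
    for code, count in spec.parts:
        base = build_structure(code)
        for _ in range(count):
            ped = replace(base, family_id=f"{code}_{fam}")
            if hypothesis == "H0":
                gt = simulate_marker_h0(ped, marker, rng)
            else:
                gt = simulate_marker_h1(ped, model, marker, rng)
            out.append((ped, gt))
            fam += 1
    return out
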