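"""Parametric two-point linkage statistics: LOD and MOD scores.

The sample LOD at recombination fraction theta is the sum over pedigrees
of log10 L(theta)/L(1/2); the LOD statistic maximizes it over a fixed
theta grid (0 to 0.48 in steps of 0.02, ties resolved toward smaller
theta).  The MOD score additionally maximizes over trait-model parameters
(penetrances and disease allele frequency) on a grid, one shared model for
the whole sample, with optional local coordinate refinement.

Per pedigree the likelihood ratio has the closed form

    LR(theta) = sum_S qhat_S * rhat_S * (1 - 2 theta)^{|S|}

over subsets S of meioses, where qhat / rhat are Walsh-Hadamard transforms
of the marker-side inheritance-vector posterior and the trait-side
phenotype-likelihood distribution.  This makes the whole theta curve a
polynomial in (1 - 2 theta) with m+1 coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .gene_drop import GenotypeTable, MarkerModel, _penetrance_weights, _phased_tables
from .likelihood import (
    LOG_FLOOR,
    fwht,
    loglik_iv,
    loglik_peeling,
    marker_vector,
    popcounts,
)
from .pedigree import Pedigree
from .trait_models import TraitModel, analysis_model

__all__ = [
    "ThetaGrid",
    "ModGrid",
    "ModResult",
    "DEFAULT_THETA_GRID",
    "default_mod_grid",
    "loglik",
    "lod_curve",
    "max_lod",
    "mod_score",
]

_IV_MEIOSIS_CAP = 12  # beyond this, loglik falls back to peeling


@dataclass(frozen=True)
class ThetaGrid:
    """Recombination-fraction grid for LOD maximization."""

    values: tuple[float, ...] = tuple(round(0.02 * i, 2) for i in range(25))

    def __post_init__(self) -> None:
        if any(not 0.0 <= t <= 0.5 for t in self.values):
            raise ValueError("theta values must lie in [0, 0.5]")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)


DEFAULT_THETA_GRID = ThetaGrid()

_PENETRANCE_LEVELS = (0.0, 0.003, 0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)
_P_LEVELS = (0.01, 0.05, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ModGrid:
    """Trait-model grid for MOD maximization.

    The default crosses 8 disease-allele frequencies with all ordered
    penetrance triples from a 9-level set (f0 <= f1 <= f2, excluding flat
    triples whose LOD is identically zero), and contains the parameter
    points of all three analysis models.
    """

    models: tuple[TraitModel, ...] = field(
        default_factory=lambda: _default_grid_models()
    )

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("empty model grid")


def _default_grid_models() -> tuple[TraitModel, ...]:
    out = []
    for p in _P_LEVELS:
        for i, f0 in enumerate(_PENETRANCE_LEVELS):
            for j, f1 in enumerate(_PENETRANCE_LEVELS[i:], start=i):
                for f2 in _PENETRANCE_LEVELS[j:]:
                    if f0 < f2:
                        out.append(TraitModel(f0, f1, f2, p))
    return tuple(out)


@lru_cache(maxsize=2)
def default_mod_grid() -> ModGrid:
    return ModGrid()


@dataclass(frozen=True)
class ModResult:
    score: float
    model: TraitModel
    theta: float


# ---------------------------------------------------------------------------
# likelihood wrappers
# ---------------------------------------------------------------------------

def loglik(
    ped: Pedigree,
    genotypes: GenotypeTable,
    model: TraitModel,
    marker: MarkerModel,
    theta: float,
    engine: str = "auto",
) -> float:
    """Natural-log P(marker data, affection pattern | model, marker, theta).

    ``engine`` selects the inheritance-vector path ("iv"), genotype
    elimination peeling ("peeling"), or a meiosis-count based choice
    ("auto": IV up to 12 meioses).
    """
    if engine == "auto":
        engine = "iv" if ped.n_meioses <= _IV_MEIOSIS_CAP else "peeling"
    if engine == "iv":
        return loglik_iv(ped, genotypes, model, marker, theta)
    if engine == "peeling":
        return loglik_peeling(ped, genotypes, model, marker, theta)
    raise ValueError(f"unknown engine {engine!r}")


def trait_vectors_batch(
    ped: Pedigree, models: Sequence[TraitModel]
) -> np.ndarray:
    """P(affection pattern | v), unnormalized, for a batch of trait models.

    Returns shape (n_models, 2**m).
    """
    _, abits, counts = _phased_tables(ped)
    nhap = abits.shape[1]
    k = abits.sum(axis=1)
    p = np.array([mo.p for mo in models])[:, None]
    prior = p**k[None, :] * (1.0 - p) ** (nhap - k)[None, :]
    f = np.array([mo.penetrances for mo in models])  # [nmod, 3]
    like = np.ones((len(models),) + counts.shape[:2])
    for i, ind in enumerate(ped.members):
        if ind.affection == "affected":
            pw = f
        elif ind.affection == "unaffected":
            pw = 1.0 - f
        else:
            continue
        like *= pw[:, counts[:, :, i]]
    return np.einsum("ma,mav->mv", prior, like)


@lru_cache(maxsize=32)
def _rhat_for_models(members: tuple, models: tuple) -> np.ndarray:
    """Normalized, Walsh-Hadamard-transformed trait vectors, (nmod, 2**m)."""
    ped = Pedigree("_cache", members)
    B = trait_vectors_batch(ped, models)
    r = B / B.sum(axis=1, keepdims=True)
    return fwht(r)


def _qhat(ped: Pedigree, gt: GenotypeTable, marker: MarkerModel) -> np.ndarray:
    A = marker_vector(ped, gt, marker)
    total = A.sum()
    if total <= 0:
        raise ValueError(
            f"family {ped.family_id!r}: Mendelian-inconsistent marker data"
        )
    return fwht(A / total)


def _sample_lod_curves(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    models: tuple[TraitModel, ...],
    marker: MarkerModel,
    theta_grid: ThetaGrid,
) -> np.ndarray:
    """Sample log10-LR curves, shape (n_models, n_theta)."""
    thetas = theta_grid.array
    total = None
    for ped, gt in sample:
        m = ped.n_meioses
        pc = popcounts(1 << m)
        tpow = (1.0 - 2.0 * thetas)[None, :] ** np.arange(m + 1)[:, None]
        rhat = _rhat_for_models(ped.members, models)
        qh = _qhat(ped, gt, marker)
        ck = np.zeros((len(models), m + 1))
        for k in range(m + 1):
            cols = pc == k
            ck[:, k] = rhat[:, cols] @ qh[cols]
        lr = ck @ tpow  # [nmod, ntheta]
        contrib = np.log10(np.clip(lr, LOG_FLOOR, None))
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("empty sample")
    return total


def lod_curve(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    model: TraitModel,
    marker: MarkerModel = MarkerModel(),
    theta_grid: ThetaGrid = DEFAULT_THETA_GRID,
) -> np.ndarray:
    """Per-theta sample LOD: sum over pedigrees of log10 L(theta)/L(0.5)."""
    return _sample_lod_curves(sample, (model,), marker, theta_grid)[0]


def max_lod(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    model: TraitModel,
    theta_grid: ThetaGrid = DEFAULT_THETA_GRID,
    marker: MarkerModel = MarkerModel(),
) -> float:
    """Maximum of the sample LOD over the theta grid (first max wins,
    i.e. ties break toward smaller theta)."""
    return float(lod_curve(sample, model, marker, theta_grid).max())


def mod_score(
    sample: Sequence[tuple[Pedigree, GenotypeTable]],
    grid: Optional[ModGrid] = None,
    theta_grid: ThetaGrid = DEFAULT_THETA_GRID,
    refine: bool = False,
    marker: MarkerModel = MarkerModel(),
) -> ModResult:
    """MOD score: max-LOD additionally maximized over trait-model space.

    One shared trait model is fitted for the whole sample.  With
    ``refine`` a coordinate search with step halving polishes the best
    grid point (termination when score gains fall below 1e-3).
    """
    grid = grid or default_mod_grid()
    curves = _sample_lod_curves(sample, grid.models, marker, theta_grid)
    flat = int(np.argmax(curves))
    imod, ith = divmod(flat, curves.shape[1])
    best = ModResult(
        float(curves[imod, ith]), grid.models[imod], float(theta_grid.values[ith])
    )
    if refine:
        best = _refine(sample, best, marker, theta_grid)
    return best


def _refine(
    sample,
    start: ModResult,
    marker: MarkerModel,
    theta_grid: ThetaGrid,
    tol: float = 1e-3,
) -> ModResult:
    def evaluate(params) -> Optional[ModResult]:
        f0, f1, f2, p = params
        if not (0.0 <= f0 <= f1 <= f2 <= 1.0 and f0 < f2 and 0.0 < p < 1.0):
            return None
        model = TraitModel(f0, f1, f2, p)
        curve = _sample_lod_curves(sample, (model,), marker, theta_grid)[0]
        i = int(np.argmax(curve))
        return ModResult(float(curve[i]), model, float(theta_grid.values[i]))

    best = start
    step = 0.05
    while step >= tol / 2:
        improved = False
        for axis in range(4):
            for sign in (+1, -1):
                params = [best.model.f0, best.model.f1, best.model.f2, best.model.p]
                params[axis] += sign * step
                cand = evaluate(params)
                if cand is not None and cand.score > best.score + tol:
                    best = cand
                    improved = True
        if not improved:
            step /= 2.0
    return best
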