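"""Trait-model parameterization.

A trait model is a penetrance triple ``(f0, f1, f2)`` — the probability of
being affected given 0, 1 or 2 copies of the disease allele — plus the
disease allele frequency ``p``.  The same type serves two roles: the mode
of inheritance used to *simulate* data (MOI) and the mode assumed when
*analyzing* it parametrically (AMOI).  The two sets of parameters are
deliberately different, reflecting the practical situation that the true
trait model of a complex disease is unknown at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TraitModel",
    "MOI_NAMES",
    "simulation_model",
    "analysis_model",
    "prevalence",
]

MOI_NAMES = ("dominant", "additive", "recessive")


@dataclass(frozen=True)
class TraitModel:
    f0: float
    f1: float
    f2: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f0 <= self.f1 <= self.f2 <= 1.0):
            raise ValueError("penetrances must satisfy 0 <= f0 <= f1 <= f2 <= 1")
        if not (0.0 < self.p < 1.0):
            raise ValueError("disease allele frequency must be in (0, 1)")

    @property
    def penetrances(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


# Generating models: moderate genotype relative risks, phenocopies (f0 > 0)
# and strongly reduced penetrance, calibrated for ~80% power with 500 ASPs.
_SIMULATION_MODELS = {
    "dominant": TraitModel(0.04, 0.20, 0.20, 0.05),
    "additive": TraitModel(0.03, 0.13, 0.23, 0.10),
    "recessive": TraitModel(0.04, 0.04, 0.20, 0.20),
}

# Analysis models: near-zero phenocopy rate, 50% top penetrance, and a high
# disease allele frequency (p = 0.25) that buffers penetrance misspecification.
_ANALYSIS_MODELS = {
    "dominant": TraitModel(0.003, 0.50, 0.50, 0.25),
    "additive": TraitModel(0.003, 0.25, 0.50, 0.25),
    "recessive": TraitModel(0.003, 0.05, 0.50, 0.25),
}


def _lookup(table: dict[str, TraitModel], name: str, kind: str) -> TraitModel:
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown {kind} {name!r}; valid: {tuple(table)}"
        ) from None


def simulation_model(moi: str) -> TraitModel:
    """Generating trait model (MOI) for H1 simulation."""
    return _lookup(_SIMULATION_MODELS, moi, "MOI")


def analysis_model(amoi: str) -> TraitModel:
    """Assumed trait model (AMOI) for parametric LOD analysis."""
    return _lookup(_ANALYSIS_MODELS, amoi, "AMOI")


def prevalence(model: TraitModel) -> float:
    """Population disease prevalence K under Hardy-Weinberg equilibrium."""
    p, q = model.p, 1.0 - model.p
    return p * p * model.f2 + 2.0 * p * q * model.f1 + q * q * model.f0
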