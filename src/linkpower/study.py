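"""Replicate studies: null distributions, critical values, and power.

Power is estimated as P(Z) = #{replicates with T >= Z} / N for a statistic
T and critical value Z.  Critical values come from the asymptotic null
distributions (standard normal for the NPL; z_alpha^2 / (2 ln 10) for
KC-LOD and LOD, the inversion of the half-chi-square-1 / half-point-mass
law of 2 ln(10) LOD), from empirical H0 quantiles, or — for the MOD score,
whose null distribution depends on pedigree structure — from published
simulation-based constants (ASP 3.61, DST 4.20, DSQ 4.36, mixture 4.01 at
the significant level), with empirical re-estimation available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.stats import norm

from .engine import get_engine
from .pedigree import MIXTURE_SPEC, SampleSpec
from .trait_models import simulation_model
from .allele_sharing import kc_lod_from_z

__all__ = [
    "ALPHA_SUGGESTIVE",
    "ALPHA_LOD3",
    "ALPHA_SIGNIFICANT",
    "MOD_SIGNIFICANT_THRESHOLDS",
    "NullDistribution",
    "PowerResult",
    "StudyConfig",
    "asymptotic_threshold",
    "empirical_critical_value",
    "power",
    "run_replicates",
    "run_null_study",
    "run_power_study",
]

#: Genome-wide pointwise significance levels (Lander-Kruglyak), plus the
#: classical LOD-3 criterion.
ALPHA_SUGGESTIVE = 0.0017
ALPHA_LOD3 = 0.0001
ALPHA_SIGNIFICANT = 0.000049
DEFAULT_ALPHAS = (ALPHA_SUGGESTIVE, ALPHA_LOD3, ALPHA_SIGNIFICANT)

#: Simulation-based MOD critical values at the significant level, from a
#: 10^6-replicate reference study (re-estimation by run_null_study is
#: available at reduced precision).
MOD_SIGNIFICANT_THRESHOLDS = {"ASP": 3.61, "DST": 4.20, "DSQ": 4.36, "MIX": 4.01}

_LOD_STATS = ("LOD_dominant", "LOD_additive", "LOD_recessive")
_ALL_STATS = ("NPL", "KC-LOD") + _LOD_STATS + ("MOD",)


def _expand_stats(statistics: Sequence[str]) -> tuple[str, ...]:
    out: list[str] = []
    alias = {s.lower(): s for s in _ALL_STATS}
    alias.update({"kclod": "KC-LOD", "kc-lod": "KC-LOD"})
    for s in statistics:
        low = s.lower()
        if low == "lod":
            out.extend(_LOD_STATS)
        elif low in alias:
            out.append(alias[low])
        elif low.startswith("lod_"):
            name = "LOD_" + low[4:]
            if name not in _LOD_STATS:
                raise ValueError(f"unknown statistic {s!r}")
            out.append(name)
        else:
            raise ValueError(f"unknown statistic {s!r}; valid: {_ALL_STATS}")
    return tuple(dict.fromkeys(out))


# ---------------------------------------------------------------------------
# thresholds and power
# ---------------------------------------------------------------------------

def asymptotic_threshold(stat: str, alpha: float) -> float:
    """Critical value from the asymptotic null distribution.

    NPL: upper-alpha standard normal quantile.  KC-LOD and LOD:
    z_alpha^2 / (2 ln 10), the upper tail of the half-chi-square(1)
    (plus half point mass at zero) law on the log10 scale.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    z = float(norm.isf(alpha))
    name = _expand_stats([stat])[0] if stat.lower() != "mod" else "MOD"
    if name == "NPL":
        return z
    if name == "KC-LOD" or name.startswith("LOD"):
        return z * z / (2.0 * math.log(10.0))
    raise ValueError(
        "the MOD null distribution depends on pedigree structure; use "
        "empirical critical values or the published constants"
    )


def empirical_critical_value(scores: Sequence[float], alpha: float) -> float:
    """The floor(N * alpha)-th largest score.

    With this convention exactly floor(N * alpha) replicates meet or
    exceed the threshold, so its own empirical P-value is <= alpha.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    k = int(math.floor(n * alpha))
    if k < 1:
        raise ValueError(
            f"N * alpha = {n * alpha:.3g} < 1: need more replicates to "
            f"estimate the alpha = {alpha} critical value"
        )
    return float(np.sort(scores)[::-1][k - 1])


def power(scores: Sequence[float], threshold: float) -> float:
    """P(Z) = #{T >= Z} / N; ties count as exceedances."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    return float(np.mean(scores >= threshold))


@dataclass
class NullDistribution:
    statistic: str
    scores: np.ndarray  # sorted descending
    critical_values: dict[float, float]

    @property
    def n_replicates(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class PowerResult:
    statistic: str
    structure: str
    moi: Optional[str]
    threshold: float
    power: float
    n_replicates: int


# ---------------------------------------------------------------------------
# replicate generation + statistic evaluation
# ---------------------------------------------------------------------------

def _resolve_spec(structure: str, n_pedigrees: int) -> SampleSpec:
    if structure.upper() == "MIX":
        return MIXTURE_SPEC
    return SampleSpec.homogeneous(structure, n_pedigrees)


def run_replicates(
    spec: SampleSpec,
    hypothesis: str,
    moi: Optional[str],
    statistics: Sequence[str],
    n_replicates: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-replicate statistic values, one row per replicate.

    All replicates are simulated in vectorized batches from a single
    generator; the run is exactly reproducible from (spec, seed).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    stats = _expand_stats(statistics)
    model = None
    if hypothesis == "H1":
        if moi is None:
            raise ValueError("H1 runs need a simulation MOI")
        model = simulation_model(moi)
    if rng is None:
        rng = np.random.default_rng(seed)

    n_total = spec.n_pedigrees
    want_z = "NPL" in stats or "KC-LOD" in stats
    want_lod = any(s.startswith("LOD_") for s in stats)
    want_mod = "MOD" in stats

    sumz = np.zeros(n_replicates)
    lodsum: Optional[np.ndarray] = None
    modsum: Optional[np.ndarray] = None
    kc_parts: list[tuple[sparse.csr_matrix, np.ndarray, float]] = []

    for code, count in spec.parts:
        if count == 0:
            continue
        eng = get_engine(code)
        ids = eng.simulate_class_ids(n_replicates * count, hypothesis, model, rng)
        rep_idx = np.repeat(
            np.arange(n_replicates, dtype=np.int64), count
        )
        present, inv = np.unique(ids, return_inverse=True)
        mat = sparse.coo_matrix(
            (np.ones(ids.size, dtype=np.float32), (rep_idx, inv)),
            shape=(n_replicates, present.size),
        ).tocsr()
        mat.sum_duplicates()
        if want_z:
            zvals = eng.class_z[present]
            sumz += mat @ zvals
            if "KC-LOD" in stats:
                kc_parts.append((mat, zvals, eng.min_z))
        if want_lod:
            sub = eng.lod3_matrix(present)
            block = mat @ sub
            lodsum = block if lodsum is None else lodsum + block
        if want_mod:
            sub = eng.mod_matrix(present)
            if modsum is None:
                modsum = np.zeros((n_replicates, sub.shape[1]), dtype=np.float32)
            for lo in range(0, n_replicates, 1024):
                hi = min(lo + 1024, n_replicates)
                modsum[lo:hi] += mat[lo:hi] @ sub

    cols: dict[str, np.ndarray] = {}
    sqrt_n = math.sqrt(n_total)
    if "NPL" in stats:
        cols["NPL"] = sumz / sqrt_n
    if "KC-LOD" in stats:
        cols["KC-LOD"] = _kc_column(kc_parts, n_replicates)
    if want_lod:
        nth = len(get_engine(spec.parts[0][0]).theta_grid.values)
        for j, name in enumerate(_LOD_STATS):
            if name in stats:
                cols[name] = lodsum[:, j * nth : (j + 1) * nth].max(axis=1)
    if want_mod:
        cols["MOD"] = modsum.max(axis=1).astype(float)

    df = pd.DataFrame({s: cols[s] for s in stats})
    df.index.name = "replicate"
    return df


def _kc_column(
    kc_parts: list[tuple[sparse.csr_matrix, np.ndarray, float]],
    n_replicates: int,
) -> np.ndarray:
    out = np.zeros(n_replicates)
    min_z = np.array([p[2] for p in kc_parts])
    for i in range(n_replicates):
        zs = []
        for mat, zvals, _ in kc_parts:
            sl = slice(mat.indptr[i], mat.indptr[i + 1])
            zs.append(np.repeat(zvals[mat.indices[sl]], mat.data[sl].astype(int)))
        z = np.concatenate(zs)
        out[i] = kc_lod_from_z(z, min_z=min_z).kc_lod
    return out


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Configuration for a null or power study.

    ``structure`` is one of the seven codes or "MIX" (the 100 AST + 100
    ASQ + 100 DST + 100 DSQ sample).  ``thresholds`` selects where power
    critical values come from: "asymptotic" (with published MOD
    constants), "empirical" (requires ``null_scores``), or "fixed"
    (explicit ``fixed_thresholds``).
    """

    structure: str
    statistics: tuple[str, ...] = ("npl",)
    moi: Optional[str] = None
    n_replicates: int = 500
    n_pedigrees: int = 500
    seed: int = 0
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    thresholds: str = "asymptotic"
    fixed_thresholds: Optional[dict[str, float]] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("statistics", "alphas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "fixed_thresholds" in raw and raw["fixed_thresholds"] is not None:
            raw["fixed_thresholds"] = dict(raw["fixed_thresholds"])
        return cls(**raw)

    @property
    def spec(self) -> SampleSpec:
        return _resolve_spec(self.structure, self.n_pedigrees)


def run_null_study(
    config: StudyConfig, out_dir: Optional[str | Path] = None
) -> dict[str, NullDistribution]:
    """H0 replicates plus empirical critical values per statistic."""
    df = run_replicates(
        config.spec,
        "H0",
        None,
        config.statistics,
        config.n_replicates,
        seed=config.seed,
    )
    out: dict[str, NullDistribution] = {}
    for stat in df.columns:
        scores = np.sort(df[stat].to_numpy())[::-1]
        crit = {
            a: empirical_critical_value(scores, a) for a in config.alphas
        }
        out[stat] = NullDistribution(stat, scores, crit)
    if out_dir is not None:
        _write_null_tables(df, out, Path(out_dir))
    return out


def _power_threshold(config: StudyConfig, stat: str) -> float:
    alpha = min(config.alphas)
    if config.thresholds == "fixed":
        if not config.fixed_thresholds or stat not in config.fixed_thresholds:
            raise ValueError(f"no fixed threshold given for {stat!r}")
        return float(config.fixed_thresholds[stat])
    if config.thresholds == "asymptotic":
        if stat == "MOD":
            key = config.structure.upper()
            if key not in MOD_SIGNIFICANT_THRESHOLDS or not math.isclose(
                alpha, ALPHA_SIGNIFICANT
            ):
                raise ValueError(
                    f"no published MOD critical value for structure "
                    f"{config.structure!r} at alpha={alpha}; run an empirical "
                    "null study instead"
                )
            return MOD_SIGNIFICANT_THRESHOLDS[key]
        return asymptotic_threshold(stat, alpha)
    raise ValueError(f"unknown thresholds source {config.thresholds!r}")


def run_power_study(
    config: StudyConfig,
    out_dir: Optional[str | Path] = None,
    null_scores: Optional[dict[str, NullDistribution]] = None,
) -> pd.DataFrame:
    """Power table at the configured significance level (smallest alpha)."""
    if config.moi is None:
        raise ValueError("power studies simulate under H1 and need a MOI")
    df = run_replicates(
        config.spec,
        "H1",
        config.moi,
        config.statistics,
        config.n_replicates,
        seed=config.seed,
    )
    alpha = min(config.alphas)
    rows = []
    for stat in df.columns:
        if config.thresholds == "empirical":
            if null_scores is None or stat not in null_scores:
                raise ValueError("empirical thresholds need null_scores")
            thr = null_scores[stat].critical_values[alpha]
        else:
            thr = _power_threshold(config, stat)
        rows.append(
            PowerResult(
                stat,
                config.structure.upper(),
                config.moi,
                thr,
                power(df[stat].to_numpy(), thr),
                config.n_replicates,
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "power.tsv", sep="\t", index=False)
    return table


def _write_null_tables(
    df: pd.DataFrame, dists: dict[str, NullDistribution], out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    long = df.reset_index().melt(
        id_vars="replicate", var_name="statistic", value_name="value"
    )
    long.to_csv(out / "null_scores.tsv", sep="\t", index=False)
    rows = [
        {"statistic": s, "alpha": a, "critical_value": v}
        for s, d in dists.items()
        for a, v in d.critical_values.items()
    ]
    pd.DataFrame(rows).to_csv(out / "critical_values.tsv", sep="\t", index=False)
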