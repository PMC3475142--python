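"""Vectorized replicate engine with genotype-configuration caching.

Replicate studies evaluate the same statistics on millions of pedigrees of
a handful of fixed structures.  With an equifrequent marker, every
statistic considered here depends on a pedigree's genotypes only through
the inheritance-vector posterior, which is invariant under relabeling of
marker alleles.  The engine therefore canonicalizes each simulated
genotype configuration (allele labels renumbered by first appearance) and
caches, per canonical class:

* the marker-side posterior ``q(v | M)`` and its Walsh-Hadamard transform,
* the NPL z score,
* log10 likelihood-ratio curves over the theta grid for the three
  analysis models (LOD) and for the full MOD model grid.

A replicate's sample statistic is then a multiplicity-weighted sum over
the classes it contains, which turns a study into a sparse matrix product.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .allele_sharing import s_pairs_vector
from .gene_drop import MarkerModel, _joint_posterior
from .parametric import (
    DEFAULT_THETA_GRID,
    ModGrid,
    ThetaGrid,
    default_mod_grid,
)
from .parametric import trait_vectors_batch
from .likelihood import LOG_FLOOR, fwht, popcounts
from .pedigree import Pedigree, build_structure
from .trait_models import TraitModel, analysis_model

__all__ = ["StructureEngine", "get_engine", "clear_engines"]

_SIM_CHUNK = 500_000  # pedigrees canonicalized per chunk
_AMOI_NAMES = ("dominant", "additive", "recessive")


def _canonical_keys(geno: np.ndarray) -> np.ndarray:
    """Canonical integer key per genotype configuration.

    ``geno`` is (N, n_members, 2) with 0-based allele labels.  Pairs are
    sorted, alleles renamed by order of first appearance, twice (the
    second pass resolves pair orderings changed by the first renaming).
    The result is invariant under most allele permutations; imperfect
    canonicalization only duplicates cache entries, never changes values.
    """
    g = np.sort(geno, axis=2)
    N, n, _ = g.shape
    L = 2 * n
    ar = np.arange(L)
    for _ in range(2):
        flat = g.reshape(N, L)
        eq = flat[:, :, None] == flat[:, None, :]
        first = eq.argmax(axis=2)
        isfirst = first == ar[None, :]
        cum = np.cumsum(isfirst, axis=1)
        labels = np.take_along_axis(cum, first, axis=1) - 1
        g = np.sort(labels.reshape(N, n, 2), axis=2)
    powers = (16 ** np.arange(L)).astype(np.int64)
    return g.reshape(N, L).astype(np.int64) @ powers


def _unpack_key(key: int, n_members: int) -> np.ndarray:
    out = np.zeros((n_members, 2), dtype=np.int8)
    for j in range(2 * n_members):
        out[j // 2, j % 2] = (key >> (4 * j)) & 0xF
    return out


class StructureEngine:
    """Cached statistic evaluator for one pedigree structure."""

    def __init__(
        self,
        code: str,
        marker: Optional[MarkerModel] = None,
        theta_grid: ThetaGrid = DEFAULT_THETA_GRID,
        mod_grid: Optional[ModGrid] = None,
    ) -> None:
        self.code = code
        self.ped: Pedigree = build_structure(code)
        self.marker = marker or MarkerModel()
        if not self.marker.is_equifrequent:
            raise ValueError("the batch engine assumes an equifrequent marker")
        self.theta_grid = theta_grid
        self.mod_grid = mod_grid or default_mod_grid()
        self.m = self.ped.n_meioses
        self.nv = 1 << self.m
        self.fh = self.ped.founder_hap_map()
        self.nhap = 2 * len(self.ped.founders)
        self.n_members = self.ped.n_members

        svec = s_pairs_vector(self.ped)
        self.svec = svec
        self.mu = float(svec.mean())
        self.sd = float(svec.std())
        self.min_z = float((svec.min() - self.mu) / self.sd)

        self._pc = popcounts(self.nv)
        self._pc_cols = [np.where(self._pc == k)[0] for k in range(self.m + 1)]
        th = theta_grid.array
        self._tpow = (1.0 - 2.0 * th)[None, :] ** np.arange(self.m + 1)[:, None]

        self._key_to_id: dict[int, int] = {}
        self._qhat: list[np.ndarray] = []  # per class, float64 [nv]
        self._z: list[float] = []
        self._lod3_rows: dict[int, np.ndarray] = {}
        self._mod_rows: dict[int, np.ndarray] = {}
        self._rhat_amoi: Optional[np.ndarray] = None
        self._rhat_mod: Optional[np.ndarray] = None

    # -- simulation ----------------------------------------------------
    def _drop(self, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Founder-allele draw + transmission along vectors v -> genotypes."""
        n = len(v)
        falle = rng.integers(
            0, self.marker.n_alleles, size=(n, self.nhap), dtype=np.int8
        )
        return falle[np.arange(n)[:, None, None], self.fh[v]]

    def simulate_class_ids(
        self,
        n_pedigrees: int,
        hypothesis: str,
        model: Optional[TraitModel],
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Simulate pedigrees and return their canonical class ids."""
        if hypothesis not in ("H0", "H1"):
            raise ValueError("hypothesis must be 'H0' or 'H1'")
        if hypothesis == "H1" and model is None:
            raise ValueError("H1 simulation requires a trait model")
        out = np.empty(n_pedigrees, dtype=np.int64)
        if hypothesis == "H1":
            joint = _joint_posterior(self.ped, model).reshape(-1)
        for lo in range(0, n_pedigrees, _SIM_CHUNK):
            hi = min(lo + _SIM_CHUNK, n_pedigrees)
            size = hi - lo
            if hypothesis == "H0":
                v = rng.integers(0, self.nv, size=size)
            else:
                v = rng.choice(joint.size, size=size, p=joint) % self.nv
            geno = self._drop(v, rng)
            out[lo:hi] = self.class_ids_for(geno)
        return out

    def class_ids_for(self, geno: np.ndarray) -> np.ndarray:
        """Canonical class ids for explicit genotype configurations
        (0-based alleles, shape (N, n_members, 2)); registers new classes."""
        keys = _canonical_keys(np.asarray(geno, dtype=np.int8))
        uniq, inv = np.unique(keys, return_inverse=True)
        new = [k for k in uniq.tolist() if k not in self._key_to_id]
        if new:
            # canonical representatives decode directly from the keys
            reps = np.stack([_unpack_key(k, self.n_members) for k in new])
            self._register_classes(new, reps)
        lookup = np.array([self._key_to_id[k] for k in uniq.tolist()])
        return lookup[inv]

    def _register_classes(self, keys: list[int], reps: np.ndarray) -> None:
        q = self._posteriors_for(reps)
        qh = fwht(q)
        z = (q @ self.svec - self.mu) / self.sd
        base = len(self._z)
        for j, k in enumerate(keys):
            self._key_to_id[k] = base + j
            self._qhat.append(qh[j])
            self._z.append(float(z[j]))

    def _posteriors_for(self, geno: np.ndarray) -> np.ndarray:
        """Batched inheritance-vector posteriors q(v | M), (nc, 2**m).

        Sums phase assignments over all members; homozygous members are
        phase-symmetric, so the duplicate count 2**(n hom) divides out.
        Equifrequent alleles make the result label-invariant.
        """
        nc = len(geno)
        out = np.empty((nc, self.nv))
        for lo in range(0, nc, 512):
            out[lo : lo + 512] = self._posterior_block(geno[lo : lo + 512])
        return out

    def _posterior_block(self, g: np.ndarray) -> np.ndarray:
        nc = len(g)
        nv, nhap, n = self.nv, self.nhap, self.n_members
        rows = np.arange(nv)
        invfreq = 1.0 / self.marker.n_alleles
        nhom = (g[:, :, 0] == g[:, :, 1]).sum(axis=1)
        A = np.zeros((nc, nv))
        for phase in range(1 << n):
            flips = (phase >> np.arange(n)) & 1
            slot = np.where(flips[None, :, None] == 1, g[:, :, ::-1], g)
            reg = np.full((nc, nv, nhap), -1, dtype=np.int8)
            ok = np.ones((nc, nv), dtype=bool)
            for i in range(n):
                for s in (0, 1):
                    f = self.fh[:, i, s]
                    a = slot[:, i, s]
                    cur = reg[:, rows, f]
                    fresh = cur < 0
                    ok &= fresh | (cur == a[:, None])
                    reg[:, rows, f] = np.where(fresh, a[:, None], cur)
            cnt = (reg >= 0).sum(axis=2)
            A += ok * invfreq**cnt
        A /= (2.0 ** nhom)[:, None]
        total = A.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("Mendelian-inconsistent genotype configuration")
        return A / total

    # -- per-class statistic tables -------------------------------------
    @property
    def class_z(self) -> np.ndarray:
        return np.asarray(self._z)

    def _rhat(self, which: str) -> np.ndarray:
        if which == "amoi":
            if self._rhat_amoi is None:
                models = tuple(analysis_model(a) for a in _AMOI_NAMES)
                self._rhat_amoi = self._rhat_from_models(models)
            return self._rhat_amoi
        if self._rhat_mod is None:
            self._rhat_mod = self._rhat_from_models(self.mod_grid.models)
        return self._rhat_mod

    def _rhat_from_models(self, models) -> np.ndarray:
        B = trait_vectors_batch(self.ped, models)
        r = B / B.sum(axis=1, keepdims=True)
        return fwht(r)

    def _curves_for(self, qhat_block: np.ndarray, rhat: np.ndarray) -> np.ndarray:
        """log10 LR curves for a block of classes.

        Returns float32 of shape (n_classes, n_models * n_theta).
        """
        nmod = rhat.shape[0]
        nth = self._tpow.shape[1]
        nc = qhat_block.shape[0]
        ck = np.empty((nc, nmod, self.m + 1))
        for k, cols in enumerate(self._pc_cols):
            ck[:, :, k] = qhat_block[:, cols] @ rhat[:, cols].T
        lr = np.einsum("cmk,kt->cmt", ck, self._tpow)
        np.clip(lr, LOG_FLOOR, None, out=lr)
        return np.log10(lr).reshape(nc, nmod * nth).astype(np.float32)

    def _rows_matrix(
        self, class_ids: np.ndarray, cache: dict[int, np.ndarray], which: str
    ) -> np.ndarray:
        missing = [int(c) for c in class_ids if int(c) not in cache]
        if missing:
            rhat = self._rhat(which)
            for lo in range(0, len(missing), 256):
                blk = missing[lo : lo + 256]
                qb = np.stack([self._qhat[c] for c in blk])
                rows = self._curves_for(qb, rhat)
                for c, row in zip(blk, rows):
                    cache[c] = row
        return np.stack([cache[int(c)] for c in class_ids])

    def lod3_matrix(self, class_ids: np.ndarray) -> np.ndarray:
        """(n_classes, 3 * n_theta) log10-LR rows for the three AMOIs."""
        return self._rows_matrix(class_ids, self._lod3_rows, "amoi")

    def mod_matrix(self, class_ids: np.ndarray) -> np.ndarray:
        """(n_classes, n_grid_models * n_theta) log10-LR rows."""
        return self._rows_matrix(class_ids, self._mod_rows, "mod")


_ENGINES: dict[str, StructureEngine] = {}


def get_engine(code: str) -> StructureEngine:
    """Shared per-structure engine with default marker/grids; class caches
    persist across runs within a process."""
    if code not in _ENGINES:
        _ENGINES[code] = StructureEngine(code)
    return _ENGINES[code]


def clear_engines() -> None:
    _ENGINES.clear()
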