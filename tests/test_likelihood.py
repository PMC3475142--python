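"""Likelihood engine checks: inheritance-vector factorization vs
Elston-Stewart peeling vs a brute-force transmission-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest

import linkpower as lp
from linkpower import MarkerModel, TraitModel, build_structure, simulation_model
from linkpower.likelihood import (
    _theta_transform,
    loglik_iv,
    loglik_peeling,
    marker_vector,
    trait_vector,
)

THETAS = (0.0, 0.1, 0.3, 0.5)
MODELS = (
    simulation_model("recessive"),
    lp.analysis_model("dominant"),
    TraitModel(0.0, 0.5, 1.0, 0.1),
)


def brute_force_loglik(ped, gt, model, marker, theta):
    """Exhaustive sum over founder ordered two-locus haplotype pairs and
    per-meiosis gamete choices.  Exponential; only for tiny pedigrees."""
    K = marker.n_alleles
    freqs = marker.frequencies
    haps = [(ma, ta) for ma in range(K) for ta in (0, 1)]

    def hap_prob(h):
        return freqs[h[0]] * (model.p if h[1] else 1.0 - model.p)

    founders = [i.id for i in ped.founders]
    nonf = [i for i in ped.members if not i.is_founder]
    pen = {
        "affected": lambda c: model.penetrances[c],
        "unaffected": lambda c: 1.0 - model.penetrances[c],
        "unknown": lambda c: 1.0,
    }
    obs = {i.id: tuple(sorted(gt.pair(i.id))) for i in ped.members}
    total = 0.0
    for fgenos in itertools.product(itertools.product(haps, haps), repeat=len(founders)):
        genos = dict(zip(founders, fgenos))
        base = 1.0
        for fid in founders:
            h1, h2 = genos[fid]
            base *= hap_prob(h1) * hap_prob(h2)
        # enumerate gamete choices: per meiosis (marker source, trait source)
        def rec(idx, prob):
            nonlocal total
            if prob == 0.0:
                return
            if idx == len(nonf):
                w = prob
                for ind in ped.members:
                    (m1, t1), (m2, t2) = genos[ind.id]
                    if tuple(sorted((m1 + 1, m2 + 1))) != obs[ind.id]:
                        w = 0.0
                        break
                    w *= pen[ind.affection](t1 + t2)
                total += w
                return
            ind = nonf[idx]
            for pm, pt in itertools.product((0, 1), repeat=2):
                for qm, qt in itertools.product((0, 1), repeat=2):
                    fpair = genos[ind.father_id]
                    mpair = genos[ind.mother_id]
                    ph = (fpair[pm][0], fpair[pt][1])
                    mh = (mpair[qm][0], mpair[qt][1])
                    pw = (1 - theta if pm == pt else theta) * 0.5
                    qw = (1 - theta if qm == qt else theta) * 0.5
                    genos[ind.id] = (ph, mh)
                    rec(idx + 1, prob * pw * qw)
            del genos[ind.id]

        rec(0, base)
    return math.log(total)


@pytest.fixture(scope="module")
def small_samples():
    """One simulated genotype table per structure (H1 recessive)."""
    rng = np.random.default_rng(11)
    marker = MarkerModel()
    out = {}
    for code in lp.STRUCTURE_CODES:
        ped = build_structure(code)
        out[code] = (ped, lp.simulate_marker_h1(
            ped, simulation_model("recessive"), marker, rng
        ))
    return out


@pytest.mark.parametrize("code", lp.STRUCTURE_CODES)
def test_peeling_equals_vector_enumeration(small_samples, code):
    """The two exact engines agree to 1e-10 relative tolerance on every
    structure, model and recombination fraction."""
    marker = MarkerModel()
    ped, gt = small_samples[code]
    for model in MODELS:
        for theta in THETAS:
            a = loglik_iv(ped, gt, model, marker, theta)
            b = loglik_peeling(ped, gt, model, marker, theta)
            assert a == pytest.approx(b, rel=1e-10), (code, theta)


def test_engines_match_brute_force_trio():
    """Both engines equal the exhaustive genotype-assignment oracle on a
    parent-parent-child trio with a 3-allele marker."""
    marker = MarkerModel(3)
    members = (
        lp.Individual("1", None, None, "male", "unknown"),
        lp.Individual("2", None, None, "female", "unaffected"),
        lp.Individual("3", "1", "2", "male", "affected"),
    )
    ped = lp.Pedigree("trio", members)
    gt = lp.GenotypeTable(ped.member_ids, np.array([[1, 2], [2, 3], [2, 2]]))
    model = TraitModel(0.05, 0.3, 0.8, 0.2)
    for theta in (0.0, 0.2, 0.5):
        ref = brute_force_loglik(ped, gt, model, marker, theta)
        assert loglik_iv(ped, gt, model, marker, theta) == pytest.approx(ref, rel=1e-10)
        assert loglik_peeling(ped, gt, model, marker, theta) == pytest.approx(ref, rel=1e-10)


def test_engines_match_brute_force_asp():
    marker = MarkerModel(3)
    ped = build_structure("ASP")
    gt = lp.GenotypeTable(ped.member_ids, np.array([[1, 2], [1, 3], [1, 1], [2, 3]]))
    model = simulation_model("additive")
    for theta in (0.0, 0.3):
        ref = brute_force_loglik(ped, gt, model, marker, theta)
        assert loglik_iv(ped, gt, model, marker, theta) == pytest.approx(ref, rel=1e-10)


def test_flat_model_gives_constant_likelihood(small_samples):
    """With f0=f1=f2 the trait is uninformative: loglik is theta-free."""
    marker = MarkerModel()
    ped, gt = small_samples["DSQ"]
    flat = TraitModel(0.3, 0.3, 0.3, 0.2)
    ref = loglik_iv(ped, gt, flat, marker, 0.5)
    for theta in THETAS:
        assert loglik_iv(ped, gt, flat, marker, theta) == pytest.approx(ref, rel=1e-12)


def test_phase_known_nonrecombinant_closed_form():
    """Ten informative meioses, no recombinants, known phase: the log10
    likelihood ratio at theta=0 is 10*log10(2) (engine-level check with
    point-mass marker and trait distributions)."""
    m = 10
    A = np.zeros(1 << m)
    A[0] = 1.0
    B = A.copy()
    lr0 = float(A @ _theta_transform(B, 0.0)) / (1 << m)
    lr5 = float(A @ _theta_transform(B, 0.5)) / (1 << m)
    lod = math.log10(lr0 / lr5)
    assert lod == pytest.approx(m * math.log10(2.0), abs=1e-12)


def test_mendelian_inconsistency_flags_minus_inf(marker):
    ped = build_structure("ASP")
    # child carries an allele absent from both parents
    gt = lp.GenotypeTable(ped.member_ids, np.array([[1, 2], [3, 4], [5, 5], [1, 3]]))
    assert loglik_iv(ped, gt, simulation_model("dominant"), marker, 0.1) == -math.inf
    assert loglik_peeling(ped, gt, simulation_model("dominant"), marker, 0.1) == -math.inf


def test_marker_vector_respects_frequencies():
    """Non-equifrequent marker: homozygous founders weight by freq^2."""
    marker = MarkerModel(2, freqs=(0.9, 0.1))
    members = (lp.Individual("1", None, None, "male"),)
    ped = lp.Pedigree("solo", members)
    A_common = marker_vector(ped, lp.GenotypeTable(("1",), np.array([[1, 1]])), marker)
    A_rare = marker_vector(ped, lp.GenotypeTable(("1",), np.array([[2, 2]])), marker)
    assert A_common[0] == pytest.approx(0.81)
    assert A_rare[0] == pytest.approx(0.01)


def test_trait_vector_uniform_for_unknowns(marker):
    """All-unknown phenotypes: every inheritance vector equally likely."""
    members = tuple(
        lp.Individual(i.id, i.father_id, i.mother_id, i.sex, "unknown")
        for i in build_structure("AST").members
    )
    ped = lp.Pedigree("blank", members)
    B = trait_vector(ped, simulation_model("dominant"))
    assert np.allclose(B, B[0])
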