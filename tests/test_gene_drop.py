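"""Synthetic-data generator checks: exact conditional posterior, gene-drop
Mendelian consistency, and distributional agreement with independent
oracles (rejection sampling, goodness-of-fit)."""

import numpy as np
import pytest
from scipy.stats import chisquare, chi2_contingency

import linkpower as lp
from linkpower import (
    MarkerModel,
    SampleSpec,
    TraitModel,
    build_structure,
    conditional_trait_posterior,
    simulate_marker_h0,
    simulate_marker_h1,
    simulate_replicate,
    simulation_model,
)
from linkpower.gene_drop import sample_phased_trait_configs
from linkpower.pedigree import MIXTURE_SPEC

SEED = 424242


def _pooled_gof(obs, exp, floor=5.0):
    """Chi-square GOF with rare expected cells pooled into one."""
    obs, exp = np.asarray(obs, float), np.asarray(exp, float)
    big = exp >= floor
    if (~big).any():
        obs = np.append(obs[big], obs[~big].sum())
        exp = np.append(exp[big], exp[~big].sum())
    return chisquare(obs, exp * obs.sum() / exp.sum())


def test_marker_model_validation():
    assert MarkerModel().frequencies.sum() == pytest.approx(1.0)
    assert MarkerModel().is_equifrequent
    with pytest.raises(ValueError):
        MarkerModel(8, freqs=(0.5, 0.5))
    with pytest.raises(ValueError):
        MarkerModel(1)


def test_posterior_normalizes_and_supports_mendelian_counts():
    ped = build_structure("DST")
    post = conditional_trait_posterior(ped, simulation_model("additive"))
    assert post.probs.sum() == pytest.approx(1.0)
    for counts in post.support:
        assert all(c in (0, 1, 2) for c in counts)


def test_conditioning_enriches_recessive_homozygotes():
    """Both affected ASP sibs carrying two disease alleles is likelier
    after conditioning on their affection than unconditionally."""
    ped = build_structure("ASP")
    model = simulation_model("recessive")
    flat = TraitModel(0.5, 0.5, 0.5, model.p)  # uninformative phenotype
    post = conditional_trait_posterior(ped, model)
    uncond = conditional_trait_posterior(ped, flat)

    def both_sibs_hom(p):
        return sum(
            pr for cv, pr in zip(p.support, p.probs) if cv[2] == 2 and cv[3] == 2
        )

    assert both_sibs_hom(post) > both_sibs_hom(uncond)


def test_flat_penetrance_posterior_is_unconditional():
    """With f0=f1=f2 the affection pattern is uninformative, so the
    posterior equals the Mendelian-HWE law regardless of who is affected."""
    ped = build_structure("DSQ")
    p = 0.3
    post = conditional_trait_posterior(ped, TraitModel(0.2, 0.2, 0.2, p))
    blank = lp.Pedigree(
        "b",
        tuple(
            lp.Individual(i.id, i.father_id, i.mother_id, i.sex, "unknown")
            for i in ped.members
        ),
    )
    ref = conditional_trait_posterior(blank, TraitModel(0.9, 0.9, 0.9, p))
    assert post.support == ref.support
    np.testing.assert_allclose(post.probs, ref.probs, atol=1e-12)


def test_dst_posterior_matches_rejection_sampling():
    """Exact enumeration vs a 10^6-draw rejection-sampling oracle for the
    discordant sib triplet under the dominant generating model."""
    ped = build_structure("DST")
    model = simulation_model("dominant")
    post = conditional_trait_posterior(ped, model)

    rng = np.random.default_rng(SEED)
    n = 1_000_000
    # unconditional gene drop at the trait locus
    fhap = rng.random((n, 4)) < model.p  # founder haplotype indicators
    fh = ped.founder_hap_map()
    v = rng.integers(0, 1 << ped.n_meioses, size=n)
    origins = fh[v]  # [n, 5, 2]
    counts = fhap[np.arange(n)[:, None, None], origins].sum(axis=2)
    f = np.array(model.penetrances)
    affected = rng.random((n, ped.n_members)) < f[counts]
    # keep draws matching the affection pattern (parents unconstrained)
    want = np.array([i.affection == "affected" for i in ped.members])
    care = np.array([i.affection != "unknown" for i in ped.members])
    keep = np.all((affected == want)[:, care], axis=1)
    kept = counts[keep]
    assert kept.shape[0] > 1000

    keys = [tuple(row) for row in kept.tolist()]
    observed = {}
    for key in keys:
        observed[key] = observed.get(key, 0) + 1
    exp = np.array([post.prob_of(s) for s in observed]) * len(keys)
    obs = np.array(list(observed.values()), dtype=float)
    stat, p = _pooled_gof(obs, exp)
    assert p > 1e-3


@pytest.mark.parametrize("code", lp.STRUCTURE_CODES)
@pytest.mark.parametrize("moi", ("dominant", "additive", "recessive"))
def test_phased_sampler_matches_posterior(code, moi):
    """Sampled (founder indicators, vector) configurations follow the
    enumerated joint posterior (chi-square GOF, 1e5 draws)."""
    from linkpower.gene_drop import _joint_posterior

    ped = build_structure(code)
    model = simulation_model(moi)
    rng = np.random.default_rng(SEED)
    n = 100_000
    a, v = sample_phased_trait_configs(ped, model, rng, n)
    joint = _joint_posterior(ped, model)
    flat = a * joint.shape[1] + v
    probs = joint.reshape(-1)
    obs = np.bincount(flat, minlength=probs.size).astype(float)
    exp = probs * n
    stat, p = _pooled_gof(obs, exp)
    assert p > 1e-4, (code, moi, p)


def test_h0_child_alleles_are_mendelian(rng, marker):
    for code in ("ASP", "D3G"):
        ped = build_structure(code)
        for _ in range(50):
            gt = simulate_marker_h0(ped, marker, rng)
            for ind in ped.nonfounders:
                pair = gt.pair(ind.id)
                assert pair[0] in gt.pair(ind.father_id)
                assert pair[1] in gt.pair(ind.mother_id)


def test_h0_founder_allele_frequencies(marker):
    """Founder alleles are i.i.d. equifrequent (chi-square GOF, 7 df)."""
    ped = build_structure("ASP")
    rng = np.random.default_rng(SEED)
    alleles = []
    for _ in range(25_000):
        gt = simulate_marker_h0(ped, marker, rng)
        alleles.extend(gt.pair("1"))
        alleles.extend(gt.pair("2"))
    counts = np.bincount(np.array(alleles) - 1, minlength=8)
    stat, p = chisquare(counts)
    assert counts.sum() == 100_000
    assert p > 1e-3


def test_same_seed_same_genotypes(marker):
    ped = build_structure("DSQ")
    model = simulation_model("recessive")
    g1 = simulate_marker_h0(ped, marker, np.random.default_rng(5))
    g2 = simulate_marker_h0(ped, marker, np.random.default_rng(5))
    assert g1 == g2
    h1 = simulate_marker_h1(ped, model, marker, np.random.default_rng(5))
    h2 = simulate_marker_h1(ped, model, marker, np.random.default_rng(5))
    assert h1 == h2


def test_h1_marker_rides_trait_vector(marker, rng):
    """Complete linkage: the marker is transmitted on exactly the meioses
    drawn for the trait locus, so marker IBD equals trait IBD bitwise."""
    ped = build_structure("ASP")
    model = simulation_model("recessive")
    fh = ped.founder_hap_map()
    for _ in range(200):
        gt, v, a = simulate_marker_h1(ped, model, marker, rng, _return_detail=True)
        alle = np.array([gt.pair(m) for m in ped.member_ids])
        origins = fh[v]
        founder_alleles = {}
        for i in range(ped.n_members):
            for s in (0, 1):
                h = origins[i, s]
                founder_alleles.setdefault(h, alle[i, s])
                assert founder_alleles[h] == alle[i, s]


def test_h1_recessive_asp_excess_sharing(marker):
    """Mean marker IBD among affected sibs exceeds the null mean of 1."""
    ped = build_structure("ASP")
    model = simulation_model("recessive")
    rng = np.random.default_rng(SEED)
    fh = ped.founder_hap_map()
    share = []
    for _ in range(10_000):
        _, v, _ = simulate_marker_h1(ped, model, marker, rng, _return_detail=True)
        o = fh[v]
        share.append(len(set(o[2]) & set(o[3])))
    assert np.mean(share) > 1.05


def test_h1_flat_penetrance_indistinguishable_from_h0():
    """With a flat penetrance the phenotype carries no linkage signal, so
    H1 output matches H0 (two-sample chi-square on genotype classes)."""
    from linkpower.engine import StructureEngine

    eng = StructureEngine("ASP")
    flat = TraitModel(0.1, 0.1, 0.1, 0.2)
    n = 100_000
    ids0 = eng.simulate_class_ids(n, "H0", None, np.random.default_rng(SEED))
    ids1 = eng.simulate_class_ids(n, "H1", flat, np.random.default_rng(SEED + 1))
    nclass = max(ids0.max(), ids1.max()) + 1
    c0 = np.bincount(ids0, minlength=nclass)
    c1 = np.bincount(ids1, minlength=nclass)
    both = (c0 + c1) >= 10
    table = np.stack([np.append(c0[both], c0[~both].sum()),
                      np.append(c1[both], c1[~both].sum())])
    table = table[:, table.sum(axis=0) > 0]
    stat, p, dof, _ = chi2_contingency(table)
    assert p > 1e-3


def test_simulate_replicate_shapes(rng, marker):
    model = simulation_model("dominant")
    sample = simulate_replicate(
        SampleSpec.homogeneous("ASP", 7), "H1", model, marker, rng
    )
    assert len(sample) == 7
    assert all(gt.fully_genotyped for _, gt in sample)
    mix = simulate_replicate(MIXTURE_SPEC, "H0", None, marker, rng)
    assert len(mix) == 400
    assert len({p.family_id for p, _ in mix}) == 400
    empty = simulate_replicate(SampleSpec((("ASP", 0),)), "H0", None, marker, rng)
    assert empty == []
    with pytest.raises(ValueError, match="trait model"):
        simulate_replicate(SampleSpec.homogeneous("ASP", 1), "H1", None, marker, rng)
    with pytest.raises(ValueError, match="hypothesis"):
        simulate_replicate(SampleSpec.homogeneous("ASP", 1), "H2", None, marker, rng)
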