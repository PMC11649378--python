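"""Synthetic genomes, trees and traits with recoverable ground truth."""

import logging
import math

import numpy as np
import pytest
from scipy import stats

import genarch as ga


# ------------------------------------------------------------------- trees


def test_yule_two_tips_is_cherry():
    t = ga.simulate_tree(2, 50.0, rng=0)
    assert t.n_tips == 2
    assert t.root_age() == pytest.approx(50.0, abs=1e-9)


def test_yule_tips_at_present(rng):
    t = ga.simulate_tree(30, 123.0, rng=rng)
    ages = t.ages()
    for tip in t.tips():
        assert ages[tip] == pytest.approx(0.0, abs=1e-9)
    assert t.root_age() == pytest.approx(123.0, abs=1e-9)


def test_yule_cherry_fraction():
    """Yule trees have ≈ n/3 cherries in expectation at large n."""
    rng = np.random.default_rng(17)
    n = 120
    counts = []
    for _ in range(40):
        t = ga.simulate_tree(n, 100.0, rng=rng)
        cherries = sum(
            1 for node in t.internal_nodes()
            if len(node.children) == 2
            and all(c.is_leaf() for c in node.children)
        )
        counts.append(cherries)
    mean = np.mean(counts)
    # E = n/3, sd of the mean comfortably below 2
    assert abs(mean - n / 3) < 3.0


# ---------------------------------------------------------------------- BM


def test_bm_zero_variance_is_constant(yule_tree):
    tips, truth = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.0, root=1.5),
                                 rng=0)
    assert np.allclose(tips.values, 1.5)
    assert all(v == 1.5 for v in truth.node_states.values())


def test_bm_single_branch_variance_scaling():
    """Tip variance on one branch of length ℓ approximates σ²ℓ."""
    t = ga.read_newick("(A:10,B:10,C:10);")
    rng = np.random.default_rng(3)
    sigma2 = 0.25
    vals = []
    for _ in range(2000):
        tips, _ = ga.simulate_bm(t, ga.TraitSimSpec(sigma2=sigma2), rng=rng)
        vals.append(tips["A"])
    var = np.var(vals)
    assert abs(var - sigma2 * 10) / (sigma2 * 10) < 0.10


def test_bm_telescoping_increments(yule_tree, rng):
    tips, truth = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.05, root=2.0),
                                 rng=rng)
    states = truth.node_states
    for name in yule_tree.tip_names():
        assert tips[name] == states[name]
    for node in yule_tree.branches():
        # child state = parent state + increment; exact by construction
        parent_key = yule_tree.clade_key(node.parent)
        child_key = yule_tree.clade_key(node)
        assert np.isfinite(states[child_key] - states[parent_key])
    root_key = yule_tree.clade_key(yule_tree.root)
    assert states[root_key] == 2.0


def test_bm_clade_multiplier_raises_within_clade_variance():
    rng = np.random.default_rng(8)
    inside_sds, outside_sds = [], []
    reps = 0
    while reps < 30:
        tree = ga.simulate_tree(20, 300.0, rng=rng)
        left = tree._tipset(tree.root.children[0])
        if not (5 <= len(left) <= 15):
            continue
        reps += 1
        cm = {n: ("L" if n in left else "R") for n in tree.tip_names()}
        tips, _ = ga.simulate_bm(
            tree,
            ga.TraitSimSpec(sigma2=0.01, clade_rate_multipliers={"L": 5.0}),
            rng=rng, clade_map=cm,
        )
        inside_sds.append(np.std([tips[n] for n in tips.index if cm[n] == "L"]))
        outside_sds.append(np.std([tips[n] for n in tips.index if cm[n] == "R"]))
    stat = stats.wilcoxon(
        np.array(inside_sds) - np.array(outside_sds), alternative="greater"
    )
    assert stat.pvalue < 0.05


# ------------------------------------------------------------------ genomes


def test_intronless_fraction_one_yields_single_exon_genes():
    gff3, truth = ga.simulate_genome(
        ga.GenomeSpec(n_genes=60, intronless_fraction=1.0, seed=2)
    )
    _, summary = ga.extract_species(gff3, "s")
    assert summary.fraction_intronless == 1.0
    assert summary.mean_n_introns == 0.0


def test_deterministic_laws_fixed_ratio():
    """3 exons of 100 bp with 200-bp introns: every gene ratio = 400/300."""
    spec = ga.GenomeSpec(
        n_genes=25, fixed_exon_count=3, exon_len_median=100.0, exon_len_sdlog=0.0,
        intron_len_median=200.0, intron_len_sdlog=0.0,
        intronless_fraction=0.0, seed=3,
    )
    gff3, truth = ga.simulate_genome(spec)
    records, _ = ga.extract_species(gff3, "s")
    for rec in records:
        assert rec.total_exon_len == 300
        assert rec.total_intron_len == 400
        assert rec.intron_ratio == pytest.approx(400 / 300)


def test_extraction_reproduces_generator_truth_exactly():
    gff3, truth = ga.simulate_genome(ga.GenomeSpec(n_genes=200, seed=4))
    _, summary = ga.extract_species(gff3, "s")
    ref = truth.species_summary
    assert summary.n_genes == ref.n_genes
    assert summary.mean_intron_ratio == pytest.approx(ref.mean_intron_ratio)
    assert summary.mean_intron_len == pytest.approx(ref.mean_intron_len)
    assert summary.mean_n_introns == pytest.approx(ref.mean_n_introns)
    assert summary.fraction_intronless == pytest.approx(ref.fraction_intronless)


def test_summary_recovers_spec_parameters_within_3se():
    """At n=1000 genes the extracted summary sits within Monte-Carlo error
    of the generating parameters."""
    spec = ga.GenomeSpec(n_genes=1000, seed=5)
    gff3, truth = ga.simulate_genome(spec)
    _, s = ga.extract_species(gff3, "s")
    # intronless fraction: binomial
    f = spec.intronless_fraction
    se_f = math.sqrt(f * (1 - f) / spec.n_genes)
    assert abs(s.fraction_intronless - f) < 3 * se_f
    # mean introns per gene
    exp_introns = spec.expected_mean_n_introns()
    # sd of per-gene intron count ≈ sqrt(var(Bernoulli mix) + Poisson var)
    sd_n = math.sqrt(spec.exon_count_mean - 2.0 + exp_introns**2)
    assert abs(s.mean_n_introns - exp_introns) < 3 * sd_n / math.sqrt(spec.n_genes)
    # pooled intron length: lognormal mean
    exp_len = spec.expected_mean_intron_len()
    n_introns_total = int(round(s.mean_n_introns * s.n_genes))
    sd_len = exp_len * math.sqrt(math.exp(spec.intron_len_sdlog**2) - 1)
    assert abs(s.mean_intron_len - exp_len) < 3 * sd_len / math.sqrt(n_introns_total)


def test_same_seed_byte_identical_gff3():
    a, _ = ga.simulate_genome(ga.GenomeSpec(n_genes=30, seed=9))
    b, _ = ga.simulate_genome(ga.GenomeSpec(n_genes=30, seed=9))
    assert a == b


def test_generated_gff3_parses_without_warnings(caplog):
    gff3, _ = ga.simulate_genome(ga.GenomeSpec(n_genes=50, seed=10))
    with caplog.at_level(logging.WARNING, logger="genarch.genes"):
        genes = ga.parse_annotations(gff3)
    assert len(genes) == 50
    assert not caplog.records


def test_utr_decoration_does_not_change_features():
    """UTR exons and flanks are trimmed away: extraction matches truth."""
    spec = ga.GenomeSpec(n_genes=80, utr_decoration=True, seed=11)
    gff3, truth = ga.simulate_genome(spec)
    _, summary = ga.extract_species(gff3, "s")
    ref = truth.species_summary
    assert summary.mean_intron_ratio == pytest.approx(ref.mean_intron_ratio)
    assert summary.mean_total_exon_len == pytest.approx(ref.mean_total_exon_len)


def test_alt_transcripts_do_not_change_canonical_features():
    """Shorter-CDS second transcripts never displace the canonical one."""
    spec = ga.GenomeSpec(n_genes=80, alt_transcript_prob=0.5, seed=12)
    gff3, truth = ga.simulate_genome(spec)
    _, summary = ga.extract_species(gff3, "s")
    assert summary.mean_intron_ratio == pytest.approx(
        truth.species_summary.mean_intron_ratio
    )


def test_intron_length_mixture_shifts_pooled_mean():
    base = ga.GenomeSpec(n_genes=400, seed=13)
    mixed = ga.GenomeSpec(n_genes=400, seed=13,
                          intron_len_mixture=(60.0, 0.5))
    _, t1 = ga.simulate_genome(base)
    _, t2 = ga.simulate_genome(mixed)
    assert (t2.species_summary.mean_intron_len
            < t1.species_summary.mean_intron_len)
    assert mixed.expected_mean_intron_len() < base.expected_mean_intron_len()


# ------------------------------------------------------------ study fixture


def test_study_fixture_flat_traits_recover_root():
    """Flat traits (σ²=0) on 8 species: pipeline root estimate ≈ the flat value."""
    specs = {
        "log10_mean_intron_ratio": ga.TraitSimSpec(sigma2=0.0, root=0.3),
        "log10_mean_intron_len": ga.TraitSimSpec(sigma2=0.0, root=2.8),
        "mean_n_introns": ga.TraitSimSpec(sigma2=0.0, root=5.0),
    }
    tree, gffs, cm, truth = ga.build_study_fixture(
        n_species=8, tree_depth=300.0, trait_specs=specs, n_genes=400, rng=21
    )
    values = {}
    for sp, gff3 in gffs.items():
        _, s = ga.extract_species(gff3, sp)
        values[sp] = s.log10["mean_intron_ratio"]
    fit = ga.RidgeRateModel(tree, values).fit()
    assert fit.root_state == pytest.approx(0.3, abs=0.1)


def test_study_fixture_infeasible_traits_error():
    specs = {
        "log10_mean_intron_ratio": ga.TraitSimSpec(sigma2=0.0, root=0.0),
        "log10_mean_intron_len": ga.TraitSimSpec(sigma2=0.0, root=3.0),
        "mean_n_introns": ga.TraitSimSpec(sigma2=0.0, root=0.2),  # < 1-f
    }
    with pytest.raises(ValueError, match="infeasible"):
        ga.build_study_fixture(n_species=4, trait_specs=specs, rng=1)


def test_study_fixture_two_rate_clades_detectable():
    """Distinct clade mean shifts in the fixture are visible to phylo-ANOVA."""
    rng = np.random.default_rng(33)
    detected = 0
    reps = 0
    while reps < 5:
        tree, gffs, cm, truth = ga.build_study_fixture(
            n_species=12, tree_depth=400.0, n_genes=150, rng=rng
        )
        counts = {c: sum(1 for v in cm.values() if v == c) for c in set(cm.values())}
        if min(counts.values()) < 3:
            continue
        reps += 1
        values = {}
        for sp, gff3 in gffs.items():
            _, s = ga.extract_species(gff3, sp)
            values[sp] = s.log10["mean_intron_ratio"]
        import pandas as pd
        y = pd.Series(values)
        shifted = y.copy()
        for name in y.index:
            if cm[name] == "cladeA":
                shifted[name] += 2.0
        res = ga.PhylogeneticANOVA(shifted, cm, tree).fit(n_sims=199, rng=1)
        detected += res.p_sim <= 0.05
    assert detected >= 4
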