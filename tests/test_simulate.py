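"""MSC genealogies, sequence evolution, degradation, dataset generation.

Monte-Carlo assertions run at fixed seeds with 3-standard-error bands
around the analytic expectations.
"""

import numpy as np
import pytest

from shsweep.io import SampleInfo, SpeciesMap
from shsweep.distances import pairwise_p_distance
from shsweep.simulate import (
    DatasetConfig,
    DegradationSpec,
    LocusSpec,
    Region,
    SpeciesNode,
    SpeciesTreeModel,
    SubstitutionModel,
    albonigra_like_model,
    ambiguate,
    default_locus,
    degrade,
    evolve_sequences,
    generate_dataset,
    sample_inverse_gamma,
    simulate_genealogy,
)


def one_population(theta=0.002):
    return SpeciesTreeModel(SpeciesNode("pop", 0.0, theta))


def test_pair_tmrca_mean_is_half_theta(rng):
    theta = 0.002
    model = one_population(theta)
    times = np.array(
        [simulate_genealogy(model, {"pop": 2}, rng).tmrca for _ in range(2000)]
    )
    # T2 ~ Exp(mean theta/2): SE of the mean = (theta/2)/sqrt(n)
    se = (theta / 2) / np.sqrt(len(times))
    assert abs(times.mean() - theta / 2) < 3 * se


def test_tmrca_distribution_matches_msprime_oracle(rng):
    """Independent oracle: msprime with ploidy 1 and Ne = theta/2 has the
    same pairwise coalescent time distribution (mean theta/2)."""
    msprime = pytest.importorskip("msprime")
    theta = 0.002
    model = one_population(theta)
    mine = np.array(
        [simulate_genealogy(model, {"pop": 2}, rng).tmrca for _ in range(1500)]
    )
    ts_times = np.array(
        [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=2, ploidy=1, population_size=theta / 2,
                num_replicates=1500, random_seed=987,
            )
        ]
    )
    se = np.sqrt(mine.var() / mine.size + ts_times.var() / ts_times.size)
    assert abs(mine.mean() - ts_times.mean()) < 3 * se


def test_genealogy_respects_species_barriers(complex_dataset):
    """Lineages from different species never coalesce below the species'
    divergence time; node times increase root-ward."""
    model, genealogy, _, _ = complex_dataset
    heights = {frozenset(c): None for c in model.clades()}

    def mrca_constraint(node):
        if node.is_leaf:
            return {genealogy.tip_species[node.id]}
        species = set()
        for child in node.children:
            assert child.time <= node.time
            species |= mrca_constraint(child)
        if len(species) > 1:
            # divergence time of the smallest species clade containing them
            tau = min(
                tau_of(c) for c in model.clades() if species <= c
            )
            assert node.time >= tau
        return species

    def tau_of(clade):
        def walk(n):
            if frozenset(l.label for l in _leaves(n)) == clade:
                return n.tau
            for c in n.children:
                r = walk(c)
                if r is not None:
                    return r
            return None

        return walk(model.root)

    def _leaves(n):
        return [n] if n.is_leaf else [x for c in n.children for x in _leaves(c)]

    mrca_constraint(genealogy.root)


def test_species_monophyly_when_tau_dominates_theta():
    """One sample per species, tau >= 0.01 >> theta = 0.0005: the genealogy
    topology equals the species topology in >= 99% of replicates."""
    model = albonigra_like_model(theta=0.0005)
    expected = model.clades()
    rng = np.random.default_rng(42)
    hits = sum(
        simulate_genealogy(model, {l: 1 for l in model.leaf_labels()}, rng)
        .species_clades() == expected
        for _ in range(500)
    )
    assert hits / 500 >= 0.99


def test_validation_errors():
    with pytest.raises(ValueError, match="empty"):
        simulate_genealogy(one_population(), {}, 0)
    with pytest.raises(ValueError, match=">= 1"):
        simulate_genealogy(one_population(), {"pop": 0}, 0)
    bad = SpeciesTreeModel(
        SpeciesNode("r", 0.01, 0.001,
                    [SpeciesNode("a", 0.002, 0.001), SpeciesNode("b", 0.0, 0.001)])
    )
    with pytest.raises(ValueError, match="ultrametric"):
        simulate_genealogy(bad, {"a": 1, "b": 1}, 0)
    with pytest.raises(ValueError, match="theta"):
        SpeciesTreeModel(SpeciesNode("p", 0.0, 0.0)).validate()


def test_zero_branch_lengths_give_identical_sequences(rng):
    from shsweep.simulate import GeneGenealogy, GeneNode

    tips = [GeneNode(f"t{i}", 0.0, species="p") for i in range(3)]
    root = GeneNode("r", 0.0, [tips[0], GeneNode("i", 0.0, tips[1:])])
    g = GeneGenealogy(root, {t.id: "p" for t in tips})
    aln = evolve_sequences(g, default_locus(), rng)
    assert len({r.seq for r in aln.records}) == 1


def test_jc69_expected_p_distance(rng):
    """Realized p-distance over a path of b = 0.01 matches
    3/4 (1 - exp(-4b/3)) within 3 binomial SE at 1e5 sites."""
    from shsweep.simulate import GeneGenealogy, GeneNode

    b = 0.01
    tips = [GeneNode("x", 0.0, species="p"), GeneNode("y", 0.0, species="p")]
    root = GeneNode("r", b / 2, list(tips))
    g = GeneGenealogy(root, {"x": "p", "y": "p"})
    n = 100_000
    locus = LocusSpec((Region("flat", n, 1.0),))
    aln = evolve_sequences(g, locus, rng)
    expect = 0.75 * (1 - np.exp(-4 * b / 3))
    got = pairwise_p_distance(aln.records[0].seq, aln.records[1].seq, 1)
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(got - expect) < 3 * se


def test_conserved_region_with_zero_rate_is_invariant(rng):
    model = albonigra_like_model(theta=0.002)
    g = simulate_genealogy(model, {l: 2 for l in model.leaf_labels()}, rng)
    locus = LocusSpec(
        (Region("ITS1", 150, 1.0), Region("5.8S", 100, 0.0), Region("ITS2", 150, 1.0))
    )
    aln = evolve_sequences(g, locus, rng)
    chunks = {r.seq[150:250] for r in aln.records}
    assert len(chunks) == 1


def test_hky_evolution_runs_and_biases_transitions(rng):
    from shsweep.simulate import GeneGenealogy, GeneNode

    root = GeneNode("r", 0.05, [GeneNode("x", 0.0, species="p"),
                                GeneNode("y", 0.0, species="p")])
    g = GeneGenealogy(root, {"x": "p", "y": "p"})
    locus = LocusSpec(
        (Region("flat", 30_000, 1.0),),
        SubstitutionModel("HKY", kappa=8.0, base_freqs=(0.25, 0.25, 0.25, 0.25)),
    )
    aln = evolve_sequences(g, locus, rng)
    a, b = aln.records[0].seq, aln.records[1].seq
    transitions = transversions = 0
    pairs = {frozenset(p) for p in (("A", "G"), ("C", "T"))}
    for x, y in zip(a, b):
        if x != y:
            if frozenset((x, y)) in pairs:
                transitions += 1
            else:
                transversions += 1
    assert transitions > transversions  # kappa = 8 favours transitions


def test_within_and_between_species_distance_expectations():
    """Mean within-species p-distance ~ theta; between-species for species
    diverged at tau ~ 2 tau + theta_ancestral (low saturation), within 3 SE."""
    theta, tau = 0.002, 0.008
    model = SpeciesTreeModel(
        SpeciesNode("anc", tau, theta,
                    [SpeciesNode("a", 0.0, theta), SpeciesNode("b", 0.0, theta)])
    )
    rng = np.random.default_rng(99)
    locus = LocusSpec((Region("flat", 2000, 1.0),))
    within, between = [], []
    for _ in range(400):
        g = simulate_genealogy(model, {"a": 2, "b": 1}, rng)
        aln = evolve_sequences(g, locus, rng)
        seq = {r.id: r.seq for r in aln.records}
        within.append(pairwise_p_distance(seq["a_01"], seq["a_02"], 1))
        between.append(pairwise_p_distance(seq["a_01"], seq["b_01"], 1))
    within, between = np.array(within), np.array(between)
    se_w = within.std(ddof=1) / np.sqrt(within.size)
    se_b = between.std(ddof=1) / np.sqrt(between.size)
    # JC saturation shrinks expectations by < 1%; well inside 3 SE here
    assert abs(within.mean() - theta) < 3 * se_w
    assert abs(between.mean() - (2 * tau + theta)) < 3 * se_b


# --- degradation -----------------------------------------------------------


def test_truncation_blanks_other_regions(complex_dataset):
    _, _, alignment, _ = complex_dataset
    damaged, flags = degrade(alignment, DegradationSpec(p_partial_its2=1.0), 0)
    start, end = alignment.region_map["ITS2"]
    for rec in damaged.records:
        assert flags[rec.id] == ("partial:ITS2",)
        assert set(rec.seq[:start]) == {"?"}
        assert "?" not in rec.seq[start:end]


def test_zero_rates_leave_records_unchanged(complex_dataset):
    _, _, alignment, _ = complex_dataset
    damaged, flags = degrade(alignment, DegradationSpec(), 0)
    assert [r.seq for r in damaged.records] == [r.seq for r in alignment.records]
    assert all(f == ("full_length",) for f in flags.values())


def test_ambiguity_count_binomial_mean(rng):
    """Rate 0.05 on 500 sites -> ambiguous-site count ~ Binomial(500, 0.05)."""
    seq = "".join(rng.choice(list("ACGT"), 500))
    counts = [
        sum(c not in "ACGT" for c in ambiguate(seq, 0.05, rng)) for _ in range(200)
    ]
    se = np.sqrt(500 * 0.05 * 0.95 / len(counts))
    assert abs(np.mean(counts) - 25) < 3 * se


def test_degradation_rate_validation():
    with pytest.raises(ValueError, match="outside"):
        DegradationSpec(ambiguity_rate=1.5)
    with pytest.raises(ValueError, match="outside"):
        DegradationSpec(p_partial_its1=-0.1)


# --- dataset generation ----------------------------------------------------


def test_generate_dataset_bookkeeping(tmp_path):
    cfg = DatasetConfig(seed=5, samples_per_species=4)
    result = generate_dataset(cfg, tmp_path)
    assert len(result.alignment) == 20
    assert len(result.truth) == 20
    assert set(result.truth["species"]) == set(result.model.leaf_labels())
    assert (tmp_path / "alignment.fasta").exists()
    assert (tmp_path / "species_tree.nwk").read_text().count("theta=") == 9


def test_same_seed_byte_identical_different_seed_not(tmp_path):
    cfg = DatasetConfig(seed=11, degradation=DegradationSpec(p_partial_its2=0.2))
    a, b = tmp_path / "a", tmp_path / "b"
    generate_dataset(cfg, a)
    generate_dataset(cfg, b)
    for name in ("alignment.fasta", "truth.tsv", "species_tree.nwk", "config.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
    other = generate_dataset(DatasetConfig(seed=12), tmp_path / "c")
    assert (a / "alignment.fasta").read_bytes() != (
        tmp_path / "c" / "alignment.fasta"
    ).read_bytes()


def test_inverse_gamma_sampler_mean(rng):
    alpha, beta = 3.0, 0.002
    draws = sample_inverse_gamma(alpha, beta, rng, 10_000)
    expect = beta / (alpha - 1)
    # IG(3, b) variance = b^2 / ((a-1)^2 (a-2)) = b^2/4
    se = (beta / 2) / np.sqrt(draws.size)
    assert abs(draws.mean() - expect) < 3 * se


def test_config_with_priors_samples_model(tmp_path, rng):
    cfg = DatasetConfig(seed=3, theta_prior=(3, 0.002), tau_prior=(3, 0.02))
    result = generate_dataset(cfg)
    thetas = {n.theta for n in result.model.leaves()}
    assert len(thetas) == 1 and 0 < thetas.pop() != 0.0005
    result.model.validate()  # rescaled heights still ultrametric/ordered


def test_config_yaml_round_trip(tmp_path):
    cfg = DatasetConfig(seed=9, tree="tight_complex",
                        degradation=DegradationSpec(p_ambiguate=0.5))
    import json, yaml

    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    back = DatasetConfig.from_yaml(path)
    assert back == cfg
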