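"""Synthetic-data generator: determinism, composition targets, sampling models."""
import numpy as np
import pytest
from scipy import stats

from islandscape import (
    IslandSpec,
    KineticParams,
    SimConfig,
    TrackSpec,
    generate_genome,
    simulate_bisulfite_clones,
    simulate_chip_tags,
    simulate_expression,
    simulate_sensorgrams,
)
from islandscape.cgi import cpg_oe_ratio, gc_fraction
from islandscape.intervals import GenomicInterval
from islandscape.simulate import SimulationError, sampling_weights


def _mean_density(tags, start, end, chrom="chr1"):
    pos = tags.chrom_positions(chrom)
    return (np.searchsorted(pos, end) - np.searchsorted(pos, start)) / (end - start)


def test_no_islands_means_fully_methylated_genome():
    config = SimConfig(genome_length=50_000, island_specs=[], n_genes=3, seed=5)
    genome, islands, genes, meth = generate_genome(config)
    assert islands == []
    assert np.all(meth.maternal["chr1"] == 1)
    assert np.all(meth.paternal["chr1"] == 1)


def test_same_seed_identical_outputs(small_world):
    config, genome, islands, genes, meth = small_world
    genome2, islands2, genes2, meth2 = generate_genome(config)
    assert genome == genome2
    assert [(i.start, i.end) for i in islands] == [(i.start, i.end) for i in islands2]
    assert [(g.start, g.end, g.strand, g.expressed) for g in genes] == [
        (g.start, g.end, g.strand, g.expressed) for g in genes2
    ]
    np.testing.assert_array_equal(meth.positions["chr1"], meth2.positions["chr1"])
    t1 = simulate_chip_tags(genome, meth, genes, TrackSpec("KDM2A", n_tags=5000), seed=9)
    t2 = simulate_chip_tags(genome2, meth2, genes2, TrackSpec("KDM2A", n_tags=5000), seed=9)
    np.testing.assert_array_equal(t1.tags["chr1"][0], t2.tags["chr1"][0])


def test_island_composition_hits_targets():
    """Emitted island region matches its GC / O-E spec within +/- 0.05,
    measured with the independent character-count oracle."""
    config = SimConfig(
        genome_length=100_000,
        island_specs=[IslandSpec(length=1000, gc=0.65, oe=1.0, assoc="orphan")],
        n_genes=0,
        seed=2,
    )
    genome, islands, _, _ = generate_genome(config)
    isl = islands[0]
    span = genome[isl.chrom][isl.start : isl.end]
    assert gc_fraction(span) == pytest.approx(0.65, abs=0.05)
    assert cpg_oe_ratio(span) == pytest.approx(1.0, abs=0.05)
    bg = genome["chr1"][: isl.start]
    assert gc_fraction(bg) == pytest.approx(0.40, abs=0.05)
    assert cpg_oe_ratio(bg) == pytest.approx(0.20, abs=0.05)


def test_methylome_covers_every_cpg(small_world):
    """Rescanning the emitted sequence finds exactly the methylome entries."""
    _, genome, _, _, meth = small_world
    seq = genome["chr1"]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rescanned = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    np.testing.assert_array_equal(rescanned, meth.positions["chr1"])


def test_imprinted_island_is_hemimethylated(small_world):
    _, _, islands, _, meth = small_world
    imp = next(i for i in islands if i.methylation == "imprinted_50_50")
    idx = meth.sites_in(imp.chrom, imp.start, imp.end)
    assert idx.size > 10
    assert np.all(meth.maternal[imp.chrom][idx] == 1)
    assert np.all(meth.paternal[imp.chrom][idx] == 0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(island_specs=[IslandSpec(length=100)]).validate()
    with pytest.raises(ValueError):
        SimConfig(background_gc=1.2).validate()
    with pytest.raises(SimulationError):
        # 20 islands with mandatory gaps cannot fit in 30 kb
        generate_genome(
            SimConfig(
                genome_length=30_000,
                island_specs=[IslandSpec(assoc="orphan") for _ in range(20)],
                seed=0,
            )
        )


def test_tag_conservation_and_uniform_input(small_world):
    _, genome, _, genes, meth = small_world
    tags = simulate_chip_tags(genome, meth, genes, TrackSpec("input", n_tags=10_000), seed=3)
    assert tags.total_tags == 10_000
    pos = tags.tags["chr1"][0]
    counts, _ = np.histogram(pos, bins=np.arange(0, 200_001, 1000))
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    p = stats.chi2.sf(chi2, counts.size - 1)
    assert p > 0.001


def test_methylation_blocks_kdm2a_binding():
    """Fully methylated islands draw only background-level KDM2A tags."""
    config = SimConfig(
        genome_length=100_000,
        island_specs=[IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="orphan",
                                 methylation="full")],
        n_genes=0,
        seed=4,
    )
    genome, islands, genes, meth = generate_genome(config)
    tags = simulate_chip_tags(genome, meth, genes, TrackSpec("KDM2A", n_tags=10_000), seed=5)
    isl = islands[0]
    island_dens = _mean_density(tags, isl.start, isl.end)
    bg_dens = _mean_density(tags, 0, isl.start)
    assert island_dens / bg_dens < 2.0


def test_kdm2a_enrichment_at_nonmethylated_island():
    config = SimConfig(
        genome_length=100_000,
        island_specs=[IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="orphan")],
        n_genes=0,
        seed=4,
    )
    genome, islands, genes, meth = generate_genome(config)
    tags = simulate_chip_tags(
        genome, meth, genes, TrackSpec("KDM2A", n_tags=100_000, island_fold=20), seed=5
    )
    isl = islands[0]
    ratio = _mean_density(tags, isl.start, isl.end) / _mean_density(tags, 0, isl.start - 2000)
    assert ratio > 5.0


def test_tag_counts_match_analytic_weights(small_world):
    """Binding-model fidelity: binned tag counts agree with the sampling
    weights under a multinomial goodness-of-fit test."""
    _, genome, _, genes, meth = small_world
    spec = TrackSpec("KDM2A", n_tags=200_000)
    tags = simulate_chip_tags(genome, meth, genes, spec, seed=6)
    w = sampling_weights(genome, meth, genes, spec)["chr1"]
    bins = np.arange(0, 200_001, 2000)
    expected = np.add.reduceat(w, bins[:-1])
    expected = expected / expected.sum() * 200_000
    # tag 5' positions are midpoint -/+ 75, so pad compare on midpoints
    pos, strand = tags.tags["chr1"]
    mid = np.where(strand > 0, pos + 75, pos - 75)
    observed, _ = np.histogram(mid, bins=bins)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, bins.size - 2) > 0.001


def test_zero_weight_errors(small_world):
    _, genome, _, genes, meth = small_world
    spec = TrackSpec("H3K36me3", n_tags=100, baseline=0.0, body_gain=5.0)
    no_expr = [g for g in genes if not g.expressed]
    with pytest.raises(SimulationError):
        simulate_chip_tags(genome, meth, no_expr, spec, seed=1)


# --- bisulfite clones ------------------------------------------------------


def _imprinted_region(small_world):
    _, genome, islands, _, meth = small_world
    imp = next(i for i in islands if i.methylation == "imprinted_50_50")
    return GenomicInterval(imp.chrom, imp.start, imp.end), genome, meth


def test_full_conversion_removes_all_cpg_cs(small_world):
    region, genome, meth = _imprinted_region(small_world)
    sim = simulate_bisulfite_clones(
        region, genome, meth, n_clones=5, allele_weights=(0.0, 1.0),
        conversion_rate=1.0, seed=1,
    )
    rel = sim.cpg_positions - region.start
    for seq in sim.sequences:
        assert all(seq[i] == "T" for i in rel)


def test_methylated_allele_retains_every_cpg_c(small_world):
    region, genome, meth = _imprinted_region(small_world)
    sim = simulate_bisulfite_clones(
        region, genome, meth, n_clones=5, allele_weights=(1.0, 0.0),
        conversion_rate=1.0, seed=1,
    )
    rel = sim.cpg_positions - region.start
    for seq in sim.sequences:
        assert all(seq[i] == "C" for i in rel)


def test_allele_sampling_fraction(small_world):
    region, genome, meth = _imprinted_region(small_world)
    sim = simulate_bisulfite_clones(
        region, genome, meth, n_clones=1000, allele_weights=(0.5, 0.5), seed=2
    )
    frac_mat = np.mean([a == "maternal" for a in sim.alleles])
    assert frac_mat == pytest.approx(0.5, abs=0.05)  # binomial CI at n=1000


def test_no_cpg_region_errors(small_world):
    _, genome, _, _, meth = small_world
    pos = meth.positions["chr1"]
    gaps = np.diff(pos)
    i = int(np.argmax(gaps))
    region = GenomicInterval("chr1", int(pos[i]) + 2, int(pos[i + 1]) - 1)
    with pytest.raises(ValueError):
        simulate_bisulfite_clones(region, genome, meth, n_clones=2, seed=0)


# --- sensorgrams -----------------------------------------------------------


def test_sensorgram_closed_form_limits():
    params = KineticParams(kon=1e5, koff=0.064, rmax=100.0)
    kd = params.kd
    conc = 2 * kd
    sgs = simulate_sensorgrams(params, [conc], t_assoc=2000.0, t_dissoc=10.0, noise_sd=0.0)
    sg = sgs[0]
    assert sg.response[0] == pytest.approx(0.0, abs=1e-12)  # t = 0
    plateau = 100.0 * conc / (conc + kd)
    at_end = sg.response[np.searchsorted(sg.times, 2000.0)]
    assert at_end == pytest.approx(plateau, rel=1e-6)


def test_dissociation_half_life_identity():
    params = KineticParams(kon=1e5, koff=0.05, rmax=80.0)
    sgs = simulate_sensorgrams(
        params, [1e-6], t_assoc=100.0, t_dissoc=200.0, noise_sd=0.0, dt=0.1
    )
    sg = sgs[0]
    t0 = 150.0  # grid point inside the dissociation phase
    half = np.log(2) / 0.05
    r_t0 = sg.response[np.searchsorted(sg.times, t0)]
    from islandscape import langmuir_response

    r_half = langmuir_response(t0 + half - 100.0, sg.conc,
                               KineticParams(1e5, 0.05, 80.0),
                               "dissociation",
                               r0=sg.response[np.searchsorted(sg.times, 100.0)])
    assert r_half == pytest.approx(r_t0 / 2, abs=1e-9)


def test_negative_noise_errors():
    params = KineticParams(kon=1e5, koff=0.05, rmax=80.0)
    with pytest.raises(ValueError):
        simulate_sensorgrams(params, [1e-6], noise_sd=-1.0)


# --- expression ------------------------------------------------------------


def test_knockdown_arithmetic(small_world):
    _, _, _, genes, _ = small_world
    expr, cond = simulate_expression(
        genes, n_replicates=3, knockdown_fraction=0.6, noise_sd_log2=0.0, seed=1
    )
    kd_cols = cond.index[cond == "knockdown"]
    ctrl_cols = cond.index[cond == "control"]
    ratio = expr.loc["KDM2A", kd_cols].mean() / expr.loc["KDM2A", ctrl_cols].mean()
    assert ratio == pytest.approx(0.4, rel=1e-12)
    others = expr.drop(index="KDM2A")
    np.testing.assert_allclose(others[kd_cols].to_numpy(), others[ctrl_cols].to_numpy())


def test_expression_independent_of_island_association(rng):
    from islandscape.intervals import GeneModel

    genes = [GeneModel("chr1", i * 1000, i * 1000 + 500, "+", f"g{i}") for i in range(1000)]
    expr, cond = simulate_expression(genes, seed=7, knockdown_fraction=0.0)
    island_indicator = np.arange(1000) % 2  # arbitrary labelling; baselines are iid
    means = expr.loc[[f"g{i}" for i in range(1000)]].mean(axis=1).to_numpy()
    r = np.corrcoef(island_indicator, means)[0, 1]
    assert abs(r) < 0.1


def test_expression_validation(small_world):
    _, _, _, genes, _ = small_world
    with pytest.raises(ValueError):
        simulate_expression(genes, n_replicates=1)
    with pytest.raises(ValueError):
        simulate_expression(genes, knockdown_fraction=1.5)
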