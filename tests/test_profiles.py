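"""Tag densities, meta-profiles and enrichment normalisation."""
import numpy as np
import pandas as pd
import pytest

from islandscape import (
    TagCollection,
    TrackSpec,
    h3_normalize,
    percent_input,
    promoter_body_test,
    scaled_island_metaprofile,
    simulate_chip_tags,
    tag_density,
    tss_metaprofile,
)
from islandscape.intervals import CpGIsland, GeneModel, GenomicInterval


def _tc(records, name="t", fl=150):
    """records: {chrom: [(pos, strand), ...]}"""
    tags = {
        c: (np.array([p for p, _ in v]), np.array([s for _, s in v], dtype=np.int8))
        for c, v in records.items()
    }
    return TagCollection(name=name, fragment_length=fl, tags=tags)


def _brute_force_coverage(tags, chrom, start, end):
    cov = np.zeros(end - start)
    pos, strand = tags.tags.get(chrom, (np.empty(0, int), np.empty(0, np.int8)))
    for p, s in zip(pos, strand):
        lo = p if s > 0 else p - tags.fragment_length + 1
        for b in range(lo, lo + tags.fragment_length):
            if start <= b < end:
                cov[b - start] += 1
    return cov


def test_single_plus_tag_density():
    tags = _tc({"chr1": [(1000, 1)]})
    dens = tag_density(tags, GenomicInterval("chr1", 900, 1300), bin_size=1)
    np.testing.assert_array_equal(dens[:100], 0.0)
    np.testing.assert_array_equal(dens[100:250], 1.0)
    np.testing.assert_array_equal(dens[250:], 0.0)


def test_minus_tag_mirrors_plus_tag():
    plus = tag_density(_tc({"chr1": [(1000, 1)]}), GenomicInterval("chr1", 800, 1200))
    minus = tag_density(_tc({"chr1": [(1000, -1)]}), GenomicInterval("chr1", 800, 1200))
    # - strand fragment covers (p - L, p]; reflecting around the 5' base maps
    # position p + d onto p - d
    np.testing.assert_array_equal(plus[200:], minus[:201][::-1][:200])


def test_density_matches_per_base_oracle(rng):
    pos = rng.integers(0, 10_000, size=300)
    strand = np.where(rng.random(300) < 0.5, 1, -1)
    tags = _tc({"chr1": list(zip(pos, strand))})
    region = GenomicInterval("chr1", 500, 9_500)
    oracle = _brute_force_coverage(tags, "chr1", 500, 9_500)
    np.testing.assert_array_equal(tag_density(tags, region, bin_size=1), oracle)
    # conservation at coarser bins: sum x bin_size = total fragment bp
    dens = tag_density(tags, region, bin_size=100)
    assert dens.sum() * 100 == pytest.approx(oracle.sum())


def test_empty_track_zero_density():
    tags = _tc({})
    dens = tag_density(tags, GenomicInterval("chr1", 0, 1000))
    np.testing.assert_array_equal(dens, 0.0)


def test_tss_profile_uniform_tags_flat():
    # a tag every 5 bp on both strands: interior coverage is exactly constant
    records = [(p, 1) for p in range(0, 30_000, 5)] + [(p, -1) for p in range(0, 30_000, 5)]
    tags = _tc({"chr1": records})
    genes = [GeneModel("chr1", 15_000, 20_000, "+", "g1")]
    prof = tss_metaprofile(tags, genes, half_window=2000)
    assert prof.n_anchors == 1
    assert np.ptp(prof.values) / prof.values.mean() < 1e-9


def test_tss_profile_single_gene_equals_density():
    tags = _tc({"chr1": [(5_000, 1), (5_400, -1)]})
    gene = GeneModel("chr1", 5_100, 9_000, "+", "g1")
    prof = tss_metaprofile(tags, [gene], half_window=500)
    dens = tag_density(tags, GenomicInterval("chr1", 4_600, 5_600), bin_size=1)
    np.testing.assert_array_equal(prof.values, dens)


def test_tss_profile_minus_strand_reversed():
    tags = _tc({"chr1": [(5_200, 1)]})
    plus = tss_metaprofile(tags, [GeneModel("chr1", 5_000, 8_000, "+", "g")], half_window=500)
    minus = tss_metaprofile(tags, [GeneModel("chr1", 2_000, 5_001, "-", "g")], half_window=500)
    np.testing.assert_array_equal(minus.values, plus.values[::-1])


def test_tss_profile_requires_usable_genes():
    tags = _tc({"chr1": [(100, 1)]})
    with pytest.raises(ValueError):
        tss_metaprofile(tags, [GeneModel("chr1", 100, 500, "+", "g")], half_window=2000)


def test_island_gene_profile_exceeds_background_genes(small_world):
    """KDM2A is concentrated at CpG-island TSSs but not at non-island TSSs."""
    _, genome, islands, genes, meth = small_world
    tags = simulate_chip_tags(genome, meth, genes, TrackSpec("KDM2A", n_tags=100_000), seed=8)
    island_chroms = {(i.chrom, i.start, i.end) for i in islands}
    island_genes = [
        g for g in genes
        if any(c == g.chrom and s <= g.tss < e for c, s, e in island_chroms)
    ]
    other_genes = [g for g in genes if g not in island_genes]
    assert island_genes and other_genes
    p_isl = tss_metaprofile(tags, island_genes, half_window=1000)
    p_other = tss_metaprofile(tags, other_genes, half_window=1000)
    centre = slice(900, 1100)
    assert p_isl.values[centre].mean() > 3 * p_other.values[centre].mean()


def test_scaled_profile_uniform_flat():
    records = [(p, 1) for p in range(0, 30_000, 5)]
    tags = _tc({"chr1": records})
    islands = [CpGIsland(GenomicInterval("chr1", 10_000, 11_000), 0.6, 0.8)]
    prof = scaled_island_metaprofile(tags, islands, n_bins_island=20)
    assert np.ptp(prof.values) / prof.values.mean() < 1e-9


def test_scaled_profile_empty_track():
    islands = [CpGIsland(GenomicInterval("chr1", 10_000, 11_000), 0.6, 0.8)]
    prof = scaled_island_metaprofile(_tc({}), islands)
    assert prof.n_anchors == 1
    np.testing.assert_array_equal(prof.values, 0.0)


def test_kdm2a_scaled_profile_peaks_inside_islands(small_world):
    """Island body density beats flank density for TSS, TES and orphan
    islands alike, and the reciprocal H3K36me2 dip sits inside the island."""
    _, genome, islands, genes, meth = small_world
    kdm2a = simulate_chip_tags(genome, meth, genes, TrackSpec("KDM2A", n_tags=100_000), seed=9)
    me2 = simulate_chip_tags(genome, meth, genes, TrackSpec("H3K36me2", n_tags=100_000), seed=10)
    nonmeth = [i for i in islands if i.methylation == "none"]
    for assoc in ("TSS", "TES", "other"):
        subset = [i for i in nonmeth if i.assoc == assoc]
        if not subset:
            continue
        prof = scaled_island_metaprofile(kdm2a, subset, n_bins_island=20)
        inside = (prof.positions >= 0) & (prof.positions <= 1)
        assert prof.values[inside].mean() > prof.values[~inside].mean()
    kprof = scaled_island_metaprofile(kdm2a, nonmeth, n_bins_island=20)
    mprof = scaled_island_metaprofile(me2, nonmeth, n_bins_island=20)
    inside = (kprof.positions >= 0) & (kprof.positions <= 1)
    assert inside[np.argmax(kprof.values)]
    assert inside[np.argmin(mprof.values)]


def _amplicons():
    return [
        (GenomicInterval("chr1", 10_000, 11_000), "g1", "promoter"),
        (GenomicInterval("chr1", 14_000, 15_000), "g1", "body"),
    ]


def test_percent_input_identity(rng):
    pos = rng.integers(0, 50_000, 2000)
    strand = np.where(rng.random(2000) < 0.5, 1, -1)
    tags = _tc({"chr1": list(zip(pos, strand))})
    table = percent_input(tags, tags, _amplicons())
    np.testing.assert_allclose(table["percent_input"], 100.0)


def test_percent_input_duplication_invariant(rng):
    pos = rng.integers(0, 50_000, 1000)
    strand = np.where(rng.random(1000) < 0.5, 1, -1)
    ip = _tc({"chr1": list(zip(pos, strand))}, name="ip")
    inp = _tc({"chr1": list(zip(rng.integers(0, 50_000, 1000),
                                np.where(rng.random(1000) < 0.5, 1, -1)))}, name="in")
    doubled = lambda t: _tc(
        {c: list(zip(np.repeat(p, 2), np.repeat(s, 2))) for c, (p, s) in t.tags.items()},
        name=t.name,
    )
    t1 = percent_input(ip, inp, _amplicons())
    t2 = percent_input(doubled(ip), doubled(inp), _amplicons())
    np.testing.assert_allclose(t1["percent_input"], t2["percent_input"])


def test_percent_input_empty_ip(rng):
    inp = _tc({"chr1": [(int(p), 1) for p in rng.integers(0, 50_000, 1000)]})
    table = percent_input(_tc({}, name="ip"), inp, _amplicons())
    np.testing.assert_array_equal(table["percent_input"], 0.0)


def test_percent_input_reflects_simulated_fold(small_world):
    _, genome, islands, genes, meth = small_world
    ip = simulate_chip_tags(
        genome, meth, genes, TrackSpec("KDM2A", n_tags=200_000, island_fold=20), seed=12
    )
    inp = simulate_chip_tags(genome, meth, genes, TrackSpec("input", n_tags=200_000), seed=13)
    isl = next(i for i in islands if i.methylation == "none")
    amps = [
        (GenomicInterval(isl.chrom, isl.start, isl.end), "isl", "promoter"),
        (GenomicInterval("chr1", isl.end + 20_000, isl.end + 21_000), "bg", "body"),
    ]
    table = percent_input(ip, inp, amps)
    ratio = table["percent_input"].iloc[0] / table["percent_input"].iloc[1]
    # fragments bleed 150 bp over island edges, so the realised amplicon-level
    # fold sits slightly below the nominal 20
    assert 10 < ratio < 30


def test_h3_normalize_identity_and_scale_invariance():
    amp = _amplicons()
    base = pd.DataFrame(
        {
            "chrom": [a[0].chrom for a in amp],
            "start": [a[0].start for a in amp],
            "end": [a[0].end for a in amp],
            "gene": [a[1] for a in amp],
            "region": [a[2] for a in amp],
            "percent_input": [40.0, 120.0],
        }
    )
    ident = h3_normalize(base, base)
    np.testing.assert_allclose(ident["normalized"], 1.0)
    doubled = base.assign(percent_input=base["percent_input"] * 2)
    np.testing.assert_allclose(
        h3_normalize(doubled, doubled)["normalized"], 1.0
    )
    h3_flat = base.assign(percent_input=[100.0, 100.0])
    mod = base.assign(percent_input=[100.0 / 3, 100.0])
    norm = h3_normalize(mod, h3_flat)
    prom = norm.loc[norm.region == "promoter", "normalized"].iloc[0]
    body = norm.loc[norm.region == "body", "normalized"].iloc[0]
    assert prom / body == pytest.approx(1 / 3)


def test_h3_zero_flagged_undefined():
    amp = _amplicons()
    base = pd.DataFrame(
        {
            "chrom": [a[0].chrom for a in amp],
            "start": [a[0].start for a in amp],
            "end": [a[0].end for a in amp],
            "gene": [a[1] for a in amp],
            "region": [a[2] for a in amp],
            "percent_input": [40.0, 120.0],
        }
    )
    h3 = base.assign(percent_input=[0.0, 100.0])
    norm = h3_normalize(base, h3)
    assert np.isnan(norm["normalized"].iloc[0])
    assert np.isfinite(norm["normalized"].iloc[1])


def test_promoter_body_equal_values_null():
    rows = []
    for g in range(5):
        for region in ("promoter", "body"):
            rows.append({"gene": f"g{g}", "region": region, "normalized": 1.7,
                         "chrom": "chr1", "start": g, "end": g + 1})
    res = promoter_body_test(pd.DataFrame(rows))
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.n == 5


def test_promoter_body_requires_three_genes():
    rows = [
        {"gene": "g0", "region": r, "normalized": v, "chrom": "c", "start": 0, "end": 1}
        for r, v in (("promoter", 1.0), ("body", 2.0))
    ]
    with pytest.raises(ValueError):
        promoter_body_test(pd.DataFrame(rows))
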