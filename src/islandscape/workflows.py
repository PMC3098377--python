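"""End-to-end experiments composed from the library's stages.

These are the worked examples the package is built around: the genome-wide
island-occupancy experiment, the imprinted-allele bisulfite experiment, the
H3-normalised promoter-vs-body depletion test, and the K_D round trips.
Each takes a seed and returns the downstream statistics; tests and the
acceptance script both run these.
"""
from __future__ import annotations

import numpy as np

from .bisulfite import AlleleCallSummary, build_clone_set, classify_clones
from .binding import KineticParams, fit_kinetics, fit_steady_state
from .cgi import classify_islands, detect_islands
from .intervals import GenomicInterval
from .occupancy import OccupancyReport, call_peaks, island_occupancy
from .profiles import TestResult, h3_normalize, percent_input, promoter_body_test
from .simulate import (
    IslandSpec,
    SimConfig,
    TrackSpec,
    generate_genome,
    simulate_bisulfite_clones,
    simulate_chip_tags,
    simulate_sensorgrams,
)


def occupancy_config(
    seed: int,
    genome_length: int = 10_000_000,
    n_islands: int = 200,
    n_tss: int = 120,
    n_tes: int = 40,
) -> SimConfig:
    """A 10-Mb single-chromosome world with 200 nonmethylated islands,
    120 of them TSS-associated (the remainder split TES/orphan)."""
    n_orphan = n_islands - n_tss - n_tes
    specs = (
        [IslandSpec(length=1000, gc=0.65, oe=0.85, assoc="TSS") for _ in range(n_tss)]
        + [IslandSpec(length=1000, gc=0.65, oe=0.85, assoc="TES") for _ in range(n_tes)]
        + [IslandSpec(length=1000, gc=0.65, oe=0.85, assoc="orphan") for _ in range(n_orphan)]
    )
    return SimConfig(
        genome_length=genome_length,
        island_specs=specs,
        n_genes=n_tss + n_tes,
        seed=seed,
    )


def occupancy_experiment(
    seed: int,
    n_tags: int = 500_000,
    island_fold: float = 20.0,
    fdr: float = 0.05,
    genome_length: int = 10_000_000,
    n_islands: int = 200,
) -> OccupancyReport:
    """Simulate KDM2A vs input, detect islands, call peaks, report occupancy."""
    config = occupancy_config(seed, genome_length=genome_length, n_islands=n_islands,
                              n_tss=int(round(n_islands * 0.6)), n_tes=int(round(n_islands * 0.2)))
    genome, _, genes, methylome = generate_genome(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2 ** 31))
    kdm2a = simulate_chip_tags(
        genome, methylome, genes,
        TrackSpec(name="KDM2A", n_tags=n_tags, island_fold=island_fold), seed=rng,
    )
    inp = simulate_chip_tags(
        genome, methylome, genes, TrackSpec(name="input", n_tags=n_tags), seed=rng
    )
    islands = classify_islands(detect_islands(genome), genes)
    sizes = {c: len(s) for c, s in genome.items()}
    peaks = call_peaks(kdm2a, inp, chrom_sizes=sizes, fdr=fdr)
    return island_occupancy(peaks, islands, genome=genome)


def imprinting_experiment(
    seed: int,
    n_clones: int = 24,
    n_cpgs: int = 15,
    allele_weights: tuple[float, float] = (0.5, 0.5),
    conversion_rate: float = 0.99,
) -> AlleleCallSummary:
    """Simulate bisulfite clones from an imprinted amplicon and classify them.

    The amplicon spans the first ``n_cpgs`` CpGs of an imprinted island
    (maternal allele fully methylated, paternal fully nonmethylated).
    """
    config = SimConfig(
        genome_length=60_000,
        island_specs=[IslandSpec(length=1200, gc=0.65, oe=0.9, assoc="orphan",
                                 methylation="imprinted_50_50")],
        n_genes=0,
        seed=seed,
    )
    genome, islands, _, methylome = generate_genome(config)
    isl = islands[0]
    sites = methylome.positions[isl.chrom]
    inside = sites[(sites >= isl.start) & (sites < isl.end)]
    if inside.size < n_cpgs:
        raise RuntimeError("island has fewer CpGs than requested amplicon size")
    region = GenomicInterval(isl.chrom, int(inside[0]) - 5, int(inside[n_cpgs - 1]) + 10)
    sim = simulate_bisulfite_clones(
        region, genome, methylome, n_clones=n_clones, allele_weights=allele_weights,
        conversion_rate=conversion_rate,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % (2 ** 31)),
    )
    clones = dict(zip(sim.names(), sim.sequences))
    calls, _rejected = build_clone_set(clones, sim.reference, region)
    return classify_clones(calls)


def promoter_body_experiment(
    seed: int,
    n_genes: int = 9,
    depletion: float = 1 / 3,
    n_tags: int = 200_000,
    genome_length: int = 500_000,
    resample_seed: int | None = None,
    _cache: dict | None = None,
) -> TestResult:
    """H3-normalised promoter-vs-body H3K36me2 test across CpG-island genes.

    Simulates ``n_genes`` nonexpressed CpG-island genes whose islands deplete
    H3K36me2 by ``depletion`` (1.0 = no depletion, the null), with uniform H3
    and input; computes percent-input per promoter/body amplicon, normalises
    to H3, and runs the paired two-sided t-test. ``_cache`` lets calibration
    sweeps reuse the genome while resampling tags with ``resample_seed``.
    """
    key = (seed, n_genes, genome_length)
    if _cache is not None and key in _cache:
        genome, genes, methylome, amplicons = _cache[key]
    else:
        config = SimConfig(
            genome_length=genome_length,
            island_specs=[IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="TSS")
                          for _ in range(n_genes)],
            n_genes=n_genes,
            frac_expressed=0.0,  # keep gene bodies at baseline H3K36me2
            seed=seed,
        )
        genome, islands, genes, methylome = generate_genome(config)
        amplicons = []
        for isl, g in zip(islands, genes):
            body_lo = g.tss + 2000 if g.strand == "+" else g.tss - 3000
            amplicons.append((GenomicInterval(isl.chrom, isl.start, isl.end), g.name, "promoter"))
            amplicons.append((GenomicInterval(g.chrom, body_lo, body_lo + 1000), g.name, "body"))
        if _cache is not None:
            _cache[key] = (genome, genes, methylome, amplicons)
    tag_seed = resample_seed if resample_seed is not None else seed
    rng = np.random.default_rng(np.random.SeedSequence([tag_seed, 3]).generate_state(1)[0] % (2 ** 31))
    me2 = simulate_chip_tags(
        genome, methylome, genes,
        TrackSpec(name="H3K36me2", n_tags=n_tags, island_depletion=depletion), seed=rng,
    )
    h3 = simulate_chip_tags(genome, methylome, genes, TrackSpec(name="H3", n_tags=n_tags), seed=rng)
    inp = simulate_chip_tags(genome, methylome, genes, TrackSpec(name="input", n_tags=n_tags),
                             seed=rng)
    me2_tab = percent_input(me2, inp, amplicons)
    h3_tab = percent_input(h3, inp, amplicons)
    return promoter_body_test(h3_normalize(me2_tab, h3_tab))


def kd_kinetic_roundtrip(kd_uM: float = 0.64, kon: float = 1e5, rmax: float = 100.0) -> float:
    """Noise-free sensorgram round trip: recovered K_D in uM.

    Truth koff is chosen so koff/kon equals the requested K_D.
    """
    koff = kon * kd_uM * 1e-6
    params = KineticParams(kon=kon, koff=koff, rmax=rmax)
    kd_M = kd_uM * 1e-6
    concs = kd_M * np.array([0.1, 0.3, 1.0, 3.0, 10.0])
    sgs = simulate_sensorgrams(params, concs, t_assoc=120.0, t_dissoc=120.0, noise_sd=0.0)
    return fit_kinetics(sgs).kd_uM


def kd_steady_state_roundtrip(kd_uM: float = 0.56, rmax: float = 100.0) -> float:
    """Noise-free isotherm round trip: recovered K_D in uM."""
    kd_M = kd_uM * 1e-6
    conc = kd_M * np.array([0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0])
    req = rmax * conc / (conc + kd_M)
    return fit_steady_state(conc, req).kd_uM
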