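"""Synthetic genome, methylome, ChIP-tag, bisulfite, SPR and expression data.

The generator encodes the biological model under study: a CpG-depleted,
methylated background genome carrying GC/CpG-rich nonmethylated islands
(TSS-associated, TES-associated or orphan; optionally imprinted 50/50 or
fully methylated), KDM2A tags concentrated over nonmethylated CpG-dense
regions, uniform input and H3, H3K36me2 depleted over nonmethylated islands
and over expressed gene bodies where H3K36me3 takes over, bisulfite clones
with allele-of-origin labels, 1:1 Langmuir sensorgrams, and a two-condition
expression matrix with a knockdown.

Everything is driven by a single numpy Generator per call: the same config
and seed reproduce byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seqgen import (
    SequenceGenerationError,
    codes_to_str,
    generate_sequence,
    measure_gc_oe,
)
from .binding import KineticParams, Sensorgram, langmuir_response
from .intervals import CpGIsland, GeneModel, GenomicInterval
from .profiles import TagCollection


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IslandSpec:
    """One CpG island to synthesise: size, composition, gene association
    (TSS / TES / orphan) and methylation state (none / full / imprinted_50_50)."""

    length: int = 1000
    gc: float = 0.65
    oe: float = 0.85
    assoc: str = "TSS"
    methylation: str = "none"

    def validate(self, idx: int) -> None:
        if self.length < 200:
            raise ValueError(f"island spec {idx}: length must be >= 200 bp")
        if not (0 <= self.gc <= 1):
            raise ValueError(f"island spec {idx}: gc must be in [0, 1]")
        if self.oe < 0:
            raise ValueError(f"island spec {idx}: oe must be >= 0")
        if self.assoc not in ("TSS", "TES", "orphan"):
            raise ValueError(f"island spec {idx}: unknown assoc {self.assoc!r}")
        if self.methylation not in ("none", "full", "imprinted_50_50"):
            raise ValueError(f"island spec {idx}: unknown methylation {self.methylation!r}")


@dataclass
class SimConfig:
    """World description for the toy genome."""

    genome_length: int = 1_000_000
    n_chroms: int = 1
    island_specs: list[IslandSpec] = field(default_factory=list)
    background_gc: float = 0.40
    background_oe: float = 0.20
    n_genes: int = 20
    frac_expressed: float = 0.5
    gene_length_range: tuple[int, int] = (5_000, 15_000)
    island_gap: int = 2_000
    mosaic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for frac, name in (
            (self.background_gc, "background_gc"),
            (self.background_oe, "background_oe"),
            (self.frac_expressed, "frac_expressed"),
            (self.mosaic_fraction, "mosaic_fraction"),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 1 or self.n_chroms < 1:
            raise ValueError("genome_length and n_chroms must be positive")
        for i, spec in enumerate(self.island_specs):
            spec.validate(i)


@dataclass
class Methylome:
    """Per-CpG methylation state per allele (maternal, paternal), values 0/1.

    Every CG dinucleotide in the emitted genome has an entry; ``positions``
    are the coordinates of the C.
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    maternal: dict[str, np.ndarray] = field(default_factory=dict)
    paternal: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, chrom: str) -> np.ndarray:
        """Allele-averaged methylation per site (0, 0.5 or 1)."""
        return (self.maternal[chrom] + self.paternal[chrom]) / 2.0

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of CpG sites with C inside [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(pos, [start, end])
        return np.arange(lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.positions:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": self.positions[chrom],
                        "maternal": self.maternal[chrom],
                        "paternal": self.paternal[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "pos", "maternal", "paternal"]
        )


@dataclass
class TrackSpec:
    """Sampling-weight model for one ChIP track.

    island_fold is the saturation enrichment of KDM2A over nonmethylated
    CpG-dense sequence; island_depletion multiplies H3K36me1/2 weight where
    nonmethylated CpGs are dense; body_depletion further reduces H3K36me2
    over expressed gene bodies (where me3 takes over); body_gain concentrates
    H3K36me3 over expressed gene bodies. Defaults are free parameters of the
    simulation, not measured quantities.
    """

    name: str = "KDM2A"
    n_tags: int = 100_000
    fragment_length: int = 150
    island_fold: float = 20.0
    island_depletion: float = 1 / 3
    body_depletion: float = 0.5
    body_gain: float = 10.0
    baseline: float = 0.1
    cpg_window: int = 200
    cpg_saturation: float = 8.0

    KNOWN = ("KDM2A", "input", "H3", "H3K36me1", "H3K36me2", "H3K36me3")

    def validate(self) -> None:
        if self.name not in self.KNOWN:
            raise ValueError(f"unknown track {self.name!r}; expected one of {self.KNOWN}")
        if self.n_tags <= 0:
            raise ValueError("n_tags must be > 0")
        if not (0.0 < self.island_depletion <= 1.0):
            raise ValueError("island_depletion must be in (0, 1]")
        if self.island_fold < 1.0:
            raise ValueError("island_fold must be >= 1")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")


def default_track_spec(name: str, n_tags: int = 100_000, **kw) -> TrackSpec:
    """Per-track defaults; H3K36me1 is depleted more mildly than me2."""
    defaults = {"H3K36me1": {"island_depletion": 0.6, "body_depletion": 1.0}}
    params = {**defaults.get(name, {}), **kw}
    return TrackSpec(name=name, n_tags=n_tags, **params)


# ---------------------------------------------------------------------------
# genome generation

def _scan_cpg(codes: np.ndarray) -> np.ndarray:
    """Positions of the C of every CG dinucleotide."""
    if codes.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2)).astype(np.int64)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    extent_len: int,
    chrom_len: int,
    gap: int,
    tries: int = 500,
) -> int | None:
    """Uniform-random non-overlapping placement with a minimum gap."""
    if chrom_len - extent_len - 2 <= 1:
        return None
    for _ in range(tries):
        start = int(rng.integers(1, chrom_len - extent_len - 1))
        if all(start - gap >= e or start + extent_len + gap <= s for s, e in occupied):
            return start
    return None


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[CpGIsland], list[GeneModel], Methylome]:
    """Synthesise the toy world: sequences, truth islands, genes, methylome.

    Background sequence is drawn from a dinucleotide Markov chain hitting the
    configured background GC / CpG O/E; island spans are overwritten with
    island-composition sequence. TSS-associated islands get a gene starting
    at the island midpoint, TES-associated ones a gene ending there; extra
    genes up to ``n_genes`` are placed clear of any island. Methylation is
    1/1 at every background CpG (optionally mosaic), 0/0 inside
    nonmethylated islands, 1/0 (maternal/paternal) inside imprinted ones and
    1/1 inside fully methylated ones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chroms
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    codes: dict[str, np.ndarray] = {
        c: generate_sequence(chrom_len, config.background_gc, config.background_oe, rng)
        for c in chroms
    }

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    islands: list[CpGIsland] = []
    genes: list[GeneModel] = []
    n_assoc_genes = 0

    for i, spec in enumerate(config.island_specs):
        chrom = chroms[i % config.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(*config.gene_length_range))
        # extent of the island plus its gene (if any), relative to island start
        if spec.assoc == "TSS":
            anchor = spec.length // 2
            rel = (0, anchor + glen) if strand == "+" else (min(0, anchor - glen + 1), spec.length)
        elif spec.assoc == "TES":
            anchor = spec.length // 2
            rel = (min(0, anchor - glen + 1), spec.length) if strand == "+" else (0, anchor + glen)
        else:
            rel = (0, spec.length)
        rel = (min(rel[0], 0), max(rel[1], spec.length))
        extent_len = rel[1] - rel[0]
        offset = _place(rng, occupied[chrom], extent_len, chrom_len, config.island_gap)
        if offset is None:
            raise SimulationError(f"island spec {i} ({spec.assoc}): placement failed")
        start = offset - rel[0]
        occupied[chrom].append((offset, offset + extent_len))

        isl_codes = generate_sequence(spec.length, spec.gc, spec.oe, rng)
        codes[chrom][start : start + spec.length] = isl_codes
        gc_hat, oe_hat = measure_gc_oe(isl_codes)
        islands.append(
            CpGIsland(
                GenomicInterval(chrom, start, start + spec.length),
                gc=gc_hat,
                oe=oe_hat,
                assoc="other" if spec.assoc == "orphan" else spec.assoc,
                name=f"truth_{i}",
                methylation=spec.methylation,
            )
        )
        if spec.assoc in ("TSS", "TES"):
            mid = start + spec.length // 2
            if spec.assoc == "TSS":
                g = (mid, mid + glen) if strand == "+" else (mid - glen + 1, mid + 1)
            else:
                g = (mid - glen + 1, mid + 1) if strand == "+" else (mid, mid + glen)
            genes.append(GeneModel(chrom, g[0], g[1], strand, f"gene_{len(genes)}"))
            n_assoc_genes += 1

    for _ in range(max(0, config.n_genes - n_assoc_genes)):
        chrom = chroms[int(rng.integers(config.n_chroms))]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(*config.gene_length_range))
        offset = _place(rng, occupied[chrom], glen, chrom_len, config.island_gap)
        if offset is None:
            continue  # crowded genome: fewer background genes, not an error
        occupied[chrom].append((offset, offset + glen))
        genes.append(GeneModel(chrom, offset, offset + glen, strand, f"gene_{len(genes)}"))

    expressed = rng.random(len(genes)) < config.frac_expressed
    for g, e in zip(genes, expressed):
        g.expressed = bool(e)

    meth = Methylome()
    for chrom in chroms:
        pos = _scan_cpg(codes[chrom])
        mat = np.ones(pos.size, dtype=np.int8)
        pat = np.ones(pos.size, dtype=np.int8)
        if config.mosaic_fraction > 0:
            mosaic = rng.random(pos.size) < config.mosaic_fraction
            mat[mosaic] = 0
            pat[mosaic] = 0
        for isl in islands:
            if isl.chrom != chrom:
                continue
            inside = (pos >= isl.start) & (pos < isl.end)
            if isl.methylation == "none":
                mat[inside] = 0
                pat[inside] = 0
            elif isl.methylation == "imprinted_50_50":
                mat[inside] = 1
                pat[inside] = 0
            else:  # full
                mat[inside] = 1
                pat[inside] = 1
        meth.positions[chrom] = pos
        meth.maternal[chrom] = mat
        meth.paternal[chrom] = pat

    genome = {c: codes_to_str(codes[c]) for c in chroms}
    return genome, islands, genes, meth


# ---------------------------------------------------------------------------
# ChIP tag simulation

def _windowed_sum(indicator: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window sum of a per-base indicator array."""
    cum = np.concatenate([[0.0], np.cumsum(indicator)])
    half = window // 2
    n = indicator.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return cum[hi] - cum[lo]


def sampling_weights(
    genome: dict[str, str],
    methylome: Methylome,
    genes: list[GeneModel],
    spec: TrackSpec,
) -> dict[str, np.ndarray]:
    """Per-base tag-sampling weight for one track.

    input/H3: uniform. KDM2A: 1 + (fold - 1) x saturating local density of
    nonmethylated CpGs, so fully methylated islands sit at background.
    H3K36me1/2: uniform x depletion where nonmethylated CpGs are dense,
    further reduced over expressed gene bodies (me2 only). H3K36me3:
    small baseline plus a large gain over expressed gene bodies.
    """
    spec.validate()
    weights: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        n = len(seq)
        if spec.name in ("input", "H3"):
            weights[chrom] = np.ones(n, dtype=np.float64)
            continue
        pos = methylome.positions.get(chrom, np.empty(0, np.int64))
        unmeth = np.zeros(n, dtype=np.float64)
        if pos.size:
            unmeth[pos] = 1.0 - methylome.mean(chrom)
        sat = np.minimum(_windowed_sum(unmeth, spec.cpg_window) / spec.cpg_saturation, 1.0)
        in_expressed_body = np.zeros(n, dtype=bool)
        for g in genes:
            if g.chrom == chrom and g.expressed:
                in_expressed_body[g.start : g.end] = True
        if spec.name == "KDM2A":
            w = 1.0 + (spec.island_fold - 1.0) * sat
        elif spec.name in ("H3K36me1", "H3K36me2"):
            w = 1.0 - (1.0 - spec.island_depletion) * sat
            if spec.name == "H3K36me2":
                w[in_expressed_body] *= spec.body_depletion
        else:  # H3K36me3
            w = np.full(n, spec.baseline)
            w[in_expressed_body] += spec.body_gain
        weights[chrom] = w
    return weights


def simulate_chip_tags(
    genome: dict[str, str],
    methylome: Methylome,
    genes: list[GeneModel],
    spec: TrackSpec,
    seed: int | np.random.Generator = 0,
) -> TagCollection:
    """Draw exactly ``spec.n_tags`` single-end tags from the track's weights.

    A tag's sampled base is the fragment midpoint; the 5' position is then
    midpoint -/+ fragment_length // 2 for + / - strands (clipped to bounds),
    with strands assigned 50/50.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = sampling_weights(genome, methylome, genes, spec)
    chroms = list(weights)
    totals = np.array([weights[c].sum() for c in chroms])
    if totals.sum() <= 0:
        raise SimulationError(f"track {spec.name}: zero total sampling weight")
    counts = rng.multinomial(spec.n_tags, totals / totals.sum())
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    half = spec.fragment_length // 2
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        cdf = np.cumsum(weights[chrom])
        mid = np.searchsorted(cdf, rng.random(k) * cdf[-1], side="right")
        strand = np.where(rng.random(k) < 0.5, 1, -1).astype(np.int8)
        five = np.where(strand > 0, mid - half, mid + half)
        five = np.clip(five, 0, len(weights[chrom]) - 1).astype(np.int64)
        tags[chrom] = (five, strand)
    return TagCollection(name=spec.name, fragment_length=spec.fragment_length, tags=tags)


# ---------------------------------------------------------------------------
# bisulfite clones

@dataclass
class SimulatedClones:
    """Bisulfite clone sequences plus the truth needed for testing."""

    region: GenomicInterval
    reference: str  # unconverted top-strand amplicon
    sequences: list[str]
    alleles: list[str]  # "maternal" | "paternal" per clone
    cpg_positions: np.ndarray  # absolute coordinates of CpG Cs in the region
    truth: np.ndarray  # clones x CpGs methylation of the sampled allele

    def names(self) -> list[str]:
        return [f"clone_{i}|{a}" for i, a in enumerate(self.alleles)]


def simulate_bisulfite_clones(
    region: GenomicInterval,
    genome: dict[str, str],
    methylome: Methylome,
    n_clones: int = 24,
    allele_weights: tuple[float, float] = (0.5, 0.5),
    conversion_rate: float = 0.99,
    seed: int | np.random.Generator = 0,
) -> SimulatedClones:
    """Simulate top-strand bisulfite PCR clones from one amplicon.

    Each clone samples an allele (maternal, paternal) by ``allele_weights``;
    every non-CpG C converts C->T with probability ``conversion_rate``; a
    CpG C converts (at the same rate) only when the sampled allele is
    unmethylated at that site.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if abs(sum(allele_weights) - 1.0) > 1e-9:
        raise ValueError("allele_weights must sum to 1")
    if not (0.0 <= conversion_rate <= 1.0):
        raise ValueError("conversion_rate must be in [0, 1]")
    ref = genome[region.chrom][region.start : region.end].upper()
    idx = methylome.sites_in(region.chrom, region.start, region.end)
    cpg_abs = methylome.positions[region.chrom][idx]
    if cpg_abs.size == 0:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} contains no CpG")
    cpg_rel = cpg_abs - region.start
    mat = methylome.maternal[region.chrom][idx]
    pat = methylome.paternal[region.chrom][idx]

    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    is_c = ref_arr == ord("C")
    cpg_mask = np.zeros(len(ref), dtype=bool)
    cpg_mask[cpg_rel] = True
    non_cpg_c = np.flatnonzero(is_c & ~cpg_mask)

    seqs, alleles, truth = [], [], np.empty((n_clones, cpg_rel.size), dtype=np.int8)
    for i in range(n_clones):
        allele = "maternal" if rng.random() < allele_weights[0] else "paternal"
        meth = mat if allele == "maternal" else pat
        out = ref_arr.copy()
        conv = non_cpg_c[rng.random(non_cpg_c.size) < conversion_rate]
        out[conv] = ord("T")
        unmeth_sites = cpg_rel[meth == 0]
        conv_cpg = unmeth_sites[rng.random(unmeth_sites.size) < conversion_rate]
        out[conv_cpg] = ord("T")
        seqs.append(out.tobytes().decode("ascii"))
        alleles.append(allele)
        truth[i] = meth
    return SimulatedClones(region, ref, seqs, alleles, cpg_abs, truth)


# ---------------------------------------------------------------------------
# sensorgrams

def simulate_sensorgrams(
    params: KineticParams,
    concentrations: np.ndarray,
    t_assoc: float = 120.0,
    t_dissoc: float = 120.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    dt: float = 0.5,
) -> list[Sensorgram]:
    """1:1 Langmuir sensorgrams with additive Gaussian noise.

    Association R(t) = Req (1 - exp(-(kon c + koff) t)) with
    Req = Rmax c / (c + KD); dissociation decays exponentially at koff from
    the end-of-association level.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c in concentrations:
        t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
        assoc = t <= t_assoc
        r = np.empty_like(t)
        r[assoc] = langmuir_response(t[assoc], c, params, phase="association")
        r0 = langmuir_response(t_assoc, c, params, phase="association")
        r[~assoc] = langmuir_response(t[~assoc] - t_assoc, c, params, phase="dissociation", r0=r0)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, r.size)
        out.append(Sensorgram(conc=float(c), times=t, response=r, t_assoc=t_assoc))
    return out


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genes: list[GeneModel],
    n_replicates: int = 3,
    knockdown_fraction: float = 0.6,
    seed: int | np.random.Generator = 0,
    noise_sd_log2: float = 0.1,
    baseline_mean_log2: float = 8.0,
    baseline_sd_log2: float = 2.0,
    kd_transcript: str = "KDM2A",
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-condition expression matrix with a KDM2A knockdown.

    Per-gene log-normal baselines are drawn independently of island status;
    a designated KDM2A transcript is scaled by (1 - knockdown_fraction) in
    the knockdown condition; replicate noise is multiplicative log-normal
    (sd ``noise_sd_log2`` on the log2 scale). Returns (genes x samples
    matrix, sample -> condition labels).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if not (0.0 <= knockdown_fraction <= 1.0):
        raise ValueError("knockdown_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [g.name for g in genes]
    if kd_transcript not in names:
        names = names + [kd_transcript]
    n = len(names)
    baseline = 2.0 ** rng.normal(baseline_mean_log2, baseline_sd_log2, n)
    cols, conds, data = [], [], []
    for cond in ("control", "knockdown"):
        for r in range(n_replicates):
            mu = baseline.copy()
            if cond == "knockdown":
                mu[names.index(kd_transcript)] *= 1.0 - knockdown_fraction
            vals = mu * 2.0 ** rng.normal(0.0, noise_sd_log2, n)
            cols.append(f"{cond}_{r + 1}")
            conds.append(cond)
            data.append(vals)
    df = pd.DataFrame(np.column_stack(data), index=names, columns=cols)
    return df, pd.Series(conds, index=cols, name="condition")
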