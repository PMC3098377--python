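"""ChIP-seq tag densities, meta-profiles and enrichment tables.

Tags are single-end: each record is a 5' position and strand, and every tag
is extended ``fragment_length`` bases 3'-ward for coverage purposes. Density
units are fragment-bp per bp per anchor; an optional per-million scaling is
applied when comparing tracks of different depth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import CpGIsland, GeneModel, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class TagCollection:
    """Aligned single-end ChIP tags for one track.

    ``tags`` maps chromosome -> (positions, strands) where positions are 5'
    coordinates sorted ascending and strands are +1 / -1 (int8) aligned with
    them.
    """

    name: str
    fragment_length: int = 150
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        fixed = {}
        for chrom, (pos, strand) in self.tags.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            if pos.shape != strand.shape:
                raise ValueError("positions and strands must align")
            order = np.argsort(pos, kind="stable")
            fixed[chrom] = (pos[order], strand[order])
        self.tags = fixed

    @property
    def total_tags(self) -> int:
        return int(sum(p.size for p, _ in self.tags.values()))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.tags.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int8)))[0]

    def fragments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Half-open extended-fragment spans [start, end) on one chromosome.

        A + tag at p covers [p, p + L); a - tag at p covers (p - L, p], i.e.
        [p - L + 1, p + 1).
        """
        pos, strand = self.tags.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int8)))
        starts = np.where(strand >= 0, pos, pos - self.fragment_length + 1)
        return starts, starts + self.fragment_length


@dataclass
class MetaProfile:
    """Average tag-density profile over a set of anchors."""

    kind: str  # "TSS" | "scaled_island"
    positions: np.ndarray  # bp offsets, or scaled units for islands
    values: np.ndarray
    n_anchors: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    name: str


def coverage(tags: TagCollection, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base extended-fragment coverage over [start, end)."""
    if end <= start:
        return np.zeros(0, dtype=np.float64)
    fs, fe = tags.fragments(chrom)
    s = np.clip(fs, start, end)
    e = np.clip(fe, start, end)
    keep = e > s
    diff = np.zeros(end - start + 1, dtype=np.float64)
    np.add.at(diff, s[keep] - start, 1.0)
    np.add.at(diff, e[keep] - start, -1.0)
    return np.cumsum(diff)[:-1]


def tag_density(tags: TagCollection, region: GenomicInterval, bin_size: int = 1) -> np.ndarray:
    """Mean fragment coverage per bin over ``region``.

    Bin value = overlapping extended-fragment bp / bin_size (the trailing
    partial bin, if any, is also divided by the full bin_size so that
    sum(density) * bin_size equals the total fragment bp in the region).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    cov = coverage(tags, region.chrom, region.start, region.end)
    if cov.size == 0:
        return cov
    if tags.total_tags == 0:
        log.warning("tag_density on empty track %s", tags.name)
    edges = np.arange(0, cov.size, bin_size)
    sums = np.add.reduceat(cov, edges)
    return sums / bin_size


def tss_metaprofile(
    tags: TagCollection,
    genes: Sequence[GeneModel],
    half_window: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
    per_million: bool = False,
) -> MetaProfile:
    """Average density in a +/- half_window region around every TSS.

    Per-gene vectors are reversed for minus-strand genes so upstream is
    always on the left. Genes whose window exceeds chromosome bounds are
    dropped (and counted in the log).
    """
    acc = np.zeros(2 * half_window, dtype=np.float64)
    used = dropped = 0
    for g in genes:
        lo, hi = g.tss - half_window, g.tss + half_window
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        if lo < 0 or (size is not None and hi > size):
            dropped += 1
            continue
        cov = coverage(tags, g.chrom, lo, hi)
        if g.strand == "-":
            cov = cov[::-1]
        acc += cov
        used += 1
    if used == 0:
        raise ValueError("no usable genes for TSS meta-profile")
    if dropped:
        log.info("tss_metaprofile dropped %d/%d genes at chromosome bounds", dropped, len(genes))
    values = acc / used
    if per_million and tags.total_tags:
        values = values * 1e6 / tags.total_tags
    return MetaProfile("TSS", np.arange(-half_window, half_window), values, used)


def _rebin(cum: np.ndarray, origin: float, edges: np.ndarray) -> np.ndarray:
    """Mean coverage per (possibly fractional) bin from a cumulative array."""
    x = np.arange(cum.size, dtype=np.float64)
    vals = np.interp(edges - origin, x, cum)
    widths = np.diff(edges)
    return np.diff(vals) / np.maximum(widths, 1e-12)


def scaled_island_metaprofile(
    tags: TagCollection,
    islands: Sequence[CpGIsland],
    n_bins_island: int = 50,
    flank_lengths: float = 1.0,
    flank_mode: str = "scaled",
    fixed_flank_bp: int = 2000,
    per_million: bool = False,
) -> MetaProfile:
    """Length-normalised island meta-profile with flanks.

    Each island span maps to scaled coordinates [0, 1] in ``n_bins_island``
    bins; flanks of ``flank_lengths`` x island-length (or ``fixed_flank_bp``
    when flank_mode="fixed") map to [-flank_lengths, 0) and
    (1, 1 + flank_lengths]. Values are mean density (fragment-bp per bp)
    across islands. Regions beyond chromosome start contribute zero coverage.
    """
    if not islands:
        raise ValueError("no islands given")
    if flank_mode not in ("scaled", "fixed"):
        raise ValueError("flank_mode must be 'scaled' or 'fixed'")
    n_flank = max(1, int(round(n_bins_island * flank_lengths)))
    n_total = n_bins_island + 2 * n_flank
    acc = np.zeros(n_total, dtype=np.float64)
    short = 0
    for isl in islands:
        L = len(isl)
        if L < n_bins_island:
            short += 1
        flank = flank_lengths * L if flank_mode == "scaled" else float(fixed_flank_bp)
        lo = isl.start - flank
        hi = isl.end + flank
        clip_lo = max(0, int(np.floor(lo)))
        cov = coverage(tags, isl.chrom, clip_lo, int(np.ceil(hi)))
        cum = np.concatenate([[0.0], np.cumsum(cov)])
        edges = np.concatenate(
            [
                np.linspace(lo, isl.start, n_flank + 1)[:-1],
                np.linspace(isl.start, isl.end, n_bins_island + 1)[:-1],
                np.linspace(isl.end, hi, n_flank + 1),
            ]
        )
        edges = np.clip(edges, clip_lo, None)  # below-origin bases: zero coverage
        acc += _rebin(cum, clip_lo, edges)
    if short:
        log.info("%d islands shorter than n_bins_island; fractional bins used", short)
    values = acc / len(islands)
    if per_million and tags.total_tags:
        values = values * 1e6 / tags.total_tags
    scaled_edges = np.concatenate(
        [
            np.linspace(-flank_lengths, 0, n_flank + 1)[:-1],
            np.linspace(0, 1, n_bins_island + 1)[:-1],
            np.linspace(1, 1 + flank_lengths, n_flank + 1),
        ]
    )
    centers = (scaled_edges[:-1] + scaled_edges[1:]) / 2
    return MetaProfile("scaled_island", centers, values, len(islands))


def _amplicons_frame(amplicons) -> pd.DataFrame:
    if isinstance(amplicons, pd.DataFrame):
        return amplicons.reset_index(drop=True)
    rows = []
    for a in amplicons:
        if isinstance(a, (tuple, list)):
            iv, gene, region = a
            rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                         "gene": gene, "region": region})
        else:
            rows.append({"chrom": a.chrom, "start": a.start, "end": a.end,
                         "gene": "", "region": ""})
    return pd.DataFrame(rows)


def percent_input(ip: TagCollection, input_tags: TagCollection, amplicons) -> pd.DataFrame:
    """Library-size-normalised percent-of-input proxy per amplicon.

    value = (IP fragment-bp density / IP total tags) /
            (input fragment-bp density / input total tags) * 100.
    Amplicons with zero input coverage are flagged undefined (NaN) and should
    be excluded downstream.
    """
    if input_tags.total_tags == 0:
        raise ValueError("input track is empty")
    amp = _amplicons_frame(amplicons)
    vals = []
    for _, row in amp.iterrows():
        ip_bp = coverage(ip, row.chrom, int(row.start), int(row.end)).sum()
        in_bp = coverage(input_tags, row.chrom, int(row.start), int(row.end)).sum()
        if in_bp == 0:
            vals.append(np.nan)
        elif ip.total_tags == 0:
            vals.append(0.0)
        else:
            vals.append((ip_bp / ip.total_tags) / (in_bp / input_tags.total_tags) * 100.0)
    out = amp.copy()
    out["track"] = ip.name
    out["percent_input"] = vals
    return out


def h3_normalize(mod_table: pd.DataFrame, h3_table: pd.DataFrame) -> pd.DataFrame:
    """Normalise a modification's percent-input to histone H3 occupancy.

    Controls for nucleosome density: a low modification signal over a region
    that simply has fewer nucleosomes is not a specific depletion. Requires
    identical amplicon sets; H3 values of zero yield NaN (excluded downstream).
    """
    key = ["chrom", "start", "end"]
    a = mod_table.sort_values(key).reset_index(drop=True)
    b = h3_table.sort_values(key).reset_index(drop=True)
    if not (a[key].values == b[key].values).all():
        raise ValueError("amplicon sets differ between modification and H3 tables")
    out = a.copy()
    denom = b["percent_input"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = a["percent_input"].to_numpy(dtype=float) / denom
    norm[denom == 0] = np.nan
    out["normalized"] = norm
    return out


def promoter_body_test(
    table: pd.DataFrame,
    value_col: str | None = None,
    paired: bool = True,
) -> TestResult:
    """Two-sided test of promoter vs gene-body enrichment across genes.

    Defaults to a paired t-test on per-gene (promoter - body) values; Welch's
    unpaired t-test is available with paired=False. Requires >= 3 genes with
    both values defined.
    """
    col = value_col or ("normalized" if "normalized" in table.columns else "percent_input")
    piv = table.pivot_table(index="gene", columns="region", values=col, aggfunc="mean")
    if "promoter" not in piv.columns or "body" not in piv.columns:
        raise ValueError("table must contain promoter and body amplicons")
    piv = piv.dropna(subset=["promoter", "body"])
    n = len(piv)
    if n < 3:
        raise ValueError(f"need >= 3 genes with promoter and body values, got {n}")
    prom = piv["promoter"].to_numpy(dtype=float)
    body = piv["body"].to_numpy(dtype=float)
    if paired:
        diffs = prom - body
        if np.allclose(diffs, 0.0):
            return TestResult(0.0, 1.0, n, "paired t-test")
        stat, p = stats.ttest_rel(prom, body)
        return TestResult(float(stat), float(p), n, "paired t-test")
    stat, p = stats.ttest_ind(prom, body, equal_var=False)
    return TestResult(float(stat), float(p), n, "Welch t-test")
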