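"""KDM2A-enriched region calling and CpG-island occupancy statistics.

Peak calling is a windowed Poisson test against library-size-scaled input
(floored at the genome-wide background rate), Benjamini-Hochberg corrected
across all windows; passing windows are merged into peaks. Occupancy is the
fraction of islands with at least ``min_overlap`` bp of peak overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .cgi import cpg_oe_ratio, gc_fraction
from .intervals import CpGIsland, GeneModel, GenomicInterval, merge_intervals
from .profiles import TagCollection, TestResult, coverage


@dataclass
class Peak:
    interval: GenomicInterval
    ip_count: int
    input_scaled: float
    fold: float
    p_value: float
    q_value: float
    summit: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def _infer_sizes(*tracks: TagCollection) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for tc in tracks:
        for chrom, (pos, _) in tc.tags.items():
            if pos.size:
                hi = int(pos.max()) + tc.fragment_length
                sizes[chrom] = max(sizes.get(chrom, 0), hi)
    return sizes


def call_peaks(
    ip: TagCollection,
    input_tags: TagCollection,
    chrom_sizes: Mapping[str, int] | None = None,
    window: int = 500,
    step: int = 250,
    fdr: float = 0.05,
    min_fold: float = 2.0,
) -> list[Peak]:
    """Call IP-enriched regions against input.

    Each window's IP tag count is tested against a Poisson rate equal to the
    scaled input count, floored at the genome-wide expected IP count per
    window; q-values are BH across all windows genome-wide. Overlapping
    windows passing both the FDR and ``min_fold`` are merged, and the summit
    is the maximum-coverage base inside the merged span.
    """
    if ip.total_tags == 0 or input_tags.total_tags == 0:
        raise ValueError("both IP and input tracks must be non-empty")
    sizes = dict(chrom_sizes) if chrom_sizes else _infer_sizes(ip, input_tags)
    genome_len = sum(sizes.values())
    scale = ip.total_tags / input_tags.total_tags
    background = ip.total_tags * window / genome_len

    recs = []  # (chrom, start, ip_count, lam)
    for chrom, size in sizes.items():
        if size < window:
            continue
        starts = np.arange(0, size - window + 1, step, dtype=np.int64)
        ip_pos = ip.chrom_positions(chrom)
        in_pos = input_tags.chrom_positions(chrom)
        ipc = np.searchsorted(ip_pos, starts + window) - np.searchsorted(ip_pos, starts)
        inc = np.searchsorted(in_pos, starts + window) - np.searchsorted(in_pos, starts)
        lam = np.maximum(inc * scale, background)
        for s, k, l in zip(starts, ipc, lam):
            recs.append((chrom, int(s), int(k), float(l)))
    if not recs:
        return []
    pvals = np.array([stats.poisson.sf(k - 1, l) if k > 0 else 1.0 for _, _, k, l in recs])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    folds = np.array([k / l for _, _, k, l in recs])
    passing = (qvals <= fdr) & (folds >= min_fold) & (np.array([k for _, _, k, _ in recs]) > 0)

    by_chrom: dict[str, list[int]] = {}
    for i in np.flatnonzero(passing):
        by_chrom.setdefault(recs[i][0], []).append(i)

    peaks: list[Peak] = []
    for chrom, idxs in by_chrom.items():
        spans = merge_intervals([(recs[i][1], recs[i][1] + window) for i in idxs])
        members: dict[tuple[int, int], list[int]] = {sp: [] for sp in spans}
        for i in idxs:
            s = recs[i][1]
            for sp in spans:
                if sp[0] <= s < sp[1]:
                    members[sp].append(i)
                    break
        ip_pos = ip.chrom_positions(chrom)
        in_pos = input_tags.chrom_positions(chrom)
        for (s, e), mem in members.items():
            k = int(np.searchsorted(ip_pos, e) - np.searchsorted(ip_pos, s))
            inc = float(np.searchsorted(in_pos, e) - np.searchsorted(in_pos, s))
            lam = max(inc * scale, background * (e - s) / window)
            cov = coverage(ip, chrom, s, e)
            summit = s + int(np.argmax(cov)) if cov.size else s
            peaks.append(
                Peak(
                    GenomicInterval(chrom, s, e),
                    ip_count=k,
                    input_scaled=lam,
                    fold=k / lam if lam > 0 else np.inf,
                    p_value=float(min(pvals[i] for i in mem)),
                    q_value=float(min(qvals[i] for i in mem)),
                    summit=summit,
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


@dataclass
class OccupancyReport:
    """Island-occupancy fractions plus non-island peak characterisation."""

    n_islands: int
    n_occupied: int
    fraction: float
    n_tss_islands: int
    n_tss_occupied: int
    tss_fraction: float
    non_island_peaks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {
            "n_islands": self.n_islands,
            "n_occupied": self.n_occupied,
            "fraction": self.fraction,
            "n_tss_islands": self.n_tss_islands,
            "n_tss_occupied": self.n_tss_occupied,
            "tss_fraction": self.tss_fraction,
            "n_non_island_peaks": int(len(self.non_island_peaks)),
        }
        return d


def island_occupancy(
    peaks: Sequence[Peak],
    islands: Sequence[CpGIsland],
    genome: Mapping[str, str] | None = None,
    min_overlap: int = 1,
) -> OccupancyReport:
    """Fraction of islands overlapped by at least one peak.

    Computed overall and restricted to TSS-associated islands. Peaks that
    touch no island are returned with their spans' GC fraction and CpG O/E
    when ``genome`` is provided (the 'missed island' characterisation).
    """
    if not islands:
        raise ValueError("empty island set")
    peak_spans: dict[str, np.ndarray] = {}
    for p in peaks:
        peak_spans.setdefault(p.chrom, []).append((p.start, p.end))
    peak_spans = {
        c: np.array(merge_intervals(v), dtype=np.int64).reshape(-1, 2)
        for c, v in peak_spans.items()
    }

    def overlap_bp(chrom: str, start: int, end: int) -> int:
        spans = peak_spans.get(chrom)
        if spans is None or spans.size == 0:
            return 0
        lo = np.clip(spans[:, 0], start, end)
        hi = np.clip(spans[:, 1], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    occupied = np.array([overlap_bp(i.chrom, i.start, i.end) >= min_overlap for i in islands])
    is_tss = np.array([i.assoc == "TSS" for i in islands])
    n, n_occ = len(islands), int(occupied.sum())
    n_tss, n_tss_occ = int(is_tss.sum()), int((occupied & is_tss).sum())

    rows = []
    for p in peaks:
        hit = any(
            isl.chrom == p.chrom and min(isl.end, p.end) - max(isl.start, p.start) >= min_overlap
            for isl in islands
        )
        if hit:
            continue
        row = {"chrom": p.chrom, "start": p.start, "end": p.end, "fold": p.fold}
        if genome is not None:
            span = str(genome[p.chrom])[p.start : p.end]
            row["gc"] = gc_fraction(span)
            row["oe"] = cpg_oe_ratio(span)
        rows.append(row)

    return OccupancyReport(
        n_islands=n,
        n_occupied=n_occ,
        fraction=n_occ / n,
        n_tss_islands=n_tss,
        n_tss_occupied=n_tss_occ,
        tss_fraction=n_tss_occ / n_tss if n_tss else float("nan"),
        non_island_peaks=pd.DataFrame(rows),
    )


def expression_vs_tags(
    tags: TagCollection,
    genes: Sequence[GeneModel],
    expression: Mapping[str, float] | pd.Series,
    tss_half_window: int = 1000,
    loess_span: float = 0.3,
):
    """Relate expression level to TSS-proximal tag count across genes.

    Returns (per-gene DataFrame, (grid, loess fit), Spearman TestResult).
    The loess trend is evaluated on a 100-point grid over the expression
    range. A constant expression vector makes the correlation undefined
    (NaN, flagged via the test name); a constant tag vector gives rho = 0.
    """
    if len(genes) < 10:
        raise ValueError("need >= 10 genes")
    x, y, names = [], [], []
    for g in genes:
        if g.name not in expression:
            raise KeyError(f"no expression value for gene {g.name}")
        pos = tags.chrom_positions(g.chrom)
        lo, hi = g.tss - tss_half_window, g.tss + tss_half_window
        y.append(int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo)))
        x.append(float(expression[g.name]))
        names.append(g.name)
    x = np.array(x)
    y = np.array(y, dtype=float)
    pairs = pd.DataFrame({"gene": names, "expression": x, "tag_count": y})

    grid = np.linspace(x.min(), x.max(), 100)
    if np.ptp(x) == 0:
        trend = np.full(100, y.mean())
        rho = TestResult(float("nan"), float("nan"), len(x), "spearman (undefined: constant x)")
        return pairs, (grid, trend), rho
    if np.ptp(y) == 0:  # flat tag counts: loess is the constant, rho is 0
        trend = np.full(100, y[0])
        rho = TestResult(0.0, 1.0, len(x), "spearman (constant y)")
        return pairs, (grid, trend), rho
    trend = lowess(y, x, frac=loess_span, xvals=grid)
    r, p = stats.spearmanr(x, y)
    rho = TestResult(float(r), float(p), len(x), "spearman")
    return pairs, (grid, trend), rho


def volcano(
    expr: pd.DataFrame,
    conditions: pd.Series,
    control: str = "control",
    knockdown: str = "knockdown",
) -> pd.DataFrame:
    """Per-transcript log2 fold change (knockdown/control) and two-sided t p.

    Uses the pooled-variance two-sample t-test. Transcripts with a
    nonpositive mean in either condition are flagged and excluded. Rows are
    ordered by p-value.
    """
    a_cols = conditions.index[conditions == control]
    b_cols = conditions.index[conditions == knockdown]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    rows, excluded = [], []
    for gene, row in expr.iterrows():
        a = row[a_cols].to_numpy(dtype=float)
        b = row[b_cols].to_numpy(dtype=float)
        if a.mean() <= 0 or b.mean() <= 0:
            excluded.append(gene)
            continue
        t, p = stats.ttest_ind(b, a, equal_var=True)
        rows.append({"transcript": gene, "log2fc": float(np.log2(b.mean() / a.mean())),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out
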