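"""CpG-island prediction from sequence.

Implements the classical sliding-window island criteria: windows of
``window`` bp qualifying on GC content and CpG observed/expected ratio are
merged into maximal runs, trimmed so the reported interval itself satisfies
all thresholds, and filtered on a minimum length. Thresholds default to the
canonical (200 bp, GC >= 0.50, O/E >= 0.60) lineage and are fully
parameterised so stricter prediction sets can be mimicked.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .intervals import CpGIsland, GeneModel, GenomicInterval, merge_intervals

log = logging.getLogger(__name__)

_A, _C, _G, _T, _N = ord("A"), ord("C"), ord("G"), ord("T"), ord("N")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _counts(arr: np.ndarray) -> tuple[int, int, int, int, int]:
    """(#C, #G, #CpG, #N, non-N length) for an encoded sequence."""
    is_c = arr == _C
    is_g = arr == _G
    known = is_c | is_g | (arr == _A) | (arr == _T)
    n_n = int(arr.size - known.sum())
    n_cg = int((is_c[:-1] & is_g[1:]).sum()) if arr.size > 1 else 0
    return int(is_c.sum()), int(is_g.sum()), n_cg, n_n, int(known.sum())


def gc_fraction(seq: str) -> float:
    """(#C + #G) / #non-N bases. N bases are excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    n_c, n_g, _, _, non_n = _counts(_encode(seq))
    if non_n == 0:
        raise ValueError("sequence contains only N bases")
    return (n_c + n_g) / non_n


def cpg_oe_ratio(seq: str) -> float:
    """CpG observed/expected ratio: (#CpG x L) / (#C x #G), L = non-N length.

    Returns 0 when the sequence has no C or no G.
    """
    if not seq:
        raise ValueError("empty sequence")
    n_c, n_g, n_cg, _, non_n = _counts(_encode(seq))
    if non_n == 0:
        raise ValueError("sequence contains only N bases")
    if n_c * n_g == 0:
        return 0.0
    return n_cg * non_n / (n_c * n_g)


def _window_stats(arr: np.ndarray, window: int, step: int):
    """Vectorised per-window (GC, O/E, non-N) via cumulative sums."""
    is_c = (arr == _C).astype(np.int64)
    is_g = (arr == _G).astype(np.int64)
    known = ((arr == _A) | (arr == _T)).astype(np.int64) + is_c + is_g
    is_cg = np.zeros(arr.size, dtype=np.int64)
    if arr.size > 1:
        is_cg[:-1] = (arr[:-1] == _C) & (arr[1:] == _G)

    def cum(x):
        out = np.zeros(x.size + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    c_c, c_g, c_k, c_cg = cum(is_c), cum(is_g), cum(known), cum(is_cg)
    starts = np.arange(0, arr.size - window + 1, step, dtype=np.int64)
    ends = starts + window
    n_c = c_c[ends] - c_c[starts]
    n_g = c_g[ends] - c_g[starts]
    non_n = c_k[ends] - c_k[starts]
    # CpG pairs fully inside the window start in [s, s+w-1)
    n_cg = c_cg[ends - 1] - c_cg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(non_n > 0, (n_c + n_g) / np.maximum(non_n, 1), 0.0)
        oe = np.where(n_c * n_g > 0, n_cg * non_n / np.maximum(n_c * n_g, 1), 0.0)
    return starts, gc, oe, non_n


def _snap_to_cpg(arr: np.ndarray, start: int, end: int):
    """Clip [start, end) to the outermost CpG it contains.

    Window-run boundaries overshoot into CpG-poor flanks by up to a window
    length; anchoring the reported interval at its first and last CpG removes
    that slop. Returns None when the span holds no CpG at all.
    """
    sub = arr[start:end]
    cg = np.flatnonzero((sub[:-1] == _C) & (sub[1:] == _G))
    if cg.size == 0:
        return None
    return start + int(cg[0]), start + int(cg[-1]) + 2


def _trim(arr: np.ndarray, start: int, end: int, min_length: int, min_gc: float, min_oe: float):
    """Shrink [start, end) until the interval itself passes all thresholds.

    Trims one base at a time, preferring to drop terminal non-G/C bases.
    Returns None when the interval shrinks below min_length before passing.
    """
    while end - start >= max(min_length, 1):
        sub = arr[start:end]
        n_c, n_g, n_cg, _, non_n = _counts(sub)
        if non_n > 0:
            gc = (n_c + n_g) / non_n
            oe = n_cg * non_n / (n_c * n_g) if n_c * n_g > 0 else 0.0
            if gc >= min_gc and oe >= min_oe:
                return start, end, gc, oe
        if sub[0] not in (_C, _G):
            start += 1
        elif sub[-1] not in (_C, _G):
            end -= 1
        else:
            end -= 1
    return None


def detect_islands(
    genome: Mapping[str, str],
    min_length: int = 200,
    min_gc: float = 0.50,
    min_oe: float = 0.60,
    window: int = 200,
    step: int = 1,
    max_n_frac: float = 0.5,
) -> list[CpGIsland]:
    """Predict CpG islands on every chromosome of ``genome``.

    Windows with more than ``max_n_frac`` N are skipped. Chromosomes shorter
    than ``window`` yield no islands. Output is coordinate-sorted and
    non-overlapping, and every reported interval individually satisfies the
    length, GC and O/E thresholds.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    islands: list[CpGIsland] = []
    k = 0
    for chrom in genome:
        seq = str(genome[chrom])
        arr = _encode(seq)
        if arr.size < window:
            continue
        starts, gc, oe, non_n = _window_stats(arr, window, step)
        qual = (non_n >= window * (1.0 - max_n_frac)) & (gc >= min_gc) & (oe >= min_oe)
        if not qual.any():
            continue
        spans = merge_intervals([(int(s), int(s) + window) for s in starts[qual]])
        for s, e in spans:
            if min_oe > 0:  # anchor ends at CpGs unless CpG-free islands are allowed
                snapped = _snap_to_cpg(arr, s, e)
                if snapped is None:
                    continue
                s, e = snapped
            trimmed = _trim(arr, s, e, min_length, min_gc, min_oe)
            if trimmed is None:
                continue
            ts, te, tgc, toe = trimmed
            k += 1
            islands.append(
                CpGIsland(GenomicInterval(chrom, ts, te), gc=tgc, oe=toe, name=f"CGI_{k}")
            )
    return islands


def classify_islands(
    islands: Sequence[CpGIsland],
    genes: Sequence[GeneModel],
    tss_window: int = 1000,
) -> list[CpGIsland]:
    """Assign each island's association class: TSS, TES or other.

    An island is TSS-associated if it overlaps any gene's TSS +/- tss_window;
    otherwise TES-associated by the same rule at TESs; otherwise "other".
    TSS takes precedence over TES.
    """
    by_chrom_tss: dict[str, np.ndarray] = {}
    by_chrom_tes: dict[str, np.ndarray] = {}
    for g in genes:
        by_chrom_tss.setdefault(g.chrom, []).append(g.tss)  # type: ignore[union-attr]
        by_chrom_tes.setdefault(g.chrom, []).append(g.tes)  # type: ignore[union-attr]
    by_chrom_tss = {c: np.sort(np.asarray(v)) for c, v in by_chrom_tss.items()}
    by_chrom_tes = {c: np.sort(np.asarray(v)) for c, v in by_chrom_tes.items()}

    def hits(pos_sorted: np.ndarray | None, start: int, end: int) -> bool:
        if pos_sorted is None or pos_sorted.size == 0:
            return False
        # island overlaps [pos - w, pos + w + 1) for some anchor pos
        lo = np.searchsorted(pos_sorted, start - tss_window)
        hi = np.searchsorted(pos_sorted, end + tss_window - 1, side="right")
        return hi > lo

    out = []
    for isl in islands:
        if hits(by_chrom_tss.get(isl.chrom), isl.start, isl.end):
            assoc = "TSS"
        elif hits(by_chrom_tes.get(isl.chrom), isl.start, isl.end):
            assoc = "TES"
        else:
            assoc = "other"
        out.append(
            CpGIsland(isl.interval, isl.gc, isl.oe, assoc=assoc, name=isl.name,
                      strength=isl.strength, methylation=isl.methylation)
        )
    return out


def split_strength(islands: Sequence[CpGIsland]) -> list[CpGIsland]:
    """Label islands strong/weak by a length x O/E score split at the median.

    A stand-in definition: no canonical strong/weak criterion exists, so the
    score split is exposed for exploratory contrasts only.
    """
    if not islands:
        return []
    scores = np.array([len(i) * i.oe for i in islands])
    med = float(np.median(scores))
    out = []
    for isl, s in zip(islands, scores):
        out.append(
            CpGIsland(isl.interval, isl.gc, isl.oe, assoc=isl.assoc, name=isl.name,
                      strength="strong" if s >= med else "weak", methylation=isl.methylation)
        )
    return out
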