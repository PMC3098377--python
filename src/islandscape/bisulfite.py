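"""Bisulfite clone methylation calling and allele-resolved analysis.

Clones are top-strand PCR-amplicon sequences compared ungapped against the
unconverted reference: a retained C at a reference CpG reports methylation,
a T reports an unmethylated (converted) cytosine. Conversion efficiency is
measured at non-CpG reference cytosines, which should always read T; clones
below the efficiency cutoff are rejected as failed conversions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .profiles import TestResult

METH, UNMETH, MISSING = 1, 0, -1


class CloneRejected(Exception):
    """Raised (or recorded) when a clone fails alignment or conversion QC."""


@dataclass
class CloneSet:
    """Clones x CpG-site methylation calls for one amplicon."""

    region: GenomicInterval
    cpg_positions: np.ndarray  # absolute coordinate of each CpG C
    matrix: np.ndarray  # int8, clones x CpGs, values {1, 0, -1}
    conversion: np.ndarray  # per-clone efficiency in [0, 1]
    clone_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.cpg_positions):
            raise ValueError("matrix columns must match cpg_positions")
        if self.matrix.shape[0] != len(self.clone_names):
            raise ValueError("matrix rows must match clone_names")

    @property
    def n_clones(self) -> int:
        return self.matrix.shape[0]

    def clone_meth_fraction(self) -> np.ndarray:
        """Fraction of methylated calls per clone, over informative sites."""
        informative = self.matrix != MISSING
        meth = self.matrix == METH
        with np.errstate(invalid="ignore"):
            return np.where(
                informative.sum(axis=1) > 0,
                meth.sum(axis=1) / np.maximum(informative.sum(axis=1), 1),
                np.nan,
            )


@dataclass
class AlleleCallSummary:
    n_clones: int
    n_methylated: int
    n_nonmethylated: int
    n_partial: int
    percent_methylated: float


def reference_cpg_sites(reference: str) -> np.ndarray:
    """0-based indices of the C of every CG in the reference amplicon."""
    arr = np.frombuffer(reference.upper().encode(), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)


def call_methylation(
    clone_seq: str,
    reference: str,
    max_mismatch: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Per-CpG methylation calls and conversion efficiency for one clone.

    The clone must be full length (exact-position, ungapped comparison). At
    each reference CpG C: clone C -> methylated, T -> unmethylated, anything
    else -> missing. Efficiency = T / (T + C) at non-CpG reference Cs.
    Raises CloneRejected when the mismatch rate at non-C reference positions
    exceeds ``max_mismatch``.
    """
    clone = clone_seq.upper()
    ref = reference.upper()
    if len(clone) != len(ref):
        raise CloneRejected(f"length mismatch: clone {len(clone)} vs reference {len(ref)}")
    c_arr = np.frombuffer(clone.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    cpg = reference_cpg_sites(ref)
    is_ref_c = r_arr == ord("C")
    non_c = ~is_ref_c
    if non_c.sum() > 0:
        mm = float((c_arr[non_c] != r_arr[non_c]).mean())
        if mm > max_mismatch:
            raise CloneRejected(f"mismatch rate {mm:.3f} at non-C positions exceeds {max_mismatch}")
    cpg_mask = np.zeros(r_arr.size, dtype=bool)
    cpg_mask[cpg] = True
    non_cpg_c = is_ref_c & ~cpg_mask
    n_t = int((c_arr[non_cpg_c] == ord("T")).sum())
    n_c = int((c_arr[non_cpg_c] == ord("C")).sum())
    eff = n_t / (n_t + n_c) if (n_t + n_c) > 0 else 1.0
    calls = np.full(cpg.size, MISSING, dtype=np.int8)
    calls[c_arr[cpg] == ord("C")] = METH
    calls[c_arr[cpg] == ord("T")] = UNMETH
    return calls, eff


def build_clone_set(
    clones: dict[str, str],
    reference: str,
    region: GenomicInterval,
    min_conversion: float = 0.95,
    max_mismatch: float = 0.1,
) -> tuple[CloneSet, list[tuple[str, str]]]:
    """Call every clone against the reference; QC-failing clones are returned
    separately with the rejection reason, never silently dropped."""
    cpg = reference_cpg_sites(reference) + region.start
    rows, names, effs, rejected = [], [], [], []
    for name, seq in clones.items():
        try:
            calls, eff = call_methylation(seq, reference, max_mismatch=max_mismatch)
        except CloneRejected as exc:
            rejected.append((name, str(exc)))
            continue
        if eff < min_conversion:
            rejected.append((name, f"conversion efficiency {eff:.3f} < {min_conversion}"))
            continue
        rows.append(calls)
        names.append(name)
        effs.append(eff)
    matrix = np.array(rows, dtype=np.int8) if rows else np.empty((0, cpg.size), dtype=np.int8)
    cs = CloneSet(region, cpg, matrix, np.array(effs, dtype=float), names)
    return cs, rejected


def classify_clones(calls: CloneSet, hi: float = 0.8, lo: float = 0.2) -> AlleleCallSummary:
    """Classify clones into methylated / nonmethylated / partial alleles.

    A clone is methylated when its methylated-CpG fraction is >= ``hi``,
    nonmethylated when <= ``lo``, otherwise partial (mosaic clones are
    reported, not dropped). percent_methylated is over classified clones
    only, on the 0-100 scale.
    """
    if calls.n_clones == 0:
        raise ValueError("no clones surviving QC")
    frac = calls.clone_meth_fraction()
    n_meth = int(np.sum(frac >= hi))
    n_non = int(np.sum(frac <= lo))
    n_partial = calls.n_clones - n_meth - n_non
    informative = n_meth + n_non
    pct = 100.0 * n_meth / informative if informative else float("nan")
    return AlleleCallSummary(calls.n_clones, n_meth, n_non, n_partial, pct)


def allele_enrichment_test(
    chip: AlleleCallSummary, input_: AlleleCallSummary
) -> tuple[TestResult, float]:
    """Is the ChIP material enriched for the nonmethylated allele?

    ratio = (nonmethylated fraction in ChIP) / (nonmethylated fraction in
    input); p from a two-sided Fisher exact test on the 2x2 table of
    [nonmethylated, methylated] clone counts.
    """
    for s, label in ((chip, "ChIP"), (input_, "input")):
        if s.n_methylated + s.n_nonmethylated < 1:
            raise ValueError(f"no informative clones in {label}")
    table = np.array(
        [
            [chip.n_nonmethylated, chip.n_methylated],
            [input_.n_nonmethylated, input_.n_methylated],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    chip_frac = chip.n_nonmethylated / (chip.n_nonmethylated + chip.n_methylated)
    input_frac = input_.n_nonmethylated / (input_.n_nonmethylated + input_.n_methylated)
    ratio = chip_frac / input_frac if input_frac > 0 else float("inf")
    n = int(table.sum())
    return TestResult(float(ratio), float(p), n, "Fisher exact (allele enrichment)"), float(ratio)


_GLYPHS = {METH: "●", UNMETH: "○", MISSING: "·"}
_INVERSE = {v: k for k, v in _GLYPHS.items()}


def lollipop_render(calls: CloneSet) -> str:
    """Text lollipop diagram: one line per clone, filled circle = methylated,
    empty circle = nonmethylated, middle dot = missing."""
    return "\n".join(
        "".join(_GLYPHS[int(v)] for v in row) for row in calls.matrix
    )


def parse_lollipop(text: str) -> np.ndarray:
    """Inverse of lollipop_render: diagram back to a calls matrix."""
    rows = [[_INVERSE[ch] for ch in line] for line in text.splitlines() if line]
    return np.array(rows, dtype=np.int8)
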