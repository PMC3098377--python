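"""Dinucleotide Markov-chain DNA synthesis with GC and CpG O/E targets.

The chain has two transition rows: one used after a C, one used everywhere
else. The after-C row carries a reduced (or raised) probability of emitting G,
which sets the CpG observed/expected ratio; both rows share a common base
composition that sets GC content. Row parameters are tuned by fixed-point
iteration against the chain's stationary distribution, and each emitted
sequence is verified by direct counting with rejection outside a tolerance.
"""
from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SequenceGenerationError(RuntimeError):
    pass


def tune_chain(gc: float, oe: float, n_iter: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Return (p, q): base probabilities after a non-C base and after a C.

    The stationary composition of the resulting chain hits ``gc`` and the
    stationary CpG observed/expected ratio hits ``oe`` (to within the
    fixed-point convergence, typically <1e-6).
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc target must be in (0, 1)")
    if oe < 0.0:
        raise ValueError("oe target must be >= 0")
    g_adj, r_adj = gc, max(oe, 1e-6)
    p = q = None
    for _ in range(n_iter):
        g_adj = float(np.clip(g_adj, 0.02, 0.98))
        p = np.array([(1 - g_adj) / 2, g_adj / 2, g_adj / 2, (1 - g_adj) / 2])
        qG = float(np.clip(r_adj * p[G], 0.0, 0.95))
        q = p.copy()
        delta = p[G] - qG  # mass moved off (or onto) G after a C
        q[G] = qG
        others = np.array([A, C, T])
        q[others] += delta * p[others] / p[others].sum()
        q = np.clip(q, 1e-9, None)
        q /= q.sum()
        # stationary distribution: pi = (1 - pi_C) p + pi_C q
        piC = p[C] / (1.0 - q[C] + p[C])
        pi = (1 - piC) * p + piC * q
        gc_hat = pi[C] + pi[G]
        oe_hat = q[G] / pi[G]
        g_adj *= gc / max(gc_hat, 1e-9)
        r_adj *= max(oe, 1e-6) / max(oe_hat, 1e-9)
    return p, q


def _scan_impl(u, cdf_p, cdf_q, out):  # pragma: no cover - jitted
    prev_c = False
    for i in range(u.size):
        cdf = cdf_q if prev_c else cdf_p
        x = u[i]
        if x < cdf[0]:
            b = 0
        elif x < cdf[1]:
            b = 1
        elif x < cdf[2]:
            b = 2
        else:
            b = 3
        out[i] = b
        prev_c = b == 1
    return out


try:  # numba gives ~100x on the sequential scan; fall back transparently
    from numba import njit

    _scan = njit(cache=True)(_scan_impl)
except Exception:  # pragma: no cover
    _scan = _scan_impl


def sample_chain(length: int, p: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample base codes (0..3 = ACGT) from the two-row chain."""
    u = rng.random(length)
    cdf_p = np.cumsum(p)[:3]
    cdf_q = np.cumsum(q)[:3]
    out = np.empty(length, dtype=np.int8)
    return _scan(u, cdf_p, cdf_q, out)


def measure_gc_oe(codes: np.ndarray) -> tuple[float, float]:
    """GC fraction and CpG observed/expected ratio by direct counting."""
    n = codes.size
    nC = int((codes == C).sum())
    nG = int((codes == G).sum())
    gc = (nC + nG) / n if n else 0.0
    ncg = int(((codes[:-1] == C) & (codes[1:] == G)).sum()) if n > 1 else 0
    oe = ncg * n / (nC * nG) if nC * nG > 0 else 0.0
    return gc, oe


def generate_sequence(
    length: int,
    gc: float,
    oe: float,
    rng: np.random.Generator,
    tol: float = 0.05,
    max_tries: int = 25,
) -> np.ndarray:
    """Sample a sequence hitting ``gc``/``oe`` within ``tol``, with rejection.

    Raises SequenceGenerationError if no draw lands inside the tolerance box
    after ``max_tries`` attempts (only plausible for very short sequences or
    unreachable target combinations).
    """
    p, q = tune_chain(gc, oe)
    last = (None, None)
    for _ in range(max_tries):
        codes = sample_chain(length, p, q, rng)
        gc_hat, oe_hat = measure_gc_oe(codes)
        if abs(gc_hat - gc) <= tol and abs(oe_hat - oe) <= tol:
            return codes
        last = (gc_hat, oe_hat)
    raise SequenceGenerationError(
        f"could not hit GC={gc:.3f}/OE={oe:.3f} within ±{tol} in {max_tries} tries "
        f"(last draw GC={last[0]:.3f}, OE={last[1]:.3f})"
    )


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes.astype(np.intp)].tobytes().decode("ascii")
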