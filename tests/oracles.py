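"""Independent reference implementations used only as test oracles.

Each oracle takes a deliberately different algorithmic path from the
package implementation it checks: the probe scanner enumerates every
alignment window with vectorized boolean algebra instead of seed lookup,
median polish is a direct transliteration of the classic sweep
procedure, the hypergeometric tail is exhaustive enumeration with exact
integer binomials, and the step-up FDR adjustment is coded from the
textbook definition.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.integrate import quad

from orthoarray.probematch import MatchConfig, reverse_complement


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def brute_force_hits(probes, transcripts, config: MatchConfig):
    """All (probe_id, transcript_id, offset, strand, tier) tuples.

    Slides every probe over every full 25-nt window of every transcript
    and classifies each window directly, with no seeding or extension.
    """
    out = set()
    n_code = ord("N")
    for rec in transcripts:
        if len(rec.sequence) < 25:
            continue
        t = _encode(rec.sequence)
        windows = sliding_window_view(t, 25)  # (W, 25)
        not_n = windows != n_code
        for probe in probes:
            if probe.role != "PM":
                continue
            queries = [(probe.sequence, "+")]
            if config.search_reverse_complement:
                queries.append((reverse_complement(probe.sequence), "-"))
            for qseq, strand in queries:
                q = _encode(qseq)
                match = (windows == q[None, :]) & not_n  # (W, 25)
                tiers = _classify_windows(match, config)
                for off in np.nonzero(tiers != 0)[0]:
                    tier = ("", "EXACT", "END_MM", "TANDEM", "RESCUE")[tiers[off]]
                    out.add((probe.probe_id, rec.transcript_id, int(off), strand, tier))
    return out


def _classify_windows(match: np.ndarray, config: MatchConfig) -> np.ndarray:
    """Tier codes per window row: 0 none, 1 EXACT, 2 END_MM, 3 TANDEM, 4 RESCUE."""
    w = match.shape[0]
    n_match = match.sum(axis=1)
    nm = 25 - n_match
    any_match = n_match > 0
    first = np.argmax(match, axis=1)
    last = 24 - np.argmax(match[:, ::-1], axis=1)
    # all mismatches terminal <=> matches fill [first, last] entirely
    terminal = any_match & (n_match == last - first + 1)
    # longest exact run >= min_tandem via sliding sums of width min_tandem
    k = config.min_tandem
    csum = np.zeros((w, 26), dtype=int)
    csum[:, 1:] = np.cumsum(match, axis=1)
    has_run = np.zeros(w, dtype=bool)
    for start in range(0, 25 - k + 1):
        has_run |= (csum[:, start + k] - csum[:, start]) == k

    tiers = np.zeros(w, dtype=int)
    exact = nm == 0
    end_mm = ~exact & terminal & (nm <= config.max_end_mismatch)
    tandem = ~exact & ~end_mm & has_run
    tiers[exact] = 1
    tiers[end_mm] = 2
    tiers[tandem] = 3
    if config.rescue_enabled:
        rescue = (
            ~exact & ~end_mm & ~tandem & terminal
            & (nm <= config.rescue_max_end_mismatch)
        )
        tiers[rescue] = 4
    return tiers


def median_polish_reference(matrix, tol=0.01, max_iter=10):
    """Classic alternating-median sweep, plain loops, no vectorization."""
    z = [list(map(float, row)) for row in np.asarray(matrix)]
    nr, nc = len(z), len(z[0])
    overall = 0.0
    row_eff = [0.0] * nr
    col_eff = [0.0] * nc
    oldsum = 0.0

    def med(values):
        s = sorted(values)
        m = len(s)
        return s[m // 2] if m % 2 else 0.5 * (s[m // 2 - 1] + s[m // 2])

    for _ in range(max_iter):
        for i in range(nr):
            d = med(z[i])
            for j in range(nc):
                z[i][j] -= d
            row_eff[i] += d
        d = med(col_eff)
        col_eff = [c - d for c in col_eff]
        overall += d
        for j in range(nc):
            d = med([z[i][j] for i in range(nr)])
            for i in range(nr):
                z[i][j] -= d
            col_eff[j] += d
        d = med(row_eff)
        row_eff = [r - d for r in row_eff]
        overall += d
        newsum = sum(abs(v) for row in z for v in row)
        if newsum == 0 or abs(newsum - oldsum) < tol:
            break
        oldsum = newsum
    return overall, np.array(row_eff), np.array(col_eff), np.array(z)


def normexp_quadrature(x: float, alpha: float, mu: float, sigma: float) -> float:
    """E[signal | observed] by numerical integration of the posterior."""

    def density(s):
        return math.exp(
            -((x - s - mu) ** 2) / (2 * sigma**2) - s / alpha
        )

    # The posterior is a Gaussian bump of width sigma centred near
    # x - mu - sigma^2/alpha (truncated at 0); integrate a window that
    # comfortably contains it so quadrature cannot miss the mass.
    centre = x - mu - sigma**2 / alpha
    lo = max(0.0, centre - 15 * sigma)
    hi = max(centre + 15 * sigma, 30 * sigma)
    pts = [p for p in (max(centre, 0.0),) if lo < p < hi]
    num, _ = quad(lambda s: s * density(s), lo, hi, limit=400, points=pts)
    den, _ = quad(density, lo, hi, limit=400, points=pts)
    return num / den


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact integer binomial enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def bh_stepup_reference(p):
    """Textbook Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
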