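"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (dense grids, exhaustive scans,
textbook formulas) and shares no code with the package's own paths.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# stop-process likelihood, maximised by dense grid search


def stop_process_loglik(s: np.ndarray, X: np.ndarray, X_full: int) -> float:
    """Explicit log-likelihood of observed stop counts under the n->1 walk
    with per-site stop probabilities s (vector in [0,1))."""
    s = np.asarray(s, dtype=float)
    n = len(s)
    log_surv = np.log1p(-s)
    ll = X_full * log_surv.sum()
    for k in range(n):  # P(stop at k+1) = s_k * prod_{j>k} (1 - s_j)
        if X[k] == 0:
            continue
        if s[k] <= 0:
            return -np.inf
        ll += X[k] * (np.log(s[k]) + log_surv[k + 1 :].sum())
    return float(ll)


S_MAX = 1.0 - 1e-6  # stop probabilities live in [0, 1 - eps]: a site where
# every surviving transcript stops is represented by the boundary value


def _grid_maximise_channel(X: np.ndarray, X_full: int, levels: int = 3,
                           points: int = 401) -> np.ndarray:
    """Coordinate-wise dense grid maximisation of the stop-process
    likelihood (the likelihood is separable across sites, so a single
    sweep per refinement level attains the joint maximum)."""
    n = len(X)
    s = np.full(n, 0.1)
    lo = np.zeros(n)
    hi = np.full(n, S_MAX)
    for _ in range(levels):
        for k in range(n):
            grid = np.linspace(lo[k], hi[k], points)
            lls = np.empty(points)
            trial = s.copy()
            for i, v in enumerate(grid):
                trial[k] = v
                lls[i] = stop_process_loglik(trial, X, X_full)
            best = int(np.argmax(lls))
            s[k] = grid[best]
            step = grid[1] - grid[0] if points > 1 else 0.0
            lo[k] = max(0.0, grid[best] - 2 * step)
            hi[k] = min(S_MAX, grid[best] + 2 * step)
    return s


def grid_search_theta(plus_X, plus_full: int, minus_X, minus_full: int) -> np.ndarray:
    """Maximum-likelihood theta via dense grid search over per-site stop
    probabilities in both channels, followed by the drop-off correction
    raw_k = ln(1 - g_k) - ln(1 - b_k) truncated at 0 and normalised."""
    b = _grid_maximise_channel(np.asarray(plus_X), plus_full)
    g = _grid_maximise_channel(np.asarray(minus_X), minus_full)
    raw = np.maximum(0.0, np.log1p(-g) - np.log1p(-b))
    total = raw.sum()
    return raw / total if total > 0 else np.zeros_like(raw)


# ---------------------------------------------------------------------------
# exhaustive suffix-prefix adapter scan


def brute_force_trim(read: str, adapter: str, min_overlap: int) -> str:
    best = 0
    for L in range(min_overlap, min(len(read), len(adapter)) + 1):
        suffix = read[len(read) - L :]
        prefix = adapter[:L]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= L // 10:
            best = max(best, L)
    return read[: len(read) - best] if best else read


# ---------------------------------------------------------------------------
# brute-force all-offsets Hamming alignment


def brute_force_align(read: str, targets: dict[str, str], max_mismatches: int):
    """All minimal-mismatch placements of read across a panel of DNA
    target strings; returns list of (target, offset, mismatches)."""
    hits = []
    for name, seq in targets.items():
        for off in range(len(seq) - len(read) + 1):
            mm = sum(a != b for a, b in zip(read, seq[off : off + len(read)]))
            if mm <= max_mismatches:
                hits.append((name, off, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return [h for h in hits if h[2] == best]


# ---------------------------------------------------------------------------
# brute-force sliding-window scan


def brute_force_window_scan(on, off, w: int):
    on = np.asarray(on, dtype=float)
    off = np.asarray(off, dtype=float)
    on = np.where(np.isnan(on), 0.0, on)
    off = np.where(np.isnan(off), 0.0, off)
    best_start, best_diff = None, -np.inf
    for start in range(1, len(on) - w + 2):
        d = on[start - 1 : start - 1 + w].sum() - off[start - 1 : start - 1 + w].sum()
        if d > best_diff:
            best_start, best_diff = start, d
    return best_start, best_diff


# ---------------------------------------------------------------------------
# textbook Welch t-test


def welch_textbook(a, b, direction: str = "greater") -> tuple[float, float, float]:
    """(t, satterthwaite df, one-sided p) from the standard formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = t_dist.sf(t, df) if direction == "greater" else t_dist.cdf(t, df)
    return float(t), float(df), float(p)
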