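"""Independent reference implementations used only to check the package.

Each oracle is written directly from the rule or formula definition with a
deliberately different mechanism from the implementation it checks (forward
exhaustive scans instead of run-length merging, explicit double sums instead
of library calls), so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def block_sum_oracle(values: np.ndarray, factor: int) -> np.ndarray:
    """Reintegration oracle via cumulative sums."""
    csum = np.concatenate(([0], np.cumsum(values)))
    n_blocks = len(values) // factor
    return np.array([csum[(i + 1) * factor] - csum[i * factor] for i in range(n_blocks)])


def fixed_window_oracle(cpm: np.ndarray, window: int) -> np.ndarray:
    """Minute mask of non-wear: every maximal zero run of length >= window."""
    n = len(cpm)
    mark = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if cpm[i] == 0:
            j = i
            while j < n and cpm[j] == 0:
                j += 1
            if j - i >= window:
                mark[i:j] = True
            i = j
        else:
            i += 1
    return mark


def _zero_run_starts(cpm: np.ndarray):
    for s in range(len(cpm)):
        if cpm[s] == 0 and (s == 0 or cpm[s - 1] != 0):
            yield s


def troiano_oracle(
    cpm: np.ndarray, window: int = 60, max_interruption: int = 2, ceiling: int = 100
) -> np.ndarray:
    """Union of valid Troiano spans by forward scan from each zero-run start.

    A valid span starts and ends with zero minutes, has length >= window, and
    contains only zeros and interruption runs of at most ``max_interruption``
    consecutive minutes each with counts strictly between 0 and ``ceiling``.
    """
    n = len(cpm)
    mark = np.zeros(n, dtype=bool)
    for s in _zero_run_starts(cpm):
        last_valid_end = None
        nz_run = 0
        p = s
        while p < n:
            c = cpm[p]
            if c == 0:
                nz_run = 0
                last_valid_end = p + 1
            else:
                if c >= ceiling:
                    break
                nz_run += 1
                if nz_run > max_interruption:
                    break
            p += 1
        if last_valid_end is not None and last_valid_end - s >= window:
            mark[s:last_valid_end] = True
    return mark


def choi_oracle(
    cpm: np.ndarray, window: int = 90, max_interruption: int = 2, flank: int = 30
) -> np.ndarray:
    """Union of valid Choi spans by forward scan from each zero-run start.

    Interruption runs of at most ``max_interruption`` consecutive nonzero
    minutes (any magnitude) are allowed only when at least ``flank`` zero
    minutes immediately precede and follow them; span ends inside an
    unconfirmed right flank are invalid.
    """
    n = len(cpm)
    mark = np.zeros(n, dtype=bool)
    for s in _zero_run_starts(cpm):
        last_valid_end = None
        zeros_before = 0
        zeros_after = 0
        nz_run = 0
        pending = False  # interruption awaiting its right flank
        p = s
        while p < n:
            if cpm[p] == 0:
                if nz_run > 0:
                    pending = True
                    zeros_after = 0
                nz_run = 0
                zeros_before += 1
                if pending:
                    zeros_after += 1
                    if zeros_after >= flank:
                        pending = False
                if not pending:
                    last_valid_end = p + 1
            else:
                if nz_run == 0:
                    if pending or zeros_before < flank:
                        break
                nz_run += 1
                if nz_run > max_interruption:
                    break
                zeros_before = 0
            p += 1
        if last_valid_end is not None and last_valid_end - s >= window:
            mark[s:last_valid_end] = True
    return mark


def troiano_total_oracle(
    cpm: np.ndarray, window: int = 60, budget: int = 2, ceiling: int = 100
) -> np.ndarray:
    """Total-interruption-budget variant by brute force over all (start, end)
    pairs; quadratic, for short traces only."""
    n = len(cpm)
    mark = np.zeros(n, dtype=bool)
    for s in range(n):
        if cpm[s] != 0:
            continue
        for e in range(s + window, n + 1):
            seg = cpm[s:e]
            if seg[-1] != 0:
                continue
            if np.any(seg >= ceiling):
                continue
            if int(np.count_nonzero(seg)) <= budget:
                mark[s:e] = True
    return mark


def diary_minute_mask_oracle(wake: int, bed: int, offs) -> np.ndarray:
    """Per-minute wear mask built by marking each minute individually."""
    mask = np.zeros(1440, dtype=bool)
    for minute in range(1440):
        worn = wake <= minute < bed
        for off, on in offs:
            if off <= minute < on:
                worn = False
        mask[minute] = worn
    return mask


def lin_ccc_oracle(x, y) -> float:
    """Lin's CCC, 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).sum() / (n - 1)
    sx2 = ((x - mx) ** 2).sum() / (n - 1)
    sy2 = ((y - my) ** 2).sum() / (n - 1)
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def kappa_oracle(table: np.ndarray, weights: np.ndarray | None = None) -> float:
    """(Weighted) kappa by explicit double sums over a contingency table."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    if weights is None:
        weights = np.eye(k)
    n = table.sum()
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_obs = 0.0
    p_exp = 0.0
    for i in range(k):
        for j in range(k):
            p_obs += weights[i, j] * table[i, j] / n
            p_exp += weights[i, j] * row[i] * col[j]
    return (p_obs - p_exp) / (1 - p_exp)


def linear_weights(k: int) -> np.ndarray:
    w = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            w[i, j] = 1 - abs(i - j) / (k - 1)
    return w


def pearson_chi2_oracle(table: np.ndarray) -> float:
    """Textbook Pearson chi-square: sum (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


def random_rule_trace(rng, max_len: int = 200, alphabet=(0, 50, 200)) -> np.ndarray:
    """Run-structured random minute trace biased toward zero runs, so that
    candidate non-wear spans with interruptions actually occur."""
    n = int(rng.integers(1, max_len + 1))
    out = []
    while len(out) < n:
        if rng.random() < 0.55:
            value = 0
            length = int(rng.integers(1, 80))
        else:
            value = int(rng.choice(alphabet[1:]))
            length = int(rng.integers(1, 5))
        out.extend([value] * length)
    return np.array(out[:n])
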