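"""Brute-force re-implementation of the window/block/breakpoint rules.

Written independently of the package (plain loops, no vectorization, no
shared helpers) so it can serve as an oracle for the fast implementation:
every window recounted from scratch, every marker's consensus recounted,
blocks and breakpoints re-derived directly from the documented rules.
"""

from __future__ import annotations


def oracle_window_calls(calls, window, step, a_thr, b_thr, min_inf):
    calls = list(calls)
    n = len(calls)
    if n < window:
        starts, width = [0], n
    else:
        starts, width = list(range(0, n - window + 1, step)), window
    out = []
    total = a_thr + b_thr
    for s in starts:
        a = b = 0
        for c in calls[s:s + width]:
            if c == "A":
                a += 1
            elif c == "B":
                b += 1
        if a + b < max(min_inf, 1):
            out.append("U")
        elif a * total >= a_thr * (a + b):
            out.append("A")
        elif a * total <= b_thr * (a + b):
            out.append("B")
        else:
            out.append("U")
    return out, starts


def oracle_consensus(window_calls, starts, n_markers, window):
    w = min(window, n_markers)
    cons = []
    for i in range(n_markers):
        a = b = 0
        for s, c in zip(starts, window_calls):
            if s <= i < s + w:
                if c == "A":
                    a += 1
                elif c == "B":
                    b += 1
        cons.append("A" if a > b else ("B" if b > a else "U"))
    return cons


def oracle_blocks_breakpoints(calls, positions, chrom_length, window, step,
                              a_thr, b_thr, min_inf):
    """(blocks, breakpoints) where blocks are (genotype, first, last,
    start_bp, end_bp) and breakpoints are bp positions."""
    positions = list(positions)
    n = len(positions)
    wc, starts = oracle_window_calls(calls, window, step, a_thr, b_thr, min_inf)
    cons = oracle_consensus(wc, starts, n, window)

    # run-length encode
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and cons[j + 1] == cons[i]:
            j += 1
        runs.append((cons[i], i, j))
        i = j + 1

    det = [r for r in runs if r[0] != "U"]
    if not det:
        return [("U", 0, n - 1, 0, chrom_length)], []

    # assign every marker a final genotype, recording breakpoints as we go
    final = [None] * n
    breakpoints = []
    # leading/trailing undetermined runs adopt their single neighbour
    for geno, a, b in runs:
        if geno != "U":
            for k in range(a, b + 1):
                final[k] = geno
    first_det, last_det = det[0], det[-1]
    for k in range(0, first_det[1]):
        final[k] = first_det[0]
    for k in range(last_det[2] + 1, n):
        final[k] = last_det[0]
    # internal undetermined runs
    for idx, (geno, a, b) in enumerate(runs):
        if geno != "U" or a == 0 or b == n - 1:
            continue
        left = runs[idx - 1][0]
        right = runs[idx + 1][0]
        if left == right:
            for k in range(a, b + 1):
                final[k] = left
        else:
            mid = (positions[a] + positions[b]) // 2
            for k in range(a, b + 1):
                final[k] = left if positions[k] <= mid else right
            breakpoints.append(mid)
    # direct transitions between determined runs
    for idx in range(len(runs) - 1):
        g1, _, e1 = runs[idx]
        g2, s2, _ = runs[idx + 1]
        if g1 != "U" and g2 != "U" and g1 != g2:
            breakpoints.append((positions[e1] + positions[s2]) // 2)
    breakpoints.sort()

    # final runs -> blocks with bp extents bounded by the breakpoints
    blocks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and final[j + 1] == final[i]:
            j += 1
        blocks.append((final[i], i, j))
        i = j + 1
    assert len(blocks) == len(breakpoints) + 1
    out = []
    for k, (geno, a, b) in enumerate(blocks):
        start_bp = 0 if k == 0 else breakpoints[k - 1]
        end_bp = chrom_length if k == len(blocks) - 1 else breakpoints[k]
        out.append((geno, a, b, start_bp, end_bp))
    return out, breakpoints
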