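"""Independent brute-force recurrence-feature oracle for tests.

Walks every diagonal and every column of a binary matrix cell by cell,
accumulating maximal run lengths with explicit loops, and evaluates the
feature formulas directly from the resulting counts.  Shares no code
with toothrqa.rqa beyond the conventions: Theiler masking removes cells
with |i - j| < w, and masked cells break vertical white runs.
"""
from collections import Counter

import math


def brute_force_histograms(matrix, theiler=0):
    n_rows = len(matrix)
    n_cols = len(matrix[0]) if n_rows else 0
    diag = Counter()
    for k in range(-(n_rows - 1), n_cols):
        run = 0
        for i in range(n_rows):
            j = i + k
            if j < 0 or j >= n_cols:
                continue
            if abs(i - j) < theiler:
                if run:
                    diag[run] += 1
                run = 0
                continue
            if matrix[i][j]:
                run += 1
            elif run:
                diag[run] += 1
                run = 0
        if run:
            diag[run] += 1
    white = Counter()
    for j in range(n_cols):
        run = 0
        for i in range(n_rows):
            if abs(i - j) < theiler:
                if run:
                    white[run] += 1
                run = 0
                continue
            if not matrix[i][j]:
                run += 1
            elif run:
                white[run] += 1
                run = 0
        if run:
            white[run] += 1
    return dict(diag), dict(white)


def brute_force_features(matrix, theiler=0, l_min=2):
    """(rr, det, mdl, entr, rt) computed from the brute-force counts;
    undefined features come back as None."""
    diag, white = brute_force_histograms(matrix, theiler)
    n_rows = len(matrix)
    n_cols = len(matrix[0]) if n_rows else 0
    unmasked = ones = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if abs(i - j) < theiler:
                continue
            unmasked += 1
            if matrix[i][j]:
                ones += 1
    rr = ones / unmasked if unmasked else float("nan")

    total = sum(l * c for l, c in diag.items())
    long_pts = sum(l * c for l, c in diag.items() if l >= l_min)
    long_lines = sum(c for l, c in diag.items() if l >= l_min)
    det = long_pts / total if total else None
    mdl = long_pts / long_lines if long_lines else None
    entr = None
    if long_lines:
        entr = 0.0
        for l, c in diag.items():
            if l >= l_min:
                p = c / long_lines
                entr -= p * math.log(p)
    w_lines = sum(white.values())
    rt = sum(l * c for l, c in white.items()) / w_lines if w_lines else None
    return rr, det, mdl, entr, rt
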