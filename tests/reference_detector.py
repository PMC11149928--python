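"""Naive per-sample reference SWR detector used as an independent oracle.

Deliberately brute-force: scans samples one by one, extends boundaries by
stepping outward, merges by repeated pairwise passes until a fixed point,
and sums integrals in a Python loop.  Shares no code with the package's
vectorized detector.
"""

import math


def naive_detect(
    z,
    fs,
    threshold_sd=3.0,
    min_duration_ms=15.0,
    merge_gap_ms=15.0,
    boundary_sd=None,
):
    """Return a list of (start, end, peak, integral) with half-open sample spans."""
    boundary = threshold_sd if boundary_sd is None else boundary_sd
    n = len(z)
    runs = []
    i = 0
    while i < n:
        if z[i] > threshold_sd:
            j = i
            while j < n and z[j] > threshold_sd:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    extended = []
    for s, e in runs:
        while s > 0 and z[s - 1] > boundary:
            s -= 1
        while e < n and z[e] > boundary:
            e += 1
        extended.append((s, e))
    # union of overlapping spans, repeated passes until stable
    spans = sorted(set(extended))
    changed = True
    while changed:
        changed = False
        out = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
                changed = True
            else:
                out.append((s, e))
        spans = out
    # pairwise merge passes until stable
    gap = merge_gap_ms * fs / 1000.0
    changed = True
    while changed:
        changed = False
        out = []
        for s, e in spans:
            if out and s - out[-1][1] <= gap + 1e-9:
                out[-1] = (out[-1][0], max(out[-1][1], e))
                changed = True
            else:
                out.append((s, e))
        spans = out
    min_samples = min_duration_ms * fs / 1000.0
    events = []
    for s, e in spans:
        if e - s < min_samples - 1e-9:
            continue
        peak = z[s]
        for k in range(s + 1, e):
            if z[k] > peak:
                peak = z[k]
        integral = math.fsum(z[s:e])
        events.append((s, e, peak, integral))
    return events
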