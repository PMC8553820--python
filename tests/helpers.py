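"""Shared independent oracles for the test suite."""

import numpy as np


def oracle_detect(env, rate, spec):
    """Literal threshold-scan bout detector, independent of the package.

    Enumerate maximal runs above the onset threshold, keep runs whose max
    reaches the peak threshold, merge gaps < merge_gap, discard long bouts.
    Returns (i0, i1, peak_idx) sample triples.
    """
    runs = []
    i = 0
    n = len(env)
    while i < n:
        if env[i] > spec.onset_offset_threshold:
            j = i
            while j < n and env[j] > spec.onset_offset_threshold:
                j += 1
            if max(env[i:j]) >= spec.peak_threshold:
                runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) / rate * 1000.0 < spec.merge_gap_ms:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    out = []
    for i0, i1 in merged:
        if (i1 - i0) / rate * 1000.0 > spec.max_duration_ms:
            continue
        peak = i0 + int(np.argmax(env[i0:i1]))
        out.append((i0, i1, peak))
    return out
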