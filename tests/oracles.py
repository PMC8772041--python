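"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and dictionaries, no shared code
with the package internals beyond the class vocabularies.
"""

import math

from metalbind.features import TRACK_CLASSES, track_tokens


def brute_pwm(fragments, track, p0=None):
    """Tally-and-formula PWM: returns (p, m) as nested lists.

    p[i][j] = (n_ij + sqrt(N_i)/q) / (N_i + sqrt(N_i)); m = ln(p / p0).
    """
    classes = TRACK_CLASSES[track]
    q = len(classes)
    L = len(fragments[0])
    if p0 is None:
        p0 = [1.0 / q] * q
    p, m = [], []
    for i in range(L):
        counts = {c: 0 for c in classes}
        for frag in fragments:
            counts[track_tokens(frag, track)[i]] += 1
        N = sum(counts.values())
        row_p = [(counts[c] + math.sqrt(N) / q) / (N + math.sqrt(N)) for c in classes]
        p.append(row_p)
        m.append([math.log(pj / p0j) for pj, p0j in zip(row_p, p0)])
    return p, m


def brute_background(fragments, track):
    """Pooled smoothed class frequencies over every site of every fragment."""
    classes = TRACK_CLASSES[track]
    q = len(classes)
    counts = {c: 0 for c in classes}
    for frag in fragments:
        for tok in track_tokens(frag, track):
            counts[tok] += 1
    N = sum(counts.values())
    return [(counts[c] + math.sqrt(N) / q) / (N + math.sqrt(N)) for c in classes]


def brute_metrics(pairs):
    """Recount Sn/Sp/Acc/MCC from raw (label, call) pairs."""
    tp = sum(1 for t, c in pairs if t and c)
    fp = sum(1 for t, c in pairs if not t and c)
    tn = sum(1 for t, c in pairs if not t and not c)
    fn = sum(1 for t, c in pairs if t and not c)
    total = tp + fp + tn + fn
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return tp, fp, tn, fn, sn, sp, acc, mcc
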