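"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities sample by sample (plain loops, no
shared code with the package) so that the implementation is checked
against an independent computation of the same stated rules.
"""

import numpy as np


def oracle_speed(trace):
    """Central-difference speed, one-sided at the ends, via explicit loops."""
    xy, t = trace.xy_cm, trace.t_ms
    n = len(t)
    sp = np.empty(n)
    for i in range(n):
        if i == 0:
            d = (xy[1] - xy[0]) / (t[1] - t[0])
        elif i == n - 1:
            d = (xy[-1] - xy[-2]) / (t[-1] - t[-2])
        else:
            d = (xy[i + 1] - xy[i - 1]) / (t[i + 1] - t[i - 1])
        sp[i] = np.hypot(*d) * 1000.0
    return sp


def oracle_onset(trace):
    """First sample with speed > 5 cm/s AND radius > 0.5 cm, by exhaustive scan."""
    sp = oracle_speed(trace)
    home = np.asarray(trace.home_xy_cm)
    for i in range(len(sp)):
        r = np.hypot(*(trace.xy_cm[i] - home))
        if sp[i] > 5.0 and r > 0.5:
            return trace.t_ms[i]
    return None


def oracle_offset(trace, onset_ms):
    """First drop below 5 cm/s after the first post-onset speed peak."""
    sp = oracle_speed(trace)
    i = int(np.searchsorted(trace.t_ms, onset_ms))
    while i + 1 < len(sp) and sp[i + 1] >= sp[i]:
        i += 1
    for j in range(i + 1, len(sp)):
        if sp[j] < 5.0:
            return trace.t_ms[j], False
    return trace.t_ms[-1], True
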