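"""Independent, dictionary-based reference implementations of the four
spectral accuracy measures.

Deliberately non-vectorized and independent of aminospec internals: each
oracle works directly on sparse {m/z: intensity} dicts with plain Python
loops, so agreement with the numpy implementations is a genuine
cross-check, not a tautology.  Inputs for rmse/sca/wcs are assumed already
base-peak-100 normalized with integer m/z; sen normalizes internally.
"""

import math


def _grid(a: dict, b: dict) -> range:
    return range(int(max(max(a), max(b))) + 1)


def rmse_oracle(a: dict, b: dict) -> float:
    grid = _grid(a, b)
    total = 0.0
    for i in grid:
        total += (b.get(i, 0.0) - a.get(i, 0.0)) ** 2
    return math.sqrt(total / len(grid))


def sca_oracle(a: dict, b: dict) -> float:
    dot = na = nb = 0.0
    for i in _grid(a, b):
        ai = a.get(i, 0.0)
        bi = b.get(i, 0.0)
        dot += ai * bi
        na += ai * ai
        nb += bi * bi
    cos = dot / math.sqrt(na * nb)
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def wcs_oracle(a: dict, b: dict, mz_exp: float = 1.0, int_exp: float = 0.5) -> float:
    dot = na = nb = 0.0
    for i in _grid(a, b):
        wa = (i ** mz_exp) * (a.get(i, 0.0) ** int_exp)
        wb = (i ** mz_exp) * (b.get(i, 0.0) ** int_exp)
        dot += wa * wb
        na += wa * wa
        nb += wb * wb
    return dot / math.sqrt(na * nb)


def _entropy(d: dict) -> float:
    return -sum(v * math.log(v) for v in d.values() if v > 0)


def sen_oracle(a: dict, b: dict) -> float:
    sa = sum(a.values())
    sb = sum(b.values())
    p = {k: v / sa for k, v in a.items()}
    q = {k: v / sb for k, v in b.items()}
    m = {}
    for k in set(p) | set(q):
        m[k] = 0.5 * (p.get(k, 0.0) + q.get(k, 0.0))
    return 1.0 - (2.0 * _entropy(m) - _entropy(p) - _entropy(q)) / math.log(4.0)
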