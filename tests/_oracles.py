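"""Independent brute-force oracles shared by the test suite.

These implement the scored quantities straight from their definitions
(exhaustive enumeration, all-offsets scans, exact rational arithmetic) and
are deliberately kept free of any package internals beyond data containers.
"""

from __future__ import annotations

import random
from fractions import Fraction
from math import comb

from cfrefrag.catalog import make_region
from cfrefrag.fragments import Fragment


def lc_oracle(seq: str) -> float:
    """Linguistic complexity by exhaustive distinct-substring enumeration."""
    seq = seq.upper()
    L = len(seq)
    num = sum(
        len({seq[i : i + k] for i in range(L - k + 1)}) for k in range(1, L + 1)
    )
    den = sum(min(4**k, L - k + 1) for k in range(1, L + 1))
    return num / den


def brute_units(fragment: Fragment, locus) -> int | None:
    """All-offsets, all-rotations tandem-run scan on the locus-facing slice."""
    seq = fragment.sequence
    n1 = locus.n1
    if not seq:
        return None
    if min(fragment.end, locus.end) - max(fragment.start, locus.start) < n1:
        return None
    lo = max(0, (locus.start - n1) - fragment.start)
    hi = len(seq) - max(0, fragment.end - (locus.end + n1))
    if hi <= lo:
        return None
    segment = seq[lo:hi]
    best = 0
    for r in range(n1):
        rot = locus.motif[r:] + locus.motif[:r]
        for i in range(len(segment) - n1 + 1):
            run, j = 0, i
            while segment[j : j + n1] == rot:
                run += 1
                j += n1
            best = max(best, run)
    return best


def random_locus_read_pairs(rng: random.Random, n: int):
    """Random (fragment, STR locus) pairs, half with planted +k insertions."""
    for trial in range(n):
        n1 = rng.randint(1, 6)
        motif = "".join(rng.choice("ACGT") for _ in range(n1))
        n2 = rng.randint(4, 20)
        locus = make_region("chr1", 500, 500 + n1 * n2, "+", f"({motif}){n2}",
                            "Simple_repeat", "Simple_repeat")
        origin = 420
        ref = ("".join(rng.choice("ACGT") for _ in range(80))
               + motif * n2
               + "".join(rng.choice("ACGT") for _ in range(80)))
        start = origin + rng.randint(0, 80 + n1 * n2 - n1)
        end = min(start + rng.randint(n1, 160), origin + len(ref))
        if end - start < n1:
            continue
        covers = start <= locus.start and end >= locus.end
        if trial % 2 and covers:
            k = rng.randint(1, 5)
            seq = (ref[start - origin : locus.start - origin]
                   + motif * (n2 + k)
                   + ref[locus.end - origin : end - origin])
        else:
            seq = ref[start - origin : end - origin]
        yield Fragment("chr1", start, end, name=f"t{trial}", sequence=seq), locus


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), total)
    p = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), total)
        if px <= p_obs:
            p += px
    return float(p)


def youden_oracle(scores, labels) -> float:
    """Exhaustive threshold sweep maximising sensitivity + specificity - 1."""
    best_t, best_j = min(scores), -1e9
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t
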