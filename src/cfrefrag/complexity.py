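"""Linguistic sequence complexity of nucleotide reads.

The linguistic complexity (LC) of a sequence of length ``L`` is the number of
distinct substrings it contains divided by the maximum number of distinct
substrings a sequence of that length over a 4-letter alphabet could contain:

    LC = sum_k U_k / sum_k min(4**k, L - k + 1),   k = 1..L

where ``U_k`` is the number of distinct k-mers actually observed.  LC lies in
(0, 1]; a homopolymer approaches 0 with growing length while a sequence whose
substrings are all distinct scores exactly 1.

Distinct-substring spectra are computed with a suffix automaton (linear in
``L``), falling back to direct substring enumeration for sequences containing
characters outside {A, C, G, T} — such k-mers are excluded from the counts
while the denominator keeps the full length.
"""

from __future__ import annotations

__all__ = ["linguistic_complexity", "distinct_kmer_counts"]

_ACGT = frozenset("ACGT")


def _spectrum_suffix_automaton(seq: str) -> list[int]:
    """Distinct k-mer counts for k = 1..len(seq) via a suffix automaton.

    Every automaton state recognises the substrings whose lengths fall in
    ``(link.len, state.len]``, each exactly once, so a difference array over
    those intervals yields the per-length spectrum.
    """
    # state arrays: transition dict, suffix link, max length
    trans: list[dict[str, int]] = [{}]
    link = [-1]
    maxlen = [0]
    last = 0
    for ch in seq:
        cur = len(trans)
        trans.append({})
        link.append(-1)
        maxlen.append(maxlen[last] + 1)
        p = last
        while p != -1 and ch not in trans[p]:
            trans[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][ch]
            if maxlen[p] + 1 == maxlen[q]:
                link[cur] = q
            else:
                clone = len(trans)
                trans.append(dict(trans[q]))
                link.append(link[q])
                maxlen.append(maxlen[p] + 1)
                while p != -1 and trans[p].get(ch) == q:
                    trans[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur

    n = len(seq)
    diff = [0] * (n + 2)
    for v in range(1, len(trans)):
        diff[maxlen[link[v]] + 1] += 1
        diff[maxlen[v] + 1] -= 1
    counts = []
    running = 0
    for k in range(1, n + 1):
        running += diff[k]
        counts.append(running)
    return counts


def _spectrum_enumerate(seq: str) -> list[int]:
    """Set-based distinct k-mer counts; k-mers with non-ACGT letters excluded."""
    n = len(seq)
    counts = []
    for k in range(1, n + 1):
        kmers = {
            seq[i : i + k]
            for i in range(n - k + 1)
            if _ACGT.issuperset(seq[i : i + k])
        }
        counts.append(len(kmers))
    return counts


def distinct_kmer_counts(sequence: str) -> list[int]:
    """Number of distinct k-mers of ``sequence`` for every k = 1..L."""
    seq = sequence.upper()
    if _ACGT.issuperset(seq):
        return _spectrum_suffix_automaton(seq)
    return _spectrum_enumerate(seq)


def linguistic_complexity(sequence: str) -> float:
    """Linguistic complexity of a read sequence, in (0, 1].

    Parameters
    ----------
    sequence
        Non-empty nucleotide string.  Case-insensitive; k-mers containing
        letters outside A/C/G/T are not counted as vocabulary, but the
        sequence length still sets the denominator.

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("linguistic complexity is undefined for an empty sequence")
    observed = sum(distinct_kmer_counts(seq))
    possible = 0
    for k in range(1, L + 1):
        cap = L - k + 1
        # 4**k overtakes L-k+1 almost immediately; skip huge exponentials
        possible += min(4**k, cap) if k < 32 else cap
    return observed / possible
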