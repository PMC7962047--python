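"""Independent dynamic-programming decomposition oracle.

Used only by the tests as a ground truth for total unit counts: a minimal-
error segmentation of a tract into triplet units, where a unit may consume

* 3 nt — an exact alphabet motif (0 errors) or any other codon (1 error),
* 2 nt — a motif with one base deleted (1 error),
* 4 nt — a motif with one base inserted (1 error),

plus an optional 1–2 nt skip at either tract boundary (1 error, 0 units).
Among equal-error segmentations the one with the most units wins, matching
the convention that broken units still count toward the tract length.
"""

from __future__ import annotations

from functools import lru_cache

DEFAULT_ALPHABET = ("CTG", "CCG", "CAG", "CTC")


def _deletion_forms(alphabet) -> frozenset[str]:
    forms = set()
    for m in alphabet:
        forms.update({m[1:], m[:2], m[0] + m[2]})
    return frozenset(forms)


def _contains_motif_subseq(s4: str, alphabet) -> bool:
    for drop in range(4):
        if s4[:drop] + s4[drop + 1 :] in alphabet:
            return True
    return False


def dp_decompose(tract: str, alphabet=DEFAULT_ALPHABET) -> tuple[int, int]:
    """Return (total_units, errors) of the optimal segmentation."""
    aset = frozenset(alphabet)
    del_forms = _deletion_forms(alphabet)
    L = len(tract)
    INF = (10**9, 0)

    @lru_cache(maxsize=None)
    def best(i: int) -> tuple[int, int]:
        """(errors, -units) from position i to the end."""
        if i == L:
            return (0, 0)
        options = []
        if L - i <= 2:  # trailing skip
            options.append((1, 0))
        if i + 3 <= L:
            codon = tract[i : i + 3]
            e, u = best(i + 3)
            options.append((e + (0 if codon in aset else 1), u - 1))
        if i + 2 <= L:
            e, u = best(i + 2)
            options.append((e + 1, u - 1))
        if i + 4 <= L:
            e, u = best(i + 4)
            options.append((e + 1, u - 1))
        return min(options, default=INF)

    candidates = [best(0)]
    for skip in (1, 2):  # leading skip
        if L > skip:
            e, u = best(skip)
            candidates.append((e + 1, u))
    errors, neg_units = min(candidates)
    best.cache_clear()
    return -neg_units, errors
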