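"""Shared pairwise-alignment helpers.

Local (Smith-Waterman) alignment goes through scikit-bio's ``pair_align``;
this module walks the returned alignment path into per-column match flags,
which both the isoform linker and the stage-2 clusterer consume.
"""

from __future__ import annotations

from skbio.alignment import pair_align


def best_local_path(a: str, b: str):
    """Optimal local alignment of two strings; returns (path, match_flags).

    ``match_flags`` is a per-column list of booleans (True where both
    sequences align identical characters). Returns (None, []) when no
    positive-scoring local alignment exists.
    """
    res = pair_align(a, b, mode="local", sub_score=(1.0, -1.0), gap_cost=2.0)
    if not res.paths:
        return None, []
    path = res.paths[0]
    bits = path.to_bits()
    if bits.shape[1] == 0:
        return None, []
    (a0, _), (b0, _) = path.ranges
    i, j = int(a0), int(b0)
    flags: list[bool] = []
    for c in range(bits.shape[1]):
        a_gap = bits[0, c] == 1
        b_gap = bits[1, c] == 1
        flags.append(not a_gap and not b_gap and a[i] == b[j])
        if not a_gap:
            i += 1
        if not b_gap:
            j += 1
    return path, flags
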