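"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops and pairwise
enumeration, deliberately sharing no code path with the package.
"""

from itertools import combinations


def enumerate_maps(block):
    """All transform maps of one block by direct enumeration: identities
    first, then pairwise differences (i, j), i < j, lexicographic."""
    n = len(block)
    maps = [list(v) for v in block]
    for i, j in combinations(range(n), 2):
        maps.append([block[i][c] - block[j][c] for c in range(len(block[i]))])
    return maps


def rank_desc(values):
    """1-based channel indices by descending value, ties to lower index."""
    order = sorted(range(len(values)), key=lambda c: (-values[c], c))
    return [c + 1 for c in order]


def brute_force_features(segment, n=5, stride=1):
    """Loop-based re-derivation of the full feature vector."""
    L = len(segment)
    nc = len(segment[0])
    starts = list(range(0, L - n + 1, stride))
    n_maps = n + n * (n - 1) // 2
    sequences = [[] for _ in range(n_maps)]
    for s in starts:
        block = [list(segment[s + r]) for r in range(n)]
        for u, p in enumerate(enumerate_maps(block)):
            sequences[u].extend(rank_desc(p))
    features = []
    for seq in sequences:
        table = [[0] * nc for _ in range(nc)]
        for q in range(len(seq) - 1):
            table[seq[q] - 1][seq[q + 1] - 1] += 1
        for row in table:
            features.extend(row)
    return features
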