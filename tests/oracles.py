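"""Independent brute-force oracles used to cross-check the package.

Deliberately naive implementations that share no code with the package:
motif scanning by position-by-position comparison, digestion by direct
cut enumeration, Dice similarity by literal counting, and Smith-
Waterman local alignment by the full affine dynamic programme.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def scan_motif(seq: str, motif: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - len(motif) + 1)
        if all(seq[i + k] == motif[k] for k in range(len(motif)))
    ]


def brute_force_digest(seq: str, states: dict[int, str], enzyme: str) -> list[tuple[int, int]]:
    """Fragment intervals of an EcoRI + MspI/HpaII double digest.

    `states` maps CCGG starts to state labels; missing sites are NONE.
    Cut rules restated independently: EcoRI cuts every GAATTC after
    offset 1; MspI cuts CCGG after offset 1 unless the outer C is
    methylated (hemi/full mCCGG) or both are (mCmCGG); HpaII cuts only
    unmethylated CCGG and hemimethylated mCCGG.
    """
    mspi_ok = {"NONE", "HEMI_INTERNAL", "FULL_INTERNAL"}
    hpaii_ok = {"NONE", "HEMI_EXTERNAL"}
    allowed = mspi_ok if enzyme == "MSPI" else hpaii_ok
    cuts = set()
    for p in scan_motif(seq, "GAATTC"):
        cuts.add(p + 1)
    for q in scan_motif(seq, "CCGG"):
        if states.get(q, "NONE") in allowed:
            cuts.add(q + 1)
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def dice_by_counting(x, y) -> float:
    a = sum(1 for i, j in zip(x, y) if i == 1 and j == 1)
    b = sum(1 for i, j in zip(x, y) if i == 1 and j == 0)
    c = sum(1 for i, j in zip(x, y) if i == 0 and j == 1)
    return 2 * a / (2 * a + b + c)


def smith_waterman(
    q: str,
    s: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Best local alignment score; affine gaps where the first gapped
    column scores `gap_open` and each further column `gap_extend`."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in match/mismatch or 0
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(
                0.0,
                max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + sub,
            )
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def upgma_cophenetic(dist: dict[frozenset, float], labels: list[str]) -> dict[frozenset, float]:
    """Cophenetic distances implied by UPGMA, computed by naive
    agglomeration (same arithmetic-mean linkage and lexicographic
    tie-break, independent bookkeeping)."""
    live = [frozenset([l]) for l in labels]
    size = {c: 1 for c in live}
    d: dict[frozenset, float] = {}
    for i, a in enumerate(live):
        for b in live[i + 1 :]:
            d[frozenset([a, b])] = dist[frozenset([next(iter(a)), next(iter(b))])]
    coph: dict[frozenset, float] = {}
    while len(live) > 1:
        best = None
        for i in range(len(live)):
            for j in range(i + 1, len(live)):
                x, y = live[i], live[j]
                key = (d[frozenset([x, y])], tuple(sorted([min(x), min(y)])))
                if best is None or key < best[:2]:
                    best = (key[0], key[1], x, y)
        dmin, _tie, x, y = best
        for a in x:
            for b in y:
                coph[frozenset([a, b])] = dmin
        merged = x | y
        for z in live:
            if z in (x, y):
                continue
            d[frozenset([merged, z])] = (
                size[x] * d[frozenset([x, z])] + size[y] * d[frozenset([y, z])]
            ) / (size[x] + size[y])
        size[merged] = size[x] + size[y]
        live = [z for z in live if z not in (x, y)] + [merged]
    return coph
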