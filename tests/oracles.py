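"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by different routes than the package:
explicit Gotoh matrices for alignment scores, depth-first path enumeration
for codon substitution counting, and textbook formulas for Pearson r.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

NEG = float("-inf")


def local_affine_score(a, b, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0):
    """Smith-Waterman with affine gaps (Gotoh); returns the best score."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
            best = max(best, M[i][j])
    return best


def global_affine_score(a, b, score_fn, gap_open, gap_extend):
    """Needleman-Wunsch with affine gaps for arbitrary alphabets."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
    return max(M[n][m], X[n][m], Y[n][m])


def translate4(codon):
    return str(Seq(codon).translate(table=4))


def ng86_codon_oracle(ca, cb):
    """Exhaustive-path NG86 counts for one codon pair under table 4.

    Returns (sa, sb, sd, nd): synonymous sites of each codon and averaged
    synonymous/nonsynonymous differences.  Synonymy is decided via
    Biopython's table-4 translation, independently of the package.
    """
    def sites(codon):
        total = 0.0
        for pos in range(3):
            syn = 0
            non_stop = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if translate4(alt) == "*":
                    continue
                non_stop += 1
                if translate4(alt) == translate4(codon):
                    syn += 1
            if non_stop:
                total += syn / non_stop
        return total

    diff = [i for i in range(3) if ca[i] != cb[i]]
    all_paths = []
    for order in permutations(diff):
        path = [ca]
        cur = ca
        for pos in order:
            cur = cur[:pos] + cb[pos] + cur[pos + 1:]
            path.append(cur)
        all_paths.append(path)
    valid = [p for p in all_paths if all(translate4(c) != "*" for c in p[1:-1])]
    if not valid:
        valid = all_paths
    sd = nd = 0.0
    for path in valid:
        for prev, nxt in zip(path, path[1:]):
            if translate4(prev) == translate4(nxt) and translate4(prev) != "*":
                sd += 1
            else:
                nd += 1
    k = len(valid)
    return sites(ca), sites(cb), sd / k if k else 0.0, nd / k if k else 0.0


def pearson_closed_form(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den
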