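"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's alignment machinery: plain
dynamic-programming matrices in numpy, exhaustive scans, and closed-form
algebra, so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1


def smith_waterman(a: str, b: str) -> tuple[int, float, int, int, int, int]:
    """Affine-gap local alignment by the full O(nm) Gotoh recurrence.

    Returns (score, identity, a_start, a_end, b_start, b_end) where
    identity counts matches over alignment columns (gaps included).
    """
    n, m = len(a), len(b)
    neg = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXTEND)
            sub = MATCH if ai == b[j - 1] and ai != "N" else MISMATCH
            diag = H[i - 1, j - 1] + sub
            H[i, j] = max(0, diag, E[i, j], F[i, j])
    score = int(H.max())
    if score == 0:
        return 0, 0.0, 0, 0, 0, 0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    a_end, b_end = int(i), int(j)
    matches = 0
    columns = 0
    state = "H"
    while H[i, j] > 0:
        if state == "H":
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i -= 1
            j -= 1
        elif state == "E":
            columns += 1
            if E[i, j] == E[i, j - 1] + GAP_EXTEND:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            columns += 1
            if F[i, j] == F[i - 1, j] + GAP_EXTEND:
                i -= 1
            else:
                i -= 1
                state = "H"
    return score, matches / columns, int(i), a_end, int(j), b_end


def needleman_wunsch_identity(a: str, b: str) -> float:
    """Global-alignment identity (matches / columns, unit gap cost)."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    import re

    matches = 0
    columns = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        columns += int(count)
        if op == "=":
            matches += int(count)
    return matches / columns if columns else 0.0


def orf_scan(sequence: str, min_nt: int) -> set[tuple[int, int, str]]:
    """Regex-free brute-force ORF enumeration used to cross-check the
    codon-walk scanner: for every stop codon in every frame/strand, pair it
    with the first ATG after the previous in-frame stop."""
    comp = str.maketrans("ACGT", "TGCA")
    out: set[tuple[int, int, str]] = set()
    n = len(sequence)
    for strand in ("+", "-"):
        s = sequence if strand == "+" else sequence.translate(comp)[::-1]
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            starts = [i for i, c in enumerate(codons) if c == "ATG"]
            stops = [i for i, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
            prev_stop = -1
            for stop in stops:
                atg = next((x for x in starts if prev_stop < x <= stop), None)
                if atg is not None and atg < stop:
                    nt_start = frame + 3 * atg
                    nt_end = frame + 3 * stop + 3
                    if nt_end - nt_start >= min_nt:
                        if strand == "+":
                            out.add((nt_start, nt_end, "+"))
                        else:
                            out.add((n - nt_end, n - nt_start, "-"))
                prev_stop = stop
    return out


def union_find_components(n_nodes: int, edges) -> list[set[int]]:
    """Brute-force union-find, as an independent check of graph
    connected-components clustering."""
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for i in range(n_nodes):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def ols_loglog(lengths, copies) -> tuple[float, float, float, float]:
    """Closed-form normal-equation OLS of log10(copies) on log10(length):
    (slope, intercept, slope_se, intercept_se)."""
    x = np.log10(np.asarray(lengths, dtype=float))
    y = np.log10(np.asarray(copies, dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    return (
        float(beta[1]),
        float(beta[0]),
        float(np.sqrt(cov[1, 1])),
        float(np.sqrt(cov[0, 0])),
    )
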