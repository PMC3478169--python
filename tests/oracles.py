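"""Independent brute-force oracles used to validate pipeline operations.

These are deliberately simple, loop-based implementations that share no
code with the package: enumeration, plain dynamic programming with score
tuples, and exhaustive scans.
"""

from __future__ import annotations

NEG = float("-inf")


def identity_oracle(a: str, b: str) -> float:
    """Semi-global identity by tuple dynamic programming.

    The shorter sequence is aligned globally against the longer (match +1,
    mismatch -1, gap open -2, gap extend -1; overhangs of the longer are
    free).  Cells hold (score, identities) compared lexicographically, so
    among maximum-score alignments the one with the most identical aligned
    bases wins.  Returns identities / len(shorter).
    """
    x, y = (a, b) if len(a) >= len(b) else (b, a)
    n, m = len(x), len(y)
    neg = (NEG, 0)

    def add(cell, ds, di=0):
        return (cell[0] + ds, cell[1] + di) if cell[0] != NEG else neg

    M = [neg] * (m + 1)
    Ix = [neg] * (m + 1)
    Iy = [neg] * (m + 1)
    M[0] = (0.0, 0)
    for j in range(1, m + 1):
        Iy[j] = (-2.0 - (j - 1), 0)
    for i in range(1, n + 1):
        nM = [neg] * (m + 1)
        nIx = [neg] * (m + 1)
        nIy = [neg] * (m + 1)
        for j in range(m + 1):
            if j > 0:
                prev = max(M[j - 1], Ix[j - 1], Iy[j - 1])
                if x[i - 1] == y[j - 1]:
                    nM[j] = add(prev, 1.0, 1)
                else:
                    nM[j] = add(prev, -1.0, 0)
            opened = max(M[j], Iy[j])
            if j == 0 or j == m:
                nIx[j] = max(opened, Ix[j])
            else:
                nIx[j] = max(add(opened, -2.0), add(Ix[j], -1.0))
        for j in range(1, m + 1):
            nIy[j] = max(
                add(max(nM[j - 1], nIx[j - 1]), -2.0),
                add(nIy[j - 1], -1.0),
            )
        M, Ix, Iy = nM, nIx, nIy
    best = max(M[m], Ix[m], Iy[m])
    return best[1] / m


def n50_oracle(lengths) -> int:
    """Brute force over sorted cumulative sums."""
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return L
    raise ValueError("empty input")


def msat_oracle(seq: str, min_units: dict[int, int]):
    """Exhaustive microsatellite scan: every primitive motif at every start.

    Returns the set of maximal hits as (canonical_motif, start_1based,
    end_1based, unit_count) tuples.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def primitive(motif):
        for d in range(1, len(motif)):
            if len(motif) % d == 0 and motif[:d] * (len(motif) // d) == motif:
                return False
        return True

    def canonical(motif):
        rc = "".join(comp[c] for c in reversed(motif))
        forms = [motif[i:] + motif[:i] for i in range(len(motif))]
        forms += [rc[i:] + rc[:i] for i in range(len(rc))]
        return min(forms)

    hits = set()
    n = len(seq)
    for k, min_u in min_units.items():
        for start in range(n):
            motif = seq[start : start + k]
            if len(motif) < k or not primitive(motif):
                continue
            units = 1
            while seq[start + units * k : start + (units + 1) * k] == motif:
                units += 1
            if units < min_u:
                continue
            # leftmost anchoring: skip starts where the periodic run
            # continues to the left by even a single base
            if start >= 1 and seq[start - 1] == seq[start - 1 + k]:
                continue
            hits.add((canonical(motif), start + 1, start + units * k, units))
    return hits


def greedy_cluster_oracle(sequences, threshold, identity_fn):
    """Transitive-closure-free greedy clustering, longest first (ties by
    input order), first-fit against cluster representatives.  Returns the
    cluster assignment as a list of member-index lists."""
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    clusters: list[list[int]] = []
    for i in order:
        for members in clusters:
            if identity_fn(sequences[members[0]], sequences[i]) >= threshold:
                members.append(i)
                break
        else:
            clusters.append([i])
    return clusters
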