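"""Independent reference implementations used to verify the package.

These are deliberately written against Biopython primitives and naive
enumeration, sharing no code with the package's numba kernels.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def _score(a: str, b: str) -> float:
    # the package maps '*' to the matrix minimum; BLOSUM62's own '*' value
    # (-4) equals that minimum, so direct lookup matches
    return float(_B62[a][b])


def six_frames(dna: str) -> list[str]:
    """Frames ordered +1,+2,+3,-1,-2,-3; trailing partial codons dropped."""
    out = []
    for strand in (dna, str(Seq(dna).reverse_complement())):
        for off in range(3):
            sub = strand[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append(str(Seq(sub).translate()) if sub else "")
    return out


def best_seeded_alignment(query_aa: str, subject_aa: str) -> float | None:
    """Best ungapped local alignment score containing an exact 4-residue seed.

    Seeds must be 4 consecutive identical canonical residues; extension is
    unbounded (no X-drop), taking the best non-negative prefix sum on each
    side of the seed.  Returns None when no seed exists.
    """
    best = None
    lq, ls = len(query_aa), len(subject_aa)
    for i in range(lq - 3):
        w = query_aa[i : i + 4]
        if not set(w) <= _CANONICAL:
            continue
        for j in range(ls - 3):
            if subject_aa[j : j + 4] != w:
                continue
            seed = sum(_score(w[k], w[k]) for k in range(4))
            # right extension
            right = 0.0
            run = 0.0
            qi, sj = i + 4, j + 4
            while qi < lq and sj < ls:
                run += _score(query_aa[qi], subject_aa[sj])
                right = max(right, run)
                qi += 1
                sj += 1
            # left extension
            left = 0.0
            run = 0.0
            qi, sj = i - 1, j - 1
            while qi >= 0 and sj >= 0:
                run += _score(query_aa[qi], subject_aa[sj])
                left = max(left, run)
                qi -= 1
                sj -= 1
            total = seed + left + right
            if best is None or total > best:
                best = total
    return best


def oracle_best_hit(
    dna: str, entries: list[tuple[str, str]]
) -> tuple[float, list[str]] | None:
    """Best raw score over all frames/entries, with the entry ids achieving it.

    ``entries`` is a list of (entry_id, protein) pairs.  Returns None when no
    frame of the read shares a 4-residue seed with any entry.
    """
    frames = six_frames(dna)
    best: float | None = None
    winners: list[str] = []
    for eid, prot in entries:
        escore: float | None = None
        for q in frames:
            s = best_seeded_alignment(q, prot)
            if s is not None and (escore is None or s > escore):
                escore = s
        if escore is None:
            continue
        if best is None or escore > best:
            best, winners = escore, [eid]
        elif escore == best:
            winners.append(eid)
    if best is None:
        return None
    return best, sorted(winners)


def bit_and_evalue(
    raw: float, search_space: float, lam: float = 0.318, k: float = 0.13
) -> tuple[float, float]:
    bit = (lam * raw - math.log(k)) / math.log(2.0)
    return bit, search_space * 2.0**-bit


def mwu_exact_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full labeling enumeration."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    mu = n * m / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for c in combinations(range(n + m), n):
        u = sum(ranks[i] for i in c) - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            count += 1
    return u_obs, count / total
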