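"""Numba-compiled inner loops for the translated search and host k-mer filter.

These kernels work on flat integer-coded arrays (see :mod:`hydroprofiler._seq`)
so that per-read work is allocation-free.  The public, documented interfaces
live in :mod:`hydroprofiler.search`; nothing here is part of the package API.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

from . import _seq

SEED_LEN = 4
_N_KEYS = _seq.N_AA ** SEED_LEN  # 22^4 = 234,256


def build_seed_index(
    proteins: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CSR seed index over all 4-mers of the reference proteins.

    Returns ``(ref_concat, entry_starts, seed_start, seed_hits)`` where
    ``seed_hits`` packs ``entry_index * 2**32 + position`` for each occurrence
    of a seed key; occurrences of key ``q`` live at
    ``seed_hits[seed_start[q]:seed_start[q + 1]]``.  Seeds containing X or a
    stop are not indexed.
    """
    keys_all: list[np.ndarray] = []
    ents_all: list[np.ndarray] = []
    poss_all: list[np.ndarray] = []
    for ei, p in enumerate(proteins):
        if len(p) < SEED_LEN:
            continue
        w = sliding_window_view(p.astype(np.int64), SEED_LEN)
        ok = (w < 20).all(axis=1)
        idx = np.nonzero(ok)[0]
        if len(idx) == 0:
            continue
        ww = w[idx]
        k = ((ww[:, 0] * _seq.N_AA + ww[:, 1]) * _seq.N_AA + ww[:, 2]) * _seq.N_AA + ww[:, 3]
        keys_all.append(k)
        ents_all.append(np.full(len(idx), ei, dtype=np.int64))
        poss_all.append(idx.astype(np.int64))

    if keys_all:
        keys = np.concatenate(keys_all)
        ents = np.concatenate(ents_all)
        poss = np.concatenate(poss_all)
    else:
        keys = np.zeros(0, dtype=np.int64)
        ents = np.zeros(0, dtype=np.int64)
        poss = np.zeros(0, dtype=np.int64)

    order = np.argsort(keys, kind="stable")
    keys, ents, poss = keys[order], ents[order], poss[order]
    seed_start = np.zeros(_N_KEYS + 1, dtype=np.int64)
    np.add.at(seed_start, keys + 1, 1)
    np.cumsum(seed_start, out=seed_start)
    seed_hits = ents * (1 << 32) + poss

    ref_concat = (
        np.concatenate(proteins) if proteins else np.zeros(0, dtype=np.int8)
    ).astype(np.int8)
    entry_starts = np.zeros(len(proteins) + 1, dtype=np.int64)
    np.cumsum([len(p) for p in proteins], out=entry_starts[1:])
    return ref_concat, entry_starts, seed_start, seed_hits


@njit(cache=False)
def search_batch(
    nt_concat,
    offsets,
    codon_aa,
    blosum,
    ref,
    entry_starts,
    seed_start,
    seed_hits,
    xdrop,
):
    """Best seeded ungapped translated alignment per query sequence.

    For every query, all six reading frames are translated, every exact
    4-residue seed shared with the reference is extended without gaps in both
    directions, and the single best-scoring alignment is kept (ties break to
    the lowest entry index).  ``xdrop <= 0`` disables the X-drop early stop,
    making the reported score exactly the best ungapped local alignment that
    contains a seed.

    Returns ``(best_score, best_entry, best_frame, best_ref_start)``; entries
    are -1 where no seed extended at all.
    """
    n = len(offsets) - 1
    out_score = np.full(n, -1, dtype=np.int64)
    out_entry = np.full(n, -1, dtype=np.int64)
    out_frame = np.zeros(n, dtype=np.int64)
    out_rstart = np.zeros(n, dtype=np.int64)

    max_len = 0
    for i in range(n):
        l = offsets[i + 1] - offsets[i]
        if l > max_len:
            max_len = l
    qbuf = np.empty(max_len // 3 + 1, dtype=np.int64)
    rc = np.empty(max_len, dtype=np.int8)

    for i in range(n):
        o0 = offsets[i]
        L = offsets[i + 1] - o0
        for j in range(L):
            b = nt_concat[o0 + L - 1 - j]
            rc[j] = 4 if b >= 4 else 3 - b

        best_sc = np.int64(-1)
        best_e = np.int64(-1)
        best_f = np.int64(0)
        best_r = np.int64(0)

        for fi in range(6):
            off = fi if fi < 3 else fi - 3
            flen = (L - off) // 3
            if flen < SEED_LEN:
                continue
            if fi < 3:
                for t in range(flen):
                    p = o0 + off + 3 * t
                    qbuf[t] = codon_aa[
                        nt_concat[p] * 25 + nt_concat[p + 1] * 5 + nt_concat[p + 2]
                    ]
            else:
                for t in range(flen):
                    p = off + 3 * t
                    qbuf[t] = codon_aa[rc[p] * 25 + rc[p + 1] * 5 + rc[p + 2]]
            frame_code = fi + 1 if fi < 3 else -(fi - 2)

            key = np.int64(0)
            run = 0
            for t in range(flen):
                a = qbuf[t]
                key = (key * 22 + a) % 234256
                if a >= 20:
                    run = 0
                    continue
                run += 1
                if run < SEED_LEN:
                    continue
                lo = seed_start[key]
                hi = seed_start[key + 1]
                if lo == hi:
                    continue
                qpos = t - SEED_LEN + 1
                for s in range(lo, hi):
                    packed = seed_hits[s]
                    e = packed >> 32
                    rpos = packed & 0xFFFFFFFF
                    e0 = entry_starts[e]
                    elen = entry_starts[e + 1] - e0

                    sc = np.int64(0)
                    for k in range(SEED_LEN):
                        sc += blosum[qbuf[qpos + k], ref[e0 + rpos + k]]

                    # right extension
                    acc = np.int64(0)
                    best_right = np.int64(0)
                    qi = qpos + SEED_LEN
                    ri = rpos + SEED_LEN
                    while qi < flen and ri < elen:
                        acc += blosum[qbuf[qi], ref[e0 + ri]]
                        if acc > best_right:
                            best_right = acc
                        elif xdrop > 0 and acc < best_right - xdrop:
                            break
                        qi += 1
                        ri += 1

                    # left extension
                    acc = np.int64(0)
                    best_left = np.int64(0)
                    left_len = np.int64(0)
                    qi = qpos - 1
                    ri = rpos - 1
                    steps = np.int64(0)
                    while qi >= 0 and ri >= 0:
                        steps += 1
                        acc += blosum[qbuf[qi], ref[e0 + ri]]
                        if acc > best_left:
                            best_left = acc
                            left_len = steps
                        elif xdrop > 0 and acc < best_left - xdrop:
                            break
                        qi -= 1
                        ri -= 1

                    total = sc + best_right + best_left
                    if total > best_sc or (total == best_sc and e < best_e):
                        best_sc = total
                        best_e = e
                        best_f = frame_code
                        best_r = rpos - left_len

        out_score[i] = best_sc
        out_entry[i] = best_e
        out_frame[i] = best_f
        out_rstart[i] = best_r
    return out_score, out_entry, out_frame, out_rstart


def build_host_kmer_set(codes: np.ndarray, k: int) -> np.ndarray:
    """Sorted array of canonical (min of strand pair) k-mer keys of a genome."""
    if len(codes) < k:
        return np.zeros(0, dtype=np.int64)
    valid = codes < 4
    w = sliding_window_view(codes.astype(np.int64), k)
    ok = sliding_window_view(valid, k).all(axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = w @ weights
    rc_codes = _seq.revcomp_codes(codes)
    wr = sliding_window_view(rc_codes.astype(np.int64), k)
    rev = (wr @ weights)[::-1]  # rev[i] = revcomp key of window starting at i
    canon = np.minimum(fwd, rev)[ok]
    return np.unique(canon)


@njit(cache=False)
def host_shared_kmers(nt_concat, offsets, host_sorted, k, stop_at):
    """Count canonical k-mers each read shares with the host set.

    Counting stops early once ``stop_at`` shared k-mers are found.
    """
    n = len(offsets) - 1
    out = np.zeros(n, dtype=np.int64)
    mask = (np.int64(1) << np.int64(2 * k)) - np.int64(1)
    top_shift = np.int64(2 * (k - 1))
    nhost = len(host_sorted)
    for i in range(n):
        o0 = offsets[i]
        L = offsets[i + 1] - o0
        key = np.int64(0)
        rkey = np.int64(0)
        run = 0
        cnt = np.int64(0)
        for j in range(L):
            b = np.int64(nt_concat[o0 + j])
            if b >= 4:
                run = 0
                key = np.int64(0)
                rkey = np.int64(0)
                continue
            key = ((key << 2) | b) & mask
            rkey = (rkey >> 2) | ((np.int64(3) - b) << top_shift)
            run += 1
            if run < k:
                continue
            canon = key if key < rkey else rkey
            lo = np.searchsorted(host_sorted, canon)
            if lo < nhost and host_sorted[lo] == canon:
                cnt += 1
                if cnt >= stop_at:
                    break
        out[i] = cnt
    return out
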