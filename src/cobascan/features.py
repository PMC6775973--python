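"""Rho-independent terminator scanning and bidirectional pairing.

Candidate hairpins (stem 4-20 bp with at most one mismatched rung, loop
4-12 nt) followed by a T-tract on the coding strand are scored with a
simplified nearest-neighbor model: each stack of adjacent paired rungs
contributes the strength of its weaker rung (G:C 3.3, A:T 1.1, G:U wobble
0.0 kcal/mol), hairpin-loop initiation costs 4.0 plus 1.0 per loop base
beyond four, and a mismatched rung costs 3.0 and breaks stacking. Calls
with |dG| >= 10.5 kcal/mol are kept, mirroring the magnitude cutoff used
for terminator screening of phage genomes. Both strands are scanned;
opposite-strand calls at the same locus merge into one bidirectional call,
the arrangement that separates the two transcriptional arms of cobavirus
genomes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .records import reverse_complement


@dataclass
class TerminatorModel:
    """Scoring constants of the hairpin ΔG surrogate (kcal/mol magnitudes)."""

    stack_gc: float = 3.3
    stack_at: float = 1.1
    stack_wobble: float = 0.0
    loop_init: float = 4.0
    loop_per_extra_base: float = 1.0
    mismatch_penalty: float = 3.0
    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 4
    loop_max: int = 12
    max_stem_mismatches: int = 1
    u_tract_window: int = 8


@dataclass
class TerminatorCall:
    position: int  # 0-based hairpin start on the forward genome
    end: int  # hairpin end (exclusive)
    strand: str
    stem_len: int
    loop_len: int
    mismatches_in_stem: int
    delta_g: float  # negative = stable
    u_tract_len: int
    bidirectional: bool = False


def _scan_strand(arr: np.ndarray, model: TerminatorModel, min_abs_dg: float,
                 min_u_tract: int) -> list[tuple]:
    """Best qualifying hairpin per loop-start position on one strand.

    Returns tuples (hairpin_start, hairpin_end, stem, loop, mm, |dG|, u_len)
    in strand-local coordinates.
    """
    n = len(arr)
    if n < model.stem_min * 2 + model.loop_min + min_u_tract:
        return []
    A, C, G, T = 65, 67, 71, 84
    is_t = arr == T
    # T-run length starting at each position: distance to the next non-T base
    not_t_idx = np.flatnonzero(~is_t)
    nxt = np.full(n + 1, n, dtype=np.int64)
    if len(not_t_idx):
        # next non-T at or after each position
        nxt[:n] = not_t_idx[np.searchsorted(not_t_idx, np.arange(n))
                            .clip(max=len(not_t_idx) - 1)]
        nxt[:n][np.arange(n) > not_t_idx[-1]] = n
    run = np.zeros(n + 1, dtype=np.int64)
    run[:n] = np.maximum(nxt[:n] - np.arange(n), 0)
    # u_ok[e]: a T-run of >= min_u_tract starts within [e, e+window]
    starts = run[:n] >= min_u_tract
    w = model.u_tract_window
    shifted = np.zeros((w + 1, n + 1), dtype=bool)
    for off in range(w + 1):
        if n - off > 0:
            shifted[off, :n - off] = starts[off:]
    u_ok = shifted.any(axis=0)
    first = np.argmax(shifted, axis=0)
    u_len = np.zeros(n + 1, dtype=np.int64)
    e_idx = np.flatnonzero(u_ok)
    u_len[e_idx] = run[e_idx + first[e_idx]]

    # rung at depth i of a hairpin with loop start a pairs positions
    # (a-1-i, a+loop+i); the pair class depends only on the left position and
    # the gap g = loop + 2i + 1, so classify once per gap via a 4x4 table.
    code = np.zeros(n, dtype=np.int8)
    code[arr == C] = 1
    code[arr == G] = 2
    code[arr == T] = 3
    cls_lut = np.zeros(16, dtype=np.int8)  # 0 none, 1 AT, 2 GC, 3 GT wobble
    cls_lut[0 * 4 + 3] = cls_lut[3 * 4 + 0] = 1
    cls_lut[2 * 4 + 1] = cls_lut[1 * 4 + 2] = 2
    cls_lut[2 * 4 + 3] = cls_lut[3 * 4 + 2] = 3
    str_lut = np.array(
        [0.0, model.stack_at, model.stack_gc, model.stack_wobble], dtype=np.float32
    )
    kmax = model.stem_max
    gap_cls: dict[int, np.ndarray] = {}

    def cls_for_gap(g: int) -> np.ndarray:
        got = gap_cls.get(g)
        if got is None:
            got = cls_lut[code[: n - g] * 4 + code[g:]]
            gap_cls[g] = got
        return got

    best: dict[int, tuple] = {}
    for loop in range(model.loop_min, model.loop_max + 1):
        # row i holds, indexed by loop start a, the class of rung i
        pc = np.zeros((kmax, n), dtype=np.int8)
        for i in range(kmax):
            g = loop + 2 * i + 1
            cl = cls_for_gap(g)  # indexed by left position, length n-g
            hi = min(n, 1 + i + len(cl))
            pc[i, 1 + i: hi] = cl[: hi - (1 + i)]
        strength = str_lut[pc]
        paired = pc != 0
        stack = np.minimum(strength[:-1], strength[1:])
        stack[~(paired[:-1] & paired[1:])] = 0.0
        cum_stack = np.cumsum(stack, axis=0, dtype=np.float32)
        cum_mm = np.cumsum(~paired, axis=0, dtype=np.int16)
        loop_pen = model.loop_init + model.loop_per_extra_base * (loop - model.loop_min)
        for k in range(model.stem_min, kmax + 1):
            mm = cum_mm[k - 1]
            dg = (cum_stack[k - 2] if k >= 2 else np.zeros(n, np.float32)) \
                - loop_pen - model.mismatch_penalty * mm
            uo = np.zeros(n, dtype=bool)
            ul = np.zeros(n, dtype=np.int64)
            shift = loop + k
            uo[: n - shift + 1] = u_ok[shift:]
            ul[: n - shift + 1] = u_len[shift:]
            valid = (
                (mm <= model.max_stem_mismatches)
                & paired[k - 1]
                & uo
                & (dg >= min_abs_dg)
            )
            valid[:k] = False
            for a in np.where(valid)[0]:
                h_start, h_end = a - k, a + loop + k
                cand = (h_start, h_end, k, loop, int(mm[a]), float(dg[a]), int(ul[a]))
                prev = best.get(a)
                if prev is None or cand[5] > prev[5]:
                    best[a] = cand
    return list(best.values())


def _reduce_overlaps(cands: list[tuple]) -> list[tuple]:
    """Keep the best-|dG| call among mutually overlapping candidates."""
    kept: list[tuple] = []
    for c in sorted(cands, key=lambda t: (-t[5], t[0])):
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    return sorted(kept)


def find_terminators(
    genome,
    min_abs_delta_g: float = 10.5,
    min_u_tract: int = 3,
    model: TerminatorModel | None = None,
) -> list[TerminatorCall]:
    """Scan both strands for terminator hairpins passing the |ΔG| cutoff."""
    model = model or TerminatorModel()
    seq = genome.sequence if hasattr(genome, "sequence") else str(genome).upper()
    n = len(seq)
    calls: list[TerminatorCall] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        cands = _reduce_overlaps(_scan_strand(arr, model, min_abs_delta_g, min_u_tract))
        for h_start, h_end, k, loop, mm, dg, ul in cands:
            if strand == "-":
                h_start, h_end = n - h_end, n - h_start
            calls.append(
                TerminatorCall(
                    position=h_start,
                    end=h_end,
                    strand=strand,
                    stem_len=k,
                    loop_len=loop,
                    mismatches_in_stem=mm,
                    delta_g=-dg,
                    u_tract_len=ul,
                )
            )
    return sorted(calls, key=lambda c: (c.position, c.strand))


def pair_bidirectional(
    calls: list[TerminatorCall], max_gap: int = 60
) -> list[TerminatorCall]:
    """Merge opposite-strand calls at one locus into bidirectional calls.

    A + and a - call whose hairpins overlap or lie within ``max_gap`` bp are
    merged into a single call at the midpoint of the two hairpins, keeping
    the statistics of the more stable partner. Unpaired calls pass through.
    """
    plus = [c for c in calls if c.strand == "+"]
    minus = [c for c in calls if c.strand == "-"]
    used: set[int] = set()
    out: list[TerminatorCall] = []
    for p in plus:
        match = None
        for j, m in enumerate(minus):
            if j in used:
                continue
            gap = max(p.position, m.position) - min(p.end, m.end)
            if gap <= max_gap:
                match = j
                break
        if match is None:
            out.append(p)
            continue
        used.add(match)
        m = minus[match]
        strong = p if p.delta_g <= m.delta_g else m
        mid = (min(p.position, m.position) + max(p.end, m.end)) // 2
        out.append(
            replace(
                strong,
                position=mid,
                end=mid,
                strand=".",
                bidirectional=True,
            )
        )
    out.extend(m for j, m in enumerate(minus) if j not in used)
    return sorted(out, key=lambda c: (c.position, c.strand))
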