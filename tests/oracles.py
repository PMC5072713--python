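"""Independent brute-force oracles used to validate the scanners and callers.

Everything here recomputes results from first principles (full scans,
exhaustive enumeration, hand-rolled SAM walking) without reusing the
package's seed-and-extend / dynamic-programming machinery.
"""

from __future__ import annotations

import itertools
import re

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Longest disjoint inverted pair (quadratic DP)
# ---------------------------------------------------------------------------

def longest_disjoint_inverted_pair(seq: str) -> int:
    """Length of the longest pair of disjoint substrings that are exact
    reverse complements of each other (linear sequence)."""
    L = len(seq)
    R = revcomp(seq)
    best = 0
    prev = [0] * (L + 1)
    for i in range(L):
        cur = [0] * (L + 1)
        for j in range(L):
            if seq[i] == R[j]:
                m = prev[j] + 1
                cur[j + 1] = m
                # first interval ends at i, second starts at b = L-1-j; as the
                # shared length m' shrinks, the first loses bases on the left
                # and the second on the right
                b = L - 1 - j
                if i < b:
                    fit = m                       # disjoint at full length
                else:
                    fit = min(m, max(0, (i - b + 1) // 2))
                best = max(best, fit)
        prev = cur
    return best


# ---------------------------------------------------------------------------
# SSR enumeration (full scan, base-level maximality, minimal period)
# ---------------------------------------------------------------------------

def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[int, int, int]]:
    """All qualifying maximal perfect tandem runs as (start 1-based, unit, copies)."""
    n = len(seq)
    out = set()
    for p in sorted(thresholds):
        for i in range(n - 2 * p + 1):
            motif = seq[i:i + p]
            if "N" in motif:
                continue
            if any(p % d == 0 and motif == motif[:d] * (p // d)
                   for d in range(1, p)):
                continue
            if i > 0 and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                continue       # not base-level maximal on the left
            copies = 1
            while seq[i + copies * p:i + (copies + 1) * p] == motif:
                copies += 1
            if copies >= thresholds[p]:
                out.add((i + 1, p, copies))
    return out


# ---------------------------------------------------------------------------
# Maximal repeat pairs (full per-diagonal scan)
# ---------------------------------------------------------------------------

def brute_repeat_pairs(seq: str, min_len: int,
                       max_mm: int) -> set[tuple[str, tuple, tuple, int, int]]:
    """All maximal forward/palindromic repeat pairs by scanning every
    diagonal completely (no seeding)."""
    L = len(seq)
    found = set()
    for b, kind in ((seq, "forward"), (revcomp(seq), "palindromic")):
        nb = len(b)
        for d in range(-(nb - 1), L):
            lo, hi = max(0, d), min(L, nb + d) - 1
            if hi - lo + 1 < min_len:
                continue
            if kind == "forward" and d == 0:
                continue
            mism = [x for x in range(lo, hi + 1) if seq[x] != b[x - d]]
            bounds = [lo - 1] + mism + [hi + 1]
            for t in range(len(bounds) - (max_mm + 1)):
                a0, a1 = bounds[t] + 1, bounds[t + max_mm + 1] - 1
                length = a1 - a0 + 1
                if length < min_len:
                    continue
                mm = sum(1 for x in mism if a0 <= x <= a1)
                if kind == "forward":
                    p1, p2 = sorted(((a0, a1), (a0 - d, a1 - d)))
                else:
                    s2 = L - (a0 - d) - length
                    p1, p2 = sorted(((a0, a1), (s2, s2 + length - 1)))
                if p1 == p2 or p1[1] >= p2[0]:
                    continue
                found.add((kind, (p1[0] + 1, p1[1] + 1),
                           (p2[0] + 1, p2[1] + 1), length, mm))
    return _drop_contained_pairs(found)


def _drop_contained_pairs(found: set) -> set:
    keep = set()
    for item in found:
        kind, p1, p2, length, mm = item
        contained = False
        for other in found:
            if other == item or other[0] != kind or other[3] <= length:
                continue
            q1, q2 = other[1], other[2]
            if (q1[0] <= p1[0] and p1[1] <= q1[1] and q2[0] <= p2[0]
                    and p2[1] <= q2[1] and p1[0] - q1[0] == p2[0] - q2[0]):
                contained = True
                break
        if not contained:
            keep.add(item)
    return keep


# ---------------------------------------------------------------------------
# Naive SAM pileup walker
# ---------------------------------------------------------------------------

def naive_pileup(sam_path, ref_seq: str, circular: bool = True,
                 min_qual: int = 25) -> dict[int, dict[str, int]]:
    """Hand-parsed, CIGAR-walking pileup: {position: {base: count}}."""
    counts: dict[int, dict[str, int]] = {}
    L = len(ref_seq)
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag, pos, mapq = int(f[1]), int(f[3]), int(f[4])
            cigar, seqs, quals = f[5], f[9], f[10]
            if flag & 0x4 or flag & 0x100 or flag & 0x800 or mapq == 0:
                continue
            nh = [x for x in f[11:] if x.startswith("NH:i:")]
            if nh and int(nh[0].split(":")[2]) > 1:
                continue
            qpos, rpos = 0, pos - 1
            for num, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                num = int(num)
                if op in "M=X":
                    for t in range(num):
                        q = ord(quals[qpos + t]) - 33
                        base = seqs[qpos + t]
                        if q >= min_qual and base != "N":
                            p = (rpos + t) % L + 1 if circular else rpos + t + 1
                            counts.setdefault(p, {})
                            counts[p][base] = counts[p].get(base, 0) + 1
                    qpos += num
                    rpos += num
                elif op in "IS":
                    qpos += num
                elif op in "DN":
                    rpos += num
                # H, P: nothing
    return counts


# ---------------------------------------------------------------------------
# Exhaustive most-parsimonious reconstruction enumeration
# ---------------------------------------------------------------------------

def exhaustive_mprs(tree, character: dict[str, int],
                    fix_root: int | None = None) -> tuple[int, list[dict]]:
    """(min changes, optimal internal assignments) by trying all 2^n maps."""
    internals = [n for n in tree.nodes if not n.is_leaf]
    leaves = {n.name: int(character[n.name]) for n in tree.nodes if n.is_leaf}
    best, winners = None, []
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip((n.index for n in internals), combo))
        if fix_root is not None and assign[tree.root.index] != fix_root:
            continue
        changes = 0
        for node in tree.nodes:
            st = assign[node.index] if not node.is_leaf else leaves[node.name]
            for child in node.children:
                cs = (assign[child.index] if not child.is_leaf
                      else leaves[child.name])
                changes += st != cs
        if best is None or changes < best:
            best, winners = changes, [assign]
        elif changes == best:
            winners.append(assign)
    return best, winners
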