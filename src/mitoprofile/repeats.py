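"""Detection of SSRs, tandem repeats, inverted repeats, palindromes, hairpins
and ambiguity-coded motifs.

Coordinate and maximality conventions (documented because census totals from
web tools depend on them):

* all hits use 1-based inclusive coordinates on the forward strand;
* an SSR is a maximal perfect run of a primitive unit, trimmed to whole
  copies and reported once with its smallest period ((AT)3, never (ATAT)1.5);
* a palindrome is an even-length window equal to its own reverse complement;
  by default only the maximal palindrome per center is reported
  (``count_all=True`` reports every qualifying sub-length, the convention
  used by palindrome-census web tools);
* an inverted repeat is a pair of arms (arm, spacer, reverse-complement arm)
  maximal along its anti-diagonal: the arms cannot be grown outward or inward
  without breaking a pair, with the spacer (gap) bounded;
* a hairpin is an inverted repeat whose spacer length lies in a loop window;
* the tandem-repeat detector is a simplified seed-and-extend scanner with
  wraparound dynamic programming against a majority consensus, honouring the
  Tandem Repeats Finder weights (match +2, mismatch -7, indel -7, minimum
  alignment score 50, maximum period 500); exact agreement with TRF's
  probabilistic model is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import MitoprofileError
from .seq_io import revcomp

_COMP = str.maketrans("ACGTN", "TGCAN")


def _comp_char(c: str) -> str:
    return c.translate(_COMP)


@dataclass
class ScanHit:
    kind: str  # SSR | tandem | inverted | palindrome | hairpin | motif
    start: int  # 1-based inclusive
    end: int
    unit_or_motif: str = ""
    period: int | None = None
    copy_number: float | None = None
    percent_matches: float | None = None
    arm_length: int | None = None
    loop_length: int | None = None
    gap: int | None = None
    score: float | None = None
    strand: str = "+"

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple:
        return (self.start, self.end, self.kind, self.unit_or_motif, self.gap)


def _is_primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


# ---------------------------------------------------------------------------
# SSRs (perfect short tandem repeats, homopolymers included at unit_min=1)
# ---------------------------------------------------------------------------

def find_ssrs(
    seq: str,
    unit_min: int = 1,
    unit_max: int = 10,
    min_copies: int = 3,
    min_length: int = 6,
    mismatch_pct: float = 0,
    circular: bool = False,
) -> list[ScanHit]:
    """Maximal perfect tandem runs of primitive units.

    A run is reported when it holds at least ``min_copies`` whole copies and
    the whole-copy span is at least ``min_length`` bp. Overlapping runs of
    different units are all reported.
    """
    if mismatch_pct:
        raise MitoprofileError("find_ssrs is a perfect-repeat scanner (mismatch_pct must be 0)")
    L = len(seq)
    overhang = min(L, unit_max * (min_copies + 1) * 4) if circular else 0
    s = seq + seq[:overhang]
    hits: list[ScanHit] = []
    for p in range(unit_min, unit_max + 1):
        run_start: int | None = None
        for i in range(p, len(s) + 1):
            matched = i < len(s) and s[i] == s[i - p]
            if matched and run_start is None:
                run_start = i
            elif not matched and run_start is not None:
                a = run_start - p  # left edge of the periodic region
                span = i - a
                copies = span // p
                unit = s[a : a + p]
                if (
                    copies >= min_copies
                    and copies * p >= min_length
                    and _is_primitive(unit)
                ):
                    hits.append(
                        ScanHit(
                            kind="SSR",
                            start=a + 1,
                            end=a + copies * p,
                            unit_or_motif=unit,
                            period=p,
                            copy_number=float(copies),
                            percent_matches=100.0,
                        )
                    )
                run_start = None
    if circular:
        hits = _dedupe_circular(hits, L)
    return sorted(hits, key=ScanHit.key)


def _dedupe_circular(hits: list[ScanHit], L: int) -> list[ScanHit]:
    """Drop hits in the wrapped prefix that re-describe a hit crossing the origin."""
    kept = [h for h in hits if h.start <= L]
    spans = [(h.start, h.end) for h in kept]
    out = []
    for h in kept:
        shadow = (h.start + L, h.end + L)
        if any(s <= shadow[0] and shadow[1] <= e for (s, e) in spans):
            continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# inverted repeats / hairpins / palindromes (anti-diagonal scan)
# ---------------------------------------------------------------------------

def _inverted_scan(
    seq: str,
    arm_min: int,
    arm_max: int,
    gap_min: int,
    gap_max: int,
) -> list[tuple[int, int, int, int]]:
    """All maximal (left_start0, arm, gap) triples; returns
    (start0, end0, arm, gap) tuples in 0-based inclusive coordinates.

    Pairs of positions (p, q) with p + q = S match when seq[p] is the
    complement of seq[q]; a maximal run of consecutive matching pairs along
    anti-diagonal S is one candidate hit whose gap is fixed by its innermost
    pair. Arms longer than ``arm_max`` are trimmed outward (inner anchor kept).
    """
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    carr = comp[arr]
    window = gap_max // 2 + 1 + arm_max + 1
    out = []
    for S in range(1, 2 * L - 2):
        pmax = (S - 1) // 2
        pmin = max(0, S - L + 1)
        if pmax < pmin:
            continue
        plo = max(pmin, pmax - window + 1)
        ps = np.arange(plo, pmax + 1)
        m = arr[ps] == carr[S - ps]
        # maximal runs of True, walking outward->inward
        idx = np.flatnonzero(m)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = np.split(idx, breaks + 1)
        for run in run_bounds:
            p_outer, p_inner = plo + run[0], plo + run[-1]
            # a run starting at the window edge may extend further out;
            # its true length is >= arm_max + offset, so trimming applies
            gap = S - 2 * p_inner - 1
            if gap < gap_min or gap > gap_max:
                continue
            arm = p_inner - p_outer + 1
            if p_outer == plo and plo > pmin:
                arm = arm_max  # touches window edge: at least arm_max long
            arm_eff = min(arm, arm_max)
            if arm_eff < arm_min:
                continue
            left0 = p_inner - arm_eff + 1
            right_end0 = (S - p_inner) + arm_eff - 1
            out.append((left0, right_end0, arm_eff, gap))
    return out


def find_inverted_repeats(
    seq: str,
    arm_min: int = 6,
    arm_max: int = 50,
    gap_max: int = 20,
    mismatches: int = 0,
) -> list[ScanHit]:
    """Short inverted repeats: arm + spacer (<= gap_max) + reverse-complement arm."""
    if mismatches:
        raise MitoprofileError("find_inverted_repeats supports mismatches=0 only")
    hits = []
    for left0, right_end0, arm, gap in _inverted_scan(seq, arm_min, arm_max, 0, gap_max):
        hits.append(
            ScanHit(
                kind="inverted",
                start=left0 + 1,
                end=right_end0 + 1,
                unit_or_motif=seq[left0 : left0 + arm],
                arm_length=arm,
                gap=gap,
                percent_matches=100.0,
            )
        )
    return sorted(hits, key=ScanHit.key)


def find_hairpins(
    seq: str,
    stem_min: int = 5,
    loop_min: int = 3,
    loop_max: int = 20,
    mismatches: int = 0,
    stem_max: int = 100,
) -> list[ScanHit]:
    """Potential hairpins: inverted repeats whose spacer is a plausible loop."""
    if mismatches:
        raise MitoprofileError("find_hairpins supports mismatches=0 only")
    hits = []
    for left0, right_end0, arm, gap in _inverted_scan(seq, stem_min, stem_max, loop_min, loop_max):
        hits.append(
            ScanHit(
                kind="hairpin",
                start=left0 + 1,
                end=right_end0 + 1,
                unit_or_motif=seq[left0 : left0 + arm],
                arm_length=arm,
                loop_length=gap,
                gap=gap,
                percent_matches=100.0,
            )
        )
    return sorted(hits, key=ScanHit.key)


def find_palindromes(
    seq: str,
    len_min: int = 6,
    len_max: int = 30,
    count_all: bool = False,
) -> list[ScanHit]:
    """Even-length windows equal to their own reverse complement.

    Default reports the maximal palindrome per center (capped at ``len_max``);
    ``count_all=True`` additionally reports every shorter even-length
    palindrome sharing a center, the convention of census web tools.
    """
    L = len(seq)
    hits = []
    for c in range(1, L):  # center between positions c-1 and c (0-based)
        t = 0
        while c - 1 - t >= 0 and c + t < L and seq[c - 1 - t] == _comp_char(seq[c + t]):
            t += 1
        max_len = min(2 * t, len_max if len_max % 2 == 0 else len_max - 1)
        if max_len < len_min:
            continue
        lengths = range(len_min + (len_min % 2), max_len + 1, 2) if count_all else [max_len]
        for length in lengths:
            half = length // 2
            hits.append(
                ScanHit(
                    kind="palindrome",
                    start=c - half + 1,
                    end=c + half,
                    unit_or_motif=seq[c - half : c + half],
                )
            )
    return sorted(hits, key=ScanHit.key)


# ---------------------------------------------------------------------------
# ambiguity-coded motif search
# ---------------------------------------------------------------------------

def _mismatch_counts(s: str, pattern: str) -> np.ndarray:
    """Per-start mismatch counts of ``pattern`` (N = wildcard) along ``s``."""
    L, P = len(s), len(pattern)
    if P > L:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    n = L - P + 1
    mm = np.zeros(n, dtype=np.int64)
    for j, ch in enumerate(pattern):
        if ch == "N":
            continue
        mm += arr[j : j + n] != ord(ch)
    return mm


def find_motif(
    seq: str,
    pattern: str,
    max_mismatch: int = 0,
    circular: bool = True,
) -> list[ScanHit]:
    """Occurrences of an {A,C,G,T,N} pattern on both strands.

    N matches any base and never counts as a mismatch. Reverse-strand hits
    are reported by their forward-strand coordinates with ``strand='-'``.
    With ``circular`` the scan wraps across the origin (hit start stays within
    the sequence; the end may exceed its length).
    """
    pattern = pattern.upper()
    if set(pattern) - set("ACGTN"):
        raise MitoprofileError("motif pattern must be over {A,C,G,T,N}")
    L, P = len(seq), len(pattern)
    if P > L:
        return []
    s = seq + (seq[: P - 1] if circular and P > 1 else "")
    hits = []
    for pat, strand in ((pattern, "+"), (revcomp(pattern), "-")):
        if strand == "-" and pat == pattern:
            continue  # palindromic pattern: avoid duplicate reverse hits
        mm = _mismatch_counts(s, pat)
        for i in np.flatnonzero(mm <= max_mismatch):
            if i >= L:
                continue
            hits.append(
                ScanHit(
                    kind="motif",
                    start=int(i) + 1,
                    end=int(i) + P,
                    unit_or_motif=pattern,
                    strand=strand,
                    score=float(-mm[i]),
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------------------
# approximate tandem repeats (simplified TRF)
# ---------------------------------------------------------------------------

@dataclass
class _Alignment:
    score: float
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    seg_start: int = 0  # 0-based aligned span within the segment
    seg_end: int = 0  # exclusive

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def pattern_cols(self) -> int:
        return self.matches + self.mismatches + self.deletions


def wraparound_align(
    segment: str,
    pattern: str,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
) -> _Alignment:
    """Locally align ``segment`` against cyclic repetitions of ``pattern``.

    Wraparound dynamic programming: the alignment may start at any pattern
    column and at any segment position, the pattern wraps from its last
    column back to its first, and the alignment ends wherever the score
    peaks (so non-repetitive flanks are excluded rather than forced in).
    Returns the score, the aligned segment span and the alignment-column
    tallies used for copy-number and percent-matches reporting.
    """
    R, p = len(segment), len(pattern)
    # D[i][j]: best score of an alignment ending at segment position i (1-based)
    # with pattern column j just consumed; 0 = fresh start (local alignment)
    prev = np.zeros(p)
    rows = [prev.copy()]
    back: list[np.ndarray] = []  # 0=diag, 1=ins (gap in pattern), 2=del, 3=start
    for i in range(1, R + 1):
        cur = np.zeros(p)
        bk = np.full(p, 3, dtype=np.int8)
        ch = segment[i - 1]
        for j in range(p):
            jp = (j - 1) % p
            diag = prev[jp] + (match if pattern[j] == ch else -mismatch)
            ins = prev[j] - indel
            if diag >= ins and diag > 0:
                cur[j], bk[j] = diag, 0
            elif ins > 0:
                cur[j], bk[j] = ins, 1
        # deletions within the row (skip pattern columns); two sweeps cover wrap
        for _ in range(2):
            for j in range(p):
                jp = (j - 1) % p
                if cur[jp] - indel > cur[j]:
                    cur[j] = cur[jp] - indel
                    bk[j] = 2
        prev = cur
        rows.append(cur.copy())
        back.append(bk)
    mat = np.vstack(rows)
    i, j = np.unravel_index(int(np.argmax(mat)), mat.shape)
    i, j = int(i), int(j)
    tallies = _Alignment(
        score=float(mat[i, j]), matches=0, mismatches=0, insertions=0, deletions=0,
        seg_end=i,
    )
    while i > 0 and mat[i, j] > 0:
        move = back[i - 1][j]
        if move == 3:
            break
        if move == 0:
            if pattern[j] == segment[i - 1]:
                tallies.matches += 1
            else:
                tallies.mismatches += 1
            i -= 1
            j = (j - 1) % p
        elif move == 1:
            tallies.insertions += 1
            i -= 1
        else:
            tallies.deletions += 1
            j = (j - 1) % p
    tallies.seg_start = i
    return tallies


def _consensus(segment: str, period: int) -> str:
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i, ch in enumerate(segment):
        d = cols[i % period]
        d[ch] = d.get(ch, 0) + 1
    return "".join(max(sorted(d), key=d.get) if d else "A" for d in cols)


def find_tandem_repeats(
    seq: str,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
    min_score: int = 50,
    max_period: int = 500,
    seed_density: float = 0.7,
) -> list[ScanHit]:
    """Approximate tandem repeats by seed-and-extend plus wraparound DP.

    Candidate periods are seeded wherever ``seq[i] == seq[i+p]`` matches are
    dense over a window of one period; each merged candidate region is aligned
    to its majority consensus by wraparound dynamic programming under the
    stated weights. Hits below ``min_score`` are suppressed; overlapping hits
    are resolved by score (ties prefer the smaller period).
    """
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[tuple[int, int, int]] = []  # (start0, end0, period)
    for p in range(1, min(max_period, L // 2) + 1):
        m = (arr[p:] == arr[:-p]).astype(np.int32)
        if m.size < p:
            continue
        # fraction of matches in each window of one period
        csum = np.concatenate(([0], np.cumsum(m)))
        frac = (csum[p:] - csum[:-p]) / p
        seeds = np.flatnonzero(frac >= seed_density)
        if seeds.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(seeds) > p)
        for grp in np.split(seeds, breaks + 1):
            a, b = int(grp[0]), int(grp[-1])
            candidates.append((a, min(b + 2 * p - 1, L - 1), p))
    raw: list[ScanHit] = []
    for a, b, p in candidates:
        # trim edges that break the periodicity (chance matches at the seed
        # boundary otherwise inflate the copy number)
        while a < b and seq[a] != seq[a + p]:
            a += 1
        while b > a and seq[b] != seq[b - p]:
            b -= 1
        segment = seq[a : b + 1]
        if len(segment) < 2 * p:
            continue
        pattern = _consensus(segment, p)
        if not _is_primitive(pattern):
            continue
        aln = wraparound_align(segment, pattern, match=match, mismatch=mismatch, indel=indel)
        if aln.score < min_score or aln.columns == 0:
            continue
        raw.append(
            ScanHit(
                kind="tandem",
                start=a + aln.seg_start + 1,
                end=a + aln.seg_end,
                unit_or_motif=pattern,
                period=p,
                copy_number=round(aln.pattern_cols / p, 1),
                percent_matches=100.0 * aln.matches / aln.columns,
                score=aln.score,
            )
        )
    # resolve overlaps by score; ties prefer smaller period then leftmost
    raw.sort(key=lambda h: (-(h.score or 0), h.period or 0, h.start))
    kept: list[ScanHit] = []
    for h in raw:
        clash = False
        for g in kept:
            ov = min(h.end, g.end) - max(h.start, g.start) + 1
            if ov > 0.5 * min(h.span, g.span):
                clash = True
                break
        if not clash:
            kept.append(h)
    return sorted(kept, key=ScanHit.key)
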