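"""Seeded local alignment for junction realignment.

The aligner is a Gotoh-style affine-gap Smith-Waterman (match +1, mismatch -1,
gap open -2, gap extend -0.5; a gap of length k costs open + k*extend) run
inside narrow target windows located by exact k-mer seeding, the same
seed-and-extend shape practitioners expect from read aligners. Seeding is a
heuristic: a hit whose every seed k-mer is mutated can be missed, which is
acceptable for junction consensus sequences that are near-exact copies of
their source.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class LocalAlignment:
    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    n_matches: int
    n_columns: int
    strand: str = "+"

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def smith_waterman(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> LocalAlignment:
    """Best local alignment of query against target (affine gaps, traceback)."""
    m, n = len(query), len(target)
    NEG = float("-inf")
    # H: best score ending at (i, j); E: ending with a gap in target (consumes
    # query); F: ending with a gap in query (consumes target).
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    # pointers: H 0=stop 1=diag 2=E 3=F; E/F: 1=open(from H) 0=extend
    PH = [[0] * (n + 1) for _ in range(m + 1)]
    PE = [[0] * (n + 1) for _ in range(m + 1)]
    PF = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        qc = query[i - 1]
        Hi, Hu = H[i], H[i - 1]
        Ei, Eu = E[i], E[i - 1]
        Fi = F[i]
        PHi, PEi, PFi = PH[i], PE[i], PF[i]
        for j in range(1, n + 1):
            e_open = Hu[j] + gap_open + gap_extend
            e_ext = Eu[j] + gap_extend
            if e_open >= e_ext:
                Ei[j] = e_open
                PEi[j] = 1
            else:
                Ei[j] = e_ext
                PEi[j] = 0
            f_open = Hi[j - 1] + gap_open + gap_extend
            f_ext = Fi[j - 1] + gap_extend
            if f_open >= f_ext:
                Fi[j] = f_open
                PFi[j] = 1
            else:
                Fi[j] = f_ext
                PFi[j] = 0
            diag = Hu[j - 1] + (match if qc == target[j - 1] else mismatch)
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if Ei[j] > h:
                h, p = Ei[j], 2
            if Fi[j] > h:
                h, p = Fi[j], 3
            Hi[j] = h
            PHi[j] = p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    # traceback
    i, j, state = bi, bj, "H"
    n_match = n_cols = 0
    while True:
        if state == "H":
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if query[i - 1] == target[j - 1]:
                    n_match += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            opened = PE[i][j] == 1
            n_cols += 1
            i -= 1
            state = "H" if opened else "E"
        else:
            opened = PF[i][j] == 1
            n_cols += 1
            j -= 1
            state = "H" if opened else "F"
    return LocalAlignment(best, i, bi, j, bj, n_match, n_cols)


def _seed_windows(query: str, target: str, k: int, pad: int, max_candidates: int = 20):
    """Candidate target windows from exact k-mer seed diagonals."""
    qlen = len(query)
    if qlen < k:
        return []
    n_seeds = min(7, qlen - k + 1)
    if n_seeds == 1:
        offsets = [0]
    else:
        step = (qlen - k) / (n_seeds - 1)
        offsets = sorted({int(round(i * step)) for i in range(n_seeds)})
    votes: dict = {}
    for off in offsets:
        sub = query[off : off + k]
        start = 0
        hits = 0
        while hits < 200:
            idx = target.find(sub, start)
            if idx < 0:
                break
            d = idx - off
            votes[d] = votes.get(d, 0) + 1
            start = idx + 1
            hits += 1
    if not votes:
        return []
    # merge nearby diagonals into bands
    diags = sorted(votes)
    bands = []
    cur = [diags[0]]
    for d in diags[1:]:
        if d - cur[-1] <= 12:
            cur.append(d)
        else:
            bands.append(cur)
            cur = [d]
    bands.append(cur)
    scored = sorted(bands, key=lambda b: -sum(votes[d] for d in b))[:max_candidates]
    windows = []
    for band in scored:
        lo = max(0, min(band) - pad)
        hi = min(len(target), max(band) + qlen + pad)
        windows.append((lo, hi))
    # merge overlapping windows
    windows.sort()
    merged = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def find_alignments(
    query: str,
    target: str,
    min_identity: float = 0.9,
    min_hit_len: int = 20,
    k: int = 14,
    pad: int = 25,
    both_strands: bool = True,
) -> list:
    """All seeded local hits of query (and its reverse complement) in target.

    Returns LocalAlignment records with query coordinates on the original
    (forward) query, best-first by identity * aligned columns. Small targets
    (< 400 bp) are aligned directly without seeding.
    """
    results = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        if len(target) < 400:
            windows = [(0, len(target))]
        else:
            windows = _seed_windows(q, target, k, pad)
        for lo, hi in windows:
            aln = smith_waterman(q, target[lo:hi])
            if aln.score <= 0 or aln.n_columns < min_hit_len or aln.identity < min_identity:
                continue
            qs, qe = aln.query_start, aln.query_end
            if strand == "-":
                qs, qe = len(q) - aln.query_end, len(q) - aln.query_start
            results.append(
                LocalAlignment(
                    score=aln.score,
                    query_start=qs,
                    query_end=qe,
                    target_start=lo + aln.target_start,
                    target_end=lo + aln.target_end,
                    n_matches=aln.n_matches,
                    n_columns=aln.n_columns,
                    strand=strand,
                )
            )
    results.sort(key=lambda a: (-(a.identity * a.n_columns), -a.score, a.strand != "+", a.target_start))
    deduped = []
    for a in results:
        if any(
            b.strand == a.strand and abs(b.target_start - a.target_start) <= 5
            for b in deduped
        ):
            continue
        deduped.append(a)
    return deduped
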