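"""Pairwise and progressive multiple alignment helpers.

All alignment in the package runs through Biopython's ``PairwiseAligner``
with one scoring scheme: match 2, mismatch -3, gap open 10, gap extend 0.5
(affine). ``compare`` reduces an optimal pairwise alignment to the two
quantities the decoders care about -- substitution mismatches and a list of
indel events on reference coordinates -- and ``multi_align_window`` builds a
center-star progressive multiple alignment for amplicon-scale windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=4)
def _aligner(end_free: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if end_free:
        # free end gaps on the reference: the query may be an internal
        # fragment of the reference (e.g. a Sanger read inside a gene)
        try:
            aligner.end_insertion_score = 0.0
        except AttributeError:  # Biopython < 1.86 name
            aligner.target_end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class Indel:
    """A single insertion (size > 0) or deletion (size < 0) event.

    ``ref_pos`` is the reference coordinate of the event: the first deleted
    base for deletions, the base immediately left of the insertion point for
    insertions. ``seq`` holds the inserted or deleted bases.
    """

    size: int
    ref_pos: int
    seq: str

    def interval(self) -> tuple[int, int]:
        """Reference interval touched by the event (point for insertions)."""
        if self.size < 0:
            return (self.ref_pos, self.ref_pos - self.size)
        return (self.ref_pos, self.ref_pos)

    def overlaps(self, start: int, end: int) -> bool:
        a, b = self.interval()
        if a == b:  # insertion: point event
            return start <= a <= end
        return a <= end and b >= start


@dataclass(frozen=True)
class CompareResult:
    mismatches: int
    indels: tuple[Indel, ...]
    score: float
    mismatch_positions: tuple[int, ...] = ()  # reference coordinates
    ref_span: tuple[int, int] = (0, 0)        # aligned reference interval

    @property
    def indel_bp(self) -> int:
        return sum(abs(i.size) for i in self.indels)

    @property
    def distance(self) -> int:
        """Unit edit distance: substitutions plus indel base pairs."""
        return self.mismatches + self.indel_bp


def compare(query: str, ref: str, end_free: bool = False) -> CompareResult:
    """Optimally align ``query`` to ``ref`` and summarize the differences.

    With ``end_free=True`` reference overhangs beyond the aligned query are
    not counted as deletions (the query is treated as a fragment).
    """
    if query == ref:
        return CompareResult(0, (), MATCH * len(ref), (), (0, len(ref)))
    aln = _aligner(end_free).align(ref, query)[0]
    tblocks, qblocks = aln.aligned
    tblocks = [(int(a), int(b)) for a, b in tblocks]
    qblocks = [(int(a), int(b)) for a, b in qblocks]
    mism_pos: list[int] = []
    indels: list[Indel] = []
    for (ts, te), (qs, _qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            if ref[ts + k] != query[qs + k]:
                mism_pos.append(ts + k)
    # gaps between consecutive aligned blocks
    for i in range(len(tblocks) - 1):
        t_gap = tblocks[i + 1][0] - tblocks[i][1]
        q_gap = qblocks[i + 1][0] - qblocks[i][1]
        pos = tblocks[i][1]
        if t_gap > 0:
            indels.append(Indel(-t_gap, pos, ref[pos:pos + t_gap]))
        if q_gap > 0:
            qpos = qblocks[i][1]
            indels.append(Indel(q_gap, pos, query[qpos:qpos + q_gap]))
    if not end_free and len(tblocks):
        # terminal gaps count as indels when the query is a full-length product
        lead_t, lead_q = tblocks[0][0], qblocks[0][0]
        if lead_t > 0:
            indels.insert(0, Indel(-lead_t, 0, ref[:lead_t]))
        if lead_q > 0:
            indels.insert(0, Indel(lead_q, 0, query[:lead_q]))
        tail_t = len(ref) - tblocks[-1][1]
        tail_q = len(query) - qblocks[-1][1]
        if tail_t > 0:
            indels.append(Indel(-tail_t, tblocks[-1][1], ref[tblocks[-1][1]:]))
        if tail_q > 0:
            indels.append(Indel(tail_q, tblocks[-1][1], query[qblocks[-1][1]:]))
    span = (tblocks[0][0], tblocks[-1][1]) if len(tblocks) else (0, 0)
    return CompareResult(len(mism_pos), tuple(indels), aln.score,
                         tuple(mism_pos), span)


def _pair_rows(ref: str, seq: str) -> tuple[str, str]:
    """Gapped rows (ref_row, seq_row) of the optimal pairwise alignment."""
    if ref == seq:
        return ref, seq
    aln = _aligner(False).align(ref, seq)[0]
    return str(aln[0]), str(aln[1])


def multi_align_window(seqs: list[str]) -> list[str]:
    """Center-star progressive multiple alignment of short DNA windows.

    The center sequence is the one with minimal summed pairwise distance to
    the others; every sequence is aligned to the center and the pairwise gap
    structures are merged. Ungapping any returned row reproduces its input.
    """
    if not seqs:
        raise ValueError("multi_align_window requires at least one sequence")
    if any(len(s) > 2000 for s in seqs):
        raise ValueError("sequences longer than 2 kb are not supported")
    if len(seqs) == 1:
        return [seqs[0]]
    uniq = sorted(set(seqs))
    dist: dict[tuple[str, str], int] = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            d = compare(b, a).distance
            dist[(a, b)] = dist[(b, a)] = d
    totals = [sum(dist.get((s, o), 0) for o in uniq if o != s) for s in seqs]
    center = seqs[min(range(len(seqs)), key=lambda i: (totals[i], -len(seqs[i])))]

    # per-sequence gap runs, expressed as insert lengths between center bases
    n = len(center)
    max_ins = [0] * (n + 1)  # insertions after center position i (0 = before)
    parsed: list[tuple[str, str]] = []
    for s in seqs:
        c_row, s_row = _pair_rows(center, s)
        ins = [0] * (n + 1)
        ci = 0
        for cch in c_row:
            if cch == "-":
                ins[ci] += 1
            else:
                ci += 1
        parsed.append((c_row, s_row))
        for i, v in enumerate(ins):
            max_ins[i] = max(max_ins[i], v)

    rows: list[str] = []
    for c_row, s_row in parsed:
        out: list[str] = []
        ci = 0
        # walk the pairwise alignment, padding each insert run to max_ins
        buf_ins: list[str] = []
        for cch, sch in zip(c_row, s_row):
            if cch == "-":
                buf_ins.append(sch)
            else:
                out.append("".join(buf_ins) + "-" * (max_ins[ci] - len(buf_ins)))
                buf_ins = []
                ci += 1
                out.append(sch)
        out.append("".join(buf_ins) + "-" * (max_ins[ci] - len(buf_ins)))
        rows.append("".join(out))
    width = {len(r) for r in rows}
    assert len(width) == 1, "center-star merge produced ragged rows"
    return rows


def substitution_columns(rows: list[str]) -> list[int]:
    """Columns of a gapped matrix where >=2 rows carry differing bases."""
    cols = []
    for j in range(len(rows[0]) if rows else 0):
        bases = {r[j] for r in rows if r[j] != "-"}
        if len(bases) > 1:
            cols.append(j)
    return cols
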