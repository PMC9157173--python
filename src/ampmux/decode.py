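"""Paralog-aware decoding of amplicon reads into per-allele genotypes.

Reads from a consensus primer pair are assigned to near-identical candidate
alleles by minimizing the NON-indel mismatch count of an optimal alignment:
indels are the expected editing signal, so they never count against an
allele during assignment (only substitutions at discriminating SNP columns
do). Two assignment modes exist:

``repeat_normalized`` (default)
    Declared/detected tandem-repeat tracts are collapsed in both read and
    reference before alignment, and mismatch ties go to ``ambiguous``.
    Alleles differing only in repeat-tract length can then never steal each
    other's reads.

``naive``
    No repeat collapsing; mismatch ties are broken by model order, the
    behavior of reference-assignment tools that treat indels as free. On
    repeat-length-only allele pairs this reproduces the classic artifact:
    reads of the later allele are absorbed by the earlier one and surface
    as spurious +/-2-type indel calls at the repeat tract, far from the cut
    site.

No-amplification (NA) alleles are called fractionally against an unedited
control decoded with the same pipeline: consensus primers co-amplify every
allele, so each allele's control share is a built-in expectation for its
sample share.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .align import CompareResult, compare, revcomp
from .guides import GuideSite
from .locus import (DiscriminatingSnpTable, LocusModel, PrimerPair,
                    collapse_repeats)

AMBIGUOUS = "ambiguous"


class InsufficientDepthError(RuntimeError):
    """Total sample depth too low for any confident call (explicit no-call)."""


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    seq: str                       # oriented to the forward amplicon strand
    allele: str                    # best allele id or "ambiguous"
    distances: dict[str, int]      # per-allele mismatches + indel bp
    mismatches: dict[str, int]     # per-allele substitution-only counts
    evidence: tuple[tuple[int, str, frozenset], ...] = ()


@dataclass
class AssignmentResult:
    assignments: list[ReadAssignment]
    unmatched: int                 # reads dropped for missing primer match
    mode: str

    @property
    def total(self) -> int:
        return len(self.assignments) + self.unmatched

    def counts(self) -> dict[str, int]:
        c: Counter = Counter(a.allele for a in self.assignments)
        c.pop(AMBIGUOUS, None)
        return dict(c)


@dataclass(frozen=True)
class IndelPattern:
    size: int
    position: int                  # amplicon-relative (reference) coordinate
    seq: str
    count: int
    frequency: float


@dataclass
class AlleleCall:
    allele_id: str
    call: str                      # WT | indel | NA | chimeric
    patterns: list[IndelPattern] = field(default_factory=list)
    reads: int = 0
    rel_abundance: float = float("nan")

    @property
    def dominant(self) -> IndelPattern | None:
        return self.patterns[0] if self.patterns else None


# -- read ingestion --------------------------------------------------------

def iter_reads(source) -> Iterator[tuple[str, str]]:
    """Normalize FASTQ paths, SeqRecords or (id, seq) pairs to (id, seq)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()
        return
    for item in source:
        if hasattr(item, "seq"):
            yield item.id, str(item.seq).upper()
        else:
            rid, seq = item
            yield rid, seq.upper()


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def orient_read(seq: str, pair: PrimerPair, max_mm: int = 2) -> str | None:
    """Orient a merged read to the forward amplicon strand, or None."""
    k = len(pair.forward)
    if len(seq) >= k and _hamming_leq(seq[:k], pair.forward, max_mm):
        return seq
    rc = revcomp(seq)
    if len(rc) >= k and _hamming_leq(rc[:k], pair.forward, max_mm):
        return rc
    return None


# -- assignment ------------------------------------------------------------

class _RefSet:
    """Per-mode candidate amplicon references with cached comparisons."""

    def __init__(self, model: LocusModel, pair: PrimerPair, mode: str):
        self.ids = [aid for aid in model.allele_ids if aid in pair.targets]
        raw = {aid: model.amplicon(aid, pair) for aid in self.ids}
        if mode == "repeat_normalized":
            self.refs = {aid: collapse_repeats(s) for aid, s in raw.items()}
            self.transform = collapse_repeats
        else:
            self.refs = raw
            self.transform = lambda s: s
        self.raw = raw
        self._cache: dict[str, dict[str, CompareResult]] = {}
        self._exact = {seq: aid for aid, seq in self.refs.items()}
        # ref-vs-ref comparisons let exact-match reads skip alignment
        self._ref_vs_ref = {
            a: {b: compare(self.refs[a], self.refs[b]) for b in self.ids}
            for a in self.ids}

    def results(self, seq: str) -> dict[str, CompareResult]:
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        exact = self._exact.get(seq)
        if exact is not None:
            res = self._ref_vs_ref[exact]
        else:
            res = {aid: compare(seq, ref) for aid, ref in self.refs.items()}
        self._cache[seq] = res
        return res


def _snp_evidence(seq: str, allele_id: str, refset: _RefSet,
                  snps: DiscriminatingSnpTable | None):
    if snps is None or seq != refset.refs.get(allele_id):
        return ()
    row = snps.msa.get(allele_id)
    if row is None or "-" in row:
        return ()
    ev = []
    for col in snps.columns():
        base = row[col]
        support = frozenset(a for a, r in snps.msa.items()
                            if "-" not in r and r[col] == base)
        ev.append((col, base, support))
    return tuple(ev)


def assign_reads(reads, model: LocusModel,
                 snps: DiscriminatingSnpTable | None = None,
                 mode: str = "repeat_normalized",
                 pair: PrimerPair | None = None,
                 primer_max_mm: int = 2) -> AssignmentResult:
    """Assign merged amplicon reads to candidate alleles.

    Reads are oriented by forward-primer match (unmatched reads are dropped
    and counted), aligned to every candidate amplicon, and assigned to the
    allele with the fewest substitution mismatches. See the module docstring
    for the two tie-handling modes.
    """
    if mode not in ("naive", "repeat_normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    if pair is None:
        pair = model.primer_pairs[0]
    refset = _RefSet(model, pair, mode)
    assignments: list[ReadAssignment] = []
    unmatched = 0
    seen_any = False
    transform_cache: dict[str, str] = {}
    for rid, raw_seq in iter_reads(reads):
        seen_any = True
        oriented = orient_read(raw_seq, pair, primer_max_mm)
        if oriented is None:
            unmatched += 1
            continue
        key = transform_cache.get(oriented)
        if key is None:
            key = refset.transform(oriented)
            transform_cache[oriented] = key
        res = refset.results(key)
        mism = {aid: r.mismatches for aid, r in res.items()}
        dist = {aid: r.distance for aid, r in res.items()}
        best_mm = min(mism.values())
        tied = [aid for aid in refset.ids if mism[aid] == best_mm]
        if mode == "naive":
            winner = tied[0]
        else:
            if len(tied) > 1:
                best_d = min(dist[aid] for aid in tied)
                tied = [aid for aid in tied if dist[aid] == best_d]
            winner = tied[0] if len(tied) == 1 else AMBIGUOUS
        ev = (_snp_evidence(key, winner, refset, snps)
              if winner != AMBIGUOUS else ())
        assignments.append(ReadAssignment(
            read_id=rid, seq=oriented, allele=winner, distances=dist,
            mismatches=mism, evidence=ev))
    if not seen_any:
        raise ValueError("empty read stream")
    if not assignments:
        raise ValueError("no reads matched the primer pair")
    return AssignmentResult(assignments=assignments, unmatched=unmatched,
                            mode=mode)


# -- indel pattern calling -------------------------------------------------

def amplicon_cut(model: LocusModel, allele_id: str, guide: GuideSite,
                 pair: PrimerPair | None = None) -> int:
    """Amplicon-relative cut coordinate for one allele."""
    if pair is None:
        pair = model.primer_pairs[0]
    start, _ = model.primer_sites(allele_id, pair)
    return guide.cut_site(allele_id) - start


def call_indel_patterns(assignments: Sequence[ReadAssignment] |
                        AssignmentResult,
                        allele_id: str, model: LocusModel, guide: GuideSite,
                        mismatch_allowance: float = 0.01,
                        min_pattern_frac: float = 0.01,
                        window: int = 10,
                        pair: PrimerPair | None = None) -> list[IndelPattern]:
    """Aggregate per-read indel patterns for one allele.

    Each assigned read is aligned to the allele's (uncollapsed) amplicon;
    indels overlapping cut +/- ``window`` bp form the read's pattern.
    Reads whose substitution fraction exceeds ``mismatch_allowance`` are
    discarded as noise, and patterns supported by less than
    ``min_pattern_frac`` of the allele's reads are suppressed. A read with
    indels only outside the window reports its largest such indel -- this
    is how repeat misassignment artifacts become visible.
    """
    if isinstance(assignments, AssignmentResult):
        assignments = assignments.assignments
    if pair is None:
        pair = model.primer_pairs[0]
    reads = [a.seq for a in assignments if a.allele == allele_id]
    if not reads:
        raise ValueError(f"no reads assigned to {allele_id}; "
                         "route zero-coverage alleles to NA calling")
    ref = model.amplicon(allele_id, pair)
    cut = amplicon_cut(model, allele_id, guide, pair)
    max_mm = mismatch_allowance * len(ref)
    per_seq: dict[str, tuple[int, int, str] | None] = {}
    counts: Counter = Counter()
    kept = 0
    for seq, n in Counter(reads).items():
        if seq not in per_seq:
            res = compare(seq, ref)
            if res.mismatches > max_mm:
                per_seq[seq] = None
            else:
                hits = [i for i in res.indels
                        if i.overlaps(cut - window, cut + window)]
                if hits:
                    size = sum(i.size for i in hits)
                    per_seq[seq] = (size, hits[0].ref_pos,
                                    "".join(i.seq for i in hits))
                elif res.indels:
                    top = max(res.indels, key=lambda i: abs(i.size))
                    per_seq[seq] = (top.size, top.ref_pos, top.seq)
                else:
                    per_seq[seq] = (0, cut, "")
        pat = per_seq[seq]
        if pat is not None:
            counts[pat] += n
            kept += n
    patterns = [IndelPattern(size=s, position=p, seq=q, count=c,
                             frequency=c / kept)
                for (s, p, q), c in counts.items()
                if c / kept >= min_pattern_frac]
    patterns.sort(key=lambda p: (-p.count, p.position))
    return patterns


# -- NA calling ------------------------------------------------------------

def call_na(per_allele_counts: dict[str, int],
            control_profile: dict[str, float],
            min_total_depth: int = 100,
            na_frac: float = 0.05) -> set[str]:
    """Flag no-amplification alleles against the built-in control profile.

    An allele is NA when its share of the sample's assigned reads falls
    below ``na_frac`` times its share in the unedited control decoded with
    the same pipeline. Raises :class:`InsufficientDepthError` below
    ``min_total_depth`` -- low depth is a no-call, never an NA call.
    """
    total = sum(per_allele_counts.values())
    if total < min_total_depth:
        raise InsufficientDepthError(
            f"total assigned depth {total} < {min_total_depth}")
    ctl_total = sum(control_profile.values())
    if ctl_total <= 0:
        raise ValueError("control profile is empty")
    flagged = set()
    for aid, ctl in control_profile.items():
        ctl_frac = ctl / ctl_total
        frac = per_allele_counts.get(aid, 0) / total
        if ctl_frac > 0 and frac < na_frac * ctl_frac:
            flagged.add(aid)
    return flagged


def control_profile_from_reads(reads, model: LocusModel,
                               snps: DiscriminatingSnpTable | None = None,
                               mode: str = "repeat_normalized",
                               ) -> dict[str, int]:
    """Decode an unedited control sample into a per-allele depth profile."""
    return assign_reads(reads, model, snps=snps, mode=mode).counts()


# -- per-line genotyping ---------------------------------------------------

def genotype_line(reads, model: LocusModel, guide: GuideSite,
                  control_profile: dict[str, float],
                  snps: DiscriminatingSnpTable | None = None,
                  mode: str = "repeat_normalized",
                  chimera_floor: float = 0.10,
                  min_total_depth: int = 100,
                  na_frac: float = 0.05,
                  mismatch_allowance: float = 0.01,
                  min_pattern_frac: float = 0.01) -> list[AlleleCall]:
    """Decode one line into per-allele calls (WT / indel / NA / chimeric).

    Composes read assignment, fractional NA calling and indel pattern
    calling. An allele is chimeric when both the WT pattern and an edited
    pattern each reach ``chimera_floor``; otherwise the dominant pattern
    decides WT vs indel. Alleles with no uniquely assigned reads that do
    not meet the NA contract (e.g. members of an amplicon-identical pair,
    whose reads are ambiguous in the control too) default to WT with NaN
    relative abundance.
    """
    result = assign_reads(reads, model, snps=snps, mode=mode)
    counts = result.counts()
    na = call_na(counts, control_profile, min_total_depth=min_total_depth,
                 na_frac=na_frac)
    total = sum(counts.values())
    ctl_total = sum(control_profile.values())
    calls: list[AlleleCall] = []
    for aid in model.allele_ids:
        n = counts.get(aid, 0)
        ctl_frac = control_profile.get(aid, 0) / ctl_total
        rel = ((n / total) / ctl_frac) if ctl_frac > 0 and total else \
            float("nan")
        if aid in na:
            calls.append(AlleleCall(aid, "NA", reads=n, rel_abundance=rel))
            continue
        if n == 0:
            calls.append(AlleleCall(aid, "WT", reads=0, rel_abundance=rel))
            continue
        patterns = call_indel_patterns(
            result, aid, model, guide,
            mismatch_allowance=mismatch_allowance,
            min_pattern_frac=min_pattern_frac)
        wt_freq = sum(p.frequency for p in patterns if p.size == 0)
        edited = [p for p in patterns if p.size != 0]
        top_edit = max(edited, key=lambda p: p.frequency, default=None)
        if top_edit is not None and wt_freq >= chimera_floor and \
                top_edit.frequency >= chimera_floor:
            call = "chimeric"
        elif top_edit is not None and top_edit.frequency > wt_freq:
            call = "indel"
        else:
            call = "WT"
        calls.append(AlleleCall(aid, call, patterns=patterns, reads=n,
                                rel_abundance=rel))
    return calls


# -- dereplication ---------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def dereplicate(reads, max_mm: int = 2, allow_gaps: bool = False,
                min_group_size: int = 5,
                min_unique_depth: int = 2) -> list[tuple[str, int]]:
    """Collapse oriented same-primer reads into distinct tag sequences.

    Single-linkage grouping of reads within ``max_mm`` mismatches (Hamming;
    reads of different length never group unless ``allow_gaps``); each
    group's column-majority consensus is emitted with its size, largest
    group first. Groups below ``min_group_size`` reads are dropped.

    Unique sequences seen fewer than ``min_unique_depth`` times are
    excluded before clustering: a singleton error read lying between two
    true tags would otherwise chain them into one group -- the collapse
    that tag-assembly parameters must be tuned to avoid when paralogous
    alleles differ by few substitutions.
    """
    seq_counts = Counter(seq for _, seq in iter_reads(reads))
    seq_counts = Counter({s: c for s, c in seq_counts.items()
                          if c >= min_unique_depth})
    uniq = list(seq_counts)
    uf = _UnionFind(len(uniq))
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(uniq):
        by_len[len(s)].append(i)
    if allow_gaps:
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                if abs(len(uniq[i]) - len(uniq[j])) <= max_mm and \
                        compare(uniq[i], uniq[j]).distance <= max_mm:
                    uf.union(i, j)
    else:
        for idxs in by_len.values():
            if len(idxs) == 1:
                continue
            mat = np.frombuffer("".join(uniq[i] for i in idxs).encode(),
                                dtype=np.uint8).reshape(len(idxs), -1)
            for a in range(len(idxs)):
                mm = (mat[a] != mat[a + 1:]).sum(axis=1)
                for off in np.nonzero(mm <= max_mm)[0]:
                    uf.union(idxs[a], idxs[a + 1 + off])
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(uniq)):
        groups[uf.find(i)].append(i)
    tags: list[tuple[str, int]] = []
    for members in groups.values():
        count = sum(seq_counts[uniq[i]] for i in members)
        if count < min_group_size:
            continue
        # column-majority consensus over the (equal-length) bulk of the group
        lengths = Counter(len(uniq[i]) for i in members)
        L = max(lengths, key=lambda l: sum(
            seq_counts[uniq[i]] for i in members if len(uniq[i]) == l))
        cols = [Counter() for _ in range(L)]
        for i in members:
            s = uniq[i]
            if len(s) != L:
                continue
            w = seq_counts[s]
            for j, ch in enumerate(s):
                cols[j][ch] += w
        consensus = "".join(c.most_common(1)[0][0] for c in cols)
        tags.append((consensus, count))
    tags.sort(key=lambda t: (-t[1], t[0]))
    return tags
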