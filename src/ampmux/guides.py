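"""Consensus gRNA enumeration and mismatch-limited off-target scanning.

A consensus guide is a 20-nt spacer whose spacer+PAM 23-mer occurs
byte-identically, exactly once, in every allele of every target gene and
overlaps no known genotype SNP -- the design constraint that lets a single
gRNA cut a whole duplicated gene family without allele dropout from
mispairing. The cut site follows the SpCas9 blunt-cut convention, 3 bp 5'
of the NGG PAM on the protospacer strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .align import revcomp
from .locus import LocusModel

SPACER_LEN = 20
_WINDOW = SPACER_LEN + 3


@dataclass(frozen=True)
class GuideHit:
    allele_id: str
    strand: str          # "+" | "-"
    start: int           # leftmost allele coordinate of the 20-nt spacer
    cut: int             # blunt cut coordinate (between cut-1 and cut)
    exonic: bool


@dataclass(frozen=True)
class GuideSite:
    spacer: str
    pam: str
    hits: dict[str, GuideHit]
    duplicates: int = 0  # extra occurrences elsewhere in the modeled locus

    def cut_site(self, allele_id: str) -> int:
        if allele_id not in self.hits:
            raise KeyError(f"guide has no hit in allele {allele_id!r}")
        return self.hits[allele_id].cut


def cut_site(site: GuideSite, allele_id: str) -> int:
    """Allele-local blunt-cut coordinate of a guide hit."""
    return site.cut_site(allele_id)


def _plus_hits(seq: str, word: str) -> list[int]:
    hits, i = [], seq.find(word)
    while i != -1:
        hits.append(i)
        i = seq.find(word, i + 1)
    return hits


def _site_occurrences(seq: str, word: str) -> list[tuple[str, int]]:
    """All (strand, spacer_start) occurrences of a spacer+PAM word."""
    out = [("+", p) for p in _plus_hits(seq, word)]
    rc = revcomp(word)
    # on the minus strand the 23-mer window reads PAM-complement first;
    # spacer_start is the leftmost forward coordinate of the 20-mer
    out += [("-", p + 3) for p in _plus_hits(seq, rc)]
    return out


def _hit_from_occurrence(allele_seq_len: int, strand: str, spacer_start: int,
                         allele_id: str, exons: list[tuple[int, int]],
                         spacer_len: int = SPACER_LEN) -> GuideHit:
    if strand == "+":
        cut = spacer_start + spacer_len - 3
    else:
        cut = spacer_start + 3
    exonic = any(spacer_start < e and spacer_start + spacer_len > s
                 for s, e in exons)
    return GuideHit(allele_id=allele_id, strand=strand, start=spacer_start,
                    cut=cut, exonic=exonic)


def locate_site(model: LocusModel, spacer: str, pam: str,
                targets: list[str]) -> GuideSite:
    """Build a GuideSite for a known spacer+PAM over the given alleles."""
    word = spacer + pam
    hits: dict[str, GuideHit] = {}
    extra = 0
    for a in model.alleles:
        occ = _site_occurrences(a.seq, word)
        if a.id in targets:
            if len(occ) != 1:
                raise ValueError(
                    f"spacer+PAM occurs {len(occ)} times in {a.id}")
            strand, start = occ[0]
            hits[a.id] = _hit_from_occurrence(len(a.seq), strand, start,
                                              a.id, a.exons, len(spacer))
        else:
            extra += len(occ)
    return GuideSite(spacer=spacer, pam=pam, hits=hits, duplicates=extra)


def _overlaps_variant(model: LocusModel, allele_id: str, start: int,
                      end: int) -> bool:
    return any(v.allele_id == allele_id and start <= v.pos < end
               for v in model.variants)


def enumerate_consensus_guides(model: LocusModel, target_genes: list[str],
                               require_exonic: bool = True,
                               spacer_len: int = SPACER_LEN,
                               ) -> list[GuideSite]:
    """All single-gRNA consensus sites across every allele of the targets.

    A site qualifies when its spacer+PAM word occurs identically exactly
    once (on either strand) in every allele of every target gene, overlaps
    no genotype SNP in any allele, and -- when ``require_exonic`` -- every
    hit's spacer overlaps an exon. Sites are sorted by the number of
    duplicate occurrences elsewhere in the locus, then position.
    """
    targets = [a.id for a in model.alleles if a.gene in target_genes]
    if not targets:
        return []
    window = spacer_len + 3
    first = model.allele(targets[0])
    candidates: dict[str, tuple[str, int]] = {}
    for strand in "+-":
        seq = first.seq if strand == "+" else revcomp(first.seq)
        for i in range(len(seq) - window + 1):
            if seq[i + spacer_len + 1:i + spacer_len + 3] == "GG":
                word = seq[i:i + window]
                if "N" not in word:
                    candidates.setdefault(word, (strand, i))
    sites: list[GuideSite] = []
    for word in sorted(candidates):
        ok = True
        hits: dict[str, GuideHit] = {}
        extra = 0
        for a in model.alleles:
            occ = _site_occurrences(a.seq, word)
            if a.id not in targets:
                extra += len(occ)
                continue
            if len(occ) != 1:
                ok = False
                break
            strand, start = occ[0]
            if _overlaps_variant(model, a.id, start - (3 if strand == "-"
                                                       else 0),
                                 start + spacer_len + (3 if strand == "+"
                                                      else 0)):
                ok = False
                break
            hit = _hit_from_occurrence(len(a.seq), strand, start, a.id,
                                       a.exons, spacer_len)
            if require_exonic and not hit.exonic:
                ok = False
                break
            hits[a.id] = hit
        if ok:
            sites.append(GuideSite(spacer=word[:spacer_len],
                                   pam=word[spacer_len:], hits=hits,
                                   duplicates=extra))
    sites.sort(key=lambda s: (s.duplicates,
                              min(h.start for h in s.hits.values()),
                              s.spacer))
    return sites


# -- off-target scanning ---------------------------------------------------

@dataclass(frozen=True)
class OffTargetHit:
    contig: str
    strand: str
    start: int                    # forward-strand start of the 23-mer window
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based from the PAM-distal end
    score: float

    def sort_key(self):
        return (self.mismatches, self.score, self.contig, self.start)


def _scan_strand(arr: np.ndarray, spacer: str,
                 max_mm: int) -> list[tuple[int, int]]:
    """(pos, mismatches) of NGG-adjacent windows on one strand's array."""
    n = arr.size - _WINDOW + 1
    if n <= 0:
        return []
    sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(SPACER_LEN):
        mm += arr[j:j + n] != sp[j]
    g = ord("G")
    pam_ok = (arr[SPACER_LEN + 1:SPACER_LEN + 1 + n] == g) & \
             (arr[SPACER_LEN + 2:SPACER_LEN + 2 + n] == g)
    idx = np.nonzero(pam_ok & (mm <= max_mm))[0]
    return [(int(i), int(mm[i])) for i in idx]


def _load_genome(genome) -> list[tuple[str, str]]:
    if isinstance(genome, (str, Path)):
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(genome), "fasta")]
    if isinstance(genome, dict):
        return [(k, v.upper()) for k, v in genome.items()]
    return [(name, seq.upper()) for name, seq in genome]


def scan_offtargets(genome, site: GuideSite | str, max_mm: int = 3,
                    ) -> list[OffTargetHit]:
    """Exhaustive mismatch-limited scan for NGG-adjacent near-matches.

    ``genome`` may be a FASTA path, a mapping name->sequence, or an iterable
    of (name, sequence). Every window with at most ``max_mm`` spacer
    mismatches and an NGG PAM is reported (N never matches). Hits are
    ranked by mismatch count, then by the summed PAM-proximity weight
    w(i) = i / spacer_len over mismatch positions i counted from the
    PAM-distal end -- PAM-distal mismatches perturb cleavage least, so
    windows whose mismatches sit distally rank as the most plausible
    off-targets.
    """
    spacer = site.spacer if isinstance(site, GuideSite) else site
    if len(spacer) != SPACER_LEN:
        raise ValueError("spacer must be 20 nt")
    hits: list[OffTargetHit] = []
    for contig, seq in _load_genome(genome):
        fwd = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand in "+-":
            arr = fwd if strand == "+" else np.frombuffer(
                revcomp(seq).encode(), dtype=np.uint8)
            for pos, n_mm in _scan_strand(arr, spacer, max_mm):
                window = (seq[pos:pos + _WINDOW] if strand == "+"
                          else revcomp(seq)[pos:pos + _WINDOW])
                mpos = tuple(j + 1 for j in range(SPACER_LEN)
                             if window[j] != spacer[j])
                start = pos if strand == "+" else len(seq) - pos - _WINDOW
                score = sum(i / SPACER_LEN for i in mpos)
                hits.append(OffTargetHit(contig=contig, strand=strand,
                                         start=start, mismatches=n_mm,
                                         mismatch_positions=mpos,
                                         score=score))
    hits.sort(key=OffTargetHit.sort_key)
    return hits
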