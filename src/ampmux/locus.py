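"""Multi-allele target locus model.

A locus groups near-identical alleles of a small gene family across
sub-genomes and tandem chromosome copies -- the situation created when a
hybrid genome carries both haplotypes of a tandemly duplicated gene pair.
The model tracks, per allele, the gene it belongs to, its chromosome-copy
label and ordinal position there, its sequence, exon structure and declared
tandem-repeat tracts, plus locus-wide primer pairs and known genotype SNPs.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import compare, multi_align_window, revcomp, substitution_columns

_DNA = re.compile(r"^[ACGT]+$")


class LocusError(ValueError):
    """Raised when a locus model violates its invariants."""


@dataclass(frozen=True)
class Variant:
    """A known genotype SNP: ``allele_id`` carries ``alt`` at ``pos``.

    ``ref`` is the base carried by the locus consensus at the homologous
    position; the allele's own sequence holds ``alt``.
    """

    allele_id: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    targets: tuple[str, ...]


@dataclass
class Allele:
    id: str
    gene: str
    chrom: str
    copy_index: int
    seq: str
    start: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    repeats: list[tuple[int, str, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not _DNA.match(self.seq):
            raise LocusError(f"{self.id}: sequence alphabet must be ACGT")
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.seq)):
                raise LocusError(f"{self.id}: exon ({s},{e}) outside sequence")
            if s < prev_end:
                raise LocusError(f"{self.id}: exons unsorted or overlapping")
            prev_end = e
        for pos, unit, count in self.repeats:
            expanded = unit * count
            if self.seq[pos:pos + len(expanded)] != expanded:
                raise LocusError(
                    f"{self.id}: repeat tract {unit}x{count}@{pos} does not "
                    "match the sequence")

    def cut_local(self, cut_offset: int) -> int:
        return cut_offset


@dataclass
class LocusModel:
    """The full target universe for one multiplexed editing experiment."""

    alleles: list[Allele]
    chrom_layouts: dict[str, list[str]]
    primer_pairs: list[PrimerPair]
    variants: set[Variant] = field(default_factory=set)
    amplicon_len_range: tuple[int, int] = (264, 280)

    def __post_init__(self) -> None:
        self._by_id = {a.id: a for a in self.alleles}

    def allele(self, allele_id: str) -> Allele:
        try:
            return self._by_id[allele_id]
        except KeyError:
            raise LocusError(f"unknown allele id {allele_id!r}") from None

    @property
    def allele_ids(self) -> list[str]:
        return [a.id for a in self.alleles]

    def gaps(self, chrom: str) -> list[int]:
        """Genomic gaps (bp) between consecutive alleles on one chromosome."""
        ids = self.chrom_layouts[chrom]
        out = []
        for a, b in zip(ids, ids[1:]):
            aa, bb = self.allele(a), self.allele(b)
            out.append(bb.start - (aa.start + len(aa.seq)))
        return out

    def variants_for(self, allele_id: str) -> list[Variant]:
        return sorted((v for v in self.variants if v.allele_id == allele_id),
                      key=lambda v: v.pos)

    # -- amplicons ---------------------------------------------------------
    def primer_sites(self, allele_id: str, pair: PrimerPair) -> tuple[int, int]:
        """(product_start, product_end) of ``pair`` on an allele.

        Each primer must match exactly once in its orientation.
        """
        seq = self.allele(allele_id).seq
        f_hits = _find_all(seq, pair.forward)
        r_hits = _find_all(seq, revcomp(pair.reverse))
        if len(f_hits) != 1 or len(r_hits) != 1:
            raise LocusError(
                f"primer pair matches {len(f_hits)}/{len(r_hits)} sites in "
                f"{allele_id} (exactly one each required)")
        start = f_hits[0]
        end = r_hits[0] + len(pair.reverse)
        if end <= start:
            raise LocusError(f"primer pair inverted on {allele_id}")
        return start, end

    def amplicon(self, allele_id: str, pair: PrimerPair | None = None) -> str:
        if pair is None:
            pair = self.primer_pairs[0]
        s, e = self.primer_sites(allele_id, pair)
        return self.allele(allele_id).seq[s:e]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        ids = [a.id for a in self.alleles]
        if len(set(ids)) != len(ids):
            raise LocusError("duplicate allele ids")
        for a in self.alleles:
            a.validate()
        for chrom, layout in self.chrom_layouts.items():
            for aid in layout:
                if aid not in self._by_id:
                    raise LocusError(f"layout {chrom} references unknown "
                                     f"allele {aid!r}")
            for g in self.gaps(chrom):
                if g < 0:
                    raise LocusError(f"negative inter-allele gap on {chrom}")
        lo, hi = self.amplicon_len_range
        for pair in self.primer_pairs:
            for aid in pair.targets:
                product = self.amplicon(aid, pair)
                if not (lo <= len(product) <= hi):
                    raise LocusError(
                        f"amplicon of {aid} is {len(product)} bp, outside "
                        f"[{lo}, {hi}]")
        for v in self.variants:
            a = self.allele(v.allele_id)
            if not (0 <= v.pos < len(a.seq)):
                raise LocusError(f"variant {v} outside {a.id}")
            if a.seq[v.pos] != v.alt:
                raise LocusError(
                    f"variant {v}: allele carries {a.seq[v.pos]} not alt")


def _find_all(seq: str, sub: str) -> list[int]:
    hits, i = [], seq.find(sub)
    while i != -1:
        hits.append(i)
        i = seq.find(sub, i + 1)
    return hits


# -- repeat collapse -------------------------------------------------------

def collapse_repeats(seq: str, min_copies: int = 3, max_unit: int = 3,
                     keep_copies: int = 3) -> str:
    """Collapse tandem repeat tracts to a canonical copy number.

    Any run of >= ``min_copies`` consecutive copies of a 1-3 bp unit is
    shortened to ``keep_copies`` copies, so sequences differing only in
    repeat-tract length become identical. Idempotent; the length change is
    always a multiple of the unit length.
    """
    out = []
    i, n = 0, len(seq)
    while i < n:
        best = None  # (total_len, unit_len, copies)
        for u in range(1, max_unit + 1):
            unit = seq[i:i + u]
            if len(unit) < u or _is_periodic(unit):
                continue
            k = 1
            while seq[i + k * u:i + (k + 1) * u] == unit:
                k += 1
            if k >= min_copies and (best is None or k * u > best[0]):
                best = (k * u, u, k)
        if best is not None:
            total, u, k = best
            out.append(seq[i:i + u] * keep_copies)
            i += total
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def _is_periodic(unit: str) -> bool:
    """True when a unit is itself a repeat of a shorter unit (e.g. 'AA')."""
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return True
    return False


# -- discriminating SNP discovery ------------------------------------------

@dataclass
class DiscriminatingSnpTable:
    """Pairwise substitution differences between allele amplicons.

    ``entries`` maps each ordered allele pair to its (column, base_a, base_b)
    substitution differences on the repeat-collapsed multiple alignment of
    the window; pairs with no differences at all sit in ``identical_pairs``
    and pairs whose only differences are repeat-tract length in
    ``repeat_only_pairs``. Every unordered pair belongs to exactly one of
    the three groups.
    """

    window: tuple[int, int]
    allele_ids: list[str]
    msa: dict[str, str]
    entries: dict[tuple[str, str], list[tuple[int, str, str]]]
    identical_pairs: set[frozenset]
    repeat_only_pairs: set[frozenset]

    def columns(self) -> list[int]:
        cols: set[int] = set()
        for diffs in self.entries.values():
            cols.update(c for c, _, _ in diffs)
        return sorted(cols)

    def pair_class(self, a: str, b: str) -> str:
        key = frozenset((a, b))
        if key in self.identical_pairs:
            return "identical"
        if key in self.repeat_only_pairs:
            return "repeat_only"
        return "snp"


def find_discriminating_positions(
        model: LocusModel,
        window: tuple[int, int] | None = None,
        pair: PrimerPair | None = None) -> DiscriminatingSnpTable:
    """Classify every allele pair of a shared amplicon by its differences.

    The window is amplicon-relative; by default the full amplicon product of
    the model's first primer pair is used. Substitution columns are computed
    on a repeat-collapsed multiple alignment so that repeat-length
    polymorphism never masquerades as substitutions.
    """
    if pair is None:
        pair = model.primer_pairs[0]
    ids = list(pair.targets)
    products = {aid: model.amplicon(aid, pair) for aid in ids}
    min_len = min(len(p) for p in products.values())
    if window is None:
        # full per-allele amplicon product (repeat tracts may make product
        # lengths differ between alleles)
        window = (0, max(len(p) for p in products.values()))
        raw = dict(products)
    else:
        ws, we = window
        if not (0 <= ws < we):
            raise LocusError(f"bad window {window}")
        if ws >= min_len:
            raise LocusError(f"window {window} not covered by the shared "
                             "primer pair")
        raw = {aid: products[aid][ws:min(we, len(products[aid]))]
               for aid in ids}
    ws, we = window
    collapsed = {aid: collapse_repeats(s) for aid, s in raw.items()}

    rows = multi_align_window([collapsed[aid] for aid in ids])
    msa = dict(zip(ids, rows))

    entries: dict[tuple[str, str], list[tuple[int, str, str]]] = {}
    identical: set[frozenset] = set()
    repeat_only: set[frozenset] = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            key = frozenset((a, b))
            if raw[a] == raw[b]:
                identical.add(key)
                continue
            if collapsed[a] == collapsed[b]:
                repeat_only.add(key)
                continue
            diffs = []
            for col, (ca, cb) in enumerate(zip(msa[a], msa[b])):
                if ca != "-" and cb != "-" and ca != cb:
                    diffs.append((col, ca, cb))
            entries[(a, b)] = diffs
            entries[(b, a)] = [(c, y, x) for c, x, y in diffs]
    return DiscriminatingSnpTable(window=(ws, we), allele_ids=ids, msa=msa,
                                  entries=entries, identical_pairs=identical,
                                  repeat_only_pairs=repeat_only)


# -- I/O -------------------------------------------------------------------
#
# Plain-text locus dialect (documented in the README):
#   alleles FASTA    one record per allele, id matching the annotation
#   annotation TSV   rows starting with "allele": id gene chrom copy_index
#                    start exons repeats gap_to_next; rows starting with
#                    "primer": forward reverse targets(comma-separated)
#   variants TSV     allele_id pos ref alt  (minimal VCF-like dialect)

def _fmt_exons(exons: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons) or "."


def _parse_exons(text: str) -> list[tuple[int, int]]:
    if text in (".", ""):
        return []
    return [tuple(int(x) for x in part.split("-"))  # type: ignore[misc]
            for part in text.split(";")]


def _fmt_repeats(reps: list[tuple[int, str, int]]) -> str:
    return ";".join(f"{p}:{u}:{c}" for p, u, c in reps) or "."


def _parse_repeats(text: str) -> list[tuple[int, str, int]]:
    if text in (".", ""):
        return []
    out = []
    for part in text.split(";"):
        p, u, c = part.split(":")
        out.append((int(p), u, int(c)))
    return out


def load_locus(allele_fasta: str | Path, annotation: str | Path,
               variants: str | Path | None = None) -> LocusModel:
    """Read a locus from FASTA + annotation TSV (+ optional variant TSV)."""
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(allele_fasta), "fasta")}
    alleles: list[Allele] = []
    layouts: dict[str, list[str]] = {}
    primer_pairs: list[PrimerPair] = []
    with open(annotation, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "allele":
                (_, aid, gene, chrom, copy_index, start, exons, repeats,
                 _gap) = row
                if aid not in seqs:
                    raise LocusError(f"annotation references {aid!r} absent "
                                     "from FASTA")
                alleles.append(Allele(
                    id=aid, gene=gene, chrom=chrom,
                    copy_index=int(copy_index), seq=seqs[aid],
                    start=int(start), exons=_parse_exons(exons),
                    repeats=_parse_repeats(repeats)))
                layouts.setdefault(chrom, []).append(aid)
            elif row[0] == "primer":
                _, fwd, rev, targets = row
                primer_pairs.append(PrimerPair(fwd, rev,
                                               tuple(targets.split(","))))
            else:
                raise LocusError(f"unknown annotation record {row[0]!r}")
    for chrom in layouts:
        layouts[chrom].sort(key=lambda aid: next(
            a.start for a in alleles if a.id == aid))
    var_set: set[Variant] = set()
    if variants is not None:
        with open(variants, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                aid, pos, ref, alt = row
                var_set.add(Variant(aid, int(pos), ref, alt))
    model = LocusModel(alleles=alleles, chrom_layouts=layouts,
                       primer_pairs=primer_pairs, variants=var_set)
    model.validate()
    return model


def write_locus(model: LocusModel, outdir: str | Path) -> dict[str, Path]:
    """Write a locus back to the three plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "alleles.fasta"
    annot = outdir / "annotation.tsv"
    vars_path = outdir / "variants.tsv"
    SeqIO.write([SeqRecord(Seq(a.seq), id=a.id, description=a.gene)
                 for a in model.alleles], str(fasta), "fasta")
    with open(annot, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for chrom, layout in model.chrom_layouts.items():
            gaps = model.gaps(chrom) + [0]
            for aid, gap in zip(layout, gaps):
                a = model.allele(aid)
                w.writerow(["allele", a.id, a.gene, a.chrom, a.copy_index,
                            a.start, _fmt_exons(a.exons),
                            _fmt_repeats(a.repeats), gap])
        for pair in model.primer_pairs:
            w.writerow(["primer", pair.forward, pair.reverse,
                        ",".join(pair.targets)])
    with open(vars_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for v in sorted(model.variants, key=lambda v: (v.allele_id, v.pos)):
            w.writerow([v.allele_id, v.pos, v.ref, v.alt])
    return {"fasta": fasta, "annotation": annot, "variants": vars_path}
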