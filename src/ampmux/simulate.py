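"""Ground-truth simulation of a tandem-duplicated multi-allele target locus.

The default locus emulates a hybrid aspen-like genotype in which a single
consensus gRNA targets three paralogous MYB genes whose Chr8 copies were
tandemly duplicated on one sub-genome, yielding eight target alleles:

    Chr8m  : MYB186m1 - MYB138m1 - MYB186m2 - MYB138m2   (four tandem copies)
    Chr8a  : MYB186a - MYB138a                            (two tandem copies)
    Chr10m : MYB38m
    Chr10a : MYB38a

All eight alleles carry one byte-identical guide site in exon 2. Within the
consensus amplicon (~270 bp, spanning the cut site and an intronic GT
dinucleotide repeat), one cross-gene pair is identical (MYB138m1/MYB186m2),
one pair differs only in GT-repeat length (MYB186m1/MYB186a), and every
other pair is separated by at least one discriminating SNP. Discriminating
SNPs inside the amplicon all sit upstream of the cut, as in the real locus
where they cluster in the flanking introns; additional SNPs outside the
amplicon (used by the fusion caller's longer PCR fragment) make every allele
uniquely identifiable on both flanks of the cut.

Default cut-to-cut distances on Chr8m are 29,000 bp (MYB186m1 to MYB138m1)
and 62,000 bp (MYB138m1 to MYB138m2), anchoring simulated dropout-fusion
sizes to the two resolved fusion alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .align import revcomp
from .guides import GuideSite, locate_site
from .locus import Allele, LocusModel, PrimerPair, Variant

ALLELE_ORDER = ["MYB186m1", "MYB138m1", "MYB186m2", "MYB138m2",
                "MYB186a", "MYB138a", "MYB38m", "MYB38a"]

# template geometry (coordinates on the GT8 backbone)
_LEN = 740
_EXON1 = (0, 150)
_EXON2 = (250, 470)
_INTRON2 = (470, 590)
_EXON3 = (590, 740)
_FWD = (270, 290)
_REV = (520, 540)
_SPACER = (334, 354)
_PAM = (354, 357)
_CUT = 351
_GT_START = 480
_GT_BASE = 8

# discriminating SNP columns (template coordinates); every column carries a
# fixed G-A-T neighborhood (ref base A, alt base C) so that neither ref nor
# alt can ever extend a tandem-repeat run -- repeat collapsing must never
# erase a discriminating substitution
_C = {f"c{i}": pos for i, pos in enumerate(
    [292, 296, 300, 304, 308, 312, 316, 320, 324], start=1)}
_C["c10"] = 328   # used only when the identical pair is disabled
_C["c11"] = 332   # used only when the repeat-only pair is disabled
_Y = {"y1": 254, "y2": 258}                      # upstream, outside amplicon
_X = {f"x{i}": pos for i, pos in enumerate(
    [548, 554, 560, 566, 572, 578, 584], start=1)}  # downstream, outside

_GENE_SNPS = {"MYB138": [20, 60, 620, 680], "MYB38": [40, 80, 610, 670]}
_ALL_SNP_POSITIONS = sorted(set(_C.values()) | set(_Y.values()) |
                            set(_X.values()) |
                            {p for ps in _GENE_SNPS.values() for p in ps})

# (gene, chrom, copy_index, start, GT copies, snp column names)
_ALLELE_SPECS = {
    "MYB186m1": ("MYB186", "Chr8m", 0, 100_000, 8, []),
    "MYB138m1": ("MYB138", "Chr8m", 1, 129_000, 8, ["c1", "c2", "c3", "x1"]),
    "MYB186m2": ("MYB186", "Chr8m", 2, 162_000, 8,
                 ["c1", "c2", "c3", "y2", "x2"]),
    "MYB138m2": ("MYB138", "Chr8m", 3, 191_000, 8, ["c4", "c5", "c6", "x6"]),
    "MYB186a": ("MYB186", "Chr8a", 0, 100_000, 11, ["y1", "x3"]),
    "MYB138a": ("MYB138", "Chr8a", 1, 131_000, 9,
                ["c1", "c2", "c4", "c5", "x4"]),
    "MYB38m": ("MYB38", "Chr10m", 0, 50_000, 8, ["c7", "c8", "c9", "x5"]),
    "MYB38a": ("MYB38", "Chr10a", 0, 50_000, 10, ["c7", "c8", "c9", "c1",
                                                  "x7"]),
}

_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _make_template(rng: np.random.Generator) -> str:
    bases = rng.choice(list("ACGT"), size=_LEN)
    t = list("".join(bases))
    t[470:472] = "GT"            # intron 2 splice donor
    t[478:480] = "CA"            # stop runs bleeding into the repeat tract
    t[_GT_START:_GT_START + 2 * _GT_BASE] = "GT" * _GT_BASE
    t[496:498] = "AC"
    t[_PAM[0] + 1:_PAM[1]] = "GG"  # NGG PAM
    for p in _ALL_SNP_POSITIONS:
        t[p - 1:p + 2] = "GAT"   # run-proof SNP neighborhood
    return "".join(t)


def build_default_locus(seed: int = 1, identical_pair: bool = True,
                        repeat_only_pair: bool = True) -> LocusModel:
    """Deterministically build the default eight-allele locus.

    ``identical_pair=False`` gives MYB186m2 one extra in-amplicon SNP so no
    pair is amplicon-identical; ``repeat_only_pair=False`` does the same for
    MYB186a so no pair differs only in repeat length. Both switches produce
    the fully resolvable variant used for decoder round-trip testing.
    """
    rng = np.random.default_rng(seed)
    template = _make_template(rng)
    col_pos = {**_C, **_Y, **_X}

    alleles: list[Allele] = []
    layouts: dict[str, list[str]] = {}
    variants: set[Variant] = set()
    for aid in ALLELE_ORDER:
        gene, chrom, copy_index, start, gt, cols = _ALLELE_SPECS[aid]
        cols = list(cols)
        if not identical_pair and aid == "MYB186m2":
            cols.append("c10")
        if not repeat_only_pair and aid == "MYB186a":
            cols.append("c11")
        core = list(template)
        snp_positions = [col_pos[c] for c in cols]
        snp_positions += _GENE_SNPS.get(gene, [])
        for pos in snp_positions:
            core[pos] = "C"  # alt base; ref is A at every SNP column
        delta = 2 * (gt - _GT_BASE)
        seq = ("".join(core[:_GT_START]) + "GT" * gt +
               "".join(core[_GT_START + 2 * _GT_BASE:]))
        exons = [_EXON1, _EXON2,
                 (_EXON3[0] + delta, _EXON3[1] + delta)]
        alleles.append(Allele(id=aid, gene=gene, chrom=chrom,
                              copy_index=copy_index, seq=seq, start=start,
                              exons=exons, repeats=[(_GT_START, "GT", gt)]))
        layouts.setdefault(chrom, []).append(aid)
        for pos in sorted(snp_positions):
            local = pos if pos < _GT_START else pos + delta
            variants.add(Variant(aid, local, template[pos], seq[local]))

    fwd = template[_FWD[0]:_FWD[1]]
    rev = revcomp(template[_REV[0]:_REV[1]])
    model = LocusModel(alleles=alleles, chrom_layouts=layouts,
                       primer_pairs=[PrimerPair(fwd, rev,
                                                tuple(ALLELE_ORDER))],
                       variants=variants)
    model.validate()
    return model


def planted_guide(model: LocusModel) -> GuideSite:
    """The planted exon-2 consensus guide of a default-locus model."""
    ref = model.allele(ALLELE_ORDER[0]).seq
    spacer = ref[_SPACER[0]:_SPACER[1]]
    pam = ref[_PAM[0]:_PAM[1]]
    return locate_site(model, spacer, pam, targets=model.allele_ids)


# -- edit simulation -------------------------------------------------------

_OTHER_SIZES = (-12, -11, -10, -9, -8, -7, -5, 2, 3, 4, 5, 6)

#: default indel class weights; the four frameshift classes -1/-2/-4/+1
#: jointly carry 0.82 (>three-quarters of indels) and the in-frame classes
#: -3/-6 carry 0.10, matching the reported aggregate spectrum.
DEFAULT_INDEL_WEIGHTS = {-1: 0.30, -2: 0.28, -4: 0.12, 1: 0.12,
                         -3: 0.07, -6: 0.03, "other": 0.08}


@dataclass
class EditSpectrumConfig:
    """Per-line edit sampling model.

    ``indel_weights`` are per-class probabilities over signed indel sizes
    (key ``"other"`` draws uniformly from a pool of rarer sizes).
    ``dropout_prob`` applies per ordered pair of same-chromosome cut sites;
    at most one dropout fusion is realized per chromosome copy per line.
    """

    indel_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_INDEL_WEIGHTS))
    p_edit: float = 0.9
    p_chimera: float = 0.1
    dropout_prob: float = 0.2
    junction_indel_prob: float = 0.8
    mixture_range: tuple[float, float] = (0.1, 0.9)
    max_indel: int = 50

    def validate(self) -> None:
        probs = [self.p_edit, self.p_chimera, self.dropout_prob,
                 self.junction_indel_prob, *self.mixture_range]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.indel_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel class weights sum to {total}, not 1")
        for k in self.indel_weights:
            if k != "other" and (k == 0 or abs(k) > self.max_indel):
                raise ValueError(f"bad indel class {k!r}")

    def sample_indel(self, rng: np.random.Generator) -> int:
        keys = list(self.indel_weights)
        probs = [self.indel_weights[k] for k in keys]
        k = keys[rng.choice(len(keys), p=probs)]
        if k == "other":
            k = int(_OTHER_SIZES[rng.integers(len(_OTHER_SIZES))])
        return int(k)


@dataclass(frozen=True)
class EditEvent:
    kind: str                     # "indel" | "dropout_fusion" | "chimera"
    allele_id: str | None = None
    donors: tuple[str, str] | None = None
    indel_size: int = 0
    inserted_seq: str = ""
    mixture_fraction: float | None = None


@dataclass
class EditedGenotype:
    """Planted per-allele edits and the realized sequences they produce."""

    line_id: str
    events: list[EditEvent]
    realized: dict[str, str | None]
    chimera_edited: dict[str, str]
    seed: int


def apply_indel(seq: str, cut: int, size: int, inserted: str = "") -> str:
    if size == 0:
        return seq
    if size > 0:
        if len(inserted) != size:
            raise ValueError("inserted_seq length must equal indel size")
        return seq[:cut] + inserted + seq[cut:]
    span = -size
    left = cut - (span - span // 2)
    return seq[:left] + seq[left + span:]


def _random_insert(rng: np.random.Generator, size: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=size))


def simulate_line_edits(model: LocusModel, guide: GuideSite,
                        cfg: EditSpectrumConfig, seed: int,
                        line_id: str | None = None) -> EditedGenotype:
    """Sample one line's ground-truth genotype.

    Dropout fusions join the upstream donor's prefix (through its cut site)
    to the downstream donor's suffix (from its cut site), optionally with a
    junction indel; the fused chromosome loses the downstream donor and all
    alleles strictly between the donors. Surviving alleles are then edited
    independently (indel or chimeric mixture).
    """
    cfg.validate()
    for aid in model.allele_ids:
        if aid not in guide.hits:
            raise ValueError(f"guide does not hit allele {aid}")
    rng = np.random.default_rng(seed)
    line_id = line_id or f"line-{seed}"
    events: list[EditEvent] = []
    realized: dict[str, str | None] = {a.id: a.seq for a in model.alleles}
    chimera_edited: dict[str, str] = {}
    consumed: set[str] = set()

    for chrom, layout in model.chrom_layouts.items():
        sites = [aid for aid in layout if aid in guide.hits]
        pairs = [(u, d) for i, u in enumerate(sites) for d in sites[i + 1:]]
        hits = [p for p in pairs if rng.random() < cfg.dropout_prob]
        if not hits:
            continue
        u, d = hits[rng.integers(len(hits))]
        size, ins = 0, ""
        if rng.random() < cfg.junction_indel_prob:
            size = cfg.sample_indel(rng)
            if size > 0:
                ins = _random_insert(rng, size)
        cut_u = guide.hits[u].cut
        cut_d = guide.hits[d].cut
        fused = model.allele(u).seq[:cut_u] + model.allele(d).seq[cut_d:]
        fused = apply_indel(fused, cut_u, size, ins)
        realized[u] = fused
        i_u, i_d = layout.index(u), layout.index(d)
        for mid in layout[i_u + 1:i_d + 1]:
            realized[mid] = None
        events.append(EditEvent(kind="dropout_fusion", donors=(u, d),
                                indel_size=size, inserted_seq=ins))
        consumed.update(layout[i_u:i_d + 1])

    for aid in model.allele_ids:
        if aid in consumed or rng.random() >= cfg.p_edit:
            continue
        size = cfg.sample_indel(rng)
        ins = _random_insert(rng, size) if size > 0 else ""
        cut = guide.hits[aid].cut
        edited = apply_indel(model.allele(aid).seq, cut, size, ins)
        if rng.random() < cfg.p_chimera:
            frac = float(rng.uniform(*cfg.mixture_range))
            chimera_edited[aid] = edited
            events.append(EditEvent(kind="chimera", allele_id=aid,
                                    indel_size=size, inserted_seq=ins,
                                    mixture_fraction=frac))
        else:
            realized[aid] = edited
            events.append(EditEvent(kind="indel", allele_id=aid,
                                    indel_size=size, inserted_seq=ins))
    return EditedGenotype(line_id=line_id, events=events, realized=realized,
                          chimera_edited=chimera_edited, seed=seed)


def expected_calls(genotype: EditedGenotype, model: LocusModel,
                   guide: GuideSite) -> dict[str, tuple[str, int | None]]:
    """Amplicon-observable ground truth: allele id -> (class, indel size).

    A dropout fusion is observed as NA at the downstream donor and every
    intervening allele, and as the junction indel at the upstream donor. A
    seamless fusion (no junction indel) between donors of equal repeat
    length is indistinguishable from an intact upstream allele and is
    therefore expected WT; if the donors' repeat lengths differ, the
    repeat-length shift surfaces as the upstream donor's apparent indel.
    """
    out: dict[str, tuple[str, int | None]] = {
        aid: ("WT", 0) for aid in model.allele_ids}
    for ev in genotype.events:
        if ev.kind == "dropout_fusion":
            u, d = ev.donors
            chrom = model.allele(u).chrom
            layout = model.chrom_layouts[chrom]
            for mid in layout[layout.index(u) + 1:layout.index(d) + 1]:
                out[mid] = ("NA", None)
            gt_u = sum(c * len(unit) for _, unit, c in model.allele(u).repeats)
            gt_d = sum(c * len(unit) for _, unit, c in model.allele(d).repeats)
            if ev.indel_size != 0:
                out[u] = ("indel", ev.indel_size)
            elif gt_d != gt_u:
                out[u] = ("indel", gt_d - gt_u)
            else:
                out[u] = ("WT", 0)
        elif ev.kind == "chimera":
            out[ev.allele_id] = ("chimeric", ev.indel_size)
        else:
            out[ev.allele_id] = ("indel", ev.indel_size)
    return out


# -- read simulation -------------------------------------------------------

def _extract_product(seq: str, pair: PrimerPair) -> str | None:
    f = seq.find(pair.forward)
    if f == -1:
        return None
    r = seq.find(revcomp(pair.reverse), f)
    if r == -1:
        return None
    return seq[f:r + len(pair.reverse)]


def simulate_amplicon_reads(genotype: EditedGenotype, model: LocusModel,
                            depth: int = 500, error_rate: float = 0.001,
                            read_len: int = 150, seed: int = 0,
                            ) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) merged amplicon reads for one line.

    Reads are drawn from the realized amplicon of every allele whose primer
    sites survived; substitution errors are i.i.d. at ``error_rate``; about
    half the reads are emitted reverse-complemented. Chimeric alleles emit
    the configured mixture of edited and unedited products.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= error_rate < 0.1):
        raise ValueError("error_rate must lie in [0, 0.1)")
    rng = np.random.default_rng(seed)
    pair = model.primer_pairs[0]
    for aid in model.allele_ids:
        seq = genotype.realized[aid]
        if seq is None:
            continue
        product = _extract_product(seq, pair)
        if product is None:
            continue  # primer site destroyed
        if 2 * read_len < len(product):
            raise ValueError(
                f"read_len {read_len} cannot cover the {len(product)} bp "
                "product of a merged read pair")
        edited_product = None
        frac = 0.0
        if aid in genotype.chimera_edited:
            edited_product = _extract_product(genotype.chimera_edited[aid],
                                              pair)
            frac = next(ev.mixture_fraction for ev in genotype.events
                        if ev.kind == "chimera" and ev.allele_id == aid)
        n_edited = int(rng.binomial(depth, frac)) if edited_product else 0
        for i in range(depth):
            src = edited_product if i < n_edited else product
            read = list(src)
            n_err = rng.binomial(len(read), error_rate)
            if n_err:
                for pos in rng.choice(len(read), size=n_err, replace=False):
                    choices = [b for b in "ACGT" if b != read[pos]]
                    read[pos] = choices[rng.integers(3)]
            out = "".join(read)
            if rng.random() < 0.5:
                out = revcomp(out)
            yield f"{genotype.line_id}|{aid}|{i}", out


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write merged reads as FASTQ (Phred+33, constant Q37)."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'F' * len(seq)}\n")
            n += 1
    return n


def write_ground_truth(genotype: EditedGenotype, path: str | Path) -> None:
    rows = []
    for ev in genotype.events:
        rows.append({
            "line": genotype.line_id, "kind": ev.kind,
            "allele": ev.allele_id or "",
            "donors": "-".join(ev.donors) if ev.donors else "",
            "indel_size": ev.indel_size, "inserted_seq": ev.inserted_seq,
            "mixture_fraction": ev.mixture_fraction})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- stand-in for the published per-allele mutation table -------------------

# class string grammar: integer = indel of that size; "c<int>" = chimeric
# with that edited size; "NA" = no amplification; "WT" = unedited.
_KO_TABLE = {
    "KO-1":  ["-1", "-2", "-1", "+1", "-2", "-4", "-1", "-2"],
    "KO-2":  ["-2", "NA", "NA", "-1", "-1", "-3", "-2", "-1"],
    "KO-3":  ["NA", "NA", "NA", "-1", "-2", "+1", "-1", "-4"],
    "KO-4":  ["-1", "NA", "NA", "NA", "-2", "-2", "+1", "-1"],
    "KO-5":  ["-2", "NA", "NA", "NA", "NA", "NA", "-1", "-2"],
    "KO-6":  ["NA", "-4", "NA", "NA", "-1", "-6", "-2", "-1"],
    "KO-7":  ["-3", "NA", "NA", "NA", "-1", "-2", "c-2", "-1"],
    "KO-8":  ["-1", "-2", "-4", "-2", "+1", "-1", "-2", "+2"],
    "KO-9":  ["NA", "NA", "-2", "NA", "-1", "-1", "-4", "c+1"],
    "KO-10": ["-2", "NA", "NA", "NA", "-3", "-1", "-1", "-2"],
    "KO-11": ["NA", "-1", "NA", "-2", "NA", "-2", "+1", "-5"],
    "KO-12": ["-4", "-1", "-2", "-1", "-2", "+1", "-1", "-1"],
    "KO-13": ["NA", "NA", "-1", "NA", "-2", "-4", "-3", "-2"],
    "KO-14": ["-1", "NA", "-2", "NA", "-4", "-2", "c-1", "+1"],
    "KO-15": ["NA", "-2", "NA", "NA", "-1", "-1", "-2", "-6"],
    "KO-16": ["-5", "NA", "NA", "-2", "NA", "-1", "-1", "-2"],
    "KO-17": ["NA", "NA", "-4", "NA", "-2", "-2", "-1", "+3"],
    "KO-18": ["-2", "-1", "NA", "NA", "NA", "+1", "-3", "-1"],
    "KO-19": ["-1", "-2", "-2", "-4", "-1", "+1", "-2", "-1"],
    "KO-20": ["NA", "-3", "-6", "NA", "NA", "-2", "-1", "-1"],
    "KO-21": ["-1", "NA", "NA", "-1", "-2", "NA", "-4", "c-2"],
    "KO-22": ["NA", "NA", "-2", "NA", "+2", "-1", "-1", "-8"],
    "KO-23": ["-2", "-5", "NA", "NA", "NA", "-1", "+1", "-2"],
    "KO-24": ["+1", "-1", "-2", "-1", "-4", "-2", "-1", "-2"],
    "KO-25": ["NA", "NA", "NA", "-3", "-1", "-2", "-2", "+2"],
    "KO-26": ["-6", "NA", "NA", "-1", "-2", "NA", "-1", "-4"],
    "KO-27": ["-3", "-1", "-2", "-1", "-2", "-4", "WT", "WT"],
    "KO-63": ["-1", "NA", "NA", "-2", "NA", "NA", "-3", "+1"],
    "KO-69": ["NA", "-2", "NA", "NA", "NA", "NA", "-1", "-2"],
    "KO-70": ["NA", "-2", "NA", "NA", "-6", "NA", "-1", "-1"],
}


def synthetic_ko_cohort() -> pd.DataFrame:
    """SYNTHETIC stand-in for the published per-allele mutation table.

    The original supplementary per-allele table of the 30 knockout lines is
    not redistributable here; this stand-in was constructed a priori from
    the aggregate statistics the study reports -- a mean of 5.4 indel
    alleles per line over 30 lines, KO-27 with six edited and two unedited
    alleles, KO-5/KO-69 with a single detectable Chr8 allele carrying -2 and
    five Chr8 NA alleles, KO-63/KO-70 with two detectable Chr8 alleles and
    four NA, 80% of lines harboring at least one NA allele, NA concentrated
    on the duplicated Chr8m copies, predominantly frameshift indel classes
    (-1/-2/-4/+1) and ~10% in-frame (-3/-6) sites. It is a constructed
    object, not the published data set.

    Returns a tidy table with columns line, allele, call, indel_size.
    """
    rows = []
    for line, cells in _KO_TABLE.items():
        for aid, cell in zip(ALLELE_ORDER, cells):
            if cell == "WT":
                rows.append((line, aid, "WT", 0))
            elif cell == "NA":
                rows.append((line, aid, "NA", None))
            elif cell.startswith("c"):
                rows.append((line, aid, "chimeric", int(cell[1:])))
            else:
                rows.append((line, aid, "indel", int(cell)))
    return pd.DataFrame(rows, columns=["line", "allele", "call",
                                       "indel_size"])
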