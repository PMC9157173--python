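"""SNP-phased reconstruction of large dropout/fusion alleles.

A Cas9 cut at two tandem gene copies on the same chromosome can resolve as
one large deletion joining the upstream copy's 5' portion (through its cut
site) to the downstream copy's 3' portion -- a fusion allele. Within a
short amplicon such an allele often looks like a plain indel at one donor,
but a longer sequence spanning the junction carries discriminating SNPs on
both flanks: the 5' flank phases to the upstream donor, the 3' flank to the
downstream donor, and the cut-to-cut distance in the locus layout gives the
dropout size.

Flank matching counts only substitution mismatches, so repeat-tract length
differences (which align as indels) never break a flank match -- the same
indel-blind metric used for read assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import compare
from .guides import GuideSite
from .locus import LocusModel


@dataclass(frozen=True)
class FusionCall:
    upstream: str
    downstream: str
    junction_size: int
    junction_seq: str
    dropout_bp: int
    evidence_up: tuple[int, ...]    # covered discriminating positions, 5'
    evidence_down: tuple[int, ...]  # covered discriminating positions, 3'


@dataclass(frozen=True)
class PlainIndel:
    allele_id: str
    size: int
    seq: str


@dataclass(frozen=True)
class Ambiguous:
    reason: str
    candidates_up: tuple[str, ...] = ()
    candidates_down: tuple[str, ...] = ()


def dropout_span(model: LocusModel, upstream_id: str, downstream_id: str,
                 guide: GuideSite) -> tuple[int, list[str]]:
    """Cut-to-cut dropout length and the fully deleted intervening alleles.

    Donors must be colinear: same chromosome copy, upstream strictly first.
    """
    u = model.allele(upstream_id)
    d = model.allele(downstream_id)
    if u.chrom != d.chrom:
        raise ValueError(f"{upstream_id} and {downstream_id} lie on "
                         "different chromosome copies")
    layout = model.chrom_layouts[u.chrom]
    iu, idx = layout.index(upstream_id), layout.index(downstream_id)
    if iu >= idx:
        raise ValueError(f"{upstream_id} does not precede {downstream_id} "
                         "in the layout")
    length = (d.start + guide.cut_site(downstream_id)) - \
        (u.start + guide.cut_site(upstream_id))
    return length, layout[iu + 1:idx]


def _variant_positions(model: LocusModel, allele_id: str) -> set[int]:
    return {v.pos for v in model.variants if v.allele_id == allele_id}


def _distinguishing(model: LocusModel, a: str, b: str) -> set[int]:
    """Approximate positions at which alleles a and b differ (union of
    their genotype-SNP positions that are not shared)."""
    va, vb = _variant_positions(model, a), _variant_positions(model, b)
    return va ^ vb


def phase_fusion(seq: str, model: LocusModel, guide: GuideSite,
                 max_flank_mm: int = 0, min_flank: int = 25,
                 window: int = 10):
    """Phase a junction-spanning sequence to its donor allele(s).

    Returns a :class:`FusionCall` when the 5' and 3' flanks uniquely match
    different colinear alleles, a :class:`PlainIndel` when both flanks
    match the same allele, and :class:`Ambiguous` otherwise (with the
    reason and conflicting candidates). ``max_flank_mm`` defaults to 0:
    Sanger-grade input is assumed; raise it for noisy reads.
    """
    seq = seq.upper()
    cands = sorted(guide.hits)
    per: dict[str, dict] = {}
    for aid in cands:
        ref = model.allele(aid).seq
        cut = guide.cut_site(aid)
        res = compare(seq, ref, end_free=True)
        up_mm = sum(1 for p in res.mismatch_positions if p < cut - window)
        down_mm = sum(1 for p in res.mismatch_positions if p >= cut + window)
        rs, re = res.ref_span
        per[aid] = {"res": res, "cut": cut,
                    "up_mm": up_mm, "down_mm": down_mm,
                    "up_cov": (rs, min(re, cut)),
                    "down_cov": (max(rs, cut), re)}

    def flank_matches(side: str) -> list[str]:
        out = []
        for aid in cands:
            info = per[aid]
            lo, hi = info[f"{side}_cov"]
            if hi - lo >= min_flank and info[f"{side}_mm"] <= max_flank_mm:
                out.append(aid)
        return out

    up = flank_matches("up")
    down = flank_matches("down")

    def resolve(side: str, matches: list[str]):
        """(unique_id | None, reason | None)"""
        if not matches:
            return None, f"no {side}stream flank match"
        if len(matches) == 1:
            return matches[0], None
        # several zero-mismatch matches: either the distinguishing columns
        # are outside the covered span, or the alleles are truly identical
        # on this flank
        for i, a in enumerate(matches):
            for b in matches[i + 1:]:
                diff = _distinguishing(model, a, b)
                lo, hi = per[a][f"{side}_cov"]
                if any(lo <= p < hi for p in diff):
                    return None, "conflicting evidence"
        return None, "insufficient SNP coverage"

    u, up_reason = resolve("up", up)
    d, down_reason = resolve("down", down)
    if u is None or d is None:
        return Ambiguous(reason=up_reason or down_reason,
                         candidates_up=tuple(up), candidates_down=tuple(down))

    def junction(ref: str, cut: int) -> tuple[int, str]:
        res = compare(seq, ref, end_free=True)
        hits = [i for i in res.indels
                if i.overlaps(cut - window, cut + window)]
        return (sum(i.size for i in hits), "".join(i.seq for i in hits))

    def covered_evidence(aid: str, side: str) -> tuple[int, ...]:
        lo, hi = per[aid][f"{side}_cov"]
        return tuple(sorted(p for p in _variant_positions(model, aid)
                            if lo <= p < hi))

    if u == d:
        size, jseq = junction(model.allele(u).seq, per[u]["cut"])
        return PlainIndel(allele_id=u, size=size, seq=jseq)

    uc, dc = model.allele(u), model.allele(d)
    if uc.chrom != dc.chrom:
        return Ambiguous(reason="flanks match alleles on different "
                         "chromosome copies",
                         candidates_up=(u,), candidates_down=(d,))
    layout = model.chrom_layouts[uc.chrom]
    if layout.index(u) >= layout.index(d):
        return Ambiguous(reason="flank matches are not layout-colinear",
                         candidates_up=(u,), candidates_down=(d,))
    cut_u, cut_d = per[u]["cut"], per[d]["cut"]
    fused_ref = uc.seq[:cut_u] + dc.seq[cut_d:]
    size, jseq = junction(fused_ref, cut_u)
    dropout, _ = dropout_span(model, u, d, guide)
    return FusionCall(upstream=u, downstream=d, junction_size=size,
                      junction_seq=jseq, dropout_bp=dropout,
                      evidence_up=covered_evidence(u, "up"),
                      evidence_down=covered_evidence(d, "down"))
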