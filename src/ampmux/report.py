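"""Cohort-level mutation-spectrum summaries and headline statistics.

The canonical cohort representation is a tidy table with one row per
(line, allele): columns ``line``, ``allele``, ``call`` (WT / indel / NA /
chimeric) and ``indel_size`` (signed bp; the edited pattern's size for
chimeric alleles, NaN for NA). Decoded :class:`~ampmux.decode.AlleleCall`
lists convert losslessly into this table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .decode import AlleleCall

EDITED_CALLS = ("indel", "chimeric")


def classify_frame(indel_size: int) -> str:
    """Reading-frame effect of a signed indel size.

    0 -> "none"; multiples of 3 -> "in_frame"; everything else ->
    "frameshift". In-frame indels at a DNA-binding helix are not
    necessarily functional, but that is an annotation question, not a
    frame question.
    """
    size = int(indel_size)
    if abs(size) > 50:
        raise ValueError("indel size out of range (|size| <= 50)")
    if size == 0:
        return "none"
    return "in_frame" if size % 3 == 0 else "frameshift"


def cohort_from_calls(lines: dict[str, list[AlleleCall]]) -> pd.DataFrame:
    rows = []
    for line_id, calls in lines.items():
        for c in calls:
            size: float | int | None
            if c.call == "NA":
                size = None
            elif c.call in EDITED_CALLS:
                edited = [p for p in c.patterns if p.size != 0]
                size = edited[0].size if edited else 0
            else:
                size = 0
            rows.append((line_id, c.allele_id, c.call, size))
    return pd.DataFrame(rows, columns=["line", "allele", "call",
                                       "indel_size"])


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the literal call string "NA" must survive parsing
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = {"line", "allele", "call"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    if "indel_size" not in df.columns:
        df["indel_size"] = 0
    return df


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return cohort


def mutation_rate(cohort: pd.DataFrame, count_na: bool = False) -> float:
    """Fraction of potential target sites with a detected edit.

    By default only indel and chimeric sites count as edited -- the
    conservative reading in which an NA allele is not attributed to
    editing; ``count_na=True`` adds NA sites (many NA alleles do arise
    from cleavage-induced dropouts).
    """
    cohort = _check_cohort(cohort)
    edited = cohort["call"].isin(EDITED_CALLS)
    if count_na:
        edited |= cohort["call"] == "NA"
    return float(edited.mean())


def cleavages_per_line(cohort: pd.DataFrame) -> float:
    """Mean number of indel-bearing alleles per line.

    Counts alleles called indel or chimeric (a chimeric site is one
    cleavage); NA alleles are excluded, so this is a lower bound on true
    cleavage activity when dropouts are present.
    """
    cohort = _check_cohort(cohort)
    per_line = cohort.groupby("line")["call"].apply(
        lambda s: int(s.isin(EDITED_CALLS).sum()))
    return float(per_line.mean())


@dataclass
class MutationSpectrum:
    n_lines: int
    n_alleles: int
    class_counts: dict[str, int]          # WT / indel / NA / chimeric
    indel_size_counts: dict[int, int]     # over indel+chimeric sites
    edited_fraction: float
    frameshift_fraction: float            # of sized indel sites
    in_frame_fraction: float
    genotype_strings: dict[str, str] = field(default_factory=dict)

    @property
    def total_sites(self) -> int:
        return sum(self.class_counts.values())

    def indel_class_frequencies(self) -> dict[int, float]:
        total = sum(self.indel_size_counts.values())
        return {k: v / total for k, v in
                sorted(self.indel_size_counts.items())} if total else {}

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "n_alleles": self.n_alleles,
            "class_counts": self.class_counts,
            "indel_size_counts": {str(k): v for k, v in
                                  sorted(self.indel_size_counts.items())},
            "edited_fraction": self.edited_fraction,
            "frameshift_fraction": self.frameshift_fraction,
            "in_frame_fraction": self.in_frame_fraction,
            "genotype_strings": self.genotype_strings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _genotype_string(sub: pd.DataFrame) -> str:
    parts = []
    for _, row in sub.iterrows():
        if row["call"] == "WT":
            parts.append("WT")
        elif row["call"] == "NA":
            parts.append("NA")
        else:
            size = int(row["indel_size"])
            token = f"{size:+d}"
            if row["call"] == "chimeric":
                token += "*"
            parts.append(token)
    return "/".join(parts)


def summarize(cohort: pd.DataFrame) -> MutationSpectrum:
    """Aggregate a decoded cohort into its mutation spectrum.

    Class counts always sum to lines x alleles; the frameshift/in-frame
    split is computed over sized indel and chimeric sites.
    """
    # stable sort by line only: within a line, rows stay in their given
    # (genomic) order, as in a per-line genotype panel
    cohort = _check_cohort(cohort).sort_values("line", kind="stable")
    lines = cohort["line"].unique()
    alleles = cohort["allele"].unique()
    class_counts = cohort["call"].value_counts().to_dict()
    for cls in ("WT", "indel", "NA", "chimeric"):
        class_counts.setdefault(cls, 0)
    sized = cohort[cohort["call"].isin(EDITED_CALLS)]
    size_counts = (sized["indel_size"].astype(int).value_counts()
                   .sort_index().to_dict())
    frames = [classify_frame(s) for s in sized["indel_size"].astype(int)
              if s != 0]
    n_frames = len(frames)
    spectrum = MutationSpectrum(
        n_lines=len(lines), n_alleles=len(alleles),
        class_counts=class_counts, indel_size_counts=size_counts,
        edited_fraction=mutation_rate(cohort),
        frameshift_fraction=(frames.count("frameshift") / n_frames
                             if n_frames else 0.0),
        in_frame_fraction=(frames.count("in_frame") / n_frames
                           if n_frames else 0.0),
        genotype_strings={
            line: _genotype_string(cohort[cohort["line"] == line])
            for line in lines},
    )
    assert spectrum.total_sites == len(cohort)
    return spectrum


def write_report(spectrum: MutationSpectrum, outdir: str | Path) -> dict:
    """Write the TSV + JSON report files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "genotypes.tsv"
    with open(tsv, "w") as fh:
        fh.write("line\tgenotype\n")
        for line, s in spectrum.genotype_strings.items():
            fh.write(f"{line}\t{s}\n")
    js = outdir / "spectrum.json"
    spectrum.to_json(js)
    return {"genotypes": tsv, "spectrum": js}
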