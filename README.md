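# ampmux

Single-gRNA multiplex CRISPR editing analysis for duplicated alleles:
consensus guide design, paralog-aware amplicon decoding, and SNP-phased
reconstruction of large genomic dropouts between tandem gene copies.

## The problem

When one gRNA targets a conserved exonic site shared by a small gene
family, a single construct can knock out every paralog, homoeolog and
tandem copy at once -- in a hybrid genome that can mean eight or more
near-identical target alleles. Reading the outcome back out of
consensus-primer amplicon sequencing is then the hard part:

* reads must be assigned to alleles that differ by only a few
  discriminating SNPs (and sometimes only by the length of an intronic
  GT-dinucleotide repeat, or not at all within the amplicon);
* Cas9 cuts at two sites on the same chromosome can resolve as large
  dropouts whose fusion product masquerades as a plain indel at one
  allele while the other alleles silently stop amplifying;
* repeat-length polymorphism between sibling alleles produces spurious
  +/-2-type indel calls far from the cut site if assignment treats indels
  as free and ties carelessly.

`ampmux` is for anyone designing or decoding such experiments: it models
the locus, designs SNP-free consensus guides (spacer+PAM byte-identical in
every target allele, cut 3 bp 5' of the NGG PAM), scans for mismatch-
limited off-targets, simulates edited lines with ground truth, decodes
per-allele mutation spectra {WT, indel, NA, chimeric}, and phases fusion
alleles from junction-spanning sequences, estimating the dropout size from
the cut-to-cut layout distance.

Key conventions: reads are assigned by minimal substitution-mismatch count
(indels are the editing signal, never a penalty); no-amplification (NA)
alleles are called fractionally against an unedited control amplified with
the same consensus primers (the built-in-control contract: allele flagged
when its sample share < 0.05 x its control share); an allele is chimeric
when WT and an edited pattern each hold >= 10% of its reads; frameshift
vs in-frame is size mod 3.

## Worked example

Simulate one edited line on the default eight-allele locus (three MYB
genes across two sub-genomes, with the MYB186/MYB138 block tandemly
duplicated on Chr8m) and decode it against a simulated control:

```python
import ampmux as m
from ampmux.decode import control_profile_from_reads
from ampmux.simulate import (EditSpectrumConfig, EditedGenotype,
                             simulate_amplicon_reads, simulate_line_edits)

model = m.build_default_locus(seed=1, identical_pair=False,
                              repeat_only_pair=False)
guide = m.planted_guide(model)
snps = m.find_discriminating_positions(model)

wt = EditedGenotype("control", [], {a.id: a.seq for a in model.alleles},
                    {}, 1)
profile = control_profile_from_reads(
    simulate_amplicon_reads(wt, model, depth=300, error_rate=0.001, seed=1),
    model, snps=snps)

cfg = EditSpectrumConfig(junction_indel_prob=1.0)
gt = simulate_line_edits(model, guide, cfg, seed=1007, line_id="KO-8")
reads = simulate_amplicon_reads(gt, model, depth=200, error_rate=0.001,
                                seed=1007)
for c in m.genotype_line(reads, model, guide, profile, snps=snps):
    top = c.dominant
    pat = f"{top.size:+d} @ {top.position}" if top and top.size else "WT"
    print(f"{c.allele_id:<9} {c.call:<8} reads={c.reads:<4} {pat}")
```

prints

```
MYB186m1  indel    reads=201  -2 @ 80
MYB138m1  indel    reads=198  -2 @ 80
MYB186m2  NA       reads=1    WT
MYB138m2  indel    reads=200  -4 @ 79
MYB186a   indel    reads=199  -2 @ 80
MYB138a   NA       reads=0    WT
MYB38m    indel    reads=201  -2 @ 80
MYB38a    indel    reads=199  +1 @ 81
```

Reading this: six alleles carry indels at the cut (amplicon position ~80);
the two NA alleles are the downstream casualties of two dropout fusions --
on Chr8m the `-2` at MYB138m1 is the junction indel of a fusion that
deleted MYB186m2's amplicon, and on Chr8a the `-2` at MYB186a pairs with
the silent MYB138a. The decoded genotype string `-2/-2/NA/-4/-2/NA/-2/+1`
matches the planted truth exactly. Phasing the fusion donors and the
dropout size needs the longer PCR fragment:

```python
res = m.phase_fusion(fragment, model, guide)
# FusionCall(upstream='MYB186m1', downstream='MYB138m1',
#            junction_size=-2, ..., dropout_bp=29000)
```

## Command line

```
ampmux --seed 1 simulate --out demo --lines 3     # locus + FASTQs + truth
ampmux design --locus demo --genes MYB186,MYB138,MYB38
ampmux offtarget --genome genome.fa --spacer <20nt> --max-mm 3
ampmux decode --locus demo --reads demo/KO-1.fastq \
              --control demo/control.fastq --out decoded
ampmux fuse --locus demo --seqs junctions.fasta
ampmux report --cohort cohort.tsv --out report
```

## File formats

A locus is three plain-text files: `alleles.fasta` (one record per
allele); `annotation.tsv` with `allele` rows (id, gene, chrom, copy_index,
start, exons `s-e;s-e`, repeats `pos:unit:count`, gap_to_next) and
`primer` rows (forward, reverse, comma-separated targets); and a minimal
VCF-like `variants.tsv` (allele_id, pos, ref, alt -- the allele carries
alt at pos). Cohort tables are tidy TSVs (line, allele, call, indel_size).
Reads are standard FASTQ (gzip accepted).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the pipeline end to end from scratch -- builds the default locus,
enumerates consensus guides, dereplicates a simulated control, simulates
and decodes a ten-line cohort against its planted truth, phases a fusion
fragment, and summarizes the cohort's mutation spectrum -- printing a
short summary and writing the acceptance JSON to `--out`.

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.
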