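# domainskip

Protein-domain-oriented exon skipping design: find in-frame exon combinations
that cleanly excise whole protein domains from a coding transcript, rank them
by pathogenic-variant burden and treatable-population reach, design
splice-modulating antisense oligonucleotides (ASOs) against the target exons
— with four-mismatch non-binding controls — and predict the RT-PCR band
patterns a validation splice assay would show.

## Who this is for

Splice-modulation therapy groups working on large structural genes built
from arrays of repetitive protein domains (*USH2A*, *DMD*, *NOTCH3*, ...).
Most loss-of-function variants in such genes are private, so instead of
fixing single mutations one selects *exons* whose removal (i) preserves the
reading frame and (ii) deletes exactly one complete domain from a
bead-on-a-string protein — avoiding hybrid fusion domains that may misfold.
Single exons rarely satisfy both conditions; *combinations* of consecutive
exons often do ("dual exon skipping").

## The core selection rule

For a contiguous exon run *i..j* with summed CDS length
L = Σ<sub>k=i..j</sub> cds(k):

* **frame**: the run is skippable iff L ≡ 0 (mod 3);
* **domain impact**: translate the removal into a protein interval
  (a boundary codon counts as removed only when ≥ 2 of its 3 nt are
  removed; a surviving hybrid junction codon is translated and reported as
  `p.X<i>_X<j>delins<Z>`). A candidate is *clean* when ≥ 1 annotated domain
  lies entirely inside the removed interval and none is cut; inter-domain
  linker residues never veto a clean call;
* **reach**: with summed pathogenic allele frequency a<sub>t</sub> in the
  target exons and a<sub>g</sub> gene-wide, the expected number of affected
  individuals who carry ≥ 1 target-exon allele under Hardy–Weinberg random
  mating is N·a<sub>t</sub>·(2a<sub>g</sub> − a<sub>t</sub>).

ASO candidates tile the exon plus 50 nt of intronic flank (lengths
17–23 nt), targeting either intron–exon boundaries or exonic splicing
enhancer (ESE) motifs found by SRSF1/2/5/6 position-weight-matrix scanning.
Hard filters: duplex T<sub>m</sub> ≥ 48 °C (RNA:RNA nearest-neighbor model)
and length; the 40–60 % GC window is a *soft* flag — validated published
leads exist just below it.

## Worked example

```bash
domainskip make-fixture --seed 1 --out fx/
domainskip find-targets --gff fx/toy_gene.gff3 --fasta fx/toy_gene.fa \
    --domains fx/toy_domains.tsv --out reports/
```

prints

```
wrote 51 candidates to reports/skip_candidates.tsv
top candidate: Δex2-3 (clean_single_domain, 306 nt, reach 0)
```

The toy gene carries 13 FN3-like domains of 102 aa, each split over two
exons (154 + 152 nt) so that neither exon alone is in-frame skippable while
every pair is: the top candidate removes 306 nt = 102 codons, exactly one
domain, with no junction residue. Designing oligos for one target exon:

```bash
domainskip design-asos --gff fx/toy_gene.gff3 --fasta fx/toy_gene.fa \
    --exon 14 --seed 7 --out reports/
# -> wrote 1211 candidates (65 ESE hits) to reports/asos_exon14.tsv
```

Each row carries sequence, GC %, T<sub>m</sub>, ESE coverage, hairpin and
self-dimer scores, advisory flags and a seeded four-mismatch control.
Finally, the predicted validation readout:

```bash
domainskip predict-products --gff fx/toy_gene.gff3 --fasta fx/toy_gene.fa \
    --fwd-exon 12 --rev-exon 17 --skip 14-15 --out reports/
 product_nt    isoform  frame_preserving
        765       full              True
        459 Δex14Δex15              True
```

— the skipped band runs exactly 306 nt below the full-length product.

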