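# Methods

## Coordinate model

All internal intervals are 0-based half-open on the + strand of the
reference; user-facing c./p. output is 1-based inclusive (community
convention). Exon "length" for the frame rule is the exon's CDS overlap,
not its full length, so UTR-containing terminal exons are handled
correctly; for fully coding internal exons the two coincide. Exon numbering
is the per-transcript 5'→3' rank, matching clinical usage. Phases satisfy
end_phase(k) = (start_phase(k) + cds_overlap(k)) mod 3 and chain across
coding exons; both are validated at load time together with CDS length
divisibility, absence of internal stop codons and exon non-overlap.
Minus-strand genes are reverse-complemented into transcript orientation at
load; a plus/minus twin of the same gene yields byte-identical transcripts.

## Skip consequences

A skip removes a contiguous run of exons from the mature transcript. With
skipped CDS span [s, e) in coding coordinates, the event is frame-preserving
iff (e − s) ≡ 0 (mod 3). For φ = s mod 3 = 0 the removal is codon-bounded
and reported as `p.X<i>_X<j>del`. For φ ≠ 0 the surviving hybrid codon
(upstream leftover + first retained bases) is translated; if its residue
equals the reference residue at either flank the event collapses to a plain
deletion, otherwise a single-residue `delins` is reported. Frameshifts are
reported as `p.X<pos>fs` at the first divergent residue of the re-translated
product. Intronic breakpoints in input HGVS (e.g. `c.123-5`) are accepted
but only the exonic consequence is modeled. Disjoint (non-adjacent)
frame-preserving event sets report frame status only (`p.?`); the
contiguous case — the one used by candidate enumeration — gets the full
annotation.

For *domain impact* the removed residue interval uses a whole-codon rule: a
codon split by the skip boundary counts as removed only when it loses ≥ 2 of
its 3 nucleotides; the hybrid junction codon persists as a (possibly novel)
residue and is never counted as removed. This matches the delins behavior
above: exactly one of the two boundary codons survives.

## Candidate enumeration, classification and ranking

All contiguous runs of ≤ `max_exons` internal coding exons are enumerated
(default 2, the dual-skip scope; configurable). The first and last coding
exons are never candidates (start/stop codon protection). Classification:
`frameshift` if the frame breaks; otherwise domains fully inside the
removed interval are "removed", domains overlapping but not contained force
`partial_domain_disruption`, and clean candidates are split into
`clean_single_domain` / `clean_multi_domain`. Linker residues outside any
annotated domain never block a clean call — the structural concern is
cutting into a neighboring domain, not losing linker. Ranking is the total
order (impact class, reach desc, burden desc, fewer exons, exon range);
the final key makes it deterministic on ties.

## Variant burden and reach

Loss-of-function classes counted by default: nonsense, frameshift,
canonical splice; missense is excluded (configurable via the class set).
Burden counts unique HGVS descriptions in the exon range; intronic records
are kept but flagged and never counted. Reach assumes Hardy–Weinberg random
mating, full penetrance of biallelic loss of function, and that one
restored allele suffices (the skipped transcript rescues any allele whose
variant lies in the skipped exons): with target-exon pathogenic allele
frequency a_t and gene-wide a_g,

    eligible = N · a_t · (2·a_g − a_t)        (≥ 1 target-exon allele)
    strict   = N · a_t²                        (both alleles in target exons)

Both are reported because published prevalence statements rarely say which
definition they use. The population constant defaults to 8.0×10⁹
(configurable). A convenience converter halves carrier frequencies under
the rare-allele approximation. Absolute reach numbers depend entirely on
the input frequency table; with synthetic tables they exercise the
arithmetic, not epidemiology.

## ASO design

Target regions are the exon plus `flank_nt` (default 50) intronic
nucleotides on each side, in sense orientation; flanks truncate with a
warning at reference ends. Every window of length 17–23 that overlaps the
exon is emitted, classed `boundary` when it crosses an intron–exon
junction, else `exonic_ese`; the oligo sequence is the exact reverse
complement in RNA alphabet.

**Tm.** The melting temperature of the oligo:pre-mRNA duplex is computed
with Watson–Crick RNA:RNA nearest-neighbor parameters (duplex initiation
3.61 kcal/mol, −1.5 eu; per-terminal A:U penalty 3.72 kcal/mol, 10.5 eu),
two-state Tm = ΔH/(ΔS + R·ln(C_T/4)) at total strand concentration 250 nM
(a typical screening dose) and a Schildkraut–Lifson correction of
+16.6·log₁₀[Na⁺] from the 1 M reference to 100 mM monovalent salt. No
correction is applied for 2′-MOE/phosphorothioate chemistry — absolute
values are therefore approximate for modified oligos and the 48 °C hard
threshold is configurable. The implementation agrees with an independent
nearest-neighbor implementation (Biopython's RNA table) to < 0.05 °C.

**ESE scanning.** Sense-strand windows inside the exon are scored against
bundled position weight matrices for SRSF1/SRSF2/SRSF5/SRSF6 (widths
7/8/7/6, thresholds 1.956/2.383/2.67/2.676). The weight tables are
own-constructed encodings of the factors' degenerate binding consensuses,
scaled so a consensus site scores moderately above threshold (one
unfavorable substitution can abolish a site, as with the original published
matrices); they ship as TSV data files so users can substitute matrices
from any other source. An oligo's `ese_hits` is the number of motif
footprints overlapping its window.

**Structure.** Hairpin propensity is the maximum number of nested
Watson–Crick+GU pairs with minimum loop 3 (maximum-pairing recursion) —
deterministic and parameter-free, used only for ranking, not as a folding
prediction; an external energy-model folding engine can replace it where
installed. Self-dimerization is the longest ungapped antiparallel
complementary run (longest common substring with the reverse complement).

**Filtering and ranking.** Hard filters: length within [17, 23] and
Tm ≥ 48 °C. Everything else is soft: rank = 2·[boundary] + 1·ese_hits
− 8·(GC distance outside [0.40, 0.60]) − 0.5·max(0, hairpin − 4)
− 0.5·max(0, dimer_run − 6), ties broken by window start, length, id. GC
is deliberately soft because an experimentally validated published lead
computes to 9/23 ≈ 39.1 % GC — a hard floor at 40 % would reject it; the
validator flags it instead.

**Mismatch controls.** Four substitutions at seeded-random interior
positions (never the first 3 or last 2 bases). Each replacement maximally
disrupts pairing with the target base: same-class purine↔purine /
pyrimidine↔pyrimidine swap where that does not create a Watson–Crick or GU
wobble pair, otherwise the disruptive base with minimal GC change,
alphabetical on ties. No spacing constraint beyond interior placement —
published control sets include adjacent mismatches. Generation is
deterministic per (sequence, seed).

## Splice-readout prediction

Minigene constructs model an insert of target exons between two
heterologous flanking exons carrying the primers (defaults amplify the
whole flanking exons; offsets configurable, since published constructs name
the flanking exons but not primer coordinates). Endogenous RT-PCR uses
primers at the centers of a named upstream and downstream exon. Product
size of a skipped isoform is the full product minus the summed skipped exon
lengths — exact by construction; band tables sort by size and merge
co-migrating isoforms. Band intensities, skip efficiencies and gel mobility
are experimental quantities and are not modeled.

## Synthetic fixtures

The generator emulates the repetitive architecture of domain-array genes:
`n_domains` domains of `domain_aa` residues (defaults 13 × 102 aa), each
encoded by one or two exons, optional linkers, intronic context with GT/AG
ends, one UTR+lead exon and one tail+stop exon. The default two-exon unit
spans 306 coding nt split 154 + 152 so the internal phase is 1: neither
exon alone is frame-preserving, the pair is — the dual
exon skipping geometry with a phase-0 unit start (no junction residue on a
clean pair skip). Codon sampling excludes stop codons so any seed yields a
valid CDS; generation is byte-reproducible per seed. What the fixtures do
*not* emulate: real splice-site strength distributions, base composition,
ESE density of real exons, or real variant spectra — so green tests
demonstrate arithmetic and algorithmic correctness, not the biology of any
particular gene. Checks of printed facts about the real human *USH2A*
isoform-B annotation require a user-supplied download
(`data/external/ush2a.{gff3,fa}`); they are the only tests with an external
input.

Test problem sizes were chosen for fast feedback: randomized sweeps use 50
genes of 3–5 domains (21–25 aa each), structure oracles enumerate all
pairings for sequences ≤ 12 nt, and exhaustive window/subset checks run on
single fixture regions.

## Known limitations

- Tm is for unmodified RNA:RNA duplexes; chemistry-aware thermodynamics are
  out of scope.
- No off-target transcriptome screen; sequence selectivity must be checked
  externally.
- Domains are inputs (TSV); there is no de novo domain prediction or 3D
  structural assessment.
- The Hardy–Weinberg reach model ignores population substructure and
  variant-level penetrance differences.
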