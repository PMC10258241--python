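"""Deterministic toy genes with repetitive domain architecture.

Real skip-design targets are large multi-exon genes encoding arrays of
near-identical protein domains (usherin's FN3 repeats being the motivating
case).  This module emulates that architecture at toy scale: ``n_domains``
equal-sized domains, each encoded by one or two exons, separated by
configurable linkers, with intronic context around every exon.  By default
each two-exon domain unit spans 306 coding nucleotides (102 codons) split so
that neither exon alone is frame-preserving while the pair is -- the dual
exon skipping geometry.

Everything is generated from a single integer seed and is byte-reproducible;
generated annotations round-trip through :func:`domainskip.gene_model.
load_gene_model`.
"""

from __future__ import annotations

import random
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .aso_designer import TargetRegion
from .gene_model import GeneModel, Transcript, load_gene_model

__all__ = [
    "FixtureSpec",
    "make_toy_gene",
    "write_toy_gene",
    "load_toy_gene",
    "designated_pair",
    "make_variant_table",
    "plant_ese",
]

# sense codons only; stop codons are excluded so any sampled CDS translates
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated toy gene."""

    n_domains: int = 13
    domain_aa: int = 102
    exons_per_domain: int = 2
    phase_pattern: tuple[int, ...] | None = None  # start phase per domain exon
    linker_aa: int = 0
    flank_intron_nt: int = 150
    lead_aa: int = 8   # residues between the initiator Met and the first domain
    tail_aa: int = 8
    utr_nt: int = 12
    seed: int = 1

    def __post_init__(self):
        if self.exons_per_domain not in (1, 2):
            raise ValueError("exons_per_domain must be 1 or 2")
        if min(self.n_domains, self.domain_aa, self.flank_intron_nt) <= 0:
            raise ValueError("fixture parameters must be positive")
        if self.linker_aa < 0:
            raise ValueError("linker_aa must be >= 0")


def _unit_exon_lengths(spec: FixtureSpec) -> list[int]:
    """Coding lengths of the exons of one domain unit (domain + linker)."""
    unit_nt = 3 * (spec.domain_aa + spec.linker_aa)
    if spec.exons_per_domain == 1:
        lengths = [unit_nt]
    else:
        # default split leaves an internal phase of 1: neither exon is
        # individually frame-preserving, the pair is
        u1 = (unit_nt // 2) // 3 * 3 + 1
        lengths = [u1, unit_nt - u1]
    if spec.phase_pattern is not None:
        if len(spec.phase_pattern) != spec.exons_per_domain:
            raise ValueError("phase_pattern must give one start phase per domain exon")
        if spec.phase_pattern[0] != 0:
            raise ValueError("impossible phase pattern: each unit starts at phase 0")
        bounds = list(spec.phase_pattern) + [0]
        lengths = []
        remaining = unit_nt
        for k in range(spec.exons_per_domain):
            want = (bounds[k + 1] - bounds[k]) % 3
            if k == spec.exons_per_domain - 1:
                L = remaining
                if L % 3 != want % 3 or L <= 0:
                    raise ValueError("impossible phase pattern for this unit length")
            else:
                L = max(3, (remaining // 2) // 3 * 3) + want
                L = min(L, remaining - (spec.exons_per_domain - k - 1))
            lengths.append(L)
            remaining -= L
    if any(x <= 0 for x in lengths) or sum(lengths) != unit_nt:
        raise ValueError("impossible phase pattern: degenerate exon lengths")
    return lengths


def designated_pair(spec: FixtureSpec) -> tuple[int, int]:
    """Exon index range of the middle domain's unit -- the canonical clean
    skip target of the fixture (306 nt under the defaults)."""
    d = spec.n_domains // 2  # 0-based ordinal of the middle domain
    first = 2 + d * spec.exons_per_domain
    return (first, first + spec.exons_per_domain - 1)


def make_toy_gene(spec: FixtureSpec) -> tuple[str, str, str]:
    """Generate (GFF3 text, FASTA text, domain TSV text) for a toy gene.

    Layout per transcript: one UTR+lead exon, ``n_domains`` domain units of
    ``exons_per_domain`` exons, one tail+stop+UTR exon, all on the + strand
    of a single synthetic chromosome with ``flank_intron_nt`` introns.
    """
    rng = random.Random(spec.seed)

    def codons(n):
        return "".join(rng.choice(_SENSE_CODONS) for _ in range(n))

    def bases(n):
        return "".join(rng.choice("ACGT") for _ in range(n))

    def intron():
        return "GT" + bases(spec.flank_intron_nt - 4) + "AG"

    # coding pieces, in translation order
    cds_chunks: list[str] = ["ATG" + codons(spec.lead_aa)]
    unit_lengths = _unit_exon_lengths(spec)
    for _ in range(spec.n_domains):
        unit = codons(spec.domain_aa + spec.linker_aa)
        off = 0
        for L in unit_lengths:
            cds_chunks.append(unit[off : off + L])
            off += L
    cds_chunks.append(codons(spec.tail_aa) + "TAA")

    # assemble chromosome: spacer, then exon/intron alternation;
    # exon 1 = 5'UTR + first cds chunk, last exon = last chunk + 3'UTR
    exon_seqs = list(cds_chunks)
    chrom = bases(60)
    records = []  # (index, g0, g1, c0, c1) 0-based half-open
    pos = len(chrom)
    pieces = [chrom]
    for i, chunk in enumerate(exon_seqs):
        if i == 0:
            utr = bases(spec.utr_nt)
            exon_seq = utr + chunk
            c0, c1 = pos + len(utr), pos + len(utr) + len(chunk)
        elif i == len(exon_seqs) - 1:
            utr = bases(spec.utr_nt)
            exon_seq = chunk + utr
            c0, c1 = pos, pos + len(chunk)
        else:
            exon_seq = chunk
            c0, c1 = pos, pos + len(chunk)
        records.append((i + 1, pos, pos + len(exon_seq), c0, c1))
        pieces.append(exon_seq)
        pos += len(exon_seq)
        if i < len(exon_seqs) - 1:
            iv = intron()
            pieces.append(iv)
            pos += len(iv)
    pieces.append(bases(60))
    chrom_seq = "".join(pieces)

    chrom_name = "chrSyn"
    gene_id = "TOY1"
    tx_id = "TOY1-tx1"
    g_start = records[0][1] + 1
    g_end = records[-1][2]
    lines = [
        "##gff-version 3",
        f"{chrom_name}\tdomainskip\tgene\t{g_start}\t{g_end}\t.\t+\t.\tID={gene_id}",
        f"{chrom_name}\tdomainskip\tmRNA\t{g_start}\t{g_end}\t.\t+\t.\tID={tx_id};Parent={gene_id}",
    ]
    for idx, g0, g1, c0, c1 in records:
        lines.append(
            f"{chrom_name}\tdomainskip\texon\t{g0 + 1}\t{g1}\t.\t+\t.\t"
            f"ID={tx_id}.exon{idx};Parent={tx_id}"
        )
    for idx, g0, g1, c0, c1 in records:
        phase = "."
        lines.append(
            f"{chrom_name}\tdomainskip\tCDS\t{c0 + 1}\t{c1}\t.\t+\t{phase}\t"
            f"ID={tx_id}.cds{idx};Parent={tx_id}"
        )
    gff3 = "\n".join(lines) + "\n"

    fasta_lines = [f">{chrom_name}"]
    for i in range(0, len(chrom_seq), 70):
        fasta_lines.append(chrom_seq[i : i + 70])
    fasta = "\n".join(fasta_lines) + "\n"

    dom_lines = ["name\tordinal\taa_start\taa_end"]
    unit_aa = spec.domain_aa + spec.linker_aa
    first_aa = 1 + 1 + spec.lead_aa  # after Met + lead residues
    for d in range(spec.n_domains):
        a = first_aa + d * unit_aa
        b = a + spec.domain_aa - 1
        dom_lines.append(f"FN3\t{d + 1}\t{a}\t{b}")
    domains_tsv = "\n".join(dom_lines) + "\n"

    return gff3, fasta, domains_tsv


def write_toy_gene(spec: FixtureSpec, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff3, fasta, domains = make_toy_gene(spec)
    paths = {
        "gff3": outdir / "toy_gene.gff3",
        "fasta": outdir / "toy_gene.fa",
        "domains": outdir / "toy_domains.tsv",
    }
    paths["gff3"].write_text(gff3)
    paths["fasta"].write_text(fasta)
    paths["domains"].write_text(domains)
    return paths


def load_toy_gene(spec: FixtureSpec) -> tuple[GeneModel, Path]:
    """Generate a toy gene and load it back through the standard loader."""
    tmp = Path(tempfile.mkdtemp(prefix="domainskip_fixture_"))
    paths = write_toy_gene(spec, tmp)
    return load_gene_model(paths["gff3"], paths["fasta"]), paths["domains"]


def make_variant_table(tx: Transcript, per_exon_lof_counts: dict[int, int],
                       freq_range: tuple[float, float] = (1e-6, 1e-4),
                       seed: int = 0) -> str:
    """A TSV of unique nonsense variants, ``count`` per requested exon.

    Positions are distinct CDS coordinates inside each exon's coding overlap;
    frequencies are uniform draws from ``freq_range``.
    """
    rng = random.Random(seed)
    rows = ["hgvs_c\tconsequence\tallele_frequency\tsource"]
    cds = tx.cds_seq
    for exon_idx in sorted(per_exon_lof_counts):
        count = per_exon_lof_counts[exon_idx]
        lo, hi = tx.exon_cds_interval(exon_idx)
        if hi - lo < count:
            raise ValueError(f"exon {exon_idx}: cannot place {count} unique variants")
        positions = rng.sample(range(lo, hi), count)
        for p in sorted(positions):
            ref = cds[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            af = rng.uniform(*freq_range)
            rows.append(f"c.{p + 1}{ref}>{alt}\tnonsense\t{af:.3e}\tsynthetic")
    return "\n".join(rows) + "\n"


def plant_ese(region: TargetRegion, matrix, offset: int) -> TargetRegion:
    """Write a matrix's maximal-score motif into the exon at ``offset``
    (exon-relative, 0-based).  Planting into the flank is an error."""
    consensus = matrix.consensus.replace("U", "T")
    ex_a, ex_b = region.exon_offset
    if offset < 0 or ex_a + offset + matrix.width > ex_b:
        raise ValueError("motif offset outside the exon")
    pos = ex_a + offset
    seq = region.sequence[:pos] + consensus + region.sequence[pos + matrix.width :]
    return TargetRegion(region.exon_index, seq, region.flank_nt, region.exon_offset)
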