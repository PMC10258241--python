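"""Gene models with exact coordinate arithmetic for exon skipping.

This module loads a gene annotation (GFF3 or a simple exon TSV) together with
genomic sequence and exposes a :class:`Transcript` that knows how to convert
between genomic, spliced-transcript, coding (c.) and protein (p.) coordinate
spaces.  Skip events -- the removal of a contiguous run of exons from the
mature transcript -- are applied at this level, and their protein-level
consequence (clean deletion, deletion-insertion via a hybrid junction codon,
or frameshift) is reported in HGVS-like p. notation.

Internally every interval is 0-based half-open on the + strand of the
reference; user-facing c./p. output is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "SkipEvent",
    "ProteinConsequence",
    "GeneModelError",
    "load_gene_model",
    "exon_phases",
    "apply_skip",
    "protein_consequence",
    "count_inframe_single_exons",
]


class GeneModelError(ValueError):
    """Raised when an annotation violates a structural invariant."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript.

    ``index`` is the per-transcript 5'->3' rank (1-based), i.e. the exon
    numbering used in clinical nomenclature.  ``genomic_interval`` is 0-based
    half-open on the + strand of the reference; ``tx_interval`` is the exon's
    footprint in spliced-transcript coordinates.  ``start_phase``/``end_phase``
    are the codon offsets at the exon's coding boundaries (0/1/2), or -1 for
    exons without CDS overlap.
    """

    index: int
    genomic_interval: tuple[int, int]
    tx_interval: tuple[int, int]
    cds_overlap_nt: int
    start_phase: int
    end_phase: int
    seq: str  # transcript (sense) orientation

    def __len__(self) -> int:
        return self.tx_interval[1] - self.tx_interval[0]

    @property
    def is_coding(self) -> bool:
        return self.cds_overlap_nt > 0


@dataclass(frozen=True)
class SkipEvent:
    """A contiguous run of exons removed from the mature transcript."""

    exon_indices: tuple[int, int]  # inclusive [i..j] in exon numbering
    kind: str = "intended"  # or "co_skip"

    def __post_init__(self):
        i, j = self.exon_indices
        if not (1 <= i <= j):
            raise GeneModelError(f"invalid exon range [{i}..{j}]")

    def indices(self) -> range:
        return range(self.exon_indices[0], self.exon_indices[1] + 1)


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level outcome of a skip event set.

    ``removed_aa_interval`` is the 1-based inclusive residue interval deleted
    (for delins: the replaced interval); ``junction_residue`` is the single
    amino acid encoded by the hybrid codon formed when the skip boundary
    splits codons (present iff the first skipped coding base is not at a
    codon boundary).
    """

    removed_aa_interval: tuple[int, int] | None
    junction_residue: str | None
    frame_preserving: bool
    hgvs_p: str


@dataclass
class Transcript:
    tx_id: str
    chromosome: str
    strand: str
    exons: list[Exon]
    spliced_seq: str
    cds_tx_interval: tuple[int, int]
    protein_seq: str
    chrom_seq: str | None = None  # reference chromosome (+ strand), if kept
    frame_intact: bool = True

    # -- basic accessors -------------------------------------------------
    def exon(self, index: int) -> Exon:
        for e in self.exons:
            if e.index == index:
                return e
        raise GeneModelError(f"{self.tx_id}: no exon with index {index}")

    @property
    def cds_seq(self) -> str:
        s, e = self.cds_tx_interval
        return self.spliced_seq[s:e]

    def __len__(self) -> int:
        return len(self.spliced_seq)

    # -- coordinate maps -------------------------------------------------
    def genomic_to_tx(self, gpos: int) -> int:
        """Map a 0-based + strand genomic position to a transcript offset."""
        for e in self.exons:
            g0, g1 = e.genomic_interval
            if g0 <= gpos < g1:
                off = gpos - g0 if self.strand == "+" else g1 - 1 - gpos
                return e.tx_interval[0] + off
        raise GeneModelError(f"{self.tx_id}: genomic position {gpos} is intronic/outside")

    def tx_to_genomic(self, tpos: int) -> int:
        for e in self.exons:
            t0, t1 = e.tx_interval
            if t0 <= tpos < t1:
                off = tpos - t0
                g0, g1 = e.genomic_interval
                return g0 + off if self.strand == "+" else g1 - 1 - off
        raise GeneModelError(f"{self.tx_id}: transcript position {tpos} out of range")

    def cds_pos_to_exon(self, cds_pos1: int) -> int:
        """Exon index containing coding position c.``cds_pos1`` (1-based)."""
        tpos = self.cds_tx_interval[0] + cds_pos1 - 1
        if not (0 < cds_pos1 <= self.cds_tx_interval[1] - self.cds_tx_interval[0]):
            raise GeneModelError(f"{self.tx_id}: c.{cds_pos1} outside CDS")
        for e in self.exons:
            if e.tx_interval[0] <= tpos < e.tx_interval[1]:
                return e.index
        raise GeneModelError(f"{self.tx_id}: c.{cds_pos1} unmapped")

    def exon_cds_interval(self, index: int) -> tuple[int, int]:
        """CDS-coordinate interval (0-based half-open) covered by an exon."""
        e = self.exon(index)
        cs, ce = self.cds_tx_interval
        lo = max(e.tx_interval[0], cs) - cs
        hi = min(e.tx_interval[1], ce) - cs
        return (lo, max(lo, hi))


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self):
        if not self.transcripts:
            raise GeneModelError(f"{self.gene_id}: gene has no transcripts")
        strands = {t.strand for t in self.transcripts}
        if strands != {self.strand}:
            raise GeneModelError(f"{self.gene_id}: transcripts on mixed strands")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_transcript(
    tx_id: str,
    chromosome: str,
    strand: str,
    chrom_seq: str,
    exon_records: list[tuple[int, int, int, int | None, int | None]],
    *,
    strict: bool = True,
    keep_chrom_seq: bool = True,
) -> Transcript:
    """Assemble a :class:`Transcript` from per-exon genomic records.

    ``exon_records`` holds ``(index, g_start, g_end, cds_g_start, cds_g_end)``
    tuples (0-based half-open, + strand; CDS columns None for non-coding
    exons).  With ``strict`` the standard invariants are enforced (CDS length
    divisible by 3, stop-terminated translation without internal stops);
    edited/skipped transcripts are built with ``strict=False`` so frameshift
    products can be represented.
    """
    if strand not in "+-":
        raise GeneModelError(f"{tx_id}: bad strand {strand!r}")
    recs = sorted(exon_records, key=lambda r: r[1], reverse=(strand == "-"))
    # overlap check in genomic order
    by_g = sorted(recs, key=lambda r: r[1])
    for a, b in zip(by_g, by_g[1:]):
        if a[2] > b[1]:
            raise GeneModelError(f"{tx_id}: overlapping exons at {a[1]}-{a[2]} / {b[1]}-{b[2]}")

    exons: list[Exon] = []
    tx_cursor = 0
    cds_cum = 0
    cds_tx_start = None
    cds_tx_end = None
    pieces = []
    for (idx, g0, g1, c0, c1) in recs:
        if not (0 <= g0 < g1 <= len(chrom_seq)):
            raise GeneModelError(f"{tx_id}: exon {idx} interval [{g0},{g1}) outside sequence")
        raw = chrom_seq[g0:g1]
        s = raw.upper() if strand == "+" else _revcomp(raw.upper())
        length = g1 - g0
        if c0 is not None and c1 is not None and c1 > c0:
            if not (g0 <= c0 < c1 <= g1):
                raise GeneModelError(f"{tx_id}: exon {idx} CDS [{c0},{c1}) outside exon")
            overlap = c1 - c0
            # transcript offset of the first coding base of this exon
            if strand == "+":
                cds_off = c0 - g0
            else:
                cds_off = g1 - c1
            start_phase = cds_cum % 3
            end_phase = (cds_cum + overlap) % 3
            if cds_tx_start is None:
                cds_tx_start = tx_cursor + cds_off
            cds_tx_end = tx_cursor + cds_off + overlap
            cds_cum += overlap
        else:
            overlap, start_phase, end_phase = 0, -1, -1
        exons.append(
            Exon(
                index=idx,
                genomic_interval=(g0, g1),
                tx_interval=(tx_cursor, tx_cursor + length),
                cds_overlap_nt=overlap,
                start_phase=start_phase,
                end_phase=end_phase,
                seq=s,
            )
        )
        pieces.append(s)
        tx_cursor += length

    spliced = "".join(pieces)
    if cds_tx_start is None:
        raise GeneModelError(f"{tx_id}: transcript has no CDS")
    cds = spliced[cds_tx_start:cds_tx_end]

    frame_intact = len(cds) % 3 == 0
    if strict and not frame_intact:
        raise GeneModelError(f"{tx_id}: CDS length {len(cds)} not divisible by 3")
    if strict:
        aa = str(Seq(cds).translate())
        if "*" in aa[:-1]:
            raise GeneModelError(f"{tx_id}: internal stop codon in CDS")
        protein = aa[:-1] if aa.endswith("*") else aa
    else:
        usable = cds[: (len(cds) // 3) * 3]
        aa = str(Seq(usable).translate()) if usable else ""
        protein = aa.split("*", 1)[0]

    return Transcript(
        tx_id=tx_id,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        spliced_seq=spliced,
        cds_tx_interval=(cds_tx_start, cds_tx_end),
        protein_seq=protein,
        chrom_seq=chrom_seq if keep_chrom_seq else None,
        frame_intact=frame_intact,
    )


def _load_fasta(path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise GeneModelError(f"no sequences in {path}")
    return seqs


def _load_gff3(path, seqs: dict[str, str]) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise GeneModelError(f"{path}: no gene feature")
    gene = genes[0]
    if gene.seqid not in seqs:
        raise GeneModelError(f"{path}: sequence {gene.seqid!r} missing from FASTA")
    chrom_seq = seqs[gene.seqid]
    transcripts = []
    for mrna in db.children(gene, featuretype="mRNA"):
        exon_feats = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not exon_feats:
            raise GeneModelError(f"{mrna.id}: mRNA without exons")
        if not cds_feats:
            raise GeneModelError(f"{mrna.id}: mRNA without CDS")
        records = []
        order = exon_feats if mrna.strand == "+" else exon_feats[::-1]
        for rank, ex in enumerate(order, start=1):
            g0, g1 = ex.start - 1, ex.end  # GFF3 1-based inclusive -> half-open
            c0 = c1 = None
            for cf in cds_feats:
                cg0, cg1 = cf.start - 1, cf.end
                if cg0 < g1 and g0 < cg1:
                    if c0 is not None:
                        raise GeneModelError(f"{mrna.id}: multiple CDS segments in one exon")
                    c0, c1 = max(g0, cg0), min(g1, cg1)
            records.append((rank, g0, g1, c0, c1))
        transcripts.append(
            build_transcript(mrna.id, gene.seqid, mrna.strand, chrom_seq, records)
        )
    return GeneModel(gene.id, gene.seqid, gene.strand, transcripts)


def _load_exon_tsv(path, seqs: dict[str, str]) -> GeneModel:
    """Simple exon-table dialect: tx_id, exon_index, chrom, start, end, strand,
    cds_start, cds_end -- 1-based inclusive genomic coordinates, empty CDS
    columns for non-coding exons."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"tx_id": str, "chrom": str})
    required = {"tx_id", "exon_index", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise GeneModelError(f"{path}: exon TSV missing columns {required - set(df.columns)}")
    transcripts = []
    for tx_id, grp in df.groupby("tx_id", sort=False):
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        if chrom not in seqs:
            raise GeneModelError(f"{path}: sequence {chrom!r} missing from FASTA")
        records = []
        for _, row in grp.iterrows():
            c0 = c1 = None
            if "cds_start" in grp.columns and not pd.isna(row.get("cds_start")):
                c0, c1 = int(row["cds_start"]) - 1, int(row["cds_end"])
            records.append((int(row["exon_index"]), int(row["start"]) - 1, int(row["end"]), c0, c1))
        transcripts.append(build_transcript(str(tx_id), chrom, strand, seqs[chrom], records))
    chrom = transcripts[0].chromosome
    strand = transcripts[0].strand
    return GeneModel(f"gene_of_{transcripts[0].tx_id}", chrom, strand, transcripts)


def load_gene_model(annotation_path, sequence_path) -> GeneModel:
    """Load a gene model from GFF3 (or exon TSV) plus FASTA.

    The annotation flavor is chosen by extension (``.gff``/``.gff3`` vs
    ``.tsv``).  Minus-strand features are reverse-complemented into transcript
    orientation; all structural invariants are validated at load time.
    """
    seqs = _load_fasta(sequence_path)
    p = str(annotation_path)
    if p.endswith((".gff", ".gff3")):
        return _load_gff3(p, seqs)
    return _load_exon_tsv(p, seqs)


# ---------------------------------------------------------------------------
# phases, skipping, consequences
# ---------------------------------------------------------------------------

def exon_phases(tx: Transcript) -> list[tuple[int, int]]:
    """(start_phase, end_phase) per exon, in transcript order."""
    return [(e.start_phase, e.end_phase) for e in tx.exons]


def _merge_event_indices(tx: Transcript, events) -> list[int]:
    skipped: set[int] = set()
    valid = {e.index for e in tx.exons}
    for ev in events:
        for i in ev.indices():
            if i not in valid:
                raise GeneModelError(f"{tx.tx_id}: skip references missing exon {i}")
            if i in skipped:
                raise GeneModelError(f"{tx.tx_id}: overlapping skip events at exon {i}")
            skipped.add(i)
    return sorted(skipped)


def apply_skip(tx: Transcript, events) -> Transcript:
    """Return the transcript with all exons named by ``events`` removed.

    Exon indices of retained exons are preserved (so isoform labels line up
    with the reference numbering).  Frameshifted products are represented
    with ``frame_intact=False`` and a translation truncated at the first
    premature stop.
    """
    skipped = set(_merge_event_indices(tx, events))
    retained = [e for e in tx.exons if e.index not in skipped]
    if not any(e.is_coding for e in retained):
        raise GeneModelError(f"{tx.tx_id}: skip removes every coding exon")
    if tx.chrom_seq is None:
        raise GeneModelError(f"{tx.tx_id}: chromosome sequence not retained; cannot re-splice")
    records = []
    cs, ce = tx.cds_tx_interval
    for e in retained:
        t0, t1 = e.tx_interval
        lo = max(t0, cs)
        hi = min(t1, ce)
        if hi > lo:
            ga = tx.tx_to_genomic(lo)
            gb = tx.tx_to_genomic(hi - 1)
            c0, c1 = (ga, gb + 1) if tx.strand == "+" else (gb, ga + 1)
        else:
            c0 = c1 = None
        records.append((e.index, *e.genomic_interval, c0, c1))
    return build_transcript(
        tx.tx_id, tx.chromosome, tx.strand, tx.chrom_seq, records, strict=False
    )


def _skipped_cds_span(tx: Transcript, skipped: list[int]) -> tuple[int, int, int]:
    """(cds_start, cds_end, total_cds_nt) of the skipped exons, CDS coords."""
    total = 0
    lo, hi = None, None
    for i in skipped:
        a, b = tx.exon_cds_interval(i)
        if b > a:
            total += b - a
            lo = a if lo is None else min(lo, a)
            hi = b if hi is None else max(hi, b)
    if lo is None:
        return (0, 0, 0)
    return (lo, hi, total)


def protein_consequence(tx: Transcript, events) -> ProteinConsequence:
    """Protein-level consequence of skipping a set of exon runs.

    For frame-preserving skips whose boundaries fall between codons a plain
    ``p.X<i>_X<j>del`` is emitted.  When the boundary splits codons, the
    hybrid junction codon is translated: if its residue equals the reference
    residue at either flank the event collapses to a plain deletion,
    otherwise ``delins<X>`` is reported (one novel junction residue).
    """
    skipped = _merge_event_indices(tx, events)
    if not skipped:
        return ProteinConsequence(None, None, True, "p.(=)")
    s, e, total = _skipped_cds_span(tx, skipped)
    if total == 0:
        return ProteinConsequence(None, None, True, "p.(=)")
    contiguous = skipped == list(range(skipped[0], skipped[-1] + 1)) and total == e - s
    frame_ok = total % 3 == 0
    prot = tx.protein_seq

    if not frame_ok:
        # first affected residue: translate edited CDS and find divergence
        edited = apply_skip(tx, events)
        pos = 1
        for a, b in zip(prot, edited.protein_seq):
            if a != b:
                break
            pos += 1
        ref_aa = prot[pos - 1] if pos <= len(prot) else "*"
        return ProteinConsequence(None, None, False, f"p.{ref_aa}{pos}fs")

    if not contiguous:
        # disjoint frame-preserving events: report only the frame status
        return ProteinConsequence(None, None, True, "p.?")

    phi = s % 3
    c1 = s // 3  # 0-based codon holding the first skipped base
    c2 = e // 3  # 0-based codon holding the first retained base after the skip
    if phi == 0:
        a, b = c1 + 1, c2  # clean codon-bounded deletion
        hgvs = f"p.{prot[a - 1]}{a}_{prot[b - 1]}{b}del" if a < b else f"p.{prot[a - 1]}{a}del"
        return ProteinConsequence((a, b), None, True, hgvs)

    cds = tx.cds_seq
    hybrid = cds[3 * c1 : s] + cds[e : 3 * c2 + 3]
    junction = str(Seq(hybrid).translate())
    a, b = c1 + 1, c2 + 1  # replaced residue interval, 1-based
    if junction == prot[a - 1]:
        return ProteinConsequence((a + 1, b), None, True,
                                  f"p.{prot[a]}{a + 1}_{prot[b - 1]}{b}del")
    if junction == prot[b - 1]:
        return ProteinConsequence((a, b - 1), None, True,
                                  f"p.{prot[a - 1]}{a}_{prot[b - 2]}{b - 1}del")
    return ProteinConsequence((a, b), junction, True,
                              f"p.{prot[a - 1]}{a}_{prot[b - 1]}{b}delins{junction}")


def removed_codon_interval(tx: Transcript, skipped: list[int]) -> tuple[int, int] | None:
    """Residues counted as *removed* for domain-impact purposes.

    A codon split across the skip boundary belongs to the removed interval
    only if at least 2 of its 3 nucleotides are removed; the surviving hybrid
    junction codon persists as a (possibly novel) residue and is not counted.
    Returns a 1-based inclusive interval or None.
    """
    s, e, total = _skipped_cds_span(tx, skipped)
    if total == 0 or total % 3 != 0:
        return None
    phi = s % 3
    c1, c2 = s // 3, e // 3
    if phi == 0:
        lo, hi = c1, c2 - 1
    elif phi == 1:  # codon c1 loses 2 nt -> removed; codon c2 loses 1 -> kept
        lo, hi = c1, c2 - 1
    else:  # phi == 2: codon c1 keeps 2 nt; codon c2 loses 2 -> removed
        lo, hi = c1 + 1, c2
    if hi < lo:
        return None
    return (lo + 1, hi + 1)


def count_inframe_single_exons(tx: Transcript) -> dict[str, int]:
    """How many internal coding exons are single-skippable in frame.

    Two definitions circulate: CDS-overlap length divisible by three, and
    start/end phase compatibility.  For fully coding internal exons they
    coincide; both are reported so callers need not guess.
    """
    coding = [e for e in tx.exons if e.is_coding]
    internal = coding[1:-1]
    div3 = sum(1 for e in internal if e.cds_overlap_nt % 3 == 0)
    phase = sum(1 for e in internal if e.start_phase == e.end_phase)
    return {"length_divisible_by_3": div3, "phase_compatible": phase}
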