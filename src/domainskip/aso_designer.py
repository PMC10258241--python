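"""Design, scoring and ranking of splice-modulating antisense oligonucleotides.

Candidate ASOs tile a target exon plus 50 nt of flanking intronic context and
fall into two mechanistic categories: ``boundary`` oligos that mask an
intron-exon junction (splice-site occlusion) and ``exonic_ese`` oligos that
cover exonic splicing enhancer motifs (SR-protein displacement).  Each window
is scored for length, GC fraction, duplex melting temperature (RNA:RNA
nearest-neighbor model), ESE coverage and self-structure, then filtered and
ranked.  For every lead a four-mismatch non-binding control oligo can be
generated, mirroring the mmASO controls used in splice-switching studies.

Design guideline defaults: length 17-23 nt, Tm >= 48 degC, GC 40-60%.  The
GC bound is deliberately a *soft* criterion (flagged, not excluded):
published, experimentally validated leads exist just below the 40% floor.
"""

from __future__ import annotations

import logging
import math
import random
import re
from dataclasses import dataclass, field, replace
from importlib import resources

from .gene_model import GeneModelError, Transcript

log = logging.getLogger(__name__)

__all__ = [
    "TargetRegion",
    "AsoCandidate",
    "MismatchControl",
    "EseMatrix",
    "DesignCriteria",
    "TmParameters",
    "build_target_region",
    "generate_windows",
    "gc_content",
    "melting_temperature",
    "load_ese_matrices",
    "ese_scan",
    "hairpin_score",
    "self_dimer_run",
    "score_candidates",
    "filter_and_rank",
    "check_design_guidelines",
    "design_mismatch_control",
    "published_aso_pairs",
    "validate_mismatch_pair",
    "design_asos",
]

_DNA_COMP = str.maketrans("ACGTU", "TGCAA")
_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_PURINES = {"A", "G"}


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def antisense(sense: str) -> str:
    """Reverse complement of a sense window, in RNA alphabet (5'->3')."""
    return "".join(_RNA_COMP[b] for b in reversed(as_rna(sense)))


# ---------------------------------------------------------------------------
# target regions and windows
# ---------------------------------------------------------------------------

@dataclass
class TargetRegion:
    """A target exon in pre-mRNA (sense) orientation with intronic flanks."""

    exon_index: int
    sequence: str               # sense strand, 5'->3'
    flank_nt: int
    exon_offset: tuple[int, int]  # exon footprint within ``sequence``

    @property
    def exon_seq(self) -> str:
        a, b = self.exon_offset
        return self.sequence[a:b]


def build_target_region(tx: Transcript, exon_index: int, flank_nt: int = 50) -> TargetRegion:
    """Exon plus up/downstream intronic flank, in transcript orientation.

    Flanks are truncated (with a warning) where the reference sequence ends.
    """
    e = tx.exon(exon_index)
    if tx.chrom_seq is None:
        raise GeneModelError(f"{tx.tx_id}: chromosome sequence not retained")
    g0, g1 = e.genomic_interval
    lo = max(0, g0 - flank_nt)
    hi = min(len(tx.chrom_seq), g1 + flank_nt)
    if lo > g0 - flank_nt or hi < g1 + flank_nt:
        log.warning("exon %d: flank truncated at reference boundary", exon_index)
    raw = tx.chrom_seq[lo:hi].upper()
    if tx.strand == "+":
        up = g0 - lo
        seq = raw
    else:
        up = hi - g1
        seq = _revcomp_dna(raw)
    exon_len = g1 - g0
    return TargetRegion(exon_index, seq, flank_nt, (up, up + exon_len))


@dataclass
class AsoCandidate:
    id: str
    target_exon: int
    window: tuple[int, int]     # on the TargetRegion, sense coordinates
    sequence: str               # antisense RNA, 5'->3'
    length_nt: int
    category: str               # boundary | exonic_ese
    gc_fraction: float = 0.0
    tm_c: float = 0.0
    ese_hits: int = 0
    hairpin_pairs: int = 0
    self_dimer_run: int = 0
    rank_score: float = 0.0
    chemistry: str = "2'-MOE, full PS backbone"


def generate_windows(region: TargetRegion, min_len: int = 17, max_len: int = 23) -> list[AsoCandidate]:
    """Every window of each allowed length that overlaps the exon.

    Windows crossing an intron-exon boundary are classed ``boundary``;
    windows lying within the exon (or touching only its edge from inside)
    are ``exonic_ese``.
    """
    n = len(region.sequence)
    if n < min_len:
        raise ValueError("target region shorter than the minimum ASO length")
    ex_a, ex_b = region.exon_offset
    out = []
    for L in range(min_len, max_len + 1):
        for a in range(0, n - L + 1):
            b = a + L
            if b <= ex_a or a >= ex_b:
                continue  # no exon overlap
            boundary = (a < ex_a < b) or (a < ex_b < b)
            sense = region.sequence[a:b]
            out.append(
                AsoCandidate(
                    id=f"ex{region.exon_index}_p{a}_L{L}",
                    target_exon=region.exon_index,
                    window=(a, b),
                    sequence=antisense(sense),
                    length_nt=L,
                    category="boundary" if boundary else "exonic_ese",
                )
            )
    return out


# ---------------------------------------------------------------------------
# sequence scores
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """(G+C)/length of a nucleotide string (ACGT/ACGU)."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if re.search(r"[^ACGTU]", s):
        raise ValueError(f"ambiguous bases in {seq!r}")
    return (s.count("G") + s.count("C")) / len(s)


# Nearest-neighbor free-energy parameters for RNA:RNA duplexes
# (Watson-Crick stacks; dH kcal/mol, dS cal/(mol*K); 1 M NaCl reference).
_NN_RNA: dict[str, tuple[float, float]] = {
    "AA": (-6.82, -19.0),
    "AU": (-9.38, -26.7),
    "UA": (-7.69, -20.5),
    "CU": (-10.48, -27.1),
    "CA": (-10.44, -26.9),
    "GU": (-11.40, -29.5),
    "GA": (-12.44, -32.5),
    "CG": (-10.64, -26.7),
    "GG": (-13.39, -32.7),
    "GC": (-14.88, -36.9),
}
_NN_INIT = (3.61, -1.5)
_NN_TERM_AU = (3.72, 10.5)
_R_GAS = 1.9872  # cal/(mol*K)


@dataclass(frozen=True)
class TmParameters:
    """Conditions for the duplex Tm calculation.

    ``oligo_conc_m`` is the total strand concentration (default 250 nM, a
    typical screening dose); ``na_m`` the monovalent salt molarity used for
    the Schildkraut-Lifson correction from the 1 M reference state.  Values
    are for an unmodified RNA:RNA duplex; backbone chemistry is not modeled.
    """

    oligo_conc_m: float = 250e-9
    na_m: float = 0.1

    def describe(self) -> str:
        return (
            f"RNA:RNA nearest-neighbor duplex Tm; CT={self.oligo_conc_m:.3g} M, "
            f"[Na+]={self.na_m:.3g} M (Schildkraut-Lifson corrected)"
        )


def _stack_params(dinuc: str) -> tuple[float, float]:
    if dinuc in _NN_RNA:
        return _NN_RNA[dinuc]
    rc = _RNA_COMP[dinuc[1]] + _RNA_COMP[dinuc[0]]
    return _NN_RNA[rc]


def melting_temperature(seq: str, params: TmParameters = TmParameters()) -> float:
    """Nearest-neighbor Tm (degC) of ``seq`` duplexed with its perfect RNA
    complement.

    Stack enthalpies/entropies are summed 5'->3' along the oligo; duplex
    initiation and per-terminal A:U penalties are applied, then the
    two-state Tm for a non-self-complementary duplex at total strand
    concentration CT: Tm = dH / (dS + R ln(CT/4)).
    """
    s = as_rna(seq)
    if len(s) < 8:
        raise ValueError("sequence too short for a meaningful duplex Tm")
    if re.search(r"[^ACGU]", s):
        raise ValueError(f"non-RNA alphabet in {seq!r}")
    dh, ds = _NN_INIT
    for i in range(len(s) - 1):
        h, sv = _stack_params(s[i : i + 2])
        dh += h
        ds += sv
    for end in (s[0], s[-1]):
        if end in ("A", "U"):
            dh += _NN_TERM_AU[0]
            ds += _NN_TERM_AU[1]
    tm_k = (dh * 1000.0) / (ds + _R_GAS * math.log(params.oligo_conc_m / 4.0))
    tm_c = tm_k - 273.15
    tm_c += 16.6 * math.log10(params.na_m / 1.0)
    return tm_c


# ---------------------------------------------------------------------------
# ESE scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EseMatrix:
    """Position weight matrix for an SR-protein exonic splicing enhancer."""

    factor: str
    width: int
    weights: tuple[tuple[float, float, float, float], ...]  # per pos: A,C,G,U
    threshold: float

    _IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

    def score(self, window: str) -> float:
        if len(window) != self.width:
            raise ValueError(f"{self.factor}: window length {len(window)} != {self.width}")
        return sum(self.weights[i][self._IDX[b]] for i, b in enumerate(window.upper()))

    @property
    def consensus(self) -> str:
        bases = "ACGU"
        return "".join(bases[row.index(max(row))] for row in self.weights)

    @property
    def max_score(self) -> float:
        return sum(max(row) for row in self.weights)


def _parse_matrix(text: str) -> EseMatrix:
    factor, threshold = None, None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"factor=(\S+)\s+threshold=([\d.]+)", line)
            if m:
                factor, threshold = m.group(1), float(m.group(2))
            continue
        if line.startswith("pos\t"):
            continue
        parts = line.split("\t")
        rows.append(tuple(float(x) for x in parts[1:5]))
    if factor is None or threshold is None:
        raise ValueError("matrix file lacks '# factor=... threshold=...' header")
    return EseMatrix(factor, len(rows), tuple(rows), threshold)


def load_ese_matrices(paths=None) -> list[EseMatrix]:
    """Load ESE matrices from TSV files (default: the bundled SRSF1/2/5/6 set)."""
    if paths is None:
        pkg = resources.files("domainskip").joinpath("data/ese_matrices")
        paths = sorted(p for p in pkg.iterdir() if p.name.endswith(".tsv"))
        return [_parse_matrix(p.read_text()) for p in paths]
    out = []
    for p in paths:
        with open(p) as fh:
            out.append(_parse_matrix(fh.read()))
    return out


@dataclass(frozen=True)
class EseHit:
    factor: str
    position: int  # region coordinate of the motif start
    width: int
    score: float


def ese_scan(region: TargetRegion, matrices: list[EseMatrix]) -> list[EseHit]:
    """All sense-strand motif windows inside the exon scoring >= threshold."""
    ex_a, ex_b = region.exon_offset
    exon = as_rna(region.sequence[ex_a:ex_b])
    hits = []
    for m in matrices:
        for off in range(0, len(exon) - m.width + 1):
            sc = m.score(exon[off : off + m.width])
            if sc >= m.threshold:
                hits.append(EseHit(m.factor, ex_a + off, m.width, sc))
    return sorted(hits, key=lambda h: (h.position, h.factor))


# ---------------------------------------------------------------------------
# self-structure
# ---------------------------------------------------------------------------

def hairpin_score(seq: str) -> int:
    """Maximum number of nested Watson-Crick + GU pairs (minimum loop 3).

    A maximum-pairing recursion over the single strand -- a deterministic,
    parameter-free proxy for hairpin propensity used only for ranking.
    """
    s = as_rna(seq)
    n = len(s)
    if n < 4:
        raise ValueError("sequence too short")
    best = [[0] * n for _ in range(n)]
    for span in range(4, n):  # j - i >= 4 enforces a loop of >= 3
        for i in range(0, n - span):
            j = i + span
            b = best[i][j - 1]
            for k in range(i, j - 3):
                pair = 1 if (s[k], s[j]) in _PAIRS else 0
                if pair:
                    left = best[i][k - 1] if k > i else 0
                    inner = best[k + 1][j - 1]
                    b = max(b, left + inner + 1)
            best[i][j] = b
    return best[0][n - 1]


def self_dimer_run(seq: str) -> int:
    """Longest contiguous antiparallel complementarity of a sequence with a
    second copy of itself (ungapped, Watson-Crick), i.e. the longest common
    substring of the sequence and its reverse complement."""
    s = as_rna(seq)
    rc = "".join(_RNA_COMP[b] for b in reversed(s))
    n = len(s)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if s[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


# ---------------------------------------------------------------------------
# filtering, ranking, controls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignCriteria:
    """Hard filters, soft penalties and ranking weights.

    Length and Tm are hard requirements; the GC range is a soft guideline
    (distance outside it is penalized in the rank score but never excludes a
    candidate).  Structure caps bound the tolerated hairpin pairing and
    self-dimer run before penalties apply.
    """

    min_len: int = 17
    max_len: int = 23
    tm_min: float = 48.0
    gc_range: tuple[float, float] = (0.40, 0.60)
    hairpin_cap: int = 4
    dimer_cap: int = 6
    w_boundary: float = 2.0
    w_ese: float = 1.0
    w_gc: float = 8.0
    w_structure: float = 0.5
    tm_params: TmParameters = TmParameters()


def _gc_excess(gc: float, lo: float, hi: float) -> float:
    if gc < lo:
        return lo - gc
    if gc > hi:
        return gc - hi
    return 0.0


def score_candidates(candidates: list[AsoCandidate], hits: list[EseHit],
                     criteria: DesignCriteria = DesignCriteria()) -> list[AsoCandidate]:
    """Compute all per-candidate scores (GC, Tm, ESE coverage, structure)."""
    for c in candidates:
        c.gc_fraction = gc_content(c.sequence)
        c.tm_c = melting_temperature(c.sequence, criteria.tm_params)
        a, b = c.window
        c.ese_hits = sum(1 for h in hits if h.position < b and h.position + h.width > a)
        c.hairpin_pairs = hairpin_score(c.sequence)
        c.self_dimer_run = self_dimer_run(c.sequence)
        lo, hi = criteria.gc_range
        c.rank_score = (
            criteria.w_boundary * (c.category == "boundary")
            + criteria.w_ese * c.ese_hits
            - criteria.w_gc * _gc_excess(c.gc_fraction, lo, hi)
            - criteria.w_structure * max(0, c.hairpin_pairs - criteria.hairpin_cap)
            - criteria.w_structure * max(0, c.self_dimer_run - criteria.dimer_cap)
        )
    return candidates


def check_design_guidelines(c: AsoCandidate, criteria: DesignCriteria = DesignCriteria()) -> list[str]:
    """Advisory flags for a scored candidate (soft criteria included)."""
    flags = []
    if not (criteria.min_len <= c.length_nt <= criteria.max_len):
        flags.append("length_out_of_range")
    if c.tm_c < criteria.tm_min:
        flags.append("tm_below_min")
    lo, hi = criteria.gc_range
    if c.gc_fraction < lo:
        flags.append("gc_below_range")
    elif c.gc_fraction > hi:
        flags.append("gc_above_range")
    if c.hairpin_pairs > criteria.hairpin_cap:
        flags.append("hairpin_above_cap")
    if c.self_dimer_run > criteria.dimer_cap:
        flags.append("self_dimer_above_cap")
    return flags


def filter_and_rank(candidates: list[AsoCandidate],
                    criteria: DesignCriteria = DesignCriteria()) -> list[AsoCandidate]:
    """Apply hard filters (length, Tm) and sort by rank score.

    Ties break deterministically by window start, then length, then id.
    GC outside the guideline range, hairpin pairing and self-dimer runs only
    penalize the rank score.
    """
    kept = [
        c
        for c in candidates
        if criteria.min_len <= c.length_nt <= criteria.max_len and c.tm_c >= criteria.tm_min
    ]
    if not kept:
        log.warning("no ASO candidate survives the hard filters")
    return sorted(kept, key=lambda c: (-c.rank_score, c.window[0], c.length_nt, c.id))


@dataclass(frozen=True)
class MismatchControl:
    """A non-binding control oligo: the parent ASO with exactly four interior
    mismatches relative to the target sequence."""

    parent_id: str
    sequence: str
    mismatch_positions: tuple[int, ...]  # 1-based, on the oligo


def _disruptive_substitution(base: str) -> str:
    """Replacement base that cannot pair (WC or GU wobble) with the target
    base complementary to ``base``, preferring a same-class purine/pyrimidine
    swap, then minimal GC change, then alphabetical order."""
    target = _RNA_COMP[base]
    options = [b for b in "ACGU" if b != base and (b, target) not in _PAIRS]
    same_class = [b for b in options if (b in _PURINES) == (base in _PURINES)]
    pool = same_class or options
    gc = {"G", "C"}

    def gc_change(b):
        return abs((b in gc) - (base in gc))

    return sorted(pool, key=lambda b: (gc_change(b), b))[0]


def design_mismatch_control(aso: AsoCandidate | str, n: int = 4, seed: int = 0,
                            parent_id: str | None = None) -> MismatchControl:
    """Generate a deterministic ``n``-mismatch control for an ASO.

    Mismatch positions are drawn (seeded) from the interior of the oligo --
    never the first three or last two bases, where a mismatch would least
    affect binding.  Each substituted base is chosen to disrupt pairing with
    the target maximally (see :func:`_disruptive_substitution`).
    """
    if isinstance(aso, AsoCandidate):
        seq, pid = aso.sequence, aso.id
    else:
        seq, pid = as_rna(aso), parent_id or "aso"
    L = len(seq)
    if L < 12:
        raise ValueError("oligo too short for a mismatch control")
    interior = list(range(4, L - 1))  # 1-based positions 4 .. L-2
    if n > len(interior):
        raise ValueError(f"cannot place {n} mismatches in {len(interior)} interior positions")
    rng = random.Random(seed)
    positions = tuple(sorted(rng.sample(interior, n)))
    bases = list(seq)
    for p in positions:
        bases[p - 1] = _disruptive_substitution(bases[p - 1])
    return MismatchControl(pid, "".join(bases), positions)


# ---------------------------------------------------------------------------
# published lead oligos (printed reference sequences)
# ---------------------------------------------------------------------------

def published_aso_pairs() -> list[dict]:
    """The five published USH2A exon 30/31/39/40 lead ASOs with their
    four-mismatch controls, as printed (5'->3' RNA)."""
    text = resources.files("domainskip").joinpath("data/published_asos.tsv").read_text()
    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        rows.append(dict(zip(header, ln.split("\t"))))
    for r in rows:
        r["target_exon"] = int(r["target_exon"])
    return rows


def validate_mismatch_pair(aso: str, mmaso: str) -> dict:
    """Positional comparison of an ASO and its mismatch control.

    Returns the mismatch positions (1-based), their count, and whether all
    mismatches are interior (not in the first 3 or last 2 positions).
    """
    a, m = as_rna(aso), as_rna(mmaso)
    if len(a) != len(m):
        raise ValueError("ASO and control differ in length")
    positions = tuple(i + 1 for i, (x, y) in enumerate(zip(a, m)) if x != y)
    interior = all(4 <= p <= len(a) - 2 for p in positions)
    return {
        "length": len(a),
        "mismatch_positions": positions,
        "n_mismatches": len(positions),
        "all_interior": interior,
    }


# ---------------------------------------------------------------------------
# one-call design entry point
# ---------------------------------------------------------------------------

def design_asos(tx: Transcript, exon_index: int, flank_nt: int = 50,
                criteria: DesignCriteria = DesignCriteria(),
                matrices: list[EseMatrix] | None = None,
                seed: int = 0) -> tuple[list[AsoCandidate], list[MismatchControl], list[EseHit]]:
    """Full single-exon design: windows -> scores -> filter/rank -> controls."""
    region = build_target_region(tx, exon_index, flank_nt)
    if matrices is None:
        matrices = load_ese_matrices()
    hits = ese_scan(region, matrices)
    cands = generate_windows(region, criteria.min_len, criteria.max_len)
    score_candidates(cands, hits, criteria)
    ranked = filter_and_rank(cands, criteria)
    controls = [design_mismatch_control(c, seed=seed) for c in ranked[:5]]
    return ranked, controls, hits
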