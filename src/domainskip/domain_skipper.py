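"""Domain-oriented enumeration and ranking of exon skip candidates.

The selection principle: find contiguous runs of internal exons whose summed
CDS length is divisible by three (so the reading frame survives) and whose
removal deletes one or more *complete* protein domains without cutting into a
neighbor.  Repetitive architectures such as the usherin FN3 array are the
intended use case -- removing exactly one repeat from a bead-on-a-string
protein is far less likely to destabilize the fold than creating a hybrid
domain.

Candidates are then ranked by how many affected individuals they could serve
(reach), using pathogenic-variant burden in the target exons as a secondary
key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gene_model import (
    GeneModelError,
    ProteinConsequence,
    SkipEvent,
    Transcript,
    protein_consequence,
    removed_codon_interval,
)

__all__ = [
    "ProteinDomain",
    "SkipCandidate",
    "load_domains",
    "map_domain_to_exons",
    "enumerate_skip_candidates",
    "classify_skip",
    "rank_candidates",
    "candidates_to_frame",
    "IMPACT_ORDER",
]

IMPACT_ORDER = [
    "clean_single_domain",
    "clean_multi_domain",
    "no_domain_removed",
    "partial_domain_disruption",
    "frameshift",
]


@dataclass(frozen=True)
class ProteinDomain:
    """A named amino-acid interval on the translated product (1-based incl.)."""

    name: str
    ordinal: int
    aa_interval: tuple[int, int]

    def __post_init__(self):
        a, b = self.aa_interval
        if not (1 <= a <= b):
            raise ValueError(f"{self.name}({self.ordinal}): bad interval [{a}..{b}]")

    @property
    def label(self) -> str:
        return f"{self.name}({self.ordinal})"


def load_domains(path, protein_length: int | None = None) -> list[ProteinDomain]:
    """Read a domain TSV (name, ordinal, aa_start, aa_end; 1-based inclusive).

    Overlapping domains, or domains outside the protein, are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    domains = [
        ProteinDomain(str(r["name"]), int(r["ordinal"]), (int(r["aa_start"]), int(r["aa_end"])))
        for _, r in df.iterrows()
    ]
    check_domains(domains, protein_length)
    return domains


def check_domains(domains: list[ProteinDomain], protein_length: int | None = None) -> None:
    ordered = sorted(domains, key=lambda d: d.aa_interval)
    for a, b in zip(ordered, ordered[1:]):
        if b.aa_interval[0] <= a.aa_interval[1]:
            raise ValueError(f"domains {a.label} and {b.label} overlap")
    if protein_length is not None:
        for d in domains:
            if d.aa_interval[1] > protein_length:
                raise ValueError(f"{d.label} extends past protein end ({protein_length} aa)")


@dataclass
class SkipCandidate:
    """A contiguous exon run evaluated as a skipping target."""

    exon_range: tuple[int, int]
    skipped_cds_nt: int
    frame_preserving: bool
    consequence: ProteinConsequence
    impact_class: str = "no_domain_removed"
    removed_domains: list[ProteinDomain] = field(default_factory=list)
    removed_aa_interval: tuple[int, int] | None = None  # whole-codon rule
    burden: int = 0
    reach: float = 0.0

    @property
    def n_exons(self) -> int:
        return self.exon_range[1] - self.exon_range[0] + 1

    @property
    def label(self) -> str:
        i, j = self.exon_range
        return f"Δex{i}" if i == j else f"Δex{i}-{j}"


# ---------------------------------------------------------------------------

def map_domain_to_exons(domain: ProteinDomain, tx: Transcript):
    """Minimal exon run whose CDS covers the domain's codons.

    Returns ``(exon_range, start_coincides, end_coincides)`` where the flags
    say whether the domain boundary falls exactly on an exon's coding
    boundary (the precondition for a perfectly clean excision).
    """
    a, b = domain.aa_interval
    cds_lo = 3 * (a - 1)          # first coding base of the domain
    cds_hi = 3 * b                # one past the last
    cds_len = tx.cds_tx_interval[1] - tx.cds_tx_interval[0]
    if cds_hi > cds_len:
        raise GeneModelError(f"{domain.label} outside CDS of {tx.tx_id}")
    hit = [
        e.index
        for e in tx.exons
        if e.is_coding
        and tx.exon_cds_interval(e.index)[0] < cds_hi
        and tx.exon_cds_interval(e.index)[1] > cds_lo
    ]
    first, last = min(hit), max(hit)
    start_ok = tx.exon_cds_interval(first)[0] == cds_lo
    end_ok = tx.exon_cds_interval(last)[1] == cds_hi
    return (first, last), start_ok, end_ok


def classify_skip(candidate: SkipCandidate, domains: list[ProteinDomain]) -> SkipCandidate:
    """Assign the domain-impact class of a candidate (in place, returned).

    clean_* requires that every annotated domain lies entirely inside or
    entirely outside the removed residue interval and that at least one lies
    inside; any domain cut by the boundary forces partial_domain_disruption.
    Inter-domain linker residues carry no annotation and never veto a clean
    call.  The removed interval follows the whole-codon rule: a boundary
    codon counts as removed only when it loses >= 2 of its 3 nucleotides.
    """
    if not candidate.frame_preserving:
        candidate.impact_class = "frameshift"
        candidate.removed_domains = []
        return candidate
    iv = candidate.removed_aa_interval
    if iv is None:
        candidate.impact_class = "no_domain_removed"
        candidate.removed_domains = []
        return candidate
    lo, hi = iv
    inside, partial = [], []
    for d in domains:
        a, b = d.aa_interval
        if a >= lo and b <= hi:
            inside.append(d)
        elif a <= hi and b >= lo:  # overlaps but not contained
            partial.append(d)
    if partial:
        candidate.impact_class = "partial_domain_disruption"
    elif len(inside) == 1:
        candidate.impact_class = "clean_single_domain"
    elif len(inside) > 1:
        candidate.impact_class = "clean_multi_domain"
    else:
        candidate.impact_class = "no_domain_removed"
    candidate.removed_domains = sorted(inside, key=lambda d: d.aa_interval)
    return candidate


def enumerate_skip_candidates(
    tx: Transcript,
    domains: list[ProteinDomain],
    max_exons: int = 2,
) -> list[SkipCandidate]:
    """All contiguous runs of <= ``max_exons`` internal coding exons.

    The first and last coding exons are never candidates (start/stop codon
    protection).  Each candidate carries its frame status, protein
    consequence and domain-impact class; burden and reach start at zero and
    are filled in by the variant layer.
    """
    if max_exons < 1:
        raise ValueError("max_exons must be >= 1")
    coding = [e.index for e in tx.exons if e.is_coding]
    internal = coding[1:-1]
    out: list[SkipCandidate] = []
    for k in range(1, max_exons + 1):
        for p in range(0, len(internal) - k + 1):
            i, j = internal[p], internal[p + k - 1]
            ev = [SkipEvent((i, j))]
            skipped = list(range(i, j + 1))
            total = sum(
                tx.exon_cds_interval(x)[1] - tx.exon_cds_interval(x)[0] for x in skipped
            )
            cons = protein_consequence(tx, ev)
            cand = SkipCandidate(
                exon_range=(i, j),
                skipped_cds_nt=total,
                frame_preserving=total % 3 == 0,
                consequence=cons,
                removed_aa_interval=removed_codon_interval(tx, skipped),
            )
            out.append(classify_skip(cand, domains))
    return out


def _rank_key(c: SkipCandidate):
    return (
        IMPACT_ORDER.index(c.impact_class),
        -c.reach,
        -c.burden,
        c.n_exons,
        c.exon_range,
    )


def rank_candidates(candidates: list[SkipCandidate]) -> list[SkipCandidate]:
    """Total order: impact class, then reach desc, burden desc, fewer exons,
    then exon range as the deterministic tie-break."""
    return sorted(candidates, key=_rank_key)


def candidates_to_frame(candidates: list[SkipCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "label": c.label,
                "exon_first": c.exon_range[0],
                "exon_last": c.exon_range[1],
                "skipped_cds_nt": c.skipped_cds_nt,
                "frame_preserving": c.frame_preserving,
                "impact_class": c.impact_class,
                "removed_domains": ";".join(d.label for d in c.removed_domains),
                "removed_aa_start": c.removed_aa_interval[0] if c.removed_aa_interval else "",
                "removed_aa_end": c.removed_aa_interval[1] if c.removed_aa_interval else "",
                "hgvs_p": c.consequence.hgvs_p,
                "burden": c.burden,
                "reach": c.reach,
            }
        )
    return pd.DataFrame(rows)
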