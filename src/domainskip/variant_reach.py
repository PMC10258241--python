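"""Pathogenic-variant burden per exon and treatable-population estimates.

An exon-skipping therapy restores the reading frame of any allele whose
loss-of-function variant sits inside the skipped exons.  Given per-variant
allele frequencies, the number of affected individuals who carry at least one
such allele (and are biallelically affected, assuming Hardy-Weinberg random
mating and full penetrance of biallelic loss of function) is

    eligible = N * a_t * (2 * a_g - a_t)

where ``a_t`` is the summed pathogenic allele frequency in the target exons,
``a_g`` the gene-wide summed pathogenic allele frequency and ``N`` the
population size.  The stricter count of patients with *both* alleles in the
target exons is ``N * a_t**2``; both numbers are reported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .gene_model import GeneModelError, Transcript

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "ReachEstimate",
    "LOF_CLASSES",
    "load_variants",
    "lof_burden",
    "estimate_reach",
    "annotate_candidates",
    "carrier_to_allele_frequency",
]

LOF_CLASSES = frozenset({"nonsense", "frameshift", "canonical_splice"})

# c.123A>G / c.123del / c.123_130dup ... ; an offset like c.123-5 or c.123+12
# marks an intronic position.
_C_POS = re.compile(r"^c\.(\d+)([+-]\d+)?")

_CSQ_MAP = {
    "stop_gained": "nonsense",
    "nonsense": "nonsense",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "splice_acceptor_variant": "canonical_splice",
    "splice_donor_variant": "canonical_splice",
    "canonical_splice": "canonical_splice",
    "missense": "missense",
    "missense_variant": "missense",
}


@dataclass(frozen=True)
class VariantRecord:
    hgvs_c: str
    exon_index: int | None  # None when intronic / unmappable
    consequence_class: str
    allele_frequency: float
    source: str = ""

    @property
    def intronic(self) -> bool:
        return self.exon_index is None


@dataclass(frozen=True)
class ReachEstimate:
    a_target: float
    a_gene: float
    population: int
    eligible_affected: float          # >= 1 target-exon allele, biallelic LoF
    target_biallelic: float           # both alleles in the target exons
    formula: str = "population * a_target * (2*a_gene - a_target)"


def _classify_consequence(raw: str) -> str:
    raw = str(raw).strip().lower()
    for key, val in _CSQ_MAP.items():
        if key in raw:
            return val
    return "other"


def _resolve_exon(tx: Transcript, hgvs_c: str) -> int | None:
    m = _C_POS.match(hgvs_c.strip())
    if not m:
        return None
    if m.group(2):  # intronic offset
        return None
    pos = int(m.group(1))
    try:
        return tx.cds_pos_to_exon(pos)
    except GeneModelError:
        return None


def load_variants(path, tx: Transcript) -> list[VariantRecord]:
    """Load a variant table (LOVD-style TSV, or VCF) against a transcript.

    TSV columns: hgvs_c, consequence, allele_frequency (optional ``source``).
    Each record is assigned to an exon from its c. position; intronic or
    unparseable positions are flagged (exon_index None) and malformed rows
    are skipped with a logged count.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return _load_vcf(p, tx)
    try:
        df = pd.read_csv(p, sep="\t")
    except Exception as exc:  # unreadable file is fatal
        raise GeneModelError(f"cannot read variant table {p}: {exc}") from exc
    records: list[VariantRecord] = []
    bad = 0
    for _, row in df.iterrows():
        try:
            hgvs = str(row["hgvs_c"])
            af = float(row["allele_frequency"])
            if not (0.0 <= af <= 1.0):
                raise ValueError("allele frequency outside [0,1]")
            records.append(
                VariantRecord(
                    hgvs_c=hgvs,
                    exon_index=_resolve_exon(tx, hgvs),
                    consequence_class=_classify_consequence(row["consequence"]),
                    allele_frequency=af,
                    source=str(row.get("source", "")),
                )
            )
        except (KeyError, ValueError, TypeError):
            bad += 1
    if bad:
        log.warning("%s: skipped %d malformed variant rows", p, bad)
    if not records:
        log.warning("%s: no usable variant records", p)
    return records


def _load_vcf(path: str, tx: Transcript) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    for v in VCF(path):
        try:
            gpos = v.POS - 1
            try:
                tpos = tx.genomic_to_tx(gpos)
                cs = tx.cds_tx_interval[0]
                cpos = tpos - cs + 1
                exon = tx.cds_pos_to_exon(cpos) if cpos >= 1 else None
            except GeneModelError:
                exon = None
            af = v.INFO.get("AF")
            af = float(af[0] if isinstance(af, tuple) else af) if af is not None else 0.0
            csq = v.INFO.get("CSQ") or v.INFO.get("Consequence") or ""
            hgvs = v.INFO.get("HGVSC") or f"c.?_{v.CHROM}:{v.POS}{v.REF}>{v.ALT[0]}"
            records.append(
                VariantRecord(str(hgvs), exon, _classify_consequence(str(csq)), af, "vcf")
            )
        except (ValueError, TypeError, IndexError):
            continue
    return records


def lof_burden(variants: list[VariantRecord], exon_range: tuple[int, int],
               classes: frozenset[str] = LOF_CLASSES) -> int:
    """Unique loss-of-function variants assigned to exons [i..j].

    Duplicated HGVS descriptions count once; intronic records and (by
    default) missense variants are excluded.
    """
    i, j = exon_range
    seen = {
        v.hgvs_c
        for v in variants
        if v.exon_index is not None and i <= v.exon_index <= j
        and v.consequence_class in classes
    }
    return len(seen)


def allele_frequency_sum(variants: list[VariantRecord], exon_range: tuple[int, int] | None,
                         classes: frozenset[str] = LOF_CLASSES) -> float:
    """Summed allele frequency of unique LoF variants in a range (or gene-wide)."""
    best: dict[str, float] = {}
    for v in variants:
        if v.exon_index is None or v.consequence_class not in classes:
            continue
        if exon_range is not None and not (exon_range[0] <= v.exon_index <= exon_range[1]):
            continue
        best[v.hgvs_c] = v.allele_frequency
    return float(sum(best.values()))


def estimate_reach(a_target: float, a_gene: float, population: int = 8_000_000_000) -> ReachEstimate:
    """Hardy-Weinberg estimate of the treatable affected population.

    Counts individuals with at least one pathogenic allele in the target
    exons whose other allele is also pathogenic (anywhere in the gene):
    ``N * (a_t^2 + 2*a_t*(a_g - a_t)) = N * a_t * (2*a_g - a_t)``.
    """
    if not (0.0 <= a_target <= a_gene <= 1.0):
        raise ValueError(f"need 0 <= a_target ({a_target}) <= a_gene ({a_gene}) <= 1")
    eligible = population * a_target * (2.0 * a_gene - a_target)
    return ReachEstimate(
        a_target=a_target,
        a_gene=a_gene,
        population=population,
        eligible_affected=eligible,
        target_biallelic=population * a_target * a_target,
    )


def carrier_to_allele_frequency(carrier_frequency: float) -> float:
    """Convert a carrier frequency to an allele frequency (rare-allele
    approximation: carriers ~ 2q, so q ~ carrier/2)."""
    if not (0.0 <= carrier_frequency <= 1.0):
        raise ValueError("carrier frequency outside [0,1]")
    return carrier_frequency / 2.0


def annotate_candidates(candidates, variants: list[VariantRecord],
                        population: int = 8_000_000_000):
    """Fill burden and reach on skip candidates from a variant list."""
    a_gene = allele_frequency_sum(variants, None)
    for c in candidates:
        c.burden = lof_burden(variants, c.exon_range)
        a_t = allele_frequency_sum(variants, c.exon_range)
        c.reach = estimate_reach(min(a_t, a_gene), a_gene, population).eligible_affected
    return candidates
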