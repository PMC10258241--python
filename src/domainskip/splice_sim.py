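"""Predicted RT-PCR readouts for minigene and endogenous splice assays.

Exon skipping experiments are read out as band patterns: an amplicon with
the target exons retained and shorter amplicons for each skipped isoform.
Given primer positions and the exon lengths between them, every isoform's
product size is exact arithmetic -- the in silico twin of a validation gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import pandas as pd

from .gene_model import SkipEvent, Transcript

__all__ = [
    "MinigeneConstruct",
    "AmpliconPrediction",
    "predict_minigene_products",
    "predict_rtpcr",
    "band_table",
    "parse_band_table",
    "isoform_label",
]


def isoform_label(skipped: list[int]) -> str:
    """Canonical isoform label: '+all' for the full product, else Δex<i>... ."""
    if not skipped:
        return "full"
    return "".join(f"Δex{i}" for i in sorted(skipped))


@dataclass(frozen=True)
class AmpliconPrediction:
    isoform_label: str
    product_nt: int
    frame_preserving: bool
    skipped_exons: tuple[int, ...] = ()


@dataclass
class MinigeneConstruct:
    """A minigene splice reporter: insert exons flanked by two heterologous
    (rhodopsin) exons carrying the RT-PCR primers.

    ``insert_exons`` maps exon index -> length (nt).  Primer offsets locate
    the amplified part of each flanking exon; the defaults amplify the whole
    flanking exons.
    """

    upstream_flank_exon_nt: int
    downstream_flank_exon_nt: int
    insert_exons: dict[int, int]
    primer_fwd_offset: int = 0          # 5' offset of fwd primer in upstream flank
    primer_rev_end: int | None = None   # 3' end of rev primer in downstream flank

    def __post_init__(self):
        if self.primer_rev_end is None:
            self.primer_rev_end = self.downstream_flank_exon_nt
        if not (0 <= self.primer_fwd_offset < self.upstream_flank_exon_nt):
            raise ValueError("forward primer outside the upstream flanking exon")
        if not (0 < self.primer_rev_end <= self.downstream_flank_exon_nt):
            raise ValueError("reverse primer outside the downstream flanking exon")

    @property
    def full_product_nt(self) -> int:
        return (
            (self.upstream_flank_exon_nt - self.primer_fwd_offset)
            + sum(self.insert_exons.values())
            + self.primer_rev_end
        )


def _merge_skip_sets(skip_sets) -> list[tuple[int, ...]]:
    out = []
    for events in skip_sets:
        idx: set[int] = set()
        for ev in events:
            idx.update(ev.indices())
        out.append(tuple(sorted(idx)))
    return out


def predict_minigene_products(construct: MinigeneConstruct, skip_sets) -> list[AmpliconPrediction]:
    """Amplicon sizes for the full product and each skipped isoform.

    ``skip_sets`` is a list of SkipEvent collections, each describing one
    isoform; the unskipped reference is always included first.  Skipping a
    flanking exon is impossible by construction and rejected.
    """
    preds = [AmpliconPrediction("full", construct.full_product_nt, True, ())]
    for skipped in _merge_skip_sets(skip_sets):
        missing = [i for i in skipped if i not in construct.insert_exons]
        if missing:
            raise ValueError(f"skip references non-insert exon(s) {missing}")
        removed = sum(construct.insert_exons[i] for i in skipped)
        preds.append(
            AmpliconPrediction(
                isoform_label(list(skipped)),
                construct.full_product_nt - removed,
                removed % 3 == 0,
                tuple(skipped),
            )
        )
    return preds


def predict_rtpcr(tx: Transcript, fwd_exon: int, rev_exon: int, skip_sets) -> list[AmpliconPrediction]:
    """Endogenous-transcript RT-PCR products for a set of skip isoforms.

    Primers sit in ``fwd_exon`` and ``rev_exon`` (defaults: exon centers);
    every skipped exon must lie strictly between them.  Frame preservation
    is judged on the summed skipped CDS nucleotides, matching the
    protein-consequence arithmetic of the gene model.
    """
    fe, re_ = tx.exon(fwd_exon), tx.exon(rev_exon)
    if fe.tx_interval[0] >= re_.tx_interval[0]:
        raise ValueError("forward primer exon must precede reverse primer exon")
    fwd_start = fe.tx_interval[0] + len(fe) // 2
    rev_end = re_.tx_interval[0] + len(re_) - len(re_) // 2
    full = rev_end - fwd_start
    preds = [AmpliconPrediction("full", full, True, ())]
    for skipped in _merge_skip_sets(skip_sets):
        for i in skipped:
            if not (fwd_exon < i < rev_exon):
                raise ValueError(f"skipped exon {i} not strictly between the primers")
        removed = sum(len(tx.exon(i)) for i in skipped)
        removed_cds = sum(
            tx.exon_cds_interval(i)[1] - tx.exon_cds_interval(i)[0] for i in skipped
        )
        preds.append(
            AmpliconPrediction(
                isoform_label(list(skipped)),
                full - removed,
                removed_cds % 3 == 0,
                tuple(skipped),
            )
        )
    return preds


def band_table(predictions: list[AmpliconPrediction]) -> pd.DataFrame:
    """Gel-style table: isoforms sorted by product size, duplicates merged.

    Isoforms with identical product sizes co-migrate and are reported as one
    band with a combined label.
    """
    if not predictions:
        raise ValueError("no predictions to tabulate")
    by_size: dict[int, list[AmpliconPrediction]] = {}
    for p in predictions:
        by_size.setdefault(p.product_nt, []).append(p)
    rows = []
    for size in sorted(by_size, reverse=True):
        group = by_size[size]
        rows.append(
            {
                "product_nt": size,
                "isoform": "/".join(p.isoform_label for p in group),
                "frame_preserving": all(p.frame_preserving for p in group),
            }
        )
    return pd.DataFrame(rows)


def parse_band_table(text: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text), sep="\t")
    df["frame_preserving"] = df["frame_preserving"].astype(bool)
    return df
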