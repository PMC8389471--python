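"""Detection of transposon-splice fusion reads and expression contrasts.

The SB transposon carries a splice donor (SD, driven by an internal CAG
promoter) and bidirectional splice acceptors (SA). In tumors its
insertions produce chimeric transcripts: RNA reads containing the
transposon SD spliced onto the start of a downstream exon (sense SD
fusions start an N-terminally truncated, promoter-driven transcript —
the activating pattern), or an exon end spliced into the transposon SA
(truncating, inactivating).

Detection here is exact-match at desk scale: a read is a fusion call
when it contains a configured SD/SA motif and the k bases flanking the
junction map uniquely to an annotated exon boundary of the supplied
transcriptome. Reads whose flank is ambiguous (multiple genes) or too
short are discarded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

__all__ = [
    "FusionRead",
    "detect_fusion_reads",
    "expression_contrast",
]


@dataclass(frozen=True)
class FusionRead:
    """A chimeric transposon-exon junction call from one RNA read."""

    read_id: str
    element: str  # splice_donor | splice_acceptor
    gene_id: str
    junction_exon: int  # 0-based exon index within the transcript
    orientation: str  # sense | antisense (strand of read carrying the junction)
    predicted_effect: str  # activating_truncation | inactivating_truncation


def _effect(element: str, orientation: str) -> str:
    # only a sense splice-donor fusion puts the CAG promoter upstream of
    # the downstream exons; every other combination truncates
    if element == "splice_donor" and orientation == "sense":
        return "activating_truncation"
    return "inactivating_truncation"


def _boundary_index(
    transcriptome: dict[str, list[str]], k: int
) -> tuple[dict[str, list], dict[str, list]]:
    """k-mer lookup of exon starts (SD targets) and exon ends (SA sources)."""
    starts: dict[str, list] = {}
    ends: dict[str, list] = {}
    for gene, exons in transcriptome.items():
        for i, exon in enumerate(exons):
            exon = exon.upper()
            if len(exon) < k:
                continue
            starts.setdefault(exon[:k], []).append((gene, i))
            ends.setdefault(exon[-k:], []).append((gene, i))
    return starts, ends


def detect_fusion_reads(
    reads: list[tuple[str, str]],
    motifs: dict[str, str],
    transcriptome: dict[str, list[str]],
    k: int = 20,
) -> tuple[list[FusionRead], pd.DataFrame]:
    """Scan RNA reads for transposon-exon splice junctions.

    Parameters
    ----------
    reads
        (read_id, sequence) pairs.
    motifs
        Junction motifs keyed 'splice_donor' and/or 'splice_acceptor';
        the terminal transposon sequence retained in the mature chimeric
        transcript.
    transcriptome
        gene_id -> ordered exon sequences (transcript orientation).
    k
        Exact-match flank length anchoring the junction to an exon
        boundary.

    Returns the fusion calls plus a DataFrame of discarded
    motif-containing reads with a ``reason`` column (ambiguous flank,
    short flank, unknown boundary).
    """
    if not motifs:
        raise ValueError("no junction motifs supplied")
    starts, ends = _boundary_index(transcriptome, k)
    calls: list[FusionRead] = []
    discards: list[dict] = []

    for read_id, seq in reads:
        seq = seq.upper()
        call = None
        reason = None
        for orientation, s in (("sense", seq), ("antisense", reverse_complement(seq))):
            for element, motif in motifs.items():
                motif = motif.upper()
                at = s.find(motif)
                if at < 0:
                    continue
                if element == "splice_donor":
                    flank = s[at + len(motif):]
                    key = flank[:k]
                    lookup = starts
                else:
                    flank = s[:at]
                    key = flank[-k:]
                    lookup = ends
                if len(key) < k:
                    reason = "flank_too_short"
                    continue
                hits = lookup.get(key, [])
                if len(hits) == 0:
                    reason = "no_exon_boundary_match"
                    continue
                genes = {g for g, _ in hits}
                if len(genes) > 1 or len(hits) > 1:
                    reason = "ambiguous_flank"
                    continue
                gene, exon_idx = hits[0]
                call = FusionRead(
                    read_id, element, gene, exon_idx, orientation,
                    _effect(element, orientation),
                )
                break
            if call:
                break
        if call:
            calls.append(call)
        elif reason:
            discards.append({"read_id": read_id, "reason": reason})
    return calls, pd.DataFrame(discards, columns=["read_id", "reason"])


def expression_contrast(
    expr: pd.DataFrame, insertion_status: pd.DataFrame, epsilon: float | None = None
) -> pd.DataFrame:
    """Contrast normalized expression by insertion status, per gene.

    ``expr`` is a specimen x gene normalized-expression matrix;
    ``insertion_status`` a binary specimen x gene matrix on the same
    specimen axis (genes may differ; only shared genes are contrasted).
    Returns per gene the carrier/non-carrier group means, the fold
    change mean_with / mean_without (a pseudo-count ``epsilon`` —
    default: the smallest positive value of ``expr`` — replaces a zero
    denominator), direction, and an ``untestable`` flag when either
    group is empty or the gene is all-zero.
    """
    if not expr.index.equals(insertion_status.index):
        insertion_status = insertion_status.reindex(expr.index)
        if insertion_status.isna().any().any():
            raise ValueError("expression and insertion matrices must share specimens")
    if epsilon is None:
        positive = expr.to_numpy()[expr.to_numpy() > 0]
        epsilon = float(positive.min()) if positive.size else 1.0
    rows = []
    for gene in expr.columns.intersection(insertion_status.columns):
        status = insertion_status[gene].astype(bool)
        vals = expr[gene]
        with_g = vals[status]
        without_g = vals[~status]
        untestable = len(with_g) < 1 or len(without_g) < 1 or (vals == 0).all()
        mean_with = float(with_g.mean()) if len(with_g) else np.nan
        mean_without = float(without_g.mean()) if len(without_g) else np.nan
        if untestable:
            fold = np.nan
        else:
            denom = mean_without if mean_without > 0 else epsilon
            fold = mean_with / denom
        rows.append(
            {
                "gene_id": gene,
                "mean_expr_with": mean_with,
                "mean_expr_without": mean_without,
                "fold_change": fold,
                "direction": (
                    "up" if fold > 1 else "down"
                ) if np.isfinite(fold) else pd.NA,
                "untestable": untestable,
            }
        )
    return pd.DataFrame(rows)
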