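"""Splice-boundary extraction, GT/AG filtering and sequence-logo matrices.

Internal exon boundaries are read from a GTF + genome FASTA: the donor
window spans the last 6 exonic and first 6 intronic bases at an exon 3'
end, the acceptor window the last 50 intronic and first 2 exonic bases at
an exon 5' start, both read 5'->3' in transcript orientation (minus-strand
features are reverse-complemented). Canonical boundaries (introns opening
GT and closing AG) feed a position-frequency matrix whose per-position
information content, IC_j = 2 + sum_b p_bj log2 p_bj bits, gives the
column heights of a sequence logo. A variant can be mapped to its offset
from the nearest splice junction ("donor+5" = fifth intronic base after
the exon).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._util import revcomp

DONOR_EXONIC, DONOR_INTRONIC = 6, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 50, 2
DONOR_LEN = DONOR_EXONIC + DONOR_INTRONIC  # 12
ACCEPTOR_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 52


@dataclass
class BoundarySequenceSet:
    """Equal-length boundary windows of one site class."""

    site_class: str  # donor | acceptor
    sequences: list[str]
    keys: list[tuple] = field(default_factory=list)
    n_skipped: int = 0

    def __post_init__(self):
        expected = DONOR_LEN if self.site_class == "donor" else ACCEPTOR_LEN
        for s in self.sequences:
            if len(s) != expected:
                raise ValueError(
                    f"{self.site_class} window length {len(s)} != {expected}"
                )

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class PositionWeightMatrix:
    """Per-position base frequencies and information content (bits)."""

    frequencies: pd.DataFrame  # positions x [A, C, G, T]
    information_content: np.ndarray
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out["IC"] = self.information_content
        return out


def _transcript_exons(db) -> dict[str, list]:
    by_tx: dict[str, list] = defaultdict(list)
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", ["?"])[0]
        by_tx[tid].append(exon)
    return by_tx


def extract_boundaries(
    gtf_path: str, fasta_path: str
) -> tuple[BoundarySequenceSet, BoundarySequenceSet]:
    """Donor and acceptor windows for every internal exon boundary.

    First and last exons contribute only their internal junction;
    single-exon transcripts contribute nothing. Boundaries shared by
    several transcripts are counted once (deduplicated by genomic key);
    windows running off a contig end are skipped and counted.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(str(fasta_path), sequence_always_upper=True)

    donor_seen: dict[tuple, str] = {}
    acceptor_seen: dict[tuple, str] = {}
    skipped_d = skipped_a = 0

    def fetch(chrom: str, start: int, end: int) -> Optional[str]:
        # 1-based inclusive
        if start < 1 or end > len(genome[chrom]):
            return None
        return genome[chrom][start - 1 : end].seq

    for tid, exons in _transcript_exons(db).items():
        exons = sorted(exons, key=lambda e: e.start)
        if len(exons) < 2:
            continue
        strand = exons[0].strand
        chrom = exons[0].seqid
        tx_order = exons if strand == "+" else exons[::-1]
        for up, down in zip(tx_order[:-1], tx_order[1:]):
            if strand == "+":
                dkey = (chrom, strand, "donor", up.end)
                akey = (chrom, strand, "acceptor", down.start)
                dseq = fetch(chrom, up.end - DONOR_EXONIC + 1, up.end + DONOR_INTRONIC)
                aseq = fetch(
                    chrom, down.start - ACCEPTOR_INTRONIC, down.start + ACCEPTOR_EXONIC - 1
                )
            else:
                dkey = (chrom, strand, "donor", up.start)
                akey = (chrom, strand, "acceptor", down.end)
                dseq = fetch(chrom, up.start - DONOR_INTRONIC, up.start + DONOR_EXONIC - 1)
                dseq = revcomp(dseq) if dseq is not None else None
                aseq = fetch(
                    chrom, down.end - ACCEPTOR_EXONIC + 1, down.end + ACCEPTOR_INTRONIC
                )
                aseq = revcomp(aseq) if aseq is not None else None
            if dseq is None:
                skipped_d += 1
            elif dkey not in donor_seen:
                donor_seen[dkey] = dseq
            if aseq is None:
                skipped_a += 1
            elif akey not in acceptor_seen:
                acceptor_seen[akey] = aseq

    donors = BoundarySequenceSet(
        "donor", list(donor_seen.values()), list(donor_seen.keys()), skipped_d
    )
    acceptors = BoundarySequenceSet(
        "acceptor", list(acceptor_seen.values()), list(acceptor_seen.keys()), skipped_a
    )
    return donors, acceptors


def filter_gt_ag(
    donors: BoundarySequenceSet, acceptors: BoundarySequenceSet
) -> tuple[BoundarySequenceSet, BoundarySequenceSet, dict[str, int]]:
    """Keep donors whose intron opens GT and acceptors whose intron closes AG."""
    kept_d = [
        (s, k)
        for s, k in zip(donors.sequences, donors.keys or [None] * len(donors))
        if s[DONOR_EXONIC : DONOR_EXONIC + 2] == "GT"
    ]
    kept_a = [
        (s, k)
        for s, k in zip(acceptors.sequences, acceptors.keys or [None] * len(acceptors))
        if s[ACCEPTOR_INTRONIC - 2 : ACCEPTOR_INTRONIC] == "AG"
    ]
    counts = {
        "donors_kept": len(kept_d),
        "donors_dropped": len(donors) - len(kept_d),
        "acceptors_kept": len(kept_a),
        "acceptors_dropped": len(acceptors) - len(kept_a),
    }
    return (
        BoundarySequenceSet("donor", [s for s, _ in kept_d], [k for _, k in kept_d]),
        BoundarySequenceSet("acceptor", [s for s, _ in kept_a], [k for _, k in kept_a]),
        counts,
    )


def build_pwm(seqs: BoundarySequenceSet) -> PositionWeightMatrix:
    """Position frequencies and information content of a boundary set.

    N bases are excluded from a position's denominator; IC uses the
    convention 0*log(0) = 0 and no small-sample correction.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    length = len(seqs.sequences[0])
    arr = np.frombuffer("".join(seqs.sequences).encode(), dtype=np.uint8).reshape(
        len(seqs), length
    )
    counts = np.zeros((length, 4), dtype=float)
    for j, base in enumerate(b"ACGT"):
        counts[:, j] = (arr == base).sum(axis=0)
    denom = counts.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("a position has no non-N bases")
    freqs = counts / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    positions = _position_labels(seqs.site_class, length)
    frame = pd.DataFrame(freqs, columns=list("ACGT"), index=positions)
    frame.index.name = "position"
    return PositionWeightMatrix(frame, ic, len(seqs))


def _position_labels(site_class: str, length: int) -> list[str]:
    if site_class == "donor" and length == DONOR_LEN:
        return [f"E{-i}" for i in range(DONOR_EXONIC, 0, -1)] + [
            f"+{i}" for i in range(1, DONOR_INTRONIC + 1)
        ]
    if site_class == "acceptor" and length == ACCEPTOR_LEN:
        return [f"-{i}" for i in range(ACCEPTOR_INTRONIC, 0, -1)] + [
            f"E{i}" for i in range(1, ACCEPTOR_EXONIC + 1)
        ]
    return [str(i + 1) for i in range(length)]


@dataclass(frozen=True)
class SpliceOffset:
    label: str
    distance: int

    def __str__(self) -> str:
        return self.label


def variant_splice_offset(
    variant_pos: int, exons: Sequence[tuple[int, int]], strand: str
) -> SpliceOffset:
    """Transcript-oriented offset of a variant from its nearest exon edge.

    "donor+k" marks the k-th intronic base after an exon's 3' end,
    "acceptor-k" the k-th intronic base before an exon's 5' start;
    variants inside an exon get "exonic" with the distance to the nearest
    edge, variants outside the transcript get "intergenic".
    """
    exons = sorted(tuple(e) for e in exons)
    for a, b in exons:
        if a <= variant_pos <= b:
            return SpliceOffset("exonic", min(variant_pos - a, b - variant_pos))
    for (a1, b1), (a2, b2) in zip(exons[:-1], exons[1:]):
        if b1 < variant_pos < a2:
            if strand == "+":
                d_donor = variant_pos - b1
                d_acceptor = a2 - variant_pos
            else:
                d_donor = a2 - variant_pos
                d_acceptor = variant_pos - b1
            if d_donor <= d_acceptor:
                return SpliceOffset(f"donor+{d_donor}", d_donor)
            return SpliceOffset(f"acceptor-{d_acceptor}", d_acceptor)
    return SpliceOffset("intergenic", 0)


def plot_logo(pwm: PositionWeightMatrix, path: str) -> None:
    """IC-scaled stacked-bar logo (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    f = pwm.frequencies
    heights = f.mul(pwm.information_content, axis=0)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(f)), 2.5))
    bottom = np.zeros(len(f))
    x = np.arange(len(f))
    for base in "ACGT":
        h = heights[base].to_numpy()
        ax.bar(x, h, bottom=bottom, color=colors[base], width=0.85, label=base)
        bottom += h
    ax.set_xticks(x)
    ax.set_xticklabels(f.index, rotation=90, fontsize=6)
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.legend(ncol=4, fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
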