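"""Candidate-variant prioritization within risk-haplotype regions.

Given annotated variants (consequence and deleteriousness labels are
consumed as input, not computed) inside a risk region +/- flank, apply the
four selection criteria for a recessive lethal candidate:

  C1  no homozygotes among the genotyped animals;
  C2  variant allele frequency approximately equal to the risk-haplotype
      frequency;
  C3  annotated as deleterious;
  C4  detected in the haplotype carriers.

plus a veto from validation genotyping of an independent healthy cohort
(any surviving risk-allele homozygote disproves complete recessive
lethality), and haplotype-variant linkage disequilibrium r^2.

Splice-region variants are deliberately NOT in the default deleterious
set; a variant passing C1, C2 and C4 but failing C3 is flagged as a
near-miss, since a splice-donor-adjacent substitution can be causal while
annotators call it benign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scan import PhasedPanel, RiskRegion
from .stats import GenotypeCounts, allele_frequency, hwe_expected
from ._util import round_half_away

#: Consequences accepted as deleterious regardless of prediction scores.
DELETERIOUS_CONSEQUENCES = {
    "stop_gained",
    "stop_lost",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "inframe_insertion",
    "inframe_deletion",
    "exon_deletion",  # CNV deletions consumed as pseudo-biallelic markers
}

#: Consequences deleterious only with a damaging prediction label.
PREDICTION_GATED_CONSEQUENCES = {"missense_variant"}


@dataclass
class AnnotatedVariant:
    """One site with per-sample genotypes and consumed annotation labels.

    Genotypes are risk-allele dosages 0/1/2, -1 for missing, aligned to
    the panel sample order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    prediction: Optional[str]
    score: Optional[float]
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:g.{self.pos}{self.ref}>{self.alt}"

    def genotype_counts(self) -> GenotypeCounts:
        gt = self.genotypes[self.genotypes >= 0]
        return GenotypeCounts(
            int((gt == 0).sum()), int((gt == 1).sum()), int((gt == 2).sum())
        )


@dataclass(frozen=True)
class CarrierSet:
    """Samples flagged as carriers of one risk haplotype."""

    haplotype_id: str
    sample_ids: tuple[str, ...]


@dataclass
class CriteriaResult:
    c1_no_homozygotes: bool
    c2_frequency_match: bool
    c3_deleterious: bool
    c4_in_carriers: bool
    allele_freq: float
    carrier_fraction: float

    @property
    def passes(self) -> bool:
        return (
            self.c1_no_homozygotes
            and self.c2_frequency_match
            and self.c3_deleterious
            and self.c4_in_carriers
        )

    @property
    def near_miss(self) -> bool:
        """Passes everything except the deleteriousness annotation."""
        return (
            self.c1_no_homozygotes
            and self.c2_frequency_match
            and self.c4_in_carriers
            and not self.c3_deleterious
        )

    def as_vector(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.c1_no_homozygotes,
            self.c2_frequency_match,
            self.c3_deleterious,
            self.c4_in_carriers,
        )


def search_interval(region: RiskRegion, flank: int = 6_000_000) -> tuple[str, int, int]:
    """Candidate search interval: region +/- flank, clipped at position 1.

    Causal variants can lie megabases outside the haplotype span while in
    LD with it, so the search deliberately extends well beyond the region.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return region.chromosome, max(1, region.start_pos - flank), region.end_pos + flank


def is_deleterious(
    variant: AnnotatedVariant,
    deleterious_consequences: set[str] = DELETERIOUS_CONSEQUENCES,
    prediction_gated: set[str] = PREDICTION_GATED_CONSEQUENCES,
) -> bool:
    if variant.consequence in deleterious_consequences:
        return True
    if variant.consequence in prediction_gated:
        return (variant.prediction or "").lower() == "deleterious"
    return False


def apply_criteria(
    variant: AnnotatedVariant,
    hap_freq: float,
    carriers: CarrierSet,
    samples: Sequence[str],
    freq_tol: float = 0.05,
    min_carrier_fraction: float = 1.0,
    deleterious_consequences: set[str] = DELETERIOUS_CONSEQUENCES,
) -> CriteriaResult:
    """Evaluate the four candidate-selection criteria for one variant.

    ``freq_tol`` is an absolute tolerance on |variant freq - haplotype
    freq| (criterion 2 is only "approximately equal" in practice, and
    observed causal variants can be markedly commoner than the haplotype
    when they predate it). ``min_carrier_fraction`` is the fraction of
    genotyped haplotype carriers that must carry the variant allele.
    """
    if not 0.0 < hap_freq < 1.0:
        raise ValueError("hap_freq must be in (0, 1)")
    gt = variant.genotypes
    if (gt >= 0).sum() == 0:
        raise ValueError("all genotypes missing")
    counts = variant.genotype_counts()
    freq = (counts.n_rv + 2 * counts.n_vv) / (2 * counts.total)
    sample_index = {s: i for i, s in enumerate(samples)}
    idx = [sample_index[s] for s in carriers.sample_ids if s in sample_index]
    cgt = gt[idx] if idx else np.empty(0, dtype=np.int8)
    cgt = cgt[cgt >= 0]
    carrier_fraction = float((cgt >= 1).mean()) if cgt.size else 0.0
    return CriteriaResult(
        c1_no_homozygotes=counts.n_vv == 0,
        c2_frequency_match=abs(freq - hap_freq) <= freq_tol,
        c3_deleterious=is_deleterious(
            variant, deleterious_consequences=deleterious_consequences
        ),
        c4_in_carriers=cgt.size > 0 and carrier_fraction >= min_carrier_fraction,
        allele_freq=freq,
        carrier_fraction=carrier_fraction,
    )


def filter_candidates(
    variants: Sequence[AnnotatedVariant],
    hap_freq: float,
    carriers: CarrierSet,
    samples: Sequence[str],
    **kwargs,
) -> list[AnnotatedVariant]:
    """Variants passing all four criteria."""
    return [
        v
        for v in variants
        if apply_criteria(v, hap_freq, carriers, samples, **kwargs).passes
    ]


def survivor_homozygote_veto(validation_counts: GenotypeCounts) -> bool:
    """True (reject the candidate) iff healthy adults homozygous for the
    risk allele exist in an independent validation cohort.

    A surviving homozygote disproves complete recessive lethality (or
    flags incomplete penetrance)."""
    if validation_counts.total == 0:
        raise ValueError("empty validation cohort")
    return validation_counts.n_vv > 0


def ld_r2(a, b, mode: str = "auto") -> float:
    """Squared correlation between two loci.

    Phased mode (0/1 allele vectors over chromosomes):
    r^2 = D^2 / (pA(1-pA) pB(1-pB)) with D = pAB - pA*pB from haplotype
    counts. Genotype mode (0/1/2 dosage vectors over samples): squared
    Pearson correlation. Haplotype-vs-variant LD is computed by coding
    haplotype carriage as a pseudo-marker (see haplotype_dosage).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic input")
    if mode == "auto":
        mode = "phased" if set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0} else "genotype"
    if mode == "phased":
        pa, pb = a.mean(), b.mean()
        pab = (a * b).mean()
        d = pab - pa * pb
        return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))
    if mode == "genotype":
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    raise ValueError("mode must be auto|phased|genotype")


def region_carriers(panel: PhasedPanel, region: RiskRegion) -> CarrierSet:
    """Carriers of the region's top-window risk haplotype in a panel."""
    if region.top_window is None:
        raise ValueError("region lacks its top window; rerun scan/merge_regions")
    w = region.top_window
    lo, _ = panel.chrom_slice(region.chromosome)
    target = np.frombuffer(w.hap.encode(), dtype=np.uint8) - ord("0")
    sub = panel.haplotypes[:, lo + w.start_marker : lo + w.end_marker]
    match = (sub == target).all(axis=1)
    per_sample = match[0::2].astype(int) + match[1::2].astype(int)
    ids = tuple(
        s for s, c in zip(panel.samples, per_sample) if c >= 1
    )
    return CarrierSet(haplotype_id=region.id, sample_ids=ids)


def haplotype_dosage(panel: PhasedPanel, region: RiskRegion) -> np.ndarray:
    """Per-sample copy number (0/1/2) of the region's risk haplotype."""
    if region.top_window is None:
        raise ValueError("region lacks its top window; rerun scan/merge_regions")
    w = region.top_window
    lo, _ = panel.chrom_slice(region.chromosome)
    target = np.frombuffer(w.hap.encode(), dtype=np.uint8) - ord("0")
    sub = panel.haplotypes[:, lo + w.start_marker : lo + w.end_marker]
    match = (sub == target).all(axis=1)
    return match[0::2].astype(np.int8) + match[1::2].astype(np.int8)


def build_candidate_report(
    variants: Sequence[AnnotatedVariant],
    region: RiskRegion,
    carriers: CarrierSet,
    panel: Optional[PhasedPanel] = None,
    hap_freq: Optional[float] = None,
    flank: int = 6_000_000,
    freq_tol: float = 0.05,
    min_carrier_fraction: float = 1.0,
) -> pd.DataFrame:
    """One row per variant inside the search interval, with observed and
    HWE-expected genotype triples ("rr/rv/vv" strings), allele frequency,
    the criteria vector, carrier concordance and LD r^2 against the risk
    haplotype; sorted by pass/fail then r^2. Filtering only annotates —
    no variant inside the interval is dropped.
    """
    hap_freq = region.q if hap_freq is None else hap_freq
    chrom, lo_bp, hi_bp = search_interval(region, flank)
    dosage = None
    if panel is not None:
        try:
            dosage = haplotype_dosage(panel, region)
        except ValueError:
            dosage = None
    samples = panel.samples if panel is not None else []
    rows = []
    for v in variants:
        if v.chrom != chrom or not (lo_bp <= v.pos <= hi_bp):
            continue
        crit = apply_criteria(
            v, hap_freq, carriers, samples,
            freq_tol=freq_tol, min_carrier_fraction=min_carrier_fraction,
        )
        counts = v.genotype_counts()
        _, exp_rounded = hwe_expected(counts)
        r2 = np.nan
        if dosage is not None:
            gt = v.genotypes.astype(float)
            gt[gt < 0] = np.nan
            ok = ~np.isnan(gt)
            try:
                r2 = ld_r2(gt[ok], dosage[ok], mode="genotype")
            except ValueError:
                r2 = np.nan
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "gene": v.gene,
                "consequence": v.consequence,
                "prediction": v.prediction,
                "observed": "/".join(map(str, counts.as_tuple())),
                "expected": "/".join(map(str, exp_rounded)),
                "risk_allele_freq": f"{round_half_away(crit.allele_freq, 3):.3f}",
                "c1_no_homozygotes": crit.c1_no_homozygotes,
                "c2_frequency_match": crit.c2_frequency_match,
                "c3_deleterious": crit.c3_deleterious,
                "c4_in_carriers": crit.c4_in_carriers,
                "passes": crit.passes,
                "near_miss": crit.near_miss,
                "carrier_concordance": crit.carrier_fraction,
                "ld_r2": r2,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(
            ["passes", "ld_r2"], ascending=[False, False], na_position="last"
        ).reset_index(drop=True)
    return frame
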