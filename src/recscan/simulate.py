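"""Forward simulation of every input the pipeline consumes, with known truth.

The generator emulates a livestock SNP-array cohort in which a recessive
deleterious haplotype segregates: a census of N adult survivors whose
diplotypes were drawn by random mating from a founder haplotype pool, with
individuals homozygous for a lethal planted haplotype removed (and the
census refilled) before genotyping; AI mating records in which
carrier x carrier matings suffer excess early returns; embryo genotypes
from het x het matings with recessive loss; annotated variant tables
containing one causal variant riding the risk haplotype plus decoys that
each violate exactly one selection criterion; and a toy genome + GTF whose
introns obey the GT/AG rule with controllable fidelity.

Background markers are drawn independently (no background LD), which makes
the null behavior of the downstream scan interpretable; every stochastic
operation derives an independent substream from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .prioritize import AnnotatedVariant, CarrierSet, region_carriers
from .scan import PhasedPanel, RiskRegion
from .stats import RETURN_BINS, RETURN_BIN_LABELS, GenotypeCounts

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedHaplotype:
    """Ground-truth risk haplotype planted into the founder pool."""

    chromosome: str
    marker_span: tuple[int, int]  # half-open marker-index interval within chromosome
    allele_string: str
    target_frequency: float
    lethality: str = "embryonic"  # embryonic | postnatal | none
    penetrance: float = 1.0
    name: str = ""

    def __post_init__(self):
        if not 0.0 < self.target_frequency < 0.5:
            raise ValueError("target_frequency must be in (0, 0.5)")
        if len(self.allele_string) != self.marker_span[1] - self.marker_span[0]:
            raise ValueError("allele_string length must equal span length")
        if set(self.allele_string) - {"0", "1"}:
            raise ValueError("allele_string must be over {0,1}")
        if self.lethality not in {"embryonic", "postnatal", "none"}:
            raise ValueError("lethality must be embryonic|postnatal|none")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings; the seed fully determines the output."""

    n_samples: int
    n_chromosomes: int = 5
    markers_per_chromosome: int = 2000
    marker_spacing: int = 80_000  # 32k-array density on a ~2.6 Gb genome
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    risk_haplotypes: tuple[PlantedHaplotype, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if self.n_chromosomes <= 0 or self.markers_per_chromosome <= 0:
            raise ValueError("need at least one chromosome and one marker")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie in (0, 1)")
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for h in self.risk_haplotypes:
            if str(h.chromosome) not in chroms:
                raise ValueError(f"planted chromosome {h.chromosome!r} not in panel")
            s, e = h.marker_span
            if not (0 <= s < e <= self.markers_per_chromosome):
                raise ValueError("planted span outside chromosome")


@dataclass
class SimTruth:
    """Realized state of one planted haplotype in the census panel."""

    haplotype: PlantedHaplotype
    census_copies: int
    census_frequency: float
    carrier_samples: list[str]
    homozygote_samples: list[str]
    start_pos: int
    end_pos: int


def _default_hap_name(i: int, h: PlantedHaplotype) -> str:
    return h.name or f"planted_{i + 1}_chr{h.chromosome}"


def simulate_panel(config: SimConfig) -> tuple[PhasedPanel, list[SimTruth]]:
    """Draw a census of N diplotypes by random mating from a founder pool.

    Each founder haplotype carries a planted allele string over its span
    with probability target_frequency (background haplotypes that happen to
    match the string are redrawn, so carriage flags are exact). Individuals
    homozygous for a lethal planted haplotype are rejected with probability
    ``penetrance`` and redrawn, keeping the census size fixed at N — the
    panel is a census of survivors, so it shows a homozygote deficit at
    the planted span and Hardy-Weinberg proportions elsewhere.
    """
    n = config.n_samples
    n2 = 2 * n
    m = config.markers_per_chromosome
    ss = np.random.SeedSequence(config.seed)
    chrom_seeds = ss.spawn(config.n_chromosomes)

    planted_by_chrom: dict[str, list[tuple[int, PlantedHaplotype]]] = {}
    for i, h in enumerate(config.risk_haplotypes):
        planted_by_chrom.setdefault(str(h.chromosome), []).append((i, h))

    hap_blocks = []
    flags_global: dict[int, np.ndarray] = {}
    markers_rows = []
    samples = [f"S{i + 1:05d}" for i in range(n)]

    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        rng = np.random.default_rng(chrom_seeds[c])
        lo, hi = config.allele_freq_range
        freqs = rng.uniform(lo, hi, m)
        planted = planted_by_chrom.get(chrom, [])
        strings = {
            i: np.frombuffer(h.allele_string.encode(), dtype=np.uint8) - ord("0")
            for i, h in planted
        }

        def draw(nrows: int):
            rows = (rng.random((nrows, m)) < freqs).astype(np.uint8)
            flg = {}
            for i, h in planted:
                s, e = h.marker_span
                target = strings[i]
                is_p = rng.random(nrows) < h.target_frequency
                rows[is_p, s:e] = target
                # background haplotypes must not coincide with the planted
                # string, so carriage flags are exact
                bg = np.flatnonzero(~is_p)
                while bg.size:
                    match = bg[(rows[bg, s:e] == target).all(axis=1)]
                    if not match.size:
                        break
                    rows[np.ix_(match, np.arange(s, e))] = (
                        rng.random((match.size, e - s)) < freqs[s:e]
                    ).astype(np.uint8)
                    bg = match
                flg[i] = is_p
            return rows, flg

        rows, flg = draw(n2)
        lethal = [(i, h) for i, h in planted if h.lethality != "none"]
        while lethal:
            reject = np.zeros(n, dtype=bool)
            for i, h in lethal:
                hom = flg[i][0::2] & flg[i][1::2]
                reject |= hom & (rng.random(n) < h.penetrance)
            idx = np.flatnonzero(reject)
            if not idx.size:
                break
            rows2, flg2 = draw(2 * idx.size)
            chrom_rows = np.empty(2 * idx.size, dtype=np.intp)
            chrom_rows[0::2] = 2 * idx
            chrom_rows[1::2] = 2 * idx + 1
            rows[chrom_rows] = rows2
            for i, _ in planted:
                flg[i][chrom_rows] = flg2[i]
        hap_blocks.append(rows)
        for i, _ in planted:
            flags_global[i] = flg[i]
        pos = config.marker_spacing * np.arange(1, m + 1)
        for j in range(m):
            markers_rows.append((chrom, int(pos[j]), f"chr{chrom}_m{j + 1}"))

    markers = pd.DataFrame(markers_rows, columns=["chrom", "pos", "id"])
    panel = PhasedPanel(markers, samples, np.hstack(hap_blocks))

    truth: list[SimTruth] = []
    for i, h in enumerate(config.risk_haplotypes):
        flg = flags_global[i]
        per_sample = flg[0::2].astype(int) + flg[1::2].astype(int)
        carriers = [samples[j] for j in np.flatnonzero(per_sample >= 1)]
        homs = [samples[j] for j in np.flatnonzero(per_sample == 2)]
        s, e = h.marker_span
        truth.append(
            SimTruth(
                haplotype=replace(h, name=_default_hap_name(i, h)),
                census_copies=int(flg.sum()),
                census_frequency=float(flg.sum()) / n2,
                carrier_samples=carriers,
                homozygote_samples=homs,
                start_pos=config.marker_spacing * (s + 1),
                end_pos=config.marker_spacing * e,
            )
        )
    return panel, truth


def simulate_matings(
    n_records: int,
    carrier_freq: float,
    baseline_return: dict[str, float],
    excess_early_loss: float,
    seed: int,
    early_bin: str = "30-60",
    n_sires: Optional[int] = None,
    n_cows: Optional[int] = None,
) -> pd.DataFrame:
    """AI service records with elevated early returns for carrier x carrier matings.

    ``baseline_return`` maps return-interval bin labels to per-service
    probabilities of a second AI in that bin; the remaining mass is
    non-return (conception). Risk matings receive ``excess_early_loss``
    added to ``early_bin``. Sires and cows come from finite pools with
    per-individual carrier flags drawn at ``carrier_freq``.
    """
    if not 0.0 <= carrier_freq <= 1.0:
        raise ValueError("carrier_freq must be in [0, 1]")
    if not 0.0 <= excess_early_loss <= 1.0:
        raise ValueError("excess_early_loss must be in [0, 1]")
    unknown = set(baseline_return) - set(RETURN_BIN_LABELS)
    if unknown:
        raise ValueError(f"unknown bins {sorted(unknown)}")
    if early_bin not in RETURN_BIN_LABELS:
        raise ValueError(f"early_bin must be one of {RETURN_BIN_LABELS}")
    if any(p < 0 for p in baseline_return.values()):
        raise ValueError("bin probabilities must be >= 0")
    if sum(baseline_return.values()) + excess_early_loss > 1.0:
        raise ValueError("bin probabilities (plus excess) sum above 1")

    cols = ["cow_id", "sire_id", "ai_date", "days_to_2nd_ai", "sire_carrier", "cow_carrier"]
    if n_records == 0:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_sires = n_sires or max(1, n_records // 500)
    n_cows = n_cows or max(1, n_records // 10)
    sire_flag = rng.random(n_sires) < carrier_freq
    cow_flag = rng.random(n_cows) < carrier_freq
    sire_idx = rng.integers(0, n_sires, n_records)
    cow_idx = rng.integers(0, n_cows, n_records)
    sire_c = sire_flag[sire_idx]
    cow_c = cow_flag[cow_idx]
    risk = sire_c & cow_c

    bins = [b for b in RETURN_BIN_LABELS if b in baseline_return]
    base = np.array([baseline_return[b] for b in bins])
    probs = np.tile(base, (n_records, 1))
    if excess_early_loss and early_bin in bins:
        probs[risk, bins.index(early_bin)] += excess_early_loss
    elif excess_early_loss:
        bins = bins + [early_bin]
        probs = np.hstack([probs, np.where(risk, excess_early_loss, 0.0)[:, None]])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n_records)
    cat = (u[:, None] >= cum).sum(axis=1)  # len(bins) = non-return

    days = np.full(n_records, np.nan)
    for bi, label in enumerate(bins):
        lo, hi, _ = next(b for b in RETURN_BINS if b[2] == label)
        hi = hi if hi is not None else 285
        sel = cat == bi
        days[sel] = rng.integers(lo, hi + 1, int(sel.sum()))

    dates = pd.Timestamp("2015-01-01") + pd.to_timedelta(
        rng.integers(0, 365, n_records), unit="D"
    )
    return pd.DataFrame(
        {
            "cow_id": [f"C{i + 1:06d}" for i in cow_idx],
            "sire_id": [f"B{i + 1:04d}" for i in sire_idx],
            "ai_date": dates.strftime("%Y-%m-%d"),
            "days_to_2nd_ai": days,
            "sire_carrier": sire_c,
            "cow_carrier": cow_c,
        }
    )


def simulate_embryos(
    n_embryos: int, loss_before_observation: float, seed: int
) -> GenotypeCounts:
    """Embryo genotypes from het x het matings with recessive loss.

    Genotypes are drawn 1:2:1; risk homozygotes are removed before
    counting with probability ``loss_before_observation``.
    """
    if n_embryos < 0:
        raise ValueError("n_embryos must be >= 0")
    if not 0.0 <= loss_before_observation <= 1.0:
        raise ValueError("loss probability must be in [0, 1]")
    if n_embryos == 0:
        return GenotypeCounts(0, 0, 0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rr, rv, vv = rng.multinomial(n_embryos, [0.25, 0.5, 0.25])
    vv_seen = rng.binomial(vv, 1.0 - loss_before_observation)
    return GenotypeCounts(int(rr), int(rv), int(vv_seen))


@dataclass(frozen=True)
class CausalConfig:
    """Shape of the causal variant planted on the risk haplotype."""

    gene: str = "GENE_A"
    consequence: str = "splice_donor_variant"
    prediction: str = "deleterious"
    score: float = 0.0
    include_causal: bool = True
    position: Optional[int] = None
    extra_noncarrier_hets: int = 0  # variant older than the haplotype


def simulate_variant_table(
    panel: PhasedPanel,
    region: RiskRegion,
    causal_config: CausalConfig = CausalConfig(),
    n_decoys: int = 4,
    seed: int = 0,
    flank: int = 6_000_000,
) -> tuple[list[AnnotatedVariant], dict[str, dict]]:
    """Annotated variants in region +/- flank: one causal variant every
    risk-haplotype carrier is heterozygous for, plus decoys that each
    violate exactly one of the four selection criteria (recorded in truth).
    """
    carriers = region_carriers(panel, region)
    carrier_idx = np.array(
        [panel.samples.index(s) for s in carriers.sample_ids], dtype=int
    )
    if carrier_idx.size == 0:
        raise ValueError("region has no haplotype carriers in the panel")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = panel.n_samples
    hap_freq = region.q
    chrom = region.chromosome
    lo_bp = max(1, region.start_pos - flank)
    hi_bp = region.end_pos + flank
    non_carrier_idx = np.setdiff1d(np.arange(n), carrier_idx)

    variants: list[AnnotatedVariant] = []
    truth: dict[str, dict] = {}

    def base_pair():
        ref, alt = rng.choice(_BASES, 2, replace=False)
        return str(ref), str(alt)

    def pos_draw():
        return int(rng.integers(lo_bp, hi_bp + 1))

    if causal_config.include_causal:
        gt = np.zeros(n, dtype=np.int8)
        gt[carrier_idx] = 1
        extra = min(causal_config.extra_noncarrier_hets, non_carrier_idx.size)
        if extra:
            gt[rng.choice(non_carrier_idx, extra, replace=False)] = 1
        ref, alt = base_pair()
        pos = causal_config.position or (region.start_pos + region.end_pos) // 2
        v = AnnotatedVariant(
            chrom, pos, ref, alt, causal_config.gene, causal_config.consequence,
            causal_config.prediction, causal_config.score, gt,
        )
        variants.append(v)
        truth[v.variant_id] = {"role": "causal", "violates": None}

    violations = [1, 2, 3, 4]
    for d in range(n_decoys):
        crit = violations[d % 4]
        gt = np.zeros(n, dtype=np.int8)
        gene = f"DECOY_{d + 1}"
        consequence, prediction, score = "missense_variant", "deleterious", 0.01
        if crit == 1:  # has homozygotes
            gt[carrier_idx] = 1
            n_hom = max(1, non_carrier_idx.size // 200)
            gt[rng.choice(non_carrier_idx, n_hom, replace=False)] = 2
        elif crit == 2:  # frequency far from the haplotype frequency
            gt[carrier_idx] = 1
            n_extra = int(np.ceil((hap_freq + 0.15) * 2 * n)) - carrier_idx.size
            n_extra = min(max(n_extra, 0), non_carrier_idx.size)
            gt[rng.choice(non_carrier_idx, n_extra, replace=False)] = 1
        elif crit == 3:  # not annotated as deleterious
            gt[carrier_idx] = 1
            prediction, score = "tolerated", 0.71
        else:  # absent from some carriers
            keep = rng.choice(carrier_idx, carrier_idx.size // 2, replace=False)
            gt[keep] = 1
        ref, alt = base_pair()
        v = AnnotatedVariant(
            chrom, pos_draw(), ref, alt, gene, consequence, prediction, score, gt
        )
        variants.append(v)
        truth[v.variant_id] = {"role": "decoy", "violates": crit}
    variants.sort(key=lambda v: v.pos)
    return variants, truth


# cattle-like splice-donor intronic consensus for positions +3..+6
_DONOR_PROFILE = {
    3: {"A": 0.60, "C": 0.03, "G": 0.34, "T": 0.03},
    4: {"A": 0.71, "C": 0.08, "G": 0.11, "T": 0.10},
    5: {"A": 0.07, "C": 0.06, "G": 0.82, "T": 0.05},
    6: {"A": 0.17, "C": 0.16, "G": 0.20, "T": 0.47},
}


def _rand_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def _rand_dinuc_not(rng, avoid: str) -> str:
    while True:
        d = _rand_seq(rng, 2)
        if d != avoid:
            return d


def simulate_genome_annotation(
    n_genes: int,
    exons_per_gene: int,
    donor_consensus_strength: float,
    seed: int,
) -> tuple[str, str, dict]:
    """Toy genome FASTA + GTF with genes on both strands.

    Each intron begins with GT (plus a cattle-like +3..+6 donor consensus)
    and ends with AG with probability ``donor_consensus_strength``;
    otherwise its terminal dinucleotides are explicitly non-consensus.
    Truth records the realized donor-window base composition and the
    consensus counts.
    """
    if n_genes <= 0 or exons_per_gene <= 0:
        raise ValueError("counts must be > 0")
    if not 0.0 <= donor_consensus_strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom = "sim1"
    parts: list[str] = []
    gtf_lines: list[str] = []
    cursor = 1  # next free 1-based position
    donor_counts = np.zeros((12, 4), dtype=int)
    n_donors = n_consensus_donors = n_acceptors = n_consensus_acceptors = 0

    for g in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(90, 240, exons_per_gene)
        intron_lens = rng.integers(80, 400, max(exons_per_gene - 1, 0))
        tx_parts: list[str] = []
        offsets = []  # transcript-orientation exon offsets
        off = 0
        for e in range(exons_per_gene):
            offsets.append((off, off + int(exon_lens[e])))
            tx_parts.append(_rand_seq(rng, int(exon_lens[e])))
            off += int(exon_lens[e])
            if e < exons_per_gene - 1:
                ilen = int(intron_lens[e])
                donor_ok = rng.random() < donor_consensus_strength
                acceptor_ok = rng.random() < donor_consensus_strength
                if donor_ok:
                    head = "GT" + "".join(
                        rng.choice(
                            list(_DONOR_PROFILE[p]), p=list(_DONOR_PROFILE[p].values())
                        )
                        for p in (3, 4, 5, 6)
                    )
                    n_consensus_donors += 1
                else:
                    head = _rand_dinuc_not(rng, "GT") + _rand_seq(rng, 4)
                tail = ("AG" if acceptor_ok else _rand_dinuc_not(rng, "AG"))
                if acceptor_ok:
                    n_consensus_acceptors += 1
                mid = _rand_seq(rng, ilen - 8)
                tx_parts.append(head + mid + tail)
                n_donors += 1
                n_acceptors += 1
                off += ilen
        tx_seq = "".join(tx_parts)
        gene_len = len(tx_seq)
        genome_seq = tx_seq if strand == "+" else revcomp(tx_seq)
        gstart, gend = cursor, cursor + gene_len - 1

        gid, tid = f"g{g + 1}", f"g{g + 1}.t1"
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        exon_coords = []
        for (o1, o2) in offsets:
            if strand == "+":
                exon_coords.append((gstart + o1, gstart + o2 - 1))
            else:
                exon_coords.append((gend - (o2 - 1), gend - o1))
        exon_coords.sort()
        gtf_lines.append(
            f"{chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}"
        )
        gtf_lines.append(
            f"{chrom}\tsim\ttranscript\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}"
        )
        for (a, b) in exon_coords:
            gtf_lines.append(
                f"{chrom}\tsim\texon\t{a}\t{b}\t.\t{strand}\t.\t{attrs}"
            )
        # record realized donor windows (transcript orientation)
        for (o1, o2) in offsets[:-1]:
            win = tx_seq[o2 - 6 : o2 + 6]
            for j, b in enumerate(win):
                donor_counts[j, "ACGT".index(b)] += 1

        parts.append(genome_seq)
        parts.append(_rand_seq(rng, 300))
        cursor = gend + 1 + 300

    seq = "".join(parts)
    fasta = f">{chrom}\n" + "\n".join(
        seq[i : i + 60] for i in range(0, len(seq), 60)
    ) + "\n"
    gtf = "\n".join(gtf_lines) + "\n"
    truth = {
        "donor_base_counts": donor_counts.tolist(),
        "n_donors": n_donors,
        "n_consensus_donors": n_consensus_donors,
        "n_acceptors": n_acceptors,
        "n_consensus_acceptors": n_consensus_acceptors,
    }
    return fasta, gtf, truth
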