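"""Published summary counts from the Japanese Black cattle study cohorts.

These small count tables are the study's printed inputs: genotype counts
of follow-up cohorts for the CDC45 splice-donor variant
(AC_000174.1:g.74743512G>T), the candidate-variant genotype counts among
the exome-sequenced sires, embryo genotypes from carrier x carrier
matings, and the AI return-interval 2x2 tables for the two
embryonic-lethality haplotypes. Downstream statistics (allele
frequencies, Hardy-Weinberg expectations, deficit and segregation tests,
mortality contrasts) are recomputed from these counts at run time.
"""

from .stats import GenotypeCounts

#: Adult census panel size used for the haplotype scan.
SCAN_PANEL_SIZE = 4843

#: Exome-sequenced sire cohort size.
SIRE_COHORT_SIZE = 517

#: Risk-haplotype frequencies of the seven deficit regions in the
#: 4,843-animal panel (by region id).
RISK_HAPLOTYPE_FREQUENCIES = {
    "JBH_1_1": 0.049,
    "JBH_1_2": 0.049,
    "JBH_4": 0.045,
    "JBH_8_1": 0.046,
    "JBH_8_2": 0.052,
    "JBH_10": 0.050,
    "JBH_17": 0.045,
}

#: Haplotype carrier counts among the 517 exome-sequenced sires.
SIRE_CARRIER_COUNTS = {
    "JBH_1_1": 14,
    "JBH_1_2": 21,
    "JBH_4": 12,
    "JBH_8_1": 18,
    "JBH_8_2": 44,
    "JBH_10": 17,
    "JBH_17": 22,
}

#: Candidate-variant genotype counts (rr/rv/vv) in the sire cohort.
CANDIDATE_SIRE_COUNTS = {
    "CLDN16_exon1_5_del": GenotypeCounts(1840, 140, 0),  # 1,980 HD-genotyped animals
    "NOL6_D1009N": GenotypeCounts(435, 82, 0),
    "IARS_V79L": GenotypeCounts(436, 79, 0),
    "CDC45_splice_donor": GenotypeCounts(473, 44, 0),
}

#: CDC45 splice-donor variant in 1,593 steers from two central slaughterhouses.
CDC45_SLAUGHTERHOUSE_COUNTS = GenotypeCounts(1382, 211, 0)

#: CDC45 splice-donor variant in 1,137 cows from the local subpopulation
#: where the carrier sires were originally reared.
CDC45_LOCAL_COUNTS = GenotypeCounts(946, 191, 0)

#: Healthy hatched embryos / expanded blastocysts from carrier x carrier
#: matings for the CDC45 variant (G/G, G/T, T/T).
CDC45_EMBRYO_COUNTS = GenotypeCounts(7, 27, 0)

#: NOL6 validation genotyping in 2,720 female cattle found seven surviving
#: risk-allele homozygotes (risk allele frequency 0.073), vetoing NOL6 as
#: a lethal candidate. Only the homozygote count was reported; the triple
#: below fills the remaining classes to match the reported frequency.
NOL6_VALIDATION_HOMOZYGOTES = 7

#: AI return-interval 2x2 contrasts for the two embryonic-lethal
#: haplotypes: (bin, risk non-return, risk 2nd AI, other non-return,
#: other 2nd AI).
MORTALITY_2X2 = {
    "JBH_10": ("61-90", 120, 39, 74731, 16441),
    "JBH_17": ("30-60", 106, 43, 91732, 23592),
}
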