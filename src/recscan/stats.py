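"""Genotype-count statistics and AI return-interval mortality contrasts.

Implements the single-locus statistics used when following up a risk
haplotype: allele frequencies from genotype counts, Hardy-Weinberg
expected genotype numbers under random mating, a chi-square deficit test
for missing homozygotes, a closed-form binomial test for a completely
absent homozygote class, the 1:2:1 segregation test for embryos from
carrier x carrier matings, and the artificial-insemination (AI)
return-interval contrast that estimates embryonic mortality from mating
records.

A cow that shows no second AI after the first service is taken as having
conceived ("non-return"); a second AI marks failure of the first
conception, and the interval from the first AI to the second classifies
when the pregnancy was lost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import round_half_away

log = logging.getLogger(__name__)

#: Inclusive day ranges of the return-interval bins; a second AI at >= 141
#: days (up to parturition) falls in the open-ended last bin.
RETURN_BINS: list[tuple[int, Optional[int], str]] = [
    (18, 29, "18-29"),
    (30, 60, "30-60"),
    (61, 90, "61-90"),
    (91, 140, "91-140"),
    (141, None, "141+"),
]

RETURN_BIN_LABELS = [label for _, _, label in RETURN_BINS]


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of (reference-homozygote, heterozygote, risk-homozygote)."""

    n_rr: int
    n_rv: int
    n_vv: int

    def __post_init__(self):
        if min(self.n_rr, self.n_rv, self.n_vv) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_rr + self.n_rv + self.n_vv

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_rr, self.n_rv, self.n_vv)


@dataclass(frozen=True)
class ReturnRecord:
    """One AI service: who was mated and when (if ever) estrus resumed."""

    cow_id: str
    sire_id: str
    ai_date: str
    days_to_second_ai: Optional[int]  # None = non-return (conceived)
    sire_carrier: Optional[bool]
    cow_carrier: Optional[bool]

    def __post_init__(self):
        if self.days_to_second_ai is not None and self.days_to_second_ai < 0:
            raise ValueError("days_to_second_ai must be >= 0")


@dataclass
class MortalityTable:
    """2x2 contrast of second-AI returns in one interval bin."""

    bin_label: str
    risk_non_return: int
    risk_second_ai: int
    other_non_return: int
    other_second_ai: int
    mortality_risk_pct: int
    mortality_other_pct: int
    chi2: float
    p: float
    n_dropped_unknown: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mating_type": ["carrier_x_carrier", "others"],
                "timing_2nd_ai": [self.bin_label] * 2,
                "n_non_return": [self.risk_non_return, self.other_non_return],
                "n_2nd_ai": [self.risk_second_ai, self.other_second_ai],
                "embryonic_mortality_pct": [
                    self.mortality_risk_pct,
                    self.mortality_other_pct,
                ],
                "chi2": [self.chi2, np.nan],
                "p_value": [self.p, np.nan],
            }
        )


def _freq_exact(counts: GenotypeCounts) -> float:
    if counts.total == 0:
        raise ValueError("cannot compute an allele frequency from zero genotypes")
    return (counts.n_rv + 2 * counts.n_vv) / (2 * counts.total)


def allele_frequency(counts: GenotypeCounts, decimals: int = 3) -> float:
    """Risk-allele frequency (n_rv + 2 n_vv) / 2N, rounded half away from zero."""
    return round_half_away(_freq_exact(counts), decimals)


def hwe_expected(
    counts: GenotypeCounts,
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Random-mating expected genotype numbers from the observed allele frequency.

    Returns the exact triple (N(1-p)^2, 2Np(1-p), Np^2) computed from the
    *unrounded* allele frequency, plus the half-away-from-zero rounded
    integer triple used in printed tables.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty genotype counts")
    p = _freq_exact(counts)
    exact = (n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p * p)
    rounded = tuple(int(round_half_away(e)) for e in exact)
    return exact, rounded


def hwe_deficit_chisq(counts: GenotypeCounts, df: int = 1) -> tuple[float, float]:
    """Goodness-of-fit chi-square of observed genotypes against HWE expectations.

    df defaults to 1 (one allele frequency estimated from two free genotype
    classes); exposed because the appropriate df for small expected classes
    is debatable.
    """
    (e_rr, e_rv, e_vv), _ = hwe_expected(counts)
    if min(e_rr, e_rv, e_vv) <= 0:
        raise ValueError(
            "an expected genotype class is zero; use homozygote_absence_binomial"
        )
    obs = np.array(counts.as_tuple(), dtype=float)
    exp = np.array([e_rr, e_rv, e_vv])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(chi2, df))
    return chi2, p


def homozygote_absence_binomial(counts: GenotypeCounts) -> float:
    """P(no risk homozygote among N under HWE) = (1 - f^2)^N.

    One-sided companion test for the case where the expected homozygote
    class is too small for a chi-square.
    """
    f = _freq_exact(counts)
    return float((1.0 - f * f) ** counts.total)


def segregation_test(
    counts: GenotypeCounts,
    ratio: Sequence[float] = (1, 2, 1),
    df: int = 1,
) -> tuple[tuple[float, float, float], float, float]:
    """Test observed genotypes against a Mendelian ratio (default 1:2:1).

    Used for embryos recovered from carrier x carrier matings, where a
    missing risk-homozygote class indicates recessive embryonic loss.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty genotype counts")
    ratio = np.asarray(ratio, dtype=float)
    expected = n * ratio / ratio.sum()
    obs = np.array(counts.as_tuple(), dtype=float)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df))
    return tuple(expected), chi2, p


def bin_return_interval(days: int) -> str:
    """Map days from 1st AI to 2nd AI onto the standard interval bins.

    Returns "excluded" for returns earlier than 18 days (too early to
    reflect conception failure of the first service).
    """
    if days < 0:
        raise ValueError("days to second AI must be >= 0")
    for lo, hi, label in RETURN_BINS:
        if days >= lo and (hi is None or days <= hi):
            return label
    return "excluded"


def classify_mating(sire_carrier: bool, cow_carrier: bool) -> str:
    """"risk" iff both parents carry the haplotype/allele, else "other"."""
    if sire_carrier is None or cow_carrier is None:
        raise ValueError("carrier status unknown")
    return "risk" if (sire_carrier and cow_carrier) else "other"


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        (r.cow_id, r.sire_id, r.ai_date, r.days_to_second_ai, r.sire_carrier, r.cow_carrier)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cow_id",
            "sire_id",
            "ai_date",
            "days_to_2nd_ai",
            "sire_carrier",
            "cow_carrier",
        ],
    )


def mortality_contrast(
    records,
    bin_label: str,
    method: str = "chisq",
) -> MortalityTable:
    """Contrast second-AI returns in one interval bin between mating types.

    Builds the 2x2 table (risk/other mating) x (non-return / second AI in
    `bin_label`). Records whose second AI falls in a different bin are
    excluded from this bin's contrast, so each bin contrasts "returned in
    this bin" against "never returned". Mortality % = 100 * secondAI /
    (non-return + secondAI), rounded to integer. Chi-square is computed
    without continuity correction (df=1); `method="fisher"` uses Fisher's
    exact test instead.
    """
    if bin_label not in RETURN_BIN_LABELS:
        raise ValueError(f"unknown bin {bin_label!r}; choose from {RETURN_BIN_LABELS}")
    df = _records_frame(records)
    known = df["sire_carrier"].notna() & df["cow_carrier"].notna()
    n_dropped = int((~known).sum())
    if n_dropped:
        log.info("mortality_contrast dropped_unknown_carrier=%d", n_dropped)
    df = df[known]
    risk = df["sire_carrier"].astype(bool) & df["cow_carrier"].astype(bool)
    days = df["days_to_2nd_ai"]
    non_return = days.isna()
    in_bin = pd.Series(False, index=df.index)
    returned = df.index[days.notna()]
    if len(returned):
        in_bin.loc[returned] = [
            bin_return_interval(int(d)) == bin_label for d in days.loc[returned]
        ]

    table = np.array(
        [
            [int((risk & non_return).sum()), int((risk & in_bin).sum())],
            [int((~risk & non_return).sum()), int((~risk & in_bin).sum())],
        ]
    )

    def pct(nr, ai):
        return int(round_half_away(100.0 * ai / (nr + ai))) if (nr + ai) > 0 else 0

    chi2 = p = float("nan")
    if table[:, 1].sum() == 0 or table.sum() == 0 or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table; chi-square skipped", stacklevel=2)
    elif method == "fisher":
        chi2 = float("nan")
        _, p = sps.fisher_exact(table)
    else:
        expected = sps.contingency.expected_freq(table)
        if expected.min() < 1:
            warnings.warn("expected cell < 1; chi-square skipped", stacklevel=2)
        else:
            chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return MortalityTable(
        bin_label=bin_label,
        risk_non_return=int(table[0, 0]),
        risk_second_ai=int(table[0, 1]),
        other_non_return=int(table[1, 0]),
        other_second_ai=int(table[1, 1]),
        mortality_risk_pct=pct(table[0, 0], table[0, 1]),
        mortality_other_pct=pct(table[1, 0], table[1, 1]),
        chi2=float(chi2),
        p=float(p),
        n_dropped_unknown=n_dropped,
    )


def mortality_table_from_counts(
    bin_label: str,
    risk_non_return: int,
    risk_second_ai: int,
    other_non_return: int,
    other_second_ai: int,
    method: str = "chisq",
) -> MortalityTable:
    """Build the 2x2 contrast directly from published summary counts."""
    table = np.array(
        [[risk_non_return, risk_second_ai], [other_non_return, other_second_ai]]
    )

    def pct(nr, ai):
        return int(round_half_away(100.0 * ai / (nr + ai))) if (nr + ai) > 0 else 0

    if method == "fisher":
        chi2 = float("nan")
        _, p = sps.fisher_exact(table)
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return MortalityTable(
        bin_label=bin_label,
        risk_non_return=risk_non_return,
        risk_second_ai=risk_second_ai,
        other_non_return=other_non_return,
        other_second_ai=other_second_ai,
        mortality_risk_pct=pct(risk_non_return, risk_second_ai),
        mortality_other_pct=pct(other_non_return, other_second_ai),
        chi2=float(chi2),
        p=float(p),
    )


def concordance_rate(calls_a, calls_b) -> float:
    """Percent agreement between two genotype matrices sharing keys.

    Entries missing (NaN) in either matrix are excluded from both the
    numerator and the denominator. Used to validate sequencing-derived
    genotypes against array genotypes.
    """
    a = pd.DataFrame(calls_a)
    b = pd.DataFrame(calls_b)
    b = b.reindex(index=a.index, columns=a.columns)
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    comparable = ~(np.isnan(av) | np.isnan(bv))
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable genotype calls")
    match = int((av[comparable] == bv[comparable]).sum())
    return 100.0 * match / n
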