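#!/usr/bin/env python
"""Single-locus statistics of the candidate variants and follow-up cohorts.

From the published genotype-count triples: risk-allele frequencies,
Hardy-Weinberg expected genotype numbers, the chi-square deficit test for
missing homozygotes, the closed-form homozygote-absence binomial, and the
1:2:1 segregation test on embryos from carrier x carrier matings.
Writes results/genotype_statistics.tsv.
"""

from pathlib import Path

import pandas as pd

from recscan import (
    allele_frequency,
    homozygote_absence_binomial,
    hwe_deficit_chisq,
    hwe_expected,
    segregation_test,
)
from recscan.datasets import (
    CANDIDATE_SIRE_COUNTS,
    CDC45_EMBRYO_COUNTS,
    CDC45_LOCAL_COUNTS,
    CDC45_SLAUGHTERHOUSE_COUNTS,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    cohorts = dict(CANDIDATE_SIRE_COUNTS)
    cohorts["CDC45_slaughterhouse_steers"] = CDC45_SLAUGHTERHOUSE_COUNTS
    cohorts["CDC45_local_cows"] = CDC45_LOCAL_COUNTS
    for name, gc in cohorts.items():
        exact, rounded = hwe_expected(gc)
        row = {
            "cohort": name,
            "observed": "/".join(map(str, gc.as_tuple())),
            "expected": "/".join(map(str, rounded)),
            "expected_vv_exact": round(exact[2], 2),
            "risk_allele_freq": allele_frequency(gc),
            "absence_binomial_p": f"{homozygote_absence_binomial(gc):.2e}",
        }
        try:
            chi2, p = hwe_deficit_chisq(gc, df=1)
            row["hwe_chi2"] = round(chi2, 2)
            row["hwe_p_df1"] = round(p, 4)
        except ValueError:
            row["hwe_chi2"] = row["hwe_p_df1"] = None
        rows.append(row)
        print(
            f"{name}: obs {row['observed']}, exp {row['expected']}, "
            f"freq {row['risk_allele_freq']}, HWE p {row['hwe_p_df1']}"
        )

    expected, chi2, p = segregation_test(CDC45_EMBRYO_COUNTS, df=1)
    print(
        f"embryos from het x het matings: observed "
        f"{CDC45_EMBRYO_COUNTS.as_tuple()}, expected "
        f"({', '.join(f'{e:.1f}' for e in expected)}), chi2={chi2:.2f}, p={p:.4f}"
    )
    rows.append(
        {
            "cohort": "CDC45_embryos_het_x_het",
            "observed": "/".join(map(str, CDC45_EMBRYO_COUNTS.as_tuple())),
            "expected": "/".join(f"{e:.1f}" for e in expected),
            "expected_vv_exact": round(expected[2], 2),
            "risk_allele_freq": allele_frequency(CDC45_EMBRYO_COUNTS),
            "absence_binomial_p": None,
            "hwe_chi2": round(chi2, 2),
            "hwe_p_df1": round(p, 4),
        }
    )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "genotype_statistics.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'genotype_statistics.tsv'}")


if __name__ == "__main__":
    main()
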