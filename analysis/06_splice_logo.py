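#!/usr/bin/env python
"""Splice-boundary sequence logos from a simulated genome annotation.

Generates a toy genome + GTF whose introns follow the GT/AG rule with 95%
fidelity (plus a cattle-like donor consensus at intronic positions +3 to
+6), extracts donor (6 exonic + 6 intronic bases) and acceptor
(50 intronic + 2 exonic) windows on both strands, filters to canonical
GT/AG boundaries, and builds position-frequency matrices with
per-position information content — the quantity a sequence logo draws.
Writes results/pwm_donor.tsv and results/pwm_acceptor.tsv; the logo
figure goes to scratch/figures/.
"""

import tempfile
from pathlib import Path

from recscan import build_pwm, extract_boundaries, filter_gt_ag, simulate_genome_annotation
from recscan.splice import DONOR_EXONIC, plot_logo

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20210323


def main() -> None:
    fasta, gtf, truth = simulate_genome_annotation(
        n_genes=200, exons_per_gene=5, donor_consensus_strength=0.95, seed=SEED
    )
    with tempfile.TemporaryDirectory() as td:
        fa, gt = Path(td) / "genome.fa", Path(td) / "genes.gtf"
        fa.write_text(fasta)
        gt.write_text(gtf)
        donors, acceptors = extract_boundaries(str(gt), str(fa))
    donors_f, acceptors_f, counts = filter_gt_ag(donors, acceptors)
    print(
        f"{len(donors)} donor / {len(acceptors)} acceptor boundaries; "
        f"kept {counts['donors_kept']} GT donors and "
        f"{counts['acceptors_kept']} AG acceptors"
    )
    pwm_d = build_pwm(donors_f)
    pwm_a = build_pwm(acceptors_f)
    RESULTS.mkdir(exist_ok=True)
    pwm_d.to_frame().round(4).to_csv(RESULTS / "pwm_donor.tsv", sep="\t")
    pwm_a.to_frame().round(4).to_csv(RESULTS / "pwm_acceptor.tsv", sep="\t")
    plus5 = pwm_d.frequencies.iloc[DONOR_EXONIC + 4]
    print(
        "donor +5 base composition: "
        + ", ".join(f"{b}={plus5[b]:.2f}" for b in "ACGT")
        + f"; IC={pwm_d.information_content[DONOR_EXONIC + 4]:.2f} bits"
    )
    figdir = ROOT / "scratch" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    plot_logo(pwm_d, str(figdir / "donor_logo.png"))
    plot_logo(pwm_a, str(figdir / "acceptor_logo.png"))
    print(f"wrote {RESULTS / 'pwm_donor.tsv'} and logos under {figdir}")


if __name__ == "__main__":
    main()
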