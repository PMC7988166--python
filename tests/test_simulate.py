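"""Synthetic cohort generator: determinism, planted structure, null behavior."""

import numpy as np
import pytest
from scipy import stats as sps

from recscan import (
    CausalConfig,
    GenotypeCounts,
    PlantedHaplotype,
    SimConfig,
    Window,
    filter_candidates,
    haplotype_counts,
    merge_regions,
    region_carriers,
    scan,
    simulate_embryos,
    simulate_genome_annotation,
    simulate_matings,
    simulate_panel,
    simulate_variant_table,
)


def _planted(q=0.05, lethality="embryonic", penetrance=1.0, span=(100, 120), seed=0):
    rng = np.random.default_rng(seed)
    allele = "".join(rng.integers(0, 2, span[1] - span[0]).astype(str))
    return PlantedHaplotype("1", span, allele, q, lethality, penetrance)


def _config(n=2000, planted=(), seed=0, m=300):
    return SimConfig(
        n_samples=n, n_chromosomes=1, markers_per_chromosome=m,
        risk_haplotypes=tuple(planted), seed=seed,
    )


def test_identical_seeds_identical_panels():
    cfg = _config(n=300, planted=(_planted(),), seed=42)
    p1, t1 = simulate_panel(cfg)
    p2, t2 = simulate_panel(cfg)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    assert p1.markers.equals(p2.markers)
    assert t1[0].carrier_samples == t2[0].carrier_samples
    p3, _ = simulate_panel(_config(n=300, planted=(_planted(),), seed=43))
    assert not np.array_equal(p1.haplotypes, p3.haplotypes)


def test_lethality_disabled_keeps_hwe_at_planted_span():
    ph = _planted(q=0.08, penetrance=0.0)
    panel, truth = simulate_panel(_config(n=5000, planted=(ph,), seed=5))
    n = panel.n_samples
    q = truth[0].census_frequency
    obs_hom = len(truth[0].homozygote_samples)
    lo = sps.binom.ppf(0.0005, n, q * q)
    hi = sps.binom.ppf(0.9995, n, q * q)
    assert lo <= obs_hom <= hi


def test_full_penetrance_removes_all_homozygotes():
    ph = _planted(q=0.05, penetrance=1.0)
    panel, truth = simulate_panel(_config(n=5000, planted=(ph,), seed=1))
    assert truth[0].homozygote_samples == []
    n_carriers = len(truth[0].carrier_samples)
    # generous binomial band around 2Nq(1-q)
    band = sps.binom.ppf([1e-4, 1 - 1e-4], 5000, 2 * 0.05 * 0.95)
    assert band[0] <= n_carriers <= band[1]
    # string-identity check against the panel itself
    tab = haplotype_counts(panel, Window("1", *ph.marker_span[:1], ph.marker_span[1] - ph.marker_span[0]))
    row = tab[tab.hap == ph.allele_string]
    assert int(row.homozygotes.iloc[0]) == 0
    assert int(row.carriers.iloc[0]) == n_carriers


def test_planted_frequency_recovered_within_3_se():
    for seed in range(3):
        ph = _planted(q=0.05, lethality="none")
        panel, truth = simulate_panel(_config(n=4000, planted=(ph,), seed=seed))
        n2 = 2 * panel.n_samples
        se = np.sqrt(0.05 * 0.95 / n2)
        assert abs(truth[0].census_frequency - 0.05) <= 3 * se


def test_null_deficit_pvalues_not_anticonservative():
    """At non-planted windows the deficit test should not over-reject."""
    panel, _ = simulate_panel(_config(n=1000, seed=9, m=200))
    n = panel.n_samples
    ps = []
    for start in range(0, 195, 5):
        tab = haplotype_counts(panel, Window("1", start, 3))
        for _, row in tab[tab.q >= 0.05].iterrows():
            ps.append(sps.binom.cdf(row.homozygotes, n, row.q ** 2))
    ps = np.array(ps)
    assert ps.size > 100
    assert (ps <= 0.1).mean() <= 0.15
    assert (ps <= 0.5).mean() <= 0.60


def test_invalid_configs_error():
    with pytest.raises(ValueError):
        PlantedHaplotype("1", (0, 5), "01010", 0.6)
    with pytest.raises(ValueError):
        PlantedHaplotype("1", (0, 5), "0101", 0.1)
    with pytest.raises(ValueError):
        SimConfig(n_samples=0)
    with pytest.raises(ValueError):
        _config(planted=(PlantedHaplotype("1", (290, 310), "0" * 20, 0.1),))


BASELINE = {"18-29": 0.10, "30-60": 0.08, "61-90": 0.05, "91-140": 0.03, "141+": 0.02}


def test_matings_null_has_equal_rates():
    records = simulate_matings(60_000, 0.2, BASELINE, 0.0, seed=3)
    risk = records.sire_carrier & records.cow_carrier
    early = records.days_to_2nd_ai.between(30, 60)
    r1, r0 = early[risk].mean(), early[~risk].mean()
    se = np.sqrt(r0 * (1 - r0) * (1 / risk.sum() + 1 / (~risk).sum()))
    assert abs(r1 - r0) < 4 * se


def test_matings_empty_and_validation():
    assert len(simulate_matings(0, 0.1, BASELINE, 0.0, seed=0)) == 0
    with pytest.raises(ValueError):
        simulate_matings(10, 0.1, {"18-29": 0.6, "30-60": 0.5}, 0.0, seed=0)
    with pytest.raises(ValueError):
        simulate_matings(10, 0.1, BASELINE, 0.9, seed=0)  # sums above 1
    with pytest.raises(ValueError):
        simulate_matings(10, 1.5, BASELINE, 0.0, seed=0)


def test_matings_deterministic():
    a = simulate_matings(1000, 0.2, BASELINE, 0.05, seed=8)
    b = simulate_matings(1000, 0.2, BASELINE, 0.05, seed=8)
    assert a.equals(b)


def test_embryos_ratio_and_loss():
    gc = simulate_embryos(30_000, 1.0, seed=3)
    assert gc.n_vv == 0
    assert gc.n_rv / gc.n_rr == pytest.approx(2.0, abs=0.1)
    gc = simulate_embryos(10_000, 0.0, seed=3)
    for obs, p in zip(gc.as_tuple(), (0.25, 0.5, 0.25)):
        band = sps.binom.ppf([5e-4, 1 - 5e-4], 10_000, p)
        assert band[0] <= obs <= band[1]
    assert simulate_embryos(0, 0.5, seed=1).as_tuple() == (0, 0, 0)


@pytest.fixture(scope="module")
def scanned_region():
    ph = _planted(q=0.06, span=(100, 125), seed=2)
    cfg = SimConfig(
        n_samples=4843, n_chromosomes=1, markers_per_chromosome=300,
        risk_haplotypes=(ph,), seed=21,
    )
    panel, truth = simulate_panel(cfg)
    regions = merge_regions(scan(panel, fdr=0.05), panel, prefix="SIM")
    assert len(regions) == 1
    return panel, regions[0], truth[0]


def test_variant_table_causal_only(scanned_region):
    panel, region, _ = scanned_region
    variants, truth = simulate_variant_table(panel, region, n_decoys=0, seed=1)
    assert len(variants) == 1
    carriers = region_carriers(panel, region)
    passing = filter_candidates(variants, region.q, carriers, panel.samples)
    assert [v.variant_id for v in passing] == [variants[0].variant_id]


def test_variant_table_decoys_each_fail_once(scanned_region):
    panel, region, _ = scanned_region
    variants, truth = simulate_variant_table(panel, region, n_decoys=4, seed=11)
    carriers = region_carriers(panel, region)
    passing = filter_candidates(variants, region.q, carriers, panel.samples)
    assert len(passing) == 1
    assert truth[passing[0].variant_id]["role"] == "causal"
    from recscan import apply_criteria

    for v in variants:
        info = truth[v.variant_id]
        crit = apply_criteria(v, region.q, carriers, panel.samples)
        if info["role"] == "causal":
            assert crit.passes
        else:
            failed = [i + 1 for i, ok in enumerate(crit.as_vector()) if not ok]
            assert failed == [info["violates"]]


def test_variant_table_without_causal_filters_to_empty(scanned_region):
    panel, region, _ = scanned_region
    variants, _ = simulate_variant_table(
        panel, region, CausalConfig(include_causal=False), n_decoys=4, seed=5
    )
    carriers = region_carriers(panel, region)
    assert filter_candidates(variants, region.q, carriers, panel.samples) == []


def test_genome_annotation_shape_and_determinism():
    fasta, gtf, truth = simulate_genome_annotation(20, 4, 0.9, seed=4)
    fasta2, gtf2, _ = simulate_genome_annotation(20, 4, 0.9, seed=4)
    assert fasta == fasta2 and gtf == gtf2
    assert fasta.startswith(">sim1\n")
    exon_lines = [l for l in gtf.splitlines() if "\texon\t" in l]
    assert len(exon_lines) == 20 * 4
    assert truth["n_donors"] == 20 * 3
    with pytest.raises(ValueError):
        simulate_genome_annotation(0, 2, 0.5, seed=1)
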