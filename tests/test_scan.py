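"""Window enumeration, haplotype counting, deficiency testing and merging."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recscan import (
    Window,
    WindowTest,
    deficiency_test,
    enumerate_windows,
    fdr_adjust,
    haplotype_counts,
    merge_regions,
    scan,
)
from recscan.scan import _scan_chromosome

from conftest import make_panel


def _count_windows(n_markers_per_chrom, k_min, k_max):
    panel = make_panel(["0" * n_markers_per_chrom] * 2)
    return sum(1 for _ in enumerate_windows(panel, k_min, k_max))


@pytest.mark.parametrize(
    "n_markers, k_min, k_max, expected",
    [
        (5, 2, 3, 7),  # 4 + 3
        (101, 2, 100, sum(102 - k for k in range(2, 101))),  # 5049
    ],
)
def test_enumerate_window_counts(n_markers, k_min, k_max, expected):
    assert _count_windows(n_markers, k_min, k_max) == expected


def test_enumerate_windows_respect_chromosome_boundaries():
    hap = np.zeros((2, 200), dtype=np.uint8)
    import pandas as pd

    markers = pd.DataFrame(
        {
            "chrom": ["1"] * 100 + ["2"] * 100,
            "pos": list(range(1, 101)) * 2,
            "id": [f"m{i}" for i in range(200)],
        }
    )
    from recscan import PhasedPanel

    panel = PhasedPanel(markers, ["s0"], hap)
    wins = list(enumerate_windows(panel, 100, 100))
    assert len(wins) == 2
    assert {w.chrom for w in wins} == {"1", "2"}


def test_haplotype_counts_hand_example(six_sample_panel):
    tab = haplotype_counts(six_sample_panel, Window("1", 0, 2))
    row = tab[tab.hap == "11"].iloc[0]
    assert row.copies == 3
    assert row.q == pytest.approx(0.25)
    assert row.carriers == 3
    assert row.homozygotes == 0
    # conservation: copies sum to 2N, frequencies to 1
    assert tab.copies.sum() == 12
    assert tab.q.sum() == pytest.approx(1.0)


def test_haplotype_counts_all_homozygous():
    panel = make_panel(["000", "000"] * 4)
    tab = haplotype_counts(panel, Window("1", 0, 3))
    assert len(tab) == 1
    assert tab.iloc[0].q == 1.0
    assert tab.iloc[0].homozygotes == 4


def _enumerate_oracle(hap_rows, start, k):
    """Independent exhaustive window counting over explicit strings."""
    strings = [row[start : start + k] for row in hap_rows]
    copies = Counter(strings)
    carriers = Counter()
    homs = Counter()
    for i in range(0, len(strings), 2):
        a, b = strings[i], strings[i + 1]
        for s in set((a, b)):
            carriers[s] += 1
        if a == b:
            homs[a] += 1
    return copies, carriers, homs


@pytest.mark.parametrize("seed", range(5))
def test_window_counts_agree_with_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, 11), rng.integers(2, 11)
    rows = ["".join(rng.integers(0, 2, m).astype(str)) for _ in range(2 * n)]
    panel = make_panel(rows)
    for start, k in itertools.product(range(m - 1), range(2, m + 1)):
        if start + k > m:
            continue
        tab = haplotype_counts(panel, Window("1", start, k))
        copies, carriers, homs = _enumerate_oracle(rows, start, k)
        for _, row in tab.iterrows():
            assert row.copies == copies[row.hap]
            assert row.carriers == carriers[row.hap]
            assert row.homozygotes == homs[row.hap]
        assert set(tab.hap) == set(copies)


@pytest.mark.parametrize("seed", [0, 1])
def test_fast_paths_agree(seed):
    """numpy and numba scan kernels produce identical test tables."""
    from recscan.scan import _HAVE_NUMBA, _scan_chromosome_numba

    if not _HAVE_NUMBA:
        pytest.skip("numba unavailable")
    rng = np.random.default_rng(seed)
    hap = (rng.random((60, 50)) < 0.4).astype(np.uint8)
    a = _scan_chromosome(hap, 2, 10, 1, 3)
    b = _scan_chromosome_numba(hap, 2, 10, 1, 3)

    def as_set(res):
        return {
            (s, k, c, o)
            for s, k, c, o in zip(res[0], res[1], res[2], res[3])
        }

    assert as_set(a) == as_set(b)


def test_deficiency_test_closed_form():
    exp_hom, p = deficiency_test(0.052, 4843, 0)
    assert exp_hom == pytest.approx(13.095472)
    assert p == pytest.approx((1 - 0.052**2) ** 4843, rel=1e-12)
    assert p == pytest.approx(2.018e-6, rel=1e-3)


def test_deficiency_test_degenerate_cases():
    assert deficiency_test(0.0, 100, 0) == (0.0, 1.0)
    _, p = deficiency_test(0.3, 100, 100)
    assert p == 1.0
    with pytest.raises(ValueError):
        deficiency_test(1.2, 100, 0)


def test_deficiency_p_decreasing_in_q():
    ps = [deficiency_test(q, 4843, 0)[1] for q in np.linspace(0.01, 0.2, 25)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_fdr_adjust_examples():
    assert fdr_adjust([0.01]) == pytest.approx([0.01])
    assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    assert fdr_adjust([]).size == 0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_fdr_adjust_bounds_and_dominates_p(p_values):
    q = fdr_adjust(p_values)
    assert np.all((q >= np.asarray(p_values) - 1e-12) & (q <= 1.0 + 1e-12))


def test_scan_min_q_one_is_empty(six_sample_panel):
    assert scan(six_sample_panel, min_q=1.0) == []


def _mk_window(chrom, sm, em, start_pos, end_pos, p=1e-6):
    return WindowTest(
        chromosome=chrom, start_marker=sm, end_marker=em, k=em - sm,
        hap="0" * (em - sm), q=0.05, n_carriers=10, obs_hom=0,
        exp_hom=5.0, p_deficit=p, q_value=p * 10,
        start_pos=start_pos, end_pos=end_pos,
    )


def test_merge_regions_interval_union():
    panel = make_panel(["0" * 40] * 2, spacing=1000)
    wins = [
        _mk_window("1", 10, 20, 11000, 20000, p=1e-6),
        _mk_window("1", 15, 31, 16000, 31000, p=1e-7),
    ]
    regions = merge_regions(wins, panel, prefix="R")
    assert len(regions) == 1
    r = regions[0]
    assert r.id == "R_1"
    assert (r.start_pos, r.end_pos) == (11000, 31000)
    assert r.n_markers == 21  # markers at 11000..31000 step 1000
    assert r.p_min == 1e-7
    assert r.length == r.end_pos - r.start_pos


def test_merge_regions_disjoint_get_suffixes():
    panel = make_panel(["0" * 40] * 2, spacing=1000)
    wins = [
        _mk_window("1", 2, 5, 3000, 5000),
        _mk_window("1", 20, 25, 21000, 25000),
    ]
    regions = merge_regions(wins, panel, prefix="R")
    assert [r.id for r in regions] == ["R_1_1", "R_1_2"]
    assert merge_regions([], panel) == []


def test_scan_recovers_planted_lethal(lethal_sim):
    cfg, panel, truth = lethal_sim
    sig = scan(panel, fdr=0.05)
    assert sig, "planted lethal haplotype not detected"
    regions = merge_regions(sig, panel, prefix="SIM")
    t = truth[0]
    overlapping = [
        r
        for r in regions
        if r.start_pos <= t.end_pos and r.end_pos >= t.start_pos
    ]
    assert len(overlapping) >= 1
    top = overlapping[0]
    assert top.obs_hom == 0
    assert top.q == pytest.approx(t.census_frequency, abs=0.01)


def test_scan_recovery_rate_across_replicates():
    """Planted q=0.05 lethal at census scale is found in >=9/10 seeds."""
    from recscan import PlantedHaplotype, SimConfig, simulate_panel

    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        allele = "".join(rng.integers(0, 2, 30).astype(str))
        planted = PlantedHaplotype("1", (300, 330), allele, 0.05, "embryonic", 1.0)
        cfg = SimConfig(
            n_samples=4843, n_chromosomes=1, markers_per_chromosome=1000,
            risk_haplotypes=(planted,), seed=1000 + seed,
        )
        panel, truth = simulate_panel(cfg)
        regions = merge_regions(scan(panel, fdr=0.05), panel)
        t = truth[0]
        hits += any(
            r.start_pos <= t.end_pos and r.end_pos >= t.start_pos for r in regions
        )
    assert hits >= 9
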