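"""Readers and writers for the file formats shared by all modules.

Phased VCF v4.2 (GT "0|1" style, biallelic sites only), sample-metadata
TSV, mating-records CSV, variant-table TSV, FASTA/GTF text, truth JSON and
the Table-style report TSVs. All interface coordinates are 1-based
inclusive (VCF/GTF convention); marker indices are half-open internally.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .prioritize import AnnotatedVariant
from .scan import PhasedPanel

log = logging.getLogger(__name__)


def write_vcf(panel: PhasedPanel, path) -> None:
    """Write a panel as phased VCF v4.2 (alleles A=0 / G=1)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=recscan\n")
        pos = panel.markers["pos"].to_numpy()
        for chrom in panel.chromosomes:
            lo, hi = panel.chrom_slice(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(pos[hi - 1]) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        hap = panel.haplotypes
        for j, (chrom, p, mid) in enumerate(
            panel.markers.itertuples(index=False, name=None)
        ):
            col = hap[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_samples)
            )
            fh.write(f"{chrom}\t{p}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> PhasedPanel:
    """Read a phased VCF into a panel via cyvcf2.

    Multi-allelic records and records with any unphased or missing
    genotype are rejected (counted in the log); the panel keeps only fully
    phased biallelic sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps = []
    n_multi = n_unphased = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        arr = v.genotype.array()  # (n, 3): allele_a, allele_b, phased flag
        if arr[:, :2].min() < 0 or not arr[:, 2].all():
            n_unphased += 1
            continue
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}"))
        haps.append(arr[:, :2].astype(np.uint8).reshape(-1))
    vcf.close()
    if n_multi or n_unphased:
        log.info("read_vcf rejected_multiallelic=%d rejected_unphased=%d", n_multi, n_unphased)
    if not rows:
        raise ValueError("no usable phased biallelic records in VCF")
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    hap = np.stack(haps, axis=1)
    return PhasedPanel(markers, samples, hap)


def write_sample_metadata(panel: PhasedPanel, truth, path) -> None:
    """Sample TSV with per-planted-haplotype carrier flags and copy numbers."""
    data = {"sample_id": panel.samples}
    for t in truth:
        name = t.haplotype.name
        carriers = set(t.carrier_samples)
        homs = set(t.homozygote_samples)
        data[f"carrier_{name}"] = [s in carriers for s in panel.samples]
        data[f"copies_{name}"] = [
            2 if s in homs else (1 if s in carriers else 0) for s in panel.samples
        ]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_matings(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_matings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cow_id", "sire_id", "days_to_2nd_ai", "sire_carrier", "cow_carrier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mating CSV lacks columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("empty mating-record CSV")
    return df


def write_variant_table(
    variants: Sequence[AnnotatedVariant], samples: Sequence[str], path
) -> None:
    meta_cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "prediction", "score"]
    rows = []
    for v in variants:
        gt = ["NA" if g < 0 else str(int(g)) for g in v.genotypes]
        rows.append(
            [v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence, v.prediction, v.score]
            + gt
        )
    pd.DataFrame(rows, columns=meta_cols + list(samples)).to_csv(
        path, sep="\t", index=False
    )


def read_variant_table(path) -> tuple[list[AnnotatedVariant], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "prediction", "score"]
    samples = [c for c in df.columns if c not in meta_cols]
    variants = []
    for _, row in df.iterrows():
        gt = np.array(
            [-1 if pd.isna(g) or g == "NA" else int(g) for g in row[samples]],
            dtype=np.int8,
        )
        variants.append(
            AnnotatedVariant(
                str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"],
                row["gene"], row["consequence"],
                None if pd.isna(row["prediction"]) else row["prediction"],
                None if pd.isna(row["score"]) else float(row["score"]),
                gt,
            )
        )
    return variants, samples


def write_truth_json(truth, path) -> None:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            from dataclasses import asdict

            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=default) + "\n")


def write_text(text: str, path) -> None:
    Path(path).write_text(text)


def write_run_log(out_dir, config: dict, counts: Optional[dict] = None) -> None:
    """Plain-text run log with machine-readable key=value lines."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [f"recscan_version={__version__}"]
    lines += [f"config.{k}={v}" for k, v in config.items()]
    lines += [f"count.{k}={v}" for k, v in (counts or {}).items()]
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")


def validate_inputs(
    vcf_path=None, matings_path=None, variants_path=None
) -> dict[str, object]:
    """Check readable inputs; summarize rejects; raise on zero usable records."""
    report: dict[str, object] = {}
    if vcf_path is not None:
        panel = read_vcf(vcf_path)
        report["vcf_samples"] = panel.n_samples
        report["vcf_markers"] = len(panel.markers)
    if matings_path is not None:
        df = read_matings(matings_path)
        report["mating_records"] = len(df)
        report["mating_unknown_carrier"] = int(
            (df["sire_carrier"].isna() | df["cow_carrier"].isna()).sum()
        )
    if variants_path is not None:
        variants, samples = read_variant_table(variants_path)
        if not variants:
            raise ValueError("variant table contains no records")
        report["variants"] = len(variants)
        report["variant_samples"] = len(samples)
    return report
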