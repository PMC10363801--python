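"""File formats and run configuration.

VCF is the canonical genotype interchange (biallelic SNPs, GT field,
``chr2``/``chr3``-style contigs with declared lengths); PLINK PED/MAP pairs
are written for cross-checks against the tooling commonly used for these
analyses. Phenotypes, pedigrees, per-individual F tables and ROH segment
tables travel as headered TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .genome import Chromosome, GenomeConfig, MutationModel
from .roh import ROHParams, ROHResult

logger = logging.getLogger("inbreedkit")

__all__ = [
    "read_vcf",
    "write_vcf",
    "write_plink_pedmap",
    "read_plink_pedmap",
    "write_phenotypes",
    "write_pedigree",
    "write_f_table",
    "write_segments",
    "RunConfig",
    "load_config",
]


def read_vcf(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    """Read biallelic SNP genotypes from a VCF.

    Returns ``(dosages, chrom, pos, samples, n_skipped)`` where dosages count
    ALT alleles (float matrix, nan = missing) and multiallelic or non-SNP
    records are skipped and counted.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    chroms = []
    positions = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            skipped += 1
            continue
        gt = variant.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    X = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return (
        X,
        np.asarray(chroms, dtype=object),
        np.asarray(positions, dtype=np.int64),
        samples,
        skipped,
    )


def write_vcf(
    path,
    dosages: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    samples: list[str],
    contig_lengths: dict[str, int] | None = None,
    ref: str = "A",
    alt: str = "C",
) -> None:
    """Write an ALT-dosage matrix as an uncompressed VCF 4.2 with GT only."""
    X = np.asarray(dosages, dtype=float)
    if X.shape != (len(samples), len(pos)):
        raise ValueError("dosage matrix shape mismatch")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=inbreedkit\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for k in range(len(pos)):
            calls = "\t".join(
                gt_map.get(X[i, k], "./.") if np.isfinite(X[i, k]) else "./."
                for i in range(len(samples))
            )
            fh.write(
                f"{chrom[k]}\t{pos[k]}\tsnp{k}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


_PED_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "C"), 2.0: ("C", "C")}


def write_plink_pedmap(
    dosages: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    samples: list[str],
    ped_path,
    map_path,
) -> None:
    """PED (one row per individual, two allele columns per SNP; missing =
    ``0 0``) and MAP (chrom, id, 0, bp) files consistent with the matrix."""
    X = np.asarray(dosages, dtype=float)
    with open(map_path, "w") as fh:
        for k in range(len(pos)):
            fh.write(f"{chrom[k]}\tsnp{k}\t0\t{pos[k]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(samples):
            cols = [sid, sid, "0", "0", "0", "-9"]
            for k in range(len(pos)):
                a, b = (
                    _PED_ALLELES.get(X[i, k], ("0", "0"))
                    if np.isfinite(X[i, k])
                    else ("0", "0")
                )
                cols.extend((a, b))
            fh.write("\t".join(cols) + "\n")


def read_plink_pedmap(ped_path, map_path):
    """Inverse of :func:`write_plink_pedmap` (ALT = ``C`` counted)."""
    mp = pd.read_csv(
        map_path, sep="\t", header=None, names=["chrom", "id", "cm", "pos"]
    )
    dosages = []
    samples = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            alleles = parts[6:]
            row = np.empty(len(alleles) // 2)
            for k in range(len(alleles) // 2):
                a, b = alleles[2 * k], alleles[2 * k + 1]
                row[k] = np.nan if "0" in (a, b) else (a == "C") + (b == "C")
            dosages.append(row)
    return (
        np.asarray(dosages),
        mp["chrom"].to_numpy(dtype=object),
        mp["pos"].to_numpy(np.int64),
        samples,
    )


def write_phenotypes(records, path) -> None:
    rows = [
        {
            "pair_id": r.pair_id,
            "scheme": r.scheme,
            "P": r.p,
            "W": "" if r.w is None else r.w,
            "sequenced_designate": int(r.sequenced_designate),
            "contributing_parents": ",".join(r.contributing_parent_ids),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pedigree(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_f_table(frame: pd.DataFrame, path) -> None:
    """Per-individual F table: id, group, F_YAN, F_ROH-0.1, F_ROH-1."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_segments(results: dict[str, ROHResult], path) -> None:
    """Segment table: id, chrom, start, end, kb, n_snps (Table-2 style)."""
    rows = []
    for sid, res in results.items():
        for seg in res.segments:
            rows.append(
                {
                    "id": sid,
                    "chrom": seg.chrom,
                    "start": seg.start_bp,
                    "end": seg.end_bp,
                    "kb": seg.length_kb,
                    "n_snps": seg.n_snps,
                }
            )
    pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "kb", "n_snps"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see ``load_config``)."""

    genome: GenomeConfig
    mutation: MutationModel
    n_base: int
    burn_in: int
    n_pairs: int
    n_sequenced: int
    group_size: int
    marker_count: int | None
    roh: ROHParams
    l_auto: int
    maf_min: float
    ld_window: int
    ld_step: int
    ld_r2: float
    n_boot: int
    n_perm: int
    seed: int


_BLOCK_KEYS = {
    "genome": {"chromosomes", "male_recombination", "l_auto"},
    "mutation": {"u", "mean_s", "lethal_rate", "lethal_h"},
    "scheme": {"n_base", "burn_in", "n_pairs", "n_sequenced", "group_size", "marker_count"},
    "estimator": {
        "roh",
        "maf_min",
        "ld_window",
        "ld_step",
        "ld_r2",
    },
    "inference": {"n_boot", "n_perm"},
}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys(raw, set(_BLOCK_KEYS) | {"seed"}, "top level")
    g = raw.get("genome", {})
    _check_keys(g, _BLOCK_KEYS["genome"], "genome")
    chroms = tuple(
        Chromosome(int(c["length_bp"]), float(c["morgans"]))
        for c in g.get(
            "chromosomes",
            [{"length_bp": 60_000_000, "morgans": 1.08},
             {"length_bp": 59_000_000, "morgans": 1.07}],
        )
    )
    genome = GenomeConfig(
        chromosomes=chroms,
        male_recombination=bool(g.get("male_recombination", False)),
        l_auto=g.get("l_auto"),
    )
    mu = raw.get("mutation", {})
    _check_keys(mu, _BLOCK_KEYS["mutation"], "mutation")
    mutation = MutationModel(
        u=float(mu.get("u", 0.061)),
        mean_s=float(mu.get("mean_s", 0.11)),
        lethal_rate=float(mu.get("lethal_rate", 0.015)),
        lethal_h=float(mu.get("lethal_h", 0.02)),
    )
    sc = raw.get("scheme", {})
    _check_keys(sc, _BLOCK_KEYS["scheme"], "scheme")
    est = raw.get("estimator", {})
    _check_keys(est, _BLOCK_KEYS["estimator"], "estimator")
    roh_block = est.get("roh", {})
    _check_keys(roh_block, {f.name for f in fields(ROHParams)}, "estimator.roh")
    inf = raw.get("inference", {})
    _check_keys(inf, _BLOCK_KEYS["inference"], "inference")
    return RunConfig(
        genome=genome,
        mutation=mutation,
        n_base=int(sc.get("n_base", 200)),
        burn_in=int(sc.get("burn_in", 100)),
        n_pairs=int(sc.get("n_pairs", 20)),
        n_sequenced=int(sc.get("n_sequenced", 5)),
        group_size=int(sc.get("group_size", 4)),
        marker_count=sc.get("marker_count"),
        roh=ROHParams(**roh_block),
        l_auto=int(genome.l_auto),
        maf_min=float(est.get("maf_min", 0.0)),
        ld_window=int(est.get("ld_window", 50)),
        ld_step=int(est.get("ld_step", 5)),
        ld_r2=float(est.get("ld_r2", 0.9)),
        n_boot=int(inf.get("n_boot", 10_000)),
        n_perm=int(inf.get("n_perm", 10_000)),
        seed=int(raw.get("seed", 0)),
    )
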