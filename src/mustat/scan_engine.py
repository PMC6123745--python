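"""Scan orchestration and the command-line interface.

``run_scan`` drives the two-step loop per dataset — fetch SNPs into the
pattern pool and chunk until the pool fills, compute the pending windows,
relocate the window tail, repeat — and writes the report and info files.

CLI::

    mustat scan -n RUN -I input.ms -L 100000 [-w 50] [-k 1.0] [-X mask.bed]
                [-O] [-s] [--impute-missing] [--format auto|ms|vcf]
    mustat fixtures -o out.ms [--sweep] [-S 20] [-D 1000] [-L 100000] [--seed 7] ...

Exit codes: 0 success, 1 parse/configuration error, 2 I/O error.
"""

from __future__ import annotations

import argparse
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import fixtures as fx
from .io_formats import (
    ParseError,
    flatten_mask,
    read_bed_mask,
    read_ms,
    read_vcf,
    write_info,
    write_report,
)
from .mu_statistic import ChunkedScanner, MuScore, ScanConfig
from .snp_core import (
    DEFAULT_POOL_BUDGET,
    ConfigurationError,
    Dataset,
    InputError,
    filter_monomorphic,
)

logger = logging.getLogger("mustat")


@dataclass
class RunConfig:
    run_name: str
    input_path: str
    input_format: str = "auto"  # auto | ms | vcf
    window_size: int = 50
    k: float = 1.0
    region_length: Optional[int] = None
    mask_path: Optional[str] = None
    out_dir: str = "."
    per_dataset_reports: bool = False
    separators: bool = True
    impute_missing: bool = False
    pool_budget: int = DEFAULT_POOL_BUDGET

    def __post_init__(self) -> None:
        if not self.run_name:
            raise ConfigurationError("run_name must be non-empty")


@dataclass
class ScanResult:
    name: str
    scores: list[MuScore]
    snp_count: int
    region_length: int
    monomorphic_removed: int = 0


def _resolve_format(config: RunConfig) -> str:
    if config.input_format != "auto":
        return config.input_format
    suffixes = "".join(Path(config.input_path).suffixes).lower()
    return "vcf" if ".vcf" in suffixes else "ms"


def _load_datasets(config: RunConfig) -> tuple[list[Dataset], dict]:
    fmt = _resolve_format(config)
    meta: dict = {"input": config.input_path, "format": fmt}
    if fmt == "ms":
        if not config.region_length:
            raise ConfigurationError("ms input requires a region length (-L)")
        datasets = list(read_ms(config.input_path, config.region_length))
        meta["region_length"] = config.region_length
    else:
        per_chrom = read_vcf(
            config.input_path,
            strict_missing=not config.impute_missing,
            region_length=config.region_length,
        )
        datasets = [v.dataset for v in per_chrom]
        meta["sites_dropped_missing"] = sum(v.dropped_missing for v in per_chrom)
        meta["sites_skipped_non_biallelic"] = sum(
            v.skipped_non_biallelic for v in per_chrom
        )
    return datasets, meta


def scan_dataset(
    dataset: Dataset, scan_config: ScanConfig, pool_budget: int = DEFAULT_POOL_BUDGET
) -> ScanResult:
    """Filter, stream through the chunked scanner, and summarise one dataset."""
    filtered, removed = filter_monomorphic(dataset)
    scanner = ChunkedScanner(
        filtered.sample_count if filtered.snp_count else dataset.sample_count,
        scan_config.region_length or filtered.region_length,
        scan_config,
        pool_budget=pool_budget,
    )
    scores: list[MuScore] = []
    counts = filtered.derived_counts
    for i in range(filtered.snp_count):
        scores.extend(
            scanner.push(
                filtered.genotypes[i], int(filtered.locations[i]), int(counts[i])
            )
        )
    scores.extend(scanner.finish())
    return ScanResult(
        name=dataset.name,
        scores=scores,
        snp_count=filtered.snp_count,
        region_length=scan_config.region_length or filtered.region_length,
        monomorphic_removed=removed,
    )


def run_scan(config: RunConfig) -> list[ScanResult]:
    """Scan every dataset in the input and write report + info files."""
    datasets, meta = _load_datasets(config)
    mask: Sequence[tuple[int, int]] = ()
    if config.mask_path:
        mask = flatten_mask(read_bed_mask(config.mask_path))
    results = []
    for ds in datasets:
        scan_config = ScanConfig(
            window_size=config.window_size,
            k=config.k,
            region_length=config.region_length or ds.region_length,
            mask=mask,
        )
        result = scan_dataset(ds, scan_config, pool_budget=config.pool_budget)
        if not result.scores:
            logger.warning(
                "dataset %s: %d SNPs after filtering, fewer than window size %d",
                ds.name,
                result.snp_count,
                config.window_size,
            )
        results.append(result)
    write_report(
        [r.scores for r in results],
        config.run_name,
        config.out_dir,
        per_dataset=config.per_dataset_reports,
        separators=config.separators,
    )
    meta.update(
        {
            "run_name": config.run_name,
            "window_size": config.window_size,
            "k": config.k,
            "datasets": len(results),
            "samples": datasets[0].sample_count if datasets else 0,
            "snps_per_dataset": ",".join(str(r.snp_count) for r in results),
            "monomorphic_removed": sum(r.monomorphic_removed for r in results),
            "scores_per_dataset": ",".join(str(len(r.scores)) for r in results),
        }
    )
    write_info(meta, config.run_name, config.out_dir)
    return results


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="mustat",
        description="Selective-sweep scans with the composite mu statistic",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    scan = sub.add_parser("scan", help="scan an ms or VCF input file")
    scan.add_argument("-n", "--name", required=True, help="run name")
    scan.add_argument("-I", "--input", required=True, help="input file path")
    scan.add_argument(
        "-L", "--length", type=int, default=None, help="region length in bp (ms input)"
    )
    scan.add_argument("-w", "--window", type=int, default=50, help="window size (SNPs)")
    scan.add_argument(
        "-k", type=float, default=1.0, help="exponent on the diversity factor"
    )
    scan.add_argument("-X", "--mask", default=None, help="BED mask of excluded regions")
    scan.add_argument(
        "-O",
        "--per-dataset",
        action="store_true",
        help="one report file per dataset",
    )
    scan.add_argument(
        "-s",
        "--no-separators",
        action="store_true",
        help="suppress '//' dataset separators in the single report",
    )
    scan.add_argument(
        "--format", choices=("auto", "ms", "vcf"), default="auto", dest="fmt"
    )
    missing = scan.add_mutually_exclusive_group()
    missing.add_argument(
        "--strict-missing",
        action="store_true",
        help="drop VCF sites with missing alleles (default)",
    )
    missing.add_argument(
        "--impute-missing",
        action="store_true",
        help="treat missing VCF alleles as ancestral",
    )
    scan.add_argument("--out-dir", default=".", help="output directory")

    fixt = sub.add_parser("fixtures", help="write a synthetic ms-format fixture")
    fixt.add_argument("-o", "--output", required=True, help="output ms file")
    fixt.add_argument("-S", "--samples", type=int, default=20)
    fixt.add_argument("-D", "--snps", type=int, default=1000)
    fixt.add_argument("-L", "--length", type=int, default=100_000)
    fixt.add_argument("--seed", type=int, default=0)
    fixt.add_argument("--replicates", type=int, default=1)
    fixt.add_argument("--sweep", action="store_true", help="embed sweep signatures")
    fixt.add_argument("--center", type=int, default=None, help="sweep center (bp)")
    fixt.add_argument("--density-drop", type=float, default=4.0)
    fixt.add_argument("--sfs-skew", type=float, default=0.7)
    fixt.add_argument("--homogeneity", type=float, default=0.85)
    return parser


def _cmd_scan(args: argparse.Namespace) -> int:
    config = RunConfig(
        run_name=args.name,
        input_path=args.input,
        input_format=args.fmt,
        window_size=args.window,
        k=args.k,
        region_length=args.length,
        mask_path=args.mask,
        out_dir=args.out_dir,
        per_dataset_reports=args.per_dataset,
        separators=not args.no_separators,
        impute_missing=args.impute_missing,
    )
    results = run_scan(config)
    logger.info(
        "scanned %d dataset(s); %d scores total",
        len(results),
        sum(len(r.scores) for r in results),
    )
    return 0


def _cmd_fixtures(args: argparse.Namespace) -> int:
    from .io_formats import write_ms

    sweep = (
        fx.SweepSpec(
            center_bp=args.center,
            density_drop=args.density_drop,
            sfs_skew=args.sfs_skew,
            flank_pattern_homogeneity=args.homogeneity,
        )
        if args.sweep
        else None
    )
    datasets = []
    for rep in range(args.replicates):
        spec = fx.FixtureSpec(
            sample_count=args.samples,
            snp_count=args.snps,
            region_length=args.length,
            seed=args.seed + rep,
            sweep=sweep,
        )
        datasets.append(fx.generate(spec)[0])
    with open(args.output, "wt") as fh:
        write_ms(datasets, fh)
    logger.info("wrote %d replicate(s) to %s", len(datasets), args.output)
    return 0


def main(argv: Sequence[str] | None = None) -> int:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    parser = _build_parser()
    args = parser.parse_args(argv)
    try:
        if args.command == "scan":
            return _cmd_scan(args)
        return _cmd_fixtures(args)
    except (ParseError, ConfigurationError, InputError) as exc:
        logger.error("error: %s", exc)
        return 1
    except OSError as exc:
        logger.error("I/O error: %s", exc)
        return 2


if __name__ == "__main__":
    sys.exit(main())
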