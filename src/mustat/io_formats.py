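"""Readers and writers: ms-format and VCF input, TSV report and info output.

ms input is the Hudson coalescent-simulator dialect: replicates delimited by
``//`` lines, a ``segsites: n`` header, a ``positions:`` line of unit-interval
fractions, then one 0/1 haplotype row per sample.  Positions are scaled to bp
by a caller-supplied region length (nearest integer, halves up, clamped to
>= 1); duplicate bp locations after rounding are retained, since dropping
them would change the SNP count and hence the number of emitted windows.

VCF input keeps biallelic single-base SNP records only; each diploid genotype
contributes two haplotypes in written order, ALT is treated as derived (an
``AA`` INFO key can repolarize), and sites with missing alleles are dropped in
strict mode or imputed as ancestral on request.

Report files follow the ``RAiSD_Report.<run>`` naming convention of the
original C scanner so existing downstream scripts keep working.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import pandas as pd

from .mu_statistic import MuScore
from .snp_core import Dataset, InputError

REPORT_COLUMNS = [
    "position",
    "window_start",
    "window_end",
    "mu_var",
    "mu_sfs",
    "mu_ld",
    "mu",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _open_lines(source: str | Path | TextIO):
    if isinstance(source, (str, Path)):
        handle = open(source, "rt")
        return handle, True
    return source, False


def scale_position(fraction: float, region_length: int) -> int:
    """Unit-interval position -> 1-based bp: nearest integer, halves up, >= 1."""
    return max(1, int(np.floor(fraction * region_length + 0.5)))


def read_ms(
    source: str | Path | TextIO, region_length: int, name: str = ""
) -> Iterator[Dataset]:
    """Yield one :class:`Dataset` per ms replicate.

    The sample count is inferred from the first replicate's row count and
    enforced for the rest.  ``segsites: 0`` yields an empty dataset.
    """
    if region_length <= 0:
        raise InputError("region_length must be positive for ms input")
    handle, owns = _open_lines(source)
    expected_s: int | None = None

    def parse_error(msg: str, lineno: int) -> ParseError:
        return ParseError(msg, lineno)

    try:
        rep_index = 0
        it = enumerate(handle, start=1)
        lineno = 0
        line = ""

        def nextline() -> tuple[int, str] | None:
            try:
                return next(it)
            except StopIteration:
                return None

        # Skip preamble until the first replicate delimiter.
        current = nextline()
        while current is not None:
            lineno, line = current
            if not line.strip().startswith("//"):
                current = nextline()
                continue
            # --- one replicate ---
            current = nextline()
            while current is not None and not current[1].strip():
                current = nextline()
            if current is None:
                raise parse_error("replicate truncated before 'segsites'", lineno)
            lineno, line = current
            if not line.strip().startswith("segsites:"):
                raise parse_error(f"expected 'segsites:', got {line.strip()!r}", lineno)
            try:
                segsites = int(line.split(":", 1)[1])
            except ValueError:
                raise parse_error("unparseable segsites count", lineno) from None
            positions: list[float] = []
            rows: list[str] = []
            if segsites > 0:
                current = nextline()
                while current is not None and not current[1].strip():
                    current = nextline()
                if current is None or not current[1].strip().startswith("positions:"):
                    raise parse_error(
                        "expected 'positions:' line", current[0] if current else lineno
                    )
                lineno, line = current
                try:
                    positions = [float(tok) for tok in line.split(":", 1)[1].split()]
                except ValueError:
                    raise parse_error("unparseable position value", lineno) from None
                if len(positions) != segsites:
                    raise parse_error(
                        f"{len(positions)} positions for segsites={segsites}", lineno
                    )
                current = nextline()
                while current is not None:
                    lineno, line = current
                    text = line.strip()
                    if not text or text.startswith("//"):
                        break
                    if set(text) - {"0", "1"}:
                        raise parse_error(
                            "haplotype row contains non-binary characters", lineno
                        )
                    if len(text) != segsites:
                        raise parse_error(
                            f"row length {len(text)} != segsites {segsites}", lineno
                        )
                    rows.append(text)
                    current = nextline()
            else:
                current = nextline()
            if segsites > 0:
                if expected_s is None:
                    expected_s = len(rows)
                    if expected_s == 0:
                        raise parse_error("replicate has no haplotype rows", lineno)
                elif len(rows) != expected_s:
                    raise parse_error(
                        f"replicate {rep_index} has {len(rows)} rows, expected "
                        f"{expected_s}",
                        lineno,
                    )
                matrix = np.frombuffer(
                    "".join(rows).encode("ascii"), dtype=np.uint8
                ).reshape(len(rows), segsites) - ord("0")
                locations = np.array(
                    [scale_position(p, region_length) for p in positions], dtype=np.int64
                )
                genotypes = np.ascontiguousarray(matrix.T)
            else:
                s = expected_s or 0
                genotypes = np.zeros((0, s), dtype=np.uint8)
                locations = np.zeros(0, dtype=np.int64)
            yield Dataset(
                genotypes=genotypes,
                locations=locations,
                region_length=region_length,
                name=f"{name or 'ms'}.{rep_index}",
            )
            rep_index += 1
            # `current` already sits on the next '//' (or trailing content).
            while current is not None and not current[1].strip().startswith("//"):
                current = nextline()
    finally:
        if owns:
            handle.close()


def write_ms(
    datasets: Iterable[Dataset], stream: TextIO, command_line: str = "mustat fixtures"
) -> None:
    """Write datasets as an ms-dialect file (positions as fractions of the
    region length, printed with enough digits to round-trip the bp integers)."""
    datasets = list(datasets)
    if not datasets:
        raise InputError("nothing to write")
    s = datasets[0].sample_count
    stream.write(f"{command_line} {s} {len(datasets)}\n0 0 0\n")
    for ds in datasets:
        stream.write("\n//\n")
        stream.write(f"segsites: {ds.snp_count}\n")
        if ds.snp_count:
            fractions = " ".join(
                f"{loc / ds.region_length:.10f}" for loc in ds.locations
            )
            stream.write(f"positions: {fractions}\n")
            for row in ds.genotypes.T:
                stream.write("".join("1" if a else "0" for a in row) + "\n")


def ms_text(datasets: Iterable[Dataset]) -> str:
    buf = io.StringIO()
    write_ms(datasets, buf)
    return buf.getvalue()


@dataclass
class VcfDataset:
    """One chromosome's worth of haplotype columns plus parsing tallies."""

    chrom: str
    dataset: Dataset
    dropped_missing: int = 0
    skipped_non_biallelic: int = 0


def read_vcf(
    path: str | Path,
    strict_missing: bool = True,
    region_length: int | None = None,
    ancestral_key: str | None = None,
) -> list[VcfDataset]:
    """Read biallelic SNPs from a VCF into per-chromosome datasets.

    Each diploid sample contributes two haplotypes (alleles in written order —
    arbitrary for unphased heterozygotes, but deterministic).  ALT is derived
    unless ``ancestral_key`` names an INFO field whose value equals ALT, in
    which case the site is repolarized.  ``region_length`` defaults to the
    maximum POS seen on the chromosome.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    per_chrom: dict[str, dict[str, list]] = {}
    for variant in vcf:
        chrom = variant.CHROM
        buckets = per_chrom.setdefault(
            chrom,
            {"cols": [], "locs": [], "dropped": [0], "skipped": [0], "maxpos": [0]},
        )
        buckets["maxpos"][0] = max(buckets["maxpos"][0], variant.POS)
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF not in "ACGT"
            or variant.ALT[0] not in "ACGT"
        ):
            buckets["skipped"][0] += 1
            continue
        gts = variant.genotypes  # [[a1, a2, phased], ...]
        hap = []
        missing = False
        for g in gts:
            for allele in g[:-1]:
                if allele < 0:
                    missing = True
                    allele = 0  # ancestral fill (used only when imputing)
                hap.append(allele)
        if missing and strict_missing:
            buckets["dropped"][0] += 1
            continue
        column = np.asarray(hap, dtype=np.uint8)
        if ancestral_key is not None:
            aa = variant.INFO.get(ancestral_key)
            if aa is not None and str(aa).upper() == variant.ALT[0]:
                column = 1 - column
        buckets["cols"].append(column)
        buckets["locs"].append(variant.POS)
    out = []
    for chrom, b in per_chrom.items():
        n = len(b["cols"])
        length = region_length or max(b["maxpos"][0], 1)
        genotypes = (
            np.vstack(b["cols"]) if n else np.zeros((0, 0), dtype=np.uint8)
        )
        out.append(
            VcfDataset(
                chrom=chrom,
                dataset=Dataset(
                    genotypes=genotypes,
                    locations=np.asarray(b["locs"], dtype=np.int64),
                    region_length=length,
                    name=chrom,
                ),
                dropped_missing=b["dropped"][0],
                skipped_non_biallelic=b["skipped"][0],
            )
        )
    return out


def _format_record(score: MuScore) -> str:
    return "\t".join(
        [
            f"{score.position:.2f}",
            str(score.window_first_bp),
            str(score.window_last_bp),
            f"{score.mu_var:.8e}",
            f"{score.mu_sfs:.8e}",
            f"{score.mu_ld:.8e}",
            f"{score.mu:.8e}",
        ]
    )


def report_paths(
    run_name: str, out_dir: str | Path = ".", n_datasets: int = 1, per_dataset: bool = False
) -> list[Path]:
    out_dir = Path(out_dir)
    if per_dataset:
        return [out_dir / f"RAiSD_Report.{run_name}.{i}" for i in range(n_datasets)]
    return [out_dir / f"RAiSD_Report.{run_name}"]


def write_report(
    score_blocks: Sequence[Sequence[MuScore]],
    run_name: str,
    out_dir: str | Path = ".",
    per_dataset: bool = False,
    separators: bool = True,
) -> list[Path]:
    """Write score blocks as tab-separated report file(s).

    Masked windows are suppressed.  In single-file mode with separators on, a
    ``// <index>`` line precedes each dataset's block.
    """
    import warnings

    if not any(len(block) for block in score_blocks):
        warnings.warn("no scores to report", stacklevel=2)
    paths = report_paths(run_name, out_dir, len(score_blocks), per_dataset)
    if per_dataset:
        for path, block in zip(paths, score_blocks):
            with open(path, "wt") as fh:
                for score in block:
                    if not score.masked:
                        fh.write(_format_record(score) + "\n")
    else:
        with open(paths[0], "wt") as fh:
            for i, block in enumerate(score_blocks):
                if separators:
                    fh.write(f"// {i}\n")
                for score in block:
                    if not score.masked:
                        fh.write(_format_record(score) + "\n")
    return paths


def read_report(path: str | Path) -> list[pd.DataFrame]:
    """Read a report back into one DataFrame per dataset block."""
    blocks: list[list[str]] = []
    current: list[str] = []
    started = False
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("//"):
                if started:
                    blocks.append(current)
                current = []
                started = True
            elif line.strip():
                current.append(line)
    blocks.append(current)
    frames = []
    for block in blocks:
        if block:
            frames.append(
                pd.read_csv(
                    io.StringIO("".join(block)),
                    sep="\t",
                    names=REPORT_COLUMNS,
                    header=None,
                )
            )
        else:
            frames.append(pd.DataFrame(columns=REPORT_COLUMNS))
    return frames


def write_info(metadata: dict, run_name: str, out_dir: str | Path = ".") -> Path:
    """Persist run metadata (sample counts, window size, drop tallies, ...)
    as free-text ``key: value`` lines."""
    path = Path(out_dir) / f"RAiSD_Info.{run_name}"
    with open(path, "wt") as fh:
        for key, value in metadata.items():
            fh.write(f"{key}: {value}\n")
    return path


def read_bed_mask(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file (0-based half-open) into per-chromosome 1-based
    inclusive bp intervals suitable for :class:`ScanConfig.mask`."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    mask: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        mask.setdefault(row.chrom, []).append((int(row.start) + 1, int(row.end)))
    return mask


def flatten_mask(mask: dict[str, list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Union of all chromosomes' intervals (for chromosome-less ms input)."""
    return [iv for ivs in mask.values() for iv in ivs]
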