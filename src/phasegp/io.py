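"""Reading, writing and quality filtering of genotype/phenotype data.

Supported genotype formats: VCF 4.2 (GT + optional DP), HapMap-like TSV
(``rs, alleles, chrom, pos`` then one column per sample, two-letter
genotype calls) and plain dosage CSV (header row of marker IDs, first
column sample IDs, missing as ``NA``).

The post-calling quality filters follow the standard GBS recipe: read-depth
masking, per-marker and per-sample missingness caps, and a minor-allele
frequency floor, applied in that fixed order.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, MarkerInfo, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_matrix",
    "minor_allele_freq",
    "genotype_means",
    "FilterReport",
    "EmptyMatrixError",
    "GenotypeParseError",
]


class EmptyMatrixError(ValueError):
    """All markers (or samples) were removed by filtering."""


class GenotypeParseError(ValueError):
    """A genotype file record could not be interpreted."""


# Tassel-style (S1_12345) and colon-style (1:12345) marker names carry the
# map position; used to recover coordinates from plain dosage CSVs.
_ID_PATTERNS = (re.compile(r"^S([\w.]+)_(\d+)$"), re.compile(r"^([\w.]+):(\d+)$"))


def _marker_from_id(marker_id: str, column_index: int) -> MarkerInfo:
    for pat in _ID_PATTERNS:
        m = pat.match(marker_id)
        if m:
            return MarkerInfo(marker_id, m.group(1), int(m.group(2)))
    return MarkerInfo(marker_id, "0", column_index + 1)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, HapMap TSV or dosage CSV.

    Dosages are the count of the alternate allele.  Multi-allelic or
    non-SNP records are dropped with a logged count.  Markers are returned
    sorted by (chromosome, position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".csv": "csv", ".hmp": "hapmap",
                  ".tsv": "hapmap", ".txt": "hapmap"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if format == "vcf":
        geno = _read_vcf(path)
    elif format == "hapmap":
        geno = _read_hapmap(path)
    elif format == "csv":
        geno = _read_csv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if not geno.is_sorted():
        geno = geno.sort_markers()
    return geno


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0,1,2 dosage; 3 unknown
    samples = list(vcf.samples)
    markers: list[MarkerInfo] = []
    rows: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    have_depth = False
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        rows.append(gt)
        dp = var.gt_depths
        if dp is not None and not np.all(dp < 0):
            have_depth = True
        depths.append(np.maximum(np.asarray(dp, dtype=np.int32), 0)
                      if dp is not None else np.zeros(len(samples), np.int32))
        mid = var.ID if var.ID not in (None, ".") else f"S{var.CHROM}_{var.POS}"
        markers.append(MarkerInfo(mid, str(var.CHROM), int(var.POS),
                                  var.REF, var.ALT[0]))
    vcf.close()
    if n_dropped:
        logger.info("read_genotypes: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not markers:
        raise GenotypeParseError(f"{path}: no biallelic SNP records")
    dosages = np.column_stack(rows)
    depth = np.column_stack(depths) if have_depth else None
    return GenotypeMatrix(samples, markers, dosages, depth)


def _read_hapmap(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rs", "alleles", "chrom", "pos"]
    lowered = {c.lower().lstrip("#"): c for c in df.columns}
    if not all(r in lowered for r in required):
        raise GenotypeParseError(f"{path}: HapMap header must contain {required}")
    meta_cols = [lowered[r] for r in required]
    known_meta = {"rs", "alleles", "chrom", "pos", "strand", "assembly",
                  "center", "protlsid", "assaylsid", "panellsid", "qccode"}
    sample_cols = [c for c in df.columns
                   if c.lower().lstrip("#") not in known_meta]
    markers, rows = [], []
    for i, rec in df.iterrows():
        alleles = str(rec[lowered["alleles"]]).split("/")
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            logger.info("hapmap: skipping non-biallelic marker %s", rec[lowered["rs"]])
            continue
        ref, alt = alleles
        try:
            pos = int(rec[lowered["pos"]])
        except (TypeError, ValueError) as exc:
            raise GenotypeParseError(f"{path} line {i + 2}: bad position") from exc
        markers.append(MarkerInfo(str(rec[lowered["rs"]]),
                                  str(rec[lowered["chrom"]]), pos, ref, alt))
        row = np.empty(len(sample_cols), dtype=np.int16)
        for k, c in enumerate(sample_cols):
            call = str(rec[c])
            if call in ("NN", "N", "nan", "NA", ""):
                row[k] = MISSING
            elif len(call) == 2 and set(call) <= {ref, alt}:
                row[k] = call.count(alt)
            else:
                raise GenotypeParseError(
                    f"{path} line {i + 2}: genotype {call!r} not in {{{ref},{alt}}}"
                )
        rows.append(row)
    if not markers:
        raise GenotypeParseError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(sample_cols, markers, np.column_stack(rows))


def _read_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    samples = [str(s) for s in df.index]
    markers = [_marker_from_id(str(c), j) for j, c in enumerate(df.columns)]
    dosages = df.to_numpy(dtype=float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: non-dosage value {dosages[i, j]!r} at sample "
            f"{samples[i]}, marker {df.columns[j]}"
        )
    out = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int16)
    return GenotypeMatrix(samples, markers, out)


def write_genotypes(geno: GenotypeMatrix, path: str | Path,
                    format: str | None = None) -> None:
    """Write a genotype matrix as VCF 4.2 or dosage CSV."""
    path = Path(path)
    if format is None:
        format = {".vcf": "vcf", ".csv": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "vcf":
        _write_vcf(geno, path)
    elif format == "csv":
        _write_csv(geno, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(geno: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if geno.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        fmt = "GT:DP" if geno.depth is not None else "GT"
        for j, mk in enumerate(geno.markers):
            calls = []
            for i in range(geno.n_samples):
                gt = _GT_CODE[int(geno.dosages[i, j])]
                if geno.depth is not None:
                    gt = f"{gt}:{int(geno.depth[i, j])}"
                calls.append(gt)
            fh.write(f"{mk.chromosome}\t{mk.position}\t{mk.marker_id}\t"
                     f"{mk.ref_allele}\t{mk.alt_allele}\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(calls) + "\n")


def _write_csv(geno: GenotypeMatrix, path: Path) -> None:
    vals = geno.dosages.astype(object)
    vals[geno.dosages == MISSING] = "NA"
    df = pd.DataFrame(vals, index=geno.samples, columns=geno.marker_ids)
    df.to_csv(path, index_label="sample")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a replicate-level phenotype CSV.

    Expected columns: ``genotype_id, locality, trait, replicate, value``;
    a missing ``replicate`` column defaults to 1 (genotype-level data).
    """
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Counts removed per rule during :func:`filter_matrix`."""

    n_markers_in: int
    n_samples_in: int
    entries_depth_masked: int = 0
    markers_removed_missing: int = 0
    samples_removed_missing: int = 0
    markers_removed_maf: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def minor_allele_freq(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker minor-allele frequency, folded to [0, 0.5].

    ``maf = min(p, 1-p)`` with ``p`` the alternate-allele frequency over
    non-missing calls.  Raises on an all-missing marker.
    """
    dosages = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    obs = dosages != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(f"marker column {j} has no non-missing calls")
    alt = np.where(obs, dosages, 0).sum(axis=0)
    p = alt / (2.0 * n_obs)
    return np.minimum(p, 1.0 - p)


def filter_matrix(
    geno: GenotypeMatrix,
    max_marker_missing: float = 0.20,
    max_sample_missing: float = 0.20,
    min_maf: float = 0.05,
    min_depth: int = 3,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the post-calling quality filters in a fixed order.

    Order: depth mask (entries with depth < ``min_depth`` set missing, only
    when a depth layer exists) -> marker missingness -> sample missingness
    -> MAF.  Returns the filtered matrix and a :class:`FilterReport`.
    """
    for name, thr in (("max_marker_missing", max_marker_missing),
                      ("max_sample_missing", max_sample_missing),
                      ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")

    report = FilterReport(
        n_markers_in=geno.n_markers,
        n_samples_in=geno.n_samples,
        thresholds={"max_marker_missing": max_marker_missing,
                    "max_sample_missing": max_sample_missing,
                    "min_maf": min_maf, "min_depth": min_depth},
    )
    g = geno.copy()

    # 1. depth mask
    if g.depth is not None and min_depth > 0:
        low = (g.depth < min_depth) & (g.dosages != MISSING)
        report.entries_depth_masked = int(low.sum())
        g.dosages[low] = MISSING
    elif min_depth > 0:
        logger.warning("filter_matrix: no depth layer; depth filter skipped")

    # 2. marker missingness
    miss_frac_m = (g.dosages == MISSING).mean(axis=0)
    keep_m = miss_frac_m <= max_marker_missing
    report.markers_removed_missing = int((~keep_m).sum())
    g = g.take_markers(np.flatnonzero(keep_m))
    if g.n_markers == 0:
        raise EmptyMatrixError("all markers removed by missingness filter")

    # 3. sample missingness
    miss_frac_s = (g.dosages == MISSING).mean(axis=1)
    keep_s = miss_frac_s <= max_sample_missing
    report.samples_removed_missing = int((~keep_s).sum())
    g = g.take_samples(np.flatnonzero(keep_s))
    if g.n_samples == 0:
        raise EmptyMatrixError("all samples removed by missingness filter")

    # 4. MAF floor (markers that became all-missing count as MAF 0)
    n_obs = (g.dosages != MISSING).sum(axis=0)
    alt = np.where(g.dosages != MISSING, g.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / np.maximum(2.0 * n_obs, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = 0.0
    keep_maf = maf >= min_maf
    report.markers_removed_maf = int((~keep_maf).sum())
    g = g.take_markers(np.flatnonzero(keep_maf))
    if g.n_markers == 0:
        raise EmptyMatrixError("all markers removed by MAF filter")

    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    logger.info(
        "filter_matrix: %d/%d markers, %d/%d samples retained",
        g.n_markers, report.n_markers_in, g.n_samples, report.n_samples_in,
    )
    return g, report


def genotype_means(pheno: PhenotypeTable) -> pd.DataFrame:
    """Replicate means per (genotype, locality, trait); see
    :meth:`PhenotypeTable.genotype_means`."""
    return pheno.genotype_means()
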