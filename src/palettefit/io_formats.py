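"""Readers and writers for the interchange formats the pipeline touches.

Conventions: physical positions (VCF, .bim) are 1-based bp; genetic
positions are cM from chromosome start; internal intervals are half-open
[start, end).  Palette files are tab-delimited with a header whose first
word is ``Recipient`` followed by donor-group names, matching
CHROMOPAINTER chunk-lengths output (whitespace-tolerant on read).
Missing genotypes are rejected: the copying model has no missingness
emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import QMatrix
from .painting import PaletteMatrix
from .simulate import SimulatedDataset

__all__ = [
    "LabelMap",
    "read_q_file",
    "write_q_file",
    "read_fam_labels",
    "write_fam",
    "read_bim_map",
    "write_bim",
    "read_chromopainter_matrix",
    "write_palette_matrix",
    "read_vcf_haplotypes",
    "write_vcf",
    "write_tracts",
    "read_tracts",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelMap:
    """Ordered individual id -> group label mapping."""

    ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")

    def __len__(self) -> int:
        return len(self.ids)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.labels))


# ---------------------------------------------------------------------------
# ADMIXTURE-style Q files
# ---------------------------------------------------------------------------

def read_q_file(path, individual_ids=None) -> QMatrix:
    """Read a whitespace-delimited N x K admixture-proportion file.

    Rows whose sums are off by at most 1e-3 are renormalized with a
    warning; larger deviations are an error.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            try:
                rows.append([float(x) for x in fields])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-numeric field ({e})") from None
    if not rows:
        raise ValueError(f"{path}: empty Q file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (column counts {sorted(widths)})")
    q = np.asarray(rows, dtype=float)
    sums = q.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > 1e-3 + 1e-12):
        bad = int(np.argmax(off)) + 1
        raise ValueError(f"{path}: row {bad} sums to {sums[bad - 1]:.6g} (off by > 1e-3)")
    if np.any(off > 1e-6):
        logger.warning("%s: renormalizing %d rows with sums off by up to %.2e",
                       path, int(np.sum(off > 1e-6)), float(off.max()))
        q = q / sums[:, None]
    n, k = q.shape
    ids = list(individual_ids) if individual_ids is not None else [f"ind{i}" for i in range(n)]
    return QMatrix(q, ids, [f"comp{j + 1}" for j in range(k)])


def write_q_file(qmat: QMatrix, path) -> None:
    np.savetxt(path, qmat.values, fmt="%.6f", delimiter=" ")


# ---------------------------------------------------------------------------
# PLINK .fam / .bim
# ---------------------------------------------------------------------------

def read_fam_labels(path) -> LabelMap:
    """Labels from a PLINK .fam file (family-ID column holds the group)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 6:
        raise ValueError(f"{path}: .fam must have 6 columns, found {df.shape[1]}")
    return LabelMap(ids=list(df[1]), labels=list(df[0]))


def write_fam(ids, labels, path) -> None:
    with open(path, "w") as fh:
        for i, l in zip(ids, labels):
            fh.write(f"{l} {i} 0 0 0 -9\n")


def read_bim_map(path):
    """Positions from a PLINK .bim file.

    Returns ``(chrom, bp, cm)`` arrays.  When the genetic-position column
    is all zero (common in practice) it falls back to a uniform
    1 cM/Mb map, with a log message.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] != 6:
        raise ValueError(f"{path}: .bim must have 6 columns, found {df.shape[1]}")
    chrom = df[0].to_numpy()
    cm = df[2].to_numpy(dtype=float)
    bp = df[3].to_numpy(dtype=np.int64)
    if np.all(cm == 0):
        logger.info("%s: genetic positions all zero; using 1 cM/Mb fallback", path)
        cm = bp * 1e-6
    return chrom, bp, cm


def write_bim(chrom, bp, cm, path) -> None:
    with open(path, "w") as fh:
        for c, b, g in zip(chrom, bp, cm):
            fh.write(f"{c} snp_{c}_{b} {g:.6f} {b} A G\n")


# ---------------------------------------------------------------------------
# palette matrices (CHROMOPAINTER chunk-lengths dialect)
# ---------------------------------------------------------------------------

def read_chromopainter_matrix(path) -> PaletteMatrix:
    """Read a palette/chunk matrix with a ``Recipient`` header row.

    Rows that sum to 1 (within 1e-6) are genome fractions; otherwise the
    payload is recorded as chunk counts (normalize on demand via
    :meth:`PaletteMatrix.normalized`).  Negative entries are an error.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"{path}: missing header row")
        donor_names = header[1:]
        ids, rows = [], []
        for ln, line in enumerate(fh, 2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{ln}: expected {len(header)} fields, found {len(fields)}"
                )
            ids.append(fields[0])
            try:
                row = [float(x) for x in fields[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-numeric entry ({e})") from None
            for j, v in enumerate(row):
                if v < 0:
                    raise ValueError(
                        f"{path}:{ln}: negative entry {v} for recipient "
                        f"{fields[0]!r}, donor {donor_names[j]!r}"
                    )
            rows.append(row)
    values = np.asarray(rows, dtype=float)
    sums = values.sum(axis=1)
    payload = "genome_fraction" if np.allclose(sums, 1.0, atol=1e-6) else "chunk_count"
    return PaletteMatrix(values, ids, donor_names, payload=payload)


def write_palette_matrix(pm: PaletteMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("Recipient\t" + "\t".join(pm.donor_groups) + "\n")
        for rid, row in zip(pm.recipient_ids, pm.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_haplotypes(path):
    """Phased haplotypes from a VCF with biallelic SNPs.

    Returns ``(haplotypes (2N, L) int8, chrom, positions_bp, sample_ids)``.
    Unphased, missing or multiallelic records are rejected with the site
    identified.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, chroms, pos = [], [], []
    for v in vcf:
        site = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ValueError(f"{path}: multiallelic record at {site}")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(f"{path}: missing genotype at {site}, sample {samples[i]}")
            if not phased:
                raise ValueError(f"{path}: unphased genotype at {site}, sample {samples[i]}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        cols.append(col)
        chroms.append(v.CHROM)
        pos.append(v.POS)
    if not cols:
        raise ValueError(f"{path}: no variant records")
    haps = np.stack(cols, axis=1)
    return haps, np.asarray(chroms), np.asarray(pos, dtype=np.int64), samples


def write_vcf(dataset: SimulatedDataset, path) -> None:
    """Write a dataset's phased haplotypes as an uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=palettefit\n")
        chrom_len = (int(round(dataset.config.chromosome_length_cm * 1e6))
                     if dataset.config else int(dataset.physical_pos.max()) + 1)
        for c in np.unique(dataset.chrom):
            fh.write(f"##contig=<ID={c},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.individual_ids) + "\n")
        h = dataset.haplotypes
        for j in range(dataset.n_sites):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
                            for i in range(dataset.n_individuals))
            fh.write(f"{dataset.chrom[j]}\t{dataset.physical_pos[j]}\t"
                     f"snp_{dataset.chrom[j]}_{dataset.physical_pos[j]}\t"
                     f"A\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# tract sidecar files
# ---------------------------------------------------------------------------

def write_tracts(dataset: SimulatedDataset, path) -> None:
    """True-ancestry segments as a tab-delimited sidecar file."""
    with open(path, "w") as fh:
        fh.write("chrom\thap_id\tstart_cM\tend_cM\tsource_pop\tdonor_hap\n")
        for ind, pair in dataset.tracts.items():
            for k, tm in enumerate(pair):
                hap_id = f"{ind}.{k}"
                for t in tm.tracts:
                    fh.write(f"{t.chrom}\t{hap_id}\t{t.start_cm:.9g}\t"
                             f"{t.end_cm:.9g}\t{t.source}\t{t.donor_hap}\n")


def read_tracts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "hap_id", "start_cM", "end_cM", "source_pop", "donor_hap"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    return df
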