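"""Readers and writers for the formats the pipeline touches.

VCF 4.x is the canonical interchange format for genotype + per-allele depth
matrices (the ``AD`` FORMAT field); a flat TSV dialect is provided for the
project's own intermediate files.  FASTA/FASTQ handling is delegated to
Biopython; paired FASTQ reading extracts the degenerate base region (DBR)
tag used for PCR-duplicate detection.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .table import (
    GT_HET,
    GT_HOM1,
    GT_HOM2,
    GT_MISSING,
    GENOTYPE_LABELS,
    LABEL_TO_CODE,
    GenotypeTable,
    default_sample_meta,
)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class MultiAllelicError(FormatError):
    """A VCF record carries more than one ALT allele."""


# --------------------------------------------------------------------- VCF

def read_genotype_vcf(path: str | Path) -> GenotypeTable:
    """Read a biallelic-SNP VCF with per-sample allelic depths (``AD``).

    Missing calls (``./.``) map to MISSING with zero depth.  Records whose
    ``AD`` field is absent are imported with zero depths and reported in the
    table's ``sample_meta.attrs['no_depth_loci']`` flag list, because the
    genomic-composition analysis requires depths.  Multi-allelic records are
    rejected outright.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as e:  # htslib raises bare Exceptions on bad input
        raise FormatError(f"{path}: not a readable VCF ({e})") from e
    samples = list(vcf.samples)
    genotype_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    no_depth: list[str] = []
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise MultiAllelicError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has "
                    f"{len(rec.ALT)} ALT alleles; only biallelic SNPs are supported")
            locus = rec.ID if rec.ID not in (None, ".", "") else f"{rec.CHROM}:{rec.POS}"
            locus_ids.append(locus)
            # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
            gt = np.asarray(rec.gt_types)
            col = np.full(len(samples), GT_MISSING, dtype=np.int8)
            col[gt == 0] = GT_HOM1
            col[gt == 1] = GT_HET
            col[gt == 3] = GT_HOM2
            ad = rec.format("AD")
            if ad is None:
                d = np.zeros((len(samples), 2), dtype=np.int64)
                no_depth.append(locus)
            else:
                d = np.asarray(ad, dtype=np.int64)[:, :2]
                d[d < 0] = 0
            d[col == GT_MISSING] = 0
            genotype_cols.append(col)
            depth_cols.append(d)
    except MultiAllelicError:
        raise
    except Exception as e:
        raise FormatError(f"{path}: malformed VCF near record "
                          f"{len(locus_ids) + 1} ({e})") from e
    if locus_ids:
        genotype = np.stack(genotype_cols, axis=1)
        depth = np.stack(depth_cols, axis=1)
    else:
        genotype = np.zeros((len(samples), 0), dtype=np.int8)
        depth = np.zeros((len(samples), 0, 2), dtype=np.int64)
    table = GenotypeTable(samples, locus_ids, genotype, depth)
    table.sample_meta.attrs["no_depth_loci"] = no_depth
    return table


def write_genotype_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write the table as a minimal VCF 4.2 file with GT and AD fields.

    Loci are anonymous RAD tags; they are emitted on a single pseudo-contig
    ``rad`` at consecutive 1-based positions, with the locus id in the ID
    column and placeholder A/C alleles.
    """
    gt_str = {GT_HOM1: "0/0", GT_HET: "0/1", GT_HOM2: "1/1", GT_MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write(f"##contig=<ID=rad,length={max(table.n_loci, 1)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.individual_ids) + "\n")
        for j, locus in enumerate(table.locus_ids):
            cells = []
            for i in range(table.n_individuals):
                g = int(table.genotype[i, j])
                d1, d2 = (int(x) for x in table.depth[i, j])
                cells.append(f"{gt_str[g]}:{d1},{d2}")
            fh.write(f"rad\t{j + 1}\t{locus}\tA\tC\t.\t.\t.\tGT:AD\t"
                     + "\t".join(cells) + "\n")


# --------------------------------------------------------------------- TSV

TSV_COLUMNS = ["individual", "locus", "allele1_depth", "allele2_depth", "genotype"]


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    """Long-format TSV: one row per (individual, locus) cell.

    Header: ``individual  locus  allele1_depth  allele2_depth  genotype``
    with genotype spelled A1A1 / A1A2 / A2A2 / MISSING.  An empty table
    yields a header-only file.
    """
    n, m = table.n_individuals, table.n_loci
    frame = pd.DataFrame(
        {
            "individual": np.repeat(table.individual_ids, m),
            "locus": np.tile(table.locus_ids, n),
            "allele1_depth": table.depth[:, :, 0].ravel(),
            "allele2_depth": table.depth[:, :, 1].ravel(),
            "genotype": [GENOTYPE_LABELS[g] for g in table.genotype.ravel()],
        }
    )
    frame.to_csv(path, sep="\t", index=False, columns=TSV_COLUMNS)


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    """Inverse of :func:`write_genotype_tsv` (sample_meta is not stored)."""
    frame = pd.read_csv(path, sep="\t", dtype={"individual": str, "locus": str})
    if list(frame.columns) != TSV_COLUMNS:
        raise FormatError(f"{path}: expected columns {TSV_COLUMNS}, "
                          f"got {list(frame.columns)}")
    individuals = list(dict.fromkeys(frame["individual"]))
    loci = list(dict.fromkeys(frame["locus"]))
    n, m = len(individuals), len(loci)
    genotype = np.full((n, m), GT_MISSING, dtype=np.int8)
    depth = np.zeros((n, m, 2), dtype=np.int64)
    ind_pos = {v: k for k, v in enumerate(individuals)}
    loc_pos = {v: k for k, v in enumerate(loci)}
    bad = set(frame["genotype"]) - set(LABEL_TO_CODE)
    if bad:
        raise FormatError(f"{path}: unknown genotype labels {sorted(bad)}")
    if len(frame):
        ri = frame["individual"].map(ind_pos).to_numpy(dtype=np.intp)
        ci = frame["locus"].map(loc_pos).to_numpy(dtype=np.intp)
        genotype[ri, ci] = frame["genotype"].map(LABEL_TO_CODE).to_numpy(dtype=np.int8)
        depth[ri, ci, 0] = frame["allele1_depth"].to_numpy()
        depth[ri, ci, 1] = frame["allele2_depth"].to_numpy()
    return GenotypeTable(individuals, loci, genotype, depth)


def write_sample_meta(table: GenotypeTable, path: str | Path) -> None:
    table.sample_meta.to_csv(path, sep="\t", index=True)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="individual",
                       dtype={"pond_id": str, "replicate_group": str})
    meta.index = meta.index.astype(str)
    return meta


# ------------------------------------------------------------ FASTA / FASTQ

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, uppercase sequence) tuples."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(f"{path}: record {rec.id} has non-IUPAC "
                              f"characters {sorted(bad)}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


@dataclasses.dataclass(frozen=True)
class DbrSpec:
    """Location of the degenerate base region within a read pair.

    ``read`` selects mate 1 or 2; the DBR occupies ``length`` bases starting
    at 0-based ``offset`` and is removed from the template sequence.
    """

    read: int = 2
    offset: int = 0
    length: int = 8

    def __post_init__(self) -> None:
        if self.read not in (1, 2):
            raise ValueError("dbr read must be 1 or 2")
        if self.offset < 0 or self.length < 1:
            raise ValueError("dbr offset must be >=0 and length >=1")


@dataclasses.dataclass
class ReadPair:
    """One paired-end read with its extracted DBR tag."""

    id: str
    read1_seq: str
    read2_seq: str
    qual1: str
    qual2: str
    dbr: str


def _strip_dbr(seq: str, qual: str, spec: DbrSpec) -> tuple[str, str, str]:
    lo, hi = spec.offset, spec.offset + spec.length
    if hi > len(seq):
        raise FormatError(f"read of length {len(seq)} too short for DBR "
                          f"region [{lo}, {hi})")
    return seq[lo:hi], seq[:lo] + seq[hi:], qual[:lo] + qual[hi:]


def read_fastq_pairs(path1: str | Path, path2: str | Path,
                     dbr_spec: DbrSpec = DbrSpec()) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (phred+33).

    The DBR is cut out of the mate named by ``dbr_spec`` and carried on the
    :class:`ReadPair` separately from the template sequence.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError(f"unpaired FASTQ records: {path1} and {path2} "
                              "have different read counts")
        s1, s2 = str(r1.seq).upper(), str(r2.seq).upper()
        for which, s in (("read1", s1), ("read2", s2)):
            bad = set(s) - IUPAC_DNA
            if bad:
                raise FormatError(f"{which} {r1.id}: non-IUPAC characters {sorted(bad)}")
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        if dbr_spec.read == 1:
            dbr, s1, q1 = _strip_dbr(s1, q1, dbr_spec)
        else:
            dbr, s2, q2 = _strip_dbr(s2, q2, dbr_spec)
        yield ReadPair(id=r1.id, read1_seq=s1, read2_seq=s2,
                       qual1=q1, qual2=q2, dbr=dbr)


def write_fastq_pairs(pairs: Sequence[ReadPair], path1: str | Path,
                      path2: str | Path, dbr_spec: DbrSpec = DbrSpec()) -> None:
    """Write pairs back to two FASTQ files, re-inserting the DBR tag."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            s1, q1, s2, q2 = p.read1_seq, p.qual1, p.read2_seq, p.qual2
            dq = "I" * len(p.dbr)
            if dbr_spec.read == 1:
                o = dbr_spec.offset
                s1 = s1[:o] + p.dbr + s1[o:]
                q1 = q1[:o] + dq + q1[o:]
            else:
                o = dbr_spec.offset
                s2 = s2[:o] + p.dbr + s2[o:]
                q2 = q2[:o] + dq + q2[o:]
            f1.write(f"@{p.id}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{p.id}\n{s2}\n+\n{q2}\n")
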