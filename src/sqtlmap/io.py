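"""Readers and writers for the tables the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals.
VCF positions (1-based) are converted on read; BED files are consumed
natively; the genotype TSV dialect uses 0-based half-open ``start``/``end``
columns like BED.

Supported inputs
----------------
* transcript expression: TSV with ``transcript_id``, ``gene_id`` and one
  column per sample (TPM units);
* genotypes: VCF (optionally bgzip+tabix indexed, read through cyvcf2) or a
  tab-delimited ``chrom  start  end  variant_id`` table followed by one dosage
  column per sample (optionally bgzip+tabix indexed with the BED preset —
  the dialect's coordinates are 0-based half-open — read through pysam);
* gene annotation: BED (gene bodies) or GTF (exon structures, read through
  gffutils);
* sample covariates: TSV with a ``sample_id`` column.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .events import TranscriptStructure

MISSING_DOSAGE = -1
_VALID_DOSAGES = frozenset({-1, 0, 1, 2})


class FormatError(ValueError):
    """Raised when an input file violates the expected table format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Transcript-level TPM matrix with a transcript -> gene mapping.

    ``tpm`` is indexed by transcript id, one column per sample; ``gene_id``
    maps every transcript to exactly one gene. Sample order is preserved from
    the source file.
    """

    tpm: pd.DataFrame
    gene_id: pd.Series

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            dupes = self.tpm.index[self.tpm.index.duplicated()].tolist()
            raise FormatError(f"duplicate transcript ids: {dupes[:5]}")
        if (self.tpm.to_numpy() < 0).any():
            raise FormatError("negative TPM values")
        if not self.tpm.index.equals(self.gene_id.index):
            raise FormatError("transcript ids of tpm and gene_id differ")

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape

    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.gene_id))

    def gene_subset(self, gene: str) -> pd.DataFrame:
        return self.tpm.loc[self.gene_id == gene]


@dataclass
class GenotypeTable:
    """Per-variant sample dosages (0/1/2, missing = -1) plus variant metadata.

    ``dosages`` is variants x samples (int8); ``meta`` carries chrom, start,
    end (0-based half-open), ref and alt, indexed like ``dosages``.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = set(np.unique(self.dosages.to_numpy())) if self.dosages.size else set()
        if not vals <= _VALID_DOSAGES:
            raise FormatError(f"dosages outside {{-1,0,1,2}}: {sorted(vals - _VALID_DOSAGES)}")
        if self.dosages.index.duplicated().any():
            raise FormatError("duplicate variant ids")
        if not self.dosages.index.equals(self.meta.index):
            raise FormatError("variant ids of dosages and meta differ")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_variants(self) -> int:
        return len(self.dosages)

    def subset_region(self, chrom: str, start: int, end: int) -> "GenotypeTable":
        """Variants overlapping [start, end) on ``chrom`` (0-based half-open)."""
        keep = (
            (self.meta["chrom"] == chrom)
            & (self.meta["start"] < end)
            & (self.meta["end"] > start)
        )
        return GenotypeTable(self.dosages.loc[keep], self.meta.loc[keep])


@dataclass
class GeneAnnotation:
    """Gene body plus (optionally) the exon structures of its transcripts."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"{self.gene_id}: start >= end")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            if tx.exons[0][0] < self.start or tx.exons[-1][1] > self.end:
                raise FormatError(f"{tx.transcript_id}: exons outside gene body")


@dataclass
class CovariateTable:
    """One row per sample; numeric and categorical columns, no missing values."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in covariates")
        if self.table.isna().any().any():
            raise FormatError("missing values in covariates")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# expression / covariates
# ---------------------------------------------------------------------------


def read_expression(path: str | os.PathLike) -> ExpressionTable:
    """Read a transcript TPM table (TSV: transcript_id, gene_id, samples...)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or list(df.columns[:2]) != ["transcript_id", "gene_id"]:
        raise FormatError(
            "expression header must start with 'transcript_id\\tgene_id' "
            "followed by sample columns"
        )
    tpm = df.set_index("transcript_id").drop(columns="gene_id").astype(float)
    gene_id = df.set_index("transcript_id")["gene_id"]
    return ExpressionTable(tpm=tpm, gene_id=gene_id)


def write_expression(table: ExpressionTable, path: str | os.PathLike) -> None:
    out = table.tpm.copy()
    out.insert(0, "gene_id", table.gene_id)
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_covariates(path: str | os.PathLike) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise FormatError("covariate header must start with 'sample_id'")
    return CovariateTable(df.set_index("sample_id"))


def write_covariates(cov: CovariateTable, path: str | os.PathLike) -> None:
    out = cov.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive, the samtools convention)
    into 0-based half-open coordinates."""
    try:
        chrom, span = region.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start, end = int(lo) - 1, int(hi)
    except ValueError as exc:
        raise FormatError(f"malformed region {region!r}; expected chrom:start-end") from exc
    if start < 0 or end <= start:
        raise FormatError(f"empty or negative region {region!r}")
    return chrom, start, end


def read_genotypes(
    path: str | os.PathLike,
    region: str | None = None,
    samples: list[str] | None = None,
) -> GenotypeTable:
    """Read genotypes from VCF(.gz) or dosage TSV(.gz).

    Only biallelic records are returned; VCF dosages are computed from the GT
    field (missing calls become -1). ``region`` is 'chrom:start-end'
    (1-based inclusive); without an index a full scan plus filter is
    performed. ``samples`` restricts and validates the sample set.
    """
    path = str(path)
    base = path[:-3] if path.endswith(".gz") else path
    if base.endswith(".vcf") or base.endswith(".bcf"):
        table = _read_vcf(path, region)
    else:
        table = _read_genotype_tsv(path, region)
    if samples is not None:
        unknown = set(samples) - set(table.samples)
        if unknown:
            raise FormatError(f"unknown samples requested: {sorted(unknown)[:5]}")
        table = GenotypeTable(table.dosages[samples], table.meta)
    return table


def _read_vcf(path: str, region: str | None) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    scan_filter: tuple[str, int, int] | None = None
    if region is not None:
        if os.path.exists(path + ".tbi") or os.path.exists(path + ".csi"):
            records = vcf(region)
        else:  # full scan + filter
            records = iter(vcf)
            scan_filter = parse_region(region)
    else:
        records = iter(vcf)

    ids, chroms, starts, ends, refs, alts, rows = [], [], [], [], [], [], []
    for v in records:
        if len(v.ALT) != 1:
            continue  # biallelic only
        if scan_filter is not None:
            chrom, lo, hi = scan_filter
            if v.CHROM != chrom or v.start >= hi or v.end <= lo:
                continue
        dose = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            dose[i] = MISSING_DOSAGE if (a < 0 or b < 0) else a + b
        vid = v.ID if v.ID else f"{v.CHROM}_{v.POS}_{v.REF}_{v.ALT[0]}"
        ids.append(vid)
        chroms.append(v.CHROM)
        starts.append(v.start)
        ends.append(v.end)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dose)
    dosages = pd.DataFrame(
        np.array(rows, dtype=np.int8).reshape(len(rows), len(sample_ids)),
        index=pd.Index(ids, name="variant_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "ref": refs, "alt": alts},
        index=dosages.index,
    )
    return GenotypeTable(dosages, meta)


_TSV_META_COLS = ["chrom", "start", "end", "variant_id"]


def _read_genotype_tsv(path: str, region: str | None) -> GenotypeTable:
    import pysam

    if region is not None and os.path.exists(path + ".tbi"):
        chrom, start, end = parse_region(region)
        tbx = pysam.TabixFile(path)
        header = tbx.header[-1].lstrip("#").split("\t")
        lines = [line.split("\t") for line in tbx.fetch(chrom, start, end)]
        df = pd.DataFrame(lines, columns=header)
        df = df.astype({"start": int, "end": int})
        sample_cols = header[4:]
        df[sample_cols] = df[sample_cols].astype(np.int8)
    else:
        df = pd.read_csv(path, sep="\t")
        df.columns = [str(c).lstrip("#") for c in df.columns]
    if list(df.columns[:4]) != _TSV_META_COLS:
        raise FormatError(
            f"genotype TSV header must start with {_TSV_META_COLS}, got {list(df.columns[:4])}"
        )
    sample_cols = list(df.columns[4:])
    dose = df[sample_cols].to_numpy()
    bad = ~np.isin(dose, (-1, 0, 1, 2)).all(axis=1)
    if bad.any():
        warnings.warn(
            f"skipping {int(bad.sum())} non-biallelic genotype rows "
            "(dosage outside {-1,0,1,2})",
            stacklevel=2,
        )
        df = df.loc[~bad]
    if region is not None and not os.path.exists(path + ".tbi"):
        chrom, start, end = parse_region(region)
        df = df[(df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)]
    dosages = df.set_index("variant_id")[sample_cols].astype(np.int8)
    meta = df.set_index("variant_id")[["chrom", "start", "end"]].copy()
    meta["ref"] = "N"
    meta["alt"] = "N"
    return GenotypeTable(dosages, meta)


def write_genotypes(table: GenotypeTable, path: str | os.PathLike) -> None:
    """Write the TSV dialect (chrom, start, end, variant_id, samples...)."""
    out = table.meta[["chrom", "start", "end"]].copy()
    out["variant_id"] = out.index
    out = pd.concat([out.reset_index(drop=True),
                     table.dosages.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_bed(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Gene bodies from BED6 (chrom, start, end, gene_id, score, strand)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "gene_id": str},
    )
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in out:
            raise FormatError(f"duplicate gene id {row.gene_id} in BED")
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id, chrom=row.chrom,
            start=int(row.start), end=int(row.end), strand=row.strand,
        )
    return out


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    rows = [
        (g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_gtf(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Transcript exon structures from GTF (exon features; gffutils backend)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_info: dict[str, tuple[str, str]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        tid = ex.attributes["transcript_id"][0]
        # GTF is 1-based inclusive; convert to 0-based half-open
        tx_exons.setdefault(tid, []).append((ex.start - 1, ex.end))
        tx_info[tid] = (gid, ex.strand)
        info = per_gene.setdefault(gid, {"chrom": ex.seqid, "strand": ex.strand,
                                         "start": ex.start - 1, "end": ex.end})
        info["start"] = min(info["start"], ex.start - 1)
        info["end"] = max(info["end"], ex.end)
    out: dict[str, GeneAnnotation] = {}
    for gid, info in per_gene.items():
        txs = [
            TranscriptStructure(tid, tx_info[tid][1], sorted(exons))
            for tid, exons in tx_exons.items()
            if tx_info[tid][0] == gid
        ]
        out[gid] = GeneAnnotation(
            gene_id=gid, chrom=info["chrom"], start=info["start"],
            end=info["end"], strand=info["strand"],
            transcripts=sorted(txs, key=lambda t: t.transcript_id),
        )
    return out


def read_bed_track(path: str | os.PathLike, name: str | None = None):
    """Annotation intervals from BED3+ as an enrichment AnnotationTrack."""
    from .enrichment import AnnotationTrack

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    intervals = [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    if name is None:
        name = os.path.basename(str(path)).rsplit(".bed", 1)[0]
    return AnnotationTrack(name=name, intervals=intervals)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def _format_value(v) -> str:
    if isinstance(v, float):
        return "NA" if np.isnan(v) else f"{v:.6g}"
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v) if v else "."
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if v is None:
        return "NA"
    return str(v)


def write_results(records: Iterable, path: str | os.PathLike, schema=None) -> None:
    """Stream association or gene-level result records to a TSV.

    All records must share one dataclass schema (column order = field order,
    floats at 6 significant digits). An empty stream with ``schema`` given
    writes a header-only file; mixing schemas raises :class:`FormatError`.
    """
    it = iter(records)
    first = next(it, None)
    if first is None:
        if schema is None:
            raise FormatError("empty stream and no schema given")
        cls = schema
    else:
        cls = type(first)
    if not dataclasses.is_dataclass(cls):
        raise FormatError("records must be dataclass instances")
    fields = [
        f.name for f in dataclasses.fields(cls)
        if f.metadata.get("serialize", True)
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for rec in ([] if first is None else _chain_one(first, it)):
            if type(rec) is not cls:
                raise FormatError(
                    f"schema mix: expected {cls.__name__}, got {type(rec).__name__}"
                )
            vals = [_format_value(getattr(rec, f)) for f in fields]
            fh.write("\t".join(vals) + "\n")


def _chain_one(first, rest: Iterator) -> Iterator:
    yield first
    yield from rest


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read a result TSV back as a DataFrame ('NA' -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
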