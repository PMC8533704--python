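"""Readers and writers for the formats the pipeline touches.

Supported inputs are MAF-like tab-separated variant tables, a VCF 4.2
subset, COSMIC-style reference-signature TSVs and FASTA reference
sequence (for context extraction).  All coordinates are stored 1-based,
fully closed; VCF input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import MOTIF_INDEX, MOTIF_ORDER
from .records import CONTEXT_FLANK, RecordError, VariantRecord

MAF_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "depth",
    "alt_fwd",
    "alt_rev",
    "ref_fwd",
    "ref_rev",
    "vaf",
    "phred_quality",
    "context41",
    "germline_flag",
    "snp_flag",
)


class FormatError(ValueError):
    """Input file violating the declared format contract."""


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize a chromosome name to the configured style.

    ``style="chr"`` adds the ``chr`` prefix where missing; ``style="bare"``
    strips it.  Mixed-source inputs (panel MAFs vs VCFs) disagree on this.
    """
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + bare
    if style == "bare":
        return bare
    raise ValueError(f"unknown chromosome style {style!r}")


def record_sort_key(rec: VariantRecord) -> tuple:
    return (rec.sample_id, rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)


# ---------------------------------------------------------------------------
# MAF-like tables
# ---------------------------------------------------------------------------

_BOOL_MAP = {"0": False, "1": True, "false": False, "true": True}


def _coerce_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"not a boolean flag: {value!r}")


def _read_maf(path: Path, chrom_style: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[VariantRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            records.append(
                VariantRecord(
                    sample_id=row.sample_id,
                    chrom=normalize_chrom(row.chrom, chrom_style),
                    pos=int(row.pos),
                    ref_allele=row.ref,
                    alt_allele=row.alt,
                    gene=row.gene,
                    variant_class=row.variant_class,
                    depth=int(row.depth),
                    alt_fwd=int(row.alt_fwd),
                    alt_rev=int(row.alt_rev),
                    ref_fwd=int(row.ref_fwd),
                    ref_rev=int(row.ref_rev),
                    vaf=float(row.vaf),
                    phred_quality=float(row.phred_quality),
                    context41=row.context41,
                    is_putative_germline=_coerce_bool(row.germline_flag),
                    is_common_snp=_coerce_bool(row.snp_flag),
                )
            )
        except (ValueError, RecordError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records as a MAF-like TSV with the canonical column set."""
    rows = [
        {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "gene": r.gene,
            "variant_class": r.variant_class,
            "depth": r.depth,
            "alt_fwd": r.alt_fwd,
            "alt_rev": r.alt_rev,
            "ref_fwd": r.ref_fwd,
            "ref_rev": r.ref_rev,
            "vaf": f"{r.vaf:.6g}",
            "phred_quality": f"{r.phred_quality:.6g}",
            "context41": r.context41,
            "germline_flag": int(r.is_putative_germline),
            "snp_flag": int(r.is_common_snp),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MAF_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=sigstrat
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC-style gene symbol">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant classification">
##INFO=<ID=CTX41,Number=1,Type=String,Description="41-base reference context centred on the first changed base">
##INFO=<ID=GERM,Number=0,Type=Flag,Description="Putative germline per upstream annotation">
##INFO=<ID=SNP,Number=0,Type=Flag,Description="Common SNP per upstream annotation">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=SB4,Number=4,Type=Integer,Description="Strand counts: ref_fwd,ref_rev,alt_fwd,alt_rev">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">
"""


def _to_vcf_alleles(rec: VariantRecord) -> tuple[int, str, str]:
    """MAF-style alleles -> (vcf_pos, REF, ALT) using the context anchor base."""
    if rec.is_snv:
        return rec.pos, rec.ref_allele, rec.alt_allele
    if rec.alt_allele == "-":  # deletion: anchor on the base left of the run
        anchor = rec.context41[CONTEXT_FLANK - 1]
        return rec.pos - 1, anchor + rec.ref_allele, anchor
    if rec.ref_allele == "-":  # insertion: anchor on the base at pos
        anchor = rec.context41[CONTEXT_FLANK]
        return rec.pos, anchor, anchor + rec.alt_allele
    return rec.pos, rec.ref_allele, rec.alt_allele  # MNV passthrough


def _from_vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    if len(ref) > len(alt) and ref.startswith(alt) and len(alt) == 1:
        return pos + 1, ref[1:], "-"
    if len(alt) > len(ref) and alt.startswith(ref) and len(ref) == 1:
        return pos, "-", alt[1:]
    return pos, ref, alt


def write_vcf(records: Sequence[VariantRecord], path) -> None:
    """Write records as a minimal multi-sample VCF 4.2 file.

    One data line per record; other samples' genotype columns are missing
    (``.``), so per-sample metrics never collide across samples.
    """
    samples = sorted({r.sample_id for r in records})
    chroms = sorted({r.chrom for r in records})
    lines = [_VCF_HEADER.rstrip("\n")]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.sample_id))
    for rec in ordered:
        vpos, ref, alt = _to_vcf_alleles(rec)
        info = [f"GENE={rec.gene}", f"VCLASS={rec.variant_class}", f"CTX41={rec.context41}"]
        if rec.is_putative_germline:
            info.append("GERM")
        if rec.is_common_snp:
            info.append("SNP")
        fmt = f"{rec.depth}:{rec.ref_fwd},{rec.ref_rev},{rec.alt_fwd},{rec.alt_rev}:{rec.vaf:.6g}"
        cols = [fmt if s == rec.sample_id else "." for s in samples]
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(vpos),
                    ".",
                    ref,
                    alt,
                    f"{rec.phred_quality:.6g}",
                    "PASS",
                    ";".join(info),
                    "DP:SB4:AF",
                ]
                + cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path, chrom_style: str) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    errors: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                multi = len(rec.alts or ()) > 1
                alt = (rec.alts or ("N",))[0]
                pos, ref_a, alt_a = _from_vcf_alleles(rec.pos, rec.ref, alt)
                info = rec.info
                for sample_id, call in rec.samples.items():
                    dp = call.get("DP")
                    if dp is None:
                        continue
                    sb4 = call.get("SB4")
                    af = call.get("AF")
                    records.append(
                        VariantRecord(
                            sample_id=sample_id,
                            chrom=normalize_chrom(rec.chrom, chrom_style),
                            pos=pos,
                            ref_allele=ref_a,
                            alt_allele=alt_a,
                            gene=str(info.get("GENE", "")),
                            variant_class=str(info.get("VCLASS", "")),
                            depth=int(dp),
                            ref_fwd=int(sb4[0]),
                            ref_rev=int(sb4[1]),
                            alt_fwd=int(sb4[2]),
                            alt_rev=int(sb4[3]),
                            # htslib stores AF/QUAL as single precision; round
                            # back to the 6 significant digits the writer emits
                            vaf=float(f"{float(af):.6g}"),
                            phred_quality=float(
                                f"{float(rec.qual if rec.qual is not None else 0.0):.6g}"
                            ),
                            context41=str(info.get("CTX41", "")),
                            is_putative_germline=bool(info.get("GERM", False)),
                            is_common_snp=bool(info.get("SNP", False)),
                            is_multiallelic=multi,
                        )
                    )
            except (ValueError, KeyError, RecordError, TypeError) as exc:
                errors.append(f"{rec.chrom}:{rec.pos}: {exc}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} malformed record(s):\n" + "\n".join(errors))
    return records


def read_variant_table(path, dialect: str = "maf_like", chrom_style: str = "chr") -> list[VariantRecord]:
    """Read a variant table in the given dialect into :class:`VariantRecord` s.

    Parameters
    ----------
    path
        Input file; must exist.
    dialect
        ``"maf_like"`` for the tab-separated table with the canonical
        column set, ``"vcf"`` for the VCF 4.2 subset (INFO keys GENE,
        VCLASS, CTX41, GERM, SNP; FORMAT keys DP, SB4, AF).  Multi-allelic
        VCF sites keep the first alternate allele and are flagged.
    chrom_style
        Chromosome-name style records are normalized to.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf_like":
        return _read_maf(path, chrom_style)
    if dialect == "vcf":
        return _read_vcf(path, chrom_style)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Reference signature matrices
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSignatureSet:
    """A 96 x k matrix of reference signatures, columns summing to one."""

    names: list[str]
    matrix: np.ndarray  # 96 x k
    motif_order: tuple[str, ...] = MOTIF_ORDER

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise FormatError(
                f"signature matrix has shape {self.matrix.shape}, expected (96, {len(self.names)})"
            )
        if (self.matrix < 0).any():
            raise FormatError("signature matrix contains negative entries")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise FormatError("signature columns do not sum to 1")


def read_signature_matrix(path) -> ReferenceSignatureSet:
    """Read a COSMIC-style signature TSV (column ``motif`` then one per signature).

    Columns whose sums are within 1e-3 of 1 are renormalized exactly;
    larger deviations are format errors.  Motif rows are reordered to
    the canonical order regardless of file order.
    """
    df = pd.read_csv(path, sep="\t")
    if "motif" not in df.columns:
        raise FormatError(f"{path}: missing required column 'motif'")
    if len(df) != 96:
        raise FormatError(f"{path}: expected 96 motif rows, found {len(df)}")
    unknown = [m for m in df["motif"] if m not in MOTIF_INDEX]
    if unknown:
        raise FormatError(f"{path}: unknown motif label(s): {unknown[:3]}")
    if df["motif"].duplicated().any():
        raise FormatError(f"{path}: duplicated motif rows")
    df = df.set_index("motif").loc[list(MOTIF_ORDER)]
    names = [str(c) for c in df.columns]
    if not names:
        raise FormatError(f"{path}: no signature columns")
    matrix = df.to_numpy(dtype=float)
    if (matrix < 0).any():
        raise FormatError(f"{path}: negative signature entries")
    sums = matrix.sum(axis=0)
    bad = [n for n, s in zip(names, sums) if abs(s - 1.0) > 1e-3]
    if bad:
        raise FormatError(f"{path}: column(s) not summing to 1: {', '.join(bad)}")
    matrix = matrix / sums
    return ReferenceSignatureSet(names=names, matrix=matrix)


def write_signature_matrix(sigs: ReferenceSignatureSet, path) -> None:
    df = pd.DataFrame(sigs.matrix, index=list(sigs.motif_order), columns=sigs.names)
    df.index.name = "motif"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA context extraction
# ---------------------------------------------------------------------------


def extract_context(fasta, chrom: str, pos: int, flank: int = CONTEXT_FLANK) -> tuple[str, bool]:
    """Extract the ``2*flank+1``-base window centred on 1-based ``pos``.

    ``fasta`` is a :class:`pyfaidx.Fasta` (or path to a FASTA file).
    Windows running off a chromosome end are padded with ``N`` and the
    second return value flags the padding.
    """
    import pyfaidx

    if not isinstance(fasta, pyfaidx.Fasta):
        fasta = pyfaidx.Fasta(str(fasta))
    seq = fasta[chrom]
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {chrom}:{pos} outside chromosome (length {n})")
    lo = max(1, pos - flank)
    hi = min(n, pos + flank)
    window = str(seq[lo - 1 : hi]).upper()
    left_pad = lo - (pos - flank)
    right_pad = (pos + flank) - hi
    padded = left_pad > 0 or right_pad > 0
    return "N" * left_pad + window + "N" * right_pad, padded
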