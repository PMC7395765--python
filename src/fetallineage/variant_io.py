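"""Reading and writing the formats the pipeline touches.

Normalizes VCF rows into :class:`VariantRecord` / :class:`SampleCall`,
reads signature catalogs and sample metadata, and writes the simple
VCFv4.2 dialect used throughout (FORMAT ``GT:GQ:DP:AD``, INFO ``MQ`` and
optional ``EFFECT``/``GENE`` annotations).

Conventions: coordinates are 1-based inclusive (VCF); VAF is always
recomputed from AD rather than trusted from the file; a missing MQ is
treated as failing the MQ threshold downstream (conservative).
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import trinucleotide_context  # re-exported  # noqa: F401
from .signatures import SignatureCatalog


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class SampleCall:
    """One sample's genotype call at one site."""

    gt: tuple | None = None      # allele indices; phasing ignored
    gq: float | None = None
    dp: int | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None

    @property
    def vaf(self) -> float | None:
        """ad_alt / (ad_ref + ad_alt); None when the denominator is 0."""
        if self.ad_ref is None or self.ad_alt is None:
            return None
        denom = self.ad_ref + self.ad_alt
        if denom == 0:
            return None
        return self.ad_alt / denom

    @property
    def is_alt(self) -> bool:
        """Any non-reference allele called."""
        return self.gt is not None and any(a not in (0, None) for a in self.gt)

    @property
    def is_hom_ref(self) -> bool:
        return self.gt is not None and len(self.gt) > 0 and all(a == 0 for a in self.gt)


@dataclass(slots=True)
class VariantRecord:
    """One called site with its site metrics and per-sample calls."""

    contig: str
    pos: int                      # 1-based
    ref: str
    alts: tuple
    qual: float | None = None
    mq: float | None = None
    ids: tuple = ()
    effect: str | None = None     # snpEff-style impact (MODERATE/HIGH/...)
    gene: str | None = None
    filter_pass: bool = True
    calls: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref:
            raise ValueError("ref must be non-empty")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alts) == 1 and len(self.alts[0]) == 1

    @property
    def is_indel(self) -> bool:
        return not self.multiallelic and len(self.ref) != len(self.alts[0])

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alts[0])


@dataclass(slots=True)
class SampleMeta:
    sample_id: str
    donor_id: str
    role: str                      # clone | bulk
    cell_type: str                 # HSPC | ISC | other
    trisomy21: bool
    sex: str                       # M | F
    age_since_conception: float    # years

    def __post_init__(self):
        if self.role not in ("clone", "bulk"):
            raise ValueError(f"role must be clone or bulk, got {self.role!r}")
        if self.age_since_conception <= 0:
            raise ValueError("age since conception must be positive")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_REQUIRED_FORMAT = ("GT", "GQ", "DP", "AD")


def read_vcf(path, sample_filter=None) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects.

    Requires FORMAT fields GT, GQ, DP, AD.  Multi-allelic rows are retained
    (flagged through :attr:`VariantRecord.multiallelic`); VAF is derived
    from AD on access.  Emits a warning for unsorted files.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    samples = list(vcf.samples)
    if sample_filter is not None:
        keep_idx = [i for i, s in enumerate(samples) if s in set(sample_filter)]
    else:
        keep_idx = list(range(len(samples)))

    header_text = vcf.raw_header
    for f in _REQUIRED_FORMAT:
        if f"ID={f}," not in header_text and f"ID={f}>" not in header_text:
            raise ValueError(f"VCF {path} missing required FORMAT field {f}")

    records = []
    last = None
    for v in vcf:
        if last is not None and v.CHROM == last[0] and v.POS < last[1]:
            warnings.warn(f"unsorted VCF {path} at {v.CHROM}:{v.POS}")
        last = (v.CHROM, v.POS)

        gq = v.format("GQ")
        dp = v.format("DP")
        ad = v.format("AD")

        def scalar(arr, i):
            if arr is None:
                return None
            x = arr[i]
            x = x[0] if np.ndim(x) else x
            x = float(x)
            if np.isnan(x) or x < -2e9:
                return None
            return x

        calls = {}
        for i in keep_idx:
            g = v.genotypes[i]
            alleles = tuple(a for a in g[:-1])
            gt = None if any(a is None or a < 0 for a in alleles) else alleles
            ad_ref = ad_alt = None
            if ad is not None:
                row = np.atleast_1d(ad[i])
                if len(row) >= 2 and row[0] >= 0:
                    ad_ref = int(row[0])
                    ad_alt = int(row[1]) if row[1] >= 0 else 0
            gq_i = scalar(gq, i)
            dp_i = scalar(dp, i)
            calls[samples[i]] = SampleCall(
                gt=gt,
                gq=gq_i,
                dp=int(dp_i) if dp_i is not None and dp_i >= 0 else None,
                ad_ref=ad_ref,
                ad_alt=ad_alt,
            )
        mq = v.INFO.get("MQ")
        effect = v.INFO.get("EFFECT")
        gene = v.INFO.get("GENE")
        ids = tuple(v.ID.split(";")) if v.ID else ()
        records.append(VariantRecord(
            contig=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
            qual=float(v.QUAL) if v.QUAL is not None else None,
            mq=float(mq) if mq is not None else None,
            ids=ids, effect=effect, gene=gene,
            filter_pass=(v.FILTER is None),
            calls=calls,
        ))
    return records


def write_vcf(records, samples, path, contigs=None) -> None:
    """Write records as VCFv4.2 with FORMAT GT:GQ:DP:AD."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted impact">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    body = []
    for rec in records:
        info = []
        if rec.mq is not None:
            info.append(f"MQ={rec.mq:g}")
        if rec.effect:
            info.append(f"EFFECT={rec.effect}")
        if rec.gene:
            info.append(f"GENE={rec.gene}")
        cols = [
            rec.contig, str(rec.pos), ";".join(rec.ids) if rec.ids else ".",
            rec.ref, ",".join(rec.alts),
            f"{rec.qual:g}" if rec.qual is not None else ".",
            "PASS" if rec.filter_pass else "FAIL",
            ";".join(info) if info else ".",
            "GT:GQ:DP:AD",
        ]
        for s in samples:
            call = rec.calls.get(s)
            if call is None or call.gt is None:
                cols.append("./.:.:.:.")
                continue
            gt = "/".join(str(a) for a in call.gt)
            gq = f"{call.gq:g}" if call.gq is not None else "."
            dp = str(call.dp) if call.dp is not None else "."
            if call.ad_ref is None:
                adtxt = "."
            else:
                adtxt = f"{call.ad_ref},{call.ad_alt}"
            cols.append(f"{gt}:{gq}:{dp}:{adtxt}")
        body.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines + body) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences, path, width: int = 80) -> None:
    """Write contig sequences plus a .fai index."""
    fai = []
    offset = 0
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            seq = str(seq)
            header = f">{name}\n"
            fh.write(header)
            offset += len(header)
            n = len(seq)
            fai.append((name, n, offset, width, width + 1))
            for i in range(0, n, width):
                fh.write(seq[i:i + width] + "\n")
            offset += n + (n + width - 1) // width
    with open(f"{path}.fai", "w") as fh:
        for row in fai:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_fasta(path):
    import pyfaidx

    return pyfaidx.Fasta(os.fspath(path), sequence_always_upper=True)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-layout TSV (96 context rows x >=1 signature columns).

    Columns are renormalized to sum to 1 and rows canonicalized to the 96
    lexicographic pyrimidine-centred contexts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(df)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.matrix.to_csv(path, sep="\t", index_label="context")


_META_COLS = ["sample_id", "donor_id", "role", "cell_type", "trisomy21", "sex",
              "age_since_conception"]


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(SampleMeta(
            sample_id=str(row.sample_id), donor_id=str(row.donor_id),
            role=str(row.role), cell_type=str(row.cell_type),
            trisomy21=bool(row.trisomy21) if not isinstance(row.trisomy21, str)
            else row.trisomy21.lower() in ("true", "1", "yes"),
            sex=str(row.sex), age_since_conception=float(row.age_since_conception),
        ))
    donors_with_bulk = {m.donor_id for m in metas if m.role == "bulk"}
    for m in metas:
        if m.donor_id not in donors_with_bulk:
            raise ValueError(f"donor {m.donor_id} has no bulk sample")
    return metas


def write_metadata(metas, path) -> None:
    rows = [{c: getattr(m, c) for c in _META_COLS} for m in metas]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_site_list(path) -> set:
    """Read an exclusion/rescue site list: contig, pos, ref, alt TSV."""
    df = pd.read_csv(path, sep="\t")
    return {(str(r.contig), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()}
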