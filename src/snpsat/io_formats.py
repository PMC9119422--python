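"""Readers and writers for the standard formats the toolkit touches.

All coordinates are 1-based inclusive throughout the package.  Variant
records are single-nucleotide substitutions only: indels and symbolic
alleles are dropped on read (with a logged count) and multi-allelic sites
are split into one record per alternate allele, so that the intersection
key ``(chrom, pos, ref, alt)`` is always well defined.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One SNP call.

    ``pos`` is 1-based.  ``var_freq`` is the alternate allele frequency in
    [0, 1].  Optional caller-specific fields (``variant_quality``,
    ``rms_mapq``, ``p_value``, ``effect``) are ``None`` when the producing
    caller did not emit them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: Optional[int] = None
    alt_reads: Optional[int] = None
    var_freq: Optional[float] = None
    variant_quality: Optional[float] = None
    rms_mapq: Optional[float] = None
    p_value: Optional[float] = None
    caller: str = ""
    effect: Optional[str] = None
    in_cds: Optional[bool] = None
    gene_product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.total_depth is not None and self.total_depth < 0:
            raise InputError("total_depth must be >= 0")
        if (
            self.alt_reads is not None
            and self.total_depth is not None
            and self.alt_reads > self.total_depth
        ):
            raise InputError(
                f"alt_reads {self.alt_reads} exceeds depth {self.total_depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.var_freq is not None and not (0.0 <= self.var_freq <= 1.0):
            raise InputError(
                f"var_freq {self.var_freq} outside [0, 1] at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self, **changes) -> "VariantRecord":
        return replace(self, **changes)


@dataclass
class DepthTable:
    """Per-base depths for one strain, grouped by reference sequence.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (1-based) and
    ``depth``; positions are strictly increasing within each chrom and
    uncovered positions are simply absent.
    """

    strain: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["chrom", "pos", "depth"]:
            self.table = t = t.rename(
                columns=dict(zip(t.columns, ["chrom", "pos", "depth"]))
            )
        if len(t) and (t["depth"] < 0).any():
            raise InputError("negative depth in depth table")
        for chrom, grp in t.groupby("chrom", sort=False):
            d = grp["pos"].diff().dropna()
            if (d <= 0).any():
                raise FormatError(
                    f"positions not strictly increasing on {chrom} "
                    f"(strain {self.strain})"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_covered(self) -> int:
        """Positions with depth >= 1."""
        return int((self.table["depth"] >= 1).sum())

    @property
    def total_bases(self) -> int:
        return int(self.table["depth"].sum())

    def depth_at(self, chrom: str, pos: int) -> int:
        sub = self.table[(self.table["chrom"] == chrom) & (self.table["pos"] == pos)]
        if sub.empty:
            return 0
        return int(sub["depth"].iloc[0])

    def depth_lookup(self) -> dict:
        """(chrom, pos) -> depth mapping for bulk queries."""
        t = self.table
        return dict(zip(zip(t["chrom"], t["pos"]), t["depth"].astype(int)))


@dataclass(frozen=True)
class FeatureRecord:
    """A gene/CDS interval from a GFF3 annotation (1-based inclusive)."""

    seqid: str
    start: int
    end: int
    strand: str
    kind: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature start {self.start} > end {self.end} on {self.seqid}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# VCF


def _effect_from_info(info) -> Optional[str]:
    if "EFF" in info:
        val = info["EFF"]
        if isinstance(val, tuple):
            val = val[0]
        return str(val).split("(")[0]
    if "ANN" in info:
        val = info["ANN"]
        if isinstance(val, tuple):
            val = val[0]
        parts = str(val).split("|")
        if len(parts) > 1:
            return parts[1]
    if "EFFECT" in info:
        val = info["EFFECT"]
        return str(val[0] if isinstance(val, tuple) else val)
    return None


def read_variant_records(path: str, caller_tag: str = "") -> list[VariantRecord]:
    """Read SNP records from a VCF (v4.x).

    Only single-base substitutions are returned; indels and symbolic
    alleles are skipped (count logged).  Multi-allelic sites are split into
    one record per alternate allele.  Depth is taken from FORMAT/DP of the
    first sample when present, else INFO/DP; alt-supporting reads from
    FORMAT/AD (ref+alt tuple), VarScan-style FORMAT/RD+AD scalars, or
    INFO/AO; frequency from FORMAT/FREQ, INFO/AF, or derived from counts.
    """
    if not os.path.exists(path):
        raise InputError(f"VCF file not found: {path}")
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc

    records: list[VariantRecord] = []
    n_skipped = 0
    with vf:
        for rec in vf:
            info = rec.info
            sample = rec.samples[0] if rec.samples else None
            for i, alt in enumerate(rec.alts or ()):
                if (
                    rec.ref is None
                    or len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref.upper() not in _BASES
                    or alt.upper() not in _BASES
                ):
                    n_skipped += 1
                    continue

                depth = None
                alt_reads = None
                freq = None
                pval = None

                if sample is not None:
                    sv = dict(sample.items())
                    depth = sv.get("DP")
                    ad = sv.get("AD")
                    rd = sv.get("RD")
                    if isinstance(ad, tuple) and len(ad) >= 2 and rd is None:
                        alt_reads = ad[i + 1]
                    elif rd is not None:
                        # VarScan convention: RD = ref reads, AD = alt reads
                        alt_reads = ad[0] if isinstance(ad, tuple) else ad
                    fq = sv.get("FREQ")
                    if fq is not None:
                        fq = fq[0] if isinstance(fq, tuple) else fq
                        freq = float(str(fq).rstrip("%")) / 100.0
                    pv = sv.get("PVAL")
                    if pv is not None:
                        pval = float(pv[0] if isinstance(pv, tuple) else pv)

                if depth is None and "DP" in info:
                    depth = info["DP"]
                if alt_reads is None and "AO" in info:
                    ao = info["AO"]
                    alt_reads = ao[i] if isinstance(ao, tuple) else ao
                if freq is None and "AF" in info:
                    af = info["AF"]
                    freq = float(af[i] if isinstance(af, tuple) else af)
                if pval is None and "PVAL" in info:
                    pv = info["PVAL"]
                    pval = float(pv[0] if isinstance(pv, tuple) else pv)
                if freq is None and depth:
                    if alt_reads is not None:
                        freq = alt_reads / depth

                rms_mapq = float(info["MQ"]) if "MQ" in info else None

                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        total_depth=None if depth is None else int(depth),
                        alt_reads=None if alt_reads is None else int(alt_reads),
                        var_freq=freq,
                        variant_quality=rec.qual,
                        rms_mapq=rms_mapq,
                        p_value=pval,
                        caller=caller_tag,
                        effect=_effect_from_info(info),
                    )
                )
    if n_skipped:
        logger.info("%s: skipped %d non-SNP allele(s)", path, n_skipped)
    return records


def write_variant_records(
    path: str, records: Iterable[VariantRecord], contigs: Optional[Iterable[str]] = None
) -> None:
    """Write SNP records as a sites-only VCF v4.2 with INFO-encoded fields."""
    records = list(records)
    if contigs is None:
        seen = []
        for r in records:
            if r.chrom not in seen:
                seen.append(r.chrom)
        contigs = seen
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c)
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.info.add("AO", "A", "Integer", "Alternate allele supporting reads")
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("PVAL", 1, "Float", "Caller significance p-value")
    header.info.add("EFFECT", 1, "String", "Annotated variant effect")
    order = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in sorted(records, key=lambda r: (order.get(r.chrom, 0), r.pos, r.alt)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            rec.qual = r.variant_quality
            if r.total_depth is not None:
                rec.info["DP"] = r.total_depth
            if r.alt_reads is not None:
                rec.info["AO"] = (r.alt_reads,)
            if r.var_freq is not None:
                rec.info["AF"] = (r.var_freq,)
            if r.rms_mapq is not None:
                rec.info["MQ"] = r.rms_mapq
            if r.p_value is not None:
                rec.info["PVAL"] = r.p_value
            if r.effect is not None:
                rec.info["EFFECT"] = r.effect
            out.write(rec)


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth style three-column TSV)


def read_depth_table(path: str, strain: str = "") -> DepthTable:
    if not os.path.exists(path):
        raise InputError(f"depth table not found: {path}")
    if os.path.getsize(path) == 0:
        logger.warning("%s: empty depth table", path)
        return DepthTable(
            strain, pd.DataFrame(columns=["chrom", "pos", "depth"]).astype(
                {"pos": int, "depth": int}
            )
        )
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse depth table {path}: {exc}") from exc
    for col in ("pos", "depth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            raise FormatError(f"non-integer {col} value in {path}")
        df[col] = vals.astype(int)
    return DepthTable(strain or os.path.basename(path), df)


def write_depth_table(path: str, depths: DepthTable) -> None:
    depths.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3


def read_feature_table(path: str, kinds: tuple[str, ...] = ("CDS",)) -> list[FeatureRecord]:
    """Read CDS (by default) intervals from a GFF3 file.

    Coordinates stay 1-based inclusive.  The ``product`` attribute (or
    ``Name``/``gene`` as fallbacks) supplies the function text.
    """
    if not os.path.exists(path):
        raise InputError(f"GFF3 file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    out: list[FeatureRecord] = []
    for kind in kinds:
        for f in db.features_of_type(kind):
            product = ""
            for key in ("product", "Name", "gene"):
                if key in f.attributes:
                    product = f.attributes[key][0]
                    break
            out.append(
                FeatureRecord(
                    seqid=f.seqid,
                    start=f.start,
                    end=f.end,
                    strand=f.strand or ".",
                    kind=f.featuretype,
                    product=product,
                )
            )
    return out


def write_feature_table(path: str, features: Iterable[FeatureRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"product={f.product}" if f.product else "."
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        "snpsat",
                        f.kind,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )
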