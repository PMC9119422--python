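"""Per-strain and cross-sample SNP profiles.

Covers length-normalised relative abundance, genome depth/coverage
metrics, CDS vs non-CDS classification of SNPs against a GFF3 annotation,
dN/dS from annotated effect categories, allele-frequency spectra,
taxon-level SNP aggregation, shared-SNP partitions across samples and the
chi-square comparison of non-synonymous/synonymous composition between
partition categories.

dN/dS here is the raw count ratio n_nonsyn / n_syn (no per-site
opportunity correction), which is how strain-level metagenomic surveys
typically report it; it is scale-invariant, so category proportions work
as well as counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

from .errors import InputError, UndefinedMetricError
from .io_formats import DepthTable, FeatureRecord, VariantRecord

logger = logging.getLogger(__name__)

# SnpEff-style effect categories
NONSYNONYMOUS_EFFECTS = frozenset(
    {"missense_variant", "start_lost", "stop_gained", "stop_lost"}
)
SYNONYMOUS_EFFECTS = frozenset(
    {"start_retained_variant", "stop_retained_variant", "synonymous_variant"}
)

TAXONOMIC_LEVELS = (
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)


def _normalize_effect(label: str) -> str:
    return label.strip().lower().replace(" ", "_")


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass
class StrainAbundance:
    strain: str
    n_reads: int
    genome_length: int
    abundance: float


@dataclass
class StrainMetrics:
    strain: str
    genome_depth: float
    coverage: float
    snp_count: int
    snp_density: float


@dataclass
class DnDsResult:
    n_nonsyn: float
    n_syn: float
    n_other: float
    ratio: Optional[float]  # None when n_syn == 0 (undefined)

    @property
    def ratio_2dp(self) -> Optional[float]:
        return None if self.ratio is None else round_half_up(self.ratio, 2)


@dataclass
class SharedSnpPartition:
    """Partition of the union of SNP keys by the exact subset of samples
    sharing each key, with per-subset dN/dS."""

    samples: tuple[str, ...]
    subsets: dict[frozenset, set] = field(default_factory=dict)
    dnds: dict[frozenset, DnDsResult] = field(default_factory=dict)

    def n_shared_by_all(self) -> int:
        return len(self.subsets.get(frozenset(self.samples), set()))

    def union_size(self) -> int:
        return sum(len(v) for v in self.subsets.values())

    def shared_by_all_percentage(self) -> float:
        total = self.union_size()
        if total == 0:
            raise UndefinedMetricError("empty partition")
        return 100.0 * self.n_shared_by_all() / total


# ---------------------------------------------------------------------------


def relative_abundance(
    counts: Mapping[str, int], lengths: Mapping[str, int]
) -> list[StrainAbundance]:
    """r_s = (n_s / l_s) / sum_t (n_t / l_t): length-normalised share of
    uniquely mapped reads."""
    if set(counts) != set(lengths):
        raise InputError("strain sets of counts and lengths differ")
    if any(l <= 0 for l in lengths.values()):
        raise InputError("genome lengths must be positive")
    if any(n < 0 for n in counts.values()):
        raise InputError("read counts must be non-negative")
    dens = {s: counts[s] / lengths[s] for s in counts}
    total = sum(dens.values())
    if total == 0:
        raise UndefinedMetricError("all read counts are zero; abundance undefined")
    return [
        StrainAbundance(s, counts[s], lengths[s], dens[s] / total)
        for s in sorted(counts)
    ]


def strain_metrics(
    depths: DepthTable,
    genome_length: int,
    snps: Sequence[VariantRecord],
    strain: Optional[str] = None,
) -> StrainMetrics:
    """Genome depth = mapped bases / genome size; coverage = fraction of
    positions with depth >= 1; SNP density = SNPs / covered length."""
    if genome_length <= 0:
        raise InputError("genome_length must be positive")
    covered = depths.n_covered
    if covered == 0 and len(snps) > 0:
        raise InputError("SNPs reported on a strain with zero covered positions")
    if covered > genome_length:
        raise InputError("covered positions exceed genome length")
    return StrainMetrics(
        strain=strain or depths.strain,
        genome_depth=depths.total_bases / genome_length,
        coverage=covered / genome_length,
        snp_count=len(snps),
        snp_density=(len(snps) / covered) if covered else 0.0,
    )


def annotate_snp_context(
    snps: Iterable[VariantRecord], features: Sequence[FeatureRecord]
) -> list[VariantRecord]:
    """Flag each SNP as CDS/non-CDS and attach the gene product text.

    A SNP is CDS iff its position falls inside any CDS interval (1-based
    inclusive).  A SNP on a contig absent from the annotation is classified
    non-CDS with a warning; fully disjoint contig namespaces are an error
    (they signal mismatched references, not intergenic SNPs).
    """
    snps = list(snps)
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.kind != "CDS":
            continue
        # IntervalTree is half-open; +1 makes the 1-based end inclusive
        trees.setdefault(f.seqid, IntervalTree()).addi(f.start, f.end + 1, f)

    snp_contigs = {r.chrom for r in snps}
    if snps and features and trees and not (snp_contigs & set(trees)):
        raise InputError(
            "no contig shared between variants and annotation: "
            f"{sorted(snp_contigs)[:3]} vs {sorted(trees)[:3]}"
        )

    out: list[VariantRecord] = []
    warned: set[str] = set()
    for r in snps:
        tree = trees.get(r.chrom)
        if tree is None:
            if r.chrom not in warned:
                logger.warning("contig %s absent from annotation; non-CDS", r.chrom)
                warned.add(r.chrom)
            out.append(r.copy(in_cds=False, gene_product=None))
            continue
        hits = tree[r.pos]
        if hits:
            feat = sorted(hits)[0].data
            out.append(r.copy(in_cds=True, gene_product=feat.product))
        else:
            out.append(r.copy(in_cds=False, gene_product=None))
    return out


def cds_proportions(annotated: Sequence[VariantRecord]) -> tuple[float, float]:
    if not annotated:
        raise UndefinedMetricError("no SNPs to classify")
    if any(r.in_cds is None for r in annotated):
        raise InputError("records not annotated; run annotate_snp_context first")
    p_cds = sum(1 for r in annotated if r.in_cds) / len(annotated)
    return p_cds, 1.0 - p_cds


def compute_dnds(
    snps: Optional[Iterable[VariantRecord]] = None,
    *,
    counts: Optional[tuple[float, float]] = None,
    other: float = 0.0,
) -> DnDsResult:
    """Count (or take) non-synonymous and synonymous variants and form
    their ratio.

    Pass either annotated records, or ``counts=(n_nonsyn, n_syn)`` —
    proportions are fine since the ratio is scale-invariant.  A zero
    synonymous count leaves the ratio undefined (``None``), not infinite.
    """
    if (snps is None) == (counts is None):
        raise InputError("provide exactly one of snps or counts")
    if counts is not None:
        n_non, n_syn = counts
        n_other = other
        if n_non < 0 or n_syn < 0:
            raise InputError("counts must be non-negative")
    else:
        n_non = n_syn = n_other = 0
        for r in snps:  # type: ignore[union-attr]
            if r.effect is None:
                raise InputError(f"record at {r.chrom}:{r.pos} has no effect label")
            eff = _normalize_effect(r.effect)
            if eff in NONSYNONYMOUS_EFFECTS:
                n_non += 1
            elif eff in SYNONYMOUS_EFFECTS:
                n_syn += 1
            else:
                n_other += 1
    ratio = None if n_syn == 0 else n_non / n_syn
    if ratio is None:
        logger.warning("dN/dS undefined: no synonymous variants")
    return DnDsResult(n_non, n_syn, n_other, ratio)


def shared_snp_partition(
    per_sample_sets: Mapping[str, set],
    effects: Optional[Mapping[object, str]] = None,
) -> SharedSnpPartition:
    """Assign every SNP key to the exact subset of samples containing it.

    With an ``effects`` map (key -> effect label), per-subset dN/dS is also
    computed.  Works for any hashable keys, so the same partition serves
    SNP sharing across samples and strain sharing across samples.
    """
    if len(per_sample_sets) < 2:
        raise InputError("need at least 2 samples to partition")
    samples = tuple(per_sample_sets)
    subsets: dict[frozenset, set] = {}
    union = set().union(*per_sample_sets.values())
    for key in union:
        members = frozenset(s for s in samples if key in per_sample_sets[s])
        subsets.setdefault(members, set()).add(key)
    part = SharedSnpPartition(samples=samples, subsets=subsets)
    if effects is not None:
        for members, keys in subsets.items():
            n_non = sum(
                1 for k in keys if _normalize_effect(effects[k]) in NONSYNONYMOUS_EFFECTS
            )
            n_syn = sum(
                1 for k in keys if _normalize_effect(effects[k]) in SYNONYMOUS_EFFECTS
            )
            part.dnds[members] = compute_dnds(
                counts=(n_non, n_syn), other=len(keys) - n_non - n_syn
            )
    return part


def chi_square_nonsyn_syn(
    tables: Mapping[str, tuple[float, float]]
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the 2 x k table of
    (non-synonymous, synonymous) counts across k categories."""
    rows = {}
    for name, (n_non, n_syn) in tables.items():
        if n_non + n_syn == 0:
            logger.warning("category %s has zero total; dropped", name)
            continue
        rows[name] = (n_non, n_syn)
    if len(rows) < 2:
        raise InputError("need at least 2 non-empty categories")
    obs = np.array(list(rows.values()), dtype=float).T  # 2 x k
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise InputError("a margin of the contingency table is zero")
    stat, p, dof, _ = chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def aggregate_snps_by_taxon(
    snp_counts: Mapping[str, int],
    taxonomy: Mapping[str, Mapping[str, str]],
    levels: Sequence[str] = TAXONOMIC_LEVELS,
) -> pd.DataFrame:
    """Per-level SNP proportions and mean SNPs per genome.

    ``taxonomy`` maps strain -> {level -> taxon name}.  At each level the
    proportion is SNPs in the taxon / total SNPs (sums to 1 per level) and
    the mean is SNPs in the taxon / number of genomes in it.  Strains with
    incomplete lineages are excluded with a warning.
    """
    rows = []
    for strain, n in snp_counts.items():
        lineage = taxonomy.get(strain)
        if lineage is None or any(lv not in lineage for lv in levels):
            logger.warning("strain %s missing lineage; excluded", strain)
            continue
        rows.append({"strain": strain, "snps": n, **{lv: lineage[lv] for lv in levels}})
    if not rows:
        raise InputError("no strain with a complete lineage")
    df = pd.DataFrame(rows)
    total = df["snps"].sum()
    out = []
    for lv in levels:
        grp = df.groupby(lv).agg(snps=("snps", "sum"), n_genomes=("strain", "nunique"))
        for taxon, row in grp.iterrows():
            out.append(
                {
                    "level": lv,
                    "taxon": taxon,
                    "snps": int(row["snps"]),
                    "proportion": row["snps"] / total if total else 0.0,
                    "n_genomes": int(row["n_genomes"]),
                    "mean_snps_per_genome": row["snps"] / row["n_genomes"],
                }
            )
    return pd.DataFrame(out)


def allele_frequency_spectrum(
    snps: Sequence[VariantRecord], n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of alternate allele frequencies over [0, 1].

    The final bin is right-closed so frequency 1.0 is counted.  Returns
    (counts, bin edges).
    """
    freqs = []
    for r in snps:
        if r.var_freq is None:
            raise InputError(f"record at {r.chrom}:{r.pos} has no var_freq")
        if not (0.0 <= r.var_freq <= 1.0):
            raise InputError(f"var_freq out of [0,1] at {r.chrom}:{r.pos}")
        freqs.append(r.var_freq)
    counts, edges = np.histogram(freqs, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


def snp_enriched_genes(
    annotated: Sequence[VariantRecord], features: Sequence[FeatureRecord]
) -> pd.DataFrame:
    """Rank CDS features by length-normalised SNP count.

    Returns a DataFrame (product, interval, snps, cds_length, snps_per_kb)
    sorted by snps_per_kb descending.  This is a ranking, not an
    enrichment test.
    """
    cds = [f for f in features if f.kind == "CDS"]
    counts = {f: 0 for f in cds}
    trees: dict[str, IntervalTree] = {}
    for f in cds:
        trees.setdefault(f.seqid, IntervalTree()).addi(f.start, f.end + 1, f)
    for r in annotated:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree[r.pos]:
            counts[hit.data] += 1
    rows = [
        {
            "seqid": f.seqid,
            "start": f.start,
            "end": f.end,
            "product": f.product,
            "snps": c,
            "cds_length": f.length,
            "snps_per_kb": 1000.0 * c / f.length,
        }
        for f, c in counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["snps_per_kb", "seqid", "start"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
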