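"""Dual-caller quality filtering and consensus intersection.

Two SNP call sets — one mpileup/bcftools-style, one VarScan-style — are
filtered with the conventional thresholds for each caller and then
intersected on the ``(chrom, pos, ref, alt)`` key, keeping only calls both
callers agree on.  All threshold comparisons are inclusive.  A record
missing an optional field (p-value, RMS mapping quality, variant quality)
skips that sub-test rather than failing it; skip counts are logged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .errors import InputError
from .io_formats import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class FilterPolicy:
    """Inclusive thresholds for both caller-style filters.

    ``min_depth``/``min_alt_reads`` apply to both callers; ``min_rms_mapq``
    and ``min_variant_quality`` to the mpileup-style filter (the VCFtools
    letter codes d/a/Q/q); ``min_var_freq`` and ``max_p`` to the
    VarScan-style filter.
    """

    min_depth: int = 10
    min_alt_reads: int = 4
    min_var_freq: float = 0.2
    max_p: float = 0.05
    min_variant_quality: float = 10.0
    min_rms_mapq: float = 15.0

    def __post_init__(self) -> None:
        if min(
            self.min_depth,
            self.min_alt_reads,
            self.min_var_freq,
            self.max_p,
            self.min_variant_quality,
            self.min_rms_mapq,
        ) < 0:
            raise InputError("policy thresholds must be non-negative")
        if not 0.0 <= self.min_var_freq <= 1.0:
            raise InputError("min_var_freq must be in [0, 1]")


def _passes(value, threshold, op, skipped: Counter, name: str) -> bool:
    if value is None:
        skipped[name] += 1
        return True
    return op(value, threshold)


def filter_samtools_style(
    records: Iterable[VariantRecord], policy: FilterPolicy | None = None
) -> list[VariantRecord]:
    """depth >= d AND alt reads >= a AND RMS mapq >= Q AND variant quality >= q."""
    policy = policy or FilterPolicy()
    skipped: Counter = Counter()
    ge = lambda v, t: v >= t
    kept = [
        r
        for r in records
        if _passes(r.total_depth, policy.min_depth, ge, skipped, "total_depth")
        and _passes(r.alt_reads, policy.min_alt_reads, ge, skipped, "alt_reads")
        and _passes(r.rms_mapq, policy.min_rms_mapq, ge, skipped, "rms_mapq")
        and _passes(
            r.variant_quality, policy.min_variant_quality, ge, skipped, "variant_quality"
        )
    ]
    if skipped:
        logger.info("samtools-style filter skipped absent fields: %s", dict(skipped))
    return kept


def filter_varscan_style(
    records: Iterable[VariantRecord], policy: FilterPolicy | None = None
) -> list[VariantRecord]:
    """depth >= min-coverage AND alt reads >= min-reads2 AND freq >= min-var-freq
    AND p <= p-value."""
    policy = policy or FilterPolicy()
    skipped: Counter = Counter()
    ge = lambda v, t: v >= t
    le = lambda v, t: v <= t
    kept = [
        r
        for r in records
        if _passes(r.total_depth, policy.min_depth, ge, skipped, "total_depth")
        and _passes(r.alt_reads, policy.min_alt_reads, ge, skipped, "alt_reads")
        and _passes(r.var_freq, policy.min_var_freq, ge, skipped, "var_freq")
        and _passes(r.p_value, policy.max_p, le, skipped, "p_value")
    ]
    if skipped:
        logger.info("varscan-style filter skipped absent fields: %s", dict(skipped))
    return kept


def _keyed(records: Iterable[VariantRecord], label: str) -> dict:
    out: dict = {}
    for r in records:
        if r.key in out:
            raise InputError(f"duplicate key {r.key} in input {label}")
        out[r.key] = r
    return out


def intersect_calls(
    set_a: Iterable[VariantRecord], set_b: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Calls present in both sets by (chrom, pos, ref, alt).

    The merged record carries both callers' provenance tags and the larger
    of the two reported depths (the callers pile up reads differently);
    depth disagreement is logged.
    """
    a = _keyed(set_a, "A")
    b = _keyed(set_b, "B")
    merged: list[VariantRecord] = []
    n_disagree = 0
    for key in a:
        if key not in b:
            continue
        ra, rb = a[key], b[key]
        depths = [d for d in (ra.total_depth, rb.total_depth) if d is not None]
        if len(depths) == 2 and depths[0] != depths[1]:
            n_disagree += 1
        base = ra if (ra.total_depth or 0) >= (rb.total_depth or 0) else rb
        caller = "+".join(t for t in (ra.caller, rb.caller) if t) or base.caller
        merged.append(
            base.copy(
                total_depth=max(depths) if depths else None,
                caller=caller,
                effect=ra.effect if ra.effect is not None else rb.effect,
            )
        )
    if n_disagree:
        logger.info("intersection: %d site(s) with caller depth disagreement", n_disagree)
    merged.sort(key=lambda r: r.key)
    return merged
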