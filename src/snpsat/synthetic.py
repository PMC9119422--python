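"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data shapes the toolkit consumes — per-base
depth profiles drawn from an exponential+normal mixture, paired caller
call sets whose detection model mirrors the dual-caller thresholds,
downsampling SNP-count series, and strain feature tables for the
saturation-number predictor.  Every generator is bit-reproducible for a
fixed seed (per-strain streams are derived with ``numpy`` seed
sequences), and the generating parameters are retained so tests can score
recovery against them.

Depth draws are independent across positions; the histogram-based mixture
fit ignores position order, so autocorrelation is deliberately not
modelled.  No read-level sequence is simulated — counts, not bases.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .io_formats import (
    DepthTable,
    FeatureRecord,
    VariantRecord,
    write_depth_table,
    write_feature_table,
    write_variant_records,
)
from .depth_mixture import DepthHistogram
from .predictor import FEATURES, TARGET

_BASES = np.array(list("ACGT"))

_EFFECT_LABELS = (
    "synonymous_variant",
    "missense_variant",
    "stop_gained",
    "start_lost",
    "intergenic_region",
    "upstream_gene_variant",
)
_EFFECT_PROBS = (0.55, 0.18, 0.02, 0.01, 0.14, 0.10)


@dataclass
class StrainSpec:
    name: str
    genome_length: int
    abundance: float
    n_snps: int
    w_exp: float = 0.3
    lam: float = 0.2
    mu: float = 50.0
    sigma: float = 5.0
    error_rate: float = 0.005
    p_fixed: float = 0.7  # fraction of SNPs at allele frequency 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.1):
            raise InputError("error_rate must be in [0, 0.1]")
        if self.mu <= 0:
            raise InputError("mu must be positive")


@dataclass
class SimulationScenario:
    seed: int
    strains: list[StrainSpec]
    schedule: tuple[int, ...] = (
        4_000_000,
        6_000_000,
        8_000_000,
        10_000_000,
        14_000_000,
        20_000_000,
    )

    def __post_init__(self) -> None:
        total = sum(s.abundance for s in self.strains)
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"strain abundances sum to {total}, expected 1")

    def strain(self, name: str) -> StrainSpec:
        for s in self.strains:
            if s.name == name:
                return s
        raise InputError(f"unknown strain {name}")

    def rng_for(self, name: str, stream: int = 0) -> np.random.Generator:
        idx = [s.name for s in self.strains].index(name)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(idx, stream))
        )


def default_scenario(seed: int = 42) -> SimulationScenario:
    """A small three-strain community sized for fast end-to-end runs."""
    return SimulationScenario(
        seed=seed,
        strains=[
            StrainSpec("strainA", 30_000, 0.5, 150, mu=60.0, sigma=6.0),
            StrainSpec("strainB", 20_000, 0.3, 100, mu=45.0, sigma=5.0),
            StrainSpec("strainC", 25_000, 0.2, 60, mu=30.0, sigma=4.0),
        ],
    )


# ---------------------------------------------------------------------------


def simulate_depth_profile(
    scenario: SimulationScenario, strain: str, n_positions: Optional[int] = None
) -> tuple[DepthTable, DepthHistogram]:
    """Per-position depths from the strain's two-component mixture.

    Exponential draws are rounded up to >= 1; normal draws rounded and
    clipped at 1.  All ``n_positions`` (default: the genome length)
    positions are emitted as covered.
    """
    spec = scenario.strain(strain)
    rng = scenario.rng_for(strain, stream=0)
    n = n_positions or spec.genome_length
    from_exp = rng.random(n) < spec.w_exp
    depths = np.empty(n, dtype=int)
    n_exp = int(from_exp.sum())
    depths[from_exp] = np.ceil(rng.exponential(1.0 / spec.lam, n_exp)).astype(int)
    depths[~from_exp] = np.maximum(
        np.rint(rng.normal(spec.mu, spec.sigma, n - n_exp)).astype(int), 1
    )
    table = DepthTable(
        strain,
        pd.DataFrame(
            {"chrom": strain, "pos": np.arange(1, n + 1), "depth": depths}
        ),
    )
    return table, DepthHistogram.from_depth_table(table, genome_length=spec.genome_length)


def true_snp_set(
    scenario: SimulationScenario, strain: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth SNPs: (positions, ref, alt, true allele freqs, effects)."""
    spec = scenario.strain(strain)
    rng = scenario.rng_for(strain, stream=1)
    pos = np.sort(
        rng.choice(np.arange(1, spec.genome_length + 1), size=spec.n_snps, replace=False)
    )
    ref_idx = rng.integers(0, 4, spec.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, spec.n_snps)) % 4
    # mostly fixed substitutions, a minority segregating
    freqs = np.where(
        rng.random(spec.n_snps) < spec.p_fixed,
        1.0,
        rng.uniform(0.25, 0.95, spec.n_snps),
    )
    effects = rng.choice(_EFFECT_LABELS, size=spec.n_snps, p=_EFFECT_PROBS)
    return pos, _BASES[ref_idx], _BASES[alt_idx], freqs, effects


def _emit_record(
    strain: str,
    pos: int,
    ref: str,
    alt: str,
    depth: int,
    alt_reads: int,
    caller: str,
    rng: np.random.Generator,
    effect: Optional[str],
    is_true: bool,
) -> VariantRecord:
    return VariantRecord(
        chrom=strain,
        pos=int(pos),
        ref=str(ref),
        alt=str(alt),
        total_depth=int(depth),
        alt_reads=int(alt_reads),
        var_freq=alt_reads / depth if depth else 0.0,
        variant_quality=float(np.round(rng.uniform(20, 60), 1)),
        rms_mapq=float(np.round(rng.uniform(20, 60), 1)),
        p_value=float(1e-6 if is_true else rng.uniform(0.0, 0.05)),
        caller=caller,
        effect=effect,
    )


def simulate_call_sets(
    scenario: SimulationScenario, strain: str
) -> tuple[list[VariantRecord], list[VariantRecord], set]:
    """Paired caller call sets plus the ground-truth key set.

    A caller detects a true SNP iff the site depth is >= 10 and its
    independent binomial draw of alt-supporting reads (success probability
    ``freq * (1 - error)``) reaches 4 reads and frequency 0.2 — mirroring
    the dual-caller thresholds.  Each caller also emits its own
    false-positive records at sites governed by the strain error rate, so
    intersecting the two sets removes most of them.
    """
    spec = scenario.strain(strain)
    depth_table, _ = simulate_depth_profile(scenario, strain)
    site_depth = depth_table.table.set_index("pos")["depth"]
    pos, ref, alt, freqs, effects = true_snp_set(scenario, strain)
    truth = {(strain, int(p), str(r), str(a)) for p, r, a in zip(pos, ref, alt)}

    calls: dict[str, list[VariantRecord]] = {"callerA": [], "callerB": []}
    for ci, caller in enumerate(calls):
        rng = scenario.rng_for(strain, stream=2 + ci)
        for p, r, a, f, eff in zip(pos, ref, alt, freqs, effects):
            d = int(site_depth.get(p, 0))
            if d < 10:
                continue
            b = int(rng.binomial(d, min(f * (1.0 - spec.error_rate), 1.0)))
            if b >= 4 and b / d >= 0.2:
                calls[caller].append(
                    _emit_record(strain, p, r, a, d, b, caller, rng, eff, True)
                )
        # independent false positives per caller
        n_fp = int(rng.poisson(spec.error_rate * spec.genome_length * 0.1))
        fp_pool = np.setdiff1d(
            rng.integers(1, spec.genome_length + 1, size=max(4 * n_fp, 8)), pos
        )
        rng.shuffle(fp_pool)
        emitted = 0
        for p in fp_pool:
            if emitted >= n_fp:
                break
            d = int(site_depth.get(int(p), 0))
            if d < 10:
                continue
            b = int(rng.binomial(d, 0.3))
            if b < 4 or b / d < 0.2:
                continue
            r, a = rng.choice(_BASES, size=2, replace=False)
            calls[caller].append(
                _emit_record(strain, int(p), r, a, d, b, caller, rng, None, False)
            )
            emitted += 1
    return calls["callerA"], calls["callerB"], truth


def simulate_saturation_series(
    scenario: SimulationScenario,
    strain: str,
    schedule: Optional[Sequence[int]] = None,
    full_depth: Optional[float] = None,
    level_max: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(levels, SNP counts) for a downsampling series.

    At level L the strain's sites carry binomially thinned depth
    ``Binomial(full site depth, L / level_max)``; a SNP counts as detected
    when the thinned site passes the depth/alt-reads/frequency detection
    rule.  The expected curve is concave increasing towards the true SNP
    number.  ``full_depth`` is the strain's site depth at ``level_max``
    (default: the deepest schedule level), so passing a schedule cut short
    of ``level_max`` yields a series truncated before its plateau.
    """
    spec = scenario.strain(strain)
    schedule = tuple(scenario.schedule if schedule is None else schedule)
    rng = scenario.rng_for(strain, stream=7)
    pos, _, _, freqs, _ = true_snp_set(scenario, strain)
    base_depth = full_depth or spec.mu
    full = np.maximum(np.rint(rng.normal(base_depth, spec.sigma, len(pos))), 1).astype(int)
    counts = []
    lmax = level_max or schedule[-1]
    for level in schedule:
        thin = rng.binomial(full, level / lmax)
        b = rng.binomial(thin, np.minimum(freqs * (1 - spec.error_rate), 1.0))
        detected = (thin >= 10) & (b >= 4) & (b >= 0.2 * thin)
        counts.append(int(detected.sum()))
    return np.array(schedule, dtype=float), np.array(counts, dtype=float)


# ---------------------------------------------------------------------------
# Predictor cohorts


def _predictor_features(n: int, rng: np.random.Generator) -> pd.DataFrame:
    coverage = rng.uniform(0.5, 1.0, n)
    depth = rng.uniform(1.0, 500.0, n)
    abundance = rng.uniform(0.01, 0.3, n)
    genome_length = rng.uniform(2e6, 7e6, n)
    snp_count = np.power(10.0, rng.uniform(3.0, 5.0, n))
    snp_density = snp_count / (coverage * genome_length)
    return pd.DataFrame(
        {
            "coverage": coverage,
            "depth": depth,
            "abundance": abundance,
            "genome_length": genome_length,
            "snp_count": snp_count,
            "snp_density": snp_density,
        }
    )


LINEAR_COEFS = {
    "coverage": 2_000.0,
    "depth": 15.0,
    "abundance": 8_000.0,
    "genome_length": 1e-3,
    "snp_count": 1.4,
    "snp_density": 5e5,
}
LINEAR_INTERCEPT = 500.0


def nonlinear_target(df: pd.DataFrame) -> np.ndarray:
    """Noise-free nonlinear ground truth: the saturated count is the
    current count inflated by a smooth monotone factor of SNP density
    (densely mutated strains are closer to saturation in this model)."""
    # inflation factor stays >= 1: saturation can only add SNPs
    log_density = np.log10(df["snp_density"].to_numpy())
    return df["snp_count"].to_numpy() * (
        2.0 + np.tanh(2.0 * (log_density + 2.4))
    )


def linear_target(df: pd.DataFrame) -> np.ndarray:
    out = np.full(len(df), LINEAR_INTERCEPT)
    for name, c in LINEAR_COEFS.items():
        out = out + c * df[name].to_numpy()
    return out


def simulate_predictor_dataset(
    n_strains: int,
    relation: str = "nonlinear",
    noise_sd: float = 0.02,
    seed: int = 42,
) -> pd.DataFrame:
    """Strain feature table with a known target function.

    ``noise_sd`` is the relative (multiplicative) noise level.  The
    noise-free ground truth is kept in the ``target_truth`` column.
    """
    if n_strains < 25:
        raise InputError("need at least 25 strains")
    if relation not in ("linear", "nonlinear"):
        raise InputError(f"unknown relation {relation!r}")
    rng = np.random.default_rng(seed)
    df = _predictor_features(n_strains, rng)
    truth = linear_target(df) if relation == "linear" else nonlinear_target(df)
    noisy = truth * (1.0 + noise_sd * rng.standard_normal(n_strains))
    df.insert(0, "strain", [f"s{i:04d}" for i in range(n_strains)])
    df.insert(1, "sample", "sim")
    df.insert(2, "level", 1_000_000)
    df[TARGET] = noisy
    df["target_truth"] = truth
    return df


# ---------------------------------------------------------------------------
# FASTQ and annotation fixtures


def simulate_reads(
    n_reads: int = 200,
    read_length: int = 100,
    n_overlong: int = 1,
    seed: int = 42,
) -> list[SeqRecord]:
    """Uniform-length reads plus a few ragged overlong ones whose extra
    cycles are the trimming target."""
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        length = read_length + (5 if i < n_overlong else 0)
        seq = "".join(rng.choice(_BASES, size=length))
        rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = list(
            rng.integers(25, 40, size=length)
        )
        reads.append(rec)
    return reads


def simulate_annotation(
    scenario: SimulationScenario, strain: str, n_cds: int = 20
) -> list[FeatureRecord]:
    """Non-overlapping CDS intervals tiling part of the strain genome."""
    spec = scenario.strain(strain)
    rng = scenario.rng_for(strain, stream=9)
    starts = np.sort(
        rng.choice(
            np.arange(1, spec.genome_length - 500, 1), size=n_cds, replace=False
        )
    )
    feats = []
    prev_end = 0
    products = ["ABC transporter", "MFS transporter", "integrase", "kinase", "hypothetical protein"]
    for s in starts:
        s = max(int(s), prev_end + 1)
        e = min(int(s) + int(rng.integers(150, 450)), spec.genome_length)
        if e <= s:
            continue
        feats.append(
            FeatureRecord(
                seqid=strain,
                start=s,
                end=e,
                strand="+" if rng.random() < 0.5 else "-",
                kind="CDS",
                product=str(rng.choice(products)),
            )
        )
        prev_end = e
    return feats


def write_fixture_dir(scenario: SimulationScenario, out_dir: str) -> dict:
    """Materialise the scenario as on-disk fixtures (VCF/TSV/GFF3/FASTQ)
    plus a ground_truth.json; returns the manifest of written paths."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"strains": {}, "schedule": list(scenario.schedule)}
    truth_all: dict = {}
    from Bio import SeqIO

    for spec in scenario.strains:
        name = spec.name
        depth_table, _ = simulate_depth_profile(scenario, name)
        depth_path = os.path.join(out_dir, f"{name}.depth.tsv")
        write_depth_table(depth_path, depth_table)

        calls_a, calls_b, truth = simulate_call_sets(scenario, name)
        vcf_a = os.path.join(out_dir, f"{name}.callerA.vcf")
        vcf_b = os.path.join(out_dir, f"{name}.callerB.vcf")
        write_variant_records(vcf_a, calls_a, contigs=[name])
        write_variant_records(vcf_b, calls_b, contigs=[name])

        gff_path = os.path.join(out_dir, f"{name}.gff3")
        write_feature_table(gff_path, simulate_annotation(scenario, name))

        levels, counts = simulate_saturation_series(scenario, name)
        series_path = os.path.join(out_dir, f"{name}.series.tsv")
        pd.DataFrame(
            {"strain": name, "level": levels.astype(int), "snp_count": counts.astype(int)}
        ).to_csv(series_path, sep="\t", index=False)

        truth_all[name] = {
            "genome_length": spec.genome_length,
            "abundance": spec.abundance,
            "n_true_snps": spec.n_snps,
            "mixture": {
                "w_exp": spec.w_exp,
                "lam": spec.lam,
                "mu": spec.mu,
                "sigma": spec.sigma,
            },
            "true_keys": sorted([list(k) for k in truth]),
        }
        manifest["strains"][name] = {
            "depth": depth_path,
            "vcf_a": vcf_a,
            "vcf_b": vcf_b,
            "gff": gff_path,
            "series": series_path,
        }

    reads_path = os.path.join(out_dir, "reads.fastq")
    SeqIO.write(simulate_reads(seed=scenario.seed), reads_path, "fastq")
    manifest["reads"] = reads_path

    strains_tsv = os.path.join(out_dir, "strains.tsv")
    pd.DataFrame(
        [
            {
                "strain": s.name,
                "genome_length": s.genome_length,
                # read counts proportional to abundance * genome length
                "mapped_reads": int(round(s.abundance * s.genome_length * 10)),
            }
            for s in scenario.strains
        ]
    ).to_csv(strains_tsv, sep="\t", index=False)
    manifest["strains_tsv"] = strains_tsv

    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth_all, fh, indent=2, sort_keys=True)
    manifest["ground_truth"] = os.path.join(out_dir, "ground_truth.json")
    return manifest
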