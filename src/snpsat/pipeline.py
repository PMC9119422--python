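"""End-to-end orchestration: simulate → depth fit → dual-caller filter →
depth filter → profiles → saturation, with a hashed output manifest.

Every stage writes under the configured output directory only, and a
re-run with the same config and seed reproduces byte-identical outputs
(the manifest records a sha256 per file so tests and users can check)."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import depth_mixture, io_formats, saturation, strain_profiles, variant_filter
from .errors import InputError
from .synthetic import SimulationScenario, StrainSpec, default_scenario, write_fixture_dir

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 42
    scenario_path: str | None = None
    keep_normal: float = 0.9
    discard_exp: float = 0.5
    final_r_threshold: float = saturation.FINAL_R_THRESHOLD
    mono_tolerance: float = saturation.MONO_TOLERANCE
    policy: variant_filter.FilterPolicy = field(default_factory=variant_filter.FilterPolicy)
    em: depth_mixture.EMConfig = field(default_factory=depth_mixture.EMConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.seed < 0:
            raise InputError("seed must be a non-negative integer")
        if self.scenario_path is not None and not os.path.exists(self.scenario_path):
            raise InputError(f"scenario file not found: {self.scenario_path}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        if not os.path.exists(path):
            raise InputError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError("config must be a flat key/value mapping")
        known = {f for f in cls.__dataclass_fields__ if f not in ("policy", "em")}
        policy_kwargs = {}
        em_kwargs = {}
        kwargs = {}
        for key, val in data.items():
            if key in known:
                kwargs[key] = val
            elif key in variant_filter.FilterPolicy.__dataclass_fields__:
                policy_kwargs[key] = val
            elif key in depth_mixture.EMConfig.__dataclass_fields__:
                em_kwargs[key] = val
            else:
                raise InputError(f"unknown config key: {key}")
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        if policy_kwargs:
            cfg.policy = variant_filter.FilterPolicy(**policy_kwargs)
        if em_kwargs:
            cfg.em = depth_mixture.EMConfig(**em_kwargs)
        return cfg


def load_scenario(path: str) -> SimulationScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        strains = [StrainSpec(**s) for s in data["strains"]]
        return SimulationScenario(
            seed=int(data["seed"]),
            strains=strains,
            schedule=tuple(data.get("schedule", SimulationScenario(0, []).schedule))
            if data.get("schedule")
            else SimulationScenario.__dataclass_fields__["schedule"].default,
        )
    except (KeyError, TypeError) as exc:
        raise InputError(f"invalid scenario file {path}: {exc}") from exc


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the configured (or default) scenario.

    Returns the manifest: per-file relative path, size and sha256, plus
    the parameters actually used at each stage (audit log)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    if config.scenario_path:
        scenario = load_scenario(config.scenario_path)
    else:
        scenario = default_scenario(seed=config.seed)

    stage = "simulate"
    audit: dict = {
        "seed": config.seed,
        "keep_normal": config.keep_normal,
        "discard_exp": config.discard_exp,
        "final_r_threshold": config.final_r_threshold,
        "mono_tolerance": config.mono_tolerance,
        "policy": asdict(config.policy),
        "em": asdict(config.em),
    }
    try:
        fixtures_dir = os.path.join(out, "fixtures")
        fixtures = write_fixture_dir(scenario, fixtures_dir)

        strains_df = pd.read_csv(fixtures["strains_tsv"], sep="\t")
        lengths = dict(zip(strains_df["strain"], strains_df["genome_length"]))
        counts = dict(zip(strains_df["strain"], strains_df["mapped_reads"]))

        stage = "fit-depth"
        fits = {}
        thresholds = {}
        for name, paths in fixtures["strains"].items():
            depth_table = io_formats.read_depth_table(paths["depth"], strain=name)
            hist = depth_mixture.DepthHistogram.from_depth_table(
                depth_table, genome_length=lengths[name]
            )
            fit = depth_mixture.fit_depth_mixture(hist, config.em)
            thr = depth_mixture.select_threshold(
                fit, config.keep_normal, config.discard_exp
            )
            fits[name] = fit
            thresholds[name] = thr
            with open(os.path.join(out, f"{name}.fit.json"), "w") as fh:
                json.dump(
                    {
                        "strain": name,
                        "w_exp": fit.w_exp,
                        "w_norm": fit.w_norm,
                        "lambda": fit.lam,
                        "mu": fit.mu,
                        "sigma": fit.sigma,
                        "log_likelihood": fit.log_likelihood,
                        "n_iterations": fit.n_iterations,
                        "converged": fit.converged,
                        "t_norm": thr.t_norm,
                        "t_exp": thr.t_exp,
                        "t_final": thr.t_final,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            logger.info("%s: threshold t_final=%d (t_norm=%d, t_exp=%d)", name, thr.t_final, thr.t_norm, thr.t_exp)

        stage = "filter"
        credible: dict[str, list] = {}
        for name, paths in fixtures["strains"].items():
            calls_a = io_formats.read_variant_records(paths["vcf_a"], "callerA")
            calls_b = io_formats.read_variant_records(paths["vcf_b"], "callerB")
            kept_a = variant_filter.filter_samtools_style(calls_a, config.policy)
            kept_b = variant_filter.filter_varscan_style(calls_b, config.policy)
            tentative = variant_filter.intersect_calls(kept_a, kept_b)
            depth_table = io_formats.read_depth_table(paths["depth"], strain=name)
            final, removed = depth_mixture.apply_depth_filter(
                tentative, depth_table, thresholds[name]
            )
            credible[name] = final
            logger.info(
                "%s: %d/%d calls intersected, %d removed by depth filter",
                name,
                len(tentative),
                min(len(kept_a), len(kept_b)),
                removed,
            )
            io_formats.write_variant_records(
                os.path.join(out, f"{name}.credible.vcf"), final, contigs=[name]
            )

        stage = "profile"
        abundances = strain_profiles.relative_abundance(counts, lengths)
        pd.DataFrame(
            [
                {
                    "strain": a.strain,
                    "mapped_reads": a.n_reads,
                    "genome_length": a.genome_length,
                    "abundance": a.abundance,
                }
                for a in abundances
            ]
        ).to_csv(os.path.join(out, "abundance.tsv"), sep="\t", index=False)

        metric_rows = []
        for name, paths in fixtures["strains"].items():
            depth_table = io_formats.read_depth_table(paths["depth"], strain=name)
            feats = io_formats.read_feature_table(paths["gff"])
            annotated = strain_profiles.annotate_snp_context(credible[name], feats)
            m = strain_profiles.strain_metrics(depth_table, lengths[name], annotated)
            labelled = [r for r in annotated if r.effect is not None]
            dnds = strain_profiles.compute_dnds(labelled) if labelled else None
            p_cds, _ = (
                strain_profiles.cds_proportions(annotated) if annotated else (float("nan"),) * 2
            )
            metric_rows.append(
                {
                    "strain": name,
                    "genome_depth": m.genome_depth,
                    "coverage": m.coverage,
                    "snp_count": m.snp_count,
                    "snp_density": m.snp_density,
                    "prop_cds": p_cds,
                    "dnds": "" if dnds is None or dnds.ratio is None else dnds.ratio,
                    "t_final": thresholds[name].t_final,
                }
            )
        pd.DataFrame(metric_rows).to_csv(
            os.path.join(out, "metrics.tsv"), sep="\t", index=False
        )

        afs_rows = []
        for name in fixtures["strains"]:
            if not credible[name]:
                continue
            counts_hist, edges = strain_profiles.allele_frequency_spectrum(credible[name])
            for c, lo, hi in zip(counts_hist, edges[:-1], edges[1:]):
                afs_rows.append(
                    {"strain": name, "bin_low": lo, "bin_high": hi, "count": int(c)}
                )
        pd.DataFrame(afs_rows).to_csv(os.path.join(out, "afs.tsv"), sep="\t", index=False)

        stage = "saturation"
        verdict_rows = []
        for name, paths in fixtures["strains"].items():
            series = pd.read_csv(paths["series"], sep="\t")
            result = saturation.evaluate_series(
                name,
                series["level"].to_numpy(),
                series["snp_count"].to_numpy(),
                config.final_r_threshold,
                config.mono_tolerance,
            )
            verdict_rows.append(
                {
                    "strain": name,
                    "saturated": result.saturated,
                    "saturated_snp_count": result.saturated_snp_count,
                    "final_R": result.ratios[-1],
                    "reasons": "; ".join(result.reasons),
                }
            )
        pd.DataFrame(verdict_rows).to_csv(
            os.path.join(out, "saturation.tsv"), sep="\t", index=False
        )
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    manifest_files = []
    for root, _, files in os.walk(out):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            path = os.path.join(root, f)
            manifest_files.append(
                {
                    "path": os.path.relpath(path, out),
                    "size": os.path.getsize(path),
                    "sha256": _sha256(path),
                }
            )
    manifest_files.sort(key=lambda e: e["path"])
    manifest = {"parameters": audit, "files": manifest_files}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
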