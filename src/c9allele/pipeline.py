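"""Config-driven orchestration of the analysis stages.

A YAML run configuration selects stages and parameters; outputs are TSV/JSON
files under the output directory with documented names, and a rerun with the
same configuration and seed reproduces them byte for byte.  Stages:

* ``simulate``        — write synthetic genotypes (VCF + TSV), reads
  (SAM + tabular) and the ground-truth JSON;
* ``call-haplotypes`` — diploid haplotype call from the genotypes;
* ``splice-quant``    — boundary classification, transcript-class fractions,
  intron retention scores, allelic fold decomposition;
* ``report``          — summary statistics JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import haplomap, simulate, splicequant
from .genemodel import build_registry, default_gene_model

log = logging.getLogger("c9allele")

_KNOWN_KEYS = {
    "stages",
    "seed",
    "out_dir",
    "pair",
    "depth",
    "read_length",
    "antisense_density",
    "expression_weights",
    "class_fractions",
    "joint_intron2_fraction",
    "genotype_error_rate",
    "hybrid_threshold",
    "log_level",
}

_ALL_STAGES = ("simulate", "call-haplotypes", "splice-quant", "report")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    stages: tuple[str, ...] = _ALL_STAGES
    pair: tuple[str, str] = ("R", "F")
    depth: int = 5000
    read_length: int = 75
    antisense_density: float = 0.0
    expression_weights: tuple[float, float] = (1.9, 1.0)
    class_fractions: dict = field(
        default_factory=lambda: {"R": (0.57, 0.31, 0.12), "F": (0.91, 0.08, 0.01)}
    )
    joint_intron2_fraction: float = 0.4
    genotype_error_rate: float = 0.0
    hybrid_threshold: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ConfigError("config requires 'seed' and 'out_dir'")
        kwargs = dict(raw)
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        for key in ("stages", "pair", "expression_weights"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "class_fractions" in kwargs:
            kwargs["class_fractions"] = {
                h: tuple(v) for h, v in kwargs["class_fractions"].items()
            }
        cfg = cls(**kwargs)
        for stage in cfg.stages:
            if stage not in _ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; returns the per-stage result index."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hap_map = haplomap.packaged_map()
    model = default_gene_model()
    registry = build_registry(model)
    results: dict = {"stages": list(config.stages)}

    reads = None
    genotypes = None
    for stage in config.stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            genotypes, gt_truth = simulate.gen_genotypes(
                hap_map,
                config.pair,
                error_rate=config.genotype_error_rate,
                seed=config.seed,
            )
            simulate.genotypes_to_vcf(genotypes, hap_map, out / "genotypes.vcf")
            _write_genotypes_tsv(genotypes, out / "genotypes.tsv")
            sim_cfg = simulate.SimulationConfig(
                seed=config.seed,
                pair=config.pair,
                depth=config.depth,
                read_length=config.read_length,
                antisense_density=config.antisense_density,
                expression_weights=config.expression_weights,
                class_fractions=dict(config.class_fractions),
                joint_intron2_fraction=config.joint_intron2_fraction,
            )
            reads, read_truth = simulate.gen_reads(model, registry, hap_map, sim_cfg)
            splicequant.write_sam(reads, out / "reads.sam")
            splicequant.reads_to_tsv(reads, out / "reads.tsv")
            (out / "truth.json").write_text(
                json.dumps(
                    {"genotypes": gt_truth.truth, "reads": read_truth.truth},
                    indent=2,
                    sort_keys=True,
                )
            )
            results["simulate"] = {"n_reads": len(reads)}
        elif stage == "call-haplotypes":
            if genotypes is None:
                genotypes = haplomap.genotypes_from_tsv(out / "genotypes.tsv")
            call = hap_map.call_diploid(
                genotypes, hybrid_threshold=config.hybrid_threshold
            )
            call.summary().to_csv(out / "haplotype_calls.tsv", sep="\t", index=False)
            results["call-haplotypes"] = {
                "best": ["".join(sorted(p)) for p in call.best],
                "mismatches": call.best_mismatch,
                "ambiguous": call.ambiguous,
                "hybrid_suspect": call.hybrid_suspect,
            }
        elif stage == "splice-quant":
            if reads is None:
                reads = splicequant.reads_from_tsv(out / "reads.tsv")
            fractions = splicequant.transcript_fractions_from_reads(
                reads, model, registry
            )
            retention = {
                n: splicequant.intron_retention_score(reads, model, n).score
                for n in (1, 2)
            }
            het = splicequant.het_site_bases(hap_map, config.pair)
            intron1 = splicequant.allelic_read_counts(
                reads, model, het, config.pair, region="intron1"
            )
            body = splicequant.allelic_read_counts(
                reads, model, het, config.pair, region="body"
            )
            quant: dict = {
                "fractions": {
                    "normal": fractions.normal,
                    "unspliced": fractions.unspliced,
                    "cryptic": fractions.cryptic,
                },
                "intron_retention": retention,
                "allelic_counts": {"intron1": intron1, "body": body},
            }
            if all(v > 0 for v in (*intron1.values(), *body.values())):
                h1, h2 = config.pair
                fold = splicequant.decompose_fold(
                    intron1[h1], intron1[h2], body[h1], body[h2]
                )
                quant["fold"] = {
                    "total": fold.total_fold,
                    "expression": fold.expression_fold,
                    "splicing": fold.splicing_fold,
                }
            (out / "splice_quant.json").write_text(
                json.dumps(quant, indent=2, sort_keys=True)
            )
            results["splice-quant"] = quant
        elif stage == "report":
            (out / "report.json").write_text(
                json.dumps(results, indent=2, sort_keys=True, default=str)
            )
    (out / "run.log.json").write_text(
        json.dumps(
            {"config": _config_dict(config), "results": results},
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d


def _write_genotypes_tsv(genotypes: haplomap.GenotypeSet, path: Path) -> None:
    lines = ["rs_id\tallele1\tallele2"]
    for rs_id, (a1, a2) in genotypes.calls.items():
        lines.append(f"{rs_id}\t{a1}\t{a2}")
    path.write_text("\n".join(lines) + "\n")
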