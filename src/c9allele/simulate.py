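"""Ground-truthed synthetic inputs for every stage of the pipeline.

Each generator emulates the statistical structure one stage consumes and
returns the generated artifact together with every latent parameter used, so
downstream estimators can be checked for parameter recovery:

* diploid genotypes drawn from two haplotype columns of the map, with an
  optional per-site corruption rate;
* paired cDNA/gDNA chromatogram peak heights with base-specific
  multiplicative bias, additive Gaussian noise and allele-specific
  background;
* fragment-length profiles — single peaks on the 118 + 6·u grid for normal
  alleles, a geometric-decay sawtooth run for intermediate expansions;
* strand-aware reads drawn per allele from a mixture of authentic (V1/V2/V3),
  unspliced (intron 1, ± intron 2) and cryptically spliced (C1–C4)
  transcripts carrying haplotype-consistent bases at informative SNPs, plus
  optional antisense reads confined to the intron-1 zone just downstream of
  the repeat.

Default mixture parameters follow the measured C9-ALS study conditions: the
expanded allele produces 57% normal / 31% unspliced / 12% cryptic
transcripts, the normal allele 91% / 8% / 1%, a 1.9× allelic expression
imbalance, and ~40% of intron-1-retaining transcripts also retain intron 2.
All draws are taken from a seeded generator; regeneration with the same
configuration is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chromoratio import CalibrationSeries, TraceSite
from .genemodel import CrypticSiteRegistry, GeneModel, Interval
from .haplomap import GenotypeSet, HaplotypeMap
from .repeat_sizing import FragmentProfile, Peak
from .splicequant import ReadRecord


@dataclass
class GroundTruthBundle:
    """Generated artifact plus the latent parameters that produced it."""

    params: dict
    truth: dict


# -- genotypes ---------------------------------------------------------------


def gen_genotypes(
    hap_map: HaplotypeMap,
    pair: tuple[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeSet, GroundTruthBundle]:
    """Noiseless-or-corrupted unphased genotype for a haplotype pair.

    Each site's unordered allele pair is read off the two haplotype columns
    (first listed alternative at wildcard cells); with probability
    ``error_rate`` a site is replaced by a random valid allele pair drawn
    from the alleles observed at that marker.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    for h in pair:
        if h not in hap_map.haplotypes:
            raise KeyError(f"unknown haplotype {h!r}")
    rng = np.random.default_rng(seed)
    calls: dict[str, tuple[str, str]] = {}
    corrupted: list[str] = []
    for m in hap_map.markers:
        a1 = sorted(m.allele_set(pair[0]))[0]
        a2 = sorted(m.allele_set(pair[1]))[0]
        if error_rate and rng.random() < error_rate:
            pool = sorted(
                {al for h in hap_map.haplotypes for al in m.allele_set(h)}
            )
            a1, a2 = rng.choice(pool), rng.choice(pool)
            corrupted.append(m.rs_id)
        calls[m.rs_id] = (a1, a2)
    bundle = GroundTruthBundle(
        params={"pair": list(pair), "error_rate": error_rate, "seed": seed},
        truth={"pair": sorted(pair), "corrupted_sites": corrupted},
    )
    return GenotypeSet(calls=calls), bundle


def genotypes_to_vcf(
    genotypes: GenotypeSet, hap_map: HaplotypeMap, path: str | Path
) -> None:
    """Write an unphased single-sample VCF (GRCh38 coordinates from the map)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr9,length=138394717>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for m in hap_map.markers:
        obs = genotypes.calls.get(m.rs_id)
        if obs is None:
            continue
        if any(a in {"-", "--"} or a.isdigit() for a in obs):
            continue  # indel/repeat tokens are carried in the TSV form only
        alleles = sorted(set(obs))
        ref = alleles[0]
        alts = alleles[1:] or ["."]
        order = {a: i for i, a in enumerate(alleles)}
        gt = "/".join(str(order[a]) for a in obs)
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    str(m.pos),
                    m.rs_id,
                    ref,
                    ",".join(alts),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                    gt,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- chromatogram traces -----------------------------------------------------


def gen_trace_sites(
    true_ratio: float,
    bias: float = 1.3,
    background: float = 0.0,
    noise_sd: float = 0.0,
    n_sites: int = 1,
    seed: int = 0,
    rs_id: str = "rs10757668",
    bases: tuple[str, str] = ("T", "C"),
    scale: float = 1000.0,
) -> tuple[list[tuple[TraceSite, TraceSite]], GroundTruthBundle]:
    """Paired cDNA/gDNA trace sites encoding a known allelic ratio.

    gDNA heights encode the 1:1 genomic ratio distorted by the base-a
    multiplicative ``bias``; cDNA heights encode ``true_ratio`` with the same
    bias.  Gaussian noise (sd = ``noise_sd`` × scale) is added to every
    height, and ``background`` is added per allele on top of the signal.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    p_cdna = true_ratio / (1.0 + true_ratio)
    pairs = []
    for i in range(n_sites):
        heights = {}
        for label, p in (("cDNA", p_cdna), ("gDNA", 0.5)):
            h_a = scale * p * bias + rng.normal(0.0, noise_sd * scale)
            h_b = scale * (1.0 - p) + rng.normal(0.0, noise_sd * scale)
            heights[label] = (max(h_a, 0.0) + background, max(h_b, 0.0) + background)
        bg = background or None
        cdna = TraceSite(
            rs_id=f"{rs_id}" if n_sites == 1 else f"{rs_id}_{i}",
            base_a=bases[0],
            base_b=bases[1],
            height_a=heights["cDNA"][0],
            height_b=heights["cDNA"][1],
            background_a=bg,
            background_b=bg,
            source="cDNA",
        )
        gdna = TraceSite(
            rs_id=cdna.rs_id,
            base_a=bases[0],
            base_b=bases[1],
            height_a=heights["gDNA"][0],
            height_b=heights["gDNA"][1],
            background_a=bg,
            background_b=bg,
            source="gDNA",
        )
        pairs.append((cdna, gdna))
    bundle = GroundTruthBundle(
        params={
            "true_ratio": true_ratio,
            "bias": bias,
            "background": background,
            "noise_sd": noise_sd,
            "n_sites": n_sites,
            "seed": seed,
        },
        truth={"true_ratio": true_ratio, "true_proportion": p_cdna},
    )
    return pairs, bundle


def gen_mixture_series(
    proportions: Sequence[float] | None = None,
    bias: float = 1.3,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[CalibrationSeries, GroundTruthBundle]:
    """Calibration mixture series of two homozygous templates.

    Defaults emulate the published design: mixtures from 9:1 to 1:9 measured
    over repeated sequencing runs.  Each measured point is the
    gDNA-normalized allele-a proportion computed from a generated trace pair.
    """
    from .chromoratio import normalize_ratio

    if proportions is None:
        proportions = [i / 10 for i in range(1, 10)]  # 0.1 ... 0.9
    points = []
    rng_seed = np.random.default_rng(seed)
    for p in proportions:
        if not 0 < p < 1:
            raise ValueError("mixture proportions must lie strictly in (0, 1)")
        for _ in range(replicates):
            sub_seed = int(rng_seed.integers(0, 2**31 - 1))
            (pair,), _ = gen_trace_sites(
                true_ratio=p / (1 - p),
                bias=bias,
                noise_sd=noise_sd,
                n_sites=1,
                seed=sub_seed,
            )
            points.append((p, normalize_ratio(*pair).proportion))
    bundle = GroundTruthBundle(
        params={
            "proportions": list(proportions),
            "bias": bias,
            "noise_sd": noise_sd,
            "replicates": replicates,
            "seed": seed,
        },
        truth={"slope": 1.0, "intercept": 0.0},
    )
    return CalibrationSeries(points=points), bundle


# -- fragment profiles -------------------------------------------------------


def gen_fragment_profile(
    allele_units: Sequence[int] = (),
    intermediate: tuple[int, int, int] | None = None,
    peak_height: float = 1000.0,
    stutter_decay: float = 0.75,
    flank_total_bp: int = 118,
    unit_bp: int = 6,
    seed: int = 0,
) -> tuple[FragmentProfile, GroundTruthBundle]:
    """Fragment-length profile for up to two repeat alleles.

    Normal alleles give one peak at 118 + 6·u each (two equal alleles
    collapse onto a single, doubled peak).  ``intermediate`` = (lo, modal,
    hi) adds a sawtooth run of unit-spaced peaks whose heights decay
    geometrically away from the modal unit.
    """
    heights: dict[int, float] = {}
    for u in allele_units:
        if u < 0:
            raise ValueError("unit counts must be non-negative")
        length = flank_total_bp + unit_bp * u
        heights[length] = heights.get(length, 0.0) + peak_height
    if intermediate is not None:
        lo, modal, hi = intermediate
        if not lo <= modal <= hi:
            raise ValueError("intermediate modal unit outside range")
        for u in range(lo, hi + 1):
            length = flank_total_bp + unit_bp * u
            h = peak_height * stutter_decay ** abs(u - modal)
            heights[length] = heights.get(length, 0.0) + h
    peaks = [Peak(length_bp=l, height=h) for l, h in sorted(heights.items())]
    profile = FragmentProfile(
        peaks=peaks, flank_total_bp=flank_total_bp, unit_bp=unit_bp
    )
    bundle = GroundTruthBundle(
        params={
            "allele_units": list(allele_units),
            "intermediate": list(intermediate) if intermediate else None,
            "stutter_decay": stutter_decay,
            "seed": seed,
        },
        truth={
            "units": sorted(allele_units, reverse=True),
            "intermediate": list(intermediate) if intermediate else None,
        },
    )
    return profile, bundle


# -- reads -------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Read-simulation parameters; defaults follow the C9-ALS study design."""

    seed: int
    pair: tuple[str, str] = ("R", "F")
    depth: int = 5000
    read_length: int = 75
    stranded: bool = True
    antisense_density: float = 0.0  # fraction of depth added as antisense reads
    # per-allele expression weights (gene-body abundance), allele order = pair
    expression_weights: tuple[float, float] = (1.9, 1.0)
    # per-allele (normal, unspliced, cryptic) transcript-class fractions
    class_fractions: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"R": (0.57, 0.31, 0.12), "F": (0.91, 0.08, 0.01)}
    )
    # fraction of intron-1-retaining transcripts that also retain intron 2
    joint_intron2_fraction: float = 0.4
    variant_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"V1": 0.10, "V2": 0.85, "V3": 0.05}
    )
    cryptic_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"C1": 0.4, "C2": 0.3, "C3": 0.2, "C4": 0.1}
    )
    cryptic_exon_bp: int = 150
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for hap, fracs in self.class_fractions.items():
            if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(
                    f"class fractions for {hap} must be non-negative and sum to 1"
                )
        for name, table in (
            ("variant_fractions", self.variant_fractions),
            ("cryptic_fractions", self.cryptic_fractions),
        ):
            vals = list(table.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.joint_intron2_fraction <= 1.0:
            raise ValueError("joint_intron2_fraction must lie in [0, 1]")
        if not 0.0 <= self.antisense_density <= 1.0:
            raise ValueError("antisense_density must lie in [0, 1]")


def _transcript_chain(
    model: GeneModel,
    registry: CrypticSiteRegistry,
    kind: str,
    detail: str | None,
    cryptic_exon_bp: int,
    retain_intron2: bool,
) -> list[Interval]:
    """Genomic intervals of one transcript class in transcript order
    (decreasing coordinates on the minus strand)."""
    if kind == "authentic":
        return model.variant_chain(detail)
    tail = [model.exons[str(i)] for i in range(3, 12)]
    if kind == "unspliced":
        # V2 pre-mRNA: exon 1b .. intron 1 .. exon 2 are genomically contiguous
        if retain_intron2:
            head = [Interval(model.exons["3"].start, model.exons["1b"].end)]
            return head + [model.exons[str(i)] for i in range(4, 12)]
        return [Interval(model.exons["2"].start, model.exons["1b"].end)] + tail
    if kind == "cryptic":
        site = registry[detail]
        head = Interval(site.pos, site.pos + cryptic_exon_bp - 1)
        return [head, model.exons["2"]] + tail
    raise ValueError(f"unknown transcript kind {kind!r}")


def _read_blocks_from_chain(
    chain: Sequence[Interval], t_start: int, read_length: int
) -> list[tuple[int, int]]:
    """Genomic blocks of a read covering transcript offsets
    [t_start, t_start + read_length)."""
    blocks: list[tuple[int, int]] = []
    remaining = read_length
    offset = 0
    for iv in chain:
        L = len(iv)
        if t_start >= offset + L:
            offset += L
            continue
        local = max(t_start - offset, 0)
        take = min(L - local, remaining)
        # transcript runs from iv.end downward on the minus strand
        hi = iv.end - local
        lo = hi - take + 1
        blocks.append((lo, hi))
        remaining -= take
        offset += L
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends beyond transcript")
    return sorted(blocks)


def gen_reads(
    model: GeneModel,
    registry: CrypticSiteRegistry,
    hap_map: HaplotypeMap,
    config: SimulationConfig,
) -> tuple[list[ReadRecord], GroundTruthBundle]:
    """Strand-aware reads from a per-allele transcript-class mixture.

    Reads are sampled with probability proportional to class fraction ×
    transcript length (reads are drawn from RNA mass, as in rRNA-depleted
    sequencing), then placed uniformly along the transcript; per-base
    coverage over regions shared by all classes is therefore proportional to
    transcript copy number, which is what the coverage-equivalent estimators
    assume.  Every read records the originating haplotype's base at each
    single-base map marker it overlaps.
    """
    rng = np.random.default_rng(config.seed)
    pair = config.pair
    rl = config.read_length

    snp_positions = [
        (m.pos, {h: sorted(m.allele_set(h))[0] for h in pair})
        for m in hap_map.markers
        if all(
            len(a) == 1 and a.isalpha()
            for h in pair
            for a in [sorted(m.allele_set(h))[0]]
        )
    ]

    # enumerate concrete transcript templates per allele with sampling weights
    templates = []  # (allele, class_kind, detail, chain, weight)
    for allele, expr in zip(pair, config.expression_weights):
        f_normal, f_unspliced, f_cryptic = config.class_fractions[allele]
        specs: list[tuple[str, str | None, float, bool]] = []
        for variant, vf in config.variant_fractions.items():
            specs.append(("authentic", variant, f_normal * vf, False))
        ji = config.joint_intron2_fraction
        specs.append(("unspliced", None, f_unspliced * (1 - ji), False))
        specs.append(("unspliced", None, f_unspliced * ji, True))
        for site, cf in config.cryptic_fractions.items():
            specs.append(("cryptic", site, f_cryptic * cf, False))
        for kind, detail, frac, retain2 in specs:
            if frac <= 0:
                continue
            chain = _transcript_chain(
                model, registry, kind, detail, config.cryptic_exon_bp, retain2
            )
            length = sum(len(iv) for iv in chain)
            templates.append((allele, kind, detail, retain2, chain, expr * frac * length))

    weights = np.array([t[-1] for t in templates], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(config.depth, weights) if config.depth else np.zeros(
        len(templates), dtype=int
    )

    reads: list[ReadRecord] = []
    class_counts: dict[str, int] = {}
    allele_class_counts: dict[str, dict[str, int]] = {h: {} for h in pair}
    idx = 0
    for (allele, kind, detail, retain2, chain, _w), n in zip(templates, counts):
        length = sum(len(iv) for iv in chain)
        if length < rl:
            raise ValueError("transcript shorter than the read length")
        starts = rng.integers(0, length - rl + 1, size=n)
        for t_start in starts:
            blocks = _read_blocks_from_chain(chain, int(t_start), rl)
            snp_obs = {
                pos: base_by_hap[allele]
                for pos, base_by_hap in snp_positions
                if any(s <= pos <= e for s, e in blocks)
            }
            reads.append(
                ReadRecord(
                    name=f"sim_{idx}",
                    chrom=model.chrom,
                    blocks=blocks,
                    strand="-",
                    snp_obs=snp_obs,
                )
            )
            idx += 1
            key = kind if detail is None else f"{kind}:{detail}"
            if retain2:
                key += "+intron2"
            class_counts[key] = class_counts.get(key, 0) + 1
            allele_class_counts[allele][kind] = (
                allele_class_counts[allele].get(kind, 0) + 1
            )

    n_antisense = int(round(config.antisense_density * config.depth))
    if n_antisense:
        # antisense transcripts co-localize with the intron-1 zone just
        # downstream of the repeat — inside the region the sense mask excludes
        zone_hi = model.intron(1).end
        zone_lo = model.hr.start - model.antisense_mask_bp
        starts = rng.integers(zone_lo, zone_hi - rl + 2, size=n_antisense)
        for s in starts:
            reads.append(
                ReadRecord(
                    name=f"sim_{idx}",
                    chrom=model.chrom,
                    blocks=[(int(s), int(s) + rl - 1)],
                    strand="+",
                    snp_obs={},
                )
            )
            idx += 1

    cfg = asdict(config)
    cfg["pair"] = list(config.pair)
    bundle = GroundTruthBundle(
        params=cfg,
        truth={
            "class_counts": class_counts,
            "allele_class_counts": allele_class_counts,
            "n_sense": int(counts.sum()),
            "n_antisense": n_antisense,
            "expected_fractions": _expected_overall_fractions(config),
        },
    )
    return reads, bundle


def _expected_overall_fractions(config: SimulationConfig) -> dict[str, float]:
    """Depth-weighted (normal, unspliced, cryptic) fractions across alleles."""
    w = np.array(config.expression_weights, dtype=float)
    w /= w.sum()
    fracs = np.zeros(3)
    for allele, weight in zip(config.pair, w):
        fracs += weight * np.array(config.class_fractions[allele])
    return {
        "normal": float(fracs[0]),
        "unspliced": float(fracs[1]),
        "cryptic": float(fracs[2]),
    }
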