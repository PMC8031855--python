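"""Allele-specific expression ratios from Sanger chromatogram peak heights.

At a heterozygous SNP inside an RT-PCR amplicon, the two alleles contribute
two superimposed base peaks.  The raw cDNA peak-height ratio confounds the
true allelic expression ratio with a base-specific incorporation bias, so it
is normalized by the same ratio measured in genomic DNA, where the two
alleles are present 1:1 by construction.  The normalization cancels any
multiplicative base bias exactly:

    ratio = (h_a(cDNA) / h_b(cDNA)) / (h_a(gDNA) / h_b(gDNA))

Allele-specific background is subtracted beforehand; sites where background
exceeds a configurable fraction of the peak are excluded.  Mixture series of
opposite homozygotes calibrate the method (measured proportion vs true
proportion is linear with slope ~1), and intron-retention ratios are the
intronic allelic ratio normalized to the mean exonic allelic ratio of the
same sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm


class ExcludedSiteError(ValueError):
    pass


@dataclass(frozen=True)
class TraceSite:
    """Paired peak heights at one heterozygous site in one trace."""

    rs_id: str
    base_a: str
    base_b: str
    height_a: float
    height_b: float
    source: str  # "cDNA" | "gDNA"
    background_a: float | None = None
    background_b: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise ValueError("the two alternative bases must differ")
        if self.height_a < 0 or self.height_b < 0:
            raise ValueError("peak heights must be non-negative")


@dataclass(frozen=True)
class AllelicRatioResult:
    """Normalized allele-a over allele-b expression contribution."""

    rs_id: str
    ratio: float
    raw_cdna_ratio: float
    gdna_ratio: float
    monoallelic: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def proportion(self) -> float:
        """Allele-a proportion p = ratio / (1 + ratio)."""
        if math.isinf(self.ratio):
            return 1.0
        return self.ratio / (1.0 + self.ratio)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rsquared: float
    pvalue_slope: float
    results: object | None = None  # statsmodels RegressionResults

    def summary(self):
        return self.results.summary() if self.results is not None else repr(self)


@dataclass
class CalibrationSeries:
    """(true allele-a proportion, measured normalized proportion) points."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for p, _ in self.points:
            if not 0.0 <= p <= 1.0:
                raise ValueError("mixture proportions must lie in [0, 1]")


@dataclass
class RetentionRatioAmplicon:
    """Intron-level allelic ratio normalized to the exonic allelic ratio."""

    intron_id: str
    ratio: float
    intronic_sites: list[str]
    exonic_sites: list[str]


def subtract_background(
    site: TraceSite, exclusion_fraction: float = 0.3
) -> TraceSite:
    """Subtract allele-specific background from a trace site.

    Corrected heights are clipped at zero.  If the background exceeds
    ``exclusion_fraction`` of the measured peak on either allele the site is
    flagged excluded (high-background traces are unreliable); exclusion is a
    flagged state, never an exception.  Sites without background fields pass
    through unchanged.
    """
    if site.background_a is None and site.background_b is None:
        return site
    bg_a = site.background_a or 0.0
    bg_b = site.background_b or 0.0
    high_a = site.height_a > 0 and bg_a > exclusion_fraction * site.height_a
    high_b = site.height_b > 0 and bg_b > exclusion_fraction * site.height_b
    corrected = replace(
        site,
        height_a=max(site.height_a - bg_a, 0.0),
        height_b=max(site.height_b - bg_b, 0.0),
        background_a=None,
        background_b=None,
    )
    if high_a or high_b:
        which = "/".join(
            b for b, high in ((site.base_a, high_a), (site.base_b, high_b)) if high
        )
        return replace(
            corrected,
            excluded=True,
            exclusion_reason=f"background > {exclusion_fraction:.0%} of peak ({which})",
        )
    return corrected


def normalize_ratio(cdna: TraceSite, gdna: TraceSite) -> AllelicRatioResult:
    """Normalize a cDNA allelic peak ratio by the genomic-DNA 1:1 ratio."""
    if cdna.rs_id != gdna.rs_id or {cdna.base_a, cdna.base_b} != {
        gdna.base_a,
        gdna.base_b,
    }:
        raise ValueError("cDNA and gDNA sites must share rs_id and base pair")
    if gdna.base_a != cdna.base_a:  # allow swapped base order in the gDNA record
        gdna = replace(
            gdna,
            base_a=gdna.base_b,
            base_b=gdna.base_a,
            height_a=gdna.height_b,
            height_b=gdna.height_a,
        )
    if gdna.height_a <= 0 or gdna.height_b <= 0:
        raise ValueError(f"zero gDNA peak height at {gdna.rs_id}")
    gdna_ratio = gdna.height_a / gdna.height_b

    if cdna.excluded or gdna.excluded:
        return AllelicRatioResult(
            rs_id=cdna.rs_id,
            ratio=float("nan"),
            raw_cdna_ratio=float("nan"),
            gdna_ratio=gdna_ratio,
            excluded=True,
            exclusion_reason=cdna.exclusion_reason or gdna.exclusion_reason,
        )
    monoallelic = cdna.height_a == 0 or cdna.height_b == 0
    raw = (
        float("inf")
        if cdna.height_b == 0 and cdna.height_a > 0
        else cdna.height_a / cdna.height_b
        if cdna.height_b > 0
        else 0.0
    )
    ratio = raw / gdna_ratio if not math.isinf(raw) else float("inf")
    return AllelicRatioResult(
        rs_id=cdna.rs_id,
        ratio=ratio,
        raw_cdna_ratio=raw,
        gdna_ratio=gdna_ratio,
        monoallelic=monoallelic,
    )


def fit_calibration(series: CalibrationSeries) -> LinearFit:
    """OLS of measured normalized proportion on true mixture proportion."""
    if len(series.points) < 3:
        raise ValueError("calibration needs at least 3 points")
    x = np.array([p for p, _ in series.points], dtype=float)
    y = np.array([m for _, m in series.points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mixture proportions")
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        rsquared=float(res.rsquared),
        pvalue_slope=float(res.pvalues[1]),
        results=res,
    )


def _geometric_mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ratios must be positive for geometric averaging")
    return float(np.exp(np.mean(np.log(arr))))


def intron_retention_ratio(
    intronic: Sequence[AllelicRatioResult],
    exonic: Sequence[AllelicRatioResult],
    intron_id: str = "intron",
) -> RetentionRatioAmplicon:
    """Intronic allelic ratio normalized to the exonic allelic ratio.

    Ratios from multiple heterozygous sites of one amplicon are combined by
    geometric mean (allelic ratios compose multiplicatively); excluded sites
    are dropped with provenance kept on the result.
    """
    usable_i = [r for r in intronic if not r.excluded]
    usable_e = [r for r in exonic if not r.excluded]
    if not usable_i or not usable_e:
        raise ExcludedSiteError("all intronic or all exonic sites excluded")
    ratio = _geometric_mean([r.ratio for r in usable_i]) / _geometric_mean(
        [r.ratio for r in usable_e]
    )
    return RetentionRatioAmplicon(
        intron_id=intron_id,
        ratio=ratio,
        intronic_sites=[r.rs_id for r in usable_i],
        exonic_sites=[r.rs_id for r in usable_e],
    )


def hr_ratio(units_a: int, units_b: int) -> float:
    """HR-length ratio of a diploid sample: longer over shorter allele
    (e.g. 10 and 2 repeats → 5)."""
    if units_a <= 0 or units_b <= 0:
        raise ValueError("repeat unit counts must be positive")
    return max(units_a, units_b) / min(units_a, units_b)


def regress_expression_vs_hr(
    samples: Sequence[tuple[float, float, bool]]
) -> LinearFit:
    """OLS of allelic expression ratio on HR-length ratio.

    Each sample is (hr_ratio, expression_ratio, intermediate_flag); samples
    whose repeat length is an intermediate expansion are excluded from the
    fit because their sawtooth length call is uncertain.  The slope p-value
    is the two-sided t-test on the regression coefficient.
    """
    usable = [(x, y) for x, y, intermediate in samples if not intermediate]
    if len(usable) < 3:
        raise ValueError("need at least 3 non-intermediate samples")
    x = np.array([u[0] for u in usable])
    y = np.array([u[1] for u in usable])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        rsquared=float(res.rsquared),
        pvalue_slope=float(res.pvalues[1]),
        results=res,
    )


def trace_sites_from_tsv(source) -> list[TraceSite]:
    """Load a peak table (TSV: rs_id, base_a, base_b, height_a, height_b,
    background_a, background_b, source)."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    sites = []
    for _, row in df.iterrows():
        bg_a = row.get("background_a")
        bg_b = row.get("background_b")
        sites.append(
            TraceSite(
                rs_id=str(row["rs_id"]),
                base_a=str(row["base_a"]),
                base_b=str(row["base_b"]),
                height_a=float(row["height_a"]),
                height_b=float(row["height_b"]),
                source=str(row["source"]),
                background_a=None if pd.isna(bg_a) else float(bg_a),
                background_b=None if pd.isna(bg_b) else float(bg_b),
            )
        )
    return sites
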