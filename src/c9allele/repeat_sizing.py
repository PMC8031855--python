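"""Hexanucleotide-repeat sizing from fluorescent fragment-length profiles.

The GGGGCC repeat is PCR-amplified with flanking primers and sized on a
capillary analyzer.  The amplicon carries a fixed 118 bp of flanking sequence,
so the repeat unit count is (fragment length − 118) / 6.  Normal alleles give
one sharp peak per distinct length; intermediate expansions (~20–35 units)
appear as a sawtooth run of unit-spaced stutter peaks with a modal maximum;
large pathological expansions fail to amplify and are invisible — a diploid
profile with a single normal peak is therefore reported with a second
``large_expansion_undetected`` allele when two alleles are expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import pandas as pd

FLANK_TOTAL_BP = 118
UNIT_BP = 6


class OffGridLengthError(ValueError):
    """Fragment length is not on the 118 + 6·u grid within tolerance."""


@dataclass(frozen=True)
class Peak:
    length_bp: int
    height: float


@dataclass
class FragmentProfile:
    """Fragment-length analyzer output: (length, height) peaks."""

    peaks: list[Peak]
    flank_total_bp: int = FLANK_TOTAL_BP
    unit_bp: int = UNIT_BP

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.length_bp <= 0:
                raise ValueError("fragment lengths must be positive")
            if p.height < 0:
                raise ValueError("peak heights must be non-negative")

    @classmethod
    def from_tsv(cls, source: str | Path | StringIO, **kwargs) -> "FragmentProfile":
        df = pd.read_csv(source, sep="\t")
        peaks = [
            Peak(int(r["length_bp"]), float(r["height"])) for _, r in df.iterrows()
        ]
        return cls(peaks=peaks, **kwargs)


@dataclass(frozen=True)
class AlleleCall:
    category: str  # "normal" | "intermediate" | "large_expansion_undetected"
    units: int | None = None
    unit_range: tuple[int, int] | None = None
    modal_units: int | None = None

    def __post_init__(self) -> None:
        if self.category == "normal" and (self.units is None or self.units < 0):
            raise ValueError("normal allele needs a non-negative unit count")
        if self.category == "intermediate":
            lo, hi = self.unit_range
            if not (lo <= self.modal_units <= hi):
                raise ValueError("modal units outside sawtooth range")


@dataclass
class HRCall:
    alleles: list[AlleleCall] = field(default_factory=list)

    @property
    def unit_counts(self) -> list[int | None]:
        return [a.units for a in self.alleles]


def units_from_length(
    length_bp: int,
    flank_total_bp: int = FLANK_TOTAL_BP,
    unit_bp: int = UNIT_BP,
    tolerance_bp: int = 1,
) -> int:
    """Repeat unit count of one amplicon length.

    Subtracts the total flanking length and divides by the unit size,
    rounding to the nearest integer; a residue beyond ``tolerance_bp``
    (capillary sizing jitter) is an off-grid error.
    """
    if length_bp < flank_total_bp:
        raise ValueError(
            f"fragment ({length_bp} bp) shorter than flanks ({flank_total_bp} bp)"
        )
    units = round((length_bp - flank_total_bp) / unit_bp)
    residue = abs(length_bp - flank_total_bp - units * unit_bp)
    if residue > tolerance_bp:
        raise OffGridLengthError(
            f"{length_bp} bp is {residue} bp off the {flank_total_bp}+{unit_bp}u grid"
        )
    return int(units)


def _sawtooth_runs(
    peaks: Sequence[Peak], unit_bp: int, spacing_tol: int = 1, min_run: int = 5
) -> list[list[Peak]]:
    """Maximal runs of consecutive peaks spaced unit_bp ± spacing_tol."""
    ordered = sorted(peaks, key=lambda p: p.length_bp)
    runs: list[list[Peak]] = []
    current = [ordered[0]] if ordered else []
    for prev, nxt in zip(ordered, ordered[1:]):
        if abs(nxt.length_bp - prev.length_bp - unit_bp) <= spacing_tol:
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    if current:
        runs.append(current)
    return [r for r in runs if len(r) >= min_run]


def call_alleles(
    profile: FragmentProfile,
    expected_two_alleles: bool = False,
    peak_fraction: float = 0.10,
    sawtooth_min_run: int = 5,
    tolerance_bp: int = 1,
) -> HRCall:
    """Call up to two repeat alleles from a fragment profile.

    Peaks below ``peak_fraction`` of the tallest peak are noise.  A run of at
    least ``sawtooth_min_run`` unit-spaced peaks is one intermediate allele,
    reported with its unit range and the modal (tallest-peak) unit count.
    Remaining isolated peaks are normal alleles; two alleles of equal length
    collapse to a single homozygous-length peak.  When two alleles are
    expected but only one call is made, the second allele is reported as an
    undetected large expansion (too long to PCR-amplify).
    """
    if not profile.peaks:
        raise ValueError("empty fragment profile")
    max_h = max(p.height for p in profile.peaks)
    kept = [p for p in profile.peaks if p.height >= peak_fraction * max_h]
    if not kept:
        raise ValueError("no peak above the calling threshold")

    alleles: list[AlleleCall] = []
    runs = _sawtooth_runs(kept, profile.unit_bp, min_run=sawtooth_min_run)
    in_run = {id(p) for run in runs for p in run}
    for run in runs:
        lo = units_from_length(
            run[0].length_bp, profile.flank_total_bp, profile.unit_bp, tolerance_bp
        )
        hi = units_from_length(
            run[-1].length_bp, profile.flank_total_bp, profile.unit_bp, tolerance_bp
        )
        tallest = max(run, key=lambda p: p.height)
        modal = units_from_length(
            tallest.length_bp, profile.flank_total_bp, profile.unit_bp, tolerance_bp
        )
        alleles.append(
            AlleleCall(
                category="intermediate", unit_range=(lo, hi), modal_units=modal
            )
        )

    isolated = sorted(
        (p for p in kept if id(p) not in in_run), key=lambda p: -p.height
    )
    for p in isolated[:2]:
        alleles.append(
            AlleleCall(
                category="normal",
                units=units_from_length(
                    p.length_bp, profile.flank_total_bp, profile.unit_bp, tolerance_bp
                ),
            )
        )
    alleles = alleles[:2]
    if expected_two_alleles and len(alleles) == 1:
        alleles.append(AlleleCall(category="large_expansion_undetected"))
    alleles.sort(
        key=lambda a: (
            {"normal": 0, "intermediate": 1, "large_expansion_undetected": 2}[
                a.category
            ],
            -(a.units if a.units is not None else -1),
        )
    )
    return HRCall(alleles=alleles)
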