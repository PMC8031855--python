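"""Haplotype signature map of the *C9orf72* locus and diploid haplotype calling.

The *C9orf72* gene (chr9, minus strand, GRCh38) segregates in Caucasians as a
small set of haplotypes — R (the ALS/FTD risk haplotype), F, K, P, N, J, Q and
the Asian-enriched Z — each identified by its joint allele signature over ~105
SNP/indel markers in the transcribed region.  This module encodes that map,
derives haplotype-specific markers, calls the diploid haplotype pair of an
unphased genotype by exhaustive signature matching, and estimates haplotype
frequencies.

Alleles are stored as plus-strand bases exactly as tabulated; because the gene
is on the minus strand, transcript-space bases are their complements
(:func:`to_transcript_strand`).  Sub-haplotype variable cells ("A/G") match
either base during calling and are never counted as haplotype-specific.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HAPLOTYPES: tuple[str, ...] = ("R", "F", "K", "P", "N", "J", "Q", "Z")

_MARKER_KINDS = {"snp", "indel", "short_repeat"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class MapLoadError(ValueError):
    """Raised when a haplotype map table cannot be validated."""


class UnknownSiteError(KeyError):
    """Raised when a genotype refers to a marker absent from the map."""


def to_transcript_strand(token: str) -> str:
    """Complement a plus-strand allele token into transcript space.

    Deletion tokens ("-", "--") and repeat-count tokens ("5", "6") pass
    through unchanged; wildcard tokens complement each alternative.
    """
    if token in {"-", "--"} or token.isdigit():
        return token
    if "/" in token:
        return "/".join(to_transcript_strand(t) for t in token.split("/"))
    return token.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkerRecord:
    """One polymorphic marker with its per-haplotype plus-strand allele."""

    rs_id: str
    chrom: str
    pos: int
    marker_kind: str
    allele_by_haplotype: Mapping[str, str]
    specific_for: str | None = None

    def allele_set(self, hap: str) -> frozenset[str]:
        """Set of alleles the haplotype may carry here (singleton unless a
        sub-haplotype wildcard cell)."""
        return frozenset(self.allele_by_haplotype[hap].split("/"))

    def is_wildcard(self, hap: str) -> bool:
        return "/" in self.allele_by_haplotype[hap]

    def recompute_specific(self, haplotypes: Sequence[str] = HAPLOTYPES) -> str | None:
        """Haplotype whose allele differs from every other haplotype, if any.

        Wildcard cells are excluded: a wildcard haplotype is never specific,
        and another haplotype is not specific if its allele is contained in a
        wildcard set.
        """
        for hap in haplotypes:
            if self.is_wildcard(hap):
                continue
            allele = self.allele_by_haplotype[hap]
            if all(
                allele not in self.allele_set(other)
                for other in haplotypes
                if other != hap
            ):
                return hap
        return None


@dataclass(frozen=True)
class HRUnits:
    """Hexanucleotide-repeat length of one haplotype.

    Either a fixed unit count, a categorical distribution (modal value plus
    the observed range), or undetermined (haplotype Z).
    """

    kind: str  # "fixed" | "variable" | "undetermined"
    units: int | None = None
    modal: int | None = None
    lo: int | None = None
    hi: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "variable" and not (self.lo <= self.modal <= self.hi):
            raise ValueError("modal repeat length outside observed range")


@dataclass
class GenotypeSet:
    """Unphased genotype: unordered plus-strand allele pair per marker."""

    calls: dict[str, tuple[str, str]]

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class DiploidHaplotypeCall:
    """Ranked haplotype pairs compatible with an unphased genotype."""

    candidates: list[tuple[tuple[str, str], int]]
    best: list[tuple[str, str]]
    best_mismatch: int
    ambiguous: bool
    hybrid_suspect: bool
    hybrid_detail: dict | None = None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(a, b, m) for (a, b), m in self.candidates],
            columns=["hap1", "hap2", "mismatches"],
        )
        return df.sort_values(["mismatches", "hap1", "hap2"]).reset_index(drop=True)


@dataclass
class FrequencyTable:
    """Haplotype counts and proportions over a set of called alleles."""

    table: pd.DataFrame  # columns: haplotype, count, proportion, percent

    def proportion(self, hap: str) -> float:
        row = self.table.loc[self.table["haplotype"] == hap]
        if row.empty:
            return 0.0
        return float(row["proportion"].iloc[0])


@dataclass
class DistinguishingSites:
    """Result of a minimal discriminating-marker search."""

    sites: list[str]
    minimal: bool
    unresolved_pairs: list[tuple[str, str]]

    @property
    def indistinguishable(self) -> bool:
        return bool(self.unresolved_pairs)


@dataclass
class HaplotypeMap:
    """The full per-haplotype allele matrix plus the HR-unit table."""

    markers: list[MarkerRecord]
    haplotypes: tuple[str, ...] = HAPLOTYPES
    hr_units: dict[str, HRUnits] = field(default_factory=dict)
    strand_note: bool = True  # transcript bases are complements of stored bases
    specific_flag_disagreements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: m.pos)
        self._by_rs = {m.rs_id: m for m in self.markers}
        if len(self._by_rs) != len(self.markers):
            raise MapLoadError("duplicate rs_id in marker list")
        for a, b in itertools.combinations(self.haplotypes, 2):
            if not self._differing(a, b):
                raise MapLoadError(f"haplotype signatures collide: {a} vs {b}")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.markers)

    def marker(self, rs_id: str) -> MarkerRecord:
        try:
            return self._by_rs[rs_id]
        except KeyError:
            raise UnknownSiteError(f"marker {rs_id} not in map") from None

    def __contains__(self, rs_id: str) -> bool:
        return rs_id in self._by_rs

    def _differing(self, h1: str, h2: str, rs_ids: Iterable[str] | None = None):
        markers = self.markers if rs_ids is None else [self.marker(r) for r in rs_ids]
        return [
            m for m in markers if not (m.allele_set(h1) & m.allele_set(h2))
        ]

    # -- operations --------------------------------------------------------

    def specific_snps(self, hap: str) -> list[str]:
        """rs_ids whose allele in ``hap`` differs from all 7 other haplotypes,
        ordered by position."""
        if hap not in self.haplotypes:
            raise KeyError(f"unknown haplotype {hap!r}")
        return [
            m.rs_id for m in self.markers if m.recompute_specific(self.haplotypes) == hap
        ]

    def informative_het_sites(self, pair: tuple[str, str]) -> list[str]:
        """Markers at which the two haplotypes carry disjoint alleles, ordered
        by position; these identify the allelic origin of transcripts."""
        h1, h2 = pair
        for h in (h1, h2):
            if h not in self.haplotypes:
                raise KeyError(f"unknown haplotype {h!r}")
        if h1 == h2:
            return []
        return [m.rs_id for m in self._differing(h1, h2)]

    def distinguishing_sites(
        self,
        haps: Sequence[str],
        candidate_sites: Sequence[str] | None = None,
        exhaustive_limit: int = 12,
    ) -> DistinguishingSites:
        """Minimal marker subset whose joint signature separates ``haps``.

        Exhaustive (guaranteed minimal) for small candidate sets; greedy
        set-cover otherwise, flagged non-minimal.  An empty or insufficient
        candidate set yields an indistinguishable report, not an exception.
        """
        haps = list(haps)
        if len(haps) < 2:
            raise ValueError("need at least two haplotypes to distinguish")
        if candidate_sites is None:
            candidates = [m.rs_id for m in self.markers]
        else:
            candidates = [self.marker(r).rs_id for r in candidate_sites]
        pairs = list(itertools.combinations(sorted(haps), 2))

        def separated(rs: str, pair: tuple[str, str]) -> bool:
            m = self.marker(rs)
            return not (m.allele_set(pair[0]) & m.allele_set(pair[1]))

        solvable = [p for p in pairs if any(separated(rs, p) for rs in candidates)]
        unresolved = [p for p in pairs if p not in solvable]
        if unresolved:
            return DistinguishingSites([], False, unresolved)

        if len(candidates) <= exhaustive_limit:
            for size in range(1, len(candidates) + 1):
                for combo in itertools.combinations(candidates, size):
                    if all(any(separated(rs, p) for rs in combo) for p in pairs):
                        return DistinguishingSites(sorted(
                            combo, key=lambda r: self.marker(r).pos), True, [])
            return DistinguishingSites([], False, pairs)  # pragma: no cover

        chosen: list[str] = []
        remaining = set(pairs)
        while remaining:
            best_rs = max(
                candidates,
                key=lambda rs: sum(1 for p in remaining if separated(rs, p)),
            )
            covered = {p for p in remaining if separated(best_rs, p)}
            if not covered:  # pragma: no cover - guarded by solvable check
                return DistinguishingSites(chosen, False, sorted(remaining))
            chosen.append(best_rs)
            remaining -= covered
        return DistinguishingSites(
            sorted(chosen, key=lambda r: self.marker(r).pos), False, []
        )

    def hr_length_lookup(self, hap: str) -> HRUnits:
        """HR unit count for a haplotype; haplotype Z reports undetermined."""
        if hap not in self.haplotypes:
            raise KeyError(f"unknown haplotype {hap!r}")
        try:
            return self.hr_units[hap]
        except KeyError:
            return HRUnits(kind="undetermined")

    # -- diploid calling ---------------------------------------------------

    def call_diploid(
        self, genotypes: GenotypeSet, hybrid_threshold: int = 3
    ) -> DiploidHaplotypeCall:
        """Assign the best unordered haplotype pair to an unphased genotype.

        Every one of the 36 unordered pairs is scored by the number of
        genotyped markers whose observed allele pair cannot be formed from the
        two haplotype columns (wildcards match any listed alternative).  All
        minimum-mismatch pairs are returned; with zero informative sites all
        pairs tie and the call is flagged ambiguous.  When the best pure pair
        still leaves more than ``hybrid_threshold`` mismatches, a two-segment
        haplotype (one switch point scanned along marker order, the
        recombinant F→K style) is tried against every pure partner.
        """
        if len(genotypes) == 0:
            raise ValueError("no genotyped sites")
        sites = []
        for rs_id, obs in genotypes.calls.items():
            if rs_id not in self:
                raise UnknownSiteError(f"genotyped site {rs_id} not in map")
            if obs is not None:
                sites.append((self.marker(rs_id), tuple(obs)))
        sites.sort(key=lambda t: t[0].pos)

        pairs = list(itertools.combinations_with_replacement(self.haplotypes, 2))
        n_sites = len(sites)
        # compat[i, a, b]: observed pair at site i can be formed from haps (a, b)
        nh = len(self.haplotypes)
        compat = np.zeros((max(n_sites, 1), nh, nh), dtype=bool)
        for i, (marker, obs) in enumerate(sites):
            sets = [marker.allele_set(h) for h in self.haplotypes]
            for a in range(nh):
                for b in range(nh):
                    g1, g2 = obs
                    compat[i, a, b] = (g1 in sets[a] and g2 in sets[b]) or (
                        g2 in sets[a] and g1 in sets[b]
                    )

        idx = {h: i for i, h in enumerate(self.haplotypes)}
        candidates = []
        for h1, h2 in pairs:
            mism = int(n_sites - compat[:n_sites, idx[h1], idx[h2]].sum()) if n_sites else 0
            candidates.append((tuple(sorted((h1, h2))), mism))
        candidates.sort(key=lambda t: (t[1], t[0]))
        best_mismatch = min(m for _, m in candidates)
        best = [p for p, m in candidates if m == best_mismatch]
        ambiguous = len(best) > 1

        hybrid_suspect = False
        hybrid_detail = None
        if best_mismatch > hybrid_threshold and n_sites:
            hybrid_detail = self._scan_hybrid(compat[:n_sites], idx)
            if hybrid_detail["mismatches"] < best_mismatch:
                hybrid_suspect = True
                hybrid_detail["sites"] = [m.rs_id for m, _ in sites]
            else:
                hybrid_detail = None
        return DiploidHaplotypeCall(
            candidates=candidates,
            best=best,
            best_mismatch=best_mismatch,
            ambiguous=ambiguous,
            hybrid_suspect=hybrid_suspect,
            hybrid_detail=hybrid_detail,
        )

    def _scan_hybrid(self, compat: np.ndarray, idx: dict[str, int]) -> dict:
        """Best (pure partner, hybrid A→B, switch point) assignment.

        The hybrid chromosome carries haplotype A's alleles before the switch
        point (marker order) and B's from it onward.
        """
        n_sites = compat.shape[0]
        haps = list(idx)
        best = {"mismatches": np.inf, "partner": None, "hybrid": None, "switch": None}
        for partner in haps:
            c = idx[partner]
            for a, b in itertools.permutations(haps, 2):
                ca = compat[:, c, idx[a]].astype(int)
                cb = compat[:, c, idx[b]].astype(int)
                # prefix of a, suffix of b: mismatches(k) for switch before site k
                pre = np.concatenate([[0], np.cumsum(1 - ca)])
                suf = np.concatenate([np.cumsum((1 - cb)[::-1])[::-1], [0]])
                k = int(np.argmin(pre + suf))
                m = int(pre[k] + suf[k])
                if 0 < k < n_sites and m < best["mismatches"]:
                    best = {"mismatches": m, "partner": partner,
                            "hybrid": (a, b), "switch": k}
        return best


# -- frequency estimation ---------------------------------------------------


def estimate_frequencies(
    calls: Sequence[str], haplotypes: Sequence[str] = HAPLOTYPES
) -> FrequencyTable:
    """Haplotype counts and proportions over a list of per-allele labels.

    Percent values are reported to one decimal, matching the convention used
    for published haplotype distributions (e.g. 27 of 95 alleles → 28.4%).
    """
    if not calls:
        raise ValueError("empty label list")
    unknown = sorted(set(calls) - set(haplotypes))
    if unknown:
        raise KeyError(f"unknown haplotype labels: {unknown}")
    counts = pd.Series(calls).value_counts()
    total = int(counts.sum())
    rows = [
        {
            "haplotype": hap,
            "count": int(counts.get(hap, 0)),
            "proportion": counts.get(hap, 0) / total,
            "percent": round(100.0 * counts.get(hap, 0) / total, 1),
        }
        for hap in haplotypes
        if counts.get(hap, 0) > 0
    ]
    table = pd.DataFrame(rows)
    assert abs(table["proportion"].sum() - 1.0) < 1e-9
    return FrequencyTable(table=table)


def predict_frequency_from_markers(
    marker_freqs: Mapping[str, float],
    hap_map: HaplotypeMap,
    hap: str,
    partner: str | None = None,
    partner_frequency: float | None = None,
    shared_marker: str | None = None,
) -> float:
    """Predict a haplotype's population frequency from marker frequencies.

    For a haplotype with specific markers the prediction is the mean of its
    specific-marker minor-allele frequencies.  Haplotype Q carries no specific
    marker, so its frequency is inferred from a marker shared by Q and a
    partner haplotype of known frequency: shared frequency minus partner
    frequency, floored at zero.
    """
    specific = hap_map.specific_snps(hap)
    if specific:
        usable = [marker_freqs[rs] for rs in specific if rs in marker_freqs]
        if not usable:
            raise ValueError(f"no specific-marker frequency supplied for {hap}")
        return float(np.mean(usable))
    if shared_marker is None or partner_frequency is None:
        raise ValueError(
            f"haplotype {hap} has no specific markers; supply shared_marker "
            "and partner_frequency"
        )
    if shared_marker not in marker_freqs:
        raise ValueError(f"no frequency supplied for shared marker {shared_marker}")
    estimate = marker_freqs[shared_marker] - partner_frequency
    if estimate < 0:
        warnings.warn(
            "shared-marker frequency below partner frequency; flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return float(estimate)


# -- loaders -----------------------------------------------------------------

_ALLELE_TOKEN = None  # validated in _parse_allele


def _parse_allele(token: str, rs_id: str) -> str:
    token = str(token).strip()
    parts = token.split("/")
    ok = all(
        p in {"-", "--"} or p.isdigit() or (p.isalpha() and set(p) <= set("ACGT"))
        for p in parts
    ) and all(parts)
    if not token or not ok:
        raise MapLoadError(f"unparseable allele token {token!r} at {rs_id}")
    return token


def load_map(
    source: str | Path | StringIO,
    hr_units_source: str | Path | StringIO | None = None,
    haplotypes: Sequence[str] = HAPLOTYPES,
) -> HaplotypeMap:
    """Load a haplotype map TSV (columns: rs_id, chrom, pos, kind, one column
    per haplotype, specific_for) and optional HR-unit table.

    The haplotype-specific flag is recomputed from the allele matrix; any
    disagreement with the input flags is recorded on the returned map and
    warned about.
    """
    if isinstance(source, (str, Path)) and "\t" in str(source):
        source = StringIO(str(source))
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise MapLoadError("empty map table") from None
    if df.empty:
        raise MapLoadError("empty map table")
    missing = [h for h in haplotypes if h not in df.columns]
    if missing:
        raise MapLoadError(f"missing haplotype columns: {missing}")
    for col in ("rs_id", "chrom", "pos"):
        if col not in df.columns:
            raise MapLoadError(f"missing column {col!r}")
    dups = df["rs_id"][df["rs_id"].duplicated()].tolist()
    if dups:
        raise MapLoadError(f"duplicate rs_id: {sorted(set(dups))}")

    markers = []
    disagreements = []
    for _, row in df.iterrows():
        rs_id = row["rs_id"]
        kind = row.get("kind", "snp") or "snp"
        if kind not in _MARKER_KINDS:
            raise MapLoadError(f"unknown marker kind {kind!r} at {rs_id}")
        alleles = {h: _parse_allele(row[h], rs_id) for h in haplotypes}
        rec = MarkerRecord(
            rs_id=rs_id,
            chrom=row["chrom"],
            pos=int(row["pos"]),
            marker_kind=kind,
            allele_by_haplotype=alleles,
        )
        recomputed = rec.recompute_specific(haplotypes)
        declared = row.get("specific_for", "") or None
        if declared != recomputed:
            disagreements.append(
                f"{rs_id}: declared specific_for={declared!r}, "
                f"recomputed {recomputed!r}"
            )
        markers.append(
            MarkerRecord(
                rs_id=rec.rs_id,
                chrom=rec.chrom,
                pos=rec.pos,
                marker_kind=rec.marker_kind,
                allele_by_haplotype=alleles,
                specific_for=recomputed,
            )
        )
    hr_units = load_hr_units(hr_units_source) if hr_units_source is not None else {}
    if disagreements:
        warnings.warn(
            "specific_for flags disagree with allele matrix: "
            + "; ".join(disagreements),
            stacklevel=2,
        )
    hmap = HaplotypeMap(
        markers=markers, haplotypes=tuple(haplotypes), hr_units=hr_units
    )
    hmap.specific_flag_disagreements = disagreements
    return hmap


def load_hr_units(source: str | Path | StringIO) -> dict[str, HRUnits]:
    """Load the per-haplotype HR-unit table (TSV: haplotype, kind, units,
    modal, lo, hi)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, HRUnits] = {}
    for _, row in df.iterrows():
        kind = row["kind"]
        if kind == "fixed":
            out[row["haplotype"]] = HRUnits(kind="fixed", units=int(row["units"]))
        elif kind == "variable":
            out[row["haplotype"]] = HRUnits(
                kind="variable",
                modal=int(row["modal"]),
                lo=int(row["lo"]),
                hi=int(row["hi"]),
            )
        else:
            out[row["haplotype"]] = HRUnits(kind="undetermined")
    return out


def packaged_map() -> HaplotypeMap:
    """The packaged *C9orf72* haplotype map fixture.

    Alleles, marker order and haplotype-specific flags are transcribed from
    the published map; marker positions are synthetic placeholders, evenly
    spaced across the GRCh38 gene span in printed order (the per-marker
    supplementary coordinates are not redistributed with this package).
    """
    data = resources.files("c9allele.data")
    with resources.as_file(data / "haplotype_map.tsv") as map_path, resources.as_file(
        data / "hr_units.tsv"
    ) as hr_path:
        return load_map(map_path, hr_path)


# -- genotype ingestion ------------------------------------------------------


def genotypes_from_tsv(source: str | Path | StringIO) -> GenotypeSet:
    """Minimal genotype table: rs_id, allele1, allele2 (tab-separated)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    calls = {
        row["rs_id"]: (row["allele1"], row["allele2"]) for _, row in df.iterrows()
    }
    return GenotypeSet(calls=calls)


def genotypes_from_vcf(path: str | Path) -> GenotypeSet:
    """Read unphased genotypes from a VCF (GRCh38 assumed); the ID column must
    carry the dbSNP rs identifier."""
    import pysam

    calls: dict[str, tuple[str, str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.id is None:
                continue
            sample = next(iter(rec.samples.values()))
            alleles = sample.alleles
            if alleles is None or any(a is None for a in alleles):
                continue
            if len(alleles) == 1:
                alleles = (alleles[0], alleles[0])
            calls[rec.id] = (alleles[0], alleles[1])
    return GenotypeSet(calls=calls)
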