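"""*C9orf72* gene model and the intron-1 cryptic donor site registry.

The gene lies on the minus strand of chromosome 9 (GRCh38), with two
alternative first exons flanking the GGGGCC repeat: exon 1a (variants V1/V3,
upstream of the repeat, which is spliced out) and exon 1b (variant V2,
downstream of it).  Four cryptic donor sites C1–C4, normally silent but
activated by repeat expansion, lie 665, 910, 2295 and 2308 bp downstream of
the V2 donor at chr9:27,572,766 / 27,572,520 / 27,571,136 / 27,571,123; all
splice to the 5' end of exon 2.  On the minus strand "downstream" means
decreasing plus-strand coordinates.

The packaged default model anchors the printed coordinates (C1–C4, the V2
donor they imply, the repeat location) and fills the remaining exon intervals
with synthetic-realistic coordinates; it is not a transcription of the
Ensembl annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval on the plus strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)


# transcript-ordered exon names for the 11-exon variants
_EXON_ORDER = ["1a", "1b", "2", "3", "4", "5", "6", "7", "8", "9", "10", "11"]


@dataclass
class GeneModel:
    """Exon/intron structure of *C9orf72* plus variant donor/acceptor sites."""

    chrom: str
    exons: dict[str, Interval]
    hr: Interval
    donors: dict[str, int]  # variant -> donor base (last transcribed base)
    extended_exon5: Interval | None = None
    strand: str = "-"
    antisense_mask_bp: int = 500  # intron-1 zone downstream of the HR to mask

    def __post_init__(self) -> None:
        if self.strand != "-":
            raise ValueError("C9orf72 is a minus-strand gene")
        ordered = [self.exons[n] for n in _EXON_ORDER if n in self.exons]
        for a, b in zip(ordered, ordered[1:]):
            # transcript order on the minus strand = decreasing coordinates
            if b.end >= a.start:
                raise ValueError("exons overlap or are out of transcript order")

    # -- boundaries --------------------------------------------------------

    @property
    def exon2_boundary(self) -> int:
        """First base of exon 2 in transcript orientation (its highest
        plus-strand coordinate)."""
        return self.exons["2"].end

    def intron(self, number: int) -> Interval:
        """Intron ``number`` of the 11-exon transcript (intron 1 between
        exon 1b and exon 2, intron 2 between exons 2 and 3, ...)."""
        names = ["1b"] + [str(i) for i in range(2, 12)]
        up, down = names[number - 1], names[number]
        return Interval(self.exons[down].end + 1, self.exons[up].start - 1)

    @property
    def intron1_masked(self) -> Interval:
        """Intron 1 with the first ``antisense_mask_bp`` downstream of the HR
        removed (antisense transcripts co-localize there)."""
        full = self.intron(1)
        ceiling = self.hr.start - self.antisense_mask_bp - 1
        return Interval(full.start, min(full.end, ceiling))

    def exon_span(self, names: tuple[str, ...] = ("2", "3", "4", "5")) -> list[Interval]:
        return [self.exons[n] for n in names]

    def variant_chain(self, variant: str) -> list[Interval]:
        """Genomic exon intervals of a spliced variant in transcript order
        (decreasing coordinates)."""
        donor = self.donors[variant]
        first_name = "1b" if variant == "V2" else "1a"
        first = self.exons[first_name]
        chain = [Interval(donor, first.end)]
        chain += [self.exons[str(i)] for i in range(2, 12)]
        return chain

    # -- serialization -----------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        gene_start = min(iv.start for iv in self.exons.values())
        gene_end = max(iv.end for iv in self.exons.values())
        lines = ["##gff-version 3"]

        def feat(ftype, iv, attrs):
            lines.append(
                "\t".join(
                    [
                        self.chrom,
                        "c9allele",
                        ftype,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        self.strand,
                        ".",
                        attrs,
                    ]
                )
            )

        feat("gene", Interval(gene_start, gene_end), "ID=C9orf72;Name=C9orf72")
        for name, iv in self.exons.items():
            feat("exon", iv, f"ID=exon_{name};Parent=C9orf72;Name=exon_{name}")
        if self.extended_exon5 is not None:
            feat(
                "exon",
                self.extended_exon5,
                "ID=exon_5ext;Parent=C9orf72;Name=exon_5ext",
            )
        feat("repeat_region", self.hr, "ID=HR;Name=GGGGCC_repeat")
        for variant, donor in self.donors.items():
            feat(
                "splice_donor_site",
                Interval(donor, donor),
                f"ID=donor_{variant};Parent=C9orf72;Name=donor_{variant}",
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModel":
        exons: dict[str, Interval] = {}
        hr = None
        donors: dict[str, int] = {}
        extended = None
        chrom = None
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom = f[0]
            ftype, start, end = f[2], int(f[3]), int(f[4])
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name", "")
            if ftype == "exon" and name.startswith("exon_"):
                label = name.removeprefix("exon_")
                if label == "5ext":
                    extended = Interval(start, end)
                else:
                    exons[label] = Interval(start, end)
            elif ftype == "repeat_region":
                hr = Interval(start, end)
            elif ftype == "splice_donor_site":
                donors[name.removeprefix("donor_")] = start
        if chrom is None or hr is None or not exons:
            raise ValueError(f"not a C9orf72 gene model GFF3: {path}")
        return cls(
            chrom=chrom, exons=exons, hr=hr, donors=donors, extended_exon5=extended
        )


def default_gene_model() -> GeneModel:
    """The packaged minus-strand model (printed anchors, synthetic filler)."""
    exons = {
        "1a": Interval(27_573_705, 27_573_866),
        "1b": Interval(27_573_431, 27_573_480),
        "2": Interval(27_565_958, 27_566_307),
        "3": Interval(27_563_690, 27_563_900),
        "4": Interval(27_561_800, 27_561_950),
        "5": Interval(27_560_500, 27_561_150),
        "6": Interval(27_556_500, 27_556_650),
        "7": Interval(27_555_000, 27_555_150),
        "8": Interval(27_553_000, 27_553_200),
        "9": Interval(27_551_500, 27_551_650),
        "10": Interval(27_549_500, 27_549_700),
        "11": Interval(27_546_546, 27_547_200),
    }
    return GeneModel(
        chrom="chr9",
        exons=exons,
        hr=Interval(27_573_485, 27_573_546),
        donors={"V1": 27_573_720, "V2": 27_573_431, "V3": 27_573_705},
        extended_exon5=Interval(27_559_800, 27_561_150),
    )


# -- cryptic donor sites -----------------------------------------------------

#: printed coordinates and offsets downstream of the V2 donor (GRCh38)
CRYPTIC_SITES_PRINTED: tuple[tuple[str, int, int], ...] = (
    ("C1", 27_572_766, 665),
    ("C2", 27_572_520, 910),
    ("C3", 27_571_136, 2295),
    ("C4", 27_571_123, 2308),
)


@dataclass(frozen=True)
class CrypticSite:
    name: str
    chrom: str
    pos: int
    offset_bp: int


@dataclass
class CrypticSiteRegistry:
    """The four intron-1 cryptic donor sites, transcript-ordered C1→C4."""

    entries: list[CrypticSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [e.pos for e in self.entries]
        if positions != sorted(positions, reverse=True):
            raise ValueError(
                "cryptic sites must be in decreasing coordinate order "
                "(minus-strand downstream)"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> CrypticSite:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def match(self, donor_pos: int, window_bp: int = 2) -> CrypticSite | None:
        """Closest registry site within ``window_bp`` of a junction donor,
        or None."""
        best = min(self.entries, key=lambda e: abs(e.pos - donor_pos))
        return best if abs(best.pos - donor_pos) <= window_bp else None


def build_registry(
    model: GeneModel, offset_tolerance_bp: int = 1
) -> CrypticSiteRegistry:
    """Registry of the printed C1–C4 coordinates, with their offsets from the
    model's V2 donor revalidated to ±``offset_tolerance_bp``."""
    v2 = model.donors["V2"]
    intron1 = model.intron(1)
    entries = []
    for name, pos, printed_offset in CRYPTIC_SITES_PRINTED:
        recomputed = v2 - pos
        if abs(recomputed - printed_offset) > offset_tolerance_bp:
            raise ValueError(
                f"{name}: offset from V2 donor is {recomputed} bp, printed "
                f"{printed_offset} bp"
            )
        if pos not in intron1:
            raise ValueError(f"{name} at {pos} falls outside intron 1")
        entries.append(
            CrypticSite(name=name, chrom=model.chrom, pos=pos, offset_bp=printed_offset)
        )
    return CrypticSiteRegistry(entries=entries)


def registry_from_tsv(source: str | Path) -> CrypticSiteRegistry:
    df = pd.read_csv(source, sep="\t")
    entries = [
        CrypticSite(
            name=str(r["site"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            offset_bp=int(r["offset_bp"]),
        )
        for _, r in df.iterrows()
    ]
    return CrypticSiteRegistry(entries=entries)


def packaged_registry() -> CrypticSiteRegistry:
    data = resources.files("c9allele.data")
    with resources.as_file(data / "cryptic_sites.tsv") as path:
        return registry_from_tsv(path)
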