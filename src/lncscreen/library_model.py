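"""sgRNA library model and lncRNA genomic classification.

The library design table lists every guide with its spacer sequence and
role: ``tss_targeting`` guides silence a lncRNA transcription start site
via CRISPRi, ``non_targeting`` guides match nowhere in the genome and
supply the empirical null, and ``positive_control`` guides target
protein-coding genes with known growth phenotypes.

lncRNA hits are classified relative to their protein-coding neighbours
into the standard genomic categories: antisense (overlapping a gene on
the opposite strand), intronic (contained in a neighbour's intron),
bidirectional (TSS within a short window of a neighbour's TSS on the
opposite strand, no overlap), and intergenic (own promoter well away
from any neighbour's).  Coordinates are 0-based half-open (BED
convention); the TSS of a minus-strand gene is ``end - 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GUIDE_CLASSES = ("tss_targeting", "non_targeting", "positive_control")

_SPACER_ALPHABET = frozenset("ACGT")


class LibraryError(ValueError):
    """Raised for malformed library designs (duplicates, bad spacers...)."""


class ClassificationError(ValueError):
    """Raised when a gene fits no genomic category."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: identifier, spacer sequence, role, and target gene."""

    guide_id: str
    spacer: str
    guide_class: str
    target_gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise LibraryError("guide_id must be non-empty")
        if not self.spacer or not set(self.spacer) <= _SPACER_ALPHABET:
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer must be non-empty uppercase ACGT, "
                f"got {self.spacer!r}"
            )
        if not 19 <= len(self.spacer) <= 20:
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer length {len(self.spacer)} outside 19-20 nt"
            )
        if self.guide_class not in GUIDE_CLASSES:
            raise LibraryError(
                f"guide {self.guide_id!r}: unknown guide_class {self.guide_class!r}"
            )
        if self.guide_class == "non_targeting" and self.target_gene_id:
            raise LibraryError(
                f"guide {self.guide_id!r}: non_targeting guides must have empty target_gene_id"
            )
        if self.guide_class != "non_targeting" and not self.target_gene_id:
            raise LibraryError(
                f"guide {self.guide_id!r}: {self.guide_class} guide needs a target_gene_id"
            )


@dataclass
class LibraryDesign:
    """Ordered sgRNA library with uniqueness invariants enforced on build."""

    guides: list[GuideRecord]
    guides_per_gene: int = 10

    #: spacer duplicates are an error unless downgraded at construction
    allow_duplicate_spacers: bool = False
    duplicate_spacer_warnings: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.guides_per_gene <= 0:
            raise LibraryError("guides_per_gene must be positive")
        seen_ids: set[str] = set()
        seen_spacers: dict[str, str] = {}
        for g in self.guides:
            if g.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {g.guide_id!r}")
            seen_ids.add(g.guide_id)
            prev = seen_spacers.get(g.spacer)
            if prev is not None:
                msg = f"spacer of {g.guide_id!r} duplicates {prev!r}"
                if self.allow_duplicate_spacers:
                    self.duplicate_spacer_warnings.append(msg)
                else:
                    raise LibraryError(msg + " (counting cannot disambiguate)")
            else:
                seen_spacers[g.spacer] = g.guide_id

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    def guides_by_class(self, guide_class: str) -> list[GuideRecord]:
        return [g for g in self.guides if g.guide_class == guide_class]

    def gene_to_guides(self) -> dict[str, list[str]]:
        """Map each target gene to its guide ids (NTCs excluded)."""
        out: dict[str, list[str]] = {}
        for g in self.guides:
            if g.target_gene_id:
                out.setdefault(g.target_gene_id, []).append(g.guide_id)
        return out

    def composition(self) -> dict[str, int]:
        """Guide counts per class plus gene counts per class."""
        genes_by_class: dict[str, set[str]] = {c: set() for c in GUIDE_CLASSES}
        n_by_class = {c: 0 for c in GUIDE_CLASSES}
        for g in self.guides:
            n_by_class[g.guide_class] += 1
            if g.target_gene_id:
                genes_by_class[g.guide_class].add(g.target_gene_id)
        return {
            "n_guides": len(self.guides),
            "n_tss_targeting": n_by_class["tss_targeting"],
            "n_non_targeting": n_by_class["non_targeting"],
            "n_positive_control": n_by_class["positive_control"],
            "n_lnc_genes": len(genes_by_class["tss_targeting"]),
            "n_positive_genes": len(genes_by_class["positive_control"]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "spacer": [g.spacer for g in self.guides],
                "guide_class": [g.guide_class for g in self.guides],
                "target_gene_id": [g.target_gene_id for g in self.guides],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, guides_per_gene: int = 10, allow_duplicate_spacers: bool = False
    ) -> "LibraryDesign":
        required = {"guide_id", "spacer", "guide_class", "target_gene_id"}
        missing = required - set(df.columns)
        if missing:
            raise LibraryError(f"library table missing columns: {sorted(missing)}")
        guides = [
            GuideRecord(
                guide_id=str(r.guide_id),
                spacer=str(r.spacer),
                guide_class=str(r.guide_class),
                target_gene_id="" if pd.isna(r.target_gene_id) else str(r.target_gene_id),
            )
            for r in df.itertuples()
        ]
        return cls(
            guides, guides_per_gene=guides_per_gene, allow_duplicate_spacers=allow_duplicate_spacers
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, guides_per_gene: int = 10, allow_duplicate_spacers: bool = False
    ) -> "LibraryDesign":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls.from_frame(
            df, guides_per_gene=guides_per_gene, allow_duplicate_spacers=allow_duplicate_spacers
        )


def build_default_library(
    n_lnc_genes: int = 2342,
    guides_per_gene: int = 10,
    n_ntc: int = 700,
    n_positive_genes: int = 50,
    seed: int = 0,
) -> LibraryDesign:
    """Build a synthetic library mirroring the screen's design.

    Defaults reproduce the published composition: 10 sgRNAs per TSS for
    2342 lncRNAs, 700 non-targeting controls, and 10 sgRNAs for each of
    50 protein-coding positive-control genes (24,620 guides, ~25k).
    Spacers are unique random 20-mers drawn deterministically from
    ``seed``.
    """
    for name, v in (
        ("n_lnc_genes", n_lnc_genes),
        ("guides_per_gene", guides_per_gene),
        ("n_ntc", n_ntc),
        ("n_positive_genes", n_positive_genes),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n_targeting = n_lnc_genes * guides_per_gene
    n_pos = n_positive_genes * guides_per_gene
    total = n_targeting + n_ntc + n_pos

    rng = np.random.default_rng(seed)
    spacers = _unique_spacers(rng, total, length=20)

    guides: list[GuideRecord] = []
    it = iter(spacers)
    for i in range(n_lnc_genes):
        gene = f"LNC{i + 1:05d}"
        for j in range(guides_per_gene):
            guides.append(GuideRecord(f"{gene}_sg{j + 1}", next(it), "tss_targeting", gene))
    for i in range(n_ntc):
        guides.append(GuideRecord(f"NTC_{i + 1:04d}", next(it), "non_targeting"))
    for i in range(n_positive_genes):
        gene = f"POS{i + 1:03d}"
        for j in range(guides_per_gene):
            guides.append(GuideRecord(f"{gene}_sg{j + 1}", next(it), "positive_control", gene))
    gpg = guides_per_gene if guides_per_gene > 0 else 10
    return LibraryDesign(guides, guides_per_gene=gpg)


def _unique_spacers(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    """Draw n distinct random DNA k-mers; redraws collisions (rare at k=20)."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            s = "".join(bases[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


# ---------------------------------------------------------------------------
# genomic annotation and lncRNA categories
# ---------------------------------------------------------------------------


class LncCategory(enum.Enum):
    """Genomic category of a screen hit; a partition — one label per gene."""

    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    BIDIRECTIONAL = "bidirectional"
    PROTEIN_CODING = "protein_coding"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """Gene interval in 0-based half-open coordinates with optional exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "other"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in ("protein_coding", "lncRNA", "other"):
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exons must be sorted, disjoint, inside the gene")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty without >= 2 exons)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]

    def overlaps(self, other: "GeneAnnotationRecord") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def classify_lnc_category(
    lnc: GeneAnnotationRecord,
    neighbors: Sequence[GeneAnnotationRecord],
    bidirectional_window: int = 1000,
    intergenic_min_distance: int = 1000,
) -> LncCategory:
    """Assign exactly one genomic category to a gene.

    Precedence (overlap beats distance): protein_coding biotype; antisense
    (overlap on the opposite strand); intronic (fully inside one intron of
    a neighbour); bidirectional (TSS-to-TSS distance <= window, opposite
    strand, no overlap); intergenic (nearest TSS at least
    ``intergenic_min_distance`` away, no overlap).  A gene matching none
    raises :class:`ClassificationError`.
    """
    if bidirectional_window <= 0 or intergenic_min_distance <= 0:
        raise ValueError("windows must be positive")
    for nb in neighbors:
        if nb.chrom != lnc.chrom:
            raise ValueError(
                f"neighbor {nb.gene_id} on {nb.chrom} but {lnc.gene_id} on {lnc.chrom}"
            )
    if lnc.biotype == "protein_coding":
        return LncCategory.PROTEIN_CODING

    others = [nb for nb in neighbors if nb.gene_id != lnc.gene_id]

    for nb in others:
        if lnc.overlaps(nb) and nb.strand != lnc.strand:
            return LncCategory.ANTISENSE
    for nb in others:
        for (istart, iend) in nb.introns():
            if istart <= lnc.start and lnc.end <= iend:
                return LncCategory.INTRONIC
    any_overlap = any(lnc.overlaps(nb) for nb in others)
    if not any_overlap:
        for nb in others:
            if nb.strand != lnc.strand and abs(lnc.tss - nb.tss) <= bidirectional_window:
                return LncCategory.BIDIRECTIONAL
        tss_dists = [abs(lnc.tss - nb.tss) for nb in others]
        if not tss_dists or min(tss_dists) >= intergenic_min_distance:
            return LncCategory.INTERGENIC
    raise ClassificationError(
        f"gene {lnc.gene_id} fits no category "
        "(overlaps a same-strand neighbor or sits closer than the intergenic "
        "distance without qualifying as bidirectional)"
    )


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation_bed(
    path: str | Path, exon_bed: str | Path | None = None
) -> list[GeneAnnotationRecord]:
    """Read genes from a BED6-style TSV (chrom, start, end, gene_id, biotype, strand).

    ``exon_bed`` optionally supplies exon intervals as BED with the gene id
    in column 4.
    """
    cols = ["chrom", "start", "end", "gene_id", "biotype", "strand"]
    df = pd.read_csv(path, sep="\t", names=cols, dtype={"chrom": str, "gene_id": str}, comment="#")
    exons: dict[str, list[tuple[int, int]]] = {}
    if exon_bed is not None:
        edf = pd.read_csv(
            exon_bed, sep="\t", names=["chrom", "start", "end", "gene_id"],
            usecols=range(4), dtype={"chrom": str, "gene_id": str}, comment="#",
        )
        for r in edf.itertuples():
            exons.setdefault(r.gene_id, []).append((int(r.start), int(r.end)))
    records = []
    for r in df.itertuples():
        ex = tuple(sorted(exons.get(r.gene_id, [])))
        records.append(
            GeneAnnotationRecord(
                gene_id=r.gene_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
                strand=r.strand, biotype=r.biotype, exons=ex,
            )
        )
    return records


def read_annotation_gtf(path: str | Path) -> list[GeneAnnotationRecord]:
    """Convenience GTF reader: gene and exon features → annotation records.

    GTF is 1-based inclusive; converted to 0-based half-open here.  Needs
    ``gene_id`` in the attributes; ``gene_biotype``/``gene_type`` map to
    the biotype field (anything unrecognized becomes ``other``).
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                continue
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                bt = _gtf_attr(attrs, "gene_biotype") or _gtf_attr(attrs, "gene_type") or "other"
                if bt not in ("protein_coding", "lncRNA"):
                    bt = "lncRNA" if bt in ("lincRNA", "antisense") else "other"
                genes[gid] = dict(chrom=chrom, start=s, end=e, strand=strand, biotype=bt)
            elif feature == "exon":
                exons.setdefault(gid, []).append((s, e))
    out = []
    for gid, g in genes.items():
        ex = tuple(sorted(set(exons.get(gid, []))))
        out.append(GeneAnnotationRecord(gene_id=gid, exons=ex, **g))
    return out


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def classify_all(
    genes: Iterable[GeneAnnotationRecord],
    annotation: Sequence[GeneAnnotationRecord],
    bidirectional_window: int = 1000,
    intergenic_min_distance: int = 1000,
) -> dict[str, LncCategory]:
    """Classify each gene against same-chromosome neighbours from ``annotation``."""
    by_chrom: dict[str, list[GeneAnnotationRecord]] = {}
    for a in annotation:
        by_chrom.setdefault(a.chrom, []).append(a)
    return {
        g.gene_id: classify_lnc_category(
            g, by_chrom.get(g.chrom, []), bidirectional_window, intergenic_min_distance
        )
        for g in genes
    }
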