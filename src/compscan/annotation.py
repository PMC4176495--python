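"""Gene models, genome annotation and region sets.

Coordinates are 0-based, half-open everywhere internally (the BED
convention).  GFF3 input (1-based, closed) is converted on read.
Transcript length is defined as the genomic span ``end - start``,
introns included.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its chromosome arm, genomic span, strand and exons.

    Exons are ordered, disjoint, half-open intervals contained in
    ``[start, end)``.
    """

    gene_id: str
    arm: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise AnnotationError(f"gene {self.gene_id}: empty exon [{a},{b})")
            if a < self.start or b > self.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{a},{b}) outside span "
                    f"[{self.start},{self.end})"
                )
            if prev_end is not None and a < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = b
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")

    @property
    def length(self) -> int:
        """Transcript length: genomic span, introns included."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1


def transcript_length(gene: GeneModel) -> int:
    """Length as the difference between gene start and end positions."""
    return gene.end - gene.start


@dataclass
class GenomeAnnotation:
    """Collection of :class:`GeneModel` keyed by gene id, plus arm lengths."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    arms: dict[str, int] = field(default_factory=dict)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id}")
        arm_len = self.arms.get(gene.arm)
        if arm_len is not None and gene.end > arm_len:
            raise AnnotationError(
                f"gene {gene.gene_id} extends past arm {gene.arm} length {arm_len}"
            )
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def on_arm(self, arm: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.arm == arm]

    def arm_names(self) -> list[str]:
        return sorted(self.arms) if self.arms else sorted({g.arm for g in self})


@dataclass
class RegionSet:
    """A named list of (arm, start, end) half-open intervals."""

    name: str
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for arm, a, b in self.regions:
            if a >= b:
                raise AnnotationError(f"region set {self.name}: empty region [{a},{b})")

    def __len__(self) -> int:
        return len(self.regions)

    def by_arm(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for arm, a, b in self.regions:
            trees.setdefault(arm, IntervalTree()).addi(a, b)
        return trees


# ---------------------------------------------------------------------------
# Readers / writers


def read_annotation(path: str | os.PathLike, fmt: str = "auto") -> GenomeAnnotation:
    """Read a :class:`GenomeAnnotation` from BED12 or GFF3.

    BED coordinates are taken as-is (0-based half-open); GFF3 is converted
    from 1-based closed.  Genes without exon records get a single exon
    spanning the gene, with a logged warning.
    """
    path = os.fspath(path)
    if fmt == "auto":
        fmt = "GFF3" if path.endswith((".gff", ".gff3")) else "BED12"
    fmt = fmt.upper()
    if fmt == "BED12":
        return _read_bed12(path)
    if fmt == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed12(path: str) -> GenomeAnnotation:
    ann = GenomeAnnotation()
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                arm = parts[0]
                start, end = int(parts[1]), int(parts[2])
                gene_id = parts[3]
                strand = parts[5]
                block_count = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(offsets) != block_count:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            ann.add(GeneModel(gene_id, arm, start, end, strand, exons))
            n += 1
    log.info("read %d genes from %s (BED12)", n, path)
    return ann


def _read_gff3(path: str) -> GenomeAnnotation:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            path,
            dbpath,
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        ann = GenomeAnnotation()
        n_default = 0
        for gene in db.features_of_type("gene"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
            )
            start, end = gene.start - 1, gene.end
            if not exons:
                exons = [(start, end)]
                n_default += 1
            ann.add(
                GeneModel(gene.id, gene.seqid, start, end, gene.strand, tuple(exons))
            )
        if n_default:
            log.warning(
                "%d genes had no exon records; used gene span as single exon", n_default
            )
        log.info("read %d genes from %s (GFF3)", len(ann), path)
        return ann
    except gffutils.exceptions.DuplicateIDError as exc:
        raise AnnotationError(str(exc)) from exc
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)


def write_bed12(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann, key=lambda g: (g.arm, g.start)):
            sizes = ",".join(str(b - a) for a, b in g.exons)
            offsets = ",".join(str(a - g.start) for a, b in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.arm,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_gff3(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for arm, length in sorted(ann.arms.items()):
            fh.write(f"##sequence-region {arm} 1 {length}\n")
        for g in sorted(ann, key=lambda g: (g.arm, g.start)):
            fh.write(
                f"{g.arm}\tcompscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.arm}\tcompscan\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_regions(path: str | os.PathLike, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a :class:`RegionSet`."""
    path = os.fspath(path)
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected >=3 BED fields")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet(name or os.path.basename(path), regions)


def write_regions(regions: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for arm, a, b in regions.regions:
            fh.write(f"{arm}\t{a}\t{b}\n")
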