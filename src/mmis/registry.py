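"""Gene panel registry for mitochondrial-disease variant screening.

The panel covers three gene categories: the 13 protein-coding mtDNA genes,
nuclear genes with direct evidence of mitochondrial-disease pathogenicity,
and nuclear genes whose protein product localizes to mitochondria. Each gene
carries one MANE (Matched Annotation from NCBI and EMBL-EBI) representative
transcript plus the full transcript list, so variant annotation can be
reported on a single authoritative transcript per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

GENE_CATEGORIES = ("mt_protein_coding", "disease_nuclear", "mito_localized_nuclear")

#: TSV header expected by :func:`load_gene_registry`.
REGISTRY_COLUMNS = (
    "symbol",
    "chromosome",
    "start",
    "end",
    "strand",
    "category",
    "mane_transcript",
    "transcripts",
)


class RegistryError(ValueError):
    """Malformed registry table or invalid gene record."""


@dataclass(frozen=True)
class GeneRecord:
    """One panel gene with a 1-based inclusive genomic interval.

    ``strand`` is carried through for provenance but no downstream
    computation consumes it.
    """

    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str
    category: str
    mane_transcript: str
    all_transcripts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbol:
            raise RegistryError("gene symbol must be non-empty")
        if self.start < 1 or self.start > self.end:
            raise RegistryError(
                f"{self.symbol}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise RegistryError(f"{self.symbol}: strand must be '+' or '-'")
        if self.category not in GENE_CATEGORIES:
            raise RegistryError(
                f"{self.symbol}: unknown category {self.category!r}; "
                f"expected one of {GENE_CATEGORIES}"
            )
        if not self.all_transcripts:
            raise RegistryError(f"{self.symbol}: at least one transcript required")
        if self.mane_transcript not in self.all_transcripts:
            raise RegistryError(
                f"{self.symbol}: MANE transcript {self.mane_transcript!r} "
                "not among the gene's transcripts"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        """1-based inclusive overlap test."""
        return (
            chromosome == self.chromosome and self.start <= position <= self.end
        )


@dataclass
class GeneRegistry:
    """Validated collection of panel genes with interval lookup.

    Symbols are unique; intervals on the same contig may overlap (a variant
    inside two panel genes is legitimately reported once per gene).
    """

    records: tuple[GeneRecord, ...]
    build: str = "hg19"
    _by_symbol: dict = field(init=False, repr=False)
    _trees: dict = field(init=False, repr=False)

    def __init__(self, records: Iterable[GeneRecord], build: str = "hg19") -> None:
        recs = tuple(records)
        seen: set[str] = set()
        for r in recs:
            if r.symbol in seen:
                raise RegistryError(f"duplicate gene symbol: {r.symbol}")
            seen.add(r.symbol)
        object.__setattr__(self, "records", recs)
        object.__setattr__(self, "build", build)
        object.__setattr__(self, "_by_symbol", {r.symbol: r for r in recs})
        trees: dict[str, IntervalTree] = {}
        for r in recs:
            # intervaltree is end-exclusive; our intervals are inclusive
            trees.setdefault(r.chromosome, IntervalTree()).addi(
                r.start, r.end + 1, r
            )
        object.__setattr__(self, "_trees", trees)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self._by_symbol[symbol]

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    @property
    def contigs(self) -> frozenset[str]:
        return frozenset(self._trees)

    def genes_at(self, chromosome: str, position: int) -> list[GeneRecord]:
        """All panel genes whose interval covers ``position`` (1-based)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[position]]
        hits.sort(key=lambda r: r.symbol)
        return hits

    def gene_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in GENE_CATEGORIES}
        for r in self.records:
            counts[r.category] += 1
        return counts

    def transcript_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in GENE_CATEGORIES}
        for r in self.records:
            counts[r.category] += len(r.all_transcripts)
        return counts

    @property
    def total_genes(self) -> int:
        return len(self.records)

    @property
    def total_transcripts(self) -> int:
        return sum(len(r.all_transcripts) for r in self.records)


def load_gene_registry(path, build: str = "hg19") -> GeneRegistry:
    """Read a gene registry from a TSV with header ``REGISTRY_COLUMNS``.

    ``transcripts`` is a comma-separated list containing the MANE
    transcript. Parse failures raise :class:`RegistryError` naming the
    offending line number; duplicate symbols and unknown category tokens are
    rejected.
    """
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(REGISTRY_COLUMNS):
            raise RegistryError(
                f"{path}: expected header {list(REGISTRY_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(REGISTRY_COLUMNS):
                raise RegistryError(
                    f"{path}:{lineno}: expected {len(REGISTRY_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            row = dict(zip(REGISTRY_COLUMNS, parts))
            try:
                rec = GeneRecord(
                    symbol=row["symbol"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    category=row["category"],
                    mane_transcript=row["mane_transcript"],
                    all_transcripts=tuple(
                        t for t in row["transcripts"].split(",") if t
                    ),
                )
            except RegistryError as exc:
                raise RegistryError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise RegistryError(
                    f"{path}:{lineno}: malformed row ({exc})"
                ) from exc
            records.append(rec)
    return GeneRegistry(records, build=build)


def write_gene_registry(registry: GeneRegistry, path) -> int:
    """Write a registry in the TSV layout :func:`load_gene_registry` reads."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(REGISTRY_COLUMNS) + "\n")
        for r in registry:
            fh.write(
                "\t".join(
                    [
                        r.symbol,
                        r.chromosome,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.category,
                        r.mane_transcript,
                        ",".join(r.all_transcripts),
                    ]
                )
                + "\n"
            )
    return len(registry)
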