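"""Panel filtering and multi-source annotation of missense variants.

A VCF stream is reduced to the variants falling inside a panel gene's
interval, each variant is assigned one representative (MANE) transcript,
and a typed annotation schema is joined on from per-level source tables:
variant-level tables keyed by (chromosome, position, ref, alt), gene-level
tables keyed by gene symbol, transcript-level tables keyed by transcript id.
Every schema field appears in every output record; a value that cannot be
found or coerced becomes an explicit missing marker ("." in tabular output).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .registry import GeneRecord, GeneRegistry

logger = logging.getLogger(__name__)

MISSING_TOKEN = "."

FIELD_CATEGORIES = (
    "basic",
    "predictor_score",
    "allele_frequency",
    "tissue_expression",
    "amino_acid_property",
    "mito_specific",
)
FIELD_DTYPES = ("integer", "boolean", "continuous")
FIELD_LEVELS = ("variant", "gene", "transcript")

#: fixed leading columns of the annotated table (before schema fields)
KEY_COLUMNS = ("chromosome", "position", "ref", "alt", "gene", "transcript", "consequence")


class SchemaError(ValueError):
    """Invalid annotation schema or field definition."""


class VcfFormatError(ValueError):
    """Input VCF could not be parsed."""


@dataclass(frozen=True)
class AnnotationField:
    name: str
    category: str
    dtype: str
    level: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("annotation field name must be non-empty")
        if self.category not in FIELD_CATEGORIES:
            raise SchemaError(
                f"{self.name}: unknown category {self.category!r}; "
                f"expected one of {FIELD_CATEGORIES}"
            )
        if self.dtype not in FIELD_DTYPES:
            raise SchemaError(
                f"{self.name}: unknown dtype {self.dtype!r}; "
                f"expected one of {FIELD_DTYPES}"
            )
        if self.level not in FIELD_LEVELS:
            raise SchemaError(
                f"{self.name}: unknown level {self.level!r}; "
                f"expected one of {FIELD_LEVELS}"
            )


class AnnotationSchema:
    """Ordered, uniquely named annotation fields.

    The schema is data, not code: field content is supplied by the user (or
    the synthetic generator) as YAML. Column order of all tabular output is
    fully determined by schema order.
    """

    def __init__(self, fields: Iterable[AnnotationField]) -> None:
        self.fields: tuple[AnnotationField, ...] = tuple(fields)
        names = [f.name for f in self.fields]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise SchemaError(f"duplicate field names in schema: {dupes}")
        self._by_name = {f.name: f for f in self.fields}

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self) -> Iterator[AnnotationField]:
        return iter(self.fields)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AnnotationField:
        return self._by_name[name]

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def count_category(self, category: str) -> int:
        if category not in FIELD_CATEGORIES:
            raise SchemaError(f"unknown category {category!r}")
        return sum(1 for f in self.fields if f.category == category)

    @property
    def mito_specific_count(self) -> int:
        return self.count_category("mito_specific")

    def names_in_category(self, category: str) -> tuple[str, ...]:
        if category not in FIELD_CATEGORIES:
            raise SchemaError(f"unknown category {category!r}")
        return tuple(f.name for f in self.fields if f.category == category)

    @classmethod
    def from_yaml(cls, path) -> "AnnotationSchema":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "fields" not in raw:
            raise SchemaError(f"{path}: expected a mapping with a 'fields' list")
        fields = [
            AnnotationField(
                name=item["name"],
                category=item["category"],
                dtype=item["dtype"],
                level=item["level"],
                source=item.get("source", ""),
            )
            for item in raw["fields"]
        ]
        return cls(fields)

    def to_yaml(self, path) -> None:
        payload = {
            "fields": [
                {
                    "name": f.name,
                    "category": f.category,
                    "dtype": f.dtype,
                    "level": f.level,
                    "source": f.source,
                }
                for f in self.fields
            ]
        }
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """VCF-convention variant identity: 1-based position, explicit alleles."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(
                    f"{name} allele must be non-empty uppercase ACGT, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}:{self.alt}"


@dataclass
class AnnotatedVariant:
    key: VariantKey
    gene: str
    transcript: str
    consequence: str | None
    values: dict  # field name -> value or None (missing)


# ---------------------------------------------------------------------------
# VCF reading and panel filtering
# ---------------------------------------------------------------------------

def read_vcf(path, consequence_key: str | None = None):
    """Yield ``(VariantKey, consequence)`` from a VCF 4.x file.

    Multi-allelic records are decomposed into one key per ALT allele.
    Symbolic and non-ACGT alleles are skipped. ``consequence_key`` names the
    INFO field holding a consequence term (e.g. ``missense_variant``); when
    absent the consequence is None.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise VcfFormatError(f"{path}: cannot open VCF ({exc})") from exc
    for record in vcf:
        csq = None
        if consequence_key is not None:
            raw = record.INFO.get(consequence_key)
            csq = str(raw) if raw is not None else None
        ref = str(record.REF).upper()
        if not set(ref) <= _VALID_BASES:
            continue
        for alt in record.ALT:
            alt = str(alt).upper()
            if not alt or not set(alt) <= _VALID_BASES or alt == ref:
                continue
            yield VariantKey(record.CHROM, record.POS, ref, alt), csq


def _is_missense(consequence: str | None) -> bool:
    return consequence is not None and "missense" in consequence


def filter_to_panel(
    variants: Iterable,
    registry: GeneRegistry,
    missense_only: bool = False,
) -> Iterator[tuple[VariantKey, str]]:
    """Restrict a variant stream to the gene panel.

    ``variants`` yields either ``VariantKey`` or ``(VariantKey, consequence)``
    pairs. A variant is kept when its position lies inside a registry gene
    interval on the same contig (1-based inclusive); a variant inside two
    panel genes is emitted once per gene. Input order is preserved. Variants
    on contigs absent from the registry are dropped (debug-logged).
    """
    for item in variants:
        if isinstance(item, VariantKey):
            key, csq = item, None
        else:
            key, csq = item
        if missense_only and not _is_missense(csq):
            continue
        if key.chromosome not in registry.contigs:
            logger.debug("contig %s not in registry; dropping %s", key.chromosome, key)
            continue
        for gene in registry.genes_at(key.chromosome, key.position):
            yield key, gene.symbol


def select_mane_transcript(
    gene: GeneRecord, observed_transcripts: Iterable[str]
) -> str:
    """Pick the representative transcript for a gene.

    The MANE transcript is returned whenever it is among the observed
    transcripts or when nothing was observed; otherwise the
    lexicographically smallest observed id is the deterministic fallback.
    """
    observed = sorted(set(observed_transcripts))
    if not observed or gene.mane_transcript in observed:
        return gene.mane_transcript
    fallback = observed[0]
    logger.info(
        "MANE transcript %s absent for %s; falling back to %s",
        gene.mane_transcript,
        gene.symbol,
        fallback,
    )
    return fallback


# ---------------------------------------------------------------------------
# Value coercion
# ---------------------------------------------------------------------------

_MISSING_STRINGS = frozenset({"", ".", "na", "nan", "none", "null"})
_TRUE_TOKENS = frozenset({"1", "true", "t", "yes", "y"})
_FALSE_TOKENS = frozenset({"0", "false", "f", "no", "n"})


class CoercionFailure(Exception):
    pass


def coerce_value(raw, dtype: str):
    """Coerce a raw source token to the field dtype.

    Returns None for recognized missing tokens; raises
    :class:`CoercionFailure` for values that are present but unparseable
    (the caller records these and treats them as missing).
    """
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    if isinstance(raw, str) and raw.strip().lower() in _MISSING_STRINGS:
        return None
    if dtype == "boolean":
        if isinstance(raw, bool):
            return raw
        token = str(raw).strip().lower()
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        try:
            num = float(token)
        except ValueError:
            raise CoercionFailure(raw)
        if num == 1.0:
            return True
        if num == 0.0:
            return False
        raise CoercionFailure(raw)
    if dtype == "integer":
        try:
            num = float(str(raw).strip())
        except ValueError:
            raise CoercionFailure(raw)
        if not math.isfinite(num) or num != int(num):
            raise CoercionFailure(raw)
        return int(num)
    if dtype == "continuous":
        try:
            num = float(str(raw).strip())
        except ValueError:
            raise CoercionFailure(raw)
        if not math.isfinite(num):
            return None
        return num
    raise SchemaError(f"unknown dtype {dtype!r}")


# ---------------------------------------------------------------------------
# Annotation sources and the join
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSources:
    """Per-level source tables.

    variant: DataFrame keyed by (chromosome, position, ref, alt);
    gene: DataFrame keyed by 'gene'; transcript: DataFrame keyed by
    'transcript' (with an optional 'gene' column used to collect the
    observed transcripts per gene).
    """

    variant: pd.DataFrame | None = None
    gene: pd.DataFrame | None = None
    transcript: pd.DataFrame | None = None
    _variant_index: dict = field(init=False, default_factory=dict, repr=False)
    _gene_index: dict = field(init=False, default_factory=dict, repr=False)
    _transcript_index: dict = field(init=False, default_factory=dict, repr=False)
    _gene_transcripts: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.variant is not None:
            for col in ("chromosome", "position", "ref", "alt"):
                if col not in self.variant.columns:
                    raise SchemaError(f"variant source lacks key column {col!r}")
            for _, row in self.variant.iterrows():
                k = (str(row["chromosome"]), int(row["position"]),
                     str(row["ref"]), str(row["alt"]))
                self._variant_index[k] = row
        if self.gene is not None:
            if "gene" not in self.gene.columns:
                raise SchemaError("gene source lacks key column 'gene'")
            for _, row in self.gene.iterrows():
                self._gene_index[str(row["gene"])] = row
        if self.transcript is not None:
            if "transcript" not in self.transcript.columns:
                raise SchemaError("transcript source lacks key column 'transcript'")
            for _, row in self.transcript.iterrows():
                tid = str(row["transcript"])
                self._transcript_index[tid] = row
                if "gene" in self.transcript.columns:
                    self._gene_transcripts.setdefault(str(row["gene"]), []).append(tid)

    @classmethod
    def from_dir(cls, directory) -> "AnnotationSources":
        """Load ``variant.tsv`` / ``gene.tsv`` / ``transcript.tsv`` if present."""
        directory = Path(directory)
        kwargs = {}
        for level in ("variant", "gene", "transcript"):
            p = directory / f"{level}.tsv"
            if p.exists():
                kwargs[level] = pd.read_csv(p, sep="\t", dtype=str)
        return cls(**kwargs)

    def observed_transcripts(self, gene_symbol: str) -> list[str]:
        return list(self._gene_transcripts.get(gene_symbol, []))

    def lookup(self, level: str, key):
        index = {
            "variant": self._variant_index,
            "gene": self._gene_index,
            "transcript": self._transcript_index,
        }[level]
        return index.get(key)


@dataclass
class AnnotationReport:
    """Per-field missingness and coercion-failure accounting."""

    missing_counts: Counter = field(default_factory=Counter)
    coercion_failures: Counter = field(default_factory=Counter)
    n_variants: int = 0


def annotate(
    variants: Iterable,
    schema: AnnotationSchema,
    sources: AnnotationSources,
    registry: GeneRegistry,
    report: AnnotationReport | None = None,
) -> Iterator[AnnotatedVariant]:
    """Attach every schema field to each (variant, gene) pair.

    ``variants`` yields ``(VariantKey, gene_symbol)`` or
    ``(VariantKey, gene_symbol, consequence)``. The representative
    transcript is the gene's MANE transcript, falling back per
    :func:`select_mane_transcript` to the transcripts observed in the
    transcript-level source. Values failing dtype coercion are recorded as
    missing and counted in the report (never fatal). The operation is
    idempotent: re-annotating its own output with the same sources changes
    nothing.
    """
    for item in variants:
        if len(item) == 3:
            key, gene_symbol, consequence = item
        else:
            key, gene_symbol = item
            consequence = None
        if gene_symbol not in registry:
            raise SchemaError(f"gene {gene_symbol!r} not in registry")
        gene = registry[gene_symbol]
        transcript = select_mane_transcript(
            gene, sources.observed_transcripts(gene_symbol)
        )
        variant_row = sources.lookup(
            "variant", (key.chromosome, key.position, key.ref, key.alt)
        )
        # consequence preference: variant-level source column, then stream
        if variant_row is not None and "consequence" in variant_row.index:
            src_csq = variant_row["consequence"]
            if isinstance(src_csq, str) and src_csq.strip().lower() not in _MISSING_STRINGS:
                consequence = src_csq
        values: dict = {}
        for fld in schema:
            if fld.level == "variant":
                row = variant_row
            elif fld.level == "gene":
                row = sources.lookup("gene", gene_symbol)
            else:
                row = sources.lookup("transcript", transcript)
            raw = None
            if row is not None and fld.name in row.index:
                raw = row[fld.name]
            try:
                value = coerce_value(raw, fld.dtype)
            except CoercionFailure:
                if report is not None:
                    report.coercion_failures[fld.name] += 1
                value = None
            if value is None and report is not None:
                report.missing_counts[fld.name] += 1
            values[fld.name] = value
        if report is not None:
            report.n_variants += 1
        yield AnnotatedVariant(
            key=key,
            gene=gene_symbol,
            transcript=transcript,
            consequence=consequence,
            values=values,
        )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def _render(value, dtype: str) -> str:
    if value is None:
        return MISSING_TOKEN
    if dtype == "boolean":
        return "1" if value else "0"
    if dtype == "integer":
        return str(int(value))
    return repr(float(value))


def write_annotated_table(
    variants: Iterable[AnnotatedVariant], schema: AnnotationSchema, path
) -> int:
    """Write annotated variants as TSV; returns the number of data rows.

    Columns: chromosome, position, ref, alt, gene, transcript, consequence,
    then schema fields in schema order. Missing values render as ".".
    """
    count = 0
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(KEY_COLUMNS + schema.field_names) + "\n")
        for av in variants:
            row = [
                av.key.chromosome,
                str(av.key.position),
                av.key.ref,
                av.key.alt,
                av.gene,
                av.transcript,
                av.consequence if av.consequence else MISSING_TOKEN,
            ]
            for fld in schema:
                row.append(_render(av.values[fld.name], fld.dtype))
            fh.write("\t".join(row) + "\n")
            count += 1
    return count


def read_annotated_table(path, schema: AnnotationSchema) -> list[AnnotatedVariant]:
    """Inverse of :func:`write_annotated_table` (value-identical round trip)."""
    out: list[AnnotatedVariant] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = list(KEY_COLUMNS + schema.field_names)
        if header != expected:
            raise SchemaError(f"{path}: header does not match schema")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            key = VariantKey(
                row["chromosome"], int(row["position"]), row["ref"], row["alt"]
            )
            values = {
                fld.name: coerce_value(row[fld.name], fld.dtype) for fld in schema
            }
            csq = row["consequence"]
            out.append(
                AnnotatedVariant(
                    key=key,
                    gene=row["gene"],
                    transcript=row["transcript"],
                    consequence=None if csq == MISSING_TOKEN else csq,
                    values=values,
                )
            )
    return out
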