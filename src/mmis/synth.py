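"""Synthetic fixture generators: every input the toolkit consumes.

These stand in for the real curated resources (gene panel, annotation
databases, ClinVar-derived labeled variant sets, 1000 Genomes background
exomes), none of which ship with the package. Every generator is a pure
function of its parameters and seed, so reruns are byte-identical. Labels
come from the same Bernoulli-logistic generative model the predictor
assumes, which makes parameter recovery a valid end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotationField, AnnotationSchema
from .exome import BackgroundExome
from .features import FeatureMatrix, FeatureSpec
from .registry import GENE_CATEGORIES, GeneRecord, GeneRegistry

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticTruth:
    """Known generative parameters behind a labeled dataset.

    Labels are drawn Bernoulli(sigmoid(intercept + w . x)); with w = 0 the
    label prevalence is sigmoid(intercept), i.e. ``class_prior`` when the
    intercept is its logit. Missingness is completely at random.
    """

    true_coefficients: tuple[float, ...]
    true_intercept: float = 0.0
    class_prior: float = 0.5
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.class_prior < 1):
            raise ValueError("class_prior must be in (0,1)")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0,1)")


# ---------------------------------------------------------------------------
# Gene registry
# ---------------------------------------------------------------------------

def gen_registry(
    n_per_category: tuple[int, int, int] = (13, 321, 1127),
    seed: int = 0,
    gap: int = 10_000,
) -> GeneRegistry:
    """Synthetic panel with non-overlapping intervals per contig.

    mtDNA genes go on chrM; nuclear genes cycle over chr1..chr22. Each gene
    gets 1-5 transcripts with the first marked MANE. The default shape
    mirrors the covered panel: 13 mtDNA protein-coding genes, 321 nuclear
    disease genes, 1127 mitochondrially localized nuclear genes.
    """
    if any(n < 0 for n in n_per_category):
        raise ValueError("category counts must be >= 0")
    rng = np.random.default_rng(seed)
    nuclear_contigs = [f"chr{i}" for i in range(1, 23)]
    cursors: dict[str, int] = {}
    records = []
    idx = 0
    for category, n in zip(GENE_CATEGORIES, n_per_category):
        for _ in range(n):
            if category == "mt_protein_coding":
                contig = "chrM"
            else:
                contig = nuclear_contigs[idx % len(nuclear_contigs)]
            start = cursors.get(contig, 1) + int(rng.integers(gap // 2, gap))
            length = int(rng.integers(500, 20_000))
            end = start + length
            cursors[contig] = end
            symbol = f"SYN{category.upper()[:2]}{idx:05d}"
            n_tx = int(rng.integers(1, 6))
            transcripts = tuple(f"{symbol}.t{t + 1}" for t in range(n_tx))
            records.append(
                GeneRecord(
                    symbol=symbol,
                    chromosome=contig,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    category=category,
                    mane_transcript=transcripts[0],
                    all_transcripts=transcripts,
                )
            )
            idx += 1
    return GeneRegistry(records, build="synthetic")


def gen_schema(
    n_per_category: dict[str, int] | None = None, seed: int = 0
) -> AnnotationSchema:
    """Synthetic typed schema; dtypes and levels cycle deterministically.

    The default shape mirrors the covered annotation set scaled down: a few
    fields per category including mito-specific ones.
    """
    if n_per_category is None:
        n_per_category = {
            "basic": 2,
            "predictor_score": 3,
            "allele_frequency": 2,
            "tissue_expression": 2,
            "amino_acid_property": 2,
            "mito_specific": 3,
        }
    rng = np.random.default_rng(seed)
    dtypes = ("continuous", "boolean", "integer")
    levels = ("variant", "gene", "transcript")
    fields = []
    i = 0
    for category, n in n_per_category.items():
        for _ in range(n):
            fields.append(
                AnnotationField(
                    name=f"{category}_{i:03d}",
                    category=category,
                    dtype=dtypes[int(rng.integers(0, 3))],
                    level=levels[int(rng.integers(0, 3))],
                    source="synthetic",
                )
            )
            i += 1
    return AnnotationSchema(fields)


# ---------------------------------------------------------------------------
# Labeled feature matrices
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def gen_labeled_dataset(
    n: int,
    truth: SyntheticTruth,
    spec: FeatureSpec | None = None,
    schema: AnnotationSchema | None = None,
) -> FeatureMatrix:
    """Labeled feature matrix from the known logistic generative model.

    Continuous features are standard normal, booleans Bernoulli(0.5),
    integers uniform on 0..4 (dtypes read from ``schema`` when given,
    otherwise all features are continuous). Missingness is applied
    completely at random at ``truth.missingness_rate`` after labels are
    drawn from the fully observed features.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    w = np.asarray(truth.true_coefficients, dtype=float)
    p = len(w)
    if spec is None:
        spec = FeatureSpec(tuple(f"f{j}" for j in range(p)))
    if len(spec) != p:
        raise ValueError("spec length must match the coefficient vector")
    rng = np.random.default_rng(truth.seed)
    X = np.empty((n, p))
    for j, name in enumerate(spec.feature_names):
        dtype = schema[name].dtype if schema is not None and name in schema else "continuous"
        if dtype == "continuous":
            X[:, j] = rng.standard_normal(n)
        elif dtype == "boolean":
            X[:, j] = rng.integers(0, 2, n).astype(float)
        else:
            X[:, j] = rng.integers(0, 5, n).astype(float)
    probs = _sigmoid(truth.true_intercept + X @ w)
    labels = (rng.random(n) < probs).astype(int)
    if truth.missingness_rate > 0:
        mask = rng.random((n, p)) < truth.missingness_rate
        X = X.copy()
        X[mask] = np.nan
    ids = [f"v{i:06d}" for i in range(n)]
    return FeatureMatrix(ids, spec.feature_names, X, labels)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def gen_vcf(
    n_variants: int,
    registry: GeneRegistry,
    fraction_in_panel: float,
    seed: int = 0,
    path=None,
    consequence: str = "missense_variant",
) -> str:
    """Write a valid VCF 4.2 with a controlled fraction of in-panel positions.

    In-panel variants are placed uniformly inside randomly chosen registry
    gene intervals; the rest go far beyond any gene on the same contigs.
    Each record carries a ``CSQ`` INFO consequence term. Returns the path.
    """
    if not (0 <= fraction_in_panel <= 1):
        raise ValueError("fraction_in_panel must be in [0,1]")
    if path is None:
        raise ValueError("an output path is required")
    rng = np.random.default_rng(seed)
    n_in = round(n_variants * fraction_in_panel)
    genes = list(registry)
    if n_in > 0 and not genes:
        raise ValueError("registry is empty; cannot place in-panel variants")
    max_end: dict[str, int] = {}
    for g in genes:
        max_end[g.chromosome] = max(max_end.get(g.chromosome, 0), g.end)
    contigs = sorted(max_end) or ["chr1"]
    rows = []
    for i in range(n_variants):
        if i < n_in:
            g = genes[int(rng.integers(0, len(genes)))]
            chrom = g.chromosome
            pos = int(rng.integers(g.start, g.end + 1))
        else:
            chrom = contigs[int(rng.integers(0, len(contigs)))]
            # well beyond every gene on this contig
            pos = max_end.get(chrom, 0) + 100_000 + int(rng.integers(0, 1_000_000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        rows.append((chrom, pos, str(ref), str(alt)))
    rows.sort(key=lambda r: (r[0], r[1]))
    all_contigs = sorted({r[0] for r in rows} | set(contigs))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        for c in all_contigs:
            fh.write(f"##contig=<ID={c},length=300000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tCSQ={consequence}\n"
            )
    return str(path)


# ---------------------------------------------------------------------------
# Background exomes
# ---------------------------------------------------------------------------

def gen_background_exomes(
    n_exomes: int,
    variants_per_exome: int = 400,
    seed: int = 0,
    tools: tuple[str, ...] = ("mmisp", "toolx"),
    size_jitter_sd: float = 0.02,
    score_missing_rate: float = 0.0,
) -> list[BackgroundExome]:
    """Synthetic healthy-exome candidate lists with per-tool scores.

    Per-exome size is the target with small Gaussian jitter (sd =
    ``size_jitter_sd`` x target, floor 1), matching the "about 400
    variants after frequency filtering" framing. MAFs follow Beta(0.2, 20)
    (mostly rare, a tail above the 1% filter cutoff); background scores
    follow Beta(2, 5) per tool, i.e. benign-shifted.
    """
    if n_exomes < 1 or variants_per_exome < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    exomes = []
    for e in range(n_exomes):
        size = max(
            1,
            int(round(rng.normal(variants_per_exome, size_jitter_sd * variants_per_exome))),
        )
        table = pd.DataFrame(
            {
                "variant_id": [f"ex{e:03d}_v{i:05d}" for i in range(size)],
                "maf": rng.beta(0.2, 20, size),
            }
        )
        for tool in tools:
            scores = rng.beta(2, 5, size)
            if score_missing_rate > 0:
                scores[rng.random(size) < score_missing_rate] = np.nan
            table[tool] = scores
        exomes.append(BackgroundExome(f"exome{e:03d}", table, provenance="synthetic"))
    return exomes


def gen_causative_variants(
    n: int, seed: int = 0, tools: tuple[str, ...] = ("mmisp", "toolx")
) -> list[dict]:
    """Causative (pathogenic) variants with high-shifted scores Beta(8, 2)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        row = {"variant_id": f"causative_{i:04d}", "maf": float(rng.beta(0.2, 200))}
        for tool in tools:
            row[tool] = float(rng.beta(8, 2))
        out.append(row)
    return out


def write_background_exomes(exomes: list[BackgroundExome], path) -> None:
    """Single TSV: exome_id, variant_id, maf, per-tool score columns."""
    frames = []
    for ex in exomes:
        t = ex.table.copy()
        t.insert(0, "exome_id", ex.exome_id)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_background_exomes(path) -> list[BackgroundExome]:
    df = pd.read_csv(path, sep="\t")
    return [
        BackgroundExome(str(eid), grp.drop(columns="exome_id").reset_index(drop=True))
        for eid, grp in df.groupby("exome_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# Annotation sources matched to a registry + schema
# ---------------------------------------------------------------------------

def gen_sources(
    registry: GeneRegistry,
    schema: AnnotationSchema,
    variant_keys,
    seed: int = 0,
    missing_rate: float = 0.1,
):
    """Source tables covering the given variants/genes/transcripts.

    Values are drawn per dtype (standard normal, 0/1, small integers) with
    tokens blanked to "." at ``missing_rate``, exercising the explicit-
    missingness path of the annotation join.
    """
    from .annotate import AnnotationSources

    rng = np.random.default_rng(seed)

    def draw(dtype):
        if rng.random() < missing_rate:
            return "."
        if dtype == "continuous":
            return repr(float(rng.standard_normal()))
        if dtype == "boolean":
            return str(int(rng.integers(0, 2)))
        return str(int(rng.integers(0, 5)))

    variant_fields = [f for f in schema if f.level == "variant"]
    gene_fields = [f for f in schema if f.level == "gene"]
    transcript_fields = [f for f in schema if f.level == "transcript"]

    vrows = []
    for key in variant_keys:
        row = {
            "chromosome": key.chromosome,
            "position": key.position,
            "ref": key.ref,
            "alt": key.alt,
            "consequence": "missense_variant",
        }
        for f in variant_fields:
            row[f.name] = draw(f.dtype)
        vrows.append(row)
    grows = []
    trows = []
    for g in registry:
        row = {"gene": g.symbol}
        for f in gene_fields:
            row[f.name] = draw(f.dtype)
        grows.append(row)
        for tx in g.all_transcripts:
            trow = {"transcript": tx, "gene": g.symbol}
            for f in transcript_fields:
                trow[f.name] = draw(f.dtype)
            trows.append(trow)
    return AnnotationSources(
        variant=pd.DataFrame(vrows) if vrows else None,
        gene=pd.DataFrame(grows) if grows else None,
        transcript=pd.DataFrame(trows) if trows else None,
    )
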