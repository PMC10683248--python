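"""Simulated Mendelian-disease exome benchmark.

A background exome is a frequency-filtered candidate list (~400 rare
variants) from a healthy individual; spiking exactly one known
disease-causing ("causative") variant into it simulates a patient exome.
Predictors are then compared on two axes: how long a candidate list they
produce (percent of variants called pathogenic at the tool's recommended
threshold) and where the causative variant lands when variants are sorted
by score (rank 1 = top). Rank ties are resolved pessimistically — the
causative variant is placed after every non-causative variant sharing its
score — so reported ranks are conservative. Tool-versus-tool rank
comparisons use the Mann-Whitney rank-sum test (exact tie-aware null
distribution for small groups, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ExomeError(ValueError):
    pass


@dataclass
class BackgroundExome:
    """Candidate variants of one healthy exome with per-tool scores.

    ``table`` columns: ``variant_id``, ``maf``, one score column per tool.
    """

    exome_id: str
    table: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if "variant_id" not in self.table.columns:
            raise ExomeError("background table requires a 'variant_id' column")
        if self.table["variant_id"].duplicated().any():
            raise ExomeError(f"{self.exome_id}: duplicate variant ids")
        if "causative" in self.table.columns and self.table["causative"].any():
            raise ExomeError("background exome must not contain causative flags")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def score_columns(self) -> list[str]:
        return [
            c for c in self.table.columns
            if c not in ("variant_id", "maf", "causative")
        ]


@dataclass
class SpikedExome:
    """Background exome plus exactly one flagged causative variant."""

    exome_id: str
    table: pd.DataFrame  # background rows + causative row, 'causative' column
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if int(self.table["causative"].sum()) != 1:
            raise ExomeError("exactly one causative flag required")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def causative_row(self) -> pd.Series:
        return self.table.loc[self.table["causative"]].iloc[0]


def frequency_filter(variants: pd.DataFrame, maf_cutoff: float = 0.01) -> pd.DataFrame:
    """Drop common variants (MAF > cutoff); missing MAF is treated as rare.

    The 1% default is the standard triage filter for Mendelian exomes.
    """
    if maf_cutoff < 0:
        raise ExomeError(f"negative MAF cutoff: {maf_cutoff}")
    if "maf" not in variants.columns:
        raise ExomeError("variants lack a 'maf' column")
    maf = pd.to_numeric(variants["maf"], errors="coerce")
    keep = ~(maf > maf_cutoff)  # NaN compares False, hence kept
    out = variants.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("frequency filter removed every variant")
    return out


def spike(background: BackgroundExome, causative: dict) -> SpikedExome:
    """Insert one causative variant; its id must be new to the exome."""
    vid = causative.get("variant_id")
    if vid is None:
        raise ExomeError("causative variant requires a 'variant_id'")
    if (background.table["variant_id"] == vid).any():
        raise ExomeError(f"causative id {vid!r} already present in background")
    bg = background.table.copy()
    bg["causative"] = False
    row = dict(causative)
    row["causative"] = True
    table = pd.concat([bg, pd.DataFrame([row])], ignore_index=True)
    return SpikedExome(background.exome_id, table, background.provenance)


def percent_pathogenic(
    exome: SpikedExome, tool: str, threshold: float
) -> tuple[float, int]:
    """Percent of scored variants called pathogenic (score > threshold).

    Returns (percentage, number of unscored variants excluded); errors when
    nothing is scored.
    """
    if tool not in exome.table.columns:
        raise ExomeError(f"no score column {tool!r} in exome {exome.exome_id}")
    scores = pd.to_numeric(exome.table[tool], errors="coerce")
    scored = scores.dropna()
    if scored.empty:
        raise ExomeError(f"{exome.exome_id}: no scored variants for {tool!r}")
    n_missing = int(scores.isna().sum())
    if n_missing:
        logger.info(
            "%s: %d variants unscored by %s excluded from the denominator",
            exome.exome_id, n_missing, tool,
        )
    pct = 100.0 * float((scored > threshold).sum()) / len(scored)
    return pct, n_missing


def causative_rank(exome: SpikedExome, tool: str) -> int:
    """Rank of the causative variant in the descending score list.

    rank = 1 + #(strictly higher scores) + #(non-causative ties); an
    unscored causative variant is unrankable and raises.
    """
    if tool not in exome.table.columns:
        raise ExomeError(f"no score column {tool!r} in exome {exome.exome_id}")
    scores = pd.to_numeric(exome.table[tool], errors="coerce")
    causative_mask = exome.table["causative"].to_numpy(dtype=bool)
    c_val = scores[causative_mask].iloc[0]
    if pd.isna(c_val):
        raise ExomeError(
            f"{exome.exome_id}: causative variant unscored by {tool!r} (unrankable)"
        )
    c_score = float(c_val)
    others = scores[~causative_mask].dropna()
    higher = int((others > c_score).sum())
    tied = int((others == c_score).sum())
    return 1 + higher + tied


@dataclass
class RankSummary:
    ranks: list[int]
    mean: float
    sd: float | None  # sample sd (n-1); None for a single rank
    median: float

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.ranks):
            raise ExomeError("ranks must be >= 1")


def summarize_ranks(ranks) -> RankSummary:
    """Mean, sample SD and median of per-exome causative ranks."""
    ranks = [int(r) for r in ranks]
    if not ranks:
        raise ExomeError("empty rank list")
    arr = np.asarray(ranks, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else None
    return RankSummary(
        ranks=ranks,
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks doubled to integers (ties get the average rank)."""
    order = np.argsort(pooled, kind="mergesort")
    doubled = np.empty(len(pooled), dtype=object)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        # ranks i+1..j averaged, doubled: (i+1 + j)
        for k in range(i, j):
            doubled[order[k]] = i + 1 + j
        i = j
    return np.array([int(d) for d in doubled])


def _exact_rank_sum_p(doubled_ranks: np.ndarray, n_a: int, w_obs: int) -> float:
    """Two-sided exact p for the permutation distribution of the rank sum.

    Counts size-``n_a`` subsets of the pooled (doubled) midranks by their
    sum with a subset-sum dynamic program; p = min(1, 2 * min(P(W <= w),
    P(W >= w))) where W is the doubled rank sum of group a.
    """
    total = math.comb(len(doubled_ranks), n_a)
    # dp[size][sum] -> count
    dp: list[dict[int, int]] = [dict() for _ in range(n_a + 1)]
    dp[0][0] = 1
    for r in doubled_ranks:
        for size in range(min(n_a, len(doubled_ranks)) - 1, -1, -1):
            if not dp[size]:
                continue
            nxt = dp[size + 1]
            for s, c in dp[size].items():
                nxt[s + int(r)] = nxt.get(s + int(r), 0) + c
    dist = dp[n_a]
    le = sum(c for s, c in dist.items() if s <= w_obs)
    ge = sum(c for s, c in dist.items() if s >= w_obs)
    p = 2 * Fraction(min(le, ge), total)
    return float(min(p, Fraction(1)))


def rank_sum_test(ranks_a, ranks_b) -> tuple[float, float]:
    """Mann-Whitney U (group a) with a two-sided p-value.

    Exact tie-aware enumeration of the permutation null when
    n_a * n_b <= 200; tie-corrected normal approximation (scipy) otherwise.
    U_a + U_b = n_a * n_b always holds (ties contribute 1/2 to each).
    """
    a = np.asarray(list(ranks_a), dtype=float)
    b = np.asarray(list(ranks_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ExomeError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    doubled = _midranks(pooled)
    w_doubled = int(doubled[:n_a].sum())
    u_a = w_doubled / 2.0 - n_a * (n_a + 1) / 2.0
    if n_a * n_b <= 200:
        p = _exact_rank_sum_p(doubled, n_a, w_doubled)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    return float(u_a), p


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    per_exome: pd.DataFrame  # exome_id, tool, percent_pathogenic, causative_rank
    summaries: dict[str, RankSummary] = field(default_factory=dict)
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def run_benchmark(
    backgrounds: list[BackgroundExome],
    causatives: list[dict],
    thresholds: dict[str, float],
    maf_cutoff: float = 0.01,
) -> BenchmarkResult:
    """Spike, score and rank one causative variant per background exome."""
    if len(causatives) < len(backgrounds):
        raise ExomeError(
            f"{len(backgrounds)} exomes but only {len(causatives)} causative variants"
        )
    rows = []
    ranks: dict[str, list[int]] = {t: [] for t in thresholds}
    for bg, causative in zip(backgrounds, causatives):
        filtered = BackgroundExome(
            bg.exome_id, frequency_filter(bg.table, maf_cutoff), bg.provenance
        )
        spiked = spike(filtered, causative)
        for tool, thr in thresholds.items():
            pct, n_missing = percent_pathogenic(spiked, tool, thr)
            try:
                rank = causative_rank(spiked, tool)
                ranks[tool].append(rank)
            except ExomeError:
                rank = None
            rows.append(
                {
                    "exome_id": spiked.exome_id,
                    "tool": tool,
                    "n_variants": len(spiked),
                    "n_unscored": n_missing,
                    "percent_pathogenic": pct,
                    "causative_rank": rank,
                }
            )
    result = BenchmarkResult(per_exome=pd.DataFrame(rows))
    for tool, r in ranks.items():
        if r:
            result.summaries[tool] = summarize_ranks(r)
    tools = [t for t in thresholds if ranks.get(t)]
    for i, t1 in enumerate(tools):
        for t2 in tools[i + 1:]:
            _, p = rank_sum_test(ranks[t1], ranks[t2])
            result.pairwise_p[(t1, t2)] = p
    return result


def write_benchmark(result: BenchmarkResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_exome.to_csv(out / "per_exome.tsv", sep="\t", index=False)
    rows = []
    for tool, s in result.summaries.items():
        rows.append(
            {
                "tool": tool,
                "mean_rank": round(s.mean, 3),
                "sd_rank": "." if s.sd is None else round(s.sd, 3),
                "median_rank": s.median,
                "n_exomes": len(s.ranks),
            }
        )
    pd.DataFrame(rows).to_csv(out / "rank_summary.tsv", sep="\t", index=False)
    with open(out / "rank_sum_tests.tsv", "wt", encoding="utf-8") as fh:
        fh.write("tool_a\ttool_b\ttwo_sided_p\n")
        for (t1, t2), p in result.pairwise_p.items():
            fh.write(f"{t1}\t{t2}\t{p:.6g}\n")
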