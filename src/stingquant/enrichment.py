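"""Preranked gene-set enrichment on log2-fold-change-ranked lists.

Implements the weighted Kolmogorov–Smirnov-style enrichment statistic used by
preranked GSEA/fgsea: genes are ranked by log2 fold change (descending), a
running sum is accumulated that steps up by ``|score|^p / N_R`` at member
genes and down by ``1/(N - N_h)`` elsewhere, and the enrichment score (ES)
is the signed extremum of that running sum. Significance comes from a
gene-sampling permutation null: ES values of uniformly sampled gene sets of
the same size. A random-gene-set negative control reports the fraction of
random sets reaching nominal significance, which should track the nominal
level when only a specific pathway is truly shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "RankedGeneList",
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "sting_core_panel",
    "rank_by_log2fc",
    "enrichment_score",
    "permutation_null",
    "normalize",
    "analyze_gene_set",
    "random_geneset_control",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        inter = self.members & set(universe)
        if not inter:
            raise ConfigurationError(
                f"gene set {self.name!r} is disjoint from the ranked universe"
            )
        return GeneSet(self.name, frozenset(inter), self.description)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RankedGeneList:
    """Genes sorted by score (log2FC) descending, ties broken by gene id."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.genes) != len(scores):
            raise ValueError("genes and scores lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class EnrichmentResult:
    """ES with its permutation-null context for one gene set."""

    gene_set: str
    es: float
    nes: float
    p_emp: float
    n_perm: int
    n_members: int
    leading_edge: list[str] = field(default_factory=list)
    seed: int | None = None
    p_floored: bool = False

    def to_dict(self) -> dict:
        return {
            "gene_set": self.gene_set,
            "es": self.es,
            "nes": self.nes,
            "p_emp": self.p_emp,
            "n_perm": self.n_perm,
            "n_members": self.n_members,
            "leading_edge": list(self.leading_edge),
            "seed": self.seed,
            "p_floored": self.p_floored,
        }


# ---------------------------------------------------------------------------
# gene-set files


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(parts[0], frozenset(parts[2:]), parts[1]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([s.name, s.description or "na", *sorted(s.members)]) for s in sets
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def sting_core_panel() -> GeneSet:
    """The bundled 25-gene cGAS–STING core pathway panel.

    This is a synthetic stand-in panel assembled from well-established
    pathway members (sensor, adaptor, trafficking, kinases, transcription
    factors, interferon-stimulated readouts); it is intended for use with
    the synthetic DE generator and can be replaced by any user GMT file.
    """
    with resources.files("stingquant.data").joinpath("sting_core_panel.gmt").open() as fh:
        line = fh.read().strip().splitlines()[0]
    parts = line.split("\t")
    return GeneSet(parts[0], frozenset(parts[2:]), parts[1])


# ---------------------------------------------------------------------------
# ranking


def rank_by_log2fc(
    de_table: pd.DataFrame, gene_col: str = "gene", score_col: str = "log2fc"
) -> RankedGeneList:
    """Build a descending-ranked gene list from a DE result table.

    Duplicate gene rows are collapsed to the row with maximal ``|log2FC|``
    (with a warning); ties in score are broken lexicographically by gene id
    so the ranking is deterministic.
    """
    if de_table.empty:
        raise ValueError("DE table is empty")
    df = de_table[[gene_col, score_col]].dropna()
    if df[gene_col].duplicated().any():
        warnings.warn("duplicate gene ids collapsed by max |log2FC|", stacklevel=2)
        df = df.loc[df[score_col].abs().groupby(df[gene_col]).idxmax()]
    df = df.sort_values(
        [score_col, gene_col], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(tuple(df[gene_col]), df[score_col].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# enrichment statistic


def _running_sum(scores: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    n = len(scores)
    n_h = int(hit.sum())
    if n_h == 0 or n_h >= n:
        raise ValueError("gene set must satisfy 1 <= N_h < N within the universe")
    w = np.where(hit, np.abs(scores) ** p, 0.0)
    n_r = w.sum()
    if n_r == 0:
        raise ValueError("all member scores are zero (N_R = 0)")
    steps = w / n_r - (~hit) / (n - n_h)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedGeneList, gene_set: GeneSet, p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and running sum for one gene set.

    Returns ``(es, running_sum)`` where ``running_sum`` has length N and, by
    construction, ends at 0 (hit and miss mass each integrate to 1). ES is
    the running-sum value of maximal absolute deviation, signed.
    """
    members = gene_set.intersect(ranked.genes).members
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    rs = _running_sum(ranked.scores, hit, p)
    i = int(np.argmax(np.abs(rs)))
    return float(np.clip(rs[i], -1.0, 1.0)), rs


def leading_edge(
    ranked: RankedGeneList, gene_set: GeneSet, p: float = 1.0
) -> list[str]:
    """Member genes at or before (after, for ES<0) the running-sum extremum."""
    members = gene_set.intersect(ranked.genes).members
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    rs = _running_sum(ranked.scores, hit, p)
    i = int(np.argmax(np.abs(rs)))
    if rs[i] >= 0:
        idx = np.flatnonzero(hit[: i + 1])
    else:
        idx = np.flatnonzero(hit[i + 1 :]) + i + 1
    return [ranked.genes[j] for j in idx]


def _sample_index_sets(
    rng: np.random.Generator, n: int, size: int, n_sets: int
) -> np.ndarray:
    """(n_sets, size) sorted arrays of distinct indices drawn uniformly."""
    if size * 8 > n:
        # dense sets: rejection sampling would stall, permute instead
        base = np.tile(np.arange(n), (n_sets, 1))
        return np.sort(rng.permuted(base, axis=1)[:, :size], axis=1)
    draws = rng.integers(0, n, size=(n_sets, size))
    draws.sort(axis=1)
    bad = np.flatnonzero((np.diff(draws, axis=1) == 0).any(axis=1))
    while bad.size:
        draws[bad] = rng.integers(0, n, size=(bad.size, size))
        draws[bad] = np.sort(draws[bad], axis=1)
        bad = bad[(np.diff(draws[bad], axis=1) == 0).any(axis=1)]
    return draws


def _es_from_hit_positions(
    positions: np.ndarray, abs_w: np.ndarray, n: int
) -> np.ndarray:
    """Vectorised ES for many index sets over one ranked list.

    ``positions`` is (n_sets, N_h), sorted 0-based hit ranks; ``abs_w`` is
    |score|^p per rank. Between hits the running sum decreases linearly, so
    its maximum is attained just after some hit and its minimum just before
    some hit (or at the ends, where it is 0 by construction).
    """
    n_sets, n_h = positions.shape
    miss_step = 1.0 / (n - n_h)
    w = abs_w[positions]
    n_r = w.sum(axis=1, keepdims=True)
    if np.any(n_r == 0):
        raise ValueError("a sampled set has all-zero scores (N_R = 0)")
    hit_cum = np.cumsum(w, axis=1) / n_r
    m = np.arange(1, n_h + 1)
    misses_before = positions + 1 - m  # misses up to and including rank i_m
    dev_after = hit_cum - misses_before * miss_step
    dev_before = np.concatenate(
        [np.zeros((n_sets, 1)), hit_cum[:, :-1]], axis=1
    ) - misses_before * miss_step
    top = np.maximum(dev_after.max(axis=1), 0.0)
    bot = np.minimum(dev_before.min(axis=1), 0.0)
    return np.clip(np.where(top >= -bot, top, bot), -1.0, 1.0)


def permutation_null(
    ranked: RankedGeneList,
    set_size: int,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    p: float = 1.0,
) -> np.ndarray:
    """ES values of ``n_perm`` uniformly sampled gene sets of ``set_size``.

    This is the fgsea-style gene-sampling null: only the ranked list is
    consumed, so phenotype labels are never permuted.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError("set_size must satisfy 1 <= size < N")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** p
    positions = _sample_index_sets(rng, n, set_size, n_perm)
    return _es_from_hit_positions(positions, abs_w, n)


def normalize(es: float, null: np.ndarray) -> tuple[float, float, bool]:
    """NES and empirical p for an observed ES against a permutation null.

    NES divides ES by the mean |ES| of null draws with matching sign; the
    empirical p-value is two-sided on |ES|, ``(1 + #{|null| >= |es|}) /
    (n_perm + 1)``, which is floored at ``1/(n_perm+1)`` and keeps the
    false-positive rate of random gene sets at the nominal level.

    Returns ``(nes, p_emp, floored)``.
    """
    null = np.asarray(null, dtype=float)
    same_sign = null[null > 0] if es > 0 else null[null < 0]
    floored = False
    if same_sign.size == 0:
        warnings.warn("no matching-sign null draws; NES floored", stacklevel=2)
        nes = float(np.sign(es)) * float("inf") if es != 0 else 0.0
        floored = True
    else:
        nes = es / float(np.mean(np.abs(same_sign)))
    n_perm = null.size
    n_extreme = int(np.sum(np.abs(null) >= abs(es)))
    p_emp = (1 + n_extreme) / (n_perm + 1)
    if n_extreme == 0:
        floored = True
    return float(nes), float(p_emp), floored


def analyze_gene_set(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    n_perm: int = 10000,
    seed: int = 0,
    p: float = 1.0,
    null: np.ndarray | None = None,
) -> EnrichmentResult:
    """ES/NES/empirical p for one gene set, with leading edge."""
    inter = gene_set.intersect(ranked.genes)
    es, _ = enrichment_score(ranked, inter, p)
    if null is None:
        null = permutation_null(ranked, len(inter), n_perm=n_perm, seed=seed, p=p)
    nes, p_emp, floored = normalize(es, null)
    return EnrichmentResult(
        gene_set=gene_set.name,
        es=es,
        nes=nes,
        p_emp=p_emp,
        n_perm=len(null),
        n_members=len(inter),
        leading_edge=leading_edge(ranked, inter, p),
        seed=seed if isinstance(seed, int) else None,
        p_floored=floored,
    )


def random_geneset_control(
    ranked: RankedGeneList,
    size: int = 30,
    n_sets: int = 200,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    p: float = 1.0,
) -> pd.DataFrame:
    """Negative control: enrichment of uniformly random gene sets.

    Draws ``n_sets`` random sets of ``size`` genes, scores each against a
    shared gene-sampling null of ``n_perm`` draws, and returns a per-set
    table (es, nes, p_emp, significant). On data where only a specific
    pathway is shifted, the significant fraction should stay near ``alpha``.
    """
    if not 1 <= size < len(ranked):
        raise ValueError("size must satisfy 1 <= size < N")
    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** p
    null = permutation_null(ranked, size, n_perm=n_perm, seed=rng, p=p)
    positions = _sample_index_sets(rng, len(ranked), size, n_sets)
    es_values = _es_from_hit_positions(positions, abs_w, len(ranked))
    rows = []
    for i, es in enumerate(es_values):
        nes, p_emp, floored = normalize(float(es), null)
        rows.append(
            {
                "set_index": i,
                "es": float(es),
                "nes": nes,
                "p_emp": p_emp,
                "significant": p_emp < alpha,
                "p_floored": floored,
            }
        )
    return pd.DataFrame(rows)
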