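"""Composite disease-gene evidence scoring and the SKiM prediction score.

Four evidence sources support a gene-disease association: expert-curated
gene-disease databases (weight 3), the KinderMiner text-mining system
(weight 2), a GWAS catalog (weight 2), and the SKiM literature-based
discovery system (weight 1). A gene's composite score is the sum of the
weights of the sources that report it, so it ranges from 1 (SKiM only) to 8
(all four). SKiM itself ranks intermediate terms by a prediction score:
the negative log of a Fisher exact test p-value plus the sort ratio (the
fraction of abstracts mentioning the B term that also mention the A term).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

SOURCES = ("disease_db", "kinderminer", "gwas", "skim")


@dataclass(frozen=True)
class SkimCounts:
    n_ab: int
    n_b: int
    fet_p: float

    def __post_init__(self):
        if not (0 <= self.n_ab <= self.n_b):
            raise ValueError("need 0 <= n_ab <= n_b")
        if not (0.0 < self.fet_p <= 1.0):
            raise ValueError("fet_p must lie in (0, 1]")


@dataclass
class ScoreConfig:
    weights: dict[str, int] = field(
        default_factory=lambda: {"disease_db": 3, "kinderminer": 2, "gwas": 2, "skim": 1}
    )
    log_base: float = 10.0

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")


def composite_score(
    gene: str, evidence: set[str], cfg: ScoreConfig | None = None
) -> int:
    """Sum of source weights over the evidence reporting ``gene``."""
    cfg = cfg or ScoreConfig()
    if not evidence:
        raise ValueError(f"{gene}: evidence set is empty")
    unknown = evidence - set(cfg.weights)
    if unknown:
        raise ValueError(f"{gene}: unknown evidence source(s) {sorted(unknown)}")
    return sum(cfg.weights[src] for src in evidence)


def skim_prediction_score(counts: SkimCounts, cfg: ScoreConfig | None = None) -> float:
    """-log(FET p) + n_ab / n_b, with the log base taken from the config."""
    cfg = cfg or ScoreConfig()
    sort_ratio = counts.n_ab / counts.n_b if counts.n_b else 0.0
    return -math.log(counts.fet_p, cfg.log_base) + sort_ratio


def rank_genes(score_table: dict[str, int] | pd.DataFrame) -> list[str]:
    """Genes ordered by descending score; ties broken lexicographically."""
    if isinstance(score_table, pd.DataFrame):
        items = list(zip(score_table["gene"], score_table["score"]))
    else:
        items = list(score_table.items())
    return [g for g, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def score_evidence_table(
    evidence: pd.DataFrame, cfg: ScoreConfig | None = None
) -> pd.DataFrame:
    """Aggregate a `gene source` table into a ranked `gene score sources` table."""
    cfg = cfg or ScoreConfig()
    grouped = evidence.groupby("gene")["source"].agg(lambda s: set(s))
    rows = [
        {
            "gene": gene,
            "score": composite_score(gene, srcs, cfg),
            "sources": ",".join(sorted(srcs)),
        }
        for gene, srcs in grouped.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "score", "sources"])
    order = rank_genes(dict(zip(df["gene"], df["score"]))) if len(df) else []
    return df.set_index("gene").loc[order].reset_index()
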