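"""TargetScan-style context-score ingestion and pseudo-logFC gene scoring.

Predicted miRNA->gene interactions carry non-positive context scores (more
negative = stronger predicted repression). Per gene, site-level events are
split by the direction of the targeting miRNA in metastasis, absolute
scores are summed per group, and the two group sums are combined into a
signed expression-like value:

    pseudo_logfc = w_down * sum_down - w_up * sum_up

Targets of upregulated miRNAs are predicted downregulated (negative) and
vice versa; genes hit by both groups partially cancel, so single-direction
targets outrank mixed ones at equal total score. ``simple`` weighting uses
w = 1; ``group_scaled`` weights each group by its share of all retained
events, the literal reading of scaling by the total number of interactions
in each group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_ALIASES = {
    "gene_symbol": ("Gene Symbol", "gene_symbol", "Gene"),
    "mirna": ("miRNA", "mirna", "miRNA family"),
    "context_score": ("context++ score", "context_score", "Context Score"),
    "transcript_id": ("Transcript ID", "transcript_id"),
}

SUMMARY_COLUMNS = [
    "n_events_up",
    "n_events_down",
    "n_links_up",
    "n_links_down",
    "sum_up",
    "sum_down",
    "cumulative_score",
    "pseudo_logfc",
    "predicted_direction",
]


@dataclass(frozen=True)
class TargetInteraction:
    """One predicted miRNA binding site ("event") on a gene."""

    mirna: str
    gene_symbol: str
    context_score: float
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if not self.mirna or not self.gene_symbol:
            raise DomainError("mirna and gene_symbol must be non-empty")


@dataclass(frozen=True)
class ScoringConfig:
    weighting_mode: str = "simple"  # simple | group_scaled
    cumulative_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.weighting_mode not in ("simple", "group_scaled"):
            raise DomainError(f"unknown weighting_mode {self.weighting_mode!r}")
        if self.cumulative_threshold < 0:
            raise DomainError("cumulative_threshold must be >= 0")


@dataclass
class ParsedTargets:
    interactions: list[TargetInteraction]
    n_skipped: int


def read_targetscan(path, column_aliases: dict | None = None) -> ParsedTargets:
    """Read a TargetScan-style TSV of predicted interactions.

    The header must name the gene-symbol, miRNA and context-score columns
    under any of the configured aliases. Rows whose score is missing or
    non-numeric are skipped with a logged warning and counted; scores keep
    their sign (canonically <= 0).
    """
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        for key, names in column_aliases.items():
            aliases[key] = tuple(names) if not isinstance(names, str) else (names,)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def find(key: str, required: bool) -> str | None:
        for name in aliases[key]:
            if name in df.columns:
                return name
        if required:
            raise FormatError(
                f"no column for {key!r}; tried {list(aliases[key])}"
            )
        return None

    gene_col = find("gene_symbol", required=True)
    mirna_col = find("mirna", required=True)
    score_col = find("context_score", required=True)
    tx_col = find("transcript_id", required=False)

    interactions: list[TargetInteraction] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            score = float(row[score_col])
        except ValueError:
            n_skipped += 1
            logger.warning(
                "skipping row with non-numeric context score %r (gene %s, miRNA %s)",
                row[score_col], row[gene_col], row[mirna_col],
            )
            continue
        if not np.isfinite(score):
            n_skipped += 1
            logger.warning("skipping row with non-finite context score")
            continue
        interactions.append(
            TargetInteraction(
                mirna=row[mirna_col],
                gene_symbol=row[gene_col],
                context_score=score,
                transcript_id=row[tx_col] if tx_col else None,
            )
        )
    return ParsedTargets(interactions=interactions, n_skipped=n_skipped)


def interactions_frame(interactions) -> pd.DataFrame:
    """List of :class:`TargetInteraction` -> tidy DataFrame."""
    return pd.DataFrame(
        [(i.mirna, i.gene_symbol, i.context_score) for i in interactions],
        columns=["mirna", "gene_symbol", "context_score"],
    )


class TargetScoreTransformer(TransformerMixin, BaseEstimator):
    """Aggregate per-site interactions into per-gene signed pseudo-logFC.

    ``transform(X)`` takes a tidy interaction DataFrame (columns ``mirna``,
    ``gene_symbol``, ``context_score``) and returns one row per retained
    gene with event/link counts, per-group absolute-score sums, the
    cumulative score, the signed pseudo-logFC and the predicted direction.

    Parameters
    ----------
    direction_map : dict[str, str]
        miRNA name -> "up" | "down" (its direction in metastasis).
        Interactions for miRNAs outside the map are ignored.
    weighting_mode : {"simple", "group_scaled"}
    cumulative_threshold : float
        Genes whose total absolute context score falls below this are
        dropped before weighting.
    """

    def __init__(self, direction_map=None, weighting_mode: str = "simple",
                 cumulative_threshold: float = 0.01):
        self.direction_map = direction_map
        self.weighting_mode = weighting_mode
        self.cumulative_threshold = cumulative_threshold

    def _validate(self) -> ScoringConfig:
        if not self.direction_map:
            raise DomainError("direction_map (the signature) must be non-empty")
        bad = set(self.direction_map.values()) - {"up", "down"}
        if bad:
            raise DomainError(f"directions must be up/down, got {sorted(bad)}")
        return ScoringConfig(
            weighting_mode=self.weighting_mode,
            cumulative_threshold=self.cumulative_threshold,
        )

    def fit(self, X, y=None):
        self._validate()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        config = self._validate()
        df = X[X["mirna"].isin(self.direction_map)].copy()
        out = pd.DataFrame(columns=SUMMARY_COLUMNS)
        out.index.name = "gene_symbol"
        if df.empty:
            return out
        df["group"] = df["mirna"].map(self.direction_map)
        df["abs_score"] = df["context_score"].abs()

        grouped = df.groupby(["gene_symbol", "group"])
        events = grouped.size().unstack("group", fill_value=0)
        links = (
            grouped["mirna"].nunique().unstack("group", fill_value=0)
        )
        sums = grouped["abs_score"].sum().unstack("group", fill_value=0.0)
        for frame in (events, links, sums):
            for g in ("up", "down"):
                if g not in frame.columns:
                    frame[g] = 0 if frame is not sums else 0.0

        summary = pd.DataFrame(
            {
                "n_events_up": events["up"],
                "n_events_down": events["down"],
                "n_links_up": links["up"],
                "n_links_down": links["down"],
                "sum_up": sums["up"].astype(float),
                "sum_down": sums["down"].astype(float),
            }
        )
        summary["cumulative_score"] = summary["sum_up"] + summary["sum_down"]
        summary = summary[summary["cumulative_score"] >= config.cumulative_threshold]
        if summary.empty:
            return out

        if config.weighting_mode == "simple":
            w_up = w_down = 1.0
        else:
            n_up = int(summary["n_events_up"].sum())
            n_down = int(summary["n_events_down"].sum())
            total = n_up + n_down
            w_up = n_up / total
            w_down = n_down / total
        summary["pseudo_logfc"] = (
            w_down * summary["sum_down"] - w_up * summary["sum_up"]
        )
        summary["predicted_direction"] = np.select(
            [summary["pseudo_logfc"] > 0, summary["pseudo_logfc"] < 0],
            ["up_in_bm", "down_in_bm"],
            default="neutral",
        )
        summary.index.name = "gene_symbol"
        return summary[SUMMARY_COLUMNS]


def summarize_gene_targets(
    interactions,
    signature,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Per-gene aggregation of interaction events into signed pseudo-logFC.

    ``signature`` is either a DataFrame with ``mirna``/``direction`` columns
    (as produced by :func:`mirsig.de.call_signature`) or a plain
    miRNA -> direction mapping. Interactions of miRNAs outside the
    signature are ignored; genes below the cumulative threshold are
    dropped.
    """
    if config is None:
        config = ScoringConfig()
    if isinstance(signature, pd.DataFrame):
        if signature.empty:
            raise DomainError("signature is empty")
        pairs = signature[["mirna", "direction"]].drop_duplicates()
        dup = pairs["mirna"].duplicated()
        if dup.any():
            raise DomainError(
                f"conflicting directions for miRNAs: "
                f"{sorted(pairs['mirna'][dup])}"
            )
        direction_map = dict(zip(pairs["mirna"], pairs["direction"]))
    else:
        direction_map = dict(signature)
    if not direction_map:
        raise DomainError("signature is empty")
    X = (
        interactions
        if isinstance(interactions, pd.DataFrame)
        else interactions_frame(interactions)
    )
    est = TargetScoreTransformer(
        direction_map=direction_map,
        weighting_mode=config.weighting_mode,
        cumulative_threshold=config.cumulative_threshold,
    ).fit(X)
    return est.transform(X)


def rank_genes(summaries: pd.DataFrame) -> pd.DataFrame:
    """Order genes by |pseudo_logfc| descending.

    Ties broken by higher cumulative score, then lexicographic gene symbol;
    fully deterministic.
    """
    if summaries.empty:
        return summaries.copy()
    key = summaries.assign(
        _abs=summaries["pseudo_logfc"].abs(),
        _gene=summaries.index,
    )
    ordered = key.sort_values(
        by=["_abs", "cumulative_score", "_gene"],
        ascending=[False, False, True],
        kind="stable",
    )
    return ordered.drop(columns=["_abs", "_gene"])
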