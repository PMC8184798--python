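"""Per-transcript RIP enrichment and Dicer cleavage scores.

Both statistics are log2 ratios of within-library read proportions:

    enrich_i  = log2( (RIP_i  / RIP_total)  / (input_i / input_total) )
    cleave_i  = log2( (Dead_i / Dead_total) / (WT_i    / WT_total) )

A transcript with a zero count in either condition gets a null (NaN)
score rather than +/-inf; membership in the enriched set requires a
strictly positive score.  No dispersion modelling or significance
testing is applied — the raw log-ratio is the statistic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _as_series(counts) -> pd.Series:
    if isinstance(counts, pd.Series):
        s = counts
    elif isinstance(counts, pd.DataFrame):
        s = counts.set_index(counts.columns[0])[counts.columns[1]]
    else:
        s = pd.Series(counts)
    s = s.astype(float)
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    return s


def log_ratio_score(numerator_counts, denominator_counts,
                    pseudocount: float = 0.0) -> pd.Series:
    """log2 proportion ratio per transcript; zero counts yield NaN.

    Transcripts absent from one table are treated as count 0 there.
    ``pseudocount`` (non-canonical, default 0) is added to every count
    before forming proportions, for exploration only.
    """
    num = _as_series(numerator_counts)
    den = _as_series(denominator_counts)
    idx = num.index.union(den.index, sort=False)
    num = num.reindex(idx, fill_value=0.0) + pseudocount
    den = den.reindex(idx, fill_value=0.0) + pseudocount
    num_total, den_total = num.sum(), den.sum()
    if num_total <= 0 or den_total <= 0:
        raise ValueError("both conditions need a positive total count")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2((num / num_total) / (den / den_total))
    bad = ~np.isfinite(score)
    if bad.any():
        logger.info("%d transcripts with a zero count set to null", int(bad.sum()))
    score[bad] = np.nan
    return score


def enrichment_score(rip_counts, input_counts,
                     pseudocount: float = 0.0) -> pd.Series:
    """RIP enrichment score: log2((RIP_i/RIP_total)/(input_i/input_total))."""
    return log_ratio_score(rip_counts, input_counts, pseudocount)


def cleavage_score(dead_counts, wt_counts,
                   pseudocount: float = 0.0) -> pd.Series:
    """Dicer cleavage score: log2((Dead_i/Dead_total)/(WT_i/WT_total))."""
    return log_ratio_score(dead_counts, wt_counts, pseudocount)


def classify_enriched(scores: pd.Series) -> set[str]:
    """Transcripts with strictly positive score; null scores excluded."""
    scores = pd.Series(scores)
    return set(scores.index[scores > 0])


def score_table(counts_a, counts_b, pseudocount: float = 0.0) -> pd.DataFrame:
    """TSV-ready table: transcript, both counts, score, enriched flag."""
    a, b = _as_series(counts_a), _as_series(counts_b)
    score = log_ratio_score(a, b, pseudocount)
    idx = score.index
    return pd.DataFrame({
        "transcript": idx,
        "count_a": a.reindex(idx, fill_value=0.0).to_numpy(),
        "count_b": b.reindex(idx, fill_value=0.0).to_numpy(),
        "score": score.to_numpy(),
        "enriched": (score > 0).to_numpy(),
    })
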