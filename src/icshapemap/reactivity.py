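"""Reactivity scoring from NAI/DMSO mutation rates, plus QC analyses.

The per-nucleotide score is

    s_i = (r_nai_i - r_dmso_i) / f

where r_* are all-class mutation rates in the treated and control
libraries and f is a per-transcript normalization factor.  f follows the
boxplot convention: values above Q3 + 1.5*IQR are excluded (capped at
10% of the usable positions), and f is the mean of the top 10% of the
remainder, so the top decile of normalized scores averages 1.

QC utilities: windowed between-replicate Pearson correlation of mutation
rates under increasing coverage cutoffs, and the ROC AUC of scores as a
predictor of the unpaired state against a reference structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .profiling import MutationCounts, mutation_rate

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 1000   # "well-covered" cutoff; 2000x gives very
                              # high-quality scores and is recommended
DEFAULT_MAX_BACKGROUND = 0.05
BOXPLOT_WHISKER = 1.5
MAX_EXCLUDED_FRACTION = 0.10
TOP_FRACTION = 0.10
MIN_USABLE_POSITIONS = 10

QC_COVERAGE_CUTOFFS = (500, 1000, 2000, 3000, 4000, 5000)
QC_WINDOW = 50
QC_STEP = 10


@dataclass
class ReactivityProfile:
    """Normalized per-nucleotide reactivities for one transcript.

    ``scores`` is a float array with NaN at masked positions;
    ``norm_factor`` is None when the profile could not be normalized.
    """

    transcript: str
    sequence: str
    scores: np.ndarray
    coverage: np.ndarray
    norm_factor: float | None

    def __post_init__(self):
        if len(self.scores) != len(self.sequence):
            raise ValueError("score vector must match sequence length")


def raw_reactivity(nai_rate, dmso_rate) -> np.ndarray:
    """Raw score: NAI minus DMSO mutation rate; NaN propagates."""
    nai = np.asarray(nai_rate, dtype=float)
    dmso = np.asarray(dmso_rate, dtype=float)
    if nai.shape != dmso.shape:
        raise ValueError("rate vectors differ in length")
    return nai - dmso


def boxplot_normalization_factor(raw) -> float | None:
    """The boxplot normalization factor of a raw score vector.

    Returns None when fewer than MIN_USABLE_POSITIONS values are usable
    or the factor would be non-positive.
    """
    values = np.asarray(raw, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < MIN_USABLE_POSITIONS:
        return None
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + BOXPLOT_WHISKER * (q3 - q1)
    order = np.sort(values)
    n_above = int(np.sum(order > fence))
    n_excluded = min(n_above, int(MAX_EXCLUDED_FRACTION * values.size))
    remainder = order[:values.size - n_excluded] if n_excluded else order
    n_top = max(1, int(np.ceil(TOP_FRACTION * remainder.size)))
    f = float(np.mean(remainder[-n_top:]))
    return f if f > 0 else None


def normalize_profile(raw, transcript: str = "", sequence: str | None = None,
                      coverage=None) -> ReactivityProfile:
    """Normalize raw scores into a ReactivityProfile.

    When normalization is impossible (too few usable positions, or a
    non-positive factor as for an all-zero profile) the profile is
    emitted fully null with ``norm_factor`` None and a warning.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    sequence = sequence if sequence is not None else "N" * n
    coverage = (np.zeros(n, dtype=np.int64) if coverage is None
                else np.asarray(coverage))
    f = boxplot_normalization_factor(raw)
    if f is None:
        warnings.warn(
            f"transcript {transcript!r}: cannot normalize "
            "(too few usable positions or non-positive factor); "
            "profile emitted fully null")
        return ReactivityProfile(transcript, sequence,
                                 np.full(n, np.nan), coverage, None)
    return ReactivityProfile(transcript, sequence, raw / f, coverage, f)


def mask_profile(profile: ReactivityProfile,
                 min_coverage: int = DEFAULT_MIN_COVERAGE,
                 dmso_rate=None,
                 max_background: float = DEFAULT_MAX_BACKGROUND
                 ) -> ReactivityProfile:
    """Null out unreliable positions: low coverage, or a DMSO mutation
    rate so high it marks an endogenous modification site (m1A-like)."""
    if min_coverage <= 0 or max_background <= 0:
        raise ValueError("thresholds must be positive")
    scores = profile.scores.copy()
    scores[profile.coverage < min_coverage] = np.nan
    if dmso_rate is not None:
        dmso = np.asarray(dmso_rate, dtype=float)
        with np.errstate(invalid="ignore"):
            scores[dmso > max_background] = np.nan
    return ReactivityProfile(profile.transcript, profile.sequence, scores,
                             profile.coverage, profile.norm_factor)


def score_transcript(nai: MutationCounts, dmso: MutationCounts,
                     sequence: str,
                     nai2: MutationCounts | None = None,
                     dmso2: MutationCounts | None = None,
                     min_coverage: int = DEFAULT_MIN_COVERAGE,
                     max_background: float = DEFAULT_MAX_BACKGROUND
                     ) -> ReactivityProfile:
    """Counts-to-profile convenience: combine replicates (summing event
    counts and coverage before the rate step), score, normalize, mask."""
    if nai2 is not None:
        nai = nai + nai2
    if dmso2 is not None:
        dmso = dmso + dmso2
    r_nai = mutation_rate(nai, min_coverage=1)
    r_dmso = mutation_rate(dmso, min_coverage=1)
    raw = raw_reactivity(r_nai, r_dmso)
    # mask on the *minimum* of the two libraries' coverage
    cov = np.minimum(nai.coverage, dmso.coverage)
    profile = normalize_profile(raw, nai.transcript, sequence, cov)
    return mask_profile(profile, min_coverage, r_dmso, max_background)


# ---------------------------------------------------------------------------
# replicate QC


def _downsample_counts(counts: MutationCounts, fraction: float,
                       rng: np.random.Generator) -> MutationCounts:
    """Thin coverage binomially and events hypergeometrically to match."""
    out = MutationCounts(counts.transcript, counts.length)
    ev = counts.total_events
    new_cov = rng.binomial(counts.coverage, fraction)
    new_ev = np.zeros(counts.length, dtype=np.int64)
    for i in range(counts.length):
        c, e = int(counts.coverage[i]), int(ev[i])
        k = min(int(new_cov[i]), c)
        if k > 0 and e > 0:
            new_ev[i] = rng.hypergeometric(e, c - e, k)
        new_cov[i] = k
    out.coverage = new_cov.astype(np.int64)
    out.counts["mismatch"] = new_ev  # class identity is irrelevant for QC rates
    return out


def replicate_correlation(rep1, rep2, window: int = QC_WINDOW,
                          step: int = QC_STEP,
                          cutoffs=QC_COVERAGE_CUTOFFS,
                          seed: int = 0) -> dict[int, np.ndarray]:
    """Windowed between-replicate Pearson r of mutation rates per cutoff.

    ``rep1``/``rep2`` are matched lists of MutationCounts over the same
    references.  Total coverages are first balanced by seeded
    down-sampling of the deeper replicate; bases are then sorted by
    (balanced, pairwise-minimum) coverage, and for each coverage cutoff
    the qualifying bases are windowed (size 50, step 10) with Pearson r
    of the two replicates' mutation rates computed per window.  Windows
    with zero variance in either replicate are skipped and logged.
    """
    from scipy.stats import pearsonr

    if isinstance(rep1, MutationCounts):
        rep1, rep2 = [rep1], [rep2]
    if len(rep1) != len(rep2):
        raise ValueError("replicates must cover the same references")

    total1 = sum(int(c.coverage.sum()) for c in rep1)
    total2 = sum(int(c.coverage.sum()) for c in rep2)
    rng = np.random.default_rng(seed)
    if total1 > total2 and total1 > 0:
        rep1 = [_downsample_counts(c, total2 / total1, rng) for c in rep1]
    elif total2 > total1 and total2 > 0:
        rep2 = [_downsample_counts(c, total1 / total2, rng) for c in rep2]

    cov1 = np.concatenate([c.coverage for c in rep1])
    cov2 = np.concatenate([c.coverage for c in rep2])
    with np.errstate(divide="ignore", invalid="ignore"):
        rate1 = np.concatenate([c.total_events for c in rep1]) / cov1
        rate2 = np.concatenate([c.total_events for c in rep2]) / cov2
    pair_cov = np.minimum(cov1, cov2)

    order = np.argsort(-pair_cov, kind="stable")
    results: dict[int, np.ndarray] = {}
    for cutoff in cutoffs:
        sel = order[pair_cov[order] > cutoff]
        r1, r2 = rate1[sel], rate2[sel]
        rs: list[float] = []
        if sel.size == 0:
            results[cutoff] = np.array([])
            continue
        starts = range(0, max(sel.size - window, 0) + 1, step) \
            if sel.size >= window else [0]
        for s in starts:
            w1, w2 = r1[s:s + window], r2[s:s + window]
            if np.std(w1) == 0 or np.std(w2) == 0:
                logger.info("cutoff %d: window at %d skipped (zero variance)",
                            cutoff, s)
                continue
            rs.append(float(pearsonr(w1, w2)[0]))
        results[cutoff] = np.array(rs)
    return results


def structure_auc(profile, reference_structure) -> float:
    """ROC AUC of reactivity as a predictor of the unpaired state.

    Higher score should mean unpaired; ties count half (trapezoidal
    ROC); null (NaN) positions are excluded.  Raises if the reference
    has only one class among the scored positions.
    """
    from sklearn.metrics import roc_auc_score

    scores = profile.scores if hasattr(profile, "scores") else np.asarray(profile, float)
    pair_table = reference_structure.pair_table \
        if hasattr(reference_structure, "pair_table") else np.asarray(reference_structure)
    if len(scores) != len(pair_table):
        raise ValueError("profile/structure length mismatch")
    keep = np.isfinite(scores)
    labels = (pair_table[keep] == 0).astype(int)  # 1 = unpaired
    if labels.min() == labels.max():
        raise ValueError("reference structure has a single class at scored positions")
    return float(roc_auc_score(labels, scores[keep]))
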