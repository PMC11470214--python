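"""Profile-matched inter- and intra-rater reproducibility via Kendall W.

Scales cannot be re-administered to the same patient (a first consultation
for violence is not repeatable), so reproducibility is assessed on *matched*
patients: within each violence-situation profile, patients of two physicians
(interrater) or of one physician (intrarater) are randomly paired, and the
paired scores form an n-subjects x 2-raters ratings matrix.  Agreement is
the tie-corrected Kendall coefficient of concordance

    W = 12 S / (m^2 (n^3 - n) - m sum_j T_j),

with S the squared deviation of subject rank sums from their mean,
mid-ranks within each rater column, and T_j = sum over tie groups of
(t^3 - t).  For m = 2 without ties, W = (rho_Spearman + 1) / 2.

Because a single random matching is a lottery, the matching is repeated
(default 100 times) and W is summarized by its mean and 2.5/97.5
percentiles over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .gower import DissimilarityMatrix
from .pam import ClusteringResult

__all__ = [
    "DegenerateRatingsError",
    "RatingsMatrix",
    "MatchedPairSet",
    "ConcordanceResult",
    "rank_with_ties",
    "kendall_w",
    "match_interrater",
    "match_intrarater",
    "concordance_analysis",
    "sensitivity_fine_profiles",
    "labels_series",
]


class DegenerateRatingsError(ValueError):
    """The tie-corrected denominator vanished (e.g. an all-constant rater)."""


def rank_with_ties(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Mid-ranks and the tie term T = sum(t^3 - t) over tie groups."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    ranks = rankdata(arr, method="average")
    _, counts = np.unique(arr, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_term


@dataclass
class RatingsMatrix:
    """n subjects x m raters ordinal scores."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-dimensional (subjects x raters)")
        n, m = self.scores.shape
        if n < 2 or m < 2:
            raise ValueError(f"need >=2 subjects and >=2 raters, got {n}x{m}")

    @property
    def ranks(self) -> np.ndarray:
        return np.column_stack([rank_with_ties(col)[0] for col in self.scores.T])

    @property
    def tie_terms(self) -> np.ndarray:
        return np.array([rank_with_ties(col)[1] for col in self.scores.T])


def kendall_w(ratings: RatingsMatrix | np.ndarray) -> float:
    """Tie-corrected Kendall coefficient of concordance, in [0, 1].

    Raises
    ------
    DegenerateRatingsError
        If the tie-corrected denominator is not positive (e.g. every rater
        column constant), in which case W is undefined rather than 0 or 1.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(ratings)
    n, m = ratings.scores.shape
    ranks = ratings.ranks
    tie_sum = float(ratings.tie_terms.sum())
    denom = m * m * (n**3 - n) - m * tie_sum
    if denom <= 0:
        raise DegenerateRatingsError(
            "Kendall W undefined: tie-corrected denominator is not positive"
        )
    rank_sums = ranks.sum(axis=1)
    s = float(np.sum((rank_sums - m * (n + 1) / 2.0) ** 2))
    return 12.0 * s / denom


@dataclass
class MatchedPairSet:
    """Random within-profile pairing of patients."""

    pairs: list[tuple[object, object, object]]  # (id_a, id_b, profile)
    matching_seed: int | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def by_profile(self) -> dict:
        out: dict = {}
        for a, b, pr in self.pairs:
            out.setdefault(pr, []).append((a, b))
        return out


def labels_series(result: ClusteringResult) -> pd.Series:
    """Profile labels indexed by patient id, from a clustering result."""
    return pd.Series(result.labels, index=result.ids, name="profile")


def _labels_lookup(labels) -> pd.Series:
    if isinstance(labels, ClusteringResult):
        return labels_series(labels)
    if isinstance(labels, pd.Series):
        return labels
    if isinstance(labels, dict):
        return pd.Series(labels)
    raise TypeError("labels must be a ClusteringResult, Series or dict keyed by patient_id")


def match_interrater(
    cohort: Cohort,
    labels,
    physician_a,
    physician_b,
    seed: int | None = None,
) -> MatchedPairSet:
    """Random within-profile bijection between two physicians' patients.

    For each profile seen by both physicians, ``min(n_a, n_b)`` patients are
    drawn without replacement from the larger side and paired uniformly at
    random with the smaller side.  At least one shared profile must hold >=2
    patients of each physician.
    """
    lab = _labels_lookup(labels)
    df = cohort.df
    rng = np.random.default_rng(seed)
    ids_a = df.loc[df["physician_id"] == physician_a, "patient_id"]
    ids_b = df.loc[df["physician_id"] == physician_b, "patient_id"]
    prof_a = lab.reindex(ids_a).dropna()
    prof_b = lab.reindex(ids_b).dropna()
    shared = sorted(set(prof_a.unique()) & set(prof_b.unique()), key=str)
    if not any(
        (prof_a == pr).sum() >= 2 and (prof_b == pr).sum() >= 2 for pr in shared
    ):
        raise ValueError(
            f"physicians {physician_a!r} and {physician_b!r} share no profile "
            "with at least 2 patients each"
        )
    pairs: list[tuple[object, object, object]] = []
    for pr in shared:
        a = prof_a.index[prof_a == pr].to_numpy()
        b = prof_b.index[prof_b == pr].to_numpy()
        s = min(len(a), len(b))
        if s < 1:
            continue
        a = rng.permutation(a)[:s]
        b = rng.permutation(b)[:s]
        pairs.extend((x, y, pr) for x, y in zip(a, b))
    return MatchedPairSet(pairs=pairs, matching_seed=seed)


def match_intrarater(cohort: Cohort, labels, physician, seed: int | None = None) -> MatchedPairSet:
    """Random within-profile partition of one physician's patients into pairs.

    Within each profile the patients are shuffled and paired consecutively
    (uniform over perfect matchings); one patient is left unpaired when the
    count is odd.  Member order within a pair is random.
    """
    lab = _labels_lookup(labels)
    df = cohort.df
    rng = np.random.default_rng(seed)
    ids = df.loc[df["physician_id"] == physician, "patient_id"]
    prof = lab.reindex(ids).dropna()
    profiles = sorted(prof.unique(), key=str)
    if not any((prof == pr).sum() >= 2 for pr in profiles):
        raise ValueError(f"physician {physician!r} has no profile with >=2 patients")
    pairs: list[tuple[object, object, object]] = []
    for pr in profiles:
        members = rng.permutation(prof.index[prof == pr].to_numpy())
        for i in range(0, len(members) - 1, 2):
            pairs.append((members[i], members[i + 1], pr))
    return MatchedPairSet(pairs=pairs, matching_seed=seed)


@dataclass
class ConcordanceResult:
    """Repeated-matching concordance of one scale in one rating context."""

    scale: str
    context: object  # (physician_a, physician_b) or a single physician
    repetitions: int
    pooled_W: float  # mean over repetitions (NaN if never defined)
    W_mean: float
    W_p2_5: float
    W_p97_5: float
    per_profile_W: dict = field(default_factory=dict)
    n_pairs_per_profile: dict = field(default_factory=dict)
    n_undefined: int = 0
    pooled_values: np.ndarray | None = None


def _pairs_ratings(pairs: Iterable[tuple], scores: pd.Series) -> np.ndarray:
    """Usable (non-missing both sides) paired scores as an n x 2 array."""
    rows = []
    for a, b, _ in pairs:
        sa, sb = scores.get(a), scores.get(b)
        if pd.notna(sa) and pd.notna(sb):
            rows.append((float(sa), float(sb)))
    return np.asarray(rows, dtype=float).reshape(-1, 2)


def _safe_w(mat: np.ndarray) -> float:
    if mat.shape[0] < 2:
        return np.nan
    try:
        return kendall_w(mat)
    except DegenerateRatingsError:
        return np.nan


def concordance_analysis(
    cohort: Cohort,
    labels,
    scale: str,
    contexts: Sequence,
    repetitions: int = 100,
    seed: int | None = None,
) -> dict:
    """Repeated-matching Kendall W per context (physician pair or physician).

    A context given as a 2-tuple is analysed interrater, a scalar context
    intrarater.  Per repetition the matching is redrawn, missing scores are
    excluded pairwise, W is computed per profile and pooled (all pairs
    concatenated); cells with fewer than 2 usable pairs are reported as
    undefined (NaN), never silently dropped.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    lab = _labels_lookup(labels)
    if scale not in cohort.df.columns:
        raise ValueError(f"scale {scale!r} absent from the cohort")
    scores = cohort.df.set_index("patient_id")[scale]
    ss = np.random.SeedSequence(seed)
    results: dict = {}
    for context in contexts:
        interrater = isinstance(context, (tuple, list)) and len(context) == 2
        rep_seeds = ss.spawn(repetitions)
        pooled_vals = np.full(repetitions, np.nan)
        per_profile: dict = {}
        n_pairs: dict = {}
        n_undef = 0
        for r, child in enumerate(rep_seeds):
            rep_rng_seed = int(child.generate_state(1)[0] % (2**31))
            if interrater:
                matched = match_interrater(cohort, lab, context[0], context[1], rep_rng_seed)
            else:
                matched = match_intrarater(cohort, lab, context, rep_rng_seed)
            pooled = _pairs_ratings(matched.pairs, scores)
            w = _safe_w(pooled)
            pooled_vals[r] = w
            if np.isnan(w):
                n_undef += 1
            for pr, pr_pairs in matched.by_profile().items():
                mat = _pairs_ratings([(a, b, pr) for a, b in pr_pairs], scores)
                per_profile.setdefault(pr, []).append(_safe_w(mat))
                n_pairs.setdefault(pr, []).append(mat.shape[0])
        defined = pooled_vals[~np.isnan(pooled_vals)]
        results[context if not interrater else tuple(context)] = ConcordanceResult(
            scale=scale,
            context=context if not interrater else tuple(context),
            repetitions=repetitions,
            pooled_W=float(defined.mean()) if len(defined) else np.nan,
            W_mean=float(defined.mean()) if len(defined) else np.nan,
            W_p2_5=float(np.percentile(defined, 2.5)) if len(defined) else np.nan,
            W_p97_5=float(np.percentile(defined, 97.5)) if len(defined) else np.nan,
            per_profile_W={
                pr: float(np.nanmean(v)) if not np.all(np.isnan(v)) else np.nan
                for pr, v in per_profile.items()
            },
            n_pairs_per_profile={pr: float(np.mean(v)) for pr, v in n_pairs.items()},
            n_undefined=n_undef,
            pooled_values=pooled_vals,
        )
    return results


def sensitivity_fine_profiles(
    cohort: Cohort,
    dissim: DissimilarityMatrix,
    base_labels,
    scale: str,
    contexts: Sequence,
    repetitions: int = 20,
    seed: int | None = None,
    n_profiles_large: int | None = None,
) -> pd.DataFrame:
    """Re-run the concordance analysis under a much finer typology.

    Re-clusters at ``n_profiles_large`` (default n/5, capped at n/2) so that
    matched patients share nearly identical situations, then repeats the
    concordance analysis with the *same* matching seed as the base run, so
    any W difference is attributable to profiling granularity alone.
    Returns a tidy frame with base and fine pooled W per context.
    """
    from .pam import pam as run_pam

    n = len(cohort)
    if n_profiles_large is None:
        n_profiles_large = max(2, n // 5)
    if n_profiles_large > n // 2:
        raise ValueError(f"n_profiles_large={n_profiles_large} exceeds n/2={n // 2}")
    fine = run_pam(dissim, n_profiles_large)
    base_res = concordance_analysis(cohort, base_labels, scale, contexts, repetitions, seed)
    fine_res = concordance_analysis(cohort, labels_series(fine), scale, contexts, repetitions, seed)
    rows = []
    for ctx in base_res:
        rows.append(
            {
                "scale": scale,
                "context": str(ctx),
                "k_base": len(pd.unique(_labels_lookup(base_labels).dropna())),
                "k_fine": n_profiles_large,
                "W_base": base_res[ctx].pooled_W,
                "W_fine": fine_res[ctx].pooled_W,
                "delta": fine_res[ctx].pooled_W - base_res[ctx].pooled_W,
            }
        )
    return pd.DataFrame(rows)
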