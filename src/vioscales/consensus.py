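"""Consensus-resampled selection of the number of violence-situation profiles.

The cohort is repeatedly subsampled without replacement; each subsample is
clustered with PAM at every candidate number of clusters k (sharing the
draws across k keeps pure sampling noise out of the between-k comparison),
and the per-k consensus matrix records for every patient pair the fraction
of co-subsampled runs in which the pair landed in the same cluster.  Four
stability metrics are computed per k and combined by mean rank:

* **PAC** (proportion of ambiguous clustering): fraction of defined
  off-diagonal consensus entries inside an ambiguity band (default
  (0.1, 0.9)); lower is more stable.
* **mean consensus**: mean consensus over pairs co-clustered by the
  reference full-data PAM partition at that k; higher is better.
* **Jaccard stability**: mean, over resample runs, of the Jaccard index
  between the run's co-membership pairs and the reference partition's
  co-membership pairs restricted to the subsample; higher is better.
* **consensus silhouette**: silhouette of the reference partition on
  1 - consensus; higher is better.

Pairs never drawn together have an undefined consensus entry (NaN); they
are excluded from PAC and mean consensus and imputed with the mean defined
entry for the silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from .cohort import Cohort
from .gower import DissimilarityMatrix, gower_dissimilarity
from .pam import PAM, ClusteringResult, pam

__all__ = [
    "ConsensusClustering",
    "ConsensusResult",
    "consensus_clustering",
    "select_n_profiles",
    "assign_profiles",
    "profile_summary",
]

logger = logging.getLogger(__name__)

#: Metric orientation used by the mean-rank rule: +1 = higher is better.
METRIC_ORIENTATION = {"pac": -1, "mean_consensus": 1, "jaccard": 1, "silhouette": 1}


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and metrics, plus the selected k."""

    consensus: dict[int, np.ndarray]
    metrics: pd.DataFrame  # indexed by k, columns = METRIC_ORIENTATION keys
    selected_k: int
    reference_labels: dict[int, np.ndarray]
    resample_log: list[dict] = field(default_factory=list)
    ids: np.ndarray | None = None


class ConsensusClustering(BaseEstimator):
    """Scan a k range with resampled PAM and pick the most stable k.

    Parameters
    ----------
    k_range:
        Candidate numbers of clusters (default 2..10).
    n_resamples:
        Subsampled PAM runs per candidate k.
    subsample_frac:
        Fraction of records drawn (without replacement) per run.  0.8 is
        the classical desk default; large cohorts use smaller fractions.
    pac_bounds:
        The ambiguity band for PAC.
    random_state:
        Seed for the subsample draws (PAM itself is deterministic).

    Attributes
    ----------
    consensus_ : dict of k -> (n, n) float32 matrix (NaN where undefined)
    metrics_ : DataFrame indexed by k
    selected_k_ : int
    reference_labels_ : dict of k -> full-data PAM labels
    resample_log_ : list of per-run records (k, run, seed, indices, labels)
    """

    def __init__(
        self,
        k_range=tuple(range(2, 11)),
        n_resamples: int = 50,
        subsample_frac: float = 0.8,
        pac_bounds: tuple[float, float] = (0.1, 0.9),
        random_state: int | None = None,
        keep_resample_log: bool = False,
    ):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_frac = subsample_frac
        self.pac_bounds = pac_bounds
        self.random_state = random_state
        self.keep_resample_log = keep_resample_log

    def fit(self, X, y=None):
        d = X.values if isinstance(X, DissimilarityMatrix) else np.asarray(X, dtype=float)
        n = d.shape[0]
        ks = sorted(int(k) for k in self.k_range)
        if not ks:
            raise ValueError("k_range is empty")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must lie in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        m = int(round(self.subsample_frac * n))
        m = max(m, max(ks))
        rng = np.random.default_rng(self.random_state)
        # one subsample per resampling iteration, clustered at every k, so
        # the between-k comparison shares the same draws
        subsamples = [np.sort(rng.choice(n, size=m, replace=False))
                      for _ in range(self.n_resamples)]

        self.consensus_ = {}
        self.reference_labels_ = {}
        self.resample_log_ = []
        rows = []
        for k in ks:
            cocluster = np.zeros((n, n), dtype=np.int32)
            cosample = np.zeros((n, n), dtype=np.int32)
            run_labels = []
            for run in range(self.n_resamples):
                idx = subsamples[run]
                labels = PAM(n_clusters=k).fit(d[np.ix_(idx, idx)]).labels_
                run_labels.append((idx, labels))
                block = np.ix_(idx, idx)
                cosample[block] += 1
                for c in range(k):
                    members = idx[labels == c]
                    cocluster[np.ix_(members, members)] += 1
                if self.keep_resample_log:
                    self.resample_log_.append(
                        {"k": k, "run": run, "indices": idx, "labels": labels}
                    )
            with np.errstate(invalid="ignore", divide="ignore"):
                consensus = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), np.nan)
            consensus = consensus.astype(np.float32)
            self.consensus_[k] = consensus

            ref = PAM(n_clusters=k).fit(d).labels_
            self.reference_labels_[k] = ref
            rows.append(
                {
                    "k": k,
                    "pac": _pac(consensus, self.pac_bounds),
                    "mean_consensus": _mean_within_cluster_consensus(consensus, ref),
                    "jaccard": _mean_jaccard(run_labels, ref),
                    "silhouette": _consensus_silhouette(consensus, ref),
                }
            )
        self.metrics_ = pd.DataFrame(rows).set_index("k")
        self.selected_k_ = select_n_profiles(self.metrics_)
        return self

    def result(self, ids: np.ndarray | None = None) -> ConsensusResult:
        return ConsensusResult(
            consensus=self.consensus_,
            metrics=self.metrics_,
            selected_k=self.selected_k_,
            reference_labels=self.reference_labels_,
            resample_log=self.resample_log_,
            ids=ids,
        )


def _offdiag_defined(consensus: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    return vals[~np.isnan(vals)]


def _pac(consensus: np.ndarray, bounds: tuple[float, float]) -> float:
    vals = _offdiag_defined(consensus)
    if len(vals) == 0:
        return np.nan
    lo, hi = bounds
    return float(np.mean((vals > lo) & (vals < hi)))


def _mean_within_cluster_consensus(consensus: np.ndarray, ref: np.ndarray) -> float:
    same = ref[:, None] == ref[None, :]
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    mask = same[iu] & ~np.isnan(vals)
    if not mask.any():
        return np.nan
    return float(vals[mask].mean())


def _mean_jaccard(run_labels: list[tuple[np.ndarray, np.ndarray]], ref: np.ndarray) -> float:
    scores = []
    for idx, labels in run_labels:
        a = labels[:, None] == labels[None, :]
        r = ref[idx]
        b = r[:, None] == r[None, :]
        iu = np.triu_indices(len(idx), k=1)
        a, b = a[iu], b[iu]
        union = np.count_nonzero(a | b)
        if union == 0:
            continue
        scores.append(np.count_nonzero(a & b) / union)
    return float(np.mean(scores)) if scores else np.nan


def _consensus_silhouette(consensus: np.ndarray, ref: np.ndarray) -> float:
    filled = consensus.astype(float)
    defined = _offdiag_defined(consensus)
    fill = float(defined.mean()) if len(defined) else 0.5
    filled[np.isnan(filled)] = fill
    dist = 1.0 - filled
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if len(np.unique(ref)) < 2:
        return np.nan
    return float(silhouette_score(dist, ref, metric="precomputed"))


def select_n_profiles(metrics: pd.DataFrame, rule: str = "mean_rank") -> int:
    """Combine the stability metrics into one selected k.

    The default (and only) rule ranks the candidate k on each metric in its
    good direction (PAC ascending, the rest descending) and returns the k
    with the best mean rank; exact ties go to the smaller k.  If every
    candidate is metrically indistinguishable the smallest k is returned
    with a logged warning.
    """
    if rule != "mean_rank":
        raise ValueError(f"unknown selection rule {rule!r}")
    if len(metrics) < 2:
        return int(metrics.index[0])
    from scipy.stats import rankdata

    ranks = []
    for col, orientation in METRIC_ORIENTATION.items():
        vals = metrics[col].to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            continue
        ranks.append(rankdata(-orientation * vals, method="average", nan_policy="omit"))
    if not ranks:
        logger.warning("no finite stability metrics; returning the smallest k")
        return int(metrics.index.min())
    mean_rank = np.nanmean(np.vstack(ranks), axis=0)
    if np.allclose(mean_rank, mean_rank[0]):
        logger.warning("all candidate k are metrically equivalent; returning the smallest")
        return int(metrics.index.min())
    best = np.flatnonzero(mean_rank == mean_rank.min())
    return int(metrics.index[best[0]])  # index ascending -> smallest k wins ties


def consensus_clustering(
    cohort: Cohort | DissimilarityMatrix | np.ndarray,
    k_range=tuple(range(2, 11)),
    n_resamples: int = 50,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    keep_resample_log: bool = False,
) -> ConsensusResult:
    """Run the consensus scan on a cohort (or a precomputed dissimilarity)."""
    if isinstance(cohort, Cohort):
        dissim = gower_dissimilarity(cohort)
        ids = dissim.ids
        d = dissim.values
    elif isinstance(cohort, DissimilarityMatrix):
        d, ids = cohort.values, cohort.ids
    else:
        d = np.asarray(cohort, dtype=float)
        ids = np.arange(d.shape[0])
    est = ConsensusClustering(
        k_range=k_range,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        random_state=seed,
        keep_resample_log=keep_resample_log,
    ).fit(d)
    return est.result(ids=ids)


def assign_profiles(
    cohort: Cohort,
    dissim: DissimilarityMatrix,
    k_star: int,
    seed: int | None = None,
) -> tuple[ClusteringResult, pd.DataFrame]:
    """Final full-cohort PAM at the selected k plus per-profile summaries."""
    result = pam(dissim, k_star, seed)
    summary = profile_summary(cohort, result.labels)
    return result, summary


def profile_summary(cohort: Cohort, labels: np.ndarray) -> pd.DataFrame:
    """Per-profile description: n, binary counts (%), numeric median (IQR).

    One row per variable, one column per profile (labeled by cluster index)
    plus an ``all`` column, mirroring the classical cohort-table layout.
    """
    df = cohort.df
    groups = {str(c): df[labels == c] for c in np.unique(labels)}
    groups["all"] = df
    rows = []
    for var, kind in cohort.feature_spec.items():
        row: dict[str, object] = {"variable": var, "type": kind}
        for name, g in groups.items():
            col = g[var].dropna()
            if kind == "numeric":
                if len(col) == 0:
                    row[name] = ""
                else:
                    q1, med, q3 = np.percentile(col.astype(float), [25, 50, 75])
                    row[name] = f"{med:g} ({q1:g}-{q3:g})"
            else:
                cnt = int(pd.to_numeric(col).sum())
                pct = 100.0 * cnt / len(col) if len(col) else 0.0
                row[name] = f"{cnt} ({pct:.1f}%)"
        rows.append(row)
    header = {"variable": "n", "type": "count"}
    for name, g in groups.items():
        header[name] = str(len(g))
    return pd.DataFrame([header] + rows)
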