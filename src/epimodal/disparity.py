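"""Sequence-vs-profile disparity and its chromatin-structure explanation.

Sequence-only predictors must give similar outputs to similar inputs, yet
genomic windows of low sequence similarity often share near-identical
epigenetic profiles.  The hypothesis tested here is that such disparity is
explained by 3D proximity: among randomly drawn window pairs with nonzero
Hi-C contact frequency, pairs whose sequence-similarity percentile falls
*under* their profile-similarity percentile should show *higher* contact
frequencies than percentile-consistent pairs (and "over" pairs lower), as
judged by one-sided Wilcoxon rank-sum tests.

The rank-sum test is computed exactly by enumeration for small samples
(combined size <= 12, mid-ranks for ties) and by a normal approximation
with tie and continuity corrections otherwise.

Similarity metrics default to positional identity (sequences, N positions
masked) and the Jaccard index (binary profiles); k-mer-cosine and cosine
alternatives are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata, spearmanr

from .hic_io import InteractionMatrix

EXACT_LIMIT = 12


# --- similarity metrics -----------------------------------------------------

def sequence_similarity(s1: str, s2: str) -> float:
    """Fraction of positions with identical bases, N positions masked out.

    Returns 0 when no position is comparable (both-N everywhere).
    """
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    mask = (a != ord("N")) & (b != ord("N"))
    if not mask.any():
        return 0.0
    return float((a[mask] == b[mask]).mean())


def kmer_cosine_similarity(s1: str, s2: str, k: int = 4) -> float:
    """Cosine similarity of k-mer count vectors (alternative metric)."""
    from .encoders import KmerRegionEmbedder

    emb = KmerRegionEmbedder(k=k, out_dim=1, seed=0)
    v1, v2 = emb._counts(s1), emb._counts(s2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    return float(v1 @ v2 / (n1 * n2))


def profile_similarity(p1, p2) -> float:
    """Jaccard index of two binary profiles; undefined for two all-zero
    profiles (raises — such pairs are excluded upstream)."""
    p1 = np.asarray(p1).astype(bool)
    p2 = np.asarray(p2).astype(bool)
    if p1.shape != p2.shape:
        raise ValueError("profile length mismatch")
    union = (p1 | p2).sum()
    if union == 0:
        raise ValueError("profile similarity undefined for two all-zero profiles")
    return float((p1 & p2).sum() / union)


def profile_cosine(p1, p2) -> float:
    """Cosine similarity for continuous (or binary) profile vectors."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 == 0 or n2 == 0:
        return 0.0
    return float(p1 @ p2 / (n1 * n2))


SEQ_METRICS = {"identity": sequence_similarity, "kmer_cosine": kmer_cosine_similarity}
PROFILE_METRICS = {"jaccard": profile_similarity, "cosine": profile_cosine}


# --- sample pairs and partition --------------------------------------------

@dataclass(frozen=True)
class SamplePair:
    i: int
    j: int
    seq_sim: float
    prof_sim: float
    freq: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a pair must join two distinct windows")
        if self.freq < 0:
            raise ValueError("interaction frequency must be nonnegative")


@dataclass
class PartitionResult:
    """Disjoint, exhaustive split of nonzero-frequency pairs by the signed
    difference of sequence- and profile-similarity percentile ranks."""

    over: list[SamplePair]
    consistent: list[SamplePair]
    under: list[SamplePair]
    margin: float

    def cells(self) -> dict[str, list[SamplePair]]:
        return {"over": self.over, "consistent": self.consistent, "under": self.under}


def percentile_partition(pairs: list[SamplePair], margin: float = 10.0) -> PartitionResult:
    """Partition pairs by percentile disparity.

    Percentile ranks (average rank for ties, scaled to 0-100) are computed
    within the given pair set.  A pair is "over" when its sequence
    percentile exceeds its profile percentile by more than ``margin``
    points, "under" when it lags by more than ``margin``, else "consistent".
    """
    if not (0 < margin < 100):
        raise ValueError(f"margin must lie in (0, 100), got {margin}")
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to partition")
    if any(p.freq <= 0 for p in pairs):
        raise ValueError("partition expects pairs with positive frequency only")
    n = len(pairs)
    seq_pct = rankdata([p.seq_sim for p in pairs]) / n * 100.0
    prof_pct = rankdata([p.prof_sim for p in pairs]) / n * 100.0
    out = PartitionResult([], [], [], margin)
    for p, d in zip(pairs, seq_pct - prof_pct):
        if d > margin:
            out.over.append(p)
        elif d < -margin:
            out.under.append(p)
        else:
            out.consistent.append(p)
    return out


# --- one-sided Wilcoxon rank-sum test ---------------------------------------

def rank_sum_one_sided(x, y, alternative: str) -> float:
    """One-sided Wilcoxon rank-sum p-value for the location of x vs y.

    ``alternative='greater'`` tests whether x tends to exceed y (small p
    rejects "x not greater").  Exact by enumeration over all equally likely
    rank assignments when the combined size is <= 12 (mid-ranks for ties);
    otherwise a normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    if alternative not in ("less", "greater"):
        raise ValueError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, nx = pooled.size, x.size
    w_obs = ranks[:nx].sum()
    if n <= EXACT_LIMIT:
        total = comb(n, nx)
        count = 0
        for subset in combinations(range(n), nx):
            w = ranks[list(subset)].sum()
            if alternative == "greater":
                count += w >= w_obs - 1e-9
            else:
                count += w <= w_obs + 1e-9
        return count / total
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = nx * (n - nx) / 12.0 * ((n + 1) - tie_term)
    sd = np.sqrt(var)
    if sd == 0:
        return 1.0
    if alternative == "greater":
        return float(norm.sf((w_obs - mean - 0.5) / sd))
    return float(norm.cdf((w_obs - mean + 0.5) / sd))


# --- the disparity test -----------------------------------------------------

@dataclass
class TestReport:
    """Per-repeat one-sided p-values and the frequency of p < .05.

    ``under_p[r]`` tests whether "under" pairs' frequencies exceed
    "consistent" pairs'; ``over_p[r]`` whether "over" pairs' lag them.
    A repeat with an empty cell records NaN for that comparison.
    """

    under_p: list[float]
    over_p: list[float]
    frac: float
    repeats: int
    margin: float
    seed: int
    cell_sizes: list[dict[str, int]] = field(default_factory=list)

    def significance_frequency(self, which: str, alpha: float = 0.05) -> float:
        ps = np.asarray(self.under_p if which == "under" else self.over_p)
        ps = ps[~np.isnan(ps)]
        if ps.size == 0:
            return float("nan")
        return float((ps < alpha).mean())


def _pairs_from_sample(idx, sequences, profiles, bins, matrix, seq_metric, prof_metric):
    pairs = []
    freq = matrix.values
    for a, b in combinations(idx, 2):
        f = float(freq[bins[a], bins[b]])
        if f <= 0:
            continue
        pa, pb = profiles[a], profiles[b]
        if prof_metric is profile_similarity and not (np.any(pa) or np.any(pb)):
            continue  # similarity undefined for two empty profiles
        pairs.append(
            SamplePair(
                i=int(a), j=int(b),
                seq_sim=seq_metric(sequences[a], sequences[b]),
                prof_sim=prof_metric(pa, pb),
                freq=f,
            )
        )
    return pairs


def run_disparity_test(sequences, profiles, bins, matrix: InteractionMatrix,
                       frac: float = 0.02, repeats: int = 3, margin: float = 10.0,
                       seed: int = 0, seq_metric: str = "identity",
                       profile_metric: str = "jaccard") -> TestReport:
    """Run the disparity hypothesis test.

    Per repeat: draw ``floor(frac * N)`` windows without replacement, form
    all pairs, drop zero-frequency and undefined-profile pairs, partition
    by percentile disparity, then compare interaction frequencies with
    one-sided rank-sum tests — "under" vs "consistent" (alternative
    ``greater``) and "over" vs "consistent" (alternative ``less``).

    Parameters are aligned arrays: window sequences, binary profiles
    (N x E), and each window's global Hi-C bin index.
    """
    sequences = list(sequences)
    profiles = np.asarray(profiles)
    bins = np.asarray(bins, dtype=np.intp)
    n = len(sequences)
    m = int(frac * n)
    if m < 2:
        raise ValueError(
            f"frac={frac} draws only {m} of {n} windows; increase frac (need >= 2)"
        )
    seq_fn = SEQ_METRICS[seq_metric]
    prof_fn = PROFILE_METRICS[profile_metric]
    rng = np.random.default_rng(seed)
    under_p: list[float] = []
    over_p: list[float] = []
    cell_sizes = []
    for _ in range(repeats):
        idx = rng.choice(n, size=m, replace=False)
        pairs = _pairs_from_sample(idx, sequences, profiles, bins, matrix, seq_fn, prof_fn)
        if len(pairs) < 2:
            under_p.append(float("nan"))
            over_p.append(float("nan"))
            cell_sizes.append({"over": 0, "consistent": 0, "under": 0})
            continue
        part = percentile_partition(pairs, margin=margin)
        cell_sizes.append({k: len(v) for k, v in part.cells().items()})
        cons = [p.freq for p in part.consistent]
        und = [p.freq for p in part.under]
        ovr = [p.freq for p in part.over]
        under_p.append(
            rank_sum_one_sided(und, cons, "greater") if und and cons else float("nan")
        )
        over_p.append(
            rank_sum_one_sided(ovr, cons, "less") if ovr and cons else float("nan")
        )
    return TestReport(under_p=under_p, over_p=over_p, frac=frac, repeats=repeats,
                      margin=margin, seed=seed, cell_sizes=cell_sizes)


def label_similarity_spearman(true_profiles, predicted_probs, n_pairs: int,
                              seed: int = 0, sequences=None,
                              margin: float = 10.0) -> dict[str, float]:
    """Spearman rho between true and predicted label similarities.

    For randomly sampled window pairs, the true similarity is the Jaccard
    index of the binary profiles and the predicted similarity the cosine of
    the probability vectors.  When window ``sequences`` are supplied, pairs
    are partitioned by sequence-vs-profile percentile disparity and a rho
    is reported per cell ("over"/"consistent"/"under"); otherwise a single
    "all" cell is reported.  A cell with a constant similarity vector
    reports NaN.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    true_profiles = np.asarray(true_profiles)
    predicted_probs = np.asarray(predicted_probs)
    n = true_profiles.shape[0]
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, n, size=n_pairs)
    jj = rng.integers(0, n - 1, size=n_pairs)
    jj = np.where(jj >= ii, jj + 1, jj)  # distinct partner
    # thresholded (binary) predictions use the same Jaccard metric as the
    # true profiles, so perfect predictions give rho = 1; continuous
    # probability vectors use cosine similarity
    binary_preds = np.isin(predicted_probs, (0.0, 1.0)).all()

    def pred_sim_fn(a, b):
        if binary_preds:
            pa, pb = predicted_probs[a], predicted_probs[b]
            if not (np.any(pa) or np.any(pb)):
                return 1.0  # identical empty predictions
            return profile_similarity(pa, pb)
        return profile_cosine(predicted_probs[a], predicted_probs[b])

    true_sim, pred_sim, seq_sim = [], [], []
    for a, b in zip(ii, jj):
        if not (np.any(true_profiles[a]) or np.any(true_profiles[b])):
            continue
        true_sim.append(profile_similarity(true_profiles[a], true_profiles[b]))
        pred_sim.append(pred_sim_fn(a, b))
        if sequences is not None:
            seq_sim.append(sequence_similarity(sequences[a], sequences[b]))
    true_sim = np.asarray(true_sim)
    pred_sim = np.asarray(pred_sim)
    if sequences is None:
        return {"all": _safe_spearman(true_sim, pred_sim)}
    k = true_sim.size
    seq_pct = rankdata(seq_sim) / k * 100.0
    prof_pct = rankdata(true_sim) / k * 100.0
    d = seq_pct - prof_pct
    out = {}
    for name, mask in (("over", d > margin),
                       ("consistent", (d >= -margin) & (d <= margin)),
                       ("under", d < -margin)):
        out[name] = _safe_spearman(true_sim[mask], pred_sim[mask])
    return out


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = spearmanr(a, b).statistic
    return float(rho)
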