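"""Polarity-invariant microstate clustering.

Stage 1 (individual level): topographies at GFP peaks are clustered with a
polarity-invariant modified k-means over a range of k, repeatedly on random
subsamples ("epochs"); a meta-criterion aggregating six cluster-validity
indices picks each epoch's optimal k.  Stage 2 (group level): the per-epoch
optimal maps from all subjects are pooled and clustered the same way, with
the meta-criterion used as guidance (an explicit override is available).

Polarity is ignored throughout: topographies ``u`` and ``-u`` are the same
state, so similarity is the squared spatial (Pearson) correlation and the
dissimilarity used by the validity criteria is ``d = sqrt(1 - corr^2)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .recording import Recording

CRITERION_NAMES = (
    "hubert_gamma",
    "silhouette",
    "davies_bouldin",
    "point_biserial",
    "dunn",
    "krzanowski_lai",
)


# ---------------------------------------------------------------------------
# Topography utilities
# ---------------------------------------------------------------------------

def normalize_topographies(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows. Rows with zero variance become zero rows."""
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def orient_maps(maps: np.ndarray) -> np.ndarray:
    """Sign convention: largest-|value| channel of each map is positive."""
    maps = np.array(maps, dtype=float)
    for row in maps:
        i = int(np.argmax(np.abs(row)))
        if row[i] < 0:
            row *= -1.0
    return maps


def spatial_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of A and rows of B."""
    An = normalize_topographies(np.atleast_2d(A))
    Bn = normalize_topographies(np.atleast_2d(B))
    return An @ Bn.T


@dataclass
class TopographySet:
    """K microstate maps: zero-mean, unit-norm, sign-normalized channel rows."""

    maps: np.ndarray  # (K, n_channels)
    labels_meta: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if maps.shape[0] < 1:
            raise ValueError("need at least one map")
        maps = orient_maps(normalize_topographies(maps))
        self.maps = maps
        if not self.labels_meta:
            self.labels_meta = tuple(str(k + 1) for k in range(maps.shape[0]))

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


# ---------------------------------------------------------------------------
# GFP and peak extraction
# ---------------------------------------------------------------------------

def gfp(rec: Recording) -> np.ndarray:
    """Global field power: per-sample population SD across channels."""
    return rec.data.std(axis=0, ddof=0)


def extract_gfp_peaks(
    rec: Recording, min_separation_ms: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local GFP maxima and their topographies.

    A sample t (0 < t < T-1) is a peak when GFP(t-1) < GFP(t) >= GFP(t+1),
    so the first sample of a plateau wins and endpoints are never peaks.
    With ``min_separation_ms`` > 0, peaks are greedily thinned highest-GFP
    first until all survivors are at least that far apart.

    Returns ``(indices, topographies)`` with topographies (n_peaks, n_channels).
    """
    g = gfp(rec)
    if len(g) < 3:
        return np.array([], dtype=int), np.empty((0, rec.n_channels))
    peaks = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:])) + 1
    if min_separation_ms > 0 and len(peaks) > 1:
        min_sep = min_separation_ms * rec.srate / 1000.0
        order = peaks[np.argsort(g[peaks], kind="stable")[::-1]]
        kept: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_sep for q in kept):
                kept.append(int(p))
        peaks = np.array(sorted(kept), dtype=int)
    return peaks, rec.data[:, peaks].T


# ---------------------------------------------------------------------------
# Modified k-means (polarity invariant)
# ---------------------------------------------------------------------------

def _principal_map(X: np.ndarray, v0: np.ndarray) -> np.ndarray:
    """Leading eigenvector of X^T X by power iteration started at v0.

    Warm-starting at the current map makes convergence fast inside the
    k-means loop; eigenvectors are sign-arbitrary so progress is measured
    up to sign.
    """
    v = v0 / math.sqrt(v0 @ v0)
    for _ in range(40):
        w = X.T @ (X @ v)
        nw = math.sqrt(w @ w)
        if nw == 0:
            return v
        w /= nw
        align = abs(w @ v)
        v = w
        if 1.0 - align < 1e-12:
            break
    v = v - v.mean()
    n = math.sqrt(v @ v)
    return v / n if n > 0 else v


def _gev(corr_win: np.ndarray, weights: np.ndarray) -> float:
    """Global explained variance given per-sample |corr| and GFP weights."""
    denom = float(np.sum(weights**2))
    if denom == 0:
        return 0.0
    return float(np.sum((weights * corr_win) ** 2) / denom)


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-invariant modified k-means for EEG topographies.

    Each sample (a scalp topography) is assigned to the map with the largest
    squared spatial correlation, and each map is updated to the principal
    eigenvector of the outer-product sum of its assigned samples — the
    classical microstate clustering of quasi-stable scalp fields where
    ``u`` and ``-u`` represent the same state.

    Parameters
    ----------
    n_clusters : number of maps k.
    n_repeats : independent random restarts; the best run by GEV is kept.
    max_iter, tol : per-run iteration cap and relative-GEV stopping rule.
    random_state : int seed or numpy Generator.

    Attributes
    ----------
    maps_ : (k, n_channels) fitted maps, zero-mean unit-norm, sign-normalized.
    labels_ : (n_samples,) 0-based cluster assignment of the training samples.
    gev_ : global explained variance of the training samples (GFP-weighted).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_repeats: int = 50,
        max_iter: int = 200,
        tol: float = 1e-7,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.n_repeats = n_repeats
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- core single run ----------------------------------------------------
    def _run_once(self, Xn, weights, rng):
        m, n_ch = Xn.shape
        k = self.n_clusters
        idx = rng.choice(m, size=k, replace=False)
        maps = Xn[idx].copy()
        prev_gev = -np.inf
        assign = np.zeros(m, dtype=int)
        for _ in range(self.max_iter):
            corr = maps @ Xn.T  # (k, m); rows unit-norm & zero-mean
            assign = np.argmax(corr**2, axis=0)
            best = np.abs(corr[assign, np.arange(m)])
            # re-seed empty clusters from the worst-fitted sample
            for c in range(k):
                if not np.any(assign == c):
                    worst = int(np.argmin(best))
                    maps[c] = Xn[worst]
                    assign[worst] = c
                    best[worst] = 1.0
            for c in range(k):
                members = Xn[assign == c]
                maps[c] = _principal_map(members, maps[c])
            corr = maps @ Xn.T
            assign = np.argmax(corr**2, axis=0)
            best = np.abs(corr[assign, np.arange(m)])
            cur_gev = _gev(best, weights)
            if prev_gev > -np.inf and abs(cur_gev - prev_gev) <= self.tol * max(
                prev_gev, 1e-300
            ):
                prev_gev = cur_gev
                break
            prev_gev = cur_gev
        return maps, assign, prev_gev

    def fit(self, X, y=None, sample_weight=None):
        """Cluster topographies.

        X is (n_samples, n_channels); ``sample_weight`` defaults to each
        sample's GFP (used only in the GEV objective, not the assignment).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_channels)")
        m = X.shape[0]
        if m < self.n_clusters:
            raise ValueError(f"{m} samples < n_clusters={self.n_clusters}")
        Xn = normalize_topographies(X)
        if sample_weight is None:
            sample_weight = (X - X.mean(axis=1, keepdims=True)).std(axis=1, ddof=0)
        weights = np.asarray(sample_weight, dtype=float)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        best = None
        for _ in range(self.n_repeats):
            maps, assign, gev_val = self._run_once(Xn, weights, rng)
            if best is None or gev_val > best[2]:
                best = (maps, assign, gev_val)
        maps, assign, gev_val = best
        self.maps_ = orient_maps(maps)
        self.labels_ = assign
        self.gev_ = gev_val
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Assign topographies to the fitted maps (polarity ignored)."""
        Xn = normalize_topographies(np.asarray(X, dtype=float))
        corr = self.maps_ @ Xn.T
        return np.argmax(corr**2, axis=0)

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_


def modified_kmeans(
    samples: np.ndarray,
    k: int,
    n_repeats: int = 50,
    max_iter: int = 200,
    tol: float = 1e-7,
    seed=None,
    sample_weight=None,
) -> tuple[TopographySet, np.ndarray, float]:
    """Functional wrapper around :class:`ModifiedKMeans`.

    Returns ``(TopographySet, assignment, gev)``.
    """
    est = ModifiedKMeans(
        n_clusters=k, n_repeats=n_repeats, max_iter=max_iter, tol=tol,
        random_state=seed,
    ).fit(samples, sample_weight=sample_weight)
    return (
        TopographySet(maps=est.maps_, provenance={"k": k}),
        est.labels_,
        est.gev_,
    )


# ---------------------------------------------------------------------------
# Cluster validity criteria and meta-criterion
# ---------------------------------------------------------------------------

def _dissimilarity_matrix(Xn: np.ndarray) -> np.ndarray:
    corr = np.clip(Xn @ Xn.T, -1.0, 1.0)
    d = np.sqrt(np.maximum(0.0, 1.0 - corr**2))
    np.fill_diagonal(d, 0.0)
    return d


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of (sum of within-cluster squared d) / (2 m_c)."""
    w = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        sub = D[np.ix_(members, members)]
        w += float(np.sum(sub**2)) / (2.0 * len(members))
    return w


def cluster_validity_criteria(
    samples: np.ndarray,
    assignment: np.ndarray,
    maps: np.ndarray,
    within_dispersions: dict[int, float] | None = None,
) -> dict[str, float]:
    """Six cluster-validity criteria on the polarity-invariant dissimilarity.

    All values are oriented so larger = better (Davies-Bouldin is negated).
    Krzanowski-Lai compares within-cluster dispersion at k-1, k, k+1; when
    ``within_dispersions`` (a dict k -> W_k covering those) is not supplied
    it is reported as NaN.  Singleton or degenerate clusters yield NaN for
    the affected criterion.
    """
    Xn = normalize_topographies(np.asarray(samples, dtype=float))
    D = _dissimilarity_matrix(Xn)
    maps_arr = normalize_topographies(np.atleast_2d(np.asarray(maps, dtype=float)))
    corr_sm = np.clip(maps_arr @ Xn.T, -1, 1)
    maps_d = np.sqrt(np.maximum(0.0, 1.0 - corr_sm**2))
    return _validity(D, np.asarray(assignment), maps_arr, maps_d,
                     Xn.shape[1], within_dispersions)


def _validity(D, labels, maps_arr, maps_d, n_channels, within_dispersions=None):
    m = D.shape[0]
    ks = np.unique(labels)
    k = len(ks)
    out = dict.fromkeys(CRITERION_NAMES, np.nan)
    if k < 2 or m < 3:
        return out
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(m, 1)
    d_flat = D[iu]
    between = ~same[iu]
    n_b = int(between.sum())
    n_w = int(len(d_flat) - n_b)
    if n_b and n_w and d_flat.std() > 0:
        out["hubert_gamma"] = float(
            np.corrcoef(d_flat, between.astype(float))[0, 1]
        )
        mb = d_flat[between].mean()
        mw = d_flat[~between].mean()
        out["point_biserial"] = float(
            (mb - mw) * math.sqrt(n_w * n_b) / (len(d_flat) * d_flat.std())
        )
        try:
            out["silhouette"] = float(
                silhouette_score(D, labels, metric="precomputed")
            )
        except ValueError:
            pass
        max_diam = max(float(D[np.ix_(labels == c, labels == c)].max()) for c in ks)
        min_between = float(d_flat[between].min())
        if max_diam > 0:
            out["dunn"] = min_between / max_diam
    # Davies-Bouldin (negated): scatter = mean member-to-map dissimilarity,
    # separation = dissimilarity between the two maps.
    if maps_d.shape[0] >= 2:
        corr_mm = np.clip(maps_arr @ maps_arr.T, -1, 1)
        sep = np.sqrt(np.maximum(0.0, 1.0 - corr_mm**2))
        scatter = np.array(
            [
                maps_d[c, labels == c].mean() if np.any(labels == c) else 0.0
                for c in range(maps_d.shape[0])
            ]
        )
        ratios = []
        for i in range(maps_d.shape[0]):
            vals = [
                (scatter[i] + scatter[j]) / sep[i, j]
                for j in range(maps_d.shape[0])
                if j != i and sep[i, j] > 0
            ]
            ratios.append(max(vals) if vals else np.inf)
        db = float(np.mean(ratios))
        out["davies_bouldin"] = -db if np.isfinite(db) else np.nan
    # Krzanowski-Lai from the within-dispersion curve.
    if within_dispersions is not None:
        p = max(n_channels - 1, 1)  # zero-mean constraint removes one dof
        kk = maps_d.shape[0]
        need = (kk - 1, kk, kk + 1)
        if all(j in within_dispersions for j in need) and kk >= 2:
            def diff(j):
                return (j - 1) ** (2.0 / p) * within_dispersions[j - 1] - j ** (
                    2.0 / p
                ) * within_dispersions[j]

            denom = diff(kk + 1)
            if denom != 0:
                out["krzanowski_lai"] = float(abs(diff(kk)) / abs(denom))
    return out


def meta_criterion(
    curves: dict[str, Sequence[float]], ks: Sequence[int]
) -> tuple[int, np.ndarray, bool]:
    """Aggregate validity curves into a model-order choice.

    Each criterion curve (indexed like ``ks``) is min-max rescaled to [0, 1]
    over the k-range (flat or all-NaN curves are dropped); the aggregate is
    the per-k median of the rescaled curves, with k = 1 forced to 0 so a
    single-cluster solution can never win.  Returns ``(chosen_k, aggregate,
    degenerate_flag)``; ties and fully flat aggregates resolve to the
    smallest k.
    """
    ks = np.asarray(list(ks))
    rescaled = []
    for name, vals in curves.items():
        v = np.asarray(vals, dtype=float)
        if len(v) != len(ks):
            raise ValueError(f"curve '{name}' length mismatch")
        finite = np.isfinite(v)
        if finite.sum() < 2:
            continue
        lo, hi = np.nanmin(v[finite]), np.nanmax(v[finite])
        if hi - lo <= 0:
            # a flat curve votes neutrally at every k rather than being
            # dropped, so it dilutes (never amplifies) any single peaked curve
            r = np.where(np.isfinite(v), 0.5, np.nan)
        else:
            r = (v - lo) / (hi - lo)
        rescaled.append(r)
    if not rescaled:
        return int(ks.min()), np.zeros(len(ks)), True
    R = np.vstack(rescaled)
    aggregate = np.zeros(len(ks))
    has_value = np.any(np.isfinite(R), axis=0)
    if np.any(has_value):
        aggregate[has_value] = np.nanmedian(R[:, has_value], axis=0)
    aggregate = np.where(np.isfinite(aggregate), aggregate, 0.0)
    aggregate[ks == 1] = 0.0
    best = float(np.max(aggregate))
    degenerate = bool(np.allclose(aggregate, aggregate[0]))
    # ties (and the degenerate all-equal case) go to the smallest k
    chosen = int(ks[np.flatnonzero(aggregate >= best - 1e-12)[0]])
    return chosen, aggregate, degenerate


# ---------------------------------------------------------------------------
# Resampled clustering (epochs of random subsamples)
# ---------------------------------------------------------------------------


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

def subsample_size(M: int, n_epochs: int, coverage_target: float) -> int:
    """Per-epoch subsample size so P(any sample drawn at least once
    across ``n_epochs`` epochs) = ``coverage_target``.

    m = ceil(M * (1 - (1 - coverage)^(1/E))).
    """
    frac = 1.0 - (1.0 - coverage_target) ** (1.0 / n_epochs)
    return int(math.ceil(M * frac))


@dataclass
class EpochResult:
    """One resampling epoch: its optimal maps and the per-k diagnostics."""

    maps: TopographySet
    chosen_k: int
    gev_by_k: dict[int, float]
    criteria: dict[int, dict[str, float]]
    meta_curve: np.ndarray
    sample_indices: np.ndarray


def resampled_clustering(
    samples: np.ndarray,
    k_range: Sequence[int] = range(1, 13),
    n_epochs: int = 50,
    coverage_target: float = 0.999,
    n_repeats: int = 50,
    seed=None,
    sample_weight=None,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> list[EpochResult]:
    """Cluster random subsamples ("epochs") over a k-range.

    Each epoch draws ``m = subsample_size(M, n_epochs, coverage_target)``
    samples without replacement, clusters them at every k in ``k_range``,
    and picks the epoch's optimal k with the meta-criterion.  Per-epoch
    seeds are spawned from ``seed`` via numpy SeedSequence, so results are
    reproducible and epochs independent.
    """
    X = np.asarray(samples, dtype=float)
    M = X.shape[0]
    ks = sorted(int(k) for k in k_range)
    m = subsample_size(M, n_epochs, coverage_target)
    m = min(m, M)
    if m < max(ks):
        raise ValueError(
            f"epoch subsample size {m} < max k {max(ks)}; "
            "reduce k_range or raise coverage"
        )
    if sample_weight is None:
        sample_weight = (X - X.mean(axis=1, keepdims=True)).std(axis=1, ddof=0)
    weights = np.asarray(sample_weight, dtype=float)
    ss = _as_seedseq(seed)
    children = ss.spawn(n_epochs)
    results: list[EpochResult] = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(M, size=m, replace=False)
        sub, wsub = X[idx], weights[idx]
        Xn = normalize_topographies(sub)
        D = _dissimilarity_matrix(Xn)
        per_k_maps: dict[int, TopographySet] = {}
        gev_by_k: dict[int, float] = {}
        assign_by_k: dict[int, np.ndarray] = {}
        wdisp: dict[int, float] = {}
        for k in range(min(ks), max(ks) + 2):  # +1 for Krzanowski-Lai
            if k > m:
                continue
            est = ModifiedKMeans(
                n_clusters=k, n_repeats=n_repeats, max_iter=max_iter, tol=tol,
                random_state=rng,
            ).fit(sub, sample_weight=wsub)
            if k in ks:
                per_k_maps[k] = TopographySet(
                    maps=est.maps_, provenance={"k": k, "level": "epoch"}
                )
                gev_by_k[k] = est.gev_
                assign_by_k[k] = est.labels_
            wdisp[k] = _within_dispersion(D, est.labels_)
        # Krzanowski-Lai at k=2 needs the one-cluster dispersion
        wdisp.setdefault(1, _within_dispersion(D, np.zeros(m, dtype=int)))
        criteria: dict[int, dict[str, float]] = {}
        for k in ks:
            if k == 1 or k not in per_k_maps:
                criteria[k] = dict.fromkeys(CRITERION_NAMES, np.nan)
                continue
            maps_arr = per_k_maps[k].maps
            corr_sm = np.clip(maps_arr @ Xn.T, -1, 1)
            maps_d = np.sqrt(np.maximum(0.0, 1.0 - corr_sm**2))
            criteria[k] = _validity(
                D, assign_by_k[k], maps_arr, maps_d, X.shape[1], wdisp
            )
        curves = {
            name: [criteria[k][name] for k in ks] for name in CRITERION_NAMES
        }
        chosen_k, agg, _ = meta_criterion(curves, ks)
        results.append(
            EpochResult(
                maps=per_k_maps[chosen_k],
                chosen_k=chosen_k,
                gev_by_k=gev_by_k,
                criteria=criteria,
                meta_curve=agg,
                sample_indices=idx,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Individual + group level drivers
# ---------------------------------------------------------------------------

def individual_clustering(
    rec: Recording,
    k_range: Sequence[int] = range(1, 13),
    n_epochs: int = 50,
    coverage_target: float = 0.999,
    n_repeats: int = 50,
    seed=None,
    min_separation_ms: float = 0.0,
    max_peaks: int | None = None,
) -> list[EpochResult]:
    """Stage 1 for one subject: GFP-peak extraction + resampled clustering.

    ``max_peaks`` randomly thins the extracted peak set (a cost control for
    large recordings); thinning uses a seed spawned from ``seed``.
    """
    ss = _as_seedseq(seed)
    s_thin, s_cluster = ss.spawn(2)
    idx, topos = extract_gfp_peaks(rec, min_separation_ms)
    if len(idx) == 0:
        raise ValueError("no GFP peaks found")
    peak_gfp = gfp(rec)[idx]
    if max_peaks is not None and len(idx) > max_peaks:
        keep = np.sort(
            np.random.default_rng(s_thin).choice(len(idx), max_peaks, replace=False)
        )
        topos, peak_gfp = topos[keep], peak_gfp[keep]
    return resampled_clustering(
        topos,
        k_range=k_range,
        n_epochs=n_epochs,
        coverage_target=coverage_target,
        n_repeats=n_repeats,
        seed=s_cluster,
        sample_weight=peak_gfp,
    )


@dataclass
class ClusteringResult:
    """Outcome of the final (group-level) clustering pass."""

    maps_by_k: dict[int, TopographySet]
    gev_by_k: dict[int, float]
    criteria: dict[int, dict[str, float]]
    meta_curve: np.ndarray
    k_range: tuple[int, ...]
    chosen_k: int
    forced: bool = False
    degenerate: bool = False

    @property
    def maps(self) -> TopographySet:
        return self.maps_by_k[self.chosen_k]


def group_level_clustering(
    individual_results: Sequence[Sequence[EpochResult]],
    k_range: Sequence[int] = range(1, 16),
    n_epochs: int = 100,
    coverage_target: float = 0.999,
    n_repeats: int = 100,
    seed=None,
    force_k: int | None = None,
) -> ClusteringResult:
    """Stage 2: pool per-epoch optimal maps across subjects and re-cluster.

    The pooled maps are clustered with the same resampled scheme; the
    per-epoch optima are pooled once more and submitted to a final
    modified-k-means pass over ``k_range``.  Model order: ``chosen_k``
    defaults to the resampling consensus — the median of the group epochs'
    meta-criterion optima (ties to the smaller k) — which is far more
    stable than re-running the validity criteria on the small pool of
    near-duplicate epoch maps; the final pass's own meta-criterion curve is
    still returned as guidance, and ``force_k`` overrides everything
    (researcher judgment at the group level).
    """
    pooled = np.vstack(
        [ep.maps.maps for subj in individual_results for ep in subj]
    )
    ks = sorted(int(k) for k in k_range)
    epochs = resampled_clustering(
        pooled,
        k_range=ks,
        n_epochs=n_epochs,
        coverage_target=coverage_target,
        n_repeats=n_repeats,
        seed=_as_seedseq(seed).spawn(2)[0],
        sample_weight=np.ones(pooled.shape[0]),
    )
    final_pool = np.vstack([ep.maps.maps for ep in epochs])
    epoch_ks = sorted(ep.chosen_k for ep in epochs)
    # median with ties broken toward the smaller k (lower of the two
    # middle values for even counts)
    consensus_k = int(epoch_ks[(len(epoch_ks) - 1) // 2])
    result = _final_pass(
        final_pool, ks, n_repeats,
        _as_seedseq(seed).spawn(2)[1], force_k,
    )
    if force_k is None:
        result.chosen_k = consensus_k if consensus_k in result.maps_by_k else result.chosen_k
    return result


def _final_pass(samples, ks, n_repeats, seed, force_k):
    X = np.asarray(samples, dtype=float)
    m = X.shape[0]
    weights = np.ones(m)
    Xn = normalize_topographies(X)
    D = _dissimilarity_matrix(Xn)
    rng = np.random.default_rng(seed)
    maps_by_k, gev_by_k, criteria, wdisp, assign_by_k = {}, {}, {}, {}, {}
    for k in range(min(ks), max(ks) + 2):
        if k > m:
            continue
        est = ModifiedKMeans(
            n_clusters=k, n_repeats=n_repeats, random_state=rng
        ).fit(X, sample_weight=weights)
        wdisp[k] = _within_dispersion(D, est.labels_)
        if k in ks:
            maps_by_k[k] = TopographySet(
                maps=est.maps_, provenance={"k": k, "level": "group"}
            )
            gev_by_k[k] = est.gev_
            assign_by_k[k] = est.labels_
    wdisp.setdefault(1, _within_dispersion(D, np.zeros(m, dtype=int)))
    for k in ks:
        if k == 1 or k not in maps_by_k:
            criteria[k] = dict.fromkeys(CRITERION_NAMES, np.nan)
            continue
        maps_arr = maps_by_k[k].maps
        corr_sm = np.clip(maps_arr @ Xn.T, -1, 1)
        maps_d = np.sqrt(np.maximum(0.0, 1.0 - corr_sm**2))
        criteria[k] = _validity(D, assign_by_k[k], maps_arr, maps_d, X.shape[1], wdisp)
    curves = {name: [criteria[k][name] for k in ks] for name in CRITERION_NAMES}
    chosen, agg, degenerate = meta_criterion(curves, ks)
    forced = force_k is not None
    if forced:
        if force_k not in maps_by_k:
            raise ValueError(f"force_k={force_k} outside searched range")
        chosen = int(force_k)
    return ClusteringResult(
        maps_by_k=maps_by_k,
        gev_by_k=gev_by_k,
        criteria=criteria,
        meta_curve=agg,
        k_range=tuple(ks),
        chosen_k=chosen,
        forced=forced,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Map matching
# ---------------------------------------------------------------------------

def match_maps(
    set_a: TopographySet | np.ndarray, set_b: TopographySet | np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray, list[int]]:
    """Optimal one-to-one pairing of two map sets by total |spatial corr|.

    Exhaustive over permutations for min(K) <= 8, otherwise the Hungarian
    algorithm on ``-|corr|``.  Returns ``(pairs, abs_corr_per_pair,
    unmatched)`` where ``pairs`` are (index_in_a, index_in_b) and
    ``unmatched`` lists surplus indices of the larger set.
    """
    A = set_a.maps if isinstance(set_a, TopographySet) else np.atleast_2d(set_a)
    B = set_b.maps if isinstance(set_b, TopographySet) else np.atleast_2d(set_b)
    C = np.abs(spatial_correlation(A, B))  # (Ka, Kb)
    ka, kb = C.shape
    if min(ka, kb) <= 8 and max(ka, kb) <= 8:
        if ka <= kb:
            best = max(
                itertools.permutations(range(kb), ka),
                key=lambda p: sum(C[i, p[i]] for i in range(ka)),
            )
            pairs = [(i, best[i]) for i in range(ka)]
        else:
            best = max(
                itertools.permutations(range(ka), kb),
                key=lambda p: sum(C[p[j], j] for j in range(kb)),
            )
            pairs = [(best[j], j) for j in range(kb)]
    else:
        rows, cols = linear_sum_assignment(-C)
        pairs = list(zip(rows.tolist(), cols.tolist()))
    corr = np.array([C[i, j] for i, j in pairs])
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    if ka > kb:
        unmatched = sorted(set(range(ka)) - matched_a)
    else:
        unmatched = sorted(set(range(kb)) - matched_b)
    return pairs, corr, unmatched
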