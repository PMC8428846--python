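"""Statistical machinery: pose PCA, trajectory direction statistics, the
balanced hierarchical bootstrap, the probability sum rule, pulse-matched
latencies, Friedman/Dunn tests and regression fits.

The centerpiece is the balanced hierarchical bootstrap for nested
(mouse -> trial) designs: mice are resampled with replacement as many times
as there are mice, and from each sampled mouse a *fixed* number of trials is
drawn with replacement so every mouse contributes equally to the resampled
population. The statistic (median by default; mean for motion-energy
magnitudes) is computed per replicate and summarised as the mean of the
bootstrap distribution ± its SD (the bootstrap standard error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


# ---------------------------------------------------------------------------
# PCA of aligned pose features
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """Principal components of aligned pose features at one time point."""

    loadings: np.ndarray            # (k, n_features), rows orthonormal
    explained_variance: np.ndarray  # fractions, non-increasing
    mean: np.ndarray                # (n_features,)
    feature_names: tuple[str, ...] = ()
    fit_time_ms: float | None = None
    split_report: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.loadings.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def _pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return mean, _fix_signs(vt[:k]), frac[:k]


def fit_pose_pca(
    features: np.ndarray,
    k: int = 3,
    feature_names: tuple[str, ...] = (),
    fit_time_ms: float | None = None,
    split: float | None = None,
    split_seed: int | None = None,
) -> PCModel:
    """Mean-centered PCA of trials x features (rows with NaN are dropped).

    With ``split`` (e.g. 0.8) the trials are pseudo-randomly divided into
    training and test sets; the components are fit on the training set and
    the variance they explain in each set is reported in ``split_report``
    (cross-validation of the low-dimensional structure). The returned model
    is always fit on all complete rows.
    """
    X = np.asarray(features, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[0] < k:
        raise ValidationError(f"need at least {k} complete rows, have {X.shape[0]}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < k:
        import warnings

        warnings.warn(
            f"feature matrix has rank {rank} < k={k}; returning {rank} components",
            RuntimeWarning,
            stacklevel=2,
        )
        k = rank
    mean, comps, frac = _pca(X, k)
    report: dict = {}
    if split is not None:
        rng = np.random.default_rng(split_seed)
        idx = rng.permutation(X.shape[0])
        n_train = int(round(split * X.shape[0]))
        tr, te = X[idx[:n_train]], X[idx[n_train:]]
        mu_tr, comps_tr, frac_tr = _pca(tr, k)
        report["train_explained"] = frac_tr
        if te.shape[0] > 1:
            te_c = te - te.mean(axis=0)
            total = (te_c**2).sum()
            scores = te_c @ comps_tr.T
            report["test_explained"] = (scores**2).sum(axis=0) / total
    return PCModel(
        loadings=comps,
        explained_variance=frac,
        mean=mean,
        feature_names=tuple(feature_names),
        fit_time_ms=fit_time_ms,
        split_report=report,
    )


def project_trajectories(
    features: np.ndarray | list[np.ndarray],
    model: PCModel,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Project feature time courses onto a fitted PC model.

    ``features`` is ``(n_trials, n_frames, n_features)`` (or a list of
    per-trial ``(n_frames, n_features)`` arrays). Returns per-trial score
    trajectories (NaN rows skipped -> NaN scores) and the fraction of the
    pooled time-course variance captured by each component.
    """
    trials = [np.asarray(f, dtype=float) for f in features]
    scores = []
    pooled = []
    for F in trials:
        S = np.full((F.shape[0], model.k), np.nan)
        ok = np.isfinite(F).all(axis=1)
        S[ok] = (F[ok] - model.mean) @ model.loadings.T
        scores.append(S)
        pooled.append(F[ok])
    P = np.vstack(pooled) if pooled else np.empty((0, model.mean.size))
    if P.shape[0] > 1:
        Pc = P - P.mean(axis=0)
        total = (Pc**2).sum()
        per_pc = ((Pc @ model.loadings.T) ** 2).sum(axis=0) / total
    else:
        per_pc = np.zeros(model.k)
    return scores, per_pc


# ---------------------------------------------------------------------------
# Circular statistics of trajectory directions
# ---------------------------------------------------------------------------

def circular_sd_deg(angles_deg: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValidationError("no finite angles")
    rbar = float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))
    if rbar <= 0:
        return float("inf")
    rbar = min(rbar, 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def shuffle_parts(features: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute part identities ((x, y) pairs) independently per trial.

    ``features`` is ``(n_trials, n_frames, 2 * n_parts)``; the control
    destroys part identity while keeping each trial's coordinate set.
    """
    F = np.asarray(features, dtype=float)
    n_parts = F.shape[-1] // 2
    out = F.reshape(F.shape[0], F.shape[1], n_parts, 2).copy()
    for i in range(out.shape[0]):
        out[i] = out[i][:, rng.permutation(n_parts), :]
    return out.reshape(F.shape)


def trajectory_direction_stats(
    trajectories: list[np.ndarray],
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = (35.0, 115.0),
    shuffle: str = "none",
    seed: int | None = None,
    model: PCModel | None = None,
    features: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Direction statistics of PC1-PC2 trajectories.

    Each trial's direction is the angle of its (PC1, PC2) displacement from
    the start to the end of the window; returns (circular mean deg, circular
    SD deg, n_used). Trials with zero displacement or missing endpoint
    scores are excluded and counted out of ``n_used``.

    ``shuffle="parts"`` recomputes trajectories after permuting part
    identities within each trial (requires ``features`` and ``model``) — the
    non-directional control.
    """
    if shuffle not in ("none", "parts"):
        raise ValidationError(f"unknown shuffle mode {shuffle!r}")
    if shuffle == "parts":
        if features is None or model is None:
            raise ValidationError("shuffle='parts' needs features and model")
        rng = np.random.default_rng(seed)
        trajectories, _ = project_trajectories(shuffle_parts(features, rng), model)
    times = np.asarray(times_ms, dtype=float)
    i0 = int(np.argmin(np.abs(times - window_ms[0])))
    i1 = int(np.argmin(np.abs(times - window_ms[1])))
    angles = []
    for S in trajectories:
        d = S[i1, :2] - S[i0, :2]
        if not np.isfinite(d).all() or np.hypot(d[0], d[1]) == 0:
            continue
        angles.append(np.degrees(np.arctan2(d[1], d[0])))
    if len(angles) < 2:
        raise ValidationError("need at least 2 usable trials for direction stats")
    arr = np.asarray(angles)
    return circular_mean_deg(arr), circular_sd_deg(arr), len(angles)


# ---------------------------------------------------------------------------
# Balanced hierarchical bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapEstimate:
    """Mean bootstrap estimate of the statistic ± its standard error."""

    estimate: float
    se: float
    n_boot: int
    estimator: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be >= 0")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")


def hierarchical_bootstrap(
    values: dict[str, np.ndarray] | list[np.ndarray],
    estimator: str = "median",
    n_boot: int = 10_000,
    k: int | None = None,
    seed: int | None = None,
) -> BootstrapEstimate:
    """Balanced hierarchical bootstrap over mouse -> trial nesting.

    Each replicate samples M mice with replacement (M = number of mice) and,
    from each sampled mouse, ``k`` trials with replacement, with ``k`` the
    same for every mouse so each contributes equally (default: the rounded
    mean trials per mouse, keeping the resample close to the original size).
    The statistic (median or mean) is computed on the pooled M*k values per
    replicate; the returned estimate is the mean of the ``n_boot`` replicate
    statistics and ``se`` their SD.
    """
    groups = list(values.values()) if isinstance(values, dict) else list(values)
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    groups = [g for g in groups if g.size > 0]
    if not groups:
        raise ValidationError("need at least one mouse with at least one trial")
    if estimator not in ("median", "mean"):
        raise ValidationError(f"estimator must be median or mean, got {estimator!r}")
    M = len(groups)
    if k is None:
        k = int(round(np.mean([g.size for g in groups])))
        k = max(k, 1)
    rng = np.random.default_rng(seed)
    sizes = np.array([g.size for g in groups])
    # pad to a rectangular array for vectorized gathering
    maxn = sizes.max()
    mat = np.zeros((M, maxn))
    for i, g in enumerate(groups):
        mat[i, : g.size] = g
    mice = rng.integers(0, M, size=(n_boot, M))
    trial_idx = rng.random((n_boot, M, k))
    trial_idx = (trial_idx * sizes[mice][:, :, None]).astype(np.int64)
    samples = mat[mice[:, :, None], trial_idx].reshape(n_boot, M * k)
    stat = np.median(samples, axis=1) if estimator == "median" else samples.mean(axis=1)
    return BootstrapEstimate(
        estimate=float(stat.mean()),
        se=float(stat.std()),
        n_boot=n_boot,
        estimator=estimator,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Probability sum rule and pulse-matched latencies
# ---------------------------------------------------------------------------

def sum_rule(p: float, n: int) -> float:
    """P(at least one response in n independent pulses) = 1 - (1 - p)^n."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if n == 1:
        return float(p)  # exact: 1 - (1 - p) loses an ulp in floating point
    return 1.0 - (1.0 - p) ** n


def pulse_matched_latency(
    latency_ms: float, isi_ms: float, n_pulses: int
) -> tuple[int, float, float]:
    """Express a response latency relative to the most recent pulse.

    Returns ``(pulse_index, residual_ms, latency_over_isi)`` where
    ``pulse_index`` is the largest i with i*isi <= latency (capped at
    ``n_pulses - 1``) and ``residual_ms = latency - pulse_index * isi``.
    """
    if latency_ms < 0:
        raise ValidationError("latency must be >= 0")
    if isi_ms <= 0:
        raise ValidationError("isi must be > 0")
    index = min(int(latency_ms // isi_ms), n_pulses - 1)
    return index, latency_ms - index * isi_ms, latency_ms / isi_ms


# ---------------------------------------------------------------------------
# Friedman / Dunn and regression fits
# ---------------------------------------------------------------------------

@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    mean_ranks: np.ndarray
    pairwise: list[dict]


def friedman_dunn(
    table: np.ndarray, adjust: str | None = None
) -> FriedmanResult:
    """Friedman test (subjects x conditions) with Dunn's pairwise post-hoc.

    The tie-corrected Friedman chi-square is computed from within-subject
    ranks; an all-tied table returns statistic 0 and p 1. Dunn's comparisons
    use z = |R_i - R_j| / sqrt(k(k+1)/(6n)) on mean ranks, two-sided normal
    p-values; ``adjust`` may name a statsmodels multiple-testing method
    (e.g. ``"bonferroni"``), default none.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a complete subjects x conditions table (>=2 each)")
    if not np.isfinite(X).all():
        raise ValidationError("table has missing cells; drop incomplete subjects first")
    n, kcond = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    rank_sums = ranks.sum(axis=0)
    mean_ranks = rank_sums / n
    chi = (12.0 / (n * kcond * (kcond + 1))) * (rank_sums**2).sum() - 3 * n * (kcond + 1)
    # tie correction
    tie_term = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n * kcond * (kcond**2 - 1))
    if denom <= 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = chi / denom
        p = float(sps.chi2.sf(statistic, kcond - 1))
    se = np.sqrt(kcond * (kcond + 1) / (6.0 * n))
    pairwise = []
    pvals = []
    for i, j in combinations(range(kcond), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        pz = 2.0 * sps.norm.sf(z)
        pairwise.append({"i": i, "j": j, "z": float(z), "p": float(pz)})
        pvals.append(pz)
    if adjust is not None and pairwise:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method=adjust)
        for d, a in zip(pairwise, adj):
            d["p_adj"] = float(a)
    return FriedmanResult(
        statistic=float(statistic), df=kcond - 1, p_value=float(p),
        mean_ranks=mean_ranks, pairwise=pairwise,
    )


@dataclass
class FitResult:
    kind: str
    coefficients: dict[str, float]
    r_squared: float
    pearson_r: float | None = None

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValidationError("R^2 cannot exceed 1")


def regression_fits(x: np.ndarray, y: np.ndarray, kind: str = "linear") -> FitResult:
    """Least-squares fits: linear, log-log, or lognormal (y on log x).

    ``loglog`` regresses log y on log x (power law y = a x^b); ``lognormal``
    regresses y on log x — and, when all y are positive, also reports the
    log y on log x coefficients under ``log_*`` keys. R^2 is computed in the
    transformed space of the primary fit; Pearson r is reported for the
    linear kind.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("need at least 3 finite (x, y) pairs")

    def _check_positive(v: np.ndarray, name: str) -> None:
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise ValidationError(
                f"log transform needs positive {name}; offending indices {bad.tolist()}"
            )

    if kind == "linear":
        res = sps.linregress(x, y)
        return FitResult(
            kind=kind,
            coefficients={"slope": float(res.slope), "intercept": float(res.intercept)},
            r_squared=float(res.rvalue**2),
            pearson_r=float(res.rvalue),
        )
    if kind == "loglog":
        _check_positive(x, "x")
        _check_positive(y, "y")
        res = sps.linregress(np.log10(x), np.log10(y))
        return FitResult(
            kind=kind,
            coefficients={"slope": float(res.slope),
                          "log10_intercept": float(res.intercept)},
            r_squared=float(res.rvalue**2),
        )
    if kind == "lognormal":
        _check_positive(x, "x")
        res = sps.linregress(np.log10(x), y)
        coefs = {"slope": float(res.slope), "intercept": float(res.intercept)}
        if (y > 0).all():
            res2 = sps.linregress(np.log10(x), np.log10(y))
            coefs["log_slope"] = float(res2.slope)
            coefs["log_intercept"] = float(res2.intercept)
        return FitResult(kind=kind, coefficients=coefs, r_squared=float(res.rvalue**2))
    raise ValidationError(f"unknown fit kind {kind!r}")
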