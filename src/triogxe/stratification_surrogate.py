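"""Stratification surrogates for the trio G x E risk model.

The group indicator X_E that separates exposure distributions is latent; two
observable surrogates stand in for it:

* **SRA** — self-reported ancestry, encoded 0 for a reference group and 1
  for a comparison group (e.g. East Asian -> 0, European -> 1); trios in
  any other group are excluded from the SRA analysis.
* **EEGM** — the expected exposure given genetic markers: fitted
  probabilities from a logistic regression of the binary exposure on
  principal components of a marker panel, rescaled onto [0, 1] by
  subtracting the minimum and dividing by the range.

A diagnostic likelihood-ratio test of exposure on the PCs checks whether a
cohort (or a within-ancestry subset) carries any exposure-related structure
for EEGM to exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trio_data import MISSING, TrioDataset

logger = logging.getLogger(__name__)

_RIDGE_PENALTY = 1e-4
_SEPARATION_BOUND = 15.0
_DEGENERATE_RANGE = 1e-12


class SurrogateError(ValueError):
    """Raised on unusable input for surrogate construction."""


@dataclass
class PCMatrix:
    """Principal-component scores of a marker genotype matrix.

    Columns are ordered by decreasing explained variance and centered; the
    sign of each component is fixed so its largest-magnitude marker loading
    is positive, making the decomposition bit-reproducible.
    """

    scores: np.ndarray  # (n_trios, k)
    explained_var: np.ndarray  # (k,) proportions of total variance
    loadings: np.ndarray  # (n_markers_used, k)
    source: str = "child"

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class SurrogateAssignment:
    """One surrogate value per trio.

    SRA values are 0/1 with NaN for trios outside the two named groups
    (``excluded`` mask set); EEGM values span [0, 1] after rescaling unless
    the fit was degenerate.
    """

    values: np.ndarray
    method: str  # "sra" or "eegm"
    excluded: np.ndarray = None  # type: ignore[assignment]
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.excluded is None:
            self.excluded = np.isnan(self.values)
        self.excluded = np.asarray(self.excluded, dtype=bool)


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------


def prune_markers(
    genotypes: np.ndarray, window: int = 50, step: int = 5, r2_threshold: float = 0.2
) -> np.ndarray:
    """Greedy window-based LD pruning; returns indices of retained markers.

    Within each sliding window, a marker correlated at r^2 above the
    threshold with an already-retained marker in the window is dropped.
    Simulated panels are generated independent, so this matters only for
    real genotype input.
    """
    g = np.asarray(genotypes, dtype=float)
    m = g.shape[1]
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        if idx.size < 2:
            continue
        sub = g[:, idx]
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        corr = (sub / sd).T @ (sub / sd) / len(sub)
        r2 = corr**2
        for a in range(1, idx.size):
            if keep[idx[a]] and np.any(r2[a, :a][keep[idx[:a]]] > r2_threshold):
                keep[idx[a]] = False
    return np.flatnonzero(keep)


def compute_pcs(
    dataset_or_matrix,
    k: int | str = 10,
    member: str = "child",
    snp_ids=None,
    prune: bool = False,
) -> PCMatrix:
    """PCA of a frequency-standardized genotype matrix.

    Accepts either a :class:`TrioDataset` (using ``member``'s genotypes at
    ``snp_ids``, default all SNPs) or a plain (trios x markers) genotype
    matrix.  Each marker column is centered at twice its allele frequency
    and scaled by sqrt(2 p (1-p)); monomorphic markers are dropped.
    Missing genotypes are mean-imputed per marker before standardization.

    ``k="auto"`` retains only the axes of genuine population structure:
    components whose covariance eigenvalue exceeds the Marchenko-Pastur
    bulk edge ``(1 + sqrt(m/n))**2`` expected of a structureless
    standardized matrix (always at least one, at most 10).  Feeding noise
    axes into the downstream exposure regression only lets it overfit.
    """
    if isinstance(dataset_or_matrix, TrioDataset):
        ds = dataset_or_matrix
        if snp_ids is not None:
            ds = ds.subset_snps(snp_ids)
        g = ds.genotypes(member).astype(float)
    else:
        g = np.asarray(dataset_or_matrix, dtype=float)
    g = g.copy()
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(g))
    g[nan_rows, nan_cols] = col_mean[nan_cols]

    if prune:
        g = g[:, prune_markers(g)]
        col_mean = g.mean(axis=0)

    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise SurrogateError("no polymorphic markers")
    g = g[:, poly]
    p = p[poly]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    n, m = z.shape
    auto = k == "auto"
    if not auto:
        k = int(min(k, n, m))
        if k < 1:
            raise SurrogateError("k must be at least 1")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var <= 0:
        raise SurrogateError("no polymorphic markers")
    if auto:
        edge = (1.0 + np.sqrt(m / n)) ** 2
        k = int(np.clip(((s**2) / n > edge).sum(), 1, min(10, n, m)))
    # sign convention: largest-|loading| entry of each PC positive
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    return PCMatrix(
        scores=scores,
        explained_var=(s[:k] ** 2) / total_var,
        loadings=vt[:k].T,
        source=member if isinstance(dataset_or_matrix, TrioDataset) else "matrix",
    )


# ---------------------------------------------------------------------------
# Logistic regression of exposure on PCs
# ---------------------------------------------------------------------------


def _fit_logistic(y: np.ndarray, X: np.ndarray, X_predict: np.ndarray):
    """Logistic MLE with a small-ridge fallback on detected separation.

    Fits on (y, X); returns (probabilities predicted on X_predict, llf,
    llnull, separation_flag), log-likelihoods evaluated on the fitted rows.
    """
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _SEPARATION_BOUND:
            raise ValueError("coefficients diverged")
        pred = np.asarray(fit.predict(sm.add_constant(X_predict, has_constant="add")))
        return pred, float(fit.llf), float(fit.llnull), False
    except Exception:
        pass

    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / _RIDGE_PENALTY, max_iter=1000)
    clf.fit(X, y)
    prob = clf.predict_proba(X)[:, 1]
    eps = 1e-12
    llf = float(np.sum(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
    p0 = y.mean()
    llnull = float(len(y) * (p0 * np.log(p0 + eps) + (1 - p0) * np.log(1 - p0 + eps)))
    return clf.predict_proba(X_predict)[:, 1], llf, llnull, True


def rescale_unit(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Map values onto [0, 1] by (v - min) / range; order-preserving and
    idempotent on vectors already spanning [0, 1].  A degenerate range
    yields all zeros with a flag."""
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    rng = finite.max() - finite.min() if finite.size else 0.0
    if rng < _DEGENERATE_RANGE:
        return np.where(np.isnan(v), np.nan, 0.0), True
    return (v - finite.min()) / rng, False


def estimate_eegm(exposure: np.ndarray, pcs: PCMatrix) -> SurrogateAssignment:
    """Expected exposure given markers, rescaled to the unit interval.

    Fits logistic regression of the binary exposure on the PC columns
    (complete cases), predicts for every trio, then rescales fitted
    probabilities by subtracting the minimum and dividing by the range.
    Complete separation triggers a flagged bounded-ridge refit; a constant
    fit returns all zeros with a ``degenerate`` flag.
    """
    e = np.asarray(exposure, dtype=float)
    fit_mask = ~np.isnan(e)
    y = e[fit_mask]
    if y.size == 0 or y.min() == y.max():
        raise SurrogateError("need at least one exposed and one unexposed trio")
    if pcs.k < 1:
        raise SurrogateError("need at least one PC column")

    prob, _, _, separated = _fit_logistic(y, pcs.scores[fit_mask], pcs.scores)
    values, degenerate = rescale_unit(prob)
    flags = set()
    if separated:
        flags.add("separation")
    if degenerate:
        flags.add("degenerate")
    return SurrogateAssignment(
        values=values, method="eegm", excluded=np.isnan(values), flags=flags
    )


def encode_sra(
    labels, reference_group: str, comparison_group: str
) -> SurrogateAssignment:
    """Binary SRA surrogate: reference group -> 0, comparison group -> 1.

    Trios in any other group get NaN and are flagged excluded from the SRA
    analysis (their count is logged)."""
    labels = np.asarray(labels, dtype=object)
    present = set(x for x in labels if x is not None)
    for grp in (reference_group, comparison_group):
        if grp not in present:
            raise SurrogateError(f"group {grp!r} not present in labels")
    values = np.full(len(labels), np.nan)
    values[labels == reference_group] = 0.0
    values[labels == comparison_group] = 1.0
    excluded = np.isnan(values)
    if excluded.any():
        logger.info(
            "encode_sra: %d trios outside %r/%r excluded from SRA analysis",
            int(excluded.sum()),
            reference_group,
            comparison_group,
        )
    return SurrogateAssignment(values=values, method="sra", excluded=excluded)


@dataclass(frozen=True)
class StructureTestResult:
    statistic: float
    df: int
    p: float
    flags: frozenset = frozenset()


def exposure_structure_test(exposure: np.ndarray, pcs: PCMatrix) -> StructureTestResult:
    """Likelihood-ratio test that no PC predicts exposure.

    Logistic regression of E on the k PCs against the intercept-only model;
    the statistic is referred to chi-square with k degrees of freedom.  A
    non-predictive panel (p large) means EEGM adjustment has nothing to
    adjust for in this cohort.
    """
    e = np.asarray(exposure, dtype=float)
    mask = ~np.isnan(e)
    y = e[mask]
    if y.size == 0 or y.min() == y.max():
        raise SurrogateError("need at least one exposed and one unexposed trio")
    if pcs.k < 1:
        raise SurrogateError("need at least one PC column")
    _, llf, llnull, separated = _fit_logistic(y, pcs.scores[mask], pcs.scores[mask])
    stat = max(2.0 * (llf - llnull), 0.0)
    flags = frozenset({"separation"}) if separated else frozenset()
    return StructureTestResult(
        statistic=stat, df=pcs.k, p=float(stats.chi2.sf(stat, pcs.k)), flags=flags
    )
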