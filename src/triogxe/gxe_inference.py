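"""Conditional-likelihood inference of gene-environment interaction from
case-parent trios.

The disease model is log-linear in the child's minor-allele count ``g``, the
binary maternal exposure ``e`` and a stratification surrogate ``x`` in
[0, 1]:

    log P(D=1 | g, e, x) = b0 + g*bG + e*bE + x*bX
                           + g*e*bGE + g*x*bGX + e*x*bEX + g*e*x*bGEX

Conditioning the affected child's genotype on both parental genotypes
removes every term not involving ``g``: the estimable kernel is the
genotypic odds exp(k_p + bG + e*bGE + x*bGX + e*x*bGEX) per additional
allele copy, where k_p is the log-ratio of consecutive Mendelian
transmission probabilities and cancels in the normalized likelihood.  The
null of no interaction, bGE = bGEX = 0, is tested by a likelihood-ratio
statistic on 2 degrees of freedom (1 df without adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .trio_data import MISSING, TrioDataset, mendelian_consistent

logger = logging.getLogger(__name__)

PARAM_NAMES = ("beta_g", "beta_ge", "beta_gx", "beta_gex")

ModelSpecName = Literal[
    "unadjusted",
    "unadjusted_null",
    "adjusted",
    "adjusted_null",
    "common_gxe",
    "common_gxe_null",
]

#: free parameters (as boolean mask over PARAM_NAMES) of each model spec
MODEL_SPECS: dict[str, tuple[bool, bool, bool, bool]] = {
    "unadjusted": (True, True, False, False),
    "unadjusted_null": (True, False, False, False),
    "adjusted": (True, True, True, True),
    "adjusted_null": (True, False, True, False),
    "common_gxe": (True, True, True, False),
    "common_gxe_null": (True, False, True, False),
}

#: fallback ladder when a fit is unidentifiable
_FALLBACK = {
    "adjusted": "common_gxe",
    "common_gxe": "unadjusted",
    "adjusted_null": "unadjusted_null",
    "common_gxe_null": "unadjusted_null",
}

_SEPARATION_BOUND = 15.0
_GRAD_TOL = 1e-8
_EIG_RATIO_TOL = 1e-8


class InferenceError(ValueError):
    """Raised on unusable input to the conditional likelihood."""


# ---------------------------------------------------------------------------
# Mendelian transmission
# ---------------------------------------------------------------------------

def _punnett(gm: int, gf: int) -> np.ndarray:
    # each parent transmits its minor allele with prob g/2
    pm, pf = gm / 2.0, gf / 2.0
    return np.array(
        [
            (1 - pm) * (1 - pf),
            pm * (1 - pf) + (1 - pm) * pf,
            pm * pf,
        ]
    )


#: TRANSMISSION[gm, gf] = P(child genotype | parents), shape (3, 3, 3)
TRANSMISSION = np.array([[_punnett(a, b) for b in range(3)] for a in range(3)])


def mendelian_probs(g_m: int, g_f: int) -> np.ndarray:
    """Exact transmission probabilities over the child genotype {0,1,2}."""
    if g_m not in (0, 1, 2) or g_f not in (0, 1, 2):
        raise InferenceError(f"genotypes must be in {{0,1,2}}, got ({g_m}, {g_f})")
    return TRANSMISSION[g_m, g_f].copy()


# ---------------------------------------------------------------------------
# Parameters and model evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimableParams:
    """The four genotype-involving log relative risks estimable from trios.

    Per-copy effects: the linear predictor for a child with ``g`` copies is
    ``g * (beta_g + e*beta_ge + x*beta_gx + e*x*beta_gex)``.  Effects not
    involving the genotype (exposure and surrogate main effects and their
    product) cancel out of the conditional likelihood and have no home here.
    """

    beta_g: float = 0.0
    beta_ge: float = 0.0
    beta_gx: float = 0.0
    beta_gex: float = 0.0
    model_spec: str = "adjusted"

    def __post_init__(self) -> None:
        if self.model_spec not in MODEL_SPECS:
            raise InferenceError(f"unknown model spec {self.model_spec!r}")
        free = MODEL_SPECS[self.model_spec]
        vals = (self.beta_g, self.beta_ge, self.beta_gx, self.beta_gex)
        for name, is_free, v in zip(PARAM_NAMES, free, vals):
            if not is_free and v != 0.0:
                raise InferenceError(
                    f"{name} must be 0 under model spec {self.model_spec!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.beta_g, self.beta_ge, self.beta_gx, self.beta_gex])


def linear_predictor(g: int, e: float, x: float, params: EstimableParams) -> float:
    """Genotype-involving part of the log relative risk for ``g`` copies."""
    return g * (
        params.beta_g
        + e * params.beta_ge
        + x * params.beta_gx
        + e * x * params.beta_gex
    )


def conditional_child_distribution(
    g_m: int, g_f: int, e: float, x: float, params: EstimableParams
) -> np.ndarray:
    """P(child genotype | affected, parents, e, x) over {0, 1, 2}.

    Mendelian transmission probabilities reweighted by the genotypic odds;
    normalizes to 1 over the Mendelian-compatible genotypes.
    """
    t = mendelian_probs(g_m, g_f)
    eta = params.beta_g + e * params.beta_ge + x * params.beta_gx + e * x * params.beta_gex
    w = t * np.exp(np.arange(3) * eta)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Vectorized per-SNP likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class _TrioArrays:
    """Per-SNP complete-case arrays feeding the conditional likelihood."""

    g_child: np.ndarray  # (n,)
    logT: np.ndarray  # (n, 3) log transmission probs, -inf where impossible
    design: np.ndarray  # (n, 4) covariate of each beta: [1, e, x, e*x]
    informative: np.ndarray  # (n,) bool: >1 Mendelian-compatible child genotype
    trio_index: np.ndarray  # (n,) positions in the source dataset

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())


def _prepare_arrays(
    dataset: TrioDataset,
    surrogate_values: np.ndarray | None,
    snp: int | str = 0,
    trio_mask: np.ndarray | None = None,
) -> _TrioArrays:
    j = dataset.snp_index(snp) if isinstance(snp, str) else snp
    gm = dataset.geno_mother[:, j].astype(int)
    gf = dataset.geno_father[:, j].astype(int)
    gc = dataset.geno_child[:, j].astype(int)
    e = dataset.exposure
    x = (
        np.zeros(len(dataset))
        if surrogate_values is None
        else np.asarray(surrogate_values, dtype=float)
    )
    keep = (gm != MISSING) & (gf != MISSING) & (gc != MISSING)
    keep &= ~np.isnan(e) & ~np.isnan(x)
    if trio_mask is not None:
        keep &= np.asarray(trio_mask, dtype=bool)
    idx = np.flatnonzero(keep)
    gm, gf, gc, e, x = gm[idx], gf[idx], gc[idx], e[idx], x[idx]
    if not mendelian_consistent(gm, gf, gc).all():
        raise InferenceError(
            "Mendelian-inconsistent trio reached the likelihood; screen upstream"
        )
    t = TRANSMISSION[gm, gf]  # (n, 3)
    with np.errstate(divide="ignore"):
        logT = np.log(t)
    informative = (t > 0).sum(axis=1) > 1
    design = np.column_stack([np.ones_like(e), e, x, e * x])
    return _TrioArrays(gc, logT, design, informative, idx)


def _loglik_terms(beta: np.ndarray, arr: _TrioArrays):
    """Per-trio log-likelihood, conditional mean and variance of g."""
    eta = arr.design @ beta  # (n,)
    lw = arr.logT + np.arange(3)[None, :] * eta[:, None]
    m = lw.max(axis=1, keepdims=True)
    w = np.exp(lw - m)
    z = w.sum(axis=1)
    p = w / z[:, None]
    ll = lw[np.arange(len(arr.g_child)), arr.g_child] - (np.log(z) + m[:, 0])
    mean = p @ np.arange(3)
    var = p @ (np.arange(3) ** 2) - mean**2
    return ll, mean, var


def _negloglik_grad_hess(theta: np.ndarray, arr: _TrioArrays, free: np.ndarray):
    beta = np.zeros(4)
    beta[free] = theta
    ll, mean, var = _loglik_terms(beta, arr)
    resid = arr.g_child - mean
    grad = arr.design.T @ resid  # d loglik / d beta
    X = arr.design
    hess = -(X.T * var) @ X
    return -ll.sum(), -grad[free], -hess[np.ix_(free, free)]


def conditional_loglik(
    params: EstimableParams,
    dataset: TrioDataset,
    surrogate=None,
    snp: int | str = 0,
    trio_mask: np.ndarray | None = None,
) -> float:
    """Log conditional likelihood of the child genotypes at one SNP.

    Sums ``log[ T(g_c|g_m,g_f) exp(LP(g_c)) / sum_g T(g|g_m,g_f) exp(LP(g)) ]``
    over complete-case trios; trios with a single compatible child genotype
    contribute exactly 0.  ``surrogate`` may be a SurrogateAssignment or a
    plain array of x values (ignored trios carry NaN).
    """
    values = getattr(surrogate, "values", surrogate)
    arr = _prepare_arrays(dataset, values, snp, trio_mask)
    ll, _, _ = _loglik_terms(params.as_array(), arr)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Maximum likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: EstimableParams
    vcov: np.ndarray  # covariance of the free parameters, in PARAM_NAMES order
    loglik: float
    n_informative: int
    converged: bool
    identifiability_flags: set = field(default_factory=set)
    free_names: tuple = ()
    trio_index: np.ndarray | None = None

    def se(self, name: str) -> float:
        i = self.free_names.index(name)
        return float(np.sqrt(self.vcov[i, i]))


def _newton_maximize(
    arr: _TrioArrays,
    free: np.ndarray,
    start: np.ndarray,
    bound: float = _SEPARATION_BOUND,
):
    """Projected Newton on the concave conditional log-likelihood.

    Estimates are confined to the box |beta| <= bound; a monotone
    likelihood direction (separation) parks its coordinate at the bound,
    where the likelihood is numerically at its supremum, so nested fits
    keep loglik(full) >= loglik(reduced).  Returns (theta, converged,
    hit_bound).
    """
    theta = np.clip(start, -bound, bound)
    nll, grad, hess = _negloglik_grad_hess(theta, arr, free)
    loose_ok = False
    for _ in range(200):
        lower = (theta <= -bound + 1e-9) & (grad > 0)
        upper = (theta >= bound - 1e-9) & (grad < 0)
        active = lower | upper
        pgrad = np.where(active, 0.0, grad)
        if np.max(np.abs(pgrad)) < _GRAD_TOL:
            return theta, True, bool(active.any())
        loose_ok = np.max(np.abs(pgrad)) < 1e-5
        inact = ~active
        step = np.zeros_like(theta)
        sub = hess[np.ix_(inact, inact)]
        gsub = grad[inact]
        try:
            step[inact] = np.linalg.solve(sub, -gsub)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * max(1.0, np.trace(sub)) * np.eye(sub.shape[0])
            step[inact] = np.linalg.solve(sub + ridge, -gsub)
        t = 1.0
        for _ in range(50):
            cand = np.clip(theta + t * step, -bound, bound)
            nll_new, grad_new, hess_new = _negloglik_grad_hess(cand, arr, free)
            if nll_new < nll - 1e-13:
                theta, nll, grad, hess = cand, nll_new, grad_new, hess_new
                break
            t /= 2.0
        else:
            # no descent possible: numerically at the optimum
            return theta, loose_ok, bool(active.any())
    return theta, loose_ok, bool((np.abs(theta) >= bound - 1e-9).any())


def _sparse_gex_cells(arr: _TrioArrays) -> bool:
    """For a binary surrogate: is some exposed x-stratum cell empty of
    informative trios, leaving the three-way term unidentified?"""
    x = arr.design[arr.informative, 2]
    e = arr.design[arr.informative, 1]
    if not np.isin(x, (0.0, 1.0)).all():
        return False  # continuous surrogate: rely on the information rank
    return any(((e == 1) & (x == v)).sum() == 0 for v in (0.0, 1.0))


def _fit_arrays(arr: _TrioArrays, spec: str, rng_restart_seed: int = 0):
    free = np.asarray(MODEL_SPECS[spec])
    k = int(free.sum())
    flags: set = set()

    # identifiability: rank of the information at beta=0, plus an SRA-style
    # cell-count check for the three-way interaction-adjustment term
    _, _, info0 = _negloglik_grad_hess(np.zeros(k), arr, free)
    eig = np.linalg.eigvalsh(info0)  # observed information at beta = 0
    unident = eig[-1] <= 0 or eig[0] < _EIG_RATIO_TOL * eig[-1]
    if not unident and free[3]:
        unident = _sparse_gex_cells(arr)
    if unident:
        fb = _FALLBACK.get(spec)
        if fb is None:
            raise InferenceError(f"model {spec!r} unidentifiable and no fallback")
        flags.add("dropped_gexhat" if spec == "adjusted" else f"fallback_from_{spec}")
        sub = _fit_arrays(arr, fb, rng_restart_seed)
        sub.identifiability_flags |= flags
        return sub

    theta, converged, hit_bound = _newton_maximize(arr, free, np.zeros(k))
    if not converged:
        rng = np.random.default_rng(rng_restart_seed + 12345)
        for _ in range(3):
            theta_j, converged, hit_bound = _newton_maximize(
                arr, free, rng.normal(scale=0.1, size=k)
            )
            if converged:
                theta = theta_j
                break
    if not converged:
        res = optimize.minimize(
            lambda t: _negloglik_grad_hess(t, arr, free)[0],
            theta,
            jac=lambda t: _negloglik_grad_hess(t, arr, free)[1],
            method="L-BFGS-B",
            bounds=[(-_SEPARATION_BOUND, _SEPARATION_BOUND)] * k,
            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500},
        )
        nll_res, _, _ = _negloglik_grad_hess(theta, arr, free)
        if res.fun <= nll_res:
            theta = res.x
        converged = bool(res.success)
        hit_bound = bool(np.any(np.abs(theta) >= _SEPARATION_BOUND - 1e-6))

    if hit_bound:
        flags |= {"separation", "vcov_unreliable"}

    nll, grad, hess = _negloglik_grad_hess(theta, arr, free)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
        flags.add("vcov_unreliable")

    beta = np.zeros(4)
    beta[free] = theta
    params = EstimableParams(*beta, model_spec=spec)
    return FitResult(
        params=params,
        vcov=vcov,
        loglik=-nll,
        n_informative=arr.n_informative,
        converged=converged,
        identifiability_flags=flags,
        free_names=tuple(n for n, f in zip(PARAM_NAMES, free) if f),
        trio_index=arr.trio_index,
    )


def fit_model(
    dataset: TrioDataset,
    surrogate=None,
    spec: ModelSpecName = "adjusted",
    snp: int | str = 0,
    trio_mask: np.ndarray | None = None,
) -> FitResult:
    """Maximize the conditional likelihood at one SNP.

    ``spec`` selects the free parameters (see :data:`MODEL_SPECS`); the
    ``*_null`` variants are the reduced models of the interaction LRTs.  If
    the information matrix is rank-deficient — e.g. no informative trios in
    a surrogate x exposure cell needed for the three-way term — the fit
    automatically falls back along adjusted -> common_gxe -> unadjusted,
    flagging each step (``dropped_gexhat`` for the first).
    """
    if spec not in MODEL_SPECS:
        raise InferenceError(f"unknown model spec {spec!r}")
    values = getattr(surrogate, "values", surrogate)
    arr = _prepare_arrays(dataset, values, snp, trio_mask)
    if arr.n_informative < 1:
        raise InferenceError("no informative trios (no heterozygous parents)")
    return _fit_arrays(arr, spec)


# ---------------------------------------------------------------------------
# Tests and contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested conditional-likelihood fits.

    The statistic ``2 (l_full - l_reduced)`` is floored at 0 and referred to
    the upper tail of chi-square with df = difference in free parameters.
    """
    if not set(reduced.free_names) <= set(full.free_names):
        raise InferenceError("reduced model is not nested in the full model")
    if full.trio_index is not None and reduced.trio_index is not None:
        if not np.array_equal(full.trio_index, reduced.trio_index):
            raise InferenceError("full and reduced fits used different trios")
    df = len(full.free_names) - len(reduced.free_names)
    if df < 1:
        raise InferenceError("models have the same number of free parameters")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise InferenceError(f"negative LRT statistic {stat:.3g}: optimizer failure")
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


@dataclass(frozen=True)
class ContrastResult:
    estimate: float  # exponentiated
    ci_lo: float
    ci_hi: float
    available: bool = True


def interaction_contrasts(
    fit: FitResult, which: Literal["reference", "comparison"]
) -> ContrastResult:
    """Exponentiated G x E relative-risk contrast with 95% Wald CI.

    ``reference`` is exp(bGE) — the interaction in the surrogate-0 group;
    ``comparison`` is exp(bGE + bGEX) — the interaction in the surrogate-1
    group, with SE from var(bGE) + var(bGEX) + 2 cov(bGE, bGEX).
    """
    if which not in ("reference", "comparison"):
        raise InferenceError(f"unknown contrast {which!r}")
    if "beta_ge" not in fit.free_names:
        return ContrastResult(np.nan, np.nan, np.nan, available=False)
    i = fit.free_names.index("beta_ge")
    est = fit.params.beta_ge
    var = fit.vcov[i, i]
    if which == "comparison":
        if "beta_gex" in fit.free_names:
            j = fit.free_names.index("beta_gex")
            est = est + fit.params.beta_gex
            var = var + fit.vcov[j, j] + 2.0 * fit.vcov[i, j]
        # under the common-GxE fallback the comparison equals the reference
    if "vcov_unreliable" in fit.identifiability_flags or var < 0:
        return ContrastResult(float(np.exp(est)), np.nan, np.nan, available=False)
    se = float(np.sqrt(var))
    with np.errstate(over="ignore"):
        return ContrastResult(
            estimate=float(np.exp(est)),
            ci_lo=float(np.exp(est - 1.96 * se)),
            ci_hi=float(np.exp(est + 1.96 * se)),
        )


# ---------------------------------------------------------------------------
# Per-SNP scan row
# ---------------------------------------------------------------------------

_NULL_OF = {
    "unadjusted": "unadjusted_null",
    "adjusted": "adjusted_null",
    "common_gxe": "common_gxe_null",
}


def _interaction_test(dataset, surrogate, spec, snp, trio_mask):
    """Fit full model (with fallback), then the matching null; return
    (LRTResult, full fit)."""
    full = fit_model(dataset, surrogate, spec, snp, trio_mask)
    reached = full.params.model_spec
    null = fit_model(dataset, surrogate, _NULL_OF[reached], snp, trio_mask)
    return lrt(full, null), full


def scan_snp(
    dataset: TrioDataset,
    snp: int | str,
    sra=None,
    eegm=None,
) -> dict:
    """One results row for a SNP: unadjusted 1-df p, SRA- and EEGM-adjusted
    2-df p-values, and the SRA-based interaction contrasts.

    Trios excluded by either surrogate (or with missing exposure/genotype at
    this SNP) are dropped from all three analyses so the fits compare like
    with like.  Errors are recorded per analysis rather than aborting.
    """
    j = dataset.snp_index(snp) if isinstance(snp, str) else snp
    snp_id = dataset.snps[j].snp_id
    flags: list[str] = []
    row: dict = {c: np.nan for c in (
        "n_informative", "p_unadj_1df", "p_sra_2df", "p_eegm_2df",
        "exp_bGE_sra", "exp_bGE_sra_lo", "exp_bGE_sra_hi",
        "exp_bGE_plus_sra", "exp_bGE_plus_sra_lo", "exp_bGE_plus_sra_hi",
    )}
    row["snp_id"] = snp_id

    mask = np.ones(len(dataset), dtype=bool)
    for surr in (sra, eegm):
        if surr is not None:
            vals = getattr(surr, "values", surr)
            mask &= ~np.isnan(np.asarray(vals, dtype=float))

    try:
        test, full = _interaction_test(dataset, None, "unadjusted", j, mask)
        row["p_unadj_1df"] = test.p
        row["n_informative"] = full.n_informative
    except InferenceError as err:
        flags.append(f"unadjusted:{err}")

    if sra is not None:
        try:
            test, full = _interaction_test(dataset, sra, "adjusted", j, mask)
            row["p_sra_2df"] = test.p
            flags.extend(sorted(f"sra:{f}" for f in full.identifiability_flags))
            ref = interaction_contrasts(full, "reference")
            cmp_ = interaction_contrasts(full, "comparison")
            row.update(
                exp_bGE_sra=ref.estimate, exp_bGE_sra_lo=ref.ci_lo,
                exp_bGE_sra_hi=ref.ci_hi, exp_bGE_plus_sra=cmp_.estimate,
                exp_bGE_plus_sra_lo=cmp_.ci_lo, exp_bGE_plus_sra_hi=cmp_.ci_hi,
            )
        except InferenceError as err:
            flags.append(f"sra:{err}")

    if eegm is not None:
        try:
            test, full = _interaction_test(dataset, eegm, "adjusted", j, mask)
            row["p_eegm_2df"] = test.p
            flags.extend(sorted(f"eegm:{f}" for f in full.identifiability_flags))
        except InferenceError as err:
            flags.append(f"eegm:{err}")

    row["flags"] = ";".join(flags)
    return row
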