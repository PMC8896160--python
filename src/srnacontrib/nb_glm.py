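"""Per-gene factorial negative-binomial GLM with Wald and likelihood-ratio tests.

The model
---------
For each gene, counts in library *j* are modelled as negative binomial with
mean ``mu_j = s_j * q * 2**(x_j . beta)`` and variance ``mu_j + alpha *
mu_j**2``, where ``s_j`` is the library size factor, ``x_j`` the row of the
2x2 factorial design matrix (intercept, condition, genotype, interaction)
and ``alpha`` the gene's dispersion.  With reference levels fixed to
(condition = reference, genotype = deletion), the coefficients carry a
direct biological reading:

* ``beta1`` — the condition effect in the sRNA *deletion* strain, i.e. the
  part of the stress response that does not involve the sRNA;
* ``beta2`` — the genotype effect at the reference condition;
* ``beta3`` — the interaction: the extra condition response present only
  when the sRNA is there, i.e. the sRNA's contribution.

The total stress response of the wild type is the contrast
``log2FC_wt = beta1 + beta3``; in the deletion strain it is
``log2FC_del = beta1``.

Fitting is by iteratively reweighted least squares (IRLS) on the natural-log
scale with ``log(s_j)`` offsets; reported coefficients are divided by
``ln 2`` so that they are log2 fold changes.  Per-gene dispersions are
estimated by profile maximum likelihood, moderated towards a mean-dispersion
trend ``alpha ~ a1/mu + a0`` by a normal prior on the log dispersion
(empirical-Bayes shrinkage), and the moderated value is used for the final
fit and both hypothesis tests.  The interaction is tested by a likelihood
ratio test against the reduced model without the interaction column
(chi-square, 1 df); individual contrasts are tested by Wald z-tests.
Benjamini-Hochberg correction is applied separately within each test
family across all tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .data_io import GROUPS, CountMatrix, SampleDesign, check_pairing
from .normalization import normalize, size_factors_median_of_ratios

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: natural-log magnitude at which a coefficient is declared separated
#: (a 2**30-fold change, far beyond any biologically meaningful estimate)
BETA_CLAMP = 30.0 * LN2

DESIGN_COLUMNS = ("intercept", "condition", "genotype", "interaction")

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


@dataclass(frozen=True)
class DispersionModel:
    """Mean-dispersion trend ``alpha_trend(mu) = a1 / mu + a0`` plus the
    variance of the log-dispersion prior used for shrinkage."""

    a0: float
    a1: float
    prior_var: float

    def trend(self, mu):
        mu = np.asarray(mu, dtype=float)
        out = self.a1 / mu + self.a0
        return np.maximum(out, ALPHA_MIN)


@dataclass
class FitConfig:
    """Tunable knobs of the per-gene fitting pipeline."""

    padj_threshold: float = 0.1
    low_count_threshold: float = 1.0     # min base mean (normalized counts)
    trend_min_base_mean: float = 5.0
    trend_min_genes: int = 50
    epsilon: float = 0.1                 # |log2FC| below which a component is "zero"
    exclude_genes: tuple = ("srna",)     # e.g. the deleted sRNA gene itself


def build_design(design: SampleDesign) -> pd.DataFrame:
    """0/1 design matrix (libraries x [intercept, condition, genotype,
    interaction]) with reference levels condition=reference,
    genotype=deletion, so that

    * (reference, deletion)  -> (1, 0, 0, 0)
    * (stress,    deletion)  -> (1, 1, 0, 0)
    * (reference, wildtype)  -> (1, 0, 1, 0)
    * (stress,    wildtype)  -> (1, 1, 1, 1)
    """
    t = design.table
    cond = (t["condition"] == "stress").astype(int)
    geno = (t["genotype"] == "wildtype").astype(int)
    X = pd.DataFrame(
        {
            "intercept": 1,
            "condition": cond,
            "genotype": geno,
            "interaction": cond * geno,
        },
        index=t.index,
    )
    return X


def nb_loglik(counts: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative-binomial log likelihood with mean ``mu`` and variance
    ``mu + alpha*mu**2``, summed over observations."""
    y = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("counts and mu must have the same length")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if (mu <= 0).any():
        raise ValueError("mu must be positive")
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


@dataclass
class IRLSResult:
    beta: np.ndarray          # natural-log scale
    cov: np.ndarray           # natural-log scale
    mu: np.ndarray
    loglik: float
    converged: bool
    clamped: bool
    n_iter: int


def _solve_wls(X, w, z):
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ z
    try:
        return np.linalg.solve(A, b), A
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0], A


def irls_fit(
    counts: np.ndarray,
    design_matrix: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    beta_init: np.ndarray | None = None,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> IRLSResult:
    """Maximum-likelihood fit of the NB GLM with log link and ``log(s_j)``
    offsets by iteratively reweighted least squares.

    Returns natural-log-scale coefficients and the inverse Fisher
    information as covariance.  Separated coefficients (a factor level with
    no counts) are clamped at +-30*ln2 and flagged rather than diverging.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    offset = np.log(s)

    if beta_init is not None:
        beta = np.asarray(beta_init, dtype=float).copy()
        eta = offset + X @ beta
    else:
        eta = np.log(y + 0.5)
        w0 = np.ones_like(y)
        beta, _ = _solve_wls(X, w0, eta - offset)
        eta = offset + X @ beta

    converged = False
    clamped = False
    it = 0
    for it in range(1, maxiter + 1):
        mu = np.clip(np.exp(np.clip(eta, -500, 50)), 1e-10, 1e14)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        beta_new, _ = _solve_wls(X, w, z)
        over = np.abs(beta_new) > BETA_CLAMP
        if over.any():
            beta_new = np.clip(beta_new, -BETA_CLAMP, BETA_CLAMP)
            clamped = True
        step = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        eta = offset + X @ beta
        if step < tol:
            converged = True
            break

    mu = np.clip(np.exp(np.clip(eta, -500, 50)), 1e-10, 1e14)
    w = mu / (1.0 + alpha * mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    ll = nb_loglik(y, mu, alpha)
    return IRLSResult(beta, cov, mu, ll, converged, clamped, it)


def _profile_objective(y, X, s, penalty=None):
    """Closure returning -profile-loglik(log alpha), warm-starting beta."""
    state = {"beta": None}

    def nll(log_alpha):
        alpha = float(np.exp(log_alpha))
        res = irls_fit(y, X, s, alpha, beta_init=state["beta"])
        state["beta"] = res.beta
        val = -res.loglik
        if penalty is not None:
            val += penalty(log_alpha)
        return val

    return nll


_LOG_BOUNDS = (np.log(ALPHA_MIN), np.log(ALPHA_MAX))


def _maximize_alpha(nll) -> tuple[float, bool]:
    res = minimize_scalar(nll, bounds=_LOG_BOUNDS, method="bounded",
                          options={"xatol": 1e-6})
    la = float(res.x)
    # the bounded search stops short of the bounds; half a log-unit is close
    # enough to call the solution a boundary value
    at_boundary = (la - _LOG_BOUNDS[0] < 0.5) or (_LOG_BOUNDS[1] - la < 0.5)
    return float(np.exp(la)), at_boundary


def profile_dispersion_mle(counts, design_matrix, size_factors) -> tuple[float, bool]:
    """Gene-wise dispersion by profile maximum likelihood: the coefficients
    are re-fit for every candidate alpha and the profile log likelihood is
    maximized over log alpha in [log 1e-8, log 10] by bounded scalar search
    (tolerance 1e-6 in log alpha).

    Returns ``(alpha_hat, at_boundary)``.
    """
    nll = _profile_objective(np.asarray(counts, float), np.asarray(design_matrix, float),
                             np.asarray(size_factors, float))
    return _maximize_alpha(nll)


def map_dispersion(counts, design_matrix, size_factors, alpha_trend: float,
                   prior_var: float) -> tuple[float, bool]:
    """Maximum a posteriori dispersion: profile log likelihood plus a normal
    log-prior on log alpha centred at ``log(alpha_trend)`` with variance
    ``prior_var``."""
    if alpha_trend <= 0 or prior_var <= 0:
        raise ValueError("alpha_trend and prior_var must be positive")
    mu_prior = float(np.log(alpha_trend))

    def penalty(log_alpha):
        return 0.5 * (log_alpha - mu_prior) ** 2 / prior_var

    nll = _profile_objective(np.asarray(counts, float), np.asarray(design_matrix, float),
                             np.asarray(size_factors, float), penalty=penalty)
    return _maximize_alpha(nll)


def fit_trend(base_means, alpha_genes, min_genes: int = 50,
              min_base_mean: float = 5.0) -> DispersionModel:
    """Fit the mean-dispersion trend ``alpha ~ a1/mu + a0`` by nonnegative
    least squares, iterated twice with exclusion of genes more than two
    decades off the current trend, then estimate the prior variance of the
    log dispersion around the trend.

    With fewer than ``min_genes`` usable genes the trend degenerates to the
    constant ``a0 = median(alpha)``.
    """
    mu = np.asarray(base_means, dtype=float)
    a = np.asarray(alpha_genes, dtype=float)
    keep = np.isfinite(mu) & np.isfinite(a) & (mu > min_base_mean) & (a > 0)
    mu, a = mu[keep], a[keep]

    if len(a) < min_genes:
        logger.info("only %d genes usable for the dispersion trend; "
                    "falling back to a constant trend", len(a))
        a0 = float(np.median(a)) if len(a) else 0.1
        a0 = max(a0, ALPHA_MIN)
        resid_var = float(np.var(np.log(a / a0))) if len(a) else 1.0
        return DispersionModel(a0=a0, a1=0.0, prior_var=max(0.25, resid_var - 0.5))

    sel = np.ones(len(a), dtype=bool)
    a0 = a1 = 0.0
    for _ in range(2):
        Xd = np.column_stack([1.0 / mu[sel], np.ones(sel.sum())])
        coef, _ = nnls(Xd, a[sel])
        a1, a0 = float(coef[0]), float(coef[1])
        trend = np.maximum(a1 / mu + a0, ALPHA_MIN)
        sel = np.abs(np.log10(a) - np.log10(trend)) <= 2.0
        if not sel.any():
            sel = np.ones(len(a), dtype=bool)
    if a0 <= 0 and a1 <= 0:
        a0 = max(float(np.median(a)), ALPHA_MIN)
    trend = np.maximum(a1 / mu + a0, ALPHA_MIN)
    log_resid = np.log(a) - np.log(trend)
    # 0.5 is a proxy for the sampling variance of a log-dispersion estimate
    prior_var = max(0.25, float(np.var(log_resid)) - 0.5)
    return DispersionModel(a0=a0, a1=a1, prior_var=prior_var)


def wald_test(beta: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z-test of ``beta = 0``; returns ``(z, p)``."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    return z, float(2.0 * norm.sf(abs(z)))


def lrt_interaction(counts, design_full, design_reduced, size_factors,
                    alpha_map: float) -> tuple[float, float, bool]:
    """Likelihood ratio test of the interaction term.

    Both models are fit at the same (full-model) dispersion, which keeps the
    statistic nonnegative.  Returns ``(lrt_stat, p, ok)``; ``p`` is NaN if
    either fit fails to converge.
    """
    full = irls_fit(counts, design_full, size_factors, alpha_map)
    red = irls_fit(counts, design_reduced, size_factors, alpha_map)
    stat = 2.0 * (full.loglik - red.loglik)
    if stat < -1e-8:
        logger.debug("negative LRT statistic %.3g clamped to 0", stat)
    stat = max(stat, 0.0)
    ok = full.converged and red.converged
    p = float(chi2.sf(stat, df=1)) if ok else float("nan")
    return stat, p, ok


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the correction and restored as NaN;
    the output satisfies ``padj >= p`` and ``padj <= 1``.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    pm = p[mask]
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# full pipeline

#: contrast vectors on the coefficient scale
CONTRAST_WT = np.array([0.0, 1.0, 0.0, 1.0])    # stress vs reference, wildtype
CONTRAST_DEL = np.array([0.0, 1.0, 0.0, 0.0])   # stress vs reference, deletion
CONTRAST_GENO_STRESS = np.array([0.0, 0.0, 1.0, 1.0])  # wt vs del, stress
CONTRAST_GENO_REF = np.array([0.0, 0.0, 1.0, 0.0])     # wt vs del, reference

FIT_COLUMNS = [
    "base_mean",
    "mean_reference_wildtype", "mean_stress_wildtype",
    "mean_reference_deletion", "mean_stress_deletion",
    "beta0", "beta1", "beta2", "beta3",
    "se0", "se1", "se2", "se3",
    "log2fc_wt", "se_wt", "log2fc_del", "se_del",
    "wald_p_wt", "padj_wt", "wald_p_del", "padj_del",
    "lrt_stat", "lrt_p", "padj_interaction",
    "alpha_gene", "alpha_map", "status", "flags",
]


def fit_all(counts: CountMatrix, design: SampleDesign,
            config: FitConfig | None = None) -> pd.DataFrame:
    """Run the whole per-gene pipeline on a validated count matrix and
    sample design.

    Steps: size factors -> gene-wise profile-ML dispersions -> mean-dispersion
    trend -> MAP dispersions -> final IRLS fit -> Wald tests for the two
    condition contrasts -> interaction LRT -> BH correction within each test
    family.  Returns a DataFrame indexed by gene with the columns in
    ``FIT_COLUMNS``; genes excluded from testing carry NaN adjusted p-values
    and an explanatory ``status``.
    """
    config = config or FitConfig()
    check_pairing(counts, design)

    df = counts.counts
    if config.exclude_genes:
        drop = [g for g in config.exclude_genes if g in df.index]
        if drop:
            logger.info("excluding %d gene(s) from fitting: %s", len(drop), drop)
            df = df.drop(index=drop)

    X_full = build_design(design).reindex(df.columns).to_numpy(dtype=float)
    X_red = X_full[:, :3]
    sizes = design.group_sizes()
    logger.info("libraries per group: %s",
                {f"{c}/{g}": n for (c, g), n in sizes.items()})

    s = size_factors_median_of_ratios(df)
    s_arr = s.to_numpy()
    norm_counts = normalize(df, s)
    base_mean = norm_counts.mean(axis=1)

    # group means of normalized counts
    group_means = {}
    for cond, geno in GROUPS:
        libs = design.table.index[
            (design.table["condition"] == cond) & (design.table["genotype"] == geno)
        ]
        group_means[f"mean_{cond}_{geno}"] = norm_counts[libs].mean(axis=1)

    Y = df.to_numpy(dtype=float)
    n_genes = Y.shape[0]
    all_zero = Y.sum(axis=1) == 0
    low_count = (~all_zero) & (base_mean.to_numpy() < config.low_count_threshold)
    logger.info("%d genes; %d all-zero, %d below the low-count threshold",
                n_genes, int(all_zero.sum()), int(low_count.sum()))

    alpha_gene = np.full(n_genes, np.nan)
    bflag = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        if all_zero[i]:
            continue
        alpha_gene[i], bflag[i] = profile_dispersion_mle(Y[i], X_full, s_arr)

    usable = (~all_zero) & (~low_count)
    trend_model = fit_trend(base_mean.to_numpy()[usable], alpha_gene[usable],
                            min_genes=config.trend_min_genes,
                            min_base_mean=config.trend_min_base_mean)
    logger.info("dispersion trend: a0=%.4g a1=%.4g prior_var=%.3g",
                trend_model.a0, trend_model.a1, trend_model.prior_var)

    res = {c: np.full(n_genes, np.nan) for c in FIT_COLUMNS
           if c not in ("status", "flags")}
    status = np.array(["ok"] * n_genes, dtype=object)
    flags = np.array([""] * n_genes, dtype=object)

    res["base_mean"] = base_mean.to_numpy()
    for k, v in group_means.items():
        res[k] = v.to_numpy()
    res["alpha_gene"] = alpha_gene

    for i in range(n_genes):
        if all_zero[i]:
            status[i] = "all_zero"
            continue
        gene_flags = []
        if bflag[i]:
            gene_flags.append("alpha_boundary")
        a_tr = float(trend_model.trend(base_mean.iloc[i]))
        a_map, mb = map_dispersion(Y[i], X_full, s_arr, a_tr, trend_model.prior_var)
        if mb:
            gene_flags.append("alpha_map_boundary")
        res["alpha_map"][i] = a_map

        fit = irls_fit(Y[i], X_full, s_arr, a_map)
        if not fit.converged:
            status[i] = "no_convergence"
            gene_flags.append("irls_max_iter")
        if fit.clamped:
            gene_flags.append("separation_clamped")
        beta2 = fit.beta / LN2
        se2 = np.sqrt(np.maximum(np.diag(fit.cov), 0.0)) / LN2
        for k in range(4):
            res[f"beta{k}"][i] = beta2[k]
            res[f"se{k}"][i] = se2[k]

        # contrasts by linear algebra on the fitted coefficients
        for name, c in (("wt", CONTRAST_WT), ("del", CONTRAST_DEL)):
            est = float(c @ fit.beta) / LN2
            se_c = float(np.sqrt(max(c @ fit.cov @ c, 0.0))) / LN2
            res[f"log2fc_{name}"][i] = est
            res[f"se_{name}"][i] = se_c
            if status[i] == "ok" and se_c > 0:
                _, p = wald_test(est, se_c)
                res[f"wald_p_{name}"][i] = p

        stat, p, ok = lrt_interaction(Y[i], X_full, X_red, s_arr, a_map)
        res["lrt_stat"][i] = stat
        if ok and status[i] == "ok":
            res["lrt_p"][i] = p
        elif not ok:
            gene_flags.append("lrt_no_convergence")

        if low_count[i] and status[i] == "ok":
            status[i] = "low_count"
        flags[i] = ";".join(gene_flags)

    # BH within each test family across tested genes only
    tested = status == "ok"
    for fam, src in (("padj_wt", "wald_p_wt"), ("padj_del", "wald_p_del"),
                     ("padj_interaction", "lrt_p")):
        p = np.where(tested, res[src], np.nan)
        res[fam] = bh_adjust(p)

    out = pd.DataFrame(res, index=df.index)
    out["status"] = status
    out["flags"] = flags
    out = out[FIT_COLUMNS]
    out.index.name = "gene"
    n_sig = int((out["padj_wt"] <= config.padj_threshold).sum())
    n_int = int((out["padj_interaction"] <= config.padj_threshold).sum())
    logger.info("significant total change at padj<=%g: %d; "
                "significant interaction: %d", config.padj_threshold, n_sig, n_int)
    return out
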