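"""Synthetic RNA-seq datasets with the exact structure the analysis assumes.

The generator emulates a bacterial stress experiment: two strains (wild type
and an sRNA deletion) each sequenced under a reference and a stress
condition, 13 libraries in four groups (4/3/3/3), ~4377 genes of which 195
are annotated direct sRNA targets and 56 more share an operon with a
target (251 operon-covered genes in total).  Counts are negative binomial
with library-specific size factors, a lognormal baseline, a 1/mean + const
dispersion trend with lognormal gene-to-gene scatter, and per-gene log2
effects: ``beta1`` (condition, sRNA-independent), ``beta2`` (genotype) and
``beta3`` (the sRNA's contribution, nonzero only for targets and, shared,
for their operon partners).

The deleted sRNA itself is simulated as a designated gene (id ``srna``)
that is strongly induced by stress in the wild type and has zero counts in
every deletion library, mirroring a clean gene knockout; it is excluded
from model fitting by default.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import GROUPS, CountMatrix, SampleDesign, TargetAnnotation


@dataclass
class SimulationConfig:
    """Generating parameters; defaults reproduce the study-scale scenario."""

    n_genes: int = 4377
    replicates: tuple = (4, 3, 3, 3)      # (ref/wt, stress/wt, ref/del, stress/del)
    n_direct_targets: int = 195
    n_operon_partners: int = 56           # targets + partners = 251 operon-covered genes
    fraction_condition_responsive: float = 0.08
    beta1_mean: float = 0.0
    beta1_sd: float = 1.5
    fraction_genotype_responsive: float = 0.02
    beta2_mean: float = 0.0
    beta2_sd: float = 0.5
    target_beta3_magnitude_mean: float = 1.5
    target_beta3_sd: float = 0.5
    repression_fraction: float = 0.8      # sign mix of target effects
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    dispersion_log_noise_sd: float = 0.3
    baseline_log_mean: float = 5.0        # natural-log scale of baseline expression
    baseline_log_sd: float = 1.5
    size_factor_log_sd: float = 0.2
    include_srna_gene: bool = True
    srna_gene_id: str = "srna"
    srna_induction_log2: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.replicates) != 4 or any(r < 1 for r in self.replicates):
            raise ValueError("replicates must be four positive integers")
        if self.n_direct_targets + self.n_operon_partners > self.n_genes:
            raise ValueError("targets plus operon partners exceed n_genes")
        for name in ("fraction_condition_responsive", "fraction_genotype_responsive",
                     "repression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend parameters must be nonnegative")


@dataclass
class SimulationTruth:
    """Generating parameters of a simulated dataset, for recovery tests."""

    genes: pd.DataFrame          # q, beta1, beta2, beta3, alpha, label per gene
    size_factors: pd.Series
    config: SimulationConfig


def sample_counts(rng: np.random.Generator, mean, alpha) -> np.ndarray:
    """Draw negative-binomial counts with the ``mu + alpha*mu**2`` variance
    parameterization used by the fitting module.  Zero means give zero
    counts exactly."""
    mu = np.asarray(mean, dtype=float)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    r = 1.0 / a[pos]
    out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return out


def _library_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    short = {("reference", "wildtype"): "ref_wt", ("stress", "wildtype"): "str_wt",
             ("reference", "deletion"): "ref_del", ("stress", "deletion"): "str_del"}
    for (cond, geno), n_rep in zip(GROUPS, config.replicates):
        for r in range(1, n_rep + 1):
            rows.append({"library": f"{short[(cond, geno)]}_{r}",
                         "condition": cond, "genotype": geno, "replicate": str(r)})
    return pd.DataFrame(rows).set_index("library")


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[CountMatrix, SampleDesign, TargetAnnotation, SimulationTruth]:
    """Generate one dataset: counts, sample sheet, target annotation and the
    generating truth.  Bit-identical for identical configs (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    lib_table = _library_layout(config)
    design = SampleDesign(lib_table)
    n_libs = len(lib_table)

    # gene roles: targets first, then operon partners, then the rest
    perm = rng.permutation(n)
    target_idx = perm[: config.n_direct_targets]
    partner_idx = perm[config.n_direct_targets:
                       config.n_direct_targets + config.n_operon_partners]
    label = np.array(["other"] * n, dtype=object)
    label[target_idx] = "direct_target"
    label[partner_idx] = "operon_with_target"

    # operons: each partner shares an operon with one target (round robin)
    operon_id = np.array([None] * n, dtype=object)
    if config.n_direct_targets > 0:
        for j, pi in enumerate(partner_idx):
            ti = target_idx[j % config.n_direct_targets]
            op = f"op{j % config.n_direct_targets:04d}"
            operon_id[pi] = op
            operon_id[ti] = op

    q = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))

    beta1 = np.zeros(n)
    responsive = rng.random(n) < config.fraction_condition_responsive
    beta1[responsive] = rng.normal(config.beta1_mean, config.beta1_sd,
                                   int(responsive.sum()))
    beta2 = np.zeros(n)
    geno_resp = rng.random(n) < config.fraction_genotype_responsive
    beta2[geno_resp] = rng.normal(config.beta2_mean, config.beta2_sd,
                                  int(geno_resp.sum()))

    beta3 = np.zeros(n)
    if len(target_idx):
        mag = rng.normal(config.target_beta3_magnitude_mean,
                         config.target_beta3_sd, len(target_idx))
        sign = np.where(rng.random(len(target_idx)) < config.repression_fraction,
                        -1.0, 1.0)
        beta3[target_idx] = sign * np.abs(mag)
        # operon partners inherit the effect of their co-transcribed target
        for j, pi in enumerate(partner_idx):
            beta3[pi] = beta3[target_idx[j % config.n_direct_targets]]

    alpha = (config.dispersion_a0 + config.dispersion_a1 / q) * np.exp(
        rng.normal(0.0, config.dispersion_log_noise_sd, n))
    alpha = np.maximum(alpha, 1e-8)

    s = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_libs))

    cond = (lib_table["condition"] == "stress").to_numpy().astype(float)
    geno = (lib_table["genotype"] == "wildtype").to_numpy().astype(float)
    # log2-scale linear predictor through the factorial design
    log2_effect = (np.outer(beta1, cond) + np.outer(beta2, geno)
                   + np.outer(beta3, cond * geno))
    mu = s[None, :] * q[:, None] * np.power(2.0, log2_effect)
    counts = sample_counts(rng, mu, alpha[:, None])

    gene_ids = list(genes)
    if config.include_srna_gene:
        gene_ids.append(config.srna_gene_id)
        q_s = np.exp(config.baseline_log_mean)
        mu_s = s * q_s * np.power(2.0, config.srna_induction_log2 * cond)
        mu_s = np.where(geno > 0, mu_s, 0.0)   # clean knockout: zero in deletion
        row = sample_counts(rng, mu_s, 0.05)
        counts = np.vstack([counts, row[None, :]])
        label = np.append(label, "srna")
        operon_id = np.append(operon_id, None)
        q = np.append(q, q_s)
        beta1 = np.append(beta1, config.srna_induction_log2)
        beta2 = np.append(beta2, 0.0)
        beta3 = np.append(beta3, 0.0)
        alpha = np.append(alpha, 0.05)

    count_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                            columns=lib_table.index)
    count_matrix = CountMatrix(count_df)

    ann = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    ann["is_direct_target"] = label == "direct_target"
    ann["operon_id"] = pd.array([op if op is not None else pd.NA
                                 for op in operon_id], dtype="string")
    ann["provenance"] = "synthetic"
    annotation = TargetAnnotation(ann)

    truth_genes = pd.DataFrame(
        {"q": q, "beta1": beta1, "beta2": beta2, "beta3": beta3,
         "alpha": alpha, "label": label},
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = SimulationTruth(
        genes=truth_genes,
        size_factors=pd.Series(s, index=lib_table.index, name="size_factor"),
        config=config,
    )
    return count_matrix, design, annotation, truth


# ---------------------------------------------------------------------------
# parameter-recovery evaluation

@dataclass
class RecoveryReport:
    """Accuracy of the fit against the generating truth."""

    coefficients: pd.DataFrame    # bias, rmse, coverage per beta1..beta3
    interaction: pd.DataFrame     # rejection counts/rates by gene label
    null_rejection_rate: float    # padj-based rate among true-null genes
    power: float                  # padj-based rate among true-effect genes

    def __str__(self) -> str:
        lines = ["coefficient recovery:", self.coefficients.to_string(),
                 "", "interaction test by label:", self.interaction.to_string(),
                 "", f"null rejection rate (padj): {self.null_rejection_rate:.4f}",
                 f"power (padj): {self.power:.4f}"]
        return "\n".join(lines)


def evaluate_recovery(fit_table: pd.DataFrame, truth: SimulationTruth,
                      padj_threshold: float = 0.1) -> RecoveryReport:
    """Compare fitted coefficients and interaction calls with the generating
    truth: per-coefficient bias, RMSE and 95% Wald interval coverage, and
    empirical rejection rates of the interaction test at the given adjusted
    p-value threshold, stratified by gene label."""
    tg = truth.genes
    missing = fit_table.index.difference(tg.index)
    if len(missing):
        raise ValueError(f"fit table contains genes absent from the truth: "
                         f"{list(missing[:5])}")
    tg = tg.reindex(fit_table.index)
    ok = fit_table["status"] == "ok"

    rows = {}
    for i in (1, 2, 3):
        est = fit_table.loc[ok, f"beta{i}"]
        se = fit_table.loc[ok, f"se{i}"]
        true = tg.loc[ok, f"beta{i}"]
        err = est - true
        cover = (np.abs(err) <= 1.96 * se).mean()
        rows[f"beta{i}"] = {"n": int(ok.sum()), "bias": float(err.mean()),
                            "rmse": float(np.sqrt((err ** 2).mean())),
                            "coverage95": float(cover)}
    coef = pd.DataFrame(rows).T

    rejected = fit_table["padj_interaction"] <= padj_threshold
    tested = fit_table["padj_interaction"].notna()
    null = tg["beta3"] == 0
    strata = []
    for lab, sub in tg.groupby("label"):
        idx = sub.index
        t = tested.reindex(idx)
        r = rejected.reindex(idx) & t
        strata.append({"label": lab, "n_tested": int(t.sum()),
                       "n_rejected": int(r.sum()),
                       "rate": float(r.sum() / t.sum()) if t.sum() else float("nan")})
    interaction = pd.DataFrame(strata).set_index("label")

    null_tested = tested & null
    eff_tested = tested & ~null
    null_rate = float((rejected & null_tested).sum() / null_tested.sum()) \
        if null_tested.sum() else float("nan")
    power = float((rejected & eff_tested).sum() / eff_tested.sum()) \
        if eff_tested.sum() else float("nan")
    return RecoveryReport(coefficients=coef, interaction=interaction,
                          null_rejection_rate=null_rate, power=power)
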