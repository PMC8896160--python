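"""Operon propagation of target labels and hypergeometric enrichment tests.

Bacterial operons are co-transcribed, so destabilisation of one cistron by
an sRNA propagates to its operon partners.  Genes sharing an operon with an
annotated direct target are therefore labelled ``operon_with_target``
(direct targets keep their own label; the two labels never co-occur).

Enrichment of targets / operon partners among significant gene sets is
assessed by the one-sided (upper-tail, over-representation) hypergeometric
test.  Four planned tests are reported with raw p-values:

1. direct targets among genes with a significant total change;
2. operon partners among genes with a significant total change;
3. direct targets among genes with a significant sRNA interaction, with the
   total-change-significant set as the population (the interaction test
   only resolves genes whose level changed at all);
4. operon partners among interaction-significant genes, same population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .data_io import TargetAnnotation


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``
    (population ``N`` with ``K`` successes, ``n`` draws), accumulated in log
    space for numerical safety at very small tails."""
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError("K and n cannot exceed N")
    lo, hi = max(0, n + K - N), min(n, K)
    if k < lo or k > hi + 1:
        raise ValueError(f"k={k} outside the support [{lo}, {hi}]")
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def propagate_operons(annotation: TargetAnnotation) -> TargetAnnotation:
    """Add a ``label`` column: genes sharing an ``operon_id`` with a direct
    target become ``operon_with_target``; direct targets stay
    ``direct_target`` (direct takes precedence); everything else is
    ``other``.  Genes without an operon id are unaffected."""
    df = annotation.table.copy()
    label = pd.Series("other", index=df.index, dtype=object)
    has_op = df["operon_id"].notna()
    target_operons = set(df.loc[df["is_direct_target"] & has_op, "operon_id"])
    in_target_operon = has_op & df["operon_id"].isin(target_operons)
    label[in_target_operon] = "operon_with_target"
    label[df["is_direct_target"]] = "direct_target"
    df["label"] = label
    return TargetAnnotation(df)


ENRICHMENT_COLUMNS = ["name", "N", "K", "n", "k", "expected", "p"]


def _one_test(name: str, population: pd.Index, successes: set,
              drawn: set) -> dict:
    N = len(population)
    K = len(successes & set(population))
    n = len(drawn & set(population))
    k = len(drawn & successes & set(population))
    p = hypergeom_tail(N, K, n, k) if N > 0 and n > 0 else 1.0
    expected = n * K / N if N > 0 else 0.0
    return dict(name=name, N=N, K=K, n=n, k=k, expected=expected, p=p)


def enrichment_suite(fit_table: pd.DataFrame, annotation: TargetAnnotation,
                     padj_threshold: float = 0.1) -> pd.DataFrame:
    """Run the four planned over-representation tests on a fitted table and
    a propagated annotation; returns one row per test."""
    if "label" not in annotation.table.columns:
        annotation = propagate_operons(annotation)
    lab = annotation.table["label"]
    targets = set(lab.index[lab == "direct_target"])
    partners = set(lab.index[lab == "operon_with_target"])

    tested = fit_table.index[fit_table["padj_wt"].notna()]
    sig_total = set(fit_table.index[fit_table["padj_wt"] <= padj_threshold])
    sig_int = set(fit_table.index[fit_table["padj_interaction"] <= padj_threshold])

    rows = [
        _one_test("targets_in_condition_significant", tested, targets, sig_total),
        _one_test("operon_partners_in_condition_significant", tested, partners, sig_total),
        _one_test("targets_in_interaction_significant",
                  pd.Index(sorted(sig_total)), targets, sig_int),
        _one_test("operon_partners_in_interaction_significant",
                  pd.Index(sorted(sig_total)), partners, sig_int),
    ]
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS).set_index("name")
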