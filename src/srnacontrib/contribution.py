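"""Decomposition of per-gene expression changes into sRNA-dependent and
sRNA-independent components.

The total log2 fold change of a gene in the wild type under stress splits
exactly as ``log2FC_wt = beta1 + beta3``: the part that survives deletion of
the sRNA (``beta1``, equal to ``log2FC_del``) plus the sRNA's own
contribution (``beta3``, the interaction term).  The *contribution fraction*
``beta3 / log2FC_wt`` is computed on the log2 scale; when the two components
act in opposite directions the fraction can exceed 1 and the gene is
categorised ``opposing``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import TargetAnnotation

CATEGORIES = ("concordant", "opposing", "srna_only", "independent_only", "undefined")


def fold_change(log2fc: float):
    """Convert a log2 fold change to a linear fold change, ``2**log2fc``."""
    return np.power(2.0, log2fc)


def ddct_quantity(delta_delta_ct: float):
    """qPCR relative quantity ``2**ddCt`` (target normalized to a reference
    gene and relative to a calibrator sample)."""
    return np.power(2.0, delta_delta_ct)


def contribution_fraction(log2fc_wt: float, beta3: float,
                          epsilon: float = 0.1) -> tuple[float, str]:
    """Share of the total change attributed to the sRNA, plus a direction
    category.

    The fraction ``beta3 / log2fc_wt`` is defined only when the total change
    is itself appreciable (``|log2fc_wt| >= epsilon``); it may exceed 1 when
    the sRNA opposes the sRNA-independent component.  Categories:

    * ``srna_only``         — the sRNA-independent part is ~0 (|beta1| < eps)
    * ``independent_only``  — the sRNA's part is ~0 (|beta3| < eps)
    * ``concordant``        — both act in the same direction
    * ``opposing``          — they act in opposite directions
    * ``undefined``         — both components ~0
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    beta1 = log2fc_wt - beta3
    small1 = abs(beta1) < epsilon
    small3 = abs(beta3) < epsilon
    if small1 and small3:
        category = "undefined"
    elif small1:
        category = "srna_only"
    elif small3:
        category = "independent_only"
    elif beta1 * beta3 > 0:
        category = "concordant"
    else:
        category = "opposing"
    if abs(log2fc_wt) >= epsilon:
        fraction = beta3 / log2fc_wt
    else:
        fraction = float("nan")
    return fraction, category


CONTRIB_COLUMNS = [
    "log2fc_wt", "log2fc_del", "beta2", "beta3",
    "fraction", "percent", "category", "fold_change_wt",
    "significant_total", "significant_interaction", "label",
]


def decompose(fit_table: pd.DataFrame, padj_threshold: float = 0.1,
              epsilon: float = 0.1,
              annotation: TargetAnnotation | None = None) -> pd.DataFrame:
    """Build the per-gene contribution table from a fitted-model table.

    Rows with a non-ok fit status keep NaN numeric fields and category
    ``undefined``.  If a (propagated) annotation is given, each gene also
    gets a ``label`` in {direct_target, operon_with_target, other}.
    """
    genes = fit_table.index
    ok = fit_table["status"] == "ok"
    log2fc_wt = fit_table["log2fc_wt"].where(ok)
    beta3 = fit_table["beta3"].where(ok)

    fractions = np.full(len(genes), np.nan)
    categories = np.array(["undefined"] * len(genes), dtype=object)
    for i, (t, b3) in enumerate(zip(log2fc_wt, beta3)):
        if np.isfinite(t) and np.isfinite(b3):
            fractions[i], categories[i] = contribution_fraction(t, b3, epsilon)

    out = pd.DataFrame(index=genes)
    out["log2fc_wt"] = log2fc_wt
    out["log2fc_del"] = fit_table["log2fc_del"].where(ok)
    out["beta2"] = fit_table["beta2"].where(ok)
    out["beta3"] = beta3
    out["fraction"] = fractions
    out["percent"] = np.round(fractions * 100.0)
    out["category"] = categories
    out["fold_change_wt"] = fold_change(log2fc_wt)
    out["significant_total"] = fit_table["padj_wt"] <= padj_threshold
    out["significant_interaction"] = fit_table["padj_interaction"] <= padj_threshold
    out["label"] = classify_genes(genes, annotation)
    out.index.name = "gene"
    return out[CONTRIB_COLUMNS]


def classify_genes(genes, annotation: TargetAnnotation | None) -> pd.Series:
    """Per-gene label from a propagated annotation: ``direct_target``,
    ``operon_with_target`` or ``other`` (genes absent from the annotation
    are ``other``)."""
    genes = pd.Index(genes)
    if annotation is None:
        return pd.Series("other", index=genes, name="label")
    table = annotation.table
    if "label" in table.columns:
        lab = table["label"]
    else:
        lab = table["is_direct_target"].map({True: "direct_target", False: "other"})
    out = lab.reindex(genes).fillna("other")
    out.name = "label"
    return out


def classify_gene(gene: str, record: pd.Series,
                  annotation: TargetAnnotation | None) -> set:
    """Label set for a single gene: its annotation class plus any
    significance flags from its contribution record."""
    labels = {classify_genes([gene], annotation).iloc[0]}
    if bool(record.get("significant_total", False)):
        labels.add("significant_total")
    if bool(record.get("significant_interaction", False)):
        labels.add("significant_interaction")
    return labels
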