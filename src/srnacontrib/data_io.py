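"""Reading, validation and writing of the pipeline's tabular inputs and outputs.

All files are tab-separated UTF-8 with "." as the decimal separator and no
quoting, the dialect emitted by the common RNA-seq count quantifiers.

The factor vocabulary is fixed: condition is one of ``reference``/``stress``
and genotype is one of ``wildtype``/``deletion``.  Study-specific labels
(e.g. ``iron+``/``iron-``, ``wt``/``dRyhB``) are translated at read time via
alias maps, which keeps the core of the package agnostic to the particular
sRNA and stress being analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("reference", "stress")
GENOTYPES = ("wildtype", "deletion")

#: the four condition/genotype groups in canonical order
GROUPS = (
    ("reference", "wildtype"),
    ("stress", "wildtype"),
    ("reference", "deletion"),
    ("stress", "deletion"),
)


class ValidationError(ValueError):
    """Raised when an input table violates one of its documented invariants."""


@dataclass(frozen=True)
class CountMatrix:
    """A gene x library matrix of raw (un-normalized) read counts.

    ``counts`` is a DataFrame indexed by gene id with one column per library;
    entries are nonnegative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate library identifiers: {dups[:5]}")
        if df.shape[0] < 1 or df.shape[1] < 4:
            raise ValidationError(
                f"need at least 1 gene and 4 libraries, got {df.shape[0]} x {df.shape[1]}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            g, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {df.index[g]!r} in library {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SampleDesign:
    """Per-library factor labels for the 2x2 condition x genotype design.

    ``table`` is indexed by library id and has columns ``condition``,
    ``genotype`` and ``replicate`` (free-text replicate label).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate library identifiers in sample sheet: {dups[:5]}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown condition level(s) {sorted(bad_cond)}; allowed: {CONDITIONS}"
            )
        bad_geno = set(df["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(
                f"unknown genotype level(s) {sorted(bad_geno)}; allowed: {GENOTYPES}"
            )
        sizes = self.group_sizes()
        missing = [g for g, n in sizes.items() if n == 0]
        if missing:
            raise ValidationError(
                "empty condition/genotype group(s): "
                + ", ".join(f"{c}/{g}" for c, g in missing)
            )
        small = [g for g, n in sizes.items() if n < 2]
        if small:
            warnings.warn(
                "group(s) with fewer than 2 replicates: "
                + ", ".join(f"{c}/{g}" for c, g in small),
                stacklevel=2,
            )

    @property
    def library_ids(self) -> list:
        return list(self.table.index)

    def group_sizes(self) -> dict:
        out = {}
        for cond, geno in GROUPS:
            mask = (self.table["condition"] == cond) & (self.table["genotype"] == geno)
            out[(cond, geno)] = int(mask.sum())
        return out


@dataclass(frozen=True)
class TargetAnnotation:
    """Per-gene annotation of direct sRNA targets and operon membership.

    ``table`` is indexed by gene id with columns ``is_direct_target`` (bool),
    ``operon_id`` (nullable string) and ``provenance`` (free text).  After
    operon propagation (see :mod:`srnacontrib.enrichment`) a ``label`` column
    in {direct_target, operon_with_target, other} is present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"gene(s) listed more than once in annotation: {dups[:5]}")

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    @property
    def n_targets(self) -> int:
        return int(self.table["is_direct_target"].sum())


_READ_KW = dict(sep="\t", dtype_backend="numpy_nullable")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_bool(series: pd.Series, colname: str) -> pd.Series:
    out = []
    for v in series:
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out.append(True)
        elif s in _FALSY:
            out.append(False)
        else:
            raise ValidationError(f"cannot interpret {v!r} in column {colname!r} as boolean")
    return pd.Series(out, index=series.index)


def read_counts(path) -> CountMatrix:
    """Read a gene x library count matrix from a TSV file.

    The header row gives library ids; the first column gives gene ids.
    Parse order of both axes is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-integer count for gene {gene!r} in library {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        neg = vals < 0
        if neg.any():
            gene = df.index[neg.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"negative count for gene {gene!r} in library {col!r}: {df.loc[gene, col]!r}"
            )
    return CountMatrix(df.astype(np.int64))


def read_samples(path, condition_aliases: dict | None = None,
                 genotype_aliases: dict | None = None) -> SampleDesign:
    """Read the sample sheet (columns ``library``, ``condition``, ``genotype``,
    optional ``replicate``), mapping study-specific factor labels to the
    canonical vocabulary via the alias dicts."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library", "condition", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {sorted(missing)}")
    df = df.set_index("library")
    if condition_aliases:
        df["condition"] = df["condition"].replace(condition_aliases)
    if genotype_aliases:
        df["genotype"] = df["genotype"].replace(genotype_aliases)
    if "replicate" not in df.columns:
        df["replicate"] = [str(i + 1) for i in range(len(df))]
    return SampleDesign(df[["condition", "genotype", "replicate"]])


def read_annotation(path) -> TargetAnnotation:
    """Read the target annotation table (columns ``gene``, ``is_direct_target``,
    optional ``operon_id`` and ``provenance``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "is_direct_target"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
    df = df.set_index("gene")
    out = pd.DataFrame(index=df.index)
    out["is_direct_target"] = _parse_bool(df["is_direct_target"], "is_direct_target")
    if "operon_id" in df.columns:
        op = df["operon_id"].astype("string")
        op = op.where(~op.isin(["", "nan", "NA", "None"]), pd.NA)
        out["operon_id"] = op
    else:
        out["operon_id"] = pd.Series(pd.NA, index=df.index, dtype="string")
    out["provenance"] = df["provenance"] if "provenance" in df.columns else ""
    return TargetAnnotation(out)


def check_pairing(counts: CountMatrix, design: SampleDesign) -> None:
    """Reject a count matrix / sample sheet pair whose library sets differ."""
    cm = set(counts.library_ids)
    ds = set(design.library_ids)
    if cm != ds:
        only_counts = sorted(cm - ds)
        only_design = sorted(ds - cm)
        raise ValidationError(
            "library sets differ between count matrix and sample sheet; "
            f"only in counts: {only_counts[:5]}; only in sample sheet: {only_design[:5]}"
        )


def flag_unknown_genes(annotation: TargetAnnotation, counts: CountMatrix) -> pd.Series:
    """Boolean Series (indexed like the annotation) marking annotated genes
    that are absent from the count matrix.  Such genes are retained but take
    no part in enrichment populations."""
    present = set(counts.gene_ids)
    return pd.Series(
        [g not in present for g in annotation.gene_ids],
        index=annotation.table.index,
        name="absent_from_counts",
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a stable column order and floats
    rendered at 6 significant digits."""
    table.to_csv(path, sep="\t", float_format="%.6g", index=True)


def read_results(path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)
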