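"""rpkm expression profiles and the high-light/low-light comparison.

rpkm = count / ((gene length / 1000) * (library size / 10^6)), with the
library size being uniquely mapped reads per sample.  Replicate samples of
the same condition are averaged on the rpkm scale and the replicate count
recorded.  The comparison between conditions is descriptive — log2 fold
changes with a pseudocount and genome-wide expression ranks — matching how
LH transcript levels are usually reported (no differential-test model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("HL", "LL", "ELL", "other")


def compute_rpkm(count, length_bp, library_size):
    """Reads per kilobase of gene per million uniquely mapped reads.

    Vectorized: any argument may be an array/Series; shapes broadcast.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("gene length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    return count / ((length_bp / 1000.0) * (library_size / 1e6))


def rpkm_matrix(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Per-sample rpkm for a gene x sample count matrix."""
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise KeyError(f"no length for gene(s): {list(missing)[:5]}")
    lengths = gene_lengths.loc[counts.index].to_numpy(float)[:, None]
    libs = library_sizes.loc[counts.columns].to_numpy(float)[None, :]
    values = compute_rpkm(counts.to_numpy(float), lengths, libs)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def condition_means(
    rpkm: pd.DataFrame, condition_of_sample: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Average replicate rpkm per condition.

    Returns (gene x condition means, replicate count per condition).
    """
    cond = pd.Series({s: condition_of_sample[s] for s in rpkm.columns})
    means = rpkm.T.groupby(cond).mean().T
    n_reps = cond.value_counts()
    return means, n_reps


@dataclass
class ClassExpressionMatrix:
    """Per-gene and per-category-summed rpkm by strain, LH category, condition."""

    per_gene: pd.DataFrame  # columns: strain, gene, category, condition, rpkm
    sums: pd.DataFrame      # index (strain, category), columns conditions
    absent: list            # (strain, category) cells with no gene
    warnings: list          # classified genes missing from the counts


def build_class_matrix(
    condition_rpkm: pd.DataFrame,
    classifications: pd.DataFrame,
    strain: str = "strain",
) -> ClassExpressionMatrix:
    """Aggregate rpkm by LH category for one strain.

    *classifications* needs columns ``gene`` and ``category``; genes present
    there but absent from the rpkm table are reported in ``warnings``;
    categories with no gene in the strain appear in ``absent`` rather than
    as zeros.
    """
    from .classify import INVENTORY_CATEGORIES

    class_of = dict(zip(classifications["gene"], classifications["category"]))
    missing = [g for g in class_of if g not in condition_rpkm.index]
    records = []
    for gene, category in class_of.items():
        if gene in missing:
            continue
        for condition in condition_rpkm.columns:
            records.append(dict(
                strain=strain, gene=gene, category=category,
                condition=condition,
                rpkm=float(condition_rpkm.at[gene, condition]),
            ))
    per_gene = pd.DataFrame(records,
                            columns=["strain", "gene", "category", "condition", "rpkm"])
    if len(per_gene):
        sums = per_gene.pivot_table(index=["strain", "category"], columns="condition",
                                    values="rpkm", aggfunc="sum")
    else:
        sums = pd.DataFrame()
    present = set(per_gene["category"]) if len(per_gene) else set()
    absent = [(strain, c) for c in INVENTORY_CATEGORIES if c not in present]
    return ClassExpressionMatrix(per_gene, sums, absent, missing)


def compare_conditions(
    condition_rpkm: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 fold change cond_a -> cond_b plus genome-wide ranks.

    lfc = log2((rpkm_b + c) / (rpkm_a + c)); the result is sorted by lfc
    descending and carries each gene's expression rank (1 = highest rpkm)
    within each condition.
    """
    for cond in (cond_a, cond_b):
        if cond not in condition_rpkm.columns:
            raise KeyError(f"condition {cond!r} not present")
    a = condition_rpkm[cond_a].astype(float)
    b = condition_rpkm[cond_b].astype(float)
    lfc = np.log2((b + pseudocount) / (a + pseudocount))
    out = pd.DataFrame({
        f"rpkm_{cond_a}": a,
        f"rpkm_{cond_b}": b,
        "log2_fold_change": lfc,
        f"rank_{cond_a}": a.rank(ascending=False, method="min").astype(int),
        f"rank_{cond_b}": b.rank(ascending=False, method="min").astype(int),
    })
    return out.sort_values("log2_fold_change", ascending=False)
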