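"""Gene-category enrichment of significant gene lists against a chip background.

For each category the 2x2 table

    [significant genes in category,   significant genes not in category]
    [chip genes in category,          chip genes not in category]

is tested with an uncorrected Pearson chi-square; the enrichment score is
-log10(p).  The chip background includes the significant genes by default
(an ``exclude_sig_from_background`` toggle subtracts them).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._util import ValidationError
from .data_io import annotation_genes


class CategoryMap:
    """category_id -> gene set, together with the chip-wide gene universe."""

    def __init__(self, categories: dict[str, set[str]], universe: set[str]):
        self.universe = set(universe)
        self.categories = {}
        self.empty_categories = []
        for cid, genes in categories.items():
            inter = set(genes) & self.universe
            self.categories[cid] = inter
            if not inter:
                self.empty_categories.append(cid)

    @classmethod
    def from_tsv(cls, path, universe: set[str]) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["category_id", "gene"], dtype=str)
        grouped = {cid: set(g["gene"]) for cid, g in df.groupby("category_id")}
        return cls(grouped, universe)


def significant_genes(dml_loci, annotation: pd.DataFrame) -> set[str]:
    """Genes with at least one locus in the DML list."""
    genes = annotation_genes(annotation.loc[annotation.index.intersection(pd.Index(dml_loci))])
    return {g for lst in genes for g in lst}


def enrichment_score(
    sig_genes,
    category_map: CategoryMap,
    exclude_sig_from_background: bool = False,
) -> pd.DataFrame:
    """Per-category chi-square enrichment, ranked by score descending.

    Columns: n_sig_in_cat, n_sig, n_chip_in_cat, n_chip, chi2, p, score,
    flags.  Degenerate tables (empty category, category spanning the whole
    background, zero margin) are flagged with score 0 rather than dropped.
    An empty significant list flags every category ``undefined``.
    """
    sig = set(sig_genes)
    dropped = sig - category_map.universe
    if dropped:
        warnings.warn(f"{len(dropped)} significant gene(s) not on the chip; dropped", stacklevel=2)
        sig &= category_map.universe

    background = category_map.universe - sig if exclude_sig_from_background else category_map.universe
    n_sig, n_chip = len(sig), len(background)

    rows = []
    for cid, genes in category_map.categories.items():
        cat_bg = genes - sig if exclude_sig_from_background else genes
        in_cat_sig = len(sig & genes)
        in_cat_chip = len(cat_bg & background)
        flags = []
        chi2 = p = score = np.nan
        if n_sig == 0:
            flags.append("undefined")
        elif in_cat_chip == 0 or in_cat_chip == n_chip:
            flags.append("degenerate")
            chi2, p, score = 0.0, 1.0, 0.0
        else:
            table = np.array(
                [[in_cat_sig, n_sig - in_cat_sig], [in_cat_chip, n_chip - in_cat_chip]]
            )
            if np.any(table.sum(axis=0) == 0):
                flags.append("degenerate")
                chi2, p, score = 0.0, 1.0, 0.0
            else:
                chi2, p, _, _ = chi2_contingency(table, correction=False)
                score = -np.log10(max(p, np.finfo(float).tiny))
        rows.append([cid, in_cat_sig, n_sig, in_cat_chip, n_chip, chi2, p, score, ";".join(flags)])

    out = pd.DataFrame(
        rows,
        columns=["category_id", "n_sig_in_cat", "n_sig", "n_chip_in_cat", "n_chip", "chi2", "p", "score", "flags"],
    ).set_index("category_id")
    return out.sort_values("score", ascending=False, na_position="last")
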