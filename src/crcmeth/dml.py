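"""DML calling, interaction classification, region tabulation, enrichment
inputs — the post-scan half of the pipeline.

A *differentially methylated locus* (DML) in a stratum passes both a
Benjamini–Hochberg FDR threshold on the paired test (default q <= 0.001) and
a magnitude filter on the tumor-minus-normal mean beta difference (default
|delta beta| >= 0.2).  Interaction-significant loci pass an FDR threshold
(default 0.05) on the Tumor*MSI term; no magnitude filter is applied to
interaction membership.

Loci are then classified by their membership in the three sets
(MSI-DML, MSS-DML, interaction):

=========  ============================================================
category   meaning
=========  ============================================================
A          DML in both strata, no interaction (shared tumor effect)
B          MSI-DML with interaction, not MSS-DML (MSI-specific)
C          DML in both strata *and* interaction (both, different size)
D          MSS-DML with interaction, not MSI-DML (MSS-specific)
none       everything else
=========  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError, round_half_up

CATEGORIES = ("A", "B", "C", "D", "none")


@dataclass
class DmlThresholds:
    """Significance and magnitude thresholds for DML calling."""

    q_dml: float = 0.001
    q_interaction: float = 0.05
    min_abs_delta: float = 0.2
    bonferroni_alpha: float = 0.05

    def validate(self) -> "DmlThresholds":
        for name in ("q_dml", "q_interaction", "min_abs_delta", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        return self


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries are propagated."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_dml(results: pd.DataFrame, stratum: str, thresholds: DmlThresholds | None = None) -> pd.DataFrame:
    """Call DML for one stratum ('msi' or 'mss') from a scan result table.

    Returns a per-locus frame with the stratum q-value, delta beta,
    ``is_dml`` and ``direction`` (hyper/hypo for called loci).  Loci whose
    scan carries flags are never called; the reason is recorded.
    """
    thresholds = (thresholds or DmlThresholds()).validate()
    stratum = stratum.lower()
    if stratum not in ("msi", "mss"):
        raise ValidationError("stratum must be 'msi' or 'mss'")
    p = results[f"p_tumor_{stratum}"]
    delta = results[f"delta_beta_{stratum}"]
    q = bh_fdr(p)
    flagged = results["flags"].fillna("").astype(str) != ""
    is_dml = (q <= thresholds.q_dml) & (np.abs(delta) >= thresholds.min_abs_delta) & ~flagged
    is_dml = is_dml.fillna(False)
    out = pd.DataFrame(
        {
            "q": q,
            "delta_beta": delta,
            "is_dml": is_dml,
            "direction": np.where(is_dml, np.where(delta > 0, "hyper", "hypo"), ""),
            "excluded_reason": np.where(flagged, results["flags"].fillna(""), ""),
        },
        index=results.index,
    )
    return out


def interaction_set(results: pd.DataFrame, thresholds: DmlThresholds | None = None) -> pd.Series:
    """Boolean membership in the interaction-significant set (BH on p_interaction)."""
    thresholds = (thresholds or DmlThresholds()).validate()
    q = bh_fdr(results["p_interaction"])
    flagged = results["flags"].fillna("").astype(str) != ""
    member = pd.Series(q <= thresholds.q_interaction, index=results.index) & ~flagged
    return member.fillna(False)


def classify_interaction(msi_dml: pd.Series, mss_dml: pd.Series, interaction: pd.Series) -> pd.Series:
    """Map the membership triple to the A/B/C/D/none category per locus."""
    if not (msi_dml.index.equals(mss_dml.index) and msi_dml.index.equals(interaction.index)):
        raise ValidationError("membership series must share one locus universe")
    a, b, i = msi_dml.astype(bool), mss_dml.astype(bool), interaction.astype(bool)
    cat = pd.Series("none", index=a.index, name="category")
    cat[a & b & ~i] = "A"
    cat[a & ~b & i] = "B"
    cat[a & b & i] = "C"
    cat[~a & b & i] = "D"
    return cat


def venn_counts(set_a, set_b) -> dict[str, int]:
    """Two-set overlap arithmetic: exclusive counts and the intersection."""
    sa, sb = set(set_a), set(set_b)
    shared = len(sa & sb)
    return {"only_a": len(sa) - shared, "only_b": len(sb) - shared, "shared": shared}


def build_catalog(results: pd.DataFrame, thresholds: DmlThresholds | None = None) -> pd.DataFrame:
    """Full DML catalog from a merged scan result table.

    Columns: q_msi, q_mss, q_interaction, delta_msi, delta_mss,
    direction_msi, direction_mss, in_msi_dml, in_mss_dml, in_interaction,
    category.
    """
    thresholds = (thresholds or DmlThresholds()).validate()
    msi = call_dml(results, "msi", thresholds)
    mss = call_dml(results, "mss", thresholds)
    inter = interaction_set(results, thresholds)
    cat = classify_interaction(msi["is_dml"], mss["is_dml"], inter)
    return pd.DataFrame(
        {
            "q_msi": msi["q"],
            "q_mss": mss["q"],
            "q_interaction": bh_fdr(results["p_interaction"]),
            "delta_msi": msi["delta_beta"],
            "delta_mss": mss["delta_beta"],
            "direction_msi": msi["direction"],
            "direction_mss": mss["direction"],
            "in_msi_dml": msi["is_dml"],
            "in_mss_dml": mss["is_dml"],
            "in_interaction": inter,
            "category": cat,
        },
        index=results.index,
    )


# ---------------------------------------------------------------------------
# Region tabulation
# ---------------------------------------------------------------------------

_REGION_ORDER = ("Island", "N_Shelf", "N_Shore", "S_Shelf", "S_Shore", "OpenSea")


def tabulate_regions(
    dml: pd.DataFrame,
    annotation: pd.DataFrame,
    chip_totals: dict[str, int],
) -> pd.DataFrame:
    """Region table for a DML set: hypo/hyper/total counts, % of the DML
    set, chip counts and % of the chip, with a Total row.

    ``dml`` needs a boolean selection already applied (one row per DML
    locus) and a ``direction`` column with 'hyper'/'hypo'.  Every DML locus
    must be annotated.
    """
    missing = [str(i) for i in dml.index if i not in annotation.index]
    if missing:
        raise ValidationError(f"unannotated DML locus IDs: {', '.join(missing[:10])}")
    region = annotation.loc[dml.index, "region"] if len(dml) else pd.Series(dtype=object)
    grand_total = len(dml)
    chip_grand = sum(chip_totals.values())

    rows = []
    for reg in _REGION_ORDER:
        sel = dml[region == reg] if len(dml) else dml
        hypo = int((sel["direction"] == "hypo").sum()) if len(sel) else 0
        hyper = int((sel["direction"] == "hyper").sum()) if len(sel) else 0
        total = hypo + hyper
        pct_dml = round_half_up(100 * total / grand_total, 2) if grand_total else 0.0
        chip_n = chip_totals.get(reg, 0)
        pct_chip = round_half_up(100 * chip_n / chip_grand, 2) if chip_grand else 0.0
        rows.append([reg, hypo, hyper, total, pct_dml, chip_n, pct_chip])
    rows.append(
        [
            "Total",
            sum(r[1] for r in rows),
            sum(r[2] for r in rows),
            sum(r[3] for r in rows),
            round_half_up(sum(r[4] for r in rows), 2),
            chip_grand,
            round_half_up(sum(r[6] for r in rows), 2),
        ]
    )
    return pd.DataFrame(
        rows,
        columns=["region", "hypo", "hyper", "total", "pct_of_dml", "chip_count", "pct_of_chip"],
    ).set_index("region")


# ---------------------------------------------------------------------------
# Promoter-island strong-interaction list
# ---------------------------------------------------------------------------


def promoter_island_filter(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: DmlThresholds | None = None,
) -> pd.DataFrame:
    """Strong-interaction list restricted to promoter-associated island loci.

    The universe is the set of annotated loci with region == Island and the
    promoter flag set; the Bonferroni threshold is ``bonferroni_alpha``
    divided by the universe size.  Returns the loci whose interaction p
    clears it, with gene symbols and hyper/hypo direction (from the overall
    tumor-minus-normal delta).
    """
    thresholds = (thresholds or DmlThresholds()).validate()
    ann = annotation.loc[annotation.index.intersection(results.index)]
    universe = ann.index[(ann["region"] == "Island") & ann["promoter_associated"]]
    if len(universe) == 0:
        import warnings

        warnings.warn("promoter-island universe is empty", stacklevel=2)
        return pd.DataFrame(columns=["p_interaction", "bonferroni_threshold", "gene_symbols", "direction"])
    threshold = thresholds.bonferroni_alpha / len(universe)
    sub = results.loc[universe]
    hits = sub[sub["p_interaction"] < threshold]
    direction = np.where(hits["delta_beta_all"] > 0, "hyper", "hypo")
    return pd.DataFrame(
        {
            "p_interaction": hits["p_interaction"],
            "bonferroni_threshold": threshold,
            "gene_symbols": annotation.loc[hits.index, "gene_symbols"],
            "direction": direction,
        },
        index=hits.index,
    )
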