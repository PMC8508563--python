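"""Paired expression analysis: fold changes with 95% CIs, the Tumor*MSI
interaction scan on log2 expression, and gene-set average folds.

Fold changes use the signed convention common in array software: for a
tumor/normal ratio r = 2^(mean paired log2 difference), the reported fold is
r when r >= 1 and -1/r when r < 1, so |fold| >= 1 always and a fold of
-1.25 reads "25% down in the tumor".  Confidence intervals are t-based on
the paired log2 differences and back-transformed with the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError
from .anova import genomewide_scan
from .data_io import PairingReport


def signed_fold(ratio: float) -> float:
    """Map a positive ratio to the signed fold convention (|fold| >= 1)."""
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


@dataclass
class FoldChangeResult:
    id: str
    group: str  # 'MSI', 'MSS' or 'all'
    n_pairs: int
    log2fc: float
    fold: float  # signed convention
    ci_low: float
    ci_high: float
    flags: list = field(default_factory=list)


def _pairs_for_group(sheet: pd.DataFrame, pairing: PairingReport, group: str):
    status = sheet.drop_duplicates("person_id").set_index("person_id")["msi_status"]
    if group == "all":
        return list(pairing.pairs.items())
    return [(p, tn) for p, tn in pairing.pairs.items() if status[p] == group]


def _fold_from_diffs(diffs: np.ndarray, id_: str, group: str, conf: float) -> FoldChangeResult:
    n = len(diffs)
    if n < 2:
        return FoldChangeResult(id_, group, n, np.nan, np.nan, np.nan, np.nan, ["insufficient_pairs"])
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    flags = []
    if np.ptp(diffs) == 0:  # identical differences: no spread
        lo = hi = mean
        flags.append("degenerate_ci")
    else:
        half = stats.t.ppf(0.5 + conf / 2, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    return FoldChangeResult(
        id_,
        group,
        n,
        float(mean),
        signed_fold(2.0**mean),
        signed_fold(2.0**lo),
        signed_fold(2.0**hi),
        flags,
    )


def paired_fold_change(
    expr: pd.Series,
    sheet: pd.DataFrame,
    pairing: PairingReport,
    group: str = "all",
    conf: float = 0.95,
) -> FoldChangeResult:
    """Tumor/normal fold change for one probe within an MSI group.

    ``expr`` is log2 expression indexed by sample ID.  The point estimate is
    2^(mean paired log2 difference); pairs with a missing value are dropped.
    """
    if group not in ("all", "MSI", "MSS"):
        raise ValidationError("group must be 'all', 'MSI' or 'MSS'")
    diffs = []
    for _, (t_id, n_id) in _pairs_for_group(sheet, pairing, group):
        tv, nv = expr.get(t_id, np.nan), expr.get(n_id, np.nan)
        if not (np.isnan(tv) or np.isnan(nv)):
            diffs.append(tv - nv)
    return _fold_from_diffs(np.asarray(diffs, float), str(expr.name), group, conf)


def expression_interaction_scan(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    include_person: bool = False,
) -> pd.DataFrame:
    """Per-probe Tumor*MSI interaction p on log2 expression.

    Reuses the methylation interaction model on the expression matrix;
    probes with interaction p < ``alpha`` (unadjusted) are flagged
    significant.
    """
    res = genomewide_scan(expr, sheet, model="interaction", include_person=include_person)
    out = res[["n_eff", "delta_beta_all", "delta_beta_msi", "delta_beta_mss", "p_interaction", "flags"]].copy()
    out = out.rename(
        columns={
            "delta_beta_all": "log2fc_all",
            "delta_beta_msi": "log2fc_msi",
            "delta_beta_mss": "log2fc_mss",
        }
    )
    out["significant"] = (out["p_interaction"] < alpha).fillna(False) & (out["flags"] == "")
    out.index.name = "probe_id"
    return out


def geneset_average_fold(
    expr: pd.DataFrame,
    probes,
    sheet: pd.DataFrame,
    pairing: PairingReport,
    group: str = "all",
    conf: float = 0.95,
) -> FoldChangeResult:
    """Average fold over a probe set: paired log2 differences pooled with
    equal weight across set members, t-interval on the pooled differences.

    For a single-probe set this reduces exactly to ``paired_fold_change``.
    """
    probes = [p for p in probes]
    if not probes:
        raise ValidationError("probe set is empty")
    missing = [p for p in probes if p not in expr.index]
    if missing:
        raise ValidationError(f"probe(s) not in expression matrix: {missing[:5]}")
    diffs = []
    pairs = _pairs_for_group(sheet, pairing, group)
    for probe in probes:
        row = expr.loc[probe]
        for _, (t_id, n_id) in pairs:
            tv, nv = row.get(t_id, np.nan), row.get(n_id, np.nan)
            if not (np.isnan(tv) or np.isnan(nv)):
                diffs.append(tv - nv)
    return _fold_from_diffs(np.asarray(diffs, float), f"set[{len(probes)}]", group, conf)
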