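"""Per-locus ANOVA models for paired tumor/normal methylation data.

Three models are supported, all with the locus value (beta, or log2
expression) as the response:

* **paired** — ``Y = mu + Tumor + Person + eps`` with Person a random
  intercept: the classic paired layout.  The tumor effect is the mean of the
  within-person tumor-minus-normal differences, its F equals the squared
  paired-t statistic, and the person variance component is estimated by the
  method of moments, ``sigma2_person = max(0, (MS_person - MS_error) / 2)``.
* **interaction** — ``Y = mu + Tumor + MSI + Tumor*MSI + eps``: the
  tumor-by-MSI interaction test asking whether delta beta differs between
  MSI and MSS persons.  Fitted by least squares with sum-to-zero (effect)
  coding; Type III sums of squares, so the tests are marginal even in
  unbalanced designs.
* **location** — adds Location and Tumor*Location to the interaction model,
  giving the MSI interaction adjusted for tumor side.

The interaction and location models are written without a Person term by
default.  When person intercepts are present in the data this leaves the
interaction F-test conservative (the mean-squared error absorbs the
between-person variance, which the paired interaction contrast does not
contain).  ``include_person=True`` switches to the split-plot analysis that
strata the data by person: within-person tumor-minus-normal differences
carry the Tumor, Tumor*MSI (and Tumor*Location) tests; person means carry
the MSI (and Location) tests.  That variant is exactly calibrated under
person heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError
from .data_io import PairingReport, validate_pairing

TINY = np.finfo(float).tiny

RESULT_COLUMNS = [
    "n_eff",
    "n_eff_msi",
    "n_eff_mss",
    "delta_beta_all",
    "delta_beta_msi",
    "delta_beta_mss",
    "p_tumor",
    "p_tumor_msi",
    "p_tumor_mss",
    "p_msi",
    "p_interaction",
    "p_location",
    "p_tumor_x_location",
    "frac_person",
    "frac_tumor",
    "frac_error",
    "flags",
]


@dataclass
class TermStats:
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class AnovaFit:
    """Per-term ANOVA decomposition plus effect estimates for one locus."""

    terms: dict[str, TermStats]
    ss_total: float = np.nan
    grand_mean: float = np.nan
    effects: dict[str, float] = field(default_factory=dict)
    sigma2_error: float = np.nan
    sigma2_person: float = np.nan  # method-of-moments, truncated at 0
    sigma2_person_raw: float = np.nan  # pre-truncation diagnostic
    n_eff: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return "insufficient_data" not in self.flags


def _f_p(ss_num: float, df_num: int, ss_err: float, df_err: int) -> tuple[float, float, list[str]]:
    """F statistic and p for a term against an error stratum, with
    degenerate handling: zero error SS gives F=inf (p floored at tiny) when
    the term SS is positive, and F=0, p=1 when both are zero."""
    if df_err <= 0:
        return np.nan, np.nan, ["insufficient_df"]
    ms_err = ss_err / df_err
    if ms_err == 0:
        if ss_num == 0:
            return 0.0, 1.0, []
        return np.inf, TINY, ["degenerate"]
    f = (ss_num / df_num) / ms_err
    return f, float(stats.f.sf(f, df_num, df_err)), []


# ---------------------------------------------------------------------------
# Paired model
# ---------------------------------------------------------------------------


def paired_t_test(deltas) -> tuple[float, float]:
    """Two-sided paired t-test on precomputed within-pair differences.

    Degenerate spreads follow a fixed convention: zero SD with a nonzero
    mean gives (inf, 0-floored-at-tiny); zero SD and zero mean gives (0, 1).
    """
    d = np.asarray(deltas, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        raise ValidationError("paired t-test needs at least 2 differences")
    sd = d.std(ddof=1)
    mean = d.mean()
    if np.ptp(d) == 0:  # all differences identical: zero true spread
        return (0.0, 1.0) if mean == 0 else (np.inf, TINY)
    t = mean / (sd / np.sqrt(len(d)))
    return float(t), float(2 * stats.t.sf(abs(t), len(d) - 1))


def fit_paired_model(y: pd.Series, pairing: PairingReport | dict) -> AnovaFit:
    """Two-way paired ANOVA (tumor/normal x person) for one locus.

    ``y`` is indexed by sample ID; pairs with a missing value on either side
    are dropped (pairwise deletion) and the effective n recorded.  With
    fewer than 2 complete pairs the fit is returned flagged
    ``insufficient_data`` rather than raising.
    """
    pairs = pairing.pairs if isinstance(pairing, PairingReport) else pairing
    t_vals, n_vals = [], []
    for tumor_id, normal_id in pairs.values():
        tv = y.get(tumor_id, np.nan)
        nv = y.get(normal_id, np.nan)
        if not (np.isnan(tv) or np.isnan(nv)):
            t_vals.append(tv)
            n_vals.append(nv)
    t_arr, n_arr = np.asarray(t_vals), np.asarray(n_vals)
    n = len(t_arr)
    if n < 2:
        return AnovaFit(terms={}, n_eff=n, flags=["insufficient_data"])

    d = t_arr - n_arr
    grand = (t_arr.sum() + n_arr.sum()) / (2 * n)
    person_means = (t_arr + n_arr) / 2
    ss_person = 2 * np.sum((person_means - grand) ** 2)
    ss_tumor = n * d.mean() ** 2 / 2
    ss_total = np.sum((t_arr - grand) ** 2) + np.sum((n_arr - grand) ** 2)
    ss_error = max(0.0, ss_total - ss_person - ss_tumor)
    df_err = n - 1

    f_t, p_t, flags_t = _f_p(ss_tumor, 1, ss_error, df_err)
    f_p_, p_p, flags_p = _f_p(ss_person, n - 1, ss_error, df_err)
    ms_err = ss_error / df_err
    ms_person = ss_person / (n - 1)
    sigma2_person_raw = (ms_person - ms_err) / 2

    terms = {
        "Tumor": TermStats(ss_tumor, 1, ss_tumor, f_t, p_t),
        "Person": TermStats(ss_person, n - 1, ms_person, f_p_, p_p),
        "Error": TermStats(ss_error, df_err, ms_err, np.nan, np.nan),
    }
    return AnovaFit(
        terms=terms,
        ss_total=ss_total,
        grand_mean=grand,
        effects={"tumor_effect": float(d.mean())},
        sigma2_error=ms_err,
        sigma2_person=max(0.0, sigma2_person_raw),
        sigma2_person_raw=sigma2_person_raw,
        n_eff=n,
        flags=sorted(set(flags_t + flags_p)),
    )


# ---------------------------------------------------------------------------
# Fixed-effect models with Type III sums of squares
# ---------------------------------------------------------------------------


def _effect_code(values, pos_level) -> np.ndarray:
    return np.where(np.asarray(values) == pos_level, 1.0, -1.0)


def _ols_typeiii(y: np.ndarray, X: np.ndarray, names: list[str]) -> AnovaFit:
    """OLS with sum-to-zero single-df columns; Type III SS per column.

    For effect coding, the SS for dropping column j from the full model is
    beta_j^2 / [(X'X)^-1]_jj, which is exactly the Type III (marginal) sum
    of squares.
    """
    n, k = X.shape
    xtx = X.T @ X
    flags: list[str] = []
    if np.linalg.matrix_rank(xtx) < k:
        raise ValidationError("design matrix is rank deficient")
    inv = np.linalg.inv(xtx)
    beta = inv @ X.T @ y
    resid = y - X @ beta
    ss_error = float(resid @ resid)
    df_err = n - k
    grand = float(beta[0])

    terms: dict[str, TermStats] = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        ss_j = float(beta[j] ** 2 / inv[j, j])
        f, p, fl = _f_p(ss_j, 1, ss_error, df_err)
        flags += fl
        terms[name] = TermStats(ss_j, 1, ss_j, f, p)
    ms_err = ss_error / df_err if df_err > 0 else np.nan
    terms["Error"] = TermStats(ss_error, df_err, ms_err, np.nan, np.nan)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return AnovaFit(
        terms=terms,
        ss_total=ss_total,
        grand_mean=grand,
        effects={names[j]: float(beta[j]) for j in range(k)},
        sigma2_error=ms_err,
        n_eff=n,
        flags=sorted(set(flags)),
    )


def _group_deltas(y, tumor, msi) -> dict[str, float]:
    """Tumor-minus-normal mean differences overall and per MSI level."""
    y = np.asarray(y, float)
    tumor = np.asarray(tumor, bool)
    msi = np.asarray(msi, bool)
    out = {}
    for label, mask in (("all", np.ones_like(msi)), ("msi", msi), ("mss", ~msi)):
        t_mask, n_mask = tumor & mask, ~tumor & mask
        if t_mask.any() and n_mask.any():
            out[f"delta_beta_{label}"] = float(y[t_mask].mean() - y[n_mask].mean())
        else:
            out[f"delta_beta_{label}"] = np.nan
    return out


def fit_interaction_model(
    y, tumor, msi, include_person: bool = False, person=None
) -> AnovaFit:
    """Tumor x MSI two-factor model for one locus.

    ``tumor`` and ``msi`` are boolean arrays (tumor sample / MSI person)
    aligned to ``y``.  Missing responses are dropped.  An empty design cell
    flags the fit ``inestimable_interaction`` rather than raising.
    """
    y = np.asarray(y, float)
    tumor = np.asarray(tumor, bool)
    msi = np.asarray(msi, bool)
    keep = ~np.isnan(y)
    y, tumor, msi = y[keep], tumor[keep], msi[keep]
    if person is not None:
        person = np.asarray(person)[keep]

    cells = {(t, m): np.sum((tumor == t) & (msi == m)) for t in (0, 1) for m in (0, 1)}
    if min(cells.values()) == 0:
        return AnovaFit(terms={}, n_eff=len(y), flags=["inestimable_interaction"])

    if include_person:
        if person is None:
            raise ValidationError("include_person=True requires person labels")
        return _split_plot_fit(y, tumor, {"MSI": msi}, person)

    tcol = np.where(tumor, 1.0, -1.0)
    mcol = np.where(msi, 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), tcol, mcol, tcol * mcol])
    fit = _ols_typeiii(y, X, ["Intercept", "Tumor", "MSI", "Tumor*MSI"])
    fit.effects.update(_group_deltas(y, tumor, msi))
    return fit


def fit_location_model(
    y, tumor, msi, location, include_person: bool = False, person=None
) -> AnovaFit:
    """Tumor x MSI model additionally adjusted for tumor location.

    Terms: Tumor, MSI, Location, Tumor*MSI, Tumor*Location.  A factor with a
    single observed level is dropped and its terms flagged ``inestimable``;
    if the model then reduces to the two-factor interaction model the fit
    matches it exactly.
    """
    y = np.asarray(y, float)
    tumor = np.asarray(tumor, bool)
    msi = np.asarray(msi, bool)
    location = np.asarray(location)
    keep = ~np.isnan(y)
    y, tumor, msi, location = y[keep], tumor[keep], msi[keep], location[keep]
    if person is not None:
        person = np.asarray(person)[keep]

    if location.dtype == bool:
        right = location
    else:
        right = np.asarray([str(v) == "right" for v in location])

    flags = []
    factors: dict[str, np.ndarray] = {}
    for name, col in (("MSI", msi), ("Location", right)):
        if len(np.unique(col)) < 2:
            flags.append(f"inestimable:{name}")
        else:
            factors[name] = col
    if len(np.unique(tumor)) < 2:
        return AnovaFit(terms={}, n_eff=len(y), flags=["inestimable_interaction"])

    if include_person:
        if person is None:
            raise ValidationError("include_person=True requires person labels")
        fit = _split_plot_fit(y, tumor, factors, person)
        fit.flags = sorted(set(fit.flags + flags))
        return fit

    names = ["Intercept", "Tumor"]
    cols = [np.ones_like(y), np.where(tumor, 1.0, -1.0)]
    for name, col in factors.items():
        names.append(name)
        cols.append(np.where(col, 1.0, -1.0))
    for name in list(factors):
        names.append(f"Tumor*{name}")
        cols.append(np.where(tumor, 1.0, -1.0) * np.where(factors[name], 1.0, -1.0))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        # collinear factors (e.g. MSI == Location): report what is estimable
        return AnovaFit(terms={}, n_eff=len(y), flags=sorted(set(flags + ["collinear_design"])))
    fit = _ols_typeiii(y, X, names)
    fit.effects.update(_group_deltas(y, tumor, msi))
    fit.flags = sorted(set(fit.flags + flags))
    return fit


def _split_plot_fit(y, tumor, factors: dict[str, np.ndarray], person) -> AnovaFit:
    """Split-plot (person-stratified) fit.

    Within-person tumor-minus-normal differences carry the Tumor and
    Tumor*factor tests; person means carry the between-person factor tests.
    Only persons contributing one tumor and one normal value are used.
    """
    person = np.asarray(person)
    d, s, covars = [], [], {name: [] for name in factors}
    for p in pd.unique(person):
        sel = person == p
        tv, nv = y[sel & tumor], y[sel & ~tumor]
        if len(tv) == 1 and len(nv) == 1:
            d.append(tv[0] - nv[0])
            s.append((tv[0] + nv[0]) / 2)
            for name, col in factors.items():
                covars[name].append(bool(col[sel][0]))
    d, s = np.asarray(d), np.asarray(s)
    n = len(d)
    if n < len(factors) + 2:
        return AnovaFit(terms={}, n_eff=n, flags=["insufficient_data"])

    names_w = ["Intercept"] + list(factors)
    Xw = np.column_stack([np.ones(n)] + [np.where(covars[f], 1.0, -1.0) for f in factors])
    if np.linalg.matrix_rank(Xw.T @ Xw) < Xw.shape[1]:
        return AnovaFit(terms={}, n_eff=n, flags=["collinear_design"])

    within = _ols_typeiii(d, Xw, names_w)
    between = _ols_typeiii(s, Xw, names_w)

    terms: dict[str, TermStats] = {}
    # intercept of the difference regression tests the Tumor main effect
    beta0 = within.effects["Intercept"]
    ss_err_w = within.terms["Error"].ss
    df_err_w = within.terms["Error"].df
    inv = np.linalg.inv(Xw.T @ Xw)
    ss_tumor = float(beta0**2 / inv[0, 0])
    f, p, fl = _f_p(ss_tumor, 1, ss_err_w, df_err_w)
    terms["Tumor"] = TermStats(ss_tumor, 1, ss_tumor, f, p)
    flags = list(fl)
    for name in factors:
        tw = within.terms[name]
        terms[f"Tumor*{name}"] = TermStats(tw.ss, tw.df, tw.ms, tw.f, tw.p)
        tb = between.terms[name]
        terms[name] = TermStats(tb.ss, tb.df, tb.ms, tb.f, tb.p)
    terms["Error"] = TermStats(ss_err_w, df_err_w, ss_err_w / df_err_w if df_err_w else np.nan, np.nan, np.nan)

    msi = factors.get("MSI")
    fit = AnovaFit(
        terms=terms,
        grand_mean=float(s.mean()),
        effects={"tumor_effect": float(d.mean())},
        sigma2_error=ss_err_w / df_err_w / 2 if df_err_w else np.nan,
        n_eff=n,
        flags=sorted(set(flags + within.flags + between.flags)),
    )
    if msi is not None:
        msi_mask = np.asarray(covars["MSI"], bool)
        fit.effects["delta_beta_all"] = float(d.mean())
        fit.effects["delta_beta_msi"] = float(d[msi_mask].mean()) if msi_mask.any() else np.nan
        fit.effects["delta_beta_mss"] = float(d[~msi_mask].mean()) if (~msi_mask).any() else np.nan
    return fit


# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------


def variance_decomposition(fit: AnovaFit) -> dict:
    """Per-factor share of the total sum of squares, plus F-ratios.

    Shares (including the residual "Error" share) sum to 1; a constant
    response (zero total SS) yields all-zero shares with a degenerate flag.
    """
    ss = {name: t.ss for name, t in fit.terms.items()}
    total = sum(ss.values())
    if total == 0:
        return {
            "shares": {name: 0.0 for name in ss},
            "f_ratios": {name: np.nan for name in ss if name != "Error"},
            "flags": ["degenerate"],
        }
    return {
        "shares": {name: v / total for name, v in ss.items()},
        "f_ratios": {name: t.f for name, t in fit.terms.items() if name != "Error"},
        "flags": [],
    }


# ---------------------------------------------------------------------------
# Genome-wide scans
# ---------------------------------------------------------------------------


def _empty_results(index) -> pd.DataFrame:
    res = pd.DataFrame(index=index, columns=RESULT_COLUMNS, dtype=float)
    res.index.name = "locus_id"
    res["flags"] = ""
    return res


def _pair_arrays(matrix: pd.DataFrame, sheet: pd.DataFrame, persons: list[str], pairs):
    t_ids = [pairs[p][0] for p in persons]
    n_ids = [pairs[p][1] for p in persons]
    return matrix[t_ids].to_numpy(float), matrix[n_ids].to_numpy(float)


def _paired_scan(matrix, sheet, pairing, stratum) -> pd.DataFrame:
    status = sheet.drop_duplicates("person_id").set_index("person_id")["msi_status"]
    persons = [p for p in pairing.pairs if stratum is None or status[p] == stratum]
    res = _empty_results(matrix.index)
    if not persons:
        res["flags"] = "insufficient_data"
        return res
    T, N = _pair_arrays(matrix, sheet, persons, pairing.pairs)
    D = T - N
    complete = ~np.isnan(D)
    n = complete.sum(axis=1)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_d = np.nanmean(np.where(complete, D, np.nan), axis=1)
        sd_d = np.nanstd(np.where(complete, D, np.nan), axis=1, ddof=1)
        t_stat = mean_d / (sd_d / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t_stat), n - 1)
        constant = np.nanmax(np.where(complete, D, -np.inf), axis=1) == np.nanmin(
            np.where(complete, D, np.inf), axis=1
        )
        p = np.where(constant, np.where(mean_d == 0, 1.0, TINY), p)

        # SS decomposition (complete-pair subsets)
        Tm, Nm = np.where(complete, T, np.nan), np.where(complete, N, np.nan)
        grand = (np.nansum(Tm, axis=1) + np.nansum(Nm, axis=1)) / (2 * n)
        pm = (Tm + Nm) / 2
        ss_person = 2 * np.nansum((pm - grand[:, None]) ** 2, axis=1)
        ss_tumor = n * mean_d**2 / 2
        ss_total = np.nansum((Tm - grand[:, None]) ** 2, axis=1) + np.nansum(
            (Nm - grand[:, None]) ** 2, axis=1
        )
        ss_error = np.maximum(0.0, ss_total - ss_person - ss_tumor)

    label = {"MSI": "msi", "MSS": "mss", None: "all"}[stratum]
    res["n_eff"] = n
    res[f"delta_beta_{label}"] = mean_d
    col_p = {"all": "p_tumor", "msi": "p_tumor_msi", "mss": "p_tumor_mss"}[label]
    res[col_p] = p
    if stratum is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = np.where(ss_total > 0, ss_total, np.nan)
            res["frac_person"] = ss_person / tot
            res["frac_tumor"] = ss_tumor / tot
            res["frac_error"] = ss_error / tot
    res.loc[n < 2, "flags"] = "insufficient_data"
    res.loc[constant & (n >= 2) & (mean_d != 0), "flags"] = "degenerate"
    return res


def _fixed_scan(matrix, sheet, model, include_person) -> pd.DataFrame:
    Y = matrix.to_numpy(float)
    res = _empty_results(matrix.index)
    tumor = (sheet["tissue"] == "tumor").to_numpy()
    msi = (sheet["msi_status"] == "MSI").to_numpy()
    right = (sheet["location"] == "right").to_numpy()
    person = sheet["person_id"].to_numpy()

    has_nan = np.isnan(Y).any(axis=1)

    def store(i, fit: AnovaFit):
        res.iloc[i, res.columns.get_loc("n_eff")] = fit.n_eff
        for key in ("delta_beta_all", "delta_beta_msi", "delta_beta_mss"):
            if key in fit.effects:
                res.iloc[i, res.columns.get_loc(key)] = fit.effects[key]
        mapping = {
            "Tumor": "p_tumor",
            "MSI": "p_msi",
            "Tumor*MSI": "p_interaction",
            "Location": "p_location",
            "Tumor*Location": "p_tumor_x_location",
        }
        for term, col in mapping.items():
            if term in fit.terms:
                res.iloc[i, res.columns.get_loc(col)] = fit.terms[term].p
        res.iloc[i, res.columns.get_loc("flags")] = ";".join(fit.flags)

    # complete-case loci: vectorised least squares
    idx_complete = np.flatnonzero(~has_nan)
    if len(idx_complete):
        Yc = Y[idx_complete]
        if include_person:
            _vector_split_plot(res, idx_complete, Yc, tumor, msi, right, person, model)
        else:
            _vector_ols(res, idx_complete, Yc, tumor, msi, right, model)

    for i in np.flatnonzero(has_nan):
        yi = Y[i]
        if model == "interaction":
            fit = fit_interaction_model(yi, tumor, msi, include_person, person)
        else:
            fit = fit_location_model(yi, tumor, msi, sheet["location"].to_numpy(), include_person, person)
        store(i, fit)
    return res


def _vector_ols(res, idx, Y, tumor, msi, right, model):
    tcol = np.where(tumor, 1.0, -1.0)
    mcol = np.where(msi, 1.0, -1.0)
    cols = [np.ones_like(tcol), tcol, mcol, tcol * mcol]
    names = ["Intercept", "Tumor", "MSI", "Tumor*MSI"]
    if model == "location":
        lcol = np.where(right, 1.0, -1.0)
        cols = [np.ones_like(tcol), tcol, mcol, lcol, tcol * mcol, tcol * lcol]
        names = ["Intercept", "Tumor", "MSI", "Location", "Tumor*MSI", "Tumor*Location"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        res.iloc[idx, res.columns.get_loc("flags")] = "collinear_design"
        return
    inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ inv  # loci x k
    fitted = B @ X.T
    sse = np.sum((Y - fitted) ** 2, axis=1)
    df_err = Y.shape[1] - X.shape[1]

    col_map = {
        "Tumor": "p_tumor",
        "MSI": "p_msi",
        "Tumor*MSI": "p_interaction",
        "Location": "p_location",
        "Tumor*Location": "p_tumor_x_location",
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_err = sse / df_err
        for j, name in enumerate(names):
            if name == "Intercept":
                continue
            ss_j = B[:, j] ** 2 / inv[j, j]
            f = ss_j / ms_err
            p = stats.f.sf(f, 1, df_err)
            p = np.where(ms_err == 0, np.where(ss_j == 0, 1.0, TINY), p)
            res.iloc[idx, res.columns.get_loc(col_map[name])] = p

    for label, mask in (("all", np.ones_like(msi, bool)), ("msi", msi), ("mss", ~msi)):
        tm, nm = tumor & mask, ~tumor & mask
        if tm.any() and nm.any():
            delta = Y[:, tm].mean(axis=1) - Y[:, nm].mean(axis=1)
            res.iloc[idx, res.columns.get_loc(f"delta_beta_{label}")] = delta
    res.iloc[idx, res.columns.get_loc("n_eff")] = Y.shape[1]
    degen = sse == 0
    if degen.any():
        flag_col = res.columns.get_loc("flags")
        res.iloc[idx[degen], flag_col] = "degenerate"


def _vector_split_plot(res, idx, Y, tumor, msi, right, person, model):
    """Vectorised split-plot scan on complete data.

    Builds the loci x persons matrices of differences and person means once,
    then runs the within/between single-df regressions for all loci at once.
    """
    persons = pd.unique(person)
    t_pos, n_pos, keep_person = [], [], []
    for p in persons:
        sel = np.flatnonzero(person == p)
        tsel = [i for i in sel if tumor[i]]
        nsel = [i for i in sel if not tumor[i]]
        if len(tsel) == 1 and len(nsel) == 1:
            t_pos.append(tsel[0])
            n_pos.append(nsel[0])
            keep_person.append(p)
    D = Y[:, t_pos] - Y[:, n_pos]
    S = (Y[:, t_pos] + Y[:, n_pos]) / 2
    m = msi[t_pos]
    r = right[t_pos]

    names = ["Intercept", "MSI"]
    cols = [np.ones(len(keep_person)), np.where(m, 1.0, -1.0)]
    if model == "location":
        names.append("Location")
        cols.append(np.where(r, 1.0, -1.0))
    Xw = np.column_stack(cols)
    if np.linalg.matrix_rank(Xw.T @ Xw) < Xw.shape[1]:
        res.iloc[idx, res.columns.get_loc("flags")] = "collinear_design"
        return
    inv = np.linalg.inv(Xw.T @ Xw)
    df_err = len(keep_person) - Xw.shape[1]

    def stratum_tests(Z):
        B = Z @ Xw @ inv
        sse = np.sum((Z - B @ Xw.T) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ms_err = sse / df_err
            out = {}
            for j, name in enumerate(names):
                ss_j = B[:, j] ** 2 / inv[j, j]
                f = ss_j / ms_err
                p = stats.f.sf(f, 1, df_err)
                out[name] = np.where(ms_err == 0, np.where(ss_j == 0, 1.0, TINY), p)
        return out, sse

    within, sse_w = stratum_tests(D)
    between, _ = stratum_tests(S)

    res.iloc[idx, res.columns.get_loc("p_tumor")] = within["Intercept"]
    res.iloc[idx, res.columns.get_loc("p_interaction")] = within["MSI"]
    res.iloc[idx, res.columns.get_loc("p_msi")] = between["MSI"]
    if model == "location":
        res.iloc[idx, res.columns.get_loc("p_tumor_x_location")] = within["Location"]
        res.iloc[idx, res.columns.get_loc("p_location")] = between["Location"]

    res.iloc[idx, res.columns.get_loc("delta_beta_all")] = D.mean(axis=1)
    if m.any():
        res.iloc[idx, res.columns.get_loc("delta_beta_msi")] = D[:, m].mean(axis=1)
    if (~m).any():
        res.iloc[idx, res.columns.get_loc("delta_beta_mss")] = D[:, ~m].mean(axis=1)
    res.iloc[idx, res.columns.get_loc("n_eff")] = len(keep_person)
    degen = sse_w == 0
    if degen.any():
        res.iloc[idx[degen], res.columns.get_loc("flags")] = "degenerate"


def genomewide_scan(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    model: str = "paired",
    stratum: str | None = None,
    include_person: bool = False,
) -> pd.DataFrame:
    """Fit one model at every locus; one output row per input locus, in order.

    ``model`` is ``paired`` (optionally restricted to ``stratum`` 'MSI' or
    'MSS'), ``interaction`` or ``location``.  Loci failing preconditions are
    flagged in the ``flags`` column, never dropped.
    """
    if model not in ("paired", "interaction", "location"):
        raise ValidationError(f"unknown model {model!r}")
    if stratum not in (None, "MSI", "MSS"):
        raise ValidationError("stratum must be None, 'MSI' or 'MSS'")
    missing = [s for s in matrix.columns if s not in set(sheet["sample_id"])]
    if missing:
        raise ValidationError(f"matrix samples absent from sheet: {missing[:5]}")
    sheet = sheet[sheet["sample_id"].isin(matrix.columns)].reset_index(drop=True)
    matrix = matrix[sheet["sample_id"].to_numpy()]
    if model == "location" and "location" not in sheet.columns:
        raise ValidationError("sheet lacks a 'location' column")

    if model == "paired":
        pairing = validate_pairing(sheet)
        return _paired_scan(matrix, sheet, pairing, stratum)
    return _fixed_scan(matrix, sheet, model, include_person)


def full_scan(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    include_person: bool = False,
    with_location: bool = False,
) -> pd.DataFrame:
    """Run the stratified paired scans plus the interaction scan and merge.

    Produces the per-locus result table the DML pipeline consumes: stratum
    delta betas and paired p-values, the interaction p, and the paired-model
    variance fractions.
    """
    res = _paired_scan_merge(
        genomewide_scan(matrix, sheet, "paired"),
        genomewide_scan(matrix, sheet, "paired", stratum="MSI"),
        genomewide_scan(matrix, sheet, "paired", stratum="MSS"),
    )
    inter = genomewide_scan(matrix, sheet, "interaction", include_person=include_person)
    res["p_msi"] = inter["p_msi"]
    res["p_interaction"] = inter["p_interaction"]
    if with_location:
        loc = genomewide_scan(matrix, sheet, "location", include_person=include_person)
        res["p_location"] = loc["p_location"]
        res["p_tumor_x_location"] = loc["p_tumor_x_location"]
        res["p_interaction_location_adjusted"] = loc["p_interaction"]
    flags = [
        ";".join(sorted({f for f in (a, b) if f}))
        for a, b in zip(res["flags"].fillna(""), inter["flags"].fillna(""))
    ]
    res["flags"] = flags
    return res


def _paired_scan_merge(all_res, msi_res, mss_res) -> pd.DataFrame:
    res = all_res.copy()
    res["n_eff_msi"] = msi_res["n_eff"]
    res["n_eff_mss"] = mss_res["n_eff"]
    res["delta_beta_msi"] = msi_res["delta_beta_msi"]
    res["delta_beta_mss"] = mss_res["delta_beta_mss"]
    res["p_tumor_msi"] = msi_res["p_tumor_msi"]
    res["p_tumor_mss"] = mss_res["p_tumor_mss"]
    merged_flags = []
    for a, b, c in zip(all_res["flags"].fillna(""), msi_res["flags"].fillna(""), mss_res["flags"].fillna("")):
        parts = sorted({f for f in (a, b, c) if f})
        merged_flags.append(";".join(parts))
    res["flags"] = merged_flags
    return res
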