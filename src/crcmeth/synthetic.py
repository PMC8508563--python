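"""Synthetic paired tumor/normal methylation cohorts with known ground truth.

The generator emulates the study design the analysis modules assume: each
person contributes one tumor and one matched normal array sample; a subgroup
of persons is microsatellite-unstable (MSI); per-person random intercepts
dominate the variance of most loci; and each locus belongs to a planted
effect class describing how the tumor-vs-normal methylation difference
(delta beta) depends on MSI status.

Generation is on the logit scale so that betas stay strictly inside (0, 1):

    y = expit( logit(baseline) + tumor * shift(group) + b_person + eps )

with ``b_person ~ N(0, sigma_person^2)`` shared between a person's two
samples and ``eps ~ N(0, sigma_error^2)`` per sample.  The logit shift for a
group is chosen so that, at zero noise, the tumor-minus-normal difference on
the *beta* scale equals the requested delta exactly:

    shift = logit(baseline + delta) - logit(baseline)

Deltas are therefore specified on the beta scale, matching how magnitude
thresholds are applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError, expit, logit, spawn_rngs
from .data_io import REGIONS, validate_sample_sheet

EFFECT_CLASSES = ("null", "shared", "msi_only", "mss_only", "both_diff")

#: 450K chip composition by relation to the nearest CpG island
#: (island / shelves / shores split north–south / open sea).
CHIP_REGION_COUNTS = {
    "Island": 150254,
    "N_Shelf": 24844,
    "N_Shore": 62870,
    "S_Shelf": 22300,
    "S_Shore": 49197,
    "OpenSea": 176112,
}
CHIP_TOTAL_LOCI = sum(CHIP_REGION_COUNTS.values())  # 485577


@dataclass
class CohortConfig:
    """Cohort design: 125 persons, 30 of them MSI, by default.

    ``p_right_given_msi``/``p_right_given_mss`` are the probabilities of a
    right-sided tumor given MSI status (defaults 13/30 and 11/95, the
    observed cohort rates); ``sex_split`` is the male fraction (72/125).
    """

    n_persons: int = 125
    n_msi: int = 30
    p_right_given_msi: float = 13 / 30
    p_right_given_mss: float = 11 / 95
    sex_split: float = 72 / 125
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_persons < 0:
            raise ValidationError("n_persons must be >= 0")
        if not 0 <= self.n_msi <= self.n_persons:
            raise ValidationError("need 0 <= n_msi <= n_persons")
        for name in ("p_right_given_msi", "p_right_given_mss", "sex_split"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        return self


@dataclass
class NoiseSpec:
    """Gaussian noise SDs on the logit scale.

    ``sigma_person`` is the SD of the per-person random intercept (shared by
    a person's two samples); ``sigma_error`` is the per-sample residual SD.
    The defaults (0.20, 0.35) put the person term's share of the paired-model
    sum of squares near 62% at 125 persons.
    """

    sigma_person: float = 0.20
    sigma_error: float = 0.35

    def validate(self) -> "NoiseSpec":
        if self.sigma_person < 0 or self.sigma_error < 0:
            raise ValidationError("noise SDs must be >= 0")
        return self

    @property
    def person_variance_fraction(self) -> float:
        tot = self.sigma_person**2 + self.sigma_error**2
        return 0.0 if tot == 0 else self.sigma_person**2 / tot


@dataclass
class LocusEffectSpec:
    """Planted per-locus effect: how delta beta depends on MSI status."""

    effect_class: str
    delta_msi: float = 0.0
    delta_mss: float = 0.0
    baseline: float = 0.5

    def validate(self) -> "LocusEffectSpec":
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {self.effect_class!r}")
        if not 0 < self.baseline < 1:
            raise ValidationError("baseline must be strictly inside (0, 1)")
        if self.effect_class == "null" and (self.delta_msi or self.delta_mss):
            raise ValidationError("null loci must have zero deltas")
        if self.effect_class == "shared" and self.delta_msi != self.delta_mss:
            raise ValidationError("shared loci must have delta_msi == delta_mss")
        for d in (self.delta_msi, self.delta_mss):
            if not 0 < self.baseline + d < 1:
                raise ValidationError("baseline + delta must stay inside (0, 1)")
        return self


def sigma_person_for_ss_share(target_share: float, sigma_error: float) -> float:
    """Person-intercept SD giving a target person share of the paired-model SS.

    For the paired two-way layout (tumor/normal x person) on null loci the
    expected sums of squares are E[SS_person] = (n-1)(sigma_e^2 + 2
    sigma_p^2) and E[SS_error] ~ (n-1) sigma_e^2, so the person share f of
    the total solves sigma_p^2 = sigma_e^2 (2f - 1) / (2 (1 - f)), valid for
    f in (0.5, 1).
    """
    if not 0.5 < target_share < 1:
        raise ValidationError("target person SS share must be in (0.5, 1)")
    return sigma_error * np.sqrt((2 * target_share - 1) / (2 * (1 - target_share)))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a sample sheet: two rows (tumor, normal) per person."""
    config.validate()
    rng_msi, rng_loc, rng_sex, rng_age, rng_stage = spawn_rngs(config.seed, 5)
    n = config.n_persons
    width = max(3, len(str(max(n, 1))))
    persons = [f"P{i + 1:0{width}d}" for i in range(n)]
    msi_persons = set(rng_msi.choice(n, size=config.n_msi, replace=False)) if n else set()

    rows = []
    for i, person in enumerate(persons):
        is_msi = i in msi_persons
        p_right = config.p_right_given_msi if is_msi else config.p_right_given_mss
        location = "right" if rng_loc.random() < p_right else "left"
        sex = "male" if rng_sex.random() < config.sex_split else "female"
        age = float(np.clip(round(rng_age.normal(46.0, 14.0), 1), 20.0, 85.0))
        stage = int(rng_stage.choice([1, 2, 3], p=[25 / 125, 33 / 125, 67 / 125]))
        for tissue, suffix in (("tumor", "T"), ("normal", "N")):
            rows.append(
                {
                    "sample_id": f"{person}_{suffix}",
                    "person_id": person,
                    "tissue": tissue,
                    "msi_status": "MSI" if is_msi else "MSS",
                    "location": location,
                    "sex": sex,
                    "age": age,
                    "stage": stage,
                }
            )
    sheet = pd.DataFrame(rows, columns=list(pd.Index(
        ["sample_id", "person_id", "tissue", "msi_status", "location", "sex", "age", "stage"]
    )))
    if len(sheet):
        validate_sample_sheet(sheet)
    return sheet


# ---------------------------------------------------------------------------
# Effect panels
# ---------------------------------------------------------------------------

#: Default planted deltas per effect class: (delta_msi, delta_mss).  The
#: both_diff class plants equal magnitudes with opposite sign so that both
#: strata clear the magnitude filter while the interaction contrast is large.
DEFAULT_CLASS_DELTAS = {
    "null": (0.0, 0.0),
    "shared": (0.3, 0.3),
    "msi_only": (0.3, 0.0),
    "mss_only": (0.0, 0.3),
    "both_diff": (0.3, -0.3),
}


def make_effect_panel(
    class_counts: dict[str, int],
    seed: int = 0,
    class_deltas: dict[str, tuple[float, float]] | None = None,
    baseline_range: tuple[float, float] = (0.35, 0.65),
) -> list[LocusEffectSpec]:
    """Build a locus effect panel with baselines drawn uniformly.

    The baseline range is kept away from the (0, 1) boundaries so that
    baseline + delta stays valid for the default |delta| = 0.3 classes.
    """
    deltas = dict(DEFAULT_CLASS_DELTAS, **(class_deltas or {}))
    rng = np.random.default_rng(seed)
    specs: list[LocusEffectSpec] = []
    for cls, count in class_counts.items():
        if cls not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {cls!r}")
        d_msi, d_mss = deltas[cls]
        for _ in range(count):
            b = float(rng.uniform(*baseline_range))
            specs.append(LocusEffectSpec(cls, d_msi, d_mss, b).validate())
    return specs


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


def simulate_beta_matrix(
    sheet: pd.DataFrame,
    effects: list[LocusEffectSpec],
    noise: NoiseSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a loci x samples beta matrix plus its ground-truth table."""
    if not len(sheet):
        raise ValidationError("sample sheet is empty")
    validate_sample_sheet(sheet)
    noise.validate()
    for spec in effects:
        spec.validate()

    rng_person, rng_resid = spawn_rngs(seed, 2)
    n_loci = len(effects)
    sample_ids = sheet["sample_id"].to_numpy()
    persons = pd.Index(sheet["person_id"].unique())
    person_idx = persons.get_indexer(sheet["person_id"])
    tumor = (sheet["tissue"] == "tumor").to_numpy()
    is_msi = (sheet["msi_status"] == "MSI").to_numpy()

    baseline = np.array([s.baseline for s in effects])
    d_msi = np.array([s.delta_msi for s in effects])
    d_mss = np.array([s.delta_mss for s in effects])
    mu0 = logit(baseline)
    shift_msi = logit(baseline + d_msi) - mu0  # per-locus logit shifts
    shift_mss = logit(baseline + d_mss) - mu0

    # loci x samples systematic part
    shift = np.where(is_msi[None, :], shift_msi[:, None], shift_mss[:, None])
    eta = mu0[:, None] + tumor[None, :] * shift
    b_person = rng_person.normal(0.0, noise.sigma_person, size=(n_loci, len(persons)))
    eta = eta + b_person[:, person_idx]
    eta = eta + rng_resid.normal(0.0, noise.sigma_error, size=(n_loci, len(sample_ids)))

    width = max(5, len(str(n_loci)))
    locus_ids = [f"cg{i + 1:0{width}d}" for i in range(n_loci)]
    matrix = pd.DataFrame(expit(eta), index=pd.Index(locus_ids, name="locus_id"), columns=sample_ids)

    truth = pd.DataFrame(
        {
            "effect_class": [s.effect_class for s in effects],
            "true_delta_msi": d_msi,
            "true_delta_mss": d_mss,
            "baseline": baseline,
            "true_person_variance_fraction": noise.person_variance_fraction,
        },
        index=matrix.index.copy(),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    n_loci: int,
    region_proportions: dict[str, float] | None = None,
    promoter_rate: float = 0.4,
    genes_per_locus_map: dict[int, float] | None = None,
    seed: int = 0,
    mean_loci_per_gene: float = 17.0,
) -> pd.DataFrame:
    """Assign each locus a CpG-island relation band, genes, and promoter flag.

    Region counts follow ``region_proportions`` (default: the 450K chip
    composition) by deterministic largest-remainder apportionment, then a
    seeded shuffle; the realised fractions therefore match the requested ones
    to within 1/n_loci.  ``genes_per_locus_map`` maps a gene count to its
    probability (default: 10% intergenic, 80% one gene, 10% two genes);
    the gene pool size targets ~17 loci per gene, the chip's average density.
    """
    if region_proportions is None:
        region_proportions = {k: v / CHIP_TOTAL_LOCI for k, v in CHIP_REGION_COUNTS.items()}
    props = {k: float(v) for k, v in region_proportions.items()}
    unknown = set(props) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region(s) in proportions: {unknown}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"region proportions must sum to 1 (got {total})")
    if not 0 <= promoter_rate <= 1:
        raise ValidationError("promoter_rate must be in [0, 1]")
    gmap = genes_per_locus_map or {0: 0.1, 1: 0.8, 2: 0.1}
    if abs(sum(gmap.values()) - 1.0) > 1e-9:
        raise ValidationError("genes_per_locus_map probabilities must sum to 1")

    rng_shuffle, rng_gene, rng_prom = spawn_rngs(seed, 3)

    # largest-remainder apportionment of region counts
    quotas = {k: p * n_loci for k, p in props.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n_loci - sum(counts.values())
    for k in sorted(props, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    regions = np.array([r for r in REGIONS if r in counts for _ in range(counts[r])])
    rng_shuffle.shuffle(regions)

    n_genes = max(1, int(round(n_loci / mean_loci_per_gene)))
    gene_pool = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    k_choices = np.array(sorted(gmap))
    k_probs = np.array([gmap[k] for k in k_choices])
    n_per_locus = rng_gene.choice(k_choices, size=n_loci, p=k_probs)
    gene_symbols = [
        ";".join(rng_gene.choice(gene_pool, size=k, replace=False)) if k else ""
        for k in n_per_locus
    ]

    width = max(5, len(str(n_loci)))
    ann = pd.DataFrame(
        {
            "gene_symbols": gene_symbols,
            "region": regions,
            "promoter_associated": rng_prom.random(n_loci) < promoter_rate,
        },
        index=pd.Index([f"cg{i + 1:0{width}d}" for i in range(n_loci)], name="locus_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ProbeEffect:
    """Planted expression effect: tumor/normal fold change per MSI group."""

    probe_id: str
    gene: str
    fold_msi: float = 1.0
    fold_mss: float = 1.0
    baseline_log2: float = 8.0

    def validate(self) -> "ProbeEffect":
        if self.fold_msi <= 0 or self.fold_mss <= 0:
            raise ValidationError("fold changes must be positive ratios")
        return self


@dataclass
class ExpressionNoise:
    sigma_person: float = 0.3
    sigma_error: float = 0.3

    def validate(self) -> "ExpressionNoise":
        if self.sigma_person < 0 or self.sigma_error < 0:
            raise ValidationError("noise SDs must be >= 0")
        return self


def simulate_expression(
    sheet: pd.DataFrame,
    gene_effects: list[ProbeEffect],
    noise: ExpressionNoise | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a probes x samples log2 expression matrix.

    A planted fold f in a group yields a paired tumor-minus-normal mean
    difference of log2(f) for that group's persons.  Returns the matrix and
    a probe -> gene map.
    """
    if not len(sheet):
        raise ValidationError("sample sheet is empty")
    validate_sample_sheet(sheet)
    noise = (noise or ExpressionNoise()).validate()
    for eff in gene_effects:
        eff.validate()

    rng_person, rng_resid = spawn_rngs(seed, 2)
    persons = pd.Index(sheet["person_id"].unique())
    person_idx = persons.get_indexer(sheet["person_id"])
    tumor = (sheet["tissue"] == "tumor").to_numpy()
    is_msi = (sheet["msi_status"] == "MSI").to_numpy()

    base = np.array([e.baseline_log2 for e in gene_effects])
    lf_msi = np.log2([e.fold_msi for e in gene_effects])
    lf_mss = np.log2([e.fold_mss for e in gene_effects])
    shift = np.where(is_msi[None, :], lf_msi[:, None], lf_mss[:, None])
    y = base[:, None] + tumor[None, :] * shift
    b_person = rng_person.normal(0.0, noise.sigma_person, size=(len(gene_effects), len(persons)))
    y = y + b_person[:, person_idx]
    y = y + rng_resid.normal(0.0, noise.sigma_error, size=y.shape)

    probe_ids = pd.Index([e.probe_id for e in gene_effects], name="probe_id")
    matrix = pd.DataFrame(y, index=probe_ids, columns=sheet["sample_id"].to_numpy())
    gene_map = pd.DataFrame({"gene": [e.gene for e in gene_effects]}, index=probe_ids.copy())
    return matrix, gene_map
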