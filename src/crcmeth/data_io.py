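"""Core containers and file I/O for paired methylation-array data.

In-memory conventions (pandas throughout):

* **BetaMatrix** — ``pandas.DataFrame``, loci as rows (index ``locus_id``),
  samples as columns, beta values in ``[0, 1]`` with ``NaN`` for missing.
* **SampleSheet** — ``pandas.DataFrame`` with one row per array sample and
  columns ``sample_id, person_id, tissue, msi_status, location, sex, age,
  stage``.  ``tissue`` is ``tumor``/``normal``; ``msi_status`` is
  ``MSI``/``MSS``; ``location`` is ``left``/``right``.
* **LocusAnnotation** — ``pandas.DataFrame`` indexed by ``locus_id`` with
  columns ``gene_symbols`` (semicolon-joined, possibly empty), ``region``
  (one of the CpG-island relation bands) and ``promoter_associated`` (bool).

Files are plain text: beta matrices and annotations are TSV (``NA`` for
missing), sample sheets are CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

#: Region categories: distance bands from a CpG island (0 / 0-2 kb / 2-4 kb /
#: >4 kb, split north/south of the island).  "DeepSea" is accepted as an
#: input alias for OpenSea.
REGIONS = ("Island", "N_Shelf", "N_Shore", "S_Shelf", "S_Shore", "OpenSea")
_REGION_ALIASES = {"DeepSea": "OpenSea", "Deep Sea": "OpenSea", "Open Sea": "OpenSea"}

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "person_id",
    "tissue",
    "msi_status",
    "location",
    "sex",
    "age",
    "stage",
)


class UndefinedBetaError(ValidationError):
    """Raised when both channel intensities are zero (beta is 0/0)."""


class PairingError(ValidationError):
    """Raised when a person carries duplicate tumor or normal samples."""


def compute_beta(x_meth, y_unmeth, offset: float = 0.0):
    """Methylation score (beta value) from channel intensities.

    beta = X / (X + Y + offset), where X is the methylated-probe intensity
    and Y the unmethylated-probe intensity.  The default ``offset`` is 0
    (the plain intensity fraction); the common array-software stabilising
    constant (e.g. 100) can be supplied explicitly.

    Accepts scalars or array-likes; fully vectorised.

    Raises
    ------
    ValidationError
        If any intensity is negative.
    UndefinedBetaError
        If ``x + y + offset == 0`` anywhere (distinct from a missing value).
    """
    x = np.asarray(x_meth, dtype=float)
    y = np.asarray(y_unmeth, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("intensities must be non-negative")
    denom = x + y + offset
    if np.any(denom == 0):
        raise UndefinedBetaError("beta undefined: methylated + unmethylated intensity is 0")
    beta = x / denom
    return float(beta) if beta.ndim == 0 else beta


# ---------------------------------------------------------------------------
# Beta-matrix I/O
# ---------------------------------------------------------------------------


def _check_unique(ids, what: str):
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate {what} ID(s): {', '.join(map(str, dup[:5]))}")


def validate_beta_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a loci x samples beta DataFrame; returns it unchanged."""
    _check_unique(matrix.index, "locus")
    _check_unique(matrix.columns, "sample")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad & ~np.isnan(values)):
        i, j = np.argwhere(bad & ~np.isnan(values))[0]
        raise ValidationError(
            f"beta value out of [0, 1] at locus {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}: {values[i, j]}"
        )
    return matrix


def _check_rectangular(path, sep: str):
    n_fields = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count(sep) + 1
            if n_fields is None:
                n_fields = n
            elif n != n_fields:
                raise ValidationError(f"ragged row at line {lineno} of {path}: {n} fields, expected {n_fields}")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a TSV beta matrix (first column locus_id, header sample IDs)."""
    _check_rectangular(path, "\t")
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "locus_id"
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    return validate_beta_matrix(matrix)


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    """Write TSV; 12 significant digits so a round-trip is lossless."""
    validate_beta_matrix(matrix)
    out = matrix.copy()
    out.index.name = "locus_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {', '.join(missing)}")
    _check_unique(sheet["sample_id"], "sample")
    bad_tissue = set(sheet["tissue"]) - {"tumor", "normal"}
    if bad_tissue:
        raise ValidationError(f"unknown tissue value(s): {bad_tissue}")
    bad_msi = set(sheet["msi_status"]) - {"MSI", "MSS"}
    if bad_msi:
        raise ValidationError(f"unknown msi_status value(s): {bad_msi}")
    # person-level covariates must be constant within person
    for col in ("msi_status", "location", "sex", "age"):
        per = sheet.groupby("person_id")[col].nunique()
        if (per > 1).any():
            person = per[per > 1].index[0]
            raise ValidationError(f"{col} is not constant within person {person!r}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    _check_rectangular(path, ",")
    sheet = pd.read_csv(path, dtype={"sample_id": str, "person_id": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Locus annotation
# ---------------------------------------------------------------------------


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ("region", "promoter_associated"):
        if col not in ann.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    _check_unique(ann.index, "locus")
    ann = ann.copy()
    ann["region"] = ann["region"].replace(_REGION_ALIASES)
    unknown = set(ann["region"]) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region value(s): {unknown}")
    if "gene_symbols" not in ann.columns:
        ann["gene_symbols"] = ""
    ann["gene_symbols"] = ann["gene_symbols"].fillna("")
    ann["promoter_associated"] = ann["promoter_associated"].astype(bool)
    return ann


def read_annotation(path) -> pd.DataFrame:
    _check_rectangular(path, "\t")
    ann = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    ann.index = ann.index.astype(str)
    ann.index.name = "locus_id"
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann).to_csv(path, sep="\t", na_rep="NA")


def annotation_genes(ann: pd.DataFrame) -> pd.Series:
    """Per-locus list of gene symbols (split on ';', empty list if none)."""
    return ann["gene_symbols"].map(lambda s: [g for g in str(s).split(";") if g])


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


@dataclass
class PairingReport:
    """Complete tumor/normal pairs plus a report of incomplete persons."""

    pairs: dict[str, tuple[str, str]]  # person -> (tumor sample, normal sample)
    incomplete: dict[str, str] = field(default_factory=dict)  # person -> missing half

    def __len__(self) -> int:
        return len(self.pairs)


def validate_pairing(sheet: pd.DataFrame) -> PairingReport:
    """Map persons to their (tumor, normal) sample pair.

    Persons missing one half are excluded from ``pairs`` and listed in
    ``incomplete``.  Two samples of the same tissue for one person is a data
    integrity error.
    """
    validate_sample_sheet(sheet)
    pairs: dict[str, tuple[str, str]] = {}
    incomplete: dict[str, str] = {}
    for person, grp in sheet.groupby("person_id", sort=False):
        counts = grp["tissue"].value_counts()
        if counts.get("tumor", 0) > 1 or counts.get("normal", 0) > 1:
            raise PairingError(f"person {person!r} has duplicate tumor or normal samples")
        tumor = grp.loc[grp["tissue"] == "tumor", "sample_id"]
        normal = grp.loc[grp["tissue"] == "normal", "sample_id"]
        if len(tumor) and len(normal):
            pairs[str(person)] = (tumor.iloc[0], normal.iloc[0])
        else:
            incomplete[str(person)] = "tumor" if len(normal) else "normal"
    return PairingReport(pairs=pairs, incomplete=incomplete)
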