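"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices arrive as TSV (first column = feature id, header row =
sample ids) or GCT 1.2.  Clinical tables are CSV with mandatory columns
``sample_id``, ``time_months``, ``event``; any additional column is carried
as a covariate.  Present/absent call matrices use MAS5-style P/A/M codes
(M, "marginal", is treated as absent).  Signatures and gene lists are TSV.

Writers emit a leading ``#`` comment line carrying provenance (config hash,
seed) when supplied; readers skip ``#`` lines, so round-trips are lossless.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, Signature

logger = logging.getLogger(__name__)


class ExpressionFormatError(ValueError):
    """Malformed expression input (ragged rows, non-numeric cells, bad GCT)."""


class DuplicateIdError(ExpressionFormatError):
    """Duplicate feature or sample identifiers in an input file."""


class DimensionMismatchError(ExpressionFormatError):
    """GCT header counts disagree with the body."""


class ClinicalSchemaError(ValueError):
    """Clinical table violates the required schema."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read a feature × sample expression matrix from TSV or GCT 1.2.

    ``format='auto'`` picks GCT for a ``.gct`` suffix, TSV otherwise.
    """
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        matrix = _read_expression_tsv(path)
    elif format == "gct":
        matrix = _read_expression_gct(path)
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    logger.info(
        "read expression matrix %s: %d features x %d samples",
        path.name, matrix.n_features, matrix.n_samples,
    )
    return matrix


def _finalize_frame(df: pd.DataFrame, path: Path) -> ExpressionMatrix:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionFormatError(f"{path}: non-numeric expression values ({exc})") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise ExpressionFormatError(f"{path}: non-finite expression values")
    return ExpressionMatrix(values)


def _read_expression_tsv(path: Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ExpressionFormatError(f"{path}: ragged or unparseable TSV ({exc})") from exc
    # pandas silently mangles duplicate header names (A, A.1): detect them raw
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
    if header is not None:
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise DuplicateIdError(f"{path}: duplicate sample ids in header")
    return _finalize_frame(df, path)


def _read_expression_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ExpressionFormatError(f"{path}: unsupported GCT version line {version!r}")
        try:
            n_rows, n_cols = (int(tok) for tok in fh.readline().split())
        except ValueError as exc:
            raise ExpressionFormatError(f"{path}: bad GCT dimension line") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0].lower() != "name":
            raise ExpressionFormatError(f"{path}: bad GCT header line")
        samples = header[2:]
        if len(samples) != n_cols:
            raise DimensionMismatchError(
                f"{path}: header declares {n_cols} samples, found {len(samples)}"
            )
        if len(set(samples)) != len(samples):
            raise DuplicateIdError(f"{path}: duplicate sample ids")
        names, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 2:
                raise ExpressionFormatError(f"{path}: ragged GCT data row")
            names.append(parts[0])
            rows.append(parts[2:])
        if len(names) != n_rows:
            raise DimensionMismatchError(
                f"{path}: header declares {n_rows} rows, found {len(names)}"
            )
    df = pd.DataFrame(rows, index=pd.Index(names, name="feature_id"), columns=samples)
    return _finalize_frame(df, path)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    """Write the matrix as TSV, optionally preceded by a '#' provenance line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.values.copy()
        out.index.name = out.index.name or "feature_id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation / call matrix
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: feature_id, gene_symbol, chromosome, is_ion_channel."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: annotation needs a feature_id column")
    df = df.set_index("feature_id")
    if df.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate feature ids in annotation")
    if "is_ion_channel" in df.columns:
        df["is_ion_channel"] = (
            df["is_ion_channel"].fillna("0").str.strip().str.lower()
            .isin({"1", "true", "yes", "y"})
        )
    return df


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    """P/A/M detection-call TSV → boolean present/absent frame (M → absent)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    codes = df.apply(lambda s: s.str.strip().str.upper())
    bad = ~codes.isin(["P", "A", "M"]).to_numpy()
    if bad.any():
        raise ValueError(f"{path}: call matrix entries must be P/A/M")
    return codes == "P"


def write_call_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    codes = calls.replace({True: "P", False: "A"})
    codes.index.name = codes.index.name or "feature_id"
    codes.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

REQUIRED_CLINICAL = ("sample_id", "time_months", "event")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical CSV.

    Required columns: sample_id, time_months (>0), event (0/1).  Every other
    column (grade, age, sex, surgery, ...) is carried through as a covariate;
    blanks become NaN and are reported.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ClinicalSchemaError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ClinicalSchemaError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")

    times = pd.to_numeric(df["time_months"], errors="coerce")
    bad = df.index[~(times > 0) | ~np.isfinite(times)]
    if len(bad):
        rows = [df.index.get_loc(b) + 2 for b in bad[:5]]  # 1-based + header
        raise ClinicalSchemaError(
            f"{path}: non-positive or non-numeric time_months at file row(s) {rows}"
        )
    df["time_months"] = times.astype(float)

    events = pd.to_numeric(df["event"], errors="coerce")
    if not events.isin([0, 1]).all():
        bad = df.index[~events.isin([0, 1])][:5].tolist()
        raise ClinicalSchemaError(f"{path}: event must be 0 or 1 (bad samples: {bad})")
    df["event"] = events.astype(int)

    for col in df.columns:
        if col in ("time_months", "event"):
            continue
        n_missing = df[col].isna().sum()
        if n_missing == len(df):
            logger.warning("clinical covariate %r is entirely missing", col)
        elif n_missing:
            logger.info("clinical covariate %r: %d missing value(s)", col, n_missing)
    return df


# ---------------------------------------------------------------------------
# signatures / gene lists / association tables
# ---------------------------------------------------------------------------

def read_signature(path: str | Path) -> Signature:
    """Signature TSV with columns gene_symbol, weight (±1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_symbol", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: signature needs gene_symbol and weight columns")
    return Signature(pd.Series(df["weight"].to_numpy(), index=df["gene_symbol"], dtype=int))


def write_signature(
    signature: Signature, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_symbol\tweight\n")
        for gene, weight in signature:
            fh.write(f"{gene}\t{weight}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line (or first TSV column); '#' lines skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0])
    return genes


def load_icg_signature() -> Signature:
    """The packaged 18-gene ion-channel signature (2 up, 16 down)."""
    ref = resources.files("icgsig.data") / "icg_signature.tsv"
    with resources.as_file(ref) as path:
        return read_signature(path)


def write_association_table(
    assoc: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a grade-association table (feature_id, gene_symbol, rho, p_raw, p_adj, direction)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = assoc.copy()
        out.index.name = out.index.name or "feature_id"
        out.to_csv(fh, sep="\t", float_format="%.6g")
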