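"""Readers/writers for expression, Ct and metadata tables, plus model JSON.

File dialect: tab-separated text, one header row of sample IDs, one leading
column of miRNA IDs (the flat layout of GEO series-matrix exports and of
qPCR spreadsheets). Missing cells are the empty string or ``NA`` and are
preserved as NaN; they are never imputed. Model files are JSON with an
explicit schema version so panels travel across languages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODEL_SCHEMA_VERSION = 1

LINEAR_ALGORITHMS = frozenset({"lasso_logistic", "logistic"})
ALGORITHMS = frozenset({"lasso_logistic", "logistic", "random_forest", "svm"})

_MODEL_KEYS = {
    "schema_version",
    "pairs",
    "algorithm",
    "parameters",
    "coefficients",
    "lambda",
    "covariates_used",
    "training_fingerprint",
}


class FormatError(ValueError):
    """Malformed input table (duplicates, empty file, bad cell)."""


class ModelValidationError(ValueError):
    """Model file violates the schema or its internal invariants."""


@dataclass
class ExpressionMatrix:
    """miRNA x sample matrix of log2 intensities or RT-qPCR Ct values.

    ``values`` is a DataFrame indexed by miRNA ID with sample IDs as
    columns, in file order. ``scale_tag`` declares the scale: ``"log2"``
    for chip-style log2 abundances, ``"ct"`` for cycle thresholds (where
    abundance is modelled as proportional to ``2**-Ct``).
    """

    values: pd.DataFrame
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "ct"):
            raise ValueError(f"scale_tag must be 'log2' or 'ct', got {self.scale_tag!r}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise FormatError("expression matrix must have at least one row and column")
        dup_m = self.values.index[self.values.index.duplicated()]
        if len(dup_m):
            raise FormatError(f"duplicate miRNA ID(s): {sorted(set(dup_m))}")
        dup_s = self.values.columns[self.values.columns.duplicated()]
        if len(dup_s):
            raise FormatError(f"duplicate sample ID(s): {sorted(set(dup_s))}")
        self.values = self.values.astype(float)
        if self.scale_tag == "ct":
            finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
            if finite.size and (finite <= 0).any():
                raise FormatError("Ct matrix contains non-positive cycle thresholds")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_by_mirnas(self) -> pd.DataFrame:
        """Samples x miRNAs orientation, for estimator-style consumers."""
        return self.values.T


METADATA_COLUMNS = ("sample_id", "label", "age", "sex", "stage")
LABELS = ("control", "case")


def read_expression_matrix(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a TSV expression/Ct matrix (header: sample IDs, col 0: miRNA IDs)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in header:  # pandas silently mangles duplicate columns, so check here
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample ID {sid!r}")
        seen.add(sid)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=0,
            na_values=["NA"], keep_default_na=False, dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    frame.index = frame.index.astype(str)
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for j, col in enumerate(frame.columns):
        raw = frame[col].to_numpy(dtype=object)
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or (isinstance(cell, str) and cell.strip() == ""):
                out[i] = np.nan
                continue
            try:
                # np.float64 parses shortest-repr decimals back bit-exactly
                out[i] = np.float64(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{frame.index[i]!r} (#{i + 1}), column {col!r} (#{j + 1})"
                ) from exc
        numeric[col] = out
    return ExpressionMatrix(numeric, scale_tag=scale_tag)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips exactly through ``read_expression_matrix``."""
    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("expected an ExpressionMatrix")
    out = matrix.values.copy()
    out.index.name = "mirna_id"
    # repr() of a float is shortest-exact in Python 3: lossless round trip
    out.to_csv(path, sep="\t", na_rep="", float_format=lambda v: repr(float(v)))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, label, optional age/sex/stage)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                       na_values=["NA", ""], keep_default_na=False)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in meta.columns or "label" not in meta.columns:
        raise FormatError("metadata requires 'sample_id' and 'label' columns")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s) in metadata: {dups}")
    bad = set(meta["label"]) - set(LABELS)
    if bad:
        raise FormatError(f"labels must be in {LABELS}, got {sorted(bad)}")
    for col in ("age", "sex", "stage"):
        if col not in meta.columns:
            meta[col] = np.nan
    if meta["age"].notna().any():
        ages = pd.to_numeric(meta["age"], errors="raise")
        if (ages.dropna() < 0).any():
            raise FormatError("negative age in metadata")
        meta["age"] = ages
    for col, allowed in (("sex", {"female", "male"}), ("stage", {"early", "advanced"})):
        vals = set(meta[col].dropna()) - allowed
        if vals:
            raise FormatError(f"{col} values must be in {sorted(allowed)}, got {sorted(vals)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta.copy()).to_csv(path, sep="\t", index=False, na_rep="")


def labels_for(matrix_samples: Sequence[str], meta: pd.DataFrame) -> np.ndarray:
    """0/1 label vector (control=0, case=1) aligned to ``matrix_samples``.

    Every sample must have exactly one metadata row and both classes must be
    present — a single-class cohort cannot be modelled.
    """
    lookup = meta.set_index("sample_id")["label"]
    missing = [s for s in matrix_samples if s not in lookup.index]
    if missing:
        raise FormatError(f"samples without metadata: {missing[:5]}")
    y = np.asarray([1 if lookup[s] == "case" else 0 for s in matrix_samples])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (case and control) must be present")
    return y


@dataclass
class ModelFile:
    """Serializable description of a fitted pair-panel model.

    Linear families (``logistic``, ``lasso_logistic``) carry their
    coefficients as ``[intercept, *pair_coefs, *covariate_coefs]``; tree and
    kernel families must not.
    """

    pairs: list[tuple[str, str]]
    algorithm: str
    parameters: dict = field(default_factory=dict)
    coefficients: list[float] | None = None
    lambda_: float | None = None
    covariates_used: list[str] = field(default_factory=list)
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        if not self.pairs:
            raise ModelValidationError("pairs must be non-empty")
        for a, b in self.pairs:
            if not a < b:
                raise ModelValidationError(
                    f"pair ({a!r}, {b!r}) not in canonical lexicographic order"
                )
        if self.algorithm not in ALGORITHMS:
            raise ModelValidationError(f"unknown algorithm {self.algorithm!r}")
        if set(self.covariates_used) - {"age", "sex"}:
            raise ModelValidationError("covariates_used must be a subset of {age, sex}")
        if self.algorithm in LINEAR_ALGORITHMS:
            if self.coefficients is None:
                raise ModelValidationError("linear models require coefficients")
            expect = 1 + len(self.pairs) + len(self.covariates_used)
            if len(self.coefficients) != expect:
                raise ModelValidationError(
                    f"coefficients length {len(self.coefficients)} != "
                    f"1 intercept + {len(self.pairs)} pairs + "
                    f"{len(self.covariates_used)} covariates = {expect}"
                )
        elif self.coefficients is not None:
            raise ModelValidationError(
                f"{self.algorithm} models must not carry coefficients"
            )
        if self.lambda_ is not None and not self.lambda_ > 0:
            raise ModelValidationError("lambda must be positive when present")

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "pairs": [list(p) for p in self.pairs],
            "algorithm": self.algorithm,
            "parameters": self.parameters,
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "covariates_used": list(self.covariates_used),
            "training_fingerprint": self.training_fingerprint,
        }


def write_model(model: ModelFile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path: str | Path) -> ModelFile:
    doc = json.loads(Path(path).read_text())
    return model_from_dict(doc)


def model_from_dict(doc: dict) -> ModelFile:
    if not isinstance(doc, dict):
        raise ModelValidationError("model document must be a JSON object")
    unknown = set(doc) - _MODEL_KEYS
    if unknown:
        raise ModelValidationError(f"unknown top-level key(s): {sorted(unknown)}")
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelValidationError(f"unsupported schema_version {version!r}")
    return ModelFile(
        pairs=[tuple(p) for p in doc.get("pairs", [])],
        algorithm=doc.get("algorithm", ""),
        parameters=doc.get("parameters", {}) or {},
        coefficients=doc.get("coefficients"),
        lambda_=doc.get("lambda"),
        covariates_used=list(doc.get("covariates_used", []) or []),
        training_fingerprint=doc.get("training_fingerprint", "") or "",
    )
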