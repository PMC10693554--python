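"""Feature-table ingestion and design construction for rumen-microbiome CH4 models.

The modeling pipeline starts from a per-observation table: each row is one
respiration-chamber measurement round of one animal, carrying the two methane
responses (CH4 production in g/d and CH4 yield in g/kg DMI), animal covariates
(dry matter intake, body weight, acetate:propionate ratio, sex, breed) and the
relative sequence abundances of microbial genera profiled from the rumen
sample taken at that round. Genus columns are named ``<domain>__<genus>`` with
domain one of ``bacteria``, ``archaea``, ``protozoa``, ``fungi``.

This module validates such tables, applies the rare-genus prevalence filter
and the log transform, and assembles the standardized design matrices used by
the two model families:

* ``ANIM-B`` — predicts CH4 production; animal predictors DMI, BW, A:P ratio.
* ``DMI-B``  — predicts CH4 yield; DMI is excluded (it is the denominator of
  the response), leaving BW and A:P ratio.

Sex and breed never enter a design matrix. All operations are pure: they
return new objects and never mutate their inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "ANIMAL_PREDICTORS",
    "FAMILY_RESPONSE",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "EmptyFeatureError",
    "ObservationRecord",
    "ObservationTable",
    "ModelingMatrix",
    "load_dataset",
    "filter_genera",
    "log_transform_abundances",
    "build_design",
    "prepare_matrix",
    "standardize_train_apply_test",
    "destandardize",
    "save_matrix",
    "load_matrix",
]

DOMAINS = ("bacteria", "archaea", "protozoa", "fungi")

#: canonical per-observation (non-genus) column names
CANONICAL_COLUMNS = (
    "animal_id",
    "round_index",
    "ch4_production",
    "ch4_yield",
    "dmi",
    "bw",
    "ap_ratio",
    "sex",
    "breed",
)

#: animal-covariate candidate predictors per model family
ANIMAL_PREDICTORS = {"ANIM-B": ("dmi", "bw", "ap_ratio"), "DMI-B": ("bw", "ap_ratio")}
FAMILY_RESPONSE = {"ANIM-B": "ch4_production", "DMI-B": "ch4_yield"}

_POSITIVE_COLUMNS = ("dmi", "bw", "ap_ratio")
_NUMERIC_COLUMNS = ("ch4_production", "ch4_yield", "dmi", "bw", "ap_ratio")
_DOMAIN_SUM_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or a genus column is malformed."""


class ValidationError(ValueError):
    """A row violates the observation-record contract."""


class ConfigurationError(ValueError):
    """Mutually inconsistent options (e.g. family/response mismatch)."""


class EmptyFeatureError(ValueError):
    """A filter removed every genus column."""


@dataclass(frozen=True)
class ObservationRecord:
    """One animal-round observation (a single row of the feature table)."""

    animal_id: str
    round_index: int
    ch4_production: float
    ch4_yield: float
    dmi: float
    bw: float
    ap_ratio: float
    sex: str
    breed: str
    abundances: Mapping[str, float]


@dataclass(frozen=True)
class ObservationTable:
    """A validated collection of observation records.

    ``data`` holds one row per observation with the canonical columns followed
    by the genus columns; ``genus_columns`` preserves column order and
    ``genus_domains`` maps each genus column to its amplicon domain.
    ``log_transformed`` flags whether genus columns hold log abundances (the
    transform is refused a second time).
    """

    data: pd.DataFrame
    genus_columns: tuple[str, ...]
    genus_domains: Mapping[str, str]
    log_transformed: bool = False
    pseudocount: float | None = None

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_animals(self) -> int:
        return self.data["animal_id"].nunique()

    def records(self) -> Iterator[ObservationRecord]:
        for _, row in self.data.iterrows():
            yield ObservationRecord(
                animal_id=str(row["animal_id"]),
                round_index=int(row["round_index"]),
                ch4_production=float(row["ch4_production"]),
                ch4_yield=float(row["ch4_yield"]),
                dmi=float(row["dmi"]),
                bw=float(row["bw"]),
                ap_ratio=float(row["ap_ratio"]),
                sex=str(row["sex"]),
                breed=str(row["breed"]),
                abundances={g: float(row[g]) for g in self.genus_columns},
            )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _parse_genus_domain(column: str) -> str:
    domain, sep, genus = column.partition("__")
    if not sep or domain not in DOMAINS or not genus:
        raise SchemaError(
            f"genus column {column!r} must be named '<domain>__<genus>' with "
            f"domain in {DOMAINS}"
        )
    return domain


def _validate_frame(df: pd.DataFrame, genus_columns: Sequence[str],
                    validate_abundances: bool = True) -> None:
    for col in _NUMERIC_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"column {col!r} missing/non-numeric in row(s) {list(bad)}")
    for col in _POSITIVE_COLUMNS:
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(f"column {col!r} must be > 0; violated in row(s) {list(bad)}")
    rounds = df["round_index"]
    if not rounds.isin((1, 2)).all():
        bad = df.index[~rounds.isin((1, 2))]
        raise ValidationError(f"round_index must be 1 or 2; violated in row(s) {list(bad)}")
    dup = df.duplicated(subset=["animal_id", "round_index"])
    if dup.any():
        raise ValidationError(
            f"duplicate (animal_id, round_index) pairs in row(s) {list(df.index[dup])}"
        )
    if genus_columns:
        ab = df[list(genus_columns)]
        if ab.isna().any().any():
            bad = df.index[ab.isna().any(axis=1)]
            raise ValidationError(f"missing abundance value(s) in row(s) {list(bad)}")
        if validate_abundances:
            if (ab.to_numpy() < 0).any():
                bad = df.index[(ab < 0).any(axis=1)]
                raise ValidationError(f"negative abundance value(s) in row(s) {list(bad)}")
            domains = {g: _parse_genus_domain(g) for g in genus_columns}
            for domain in DOMAINS:
                cols = [g for g in genus_columns if domains[g] == domain]
                if not cols:
                    continue
                sums = ab[cols].sum(axis=1)
                over = df.index[sums > 1.0 + _DOMAIN_SUM_TOL]
                if len(over):
                    raise ValidationError(
                        f"{domain} abundances sum to > 1 in row(s) {list(over)}"
                    )


def load_dataset(path, schema: Mapping[str, str] | None = None) -> ObservationTable:
    """Read a delimited per-observation table into a validated ObservationTable.

    Parameters
    ----------
    path
        CSV/TSV file, one row per observation, UTF-8.
    schema
        Optional mapping from canonical column names (``animal_id`` ...) to the
        names used in the file. Unmapped columns are treated as genus-abundance
        columns and must follow the ``<domain>__<genus>`` convention.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"mapped column(s) {missing} not found in {path}")
    df = df.rename(columns=rename)
    genus_columns = tuple(c for c in df.columns if c not in CANONICAL_COLUMNS)
    genus_domains = {g: _parse_genus_domain(g) for g in genus_columns}
    for col in _NUMERIC_COLUMNS + tuple(genus_columns):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["animal_id"] = df["animal_id"].astype(str)
    df["round_index"] = pd.to_numeric(df["round_index"], errors="coerce")
    if df["round_index"].isna().any():
        bad = df.index[df["round_index"].isna()]
        raise ValidationError(f"non-integer round_index in row(s) {list(bad)}")
    df["round_index"] = df["round_index"].astype(int)
    _validate_frame(df, genus_columns)
    ordered = list(CANONICAL_COLUMNS) + list(genus_columns)
    return ObservationTable(
        data=df[ordered].reset_index(drop=True),
        genus_columns=genus_columns,
        genus_domains=genus_domains,
    )


def filter_genera(
    table: ObservationTable,
    min_abundance: float = 1e-4,
    prevalence_rule: str | float = "any",
) -> tuple[ObservationTable, list[str]]:
    """Drop rare genera by a (threshold, prevalence) rule.

    A genus is retained when its relative abundance exceeds ``min_abundance``
    in: every sample (``"all"``), at least one sample (``"any"``), or at least
    a fraction ``p`` of samples (``prevalence_rule=p`` with ``0 < p <= 1``).
    Returns the reduced table and the list of dropped genus columns.
    """
    if not 0 <= min_abundance < 1:
        raise ConfigurationError("min_abundance must satisfy 0 <= min_abundance < 1")
    if table.log_transformed:
        raise ConfigurationError("filter_genera must run before the log transform")
    ab = table.data[list(table.genus_columns)].to_numpy()
    frac_above = (ab > min_abundance).mean(axis=0)
    if prevalence_rule == "all":
        keep_mask = frac_above == 1.0
    elif prevalence_rule == "any":
        keep_mask = frac_above > 0.0
    else:
        p = float(prevalence_rule)
        if not 0 < p <= 1:
            raise ConfigurationError("fractional prevalence rule must be in (0, 1]")
        keep_mask = frac_above >= p
    kept = tuple(g for g, k in zip(table.genus_columns, keep_mask) if k)
    dropped = [g for g, k in zip(table.genus_columns, keep_mask) if not k]
    if not kept:
        raise EmptyFeatureError(
            f"filter (min_abundance={min_abundance}, rule={prevalence_rule!r}) "
            "removed every genus"
        )
    data = table.data[list(CANONICAL_COLUMNS) + list(kept)].copy()
    domains = {g: table.genus_domains[g] for g in kept}
    return (
        ObservationTable(data=data, genus_columns=kept, genus_domains=domains,
                         log_transformed=False),
        dropped,
    )


def log_transform_abundances(
    table: ObservationTable, pseudocount: float = 1e-6
) -> ObservationTable:
    """Replace each abundance x by ln(x + pseudocount).

    A pseudocount of 0 is only legal when no abundance is exactly zero. The
    returned table is flagged so the transform cannot be applied twice.
    """
    if table.log_transformed:
        raise ConfigurationError("abundances are already log-transformed")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    ab = table.data[list(table.genus_columns)].to_numpy(dtype=float)
    if pseudocount == 0 and (ab == 0).any():
        raise ValidationError("zero abundance present; a positive pseudocount is required")
    data = table.data.copy()
    data[list(table.genus_columns)] = np.log(ab + pseudocount)
    return ObservationTable(
        data=data,
        genus_columns=table.genus_columns,
        genus_domains=dict(table.genus_domains),
        log_transformed=True,
        pseudocount=pseudocount,
    )


@dataclass(frozen=True)
class ModelingMatrix:
    """Aligned response, design and animal grouping for one model family.

    ``column_kind`` marks each design column ``"animal"`` or ``"microbial"``.
    ``center``/``scale`` are present only after standardization and always come
    from a designated training subset.
    """

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...]
    column_kind: tuple[str, ...]
    group: np.ndarray
    family: str
    response: str
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.y)
        if self.X.shape != (n, len(self.columns)) or len(self.group) != n:
            raise ConfigurationError("response, design and group must align")
        if len(self.column_kind) != len(self.columns):
            raise ConfigurationError("column_kind must label every column")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return len(self.columns)

    @property
    def is_standardized(self) -> bool:
        return self.center is not None

    def restrict(self, columns: Sequence[str]) -> "ModelingMatrix":
        """Return a copy keeping only ``columns`` (order as given)."""
        idx = []
        pos = {c: i for i, c in enumerate(self.columns)}
        for c in columns:
            if c not in pos:
                raise ConfigurationError(f"column {c!r} not in matrix")
            idx.append(pos[c])
        idx = np.asarray(idx, dtype=int)
        return dataclasses.replace(
            self,
            X=self.X[:, idx].copy() if len(idx) else np.empty((self.n_obs, 0)),
            columns=tuple(self.columns[i] for i in idx),
            column_kind=tuple(self.column_kind[i] for i in idx),
            center=None if self.center is None else self.center[idx].copy(),
            scale=None if self.scale is None else self.scale[idx].copy(),
        )

    def subset_rows(self, mask_or_index) -> "ModelingMatrix":
        idx = np.asarray(mask_or_index)
        return dataclasses.replace(
            self,
            y=self.y[idx].copy(),
            X=self.X[idx].copy(),
            group=self.group[idx].copy(),
        )

    def split_by_animals(
        self, train_animals: Sequence, test_animals: Sequence
    ) -> tuple["ModelingMatrix", "ModelingMatrix"]:
        train_set, test_set = set(train_animals), set(test_animals)
        if train_set & test_set:
            raise ConfigurationError("train and test animal sets overlap")
        in_train = np.array([g in train_set for g in self.group])
        in_test = np.array([g in test_set for g in self.group])
        return self.subset_rows(in_train), self.subset_rows(in_test)


def build_design(
    table: ObservationTable,
    family: str,
    response_choice: str | None = None,
) -> ModelingMatrix:
    """Assemble the (unstandardized) modeling matrix for one family.

    ANIM-B uses CH4 production with candidate animal columns DMI, BW, A:P;
    DMI-B uses CH4 yield with BW and A:P (DMI excluded). All retained genus
    columns (which must already be log-transformed) are appended as microbial
    candidates. Sex and breed are never included.
    """
    if family not in ANIMAL_PREDICTORS:
        raise ConfigurationError(f"unknown family {family!r}; expected ANIM-B or DMI-B")
    response = FAMILY_RESPONSE[family]
    if response_choice is not None and response_choice != response:
        raise ConfigurationError(
            f"family {family} predicts {response!r}, not {response_choice!r}"
        )
    if not table.log_transformed:
        raise ConfigurationError(
            "abundances must be log-transformed before building the design"
        )
    animal_cols = ANIMAL_PREDICTORS[family]
    cols = list(animal_cols) + list(table.genus_columns)
    kinds = ("animal",) * len(animal_cols) + ("microbial",) * len(table.genus_columns)
    X = table.data[cols].to_numpy(dtype=float)
    return ModelingMatrix(
        y=table.data[response].to_numpy(dtype=float),
        X=X,
        columns=tuple(cols),
        column_kind=kinds,
        group=table.data["animal_id"].to_numpy(),
        family=family,
        response=response,
    )


def prepare_matrix(
    table: ObservationTable,
    family: str,
    min_abundance: float = 1e-4,
    prevalence_rule: str | float = "any",
    pseudocount: float = 1e-6,
    response_choice: str | None = None,
) -> ModelingMatrix:
    """Convenience: filter rare genera, log-transform, build the design."""
    filtered, _ = filter_genera(table, min_abundance, prevalence_rule)
    logged = log_transform_abundances(filtered, pseudocount)
    return build_design(logged, family, response_choice)


def standardize_train_apply_test(
    train: ModelingMatrix,
    test: ModelingMatrix | None = None,
) -> tuple[ModelingMatrix, ModelingMatrix | None]:
    """Center/scale predictors with training statistics only.

    Uses the sample standard deviation (denominator n-1). The response is left
    on its original scale, so fitted intercepts stay in response units. A
    zero-variance training column is an error naming the column.
    """
    if test is not None and test.columns != train.columns:
        raise ConfigurationError("train and test matrices must share columns")
    center = train.X.mean(axis=0)
    scale = train.X.std(axis=0, ddof=1)
    zero = [c for c, s in zip(train.columns, scale) if not np.isfinite(s) or s == 0]
    if zero:
        raise ValidationError(f"zero-variance training column(s): {zero}")
    train_s = dataclasses.replace(
        train, X=(train.X - center) / scale, center=center, scale=scale
    )
    test_s = None
    if test is not None:
        test_s = dataclasses.replace(
            test, X=(test.X - center) / scale, center=center.copy(), scale=scale.copy()
        )
    return train_s, test_s


def destandardize(matrix: ModelingMatrix) -> ModelingMatrix:
    """Invert standardization using the stored statistics."""
    if not matrix.is_standardized:
        raise ConfigurationError("matrix is not standardized")
    return dataclasses.replace(
        matrix, X=matrix.X * matrix.scale + matrix.center, center=None, scale=None
    )


def save_matrix(matrix: ModelingMatrix, path_prefix: str) -> None:
    """Write a matrix as ``<prefix>.csv`` plus a ``<prefix>.json`` sidecar."""
    df = pd.DataFrame(matrix.X, columns=list(matrix.columns))
    df.insert(0, "animal_id", matrix.group)
    df.insert(1, "response", matrix.y)
    df.to_csv(f"{path_prefix}.csv", index=False)
    meta = {
        "family": matrix.family,
        "response": matrix.response,
        "columns": list(matrix.columns),
        "column_kind": list(matrix.column_kind),
        "center": None if matrix.center is None else list(map(float, matrix.center)),
        "scale": None if matrix.scale is None else list(map(float, matrix.scale)),
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_matrix(path_prefix: str) -> ModelingMatrix:
    df = pd.read_csv(f"{path_prefix}.csv")
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    return ModelingMatrix(
        y=df["response"].to_numpy(dtype=float),
        X=df[meta["columns"]].to_numpy(dtype=float),
        columns=tuple(meta["columns"]),
        column_kind=tuple(meta["column_kind"]),
        group=df["animal_id"].to_numpy(),
        family=meta["family"],
        response=meta["response"],
        center=None if meta["center"] is None else np.asarray(meta["center"], dtype=float),
        scale=None if meta["scale"] is None else np.asarray(meta["scale"], dtype=float),
    )
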