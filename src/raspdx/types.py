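"""Core data containers for the PDX signature-response pipeline.

The containers are thin, validated wrappers around pandas objects.  They
exist to make the invariants of each stage explicit (disjoint up/down gene
sets, finite log-scale expression, one arm per animal, a controlled KRAS
vocabulary) and to carry provenance that downstream joins can check.

Gene identifiers are case-normalized to upper case on construction, so all
set comparisons inside the package are case-insensitive.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

logger = logging.getLogger(__name__)

#: Accepted values for :attr:`ExpressionMatrix.scale_tag`.
SCALE_TAGS = ("log10", "log2", "linear", "zscored")

#: Controlled vocabulary for the KRAS codon-12/13 class.
KRAS_CLASSES = ("WT", "G12x", "G13D")

ARMS = ("control", "treated")


def _dedupe_upper(genes: Iterable[str], direction: str) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    n_dup = 0
    for g in genes:
        gu = str(g).strip().upper()
        if not gu:
            raise ValidationError(f"empty gene identifier in '{direction}' set")
        if gu in seen:
            n_dup += 1
        seen[gu] = None
    if n_dup:
        logger.warning("collapsed %d duplicate gene(s) in '%s' set", n_dup, direction)
    return tuple(seen)


@dataclass(frozen=True)
class GeneSignature:
    """An up/down expression signature: two disjoint, ordered gene sets.

    The canonical instance in this package is the Loboda-style RAS-pathway
    signature with 105 'Up' and 42 'Down' genes; any pair of disjoint
    non-empty symbol lists is accepted.
    """

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", _dedupe_upper(self.up, "up"))
        object.__setattr__(self, "down", _dedupe_upper(self.down, "down"))
        if not self.up or not self.down:
            raise ValidationError(
                f"signature {self.name!r}: both directions must be non-empty "
                f"(got {len(self.up)} up, {len(self.down)} down)"
            )
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: gene(s) in both directions: "
                + ", ".join(sorted(overlap))
            )


@dataclass(frozen=True)
class MappingReport:
    """Coverage of a signature on one expression platform."""

    signature_name: str
    platform: str
    n_up_requested: int
    n_up_mapped: int
    n_down_requested: int
    n_down_mapped: int
    unmapped_up: tuple[str, ...] = ()
    unmapped_down: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for d, req, mapped, unmapped in (
            ("up", self.n_up_requested, self.n_up_mapped, self.unmapped_up),
            ("down", self.n_down_requested, self.n_down_mapped, self.unmapped_down),
        ):
            if mapped > req:
                raise ValidationError(f"mapping report: {d} mapped > requested")
            if len(unmapped) != req - mapped:
                raise ValidationError(f"mapping report: {d} unmapped list length mismatch")

    def to_dict(self) -> dict:
        return {
            "signature_name": self.signature_name,
            "platform": self.platform,
            "n_up_requested": self.n_up_requested,
            "n_up_mapped": self.n_up_mapped,
            "n_down_requested": self.n_down_requested,
            "n_down_mapped": self.n_down_mapped,
            "unmapped_up": list(self.unmapped_up),
            "unmapped_down": list(self.unmapped_down),
        }


@dataclass(frozen=True)
class MappedSignature:
    """A signature restricted to the genes present in a given matrix."""

    name: str
    up_mapped: tuple[str, ...]
    down_mapped: tuple[str, ...]
    report: MappingReport

    def __post_init__(self) -> None:
        if not self.up_mapped or not self.down_mapped:
            raise ValidationError(
                f"signature {self.name!r} cannot be scored: a direction maps to "
                "no genes in the matrix"
            )


class ExpressionMatrix:
    """A genes x samples real matrix of log-scale expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Identifiers must be unique; values must be finite.
    scale_tag
        One of ``log10``, ``log2``, ``linear``, ``zscored``.
    """

    def __init__(self, values: pd.DataFrame, scale_tag: str = "log2") -> None:
        if scale_tag not in SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {scale_tag!r}; expected one of {SCALE_TAGS}")
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        values = values.copy()
        values.index = values.index.astype(str).str.strip().str.upper()
        values.columns = values.columns.astype(str).str.strip()
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        self.values = values.astype(float)
        self.scale_tag = scale_tag
        if scale_tag == "linear":
            logger.warning(
                "expression matrix is on a linear scale; signature scoring "
                "assumes log-scale input — consider log-transforming first"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_set_hash(self) -> str:
        """Hash of the ordered sample-id set, used for cohort-match checks."""
        h = hashlib.sha256("\t".join(self.sample_ids).encode()).hexdigest()
        return h[:16]

    def drop_incomplete_genes(self) -> "ExpressionMatrix":
        """Remove genes with any missing entry (cleaning pass for raw input)."""
        keep = self.values.notna().all(axis=1)
        if not keep.all():
            logger.warning("dropping %d gene(s) with missing values", int((~keep).sum()))
        return ExpressionMatrix(self.values.loc[keep], self.scale_tag)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples, {self.scale_tag})"


@dataclass
class ScoreTable:
    """Per-sample signature scores with scoring provenance."""

    scores: pd.Series  # index: sample_id, values: score
    signature_name: str
    n_up_used: int
    n_down_used: int
    normalization: str
    sample_set_hash: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite signature score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.scores.index, "score": self.scores.to_numpy()})


class VolumeSeries:
    """Per-animal tumor-volume time courses for a mouse clinical trial.

    Long-format records of (model, animal, arm, day, volume).  Each animal
    belongs to exactly one model and one arm, has a day-0 baseline record,
    and volumes are strictly positive (mm^3).
    """

    REQUIRED = ("model", "animal", "arm", "day", "volume")

    def __init__(self, records: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in records.columns]
        if missing:
            raise ValidationError(f"volume table missing column(s): {missing}")
        df = records.loc[:, list(self.REQUIRED)].copy()
        df["model"] = df["model"].astype(str)
        df["animal"] = df["animal"].astype(str)
        df["arm"] = df["arm"].astype(str).str.lower()
        bad_arms = sorted(set(df["arm"]) - set(ARMS))
        if bad_arms:
            raise ValidationError(f"unknown arm label(s): {bad_arms}; expected {ARMS}")
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
        if (df["day"] < 0).any():
            raise ValidationError("negative measurement day")
        df["volume"] = pd.to_numeric(df["volume"], errors="raise").astype(float)
        if (df["volume"] <= 0).any() or not np.isfinite(df["volume"]).all():
            bad = df.loc[(df["volume"] <= 0) | ~np.isfinite(df["volume"])].iloc[0]
            raise ValidationError(
                f"non-positive volume for animal {bad['animal']!r} at day {bad['day']}"
            )
        if df.duplicated(subset=["animal", "day"]).any():
            bad = df.loc[df.duplicated(subset=["animal", "day"])].iloc[0]
            raise ValidationError(
                f"duplicate record for animal {bad['animal']!r} at day {bad['day']}"
            )
        per_animal = df.groupby("animal").agg(
            n_arms=("arm", "nunique"), n_models=("model", "nunique"), min_day=("day", "min")
        )
        multi_arm = per_animal.index[per_animal["n_arms"] > 1].tolist()
        if multi_arm:
            raise ValidationError(f"animal(s) assigned to both arms: {multi_arm}")
        multi_model = per_animal.index[per_animal["n_models"] > 1].tolist()
        if multi_model:
            raise ValidationError(f"animal(s) assigned to several models: {multi_model}")
        no_baseline = per_animal.index[per_animal["min_day"] != 0].tolist()
        if no_baseline:
            raise ValidationError(f"animal(s) missing a day-0 baseline record: {no_baseline}")
        self.records = df.reset_index(drop=True)

    @property
    def model_ids(self) -> list[str]:
        return sorted(self.records["model"].unique())

    def for_model(self, model_id: str) -> pd.DataFrame:
        sub = self.records.loc[self.records["model"] == str(model_id)]
        if sub.empty:
            raise ValidationError(f"no volume records for model {model_id!r}")
        return sub

    def __len__(self) -> int:
        return len(self.records)


def kras_class(allele: str) -> str:
    """Collapse a KRAS codon-12/13 allele string into the controlled class.

    ``WT`` stays ``WT``; any codon-12 allele (G12C, G12D, G12V, ...) becomes
    ``G12x``; ``G13D`` stays ``G13D``.  The raw allele string is retained on
    the :class:`ModelTable` so finer splits remain possible.
    """
    a = str(allele).strip().upper()
    if a in ("WT", "WILDTYPE", "WILD-TYPE", "WILD TYPE"):
        return "WT"
    if a.startswith("G12"):
        return "G12x"
    if a == "G13D":
        return "G13D"
    raise ValidationError(f"KRAS allele {allele!r} outside the controlled vocabulary")


class ModelTable:
    """Per-model join of signature score, ΔT/ΔC response, and KRAS status.

    Columns: ``model_id``, ``ras_score``, ``delta_t_over_delta_c``,
    ``kras_allele`` (as annotated) and the derived ``kras_class``
    (WT / G12x / G13D).
    """

    def __init__(self, records: pd.DataFrame) -> None:
        required = ("model_id", "ras_score", "delta_t_over_delta_c", "kras_allele")
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValidationError(f"model table missing column(s): {missing}")
        df = records.copy()
        df["model_id"] = df["model_id"].astype(str)
        if df["model_id"].duplicated().any():
            dups = df.loc[df["model_id"].duplicated(), "model_id"].tolist()
            raise ValidationError(f"duplicate model_id(s): {dups}")
        for col in ("ras_score", "delta_t_over_delta_c"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            if not np.isfinite(df[col]).all():
                raise ValidationError(f"non-finite value in column {col!r}")
        df["kras_allele"] = df["kras_allele"].astype(str).str.strip()
        df["kras_class"] = df["kras_allele"].map(kras_class)
        self.records = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "ModelTable":
        return ModelTable(self.records.loc[mask].drop(columns=["kras_class"]))

    def wild_type(self) -> "ModelTable":
        return self.subset(self.records["kras_class"] == "WT")

    def mutant(self) -> "ModelTable":
        """Combined codon-12 and codon-13 mutants."""
        return self.subset(self.records["kras_class"] != "WT")


@dataclass(frozen=True)
class EndpointResult:
    """ΔT/ΔC tumor-growth-inhibition endpoint for one PDX model."""

    model_id: str
    delta_t: float
    delta_c: float
    delta_t_over_delta_c: float
    n_treated: int
    n_control: int
    evaluation_day: int

    def __post_init__(self) -> None:
        if self.n_treated < 1 or self.n_control < 1:
            raise ValidationError("endpoint requires at least one animal per arm")
        if self.delta_c == 0:
            raise ValidationError(f"model {self.model_id!r}: ΔC is zero, ratio undefined")
        expected = self.delta_t / self.delta_c
        if not np.isclose(self.delta_t_over_delta_c, expected, rtol=0, atol=1e-12):
            raise ContractError("delta_t_over_delta_c must equal delta_t / delta_c")


@dataclass(frozen=True)
class AssociationResult:
    """One biomarker-response test: statistic, p-value, subgroup, size."""

    subgroup: str
    n: int
    statistic_name: str  # "pearson_r" or "welch_t"
    statistic: float
    p_value: float
    df: float
    covariate: str = ""

    def __post_init__(self) -> None:
        if self.statistic_name == "pearson_r" and not -1.0 <= self.statistic <= 1.0 + 1e-12:
            raise ValidationError(f"pearson r out of range: {self.statistic}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p-value out of (0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "subgroup": self.subgroup,
            "n": self.n,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
        }
        if self.covariate:
            d["covariate"] = self.covariate
        return d


@dataclass(frozen=True)
class SignContingency:
    """Models cross-classified by score sign and response class in a stratum.

    ``poor`` means ΔT/ΔC above the response threshold (tumor kept growing
    at least as fast as the threshold allows); ``sensitive`` is the
    complement.  Thresholds are strict: a model exactly at a threshold falls
    in the non-positive / sensitive margin.
    """

    subgroup: str
    positive_poor: int
    positive_sensitive: int
    nonpositive_poor: int
    nonpositive_sensitive: int
    score_threshold: float = 0.0
    response_threshold: float = 0.0

    @property
    def n(self) -> int:
        return (
            self.positive_poor
            + self.positive_sensitive
            + self.nonpositive_poor
            + self.nonpositive_sensitive
        )

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "positive_poor": self.positive_poor,
            "positive_sensitive": self.positive_sensitive,
            "nonpositive_poor": self.nonpositive_poor,
            "nonpositive_sensitive": self.nonpositive_sensitive,
            "n": self.n,
            "score_threshold": self.score_threshold,
            "response_threshold": self.response_threshold,
        }
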