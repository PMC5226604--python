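"""Up/down signature scoring of expression matrices.

The score follows the Loboda-style convention for RAS-pathway activity:
every gene is z-normalized across the cohort (mean 0, unit variance per
gene), and a sample's score is the mean z-value of the 'Up' genes minus the
mean z-value of the 'Down' genes.  A higher score indicates stronger
pathway activation.

Two consequences of the construction are worth keeping in mind:

* scores are *cohort-relative* — adding or removing samples changes every
  score, so each :class:`~raspdx.types.ScoreTable` records a hash of the
  sample set it was computed on;
* z-scoring absorbs any per-gene positive affine transform of the raw
  matrix, so the base of the input logarithm is irrelevant.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ContractError, ValidationError
from .types import (
    ExpressionMatrix,
    GeneSignature,
    MappedSignature,
    MappingReport,
    ScoreTable,
)

logger = logging.getLogger(__name__)


def map_signature(
    signature: GeneSignature, matrix: ExpressionMatrix, platform: str = "matrix"
) -> MappedSignature:
    """Intersect each signature direction with the matrix gene set.

    Returns the mapped signature together with a coverage report
    (requested/mapped counts and the identifiers that failed to map).
    Raises if either direction maps to nothing, since the score would be
    undefined.
    """
    present = set(matrix.gene_ids)
    up_mapped = tuple(g for g in signature.up if g in present)
    down_mapped = tuple(g for g in signature.down if g in present)
    report = MappingReport(
        signature_name=signature.name,
        platform=platform,
        n_up_requested=len(signature.up),
        n_up_mapped=len(up_mapped),
        n_down_requested=len(signature.down),
        n_down_mapped=len(down_mapped),
        unmapped_up=tuple(g for g in signature.up if g not in present),
        unmapped_down=tuple(g for g in signature.down if g not in present),
    )
    if not up_mapped or not down_mapped:
        raise ValidationError(
            f"signature {signature.name!r} cannot be scored on this matrix: "
            f"{report.n_up_mapped}/{report.n_up_requested} up and "
            f"{report.n_down_mapped}/{report.n_down_requested} down genes mapped"
        )
    return MappedSignature(
        name=signature.name, up_mapped=up_mapped, down_mapped=down_mapped, report=report
    )


def zscore_normalize(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Z-normalize each gene across samples (mean 0, sd 1, sample sd by default).

    Zero-variance genes cannot be normalized and are dropped with a warning
    rather than emitted as NaN.  Requires at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z-normalization needs at least 2 samples (variance undefined)")
    values = matrix.values
    sd = values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d zero-variance gene(s) before scoring", int(constant.sum()))
        values = values.loc[~constant]
        sd = sd.loc[~constant]
        if values.empty:
            raise ValidationError("all genes have zero variance; nothing to score")
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, scale_tag="zscored")


def score_samples(matrix: ExpressionMatrix, mapped: MappedSignature) -> ScoreTable:
    """Score each sample as mean(up z-values) - mean(down z-values).

    The matrix must already be z-normalized (``scale_tag == "zscored"``);
    passing raw values is a contract error, use :func:`score_pipeline` for
    the one-call composition.  Signature genes dropped during normalization
    (zero variance) are excluded and the per-direction denominators reflect
    the genes actually used.
    """
    if matrix.scale_tag != "zscored":
        raise ContractError(
            f"score_samples requires a z-scored matrix, got scale_tag={matrix.scale_tag!r}"
        )
    present = set(matrix.gene_ids)
    up_used = [g for g in mapped.up_mapped if g in present]
    down_used = [g for g in mapped.down_mapped if g in present]
    if not up_used or not down_used:
        raise ValidationError(
            "all genes of one signature direction were dropped during normalization"
        )
    scores = matrix.values.loc[up_used].mean(axis=0) - matrix.values.loc[down_used].mean(axis=0)
    return ScoreTable(
        scores=scores,
        signature_name=mapped.name,
        n_up_used=len(up_used),
        n_down_used=len(down_used),
        normalization="per-gene z-score, sample sd (ddof=1)",
        sample_set_hash=matrix.sample_set_hash(),
    )


def score_pipeline(
    matrix: ExpressionMatrix, signature: GeneSignature, platform: str = "matrix"
) -> tuple[ScoreTable, MappingReport]:
    """Map, normalize and score in one deterministic pass.

    Normalization is restricted to the mapped signature genes; background
    genes never influence the score.  Returns the per-sample scores and the
    mapping coverage report.
    """
    if matrix.scale_tag == "zscored":
        raise ContractError("score_pipeline expects a raw (non-z-scored) matrix")
    mapped = map_signature(signature, matrix.drop_incomplete_genes(), platform=platform)
    restricted = ExpressionMatrix(
        matrix.values.loc[list(mapped.up_mapped) + list(mapped.down_mapped)],
        scale_tag=matrix.scale_tag,
    )
    z = zscore_normalize(restricted)
    return score_samples(z, mapped), mapped.report
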