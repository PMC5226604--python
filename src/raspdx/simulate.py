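"""Synthetic PDX cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
single latent RAS-activation variable per model drives the signature genes
up or down, drives the treatment response (ΔT/ΔC) at a tunable correlation
``rho``, and is only weakly shifted by KRAS genotype — so the Welch test of
scores by genotype is typically nonsignificant, as observed in real
cohorts.  Tumor-volume curves are back-constructed from each model's
programmed ΔT/ΔC (exponential control growth, treated growth scaled so the
group-mean volume-change ratio equals the programmed value in expectation),
which exercises the endpoint module end-to-end and guarantees ΔC > 0.

Everything is deterministic given ``CohortSpec.seed``; independent named
substreams for genotype, expression, response and volumes mean that e.g.
changing the number of animals does not perturb the expression draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .scoring import score_pipeline
from .association import pearson, welch_t_test
from .types import ExpressionMatrix, GeneSignature, ScoreTable, VolumeSeries

MUTANT_ALLELES = ("G12C", "G12D", "G12V", "G13D")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the published 25-model trial: 105 up / 42 down
    signature genes, a 15/10 wild-type/mutant split, a latent-response
    correlation of 0.6 (the magnitude observed in that cohort), and a small
    genotype shift (0.2 sd) chosen so genotype and score are only weakly
    related.  ``beta`` is the expression effect of one sd of latent
    activation, in units of the within-gene noise sd.
    """

    n_models: int = 25
    n_background_genes: int = 300
    n_up: int = 105
    n_down: int = 42
    beta: float = 1.0
    rho: float = 0.6
    noise_sd: float = 1.0
    frac_mutant: float = 0.4
    mutant_shift: float = 0.2
    n_animals_per_arm: int = 3
    measurement_days: tuple[int, ...] = (0, 3, 7, 10, 14)
    ratio_center: float = 0.5
    ratio_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_models, self.n_up, self.n_down, self.n_animals_per_arm) < 1:
            raise ValidationError("n_models, n_up, n_down, n_animals_per_arm must all be >= 1")
        if self.n_models < 2:
            raise ValidationError("need at least 2 models (scores are cohort-relative)")
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("rho must lie strictly inside (-1, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0.0 <= self.frac_mutant <= 1.0:
            raise ValidationError("frac_mutant must lie in [0, 1]")
        if sorted(self.measurement_days)[0] != 0 or len(set(self.measurement_days)) < 2:
            raise ValidationError("measurement_days must include day 0 and at least one later day")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth ledger."""

    spec: CohortSpec
    expression: ExpressionMatrix
    signature: GeneSignature
    volumes: VolumeSeries
    annotations: pd.DataFrame  # model_id, kras_allele
    truth: pd.DataFrame  # model_id, latent_activation, response_mean, programmed_ratio, kras_allele


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the latent-activation model (deterministic in seed)."""
    ss = np.random.SeedSequence(spec.seed)
    rng_geno, rng_expr, rng_resp, rng_vol = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    model_ids = [f"SM{i:04d}" for i in range(1, spec.n_models + 1)]

    # genotype: fixed mutant count, random placement and allele
    n_mut = int(round(spec.frac_mutant * spec.n_models))
    is_mut = np.zeros(spec.n_models, dtype=bool)
    is_mut[rng_geno.choice(spec.n_models, size=n_mut, replace=False)] = True
    alleles = np.where(is_mut, rng_geno.choice(MUTANT_ALLELES, size=spec.n_models), "WT")

    # latent activation: standard normal plus a small genotype shift
    a = rng_geno.standard_normal(spec.n_models) + spec.mutant_shift * is_mut

    # expression: gene baseline +/- beta * a + noise; background is pure noise
    up_genes = [f"SUP{i:04d}" for i in range(1, spec.n_up + 1)]
    dn_genes = [f"SDN{i:04d}" for i in range(1, spec.n_down + 1)]
    bg_genes = [f"SBG{i:04d}" for i in range(1, spec.n_background_genes + 1)]
    genes = up_genes + dn_genes + bg_genes
    direction = np.concatenate(
        [np.ones(spec.n_up), -np.ones(spec.n_down), np.zeros(spec.n_background_genes)]
    )
    baseline = rng_expr.normal(7.0, 1.0, size=len(genes))
    noise = rng_expr.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_models))
    values = baseline[:, None] + spec.beta * direction[:, None] * a[None, :] + noise
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=model_ids), scale_tag="log2"
    )
    signature = GeneSignature(name="SYNRAS", up=tuple(up_genes), down=tuple(dn_genes))

    # response: corr(a, response) = rho by construction, mapped to the
    # ΔT/ΔC scale and clipped so back-constructed volumes stay positive
    az = (a - a.mean()) / a.std(ddof=0)
    w = spec.rho * az + np.sqrt(1.0 - spec.rho**2) * rng_resp.standard_normal(spec.n_models)
    response_mean = spec.ratio_center + spec.ratio_scale * spec.rho * az
    ratio = np.clip(spec.ratio_center + spec.ratio_scale * w, -0.8, 2.5)

    volumes = _build_volumes(spec, model_ids, ratio, rng_vol)

    annotations = pd.DataFrame({"model_id": model_ids, "kras_allele": alleles})
    truth = pd.DataFrame(
        {
            "model_id": model_ids,
            "latent_activation": a,
            "response_mean": response_mean,
            "programmed_ratio": ratio,
            "kras_allele": alleles,
        }
    )
    return SyntheticCohort(
        spec=spec,
        expression=expression,
        signature=signature,
        volumes=volumes,
        annotations=annotations,
        truth=truth,
    )


def _build_volumes(
    spec: CohortSpec, model_ids: list[str], ratio: np.ndarray, rng: np.random.Generator
) -> VolumeSeries:
    """Back-construct per-animal volume curves from programmed ΔT/ΔC.

    Controls double over the trial (V_t = V0 * exp(g t), g = ln2 / T) with
    per-animal growth jitter; each treated animal's change from baseline is
    the control change profile scaled by the model's programmed ratio, so
    the mean-change ratio recovers it up to animal noise.  Enrollment
    volumes are drawn uniformly from the 100-150 mm^3 grouping window.
    """
    days = sorted(spec.measurement_days)
    t_end = days[-1]
    g = np.log(2.0) / t_end
    rows = []
    for m, model in enumerate(model_ids):
        for arm, n in (("control", spec.n_animals_per_arm), ("treated", spec.n_animals_per_arm)):
            for i in range(n):
                v0 = rng.uniform(100.0, 150.0)
                g_i = g * (1.0 + 0.1 * rng.standard_normal())
                meas = 1.0 + 0.03 * rng.standard_normal(len(days))
                for day, eps in zip(days, meas):
                    growth = np.expm1(g_i * day)
                    if arm == "control":
                        v = v0 * (1.0 + growth)
                    else:
                        v = v0 * (1.0 + ratio[m] * growth)
                    if day > 0:
                        v *= eps
                    rows.append(
                        {
                            "model": model,
                            "animal": f"{model}-{arm[0].upper()}{i + 1}",
                            "arm": arm,
                            "day": day,
                            "volume": max(v, 1.0),
                        }
                    )
    return VolumeSeries(pd.DataFrame(rows))


def recovery_report(
    cohort: SyntheticCohort,
    scores: ScoreTable | None = None,
    endpoints: pd.DataFrame | None = None,
) -> dict:
    """Compare pipeline outputs against the cohort's ground truth.

    Scores are computed with :func:`~raspdx.scoring.score_pipeline` when not
    supplied; supplied scores must carry the cohort's sample-set hash
    (cohort-relative scores from a different sample set are meaningless
    here).  ``endpoints`` is an optional DataFrame with ``model_id`` and
    ``delta_t_over_delta_c`` from the endpoint module.

    Returns correlations of the recovered score with the latent activation
    and with the programmed and measured ΔT/ΔC, plus the Welch p for scores
    by genotype.
    """
    if scores is None:
        scores, _ = score_pipeline(cohort.expression, cohort.signature)
    elif scores.sample_set_hash != cohort.expression.sample_set_hash():
        raise ContractError("score table was computed on a different sample set than this cohort")
    truth = cohort.truth.set_index("model_id")
    s = scores.scores.reindex(truth.index)
    if s.isna().any():
        raise ContractError("score table does not cover every cohort model")
    out = {
        "n_models": len(truth),
        "corr_score_latent": pearson(s, truth["latent_activation"]).statistic,
        "corr_score_programmed_ratio": pearson(s, truth["programmed_ratio"]).statistic,
    }
    wt = truth["kras_allele"] == "WT"
    if wt.sum() >= 2 and (~wt).sum() >= 2:
        out["welch_p_by_genotype"] = welch_t_test(s[wt], s[~wt]).p_value
    if endpoints is not None:
        measured = endpoints.set_index("model_id")["delta_t_over_delta_c"].reindex(truth.index)
        if measured.isna().any():
            raise ContractError("endpoints do not cover every cohort model")
        out["corr_score_measured_ratio"] = pearson(s, measured).statistic
        out["corr_measured_programmed_ratio"] = pearson(
            measured, truth["programmed_ratio"]
        ).statistic
    return out
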