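"""Association statistics: Pearson correlation, Welch's t-test, stratified
subgroup analyses, sign-based contingency counts, and a single-covariate
response screen.

Pearson r and Welch's t are implemented directly from their closed forms —
r's p-value from t = r * sqrt((n-2)/(1-r^2)) against Student's t with n-2
degrees of freedom, Welch's with Satterthwaite degrees of freedom — and are
cross-validated against SciPy in the test suite.  All p-values are
two-sided and reported at full precision; rounding happens only when
comparing to published values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .errors import ContractError, ValidationError
from .types import AssociationResult, ModelTable, SignContingency

logger = logging.getLogger(__name__)


def pearson(x, y, subgroup: str = "all", covariate: str = "") -> AssociationResult:
    """Pearson correlation with a two-sided t-distribution p-value.

    Requires n >= 3 and both vectors non-constant.  With |r| = 1 the t
    statistic diverges and the p-value is reported as the smallest positive
    float, keeping it inside (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(f"pearson needs equal-length 1-d vectors, got {x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise ContractError(f"pearson needs n >= 3, got n = {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0 or syy == 0:
        raise ValidationError("correlation undefined: a vector is constant")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = float(np.nextafter(0.0, 1.0))
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
        p = min(p, 1.0)
        if p == 0.0:  # underflow at extreme |t|
            p = float(np.nextafter(0.0, 1.0))
    return AssociationResult(
        subgroup=subgroup, n=n, statistic_name="pearson_r", statistic=r, p_value=p,
        df=float(df), covariate=covariate,
    )


def welch_t_test(a, b, subgroup: str = "all") -> AssociationResult:
    """Welch's two-sample t-test, two-sided, Satterthwaite degrees of freedom.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b); no equal-variance
    assumption.  Each group needs at least two observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ContractError(f"welch_t_test needs >= 2 observations per group, got {na} and {nb}")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValidationError("both groups are constant; t undefined")
    t = (float(a.mean()) - float(b.mean())) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = min(2.0 * float(stats.t.sf(abs(t), df)), 1.0)
    if p == 0.0:
        p = float(np.nextafter(0.0, 1.0))
    return AssociationResult(
        subgroup=subgroup, n=na + nb, statistic_name="welch_t", statistic=t, p_value=p, df=df
    )


DEFAULT_STRATA = ("all", "WT", "mutant")


def stratified_association(
    table: ModelTable, strata: tuple[str, ...] = DEFAULT_STRATA
) -> list[AssociationResult]:
    """Pearson r between signature score and ΔT/ΔC, per stratum.

    Default strata: all models, KRAS-12/13 wild type, and the combined
    codon-12/13 mutant group.  ``G12x`` and ``G13D`` are accepted for a
    finer split.  Strata too small for a correlation (n < 3) are skipped
    with a warning rather than failing the whole analysis.
    """
    df = table.records
    masks = {
        "all": np.ones(len(df), dtype=bool),
        "WT": (df["kras_class"] == "WT").to_numpy(),
        "mutant": (df["kras_class"] != "WT").to_numpy(),
        "G12x": (df["kras_class"] == "G12x").to_numpy(),
        "G13D": (df["kras_class"] == "G13D").to_numpy(),
    }
    unknown = set(strata) - set(masks)
    if unknown:
        raise ContractError(f"unknown strata {sorted(unknown)}; choose from {sorted(masks)}")
    results = []
    for name in strata:
        mask = masks[name]
        if mask.sum() < 3:
            logger.warning("stratum %r has n=%d < 3; skipped", name, int(mask.sum()))
            continue
        results.append(
            pearson(
                df.loc[mask, "ras_score"],
                df.loc[mask, "delta_t_over_delta_c"],
                subgroup=name,
            )
        )
    return results


def score_by_genotype_test(table: ModelTable) -> AssociationResult:
    """Welch test of signature scores, wild type vs combined 12/13 mutants."""
    return welch_t_test(
        table.wild_type().records["ras_score"],
        table.mutant().records["ras_score"],
        subgroup="WT_vs_mutant",
    )


def sign_contingency(
    table: ModelTable,
    score_threshold: float = 0.0,
    response_threshold: float = 0.0,
    strata: tuple[str, ...] = DEFAULT_STRATA,
) -> dict[str, SignContingency]:
    """Cross-classify models by score sign and response class per stratum.

    'Positive score' means score strictly above ``score_threshold``; 'poor'
    response means ΔT/ΔC strictly above ``response_threshold``.  Boundary
    models fall in the non-positive / sensitive margins.
    """
    df = table.records
    masks = {
        "all": np.ones(len(df), dtype=bool),
        "WT": (df["kras_class"] == "WT").to_numpy(),
        "mutant": (df["kras_class"] != "WT").to_numpy(),
        "G12x": (df["kras_class"] == "G12x").to_numpy(),
        "G13D": (df["kras_class"] == "G13D").to_numpy(),
    }
    out: dict[str, SignContingency] = {}
    for name in strata:
        sub = df.loc[masks[name]]
        pos = sub["ras_score"] > score_threshold
        poor = sub["delta_t_over_delta_c"] > response_threshold
        out[name] = SignContingency(
            subgroup=name,
            positive_poor=int((pos & poor).sum()),
            positive_sensitive=int((pos & ~poor).sum()),
            nonpositive_poor=int((~pos & poor).sum()),
            nonpositive_sensitive=int((~pos & ~poor).sum()),
            score_threshold=score_threshold,
            response_threshold=response_threshold,
        )
    return out


def covariate_screen(
    table: ModelTable, covariates, covariate_names: list[str] | None = None
) -> "pd.DataFrame":
    """Correlate each per-model covariate with ΔT/ΔC.

    ``covariates`` is a DataFrame indexed by model_id with one numeric
    column per covariate (expression, copy number, ...).  Returns one row
    per covariate with r, the raw two-sided p and the Benjamini–Hochberg
    adjusted q side by side; constant covariates are flagged and skipped.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    cols = covariate_names if covariate_names is not None else list(covariates.columns)
    df = table.records.set_index("model_id")
    joined = df.join(covariates, how="inner")
    if len(joined) < 3:
        raise ValidationError("fewer than 3 models shared between table and covariates")
    rows = []
    for name in cols:
        vals = pd.to_numeric(joined[name], errors="raise")
        if vals.isna().any():
            raise ValidationError(f"covariate {name!r} has missing values")
        if vals.nunique() == 1:
            logger.warning("covariate %r is constant; skipped", name)
            rows.append({"covariate": name, "n": len(joined), "r": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        res = pearson(vals, joined["delta_t_over_delta_c"], covariate=name)
        rows.append({"covariate": name, "n": res.n, "r": res.statistic, "p": res.p_value,
                     "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["q_bh"] = np.nan
    if tested.any():
        out.loc[tested, "q_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out
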