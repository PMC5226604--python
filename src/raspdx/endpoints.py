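"""Mouse-clinical-trial endpoints: ΔT/ΔC per model and waterfall ordering.

ΔT/ΔC is the classic tumor-growth-inhibition readout: the mean
tumor-volume change from baseline in the treated arm divided by the mean
change in the control arm, evaluated at a common measurement day.
Negative values mean the treated tumors regressed on average while
controls grew; values near 1 mean no treatment effect; values above 1 mean
faster-than-control growth.  The ratio is undefined when the control arm
failed to grow (ΔC <= 0).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .types import EndpointResult, VolumeSeries


def _evaluation_day(sub: pd.DataFrame) -> int:
    """Last measurement day present in both arms (the default convention)."""
    common: set[int] | None = None
    for _, arm_days in sub.groupby("arm")["day"]:
        days = set(arm_days)
        common = days if common is None else common & days
    if not common:
        raise ValidationError("arms share no common measurement day")
    return max(common)


def compute_delta_t_delta_c(
    volumes: VolumeSeries, model_id: str, evaluation_day: int | None = None
) -> EndpointResult:
    """Compute ΔT/ΔC for one model.

    ΔT is the mean over treated animals of (V_day - V_0), ΔC likewise for
    controls.  If ``evaluation_day`` is omitted, the last day measured in
    both arms is used.  Every animal must have a record at the evaluation
    day; animals lost to follow-up are an error, not silently imputed.
    """
    sub = volumes.for_model(model_id)
    arms = set(sub["arm"])
    if arms != {"control", "treated"}:
        raise ValidationError(f"model {model_id!r}: needs both arms, has {sorted(arms)}")
    day = _evaluation_day(sub) if evaluation_day is None else int(evaluation_day)
    if day <= 0:
        raise ValidationError(f"model {model_id!r}: evaluation day must be positive, got {day}")

    wide = sub.pivot(index="animal", columns="day", values="volume")
    if day not in wide.columns:
        raise ValidationError(f"model {model_id!r}: no records at day {day}")
    missing = wide.index[wide[day].isna() | wide[0].isna()].tolist()
    if missing:
        raise ValidationError(
            f"model {model_id!r}: animal(s) missing day-0 or day-{day} records: {missing}"
        )
    change = wide[day] - wide[0]
    arm_of = sub.drop_duplicates("animal").set_index("animal")["arm"]
    delta_t = float(change[arm_of == "treated"].mean())
    delta_c = float(change[arm_of == "control"].mean())
    if delta_c <= 0:
        raise ValidationError(
            f"model {model_id!r}: control arm failed to grow (ΔC={delta_c:.3g} mm³); "
            "ΔT/ΔC is undefined"
        )
    return EndpointResult(
        model_id=str(model_id),
        delta_t=delta_t,
        delta_c=delta_c,
        delta_t_over_delta_c=delta_t / delta_c,
        n_treated=int((arm_of == "treated").sum()),
        n_control=int((arm_of == "control").sum()),
        evaluation_day=day,
    )


def compute_all_endpoints(
    volumes: VolumeSeries, evaluation_day: int | None = None
) -> list[EndpointResult]:
    """ΔT/ΔC for every model in a volume series."""
    return [compute_delta_t_delta_c(volumes, m, evaluation_day) for m in volumes.model_ids]


def waterfall(results: Iterable[EndpointResult] | pd.DataFrame) -> pd.DataFrame:
    """Order models from best responder to worst (ascending ΔT/ΔC).

    Ties are broken by model_id so the ordering is total and stable.
    Accepts either endpoint results or any DataFrame with ``model_id`` and
    ``delta_t_over_delta_c`` columns (e.g. a model table) and returns a
    plot-ready copy sorted for a waterfall bar chart.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if not {"model_id", "delta_t_over_delta_c"} <= set(df.columns):
            raise ValidationError("waterfall needs model_id and delta_t_over_delta_c columns")
    else:
        rows = [
            {
                "model_id": r.model_id,
                "delta_t_over_delta_c": r.delta_t_over_delta_c,
                "delta_t": r.delta_t,
                "delta_c": r.delta_c,
                "evaluation_day": r.evaluation_day,
            }
            for r in results
        ]
        if not rows:
            raise ValidationError("waterfall needs at least one endpoint result")
        df = pd.DataFrame(rows)
    return df.sort_values(
        ["delta_t_over_delta_c", "model_id"], kind="stable", ignore_index=True
    )


def classify_response(delta_t_over_delta_c: float, threshold: float = 0.0) -> str:
    """Sign-based response call: responder iff ΔT/ΔC < threshold (strict)."""
    return "responder" if delta_t_over_delta_c < threshold else "non_responder"


def plot_waterfall(ordered: pd.DataFrame, path: str, kras_class: Sequence[str] | None = None):
    """Save a waterfall bar chart; bars shaded by KRAS class when given.

    Mirrors the field's convention: open bars wild type, solid bars
    codon-12 mutants, hatched bars G13D.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(ordered)), 4))
    colors, hatches = [], []
    for cls in kras_class if kras_class is not None else ["WT"] * len(ordered):
        if cls == "G12x":
            colors.append("black")
            hatches.append("")
        elif cls == "G13D":
            colors.append("lightgray")
            hatches.append("//")
        else:
            colors.append("white")
            hatches.append("")
    bars = ax.bar(
        ordered["model_id"], ordered["delta_t_over_delta_c"], color=colors, edgecolor="black"
    )
    for bar, hatch in zip(bars, hatches):
        bar.set_hatch(hatch)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("ΔT/ΔC")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
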