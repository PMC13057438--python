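"""Equation selection and equation comparison.

``recommend_equations`` is the rule engine behind the decision tree for
choosing a resource-use scaling and a trophic-position equation from three
diagnostics: baseline habitat distinctness, the rate of boundary violations
in raw littoral carbon use, and whether the two baselines share an assumed
trophic position. ``compare_equation_variants`` quantifies how much the
choice matters for a given dataset, via Kruskal–Wallis across the variants
followed by Dunn's pairwise tests.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import PairwiseResult, dunn_posthoc, friedman_test, kruskal_wallis
from .baselines import DistinctnessReport
from .types import LCU_KEYS, TP_KEYS, MetricRecord, ViolationSummary


@dataclass(frozen=True)
class Recommendation:
    """Decision-engine output: which scaling and equation to use, and why.

    ``rationale`` is the ordered trace of rules that fired, each with the
    diagnostic values it saw, so a diverging recommendation is auditable.
    """

    ru_method: str  # "lcu" | "lcu_r" | "not_applicable"
    tp_method: str  # "tp1_lb" | "tp1_p" | "tp1_lbp" | "tp2" | "tp2_abs"
    alpha_source: str  # "lcu" | "lcu_adj" | "lcu_r" | "none"
    rationale: tuple[str, ...] = ()

    def __post_init__(self):
        if self.tp_method in ("tp2", "tp2_abs") and self.alpha_source == "none":
            raise ValueError("two-source TP requires an alpha source")
        if self.ru_method == "not_applicable" and self.tp_method not in (
            "tp1_lb", "tp1_p", "tp1_lbp",
        ):
            raise ValueError(
                "without a usable resource-use metric the TP equation must be one-source"
            )


@dataclass(frozen=True)
class EquationComparisonReport:
    species: str
    metric_family: str  # "lcu" | "tp"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: tuple[PairwiseResult, ...]
    paired_statistic: float | None = None
    paired_p: float | None = None

    @property
    def significant_pairs(self) -> list[PairwiseResult]:
        return [p for p in self.pairwise if p.significant]


def recommend_equations(
    distinctness: tuple[DistinctnessReport, DistinctnessReport],
    violations: ViolationSummary,
    lambdas_equal: bool,
) -> Recommendation:
    """Choose a resource-use scaling and trophic-position equation.

    Rule chain:

    1. Baselines not distinct in δ13C → the two habitats cannot be separated
       on the mixing axis: no resource-use metric, one-source TP with all
       baselines pooled.
    2. Distinct δ13C: if more than the threshold fraction of raw LCU values
       fall outside [0, 1], use min-max rescaled LCU (and feed it into the
       two-source TP as α); otherwise use raw LCU.
    3. Equal assumed baseline trophic positions → plain two-source TP;
       unequal → absolute-λ two-source TP.

    δ15N non-distinctness with distinct δ13C does not change the path but is
    recorded as a caution: the two δ15N baselines then contribute little
    beyond a pooled one.
    """
    d13c, d15n = distinctness
    trace: list[str] = []

    trace.append(
        f"baseline d13c distinctness: p={d13c.p_value:.4g} "
        f"({'distinct' if d13c.distinct else 'not distinct'} at "
        f"alpha={d13c.alpha_level})"
    )
    if not d13c.distinct:
        trace.append(
            "rule: d13c baselines not distinct -> one-source system; "
            "resource use not applicable, TP from pooled baselines (tp1_lbp)"
        )
        return Recommendation(
            ru_method="not_applicable",
            tp_method="tp1_lbp",
            alpha_source="none",
            rationale=tuple(trace),
        )

    if not d15n.distinct:
        trace.append(
            f"caution: baseline d15n not distinct (p={d15n.p_value:.4g}); "
            "two-source d15n baseline adds little over a pooled one"
        )

    trace.append(
        f"raw LCU boundary violations: {violations.n_outside}/{violations.n_total} "
        f"({violations.pct_outside:.1f}%) outside [0, 1]"
    )
    if violations.exceeds_threshold:
        ru = "lcu_r"
        trace.append(
            "rule: violation rate exceeds threshold -> use min-max rescaled LCU "
            "(lcu_r) as resource-use metric and as alpha"
        )
    else:
        ru = "lcu"
        trace.append("rule: violation rate within threshold -> use raw LCU as alpha")

    if lambdas_equal:
        tp = "tp2"
        trace.append("rule: baseline lambdas equal -> two-source TP (tp2)")
    else:
        tp = "tp2_abs"
        trace.append(
            "rule: baseline lambdas differ -> absolute-lambda two-source TP (tp2_abs)"
        )
    return Recommendation(
        ru_method=ru, tp_method=tp, alpha_source=ru, rationale=tuple(trace)
    )


def _variant_groups(records: Sequence[MetricRecord], family: str) -> dict[str, np.ndarray]:
    if family == "lcu":
        return {
            k: np.array([getattr(r, k) for r in records], dtype=float) for k in LCU_KEYS
        }
    if family == "tp":
        return {k: np.array([r.tp[k] for r in records], dtype=float) for k in TP_KEYS}
    raise ValueError(f"unknown metric family {family!r}")


def compare_equation_variants(
    records: Sequence[MetricRecord],
    species: str = "all",
    family: str = "lcu",
    alpha_level: float = 0.05,
    paired: bool = False,
) -> EquationComparisonReport:
    """Do the variant equations give statistically different values?

    Treats each variant's per-individual values as an independent group:
    omnibus Kruskal–Wallis across the 3 LCU or 9 TP variants, then Dunn's
    pairwise z-tests with Bonferroni adjustment. Because the same individuals
    underlie every variant the groups are in truth paired; the independent-
    groups treatment is the field's convention and is kept as the default,
    with a paired Friedman omnibus available via ``paired=True`` (reported
    alongside, it does not change the pairwise machinery).

    Degenerate input (all variants identical for every individual) yields
    omnibus p = 1 and no significant pairs.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("equation comparison needs >= 2 records")
    groups = _variant_groups(records, family)

    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        # Kruskal-Wallis is undefined when every value is identical; by
        # construction there is no difference to detect.
        return EquationComparisonReport(
            species=species, metric_family=family,
            omnibus_statistic=0.0, omnibus_p=1.0, pairwise=(),
        )

    h, p = kruskal_wallis(groups)
    pairwise = tuple(dunn_posthoc(groups, alpha_level=alpha_level))
    paired_stat = paired_p = None
    if paired:
        paired_stat, paired_p = friedman_test(groups)
    return EquationComparisonReport(
        species=species, metric_family=family,
        omnibus_statistic=h, omnibus_p=p, pairwise=pairwise,
        paired_statistic=paired_stat, paired_p=paired_p,
    )


def summarize_metrics(
    records: Sequence[MetricRecord],
    measurements: Sequence = (),
    group_by: tuple[str, ...] = ("species", "stratum", "season", "tissue"),
) -> pd.DataFrame:
    """Per-group summary table: mean, SD, min, max of every LCU and TP
    variant, plus the percent of individuals with raw LCU outside [0, 1].

    Grouping labels come from ``measurements`` (joined on specimen_id); with
    no measurements, everything lands in one group. SD is the sample
    (ddof=1) standard deviation, 0 for singleton groups.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize_metrics requires at least one record")
    rows = []
    for r in records:
        row = {"specimen_id": r.specimen_id, "lcu": r.lcu, "lcu_adj": r.lcu_adj,
               "lcu_r": r.lcu_r}
        row.update(r.tp)
        rows.append(row)
    df = pd.DataFrame(rows)

    if measurements:
        meta = pd.DataFrame(
            {
                "specimen_id": [m.specimen_id for m in measurements],
                "species": [m.species for m in measurements],
                "stratum": [m.stratum for m in measurements],
                "season": [m.season for m in measurements],
                "tissue": [
                    m.tissue.value if hasattr(m.tissue, "value") else m.tissue
                    for m in measurements
                ],
            }
        )
        df = df.merge(meta, on="specimen_id", how="left")
        keys = [k for k in group_by if k in df.columns]
    else:
        df["group"] = "all"
        keys = ["group"]

    value_cols = list(LCU_KEYS) + list(TP_KEYS)
    agg = df.groupby(keys, dropna=False)[value_cols].agg(
        ["mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, "min", "max"]
    )
    agg.columns = [
        f"{col}_{name if name != '<lambda_0>' else 'sd'}" for col, name in agg.columns
    ]
    pct = (
        df.groupby(keys, dropna=False)["lcu"]
        .apply(lambda s: 100.0 * np.mean((s > 1) | (s < 0)))
        .rename("pct_lcu_outside")
    )
    return agg.join(pct).reset_index()
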