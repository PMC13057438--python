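"""Littoral carbon use and trophic position equations.

The core model is a two-endmember δ13C mixing line between littoral/benthic
and pelagic baselines. A consumer's littoral carbon use (LCU) is its position
on that line; trophic position (TP) is its δ15N excess over a baseline,
scaled by the per-step discrimination Δn and anchored at the baseline's
assumed trophic position λ.

Three LCU scalings:

* ``lcu``      — raw mixing-line position, unbounded when baselines do not
                 bracket the consumer;
* ``lcu_adj``  — raw value clipped to [0, 1];
* ``lcu_r``    — min-max rescaled to the range observed across the system.

Nine TP variants: one-source TP against the littoral, pelagic, or pooled
baseline; two-source TP with α drawn from each LCU scaling; and two-source
TP with baseline-specific λ (absolute-λ), again with each α.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

from .types import (
    DegenerateEndmembersError,
    DegenerateRangeError,
    EndmemberSet,
    IsotopeMeasurement,
    MetricConfig,
    MetricRecord,
    Role,
    ViolationSummary,
)

__all__ = [
    "compute_lcu",
    "clip_lcu",
    "rescale_lcu",
    "mix_d13c",
    "tp_one_source",
    "tp_two_source",
    "tp_two_source_abs",
    "pooled_baseline",
    "compute_metric_suite",
    "boundary_violation_stats",
]


def compute_lcu(d13c_consumer, endmembers: EndmemberSet):
    """Raw littoral carbon use: (δ13C_consumer − δ13C_P) / (δ13C_L/B − δ13C_P).

    Values near 1 indicate littoral carbon sources, near 0 pelagic. The
    result is returned unclipped and may fall outside [0, 1] when the
    baselines do not bracket the consumer.

    Raises
    ------
    DegenerateEndmembersError
        If the littoral and pelagic δ13C means are equal (one-source system).
    """
    spread = endmembers.d13c_spread
    if spread == 0:
        raise DegenerateEndmembersError(
            "littoral and pelagic baseline d13c means are equal "
            f"({endmembers.d13c_littoral}); the mixing model is undefined — "
            "use a one-source trophic position with a pooled baseline"
        )
    return (np.asarray(d13c_consumer, dtype=float) - endmembers.d13c_pelagic) / spread


def clip_lcu(lcu):
    """Clip LCU into [0, 1] (values > 1 become 1, < 0 become 0)."""
    return np.clip(lcu, 0.0, 1.0)


def rescale_lcu(lcu_values) -> np.ndarray:
    """Min-max rescale raw LCU values to [0, 1] over the observed range.

    The minimum observed value maps to 0 and the maximum to 1, expressing
    each consumer's position along the empirical δ13C gradient of the system
    rather than between the (possibly non-bracketing) baselines.

    Raises
    ------
    DegenerateRangeError
        If fewer than 2 values are supplied or all values are equal.
    """
    arr = np.asarray(list(lcu_values), dtype=float)
    if arr.size < 2:
        raise DegenerateRangeError(
            f"min-max rescaling needs >= 2 values, got {arr.size}"
        )
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateRangeError("all LCU values are equal; rescaling is undefined")
    return (arr - lo) / (hi - lo)


def mix_d13c(alpha, endmembers: EndmemberSet):
    """Forward mixing model: δ13C = α·δ13C_L/B + (1−α)·δ13C_P.

    ``alpha`` is not restricted to [0, 1]; out-of-bounds proportions are the
    forward image of out-of-bounds LCU values.
    """
    alpha = np.asarray(alpha, dtype=float)
    return alpha * endmembers.d13c_littoral + (1.0 - alpha) * endmembers.d13c_pelagic


def _check_delta_n(delta_n: float):
    if delta_n <= 0:
        raise ValueError(f"delta_n must be positive, got {delta_n}")


def tp_one_source(d15n_consumer, d15n_base, lam: float, delta_n: float):
    """One-source trophic position: λ + (δ15N_consumer − δ15N_base) / Δn."""
    _check_delta_n(delta_n)
    return lam + (np.asarray(d15n_consumer, dtype=float) - d15n_base) / delta_n


def tp_two_source(d15n_consumer, alpha, endmembers: EndmemberSet, lam: float, delta_n: float):
    """Two-source trophic position with an α-weighted δ15N baseline.

    α (the carbon-source proportion, any of the three LCU scalings) is used
    unmodified even when outside [0, 1]; clipping is the business of the
    ``_adj`` variant only.
    """
    _check_delta_n(delta_n)
    alpha = np.asarray(alpha, dtype=float)
    base = endmembers.d15n_littoral * alpha + endmembers.d15n_pelagic * (1.0 - alpha)
    return lam + (np.asarray(d15n_consumer, dtype=float) - base) / delta_n


def tp_two_source_abs(d15n_consumer, alpha, endmembers: EndmemberSet, delta_n: float):
    """Two-source trophic position with baseline-specific (absolute) λ.

    Replaces the single λ with the α-weighted mean of the two baselines'
    assumed trophic positions, so that baselines sitting at different trophic
    levels (e.g. mayfly at 2.25 vs mussel at 2.0) are weighted consistently
    with the carbon mixture.
    """
    _check_delta_n(delta_n)
    alpha = np.asarray(alpha, dtype=float)
    lam_abs = endmembers.lambda_littoral * alpha + endmembers.lambda_pelagic * (1.0 - alpha)
    base = endmembers.d15n_littoral * alpha + endmembers.d15n_pelagic * (1.0 - alpha)
    return lam_abs + (np.asarray(d15n_consumer, dtype=float) - base) / delta_n


def pooled_baseline(
    baseline_samples: Iterable[IsotopeMeasurement],
    method: str = "pooled_individuals",
    endmembers: EndmemberSet | None = None,
) -> float:
    """Pooled δ15N baseline for the combined one-source trophic position.

    ``pooled_individuals`` (default) takes the unweighted mean δ15N over all
    individual littoral and pelagic baseline specimens. ``mean_of_means``
    averages the two habitat means from ``endmembers`` instead, giving equal
    weight to habitats regardless of sample counts.
    """
    if method == "mean_of_means":
        if endmembers is None:
            raise ValueError("mean_of_means pooling requires an EndmemberSet")
        return 0.5 * (endmembers.d15n_littoral + endmembers.d15n_pelagic)
    samples = list(baseline_samples)
    littoral = [s for s in samples if s.role == Role.LITTORAL_BASELINE]
    pelagic = [s for s in samples if s.role == Role.PELAGIC_BASELINE]
    if not littoral or not pelagic:
        raise ValueError(
            "pooled baseline requires at least one littoral and one pelagic "
            f"specimen (got {len(littoral)} littoral, {len(pelagic)} pelagic)"
        )
    return float(np.mean([s.d15n for s in littoral + pelagic]))


def boundary_violation_stats(lcu_values, threshold: float = 0.05) -> ViolationSummary:
    """Count raw LCU values strictly outside [0, 1] in a population.

    Values exactly 0 or 1 count as inside. ``exceeds_threshold`` is true when
    the outside *fraction* strictly exceeds ``threshold`` (default 5 %),
    which is the trigger for recommending min-max rescaled LCU.
    """
    arr = np.asarray(list(lcu_values), dtype=float)
    if arr.size == 0:
        raise ValueError("boundary_violation_stats requires a non-empty collection")
    n_above = int(np.sum(arr > 1.0))
    n_below = int(np.sum(arr < 0.0))
    frac = (n_above + n_below) / arr.size
    return ViolationSummary(
        n_total=int(arr.size),
        n_above_1=n_above,
        n_below_0=n_below,
        pct_outside=100.0 * frac,
        exceeds_threshold=frac > threshold,
    )


def compute_metric_suite(
    consumers: Sequence[IsotopeMeasurement],
    endmembers,
    baseline_samples: Iterable[IsotopeMeasurement],
    config: MetricConfig = MetricConfig(),
) -> list[MetricRecord]:
    """Compute the full LCU/TP suite for a cohort of consumers.

    Parameters
    ----------
    consumers
        Consumer measurements (non-empty).
    endmembers
        Either a single :class:`EndmemberSet` applied to every consumer, or a
        callable ``consumer -> EndmemberSet`` (e.g. a scope resolver for
        basin- or season-matched baselines).
    baseline_samples
        Individual baseline specimens, used for the pooled one-source
        baseline.
    config
        Δn, default λ, and the rescaling scope. With ``per_stratum`` scope the
        min-max range is taken within each consumer stratum; with
        ``per_system`` (default) over all consumers passed in.

    Returns one :class:`MetricRecord` per consumer, in input order. Raw LCU is
    propagated unclipped into the two-source equations; the ``_adj`` and
    ``_r`` variants use the clipped and rescaled α respectively.
    """
    consumers = list(consumers)
    if not consumers:
        raise ValueError("compute_metric_suite requires at least one consumer")
    resolve = endmembers if callable(endmembers) else (lambda c: endmembers)
    ems = [resolve(c) for c in consumers]

    d13c = np.array([c.d13c for c in consumers])
    d15n = np.array([c.d15n for c in consumers])
    lcu = np.array([float(compute_lcu(x, em)) for x, em in zip(d13c, ems)])
    lcu_adj = clip_lcu(lcu)

    lcu_r = np.empty_like(lcu)
    if config.rescale_scope == "per_stratum":
        strata = np.array([c.stratum for c in consumers])
        for s in np.unique(strata):
            mask = strata == s
            lcu_r[mask] = rescale_lcu(lcu[mask])
    else:
        lcu_r[:] = rescale_lcu(lcu)

    pooled = pooled_baseline(baseline_samples)
    lam = config.lambda_default
    dn = config.delta_n

    records = []
    for i, (c, em) in enumerate(zip(consumers, ems)):
        tp = {
            "tp1_lb": float(tp_one_source(d15n[i], em.d15n_littoral, lam, dn)),
            "tp1_p": float(tp_one_source(d15n[i], em.d15n_pelagic, lam, dn)),
            "tp1_lbp": float(tp_one_source(d15n[i], pooled, lam, dn)),
            "tp2": float(tp_two_source(d15n[i], lcu[i], em, lam, dn)),
            "tp2_adj": float(tp_two_source(d15n[i], lcu_adj[i], em, lam, dn)),
            "tp2_r": float(tp_two_source(d15n[i], lcu_r[i], em, lam, dn)),
            "tp2abs": float(tp_two_source_abs(d15n[i], lcu[i], em, dn)),
            "tp2abs_adj": float(tp_two_source_abs(d15n[i], lcu_adj[i], em, dn)),
            "tp2abs_r": float(tp_two_source_abs(d15n[i], lcu_r[i], em, dn)),
        }
        records.append(
            MetricRecord(
                specimen_id=c.specimen_id,
                lcu=float(lcu[i]),
                lcu_adj=float(lcu_adj[i]),
                lcu_r=float(lcu_r[i]),
                tp=tp,
            )
        )
    return records
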