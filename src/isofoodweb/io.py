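"""Data ingestion, run configuration, and the end-to-end pipeline.

Interchange format: long (tidy) CSV or TSV, one row per analyzed specimen,
with case-insensitive columns ``specimen_id, species, role, tissue, season,
stratum, d13c, d15n`` (``length_mm`` optional). Rows whose isotope cells do
not parse as numbers are dropped and counted, never imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import (
    DistinctnessReport,
    GroupingPolicy,
    build_endmember_table,
    resolve_endmembers,
    screen_grouping_factors,
    test_habitat_distinctness,
)
from .decision import (
    EquationComparisonReport,
    Recommendation,
    compare_equation_variants,
    recommend_equations,
    summarize_metrics,
)
from .metrics import boundary_violation_stats, compute_metric_suite
from .types import (
    EndmemberSet,
    IsotopeMeasurement,
    MetricConfig,
    MetricRecord,
    Role,
    Tissue,
    ViolationSummary,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "specimen_id", "species", "role", "tissue", "season", "stratum", "d13c", "d15n",
)

FLOAT_FORMAT = "%.4f"  # output precision; exceeds field reporting so values round-trip


class PipelineError(RuntimeError):
    """Module error re-raised with the pipeline stage that hit it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class Dataset:
    measurements: tuple[IsotopeMeasurement, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def consumers(self) -> list[IsotopeMeasurement]:
        return [m for m in self.measurements if m.role == Role.CONSUMER]

    @property
    def baselines(self) -> list[IsotopeMeasurement]:
        return [m for m in self.measurements if m.role != Role.CONSUMER]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the data.

    Serializes losslessly to YAML (``save`` / ``load``); ``lambdas`` maps
    habitat ("littoral"/"pelagic") to the assumed trophic position of that
    habitat's baseline taxon.
    """

    metric: MetricConfig = field(default_factory=MetricConfig)
    policy: GroupingPolicy = field(default_factory=GroupingPolicy)
    lambdas: dict = field(default_factory=lambda: {"littoral": 2.0, "pelagic": 2.0})
    alpha_level: float = 0.05
    paired_comparison: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "metric": {
                "delta_n": self.metric.delta_n,
                "lambda_default": self.metric.lambda_default,
                "violation_threshold": self.metric.violation_threshold,
                "rescale_scope": self.metric.rescale_scope,
            },
            "policy": {
                "stratum_matching": self.policy.stratum_matching,
                "season_matching_by_tissue": {
                    (t.value if hasattr(t, "value") else str(t)): rule
                    for t, rule in self.policy.season_matching_by_tissue.items()
                },
            },
            "lambdas": dict(self.lambdas),
            "alpha_level": self.alpha_level,
            "paired_comparison": self.paired_comparison,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        metric = MetricConfig(**d.get("metric", {}))
        pol = d.get("policy", {})
        policy = GroupingPolicy(
            stratum_matching=pol.get("stratum_matching", False),
            season_matching_by_tissue={
                Tissue(t): rule
                for t, rule in pol.get(
                    "season_matching_by_tissue",
                    GroupingPolicy().season_matching_by_tissue,
                ).items()
            },
        )
        return cls(
            metric=metric,
            policy=policy,
            lambdas=dict(d.get("lambdas", {"littoral": 2.0, "pelagic": 2.0})),
            alpha_level=float(d.get("alpha_level", 0.05)),
            paired_comparison=bool(d.get("paired_comparison", False)),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    dataset: Dataset
    distinctness: tuple[DistinctnessReport, DistinctnessReport]
    screens: dict
    endmember_table: list[EndmemberSet]
    records: list[MetricRecord]
    violations_by_species: dict[str, ViolationSummary]
    overall_violations: ViolationSummary
    recommendation: Recommendation
    summary: pd.DataFrame
    comparisons: list[EquationComparisonReport]
    manifest: dict


def _detect_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_dataset(path, column_map: dict | None = None) -> Dataset:
    """Read a long-format isotope CSV/TSV into a validated Dataset.

    ``column_map`` renames source columns to the required schema (for
    deposits with their own naming), applied after lower-casing. Rows with
    unparseable isotope values are dropped and counted in provenance;
    duplicate specimen ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df.columns = [c.strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    n_read = len(df)
    for col in ("d13c", "d15n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = df["d13c"].notna() & df["d15n"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with unparseable isotope values",
                       path, n_dropped)
    df = df[keep]
    if df.empty:
        raise ValueError(f"{path}: no rows with parseable isotope values")
    dupes = df["specimen_id"].duplicated()
    if dupes.any():
        raise ValueError(
            f"{path}: duplicate specimen_id(s): "
            f"{sorted(df.loc[dupes, 'specimen_id'].unique())[:5]}"
        )

    length = None
    if "length_mm" in df.columns:
        length = pd.to_numeric(df["length_mm"], errors="coerce")

    measurements = []
    for i, row in enumerate(df.itertuples(index=False)):
        measurements.append(
            IsotopeMeasurement(
                specimen_id=str(row.specimen_id),
                species=str(row.species),
                role=Role(str(row.role).strip().lower()),
                tissue=Tissue(str(row.tissue).strip().lower()),
                season=str(row.season).strip().lower(),
                stratum=str(row.stratum).strip().lower(),
                d13c=float(row.d13c),
                d15n=float(row.d15n),
                length_mm=(
                    float(length.iloc[i])
                    if length is not None and pd.notna(length.iloc[i])
                    else None
                ),
            )
        )
    return Dataset(
        measurements=tuple(measurements),
        provenance={
            "source": str(path),
            "n_read": n_read,
            "n_dropped": n_dropped,
            "n_retained": len(measurements),
        },
    )


def write_dataset(measurements: Sequence[IsotopeMeasurement], path) -> None:
    from .simulate import measurements_to_frame

    measurements_to_frame(measurements).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def run_pipeline(
    dataset: Dataset, config: RunConfig, outdir=None
) -> PipelineResult:
    """End-to-end analysis in the field's canonical order: habitat
    distinctness first, then grouping screens, then the metric suite, then
    the recommendation and equation comparisons.

    Deterministic given (dataset, config); ``outdir`` (optional) receives
    the endmember table, per-individual metrics, violation and summary
    tables, comparison reports, the recommendation and a manifest.
    """
    consumers = dataset.consumers
    baselines = dataset.baselines
    if not baselines:
        raise PipelineError("baseline_builder", ValueError("dataset has no baseline rows"))
    if not consumers:
        raise PipelineError("core_metrics", ValueError("dataset has no consumer rows"))

    # 1. habitat distinctness
    littoral = [b for b in baselines if b.role == Role.LITTORAL_BASELINE]
    pelagic = [b for b in baselines if b.role == Role.PELAGIC_BASELINE]
    try:
        distinctness = test_habitat_distinctness(littoral, pelagic, config.alpha_level)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("baseline_builder", e) from e

    # 2. advisory grouping screens (factors with >= 2 levels in the data)
    screens: dict[str, list] = {}
    for factor, pool in (("stratum", baselines), ("season", baselines),
                         ("tissue", consumers)):
        levels = {getattr(m, factor) for m in pool}
        if len(levels) >= 2:
            screens[factor] = screen_grouping_factors(
                pool, factor, config.alpha_level, strict=False
            )

    # 3. endmember table and per-consumer metric suite
    try:
        table = build_endmember_table(baselines, config.policy, config.lambdas)
        resolver = lambda c: resolve_endmembers(c, table, config.policy)  # noqa: E731
        records = compute_metric_suite(consumers, resolver, baselines, config.metric)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("core_metrics", e) from e

    # 4. boundary violations, per species and overall
    thr = config.metric.violation_threshold
    raw = {r.specimen_id: r.lcu for r in records}
    violations_by_species = {}
    for sp in sorted({c.species for c in consumers}):
        vals = [raw[c.specimen_id] for c in consumers if c.species == sp]
        violations_by_species[sp] = boundary_violation_stats(vals, thr)
    overall = boundary_violation_stats(list(raw.values()), thr)

    # 5. recommendation
    lambdas_equal = config.lambdas.get("littoral", 2.0) == config.lambdas.get(
        "pelagic", 2.0
    )
    recommendation = recommend_equations(distinctness, overall, lambdas_equal)

    # 6. summaries and equation comparisons
    summary = summarize_metrics(records, consumers)
    comparisons = []
    rec_by_id = {r.specimen_id: r for r in records}
    for sp in sorted({c.species for c in consumers}):
        sp_records = [rec_by_id[c.specimen_id] for c in consumers if c.species == sp]
        if len(sp_records) < 2:
            continue
        for family in ("lcu", "tp"):
            comparisons.append(
                compare_equation_variants(
                    sp_records, species=sp, family=family,
                    alpha_level=config.alpha_level, paired=config.paired_comparison,
                )
            )

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_consumers": len(consumers),
        "n_baselines": len(baselines),
        "provenance": dataset.provenance,
        "recommendation": dataclasses.asdict(recommendation),
    }

    result = PipelineResult(
        dataset=dataset, distinctness=distinctness, screens=screens,
        endmember_table=table, records=records,
        violations_by_species=violations_by_species, overall_violations=overall,
        recommendation=recommendation, summary=summary, comparisons=comparisons,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def endmembers_to_frame(table: Sequence[EndmemberSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [em.scope[0] if em.scope[0] is not None else "pooled" for em in table],
            "season": [em.scope[1] if em.scope[1] is not None else "pooled" for em in table],
            "d13c_littoral": [em.d13c_littoral for em in table],
            "d13c_pelagic": [em.d13c_pelagic for em in table],
            "d15n_littoral": [em.d15n_littoral for em in table],
            "d15n_pelagic": [em.d15n_pelagic for em in table],
            "lambda_littoral": [em.lambda_littoral for em in table],
            "lambda_pelagic": [em.lambda_pelagic for em in table],
            "n_littoral": [em.n_littoral for em in table],
            "n_pelagic": [em.n_pelagic for em in table],
        }
    )


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"specimen_id": r.specimen_id, "lcu": r.lcu, "lcu_adj": r.lcu_adj,
               "lcu_r": r.lcu_r}
        row.update(r.tp)
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: Sequence[EquationComparisonReport]) -> pd.DataFrame:
    rows = []
    for rep in comparisons:
        if not rep.pairwise:
            rows.append(
                {"species": rep.species, "family": rep.metric_family,
                 "omnibus_h": rep.omnibus_statistic, "omnibus_p": rep.omnibus_p,
                 "variant_a": "", "variant_b": "", "z": np.nan,
                 "p_adjusted": np.nan, "significant": False}
            )
        for pw in rep.pairwise:
            rows.append(
                {"species": rep.species, "family": rep.metric_family,
                 "omnibus_h": rep.omnibus_statistic, "omnibus_p": rep.omnibus_p,
                 "variant_a": pw.group_a, "variant_b": pw.group_b, "z": pw.z,
                 "p_adjusted": pw.p_adjusted, "significant": pw.significant}
            )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    endmembers_to_frame(result.endmember_table).to_csv(
        outdir / "endmembers.csv", index=False, float_format=FLOAT_FORMAT
    )
    records_to_frame(result.records).to_csv(
        outdir / "metrics.csv", index=False, float_format=FLOAT_FORMAT
    )
    viol = pd.DataFrame(
        [
            {"species": sp, **dataclasses.asdict(v)}
            for sp, v in result.violations_by_species.items()
        ]
        + [{"species": "__all__", **dataclasses.asdict(result.overall_violations)}]
    )
    viol.to_csv(outdir / "violations.csv", index=False, float_format=FLOAT_FORMAT)
    result.summary.to_csv(outdir / "summary.csv", index=False, float_format=FLOAT_FORMAT)
    comparisons_to_frame(result.comparisons).to_csv(
        outdir / "comparisons.csv", index=False, float_format=FLOAT_FORMAT
    )
    (outdir / "recommendation.json").write_text(
        json.dumps(dataclasses.asdict(result.recommendation), indent=2) + "\n"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str) + "\n"
    )
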