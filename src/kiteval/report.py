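"""Kit-comparison reporting: thresholds, verdicts, best-per-metric matrix.

This is the top of the evaluation workflow: it takes per-sample metrics (one
set per kit and sequencing effort), applies the clinical acceptability rules,
marks the best kit per metric where a direction of merit exists, and writes
machine-readable (JSON/TSV) plus human-readable reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import DesignPartition

__all__ = [
    "SampleMetrics",
    "MetricRule",
    "ThresholdConfig",
    "evaluate_sample",
    "compare_kits",
    "render_report",
    "KitComparison",
]


@dataclass
class SampleMetrics:
    """The seven sample-level quality parameters plus derived fields.

    Percentages are on the 0-100 scale; coverages in X (fold).
    """

    label: str = ""
    median_insert: float | None = None  # bp
    on_target_rate: float | None = None  # %
    mean_cov_with_dups: float | None = None  # X
    duplicate_rate: float | None = None  # %
    mean_cov_no_dups: float | None = None  # X
    pct_target_at_30x: float | None = None  # %
    fold80: float | None = None
    evenness: float | None = None  # %
    tstv: float | None = None

    def __post_init__(self) -> None:
        if (
            self.mean_cov_no_dups is not None
            and self.mean_cov_with_dups is not None
            and self.mean_cov_no_dups > self.mean_cov_with_dups + 1e-9
        ):
            raise ValueError("dedup coverage cannot exceed dup-inclusive coverage")


@dataclass
class MetricRule:
    """One acceptability rule: direction, bound, strictness and context."""

    metric: str
    bound: float | None  # None -> advisory only
    direction: str = ">"  # '>', '<', '>=', '<=' or 'advisory'
    note: str = ""
    corrective: str = ""

    def check(self, value: float) -> bool | None:
        if self.bound is None or self.direction == "advisory":
            return None
        if self.direction == ">":
            return value > self.bound
        if self.direction == "<":
            return value < self.bound
        if self.direction == ">=":
            return value >= self.bound
        if self.direction == "<=":
            return value <= self.bound
        raise ValueError(f"bad direction {self.direction!r}")


def default_rules() -> dict[str, MetricRule]:
    """Clinical acceptability defaults for the sample metrics.

    Boundary semantics follow the stated wording: "under 20%" and ">80%"
    are strict, "at least 100X" and ">=90% at 30X" are inclusive. Insert
    size, fold-80 and evenness have no hard bound (method-dependent) and
    are advisory.
    """
    return {
        "median_insert": MetricRule(
            "median_insert", None, "advisory", note="expected around 200-250 bp",
            corrective="adjust fragmentation for optimal coverage uniformity",
        ),
        "duplicate_rate": MetricRule(
            "duplicate_rate", 20.0, "<",
            corrective="optimise input amount and PCR cycle count",
        ),
        "on_target_rate": MetricRule(
            "on_target_rate", 80.0, ">",
            note="substantially influenced by insert size",
            corrective="review capture design or insert size",
        ),
        "mean_cov_no_dups": MetricRule(
            "mean_cov_no_dups", 100.0, ">=",
            note="strongly recommended at least 100X, application-dependent",
            corrective="sequence deeper or pool fewer samples",
        ),
        "pct_target_at_30x": MetricRule(
            "pct_target_at_30x", 90.0, ">=",
            note="strongly recommended >90% at 30X",
            corrective="increase effort or change capture design",
        ),
        "fold80": MetricRule(
            "fold80", None, "advisory",
            note="1.0 is perfect uniformity; threshold depends on method",
        ),
        "evenness": MetricRule(
            "evenness", None, "advisory",
            note="100% is perfect uniformity; threshold depends on method",
        ),
        "tstv": MetricRule(
            "tstv", 2.4, ">",
            note="CDS sequencing; ~2 genome-wide, a little above 3 in coding regions",
            corrective="investigate capture, sample or sequencer drift",
        ),
        "mean_cov_with_dups": MetricRule("mean_cov_with_dups", None, "advisory"),
    }


@dataclass
class ThresholdConfig:
    rules: dict[str, MetricRule] = field(default_factory=default_rules)

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdConfig":
        """Load overrides: {"metric": {"bound": x, "direction": ">"}, ...}."""
        cfg = cls()
        with open(path) as fh:
            for metric, override in json.load(fh).items():
                rule = cfg.rules.get(metric) or MetricRule(metric, None)
                if "bound" in override:
                    rule.bound = override["bound"]
                if "direction" in override:
                    rule.direction = override["direction"]
                cfg.rules[metric] = rule
        return cfg


@dataclass
class SampleVerdict:
    metric: str
    value: float | None
    rule: str
    status: str  # 'pass' | 'fail' | 'advisory'
    note: str = ""


def evaluate_sample(
    metrics: SampleMetrics, config: ThresholdConfig | None = None
) -> list[SampleVerdict]:
    """Per-metric pass/fail/advisory verdicts for one sample.

    A missing metric with a hard rule is an error; advisory metrics may be
    absent.
    """
    config = config or ThresholdConfig()
    verdicts = []
    for name, rule in config.rules.items():
        value = getattr(metrics, name, None)
        if value is None:
            if rule.bound is not None and rule.direction != "advisory":
                raise ValueError(f"metric {name!r} required by rule but missing")
            continue
        outcome = rule.check(value)
        if outcome is None:
            status, note = "advisory", rule.note
        elif outcome:
            status, note = "pass", ""
        else:
            status = "fail"
            note = "; ".join(x for x in (rule.note, rule.corrective) if x)
        verdicts.append(
            SampleVerdict(name, value, f"{rule.direction} {rule.bound}", status, note)
        )
    return verdicts


# Direction of merit per Table-2-style column; columns without a direction
# (insert size, Ts/Tv) are never marked best.
_MERIT = {
    "on_target_rate": "high",
    "mean_cov_with_dups": "high",
    "duplicate_rate": "low",
    "mean_cov_no_dups": "high",
    "pct_target_at_30x": "high",
    "fold80": "low",
    "evenness": "high",
}


@dataclass
class KitComparison:
    efforts: list[int]  # million reads (labels)
    kits: list[str]
    cells: dict[tuple[int, str], SampleMetrics]  # (effort, kit) -> metrics
    best: dict[tuple[int, str], list[str]]  # (effort, metric) -> best kit(s)
    verdicts: dict[tuple[int, str], list[SampleVerdict]]
    ranking: list[tuple[str, dict[str, float]]]  # (kit, criteria) best first


def compare_kits(
    per_kit: Mapping[str, Mapping[int, SampleMetrics]],
    config: ThresholdConfig | None = None,
    minimal_efforts: Mapping[str, float | None] | None = None,
) -> KitComparison:
    """Build the kit-comparison matrix with per-metric best markers.

    ``per_kit`` maps kit name -> effort (million reads) -> metrics; all kits
    must share the same effort grid. Ranking criteria, in order: fewest
    threshold failures, lowest duplicate rate, smallest effort to reach 90%
    of target bases at 30X (``minimal_efforts``, optional).
    """
    kits = sorted(per_kit)
    if len(kits) < 2:
        raise ValueError("need at least 2 kits to compare")
    effort_sets = {k: tuple(sorted(per_kit[k])) for k in kits}
    if len(set(effort_sets.values())) != 1:
        raise ValueError(f"kits have mismatched effort grids: {effort_sets}")
    efforts = list(effort_sets[kits[0]])

    config = config or ThresholdConfig()
    cells: dict[tuple[int, str], SampleMetrics] = {}
    verdicts: dict[tuple[int, str], list[SampleVerdict]] = {}
    best: dict[tuple[int, str], list[str]] = {}
    failures = {k: 0 for k in kits}
    for effort in efforts:
        for kit in kits:
            m = per_kit[kit][effort]
            cells[(effort, kit)] = m
            v = evaluate_sample(m, config)
            verdicts[(effort, kit)] = v
            failures[kit] += sum(1 for x in v if x.status == "fail")
        for metric, direction in _MERIT.items():
            values = {
                kit: getattr(cells[(effort, kit)], metric) for kit in kits
            }
            values = {k: v for k, v in values.items() if v is not None}
            if not values:
                continue
            opt = min(values.values()) if direction == "low" else max(values.values())
            best[(effort, metric)] = [k for k in kits if values.get(k) == opt]

    def rank_key(kit: str) -> tuple:
        me = (minimal_efforts or {}).get(kit)
        mean_dup = sum(
            cells[(e, kit)].duplicate_rate or 0.0 for e in efforts
        ) / len(efforts)
        return (failures[kit], mean_dup, float("inf") if me is None else me)

    ranking = [
        (
            kit,
            {
                "threshold_failures": float(failures[kit]),
                "mean_duplicate_rate": rank_key(kit)[1],
                "minimal_effort_90pct_30x": rank_key(kit)[2],
            },
        )
        for kit in sorted(kits, key=rank_key)
    ]
    return KitComparison(efforts, kits, cells, best, verdicts, ranking)


_COLUMNS = [
    ("median_insert", "Median Insert Size (bp)", "{:.0f}"),
    ("on_target_rate", "On-Target Rate (%)", "{:.2f}"),
    ("mean_cov_with_dups", "Mean Coverage with Duplicates (X)", "{:.1f}"),
    ("duplicate_rate", "Duplicate Reads (%)", "{:.2f}"),
    ("mean_cov_no_dups", "Mean Coverage without Duplicates (X)", "{:.1f}"),
    ("pct_target_at_30x", "Target Base at 30X (%)", "{:.0f}"),
    ("fold80", "Fold-80 Base Penalty", "{:.1f}"),
    ("evenness", "Evenness (%)", "{:.2f}"),
    ("tstv", "Ts/Tv Ratio", "{:.1f}"),
]


def render_report(
    comparison: KitComparison,
    out_dir: str | Path,
    design_partitions: Sequence[DesignPartition] = (),
    panel_results: Mapping[str, Sequence[Mapping[str, float]]] | None = None,
) -> dict[str, Path]:
    """Write the comparison as JSON, TSV and a text summary.

    Regenerating from identical inputs yields byte-identical files (fixed
    ordering and float formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = {
        "kits": comparison.kits,
        "efforts_million_reads": comparison.efforts,
        "matrix": [
            {
                "effort": effort,
                "kit": kit,
                **{
                    k: v
                    for k, v in asdict(comparison.cells[(effort, kit)]).items()
                    if k != "label"
                },
                "best_in": sorted(
                    metric
                    for (e, metric), winners in comparison.best.items()
                    if e == effort and kit in winners
                ),
                "verdicts": [
                    asdict(v) for v in comparison.verdicts[(effort, kit)]
                ],
            }
            for effort in comparison.efforts
            for kit in comparison.kits
        ],
        "ranking": [
            {"kit": kit, "criteria": crit} for kit, crit in comparison.ranking
        ],
        "design_partitions": [asdict(p) for p in design_partitions]
        or "not evaluated",
        "panel_coverage": panel_results or "not evaluated",
    }
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    tsv_path = out_dir / "comparison.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(
            "\t".join(["Effort (M reads)", "Kit"] + [c[1] for c in _COLUMNS]) + "\n"
        )
        for effort in comparison.efforts:
            for kit in comparison.kits:
                m = comparison.cells[(effort, kit)]
                row = [str(effort), kit]
                for name, _, fmt in _COLUMNS:
                    v = getattr(m, name)
                    cell = "NA" if v is None else fmt.format(v)
                    if kit in comparison.best.get((effort, name), []):
                        cell = f"*{cell}*"
                    row.append(cell)
                fh.write("\t".join(row) + "\n")

    txt_path = out_dir / "summary.txt"
    with open(txt_path, "w") as fh:
        fh.write("Kit evaluation summary\n======================\n\n")
        fh.write("Ranking (fewest threshold failures, then duplicate rate,\n")
        fh.write("then minimal effort to 90% of target bases at 30X):\n")
        for i, (kit, crit) in enumerate(comparison.ranking, 1):
            fh.write(
                f"  {i}. {kit}: failures={crit['threshold_failures']:.0f},"
                f" mean duplicate rate={crit['mean_duplicate_rate']:.2f}%,"
                f" minimal effort={crit['minimal_effort_90pct_30x']}\n"
            )
        fh.write("\nPer-kit threshold failures:\n")
        for effort in comparison.efforts:
            for kit in comparison.kits:
                fails = [
                    v for v in comparison.verdicts[(effort, kit)] if v.status == "fail"
                ]
                for v in fails:
                    fh.write(
                        f"  {kit} @ {effort}M: {v.metric}={v.value:.2f}"
                        f" (rule {v.rule}) — {v.note}\n"
                    )
        if not design_partitions:
            fh.write("\nDesign partition: not evaluated\n")
        if not panel_results:
            fh.write("Panel coverage: not evaluated\n")
    return {"json": json_path, "tsv": tsv_path, "text": txt_path}
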