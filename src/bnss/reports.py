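"""Plain-text report writers (TSV / JSON) for the analysis results.

All writers emit UTF-8, LF-terminated, 0/1-encoded Boolean tables that
are diff-friendly and parse back losslessly.
"""

from __future__ import annotations

import json
import math

from .analysis import (
    CardinalityStats,
    EfficiencyCurve,
    FrozenVariablePartition,
    JointCensus,
    NetworkComparison,
    StateCensus,
)

__all__ = [
    "census_to_tsv",
    "cardinality_to_tsv",
    "partition_to_tsv",
    "joint_census_to_tsv",
    "efficiency_to_tsv",
    "comparison_to_tsv",
    "comparison_to_json",
]


def _bits(state: tuple[bool, ...]) -> str:
    return "".join("1" if v else "0" for v in state)


def census_to_tsv(census: StateCensus) -> str:
    lines = ["state\tcount\tvisit_times"]
    for e in census.entries:
        lines.append(f"{_bits(e.state)}\t{e.count}\t{','.join(map(str, e.visit_times))}")
    return "\n".join(lines) + "\n"


def cardinality_to_tsv(stats: CardinalityStats, label: str = "", updates: int | None = None) -> str:
    sd = "-" if math.isnan(stats.sd) else f"{stats.sd:.6g}"
    lines = ["label\tupdates\truns\tmean_states\tsd_states"]
    lines.append(
        f"{label}\t{'' if updates is None else updates}\t{len(stats.per_run)}\t"
        f"{stats.mean:.6g}\t{sd}"
    )
    return "\n".join(lines) + "\n"


def partition_to_tsv(partition: FrozenVariablePartition, node_order: tuple[str, ...]) -> str:
    lines = ["node\tstatus\tfrozen_value"]
    for node in node_order:
        if node in partition.frozen:
            lines.append(f"{node}\tfrozen\t{1 if partition.frozen[node] else 0}")
        else:
            lines.append(f"{node}\tvariable\t")
    return "\n".join(lines) + "\n"


def joint_census_to_tsv(jc: JointCensus) -> str:
    a, b = jc.pair
    lines = [f"{a}\t{b}\tcount"]
    for (va, vb), count in sorted(jc.counts.items(), reverse=True):
        lines.append(f"{1 if va else 0}\t{1 if vb else 0}\t{count}")
    lines.append(f"# verdict: {jc.verdict}")
    return "\n".join(lines) + "\n"


def efficiency_to_tsv(curve: EfficiencyCurve) -> str:
    lines = [f"t\tfraction_true\t# output={curve.output_node} runs={curve.n_runs}"]
    for t, f in zip(curve.times, curve.fractions):
        lines.append(f"{t}\t{f:.6g}")
    return "\n".join(lines) + "\n"


def comparison_to_tsv(cmp: NetworkComparison) -> str:
    lines = ["network\tmean_states\tsd_states\tn_variable\tn_frozen\ttop_state\ttop_count"]
    for rep in cmp.reports:
        sd = "-" if math.isnan(rep.cardinality.sd) else f"{rep.cardinality.sd:.6g}"
        top_state, top_count = rep.top[0] if rep.top else ((), 0)
        lines.append(
            f"{rep.label}\t{rep.cardinality.mean:.6g}\t{sd}\t"
            f"{len(rep.partition.variable)}\t{len(rep.partition.frozen)}\t"
            f"{_bits(top_state)}\t{top_count}"
        )
    lines.append("# variable_intersection: " + ",".join(sorted(cmp.variable_intersection)))
    return "\n".join(lines) + "\n"


def comparison_to_json(cmp: NetworkComparison) -> str:
    def rep_obj(rep):
        return {
            "label": rep.label,
            "cardinality": {
                "per_run": list(rep.cardinality.per_run),
                "mean": rep.cardinality.mean,
                "sd": None if math.isnan(rep.cardinality.sd) else rep.cardinality.sd,
            },
            "frozen": {k: bool(v) for k, v in rep.partition.frozen.items()},
            "variable": sorted(rep.partition.variable),
            "top_states": [[_bits(s), c] for s, c in rep.top],
            "efficiency": None
            if rep.efficiency is None
            else {"times": list(rep.efficiency.times), "fractions": list(rep.efficiency.fractions)},
        }

    obj = {
        "networks": [rep_obj(r) for r in cmp.reports],
        "variable_intersection": sorted(cmp.variable_intersection),
    }
    return json.dumps(obj, indent=1)
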