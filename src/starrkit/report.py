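"""Summary tables: count/denominator/percent rows aggregated over all stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping


def percent(count: int, denominator: int) -> float:
    """``100 * count / denominator`` rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Rows of (label, count, denominator, percent)."""

    title: str
    rows: list[tuple[str, int, int, float]] = field(default_factory=list)

    def add(self, label: str, count: int, denominator: int) -> None:
        pct = percent(count, denominator) if denominator > 0 else 0.0
        self.rows.append((label, count, denominator, pct))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tcount\tdenominator\tpercent\n")
            for label, count, denom, pct in self.rows:
                fh.write(f"{label}\t{count}\t{denom}\t{pct:.2f}\n")

    def as_dict(self) -> dict:
        return {
            label: {"count": count, "denominator": denom, "percent": pct}
            for label, count, denom, pct in self.rows
        }


REQUIRED_STAGES = ("union_calls", "categories", "accessibility", "state_classes", "qtl")


def build_report(stages: Mapping[str, object]) -> dict:
    """Aggregate per-stage outputs into summary tables and a JSON-ready dict.

    ``stages`` must provide:

    * ``union_calls``: the non-redundant union enhancer list (every
      denominator below);
    * ``categories``: per-enhancer (category, te_subclass) tuples;
    * ``accessibility``: per-enhancer 'open'/'closed' labels;
    * ``state_classes``: per-enhancer StateClass values;
    * ``qtl``: dict with n_regions and n_traits.

    Raises KeyError naming the first missing stage.
    """
    for stage in REQUIRED_STAGES:
        if stage not in stages:
            raise KeyError(f"missing stage output: {stage!r}")
    union = stages["union_calls"]
    n = len(union)  # type: ignore[arg-type]
    tables: dict[str, SummaryTable] = {}

    cat_tab = SummaryTable("feature_categories")
    cats = [c for c, _sub in stages["categories"]]  # type: ignore[union-attr]
    for cat in sorted(set(cats)):
        if n:
            cat_tab.add(cat, cats.count(cat), n)
    tables["feature_categories"] = cat_tab

    te_tab = SummaryTable("te_subclasses")
    subs = [sub for _c, sub in stages["categories"] if sub]  # type: ignore[union-attr]
    for sub in sorted(set(subs)):
        if n:
            te_tab.add(sub, subs.count(sub), n)
    tables["te_subclasses"] = te_tab

    acc_tab = SummaryTable("accessibility")
    acc = list(stages["accessibility"])  # type: ignore[arg-type]
    for label in ("open", "closed"):
        if n:
            acc_tab.add(label, acc.count(label), n)
    tables["accessibility"] = acc_tab

    state_tab = SummaryTable("state_classes")
    states = [getattr(s, "value", s) for s in stages["state_classes"]]  # type: ignore[union-attr]
    for label in ("active_only", "repressive_only", "both", "neither"):
        if n:
            state_tab.add(label, states.count(label), n)
    tables["state_classes"] = state_tab

    qtl = stages["qtl"]
    report = {
        "n_union_enhancers": n,
        "qtl": dict(qtl),  # type: ignore[call-overload]
        "tables": {name: t.as_dict() for name, t in tables.items()},
    }
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, table in report["tables"].items():
        t = SummaryTable(name)
        for label, row in table.items():
            t.rows.append((label, row["count"], row["denominator"], row["percent"]))
        t.to_tsv(out / f"{name}.tsv")
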