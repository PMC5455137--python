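"""Qualitative consistency of predicted fluxes with expressed-enzyme lists.

Given a solved flux state and a proteome or transcriptome expression list
(EC numbers), an expressed enzyme is *predicted* when any of its catalyzed
reactions carries non-zero flux.  Enzymes blocked at the network level
(no feasible flux in any steady state) are excluded from the comparison,
since their absence of flux is structural rather than condition-specific.
The comparison is qualitative by design: expression lists carry no
abundances, and flux magnitude is not compared to expression level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._opt import TOL_ZERO
from .gap_coupling import CouplingReport
from .model_core import FluxState, MetabolicModel

__all__ = ["ExpressionSet", "ComparisonReport", "compare_expression",
           "unpredicted_breakdown", "read_expression_tsv"]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass
class ExpressionSet:
    source: str                    # proteome | transcriptome | synthetic
    ecs: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for ec in self.ecs:
            if not _EC_RE.match(ec):
                raise ValueError(f"not an EC number: {ec!r}")

    @property
    def unique_ecs(self) -> list[str]:
        return sorted(set(self.ecs))


def read_expression_tsv(path, source: str = "proteome") -> ExpressionSet:
    """Two-column TSV (EC, label); extra columns ignored."""
    ecs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ec = line.split("\t")[0].strip()
            if ec.lower() in ("ec", "enzyme"):
                continue
            ecs.append(ec)
    return ExpressionSet(source=source, ecs=ecs, provenance=str(path))


@dataclass
class ComparisonReport:
    shared: list[str]
    excluded_blocked: list[str]
    predicted: list[str]
    not_predicted: list[str]
    unshared: list[str]
    status: dict[str, str] = field(default_factory=dict)
    coupling_class: dict[str, str] = field(default_factory=dict)

    @property
    def prediction_rate(self) -> float:
        comparable = len(self.shared) - len(self.excluded_blocked)
        return len(self.predicted) / comparable if comparable else float("nan")


def compare_expression(model: MetabolicModel, flux: FluxState,
                       coupling: CouplingReport, expr: ExpressionSet,
                       tol_zero: float = TOL_ZERO) -> ComparisonReport:
    """Cross-tabulate expressed enzymes against flux activity.

    Expression lists are de-duplicated; ECs absent from the model are
    listed as unshared.  Blocked enzymes (per the coupling report) are
    excluded; the prediction rate is predicted / (shared − blocked).
    """
    model_ecs = set(model.enzymes)
    shared, unshared = [], []
    for ec in expr.unique_ecs:
        (shared if ec in model_ecs or model.reactions_for_enzyme(ec)
         else unshared).append(ec)
    report = ComparisonReport(shared=shared, excluded_blocked=[],
                              predicted=[], not_predicted=[],
                              unshared=unshared)
    for ec in shared:
        cls = coupling.enzyme_classes.get(ec, "unmapped")
        report.coupling_class[ec] = cls
        if cls == "blocked":
            report.excluded_blocked.append(ec)
            report.status[ec] = "excluded"
            continue
        active = any(abs(flux.fluxes.get(r.id, 0.0)) > tol_zero
                     for r in model.reactions_for_enzyme(ec))
        if active:
            report.predicted.append(ec)
            report.status[ec] = "predicted"
        else:
            report.not_predicted.append(ec)
            report.status[ec] = "not_predicted"
    return report


def unpredicted_breakdown(report: ComparisonReport):
    """Group the not-predicted enzymes by their coupling class.

    Enzymes fully or partially coupled to growth must carry flux whenever
    the network grows, so with a growing flux state every not-predicted
    enzyme should fall in the directional (or uncoupled) classes — the
    breakdown makes that visible.
    """
    import pandas as pd

    rows = [{"ec": ec, "coupling_class": report.coupling_class.get(ec, "unmapped")}
            for ec in sorted(report.not_predicted)]
    return pd.DataFrame(rows, columns=["ec", "coupling_class"])
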