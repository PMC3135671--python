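"""Score differences → predicted fold-selectivity, vs censored IC50 data.

The empirical scoring scale used throughout carries a published
calibration: roughly 100 score units correspond to one order of
magnitude of IC50.  A filtered ensemble-average score difference between
two receptors therefore predicts a fold-selectivity of
``10^(Δscore / 100)``, which is compared with the experimental IC50
ratio.  Experimental inhibition data may be left-censored ("IC50 > 50
μm"): such entries only bound the true value, so fold ratios built on a
censored numerator are lower bounds and a censored denominator is
refused outright (no finite ratio is defensible).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import CensoringError, InvalidConfigError, PipelineInputError
from .stats import EnsembleScoreSummary

__all__ = [
    "ConversionConstant",
    "InhibitionRecord",
    "LigandSelectivity",
    "SelectivityReport",
    "score_difference_orders",
    "predicted_fold",
    "experimental_fold",
    "build_report",
    "parse_ic50",
    "read_inhibition_table",
]


@dataclass(frozen=True)
class ConversionConstant:
    """Score units per order of magnitude of IC50 (default 100)."""

    units_per_decade: float = 100.0

    def __post_init__(self) -> None:
        if self.units_per_decade <= 0:
            raise InvalidConfigError("units_per_decade must be positive")


@dataclass(frozen=True)
class InhibitionRecord:
    ligand: str
    receptor: str
    ic50: float               # μm
    censored: bool = False    # True ⇔ reported as "> ic50"

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise InvalidConfigError("ic50 must be positive")


def parse_ic50(text: str) -> tuple[float, bool]:
    """Parse an IC50 cell; a leading '>' marks a left-censored entry."""
    text = str(text).strip()
    censored = text.startswith(">")
    value = float(text.lstrip(">").strip())
    return value, censored


def read_inhibition_table(path: str | os.PathLike) -> list[InhibitionRecord]:
    """Tab-delimited inhibition table: columns ligand, receptor, ic50.

    '>'-prefixed IC50 cells are parsed as censored lower bounds.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("ligand", "receptor", "ic50") if c not in table.columns]
    if missing:
        raise PipelineInputError(f"inhibition table missing columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        value, censored = parse_ic50(row.ic50)
        records.append(InhibitionRecord(str(row.ligand), str(row.receptor), value, censored))
    return records


# ---------------------------------------------------------------------------
# elementary conversions


def score_difference_orders(mean_a: float, mean_b: float,
                            constant: ConversionConstant | None = None) -> float:
    """Signed predicted affinity difference, in orders of magnitude."""
    constant = constant or ConversionConstant()
    return (mean_a - mean_b) / constant.units_per_decade


def predicted_fold(orders: float) -> float:
    """Orders of magnitude → dimensionless fold (10^orders)."""
    return 10.0 ** orders


def experimental_fold(less_selective: InhibitionRecord,
                      more_selective: InhibitionRecord) -> tuple[float, bool]:
    """IC50 ratio (weaker / stronger receptor) with censoring propagation.

    Returns (fold, lower_bound).  ``lower_bound`` is True when the
    numerator is censored (the true fold can only be larger).  A
    censored denominator makes the ratio's direction unsupported and
    raises :class:`CensoringError`.
    """
    if less_selective.ligand != more_selective.ligand:
        raise PipelineInputError(
            f"fold ratio mixes ligands {less_selective.ligand!r} and {more_selective.ligand!r}"
        )
    if more_selective.censored:
        raise CensoringError(
            "denominator IC50 is censored ('>'): the fold ratio is unbounded below"
        )
    return less_selective.ic50 / more_selective.ic50, less_selective.censored


# ---------------------------------------------------------------------------
# report


@dataclass
class LigandSelectivity:
    """Per-ligand comparison of predicted and experimental selectivity."""

    ligand: str
    receptor_strong: str            # experimentally more potently inhibited
    receptor_weak: str
    predicted_orders: float
    predicted_fold: float
    experimental_fold: float
    experimental_lower_bound: bool
    agreement_delta_orders: float   # predicted − log10(experimental)
    consistent: bool

    def to_dict(self) -> dict:
        return {
            "ligand": self.ligand,
            "receptor_strong": self.receptor_strong,
            "receptor_weak": self.receptor_weak,
            "predicted_orders": self.predicted_orders,
            "predicted_fold": self.predicted_fold,
            "experimental_fold": self.experimental_fold,
            "experimental_lower_bound": self.experimental_lower_bound,
            "agreement_delta_orders": self.agreement_delta_orders,
            "consistent": self.consistent,
        }


@dataclass
class SelectivityReport:
    ligands: list[LigandSelectivity]
    summaries: dict[tuple[str, str], EnsembleScoreSummary] = field(default_factory=dict)
    tolerance_orders: float = 1.0

    def to_dict(self) -> dict:
        return {
            "tolerance_orders": self.tolerance_orders,
            "ligands": [entry.to_dict() for entry in self.ligands],
            "summaries": {
                f"{ligand}|{receptor}": summary.to_dict()
                for (ligand, receptor), summary in sorted(self.summaries.items())
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"{'ligand':<8}{'pred orders':>12}{'pred fold':>12}"
            f"{'exp fold':>12}{'Δ orders':>10}  verdict"
        ]
        for e in self.ligands:
            bound = ">=" if e.experimental_lower_bound else "  "
            verdict = "consistent" if e.consistent else "discrepant"
            lines.append(
                f"{e.ligand:<8}{e.predicted_orders:>12.2f}{e.predicted_fold:>12.1f}"
                f"{bound}{e.experimental_fold:>10.1f}{e.agreement_delta_orders:>10.2f}  {verdict}"
            )
        return "\n".join(lines)


def _mean_of(summary) -> float:
    if isinstance(summary, EnsembleScoreSummary):
        return summary.mean
    return float(summary)


def build_report(
    summaries: dict[tuple[str, str], EnsembleScoreSummary | float],
    inhibition: list[InhibitionRecord],
    constant: ConversionConstant | None = None,
    tolerance_orders: float = 1.0,
) -> SelectivityReport:
    """Assemble the per-ligand selectivity comparison.

    ``summaries`` maps (ligand, receptor) to an ensemble summary (or a
    bare mean score).  Every ligand must appear for exactly the two
    receptors named in the inhibition table.  Orientation is set by the
    experiment: the receptor with the lower IC50 is the strong side.  A
    prediction is flagged consistent when the experimental fold is a
    lower bound that the predicted fold exceeds, or when the agreement
    delta is within ``tolerance_orders`` orders of magnitude.
    """
    constant = constant or ConversionConstant()
    by_ligand: dict[str, list[InhibitionRecord]] = {}
    for record in inhibition:
        by_ligand.setdefault(record.ligand, []).append(record)

    entries = []
    for ligand in sorted(by_ligand):
        records = by_ligand[ligand]
        if len(records) != 2:
            raise PipelineInputError(
                f"ligand {ligand!r} needs exactly two receptor rows, got {len(records)}"
            )
        # strong = lower IC50; a censored (">") entry is by construction weak
        weak, strong = sorted(records, key=lambda r: (not r.censored, -r.ic50))
        if strong.censored:
            raise CensoringError(f"ligand {ligand!r}: both receptor entries censored")
        for record in records:
            if (ligand, record.receptor) not in summaries:
                raise PipelineInputError(
                    f"missing ensemble summary for ligand {ligand!r}, "
                    f"receptor {record.receptor!r}"
                )

        orders = score_difference_orders(
            _mean_of(summaries[(ligand, strong.receptor)]),
            _mean_of(summaries[(ligand, weak.receptor)]),
            constant,
        )
        fold = predicted_fold(orders)
        exp_fold, lower_bound = experimental_fold(weak, strong)
        delta = orders - math.log10(exp_fold)
        consistent = (lower_bound and fold > exp_fold) or abs(delta) <= tolerance_orders

        entries.append(LigandSelectivity(
            ligand=ligand,
            receptor_strong=strong.receptor,
            receptor_weak=weak.receptor,
            predicted_orders=orders,
            predicted_fold=fold,
            experimental_fold=exp_fold,
            experimental_lower_bound=lower_bound,
            agreement_delta_orders=delta,
            consistent=consistent,
        ))

    full_summaries = {
        key: value for key, value in summaries.items()
        if isinstance(value, EnsembleScoreSummary)
    }
    return SelectivityReport(entries, full_summaries, tolerance_orders)
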