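"""Cross-condition biomarker screening with dose-rate pattern labels.

A candidate dose-rate-sensitive biomarker is a transcript significantly
regulated at *every* exposure condition, with a consistent direction of
regulation, whose regulation intensity |FC| moves the same way at both
early time points when the injected activity is raised: larger at the
elevated activity at both shared times -> *direct* dose-rate response,
smaller at both -> *inverse*, anything else (including an exact tie)
-> *mixed*.  Pairs whose |FC| difference relative to the reference is
below a small threshold (default 3%) are additionally flagged as near
ties, since the pattern label then rests on a negligible difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

Condition = tuple[float, float]


class ScreenError(ValueError):
    """Raised for malformed grids or incomplete fold-change maps."""


@dataclass(frozen=True)
class ExposureGrid:
    """The exposure design: reference arm plus activity-elevated arms.

    Default mirrors a common design: a reference activity of 1.7 kBq
    observed at 1 h, 6 h and 7 days, with elevated arms of 105 kBq at
    1 h and 7.5 kBq at 6 h.  Every elevated condition must share its
    time point with a reference condition; pattern classification uses
    exactly those shared times (reference-only times, such as the 7-day
    point here, take part in the all-condition intersection but not in
    the activity comparison).
    """

    reference_activity_kbq: float = 1.7
    reference_times_h: tuple[float, ...] = (1.0, 6.0, 168.0)
    elevated: tuple[Condition, ...] = ((105.0, 1.0), (7.5, 6.0))

    def __post_init__(self) -> None:
        for act, t in self.elevated:
            if t not in self.reference_times_h:
                raise ScreenError(
                    f"elevated condition ({act}, {t}) shares no reference time point"
                )

    @property
    def reference_conditions(self) -> tuple[Condition, ...]:
        return tuple((self.reference_activity_kbq, t) for t in self.reference_times_h)

    @property
    def conditions(self) -> tuple[Condition, ...]:
        return self.reference_conditions + self.elevated

    @property
    def paired_times(self) -> tuple[tuple[Condition, Condition], ...]:
        """(reference, elevated) condition pairs sharing a time point."""
        return tuple(
            ((self.reference_activity_kbq, t), (act, t)) for act, t in self.elevated
        )


@dataclass(frozen=True)
class BiomarkerCall:
    """A transcript regulated at all conditions, with its pattern label."""

    gene: str
    probe: str
    fc_by_condition: Mapping[Condition, float]
    direction_consistent: bool
    pattern: str  # direct | inverse | mixed | (undefined when inconsistent)
    near_tie: bool
    min_abs_fc: float


def intersect_all_conditions(de_sets: Mapping[Condition, set]) -> set:
    """Transcripts significant under every condition (set intersection)."""
    if not de_sets:
        raise ScreenError("no condition sets to intersect")
    sets = list(de_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def direction_consistency(fc_by_condition: Mapping[Condition, float],
                          conditions: Iterable[Condition]) -> bool:
    """True iff the signed FC has one sign across all grid conditions."""
    fcs = []
    for cond in conditions:
        if cond not in fc_by_condition:
            raise ScreenError(f"fold change missing for condition {cond}")
        fcs.append(fc_by_condition[cond])
    return all(f > 0 for f in fcs) or all(f < 0 for f in fcs)


def classify_pattern(fc_by_condition: Mapping[Condition, float],
                     grid: ExposureGrid) -> str:
    """Label the dose-rate response pattern on regulation intensity |FC|.

    *direct* iff |FC| at the elevated activity strictly exceeds the
    reference |FC| at **both** shared time points; *inverse* iff strictly
    below at both; *mixed* otherwise (an exact tie at either time point
    is mixed — "higher or lower" is read strictly).  Classification is
    refused when the direction of regulation is not consistent.
    """
    if not direction_consistency(fc_by_condition, grid.conditions):
        raise ScreenError(
            "direction of regulation inconsistent across conditions; "
            "pattern classification refused"
        )
    cmps = []
    for ref, elev in grid.paired_times:
        a, b = abs(fc_by_condition[elev]), abs(fc_by_condition[ref])
        cmps.append("gt" if a > b else ("lt" if a < b else "eq"))
    if all(c == "gt" for c in cmps):
        return "direct"
    if all(c == "lt" for c in cmps):
        return "inverse"
    return "mixed"


def near_tie_flag(fc_by_condition: Mapping[Condition, float],
                  grid: ExposureGrid,
                  threshold: float = 0.03) -> bool:
    """True iff reference and elevated |FC| differ by < threshold (relative
    to the reference |FC|) at any shared time point."""
    for ref, elev in grid.paired_times:
        ref_fc, elev_fc = fc_by_condition[ref], fc_by_condition[elev]
        if abs(abs(elev_fc) - abs(ref_fc)) / abs(ref_fc) < threshold:
            return True
    return False


def _gene_of(probe: str, probe_gene: Mapping[str, str] | pd.Series | None) -> str:
    if probe_gene is None:
        return probe
    try:
        return str(probe_gene[probe])
    except KeyError:
        return probe


def screen(
    de_calls: Mapping[Condition, pd.DataFrame],
    grid: ExposureGrid,
    probe_gene: Mapping[str, str] | pd.Series | None = None,
    tie_threshold: float = 0.03,
) -> list[BiomarkerCall]:
    """Screen differential-expression calls for dose-rate biomarkers.

    ``de_calls`` maps each grid condition to the per-probe call table
    from :func:`atdose.diffexpr.call_de`.  Probes significant at all
    conditions are kept; each gets a direction-consistency flag, a
    pattern label on the shared early time points, and a near-tie flag.
    The list is sorted by minimum |FC| across conditions, descending.
    Probe variants of one gene stay separate entries; use
    :func:`collapse_by_gene` for the gene-level view.
    """
    missing = [c for c in grid.conditions if c not in de_calls]
    if missing:
        raise ScreenError(f"DE calls missing for grid conditions: {missing}")
    sig_sets = {
        cond: set(df.index[df["significant"]]) for cond, df in de_calls.items()
        if cond in grid.conditions
    }
    common = intersect_all_conditions(sig_sets)
    out: list[BiomarkerCall] = []
    for probe in sorted(common):
        fc = {cond: float(de_calls[cond].loc[probe, "fold_change"])
              for cond in grid.conditions}
        consistent = direction_consistency(fc, grid.conditions)
        if consistent:
            pattern = classify_pattern(fc, grid)
            tie = near_tie_flag(fc, grid, tie_threshold)
        else:
            pattern, tie = "undefined", False
        out.append(
            BiomarkerCall(
                gene=_gene_of(probe, probe_gene),
                probe=probe,
                fc_by_condition=fc,
                direction_consistent=consistent,
                pattern=pattern,
                near_tie=tie,
                min_abs_fc=min(abs(v) for v in fc.values()),
            )
        )
    out.sort(key=lambda c: (-c.min_abs_fc, c.probe))
    return out


def collapse_by_gene(calls: list[BiomarkerCall]) -> pd.DataFrame:
    """Gene-level view: one row per gene; probe variants must agree in
    direction, otherwise the gene is flagged ``discordant``."""
    rows = []
    by_gene: dict[str, list[BiomarkerCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, []).append(c)
    for gene, group in sorted(by_gene.items()):
        signs = {all(v > 0 for v in c.fc_by_condition.values()) for c in group}
        discordant = len(signs) > 1 or any(not c.direction_consistent for c in group)
        patterns = {c.pattern for c in group}
        rows.append(
            {
                "gene": gene,
                "n_probes": len(group),
                "pattern": patterns.pop() if len(patterns) == 1 else "mixed",
                "discordant": discordant,
                "near_tie": any(c.near_tie for c in group),
                "min_abs_fc": min(c.min_abs_fc for c in group),
            }
        )
    return pd.DataFrame(rows)


def screen_table(calls: list[BiomarkerCall], grid: ExposureGrid) -> pd.DataFrame:
    """Flat per-probe table with one FC column per grid condition."""
    rows = []
    for c in calls:
        row = {
            "gene": c.gene,
            "probe": c.probe,
            "pattern": c.pattern,
            "near_tie": c.near_tie,
            "min_abs_fc": c.min_abs_fc,
        }
        for cond in grid.conditions:
            row[f"fc_{cond[0]:g}kbq_{cond[1]:g}h"] = c.fc_by_condition[cond]
        rows.append(row)
    cols = ["gene", "probe", "pattern", "near_tie", "min_abs_fc"] + [
        f"fc_{c[0]:g}kbq_{c[1]:g}h" for c in grid.conditions
    ]
    return pd.DataFrame(rows, columns=cols)
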