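"""Stutter-ratio measurement and per-locus summary statistics.

Stutter is quantified as percent of parent height: for every called parent
allele and every stutter position its locus exhibits (one repeat below, one
repeat above, or 2 nt below), a peak found at that offset that is not itself
a called allele yields one observation ``stutter_height / parent_height ×
100``.  Observations are pooled across a sample population and summarized
per (locus, position) as n / mean / min / max / sample SD, together with
the mean + 3·SD value conventionally used as the profile-analysis stutter
filter.

A reference summary table for the 24-locus panel (from a large
developmental-validation donor population, n = 1092) ships with the package;
it seeds the simulator's default stutter magnitudes and the default filter
set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from strvalid.allele_call import (
    CallThresholds,
    Profile,
    STUTTER_OFFSET_TOL_NT,
    STUTTER_STUDY_THRESHOLDS,
    StutterFilterTable,
)
from strvalid.epg_sim import Genotype, PeakTable
from strvalid.kit_panel import PanelDefinition

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (display convention for summary tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StutterObservation:
    locus: str
    position: str
    parent_allele: str
    ratio_pct: float
    parent_height: float
    stutter_height: float


@dataclass(frozen=True)
class StutterStatsRow:
    locus: str
    position: str
    n_obs: int
    mean_pct: float
    min_pct: float
    max_pct: float
    sd_pct: float

    @property
    def mean_plus_3sd_pct(self) -> float:
        return self.mean_pct + 3.0 * self.sd_pct


def measure_stutter(
    table: PeakTable,
    profile: Profile,
    panel: PanelDefinition,
    thresholds: CallThresholds = STUTTER_STUDY_THRESHOLDS,
    truth: "Genotype | None" = None,
) -> list[StutterObservation]:
    """Collect stutter observations from one sample.

    ``profile`` must be the pre-stutter-filter called profile of ``table``.
    Parents are the called alleles (already at or above the analytical
    threshold); candidate stutter peaks must reach ``stutter_min_height``
    and must not sit on a true allele — a stutter position occupied by a
    true allele yields no observation.  Both heterozygous and homozygous
    parents contribute.

    When the donor genotype is known (``truth``, the normal situation in a
    population characterization where every donor is a reference sample),
    true-allele positions come from it, so a tall stutter peak that crossed
    the analytical threshold and was provisionally called still counts as
    stutter.  Without ``truth`` the called alleles stand in for the true
    ones, which slightly underestimates stutter at loci whose stutter
    routinely exceeds the analytical threshold.

    Parents whose own position coincides with a stutter offset of another
    true allele (heterozygotes one repeat apart) are excluded: their peak
    height carries the sibling's stacked stutter and every ratio they
    yield would be biased.
    """
    if table.sample_id != profile.sample_id:
        raise ValueError(
            f"peak table sample {table.sample_id!r} does not match profile "
            f"{profile.sample_id!r}"
        )
    obs: list[StutterObservation] = []
    for name, call in profile.calls.items():
        loc = panel.locus(name)
        if not loc.stutter_positions or not call.called_alleles:
            continue
        if truth is not None:
            true_labels = set(truth.calls.get(name, ()))
            true_sizes = [loc.find_bin(lab).nominal_size for lab in true_labels]
            parents = [a for a in call.called_alleles if a.allele_label in true_labels]
        else:
            true_sizes = [a.size for a in call.called_alleles]
            parents = list(call.called_alleles)
        dye_peaks = table.in_dye(loc.dye)
        for parent in parents:
            contaminated = any(
                abs(parent.size - s) > STUTTER_OFFSET_TOL_NT  # not the parent itself
                and any(
                    abs(s + loc.stutter_offset(p) - parent.size) <= STUTTER_OFFSET_TOL_NT
                    for p in loc.stutter_positions
                )
                for s in true_sizes
            )
            if contaminated:
                continue
            for pos in loc.stutter_positions:
                target = parent.size + loc.stutter_offset(pos)
                if any(abs(target - s) <= STUTTER_OFFSET_TOL_NT for s in true_sizes):
                    continue  # occupied by a true allele
                # ambiguous if the same position is a stutter offset of a
                # second true allele (e.g. plus stutter of one allele under
                # minus stutter of another): the peak is a stacked composite
                ambiguous = any(
                    (abs(s - parent.size) > STUTTER_OFFSET_TOL_NT or p2 != pos)
                    and abs(s + loc.stutter_offset(p2) - target) <= STUTTER_OFFSET_TOL_NT
                    for s in true_sizes
                    for p2 in loc.stutter_positions
                )
                if ambiguous:
                    continue
                hits = [
                    p for p in dye_peaks if abs(p.size - target) <= STUTTER_OFFSET_TOL_NT
                ]
                if not hits:
                    continue
                stutter = max(hits, key=lambda p: p.height)
                if stutter.height < thresholds.stutter_min_height:
                    continue
                obs.append(
                    StutterObservation(
                        locus=name,
                        position=pos,
                        parent_allele=parent.allele_label,
                        ratio_pct=stutter.height / parent.height * 100.0,
                        parent_height=parent.height,
                        stutter_height=stutter.height,
                    )
                )
    return obs


def summarize_stutter(obs: Iterable[StutterObservation]) -> list[StutterStatsRow]:
    """Per-(locus, position) summary: n, mean, min, max, sample SD (n−1).

    A single observation yields SD 0.  Groups with no observations are
    simply absent (callers see a logged note via :func:`filter_table_from_stats`
    when coverage matters).
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for o in obs:
        groups.setdefault((o.locus, o.position), []).append(o.ratio_pct)
    rows: list[StutterStatsRow] = []
    for (locus, pos), ratios in sorted(groups.items()):
        n = len(ratios)
        mean = sum(ratios) / n
        if n > 1:
            sd = sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1))
        else:
            sd = 0.0
        rows.append(
            StutterStatsRow(
                locus=locus, position=pos, n_obs=n,
                mean_pct=mean, min_pct=min(ratios), max_pct=max(ratios), sd_pct=sd,
            )
        )
    return rows


def filter_table_from_stats(
    rows: Sequence[StutterStatsRow],
    panel: PanelDefinition | None = None,
) -> StutterFilterTable:
    """Build a stutter filter table (unrounded mean + 3·SD per row).

    With a panel given, every (locus, position) the panel declares must be
    covered, else a configuration error lists the gaps.
    """
    table = {(r.locus, r.position): r.mean_plus_3sd_pct for r in rows}
    if panel is not None:
        missing = [
            f"{loc.name}/{pos}"
            for loc in panel.loci
            for pos in loc.stutter_positions
            if (loc.name, pos) not in table
        ]
        if missing:
            raise ValueError(
                "stutter stats do not cover panel positions: " + ", ".join(missing)
            )
    return StutterFilterTable(rows=table)


def stats_to_dataframe(rows: Sequence[StutterStatsRow], rounded: bool = True) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {
            "locus": r.locus,
            "position": r.position,
            "n": r.n_obs,
            "mean_pct": r.mean_pct,
            "min_pct": r.min_pct,
            "max_pct": r.max_pct,
            "sd_pct": r.sd_pct,
            "mean_plus_3sd_pct": r.mean_plus_3sd_pct,
        }
        if rounded:
            for k in ("mean_pct", "min_pct", "max_pct", "mean_plus_3sd_pct"):
                rec[k] = round_half_up(rec[k], 2)
            rec["sd_pct"] = round_half_up(rec["sd_pct"], 4)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def write_stats_csv(rows: Sequence[StutterStatsRow], path: str | Path) -> None:
    stats_to_dataframe(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bundled reference summary
# ---------------------------------------------------------------------------


def _reference_path():
    return resources.files("strvalid.data") / "stutter_reference.csv"


def reference_stutter_table() -> pd.DataFrame:
    """Raw bundled reference table including its printed mean+3SD column."""
    with resources.as_file(_reference_path()) as p:
        return pd.read_csv(p)


def reference_stutter_stats() -> list[StutterStatsRow]:
    """Reference per-locus stutter summary as StutterStatsRow objects."""
    df = reference_stutter_table()
    return [
        StutterStatsRow(
            locus=r.locus,
            position=r.position,
            n_obs=int(r.n_obs),
            mean_pct=float(r.mean_pct),
            min_pct=float(r.min_pct),
            max_pct=float(r.max_pct),
            sd_pct=float(r.sd_pct),
        )
        for r in df.itertuples()
    ]


def reference_filter_table(panel: PanelDefinition | None = None) -> StutterFilterTable:
    """Default stutter filters (mean + 3·SD) derived from the reference summary."""
    return filter_table_from_stats(reference_stutter_stats(), panel=panel)
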