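"""Allele calling: peak table → called profile under threshold, bin and stutter rules.

Calling is two-stage, matching how expert-system genotyping software is
applied in validation work:

1. :func:`call_alleles` — route every peak to a locus by dye channel and
   size, discard peaks outside the read region or below the analytical
   threshold (AT), designate in-bin peaks as called alleles and in-range
   out-of-bin peaks as off-ladder (OL).
2. :func:`apply_stutter_filter` — reclassify called peaks sitting at a
   stutter offset of a taller called parent when their percent ratio is at
   or below the per-(locus, position) filter value (conventionally the
   population mean stutter plus three standard deviations).

Two threshold presets are provided: ``casework_175`` (175 RFU allele-call
threshold) and ``stutter_study_150`` (150 RFU parents, 20 RFU minimum
stutter peak height) for stutter characterization runs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from strvalid.epg_sim import PeakTable
from strvalid.kit_panel import OFF_LADDER, PanelDefinition

log = logging.getLogger(__name__)

FILTER_REASONS = (
    "below_AT",
    "stutter_minus",
    "stutter_plus",
    "stutter_minus2nt",
    "outside_read_region",
)

_POSITION_TO_REASON = {
    "minus_repeat": "stutter_minus",
    "plus_repeat": "stutter_plus",
    "minus_2nt": "stutter_minus2nt",
}

#: size match tolerance when testing whether a peak sits at a stutter offset
STUTTER_OFFSET_TOL_NT = 0.5


@dataclass(frozen=True)
class CallThresholds:
    analytical_threshold: float = 175.0
    stutter_min_height: float = 20.0
    read_region_override: tuple[float, float] | None = None

    def __post_init__(self):
        if self.analytical_threshold <= 0:
            raise ValueError("analytical_threshold must be positive")
        if self.stutter_min_height < 0:
            raise ValueError("stutter_min_height must be >= 0")


#: 175 RFU allele-call threshold used for casework-style analysis.
CASEWORK_THRESHOLDS = CallThresholds(analytical_threshold=175.0, stutter_min_height=20.0)
#: 150 RFU parent / 20 RFU stutter minimum used in stutter characterization.
STUTTER_STUDY_THRESHOLDS = CallThresholds(analytical_threshold=150.0, stutter_min_height=20.0)

THRESHOLD_PRESETS = {
    "casework_175": CASEWORK_THRESHOLDS,
    "stutter_study_150": STUTTER_STUDY_THRESHOLDS,
}


@dataclass(frozen=True)
class CalledAllele:
    allele_label: str
    height: float
    size: float


@dataclass(frozen=True)
class LocusCall:
    locus: str
    called_alleles: tuple[CalledAllele, ...] = ()
    off_ladder_peaks: tuple[tuple[float, float], ...] = ()  # (size, height)
    filtered_peaks: tuple[tuple[float, float, str], ...] = ()  # (size, height, reason)

    @property
    def allele_labels(self) -> list[str]:
        return [a.allele_label for a in self.called_alleles]

    @property
    def n_peaks(self) -> int:
        return len(self.called_alleles) + len(self.off_ladder_peaks) + len(self.filtered_peaks)


@dataclass(frozen=True)
class Profile:
    sample_id: str
    calls: Mapping[str, LocusCall]
    thresholds_used: CallThresholds = CASEWORK_THRESHOLDS

    def locus_call(self, locus: str) -> LocusCall:
        return self.calls[locus]


class StutterFilterConfigError(ValueError):
    """A stutter filter table does not cover every required (locus, position)."""


@dataclass(frozen=True)
class StutterFilterTable:
    """Per-(locus, stutter position) percent filters."""

    rows: Mapping[tuple[str, str], float]

    def __post_init__(self):
        for k, v in self.rows.items():
            if v < 0:
                raise ValueError(f"negative filter percentage for {k}")

    def filter_pct(self, locus: str, position: str) -> float | None:
        return self.rows.get((locus, position))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["locus", "position", "filter_pct"])
            for (locus, pos), pct in sorted(self.rows.items()):
                w.writerow([locus, pos, f"{pct:.4f}"])

    @classmethod
    def read_csv(cls, path: str | Path) -> "StutterFilterTable":
        rows: dict[tuple[str, str], float] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"locus", "position", "filter_pct"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise ValueError(
                    f"{path}: missing required column(s): {', '.join(sorted(missing))}"
                )
            for row in reader:
                rows[(row["locus"], row["position"])] = float(row["filter_pct"])
        return cls(rows=rows)


def call_alleles(
    table: PeakTable,
    panel: PanelDefinition,
    thresholds: CallThresholds = CASEWORK_THRESHOLDS,
) -> Profile:
    """Call a peak table against a panel: bin matching + AT + read region.

    No stutter filtering happens here; every panel locus receives an entry
    (an empty one denotes locus dropout).  Peaks whose dye is absent from
    the panel raise; peaks claimed by no locus in their dye are dropped
    with a warning.
    """
    panel_dyes = {loc.dye for loc in panel.loci}
    read_region = thresholds.read_region_override or panel.read_region
    lo_rr, hi_rr = read_region

    called: dict[str, list[CalledAllele]] = {loc.name: [] for loc in panel.loci}
    off_ladder: dict[str, list[tuple[float, float]]] = {loc.name: [] for loc in panel.loci}
    filtered: dict[str, list[tuple[float, float, str]]] = {loc.name: [] for loc in panel.loci}

    for peak in table.peaks:
        if peak.dye not in panel_dyes:
            raise ValueError(
                f"sample {table.sample_id!r}: dye {peak.dye!r} not present in panel "
                f"{panel.kit_name!r}"
            )
        # locate the claiming locus within the dye channel
        locus_name = None
        in_bin = None
        for loc in panel.loci_in_dye(peak.dye):
            b = loc.bin_for(peak.size)
            if b is not None:
                locus_name, in_bin = loc.name, b
                break
        if locus_name is None:
            for loc in panel.loci_in_dye(peak.dye):
                lo, hi = loc.size_range
                if lo <= peak.size <= hi:
                    locus_name = loc.name
                    break
        if locus_name is None:
            log.warning(
                "sample %s: peak at %.2f nt (%s, %.0f RFU) claimed by no locus; dropped",
                table.sample_id, peak.size, peak.dye, peak.height,
            )
            continue
        if not (lo_rr <= peak.size <= hi_rr):
            filtered[locus_name].append((peak.size, peak.height, "outside_read_region"))
        elif peak.height < thresholds.analytical_threshold:
            filtered[locus_name].append((peak.size, peak.height, "below_AT"))
        elif in_bin is not None:
            called[locus_name].append(
                CalledAllele(allele_label=in_bin.allele_label, height=peak.height, size=peak.size)
            )
        else:
            off_ladder[locus_name].append((peak.size, peak.height))

    calls = {
        loc.name: LocusCall(
            locus=loc.name,
            called_alleles=tuple(called[loc.name]),
            off_ladder_peaks=tuple(off_ladder[loc.name]),
            filtered_peaks=tuple(filtered[loc.name]),
        )
        for loc in panel.loci
    }
    return Profile(sample_id=table.sample_id, calls=calls, thresholds_used=thresholds)


def apply_stutter_filter(
    profile: Profile,
    panel: PanelDefinition,
    filters: StutterFilterTable,
) -> Profile:
    """Reclassify called alleles that look like stutter of a taller called parent.

    A called allele ``c`` is filtered when some called parent ``p`` at the
    same locus has ``c`` at one of the locus's stutter offsets and
    ``height(c)/height(p) × 100`` is at or below the configured filter for
    that (locus, position).  Candidate parents are evaluated pre-filter
    (a peak that is itself filtered still parents others), taller first, so
    the operation is idempotent and single-pass.
    """
    missing = [
        loc.name
        for loc in panel.loci
        for pos in loc.stutter_positions
        if filters.filter_pct(loc.name, pos) is None
    ]
    if missing:
        raise StutterFilterConfigError(
            "stutter filter table missing loci: " + ", ".join(sorted(set(missing)))
        )

    new_calls: dict[str, LocusCall] = {}
    for name, call in profile.calls.items():
        loc = panel.locus(name)
        if not loc.stutter_positions or len(call.called_alleles) < 2:
            new_calls[name] = call
            continue
        pre_filter = sorted(call.called_alleles, key=lambda a: -a.height)
        kept: list[CalledAllele] = []
        newly_filtered: list[tuple[float, float, str]] = []
        for c in call.called_alleles:
            reason = None
            for p in pre_filter:  # taller candidates first
                if p is c or p.height <= 0:
                    continue
                for pos in loc.stutter_positions:
                    off = loc.stutter_offset(pos)
                    if abs((c.size - p.size) - off) > STUTTER_OFFSET_TOL_NT:
                        continue
                    ratio = c.height / p.height * 100.0
                    if ratio <= filters.filter_pct(name, pos):
                        reason = _POSITION_TO_REASON[pos]
                        break
                if reason:
                    break
            if reason:
                newly_filtered.append((c.size, c.height, reason))
            else:
                kept.append(c)
        new_calls[name] = replace(
            call,
            called_alleles=tuple(kept),
            filtered_peaks=call.filtered_peaks + tuple(newly_filtered),
        )
    return Profile(
        sample_id=profile.sample_id, calls=new_calls, thresholds_used=profile.thresholds_used
    )


def count_called_alleles(profile: Profile, loci_subset: Iterable[str] | None = None) -> int:
    """Distinct called allele labels summed over loci.

    A heterozygote contributes 2, a homozygote 1 (one merged peak, one
    label), a haploid Y locus 1, a dropped-out locus 0.
    """
    loci = set(loci_subset) if loci_subset is not None else None
    total = 0
    for name, call in profile.calls.items():
        if loci is not None and name not in loci:
            continue
        total += len(set(call.allele_labels))
    return total
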