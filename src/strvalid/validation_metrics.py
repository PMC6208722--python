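"""Validation statistics: balance ratios, recovery, sensitivity, mixtures, concordance.

Implements the summary statistics a developmental-validation study reports:

* intra-locus balance (ILB, the heterozygote peak-height ratio) and
  intra-color balance (ICB, min/max of diploidy-normalized locus heights
  within a dye channel);
* allele recovery against a known truth genotype (degradation, inhibition
  and casework-style scoring);
* per-locus sensitivity classification over a dilution series, with the
  60% heterozygote-ratio cutoff distinguishing balanced from imbalanced
  full calls;
* two-person mixture bookkeeping: minor-component mass at a given ratio and
  recovery of non-overlapping minor-contributor alleles;
* genotype concordance between kits/profiles and sex inference with
  Amelogenin-Y null redundancy (DYS391 / Y-indel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from strvalid.allele_call import LocusCall, Profile
from strvalid.epg_sim import Genotype
from strvalid.kit_panel import PanelDefinition
from strvalid.stutter_stats import round_half_up

#: Heterozygote peak-height ratio below which a full call counts as imbalanced.
LOW_HET_RATIO_PCT = 60.0


# ---------------------------------------------------------------------------
# Balance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BalanceReport:
    sample_id: str
    ilb_by_locus: Mapping[str, float]
    icb_by_dye: Mapping[str, float]
    excluded: tuple[tuple[str, str], ...]  # (locus, reason)


def heterozygote_balance(call: LocusCall) -> float | None:
    """ILB: lower allele height ÷ higher allele height × 100.

    Defined only when the locus has exactly two called alleles; homozygous,
    haploid and dropped-out loci return None.
    """
    if len(call.called_alleles) != 2:
        return None
    h1, h2 = (a.height for a in call.called_alleles)
    return 100.0 * min(h1, h2) / max(h1, h2)


def intra_color_balance(profile: Profile, panel: PanelDefinition) -> dict[str, float]:
    """ICB per dye: min/max of diploidy-normalized locus heights × 100.

    Heterozygous loci contribute the mean of their two peak heights,
    homozygous (single-peak) loci half their peak height.  Y-only loci and
    dropped-out loci are excluded; a dye with fewer than two contributing
    loci reports no value.
    """
    heights_by_dye: dict[str, list[float]] = {}
    for loc in panel.loci:
        if loc.is_y_only:
            continue
        call = profile.calls.get(loc.name)
        if call is None:
            continue
        h = _diploid_normalized_height(call)
        if h is None:
            continue
        heights_by_dye.setdefault(loc.dye, []).append(h)
    return {
        dye: 100.0 * min(hs) / max(hs)
        for dye, hs in heights_by_dye.items()
        if len(hs) >= 2
    }


def _diploid_normalized_height(call: LocusCall) -> float | None:
    n = len(call.called_alleles)
    if n == 2:
        return (call.called_alleles[0].height + call.called_alleles[1].height) / 2.0
    if n == 1:
        return call.called_alleles[0].height / 2.0
    return None


def balance_report(profile: Profile, panel: PanelDefinition) -> BalanceReport:
    """Full per-sample balance summary with exclusion provenance."""
    ilb: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for loc in panel.loci:
        call = profile.calls.get(loc.name)
        if loc.is_y_only:
            excluded.append((loc.name, "Y_locus"))
            continue
        if call is None or not call.called_alleles:
            excluded.append((loc.name, "dropout"))
            continue
        r = heterozygote_balance(call)
        if r is None:
            excluded.append((loc.name, "homozygote_for_ILB"))
        else:
            ilb[loc.name] = r
    return BalanceReport(
        sample_id=profile.sample_id,
        ilb_by_locus=ilb,
        icb_by_dye=intra_color_balance(profile, panel),
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    sample_id: str
    per_locus: Mapping[str, dict]
    total_expected: int
    total_recovered: int
    total_spurious: int

    @property
    def pct_recovered(self) -> float:
        if self.total_expected == 0:
            return 0.0
        return 100.0 * self.total_recovered / self.total_expected


def allele_recovery(profile: Profile, truth: Genotype) -> RecoveryReport:
    """Score called alleles against a truth genotype, locus by locus."""
    per_locus: dict[str, dict] = {}
    tot_exp = tot_rec = tot_spur = 0
    for locus, alleles in truth.calls.items():
        expected = set(alleles)
        call = profile.calls.get(locus)
        called = set(call.allele_labels) if call is not None else set()
        rec = len(expected & called)
        spur = len(called - expected)
        per_locus[locus] = {"expected": len(expected), "recovered": rec, "spurious": spur}
        tot_exp += len(expected)
        tot_rec += rec
        tot_spur += spur
    return RecoveryReport(
        sample_id=profile.sample_id,
        per_locus=per_locus,
        total_expected=tot_exp,
        total_recovered=tot_rec,
        total_spurious=tot_spur,
    )


def mean_allele_count(counts: Iterable[float], decimals: int = 1) -> float:
    """Replicate-averaged allele count, rounded half-up for display."""
    counts = list(counts)
    if not counts:
        raise ValueError("no counts to average")
    return round_half_up(sum(counts) / len(counts), decimals)


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

SENSITIVITY_CLASSES = (
    "full_het_balanced",
    "full_het_low_ratio",
    "partial_one_of_two",
    "dropout",
    "full_hom",
)


@dataclass(frozen=True)
class SensitivityCell:
    locus: str
    input_pg: float
    replicate: int
    cls: str


def sensitivity_grid(
    profiles: Sequence[tuple[float, int, Profile]],
    truth: Genotype,
) -> list[SensitivityCell]:
    """Classify every locus × input × replicate of a dilution series.

    Heterozygous loci: both alleles called → full (balanced if the
    heterozygote ratio is at least 60%, low-ratio otherwise); one of two →
    partial; none → dropout.  Homozygous/haploid loci: called → full_hom,
    else dropout.
    """
    cells: list[SensitivityCell] = []
    for input_pg, replicate, profile in profiles:
        for locus, alleles in truth.calls.items():
            expected = set(alleles)
            call = profile.calls.get(locus)
            called_true = [
                a for a in (call.called_alleles if call else ()) if a.allele_label in expected
            ]
            called_labels = {a.allele_label for a in called_true}
            if len(expected) == 2:
                if len(called_labels) == 2:
                    h = [a.height for a in called_true]
                    ratio = 100.0 * min(h) / max(h)
                    cls = "full_het_balanced" if ratio >= LOW_HET_RATIO_PCT else "full_het_low_ratio"
                elif len(called_labels) == 1:
                    cls = "partial_one_of_two"
                else:
                    cls = "dropout"
            else:
                cls = "full_hom" if called_labels else "dropout"
            cells.append(SensitivityCell(locus=locus, input_pg=input_pg, replicate=replicate, cls=cls))
    return cells


def sensitivity_to_dataframe(cells: Sequence[SensitivityCell]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {"locus": c.locus, "input_pg": c.input_pg, "replicate": c.replicate, "class": c.cls}
            for c in cells
        ]
    )


def dropout_fraction_by_input(cells: Sequence[SensitivityCell]) -> dict[float, float]:
    """Fraction of (locus, replicate) cells fully dropped out, per input mass."""
    df = sensitivity_to_dataframe(cells)
    frac = df.assign(dropout=df["class"] == "dropout").groupby("input_pg")["dropout"].mean()
    return {float(k): float(v) for k, v in frac.items()}


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureRecovery:
    ratio_label: str
    minor_mass_pg: float
    non_overlapping_possible: int
    non_overlapping_recovered: int
    missing: tuple[tuple[str, str], ...]  # (locus, allele)


def minor_component_mass(total_pg: float, ratio_minor: int, ratio_major: int) -> int:
    """Template mass of the minor contributor at a minor:major input ratio.

    E.g. 1 ng total at 1:5 → 167 pg; at 1:8 → 111 pg.
    """
    if ratio_minor <= 0 or ratio_major <= 0 or total_pg <= 0:
        raise ValueError("ratio parts and total mass must be positive")
    return int(round_half_up(total_pg * ratio_minor / (ratio_minor + ratio_major), 0))


def non_overlapping_minor_alleles(minor: Genotype, major: Genotype) -> list[tuple[str, str]]:
    """Minor-contributor alleles absent from the major genotype at the same locus."""
    out: list[tuple[str, str]] = []
    for locus, alleles in minor.calls.items():
        major_set = set(major.calls.get(locus, ()))
        for a in sorted(set(alleles), key=str):
            if a not in major_set:
                out.append((locus, a))
    return out


def minor_allele_recovery(
    profile: Profile,
    minor: Genotype,
    major: Genotype,
    ratio_label: str = "",
    minor_mass_pg: float = float("nan"),
) -> MixtureRecovery:
    """Count recovered non-overlapping minor alleles in a two-person mixture call."""
    possible = non_overlapping_minor_alleles(minor, major)
    missing: list[tuple[str, str]] = []
    recovered = 0
    for locus, allele in possible:
        call = profile.calls.get(locus)
        if call is not None and allele in call.allele_labels:
            recovered += 1
        else:
            missing.append((locus, allele))
    return MixtureRecovery(
        ratio_label=ratio_label,
        minor_mass_pg=minor_mass_pg,
        non_overlapping_possible=len(possible),
        non_overlapping_recovered=recovered,
        missing=tuple(missing),
    )


# ---------------------------------------------------------------------------
# Concordance and sex inference
# ---------------------------------------------------------------------------

ProfileOrGenotype = Union[Profile, Genotype]


@dataclass(frozen=True)
class ConcordanceResult:
    concordant: bool
    discordances: tuple[tuple[str, frozenset, frozenset], ...]


def _allele_set(x: ProfileOrGenotype, locus: str) -> frozenset[str]:
    if isinstance(x, Genotype):
        return frozenset(x.calls.get(locus, ()))
    call = x.calls.get(locus)
    return frozenset(call.allele_labels) if call is not None else frozenset()


def concordance(
    a: ProfileOrGenotype,
    b: ProfileOrGenotype,
    shared_loci: Iterable[str],
) -> ConcordanceResult:
    """Locus-by-locus genotype comparison; discordant iff allele label sets differ."""
    discordances = []
    for locus in shared_loci:
        sa, sb = _allele_set(a, locus), _allele_set(b, locus)
        if sa != sb:
            discordances.append((locus, sa, sb))
    return ConcordanceResult(concordant=not discordances, discordances=tuple(discordances))


def sex_inference(
    profile: ProfileOrGenotype,
    amel_locus: str = "AMEL",
    y_loci: tuple[str, ...] = ("DYS391", "Yindel"),
) -> str:
    """Infer donor sex with Amelogenin-Y null redundancy.

    AMEL X,Y → male; AMEL X-only with a called Y marker → male_amel_y_null
    (Y-chromosome deletion or primer-site variant at AMEL); AMEL X-only
    with no Y signal → female; no signal at AMEL or either Y marker →
    inconclusive.
    """
    amel = _allele_set(profile, amel_locus)
    y_called = any(_allele_set(profile, y) for y in y_loci)
    if "Y" in amel:
        return "male"
    if "X" in amel:
        return "male_amel_y_null" if y_called else "female"
    return "inconclusive"


# ---------------------------------------------------------------------------
# Bundled validation-study count tables
# ---------------------------------------------------------------------------


def _data(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("strvalid.data") / name) as p:
        return pd.read_csv(p)


def reference_degradation_counts() -> pd.DataFrame:
    """Replicate allele counts from a controlled-degradation study (DNase dosing)."""
    return _data("degradation_counts.csv")


def reference_mock_casework() -> pd.DataFrame:
    """Per-sample allele counts from a mock-casework sample set (two kit classes)."""
    return _data("mock_casework.csv")
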