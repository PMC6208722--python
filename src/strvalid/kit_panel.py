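"""Multiplex panel model: loci, dye channels, allelic-ladder bins, read region.

A panel is the static map every other stage consumes: which loci exist, in
which dye channel each is labelled, which allele bins (label + nominal size
in nucleotides) the allelic ladder defines, and the instrument read region
within which peaks are interpretable.  Two built-in fixtures ship with the
package: a three-locus toy panel for tests and a synthetic 24-locus six-dye
casework panel (21 autosomal STRs, Amelogenin, DYS391 and a Y-indel).  The
synthetic panel's bin coordinates are spaced by repeat unit inside plausible
marker size ranges; they are not any vendor's proprietary bin definitions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DYES = ("6-FAM", "VIC", "NED", "TAZ", "SID")
STUTTER_POSITIONS = ("minus_repeat", "plus_repeat", "minus_2nt")
CHROMOSOME_CLASSES = ("autosomal", "X/Y", "Y-only")

#: Sentinel returned by :func:`bin_for_size` for a peak in no defined bin.
OFF_LADDER = "OL"

DEFAULT_READ_REGION = (74.0, 444.0)
DEFAULT_HALF_WIDTH = 0.5


class PanelValidationError(ValueError):
    """Raised when a panel violates structural invariants; lists every rule broken."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "panel validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class PanelConfigError(ValueError):
    """Raised when a panel config file cannot be parsed into the schema."""


@dataclass(frozen=True)
class AlleleBin:
    """One allelic-ladder bin: a labelled size window on the electropherogram.

    Labels are text so microvariants ("9.3"), sex alleles ("X", "Y") and
    indel alleles ("1", "2") are represented uniformly.
    """

    allele_label: str
    nominal_size: float
    half_width: float = DEFAULT_HALF_WIDTH

    @property
    def lo(self) -> float:
        return self.nominal_size - self.half_width

    @property
    def hi(self) -> float:
        return self.nominal_size + self.half_width

    def contains(self, size: float) -> bool:
        return self.lo <= size <= self.hi


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    dye: str
    repeat_unit_nt: int  # 0 sentinel for non-repeat loci (AMEL, Y-indel)
    chromosome_class: str
    bins: tuple[AlleleBin, ...]
    stutter_positions: tuple[str, ...] = ()

    @property
    def is_y_only(self) -> bool:
        return self.chromosome_class == "Y-only"

    @property
    def size_range(self) -> tuple[float, float]:
        """Min/max bin edges, extended by one repeat unit each side.

        This is the locus's claim region for off-ladder assignment: a peak
        here that matches no bin is reported as OL at this locus.
        """
        lo = min(b.lo for b in self.bins)
        hi = max(b.hi for b in self.bins)
        pad = float(self.repeat_unit_nt) if self.repeat_unit_nt else 2.0
        return lo - pad, hi + pad

    def bin_for(self, size: float) -> AlleleBin | None:
        for b in self.bins:
            if b.contains(size):
                return b
        return None

    def find_bin(self, label: str) -> AlleleBin:
        for b in self.bins:
            if b.allele_label == label:
                return b
        raise KeyError(f"allele {label!r} not defined at locus {self.name}")

    def stutter_offset(self, position: str) -> float:
        if position == "minus_repeat":
            return -float(self.repeat_unit_nt)
        if position == "plus_repeat":
            return float(self.repeat_unit_nt)
        if position == "minus_2nt":
            return -2.0
        raise ValueError(f"unknown stutter position {position!r}")


@dataclass(frozen=True)
class PanelDefinition:
    kit_name: str
    loci: tuple[LocusDefinition, ...]
    read_region: tuple[float, float] = DEFAULT_READ_REGION
    dye_order: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.dye_order:
            seen: list[str] = []
            for loc in self.loci:
                if loc.dye not in seen:
                    seen.append(loc.dye)
            object.__setattr__(self, "dye_order", tuple(seen))

    def locus(self, name: str) -> LocusDefinition:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"unknown locus {name!r} in panel {self.kit_name!r}")

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def loci_in_dye(self, dye: str) -> list[LocusDefinition]:
        return [loc for loc in self.loci if loc.dye == dye]

    def autosomal_loci(self) -> list[str]:
        return [loc.name for loc in self.loci if loc.chromosome_class == "autosomal"]

    def validate(self) -> None:
        """Check every structural invariant, collecting all violations."""
        errs: list[str] = []
        names = [loc.name for loc in self.loci]
        for n in set(names):
            if names.count(n) > 1:
                errs.append(f"duplicate locus name {n!r}")
        lo_rr, hi_rr = self.read_region
        if not lo_rr < hi_rr:
            errs.append(f"read_region lower bound {lo_rr} not below upper {hi_rr}")
        for loc in self.loci:
            if loc.dye not in DYES:
                errs.append(f"{loc.name}: unknown dye {loc.dye!r}")
            if loc.chromosome_class not in CHROMOSOME_CLASSES:
                errs.append(f"{loc.name}: unknown chromosome_class {loc.chromosome_class!r}")
            if not loc.bins:
                errs.append(f"{loc.name}: no bins defined")
            if loc.repeat_unit_nt < 0:
                errs.append(f"{loc.name}: negative repeat unit")
            if loc.repeat_unit_nt == 0 and loc.stutter_positions:
                errs.append(f"{loc.name}: stutter positions declared for non-repeat locus")
            for pos in loc.stutter_positions:
                if pos not in STUTTER_POSITIONS:
                    errs.append(f"{loc.name}: unknown stutter position {pos!r}")
            labels = [b.allele_label for b in loc.bins]
            for lab in set(labels):
                if labels.count(lab) > 1:
                    errs.append(f"{loc.name}: duplicate allele label {lab!r}")
            for b in loc.bins:
                if b.nominal_size <= 0:
                    errs.append(f"{loc.name} allele {b.allele_label}: non-positive size")
                if b.half_width <= 0:
                    errs.append(f"{loc.name} allele {b.allele_label}: non-positive half_width")
                if not (lo_rr <= b.nominal_size <= hi_rr):
                    errs.append(
                        f"{loc.name} allele {b.allele_label}: nominal size "
                        f"{b.nominal_size} outside read region [{lo_rr}, {hi_rr}]"
                    )
            ordered = sorted(loc.bins, key=lambda b: b.nominal_size)
            for a, b in zip(ordered, ordered[1:]):
                # touching interval edges are tolerated (1-nt-apart microvariants)
                if b.lo < a.hi:
                    errs.append(
                        f"{loc.name}: bins {a.allele_label!r} and {b.allele_label!r} overlap"
                    )
        used_dyes = {loc.dye for loc in self.loci}
        for dye in self.dye_order:
            if dye not in used_dyes:
                errs.append(f"dye {dye!r} in dye_order used by no locus")
        if errs:
            raise PanelValidationError(errs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kit_name": self.kit_name,
            "read_region": list(self.read_region),
            "dye_order": list(self.dye_order),
            "loci": [
                {
                    "name": loc.name,
                    "dye": loc.dye,
                    "repeat_unit_nt": loc.repeat_unit_nt,
                    "chromosome_class": loc.chromosome_class,
                    "stutter_positions": list(loc.stutter_positions),
                    "bins": [
                        {
                            "allele_label": b.allele_label,
                            "nominal_size": b.nominal_size,
                            "half_width": b.half_width,
                        }
                        for b in loc.bins
                    ],
                }
                for loc in self.loci
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDefinition":
        try:
            loci = tuple(
                LocusDefinition(
                    name=str(ld["name"]),
                    dye=str(ld["dye"]),
                    repeat_unit_nt=int(ld["repeat_unit_nt"]),
                    chromosome_class=str(ld["chromosome_class"]),
                    stutter_positions=tuple(ld.get("stutter_positions", ())),
                    bins=tuple(
                        AlleleBin(
                            allele_label=str(bd["allele_label"]),
                            nominal_size=float(bd["nominal_size"]),
                            half_width=float(bd.get("half_width", DEFAULT_HALF_WIDTH)),
                        )
                        for bd in ld["bins"]
                    ),
                )
                for ld in d["loci"]
            )
            panel = cls(
                kit_name=str(d["kit_name"]),
                loci=loci,
                read_region=tuple(float(x) for x in d.get("read_region", DEFAULT_READ_REGION)),
                dye_order=tuple(d.get("dye_order", ())),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PanelConfigError(f"panel schema error: {exc!r}") from exc
        panel.validate()
        return panel

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    def export_bin_table(self, path: str | Path) -> None:
        """Write the flat bin table (locus, dye, allele, nominal_size, half_width)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["locus", "dye", "allele", "nominal_size", "half_width"])
            for loc in self.loci:
                for b in loc.bins:
                    w.writerow([loc.name, loc.dye, b.allele_label, b.nominal_size, b.half_width])


def load_panel(path: str | Path) -> PanelDefinition:
    """Load and validate a panel from a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise PanelConfigError(f"panel file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise PanelConfigError(f"cannot parse panel file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise PanelConfigError(f"panel file {path} does not contain a mapping")
    return PanelDefinition.from_dict(d)


def bin_for_size(panel: PanelDefinition, locus: str, size: float) -> AlleleBin | str:
    """Map a size to the unique containing bin at a locus, else ``OFF_LADDER``.

    Sizes outside the panel read region are always off-ladder; bin
    disjointness within a locus guarantees at most one match.
    """
    loc = panel.locus(locus)
    lo, hi = panel.read_region
    if not (lo <= size <= hi):
        return OFF_LADDER
    b = loc.bin_for(size)
    return b if b is not None else OFF_LADDER


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------


def _allele_offset_nt(label: str, repeat: int) -> float:
    """Nt offset of an allele label from the locus's minimal integer allele.

    A microvariant label "9.3" denotes 9 full repeats plus 3 nt.
    """
    if "." in label:
        whole, frac = label.split(".")
        return int(whole) * repeat + int(frac)
    return int(label) * repeat


def _str_locus(
    name: str,
    dye: str,
    repeat: int,
    alleles: list[str],
    anchor_size: float,
    chromosome_class: str = "autosomal",
    stutter_positions: tuple[str, ...] = ("minus_repeat",),
) -> LocusDefinition:
    """Build an STR locus whose bins are spaced by repeat unit from an anchor.

    ``anchor_size`` is the nominal size of the smallest integer allele in
    ``alleles``; every other allele sits at its repeat-count offset.
    """
    base_allele = min(int(a.split(".")[0]) for a in alleles)
    base_off = base_allele * repeat
    bins = tuple(
        AlleleBin(a, anchor_size + _allele_offset_nt(a, repeat) - base_off) for a in alleles
    )
    return LocusDefinition(
        name=name,
        dye=dye,
        repeat_unit_nt=repeat,
        chromosome_class=chromosome_class,
        bins=bins,
        stutter_positions=stutter_positions,
    )


def _int_range(lo: int, hi: int) -> list[str]:
    return [str(a) for a in range(lo, hi + 1)]


def _full_panel() -> PanelDefinition:
    """Synthetic 24-locus, five-sample-dye casework panel.

    Locus set, dye layout, repeat units and stutter-position declarations
    follow a contemporary 6-dye casework multiplex (21 autosomal STRs,
    Amelogenin, DYS391, Y-indel; trimeric D22S1045; −2 nt stutter at SE33
    and D1S1656; plus-stutter at D22S1045).  Bin coordinates are synthetic.
    """
    loci = [
        # 6-FAM
        _str_locus("D3S1358", "6-FAM", 4, _int_range(12, 19), 80.0),
        _str_locus("vWA", "6-FAM", 4, _int_range(11, 21), 120.0),
        _str_locus("D16S539", "6-FAM", 4, _int_range(5, 15), 175.0),
        _str_locus("CSF1PO", "6-FAM", 4, _int_range(6, 15), 230.0),
        _str_locus("TPOX", "6-FAM", 4, _int_range(6, 13), 290.0),
        # VIC
        LocusDefinition(
            "AMEL", "VIC", 0, "X/Y",
            (AlleleBin("X", 80.0), AlleleBin("Y", 86.0)),
        ),
        _str_locus("DYS391", "VIC", 4, _int_range(7, 13), 100.0,
                   chromosome_class="Y-only"),
        _str_locus("D8S1179", "VIC", 4, _int_range(8, 19), 140.0),
        _str_locus("D21S11", "VIC", 4, _int_range(24, 38) + ["31.2"], 200.0),
        _str_locus("D18S51", "VIC", 4, _int_range(7, 27), 270.0),
        LocusDefinition(
            "Yindel", "VIC", 0, "Y-only",
            (AlleleBin("1", 370.0), AlleleBin("2", 376.0)),
        ),
        # NED
        _str_locus("D2S441", "NED", 4, _int_range(8, 17) + ["11.3"], 80.0),
        _str_locus("D19S433", "NED", 4, _int_range(6, 20) + ["14.2"], 130.0),
        _str_locus("TH01", "NED", 4, _int_range(4, 11) + ["9.3"], 200.0),
        _str_locus("FGA", "NED", 4, _int_range(17, 30) + ["26.2"], 250.0),
        # TAZ
        _str_locus("D22S1045", "TAZ", 3, _int_range(8, 19), 80.0,
                   stutter_positions=("minus_repeat", "plus_repeat")),
        _str_locus("D5S818", "TAZ", 4, _int_range(7, 16), 130.0),
        _str_locus("D13S317", "TAZ", 4, _int_range(5, 16), 180.0),
        _str_locus("D7S820", "TAZ", 4, _int_range(6, 14), 240.0),
        _str_locus("SE33", "TAZ", 4, _int_range(12, 39) + ["25.2", "27.2"], 290.0,
                   stutter_positions=("minus_repeat", "minus_2nt")),
        # SID
        _str_locus("D10S1248", "SID", 4, _int_range(8, 18), 80.0),
        _str_locus("D1S1656", "SID", 4, _int_range(9, 20) + ["17.3"], 140.0,
                   stutter_positions=("minus_repeat", "minus_2nt")),
        _str_locus("D12S391", "SID", 4, _int_range(14, 27), 200.0),
        _str_locus("D2S1338", "SID", 4, _int_range(15, 28), 280.0),
    ]
    panel = PanelDefinition(
        kit_name="SynthPlex-24",
        loci=tuple(loci),
        read_region=DEFAULT_READ_REGION,
        dye_order=DYES,
    )
    panel.validate()
    return panel


def _toy_panel() -> PanelDefinition:
    loci = (
        _str_locus("TOYA", "6-FAM", 4, _int_range(6, 12), 90.0),
        _str_locus("TOYB", "6-FAM", 4, _int_range(10, 18), 160.0),
        _str_locus("TOYC", "VIC", 3, _int_range(8, 16), 100.0,
                   stutter_positions=("minus_repeat", "plus_repeat")),
    )
    panel = PanelDefinition(
        kit_name="Toy-3",
        loci=loci,
        read_region=DEFAULT_READ_REGION,
        dye_order=("6-FAM", "VIC"),
    )
    panel.validate()
    return panel


def builtin_panel(name: str = "full") -> PanelDefinition:
    """Return a built-in panel fixture: ``"full"`` (24 loci) or ``"toy"`` (3 loci)."""
    if name in ("full", "synthplex-24"):
        return _full_panel()
    if name in ("toy", "toy-3"):
        return _toy_panel()
    raise KeyError(f"unknown built-in panel {name!r} (choose 'full' or 'toy')")
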