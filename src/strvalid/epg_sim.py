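"""Stochastic electropherogram simulator for STR multiplex validation studies.

Generates peak tables (dye, size in nt, height in RFU) with the statistical
structure a developmental validation exercises:

* per-allele expected height proportional to template mass, attenuated by a
  single-exponential degradation decay in amplicon size and a global
  inhibition efficiency factor;
* realized heights log-normal around the expectation with a configurable
  coefficient of variation (heterozygote imbalance emerges from the two
  independent draws — no separate imbalance parameter);
* minus/plus-repeat and −2 nt stutter peaks whose percent ratio is drawn
  from a per-(locus, position) truncated normal;
* two-person (or n-person) mixtures at fixed total input with shared-allele
  peaks stacking and stutter generated from the summed parents;
* dilution series and Hardy–Weinberg population sampling from an allele
  frequency table.

Every sampled quantity is reproducible from one master seed; per-sample
streams are derived by seeding a generator with (master, sample index) so
adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from strvalid.kit_panel import PanelDefinition

#: Ground-truth origin tags carried by simulated peaks.
ORIGIN_TAGS = ("allele", "stutter_minus", "stutter_plus", "stutter_minus2nt", "noise")

_POSITION_TO_TAG = {
    "minus_repeat": "stutter_minus",
    "plus_repeat": "stutter_plus",
    "minus_2nt": "stutter_minus2nt",
}

#: Fallback stutter magnitudes (percent) for panels without reference rows.
_GENERIC_STUTTER = {
    "minus_repeat": (7.0, 1.5),
    "plus_repeat": (4.3, 0.8),
    "minus_2nt": (1.6, 0.3),
}

#: nt below which two same-dye peaks merge into one (heights summed).
MERGE_TOLERANCE_NT = 0.5


@dataclass(frozen=True)
class Genotype:
    """Called alleles per locus for one donor.

    ``calls`` maps locus name to a tuple of allele labels: two for diploid
    loci (identical pair = homozygote), one for haploid Y loci.
    """

    sample_id: str
    calls: Mapping[str, tuple[str, ...]]

    def alleles(self, locus: str) -> tuple[str, ...]:
        return tuple(self.calls[locus])

    def distinct_alleles(self, locus: str) -> frozenset[str]:
        return frozenset(self.calls[locus])


@dataclass(frozen=True)
class Peak:
    dye: str
    size: float
    height: float
    origin_tag: str = "allele"


@dataclass(frozen=True)
class PeakTable:
    sample_id: str
    peaks: tuple[Peak, ...]
    params_used: "SimParams | str" = "import"
    seed: int | None = None

    def in_dye(self, dye: str) -> list[Peak]:
        return [p for p in self.peaks if p.dye == dye]


@dataclass(frozen=True)
class SimParams:
    """Tunable generator parameters.

    total_input
        Template mass in pg (1000 pg = 1 ng, the standard reaction input).
    height_per_allele_at_1ng
        Expected RFU of one allele copy's peak at 1 ng input, no
        degradation, no inhibition.
    cv_height
        Coefficient of variation of the log-normal per-allele height draw.
    degradation_k
        Per-nt exponential decay rate of template availability with
        amplicon size (0 = intact DNA).
    inhibition_factor
        Global multiplicative amplification efficiency in (0, 1].
    stutter_mean_pct / stutter_sd_pct
        Percent-of-parent stutter magnitude per (locus, position); positions
        absent from the maps fall back to generic class defaults.
    """

    total_input: float = 1000.0
    height_per_allele_at_1ng: float = 2000.0
    cv_height: float = 0.15
    degradation_k: float = 0.0
    inhibition_factor: float = 1.0
    stutter_mean_pct: Mapping[tuple[str, str], float] = field(default_factory=dict)
    stutter_sd_pct: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dropout_height_floor: float = 50.0
    saturation_limit: float = 30000.0
    analytical_noise_floor: float = 20.0

    def __post_init__(self):
        if self.total_input <= 0:
            raise ValueError("total_input must be positive")
        if self.cv_height < 0:
            raise ValueError("cv_height must be >= 0")
        if self.degradation_k < 0:
            raise ValueError("degradation_k must be >= 0")
        if not (0 < self.inhibition_factor <= 1):
            raise ValueError("inhibition_factor must be in (0, 1]")
        if self.saturation_limit <= self.analytical_noise_floor:
            raise ValueError("saturation_limit must exceed the noise floor")
        for m in (self.stutter_mean_pct, self.stutter_sd_pct):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"negative stutter percentage for {k}")

    def stutter_params(self, locus: str, position: str) -> tuple[float, float]:
        mean = self.stutter_mean_pct.get((locus, position))
        sd = self.stutter_sd_pct.get((locus, position))
        gmean, gsd = _GENERIC_STUTTER[position]
        return (gmean if mean is None else mean, gsd if sd is None else sd)

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def default_sim_params(panel: PanelDefinition | None = None, **overrides) -> SimParams:
    """SimParams whose stutter magnitudes come from the bundled reference table.

    For loci without a reference row the generic per-position defaults apply.
    """
    from strvalid.stutter_stats import reference_stutter_stats

    means: dict[tuple[str, str], float] = {}
    sds: dict[tuple[str, str], float] = {}
    known = set(panel.locus_names) if panel is not None else None
    for row in reference_stutter_stats():
        if known is not None and row.locus not in known:
            continue
        means[(row.locus, row.position)] = row.mean_pct
        sds[(row.locus, row.position)] = row.sd_pct
    return SimParams(stutter_mean_pct=means, stutter_sd_pct=sds, **overrides)


# ---------------------------------------------------------------------------
# Seeding policy
# ---------------------------------------------------------------------------


def _rng_for(master_seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator for a sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def sample_genotype(
    freqs: "FrequencyTable",
    sex: str,
    seed: int,
    panel: PanelDefinition | None = None,
    sample_id: str = "sim",
) -> Genotype:
    """Draw one genotype under Hardy–Weinberg equilibrium.

    Autosomal loci draw two alleles independently from the locus's allele
    frequencies; AMEL is fixed by ``sex``; Y loci are drawn haploid for
    males and omitted for females.
    """
    from strvalid.popgen import FrequencyTable  # noqa: F401  (typing only)

    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = _rng_for(seed)
    calls: dict[str, tuple[str, ...]] = {}
    for locus, table in freqs.per_locus.items():
        cls = None
        if panel is not None:
            try:
                cls = panel.locus(locus).chromosome_class
            except KeyError:
                cls = None
        if cls is None:
            cls = "Y-only" if locus in ("DYS391", "Yindel") else (
                "X/Y" if locus == "AMEL" else "autosomal"
            )
        labels = list(table.keys())
        p = np.asarray([table[a] for a in labels], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies at {locus} sum to {p.sum()}, not 1")
        p = p / p.sum()
        if cls == "X/Y":
            calls[locus] = ("X", "X") if sex == "female" else ("X", "Y")
        elif cls == "Y-only":
            if sex == "male":
                calls[locus] = (labels[rng.choice(len(labels), p=p)],)
        else:
            i, j = rng.choice(len(labels), size=2, p=p)
            a, b = labels[i], labels[j]
            calls[locus] = tuple(sorted((a, b), key=_allele_sort_key))
    return Genotype(sample_id=sample_id, calls=calls)


def _allele_sort_key(label: str):
    try:
        return (0, float(label), "")
    except ValueError:
        return (1, 0.0, label)


# ---------------------------------------------------------------------------
# Profile simulation
# ---------------------------------------------------------------------------


def _expected_height(params: SimParams, size: float, scale: float = 1.0) -> float:
    return (
        params.height_per_allele_at_1ng
        * (params.total_input / 1000.0)
        * scale
        * params.inhibition_factor
        * np.exp(-params.degradation_k * size)
    )


def _draw_height(rng: np.random.Generator, expected: float, cv: float) -> float:
    """Log-normal draw with mean ``expected`` and coefficient of variation ``cv``."""
    if expected <= 0:
        return 0.0
    if cv == 0:
        return expected
    sigma2 = np.log1p(cv * cv)
    mu = np.log(expected) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


def _draw_stutter_pct(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal stutter percentage truncated at zero (rejection sampling)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def _allele_peaks(
    genotype: Genotype,
    panel: PanelDefinition,
    params: SimParams,
    rng: np.random.Generator,
    scale: float,
) -> list[Peak]:
    peaks: list[Peak] = []
    for locus, alleles in genotype.calls.items():
        loc = panel.locus(locus)  # raises KeyError for unknown loci
        for label in alleles:
            size = loc.find_bin(label).nominal_size
            e = _expected_height(params, size, scale)
            h = _draw_height(rng, e, params.cv_height)
            if h > 0:
                peaks.append(Peak(dye=loc.dye, size=size, height=h, origin_tag="allele"))
    return peaks


def _merge_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Sum same-dye peaks closer than the merge tolerance; keep the taller tag."""
    merged: list[Peak] = []
    by_dye: dict[str, list[Peak]] = {}
    for p in peaks:
        by_dye.setdefault(p.dye, []).append(p)
    for dye in sorted(by_dye):
        group = sorted(by_dye[dye], key=lambda p: p.size)
        cluster: list[Peak] = []
        for p in group:
            if cluster and p.size - cluster[-1].size < MERGE_TOLERANCE_NT:
                cluster.append(p)
            else:
                if cluster:
                    merged.append(_collapse(cluster))
                cluster = [p]
        if cluster:
            merged.append(_collapse(cluster))
    return merged


def _collapse(cluster: list[Peak]) -> Peak:
    if len(cluster) == 1:
        return cluster[0]
    tallest = max(cluster, key=lambda p: p.height)
    return Peak(
        dye=tallest.dye,
        size=tallest.size,
        height=sum(p.height for p in cluster),
        origin_tag=tallest.origin_tag,
    )


def _add_stutter(
    allele_peaks: list[Peak],
    panel: PanelDefinition,
    params: SimParams,
    rng: np.random.Generator,
) -> list[Peak]:
    """Spawn stutter peaks from (already merged) parent allele peaks."""
    out: list[Peak] = []
    locus_of: dict[tuple[str, float], str] = {}
    for loc in panel.loci:
        for b in loc.bins:
            locus_of[(loc.dye, b.nominal_size)] = loc.name
    for p in allele_peaks:
        locus = locus_of.get((p.dye, p.size))
        if locus is None:
            continue
        loc = panel.locus(locus)
        for position in loc.stutter_positions:
            mean, sd = params.stutter_params(locus, position)
            pct = _draw_stutter_pct(rng, mean, sd)
            h = p.height * pct / 100.0
            if h <= 0:
                continue
            out.append(
                Peak(
                    dye=p.dye,
                    size=p.size + loc.stutter_offset(position),
                    height=h,
                    origin_tag=_POSITION_TO_TAG[position],
                )
            )
    return out


def _finalize(
    sample_id: str,
    raw: list[Peak],
    params: SimParams,
    seed: int | None,
) -> PeakTable:
    capped = [
        Peak(p.dye, p.size, min(p.height, params.saturation_limit), p.origin_tag) for p in raw
    ]
    kept = [p for p in capped if p.height >= params.analytical_noise_floor]
    kept.sort(key=lambda p: (p.dye, p.size))
    return PeakTable(sample_id=sample_id, peaks=tuple(kept), params_used=params, seed=seed)


def simulate_mixture(
    genotypes: Sequence[Genotype],
    mass_fractions: Sequence[float],
    total_input: float,
    panel: PanelDefinition,
    params: SimParams,
    seed: int,
    sample_id: str | None = None,
) -> PeakTable:
    """Simulate a multi-contributor profile at fixed total template mass.

    Each contributor's expected allele heights scale with its mass fraction;
    shared-allele peaks stack (heights sum) and stutter is generated from
    the summed parent peaks.
    """
    if len(genotypes) != len(mass_fractions):
        raise ValueError("genotypes and mass_fractions must have equal length")
    if abs(sum(mass_fractions) - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {sum(mass_fractions)}, not 1")
    params = params.with_(total_input=total_input)
    rng = _rng_for(seed)
    allele_peaks: list[Peak] = []
    for frac, g in zip(mass_fractions, genotypes):
        if frac == 0:
            continue
        allele_peaks.extend(_allele_peaks(g, panel, params, rng, scale=frac))
    merged_alleles = _merge_peaks(allele_peaks)
    stutter = _add_stutter(merged_alleles, panel, params, rng)
    raw = _merge_peaks(merged_alleles + stutter)
    if sample_id is None:
        sample_id = "+".join(g.sample_id for g in genotypes)
    return _finalize(sample_id, raw, params, seed)


def simulate_profile(
    genotype: Genotype,
    panel: PanelDefinition,
    params: SimParams,
    seed: int,
) -> PeakTable:
    """Simulate a single-source profile (degenerate one-contributor mixture)."""
    return simulate_mixture(
        [genotype], [1.0], params.total_input, panel, params, seed,
        sample_id=genotype.sample_id,
    )


DEFAULT_DILUTION_LADDER_PG = (1000.0, 500.0, 250.0, 125.0, 62.5, 31.2, 15.6)


def simulate_dilution_series(
    genotype: Genotype,
    panel: PanelDefinition,
    inputs: Sequence[float] | None = None,
    replicates: int = 4,
    params: SimParams | None = None,
    seed: int = 0,
) -> list[tuple[float, int, PeakTable]]:
    """Simulate a sensitivity dilution series.

    Returns (input_pg, replicate_index, PeakTable) triples over the default
    seven-point input ladder (1000 → 15.6 pg) with four replicates, matching
    the standard sensitivity study design.  Per-table seeds derive
    deterministically from the master seed.
    """
    if inputs is None:
        inputs = DEFAULT_DILUTION_LADDER_PG
    if any(x <= 0 for x in inputs):
        raise ValueError("all inputs must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if params is None:
        params = default_sim_params(panel)
    out: list[tuple[float, int, PeakTable]] = []
    for i, pg in enumerate(inputs):
        for r in range(replicates):
            sub_seed = int(
                _rng_for(seed, i, r).integers(0, 2**31 - 1)
            )
            table = simulate_mixture(
                [genotype], [1.0], float(pg), panel, params, sub_seed,
                sample_id=f"{genotype.sample_id}_in{pg:g}_r{r}",
            )
            out.append((float(pg), r, table))
    return out


def simulate_population(
    freqs: "FrequencyTable",
    n: int,
    panel: PanelDefinition,
    params: SimParams | None = None,
    seed: int = 0,
    male_fraction: float = 0.5,
) -> list[tuple[Genotype, PeakTable]]:
    """Draw ``n`` genotypes under HWE and render each to a peak table.

    Drives population-scale studies (stutter characterization, color
    balance, allele-frequency recovery) at desk scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = default_sim_params(panel)
    out: list[tuple[Genotype, PeakTable]] = []
    for i in range(n):
        rng = _rng_for(seed, i)
        sex = "male" if rng.random() < male_fraction else "female"
        g_seed = int(rng.integers(0, 2**31 - 1))
        p_seed = int(rng.integers(0, 2**31 - 1))
        g = sample_genotype(freqs, sex, g_seed, panel=panel, sample_id=f"pop{i:05d}")
        table = simulate_profile(g, panel, params, p_seed)
        out.append((g, table))
    return out


# ---------------------------------------------------------------------------
# CSV round-trips (peak tables)
# ---------------------------------------------------------------------------


def write_peak_table(table: PeakTable, path: str | Path, origin_tags: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["sample_id", "dye", "size_nt", "height_rfu"]
        if origin_tags:
            header.append("origin_tag")
        w.writerow(header)
        for p in table.peaks:
            row = [table.sample_id, p.dye, f"{p.size:.3f}", f"{p.height:.3f}"]
            if origin_tags:
                row.append(p.origin_tag)
            w.writerow(row)


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak-table CSV (GeneMapper-style export or a simulator dump)."""
    path = Path(path)
    peaks: list[Peak] = []
    sample_id = path.stem
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "dye", "size_nt", "height_rfu"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                peaks.append(
                    Peak(
                        dye=row["dye"],
                        size=float(row["size_nt"]),
                        height=float(row["height_rfu"]),
                        origin_tag=row.get("origin_tag") or "allele",
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            sample_id = row["sample_id"] or sample_id
    peaks.sort(key=lambda p: (p.dye, p.size))
    return PeakTable(sample_id=sample_id, peaks=tuple(peaks), params_used="import")
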