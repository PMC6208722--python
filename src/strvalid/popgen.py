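"""Allele frequencies and Probability of Identity (PI).

PI at one locus is the probability that two individuals drawn at random
share a genotype.  Under Hardy–Weinberg equilibrium it is the sum of
squared genotype frequencies,

    PI = Σᵢ pᵢ⁴ + Σ_{i<j} (2 pᵢ pⱼ)²,

and per-locus values multiply across independent loci into a combined PI.
An alternative estimator based on observed genotype frequencies (the sum of
squared observed genotype proportions) is exposed for sensitivity analysis.
Y-chromosome markers are haploid and excluded from PI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from math import prod
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from strvalid.epg_sim import Genotype, _allele_sort_key
from strvalid.kit_panel import PanelDefinition

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyTable:
    population_label: str
    per_locus: Mapping[str, Mapping[str, float]]
    n_samples: int

    def __post_init__(self):
        for locus, freqs in self.per_locus.items():
            if not freqs:
                raise ValueError(f"no alleles at locus {locus}")
            total = sum(freqs.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"frequencies at {locus} sum to {total!r}, not 1")
            for a, p in freqs.items():
                if not (0 < p <= 1):
                    raise ValueError(f"frequency of {locus}:{a} outside (0, 1]: {p}")

    def loci(self) -> list[str]:
        return list(self.per_locus.keys())

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["population", "locus", "allele", "frequency", "n"])
            for locus, freqs in self.per_locus.items():
                for allele, p in freqs.items():
                    w.writerow([self.population_label, locus, allele, repr(p), self.n_samples])

    @classmethod
    def read_csv(cls, path: str | Path) -> "FrequencyTable":
        per_locus: dict[str, dict[str, float]] = {}
        label, n = "", 0
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"population", "locus", "allele", "frequency", "n"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise ValueError(
                    f"{path}: missing required column(s): {', '.join(sorted(missing))}"
                )
            for row in reader:
                label = row["population"]
                n = int(row["n"])
                per_locus.setdefault(row["locus"], {})[row["allele"]] = float(row["frequency"])
        return cls(population_label=label, per_locus=per_locus, n_samples=n)


@dataclass(frozen=True)
class PIResult:
    per_locus_pi: Mapping[str, float]
    combined_pi: float
    loci_used: tuple[str, ...]


def allele_frequencies(
    genotypes: Sequence[Genotype],
    panel: PanelDefinition | None = None,
    population_label: str = "simulated",
) -> FrequencyTable:
    """Count-based allele frequencies from a genotype collection.

    Diploid loci contribute two observations per sample (a homozygote's
    allele is counted twice), haploid Y loci one; loci are taken from the
    genotypes themselves (or restricted to the panel when given).
    """
    if not genotypes:
        raise ValueError("no genotypes supplied")
    allowed = set(panel.locus_names) if panel is not None else None
    counts: dict[str, dict[str, int]] = {}
    for g in genotypes:
        for locus, alleles in g.calls.items():
            if allowed is not None and locus not in allowed:
                continue
            c = counts.setdefault(locus, {})
            for a in alleles:
                c[a] = c.get(a, 0) + 1
    per_locus = {
        locus: {
            a: c[a] / total
            for a in sorted(c, key=_allele_sort_key)
        }
        for locus, c in counts.items()
        for total in [sum(c.values())]
    }
    return FrequencyTable(
        population_label=population_label, per_locus=per_locus, n_samples=len(genotypes)
    )


def locus_pi(freqs: Mapping[str, float]) -> float:
    """HWE Probability of Identity at one locus: Σpᵢ⁴ + Σ_{i<j}(2pᵢpⱼ)²."""
    p = list(freqs.values())
    total = sum(p)
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {total!r}, not 1")
    hom = sum(x**4 for x in p)
    het = sum((2 * a * b) ** 2 for a, b in combinations(p, 2))
    return hom + het


def observed_match_probability(genotypes: Sequence[Genotype], locus: str) -> float:
    """Empirical match probability: sum of squared observed genotype proportions."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    counts: dict[frozenset, int] = {}
    n = 0
    for g in genotypes:
        if locus not in g.calls:
            continue
        key = frozenset(g.calls[locus])
        counts[key] = counts.get(key, 0) + 1
        n += 1
    if n == 0:
        raise ValueError(f"no genotypes carry locus {locus!r}")
    return sum((c / n) ** 2 for c in counts.values())


def combined_pi(
    table: FrequencyTable,
    loci: Iterable[str] | None = None,
    panel: PanelDefinition | None = None,
) -> PIResult:
    """Product of per-locus PI over autosomal loci.

    Y-only loci are rejected (haploid markers have no HWE genotype
    distribution and are conventionally excluded from combined PI).
    """
    if loci is None:
        if panel is not None:
            loci = [l for l in panel.autosomal_loci() if l in table.per_locus]
        else:
            loci = [l for l in table.loci() if l not in ("DYS391", "Yindel", "AMEL")]
    loci = list(loci)
    y_names = (
        {loc.name for loc in panel.loci if loc.is_y_only}
        if panel is not None
        else {"DYS391", "Yindel"}
    )
    bad = [l for l in loci if l in y_names]
    if bad:
        raise ValueError(
            f"Y-specific loci are excluded from probability-of-identity: {', '.join(bad)}"
        )
    per = {l: locus_pi(table.per_locus[l]) for l in loci}
    # multiply in canonical locus order so the result is permutation-invariant
    combined = prod(per[l] for l in sorted(per))
    return PIResult(per_locus_pi=per, combined_pi=combined, loci_used=tuple(loci))


def format_pi(value: float) -> str:
    """Scientific notation to 3 significant figures, e.g. '3.71e-26'."""
    return f"{value:.2e}"


# ---------------------------------------------------------------------------
# Synthetic frequency fixture
# ---------------------------------------------------------------------------


def synthetic_frequency_table(
    panel: PanelDefinition,
    seed: int = 0,
    concentration: float = 4.0,
    population_label: str = "synthetic",
) -> FrequencyTable:
    """Deterministic synthetic allele frequencies over a panel's ladder bins.

    Each STR locus gets a unimodal frequency profile (heavier mass on
    mid-range alleles, as real STR loci show) perturbed by a seeded
    Dirichlet draw; AMEL is fixed at X/Y = 0.5 each and Y loci get a
    Dirichlet over their bins.  Intended as the sampling distribution for
    simulated population studies when no empirical table is supplied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    per_locus: dict[str, dict[str, float]] = {}
    for loc in panel.loci:
        labels = [b.allele_label for b in loc.bins]
        k = len(labels)
        if loc.chromosome_class == "X/Y":
            per_locus[loc.name] = {"X": 0.5, "Y": 0.5}
            continue
        center = (k - 1) / 2.0
        shape = np.exp(-0.5 * ((np.arange(k) - center) / max(k / 4.0, 1.0)) ** 2)
        alpha = concentration * shape / shape.sum() * k
        p = rng.dirichlet(alpha)
        p = np.maximum(p, 1e-4)
        p = p / p.sum()
        per_locus[loc.name] = {lab: float(x) for lab, x in zip(labels, p)}
    return FrequencyTable(
        population_label=population_label, per_locus=per_locus, n_samples=0
    )
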