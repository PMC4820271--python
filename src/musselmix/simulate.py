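"""Simulation of multilocus genotypes of known ancestry.

Six genotypic classes are simulated from parental allele-frequency
tables: the two purebreds (ME, MT), their F1 and F2 hybrids, and the two
first-generation backcrosses.  Gametes assume Hardy-Weinberg proportions
within each parental taxon and free recombination between the (unlinked)
loci, so an F1 parent transmits, independently at each locus, an
ME-drawn or an MT-drawn allele with probability 1/2 each.

Calibration samples mix the six classes in the standard proportions
80:80:10:10:10:10 (N = 200; 40% each purebred, 20% assorted hybrids),
mimicking field samples of roughly equal parental ancestry with limited
interbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .genotypes import AlleleRegistry, GenotypeTable, build_registry

__all__ = ["AncestryClass", "ParentalFrequencies", "LabeledCohort",
           "draw_gamete", "simulate_class", "compose_mixture",
           "DEFAULT_MIXTURE_COUNTS"]


class AncestryClass(str, Enum):
    ME = "ME"
    MT = "MT"
    F1 = "F1"
    F2 = "F2"
    BC_ME = "BC_ME"
    BC_MT = "BC_MT"

    @property
    def compound(self) -> str:
        """Three-way compound class: ME, MT or HYBRID."""
        return self.value if self in (AncestryClass.ME, AncestryClass.MT) else "HYBRID"

    @property
    def mt_fraction(self) -> float:
        """Expected genome fraction of MT ancestry."""
        return {"ME": 0.0, "MT": 1.0, "F1": 0.5, "F2": 0.5,
                "BC_ME": 0.25, "BC_MT": 0.75}[self.value]


#: the standard calibration-sample composition (N = 200)
DEFAULT_MIXTURE_COUNTS = {
    AncestryClass.ME: 80, AncestryClass.MT: 80, AncestryClass.F1: 10,
    AncestryClass.F2: 10, AncestryClass.BC_ME: 10, AncestryClass.BC_MT: 10,
}


@dataclass
class ParentalFrequencies:
    """Per-locus allele labels with frequency vectors in each parental taxon."""

    loci: list[str]
    alleles: dict[str, list[str]]                 # locus -> labels
    freq_me: dict[str, np.ndarray]                # locus -> frequencies
    freq_mt: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for locus in self.loci:
            for name, tab in (("ME", self.freq_me), ("MT", self.freq_mt)):
                f = np.asarray(tab[locus], dtype=float)
                if abs(f.sum() - 1.0) > 1e-6:
                    raise ValueError(
                        f"{name} frequencies at {locus} sum to {f.sum()}, not 1")
                tab[locus] = f

    def registry(self) -> AlleleRegistry:
        me = {l: dict(zip(self.alleles[l], self.freq_me[l])) for l in self.loci}
        mt = {l: dict(zip(self.alleles[l], self.freq_mt[l])) for l in self.loci}
        return build_registry(me, mt)

    @classmethod
    def from_registry(cls, registry: AlleleRegistry) -> "ParentalFrequencies":
        """Rebuild frequency tables from a registry that retains its full
        per-allele reference data."""
        if registry.ref_alleles_me is None or registry.ref_alleles_mt is None:
            raise ValueError("registry lacks full per-allele reference tables")
        loci = registry.loci
        alleles, fme, fmt = {}, {}, {}
        for l in loci:
            labs = sorted(set(registry.ref_alleles_me[l]) |
                          set(registry.ref_alleles_mt[l]))
            alleles[l] = labs
            fme[l] = np.array([registry.ref_alleles_me[l].get(a, 0.0) for a in labs])
            fmt[l] = np.array([registry.ref_alleles_mt[l].get(a, 0.0) for a in labs])
        return cls(loci, alleles, fme, fmt)

    @classmethod
    def diagnostic(cls, loci=("Est-D", "Gpi", "Pgm", "Odh")) -> "ParentalFrequencies":
        """Fully diagnostic references: each taxon fixed for its own allele."""
        loci = list(loci)
        return cls(
            loci,
            {l: ["100", "110"] for l in loci},
            {l: np.array([1.0, 0.0]) for l in loci},
            {l: np.array([0.0, 1.0]) for l in loci},
        )


@dataclass
class LabeledCohort:
    """Simulated genotypes with immutable true ancestry labels."""

    table: GenotypeTable
    labels: pd.Series = field(repr=False)  # AncestryClass per individual
    freqs: ParentalFrequencies = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.table.individuals.index):
            raise ValueError("labels must be indexed like the genotype table")

    def __len__(self) -> int:
        return len(self.table)

    def write(self, outdir) -> None:
        """Write the cohort as Genepop plus a labels TSV
        (id, true_class, seed)."""
        from pathlib import Path

        from .io import write_genepop

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(self.table, outdir / "genotypes.gen",
                      title="simulated cohort")
        labels = pd.DataFrame({"id": self.labels.index,
                               "true_class": [c.value for c in self.labels],
                               "seed": self.seed})
        labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    @property
    def compound_labels(self) -> pd.Series:
        out = self.labels.map(lambda c: AncestryClass(c).compound)
        out.name = "compound"
        return out

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()


def draw_gamete(class_parent: AncestryClass, freqs: ParentalFrequencies,
                rng: np.random.Generator) -> list[str]:
    """One gamete (one allele per locus) from a parent of the given class.

    ME/MT parents transmit alleles drawn from their taxon's frequencies;
    an F1 parent transmits, independently per locus (free recombination),
    an ME-frequency draw or an MT-frequency draw with probability 1/2.
    """
    out = []
    for locus in freqs.loci:
        if class_parent is AncestryClass.F1:
            tab = freqs.freq_me if rng.random() < 0.5 else freqs.freq_mt
        elif class_parent is AncestryClass.ME:
            tab = freqs.freq_me
        elif class_parent is AncestryClass.MT:
            tab = freqs.freq_mt
        else:
            raise ValueError(f"no gamete model for parent class {class_parent}")
        labels = freqs.alleles[locus]
        out.append(labels[rng.choice(len(labels), p=tab[locus])])
    return out


_PARENTS = {
    AncestryClass.ME: (AncestryClass.ME, AncestryClass.ME),
    AncestryClass.MT: (AncestryClass.MT, AncestryClass.MT),
    AncestryClass.F1: (AncestryClass.ME, AncestryClass.MT),
    AncestryClass.F2: (AncestryClass.F1, AncestryClass.F1),
    AncestryClass.BC_ME: (AncestryClass.F1, AncestryClass.ME),
    AncestryClass.BC_MT: (AncestryClass.F1, AncestryClass.MT),
}


def _simulate_genotypes(cls: AncestryClass, n: int, freqs: ParentalFrequencies,
                        rng: np.random.Generator) -> np.ndarray:
    """Vectorised genotype draws: (n, L, 2) allele-label array."""
    L = len(freqs.loci)
    out = np.empty((n, L, 2), dtype=object)
    for c, parent in enumerate(_PARENTS[cls]):
        for j, locus in enumerate(freqs.loci):
            labels = np.asarray(freqs.alleles[locus], dtype=object)
            if parent is AncestryClass.F1:
                pick_mt = rng.random(n) < 0.5
                a = np.empty(n, dtype=np.int64)
                a[~pick_mt] = rng.choice(len(labels), size=int((~pick_mt).sum()),
                                         p=freqs.freq_me[locus])
                a[pick_mt] = rng.choice(len(labels), size=int(pick_mt.sum()),
                                        p=freqs.freq_mt[locus])
            else:
                tab = freqs.freq_me if parent is AncestryClass.ME else freqs.freq_mt
                a = rng.choice(len(labels), size=n, p=tab[locus])
            out[:, j, c] = labels[a]
    return out


def simulate_class(cls: AncestryClass, n: int, freqs: ParentalFrequencies,
                   rng: np.random.Generator | int,
                   sample: str = "sim", id_prefix: str | None = None) -> LabeledCohort:
    """Simulate *n* individuals of one ancestry class."""
    cls = AncestryClass(cls)
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    alleles = _simulate_genotypes(cls, n, freqs, rng)
    prefix = id_prefix or cls.value
    ids = [f"{prefix}_{i + 1}" for i in range(n)]
    indiv = pd.DataFrame({"sample": sample, "site": sample, "substrate": "unknown"},
                         index=pd.Index(ids, name="id"))
    table = GenotypeTable(list(freqs.loci), indiv, alleles)
    labels = pd.Series([cls] * n, index=indiv.index, name="true_class")
    return LabeledCohort(table, labels, freqs, int(seed))


def compose_mixture(freqs: ParentalFrequencies,
                    counts: dict | None = None,
                    rng: np.random.Generator | int = 0,
                    sample: str = "mix") -> LabeledCohort:
    """Compose a mixed calibration sample with exact class counts
    (default 80:80:10:10:10:10), order shuffled."""
    counts = DEFAULT_MIXTURE_COUNTS if counts is None else {
        AncestryClass(k): v for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    parts_alleles, parts_labels = [], []
    for cls, n in counts.items():
        if n == 0:
            continue
        cohort = simulate_class(cls, n, freqs, rng, sample=sample,
                                id_prefix=f"{sample}_{cls.value}")
        parts_alleles.append(cohort.table.alleles)
        parts_labels.append(cohort.labels)
    if not parts_alleles:
        raise ValueError("empty mixture")
    alleles = np.concatenate(parts_alleles, axis=0)
    labels = pd.concat(parts_labels)
    order = rng.permutation(len(labels))
    alleles = alleles[order]
    labels = labels.iloc[order]
    indiv = pd.DataFrame({"sample": sample, "site": sample, "substrate": "unknown"},
                         index=labels.index)
    table = GenotypeTable(list(freqs.loci), indiv, alleles)
    return LabeledCohort(table, labels, freqs, int(seed))
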