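"""Genotype data model, compound-allele pooling and hybrid-index computation.

The White Sea contact zone between the blue mussels *Mytilus edulis* (ME)
and *M. trossulus* (MT) is scored at a handful of partially diagnostic
co-dominant loci (classically the allozymes Est-D, Gpi, Pgm and Odh).
Alleles at each locus are pooled into two compound categories: a T-allele
(more frequent in MT reference populations) and an E-allele (more frequent
in ME).  Each individual is then summarised by its T-score — the number of
T-alleles summed over the scored loci, 0..8 for four complete diploid
loci — and each sample by its T-frequency, the per-locus compound T-allele
frequency rescaled between the two parental reference frequencies and
averaged over loci.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical locus names of the allozyme panel
DEFAULT_LOCI = ("Est-D", "Gpi", "Pgm", "Odh")

SUBSTRATES = ("algae", "bottom", "unknown")


class UnresolvableAlleleError(ValueError):
    """An observed allele has no pooling assignment in the registry."""


@dataclass
class GenotypeTable:
    """Individuals x loci co-dominant genotypes with sample metadata.

    Parameters
    ----------
    loci
        Locus names, length L >= 1.
    individuals
        DataFrame indexed by individual id with columns ``sample``,
        ``site`` and ``substrate`` (one of :data:`SUBSTRATES`).
    alleles
        Object array of shape (n, L, 2); each cell holds an allele label
        (string) or ``None`` for a missing genotype.  Both copies of a
        genotype are missing together — a half-called genotype is invalid.
    """

    loci: list[str]
    individuals: pd.DataFrame
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        if len(self.loci) < 1:
            raise ValueError("at least one locus is required")
        n = len(self.individuals)
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        for col, default in (("sample", "pop_1"), ("site", "site_1"), ("substrate", "unknown")):
            if col not in self.individuals.columns:
                self.individuals[col] = default
        bad = set(self.individuals["substrate"]) - set(SUBSTRATES)
        if bad:
            raise ValueError(f"unknown substrate labels: {sorted(bad)}")
        half = (self.alleles[..., 0] == None) ^ (self.alleles[..., 1] == None)  # noqa: E711
        if half.any():
            raise ValueError("half-missing genotype cells are not allowed")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list:
        return list(self.individuals.index)

    @property
    def samples(self) -> list:
        """Sample labels in order of first appearance."""
        return list(dict.fromkeys(self.individuals["sample"]))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of missing genotype cells."""
        return self.alleles[..., 0] == None  # noqa: E711

    def observed_alleles(self, locus: str) -> set:
        """Distinct allele labels observed at *locus*."""
        j = self.loci.index(locus)
        vals = self.alleles[:, j, :].ravel()
        return {v for v in vals if v is not None}

    def subset(self, ids: Iterable) -> "GenotypeTable":
        ids = list(ids)
        pos = [self.individuals.index.get_loc(i) for i in ids]
        return GenotypeTable(self.loci, self.individuals.loc[ids].copy(), self.alleles[pos])

    def by_sample(self) -> dict:
        """Mapping sample label -> GenotypeTable restricted to that sample."""
        return {
            s: self.subset(self.individuals.index[self.individuals["sample"] == s])
            for s in self.samples
        }

    @classmethod
    def from_records(
        cls,
        loci: Sequence[str],
        records: Iterable[tuple],
    ) -> "GenotypeTable":
        """Build from an iterable of (id, sample, site, substrate, genotypes)
        where *genotypes* is a sequence of (a1, a2) pairs or None per locus."""
        ids, meta, rows = [], [], []
        for rec in records:
            iid, sample, site, substrate, genos = rec
            ids.append(iid)
            meta.append((sample, site, substrate))
            row = []
            for g in genos:
                row.append((None, None) if g is None else (str(g[0]), str(g[1])))
            rows.append(row)
        arr = np.empty((len(ids), len(loci), 2), dtype=object)
        for i, row in enumerate(rows):
            for j, (a1, a2) in enumerate(row):
                arr[i, j, 0], arr[i, j, 1] = a1, a2
        indiv = pd.DataFrame(meta, index=pd.Index(ids, name="id"),
                             columns=["sample", "site", "substrate"])
        if indiv.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        return cls(list(loci), indiv, arr)


@dataclass
class AlleleRegistry:
    """Per-locus allele -> {E, T} pooling map plus parental reference
    compound T-frequencies.

    ``ref_t`` is a DataFrame indexed by locus with columns ``ME`` and
    ``MT`` giving the compound T-allele frequency in each pure reference
    taxon.  Loci are partially diagnostic: MT reference > ME reference.
    """

    pooling: dict[str, dict[str, str]]
    ref_t: pd.DataFrame
    #: full per-allele reference frequency tables (locus -> allele -> freq),
    #: kept when the registry was built from complete reference data; they
    #: allow simulating parental genotypes without re-estimating frequencies
    ref_alleles_me: dict | None = field(default=None, repr=False)
    ref_alleles_mt: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for locus, amap in self.pooling.items():
            bad = set(amap.values()) - {"E", "T"}
            if bad:
                raise ValueError(f"invalid pooling codes at {locus}: {bad}")
        if not {"ME", "MT"} <= set(self.ref_t.columns):
            raise ValueError("ref_t needs ME and MT columns")
        nondiag = self.ref_t["MT"] <= self.ref_t["ME"]
        if nondiag.any():
            raise ValueError(
                "reference T-frequency of MT must exceed that of ME at every "
                f"locus; violated at {list(self.ref_t.index[nondiag])}"
            )

    @property
    def loci(self) -> list[str]:
        return list(self.ref_t.index)

    def dosage(self, locus: str, genotype: tuple) -> int:
        """T-allele count (0..2) of one genotype pair at *locus*."""
        amap = self.pooling[locus]
        total = 0
        for a in genotype:
            if a not in amap:
                raise UnresolvableAlleleError(
                    f"allele {a!r} at locus {locus} has no pooling assignment"
                )
            total += amap[a] == "T"
        return total


def build_registry(
    ref_me_freqs: Mapping[str, Mapping[str, float]],
    ref_mt_freqs: Mapping[str, Mapping[str, float]],
    atol: float = 1e-6,
) -> AlleleRegistry:
    """Pool alleles into compound E/T categories from two parental
    reference allele-frequency tables.

    An allele is pooled to T when its frequency in the MT reference
    strictly exceeds that in the ME reference, otherwise to E; an exact
    tie goes to E with a warning (conservative toward the resident taxon).
    The compound reference T-frequency of each taxon is the sum of its
    T-pooled allele frequencies.
    """
    if set(ref_me_freqs) != set(ref_mt_freqs):
        raise ValueError("reference tables cover different loci")
    pooling: dict[str, dict[str, str]] = {}
    rows = {}
    for locus in ref_me_freqs:
        me = dict(ref_me_freqs[locus])
        mt = dict(ref_mt_freqs[locus])
        for name, tab in (("ME", me), ("MT", mt)):
            s = sum(tab.values())
            if abs(s - 1.0) > atol:
                raise ValueError(f"{name} frequencies at {locus} sum to {s}, not 1")
        amap = {}
        for allele in set(me) | set(mt):
            f_me, f_mt = me.get(allele, 0.0), mt.get(allele, 0.0)
            if f_mt > f_me:
                amap[allele] = "T"
            else:
                if f_mt == f_me:
                    warnings.warn(
                        f"allele {allele!r} at {locus} has equal reference "
                        "frequencies; pooled to E"
                    )
                amap[allele] = "E"
        pooling[locus] = amap
        t_me = sum(me.get(a, 0.0) for a, c in amap.items() if c == "T")
        t_mt = sum(mt.get(a, 0.0) for a, c in amap.items() if c == "T")
        rows[locus] = (t_me, t_mt)
    ref_t = pd.DataFrame.from_dict(rows, orient="index", columns=["ME", "MT"])
    ref_t.index.name = "locus"
    return AlleleRegistry(pooling, ref_t,
                          {l: dict(v) for l, v in ref_me_freqs.items()},
                          {l: dict(v) for l, v in ref_mt_freqs.items()})


@dataclass
class PooledTable:
    """Individuals x loci T-allele dosages in {0, 1, 2} with NaN missing."""

    loci: list[str]
    individuals: pd.DataFrame
    dosage: np.ndarray  # float (n, L), NaN = missing
    registry: AlleleRegistry | None = field(default=None, repr=False)
    source: GenotypeTable | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.individuals)

    def subset(self, ids: Iterable) -> "PooledTable":
        ids = list(ids)
        pos = [self.individuals.index.get_loc(i) for i in ids]
        return PooledTable(self.loci, self.individuals.loc[ids].copy(),
                           self.dosage[pos], self.registry, self.source)

    def by_sample(self) -> dict:
        samples = dict.fromkeys(self.individuals["sample"])
        return {
            s: self.subset(self.individuals.index[self.individuals["sample"] == s])
            for s in samples
        }

    def t_freq_observed(self) -> pd.Series:
        """Per-locus observed compound T-allele frequency (raw, unscaled)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            n_obs = np.sum(~np.isnan(self.dosage), axis=0)
            tot = np.nansum(self.dosage, axis=0)
            freq = np.where(n_obs > 0, tot / (2 * np.maximum(n_obs, 1)), np.nan)
        return pd.Series(freq, index=self.loci, name="t_freq")


def pooled_from_dosages(dosages: np.ndarray, loci: Sequence[str] | None = None,
                        registry: AlleleRegistry | None = None,
                        sample: str = "sample_1") -> PooledTable:
    """Wrap a raw (n, L) T-dosage matrix as a :class:`PooledTable`
    (useful for simulated dosage data with no underlying raw genotypes)."""
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise ValueError("dosages must be 2-D (individuals x loci)")
    loci = list(loci) if loci is not None else [f"L{j + 1}" for j in range(d.shape[1])]
    ids = pd.Index([f"ind_{i + 1}" for i in range(d.shape[0])], name="id")
    indiv = pd.DataFrame({"sample": sample, "site": sample, "substrate": "unknown"},
                         index=ids)
    return PooledTable(loci, indiv, d, registry)


def pool(table: GenotypeTable, registry: AlleleRegistry) -> PooledTable:
    """Collapse raw genotypes to compound T-allele dosages.

    Raises :class:`UnresolvableAlleleError` if any observed allele is not
    covered by the registry — alleles are never silently dropped.
    """
    missing_loci = [l for l in table.loci if l not in registry.pooling]
    if missing_loci:
        raise UnresolvableAlleleError(f"registry lacks loci {missing_loci}")
    n, L = len(table), len(table.loci)
    out = np.full((n, L), np.nan)
    miss = table.missing_mask()
    for j, locus in enumerate(table.loci):
        for i in range(n):
            if miss[i, j]:
                continue
            out[i, j] = registry.dosage(locus, tuple(table.alleles[i, j]))
    return PooledTable(table.loci, table.individuals.copy(), out, registry, table)


def t_score(pooled: PooledTable) -> pd.DataFrame:
    """Per-individual hybrid index: T-alleles summed over scored loci.

    Returns a DataFrame indexed by individual id with integer columns
    ``t_score`` and ``n_loci_scored`` and a boolean ``scorable`` flag
    (False when every locus is missing; such individuals carry no score).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scored = np.sum(~np.isnan(pooled.dosage), axis=1)
        total = np.nansum(pooled.dosage, axis=1)
    df = pd.DataFrame(
        {
            "t_score": total.astype(int),
            "n_loci_scored": scored.astype(int),
            "scorable": scored > 0,
        },
        index=pooled.individuals.index,
    )
    if (~df["scorable"]).any():
        logger.warning("%d individual(s) unscorable (all loci missing)",
                       int((~df["scorable"]).sum()))
    return df


def t_frequency(sample: PooledTable, registry: AlleleRegistry | None = None) -> float:
    """Sample-level hybrid index on the 0..1 scale.

    Per locus the observed compound T-frequency is linearly rescaled
    between the two parental references, ``(f_obs - f_ME) / (f_MT - f_ME)``,
    clipped into [0, 1]; the rescaled values are averaged over loci
    (scale-then-average).  Loci with coincident references are excluded
    with a warning.
    """
    registry = registry or sample.registry
    obs = sample.t_freq_observed()
    vals = []
    for locus in sample.loci:
        f_me, f_mt = registry.ref_t.loc[locus, "ME"], registry.ref_t.loc[locus, "MT"]
        if f_mt == f_me:
            warnings.warn(f"locus {locus} has coincident references; excluded")
            continue
        f_obs = obs[locus]
        if np.isnan(f_obs):
            continue
        x = (f_obs - f_me) / (f_mt - f_me)
        if x < 0 or x > 1:
            logger.info("t_frequency at %s outside reference span (%.3f); clipped", locus, x)
        vals.append(min(1.0, max(0.0, x)))
    if not vals:
        raise ValueError("no locus with usable data for t_frequency")
    return float(np.mean(vals))


def allele_frequencies(table: GenotypeTable,
                       registry: AlleleRegistry | None = None) -> pd.DataFrame:
    """Per-locus raw allele frequencies over non-missing genotypes.

    Returns a tidy DataFrame with columns locus, allele, count, freq and —
    when a registry is supplied — the pooled class of each allele.  Loci
    with no scored individuals are omitted.
    """
    rows = []
    miss = table.missing_mask()
    for j, locus in enumerate(table.loci):
        vals = table.alleles[~miss[:, j], j, :].ravel()
        if vals.size == 0:
            continue
        labels, counts = np.unique(vals.astype(str), return_counts=True)
        tot = counts.sum()
        for a, c in zip(labels, counts):
            pooled_cls = registry.pooling[locus].get(a) if registry else None
            rows.append((locus, a, int(c), c / tot, pooled_cls))
    return pd.DataFrame(rows, columns=["locus", "allele", "count", "freq", "pooled"])
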