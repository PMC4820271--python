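"""Synthetic study generator.

Produces a complete, fully labelled stand-in for a White Sea hybrid-zone
survey — genotypes at four partially diagnostic loci for sites spanning
an ancestry gradient, ancestry-linked shell morphology (Z-index),
substrate assignment and quadrat count tables — so that every stage of
the analysis pipeline can be exercised and scored against known truth
without any field data.

Default conditions (all overridable in :class:`StudyConfig`):

* four loci with compound T-allele reference frequencies
  Est-D (ME 0.05, MT 0.95), Gpi (0.02, 0.97), Pgm (0.10, 0.85),
  Odh (0.05, 0.90) — per-locus differentials 0.90/0.95/0.75/0.85, within
  the 70-95% range characteristic of this allozyme panel; each locus
  carries one T-pooled and two E-pooled alleles;
* 31 sites along a linear MT-ancestry gradient from 0.02 to 0.93, ~48
  mussels each;
* a hybrid fraction of 0.20 at maximally mixed sites, attenuated by
  4s(1-s) toward pure sites (s = site MT ancestry), split equally over
  F1/F2/BC_ME/BC_MT;
* morphotype emission P(T-morph) = 0.03 for pure ME, 0.80 for pure MT,
  linear in the MT genome fraction in between (a synthetic-only model);
* shell length lognormal, ME mean 20% greater than MT (30 vs 25 mm),
  CV 0.3;
* substrate assignment P(algae) = 0.30 for ME rising linearly to 0.70
  for MT;
* six quadrats per site: three 16 x 16 cm bottom cores, three weighed
  algal tufts from 50 x 50 cm frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeTable
from .io import write_genepop
from .simulate import AncestryClass, LabeledCohort, ParentalFrequencies, simulate_class

__all__ = ["StudyConfig", "StudyBundle", "default_parental_frequencies",
           "generate_study", "truth_manifest"]

#: frozen per-locus compound reference T-frequencies (ME, MT)
DEFAULT_REF_T = {
    "Est-D": (0.05, 0.95),
    "Gpi": (0.02, 0.97),
    "Pgm": (0.10, 0.85),
    "Odh": (0.05, 0.90),
}


def default_parental_frequencies() -> ParentalFrequencies:
    """Three alleles per locus: one T-pooled ("090") carrying the compound
    T-frequency, the E mass split 70:30 over "100" and "110"."""
    loci = list(DEFAULT_REF_T)
    alleles = {l: ["090", "100", "110"] for l in loci}
    fme, fmt = {}, {}
    for l, (t_me, t_mt) in DEFAULT_REF_T.items():
        fme[l] = np.array([t_me, 0.7 * (1 - t_me), 0.3 * (1 - t_me)])
        fmt[l] = np.array([t_mt, 0.7 * (1 - t_mt), 0.3 * (1 - t_mt)])
    return ParentalFrequencies(loci, alleles, fme, fmt)


@dataclass
class StudyConfig:
    """Conditions of the synthetic study; fully determines the output
    together with ``seed``."""

    freqs: ParentalFrequencies = field(default_factory=default_parental_frequencies)
    n_sites: int = 31
    site_ancestry: np.ndarray | None = None   # target MT ancestry per site
    n_per_site: int = 48
    hybrid_fraction: float = 0.20             # at maximally mixed sites
    p_t_morph_mt: float = 0.80
    p_t_morph_me: float = 0.03
    shell_mean_me: float = 30.0               # mm; 20% greater than MT
    shell_mean_mt: float = 25.0
    shell_cv: float = 0.3
    p_algae_me: float = 0.30
    p_algae_mt: float = 0.70
    quadrats_per_substrate: int = 3
    mean_density: float = 200.0               # mussels / m^2, site-level scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_ancestry is None:
            self.site_ancestry = np.linspace(0.02, 0.93, self.n_sites)
        self.site_ancestry = np.asarray(self.site_ancestry, dtype=float)
        self.n_sites = len(self.site_ancestry)
        probs = [self.hybrid_fraction, self.p_t_morph_mt, self.p_t_morph_me,
                 self.p_algae_me, self.p_algae_mt]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "loci": {l: {"alleles": list(self.freqs.alleles[l]),
                         "freq_me": [float(x) for x in self.freqs.freq_me[l]],
                         "freq_mt": [float(x) for x in self.freqs.freq_mt[l]]}
                     for l in self.freqs.loci},
            "site_ancestry": [float(s) for s in self.site_ancestry],
            "n_per_site": self.n_per_site,
            "hybrid_fraction": self.hybrid_fraction,
            "p_t_morph": {"MT": self.p_t_morph_mt, "ME": self.p_t_morph_me},
            "shell": {"mean_me": self.shell_mean_me, "mean_mt": self.shell_mean_mt,
                      "cv": self.shell_cv},
            "p_algae": {"ME": self.p_algae_me, "MT": self.p_algae_mt},
            "quadrats_per_substrate": self.quadrats_per_substrate,
            "mean_density": self.mean_density,
            "seed": self.seed,
        }


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    genotypes: GenotypeTable
    truth: pd.DataFrame
    shells: pd.DataFrame
    quadrats: pd.DataFrame
    config: StudyConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(self.genotypes, outdir / "genotypes.gen",
                      title="synthetic study")
        self.shells.to_csv(outdir / "shells.tsv", sep="\t", index=False)
        self.quadrats.to_csv(outdir / "quadrats.tsv", sep="\t", index=False)
        truth_manifest(self).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict(),
                                                           sort_keys=False))


def _site_composition(n: int, s: float, hybrid_fraction: float) -> dict:
    """Integer class counts for a site with target MT ancestry *s*."""
    h = hybrid_fraction * min(1.0, 4 * s * (1 - s))
    x = (s - 0.5 * h) / (1 - h)  # MT share among purebreds
    if not 0 <= x <= 1:
        raise ValueError(f"infeasible composition: ancestry {s}, hybrids {h}")
    n_h = round(n * h)
    per_h, rem = divmod(n_h, 4)
    hyb_classes = [AncestryClass.F1, AncestryClass.F2,
                   AncestryClass.BC_ME, AncestryClass.BC_MT]
    counts = {c: per_h for c in hyb_classes}
    for c in hyb_classes[:rem]:
        counts[c] += 1
    n_pure = n - n_h
    n_mt = round(n_pure * x)
    counts[AncestryClass.MT] = n_mt
    counts[AncestryClass.ME] = n_pure - n_mt
    return counts


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate the full synthetic study from *config* (deterministic
    given ``config.seed``)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tables, truth_rows = [], []

    for si, s in enumerate(cfg.site_ancestry):
        site = f"site_{si + 1:02d}"
        counts = _site_composition(cfg.n_per_site, float(s), cfg.hybrid_fraction)
        for cls, n in counts.items():
            if n == 0:
                continue
            cohort = simulate_class(cls, n, cfg.freqs, rng, sample=site,
                                    id_prefix=f"{site}_{cls.value}")
            tables.append(cohort)
            t = cls.mt_fraction
            for iid in cohort.table.ids:
                truth_rows.append({"id": iid, "site": site, "true_class": cls.value,
                                   "compound": cls.compound, "mt_fraction": t})

    alleles = np.concatenate([c.table.alleles for c in tables], axis=0)
    truth = pd.DataFrame(truth_rows).set_index("id")
    order = rng.permutation(len(truth))
    alleles = alleles[order]
    truth = truth.iloc[order]

    # substrate: linear-in-ancestry probability of sitting on algae
    p_algae = cfg.p_algae_me + (cfg.p_algae_mt - cfg.p_algae_me) * truth["mt_fraction"]
    truth["substrate"] = np.where(rng.random(len(truth)) < p_algae, "algae", "bottom")

    indiv = pd.DataFrame({"sample": truth["site"], "site": truth["site"],
                          "substrate": truth["substrate"]}, index=truth.index)
    genotypes = GenotypeTable(list(cfg.freqs.loci), indiv, alleles)

    # shells: lognormal length, ligament ~ 0.45 L, dark strip from the
    # class-conditional morphotype emission (linear in MT genome fraction)
    t = truth["mt_fraction"].to_numpy()
    mean_len = cfg.shell_mean_me + (cfg.shell_mean_mt - cfg.shell_mean_me) * t
    sigma2 = np.log1p(cfg.shell_cv ** 2)
    mu = np.log(mean_len) - sigma2 / 2
    L = np.round(np.exp(rng.normal(mu, np.sqrt(sigma2))), 1)
    lig = np.round(0.45 * L, 1)
    p_t = cfg.p_t_morph_me + (cfg.p_t_morph_mt - cfg.p_t_morph_me) * t
    is_t = rng.random(len(truth)) < p_t
    # E-morphotypes: Z drawn away from 0, skewed toward 1 for ME-like ancestry
    mu_z = np.clip(0.9 - 0.5 * t, 0.05, 0.95)
    conc = 4.0
    z_raw = rng.beta(mu_z * conc, (1 - mu_z) * conc)
    a = np.where(is_t, 0.0, np.maximum(0.1, np.round(z_raw * lig, 1)))
    a = np.minimum(a, lig)  # caliper rounding must not push a past l
    shells = pd.DataFrame({"id": truth.index, "site": truth["site"].values,
                           "substrate": truth["substrate"].values,
                           "L": L, "l": lig, "a": a})
    truth["morphotype"] = np.where(is_t, "T", "E")
    truth["z"] = a / lig

    # quadrats: three bottom cores and three weighed algal tufts per site
    qrows = []
    for si in range(cfg.n_sites):
        site = f"site_{si + 1:02d}"
        d_site = cfg.mean_density * rng.lognormal(0, 0.4)
        for _ in range(cfg.quadrats_per_substrate):
            count = rng.poisson(d_site * 0.16 ** 2)
            qrows.append({"site": site, "substrate": "bottom", "count": int(count),
                          "core_side_m": 0.16, "tuft_weight_kg": np.nan,
                          "total_algae_weight_kg": np.nan, "frame_area_m2": np.nan})
        for _ in range(cfg.quadrats_per_substrate):
            total_w = rng.uniform(1.0, 2.0)
            tuft_w = rng.uniform(0.2, 0.5)
            lam = d_site * 0.25 * (tuft_w / total_w)
            qrows.append({"site": site, "substrate": "algae",
                          "count": int(rng.poisson(lam)), "core_side_m": np.nan,
                          "tuft_weight_kg": round(tuft_w, 3),
                          "total_algae_weight_kg": round(total_w, 3),
                          "frame_area_m2": 0.25})
    quadrats = pd.DataFrame(qrows)

    return StudyBundle(genotypes, truth, shells, quadrats, cfg)


def truth_manifest(bundle: StudyBundle) -> pd.DataFrame:
    """Flat truth table for parameter-recovery scoring: one row per
    individual with the true class, MT genome fraction, morphotype and
    substrate draws, and the master seed."""
    t = bundle.truth.reset_index()
    t["seed"] = bundle.config.seed
    return t[["id", "site", "true_class", "compound", "mt_fraction",
              "substrate", "morphotype", "z", "seed"]]
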