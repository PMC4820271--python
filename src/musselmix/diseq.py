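"""Genotypic disequilibrium statistics for mixed samples.

In a physical mixture of two differentiated populations, pooling inflates
homozygosity (the Wahlund effect, measured by the heterozygote deficit
F_IS = 1 - H_obs/H_exp) and creates inter-locus associations even between
unlinked loci (measured here by R', the composite correlation of allele
dosages).  Both statistics are 0 in a single panmictic population and
reach 1 in a 50:50 non-interbreeding mixture of populations fixed for
alternative alleles.  Because real diagnostic loci are only partially
diagnostic, each sample's statistics are referred to the *mixture maxima*:
the values expected in a hypothetical non-interbreeding mixture of the two
pure taxa with the same average allele frequencies.

The module also provides the expected T-score distributions under the two
null models (local panmixia; non-interbreeding mixture) and a Monte-Carlo
exact goodness-of-fit test of an observed score distribution against
either null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleRegistry, PooledTable

__all__ = [
    "fis", "r_prime", "mixture_maxima", "expected_tscore_panmixia",
    "expected_tscore_mixture", "mc_exact_test", "DisequilibriumReport",
    "TScoreDistribution", "ExactTestResult", "sample_report",
]


@dataclass
class TScoreDistribution:
    """Probability distribution over total T-scores 0..2L."""

    probabilities: np.ndarray
    provenance: str  # panmixia | mixture | empirical

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < -1e-12).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def n_scores(self) -> int:
        return len(self.probabilities)

    def mean(self) -> float:
        return float(np.arange(self.n_scores) @ self.probabilities)


@dataclass
class ExactTestResult:
    chi2_observed: float
    p_value: float
    n_reps: int
    seed: int


@dataclass
class DisequilibriumReport:
    fis_per_locus: pd.Series
    fis_mean: float
    r_per_pair: pd.Series
    r_mean: float
    fis_max: float
    r_max: float
    m_hat: float


def _het_stats(dosage_col: np.ndarray) -> tuple[float, float, int]:
    """(H_obs, p, n) for one locus column of T-dosages (NaN = missing)."""
    x = dosage_col[~np.isnan(dosage_col)]
    n = len(x)
    if n == 0:
        return np.nan, np.nan, 0
    p = x.sum() / (2 * n)
    h_obs = np.mean(x == 1)
    return float(h_obs), float(p), n


def fis(sample: PooledTable) -> tuple[pd.Series, float]:
    """Per-locus heterozygote deficit F_IS = 1 - H_obs/H_exp and its mean.

    H_exp = 2p(1-p) from the sample compound T-frequency, uncorrected for
    sample size (no small-sample correction).  Monomorphic loci have
    undefined F_IS and are excluded from the mean with a warning.
    """
    vals = {}
    for j, locus in enumerate(sample.loci):
        h_obs, p, n = _het_stats(sample.dosage[:, j])
        if n < 2:
            vals[locus] = np.nan
            continue
        h_exp = 2 * p * (1 - p)
        if h_exp == 0:
            warnings.warn(f"locus {locus} monomorphic; F_IS undefined")
            vals[locus] = np.nan
        else:
            vals[locus] = 1.0 - h_obs / h_exp
    s = pd.Series(vals, name="fis")
    mean = float(s.dropna().mean()) if s.notna().any() else np.nan
    return s, mean


def r_prime(sample: PooledTable) -> tuple[pd.Series, float]:
    """Composite (phase-free) inter-locus dosage correlation per locus pair.

    Gametic phase is unknown for diploid genotype data, so association is
    measured by Burrows' composite disequilibrium between T-dosages,
    standardised by sqrt((p1*q1 + D1) * (p2*q2 + D2)) where D is each
    locus's within-locus Hardy-Weinberg departure.  This equals the
    Pearson correlation of the two dosage vectors.  Pairs with a
    monomorphic member are excluded with a warning.
    """
    vals = {}
    L = len(sample.loci)
    for j, k in itertools.combinations(range(L), 2):
        key = f"{sample.loci[j]}:{sample.loci[k]}"
        both = ~np.isnan(sample.dosage[:, j]) & ~np.isnan(sample.dosage[:, k])
        if both.sum() < 3:
            vals[key] = np.nan
            continue
        x = sample.dosage[both, j]
        y = sample.dosage[both, k]
        if np.var(x) == 0 or np.var(y) == 0:
            warnings.warn(f"pair {key} has a monomorphic member; excluded")
            vals[key] = np.nan
            continue
        # Burrows composite: cov(X,Y)/2 = Delta, var(X)/2 = p*q + D_A,
        # so the standardised measure reduces to the dosage correlation.
        vals[key] = float(np.corrcoef(x, y)[0, 1])
    s = pd.Series(vals, name="r_prime")
    mean = float(s.dropna().mean()) if s.notna().any() else np.nan
    return s, mean


def _mixture_moments(f_me: np.ndarray, f_mt: np.ndarray, m: float):
    """Per-locus dosage mean/variance and pairwise covariance of a
    two-component mixture with HWE inside each component."""
    mean = 2 * (m * f_mt + (1 - m) * f_me)
    within_var = m * 2 * f_mt * (1 - f_mt) + (1 - m) * 2 * f_me * (1 - f_me)
    between = m * (1 - m) * (2 * (f_mt - f_me)) ** 2
    var = within_var + between
    return mean, within_var, var


def mixture_maxima(
    mean_t_freqs: pd.Series | dict,
    registry: AlleleRegistry,
) -> tuple[float, float, float]:
    """Maximum F_IS and R' for a non-interbreeding mixture of the two pure
    taxa matching the observed per-locus mean T-frequencies.

    Per locus the mixing proportion m solves
    ``f_obs = m * f_MT + (1 - m) * f_ME`` (clipped into [0, 1]); the
    estimate ``m_hat`` is the mean over usable loci.  At that common m:

    * F_IS max per locus is the Wahlund deficit
      ``1 - H_within / (2 * p_bar * (1 - p_bar))`` with H_within the
      mixture-averaged within-component heterozygosity;
    * R' max per pair is the mixture covariance of dosages
      ``4 m (1-m) df_j df_k`` standardised by the mixture dosage
      variances (df = f_MT - f_ME).

    Returns ``(fis_max, r_max, m_hat)``, each averaged over loci / pairs.
    """
    mean_t_freqs = pd.Series(mean_t_freqs)
    loci, f_me, f_mt, ms = [], [], [], []
    for locus, f_obs in mean_t_freqs.items():
        a = registry.ref_t.loc[locus, "ME"]
        b = registry.ref_t.loc[locus, "MT"]
        if b == a:
            warnings.warn(f"locus {locus} has coincident references; skipped")
            continue
        loci.append(locus)
        f_me.append(a)
        f_mt.append(b)
        ms.append(min(1.0, max(0.0, (f_obs - a) / (b - a))))
    if not loci:
        raise ValueError("no usable locus for mixture maxima")
    f_me = np.asarray(f_me)
    f_mt = np.asarray(f_mt)
    m = float(np.mean(ms))

    mean, within_var, var = _mixture_moments(f_me, f_mt, m)
    p_bar = mean / 2
    h_exp = 2 * p_bar * (1 - p_bar)
    h_within = within_var  # per-locus expected heterozygosity within components
    ok = h_exp > 0
    if not ok.any():
        fis_max = 0.0
    else:
        fis_max = float(np.mean(1 - h_within[ok] / h_exp[ok]))

    if len(loci) < 2 or m in (0.0, 1.0):
        r_max = 0.0
    else:
        df = f_mt - f_me
        rs = []
        for j, k in itertools.combinations(range(len(loci)), 2):
            denom = np.sqrt(var[j] * var[k])
            rs.append(0.0 if denom == 0 else 4 * m * (1 - m) * df[j] * df[k] / denom)
        r_max = float(np.mean(rs))
    return fis_max, r_max, m


def _locus_dosage_pmf(t: float) -> np.ndarray:
    """HWE dosage pmf Binomial(2, t)."""
    return np.array([(1 - t) ** 2, 2 * t * (1 - t), t ** 2])


def expected_tscore_panmixia(sample_t_freqs) -> TScoreDistribution:
    """Expected T-score distribution under local random mating.

    Per locus the dosage is Binomial(2, t_l); the total-score distribution
    is the convolution across loci.
    """
    t = np.asarray(pd.Series(sample_t_freqs).values, dtype=float)
    if ((t < 0) | (t > 1)).any():
        raise ValueError("per-locus frequencies must lie in [0, 1]")
    dist = np.array([1.0])
    for tl in t:
        dist = np.convolve(dist, _locus_dosage_pmf(tl))
    return TScoreDistribution(dist, "panmixia")


def expected_tscore_mixture(m: float, registry: AlleleRegistry) -> TScoreDistribution:
    """Expected T-score distribution of a non-interbreeding mixture:
    m x panmictic distribution at the MT references plus (1 - m) x the ME
    distribution."""
    if not 0 <= m <= 1:
        raise ValueError("m must lie in [0, 1]")
    d_mt = expected_tscore_panmixia(registry.ref_t["MT"]).probabilities
    d_me = expected_tscore_panmixia(registry.ref_t["ME"]).probabilities
    return TScoreDistribution(m * d_mt + (1 - m) * d_me, "mixture")


def _pool_low_expected(expected: np.ndarray, n: int, min_expected: float):
    """Partition score categories, merging adjacent ones from each tail
    inward until every pooled expected count reaches *min_expected*.
    Returns a list of index arrays."""
    exp_counts = expected * n
    groups: list[list[int]] = []
    cur: list[int] = []
    for i in range(len(exp_counts)):
        cur.append(i)
        if exp_counts[cur].sum() >= min_expected:
            groups.append(cur)
            cur = []
    if cur:
        # an under-threshold remainder stays separate: merging it into the
        # body would hide discrepancies out in the unexpected tail
        groups.append(cur)
    return [np.array(g) for g in groups]


def _chi2(obs_counts: np.ndarray, exp_counts: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs_counts - exp_counts) ** 2 / exp_counts
    terms = np.where((exp_counts == 0) & (obs_counts == 0), 0.0, terms)
    return float(np.sum(terms))


def mc_exact_test(
    observed_scores: np.ndarray,
    expected: TScoreDistribution,
    n_reps: int = 2000,
    seed: int | None = None,
    min_expected: float = 1.0,
) -> ExactTestResult:
    """Monte-Carlo exact goodness-of-fit test of observed T-score counts
    against an expected distribution.

    The chi-square statistic over score categories (adjacent categories
    with expected count below *min_expected* pooled from the tails inward)
    measures dissimilarity; replicate count vectors are drawn
    multinomially from the expected distribution at the observed total N.
    The p-value uses the add-one estimator
    ``(1 + #{chi2_sim >= chi2_obs}) / (1 + n_reps)`` and is never exactly 0.
    """
    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo test")
    obs = np.asarray(observed_scores, dtype=float)
    n = int(obs.sum())
    if n < 1:
        raise ValueError("observed counts sum to 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p = expected.probabilities
    if len(p) != len(obs):
        raise ValueError("observed and expected have different score ranges")

    groups = _pool_low_expected(p, n, min_expected)
    exp_g = np.array([p[g].sum() for g in groups]) * n
    obs_g = np.array([obs[g].sum() for g in groups])

    if np.any((exp_g == 0) & (obs_g > 0)):
        # observations where the null puts zero mass: maximal discrepancy
        return ExactTestResult(np.inf, 1.0 / (1 + n_reps), n_reps, seed)

    chi2_obs = _chi2(obs_g, exp_g)
    rng = np.random.default_rng(seed)
    p_g = exp_g / n
    sims = rng.multinomial(n, p_g, size=n_reps).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (sims - exp_g) ** 2 / exp_g
    terms = np.where(exp_g == 0, 0.0, terms)
    chi2_sim = terms.sum(axis=1)
    # add-one estimator; >= with a tiny tolerance to keep chi2==chi2_obs ties
    p_val = (1 + int(np.sum(chi2_sim >= chi2_obs - 1e-12))) / (1 + n_reps)
    return ExactTestResult(chi2_obs, float(p_val), n_reps, seed)


def sample_report(sample: PooledTable, registry: AlleleRegistry) -> DisequilibriumReport:
    """Full disequilibrium report for one sample: per-locus F_IS, pairwise
    R', their means, and the matched non-interbreeding mixture maxima."""
    fis_s, fis_mean = fis(sample)
    r_s, r_mean = r_prime(sample)
    obs = sample.t_freq_observed().dropna()
    fis_max, r_max, m_hat = mixture_maxima(obs, registry)
    return DisequilibriumReport(fis_s, fis_mean, r_s, r_mean, fis_max, r_max, m_hat)
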