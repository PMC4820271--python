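"""End-to-end orchestration: ingest -> pool -> mixture statistics ->
admixture -> threshold calibration -> classification -> morpho-ecology ->
flat TSV reports.

The stage order mirrors the analysis workflow of a two-taxon hybrid-zone
survey: raw genotypes are pooled to compound dosages; every sample gets
hybrid-index and disequilibrium statistics with mixture maxima and
Monte-Carlo exact tests against both null models; a joint admixture fit
yields ISS/PSS; simulated known-ancestry mixtures calibrate the ISS
classification thresholds; individuals are classified by both rules; and
shell/quadrat tables, when present, feed the morphotype-concordance and
substrate analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diseq, morpho
from .admixture import AdmixtureFit, fit_admixture, orient_labels, pss
from .classify import (CRITERIA, PerformanceReport, ThresholdRule,
                       classify_by_iss, classify_by_tscore, performance,
                       select_best_criterion)
from .genotypes import AlleleRegistry, GenotypeTable, pool, t_frequency, t_score
from .simulate import (DEFAULT_MIXTURE_COUNTS, LabeledCohort,
                       ParentalFrequencies, compose_mixture)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "run_calibration_experiment",
           "CalibrationExperiment"]


@dataclass
class RunConfig:
    """Inputs, seeds and knobs of a full pipeline run."""

    outdir: str | Path
    genotypes: GenotypeTable | None = None
    genotypes_path: str | None = None        # Genepop or tabular TSV
    registry: AlleleRegistry | None = None
    registry_path: str | None = None
    shells: pd.DataFrame | None = None
    quadrats: pd.DataFrame | None = None
    burn_in: int = 30_000
    keep: int = 50_000
    alpha: float = 1.0
    exact_test_reps: int = 2000
    calibration_replicates: int = 6
    calibration_counts: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE_COUNTS))
    calibration_mode: str = "simulated_only"  # or "joint"
    criteria: tuple = tuple(CRITERIA)
    min_loci: int = 4
    n_boot: int = 1000
    seed: int = 0
    precomputed_iss: pd.Series | None = None  # skip the MCMC stage

    def spawn_seeds(self, n: int, salt: int = 0) -> list[int]:
        rng = np.random.default_rng((self.seed, salt))
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _load_inputs(config: RunConfig):
    from . import io as mio
    table = config.genotypes
    if table is None:
        if config.genotypes_path is None:
            raise ValueError("no genotypes given")
        path = str(config.genotypes_path)
        table = (mio.read_tabular(path) if path.endswith((".tsv", ".txt"))
                 else mio.read_genepop(path))
    registry = config.registry
    if registry is None:
        if config.registry_path is None:
            raise ValueError("no allele registry given")
        registry = mio.read_registry(config.registry_path)
    return table, registry


def _freqs_from_fit(fit: AdmixtureFit) -> ParentalFrequencies:
    """Parental frequency tables (for simulation) from an oriented fit."""
    if not fit.oriented:
        raise ValueError("fit must be oriented first")
    loci = list(dict.fromkeys(fit.parental_freqs["ME"]["locus"]))
    alleles, fme, fmt = {}, {}, {}
    me = fit.parental_freqs["ME"].set_index(["locus", "allele"])["freq"]
    mt = fit.parental_freqs["MT"].set_index(["locus", "allele"])["freq"]
    for locus in loci:
        labs = list(me.loc[locus].index)
        alleles[locus] = labs
        a = np.array([me.loc[(locus, x)] for x in labs])
        b = np.array([mt.loc[(locus, x)] for x in labs])
        fme[locus] = a / a.sum()
        fmt[locus] = b / b.sum()
    return ParentalFrequencies(loci, alleles, fme, fmt)


@dataclass
class CalibrationExperiment:
    """Result of the replicate-mixture classification experiment."""

    tscore_report: PerformanceReport
    tscore_replicate_overalls: list[float]
    iss_reports: dict[str, PerformanceReport]
    best_rule: ThresholdRule | None
    best_report: PerformanceReport | None
    iss_labeled: pd.DataFrame | None
    replicates: list[LabeledCohort] = field(repr=False, default_factory=list)
    #: mean ISS of co-analyzed empirical individuals over the joint fits
    #: (present only in joint mode); lives on the same scale as the
    #: calibration ISS, so the calibrated thresholds apply to it directly
    empirical_iss: pd.Series | None = None

    def methods_table(self) -> pd.DataFrame:
        """S3-style comparison: Method 1 is the T-score rule, Methods 2-5
        the four ISS threshold criteria."""
        rows = [{"method": "tscore", **self.tscore_report.as_row()}]
        for crit, rep in self.iss_reports.items():
            rows.append({"method": f"iss_{crit}", **rep.as_row()})
        df = pd.DataFrame(rows)
        df.attrs["tscore_overall_sd"] = float(np.std(self.tscore_replicate_overalls, ddof=1)) \
            if len(self.tscore_replicate_overalls) > 1 else 0.0
        return df


def run_calibration_experiment(
    freqs: ParentalFrequencies,
    n_replicates: int = 6,
    counts: dict | None = None,
    burn_in: int = 30_000,
    keep: int = 50_000,
    seed: int = 0,
    criteria: tuple = tuple(CRITERIA),
    fit_iss: bool = True,
    min_loci: int = 4,
    empirical: GenotypeTable | None = None,
) -> CalibrationExperiment:
    """Simulate replicate known-ancestry mixtures and score the five
    classification methods.

    Each replicate is a mixed sample (default 80:80:10:10:10:10, N = 200)
    drawn from *freqs*.  Method 1 classifies by T-score; performance is
    pooled over replicates (per-replicate overall performances are kept
    for the spread).  Methods 2-5 fit the admixture model per replicate
    (optionally jointly with an *empirical* table, whose individuals are
    then ignored for calibration), pool the labeled ISS across
    replicates, calibrate each threshold criterion and score it; the rule
    with the best overall performance is returned.
    """
    registry = freqs.registry()
    seeds = [int(s) for s in
             np.random.default_rng((seed, 17)).integers(0, 2**31 - 1, 2 * n_replicates)]
    replicates, truth_all, pred_all, per_rep = [], [], [], []
    for r in range(n_replicates):
        cohort = compose_mixture(freqs, counts, rng=seeds[r], sample=f"rep_{r + 1}")
        replicates.append(cohort)
        scores = t_score(pool(cohort.table, registry))
        pred = classify_by_tscore(scores, min_loci=min_loci)
        truth = cohort.compound_labels
        keep_mask = pred.notna()
        truth_all.append(truth[keep_mask])
        pred_all.append(pred[keep_mask])
        per_rep.append(performance(truth[keep_mask], pred[keep_mask]).overall)
    tscore_report = performance(pd.concat(truth_all), pd.concat(pred_all))

    iss_reports: dict[str, PerformanceReport] = {}
    best_rule = best_report = iss_labeled = empirical_iss = None
    if fit_iss:
        frames, emp_iss_runs = [], []
        for r, cohort in enumerate(replicates):
            table = cohort.table
            if empirical is not None:
                # joint mode: co-analyze with the empirical genotypes so
                # calibration and empirical scores share one scale
                table = _concat_tables(cohort.table, empirical)
            fit = orient_labels(
                fit_admixture(table, burn_in=burn_in, keep=keep,
                              seed=seeds[n_replicates + r]),
                registry)
            iss = fit.iss.loc[cohort.table.individuals.index]
            frames.append(pd.DataFrame({"iss": iss,
                                        "compound": cohort.compound_labels}))
            if empirical is not None:
                emp_iss_runs.append(fit.iss.loc[empirical.individuals.index])
        iss_labeled = pd.concat(frames)
        best_rule, iss_reports = select_best_criterion(iss_labeled, criteria)
        best_report = iss_reports[best_rule.criterion_id]
        if emp_iss_runs:
            empirical_iss = pd.concat(emp_iss_runs, axis=1).mean(axis=1)
            empirical_iss.name = "iss"
    return CalibrationExperiment(tscore_report, per_rep, iss_reports,
                                 best_rule, best_report, iss_labeled, replicates,
                                 empirical_iss)


def _concat_tables(a: GenotypeTable, b: GenotypeTable) -> GenotypeTable:
    if a.loci != b.loci:
        raise ValueError("tables have different loci")
    indiv = pd.concat([a.individuals, b.individuals])
    alleles = np.concatenate([a.alleles, b.alleles], axis=0)
    return GenotypeTable(a.loci, indiv, alleles)


def run_full(config: RunConfig) -> dict:
    """Run the whole analysis; returns the report tables and writes them
    (TSV/JSON) plus the effective configuration into ``config.outdir``.

    Stage failures raise with the stage name; tables already produced are
    still written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, object] = {}
    stage = "ingest"
    try:
        table, registry = _load_inputs(config)
        reports["n_individuals"] = len(table)

        stage = "pool"
        pooled = pool(table, registry)
        scores = t_score(pooled)

        stage = "sample_stats"
        seeds = config.spawn_seeds(2 * len(pooled.by_sample()), salt=1)
        rows = []
        for i, (s, sub) in enumerate(pooled.by_sample().items()):
            rep = diseq.sample_report(sub, registry)
            tf = t_frequency(sub, registry)
            sc = scores.loc[sub.individuals.index]
            full = sc[sc["n_loci_scored"] == len(sub.loci)]
            obs_scores = np.bincount(full["t_score"],
                                     minlength=2 * len(sub.loci) + 1)
            row = {"sample": s, "n": len(sub), "t_frequency": tf,
                   "fis_mean": rep.fis_mean, "r_mean": rep.r_mean,
                   "fis_max": rep.fis_max, "r_max": rep.r_max, "m_hat": rep.m_hat}
            if obs_scores.sum() > 0:
                pan = diseq.expected_tscore_panmixia(
                    sub.t_freq_observed().dropna())
                mix = diseq.expected_tscore_mixture(rep.m_hat, registry)
                for name, dist, sd in (("panmixia", pan, seeds[2 * i]),
                                       ("mixture", mix, seeds[2 * i + 1])):
                    if dist.n_scores == len(obs_scores):
                        res = diseq.mc_exact_test(obs_scores, dist,
                                                  config.exact_test_reps, seed=sd)
                        row[f"chi2_{name}"] = res.chi2_observed
                        row[f"p_{name}"] = res.p_value
            rows.append(row)
        samples_df = pd.DataFrame(rows).set_index("sample")
        reports["samples"] = samples_df

        stage = "admixture"
        if config.precomputed_iss is not None:
            iss = config.precomputed_iss.reindex(table.individuals.index)
            fit = None
            freqs_for_sim = None
        else:
            fit = orient_labels(
                fit_admixture(table, burn_in=config.burn_in, keep=config.keep,
                              alpha=config.alpha,
                              seed=config.spawn_seeds(1, salt=2)[0]),
                registry)
            iss = fit.iss
            samples_df["pss"] = pss(fit)
            # calibration cohorts are simulated from the registry's full
            # reference tables when available: the K=2 fit systematically
            # purifies its parental-frequency estimates (hybrid alleles are
            # soft-assigned away), and cohorts drawn from purified
            # frequencies would calibrate over-tight thresholds
            try:
                freqs_for_sim = ParentalFrequencies.from_registry(registry)
            except ValueError:
                freqs_for_sim = _freqs_from_fit(fit)
            reports["admixture_diagnostics"] = fit.diagnostics

        stage = "calibration"
        rule = None
        if freqs_for_sim is not None:
            exp = run_calibration_experiment(
                freqs_for_sim,
                n_replicates=config.calibration_replicates,
                counts=config.calibration_counts,
                burn_in=config.burn_in, keep=config.keep,
                seed=config.spawn_seeds(1, salt=3)[0],
                criteria=config.criteria,
                empirical=table if config.calibration_mode == "joint" else None,
            )
            rule = exp.best_rule
            reports["calibration"] = exp.methods_table()
            reports["calibration_rule"] = rule
            if exp.empirical_iss is not None:
                # joint mode: classify by the co-analyzed scores, which
                # live on the calibration scale
                iss = exp.empirical_iss.reindex(table.individuals.index)
                samples_df["pss"] = iss.groupby(table.individuals["sample"]).mean()

        stage = "classification"
        cls = pd.DataFrame({"t_score": scores["t_score"],
                            "n_loci_scored": scores["n_loci_scored"],
                            "iss": iss})
        cls["class_tscore"] = classify_by_tscore(scores, min_loci=config.min_loci)
        if rule is not None and iss.notna().all():
            cls["class_iss"] = classify_by_iss(iss, rule)
        reports["classification"] = cls

        stage = "morpho"
        if config.shells is not None:
            shells = morpho.annotate_shells(config.shells)
            reports["shells"] = shells
            key = "class_iss" if "class_iss" in cls else "class_tscore"
            merged = shells.merge(cls[[key]], left_on="id", right_index=True,
                                  how="inner")
            conc = morpho.concordance(merged[key], merged["morphotype"])
            reports["concordance"] = conc
            merged["is_t"] = (merged["morphotype"] == "T").astype(float)
            reports["morph_contrast"] = morpho.substrate_contrast(
                merged, "is_t", n_boot=config.n_boot,
                seed=config.spawn_seeds(1, salt=4)[0])
            gen = table.individuals.join(cls[[key]])
            gen["is_mt"] = (gen[key] == "MT").astype(float)
            reports["genetic_contrast"] = morpho.substrate_contrast(
                gen[gen["substrate"] != "unknown"], "is_mt",
                n_boot=config.n_boot, seed=config.spawn_seeds(1, salt=5)[0])
        if config.quadrats is not None:
            dens = []
            for row in config.quadrats.itertuples():
                if row.substrate == "bottom":
                    est = morpho.density_bottom(row.count, row.core_side_m)
                else:
                    est = morpho.density_algae(row.count, row.tuft_weight_kg,
                                               row.total_algae_weight_kg,
                                               row.frame_area_m2)
                dens.append({"site": row.site, "substrate": row.substrate,
                             "per_m2": est.per_m2})
            reports["densities"] = pd.DataFrame(dens)
    except Exception as err:
        _write_reports(reports, outdir, config)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    _write_reports(reports, outdir, config)
    return reports


def _write_reports(reports: dict, outdir: Path, config: RunConfig) -> None:
    for name, obj in reports.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t")
    meta = {"seed": config.seed, "burn_in": config.burn_in, "keep": config.keep,
            "exact_test_reps": config.exact_test_reps,
            "calibration_mode": config.calibration_mode,
            "calibration_replicates": config.calibration_replicates}
    rule = reports.get("calibration_rule")
    if rule is not None:
        meta["threshold_rule"] = {"criterion": rule.criterion_id,
                                  "lower": rule.lower, "upper": rule.upper}
    diag = reports.get("admixture_diagnostics")
    if diag is not None:
        meta["admixture_diagnostics"] = diag
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
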