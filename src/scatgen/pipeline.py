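"""End-to-end pipeline: consensus -> identity -> diversity -> kinship ->
population size -> bottleneck -> diet, with per-stage artifacts and one
combined JSON report.

All thresholds default to the field-protocol settings (40% amplification screen,
PID-sibs < 0.01, >= 6 matching loci, MAF 0.02, 0.5% read filter, maximum
census size 25, 100 LRT / 1000 CI bootstrap replicates, 1000 coalescent
iterations).  One global seed fans out to fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import bottleneck as bn
from . import consensus as cns
from . import diet as diet_mod
from . import diversity as div
from . import identity as idy
from . import io as io_mod
from . import kinship as kin
from . import popsize as ps
from . import simulate as sim

logger = logging.getLogger("scatgen.pipeline")

STAGES = ("consensus", "identify", "diversity", "kinship", "popsize",
          "bottleneck", "diet")

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "consensus": 100,
    "identify": 200,
    "diversity": 300,
    "kinship": 400,
    "popsize": 500,
    "bottleneck": 600,
    "diet": 700,
}


@dataclass
class PipelineConfig:
    replicate_table: Optional[str] = None
    locus_metadata: Optional[str] = None
    diet_table: Optional[str] = None
    out_dir: str = "results"
    min_fraction: float = 0.40
    pid_sibs_threshold: float = 0.01
    min_overlap: int = 6
    maf: float = 0.02
    min_prop: float = 0.005
    min_reps: int = 2
    max_n: int = 25
    lrt_boot: int = 100
    ci_boot: int = 1000
    bottleneck_iter: int = 1000
    hwe_perm: int = 9999
    ld_perm: int = 9999
    permanova_perm: int = 9999
    area_ha: float = 3013.0
    seed: int = 1
    simulate: bool = True  # generate synthetic inputs when paths are absent

    def __post_init__(self) -> None:
        checks = {
            "min_fraction": (0, 1), "pid_sibs_threshold": (0, 1),
            "maf": (0, 0.5), "min_prop": (0, 1),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_overlap < 1 or self.max_n < 1:
            raise ValueError("min_overlap and max_n must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def stage_seed(self, stage: str) -> int:
        return self.seed * 1000 + STAGE_SEED_OFFSETS[stage]


def _json_default(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def _clean(obj):
    """Make a report JSON-safe and deterministic."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf"
        if math.isnan(obj):
            return None
        return round(obj, 10)
    if dataclasses.is_dataclass(obj):
        return _clean(dataclasses.asdict(obj))
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def run_pipeline(
    config: PipelineConfig,
    stages: Optional[Sequence[str]] = None,
    sim_config: Optional[sim.SimConfig] = None,
) -> Dict:
    """Run the requested stages in order and return the combined report.

    Stage failures abort with the stage name and cause; artifacts written so
    far are retained in ``config.out_dir``.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": dataclasses.asdict(config), "stages": {}}

    stage = "input"
    try:
        truth = None
        pop = None
        diet_table = None
        if config.replicate_table:
            table = io_mod.read_replicate_table(config.replicate_table)
            repeat_units = (io_mod.read_locus_metadata(config.locus_metadata)
                            if config.locus_metadata else {})
            loci = [l for l in table.loci if l != sim.SEX_LOCUS]
            if config.diet_table:
                diet_table = io_mod.read_diet_table(config.diet_table)
        elif config.simulate:
            stage = "simulate"
            if sim_config is None:
                sim_config = sim.SimConfig(seed=config.stage_seed("simulate"))
            pop = sim.simulate_population(sim_config)
            table, truth = sim.simulate_replicate_table(pop, sim_config)
            repeat_units = dict(pop.repeat_units)
            loci = list(pop.loci)
            io_mod.write_replicate_table(table, out_dir / "replicates.csv")
            io_mod.write_locus_metadata(repeat_units, out_dir / "locus_metadata.csv")
            io_mod.write_truth(truth, out_dir / "truth.json")
        else:
            raise ValueError("no replicate table provided and simulation disabled")

        n_samples_in = len(table.samples)
        logger.info("input: %d samples, %d loci", n_samples_in, len(loci))

        # ---- consensus ------------------------------------------------
        stage = "consensus"
        retained = cns.screen_samples(table, n_loci=len(loci),
                                      min_fraction=config.min_fraction, loci=loci)
        sub = table.restrict(retained)
        consensus = cns.call_consensus(sub, loci=loci)
        errors = cns.estimate_error_rates(sub, consensus)
        logger.info("consensus: %d/%d samples retained", len(retained), n_samples_in)
        report["stages"]["consensus"] = {
            "n_samples_in": n_samples_in,
            "n_samples_retained": len(retained),
            "genotyping_success_pct": 100.0 * len(retained) / n_samples_in,
            "ado_cumulative": errors.ado_cumulative,
            "fa_cumulative": errors.fa_cumulative,
            "ado_per_locus": errors.ado_per_locus,
            "fa_per_locus": errors.fa_per_locus,
        }
        if "consensus" == stages[-1]:
            return _finish(report, out_dir)

        # ---- identification -------------------------------------------
        stage = "identify"
        sex_cells = cns.call_consensus(sub, loci=[sim.SEX_LOCUS]) \
            if sim.SEX_LOCUS in table.loci else {}
        sample_sex = {}
        cells = sub.by_cell()
        for sid in sorted(retained):
            reps = [r.alleles for r in cells.get((sid, sim.SEX_LOCUS), [])]
            if reps:
                sample_sex[sid] = idy.assign_sex(reps, sim.X_ALLELE, sim.Y_ALLELE)
        sample_session = truth["session"] if truth else {}
        match = idy.match_individuals(
            consensus, min_overlap=config.min_overlap, loci=loci,
            sample_sex=sample_sex or None, sample_session=sample_session or None)
        individuals = match.individuals
        freqs = idy.AlleleFrequencies.from_genotypes(
            {i.individual_id: i.genotype for i in individuals})
        pid_rows = {loc: idy.pid_per_locus(freqs.freqs[loc])
                    for loc in sorted(freqs.freqs)}
        sibs_sorted = sorted(v[1] for v in pid_rows.values())
        cum, n_loci_needed = idy.cumulative_pid(sibs_sorted, config.pid_sibs_threshold)
        sessions = sorted({s for s in sample_session.values()}) if sample_session else None
        demo = idy.demography_summary(
            individuals, sessions=sessions, area_ha=config.area_ha,
            n_collected=n_samples_in, n_genotyped=len(retained))
        io_mod.write_genalex(individuals, loci, out_dir / "individuals.csv")
        logger.info("identify: %d individuals (%d review, %d unassigned)",
                    len(individuals), len(match.review), len(match.unassigned))
        report["stages"]["identify"] = {
            "n_individuals": len(individuals),
            "n_review": len(match.review),
            "review": match.review,
            "n_unassigned": len(match.unassigned),
            "conflicts": match.conflicts,
            "pid_per_locus": {k: list(v) for k, v in pid_rows.items()},
            "cumulative_pid_sibs": cum,
            "loci_needed_for_pid_sibs": n_loci_needed,
            "demography": demo,
        }
        if stages[-1] in ("identify",):
            return _finish(report, out_dir)
        genotypes = {i.individual_id: i.genotype for i in individuals}

        # ---- diversity -------------------------------------------------
        if "diversity" in stages:
            stage = "diversity"
            dtab = div.diversity_table(genotypes)
            hwe = {}
            for loc in sorted(freqs.freqs):
                if len(freqs.freqs[loc]) > 1:
                    hwe[loc] = div.hwe_exact_test(
                        genotypes, loc, n_perm=config.hwe_perm,
                        seed=config.stage_seed("diversity"))
            hwe_adj = dict(zip(sorted(hwe), div.bh_fdr([hwe[k] for k in sorted(hwe)])))
            ld = div.ld_pairwise_test(genotypes, n_perm=config.ld_perm,
                                      seed=config.stage_seed("diversity") + 1)
            ld_clean = {f"{a}|{b}": p for (a, b), p in ld.items()}
            ld_ps = [p for p in ld_clean.values() if p is not None]
            ld_adj = div.bh_fdr(ld_ps) if ld_ps else []
            report["stages"]["diversity"] = {
                "per_locus": dtab.rows,
                "means": dtab.means,
                "ses": dtab.ses,
                "fis_multilocus": dtab.fis_multilocus,
                "hwe_p": hwe,
                "hwe_p_bh": hwe_adj,
                "ld_p": ld_clean,
                "ld_p_bh": ld_adj,
                "fna_per_locus": {
                    r.locus: cns.null_allele_frequency(r.he, r.ho) for r in dtab.rows},
            }

        # ---- kinship ---------------------------------------------------
        if "kinship" in stages and len(individuals) >= 2:
            stage = "kinship"
            dyads = kin.kin_matrix(individuals, freqs,
                                   seed=config.stage_seed("kinship"))
            report["stages"]["kinship"] = {
                "dyads": dyads,
                "category_counts": kin.category_counts(dyads),
            }

        # ---- population size ------------------------------------------
        if "popsize" in stages:
            stage = "popsize"
            counts = ps.CaptureCounts([len(i.samples) for i in individuals])
            ecm = ps.ecm_mle(counts, config.max_n)
            tirm = ps.tirm_mle(counts, config.max_n)
            model, lrt_p, lam = ps.model_select_lrt(
                counts, config.max_n, n_boot=config.lrt_boot,
                seed=config.stage_seed("popsize"))
            ci = ps.bootstrap_ci(counts, model, config.max_n,
                                 n_boot=config.ci_boot,
                                 seed=config.stage_seed("popsize") + 1)
            try:
                ne = ps.ld_ne(genotypes, maf=config.maf)
                ne_out = {"ne_hat": ne.ne_hat, "ci95": list(ne.ci95),
                          "r2_mean": ne.r2_mean, "r2_expected": ne.r2_expected,
                          "s_harmonic": ne.s_harmonic}
            except ValueError as exc:
                ne_out = {"error": str(exc)}
            chosen_n = tirm.n_hat if model == "TIRM" else ecm.n_hat
            report["stages"]["popsize"] = {
                "capture_counts": counts.counts,
                "ecm_n_hat": ecm.n_hat,
                "tirm_n_hat": tirm.n_hat,
                "tirm_alpha": tirm.alpha,
                "model": model,
                "lrt_p": lrt_p,
                "lrt_lambda": lam,
                "nc_hat": chosen_n,
                "nc_ci95": list(ci),
                "ne": ne_out,
            }

        # ---- bottleneck ------------------------------------------------
        if "bottleneck" in stages:
            stage = "bottleneck"
            het = {}
            for model_name in bn.MODELS:
                res = bn.het_excess_test(
                    genotypes, model_name, n_iter=config.bottleneck_iter,
                    seed=config.stage_seed("bottleneck"))
                het[model_name] = {
                    "n_excess_observed": res.n_excess_observed,
                    "n_excess_expected": res.n_excess_expected,
                    "wilcoxon_p": res.wilcoxon_p,
                }
            shape = bn.mode_shift(freqs.freqs)
            sizes = {loc: sorted(freqs.freqs[loc]) for loc in freqs.freqs}
            units = {loc: repeat_units.get(loc, 2) for loc in sizes}
            per_locus_m, mean_m, m_flags = bn.m_ratio(sizes, units)
            report["stages"]["bottleneck"] = {
                "het_excess": het,
                "mode_shift": shape,
                "m_ratio_per_locus": per_locus_m,
                "m_ratio_mean": mean_m,
                "m_ratio_below_critical": mean_m < bn.MC_THRESHOLD,
                "m_ratio_flags": m_flags,
            }

        # ---- diet ------------------------------------------------------
        if "diet" in stages:
            stage = "diet"
            if diet_table is None:
                if config.diet_table:
                    raise FileNotFoundError(f"diet table not found: {config.diet_table}")
                if pop is None or truth is None:
                    raise ValueError("no diet table available")
                passing = sorted(retained)
                owners = {f"D{i + 1:03d}": truth["owner"][s]
                          for i, s in enumerate(passing)}
                assert sim_config is not None
                diet_table = sim.simulate_diet_table(pop, sim_config, sample_owners=owners)
                io_mod.write_diet_table(diet_table, out_dir / "diet_reads.csv")
            det = diet_mod.filter_reads(
                diet_table, predator_taxa=(sim.PREDATOR_TAXON, "Homo sapiens"),
                min_prop=config.min_prop, min_reps=config.min_reps)
            profiles = diet_mod.individual_profiles(
                det, diet_table.sample_to_individual)
            perman = None
            sexes = [diet_table.individual_sex.get(i, "unknown")
                     for i in sorted(profiles)]
            if profiles and len({s for s in sexes if s != "unknown"}) >= 2:
                ordered = sorted(profiles)
                dist = diet_mod.bray_curtis([profiles[i] for i in ordered])
                keep = [i for i, s in enumerate(sexes) if s != "unknown"]
                r2, f_stat, p = diet_mod.permanova(
                    dist[np.ix_(keep, keep)] if len(keep) < len(ordered) else dist,
                    [sexes[i] for i in keep],
                    n_perm=config.permanova_perm,
                    seed=config.stage_seed("diet"))
                perman = {"R2": r2, "F": f_stat, "p": p}
            report["stages"]["diet"] = {
                "n_samples_retained": det.n_samples,
                "n_samples_excluded": len(det.excluded_samples),
                "foo": diet_mod.foo(det) if det.n_samples else {},
                "wpoo": diet_mod.wpoo(det) if det.n_samples else {},
                "permanova_by_sex": perman,
            }

        return _finish(report, out_dir)
    except Exception as exc:
        _finish(report, out_dir, partial=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _finish(report: Dict, out_dir: Path, partial: bool = False) -> Dict:
    cleaned = _clean(report)
    name = "report.partial.json" if partial else "report.json"
    (out_dir / name).write_text(json.dumps(cleaned, indent=2, sort_keys=True))
    return cleaned
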