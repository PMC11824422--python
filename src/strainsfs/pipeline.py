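"""End-to-end orchestration: simulate -> phase/filter -> SFS ->
demography -> DFE, driven by a YAML-serializable configuration.

Every stage writes plain TSV/JSON into a per-species run directory so
any stage can be re-run in isolation; re-running with the same config
and seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine
from .demography import (DemographicModel, ancestral_size, fit_demography,
                         select_model, tau_to_years, MU_DEFAULT)
from .dfe import (DFEModel, SpectraCache, fit_dfe, THETA_RATIO_DEFAULT)
from .phasing import (call_quasi_phased, mean_depth_filter,
                      read_host_site_calls)
from .sfs import FoldedSFS, build_folded_sfs, project_sfs
from .synthetic import SimScenario, simulate_host_pileup

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, species: str, message: str):
        super().__init__(f"stage {stage!r} failed for {species!r}: {message}")
        self.stage = stage
        self.species = species


@dataclass
class PipelineConfig:
    """Run settings; defaults match the analysis constants."""

    out_dir: str = "run"
    calls_path: str | None = None        # HostSiteCalls TSV; None -> simulate
    n_target: int = 14
    min_qp_genomes: int = 14
    min_qp_accessory: int = 47
    mu: float = MU_DEFAULT               # 4.08e-10 (1e-10 supported)
    generations_per_day: float = 1.0
    theta_ratio: float = THETA_RATIO_DEFAULT
    demog_families: list = field(default_factory=lambda: ["one", "two"])
    dfe_families: list = field(default_factory=lambda: ["gamma"])
    m_species_pairs: int = 741
    m_core_accessory: int = 18
    seed: int = 0
    n_starts: int = 25
    accessory: bool = False
    simulate: dict | None = None         # SimScenario kwargs (sans demography)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _scenario_from_config(cfg: PipelineConfig) -> SimScenario:
    spec = dict(cfg.simulate or {})
    demog = spec.pop("demography", {"epochs": [1.0], "change_times": []})
    dfe = spec.pop("dfe", None)
    model = DemographicModel(**demog)
    dfe_model = DFEModel(**dfe) if dfe else None
    spec.setdefault("seed", cfg.seed)
    return SimScenario(demography=model, dfe=dfe_model, **spec)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.resolved.yaml")

    # -- inputs -------------------------------------------------------------
    stage = "simulate"
    scenario = None
    try:
        if cfg.calls_path is None:
            scenario = _scenario_from_config(cfg)
            calls, truth = simulate_host_pileup(scenario)
            calls.to_csv(out / "host_site_calls.tsv", sep="\t", index=False)
            truth["polymorphic_sites"].to_csv(
                out / "truth_sites.tsv", sep="\t", index=False)
            with open(out / "truth_params.json", "w") as fh:
                json.dump({
                    "theta_s": scenario.theta_s,
                    "theta_ratio": scenario.theta_ratio,
                    "demography": scenario.demography.to_dict(),
                    "dfe": scenario.dfe.to_dict() if scenario.dfe else None,
                    "seed": scenario.seed,
                }, fh, indent=2, default=float)
        else:
            calls = read_host_site_calls(cfg.calls_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "-", str(exc)) from exc

    results = {}
    for species, sp_calls in calls.groupby("species"):
        results[species] = _run_species(cfg, str(species), sp_calls, out)
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return out


def _run_species(cfg: PipelineConfig, species: str, calls: pd.DataFrame,
                 out: Path) -> dict:
    sp_dir = out / species
    sp_dir.mkdir(exist_ok=True)
    log = {"species": species}

    # -- phase --------------------------------------------------------------
    stage = "phase"
    try:
        hosts_ok = mean_depth_filter(calls)
        log["hosts_total"] = int(calls["host"].nunique())
        log["hosts_depth_pass"] = len(hosts_ok)
        haplotypes = []
        for host, grp in calls[calls["host"].isin(hosts_ok)].groupby("host"):
            haplotypes.append(call_quasi_phased(grp))
        haplotypes = [h for h in haplotypes if h.n_called() > 0]
        log["qp_genomes"] = len(haplotypes)
        min_required = (cfg.min_qp_accessory if cfg.accessory
                        else cfg.min_qp_genomes)
        if len(haplotypes) < min_required:
            reason = (f"only {len(haplotypes)} QP genomes "
                      f"(minimum {min_required})")
            logger.info("skipping %s: %s", species, reason)
            log["skipped"] = reason
            return log
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, species, str(exc)) from exc

    # -- SFS ----------------------------------------------------------------
    stage = "sfs"
    try:
        spectra = {}
        for cls in ("synonymous", "nonsynonymous"):
            table, _raw = build_folded_sfs(haplotypes, cls, species=species)
            proj = project_sfs(table, cfg.n_target, mut_class=cls,
                               species=species)
            proj.to_tsv(sp_dir / f"sfs_{cls}.tsv")
            spectra[cls] = proj
            log[f"sites_{cls}"] = float(proj.L)
            log[f"snps_{cls}"] = float(proj.total)
    except Exception as exc:
        raise PipelineError(stage, species, str(exc)) from exc

    # -- demography ---------------------------------------------------------
    stage = "fit-demog"
    try:
        fits = []
        for fam in cfg.demog_families:
            fits.append(fit_demography(spectra["synonymous"], fam,
                                       n_starts=cfg.n_starts, seed=cfg.seed))
        best = fits[0] if len(fits) == 1 else select_model(fits)
        with open(sp_dir / "demography.json", "w") as fh:
            fh.write(best.to_json())
        n_anc = ancestral_size(best.model.theta_s, mu=cfg.mu,
                               L_syn=spectra["synonymous"].L)
        log["demog_family"] = best.model.family
        log["theta_s"] = best.model.theta_s
        log["n_anc"] = n_anc
        if best.model.change_times:
            log["tau_years"] = tau_to_years(
                best.model.change_times[-1], n_anc,
                generations_per_day=cfg.generations_per_day)
    except Exception as exc:
        raise PipelineError(stage, species, str(exc)) from exc

    # -- DFE ----------------------------------------------------------------
    stage = "fit-dfe"
    try:
        cache = SpectraCache(best.model, cfg.n_target)
        dfe_fits = {}
        for fam in cfg.dfe_families:
            dfe_fits[fam] = fit_dfe(
                spectra["nonsynonymous"], best, fam,
                theta_ratio=cfg.theta_ratio, n_anc=n_anc,
                n_starts=cfg.n_starts, seed=cfg.seed, cache=cache)
        best_dfe = min(dfe_fits.values(), key=lambda f: f.aic)
        with open(sp_dir / "dfe.json", "w") as fh:
            fh.write(best_dfe.to_json())
        log["dfe_family"] = best_dfe.dfe.family
        log["dfe_shape"] = best_dfe.dfe.shape
        log["dfe_E_s"] = best_dfe.dfe.mean_s
    except Exception as exc:
        raise PipelineError(stage, species, str(exc)) from exc

    return log
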