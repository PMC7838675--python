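"""Pipeline glue: the three-way per-SNP scan (no adjustment / SRA / EEGM)
and the simulation-study harness (type-I error, power, bias, coverage).

Configuration is a single YAML mapping; every run is reproducible given the
config and a seed.  The scan runs serially in SNP order, so results are
deterministic regardless of any requested thread count.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import gxe_inference, stratification_surrogate, synthetic_cohort, trio_data
from .gxe_inference import scan_snp
from .stratification_surrogate import compute_pcs, encode_sra, estimate_eegm
from .synthetic_cohort import (
    CAUSAL_SNP,
    TEST_SNP,
    SimTruth,
    StructureConfig,
    simulate_cohort,
    single_population_scenario,
    spurious_gxe_scenario,
)
from .trio_data import TrioDataset, read_trios, summarize_cohort, write_results

logger = logging.getLogger(__name__)

PRESETS = {
    "spurious_gxe": spurious_gxe_scenario,
    "single_population": single_population_scenario,
}


class ConfigError(ValueError):
    """Raised when a run configuration violates the schema."""


def marker_snp_ids(dataset: TrioDataset) -> list[str]:
    """SNP ids of the simulated marker panel (``m0001`` style names)."""
    return [s.snp_id for s in dataset.snps if s.snp_id.startswith("m")]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _resolve_scenario(spec: dict) -> tuple[SimTruth, StructureConfig]:
    if "scenario_yaml" in spec:
        return synthetic_cohort.load_scenario(spec["scenario_yaml"])
    preset = spec.get("preset")
    if preset not in PRESETS:
        raise ConfigError(f"unknown simulation preset {preset!r}")
    kwargs = {k: v for k, v in spec.items() if k not in ("preset",)}
    truth, structure = PRESETS[preset](**kwargs)
    return truth, structure


def _load_dataset(cfg: dict, seed: int):
    """Dataset from either a trio bundle on disk or a simulation preset."""
    inp = cfg.get("input")
    if not isinstance(inp, dict):
        raise ConfigError("config requires an 'input' mapping")
    if "simulate" in inp:
        truth, structure = _resolve_scenario(inp["simulate"])
        structure = replace(structure, seed=seed)
        ds, _hidden = simulate_cohort(truth, structure)
        return ds
    for key in ("vcf", "fam", "covariates"):
        if key not in inp:
            raise ConfigError(f"input requires '{key}' (or a 'simulate' block)")
    return read_trios(
        inp["vcf"], inp["fam"], inp["covariates"], exposure_col=cfg["exposure"]
    )


def _build_surrogates(cfg: dict, dataset: TrioDataset):
    sra = eegm = pcs = None
    scfg = cfg.get("surrogate", {})
    if "sra" in scfg:
        s = scfg["sra"]
        sra = encode_sra(dataset.sra_label, s["reference"], s["comparison"])
    if "eegm" in scfg:
        s = scfg["eegm"] or {}
        markers = s.get("markers") or marker_snp_ids(dataset)
        if not markers:
            raise ConfigError("eegm surrogate requires a marker SNP list")
        k_cfg = s.get("k", 10)
        pcs = compute_pcs(
            dataset,
            k=k_cfg if k_cfg == "auto" else int(k_cfg),
            member=s.get("member", "child"),
            snp_ids=markers,
            prune=bool(s.get("prune", False)),
        )
        eegm = estimate_eegm(dataset.exposure, pcs)
    return sra, eegm, pcs


def run_scan(
    config,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    threads: int = 1,
) -> pd.DataFrame:
    """Per-SNP three-way interaction scan.

    Config keys: ``input`` (trio bundle paths or a ``simulate`` block),
    ``exposure`` (covariate column name), optional ``snps`` subset and
    ``surrogate`` settings (``sra``: reference/comparison groups, ``eegm``:
    k/member/markers).  Writes ``scan_results.tsv`` plus a run log when
    ``out_dir`` is given and returns the results table.
    """
    cfg = load_config(config)
    if "exposure" not in cfg:
        raise ConfigError("config requires an 'exposure' column name")
    seed = int(cfg.get("seed", 0) if seed is None else seed)

    handlers: list[logging.Handler] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log", mode="w")
        fh.setLevel(logging.INFO)
        logging.getLogger("triogxe").addHandler(fh)
        handlers.append(fh)
    try:
        dataset = _load_dataset(cfg, seed)
        logger.info("loaded %d trios x %d SNPs", len(dataset), dataset.n_snps)
        summary = summarize_cohort(dataset)
        logger.info("cohort by ancestry:\n%s", summary.sex_counts.to_string())
        logger.info("exposure rates:\n%s", summary.exposure_rates.to_string())

        sra, eegm, _ = _build_surrogates(cfg, dataset)
        markers = set(marker_snp_ids(dataset))
        snps: Sequence[str] = cfg.get(
            "snps", [s for s in dataset.snp_ids if s not in markers]
        )
        rows = []
        for snp_id in snps:  # serial, SNP order: deterministic merge
            rows.append(scan_snp(dataset, snp_id, sra=sra, eegm=eegm))
            if rows[-1]["flags"]:
                logger.info("%s: %s", snp_id, rows[-1]["flags"])
        results = pd.DataFrame(rows)
        if out_dir is not None:
            write_results(results, out_dir / "scan_results.tsv")
        return results
    finally:
        for h in handlers:
            logging.getLogger("triogxe").removeHandler(h)
            h.close()


# ---------------------------------------------------------------------------
# Simulation-study harness
# ---------------------------------------------------------------------------


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def type_one_error_study(
    truth: SimTruth,
    structure: StructureConfig,
    n_replicates: int,
    n_trios: int | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    snp: str = TEST_SNP,
    k_pcs: int | str = "auto",
    analyses: Sequence[str] = ("unadjusted", "sra", "eegm"),
) -> pd.DataFrame:
    """Empirical rejection rates of the interaction tests over replicates.

    Each replicate simulates a fresh cohort, builds the SRA and EEGM
    surrogates, and records the unadjusted 1-df and adjusted 2-df p-values
    at ``snp``.  Returns one row per analysis with the rejection rate at
    ``alpha`` and its binomial Monte Carlo standard error.
    """
    if n_trios is not None:
        structure = replace(structure, n_trios=n_trios)
    pvals = {a: [] for a in analyses}
    for rng in _replicate_rngs(seed, n_replicates):
        ds, _ = simulate_cohort(truth, structure, rng=rng)
        sra = (
            encode_sra(ds.sra_label, structure.subpop_names[0], structure.subpop_names[1])
            if "sra" in analyses
            else None
        )
        eegm = None
        if "eegm" in analyses:
            pcs = compute_pcs(ds, k=k_pcs, member="child", snp_ids=marker_snp_ids(ds))
            eegm = estimate_eegm(ds.exposure, pcs)
        row = scan_snp(ds, snp, sra=sra, eegm=eegm)
        key = {"unadjusted": "p_unadj_1df", "sra": "p_sra_2df", "eegm": "p_eegm_2df"}
        for a in analyses:
            pvals[a].append(row[key[a]])
    out = []
    for a in analyses:
        p = np.asarray(pvals[a], dtype=float)
        ok = ~np.isnan(p)
        rate = float((p[ok] < alpha).mean()) if ok.any() else np.nan
        out.append(
            {
                "analysis": a,
                "n_replicates": int(ok.sum()),
                "alpha": alpha,
                "rejection_rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / ok.sum())) if ok.any() else np.nan,
            }
        )
    return pd.DataFrame(out)


def parameter_recovery_study(
    truth: SimTruth,
    structure: StructureConfig,
    n_replicates: int,
    n_trios: int | None = None,
    seed: int = 0,
    snp: str = CAUSAL_SNP,
) -> pd.DataFrame:
    """Bias, empirical SE and 95% Wald coverage of the unadjusted fit.

    Simulates replicates from ``truth``/``structure``, fits the unadjusted
    model at the causal locus, and compares estimates of beta_g and beta_ge
    with their generative values.
    """
    if n_trios is not None:
        structure = replace(structure, n_trios=n_trios)
    true_vals = {"beta_g": truth.beta_g, "beta_ge": truth.beta_ge}
    est = {k: [] for k in true_vals}
    ses = {k: [] for k in true_vals}
    for rng in _replicate_rngs(seed, n_replicates):
        ds, _ = simulate_cohort(truth, structure, rng=rng)
        fit = gxe_inference.fit_model(ds, None, "unadjusted", snp)
        for name in true_vals:
            est[name].append(getattr(fit.params, name))
            ses[name].append(fit.se(name))
    rows = []
    for name, tv in true_vals.items():
        b = np.asarray(est[name])
        s = np.asarray(ses[name])
        cover = np.mean((b - 1.96 * s <= tv) & (tv <= b + 1.96 * s))
        rows.append(
            {
                "parameter": name,
                "true_value": tv,
                "n_replicates": n_replicates,
                "mean_estimate": float(b.mean()),
                "mean_bias": float(b.mean() - tv),
                "empirical_se": float(b.std(ddof=1)),
                "mean_model_se": float(s.mean()),
                "coverage_95": float(cover),
            }
        )
    return pd.DataFrame(rows)


def run_simulation_study(
    config, seed: int | None = None, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Run the scenario list of a simulation-study config.

    Each scenario names a preset (``spurious_gxe`` or ``single_population``),
    a ``kind`` (``type1`` or ``recovery``), ``n_replicates``, ``n_trios``
    and, for type-I studies, ``alpha`` and the target SNP.  Returns the
    concatenated summary (empty for zero scenarios/replicates) and writes
    ``simstudy.tsv`` under ``out_dir`` if given.
    """
    cfg = load_config(config)
    scenarios = cfg.get("scenarios")
    if not isinstance(scenarios, list):
        raise ConfigError("config requires a 'scenarios' list")
    seed = int(cfg.get("seed", 0) if seed is None else seed)

    frames = []
    for i, sc in enumerate(scenarios):
        if "preset" not in sc and "scenario_yaml" not in sc:
            raise ConfigError("each scenario requires a 'preset' or 'scenario_yaml'")
        n_rep = int(sc.get("n_replicates", 0))
        if n_rep < 1:
            continue
        truth, structure = _resolve_scenario(
            {k: sc[k] for k in ("preset", "scenario_yaml") if k in sc}
        )
        kind = sc.get("kind", "type1")
        sub_seed = (seed + 7919 * i) % (2**31)
        if kind == "type1":
            df = type_one_error_study(
                truth,
                structure,
                n_replicates=n_rep,
                n_trios=sc.get("n_trios"),
                alpha=float(sc.get("alpha", 0.05)),
                seed=sub_seed,
                snp=sc.get("snp", TEST_SNP),
                analyses=tuple(sc.get("analyses", ("unadjusted", "sra", "eegm"))),
            )
        elif kind == "recovery":
            df = parameter_recovery_study(
                truth,
                structure,
                n_replicates=n_rep,
                n_trios=sc.get("n_trios"),
                seed=sub_seed,
                snp=sc.get("snp", CAUSAL_SNP),
            )
        else:
            raise ConfigError(f"unknown scenario kind {kind!r}")
        df.insert(0, "scenario", sc.get("name", f"scenario{i}"))
        frames.append(df)
    summary = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "simstudy.tsv", sep="\t", index=False)
    return summary
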