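"""End-to-end pipeline: simulate/read -> covariate selection -> scan -> thresholds.

``run_pipeline`` ties the stages together under one master seed: build or
load a cohort, select covariates by forward stepwise entry, scan all markers
for the four contrasts, derive permutation FWER thresholds, flag markers
below threshold and (optionally) attach deep single-marker permutation
p-values to the flagged ones.  Every stage writes a TSV with deterministic
column order and fixed numeric formatting, plus a plain-text log recording
the seed and the individual/marker counts at every step.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from admixscan import __version__
from admixscan.io import CohortBundle, format_pvalues, read_cohort, write_cohort
from admixscan.models import CovariateSet, stepwise_covariates
from admixscan.scan import (
    CONTRASTS,
    STATISTICS,
    PermutationPlan,
    deep_permutation_p,
    fwer_thresholds,
    scan_markers,
)
from admixscan.simulate import (
    PhenotypeModelSpec,
    SwitchModel,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


def load_config(source) -> dict:
    """Load a pipeline configuration from a YAML file, path or mapping."""
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def phenotype_spec_from_config(cfg: Mapping) -> PhenotypeModelSpec:
    """Build a generating-model spec from a config block.

    YAML parses an unquoted ``null`` as None, so a missing/None model name
    means the null (covariates-only) trait model.
    """
    cfg = dict(cfg)
    model = cfg.pop("model", None)
    return PhenotypeModelSpec(model="null" if model is None else str(model), **cfg)


def cohort_from_config(cfg: Mapping, seed=None) -> CohortBundle:
    """Simulate a cohort from a config ``simulate`` block."""
    switch = SwitchModel(
        T=int(cfg.get("T", 12)),
        L=float(cfg.get("L", 224.6)),
        proportions=tuple(cfg.get("proportions", (0.49, 0.45, 0.06))),
    )
    spec = phenotype_spec_from_config(cfg.get("phenotype", {"sigma": 0.15, "intercept": 4.1}))
    return simulate_cohort(
        spec,
        n_individuals=int(cfg.get("n_individuals", 132)),
        n_markers=int(cfg.get("n_markers", 2000)),
        switch_model=switch,
        seed=seed,
    )


def run_pipeline(config, out_dir, seed: int = 0) -> dict:
    """Execute the full scan pipeline; returns the in-memory stage results.

    ``config`` is a mapping or YAML path with optional blocks ``simulate``
    (or ``cohort``: a directory to read), ``covariates`` (stepwise
    ``candidates`` or a ``fixed`` list), ``permutations`` (``n``, ``fwer``)
    and ``deep`` (``enabled``, ``n``, ``statistic``).  All randomness derives
    from ``seed`` through spawned substreams, recorded in the log.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"admixscan {__version__}", f"master seed: {seed}"]
    ss = np.random.SeedSequence(seed)
    sim_ss, perm_ss, deep_ss = ss.spawn(3)

    if "simulate" in cfg:
        cohort = cohort_from_config(cfg["simulate"], seed=sim_ss)
        write_cohort(cohort, out / "cohort")
        log_lines.append("cohort: simulated")
    elif "cohort" in cfg:
        cohort = read_cohort(cfg["cohort"])
        log_lines.append(f"cohort: read from {cfg['cohort']}")
    else:
        raise ValueError("config must contain a 'simulate' or 'cohort' block")
    log_lines.append(
        f"cohort size: {cohort.n_individuals} individuals x {cohort.n_markers} markers"
    )

    trait = cfg.get("trait", "trait")
    cov_cfg = cfg.get("covariates", {})
    base = CovariateSet(frame=cohort.phenotypes[["ga_N", "ga_A"]])
    if "fixed" in cov_cfg:
        covariates = list(cov_cfg["fixed"])
        log_lines.append(f"covariates (fixed): {covariates}")
    else:
        candidates = [
            c for c in cov_cfg.get("candidates", ("sex", "age", "med"))
            if c in cohort.phenotypes.columns
        ]
        selected = stepwise_covariates(
            cohort.phenotypes[candidates], cohort.log_trait(trait), base,
            alpha=float(cov_cfg.get("alpha", 0.05)),
        )
        covariates = [c for c in selected.columns if c not in ("ga_N", "ga_A")]
        log_lines.append(f"covariates (stepwise from {candidates}): {covariates}")

    results = scan_markers(cohort, trait=trait, covariates=covariates)
    p_cols = [c for c in results.columns if c.endswith("_p") or c.endswith("_stat")]
    format_pvalues(results, p_cols).to_csv(out / "scan.tsv", sep="\t")
    log_lines.append(f"scan: {len(results)} markers tested")

    perm_cfg = cfg.get("permutations", {})
    plan = PermutationPlan(
        n_permutations=int(perm_cfg.get("n", 1000)),
        fwer=float(perm_cfg.get("fwer", 0.05)),
        seed=int(perm_ss.generate_state(1)[0] % (2**31)),
    )
    thr = fwer_thresholds(cohort, trait=trait, covariates=covariates, plan=plan)
    format_pvalues(thr.thresholds, list(STATISTICS)).to_csv(out / "thresholds.tsv", sep="\t")
    log_lines.append(
        f"thresholds: {plan.n_permutations} permutations, FWER {plan.fwer}, "
        f"permutation seed {plan.seed}"
    )

    flagged_rows = []
    for contrast in CONTRASTS:
        for statistic in STATISTICS:
            pvals = results[f"{contrast}_{statistic}_p"]
            cutoff = float(thr.thresholds.loc[contrast, statistic])
            for marker in results.index[pvals < cutoff]:
                flagged_rows.append(
                    {
                        "marker": marker,
                        "contrast": contrast,
                        "statistic": statistic,
                        "p_value": float(pvals[marker]),
                        "threshold": cutoff,
                    }
                )
    flagged = pd.DataFrame(
        flagged_rows, columns=["marker", "contrast", "statistic", "p_value", "threshold"]
    )

    deep_cfg = cfg.get("deep", {})
    if deep_cfg.get("enabled", False) and len(flagged):
        n_deep = int(deep_cfg.get("n", 100_000))
        deep_seed = int(deep_ss.generate_state(1)[0] % (2**31))
        deep_p = [
            deep_permutation_p(
                cohort, trait, row["marker"], contrast=row["contrast"],
                statistic=row["statistic"], n_perm=n_deep, seed=deep_seed,
                covariates=covariates,
            )
            for _, row in flagged.iterrows()
        ]
        flagged["deep_permutation_p"] = deep_p
        log_lines.append(f"deep permutation: {n_deep} permutations per flagged marker")
    num_cols = [c for c in ("p_value", "threshold", "deep_permutation_p") if c in flagged]
    format_pvalues(flagged, num_cols).to_csv(out / "flagged.tsv", sep="\t", index=False)
    log_lines.append(f"flagged markers: {len(flagged)}")

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "cohort": cohort,
        "scan": results,
        "thresholds": thr,
        "flagged": flagged,
        "covariates": covariates,
        "log": log_lines,
    }


__all__ = ["cohort_from_config", "load_config", "phenotype_spec_from_config", "run_pipeline"]
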