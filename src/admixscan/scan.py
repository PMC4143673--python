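"""Marker scan, permutation thresholds and type-I-error harness.

At every marker four nested-model contrasts are evaluated for both the Wald
and the likelihood-ratio statistic:

* admixture                     -- M3 vs M1 (df = number of non-reference
                                   diplotype categories present),
* association                   -- M2 vs M1 (df = 1),
* association adjusted for
  admixture                     -- M4 vs M3 (df = number of ancestry strata),
* combined admixture and/or
  association                   -- M4 vs M1 (df = sum of the two above).

Family-wise error across markers is controlled empirically: whole-cohort
permutations shuffle the individual rows of (trait, global ancestry,
covariates) jointly against the fixed (genotype, local ancestry) rows, the
scan-wide minimum p-value is recorded per permutation, and the FWER-alpha
threshold is the alpha-quantile of that min-p distribution.

The scan kernel residualizes the marker design blocks against the permuted
covariate block (Frisch-Waugh-Lovell), so each permutation costs one thin QR
plus batched small Gram solves; all four model RSS values per marker follow
from sub-blocks of one Gram matrix.  Both statistics derive from the RSS
pair of each contrast: LRT = n log(RSS_red / RSS_full) and
Wald = (RSS_red - RSS_full)(n - p_full)/RSS_full, identities of Gaussian OLS
that tests verify against explicit model fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from admixscan.io import CohortBundle
from admixscan.models import CovariateSet, ModelId, build_design, fit_ols, lrt

logger = logging.getLogger(__name__)

CONTRASTS = ("admixture", "association", "association_adj_admixture", "combined")
STATISTICS = ("lrt", "wald")

_CATEGORY_ORDER = ("EE", "EN", "EA", "NN", "NA", "AA")


# --------------------------------------------------------------------------
# design preparation


@dataclass(frozen=True)
class _Group:
    """Markers sharing one retained-column signature, stacked for batch solves."""

    idx: np.ndarray          # marker positions in the scan order
    Zstack: np.ndarray       # (G, n, k) marker design blocks
    Zmat: np.ndarray         # (n, G*k) flattened view for GEMMs
    gram0: np.ndarray        # (G, k, k) unresidualized Gram matrices
    d: int                   # leading columns: diplotype dummies
    m: int                   # trailing columns: g x D stratum slopes
    columns: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.d + self.m


@dataclass(frozen=True)
class _Blocks:
    """Fixed (genotype, local ancestry) side of the scan."""

    groups: tuple[_Group, ...]
    G: np.ndarray            # (n, M) dosages
    gg0: np.ndarray          # (M,) raw dosage sums of squares
    d_per_marker: np.ndarray
    m_per_marker: np.ndarray
    markers: pd.Index
    n: int

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _prune_against_intercept(Z: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of columns of Z independent of the intercept and each other."""
    basis = np.full((n, 1), 1.0 / np.sqrt(n))
    keep = np.zeros(Z.shape[1], dtype=bool)
    for j in range(Z.shape[1]):
        col = Z[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(np.linalg.norm(col), 1.0):
            keep[j] = True
            basis = np.column_stack([basis, resid / norm])
    return keep


def _marker_blocks(cohort: CohortBundle) -> _Blocks:
    geno = cohort.genotypes.to_numpy(dtype=float)
    cats = cohort.diplotypes.to_numpy(dtype=object)
    n, M = geno.shape
    by_key: dict[tuple, list] = {}
    d_per = np.zeros(M, dtype=int)
    m_per = np.zeros(M, dtype=int)
    for j in range(M):
        cj = cats[:, j]
        gj = geno[:, j]
        cols: list[np.ndarray] = []
        names: list[str] = []
        n_dummies = 0
        for cat in _CATEGORY_ORDER:
            ind = (cj == cat).astype(float)
            if cat != "EE" and ind.any():
                cols.append(ind)
                names.append(f"D_{cat}")
                n_dummies += 1
        for cat in _CATEGORY_ORDER:
            ind = cj == cat
            if ind.any():
                cols.append(gj * ind)
                names.append(f"gxD_{cat}")
        Z = np.column_stack(cols) if cols else np.empty((n, 0))
        keep = _prune_against_intercept(Z, n)
        d_j = int(keep[:n_dummies].sum())
        m_j = int(keep[n_dummies:].sum())
        kept_names = tuple(nm for nm, k in zip(names, keep) if k)
        key = (kept_names[:d_j], kept_names[d_j:])
        by_key.setdefault(key, []).append((j, Z[:, keep]))
        d_per[j], m_per[j] = d_j, m_j
    groups = []
    for (dnames, gxnames), members in by_key.items():
        idx = np.array([j for j, _ in members])
        Zstack = np.stack([Z for _, Z in members]) if members[0][1].shape[1] else None
        if Zstack is None or Zstack.shape[2] == 0:
            continue  # no marker columns at all: every model collapses to M1
        groups.append(
            _Group(
                idx=idx,
                Zstack=Zstack,
                Zmat=np.ascontiguousarray(
                    Zstack.transpose(1, 0, 2).reshape(n, -1)
                ),
                gram0=np.einsum("gnk,gnl->gkl", Zstack, Zstack),
                d=len(dnames),
                m=len(gxnames),
                columns=dnames + gxnames,
            )
        )
    return _Blocks(
        groups=tuple(groups),
        G=geno,
        gg0=(geno * geno).sum(axis=0),
        d_per_marker=d_per,
        m_per_marker=m_per,
        markers=cohort.markers,
        n=n,
    )


def _covariate_matrix(
    cohort: CohortBundle, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    names = ["ga_N", "ga_A", *covariates]
    missing = [c for c in names if c not in cohort.phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table missing covariate columns {missing}")
    frame = cohort.phenotypes[names]
    C = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
    return C, ["const", *names]


def _prepare(cohort: CohortBundle, trait: str, covariates: Sequence[str]):
    y = cohort.log_trait(trait)
    C, names = _covariate_matrix(cohort, covariates)
    if np.isnan(C).any():
        keep = ~np.isnan(C).any(axis=1)
        logger.info("dropping %d individual(s) with missing covariates", int((~keep).sum()))
        sub = CohortBundle(
            genotypes=cohort.genotypes.loc[keep],
            diplotypes=cohort.diplotypes.loc[keep],
            marker_map=cohort.marker_map,
            phenotypes=cohort.phenotypes.loc[keep],
            truth=cohort.truth,
        )
        return _prepare(sub, trait, covariates)
    blocks = _marker_blocks(cohort)
    return y, C, names, blocks


# --------------------------------------------------------------------------
# RSS kernel


def _batched_solve(gram: np.ndarray, v: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(gram, v[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(v)
        for i in range(gram.shape[0]):
            out[i] = np.linalg.lstsq(gram[i], v[i], rcond=None)[0]
        return out


def _rss_arrays(blocks: _Blocks, C: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """RSS of models M1..M4 at every marker for one (covariate, trait) row order."""
    n, c = C.shape
    Q, _ = np.linalg.qr(C)
    Qty = Q.T @ y
    ytilde = y - Q @ Qty
    rss1 = float(ytilde @ ytilde)
    M = blocks.n_markers
    rss2 = np.full(M, np.nan)
    rss3 = np.full(M, rss1)
    rss4 = np.full(M, rss1)
    # association model: single dosage column, residualized against C
    QtG = Q.T @ blocks.G
    gsq = blocks.gg0 - np.einsum("cm,cm->m", QtG, QtG)
    gty = blocks.G.T @ ytilde
    ok = gsq > 1e-10 * np.maximum(blocks.gg0, 1.0)
    rss2[ok] = rss1 - gty[ok] ** 2 / gsq[ok]
    floor = 1e-12 * max(rss1, 1.0)
    for grp in blocks.groups:
        G_, k = grp.Zstack.shape[0], grp.k
        QtZ = (Q.T @ grp.Zmat).reshape(c, G_, k)
        gram = grp.gram0 - np.einsum("cgk,cgl->gkl", QtZ, QtZ)
        v = (grp.Zmat.T @ ytilde).reshape(G_, k)
        sol = _batched_solve(gram, v)
        rss4[grp.idx] = rss1 - np.einsum("gk,gk->g", v, sol)
        if grp.d > 0:
            dd = grp.d
            sol_d = _batched_solve(gram[:, :dd, :dd], v[:, :dd])
            rss3[grp.idx] = rss1 - np.einsum("gk,gk->g", v[:, :dd], sol_d)
    np.clip(rss2, floor, None, out=rss2)
    np.clip(rss3, floor, None, out=rss3)
    np.clip(rss4, floor, None, out=rss4)
    return {"rss1": rss1, "rss2": rss2, "rss3": rss3, "rss4": rss4, "n_cov": c}


def _contrast_frames(
    blocks: _Blocks, rss: dict, n: int
) -> dict[str, dict[str, np.ndarray]]:
    """Per-contrast statistic/df/p arrays (NaN where a contrast is undefined)."""
    c = rss["n_cov"]
    d = blocks.d_per_marker.astype(float)
    m = blocks.m_per_marker.astype(float)
    rss1, rss2, rss3, rss4 = rss["rss1"], rss["rss2"], rss["rss3"], rss["rss4"]
    spec = {
        "admixture": (np.full_like(rss3, rss1), rss3, d, c + d, d >= 1),
        "association": (np.full_like(rss2, rss1), rss2, np.ones_like(d), c + 1,
                        np.isfinite(rss2)),
        "association_adj_admixture": (rss3, rss4, m, c + d + m, m >= 1),
        "combined": (np.full_like(rss4, rss1), rss4, d + m, c + d + m, (d + m) >= 1),
    }
    out = {}
    for name, (red, full, df, p_full, valid) in spec.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            lrt_stat = np.maximum(n * np.log(red / full), 0.0)
            wald_stat = np.maximum((red - full) * (n - p_full) / full, 0.0)
            p_lrt = stats.chi2.sf(lrt_stat, df)
            p_wald = stats.chi2.sf(wald_stat, df)
        bad = ~valid
        for arr in (lrt_stat, wald_stat, p_lrt, p_wald):
            arr[bad] = np.nan
        out[name] = {
            "lrt_stat": lrt_stat, "lrt_p": p_lrt,
            "wald_stat": wald_stat, "wald_p": p_wald,
            "df": df, "valid": valid,
        }
    return out


def _min_p(frames: dict, statistic: str) -> np.ndarray:
    """Scan-wide minimum p per contrast; undefined markers count as p = 1."""
    return np.array(
        [np.nanmin(np.where(np.isfinite(f[f"{statistic}_p"]), f[f"{statistic}_p"], 1.0))
         for f in frames.values()]
    )


# --------------------------------------------------------------------------
# public operations


def scan_markers(
    cohort: CohortBundle,
    trait: str = "trait",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Four Wald/LRT contrasts at every marker of a cohort.

    Returns one row per marker with the bp position, then
    ``<contrast>_<statistic>_{stat,p}`` and ``<contrast>_df`` columns, and a
    ``flags`` column marking skipped contrasts (e.g. a monomorphic marker has
    no association contrast but keeps its admixture contrast).
    """
    y, C, _, blocks = _prepare(cohort, trait, covariates)
    rss = _rss_arrays(blocks, C, y)
    frames = _contrast_frames(blocks, rss, blocks.n)
    out = pd.DataFrame(index=blocks.markers)
    out["bp"] = cohort.marker_map.loc[blocks.markers, "bp"].to_numpy()
    flags = np.array([""] * blocks.n_markers, dtype=object)
    for name, f in frames.items():
        out[f"{name}_df"] = f["df"].astype(int)
        for statistic in STATISTICS:
            out[f"{name}_{statistic}_stat"] = f[f"{statistic}_stat"]
            out[f"{name}_{statistic}_p"] = f[f"{statistic}_p"]
        skipped = ~f["valid"]
        flags[skipped] = np.where(
            flags[skipped] == "", f"skip:{name}", flags[skipped] + f";skip:{name}"
        )
    out["flags"] = flags
    return out


@dataclass(frozen=True)
class PermutationPlan:
    """Joint row permutation of (trait, global ancestry, covariates).

    Each permutation is a bijection of individuals applied to the whole
    phenotype-side row, so a trait value never decouples from its own
    covariates; the genotype and local-ancestry rows stay fixed.
    """

    n_permutations: int
    fwer: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0 < self.fwer < 1:
            raise ValueError("target family-wise error rate must lie in (0, 1)")


@dataclass(frozen=True)
class ThresholdResult:
    """Permutation min-p distributions and the derived per-contrast thresholds."""

    thresholds: pd.DataFrame         # index: contrast, columns: lrt, wald
    min_p: dict[str, pd.DataFrame] = field(repr=False)
    plan: PermutationPlan = field(default=None)


def fwer_thresholds(
    cohort: CohortBundle,
    trait: str = "trait",
    covariates: Sequence[str] = (),
    plan: PermutationPlan = PermutationPlan(1000, 0.05, 0),
) -> ThresholdResult:
    """Per-contrast FWER p-value thresholds from whole-scan permutations.

    For each permutation the full scan is recomputed and the minimum p-value
    across markers recorded per contrast (separately for Wald and LRT); the
    threshold is the empirical ``plan.fwer``-quantile (type-7, linear
    interpolation) of each min-p distribution.
    """
    if plan.n_permutations < 100:
        raise ValueError("threshold estimation requires at least 100 permutations")
    y, C, _, blocks = _prepare(cohort, trait, covariates)
    rng = np.random.default_rng(plan.seed)
    n = blocks.n
    minp = {s: np.empty((plan.n_permutations, len(CONTRASTS))) for s in STATISTICS}
    for b in range(plan.n_permutations):
        perm = rng.permutation(n)
        rss = _rss_arrays(blocks, C[perm], y[perm])
        frames = _contrast_frames(blocks, rss, n)
        for s in STATISTICS:
            minp[s][b] = _min_p(frames, s)
    thresholds = pd.DataFrame(
        {s: np.quantile(minp[s], plan.fwer, axis=0) for s in STATISTICS},
        index=pd.Index(CONTRASTS, name="contrast"),
    )
    min_p = {
        s: pd.DataFrame(minp[s], columns=CONTRASTS) for s in STATISTICS
    }
    return ThresholdResult(thresholds=thresholds, min_p=min_p, plan=plan)


def deep_permutation_p(
    cohort: CohortBundle,
    trait: str,
    marker: str,
    contrast: str = "combined",
    statistic: str = "wald",
    n_perm: int = 10_000,
    seed: int | None = None,
    covariates: Sequence[str] = (),
    batch: int = 500,
) -> float:
    """Deep single-marker permutation p-value, computed streaming.

    p-hat = (r + 1)/(n_perm + 1) where r counts permuted statistics at least
    as large as the observed one; only the running count is stored, so very
    deep runs need constant memory.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    sub = CohortBundle(
        genotypes=cohort.genotypes[[marker]],
        diplotypes=cohort.diplotypes[[marker]],
        marker_map=cohort.marker_map.loc[[marker]],
        phenotypes=cohort.phenotypes,
        truth=cohort.truth,
    )
    y, C, _, blocks = _prepare(sub, trait, covariates)
    n = blocks.n
    key = f"{statistic}_stat"
    observed = _contrast_frames(blocks, _rss_arrays(blocks, C, y), n)[contrast][key][0]
    if not np.isfinite(observed):
        raise ValueError(f"contrast {contrast!r} undefined at marker {marker!r}")
    rng = np.random.default_rng(seed)
    r = 0
    done = 0
    while done < n_perm:
        todo = min(batch, n_perm - done)
        for _ in range(todo):
            perm = rng.permutation(n)
            stat = _contrast_frames(
                blocks, _rss_arrays(blocks, C[perm], y[perm]), n
            )[contrast][key][0]
            if np.isfinite(stat) and stat >= observed:
                r += 1
        done += todo
    return (r + 1) / (n_perm + 1)


def heterogeneity_test(
    cohort: CohortBundle,
    trait: str,
    marker: str,
    covariates: Sequence[str] = (),
) -> tuple[float, int, float]:
    """LRT of heterogeneous vs homogeneous genotype effects (M4 vs M5).

    df equals the number of ancestry strata minus one; with a single stratum
    the test is undefined and ``(0.0, 0, nan)`` is returned as an explicit
    skip.
    """
    y = cohort.log_trait(trait)
    C, names = _covariate_matrix(cohort, covariates)
    frame = pd.DataFrame(C[:, 1:], columns=names[1:], index=cohort.phenotypes.index)
    covset = CovariateSet(frame=frame)
    g = cohort.genotypes[marker].to_numpy(dtype=float)
    cats = cohort.diplotypes[marker].to_numpy(dtype=object)
    X4, _ = build_design(ModelId.M4_heterogeneous, g, cats, covset)
    X5, _ = build_design(ModelId.M5_homogeneous, g, cats, covset)
    fit4 = fit_ols(X4, y)
    fit5 = fit_ols(X5, y)
    n_strata = sum(c.startswith("gxD_") for c in fit4.columns)
    if n_strata <= 1:
        return 0.0, 0, float("nan")
    return lrt(fit4, fit5)


def bonferroni_adjust(p: float, n_markers: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * n_markers)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1]; got {p}")
    if n_markers < 1:
        raise ValueError("n_markers must be at least 1")
    return min(1.0, p * n_markers)


def type1_harness(
    cohort: CohortBundle,
    thresholds: pd.DataFrame,
    n_datasets: int = 200,
    seed: int | None = None,
    covariates: Sequence[str] = ("sex", "age"),
    contrast: str = "combined",
    spec=None,
) -> pd.DataFrame:
    """Empirical FWER of a contrast over replicated genotype-independent traits.

    Each replicate draws a fresh null trait (same individuals, covariate
    effects and residual scale as the template cohort's generating model; new
    Gaussian noise), reruns the scan, and retains the scan-wide minimum
    p-value.  The empirical FWER is the fraction of replicates whose min-p
    falls below the corresponding threshold, reported with its binomial
    standard error.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if spec is None:
        spec = (cohort.truth or {}).get("phenotype_model")
    if spec is None or spec.model != "null":
        raise ValueError("type-I harness requires a cohort generated under a null trait model")
    y0, C, names, blocks = _prepare(cohort, "trait", covariates)
    n = blocks.n
    # fixed part of the replicate traits: intercept + covariate effects
    lp = np.full(n, float(spec.intercept))
    for col, beta in spec.beta_covariates.items():
        lp += beta * cohort.phenotypes[col].to_numpy(dtype=float)
    for col, beta in spec.beta_global.items():
        lp += beta * cohort.phenotypes[col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    ci = CONTRASTS.index(contrast)
    minp = {s: np.empty(n_datasets) for s in STATISTICS}
    for b in range(n_datasets):
        y = lp + rng.normal(0.0, spec.sigma, size=n)
        frames = _contrast_frames(blocks, _rss_arrays(blocks, C, y), n)
        for s in STATISTICS:
            minp[s][b] = _min_p(frames, s)[ci]
    rows = []
    for s in STATISTICS:
        thr = float(thresholds.loc[contrast, s])
        hits = int((minp[s] < thr).sum())
        fwer = hits / n_datasets
        rows.append(
            {
                "statistic": s,
                "contrast": contrast,
                "threshold": thr,
                "empirical_fwer": fwer,
                "binomial_se": float(np.sqrt(max(fwer * (1 - fwer), 1e-12) / n_datasets)),
                "n_datasets": n_datasets,
            }
        )
    return pd.DataFrame(rows).set_index("statistic")


__all__ = [
    "CONTRASTS",
    "STATISTICS",
    "PermutationPlan",
    "ThresholdResult",
    "bonferroni_adjust",
    "deep_permutation_p",
    "fwer_thresholds",
    "heterogeneity_test",
    "scan_markers",
    "type1_harness",
]
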