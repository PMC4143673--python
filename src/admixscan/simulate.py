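"""Synthetic 3-way admixed cohorts.

The generator emulates the structure the scan assumes: each haplotype is an
ancestry mosaic produced by a Poisson breakpoint process (rate T/100 per cM,
T generations since admixture) with segment ancestries drawn independently
from the cohort's global proportions; genotypes are Bernoulli draws from
ancestry-specific allele frequencies (a Balding-Nichols model around a shared
ancestral frequency); traits are log-normal, i.e. a linear model on the log
scale plus Gaussian noise, exponentiated.

Under this mosaic the expected number of *observed* diploid ancestry switches
in a 2-way scenario is 2 haplotypes x (T/100) L breakpoints x 2 z (1 - z)
chance a breakpoint changes ancestry = 0.04 T L z (1 - z), matching the
closed form used to benchmark local-ancestry estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from admixscan.io import CohortBundle

ANCESTRIES = ("E", "N", "A")

_PAIR_CATEGORY = np.array(
    [["EE", "EN", "EA"], ["EN", "NN", "NA"], ["EA", "NA", "AA"]], dtype=object
)

PHENOTYPE_MODELS = ("null", "association", "admixture", "heterogeneous", "homogeneous")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SwitchModel:
    """Admixture history: T generations, chromosome length L (cM), global proportions.

    ``proportions`` is one probability per ancestral population, in the order
    (E, N, A) for 3-way scenarios (any length >= 1 is accepted for k-way
    mosaics); they must sum to 1.
    """

    T: int
    L: float
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T (generations since admixture) must be >= 1; got {self.T}")
        if self.L <= 0:
            raise ValueError(f"chromosome length L must be positive; got {self.L}")
        props = np.asarray(self.proportions, dtype=float)
        if props.size == 0 or np.any(props < 0) or np.any(props > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1; got sum {props.sum()!r}")
        object.__setattr__(self, "proportions", tuple(float(p) for p in props))


#: Study-condition defaults: 12 generations since admixture, chromosome-3
#: genetic length 224.6 cM, mean global proportions (0.49 E, 0.45 N, 0.06 A).
DEFAULT_SWITCH_MODEL = SwitchModel(T=12, L=224.6, proportions=(0.49, 0.45, 0.06))


@dataclass(frozen=True)
class AncestralFrequencies:
    """Per-population minor-allele frequencies and marker genetic positions.

    ``freqs`` is a (markers x {E, N, A}) table with entries strictly inside
    (0, 1); ``positions_cm`` are non-decreasing genetic positions.  Stands in
    for phased reference panels: the simulator only needs the frequency of
    the minor allele in each ancestral population.
    """

    freqs: pd.DataFrame
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        missing = [p for p in ANCESTRIES if p not in self.freqs.columns]
        if missing:
            raise ValueError(f"frequency table missing populations {missing}")
        vals = self.freqs[list(ANCESTRIES)].to_numpy(dtype=float)
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        pos = np.asarray(self.positions_cm, dtype=float)
        if pos.shape != (len(self.freqs),):
            raise ValueError("one genetic position per marker required")
        if np.any(np.diff(pos) < 0):
            raise ValueError("genetic positions must be non-decreasing")
        object.__setattr__(self, "positions_cm", pos)

    @property
    def n_markers(self) -> int:
        return len(self.freqs)

    @classmethod
    def balding_nichols(
        cls,
        n_markers: int,
        L: float,
        seed=None,
        divergence: Mapping[str, float] | None = None,
        ancestral_range: tuple[float, float] = (0.1, 0.9),
    ) -> "AncestralFrequencies":
        """Draw per-population frequencies around a shared ancestral frequency.

        For each marker an ancestral frequency p0 ~ Uniform(*ancestral_range*)
        is drawn, then each population's frequency comes from
        Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with a per-population divergence F
        (defaults E: 0.05, N: 0.05, A: 0.10, giving expected pairwise
        differentiation of roughly 0.10 for E-N and 0.15 for contrasts with
        A).  Frequencies are clipped to (0.01, 0.99) so no allele is fixed;
        marker positions form an even grid over [0, L].
        """
        if n_markers < 1:
            raise ValueError("need at least one marker")
        rng = _rng(seed)
        F = {"E": 0.05, "N": 0.05, "A": 0.10}
        if divergence:
            F.update(divergence)
        p0 = rng.uniform(*ancestral_range, size=n_markers)
        cols = {}
        for pop in ANCESTRIES:
            f = F[pop]
            a = p0 * (1 - f) / f
            b = (1 - p0) * (1 - f) / f
            cols[pop] = np.clip(rng.beta(a, b), 0.01, 0.99)
        markers = [f"m{i + 1:05d}" for i in range(n_markers)]
        freqs = pd.DataFrame(cols, index=pd.Index(markers, name="marker"))
        positions = np.linspace(0.0, L, n_markers)
        return cls(freqs=freqs, positions_cm=positions)


def simulate_mosaic(
    model: SwitchModel,
    positions_cm: Sequence[float] | np.ndarray,
    n_haplotypes: int,
    seed=None,
) -> np.ndarray:
    """Piecewise-constant ancestry mosaics along a chromosome.

    Each haplotype receives Poisson(T L / 100) breakpoints placed uniformly on
    [0, L]; segment ancestries are i.i.d. draws from the global proportions;
    the ancestry at each marker is read off its genetic position.  Returns an
    ``(n_haplotypes, n_markers)`` int8 array of population indices
    (0=E, 1=N, 2=A).
    """
    pos = np.asarray(positions_cm, dtype=float)
    if pos.size == 0:
        raise ValueError("empty marker map: cannot place a mosaic")
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker genetic positions must be non-decreasing")
    if pos[-1] > model.L + 1e-9:
        raise ValueError(
            f"marker positions extend to {pos[-1]} cM, beyond chromosome length {model.L}"
        )
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    rate = model.T * model.L / 100.0
    if rate <= 0:
        raise ValueError("breakpoint rate T*L/100 must be positive")
    rng = _rng(seed)
    props = np.asarray(model.proportions)
    k = props.size
    out = np.empty((n_haplotypes, pos.size), dtype=np.int8)
    for h in range(n_haplotypes):
        n_bp = rng.poisson(rate)
        breakpoints = np.sort(rng.uniform(0.0, model.L, size=n_bp))
        segments = rng.choice(k, size=n_bp + 1, p=props)
        out[h] = segments[np.searchsorted(breakpoints, pos, side="right")]
    return out


def simulate_genotypes(
    mosaic: np.ndarray,
    freqs: AncestralFrequencies,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype dosages and true diplotype categories from a mosaic.

    ``mosaic`` has shape ``(n_individuals, 2, n_markers)`` (population index
    per haplotype per marker).  Each haplotype allele is Bernoulli with the
    minor-allele frequency of that haplotype's local ancestry; the dosage is
    the sum over the two haplotypes.  Returns ``(dosages, categories)`` with
    shapes ``(n, n_markers)`` (float) and ``(n, n_markers)`` (two-letter
    category strings).
    """
    hap = np.asarray(mosaic)
    if hap.ndim != 3 or hap.shape[1] != 2:
        raise ValueError("mosaic must have shape (n_individuals, 2, n_markers)")
    if hap.shape[2] != freqs.n_markers:
        raise ValueError(
            f"mosaic covers {hap.shape[2]} markers but frequencies cover {freqs.n_markers}"
        )
    rng = _rng(seed)
    ftab = freqs.freqs[list(ANCESTRIES)].to_numpy(dtype=float).T  # (3, M)
    p_hap = ftab[hap, np.arange(hap.shape[2])]  # (n, 2, M)
    alleles = rng.random(p_hap.shape) < p_hap
    dosages = alleles.sum(axis=1).astype(float)
    categories = _PAIR_CATEGORY[hap[:, 0, :], hap[:, 1, :]]
    return dosages, categories


@dataclass(frozen=True)
class PhenotypeModelSpec:
    """Generating model for a log-normal trait.

    ``model`` names which terms enter the log-scale linear predictor:

    * ``null``          -- intercept, global ancestry and covariates only;
    * ``association``   -- adds a shared dosage effect ``beta_g``;
    * ``admixture``     -- adds diplotype-category effects ``beta_dummies``
                           (EE is the reference, coefficient 0);
    * ``heterogeneous`` -- category effects plus per-category dosage slopes
                           ``beta_g_by_category``;
    * ``homogeneous``   -- category effects plus the shared slope ``beta_g``.

    Coefficients must be supplied exactly for the terms the named model
    contains.  ``sigma`` is the residual standard deviation on the log scale;
    ``causal_marker`` is the column index at which genotype / local-ancestry
    terms are evaluated.
    """

    model: str
    intercept: float = 0.0
    beta_global: Mapping[str, float] = field(default_factory=dict)
    beta_covariates: Mapping[str, float] = field(default_factory=dict)
    beta_dummies: Mapping[str, float] | None = None
    beta_g: float | None = None
    beta_g_by_category: Mapping[str, float] | None = None
    sigma: float = 0.1
    causal_marker: int | None = None

    def __post_init__(self) -> None:
        if self.model not in PHENOTYPE_MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {PHENOTYPE_MODELS}")
        if self.sigma < 0:
            raise ValueError("residual standard deviation must be non-negative")
        wants_dummies = self.model in ("admixture", "heterogeneous", "homogeneous")
        wants_shared_g = self.model in ("association", "homogeneous")
        wants_strat_g = self.model == "heterogeneous"
        if wants_dummies != (self.beta_dummies is not None):
            raise ValueError(f"model {self.model!r}: beta_dummies "
                             f"{'required' if wants_dummies else 'not allowed'}")
        if wants_shared_g != (self.beta_g is not None):
            raise ValueError(f"model {self.model!r}: beta_g "
                             f"{'required' if wants_shared_g else 'not allowed'}")
        if wants_strat_g != (self.beta_g_by_category is not None):
            raise ValueError(f"model {self.model!r}: beta_g_by_category "
                             f"{'required' if wants_strat_g else 'not allowed'}")
        if self.model != "null" and self.causal_marker is None:
            raise ValueError(f"model {self.model!r} requires a causal_marker index")


def simulate_phenotype(
    spec: PhenotypeModelSpec,
    genotypes,
    diplotypes,
    global_ancestry: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    seed=None,
) -> np.ndarray:
    """Trait values on the original (exponentiated) scale.

    The linear predictor is assembled on the log scale exactly per the named
    model, Gaussian noise with sd ``sigma`` is added, and the trait returned
    as ``exp(.)`` so a downstream log transform recovers the linear model.
    """
    geno = np.asarray(genotypes, dtype=float)
    dips = np.asarray(diplotypes, dtype=object)
    n = geno.shape[0]
    if dips.shape[0] != n or len(global_ancestry) != n:
        raise ValueError("genotypes, diplotypes and global ancestry must align on individuals")
    if covariates is not None and len(covariates) != n:
        raise ValueError("covariates must align on individuals")
    lp = np.full(n, float(spec.intercept))
    for col, beta in spec.beta_global.items():
        if col not in global_ancestry.columns:
            raise ValueError(f"global-ancestry column {col!r} not available")
        lp += beta * global_ancestry[col].to_numpy(dtype=float)
    for col, beta in spec.beta_covariates.items():
        if covariates is None or col not in covariates.columns:
            raise ValueError(f"covariate {col!r} not available")
        lp += beta * covariates[col].to_numpy(dtype=float)
    if spec.model != "null":
        j = spec.causal_marker
        if not 0 <= j < geno.shape[1]:
            raise ValueError(f"causal marker index {j} out of range for {geno.shape[1]} markers")
        g = geno[:, j]
        cats = dips[:, j]
        if spec.beta_dummies is not None:
            effect = np.array([spec.beta_dummies.get(c, 0.0) for c in cats])
            lp += effect
        if spec.beta_g is not None:
            lp += spec.beta_g * g
        if spec.beta_g_by_category is not None:
            slopes = np.array([spec.beta_g_by_category.get(c, 0.0) for c in cats])
            lp += slopes * g
    noise = _rng(seed).normal(0.0, spec.sigma, size=n) if spec.sigma > 0 else 0.0
    return np.exp(lp + noise)


def _default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates: sex ~ Bernoulli(0.5), age ~ Uniform(20, 80), med ~ Bernoulli(0.3)."""
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.uniform(20.0, 80.0, size=n),
            "med": (rng.random(n) < 0.3).astype(float),
        }
    )


def simulate_cohort(
    spec: PhenotypeModelSpec,
    n_individuals: int = 132,
    n_markers: int = 2000,
    switch_model: SwitchModel = DEFAULT_SWITCH_MODEL,
    freqs: AncestralFrequencies | None = None,
    seed=None,
) -> CohortBundle:
    """Full synthetic cohort: mosaic, genotypes, covariates and trait.

    Defaults mirror the study conditions (132 unrelated individuals on a
    224.6-cM chromosome) with the marker count scaled to 2,000 for desk-scale
    runtime.  All randomness derives from ``seed``; the generating model and
    seed are recorded in the bundle's ``truth`` metadata.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_freq, rng_mosaic, rng_geno, rng_cov, rng_trait = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    if freqs is None:
        freqs = AncestralFrequencies.balding_nichols(n_markers, switch_model.L, seed=rng_freq)
    else:
        n_markers = freqs.n_markers
    hap = simulate_mosaic(
        switch_model, freqs.positions_cm, 2 * n_individuals, seed=rng_mosaic
    ).reshape(n_individuals, 2, n_markers)
    dosages, categories = simulate_genotypes(hap, freqs, seed=rng_geno)

    from admixscan.ancestry import global_from_local

    individuals = pd.Index([f"ind{i + 1:04d}" for i in range(n_individuals)], name="individual")
    markers = freqs.freqs.index
    genotypes = pd.DataFrame(dosages, index=individuals, columns=markers)
    diplotypes = pd.DataFrame(categories, index=individuals, columns=markers)
    ga = global_from_local(diplotypes)
    covariates = _default_covariates(n_individuals, rng_cov)
    covariates.index = individuals
    trait = simulate_phenotype(spec, dosages, categories, ga, covariates, seed=rng_trait)

    phenotypes = pd.concat(
        [pd.Series(trait, index=individuals, name="trait"), covariates, ga.set_axis(individuals)],
        axis=1,
    )
    bp = np.round(freqs.positions_cm * 1e6).astype(np.int64) + 1
    marker_map = pd.DataFrame(
        {"chrom": "3", "bp": bp, "cm": freqs.positions_cm}, index=markers
    )
    truth = {
        "phenotype_model": spec,
        "switch_model": switch_model,
        "seed": seed if isinstance(seed, int) else None,
    }
    return CohortBundle(
        genotypes=genotypes,
        diplotypes=diplotypes,
        marker_map=marker_map,
        phenotypes=phenotypes,
        truth=truth,
        haplotypes=hap,
    )


def simulate_null_cohort(
    n_individuals: int = 132,
    n_markers: int = 2000,
    seed=None,
    switch_model: SwitchModel = DEFAULT_SWITCH_MODEL,
    intercept: float = 4.1,
    beta_sex: float = 0.05,
    beta_age: float = 0.002,
    sigma: float = 0.15,
) -> CohortBundle:
    """Cohort whose trait is independent of genotype and local ancestry.

    The trait is log-normal around ``exp(intercept)`` (~60, a diastolic-
    blood-pressure-like level) with nonzero sex and age effects -- the
    configuration used for type-I-error assessment.  A zero residual standard
    deviation is rejected: a constant trait cannot be permuted or tested.
    """
    if sigma <= 0:
        raise ValueError("null cohort requires sigma > 0 (constant trait is degenerate)")
    spec = PhenotypeModelSpec(
        model="null",
        intercept=intercept,
        beta_covariates={"sex": beta_sex, "age": beta_age},
        sigma=sigma,
    )
    return simulate_cohort(
        spec,
        n_individuals=n_individuals,
        n_markers=n_markers,
        switch_model=switch_model,
        seed=seed,
    )


__all__ = [
    "ANCESTRIES",
    "DEFAULT_SWITCH_MODEL",
    "PHENOTYPE_MODELS",
    "AncestralFrequencies",
    "PhenotypeModelSpec",
    "SwitchModel",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_mosaic",
    "simulate_null_cohort",
    "simulate_phenotype",
]
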