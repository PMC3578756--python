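"""Replicate orchestration: simulations -> panels -> tests -> power.

A scale preset fixes the population size, panel sizes and test settings
while preserving the scaled mutational parameters (4N*mu = 100,
4N*mu_d = 10, 4N*r = 100) of the full-size model.  The ``desk`` preset
(N = 1000, panels of 150 cases / 150 controls — the upper 15% of a
population of 1000 is 150 individuals) is sized for single-machine runs
and is meant for ordering/calibration properties; the ``full`` preset is
the full-scale design (N = 20,000, panels of 3000/3000).

Power is the fraction of replicates with at least one marker (single-marker
scan, alpha = 1e-8) or a region statistic (alpha = 1e-6) reaching
significance; binomial Monte-Carlo standard errors accompany every
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SimParams
from .simcore import evolve
from .panels import CaseControlPanel, MarkerFilter, draw_case_control, ascertain_chip
from . import assoc

__all__ = [
    "ScalePreset",
    "DESK",
    "FULL",
    "PowerSummary",
    "replicate_rng_streams",
    "run_replicate",
    "run_grid",
    "power_table",
    "pvalue_ecdf",
    "top_hit_maf_distribution",
    "heritability_replicates",
]

# the full-scale grid of mean causative effect sizes
LAMBDA_GRID = (0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.125, 0.175, 0.25, 0.35, 0.5)


@dataclass(frozen=True)
class ScalePreset:
    """A miniature of the full-scale study design.

    The desk preset preserves the coalescent-scale parameters (theta,
    theta_d, rho) and the phenotypic-model constants (sigma_e, sigma_s)
    while shrinking N and the panel sizes; it is intended for
    ordering/calibration properties of the test statistics, not for exact
    full-scale power percentages.  For equilibrium heritability, which is
    sensitive to the balance of selection and drift, see
    ``h2_scaled_params`` (Ns-preserving rescaling).
    """

    name: str
    N: int
    theta: float
    theta_d: float
    rho: float
    n_cases: int
    n_controls: int
    n_perm: int
    esm_M: int
    ll_K: int
    sigma_s: float = 1.0
    sigma_e: float = 0.075

    def sim_params(self, lambda_effect: float, seed: int,
                   no_neutral: bool = False, rho: float | None = None) -> SimParams:
        return SimParams.from_scaled(
            N=self.N, theta=self.theta, theta_d=self.theta_d,
            rho=self.rho if rho is None else rho,
            lambda_effect=lambda_effect, seed=seed, no_neutral=no_neutral,
            sigma_e=self.sigma_e, sigma_s=self.sigma_s,
        )


_FULL_N = 20_000

DESK = ScalePreset(name="desk", N=1000, theta=100.0, theta_d=10.0, rho=100.0,
                   n_cases=150, n_controls=150, n_perm=1000, esm_M=50, ll_K=50)
FULL = ScalePreset(name="full", N=_FULL_N, theta=100.0, theta_d=10.0, rho=100.0,
                    n_cases=3000, n_controls=3000, n_perm=1000, esm_M=50, ll_K=250)


def h2_scaled_params(lambda_effect: float, N: int = 1000, N_full: int = _FULL_N,
                     theta_d: float = 10.0, rho: float = 100.0,
                     sigma_e: float = 0.075) -> SimParams:
    """Causative-only parameters for heritability experiments at reduced N.

    The equilibrium genetic variance reflects a balance between mutational
    input, drift and stabilizing selection.  Preserving theta_d alone makes
    reduced-N runs drift-dominated (variance far above the full-scale
    value); preserving the full-scale per-gamete mutation rate alone makes
    them drift-depleted (variance below it).  Shrinking sigma_s by
    sqrt(N / N_full) keeps the population-scaled selection strength
    (selection acts through 1/sigma_s^2, so N*s is invariant) alongside
    theta_d, which preserves both the drift-limited and selection-limited
    variance regimes and hence the heritability plateau.
    """
    return SimParams(
        N=N, mu_neutral=0.0, mu_causative=theta_d / (4.0 * N), r=rho / (4.0 * N),
        lambda_effect=lambda_effect, sigma_e=sigma_e,
        sigma_s=float(np.sqrt(N / N_full)), n_generations=8 * N,
    )


@dataclass(frozen=True)
class PowerSummary:
    lam: float
    test_name: str
    study_type: str
    n_replicates: int
    n_significant: int
    power: float
    se: float
    threshold: float


def replicate_rng_streams(base_seed: int, rep: int):
    """Independent generators (simulation, panel, permutations) for one
    replicate; the per-replicate entropy is replicate index XOR base seed."""
    ss = np.random.SeedSequence(entropy=base_seed ^ rep)
    sim, panel, perm = ss.spawn(3)
    return (np.random.default_rng(sim), np.random.default_rng(panel),
            np.random.default_rng(perm))


_STUDY = {"gwas": MarkerFilter(study_type="gwas"),
          "reseq": MarkerFilter(study_type="resequencing")}


def run_replicate(lam: float, preset: ScalePreset, base_seed: int, rep: int,
                  tests=("logistic", "esm", "mb", "ll"),
                  studies=("gwas", "reseq"),
                  rho: float | None = None,
                  panel: CaseControlPanel | None = None) -> list[dict]:
    """One full replicate: simulate, draw the panel, run the requested
    tests under each study design.  Returns tidy rows with the replicate's
    p-value per (test, study) — for the logistic scan, the smallest
    single-marker p in the region."""
    rng_sim, rng_panel, rng_perm = replicate_rng_streams(base_seed, rep)
    if panel is None:
        params = preset.sim_params(lam, seed=0, rho=rho)
        pop = evolve(params, rng=rng_sim)
        panel = draw_case_control(pop, preset.n_cases, preset.n_controls, rng_panel)
    rows = []
    for study in studies:
        flt = _STUDY[study]
        for test in tests:
            row = {"lambda": lam, "rep": rep, "test": test, "study": study}
            try:
                if test == "logistic":
                    pv = assoc.logistic_scan(panel, flt)
                    row["p"] = float(np.nanmin(pv)) if np.isfinite(pv).any() else np.nan
                    row["threshold"] = assoc.SINGLE_MARKER_ALPHA
                else:
                    if test == "esm":
                        t = assoc.ESMTest(panel, flt, assoc.ESMConfig(M=preset.esm_M))
                    elif test == "mb":
                        t = assoc.MadsenBrowningTest(panel, flt)
                    elif test == "ll":
                        # rarest K variants of the whole panel (no study
                        # filter): the test targets rare alleles directly
                        t = assoc.LiLealTest(panel, K=preset.ll_K)
                    else:
                        raise ValueError(f"unknown test {test!r}")
                    res = assoc.permutation_test(panel, t, n_perm=preset.n_perm,
                                                 rng=rng_perm)
                    row["p"] = res.p
                    row["z"] = res.z
                    row["threshold"] = assoc.REGION_ALPHA
            except ValueError:
                row["p"] = np.nan
                row["threshold"] = (assoc.SINGLE_MARKER_ALPHA if test == "logistic"
                                    else assoc.REGION_ALPHA)
            rows.append(row)
    return rows


def run_grid(lambdas, n_replicates: int, base_seed: int,
             preset: ScalePreset = DESK,
             tests=("logistic", "esm", "mb", "ll"),
             studies=("gwas", "reseq"), rho: float | None = None,
             progress: bool = False) -> pd.DataFrame:
    """Replicate p-values over a lambda grid (tidy DataFrame)."""
    rows = []
    for lam in lambdas:
        for rep in range(n_replicates):
            rows += run_replicate(lam, preset, base_seed, rep, tests=tests,
                                  studies=studies, rho=rho)
            if progress:
                print(f"lambda={lam} rep={rep} done", flush=True)
    return pd.DataFrame(rows)


def power_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(lambda, test, study) power with binomial standard errors.

    Replicates with missing p-values (e.g. numerically degenerate
    covariance in the multiple-marker test) count as non-significant,
    mirroring how an analyst without a p-value cannot declare significance.
    """
    out = []
    for (lam, test, study), grp in results.groupby(["lambda", "test", "study"]):
        thr = grp["threshold"].iloc[0]
        n = len(grp)
        k = int((grp["p"] <= thr).sum())
        pw = k / n
        out.append(PowerSummary(lam=lam, test_name=test, study_type=study,
                                n_replicates=n, n_significant=k, power=pw,
                                se=float(np.sqrt(pw * (1 - pw) / n)),
                                threshold=thr))
    return pd.DataFrame([o.__dict__ for o in out])


def pvalue_ecdf(results: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of p-values per (lambda, test, study), on the
    -log10 scale used for the diagnostic plots; a null test tracks the
    diagonal (slope ~1 against the uniform)."""
    rows = []
    for (lam, test, study), grp in results.groupby(["lambda", "test", "study"]):
        p = np.sort(grp["p"].dropna().to_numpy())
        if p.size == 0:
            continue
        ecdf = np.arange(1, p.size + 1) / p.size
        for pi, ei in zip(p, ecdf):
            rows.append({"lambda": lam, "test": test, "study": study,
                         "p": pi, "neglog10_p": -np.log10(max(pi, 1e-300)),
                         "ecdf": ei})
    return pd.DataFrame(rows)


def top_hit_maf_distribution(panel: CaseControlPanel, n_chips: int,
                             rng: np.random.Generator,
                             bins=None, alpha: float = assoc.SINGLE_MARKER_ALPHA):
    """Monte-Carlo distribution of the case minor-allele frequency of the
    most significant marker across ascertained 'imperfect chips'.

    For each chip (heterozygosity-thinned common-marker subset), the most
    significant logistic marker is recorded if it reaches ``alpha``; the
    minor allele is defined in the general population and its frequency
    measured in cases.  Returns (bin_edges, expected_counts) with counts
    normalized per panel (summed over chips / n_chips).
    """
    if bins is None:
        bins = np.linspace(0.0, 1.0, 21)
    pv = assoc.logistic_scan(panel)  # all markers once; chips subset it
    case = panel.case_mask
    d_case = panel.dosages[case].sum(axis=0) / (2.0 * case.sum())
    mid = panel.markers["minor_is_derived"].to_numpy()
    case_maf = np.where(mid, d_case, 1.0 - d_case)
    counts = np.zeros(len(bins) - 1)
    for _ in range(n_chips):
        chip = ascertain_chip(panel, rng)
        if chip.size == 0:
            continue
        pc = pv[chip]
        if not np.isfinite(pc).any():
            continue
        j = chip[np.nanargmin(pc)]
        if pv[j] <= alpha:
            b = np.clip(np.digitize(case_maf[j], bins) - 1, 0, len(bins) - 2)
            counts[b] += 1
    return bins, counts / n_chips


def heritability_replicates(lam: float, n_replicates: int, base_seed: int,
                            N: int = 1000, params: SimParams | None = None) -> np.ndarray:
    """Realized broad-sense heritability Var(G)/Var(P), one value per
    replicate population.

    By default uses the Ns-preserving causative-only parameterization of
    ``h2_scaled_params`` at the given N.
    """
    from . import phenotype as phen

    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        rng_sim, rng_panel, _ = replicate_rng_streams(base_seed, rep)
        p = params if params is not None else h2_scaled_params(lam, N=N)
        pop = evolve(p, rng=rng_sim)
        ph = phen.population_phenotypes(pop, rng_panel)
        out[rep] = phen.broad_sense_heritability(ph["G"], ph["P"])
    return out
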