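"""Genotype -> phenotype -> fitness map for the gene-based liability model.

The model treats the gene region as a single complementation unit: the
effect of one haplotype is additive over the causative mutations it carries,
and the genotypic value of a diploid is the *geometric mean* of its two
haplotype effect sums.  A wild-type (mutation-free) haplotype therefore
fully rescues the phenotype, making mutations within the region partially
recessive and mutually non-complementing, as for alleles of a classical
Mendelian gene.  Liability is the genotypic value plus Gaussian noise, and
fitness is Gaussian stabilizing selection on liability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "haplotype_effect",
    "genotypic_value",
    "phenotype",
    "fitness",
    "broad_sense_heritability",
    "alternative_gene_action",
    "population_phenotypes",
]

GENE_ACTION_MODELS = ("gene", "additive", "dominant", "recessive")


def haplotype_effect(carrier, effects) -> float | np.ndarray:
    """Additive effect sum of one haplotype.

    Parameters
    ----------
    carrier : array-like
        0/1 indicator(s) over mutation columns; either a single haplotype
        vector of length L or a matrix (n_haplotypes, L).
    effects : array-like
        Per-mutation liability effects (0 for neutral markers).
    """
    carrier = np.asarray(carrier)
    effects = np.asarray(effects, dtype=float)
    return carrier.astype(float) @ effects


def genotypic_value(E1, E2):
    """Geometric mean of the two haplotype effect sums.

    The value depends only on the two per-haplotype sums, not on which
    particular mutations sit on which haplotype (cis/trans arrangements with
    equal sums are phenotypically equivalent), and one mutation-free
    haplotype forces a genotypic value of zero.
    """
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if np.any(E1 < 0) or np.any(E2 < 0):
        raise ValueError("haplotype effect sums must be non-negative")
    return np.sqrt(E1 * E2)


def phenotype(G, sigma_e, rng):
    """Liability: genotypic value plus N(0, sigma_e^2) environmental noise."""
    G = np.asarray(G, dtype=float)
    if sigma_e == 0:
        return G.copy()
    return G + rng.normal(0.0, sigma_e, size=G.shape)


def fitness(P, sigma_s, optimum=0.0):
    """Gaussian stabilizing selection: w = exp(-(P-optimum)^2 / (2 sigma_s^2))."""
    P = np.asarray(P, dtype=float)
    return np.exp(-((P - optimum) ** 2) / (2.0 * sigma_s**2))


def broad_sense_heritability(G, P) -> float:
    """Realized broad-sense heritability Var(G)/Var(P) of a population.

    Computed on the realized genotypic values and liabilities (not from
    allelic variance components).
    """
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    if G.size < 2:
        raise ValueError("need at least 2 individuals")
    vp = np.var(P, ddof=1)
    if vp == 0:
        raise ValueError("zero phenotypic variance")
    return float(np.var(G, ddof=1) / vp)


def alternative_gene_action(E1, E2, model: str):
    """Genotypic value under alternative gene-action models.

    ``gene`` is the geometric-mean model actually simulated; ``additive``
    (E1+E2), ``dominant`` (max) and ``recessive`` (min) are the standard
    comparison models, computed from the same haplotype sums.  By the AM-GM
    inequality the gene-based value always lies between the recessive and
    additive values.
    """
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if model == "gene":
        return genotypic_value(E1, E2)
    if model == "additive":
        return E1 + E2
    if model == "dominant":
        return np.maximum(E1, E2)
    if model == "recessive":
        return np.minimum(E1, E2)
    raise ValueError(f"unknown gene-action model {model!r}; choose from {GENE_ACTION_MODELS}")


def population_phenotypes(pop, rng) -> pd.DataFrame:
    """Realized phenotype table for every diploid in a population.

    Returns a DataFrame with columns E1, E2 (haplotype effect sums including
    any fixed causative burden), G (genotypic value), x (environmental
    deviate), P (liability) and w (relative fitness).
    """
    E = pop.haplotype_effect_sums()
    E1, E2 = E[0::2], E[1::2]
    G = genotypic_value(E1, E2)
    x = rng.normal(0.0, pop.sigma_e, size=G.shape) if pop.sigma_e > 0 else np.zeros_like(G)
    P = G + x
    w = fitness(P, pop.sigma_s, optimum=pop.optimum)
    return pd.DataFrame({"E1": E1, "E2": E2, "G": G, "x": x, "P": P, "w": w})
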