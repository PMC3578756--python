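"""Simulation parameters for the gene-region model.

The simulated unit is a contiguous gene region (scaled to ~100 kb of a
typical human genome at full size) in a panmictic Wright-Fisher population
of ``N`` diploids.  Two mutation classes arise each generation: neutral
markers (effect 0) and causative mutations whose liability effects are
exponentially distributed with mean ``lambda_effect``.  Phenotypes are
liabilities under Gaussian stabilizing selection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SimParams:
    """Parameters of a single forward simulation run.

    Parameters
    ----------
    N : int
        Diploid population size.
    mu_neutral : float
        Neutral mutation rate per gamete per generation.
    mu_causative : float
        Causative (deleterious) mutation rate per gamete per generation.
    r : float
        Recombination rate per diploid per generation (expected crossovers
        per gamete, uniform along the region).
    lambda_effect : float
        Mean of the exponential distribution of causative effect sizes, in
        liability units.  ``0`` makes causative-class mutations phenotypically
        silent (control simulations).
    sigma_e : float
        Standard deviation of the Gaussian environmental deviate added to
        the genotypic value (liability units).
    sigma_s : float
        Standard deviation of the Gaussian stabilizing-selection fitness
        function (liability units).
    n_generations : int
        Number of generations to evolve (8N for equilibrium runs).
    seed : int
        Seed for the per-run random number generator.
    recenter_optimum : bool
        If True (default), the stabilizing-selection optimum tracks the
        fixed causative burden, so fixation of a causative mutation does not
        permanently displace the population from the optimum.
    """

    N: int
    mu_neutral: float
    mu_causative: float
    r: float
    lambda_effect: float
    sigma_e: float = 0.075
    sigma_s: float = 1.0
    n_generations: int = 0
    seed: int = 0
    recenter_optimum: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        for name in ("mu_neutral", "mu_causative", "r", "lambda_effect", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")

    # -- scaled parameterizations ------------------------------------------

    @classmethod
    def from_scaled(
        cls,
        N: int,
        theta: float = 100.0,
        theta_d: float = 10.0,
        rho: float = 100.0,
        lambda_effect: float = 0.0,
        sigma_e: float = 0.075,
        sigma_s: float = 1.0,
        n_generations: int | None = None,
        seed: int = 0,
        no_neutral: bool = False,
        recenter_optimum: bool = True,
    ) -> "SimParams":
        """Build parameters from the scaled quantities theta=4N*mu,
        theta_d=4N*mu_d and rho=4N*r, so that reduced-N runs preserve the
        full-scale scaled parameters.

        ``no_neutral`` sets the neutral rate to zero (causative sites only),
        which is orders of magnitude faster and leaves the phenotypic model
        untouched.
        """
        mu = 0.0 if no_neutral else theta / (4.0 * N)
        mu_d = theta_d / (4.0 * N)
        r = rho / (4.0 * N)
        if n_generations is None:
            n_generations = 8 * N
        return cls(
            N=N,
            mu_neutral=mu,
            mu_causative=mu_d,
            r=r,
            lambda_effect=lambda_effect,
            sigma_e=sigma_e,
            sigma_s=sigma_s,
            n_generations=n_generations,
            seed=seed,
            recenter_optimum=recenter_optimum,
        )

    @classmethod
    def full_scale(cls, lambda_effect: float, seed: int = 0, **kw) -> "SimParams":
        """The full-scale parameterization: N=20,000, mu=0.00125,
        mu_d=0.1*mu, r=0.00125, 8N generations (theta=rho=100, theta_d=10)."""
        return cls(
            N=20_000,
            mu_neutral=0.00125,
            mu_causative=0.000125,
            r=0.00125,
            lambda_effect=lambda_effect,
            n_generations=160_000,
            seed=seed,
            **kw,
        )

    @property
    def mu_total(self) -> float:
        return self.mu_neutral + self.mu_causative

    @property
    def theta(self) -> float:
        return 4.0 * self.N * self.mu_neutral

    @property
    def theta_d(self) -> float:
        return 4.0 * self.N * self.mu_causative

    @property
    def rho(self) -> float:
        return 4.0 * self.N * self.r

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)
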